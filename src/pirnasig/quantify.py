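"""TE-level quantification (counts, pkb, rpkm), normalization, and
differential expression with the study's cutoffs.

pkb ("piRNAs per kilobase") is aligned-read weight on a transposon divided
by its length and multiplied by 1000; rpkm additionally scales by mapped
library size in millions. Normalization is median-of-ratios; the DE engine
is a Welch t-test on log2(normalized + 0.5) with Benjamini-Hochberg
adjustment, calling up/down at p_adj <= 0.05 and |log2FC| >= 0.58 by
default. A pure fold-change mode (2-fold cutoff, no test) is provided for
single-replicate piRNA comparisons.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mapping import TEConsensus

DE_COLUMNS = ["feature", "baseMeanA", "baseMeanB", "log2fc", "p", "p_adj", "call"]


@dataclass
class TECountTable:
    """Raw counts per (TE [x strand]) x sample plus TE lengths.

    ``counts`` is features x samples; for per-strand tables the index is
    "TE:strand". ``library_size`` defaults to per-sample column totals.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    sample_genotype: dict[str, str] = field(default_factory=dict)
    library_size: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)

    def _feature_lengths(self) -> pd.Series:
        base = self.counts.index.to_series().str.split(":").str[0]
        return base.map(self.lengths)

    def pkb(self) -> pd.DataFrame:
        """counts / length * 1000 per cell."""
        return self.counts.div(self._feature_lengths(), axis=0) * 1000.0

    def rpkm(self) -> pd.DataFrame:
        """counts / (length_kb * mapped reads in millions) per cell."""
        per_kb = self.counts.div(self._feature_lengths() / 1000.0, axis=0)
        return per_kb.div(self.library_size / 1e6, axis=1)

    def samples_of(self, genotype: str) -> list[str]:
        return [s for s, g in self.sample_genotype.items() if g == genotype]


def quantify_te(
    alignments: pd.DataFrame,
    panel: list[TEConsensus],
    per_strand: bool = False,
    min_species_count: int = 0,
    species: pd.DataFrame | None = None,
) -> pd.Series:
    """Sum apportioned alignment weights per TE (optionally per strand).

    ``min_species_count`` applies the >=N read-count species filter before
    summing (used for piRNA-level analyses); it requires the species table.
    Returns a Series indexed by TE id (or "TE:strand") covering every panel
    entry, zeros included.
    """
    known = {te.id for te in panel}
    bad = set(alignments["ref_id"]) - known
    if bad:
        raise ValueError(f"alignments reference TEs absent from panel: {sorted(bad)[:5]}")
    aln = alignments
    if min_species_count > 0:
        if species is None:
            raise ValueError("min_species_count filter requires the species table")
        keep = set(species.loc[species["count"] >= min_species_count, "species_id"])
        aln = aln[aln["species_id"].isin(keep)]
    if per_strand:
        key = aln["ref_id"] + ":" + aln["strand"]
        index = [f"{te.id}:{s}" for te in panel for s in "+-"]
    else:
        key = aln["ref_id"]
        index = [te.id for te in panel]
    sums = aln.groupby(key)["weight"].sum()
    return sums.reindex(index, fill_value=0.0).rename("count")


def normalize_counts(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios size factors (geometric mean over zero-free features).

    Falls back to total-count scaling, with a warning, when no feature is
    zero-free.
    """
    if counts.shape[1] < 2:
        raise ValueError("normalization needs >= 2 samples")
    arr = counts.to_numpy(dtype=float)
    zero_free = (arr > 0).all(axis=1)
    if zero_free.any():
        logs = np.log(arr[zero_free])
        geomean = logs.mean(axis=1)
        ratios = logs - geomean[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    else:
        warnings.warn("no zero-free features; falling back to total-count scaling")
        totals = arr.sum(axis=0)
        factors = totals / totals.mean() if totals.mean() > 0 else np.ones(arr.shape[1])
    size_factors = pd.Series(factors, index=counts.columns, name="size_factor")
    return counts.div(size_factors, axis=1), size_factors


def _welch_p(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # zero within-group variance in both groups with equal means -> no evidence
    return np.where(np.isnan(p), 1.0, p)


def differential_expression(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    alpha: float = 0.05,
    lfc_theta: float = 0.58,
    method: str = "welch_log",
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature differential abundance of group B vs group A.

    Counts are median-of-ratios normalized across the union of samples;
    log2FC = log2((meanB + 0.5) / (meanA + 0.5)); p-values from a two-sided
    Welch t on log2(normalized + 0.5) (or a label-permutation null of the
    same statistic); BH adjustment over all tested features. Features with
    zero counts in every sample are dropped before testing.
    """
    if method not in ("welch_log", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    min_reps = 2 if method == "welch_log" else 3
    if len(group_a) < min_reps or len(group_b) < min_reps:
        raise ValueError(f"{method} needs >= {min_reps} replicates per group")
    sub = counts[group_a + group_b]
    sub = sub[(sub.sum(axis=1) > 0)]
    norm, _ = normalize_counts(sub)
    a = norm[group_a].to_numpy(dtype=float)
    b = norm[group_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))
    log_all = np.log2(np.concatenate([a, b], axis=1) + 0.5)
    na = len(group_a)
    obs_p = _welch_p(log_all[:, :na], log_all[:, na:])
    if method == "welch_log":
        p = obs_p
    else:
        rng = np.random.default_rng(seed % (2**31))
        obs_t = _welch_t(log_all[:, :na], log_all[:, na:])
        n_total = log_all.shape[1]
        perms = [p for p in itertools.combinations(range(n_total), na)]
        if len(perms) > n_permutations:
            idx = rng.choice(len(perms), size=n_permutations, replace=False)
            perms = [perms[i] for i in idx]
        exceed = np.zeros(log_all.shape[0])
        for pa in perms:
            pb = [i for i in range(n_total) if i not in pa]
            t = _welch_t(log_all[:, list(pa)], log_all[:, pb])
            exceed += np.abs(t) >= np.abs(obs_t) - 1e-12
        p = exceed / len(perms)
    p_adj = multipletests(p, method="fdr_bh")[1]
    call = np.where(
        (p_adj <= alpha) & (log2fc >= lfc_theta),
        "up",
        np.where((p_adj <= alpha) & (log2fc <= -lfc_theta), "down", "unchanged"),
    )
    return pd.DataFrame(
        {
            "feature": sub.index,
            "baseMeanA": mean_a,
            "baseMeanB": mean_b,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "call": call,
        }
    ).reset_index(drop=True)


def _welch_t(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    return np.where(np.isnan(t), 0.0, t)


def fold_change_calls(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    cutoff: float = 2.0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Pure fold-change mode (no test): up/down at a linear-fold cutoff.

    Used for the piRNA-level 2-fold analyses. Returns
    [feature, meanA, meanB, fc, call] with fc = (meanB+0.5)/(meanA+0.5).
    """
    sub = counts[group_a + group_b]
    if normalize and sub.shape[1] >= 2:
        sub, _ = normalize_counts(sub)
    mean_a = sub[group_a].mean(axis=1)
    mean_b = sub[group_b].mean(axis=1)
    fc = (mean_b + 0.5) / (mean_a + 0.5)
    call = np.where(fc >= cutoff, "up", np.where(fc <= 1.0 / cutoff, "down", "unchanged"))
    return pd.DataFrame(
        {"feature": sub.index, "meanA": mean_a.to_numpy(), "meanB": mean_b.to_numpy(),
         "fc": fc.to_numpy(), "call": call}
    ).reset_index(drop=True)


def split_strand_fc(
    sense: pd.DataFrame, antisense: pd.DataFrame, both: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Join per-strand fold-change tables into one record per TE.

    Inputs are fold-change tables whose ``feature`` is "TE:+" / "TE:-"
    (or plain TE ids for the both-strand table). TEs missing from one
    strand are flagged, not dropped.
    """
    def strip(frame, suffix):
        f = frame.copy()
        f["te_id"] = f["feature"].str.replace(r":[+-]$", "", regex=True)
        if f["te_id"].duplicated().any():
            raise ValueError("duplicated TE ids after strand strip")
        return f.set_index("te_id")[["fc", "call"]].rename(
            columns={"fc": f"fc_{suffix}", "call": f"call_{suffix}"}
        )

    joined = strip(sense, "sense").join(strip(antisense, "antisense"), how="outer")
    if both is not None:
        joined = joined.join(strip(both, "both"), how="outer")
    joined["missing_strand"] = joined.filter(like="fc_").isna().any(axis=1)
    return joined.reset_index()
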