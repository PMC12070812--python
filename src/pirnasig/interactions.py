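"""Downstream analytics: genetic-interaction (GI) scores for double
mutants, length x expression quadrant analysis of de-silenced TEs,
concomitant sense/antisense reduction grouping, and PIWI-clade IP piRNA
group assignment.

The GI score of a TE is the linear fold change in the double mutant
(vs. the shared control) divided by the *sum* of its fold changes in the
two single mutants; GI > 1 means the double mutant exceeds the combined
single-mutant effects and GI > 2 flags strong positive interaction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

QUADRANTS = ("long-high", "long-low", "short-high", "short-low")


def gi_scores(
    fc_double: pd.Series,
    fc_single1: pd.Series,
    fc_single2: pd.Series,
    strong_cutoff: float = 2.0,
    desilenced: set[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-TE GI records plus a summary over a de-silenced subset.

    Fold changes are linear, all against the same control; TEs missing
    from any input are excluded (and listed in the frame attrs). The
    summary reports, over the de-silenced subset (all TEs if None), the
    count and percent with GI > strong_cutoff.
    """
    frames = pd.concat(
        {"fc_double": fc_double, "fc_single1": fc_single1, "fc_single2": fc_single2}, axis=1
    )
    excluded = frames.index[frames.isna().any(axis=1)].tolist()
    frames = frames.dropna()
    denom = frames["fc_single1"] + frames["fc_single2"]
    gi = frames["fc_double"].where(denom > 0) / denom.where(denom > 0)
    records = pd.DataFrame(
        {
            "te_id": frames.index,
            "fc_double": frames["fc_double"].to_numpy(),
            "fc_single1": frames["fc_single1"].to_numpy(),
            "fc_single2": frames["fc_single2"].to_numpy(),
            "gi": gi.to_numpy(),
            "positive": (gi > 1.0).to_numpy(),
            "strong": (gi > strong_cutoff).to_numpy(),
        }
    ).reset_index(drop=True)
    records.attrs["excluded"] = excluded
    scope = records if desilenced is None else records[records["te_id"].isin(desilenced)]
    n = len(scope)
    n_strong = int(scope["strong"].sum())
    summary = {
        "n_tes": n,
        "n_strong": n_strong,
        "percent_strong": 100.0 * n_strong / n if n else float("nan"),
    }
    return records, summary


def quadrant_analysis(
    lengths: pd.Series,
    rpkm: pd.Series,
    desilenced: set[str],
    len_cut_log10: float = 3.7,
    expr_cut_log10: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition TEs into length x expression quadrants and summarize
    where the de-silenced ones fall.

    "long" iff log10(length) >= len_cut_log10 (~5 kb); "high" iff
    log10(rpkm) >= expr_cut_log10 (10 rpkm); boundaries assign upward.
    Zero-expression TEs go to "low" (flagged). Per quadrant the summary
    gives total TEs, de-silenced TEs, the distribution percent (share of
    all de-silenced TEs), and the density percent (de-silenced / total
    within the quadrant x 100).
    """
    if (lengths <= 0).any():
        raise ValueError("TE length <= 0")
    common = lengths.index.intersection(rpkm.index)
    lengths, rpkm = lengths[common], rpkm[common]
    long = np.log10(lengths) >= len_cut_log10
    zero_expr = rpkm <= 0
    with np.errstate(divide="ignore"):
        high = np.where(zero_expr, False, np.log10(rpkm.where(rpkm > 0)) >= expr_cut_log10)
    quadrant = np.where(
        long, np.where(high, "long-high", "long-low"), np.where(high, "short-high", "short-low")
    )
    records = pd.DataFrame(
        {
            "te_id": common,
            "log10_length": np.log10(lengths).to_numpy(),
            "log10_rpkm": np.where(zero_expr, -np.inf, np.log10(rpkm.replace(0, np.nan)).to_numpy()),
            "quadrant": quadrant,
            "zero_expression": zero_expr.to_numpy(),
            "desilenced": [t in desilenced for t in common],
        }
    )
    n_desil_total = int(records["desilenced"].sum())
    rows = []
    for q in QUADRANTS:
        in_q = records[records["quadrant"] == q]
        n_total, n_desil = len(in_q), int(in_q["desilenced"].sum())
        rows.append(
            {
                "quadrant": q,
                "n_total": n_total,
                "n_desilenced": n_desil,
                "distribution_percent": 100.0 * n_desil / n_desil_total if n_desil_total else float("nan"),
                "density_percent": 100.0 * n_desil / n_total if n_total else float("nan"),
            }
        )
    return records, pd.DataFrame(rows)


def concomitant_grouping(
    strand_fc: pd.DataFrame,
    reduced_both: set[str],
    cutoff: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Group TEs with both-strand piRNA reduction by which strand drives it.

    Over TEs in ``reduced_both`` (both-strand piRNAs down >= cutoff-fold):
    group 1 if the sense reduction is at least cutoff-fold stronger than
    the antisense (fc_sense <= fc_antisense / cutoff), group 3 for the
    mirror case, group 2 otherwise. Also reports what percent of the
    reduced set has sense (resp. antisense) piRNAs concomitantly reduced
    >= cutoff-fold.
    """
    sub = strand_fc[strand_fc["te_id"].isin(reduced_both)].dropna(subset=["fc_sense", "fc_antisense"])
    fs, fa = sub["fc_sense"].to_numpy(), sub["fc_antisense"].to_numpy()
    group = np.where(fs <= fa / cutoff, 1, np.where(fa <= fs / cutoff, 3, 2))
    records = pd.DataFrame({"te_id": sub["te_id"].to_numpy(), "fc_sense": fs, "fc_antisense": fa, "group": group})
    n = len(records)
    summary = {
        "n_tes": n,
        "percent_group": {
            g: 100.0 * int((group == g).sum()) / n if n else float("nan") for g in (1, 2, 3)
        },
        "percent_sense_reduced": 100.0 * int((fs <= 1.0 / cutoff).sum()) / n if n else float("nan"),
        "percent_antisense_reduced": 100.0 * int((fa <= 1.0 / cutoff).sum()) / n if n else float("nan"),
    }
    return records, summary


def ip_group_assignment(
    ip_counts: pd.DataFrame,
    libraries: tuple[str, str, str] = ("aub", "ago3", "piwi"),
    fold: float = 3.0,
    pseudocount: float = 0.5,
    min_count: int = 5,
) -> pd.DataFrame:
    """Assign piRNA species to the PIWI-clade protein whose IP enriches them.

    ``ip_counts`` holds one row per species ("sequence" column) and one raw
    count column per IP library. Counts are normalized to counts-per-million
    per library and pseudocounted; a species is assigned to a protein iff
    its CPM is >= fold x CPM in *both* other IPs (groups are mutually
    exclusive by construction), else "ambiguous". Species below
    ``min_count`` raw counts in every library are dropped.
    """
    if len(libraries) != 3:
        raise ValueError("exactly three IP libraries are required")
    missing = [c for c in libraries if c not in ip_counts.columns]
    if missing:
        raise ValueError(f"missing IP columns: {missing}")
    raw = ip_counts[list(libraries)].to_numpy(dtype=float)
    keep = (raw >= min_count).any(axis=1)
    kept = ip_counts.loc[keep].reset_index(drop=True)
    raw = raw[keep]
    totals = raw.sum(axis=0)
    cpm = raw / np.where(totals > 0, totals, 1.0) * 1e6 + pseudocount
    names = {"aub": "Aub", "ago3": "Ago3", "piwi": "Piwi"}
    assigned = np.full(len(kept), "ambiguous", dtype=object)
    for i, lib in enumerate(libraries):
        others = [j for j in range(3) if j != i]
        wins = (cpm[:, i] >= fold * cpm[:, others[0]]) & (cpm[:, i] >= fold * cpm[:, others[1]])
        assigned[wins] = names.get(lib, lib)
    out = kept.copy()
    out["assigned"] = assigned
    for i, lib in enumerate(libraries):
        out[f"cpm_{lib}"] = cpm[:, i]
    return out


def ip_group_overlap(
    species: pd.DataFrame, ip_assignments: pd.DataFrame
) -> dict[str, float]:
    """Fraction of a sample's read count matching each IP group's sequences.

    Returns percent of total sample reads whose species sequence belongs to
    each assigned group, plus "any" for the union of the three groups.
    """
    total = species["count"].sum()
    if total == 0:
        raise ValueError("empty sample")
    out = {}
    group_seqs = {}
    for g in ("Aub", "Ago3", "Piwi"):
        group_seqs[g] = set(ip_assignments.loc[ip_assignments["assigned"] == g, "sequence"])
        matched = species.loc[species["sequence"].isin(group_seqs[g]), "count"].sum()
        out[g] = 100.0 * matched / total
    union = group_seqs["Aub"] | group_seqs["Ago3"] | group_seqs["Piwi"]
    out["any"] = 100.0 * species.loc[species["sequence"].isin(union), "count"].sum() / total
    return out
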