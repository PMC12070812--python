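"""Synthetic ovary small-RNA libraries with planted piRNA structure.

The generator emits collapsed-read libraries over a random consensus-TE
panel with the hallmarks the analysis stack measures:

* ping-pong pairs — a sense read with 5' at s and an antisense partner with
  5' at s+9 in reference coordinates, i.e. an exact 10-nt 5'-5' overlap,
  with a tunable probability that the sense read carries A at position 10;
* phased trails — head-to-tail runs of same-strand reads (3'-to-5' junction
  distance 0) whose ~26-27 nt lengths create a ~27-nt 5'-5' periodicity,
  with a tunable probability that each read starts on a T (the 1U bias);
* uniform background noise reads;
* multi-mapping bait via duplicated 60-nt segments shared between TE pairs.

Biases are imposed by *placement*, never by mutating read sequences: a coin
with the target probability decides whether the constrained base (the 5'
base for 1U, the 10th sense base for 10A) must match, and the placement is
then sampled conditional on that outcome. Reads therefore stay perfect
matches to their source TE and the realized marginal bias equals the target
exactly. At phased-trail junctions the 5' position is fixed by the upstream
read's 3' end, so the condition is imposed through the upstream read's
length; when no length in the 23-28 nt window satisfies it the trail simply
terminates early.

Library depth (``n_reads``) counts reads *including* duplicate copies; each
planted read receives a copy count of 1 + Poisson(copies_mean - 1), so the
collapsed library contains species with a realistic count spectrum around
the >=5-count eligibility threshold used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._utils import child_rng, revcomp
from .mapping import TEConsensus

GT_COLUMNS = ["read_id", "te_id", "strand", "start", "end", "pathway", "group_id", "count"]


@dataclass(frozen=True)
class TEPanelSpec:
    """Parameters for a random consensus-TE panel."""

    n_te: int
    length_range: tuple[int, int] = (500, 5000)
    repeat_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if self.n_te < 1:
            raise ValueError("n_te must be >= 1")
        if not (100 <= lo <= hi):
            raise ValueError(f"invalid length_range {self.length_range}")
        if not 0.0 <= self.repeat_fraction <= 1.0:
            raise ValueError("repeat_fraction must be in [0,1]")


@dataclass(frozen=True)
class LibrarySimSpec:
    """Parameters for one simulated small-RNA library."""

    n_reads: int = 50_000
    pingpong_fraction: float = 0.3
    phased_fraction: float = 0.3
    noise_fraction: float | None = None  # None -> 1 - pingpong - phased
    read_len_mean: float = 26.5
    read_len_sd: float = 1.5
    u1_prob: float = 0.78
    a10_prob: float = 0.65
    copies_mean: float = 8.0
    trail_mean_reads: float = 6.0
    sense_scale: float = 1.0
    antisense_scale: float = 1.0
    genotype: str = "WT"
    seed: int = 0

    def __post_init__(self):
        for name in ("pingpong_fraction", "phased_fraction", "u1_prob", "a10_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        noise = self.noise_fraction
        if noise is not None and not 0.0 <= noise <= 1.0:
            raise ValueError("noise_fraction outside [0,1]")
        total = self.pingpong_fraction + self.phased_fraction + (noise or 0.0)
        if total > 1.0 + 1e-9:
            raise ValueError(f"fractions sum to {total} > 1")
        if self.sense_scale < 0 or self.antisense_scale < 0:
            raise ValueError("strand scales must be >= 0")

    @property
    def resolved_noise_fraction(self) -> float:
        """Noise absorbs whatever the planted pathways do not claim."""
        return 1.0 - self.pingpong_fraction - self.phased_fraction


@dataclass(frozen=True)
class ConditionEffect:
    """Genotype-level suppression of piRNA pathways and TE expression."""

    genotype: str
    pingpong_scale: float = 1.0
    phased_scale: float = 1.0
    sense_scale: float = 1.0
    antisense_scale: float = 1.0
    te_fc_map: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("pingpong_scale", "phased_scale", "sense_scale", "antisense_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.te_fc_map.values()):
            raise ValueError("te_fc_map values must be >= 0")


def generate_te_panel(spec: TEPanelSpec) -> list[TEConsensus]:
    """Random ACGT consensus sequences with lengths log-uniform in range.

    ``repeat_fraction`` of the TEs are grouped into pairs that share one
    exact copied 60-nt segment, creating genuine multi-mapping species.
    """
    rng = child_rng(spec.seed, 0)
    lo, hi = spec.length_range
    lengths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=spec.n_te)).round().astype(int)
    lengths = np.clip(lengths, lo, hi)
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, size=int(L))]) for L in lengths]

    n_shared = int(round(spec.repeat_fraction * spec.n_te))
    for a, b in zip(range(0, n_shared - 1, 2), range(1, n_shared, 2)):
        src, dst = seqs[a], seqs[b]
        i = int(rng.integers(0, len(src) - 60 + 1))
        j = int(rng.integers(0, len(dst) - 60 + 1))
        seqs[b] = dst[:j] + src[i : i + 60] + dst[j + 60 :]

    return [TEConsensus(f"TE{i:04d}", seq, "germline") for i, seq in enumerate(seqs)]


def apply_condition_effect(spec: LibrarySimSpec, effect: ConditionEffect) -> LibrarySimSpec:
    """Scale the pathway fractions of a library spec; slack renormalizes into noise."""
    pp = spec.pingpong_fraction * effect.pingpong_scale
    ph = spec.phased_fraction * effect.phased_scale
    if pp + ph > 1.0 + 1e-9:
        raise ValueError("scaled fractions exceed 1")
    return replace(
        spec,
        pingpong_fraction=pp,
        phased_fraction=ph,
        noise_fraction=None,
        sense_scale=spec.sense_scale * effect.sense_scale,
        antisense_scale=spec.antisense_scale * effect.antisense_scale,
        genotype=effect.genotype,
    )


def _length_pmf(mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    """Probability mass of the rounded, clipped normal length distribution
    over lo..hi (the clip bounds absorb the tails)."""
    from scipy.stats import norm

    edges = np.arange(lo, hi + 1, dtype=float)
    pmf = norm.cdf(edges + 0.5, mean, sd) - norm.cdf(edges - 0.5, mean, sd)
    pmf[0] += norm.cdf(lo - 0.5, mean, sd)
    pmf[-1] += norm.sf(hi + 0.5, mean, sd)
    return pmf / pmf.sum()


def _junction_coin_prob(u1: float, n_cand: int) -> float:
    """Coin probability that makes the marginal junction 1U equal u1.

    At a trail junction the next read's 5' base is chosen through the
    upstream read's length among ``n_cand`` candidates. Under the uniform
    background base model (each base frequency 1/4), the probability that
    no candidate junction is a T is e_N = (3/4)^n and that none is a non-T
    is e_T = (1/4)^n; when the wanted set is empty the other set must be
    used, so the realized marginal is q * (1 - e_N) + (1 - q) * e_T.
    Solving for the target marginal u1 gives
    q = (u1 - e_T) / (1 - e_N - e_T), clamped to [0, 1].
    """
    e_n = 0.75**n_cand
    e_t = 0.25**n_cand
    q = (u1 - e_t) / (1.0 - e_n - e_t)
    return float(np.clip(q, 0.0, 1.0))


class _BaseIndex:
    """Per-transcript positions of T and non-T (resp. A/non-A) bases."""

    def __init__(self, seq: str, base: str):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_base = arr == ord(base)
        self.yes = np.nonzero(is_base)[0]
        self.no = np.nonzero(~is_base)[0]

    def sample(self, rng: np.random.Generator, want: bool) -> int | None:
        pool = self.yes if want else self.no
        if len(pool) == 0:
            return None
        return int(pool[rng.integers(0, len(pool))])


def _draw_length(rng, mean, sd, lo, hi) -> int:
    return int(np.clip(np.round(rng.normal(mean, sd)), lo, hi))


def _copies(rng, mean: float) -> int:
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def _thin(rng, copies: int, scale: float) -> int:
    if scale == 1.0:
        return copies
    if scale < 1.0:
        return int(rng.binomial(copies, scale))
    whole, frac = divmod(copies * scale, 1.0)
    return int(whole) + (1 if rng.random() < frac else 0)


def simulate_library(
    panel: list[TEConsensus], spec: LibrarySimSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit one library: reads [read_id, sequence, count] + ground truth.

    Every read is an exact substring of its source TE (reverse complement
    for antisense placements); ground truth records the 0-based half-open
    reference interval, strand, pathway, and pair/trail group id.
    """
    if not panel:
        raise ValueError("panel is empty")
    min_len = 23
    if any(te.length < 100 for te in panel):
        raise ValueError("panel sequences too short for read simulation")
    rng = child_rng(spec.seed, 1)

    te_ids = [te.id for te in panel]
    seqs = {te.id: te.sequence.upper() for te in panel}
    lens = {te.id: te.length for te in panel}
    # transcript strings per strand and base indices for conditional placement
    transcripts = {}
    t_index = {}
    a_index = {}
    for te in panel:
        transcripts[(te.id, "+")] = seqs[te.id]
        transcripts[(te.id, "-")] = revcomp(seqs[te.id])
        t_index[(te.id, "+")] = _BaseIndex(transcripts[(te.id, "+")], "T")
        t_index[(te.id, "-")] = _BaseIndex(transcripts[(te.id, "-")], "T")
        a_index[te.id] = _BaseIndex(seqs[te.id], "A")

    te_weights = np.array([lens[t] for t in te_ids], dtype=float)
    te_weights /= te_weights.sum()

    pp_frac = spec.pingpong_fraction
    ph_frac = spec.phased_fraction

    reads: list[tuple[str, str, int]] = []
    gt_rows: list[tuple] = []
    total = 0
    read_no = 0
    group_no = 0

    def emit(seq, te_id, strand, start, end, pathway, group_id) -> None:
        nonlocal total, read_no
        copies = _copies(rng, spec.copies_mean)
        scale = spec.sense_scale if strand == "+" else spec.antisense_scale
        copies = _thin(rng, copies, scale)
        if copies == 0:
            return
        rid = f"r{read_no:07d}"
        read_no += 1
        reads.append((rid, seq, copies))
        gt_rows.append((rid, te_id, strand, start, end, pathway, group_id, copies))
        total += copies

    while total < spec.n_reads:
        u = rng.random()
        te_id = te_ids[rng.choice(len(te_ids), p=te_weights)] if len(te_ids) > 1 else te_ids[0]
        L = lens[te_id]
        if u < pp_frac:
            # --- ping-pong pair ----------------------------------------
            l_s = _draw_length(rng, spec.read_len_mean, spec.read_len_sd, 23, 28)
            l_a = _draw_length(rng, spec.read_len_mean, spec.read_len_sd, 23, 28)
            want_a = rng.random() < spec.a10_prob
            x = None  # reference position of the sense read's 10th base
            for _ in range(64):
                cand = a_index[te_id].sample(rng, want_a)
                if cand is None:
                    break
                s = cand - 9
                if s >= max(0, l_a - 10) and s + l_s <= L and s + 10 <= L:
                    x = cand
                    break
            if x is None:
                continue
            s = x - 9
            group_no += 1
            gid = f"pp{group_no:06d}"
            emit(seqs[te_id][s : s + l_s], te_id, "+", s, s + l_s, "pingpong", gid)
            a_start = s + 10 - l_a
            emit(revcomp(seqs[te_id][a_start : s + 10]), te_id, "-", a_start, s + 10, "pingpong", gid)
        elif u < pp_frac + ph_frac:
            # --- phased trail ------------------------------------------
            strand = "+" if rng.random() < 0.5 else "-"
            T = transcripts[(te_id, strand)]
            idx = t_index[(te_id, strand)]
            want_t = rng.random() < spec.u1_prob
            p = None
            for _ in range(64):
                cand = idx.sample(rng, want_t)
                if cand is not None and cand + min_len <= L:
                    p = cand
                    break
            if p is None:
                continue
            k = int(rng.geometric(1.0 / spec.trail_mean_reads))
            group_no += 1
            gid = f"ph{group_no:06d}"
            lengths_cand = np.arange(23, 29)
            pmf = _length_pmf(spec.read_len_mean, spec.read_len_sd, 23, 28)
            q_junction = _junction_coin_prob(spec.u1_prob, len(lengths_cand))
            for i in range(k):
                last = i == k - 1
                l = None
                if not last and p + 28 + min_len <= L:
                    # choose this read's length so the next 5' base realizes
                    # the junction coin; forced onto the other set when the
                    # wanted one is empty (see _junction_coin_prob)
                    want_next = rng.random() < q_junction
                    is_t = np.array([T[p + int(c)] == "T" for c in lengths_cand])
                    mask = is_t if want_next else ~is_t
                    if not mask.any():
                        mask = ~mask
                    w = pmf * mask
                    l = int(rng.choice(lengths_cand, p=w / w.sum()))
                if l is None:
                    l = _draw_length(rng, spec.read_len_mean, spec.read_len_sd, 23, 28)
                    if p + l > L:
                        break
                    last = True
                if strand == "+":
                    start, end = p, p + l
                else:
                    start, end = L - (p + l), L - p
                emit(T[p : p + l], te_id, strand, start, end, "phased", gid)
                if last:
                    break
                p += l
        else:
            # --- background noise --------------------------------------
            l = _draw_length(rng, spec.read_len_mean, 3.0, 19, 35)
            if L <= l:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(0, L - l + 1))
            seq = seqs[te_id][start : start + l]
            if strand == "-":
                seq = revcomp(seq)
            group_no += 1
            emit(seq, te_id, strand, start, start + l, "noise", f"nz{group_no:06d}")

    reads_df = pd.DataFrame(reads, columns=["read_id", "sequence", "count"])
    gt_df = pd.DataFrame(gt_rows, columns=GT_COLUMNS)
    return reads_df, gt_df


def expand_to_fastq_records(reads: pd.DataFrame, adapter: str = ""):
    """Yield (record_id, sequence) per copy, optionally with a 3' adapter
    suffix appended (so the fixed-length trim step has something to cut)."""
    for read_id, seq, count in reads[["read_id", "sequence", "count"]].itertuples(index=False):
        for j in range(count):
            yield f"{read_id}:{j}", seq + adapter


def simulate_count_table(
    panel: list[TEConsensus],
    genotypes: list[ConditionEffect],
    n_reps: int = 3,
    dispersion: float = 0.1,
    seed: int = 0,
    median_rpkm: float = 10.0,
    rpkm_sigma: float = 1.5,
    library_background: float = 2e7,
):
    """Replicate TE count tables with genotype-specific fold changes.

    Each TE is given a baseline expression level (rpkm, log-normal around
    ``median_rpkm`` with log-sd ``rpkm_sigma``) drawn once, independent of
    its length; baseline mean counts are rpkm x length_kb x millions of
    mapped reads, where ``library_background`` models the non-TE bulk of an
    RNA-seq library (so rpkm values come out on a realistic scale instead
    of treating the TE panel as the whole library). Each genotype's mean is
    baseline x its ``te_fc_map`` entry; replicate counts follow a
    gamma-Poisson (negative-binomial) model with the given dispersion
    (variance = mu + dispersion * mu^2; dispersion 0 is Poisson).

    Returns a :class:`~pirnasig.quantify.TECountTable` whose
    ``library_size`` includes the background, so ``.rpkm()`` recovers the
    planted expression levels.
    """
    from .quantify import TECountTable

    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = child_rng(seed, 2)
    te_ids = [te.id for te in panel]
    lengths_kb = np.array([te.length for te in panel]) / 1000.0
    rpkm = rng.lognormal(np.log(median_rpkm), rpkm_sigma, size=len(te_ids))
    baseline = rpkm * lengths_kb * (library_background / 1e6)

    columns = {}
    sample_genotype = {}
    for effect in genotypes:
        fc = np.array([effect.te_fc_map.get(t, 1.0) for t in te_ids])
        mu = baseline * fc
        for rep in range(1, n_reps + 1):
            if dispersion > 0:
                lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
            else:
                lam = mu
            sample = f"{effect.genotype}_rep{rep}"
            columns[sample] = rng.poisson(lam)
            sample_genotype[sample] = effect.genotype
    counts = pd.DataFrame(columns, index=pd.Index(te_ids, name="te_id"))
    lengths = pd.Series({te.id: te.length for te in panel}, name="length")
    library_size = counts.sum(axis=0) + library_background
    return TECountTable(
        counts=counts, lengths=lengths, sample_genotype=sample_genotype, library_size=library_size
    )


def simulate_ip_libraries(
    reads: pd.DataFrame,
    ground_truth: pd.DataFrame,
    enrichment: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic Aub/Ago3/Piwi immunoprecipitation count columns per species.

    Follows the biology the assignment step assumes: ping-pong sense reads
    are Ago3-bound, ping-pong antisense reads Aub-bound, phased reads
    Piwi-bound, noise unbound. The bound protein's library sees the species
    at ``enrichment`` times its base abundance. Returns
    [sequence, aub, ago3, piwi, true_group].
    """
    rng = child_rng(seed, 3)
    merged = reads.merge(ground_truth[["read_id", "pathway", "strand"]], on="read_id")

    def true_group(row):
        if row.pathway == "pingpong":
            return "Ago3" if row.strand == "+" else "Aub"
        if row.pathway == "phased":
            return "Piwi"
        return "none"

    merged["true_group"] = [true_group(r) for r in merged.itertuples(index=False)]
    per_seq = (
        merged.groupby("sequence")
        .agg(count=("count", "sum"), true_group=("true_group", lambda g: g.mode().iat[0]))
        .reset_index()
    )
    base = per_seq["count"].to_numpy(dtype=float)
    out = {"sequence": per_seq["sequence"], "true_group": per_seq["true_group"]}
    for protein in ("Aub", "Ago3", "Piwi"):
        mu = np.where(per_seq["true_group"] == protein, base * enrichment, base)
        out[protein.lower()] = rng.poisson(mu)
    return pd.DataFrame(out)
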