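"""Ping-pong, phasing, and nucleotide-bias statistics of piRNA libraries.

All distance histograms are weighted pair counts over 5'/3' end positions:
a pair (a, b) contributes weight(a) x weight(b) to its integer distance
bin. Pairs never cross references; per-reference histograms are summed
before scoring, giving a library-level Z (per-reference scoring is a loop
over the same primitives).

Conventions (canonical pairs score the textbook values exactly):

* ping-pong 5'-5': d = antisense_5' - sense_5' + 1 in *reference*
  coordinates, so a 10-nt 5' overlap scores d = 10;
* phasing 3'-to-5': d = 5'(downstream) - 3'(upstream) - 1 in transcript
  orientation, so a head-to-tail junction scores d = 0;
* phasing 5'-to-5': d = 5'(downstream) - 5'(upstream), giving the ~27-nt
  periodicity of phased trails.

Z scores use empty bins as zeros and the sample (n-1) standard deviation:
Z10 against background distances {1..9, 11..20}; Z0 against
{-10..-1} U {1..50}. A zero-sd background leaves the score undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import EndProfile

Z10_BACKGROUND = tuple(range(1, 10)) + tuple(range(11, 21))
Z0_BACKGROUND = tuple(range(-10, 0)) + tuple(range(1, 51))


@dataclass(frozen=True)
class SignatureScore:
    kind: str  # "Z10" or "Z0"
    value: float
    defined: bool
    signal: float
    background_mean: float
    background_sd: float


@dataclass(frozen=True)
class PeakMetrics:
    periodicity: int
    peak_positions: tuple[int, ...]
    peak_values: tuple[float, ...]
    baseline: float
    peak_height: float


@dataclass(frozen=True)
class NucleotideBiasResult:
    scope: str  # sense / antisense / both
    position: int
    base: str
    n_eligible: int
    n_hit: int
    percent: float
    defined: bool


def pair_distance_histogram(
    pos_a: dict[int, float],
    pos_b: dict[int, float],
    shift: int,
    window: tuple[int, int],
    exclude_self: bool = False,
) -> dict[int, float]:
    """Weighted histogram of d = b - a + shift over position pairs.

    ``exclude_self`` skips the a == b term (set it when A and B are the
    same profile and the same end, so a location is never paired with
    itself).
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("empty distance window")
    hist = {d: 0.0 for d in range(lo, hi + 1)}
    for a, wa in pos_a.items():
        for d in range(lo, hi + 1):
            b = a + d - shift
            if exclude_self and b == a:
                continue
            wb = pos_b.get(b)
            if wb is not None:
                hist[d] += wa * wb
    return hist


def _sum_hists(hists: list[dict[int, float]], window: tuple[int, int]) -> dict[int, float]:
    total = {d: 0.0 for d in range(window[0], window[1] + 1)}
    for h in hists:
        for d, v in h.items():
            total[d] += v
    return total


def normalize_histogram(hist: dict[int, float]) -> dict[int, float]:
    peak = max(hist.values(), default=0.0)
    if peak <= 0:
        return dict(hist)
    return {d: v / peak for d, v in hist.items()}


def zscore(hist: dict[int, float], signal: int, background: tuple[int, ...], kind: str) -> SignatureScore:
    bg = np.array([hist.get(d, 0.0) for d in background], dtype=float)
    mean = float(bg.mean())
    sd = float(bg.std(ddof=1))
    sig = float(hist.get(signal, 0.0))
    if sd == 0.0:
        return SignatureScore(kind, float("nan"), False, sig, mean, sd)
    return SignatureScore(kind, (sig - mean) / sd, True, sig, mean, sd)


def pingpong_signature(
    profiles: dict[tuple[str, str], EndProfile],
    window: tuple[int, int] = (1, 30),
) -> tuple[dict[int, float], SignatureScore]:
    """Sense-antisense 5'-5' distance histogram and the Z10 ping-pong score.

    References lacking either strand contribute nothing; an all-empty
    histogram yields an undefined score.
    """
    hists = []
    for (ref_id, strand), prof in profiles.items():
        if strand != "+":
            continue
        anti = profiles.get((ref_id, "-"))
        if anti is None:
            continue
        sense_p5 = prof.p5_reference_coords()
        anti_p5 = anti.p5_reference_coords()
        hists.append(pair_distance_histogram(sense_p5, anti_p5, shift=1, window=window))
    hist = _sum_hists(hists, window)
    return hist, zscore(hist, 10, Z10_BACKGROUND, "Z10")


def phasing_signature(
    profiles: dict[tuple[str, str], EndProfile],
    window_3p5p: tuple[int, int] = (-10, 50),
    window_5p5p: tuple[int, int] = (1, 100),
) -> tuple[dict[int, float], dict[int, float], SignatureScore]:
    """Within-strand 3'-to-5' and 5'-to-5' histograms and the Z0 score.

    Both histograms are computed in transcript orientation and summed over
    every (reference, strand) with mapped reads.
    """
    h35, h55 = [], []
    for prof in profiles.values():
        h35.append(pair_distance_histogram(prof.p3, prof.p5, shift=-1, window=window_3p5p))
        h55.append(
            pair_distance_histogram(prof.p5, prof.p5, shift=0, window=window_5p5p, exclude_self=True)
        )
    hist35 = _sum_hists(h35, window_3p5p)
    hist55 = _sum_hists(h55, window_5p5p)
    return hist35, hist55, zscore(hist35, 0, Z0_BACKGROUND, "Z0")


def peak_baseline_metrics(
    hist: dict[int, float],
    expected_period: int = 27,
    tolerance: int = 2,
    n_peaks: int = 3,
) -> PeakMetrics:
    """Locate periodic peaks and measure peak 1's height above the valley.

    Peak k is the argmax of the histogram within k*period +/- tolerance;
    the baseline is the mean value over distances strictly between peak 1
    and peak 2, excluding +/- tolerance around each; peak height is
    value(peak 1) - baseline.
    """
    if not hist:
        raise ValueError("empty histogram")
    dmax = max(hist)
    if 2 * expected_period - tolerance > dmax:
        raise ValueError("histogram window too small to hold two peaks")
    positions, values = [], []
    for k in range(1, n_peaks + 1):
        lo, hi = k * expected_period - tolerance, k * expected_period + tolerance
        cand = [d for d in range(lo, hi + 1) if d in hist]
        if not cand:
            break
        best = max(cand, key=lambda d: hist[d])
        positions.append(best)
        values.append(hist[best])
    if len(positions) < 2:
        raise ValueError("could not locate two periodic peaks")
    p1, p2 = positions[0], positions[1]
    valley = [d for d in range(p1 + tolerance + 1, p2 - tolerance) if d in hist]
    if len(valley) < 3:
        raise ValueError("valley between peaks holds fewer than 3 distances")
    baseline = float(np.mean([hist[d] for d in valley]))
    return PeakMetrics(
        periodicity=expected_period,
        peak_positions=tuple(positions),
        peak_values=tuple(values),
        baseline=baseline,
        peak_height=values[0] - baseline,
    )


def _species_strands(alignments: pd.DataFrame) -> pd.DataFrame:
    """Per-species strand membership flags derived from its alignments."""
    flags = (
        alignments.assign(
            sense=alignments["strand"] == "+", antisense=alignments["strand"] == "-"
        )
        .groupby("species_id")[["sense", "antisense"]]
        .any()
    )
    return flags


def nucleotide_bias(
    species: pd.DataFrame,
    alignments: pd.DataFrame,
    position: int = 1,
    base: str = "T",
    min_count: int = 5,
) -> dict[str, NucleotideBiasResult]:
    """1U/10A-style positional base bias per strand scope.

    Each aligned species with library count >= ``min_count`` is scored once
    (the binary selector): hit if its sequence carries ``base`` at the
    1-based ``position`` (species shorter than the position are eligible
    non-hits). 'U' is accepted as an alias for 'T'. Returns results for the
    sense, antisense and both-strand scopes.
    """
    base = base.upper().replace("U", "T")
    flags = _species_strands(alignments)
    scoped = species.set_index("species_id").join(flags, how="inner")
    scoped["both"] = True
    eligible = scoped[scoped["count"] >= min_count]
    hit = eligible["sequence"].str.len().ge(position) & (
        eligible["sequence"].str.slice(position - 1, position) == base
    )
    out = {}
    for scope in ("sense", "antisense", "both"):
        members = eligible[eligible[scope]]
        n_el = len(members)
        n_hit = int(hit[members.index].sum())
        if n_el == 0:
            out[scope] = NucleotideBiasResult(scope, position, base, 0, 0, float("nan"), False)
        else:
            out[scope] = NucleotideBiasResult(
                scope, position, base, n_el, n_hit, 100.0 * n_hit / n_el, True
            )
    return out


def ip_overlap_bias(
    species: pd.DataFrame,
    alignments: pd.DataFrame,
    ip_assignments: pd.DataFrame,
    group: str,
    position: int = 10,
    base: str = "A",
    min_count: int = 5,
) -> dict[str, NucleotideBiasResult]:
    """Same selector as :func:`nucleotide_bias`, restricted to the sample
    species whose sequences belong to one IP-assigned group (e.g. the
    Ago3-bound piRNAs)."""
    member_seqs = set(ip_assignments.loc[ip_assignments["assigned"] == group, "sequence"])
    subset = species[species["sequence"].isin(member_seqs)]
    sub_aln = alignments[alignments["species_id"].isin(subset["species_id"])]
    return nucleotide_bias(subset, sub_aln, position=position, base=base, min_count=min_count)


def compare_bias(a: NucleotideBiasResult, b: NucleotideBiasResult) -> tuple[float, float]:
    """Two-proportion z-test for a difference in bias percentages.

    Returns (difference in percent, two-sided p). Both results must be
    defined; the test treats each eligible species as one Bernoulli trial
    of the binary selector.
    """
    if not (a.defined and b.defined):
        raise ValueError("cannot compare undefined bias results")
    from statsmodels.stats.proportion import proportions_ztest

    _, p = proportions_ztest([a.n_hit, b.n_hit], [a.n_eligible, b.n_eligible])
    return a.percent - b.percent, float(p)


def histogram_frame(hist: dict[int, float]) -> pd.DataFrame:
    """Histogram as a tidy table [distance, weight, normalized] for TSV export."""
    norm = normalize_histogram(hist)
    dists = sorted(hist)
    return pd.DataFrame(
        {"distance": dists, "weight": [hist[d] for d in dists], "normalized": [norm[d] for d in dists]}
    )
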