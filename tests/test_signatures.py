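"""Distance histograms, Z scores, peak metrics, and nucleotide biases."""

import math

import numpy as np
import pandas as pd
import pytest

from pirnasig import (
    LibrarySimSpec,
    build_end_profiles,
    align_species,
    nucleotide_bias,
    ip_overlap_bias,
    pair_distance_histogram,
    peak_baseline_metrics,
    phasing_signature,
    pingpong_signature,
    simulate_library,
    simulate_ip_libraries,
    ip_group_assignment,
)
from pirnasig.signatures import Z10_BACKGROUND, zscore
from tests.conftest import collapse_reads


def brute_force_hist(pos_a, pos_b, shift, window, exclude_self=False):
    """O(n^2) oracle: enumerate every position pair."""
    lo, hi = window
    hist = {d: 0.0 for d in range(lo, hi + 1)}
    for a, wa in pos_a.items():
        for b, wb in pos_b.items():
            if exclude_self and a == b:
                continue
            d = b - a + shift
            if lo <= d <= hi:
                hist[d] += wa * wb
    return hist


class TestPairDistanceHistogram:
    def test_single_pingpong_pair(self):
        hist = pair_distance_histogram({100: 1.0}, {109: 1.0}, shift=1, window=(1, 30))
        assert hist[10] == 1.0
        assert sum(hist.values()) == 1.0

    def test_weight_product(self):
        hist = pair_distance_histogram({100: 2.0}, {109: 3.0}, shift=1, window=(1, 30))
        assert hist[10] == 6.0

    @pytest.mark.parametrize("shift,window,exclude", [(1, (1, 30), False), (-1, (-10, 50), False), (0, (1, 100), True)])
    def test_matches_bruteforce_on_random_profiles(self, shift, window, exclude):
        rng = np.random.default_rng(42 + shift)
        pos_a = {int(p): float(w) for p, w in zip(rng.integers(0, 500, 200), rng.random(200) * 5)}
        pos_b = pos_a if exclude else {int(p): float(w) for p, w in zip(rng.integers(0, 500, 200), rng.random(200) * 5)}
        fast = pair_distance_histogram(pos_a, pos_b, shift, window, exclude_self=exclude)
        slow = brute_force_hist(pos_a, pos_b, shift, window, exclude_self=exclude)
        for d in slow:
            assert fast[d] == pytest.approx(slow[d], rel=1e-9, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            pair_distance_histogram({}, {}, 0, (5, 4))


class TestZScores:
    def test_background_alternating_hand_computed(self):
        # background bins alternate 4 and 6; signal bin 55
        hist = {}
        for i, d in enumerate(Z10_BACKGROUND):
            hist[d] = 4.0 if i % 2 == 0 else 6.0
        hist[10] = 55.0
        bg = [hist[d] for d in Z10_BACKGROUND]
        mean = sum(bg) / len(bg)
        sd = math.sqrt(sum((v - mean) ** 2 for v in bg) / (len(bg) - 1))
        score = zscore(hist, 10, Z10_BACKGROUND, "Z10")
        assert score.value == pytest.approx((55.0 - mean) / sd, rel=1e-12)

    def test_uniform_histogram_undefined(self):
        hist = {d: 3.0 for d in range(1, 31)}
        score = zscore(hist, 10, Z10_BACKGROUND, "Z10")
        assert not score.defined
        assert math.isnan(score.value)

    def test_scale_invariance(self, mixed_profiles):
        _, z = pingpong_signature(mixed_profiles)
        scaled = {
            k: type(p)(p.ref_id, p.strand, p.length, {q: 7.5 * w for q, w in p.p5.items()},
                       {q: 7.5 * w for q, w in p.p3.items()})
            for k, p in mixed_profiles.items()
        }
        _, z_scaled = pingpong_signature(scaled)
        assert z_scaled.value == pytest.approx(z.value, rel=1e-9)

    def test_shift_invariance(self, mixed_profiles):
        _, z = pingpong_signature(mixed_profiles)
        h35, h55, z0 = phasing_signature(mixed_profiles)
        shifted = {
            k: type(p)(p.ref_id, p.strand, p.length + 13,
                       {q + 13: w for q, w in p.p5.items()}, {q + 13: w for q, w in p.p3.items()})
            for k, p in mixed_profiles.items()
        }
        # note: +13 on transcript positions AND length keeps reference-coordinate
        # transforms consistent for the minus strand
        _, z_s = pingpong_signature(shifted)
        h35_s, _, z0_s = phasing_signature(shifted)
        assert z0_s.value == pytest.approx(z0.value, rel=1e-9)
        for d in h35:
            assert h35_s[d] == pytest.approx(h35[d], rel=1e-9)


class TestPlantedSignatures:
    def test_pure_pingpong_hist_concentrates_at_10(self, small_panel):
        spec = LibrarySimSpec(n_reads=10_000, pingpong_fraction=1.0, phased_fraction=0.0, seed=31)
        reads, _ = simulate_library(small_panel, spec)
        aln = align_species(collapse_reads(reads), small_panel)
        profiles = build_end_profiles(aln, {te.id: te.length for te in small_panel})
        hist, z10 = pingpong_signature(profiles)
        assert max(hist, key=hist.get) == 10
        assert z10.defined and z10.value > 10

    def test_phased_junction_and_periodicity(self, small_panel):
        spec = LibrarySimSpec(n_reads=20_000, pingpong_fraction=0.0, phased_fraction=1.0, seed=32)
        reads, _ = simulate_library(small_panel, spec)
        aln = align_species(collapse_reads(reads), small_panel)
        profiles = build_end_profiles(aln, {te.id: te.length for te in small_panel})
        h35, h55, z0 = phasing_signature(profiles)
        assert max(h35, key=h35.get) == 0
        assert z0.defined and z0.value > 3
        pm = peak_baseline_metrics(h55, expected_period=27, tolerance=2)
        assert pm.peak_height > 0
        assert abs(pm.peak_positions[0] - 27) <= 2
        assert abs(pm.peak_positions[1] - 54) <= 2

    def test_permutation_null_is_calibrated(self, small_panel):
        """Randomizing 5' positions (same marginal density) drives Z0 to noise."""
        rng = np.random.default_rng(7)
        spec = LibrarySimSpec(n_reads=20_000, pingpong_fraction=0.0, phased_fraction=1.0, seed=33)
        reads, _ = simulate_library(small_panel, spec)
        aln = align_species(collapse_reads(reads), small_panel)
        profiles = build_end_profiles(aln, {te.id: te.length for te in small_panel})
        zs = []
        for _ in range(10):
            shuffled = {}
            for k, p in profiles.items():
                weights5 = list(p.p5.values())
                weights3 = list(p.p3.values())
                pos5 = rng.choice(p.length, size=len(weights5), replace=False)
                pos3 = rng.choice(p.length, size=len(weights3), replace=False)
                shuffled[k] = type(p)(p.ref_id, p.strand, p.length,
                                      dict(zip(map(int, pos5), weights5)),
                                      dict(zip(map(int, pos3), weights3)))
            _, _, z0 = phasing_signature(shuffled)
            zs.append(z0.value)
        assert sum(abs(z) <= 3 for z in zs) >= 9


class TestPeakMetrics:
    def test_synthetic_peaks_and_baseline(self):
        hist = {d: 10.0 for d in range(1, 100)}
        hist[27] = 100.0
        hist[54] = 100.0
        pm = peak_baseline_metrics(hist)
        assert pm.peak_positions[:2] == (27, 54)
        assert pm.baseline == pytest.approx(10.0)
        assert pm.peak_height == pytest.approx(90.0)

    def test_flat_histogram_zero_height(self):
        hist = {d: 5.0 for d in range(1, 100)}
        pm = peak_baseline_metrics(hist)
        assert pm.peak_height == pytest.approx(0.0)

    def test_tolerance_finds_shifted_peaks(self):
        hist = {d: 1.0 for d in range(1, 100)}
        hist[28] = 50.0
        hist[55] = 50.0  # period-28 data scored with expected period 27
        pm = peak_baseline_metrics(hist, expected_period=27, tolerance=2)
        assert pm.peak_positions[:2] == (28, 55)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            peak_baseline_metrics({d: 1.0 for d in range(1, 30)})


class TestNucleotideBias:
    @staticmethod
    def _table(seqs_counts_strands):
        species = pd.DataFrame(
            {
                "species_id": [f"s{i}" for i in range(len(seqs_counts_strands))],
                "sequence": [s for s, _, _ in seqs_counts_strands],
                "count": [c for _, c, _ in seqs_counts_strands],
            }
        )
        aln = pd.DataFrame(
            {
                "species_id": species["species_id"],
                "ref_id": "r",
                "strand": [st for _, _, st in seqs_counts_strands],
                "start": 0,
                "end": species["sequence"].str.len(),
                "n_locations": 1,
                "weight": species["count"].astype(float),
            }
        )
        return species, aln

    def test_percent_arithmetic(self):
        species, aln = self._table(
            [("T" + "A" * 25, 5, "+"), ("T" + "A" * 25 + "C", 5, "+"), ("G" + "A" * 25, 5, "+"), ("A" * 26, 5, "+")]
        )
        res = nucleotide_bias(species, aln, 1, "T", 5)
        assert res["sense"].percent == pytest.approx(50.0)
        assert res["sense"].n_eligible == 4

    def test_subthreshold_species_excluded_entirely(self):
        species, aln = self._table([("T" + "A" * 25, 5, "+"), ("T" + "A" * 25 + "C", 4, "+")])
        res = nucleotide_bias(species, aln, 1, "T", 5)
        assert res["sense"].n_eligible == 1
        assert res["sense"].percent == pytest.approx(100.0)

    def test_all_hit_gives_100(self):
        species, aln = self._table([("C" * 9 + "A" + "C" * 16, 6, "-"), ("G" * 9 + "A" + "G" * 16, 9, "-")])
        res = nucleotide_bias(species, aln, 10, "A", 5)
        assert res["antisense"].percent == pytest.approx(100.0)

    def test_short_species_is_eligible_nonhit(self):
        species, aln = self._table([("T" * 16, 5, "+"), ("T" * 26, 5, "+")])
        res = nucleotide_bias(species, aln, 20, "T", 5)
        assert res["sense"].n_eligible == 2
        assert res["sense"].percent == pytest.approx(50.0)

    def test_empty_scope_undefined(self):
        species, aln = self._table([("T" * 26, 5, "+")])
        res = nucleotide_bias(species, aln, 1, "T", 5)
        assert not res["antisense"].defined

    def test_compare_bias_two_proportion(self):
        from pirnasig.signatures import NucleotideBiasResult, compare_bias

        a = NucleotideBiasResult("sense", 1, "T", 1000, 780, 78.0, True)
        b = NucleotideBiasResult("sense", 1, "T", 1000, 700, 70.0, True)
        diff, p = compare_bias(a, b)
        assert diff == pytest.approx(8.0)
        assert p < 0.01  # 78% vs 70% at n=1000 each is clearly significant
        same_diff, same_p = compare_bias(a, a)
        assert same_diff == 0.0 and same_p == pytest.approx(1.0)


class TestIPOverlapBias:
    def test_ago3_group_recovers_planted_10a(self, small_panel):
        spec = LibrarySimSpec(n_reads=60_000, pingpong_fraction=0.6, phased_fraction=0.3,
                              a10_prob=0.65, seed=34)
        reads, gt = simulate_library(small_panel, spec)
        species = collapse_reads(reads)
        aln = align_species(species, small_panel)
        ip = simulate_ip_libraries(reads, gt, enrichment=10.0, seed=35)
        assignment = ip_group_assignment(ip)
        res = ip_overlap_bias(species, aln, assignment, "Ago3", position=10, base="A")
        assert res["sense"].n_eligible > 500
        assert res["sense"].percent == pytest.approx(65.0, abs=4.0)

    def test_group_disjoint_from_sample_undefined(self):
        species = pd.DataFrame({"species_id": ["s0"], "sequence": ["A" * 26], "count": [9]})
        aln = pd.DataFrame({"species_id": ["s0"], "ref_id": ["r"], "strand": ["+"],
                            "start": [0], "end": [26], "n_locations": [1], "weight": [9.0]})
        assignment = pd.DataFrame({"sequence": ["C" * 26], "assigned": ["Ago3"]})
        res = ip_overlap_bias(species, aln, assignment, "Ago3")
        assert not res["both"].defined
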