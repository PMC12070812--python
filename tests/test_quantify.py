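"""pkb/rpkm identities, normalization, and the differential-expression engine."""

import numpy as np
import pandas as pd
import pytest

from pirnasig import (
    ConditionEffect,
    TEConsensus,
    TECountTable,
    differential_expression,
    fold_change_calls,
    generate_te_panel,
    normalize_counts,
    quantify_te,
    simulate_count_table,
    split_strand_fc,
)
from pirnasig.simulate import TEPanelSpec


def aln_frame(rows):
    return pd.DataFrame(rows, columns=["species_id", "ref_id", "strand", "start", "end", "n_locations", "weight"])


class TestQuantify:
    panel = [TEConsensus("te1", "A" * 1000), TEConsensus("te2", "C" * 5000)]

    def test_pkb_identity(self):
        aln = aln_frame([("s1", "te1", "+", 0, 26, 1, 10.0), ("s2", "te2", "+", 0, 26, 1, 50.0)])
        counts = quantify_te(aln, self.panel)
        table = TECountTable(counts=counts.to_frame("lib"), lengths=pd.Series({"te1": 1000, "te2": 5000}))
        pkb = table.pkb()["lib"]
        assert pkb["te1"] == pytest.approx(10.0)  # 10 / 1000 * 1000
        assert pkb["te2"] == pytest.approx(10.0)  # 50 / 5000 * 1000

    def test_rpkm_identity(self):
        counts = pd.DataFrame({"lib": [900.0, 100.0]}, index=["te1", "te2"])
        table = TECountTable(counts=counts, lengths=pd.Series({"te1": 1000, "te2": 5000}),
                             library_size=pd.Series({"lib": 1e6}))
        rpkm = table.rpkm()["lib"]
        assert rpkm["te1"] == pytest.approx(900.0 / 1.0 / 1.0)
        assert rpkm["te2"] == pytest.approx(100.0 / 5.0 / 1.0)

    def test_within_te_multimapper_sums_to_count(self):
        aln = aln_frame([("s1", "te1", "+", 0, 26, 2, 3.0), ("s1", "te1", "+", 100, 126, 2, 3.0)])
        counts = quantify_te(aln, self.panel)
        assert counts["te1"] == pytest.approx(6.0)

    def test_per_strand_split(self):
        aln = aln_frame([("s1", "te1", "+", 0, 26, 1, 4.0), ("s2", "te1", "-", 10, 36, 1, 2.0)])
        counts = quantify_te(aln, self.panel, per_strand=True)
        assert counts["te1:+"] == 4.0 and counts["te1:-"] == 2.0

    def test_species_count_filter(self):
        species = pd.DataFrame({"species_id": ["s1", "s2"], "sequence": ["A" * 26] * 2, "count": [6, 4]})
        aln = aln_frame([("s1", "te1", "+", 0, 26, 1, 6.0), ("s2", "te1", "+", 5, 31, 1, 4.0)])
        counts = quantify_te(aln, self.panel, min_species_count=5, species=species)
        assert counts["te1"] == pytest.approx(6.0)

    def test_unknown_te_rejected(self):
        aln = aln_frame([("s1", "ghost", "+", 0, 26, 1, 1.0)])
        with pytest.raises(ValueError):
            quantify_te(aln, self.panel)


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        _, factors = normalize_counts(counts)
        assert factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_scaled_sample_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30, 40], "b": [20, 40, 60, 80]})
        norm, factors = normalize_counts(counts)
        assert factors["b"] / factors["a"] == pytest.approx(2.0)
        pd.testing.assert_series_equal(norm["a"], norm["b"], check_names=False)

    def test_median_robust_to_spiked_feature(self):
        rng = np.random.default_rng(3)
        base = rng.integers(50, 500, size=15).astype(float)
        counts = pd.DataFrame({"a": base, "b": base.copy()})
        counts.loc[0, "b"] *= 100
        _, factors = normalize_counts(counts)
        assert factors["b"] == pytest.approx(1.0, abs=0.05)

    def test_all_zero_feature_fallback_warns(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.warns(UserWarning):
            normalize_counts(counts)


class TestDifferentialExpression:
    @staticmethod
    def _null_table(n_features=200, seed=0):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(4, 1, n_features)
        cols = {f"{g}_{r}": rng.poisson(mu * rng.gamma(20, 1 / 20, n_features))
                for g in ("a", "b") for r in range(3)}
        return pd.DataFrame(cols)

    def test_identical_groups_zero_lfc(self):
        counts = pd.DataFrame({"a1": [10, 50], "a2": [20, 40], "b1": [10, 50], "b2": [20, 40]})
        de = differential_expression(counts, ["a1", "a2"], ["b1", "b2"])
        assert de["log2fc"].to_numpy() == pytest.approx([0.0, 0.0], abs=1e-12)
        assert (de["call"] == "unchanged").all()

    def test_bh_adjustment_hand_computed(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.02, 0.03, 0.04]
        adj = multipletests(p, method="fdr_bh")[1]
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_group_swap_symmetry(self):
        counts = self._null_table(seed=5)
        a, b = ["a_0", "a_1", "a_2"], ["b_0", "b_1", "b_2"]
        de_ab = differential_expression(counts, a, b)
        de_ba = differential_expression(counts, b, a)
        assert de_ba["log2fc"].to_numpy() == pytest.approx(-de_ab["log2fc"].to_numpy(), abs=1e-9)
        assert de_ba["p"].to_numpy() == pytest.approx(de_ab["p"].to_numpy(), rel=1e-9)

    def test_planted_fold_change_called(self):
        panel = generate_te_panel(TEPanelSpec(n_te=100, length_range=(500, 2000), seed=7))
        target = [te.id for te in panel[:10]]
        effects = [ConditionEffect("ctrl"),
                   ConditionEffect("mut", te_fc_map={t: 4.0 for t in target})]
        table = simulate_count_table(panel, effects, n_reps=5, dispersion=0.05, seed=8)
        de = differential_expression(table.counts, table.samples_of("ctrl"), table.samples_of("mut"))
        de = de.set_index("feature")
        assert np.median(de.loc[target, "log2fc"]) == pytest.approx(2.0, abs=0.3)
        assert (de.loc[target, "call"] == "up").mean() >= 0.9

    def test_permutation_agrees_with_welch_direction(self):
        counts = self._null_table(seed=9)
        counts.iloc[:5, 3:] *= 8  # strong effect in group b
        a, b = ["a_0", "a_1", "a_2"], ["b_0", "b_1", "b_2"]
        de = differential_expression(counts, a, b, method="permutation")
        assert de["p"].iloc[:5].mean() < de["p"].iloc[5:].mean()

    def test_insufficient_replicates_rejected(self):
        counts = pd.DataFrame({"a1": [1], "b1": [2], "b2": [3]})
        with pytest.raises(ValueError):
            differential_expression(counts, ["a1"], ["b1", "b2"])

    def test_matches_pydeseq2_direction_on_simulated_data(self):
        """Independent cross-check: log2FCs agree with DESeq2's estimates."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet

        panel = generate_te_panel(TEPanelSpec(n_te=60, length_range=(500, 2000), seed=17))
        target = [te.id for te in panel[:6]]
        effects = [ConditionEffect("ctrl"), ConditionEffect("mut", te_fc_map={t: 4.0 for t in target})]
        table = simulate_count_table(panel, effects, n_reps=4, dispersion=0.05, seed=18)
        de = differential_expression(table.counts, table.samples_of("ctrl"),
                                     table.samples_of("mut")).set_index("feature")

        meta = pd.DataFrame({"condition": [table.sample_genotype[s] for s in table.counts.columns]},
                            index=table.counts.columns)
        dds = DeseqDataSet(counts=table.counts.T, metadata=meta, design="~condition", quiet=True)
        dds.deseq2()
        from pydeseq2.ds import DeseqStats

        stats = DeseqStats(dds, contrast=["condition", "mut", "ctrl"], quiet=True)
        stats.summary()
        lfc_ds2 = stats.results_df["log2FoldChange"]
        corr = np.corrcoef(de["log2fc"].reindex(lfc_ds2.index), lfc_ds2)[0, 1]
        assert corr > 0.9
        assert np.median(lfc_ds2[target]) == pytest.approx(np.median(de.loc[target, "log2fc"]), abs=0.3)


class TestFoldChangeAndStrandJoin:
    def test_two_fold_calls(self):
        counts = pd.DataFrame({"c1": [100.0, 100, 100], "c2": [100.0, 100, 100],
                               "m1": [40.0, 100, 240], "m2": [40.0, 100, 240]},
                              index=["down_te", "flat_te", "up_te"])
        fc = fold_change_calls(counts, ["c1", "c2"], ["m1", "m2"], cutoff=2.0, normalize=False)
        calls = dict(zip(fc["feature"], fc["call"]))
        assert calls == {"down_te": "down", "flat_te": "unchanged", "up_te": "up"}

    def _fc_frame(self, features, fcs):
        calls = ["down" if f <= 0.5 else "up" if f >= 2 else "unchanged" for f in fcs]
        return pd.DataFrame({"feature": features, "meanA": 1.0, "meanB": 1.0, "fc": fcs, "call": calls})

    def test_join_thresholds(self):
        sense = self._fc_frame(["te1:+"], [0.4])
        anti = self._fc_frame(["te1:-"], [1.0])
        joined = split_strand_fc(sense, anti)
        row = joined.iloc[0]
        assert row["call_sense"] == "down" and row["call_antisense"] == "unchanged"
        assert not row["missing_strand"]

    def test_missing_strand_flagged_not_dropped(self):
        sense = self._fc_frame(["te1:+", "te2:+"], [1.0, 1.0])
        anti = self._fc_frame(["te1:-"], [1.0])
        joined = split_strand_fc(sense, anti).set_index("te_id")
        assert joined.loc["te2", "missing_strand"]
        assert len(joined) == 2

    def test_duplicate_te_rejected(self):
        sense = self._fc_frame(["te1:+", "te1:+"], [1.0, 1.0])
        anti = self._fc_frame(["te1:-"], [1.0])
        with pytest.raises(ValueError):
            split_strand_fc(sense, anti)
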