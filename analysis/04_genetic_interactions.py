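#!/usr/bin/env python
"""Genetic-interaction scores and the length x expression quadrant analysis.

Simulates control / two single mutants / double mutant RNA count tables in
which the double mutant's fold change on ten marked TEs is three times the
sum of the single-mutant fold changes, scores every TE's genetic
interaction (GI = FC_double / (FC_single1 + FC_single2)), and partitions
TEs into length x expression quadrants to locate the de-silenced ones.
Writes results/04_gi_scores.tsv and results/04_quadrant_summary.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pirnasig import (
    ConditionEffect,
    TEPanelSpec,
    differential_expression,
    generate_te_panel,
    gi_scores,
    quadrant_analysis,
    simulate_count_table,
)

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    panel = generate_te_panel(TEPanelSpec(n_te=100, length_range=(500, 20_000), seed=SEED))
    lengths = pd.Series({te.id: te.length for te in panel})
    # probe the baseline expression (deterministic given the seed) and mark
    # the TEs with the largest length x expression product: de-silencing is
    # planted preferentially in long, highly expressed elements
    probe = simulate_count_table(panel, [ConditionEffect("ctrl")], n_reps=3,
                                 dispersion=0.05, seed=SEED + 1)
    probe_rpkm = probe.rpkm().mean(axis=1)
    marked = (lengths * probe_rpkm).sort_values(ascending=False).head(10).index.tolist()
    effects = [
        ConditionEffect("ctrl"),
        ConditionEffect("s1", te_fc_map={t: 2.0 for t in marked}),
        ConditionEffect("s2", te_fc_map={t: 2.0 for t in marked}),
        ConditionEffect("dbl", te_fc_map={t: 12.0 for t in marked}),
    ]
    table = simulate_count_table(panel, effects, n_reps=3, dispersion=0.05, seed=SEED + 1)
    ctrl = table.samples_of("ctrl")

    def de_of(genotype):
        return differential_expression(table.counts, ctrl, table.samples_of(genotype))

    de_dbl = de_of("dbl").set_index("feature")
    desilenced = set(de_dbl.index[de_dbl["call"] == "up"])

    def linear_fc(de):
        return pd.Series(2.0 ** de["log2fc"].to_numpy(), index=de["feature"])

    records, summary = gi_scores(
        linear_fc(de_dbl.reset_index()),
        linear_fc(de_of("s1")),
        linear_fc(de_of("s2")),
        desilenced=desilenced,
    )
    rpkm_ctrl = table.rpkm()[ctrl].mean(axis=1)
    q_records, q_summary = quadrant_analysis(lengths, rpkm_ctrl, desilenced)

    OUT.mkdir(exist_ok=True)
    records.to_csv(OUT / "04_gi_scores.tsv", sep="\t", index=False)
    q_summary.to_csv(OUT / "04_quadrant_summary.tsv", sep="\t", index=False)

    marked_gi = records.set_index("te_id").loc[marked, "gi"]
    print(f"GI > 2 among de-silenced TEs: {summary['n_strong']}/{summary['n_tes']} "
          f"({summary['percent_strong']:.0f}%)")
    print(f"median GI of marked TEs: {np.median(marked_gi):.2f} "
          f"(planted 3x the additive expectation)")
    print("\nQuadrant summary:")
    print(q_summary.round(1).to_string(index=False))
    density = q_summary.set_index("quadrant")["density_percent"]
    print(f"\nDe-silenced TE density is highest in {density.idxmax()} and lowest "
          f"in {density.idxmin()}, mirroring the preferential de-silencing of "
          "long, highly expressed transposons.")


if __name__ == "__main__":
    main()
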