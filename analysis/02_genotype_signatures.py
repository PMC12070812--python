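#!/usr/bin/env python
"""Per-genotype piRNA signatures of the simulated mutant cohort.

Runs the full pipeline on the default four-genotype study (WT, a ping-pong
knockdown, a milder sense-biased mutant, and their double mutant) and
tabulates the Z10/Z0 scores and 1U/10A percentages per genotype — the
synthetic analogue of the WT -> single -> double signature collapse.
Writes results/02_genotype_signatures.tsv (scores) and
results/02_nucleotide_bias.tsv (biases); pipeline outputs go to
scratch/02_cohort/.
"""

import sys
from pathlib import Path

import pandas as pd

from pirnasig import PipelineConfig, run_pipeline

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    config = PipelineConfig.from_dict(
        dict(outdir="scratch/02_cohort", seed=SEED, n_te=50, n_reads=50_000, n_reps=3)
    )
    run_pipeline(config)
    outdir = Path(config.outdir)
    scores = pd.read_csv(outdir / "signature_scores.tsv", sep="\t")
    bias = pd.read_csv(outdir / "nucleotide_bias.tsv", sep="\t")

    OUT.mkdir(exist_ok=True)
    summary = scores.groupby("genotype")[["z10", "z0"]].agg(["mean", "std"])
    summary.columns = ["_".join(c) for c in summary.columns]
    order = [g.genotype for g in config.genotypes]
    summary = summary.reindex(order)
    summary.reset_index().to_csv(OUT / "02_genotype_signatures.tsv", sep="\t", index=False)
    bias["genotype"] = bias["sample"].str.replace(r"_rep\d+$", "", regex=True)
    bias_summary = (
        bias.groupby(["genotype", "signature", "scope"])["percent"].mean().reset_index()
    )
    bias_summary.to_csv(OUT / "02_nucleotide_bias.tsv", sep="\t", index=False)

    print("Mean signature scores per genotype (3 replicates):")
    print(summary.round(2).to_string())
    wt, dbl = summary.loc[order[0], "z10_mean"], summary.loc[order[-1], "z10_mean"]
    print(
        f"\nThe ping-pong score collapses from Z10 = {wt:.0f} in WT to "
        f"{dbl:.1f} in the double mutant, with the single mutants in between; "
        "Z0 declines in the same order. 1U/10A percentages per genotype are in "
        "results/02_nucleotide_bias.tsv."
    )


if __name__ == "__main__":
    main()
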