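#!/usr/bin/env python
"""PIWI-clade IP group assignment and the Ago3-bound 10A signature.

Simulates Aub/Ago3/Piwi immunoprecipitation libraries from one WT library
(the bound protein's IP sees each species at 10x its base abundance),
assigns species to non-overlapping groups with the 3-fold enrichment rule,
measures what fraction of the sample's reads the groups capture, and shows
that the 10A bias — diluted in total piRNAs — emerges in the Ago3-bound
sense subset. Writes results/05_ip_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from pirnasig import (
    LibrarySimSpec,
    TEPanelSpec,
    align_species,
    generate_te_panel,
    ip_group_assignment,
    ip_group_overlap,
    ip_overlap_bias,
    nucleotide_bias,
    simulate_ip_libraries,
    simulate_library,
    trim_and_collapse,
)

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    panel = generate_te_panel(TEPanelSpec(n_te=50, length_range=(500, 5000), seed=SEED))
    spec = LibrarySimSpec(n_reads=100_000, pingpong_fraction=0.6, phased_fraction=0.3,
                          a10_prob=0.65, seed=SEED + 1)
    reads, gt = simulate_library(panel, spec)
    species = trim_and_collapse(
        ((s, int(c)) for _, s, c in reads.itertuples(index=False)), trim_len=0
    )
    aln = align_species(species, panel)

    ip = simulate_ip_libraries(reads, gt, enrichment=10.0, seed=SEED + 2)
    assignment = ip_group_assignment(ip, fold=3.0)
    overlap = ip_group_overlap(species, assignment)
    a10_total = nucleotide_bias(species, aln, 10, "A")["sense"]
    a10_ago3 = ip_overlap_bias(species, aln, assignment, "Ago3", position=10, base="A")["sense"]

    rows = [{"metric": f"percent_reads_in_{g}", "value": overlap[g]} for g in ("Aub", "Ago3", "Piwi", "any")]
    rows += [
        {"metric": "a10_percent_total_sense", "value": a10_total.percent},
        {"metric": "a10_percent_ago3_bound_sense", "value": a10_ago3.percent},
    ]
    OUT.mkdir(exist_ok=True)
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "05_ip_summary.tsv", sep="\t", index=False)

    print(frame.round(1).to_string(index=False))
    print(
        f"\n{overlap['any']:.0f}% of the sample's reads match piRNAs bound by "
        f"Piwi, Aub, or Ago3. The sense-strand 10A rises from "
        f"{a10_total.percent:.0f}% in total piRNAs to {a10_ago3.percent:.0f}% in "
        "the Ago3-bound subset, where ping-pong responders concentrate."
    )


if __name__ == "__main__":
    main()
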