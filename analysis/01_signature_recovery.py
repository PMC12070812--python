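#!/usr/bin/env python
"""Signature-score recovery versus planted pathway strength.

Sweeps the planted ping-pong and phased fractions over a grid and records
the Z10 and Z0 scores each library yields, demonstrating that both scores
rise monotonically with the planted signal and stay near zero on random
libraries. Writes results/01_signature_recovery.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

from pirnasig import (
    LibrarySimSpec,
    TEPanelSpec,
    align_species,
    build_end_profiles,
    generate_te_panel,
    phasing_signature,
    pingpong_signature,
    simulate_library,
    trim_and_collapse,
)

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    panel = generate_te_panel(TEPanelSpec(n_te=20, length_range=(500, 5000), seed=SEED))
    lengths = {te.id: te.length for te in panel}
    rows = []
    for seed in (SEED, SEED + 1, SEED + 2):
        for pp, ph in [(0.0, 0.0), (0.1, 0.1), (0.3, 0.3), (0.5, 0.4)]:
            spec = LibrarySimSpec(n_reads=30_000, pingpong_fraction=pp, phased_fraction=ph,
                                  seed=seed * 100 + int(pp * 10))
            reads, _ = simulate_library(panel, spec)
            species = trim_and_collapse(
                ((s, int(c)) for _, s, c in reads.itertuples(index=False)), trim_len=0
            )
            aln = align_species(species, panel)
            profiles = build_end_profiles(aln, lengths)
            _, z10 = pingpong_signature(profiles)
            _, _, z0 = phasing_signature(profiles)
            rows.append({"seed": seed, "pingpong_fraction": pp, "phased_fraction": ph,
                         "z10": z10.value, "z0": z0.value})
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "01_signature_recovery.tsv", sep="\t", index=False)

    by_frac = frame.groupby("pingpong_fraction")[["z10", "z0"]].mean()
    print("Mean scores by planted fraction:")
    print(by_frac.round(2).to_string())
    print(
        f"\nZ10 rises from {by_frac['z10'].iloc[0]:.1f} (no planting) to "
        f"{by_frac['z10'].iloc[-1]:.1f} at fraction 0.5; Z0 behaves likewise — "
        "both scores track the planted pathway strength."
    )


if __name__ == "__main__":
    main()
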