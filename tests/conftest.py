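import pandas as pd
import pytest

from pirnasig import (
    LibrarySimSpec,
    TEPanelSpec,
    align_species,
    build_end_profiles,
    generate_te_panel,
    simulate_library,
    trim_and_collapse,
)


def collapse_reads(reads: pd.DataFrame) -> pd.DataFrame:
    """Collapse a simulated read table into species without trimming."""
    return trim_and_collapse(
        ((seq, int(c)) for _, seq, c in reads.itertuples(index=False)), trim_len=0
    )


@pytest.fixture(scope="session")
def small_panel():
    return generate_te_panel(TEPanelSpec(n_te=10, length_range=(500, 3000), seed=11))


@pytest.fixture(scope="session")
def mixed_library(small_panel):
    """One library with all three pathways planted, plus its alignments."""
    spec = LibrarySimSpec(
        n_reads=30_000, pingpong_fraction=0.35, phased_fraction=0.35, seed=12
    )
    reads, gt = simulate_library(small_panel, spec)
    species = collapse_reads(reads)
    alignments = align_species(species, small_panel)
    return {"reads": reads, "ground_truth": gt, "species": species, "alignments": alignments}


@pytest.fixture(scope="session")
def mixed_profiles(small_panel, mixed_library):
    lengths = {te.id: te.length for te in small_panel}
    return build_end_profiles(mixed_library["alignments"], lengths)
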