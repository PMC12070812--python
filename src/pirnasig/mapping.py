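"""Read trimming/collapsing, exact-match alignment to consensus transposons,
multimapper apportioning, and per-strand 5'/3' end profiles.

Small-RNA libraries are collapsed to read *species* (unique post-trim
sequence + occurrence count). Species are placed on both strands of a panel
of consensus transposable-element (TE) sequences by exact full-length
matching: a k-mer seed index (k = 15, the minimum accepted species length)
proposes candidate positions which are then verified base-for-base. A
species occurring at ``n`` locations across the panel (both strands
combined) contributes weight ``count / n`` at each location, so total
apportioned weight equals total aligned read count exactly.

Coordinates are 0-based half-open on the reference. End profiles are kept in
*transcript orientation*: for a minus-strand placement on a reference of
length L, position p maps to L-1-p, so within-strand distances read
left-to-right along the piRNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import revcomp
from .io import ALIGNMENT_COLUMNS

SEED_K = 15  # equals the minimum matched length accepted downstream


@dataclass(frozen=True)
class TEConsensus:
    """A named consensus transposon sequence used as mapping reference."""

    id: str
    sequence: str
    compartment: str = "unknown"  # germline / somatic / unknown

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class EndProfile:
    """Weighted 5'/3'-end position vectors for one (reference, strand).

    Positions are in transcript orientation; ``length`` is the reference
    length needed to map back to reference coordinates.
    """

    ref_id: str
    strand: str
    length: int
    p5: dict[int, float] = field(default_factory=dict)
    p3: dict[int, float] = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return float(sum(self.p5.values()))

    def p5_reference_coords(self) -> dict[int, float]:
        """5'-end weights keyed by *reference* position (undo the transform)."""
        if self.strand == "+":
            return dict(self.p5)
        return {self.length - 1 - p: w for p, w in self.p5.items()}


# ---------------------------------------------------------------------------
# trimming and collapsing


def trim_and_collapse(
    reads,
    mode: str = "fixed3p",
    trim_len: int = 30,
    adapter_seq: str | None = None,
    min_len: int = 15,
) -> pd.DataFrame:
    """Trim raw reads at the 3' end and collapse identical sequences.

    ``fixed3p`` removes ``trim_len`` bases from the 3' end (the library
    protocol leaves the adapter as a fixed-length 3' suffix). ``adapter``
    removes everything from the first occurrence of the first 8 nt of
    ``adapter_seq`` onward; reads without an adapter hit are kept whole.
    Post-trim sequences shorter than ``min_len`` are dropped.

    ``reads`` may be an iterable of sequences or of (sequence, count) pairs.

    Returns a species table [species_id, sequence, count] sorted by
    descending count then sequence (deterministic ids).
    """
    if mode not in ("fixed3p", "adapter"):
        raise ValueError(f"unknown trim mode {mode!r}")
    if mode == "adapter":
        if not adapter_seq or len(adapter_seq) < 8:
            raise ValueError("adapter mode requires adapter_seq of >= 8 nt")
        probe = adapter_seq[:8].upper()

    counter: Counter[str] = Counter()
    n_dropped = 0
    for item in reads:
        if isinstance(item, tuple):
            seq, count = item
        else:
            seq, count = item, 1
        seq = seq.upper()
        if mode == "fixed3p":
            trimmed = seq[: max(0, len(seq) - trim_len)]
        else:
            hit = seq.find(probe)
            trimmed = seq[:hit] if hit >= 0 else seq
        if len(trimmed) < min_len:
            n_dropped += 1
            continue
        counter[trimmed] += count

    ordered = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    frame = pd.DataFrame(
        {
            "species_id": [f"sp{i:06d}" for i in range(len(ordered))],
            "sequence": [seq for seq, _ in ordered],
            "count": [c for _, c in ordered],
        }
    )
    frame.attrs["n_dropped_short"] = n_dropped
    return frame


def size_filter(species: pd.DataFrame, lo: int = 23, hi: int = 28) -> tuple[pd.DataFrame, pd.Series]:
    """Keep species with lo <= length <= hi; also return the count-weighted
    length histogram over the 19-35 nt reporting window."""
    if lo > hi:
        raise ValueError(f"size window inverted: [{lo},{hi}]")
    lengths = species["sequence"].str.len()
    hist = (
        species.assign(length=lengths)
        .groupby("length")["count"]
        .sum()
        .reindex(range(19, 36), fill_value=0)
    )
    kept = species[(lengths >= lo) & (lengths <= hi)].reset_index(drop=True)
    return kept, hist


# ---------------------------------------------------------------------------
# alignment


class PanelIndex:
    """Exact-match seed index over the forward strands of a TE panel."""

    def __init__(self, panel: list[TEConsensus], k: int = SEED_K):
        self.k = k
        self.panel = panel
        ids = [te.id for te in panel]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate TE ids in panel")
        self.seqs = {te.id: te.sequence.upper() for te in panel}
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for te in panel:
            seq = self.seqs[te.id]
            for pos in range(len(seq) - k + 1):
                self._seeds.setdefault(seq[pos : pos + k], []).append((te.id, pos))

    def locate(self, query: str) -> list[tuple[str, int]]:
        """All (ref_id, start) of exact full-length forward occurrences."""
        if len(query) < self.k:
            return []
        hits = []
        for ref_id, pos in self._seeds.get(query[: self.k], ()):
            if self.seqs[ref_id].startswith(query, pos):
                hits.append((ref_id, pos))
        return hits


def _scan_with_mismatches(query: str, ref: str, max_mm: int) -> list[int]:
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    r = np.frombuffer(ref.encode(), dtype=np.uint8)
    n = len(r) - len(q) + 1
    if n <= 0:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(r, len(q))
    mm = (windows != q).sum(axis=1)
    return np.nonzero(mm <= max_mm)[0].tolist()


def align_species(
    species: pd.DataFrame,
    panel: list[TEConsensus],
    max_mismatches: int = 0,
    index: PanelIndex | None = None,
) -> pd.DataFrame:
    """Place every species on both strands of the panel and apportion weights.

    Reports every perfect full-length occurrence of the species (strand +)
    and of its reverse complement (strand -); ``n_locations`` counts all
    occurrences across the whole panel, and weight = count / n_locations.
    Species with no location (including any containing N) are returned in
    the frame's ``attrs['unaligned']`` list. ``max_mismatches > 0`` switches
    to a brute-force scan (off-default; slow, for small panels).
    """
    if max_mismatches == 0 and index is None:
        index = PanelIndex(panel)
    rows: list[tuple] = []
    unaligned: list[str] = []
    for species_id, seq, count in species[["species_id", "sequence", "count"]].itertuples(index=False):
        seq = seq.upper()
        rc = revcomp(seq)
        locs: list[tuple[str, str, int]] = []
        if max_mismatches == 0:
            if len(seq) < SEED_K:
                raise ValueError(f"species {species_id} shorter than minimum matched length {SEED_K}")
            locs += [(ref, "+", pos) for ref, pos in index.locate(seq)]
            locs += [(ref, "-", pos) for ref, pos in index.locate(rc)]
        else:
            for te in panel:
                ref = te.sequence.upper()
                locs += [(te.id, "+", p) for p in _scan_with_mismatches(seq, ref, max_mismatches)]
                locs += [(te.id, "-", p) for p in _scan_with_mismatches(rc, ref, max_mismatches)]
        if not locs:
            unaligned.append(species_id)
            continue
        n = len(locs)
        w = count / n
        for ref_id, strand, pos in locs:
            rows.append((species_id, ref_id, strand, pos, pos + len(seq), n, w))
    frame = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    frame.attrs["unaligned"] = unaligned
    return frame


def assign_to_regions(alignments: pd.DataFrame, regions: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Subset alignments by >=1-nt overlap with each named region.

    ``regions`` has columns [ref_id, start, end, name] (see io.read_bed).
    An alignment overlapping several regions appears in each subset.
    """
    out: dict[str, pd.DataFrame] = {}
    for ref_id, start, end, name in regions[["ref_id", "start", "end", "name"]].itertuples(index=False):
        mask = (
            (alignments["ref_id"] == ref_id)
            & (alignments["start"] < end)
            & (alignments["end"] > start)
        )
        out[name] = alignments[mask].reset_index(drop=True)
    return out


def build_end_profiles(
    alignments: pd.DataFrame, ref_lengths: dict[str, int]
) -> dict[tuple[str, str], EndProfile]:
    """Sum apportioned weights into 5'/3'-end vectors per (reference, strand).

    On the + strand the 5' end is ``start`` and the 3' end is ``end - 1``;
    on the - strand they are ``end - 1`` and ``start`` respectively, then
    both are mapped to transcript orientation (p -> L-1-p).
    """
    profiles: dict[tuple[str, str], EndProfile] = {}
    for species_id, ref_id, strand, start, end, n, w in alignments[ALIGNMENT_COLUMNS].itertuples(index=False):
        key = (ref_id, strand)
        prof = profiles.get(key)
        if prof is None:
            prof = profiles[key] = EndProfile(ref_id, strand, ref_lengths[ref_id])
        if strand == "+":
            p5, p3 = start, end - 1
        else:
            L = prof.length
            p5, p3 = L - 1 - (end - 1), L - 1 - start
        prof.p5[p5] = prof.p5.get(p5, 0.0) + w
        prof.p3[p3] = prof.p3.get(p3, 0.0) + w
    return profiles
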