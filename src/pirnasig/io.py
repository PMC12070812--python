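"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; SAM import goes through pysam; BED and all
tabular records are TSV via pandas. Coordinates are 0-based half-open
internally (BED-style); SAM import converts from 1-based.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

ALIGNMENT_COLUMNS = ["species_id", "ref_id", "strand", "start", "end", "n_locations", "weight"]
SPECIES_COLUMNS = ["species_id", "sequence", "count"]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences (uppercased) from a FASTQ file, optionally gzipped."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]]) -> None:
    """Write (read_id, sequence) pairs as FASTQ with constant 'I' qualities."""
    with _open_text(path, "wt") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Parse a BED3+ file into columns [ref_id, start, end, name].

    Unnamed intervals get "ref:start-end". Malformed lines raise with the
    offending line number.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: expected >=3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(f"malformed BED line {lineno}: invalid interval [{start},{end})")
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else f"{fields[0]}:{start}-{end}"
            rows.append((fields[0], start, end, name))
    return pd.DataFrame(rows, columns=["ref_id", "start", "end", "name"])


def read_sam_alignments(path: str | Path) -> pd.DataFrame:
    """Import perfect-match locations from a SAM/BAM file.

    Primary and secondary alignments are both treated as locations; weights
    are re-apportioned here (1 / n_locations per species), so an external
    aligner can replace the internal one. Soft-clipped or gapped records are
    skipped — the pipeline only consumes perfect full-length matches.
    """
    import pysam

    locations: dict[str, list[tuple[str, str, int, int]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.cigartuples is None or any(op != 0 for op, _ in rec.cigartuples):
                continue
            qname = rec.query_name
            strand = "-" if rec.is_reverse else "+"
            locations.setdefault(qname, []).append(
                (rec.reference_name, strand, rec.reference_start, rec.reference_end)
            )
    rows = []
    for qname, locs in locations.items():
        n = len(locs)
        for ref, strand, start, end in locs:
            rows.append((qname, ref, strand, start, end, n, 1.0 / n))
    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)


def write_tsv(path: str | Path, frame: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
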