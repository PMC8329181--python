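"""Sequence and interval I/O: FASTA, BED3/BED6/narrowPeak.

Internal coordinates are 0-based half-open throughout; report output produced
by the analysis drivers is 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Peak",
    "FastaParseError",
    "PeakParseError",
    "read_fasta",
    "write_fasta",
    "read_peaks",
    "write_peaks_bed",
    "revcomp",
]

_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(residues: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return residues.translate(_COMPLEMENT)[::-1]


class FastaParseError(ValueError):
    pass


class PeakParseError(ValueError):
    pass


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}.

    ``origin_offset`` is the genomic (or promoter-frame-anchoring) coordinate
    of the first residue, so sliced sub-regions can keep their frame.
    """

    id: str
    residues: str
    origin_offset: int = 0

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid residues {sorted(bad)!r}; "
                "alphabet is A/C/G/T/N"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, revcomp(self.residues), self.origin_offset)


@dataclass
class Peak:
    """A genomic interval (0-based half-open) with optional strand and score."""

    seq_id: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"peak {self.name!r}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.name!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"peak {self.name!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased; N is allowed.  Malformed headers, data before the
    first header, or empty sequences raise :class:`FastaParseError` naming the
    offending line number.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(
                f"{path}: empty sequence for record {header!r} (line {header_line})"
            )
        try:
            records.append(SequenceRecord(header, residues))
        except ValueError as exc:
            raise FastaParseError(f"{path}: line {header_line}: {exc}") from exc

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}: empty FASTA header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                chunks.append(line)
    if header is None:
        raise FastaParseError(f"{path}: no FASTA records found")
    _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10}

_NARROWPEAK_EXTRA = ("signalValue", "pValue", "qValue", "summit")


def read_peaks(path: str | Path, dialect: str = "bed6") -> list[Peak]:
    """Read BED3/BED6/narrowPeak intervals (0-based half-open, kept verbatim).

    narrowPeak columns 7-10 are retained in ``Peak.metadata``; the peaks are
    returned sorted by (seq_id, start, end).
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; expected bed3/bed6/narrowPeak")
    ncol = _DIALECT_COLUMNS[dialect]
    peaks: list[Peak] = []
    with open(path) as fh:
        for idx, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise PeakParseError(
                    f"{path}: record {idx}: expected >= {ncol} columns for "
                    f"{dialect}, got {len(fields)}"
                )
            seq_id, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PeakParseError(f"{path}: record {idx}: non-integer coordinates") from exc
            name = fields[3] if ncol >= 6 else f"peak_{idx}"
            score = None
            strand = "."
            if ncol >= 6:
                score = None if fields[4] == "." else float(fields[4])
                strand = fields[5]
            metadata = {}
            if dialect == "narrowPeak":
                for key, value in zip(_NARROWPEAK_EXTRA, fields[6:10]):
                    metadata[key] = float(value) if "." in value or "e" in value else int(value)
            try:
                peaks.append(Peak(seq_id, start, end, name, score, strand, metadata))
            except ValueError as exc:
                raise PeakParseError(f"{path}: record {idx}: {exc}") from exc
    peaks.sort(key=lambda p: (p.seq_id, p.start, p.end))
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED6."""
    with open(path, "w") as fh:
        for p in peaks:
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.seq_id}\t{p.start}\t{p.end}\t{p.name}\t{score}\t{p.strand}\n")
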