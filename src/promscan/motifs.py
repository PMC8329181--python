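"""Peak-restricted transcription-factor motif scanning.

Scans ChIP-seq peak intervals of a reference sequence for a JASPAR-style
position frequency matrix, on both strands, and ranks candidate sites by a
log2 likelihood-ratio (PWM log-odds) score.  A Hamming distance to the plain
argmax consensus is kept alongside as a literal approximate-string-search
filter; either criterion can be used to retain hits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Peak, SequenceRecord, revcomp

__all__ = [
    "PositionMatrix",
    "MotifHit",
    "read_jaspar",
    "consensus",
    "log_odds",
    "scan_peaks",
    "rank_report",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PositionMatrix:
    """A JASPAR-style count matrix (rows A,C,G,T) with log-odds scoring.

    ``pseudocount`` is distributed across bases proportionally to
    ``background`` before normalization, so every site has a finite score.
    """

    tf_name: str
    counts: np.ndarray  # shape (4, W)
    pseudocount: float = 1.0
    background: tuple[float, float, float, float] = UNIFORM_BACKGROUND

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x W matrix (rows A,C,G,T)")
        if self.width < 4:
            raise ValueError(f"motif width {self.width} < 4")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise ValueError("zero column sum")
        if not math.isclose(sum(self.background), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        bg = np.asarray(self.background)[:, None]
        colsum = self.counts.sum(axis=0)[None, :]
        return (self.counts + self.pseudocount * bg) / (colsum + self.pseudocount)

    @property
    def log_odds_matrix(self) -> np.ndarray:
        bg = np.asarray(self.background)[:, None]
        return np.log2(self.probabilities / bg)

    @property
    def max_score(self) -> float:
        return float(self.log_odds_matrix.max(axis=0).sum())


def read_jaspar(path: str | Path) -> PositionMatrix:
    """Parse a JASPAR 2016+ text PFM, or a raw unlabeled 4-row matrix.

    Labeled rows (``A [ 1 2 ... ]``) are assigned by their label, so files
    listing rows in any order parse to the same matrix.  Raw 4-row files are
    taken in A,C,G,T order.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    name = "motif"
    if lines and lines[0].startswith(">"):
        parts = lines[0][1:].split()
        name = parts[-1] if parts else "motif"
        lines = lines[1:]
    rows: dict[str, list[float]] = {}
    order: list[str] = []
    for ln in lines:
        label = None
        body = ln
        if ln[0].upper() in _BASE_INDEX and (len(ln) == 1 or not ln[1].isdigit() or ln[1] in " [\t"):
            head = ln.split(None, 1)
            if head[0].upper() in _BASE_INDEX:
                label = head[0].upper()
                body = head[1] if len(head) > 1 else ""
        body = body.replace("[", " ").replace("]", " ")
        try:
            values = [float(tok) for tok in body.split()]
        except ValueError as exc:
            raise ValueError(f"{path}: unparsable matrix row: {ln!r}") from exc
        if not values:
            raise ValueError(f"{path}: empty matrix row: {ln!r}")
        key = label if label is not None else f"_row{len(order)}"
        rows[key] = values
        order.append(key)
    if len(rows) != 4:
        raise ValueError(f"{path}: expected 4 matrix rows, found {len(rows)}")
    labeled = all(k in _BASE_INDEX for k in rows)
    if labeled:
        matrix = [rows[b] for b in _BASES]
    elif not any(k in _BASE_INDEX for k in rows):
        matrix = [rows[k] for k in order]
    else:
        raise ValueError(f"{path}: mixture of labeled and unlabeled rows")
    widths = {len(r) for r in matrix}
    if len(widths) != 1:
        raise ValueError(f"{path}: unequal row widths {sorted(widths)}")
    return PositionMatrix(tf_name=name, counts=np.array(matrix, dtype=float))


def consensus(matrix: PositionMatrix, warn_ties: bool = False) -> str:
    """Per-column maximal-count base; ties resolved by A<C<G<T order."""
    letters = []
    tied_cols = []
    for j in range(matrix.width):
        col = matrix.counts[:, j]
        best = int(np.argmax(col))  # argmax takes the first max: A<C<G<T order
        if (col == col[best]).sum() > 1:
            tied_cols.append(j)
        letters.append(_BASES[best])
    if tied_cols and warn_ties:
        import warnings

        warnings.warn(f"consensus ties at columns {tied_cols}; resolved A<C<G<T")
    return "".join(letters)


def log_odds(matrix: PositionMatrix, site: str) -> float:
    """log2 likelihood-ratio score of ``site`` against the background model.

    Sites containing N (or any non-ACGT base) are unscorable and raise.
    """
    site = site.upper()
    if len(site) != matrix.width:
        raise ValueError(f"site length {len(site)} != motif width {matrix.width}")
    lom = matrix.log_odds_matrix
    score = 0.0
    for j, b in enumerate(site):
        if b not in _BASE_INDEX:
            raise ValueError(f"unscorable base {b!r} at position {j}")
        score += lom[_BASE_INDEX[b], j]
    return score


@dataclass
class MotifHit:
    peak_name: str
    offset_in_peak: int
    genomic_start: int
    strand: str
    log_score: float
    mismatches_vs_consensus: int
    site_sequence: str  # strand-oriented (reverse-complemented for '-')


def scan_peaks(
    reference: SequenceRecord,
    peaks: list[Peak],
    matrix: PositionMatrix,
    max_mismatch: int | None = None,
    score_min_fraction: float = 0.8,
) -> list[MotifHit]:
    """Score every width-W window of every peak on both strands.

    A window is retained when its log-odds score is at least
    ``score_min_fraction`` of the matrix's maximum attainable score and (when
    ``max_mismatch`` is set) its Hamming distance to the consensus is within
    bound.  Windows containing N are skipped as unscorable.  Output is sorted
    by descending score, ties by (genomic_start ascending, + before -).
    """
    if not 0 <= score_min_fraction <= 1:
        raise ValueError("score_min_fraction must be in [0, 1]")
    W = matrix.width
    cons = consensus(matrix)
    threshold = score_min_fraction * matrix.max_score
    hits: list[MotifHit] = []
    for peak in peaks:
        if peak.end > len(reference):
            raise ValueError(f"peak {peak.name!r} exceeds reference bounds")
        if len(peak) < W:
            import warnings

            warnings.warn(f"peak {peak.name!r} shorter than motif; skipped")
            continue
        region = reference.residues[peak.start : peak.end]
        for off in range(len(region) - W + 1):
            window = region[off : off + W]
            if "N" in window:
                continue
            for strand in "+-":
                site = window if strand == "+" else revcomp(window)
                score = log_odds(matrix, site)
                mism = sum(a != b for a, b in zip(site, cons))
                if score < threshold:
                    continue
                if max_mismatch is not None and mism > max_mismatch:
                    continue
                hits.append(
                    MotifHit(
                        peak_name=peak.name,
                        offset_in_peak=off,
                        genomic_start=peak.start + off,
                        strand=strand,
                        log_score=score,
                        mismatches_vs_consensus=mism,
                        site_sequence=site,
                    )
                )
    hits.sort(key=lambda h: (-h.log_score, h.genomic_start, h.strand))
    return hits


def rank_report(hits: list[MotifHit], top_n: int | None = None) -> pd.DataFrame:
    """Tabulate ranked hits; also returns a per-peak best-hit summary column.

    Ordering is the deterministic scan_peaks ordering regardless of input
    order.  ``top_n`` truncates the ranked rows (0 gives an empty table) but
    the per-peak summary is computed over all hits.
    """
    ordered = sorted(hits, key=lambda h: (-h.log_score, h.genomic_start, h.strand))
    best_by_peak: dict[str, MotifHit] = {}
    for h in ordered:
        best_by_peak.setdefault(h.peak_name, h)
    rows = ordered if top_n is None else ordered[:top_n]
    table = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "peak": h.peak_name,
                "genomic_start": h.genomic_start,
                "strand": h.strand,
                "log_score": h.log_score,
                "mismatches": h.mismatches_vs_consensus,
                "site": h.site_sequence,
                "peak_best": best_by_peak[h.peak_name] is h,
            }
            for i, h in enumerate(rows)
        ],
        columns=[
            "rank", "peak", "genomic_start", "strand",
            "log_score", "mismatches", "site", "peak_best",
        ],
    )
    table.attrs["best_by_peak"] = best_by_peak
    return table
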