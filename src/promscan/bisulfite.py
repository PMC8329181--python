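"""Bisulfite-sequencing methylation calling.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as T
after PCR) while 5-methyl-cytosine in CpG context is protected.  This module
models the conversion on both strands (OT = original top, OB = original
bottom), aligns sequenced clones back to the reference with an asymmetric
substitution scheme in which reference-C vs clone-T is a converted state, not
a mismatch, calls per-CpG methylation, computes per-clone conversion QC from
non-CpG cytosines, and renders lollipop-style summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord, revcomp

__all__ = [
    "BisulfiteReference",
    "CloneAlignment",
    "MethylationMatrix",
    "PrimerCheck",
    "find_cpg_sites",
    "bisulfite_convert",
    "align_clone",
    "call_methylation",
    "conversion_qc",
    "methylation_summary",
    "check_primer",
]

METHYLATED, UNMETHYLATED, AMBIGUOUS = "methylated", "unmethylated", "ambiguous"

_CALL_GLYPH = {METHYLATED: "●", UNMETHYLATED: "○", AMBIGUOUS: "·"}


def find_cpg_sites(residues: str) -> list[int]:
    """Positions of the C of every CpG dinucleotide on the plus strand."""
    return [i for i in range(len(residues) - 1) if residues[i : i + 2] == "CG"]


@dataclass
class BisulfiteReference:
    """An analyzed region plus the ordered plus-strand CpG-C positions."""

    region: SequenceRecord
    cpg_sites: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.cpg_sites:
            self.cpg_sites = find_cpg_sites(self.region.residues)
        res = self.region.residues
        seen = set()
        for p in self.cpg_sites:
            if res[p : p + 2] != "CG":
                raise ValueError(f"position {p} is not the C of a CpG")
            if p in seen:
                raise ValueError(f"duplicate CpG site {p}")
            seen.add(p)
        self.cpg_sites = sorted(self.cpg_sites)

    def ob_site(self, p: int) -> int:
        """Index of the CpG's C in the OB-strand (revcomp) representation."""
        return len(self.region) - p - 2


def bisulfite_convert(
    reference: BisulfiteReference,
    methylated_sites: set[int] | list[int],
    strand: str = "+",
) -> SequenceRecord:
    """Apply in-silico bisulfite conversion to one strand of the reference.

    ``strand`` "+" converts the top strand in place; "-" returns the converted
    bottom strand written 5'->3' (the reverse complement frame).  Every C is
    converted to T except the CpG cytosines listed in ``methylated_sites``
    (plus-strand C positions; CpG methylation is treated as symmetric, so the
    paired bottom-strand C of a methylated CpG is protected too).  Uracil is
    represented as T (sequenced clones are post-PCR).
    """
    methylated = set(methylated_sites)
    extra = methylated - set(reference.cpg_sites)
    if extra:
        raise ValueError(f"methylated positions not CpG sites: {sorted(extra)}")
    if strand == "+":
        seq = reference.region.residues
        protected = methylated
    elif strand == "-":
        seq = revcomp(reference.region.residues)
        protected = {reference.ob_site(p) for p in methylated}
    else:
        raise ValueError(f"bad strand {strand!r}")
    out = [
        "T" if (b == "C" and i not in protected) else b
        for i, b in enumerate(seq)
    ]
    return SequenceRecord(
        f"{reference.region.id}|bisulfite({strand})",
        "".join(out),
        reference.region.origin_offset,
    )


def _bisulfite_matrix() -> substitution_matrices.Array:
    """Asymmetric scores: rows = reference base, columns = clone base.

    Reference C vs clone T scores as a match (the converted state); other
    mismatches -1; N is neutral.
    """
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if "N" in (a, b):
                m[a, b] = 0.0
            elif a == b:
                m[a, b] = 1.0
            elif a == "C" and b == "T":
                m[a, b] = 1.0
            else:
                m[a, b] = -1.0
    return m


@dataclass
class CloneAlignment:
    clone_id: str
    strand: str  # which bisulfite strand the clone matches: '+' (OT) or '-' (OB)
    score: float
    identity: float
    ref_to_clone: dict[int, str]  # reference position (strand frame) -> clone base or '-'
    alignable: bool


def _pairwise(ref: str, clone: str):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _bisulfite_matrix()
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner.align(ref, clone)[0]


def align_clone(
    clone: SequenceRecord,
    reference: BisulfiteReference,
    identity_min: float = 0.8,
) -> CloneAlignment:
    """Globally align a clone against both bisulfite reference strands.

    The better-scoring strand is chosen (ties to OT).  Identity counts exact
    matches plus converted ref-C/clone-T positions over aligned columns; a
    clone below ``identity_min`` is flagged unalignable.
    """
    if not clone.residues:
        raise ValueError("empty clone")
    best = None
    for strand in "+-":
        ref = (
            reference.region.residues
            if strand == "+"
            else revcomp(reference.region.residues)
        )
        aln = _pairwise(ref, clone.residues)
        if best is None or aln.score > best[1].score:
            best = (strand, aln, ref)
    strand, aln, ref = best
    ref_to_clone: dict[int, str] = {}
    matches = aligned = 0
    ref_aln, clone_aln = aln[0], aln[1]
    rpos = 0
    for rb, cb in zip(ref_aln, clone_aln):
        if rb != "-":
            ref_to_clone[rpos] = cb
            if cb != "-":
                aligned += 1
                if rb == cb or (rb == "C" and cb == "T"):
                    matches += 1
            rpos += 1
    identity = matches / aligned if aligned else 0.0
    return CloneAlignment(
        clone_id=clone.id,
        strand=strand,
        score=float(aln.score),
        identity=identity,
        ref_to_clone=ref_to_clone,
        alignable=identity >= identity_min,
    )


def call_methylation(
    alignment: CloneAlignment, reference: BisulfiteReference
) -> list[str]:
    """Per-CpG-site call for one aligned clone.

    At the site's C position (in the clone's strand frame): clone C means the
    cytosine was protected (methylated), clone T means converted
    (unmethylated); a gap or any other base is ambiguous.
    """
    calls = []
    for p in reference.cpg_sites:
        pos = p if alignment.strand == "+" else reference.ob_site(p)
        base = alignment.ref_to_clone.get(pos, "-")
        if base == "C":
            calls.append(METHYLATED)
        elif base == "T":
            calls.append(UNMETHYLATED)
        else:
            calls.append(AMBIGUOUS)
    return calls


def conversion_qc(
    alignment: CloneAlignment,
    reference: BisulfiteReference,
    min_rate: float = 0.95,
) -> tuple[float, bool]:
    """Conversion rate over non-CpG cytosines: converted / total aligned.

    Non-CpG C positions of the aligned strand where the clone shows T count as
    converted, C as a conversion failure; gaps and other bases are excluded.
    Returns (rate, passed).  With no informative positions the rate is NaN and
    the clone passes with a warning.
    """
    if alignment.strand == "+":
        ref = reference.region.residues
        cpg_c = set(reference.cpg_sites)
    else:
        ref = revcomp(reference.region.residues)
        cpg_c = {reference.ob_site(p) for p in reference.cpg_sites}
    converted = total = 0
    for i, b in enumerate(ref):
        if b != "C" or i in cpg_c:
            continue
        base = alignment.ref_to_clone.get(i, "-")
        if base == "T":
            converted += 1
            total += 1
        elif base == "C":
            total += 1
    if total == 0:
        warnings.warn(
            f"clone {alignment.clone_id!r}: no informative non-CpG cytosines; "
            "conversion rate undefined, clone passes"
        )
        return float("nan"), True
    rate = converted / total
    return rate, rate >= min_rate


@dataclass
class MethylationMatrix:
    """Clones x CpG-sites call grid with per-clone conversion QC."""

    clone_ids: list[str]
    sites: list[int]
    calls: list[list[str]]  # one row per clone, values in {methylated,...}
    conversion_rate: list[float]
    passed_qc: list[bool]

    def __post_init__(self) -> None:
        n, m = len(self.clone_ids), len(self.sites)
        if any(len(row) != m for row in self.calls) or len(self.calls) != n:
            raise ValueError("call grid dimensions inconsistent")
        if len(self.conversion_rate) != n or len(self.passed_qc) != n:
            raise ValueError("per-clone QC length inconsistent")


def methylation_summary(matrix: MethylationMatrix):
    """Per-site methylated fractions, region mean, and a lollipop rendering.

    Fractions are computed over non-ambiguous calls of QC-passing clones; a
    site with no informative call is NaN (rendered '·').  Failing clones are
    excluded from the fractions but still rendered, marked with '!'.
    Returns (per_site_fraction, region_mean, lollipop_text).
    """
    passing = [i for i, ok in enumerate(matrix.passed_qc) if ok]
    if not passing:
        return (
            np.full(len(matrix.sites), np.nan),
            float("nan"),
            "# no clones passed conversion QC\n",
        )
    fractions = np.full(len(matrix.sites), np.nan)
    for j in range(len(matrix.sites)):
        col = [matrix.calls[i][j] for i in passing]
        informative = [c for c in col if c != AMBIGUOUS]
        if informative:
            fractions[j] = sum(c == METHYLATED for c in informative) / len(informative)
    region_mean = float(np.nanmean(fractions)) if np.isfinite(fractions).any() else float("nan")
    lines = []
    for i, cid in enumerate(matrix.clone_ids):
        glyphs = "".join(_CALL_GLYPH[c] for c in matrix.calls[i])
        mark = " " if matrix.passed_qc[i] else "!"
        lines.append(f"{mark}{cid}\t{glyphs}")
    summary_row = "".join(
        "·" if not np.isfinite(f) else ("●" if f >= 0.5 else "○")
        for f in fractions
    )
    lines.append(f" %meth\t{summary_row}")
    return fractions, region_mean, "\n".join(lines) + "\n"


@dataclass
class PrimerCheck:
    primer_region: tuple[int, int]
    n_cpg: int
    klass: str  # bisulfite_ok | methyl_specific | inadmissible


def check_primer(reference: BisulfiteReference, primer_interval: tuple[int, int]) -> PrimerCheck:
    """Classify a primer region by its CpG count.

    Bisulfite primers must conserve at most one CpG (``bisulfite_ok``);
    methylation-specific primers require three or more (``methyl_specific``);
    a region with exactly two satisfies neither rule (``inadmissible``).
    A CpG counts when any of its two bases overlaps the interval.
    """
    start, end = primer_interval
    if not (0 <= start < end <= len(reference.region)):
        raise ValueError(f"primer interval {primer_interval} outside reference")
    n = sum(1 for p in reference.cpg_sites if p + 2 > start and p < end)
    if n <= 1:
        klass = "bisulfite_ok"
    elif n >= 3:
        klass = "methyl_specific"
    else:
        klass = "inadmissible"
    return PrimerCheck((start, end), n, klass)
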