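"""Published annotation facts for the CXXC5 locus used by the analyses.

These are documented inputs (coordinates and exon structure as annotated),
not computed results; the analyses re-derive every downstream quantity from
them.  Promoter-frame coordinates follow the signed, no-zero convention of
:mod:`promscan.coords` with +1 at the first base of the annotated first exon
(Exon3 for the promoter region of transcript variant 2).
"""

from .coords import PromoterCoordinate, interval_length_promoter

# Core promoter fragment (Segment A) in the promoter frame anchored at Exon3.
SEGMENT_A = (PromoterCoordinate(-117), PromoterCoordinate(+103))

# Bisulfite-sequenced promoter windows (same frame).
BISULFITE_REGIONS = (
    (PromoterCoordinate(-930), PromoterCoordinate(-489)),
    (PromoterCoordinate(-179), PromoterCoordinate(+103)),
)

# Coding contribution of the two last exons, shared by all transcript
# variants: Exon10 carries 924 bp and Exon11 45 bp including the stop codon.
CODING_EXON_BP = {"Exon10": 924, "Exon11": 45}


def segment_a_length() -> int:
    """Length in bp of Segment A computed from its promoter-frame endpoints."""
    return interval_length_promoter(*SEGMENT_A)


def coding_region_length() -> int:
    """Total coding-region length summed over the annotated exon contributions."""
    return sum(CODING_EXON_BP.values())
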