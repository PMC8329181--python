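"""In-silico bisulfite conversion, clone alignment, and methylation calling."""

import numpy as np
import pytest

from promscan.bisulfite import (
    AMBIGUOUS,
    METHYLATED,
    UNMETHYLATED,
    BisulfiteReference,
    MethylationMatrix,
    align_clone,
    bisulfite_convert,
    call_methylation,
    check_primer,
    conversion_qc,
    find_cpg_sites,
    methylation_summary,
)
from promscan.io import SequenceRecord, revcomp
from promscan.simulate import CloneSimSpec, LocusSpec, make_clones, make_locus


def ref_from(seq: str) -> BisulfiteReference:
    return BisulfiteReference(SequenceRecord("ref", seq))


class TestConvert:
    def test_full_conversion_removes_all_c(self):
        ref = ref_from("ACGTCCGTACCA")
        out = bisulfite_convert(ref, set(), "+")
        assert "C" not in out.residues
        assert len(out) == len(ref.region)

    def test_methylated_cpg_survives(self):
        ref = ref_from("ACGTCCGTACCA")
        out = bisulfite_convert(ref, set(ref.cpg_sites), "+")
        survivors = [i for i, b in enumerate(out.residues) if b == "C"]
        assert survivors == ref.cpg_sites

    def test_per_position_rule(self):
        # CpG at position 1 methylated: its C kept, the non-CpG C converted
        ref = ref_from("ACGACA")
        assert bisulfite_convert(ref, {1}, "+").residues == "ACGATA"
        assert bisulfite_convert(ref, set(), "+").residues == "ATGATA"

    def test_bottom_strand_conversion(self):
        ref = ref_from("ACGT")
        # OB strand of ACGT is ACGT; its CpG C is protected when methylated
        assert bisulfite_convert(ref, {1}, "-").residues == "ACGT".replace("C", "C", 1)
        assert bisulfite_convert(ref, set(), "-").residues == "ATGT"

    def test_non_cpg_site_rejected(self):
        with pytest.raises(ValueError):
            bisulfite_convert(ref_from("ACGACA"), {4}, "+")

    def test_idempotent_on_own_output(self):
        ref = ref_from("ACGTCCGTACCAACGG")
        meth = {ref.cpg_sites[0]}
        once = bisulfite_convert(ref, meth, "+")
        again = bisulfite_convert(
            BisulfiteReference(once, cpg_sites=find_cpg_sites(once.residues)),
            set(find_cpg_sites(once.residues)) & meth,
            "+",
        )
        assert again.residues == once.residues


class TestAlign:
    def test_identical_fully_converted_clone(self):
        rec, _ = make_locus(LocusSpec(length=200, island_start=50, island_end=150), seed=2)
        ref = BisulfiteReference(rec)
        clone = bisulfite_convert(ref, set(), "+")
        aln = align_clone(clone, ref)
        assert aln.strand == "+" and aln.identity == pytest.approx(1.0)
        assert aln.alignable

    def test_bottom_strand_selected(self):
        rec, _ = make_locus(LocusSpec(length=200, island_start=50, island_end=150), seed=2)
        ref = BisulfiteReference(rec)
        clone = bisulfite_convert(ref, set(), "-")
        assert align_clone(clone, ref).strand == "-"

    def test_planted_deletion_reproduced(self):
        # deletion flanked by distinct bases so the optimal gap placement is
        # unique (gaps can slide within homopolymer runs otherwise)
        seq = "TTGAAGGATAGGATTAGAGGTAAGGATTGA"
        ref = ref_from(seq)
        conv = bisulfite_convert(ref, set(), "+").residues
        clone = SequenceRecord("del", conv[:17] + conv[19:])  # drop "GA" at 17
        aln = align_clone(clone, ref)
        gaps = [p for p, b in aln.ref_to_clone.items() if b == "-"]
        assert len(gaps) == 2
        assert all(abs(g - 18) <= 2 for g in gaps)

    def test_unalignable_flagged(self, rng):
        rec, _ = make_locus(LocusSpec(length=120, island_start=30, island_end=90), seed=6)
        ref = BisulfiteReference(rec)
        junk = SequenceRecord("junk", "".join(rng.choice(list("ACGT"), size=120)))
        assert not align_clone(junk, ref).alignable

    def test_empty_clone_rejected(self):
        ref = ref_from("ACGTACGT")
        with pytest.raises(ValueError):
            align_clone(SequenceRecord("e", "A").__class__("e", ""), ref)


class TestCallMethylation:
    def test_fully_converted_all_unmethylated(self):
        ref = ref_from("TTCGAACGTTACGTT")
        clone = bisulfite_convert(ref, set(), "+")
        calls = call_methylation(align_clone(clone, ref), ref)
        assert calls == [UNMETHYLATED] * len(ref.cpg_sites)

    def test_selected_sites_methylated(self):
        rec, _ = make_locus(LocusSpec(length=300, island_start=80, island_end=220), seed=8)
        ref = BisulfiteReference(rec)
        assert len(ref.cpg_sites) >= 6
        chosen = {ref.cpg_sites[2], ref.cpg_sites[5]}
        clone = bisulfite_convert(ref, chosen, "+")
        calls = call_methylation(align_clone(clone, ref), ref)
        got = {p for p, c in zip(ref.cpg_sites, calls) if c == METHYLATED}
        assert got == chosen

    def test_gap_spanning_cpg_is_ambiguous(self):
        # A/G-rich context: the deleted methylated CpG cannot be re-read as a
        # converted C (no clone T nearby), so the gap placement is forced
        ref = ref_from("GGAACGAAGGGGAACGAAGG")
        conv = bisulfite_convert(ref, set(ref.cpg_sites), "+").residues
        p = ref.cpg_sites[0]
        clone = SequenceRecord("gap", conv[:p] + conv[p + 2 :])
        calls = call_methylation(align_clone(clone, ref), ref)
        assert calls[0] == AMBIGUOUS
        assert calls[1] == METHYLATED


class TestConversionQc:
    def test_fully_converted_rate_one(self):
        ref = ref_from("CCTACGTCCTTACC")
        clone = bisulfite_convert(ref, set(), "+")
        rate, ok = conversion_qc(align_clone(clone, ref), ref)
        assert rate == pytest.approx(1.0) and ok

    @pytest.mark.parametrize("retained,expected,passes", [(1, 0.95, True), (5, 0.75, False)])
    def test_rate_is_direct_count(self, retained, expected, passes):
        # reference with exactly 20 non-CpG C and one CpG
        seq = ("CCT" * 10) + "ACGA" + ("TA" * 10)
        ref = ref_from(seq)
        non_cpg = [i for i, b in enumerate(seq) if b == "C" and i not in ref.cpg_sites]
        assert len(non_cpg) == 20  # CpG C excluded
        conv = list(bisulfite_convert(ref, set(), "+").residues)
        for i in non_cpg[:retained]:
            conv[i] = "C"  # conversion failures
        clone = SequenceRecord("c", "".join(conv))
        rate, ok = conversion_qc(align_clone(clone, ref), ref, min_rate=0.95)
        assert rate == pytest.approx(expected)
        assert ok is passes

    def test_no_informative_positions_passes_with_warning(self):
        ref = ref_from("TTACGTTATT")  # only C is the CpG C
        clone = bisulfite_convert(ref, set(), "+")
        with pytest.warns(UserWarning, match="undefined"):
            rate, ok = conversion_qc(align_clone(clone, ref), ref)
        assert np.isnan(rate) and ok


class TestSummary:
    def _matrix_from_sim(self, n_clones, profile_levels=(0.9, 0.05), seed=13,
                         **noise):
        rec, truth = make_locus(
            LocusSpec(length=360, island_start=140, island_end=300,
                      flank_methylation=profile_levels[0],
                      island_methylation=profile_levels[1]),
            seed=seed,
        )
        ref = BisulfiteReference(rec)
        clones, tcalls = make_clones(
            ref, truth["methylation_probs"],
            CloneSimSpec(n_clones=n_clones, seed=seed, **noise),
        )
        calls, rates, passed = [], [], []
        for c in clones:
            aln = align_clone(c, ref)
            calls.append(call_methylation(aln, ref))
            r, ok = conversion_qc(aln, ref)
            rates.append(r)
            passed.append(ok)
        matrix = MethylationMatrix([c.id for c in clones], ref.cpg_sites,
                                   calls, rates, passed)
        return rec, ref, truth, tcalls, matrix

    def test_zero_noise_reproduces_planted_matrix(self):
        _, _, _, tcalls, matrix = self._matrix_from_sim(12)
        assert matrix.calls == tcalls

    def test_step_pattern_recovered(self):
        rec, ref, truth, _, matrix = self._matrix_from_sim(20)
        fractions, mean, art = methylation_summary(matrix)
        start, end = truth["island"]
        n = 20
        for p, f in zip(ref.cpg_sites, fractions):
            planted = truth["methylation_probs"][p]
            se = np.sqrt(planted * (1 - planted) / n)
            assert abs(f - planted) <= max(3 * se, 1e-9) + 1e-12
        assert "●" in art and "○" in art

    def test_fraction_convergence(self):
        """Per-site estimates approach planted probabilities as clones grow."""
        _, ref, truth, _, matrix = self._matrix_from_sim(200, seed=21)
        fractions, _, _ = methylation_summary(matrix)
        n = 200
        for p, f in zip(ref.cpg_sites, fractions):
            planted = truth["methylation_probs"][p]
            se = np.sqrt(planted * (1 - planted) / n)
            assert abs(f - planted) <= max(3 * se, 0.01)

    def test_single_clone_all_methylated(self):
        ref = ref_from("TTCGAACGTT")
        clone = bisulfite_convert(ref, set(ref.cpg_sites), "+")
        aln = align_clone(clone, ref)
        matrix = MethylationMatrix(
            ["c1"], ref.cpg_sites, [call_methylation(aln, ref)], [1.0], [True]
        )
        fractions, mean, _ = methylation_summary(matrix)
        assert fractions == pytest.approx([1.0, 1.0])
        assert mean == pytest.approx(1.0)

    def test_all_ambiguous_site_rendered_dot(self):
        ref = ref_from("TTCGAACGTT")
        matrix = MethylationMatrix(
            ["c1", "c2"], ref.cpg_sites,
            [[AMBIGUOUS, UNMETHYLATED], [AMBIGUOUS, METHYLATED]],
            [1.0, 1.0], [True, True],
        )
        fractions, _, art = methylation_summary(matrix)
        assert np.isnan(fractions[0]) and fractions[1] == pytest.approx(0.5)
        assert art.splitlines()[-1].split("\t")[1][0] == "·"

    def test_all_failed_clones_empty_summary(self):
        ref = ref_from("TTCGAACGTT")
        matrix = MethylationMatrix(
            ["c1"], ref.cpg_sites, [[METHYLATED, METHYLATED]], [0.5], [False]
        )
        fractions, mean, art = methylation_summary(matrix)
        assert np.isnan(fractions).all() and np.isnan(mean)
        assert "no clones passed" in art

    def test_failed_clone_excluded_but_rendered(self):
        ref = ref_from("TTCGAACGTT")
        matrix = MethylationMatrix(
            ["good", "bad"], ref.cpg_sites,
            [[UNMETHYLATED, UNMETHYLATED], [METHYLATED, METHYLATED]],
            [1.0, 0.5], [True, False],
        )
        fractions, _, art = methylation_summary(matrix)
        assert fractions == pytest.approx([0.0, 0.0])
        assert any(line.startswith("!bad") for line in art.splitlines())


class TestPrimerCheck:
    @pytest.mark.parametrize("n_cpg,klass", [(0, "bisulfite_ok"), (1, "bisulfite_ok"),
                                             (2, "inadmissible"), (3, "methyl_specific"),
                                             (5, "methyl_specific")])
    def test_cpg_count_rules(self, n_cpg, klass):
        seq = "TTA" + "CGTTA" * n_cpg + "TTATTT"
        ref = ref_from(seq)
        check = check_primer(ref, (0, len(seq)))
        assert check.n_cpg == n_cpg
        assert check.klass == klass

    def test_interval_bounds_enforced(self):
        ref = ref_from("ACGTACGT")
        with pytest.raises(ValueError):
            check_primer(ref, (0, 100))
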