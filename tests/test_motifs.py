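"""PFM parsing, log-odds scoring, and peak-restricted scanning."""

import math

import numpy as np
import pytest

from promscan.io import Peak, SequenceRecord, revcomp
from promscan.motifs import (
    PositionMatrix,
    consensus,
    log_odds,
    rank_report,
    read_jaspar,
    scan_peaks,
)
from promscan.simulate import make_peaks_with_motifs

JASPAR_TEXT = """\
>MA0000.1 TESTTF
A  [ 10  0  1  9 ]
C  [  0  1  0  0 ]
G  [  0  9  9  0 ]
T  [  0  0  0  1 ]
"""


class TestReadJaspar:
    def test_labeled_rows(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(JASPAR_TEXT)
        m = read_jaspar(p)
        assert m.tf_name == "TESTTF" and m.width == 4
        assert consensus(m) == "AGGA"

    def test_row_order_is_label_driven(self, tmp_path):
        shuffled = (
            ">MA0000.1 TESTTF\n"
            "T  [  0  0  0  1 ]\n"
            "G  [  0  9  9  0 ]\n"
            "C  [  0  1  0  0 ]\n"
            "A  [ 10  0  1  9 ]\n"
        )
        a = tmp_path / "a.jaspar"
        b = tmp_path / "b.jaspar"
        a.write_text(JASPAR_TEXT)
        b.write_text(shuffled)
        assert np.array_equal(read_jaspar(a).counts, read_jaspar(b).counts)

    def test_raw_unlabeled_matrix(self, tmp_path):
        p = tmp_path / "raw.pfm"
        p.write_text("10 0 1 9\n0 1 0 0\n0 9 9 0\n0 0 0 1\n")
        assert consensus(read_jaspar(p)) == "AGGA"

    def test_missing_row_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">X Y\nA [1 2 3 4]\nC [1 2 3 4]\nG [1 2 3 4]\n")
        with pytest.raises(ValueError, match="4 matrix rows"):
            read_jaspar(p)

    def test_unequal_widths_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text("A [1 2 3 4]\nC [1 2 3 4]\nG [1 2 3]\nT [1 2 3 4]\n")
        with pytest.raises(ValueError, match="unequal"):
            read_jaspar(p)

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text("A [1 2 3 -4]\nC [1 2 3 4]\nG [1 2 3 4]\nT [1 2 3 4]\n")
        with pytest.raises(ValueError):
            read_jaspar(p)


class TestConsensus:
    def test_elf1_core(self, elf1_like_matrix):
        assert consensus(elf1_like_matrix) == "AGGAA"

    def test_maz_cognate(self, maz_like_matrix):
        assert consensus(maz_like_matrix) == "GGGAGGG"

    def test_tie_break_fixed_order(self):
        counts = np.array([[5, 5], [5, 5], [0, 5], [0, 0]], float)
        m = PositionMatrix("tie", np.hstack([counts, counts]))
        assert consensus(m) == "AAAA"  # ties resolve A < C < G < T


class TestLogOdds:
    def test_uniform_matrix_scores_zero(self):
        m = PositionMatrix("uniform", np.full((4, 5), 3.0))
        for site in ["AAAAA", "ACGTA", "GGGGG"]:
            assert log_odds(m, site) == pytest.approx(0.0)

    def test_best_site_attains_max(self, maz_like_matrix):
        best = consensus(maz_like_matrix)
        assert log_odds(maz_like_matrix, best) == pytest.approx(
            maz_like_matrix.max_score, abs=1e-9
        )

    def test_hand_computed_value(self):
        """Independent arithmetic evaluation of the log-odds formula."""
        counts = np.array(
            [[8, 0, 4, 0], [0, 8, 4, 0], [0, 0, 0, 8], [0, 0, 0, 0]], float
        )
        m = PositionMatrix("hand", counts, pseudocount=1.0)
        site = "ACAG"

        def col(base_count, colsum):
            return math.log2(((base_count + 1.0 * 0.25) / (colsum + 1.0)) / 0.25)

        expected = col(8, 8) + col(8, 8) + col(4, 8) + col(8, 8)
        assert log_odds(m, site) == pytest.approx(expected)

    def test_background_expectation_nonpositive(self, elf1_like_matrix, rng):
        """Mean score over background-drawn sites is <= 0 (information inequality)."""
        W = elf1_like_matrix.width
        sites = rng.choice(list("ACGT"), size=(10_000, W))
        scores = [log_odds(elf1_like_matrix, "".join(s)) for s in sites]
        assert np.mean(scores) <= 0

    def test_n_site_unscorable(self, elf1_like_matrix):
        with pytest.raises(ValueError, match="unscorable"):
            log_odds(elf1_like_matrix, "ANGAA")


def brute_scan(reference, peaks, matrix, max_mismatch, frac):
    """Exhaustive window scoring written independently of scan_peaks."""
    cons = consensus(matrix)
    out = []
    for pk in peaks:
        if pk.end - pk.start < matrix.width:
            continue
        for off in range(pk.end - pk.start - matrix.width + 1):
            window = reference.residues[pk.start + off : pk.start + off + matrix.width]
            if "N" in window:
                continue
            for strand, site in (("+", window), ("-", revcomp(window))):
                score = sum(
                    matrix.log_odds_matrix["ACGT".index(b), j]
                    for j, b in enumerate(site)
                )
                mism = sum(a != b for a, b in zip(site, cons))
                if score >= frac * matrix.max_score and (
                    max_mismatch is None or mism <= max_mismatch
                ):
                    out.append((pk.name, off, strand, round(score, 9), mism))
    return sorted(out, key=lambda r: (-r[3], r[1], r[2]))


class TestScanPeaks:
    def test_planted_consensus_recovered(self, maz_like_matrix):
        ref, peaks, truth = make_peaks_with_motifs(maz_like_matrix, 10, seed=1)
        hits = scan_peaks(ref, peaks, maz_like_matrix, score_min_fraction=0.9)
        best = {}
        for h in hits:
            best.setdefault(h.peak_name, h)
        for t in truth:
            assert t is not None
            h = best[t["peak"]]
            assert (h.offset_in_peak, h.strand) == (t["offset"], t["strand"])
            assert h.mismatches_vs_consensus == 0

    def test_strand_symmetric_scores(self, elf1_like_matrix):
        cons = consensus(elf1_like_matrix)
        fwd = SequenceRecord("f", "TTTT" + cons + "TTTT")
        rev = SequenceRecord("r", "TTTT" + revcomp(cons) + "TTTT")
        peak_f = [Peak("f", 0, len(fwd))]
        peak_r = [Peak("r", 0, len(rev))]
        (hf,) = scan_peaks(fwd, peak_f, elf1_like_matrix, score_min_fraction=0.95)
        (hr,) = scan_peaks(rev, peak_r, elf1_like_matrix, score_min_fraction=0.95)
        assert hf.strand == "+" and hr.strand == "-"
        assert hf.log_score == pytest.approx(hr.log_score)

    def test_at_only_peak_no_hits(self, maz_like_matrix, rng):
        seq = "".join(rng.choice(list("AT"), size=100))
        ref = SequenceRecord("at", seq)
        hits = scan_peaks(ref, [Peak("at", 0, 100)], maz_like_matrix,
                          score_min_fraction=0.8)
        assert hits == []
        assert brute_scan(ref, [Peak("at", 0, 100)], maz_like_matrix, None, 0.8) == []

    def test_matches_brute_force(self, elf1_like_matrix, rng):
        """scan_peaks equals exhaustive window scoring on random peaks."""
        for _ in range(30):
            n = int(rng.integers(60, 200))
            seq = "".join(rng.choice(list("ACGT"), size=n,
                                     p=[0.3, 0.2, 0.3, 0.2]))
            ref = SequenceRecord("r", seq)
            cuts = sorted(rng.choice(np.arange(1, n), size=3, replace=False))
            peaks = [Peak("r", 0, int(cuts[0]), "p0"),
                     Peak("r", int(cuts[1]), int(cuts[2]) if cuts[2] > cuts[1] else n, "p1")]
            peaks = [p for p in peaks if len(p) >= elf1_like_matrix.width]
            frac = float(rng.uniform(0.2, 0.8))
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hits = scan_peaks(ref, peaks, elf1_like_matrix,
                                  score_min_fraction=frac)
            got = [
                (h.peak_name, h.offset_in_peak, h.strand,
                 round(h.log_score, 9), h.mismatches_vs_consensus)
                for h in hits
            ]
            assert sorted(got, key=lambda r: (-r[3], r[1], r[2])) == brute_scan(
                ref, peaks, elf1_like_matrix, None, frac
            )

    def test_revcomp_reference_reflection(self, elf1_like_matrix, rng):
        """Scanning the reverse-complemented reference swaps strands and
        reflects coordinates; the score multiset is identical."""
        for _ in range(50):
            n = int(rng.integers(40, 120))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            ref = SequenceRecord("r", seq)
            peaks = [Peak("r", 5, n - 5)]
            rc_ref = SequenceRecord("r", revcomp(seq))
            rc_peaks = [Peak("r", 5, n - 5)]
            fwd = scan_peaks(ref, peaks, elf1_like_matrix, score_min_fraction=0.5)
            rev = scan_peaks(rc_ref, rc_peaks, elf1_like_matrix, score_min_fraction=0.5)
            fwd_set = sorted(
                (n - h.genomic_start - elf1_like_matrix.width,
                 {"+": "-", "-": "+"}[h.strand], round(h.log_score, 9))
                for h in fwd
            )
            rev_set = sorted(
                (h.genomic_start, h.strand, round(h.log_score, 9)) for h in rev
            )
            assert fwd_set == rev_set

    def test_threshold_monotonic(self, maz_like_matrix):
        ref, peaks, _ = make_peaks_with_motifs(maz_like_matrix, 5, seed=2)
        prev = None
        for frac in [0.3, 0.5, 0.7, 0.9]:
            n = len(scan_peaks(ref, peaks, maz_like_matrix, score_min_fraction=frac))
            if prev is not None:
                assert n <= prev
            prev = n

    def test_mismatch_filter(self, maz_like_matrix):
        ref, peaks, truth = make_peaks_with_motifs(
            maz_like_matrix, 6, fidelity=1 - 2 / 7, seed=4
        )
        assert all(t["n_mismatches"] == 2 for t in truth)
        loose = scan_peaks(ref, peaks, maz_like_matrix, max_mismatch=2,
                           score_min_fraction=0.0)
        tight = scan_peaks(ref, peaks, maz_like_matrix, max_mismatch=1,
                           score_min_fraction=0.0)
        loose_peaks = {h.peak_name for h in loose if h.mismatches_vs_consensus <= 2}
        assert {t["peak"] for t in truth} <= loose_peaks
        assert all(h.mismatches_vs_consensus <= 1 for h in tight)

    def test_short_peak_skipped_with_warning(self, elf1_like_matrix):
        ref = SequenceRecord("r", "ACGTACGTACGT")
        with pytest.warns(UserWarning, match="shorter than motif"):
            hits = scan_peaks(ref, [Peak("r", 0, 3)], elf1_like_matrix)
        assert hits == []


class TestRankReport:
    def test_order_independent_of_input(self, maz_like_matrix, rng):
        ref, peaks, _ = make_peaks_with_motifs(maz_like_matrix, 8, seed=9)
        hits = scan_peaks(ref, peaks, maz_like_matrix, score_min_fraction=0.5)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert rank_report(shuffled).equals(rank_report(hits))

    def test_equal_scores_leftmost_first(self, maz_like_matrix):
        cons = "GGGAGGG"
        ref = SequenceRecord("r", "TT" + cons + "TTTT" + cons + "TT")
        hits = scan_peaks(ref, [Peak("r", 0, len(ref))], maz_like_matrix,
                          score_min_fraction=0.99)
        table = rank_report(hits)
        starts = table[table["log_score"] == table["log_score"].max()]["genomic_start"]
        assert list(starts) == sorted(starts)

    def test_top_zero_empty_but_summary_kept(self, maz_like_matrix):
        ref, peaks, _ = make_peaks_with_motifs(maz_like_matrix, 3, seed=5)
        hits = scan_peaks(ref, peaks, maz_like_matrix, score_min_fraction=0.5)
        table = rank_report(hits, top_n=0)
        assert len(table) == 0
        assert len(table.attrs["best_by_peak"]) > 0
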