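"""G-quadruplex consensus scanning.

Putative G4-forming sequences are found with the canonical consensus
G{3,} N{1,7} G{3,} N{1,7} G{3,} N{1,7} G{3,} : four runs of at least three
guanines separated by loops of one to seven arbitrary nucleotides.  Minus
strand hits come from scanning the reverse complement (i.e. C-run patterns on
the plus strand) and are reported in plus-strand coordinates.

The canonical hit at each anchor (the leftmost base of a maximal G-run) is the
lazy match: minimal run lengths and minimal loops, backtracking rightmost
first — the shortest valid decomposition in left-to-right lexicographic order.
``report_all`` enumerates every decomposition instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SequenceRecord, revcomp

__all__ = ["G4Hit", "G4Locus", "find_g4_hits", "merge_hits", "g4_run_score"]


@dataclass(frozen=True)
class G4Hit:
    start: int
    end: int
    strand: str
    g_run_lengths: tuple[int, int, int, int]
    loop_lengths: tuple[int, int, int]
    matched_sequence: str

    def __post_init__(self) -> None:
        if self.end - self.start != sum(self.g_run_lengths) + sum(self.loop_lengths):
            raise ValueError("hit span inconsistent with run/loop decomposition")

    @property
    def total_g_run(self) -> int:
        return sum(self.g_run_lengths)


@dataclass
class G4Locus:
    start: int
    end: int
    strand: str
    n_merged_hits: int
    best_hit: G4Hit


def _decompose(seq: str, anchor: int, min_run: int, loop_min: int, loop_max: int,
               first_only: bool) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """DFS over run/loop decompositions starting at ``anchor``.

    Choices are explored smallest-first at every level and the deepest level
    backtracks first, so the first solution found is the lazy canonical one.
    """
    n = len(seq)
    out: list[tuple[tuple[int, ...], tuple[int, ...]]] = []

    def g_extent(i: int) -> int:
        j = i
        while j < n and seq[j] == "G":
            j += 1
        return j - i

    def rec(pos: int, runs: tuple[int, ...], loops: tuple[int, ...]) -> bool:
        if len(runs) == 4:
            out.append((runs, loops))
            return True
        ext = g_extent(pos)
        if ext < min_run:
            return False
        for run in range(min_run, ext + 1):
            nxt = pos + run
            if len(runs) == 3:
                out.append((runs + (run,), loops))
                if first_only:
                    return True
                continue
            for loop in range(loop_min, loop_max + 1):
                # loops may contain G; the only constraint is their length
                if nxt + loop >= n:
                    break
                if rec(nxt + loop, runs + (run,), loops + (loop,)) and first_only:
                    return True
        return False

    rec(anchor, (), ())
    return out


def find_g4_hits(
    seq: SequenceRecord,
    min_run: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    strands: str = "+-",
    report_all: bool = False,
) -> list[G4Hit]:
    """Scan for G4 consensus matches on the requested strands.

    Returns one canonical (lazy) hit per anchor position, or every valid
    run/loop decomposition when ``report_all`` is set.  Hits are sorted by
    (start, strand).
    """
    if loop_min > loop_max:
        raise ValueError(f"loop_min {loop_min} > loop_max {loop_max}")
    if loop_min < 1:
        raise ValueError("loop_min must be >= 1")
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    hits: list[G4Hit] = []
    L = len(seq)
    for strand in strands:
        if strand not in "+-":
            raise ValueError(f"bad strand {strand!r}")
        s = seq.residues if strand == "+" else revcomp(seq.residues)
        for anchor in range(L):
            if s[anchor] != "G" or (anchor > 0 and s[anchor - 1] == "G"):
                continue
            decos = _decompose(s, anchor, min_run, loop_min, loop_max,
                               first_only=not report_all)
            for runs, loops in decos:
                span = sum(runs) + sum(loops)
                start, end = anchor, anchor + span
                if strand == "-":
                    start, end = L - end, L - start
                hits.append(
                    G4Hit(
                        start=start,
                        end=end,
                        strand=strand,
                        g_run_lengths=tuple(runs),
                        loop_lengths=tuple(loops),
                        matched_sequence=s[anchor : anchor + span],
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand, h.end))
    return hits


def merge_hits(hits: list[G4Hit], max_gap: int = 0) -> list[G4Locus]:
    """Consolidate overlapping/adjacent same-strand hits into loci.

    ``best_hit`` is the member with the largest total G-run content, ties
    broken by leftmost start.
    """
    loci: list[G4Locus] = []
    for strand in "+-":
        group = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: (h.start, h.end)
        )
        cluster: list[G4Hit] = []
        for h in group:
            if cluster and h.start <= max(c.end for c in cluster) + max_gap:
                cluster.append(h)
            else:
                if cluster:
                    loci.append(_make_locus(cluster, strand))
                cluster = [h]
        if cluster:
            loci.append(_make_locus(cluster, strand))
    loci.sort(key=lambda l: (l.start, l.strand))
    return loci


def _make_locus(cluster: list[G4Hit], strand: str) -> G4Locus:
    best = max(cluster, key=lambda h: (h.total_g_run, -h.start))
    return G4Locus(
        start=min(h.start for h in cluster),
        end=max(h.end for h in cluster),
        strand=strand,
        n_merged_hits=len(cluster),
        best_hit=best,
    )


def g4_run_score(seq: SequenceRecord, window: int = 25):
    """G4Hunter-style windowed G-richness score in [-4, 4].

    Each base in a run of k identical G (C) contributes +min(k,4) (-min(k,4));
    other bases contribute 0.  The window mean is reported; positive values
    favor a plus-strand G4, negative values the minus strand.
    """
    from .cgi import WindowProfile, _window_starts

    if window < 1:
        raise ValueError("window must be >= 1")
    res = seq.residues
    n = len(res)
    base = np.zeros(n)
    i = 0
    while i < n:
        b = res[i]
        j = i
        while j < n and res[j] == b:
            j += 1
        if b == "G":
            base[i:j] = min(j - i, 4)
        elif b == "C":
            base[i:j] = -min(j - i, 4)
        i = j
    starts = _window_starts(n, window, 1)
    csum = np.concatenate([[0.0], np.cumsum(base)])
    values = (csum[starts + window] - csum[starts]) / window
    return WindowProfile(window, 1, starts, values, np.zeros(len(starts), dtype=bool))
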