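"""Sliding-window CpG-island profiling.

Three per-window statistics over a promoter locus:

* GC content, (G+C)/(A+C+G+T) — N excluded from both counts;
* GC skew, (G-C)/(G+C) — strand asymmetry of G vs C;
* observed/expected CpG ratio, (N_CpG * L)/(N_C * N_G), the Gardiner-Garden &
  Frommer statistic, with L the number of non-N bases in the window;

plus a CpG-island caller that merges maximal runs of windows that jointly pass
a GC and an O/E threshold.  Defaults (window 100, step 1, GC >= 0.5,
O/E >= 0.6, min length 200) are the conventional Cpgplot settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import SequenceRecord, revcomp

__all__ = [
    "WindowProfile",
    "CpGIsland",
    "gc_content",
    "gc_skew",
    "cpg_obs_exp",
    "cumulative_gc_skew",
    "detect_cgi",
]

N_FLAG_FRACTION = 0.10  # windows with more N than this are flagged


@dataclass
class WindowProfile:
    """Per-window values over a sequence; NaN marks undefined windows."""

    window: int
    step: int
    starts: np.ndarray  # window start offsets, strictly increasing by `step`
    values: np.ndarray  # one value per window; NaN where undefined
    flagged: np.ndarray  # True where the window has > 10% N

    def __len__(self) -> int:
        return len(self.starts)


def _window_starts(n: int, window: int, step: int) -> np.ndarray:
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds sequence length {n}")
    # last partial window dropped, never padded
    return np.arange(0, n - window + 1, step)


def _base_indicator(seq: str) -> dict[str, np.ndarray]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return {b: (arr == ord(b)).astype(np.int64) for b in "ACGTN"}


def _window_sums(indicator: np.ndarray, starts: np.ndarray, window: int) -> np.ndarray:
    csum = np.concatenate([[0], np.cumsum(indicator)])
    return csum[starts + window] - csum[starts]


def _profile(seq: SequenceRecord, window: int, step: int):
    starts = _window_starts(len(seq), window, step)
    ind = _base_indicator(seq.residues)
    sums = {b: _window_sums(ind[b], starts, window) for b in "ACGTN"}
    flagged = sums["N"] > N_FLAG_FRACTION * window
    return starts, sums, flagged


def gc_content(seq: SequenceRecord, window: int, step: int = 1) -> WindowProfile:
    """Per-window GC fraction; windows of only N are NaN."""
    starts, s, flagged = _profile(seq, window, step)
    denom = s["A"] + s["C"] + s["G"] + s["T"]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, (s["G"] + s["C"]) / np.maximum(denom, 1), np.nan)
    values[denom == 0] = np.nan
    return WindowProfile(window, step, starts, values, flagged)


def gc_skew(seq: SequenceRecord, window: int, step: int = 1) -> WindowProfile:
    """Per-window (G-C)/(G+C); windows without any G or C are NaN."""
    starts, s, flagged = _profile(seq, window, step)
    gc = s["G"] + s["C"]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(gc > 0, (s["G"] - s["C"]) / np.maximum(gc, 1), np.nan)
    values[gc == 0] = np.nan
    return WindowProfile(window, step, starts, values, flagged)


def cumulative_gc_skew(seq: SequenceRecord) -> np.ndarray:
    """Cumulative (G-C) running sum per position (N and A/T contribute 0)."""
    ind = _base_indicator(seq.residues)
    return np.cumsum(ind["G"] - ind["C"])


def cpg_obs_exp(seq: SequenceRecord, window: int, step: int = 1) -> WindowProfile:
    """Per-window observed/expected CpG ratio.

    O/E = count(CG) * L / (count(C) * count(G)) with L the non-N length of the
    window; NaN when the window has no C or no G.  CG dinucleotides are counted
    only when both bases fall inside the window.
    """
    starts, s, flagged = _profile(seq, window, step)
    res = seq.residues
    arr = np.frombuffer(res.encode(), dtype=np.uint8)
    cg = ((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(cg)])
    # dinucleotide starting at i is inside window [w, w+window) iff i <= w+window-2
    n_cg = csum[np.minimum(starts + window - 1, len(cg))] - csum[np.minimum(starts, len(cg))]
    length = s["A"] + s["C"] + s["G"] + s["T"]
    denom = s["C"] * s["G"]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, n_cg * length / np.maximum(denom, 1), np.nan)
    values[denom == 0] = np.nan
    return WindowProfile(window, step, starts, values, flagged)


@dataclass
class CpGIsland:
    """A maximal run of qualifying windows merged into one island."""

    start: int
    end: int
    mean_gc: float
    mean_obs_exp: float
    oversized: bool = False  # longer than the conventional 2000 bp upper bound

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_cgi(
    seq: SequenceRecord,
    window: int = 100,
    step: int = 1,
    gc_threshold: float = 0.5,
    oe_threshold: float = 0.6,
    min_length: int = 200,
) -> list[CpGIsland]:
    """Call CpG islands as merged runs of windows passing both thresholds.

    A window qualifies when GC >= gc_threshold and O/E >= oe_threshold.  Each
    qualifying window covers [start, start + window); islands are the
    connected components of the union of those spans (so raising a threshold
    can only shrink the reported total), reported when the component is at
    least ``min_length`` bp.  Island statistics are the means of the member
    windows' values, so stored invariants hold exactly.  Islands longer than
    2000 bp are reported but flagged ``oversized``.
    """
    if len(seq) < window:
        import warnings

        warnings.warn(f"sequence {seq.id!r} shorter than window; no islands called")
        return []
    gc = gc_content(seq, window, step)
    oe = cpg_obs_exp(seq, window, step)
    with np.errstate(invalid="ignore"):
        ok = (
            np.nan_to_num(gc.values, nan=-1.0) >= gc_threshold
        ) & (np.nan_to_num(oe.values, nan=-1.0) >= oe_threshold)
    islands: list[CpGIsland] = []
    idx = np.flatnonzero(ok)
    if len(idx) == 0:
        return islands
    # components: qualifying spans [start, start+window) that touch or overlap
    comp_start = 0
    for k in range(1, len(idx) + 1):
        last_end = int(gc.starts[idx[k - 1]]) + window
        if k < len(idx) and int(gc.starts[idx[k]]) <= last_end:
            continue
        members = idx[comp_start:k]
        start = int(gc.starts[members[0]])
        end = int(gc.starts[members[-1]]) + window
        if end - start >= min_length:
            islands.append(
                CpGIsland(
                    start=start,
                    end=end,
                    mean_gc=float(np.mean(gc.values[members])),
                    mean_obs_exp=float(np.mean(oe.values[members])),
                    oversized=(end - start) > 2000,
                )
            )
        comp_start = k
    return islands
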