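"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the statistical structure the analyses assume: a
GC-rich locus carrying an unmethylated CpG island inside methylated,
AT-richer flanking DNA; G-quadruplex consensus motifs and TF motif instances
planted inside peak intervals; bisulfite clone reads with conversion failures
and sequencing errors; sigmoidal melt curves; CD band-rule spectra; and Ct
tables with known fold changes.

All randomness flows from one integer seed through stage-name-salted
substreams, so adding a generator never perturbs existing fixtures and
identical inputs give byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bisulfite import BisulfiteReference, bisulfite_convert, find_cpg_sites
from .biophys import MeltCurve, Spectrum
from .io import Peak, SequenceRecord, revcomp
from .motifs import PositionMatrix, consensus

__all__ = [
    "LocusSpec",
    "CloneSimSpec",
    "substream",
    "random_sequence",
    "make_locus",
    "make_clones",
    "make_peaks_with_motifs",
    "make_melt_curve",
    "melt_closed_form",
    "make_cd_spectrum",
    "make_qpcr_table",
]

_BASES = np.array(list("ACGT"))


def substream(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one named stage of one master seed."""
    salt = zlib.crc32(stage.encode()) & 0xFFFFFFFF
    return np.random.default_rng([salt, int(seed) & 0x7FFFFFFF])


def random_sequence(
    rng: np.random.Generator,
    length: int,
    gc: float,
    cpg_oe: float,
    gc_tol: float = 0.02,
    oe_tol: float = 0.1,
    max_attempts: int = 200,
) -> str:
    """Sample a sequence hitting a GC fraction and CpG observed/expected target.

    Naive IID base sampling cannot reach elevated O/E, so the sampler emits
    whole CG dinucleotide blocks at a back-solved rate w/(1+w) = OE * (GC/2)^2
    interleaved with single bases whose composition restores the overall GC
    target; accidental C->G adjacencies between emissions are redrawn.
    Rejection-sampled until measured GC is within ``gc_tol`` and O/E within
    ``oe_tol``; raises after ``max_attempts`` for infeasible targets.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    r = cpg_oe * (gc / 2.0) ** 2  # target per-base CG dinucleotide rate
    if r >= 0.5:
        raise ValueError(f"infeasible targets: CpG rate {r:.3f} >= 0.5")
    w = r / (1.0 - r)
    frac_singles = (1.0 - w) / (1.0 + w)
    p_c = (gc / 2.0 - r) / frac_singles
    p_at = (1.0 - gc) / 2.0 / frac_singles
    if p_c < 0 or p_at < 0 or p_c * 2 + p_at * 2 > 1.0 + 1e-9:
        raise ValueError(
            f"infeasible targets: gc={gc}, cpg_oe={cpg_oe} leave no valid "
            "single-base composition"
        )
    probs = np.array([p_at, p_c, p_c, p_at])  # A, C, G, T among singles
    probs = probs / probs.sum()
    for _ in range(max_attempts):
        chars: list[str] = []
        while len(chars) < length:
            if rng.random() < w:
                chars.append("C")
                chars.append("G")
                continue
            b = _BASES[rng.choice(4, p=probs)]
            # avoid accidental CpG formation outside the block channel
            while b == "G" and chars and chars[-1] == "C":
                b = _BASES[rng.choice(4, p=probs)]
            chars.append(b)
        seq = "".join(chars[:length])
        n_c, n_g = seq.count("C"), seq.count("G")
        gc_meas = (n_c + n_g) / length
        oe_meas = (
            seq.count("CG") * length / (n_c * n_g) if n_c and n_g else 0.0
        )
        if abs(gc_meas - gc) <= gc_tol and abs(oe_meas - cpg_oe) <= oe_tol:
            return seq
    raise ValueError(
        f"could not achieve gc={gc} and cpg_oe={cpg_oe} in {max_attempts} attempts"
    )


@dataclass
class LocusSpec:
    """Blueprint of a synthetic promoter locus with planted ground truth.

    The default methylation landscape mirrors a CGI promoter: heavily
    methylated flanking DNA, essentially unmethylated island.
    """

    length: int = 1000
    background_gc: float = 0.40
    background_oe: float = 0.2
    island_start: int = 350
    island_end: int = 650
    island_gc: float = 0.70
    island_oe: float = 1.0
    flank_methylation: float = 0.9
    island_methylation: float = 0.05
    # (position, (run_lengths, loop_lengths), strand) triplets
    g4_insertions: list = field(default_factory=list)
    # (position, PositionMatrix, strand, n_mismatches) triplets
    motif_insertions: list = field(default_factory=list)


def g4_sequence_from_signature(
    run_lengths, loop_lengths, rng: np.random.Generator
) -> str:
    """Build a G4 consensus instance with G-free loops of the given lengths."""
    if len(run_lengths) != 4 or len(loop_lengths) != 3:
        raise ValueError("need 4 run lengths and 3 loop lengths")
    loop_alphabet = np.array(list("ACT"))  # G-free so the decomposition is unique
    parts = []
    for i, run in enumerate(run_lengths):
        parts.append("G" * run)
        if i < 3:
            parts.append("".join(rng.choice(loop_alphabet, size=loop_lengths[i])))
    return "".join(parts)


def _mutate_site(site: str, n_mismatches: int, matrix: PositionMatrix,
                 rng: np.random.Generator) -> str:
    if n_mismatches == 0:
        return site
    pos = rng.choice(len(site), size=n_mismatches, replace=False)
    out = list(site)
    for j in pos:
        col = matrix.counts[:, j]
        worst = "ACGT"[int(np.argmin(col))]
        if worst == out[j]:
            worst = next(b for b in "TACG" if b != out[j])
        out[j] = worst
    return "".join(out)


def make_locus(spec: LocusSpec, seed: int):
    """Generate a synthetic locus plus its truth annotations.

    Returns ``(record, truth)`` where truth is a dict with the planted island
    interval, G4/motif insertion records, CpG site list, and the per-CpG
    methylation probability map (flank level outside the island, island level
    inside).  Identical (spec, seed) pairs give byte-identical sequences.
    """
    if not 0 <= spec.island_start < spec.island_end <= spec.length:
        raise ValueError("island outside locus bounds")
    rng = substream(seed, "locus")
    background = random_sequence(
        rng, spec.length, spec.background_gc, spec.background_oe
    )
    island = random_sequence(
        rng,
        spec.island_end - spec.island_start,
        spec.island_gc,
        spec.island_oe,
    )
    seq = list(background)
    seq[spec.island_start : spec.island_end] = list(island)

    occupied: list[tuple[int, int]] = []
    g4_truth = []
    for pos, signature, strand in spec.g4_insertions:
        run_lengths, loop_lengths = signature
        ins = g4_sequence_from_signature(run_lengths, loop_lengths, rng)
        if strand == "-":
            ins = revcomp(ins)
        _place(seq, pos, ins, occupied, spec.length)
        g4_truth.append({"start": pos, "end": pos + len(ins), "strand": strand,
                         "run_lengths": tuple(run_lengths),
                         "loop_lengths": tuple(loop_lengths)})
    motif_truth = []
    for pos, matrix, strand, n_mismatches in spec.motif_insertions:
        site = _mutate_site(consensus(matrix), n_mismatches, matrix, rng)
        ins = site if strand == "+" else revcomp(site)
        _place(seq, pos, ins, occupied, spec.length)
        motif_truth.append({"start": pos, "end": pos + len(ins), "strand": strand,
                            "site": site, "tf": matrix.tf_name,
                            "n_mismatches": n_mismatches})

    residues = "".join(seq)
    record = SequenceRecord(f"synthetic_locus_seed{seed}", residues)
    cpg_sites = find_cpg_sites(residues)
    meth_probs = {
        p: (
            spec.island_methylation
            if spec.island_start <= p < spec.island_end
            else spec.flank_methylation
        )
        for p in cpg_sites
    }
    truth = {
        "island": (spec.island_start, spec.island_end),
        "g4": g4_truth,
        "motifs": motif_truth,
        "cpg_sites": cpg_sites,
        "methylation_probs": meth_probs,
    }
    return record, truth


def _place(seq: list, pos: int, ins: str, occupied: list, length: int) -> None:
    end = pos + len(ins)
    if pos < 0 or end > length:
        raise ValueError(f"insertion at {pos} outside locus")
    for s, e in occupied:
        if pos < e and s < end:
            raise ValueError(f"insertion at {pos} overlaps a previous insertion")
    occupied.append((pos, end))
    seq[pos:end] = list(ins)


@dataclass
class CloneSimSpec:
    """Noise model for simulated bisulfite clones."""

    n_clones: int = 20
    conversion_failure_rate: float = 0.0  # non-CpG C left unconverted
    sequencing_error_rate: float = 0.0  # per-base substitution
    indel_rate: float = 0.0  # per-base deletion
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("conversion_failure_rate", "sequencing_error_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")


def make_clones(
    reference: BisulfiteReference,
    methylation_profile: dict[int, float],
    sim: CloneSimSpec,
):
    """Simulate sequenced bisulfite clones of the OT strand.

    Per clone, methylation states are drawn site-wise Bernoulli from
    ``methylation_profile``, bisulfite conversion applied, then conversion
    failures (non-CpG C restored), substitution errors, and deletions are
    injected at the specified rates.  Returns ``(clones, truth_calls)`` where
    truth_calls is the planted clones x sites call matrix.
    """
    missing = set(reference.cpg_sites) - set(methylation_profile)
    if missing:
        raise ValueError(f"methylation_profile missing sites {sorted(missing)[:5]}...")
    rng = substream(sim.seed, "clones")
    sites = reference.cpg_sites
    probs = np.array([methylation_profile[p] for p in sites])
    non_cpg_c = [
        i
        for i, b in enumerate(reference.region.residues)
        if b == "C" and i not in set(sites)
    ]
    clones: list[SequenceRecord] = []
    truth: list[list[str]] = []
    for k in range(sim.n_clones):
        states = rng.random(len(sites)) < probs
        methylated = {p for p, s in zip(sites, states) if s}
        conv = bisulfite_convert(reference, methylated, "+").residues
        bases = list(conv)
        for i in non_cpg_c:
            if rng.random() < sim.conversion_failure_rate:
                bases[i] = "C"  # conversion failure: C survives
        for i in range(len(bases)):
            if rng.random() < sim.sequencing_error_rate:
                bases[i] = str(rng.choice([b for b in "ACGT" if b != bases[i]]))
        if sim.indel_rate > 0:
            kept = rng.random(len(bases)) >= sim.indel_rate
            bases = [b for b, keep in zip(bases, kept) if keep]
        clones.append(SequenceRecord(f"clone_{k}", "".join(bases)))
        truth.append(["methylated" if s else "unmethylated" for s in states])
    return clones, truth


def make_peaks_with_motifs(
    matrix: PositionMatrix,
    n_peaks: int,
    fidelity: float = 1.0,
    seed: int = 0,
    peak_width: int = 60,
    reference: SequenceRecord | None = None,
    site_probability: float = 1.0,
):
    """Plant motif instances inside peak intervals of an AT-rich reference.

    ``fidelity`` 1.0 plants the exact consensus; lower values plant
    ``round((1 - fidelity) * W)`` mismatches (each mutated column set to its
    lowest-count base).  Each peak carries one planted site with probability
    ``site_probability``, at a random offset and strand.  Returns
    ``(reference, peaks, truth)`` with truth a list of dicts (or None for
    empty peaks).
    """
    W = matrix.width
    if W >= peak_width:
        raise ValueError("matrix width must be smaller than peak width")
    rng = substream(seed, "peaks")
    gap = 20
    total = n_peaks * (peak_width + gap) + gap
    if reference is None:
        reference = SequenceRecord(
            f"synthetic_peaks_seed{seed}",
            random_sequence(rng, total, gc=0.30, cpg_oe=0.25, oe_tol=0.2),
        )
    if len(reference) < total:
        raise ValueError("reference too short for requested peaks")
    n_mismatches = int(round((1.0 - fidelity) * W))
    cons = consensus(matrix)
    seq = list(reference.residues)
    peaks: list[Peak] = []
    truth: list[dict | None] = []
    for i in range(n_peaks):
        start = gap + i * (peak_width + gap)
        end = start + peak_width
        peaks.append(Peak(reference.id, start, end, name=f"peak_{i}",
                          score=100.0, strand="."))
        if rng.random() >= site_probability:
            truth.append(None)
            continue
        offset = int(rng.integers(0, peak_width - W + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = _mutate_site(cons, n_mismatches, matrix, rng)
        planted = site if strand == "+" else revcomp(site)
        seq[start + offset : start + offset + W] = list(planted)
        truth.append({"peak": f"peak_{i}", "offset": offset, "strand": strand,
                      "site": site, "n_mismatches": n_mismatches})
    reference = SequenceRecord(reference.id, "".join(seq))
    return reference, peaks, truth


def melt_closed_form(
    t: np.ndarray,
    midpoint_c: float,
    width_c: float,
    amplitude: float = 1.0,
    baseline_slopes: tuple[float, float] = (0.0, 0.0),
    baseline_offset: float = 0.0,
) -> np.ndarray:
    """Noise-free two-state melt signal with linear folded/unfolded baselines."""
    t = np.asarray(t, dtype=float)
    folded = 1.0 / (1.0 + np.exp((t - midpoint_c) / width_c))
    lo_slope, hi_slope = baseline_slopes
    folded_base = baseline_offset + lo_slope * (t - t.min())
    unfolded_base = baseline_offset + amplitude + hi_slope * (t - t.min())
    return folded * folded_base + (1.0 - folded) * unfolded_base


def make_melt_curve(
    midpoint_c: float,
    width_c: float = 3.0,
    amplitude: float = 1.0,
    baseline_slopes: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    t_min: float = 15.0,
    t_max: float = 95.0,
    t_step: float = 2.0,
    wavelength_nm: float = 262.0,
) -> tuple[MeltCurve, float]:
    """Two-state sigmoidal denaturation curve sampled over 15-95 degrees C.

    Returns (curve, true_midpoint).  Gaussian noise of ``noise_sd`` (same
    units as the signal) is added pointwise.
    """
    if not t_min <= midpoint_c <= t_max:
        raise ValueError("midpoint must lie within the temperature ramp")
    rng = substream(seed, "melt")
    t = np.arange(t_min, t_max + t_step / 2, t_step)
    signal = melt_closed_form(t, midpoint_c, width_c, amplitude, baseline_slopes)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=len(t))
    return MeltCurve(t, signal, wavelength_nm), midpoint_c


def _gaussian(w, center, sigma, amp):
    return amp * np.exp(-0.5 * ((w - center) / sigma) ** 2)


def make_cd_spectrum(
    topology: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
) -> Spectrum:
    """Synthetic CD spectrum built to the canonical G4 band rules.

    parallel: +262 / -241; antiparallel: +295, +240 / -262; hybrid: +290 with
    a 262 nm shoulder / -240.  ``scale`` multiplies the whole spectrum (the
    classifier must be invariant to it).
    """
    w = np.arange(220.0, 321.0, 1.0)
    if topology == "parallel":
        v = _gaussian(w, 262, 7, 1.0) + _gaussian(w, 241, 5, -0.55)
    elif topology == "antiparallel":
        v = (
            _gaussian(w, 295, 7, 1.0)
            + _gaussian(w, 240, 5, 0.6)
            + _gaussian(w, 262, 6, -0.8)
        )
    elif topology == "hybrid":
        v = (
            _gaussian(w, 290, 5, 1.0)
            + _gaussian(w, 262, 10, 0.55)
            + _gaussian(w, 240, 5, -0.7)
        )
    elif topology == "flat":
        v = np.zeros_like(w)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    if noise_sd > 0:
        rng = substream(seed, "cd")
        v = v + rng.normal(0.0, noise_sd, size=len(w))
    return Spectrum(w, v * scale)


def make_qpcr_table(
    fold_changes: dict[str, float],
    efficiencies: dict[str, float],
    ct_base: float = 22.0,
    noise_sd: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
    reference_gene: str = "RPLP0",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Ct table for 'control' and 'treated' samples with planted fold changes.

    For each target, Ct in the treated sample is shifted by
    -log_E(fold_change) relative to control, so the efficiency-corrected
    ddCt inversion recovers the planted fold exactly at zero noise.  The
    reference gene is flat across conditions.  Gaussian Ct noise ``noise_sd``
    is added per technical replicate.
    """
    if reference_gene not in efficiencies:
        raise ValueError(f"efficiencies must include the reference gene {reference_gene!r}")
    rng = substream(seed, "qpcr")
    rows = []
    genes = {reference_gene: 1.0, **fold_changes}
    for gene, fold in genes.items():
        eff = efficiencies[gene]
        if fold <= 0:
            raise ValueError(f"fold change for {gene!r} must be > 0")
        shift = np.log(fold) / np.log(eff)
        for sample, ct_mean in (("control", ct_base), ("treated", ct_base - shift)):
            for rep in range(n_reps):
                ct = ct_mean + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    {"sample": sample, "target": gene, "replicate": rep,
                     "ct": ct, "efficiency": eff}
                )
    table = pd.DataFrame(rows, columns=["sample", "target", "replicate", "ct", "efficiency"])
    return table, dict(fold_changes)
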