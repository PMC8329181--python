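# Methods

This note documents the models, parameter choices, and numerical decisions
behind each stage of the pipeline, what the synthetic-data generators do and
do not emulate, and the known limitations.

## Coordinate frames

Internally every interval is 0-based half-open. Promoter positions use the
signed frame common in promoter studies: …, −2, −1, +1, +2, … with +1 the
first base of the annotated first exon and no position 0. The mapping to
internal offsets is bijective (`promoter_to_offset` / `offset_to_promoter`),
and inclusive interval lengths skip the nonexistent zero — hence
−117..+103 spans 220 positions, not 221. Report output from the analysis
drivers is 1-based inclusive.

## CpG-island profiling

Per-window statistics over windows of `window` bp placed every `step` bp
(the last partial window is dropped, never padded, to avoid edge-biased
ratios):

* GC content: (G+C)/(A+C+G+T). N is excluded from numerator and
  denominator; windows with > 10 % N are flagged, all-N windows are NaN.
* GC skew: (G−C)/(G+C), NaN when the window has no G or C. The windowed
  form is the default (matching per-region display); a cumulative running
  sum is available separately.
* CpG O/E: N<sub>CpG</sub>·L/(N<sub>C</sub>·N<sub>G</sub>) with L the
  non-N window length — the Gardiner-Garden–Frommer statistic. A CpG counts
  only when both bases lie inside the window.

Island calling uses the conventional Cpgplot-style defaults — window 100,
step 1, GC ≥ 0.5, O/E ≥ 0.6, minimum length 200 bp — all exposed. Each
qualifying window contributes its span [start, start+window); islands are
the **connected components of the union of those spans**. This definition
was chosen over "runs of consecutive qualifying windows" because runs
separated by a gap narrower than the window produce overlapping spans
(self-overlapping islands), and because a shrinking qualifying set then
always shrinks the reported total — raising either threshold can never grow
the output. Island statistics are means over the member windows' values, so
the stored invariants (mean GC and mean O/E above threshold) hold exactly.
Islands longer than the conventional 2000 bp upper bound are reported but
flagged. A caveat: component *counts* can still increase when a long
component splits under a stricter threshold; total length cannot.

## G-quadruplex scanning

The consensus is four G-runs of ≥ `min_run` (default 3) guanines separated
by three loops of `loop_min`..`loop_max` (default 1–7) arbitrary
nucleotides. Anchors are the left ends of maximal G-runs. At each anchor the
*canonical* hit is the lazy match — minimal run lengths and loops explored
smallest-first with deepest-first backtracking, i.e. exactly the semantics
of a lazy regular expression — because greedy-maximal matching can swallow
the anchor of a distinct downstream match. `report_all` enumerates every
valid run/loop decomposition instead. Minus-strand hits are found on the
reverse complement and reported in plus-strand coordinates. Hits sharing
sequence on the same strand are merged into loci (a biologist counts loci,
not regex matches); the locus's best hit maximizes total G-run content,
ties to the leftmost. The windowed G-richness score (each base in a k-long
G-run contributes +min(k,4), C-runs the negative) is an optional
convenience, not part of the consensus definition.

## Peak-restricted motif scanning

The matrix is a JASPAR-style 4×W count matrix; parsing is label-driven, so
row order in the file is irrelevant. Column probabilities add a pseudocount
(default 1.0) distributed by the background composition, giving finite
scores everywhere; the default background is uniform. The score of a site is
the log2 likelihood ratio Σ log₂(p/q) ("PWM log-odds"). The plain argmax
consensus (ties broken A<C<G<T and flaggable) supports a secondary, more
literal criterion: Hamming distance of the site to the consensus
(`max_mismatch`). Scanning scores every width-W window of every peak on both
strands; windows containing N are skipped as unscorable. Hits are retained
at `score_min_fraction` of the maximum attainable score and sorted by
descending score, ties by leftmost start then + before −. Peaks are taken
verbatim — no summit centering or slop. IUPAC-degenerate consensus matching
is deliberately not used for the mismatch count.

## Bisulfite methylation calling

Conversion model: on the chosen strand every cytosine deaminates to uracil
(represented as T throughout, since sequenced clones are post-PCR) unless it
is the C of a methylated CpG. CpG methylation is treated as symmetric, so
the bottom-strand C of a methylated CpG is protected too. Both bisulfite
strands (OT/OB) are modeled; a clone is assigned the strand with the better
global alignment score, ties to OT.

Alignment scores: match +1, reference-C vs clone-T +1 (the converted state),
other mismatch −1, linear gap −2, global mode; identity (matches plus
converted positions over aligned columns) below 0.8 flags the clone
unalignable. These are QUMA-like defaults and all are exposed. The engine is
Biopython's `PairwiseAligner` with an asymmetric substitution matrix. Note
an intrinsic ambiguity of converted-C-tolerant alignment: a deleted
methylated CpG can score identically to "converted C + gap elsewhere" in
T-rich contexts; calls at such sites depend on the aligner's tie-breaking.

Per-site calls at the CpG's C position: clone C → methylated, clone T →
unmethylated, gap or other base → ambiguous (a value, never an error).
Conversion QC is the fraction of aligned non-CpG cytosines read as T
(default pass ≥ 0.95); clones with no informative position pass with a
warning. Failing clones are excluded from fractions but still rendered
(marked `!`) in the lollipop text (● methylated, ○ unmethylated, ·
ambiguous/undefined). Primer admissibility: ≤ 1 CpG in the primer region →
usable as a bisulfite primer; ≥ 3 CpG → usable as a methyl-specific primer;
exactly 2 satisfies neither rule and is classed inadmissible rather than
guessed.

## qPCR quantification

Relative expression is the efficiency-corrected 2^−ΔCt ratio
E<sub>t</sub>^−Ct_t / E<sub>r</sub>^−Ct_r (the Pfaffl form), computed in log
space to avoid overflow. Efficiency is the per-cycle amplification factor in
[1, 2] (2 = perfect doubling); a percent dialect ("95%" → 1.95) is accepted,
and efficiency is a required input — never silently defaulted. Fold changes
between conditions use 2^−ΔΔCt, or the efficiency-corrected ratio-of-ratios
when enabled (default); with all efficiencies 2 the two coincide exactly,
and both are invariant to plate-wide Ct shifts. Technical replicates are
averaged on the Ct (log) scale before ratios, switchably. Calibration
divides all ratios by the calibrator's so it maps to exactly 1. A thin
two-tailed unpaired t-test utility on replicate fold changes is included as
routine support, not a contribution.

## Curve biophysics

T<sub>m</sub> estimation (derivative method, the primary): resample the
curve to a uniform temperature grid by linear interpolation, smooth with a
5-point moving average (applied before differentiation only),
differentiate by central differences, take the temperature of extremal
|dS/dT|, and refine by quadratic interpolation of the three points around
the derivative peak. A transition is reported only when the derivative peak
exceeds 3× the baseline derivative level (median |dS/dT|); a linear ramp
(ratio 1) or a flat curve therefore reports no transition. The estimate is
invariant to affine transforms of the signal. An optional two-state sigmoid
fit cross-checks the derivative estimate; disagreement > 2 °C is flagged in
the driver output.

ThT enhancement is F−F₀ at 488 nm (negative values permitted, flagged as
quenching). Beer–Lambert: c = A/(ε·l) with ε defaulting to ThT's
36,000 M⁻¹cm⁻¹ at 412 nm.

CD topology rules, applied in the order antiparallel → hybrid → parallel on
local extrema of the spectrum (±6 nm tolerance around the nominal band,
band amplitude ≥ 5 % of the spectrum's scale, hence scale-invariant):
antiparallel = positive bands near 295 and 240 nm with a negative band near
260 nm; hybrid = positive band at 290 nm with a 260 nm shoulder and a
negative band near 240 nm; parallel = positive near 260 nm, negative near
240 nm; otherwise indeterminate. "Shoulder" is operationalized (since no
standard definition exists) as a stretch in 255–268 nm where |dS/dλ| falls
below 20 % of the main peak's flank slope while the global maximum sits in
285–295 nm.

## Synthetic data

One integer master seed drives everything through stage-name-salted
substreams (`crc32(stage)` + seed → `SeedSequence`), so generators are pure
functions of (spec, seed) and adding a stage never perturbs another's
output.

* **Locus**: background and island are sampled from a CG-block process —
  whole CG dinucleotides are emitted at rate w/(1+w) = O/E·(GC/2)²,
  interleaved with single bases whose composition restores the GC target;
  accidental single-base C→G adjacencies are redrawn. Naive IID sampling
  cannot reach elevated O/E, which is why the block process exists.
  Rejection sampling enforces GC within ±2 % and O/E within ±0.1, erroring
  after bounded attempts for infeasible targets (e.g. O/E·GC > 2). Defaults:
  1,000 bp locus, GC 0.40 / O/E 0.2 background, 300 bp island at GC 0.70 /
  O/E 1.0 — a compact version of the GC-rich (> 70 %) island-in-flank
  structure the analyses target. The planted methylation landscape is 0.90
  (flanks) / 0.05 (island), the precipitous step the methylation analysis
  should recover. G4 insertions are built from run/loop signatures with
  G-free loops (making the decomposition unique); motif insertions plant the
  consensus or a k-mismatch degradation. Insertions must not overlap.
* **Clones**: per clone, site-wise Bernoulli methylation, OT-strand
  conversion, then conversion failures (non-CpG C restored), substitution
  errors, and deletions at the specified rates. Defaults are noise-free;
  drivers use 1 % conversion failure and 0.1 % substitution, typical of a
  clean bisulfite experiment.
* **Peaks**: ten 60 bp peaks on an AT-rich (GC 0.30) background so planted
  sites dominate the score distribution.
* **Melt curves**: two-state logistic with linear folded/unfolded baselines
  over 15–95 °C at 2 °C steps; the closed form is exported for oracle
  tests. 2 % amplitude noise mirrors a well-behaved instrument. The 65/45 °C
  midpoint pair encodes the with/without-K⁺ stabilization contrast.
* **CD spectra**: sums of Gaussian bands constructed to the topology rules,
  on a 220–320 nm grid.
* **qPCR**: Ct tables where the treated-sample Ct is shifted by
  −log<sub>E</sub>(fold), so the ΔΔCt inversion is exact at zero noise;
  σ(Ct) = 0.1 over 3 replicates for the noisy recovery settings.

What the generators do *not* emulate: PCR amplification bias and chimeras in
bisulfite cloning, sequence-composition-dependent conversion efficiency,
ChIP-seq coverage structure inside peaks, instrument baseline drift beyond a
linear term, or inter-assay qPCR efficiency miscalibration. Passing tests
therefore demonstrate correctness of the computations under these idealized
noise models, not robustness to every artifact of real data.

## Problem sizes

The test suite and drivers run on desk-scale inputs chosen to exercise every
code path: a 1 kb locus, ≤ 10 peaks of 60 bp, 20–200 clones over ~40 CpG
sites, 100 replicate curves/tables per recovery experiment, and 10,000
sampled short sequences for the G4 oracle-equivalence check.

## Known limitations

* The island caller's component count is not monotone in the thresholds
  (total length is); counts on pathological sequences can split.
* Bisulfite alignment ambiguity (above) can convert a deletion over a
  methylated CpG into an unmethylated call; real pipelines share this
  behavior.
* The motif scanner's background model is 0-order; composition-matched
  backgrounds must be supplied explicitly.
* The G4 scanner predicts sequence consensus only — no thermodynamic
  stability, no i-motif calls on the C-rich strand.
* Tm estimation assumes a single two-state transition; multiphasic curves
  report the dominant derivative peak only.
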