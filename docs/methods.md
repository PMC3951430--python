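# Methods

This note records the models, parameter choices and numerical conventions
behind each stage, what the synthetic-data generators do and do not
emulate, and the design decisions taken where the underlying procedure was
ambiguous.

## Expression screen

**Model.** Probe-level log₂ intensities are treated as
`global mean + probe affinity + per-(gene, animal) effect + condition
effects + residual noise`. Chips are quantile-normalized on the log₂ scale
(every sample's sorted vector is forced to the across-sample mean of
sorted vectors; ties map to the mean reference value, ranks are preserved
within a sample). Probe sets are summarized by Tukey median polish
(alternating row/column median sweeps; at most 10 sweeps or until residual
row and column medians fall below 1e-8; ties in medians use the midpoint
convention). A trimmed-mean scaler (target 300, 2 % per tail) is available
for chip-to-chip intensity alignment on the linear scale.

**Change calls.** For each ordered chip pair the per-probe log₂
differences enter a two-sided paired test — Student t by default, an exact
Wilcoxon signed-rank variant (null enumerated by dynamic programming over
all 2ⁿ sign assignments, zeros dropped, midranks on ties) behind a flag.
The call is Increase/Decrease when the two-sided p falls below the
decision threshold γ (default 0.0025) with the matching sign of the median
difference, No Change otherwise; a zero-variance, zero-difference pair is
NC with p = 1. γ is configurable because the threshold actually used by
the original closed-source caller is not documented; the default is the
vendor-documented magnitude. No attempt is made at bit-compatibility with
closed software — the open re-implementation is the point. RMA-style
background correction is omitted: the synthetic chips have no optical
background and no parameters exist to pin it down.

**Signal-log ratio.** Default "summary-diff": difference of median-polish
summary signals of the two-column probe matrix. Alternative "probe-ratio":
one-step Tukey biweight location (c = 5, ε = 1e-4, median/MAD scaling) of
per-probe log₂ ratios. Both are antisymmetric under swapping baseline and
experiment and exact on zero-noise data.

**Consensus rule.** For k animals per group the stimulation contrast uses
k intra-animal pairs plus k(k−1) cross pairs (2 animals → the study's four
comparisons); the lesion contrast uses all PD-nonstim × control-nonstim
pairs. A probe set enters a regulation list when it collects ≥
`required_count` homonymous calls (default 4, strict) **and** |slr| ≥ 0.6
in every counted comparison — the gate is per comparison, not on the mean.
The mean slr is averaged over counted comparisons. Counter-regulation:
a gene on the stimulation list whose lesion contrast shows ≥
`lesion_min_count` (default 3, admitting genes called homonymously in three or
four of the four lesion comparisons) homonymous calls with the opposite slr sign. Genes measured
by several probe sets stay per-probe-set; there is no gene-level collapse.

**EASE.** The enrichment score is −log₁₀ of the hypergeometric upper tail
evaluated at max(k−1, 0) list hits (the jackknife discounts terms
supported by a single gene); p is clamped to [1e-300, 1]. Annotation sets
are user-supplied; no database queries are performed.

## Locomotion

Speed is the net displacement across a centred 0.3 s window divided by the
window span; edge windows shrink symmetrically, with one-sided single-step
differences at the first/last sample. On a circular path this chord-based
speed underestimates rω by at most (ωw)²/24 relative. Rest/motion
segmentation thresholds the speed at 4 cm/s; runs shorter than 0.5 s are
iteratively merged into their longer neighbour, preserving a strict
alternation and a full partition of the recording.

"max-SD" is implemented as the **maximum smoothed speed per motion
episode** (cm/s) by default. The name suggests a derivative, but the
reported units and magnitudes (≈ 17–20 cm/s) are speed-like, so the
speed reading is the default and a max-|dspeed/dt| variant sits behind a
flag. The two-mode split smooths the natural-log max-SD values with a
Gaussian KDE (Silverman's rule bandwidth), takes the two highest local
maxima as modes and the deepest minimum between them as threshold;
episodes above it are "full motion". A unimodal density returns an
explicit single-mode flag (all episodes treated as full motion) rather
than a silent guess.

"Spatial spread" is implemented as **cumulative path length over
full-motion episodes** — magnitudes of tens of metres over long recordings
are path-like, and the choice is logged per run; a convex-hull-extent
reading would be a valid alternative and neither is asserted as the
original study's definition.

## Field-potential spectra

Bipolar derivation is a sample-wise channel difference. The 50 Hz notch is
a second-order IIR notch (Q = 30) applied forward-backward for zero phase.
Welch PSDs use 2 s Hann segments with 50 % overlap (0.5 Hz resolution —
fine enough to resolve the 1 Hz band edges; the source procedure does not
state its segment length). Normalization divides by the summed power in
1–80 Hz. Band powers sum the normalized bins inside each band's inclusive
integer edges mapped to the nearest grid bins; the 50 Hz bin is excluded
from all band sums (the gamma bands deliberately skip 50 Hz). The
frequency-weighted display multiplies each time-frequency cell by its
frequency and column-normalizes, turning an exact 1/f spectrum flat;
all-zero columns are flagged, not divided.

Group statistics use the exact Wilcoxon rank-sum test (enumeration of all
rank assignments for tie-free combined n ≤ 12, tie-corrected normal
approximation otherwise; two-sided p doubles the smaller tail, capped
at 1) at the Bonferroni threshold 0.05/7 ≈ 0.00714 per band.

Note one consequence of relative (normalized) power: adding band-limited
power to one group necessarily *depresses* every other band's relative
power, so a strong planted high-beta oscillation can yield significant
decreases elsewhere. The tests assert the direction structure (high beta
up, any other significant band down) rather than pretending the bands are
independent.

## Stereology

Dissector volume = frame width × frame height × dissector height
(50×50×20 μm → 50 000 μm³); grid area = step_x × step_y (150×150 μm →
22 500 μm²). Density = ΣQ / (Σsites × dissector volume), converted to
cells/mm³. Cavalieri volume = section period × thickness × Σareas. The
section sampling period is an input column, not a constant, because
different specimens can be sampled at different rates. CE estimation
reports a decomposition: counting noise 1/√ΣQ, plus a Gundersen–Jensen
systematic-sampling component Var_SRS = (3(A − ΣQ) − 4B + C)/240 for
smoothness class m = 1 (divisor 12 for m = 0), with A = Σq²ᵢ,
B = Σqᵢqᵢ₊₁, C = Σqᵢqᵢ₊₂, clamped at zero. The headline "section-series"
value combines both in quadrature; the components are exposed separately
because for a smooth section profile the systematic-sampling part is far
below the noise part, which is the scientifically meaningful comparison.
Percent change is 100 × (a − b)/b — antisymmetric in sign only, not in
magnitude.

## Validation assays

ΔCT = mean CT(target) − mean CT(reference) per condition (triplicates
aggregated by mean; median behind a flag, since outlier handling for
triplicates is not specified anywhere); ΔΔCT = ΔCT(experiment) −
ΔCT(baseline); slr = −ΔΔCT. The baseline condition must be named
explicitly in every call — it is not inferred. The statistic is invariant
to plate-wide CT offsets. Group comparisons are pooled ("fixed-effect")
rank-sum tests with a Bonferroni threshold over the number of genes
tested; hemisphere pairs are not modelled as random effects. Densitometric
slr = log₂ of the loading-control-normalized band ratio between
conditions, invariant to lane-wide exposure scaling. No amplification-
efficiency correction is applied.

## Synthetic data: what it emulates, and what it does not

All randomness flows from one top-level seed through
`numpy.random.SeedSequence(seed, spawn_key=(k,))` with a fixed key per
stage, so any stage can be regenerated independently and every generator
is bit-deterministic given its seed.

- **Expression** (default 5 000 probe sets × 11 probes — the emulated chip
  family has 31 043 probe sets and ~11 probe pairs; the scaled-down
  default keeps the screen's statistics identical per probe set while the
  full size is a constructor argument). Planted classes: stimulation-down
  (negative slr on the stimulated hemisphere of lesioned animals),
  lesion-up (positive slr on both hemispheres of lesioned animals, the
  lesion being bilateral), counter-regulated (both). Planted |slr| ∈
  [1.0, 2.8], the magnitude range of strongly regulated genes. Noise defaults
  (probe affinity SD 1.0, per-animal effect SD 0.1, residual SD 0.2 on the
  log₂ scale) were chosen once so that the consensus screen has high power
  at |slr| ≥ 1 — the probe-level noise of the original chips is unknowable
  from the text. Not modelled: optical background, circadian drift,
  spatial chip artefacts, PM/MM probe pairs. Passing truth-recovery tests
  therefore demonstrates the *screen logic*, not robustness to real chip
  artefacts.
- **Locomotion**: alternating rest/motion schedule; bouts run at constant
  speed in straight lines (heading redrawn at walls), rest is stationary
  or sub-threshold jitter, positions confined to the 70×100 cm arena.
  Constant-speed bouts make peak-speed and path-length recovery exact at
  zero noise; real rodent bouts accelerate smoothly, so real max-SD values
  would be biased low by the windowing — a property the derivative variant
  shares with the original method.
- **Signals**: spectrally shaped Gaussian noise (PSD ∝ f^−α), a sinusoid
  at 32 Hz (high beta), and a 50 Hz line component. No non-stationarity,
  no artefacts, no volume conduction.
- **Stereology**: per-site counts are Poisson with mean density ×
  dissector volume — the idealized assumption under which 1/√ΣQ is the
  exact noise CE. No overdispersion from clustering of cells.
- **qPCR**: CT = baseline − slr (experiment condition) + Gaussian noise;
  the reference gene is constant up to noise. Perfect amplification
  efficiency is assumed, matching the ΔΔCT model itself.

## Problem sizes and determinism

Default problem sizes (5 000 probe sets, 30 s signal epochs, 20 bouts,
6 sections × 400 sites, triplicate plates) were chosen as the smallest
sizes at which each stage's statistics are clearly in their asymptotic
regime; all are constructor arguments. The acceptance script
(`scripts/acceptance.py`) derives every stage seed from its `--seed`
argument and recomputes all reported quantities at run time.

## Known limitations

- The change-call γ and the exact slr summarization of the original
  closed-source caller are unknown; list membership near the gates can
  differ from the original software even on identical data.
- Stereology software packages report a "second estimate" CE whose exact
  formula varies; the implemented Gundersen–Jensen family is the standard
  published form and is property-tested, not bit-matched against any
  particular software.
- The two-mode locomotion split assumes an antimode exists; heavily
  overlapping modes return the explicit single-mode flag.
- The relaxed "2/4 change count" exploratory list generation is available
  only through the `required_count` parameter; its original slr handling
  is undocumented.
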