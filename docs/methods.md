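# Methods

## The model

Surface EMG recorded from M muscles during running is summarized, per
gait cycle, by its linear envelope. The modular-control hypothesis holds
that these envelopes are generated by a small number N < M of motor
modules: fixed, nonnegative muscle-weighting vectors recruited as a unit
by a shared activation signal. Writing the concatenated envelopes as a
matrix X (muscles x time), the model is

    X(k) ≈ X_r(k) = S · P(k)

with S (M x N) the nonnegative muscle-weighting matrix and P (N x T) the
nonnegative activation signals. Reconstruction quality is the variance
accounted for,

    VAF = 1 − SSE / SST,

where SSE = Σ(X − X_r)² and SST = ΣX² is the *uncentered* pooled sum of
squares over the whole matrix (so a zero reconstruction scores exactly
0). Both factors are estimated by Euclidean-cost multiplicative updates
(Lee–Seung form) from uniform-random nonnegative initializations, with
seeded restarts (default 25) keeping the best-VAF solution. Convergence
is declared when the relative VAF change between checks (every 10
iterations) falls below `tol` (default 1e-6, maximum 2000 iterations). A
1e-12 epsilon in the update denominators protects zero rows. The scale
ambiguity is resolved by max-normalizing each weighting column to 1
(moving the scale into P); the permutation ambiguity by sorting modules
on the peak time of their cycle-averaged activation, so module labels
are stable across runs and conditions.

## Dimensionality

The VAF is computed for k = 1..k_max. The selected dimensionality is the
smallest k that (a) reaches the 90% floor (`vaf_min = 0.90`) and (b) is
followed by a flat segment of the curve — the gain from adding one more
module falls below `gain_eps = 0.03`. The flatness threshold
operationalizes the "change of slope" idea; it is exposed as a parameter
because no single value is canonical. If no k satisfies both conditions,
k_max is returned with a criterion-unmet flag rather than silently
accepting a poor fit.

## Gait segmentation from tibial acceleration

The uniaxial tibial trace (in g) is low-pass filtered at 60 Hz with a
second-order zero-lag (forward–backward) Butterworth filter. Candidate
impact minima are samples below an adaptive threshold (mean − 2·SD,
configurable) separated by at least 0.5 s. The trace is then
differentiated by first differences, and each foot strike is refined to
the largest positive derivative peak in the 50 ms window immediately
preceding its minimum — the pre-impact rise of the rearfoot transient.
The window length is a free parameter (the underlying idea of "the
positive derivative peak immediately prior to the minimum" does not fix
one). Detected strike spacing is validated against physiologic bounds
(0.3–2 s).

Per-cycle metrics: peak negative acceleration is the magnitude of the
most negative filtered sample within ±25 ms of the strike.
Stride-to-stride variability is the coefficient of variation computed on
the absolute filtered acceleration (avoiding near-zero-mean blowups in
the signed signal): at each normalized time sample in a %-cycle window,
the across-cycle sample SD (n−1) over the across-cycle mean, averaged
over the window and expressed in percent. A window [a%, b%] maps to
0-based samples floor(a/100·200) .. ceil(b/100·200) − 1 — the stance
window 0–35% covers samples 0–69, the pre-landing window 91–100% covers
samples 182–199.

## EMG preprocessing

Raw EMG is band-pass filtered 10–500 Hz (second-order zero-lag
Butterworth, i.e. effective fourth order after the forward–backward
pass), full-wave rectified and low-pass filtered at 10 Hz to form the
envelope. Filter ringing can push the rectified-then-filtered signal
slightly negative; values are clamped to zero (warning if the excursion
exceeds 1% of the signal maximum) because the factorization requires
nonnegative input. Envelope-level input (e.g. from the synthetic
generator) bypasses both filters: rectification is the identity on a
nonnegative signal, and re-low-passing an already-smoothed envelope
would distort it.

Each strike-to-strike cycle is time-normalized to 200 samples by linear
interpolation (endpoints inclusive). Twenty consecutive cycles are
selected (start index configurable), concatenated per muscle, and each
muscle's concatenated series divided by its own maximum, mapping it to
[0, 1]. Normalization is per condition by default — each condition's
envelope attains 1 independently — with the divisors stored for
traceability; a pooled-across-conditions option exists for magnitude
comparisons, since the choice is genuinely ambiguous for cross-condition
amplitude analyses.

Single-muscle metrics divide both conditions' across-cycle mean curves
by the reference condition's mean-cycle mean amplitude; peak EMG is the
maximum of the normalized mean curve and integrated EMG its mean over
the normalized cycle (a dimensionless %-cycle integral rather than a
real-time integral — cycles are compared after time normalization).

## Cross-condition analysis

Similarity between weighting vectors or activation signals is the
normalized scalar product (cosine), in [0, 1] for nonnegative vectors;
0.8 is the conventional threshold for "similar". Because factorization
returns modules in arbitrary order, two module sets are matched by the
Hungarian algorithm maximizing total *weighting* similarity — weightings
carry the shared spatial structure, so they define correspondence, and
activation similarity is then reported for the resulting pairs.
Activation summaries average each module's 20 time-normalized cycles;
the peak and its instant (% of cycle, first index on ties) are read from
the mean curve, and per-module condition differences are the sample-wise
absolute subtraction of the two mean curves.

The fixed-factor reconstructions test which factors transfer across
conditions: REC_W fixes the other condition's weightings and re-estimates
activations by the same multiplicative update (weightings held
constant); REC_A fixes the other condition's activations and re-estimates
weightings; REC_WA fixes both and simply evaluates VAF(X, S·P), clipping
a pathological negative VAF to 0 with a flag. Free factors are
warm-started from the target condition's own factorization (after module
matching aligns column order); pure random initialization is available.
Warm starts make the fixed-factor problem a refinement of an already
plausible solution and speed convergence; because the free problem is
convex in the free factor, the choice affects runtime more than the
solution. If the two conditions share weightings but differ in
cycle-to-cycle temporal detail, REC_W stays close to the regular
factorization while REC_A and REC_WA degrade.

## Statistics

Two-tailed paired t-tests compare conditions on per-subject metrics
(identical samples return t = 0, p = 1 by convention; constant nonzero
differences are an error). Cohen's d defaults to the pooled-SD form —
the classic 0.2/0.5/0.8 bands are defined for it — with a paired-SD
variant selectable. The four reconstruction modes are compared by a
plain one-way ANOVA on VAF. Bonferroni correction (min(1, p·m)) handles
the 11-muscle multiplicity. Shapiro–Wilk screens normality as a warning
gate only; the analysis does not switch to nonparametric tests.

## The synthetic generator

Because the analysis needs ground truth, the generator synthesizes
envelope-level EMG directly from the model: a canonical 11 x 4 weighting
matrix (knee extensors + gluteus maximus; plantar flexors; TA/PL/RF;
hamstrings — each column max-normalized, cross-loadings ≤ 0.1) driven by
per-cycle Gaussian activation bursts centered at 8, 18, 55 and 92% of
the cycle with circular wrap, so the late-swing burst spills into early
stance. Per cycle, each burst draws a timing offset (Gaussian,
SD = 0.02 cycle) and a multiplicative lognormal amplitude factor
(σ = 0.15). Half-Gaussian noise (the magnitude of zero-mean Gaussian
draws, SD = 1.2 × the mean clean amplitude) is added at envelope level;
the noise level is calibrated so that the rank-4 fit leaves 2–10% of the
pooled variation unexplained (measured ≈ 5%, VAF ≈ 94–95%), placing the
synthetic regime near real multi-muscle running data, where VAF at k = 4
sits a little above 90%. Raw interference-pattern EMG is deliberately
not synthesized: the pipeline factorizes envelopes, and carrier-level
realism would add nothing to the closed-loop tests. Cycle durations are
i.i.d. normal (0.72 ± 0.02 s, a stride frequency near 83 cycles/min),
truncated at ±3 SD; each 200-sample cycle is mapped onto its real-time
axis by linear interpolation, with a 0.25 s quiet lead-in/out.

The acceleration channel places an oscillatory impact transient — a
Gabor-like wavelet, ~110 Hz carrier under a 5 ms Gaussian envelope — at
every foot strike, on a smooth within-cycle baseline (0.3 g sinusoid
phase-locked to the strikes, hence zero at each strike) plus Gaussian
sensor noise (SD 0.05 g). The raw wavelet amplitude is calibrated
numerically through the 60 Hz analysis filter so the *filtered* dip
magnitude equals `impact_peak_g` (default 3.5 g, the scale reported for
rearfoot running); the positive derivative peak lands ~8 ms before the
minimum, within the detector's refinement window. Strike times are
shared between the EMG and acceleration signals of a run, so the two
channels are mutually consistent.

What the generator does not emulate: raw EMG carrier statistics,
electrode artifacts and crosstalk, within-burst shape changes (bursts
are always Gaussian), correlated noise across muscles, drift or fatigue
trends, and any kinematic content. Passing tests therefore demonstrate
that the pipeline recovers modular structure under realistic amplitude/
timing variability and envelope noise — not that it is robust to every
artifact of real recordings.

## Problem sizes and determinism

Default analyses use 11 muscles, 4 modules, 20 cycles of 200 samples
(matrices of 11 x 4000). Closed-loop and twin-condition checks run over
5–20 seeded repetitions, with 5–25 NMF restarts depending on the check —
sizes chosen to make the Monte-Carlo statements stable while keeping a
full run in minutes on one core. All randomness derives from explicit
seeds (NumPy `SeedSequence` spawning per stage/restart), so every result
in the reports is bit-reproducible.

## Known limitations

- The slope-change rule is one operationalization among several; with
  very flat VAF curves the 0.03 gain threshold decides the answer.
- The ANOVA treats mode VAFs as independent groups (the repeated-
  measures structure of a within-subject design is not modeled).
- The inter-subject similarity aggregates all pairwise comparisons;
  similarity-to-group-mean is an alternative the code does not report.
- The detector assumes rearfoot-type impact transients; forefoot
  strikers with weak transients would need different parameters.
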