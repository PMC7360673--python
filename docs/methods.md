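# Methods

## The estimand: band-limited phase locking

For two source time series, connectivity is quantified by the
phase-locking value

    PLV_kl = | (1/T) Σ_t exp(−j(φ_k(t) − φ_l(t))) |,

where φ are instantaneous phases and T the number of samples in one
segment. PLV is computed per 4-s epoch and averaged across epochs (not on
the concatenated recording): T is the per-segment sample count, and the
epoch mean is what the group statistics consume. PLV is invariant to
constant phase offsets and to exchanging the two signals, lies in [0, 1],
and under i.i.d. von Mises phase jitter with concentration κ has
expectation I₁(κ)/I₀(κ) plus an O(1/√T) positive bias that is negligible
at T = 4000.

A caveat the test suite documents explicitly: for *narrowband* signals the
null PLV of independent sources is well above the i.i.d.-phase value
√π/(2√T) ≈ 0.014, because band-limiting leaves only ~(bandwidth × 4 s)
effectively independent phase samples per epoch. For 20–30 Hz noise at
T = 4000 the measured null mean is ≈ 0.1. Group comparisons are unaffected
(the bias is common to both groups), but absolute PLV values must not be
read as if they had the i.i.d. null.

## Preprocessing

Epochs are consecutive non-overlapping 4-s windows from sample 0; the
trailing partial window is discarded. Filtering never happens on an
isolated epoch: each window is extended by 2 s of real neighbouring
recording on both sides, filtered, and cropped, so filter ringing lives in
the discarded pads. Where the recording ends before a pad is complete
(first/last epochs) the missing samples are filled by reflection and a
warning is logged.

The band-pass is a linear-phase FIR (Hamming-window design) applied
forward-backward, realised exactly as multiplication by |H(f)|² in the
frequency domain of the padded window. The transition width is
min(lo/2, (hi − lo)/2): narrow enough that the pass-band of a 10 Hz-wide
band stays flat (important — a sloppy transition attenuates the phase
modulation sidebands of coupled sources and biases recovered PLV upward),
while reaching the stop-band within one octave below the band. The
squared response doubles the stop-band attenuation of the underlying
design (≥ 40 dB one octave out; the contract tested is ≥ 20 dB).

Instantaneous phase is the angle of the Hilbert-transform analytic
signal. The pipeline uses a fused fast path (`analytic_epochs`) that
applies |H|² and the analytic-signal construction in a single frequency-
domain pass over the padded window; it is tested to agree with the
two-step reference path (band-pass, then Hilbert of the cropped epoch) up
to phase noise at near-zero-amplitude samples, and is in fact slightly
cleaner at epoch edges because the Hilbert step also sees the pads.

Default bands: alpha-mu 8–13 Hz, low beta 12–20 Hz, upper beta 20–30 Hz,
at fs = 1000 Hz.

## Group inference

Seed analyses compare, per distant source, the seed-to-source mean PLV
between groups with an independent-samples t-test (pooled variance by
default; Welch available). Positive t means the first-named group (by
convention the robust group) exceeds the second, so a frailty deficit
appears as a positive cluster. Family-wise error over sources is
controlled by the cluster-based permutation test: sources with two-sided
p below the cluster-forming α (default 0.05) are grouped into spatially
contiguous same-sign clusters, each scored by its summed t ("cluster
mass"); group labels are randomly reassigned (preserving group sizes)
n_permutations times (default 5000, floor 100), and each observed
cluster's p is (1 + #{null max |mass| ≥ |mass|}) / (N + 1), referencing
the maximum over both signs by default. The estimator never returns 0 and
is a valid Monte-Carlo p. For tiny samples an exhaustive mode enumerates
every distinct relabeling and returns the exact permutation p; the
Monte-Carlo p converges to it (checked at n₁ = n₂ = 4). The ≥ 100
distinct-relabelings floor applies to Monte-Carlo mode; exhaustive mode
is the supported route below it.

Spatial contiguity is face connectivity by default (neighbours within
1.1 × grid spacing); the radius is configurable since any contiguity rule
is a convention. Seed × band × laterality analyses are tested separately
without cross-analysis correction, and the run report says so. RSN mean
FC is compared per network and band with uncorrected two-sided t-tests.

Sphere membership everywhere is the closed ball (distance ≤ radius), so
boundary sources never silently vanish. The RSN pair average defaults to
all unordered pairs of distinct member sources (`all_pairs`); a
`between_spheres` policy restricting to pairs that span different
centers' spheres is provided because the field's phrasing is genuinely
ambiguous about within-sphere pairs. The shipped RSN coordinate file
contains literature-style convenience defaults and is meant to be edited;
all analyses read coordinates from configuration.

## Clinical statistics

Categorical variables: two-sided Fisher exact test under the
probability-mass convention (sum of hypergeometric probabilities of all
same-margin tables no more probable than the observed one) — the
convention that reproduces the conventional p = 0.381 for a 21/34 vs
15/20 female split. Continuous variables: Mann-Whitney U, exact by
dynamic programming over the midrank-sum distribution (default up to
m + n = 14; ties handled exactly; verified against full split
enumeration), otherwise the normal approximation with tie and continuity
corrections. Summaries are median [25th, 75th percentile] with linear
interpolation between order statistics — one convention had to be fixed
for reproducibility; alternatives are exposed via the percentile-method
argument.

## The synthetic cohort generator

The generator's job is to produce source-space recordings whose pairwise
PLV is *known in closed form*, so the whole pipeline can be scored against
ground truth.

Every source emits one narrowband oscillator per analysis band:
φ(t) = 2πf t + θ + w(t) with the carrier f uniform inside the band
(1 Hz off the edges), θ uniform, and w a Gaussian random walk
(sd 0.05 rad/sample, giving a realistic sub-Hz linewidth). The signal is
the sum of the bands' cosines plus white observation noise
(σ = 0.2 per unit carrier amplitude). The multi-band background is
deliberate: with single-band sources, the Lorentzian tail of the one
spectral line is the *only* content of every other analysis band, it is
coherent across coupled sources, and a between-group coupling difference
then leaks into bands where no effect was implanted. With genuine
independent in-band activity present, that tail is ~25 dB below the
in-band oscillator and the leak is unmeasurable; effect confinement to
the implanted band is part of the validation suite. A single-band mode
(`multiband_background=False`) is retained.

Coupling is a driven-source model: the driven source copies the driver's
phase (in the coupling's band component) plus a fixed lag and a
stochastic offset ε(t); each source may be the driven member of at most
one pair. Two offset models:

- **Sinusoidal phase modulation (default).** ε(t) = A·cos(2π·f_m·t + ψ)
  with modulation depth A = J₀⁻¹(ρ) and f_m = 1 Hz (an integer number of
  modulation cycles per epoch, so the per-epoch time average of e^{jε} is
  exactly J₀(A) = ρ). Because the modulation is slow, its sidebands stay
  inside the band and the coupling survives filtering: the full pipeline
  recovers ρ to within ~0.02 across ρ ∈ [0.1, 0.9].
- **I.i.d. von Mises offsets** with κ = (I₁/I₀)⁻¹(ρ), the natural model
  at the phase level (and the one the sample-level oracle tests use). It
  is *not* the default for time-domain cohorts for a physical reason:
  per-sample-independent jitter is spectrally white, a 10 Hz-wide filter
  removes almost all of it, and the pipeline then recovers PLV ≈ 0.78 for
  a target of 0.2. The model is kept for phase-level studies and as a
  documented cautionary contrast.

Both links are recorded per pair in the cohort's ground truth
(`truth.json`), so the expected PLV of every coupled pair is
reconstructable.

Cohort defaults mirror the motivating study's conditions: 34 robust and
20 frail subjects; per-subject epoch counts drawn as round(N(81.0, 13.1))
(robust) and round(N(77.5, 12.1)) (frail), clipped at 20; fs = 1000 Hz;
4-s epochs. The frailty-like effect reduces seed→target coupling from
ρ_robust (default 0.45) by Δρ (default 0.15) in the frail group, in the
upper beta band only. Every subject gets an independent child RNG stream
spawned from the cohort seed; identical seeds reproduce cohorts
bit-identically across processes.

What the generator does *not* emulate: volume conduction / field spread,
1/f background spectra, artifacts, inter-subject anatomical variability,
and beamformer leakage. Passing tests therefore demonstrate the
correctness and operating characteristics of the statistical chain on
data satisfying its assumptions — not robustness to the leakage structure
of real source-reconstructed MEG.

## Validation problem sizes

The validation sweep (`phaselock.validation`, driven by the acceptance
script and test suite) uses desk-scale sizes chosen as a deliberate
trade-off between statistical resolution and a single-CPU run: type-I
error on 200 null cohorts of smoothed Gaussian FC maps on a 294-source
grid (n = 12 vs 8, 500 permutations); power/selectivity on 50 simulated
cohorts on a 100-source grid (12 vs 8 subjects, 10 epochs each, effect
band upper beta, control band alpha-mu); end-to-end recovery with 10
subjects × 80 epochs per coupling strength. The connectivity code paths
are identical at full scale — `plv_matrix` streams in row blocks, and
seed analyses only ever compute the seed rows — so a 2,459-source grid
differs only in wall-clock time. The simulator works in single precision;
float32 phase-argument rounding (≲ 10⁻³ rad over a recording) is far
below the generator's own phase noise.

## Numerical conventions and degenerate inputs

- Phases are wrapped to (−π, π]; PLV is invariant to the wrapping branch.
- PLV matrices store the diagonal as 1; no averaging operation includes
  it. Matrix symmetry is enforced bit-exactly.
- A source with zero variance in both groups gets t = 0 with a warning;
  an all-zero epoch is a hard error (its phase is undefined).
- κ(ρ) and A(ρ) are solved by Brent's method to |link(·) − ρ| < 1e-10;
  ρ = 1 is rejected as unattainable.
- Cluster results are sorted by p, ties broken by |mass|; cluster mass is
  the exact sum of member t-values.
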