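# Methods

This note documents the models, estimators, numerical choices and known
limitations of `isasync`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted from
memory.

## Signals and model

The object of study is phase-to-phase coupling between infra-slow EEG
activity (ISA, 0.01–0.1 Hz) and the tonic galvanic skin response (GSR).
Both are narrow-band filtered into ten 0.01 Hz-wide bands and reduced to
instantaneous phases; all statistics are functionals of the phase
difference θ_EEG(t) − θ_GSR(t).

**Phase Synchronization Index.** ΔΘ = (1/T) Σ exp(i(θ_EEG − θ_GSR)) is the
time-resultant of the phase difference; PSI = |ΔΘ| is 1 iff the difference
is constant and 0 for uniformly dispersed differences; mPD = arg ΔΘ is the
mean phase difference. Only samples outside filter edge regions ("valid
mask") enter the sum, and sessions of one participant are concatenated
before averaging, so T counts valid samples over all sessions. PSI differs
from the phase-locking value in averaging over time rather than trials.

**Surrogate null.** The null hypothesis is "no temporal pairing between the
two phase series". Surrogates permute the GSR *phase samples* in time
(uniform random permutations), preserving both marginal phase
distributions. Significance uses the add-one permutation p-value
p = (1 + #{surrogate ≥ observed}) / (1 + n) together with a strict
greater-than comparison against the 95th surrogate percentile. The strict
inequality and add-one formula avoid p = 0 and make the boundary case
(observed equals the percentile) non-significant by convention.

**mPD–PSI coupling.** Pooling all (participant × channel) pairs of a
group, the mPD axis (−π, π] is divided into 16 equal segments
([−π + (m−1)π/8, −π + mπ/8); +π joins the last bin). The per-bin mean PSI,
normalized to sum 1, is a distribution P_PSI whose Kullback–Leibler
divergence from uniform (natural log; 0·log 0 := 0; empty bins contribute
mean 0) measures how strongly synchronization concentrates at particular
phase differences. KL is invariant to rotating all mPDs by a multiple of
the bin width, non-negative, and at most ln 16. The surrogate shuffles the
mPD labels across the pooled pairs — implemented as permuting the PSI
values against the fixed bin assignment, which is the identical
re-pairing — so the bin occupancy pattern is preserved and only the
mPD↔PSI association is destroyed. Both the α = 0.001 criterion and the
95th-percentile (α = 0.05) criterion are computed and reported; the KL
base is not configurable because a base change rescales observed and
surrogate values identically and cannot change any p-value.

**Topography.** The grand-mean phase difference per channel is the
argument of the participant-mean of the complex ΔΘ_k — an
amplitude-weighted circular mean, so participants with strong
synchronization dominate; channels whose complex means cancel below 1e−12
are flagged undefined. Functional connectivity is the Pearson correlation
of band-passed signals with negatives clipped to zero. Its principal
gradient is the first non-trivial right eigenvector of the diffusion-map
Markov operator of the α-normalized affinity (α = 0.5), scaled by
λ/(1−λ) (diffusion time 0, the convention of the standard gradient
toolbox); eigendecomposition goes through the conjugate symmetric matrix
for numerical stability, and the sign is fixed only for display (by
positive correlation with |gmPD|) since every reported statistic is
sign-invariant. |gmPD| — non-circular, unlike gmPD — is regressed on the
gradient by OLS across channels; R² and the two-sided p-value are
reported.

**Group statistics.** Band-level tests pool the (participant × channel)
PSI values per group — 12 × 64 = 768 at full size — into a one-tailed
Wilcoxon rank-sum test (Expert > Novice), exact enumeration when both
groups have ≤ 10 untied values and the tie- and continuity-corrected
normal approximation otherwise, with Benjamini–Hochberg FDR over the ten
bands. This pooling deliberately ignores within-participant dependence
across channels; it is the conventional design for this style of channel
analysis and is reported as such, not corrected. Cohen's d uses the pooled
SD with (n−1) denominators. The demographic filter retains males of any
age and females aged ≤ 38 (perimenopausal skin-sensitivity changes can
destabilize GSR), and an age-balance check uses the two-tailed rank-sum
test.

## Preprocessing choices

- **Band edges.** Band b spans [f_b, f_b + 0.01] Hz; the nominal frequency
  is the lower edge (a centered-band mode, f ± 0.005, is available via
  `centered_bands`).
- **FIR design.** Hamming-window FIR, transition width 0.005 Hz, length
  ceil(3.3/0.005 × fs) taps (5281 at 8 Hz, ≈ 660 s). The transition band
  is centered on each band edge (cutoffs at edge ∓ transition/2) so the
  nominal passband keeps ≈ unit gain; placing cutoffs exactly at the edges
  would put the −6 dB points there and attenuate the band center by ~7%.
  Zero phase is obtained by forward–backward application, implemented as a
  single convolution with the kernel's autocorrelation; phase error at the
  band center is < 1e−4 rad.
- **Edge handling.** One filter length at each end of each session is
  marked invalid before any phase statistic; filter and Hilbert transients
  live there.
- **Decimation.** Anti-aliasing uses a flat-passband Hamming FIR
  (30q + 1 taps for factor q, cutoff 0.4 × the output rate) applied
  forward–backward before taking every q-th sample. An elliptic/Chebyshev
  IIR was rejected because its passband ripple (~2% after two zero-phase
  stages) violates the unit-DC-gain contract the phase analysis assumes.
- **Surface Laplacian.** Perrin-style spherical splines: G and H kernels
  from Legendre series truncated at order 50 with spline flexibility
  m = 4, smoothing λ = 10⁻⁵, solved with the constant-constraint
  augmented system per time sample. Spatially constant fields map to
  numerical zero and per-sample reference offsets cancel exactly.
  Detrending is per session.

## The synthetic cohort

`isasync.synth` generates two-group cohorts with known coupling ground
truth. GSR = Σ_b A_b cos(φ_b(t)) + white noise, where φ_b advances at
2π f_b with a small random walk. EEG channel c adds, per band,
A_b cos(φ_b(t) + δ_c + ε(t)) plus white noise (`noise_sd`, relative to
unit oscillation amplitude) and a linear drift (`drift_slope`).

**Jitter.** Two regimes are provided, because they answer different
questions:

- `jittered_phase_pair` draws phase series directly with i.i.d. von Mises
  jitter per sample. There the population resultant is exactly
  I₁(κ)/I₀(κ), which is what the closed-form recovery and null-calibration
  checks use (mean estimated PSI within ±0.001 of the Bessel ratio at
  T = 2000, κ > 0; at κ = 0 the mean PSI equals the Rayleigh resultant
  √(π/4T), not zero).
- In raw recordings, ε(t) is held constant over `jitter_dwell`-second
  blocks, i.i.d. von Mises across blocks. This is deliberate: i.i.d.
  per-sample jitter is mathematically invisible downstream — a filter of
  bandwidth B at sampling rate fs retains only a fraction ~B/fs of the
  jitter power, so filtering would drive PSI → 1 regardless of κ. Blockwise
  jitter with dwell longer than the filter kernel (default 600 s vs
  ≈ 330 s half-kernel) passes through, at the cost that the downstream PSI
  is the resultant of K = valid-duration/dwell draws rather than T samples:
  its expectation carries an upward small-sample bias
  ≈ √(ρ² + (1−ρ²)/K) plus a smoothing bias from block transitions.
  Recording-level tests therefore assert the κ *ordering* and leave exact
  Bessel recovery to the phase level.

**Study conditions (defaults, chosen once).** 12 + 12 participants, 64
channels, 3 sessions × 90 min (sessions are concatenated downstream),
fs = 256 Hz for full fidelity or 8 Hz to generate directly at the analysis
rate, noise_sd = 0.5, drift 0.1/s, κ_Expert = 4, κ_Novice = 1.
Demographics reproduce the motivating design: Expert 3 F / 9 M, Novice
10 F / 2 M, ages ~N(39.3, 12²) and N(45, 14.8²), so the participant filter
has work to do.

**Spatial structure.** The montage is a spherical Fibonacci lattice on the
upper hemisphere, ordered by elevation. The default lag map places 3/8 of
channels in-phase (δ = 0, an outer annulus), 3/8 anti-phase (δ = π, a
polar cap — a pericentral/peripheral cluster pattern), and the remainder
at intermediate lags (±3π/8, ±5π/8) in the band between. Two asymmetries
encode the group phenomenon rather than a mere κ shift:

- *Expert concentration profile*: a scalar κ_Expert expands to κ at the
  0/π cluster channels and κ/4 at intermediate-lag channels, so Expert
  synchronization concentrates where the phase difference is 0 or π —
  which is precisely what the mPD–PSI coupling statistic detects. Without
  it the KL permutation test (invariant to bin occupancy) would have
  nothing to find in either group.
- *Novice lag disorder*: Novice channel lags receive a per-participant
  uniform scatter of half-width `lag_disorder_novice` (default π, fully
  disorganized). The organized lag topography is the Expert phenomenon;
  with shared Novice clusters the Novices would show a weak but real
  estimation-induced coupling (accurately estimated high-PSI pairs land in
  the 0/π bins) and an organized gmPD map, blurring both group contrasts.

**What the generator does not emulate.** No volume conduction (each
channel's component is injected directly), no eye-blink or muscle
artifacts, no amplitude–arousal coupling (the analysis is phase-only), no
1/f background structure. Two consequences matter. First, the surface
Laplacian — a spatial deconvolution for volume-conducted data — has
nothing to undo here and actively rotates the phase topography of broad
synthetic patterns (surround inversion), so synthetic-cohort pipelines run
with the Laplacian disabled; CSD correctness is established by its own
null-space, reference-invariance and brute-force spline oracle tests.
Second, passing tests demonstrate the estimators and their calibration,
not robustness to real-world EEG artifacts.

## Scaled-down verification cohort

The end-to-end contrast checks run a 6 + 6 participant, 16-channel,
two-band (0.03, 0.07 Hz) cohort with κ 4 vs 1 and three 90-minute
sessions — sized so the whole chain runs in well under a minute while the
pooled rank-sum, coupling and regression contrasts are stable across
seeds. At this scale (96 mPD–PSI pairs per group and band) the Expert
coupling permutation p is reliably below the 0.05 / 95th-percentile
criterion and the Novice p reliably above it; the stricter α = 0.001
criterion is exercised separately on a constructed 200-pair strong-coupling
set, where detection power at 10,000 surrogates exceeds 95% across seeds.
The "lag-shuffled" regression control reports the mean R² over 20 random
channel permutations of |gmPD|, since a single 16-channel permutation has
E[R²] ≈ 1/(n−2) with enough spread to exceed 0.2 by chance.

## Numerical conventions and degenerate inputs

- Phases are wrapped to (−π, π] everywhere; −π maps to +π.
- PSI significance and coupling significance use the add-one p-value and
  strict percentile exceedance; a single-pair coupling input yields p = 1
  (all surrogates equal the observation).
- The diffusion embedding refuses disconnected affinity graphs and
  degenerate leading eigenpairs (gap < 1e−9), e.g. the all-ones matrix.
- Zero-variance channels make correlation undefined and are reported by
  channel index; duplicate electrode positions make the spline montage
  singular and are rejected.
- Exact rank-sum enumeration applies only to untied samples with both
  n ≤ 10; ties always fall back to the corrected normal approximation.
- EDF serialization uses one-second records, 16-bit (EDF) or 24-bit
  (BDF/BioSemi) samples with per-channel physical ranges taken from the
  data; round-trip error is bounded by one quantization step, and reading
  goes through MNE, which independently parses the header.
- All randomness flows from explicit integer seeds through named
  `SeedSequence` substreams (per stage, participant, session); re-running
  any configuration reproduces every numeric output bit-for-bit.

## Known limitations

- The pooled band-level test treats channels of one participant as
  independent observations (by design, for comparability).
- The blockwise-jitter construction makes downstream PSI a K-block
  resultant; recording-level PSI is therefore biased upward relative to
  I₁(κ)/I₀(κ) for small K, and exact Bessel recovery is a phase-level
  property.
- The Novice group's p-values in the coupling test are approximately
  uniform under the default (fully disordered) conditions, so any single
  run has the usual 5% chance of a nominally significant Novice band at
  α = 0.05.
- Real-data features (artifacts, nonstationarity, volume conduction,
  montage digitization error) are out of the generator's scope; the EDF
  reader and CSD stage accept real recordings, but their behaviour on such
  data is not covered by the synthetic tests.
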