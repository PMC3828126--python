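# Methods

## Model

The package models the output layer of primary auditory cortex as an array
of `n` frequency-selective units. Unit `i` has a best frequency (BF)
φ<sub>i</sub>; BFs are geometrically (log-uniformly) spaced over a fixed
range, by default the two octaves [500, 2000] Hz centred on 1 kHz, with both
endpoints included. Density is therefore `n / octaves` and changes when the
population is resized over the same range.

The mean spike rate in response to a pure tone of frequency `f` and
intensity `l` is additive-multiplicative,

    r_i(f, l) = r_s + r_e(l) · h_i(f),

so a BF tone at the reference intensity evokes `r_s + r_e_ref` ≈ 15.1
spikes/s, and off-BF units fall back to the spontaneous rate. The tuning
curve is the rounded exponential (roex)

    h_i(f) = (1 + α g)(e^{−α g}),   g = |f − φ_i| / φ_i,

the standard psychoacoustic auditory-filter shape. The argument is the
*linear* normalised deviation `g`; a log-frequency deviation
`g = |log(f/φ)|` is equivalent to first order at these bandwidths and was
rejected in favour of the convention used for roex filters in the
psychoacoustic literature. The sharpness α is set from the quality factor
Q (BF over half-height bandwidth): the roex reaches ½ at `αg = x*` with
`(1+x*)e^{−x*} = ½` (x* ≈ 1.6783), so `α = 2 Q x*` — α ≈ 40.3 for the
sharply tuned Q = 12 population, α ≈ 12.4 for Q = 3.7. A single Q is used
per model; per-unit α is supported but defaults to uniform.

The rate-level function is linear in dB and applies to the evoked component
only: `r_e(l) = r_e_ref + k (l − 50)` with `k` in spikes/s/dB; the
spontaneous rate is intensity-independent. Intensities at which `r_e(l)`
would go negative are outside the model's validity range and raise an
error rather than clamp.

### Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| n | 1700 | — | population size (850 units/octave over 2 octaves) |
| f range | 500–2000 | Hz | BF span, two octaves centred on 1 kHz |
| Q | 12 | — | sharp cortical tuning; 3.7 models non-sharp units |
| r_s | 0.1 | spikes/s | spontaneous rate |
| r_e_ref | 15 | spikes/s | evoked rate at BF, 50 dB SPL |
| k | 0 (calibrated) | spikes/s/dB | dB-linear evoked-rate slope |
| ρ | 0.25 | — | maximal pairwise spike-count correlation |
| T | 1 | s | tone duration; counts = rates × T |

The standard probe stimuli are the human threshold-level pairs
1000 vs 1001.68 Hz and 50 vs 51.22 dB SPL (d′ = 1 behaviourally); these two
steps are taken as given constants from the psychoacoustic literature, not
fitted.

## Noise model

Spike counts are multivariate Gaussian with Poisson-like variance: the
count variance of each unit equals its mean count, and

    V_ij = C_ij √(c_i c_j),

the correlation coefficient times the geometric mean of the counts. The
correlation matrix is built from receptive-field overlap,

    C = I + ρ (G − I),   G_ij = ⟨h_i, h_j⟩ / (‖h_i‖ ‖h_j‖),

with each tuning vector `h_i` sampled at every BF on the grid. This
satisfies all the structural constraints at once — unit diagonal, maximal
off-diagonal entry approaching ρ for the most-overlapping (neighbouring)
pair, monotone decay with BF distance — and is positive semidefinite by
construction (a convex combination of the identity and a normalised Gram
matrix). An unnormalised Gram alternative was rejected because it would not
cap correlations at ρ. Because the tuning vectors are evaluated on the BF
grid, C is stimulus-independent; the stimulus dependence of V enters only
through the counts. PSD validation accepts eigenvalues above −1e−10
(certified by a cheap Cholesky of C + 1e−10·I), projects noise-scale
violations down to −1e−6 onto the nearest correlation matrix with a
warning, and rejects anything worse with the offending eigenvalue in the
message.

## Information analysis

For Gaussian responses with stimulus-dependent mean and covariance the
Fisher information about a stimulus dimension x is

    I(x) = c′ᵀ V⁻¹ c′ + ½ Tr[(V⁻¹ V′)²],

and the best achievable sensitivity for a step Δx is d′ = Δx √I(x),
evaluated at the *reference* stimulus (1 kHz, 50 dB SPL) — the local form
of d′ implies evaluation at the reference rather than the pair midpoint.
Count derivatives are analytic (`∂r_i/∂f = −r_e α² g e^{−αg} sign(f−φ_i)/φ_i`,
`∂r_i/∂l = k h_i(f)`; both validated against central finite differences at
1e−6 relative), and `∂V_ij/∂x = C_ij (c_i′c_j + c_i c_j′)/(2√(c_i c_j))`.
Linear solves use the symmetric Cholesky factorisation rather than explicit
inversion; a condition-number estimate from the factor diagonal is logged
and warns above 1e10.

The per-unit decomposition splits both terms row-wise,

    I_i = [c′]_i [V⁻¹ c′]_i + ½ Diag_i[(V⁻¹ V′)²],

the unique row split whose sum reconstructs I exactly, so the
root-sum-square of d′<sub>i</sub> = Δx √I_i equals d′. `diag((V⁻¹V′)²)` is
not sign-definite: uninformative units can carry tiny negative terms
(observed only below 1e−4 of the total information), which are clipped at
zero — silently at that cancellation scale, with a warning if ever
materially negative.

Supporting signal-detection quantities: single-unit SNR
`(c_alt − c_ref)/√c_ref`; the independent-pool closed form
d′ = √(Σ SNR²); percent correct in two-interval two-alternative forced
choice `P = 100·Φ(d′/√2)` and its inverse.

## Inverse solvers

* **Population size**: d′(n) is evaluated on a doubling ladder from
  `n_min`, then bisected on the integer grid to relative width 1%
  (BFs re-spread over the fixed range at each n). Monotonicity of d′ in n
  is *verified* on the evaluated ladder — it is not guaranteed under
  correlated noise — and a violation is reported instead of assumed away.
* **Threshold step**: Δx = target/√I, closed form by linearity.
* **Intensity-slope calibration**: bracketed Brent root finding on
  d′(k) − target. At the reference intensity V is independent of k while
  both Fisher terms scale as k², so d′ is linear in k and the scale
  consistency (double target → double k) is exact.

## Synthetic data and decoder validation

Trials are drawn from the multivariate Gaussian (eigendecomposition-based
sampling, seeded `numpy` Generator), rounded to the nearest integer
(ties-to-even, platform-stable) and clamped at zero, since spike counts are
non-negative. Clamping touches only draws below −0.5: for near-spontaneous
units (mean count 0.1) about 3% of entries, for strongly driven near-BF
units (mean ≈ 15) about 3·10⁻⁵ — both measured in the tests. Rounding adds
≈1/12 quantisation variance, which the moment-recovery tests account for;
its effect on decoded d′ is below 2%.

Two-interval trials place the reference and shifted stimulus in random
order (exactly balanced for even trial counts). The decoder is the optimal
linear discriminant `w = V⁻¹Δr` applied to the interval difference —
sufficient for equal-covariance Gaussians — with a full Gaussian
maximum-likelihood variant (both stimulus-specific covariances) available
for the intensity task where the covariance itself carries information.
Observed percent correct maps back to an empirical d′ through the inverse
2I2AFC relation (probit), with a delta-method standard error; the empirical
d′ is checked never to exceed the Fisher-bound d′ by more than 3 SE.
Decoder validation defaults to reduced populations (n ≤ 200), which keeps
Monte-Carlo runs at tens of seconds while exercising every part of the
pipeline; the Fisher analysis itself runs at full size (n = 1700).

## What the simulator does and does not emulate

The generator realises exactly the model the analysis assumes: Gaussian
counts with Poisson-like variance and overlap-structured correlations,
stationary across trials. Real cortical populations differ in ways the
model deliberately omits: non-Gaussian count statistics at low rates,
non-monotonic rate-level functions, heterogeneous tuning widths and
correlation structure, adaptation across trials, and any temporal (PSTH)
structure within the 1 s window. Passing tests therefore certify the
information analysis and its implementation, not these biological
complications; conclusions about real cortex inherit the model's
assumptions.

## Known limitations

* The exact shape of the correlation kernel is the least-constrained part
  of the model. The cosine-overlap construction used here fixes the
  correlation length to the tuning-curve overlap width; with it, the
  ρ = 0 analyses and the intensity calibration reproduce the expected
  values closely, while the ρ = 0.25 frequency-task d′ at n = 1700 comes
  out ≈0.84 rather than 1, so the size solver returns ≈2700 units and the
  ρ = 0 advantage is ≈2.0× rather than ≈1.7×. Broader correlation kernels
  (correlation lengths several times the tuning width) move those numbers
  together toward the expected trio, but no such kernel follows from the
  overlap construction itself; the discrepancy is documented rather than
  tuned away.
* Fisher information upper-bounds decoding performance; it can be
  optimistic for short windows or strongly non-Gaussian codes, and assumes
  a statistically optimal (maximum-likelihood) read-out downstream.
* The linear rate-level function is only valid over a moderate intensity
  range around 50 dB SPL.
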