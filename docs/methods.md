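# Methods

This note records the models behind `sti1dyn`, the defaults that matter,
and the choices made where the design was genuinely open. Nothing here is
an empirical claim beyond what the test suite and `scripts/acceptance.py`
compute.

## FRET relations (`sti1dyn.fret`)

Efficiency and distance are linked by the Förster relation
`E = 1/(1+(R/R₀)⁶)`. The Förster radius of the ATTO 532/647 pair used on
Sti1 is not published; the default `R₀ = 52 Å` is fixed by requiring the
published pair of observations — E ≈ 0.2 at ≈ 65 Å separation — to be
self-consistent (65/52 = 1.25, E = 0.21). R₀ is a parameter everywhere it
enters.

Intensity-based efficiency is `E = I_A/(I_A+γI_D)`. The detection
correction γ is unreported and defaults to 1.0 throughout; it is a
configuration parameter of every routine that touches intensities.

The static efficiency–lifetime line is `E = 1 − τ_D(A)/τ_D(0)`. For a
molecule exchanging between two states the fluorescence-weighted locus

    E = 1 − τ₁τ₂ / (τ_D(0) · (τ₁ + τ₂ − ⟨τ⟩_f))

is used. This is the standard two-state dynamic-FRET line; it is the only
form whose endpoints (⟨τ⟩_f = τ₁ or τ₂) coincide with the static line and
which reduces to it when τ₁ = τ₂, and both properties are enforced by
tests. Between the endpoints it lies strictly to the right of the static
line, which is the dynamics signature the burst diagnostic scores.

## Synthetic data (`sti1dyn.synthetic`)

The generators define the study conditions for every recovery test.

**State kinetics.** Conformational switching is a continuous-time Markov
chain over K FRET states (efficiency, emission s.d., rate matrix in s⁻¹).
`simulate_state_path` samples exact exponential dwells (Gillespie), with
the initial state drawn from the stationary distribution. The default
three-state parameter set (efficiencies 0.16/0.52/0.84, rates 0.9–4.5 s⁻¹,
`studies.sti1_hsp70_state_model`) is the Hsp70-bound Sti1 condition.

**Camera traces.** 30 ms frames (configurable). Per frame the
occupancy-weighted mean efficiency Ē is perturbed by the
occupancy-weighted state width (conformational noise), split into
acceptor `brightness·Ē` and donor `brightness·(1−Ē)/γ` channels, and read
out with Poisson shot noise, per-channel background and optional Gaussian
read noise — the usual EMCCD approximation; no camera model is published
for the original instrument. Photobleaching is single-step and
exponential per fluorophore: a donor bleach silences both channels, an
acceptor bleach reroutes the transfer back into the donor channel, so the
γ-corrected total intensity drops only when the donor dies. Defaults
(brightness 2000 photons/frame, background 20/frame, 200 frames) are
declared, not inferred; trace length, excitation power and frame time are
unreported for the original experiments.

**Frame-synchronous paths.** `simulate_framewise_path` draws states at
frame resolution from the exact one-frame matrix `expm(QΔt)`, i.e. from
the discrete-frame HMM's own generative model. The HMM recovery studies
use it rather than the continuous-time path: the published state/rate
tables are themselves the output of a discrete-frame HMM analysis, and
with continuous-time switching the frames that straddle a transition
carry intermediate apparent efficiencies that a 3-state Gaussian HMM
systematically routes through the middle state — at the published rates
this depresses the recovered direct low↔high rates by ≈ 40–50%, which is
a property of camera-blurred data, not of the estimator under its own
model. The camera generator keeps time-averaging as its default because
that is what a real 30 ms integration does; the blur bias is therefore a
known limitation when interpreting fitted rates from real traces whose
dwells approach the frame time.

**Bursts.** Per burst, the donor-excitation photon count N comes from the
burst-size distribution (default uniform 30–150), the acceptor count is
`Binomial(N, E)`, the PIE acceptor-excitation count is Poisson with mean
N (zero for donor-only molecules), and the mean donor-lifetime estimate
is `τ = (1−E)τ_D(0)` plus Gaussian estimator noise of s.d. `τ/√n_donor`.
With a `StateModel` and a burst duration (default 1 ms), intra-burst
switching yields the intensity-weighted E and the fluorescence-weighted
⟨τ⟩_f from the trajectory occupancies, which is what places dynamic
bursts to the right of the static line. Burst *detection* from photon
streams is out of scope; the burst-search parameters of the original
experiments are unreported and all downstream quantities depend only on
per-burst summaries.

**Sedimentation boundaries.** Each species contributes a Faxén-type
error-function boundary centred at `r_b(t) = r_m·exp(ω²st)` with width
`√(4Dt)`, scaled by its plateau signal; radial dilution
(`exp(−2ω²st)`) is behind a flag, default off, so recovery tests have an
exactly known ground truth. No Lamm-equation solver is included.

**Titrations.** `R(c) = S_max·c/(K_d+c)` plus Gaussian noise.

All generators are bit-reproducible under a fixed seed.

## Burst analysis and PDA (`sti1dyn.burst`)

Double-label selection keeps bursts with total counts ≥ 50,
acceptor-excitation counts ≥ 10 and PIE stoichiometry in [0.3, 0.7] —
community-standard defaults; the original thresholds are unreported.

PDA computes the expected acceptor-fraction histogram by Gauss–Hermite
quadrature (25 nodes) over the Gaussian distance density and exact
binomial mass per burst size, and fits `(R̄, σ_R)` by least squares on
per-bin probability masses; a multinomial reduced χ² is reported when the
burst count is known. With σ_R = 0 and a single burst size the prediction
is exactly binomial, which anchors the quadrature against a Monte-Carlo
oracle in the tests.

The E–τ deviation score is the mean signed horizontal distance from the
static line for bursts with 0.1 < E < 0.9, in ns, with its standard
error. For a truly static single-distance population it is centred on
zero; note that a static population with a *broad* distance distribution
acquires a small positive offset from the curvature of E(R) (Jensen
effect) — heterogeneity mimics weak dynamics, which is why the score is
reported with its standard error rather than thresholded internally.

## TIRF HMM (`sti1dyn.hmm`)

**Bleach screening.** Binary-segmentation change-point scan with a
two-sample t statistic, Bonferroni-corrected per segment (α = 0.01),
minimum segment 5 frames — no algorithm is published for the original
filter. The scan runs on the γ-corrected total intensity (donor bleaches)
and on the acceptor channel (acceptor bleaches, which leave the corrected
total flat by construction); coincident detections are merged. A step
must additionally drop the local signal by ≥ 10% of the trace's dynamic
range, which suppresses spurious significant "steps" in the Poisson
background after a genuine bleach. Traces with more than one step are
discarded; accepted traces are truncated at the first step and must
retain ≥ 10 frames.

**Global fit.** One Gaussian-emission HMM is fit to all traces jointly:
emission means/s.d.s and the per-frame transition matrix are shared, and
the start distribution is a single shared vector updated by standard
Baum–Welch. (Tying the start vector to the stationary distribution of the
transition matrix was considered and rejected: it breaks the EM
monotonicity guarantee, which this implementation asserts at every
iteration.) Initialization places means at the 10th–90th percentile
quantiles of the pooled data with a self-biased (0.9 diagonal) transition
matrix; 10 seeded restarts jitter the means and the best log-likelihood
wins. States are finally sorted by ascending mean, which resolves label
switching deterministically. Emission s.d.s are floored at 10⁻³ with a
degeneracy warning when K exceeds the number of distinct levels.
Convergence: relative log-likelihood change below 10⁻⁷ or 300 iterations.

**Rates.** `k_ij = A_ij/Δt` by default — the standard first-order reading
of per-frame probabilities, adequate when `A_ij ≪ 1`. At the study
conditions (rates up to 4.5 s⁻¹ at 30 ms) this estimator carries an
inherent ≈ −10% bias relative to the generating rates because
`A = expm(QΔt)` is not linear in Q; the exact inverse `logm(A)/Δt` is
available via `method="matrix_log"` and is tested to invert the
discretization exactly. Transition counts are tallied from Viterbi paths.

**Dynamic classification.** A trace counts as dynamic when its Viterbi
path contains at least one state change with both flanking dwells ≥ 3
frames and the two state means separated by ≥ 0.1 efficiency units. The
separation guard (beyond the dwell-length rule) prevents near-degenerate
fitted states from generating spurious dynamic calls; the published
analysis selected dynamic traces manually, so this classifier is a
declared surrogate, not a reconstruction, and the published dynamic-trace
percentages are not used as recovery targets (they are also internally
inconsistent between text and table in the source experiments).

## Hydrodynamics and binding (`sti1dyn.auc`)

**dc/dt.** Adjacent scan pairs (stride configurable) give
`−Δc/Δt` per radius, mapped to `s* = ln(r/r_m)/(ω²·t̄)` and averaged on a
common 200-point s* grid. Diffusional broadening is absorbed into the
fitted Gaussian widths — mirroring the descriptive bi/tri-Gaussian use in
the source analysis — and also skews g(s*) slightly toward high s; the
skew decays as the boundary advances, so scans should be (and in the
recovery studies are) taken while the boundary crosses the middle of the
cell. Species decomposition is nonlinear least squares over a sum of
Gaussians, seeded from detected peaks, with any center optionally fixed
to a known free-species value — the standard device when free and
complexed species overlap strongly. Peak areas on the s* grid scale as
`plateau·s/t̄`, so `species_populations` divides each Gaussian area by its
center before normalizing (plain area ratios are available behind a
flag).

**Svedberg relations.** `s = M(1−v̄ρ)/(N_A f)`, `f = (f/f₀)·6πη·r₀` with
the anhydrous equal-mass sphere radius `r₀ = (3Mv̄/4πN_A)^{1/3}`; closed
forms solve for any single unknown among s, M, f/f₀. Defaults are water
at 20 °C (ρ = 0.99823 g/cm³, η = 1.0016 cP) and v̄ = 0.73 cm³/g; the
buffer constants of the original experiments are unreported, so
frictional-coefficient reproduction is a consistency check, not a
recovery target.

**Langmuir.** `R(c) = S_max·c/(K_d+c)` by least squares with covariance
standard errors; a warning is raised when the titration stops below
half-saturation.

## Recovery studies and problem sizes (`sti1dyn.studies`)

- HMM: 100 traces × 400 frames at 30 ms (40,000 usable frames), emission
  s.d. 0.08, brightness 5000, no bleaching; global 3-state fit, 10
  restarts. State means recover to ±0.03 and the low→high / high→low
  rates to within ±20% (the residual deficit is the k = A/Δt
  discretization bias above).
- PDA: 5,000 bursts, sizes 30–150, population 65 ± 5 Å at R₀ = 52 Å; σ_R
  recovers to ±1 Å.
- dc/dt: 10 scans at 42,000 r.p.m., meniscus 6.0 cm; single 4.2 S species
  (late window, 12,000–15,600 s) and 4.2 + 5.6 S mixture (8,000–11,600 s,
  first center fixed); centers recover to ±0.1 / ±0.15 S.

These sizes were chosen so each study is statistically decisive while the
whole suite runs in about a minute on one core.

## Known limitations

- Fitted rates from real camera traces whose dwells approach the frame
  time are biased low by intra-frame averaging; the package quantifies
  this (see above) but does not correct it.
- PDA fits a single Gaussian population (plus optional donor-only
  fraction); no multi-population mixtures.
- No lifetime fitting from photon-arrival (TCSPC) data; lifetimes enter
  as per-burst summaries.
- No Lamm-equation or c(s) fitting; the Svedberg utilities are
  closed-form only.
- Synthetic traces lack spectral crosstalk, blinking and non-exponential
  photobleaching, so passing recovery tests demonstrates estimator
  correctness under the stated noise models, not robustness to every
  camera artifact.
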