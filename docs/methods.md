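# Methods

This note documents the models, defaults and design choices behind
`seednmr`, a virtual single-kernel NMR screening pipeline. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal model

The spin-echo amplitude of a dried kernel is modelled as the sum of two
exponentially relaxing proton pools,

    S(t) = S_o exp(−t/T2_oil) + S_w exp(−t/T2_water),

with S_o, S_w (volts) proportional to oil and bound-water proton mass and
S(0) = S_o + S_w observed directly as the FID amplitude. Line constants
are T2_oil = 100 ms and T2_water = 0.75 ms, treated as identical across
kernels; drying leaves only bound water (moisture well under 15 %), which
is what makes T2_water so short and the two pools cleanly separable.

**Time convention.** All echo times are *full* echo times t, the variable
the decay law is written in; the screening echo time is TE = 7.5 ms, at
which the water term survives at exp(−10) ≈ 4.54·10⁻⁵ of S_w.

**Noise model.** Additive i.i.d. Gaussian receiver noise on every
recorded amplitude (FID and each echo), with standard deviation
`noise_sd_v / sqrt(n_averages)` — the standard relaxometry assumption for
signal averaging. `n_averages` defaults to 2 (4 is the other operating
point, used for low-oil kernels). Spectrometer settings (22.06 MHz,
4/8 µs pulses, 100 kHz bandwidth, 500 ms recycle) are carried as
provenance metadata and never used numerically; T1 saturation and
off-resonance effects are out of scope.

**Echo grid.** Default: 12 echoes log-spaced 0.3–120 ms, plus the t = 0
FID point, spanning both relaxation regimes; the screening pipeline adds
TE = 7.5 ms to this grid. The grid is configurable; nothing downstream
depends on its exact spacing beyond the ≥ 5-point, ≥ 1-decade
requirements of the bi-exponential fit.

## Decomposition

Two routes recover (S_o, S_w) from a recorded train:

1. **Single-echo isolation** (production): S_o is read from the echo at
   TE (matched to the nearest acquired echo within 1 %), after checking
   that the residual water fraction exp(−TE/T2_water) is below 10⁻³;
   S_w = S(0) − S_o, clipped at zero with a warning if noise drives it
   negative. By default the raw echo amplitude is used
   (`correct=False`), which under-reads S_o by the fixed factor
   exp(−TE/T2_oil) = 0.928; because the factor is identical for every
   kernel sharing T2_oil, a calibration fitted on standards measured at
   the same TE absorbs it into the slope (tested as the absorption
   property). `correct=True` multiplies by exp(+TE/T2_oil) instead, for
   use when the calibration is specified in true-signal units.
2. **Full bi-exponential fit** (characterization): bound-constrained
   nonlinear least squares (`scipy.optimize.least_squares`, trf) of all
   four parameters, including the FID as the t = 0 observation.
   Initialization is a deterministic two-stage log-linear fit — the tail
   (t > 10× the fast-T2 guess, taken as the earliest echo time) fixes the
   slow component, which is subtracted before the early points fix the
   fast one. Amplitudes are constrained ≥ 0, T2s to [10⁻⁶, 10⁶] ms; cost
   tolerance 10⁻¹⁰, max 500 iterations, no random restarts. If the two
   fitted T2s differ by under 5 % while both amplitudes are material, the
   components are declared non-separable (`converged=False`). In the
   one-component limit (S_w → 0) the degeneracy check is skipped, since
   the vanishing component's T2 is unidentifiable and harmless.

## Calibration

Mass on signal, A = kS + b, by ordinary least squares — the direction the
calibration law is written in; no weighting, since no error model for the
standards is assumed. k must be positive; b is the small instrument
background. The reference slope used throughout the synthetic instrument
is 361.7 mg/V with b = 0. Negative calibrated masses (possible near S = 0
with b < 0) are clipped to zero with a warning. Recalibration scheduling
is an operations concern and out of scope; the model carries an optional
timestamp for provenance.

## Screening

OCR = 100 · (oil mass in mg / 1000) / (kernel mass in g), i.e. both
masses in a common unit before the ratio. The classifier is a fixed
threshold: OCR < 4.25 % → haploid, with ties to diploid (the conservative
convention for a clean haploid pool: the boundary kernel is discarded
from the pool rather than admitted). The threshold is an *input*: for the
field-test Gaussians neither the equal-density crossing (≈ 4.5 %) nor the
minimum of FN + FP reproduces 4.25 exactly, so the operational value is
taken as given; `optimal_threshold` exposes a 0.01-step grid minimiser
for analysis but is never used to claim the operational value.

Class models are fitted either from labels (per-class sample mean/sd,
priors from label counts) or unlabelled via a two-component Gaussian
mixture (`sklearn.mixture.GaussianMixture`, EM, seeded and hence
deterministic, 3 inits); the lower-mean component is always reported as
haploid, following the biology (the inducer raises diploid kernel oil).

Error-rate conventions: false negative = P(called haploid | diploid),
false positive = P(called diploid | haploid). `total_error` is the plain
sum FN + FP — the convention used in the field report this pipeline
mirrors — and, because that additive convention is unusual, a
prior-weighted misclassification probability is always reported
alongside. Analytic rates use the normal CDF; empirical rates use
confusion counts; both are exposed, and for the published field
parameters (diploid N(5.5, 0.52), threshold 4.25 %) the analytic false
negative is 0.81 %, consistent with the published 0.83 % within rounding
of the printed sd. The published false positive of 7.27 % is *not*
consistent with its own printed Gaussian (N(3.6, 0.47) gives ≈ 8.3 %);
the package documents the discrepancy rather than resolving it, and
asserts only the reproducible quantity.

Separability of two class Gaussians is diagnosed by comparing the mean
gap |E₂ − E₁| with the mean half-width (σ₁ + σ₂)/2 — a deliberately
simple instrument-style criterion, not a formal test.

`compare_replicates` summarises paired replicate series (mean, sd,
se = sd/√n, t = mean/se with df = n − 1, two-tailed p from the t
distribution, Pearson r), for acquisition-time repeatability studies.

## Synthetic populations

`generate_population` inverts the observed Gaussian structure of field
populations into a sampling model: class by Bernoulli/categorical draw,
weight ~ class Gaussian truncated at 0.05 g, OCR ~ class Gaussian
truncated at 0, oil mass = OCR · m · 10 mg, water mass from a WCR
Gaussian the same way. OCR and weight are sampled independently within
class — no correlation structure is imposed, because none is reported for
the populations emulated. All truncation points sit many sd from the
preset means, so the induced mean bias is negligible (< 0.1 %).

Shipped presets (JSON under `seednmr/presets/`):

| preset | classes (OCR %, weight g) |
|---|---|
| `maize_zd958` | haploid N(3.6, 0.47), N(0.40, 0.049); diploid N(5.5, 0.52), N(0.43, 0.035); 50/50 |
| `maize_zd958_induction` | same Gaussians, haploid fraction 0.0858 (the realistic induction rate implied by 321/3742 haploid calls) |
| `zheng58_cauhoi` | one reference kernel class, OCR N(6.7, 0.2), weight N(0.42, 0.02) — for stability runs |
| `soybean_feng1` / `soybean_feng2` | single class, OCR N(17.5, 2.0) / N(20.4, 1.0) |

The 50/50 maize default is for balanced testing of both error rates; use
the induction preset for realistic prevalence. The WCR default
(mean 10 %, sd 1 %) is a choice: dried-kernel moisture is only bounded
(< 15 %) by the source material, not distributed, and the water channel
feeds nothing downstream but the water mass. The reference kernel's OCR
repeatability sd of 0.2 percentage points is likewise a judgement call:
the published stability numbers (range 6.5–7.2 %, mean 6.7 %, sd quoted
as 0.7 %) are internally inconsistent if the sd is read in percentage
points for 50 repeats, and ~0.2 pp is the value the printed range
supports.

Feeder presets store the observed single-kernel pick-up success rates
(round corn 0.92, flat corn 0.90, soybean 0.974, other round seeds 0.98);
`simulate_feeder` draws i.i.d. Bernoulli attempts — no serial correlation
or jam dynamics.

`population_to_signals` closes the loop: S = (A − b)/k per pool, then the
forward signal model. On noiseless data the full pipeline (decompose →
calibrate → OCR) reproduces each generated OCR to < 0.005 percentage
points (the only residual being the 5·10⁻⁵ water leakage at TE).

## Pipeline

`run_screening` chains generate → simulate → decompose → calibrate → OCR
→ classify → report. One run seed is expanded into per-stage substreams
(population, receiver noise) via `numpy` seed sequences, so identical
configurations give byte-identical outputs, and the per-kernel noise
streams are independent of population size ordering. The pipeline
distinguishes the *instrument's* physical signal constant (used to turn
generated masses into signal amplitudes; default 361.7 mg/V, b = 0) from
the *applied* calibration (fixed k/b or fitted from a standards CSV).
With `correct_oil_decay=True` (default) the applied calibration should be
in true-signal units; with the raw-echo convention the standards must
carry the same TE bias, which the calibration then absorbs — both
configurations are exercised in the tests.

## What the synthetic data does and does not show

The generator reproduces the *statistical* structure of field
populations: Gaussian class OCR/weight distributions, class proportions,
receiver noise, feeder success rates. It does not model kernel geometry,
temperature drift, B0/B1 inhomogeneity, T1 saturation, correlated
OCR–weight variation, or classification of real biological outliers
(aneuploids, moldy or broken kernels). Passing tests therefore
demonstrate that the computational chain is correct and self-consistent
under the stated statistical assumptions — not that a physical instrument
achieves these error rates. Quantities that depend on real kernels (the
per-cross accuracies against manual inspection, instrument throughput)
enter only as fixed count arithmetic, which the package reproduces
exactly from the counts.

## Problem sizes

Default test and acceptance runs use the field-scale population
(n = 1260), 100-seed Monte-Carlo replicates for relaxometry recovery,
10⁴ kernels for model-vs-empirical rate agreement, and 10⁶ draws where a
law-of-large-numbers limit is asserted — sizes at which every Monte-Carlo
tolerance in the suite is a ≥ 3σ band.
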