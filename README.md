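# seednmr

A virtual re-implementation of the computational core of a high-throughput
time-domain NMR instrument for screening haploid maize kernels by oil
content — everything downstream of the hardware, as pure, testable Python.

## Who this is for

Doubled-haploid (DH) maize breeding needs to pick the rare haploid kernels
out of induction crosses. With a high-oil inducer line, diploid kernels
inherit the inducer's oil trait while haploids do not, so a single-kernel
oil measurement separates the classes. Benchtop spin-echo NMR measures that
oil non-destructively in seconds. This package is for people who work on or
study such screening pipelines — instrument analysts, breeders' data
scientists, method developers — and want the full signal-to-decision chain
reproducible at a desk, without a spectrometer.

## The model

A dried kernel has two proton pools with very different transverse
relaxation: oil (T2o ≈ 100 ms) and bound water (T2w ≈ 0.75 ms). The
spin-echo amplitude decays bi-exponentially,

    S(t) = S_o · exp(−t/T2o) + S_w · exp(−t/T2w),      S(0) = S_o + S_w,

with S(0) read from the FID. At echo time TE = 7.5 ms the water term is
attenuated by exp(−10) ≈ 5·10⁻⁵, so the echo isolates the oil signal
(S(TE) ≈ S_o) and S_w = S(0) − S_o. A linear calibration A = kS + b
(k ≈ 361.7 mg/V from least squares on reference standards) converts signal
to oil mass, and the oil content ratio OCR = A/m (percent, m the kernel
mass) is thresholded — OCR < 4.25 % → haploid — with per-class Gaussian
models N(E₁, σ₁), N(E₂, σ₂) giving the analytic false-negative /
false-positive rates Φ((thr−E₂)/σ₂) and 1−Φ((thr−E₁)/σ₁).

The package provides each stage as a module and as sklearn-style
estimators (`BiexponentialDecay`, `SignalMassCalibration`,
`GaussianThresholdScreen`), a synthetic-population generator with presets
for the published field populations, and a CLI that chains them.

## Worked example

```
$ seednmr screen --n 1260 --seed 7 --outdir run/
screen: n=1260 threshold=4.25% FN=0.976% FP=9.147% accuracy=94.84% -> run/
```

This generates 1260 kernels (half haploid, OCR ~ N(3.6, 0.47); half
diploid, OCR ~ N(5.5, 0.52); weights N(0.40 g, 0.049) / N(0.43 g, 0.035)),
forward-simulates an echo train per kernel, decomposes, calibrates,
computes OCR, and classifies at 4.25 %. The printed line says: 6 of 615
diploids fell below the threshold (FN = 0.98 %), 59 of 645 haploids above
it (FP = 9.15 %), for 94.84 % correct calls overall. `run/report.json`
additionally holds the fitted class Gaussians (here 3.61 ± 0.48 and
5.46 ± 0.54), the analytic error rates they imply (FN 1.22 %, FP 9.23 % —
consistent with the empirical counts), and the separability diagnostic:
the OCR class gap 1.84 exceeds the mean half-width 0.51, while the weight
gap 0.027 does not exceed its 0.042, i.e. OCR separates the classes and
weight alone cannot.

The feeder event stream works the same way:

```
$ seednmr simulate-feeder --n 9490 --seed 7
{"category": "round_corn", "n_attempts": 9490, "failures": 780, "success_rate_pct": 91.78}
```

Library use mirrors the CLI; see the module docstrings in
`src/seednmr/` and `docs/methods.md` for the full model account.

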