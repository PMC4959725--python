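"""Oil-content-ratio screening of haploid vs diploid kernels.

A kernel's oil content ratio is OCR = A/m (oil mass over total mass, in
percent). In induction crosses with a high-oil inducer line, diploid
kernels inherit the inducer's oil trait, so the OCR distributions of the
two classes separate into two Gaussians and a single threshold (4.25 %
for the ZD958 field population) classifies each kernel. This module
fits the per-class Gaussians (from labels, or unlabelled via a
two-component mixture), applies the threshold, and reports the error
probabilities both analytically (normal CDF tails) and empirically
(confusion counts).

Error-rate convention: *false negative* = a diploid called haploid,
*false positive* = a haploid called diploid, each expressed as a
percentage of its own class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture

__all__ = [
    "HAPLOID",
    "DIPLOID",
    "ClassGaussian",
    "ClassModel",
    "ScreeningReport",
    "SeparabilityResult",
    "ReplicateComparison",
    "GaussianThresholdScreen",
    "compute_ocr",
    "fit_class_gaussians",
    "fit_mixture",
    "classify",
    "model_error_rates",
    "empirical_error_rates",
    "accuracy_from_counts",
    "separability",
    "ocr_vs_oil_only",
    "compare_replicates",
    "optimal_threshold",
]

HAPLOID = "haploid"
DIPLOID = "diploid"

#: Field-test OCR threshold (percent) separating haploid from diploid.
DEFAULT_THRESHOLD_PCT = 4.25


@dataclass(frozen=True)
class ClassGaussian:
    """Gaussian summary (mean, sd) of one variable for one class."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class ClassModel:
    """Per-class Gaussians for OCR (and optionally weight) plus priors.

    Labeling convention: the haploid class has the lower OCR mean.
    """

    haploid_ocr: ClassGaussian
    diploid_ocr: ClassGaussian
    haploid_weight: ClassGaussian | None = None
    diploid_weight: ClassGaussian | None = None
    haploid_fraction: float = 0.5
    converged: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.haploid_fraction < 1:
            raise ValueError("haploid_fraction must be in (0, 1)")
        if self.haploid_ocr.mean >= self.diploid_ocr.mean:
            raise ValueError("haploid class must have the lower OCR mean")


@dataclass(frozen=True)
class ScreeningReport:
    """Threshold screening error summary (all rates in percent)."""

    threshold_pct: float
    false_negative_pct: float  # P(called haploid | diploid)
    false_positive_pct: float  # P(called diploid | haploid)
    total_error_pct: float  # additive convention FN + FP
    weighted_total_error_pct: float  # prior-weighted misclassification rate
    counts: dict | None = None  # confusion counts if empirical
    accuracy_pct: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass(frozen=True)
class SeparabilityResult:
    variable: str
    mean_difference: float
    half_width_sum: float
    separable: bool


@dataclass(frozen=True)
class ReplicateComparison:
    """Paired-replicate summary for repeatability assessment."""

    mean_diff: float
    sd_diff: float
    se: float
    t_statistic: float
    df: int
    p_value: float
    correlation: float


def compute_ocr(oil_mass_mg, mass_g):
    """Oil content ratio in percent: 100 * oil mass / total mass.

    Oil mass is given in mg and kernel mass in g; both are expressed in
    the same unit before the ratio, so OCR = oil_mass_mg / (10 * mass_g).
    """
    mass = np.asarray(mass_g, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("kernel mass must be positive")
    ocr = 100.0 * (np.asarray(oil_mass_mg, dtype=float) / 1000.0) / mass
    return float(ocr) if ocr.ndim == 0 else ocr


def _records_frame(records) -> pd.DataFrame:
    """Accept a DataFrame or a sequence of mappings/dataclass records."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([asdict(r) if hasattr(r, "__dataclass_fields__") else dict(r) for r in records])


def fit_class_gaussians(records) -> ClassModel:
    """Per-class sample mean/sd of OCR and weight from labelled kernels.

    ``records``: DataFrame (or sequence of records) with columns
    ``true_class``, ``ocr_pct`` and optionally ``mass_g``. Requires at
    least two kernels per class with non-degenerate spread.
    """
    df = _records_frame(records)
    out = {}
    for cls in (HAPLOID, DIPLOID):
        sub = df[df["true_class"] == cls]
        if len(sub) < 2:
            raise ValueError(f"need >= 2 records of class {cls!r}")
        sd = float(sub["ocr_pct"].std(ddof=1))
        if sd == 0:
            raise ValueError(f"degenerate input: zero OCR variance in class {cls!r}")
        out[cls] = {
            "ocr": ClassGaussian(float(sub["ocr_pct"].mean()), sd),
            "n": len(sub),
        }
        if "mass_g" in sub:
            wsd = float(sub["mass_g"].std(ddof=1))
            out[cls]["weight"] = ClassGaussian(float(sub["mass_g"].mean()), wsd) if wsd > 0 else None
        else:
            out[cls]["weight"] = None
    n = out[HAPLOID]["n"] + out[DIPLOID]["n"]
    return ClassModel(
        haploid_ocr=out[HAPLOID]["ocr"],
        diploid_ocr=out[DIPLOID]["ocr"],
        haploid_weight=out[HAPLOID]["weight"],
        diploid_weight=out[DIPLOID]["weight"],
        haploid_fraction=out[HAPLOID]["n"] / n,
    )


def fit_mixture(ocrs, n_components: int = 2, seed: int = 0) -> ClassModel:
    """Unlabelled two-component Gaussian mixture fit of OCR values by EM.

    The lower-mean component is reported as haploid (the inducer raises
    diploid kernel oil). Deterministic given ``seed``. A non-converged
    EM run is flagged via ``ClassModel.converged``.
    """
    x = np.asarray(ocrs, dtype=float).reshape(-1, 1)
    if x.size < 20:
        raise ValueError("need at least 20 OCR values for a mixture fit")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all OCR values identical")
    if n_components != 2:
        raise ValueError("only the two-class (haploid/diploid) mixture is supported")
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        random_state=seed,
        n_init=3,
        reg_covar=1e-10,
        max_iter=500,
    ).fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    lo, hi = int(np.argmin(means)), int(np.argmax(means))
    return ClassModel(
        haploid_ocr=ClassGaussian(float(means[lo]), float(sds[lo])),
        diploid_ocr=ClassGaussian(float(means[hi]), float(sds[hi])),
        haploid_fraction=float(weights[lo]),
        converged=bool(gm.converged_),
    )


def classify(ocr_pct, threshold_pct: float = DEFAULT_THRESHOLD_PCT):
    """Threshold rule: OCR < threshold -> haploid, OCR >= threshold -> diploid.

    The tie goes to diploid — the conservative choice when the goal is a
    clean haploid pool.
    """
    ocr = np.asarray(ocr_pct)
    labels = np.where(ocr < threshold_pct, HAPLOID, DIPLOID)
    return str(labels[()]) if labels.ndim == 0 else labels


class GaussianThresholdScreen(ClassifierMixin, BaseEstimator):
    """Threshold classifier on OCR with per-class Gaussian modelling.

    ``fit`` learns the per-class Gaussians from labelled OCR values (the
    threshold itself is a fixed parameter, as in instrument operation);
    ``predict`` applies the threshold rule. ``error_rates()`` gives the
    analytic normal-tail error probabilities of the fitted model.

    Parameters
    ----------
    threshold_pct : float
        OCR decision threshold in percent (default 4.25).

    Attributes
    ----------
    classes_ : ndarray of str
    model_ : ClassModel
    """

    def __init__(self, threshold_pct: float = DEFAULT_THRESHOLD_PCT):
        self.threshold_pct = threshold_pct

    def fit(self, X, y) -> "GaussianThresholdScreen":
        ocr = np.asarray(X, dtype=float).ravel()
        labels = np.asarray(y)
        df = pd.DataFrame({"true_class": labels, "ocr_pct": ocr})
        self.model_ = fit_class_gaussians(df)
        self.classes_ = np.array([DIPLOID, HAPLOID])
        return self

    def predict(self, X):
        return classify(np.asarray(X, dtype=float).ravel(), self.threshold_pct)

    def error_rates(self) -> ScreeningReport:
        return model_error_rates(self.model_, self.threshold_pct)


def model_error_rates(
    model: ClassModel, threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> ScreeningReport:
    """Analytic error probabilities of the threshold rule under the model.

    false_negative = 100 * Phi((thr - mu_D) / sd_D)   (diploid below thr)
    false_positive = 100 * (1 - Phi((thr - mu_H) / sd_H))  (haploid above)

    ``total_error`` is the plain sum FN + FP (the field-report
    convention); the prior-weighted misclassification probability is also
    reported since the additive convention ignores class proportions.
    """
    fn = 100.0 * stats.norm.cdf(
        (threshold_pct - model.diploid_ocr.mean) / model.diploid_ocr.sd
    )
    fp = 100.0 * stats.norm.sf(
        (threshold_pct - model.haploid_ocr.mean) / model.haploid_ocr.sd
    )
    w = model.haploid_fraction
    return ScreeningReport(
        threshold_pct=threshold_pct,
        false_negative_pct=float(fn),
        false_positive_pct=float(fp),
        total_error_pct=float(fn + fp),
        weighted_total_error_pct=float(w * fp + (1 - w) * fn),
    )


def empirical_error_rates(
    records, threshold_pct: float = DEFAULT_THRESHOLD_PCT
) -> ScreeningReport:
    """Error rates from confusion counts of labelled kernels."""
    df = _records_frame(records)
    called = classify(df["ocr_pct"].to_numpy(), threshold_pct)
    truth = df["true_class"].to_numpy()
    counts = {
        f"{a}_as_{b}": int(np.sum((truth == a) & (called == b)))
        for a in (HAPLOID, DIPLOID)
        for b in (HAPLOID, DIPLOID)
    }
    n_h = counts["haploid_as_haploid"] + counts["haploid_as_diploid"]
    n_d = counts["diploid_as_diploid"] + counts["diploid_as_haploid"]
    if n_h == 0 or n_d == 0:
        raise ValueError("both classes must be present in the records")
    fn = 100.0 * counts["diploid_as_haploid"] / n_d
    fp = 100.0 * counts["haploid_as_diploid"] / n_h
    n = n_h + n_d
    correct = counts["haploid_as_haploid"] + counts["diploid_as_diploid"]
    return ScreeningReport(
        threshold_pct=threshold_pct,
        false_negative_pct=fn,
        false_positive_pct=fp,
        total_error_pct=fn + fp,
        weighted_total_error_pct=100.0 * (n - correct) / n,
        counts=counts,
        accuracy_pct=100.0 * correct / n,
    )


def accuracy_from_counts(identified: int, true_positive: int) -> float:
    """Screening accuracy in percent, 100 * true haploids / haploids called.

    Reported to 2 decimals.
    """
    if identified <= 0:
        raise ValueError("identified count must be positive")
    if not 0 <= true_positive <= identified:
        raise ValueError("true_positive must lie in [0, identified]")
    return round(100.0 * true_positive / identified, 2)


def separability(model: ClassModel, variable: str = "ocr") -> SeparabilityResult:
    """Peak-separation diagnostic: |mean difference| vs mean half-widths.

    Two class distributions are called separable when the gap between
    their means exceeds (sd1 + sd2) / 2. OCR passes this test for the
    field population; kernel weight does not.
    """
    if variable == "ocr":
        g1, g2 = model.haploid_ocr, model.diploid_ocr
    elif variable == "weight":
        if model.haploid_weight is None or model.diploid_weight is None:
            raise ValueError("model carries no weight Gaussians")
        g1, g2 = model.haploid_weight, model.diploid_weight
    else:
        raise ValueError("variable must be 'ocr' or 'weight'")
    diff = abs(g2.mean - g1.mean)
    half_width = 0.5 * (g1.sd + g2.sd)
    return SeparabilityResult(variable, float(diff), float(half_width), bool(diff > half_width))


def ocr_vs_oil_only(records, oil_threshold_mg: float, ocr_threshold_pct: float = DEFAULT_THRESHOLD_PCT) -> dict:
    """Compare OCR-threshold screening with an oil-mass-only threshold.

    Because kernel weight varies, equal OCR classes overlap strongly in
    raw oil mass; normalising by the weighed mass is what makes the
    classes separable. Returns per-rule error rates and the haploid-pool
    contamination (fraction of the selected-haploid pool that is truly
    diploid) for both rules, plus their ratio.
    """
    df = _records_frame(records)
    truth = df["true_class"].to_numpy()
    if not (truth == HAPLOID).any() or not (truth == DIPLOID).any():
        raise ValueError("both classes must be present")

    def _rates(called):
        n_h, n_d = int((truth == HAPLOID).sum()), int((truth == DIPLOID).sum())
        fn = 100.0 * int(((truth == DIPLOID) & (called == HAPLOID)).sum()) / n_d
        fp = 100.0 * int(((truth == HAPLOID) & (called == DIPLOID)).sum()) / n_h
        pool = int((called == HAPLOID).sum())
        contam = (
            100.0 * int(((truth == DIPLOID) & (called == HAPLOID)).sum()) / pool
            if pool
            else float("nan")
        )
        return {"false_negative_pct": fn, "false_positive_pct": fp,
                "total_error_pct": fn + fp, "pool_contamination_pct": contam}

    by_ocr = _rates(classify(df["ocr_pct"].to_numpy(), ocr_threshold_pct))
    oil = df["oil_mass_mg"].to_numpy()
    by_oil = _rates(np.where(oil < oil_threshold_mg, HAPLOID, DIPLOID))
    c_ocr, c_oil = by_ocr["pool_contamination_pct"], by_oil["pool_contamination_pct"]
    return {
        "ocr_rule": by_ocr,
        "oil_only_rule": by_oil,
        "contamination_ratio_oil_over_ocr": (c_oil / c_ocr if c_ocr else float("inf")),
    }


def compare_replicates(y1, y2) -> ReplicateComparison:
    """Paired-difference summary of two replicate measurement series.

    mean/sd of d = y1 - y2, se = sd/sqrt(n), t = mean/se with df = n - 1
    (two-tailed p from the t distribution), plus Pearson correlation.
    Used to test whether a shorter acquisition changes the measured OCR.
    """
    a = np.asarray(y1, dtype=float).ravel()
    b = np.asarray(y2, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    if sd == 0:
        t_stat, p = (0.0, 1.0) if mean == 0 else (float("inf") * np.sign(mean), 0.0)
    else:
        t_stat = mean / se
        p = float(2 * stats.t.sf(abs(t_stat), df=n - 1))
    if np.std(a) == 0 or np.std(b) == 0:
        corr = 1.0 if np.allclose(a - a.mean(), b - b.mean()) else float("nan")
    else:
        corr = float(stats.pearsonr(a, b).statistic)
    return ReplicateComparison(
        mean_diff=mean, sd_diff=sd, se=float(se),
        t_statistic=float(t_stat), df=n - 1, p_value=p, correlation=corr,
    )


def optimal_threshold(
    model: ClassModel, lo: float = 0.0, hi: float = 10.0, step: float = 0.01
) -> float:
    """Grid minimiser of the additive total error FN + FP (analysis aid).

    Provided for exploration; the operational threshold is an input, not
    derived from the class model.
    """
    grid = np.arange(lo, hi + step / 2, step)
    errs = [model_error_rates(model, float(t)).total_error_pct for t in grid]
    return float(grid[int(np.argmin(errs))])
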