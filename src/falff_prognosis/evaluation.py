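"""Model-assessment statistics for LOOCV predictions.

Error is summarized by the median absolute deviation (MAD) between
predicted and actual scores; the model is compared against a zero-order
(chance) model that predicts the sample mean for everyone, using a paired
one-sided Wilcoxon signed-rank test on per-subject absolute deviations.
Explained variance is the squared Pearson correlation between predicted
and actual, with a one-sided correlation hypothesis test
(t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom). 95% confidence
intervals come from a case-resampling percentile bootstrap. The pre/post
treatment effect itself is tested with a one-sided Wilcoxon signed-rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = [
    "ModelEvaluation",
    "mad",
    "zero_order_deviations",
    "compare_to_zero_order",
    "r_squared_with_test",
    "bootstrap_ci",
    "treatment_effect_test",
    "signed_rank_test",
    "evaluate_predictions",
]


def mad(pred: np.ndarray, actual: np.ndarray) -> float:
    """Median absolute deviation between predicted and actual values.

    For an even number of subjects the midpoint (mean of the two central
    order statistics) is used.
    """
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.shape != actual.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {actual.shape}")
    if pred.size < 1:
        raise ValueError("need at least one pair")
    return float(np.median(np.abs(pred - actual)))


def zero_order_deviations(actual: np.ndarray) -> np.ndarray:
    """Per-subject absolute deviation of the actual scores from their mean.

    This is the error profile of the chance (zero-order) model that
    predicts the sample mean for every subject.
    """
    actual = np.asarray(actual, float)
    if actual.size < 2:
        raise ValueError("need at least 2 values")
    return np.abs(actual - actual.mean())


def _exact_signed_rank_p(d: np.ndarray, alternative: str) -> float:
    """Exact sign-flip permutation p-value of the signed-rank statistic.

    Average ranks are used for tied absolute differences and zeros are
    handled by the Pratt method (ranked with the rest, then held out of the
    statistic). Ranks are doubled to integers and the null distribution of
    W+ is built by dynamic programming over sign assignments — equivalent
    to full 2^m enumeration but polynomial-time.
    """
    ranks = stats.rankdata(np.abs(d))
    nonzero = d != 0
    r = np.rint(2 * ranks[nonzero]).astype(int)
    w_obs = int(r[d[nonzero] > 0].sum())
    total = int(r.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for ri in r:
        shifted = np.zeros_like(counts)
        shifted[ri:] = counts[: total + 1 - ri]
        counts = counts + shifted
    m = r.size
    if alternative == "less":
        return float(counts[: w_obs + 1].sum() / 2**m)
    if alternative == "greater":
        return float(counts[w_obs:].sum() / 2**m)
    raise ValueError(f"unknown alternative {alternative!r}")


def signed_rank_test(
    x: np.ndarray, y: np.ndarray | None = None, alternative: str = "less"
) -> float:
    """One-sided paired Wilcoxon signed-rank p-value.

    Zero differences are handled by the Pratt method (ranked, then
    dropped), which is robust to the ties that clamped predictions
    produce. For n <= 25 pairs the exact sign-flip permutation
    distribution is used (valid under ties and zeros); beyond that, the
    normal approximation with continuity and tie correction. All
    differences zero gives p = 1 with a warning (no evidence either way).
    """
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    if d.size < 5:
        raise ValueError("signed-rank test needs at least 5 pairs")
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    if d.size <= 25:
        return _exact_signed_rank_p(d, alternative)
    res = stats.wilcoxon(
        d, zero_method="pratt", alternative=alternative, correction=True, method="approx"
    )
    return float(res.pvalue)


def compare_to_zero_order(
    pred: np.ndarray, actual: np.ndarray, zero_order_of: str = "actual"
) -> float:
    """Is the model's error smaller than chance? Paired one-sided Wilcoxon.

    Per-subject absolute model deviations |pred - actual| are compared with
    the zero-order deviations; the alternative is that model deviations are
    smaller. ``zero_order_of`` selects what the chance model's mean is
    taken over: "actual" (default; a true chance model of the outcome) or
    "predicted" (deviations of the predictions from their own mean).
    """
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.shape != actual.shape:
        raise ValueError("length mismatch")
    if pred.size < 5:
        raise ValueError("need at least 5 subjects")
    model_dev = np.abs(pred - actual)
    if zero_order_of == "actual":
        chance_dev = zero_order_deviations(actual)
    elif zero_order_of == "predicted":
        chance_dev = np.abs(actual - pred.mean())
    else:
        raise ValueError("zero_order_of must be 'actual' or 'predicted'")
    return signed_rank_test(model_dev, chance_dev, alternative="less")


def r_squared_with_test(pred: np.ndarray, actual: np.ndarray) -> tuple[float, float]:
    """Squared Pearson correlation and one-sided p (positive correlation).

    A constant vector leaves the correlation undefined; it is reported as
    R^2 = 0 with p = 1 and a warning.
    """
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    if pred.size != actual.size or pred.size < 3:
        raise ValueError("need matched vectors of length >= 3")
    if pred.std() == 0 or actual.std() == 0:
        warnings.warn("constant vector: correlation undefined, reporting R^2 = 0, p = 1")
        return 0.0, 1.0
    res = stats.pearsonr(pred, actual, alternative="greater")
    return float(res.statistic**2), float(res.pvalue)


def bootstrap_ci(
    metric,
    pred: np.ndarray,
    actual: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float]:
    """Case-resampling percentile bootstrap interval for a paired metric.

    ``metric(pred, actual)`` is evaluated on ``n_boot`` seeded resamples of
    subject indices; the (2.5th, 97.5th) percentiles bound the default 95%
    interval. Replicates on which the metric is undefined (e.g. a constant
    resample for a correlation) are skipped; more than 20% degenerate
    replicates is an error.
    """
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    n = pred.size
    if n < 5:
        raise ValueError("bootstrap needs at least 5 subjects")
    rng = np.random.default_rng(seed)
    values = []
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                v = metric(pred[idx], actual[idx])
            except (ValueError, ZeroDivisionError):
                degenerate += 1
                continue
        v = v[0] if isinstance(v, tuple) else v
        if not np.isfinite(v):
            degenerate += 1
            continue
        values.append(v)
    if degenerate > 0.2 * n_boot:
        raise RuntimeError(
            f"{degenerate}/{n_boot} bootstrap replicates were degenerate; "
            "the metric is unstable at this sample size"
        )
    lo, hi = np.percentile(values, [100 * (1 - ci) / 2, 100 * (1 + ci) / 2])
    return float(lo), float(hi)


def treatment_effect_test(pre: np.ndarray, post: np.ndarray) -> float:
    """One-sided Wilcoxon signed-rank: did scores improve over treatment?

    Alternative: post > pre. All-zero differences give p = 1 with a warning.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape:
        raise ValueError("pre/post length mismatch")
    return signed_rank_test(post, pre, alternative="greater")


def _r2_strict(pred: np.ndarray, actual: np.ndarray) -> float:
    """Squared Pearson r that raises on constant input (for bootstrap skipping)."""
    if np.std(pred) == 0 or np.std(actual) == 0:
        raise ValueError("constant resample: correlation undefined")
    return float(stats.pearsonr(pred, actual).statistic ** 2)


@dataclass
class ModelEvaluation:
    """Full assessment of one model's LOOCV predictions."""

    n: int
    mad: float
    mad_ci95: tuple[float, float]
    wilcoxon_p_vs_zero_order: float
    r_squared: float
    r_squared_ci95: tuple[float, float]
    correlation_test_p: float

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_predictions(
    pred: np.ndarray,
    actual: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> ModelEvaluation:
    """Compute MAD, chance comparison, R^2 and bootstrap CIs in one report."""
    pred = np.asarray(pred, float)
    actual = np.asarray(actual, float)
    r2, r2_p = r_squared_with_test(pred, actual)
    return ModelEvaluation(
        n=int(pred.size),
        mad=mad(pred, actual),
        mad_ci95=bootstrap_ci(mad, pred, actual, n_boot=n_boot, seed=seed),
        wilcoxon_p_vs_zero_order=compare_to_zero_order(pred, actual),
        r_squared=r2,
        r_squared_ci95=bootstrap_ci(_r2_strict, pred, actual, n_boot=n_boot, seed=seed + 1),
        correlation_test_p=r2_p,
    )
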