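"""Evaluation statistics for predictive uncertainty under distribution shift.

Implements the full metric stack for comparing a model's development (IID)
behaviour with its production (OOD) behaviour:

* per-sample confidence (max softmax probability) and Shannon entropy (nats);
* micro-F1 (single-label multiclass: the fraction correct; samples whose true
  class was never in the training label set are necessarily incorrect);
* expected calibration error (ECE) over equal-width confidence bins, plus the
  per-sample absolute calibration error against the sample's bin accuracy;
* the F1-retention curve (most-uncertain predictions successively *replaced*
  by ground truth) and its area, F1-AUC;
* the F1-uncertainty curve (most-uncertain predictions successively
  *discarded*), in development and production flavours;
* ADP — the area between the development and production curves: the mean,
  over a grid of nominal development F1 targets, of the percentage-point F1
  drop when each target's development uncertainty threshold is transferred to
  production — with a percentile bootstrap confidence interval;
* the relative percent decrease used for top-vs-bottom model comparisons.

Uncertainty ordering conventions: curves sort by *descending* uncertainty and
break ties by stable original row order; a prediction is accepted at threshold
``u`` iff its uncertainty is ``<= u``, so a development sample sitting exactly
at its own threshold is retained and the development curve is self-consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tables import PredictionTable

__all__ = [
    "confidence",
    "shannon_entropy",
    "micro_f1",
    "uncertainty_scores",
    "ECEResult",
    "ece",
    "samplewise_calibration_error",
    "RetentionCurve",
    "f1_retention_curve",
    "F1UncertaintyCurve",
    "f1_uncertainty_curve",
    "ADPResult",
    "adp",
    "adp_bootstrap_ci",
    "percent_decrease",
]

DEFAULT_F1_MIN = 0.975
DEFAULT_F1_MAX = 0.990
DEFAULT_GRID_STEP = 1e-5


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2:
        raise ValueError("probs must be a 2-D (n, K) matrix")
    if np.any(probs < 0):
        raise ValueError("negative probability entries")
    if np.max(np.abs(probs.sum(axis=1) - 1.0)) > 1e-6:
        raise ValueError("rows are not stochastic (sums differ from 1 beyond 1e-6)")
    return probs


def confidence(probs: np.ndarray) -> np.ndarray:
    """Confidence score per sample: the largest softmax element, in [0, 1]."""
    return _check_probs(probs).max(axis=1)


def shannon_entropy(probs: np.ndarray) -> np.ndarray:
    """Shannon entropy per sample in nats, with 0·log 0 := 0.

    Zero for a one-hot row; ln K for the uniform row over K classes.
    """
    probs = _check_probs(probs)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(probs > 0.0, probs * np.log(probs), 0.0)
    return -t.sum(axis=1)


def micro_f1(predicted_label, true_label) -> float:
    """Micro-averaged F1 for single-label multiclass: the fraction correct.

    Samples whose true label never appears among the predictable classes
    (unseen classes) simply never match and count as errors.
    """
    pred = np.asarray(predicted_label, dtype=object)
    true = np.asarray(true_label, dtype=object)
    if pred.shape != true.shape:
        raise ValueError("predicted and true label lists differ in length")
    if pred.size == 0:
        raise ValueError("micro_f1 of an empty prediction set is undefined")
    return float(np.mean(pred == true))


def uncertainty_scores(table: PredictionTable, statistic: str = "entropy") -> np.ndarray:
    """Per-sample uncertainty used for sorting/thresholding.

    ``entropy`` (default) uses Shannon entropy; ``confidence`` uses
    1 - confidence so that larger always means more uncertain.
    """
    if statistic == "entropy":
        return np.asarray(table.entropy, dtype=float)
    if statistic == "confidence":
        return 1.0 - np.asarray(table.confidence, dtype=float)
    raise ValueError(f"unknown uncertainty statistic {statistic!r}")


# ---------------------------------------------------------------------------
# Calibration


@dataclass
class ECEResult:
    """Expected calibration error over M equal-width confidence bins.

    ``ece = Σ_m (|B_m|/n) · |acc(B_m) − conf(B_m)|`` where acc and conf are a
    bin's accuracy and mean confidence. Empty bins carry NaN acc/conf and
    weight zero.
    """

    m_bins: int
    counts: np.ndarray
    accuracy: np.ndarray
    mean_confidence: np.ndarray
    ece: float
    bin_edges: np.ndarray = field(repr=False)


def _bin_index(conf: np.ndarray, m_bins: int) -> np.ndarray:
    # equal-width bins on [0, 1]; confidence 1.0 falls in the last bin
    return np.minimum((conf * m_bins).astype(int), m_bins - 1)


def ece(conf: np.ndarray, correct: np.ndarray, m_bins: int = 10) -> ECEResult:
    """Expected calibration error of confidence scores against correctness."""
    conf = np.asarray(conf, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if m_bins < 1:
        raise ValueError("m_bins must be >= 1")
    if conf.shape != correct.shape:
        raise ValueError("confidence/correct length mismatch")
    if conf.size == 0:
        raise ValueError("ece of an empty table is undefined")
    if np.any((conf < 0) | (conf > 1)):
        raise ValueError("confidences must lie in [0, 1]")
    idx = _bin_index(conf, m_bins)
    counts = np.bincount(idx, minlength=m_bins)
    acc = np.full(m_bins, np.nan)
    mean_conf = np.full(m_bins, np.nan)
    occupied = counts > 0
    acc[occupied] = np.bincount(idx, weights=correct, minlength=m_bins)[occupied] / counts[occupied]
    mean_conf[occupied] = np.bincount(idx, weights=conf, minlength=m_bins)[occupied] / counts[occupied]
    n = conf.size
    value = float(
        np.sum(counts[occupied] / n * np.abs(acc[occupied] - mean_conf[occupied]))
    )
    return ECEResult(
        m_bins=m_bins,
        counts=counts,
        accuracy=acc,
        mean_confidence=mean_conf,
        ece=value,
        bin_edges=np.linspace(0.0, 1.0, m_bins + 1),
    )


def samplewise_calibration_error(table: PredictionTable, m_bins: int = 10) -> np.ndarray:
    """Absolute calibration error of individual samples.

    Each sample is assigned the ECE bin of its confidence and scored
    ``|conf_i − acc(B_m(i))|``: the gap between its own confidence and its
    bin's empirical accuracy. The count-weighted bin means of these values
    recover the ECE summands whenever a bin's confidences all sit on one side
    of its accuracy (the typical overconfident regime).
    """
    res = ece(table.confidence, table.correct, m_bins)
    idx = _bin_index(np.asarray(table.confidence, dtype=float), m_bins)
    return np.abs(np.asarray(table.confidence, dtype=float) - res.accuracy[idx])


# ---------------------------------------------------------------------------
# F1-retention (replacement) curve


@dataclass
class RetentionCurve:
    """F1 versus retained fraction as most-uncertain predictions are replaced
    by ground truth; ends at (0, 1). `auc` is the trapezoidal area over the
    retention fraction."""

    retention: np.ndarray
    f1: np.ndarray
    auc: float


def _sort_desc_stable(uncertainty: np.ndarray) -> np.ndarray:
    # descending uncertainty, ties broken by original row order
    return np.argsort(-np.asarray(uncertainty, dtype=float), kind="stable")


def f1_retention_curve(
    table: PredictionTable, uncertainty: np.ndarray | None = None
) -> RetentionCurve:
    """Sweep replacing the most-uncertain predictions with ground truth.

    Starting from full retention, each step records (retention fraction, F1 of
    the current prediction set) and then replaces the next most-uncertain
    prediction's label with the truth, so F1 is non-decreasing as retention
    falls. The terminal point (0, 1) is appended before integration.
    """
    if uncertainty is None:
        uncertainty = table.entropy
    uncertainty = np.asarray(uncertainty, dtype=float)
    n = table.n
    if uncertainty.shape[0] != n:
        raise ValueError("uncertainty length does not match table")
    order = _sort_desc_stable(uncertainty)
    correct = table.correct[order]
    base_correct = int(correct.sum())
    # after i replacements, every replaced prediction counts as correct
    wrong_replaced = np.concatenate([[0], np.cumsum(~correct)[:-1]])
    f1_vals = (base_correct + wrong_replaced) / n
    retention = (n - np.arange(n)) / n
    retention = np.concatenate([retention, [0.0]])
    f1_vals = np.concatenate([f1_vals, [1.0]])
    auc = float(np.trapezoid(f1_vals[::-1], retention[::-1]))
    return RetentionCurve(retention=retention, f1=f1_vals, auc=auc)


# ---------------------------------------------------------------------------
# F1-uncertainty (discard) curve


@dataclass
class F1UncertaintyCurve:
    """F1 of the retained set versus the uncertainty threshold as the
    most-uncertain predictions are successively discarded (not replaced).

    Point ``i`` records the i-th most-uncertain sample's uncertainty as the
    threshold and the F1 over the set still retained *including* that sample;
    the empty terminal set is excluded. Thresholds are non-increasing and
    ``n_retained`` decreases by one per step.
    """

    thresholds: np.ndarray
    f1: np.ndarray
    n_retained: np.ndarray
    flavour: str = "development"

    def max_f1(self) -> float:
        return float(self.f1.max())

    def retained_at(self, threshold: float) -> int:
        """Number of curve samples with uncertainty <= threshold."""
        first = int(np.searchsorted(-self.thresholds, -threshold, side="left"))
        return int(self.thresholds.size - first)


def f1_uncertainty_curve(
    table: PredictionTable,
    uncertainty: np.ndarray | None = None,
    flavour: str = "development",
) -> F1UncertaintyCurve:
    if flavour not in ("development", "production"):
        raise ValueError(f"unknown flavour {flavour!r}")
    if uncertainty is None:
        uncertainty = table.entropy
    uncertainty = np.asarray(uncertainty, dtype=float)
    n = table.n
    if uncertainty.shape[0] != n:
        raise ValueError("uncertainty length does not match table")
    if n < 2:
        raise ValueError("need at least two samples for a discard curve")
    order = _sort_desc_stable(uncertainty)
    u_sorted = uncertainty[order]
    correct = table.correct[order]
    # suffix sums: retained set at step i is samples i..n-1
    suffix_correct = np.cumsum(correct[::-1])[::-1]
    n_retained = n - np.arange(n)
    f1_vals = suffix_correct / n_retained
    return F1UncertaintyCurve(
        thresholds=u_sorted,
        f1=f1_vals,
        n_retained=n_retained,
        flavour=flavour,
    )


# ---------------------------------------------------------------------------
# ADP


@dataclass
class ADPResult:
    """Mean percentage-point F1 decrease from development to production over a
    nominal-F1 grid; the area between the two F1-uncertainty curves.

    For each nominal target ``F1_nom`` on the grid, ``u_accept`` is the most
    permissive (largest) development threshold whose development F1 meets the
    target; ``f1_prod`` is the micro-F1 of the production samples accepted at
    that threshold; ``decrease = (F1_nom − f1_prod) × 100`` percentage points,
    and ``adp`` is the arithmetic mean of the decreases.
    """

    f1_min: float
    f1_max: float
    step: float
    f1_nominal: np.ndarray
    u_accept: np.ndarray
    f1_prod: np.ndarray
    decrease: np.ndarray
    adp: float
    ci: tuple[float, float] | None = None


def _nominal_grid(f1_min: float, f1_max: float, step: float) -> np.ndarray:
    if not (0 < f1_min < f1_max <= 1):
        raise ValueError("need 0 < f1_min < f1_max <= 1")
    n_points = int(round((f1_max - f1_min) / step)) + 1
    return np.linspace(f1_min, f1_max, n_points)


def _u_accept_lookup(dev: F1UncertaintyCurve, grid: np.ndarray, f1_max: float):
    """Largest dev threshold with dev F1 >= target, vectorised over the grid."""
    if dev.max_f1() < f1_max:
        raise ValueError(
            f"development curve never attains F1 >= {f1_max}: the development "
            "sample size is not sufficiently large to support the nominal range "
            "(first ADP range check)"
        )
    order = np.argsort(-dev.f1, kind="stable")
    f1_sorted = dev.f1[order]  # descending F1
    thr_running_max = np.maximum.accumulate(dev.thresholds[order])
    # for target f: points with F1 >= f form a prefix of f1_sorted
    pos = np.searchsorted(-f1_sorted, -grid, side="right")  # count of F1 >= f
    if np.any(pos == 0):
        raise ValueError("no development curve point meets the smallest target")
    return thr_running_max[pos - 1]


def _prod_f1_at_thresholds(prod: F1UncertaintyCurve, u_accept: np.ndarray) -> np.ndarray:
    """F1 of the production samples accepted (uncertainty <= u) per threshold.

    The accepted set at any threshold is exactly a suffix of the production
    discard order, so its F1 is a recorded curve point.
    """
    # prod.thresholds is non-increasing; find first index with threshold <= u
    first = np.searchsorted(-prod.thresholds, -np.asarray(u_accept), side="left")
    if np.any(first >= prod.thresholds.size):
        bad = int(np.flatnonzero(first >= prod.thresholds.size)[0])
        raise ValueError(
            f"empty production retained set at grid point {bad} "
            f"(u_accept={np.asarray(u_accept)[bad]!r}): decrease is undefined"
        )
    return prod.f1[first]


def adp(
    dev: F1UncertaintyCurve,
    prod: F1UncertaintyCurve,
    f1_min: float = DEFAULT_F1_MIN,
    f1_max: float = DEFAULT_F1_MAX,
    step: float = DEFAULT_GRID_STEP,
) -> ADPResult:
    """Area between the development and production F1-uncertainty curves.

    Interpreted as the expected percentage-point accuracy loss when a model is
    moved from development to production under uncertainty thresholding. The
    development curve must attain ``f1_max`` somewhere; both curves must use
    uncertainties on the same scale.
    """
    grid = _nominal_grid(f1_min, f1_max, step)
    u_accept = _u_accept_lookup(dev, grid, f1_max)
    f1_prod = _prod_f1_at_thresholds(prod, u_accept)
    decrease = (grid - f1_prod) * 100.0
    return ADPResult(
        f1_min=f1_min,
        f1_max=f1_max,
        step=step,
        f1_nominal=grid,
        u_accept=u_accept,
        f1_prod=f1_prod,
        decrease=decrease,
        adp=float(decrease.mean()),
    )


def adp_bootstrap_ci(
    dev_table: PredictionTable,
    prod_table: PredictionTable,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    uncertainty: str = "entropy",
    f1_min: float = DEFAULT_F1_MIN,
    f1_max: float = DEFAULT_F1_MAX,
    step: float = DEFAULT_GRID_STEP,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap CI for ADP: production rows resampled with
    replacement against the fixed development curve.

    Degenerate resamples whose true labels collapse to a single class are
    redrawn (up to `max_redraws` extra draws in total, then a warning).
    """
    if n_boot < 100:
        raise ValueError("need at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    dev_u = uncertainty_scores(dev_table, uncertainty)
    dev_curve = f1_uncertainty_curve(dev_table, dev_u, flavour="development")
    grid = _nominal_grid(f1_min, f1_max, step)
    u_accept = _u_accept_lookup(dev_curve, grid, f1_max)

    prod_u = uncertainty_scores(prod_table, uncertainty)
    prod_correct = prod_table.correct
    prod_true = np.asarray(prod_table.true_label, dtype=object)
    order = _sort_desc_stable(prod_u)
    u_sorted = prod_u[order]
    correct_sorted = prod_correct[order].astype(float)
    true_sorted = prod_true[order]
    n = u_sorted.size
    # index of the first accepted (suffix start) per grid threshold
    first = np.searchsorted(-u_sorted, -u_accept, side="left")
    if np.any(first >= n):
        raise ValueError("empty production retained set at some grid point")

    values = np.empty(n_boot)
    redraws = 0
    b = 0
    while b < n_boot:
        counts = rng.multinomial(n, np.full(n, 1.0 / n))
        if len(set(true_sorted[counts > 0])) < 2:
            redraws += 1
            if redraws > max_redraws:
                warnings.warn(
                    "bootstrap redraw cap reached for degenerate single-class "
                    "resamples; keeping the degenerate draw",
                    stacklevel=2,
                )
            else:
                continue
        suffix_total = np.cumsum(counts[::-1])[::-1]
        suffix_correct = np.cumsum((counts * correct_sorted)[::-1])[::-1]
        retained = suffix_total[first]
        if np.any(retained == 0):
            # resample emptied an accepted set: redraw like a degenerate draw
            redraws += 1
            if redraws <= max_redraws:
                continue
            raise ValueError("bootstrap resample emptied a production retained set")
        f1_prod = suffix_correct[first] / retained
        values[b] = np.mean((grid - f1_prod) * 100.0)
        b += 1
    low, high = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


# ---------------------------------------------------------------------------
# Inter-model comparison


def percent_decrease(top: float, bottom: float, direction: str) -> float:
    """Relative percent decrease between the top and bottom ranking models.

    The reference is the worse value for lower-is-better metrics (e.g. ADP)
    and the better value for higher-is-better metrics (e.g. F1-AUC); the
    result is the gap as a percentage of that reference.
    """
    if direction == "lower_is_better":
        reference, other = bottom, top
    elif direction == "higher_is_better":
        reference, other = top, bottom
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if reference == 0:
        raise ValueError("zero reference value")
    return (reference - other) / reference * 100.0
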