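"""Cohort-level diagnostics for digital vesicle counts.

Healthy and cancer plasma give two well-separated steady-state levels of
retained (post-wash) vesicle counts per assay; a single count cutoff then
classifies samples.  This module provides the confusion-matrix metrics, the
swept-cutoff ROC curve with trapezoidal AUC, a one-proportion z-test,
Pearson correlation, the caliper tumor-volume formula V = L*W^2/2, and the
saturating power law

    count = amplitude * |volume - offset|^exponent + baseline

that captures how post-wash counts rise steeply for small tumors and
plateau as tumor volume grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError, ValidationError

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "ProportionTest",
    "PowerLawModel",
    "PowerLawFit",
    "TumorMeasurement",
    "confusion_at_cutoff",
    "sensitivity",
    "specificity",
    "fpr",
    "roc_auc",
    "proportion_z_test",
    "pearson_r",
    "tumor_volume",
    "powerlaw_eval",
    "powerlaw_fit",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_at_cutoff(
    counts: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    cutoff: float,
    positive_strict: bool = True,
) -> ConfusionCounts:
    """Classify samples as positive when ``count > cutoff`` (strict by default).

    ``labels`` are binary: 1/True = disease (positive class), 0/False = healthy.
    """
    c = np.asarray(counts, dtype=float)
    y = np.asarray(labels).astype(bool)
    if c.size == 0:
        raise ValidationError("empty cohort")
    if c.shape != y.shape:
        raise ValidationError("counts and labels must have equal length")
    called = c > cutoff if positive_strict else c >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(called & y)),
        fp=int(np.sum(called & ~y)),
        tn=int(np.sum(~called & ~y)),
        fn=int(np.sum(~called & y)),
    )


def _ratio_pct(num: int, den: int, name: str) -> float:
    if den == 0:
        import warnings

        warnings.warn(f"{name}: zero denominator, result undefined", stacklevel=3)
        return float("nan")
    return 100.0 * num / den


def sensitivity(cc: ConfusionCounts) -> float:
    """True positive rate TP/(TP+FN), in percent."""
    return _ratio_pct(cc.tp, cc.tp + cc.fn, "sensitivity")


def specificity(cc: ConfusionCounts) -> float:
    """True negative rate TN/(TN+FP), in percent."""
    return _ratio_pct(cc.tn, cc.tn + cc.fp, "specificity")


def fpr(cc: ConfusionCounts) -> float:
    """False positive rate FP/(FP+TN), as a fraction in [0, 1]."""
    pct = _ratio_pct(cc.fp, cc.fp + cc.tn, "fpr")
    return pct / 100.0


@dataclass
class RocCurve:
    """Swept-cutoff ROC: TPR/FPR at each cutoff, plus trapezoidal AUC."""

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"cutoff": self.cutoffs, "tpr": self.tpr, "fpr": self.fpr})


def roc_auc(
    counts: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    cutoff_start: float = 2.0,
    cutoff_stop: float = 1682.0,
    step: float = 2.0,
) -> RocCurve:
    """ROC curve by sweeping the count cutoff over a fixed grid.

    The cutoff runs from ``cutoff_start`` to ``cutoff_stop`` inclusive in
    increments of ``step`` (default 2..1682 step 2).  TPR and FPR are
    computed at each cutoff with a strict ``count > cutoff`` positive call;
    the AUC integrates the (FPR, TPR) points trapezoidally with (0,0) and
    (1,1) endpoints appended.
    """
    c = np.asarray(counts, dtype=float)
    y = np.asarray(labels).astype(bool)
    if c.shape != y.shape or c.size == 0:
        raise ValidationError("counts and labels must be equal-length and non-empty")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes present")

    cutoffs = np.arange(cutoff_start, cutoff_stop + 0.5 * step, step)
    # vectorized sweep: called[i, j] = count_j > cutoff_i
    called = c[None, :] > cutoffs[:, None]
    tpr = (called & y).sum(axis=1) / n_pos
    fp = (called & ~y).sum(axis=1) / n_neg

    xs = np.concatenate([[0.0], fp[::-1], [1.0]])
    ys = np.concatenate([[0.0], tpr[::-1], [1.0]])
    order = np.lexsort((ys, xs))
    auc = float(np.trapezoid(ys[order], xs[order]))
    return RocCurve(cutoffs=cutoffs, tpr=tpr, fpr=fp, auc=auc)


@dataclass(frozen=True)
class ProportionTest:
    p: float
    p0: float
    n: int
    z: float
    p_value: float


def proportion_z_test(p: float, p0: float, n: int) -> ProportionTest:
    """One-proportion z-test: z = (p - p0) / sqrt(p0 (1 - p0) / n).

    The p-value is two-sided from the standard normal.
    """
    if not 0 < p0 < 1:
        raise ValidationError("null proportion p0 must lie strictly in (0, 1)")
    if not 0 <= p <= 1:
        raise ValidationError("sample proportion must lie in [0, 1]")
    if n < 1:
        raise ValidationError("sample size must be >= 1")
    z = (p - p0) / np.sqrt(p0 * (1.0 - p0) / n)
    p_value = 2.0 * stats.norm.sf(abs(z))
    return ProportionTest(p=p, p0=p0, n=int(n), z=float(z), p_value=float(p_value))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided p-value (t transform)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 3 or xa.shape != ya.shape:
        raise ValidationError("need >= 3 paired values")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValidationError("zero variance in input")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TumorMeasurement:
    """Caliper measurement; volume by the ellipsoid rule V = L * W^2 / 2."""

    length_mm: float
    width_mm: float

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.length_mm < self.width_mm:
            raise ValidationError("require length >= width > 0 (caliper convention)")

    @property
    def volume_mm3(self) -> float:
        return tumor_volume(self.length_mm, self.width_mm)


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """V = 1/2 * length * width^2, in mm^3."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValidationError("caliper dimensions must be positive")
    return 0.5 * length_mm * width_mm**2


@dataclass(frozen=True)
class PowerLawModel:
    """Saturating power law: count = amplitude*|x - offset_x|^exponent + baseline.

    Defaults are the coefficients fitted for post-wash vesicle counts versus
    xenograft tumor volume x (mm^3).  ``offset_x`` is numerically tiny
    (3.48e-7 mm^3) and held fixed during fitting: at measurable tumor sizes
    it is irrelevant, and it is jointly unidentifiable with the exponent.
    """

    amplitude: float = 101.7
    offset_x: float = 3.48e-7
    exponent: float = 0.12013
    baseline: float = 5.42

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValidationError("amplitude must be positive")
        if not 0 < self.exponent < 1:
            raise ValidationError("exponent must lie in (0, 1)")


def powerlaw_eval(x: float | np.ndarray, model: PowerLawModel | None = None) -> float | np.ndarray:
    """Evaluate the power law at tumor volume(s) x (mm^3)."""
    model = model or PowerLawModel()
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ValidationError("tumor volume must be non-negative")
    y = model.amplitude * np.abs(xa - model.offset_x) ** model.exponent + model.baseline
    return float(y) if np.isscalar(x) else y


@dataclass(frozen=True)
class PowerLawFit:
    model: PowerLawModel
    residual_sd: float
    converged: bool
    degenerate: bool
    n: int


def powerlaw_fit(
    tumor_sizes_mm3: Sequence[float],
    counts: Sequence[float],
    init: PowerLawModel | None = None,
    max_restarts: int = 5,
    seed: int = 0,
) -> PowerLawFit:
    """Nonlinear least squares for (amplitude, exponent, baseline).

    ``offset_x`` stays fixed at the initializer's value.  Requires at least
    6 points spanning at least one decade of tumor volume.  On repeated
    non-convergence a :class:`FitError` carrying the best-so-far fit is
    raised; an exponent pinned at the lower bound (flat data) is returned
    with ``degenerate=True``.
    """
    init = init or PowerLawModel()
    x = np.asarray(tumor_sizes_mm3, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.size < 6 or x.shape != y.shape:
        raise ValidationError("need >= 6 (tumor size, count) pairs")
    pos = x[x > 0]
    if pos.size < 2 or pos.max() / pos.min() < 10.0:
        raise ValidationError("tumor sizes must span at least one decade")

    eps = 1e-6

    def f(xv, amplitude, exponent, baseline):
        return amplitude * np.abs(xv - init.offset_x) ** exponent + baseline

    rng = np.random.default_rng(seed)
    p0 = np.array([init.amplitude, init.exponent, init.baseline])
    bounds = ([eps, eps, 0.0], [np.inf, 1.0 - eps, np.inf])
    best = None
    best_cost = np.inf
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 2.0, size=3)
        start = np.clip(start, [eps, 2 * eps, 0.0], [np.inf, 1 - 2 * eps, np.inf])
        try:
            popt, _ = optimize.curve_fit(f, x, y, p0=start, bounds=bounds, maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        cost = float(np.sum((f(x, *popt) - y) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        raise FitError("power-law fit did not converge after restarts")

    amplitude, exponent, baseline = (float(v) for v in best)
    degenerate = exponent <= 10 * eps
    if degenerate:
        exponent = 10 * eps  # keep within the model's (0, 1) invariant
    model = replace(init, amplitude=amplitude, exponent=exponent, baseline=baseline)
    resid = f(x, *best) - y
    dof = max(x.size - 3, 1)
    return PowerLawFit(
        model=model,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        converged=True,
        degenerate=bool(degenerate),
        n=int(x.size),
    )
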