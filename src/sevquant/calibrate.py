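"""Contrast-to-size calibration for label-free plasmonic particle imaging.

A particle near the plasmonic surface raises the local refractive index,
red-shifting the resonance and increasing transmitted light; the resulting
ratio-image contrast (in percent above the particle-free level) grows
monotonically with particle size.  The conversion is an empirical quadratic

    size_nm = a2 * x**2 + a1 * x + a0,        x = contrast in %,

calibrated against a reference size distribution from nanoparticle tracking
analysis.  The default coefficients are (0.1531, 7.096, 20.211), the values
obtained for small extracellular vesicles; they place the 18 %
"sEV-like" contrast cutoff at ~197.5 nm, i.e. the ~200 nm upper exosome size.

Because individual particles cannot be paired between the two instruments,
`fit_calibration` matches the two distributions quantile-by-quantile and
fits the quadratic through the matched quantiles by least squares.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FitError, ValidationError

__all__ = [
    "Calibration",
    "SizeDistribution",
    "CalibrationFit",
    "size_from_contrast",
    "contrast_from_size",
    "fit_calibration",
    "size_distribution",
]

#: Default quadratic coefficients (nm/%^2, nm/%, nm).
DEFAULT_A2 = 0.1531
DEFAULT_A1 = 7.096
DEFAULT_A0 = 20.211


@dataclass(frozen=True)
class Calibration:
    """Quadratic contrast(%) -> size(nm) conversion.

    Attributes
    ----------
    a2, a1, a0 : float
        Quadratic, linear and constant coefficients (nm/%^2, nm/%, nm).
    valid_contrast_range : (float, float)
        Contrast range (%) over which the calibration was established;
        conversions outside it are flagged as extrapolated, not rejected.
    """

    a2: float = DEFAULT_A2
    a1: float = DEFAULT_A1
    a0: float = DEFAULT_A0
    valid_contrast_range: tuple[float, float] = (1.5, 40.0)

    def __post_init__(self) -> None:
        lo, hi = self.valid_contrast_range
        if not lo < hi:
            raise ValidationError("valid_contrast_range must be increasing")
        # strict monotonicity of the quadratic over the valid range
        for x in (lo, hi):
            if self.a1 + 2.0 * self.a2 * x <= 0:
                raise ValidationError(
                    "calibration is not strictly increasing over "
                    f"[{lo}, {hi}] % (derivative non-positive at {x} %)"
                )

    def in_range(self, contrast_pct: float | np.ndarray) -> np.ndarray:
        lo, hi = self.valid_contrast_range
        x = np.asarray(contrast_pct, dtype=float)
        return (x >= lo) & (x <= hi)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": "sevquant.calibration/1",
            "a2": self.a2,
            "a1": self.a1,
            "a0": self.a0,
            "valid_contrast_range": list(self.valid_contrast_range),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Calibration":
        payload = json.loads(Path(path).read_text())
        try:
            return cls(
                a2=float(payload["a2"]),
                a1=float(payload["a1"]),
                a0=float(payload["a0"]),
                valid_contrast_range=tuple(payload["valid_contrast_range"]),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValidationError(f"calibration file missing field {exc}") from exc


@dataclass
class SizeDistribution:
    """A collection of particle sizes (nm), raw or binned.

    Either ``sizes`` (per-particle list) or ``bin_edges``/``counts``
    (histogram) must be provided; both may be present.
    """

    sizes: np.ndarray | None = None
    bin_edges: np.ndarray | None = None
    counts: np.ndarray | None = None
    source: str = "panorama"  # or "reference_tracking"
    extrapolated: np.ndarray | None = None  # per-size flag, panorama only

    def __post_init__(self) -> None:
        if self.sizes is not None:
            self.sizes = np.asarray(self.sizes, dtype=float)
            if self.sizes.size and np.any(self.sizes <= 0):
                raise ValidationError("sizes must be positive")
        if (self.bin_edges is None) != (self.counts is None):
            raise ValidationError("bin_edges and counts must be given together")
        if self.sizes is None and self.bin_edges is None:
            raise ValidationError("need per-particle sizes or a histogram")

    @property
    def n(self) -> int:
        if self.sizes is not None:
            return int(self.sizes.size)
        return int(np.sum(self.counts))

    def expand(self) -> np.ndarray:
        """Per-particle sizes; histogram bins expand to their centers."""
        if self.sizes is not None:
            return self.sizes
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return np.repeat(centers, np.asarray(self.counts, dtype=int))

    @property
    def mean(self) -> float:
        return float(np.mean(self.expand())) if self.n else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.expand(), ddof=1)) if self.n > 1 else float("nan")

    @property
    def min(self) -> float:
        return float(np.min(self.expand())) if self.n else float("nan")

    @classmethod
    def from_csv(cls, path: str | Path, source: str = "reference_tracking") -> "SizeDistribution":
        """Read a tracking-analysis export: columns ``size_nm[, count]``."""
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        if "size_nm" not in df.columns:
            raise ValidationError("size CSV must have a 'size_nm' column")
        if "count" in df.columns:
            sizes = np.repeat(df["size_nm"].to_numpy(float), df["count"].to_numpy(int))
        else:
            sizes = df["size_nm"].to_numpy(float)
        return cls(sizes=sizes, source=source)


def size_from_contrast(
    contrast_pct: float | np.ndarray, cal: Calibration | None = None
) -> float | np.ndarray:
    """Convert ratio-image contrast (%) to particle size (nm).

    Negative contrasts are physically meaningless and rejected.  Values
    outside ``cal.valid_contrast_range`` are converted anyway (the quadratic
    extrapolates smoothly) — callers flag them via :meth:`Calibration.in_range`.
    """
    cal = cal or Calibration()
    x = np.asarray(contrast_pct, dtype=float)
    if np.any(x < 0):
        raise ValidationError("contrast must be non-negative")
    y = cal.a2 * x**2 + cal.a1 * x + cal.a0
    return float(y) if np.isscalar(contrast_pct) else y


def contrast_from_size(
    size_nm: float | np.ndarray, cal: Calibration | None = None
) -> float | np.ndarray:
    """Invert the calibration: positive root of a2*x^2 + a1*x + (a0 - y) = 0.

    Sizes below the constant term ``a0`` have no physical contrast and raise.
    """
    cal = cal or Calibration()
    y = np.asarray(size_nm, dtype=float)
    if np.any(y < cal.a0):
        raise ValidationError(
            f"size below calibration floor a0 = {cal.a0} nm has no physical contrast"
        )
    if cal.a2 == 0:
        x = (y - cal.a0) / cal.a1
    else:
        disc = cal.a1**2 - 4.0 * cal.a2 * (cal.a0 - y)
        x = (-cal.a1 + np.sqrt(disc)) / (2.0 * cal.a2)
    return float(x) if np.isscalar(size_nm) else x


@dataclass(frozen=True)
class CalibrationFit:
    """Result of a quantile-matched calibration fit."""

    calibration: Calibration
    rms_quantile_residual_nm: float
    n_contrasts: int
    n_reference: int


def fit_calibration(
    contrasts: Sequence[float] | np.ndarray,
    reference: SizeDistribution,
    percentiles: np.ndarray | None = None,
) -> CalibrationFit:
    """Fit the quadratic by matching contrast quantiles to reference-size quantiles.

    Percentiles 1..99 of the observed contrast distribution are paired with
    the same percentiles of the reference size distribution and a quadratic
    is fitted through the pairs by ordinary least squares.

    Raises
    ------
    ValidationError
        Fewer than 50 values on either side, or a degenerate (constant)
        distribution.
    FitError
        The fitted quadratic is not strictly increasing over the observed
        contrast range (advice: restrict the contrast range and refit).
    """
    x = np.sort(np.asarray(contrasts, dtype=float))
    if x.size < 50:
        raise ValidationError(f"need >= 50 contrasts, got {x.size}")
    if reference.n < 50:
        raise ValidationError(f"need >= 50 reference sizes, got {reference.n}")
    ref = reference.expand()
    if np.ptp(x) == 0 or np.ptp(ref) == 0:
        raise ValidationError("degenerate (constant) distribution; cannot calibrate")

    pct = np.arange(1, 100) if percentiles is None else np.asarray(percentiles, float)
    qx = np.percentile(x, pct)
    qy = np.percentile(ref, pct)
    a2, a1, a0 = np.polyfit(qx, qy, deg=2)
    lo, hi = float(x.min()), float(x.max())
    if a1 + 2 * a2 * lo <= 0 or a1 + 2 * a2 * hi <= 0:
        raise FitError(
            "fitted calibration is not monotone over the observed contrast "
            f"range [{lo:.3g}, {hi:.3g}] %; restrict the contrast range and refit"
        )
    cal = Calibration(a2=float(a2), a1=float(a1), a0=float(a0), valid_contrast_range=(lo, hi))
    resid = qy - (a2 * qx**2 + a1 * qx + a0)
    return CalibrationFit(
        calibration=cal,
        rms_quantile_residual_nm=float(np.sqrt(np.mean(resid**2))),
        n_contrasts=int(x.size),
        n_reference=int(reference.n),
    )


def size_distribution(
    detections,
    cal: Calibration | None = None,
    bin_edges: np.ndarray | None = None,
) -> SizeDistribution:
    """Sizes of a set of ratio-image detections via the calibration.

    Parameters
    ----------
    detections : DetectionSet
        Ratio-image (label-free channel) detections with ``contrast_pct`` set.
    bin_edges : array, optional
        Histogram bin edges in nm; default 10 nm bins from 0 to 400 nm.

    Returns an empty distribution (with a warning) for an empty set.
    """
    cal = cal or Calibration()
    if bin_edges is None:
        bin_edges = np.arange(0.0, 410.0, 10.0)
    contrasts = np.array([d.contrast_pct for d in detections], dtype=float)
    if contrasts.size == 0:
        warnings.warn("empty detection set: empty size distribution", stacklevel=2)
        return SizeDistribution(
            sizes=np.empty(0),
            bin_edges=bin_edges,
            counts=np.zeros(len(bin_edges) - 1, dtype=int),
            source="panorama",
            extrapolated=np.empty(0, dtype=bool),
        )
    sizes = size_from_contrast(contrasts, cal)
    counts, _ = np.histogram(sizes, bins=bin_edges)
    return SizeDistribution(
        sizes=sizes,
        bin_edges=bin_edges,
        counts=counts,
        source="panorama",
        extrapolated=~cal.in_range(contrasts),
    )
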