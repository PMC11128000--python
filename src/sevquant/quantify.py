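"""Per-sample digital-counting summaries.

One assay of 20 µl plasma yields: a settlement curve (detections per
pre-wash timepoint, saturating as particles bind the functionalized
surface), the pre-wash total and vesicle-scale ("sEV-like", contrast
<= 18 %) counts, the post-wash retained count, the retention percentage,
the absolute count per microlitre (post-wash count / assay volume), label
occurrence percentages, and contrast/size summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibrate import Calibration, size_from_contrast
from .colocalize import ColocalizationResult
from .errors import ValidationError
from .imaging import (
    CHANNEL_FLAG,
    DetectionConfig,
    DetectionSet,
    FrameStack,
    find_particles,
    ratio_image,
    register_to_background,
)

__all__ = [
    "SettlementCurve",
    "SampleMeta",
    "SampleSummary",
    "settlement_curve",
    "retention_pct",
    "asc_per_ul",
    "summarize_sample",
]

GROUP_LABELS = ("healthy", "cancer", "control", "unknown")


@dataclass
class SettlementCurve:
    """Detections per pre-wash timepoint."""

    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.times.size != self.counts.size:
            raise ValidationError("times and counts must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")


def settlement_curve(
    stack: FrameStack,
    cfg: DetectionConfig | None = None,
    register: bool = False,
) -> SettlementCurve:
    """Count detections in each pre-wash frame of a label-free stack.

    With ``register=True`` each frame is first rigidly aligned to the
    background (needed when the acquisition drifted); simulated stacks are
    already on the background grid.
    """
    cfg = cfg or DetectionConfig()
    frames = stack.pre_wash()
    if not frames:
        raise ValidationError("stack has no pre-wash frames")
    times, counts = [], []
    for f in frames:
        if register:
            f, _ = register_to_background(f, stack.background)
        dets = find_particles(ratio_image(f, stack.background), cfg)
        times.append(f.time_min if f.time_min is not None else len(times))
        counts.append(len(dets))
    return SettlementCurve(times=np.array(times), counts=np.array(counts))


def retention_pct(pre_count: int, post_count: int) -> float | None:
    """Percentage of pre-wash particles retained after the wash.

    Returns None (missing) when the pre-wash count is zero.
    """
    if pre_count < 0 or post_count < 0:
        raise ValidationError("counts must be non-negative")
    if pre_count == 0:
        return None
    return 100.0 * post_count / pre_count


def asc_per_ul(post_wash_count: int, volume_ul: float = 20.0) -> float:
    """Absolute count per microlitre: post-wash count / assay volume."""
    if volume_ul <= 0:
        raise ValidationError("assay volume must be positive")
    if post_wash_count < 0:
        raise ValidationError("count must be non-negative")
    return post_wash_count / volume_ul


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    group_label: str = "unknown"
    subtype: str = ""
    volume_ul: float = 20.0

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ValidationError(f"group_label must be one of {GROUP_LABELS}")
        if self.volume_ul <= 0:
            raise ValidationError("volume_ul must be positive")


@dataclass
class SampleSummary:
    """Digital-counting summary of one sample (one assay)."""

    sample_id: str
    group_label: str
    subtype: str
    pre_wash_total: int
    pre_wash_sev_like: int
    post_wash_count: int
    retention_pct: float | None
    retention_denominator: str  # "sev_like" or "total"
    asc_per_ul: float
    volume_ul: float
    occurrence_pct: dict[str, float] = field(default_factory=dict)
    mean_contrast_pct: float = float("nan")
    mean_size_nm: float = float("nan")

    def __post_init__(self) -> None:
        if self.pre_wash_sev_like > self.pre_wash_total:
            raise ValidationError("sEV-like count cannot exceed the pre-wash total")
        if self.post_wash_count < 0:
            raise ValidationError("post-wash count must be non-negative")


def summarize_sample(
    pre: DetectionSet,
    post: DetectionSet,
    coloc: ColocalizationResult | list[ColocalizationResult] | None,
    cal: Calibration | None = None,
    meta: SampleMeta | None = None,
) -> SampleSummary:
    """Assemble the per-sample summary from endpoint detections.

    ``pre`` is the final pre-wash detection set, ``post`` the post-wash set,
    ``coloc`` the fluorescence match result(s) computed on ``post``.  The
    retention denominator is the pre-wash sEV-like count when non-zero,
    otherwise the pre-wash total; which one was used is recorded.
    """
    if post is None:
        raise ValidationError("post-wash detection set is required")
    cal = cal or Calibration()
    meta = meta or SampleMeta(sample_id="sample")
    if pre.image_shape != post.image_shape:
        raise ValidationError("pre and post detection sets have different image shapes")

    pre_total = len(pre)
    pre_sev = sum(1 for d in pre if d.sev_like)
    post_count = len(post)

    denom_name = "sev_like" if pre_sev > 0 else "total"
    denom = pre_sev if pre_sev > 0 else pre_total
    retention = retention_pct(denom, post_count)

    occurrences: dict[str, float] = {}
    colocs = [] if coloc is None else (coloc if isinstance(coloc, list) else [coloc])
    for c in colocs:
        flag = CHANNEL_FLAG.get(c.channel, c.channel)
        occurrences[flag] = c.occurrence

    contrasts = post.contrasts() if post_count else np.empty(0)
    mean_c = float(np.mean(contrasts)) if contrasts.size else float("nan")
    mean_s = float(np.mean(size_from_contrast(contrasts, cal))) if contrasts.size else float("nan")

    return SampleSummary(
        sample_id=meta.sample_id,
        group_label=meta.group_label,
        subtype=meta.subtype,
        pre_wash_total=pre_total,
        pre_wash_sev_like=pre_sev,
        post_wash_count=post_count,
        retention_pct=retention,
        retention_denominator=denom_name,
        asc_per_ul=asc_per_ul(post_count, meta.volume_ul),
        volume_ul=meta.volume_ul,
        occurrence_pct=occurrences,
        mean_contrast_pct=mean_c,
        mean_size_nm=mean_s,
    )
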