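"""ROI statistics on T2 maps and nerve orientation relative to B0.

Reports, per region of interest, the mean T2 and its standard deviation
normalized to the mean (a unitless heterogeneity measure), mirroring how
the ROIs were quantified in the study, and validates the protocol rule
that an ROI be drawn on exactly three pairwise non-consecutive axial
slices.  Nerve orientation is reduced to the solid angle from B0 via the
cosine rule, folded into [0, 90] degrees (a fiber is direction-less).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .t2_mapping import T2Map

__all__ = [
    "RoiMask",
    "RoiStats",
    "SliceRuleResult",
    "roi_stats",
    "validate_slice_rule",
    "nerve_angle_from_b0",
]


@dataclass
class RoiMask:
    """Labeled voxel mask aligned to a T2 map (labels nonzero; 0 = outside)."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("ROI mask must be integer-typed")

    def slices_for(self, label: int) -> np.ndarray:
        """Sorted axial slice indices (third axis) occupied by a label."""
        return np.unique(np.nonzero(self.labels == label)[2])


@dataclass(frozen=True)
class RoiStats:
    label: int
    n_voxels: int
    mean_t2_ms: float
    normalized_sd: float
    n_invalid_excluded: int
    n_clamped: int


def roi_stats(
    t2map: T2Map,
    mask: RoiMask,
    label: int,
    exclude_clamped: bool = False,
) -> RoiStats:
    """Mean T2 and mean-normalized SD over one labeled ROI.

    Invalid voxels are excluded and counted.  The SD is the sample SD
    (n-1 denominator); normalized_sd = SD / mean.  Clamped voxels are
    included by default but reported, and can be excluded.
    """
    if t2map.shape != mask.labels.shape:
        raise ValueError(
            f"shape mismatch: T2 map {t2map.shape}, mask {mask.labels.shape}"
        )
    sel = mask.labels == label
    if not sel.any():
        raise ValueError(f"label {label} absent from the ROI mask")
    vals = t2map.values[sel]
    flags = t2map.flags[sel]
    valid = np.isfinite(vals)
    n_invalid = int((~valid).sum())
    n_clamped = int(((flags == 1) | (flags == 2)).sum())
    keep = valid if not exclude_clamped else valid & (flags == 0)
    vals = vals[keep]
    if vals.size == 0:
        raise ValueError(f"label {label}: ROI empty after exclusions")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return RoiStats(
        label=int(label),
        n_voxels=int(vals.size),
        mean_t2_ms=mean,
        normalized_sd=sd / mean,
        n_invalid_excluded=n_invalid,
        n_clamped=n_clamped,
    )


@dataclass(frozen=True)
class SliceRuleResult:
    ok: bool
    reason: str


def validate_slice_rule(
    mask: RoiMask, label: int, warn: bool = True
) -> SliceRuleResult:
    """Check the three-non-consecutive-slices ROI protocol rule.

    Passes iff the label occupies exactly 3 axial slices, no two adjacent.
    By default a failing mask only warns (synthetic masks need not mimic
    the clinical protocol); callers may enforce the result.
    """
    slices = mask.slices_for(label)
    if len(slices) != 3:
        res = SliceRuleResult(False, f"label {label} occupies {len(slices)} slices, not 3")
    elif np.any(np.diff(slices) == 1):
        res = SliceRuleResult(False, f"label {label} uses adjacent slices {slices.tolist()}")
    else:
        res = SliceRuleResult(True, "ok")
    if warn and not res.ok:
        warnings.warn(f"slice rule: {res.reason}", stacklevel=2)
    return res


def nerve_angle_from_b0(tangent, b0_dir=(0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, in [0, 90]) between a nerve tangent and B0.

    Cosine rule on the absolute normalized dot product, so the result is
    insensitive to the sign and scale of either vector.
    """
    v = np.asarray(tangent, dtype=float)
    b = np.asarray(b0_dir, dtype=float)
    nv, nb = np.linalg.norm(v), np.linalg.norm(b)
    if nv == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    c = abs(float(np.dot(v, b))) / (nv * nb)
    return float(np.rad2deg(np.arccos(min(c, 1.0))))
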