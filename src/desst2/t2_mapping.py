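"""Voxelwise DESS-T2 map computation and B1+-corrected MESE fitting.

The DESS path takes the two co-registered echo volumes of a single
acquisition, forms the per-voxel S-/S+ ratio, inverts the ratio equation
for an approximate T2, and corrects it with the per-tissue dictionary
(nerve and muscle use different assumed T1).  Voxels where the ratio is
unusable (non-positive signal, ratio >= 1, background) carry an explicit
invalid marker (NaN) — never 0, which would look like a legal T2.

The MESE path fits a measured CPMG echo train against extended-phase-graph
decay curves over a (T2, B1) grid with the amplitude profiled out
analytically, which corrects the stimulated-echo contamination that makes
a naive log-linear fit overestimate T2 when the transmit field deviates
from nominal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_models import (
    CLAMP_INVALID,
    AcquisitionParams,
    T2Dictionary,
    build_dictionary,
    epg_cpmg_curves,
    t2_approx_from_ratio,
)

__all__ = [
    "VolumeGrid",
    "TissueLabelMap",
    "T2Map",
    "compute_dess_t2_map",
    "fit_mese_t2",
    "MeseFit",
]


@dataclass
class VolumeGrid:
    """A 3D scalar field with voxel spacing and a voxel-to-physical affine.

    Spacing defaults to the acquisition resolution of 0.3 x 0.3 x 1.6 mm
    (in-plane x, in-plane y, slice).  Indices are 0-based; the third axis
    is the slice direction.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 1.6)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "VolumeGrid":
        """Same grid geometry, new voxel values."""
        return VolumeGrid(values, self.spacing_mm, None if self.affine is None else self.affine.copy())


@dataclass
class TissueLabelMap:
    """Integer label volume plus per-label tissue semantics.

    ``tissue_class`` maps each non-background label to "nerve" or "muscle";
    ``t1_ms`` gives the assumed T1 used for that label's dictionary
    (defaults: nerve 1600 ms, muscle 1400 ms).  Label 0 is background.
    """

    labels: np.ndarray
    tissue_class: dict[int, str] = field(default_factory=dict)
    t1_ms: dict[int, float] = field(default_factory=dict)

    DEFAULT_T1 = {"nerve": 1600.0, "muscle": 1400.0}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        for lab in self.present_labels():
            if lab not in self.tissue_class:
                raise ValueError(f"label {lab} has no tissue class assignment")
            if lab not in self.t1_ms:
                cls = self.tissue_class[lab]
                if cls not in self.DEFAULT_T1:
                    raise ValueError(f"label {lab}: unknown tissue class {cls!r}")
                self.t1_ms[lab] = self.DEFAULT_T1[cls]

    def present_labels(self) -> list[int]:
        labs = np.unique(self.labels)
        return [int(l) for l in labs if l != 0]


@dataclass
class T2Map:
    """Voxelwise T2 in ms with invalid marker (NaN) and clamp flags.

    ``flags`` uses the dictionary clamp codes: 0 ok, 1 clamped low,
    2 clamped high, -1 invalid.  Finite values lie inside the dictionary
    range.
    """

    values: np.ndarray
    flags: np.ndarray
    spacing_mm: tuple[float, float, float] = (0.3, 0.3, 1.6)
    acq: AcquisitionParams | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def compute_dess_t2_map(
    s_plus: VolumeGrid,
    s_minus: VolumeGrid,
    labels: TissueLabelMap,
    acq: AcquisitionParams,
    dictionaries: dict[int, T2Dictionary] | None = None,
    t2_min: float = 3.0,
    t2_max: float = 300.0,
    step: float = 0.1,
) -> T2Map:
    """Compute the voxelwise DESS-T2 map from paired echo volumes.

    Per voxel: ratio -> approximate T2 -> dictionary correction using the
    dictionary of the voxel's label.  Background voxels (label 0) and
    voxels with non-positive signal or ratio >= 1 are invalid.

    ``dictionaries`` may pre-supply a dictionary per label; any missing
    label's dictionary is built from its assumed T1 at the given range.
    The map is scale invariant: the ratio cancels any common positive
    scaling of both echoes.
    """
    if s_plus.shape != s_minus.shape or s_plus.shape != labels.labels.shape:
        raise ValueError(
            f"shape mismatch: s_plus {s_plus.shape}, s_minus {s_minus.shape}, "
            f"labels {labels.labels.shape}"
        )
    if tuple(s_plus.spacing_mm) != tuple(s_minus.spacing_mm):
        raise ValueError("echo volumes have different voxel spacings")

    dicts = dict(dictionaries) if dictionaries else {}
    for lab in labels.present_labels():
        if lab not in dicts:
            dicts[lab] = build_dictionary(labels.t1_ms[lab], acq, t2_min, t2_max, step)

    sp = s_plus.values
    sm = s_minus.values
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sp > 0, sm / sp, np.nan)
    ratio[(sm <= 0) | ~np.isfinite(ratio)] = np.nan
    approx = t2_approx_from_ratio(ratio, acq)

    out = np.full(sp.shape, np.nan)
    flags = np.full(sp.shape, CLAMP_INVALID, dtype=np.int8)
    for lab in labels.present_labels():
        sel = labels.labels == lab
        t2, f = dicts[lab].lookup(approx[sel])
        out[sel] = t2
        flags[sel] = f
    return T2Map(out, flags, tuple(s_plus.spacing_mm), acq)


@dataclass(frozen=True)
class MeseFit:
    """Result of a MESE T2 fit: T2 (ms), B1 estimate, and the residual
    sum of squares of the best match."""

    t2_ms: float
    b1: float
    residual: float


def fit_mese_t2(
    decay,
    te_list_ms,
    b1_scale="fit",
    method: str = "b1_corrected",
    t1_ms: float = 1400.0,
    t2_grid=None,
    b1_grid=None,
) -> MeseFit:
    """Fit T2 to a CPMG echo train.

    ``method="b1_corrected"`` least-squares matches the measured curve
    against EPG decay curves over a (T2, B1) search grid (defaults
    T2 = 3..300 ms step 0.5, B1 = 0.7..1.3 step 0.01), with the amplitude
    profiled out analytically.  ``b1_scale`` may be a known scale (the
    search then fixes B1) or ``"fit"`` to estimate it jointly.

    ``method="log_linear"`` is the baseline comparator: the slope of
    ln(signal) vs TE, which ignores stimulated-echo pathways and is exact
    only for perfect refocusing.

    Note that magnitude EPG curves are invariant under the reflection
    b1 -> 2 - b1, so the B1 estimate is identifiable only up to that
    symmetry; the T2 estimate is unaffected.

    Echo times must be uniformly spaced (a CPMG train).
    """
    y = np.asarray(decay, dtype=float)
    te = np.asarray(te_list_ms, dtype=float)
    if y.ndim != 1 or len(y) != len(te):
        raise ValueError("decay and te_list_ms must be 1D and the same length")
    if len(y) < 3:
        raise ValueError("need at least 3 echoes")
    if not np.all(np.isfinite(y)) or np.all(y == 0):
        raise ValueError("decay must be finite and not all zero")
    esp = te[1] - te[0]
    if esp <= 0 or not np.allclose(np.diff(te), esp, rtol=1e-6):
        raise ValueError("echo times must be uniformly spaced (CPMG train)")

    if method == "log_linear":
        if np.any(y <= 0):
            raise ValueError("log-linear fit requires positive magnitudes")
        slope = np.polyfit(te, np.log(y), 1)[0]
        if slope >= 0:
            raise ValueError("non-decaying train; log-linear T2 undefined")
        t2 = -1.0 / slope
        amp = np.exp(np.polyfit(te, np.log(y), 1)[1])
        resid = float(np.sum((y - amp * np.exp(-te / t2)) ** 2))
        return MeseFit(float(t2), float("nan"), resid)
    if method != "b1_corrected":
        raise ValueError(f"unknown method {method!r}")

    if t2_grid is None:
        t2_grid = np.arange(3.0, 300.0 + 0.25, 0.5)
    else:
        t2_grid = np.asarray(t2_grid, dtype=float)
    if b1_scale == "fit":
        if b1_grid is None:
            b1_grid = np.arange(0.7, 1.3 + 0.005, 0.01)
        else:
            b1_grid = np.asarray(b1_grid, dtype=float)
    else:
        b1_grid = np.asarray([float(b1_scale)])

    best = (np.inf, np.nan, np.nan)
    yy = float(np.dot(y, y))
    for b1 in b1_grid:
        curves = epg_cpmg_curves(t2_grid, t1_ms, b1, esp, len(y))  # (n_echo, nT2)
        num = curves.T @ y
        den = np.einsum("ij,ij->j", curves, curves)
        amp = np.where(den > 0, num / den, 0.0)
        resid = yy - np.where(den > 0, num**2 / den, 0.0)
        k = int(np.argmin(resid))
        if resid[k] < best[0]:
            best = (float(resid[k]), float(t2_grid[k]), float(b1))
    return MeseFit(best[1], best[2], max(best[0], 0.0))
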