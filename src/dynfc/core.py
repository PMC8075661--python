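"""Sliding-window dynamic functional connectivity (dFC) primitives.

Everything downstream of preprocessing starts here: per-subject ROI x time
matrices are windowed into stacks of Pearson-correlation matrices (the dFC
tensor), collapsed into per-window connection-strength vectors (the dFCS
matrix), or correlated over the full run (static FC).  Conventions used
throughout the package:

* dFC matrices are symmetric with an exactly-zero diagonal and entries in
  [-1, 1]; raw Pearson r is used, no Fisher transform.
* Windows advance by ``step`` time points (default 1) and window ``b`` covers
  time points ``[b, b + W)`` (0-based, half-open).
* A zero-variance segment yields correlation 0 (logged), never NaN.
* User-facing ROI indices are 1-based to match atlas tables; internal arrays
  are 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RoiTimeSeries",
    "WindowConfig",
    "DfcTensor",
    "DfcsMatrix",
    "qc_motion_exclusion",
    "drop_initial_volumes",
    "compute_window_length",
    "sliding_window_dfc",
    "dfcs_from_tensor",
    "static_fc",
]


@dataclass
class RoiTimeSeries:
    """One subject's mean BOLD signal per ROI per time point.

    ``series`` has shape ``(n_roi, n_timepoints)``; ``tr`` is the sampling
    interval in seconds.
    """

    subject_id: str
    group: str
    tr: float
    series: np.ndarray
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2:
            raise ValueError(f"series must be 2-D, got shape {self.series.shape}")
        if not np.isfinite(self.series).all():
            raise ValueError(
                f"subject {self.subject_id}: non-finite values in time series"
            )
        if self.tr <= 0:
            raise ValueError(f"subject {self.subject_id}: TR must be positive")

    @property
    def n_roi(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


@dataclass
class WindowConfig:
    """Sliding-window settings.

    ``duration_s`` is converted to a window length in time points per subject
    via :func:`compute_window_length` (36 s gives W=12 at TR=3 s, W=18 at
    TR=2 s).  ``window_length_override`` bypasses the conversion, e.g. for
    window-length sensitivity runs.
    """

    duration_s: float = 36.0
    step: int = 1
    window_length_override: int | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.step < 1:
            raise ValueError("step must be >= 1")

    def window_length(self, tr: float) -> int:
        if self.window_length_override is not None:
            w = int(self.window_length_override)
            if w < 3:
                raise ValueError(f"window length override {w} < 3")
            return w
        return compute_window_length(tr, self.duration_s)


@dataclass
class DfcTensor:
    """Stack of windowed correlation matrices for one subject.

    ``matrices`` has shape ``(n_windows, n_roi, n_roi)``.
    """

    subject_id: str
    matrices: np.ndarray
    window_length: int
    step: int = 1

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_roi(self) -> int:
        return self.matrices.shape[1]


@dataclass
class DfcsMatrix:
    """Per-ROI dFC strength over windows: entry (i, b) is the sum of absolute
    correlations of ROI i with every other ROI in window b.  Shape
    ``(n_roi, n_windows)``; entries in [0, n_roi - 1]."""

    subject_id: str
    values: np.ndarray

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# QC


def qc_motion_exclusion(
    motion_params: np.ndarray | pd.DataFrame | str,
    translation_limit_mm: float = 1.5,
    rotation_limit_deg: float = 1.5,
    rotation_unit: str = "deg",
) -> tuple[bool, str]:
    """Decide whether a subject passes head-motion QC.

    ``motion_params`` is a 6-column realignment-parameter table (or a path to
    a whitespace-delimited file): columns 1-3 translations in mm, columns 4-6
    rotations.  A subject is excluded iff any |translation| exceeds
    ``translation_limit_mm`` or any |rotation| exceeds ``rotation_limit_deg``
    (strict inequality: values exactly at the limit are kept).

    Returns ``(keep, reason)``.
    """
    if isinstance(motion_params, str):
        motion_params = _read_motion_file(motion_params)
    arr = np.asarray(motion_params, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"motion parameters must be n x 6, got shape {arr.shape}")
    trans = arr[:, :3]
    rot = arr[:, 3:]
    if rotation_unit == "rad":
        rot = np.degrees(rot)
    elif rotation_unit != "deg":
        raise ValueError(f"unknown rotation unit {rotation_unit!r}")
    max_t = float(np.abs(trans).max()) if trans.size else 0.0
    max_r = float(np.abs(rot).max()) if rot.size else 0.0
    if max_t > translation_limit_mm:
        return False, f"max |translation| {max_t:.3f} mm > {translation_limit_mm} mm"
    if max_r > rotation_limit_deg:
        return False, f"max |rotation| {max_r:.3f} deg > {rotation_limit_deg} deg"
    return True, "within motion limits"


def _read_motion_file(path: str) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ValueError(
                    f"{path}: line {lineno}: expected 6 columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return np.asarray(rows, dtype=float)


def drop_initial_volumes(ts: RoiTimeSeries, n_drop: int = 10) -> RoiTimeSeries:
    """Discard the first ``n_drop`` time points (scanner equilibration)."""
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    if ts.n_timepoints <= n_drop:
        raise ValueError(
            f"subject {ts.subject_id}: cannot drop {n_drop} of "
            f"{ts.n_timepoints} time points"
        )
    return RoiTimeSeries(
        subject_id=ts.subject_id,
        group=ts.group,
        tr=ts.tr,
        series=ts.series[:, n_drop:].copy(),
        roi_labels=ts.roi_labels,
    )


# ---------------------------------------------------------------------------
# Windowed correlation


def compute_window_length(tr_s: float, duration_s: float = 36.0) -> int:
    """Window length in time points for a target duration in seconds.

    W = round(duration / TR); a window shorter than 3 points gives a
    degenerate correlation and is rejected.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    w = int(round(duration_s / tr_s))
    if w < 3:
        raise ValueError(
            f"window of {duration_s} s at TR={tr_s} s is {w} points (< 3)"
        )
    return w


def _windowed_correlations(series: np.ndarray, w: int, step: int) -> np.ndarray:
    """Pearson correlation matrix of every length-``w`` window.

    Zero-variance ROIs within a window get correlation 0 everywhere.
    Returns shape (n_windows, n_roi, n_roi) with zero diagonal.
    """
    n_roi, m = series.shape
    starts = np.arange(0, m - w + 1, step)
    out = np.empty((starts.size, n_roi, n_roi))
    constant_hit = False
    for k, b in enumerate(starts):
        seg = series[:, b : b + w]
        seg = seg - seg.mean(axis=1, keepdims=True)
        norms = np.sqrt(np.einsum("ij,ij->i", seg, seg))
        bad = norms == 0
        if bad.any():
            constant_hit = True
            norms = np.where(bad, 1.0, norms)
        c = (seg @ seg.T) / np.outer(norms, norms)
        if bad.any():
            c[bad, :] = 0.0
            c[:, bad] = 0.0
        np.clip(c, -1.0, 1.0, out=c)
        np.fill_diagonal(c, 0.0)
        out[k] = c
    if constant_hit:
        logger.warning(
            "constant segment encountered; correlations set to 0 for the "
            "affected ROI/windows"
        )
        warnings.warn(
            "constant segment: correlation defined as 0", RuntimeWarning, stacklevel=3
        )
    return out


def sliding_window_dfc(ts: RoiTimeSeries, w: int, step: int = 1) -> DfcTensor:
    """Compute the dFC tensor: one ROI x ROI Pearson matrix per window.

    Window ``b`` covers time points ``[b*step, b*step + w)``; there are
    ``floor((M - w) / step) + 1`` windows.  Diagonals are forced to zero.
    """
    if w < 2:
        raise ValueError("window length must be >= 2")
    if ts.n_timepoints < w:
        raise ValueError(
            f"subject {ts.subject_id}: {ts.n_timepoints} time points < window {w}"
        )
    mats = _windowed_correlations(ts.series, w, step)
    return DfcTensor(subject_id=ts.subject_id, matrices=mats, window_length=w, step=step)


def dfcs_from_tensor(tensor: DfcTensor) -> DfcsMatrix:
    """dFC strength: per window, sum |r| over each ROI's row of the dFC matrix."""
    values = np.abs(tensor.matrices).sum(axis=2).T  # (n_roi, n_windows)
    return DfcsMatrix(subject_id=tensor.subject_id, values=values)


def static_fc(ts: RoiTimeSeries) -> np.ndarray:
    """Full-run Pearson correlation matrix with the same conventions as the
    windowed matrices (zero diagonal, constant ROI -> 0)."""
    if ts.n_timepoints < 3:
        raise ValueError("static FC needs at least 3 time points")
    return _windowed_correlations(ts.series, ts.n_timepoints, 1)[0]
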