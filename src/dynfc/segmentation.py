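"""Automatic quasistable-segment detection on the dFCS matrix.

The brain's windowed connectivity-strength profile (the dFCS matrix, ROI x
windows) is roughly piecewise stationary: stretches of windows share a
profile until the underlying connectome reorganises.  Segment boundaries are
located automatically as local maxima of the Euclidean distance between the
dFCS vectors of adjacent windows; each resulting segment is time-averaged
into a single whole-brain quasistable connectome pattern (WQCP) sample, the
unit that is later pooled across subjects and clustered.

The peak rule is strict: distance d_i is a boundary iff d_i > d_{i-1} and
d_i > d_{i+1}; plateaus produce no boundary, and a series with no peaks
yields a single whole-run segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DfcsMatrix

__all__ = [
    "SegmentSet",
    "WqcpSample",
    "adjacent_distances",
    "detect_segment_points",
    "build_segments",
    "compute_wqcps",
    "segment_subject",
    "wqcp_dataframe",
]


@dataclass
class SegmentSet:
    """Partition of a subject's window axis into contiguous segments.

    ``boundaries`` are window indices (0-based) that END a segment;
    ``segments`` are [start, stop) half-open intervals covering
    [0, n_windows) without gaps or overlap.
    """

    subject_id: str
    n_windows: int
    boundaries: np.ndarray
    segments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        starts = [s for s, _ in self.segments]
        stops = [e for _, e in self.segments]
        if starts[0] != 0 or stops[-1] != self.n_windows:
            raise ValueError("segments must cover [0, n_windows)")
        for (s, e), nxt in zip(self.segments, starts[1:] + [self.n_windows]):
            if e <= s or e != nxt:
                raise ValueError("segments must be non-empty, contiguous, disjoint")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.segments])


@dataclass
class WqcpSample:
    """Time-average of the dFCS columns within one quasistable segment."""

    subject_id: str
    group: str
    start: int
    stop: int
    vector: np.ndarray

    @property
    def weight(self) -> int:
        """Segment length in windows."""
        return self.stop - self.start


def adjacent_distances(dfcs: DfcsMatrix | np.ndarray) -> np.ndarray:
    """Euclidean distance between the dFCS vectors of consecutive windows.

    Returns a length ``n_windows - 1`` array; ``d[i]`` is the distance
    between windows i and i+1 along the time axis.
    """
    values = dfcs.values if isinstance(dfcs, DfcsMatrix) else np.asarray(dfcs, float)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 windows")
    diffs = np.diff(values, axis=1)
    return np.sqrt(np.einsum("ij,ij->j", diffs, diffs))


def detect_segment_points(d: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of the adjacent-distance curve.

    An interior index i (0-based, so 1 <= i <= len(d) - 2) is a segment point
    iff d[i] > d[i-1] and d[i] > d[i+1].  Endpoints are never peaks and an
    empty result is valid.
    """
    d = np.asarray(d, dtype=float)
    if d.size < 3:
        return np.array([], dtype=int)
    interior = np.arange(1, d.size - 1)
    mask = (d[interior] > d[interior - 1]) & (d[interior] > d[interior + 1])
    return interior[mask]


def build_segments(
    n_windows: int, boundaries: np.ndarray, subject_id: str = ""
) -> SegmentSet:
    """Partition the window axis at the given distance-curve peaks.

    A peak at distance index i (between windows i and i+1) ends the current
    segment after window i: intervals are [0, b0+1), [b0+1, b1+1), ...,
    [b_last+1, n_windows).
    """
    boundaries = np.asarray(boundaries, dtype=int)
    if boundaries.size and (
        np.any(np.diff(boundaries) <= 0)
        or boundaries[0] < 0
        or boundaries[-1] >= n_windows - 1
    ):
        raise ValueError(
            "boundaries must be strictly increasing and within [0, n_windows-1)"
        )
    edges = [0] + [int(b) + 1 for b in boundaries] + [n_windows]
    segments = [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]
    return SegmentSet(
        subject_id=subject_id,
        n_windows=n_windows,
        boundaries=boundaries,
        segments=segments,
    )


def compute_wqcps(
    dfcs: DfcsMatrix, segments: SegmentSet, group: str = ""
) -> list[WqcpSample]:
    """One WQCP sample per segment: columnwise mean of the dFCS matrix over
    the segment's windows."""
    samples = []
    for start, stop in segments.segments:
        vec = dfcs.values[:, start:stop].mean(axis=1)
        samples.append(
            WqcpSample(
                subject_id=dfcs.subject_id,
                group=group,
                start=start,
                stop=stop,
                vector=vec,
            )
        )
    return samples


def segment_subject(dfcs: DfcsMatrix, group: str = "") -> tuple[SegmentSet, list[WqcpSample]]:
    """Full per-subject segmentation: distances -> peaks -> segments -> WQCPs."""
    d = adjacent_distances(dfcs)
    boundaries = detect_segment_points(d)
    segs = build_segments(dfcs.n_windows, boundaries, subject_id=dfcs.subject_id)
    return segs, compute_wqcps(dfcs, segs, group=group)


def wqcp_dataframe(samples: list[WqcpSample]) -> pd.DataFrame:
    """Assemble pooled WQCP samples into a tidy table.

    Columns: subject_id, group, seg_start, seg_end, weight, v1..vN (one
    strength column per ROI, 1-based names).
    """
    if not samples:
        raise ValueError("no WQCP samples")
    n_roi = samples[0].vector.size
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in samples],
            "group": [s.group for s in samples],
            "seg_start": [s.start for s in samples],
            "seg_end": [s.stop for s in samples],
            "weight": [s.weight for s in samples],
        }
    )
    vecs = pd.DataFrame(
        np.vstack([s.vector for s in samples]),
        columns=[f"v{i}" for i in range(1, n_roi + 1)],
    )
    return pd.concat([meta, vecs], axis=1)
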