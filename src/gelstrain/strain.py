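"""Segmental circumferential strain analysis of left-ventricular wall contours.

A short-axis cine of the LV wall is reduced to a 24-segment circumferential
strain map: the classic 6-segment short-axis subdivision with each segment
split into four equal angular parts.  For each frame the wall contour is cut
by sector-boundary rays from the reference-frame centroid into ``n_segments``
arcs, and the circumferential strain of segment ``k`` is the fractional
change of its arc length relative to the end-diastolic (maximal-area) frame:

    eps_cc[k] = (l_current[k] - l_reference[k]) / l_reference[k] * 100

Negative values are contraction, positive values passive stretch — the
signature of a noncontractile infarct being pulled by its healthy
neighbours.  The strain differential between circumferentially adjacent
segments,

    d_eps_cc[k] = | eps_cc[k] - eps_cc[k+1 mod n] |,

is a proxy for the wall strain gradient; its maximum over the cardiac cycle
localizes the infarct border, where rupture risk and fibrotic expansion
concentrate.

Segments are Eulerian angular bins — fixed rays about the reference-frame
centroid — rather than material-tracked wall patches.  Segment ``k`` spans
angles ``[reference_angle + k*w, reference_angle + (k+1)*w)`` with
``w = 2*pi/n``, angles increasing counterclockwise; boundary ``k`` sits
between segments ``k`` and ``k+1`` (at angle ``reference_angle + (k+1)*w``).
All indices are 0-based.

Echocardiographic contours carry point noise, so small local zigzags (which
make the polygon technically non-star-shaped or non-simple) are tolerated in
the cine pipeline: every piece of wall is attributed to the sector it lies
in, so arc length is conserved exactly.  The strict entry points raise
``NonStarShaped`` instead, for data where a clean geometry is expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, GeometryError, NonStarShaped

__all__ = [
    "ContourFrame",
    "CineSequence",
    "SegmentationScheme",
    "StrainMap",
    "ZoneLabels",
    "polygon_area",
    "polygon_centroid",
    "resample_contour",
    "end_diastole_index",
    "end_systole_index",
    "segment_arc_lengths",
    "circumferential_strain",
    "strain_differential",
    "max_peak_strain_differential",
    "zone_mean_strain",
    "analyze_cine",
]

ZONE_NAMES = ("infarct", "border", "remote")


def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polyline (CCW positive), mm^2."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a closed polyline, mm."""
    x, y = points[:, 0], points[:, 1]
    cr = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * cr.sum()
    if abs(a) < 1e-12:
        raise GeometryError("degenerate polygon: zero area")
    cx = np.sum((x + np.roll(x, -1)) * cr) / (6.0 * a)
    cy = np.sum((y + np.roll(y, -1)) * cr) / (6.0 * a)
    return np.array([cx, cy])


@dataclass(frozen=True)
class ContourFrame:
    """One time point of the cine: a closed planar wall contour (mm).

    Points are stored counterclockwise; clockwise input is reversed on
    construction (orientation is detected from the signed area).
    """

    time: float
    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DataError("points must be an (n, 2) array")
        if len(pts) < 24:
            raise DataError("a contour needs at least 24 points")
        if not np.all(np.isfinite(pts)):
            raise DataError("contour points must be finite")
        if polygon_area(pts) < 0:
            pts = pts[::-1].copy()
        object.__setattr__(self, "points", pts)

    @property
    def area(self) -> float:
        """Enclosed area, mm^2."""
        return polygon_area(self.points)


@dataclass(frozen=True)
class CineSequence:
    """Ordered contour frames over (at least part of) a cardiac cycle."""

    frames: tuple[ContourFrame, ...]
    epicardial_frames: tuple[ContourFrame, ...] | None = None

    def __post_init__(self) -> None:
        frames = tuple(self.frames)
        if len(frames) < 2:
            raise DataError("a cine needs at least 2 frames")
        times = np.array([f.time for f in frames])
        if not np.all(np.diff(times) > 0):
            raise DataError("frame times must be strictly increasing")
        if self.epicardial_frames is not None:
            epi = tuple(self.epicardial_frames)
            if len(epi) != len(frames):
                raise DataError("epicardial frames must pair one-to-one with frames")
            object.__setattr__(self, "epicardial_frames", epi)
        object.__setattr__(self, "frames", frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass(frozen=True)
class SegmentationScheme:
    """Equal-angle sector scheme: segment count, phase, and cut centroid.

    ``n_segments`` must be divisible by 6 so the scheme refines the classic
    6-segment short-axis subdivision.  ``centroid`` is the point the
    sector-boundary rays emanate from; if None, the reference-frame centroid
    is used at analysis time.
    """

    n_segments: int = 24
    reference_angle: float = 0.0
    centroid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_segments < 6 or self.n_segments % 6 != 0:
            raise DataError("n_segments must be a positive multiple of 6")
        if self.centroid is not None:
            c = np.asarray(self.centroid, dtype=float)
            if c.shape != (2,):
                raise DataError("centroid must be a planar point")
            object.__setattr__(self, "centroid", c)

    @property
    def sector_width(self) -> float:
        return 2.0 * np.pi / self.n_segments

    def boundary_angle(self, boundary_index: int) -> float:
        """Angle (rad) of the ray between segments k and k+1."""
        return self.reference_angle + (boundary_index + 1) * self.sector_width


@dataclass(frozen=True)
class ZoneLabels:
    """Per-segment zone assignment: infarct scar, border rim, or remote wall."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        bad = sorted(set(labels) - set(ZONE_NAMES))
        if bad:
            raise DataError(f"unknown zone labels {bad}; allowed: {ZONE_NAMES}")
        object.__setattr__(self, "labels", labels)


@dataclass(frozen=True)
class StrainMap:
    """Per-frame, per-segment strain analysis of a cine.

    ``strains``: (n_frames, n_segments) circumferential strain, percent.
    ``differentials``: (n_frames, n_segments) adjacent-segment strain
    differences (boundary k between segments k and k+1), percent, >= 0.
    """

    times: np.ndarray
    reference_frame_index: int
    end_systole_frame_index: int
    strains: np.ndarray
    differentials: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.strains.shape[1]

    @property
    def peak_strains(self) -> np.ndarray:
        """Per-segment strain at end-systole (percent)."""
        return self.strains[self.end_systole_frame_index]


def resample_contour(points: np.ndarray, n: int = 360) -> np.ndarray:
    """Resample a closed polyline to ``n`` points equally spaced in arc length."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        raise GeometryError("contour has zero perimeter")
    q = np.linspace(0.0, s[-1], n, endpoint=False)
    return np.c_[np.interp(q, s, closed[:, 0]), np.interp(q, s, closed[:, 1])]


def end_diastole_index(seq: CineSequence) -> int:
    """Frame of maximal enclosed area (earliest on ties)."""
    areas = np.array([abs(f.area) for f in seq.frames])
    return int(np.argmax(areas))


def end_systole_index(seq: CineSequence) -> int:
    """Frame of minimal enclosed area (earliest on ties)."""
    areas = np.array([abs(f.area) for f in seq.frames])
    return int(np.argmin(areas))


def _ray_segment_point(c: np.ndarray, angle: float, p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Intersection of the ray from ``c`` at ``angle`` with segment p-q."""
    u = np.array([np.cos(angle), np.sin(angle)])
    d = q - p
    denom = u[0] * d[1] - u[1] * d[0]
    if abs(denom) < 1e-300:
        return 0.5 * (p + q)  # ray parallel to the edge; split at the midpoint
    s = (u[0] * (c[1] - p[1]) - u[1] * (c[0] - p[0])) / denom
    return p + np.clip(s, 0.0, 1.0) * d


def segment_arc_lengths(
    frame: ContourFrame,
    scheme: SegmentationScheme,
    centroid: np.ndarray | None = None,
    strict: bool = True,
) -> np.ndarray:
    """Arc length (mm) of the wall contour inside each angular sector.

    The contour is traversed once; every edge is split exactly at the
    sector-boundary rays it crosses (ray-segment intersection, so the pieces
    sum to the full perimeter to machine precision) and each piece is
    credited to the sector containing it.

    In strict mode a contour that crosses any boundary ray more than once —
    i.e. is not star-shaped about the centroid — raises ``NonStarShaped``.
    With ``strict=False`` (used by the cine pipeline for noisy contours)
    back-and-forth crossings are simply accumulated into the sectors they
    traverse, preserving total arc length.

    Raises ``GeometryError`` if the centroid is not enclosed by the contour
    (winding number != 1).
    """
    c = centroid if centroid is not None else scheme.centroid
    if c is None:
        c = polygon_centroid(frame.points)
    c = np.asarray(c, dtype=float)
    pts = frame.points
    n = scheme.n_segments
    w = scheme.sector_width
    ref = scheme.reference_angle

    rel = pts - c
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    dtheta = np.diff(np.concatenate([theta, theta[:1]]))
    dtheta = (dtheta + np.pi) % (2.0 * np.pi) - np.pi  # rotation per edge in (-pi, pi]
    winding = dtheta.sum() / (2.0 * np.pi)
    if abs(winding - 1.0) > 1e-6:
        raise GeometryError(
            f"centroid {c.tolist()} is not enclosed once by the contour "
            f"(winding {winding:.3f}); is the centroid inside the polygon?"
        )
    cont = np.concatenate([[theta[0]], theta[0] + np.cumsum(dtheta)])  # continuous angle

    closed = np.vstack([pts, pts[:1]])
    lengths = np.zeros(n)
    crossings = np.zeros(n, dtype=int)

    for i in range(len(pts)):
        a, b = cont[i], cont[i + 1]
        p, q = closed[i], closed[i + 1]
        if a == b:
            k = int(np.floor((a - ref) / w)) % n
            lengths[k] += float(np.hypot(*(q - p)))
            continue
        lo, hi = (a, b) if a < b else (b, a)
        # boundary grid values ref + j*w strictly inside the swept interval
        j_first = int(np.ceil((lo - ref) / w - 1e-12))
        j_last = int(np.floor((hi - ref) / w + 1e-12))
        grid = [ref + j * w for j in range(j_first, j_last + 1) if lo < ref + j * w < hi]
        if a > b:
            grid = grid[::-1]
        cut_angles = [a] + grid + [b]
        cut_points = [p] + [_ray_segment_point(c, g, p, q) for g in grid] + [q]
        for g in grid:
            # boundary j at angle ref + j*w separates segments j-1 and j,
            # i.e. it is boundary index (j-1) mod n
            crossings[(int(round((g - ref) / w)) - 1) % n] += 1
        for j in range(len(cut_angles) - 1):
            mid = 0.5 * (cut_angles[j] + cut_angles[j + 1])
            k = int(np.floor((mid - ref) / w)) % n
            lengths[k] += float(np.hypot(*(cut_points[j + 1] - cut_points[j])))

    if strict and np.any(crossings > 1):
        bad = np.flatnonzero(crossings > 1)
        raise NonStarShaped(
            f"boundary rays {bad.tolist()} intersect the contour more than once "
            "(contour is not star-shaped about the centroid)"
        )
    return lengths


def circumferential_strain(
    reference_lengths: Sequence[float] | np.ndarray,
    current_lengths: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Per-segment circumferential strain, percent (negative = contraction)."""
    ref = np.asarray(reference_lengths, dtype=float)
    cur = np.asarray(current_lengths, dtype=float)
    if ref.shape != cur.shape or ref.ndim != 1:
        raise DataError("reference and current lengths must be 1-D of equal length")
    if np.any(ref <= 0):
        raise DataError("reference lengths must be > 0")
    return (cur - ref) / ref * 100.0


def strain_differential(strains: Sequence[float] | np.ndarray) -> np.ndarray:
    """Absolute strain difference across each boundary (circular), percent."""
    s = np.asarray(strains, dtype=float)
    if s.ndim != 1 or len(s) < 2:
        raise DataError("need at least 2 segments")
    return np.abs(s - np.roll(s, -1))


def max_peak_strain_differential(strain_map: StrainMap) -> float:
    """Maximum strain differential over all frames and boundaries, percent."""
    mask = np.arange(len(strain_map.times)) != strain_map.reference_frame_index
    if not mask.any():
        raise DataError("strain map has no non-reference frame")
    return float(strain_map.differentials[mask].max())


def zone_mean_strain(
    strains: Sequence[float] | np.ndarray, labels: ZoneLabels
) -> dict[str, float]:
    """Mean strain per zone (percent); zones with no segment are omitted."""
    s = np.asarray(strains, dtype=float)
    if len(labels.labels) != len(s):
        raise DataError(
            f"{len(labels.labels)} labels for {len(s)} segments"
        )
    out: dict[str, float] = {}
    lab = np.array(labels.labels)
    for zone in ZONE_NAMES:
        sel = lab == zone
        if sel.any():
            out[zone] = float(s[sel].mean())
    return out


def _midwall_frame(endo: ContourFrame, epi: ContourFrame, n: int) -> ContourFrame:
    """Point-wise midline of endo- and epicardial contours at ``n`` angles."""
    c = polygon_centroid(endo.points)
    angles = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)

    def radius_at(pts: np.ndarray) -> np.ndarray:
        rel = resample_contour(pts, 4 * n) - c
        th = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
        r = np.hypot(rel[:, 0], rel[:, 1])
        order = np.argsort(th)
        th, r = th[order], r[order]
        # periodic extension so every query angle is bracketed
        th = np.concatenate([th - 2 * np.pi, th, th + 2 * np.pi])
        r = np.tile(r, 3)
        return np.interp(angles, th, r)

    r_mid = 0.5 * (radius_at(endo.points) + radius_at(epi.points))
    pts = c + np.c_[r_mid * np.cos(angles), r_mid * np.sin(angles)]
    return ContourFrame(endo.time, pts)


def analyze_cine(
    seq: CineSequence,
    scheme: SegmentationScheme | None = None,
    n_resample: int = 360,
) -> StrainMap:
    """Full strain analysis of a cine: segment lengths, strain, differentials.

    The reference frame is end-diastole (maximal area).  All frames are cut
    in the same fixed angular bins about the reference-frame centroid (or
    ``scheme.centroid`` if set), after resampling each contour to
    ``n_resample`` equal arc-length points.  When paired epicardial contours
    are present the analyzed contour is the point-wise mid-wall line.
    """
    if scheme is None:
        scheme = SegmentationScheme()
    if seq.epicardial_frames is not None:
        frames = [
            _midwall_frame(endo, epi, n_resample)
            for endo, epi in zip(seq.frames, seq.epicardial_frames)
        ]
        seq = CineSequence(tuple(frames))
    resampled = [
        ContourFrame(f.time, resample_contour(f.points, n_resample)) for f in seq.frames
    ]
    seq_r = CineSequence(tuple(resampled))
    ref_idx = end_diastole_index(seq_r)
    es_idx = end_systole_index(seq_r)
    centroid = (
        scheme.centroid
        if scheme.centroid is not None
        else polygon_centroid(seq_r.frames[ref_idx].points)
    )
    ref_lengths = segment_arc_lengths(
        seq_r.frames[ref_idx], scheme, centroid=centroid, strict=False
    )
    n_frames = len(seq_r.frames)
    strains = np.zeros((n_frames, scheme.n_segments))
    diffs = np.zeros((n_frames, scheme.n_segments))
    for j, frame in enumerate(seq_r.frames):
        if j == ref_idx:
            lengths = ref_lengths
        else:
            lengths = segment_arc_lengths(frame, scheme, centroid=centroid, strict=False)
        strains[j] = circumferential_strain(ref_lengths, lengths)
        diffs[j] = strain_differential(strains[j])
    return StrainMap(
        times=seq_r.times,
        reference_frame_index=ref_idx,
        end_systole_frame_index=es_idx,
        strains=strains,
        differentials=diffs,
    )
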