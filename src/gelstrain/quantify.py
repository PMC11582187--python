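"""Scalar histology and apoptosis read-outs.

These are the simple ratio and geometry formulas applied to counted nuclei
and traced wall contours: the TUNEL-positive fraction, the circumferential
infarct percentage, and the minimum LV wall thickness between the
endocardial and epicardial outlines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LinearRing, Point, Polygon

from .errors import DataError, GeometryError
from .strain import resample_contour

__all__ = [
    "CountPair",
    "WallGeometry",
    "tunel_fraction",
    "infarct_percentage",
    "min_wall_thickness",
]


@dataclass(frozen=True)
class CountPair:
    """Positive and total nucleus counts from a stained section."""

    positives: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise DataError("total count must be > 0")
        if not 0 <= self.positives <= self.total:
            raise DataError("positives must be in [0, total]")


@dataclass(frozen=True)
class WallGeometry:
    """Nested endo-/epicardial wall outlines (mm) with optional fibrotic arc.

    ``fibrotic_fraction`` is the annotated fraction of the wall circumference
    occupied by fibrosis, in [0, 1].
    """

    endocardial: np.ndarray
    epicardial: np.ndarray
    fibrotic_fraction: float | None = None

    def __post_init__(self) -> None:
        endo = np.asarray(self.endocardial, dtype=float)
        epi = np.asarray(self.epicardial, dtype=float)
        for name, pts in (("endocardial", endo), ("epicardial", epi)):
            if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
                raise DataError(f"{name} contour must be an (n>=3, 2) array")
        endo_poly, epi_poly = Polygon(endo), Polygon(epi)
        if not endo_poly.is_valid or not epi_poly.is_valid:
            raise GeometryError("wall contours must be simple polygons")
        if not epi_poly.contains(endo_poly):
            raise GeometryError(
                "epicardial contour must strictly contain the endocardial contour"
            )
        if self.fibrotic_fraction is not None and not 0 <= self.fibrotic_fraction <= 1:
            raise DataError("fibrotic_fraction must be in [0, 1]")
        object.__setattr__(self, "endocardial", endo)
        object.__setattr__(self, "epicardial", epi)


def tunel_fraction(counts: CountPair) -> float:
    """TUNEL-positive nucleus fraction, percent of total nuclei."""
    return counts.positives / counts.total * 100.0


def infarct_percentage(fibrotic_circumference: float, total_circumference: float) -> float:
    """Fibrotic fraction of the LV wall circumference, percent."""
    if total_circumference <= 0:
        raise DataError("total circumference must be > 0")
    if not 0 <= fibrotic_circumference <= total_circumference:
        raise DataError("fibrotic circumference must be in [0, total]")
    return fibrotic_circumference / total_circumference * 100.0


def min_wall_thickness(geom: WallGeometry, n_sample: int = 360) -> float:
    """Minimum wall thickness (mm): least epicardial-vertex distance to the
    endocardial outline.

    Both contours are resampled to ``n_sample`` equal arc-length points; the
    thickness is the minimum over epicardial vertices of the point-to-
    polyline distance to the endocardial ring.  The vertex-to-polyline form
    stays well defined for non-convex walls; accuracy improves quadratically
    with ``n_sample``.
    """
    endo = LinearRing(resample_contour(geom.endocardial, n_sample))
    epi = resample_contour(geom.epicardial, n_sample)
    return float(min(endo.distance(Point(p)) for p in epi))
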