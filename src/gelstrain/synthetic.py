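"""Seeded generators for rheology and cine inputs with known ground truth.

Every downstream analysis stage (gel-point extraction, relaxation fitting,
strain mapping) can be exercised without instrument data: these generators
produce frequency sweeps, stress-relaxation curves, and beating LV contour
sequences from explicit model parameters, so recovery can be checked against
the truth that produced them.

All generators are pure functions of their parameters and an explicit integer
seed; none touch global random state.  Moduli receive multiplicative
lognormal noise (positivity is preserved and rheometer error scales with the
signal), contour points receive additive isotropic Gaussian noise.

The LV phantom is a mid-wall ring whose local radius follows

    r(theta, t) = R * (1 + eps(theta) * s(t) / 100)

with ``s(t)`` a raised-cosine systolic pulse (0 at end-diastole, 1 at
end-systole) and ``eps(theta)`` the per-angle peak strain profile: the
healthy peak strain (about -20 %, contraction) outside the infarct arc, the
infarct peak strain (>= 0, passive stretch) inside it, cosine-blended over a
transition rim.  Because strain is imposed on the radius, the per-sector
circumferential strain of the truth is simply the bin average of
``eps(theta)`` — analytic ground truth for the strain pipeline.  Defaults
are scaled to a rat heart (radius 3.5 mm, 4 Hz heart rate); ``pig_phantom``
gives a 25 mm, 1.3 Hz preset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError
from .rheology import (
    FrequencySweep,
    MaxwellSpectrum,
    RelaxationCurve,
    complex_moduli,
    relaxation_modulus,
)
from .strain import CineSequence, ContourFrame, SegmentationScheme

__all__ = [
    "LVPhantomSpec",
    "SyntheticLVTruth",
    "generate_sweep",
    "generate_relaxation_curve",
    "generate_lv_cycle",
    "pig_phantom",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean lognormal factors with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=np.sqrt(sigma2), size=shape)


def generate_sweep(
    spectrum: MaxwellSpectrum,
    f_min: float = 0.1,
    f_max: float = 10.0,
    n_points: int = 30,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> FrequencySweep:
    """Simulated oscillatory frequency sweep of a Maxwell spectrum.

    Frequencies are log-spaced over [f_min, f_max] Hz (the instrument
    protocol range by default); G' and G'' are the analytic moduli times
    independent unit-mean lognormal factors of coefficient of variation
    ``noise_cv``.
    """
    if not 0 < f_min < f_max:
        raise DataError("need 0 < f_min < f_max")
    if n_points < 2:
        raise DataError("need at least 2 points")
    if noise_cv < 0:
        raise DataError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    f = np.geomspace(f_min, f_max, n_points)
    gp, gpp = complex_moduli(spectrum, f)
    gp = gp * _lognormal_factors(rng, noise_cv, n_points)
    gpp = gpp * _lognormal_factors(rng, noise_cv, n_points)
    return FrequencySweep(f, gp, gpp)


def generate_relaxation_curve(
    spectrum: MaxwellSpectrum,
    t_max: float = 50.0,
    n_points: int = 2500,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> RelaxationCurve:
    """Simulated step-strain relaxation record on a linear time grid from 0.

    The default grid (2500 points over 50 s, i.e. 50 Hz) emulates an
    instrument recording continuously through the relaxation window.
    """
    if t_max <= 0:
        raise DataError("t_max must be > 0")
    if n_points < 4:
        raise DataError("need at least 4 points")
    if noise_cv < 0:
        raise DataError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_points)
    g = relaxation_modulus(spectrum, t) * _lognormal_factors(rng, noise_cv, n_points)
    return RelaxationCurve(t, g)


@dataclass(frozen=True)
class LVPhantomSpec:
    """Parameters of the beating-ring LV phantom (defaults: rat scale)."""

    diastolic_radius: float = 3.5  # mm, mid-wall
    wall_thickness: float = 1.6  # mm (used for paired endo/epi output)
    n_frames: int = 20  # frames per cycle
    healthy_peak_strain: float = -20.0  # percent, contraction
    infarct_peak_strain: float = 0.0  # percent, >= 0 (passive stretch)
    infarct_span: float = 90.0  # degrees of arc; 0 = healthy ring
    infarct_center: float = 90.0  # degrees, arc midline
    transition_width: float = 0.0  # degrees of cosine blend on each side
    point_noise_sd: float = 0.0  # mm, isotropic Gaussian per point
    n_points: int = 240  # contour points per frame
    period: float = 0.25  # s per cycle (rat heart rate 4 Hz)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diastolic_radius <= 0 or self.wall_thickness <= 0:
            raise DataError("radius and wall thickness must be > 0")
        if self.n_frames < 4:
            raise DataError("need at least 4 frames per cycle")
        if not 0 <= self.infarct_span < 360:
            raise DataError("infarct_span must be in [0, 360)")
        if self.transition_width < 0:
            raise DataError("transition_width must be >= 0")
        if self.infarct_span + 2 * self.transition_width >= 360:
            raise DataError(
                "infarct_span + 2*transition_width must be < 360 deg "
                "(no healthy tissue would remain)"
            )
        if self.healthy_peak_strain >= 0:
            raise DataError("healthy_peak_strain must be negative (contraction)")
        if self.infarct_span > 0 and self.infarct_peak_strain < 0:
            raise DataError("infarct_peak_strain must be >= 0 (noncontractile)")
        if self.point_noise_sd < 0:
            raise DataError("point_noise_sd must be >= 0")
        if self.n_points < 24:
            raise DataError("need at least 24 contour points")
        if self.period <= 0:
            raise DataError("period must be > 0")


def pig_phantom(**overrides) -> LVPhantomSpec:
    """Porcine-scale phantom: 25 mm mid-wall radius, 1.3 Hz heart rate."""
    base = LVPhantomSpec(
        diastolic_radius=25.0, wall_thickness=9.0, period=1.0 / 1.3
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class SyntheticLVTruth:
    """Ground truth of a generated cine.

    ``peak_segment_strains``: per-segment end-systolic strain (percent), the
    bin average of the imposed strain profile.
    ``border_boundaries``: boundary indices nearest the two infarct edges
    (empty for a healthy ring).
    """

    peak_segment_strains: np.ndarray
    border_boundaries: tuple[int, ...]
    end_diastole_index: int


def _strain_profile(spec: LVPhantomSpec):
    """eps(theta): imposed peak strain (percent) as a function of angle."""
    center = np.deg2rad(spec.infarct_center)
    half = np.deg2rad(spec.infarct_span) / 2.0
    tw = np.deg2rad(spec.transition_width)
    healthy, infarct = spec.healthy_peak_strain, spec.infarct_peak_strain

    def eps(theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if spec.infarct_span == 0:
            return np.full(theta.shape, healthy)
        d = np.abs((theta - center + np.pi) % (2.0 * np.pi) - np.pi)
        # open infarct arc: a point exactly on the edge is healthy, so the
        # radial step of a sharp-edged phantom belongs to the infarct sector
        out = np.where(d < half, infarct, healthy)
        if tw > 0:
            blend = (d >= half) & (d < half + tw)
            # cosine ramp from infarct value at the arc edge to healthy
            x = (d - half) / tw
            out = np.where(
                blend, infarct + (healthy - infarct) * 0.5 * (1 - np.cos(np.pi * x)), out
            )
        return out

    return eps


def generate_lv_cycle(
    spec: LVPhantomSpec,
    scheme: SegmentationScheme | None = None,
) -> tuple[CineSequence, SyntheticLVTruth]:
    """One cardiac cycle of a beating LV ring with a noncontractile arc.

    Returns the cine (mid-wall contours) and its ground truth relative to
    ``scheme`` (default 24 segments at reference angle 0).  The first frame
    is end-diastole; end-systole falls mid-cycle (exactly on a frame when
    ``n_frames`` is even).
    """
    if scheme is None:
        scheme = SegmentationScheme()
    rng = np.random.default_rng(spec.seed)
    eps = _strain_profile(spec)
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_points, endpoint=False)
    eps_theta = eps(theta)

    frames = []
    phases = np.arange(spec.n_frames) / spec.n_frames
    pulse = 0.5 * (1.0 - np.cos(2.0 * np.pi * phases))
    for j, s in enumerate(pulse):
        r = spec.diastolic_radius * (1.0 + eps_theta * s / 100.0)
        pts = np.c_[r * np.cos(theta), r * np.sin(theta)]
        if spec.point_noise_sd > 0:
            pts = pts + rng.normal(0.0, spec.point_noise_sd, pts.shape)
        frames.append(ContourFrame(time=float(phases[j] * spec.period), points=pts))
    seq = CineSequence(tuple(frames))

    # truth: bin-averaged imposed strain at peak systole
    s_max = float(pulse.max())
    n = scheme.n_segments
    w = scheme.sector_width
    fine = 4096
    peak = np.empty(n)
    for k in range(n):
        grid = scheme.reference_angle + (k + (np.arange(fine) + 0.5) / fine) * w
        peak[k] = eps(grid).mean() * s_max

    borders: tuple[int, ...] = ()
    if spec.infarct_span > 0:
        center = np.deg2rad(spec.infarct_center)
        half = np.deg2rad(spec.infarct_span) / 2.0
        idx = []
        for edge in (center - half, center + half):
            # boundary k lies at angle reference_angle + (k+1)*w
            k = int(round((edge - scheme.reference_angle) / w)) - 1
            idx.append(k % n)
        borders = tuple(sorted(set(idx)))

    truth = SyntheticLVTruth(
        peak_segment_strains=peak,
        border_boundaries=borders,
        end_diastole_index=0,
    )
    return seq, truth
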