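"""Recipe-to-gel-point calibration and heart-rate-matched patch selection.

A gelatin network crosslinked through two interchangeable boronate-catechol
bond chemistries — phenylboronic acid (PBA, fast exchange) and its
2-fluoro analogue (FPBA, slow exchange) reacting with dopamine catechols —
has two experimentally independent handles:

* the FPBA : (FPBA + PBA) ratio sets the gel-point *frequency* ``f_GP``,
  sliding it between the pure-component crossovers (~6 Hz for pure PBA-DA,
  0.3 Hz for pure FPBA-DA);
* the gelatin weight fraction sets the gel-point *modulus* ``G_GP`` without
  moving the frequency, over roughly 0.5-2.5 kPa.

The calibration here is built from published design points rather than a
molecular model: frequency knots map the FPBA fraction to measured ``f_GP``
values and modulus knots map gelatin wt% to measured ``G_GP``.  Frequency
interpolation is monotone piecewise-cubic (PCHIP) on (fraction, log f) so
that the curve passes through every knot and cannot oscillate; the modulus
map is linear between its two knots.

``formulation_to_modes`` goes one step further and builds an explicit
two-mode Maxwell spectrum whose numeric G'/G'' crossover lands exactly on
the calibrated gel point.  The two mode times are pinned by the
pure-component crossovers (``tau = 1/(2 pi f)``); only the weight split
between them is free, and it is solved by 1-D root finding — a linear mix of
weights does not reproduce the measured mid-ratio gel points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .errors import (
    ConstructionError,
    DataError,
    ExtrapolationWarning,
    UnachievableFrequency,
    UnachievableModulus,
)
from .rheology import (
    GelPoint,
    MaxwellMode,
    MaxwellSpectrum,
    complex_moduli,
)

__all__ = [
    "Formulation",
    "CalibrationMap",
    "SpeciesDesignPoint",
    "HeartSpec",
    "DesignResult",
    "default_calibration",
    "predict_gel_point",
    "formulation_to_modes",
    "match_formulation",
]

EGCG_MECHANICS_THRESHOLD_MM = 5.0
TUNABLE_MODULUS_RANGE_PA = (500.0, 2500.0)


@dataclass(frozen=True)
class Formulation:
    """Hydrogel recipe: gelatin wt%, FPBA/(FPBA+PBA) fraction, EGCG load (mM)."""

    gtn_wt_percent: float
    fpba_fraction: float
    egcg_mM: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.gtn_wt_percent < 100:
            raise DataError("gtn_wt_percent must be in (0, 100)")
        if not 0 <= self.fpba_fraction <= 1:
            raise DataError("fpba_fraction must be in [0, 1]")
        if self.egcg_mM < 0:
            raise DataError("egcg_mM must be >= 0")
        if self.egcg_mM > EGCG_MECHANICS_THRESHOLD_MM:
            warnings.warn(
                f"EGCG load {self.egcg_mM} mM exceeds {EGCG_MECHANICS_THRESHOLD_MM} mM; "
                "above this the drug load may alter gel mechanics",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class SpeciesDesignPoint:
    """A published recipe choice for one species, kept for the matcher.

    ``g_myo_pa`` and the thickness ratio are stored for documentation only;
    the mechanical theory linking them to the target modulus is not modelled
    here, so the matcher works from the recipe and its measured gel point.
    """

    formulation: Formulation
    target_modulus_pa: float
    g_myo_pa: float
    h_myo_mm: float
    h_graft_mm: float


@dataclass(frozen=True)
class CalibrationMap:
    """Printed design-point knots mapping recipe coordinates to gel points.

    ``frequency_knots``: (fpba_fraction, f_GP Hz), strictly decreasing in f.
    ``modulus_knots``: (gtn_wt_percent, G_GP Pa), strictly increasing.
    ``species_table``: per-species published design points for the matcher.
    ``metadata``: free-form provenance notes (e.g. which knots were reported
    with a tilde).
    """

    frequency_knots: tuple[tuple[float, float], ...]
    modulus_knots: tuple[tuple[float, float], ...]
    species_table: Mapping[str, SpeciesDesignPoint] = field(default_factory=dict)
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fk = tuple(sorted((float(a), float(b)) for a, b in self.frequency_knots))
        mk = tuple(sorted((float(a), float(b)) for a, b in self.modulus_knots))
        if len(fk) < 2 or len(mk) < 2:
            raise DataError("need at least 2 knots on each axis")
        if not all(fk[i + 1][1] < fk[i][1] for i in range(len(fk) - 1)):
            raise DataError("gel-point frequency must decrease with fpba_fraction")
        if not all(mk[i + 1][1] > mk[i][1] for i in range(len(mk) - 1)):
            raise DataError("gel-point modulus must increase with gtn wt%")
        object.__setattr__(self, "frequency_knots", fk)
        object.__setattr__(self, "modulus_knots", mk)

    @property
    def fraction_hull(self) -> tuple[float, float]:
        return self.frequency_knots[0][0], self.frequency_knots[-1][0]

    @property
    def wt_percent_hull(self) -> tuple[float, float]:
        return self.modulus_knots[0][0], self.modulus_knots[-1][0]

    @property
    def frequency_range_hz(self) -> tuple[float, float]:
        """Achievable f_GP range (low, high), Hz."""
        return self.frequency_knots[-1][1], self.frequency_knots[0][1]

    def _frequency_spline(self) -> PchipInterpolator:
        x = np.array([k[0] for k in self.frequency_knots])
        y = np.log([k[1] for k in self.frequency_knots])
        return PchipInterpolator(x, y)

    def frequency_at(self, fpba_fraction: float) -> float:
        """Interpolated gel-point frequency (Hz) at an FPBA fraction."""
        return float(np.exp(self._frequency_spline()(fpba_fraction)))

    def fraction_at(self, f_gp_hz: float) -> float:
        """FPBA fraction whose interpolated gel point is ``f_gp_hz``."""
        lo, hi = self.frequency_range_hz
        if not lo <= f_gp_hz <= hi:
            raise UnachievableFrequency(
                f"{f_gp_hz} Hz outside calibrated range [{lo}, {hi}] Hz"
            )
        spl = self._frequency_spline()
        target = np.log(f_gp_hz)
        a, b = self.fraction_hull
        return float(brentq(lambda x: spl(x) - target, a, b, xtol=1e-12))

    def modulus_at(self, gtn_wt_percent: float) -> float:
        """Interpolated gel-point modulus (Pa) at a gelatin weight percent."""
        x = np.array([k[0] for k in self.modulus_knots])
        y = np.array([k[1] for k in self.modulus_knots])
        return float(np.interp(gtn_wt_percent, x, y))

    def wt_percent_at(self, g_gp_pa: float) -> float:
        """Gelatin wt% whose interpolated gel-point modulus is ``g_gp_pa``."""
        x = np.array([k[0] for k in self.modulus_knots])
        y = np.array([k[1] for k in self.modulus_knots])
        if not y[0] <= g_gp_pa <= y[-1]:
            raise UnachievableModulus(
                f"{g_gp_pa} Pa outside calibrated knot range [{y[0]}, {y[-1]}] Pa"
            )
        return float(np.interp(g_gp_pa, y, x))


@dataclass(frozen=True)
class HeartSpec:
    """Target heart: myocardial stiffness, wall/graft thickness, rate band."""

    myocardial_modulus: float  # Pa
    wall_thickness: float  # mm
    graft_thickness: float  # mm
    heart_rate_band: tuple[float, float]  # Hz (low, high)
    species: str = ""

    def __post_init__(self) -> None:
        if min(self.myocardial_modulus, self.wall_thickness, self.graft_thickness) <= 0:
            raise DataError("modulus and thicknesses must be > 0")
        lo, hi = self.heart_rate_band
        if not (0 < lo <= hi):
            raise DataError("heart_rate_band must satisfy 0 < low <= high")


@dataclass(frozen=True)
class DesignResult:
    """Selected recipe with its predicted gel point and band check."""

    formulation: Formulation
    predicted_gel_point: GelPoint
    within_band: bool
    target_modulus: float


def default_calibration() -> CalibrationMap:
    """Calibration knots from the published rat/pig patch design points.

    Frequency knots (FPBA fraction -> f_GP): pure PBA-DA gels at ~6 Hz, pure
    FPBA-DA at 0.3 Hz, with the two selected mixed recipes at 4 Hz (fraction
    0.2, rat) and 1.3 Hz (fraction 0.6, pig).  Modulus knots (gelatin wt% ->
    G_GP): 15 wt% -> 1.3 kPa and 20 wt% -> 2.5 kPa.  The advertised tunable
    modulus range is 0.5-2.5 kPa, but only the [15, 20] wt% interval is
    pinned by published values, so that is the interpolation hull.
    """
    rat = SpeciesDesignPoint(
        formulation=Formulation(gtn_wt_percent=15.0, fpba_fraction=0.2),
        target_modulus_pa=1300.0,
        g_myo_pa=5000.0,
        h_myo_mm=2.0,
        h_graft_mm=0.3,
    )
    pig = SpeciesDesignPoint(
        formulation=Formulation(gtn_wt_percent=20.0, fpba_fraction=0.6),
        target_modulus_pa=2500.0,
        g_myo_pa=5000.0,
        h_myo_mm=9.0,
        h_graft_mm=1.0,
    )
    return CalibrationMap(
        frequency_knots=((0.0, 6.0), (0.2, 4.0), (0.6, 1.3), (1.0, 0.3)),
        modulus_knots=((15.0, 1300.0), (20.0, 2500.0)),
        species_table={"rat": rat, "pig": pig},
        metadata={
            "pure_pba_frequency": "reported as ~6 Hz; taken as exactly 6.0 Hz",
            "tunable_modulus_range_pa": "500-2500",
        },
    )


def predict_gel_point(
    formulation: Formulation,
    calibration: CalibrationMap,
    strict: bool = False,
) -> GelPoint:
    """Gel point implied by the calibration for a recipe.

    The frequency depends only on the FPBA fraction and the modulus only on
    the gelatin wt% (the two handles are experimentally independent).
    Outside the knot hull the estimate is clamped to the hull edge and an
    ``ExtrapolationWarning`` is issued, or a ``DataError`` raised in strict
    mode.
    """
    frac = formulation.fpba_fraction
    wt = formulation.gtn_wt_percent
    f_lo, f_hi = calibration.fraction_hull
    w_lo, w_hi = calibration.wt_percent_hull
    clamped_frac = min(max(frac, f_lo), f_hi)
    clamped_wt = min(max(wt, w_lo), w_hi)
    if clamped_frac != frac or clamped_wt != wt:
        msg = (
            f"formulation ({wt} wt%, fraction {frac}) outside calibration hull "
            f"wt% [{w_lo}, {w_hi}] x fraction [{f_lo}, {f_hi}]; estimate clamped"
        )
        if strict:
            raise DataError(msg)
        warnings.warn(msg, ExtrapolationWarning, stacklevel=2)
    return GelPoint(
        frequency=calibration.frequency_at(clamped_frac),
        modulus=calibration.modulus_at(clamped_wt),
    )


def _crossover_roots(w_slow: float, tau_slow: float, tau_fast: float) -> list[float]:
    """All frequencies (Hz) where G' = G'' for weights (w_slow, 1 - w_slow).

    The crossover condition sum_i w_i x_i (x_i - 1) / (1 + x_i^2) = 0 with
    x_i = omega tau_i is scale-free in total stiffness.  All roots lie
    between the two pure-component crossovers 1/(2 pi tau_i); they are
    bracketed on a dense log grid and polished by Brent's method.
    """
    weights = np.array([w_slow, 1.0 - w_slow])
    taus = np.array([tau_slow, tau_fast])

    def h(omega):
        x = np.multiply.outer(np.asarray(omega, dtype=float), taus)
        return (weights * x * (x - 1.0) / (1.0 + x * x)).sum(axis=-1)

    lo = 0.999 / tau_slow
    hi = 1.001 / tau_fast
    grid = np.geomspace(lo, hi, 2000)
    vals = h(grid)
    roots = []
    for i in np.flatnonzero(vals[:-1] * vals[1:] < 0):
        omega = brentq(lambda o: float(h(o)), grid[i], grid[i + 1], xtol=1e-15, rtol=1e-15)
        roots.append(omega / (2.0 * np.pi))
    return roots


def _solve_weight(tau_slow: float, tau_fast: float, f_target: float) -> tuple[float, int]:
    """Slow-mode weight fraction whose crossover nearest the target equals it.

    Returns the weight and the number of G' = G'' crossovers of the solved
    spectrum (a well-posed construction has exactly one).
    """

    def g(w: float) -> float:
        roots = _crossover_roots(w, tau_slow, tau_fast)
        if not roots:
            raise ConstructionError("no G'=G'' crossover for candidate weights")
        nearest = min(roots, key=lambda r: abs(np.log(r / f_target)))
        return float(np.log(nearest / f_target))

    eps = 1e-12
    if g(eps) < 0 or g(1 - eps) > 0:
        raise ConstructionError("slow-mode weight root not bracketed in (0, 1)")
    w = brentq(g, eps, 1 - eps, xtol=1e-15)
    return w, len(_crossover_roots(w, tau_slow, tau_fast))


def formulation_to_modes(
    formulation: Formulation,
    calibration: CalibrationMap,
    strict: bool = False,
) -> MaxwellSpectrum:
    """Two-mode Maxwell spectrum realizing the recipe's calibrated gel point.

    The two modes stand for the two boronate-bond populations.  Their times
    start from the pure-component crossovers, ``tau = 1/(2 pi f)`` with
    f = 6 Hz (PBA, fast) and 0.3 Hz (FPBA, slow) in the default calibration,
    and the slow-mode weight fraction is solved by Brent root finding so the
    spectrum's own G'/G'' crossover equals the calibrated prediction; the
    total stiffness is then scaled to put the crossover modulus on target.

    Two Maxwell modes separated by a factor-20 time ratio cannot present a
    *single* crossover at frequencies near the geometric middle of the range:
    the loss hump of the fast mode re-crosses the storage plateau of the slow
    one, giving three crossings, which no measured gel in this family shows.
    Where that happens the mode times are compressed geometrically toward the
    target time ``1/(2 pi f_GP)`` — the largest time spread that still yields
    a unique crossover is found by bisection — reflecting that bond exchange
    in the mixed network narrows the relaxation spectrum.  At fraction 0 or 1
    the spectrum collapses to the corresponding pure-component single mode.
    """
    target = predict_gel_point(formulation, calibration, strict=strict)
    f_slow = calibration.frequency_knots[-1][1]  # pure FPBA endpoint, lowest f
    f_fast = calibration.frequency_knots[0][1]  # pure PBA endpoint, highest f
    tau_slow0 = 1.0 / (2.0 * np.pi * f_slow)
    tau_fast0 = 1.0 / (2.0 * np.pi * f_fast)
    tau_t = 1.0 / (2.0 * np.pi * target.frequency)

    def pure(tau: float) -> MaxwellSpectrum:
        # single mode: crossover at (1/(2 pi tau), G0/2)
        return MaxwellSpectrum([MaxwellMode(2.0 * target.modulus, tau)])

    rel = lambda a, b: abs(a - b) / b
    if rel(target.frequency, f_slow) < 1e-12:
        return pure(tau_slow0)
    if rel(target.frequency, f_fast) < 1e-12:
        return pure(tau_fast0)
    if not (f_slow < target.frequency < f_fast):
        raise ConstructionError(
            f"target frequency {target.frequency} Hz outside pure-component "
            f"range ({f_slow}, {f_fast}) Hz"
        )

    def taus_at(spread: float) -> tuple[float, float]:
        # spread 1 = pure-component times; spread -> 0 collapses onto tau_t
        ts = np.exp(np.log(tau_t) + spread * (np.log(tau_slow0) - np.log(tau_t)))
        tf = np.exp(np.log(tau_t) + spread * (np.log(tau_fast0) - np.log(tau_t)))
        return ts, tf

    def attempt(spread: float) -> tuple[float, float, float, int]:
        ts, tf = taus_at(spread)
        w, n_roots = _solve_weight(ts, tf, target.frequency)
        return ts, tf, w, n_roots

    ts, tf, w_slow, n_roots = attempt(1.0)
    if n_roots != 1:
        lo, hi = 0.05, 1.0  # hi known bad; small spreads approach a single mode
        for _ in range(30):
            mid = 0.5 * (lo + hi)
            if attempt(mid)[3] == 1:
                lo = mid
            else:
                hi = mid
        ts, tf, w_slow, n_roots = attempt(0.98 * lo)  # margin off the tangency
        if n_roots != 1:
            raise ConstructionError(
                "could not construct a spectrum with a unique crossover at "
                f"{target.frequency} Hz"
            )

    unit = MaxwellSpectrum([MaxwellMode(w_slow, ts), MaxwellMode(1.0 - w_slow, tf)])
    gp_unit, _ = complex_moduli(unit, np.array([target.frequency]))
    scale = target.modulus / float(gp_unit[0])
    return MaxwellSpectrum(
        [MaxwellMode(scale * w_slow, ts), MaxwellMode(scale * (1.0 - w_slow), tf)]
    )


def match_formulation(
    heart: HeartSpec,
    calibration: CalibrationMap,
    candidates: Sequence[Formulation] | None = None,
) -> DesignResult:
    """Select a heart-rate-matched recipe for a target heart.

    With explicit ``candidates``, the one whose predicted gel-point frequency
    is closest to the heart-rate band midpoint wins.  Otherwise the species
    is looked up in the calibration's design table (the published design
    points); for an unlisted species the design point whose frequency is
    nearest the band midpoint is used.  The theory tying myocardial modulus
    and thickness ratio to an optimal patch modulus is not reimplemented
    here, so the target modulus always comes from the design table.

    Raises ``UnachievableFrequency`` if the band does not intersect the
    calibrated frequency range, and ``UnachievableModulus`` if the target
    modulus falls outside the tunable 0.5-2.5 kPa window.
    """
    lo, hi = heart.heart_rate_band
    f_lo, f_hi = calibration.frequency_range_hz
    if hi < f_lo or lo > f_hi:
        raise UnachievableFrequency(
            f"heart-rate band [{lo}, {hi}] Hz does not intersect the calibrated "
            f"gel-point range [{f_lo}, {f_hi}] Hz"
        )
    midpoint = 0.5 * (lo + hi)

    if candidates is not None:
        if not candidates:
            raise DataError("candidate set is empty")
        scored = [
            (abs(predict_gel_point(f, calibration).frequency - midpoint), i, f)
            for i, f in enumerate(candidates)
        ]
        _, _, formulation = min(scored)
        design = calibration.species_table.get(heart.species)
        target_modulus = (
            design.target_modulus_pa
            if design is not None
            else predict_gel_point(formulation, calibration).modulus
        )
    else:
        if not calibration.species_table:
            raise DataError("calibration has no species design table and no candidates given")
        design = calibration.species_table.get(heart.species)
        if design is None:
            design = min(
                calibration.species_table.values(),
                key=lambda d: abs(
                    predict_gel_point(d.formulation, calibration).frequency - midpoint
                ),
            )
        formulation = design.formulation
        target_modulus = design.target_modulus_pa

    t_lo, t_hi = TUNABLE_MODULUS_RANGE_PA
    if not t_lo <= target_modulus <= t_hi:
        raise UnachievableModulus(
            f"target modulus {target_modulus} Pa outside tunable range "
            f"[{t_lo}, {t_hi}] Pa"
        )
    gel_point = predict_gel_point(formulation, calibration)
    within = lo <= gel_point.frequency <= hi
    return DesignResult(
        formulation=formulation,
        predicted_gel_point=gel_point,
        within_band=within,
        target_modulus=target_modulus,
    )
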