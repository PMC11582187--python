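"""Linear viscoelasticity of dynamic-bond hydrogel networks.

A network crosslinked by reversible bonds behaves, in the linear regime, as a
generalized Maxwell material: a parallel set of spring-dashpot modes, each
with a stiffness ``G_i`` (Pa) and a relaxation time ``tau_i`` (s).  The
relaxation modulus is the Prony series

    G(t) = sum_i G_i * exp(-t / tau_i)

and under oscillatory shear at angular frequency ``omega = 2*pi*f`` the
storage and loss moduli are

    G'(omega)  = sum_i G_i (omega tau_i)^2 / (1 + (omega tau_i)^2)
    G''(omega) = sum_i G_i (omega tau_i)   / (1 + (omega tau_i)^2)

The gel point is the frequency at which G' crosses G''; below it the material
flows on the time scale of the deformation, above it the network responds
elastically.  For an epicardial patch this crossover is the "heart rate" of
the material: a patch whose gel point sits inside the heart-rate band relaxes
implantation prestress but still reinforces the wall during each beat.

Frequencies are user-facing in hertz throughout; the angular frequency only
appears inside formulas.  No equilibrium (infinite-time) mode is modelled:
the networks of interest are fully dynamic and relax to zero stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DataError,
    DegenerateRelaxation,
    FitError,
    MultipleCrossovers,
    NoCrossover,
)

__all__ = [
    "MaxwellMode",
    "MaxwellSpectrum",
    "FrequencySweep",
    "RelaxationCurve",
    "GelPoint",
    "RelaxationFit",
    "ConvergenceResult",
    "complex_moduli",
    "relaxation_modulus",
    "find_gel_point",
    "fit_relaxation",
    "simulate_stress",
    "cycles_to_convergence",
]

_TAU_DISTINCT_RTOL = 1e-9


@dataclass(frozen=True)
class MaxwellMode:
    """One spring-dashpot element: stiffness (Pa) and relaxation time (s)."""

    modulus_weight: float
    relaxation_time: float

    def __post_init__(self) -> None:
        if not (self.modulus_weight > 0 and np.isfinite(self.modulus_weight)):
            raise DataError(f"modulus_weight must be > 0, got {self.modulus_weight}")
        if not (self.relaxation_time > 0 and np.isfinite(self.relaxation_time)):
            raise DataError(f"relaxation_time must be > 0, got {self.relaxation_time}")


@dataclass(frozen=True)
class MaxwellSpectrum:
    """An ordered set of Maxwell modes (slowest first).

    Modes are sorted by decreasing relaxation time on construction; two modes
    with relaxation times equal to within relative 1e-9 are rejected because
    the pair is indistinguishable from a single mode of summed weight.
    """

    modes: tuple[MaxwellMode, ...]

    def __init__(self, modes: Sequence[MaxwellMode]) -> None:
        modes = tuple(sorted(modes, key=lambda m: -m.relaxation_time))
        if len(modes) < 1:
            raise DataError("a spectrum needs at least one mode")
        taus = np.array([m.relaxation_time for m in modes])
        if np.any(np.abs(np.diff(taus)) <= _TAU_DISTINCT_RTOL * taus[:-1]):
            raise DataError("relaxation times must be distinct (rel. 1e-9)")
        object.__setattr__(self, "modes", modes)

    @property
    def weights(self) -> np.ndarray:
        return np.array([m.modulus_weight for m in self.modes])

    @property
    def times(self) -> np.ndarray:
        return np.array([m.relaxation_time for m in self.modes])

    @property
    def total_stiffness(self) -> float:
        """Instantaneous shear modulus G_0 = sum of mode weights, Pa."""
        return float(self.weights.sum())

    @property
    def characteristic_time(self) -> float:
        """Weight-averaged relaxation time sum(G_i tau_i) / sum(G_i), s."""
        w = self.weights
        return float((w * self.times).sum() / w.sum())


@dataclass(frozen=True)
class FrequencySweep:
    """Oscillatory sweep: frequencies (Hz) with storage/loss moduli (Pa)."""

    frequencies: np.ndarray
    storage_moduli: np.ndarray
    loss_moduli: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        gp = np.asarray(self.storage_moduli, dtype=float)
        gpp = np.asarray(self.loss_moduli, dtype=float)
        if not (f.ndim == gp.ndim == gpp.ndim == 1 and len(f) == len(gp) == len(gpp)):
            raise DataError("frequencies and moduli must be 1-D of equal length")
        if len(f) < 2:
            raise DataError("a sweep needs at least 2 points")
        if not np.all(np.diff(f) > 0) or not np.all(f > 0):
            raise DataError("frequencies must be strictly increasing and > 0")
        if np.any(gp < 0) or np.any(gpp < 0) or not np.all(np.isfinite(gp) & np.isfinite(gpp)):
            raise DataError("moduli must be finite and nonnegative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "storage_moduli", gp)
        object.__setattr__(self, "loss_moduli", gpp)


@dataclass(frozen=True)
class RelaxationCurve:
    """Step-strain relaxation record: times (s) and relaxation modulus (Pa).

    If the instrument recorded stress rather than modulus, divide by the
    step-strain amplitude before constructing the curve.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise DataError("times and values must be 1-D of equal length")
        if len(t) < 4:
            raise DataError("a relaxation curve needs at least 4 samples")
        if t[0] < 0 or not np.all(np.diff(t) > 0):
            raise DataError("times must be strictly increasing with first >= 0")
        if not np.all(np.isfinite(v)):
            raise DataError("values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class GelPoint:
    """Crossover of G' and G'': frequency (Hz) and common modulus (Pa)."""

    frequency: float
    modulus: float

    def __post_init__(self) -> None:
        if not (self.frequency > 0 and self.modulus > 0):
            raise DataError("gel point frequency and modulus must be > 0")


def complex_moduli(
    spectrum: MaxwellSpectrum, frequencies: Sequence[float] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Storage and loss moduli (Pa) of a Maxwell spectrum at given frequencies (Hz)."""
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise DataError("frequencies must be > 0")
    x = 2.0 * np.pi * f[..., None] * spectrum.times  # omega * tau, per mode
    x2 = x * x
    g_prime = (spectrum.weights * x2 / (1.0 + x2)).sum(axis=-1)
    g_double_prime = (spectrum.weights * x / (1.0 + x2)).sum(axis=-1)
    return g_prime, g_double_prime


def relaxation_modulus(spectrum: MaxwellSpectrum, time: float | np.ndarray) -> float | np.ndarray:
    """Prony-series relaxation modulus G(t) = sum G_i exp(-t/tau_i), Pa."""
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise DataError("time must be >= 0")
    g = (spectrum.weights * np.exp(-t[..., None] / spectrum.times)).sum(axis=-1)
    return float(g) if np.ndim(time) == 0 else g


def sample_sweep(
    spectrum: MaxwellSpectrum, f_min: float, f_max: float, n_points: int
) -> FrequencySweep:
    """Noise-free log-spaced sweep computed from the spectrum."""
    if not (0 < f_min < f_max):
        raise DataError("need 0 < f_min < f_max")
    f = np.geomspace(f_min, f_max, n_points)
    gp, gpp = complex_moduli(spectrum, f)
    return FrequencySweep(f, gp, gpp)


def find_gel_point(sweep: FrequencySweep) -> GelPoint:
    """Locate the G' = G'' crossover of a frequency sweep.

    The crossover is found on log-log axes: ``log(G'/G'')`` is interpolated
    linearly in ``log f`` between the two samples bracketing its single sign
    change, and the modulus is the common value of the log-linear interpolants
    of G' and G'' at that frequency.  For a single Maxwell mode
    ``G'/G'' = omega*tau`` exactly, so the recovered frequency is exact
    regardless of sampling density; the modulus converges quadratically with
    grid refinement.

    Raises
    ------
    NoCrossover
        if G' - G'' has the same sign at every sample.
    MultipleCrossovers
        if more than one sign change is present; the bracketing frequency
        pairs are attached to the exception for diagnosis.
    """
    f = sweep.frequencies
    gp = sweep.storage_moduli
    gpp = sweep.loss_moduli
    if np.any(gp <= 0) or np.any(gpp <= 0):
        raise DataError("crossover search needs strictly positive moduli")
    d = np.log(gp) - np.log(gpp)
    sign_change = np.flatnonzero(d[:-1] * d[1:] < 0)
    exact = np.flatnonzero(d == 0.0)
    if len(exact) > 0 and len(sign_change) == 0:
        if len(exact) > 1:
            raise MultipleCrossovers([(f[i], f[i]) for i in exact])
        i = int(exact[0])
        return GelPoint(float(f[i]), float(gp[i]))
    if len(sign_change) == 0:
        raise NoCrossover("G' - G'' does not change sign over the sweep")
    if len(sign_change) > 1:
        raise MultipleCrossovers([(float(f[i]), float(f[i + 1])) for i in sign_change])
    i = int(sign_change[0])
    lf = np.log(f)
    t = d[i] / (d[i] - d[i + 1])  # root of the log-log linear interpolant
    log_f_gp = lf[i] + t * (lf[i + 1] - lf[i])
    log_g_gp = np.log(gp[i]) + t * (np.log(gp[i + 1]) - np.log(gp[i]))
    return GelPoint(float(np.exp(log_f_gp)), float(np.exp(log_g_gp)))


class RelaxationFit(NamedTuple):
    """Result of an exponential-sum fit to a relaxation curve."""

    spectrum: MaxwellSpectrum
    characteristic_time: float
    residual_norm: float


def fit_relaxation(curve: RelaxationCurve, n_modes: int = 2) -> RelaxationFit:
    """Least-squares Prony-series fit of a stress-relaxation curve.

    The default two-mode fit matches a network with two dynamic-bond
    populations of distinct exchange kinetics.  Relaxation times are
    initialized log-spaced across the observed time window and weights at
    ``G(0)/n_modes``; the optimization runs on log-parameters, which keeps
    all parameters positive and scale-free.  Residuals are *relative*
    (``(model - data) / data``): rheometer error grows with the signal, so
    this weighting keeps the small late-time / fast-mode contributions from
    being swamped by the large initial modulus.

    Returns the fitted spectrum, the weight-averaged characteristic time
    ``sum(G_i tau_i)/sum(G_i)`` (s), and the residual 2-norm (Pa).
    """
    if n_modes < 1:
        raise DataError("n_modes must be >= 1")
    t, v = curve.times, curve.values
    if len(t) < 2 * n_modes + 1:
        raise DataError(f"need at least {2 * n_modes + 1} samples for {n_modes} modes")
    if np.any(v <= 0):
        raise DataError("relaxation values must be positive")
    # Non-decaying data cannot come from a Prony series with positive weights.
    head = v[: max(2, len(v) // 5)].mean()
    tail = v[-max(2, len(v) // 5):].mean()
    if tail >= 0.99 * head:
        raise DegenerateRelaxation(
            f"data do not decay (head mean {head:.4g} Pa, tail mean {tail:.4g} Pa)"
        )

    t_lo = max(t[1] if t[0] == 0 else t[0], 1e-12)
    tau0 = np.geomspace(t_lo, t[-1], n_modes + 2)[1:-1] if n_modes > 1 else np.array(
        [np.sqrt(t_lo * t[-1])]
    )
    g0 = np.full(n_modes, v[0] / n_modes)
    p0 = np.log(np.concatenate([g0, tau0]))

    def model_at(p: np.ndarray) -> np.ndarray:
        g = np.exp(p[:n_modes])
        tau = np.exp(p[n_modes:])
        return (g * np.exp(-t[:, None] / tau)).sum(axis=1)

    def residuals(p: np.ndarray) -> np.ndarray:
        return (model_at(p) - v) / v

    sol = least_squares(residuals, p0, method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"relaxation fit did not converge: {sol.message}")
    g = np.exp(sol.x[:n_modes])
    tau = np.exp(sol.x[n_modes:])
    try:
        spectrum = MaxwellSpectrum([MaxwellMode(gi, ti) for gi, ti in zip(g, tau)])
    except DataError as exc:  # collapsed modes
        raise FitError(f"fit produced a degenerate spectrum: {exc}") from exc
    resid = float(np.linalg.norm(model_at(sol.x) - v))
    return RelaxationFit(spectrum, spectrum.characteristic_time, resid)


def simulate_stress(
    spectrum: MaxwellSpectrum,
    times: Sequence[float] | np.ndarray,
    strains: Sequence[float] | np.ndarray,
) -> np.ndarray:
    """Boltzmann-superposition stress (Pa) for a piecewise-linear strain history.

    Evaluates ``sigma(t) = integral G(t-s) de/ds ds`` exactly for a strain
    history that is linear between samples, using a per-mode exponential
    update (the integral is closed-form on each interval).  The response is
    exactly linear in the strain history; a step strain reproduces
    ``eps0 * G(t)``.

    ``strains`` are dimensionless fractions; ``times`` must be strictly
    increasing.  The stress is reported at the sample times, starting from a
    stress-free state at the first time.
    """
    t = np.asarray(times, dtype=float)
    eps = np.asarray(strains, dtype=float)
    if t.ndim != 1 or eps.ndim != 1 or len(t) != len(eps):
        raise DataError("times and strains must be 1-D of equal length")
    if len(t) < 1:
        raise DataError("empty strain history")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    g = spectrum.weights
    tau = spectrum.times
    sigma = np.empty(len(t))
    state = eps[0] * g  # instantaneous response to any initial step from zero
    sigma[0] = state.sum()
    for k in range(1, len(t)):
        dt = t[k] - t[k - 1]
        rate = (eps[k] - eps[k - 1]) / dt
        decay = np.exp(-dt / tau)
        state = state * decay + rate * g * tau * (1.0 - decay)
        sigma[k] = state.sum()
    return sigma


class ConvergenceResult(NamedTuple):
    """Cycle at which per-cycle peak stress stabilizes (1-based), and whether it did."""

    cycle: int
    converged: bool


def cycles_to_convergence(
    stress: Sequence[float] | np.ndarray,
    samples_per_cycle: int,
    tolerance: float,
) -> ConvergenceResult:
    """First cycle whose peak stress settles to within ``tolerance`` (relative).

    The series is split into whole cycles of ``samples_per_cycle`` samples and
    the peak absolute stress extracted per cycle.  Returns the smallest
    1-based cycle index ``k >= 2`` such that every subsequent cycle-to-cycle
    peak change stays below ``tolerance`` relative to the preceding peak.  If
    the peaks never settle, returns the number of whole cycles with
    ``converged=False``.
    """
    s = np.asarray(stress, dtype=float)
    if samples_per_cycle < 1:
        raise DataError("samples_per_cycle must be >= 1")
    if tolerance <= 0:
        raise DataError("tolerance must be > 0")
    n_cycles = len(s) // samples_per_cycle
    if n_cycles < 2:
        raise DataError("need at least 2 whole cycles")
    peaks = np.abs(s[: n_cycles * samples_per_cycle]).reshape(n_cycles, samples_per_cycle).max(axis=1)
    ref = np.where(peaks[:-1] > 0, peaks[:-1], np.finfo(float).tiny)
    rel = np.abs(np.diff(peaks)) / ref
    ok = rel < tolerance  # ok[j]: cycle j+2 within tolerance of cycle j+1
    stable_from = n_cycles
    for j in range(len(ok) - 1, -1, -1):
        if not ok[j]:
            break
        stable_from = j + 2
    if stable_from <= n_cycles and ok[stable_from - 2]:
        return ConvergenceResult(stable_from, True)
    return ConvergenceResult(n_cycles, False)
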