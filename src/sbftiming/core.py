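"""Striatal beat-frequency (SBF) interval-timing simulator and analysis toolkit.

The SBF model times intervals in the seconds-to-minutes range by coincidence
detection over a bank of cortical oscillators.  A memory block stores the state
of every oscillator at the reinforced (criterion) time ``c``; during a trial a
readout unit compares the instantaneous oscillator states against that stored
reference, typically with a dot product, and responds maximally when the two
patterns line up again — which happens at ``t = c`` even though ``c`` far
exceeds any single oscillator period, because nearby frequencies beat against
each other.

This module provides, in the order a timing experiment runs:

* oscillator banks — abstract cosine phase oscillators on an evenly spaced
  frequency grid, and dimensionless Morris-Lecar (ML) conductance-based
  neurons integrated with a classical fixed-step 4th-order scheme, with
  period measurement, bias-current regime scanning and Hz calibration;
* parameter-noise sampling — multiplicative criterion-time ("memory") and
  frequency noise of uniform or normal family, parameterised by relative
  standard deviation;
* the coincidence-detection engine — reference and running weight vectors,
  the output function, and noiseless closed forms (Dirichlet kernels);
* envelope analysis — sinc-envelope width, the transcendental equation for
  envelope maxima, Gaussian envelope fits, width-versus-criterion ordinary
  least squares, the mean-value half-width equation, and superposition
  (timescale-invariance) metrics;
* end-to-end experiments with seeded, bit-reproducible configurations.

Two headline behaviours of the model are exposed by the analysis layer: with
noiseless oscillators the output width is set only by the frequency band and
the number of oscillators and is *independent* of the criterion (no scalar
timing), while criterion-time noise of any distribution makes the output
envelope Gaussian with a width that grows linearly with the criterion.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray
from scipy.optimize import brentq, curve_fit
from scipy.signal import find_peaks
from scipy.stats import linregress

__all__ = [
    # errors
    "ConfigurationError", "IntegrationError", "NotOscillatingError",
    "CalibrationError", "EmptyRangeError", "DegenerateWeightsError",
    "FitError", "InsufficientDataError", "NoSolutionError", "AlignmentError",
    # oscillator banks
    "OscillatorBankSpec", "make_frequency_grid", "cosine_state", "CosineBank",
    # Morris-Lecar
    "MLParams", "MLTrace", "ml_derivatives", "integrate_ml",
    "PeriodEstimate", "measure_period", "find_oscillatory_range",
    "calibrate_frequency", "calibrate_bank", "MLBank",
    # noise
    "NoiseSpec", "sample_multipliers",
    # engine
    "WeightVector", "OutputTrace", "reference_weights", "running_weights",
    "output_function", "closed_form_output", "memory_noise_output",
    "dirichlet_kernel", "simulation_grid",
    # envelope analysis
    "sinc_envelope", "noiseless_width", "envelope_maxima", "extract_envelope",
    "GaussianFit", "fit_gaussian", "ScalarRegression", "width_vs_criterion",
    "ScalarWidthSolution", "solve_scalar_width", "mean_abs_deviation",
    "SuperpositionReport", "superpose",
    # experiments
    "ExperimentConfig", "ResultBundle", "run_cosine_noiseless",
    "run_cosine_noisy", "run_ml_noise_sweep",
    "load_config", "save_config", "trace_to_csv", "trace_from_csv",
    "configure_logging",
]

logger = logging.getLogger("sbftiming")

# ----------------------------------------------------------------------------
# Configuration constants and errors
# ----------------------------------------------------------------------------

#: Fraction of a trace discarded as start-up transient before period analysis.
TRANSIENT_FRACTION = 0.2
#: Minimum number of periods discarded as transient (when estimable).
TRANSIENT_PERIODS = 5
#: Peak-to-peak amplitude below which a trace counts as non-oscillating.
OSCILLATION_AMPLITUDE_TOL = 0.02
#: Relative rate tolerance for Hz calibration of ML neurons.
CALIBRATION_RTOL = 0.005
#: Samples per stored ML limit-cycle period.
WAVEFORM_SAMPLES = 1024
#: Target integration steps per ML oscillation period.
STEPS_PER_PERIOD = 200


class ConfigurationError(ValueError):
    """Invalid model or experiment configuration."""


class IntegrationError(RuntimeError):
    """Numerical integration produced a non-finite state."""


class NotOscillatingError(RuntimeError):
    """A trace contains too few oscillation cycles to measure a period."""


class CalibrationError(RuntimeError):
    """Frequency calibration could not reach the requested rate."""


class EmptyRangeError(RuntimeError):
    """No oscillatory point found on the scanned bias-current grid."""


class DegenerateWeightsError(RuntimeError):
    """All raw oscillator states vanished; weights cannot be normalised."""


class FitError(RuntimeError):
    """Least-squares envelope fit failed to converge."""


class InsufficientDataError(RuntimeError):
    """Too few envelope points in the fit window."""


class NoSolutionError(RuntimeError):
    """The half-width equation has no root in the searched bracket."""


class AlignmentError(RuntimeError):
    """Rescaled traces do not share a common relative-time support."""


def configure_logging(level: str = "INFO") -> None:
    """Attach a simple stderr handler to the package logger."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


# ----------------------------------------------------------------------------
# Oscillator bank: evenly spaced frequency grid and cosine phase oscillators
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class OscillatorBankSpec:
    """Frequency grid of the oscillator bank.

    The ``n_osc`` base frequencies are evenly spaced, ``f_k = f1 + k*df`` for
    ``k = 1..n_osc`` with ``df = (f2 - f1)/n_osc``, so they fill ``(f1, f2]``
    and the upper bound is attained.

    Parameters
    ----------
    f1, f2 : float
        Lower and upper frequency bound in Hz, ``f2 > f1 > 0``.
    n_osc : int
        Number of oscillators (``>= 1``).
    """

    f1: float
    f2: float
    n_osc: int

    def __post_init__(self) -> None:
        if not (self.f2 > self.f1 > 0):
            raise ConfigurationError(
                f"need f2 > f1 > 0, got f1={self.f1}, f2={self.f2}")
        if int(self.n_osc) < 1 or int(self.n_osc) != self.n_osc:
            raise ConfigurationError(f"n_osc must be a positive integer, got {self.n_osc}")

    @property
    def df(self) -> float:
        """Frequency increment (f2 - f1) / n_osc in Hz."""
        return (self.f2 - self.f1) / self.n_osc


def make_frequency_grid(spec: OscillatorBankSpec) -> NDArray[np.float64]:
    """Return the ``n_osc`` base frequencies ``f1 + df, ..., f2`` (Hz)."""
    return np.linspace(spec.f1 + spec.df, spec.f2, spec.n_osc)


def cosine_state(f: float, t) -> NDArray[np.float64] | float:
    """State ``cos(2*pi*f*t)`` of a phase oscillator reset in phase at t=0."""
    if np.any(np.asarray(f) <= 0):
        raise ConfigurationError("oscillator frequency must be positive")
    return np.cos(2.0 * np.pi * f * np.asarray(t, dtype=float))


class CosineBank:
    """Bank of cosine phase oscillators on an :class:`OscillatorBankSpec` grid.

    All oscillators start in phase (state 1) at ``t = 0``, mimicking the
    neuromodulatory "start gun" that resets the bank at trial onset.
    """

    kind = "cosine"

    def __init__(self, spec: OscillatorBankSpec):
        self.spec = spec
        self.frequencies = make_frequency_grid(spec)

    @property
    def n_osc(self) -> int:
        return self.spec.n_osc

    def states(self, t, rate_multipliers=None) -> NDArray[np.float64]:
        """Oscillator states at time(s) ``t`` (s).

        Returns an array of shape ``t.shape + (n_osc,)``.  ``rate_multipliers``
        (length ``n_osc``) multiplicatively perturbs each base frequency, which
        is how frequency noise enters.
        """
        t = np.asarray(t, dtype=float)
        freqs = self.frequencies if rate_multipliers is None \
            else self.frequencies * np.asarray(rate_multipliers, dtype=float)
        return np.cos(2.0 * np.pi * t[..., None] * freqs)


# ----------------------------------------------------------------------------
# Morris-Lecar neuron: dimensionless two-variable conductance model
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class MLParams:
    """Dimensionless Morris-Lecar constants.

    ``x1`` is the membrane potential and ``x2`` the slow potassium
    activation.  Defaults are the standard dimensionless constants; the
    calcium conductance ``g_ca`` together with the bias current ``i0``
    selects the excitability class: ``g_ca = 1.0`` gives Type 1 (saddle-node
    on invariant circle, arbitrarily low firing rates at onset), ``g_ca =
    0.5`` gives Type 2 (Hopf, finite onset frequency and a near-sinusoidal
    membrane waveform).
    """

    g_ca: float = 0.5
    g_k: float = 2.0
    g_l: float = 0.5
    e_ca: float = 1.0
    e_k: float = -0.7
    e_l: float = -0.5
    v1: float = -0.01
    v2: float = 0.15
    v3: float = 0.1
    v4: float = 0.145
    xi: float = 1.0 / 3.0
    i0: float = 0.2

    @classmethod
    def type1(cls, i0: float = 0.15) -> "MLParams":
        return cls(g_ca=1.0, i0=i0)

    @classmethod
    def type2(cls, i0: float = 0.2) -> "MLParams":
        return cls(g_ca=0.5, i0=i0)

    def m_inf(self, x1):
        """Instantaneous calcium activation sigmoid."""
        return 0.5 * (1.0 + np.tanh((x1 - self.v1) / self.v2))

    def w_inf(self, x1):
        """Steady-state potassium activation sigmoid."""
        return 0.5 * (1.0 + np.tanh((x1 - self.v3) / self.v4))

    def lambda0(self, x1):
        """Voltage-dependent potassium rate (cosh form)."""
        return np.cosh((x1 - self.v3) / (2.0 * self.v4))


@dataclass
class MLTrace:
    """Integrated membrane trajectory on a uniform time grid."""

    t: NDArray[np.float64]
    x1: NDArray[np.float64]
    x2: NDArray[np.float64]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def ml_derivatives(state, params: MLParams, i0=None):
    """Right-hand side ``(dx1, dx2)`` of the Morris-Lecar flow.

    ``dx1 = -I_Ca - I_K - I_L + i0`` with ``I_Ca = g_ca*m_inf(x1)*(x1-e_ca)``,
    ``I_K = g_k*x2*(x1-e_k)``, ``I_L = g_l*(x1-e_l)``, and
    ``dx2 = xi*lambda0(x1)*(w_inf(x1)-x2)``.

    ``i0`` may override (and broadcast against) ``params.i0`` so a whole bank
    with per-neuron bias currents integrates in one vectorised sweep.
    """
    x1, x2 = state
    bias = params.i0 if i0 is None else i0
    i_ca = params.g_ca * params.m_inf(x1) * (x1 - params.e_ca)
    i_k = params.g_k * x2 * (x1 - params.e_k)
    i_l = params.g_l * (x1 - params.e_l)
    dx1 = -i_ca - i_k - i_l + bias
    dx2 = params.xi * params.lambda0(x1) * (params.w_inf(x1) - x2)
    return dx1, dx2


def _rk4_integrate(params: MLParams, i0, t_end: float, dt: float, init,
                   record: bool = True):
    """Classical fixed-step RK4 sweep, vectorised over a bias-current array.

    Returns ``(t, X1, X2)`` with state histories of shape ``(n_steps+1, n)``
    when ``record`` is true, else the final state only.
    """
    i0 = np.atleast_1d(np.asarray(i0, dtype=float))
    n = i0.size
    x1 = np.broadcast_to(np.asarray(init[0], dtype=float), (n,)).copy()
    x2 = np.broadcast_to(np.asarray(init[1], dtype=float), (n,)).copy()
    n_steps = int(round(t_end / dt))
    if record:
        X1 = np.empty((n_steps + 1, n))
        X2 = np.empty((n_steps + 1, n))
        X1[0], X2[0] = x1, x2
    for s in range(n_steps):
        k1a, k1b = ml_derivatives((x1, x2), params, i0)
        k2a, k2b = ml_derivatives((x1 + 0.5 * dt * k1a, x2 + 0.5 * dt * k1b), params, i0)
        k3a, k3b = ml_derivatives((x1 + 0.5 * dt * k2a, x2 + 0.5 * dt * k2b), params, i0)
        k4a, k4b = ml_derivatives((x1 + dt * k3a, x2 + dt * k3b), params, i0)
        x1 = x1 + (dt / 6.0) * (k1a + 2 * k2a + 2 * k3a + k4a)
        x2 = x2 + (dt / 6.0) * (k1b + 2 * k2b + 2 * k3b + k4b)
        if record:
            X1[s + 1], X2[s + 1] = x1, x2
        if (s & 0xFF) == 0 and not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
            raise IntegrationError(f"non-finite state at step {s} (t={s * dt:.3f})")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise IntegrationError(f"non-finite state at step {n_steps} (t={t_end:.3f})")
    t = np.arange(n_steps + 1) * dt
    if record:
        return t, X1, X2
    return t[-1], x1, x2


def integrate_ml(params: MLParams, t_end: float, dt: float,
                 init: tuple[float, float] = (0.0, 0.0)) -> MLTrace:
    """Integrate one Morris-Lecar neuron over ``[0, t_end]`` with step ``dt``.

    Fixed-step classical 4th-order Runge-Kutta: deterministic and of
    convergence order 4 (halving ``dt`` shrinks the terminal error ~16x).
    """
    if t_end <= 0 or dt <= 0:
        raise ConfigurationError("t_end and dt must be positive")
    t, X1, X2 = _rk4_integrate(params, params.i0, t_end, dt, init, record=True)
    return MLTrace(t=t, x1=X1[:, 0], x2=X2[:, 0])


@dataclass(frozen=True)
class PeriodEstimate:
    """Oscillation period from mean upward-crossing spacing.

    ``cv`` is the coefficient of variation of the individual cycle spacings
    (a clean limit cycle gives cv ~ 0); ``n_cycles`` counts the spacings.
    """

    period: float
    cv: float
    n_cycles: int

    def __float__(self) -> float:
        return self.period


def _upward_crossings(t: NDArray, x: NDArray) -> NDArray:
    """Times of upward crossings of the trace mean, linearly interpolated."""
    xm = x - x.mean()
    idx = np.nonzero((xm[:-1] < 0) & (xm[1:] >= 0))[0]
    if idx.size == 0:
        return np.empty(0)
    frac = -xm[idx] / (xm[idx + 1] - xm[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def measure_period(trace: MLTrace,
                   transient_fraction: float = TRANSIENT_FRACTION) -> PeriodEstimate:
    """Measure the oscillation period of a trace.

    The first ``transient_fraction`` of the trace (or five estimated periods,
    whichever is longer) is discarded, then the period is the mean spacing of
    upward crossings of the post-transient mean.

    Raises :class:`NotOscillatingError` when fewer than two crossings remain
    or the post-transient amplitude is negligible.
    """
    start = int(transient_fraction * len(trace.t))
    t, x = trace.t[start:], trace.x1[start:]
    if np.ptp(x) < OSCILLATION_AMPLITUDE_TOL:
        raise NotOscillatingError("post-transient amplitude below tolerance")
    crossings = _upward_crossings(t, x)
    if crossings.size < 2:
        raise NotOscillatingError(f"only {crossings.size} mean crossings found")
    # second pass: push the transient to >= 5 estimated periods if possible
    period0 = float(np.diff(crossings).mean())
    t5 = trace.t[0] + max(transient_fraction * (trace.t[-1] - trace.t[0]),
                          TRANSIENT_PERIODS * period0)
    keep = trace.t >= t5
    if keep.sum() > 2 and (trace.t[-1] - t5) >= 3 * period0:
        t, x = trace.t[keep], trace.x1[keep]
        crossings = _upward_crossings(t, x)
        if crossings.size < 2:
            raise NotOscillatingError("too few crossings after transient removal")
    spacings = np.diff(crossings)
    period = float(spacings.mean())
    cv = float(spacings.std() / period) if spacings.size > 1 else 0.0
    return PeriodEstimate(period=period, cv=cv, n_cycles=int(spacings.size))


def _batch_periods(t: NDArray, X1: NDArray,
                   transient_fraction: float = 0.4) -> NDArray:
    """Per-column period of a batch trace; NaN where not oscillating."""
    start = int(transient_fraction * len(t))
    out = np.full(X1.shape[1], np.nan)
    for k in range(X1.shape[1]):
        x = X1[start:, k]
        if np.ptp(x) < OSCILLATION_AMPLITUDE_TOL:
            continue
        crossings = _upward_crossings(t[start:], x)
        if crossings.size >= 3:
            out[k] = np.diff(crossings).mean()
    return out


def find_oscillatory_range(params: MLParams, i0_grid: Sequence[float],
                           t_end: float = 1500.0, dt: float = 0.02,
                           refine_tol: float = 1e-3) -> tuple[float, float]:
    """Bias-current interval supporting a sustained limit cycle.

    Every grid point is integrated (vectorised) from rest-like initial
    conditions; a point is oscillatory when the post-transient trace still
    shows mean crossings with non-negligible amplitude.  Each edge is then
    refined by bisection between the outermost oscillatory grid point and its
    non-oscillatory neighbour (or the grid end).

    Returns ``(i0_min, i0_max)``; raises :class:`EmptyRangeError` when no
    grid point oscillates.
    """
    grid = np.asarray(sorted(i0_grid), dtype=float)
    t, X1, _ = _rk4_integrate(params, grid, t_end, dt, (0.0, 0.0))
    periods = _batch_periods(t, X1)
    mask = np.isfinite(periods)
    if not mask.any():
        raise EmptyRangeError("no oscillatory bias current on the grid")
    first, last = np.nonzero(mask)[0][[0, -1]]

    def oscillates(i0: float) -> bool:
        tt, xx, _ = _rk4_integrate(params, [i0], t_end, dt, (0.0, 0.0))
        return np.isfinite(_batch_periods(tt, xx)[0])

    def bisect(lo: float, hi: float, lo_osc: bool) -> float:
        # invariant: exactly one of (lo, hi) oscillates; returns the boundary
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            if oscillates(mid) == lo_osc:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    lo_edge = grid[first] if first == 0 else bisect(grid[first - 1], grid[first], False)
    hi_edge = grid[last] if last == len(grid) - 1 else bisect(grid[last], grid[last + 1], True)
    return float(lo_edge), float(hi_edge)


# ----------------------------------------------------------------------------
# Calibration of ML neurons to firing rates in Hz
# ----------------------------------------------------------------------------
#
# The model equations are dimensionless; firing rates in Hz require a time
# scale (seconds per dimensionless time unit).  One global time scale is used
# for the whole bank and per-neuron rate differences come from per-neuron bias
# currents inside the oscillatory regime; if the attainable dimensionless rate
# interval cannot cover the requested Hz band under a single time scale, the
# calibration falls back to per-neuron time scales (and logs it).

#: Empirical Type 2 (g_ca=0.5) oscillatory bias-current interval, interior.
TYPE2_I0_RANGE = (0.145, 0.295)


def _rate_of(params: MLParams, i0, dt: float = 0.02,
             n_periods: float = 14.0, guess_period: float = 12.0) -> NDArray:
    """Dimensionless firing rate(s) at bias current(s) ``i0`` (vectorised)."""
    t_end = (TRANSIENT_PERIODS + n_periods) * guess_period
    t, X1, _ = _rk4_integrate(params, i0, t_end, dt, (0.0, 0.0))
    return 1.0 / _batch_periods(t, X1)


def calibrate_frequency(params: MLParams, target_f: float,
                        search_range: tuple[float, float] | None = None,
                        time_scale: float | None = None,
                        rtol: float = CALIBRATION_RTOL,
                        max_iter: int = 60) -> tuple[float, float]:
    """Find ``(i0, time_scale)`` so the neuron fires at ``target_f`` Hz.

    With ``time_scale`` given (seconds per dimensionless unit) the target
    dimensionless rate is ``target_f * time_scale`` and ``i0`` is found by
    monotone bisection on the measured rate inside ``search_range``.  When the
    target rate lies outside the attainable interval — or ``time_scale`` is
    None — the time scale itself is (re)derived from the rate measured at the
    mid-range bias current.
    """
    lo, hi = search_range if search_range is not None else TYPE2_I0_RANGE
    r_lo, r_hi = _rate_of(params, [lo, hi])
    if not (np.isfinite(r_lo) and np.isfinite(r_hi)):
        raise CalibrationError(
            f"search range ({lo}, {hi}) is not inside the oscillatory regime")
    increasing = r_hi >= r_lo
    r_min, r_max = min(r_lo, r_hi), max(r_lo, r_hi)
    if time_scale is None or not (r_min <= target_f * time_scale <= r_max):
        if time_scale is not None:
            logger.warning(
                "target rate %.4g outside attainable dimensionless interval "
                "(%.4g, %.4g); adjusting time scale", target_f * time_scale, r_min, r_max)
        mid = 0.5 * (lo + hi)
        r_mid = float(_rate_of(params, [mid])[0])
        time_scale = r_mid / target_f
        # mid-range bias already realises the target under the derived scale
        return mid, time_scale
    target_rate = target_f * time_scale
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = float(_rate_of(params, [mid])[0])
        if abs(r_mid - target_rate) <= rtol * target_rate:
            return mid, time_scale
        if (r_mid < target_rate) == increasing:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach {target_f} Hz within {max_iter} iterations")


class MLBank:
    """Calibrated bank of Type 2 Morris-Lecar oscillators.

    Each neuron sits on its deterministic limit cycle from ``t = 0`` (the
    start-gun reset places every neuron at its membrane-potential maximum), so
    its state at any trial time is a phase read-out of one stored
    limit-cycle period.  ``states`` returns the normalised membrane
    potential — the limit-cycle waveform with its cycle mean removed,
    rescaled to unit peak magnitude (range within ``[-1, 1]``) — evaluated
    by periodic linear interpolation of the stored waveform.
    """

    kind = "ml"

    def __init__(self, spec: OscillatorBankSpec, params: MLParams,
                 i0: NDArray, time_scale: NDArray, rates_hz: NDArray,
                 waveforms: NDArray, dimless_rates: NDArray):
        self.spec = spec
        self.params = params
        self.i0 = np.asarray(i0, dtype=float)
        self.time_scale = np.asarray(time_scale, dtype=float)  # s per dimensionless unit
        self.rates_hz = np.asarray(rates_hz, dtype=float)      # realised rates
        self.dimless_rates = np.asarray(dimless_rates, dtype=float)
        self.waveforms = np.asarray(waveforms, dtype=float)    # (n_osc, WAVEFORM_SAMPLES)
        self.frequencies = self.rates_hz

    @property
    def n_osc(self) -> int:
        return self.spec.n_osc

    def states(self, t, rate_multipliers=None) -> NDArray[np.float64]:
        """Membrane-potential states (rescaled to [-1, 1]) at time(s) ``t`` s."""
        t = np.asarray(t, dtype=float)
        rates = self.rates_hz if rate_multipliers is None \
            else self.rates_hz * np.asarray(rate_multipliers, dtype=float)
        phase = (t[..., None] * rates) % 1.0
        pos = phase * WAVEFORM_SAMPLES
        idx = pos.astype(np.intp)
        frac = pos - idx
        nxt = (idx + 1) % WAVEFORM_SAMPLES
        wf = self.waveforms
        k = np.broadcast_to(np.arange(self.n_osc), idx.shape)
        return wf[k, idx] * (1.0 - frac) + wf[k, nxt] * frac

    def save(self, path: str | Path) -> None:
        """Cache the calibration to an ``.npz`` file."""
        np.savez_compressed(
            path, f1=self.spec.f1, f2=self.spec.f2, n_osc=self.spec.n_osc,
            g_ca=self.params.g_ca, i0=self.i0, time_scale=self.time_scale,
            rates_hz=self.rates_hz, dimless_rates=self.dimless_rates,
            waveforms=self.waveforms)

    @classmethod
    def load(cls, path: str | Path, params: MLParams | None = None) -> "MLBank":
        z = np.load(path)
        spec = OscillatorBankSpec(float(z["f1"]), float(z["f2"]), int(z["n_osc"]))
        params = params if params is not None else MLParams(g_ca=float(z["g_ca"]))
        return cls(spec, params, z["i0"], z["time_scale"], z["rates_hz"],
                   z["waveforms"], z["dimless_rates"])


def calibrate_bank(spec: OscillatorBankSpec,
                   params: MLParams | None = None,
                   i0_range: tuple[float, float] = TYPE2_I0_RANGE,
                   n_tab: int = 41,
                   rtol: float = CALIBRATION_RTOL) -> MLBank:
    """Calibrate a full ML bank to the Hz frequency grid of ``spec``.

    The dimensionless rate is tabulated on a bias-current grid inside the
    oscillatory regime, a global time scale is chosen so the requested Hz band
    maps into the attainable dimensionless rate interval (falling back to
    per-neuron time scales when the band is too wide), and per-neuron bias
    currents are then refined by vectorised bisection until every realised
    rate is within ``rtol`` of its target.  Finally one limit-cycle period per
    neuron is stored, phase-aligned to its membrane-potential maximum and
    rescaled to ``[-1, 1]``.
    """
    params = params if params is not None else MLParams.type2()
    targets_hz = make_frequency_grid(spec)

    # 1. tabulate the rate curve on the bias-current grid
    tab_i0 = np.linspace(i0_range[0], i0_range[1], n_tab)
    tab_rate = _rate_of(params, tab_i0)
    ok = np.isfinite(tab_rate)
    if ok.sum() < 2:
        raise CalibrationError("oscillatory regime not found on tabulation grid")
    tab_i0, tab_rate = tab_i0[ok], tab_rate[ok]
    if not np.all(np.diff(tab_rate) > 0):
        # keep the largest strictly increasing prefix run
        brk = np.nonzero(np.diff(tab_rate) <= 0)[0]
        stop = int(brk[0]) + 1 if brk.size else len(tab_rate)
        tab_i0, tab_rate = tab_i0[:stop], tab_rate[:stop]
    r_lo, r_hi = float(tab_rate[0]), float(tab_rate[-1])

    # 2. global time scale if the Hz band fits, else per-neuron scales
    band_ratio = spec.f2 / spec.f1
    if r_hi / r_lo >= band_ratio:
        ts = math.sqrt((r_lo * r_hi) / (spec.f1 * spec.f2))
        target_rates = targets_hz * ts
        time_scale = np.full(spec.n_osc, ts)
        per_neuron_ts = False
    else:
        logger.warning(
            "attainable rate ratio %.3f < band ratio %.3f; "
            "using per-neuron time scales", r_hi / r_lo, band_ratio)
        target_rates = np.linspace(r_lo * 1.02, r_hi * 0.98, spec.n_osc)
        time_scale = None  # assigned after measuring
        per_neuron_ts = True

    # 3. vectorised bisection on the tabulated brackets
    lo = np.interp(target_rates, tab_rate, tab_i0) - 1.5 * np.diff(tab_i0).mean()
    hi = np.interp(target_rates, tab_rate, tab_i0) + 1.5 * np.diff(tab_i0).mean()
    lo = np.clip(lo, tab_i0[0], tab_i0[-1])
    hi = np.clip(hi, tab_i0[0], tab_i0[-1])
    guess_period = float(1.0 / tab_rate.mean())
    rates = None
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        rates = _rate_of(params, mid, guess_period=guess_period)
        if np.isnan(rates).any():
            raise CalibrationError("lost oscillation during bisection refinement")
        done = np.abs(rates - target_rates) <= rtol * target_rates
        if done.all():
            break
        below = rates < target_rates
        lo = np.where(below, mid, lo)
        hi = np.where(~below, mid, hi)
    i0 = 0.5 * (lo + hi)

    # 4. store one phase-aligned limit-cycle period per neuron
    dt = (1.0 / float(np.max(rates))) / STEPS_PER_PERIOD
    t_end = (TRANSIENT_PERIODS + 10.0) / float(np.min(rates))
    t, X1, _ = _rk4_integrate(params, i0, t_end, dt, (0.0, 0.0))
    waveforms = np.empty((spec.n_osc, WAVEFORM_SAMPLES))
    measured = np.empty(spec.n_osc)
    phase_grid = np.arange(WAVEFORM_SAMPLES) / WAVEFORM_SAMPLES
    for k in range(spec.n_osc):
        crossings = _upward_crossings(t[len(t) // 2:], X1[len(t) // 2:, k])
        if crossings.size < 3:
            raise CalibrationError(f"neuron {k}: no sustained limit cycle after calibration")
        period = float(np.diff(crossings).mean())
        measured[k] = 1.0 / period
        # one full cycle starting at the membrane-potential maximum
        a = crossings[-3]
        seg_t = np.arange(a, a + 2 * period, dt / 4)
        seg_x = np.interp(seg_t, t, X1[:, k])
        i_max = int(np.argmax(seg_x[: int(len(seg_x) / 2)]))
        t_max = seg_t[i_max]
        cyc = np.interp(t_max + phase_grid * period, t, X1[:, k])
        # zero-mean, unit-magnitude state: the beat interference the
        # coincidence detector reads lives in the oscillatory part, and a DC
        # component would swamp the memory-averaged reference weights
        cyc = cyc - cyc.mean()
        waveforms[k] = cyc / np.abs(cyc).max()

    if per_neuron_ts:
        time_scale = measured / targets_hz
    rates_hz = measured / time_scale
    err = np.abs(rates_hz - targets_hz) / targets_hz
    logger.info("bank calibrated: max rate error %.3g (tolerance %.3g)", err.max(), rtol)
    return MLBank(spec, params, i0, time_scale, rates_hz, waveforms, measured)


# ----------------------------------------------------------------------------
# Parameter noise: multiplicative fluctuation of criterion times / frequencies
# ----------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative parameter fluctuation ``value*(1 + x)``.

    ``family`` is ``none``, ``uniform`` or ``normal``; ``level`` is the
    relative standard deviation of ``x`` for every family (the uniform
    half-width is ``level*sqrt(3)`` so levels are comparable across
    families); ``n_samples`` is the number of draws (``Nc`` for criterion
    noise, ``Nf`` for frequency noise).
    """

    family: str = "none"
    level: float = 0.0
    n_samples: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("none", "uniform", "normal"):
            raise ConfigurationError(f"unknown noise family {self.family!r}")
        if self.level < 0:
            raise ConfigurationError("noise level must be >= 0")
        if self.family == "none" and self.level != 0:
            raise ConfigurationError("family 'none' requires level 0")
        if self.family != "none" and self.level == 0:
            raise ConfigurationError("zero level requires family 'none'")
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")


def sample_multipliers(noise: NoiseSpec,
                       rng: np.random.Generator | None = None,
                       size: int | tuple | None = None) -> NDArray[np.float64]:
    """Draw multipliers ``1 + x`` according to a :class:`NoiseSpec`.

    ``x`` is N(0, level^2) for the normal family and uniform on
    ``[-level*sqrt(3), +level*sqrt(3)]`` for the uniform family, so the
    standard deviation equals ``level`` in both cases.  Reproducible under
    ``noise.seed`` when no generator is supplied.
    """
    shape = size if size is not None else noise.n_samples
    if noise.family == "none":
        return np.ones(shape)
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    if noise.family == "normal":
        x = rng.normal(0.0, noise.level, shape)
    else:
        half = noise.level * math.sqrt(3.0)
        x = rng.uniform(-half, half, shape)
    return 1.0 + x


_NO_NOISE = NoiseSpec()


# ----------------------------------------------------------------------------
# Coincidence-detection engine: weights and the output function
# ----------------------------------------------------------------------------


@dataclass
class WeightVector:
    """Normalised per-oscillator state vector.

    ``signed`` mode divides the raw summed states by ``norm`` — the largest
    raw state magnitude over the bank, at most the number of criterion
    samples — keeping every weight in ``[-1, 1]``; ``positive`` mode maps
    the signed weights affinely onto ``[0, 1]``.
    """

    weights: NDArray[np.float64]
    criterion: float
    mode: str
    norm: float


def _normalise(raw: NDArray, mode: str) -> tuple[NDArray, float]:
    signed_max = float(raw.max())
    norm = float(np.abs(raw).max())
    if norm == 0.0:
        raise DegenerateWeightsError("all raw oscillator states are zero")
    if signed_max <= 0.0:
        # every summed state is non-positive; the magnitude convention below
        # still applies but the situation is worth flagging
        logger.warning("non-positive raw maximum; normalising by max |state|")
    # normalising by the largest state magnitude keeps every weight in
    # [-1, 1]; it coincides with the signed maximum whenever the latter is
    # also the largest in magnitude (the generic dense-bank case)
    w = raw / norm
    if mode == "positive":
        w = 0.5 * (w + 1.0)
    elif mode != "signed":
        raise ConfigurationError(f"unknown weight mode {mode!r}")
    return w, norm


def reference_weights(bank, c: float, mem_noise: NoiseSpec = _NO_NOISE,
                      mode: str = "signed",
                      rng: np.random.Generator | None = None,
                      rate_multipliers=None) -> WeightVector:
    """Stored (memory) weights: oscillator states summed over noisy criteria.

    Each of the ``Nc`` memory samples is a retrieved criterion
    ``c*(1 + x_c)``; the raw weight of oscillator ``k`` is the sum of its
    states over those retrieved times, normalised by the maximum raw value
    over the bank.  Non-positive retrieved criteria are redrawn (times must
    stay positive); the redraw count is logged.
    """
    if c <= 0:
        raise ConfigurationError("criterion time must be positive")
    rng = rng if rng is not None else np.random.default_rng(mem_noise.seed)
    mult = sample_multipliers(mem_noise, rng)
    redraws = 0
    bad = mult <= 0
    while bad.any():
        redraws += int(bad.sum())
        mult[bad] = sample_multipliers(mem_noise, rng, size=int(bad.sum()))
        bad = mult <= 0
    if redraws:
        logger.warning("redrew %d non-positive criterion samples", redraws)
    raw = bank.states(c * mult, rate_multipliers).sum(axis=0)
    w, norm = _normalise(raw, mode)
    return WeightVector(weights=w, criterion=c, mode=mode, norm=norm)


def running_weights(bank, t, freq_noise: NoiseSpec | None = None,
                    mode: str = "signed",
                    rng: np.random.Generator | None = None,
                    rate_multipliers=None) -> WeightVector:
    """Instantaneous weights at trial time ``t`` (no memory averaging).

    With a frequency :class:`NoiseSpec`, the states are averaged over ``Nf``
    per-oscillator frequency draws before normalisation.
    """
    t = float(t)
    if freq_noise is not None and freq_noise.family != "none":
        rng = rng if rng is not None else np.random.default_rng(freq_noise.seed)
        mult = sample_multipliers(freq_noise, rng,
                                  size=(freq_noise.n_samples, bank.n_osc))
        raw = np.mean([bank.states(np.array(t), m) for m in mult], axis=0)
    else:
        raw = bank.states(np.array(t), rate_multipliers)
    w, norm = _normalise(raw, mode)
    return WeightVector(weights=w, criterion=t, mode=mode, norm=norm)


@dataclass
class OutputTrace:
    """Time-resolved output of the coincidence detector, with provenance."""

    t: NDArray[np.float64]
    value: NDArray[np.float64]
    config: dict = field(default_factory=dict)

    @property
    def criterion(self) -> float | None:
        return self.config.get("criterion")


def simulation_grid(spec: OscillatorBankSpec, c: float,
                    level: float = 0.0, dt: float | None = None) -> NDArray:
    """Default evaluation grid around a criterion.

    Step ``min(1/(20*f2), c/2000)`` resolves the fastest oscillator and the
    envelope; the half window covers the noiseless main lobe and, under
    memory noise, +-5 criterion standard deviations.
    """
    if dt is None:
        dt = min(1.0 / (20.0 * spec.f2), c / 2000.0)
    lobe = 2.0 / (spec.f2 - spec.f1)
    half = max(10.0 * lobe, 5.0 * level * c)
    n_half = int(math.ceil(half / dt))
    n_lo = min(n_half, int((c - dt) / dt))  # keep the grid strictly positive
    return c + np.arange(-n_lo, n_half + 1) * dt


def output_function(bank, c: float, t_grid=None,
                    mem_noise: NoiseSpec = _NO_NOISE,
                    freq_noise: NoiseSpec = _NO_NOISE,
                    mode: str = "signed",
                    similarity: str = "dot") -> OutputTrace:
    """SBF output: projection of running weights on the reference weights.

    ``similarity='dot'`` gives ``sum_k w(k,c) w(k,t)``; ``'cosine_angle'``
    gives the absolute cosine of the angle between the two weight vectors
    (bounded by 1, equal to 1 at ``t = c`` in the noiseless case).  Memory
    noise enters through the reference weights; frequency noise averages the
    entire output over ``Nf`` independently perturbed banks, each with its
    own reference and running weights.
    """
    if similarity not in ("dot", "cosine_angle"):
        raise ConfigurationError(f"unknown similarity {similarity!r}")
    if t_grid is None:
        t_grid = simulation_grid(bank.spec, c, mem_noise.level)
    t_grid = np.asarray(t_grid, dtype=float)
    dt = float(np.min(np.diff(t_grid))) if t_grid.size > 1 else np.inf
    if dt > 1.0 / (2.0 * bank.spec.f2):
        warnings.warn("time grid coarser than half the fastest period; "
                      "output may be aliased", stacklevel=2)
    rng = np.random.default_rng(
        freq_noise.seed if freq_noise.family != "none" else mem_noise.seed)
    n_draws = freq_noise.n_samples if freq_noise.family != "none" else 1
    acc = np.zeros_like(t_grid)
    for _ in range(n_draws):
        rate_mult = None
        if freq_noise.family != "none":
            rate_mult = sample_multipliers(freq_noise, rng, size=bank.n_osc)
        ref = reference_weights(bank, c, mem_noise, mode, rng=rng,
                                rate_multipliers=rate_mult)
        run_raw = bank.states(t_grid, rate_mult)        # (n_t, n_osc)
        # same normalisation convention as _normalise, vectorised per row
        run_norm = np.abs(run_raw).max(axis=1, keepdims=True)
        run_w = run_raw / run_norm
        if mode == "positive":
            run_w = 0.5 * (run_w + 1.0)
        val = run_w @ ref.weights
        if similarity == "cosine_angle":
            val = np.abs(val) / (np.linalg.norm(run_w, axis=1)
                                 * np.linalg.norm(ref.weights))
        acc += val
    cfg = {"criterion": c, "bank": asdict(bank.spec), "kind": bank.kind,
           "mode": mode, "similarity": similarity,
           "mem_noise": asdict(mem_noise), "freq_noise": asdict(freq_noise)}
    return OutputTrace(t=t_grid, value=acc / n_draws, config=cfg)


# --- noiseless closed forms (cosine banks) ----------------------------------


def dirichlet_kernel(tau, spec: OscillatorBankSpec) -> NDArray:
    """One branch of the noiseless cosine output.

    ``0.5*sin(pi*n*df*tau)*cos(pi*(2*f1+(n+1)*df)*tau)/sin(pi*df*tau)`` with
    the removable singularities at ``sin(pi*df*tau)=0`` replaced by their
    analytic (L'Hopital) limits.  The carrier frequency ``2*f1+(n+1)*df =
    f1+f2+df`` makes the identity with the direct sum over the grid
    ``f_k = f1 + k*df`` exact; textbook statements often print the
    dense-bank form ``f1+f2``, which differs at order ``df``.
    """
    tau = np.asarray(tau, dtype=float)
    den = np.sin(np.pi * spec.df * tau)
    num = np.sin(np.pi * (spec.f2 - spec.f1) * tau)
    carrier = np.cos(np.pi * (spec.f1 + spec.f2 + spec.df) * tau)
    small = np.abs(den) < 1e-9
    ratio = np.where(
        small,
        spec.n_osc * np.cos(np.pi * (spec.f2 - spec.f1) * tau)
        / np.cos(np.pi * spec.df * tau),
        num / np.where(small, 1.0, den))
    return 0.5 * ratio * carrier


def closed_form_output(spec: OscillatorBankSpec, c: float, t_grid) -> OutputTrace:
    """Noiseless cosine output in closed form: two mirrored Dirichlet kernels.

    Equals the direct double sum ``sum_k cos(2*pi*f_k*c)*cos(2*pi*f_k*t)``
    exactly; the two branches peak at ``t = +c`` and ``t = -c``.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    value = dirichlet_kernel(t_grid - c, spec) + dirichlet_kernel(t_grid + c, spec)
    return OutputTrace(t=t_grid, value=value,
                       config={"criterion": c, "bank": asdict(spec),
                               "kind": "cosine", "closed_form": True})


def memory_noise_output(spec: OscillatorBankSpec, c: float, t_grid,
                        mem_noise: NoiseSpec,
                        rng: np.random.Generator | None = None) -> OutputTrace:
    """Criterion-noise output: per-sample Dirichlet kernels, retained branch.

    Each of the ``Nc`` retrieved criteria contributes one kernel centred on
    itself; only the physically realisable branch (centred near ``+c``) is
    kept.  Pass explicit multipliers through ``rng`` seeding for
    reproducibility.
    """
    if mem_noise.family == "none":
        raise ConfigurationError("memory_noise_output requires a noisy NoiseSpec")
    t_grid = np.asarray(t_grid, dtype=float)
    rng = rng if rng is not None else np.random.default_rng(mem_noise.seed)
    cj = c * sample_multipliers(mem_noise, rng)
    value = dirichlet_kernel(t_grid[:, None] - cj[None, :], spec).sum(axis=1)
    return OutputTrace(t=t_grid, value=value,
                       config={"criterion": c, "bank": asdict(spec),
                               "kind": "cosine", "mem_noise": asdict(mem_noise),
                               "branch": "retained"})


# ----------------------------------------------------------------------------
# Envelope analysis
# ----------------------------------------------------------------------------


def sinc_envelope(spec: OscillatorBankSpec, c: float, t) -> NDArray | float:
    """Slow (Dirichlet/sinc) envelope of the noiseless output.

    ``sin(pi*n_osc*df*(t-c)) / sin(pi*df*(t-c))`` with value ``n_osc`` at the
    removable singularity ``t = c``.  Peaks at ``t = c``; its width depends
    only on the frequency band and oscillator count — not on ``c``.
    """
    tau = np.asarray(t, dtype=float) - c
    den = np.sin(np.pi * spec.df * tau)
    small = np.abs(den) < 1e-9
    out = np.where(
        small,
        spec.n_osc * np.cos(np.pi * spec.n_osc * spec.df * tau)
        / np.cos(np.pi * spec.df * tau),
        np.sin(np.pi * spec.n_osc * spec.df * tau) / np.where(small, 1.0, den))
    return out if out.shape else float(out)


def noiseless_width(spec: OscillatorBankSpec) -> float:
    """Full width at half maximum of the noiseless sinc envelope (s).

    Solves ``envelope(c - w/2) = envelope(c)/2`` on the first lobe by
    bracketed root-finding; independent of the criterion by construction.
    """
    n = spec.n_osc

    def f(w):
        return sinc_envelope(spec, 0.0, -w / 2.0) - 0.5 * n

    # envelope(c - w/2) first hits zero at w/2 = 1/(n_osc*df)
    hi = 2.0 / (spec.n_osc * spec.df)
    lo = 1e-12 * hi
    if f(lo) <= 0 or f(hi) >= 0:
        raise FitError(f"half-max bracket failed on [{lo}, {hi}]: "
                       f"f(lo)={f(lo):.3g}, f(hi)={f(hi):.3g}")
    return float(brentq(f, lo, hi, xtol=1e-14))


def envelope_maxima(spec: OscillatorBankSpec, n_branches: int = 5) -> list[tuple[float, float]]:
    """Positions and heights of the output-envelope local maxima.

    The local maxima of ``|sin(n x)/sin(x)|`` (with ``x = pi*df*(t-c)``)
    solve ``tan(n*x0) = n*tan(x0)``; the corresponding output heights are
    ``y0 = 0.5*sin(n*x0)*cos((2*f1/df + n)*x0)/sin(x0)``.  The pairs are
    independent of the criterion time.  The trivial central maximum
    ``(0, n/2 * ...)`` is returned first, then one root per side lobe.
    """
    n = spec.n_osc
    pairs = [(0.0, 0.5 * n)]  # central peak: limit of the defining expressions
    if n < 2:
        return pairs[:1]

    def g(x):
        return math.tan(n * x) - n * math.tan(x)

    for b in range(1, n_branches + 1):
        # one root per continuity branch of tan(n*x), i.e. between the poles
        # (b+0.5)*pi/n and (b+1.5)*pi/n, where tan(n*x) sweeps -inf -> +inf
        eps = 1e-9 / n
        lo = (b - 0.5) * math.pi / n + eps
        hi = (b + 0.5) * math.pi / n - eps
        if hi >= math.pi / 2:
            break
        try:
            x0 = brentq(g, lo, hi, xtol=1e-15)
        except ValueError as exc:
            raise FitError(f"bracketing failed on side-lobe branch {b}") from exc
        # carrier index 2*f1/df + n + 1 matches the exact closed form
        y0 = 0.5 * math.sin(n * x0) * math.cos((2 * spec.f1 / spec.df + n + 1) * x0) \
            / math.sin(x0)
        pairs.append((x0, y0))
    return pairs


def extract_envelope(trace: OutputTrace,
                     window: tuple[float, float] | None = None
                     ) -> tuple[NDArray, NDArray]:
    """Upper envelope of a trace: local maxima of ``|value|``.

    Plateaus are attributed to their leftmost point.  Falls back to all
    points when the trace has fewer than five interior maxima (the trace is
    then already an envelope, e.g. an exactly sampled Gaussian).
    """
    t, v = trace.t, np.abs(trace.value)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, v = t[m], v[m]
    peaks, props = find_peaks(v, plateau_size=(None, None))
    left = props.get("left_edges")
    if left is not None and len(left):
        peaks = np.asarray(left)
    if len(peaks) < 5:
        return t, v
    return t[peaks], v[peaks]


@dataclass
class GaussianFit:
    """Least-squares Gaussian envelope fit.

    Model: ``A*exp(-(t-center)^2/(2*sigma^2)) + baseline``.  The baseline
    absorbs the flat coincidence floor a noisy or DC-carrying bank produces
    far from the criterion; it fits to ~0 for zero-mean (cosine) states.
    """

    amplitude: float
    center: float
    sigma: float
    r2: float
    baseline: float = 0.0
    n_points: int = 0


def _gauss(t, a, mu, s, b=0.0):
    return a * np.exp(-((t - mu) ** 2) / (2.0 * s * s)) + b


def fit_gaussian(trace: OutputTrace,
                 window: tuple[float, float] | None = None,
                 sigma_min: float | None = None) -> GaussianFit:
    """Fit a Gaussian to the upper envelope of an output trace.

    The envelope is the set of local maxima of ``|value|`` inside ``window``
    (default: the whole trace).  ``sigma_min`` bounds the width from below;
    the experiment runners pass the noiseless envelope width, which is a
    physical floor (noise can only broaden the output), preventing the fit
    from locking onto a single speckle spike.  Raises
    :class:`InsufficientDataError` with fewer than five envelope points and
    :class:`FitError` on non-convergence; a poor (e.g. monotone) input is
    reported through a low ``r2`` rather than a silent success.
    """
    tp, ep = extract_envelope(trace, window)
    if len(tp) < 5:
        raise InsufficientDataError(f"only {len(tp)} envelope points in window")
    wsum = ep.sum()
    if wsum <= 0:
        raise FitError("envelope is identically zero in the window")
    b0 = float(np.quantile(ep, 0.1))
    mu0 = float(np.sum(tp * np.maximum(ep - b0, 0)) / max(np.sum(np.maximum(ep - b0, 0)), 1e-300))
    s0 = float(np.sqrt(np.sum(np.maximum(ep - b0, 0) * (tp - mu0) ** 2)
                       / max(np.sum(np.maximum(ep - b0, 0)), 1e-300)))
    span = float(tp[-1] - tp[0])
    s_lo = sigma_min if sigma_min is not None else float(np.diff(tp).min()) / 2.0
    s0 = min(max(s0, s_lo * 1.001, float(np.diff(tp).min())), span)
    emax = float(ep.max())
    lower = (0.0, float(tp[0]), s_lo, 0.0)
    upper = (2.0 * emax, float(tp[-1]), 10.0 * span, emax)
    try:
        popt, _ = curve_fit(_gauss, tp, ep, p0=(emax - b0, mu0, s0, b0),
                            bounds=(lower, upper), method="trf", maxfev=20000,
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
    except RuntimeError as exc:
        resid = ep - _gauss(tp, emax - b0, mu0, s0, b0)
        raise FitError(f"Gaussian fit did not converge (initial residual "
                       f"rms {np.sqrt(np.mean(resid**2)):.3g})") from exc
    resid = ep - _gauss(tp, *popt)
    ss_tot = float(np.sum((ep - ep.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else -math.inf
    return GaussianFit(amplitude=float(popt[0]), center=float(popt[1]),
                       sigma=float(abs(popt[2])), r2=r2,
                       baseline=float(popt[3]), n_points=len(tp))


@dataclass
class ScalarRegression:
    """Ordinary least squares of output width on criterion time.

    ``slope`` is dimensionless (seconds of width per second of criterion);
    a slope indistinguishable from zero means the scalar property fails,
    a positive slope with high ``r2`` means it holds.
    """

    slope: float
    intercept: float
    r2: float
    stderr: float
    points: list[tuple[float, float]]


def width_vs_criterion(fits: Iterable[tuple[float, GaussianFit | float]]
                       ) -> ScalarRegression:
    """OLS regression of Gaussian width on criterion time (>= 3 criteria)."""
    pts = [(float(c), f.sigma if isinstance(f, GaussianFit) else float(f))
           for c, f in fits]
    if len(pts) < 3:
        raise ConfigurationError("need at least 3 (criterion, width) points")
    cs = np.array([p[0] for p in pts])
    ws = np.array([p[1] for p in pts])
    if np.allclose(ws, ws[0]):
        # degenerate: exactly constant widths (noiseless case); OLS slope is 0
        return ScalarRegression(slope=0.0, intercept=float(ws[0]), r2=0.0,
                                stderr=0.0, points=pts)
    res = linregress(cs, ws)
    return ScalarRegression(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2), stderr=float(res.stderr),
                            points=pts)


def mean_abs_deviation(noise: NoiseSpec) -> float:
    """Mean of ``|x|`` under the noise pdf (default mean-value abscissa theta)."""
    if noise.family == "normal":
        return noise.level * math.sqrt(2.0 / math.pi)
    if noise.family == "uniform":
        return noise.level * math.sqrt(3.0) / 2.0
    raise ConfigurationError("theta is undefined for noiseless specs")


@dataclass
class ScalarWidthSolution:
    """Solution of the mean-value half-width equation.

    ``y0`` is the dimensionless half-width abscissa solving the half-maximum
    condition of the noise-averaged output; the output half-width is then
    ``sigma = 2*c*theta*y0``, linear in the criterion ``c`` by construction
    (``theta`` is the mean-value abscissa of the noise pdf).
    """

    theta: float
    y0: float
    c: float
    residual: float

    @property
    def sigma(self) -> float:
        return 2.0 * self.c * self.theta * self.y0

    def sigma_at(self, c: float) -> float:
        """Width at another criterion; ``sigma_at(c)/c`` is constant."""
        return 2.0 * c * self.theta * self.y0


def solve_scalar_width(spec: OscillatorBankSpec, c: float, theta: float,
                       y_max: float = 2.0, scan: int = 4096) -> ScalarWidthSolution:
    """Solve the half-maximum equation of the noise-averaged output.

    The mean-value form of the noise-averaged output is a Dirichlet kernel
    evaluated at ``t - c - c*theta``; in the dimensionless half-width
    variable ``y0`` the half-maximum condition reads::

        K(c*theta*(1 - y0)) = K(c*theta) / 2,

    with ``K(u) = sin(pi*(f2-f1)*u)*cos(pi*(f1+f2)*u)/sin(pi*df*u)``.  The
    first root in ``(0, y_max)`` is found by scan plus bracketed
    root-finding.  Raises :class:`NoSolutionError` when no sign change exists
    (the equation is existence-conditioned).
    """
    if theta == 0:
        raise ConfigurationError("theta must be nonzero")

    def kernel(u):
        return 2.0 * float(dirichlet_kernel(u, spec))

    u0 = c * theta
    half = 0.5 * kernel(u0)

    def f(y):
        return kernel(u0 * (1.0 - y)) - half

    ys = np.linspace(0.0, y_max, scan)
    vals = np.array([f(y) for y in ys])
    sign = np.sign(vals)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    if flips.size == 0:
        raise NoSolutionError(f"no half-maximum crossing in (0, {y_max})")
    a, b = ys[flips[0]], ys[flips[0] + 1]
    y0 = float(brentq(f, a, b, xtol=1e-15, rtol=8.9e-16))
    return ScalarWidthSolution(theta=theta, y0=y0, c=c, residual=abs(f(y0)))


@dataclass
class SuperpositionReport:
    """Timescale-invariance check: rescaled traces compared pairwise.

    Each trace is mapped to relative time ``t/c`` and unit peak; scalar-
    compliant outputs superimpose (small ``max_rms``), constant-width
    outputs do not.
    """

    max_rms: float
    pairwise: dict[tuple[float, float], float]
    grid: NDArray


def superpose(traces: Sequence[OutputTrace], n_grid: int = 2001,
              use_envelope: bool = True,
              smooth: float | None = None) -> SuperpositionReport:
    """Rescale traces by criterion and peak, report max pairwise RMS distance.

    ``smooth`` (seconds) applies a fixed-width moving average to ``|value|``
    before rescaling, turning a speckled single-realisation response into the
    smooth rate profile the behavioural superposition test compares; the
    window is absolute, so it cannot itself fabricate timescale invariance.
    """
    if len(traces) < 2:
        raise ConfigurationError("need at least two traces to superpose")
    rel = []
    for tr in traces:
        c = tr.criterion
        if c is None:
            raise ConfigurationError("trace lacks a criterion in its config")
        if smooth is not None:
            dt = float(np.min(np.diff(tr.t)))
            k = max(1, int(round(smooth / dt)))
            kernel = np.ones(k) / k
            tp, ep = tr.t, np.convolve(np.abs(tr.value), kernel, mode="same")
        elif use_envelope:
            tp, ep = extract_envelope(tr)
        else:
            tp, ep = tr.t, np.abs(tr.value)
        vmax = ep.max()
        if vmax <= 0:
            raise ConfigurationError("trace has no positive peak")
        rel.append((c, tp / c, ep / vmax))
    lo = max(r[1][0] for r in rel)
    hi = min(r[1][-1] for r in rel)
    if hi <= lo:
        raise AlignmentError("rescaled traces share no relative-time overlap")
    grid = np.linspace(lo, hi, n_grid)
    resampled = {c: np.interp(grid, x, y) for c, x, y in rel}
    crits = [r[0] for r in rel]
    pairwise = {}
    for i, a in enumerate(crits):
        for b in crits[i + 1:]:
            pairwise[(a, b)] = float(
                np.sqrt(np.mean((resampled[a] - resampled[b]) ** 2)))
    return SuperpositionReport(max_rms=max(pairwise.values()),
                               pairwise=pairwise, grid=grid)


# ----------------------------------------------------------------------------
# Experiments: seeded end-to-end reproductions
# ----------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Fully serialisable description of one SBF experiment."""

    name: str = "experiment"
    f1: float = 5.5
    f2: float = 11.5
    n_osc: int = 1000
    kind: str = "cosine"                      # cosine | ml
    criteria: tuple[float, ...] = (30.0, 60.0, 90.0)
    mem_family: str = "none"
    mem_level: float = 0.0
    mem_samples: int = 500
    freq_family: str = "none"
    freq_level: float = 0.0
    freq_samples: int = 1
    mode: str = "signed"
    similarity: str = "dot"
    branch: str = "retained"                  # retained | full (noisy cosine runs)
    dt: float | None = None
    seed: int = 0
    out_dir: str | None = None

    @property
    def bank_spec(self) -> OscillatorBankSpec:
        return OscillatorBankSpec(self.f1, self.f2, self.n_osc)

    def mem_noise(self, seed: int | None = None) -> NoiseSpec:
        n = self.mem_samples if self.mem_family != "none" else 1
        return NoiseSpec(self.mem_family, self.mem_level, n,
                         self.seed if seed is None else seed)

    def freq_noise(self, seed: int | None = None) -> NoiseSpec:
        n = self.freq_samples if self.freq_family != "none" else 1
        return NoiseSpec(self.freq_family, self.freq_level, n,
                         self.seed if seed is None else seed)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "criteria" in data:
        data["criteria"] = tuple(float(x) for x in data["criteria"])
    return ExperimentConfig(**data)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    data = asdict(config)
    data["criteria"] = list(data["criteria"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _criterion_seeds(seed: int, n: int) -> list[int]:
    """Independent child seeds (one per criterion), all below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


@dataclass
class ResultBundle:
    """Traces, fits and regression of one experiment, with provenance."""

    config: ExperimentConfig
    traces: dict[float, OutputTrace]
    fits: dict[float, GaussianFit]
    regression: ScalarRegression | None
    provenance: dict

    def summary(self) -> pd.DataFrame:
        rows = [{"criterion": c, "sigma": f.sigma, "center": f.center,
                 "amplitude": f.amplitude, "r2": f.r2}
                for c, f in sorted(self.fits.items())]
        return pd.DataFrame(rows)

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frames = [pd.DataFrame({"criterion": c, "t": tr.t, "value": tr.value})
                  for c, tr in sorted(self.traces.items())]
        pd.concat(frames).to_csv(out / "traces.csv", index=False)
        self.summary().to_csv(out / "fits.csv", index=False)
        payload = {"provenance": self.provenance}
        if self.regression is not None:
            payload["regression"] = {
                "slope": self.regression.slope,
                "intercept": self.regression.intercept,
                "r2": self.regression.r2,
                "stderr": self.regression.stderr,
                "points": self.regression.points,
            }
        with open(out / "regression.json", "w") as fh:
            json.dump(payload, fh, indent=2)
        return out


def _provenance(config: ExperimentConfig) -> dict:
    return {"config": asdict(config), "config_digest": config.digest(),
            "numpy": np.__version__, "seed": config.seed}


def _fit_window(c: float, sigma0: float) -> tuple[float, float]:
    """Fit window [c - 3*sigma0, c + 3*sigma0] from an initial width guess."""
    return (c - 3.0 * sigma0, c + 3.0 * sigma0)


def _noiseless_sigma(spec: OscillatorBankSpec) -> float:
    """Gaussian-sigma equivalent of the noiseless envelope width (FWHM)."""
    return noiseless_width(spec) / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _initial_sigma(spec: OscillatorBankSpec, c: float, level: float) -> float:
    """A-priori output width for window placement.

    The floor is the noiseless envelope width.  Under criterion noise the
    realised envelope follows the square root of the criterion-time density
    (the kernels of distinct retrieved criteria add with incoherent carrier
    phases), whose Gaussian width is ``sqrt(2)*level*c``.
    """
    return max(_noiseless_sigma(spec), math.sqrt(2.0) * level * c)


def run_cosine_noiseless(config: ExperimentConfig) -> ResultBundle:
    """Noiseless cosine experiment: constant-width outputs peaking at c.

    Produces one trace per criterion, Gaussian envelope fits, and the
    width-versus-criterion regression, whose slope is zero: without noise
    the SBF model times accurately but violates the scalar property.
    """
    if config.kind != "cosine":
        raise ConfigurationError("noiseless experiment requires kind='cosine'")
    if config.mem_family != "none" or config.freq_family != "none":
        raise ConfigurationError("noiseless experiment forbids noise specs")
    spec = config.bank_spec
    bank = CosineBank(spec)
    sigma0 = _initial_sigma(spec, min(config.criteria), 0.0)
    traces, fits = {}, {}
    for c in config.criteria:
        t_grid = simulation_grid(spec, c, 0.0, config.dt)
        tr = output_function(bank, c, t_grid, mode=config.mode,
                             similarity=config.similarity)
        traces[c] = tr
        fits[c] = fit_gaussian(tr, _fit_window(c, sigma0),
                               sigma_min=0.8 * _noiseless_sigma(spec))
    reg = width_vs_criterion(fits.items())
    return ResultBundle(config, traces, fits, reg, _provenance(config))


def run_cosine_noisy(config: ExperimentConfig) -> ResultBundle:
    """Cosine experiment with criterion-time (memory) noise.

    One output per criterion (memory noise only, seeded per criterion),
    Gaussian envelope fits, and the width regression whose positive slope
    expresses the scalar property; the result holds for uniform and normal
    noise alike.

    ``config.branch`` selects the output path: ``"retained"`` (default)
    evaluates the physically realisable branch — one Dirichlet kernel per
    retrieved criterion — which is the object whose Gaussianity and scalar
    width the theory addresses; ``"full"`` runs the complete
    coincidence-detection engine, whose mirror branch recurs at multiples of
    the bank revival time 1/df and can alias into wide analysis windows.
    """
    if config.kind != "cosine":
        raise ConfigurationError("cosine experiment requires kind='cosine'")
    if config.mem_family == "none":
        raise ConfigurationError("noisy experiment requires memory noise")
    if config.branch not in ("retained", "full"):
        raise ConfigurationError(f"unknown branch {config.branch!r}")
    spec = config.bank_spec
    bank = CosineBank(spec)
    seeds = _criterion_seeds(config.seed, len(config.criteria))
    traces, fits = {}, {}
    for c, s in zip(config.criteria, seeds):
        t_grid = simulation_grid(spec, c, config.mem_level, config.dt)
        if config.branch == "retained" and config.freq_family == "none":
            tr = memory_noise_output(spec, c, t_grid, config.mem_noise(s))
        else:
            tr = output_function(bank, c, t_grid, mem_noise=config.mem_noise(s),
                                 freq_noise=config.freq_noise(s), mode=config.mode,
                                 similarity=config.similarity)
        traces[c] = tr
        fits[c] = fit_gaussian(tr, _fit_window(c, _initial_sigma(
            spec, c, config.mem_level)), sigma_min=0.8 * _noiseless_sigma(spec))
    reg = width_vs_criterion(fits.items())
    return ResultBundle(config, traces, fits, reg, _provenance(config))


def run_ml_noise_sweep(config: ExperimentConfig,
                       levels: Sequence[float] = (0.001, 0.01, 0.1),
                       bank: MLBank | None = None,
                       cache_path: str | Path | None = None
                       ) -> dict[float, ResultBundle]:
    """Morris-Lecar noise sweep: width regressions across memory-noise levels.

    Calibrates (or loads) the ML bank once and reuses it across all noise
    levels and criteria.  For each level, runs the memory-noise experiment
    and fits the width regression; the slope grows in proportion to the
    noise level, so a ten-fold level increase produces a ten-fold slope
    increase.  Returns one :class:`ResultBundle` per level.

    The readout is always the absolute cosine of the angle between the
    reference and running weight vectors: unlike the raw dot product it is
    invariant to the time-varying power of the state vector, which for the
    non-sinusoidal ML waveform otherwise fluctuates enough to move the
    noiseless response peak away from the criterion.
    """
    if config.kind != "ml":
        raise ConfigurationError("ML sweep requires kind='ml'")
    spec = config.bank_spec
    if bank is None:
        if cache_path is not None and Path(cache_path).exists():
            logger.info("loading calibrated bank from %s", cache_path)
            bank = MLBank.load(cache_path)
        else:
            import time
            start = time.perf_counter()
            bank = calibrate_bank(spec)
            logger.info("bank calibration took %.1f s", time.perf_counter() - start)
            if cache_path is not None:
                bank.save(cache_path)
    results: dict[float, ResultBundle] = {}
    level_seeds = _criterion_seeds(config.seed, len(levels))
    for level, lseed in zip(levels, level_seeds):
        cfg = replace(config, mem_family=config.mem_family
                      if config.mem_family != "none" else "normal",
                      mem_level=level, seed=lseed, similarity="cosine_angle")
        seeds = _criterion_seeds(cfg.seed, len(cfg.criteria))
        traces, fits = {}, {}
        for c, s in zip(cfg.criteria, seeds):
            t_grid = simulation_grid(spec, c, level, cfg.dt)
            tr = output_function(bank, c, t_grid, mem_noise=cfg.mem_noise(s),
                                 mode=cfg.mode, similarity=cfg.similarity)
            traces[c] = tr
            fits[c] = fit_gaussian(tr, _fit_window(c, _initial_sigma(
                spec, c, level)), sigma_min=0.8 * _noiseless_sigma(spec))
        reg = width_vs_criterion(fits.items())
        results[level] = ResultBundle(cfg, traces, fits, reg, _provenance(cfg))
        logger.info("level %.3g: slope %.4g +- %.4g (r2=%.3f)",
                    level, reg.slope, reg.stderr, reg.r2)
    return results


# ----------------------------------------------------------------------------
# Plain-text I/O helpers
# ----------------------------------------------------------------------------


def trace_to_csv(trace: OutputTrace, path: str | Path) -> None:
    """Write a trace as CSV (t, value) with a JSON provenance sidecar."""
    pd.DataFrame({"t": trace.t, "value": trace.value}).to_csv(path, index=False)
    with open(str(path) + ".json", "w") as fh:
        json.dump(trace.config, fh, indent=2, default=float)


def trace_from_csv(path: str | Path) -> OutputTrace:
    df = pd.read_csv(path)
    sidecar = Path(str(path) + ".json")
    cfg = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return OutputTrace(t=df["t"].to_numpy(), value=df["value"].to_numpy(), config=cfg)


def ml_trace_to_csv(trace: MLTrace, path: str | Path) -> None:
    """Write a membrane trajectory as CSV with columns t, x1, x2."""
    pd.DataFrame({"t": trace.t, "x1": trace.x1, "x2": trace.x2}).to_csv(
        path, index=False)


def ml_params_to_yaml(params: MLParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(params), fh, sort_keys=False)


def ml_params_from_yaml(path: str | Path) -> MLParams:
    with open(path) as fh:
        return MLParams(**(yaml.safe_load(fh) or {}))
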