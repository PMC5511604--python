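"""Waveform container, wave separation, Gaussian high-pass, reflection kernel.

In the linear long-wave regime a measured pressure/velocity pair at one site
splits into forward and backward components

    p_f = (p + rho c0 u)/2,    p_b = (p - rho c0 u)/2.

A lumped compliant insertion (an aneurysm) at round-trip lag ``Dt`` with time
constant ``tau`` reflects the forward wave with frequency response

    R(omega) = (i omega tau / (1 - i omega tau)) * exp(i omega Dt)

whose impulse response is ``-delta(t-Dt) + H(t-Dt) exp(-(t-Dt)/tau)/tau``:
an inverted, delayed copy of the incident wave plus an exponentially relaxing
tail.  ``reflect_convolve`` applies that kernel in the time domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "WaveError",
    "Waveform",
    "separate",
    "gaussian_highpass",
    "kernel_freq",
    "reflect_convolve",
]

MIN_SAMPLES = 16


class WaveError(ValueError):
    """Raised for malformed or incompatible waveforms."""


@dataclass
class Waveform:
    """Uniformly sampled time series of one physical quantity at one site.

    ``values`` in SI units of ``quantity`` (Pa, m/s, m^3/s or m^2), sampled at
    interval ``dt`` starting at ``t_start``.  ``pulse_start`` optionally marks
    the onset of the main pulse.
    """

    values: np.ndarray
    dt: float
    t_start: float = 0.0
    quantity: str = ""
    units: str = ""
    site: str = ""
    pulse_start: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise WaveError("waveform values must be one-dimensional")
        if len(self.values) < MIN_SAMPLES:
            raise WaveError(f"waveform needs >= {MIN_SAMPLES} samples, got {len(self.values)}")
        if not self.dt > 0:
            raise WaveError(f"dt must be positive, got {self.dt}")
        if not np.all(np.isfinite(self.values)):
            raise WaveError("waveform contains non-finite samples")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(len(self.values))

    @property
    def duration(self) -> float:
        return self.dt * (len(self.values) - 1)

    def with_values(self, values, **meta) -> "Waveform":
        """Copy of this waveform with new samples (and optional metadata)."""
        w = replace(self, values=np.asarray(values, dtype=float))
        for k, v in meta.items():
            setattr(w, k, v)
        return w

    def baseline(self, window: float = 0.05) -> float:
        """Mean over the initial ``window`` seconds (pre-pulse reference)."""
        n = max(1, min(len(self.values), int(round(window / self.dt))))
        return float(np.mean(self.values[:n]))


def _check_cosampled(a: Waveform, b: Waveform) -> None:
    if len(a) != len(b) or abs(a.dt - b.dt) > 1e-12 * a.dt \
            or abs(a.t_start - b.t_start) > 1e-9:
        raise WaveError("waveforms are not co-sampled at the same site/time base")


def separate(p: Waveform, u: Waveform, rho: float, c0: float,
             baseline_window: float = 0.05,
             method: str = "linear") -> tuple[Waveform, Waveform]:
    """Split co-sited pressure/velocity into forward and backward waves.

    Pressure and velocity are first referenced to their pre-pulse baselines
    (mean over the initial ``baseline_window`` seconds).  With
    ``method="linear"`` the classic small-amplitude split is used,
    ``p_f = (dp + rho c0 du)/2`` and ``p_b = (dp - rho c0 du)/2``, with the
    exact inverses ``p_f + p_b = dp`` and ``(p_f - p_b)/(rho c0) = du``.

    ``method="characteristic"`` separates in Riemann-invariant space of the
    elastic tube law: with ``c(p) = c0 sqrt(1 + dp/(2 rho c0^2))``,
    ``p_{f,b} = +-(rho c0/2) (du +- 4(c - c0))``.  It needs no parameters
    beyond ``rho`` and ``c0``, reduces to the linear split for small
    amplitudes, and yields an exactly zero backward wave for a finite-
    amplitude simple wave (the linear split leaks ~ dp^2/(16 rho c0^2)).
    """
    _check_cosampled(p, u)
    if rho <= 0 or c0 <= 0:
        raise WaveError("rho and c0 must be positive")
    if method not in ("linear", "characteristic"):
        raise WaveError(f"unknown separation method {method!r}")
    dp = p.values - p.baseline(baseline_window)
    du = u.values - u.baseline(baseline_window)
    if method == "linear":
        zu = rho * c0 * du
        pf_vals = 0.5 * (dp + zu)
        pb_vals = 0.5 * (dp - zu)
    else:
        arg = 1.0 + dp / (2.0 * rho * c0 * c0)
        if np.any(arg <= 0):
            raise WaveError("pressure excursion collapses the tube law")
        dc4 = 4.0 * c0 * (np.sqrt(arg) - 1.0)
        pf_vals = 0.5 * rho * c0 * (du + dc4)
        pb_vals = -0.5 * rho * c0 * (du - dc4)
    pf = p.with_values(pf_vals, quantity="pressure_forward")
    pb = p.with_values(pb_vals, quantity="pressure_backward")
    return pf, pb


def gaussian_highpass(w: Waveform, delta: float,
                      boundary: str = "reflect") -> Waveform:
    """High-pass by subtracting a Gaussian smoothing: ``w - G*w``.

    ``G(t) = exp(-(t/delta)^2)/(sqrt(pi) delta)``; the discrete kernel is
    normalised to unit sum so a constant input maps to (numerically) zero.
    A sinusoid at angular frequency ``omega`` keeps the fraction
    ``1 - exp(-omega^2 delta^2/4)`` of its amplitude.  ``boundary`` handles
    the record ends: ``"reflect"`` (pad by ~3.5*delta, for one-shot records)
    or ``"wrap"`` (circular convolution, exact for a record holding one
    period of a periodic signal).
    """
    if delta <= 0:
        raise WaveError("filter width delta must be positive")
    if boundary not in ("reflect", "wrap"):
        raise WaveError(f"unknown boundary mode {boundary!r}")
    if delta < 2.0 * w.dt:
        warnings.warn(
            f"Gaussian width {delta:.4g}s under-resolved at dt={w.dt:.4g}s",
            RuntimeWarning, stacklevel=2)
    n = len(w.values)
    radius = max(1, int(np.ceil(3.5 * delta / w.dt)))
    if boundary == "reflect":
        radius = min(radius, n - 1)
        k = np.arange(-radius, radius + 1) * w.dt
        g = np.exp(-((k / delta) ** 2))
        g /= g.sum()
        padded = np.concatenate([w.values[radius:0:-1], w.values,
                                 w.values[-2:-radius - 2:-1]])
        smooth = np.convolve(padded, g, mode="valid")
    else:
        # circular convolution via FFT with the periodically wrapped kernel
        k = (np.arange(n) - n // 2) * w.dt
        g = np.exp(-((k / delta) ** 2))
        g /= g.sum()
        smooth = np.fft.irfft(np.fft.rfft(w.values) *
                              np.fft.rfft(np.roll(g, -(n // 2))), n)
    return w.with_values(w.values - smooth)


def kernel_freq(omega, tau: float, dt_lag: float):
    """Aneurysm reflection coefficient ``R(omega)`` (complex, |R| < 1).

    ``R = (i omega tau/(1 - i omega tau)) exp(i omega dt_lag)``; zero at DC,
    magnitude ``omega tau / sqrt(1 + omega^2 tau^2)`` approaching 1 at high
    frequency.
    """
    if tau <= 0:
        raise WaveError("tau must be positive")
    omega = np.asarray(omega, dtype=float)
    wt = 1j * omega * tau
    R = wt / (1.0 - wt) * np.exp(1j * omega * dt_lag)
    return complex(R) if R.ndim == 0 else R


def _exp_tail(values: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """One-pole low-pass ``(1/tau) int p(t') exp(-(t-t')/tau) dt'``.

    Exact exponential integrator for piecewise-linear input: stable for any
    tau/dt ratio (no quadrature of the stiff exponential).
    """
    alpha = dt / tau
    E = np.exp(-alpha)
    # int_0^dt (1/tau) e^(-s/tau) * linear(p[n-1] -> p[n]) ds
    c_new = 1.0 - (1.0 - E) / alpha
    c_old = (1.0 - E) / alpha - E
    # one-pole IIR out[i] = E*out[i-1] + c_new*v[i] + c_old*v[i-1], relaxed
    # initial state: signal held at values[0] for t < t_start => out[0] = values[0]
    from scipy.signal import lfilter

    zi = np.array([values[0] * (1.0 - c_new)])
    out, _ = lfilter([c_new, c_old], [1.0, -E], values, zi=zi)
    return out


def _unshifted_response(values: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Kernel response before applying the lag: ``-p(t) + tail(t)``."""
    return -values + _exp_tail(values, dt, tau)


def _apply_lag(y0: np.ndarray, dt: float, t_lag: float) -> np.ndarray:
    """Delay ``y0`` by ``t_lag`` (rest-padded); sub-sample lags via cubic spline."""
    n = len(y0)
    shift = t_lag / dt
    nearest = round(shift)
    out = np.zeros(n)
    if abs(shift - nearest) < 1e-9:
        if nearest < n:
            out[nearest:] = y0[: n - nearest] if nearest else y0
        return out
    t = np.arange(n) * dt
    spline = CubicSpline(t, y0, bc_type="natural")
    tq = t - t_lag
    inside = tq >= 0
    out[inside] = spline(tq[inside])
    return out


def reflect_convolve(p_f: Waveform, tau: float, dt_lag: float) -> Waveform:
    """Predicted reflected wave ``p_b = p_f * R(.; tau, dt_lag)``.

    The delta term of the kernel is applied analytically (an inverted shifted
    copy); the exponential tail uses an exact one-pole recursion; fractional
    lags are handled by cubic-spline interpolation of the unshifted response.
    The incident wave is assumed at rest before its first sample.
    """
    if tau <= 0:
        raise WaveError("tau must be positive")
    if dt_lag < 0:
        raise WaveError("dt_lag must be >= 0")
    if dt_lag > p_f.duration:
        warnings.warn("lag exceeds record length; reflected wave is all zeros",
                      RuntimeWarning, stacklevel=2)
        return p_f.with_values(np.zeros_like(p_f.values), quantity="pressure_backward")
    y0 = _unshifted_response(p_f.values, p_f.dt, tau)
    return p_f.with_values(_apply_lag(y0, p_f.dt, dt_lag), quantity="pressure_backward")
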