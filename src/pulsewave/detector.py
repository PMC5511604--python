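"""Aneurysm detection by reflection-kernel fitting.

Given waveforms at a monitored site, the detector (i) locates the pulse
onset ``t0``, (ii) isolates the reflected content — by forward/backward
separation for a pressure/velocity pair, or by Gaussian high-pass filtering
alone for a single velocity waveform — and (iii) least-squares fits

    target(t)  ~=  source(t) * R(t; tau, Dt)  +  B

over the window ``[t0 + Dt, t0 + Dt + f_w T]``, where ``R`` is the lumped
reflection kernel of a compliant insertion, ``B`` a constant background, and
the window tracks the candidate lag as the echo must start ``Dt`` after the
pulse.  The fitted pair ``(tau, Dt)`` converts to physical indicators:

    dC_A = 2 A0 tau / (rho c0)        excess compliance (m^3/Pa)
    K    = 2 c0 tau / L_A             compliance ratio (assumed length L_A)
    x_A  = c0 Dt / 2                  distance to the aneurysm centre (m)

The optimiser is deterministic: an exhaustive coarse grid (lag step = one
sample, log-spaced tau grid) with the linear parameter ``B`` solved in closed
form at each node, followed by a Nelder-Mead polish of ``(tau, Dt)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from .waves import Waveform, WaveError, gaussian_highpass, separate, \
    _unshifted_response, _apply_lag

__all__ = [
    "DetectionError",
    "DetectorConfig",
    "KernelParams",
    "SiteParams",
    "DetectionResult",
    "detect_pulse_start",
    "fit_kernel",
    "detect_from_pressure",
    "detect_from_velocity",
    "convert",
]


class DetectionError(RuntimeError):
    """Raised when a detection stage cannot produce a result."""


@dataclass(frozen=True)
class SiteParams:
    """Physical parameters used to convert fitted times to indicators.

    ``c0`` and ``A0`` describe the vessel hosting the reflector (for carotid
    velocity detection: the aorta, not the carotid); ``L_A_assumed`` is the
    assumed aneurysm length entering the reported ``K``.
    """

    rho: float
    c0: float
    A0: float
    L_A_assumed: float = 0.09

    def __post_init__(self) -> None:
        if min(self.rho, self.c0, self.A0, self.L_A_assumed) <= 0:
            raise DetectionError("site parameters must be positive")


@dataclass
class DetectorConfig:
    """Tunable parameters of the fitting pipeline.

    ``tau_expected`` sets the high-pass width ``delta = 6 tau_expected``;
    ``period`` is the heartbeat (or pulse) period ``T`` and ``window_fraction``
    the fit-window width as a fraction of ``T``; ``dt_range``/``tau_range``
    bound the lag and time-constant search; ``pulse_threshold`` is the upstroke
    fraction used for onset detection.  ``filter_forward`` filters the
    convolution source with the same Gaussian as the target (self-consistent
    because filtering commutes with the kernel convolution); switch it off to
    convolve the raw forward wave instead.
    """

    tau_expected: float = 0.02
    period: float = 1.0
    window_fraction: float = 1.0 / 3.0
    dt_range: tuple = (0.0, 0.3)
    tau_range: tuple = (1e-3, 0.3)
    pulse_threshold: float = 0.05
    mode: str = "pressure"
    baseline_window: float = 0.05
    n_tau_grid: int = 30
    polish: bool = True
    filter_forward: bool = True
    highpass: bool = True
    separation: str = "linear"     # or "characteristic"
    periodic_record: bool = False  # record holds one period -> wrap filtering

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise DetectionError("window_fraction must be in (0, 1]")
        if self.tau_expected <= 0 or self.period <= 0:
            raise DetectionError("tau_expected and period must be positive")
        for name in ("dt_range", "tau_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi <= lo:
                raise DetectionError(f"{name} must be ordered and non-negative")
        if self.mode not in ("pressure", "velocity"):
            raise DetectionError(f"unknown mode {self.mode!r}")

    @property
    def delta(self) -> float:
        """Gaussian high-pass width (s)."""
        return 6.0 * self.tau_expected


@dataclass(frozen=True)
class KernelParams:
    """Fitted reflection-kernel parameters."""

    tau: float
    dt_lag: float
    background: float

    def __post_init__(self) -> None:
        if self.tau is not None and self.tau <= 0:
            raise DetectionError("tau must be positive")
        if self.dt_lag < 0:
            raise DetectionError("dt_lag must be >= 0")


@dataclass
class DetectionResult:
    """Fit outcome plus derived physical indicators."""

    tau: Optional[float]
    dt_lag: float
    background: float
    residual: float
    excess_compliance: float
    K: float
    x_A: float
    window: tuple
    pulse_start: float
    config: DetectorConfig
    site: SiteParams
    tau_undefined: bool = False

    def to_dict(self) -> dict:
        d = {
            "tau_s": self.tau,
            "dt_s": self.dt_lag,
            "B": self.background,
            "residual": self.residual,
            "dCA_m3_per_Pa": self.excess_compliance,
            "dCA_cm3_per_MPa": self.excess_compliance * 1e12,
            "K": self.K,
            "xA_m": self.x_A,
            "window": list(self.window),
            "pulse_start_s": self.pulse_start,
            "tau_undefined": self.tau_undefined,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "site": asdict(self.site),
        }
        return d


def detect_pulse_start(w: Waveform, threshold: float = 0.05,
                       baseline_window: float = 0.05,
                       smooth: float = 0.004) -> float:
    """Locate the onset of the dominant upstroke.

    The waveform is Gaussian-smoothed (width ``smooth`` seconds), the first
    crossing of ``baseline + threshold*(peak - baseline)`` is found, and the
    crossing is back-projected to the baseline along the local tangent.
    Raises ``DetectionError`` when no dominant upstroke exists (e.g. noise).
    """
    if not 0 < threshold < 1:
        raise DetectionError("threshold must be in (0, 1)")
    sigma = max(smooth / w.dt, 1e-6)
    ws = gaussian_filter1d(w.values, sigma, mode="nearest")
    d = np.gradient(ws, w.dt)
    imax = int(np.argmax(d))
    if d[imax] <= 0:
        raise DetectionError("no rising edge in record")
    # first crossing of the derivative threshold = onset of the first upstroke
    # (the global steepest slope may sit on a later feature of the pulse)
    above = np.nonzero(d > threshold * d[imax])[0]
    i_on = int(above[0])
    nb = max(1, int(round(baseline_window / w.dt)))
    j0 = max(0, i_on - nb)
    base = float(np.mean(ws[j0:i_on])) if i_on > j0 else float(ws[0])
    peak = float(np.max(ws)) - base
    noise = float(np.std(w.values[j0:i_on] - ws[j0:i_on])) if i_on - j0 >= 4 else 0.0
    if peak <= 0 or (noise > 0 and peak < 8.0 * noise):
        raise DetectionError("no dominant upstroke found (flat or noise-only record)")
    # back-project along the tangent at the first local derivative maximum
    # (the steepest point of *this* upstroke), the classic foot estimate
    ipk = i_on
    while ipk + 1 < len(d) and d[ipk + 1] >= d[ipk]:
        ipk += 1
    slope = float(d[ipk])
    t_pk = w.t_start + ipk * w.dt
    return float(max(t_pk - max(ws[ipk] - base, 0.0) / slope, w.t_start))


def _window_slice(n: int, dt: float, t_start: float, t1: float, n_win: int):
    i1 = int(round((t1 - t_start) / dt))
    if i1 < 0 or i1 + n_win > n:
        return None
    return slice(i1, i1 + n_win)


def fit_kernel(forward: Waveform, target: Waveform, config: DetectorConfig,
               t0: Optional[float] = None) -> tuple[KernelParams, float]:
    """Least-squares fit of ``forward * R(tau, Dt) + B`` to ``target``.

    The misfit is the RMS of the residual over the lag-tracking window
    ``[t0 + Dt, t0 + Dt + window_fraction * period]``.  ``B`` is linear and
    solved in closed form; ``(tau, Dt)`` go through an exhaustive grid
    (lag step = one sample, ``n_tau_grid`` log-spaced time constants) and an
    optional Nelder-Mead polish.  Returns the parameters and the residual.
    """
    if forward is not target:
        from .waves import _check_cosampled
        _check_cosampled(forward, target)
    if t0 is None:
        t0 = forward.pulse_start if forward.pulse_start is not None else forward.t_start
    dt = forward.dt
    n = len(forward)
    n_win = max(2, int(round(config.window_fraction * config.period / dt)))
    tvals = target.values
    scale = float(np.max(np.abs(tvals)))
    if scale == 0.0 or float(np.std(tvals)) < 1e-14 * max(scale, 1.0):
        # flat target: background-only fit, tau undefined
        return KernelParams(None, 0.0, float(np.mean(tvals))), 0.0

    lag_lo, lag_hi = config.dt_range
    # candidate integer-sample lags whose window still fits the record
    k_lo = max(0, int(np.ceil(lag_lo / dt)))
    k_hi = int(np.floor(lag_hi / dt))
    lags = []
    for k in range(k_lo, k_hi + 1):
        if _window_slice(n, dt, forward.t_start, t0 + k * dt, n_win) is not None:
            lags.append(k)
    if not lags:
        raise DetectionError("no lag candidate leaves a complete fit window in the record")

    taus = np.geomspace(config.tau_range[0], config.tau_range[1], config.n_tau_grid)

    def cost_grid(tau: float, k: int, y0: np.ndarray) -> tuple[float, float]:
        sl = _window_slice(n, dt, forward.t_start, t0 + k * dt, n_win)
        conv = np.zeros(n)
        if k < n:
            conv[k:] = y0[: n - k]
        diff = tvals[sl] - conv[sl]
        B = float(np.mean(diff))
        return float(np.sqrt(np.mean((diff - B) ** 2))), B

    best = (np.inf, None, None, None)  # residual, tau, lag_s, B
    for tau in taus:
        y0 = _unshifted_response(forward.values, dt, tau)
        for k in lags:
            r, B = cost_grid(tau, k, y0)
            if r < best[0]:
                best = (r, float(tau), k * dt, B)
    res, tau_b, lag_b, B_b = best

    if config.polish:
        def cost_cont(x) -> float:
            ltau, lag = x
            tau = math.exp(ltau)
            if not (config.tau_range[0] <= tau <= config.tau_range[1]):
                return 1e30
            if not (lag_lo - 1e-12 <= lag <= lag_hi + 1e-12) or lag < 0:
                return 1e30
            sl = _window_slice(n, dt, forward.t_start, t0 + lag, n_win)
            if sl is None:
                return 1e30
            y0 = _unshifted_response(forward.values, dt, tau)
            conv = _apply_lag(y0, dt, lag)
            diff = tvals[sl] - conv[sl]
            B = float(np.mean(diff))
            return float(np.sqrt(np.mean((diff - B) ** 2)))

        out = minimize(cost_cont, x0=[math.log(tau_b), lag_b], method="Nelder-Mead",
                       options=dict(xatol=1e-5, fatol=1e-12 * max(res, 1e-30),
                                    maxiter=400))
        if out.fun <= res:
            tau_b, lag_b = float(math.exp(out.x[0])), float(out.x[1])
            res = float(out.fun)
            sl = _window_slice(n, dt, forward.t_start, t0 + lag_b, n_win)
            conv = _apply_lag(_unshifted_response(forward.values, dt, tau_b), dt, lag_b)
            B_b = float(np.mean(tvals[sl] - conv[sl]))

    return KernelParams(tau_b, lag_b, B_b), res


def convert(tau: float, dt_lag: float, A0: float, rho: float, c0: float,
            L_A_assumed: float) -> tuple[float, float, float]:
    """Fitted times -> (dC_A m^3/Pa, K, x_A m)."""
    if min(A0, rho, c0, L_A_assumed) <= 0:
        raise DetectionError("conversion parameters must be positive")
    dca = 2.0 * A0 * tau / (rho * c0)
    K = 2.0 * c0 * tau / L_A_assumed
    x_A = 0.5 * c0 * dt_lag
    return dca, K, x_A


def _package(params: KernelParams, residual: float, t0: float,
             config: DetectorConfig, site: SiteParams) -> DetectionResult:
    tau = params.tau
    undefined = tau is None
    tau_eff = 0.0 if undefined else tau
    if undefined:
        dca = K = 0.0
        x_A = 0.5 * site.c0 * params.dt_lag
    else:
        dca, K, x_A = convert(tau_eff, params.dt_lag, site.A0, site.rho, site.c0,
                              site.L_A_assumed)
    t1 = t0 + params.dt_lag
    return DetectionResult(
        tau=tau, dt_lag=params.dt_lag, background=params.background,
        residual=residual, excess_compliance=dca, K=K, x_A=x_A,
        window=(t1, t1 + config.window_fraction * config.period),
        pulse_start=t0, config=config, site=site, tau_undefined=undefined,
    )


def detect_from_pressure(p: Waveform, u: Waveform, site: SiteParams,
                         config: DetectorConfig) -> DetectionResult:
    """Full pressure-mode pipeline: separate -> high-pass -> kernel fit.

    ``p`` and ``u`` must be co-sampled at the same site; the local healthy
    wave speed ``site.c0`` is used for the separation.
    """
    p_f, p_b = separate(p, u, site.rho, site.c0, config.baseline_window,
                        method=config.separation)
    # onset from the forward wave: it is free of the aneurysm echo
    t0 = detect_pulse_start(p_f, config.pulse_threshold, config.baseline_window)
    bnd = "wrap" if config.periodic_record else "reflect"
    target = gaussian_highpass(p_b, config.delta, bnd) if config.highpass else p_b
    source = gaussian_highpass(p_f, config.delta, bnd) \
        if (config.highpass and config.filter_forward) else p_f
    params, res = fit_kernel(source, target, config, t0=t0)
    return _package(params, res, t0, config, site)


def detect_from_velocity(u: Waveform, site: SiteParams,
                         config: DetectorConfig) -> DetectionResult:
    """Velocity-mode pipeline for sites where separation is impossible.

    The high-passed velocity ``u'`` serves as both convolution source and fit
    target: the echo of the main pulse is recognised inside the same record,
    ``u' ~ u' * R + B`` over the lag-tracking window.  ``site`` carries the
    host-vessel (aorta) parameters used for the conversion, and the lag is the
    round trip from the branch inlet to the aneurysm.
    """
    t0 = detect_pulse_start(u, config.pulse_threshold, config.baseline_window)
    du = u.values - u.baseline(config.baseline_window)
    u_ref = u.with_values(du)
    bnd = "wrap" if config.periodic_record else "reflect"
    up = gaussian_highpass(u_ref, config.delta, bnd) if config.highpass else u_ref
    params, res = fit_kernel(up, up, config, t0=t0)
    return _package(params, res, t0, config, site)
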