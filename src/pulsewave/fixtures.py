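"""Synthetic study fixtures: laboratory rig, aortic chain, pump pulses, noise.

Everything the detection pipeline needs is generated here from first
principles — no external data files.

*Laboratory rig*: a water-filled elastic main tube (ID 17 mm, wall 2 mm,
E = 2.8 MPa, length 2 m) driven by a single piston stroke (~100 cm^3),
with an exchangeable 14 cm aneurysm segment whose circular-arc bump
(L_A = 9 cm, conjugation radius 10 mm) starts 50 cm from the main-tube
inlet.  Peak diameters 24/34/44/50 mm plus a uniform control tube.  The
outlet passes through a short rigid fitting into a 6.5 m discharge tube and
a wide collecting reservoir, so distal reflections arrive late.  Pressure
and velocity are monitored 2, 10, 25 and 50 cm from the main-tube inlet.

*Aortic chain*: a serial reduction of a systemic arterial tree — the 15
aorta segments (arch to abdominal bifurcation) with printed lengths and
inlet/outlet diameters, the two common carotids branching at the arch, wall
thickness from the radius-dependent arterial law, E = 225 kPa, blood
density 1.04 g/cm^3, viscosity 4 mPa s.  A fusiform AAA (cosine bump,
L_A = 10.4 cm) sits in the Abdominal Aorta IV segment; the two severities
double (AAA-2) or triple (AAA-3) the local radius.  Remaining side branches
are absorbed into three-element Windkessel terminals with matched proximal
resistance.  The inlet is a periodic flow pulse with a 1 s heartbeat.

Ground truths (K, dC_A, tau, Dt to each monitor) are recomputed from the
geometry module at build time, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import simpson

from .detector import DetectorConfig, SiteParams
from .geometry import (
    AneurysmProfile,
    FluidProperties,
    VesselSegment,
    segment_compliance_summary,
)
from .solver import InletBC, Monitor, Network, TerminalBC
from .waves import Waveform

__all__ = [
    "PumpPulseSpec",
    "FixtureCatalogEntry",
    "pump_pulse",
    "build_rig",
    "build_aorta_chain",
    "add_noise",
    "rig_ground_truth",
    "aorta_ground_truth",
    "catalogue",
    "FIXTURE_NAMES",
    "AORTA_SEGMENTS",
]

# ---------------------------------------------------------------------------
# pump pulse
# ---------------------------------------------------------------------------

@dataclass
class PumpPulseSpec:
    """Piston-stroke velocity pulse description.

    The piston (cylinder diameter 5 cm, stroke 5 cm, ~100 cm^3) would produce
    a half-sine velocity pulse under no load; fluid loading makes the realised
    waveform two-humped.  The two-hump variant multiplies the half-sine by a
    smooth notch, keeping compact support on ``[0, duration]``.  Amplitudes
    are fixed by the stroke volume through the receiving-tube area (the
    piston/tube area ratio is implicit in prescribing the *tube* velocity).
    """

    duration: float = 0.6
    shape: str = "two-hump"          # or "half-sine"
    stroke_volume: float = 100e-6    # m^3 swept by the piston
    tube_area: float = np.pi * 8.5e-3**2   # area where the velocity is imposed
    notch_centre_frac: float = 0.5   # two-hump notch position (fraction of duration)
    notch_width_frac: float = 0.12
    notch_depth: float = 0.55

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.stroke_volume <= 0 or self.tube_area <= 0:
            raise ValueError("duration, stroke volume and tube area must be positive")
        if self.shape not in ("two-hump", "half-sine"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")
        if not 0 <= self.notch_depth < 1:
            raise ValueError("notch depth must be in [0, 1)")


def pump_pulse(spec: PumpPulseSpec, dt: float = 1e-3,
               total_time: Optional[float] = None) -> Waveform:
    """Velocity waveform of one piston stroke, scaled to the stroke volume.

    ``int A u dt`` equals ``spec.stroke_volume`` exactly (discrete trapezoid);
    the record is zero-padded to ``total_time`` if requested so that the
    series can drive longer simulations.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    T = spec.duration
    t_end = max(total_time or T, T)
    t = np.arange(0.0, t_end + 0.5 * dt, dt)

    def shape(tt):
        base = np.where((tt >= 0) & (tt <= T),
                        np.sin(np.pi * np.clip(tt / T, 0, 1)), 0.0)
        if spec.shape == "two-hump":
            base = base * (1.0 - spec.notch_depth * np.exp(
                -(((tt - spec.notch_centre_frac * T)
                   / (spec.notch_width_frac * T)) ** 2)))
        return base

    # normalise on a fixed reference grid so the amplitude is independent of
    # the requested sampling interval
    t_ref = np.linspace(0.0, T, 16385)
    vol = simpson(shape(t_ref), x=t_ref) * spec.tube_area
    u = shape(t) * (spec.stroke_volume / vol)
    return Waveform(u, dt, quantity="velocity", units="m/s", site="inlet",
                    pulse_start=0.0)


# ---------------------------------------------------------------------------
# laboratory rig
# ---------------------------------------------------------------------------

RIG_DIAMETERS_MM = (24, 34, 44, 50)

_RIG_MAIN = dict(radius=8.5e-3, h=2e-3, E=2.8e6, poisson=0.5)
_RIG_FIT = dict(radius=6.0e-3, h=2e-3, E=2.8e9, poisson=0.5)  # ~rigid: E x1000
_RIG_PROX_LEN = 0.50
_RIG_SEG_LEN = 0.14          # exchangeable aneurysm segment
_RIG_ANEURYSM_LEN = 0.09     # bump footprint, centred in the segment
_RIG_CONJ_RADIUS = 0.01
_RIG_MAIN_LEN = 2.0
_RIG_FIT_LEN = 0.10
_RIG_OUTLET_LEN = 6.5
_RIG_RESERVOIR_LEN = 1.0


def build_rig(D_mm: Optional[int] = None, stroke_volume: float = 100e-6,
              pulse_shape: str = "two-hump", pulse_dt: float = 1e-3,
              series_time: float = 1.0) -> Network:
    """Laboratory network with an arc aneurysm of peak diameter ``D_mm``.

    ``D_mm=None`` builds the uniform control tube.  Monitors sit 2, 10, 25
    and 50 cm from the main-tube inlet; the aneurysm midpoint is 57 cm from
    that inlet (55 cm from the 2 cm site).  The piston stroke is imposed as a
    velocity at the main-tube inlet; the outlet chain (rigid fitting, 6.5 m
    discharge tube, wide reservoir) delays distal reflections well past the
    aneurysm echo.
    """
    if D_mm is not None and D_mm not in RIG_DIAMETERS_MM:
        raise ValueError(f"unknown rig aneurysm diameter {D_mm} "
                         f"(choose from {RIG_DIAMETERS_MM} or None)")
    m = _RIG_MAIN
    aneurysm = None
    if D_mm is not None:
        aneurysm = AneurysmProfile(
            "arc", x1=0.5 * (_RIG_SEG_LEN - _RIG_ANEURYSM_LEN),
            length=_RIG_ANEURYSM_LEN, peak_diameter=D_mm * 1e-3,
            conjugation_radius=_RIG_CONJ_RADIUS)
    dist_len = _RIG_MAIN_LEN - _RIG_PROX_LEN - _RIG_SEG_LEN
    segments = [
        VesselSegment("main-prox", _RIG_PROX_LEN, m["radius"], m["radius"],
                      m["h"], m["E"], m["poisson"]),
        # finer mesh only when a bump must be resolved; a resolution change
        # in the uniform control tube would itself reflect (numerically)
        VesselSegment("aneurysm-seg", _RIG_SEG_LEN, m["radius"], m["radius"],
                      m["h"], m["E"], m["poisson"], aneurysm=aneurysm,
                      dx_hint=0.005 if aneurysm is not None else None),
        VesselSegment("main-dist", dist_len, m["radius"], m["radius"],
                      m["h"], m["E"], m["poisson"]),
        VesselSegment("fitting-out", _RIG_FIT_LEN, _RIG_FIT["radius"],
                      _RIG_FIT["radius"], _RIG_FIT["h"], _RIG_FIT["E"],
                      _RIG_FIT["poisson"], dx_hint=_RIG_FIT_LEN / 2),
        VesselSegment("outlet-tube", _RIG_OUTLET_LEN, m["radius"], m["radius"],
                      m["h"], m["E"], m["poisson"], dx_hint=0.02),
        VesselSegment("reservoir", _RIG_RESERVOIR_LEN,
                      m["radius"] * np.sqrt(10.0), m["radius"] * np.sqrt(10.0),
                      m["h"], m["E"], m["poisson"], dx_hint=0.02),
    ]
    spec = PumpPulseSpec(shape=pulse_shape, stroke_volume=stroke_volume,
                         tube_area=np.pi * m["radius"] ** 2)
    pulse = pump_pulse(spec, pulse_dt, total_time=series_time)
    junctions = [
        [("main-prox", "end"), ("aneurysm-seg", "start")],
        [("aneurysm-seg", "end"), ("main-dist", "start")],
        [("main-dist", "end"), ("fitting-out", "start")],
        [("fitting-out", "end"), ("outlet-tube", "start")],
        [("outlet-tube", "end"), ("reservoir", "start")],
    ]
    monitors = [Monitor("main-prox", 0.02 / _RIG_PROX_LEN),
                Monitor("main-prox", 0.10 / _RIG_PROX_LEN),
                Monitor("main-prox", 0.25 / _RIG_PROX_LEN),
                Monitor("main-prox", 1.0)]
    return Network(
        segments=segments,
        junctions=junctions,
        inlet=("main-prox", "start", InletBC.from_waveform(pulse, "velocity")),
        terminals=[("reservoir", "end", TerminalBC("nonreflecting"))],
        fluid=FluidProperties(1000.0, 1.0e-3),
        monitors=monitors,
    )


def rig_ground_truth(D_mm: Optional[int], rho: float = 1000.0) -> dict:
    """Geometry-derived reference values for a rig fixture.

    ``dt_lag`` entries give the round trip from each monitored site to the
    bump midpoint at the healthy-tube wave speed; tau/K/dC_A come from the
    compliance integrals (single source of truth: the geometry module).
    """
    net = build_rig(D_mm)
    seg = net.segment("aneurysm-seg")
    c0 = net.segment("main-prox").wave_speed0(0.0, rho)
    summary = segment_compliance_summary(seg, rho)
    mid = _RIG_PROX_LEN + 0.5 * _RIG_SEG_LEN
    lags = {}
    for site_cm in (2, 10, 25, 50):
        lags[site_cm] = 2.0 * (mid - site_cm * 1e-2) / c0
    return dict(D_mm=D_mm, c0=c0, K=summary.K, tau=summary.tau,
                tau0=summary.tau0, excess_compliance=summary.excess_compliance,
                dt_lag_by_site_cm=lags, aneurysm_mid=mid)


# ---------------------------------------------------------------------------
# aortic chain
# ---------------------------------------------------------------------------

#: (id, name, length cm, inlet diameter mm, outlet diameter mm, tabulated
#: segment-average wave speed m/s).  Serial aorta from arch to abdominal
#: bifurcation plus the two common carotids; the Abdominal Aorta IV length is
#: already adjusted to host a real-size AAA.
AORTA_SEGMENTS = [
    (1,   "aortic-arch-1",     7.44, 31.9, 25.9, 4.03),
    (3,   "aortic-arch-2",     0.96, 25.9, 25.1, 4.08),
    (15,  "aortic-arch-3",     0.70, 25.1, 24.6, 4.09),
    (19,  "aortic-arch-4",     4.31, 24.6, 21.1, 4.12),
    (20,  "thoracic-aorta-1",  0.99, 21.1, 20.7, 4.15),
    (27,  "thoracic-aorta-2",  0.79, 20.7, 20.4, 4.15),
    (29,  "thoracic-aorta-3",  1.56, 20.4, 19.8, 4.16),
    (31,  "thoracic-aorta-4",  0.53, 19.8, 19.6, 4.17),
    (33,  "thoracic-aorta-5", 12.16, 19.6, 15.1, 4.23),
    (34,  "thoracic-aorta-6",  0.32, 15.1, 15.0, 4.30),
    (35,  "abdominal-aorta-1", 1.40, 15.0, 14.6, 4.31),
    (41,  "abdominal-aorta-2", 0.43, 14.6, 14.5, 4.32),
    (43,  "abdominal-aorta-3", 1.20, 14.5, 14.2, 4.32),
    (45,  "abdominal-aorta-4",10.60, 14.2, 12.9, 4.36),
    (47,  "abdominal-aorta-5", 1.00, 12.9, 11.8, 4.43),
    (5,   "r-common-carotid",  8.12,  9.0,  6.7, 4.89),
    (14,  "l-common-carotid", 12.13,  9.0,  6.7, 4.89),
]

_AORTA_E = 225e3
_AORTA_POISSON = 0.5
_AORTA_RHO = 1040.0
_AORTA_MU = 4.0e-3
_AAA_SEGMENT = "abdominal-aorta-4"
_AAA_LEN = 0.104
_AAA_X1 = 0.001
_MEAN_PRESSURE = 12.5e3      # Pa, sets total peripheral resistance
_FLOW_SPLIT = {"abdominal-aorta-5": 0.85,
               "r-common-carotid": 0.075, "l-common-carotid": 0.075}
_WK_RELAX = 1.0              # s, R2*C of each terminal


def _aorta_segment(name: str, aaa_k: Optional[float] = None) -> VesselSegment:
    row = next(r for r in AORTA_SEGMENTS if r[1] == name)
    _, _, L_cm, d1_mm, d2_mm, _ = row
    aneurysm = None
    # several tabulated segments are sub-centimetre: mesh them at half length
    dx_hint = min(5e-3, 0.5 * L_cm * 1e-2)
    if aaa_k is not None:
        aneurysm = AneurysmProfile("cosine", x1=_AAA_X1, length=_AAA_LEN,
                                   k_delta=aaa_k)
        dx_hint = 4e-3
    return VesselSegment(name, L_cm * 1e-2, 0.5e-3 * d1_mm, 0.5e-3 * d2_mm,
                         "adan", _AORTA_E, _AORTA_POISSON,
                         aneurysm=aneurysm, dx_hint=dx_hint)


def _inflow_pulse(period: float, stroke_volume: float, dt: float) -> Waveform:
    """Systolic sin^2 ejection (0.3 s) integrating to the stroke volume."""
    t = np.arange(0.0, period + 0.5 * dt, dt)
    T_s = 0.3 * period / 1.0 if period >= 0.6 else 0.3 * period
    q = np.where(t <= T_s, np.sin(np.pi * np.clip(t / T_s, 0, 1)) ** 2, 0.0)
    q *= stroke_volume / np.trapezoid(q, t)
    return Waveform(q, dt, quantity="flow", units="m3/s", site="aortic-root",
                    pulse_start=0.0)


def build_aorta_chain(aaa: Optional[str] = None, period: float = 1.0,
                      stroke_volume: float = 85e-6,
                      pulse_dt: float = 1e-3) -> Network:
    """Serial aortic chain with carotid branches and optional AAA.

    ``aaa`` is ``None`` (healthy), ``"AAA2"`` (peak radius twice the healthy
    one) or ``"AAA3"`` (three times).  The carotids branch at the arch: the
    right at the arch-1/arch-2 node (standing in for the brachiocephalic
    origin), the left one node downstream.  Terminals are three-element
    Windkessels with matched proximal resistance; the inlet is a periodic
    flow pulse.
    """
    k = {None: None, "AAA2": 1.0, "AAA3": 2.0}.get(aaa, "bad")
    if k == "bad":
        raise ValueError(f"unknown AAA severity {aaa!r} (None, 'AAA2', 'AAA3')")
    segments = []
    aorta_names = [r[1] for r in AORTA_SEGMENTS if "carotid" not in r[1]]
    for name in aorta_names:
        segments.append(_aorta_segment(
            name, aaa_k=k if name == _AAA_SEGMENT else None))
    segments.append(_aorta_segment("r-common-carotid"))
    segments.append(_aorta_segment("l-common-carotid"))

    junctions = []
    for up, dn in zip(aorta_names[:-1], aorta_names[1:]):
        j = [(up, "end"), (dn, "start")]
        if up == "aortic-arch-1":
            j.append(("r-common-carotid", "start"))
        elif up == "aortic-arch-2":
            j.append(("l-common-carotid", "start"))
        junctions.append(j)

    q_mean = stroke_volume / period
    terminals = []
    for name, frac in _FLOW_SPLIT.items():
        seg = next(s for s in segments if s.name == name)
        a_end = seg.radius_healthy(seg.length)
        A_end = np.pi * a_end**2
        c_end = seg.wave_speed0(seg.length, _AORTA_RHO)
        R1 = _AORTA_RHO * c_end / A_end
        R_tot = _MEAN_PRESSURE / (frac * q_mean)
        R2 = max(R_tot - R1, 0.0)
        C = _WK_RELAX / R2 if R2 > 0 else 0.0
        terminals.append((name, "end", TerminalBC("windkessel", R1=R1, R2=R2, C=C)))

    inflow = _inflow_pulse(period, stroke_volume, pulse_dt)
    monitors = [Monitor(name, 0.5) for name in aorta_names[:8]]  # arch..thoracic-4
    monitors += [Monitor("r-common-carotid", 0.5), Monitor("l-common-carotid", 0.5)]
    return Network(
        segments=segments,
        junctions=junctions,
        inlet=("aortic-arch-1", "start", InletBC.from_waveform(inflow, "flow")),
        terminals=terminals,
        fluid=FluidProperties(_AORTA_RHO, _AORTA_MU),
        monitors=monitors,
    )


def aorta_ground_truth(aaa: Optional[str] = None) -> dict:
    """Geometry-derived AAA references for the chain.

    ``dt_lag_by_site`` maps each monitored site label to the round-trip lag
    from the site (aorta sites) or from the carotid origin (carotid sites) to
    the AAA midpoint, accumulated midpoint-to-midpoint over the tabulated
    segment-average wave speeds.
    """
    net = build_aorta_chain(aaa)
    seg = net.segment(_AAA_SEGMENT)
    summary = segment_compliance_summary(seg, _AORTA_RHO)
    rows = {r[1]: r for r in AORTA_SEGMENTS}
    aorta_names = [r[1] for r in AORTA_SEGMENTS if "carotid" not in r[1]]

    def transit(from_name: str, from_frac: float) -> float:
        """One-way travel time from a position to the AAA midpoint."""
        i0 = aorta_names.index(from_name)
        iA = aorta_names.index(_AAA_SEGMENT)
        t = 0.0
        for idx in range(i0, iA + 1):
            name = aorta_names[idx]
            L = rows[name][2] * 1e-2
            c = rows[name][5]
            lo = from_frac * L if idx == i0 else 0.0
            hi = (_AAA_X1 + 0.5 * _AAA_LEN) if idx == iA else L
            t += max(hi - lo, 0.0) / c
        return t

    lags = {}
    for mnt in net.monitors:
        if "carotid" in mnt.segment:
            # round trip from the carotid origin at the arch
            origin = "aortic-arch-2" if mnt.segment == "r-common-carotid" \
                else "aortic-arch-3"
            lags[mnt.label] = 2.0 * transit(origin, 0.0)
        else:
            lags[mnt.label] = 2.0 * transit(mnt.segment, mnt.s)
    c45 = seg.mean_wave_speed(_AORTA_RHO)
    A45 = np.pi * seg.radius_healthy(0.5 * seg.length) ** 2
    return dict(aaa=aaa, K=summary.K, tau=summary.tau, tau0=summary.tau0,
                excess_compliance=summary.excess_compliance,
                dt_lag_by_site=lags, c0_aaa=c45, A0_aaa=A45,
                rho=_AORTA_RHO, L_A=_AAA_LEN)


# ---------------------------------------------------------------------------
# noise and the catalogue
# ---------------------------------------------------------------------------

def add_noise(w: Waveform, relative_sigma: float, seed: int) -> Waveform:
    """Seeded white Gaussian noise at ``relative_sigma`` x RMS of the signal."""
    if relative_sigma < 0:
        raise ValueError("relative_sigma must be >= 0")
    if relative_sigma == 0:
        return w.with_values(w.values.copy())
    rms = float(np.sqrt(np.mean(w.values**2)))
    rng = np.random.default_rng(seed)
    return w.with_values(w.values + relative_sigma * rms *
                         rng.standard_normal(len(w.values)))


@dataclass
class FixtureCatalogEntry:
    """One ready-to-run study condition.

    ``build()`` returns the network; ``ground_truth`` is recomputed from the
    geometry module on construction.  ``site`` and ``config`` are the
    parameters a detection run at ``monitor_label`` should use; ``sim_kwargs``
    are the run_simulation arguments under which the fixture is known to be
    stable.
    """

    name: str
    build: callable
    ground_truth: dict
    monitor_label: str
    site: SiteParams
    config: DetectorConfig
    sim_kwargs: dict = field(default_factory=dict)


def _rig_entry(D_mm: Optional[int]) -> FixtureCatalogEntry:
    name = "rig-control" if D_mm is None else f"rig-D{D_mm}"
    gt = rig_ground_truth(D_mm)
    c0 = gt["c0"]
    site = SiteParams(rho=1000.0, c0=c0, A0=np.pi * _RIG_MAIN["radius"] ** 2,
                      L_A_assumed=_RIG_ANEURYSM_LEN)
    # window: past the echo onset, before the distal-fitting reflection
    # (round trip 2 cm -> 2 m at c0 ~ 0.19 s)
    # single clean echo: fit the unfiltered backward wave (the Gaussian
    # high-pass is needed only when many reflectors overlap, as in the chain);
    # the characteristic separation suppresses finite-amplitude leakage at the
    # rig's ~5% u/c0 pulse amplitude
    config = DetectorConfig(tau_expected=0.02, period=0.39,
                            window_fraction=1.0 / 3.0,
                            dt_range=(0.02, 0.09), tau_range=(1e-4, 0.15),
                            mode="pressure", highpass=False,
                            separation="characteristic")
    return FixtureCatalogEntry(
        name=name, build=lambda: build_rig(D_mm), ground_truth=gt,
        monitor_label="main-prox@0.04", site=site, config=config,
        sim_kwargs=dict(duration=0.45, cfl=0.5, dx=0.01, mode="single"))


def _aorta_entry(aaa: Optional[str]) -> FixtureCatalogEntry:
    suffix = {None: "healthy", "AAA2": "AAA2", "AAA3": "AAA3"}[aaa]
    gt = aorta_ground_truth(aaa)
    site = SiteParams(rho=_AORTA_RHO, c0=gt["c0_aaa"], A0=gt["A0_aaa"],
                      L_A_assumed=_AAA_LEN)
    lcc = gt["dt_lag_by_site"]["l-common-carotid@0.5"]
    config = DetectorConfig(tau_expected=0.035, period=1.0,
                            window_fraction=1.0 / 3.0,
                            dt_range=(0.6 * lcc, 1.8 * lcc),
                            tau_range=(1e-4, 0.3), mode="velocity",
                            periodic_record=True)
    return FixtureCatalogEntry(
        name=f"aorta-chain-{suffix}", build=lambda: build_aorta_chain(aaa),
        ground_truth=gt, monitor_label="l-common-carotid@0.5", site=site,
        config=config,
        sim_kwargs=dict(mode="periodic", period=1.0, n_cycles=3, cfl=0.5,
                        dx=0.005, init_pressure=10.0e3))


FIXTURE_NAMES = ("rig-control", "rig-D24", "rig-D34", "rig-D44", "rig-D50",
                 "aorta-chain-healthy", "aorta-chain-AAA2", "aorta-chain-AAA3")


def catalogue() -> dict:
    """All shipped fixtures, keyed by name."""
    entries = [_rig_entry(None)] + [_rig_entry(D) for D in RIG_DIAMETERS_MM]
    entries += [_aorta_entry(a) for a in (None, "AAA2", "AAA3")]
    return {e.name: e for e in entries}
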