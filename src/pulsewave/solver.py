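"""1D pulse-wave solver on networks of compliant tube segments.

Governing equations (cross-sectional area ``A``, mean velocity ``u``)::

    A_t + (A u)_x                  = 0
    u_t + (u^2/2 + p/rho)_x        = -8 pi mu u / (rho A)
    p = p_ext + beta(x) (sqrt(A) - sqrt(A0(x))),  beta = sqrt(pi) h E' / A0

The system is strictly hyperbolic and subcritical (|u| < c, with
``c^2 = beta sqrt(A) / 2 rho``); its Riemann invariants ``w_{f,b} = u +- 4c``
advect at ``u +- c`` and carry the boundary coupling:

* inlet: prescribed velocity/pressure/flow combined with the outgoing
  backward invariant extrapolated from the interior;
* junctions: continuity of flow rate and of total pressure
  ``p + rho u^2 / 2`` across all incident segment ends, solved by damped
  Newton iteration together with the outgoing invariants;
* terminals: non-reflecting (frozen incoming invariant) or a three-element
  Windkessel (R1 - [C || R2]) integrated implicitly.

Interior nodes advance with a two-step MacCormack (Lax-Wendroff family)
predictor-corrector, second-order on smooth solutions, with the friction
source integrated pointwise.  Pressure enters through the flux term evaluated
with the *local* ``beta`` and ``A0``, which is exactly the momentum equation
for tapered or aneurysmal vessels - no extra geometric source is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .geometry import FluidProperties, GeometryError, VesselSegment
from .waves import Waveform

__all__ = [
    "SolverError",
    "InletBC",
    "TerminalBC",
    "Monitor",
    "Network",
    "Mesh",
    "State",
    "SimulationResult",
    "discretize",
    "run_simulation",
]


class SolverError(RuntimeError):
    """Raised on instability, CFL violation, or failed boundary solves."""


# --------------------------------------------------------------------------
# boundary-condition descriptions
# --------------------------------------------------------------------------

@dataclass
class InletBC:
    """Prescribed time series at the network inlet.

    ``quantity`` is ``"velocity"`` (m/s), ``"pressure"`` (Pa, relative to the
    rest state) or ``"flow"`` (m^3/s).  Beyond the series the rest value is
    held (with a one-time warning).  ``exact_pressure`` switches the
    pressure-to-characteristic conversion from the linearised ``rho c0``
    relation to the exact inversion of the tube law.
    """

    times: np.ndarray
    values: np.ndarray
    quantity: str = "velocity"
    exact_pressure: bool = False
    _warned: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise SolverError("inlet series times/values must be matching 1D arrays")
        if self.quantity not in ("velocity", "pressure", "flow"):
            raise SolverError(f"unknown inlet quantity {self.quantity!r}")

    @classmethod
    def from_waveform(cls, w: Waveform, quantity: Optional[str] = None,
                      **kw) -> "InletBC":
        return cls(w.times, w.values, quantity or w.quantity or "velocity", **kw)

    def value_at(self, t: float) -> float:
        if t > self.times[-1] + 1e-12:
            if not self._warned:
                warnings.warn("inlet series exhausted; holding rest value",
                              RuntimeWarning, stacklevel=2)
                self._warned = True
            return 0.0
        return float(np.interp(t, self.times, self.values))


@dataclass
class TerminalBC:
    """Terminal model: ``"nonreflecting"`` or ``"windkessel"`` (R1-C-R2).

    Windkessel resistances in Pa s/m^3, compliance in m^3/Pa; ``p_out`` is the
    distal (venous) pressure.  ``R2=0, C=0`` degenerates to a pure resistor
    R1, which absorbs perfectly when R1 equals the characteristic impedance
    ``rho c0 / A0``.
    """

    kind: str = "nonreflecting"
    R1: float = 0.0
    R2: float = 0.0
    C: float = 0.0
    p_out: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("nonreflecting", "windkessel"):
            raise SolverError(f"unknown terminal kind {self.kind!r}")
        if min(self.R1, self.R2, self.C) < 0:
            raise SolverError("Windkessel parameters must be >= 0")
        if self.kind == "windkessel" and self.R1 <= 0:
            raise SolverError("windkessel needs R1 > 0")


@dataclass(frozen=True)
class Monitor:
    """A monitored site: fractional position ``s`` in [0, 1] along a segment."""

    segment: str
    s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise SolverError(f"monitor position s={self.s} outside [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.segment}@{self.s:g}"


@dataclass
class Network:
    """Segments + topology + boundary attachments + monitored sites.

    ``junctions`` is a list of junctions, each a list of ``(segment_name,
    end)`` pairs with ``end`` in {"start", "end"}.  Every segment end must be
    attached to exactly one of: the inlet, a junction, or a terminal.
    """

    segments: Sequence[VesselSegment]
    junctions: Sequence[Sequence[tuple]] = field(default_factory=list)
    inlet: tuple = None            # (segment_name, end, InletBC)
    terminals: Sequence[tuple] = field(default_factory=list)  # (name, end, TerminalBC)
    fluid: FluidProperties = field(default_factory=FluidProperties)
    monitors: Sequence[Monitor] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise SolverError("duplicate segment names")
        self._by_name = {s.name: s for s in self.segments}
        attached: dict[tuple, int] = {}

        def attach(name, end):
            if name not in self._by_name:
                raise SolverError(f"unknown segment {name!r} in attachment")
            if end not in ("start", "end"):
                raise SolverError(f"bad end {end!r}")
            key = (name, end)
            attached[key] = attached.get(key, 0) + 1

        if self.inlet is not None:
            attach(self.inlet[0], self.inlet[1])
        for junc in self.junctions:
            if not 2 <= len(junc) <= 3:
                raise SolverError("junctions must join 2 or 3 segment ends")
            for name, end in junc:
                attach(name, end)
        for name, end, _ in self.terminals:
            attach(name, end)
        for s in self.segments:
            for end in ("start", "end"):
                cnt = attached.get((s.name, end), 0)
                if cnt != 1:
                    raise SolverError(
                        f"segment end {s.name}:{end} attached {cnt} times "
                        "(must be exactly once)")
        for m in self.monitors:
            if m.segment not in self._by_name:
                raise SolverError(f"monitor references unknown segment {m.segment!r}")

    def segment(self, name: str) -> VesselSegment:
        return self._by_name[name]


# --------------------------------------------------------------------------
# mesh and state
# --------------------------------------------------------------------------

@dataclass
class _SegMesh:
    name: str
    x: np.ndarray
    dx: float
    A0: np.ndarray
    sqrtA0: np.ndarray
    beta: np.ndarray
    h: np.ndarray
    p_ext: float


@dataclass
class Mesh:
    """Per-segment nodal geometry sampled from the network."""

    segs: list
    index: dict

    def seg(self, name: str) -> _SegMesh:
        return self.segs[self.index[name]]


def discretize(network: Network, dx: float = 0.01,
               min_nodes: int = 3) -> Mesh:
    """Sample geometry onto per-segment uniform grids with spacing ~``dx``.

    A segment's own ``dx_hint`` overrides the target spacing (used for short
    stiff fittings).  Node counts are at least ``min_nodes``; requesting a
    grid coarser than half the segment length raises with the offending
    segment names.
    """
    if dx <= 0:
        raise SolverError("dx must be positive")
    too_coarse = [s.name for s in network.segments
                  if (s.dx_hint or dx) > 0.5 * s.length + 1e-12]
    if too_coarse:
        raise SolverError("segments shorter than 2*dx: " + ", ".join(too_coarse))
    segs, index = [], {}
    for s in network.segments:
        target = s.dx_hint or dx
        n_cells = max(min_nodes - 1, int(round(s.length / target)))
        x = np.linspace(0.0, s.length, n_cells + 1)
        r = np.asarray(s.radius(x), dtype=float)
        A0 = np.pi * r * r
        h = np.asarray(s.thickness(x), dtype=float)
        beta = np.sqrt(np.pi) * h * s.plate_modulus / A0
        index[s.name] = len(segs)
        segs.append(_SegMesh(s.name, x, x[1] - x[0], A0, np.sqrt(A0), beta, h,
                             s.external_pressure))
    return Mesh(segs, index)


@dataclass
class State:
    """Solution arrays (per-segment A and u) plus Windkessel charge states."""

    A: list
    u: list
    t: float = 0.0
    pc: dict = field(default_factory=dict)


def _initial_state(mesh: Mesh, network: Network, init_pressure: float) -> State:
    A, u = [], []
    for sm in mesh.segs:
        sqrtA = sm.sqrtA0 * (1.0 + init_pressure / (sm.beta * sm.sqrtA0))
        A.append(sqrtA**2)
        u.append(np.zeros_like(sm.A0))
    pc = {}
    for name, end, term in network.terminals:
        if term.kind == "windkessel":
            if term.R2 == 0.0:
                pc[(name, end)] = term.p_out
            else:
                denom = 1.0 / term.R1 + 1.0 / term.R2
                pc[(name, end)] = (init_pressure / term.R1 +
                                   term.p_out / term.R2) / denom
    return State(A, u, 0.0, pc)


# --------------------------------------------------------------------------
# local physics helpers
# --------------------------------------------------------------------------

# density is needed in tight loops; stored module-level per run (single-threaded)
_RHO = [1000.0]


def _c_of(A: float, beta: float) -> float:
    return (beta * np.sqrt(A) / (2.0 * _RHO[0])) ** 0.5


def _A_of_c(c: float, beta: float) -> float:
    # c^2 = beta sqrt(A) / 2 rho  ->  A = (2 rho c^2 / beta)^2
    return (2.0 * _RHO[0] * c * c / beta) ** 2


# --------------------------------------------------------------------------
# interior scheme
# --------------------------------------------------------------------------

def _mccormack_segment(A, u, sm: _SegMesh, dt: float, rho: float, mu: float):
    """One MacCormack step; returns updated interior (endpoints stale)."""
    dx = sm.dx
    r = dt / dx
    fric = -8.0 * np.pi * mu / rho

    p = sm.p_ext + sm.beta * (np.sqrt(A) - sm.sqrtA0)
    F1 = A * u
    F2 = 0.5 * u * u + p / rho
    # predictor (forward differences), nodes 0..n-2
    As = A.copy(); us = u.copy()
    As[:-1] = A[:-1] - r * (F1[1:] - F1[:-1])
    us[:-1] = u[:-1] - r * (F2[1:] - F2[:-1]) + dt * fric * u[:-1] / A[:-1]
    if np.any(As[:-1] <= 0):
        raise SolverError(f"negative area in predictor, segment {sm.name}")
    ps = sm.p_ext + sm.beta * (np.sqrt(As) - sm.sqrtA0)
    G1 = As * us
    G2 = 0.5 * us * us + ps / rho
    # corrector (backward differences), nodes 1..n-1
    An = A.copy(); un = u.copy()
    An[1:] = 0.5 * (A[1:] + As[1:]) - 0.5 * r * (G1[1:] - G1[:-1])
    un[1:] = 0.5 * (u[1:] + us[1:]) - 0.5 * r * (G2[1:] - G2[:-1]) \
        + 0.5 * dt * fric * us[1:] / As[1:]
    return An, un


# --------------------------------------------------------------------------
# characteristic extraction and boundary solves
# --------------------------------------------------------------------------

def _outgoing_invariant(A, u, sm: _SegMesh, dt: float, side: str) -> float:
    """Invariant advected toward the boundary, sampled at its foot point."""
    if side == "start":
        c0_, c1_ = _c_of(A[0], sm.beta[0]), _c_of(A[1], sm.beta[1])
        lam = u[0] - c0_                      # negative
        frac = min(max(-lam * dt / sm.dx, 0.0), 1.0)
        w0 = u[0] - 4.0 * c0_
        w1 = u[1] - 4.0 * c1_
        return w0 + frac * (w1 - w0)
    else:
        cN_, cM_ = _c_of(A[-1], sm.beta[-1]), _c_of(A[-2], sm.beta[-2])
        lam = u[-1] + cN_
        frac = min(max(lam * dt / sm.dx, 0.0), 1.0)
        w0 = u[-1] + 4.0 * cN_
        w1 = u[-2] + 4.0 * cM_
        return w0 + frac * (w1 - w0)


def _apply_inlet(state: State, mesh: Mesh, network: Network, dt: float,
                 rest: dict) -> None:
    name, end, bc = network.inlet
    sm = mesh.seg(name)
    i = mesh.index[name]
    A, u = state.A[i], state.u[i]
    t_new = state.t + dt
    val = bc.value_at(t_new)
    if end == "start":
        w_out = _outgoing_invariant(A, u, sm, dt, "start")   # w_b known
        beta0, node = sm.beta[0], 0
    else:
        w_out = _outgoing_invariant(A, u, sm, dt, "end")     # w_f known
        beta0, node = sm.beta[-1], -1
    c_rest, rho = rest[(name, end)], _RHO[0]

    if bc.quantity == "velocity":
        u_new = val if end == "start" else -val
        # start: w_b = u - 4c ; end: w_f = u + 4c
        c_new = 0.25 * ((u_new - w_out) if end == "start" else (w_out - u_new))
    elif bc.quantity == "pressure":
        if bc.exact_pressure:
            sqA = sm.sqrtA0[node] + val / beta0
            if sqA <= 0:
                raise SolverError("prescribed pressure collapses the inlet")
            A_new = sqA * sqA
            c_new = _c_of(A_new, beta0)
            u_new = w_out + 4.0 * c_new if end == "start" else w_out - 4.0 * c_new
            state.A[i][node], state.u[i][node] = A_new, u_new
            return
        # linearised forward-wave relation: w_in - w_rest = 2 dp / (rho c0)
        w_in_rest = 4.0 * c_rest if end == "start" else -4.0 * c_rest
        w_in = w_in_rest + (2.0 * val / (rho * c_rest)) * (1 if end == "start" else -1)
        u_new = 0.5 * (w_in + w_out)
        c_new = 0.125 * ((w_in - w_out) if end == "start" else (w_out - w_in))
    else:  # prescribed flow: solve A(c) * u(c) = Q
        Q = val if end == "start" else -val
        c_new = c_rest
        for _ in range(60):
            A_try = _A_of_c(c_new, beta0)
            u_try = w_out + 4.0 * c_new if end == "start" else w_out - 4.0 * c_new
            f = A_try * u_try - Q
            dc = 1e-8 * max(c_rest, 1.0)
            A2 = _A_of_c(c_new + dc, beta0)
            u2 = w_out + 4.0 * (c_new + dc) if end == "start" else w_out - 4.0 * (c_new + dc)
            df = (A2 * u2 - f - Q) / dc
            step = f / df if df != 0 else 0.0
            c_next = c_new - step
            if c_next <= 0:
                c_next = 0.5 * c_new
            if abs(c_next - c_new) < 1e-14 * c_rest:
                c_new = c_next
                break
            c_new = c_next
        u_new = w_out + 4.0 * c_new if end == "start" else w_out - 4.0 * c_new
    if c_new <= 0:
        raise SolverError("inlet characteristic solve gave non-positive wave speed")
    state.A[i][node] = _A_of_c(c_new, beta0)
    state.u[i][node] = u_new


def _windkessel_boundary(state: State, mesh: Mesh, name: str, end: str,
                         term: TerminalBC, dt: float, rest: dict) -> None:
    sm = mesh.seg(name)
    i = mesh.index[name]
    A, u = state.A[i], state.u[i]
    node = -1 if end == "end" else 0
    beta0 = sm.beta[node]
    sqA0 = sm.sqrtA0[node]
    w_out = _outgoing_invariant(A, u, sm, dt, end)
    rho = _RHO[0]
    pc_key = (name, end)
    pc_old = state.pc.get(pc_key, term.p_out)
    sgn = 1.0 if end == "end" else -1.0    # outflow direction along +x?

    # R2 = 0 shorts the capacitor to the venous pressure (pure R1 resistor);
    # otherwise eliminate the implicit-Euler capacitor state in closed form.
    shorted = term.R2 == 0.0
    g2 = 0.0 if shorted else 1.0 / term.R2
    cap = term.C / dt if term.C > 0 else 0.0
    denom = cap + 1.0 / term.R1 + g2

    def resid(A_try: float):
        c = _c_of(A_try, beta0)
        u_try = (w_out - 4.0 * c) if end == "end" else (w_out + 4.0 * c)
        p = sm.p_ext + beta0 * (np.sqrt(A_try) - sqA0)
        if shorted:
            pc_new = term.p_out
        else:
            pc_new = (cap * pc_old + p / term.R1 + g2 * term.p_out) / denom
        Q = sgn * A_try * u_try           # flow leaving the network
        return Q - (p - pc_new) / term.R1, u_try, pc_new

    A_try = A[node]
    ok = False
    for _ in range(80):
        f, u_try, pc_new = resid(A_try)
        dA = 1e-8 * sm.A0[node]
        f2, _, _ = resid(A_try + dA)
        df = (f2 - f) / dA
        if df == 0:
            break
        A_next = A_try - f / df
        if A_next <= 0.1 * sm.A0[node]:
            A_next = 0.5 * (A_try + 0.1 * sm.A0[node])
        if abs(A_next - A_try) < 1e-14 * sm.A0[node]:
            A_try = A_next
            ok = True
            break
        A_try = A_next
    f, u_try, pc_new = resid(A_try)
    if not ok and abs(f) > 1e-8 * max(abs(A_try * u_try), 1e-12):
        raise SolverError(f"Windkessel solve failed at {name}:{end} (residual {f:.3g})")
    state.A[i][node] = A_try
    state.u[i][node] = u_try
    state.pc[pc_key] = pc_new


def _apply_terminals(state: State, mesh: Mesh, network: Network, dt: float,
                     rest: dict) -> None:
    for name, end, term in network.terminals:
        sm = mesh.seg(name)
        i = mesh.index[name]
        node = -1 if end == "end" else 0
        if term.kind == "nonreflecting":
            w_out = _outgoing_invariant(state.A[i], state.u[i], sm, dt, end)
            c_rest = rest[(name, end)]
            # incoming invariant frozen at its rest value
            if end == "end":
                w_in = -4.0 * c_rest
                u_new = 0.5 * (w_out + w_in)
                c_new = 0.125 * (w_out - w_in)
            else:
                w_in = 4.0 * c_rest
                u_new = 0.5 * (w_in + w_out)
                c_new = 0.125 * (w_in - w_out)
            state.A[i][node] = _A_of_c(c_new, sm.beta[node])
            state.u[i][node] = u_new
        else:
            _windkessel_boundary(state, mesh, name, end, term, dt, rest)


def _junction_solve(state: State, mesh: Mesh, junction, dt: float,
                    include_dynamic: bool = True) -> None:
    """Damped Newton on the junction coupling conditions.

    Unknowns: the area at each incident end.  Constraints: signed flow-rate
    balance and equality of total pressure ``p + rho u^2/2`` across ends,
    with each end's outgoing Riemann invariant held at its advected value.
    """
    rho = _RHO[0]
    ends = []
    for name, end in junction:
        sm = mesh.seg(name)
        i = mesh.index[name]
        node = -1 if end == "end" else 0
        w = _outgoing_invariant(state.A[i], state.u[i], sm, dt, end)
        ends.append(dict(i=i, node=node, beta=sm.beta[node], sqA0=sm.sqrtA0[node],
                         p_ext=sm.p_ext, w=w, sgn=1.0 if end == "end" else -1.0,
                         A=state.A[i][node], end=end))
    m = len(ends)
    Q_scale = max(e["A"] * _c_of(e["A"], e["beta"]) for e in ends)
    p_scale = max(2.0 * rho * _c_of(e["A"], e["beta"]) ** 2 for e in ends)

    def unpack(Avec):
        us, ps = [], []
        for e, A_try in zip(ends, Avec):
            c = _c_of(A_try, e["beta"])
            u = (e["w"] - 4.0 * c) if e["end"] == "end" else (e["w"] + 4.0 * c)
            p = e["p_ext"] + e["beta"] * (np.sqrt(A_try) - e["sqA0"])
            if include_dynamic:
                p = p + 0.5 * rho * u * u
            us.append(u); ps.append(p)
        return us, ps

    def residual(Avec):
        us, ps = unpack(Avec)
        r = np.empty(m)
        r[0] = sum(e["sgn"] * A_try * u
                   for e, A_try, u in zip(ends, Avec, us)) / Q_scale
        for k in range(1, m):
            r[k] = (ps[k] - ps[0]) / p_scale
        return r

    Avec = np.array([e["A"] for e in ends])
    r = residual(Avec)
    it = 0
    while np.max(np.abs(r)) > 1e-10:
        it += 1
        if it > 50:
            raise SolverError(
                f"junction Newton failed to converge: ends={[(e['i'], e['node']) for e in ends]}, "
                f"residual={np.max(np.abs(r)):.3g}, A={Avec}")
        J = np.empty((m, m))
        for j in range(m):
            dA = 1e-8 * Avec[j]
            Ap = Avec.copy(); Ap[j] += dA
            J[:, j] = (residual(Ap) - r) / dA
        try:
            step = np.linalg.solve(J, r)
        except np.linalg.LinAlgError as exc:
            raise SolverError(f"singular junction Jacobian: {exc}")
        lam = 1.0
        norm0 = np.max(np.abs(r))
        for _ in range(12):
            A_new = Avec - lam * step
            if np.all(A_new > 0):
                r_new = residual(A_new)
                if np.max(np.abs(r_new)) < norm0:
                    break
            lam *= 0.5
        else:
            A_new = Avec - lam * step
            A_new = np.maximum(A_new, 0.05 * np.array([e["A"] for e in ends]))
            r_new = residual(A_new)
        Avec, r = A_new, r_new
    us, _ = unpack(Avec)
    for e, A_try, u in zip(ends, Avec, us):
        state.A[e["i"]][e["node"]] = A_try
        state.u[e["i"]][e["node"]] = u


# --------------------------------------------------------------------------
# time loop
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Waveforms per monitored site plus run statistics."""

    waveforms: dict            # site label -> {"p","u","Q","A"} -> Waveform
    n_steps: int
    dt_min: float
    duration: float

    def site(self, label: str) -> dict:
        return self.waveforms[label]


def _stable_dt(state: State, mesh: Mesh, cfl: float) -> float:
    dt = np.inf
    for i, sm in enumerate(mesh.segs):
        A, u = state.A[i], state.u[i]
        c = np.sqrt(sm.beta * np.sqrt(A) / (2.0 * _RHO[0]))
        speed = np.max(np.abs(u) + c)
        dt = min(dt, sm.dx / speed)
    return cfl * dt


def run_simulation(network: Network, duration: Optional[float] = None,
                   cfl: float = 0.5, dx: float = 0.01,
                   mode: str = "single", period: Optional[float] = None,
                   n_cycles: int = 3, output_dt: float = 1e-3,
                   init_pressure: float = 0.0,
                   include_dynamic_pressure: bool = True,
                   mesh: Optional[Mesh] = None) -> SimulationResult:
    """Advance the network and return monitored waveforms.

    ``mode="single"`` runs one pulse for ``duration`` seconds from rest (or
    from the uniform ``init_pressure``); ``mode="periodic"`` repeats the inlet
    series with period ``period`` for ``n_cycles`` cycles and returns the last
    cycle with time rebased to ``[0, period)``.  Output is resampled to the
    uniform rate ``1/output_dt`` (default 1 kHz).
    """
    if not 0 < cfl <= 0.9:
        raise SolverError("CFL number must be in (0, 0.9]")
    if mode not in ("single", "periodic"):
        raise SolverError(f"unknown mode {mode!r}")
    if mode == "periodic":
        if period is None:
            raise SolverError("periodic mode needs a period")
        duration = n_cycles * period
    if duration is None or duration <= 0:
        raise SolverError("duration must be positive")
    if network.inlet is None:
        raise SolverError("network has no inlet")

    mesh = mesh or discretize(network, dx)
    _RHO[0] = network.fluid.density
    mu = network.fluid.viscosity
    state = _initial_state(mesh, network, init_pressure)

    # rest wave speeds at attached ends, for characteristic conversions
    rest = {}
    ends = [(network.inlet[0], network.inlet[1])] + \
        [(n, e) for (n, e, _) in network.terminals]
    for name, end in ends:
        sm = mesh.seg(name)
        i = mesh.index[name]
        node = -1 if end == "end" else 0
        rest[(name, end)] = _c_of(state.A[i][node], sm.beta[node])

    inlet_bc = network.inlet[2]
    if mode == "periodic":
        base = inlet_bc
        times, vals = base.times, base.values

        class _Periodic:
            quantity = base.quantity
            exact_pressure = base.exact_pressure

            @staticmethod
            def value_at(t):
                return float(np.interp(t % period, times, vals,
                                       left=vals[0], right=vals[-1]))
        inlet_bc = _Periodic()
        network = Network(network.segments, network.junctions,
                          (network.inlet[0], network.inlet[1], inlet_bc),
                          network.terminals, network.fluid, network.monitors)

    # monitor bookkeeping: (segment index, node weights)
    mons = []
    for mnt in network.monitors:
        sm = mesh.seg(mnt.segment)
        i = mesh.index[mnt.segment]
        xpos = mnt.s * sm.x[-1]
        j = min(int(xpos / sm.dx), len(sm.x) - 2)
        wgt = (xpos - sm.x[j]) / sm.dx
        mons.append((mnt.label, i, j, wgt))
    rec_t = []
    rec = {lab: {"p": [], "u": [], "Q": [], "A": []} for lab, *_ in mons}

    def record():
        rec_t.append(state.t)
        for lab, i, j, wgt in mons:
            sm = mesh.segs[i]
            A = (1 - wgt) * state.A[i][j] + wgt * state.A[i][j + 1]
            u = (1 - wgt) * state.u[i][j] + wgt * state.u[i][j + 1]
            beta = (1 - wgt) * sm.beta[j] + wgt * sm.beta[j + 1]
            sqA0 = (1 - wgt) * sm.sqrtA0[j] + wgt * sm.sqrtA0[j + 1]
            p = sm.p_ext + beta * (np.sqrt(A) - sqA0)
            rec[lab]["p"].append(p)
            rec[lab]["u"].append(u)
            rec[lab]["Q"].append(A * u)
            rec[lab]["A"].append(A)

    record()
    n_steps = 0
    dt_min = np.inf
    while state.t < duration - 1e-12:
        dt = min(_stable_dt(state, mesh, cfl), duration - state.t)
        dt_min = min(dt_min, dt)
        for i, sm in enumerate(mesh.segs):
            An, un = _mccormack_segment(state.A[i], state.u[i], sm, dt,
                                        _RHO[0], mu)
            if np.any(~np.isfinite(An)) or np.any(An <= 0):
                bad = int(np.argmin(An))
                raise SolverError(
                    f"instability: segment {sm.name} node {bad} at t={state.t:.5f}s")
            state.A[i], state.u[i] = An, un
        _apply_inlet(state, mesh, network, dt, rest)
        _apply_terminals(state, mesh, network, dt, rest)
        for junc in network.junctions:
            _junction_solve(state, mesh, junc, dt, include_dynamic_pressure)
        state.t += dt
        n_steps += 1
        # subcriticality guard (cheap scan every 20 steps)
        if n_steps % 20 == 0:
            for i, sm in enumerate(mesh.segs):
                c = np.sqrt(sm.beta * np.sqrt(state.A[i]) / (2.0 * _RHO[0]))
                if np.any(np.abs(state.u[i]) >= c):
                    raise SolverError(
                        f"supercritical flow in segment {sm.name} at t={state.t:.5f}s")
        record()

    # resample to the uniform output grid
    rec_t = np.asarray(rec_t)
    if mode == "periodic":
        t_lo, t_hi = duration - period, duration
    else:
        t_lo, t_hi = 0.0, duration
    tout = np.arange(t_lo, t_hi + 0.5 * output_dt, output_dt)
    waveforms = {}
    quantity_units = {"p": ("pressure", "Pa"), "u": ("velocity", "m/s"),
                      "Q": ("flow", "m3/s"), "A": ("area", "m2")}
    for lab, *_ in mons:
        waveforms[lab] = {}
        for q, series in rec[lab].items():
            vals = np.interp(tout, rec_t, np.asarray(series))
            qname, unit = quantity_units[q]
            waveforms[lab][q] = Waveform(vals, output_dt,
                                         t_start=0.0 if mode == "periodic" else t_lo,
                                         quantity=qname, units=unit, site=lab)
    return SimulationResult(waveforms, n_steps, float(dt_min), duration)
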