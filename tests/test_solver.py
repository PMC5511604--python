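"""Pulse-wave solver: discretization, propagation physics, boundary models."""

import numpy as np
import pytest

from pulsewave.geometry import FluidProperties, VesselSegment
from pulsewave.solver import (
    InletBC,
    Monitor,
    Network,
    SolverError,
    TerminalBC,
    discretize,
    run_simulation,
)
from pulsewave.waves import separate

RHO = 1000.0


def tube(name="tube", L=1.0, a=8.5e-3, E=2.8e6, **kw):
    return VesselSegment(name, L, a, a, 2e-3, E, 0.5, **kw)


def gaussian_inlet(amp=1e-4, centre=0.02, width=0.005, t_end=0.4):
    t = np.linspace(0, t_end, int(t_end / 1e-4) + 1)
    return InletBC(t, amp * np.exp(-(((t - centre) / width) ** 2)), "velocity")


def single_tube_net(seg, terminal, inlet=None, mu=0.0, monitors=(0.5,)):
    return Network(
        segments=[seg],
        inlet=(seg.name, "start", inlet or gaussian_inlet()),
        terminals=[(seg.name, "end", terminal)],
        fluid=FluidProperties(RHO, mu),
        monitors=[Monitor(seg.name, s) for s in monitors],
    )


class TestDiscretize:
    def test_node_count_uniform_tube(self):
        mesh = discretize(single_tube_net(tube(L=2.0), TerminalBC()), dx=0.01)
        assert len(mesh.seg("tube").x) == 201

    def test_refuses_too_coarse(self):
        net = single_tube_net(tube(L=0.015), TerminalBC())
        with pytest.raises(SolverError, match="tube"):
            discretize(net, dx=0.01)

    def test_aneurysm_bump_sampled_at_peak(self):
        from pulsewave.geometry import AneurysmProfile
        seg = VesselSegment("an", 0.14, 8.5e-3, 8.5e-3, 2e-3, 2.8e6, 0.5,
                            aneurysm=AneurysmProfile(
                                "arc", 0.025, 0.09, peak_diameter=0.05,
                                conjugation_radius=0.01))
        mesh = discretize(single_tube_net(seg, TerminalBC()), dx=0.001)
        sm = mesh.seg("an")
        assert np.max(np.sqrt(sm.A0 / np.pi)) == pytest.approx(0.025, rel=1e-3)

    def test_dx_hint_overrides_target(self):
        mesh = discretize(single_tube_net(tube(L=1.0, dx_hint=0.5), TerminalBC()),
                          dx=0.01)
        assert len(mesh.seg("tube").x) == 3


class TestPropagation:
    def test_rest_state_is_fixed_point(self):
        bc = InletBC(np.array([0.0, 1.0]), np.array([0.0, 0.0]), "velocity")
        res = run_simulation(single_tube_net(tube(), TerminalBC(), bc, mu=1e-3),
                             duration=0.05, dx=0.01)
        w = res.site("tube@0.5")
        assert np.max(np.abs(w["u"].values)) == 0.0
        assert np.max(np.abs(w["p"].values)) == 0.0

    def test_small_pulse_speed_and_shape(self):
        # inviscid linear limit: d'Alembert translation at c0
        seg = tube(L=2.0)
        c0 = seg.wave_speed0(0.0, RHO)
        net = single_tube_net(seg, TerminalBC(), monitors=(0.1, 0.9))
        res = run_simulation(net, duration=0.12, cfl=0.5, dx=0.0025,
                             output_dt=2e-4)
        w1, w2 = res.site("tube@0.1")["p"], res.site("tube@0.9")["p"]
        delay = (np.argmax(w2.values) - np.argmax(w1.values)) * w1.dt
        assert 1.6 / delay == pytest.approx(c0, rel=0.01)
        shift = int(round(1.6 / c0 / w1.dt))
        pred = np.zeros_like(w2.values)
        pred[shift:] = w1.values[:len(w1.values) - shift]
        err = np.max(np.abs(w2.values - pred)) / np.max(np.abs(w1.values))
        assert err < 0.01
        # amplitude preserved (no numerical decay) to < 1 %
        assert np.max(w2.values) / np.max(w1.values) == pytest.approx(1.0, abs=0.01)

    def test_grid_convergence_second_order(self):
        # halving dx should cut the error vs the translated profile ~4x
        seg = tube(L=2.0)
        c0 = seg.wave_speed0(0.0, RHO)
        errs = []
        for dx in (0.01, 0.005):
            net = single_tube_net(seg, TerminalBC(), monitors=(0.1, 0.9))
            res = run_simulation(net, duration=0.12, cfl=0.5, dx=dx,
                                 output_dt=2e-4)
            w1, w2 = res.site("tube@0.1")["p"], res.site("tube@0.9")["p"]
            shift = int(round(1.6 / c0 / w1.dt))
            pred = np.zeros_like(w2.values)
            pred[shift:] = w1.values[:len(w1.values) - shift]
            errs.append(np.linalg.norm(w2.values - pred))
        assert errs[0] / errs[1] > 2.5

    def test_inlet_forward_impedance_relation(self):
        # reflection-free tube: p ~= rho c0 u at the inlet-side monitor
        seg = tube(L=2.0)
        c0 = seg.wave_speed0(0.0, RHO)
        net = single_tube_net(seg, TerminalBC(), monitors=(0.05,))
        res = run_simulation(net, duration=0.06, cfl=0.5, dx=0.005)
        w = res.site("tube@0.05")
        m = np.abs(w["u"].values) > 0.1 * np.max(np.abs(w["u"].values))
        ratio = w["p"].values[m] / (RHO * c0 * w["u"].values[m])
        assert np.max(np.abs(ratio - 1.0)) < 0.02

    def test_friction_steady_poiseuille_drop(self):
        # stiff tube, steady flow: dp = 8 pi mu L u / A
        seg = tube(E=2.8e9)
        A = np.pi * 8.5e-3**2
        u0, mu = 0.1, 0.05
        t = np.linspace(0, 2.0, 20001)
        vals = np.full_like(t, u0)
        vals[:100] = np.linspace(0, u0, 100)
        Zc = RHO * seg.wave_speed0(0, RHO) / A
        net = single_tube_net(seg, TerminalBC("windkessel", R1=Zc),
                              InletBC(t, vals, "velocity"), mu=mu,
                              monitors=(0.0, 1.0))
        res = run_simulation(net, duration=0.3, dx=0.01)
        dp = res.site("tube@0")["p"].values[-1] - res.site("tube@1")["p"].values[-1]
        assert dp == pytest.approx(8 * np.pi * mu * 1.0 * u0 / A, rel=0.02)

    def test_supercritical_flow_detected(self):
        # a violent inlet pulse must be flagged, not silently integrated
        seg = tube(E=2.8e3)   # extremely soft tube, c0 ~ 0.66 m/s
        t = np.linspace(0, 1.0, 10001)
        bc = InletBC(t, 2.0 * np.sin(np.pi * np.minimum(t / 0.2, 1.0)), "velocity")
        with pytest.raises(SolverError):
            run_simulation(single_tube_net(seg, TerminalBC(), bc),
                           duration=0.5, dx=0.01)

    def test_cfl_range_enforced(self):
        with pytest.raises(SolverError):
            run_simulation(single_tube_net(tube(), TerminalBC()),
                           duration=0.01, cfl=1.2)


class TestJunctions:
    def two_tube_net(self, a2, monitors=(0.5,)):
        s1, s2 = tube("a", 1.0), tube("b", 1.0, a=a2)
        return Network(
            segments=[s1, s2],
            junctions=[[("a", "end"), ("b", "start")]],
            inlet=("a", "start", gaussian_inlet()),
            terminals=[("b", "end", TerminalBC())],
            fluid=FluidProperties(RHO, 0.0),
            monitors=[Monitor("a", s) for s in monitors],
        )

    def test_identical_tubes_no_reflection(self):
        res = run_simulation(self.two_tube_net(8.5e-3), duration=0.12,
                             dx=0.0025, output_dt=2e-4)
        w = res.site("a@0.5")
        c0 = tube().wave_speed0(0, RHO)
        pf, pb = separate(w["p"], w["u"], RHO, c0, baseline_window=0.005)
        assert np.max(np.abs(pb.values)) < 0.005 * np.max(np.abs(pf.values))

    def test_area_step_matches_transmission_line(self):
        a2 = 6.0e-3
        res = run_simulation(self.two_tube_net(a2), duration=0.12,
                             dx=0.0025, output_dt=2e-4)
        w = res.site("a@0.5")
        c1 = tube().wave_speed0(0, RHO)
        c2 = tube(a=a2).wave_speed0(0, RHO)
        Y1 = np.pi * 8.5e-3**2 / (RHO * c1)
        Y2 = np.pi * a2**2 / (RHO * c2)
        pf, pb = separate(w["p"], w["u"], RHO, c1, baseline_window=0.005)
        R = np.max(np.abs(pb.values)) / np.max(np.abs(pf.values))
        assert R == pytest.approx(abs(Y1 - Y2) / (Y1 + Y2), abs=0.02)

    def test_junction_mass_balance(self):
        # flow leaving 'a' equals flow entering 'b' (sampled at the ends)
        s1, s2 = tube("a", 1.0), tube("b", 1.0, a=6e-3)
        net = Network(
            segments=[s1, s2],
            junctions=[[("a", "end"), ("b", "start")]],
            inlet=("a", "start", gaussian_inlet(amp=0.05)),
            terminals=[("b", "end", TerminalBC())],
            fluid=FluidProperties(RHO, 0.0),
            monitors=[Monitor("a", 1.0), Monitor("b", 0.0)],
        )
        res = run_simulation(net, duration=0.12, dx=0.005)
        Qa = res.site("a@1")["Q"].values
        Qb = res.site("b@0")["Q"].values
        # enforced by the junction Newton solve to its residual tolerance
        assert np.max(np.abs(Qa - Qb)) < 1e-6 * np.max(np.abs(Qa))


class TestTerminals:
    def test_matched_resistor_absorbs(self):
        seg = tube(L=1.0)
        Zc = RHO * seg.wave_speed0(0, RHO) / (np.pi * 8.5e-3**2)
        net = single_tube_net(seg, TerminalBC("windkessel", R1=Zc))
        res = run_simulation(net, duration=0.15, dx=0.0025, output_dt=2e-4)
        w = res.site("tube@0.5")
        pf, pb = separate(w["p"], w["u"], RHO, seg.wave_speed0(0, RHO),
                          baseline_window=0.005)
        assert np.max(np.abs(pb.values)) < 0.01 * np.max(np.abs(pf.values))

    def test_rcr_steady_state_pressure(self):
        seg = tube(L=1.0)
        A = np.pi * 8.5e-3**2
        Zc = RHO * seg.wave_speed0(0, RHO) / A
        R1, R2, C = Zc, 5 * Zc, 2e-11
        Q0 = 1e-6
        t = np.linspace(0, 3.0, 30001)
        vals = np.full_like(t, Q0 / A)
        vals[:10] = np.linspace(0, Q0 / A, 10)
        net = single_tube_net(seg, TerminalBC("windkessel", R1=R1, R2=R2, C=C),
                              InletBC(t, vals, "velocity"), monitors=(0.99,))
        res = run_simulation(net, duration=2.0, dx=0.02)
        p_end = res.site("tube@0.99")["p"].values[-1]
        assert p_end == pytest.approx(Q0 * (R1 + R2), rel=0.01)

    def test_large_capacitor_shorts_r2(self):
        # C -> infinity behaves as a pure R1 termination: matched R1 absorbs
        seg = tube(L=1.0)
        Zc = RHO * seg.wave_speed0(0, RHO) / (np.pi * 8.5e-3**2)
        net = single_tube_net(seg, TerminalBC("windkessel", R1=Zc, R2=50 * Zc,
                                              C=1.0))
        res = run_simulation(net, duration=0.15, dx=0.0025, output_dt=2e-4)
        w = res.site("tube@0.5")
        pf, pb = separate(w["p"], w["u"], RHO, seg.wave_speed0(0, RHO),
                          baseline_window=0.005)
        assert np.max(np.abs(pb.values)) < 0.01 * np.max(np.abs(pf.values))

    def test_mass_conservation_single_pulse(self):
        # matched outlet: injected volume reappears downstream to < 0.5 %
        seg = tube(L=1.0)
        A = np.pi * 8.5e-3**2
        Zc = RHO * seg.wave_speed0(0, RHO) / A
        net = single_tube_net(seg, TerminalBC("windkessel", R1=Zc),
                              gaussian_inlet(amp=0.05),
                              monitors=(0.0, 1.0))
        res = run_simulation(net, duration=0.4, dx=0.005)
        t = res.site("tube@0")["Q"].times
        v_in = np.trapezoid(res.site("tube@0")["Q"].values, t)
        v_out = np.trapezoid(res.site("tube@1")["Q"].values, t)
        assert v_out == pytest.approx(v_in, rel=0.005)


class TestPeriodicMode:
    def test_last_cycle_rebased_to_period(self):
        seg = tube(L=0.5, E=225e3)
        A = np.pi * 8.5e-3**2
        Zc = RHO * seg.wave_speed0(0, RHO) / A
        T = 1.0
        t = np.arange(0, T + 5e-4, 1e-3)
        q = np.where(t < 0.3, np.sin(np.pi * t / 0.3) ** 2, 0.0) * 85e-6 / 0.15
        term = TerminalBC("windkessel", R1=Zc, R2=1.4e8, C=1.4e-9)
        net = single_tube_net(seg, term, InletBC(t, q, "flow"))
        res = run_simulation(net, mode="periodic", period=T, n_cycles=2,
                             dx=0.01, init_pressure=14.1e3)
        w = res.site("tube@0.5")["p"]
        assert w.t_start == 0.0
        assert w.duration == pytest.approx(T, abs=2 * w.dt)

    def test_periodic_mode_requires_period(self):
        with pytest.raises(SolverError):
            run_simulation(single_tube_net(tube(), TerminalBC()),
                           mode="periodic")


class TestNetworkValidation:
    def test_unattached_end_rejected(self):
        with pytest.raises(SolverError, match="attached"):
            Network(segments=[tube()],
                    inlet=("tube", "start", gaussian_inlet()),
                    terminals=[], fluid=FluidProperties(), monitors=[])

    def test_doubly_attached_end_rejected(self):
        with pytest.raises(SolverError, match="attached"):
            Network(segments=[tube()],
                    inlet=("tube", "start", gaussian_inlet()),
                    terminals=[("tube", "start", TerminalBC()),
                               ("tube", "end", TerminalBC())],
                    fluid=FluidProperties(), monitors=[])

    def test_unknown_monitor_segment_rejected(self):
        with pytest.raises(SolverError, match="unknown"):
            Network(segments=[tube()],
                    inlet=("tube", "start", gaussian_inlet()),
                    terminals=[("tube", "end", TerminalBC())],
                    fluid=FluidProperties(),
                    monitors=[Monitor("ghost", 0.5)])
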