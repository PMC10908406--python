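"""1-D solver verification: equilibrium, wave propagation, convergence
order, junction conservation, reflections, Windkessel coupling, limit
cycles."""

import math

import numpy as np
import pytest

from hemopulse import (FluidProperties, NetworkSpec, PrescribedInflow,
                       Simulation, Site, SolverConfig, SolverError, Terminal,
                       VesselSegment, make_single_vessel_case, rhs_interior,
                       run_to_periodic)
from hemopulse.network import BETA_GEOM, BedParams, Junction

RHO = 1050.0


#: essentially inviscid blood for reflection tests (the viscous wake of a
#: travelling pulse would otherwise contaminate the echo window)
INVISCID = FluidProperties(mu=1e-9)


def _uniform_segment(sid="v", L=1.0, d=0.01, c0=6.0, n_nodes=None,
                     pext=1e4):
    ad = math.pi * d * d / 4.0
    beta = 2.0 * RHO * math.sqrt(ad) * c0 * c0
    h = beta / (BETA_GEOM * 4e5)
    return VesselSegment(id=sid, name=sid, length=L, d_prox=d, d_dist=d,
                         E=4e5, h_prox=h, h_dist=h, pext=pext,
                         n_nodes=n_nodes)


def _sealed_vessel(**kw):
    seg = _uniform_segment(**kw)
    return NetworkSpec(
        segments=[seg],
        terminals=[Terminal(segment=seg.id, end="proximal", kind="closed"),
                   Terminal(segment=seg.id, end="distal", kind="closed")])


def _forward_pulse(sim, seg, x0=0.5, sigma=0.08, eps=1e-3):
    """Seed a right-running simple wave: U = 4(c - c0) keeps W- uniform."""
    ad = seg.Ad_prox
    c0 = float(seg.c0(0.0, sim.net.fluid))

    def a_fn(x):
        return ad * (1.0 + eps * np.exp(-0.5 * ((x - x0) / sigma) ** 2))

    def u_fn(x):
        a = a_fn(x)
        c = np.sqrt(seg.beta_prox * np.sqrt(a) / (2.0 * RHO * ad))
        return 4.0 * (c - c0)

    sim.set_field(seg.id, A=a_fn, U=u_fn)


def _subgrid_peak(x, y):
    i = int(np.argmax(y))
    if 0 < i < len(y) - 1:
        d = 0.5 * (y[i - 1] - y[i + 1]) / (y[i - 1] - 2 * y[i] + y[i + 1])
        return x[i] + d * (x[1] - x[0])
    return x[i]


class TestInteriorDynamics:
    def test_rest_state_is_a_machine_precision_equilibrium(self):
        net = _sealed_vessel()
        sim = Simulation(net, None, SolverConfig(heart_rate=75.0))
        a0 = sim.A.copy()
        sim.advance_cycle()
        assert np.array_equal(sim.U, np.zeros_like(sim.U))
        np.testing.assert_allclose(sim.A, a0, rtol=1e-14, atol=0.0)

    def test_rhs_equilibrium_and_pure_friction(self):
        seg = _uniform_segment(n_nodes=21)
        fl = FluidProperties()
        n = 21
        a = np.full(n, seg.Ad_prox)
        dadt, dudt = rhs_interior(a, np.zeros(n), seg, fl)
        np.testing.assert_allclose(dadt, 0.0, atol=1e-12)
        np.testing.assert_allclose(dudt, 0.0, atol=1e-10)  # round-off of P
        # uniform velocity on a uniform vessel: only friction remains
        u = np.full(n, 0.3)
        fc = 2.0 * (fl.xi + 2.0) * math.pi * fl.mu / fl.rho
        dadt, dudt = rhs_interior(a, u, seg, fl)
        np.testing.assert_allclose(dudt, -fc * 0.3 / seg.Ad_prox, rtol=1e-12)
        with pytest.raises(SolverError):
            rhs_interior(-a, u, seg, fl)

    def test_small_pulse_travels_at_the_diastolic_wave_speed(self):
        seg = _uniform_segment(L=2.0, n_nodes=201)
        net = NetworkSpec(
            segments=[seg],
            terminals=[Terminal(segment="v", end="proximal", kind="closed"),
                       Terminal(segment="v", end="distal", kind="closed")])
        dt_adv = 0.15
        sim = Simulation(net, None, SolverConfig(heart_rate=60.0 / dt_adv))
        _forward_pulse(sim, seg, x0=0.4)
        x = np.arange(201) * (2.0 / 200)
        p0 = _subgrid_peak(x, sim.A)
        sim.advance_cycle()
        p1 = _subgrid_peak(x, sim.A)
        speed = (p1 - p0) / dt_adv
        assert speed == pytest.approx(6.0, rel=0.01)


class TestConvergenceOrder:
    def test_observed_order_at_least_two(self):
        """Richardson-style grid refinement on a smooth interior pulse."""
        t_final = 0.05
        sols = {}
        for n in (81, 161, 321, 641):
            seg = _uniform_segment(L=1.0, n_nodes=n)
            net = NetworkSpec(
                segments=[seg],
                terminals=[Terminal(segment="v", end="proximal",
                                    kind="closed"),
                           Terminal(segment="v", end="distal",
                                    kind="closed")])
            dx = 1.0 / (n - 1)
            cfg = SolverConfig(heart_rate=60.0 / t_final, dt=dx / 30.0)
            sim = Simulation(net, None, cfg)
            _forward_pulse(sim, seg, x0=0.35, sigma=0.08)
            sim.advance_cycle()
            sols[n] = (np.arange(n) * dx, sim.A.copy())
        x_ref, a_ref = sols[641]
        errs = []
        for n in (81, 161, 321):
            x, a = sols[n]
            errs.append(np.sqrt(np.mean(
                (a - np.interp(x, x_ref, a_ref)) ** 2)))
        orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) >= 2.0


def _bifurcation_net(d_parent=0.012, d_daughter=0.009, c0=6.0, L=1.0):
    segs = [_uniform_segment("p", L=L, d=d_parent, c0=c0),
            _uniform_segment("d1", L=L, d=d_daughter, c0=c0),
            _uniform_segment("d2", L=L, d=d_daughter, c0=c0)]
    fl = INVISCID
    terms = [Terminal(segment="p", end="proximal", kind="inflow")]
    for sid in ("d1", "d2"):
        seg = segs[1]
        ad = seg.Ad_dist
        r1 = RHO * float(seg.c0(L, fl)) / ad
        terms.append(Terminal(
            segment=sid, end="distal", kind="bed",
            bed=BedParams(R1=r1, C=2e-10, R2=30 * r1, P_out=1e4),
            label=sid))
    net = NetworkSpec(
        segments=segs,
        junctions=[Junction(ends=[("p", "distal"), ("d1", "proximal"),
                                  ("d2", "proximal")])],
        terminals=terms, fluid=fl)
    return net


def _pulse_inflow(q_peak=5e-6, width=0.04, period=1.0):
    def fn(t):
        tt = t % period
        return q_peak * math.sin(math.pi * tt / width) if tt < width else 0.0
    return PrescribedInflow(period=period, fn=fn)


class TestJunctions:
    def test_mass_and_total_pressure_conserved_every_sample(self):
        net = _bifurcation_net()
        sites = [Site("pj", "p", 1.0), Site("d1j", "d1", 0.0),
                 Site("d2j", "d2", 0.0)]
        # dt commensurate with the 1 kHz output grid: recorded samples are
        # exact solver states (interpolation would corrupt the U^2 term)
        sim = Simulation(net, _pulse_inflow(q_peak=2e-4),
                         SolverConfig(dt=5e-4), sites=sites)
        records, _ = sim.advance_cycle()
        qp = records["pj"].Q
        q1 = records["d1j"].Q
        q2 = records["d2j"].Q
        residual = np.abs(qp - q1 - q2)
        assert residual.max() < 1e-12 * np.abs(qp).max()
        # continuity of total pressure P + rho U^2 / 2
        pt = {k: records[k].P + 0.5 * RHO * records[k].U ** 2
              for k in ("pj", "d1j", "d2j")}
        umax2 = max(np.max(records[k].U ** 2) for k in pt)
        for k in ("d1j", "d2j"):
            assert np.abs(pt[k] - pt["pj"]).max() <= 1e-8 * 0.5 * RHO * umax2

    def test_identical_series_interface_is_transparent(self):
        """Two identical segments in series: reflected amplitude at the
        interface below 0.1% of the incident pulse."""
        segs = [_uniform_segment("a", L=1.0), _uniform_segment("b", L=1.0)]
        fl = INVISCID
        ad = segs[1].Ad_dist
        r1 = RHO * 6.0 / ad
        net = NetworkSpec(
            segments=segs,
            junctions=[Junction(ends=[("a", "distal"), ("b", "proximal")])],
            terminals=[Terminal(segment="a", end="proximal", kind="inflow"),
                       Terminal(segment="b", end="distal", kind="bed",
                                bed=BedParams(R1=r1, C=2e-10, R2=30 * r1,
                                              P_out=1e4))],
            fluid=fl)
        sim = Simulation(net, _pulse_inflow(), SolverConfig(),
                         sites=[Site("mid", "a", 0.5)])
        records, _ = sim.advance_cycle()
        p = records["mid"].P - 1e4
        t = records["mid"].t
        incident = np.abs(p[(t > 0.05) & (t < 0.16)]).max()
        # junction echo would reach x=0.5 at ~ 0.02 + 1.0/6 + 0.5/6 = 0.27 s;
        # the (matched) bed echo only after ~0.44 s
        reflected = np.abs(p[(t > 0.22) & (t < 0.40)]).max()
        assert reflected < 1e-3 * incident

    def test_bifurcation_reflection_matches_linear_admittance_theory(self):
        """R = (Yp - Yd1 - Yd2)/(Yp + Yd1 + Yd2) for small pulses."""
        for d_d, tol in ((0.007, 0.02), (0.012, 0.02)):
            net = _bifurcation_net(d_parent=0.012, d_daughter=d_d)
            fl = net.fluid
            yp = net.segment("p").Ad_prox / (RHO * 6.0)
            yd = net.segment("d1").Ad_prox / (RHO * 6.0)
            r_lin = (yp - 2 * yd) / (yp + 2 * yd)
            sim = Simulation(net, _pulse_inflow(), SolverConfig(),
                             sites=[Site("mid", "p", 0.5)])
            records, _ = sim.advance_cycle()
            p = records["mid"].P - 1e4
            t = records["mid"].t
            win_inc = (t > 0.05) & (t < 0.16)
            win_ref = (t > 0.24) & (t < 0.40)
            incident = p[win_inc][np.abs(p[win_inc]).argmax()]
            reflected = p[win_ref][np.abs(p[win_ref]).argmax()]
            measured = reflected / incident
            assert measured == pytest.approx(r_lin, abs=tol)

    def test_matched_bed_absorbs_incident_pulse(self):
        """A characteristic-impedance-matched bed reflects < 5% early."""
        seg = _uniform_segment("v", L=1.0)
        ad = seg.Ad_dist
        r1 = RHO * 6.0 / ad
        net = NetworkSpec(
            segments=[seg],
            terminals=[Terminal(segment="v", end="proximal", kind="inflow"),
                       Terminal(segment="v", end="distal", kind="bed",
                                bed=BedParams(R1=r1, C=1e-8, R2=30 * r1,
                                              P_out=1e4))],
            fluid=INVISCID)
        sim = Simulation(net, _pulse_inflow(q_peak=2e-5),
                         SolverConfig(), sites=[Site("mid", "v", 0.5)])
        records, _ = sim.advance_cycle()
        p = records["mid"].P - records["mid"].P[0]
        t = records["mid"].t
        incident = np.abs(p[(t > 0.04) & (t < 0.16)]).max()
        reflected = np.abs(p[(t > 0.22) & (t < 0.36)]).max()
        assert reflected < 0.05 * incident


class TestConservationAndLimitCycle:
    def test_sealed_network_volume_drift_below_1e4_per_cycle(self):
        seg = _uniform_segment(L=1.0, n_nodes=101)
        net = _sealed_vessel(L=1.0, n_nodes=101)
        sim = Simulation(net, None, SolverConfig(heart_rate=75.0))
        _forward_pulse(sim, net.segments[0], x0=0.5, eps=5e-3)
        v0 = sim.total_vessel_volume()
        sim.advance_cycle()
        v1 = sim.total_vessel_volume()
        assert abs(v1 - v0) / v0 < 1e-4

    def test_windkessel_dc_relation_at_the_outlet(self):
        """Converged mean outlet pressure = P_out + (R1+R2) Qmean (1%)."""
        net, inflow, oracle = make_single_vessel_case()
        res = run_to_periodic(net, inflow, SolverConfig())
        out = res.record("outlet")
        p_mean = np.trapezoid(out.P, out.t) / out.t[-1]
        assert p_mean == pytest.approx(oracle["p_outlet_mean"], rel=0.01)

    def test_restart_from_converged_state_is_a_fixed_point(self):
        net, inflow, _ = make_single_vessel_case()
        cfg = SolverConfig()
        res = run_to_periodic(net, inflow, cfg)
        res2 = run_to_periodic(net, inflow, cfg, warm_start=res)
        assert res2.n_cycles <= 2
        assert res2.residuals[-1] < cfg.tol

    def test_limit_cycle_independent_of_initial_condition(self):
        net, inflow, _ = make_single_vessel_case()
        cfg = SolverConfig(tol=3e-4)
        r1 = run_to_periodic(net, inflow, cfg)
        sim = Simulation(net, inflow, cfg)
        sim.A *= 1.04  # start pressurized instead of at the diastolic state
        r2 = sim.run_to_periodic()
        p1, p2 = r1.record("outlet").P, r2.record("outlet").P
        pul = p1 - p1.mean()
        assert np.linalg.norm(p1 - p2) / np.linalg.norm(pul) < 5e-3

    def test_extra_cycles_leave_the_pulsatile_power_unchanged(self):
        from hemopulse.analysis import power_decomposition
        net, inflow, _ = make_single_vessel_case()
        cfg = SolverConfig()
        sim = Simulation(net, inflow, cfg)
        res = sim.run_to_periodic()
        _, _, pp1 = power_decomposition(res.record("outlet"))
        for _ in range(4):  # well beyond the convergence point
            records, _ = sim.advance_cycle()
        _, _, pp2 = power_decomposition(records["outlet"])
        assert pp2 == pytest.approx(pp1, rel=1e-3)


class TestDiagnostics:
    def test_cfl_violation_is_reported(self):
        net, inflow, _ = make_single_vessel_case()
        with pytest.raises(SolverError, match="CFL"):
            sim = Simulation(net, inflow, SolverConfig(dt=0.05))
            sim.advance_cycle()

    def test_driver_network_mismatch_is_rejected(self, tree):
        with pytest.raises(SolverError, match="HeartParams"):
            Simulation(tree, _pulse_inflow(), SolverConfig())


def test_save_cycles_writes_columnar_csv_and_metadata(tmp_path):
    import json
    from hemopulse import save_cycles
    net, inflow, _ = make_single_vessel_case()
    res = run_to_periodic(net, inflow, SolverConfig())
    save_cycles(res, tmp_path / "cycle")
    meta = json.loads((tmp_path / "cycle" / "metadata.json").read_text())
    assert meta["converged"]
    arr = np.loadtxt(tmp_path / "cycle" / "outlet.csv", delimiter=",",
                     skiprows=1)
    rec = res.record("outlet")
    np.testing.assert_allclose(arr[:, 1], rec.P)
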