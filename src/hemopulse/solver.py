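"""Time-domain solution of the 1-D network coupled to 0-D heart and beds.

The governing system per vessel segment is

    dA/dt = -d(AU)/dx
    dU/dt = -U dU/dx - (1/rho) dP/dx - 2(xi+2) pi mu U / (rho A)

closed by the elastic tube law (see :mod:`hemopulse.network`), integrated
with a MacCormack predictor-corrector scheme (2nd order in space and time)
and characteristic boundary closures.  Junctions enforce continuity of total
pressure P + rho U^2/2 and conservation of mass to Newton tolerance each
step.  The compiled inner loop lives in :mod:`hemopulse._kernels`.

A simulation is advanced cycle by cycle until the pressure waveforms at the
monitored sites repeat to within a relative L2 tolerance (the periodic limit
cycle); the last cycle is returned resampled on a uniform grid (default
1 kHz) for analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .heart import HeartParams, activation
from .network import NetworkSpec, tube_law_pressure
from .units import LMIN, ML, MMHG, MMHG_PER_ML, MMHG_S_PER_ML

__all__ = [
    "SolverConfig",
    "SolverError",
    "ConvergenceError",
    "Site",
    "PrescribedInflow",
    "WaveformRecord",
    "PeriodicResult",
    "Simulation",
    "run_to_periodic",
    "rhs_interior",
]


class SolverError(RuntimeError):
    pass


class ConvergenceError(SolverError):
    def __init__(self, msg, residuals=None):
        super().__init__(msg)
        self.residuals = residuals or []


@dataclass
class SolverConfig:
    """Numerical controls for a simulation run.

    heart_rate in beats/min (ignored for prescribed-inflow drivers, whose
    period wins).  dt=None chooses the step from the CFL number and the
    stiffest segment; cycles_max bounds the limit-cycle search; tol is the
    relative L2 periodicity tolerance on monitored pressures;
    sample_rate (Hz) fixes the uniform output grid of the converged cycle.
    """

    heart_rate: float = 75.0
    cfl: float = 0.8
    dx_target: float = 0.01
    dt: float | None = None
    cycles_max: int = 60
    tol: float = 1e-3
    sample_rate: float = 1000.0

    def __post_init__(self):
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tol <= 0:
            raise ValueError("periodicity tolerance must be > 0")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class Site:
    """A monitoring location: fractional position along a segment."""

    label: str
    segment: str
    frac: float = 0.5


@dataclass
class PrescribedInflow:
    """Periodic inflow driver for open verification fixtures.

    Provide either ``fn`` (callable of time, one period) or ``samples`` over
    [0, period).  Flow in m^3/s, into the attached segment end.
    """

    period: float
    fn: object = None
    samples: np.ndarray | None = None

    def table(self, n: int = 4096) -> np.ndarray:
        if self.samples is not None:
            return np.asarray(self.samples, dtype=float)
        t = np.arange(n) * (self.period / n)
        return np.asarray([float(self.fn(tt)) for tt in t])


@dataclass
class WaveformRecord:
    """One converged cycle at a site: uniform t over [0, T], P, Q, U, A (SI)."""

    site: str
    t: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    U: np.ndarray
    A: np.ndarray

    @property
    def T(self) -> float:
        return float(self.t[-1])


@dataclass
class PeriodicResult:
    """Converged-cycle output of :func:`run_to_periodic`."""

    records: dict
    heart: dict
    cardiac_output: float  # L/min (nan for inflow-driven runs)
    lvedv: float  # mL (nan for inflow-driven runs)
    n_cycles: int
    residuals: list
    state: dict
    heart_rate: float
    converged: bool = True

    def record(self, label: str) -> WaveformRecord:
        return self.records[label]


_HREC_NAMES = ["V_la", "V_lv", "V_ra", "V_rv", "P_la", "P_lv",
               "q_mitral", "q_aortic", "P_root", "P_ven"]


class Simulation:
    """Packed, stateful model instance over one network + driver."""

    def __init__(self, net: NetworkSpec, driver=None,
                 config: SolverConfig | None = None,
                 sites: list[Site] | None = None):
        self.net = net
        self.config = config or SolverConfig()
        self.driver = driver
        self._build_geometry()
        self._build_topology()
        self._build_driver()
        self.sites = sites if sites is not None else self._default_sites()
        self._site_nodes = np.array(
            [self.node_index(s.segment, s.frac) for s in self.sites],
            dtype=np.int64)
        self.t = 0.0

    # ------------------------------------------------------------------
    def _build_geometry(self):
        cfg = self.config
        segs = self.net.segments
        self._seg_of = {}
        i0s, ns_, dxs = [], [], []
        Ad, beta, pext, dAd, dbeta = [], [], [], [], []
        pos = 0
        for s in segs:
            n = s.n_nodes or max(3, int(round(s.length / cfg.dx_target)) + 1)
            x = np.linspace(0.0, s.length, n)
            i0s.append(pos)
            ns_.append(n)
            dxs.append(s.length / (n - 1))
            Ad.append(s.Ad(x))
            beta.append(s.beta(x))
            pext.append(np.full(n, s.pext))
            dAd.append(np.full(n, (s.Ad_dist - s.Ad_prox) / s.length))
            dbeta.append(np.full(n, (s.beta_dist - s.beta_prox) / s.length))
            self._seg_of[s.id] = (pos, n, s.length / (n - 1))
            pos += n
        self.nn = pos
        self.seg_i0 = np.array(i0s, dtype=np.int64)
        self.seg_n = np.array(ns_, dtype=np.int64)
        self.seg_dx = np.array(dxs)
        self.Ad = np.concatenate(Ad)
        self.beta = np.concatenate(beta)
        self.pext = np.concatenate(pext)
        self.dAd = np.concatenate(dAd)
        self.dbeta = np.concatenate(dbeta)
        self.A = self.Ad.copy()
        self.U = np.zeros(self.nn)
        fl = self.net.fluid
        self.rho = fl.rho
        self.fc = 2.0 * (fl.xi + 2.0) * math.pi * fl.mu / fl.rho

    def node_index(self, seg_id: str, frac: float) -> int:
        i0, n, _ = self._seg_of[seg_id]
        return i0 + int(round(frac * (n - 1)))

    def _end_node(self, seg_id: str, end: str):
        i0, n, dx = self._seg_of[seg_id]
        if end == "proximal":
            return i0, -1.0, dx
        return i0 + n - 1, +1.0, dx

    def _build_topology(self):
        net = self.net
        nj = len(net.junctions)
        self.jn_n = np.zeros(nj, dtype=np.int64)
        self.jn_node = np.zeros((nj, 6), dtype=np.int64)
        self.jn_sign = np.zeros((nj, 6))
        self.jn_dx = np.zeros((nj, 6))
        for k, j in enumerate(net.junctions):
            if len(j.ends) > 6:
                raise SolverError(f"junction {k}: more than 6 attached ends")
            self.jn_n[k] = len(j.ends)
            for jj, (sid, end) in enumerate(j.ends):
                node, sgn, dx = self._end_node(sid, end)
                self.jn_node[k, jj] = node
                self.jn_sign[k, jj] = sgn
                self.jn_dx[k, jj] = dx

        terms = net.terminals
        nt = len(terms)
        self.tm_node = np.zeros(nt, dtype=np.int64)
        self.tm_sign = np.zeros(nt)
        self.tm_type = np.zeros(nt, dtype=np.int64)
        self.tm_dx = np.zeros(nt)
        self.bd_r1 = np.zeros(nt)
        self.bd_c = np.ones(nt)
        self.bd_r2 = np.ones(nt)
        self.bd_pout = np.zeros(nt)
        self.bd_pc = np.zeros(nt)
        self.heart_node = -1
        self.heart_dx = 0.0
        self._inflow_terminal = None
        kinds = {"bed": K.TM_BED, "closed": K.TM_CLOSED,
                 "inflow": K.TM_INFLOW, "heart": K.TM_HEART}
        for k, tmn in enumerate(terms):
            node, sgn, dx = self._end_node(tmn.segment, tmn.end)
            self.tm_node[k] = node
            self.tm_sign[k] = sgn
            self.tm_dx[k] = dx
            self.tm_type[k] = kinds[tmn.kind]
            if tmn.kind == "bed":
                self.bd_r1[k] = tmn.bed.R1
                self.bd_c[k] = tmn.bed.C
                self.bd_r2[k] = tmn.bed.R2
                self.bd_pout[k] = tmn.bed.P_out
                self.bd_pc[k] = self.pext[node]
            elif tmn.kind == "heart":
                if tmn.end != "proximal":
                    raise SolverError(
                        "heart port must attach to a proximal segment end")
                self.heart_node = node
                self.heart_dx = dx
            elif tmn.kind == "inflow":
                self._inflow_terminal = k

    def _build_driver(self):
        drv = self.driver
        self.hp = np.zeros((4, 5))
        self.act_tab = np.zeros((4, 8))
        self.vl = np.zeros((4, 5))
        self.hstate = np.zeros(K.NHSTATE)
        self.hconst = np.zeros(K.NHCONST)
        self.inflow_tab = np.zeros(2)
        self.inflow_T = 1.0
        self.heart_on = 0

        if self.heart_node >= 0:
            if not isinstance(drv, HeartParams):
                raise SolverError(
                    "network has a heart port; driver must be HeartParams")
            self.heart_on = 1
            self.T = self.config.period
            order = ["la", "lv", "ra", "rv"]
            for c, role in enumerate(order):
                ch = drv.chambers[role]
                self.hp[c] = [ch.Ees * MMHG_PER_ML, ch.Emin * MMHG_PER_ML,
                              ch.V_P0 * ML, ch.Rs * MMHG_S_PER_ML,
                              ch.Esep * MMHG_PER_ML]
            nact = 2048
            self.act_tab = np.zeros((4, nact))
            ph = np.arange(nact) / nact
            for c, role in enumerate(order):
                self.act_tab[c] = activation(ph * self.T, self.T,
                                             drv.chambers[role])
            vorder = ["mitral", "aortic", "tricuspid", "pulmonary"]
            for c, vname in enumerate(vorder):
                v = drv.valves[vname]
                self.vl[c] = [v.A_ann, v.l_eff, v.K_open, v.K_close,
                              1.0 if v.ideal else 0.0]
            f = drv.filling
            pc = drv.pericardium
            self.hconst[:] = [
                f.P_pv * MMHG, f.R_pv * MMHG_S_PER_ML,
                f.C_ven * ML / MMHG, f.R_ven * MMHG_S_PER_ML,
                f.C_pulm * ML / MMHG, f.R_pulm * MMHG_S_PER_ML,
                pc.K * MMHG, pc.V0 * ML, pc.phi * ML,
                1.0 if f.mode == "closed" else 0.0,
            ]
            self.hstate[K.HS_V + 0] = 60.0 * ML
            self.hstate[K.HS_V + 1] = 130.0 * ML
            self.hstate[K.HS_V + 2] = drv.v_ra_rest * ML
            self.hstate[K.HS_V + 3] = drv.v_rv_rest * ML
            self.hstate[K.HS_PROOT] = self.pext[self.heart_node]
            self.hstate[K.HS_PVEN] = 6.0 * MMHG
            self.hstate[K.HS_PPULM] = 13.0 * MMHG
        elif self._inflow_terminal is not None:
            if not isinstance(drv, PrescribedInflow):
                raise SolverError(
                    "network has an inflow port; driver must be "
                    "PrescribedInflow")
            self.inflow_tab = drv.table()
            self.inflow_T = drv.period
            self.T = drv.period
        else:
            if drv is not None:
                raise SolverError(
                    "network has no heart or inflow port; driver must be None")
            self.T = self.config.period

    def _default_sites(self) -> list[Site]:
        sites = []
        for t in self.net.terminals:
            if t.kind == "heart":
                sites.append(Site("inlet", t.segment, 0.0))
            elif t.kind == "inflow":
                frac = 0.0 if t.end == "proximal" else 1.0
                sites.append(Site("inlet", t.segment, frac))
            elif t.kind == "bed":
                frac = 1.0 if t.end == "distal" else 0.0
                sites.append(Site(t.label or f"{t.segment}:{t.end}",
                                  t.segment, frac))
        return sites

    # ------------------------------------------------------------------
    def _pick_dt(self) -> float:
        if self.config.dt is not None:
            return self.config.dt
        c0 = np.sqrt(self.beta / (2.0 * self.rho * np.sqrt(self.Ad)))
        vmax = 0.0
        for s in range(len(self.seg_i0)):
            i0, n = self.seg_i0[s], self.seg_n[s]
            vseg = 1.25 * float(np.max(c0[i0:i0 + n])) + 3.0
            vmax = max(vmax, vseg / self.seg_dx[s])
        return self.config.cfl / vmax

    def segment_of_node(self, node: int) -> str:
        for s, seg in enumerate(self.net.segments):
            if self.seg_i0[s] <= node < self.seg_i0[s] + self.seg_n[s]:
                return seg.id
        return "?"

    def field(self, seg_id: str):
        """Current (x, A, U, P) along one segment."""
        i0, n, dx = self._seg_of[seg_id]
        x = np.arange(n) * dx
        seg = self.net.segment(seg_id)
        sl = slice(i0, i0 + n)
        return {"x": x, "A": self.A[sl].copy(), "U": self.U[sl].copy(),
                "P": tube_law_pressure(self.A[sl], x, seg)}

    def set_field(self, seg_id: str, A=None, U=None):
        i0, n, dx = self._seg_of[seg_id]
        x = np.arange(n) * dx
        if A is not None:
            self.A[i0:i0 + n] = A(x) if callable(A) else np.asarray(A)
        if U is not None:
            self.U[i0:i0 + n] = U(x) if callable(U) else np.asarray(U)

    def total_vessel_volume(self) -> float:
        """Integral of A over all segments (m^3), trapezoidal."""
        v = 0.0
        for s in range(len(self.seg_i0)):
            i0, n = self.seg_i0[s], self.seg_n[s]
            v += float(np.trapezoid(self.A[i0:i0 + n], dx=self.seg_dx[s]))
        return v

    def get_state(self) -> dict:
        return {"A": self.A.copy(), "U": self.U.copy(),
                "bd_pc": self.bd_pc.copy(), "hstate": self.hstate.copy()}

    def set_state(self, st: dict):
        if st["A"].shape != self.A.shape:
            raise SolverError("warm-start state has a different discretization")
        self.A[:] = st["A"]
        self.U[:] = st["U"]
        self.bd_pc[:] = st["bd_pc"]
        self.hstate[:] = st["hstate"]

    # ------------------------------------------------------------------
    def advance_cycle(self, dt: float | None = None):
        """Advance one period T; returns (records, heart traces) resampled.

        Raises SolverError on divergence, CFL violation, or junction-solver
        failure, naming the offending segment and time.
        """
        T = self.T
        dt0 = dt if dt is not None else self._pick_dt()
        n_steps = max(2, int(math.ceil(T / dt0)))
        dt0 = T / n_steps
        nsite = len(self._site_nodes)
        nrec = n_steps + 1
        rec_P = np.empty((nsite, nrec))
        rec_Q = np.empty((nsite, nrec))
        rec_U = np.empty((nsite, nrec))
        rec_A = np.empty((nsite, nrec))
        hrec = np.zeros((10, nrec))
        # sample 0 = state at cycle start
        for k, node in enumerate(self._site_nodes):
            rec_A[k, 0] = self.A[node]
            rec_U[k, 0] = self.U[node]
            rec_Q[k, 0] = self.A[node] * self.U[node]
            rec_P[k, 0] = (self.pext[node] + self.beta[node] / self.Ad[node]
                           * (np.sqrt(self.A[node]) - np.sqrt(self.Ad[node])))
        hrec[:4, 0] = self.hstate[K.HS_V:K.HS_V + 4]
        hrec[4, 0] = self.hstate[K.HS_PCH]
        hrec[5, 0] = self.hstate[K.HS_PCH + 1]
        hrec[6, 0] = self.hstate[K.HS_QV]
        hrec[7, 0] = self.hstate[K.HS_QV + 1]
        hrec[8, 0] = self.hstate[K.HS_PROOT]
        hrec[9, 0] = self.hstate[K.HS_PVEN]

        stat = np.zeros(6)
        ckpt = self.get_state()
        for attempt in range(4):
            K.run_steps(
                n_steps, self.t, dt0, T,
                self.A, self.U, self.Ad, self.beta, self.dAd, self.dbeta,
                self.pext,
                self.seg_i0, self.seg_n, self.seg_dx,
                self.rho, self.fc,
                self.jn_n, self.jn_node, self.jn_sign, self.jn_dx,
                self.tm_node, self.tm_sign, self.tm_type, self.tm_dx,
                self.bd_r1, self.bd_c, self.bd_r2, self.bd_pout, self.bd_pc,
                self.inflow_tab, self.inflow_T,
                self.heart_on, self.heart_node, self.heart_dx,
                self.hp, self.act_tab, self.vl, self.hstate, self.hconst,
                self._site_nodes, rec_P, rec_Q, rec_U, rec_A, hrec,
                1, stat)
            status = int(stat[0])
            if status == 0:
                break
            if status == 2 and attempt < 3:
                # CFL violated mid-cycle: restore and retry with smaller dt
                self.set_state(ckpt)
                dt0 /= 1.5
                n_steps = int(math.ceil(T / dt0))
                dt0 = T / n_steps
                nrec = n_steps + 1
                rec_P = np.empty((nsite, nrec))
                rec_Q = np.empty((nsite, nrec))
                rec_U = np.empty((nsite, nrec))
                rec_A = np.empty((nsite, nrec))
                hrec = np.zeros((10, nrec))
                stat[:] = 0.0
                continue
            node = int(stat[1])
            when = self.t + stat[2] * dt0
            if status == 1:
                raise SolverError(
                    f"solution diverged in segment "
                    f"{self.segment_of_node(node)!r} at t={when:.4f} s")
            if status == 3:
                raise SolverError(
                    f"junction solver failed to converge (junction index "
                    f"{node}) at t={when:.4f} s")
            raise SolverError(f"CFL violation persists (Courant {stat[3]:.2f})")

        self.t += T
        # resample to the uniform output grid
        fs = self.config.sample_rate
        n_out = int(round(T * fs)) + 1
        t_out = np.linspace(0.0, T, n_out)
        t_step = np.linspace(0.0, T, nrec)
        records = {}
        for k, site in enumerate(self.sites):
            records[site.label] = WaveformRecord(
                site=site.label, t=t_out,
                P=np.interp(t_out, t_step, rec_P[k]),
                Q=np.interp(t_out, t_step, rec_Q[k]),
                U=np.interp(t_out, t_step, rec_U[k]),
                A=np.interp(t_out, t_step, rec_A[k]))
        heart = {"t": t_out}
        for i, name in enumerate(_HREC_NAMES):
            heart[name] = np.interp(t_out, t_step, hrec[i])
        return records, heart

    def run_to_periodic(self) -> PeriodicResult:
        cfg = self.config
        residuals = []
        prev = None
        records = heart = None
        for cyc in range(cfg.cycles_max):
            records, heart = self.advance_cycle()
            cur = np.concatenate([r.P for r in records.values()])
            if prev is not None:
                pul = cur - np.mean(cur)
                denom = max(float(np.linalg.norm(pul)), 1e-12)
                res = float(np.linalg.norm(cur - prev)) / denom
                residuals.append(res)
                if res < cfg.tol:
                    return self._result(records, heart, cyc + 1, residuals,
                                        True)
            prev = cur
        raise ConvergenceError(
            f"no periodic limit cycle within {cfg.cycles_max} cycles "
            f"(last residual {residuals[-1] if residuals else math.nan:.3e})",
            residuals)

    def _result(self, records, heart, ncyc, residuals, converged):
        if self.heart_on:
            co = float(np.mean(heart["q_aortic"])) / LMIN
            lvedv = float(np.max(heart["V_lv"])) / ML
        else:
            co = math.nan
            lvedv = math.nan
        return PeriodicResult(records=records, heart=heart,
                              cardiac_output=co, lvedv=lvedv,
                              n_cycles=ncyc, residuals=residuals,
                              state=self.get_state(),
                              heart_rate=60.0 / self.T, converged=converged)


def run_to_periodic(net: NetworkSpec, driver=None,
                    config: SolverConfig | None = None,
                    sites: list[Site] | None = None,
                    warm_start=None) -> PeriodicResult:
    """Simulate ``net`` under ``driver`` until the limit cycle converges.

    ``warm_start`` may be a previous :class:`PeriodicResult` (or state dict)
    from a compatible discretization; mismatched states are ignored.
    """
    sim = Simulation(net, driver, config, sites)
    if warm_start is not None:
        st = warm_start.state if isinstance(warm_start, PeriodicResult) \
            else warm_start
        try:
            sim.set_state(st)
        except SolverError:
            pass
    return sim.run_to_periodic()


def rhs_interior(A, U, seg, fluid):
    """Right-hand side of the 1-D system on a segment's node grid.

    Diagnostic/reference evaluation with centered differences (one-sided at
    the ends); the time-stepping kernel uses its own predictor-corrector
    differencing.  Returns (dA/dt, dU/dt).
    """
    A = np.asarray(A, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(A <= 0):
        raise SolverError(f"segment {seg.id!r}: non-positive area in state")
    n = A.shape[0]
    x = np.linspace(0.0, seg.length, n)
    P = tube_law_pressure(A, x, seg)
    fc = 2.0 * (fluid.xi + 2.0) * math.pi * fluid.mu / fluid.rho
    dAdt = -np.gradient(A * U, x)
    dUdt = (-U * np.gradient(U, x) - np.gradient(P, x) / fluid.rho
            - fc * U / A)
    return dAdt, dUdt


def save_cycles(result: PeriodicResult, directory) -> None:
    """Write a converged cycle as columnar CSV, one file per site, plus a
    metadata JSON (heart rate, CO, LVEDV, convergence residuals)."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for label, rec in result.records.items():
        arr = np.column_stack([rec.t, rec.P, rec.Q, rec.U, rec.A])
        np.savetxt(d / f"{label}.csv", arr, delimiter=",",
                   header="t_s,P_pa,Q_m3s,U_ms,A_m2", comments="")
    meta = {"heart_rate": result.heart_rate,
            "cardiac_output_lmin": result.cardiac_output,
            "lvedv_ml": result.lvedv,
            "n_cycles": result.n_cycles,
            "residuals": list(map(float, result.residuals)),
            "converged": result.converged}
    (d / "metadata.json").write_text(json.dumps(meta, indent=1))
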