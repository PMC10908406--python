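"""0-D four-chamber time-varying elastance heart with valves and pericardium.

Each chamber obeys

    P = Ppc + (Enat/Esep) * P_star + Enat(t) * (V - V_P0) - Rs * q,
    Enat(t) = Emin + e(t) * (Ees - Emin),

where ``e(t)`` is a normalized double-Hill activation waveform (max 1,
periodic with the cardiac period T), ``P_star`` the pressure of the
contralateral chamber (septal coupling through the finite septal elastance
Esep), ``Rs`` a source resistance penalizing outflow ``q``, and ``Ppc`` the
pericardial pressure, an exponential function of the total four-chamber
volume.

Valves follow a pressure-gradient-driven opening-state ODE with a
Bernoulli-resistance/inertance flow law (the family standard for lumped
heart models); an ideal-diode mode exists for debugging.

Public numeric conventions match clinical usage: elastances in mmHg/mL,
volumes in mL, flows in mL/s, pressures in mmHg.  The solver kernel converts
to SI internally.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .units import MMHG, ML

__all__ = [
    "ChamberParams",
    "PericardiumParams",
    "ValveParams",
    "FillingParams",
    "HeartParams",
    "activation",
    "activation_normalization",
    "chamber_pressure",
    "valve_flow",
    "set_contractility",
    "fix_cardiac_output",
    "simulate_lv_afterload",
]

#: reference cardiac period for activation-timing scaling (75 beats/min)
T_REF = 0.8

#: opening fraction below which a valve is treated as closed
ZETA_MIN = 1e-4


@dataclass
class ChamberParams:
    """Elastance-chamber parameters, clinical units (mmHg, mL, s).

    Activation timing (tau1, tau2, seconds at the reference period T_REF;
    Hill exponents m1, m2; onset as a fraction of T) is stored per chamber so
    atria can lead the ventricles.  When the heart rate changes, tau1/tau2
    are scaled by (T / T_REF)**timing_exponent: 1 keeps systole a fixed
    fraction of the cycle (the lumped-heart-model convention adopted here);
    0.5 gives the square-root law of ECG interval formulas.
    """

    role: str  # "la" | "lv" | "ra" | "rv"
    Ees: float  # mmHg/mL
    Emin: float  # mmHg/mL
    V_P0: float  # mL
    Rs: float = 0.0  # mmHg s/mL
    Esep: float = 50.0  # mmHg/mL
    tau1: float = 0.2152
    tau2: float = 0.3616
    m1: float = 1.32
    m2: float = 27.4
    onset: float = 0.0  # fraction of T
    timing_exponent: float = 1.0  # tau1/tau2 scale as (T/T_REF)**this

    def __post_init__(self):
        if not (self.Ees >= self.Emin > 0):
            raise ValueError(
                f"chamber {self.role}: require Ees >= Emin > 0 "
                f"(Ees={self.Ees}, Emin={self.Emin})")
        if self.V_P0 < 0 or self.Rs < 0 or self.Esep <= 0:
            raise ValueError(f"chamber {self.role}: invalid V_P0/Rs/Esep")


@dataclass
class PericardiumParams:
    """Ppc = K * exp((Vtot - V0) / phi), mmHg; monotone in total volume."""

    K: float = 0.5  # mmHg
    V0: float = 300.0  # mL
    phi: float = 60.0  # mL

    def pressure(self, v_total_ml: float) -> float:
        return self.K * math.exp((v_total_ml - self.V0) / self.phi)


@dataclass
class ValveParams:
    """Valve with opening-state dynamics and Bernoulli resistance.

    A_ann: annulus area (m^2); l_eff: effective inertial length (m);
    K_open/K_close: opening/closing rate constants (1/(Pa s)).
    Effective open area is zeta * A_ann with zeta in [0, 1].
    """

    A_ann: float
    l_eff: float = 0.02
    K_open: float = 0.12
    K_close: float = 0.6
    ideal: bool = False


@dataclass
class FillingParams:
    """How the left atrium is fed and where bed outflow goes.

    mode='open': LA filled from a constant pulmonary venous pressure P_pv
    through resistance R_pv; vascular beds drain to their fixed P_out
    (preload clamp — the default, and the knob used to adjust LVEDV).
    mode='closed': beds drain into a lumped venous compartment feeding the
    right heart, with a lumped pulmonary circulation back to the LA.
    """

    mode: str = "open"  # "open" | "closed"
    P_pv: float = 11.5  # mmHg (open-loop LA filling pressure)
    R_pv: float = 0.015  # mmHg s/mL
    # closed-loop lumped elements
    C_ven: float = 100.0  # mL/mmHg
    R_ven: float = 0.03  # mmHg s/mL (venous compartment -> RA)
    C_pulm: float = 8.0  # mL/mmHg
    R_pulm: float = 0.08  # mmHg s/mL (pulmonary compartment -> LA)


def _default_chambers() -> dict:
    return {
        "la": ChamberParams("la", Ees=0.35, Emin=0.18, V_P0=3.0, Rs=0.003,
                            Esep=30.0, tau1=0.088, tau2=0.144, m1=1.32,
                            m2=13.1, onset=0.85),
        "lv": ChamberParams("lv", Ees=2.5, Emin=0.08, V_P0=20.0, Rs=0.008,
                            Esep=50.0),
        "ra": ChamberParams("ra", Ees=0.30, Emin=0.15, V_P0=3.0, Rs=0.003,
                            Esep=30.0, tau1=0.088, tau2=0.144, m1=1.32,
                            m2=13.1, onset=0.85),
        "rv": ChamberParams("rv", Ees=0.55, Emin=0.04, V_P0=10.0, Rs=0.005,
                            Esep=20.0),
    }


def _default_valves() -> dict:
    return {
        "mitral": ValveParams(A_ann=5.0e-4),
        "aortic": ValveParams(A_ann=4.0e-4),
        "tricuspid": ValveParams(A_ann=6.0e-4),
        "pulmonary": ValveParams(A_ann=4.0e-4),
    }


@dataclass
class HeartParams:
    """Full four-chamber heart: chambers, valves, pericardium, filling."""

    chambers: dict = field(default_factory=_default_chambers)
    valves: dict = field(default_factory=_default_valves)
    pericardium: PericardiumParams = field(default_factory=PericardiumParams)
    filling: FillingParams = field(default_factory=FillingParams)
    # open-loop resting volumes of the idle right heart (mL)
    v_ra_rest: float = 50.0
    v_rv_rest: float = 110.0

    def copy(self) -> "HeartParams":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# activation waveform
# ---------------------------------------------------------------------------

def _double_hill_raw(tau, tau1, tau2, m1, m2):
    tau = np.maximum(np.asarray(tau, dtype=float), 0.0)
    g1 = (tau / tau1) ** m1
    g2 = (tau / tau2) ** m2
    return (g1 / (1.0 + g1)) / (1.0 + g2)


def activation_normalization(ch: ChamberParams, T: float) -> float:
    """Max of the unnormalized double-Hill over one period (for e_max = 1)."""
    s = (T / T_REF) ** ch.timing_exponent
    tau = np.linspace(0.0, T, 4001)
    return float(np.max(_double_hill_raw(tau, ch.tau1 * s, ch.tau2 * s,
                                         ch.m1, ch.m2)))


def activation(t, T: float, ch: ChamberParams):
    """Normalized activation e(t) in [0, 1], periodic with period T."""
    s = (T / T_REF) ** ch.timing_exponent
    tau = np.mod(np.asarray(t, dtype=float) - ch.onset * T, T)
    e = _double_hill_raw(tau, ch.tau1 * s, ch.tau2 * s, ch.m1, ch.m2)
    out = e / activation_normalization(ch, T)
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# chamber pressure and valve flow (clinical-unit reference implementations;
# the solver kernel mirrors these in SI)
# ---------------------------------------------------------------------------

def chamber_pressure(V, t, ch: ChamberParams, T: float = T_REF,
                     q: float = 0.0, p_star: float = 0.0,
                     p_pericardial: float = 0.0, e: float | None = None):
    """Chamber pressure (mmHg) at volume V (mL) and time t.

    ``q`` is the chamber outflow (mL/s), ``p_star`` the contralateral chamber
    pressure (mmHg).  Pass ``e`` to override the activation value (e.g. e=1
    for end-systolic analysis).
    """
    if np.any(np.asarray(V) <= 0):
        raise ValueError("chamber volume must be > 0")
    if e is None:
        e = activation(t, T, ch)
    enat = ch.Emin + e * (ch.Ees - ch.Emin)
    return (p_pericardial + (enat / ch.Esep) * p_star
            + enat * (np.asarray(V, dtype=float) - ch.V_P0) - ch.Rs * q)


def valve_flow(p_up, p_down, q, zeta, vp: ValveParams, rho: float, dt: float):
    """Advance valve state one step; returns (q_new, zeta_new).

    Pressures in Pa, q in m^3/s.  A forward gradient opens the valve
    (first-order opening dynamics on zeta); an adverse gradient closes it;
    flow follows dq/dt = (dP - B q|q|)/L with B = rho/(2 Aeff^2) and
    L = rho l_eff / Aeff, integrated semi-implicitly.
    """
    dp = p_up - p_down
    if vp.ideal:
        zeta_new = 1.0 if dp > 0 else 0.0
        if dp <= 0:
            return 0.0, zeta_new
        B = rho / (2.0 * vp.A_ann**2)
        return math.sqrt(dp / B), zeta_new
    if dp > 0:
        zeta_new = zeta + dt * vp.K_open * dp * (1.0 - zeta)
    else:
        zeta_new = zeta + dt * vp.K_close * dp * zeta
    zeta_new = min(max(zeta_new, 0.0), 1.0)
    if zeta_new <= ZETA_MIN:
        return 0.0, zeta_new
    aeff = zeta_new * vp.A_ann
    B = rho / (2.0 * aeff * aeff)
    L = rho * vp.l_eff / aeff
    q_new = (q + dt * dp / L) / (1.0 + dt * B * abs(q) / L)
    return q_new, zeta_new


def set_contractility(heart: HeartParams, ees_lv: float) -> HeartParams:
    """Return a copy of ``heart`` with the LV end-systolic elastance replaced.

    Warns outside the physiological sweep range [0.6, 5.0] mmHg/mL
    (control 2.5 mmHg/mL); errors for nonpositive values.
    """
    if ees_lv <= 0:
        raise ValueError(f"Ees must be > 0, got {ees_lv}")
    if not 0.6 <= ees_lv <= 5.0:
        warnings.warn(f"LV Ees={ees_lv} mmHg/mL outside the usual sweep "
                      "range [0.6, 5.0]", stacklevel=2)
    out = heart.copy()
    out.chambers["lv"] = replace(out.chambers["lv"], Ees=ees_lv)
    return out


# ---------------------------------------------------------------------------
# cardiac-output fixing (Frank-Starling preload adjustment)
# ---------------------------------------------------------------------------

def fix_cardiac_output(network, heart: HeartParams, config, target_co: float,
                       tol: float = 0.01, max_iter: int = 12,
                       target_lvedv: float | None = None,
                       sites=None, warm_start=None):
    """Adjust preload so the converged-cycle CO (or LVEDV) hits a target.

    Secant iteration on the open-loop LA filling pressure ``P_pv`` (the
    preload clamp): increasing P_pv raises LVEDV and, via the Frank-Starling
    mechanism, stroke volume and CO.  ``target_co`` in L/min (ignored when
    ``target_lvedv`` in mL is given).  Returns
    ``(heart_tuned, result, lvedv_ml)`` where ``result`` is the final
    converged-cycle solution.

    Raises ``RuntimeError`` if the target cannot be bracketed/reached.
    """
    from .solver import run_to_periodic  # deferred; solver imports heart

    heart = heart.copy()

    def _measure(ppv, warm=None):
        heart.filling.P_pv = ppv
        res = run_to_periodic(network, heart, config, sites=sites,
                              warm_start=warm)
        return res

    def _goal(res):
        return res.lvedv if target_lvedv is not None else res.cardiac_output

    target = target_lvedv if target_lvedv is not None else target_co

    p0 = heart.filling.P_pv
    res0 = _measure(p0, warm=warm_start)
    g0 = _goal(res0)
    if abs(g0 - target) <= tol * abs(target):
        return heart, res0, res0.lvedv
    # initial secant perturbation: preload up if below target
    p1 = p0 * (1.15 if g0 < target else 0.87)
    res1 = _measure(p1, warm=res0)
    g1 = _goal(res1)
    history = [(p0, g0), (p1, g1)]
    for _ in range(max_iter):
        if abs(g1 - target) <= tol * abs(target):
            return heart, res1, res1.lvedv
        if g1 == g0:
            raise RuntimeError(
                f"preload iteration stalled (flat response); history={history}")
        p2 = p1 + (target - g1) * (p1 - p0) / (g1 - g0)
        p2 = min(max(p2, 0.3 * p1), 3.0 * p1)  # damped step
        p0, g0 = p1, g1
        res1 = _measure(p2, warm=res1)
        p1, g1 = p2, _goal(res1)
        history.append((p1, g1))
    raise RuntimeError(
        f"cardiac-output fixing did not converge to {target} "
        f"within {max_iter} iterations; history={history}")


# ---------------------------------------------------------------------------
# isolated-LV afterload harness (0-D; used for ESPVR recovery)
# ---------------------------------------------------------------------------

def simulate_lv_afterload(ch: ChamberParams, valve: ValveParams,
                          R1: float, C: float, R2: float,
                          p_out: float = 5.0, v_init: float = 130.0,
                          p_fill: float = 10.0, r_fill: float = 0.02,
                          T: float = T_REF, n_cycles: int = 8,
                          dt: float = 2.5e-4, rho: float = 1050.0):
    """Isolated LV ejecting through a valve into a 3-element Windkessel.

    Clinical units for pressures/volumes (mmHg, mL); R1/C/R2 in
    mmHg s/mL and mL/mmHg.  Filling from a constant source pressure through
    a diode resistance.  Returns dict of last-cycle time series (t, V, P_lv,
    e) for pressure-volume-loop analysis, e.g. end-systolic point extraction
    across afterloads to recover the ESPVR slope Ees.
    """
    n = int(round(T / dt))
    v = v_init
    pc = p_out + 60.0  # windkessel compartment pressure, mmHg
    q_av = 0.0  # mL/s
    zeta = 0.0
    norm = activation_normalization(ch, T)
    s = (T / T_REF) ** ch.timing_exponent
    out = {"t": np.empty(n), "V": np.empty(n), "P": np.empty(n),
           "e": np.empty(n)}
    for cyc in range(n_cycles):
        last = cyc == n_cycles - 1
        for i in range(n):
            t = i * dt
            tau = (t - ch.onset * T) % T
            e = float(_double_hill_raw(tau, ch.tau1 * s, ch.tau2 * s,
                                       ch.m1, ch.m2)) / norm
            enat = ch.Emin + e * (ch.Ees - ch.Emin)
            p_lv = enat * (v - ch.V_P0) - ch.Rs * q_av
            p_if = pc + R1 * q_av
            q_av, zeta = valve_flow(p_lv * MMHG, p_if * MMHG,
                                    q_av * ML, zeta, valve, rho, dt)
            q_av /= ML
            q_fill = max(p_fill - p_lv, 0.0) / r_fill
            v += dt * (q_fill - q_av)
            pc += dt * (q_av - (pc - p_out) / R2) / C
            if last:
                out["t"][i] = t
                out["V"][i] = v
                out["P"][i] = p_lv
                out["e"][i] = e
    return out
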