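"""Synthetic fixtures: a reduced arterial tree and analytic test signals.

The reduced tree is an engineering stand-in for a full anatomical
parameterization: an ascending aorta / arch / descending aorta trunk (all
flagged aortic, calibrated to a prescribed baseline PWV), the three arch
branches, two common carotids and two vertebrals terminating in cerebral
Windkessel beds, two brachial continuations (arm beds), and a lower-body bed
at the abdominal aorta, all fed by the elastance left heart at the aortic
root.  Geometry follows typical adult dimensions; bed resistances are set
from target regional flow fractions at a target mean pressure (conduit
friction compensated), with R1 a fixed fraction of each bed's total
resistance — the peripheral/cerebral impedance mismatch that reflects
incident waves — and a common short RC decay time (most compliance lives in
the 1-D aorta).  Quantitative full-circulation table values require a complete
anatomical dataset in the same network format; the fixture's purpose is the
qualitative heart-aorta-brain behaviour (optimal heart rate, stiffness and
contractility trends) at physiological operating points.

Also provided: single-vessel + Windkessel verification cases with analytic
oracles, and waterhammer waveforms of known forward/backward composition for
the wave-analysis layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .heart import HeartParams
from .network import (BETA_GEOM, BedParams, FluidProperties, Junction,
                      NetworkSpec, Terminal, VesselSegment)
from .solver import PrescribedInflow, Site, WaveformRecord
from .units import LMIN, MMHG

__all__ = [
    "FixtureSpec",
    "make_reduced_tree",
    "control_heart",
    "standard_sites",
    "CAROTID_SITE",
    "CEREBRAL_SITES",
    "carotid_wave_speed",
    "make_single_vessel_case",
    "make_waterhammer_waveforms",
    "fixture_report",
]

#: analysis site label (midpoint of the left common carotid)
CAROTID_SITE = "carotid_mid"
#: the four brain-supplying terminal sites
CEREBRAL_SITES = ["carotid_L", "carotid_R", "vertebral_L", "vertebral_R"]

#: open-loop LA filling pressure (mmHg) that puts the control heart
#: (Ees 2.5 mmHg/mL, 75 beats/min) near LVEDV 136 mL / CO 5.6 L/min on the
#: reduced tree; the preload clamp that CO-fixing adjusts.
P_PV_CONTROL = 10.07


@dataclass
class FixtureSpec:
    """Calibration targets of the reduced tree."""

    name: str = "reduced-tree"
    scale: float = 1.0  # geometric scale factor
    aortic_pwv: float = 4.66  # m/s, baseline diastolic wave speed of the aorta
    target_co: float = 5.6  # L/min, control cardiac output
    target_map: float = 93.0  # mmHg, mean arterial pressure at target CO
    venous_pressure: float = 5.0  # mmHg, bed outflow reference
    diastolic_ref: float = 75.0  # mmHg, tube-law reference pressure (A = Ad)
    bed_tau: float = 0.15  # s, Windkessel decay time R2*C
    bed_r1_frac: float = 0.25  # R1 as a fraction of each bed's total R
    p_pv: float = P_PV_CONTROL  # mmHg, LA filling pressure
    # regional flow fractions of CO (cerebral = carotids + vertebrals)
    frac_carotid: float = 0.05  # each
    frac_vertebral: float = 0.017  # each
    frac_arm: float = 0.05  # each


# (id, name, L [m], d_prox [mm], d_dist [mm], c0 [m/s] or None=aortic, aortic)
_SEGMENTS = [
    ("asc_ao", "ascending aorta", 0.055, 26.1, 25.2, None, True),
    ("arch_a", "aortic arch A", 0.025, 23.4, 22.5, None, True),
    ("arch_b", "aortic arch B", 0.040, 22.5, 21.2, None, True),
    ("desc_1", "descending thoracic aorta", 0.120, 20.7, 18.0, None, True),
    ("desc_2", "thoracoabdominal aorta", 0.140, 18.0, 14.9, None, True),
    ("desc_3", "abdominal aorta", 0.140, 14.9, 11.7, None, True),
    ("bct", "brachiocephalic trunk", 0.035, 13.5, 13.0, 5.2, False),
    ("rcc", "right common carotid", 0.170, 8.0, 7.4, 6.9, False),
    ("lcc", "left common carotid", 0.190, 8.0, 7.4, 6.9, False),
    ("rsub", "right subclavian", 0.040, 9.0, 8.5, 6.0, False),
    ("lsub", "left subclavian", 0.040, 9.0, 8.5, 6.0, False),
    ("rvert", "right vertebral", 0.150, 4.0, 3.6, 9.0, False),
    ("lvert", "left vertebral", 0.150, 4.0, 3.6, 9.0, False),
    ("rbrach", "right brachial", 0.250, 8.0, 5.5, 7.5, False),
    ("lbrach", "left brachial", 0.250, 8.0, 5.5, 7.5, False),
    # both iliac-femoral pathways lumped into one equivalent conduit, so the
    # dominant lower-body reflection site sits at its anatomical distance
    ("legs", "iliac-femoral (lumped, bilateral)", 0.800, 14.0, 10.0, 7.0,
     False),
]

_JUNCTIONS = [
    [("asc_ao", "distal"), ("arch_a", "proximal"), ("bct", "proximal")],
    [("arch_a", "distal"), ("arch_b", "proximal"), ("lcc", "proximal")],
    [("arch_b", "distal"), ("desc_1", "proximal"), ("lsub", "proximal")],
    [("desc_1", "distal"), ("desc_2", "proximal")],
    [("desc_2", "distal"), ("desc_3", "proximal")],
    [("desc_3", "distal"), ("legs", "proximal")],
    [("bct", "distal"), ("rcc", "proximal"), ("rsub", "proximal")],
    [("rsub", "distal"), ("rvert", "proximal"), ("rbrach", "proximal")],
    [("lsub", "distal"), ("lvert", "proximal"), ("lbrach", "proximal")],
]

# terminal bed: segment -> (site label, flow-fraction attribute)
_BEDS = {
    "rcc": ("carotid_R", "frac_carotid"),
    "lcc": ("carotid_L", "frac_carotid"),
    "rvert": ("vertebral_R", "frac_vertebral"),
    "lvert": ("vertebral_L", "frac_vertebral"),
    "rbrach": ("arm_R", "frac_arm"),
    "lbrach": ("arm_L", "frac_arm"),
    "legs": ("lower_body", None),  # remainder of CO
}

_E_WALL = 4.0e5  # nominal elastic modulus (Pa); h is set per end from beta


def _segment_from_row(row, spec: FixtureSpec, rho: float) -> VesselSegment:
    sid, name, L, dp, dd, c0, aortic = row
    L *= spec.scale
    dp *= 1e-3 * spec.scale
    dd *= 1e-3 * spec.scale
    c0 = spec.aortic_pwv if c0 is None else c0
    # beta chosen per end so the diastolic wave speed equals c0 there
    h = []
    for d in (dp, dd):
        ad = math.pi * d * d / 4.0
        beta = 2.0 * rho * math.sqrt(ad) * c0 * c0
        h.append(beta / (BETA_GEOM * _E_WALL))
    return VesselSegment(id=sid, name=name, length=L, d_prox=dp, d_dist=dd,
                         E=_E_WALL, h_prox=h[0], h_dist=h[1],
                         pext=spec.diastolic_ref * MMHG, aortic=aortic)


def make_reduced_tree(spec: FixtureSpec | None = None) -> NetworkSpec:
    """Build the calibrated reduced arterial tree (deterministic)."""
    spec = spec or FixtureSpec()
    fluid = FluidProperties()
    segments = [_segment_from_row(r, spec, fluid.rho) for r in _SEGMENTS]
    seg_by_id = {s.id: s for s in segments}

    co = spec.target_co * LMIN
    dp_drive = (spec.target_map - spec.venous_pressure) * MMHG
    named = {k: getattr(spec, v) for k, (_, v) in _BEDS.items()
             if v is not None}
    frac_lower = 1.0 - 2 * spec.frac_carotid - 2 * spec.frac_vertebral \
        - 2 * spec.frac_arm
    terminals = [Terminal(segment="asc_ao", end="proximal", kind="heart",
                          label="aortic_root")]
    fc = 2.0 * (fluid.xi + 2.0) * math.pi * fluid.mu
    for sid, (label, frac_attr) in _BEDS.items():
        frac = named.get(sid, frac_lower)
        seg = seg_by_id[sid]
        # compensate the terminal conduit's own viscous resistance so the
        # DC path resistance (conduit + bed) hits the flow-fraction target
        x = np.linspace(0.0, seg.length, 64)
        r_visc = float(np.trapezoid(fc / seg.Ad(x) ** 2, x))
        r_tot = dp_drive / (frac * co) - r_visc
        if r_tot <= 0:
            raise ValueError(
                f"fixture calibration failed for bed {sid!r}: conduit "
                f"viscous resistance exceeds the bed's DC target")
        # reflective generic bed: R1 a fixed fraction of the bed total (the
        # cerebral/peripheral impedance mismatch that limits pulsatile
        # transmission), modest compartment compliance
        r1 = spec.bed_r1_frac * r_tot
        r2 = r_tot - r1
        bed = BedParams(R1=r1, C=spec.bed_tau / r2, R2=r2,
                        P_out=spec.venous_pressure * MMHG)
        terminals.append(Terminal(segment=sid, end="distal", kind="bed",
                                  bed=bed, label=label))
    junctions = [Junction(ends=list(e)) for e in _JUNCTIONS]
    return NetworkSpec(segments=segments, junctions=junctions,
                       terminals=terminals, fluid=fluid)


def control_heart(spec: FixtureSpec | None = None) -> HeartParams:
    """Control heart (Ees 2.5 mmHg/mL) with the fixture's preload clamp."""
    spec = spec or FixtureSpec()
    h = HeartParams()
    h.filling.P_pv = spec.p_pv
    return h


def standard_sites() -> list[Site]:
    """Monitoring sites: aortic root, carotid analysis midpoint, the four
    cerebral terminal faces, and the lower-body outlet."""
    return [
        Site("aortic_root", "asc_ao", 0.0),
        Site(CAROTID_SITE, "lcc", 0.5),
        Site("carotid_L", "lcc", 1.0),
        Site("carotid_R", "rcc", 1.0),
        Site("vertebral_L", "lvert", 1.0),
        Site("vertebral_R", "rvert", 1.0),
        Site("lower_body", "legs", 1.0),
    ]


def carotid_wave_speed(net: NetworkSpec) -> float:
    """Diastolic wave speed at the carotid analysis site (m/s)."""
    seg = net.segment("lcc")
    return float(seg.c0(0.5 * seg.length, net.fluid))


def fixture_report(net: NetworkSpec, spec: FixtureSpec | None = None) -> dict:
    """Calibration report: aortic wave speeds, DC resistances, flow split."""
    spec = spec or FixtureSpec()
    fluid = net.fluid
    c0 = {}
    for s in net.segments:
        if s.aortic:
            c0[s.id] = (float(s.c0(0.0, fluid)), float(s.c0(s.length, fluid)))
    fc = 2.0 * (fluid.xi + 2.0) * math.pi * fluid.mu
    g = {}  # per-path DC conductance: bed plus its conduit's friction
    g_beds = 0.0
    for t in net.terminals:
        if t.kind == "bed":
            seg = net.segment(t.segment)
            x = np.linspace(0.0, seg.length, 64)
            r_visc = float(np.trapezoid(fc / seg.Ad(x) ** 2, x))
            g[t.label] = 1.0 / (t.bed.R1 + t.bed.R2 + r_visc)
            g_beds += 1.0 / (t.bed.R1 + t.bed.R2)
    gtot = sum(g.values())
    co = spec.target_co * LMIN
    pred_map = spec.venous_pressure + co / gtot / MMHG
    cerebral = sum(v for k, v in g.items()
                   if k.startswith(("carotid", "vertebral"))) / gtot
    return {
        "aortic_c0": c0,
        "total_resistance": 1.0 / gtot,
        "bed_resistance": 1.0 / g_beds,
        "predicted_map_mmhg": pred_map,
        "cerebral_fraction": cerebral,
        "flow_fractions": {k: v / gtot for k, v in g.items()},
    }


# ---------------------------------------------------------------------------
# solver verification case: one vessel + Windkessel, prescribed inflow
# ---------------------------------------------------------------------------

def make_single_vessel_case(L: float = 0.2, d_mm: float = 8.0,
                            c0: float = 6.0, q_peak: float = 2.0e-4,
                            t_sys: float = 0.24, T: float = 0.8,
                            p_mean_target: float = 90.0,
                            p_out: float = 5.0, tau: float = 1.2,
                            n_nodes: int | None = None):
    """One uniform vessel with a Windkessel outlet and half-sine inflow.

    Returns (net, inflow, oracles) where ``oracles`` holds the analytic
    expectations: mean outlet pressure P_out + (R1+R2) Qmean, the pulse
    transit time L/c0, and the reflected-wave return time 2L/c0.
    """
    fluid = FluidProperties()
    d = d_mm * 1e-3
    ad = math.pi * d * d / 4.0
    beta = 2.0 * fluid.rho * math.sqrt(ad) * c0 * c0
    h = beta / (BETA_GEOM * _E_WALL)
    seg = VesselSegment(id="v", name="test vessel", length=L, d_prox=d,
                        d_dist=d, E=_E_WALL, h_prox=h, h_dist=h,
                        pext=75.0 * MMHG, n_nodes=n_nodes)
    q_mean = q_peak * 2.0 * t_sys / (math.pi * T)
    r_tot = (p_mean_target - p_out) * MMHG / q_mean
    r1 = fluid.rho * c0 / ad
    r2 = r_tot - r1
    if r2 <= 0:
        raise ValueError("single-vessel case: target pressure too low for "
                         "a matched characteristic resistance")
    bed = BedParams(R1=r1, C=tau / r2, R2=r2, P_out=p_out * MMHG)
    net = NetworkSpec(
        segments=[seg],
        terminals=[Terminal(segment="v", end="proximal", kind="inflow",
                            label="inlet"),
                   Terminal(segment="v", end="distal", kind="bed", bed=bed,
                            label="outlet")],
        fluid=fluid)

    def q_fn(t):
        tt = t % T
        return q_peak * math.sin(math.pi * tt / t_sys) if tt < t_sys else 0.0

    inflow = PrescribedInflow(period=T, fn=q_fn)
    oracles = {
        "p_outlet_mean": p_out * MMHG + r_tot * q_mean,
        "q_mean": q_mean,
        "transit_time": L / c0,
        "reflected_return": 2.0 * L / c0,
        "c0": c0,
    }
    return net, inflow, oracles


# ---------------------------------------------------------------------------
# waterhammer oracle waveforms for the analysis layer
# ---------------------------------------------------------------------------

def make_waterhammer_waveforms(rho: float = 1050.0, c: float = 6.0,
                               pulses=(("forward", 2000.0, 0.25, 0.04),),
                               T: float = 1.0, fs: float = 1000.0,
                               p0: float = 90.0 * MMHG, u0: float = 0.2,
                               a0: float = 3.0e-5):
    """Build P, U of known forward/backward composition.

    ``pulses``: iterable of (direction, amplitude [Pa], centre time [s],
    Gaussian sigma [s]).  Forward pulses satisfy dP = +rho c dU, backward
    pulses dP = -rho c dU.  Returns (record, pf_truth, pb_truth); the truth
    components are anchored like :func:`hemopulse.analysis.wave_separation`
    (forward carries the absolute level, backward starts at zero at t=0).
    """
    n = int(round(T * fs)) + 1
    t = np.linspace(0.0, T, n)
    pf = np.zeros(n)
    pb = np.zeros(n)
    for direction, amp, t0, sigma in pulses:
        g = amp * np.exp(-0.5 * ((t - t0) / sigma) ** 2)
        if direction == "forward":
            pf += g
        elif direction == "backward":
            pb += g
        else:
            raise ValueError(f"unknown pulse direction {direction!r}")
    p = p0 + pf + pb
    u = u0 + (pf - pb) / (rho * c)
    rec = WaveformRecord(site="synthetic", t=t, P=p, Q=a0 * u, U=u,
                         A=np.full(n, a0))
    pb_truth = pb - pb[0]
    pf_truth = p - pb_truth  # forward part carries the absolute level
    return rec, pf_truth, pb_truth
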