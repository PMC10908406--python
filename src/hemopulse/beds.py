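"""Three-element Windkessel (RCR) terminal vascular beds.

Each arterial outlet drains through a characteristic resistance R1 into a
compliant compartment C that empties through a distal resistance R2 toward
the venous reference pressure P_out:

    C dPc/dt = Q_in - (Pc - P_out)/R2,      P_interface = Pc + R1 Q_in.

The generic bed is used for every microvascular territory.  In open-loop
mode P_out is a fixed venous pressure; in closed-loop mode the R2 outflow is
routed into the lumped venous compartment feeding the right atrium.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .network import BedParams, FluidProperties, NetworkSpec, VesselSegment

__all__ = ["WindkesselBed", "bed_step", "match_characteristic_impedance",
           "input_impedance", "total_resistance"]


@dataclass
class WindkesselBed:
    """A parameterized bed plus its compartment-pressure state (Pa)."""

    params: BedParams
    Pc: float = 0.0

    @classmethod
    def from_params(cls, params: BedParams, Pc: float | None = None):
        return cls(params=params, Pc=params.P_out if Pc is None else Pc)


def bed_step(bed: WindkesselBed, q_in: float, dt: float) -> float:
    """Advance the bed one step; returns the interface pressure (Pa).

    Forward-Euler update of the compartment pressure (the solver time step
    is far below the R2*C time constant).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    p = bed.params
    p_if = bed.Pc + p.R1 * q_in
    bed.Pc += dt * (q_in - (bed.Pc - p.P_out) / p.R2) / p.C
    return p_if


def match_characteristic_impedance(params: BedParams, seg: VesselSegment,
                                   fluid: FluidProperties,
                                   end: str = "distal") -> BedParams:
    """Set R1 to the attached segment end's characteristic impedance.

    R1 = rho * c0 / Ad at the terminal face minimizes spurious early-time
    reflections of incident waves.  R1 + R2 (the total bed resistance) is
    preserved so the DC operating point is unchanged.
    """
    x = seg.length if end == "distal" else 0.0
    ad = float(seg.Ad(x))
    c0 = float(seg.c0(x, fluid))
    r1 = fluid.rho * c0 / ad
    r_total = params.R1 + params.R2
    if r1 >= r_total:
        raise ValueError(
            f"characteristic impedance {r1:.3e} exceeds total bed "
            f"resistance {r_total:.3e} for segment {seg.id!r}")
    return replace(params, R1=r1, R2=r_total - r1)


def input_impedance(params: BedParams, omega):
    """Analytic RCR input impedance R1 + R2/(1 + j omega R2 C)."""
    omega = np.asarray(omega, dtype=float)
    return params.R1 + params.R2 / (1.0 + 1j * omega * params.R2 * params.C)


def total_resistance(net: NetworkSpec) -> float:
    """DC resistance of all terminal beds combined (parallel network)."""
    g = 0.0
    for t in net.terminals:
        if t.kind == "bed" and t.bed is not None:
            g += 1.0 / (t.bed.R1 + t.bed.R2)
    if g == 0.0:
        raise ValueError("network has no Windkessel terminals")
    return 1.0 / g
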