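"""Vessel-network data model, wall mechanics, and the network file format.

A network is a set of 1-D vessel segments connected at junctions, with every
free segment end closed by a *terminal*: a three-element Windkessel vascular
bed, the heart (aortic-root port), a prescribed inflow, or a sealed cap (used
by verification fixtures).

Wall mechanics follow the thin-wall elastic tube law

    P(A, x) = Pext + beta(x)/Ad(x) * (sqrt(A) - sqrt(Ad(x))),
    beta(x) = (4/3) * sqrt(pi) * E(x) * h(x),

with diastolic area ``Ad`` and wall coefficient ``beta`` tapering linearly in
``x`` between proximal and distal values.  The local pulse wave speed implied
by this law is ``c = sqrt(beta * sqrt(A) / (2 rho Ad))``, reducing to
``c0 = sqrt(beta / (2 rho sqrt(Ad)))`` at the diastolic area.

Units are strict SI throughout (Pa, m, s, kg), including the on-disk schema
(field names carry the unit, e.g. ``d_prox_m``), so that a file round-trips
bit-exactly; published vessel tables in mm convert at entry.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import yaml

__all__ = [
    "FluidProperties",
    "VesselSegment",
    "Junction",
    "Terminal",
    "BedParams",
    "NetworkSpec",
    "NetworkValidationError",
    "tube_law_pressure",
    "tube_law_area",
    "wave_speed",
    "scale_aortic_stiffness",
    "load_network",
    "save_network",
    "network_to_dict",
    "network_from_dict",
]

End = Literal["proximal", "distal"]

BETA_GEOM = (4.0 / 3.0) * math.sqrt(math.pi)


class NetworkValidationError(ValueError):
    """Raised when a network description violates the schema invariants."""


@dataclass(frozen=True)
class FluidProperties:
    """Bulk blood properties entering the 1-D momentum balance.

    rho : density (kg/m^3); mu : dynamic viscosity (Pa s); xi : dimensionless
    constant of the assumed axisymmetric velocity profile (xi = 9 gives the
    22*pi*mu*U/(rho*A) friction commonly used for large arteries).
    """

    rho: float = 1050.0
    mu: float = 4.0e-3
    xi: float = 9.0

    def __post_init__(self):
        if self.rho <= 0 or self.mu <= 0 or self.xi <= 0:
            raise NetworkValidationError(
                f"fluid properties must be positive (rho={self.rho}, "
                f"mu={self.mu}, xi={self.xi})"
            )


@dataclass
class VesselSegment:
    """One tapered elastic vessel.

    Geometry is stored as proximal/distal diastolic diameters (m) and wall
    description (elastic modulus E, thickness h per end); the derived tube-law
    coefficient beta = (4/3) sqrt(pi) E h tapers linearly along x together
    with the diastolic area Ad.
    """

    id: str
    name: str
    length: float
    d_prox: float
    d_dist: float
    E: float
    h_prox: float
    h_dist: float
    pext: float = 0.0
    n_nodes: int | None = None
    aortic: bool = False

    def __post_init__(self):
        if self.length <= 0:
            raise NetworkValidationError(f"segment {self.id!r}: length must be > 0")
        for lbl, v in (("d_prox", self.d_prox), ("d_dist", self.d_dist),
                       ("E", self.E), ("h_prox", self.h_prox),
                       ("h_dist", self.h_dist)):
            if v <= 0:
                raise NetworkValidationError(
                    f"segment {self.id!r}: {lbl} must be > 0, got {v}")
        if self.n_nodes is not None and self.n_nodes < 3:
            raise NetworkValidationError(
                f"segment {self.id!r}: n_nodes must be >= 3")

    # --- derived geometry -------------------------------------------------
    @property
    def Ad_prox(self) -> float:
        return math.pi * self.d_prox**2 / 4.0

    @property
    def Ad_dist(self) -> float:
        return math.pi * self.d_dist**2 / 4.0

    @property
    def beta_prox(self) -> float:
        return BETA_GEOM * self.E * self.h_prox

    @property
    def beta_dist(self) -> float:
        return BETA_GEOM * self.E * self.h_dist

    def Ad(self, x):
        """Diastolic area at position x (m from the proximal end)."""
        s = np.clip(np.asarray(x, dtype=float) / self.length, 0.0, 1.0)
        return self.Ad_prox + (self.Ad_dist - self.Ad_prox) * s

    def beta(self, x):
        """Wall coefficient beta (Pa m) at position x."""
        s = np.clip(np.asarray(x, dtype=float) / self.length, 0.0, 1.0)
        return self.beta_prox + (self.beta_dist - self.beta_prox) * s

    def c0(self, x, fluid: FluidProperties):
        """Diastolic wave speed at position x."""
        return np.sqrt(self.beta(x) / (2.0 * fluid.rho * np.sqrt(self.Ad(x))))


@dataclass
class Junction:
    """A branching point joining >= 2 segment ends.

    ``ends`` lists (segment id, end).  Sign convention for mass conservation:
    flow A*U at a *distal* end is directed into the junction (+), at a
    *proximal* end out of it (-), so the condition is  sum(s_i A_i U_i) = 0.
    """

    ends: list[tuple[str, End]]

    def __post_init__(self):
        self.ends = [(sid, end) for sid, end in self.ends]
        if len(self.ends) < 2:
            raise NetworkValidationError(
                f"junction {self.ends}: needs at least 2 attached ends")
        for sid, end in self.ends:
            if end not in ("proximal", "distal"):
                raise NetworkValidationError(
                    f"junction end {(sid, end)}: end must be proximal|distal")


@dataclass
class BedParams:
    """Three-element Windkessel (RCR) terminal bed parameters, SI units.

    R1: characteristic resistance (Pa s/m^3); C: compliance (m^3/Pa);
    R2: distal resistance; P_out: venous reference pressure (Pa).
    """

    R1: float
    C: float
    R2: float
    P_out: float = 0.0

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0 or self.C <= 0:
            raise NetworkValidationError(
                f"bed parameters must be positive (R1={self.R1}, C={self.C}, "
                f"R2={self.R2})")


@dataclass
class Terminal:
    """Closure of a free segment end.

    kind = 'bed'    -> Windkessel vascular bed (``bed`` set)
    kind = 'heart'  -> aortic-root port of the 0-D heart
    kind = 'inflow' -> prescribed periodic inflow (verification fixtures)
    kind = 'closed' -> sealed cap, U = 0 (conservation fixtures)
    """

    segment: str
    end: End
    kind: Literal["bed", "heart", "inflow", "closed"] = "bed"
    bed: BedParams | None = None
    label: str = ""

    def __post_init__(self):
        if self.kind == "bed" and self.bed is None:
            raise NetworkValidationError(
                f"terminal at ({self.segment}, {self.end}): kind 'bed' "
                "requires bed parameters")


@dataclass
class NetworkSpec:
    """A validated vessel network: segments, junctions, terminals, fluid."""

    segments: list[VesselSegment]
    junctions: list[Junction] = field(default_factory=list)
    terminals: list[Terminal] = field(default_factory=list)
    fluid: FluidProperties = field(default_factory=FluidProperties)

    def __post_init__(self):
        self.validate()

    # --- lookups ----------------------------------------------------------
    def segment(self, sid: str) -> VesselSegment:
        for s in self.segments:
            if s.id == sid:
                return s
        raise KeyError(f"no segment with id {sid!r}")

    @property
    def segment_ids(self) -> list[str]:
        return [s.id for s in self.segments]

    @property
    def aortic_ids(self) -> list[str]:
        return [s.id for s in self.segments if s.aortic]

    def validate(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate segment ids: {dup}")
        idset = set(ids)
        # every end referenced must exist, and each (segment, end) attaches
        # to exactly one junction or terminal
        attach_count: dict[tuple[str, str], int] = {}
        for j in self.junctions:
            for sid, end in j.ends:
                if sid not in idset:
                    raise NetworkValidationError(
                        f"junction references missing segment {sid!r}")
                attach_count[(sid, end)] = attach_count.get((sid, end), 0) + 1
        for t in self.terminals:
            if t.segment not in idset:
                raise NetworkValidationError(
                    f"terminal references missing segment {t.segment!r}")
            attach_count[(t.segment, t.end)] = (
                attach_count.get((t.segment, t.end), 0) + 1)
        for sid in ids:
            for end in ("proximal", "distal"):
                n = attach_count.get((sid, end), 0)
                if n == 0:
                    raise NetworkValidationError(
                        f"segment {sid!r}: {end} end is dangling "
                        "(not attached to any junction or terminal)")
                if n > 1:
                    raise NetworkValidationError(
                        f"segment {sid!r}: {end} end attached {n} times")


# ---------------------------------------------------------------------------
# wall mechanics
# ---------------------------------------------------------------------------

def tube_law_pressure(A, x, seg: VesselSegment):
    """Transmural pressure (Pa) from the elastic tube law at area ``A``.

    Strictly increasing in A; equals ``seg.pext`` at the diastolic area.
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError(f"segment {seg.id!r}: area must be > 0")
    Ad = seg.Ad(x)
    beta = seg.beta(x)
    out = seg.pext + beta / Ad * (np.sqrt(A) - np.sqrt(Ad))
    return out if out.shape else float(out)


def tube_law_area(P, x, seg: VesselSegment):
    """Inverse tube law: area at transmural pressure ``P`` (Pa)."""
    Ad = seg.Ad(x)
    beta = seg.beta(x)
    root = np.sqrt(Ad) + (np.asarray(P, dtype=float) - seg.pext) * Ad / beta
    if np.any(root <= 0):
        raise ValueError(f"segment {seg.id!r}: pressure below collapse limit")
    out = root**2
    return out if out.shape else float(out)


def wave_speed(A, x, seg: VesselSegment, fluid: FluidProperties):
    """Local pulse wave speed c = sqrt(beta sqrt(A) / (2 rho Ad)) (m/s)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError(f"segment {seg.id!r}: area must be > 0")
    out = np.sqrt(seg.beta(x) * np.sqrt(A) / (2.0 * fluid.rho * seg.Ad(x)))
    return out if out.shape else float(out)


def scale_aortic_stiffness(net: NetworkSpec, m: float) -> NetworkSpec:
    """Return a copy of ``net`` with aortic-segment PWV scaled by ``m``.

    beta (via the elastic modulus E) of every segment flagged aortic is
    multiplied by m^2 so the diastolic wave speed scales by m; all other
    segments are untouched.  ``m`` is the PWV multiple of Table-style
    stiffening sweeps and must be >= 1.
    """
    if m < 1.0:
        raise ValueError(f"PWV multiple must be >= 1, got {m}")
    out = copy.deepcopy(net)
    for s in out.segments:
        if s.aortic:
            s.E *= m * m
    return out


# ---------------------------------------------------------------------------
# file format (YAML schema, human-editable; mm for transverse dimensions)
# ---------------------------------------------------------------------------

def network_to_dict(net: NetworkSpec) -> dict:
    d = {
        "fluid": {"rho": net.fluid.rho, "mu": net.fluid.mu, "xi": net.fluid.xi},
        "segments": [],
        "junctions": [],
        "terminals": [],
    }
    for s in net.segments:
        d["segments"].append({
            "id": s.id,
            "name": s.name,
            "length_m": s.length,
            "d_prox_m": s.d_prox,
            "d_dist_m": s.d_dist,
            "E_Pa": s.E,
            "h_prox_m": s.h_prox,
            "h_dist_m": s.h_dist,
            "pext_pa": s.pext,
            "n_nodes": s.n_nodes,
            "aortic": s.aortic,
        })
    for j in net.junctions:
        d["junctions"].append({"ends": [[sid, end] for sid, end in j.ends]})
    for t in net.terminals:
        td = {"segment": t.segment, "end": t.end, "kind": t.kind,
              "label": t.label}
        if t.bed is not None:
            td["bed"] = {"R1": t.bed.R1, "C": t.bed.C, "R2": t.bed.R2,
                         "P_out": t.bed.P_out}
        d["terminals"].append(td)
    return d


def network_from_dict(d: dict) -> NetworkSpec:
    try:
        fl = d.get("fluid", {})
        fluid = FluidProperties(rho=float(fl.get("rho", 1050.0)),
                                mu=float(fl.get("mu", 4.0e-3)),
                                xi=float(fl.get("xi", 9.0)))
        segments = []
        for sd in d["segments"]:
            segments.append(VesselSegment(
                id=str(sd["id"]),
                name=str(sd.get("name", sd["id"])),
                length=float(sd["length_m"]),
                d_prox=float(sd["d_prox_m"]),
                d_dist=float(sd["d_dist_m"]),
                E=float(sd["E_Pa"]),
                h_prox=float(sd["h_prox_m"]),
                h_dist=float(sd["h_dist_m"]),
                pext=float(sd.get("pext_pa", 0.0)),
                n_nodes=(None if sd.get("n_nodes") is None
                         else int(sd["n_nodes"])),
                aortic=bool(sd.get("aortic", False)),
            ))
        junctions = [Junction(ends=[(str(a), str(b)) for a, b in jd["ends"]])
                     for jd in d.get("junctions", [])]
        terminals = []
        for td in d.get("terminals", []):
            bed = None
            if td.get("bed") is not None:
                b = td["bed"]
                bed = BedParams(R1=float(b["R1"]), C=float(b["C"]),
                                R2=float(b["R2"]),
                                P_out=float(b.get("P_out", 0.0)))
            terminals.append(Terminal(segment=str(td["segment"]),
                                      end=str(td["end"]),
                                      kind=str(td.get("kind", "bed")),
                                      bed=bed,
                                      label=str(td.get("label", ""))))
    except KeyError as e:
        raise NetworkValidationError(f"missing required schema field: {e}") from e
    return NetworkSpec(segments=segments, junctions=junctions,
                       terminals=terminals, fluid=fluid)


def save_network(net: NetworkSpec, path) -> None:
    """Write ``net`` to a YAML network file (round-trips exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def load_network(path) -> NetworkSpec:
    """Read and validate a network file; raises NetworkValidationError."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict) or "segments" not in d:
        raise NetworkValidationError(
            f"{path}: not a network file (no 'segments' section)")
    return network_from_dict(d)
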