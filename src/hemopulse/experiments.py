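"""Sweep experiments over contractility x heart rate x aortic stiffness.

``run_sweep`` orchestrates the in-silico designs: for every grid point it
scales the aortic PWV, sets the LV end-systolic elastance and the heart
rate, optionally fixes cardiac output (or LVEDV) by preload adjustment
(Frank-Starling), runs the model to its periodic limit cycle, and computes
the full hemodynamic summary at the carotid analysis site plus cerebral
blood flow.  Results come back as a long-format DataFrame, one row per
(Ees, HR, PWV multiple), which downstream helpers interrogate for the
optimal heart rate (minimum carotid pulsatile power) and percent changes
against baseline stiffness.

Everything is deterministic: repeated runs of the same grid produce
identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .analysis import summarize
from .fixtures import CAROTID_SITE, CEREBRAL_SITES, standard_sites
from .heart import HeartParams, fix_cardiac_output, set_contractility
from .network import NetworkSpec, scale_aortic_stiffness
from .solver import (ConvergenceError, SolverConfig, SolverError,
                     run_to_periodic)

__all__ = ["SweepGrid", "run_sweep", "find_optimal_hr", "percent_change"]

# physiological sweep ranges; values outside draw a warning
_RANGES = {"ees": (0.6, 5.0), "hr": (30.0, 180.0), "pwv_multiple": (1.0, 3.0)}


@dataclass
class SweepGrid:
    """The experimental grid and its cardiac-output protocol.

    co_mode='fixed_co': preload adjusted at every grid point so the
    converged CO equals target_co (isolated-contractility designs).
    co_mode='fixed_lvedv': CO fixed (to target_co) at the smallest PWV
    multiple of each (Ees, HR) slice, then LVEDV held at that value as
    stiffness rises (the brain-perfusion design).
    co_mode='free': the preload clamp is left untouched.
    """

    ees: Sequence[float] = (0.6, 1.2, 1.8, 2.5, 3.5, 5.0)
    hr: Sequence[float] = (30.0, 50.0, 75.0, 100.0, 125.0, 150.0, 180.0)
    pwv_multiples: Sequence[float] = (1.0, 2.0, 3.0)
    co_mode: str = "fixed_co"
    target_co: float = 5.6  # L/min
    co_tol: float = 0.01

    def __post_init__(self):
        if self.co_mode not in ("fixed_co", "fixed_lvedv", "free"):
            raise ValueError(f"unknown co_mode {self.co_mode!r}")
        for attr, key in (("ees", "ees"), ("hr", "hr"),
                          ("pwv_multiples", "pwv_multiple")):
            lo, hi = _RANGES[key]
            vals = np.asarray(getattr(self, attr), dtype=float)
            if np.any(vals < lo) or np.any(vals > hi):
                warnings.warn(
                    f"{attr} values outside the physiological range "
                    f"[{lo}, {hi}]: {vals.tolist()}", stacklevel=2)


_NAN_METRICS = ["p_total_mw", "p_s_mw", "p_pulse_mw", "cpi", "fcwi", "bcwi",
                "fewi", "fcwp_w", "ri_pct", "cbf_lmin", "qmin_lmin",
                "qmax_lmin", "pmean_mmhg", "qmean_lmin"]


def run_sweep(net: NetworkSpec, heart: HeartParams, grid: SweepGrid,
              config: SolverConfig | None = None, sites=None,
              carotid_site: str = CAROTID_SITE,
              cerebral_sites: Sequence[str] = tuple(CEREBRAL_SITES),
              ) -> pd.DataFrame:
    """Run the full grid; returns one row per (Ees, HR, PWV multiple).

    Non-convergent grid points are recorded with NaN metrics and the error
    message in the ``error`` column rather than aborting the sweep.
    """
    config = config or SolverConfig()
    sites = sites if sites is not None else standard_sites()
    site_by_label = {s.label: s for s in sites}
    car = site_by_label[carotid_site]

    rows = []
    for m in grid.pwv_multiples:
        net_m = scale_aortic_stiffness(net, m)
        seg = net_m.segment(car.segment)
        c_car = float(seg.c0(car.frac * seg.length, net_m.fluid))
        for ees in grid.ees:
            h = set_contractility(heart, ees)
            warm = None
            lvedv_ref = rows_ref = None
            for hr in grid.hr:
                cfg = replace(config, heart_rate=hr)
                row = {"ees": ees, "hr": hr, "pwv_multiple": m,
                       "error": ""}
                try:
                    if grid.co_mode == "fixed_co":
                        h, res, _ = fix_cardiac_output(
                            net_m, h, cfg, grid.target_co, tol=grid.co_tol,
                            sites=sites, warm_start=warm)
                    elif grid.co_mode == "fixed_lvedv":
                        # reference LVEDV comes from the baseline-stiffness
                        # sweep of the same (ees, hr): fix CO there
                        ref = _lvedv_reference(net, heart, ees, hr, cfg,
                                               grid, sites)
                        h, res, _ = fix_cardiac_output(
                            net_m, h, cfg, grid.target_co, tol=grid.co_tol,
                            target_lvedv=ref, sites=sites, warm_start=warm)
                    else:
                        res = run_to_periodic(net_m, h, cfg, sites=sites,
                                              warm_start=warm)
                    warm = res
                    summ = summarize(res.record(carotid_site),
                                     [res.record(s) for s in cerebral_sites],
                                     net_m.fluid.rho, c_car)
                    row.update(vars(summ))
                    row["co_lmin"] = res.cardiac_output
                    row["lvedv_ml"] = res.lvedv
                    row["p_pv_mmhg"] = h.filling.P_pv
                    row["n_cycles"] = res.n_cycles
                    row["residual"] = (res.residuals[-1]
                                       if res.residuals else np.nan)
                except (SolverError, ConvergenceError, RuntimeError) as e:
                    row["error"] = str(e)
                    for k in _NAN_METRICS + ["co_lmin", "lvedv_ml",
                                             "p_pv_mmhg", "residual"]:
                        row[k] = np.nan
                    row["n_cycles"] = 0
                    warm = None
                rows.append(row)
    return pd.DataFrame(rows)


# cache of baseline-stiffness LVEDV references keyed by (id(net), ees, hr)
_LVEDV_CACHE: dict = {}


def _lvedv_reference(net, heart, ees, hr, cfg, grid, sites):
    key = (id(net), ees, hr, grid.target_co)
    if key not in _LVEDV_CACHE:
        h = set_contractility(heart, ees)
        _, _, lvedv = fix_cardiac_output(net, h, cfg, grid.target_co,
                                         tol=grid.co_tol, sites=sites)
        _LVEDV_CACHE[key] = lvedv
    return _LVEDV_CACHE[key]


def find_optimal_hr(df: pd.DataFrame, ees: float, pwv_multiple: float,
                    metric: str = "p_pulse_mw") -> dict:
    """Grid HR minimizing ``metric`` on one (Ees, PWV) slice.

    Returns {'hr_opt', 'interior_minimum', 'hr', 'values'}; the
    interior_minimum flag certifies the decreasing-then-increasing pattern
    around the minimizer (False when the minimum sits on the grid boundary).
    """
    sl = df[(df.ees == ees) & (df.pwv_multiple == pwv_multiple)]
    sl = sl.sort_values("hr")
    if len(sl) < 3:
        raise ValueError(
            f"need >= 3 heart-rate points at Ees={ees}, m={pwv_multiple}; "
            f"got {len(sl)}")
    hr = sl["hr"].to_numpy(dtype=float)
    y = sl[metric].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("slice contains non-converged grid points")
    i = int(np.argmin(y))
    d = np.diff(y)
    interior = 0 < i < len(y) - 1 and np.all(d[:i] < 0) and np.all(d[i:] > 0)
    return {"hr_opt": float(hr[i]), "interior_minimum": bool(interior),
            "hr": hr, "values": y}


def percent_change(x: float, x_ref: float) -> float:
    """100 (x - x_ref) / x_ref."""
    if x_ref == 0:
        raise ZeroDivisionError("percent change undefined for zero reference")
    return 100.0 * (x - x_ref) / x_ref
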