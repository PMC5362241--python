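"""Parameter scans over Pe and alpha, and the critical Peclet number.

A scan runs one full simulation per Peclet value from a localized
super-threshold RhoA pulse and classifies each run as propagating or
stationary.  ``critical_pe`` bisects on the verdict between a verified
propagating and a verified stationary bracket.  Boundary contact never
masquerades as a verdict: a censored run is retried on a 2x longer domain
(and a still-relaxing run with a 2x longer horizon) before the row is
declared failed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .diagnostics import (
    VERDICT_CENSORED,
    VERDICT_PROPAGATING,
    VERDICT_STATIONARY,
    VERDICT_TRANSIENT,
    ZoneTrace,
    detect_stationary,
    front_speed,
    zone_width_series,
)
from .grid import Grid
from .kinetics import KineticParams, find_fixed_points
from .mechanics import MechParams
from .pde import BlowUpError, SpaceTimeRecord, simulate
from .protocols import make_pulse

__all__ = ["RunResult", "BracketError", "run_single", "pe_scan", "critical_pe", "width_vs_pe"]

log = logging.getLogger("rhozone")

DEFAULT_T_END = 200.0
DEFAULT_RECORD_EVERY = 0.5


class BracketError(ValueError):
    """Raised when a bisection endpoint does not have the required verdict."""


@dataclass
class RunResult:
    pe: float
    verdict: str
    speed: float | None
    stationary_width: float | None
    trace: ZoneTrace
    record: SpaceTimeRecord
    grid: Grid

    def row(self) -> dict:
        return {
            "pe": self.pe,
            "verdict": self.verdict,
            "is_stationary": self.verdict == VERDICT_STATIONARY,
            "speed": self.speed,
            "stationary_width": self.stationary_width,
            "domain_length": self.grid.length,
        }


def _c_high(kp: KineticParams) -> float:
    return float(find_fixed_points(kp).high[0])


def run_single(
    kp: KineticParams,
    mp: MechParams,
    grid: Grid,
    *,
    pulse_amplitude: float | None = None,
    pulse_half_width: float = 1.0,
    pulse_species: str = "rho",
    t_end: float = DEFAULT_T_END,
    record_every: float = DEFAULT_RECORD_EVERY,
    rel_tol: float = 1e-3,
    window: float = 20.0,
    max_retries: int = 2,
) -> RunResult:
    """One pulse-ignition simulation plus classification.

    If the verdict is spoiled by boundary contact the run is repeated on a
    domain of twice the length (same dx); a run still relaxing at t_end is
    repeated with twice the horizon.
    """
    c_high = _c_high(kp)
    amplitude = c_high if pulse_amplitude is None else pulse_amplitude
    g, te = grid, t_end
    t_start = time.perf_counter()
    for attempt in range(max_retries + 1):
        init = make_pulse(g, amplitude, pulse_half_width, pulse_species, K=mp.K)
        rec = simulate(init, kp, mp, g, te, record_every)
        trace = detect_stationary(zone_width_series(rec), rel_tol=rel_tol, window=window)
        if trace.verdict == VERDICT_CENSORED and attempt < max_retries:
            g = dc_replace(g, length=2 * g.length, n_cells=2 * g.n_cells)
            continue
        if trace.verdict == VERDICT_TRANSIENT and attempt < max_retries:
            te = 2 * te
            continue
        break
    speed = None
    if trace.verdict == VERDICT_PROPAGATING:
        speed = front_speed(trace, c_high)
    elif trace.verdict == VERDICT_STATIONARY:
        speed = 0.0
    log.info(
        "run pe=%g alpha=%g mode=%s L=%g n=%d t_end=%g -> %s width=%s speed=%s "
        "[%.1fs]",
        mp.pe, kp.alpha, mp.advection_mode, g.length, g.n_cells, te,
        trace.verdict, trace.stationary_width, speed,
        time.perf_counter() - t_start,
    )
    return RunResult(
        pe=mp.pe,
        verdict=trace.verdict,
        speed=speed,
        stationary_width=trace.stationary_width,
        trace=trace,
        record=rec,
        grid=g,
    )


def pe_scan(
    kp: KineticParams,
    mp_template: MechParams,
    grid: Grid,
    pe_values,
    **run_kwargs,
) -> pd.DataFrame:
    """One full simulation + diagnostics per Peclet value.

    A failing run is recorded in its row (``error`` column) and the scan
    continues.  Deterministic given the configuration; rows are independent
    of execution order.
    """
    pe_values = list(pe_values)
    if not pe_values:
        raise ValueError("pe_values must be non-empty")
    rows = []
    for pe in pe_values:
        mp = dc_replace(mp_template, pe=float(pe))
        try:
            res = run_single(kp, mp, grid, **run_kwargs)
            row = res.row()
            row["error"] = None
        except BlowUpError as exc:
            row = {
                "pe": float(pe),
                "verdict": "failed",
                "is_stationary": False,
                "speed": None,
                "stationary_width": None,
                "domain_length": grid.length,
                "error": str(exc),
            }
        rows.append(row)
    return pd.DataFrame(rows)


def critical_pe(
    kp: KineticParams,
    mp_template: MechParams,
    grid: Grid,
    pe_lo: float,
    pe_hi: float,
    tol: float = 0.25,
    **run_kwargs,
) -> float:
    """Critical Peclet number by bisection on the stationarity verdict.

    ``pe_lo`` must be propagating and ``pe_hi`` stationary (both endpoints
    are verified before bisecting; a bad endpoint raises a
    :class:`BracketError` naming it).  Returns the bracket midpoint once
    the bracket is narrower than ``tol``.  Fully deterministic.
    """

    def verdict_at(pe: float) -> str:
        res = run_single(kp, dc_replace(mp_template, pe=pe), grid, **run_kwargs)
        return res.verdict

    v_lo = verdict_at(pe_lo)
    if v_lo != VERDICT_PROPAGATING:
        raise BracketError(f"pe_lo = {pe_lo} is not propagating (verdict: {v_lo})")
    v_hi = verdict_at(pe_hi)
    if v_hi != VERDICT_STATIONARY:
        raise BracketError(f"pe_hi = {pe_hi} is not stationary (verdict: {v_hi})")

    lo, hi = float(pe_lo), float(pe_hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        v = verdict_at(mid)
        if v == VERDICT_STATIONARY:
            hi = mid
        elif v == VERDICT_PROPAGATING:
            lo = mid
        else:
            raise BracketError(
                f"verdict at pe = {mid} is {v!r}; cannot bisect (longer-domain "
                "retries exhausted)"
            )
    return 0.5 * (lo + hi)


def width_vs_pe(
    kp: KineticParams,
    mp_template: MechParams,
    grid: Grid,
    pe_values,
    **run_kwargs,
) -> pd.DataFrame:
    """Stationary-zone width as a function of Pe.

    Below the critical Peclet number the zone is unbounded (the front
    propagates indefinitely): those rows carry ``width = inf`` and regime
    "unbounded".
    """
    scan = pe_scan(kp, mp_template, grid, pe_values, **run_kwargs)
    width = np.where(scan["is_stationary"], scan["stationary_width"].astype(float), np.inf)
    regime = np.where(scan["is_stationary"], "stationary", "unbounded")
    regime = np.where(scan["verdict"] == "failed", "failed", regime)
    return pd.DataFrame({"pe": scan["pe"], "width": width, "regime": regime})
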