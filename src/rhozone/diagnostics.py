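"""Scalar summaries of space-time records: zone width, front speed,
stationarity verdicts and clustering.

The width of the active zone is defined as the integral of the RhoA
concentration over the whole domain.  Because the high plateau sits near
concentration 1 for small kappa, this integral nearly coincides with the
geometric extent of the zone.  A propagating front makes the width grow
linearly in time; a flow-pinned stationary zone makes it level off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .pde import SpaceTimeRecord

__all__ = [
    "ZoneTrace",
    "zone_width_series",
    "front_speed",
    "detect_stationary",
    "cluster_count",
    "half_max_extent",
    "VERDICT_STATIONARY",
    "VERDICT_PROPAGATING",
    "VERDICT_CENSORED",
    "VERDICT_TRANSIENT",
]

VERDICT_STATIONARY = "stationary"
VERDICT_PROPAGATING = "propagating"
VERDICT_CENSORED = "censored"   # boundary contact spoiled the verdict
VERDICT_TRANSIENT = "transient"  # still relaxing (e.g. shrinking) at t_end

DEFAULT_REL_TOL = 1e-3
DEFAULT_WINDOW = 20.0
DEFAULT_MARGIN = 2.0


@dataclass
class ZoneTrace:
    """Width-vs-time series of one record plus derived verdicts.

    ``t_contact`` is the first time the front reaches the boundary margin
    (None if never); frames at and after contact are excluded from fits and
    a contacted run is never called stationary.
    """

    times: np.ndarray
    width: np.ndarray
    t_contact: float | None = None
    speed: float | None = None
    verdict: str | None = None
    stationary_width: float | None = None

    @property
    def is_stationary(self) -> bool:
        return self.verdict == VERDICT_STATIONARY

    def usable(self) -> np.ndarray:
        """Mask of frames unaffected by boundary contact."""
        if self.t_contact is None:
            return np.ones_like(self.times, dtype=bool)
        return self.times < self.t_contact

    def to_csv(self, path) -> Path:
        path = Path(path)
        pd.DataFrame({"time": self.times, "width": self.width}).to_csv(path, index=False)
        return path


def _contact_time(rec: SpaceTimeRecord, margin: float) -> float | None:
    """First time the rho front (half of its global maximum) enters the
    boundary margin."""
    peak = float(rec.rho_xt.max())
    if peak <= 0:
        return None
    thr = 0.5 * peak
    x = rec.grid.x
    near = (x < margin) | (x > rec.grid.length - margin)
    if not near.any():
        return None
    hit = (rec.rho_xt[:, near] > thr).any(axis=1)
    idx = np.nonzero(hit)[0]
    return float(rec.times[idx[0]]) if len(idx) else None


def zone_width_series(
    rec: SpaceTimeRecord, *, species: str = "rho", margin: float = DEFAULT_MARGIN
) -> ZoneTrace:
    """Per-frame integral of the concentration field over the domain."""
    if rec.n_frames == 0:
        raise ValueError("empty record")
    field = rec.rho_xt if species == "rho" else rec.m_xt
    if rec.grid.periodic:
        width = field.sum(axis=1) * rec.grid.dx
        t_contact = None
    else:
        width = np.trapezoid(field, dx=rec.grid.dx, axis=1)
        t_contact = _contact_time(rec, margin)
    return ZoneTrace(times=rec.times.copy(), width=width, t_contact=t_contact)


def front_speed(trace: ZoneTrace, c_high: float, *, min_frames: int = 10) -> float:
    """Front propagation speed from the growth rate of the zone width.

    Least-squares slope of width vs time over the late-time half of the
    usable (pre-contact) frames, divided by 2*c_high: two fronts move
    outward, each advancing the integral by c_high per unit length.
    """
    if c_high <= 0:
        raise ValueError("c_high must be positive")
    use = trace.usable()
    t, w = trace.times[use], trace.width[use]
    if len(t) < 2:
        raise ValueError("no usable frames before boundary contact")
    late = t >= (t[0] + t[-1]) / 2
    if late.sum() < min_frames:
        raise ValueError(
            f"fit window has {int(late.sum())} frames; at least {min_frames} required"
        )
    slope = np.polyfit(t[late], w[late], 1)[0]
    return float(slope) / (2 * c_high)


def detect_stationary(
    trace: ZoneTrace,
    rel_tol: float = DEFAULT_REL_TOL,
    window: float = DEFAULT_WINDOW,
) -> ZoneTrace:
    """Classify a width trace as stationary / propagating / censored.

    Stationary: no boundary contact, and the width range over the trailing
    ``window`` time units is below ``rel_tol`` relative to its mean; the
    stationary width is the trailing-window mean.  A trace whose front
    touched the boundary is "propagating" if the width was still growing,
    otherwise "censored" — never "stationary".  A contact-free trace still
    drifting at t_end is "propagating" (growing) or "transient" (shrinking,
    e.g. a wide initial zone still relaxing).
    """
    use = trace.usable()
    t, w = trace.times[use], trace.width[use]
    out = replace(trace)

    if trace.t_contact is not None:
        if len(t) < 5:
            out.verdict = VERDICT_CENSORED
            return out
        net = w[-1] - w[0]
        out.verdict = VERDICT_PROPAGATING if net > 0 else VERDICT_CENSORED
        return out

    if t[-1] - t[0] < 2 * window:
        raise ValueError(
            f"record spans {t[-1] - t[0]:g} time units; stationarity needs >= 2x "
            f"the window ({window:g})"
        )
    trail = t >= t[-1] - window
    wt = w[trail]
    mean = float(wt.mean())
    rng = float(wt.max() - wt.min())
    if mean > 0 and rng / mean < rel_tol:
        out.verdict = VERDICT_STATIONARY
        out.stationary_width = mean
    elif wt[-1] - wt[0] > 0:
        out.verdict = VERDICT_PROPAGATING
    else:
        out.verdict = VERDICT_TRANSIENT
    return out


def half_max_extent(field: np.ndarray, x: np.ndarray) -> float:
    """Length of the region where the field exceeds half its maximum."""
    peak = float(field.max())
    if peak <= 0:
        return 0.0
    above = field > 0.5 * peak
    dx = x[1] - x[0]
    return float(above.sum()) * dx


def cluster_count(
    rec: SpaceTimeRecord,
    frame: int,
    min_prominence: float,
    *,
    species: str = "m",
) -> int:
    """Number of concentration clusters in one frame.

    Counts local maxima of the chosen field with at least ``min_prominence``
    topographic prominence.  A single uniform plateau (no internal peaks but
    a field rising above the prominence threshold) counts as one cluster;
    an everywhere-sub-threshold field counts as zero.
    """
    field = rec.m_xt[frame] if species == "m" else rec.rho_xt[frame]
    peaks, _ = find_peaks(field, prominence=min_prominence)
    if len(peaks) == 0:
        return 1 if float(field.max()) > min_prominence else 0
    return int(len(peaks))
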