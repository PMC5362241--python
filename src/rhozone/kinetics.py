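"""Well-mixed RhoA-NMIIA positive-feedback kinetics.

Active (GTP-loaded, cortex-bound) RhoA and non-muscle myosin IIA (NMIIA)
mutually recruit each other to the junctional cortex.  In non-dimensional
form (concentrations in units of the recruitment/dissociation ratio s/k,
time in units of the diffusion time) the well-mixed system reads

    d rho / dt = alpha * ( m^n / (kappa1^n + m^n) - rho )
    d m   / dt = alpha * ( rho^n / (kappa2^n + rho^n) - m )

where ``alpha`` is the ratio of the diffusion time to the reaction time and
``kappa1``, ``kappa2`` are half-saturation concentrations of the Hill-type
cortical adsorption.  For sufficiently small kappa the system is bistable:
a low state at the origin and a high contractile state coexist, separated
by a saddle whose stable manifold (the separatrix) divides the two basins
of attraction.

This module provides the rate functions, fixed-point analysis with
stability labels, a bistability test, and phase-plane objects (nullclines,
saddle manifolds) with plain-CSV export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "FixedPointSet",
    "NonBistableError",
    "NonHyperbolicError",
    "RootFindingError",
    "hill",
    "hill_deriv",
    "reaction_rates",
    "find_fixed_points",
    "bistability_check",
    "separatrix",
    "unstable_manifold",
    "nullclines",
    "classify_basin",
    "export_phase_portrait",
]


class NonBistableError(ValueError):
    """Raised when an operation requires the bistable regime but the
    parameters admit only a single fixed point."""


class NonHyperbolicError(RuntimeError):
    """Raised when a Jacobian eigenvalue is too close to the imaginary axis
    to classify stability reliably."""


class RootFindingError(RuntimeError):
    """Raised when the fixed-point search cannot bracket/refine a root; the
    caller never receives a silently partial set."""


@dataclass(frozen=True)
class KineticParams:
    """Non-dimensional parameters of the RhoA-NMIIA feedback loop.

    alpha
        Reaction-rate prefactor: ratio of the diffusion time to the
        timescale of the reaction kinetics.
    kappa1
        Half-saturation concentration of NMIIA's activation of RhoA.
    kappa2
        Half-saturation concentration of RhoA's activation of NMIIA.
    n
        Hill coefficient of the cortical-adsorption terms (default 4).
    """

    alpha: float = 1.0
    kappa1: float = 0.2
    kappa2: float = 0.2
    n: int = 4

    def __post_init__(self) -> None:
        # alpha = 0 (frozen reactions) is allowed for transport-only runs;
        # fixed-point analysis requires alpha > 0.
        if not self.alpha >= 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if not (self.kappa1 > 0 and self.kappa2 > 0):
            raise ValueError(
                f"kappa1 and kappa2 must be positive, got {self.kappa1}, {self.kappa2}"
            )
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"Hill coefficient n must be an integer >= 1, got {self.n}")


@dataclass
class FixedPointSet:
    """Steady states of the well-mixed system with stability labels.

    ``points`` is an array of (rho, m) pairs sorted by rho; ``stability``
    holds one of {"stable", "saddle", "unstable"} per point.
    """

    points: np.ndarray
    stability: list[str] = field(default_factory=list)

    @property
    def is_bistable(self) -> bool:
        return (
            len(self.points) == 3
            and self.stability.count("stable") == 2
            and self.stability.count("saddle") == 1
        )

    def _single(self, label: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.stability) if s == label]
        if not idx:
            raise NonBistableError(f"no fixed point with stability '{label}'")
        return self.points[idx[-1]]

    @property
    def saddle(self) -> np.ndarray:
        return self._single("saddle")

    @property
    def high(self) -> np.ndarray:
        """The stable fixed point with the largest rho (the contractile state)."""
        stab = self.points[[i for i, s in enumerate(self.stability) if s == "stable"]]
        return stab[np.argmax(stab[:, 0])]

    @property
    def low(self) -> np.ndarray:
        stab = self.points[[i for i, s in enumerate(self.stability) if s == "stable"]]
        return stab[np.argmin(stab[:, 0])]


def hill(c, kappa: float, n: int):
    """Hill activation term c^n / (kappa^n + c^n), defined for c >= 0."""
    c = np.asarray(c, dtype=float)
    cn = c**n
    return cn / (kappa**n + cn)


def hill_deriv(c, kappa: float, n: int):
    """Derivative of the Hill term with respect to c."""
    c = np.asarray(c, dtype=float)
    kn = kappa**n
    return n * kn * c ** (n - 1) / (kn + c**n) ** 2


def reaction_rates(rho, m, p: KineticParams, *, rho_decay: float = 1.0, m_decay: float = 1.0):
    """Rates (d rho/dt, d m/dt) of the well-mixed feedback system.

    The optional decay factors multiply the linear dissociation terms only
    (used by the contractility-inhibition protocols); with factors of 1 the
    rates are exactly those of the base model.
    """
    rho = np.asarray(rho, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(rho < 0) or np.any(m < 0):
        raise ValueError("concentrations must be non-negative")
    d_rho = p.alpha * (hill(m, p.kappa1, p.n) - rho_decay * rho)
    d_m = p.alpha * (hill(rho, p.kappa2, p.n) - m_decay * m)
    return d_rho, d_m


def jacobian(rho: float, m: float, p: KineticParams,
             *, rho_decay: float = 1.0, m_decay: float = 1.0) -> np.ndarray:
    """Jacobian of the rate field at (rho, m)."""
    return p.alpha * np.array(
        [
            [-rho_decay, float(hill_deriv(m, p.kappa1, p.n))],
            [float(hill_deriv(rho, p.kappa2, p.n)), -m_decay],
        ]
    )


def _classify(eigvals: np.ndarray, tol: float = 1e-9) -> str:
    re = eigvals.real
    if np.any(np.abs(re) < tol):
        raise NonHyperbolicError(
            f"eigenvalue real part within {tol} of zero: {eigvals}; "
            "stability cannot be labelled reliably"
        )
    n_pos = int(np.sum(re > 0))
    return {0: "stable", 1: "saddle", 2: "unstable"}[n_pos]


def find_fixed_points(
    p: KineticParams,
    *,
    rho_decay: float = 1.0,
    m_decay: float = 1.0,
    span: float = 1.5,
    samples: int = 600,
    dedup_tol: float = 1e-6,
) -> FixedPointSet:
    """Locate all intersections of the two nullclines and label stability.

    Strategy: on the rho-nullcline, rho = H1(m)/rho_decay with
    m = H2(rho)/m_decay on the m-nullcline, so fixed points are roots of the
    scalar map F(rho) = H1(H2(rho)/m_decay)/rho_decay - rho.  F is sampled
    densely on [0, span]; each sign change is refined by Brent's method.
    The origin is always an exact root.  Roots closer than ``dedup_tol``
    are merged.
    """

    if p.alpha == 0:
        raise ValueError("fixed-point analysis requires alpha > 0 (frozen kinetics "
                         "have a continuum of steady states)")

    def F(r):
        mm = hill(r, p.kappa2, p.n) / m_decay
        return hill(mm, p.kappa1, p.n) / rho_decay - r

    rs = np.linspace(0.0, span, samples + 1)
    Fs = F(rs)
    roots = [0.0]
    # the origin is an exact root and F < 0 immediately above it (F'(0) = -1
    # for n >= 2); a very small kappa can place the saddle inside the first
    # sampling interval, so bracket (0+, rs[1]) explicitly
    tiny = 1e-9 * span
    if F(tiny) * Fs[1] < 0:
        roots.append(brentq(F, tiny, rs[1], xtol=1e-14, rtol=8.9e-16, maxiter=200))
    sign = np.sign(Fs)
    for i in range(len(rs) - 1):
        if sign[i] == 0 and rs[i] > 0:
            roots.append(rs[i])
        elif sign[i] * sign[i + 1] < 0:
            try:
                r = brentq(F, rs[i], rs[i + 1], xtol=1e-14, rtol=8.9e-16, maxiter=200)
            except Exception as exc:  # pragma: no cover - brentq is robust on a bracket
                raise RootFindingError(
                    f"root refinement failed on bracket [{rs[i]}, {rs[i + 1]}]"
                ) from exc
            roots.append(r)
    # deduplicate
    roots = sorted(roots)
    merged: list[float] = []
    for r in roots:
        if not merged or r - merged[-1] > dedup_tol:
            merged.append(r)
    pts = np.array([[r, float(hill(r, p.kappa2, p.n)) / m_decay] for r in merged])
    labels = [
        _classify(np.linalg.eigvals(jacobian(r, m, p, rho_decay=rho_decay, m_decay=m_decay)))
        for r, m in pts
    ]
    return FixedPointSet(points=pts, stability=labels)


def bistability_check(p: KineticParams, *, rho_decay: float = 1.0, m_decay: float = 1.0) -> bool:
    """True iff the system has two stable states separated by a saddle."""
    return find_fixed_points(p, rho_decay=rho_decay, m_decay=m_decay).is_bistable


def _rate_vec(y: np.ndarray, p: KineticParams) -> np.ndarray:
    # Rate field extended smoothly to slightly negative values (needed only
    # for manifold tracing, which may graze the axes).
    yc = np.clip(y, 0.0, None)
    d_rho = p.alpha * (hill(yc[1], p.kappa1, p.n) - y[0])
    d_m = p.alpha * (hill(yc[0], p.kappa2, p.n) - y[1])
    return np.array([d_rho, d_m])


def _trace_manifold(
    p: KineticParams,
    saddle: np.ndarray,
    direction: np.ndarray,
    *,
    backward: bool,
    offset: float = 1e-6,
    box=(-0.1, 2.0),
    t_max: float = 200.0,
) -> np.ndarray:
    sgn = -1.0 if backward else 1.0

    def rhs(t, y):
        return sgn * _rate_vec(y, p)

    def leave_box(t, y):
        return min(y.min() - box[0], box[1] - y.max())

    leave_box.terminal = True
    leave_box.direction = -1

    out = []
    for s in (+1.0, -1.0):
        y0 = saddle + s * offset * direction
        sol = solve_ivp(
            rhs,
            (0.0, t_max),
            y0,
            events=leave_box,
            rtol=1e-9,
            atol=1e-12,
            max_step=0.5,
            dense_output=False,
        )
        out.append(sol.y.T)
    # stitch: reversed minus-branch, saddle, plus-branch
    curve = np.vstack([out[1][::-1], saddle[None, :], out[0]])
    return curve


def _resample_arclength(curve: np.ndarray, n_points: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(curve[:1], n_points, axis=0)
    si = np.linspace(0.0, s[-1], n_points)
    return np.column_stack([np.interp(si, s, curve[:, k]) for k in range(2)])


def _saddle_eigvectors(p: KineticParams, saddle: np.ndarray):
    J = jacobian(saddle[0], saddle[1], p)
    w, V = np.linalg.eig(J)
    w, V = w.real, V.real
    stable_dir = V[:, np.argmin(w)]
    unstable_dir = V[:, np.argmax(w)]
    return stable_dir, unstable_dir


def separatrix(p: KineticParams, arc_points: int = 400) -> np.ndarray:
    """Stable manifold of the saddle: the basin boundary in the phase plane.

    Traced by backward-time integration from small offsets (1e-6) along the
    saddle's stable eigenvector, in both directions, terminated on leaving
    the box [-0.1, 2]^2; the two branches are stitched through the saddle
    and resampled uniformly in arc length to ``arc_points`` points.
    """
    fps = find_fixed_points(p)
    if not fps.is_bistable:
        raise NonBistableError("separatrix requires the bistable regime")
    saddle = fps.saddle
    stable_dir, _ = _saddle_eigvectors(p, saddle)
    curve = _trace_manifold(p, saddle, stable_dir, backward=True)
    return _resample_arclength(curve, arc_points)


def unstable_manifold(p: KineticParams, arc_points: int = 400) -> np.ndarray:
    """Unstable manifold of the saddle (forward-time heteroclinic connections
    to the two stable states)."""
    fps = find_fixed_points(p)
    if not fps.is_bistable:
        raise NonBistableError("unstable manifold requires the bistable regime")
    saddle = fps.saddle
    _, unstable_dir = _saddle_eigvectors(p, saddle)
    curve = _trace_manifold(p, saddle, unstable_dir, backward=False)
    return _resample_arclength(curve, arc_points)


def nullclines(p: KineticParams, samples: int = 400, span: float = 1.5):
    """Sampled nullclines as (rho_nullcline, m_nullcline) arrays of (rho, m).

    On the rho-nullcline rho = H1(m); on the m-nullcline m = H2(rho).
    """
    grid = np.linspace(0.0, span, samples)
    rho_nc = np.column_stack([hill(grid, p.kappa1, p.n), grid])
    m_nc = np.column_stack([grid, hill(grid, p.kappa2, p.n)])
    return rho_nc, m_nc


def classify_basin(p: KineticParams, points, sep: np.ndarray | None = None) -> list[str]:
    """Classify phase-plane points as "low" or "high" basin by which side of
    the separatrix they fall on.

    The side is measured by the cross product against the local tangent of
    the nearest separatrix vertex; the sign convention is calibrated with
    the high fixed point.
    """
    if sep is None:
        sep = separatrix(p)
    fps = find_fixed_points(p)
    high = fps.high

    tangents = np.gradient(sep, axis=0)

    def side(pt) -> float:
        d = np.linalg.norm(sep - pt, axis=1)
        i = int(np.argmin(d))
        t = tangents[i]
        r = np.asarray(pt) - sep[i]
        return float(t[0] * r[1] - t[1] * r[0])

    high_side = np.sign(side(high))
    labels = []
    for pt in np.atleast_2d(np.asarray(points, dtype=float)):
        labels.append("high" if np.sign(side(pt)) == high_side else "low")
    return labels


def export_phase_portrait(p: KineticParams, directory) -> dict[str, Path]:
    """Write nullclines, saddle manifolds and fixed points as plain CSV.

    Returns the mapping of table name to file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rho_nc, m_nc = nullclines(p)
    fps = find_fixed_points(p)
    tables = {
        "nullcline_rho": pd.DataFrame(rho_nc, columns=["rho", "m"]),
        "nullcline_m": pd.DataFrame(m_nc, columns=["rho", "m"]),
        "fixed_points": pd.DataFrame(
            {
                "rho": fps.points[:, 0],
                "m": fps.points[:, 1],
                "stability": fps.stability,
            }
        ),
    }
    if fps.is_bistable:
        tables["separatrix"] = pd.DataFrame(separatrix(p), columns=["rho", "m"])
        tables["unstable_manifold"] = pd.DataFrame(
            unstable_manifold(p), columns=["rho", "m"]
        )
    paths = {}
    for name, df in tables.items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
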