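"""Active-stress constitutive law and quasi-static cortical force balance.

The cortex is treated as a thin active fluid: viscous stress eta*dv/dx plus
a myosin-dependent active stress that saturates at high motor density,
balanced against friction with the substrate.  In non-dimensional units the
flow field solves the screened elliptic problem

    v - v'' = d/dx ( m / (K + m) )

where m is the NMIIA concentration field and K the half-saturation of the
active stress.  The operator (I - d2/dx2) is symmetric positive definite,
so the discrete problem (second-order central differences) is solved
directly: a banded Cholesky factorization for rigid walls (v = 0 at both
ends) or a prefactorized cyclic tridiagonal system on a ring.  Factors are
cached per grid, making the per-step solve O(n).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from dataclasses import dataclass

from .grid import Grid

__all__ = [
    "MechParams",
    "ADVECT_BOTH",
    "ADVECT_MYOSIN_ONLY",
    "active_stress",
    "solve_velocity",
    "solve_velocity_from_stress",
]

ADVECT_BOTH = "both"
ADVECT_MYOSIN_ONLY = "myosin_only"


@dataclass(frozen=True)
class MechParams:
    """Mechanical parameters of the contractile cortex.

    pe
        Peclet number: strength of contractile advection relative to
        diffusion (sigma_max / (gamma * D) in dimensional terms).
    K
        Non-dimensional half-saturation of the active stress in the NMIIA
        concentration.
    advection_mode
        "both": RhoA and NMIIA are both advected by the flow;
        "myosin_only": only the force-generating NMIIA is advected.
    """

    pe: float = 0.0
    K: float = 1.0
    advection_mode: str = ADVECT_BOTH

    def __post_init__(self) -> None:
        if self.pe < 0:
            raise ValueError(f"pe must be >= 0, got {self.pe}")
        if not self.K > 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if self.advection_mode not in (ADVECT_BOTH, ADVECT_MYOSIN_ONLY):
            raise ValueError(f"unknown advection_mode {self.advection_mode!r}")


def active_stress(m, K: float):
    """Saturating active stress m/(K+m); monotone in m and bounded by 1."""
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise ValueError("myosin concentration must be non-negative")
    return m / (K + m)


@lru_cache(maxsize=64)
def _dirichlet_cholesky(n_points: int, dx: float):
    # interior unknowns 1..n_points-2; upper banded form for cholesky_banded
    k = n_points - 2
    off = -1.0 / dx**2
    ab = np.zeros((2, k))
    ab[0, 1:] = off
    ab[1, :] = 1.0 + 2.0 / dx**2
    return sla.cholesky_banded(ab, lower=False)


@lru_cache(maxsize=64)
def _periodic_lu(n_points: int, dx: float):
    off = -1.0 / dx**2
    diag = 1.0 + 2.0 / dx**2
    A = sp.diags(
        [off, diag, off], [-1, 0, 1], shape=(n_points, n_points), format="lil"
    )
    A[0, -1] = off
    A[-1, 0] = off
    return spla.splu(A.tocsc())


def _stress_gradient(stress: np.ndarray, grid: Grid) -> np.ndarray:
    """Second-order central difference of the stress field."""
    if grid.periodic:
        return (np.roll(stress, -1) - np.roll(stress, 1)) / (2 * grid.dx)
    g = np.zeros_like(stress)
    g[1:-1] = (stress[2:] - stress[:-2]) / (2 * grid.dx)
    # walls: no-flux concentrations make the stress gradient vanish there;
    # the values are irrelevant anyway because v is pinned to 0.
    return g


def solve_velocity_from_stress(stress, grid: Grid) -> np.ndarray:
    """Solve v - v'' = d(stress)/dx for an arbitrary (active) stress field.

    Exposed separately so verification tests can substitute closed-form
    stresses (e.g. sin(qx) on a ring, for which v = q cos(qx)/(1+q^2)).
    """
    stress = np.asarray(stress, dtype=float)
    if stress.shape != (grid.n_points,):
        raise ValueError(
            f"stress shape {stress.shape} does not match grid ({grid.n_points},)"
        )
    g = _stress_gradient(stress, grid)
    if grid.periodic:
        lu = _periodic_lu(grid.n_points, grid.dx)
        return lu.solve(g)
    cb = _dirichlet_cholesky(grid.n_points, grid.dx)
    v = np.zeros_like(g)
    v[1:-1] = sla.cho_solve_banded((cb, False), g[1:-1])
    return v


def solve_velocity(m, grid: Grid, K: float) -> np.ndarray:
    """Cortical flow field generated by the NMIIA distribution ``m``.

    Solves the discrete force balance v - v'' = d/dx(m/(K+m)) exactly (direct
    banded solve).  A spatially uniform m produces v = 0 identically.
    """
    return solve_velocity_from_stress(active_stress(m, K), grid)
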