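"""Uniform 1D grid for the cortical domain.

Two boundary treatments are supported:

``noflux_rigid``
    A bounded junction segment: rigid walls (velocity pinned to zero at
    both ends) with no-flux conditions for the concentration fields.  The
    fields live on the ``n_cells + 1`` nodes of [0, length].
``periodic``
    A ring domain used mainly by verification tests; fields live on
    ``n_cells`` nodes, node ``n_cells`` identified with node 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "BC_NOFLUX_RIGID", "BC_PERIODIC"]

BC_NOFLUX_RIGID = "noflux_rigid"
BC_PERIODIC = "periodic"


@dataclass(frozen=True)
class Grid:
    length: float = 40.0
    n_cells: int = 400
    bc: str = BC_NOFLUX_RIGID

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.n_cells < 50:
            raise ValueError(f"n_cells must be >= 50, got {self.n_cells}")
        if self.bc not in (BC_NOFLUX_RIGID, BC_PERIODIC):
            raise ValueError(f"unknown boundary condition {self.bc!r}")

    @property
    def dx(self) -> float:
        return self.length / self.n_cells

    @property
    def n_points(self) -> int:
        """Number of field nodes (n_cells+1 for a bounded domain, n_cells on a ring)."""
        return self.n_cells + 1 if self.bc == BC_NOFLUX_RIGID else self.n_cells

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dx

    @property
    def periodic(self) -> bool:
        return self.bc == BC_PERIODIC

    def integrate(self, field: np.ndarray) -> float:
        """Integral of a nodal field over the domain (trapezoid on a bounded
        domain, Riemann sum on a ring)."""
        field = np.asarray(field)
        if self.periodic:
            return float(np.sum(field, axis=-1) * self.dx)
        return float(np.trapezoid(field, dx=self.dx, axis=-1))
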