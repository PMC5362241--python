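"""Initial conditions and time-triggered perturbation experiments.

``make_pulse`` builds the localized super-threshold activation pulse used
throughout: a centered top-hat (or Gaussian) of RhoA (optionally both
species) on an otherwise quiescent cortex.

``run_protocol`` mimics the contractility-inhibition experiments: at a
switch time the Peclet number is replaced (e.g. Pe -> 0, ROCK inhibition
switching contractility off) and the linear dissociation terms may be
scaled (e.g. a 2-fold increase of the NMIIA decay rate).  The decay factor
multiplies only the -alpha*c dissociation term, never the recruitment
term.  With identity settings the protocol run is bitwise identical to a
plain simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .grid import Grid
from .kinetics import KineticParams
from .mechanics import MechParams, solve_velocity
from .pde import SpaceTimeRecord, State, simulate

__all__ = ["PerturbationProtocol", "make_pulse", "run_protocol"]


@dataclass(frozen=True)
class PerturbationProtocol:
    """Parameter switch applied at ``t_switch``.

    After the switch the Peclet number becomes ``pe_after`` and the linear
    decay terms of NMIIA / RhoA are multiplied by the given factors.
    """

    t_switch: float
    pe_after: float
    nmiia_decay_factor: float = 1.0
    rho_decay_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.t_switch < 0:
            raise ValueError("t_switch must be >= 0")
        if self.nmiia_decay_factor <= 0 or self.rho_decay_factor <= 0:
            raise ValueError("decay factors must be positive")
        if self.pe_after < 0:
            raise ValueError("pe_after must be >= 0")


def make_pulse(
    grid: Grid,
    amplitude: float,
    half_width: float = 1.0,
    species: str = "rho",
    *,
    shape: str = "tophat",
    K: float = 1.0,
) -> State:
    """Centered localized activation pulse on a quiescent cortex.

    species: "rho" puts the pulse on RhoA only (NMIIA starts at zero);
    "both" ignites both fields.  The flow field is initialized consistently
    from the myosin field (zero for a "rho" pulse).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if not half_width < grid.length / 2:
        raise ValueError(
            f"half_width {half_width} must be smaller than the domain half-length "
            f"{grid.length / 2}"
        )
    if species not in ("rho", "both"):
        raise ValueError(f"species must be 'rho' or 'both', got {species!r}")
    x = grid.x
    center = grid.length / 2
    if shape == "tophat":
        profile = np.where(np.abs(x - center) <= half_width, float(amplitude), 0.0)
    elif shape == "gaussian":
        profile = amplitude * np.exp(-((x - center) ** 2) / (2 * half_width**2))
    else:
        raise ValueError(f"unknown pulse shape {shape!r}")
    rho = profile.copy()
    m = profile.copy() if species == "both" else np.zeros_like(profile)
    v = solve_velocity(m, grid, K)
    return State(rho=rho, m=m, v=v, t=0.0)


def run_protocol(
    init: State,
    kp: KineticParams,
    mp: MechParams,
    grid: Grid,
    protocol: PerturbationProtocol,
    t_end: float,
    record_every: float = 0.5,
) -> SpaceTimeRecord:
    """Simulate with base parameters until ``t_switch``, then with the
    perturbed parameters until ``t_end``; the record spans the switch.
    """
    if not protocol.t_switch < t_end:
        raise ValueError("t_switch must lie before t_end")

    seg1 = simulate(init, kp, mp, grid, protocol.t_switch, record_every)
    mp_after = replace(mp, pe=protocol.pe_after)
    seg2 = simulate(
        seg1.frame(seg1.n_frames - 1),
        kp,
        mp_after,
        grid,
        t_end,
        record_every,
        rho_decay=protocol.rho_decay_factor,
        m_decay=protocol.nmiia_decay_factor,
    )
    params = dict(seg1.params)
    params["protocol"] = {
        "t_switch": protocol.t_switch,
        "pe_after": protocol.pe_after,
        "nmiia_decay_factor": protocol.nmiia_decay_factor,
        "rho_decay_factor": protocol.rho_decay_factor,
    }
    params["t_end"] = t_end
    return SpaceTimeRecord(
        times=np.concatenate([seg1.times, seg2.times[1:]]),
        rho_xt=np.vstack([seg1.rho_xt, seg2.rho_xt[1:]]),
        m_xt=np.vstack([seg1.m_xt, seg2.m_xt[1:]]),
        v_xt=np.vstack([seg1.v_xt, seg2.v_xt[1:]]),
        grid=grid,
        params=params,
    )
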