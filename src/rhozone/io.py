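"""Run configuration, dimensional parameter mapping, persistence, render.

A run is declared in a single YAML mapping; unknown keys are rejected
(misspellings never fall back to silent defaults) and every output embeds
the full configuration echo so a record is sufficient to re-run itself.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .grid import Grid
from .kinetics import KineticParams
from .mechanics import MechParams
from .pde import SpaceTimeRecord
from .protocols import PerturbationProtocol

__all__ = [
    "NondimMap",
    "nondimensionalize",
    "PulseConfig",
    "RunConfig",
    "render_record",
]

log = logging.getLogger("rhozone")


@dataclass(frozen=True)
class NondimMap:
    """Dimensional cortex parameters and their non-dimensional images.

    eta: cortical viscosity; gamma: friction with the substrate; D:
    membrane diffusion coefficient; sigma_max: maximal active stress;
    Delta: half-saturation of the active stress in concentration units;
    s, k: cortical recruitment and dissociation rates.

    Derived units: length l = sqrt(eta/gamma), time tau = l^2/D,
    concentration s/k.  Non-dimensional groups: Pe = sigma_max/(gamma*D),
    K = Delta*k/s, and alpha = k*eta/(gamma*D) — the ratio of the diffusion
    time tau to the reaction time 1/k.
    """

    eta: float
    gamma: float
    D: float
    sigma_max: float
    Delta: float
    s: float
    k: float

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if f.name == "sigma_max":
                if val < 0:
                    raise ValueError("sigma_max must be >= 0")
            elif not val > 0:
                raise ValueError(f"{f.name} must be positive, got {val}")

    @property
    def unit_length(self) -> float:
        return float(np.sqrt(self.eta / self.gamma))

    @property
    def unit_time(self) -> float:
        return self.unit_length**2 / self.D

    @property
    def unit_concentration(self) -> float:
        return self.s / self.k

    @property
    def pe(self) -> float:
        return self.sigma_max / (self.gamma * self.D)

    @property
    def K(self) -> float:
        return self.Delta * self.k / self.s

    @property
    def alpha(self) -> float:
        return self.k * self.eta / (self.gamma * self.D)


def nondimensionalize(dim: NondimMap) -> tuple[float, float, float]:
    """(alpha, Pe, K) from dimensional cortex parameters.

    alpha = k*eta/(gamma*D) is used: the ratio of the diffusion time
    eta/(gamma*D) to the reaction time 1/k, which is the group that
    multiplies the kinetics in the non-dimensional equations.  The formula
    is logged so the adopted reading is always explicit.
    """
    alpha, pe, K = dim.alpha, dim.pe, dim.K
    log.info(
        "nondimensionalize: alpha = k*eta/(gamma*D) = %g, Pe = sigma_max/(gamma*D) = %g, "
        "K = Delta*k/s = %g",
        alpha,
        pe,
        K,
    )
    return alpha, pe, K


@dataclass(frozen=True)
class PulseConfig:
    """Initial activation pulse. amplitude "high" means the high fixed
    point of the kinetics."""

    amplitude: float | str = "high"
    half_width: float = 1.0
    species: str = "rho"
    shape: str = "tophat"


def _from_mapping(cls, mapping: dict, context: str):
    if not isinstance(mapping, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(
            f"{context}: unknown key(s) {sorted(unknown)}; known keys: {sorted(known)}"
        )
    return cls(**mapping)


@dataclass
class RunConfig:
    """Full declaration of a simulation run (YAML round-trippable)."""

    kinetics: KineticParams = field(default_factory=KineticParams)
    mech: MechParams = field(default_factory=MechParams)
    grid: Grid = field(default_factory=Grid)
    pulse: PulseConfig = field(default_factory=PulseConfig)
    protocol: PerturbationProtocol | None = None
    t_end: float = 200.0
    record_every: float = 0.5
    seed: int = 0  # used only by the synthetic-kymograph generator

    _SECTIONS = {
        "kinetics": KineticParams,
        "mech": MechParams,
        "grid": Grid,
        "pulse": PulseConfig,
        "protocol": PerturbationProtocol,
    }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"config: unknown key(s) {sorted(unknown)}; known keys: {sorted(known)}"
            )
        kwargs = {}
        for key, val in raw.items():
            if key in cls._SECTIONS and val is not None:
                kwargs[key] = _from_mapping(cls._SECTIONS[key], val, key)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        d = {
            "kinetics": asdict(self.kinetics),
            "mech": asdict(self.mech),
            "grid": asdict(self.grid),
            "pulse": asdict(self.pulse),
            "protocol": asdict(self.protocol) if self.protocol else None,
            "t_end": self.t_end,
            "record_every": self.record_every,
            "seed": self.seed,
        }
        return d

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)
        return path


def render_record(rec: SpaceTimeRecord, path, *, species: str = "rho", cmap: str = "viridis"):
    """Space-time PNG of a record: x horizontal, t vertical (idempotent)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    field_ = {"rho": rec.rho_xt, "m": rec.m_xt, "v": rec.v_xt}[species]
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        field_,
        aspect="auto",
        origin="lower",
        extent=[0, rec.grid.length, rec.times[0], rec.times[-1]],
        cmap=cmap,
    )
    ax.set_xlabel("x (length units)")
    ax.set_ylabel("t (time units)")
    label = {"rho": "[RhoA]", "m": "[NMIIA]", "v": "v"}[species]
    fig.colorbar(im, ax=ax, label=label)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
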