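"""Simulation configuration: the single source of truth for a run.

All tunable quantities of the gene-environment-phenotype model live here:
the genetic architecture (minor allele frequency ``maf``, effect-size
concentration ``psi``, total additive effect ``alpha``), the environmental
couplings (``epsilon`` static, ``delta`` dynamic, ``gamma`` gene-by-environment),
the GxE activation exponent ``xi`` and per-SNP interaction probability
``upsilon``, the attraction of dynamic environments to the phenotype
(``beta_range``), damping coefficients, system sizes, and the integration
grid.  Defaults are the reference parameterization of the model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the dynamical gene-environment-phenotype model.

    Attributes
    ----------
    maf
        Minor allele frequency pi shared by all loci, in (0, 1).
    psi
        Concentration of SNP effect sizes; 0 gives uniform effects, larger
        values concentrate the total additive effect on fewer SNPs.
    alpha
        Total additive genetic attraction of the phenotype to the allelic
        values (the per-SNP strengths Lambda_i are normalized to sum to one
        before scaling by ``alpha``).
    epsilon
        Attraction to static environmental factors (divided by ``n_static``).
    delta
        Attraction to dynamic environmental factors (divided by ``n_dyn``).
    gamma
        Total gene-by-environment (GxE) effect; the activation weights are
        renormalized at every instant so ``gamma`` is the total GxE force scale.
    xi
        GxE activation exponent: activation grows as the inverse ``xi``-th
        power of the SNP-environment distance.
    upsilon
        Probability that a given SNP interacts with a given dynamic
        environment.
    beta_range
        Interval from which each dynamic environment's attraction to the
        phenotype, beta_h, is drawn uniformly.
    zeta_p
        Phenotype damping ("aging") coefficient; must be <= 0.  ``None``
        resolves to the default ``-2 * epsilon``.
    zeta_d
        Dynamic-environment damping coefficient; ``None`` (default) resolves
        per environment to ``-0.2 * beta_h``.
    n_snps, n_dyn, n_static
        Numbers of SNPs, dynamic environments, and static environmental
        factors.
    t_end, dt, record_every
        Integration horizon, fixed Runge-Kutta step, and the spacing of
        recorded time points.  ``dt`` must divide ``record_every``.
    dist_floor
        Minimum SNP-environment distance used inside the GxE activation,
        preventing the inverse-power singularity.
    seed
        Default RNG seed for operations that are not handed one explicitly.
    """

    maf: float = 0.5
    psi: float = 50.0
    alpha: float = 0.05
    epsilon: float = 0.05
    delta: float = 0.05
    gamma: float = 0.05
    xi: float = 10.0
    upsilon: float = 0.1
    beta_range: tuple[float, float] = (0.0175, 0.0325)
    zeta_p: float | None = None
    zeta_d: float | None = None
    n_snps: int = 1000
    n_dyn: int = 1
    n_static: int = 1000
    t_end: float = 250.0
    dt: float = 0.1
    record_every: float = 1.0
    dist_floor: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.maf < 1.0:
            raise ConfigError(f"maf must be in (0, 1), got {self.maf}")
        for name in ("psi", "alpha", "epsilon", "delta", "gamma"):
            v = getattr(self, name)
            if v < 0:
                raise ConfigError(f"{name} must be >= 0, got {v}")
        if self.xi <= 0:
            raise ConfigError(f"xi must be > 0, got {self.xi}")
        if not 0.0 <= self.upsilon <= 1.0:
            raise ConfigError(f"upsilon must be in [0, 1], got {self.upsilon}")
        lo, hi = self.beta_range
        if not (0 <= lo <= hi):
            raise ConfigError(f"beta_range must satisfy 0 <= lo <= hi, got {self.beta_range}")
        self.beta_range = (float(lo), float(hi))
        if self.zeta_p is None:
            self.zeta_p = -2.0 * self.epsilon
        if self.zeta_p > 0:
            raise ConfigError(f"zeta_p must be <= 0 (damping), got {self.zeta_p}")
        if self.zeta_d is not None and self.zeta_d > 0:
            raise ConfigError(f"zeta_d must be <= 0 (damping), got {self.zeta_d}")
        if self.n_snps < 1 or self.n_dyn < 1:
            raise ConfigError("n_snps and n_dyn must be >= 1")
        if self.n_static < 0:
            raise ConfigError("n_static must be >= 0")
        if not (0 < self.dt < self.record_every <= self.t_end):
            raise ConfigError(
                f"need 0 < dt < record_every <= t_end, got dt={self.dt}, "
                f"record_every={self.record_every}, t_end={self.t_end}"
            )
        ratio = self.record_every / self.dt
        if abs(ratio - round(ratio)) > 1e-9 * ratio:
            raise ConfigError("dt must divide record_every")
        if self.dist_floor <= 0:
            raise ConfigError(f"dist_floor must be > 0, got {self.dist_floor}")

    # ---- derived grid quantities -------------------------------------------------

    @property
    def steps_per_record(self) -> int:
        return int(round(self.record_every / self.dt))

    @property
    def n_recorded(self) -> int:
        """Number of recorded time points, including t = 0."""
        return int(round(self.t_end / self.record_every)) + 1

    def zeta_d_for(self, beta_h: float) -> float:
        """Damping coefficient of a dynamic environment with attraction beta_h."""
        return self.zeta_d if self.zeta_d is not None else -0.2 * beta_h

    # ---- (de)serialization -------------------------------------------------------

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["beta_range"] = list(self.beta_range)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "beta_range" in d and d["beta_range"] is not None:
            d["beta_range"] = tuple(d["beta_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from a YAML or JSON document."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)
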