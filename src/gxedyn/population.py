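"""Cohort assembly: unrelated samples, twin pairs, and related-pair designs.

A cohort combines one population-level trait architecture (the SNP strength
vector and, for unrelated designs, a single shared GxE assignment), fresh
genomes and environments per individual, and vectorized integration to the
terminal phenotype.  Randomness is organized as one child seed stream per
individual (spawned deterministically from the cohort seed), so the cohort is
a pure function of (config, n, seed) and per-individual draws are independent
of execution order.

In the related-pairs design the two members of a pair share the dynamic
environment's properties (beta, initial position and velocity) and the GxE
assignment (s, l), representing a familial environment interacting with
shared genes, while static environments and phenotype starting values remain
individual.  Nothing is shared between pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import SimulationConfig
from .dynamics import CohortEnvironments, EnvironmentSpec, integrate_cohort
from .genome import (
    GeneArchitecture,
    sample_genome,
    sample_related_genome,
    write_genotypes_tsv,
)


@dataclass
class Cohort:
    """Analysis-ready sample: genotypes, terminal phenotypes, and metadata."""

    genotypes: np.ndarray  # (n, n_snps) int8
    phenotypes: np.ndarray  # (n,)
    config: SimulationConfig
    seed: int | None = None
    times: np.ndarray | None = None
    p_series: np.ndarray | None = None  # (n, n_recorded) if recorded
    pair_index: np.ndarray | None = None  # pair label per individual
    relatedness: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def __post_init__(self) -> None:
        if self.genotypes.shape[0] != self.phenotypes.shape[0]:
            raise ValueError("genotypes and phenotypes disagree on n")
        if not np.all(np.isfinite(self.phenotypes)):
            raise ValueError("non-finite phenotypes in cohort")
        if self.pair_index is not None:
            _, counts = np.unique(self.pair_index, return_counts=True)
            if not np.all(counts == 2):
                raise ValueError("each pair label must appear exactly twice")

    def subset(self, idx: np.ndarray) -> "Cohort":
        return Cohort(
            genotypes=self.genotypes[idx],
            phenotypes=self.phenotypes[idx],
            config=self.config,
            seed=self.seed,
            times=self.times,
            p_series=None if self.p_series is None else self.p_series[idx],
            pair_index=None if self.pair_index is None else self.pair_index[idx],
            relatedness=self.relatedness,
            meta=self.meta,
        )

    def to_dir(self, out_dir) -> None:
        """Write genotypes TSV, phenotypes TSV, and run-metadata JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genotypes_tsv(out / "genotypes.tsv", self.genotypes)
        with open(out / "phenotypes.tsv", "w") as fh:
            fh.write("id\tphenotype\tpair_id\trelatedness\n")
            for i in range(self.n):
                pair = "" if self.pair_index is None else str(int(self.pair_index[i]))
                rel = "" if self.relatedness is None else f"{self.relatedness:g}"
                fh.write(f"ind_{i + 1}\t{self.phenotypes[i]:.10g}\t{pair}\t{rel}\n")
        meta = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "n": self.n,
            "relatedness": self.relatedness,
        }
        (out / "run_meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def _spawn(seed, k: int) -> list[np.random.Generator]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(c) for c in ss.spawn(k)]


def simulate_cohort(
    cfg: SimulationConfig, n: int, seed=None, record_series: bool = True
) -> Cohort:
    """Simulate ``n`` independent individuals under a shared trait architecture.

    The SNP strengths and the GxE assignment (s, l) are drawn once per cohort:
    the architecture is a property of the trait, so association and
    heritability analyses across individuals are meaningful.  Genomes,
    environments, and initial conditions are drawn independently per
    individual; relatedness occurs only by chance (identity by state).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if seed is None:
        seed = cfg.seed
    arch_rng, *ind_rngs = _spawn(seed, n + 1)
    arch = GeneArchitecture.from_config(cfg, arch_rng)
    G = np.empty((n, cfg.n_snps), dtype=np.int8)
    specs = []
    for i, rng in enumerate(ind_rngs):
        G[i] = sample_genome(cfg.n_snps, cfg.maf, rng)
        specs.append(EnvironmentSpec.draw(cfg, rng))
    envs = CohortEnvironments.from_specs(specs)
    times, p_series = integrate_cohort(G, arch, envs, cfg, record=record_series)
    return Cohort(
        genotypes=G,
        phenotypes=p_series[:, -1].copy(),
        config=cfg,
        seed=seed if isinstance(seed, int) else None,
        times=times if record_series else None,
        p_series=p_series if record_series else None,
        meta={"arch": arch, "beta": envs.beta, "p0": envs.p0, "d0": envs.d0},
    )


def simulate_twin_pair(
    cfg: SimulationConfig,
    zygosity: str = "MZ",
    share_environment: bool = False,
    seed=None,
) -> Cohort:
    """Simulate one twin pair.

    MZ twins share the full genome; DZ twins are related at 0.5 by allele
    copying.  Initial conditions (p(0), d(0)) are always shared.  With
    ``share_environment=False`` each twin draws its own dynamic-environment
    attraction strengths beta_h and its own GxE assignment s — the setting in
    which genetically identical twins can diverge, one settling to a fixed
    point while the other locks into a limit cycle.  With ``True``, beta,
    d(0), s, and l are all shared (the familial-environment regime).
    """
    if zygosity not in ("MZ", "DZ"):
        raise ValueError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    shared_rng, rng1, rng2 = _spawn(cfg.seed if seed is None else seed, 3)
    arch = GeneArchitecture.from_config(cfg, shared_rng)

    g1 = sample_genome(cfg.n_snps, cfg.maf, shared_rng)
    g2 = g1.copy() if zygosity == "MZ" else sample_related_genome(g1, 0.5, cfg.maf, shared_rng)
    G = np.stack([g1, g2])

    base_env = EnvironmentSpec.draw(cfg, shared_rng)
    s_stack = None
    l_stack = None
    if share_environment:
        specs = [base_env, base_env]
    else:
        specs = []
        s_list = []
        for rng in (rng1, rng2):
            beta = rng.uniform(*cfg.beta_range, size=cfg.n_dyn)
            specs.append(
                EnvironmentSpec(
                    beta=beta,
                    e=base_env.e,
                    d0=base_env.d0,
                    d0_vel=base_env.d0_vel,
                    p0=base_env.p0,
                    p0_vel=base_env.p0_vel,
                )
            )
            s_list.append((rng.random((cfg.n_snps, cfg.n_dyn)) < cfg.upsilon).astype(np.int8))
        s_stack = np.stack(s_list)
        l_stack = np.stack([arch.l, arch.l])

    envs = CohortEnvironments.from_specs(specs)
    times, p_series = integrate_cohort(G, arch, envs, cfg, s=s_stack, l=l_stack)
    return Cohort(
        genotypes=G,
        phenotypes=p_series[:, -1].copy(),
        config=cfg,
        seed=seed if isinstance(seed, int) else None,
        times=times,
        p_series=p_series,
        pair_index=np.array([0, 0]),
        relatedness=1.0 if zygosity == "MZ" else 0.5,
        meta={"arch": arch, "zygosity": zygosity, "share_environment": share_environment},
    )


def simulate_related_cohort(
    cfg: SimulationConfig,
    n_pairs: int,
    relatedness: float,
    seed=None,
    record_series: bool = False,
) -> Cohort:
    """Simulate ``n_pairs`` pairs of relatives sharing genes and environment.

    Within each pair: the second genome copies a proportion ``relatedness``
    of the first's alleles; the dynamic environment's attraction strengths,
    initial positions and velocities, and the GxE assignment (s, l) are
    shared.  Static environmental loci and phenotype initial values are
    individual.  Across pairs everything is independent.
    """
    if not 0.0 <= relatedness <= 1.0:
        raise ValueError(f"relatedness must be in [0, 1], got {relatedness}")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    arch_rng, *pair_rngs = _spawn(cfg.seed if seed is None else seed, n_pairs + 1)
    lam_arch = GeneArchitecture.from_config(cfg, arch_rng)

    n = 2 * n_pairs
    G = np.empty((n, cfg.n_snps), dtype=np.int8)
    s_stack = np.empty((n, cfg.n_snps, cfg.n_dyn), dtype=np.int8)
    l_stack = np.empty((n, cfg.n_snps, cfg.n_dyn), dtype=np.int8)
    specs = []
    pair_index = np.repeat(np.arange(n_pairs), 2)
    for j, rng in enumerate(pair_rngs):
        g1 = sample_genome(cfg.n_snps, cfg.maf, rng)
        g2 = sample_related_genome(g1, relatedness, cfg.maf, rng)
        G[2 * j], G[2 * j + 1] = g1, g2
        s_pair = (rng.random((cfg.n_snps, cfg.n_dyn)) < cfg.upsilon).astype(np.int8)
        l_pair = rng.integers(0, 3, size=(cfg.n_snps, cfg.n_dyn)).astype(np.int8)
        s_stack[2 * j] = s_stack[2 * j + 1] = s_pair
        l_stack[2 * j] = l_stack[2 * j + 1] = l_pair
        beta = rng.uniform(*cfg.beta_range, size=cfg.n_dyn)
        d0 = rng.uniform(0.0, 2.0, size=cfg.n_dyn)
        for _ in range(2):  # individual-level p0 and static environment
            p0 = float(rng.uniform(0.0, 2.0))
            e = rng.uniform(0.0, 2.0, size=cfg.n_static)
            specs.append(
                EnvironmentSpec(
                    beta=beta, e=e, d0=d0, d0_vel=np.zeros(cfg.n_dyn), p0=p0, p0_vel=0.0
                )
            )
    envs = CohortEnvironments.from_specs(specs)
    times, p_series = integrate_cohort(
        G, lam_arch, envs, cfg, s=s_stack, l=l_stack, record=record_series
    )
    return Cohort(
        genotypes=G,
        phenotypes=p_series[:, -1].copy(),
        config=cfg,
        seed=seed if isinstance(seed, int) else None,
        times=times if record_series else None,
        p_series=p_series if record_series else None,
        pair_index=pair_index,
        relatedness=relatedness,
        meta={"arch": lam_arch},
    )


def within_pair_correlation(cohort: Cohort) -> float:
    """Pearson correlation of phenotypes across the two members of each pair."""
    if cohort.pair_index is None:
        raise ValueError("cohort has no pair structure")
    order = np.argsort(cohort.pair_index, kind="stable")
    y = cohort.phenotypes[order].reshape(-1, 2)
    return float(np.corrcoef(y[:, 0], y[:, 1])[0, 1])
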