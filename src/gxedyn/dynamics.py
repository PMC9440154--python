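"""The coupled phenotype-environment differential equations and their integration.

The phenotype p(t) moves in a one-dimensional space of possible phenotypic
values under five forces (all "gravitational" attractions except the last):

* additive genetic:   (alpha / A) * sum_i Lambda_i (g_i - p)
* gene-by-environment: (gamma / B(t)) * sum_{i,h} Gamma_{h,i}(t) (l_{h,i} - p)
* dynamic environment: (delta / N_d) * sum_h (d_h - p)
* static environment:  (epsilon / N_e) * sum_j (e_j - p)
* viscous damping:     zeta_p * dp/dt

where the GxE activation Gamma_{h,i}(t) = s_{i,h} / |g_i - d_h(t)|^xi grows as
an interacting dynamic environment approaches the SNP's allelic value, and
B(t) = sum Gamma normalizes the total GxE force to scale gamma.  Each dynamic
environment is in turn attracted to the phenotype (gene-environment
correlation): d''_h = beta_h (p - d_h) + zeta_d * d'_h.

Integration is fixed-step classical Runge-Kutta (RK4) so trajectories are
bit-reproducible at a given step size.  Two equivalent evaluation routes are
provided: a literal per-SNP summation (``system_derivatives``) and a fast
cohort-vectorized route (``integrate_cohort``) that collapses the per-SNP sums
into three sufficient statistics per (individual, environment) pair, exploiting
g_i in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .genome import GeneArchitecture, as_generator

ALLELE_VALUES = np.array([0.0, 1.0, 2.0])


class IntegrationError(RuntimeError):
    """Raised when a trajectory diverges to non-finite values."""


# ---- per-individual containers ---------------------------------------------------


@dataclass
class EnvironmentSpec:
    """One individual's environmental system and initial conditions."""

    beta: np.ndarray  # (n_dyn,) attraction of each dynamic environment to p
    e: np.ndarray  # (n_static,) static environmental loci in phenotype space
    d0: np.ndarray  # (n_dyn,) initial dynamic-environment positions
    d0_vel: np.ndarray  # (n_dyn,) initial velocities
    p0: float = 0.0
    p0_vel: float = 0.0

    @classmethod
    def draw(cls, cfg: SimulationConfig, seed=None) -> "EnvironmentSpec":
        """Random environment: p(0), d(0), e_j ~ U(0, 2) (the span of allelic
        values), velocities zero, beta_h ~ U(beta_range)."""
        rng = as_generator(seed)
        p0 = float(rng.uniform(0.0, 2.0))
        d0 = rng.uniform(0.0, 2.0, size=cfg.n_dyn)
        beta = rng.uniform(*cfg.beta_range, size=cfg.n_dyn)
        e = rng.uniform(0.0, 2.0, size=cfg.n_static)
        return cls(beta=beta, e=e, d0=d0, d0_vel=np.zeros(cfg.n_dyn), p0=p0, p0_vel=0.0)


@dataclass
class SystemState:
    """Instantaneous state (p, dp/dt, d_h, dd_h/dt) at time t."""

    p: float
    p_vel: float
    d: np.ndarray
    d_vel: np.ndarray
    t: float = 0.0


@dataclass
class Trajectory:
    """Recorded time series of one individual's system."""

    times: np.ndarray  # (n_rec,)
    p: np.ndarray  # (n_rec,)
    d: np.ndarray  # (n_rec, n_dyn)
    b: np.ndarray | None = None  # (n_rec,) GxE normalizer B(t), if recorded

    def to_tsv(self, path) -> None:
        n_dyn = self.d.shape[1]
        cols = [self.times, self.p] + [self.d[:, h] for h in range(n_dyn)]
        header = ["time", "p"] + [f"d_{h + 1}" for h in range(n_dyn)]
        if self.b is not None:
            cols.append(self.b)
            header.append("B")
        np.savetxt(
            path, np.column_stack(cols), delimiter="\t", header="\t".join(header), comments=""
        )


# ---- force terms -----------------------------------------------------------------


def gxe_activation(g, d, s, xi: float, dist_floor: float):
    """GxE activation Gamma = s / max(|g - d|, dist_floor)^xi.

    Zero wherever s = 0; the distance floor prevents the singularity as a
    dynamic environment crosses an interacting SNP's allelic value.
    Accepts scalars or broadcastable arrays.
    """
    if xi <= 0:
        raise ValueError(f"xi must be > 0, got {xi}")
    if dist_floor <= 0:
        raise ValueError(f"dist_floor must be > 0, got {dist_floor}")
    dist = np.maximum(np.abs(np.asarray(g, dtype=float) - d), dist_floor)
    return np.asarray(s) * dist**-xi


def system_derivatives(
    state: SystemState,
    genome: np.ndarray,
    arch: GeneArchitecture,
    env: EnvironmentSpec,
    cfg: SimulationConfig,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Literal evaluation of the model's accelerations at one state.

    Returns (dp/dt, d2p/dt2, dd/dt, d2d/dt2).  The GxE term is defined as
    exactly zero when B(t) = 0 (no active interaction).  This is the reference
    route: it sums over every SNP explicitly and is used to validate the
    vectorized cohort integrator.
    """
    p, pv, d, dv = state.p, state.p_vel, np.asarray(state.d, float), np.asarray(state.d_vel, float)
    if not (np.isfinite(p) and np.isfinite(pv) and np.all(np.isfinite(d)) and np.all(np.isfinite(dv))):
        raise IntegrationError(f"non-finite state at t={state.t}")
    g = np.asarray(genome, dtype=float)

    p_acc = (cfg.alpha / arch.A) * float(np.sum(arch.lambda_ * (g - p)))

    if cfg.gamma > 0:
        gamma_hi = gxe_activation(g[:, None], d[None, :], arch.s, cfg.xi, cfg.dist_floor)
        B = float(gamma_hi.sum())
        if B > 0:
            p_acc += (cfg.gamma / B) * float(np.sum(gamma_hi * (arch.l - p)))

    p_acc += (cfg.delta / cfg.n_dyn) * float(np.sum(d - p))
    if cfg.n_static > 0:
        p_acc += (cfg.epsilon / cfg.n_static) * float(np.sum(env.e - p))
    p_acc += cfg.zeta_p * pv

    zeta_d = np.array([cfg.zeta_d_for(b) for b in env.beta])
    d_acc = env.beta * (p - d) + zeta_d * dv
    return pv, p_acc, dv, d_acc


# ---- single-individual integration ----------------------------------------------


def integrate_individual(
    genome: np.ndarray,
    arch: GeneArchitecture,
    env: EnvironmentSpec,
    cfg: SimulationConfig,
    record_b: bool = True,
) -> Trajectory:
    """Integrate one individual's system with fixed-step RK4 over [0, t_end].

    The second-order system is reformulated as first order in
    (p, dp/dt, d_h, dd_h/dt) and sampled every ``record_every`` time units.
    Deterministic given its inputs.
    """
    g = np.asarray(genome, dtype=float)
    n_rec = cfg.n_recorded
    spr = cfg.steps_per_record
    dt = cfg.dt

    times = np.arange(n_rec) * cfg.record_every
    p_out = np.empty(n_rec)
    d_out = np.empty((n_rec, cfg.n_dyn))
    b_out = np.empty(n_rec) if record_b else None

    def deriv(p, pv, d, dv):
        st = SystemState(p=p, p_vel=pv, d=d, d_vel=dv)
        return system_derivatives(st, g, arch, env, cfg)

    def b_of(d):
        if cfg.gamma <= 0:
            return 0.0
        return float(gxe_activation(g[:, None], d[None, :], arch.s, cfg.xi, cfg.dist_floor).sum())

    p, pv = float(env.p0), float(env.p0_vel)
    d, dv = np.array(env.d0, dtype=float), np.array(env.d0_vel, dtype=float)

    for k in range(n_rec):
        p_out[k] = p
        d_out[k] = d
        if record_b:
            b_out[k] = b_of(d)
        if k == n_rec - 1:
            break
        for _ in range(spr):
            k1 = deriv(p, pv, d, dv)
            k2 = deriv(p + 0.5 * dt * k1[0], pv + 0.5 * dt * k1[1], d + 0.5 * dt * k1[2], dv + 0.5 * dt * k1[3])
            k3 = deriv(p + 0.5 * dt * k2[0], pv + 0.5 * dt * k2[1], d + 0.5 * dt * k2[2], dv + 0.5 * dt * k2[3])
            k4 = deriv(p + dt * k3[0], pv + dt * k3[1], d + dt * k3[2], dv + dt * k3[3])
            p += (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            pv += (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            d = d + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            dv = dv + (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if not (np.isfinite(p) and np.isfinite(pv) and np.all(np.isfinite(d))):
            raise IntegrationError(f"trajectory diverged near t={times[k] + cfg.record_every:g}")

    return Trajectory(times=times, p=p_out, d=d_out, b=b_out)


# ---- vectorized cohort integration ----------------------------------------------


@dataclass
class CohortEnvironments:
    """Stacked per-individual environments for the vectorized integrator.

    Only the mean of the static loci enters the dynamics (the static force is
    epsilon * (mean(e) - p)), so ``e_mean`` is stored instead of the full loci.
    """

    beta: np.ndarray  # (n, n_dyn)
    e_mean: np.ndarray  # (n,)
    d0: np.ndarray  # (n, n_dyn)
    d0_vel: np.ndarray  # (n, n_dyn)
    p0: np.ndarray  # (n,)
    p0_vel: np.ndarray  # (n,)

    @classmethod
    def from_specs(cls, specs: list[EnvironmentSpec]) -> "CohortEnvironments":
        return cls(
            beta=np.array([sp.beta for sp in specs]),
            e_mean=np.array([sp.e.mean() if sp.e.size else 0.0 for sp in specs]),
            d0=np.array([sp.d0 for sp in specs]),
            d0_vel=np.array([sp.d0_vel for sp in specs]),
            p0=np.array([sp.p0 for sp in specs]),
            p0_vel=np.array([sp.p0_vel for sp in specs]),
        )


def gxe_sufficient_stats(
    genotypes: np.ndarray, s: np.ndarray, l: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse per-SNP GxE sums into per-allele-class counts.

    Because g_i takes only the values 0, 1, 2, and the activation depends on
    g_i only through |g_i - d_h|, the per-SNP sums in the GxE force reduce to
    sums over the three allele classes:

        B(t)      = sum_h sum_k w_kh(t) * nk[:, h, k]
        numerator = sum_h sum_k w_kh(t) * lk[:, h, k]

    with w_kh(t) = 1 / max(|k - d_h(t)|, floor)^xi.  Returns ``nk`` (count of
    interacting SNPs with g = k) and ``lk`` (sum of their attractor loci l),
    both shaped (n, n_dyn, 3).  ``s`` and ``l`` may be shared (n_snps, n_dyn)
    or per-individual (n, n_snps, n_dyn).
    """
    G = np.asarray(genotypes)
    n = G.shape[0]
    n_dyn = s.shape[-1]
    nk = np.empty((n, n_dyn, 3))
    lk = np.empty((n, n_dyn, 3))
    for k in range(3):
        ind = (G == k).astype(np.float64)  # (n, n_snps)
        if s.ndim == 2:
            nk[:, :, k] = ind @ s.astype(np.float64)
            lk[:, :, k] = ind @ (s * l).astype(np.float64)
        else:
            nk[:, :, k] = np.einsum("ni,nih->nh", ind, s.astype(np.float64))
            lk[:, :, k] = np.einsum("ni,nih->nh", ind, (s * l).astype(np.float64))
    return nk, lk


def integrate_cohort(
    genotypes: np.ndarray,
    arch: GeneArchitecture,
    envs: CohortEnvironments,
    cfg: SimulationConfig,
    s=None,
    l=None,
    record: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many individuals simultaneously.

    Numerically identical to running :func:`integrate_individual` per row
    (same RK4 scheme, same step size); the per-SNP sums are replaced by the
    exact allele-class reduction of :func:`gxe_sufficient_stats`.

    Parameters
    ----------
    s, l
        Optional per-individual GxE structure shaped (n, n_snps, n_dyn)
        overriding the shared ``arch.s`` / ``arch.l`` (used when interaction
        assignments differ across pairs in a related-pairs design).
    record
        If True, return the full (n, n_recorded) phenotype series; otherwise
        only the terminal column is recorded (faster on memory, same values).

    Returns
    -------
    times, p_series
        The recorded grid and phenotype values, (n_recorded,) and
        (n, n_recorded) — or (1,) and (n, 1) when ``record`` is False.
    """
    G = np.asarray(genotypes, dtype=np.int8)
    n = G.shape[0]
    gbar = (G.astype(np.float64) @ arch.lambda_) / arch.A  # Lambda-weighted mean genotype

    use_gxe = cfg.gamma > 0
    if use_gxe:
        s_eff = arch.s if s is None else s
        l_eff = arch.l if l is None else l
        nk, lk = gxe_sufficient_stats(G, s_eff, l_eff)

    alpha, gamma, delta, eps = cfg.alpha, cfg.gamma, cfg.delta, cfg.epsilon
    zeta_p = cfg.zeta_p
    beta = envs.beta
    zeta_d = np.full_like(beta, cfg.zeta_d) if cfg.zeta_d is not None else -0.2 * beta
    ebar = envs.e_mean if cfg.n_static > 0 else None
    floor, xi = cfg.dist_floor, cfg.xi
    k_vals = ALLELE_VALUES[None, None, :]  # (1, 1, 3)

    def deriv(p, pv, d, dv):
        acc = alpha * (gbar - p)
        if use_gxe:
            w = np.maximum(np.abs(k_vals - d[:, :, None]), floor) ** -xi  # (n, n_dyn, 3)
            B = np.einsum("nhk,nhk->n", w, nk)
            num = np.einsum("nhk,nhk->n", w, lk)
            active = B > 0
            gxe = np.zeros(n)
            gxe[active] = gamma * (num[active] / B[active] - p[active])
            acc += gxe
        acc += delta * (d.mean(axis=1) - p)
        if ebar is not None:
            acc += eps * (ebar - p)
        acc += zeta_p * pv
        d_acc = beta * (p[:, None] - d) + zeta_d * dv
        return pv, acc, dv, d_acc

    p = envs.p0.astype(np.float64).copy()
    pv = envs.p0_vel.astype(np.float64).copy()
    d = envs.d0.astype(np.float64).copy()
    dv = envs.d0_vel.astype(np.float64).copy()

    n_rec = cfg.n_recorded
    spr = cfg.steps_per_record
    dt = cfg.dt
    times = np.arange(n_rec) * cfg.record_every
    if record:
        p_series = np.empty((n, n_rec))
    for k in range(n_rec):
        if record:
            p_series[:, k] = p
        if k == n_rec - 1:
            break
        for _ in range(spr):
            k1 = deriv(p, pv, d, dv)
            k2 = deriv(p + 0.5 * dt * k1[0], pv + 0.5 * dt * k1[1], d + 0.5 * dt * k1[2], dv + 0.5 * dt * k1[3])
            k3 = deriv(p + 0.5 * dt * k2[0], pv + 0.5 * dt * k2[1], d + 0.5 * dt * k2[2], dv + 0.5 * dt * k2[3])
            k4 = deriv(p + dt * k3[0], pv + dt * k3[1], d + dt * k3[2], dv + dt * k3[3])
            p = p + (dt / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            pv = pv + (dt / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            d = d + (dt / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            dv = dv + (dt / 6.0) * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if not np.all(np.isfinite(p)):
            bad = int(np.flatnonzero(~np.isfinite(p))[0])
            raise IntegrationError(
                f"trajectory of individual {bad} diverged near t={times[k] + cfg.record_every:g}"
            )
    if not record:
        return times[-1:], p[:, None]
    return times, p_series


# ---- trajectory summaries --------------------------------------------------------


def terminal_phenotype(traj: Trajectory) -> float:
    """The phenotype: the last recorded value of p(t)."""
    if traj.p.size == 0:
        raise ValueError("empty trajectory")
    return float(traj.p[-1])


def stabilization_ratio(traj_or_series, k: int = 50) -> float:
    """var(last k recorded points) / var(first k recorded points) of p(t).

    Values well below 1 indicate that the trajectory settled; NaN is returned
    when the initial window has zero variance (the ratio is then undefined).
    Accepts a :class:`Trajectory` or a raw phenotype series.
    """
    p = traj_or_series.p if isinstance(traj_or_series, Trajectory) else np.asarray(traj_or_series)
    if p.size < 2 * k:
        raise ValueError(f"need at least {2 * k} recorded points, have {p.size}")
    v0 = float(np.var(p[:k]))
    v1 = float(np.var(p[-k:]))
    if v0 == 0.0:
        return float("nan")
    return v1 / v0


def stabilization_ratios(p_series: np.ndarray, k: int = 50) -> np.ndarray:
    """Per-row stabilization ratios for an (n, n_rec) phenotype series."""
    p_series = np.asarray(p_series)
    if p_series.shape[1] < 2 * k:
        raise ValueError(f"need at least {2 * k} recorded points")
    v0 = np.var(p_series[:, :k], axis=1)
    v1 = np.var(p_series[:, -k:], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(v0 > 0, v1 / v0, np.nan)


def classify_attractor(traj_or_series, tol: float | None = None, window: int = 50) -> str:
    """Classify the trajectory's long-run behavior.

    ``fixed_point`` if the amplitude (max - min) of p over the terminal window
    is below ``tol``; ``cycle`` if the terminal amplitude is at least ``tol``
    but differs from the preceding window's amplitude by less than ``tol``
    (stationary oscillation); ``nonconverged`` otherwise.  ``tol`` defaults to
    1e-3 of the trajectory's total range.
    """
    p = traj_or_series.p if isinstance(traj_or_series, Trajectory) else np.asarray(traj_or_series)
    if p.size < 2 * window:
        raise ValueError(f"need at least {2 * window} recorded points, have {p.size}")
    total_range = float(p.max() - p.min())
    if tol is None:
        tol = 1e-3 * total_range if total_range > 0 else 1e-12
    amp_last = float(p[-window:].max() - p[-window:].min())
    amp_prev = float(p[-2 * window : -window].max() - p[-2 * window : -window].min())
    if amp_last < tol:
        return "fixed_point"
    if abs(amp_last - amp_prev) < tol:
        return "cycle"
    return "nonconverged"
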