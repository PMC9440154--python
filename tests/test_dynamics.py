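"""Force terms, RK4 integration, and trajectory summaries."""

import numpy as np
import pytest

from gxedyn import SimulationConfig
from gxedyn.dynamics import (
    CohortEnvironments,
    EnvironmentSpec,
    SystemState,
    Trajectory,
    classify_attractor,
    gxe_activation,
    integrate_cohort,
    integrate_individual,
    stabilization_ratio,
    stabilization_ratios,
    system_derivatives,
    terminal_phenotype,
)
from gxedyn.genome import GeneArchitecture, sample_genome, snp_strengths


def make_arch(cfg, rng):
    return GeneArchitecture.from_config(cfg, rng)


def linear_cfg(**kw):
    """Single-SNP linear configuration: only the additive force and damping."""
    defaults = dict(
        n_snps=1, n_dyn=1, n_static=0, alpha=0.05, gamma=0.0, delta=0.0,
        epsilon=0.0, zeta_p=-0.1, t_end=250.0, dt=0.1, record_every=1.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


def env_at(cfg, p0=0.0, d0=1.0):
    return EnvironmentSpec(
        beta=np.full(cfg.n_dyn, 0.025),
        e=np.ones(cfg.n_static),
        d0=np.full(cfg.n_dyn, float(d0)),
        d0_vel=np.zeros(cfg.n_dyn),
        p0=p0,
        p0_vel=0.0,
    )


class TestGxeActivation:
    def test_zero_indicator_annihilates(self):
        assert gxe_activation(0, 1.7, 0, xi=10, dist_floor=1e-3) == 0
        assert gxe_activation(2, 0.1, 0, xi=2, dist_floor=1e-3) == 0

    def test_inverse_square_value(self):
        # 1 / |0 - 2|^2 = 0.25
        assert gxe_activation(0, 2.0, 1, xi=2, dist_floor=1e-3) == pytest.approx(0.25)

    def test_monotone_in_proximity_until_floor(self):
        d = np.array([1.0, 0.5, 0.1, 1e-2, 1e-3, 1e-4, 0.0])
        vals = gxe_activation(0.0, d, 1, xi=10, dist_floor=1e-3)
        assert vals[0] == pytest.approx(1.0)
        assert np.all(np.diff(vals[:5]) > 0)
        assert vals[4] == vals[5] == vals[6]  # floor binds

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            gxe_activation(0, 1, 1, xi=0, dist_floor=1e-3)
        with pytest.raises(ValueError):
            gxe_activation(0, 1, 1, xi=2, dist_floor=0)


class TestSystemDerivatives:
    def test_additive_term_hand_value(self):
        # single SNP g=2, p=0: acceleration = alpha * (Lambda/A) * (2 - 0) = 2 alpha
        cfg = linear_cfg(psi=0.0)
        arch = make_arch(cfg, np.random.default_rng(0))
        env = env_at(cfg)
        st = SystemState(p=0.0, p_vel=0.0, d=np.array([1.0]), d_vel=np.array([0.0]))
        _, p_acc, _, d_acc = system_derivatives(st, np.array([2]), arch, env, cfg)
        assert p_acc == pytest.approx(2 * cfg.alpha)
        # environment: beta * (p - d) = 0.025 * (0 - 1)
        assert d_acc[0] == pytest.approx(0.025 * (0.0 - 1.0))

    def test_no_interacting_snps_means_no_gxe_force(self):
        cfg = SimulationConfig(n_snps=5, n_dyn=1, n_static=0, upsilon=0.0,
                               gamma=0.5, delta=0.0, epsilon=0.0, zeta_p=-0.1,
                               t_end=10.0)
        arch = make_arch(cfg, np.random.default_rng(1))
        assert arch.s.sum() == 0  # B(t) = 0 everywhere
        g = sample_genome(cfg.n_snps, 0.5, 2)
        env = env_at(cfg)
        st = SystemState(p=0.3, p_vel=0.1, d=np.array([0.9]), d_vel=np.array([0.0]))
        _, p_acc, _, _ = system_derivatives(st, g, arch, env, cfg)
        lam, A = snp_strengths(cfg.n_snps, cfg.psi)
        expected = cfg.alpha / A * np.sum(lam * (g - 0.3)) + cfg.zeta_p * 0.1
        assert p_acc == pytest.approx(expected)

    def test_equilibrium_at_weighted_mean(self):
        # gamma = delta = 0, e_j all at the Lambda-weighted genotype mean:
        # the phenotype sits at its asymptote with zero acceleration
        cfg = SimulationConfig(n_snps=8, n_dyn=1, n_static=3, gamma=0.0,
                               delta=0.0, epsilon=0.05, t_end=10.0)
        rng = np.random.default_rng(3)
        arch = make_arch(cfg, rng)
        g = sample_genome(cfg.n_snps, 0.5, rng)
        gbar = float(np.sum(arch.lambda_ * g) / arch.A)
        env = env_at(cfg)
        env.e = np.full(cfg.n_static, gbar)
        st = SystemState(p=gbar, p_vel=0.0, d=np.array([0.4]), d_vel=np.array([0.0]))
        _, p_acc, _, _ = system_derivatives(st, g, arch, env, cfg)
        assert p_acc == pytest.approx(0.0, abs=1e-14)

    def test_nonfinite_state_rejected(self):
        cfg = linear_cfg()
        arch = make_arch(cfg, np.random.default_rng(0))
        st = SystemState(p=np.nan, p_vel=0.0, d=np.array([1.0]), d_vel=np.array([0.0]))
        with pytest.raises(Exception, match="non-finite"):
            system_derivatives(st, np.array([2]), arch, env_at(cfg), cfg)


class TestIntegration:
    def test_converges_to_single_snp_attractor(self):
        # damped linear oscillator toward g=2: closed-form limit is 2
        cfg = linear_cfg()
        arch = make_arch(cfg, np.random.default_rng(0))
        traj = integrate_individual(np.array([2]), arch, env_at(cfg), cfg)
        assert terminal_phenotype(traj) == pytest.approx(2.0, abs=1e-3)

    @pytest.mark.parametrize(
        "gamma,tol",
        [
            # smooth system: RK4 at dt=0.1 is converged to well below 1e-6
            (0.0, 1e-6),
            # the inverse-power GxE activation (xi=10, floored distance) limits
            # smoothness of the right-hand side, so convergence is coarser
            (0.05, 1e-4),
        ],
    )
    def test_rk4_step_halving(self, gamma, tol):
        cfg = SimulationConfig(n_snps=6, n_dyn=2, n_static=4, t_end=50.0, dt=0.1,
                               gamma=gamma)
        rng = np.random.default_rng(5)
        arch = make_arch(cfg, rng)
        g = sample_genome(cfg.n_snps, 0.5, rng)
        env = EnvironmentSpec.draw(cfg, rng)
        t1 = integrate_individual(g, arch, env, cfg)
        t2 = integrate_individual(g, arch, env, cfg.replace(dt=0.05))
        assert np.max(np.abs(t1.p - t2.p)) < tol

    def test_gamma_zero_ignores_gxe_structure(self):
        cfg = SimulationConfig(n_snps=6, n_dyn=1, n_static=3, gamma=0.0, t_end=30.0)
        rng = np.random.default_rng(6)
        arch = make_arch(cfg, rng)
        g = sample_genome(cfg.n_snps, 0.5, rng)
        env = EnvironmentSpec.draw(cfg, rng)
        base = integrate_individual(g, arch, env, cfg)
        tweaked = GeneArchitecture(
            lambda_=arch.lambda_, A=arch.A,
            s=1 - arch.s, l=(arch.l + 1) % 3,
        )
        alt = integrate_individual(g, tweaked, env, cfg.replace(xi=2.0))
        assert np.array_equal(base.p, alt.p)

    def test_euler_oracle_on_random_small_systems(self):
        # independent transcription of the force law + first-order Euler at a
        # tiny step, compared against the RK4 production route
        rng = np.random.default_rng(42)
        for trial in range(20):
            n_snps = int(rng.integers(1, 11))
            n_dyn = int(rng.integers(1, 4))
            cfg = SimulationConfig(
                n_snps=n_snps, n_dyn=n_dyn, n_static=int(rng.integers(0, 4)),
                gamma=float(rng.uniform(0, 0.3)), t_end=5.0, dt=0.1,
                record_every=1.0,
            )
            arch = make_arch(cfg, rng)
            g = sample_genome(n_snps, 0.5, rng)
            env = EnvironmentSpec.draw(cfg, rng)
            traj = integrate_individual(g, arch, env, cfg)
            p_ref = _euler_reference(g, arch, env, cfg, dt=5e-5)
            assert abs(traj.p[-1] - p_ref) < 1e-4, f"trial {trial}"

    def test_cohort_route_matches_individual_route(self):
        cfg = SimulationConfig(n_snps=12, n_dyn=2, n_static=5, t_end=40.0)
        rng = np.random.default_rng(9)
        arch = make_arch(cfg, rng)
        G = np.stack([sample_genome(cfg.n_snps, 0.5, rng) for _ in range(4)])
        specs = [EnvironmentSpec.draw(cfg, rng) for _ in range(4)]
        envs = CohortEnvironments.from_specs(specs)
        _, P = integrate_cohort(G, arch, envs, cfg)
        for i in range(4):
            traj = integrate_individual(G[i], arch, specs[i], cfg)
            assert np.allclose(P[i], traj.p, rtol=0, atol=1e-12)

    def test_cohort_route_with_per_individual_gxe(self):
        cfg = SimulationConfig(n_snps=10, n_dyn=1, n_static=2, t_end=30.0)
        rng = np.random.default_rng(10)
        arch = make_arch(cfg, rng)
        G = np.stack([sample_genome(cfg.n_snps, 0.5, rng) for _ in range(3)])
        s = (rng.random((3, cfg.n_snps, 1)) < 0.5).astype(np.int8)
        l = rng.integers(0, 3, size=(3, cfg.n_snps, 1)).astype(np.int8)
        specs = [EnvironmentSpec.draw(cfg, rng) for _ in range(3)]
        _, P = integrate_cohort(G, arch, CohortEnvironments.from_specs(specs), cfg, s=s, l=l)
        for i in range(3):
            arch_i = GeneArchitecture(lambda_=arch.lambda_, A=arch.A, s=s[i], l=l[i])
            traj = integrate_individual(G[i], arch_i, specs[i], cfg)
            assert np.allclose(P[i], traj.p, rtol=0, atol=1e-12)

    def test_velocity_decays_without_couplings(self):
        # all attractions off: energy (1/2) v^2 must be nonincreasing
        cfg = linear_cfg(alpha=0.0, zeta_p=-0.05, t_end=100.0)
        arch = make_arch(cfg, np.random.default_rng(0))
        env = env_at(cfg)
        env.p0_vel = 1.0
        traj = integrate_individual(np.array([2]), arch, env, cfg)
        v = np.gradient(traj.p, traj.times)
        assert np.all(np.diff(np.abs(v)) < 1e-12)

    def test_gxe_force_bounded_by_gamma(self):
        # the normalized weights sum to one, so |GxE force| <= gamma * max|l - p|
        cfg = SimulationConfig(n_snps=20, n_dyn=2, n_static=0, gamma=0.3,
                               alpha=0.0, delta=0.0, epsilon=0.0, zeta_p=-0.1,
                               t_end=10.0, upsilon=0.5)
        rng = np.random.default_rng(11)
        arch = make_arch(cfg, rng)
        g = sample_genome(cfg.n_snps, 0.5, rng)
        env = env_at(cfg)
        for _ in range(50):
            p = float(rng.uniform(-1, 3))
            st = SystemState(p=p, p_vel=0.0, d=rng.uniform(0, 2, 2), d_vel=np.zeros(2))
            _, p_acc, _, _ = system_derivatives(st, g, arch, env, cfg)
            bound = cfg.gamma * np.max(np.abs(arch.l - p)) + 1e-12
            assert abs(p_acc) <= bound


def _euler_reference(g, arch, env, cfg, dt):
    """Independent brute-force integrator: naive loops, explicit Euler."""
    p, pv = env.p0, env.p0_vel
    d = [float(x) for x in env.d0]
    dv = [float(x) for x in env.d0_vel]
    n_steps = int(round(cfg.t_end / dt))
    for _ in range(n_steps):
        add = 0.0
        for i in range(cfg.n_snps):
            add += arch.lambda_[i] * (g[i] - p)
        acc = cfg.alpha / arch.A * add
        if cfg.gamma > 0:
            B = 0.0
            num = 0.0
            for i in range(cfg.n_snps):
                for h in range(cfg.n_dyn):
                    dist = max(abs(g[i] - d[h]), cfg.dist_floor)
                    gam = arch.s[i, h] / dist**cfg.xi
                    B += gam
                    num += gam * (arch.l[i, h] - p)
            if B > 0:
                acc += cfg.gamma / B * num
        for h in range(cfg.n_dyn):
            acc += cfg.delta / cfg.n_dyn * (d[h] - p)
        for j in range(cfg.n_static):
            acc += cfg.epsilon / cfg.n_static * (env.e[j] - p)
        acc += cfg.zeta_p * pv
        d_new, dv_new = [], []
        for h in range(cfg.n_dyn):
            a_h = env.beta[h] * (p - d[h]) + cfg.zeta_d_for(env.beta[h]) * dv[h]
            d_new.append(d[h] + dt * dv[h])
            dv_new.append(dv[h] + dt * a_h)
        p, pv = p + dt * pv, pv + dt * acc
        d, dv = d_new, dv_new
    return p


class TestTrajectorySummaries:
    def test_terminal_phenotype(self):
        traj = Trajectory(times=np.arange(3.0), p=np.array([0.1, 0.5, 0.9]),
                          d=np.zeros((3, 1)))
        assert terminal_phenotype(traj) == pytest.approx(0.9)
        with pytest.raises(ValueError):
            terminal_phenotype(Trajectory(times=np.array([]), p=np.array([]),
                                          d=np.zeros((0, 1))))

    def test_stabilization_ratio_cases(self):
        t = np.arange(200.0)
        oscillating_then_flat = np.where(t < 100, np.sin(t), 0.0)
        assert stabilization_ratio(oscillating_then_flat) == pytest.approx(0.0)
        pure_cycle = np.sin(0.3 * t)
        assert stabilization_ratio(pure_cycle) == pytest.approx(1.0, abs=0.15)
        constant_start = np.where(t < 100, 1.0, np.sin(t))
        assert np.isnan(stabilization_ratio(constant_start))
        with pytest.raises(ValueError):
            stabilization_ratio(np.ones(30), k=50)

    def test_stabilization_ratios_matches_scalar(self):
        rng = np.random.default_rng(1)
        P = rng.normal(size=(5, 120))
        vec = stabilization_ratios(P)
        for i in range(5):
            assert vec[i] == pytest.approx(stabilization_ratio(P[i]))

    def test_classify_attractor(self):
        t = np.arange(300.0)
        damped = 1 + np.exp(-0.05 * t) * np.sin(t)
        assert classify_attractor(damped) == "fixed_point"
        # period of 25 samples divides the 50-point window exactly, so the
        # sampled amplitude is identical window to window
        sinusoid = np.sin(2 * np.pi / 25 * t)
        assert classify_attractor(sinusoid) == "cycle"
        noise = np.random.default_rng(2).normal(size=300) * np.linspace(1, 2, 300)
        assert classify_attractor(noise) == "nonconverged"
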