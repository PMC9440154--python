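"""Genomic-relationship heritability estimation (GREML, one variance component).

The genetic relationship matrix (GRM) is built from standardized genotypes:
each SNP column is centered at twice its sample allele frequency and scaled
by the binomial standard deviation sqrt(2 p (1 - p)); K = Z Z' / m over the m
polymorphic SNPs.  For unrelated individuals the off-diagonal entries are
identity-by-state correlations concentrated near zero with standard deviation
about 1/sqrt(m).

Heritability is then the share of phenotypic variance carried by a genetic
random effect with covariance proportional to K:

    y = mu + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

fitted by restricted maximum likelihood.  The implementation eigendecomposes
K once and rotates y and the intercept into the eigenbasis, where the
covariance is diagonal; the REML criterion is then profiled over the single
ratio h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) with the total variance
available in closed form, and the profile is maximized by bounded scalar
search.  Standard errors come from the numerical curvature of the profile
log-likelihood; the 95% interval is Wald on the h^2 scale, truncated to
[0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

H2_LO, H2_HI = 1e-6, 1.0 - 1e-6


@dataclass
class GRM:
    """Genetic relationship matrix and the number of SNPs it used."""

    k: np.ndarray  # (n, n) symmetric
    n_snps_used: int

    @property
    def n(self) -> int:
        return self.k.shape[0]

    def off_diagonal(self) -> np.ndarray:
        iu = np.triu_indices(self.n, 1)
        return self.k[iu]

    def to_tsv(self, path) -> None:
        ids = [f"ind_{i + 1}" for i in range(self.n)]
        pd.DataFrame(self.k, index=ids, columns=ids).to_csv(path, sep="\t")


@dataclass
class GremlFit:
    """REML variance components and derived heritability."""

    h2: float
    sigma2_g: float
    sigma2_e: float
    se_h2: float
    ci95: tuple[float, float]
    loglik: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "h2": self.h2,
            "sigma2_g": self.sigma2_g,
            "sigma2_e": self.sigma2_e,
            "se_h2": self.se_h2,
            "ci95": list(self.ci95),
            "loglik": self.loglik,
            "converged": self.converged,
        }


def compute_grm(genotypes: np.ndarray, method: str = "gcta") -> GRM:
    """Build the GRM from an (n, m) genotype matrix.

    ``method="gcta"`` (default) standardizes each polymorphic SNP by its
    sample allele frequency, K = Z Z' / m; monomorphic SNPs carry no
    relatedness information and are excluded.  ``method="pearson"`` instead
    uses the plain row-wise Pearson correlation of genotype vectors, offered
    for sensitivity analysis.
    """
    G = np.asarray(genotypes, dtype=float)
    n, m = G.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    if method == "pearson":
        keep = G.std(axis=0) > 0
        if not keep.any():
            raise ValueError("all SNPs are monomorphic")
        return GRM(k=np.corrcoef(G[:, keep]), n_snps_used=int(keep.sum()))
    if method != "gcta":
        raise ValueError(f"method must be 'gcta' or 'pearson', got {method!r}")
    p_hat = G.mean(axis=0) / 2.0
    keep = G.std(axis=0) > 0  # monomorphic columns carry no information
    if not keep.any():
        raise ValueError("all SNPs are monomorphic")
    Gk = G[:, keep]
    pk = p_hat[keep]
    Z = (Gk - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    m_used = int(keep.sum())
    return GRM(k=(Z @ Z.T) / m_used, n_snps_used=m_used)


def _rotate(phenotype: np.ndarray, grm: GRM, psd_tol: float = 1e-6):
    """Eigendecompose K and rotate y and the intercept into its basis."""
    y = np.asarray(phenotype, dtype=float)
    if y.size != grm.n:
        raise ValueError("phenotype length does not match GRM")
    vals, vecs = np.linalg.eigh(grm.k)
    if vals[0] < -psd_tol * max(1.0, vals[-1]):
        raise ValueError(f"GRM is not positive semidefinite (min eigenvalue {vals[0]:.3g})")
    vals = np.clip(vals, 0.0, None)
    ystar = vecs.T @ y
    xstar = vecs.T @ np.ones_like(y)
    return vals, ystar, xstar


def _profile_negloglik(h2: float, vals, ystar, xstar) -> float:
    """Negative profile REML log-likelihood at heritability ratio h2.

    With V = sigma^2 [h2 K + (1 - h2) I], the eigenbasis makes V diagonal
    with weights w_i = h2 lambda_i + 1 - h2; the GLS intercept and the total
    variance sigma^2 are closed-form, leaving the standard REML criterion
    (residual term + log|V| + log|X' V^-1 X|) as a function of h2 alone.
    """
    n = ystar.size
    w = h2 * vals + (1.0 - h2)
    wi = 1.0 / w
    xwx = float(np.sum(xstar * wi * xstar))
    xwy = float(np.sum(xstar * wi * ystar))
    mu = xwy / xwx
    r = ystar - mu * xstar
    quad = float(np.sum(r * wi * r))
    sigma2 = quad / (n - 1)
    ll = -0.5 * ((n - 1) * np.log(sigma2) + np.sum(np.log(w)) + np.log(xwx) + (n - 1))
    return -ll


def reml_h2(phenotype: np.ndarray, grm: GRM, psd_tol: float = 1e-6) -> GremlFit:
    """Single-component GREML fit of heritability from a phenotype and GRM."""
    vals, ystar, xstar = _rotate(phenotype, grm, psd_tol)
    n = ystar.size

    obj = lambda h2: _profile_negloglik(h2, vals, ystar, xstar)
    opt = optimize.minimize_scalar(obj, bounds=(H2_LO, H2_HI), method="bounded",
                                   options={"xatol": 1e-8})
    h2 = float(opt.x)
    nll = float(opt.fun)
    converged = bool(opt.success)
    # boundary solutions: a flat or monotone profile pushed against the bounds
    at_boundary = h2 < 10 * H2_LO or h2 > 1 - 10 * H2_LO
    if at_boundary:
        converged = False

    # total variance at the optimum, then the components
    w = h2 * vals + (1.0 - h2)
    wi = 1.0 / w
    mu = float(np.sum(xstar * wi * ystar) / np.sum(xstar * wi * xstar))
    r = ystar - mu * xstar
    sigma2 = float(np.sum(r * wi * r)) / (n - 1)
    sigma2_g = h2 * sigma2
    sigma2_e = (1.0 - h2) * sigma2

    # curvature of the profile log-likelihood -> Wald standard error
    step = 1e-4
    lo = max(H2_LO, h2 - step)
    hi = min(H2_HI, h2 + step)
    f0, flo, fhi = nll, obj(lo), obj(hi)
    denom = (hi - h2) * (h2 - lo)
    curv = 0.0
    if denom > 0:
        # second difference on a possibly asymmetric stencil
        curv = 2.0 * ((flo - f0) * (hi - h2) + (fhi - f0) * (h2 - lo)) / (
            (hi - lo) * (hi - h2) * (h2 - lo)
        )
    se = float(1.0 / np.sqrt(curv)) if curv > 0 else float("nan")
    if np.isfinite(se):
        ci = (max(0.0, h2 - 1.96 * se), min(1.0, h2 + 1.96 * se))
    else:
        ci = (0.0, 1.0)
    return GremlFit(
        h2=h2,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        se_h2=se,
        ci95=ci,
        loglik=-nll,
        converged=converged,
    )


# ---- study drivers ---------------------------------------------------------------


def h2_vs_gamma(gammas, n: int, cfg, seed=None) -> pd.DataFrame:
    """GREML heritability across a grid of GxE effect sizes.

    One cohort is simulated per gamma from the same seed, so genomes,
    environments, and architecture draws are shared across conditions and
    only the GxE force strength differs.
    """
    from .population import simulate_cohort

    rows = []
    for g in gammas:
        if g < 0:
            raise ValueError("gamma values must be nonnegative")
        cohort = simulate_cohort(cfg.replace(gamma=float(g)), n, seed, record_series=False)
        grm = compute_grm(cohort.genotypes)
        fit = reml_h2(cohort.phenotypes, grm)
        rows.append(
            {
                "gamma": float(g),
                "h2": fit.h2,
                "sigma2_g": fit.sigma2_g,
                "sigma2_e": fit.sigma2_e,
                "se_h2": fit.se_h2,
                "ci_lo": fit.ci95[0],
                "ci_hi": fit.ci95[1],
                "loglik": fit.loglik,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def h2_vs_relatedness(relatedness_grid, n_pairs: int, cfg, seed=None) -> pd.DataFrame:
    """GREML heritability across relatedness conditions of a paired design.

    Each condition simulates ``n_pairs`` pairs at one relatedness coefficient
    with shared within-pair environmental dynamics and GxE assignments,
    builds the empirical (identity-by-state) GRM over all individuals, fits
    GREML, and records the within-pair phenotypic correlation.
    """
    from .population import simulate_related_cohort, within_pair_correlation

    rows = []
    for r in relatedness_grid:
        cohort = simulate_related_cohort(cfg, n_pairs, float(r), seed)
        grm = compute_grm(cohort.genotypes)
        fit = reml_h2(cohort.phenotypes, grm)
        rows.append(
            {
                "relatedness": float(r),
                "h2": fit.h2,
                "sigma2_g": fit.sigma2_g,
                "sigma2_e": fit.sigma2_e,
                "se_h2": fit.se_h2,
                "ci_lo": fit.ci95[0],
                "ci_hi": fit.ci95[1],
                "phenotypic_corr": within_pair_correlation(cohort),
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
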