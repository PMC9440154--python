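"""Single-SNP association scan with Bonferroni correction and summary curves.

Each SNP is regressed on the terminal phenotype separately by ordinary least
squares (slope + intercept).  The scan reports the slope, its standard error,
the squared correlation R^2, and the two-sided p-value from the t test on the
slope with n - 2 degrees of freedom.  Downstream summaries mirror the three
standard diagnostics: a pseudo-Manhattan track (-log10 p by SNP index), the
cumulative per-SNP R^2 curve, and a QQ comparison of standardized slopes to
Gaussian quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class GwasResult:
    """Per-SNP statistics from the single-SNP scan."""

    beta: np.ndarray
    se: np.ndarray
    r2: np.ndarray
    pval: np.ndarray
    n: int

    @property
    def n_snps(self) -> int:
        return self.beta.size

    @property
    def order(self) -> np.ndarray:
        """SNP indices sorted by increasing p-value (ties by index)."""
        return np.argsort(self.pval, kind="stable")

    def to_tsv(self, path, alpha: float = 0.05) -> None:
        hits = np.zeros(self.n_snps, dtype=int)
        hits[bonferroni_hits(self, alpha)] = 1
        with np.errstate(divide="ignore"):
            neglog = -np.log10(self.pval)
        cols = np.column_stack(
            [np.arange(1, self.n_snps + 1), self.beta, self.se, self.r2, self.pval, neglog, hits]
        )
        np.savetxt(
            path,
            cols,
            delimiter="\t",
            header="snp\tbeta\tse\tr2\tpval\tneglog10p\tbonferroni_hit",
            comments="",
            fmt=["%d", "%.8g", "%.8g", "%.8g", "%.8g", "%.6g", "%d"],
        )


def single_snp_regression(genotype: np.ndarray, phenotype: np.ndarray):
    """OLS of phenotype on one genotype vector.

    Returns (beta, se, r2, pval).  A constant genotype column is degenerate:
    the slope is undefined and the result is flagged as (nan, nan, 0, 1).
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.size != y.size or g.size < 3:
        raise ValueError("need matching vectors of length >= 3")
    res = scan_matrix(g[:, None], y)
    return float(res.beta[0]), float(res.se[0]), float(res.r2[0]), float(res.pval[0])


def scan_matrix(G: np.ndarray, y: np.ndarray) -> GwasResult:
    """Vectorized per-column simple OLS of ``y`` on each column of ``G``."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if G.shape[0] != n:
        raise ValueError("row count mismatch between genotypes and phenotype")
    if n < 3:
        raise ValueError("need n >= 3")
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxy = gc.T @ yc
    syy = float(yc @ yc)

    ok = sxx > 0
    beta = np.full(G.shape[1], np.nan)
    se = np.full(G.shape[1], np.nan)
    r2 = np.zeros(G.shape[1])
    pval = np.ones(G.shape[1])

    beta[ok] = sxy[ok] / sxx[ok]
    rss = np.maximum(syy - beta[ok] * sxy[ok], 0.0)
    sigma2 = rss / (n - 2)
    se[ok] = np.sqrt(sigma2 / sxx[ok])
    if syy > 0:
        r2[ok] = np.clip(sxy[ok] ** 2 / (sxx[ok] * syy), 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se[ok] > 0, beta[ok] / se[ok], np.inf * np.sign(beta[ok]))
    pval[ok] = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return GwasResult(beta=beta, se=se, r2=r2, pval=pval, n=n)


def gwas_scan(cohort) -> GwasResult:
    """Scan every SNP column of a cohort against its terminal phenotypes."""
    return scan_matrix(cohort.genotypes, cohort.phenotypes)


def bonferroni_hits(res: GwasResult, alpha: float = 0.05) -> np.ndarray:
    """Indices of SNPs significant at the Bonferroni-corrected level alpha / N_g."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return np.flatnonzero(res.pval < alpha / res.n_snps)


def cumulative_r2(res: GwasResult, by: str = "index") -> np.ndarray:
    """Running sum of per-SNP R^2, by SNP index or by decreasing significance.

    Because predictors are entered in separate regressions, the sum can in
    principle exceed 1; with independent loci it approximates the total
    linearly explainable variance.
    """
    if by == "index":
        vals = res.r2
    elif by == "significance":
        vals = res.r2[res.order]
    else:
        raise ValueError(f"by must be 'index' or 'significance', got {by!r}")
    return np.cumsum(vals)


def qq_points(res: GwasResult, standardized: bool = True):
    """QQ coordinates comparing slope effects to a Gaussian.

    With ``standardized=True`` (default) the slopes are divided by their OLS
    standard errors (z scores), the only scale-free choice; otherwise the raw
    slopes are centered and scaled by their sample moments.  Returns
    (theoretical, observed) at plotting positions (k - 0.5) / m.
    """
    z = res.beta / res.se if standardized else (res.beta - np.nanmean(res.beta)) / np.nanstd(res.beta)
    z = np.sort(z[np.isfinite(z)])
    m = z.size
    theo = stats.norm.ppf((np.arange(1, m + 1) - 0.5) / m)
    return theo, z
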