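"""Cross-validated polygenic score construction.

SNPs are ranked by their single-SNP p-value in a scan of the training half.
For each k, a multiple OLS regression of the phenotype on the top-k SNPs is
refitted on the training data; the in-sample R^2 and the out-of-sample R^2
(squared correlation between prediction and phenotype on the held-out test
half) trace the familiar polygenic-score curve: rising in-sample fit with
every added predictor, while out-of-sample performance peaks and then decays
as noise predictors accumulate.

The nested fits are computed with an incremental Cholesky factorization of
the (centered) Gram matrix, adding one ranked SNP at a time, so the full
curve over k = 1..N_g costs one O(N_g^3 / 3) sweep rather than N_g separate
least-squares solves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from .gwas import bonferroni_hits, scan_matrix

logger = logging.getLogger(__name__)


@dataclass
class PrsCurve:
    """Polygenic-score performance by number of included SNPs."""

    k: np.ndarray  # 1..max_k
    snp: np.ndarray  # SNP index added at each k (training-scan rank order)
    pval_train: np.ndarray  # training-scan p-value of that SNP
    r2_train: np.ndarray  # in-sample R^2 of the k-SNP multiple regression
    r2_test: np.ndarray  # out-of-sample R^2 of its predictions
    sig_mask: np.ndarray  # True where the added SNP was Bonferroni-significant

    @property
    def peak_r2_test(self) -> float:
        return float(np.max(self.r2_test))

    @property
    def peak_k(self) -> int:
        return int(self.k[np.argmax(self.r2_test)])

    def to_tsv(self, path) -> None:
        cols = np.column_stack(
            [self.k, self.snp + 1, self.pval_train, self.r2_train, self.r2_test, self.sig_mask]
        )
        np.savetxt(
            path,
            cols,
            delimiter="\t",
            header="k\tsnp_added\tpval_train\tr2_train\tr2_test\tsignificant",
            comments="",
            fmt=["%d", "%d", "%.8g", "%.8g", "%.8g", "%d"],
        )


def split_cohort(cohort, test_fraction: float = 0.5, seed=None):
    """Random disjoint, exhaustive train/test partition of a cohort."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError(f"test_fraction must be in (0, 1), got {test_fraction}")
    n = cohort.n
    n_test = int(round(n * test_fraction))
    if n_test < 1 or n - n_test < 3:
        raise ValueError(f"degenerate split sizes for n={n}, test_fraction={test_fraction}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return cohort.subset(train_idx), cohort.subset(test_idx)


def prs_curve(
    train,
    test,
    max_k: int | None = None,
    alpha: float = 0.05,
    weighted_sum: bool = False,
    r2_method: str = "corr",
) -> PrsCurve:
    """Incremental polygenic-score curve from a train/test cohort pair.

    Parameters
    ----------
    train, test
        Cohorts sharing the same SNP columns; ranking and fitting use only
        ``train``.
    max_k
        Largest number of SNPs to include (default: all, capped at
        n_train - 2 so the OLS stays overdetermined).
    weighted_sum
        If True, score with the single-SNP training slopes (the classical
        clumping-free PRS) instead of refitting a joint regression at each k.
    r2_method
        "corr" (default) scores the test half by the squared Pearson
        correlation of prediction and observation; "rss" uses 1 - SSE/SST,
        which additionally penalizes miscalibration.
    """
    if train.n_snps != test.n_snps:
        raise ValueError("train and test must share SNP columns")
    if r2_method not in ("corr", "rss"):
        raise ValueError(f"r2_method must be 'corr' or 'rss', got {r2_method!r}")
    n_train, m = train.n, train.n_snps
    if max_k is None:
        max_k = m
    max_k = min(max_k, m, n_train - 2)
    if max_k < 1:
        raise ValueError("training set too small for any predictor")

    res = scan_matrix(train.genotypes, train.phenotypes)
    order = res.order
    sig = np.zeros(m, dtype=bool)
    sig[bonferroni_hits(res, alpha)] = True

    Xtr = np.asarray(train.genotypes[:, order], dtype=float)
    Xte = np.asarray(test.genotypes[:, order], dtype=float)
    ytr = np.asarray(train.phenotypes, dtype=float)
    yte = np.asarray(test.phenotypes, dtype=float)

    # center on the training sample; the intercept is then the training mean
    x_mean = Xtr.mean(axis=0)
    Xtr_c = Xtr - x_mean
    Xte_c = Xte - x_mean
    y_mean = ytr.mean()
    ytr_c = ytr - y_mean
    syy = float(ytr_c @ ytr_c)

    gram = Xtr_c.T @ Xtr_c
    xty = Xtr_c.T @ ytr_c

    k_out = np.arange(1, max_k + 1)
    snp_out = np.empty(max_k, dtype=int)
    p_out = np.empty(max_k)
    r2_train = np.empty(max_k)
    r2_test = np.empty(max_k)
    sig_out = np.empty(max_k, dtype=bool)

    if weighted_sum:
        with np.errstate(invalid="ignore"):
            betas = np.where(np.diag(gram) > 0, xty / np.diag(gram), 0.0)
        for j in range(max_k):
            snp_out[j] = order[j]
            p_out[j] = res.pval[order[j]]
            sig_out[j] = sig[order[j]]
            w = betas[: j + 1]
            pred_tr = Xtr_c[:, : j + 1] @ w
            pred_te = Xte_c[:, : j + 1] @ w + y_mean
            r2_train[j] = _r2(pred_tr + y_mean, ytr, "corr")
            r2_test[j] = _r2(pred_te, yte, r2_method)
        return PrsCurve(k_out, snp_out, p_out, r2_train, r2_test, sig_out)

    # incremental Cholesky of the Gram matrix in ranked order
    L = np.zeros((max_k, max_k))
    cols: list[int] = []  # positions (in ranked order) actually included
    cand = 0
    j = 0
    while j < max_k and cand < m:
        c = cand
        cand += 1
        gcc = gram[c, c]
        if gcc <= 0:
            logger.warning("dropping constant SNP %d from the score", order[c] + 1)
            continue
        g_vec = gram[np.asarray(cols, dtype=int), c] if cols else np.empty(0)
        l12 = solve_triangular(L[:j, :j], g_vec, lower=True) if j else np.empty(0)
        diag2 = gcc - l12 @ l12
        if diag2 <= 1e-10 * gcc:
            logger.warning("dropping collinear SNP %d from the score", order[c] + 1)
            continue
        L[j, :j] = l12
        L[j, j] = np.sqrt(diag2)
        cols.append(c)

        idx = np.asarray(cols, dtype=int)
        z = solve_triangular(L[: j + 1, : j + 1], xty[idx], lower=True)
        beta = solve_triangular(L[: j + 1, : j + 1].T, z, lower=False)
        explained = float(z @ z)  # = beta' X'y for the nested fit
        r2_train[j] = explained / syy if syy > 0 else 0.0
        pred_te = Xte_c[:, idx] @ beta + y_mean
        r2_test[j] = _r2(pred_te, yte, r2_method)
        snp_out[j] = order[c]
        p_out[j] = res.pval[order[c]]
        sig_out[j] = sig[order[c]]
        j += 1

    if j < max_k:  # ran out of usable SNPs
        k_out = k_out[:j]
        snp_out, p_out = snp_out[:j], p_out[:j]
        r2_train, r2_test, sig_out = r2_train[:j], r2_test[:j], sig_out[:j]
    return PrsCurve(k_out, snp_out, p_out, r2_train, r2_test, sig_out)


def _r2(pred: np.ndarray, obs: np.ndarray, method: str) -> float:
    if method == "rss":
        sst = float(np.sum((obs - obs.mean()) ** 2))
        if sst == 0:
            return 0.0
        return 1.0 - float(np.sum((obs - pred) ** 2)) / sst
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)
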