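"""Genome sampling and the SNP effect-size / GxE architecture.

Genomes are vectors of allelic counts g_i in {0, 1, 2}, drawn independently
per locus under Hardy-Weinberg equilibrium with a common allele frequency:
P(g=0) = pi^2, P(g=1) = 2 pi (1 - pi), P(g=2) = (1 - pi)^2.  There is no
linkage, linkage disequilibrium, or population structure.

Note the coding convention: ``maf`` is the frequency pi entering the HWE
probabilities verbatim, so P(g=2) = (1 - pi)^2 even though g is an allele
count.  With the default pi = 0.5 the distinction is vacuous; for pi != 0.5
the "minor" allele is simply the one with frequency 1 - pi.

The trait architecture maps each SNP index i (1-based) to an attractor
strength Lambda_i = exp(-psi * i / N_g), so effect sizes decay exponentially
with rank and the distribution of strengths is invariant to N_g.  Each
(SNP, dynamic environment) pair independently carries a GxE interaction
with probability upsilon; interacting pairs attract the phenotype toward a
random locus l in {0, 1, 2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig

SeedLike = "int | np.random.Generator | np.random.SeedSequence | None"


def as_generator(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator / None into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class GeneArchitecture:
    """Population-level trait architecture shared by a cohort.

    Attributes
    ----------
    lambda_
        Per-SNP attractor strengths Lambda_i, strictly positive and
        nonincreasing in SNP index.
    A
        Normalizer, the exact sum of ``lambda_``.
    s
        (n_snps, n_dyn) binary matrix; s[i, h] = 1 if SNP i interacts with
        dynamic environment h.
    l
        (n_snps, n_dyn) matrix of GxE attractor loci in {0, 1, 2}.
    """

    lambda_: np.ndarray
    A: float
    s: np.ndarray
    l: np.ndarray

    @classmethod
    def from_config(cls, cfg: SimulationConfig, seed=None) -> "GeneArchitecture":
        rng = as_generator(cfg.seed if seed is None else seed)
        lam, A = snp_strengths(cfg.n_snps, cfg.psi)
        s, l = assign_gxe_architecture(cfg.n_snps, cfg.n_dyn, cfg.upsilon, rng)
        return cls(lambda_=lam, A=A, s=s, l=l)


def hwe_probabilities(maf: float) -> np.ndarray:
    """Genotype probabilities (P(g=0), P(g=1), P(g=2)) under HWE."""
    if not 0.0 < maf < 1.0:
        raise ValueError(f"maf must be in (0, 1), got {maf}")
    return np.array([maf**2, 2 * maf * (1 - maf), (1 - maf) ** 2])


def sample_genome(n_snps: int, maf: float, seed=None) -> np.ndarray:
    """Draw one genome: ``n_snps`` independent HWE genotypes in {0, 1, 2}."""
    return sample_genotype_matrix(1, n_snps, maf, seed)[0]


def sample_genotype_matrix(n: int, n_snps: int, maf: float, seed=None) -> np.ndarray:
    """Draw an (n, n_snps) genotype matrix of independent HWE genotypes."""
    if n_snps < 1 or n < 1:
        raise ValueError("n and n_snps must be >= 1")
    probs = hwe_probabilities(maf)
    rng = as_generator(seed)
    u = rng.random((n, n_snps))
    # inverse-CDF over the three genotype classes
    g = (u >= probs[0]).astype(np.int8) + (u >= probs[0] + probs[1]).astype(np.int8)
    return g


def sample_related_genome(
    base: np.ndarray,
    relatedness: float,
    maf: float,
    seed=None,
    per_locus: bool = False,
) -> np.ndarray:
    """Generate a relative of ``base`` by allele copying.

    A fresh independent HWE genome is drawn, then a proportion ``relatedness``
    of its loci are overwritten by ``base``'s values at the same loci.  By
    default exactly ``round(relatedness * n_snps)`` loci are copied (chosen
    uniformly without replacement), so relatedness 1 returns an exact copy and
    0 an independent genome; with ``per_locus=True`` each locus is copied
    independently with probability ``relatedness`` instead.
    """
    if not 0.0 <= relatedness <= 1.0:
        raise ValueError(f"relatedness must be in [0, 1], got {relatedness}")
    base = np.asarray(base)
    rng = as_generator(seed)
    fresh = sample_genome(base.size, maf, rng)
    if per_locus:
        mask = rng.random(base.size) < relatedness
    else:
        n_copy = int(round(relatedness * base.size))
        idx = rng.choice(base.size, size=n_copy, replace=False)
        mask = np.zeros(base.size, dtype=bool)
        mask[idx] = True
    fresh[mask] = base[mask]
    return fresh


def snp_strengths(n_snps: int, psi: float) -> tuple[np.ndarray, float]:
    """Attractor strengths Lambda_i = exp(-psi * i / N_g), i = 1..N_g.

    Returns the strength vector and its exact sum A.  The 1-based index is
    deliberate: Lambda_1 = exp(-psi / N_g) < 1 whenever psi > 0.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if psi < 0:
        raise ValueError(f"psi must be >= 0, got {psi}")
    i = np.arange(1, n_snps + 1, dtype=float)
    lam = np.exp(-psi * i / n_snps)
    return lam, float(lam.sum())


def assign_gxe_architecture(
    n_snps: int, n_dyn: int, upsilon: float, seed=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the GxE indicator matrix s and attractor loci l.

    Each entry s[i, h] is Bernoulli(upsilon); each l[i, h] is uniform on
    {0, 1, 2}.  l is drawn for every pair regardless of s (unused entries are
    simply inert), which keeps the draw count independent of upsilon.
    """
    if not 0.0 <= upsilon <= 1.0:
        raise ValueError(f"upsilon must be in [0, 1], got {upsilon}")
    rng = as_generator(seed)
    s = (rng.random((n_snps, n_dyn)) < upsilon).astype(np.int8)
    l = rng.integers(0, 3, size=(n_snps, n_dyn)).astype(np.int8)
    return s, l


# ---- genotype matrix I/O ---------------------------------------------------------


def write_genotypes_tsv(path, genotypes: np.ndarray) -> None:
    """Write an (n, n_snps) genotype matrix as TSV with SNP_1..SNP_Ng header."""
    genotypes = np.asarray(genotypes)
    header = "\t".join(f"SNP_{j + 1}" for j in range(genotypes.shape[1]))
    np.savetxt(path, genotypes, fmt="%d", delimiter="\t", header=header, comments="")


def read_genotypes_tsv(path) -> np.ndarray:
    """Read a genotype matrix written by :func:`write_genotypes_tsv`."""
    g = np.loadtxt(path, delimiter="\t", skiprows=1, dtype=np.int8, ndmin=2)
    if g.size and (g.min() < 0 or g.max() > 2):
        raise ValueError(f"genotype file {path} contains values outside {{0,1,2}}")
    return g


def write_vcf(path, genotypes: np.ndarray, contig: str = "sim1") -> None:
    """Export genotypes as a minimal VCF 4.2 text file (GT only).

    One pseudo-contig; positions are the 1-based SNP indices; the allele
    count g is encoded as 0/0, 0/1, 1/1.  Intended for interoperability with
    standard tooling, not as a faithful variant-call record.
    """
    genotypes = np.asarray(genotypes)
    n, m = genotypes.shape
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={m}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind_{i + 1}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(m):
            gts = "\t".join(gt_codes[int(g)] for g in genotypes[:, j])
            fh.write(f"{contig}\t{j + 1}\tSNP_{j + 1}\tA\tT\t.\t.\t.\tGT\t{gts}\n")
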