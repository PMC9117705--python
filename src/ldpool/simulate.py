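"""Synthetic genotypes with controllable LD, trend tests, phenotype models
and the Monte Carlo type-I error / power harness.

Genotype generation uses a latent-Gaussian threshold model: each individual
carries two latent haplotype vectors drawn from MVN(0, Sigma) with Sigma
the target *latent* correlation structure; each latent value below the
normal quantile of the target MAF becomes a copy of the minor allele, and
the two alleles sum to the additive 0/1/2 code.  Thresholding attenuates
the realised genotype correlation relative to the latent one (tetrachoric
attenuation), so LD profiles are specified on the latent scale and the
realised LD is whatever :func:`estimate_ld` reports — which is exactly the
quantity the combining methods consume.

The harness mirrors a case-control design: a binary phenotype is drawn (iid
Bernoulli(0.5) under the null, or through a logistic model in one or more
causal SNPs under the alternative), each SNP is tested with the
Cochran-Armitage trend test, the resulting p-values are combined with each
requested method/adjustment pair, and the rejection rate over replicates
estimates the type-I error rate or power.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, ndtri

from .combine import combine_rows
from .datatypes import (
    GenotypeMatrix,
    GeneCharacteristics,
    InputError,
    LDMatrix,
    ScenarioSpec,
)
from .dependent import brown_fit, strube_variance
from .empirical import build_null, make_sampling_root
from .neff import combine_keff_rows, estimate_keff

__all__ = [
    "simulate_genotypes",
    "estimate_ld",
    "trend_test",
    "trend_test_matrix",
    "assign_phenotype",
    "run_scenario",
    "gene_characteristics",
]


def _latent_sigma(k: int, ld_profile: dict) -> np.ndarray:
    kind = ld_profile.get("kind", "independent")
    rho = float(ld_profile.get("rho", 0.0))
    if not np.isfinite(rho) or abs(rho) > 1.0:
        raise InputError("latent rho must lie in [-1, 1]")
    if kind == "independent" or rho == 0.0:
        return np.eye(k)
    if kind == "ar1":
        idx = np.arange(k)
        return rho ** np.abs(idx[:, None] - idx[None, :])
    if kind == "exchangeable":
        lo = -1.0 / (k - 1) if k > 1 else -1.0
        if rho < lo:
            raise InputError(
                f"exchangeable rho = {rho} is infeasible for k = {k}; attainable range is [{lo:.4f}, 1]"
            )
        S = np.full((k, k), rho)
        np.fill_diagonal(S, 1.0)
        return S
    if kind == "block":
        size = int(ld_profile.get("block_size", k))
        S = np.eye(k)
        for start in range(0, k, size):
            stop = min(start + size, k)
            S[start:stop, start:stop] = rho
        np.fill_diagonal(S, 1.0)
        return S
    raise InputError(f"unknown LD profile kind {kind!r}")


def _maf_targets(k: int, maf_profile, rng: np.random.Generator) -> np.ndarray:
    if isinstance(maf_profile, (int, float)):
        maf = np.full(k, float(maf_profile))
    elif isinstance(maf_profile, (tuple, list)) and len(maf_profile) == 3 and maf_profile[0] == "uniform":
        maf = rng.uniform(float(maf_profile[1]), float(maf_profile[2]), size=k)
    else:
        maf = np.asarray(maf_profile, dtype=float)
        if maf.shape != (k,):
            raise InputError("maf_profile array must have one entry per SNP")
    if np.any(maf <= 0.0) or np.any(maf > 0.5):
        raise InputError("target MAFs must lie in (0, 0.5]")
    return maf


def simulate_genotypes(
    n: int,
    k: int,
    ld_profile: Optional[dict] = None,
    maf_profile=0.3,
    seed=None,
    max_retries: int = 20,
) -> GenotypeMatrix:
    """Draw an n x k additive-coded genotype matrix under a latent-Gaussian
    haplotype model.

    Parameters
    ----------
    ld_profile : dict
        ``{"kind": "independent"|"ar1"|"exchangeable"|"block", "rho": float,
        "block_size": int}``; correlations are on the latent (haplotype)
        scale.
    maf_profile : float, array, or ("uniform", lo, hi)
        Target minor allele frequencies in (0, 0.5].
    max_retries : int
        The whole matrix is redrawn when a column comes out monomorphic
        (possible at small n or extreme MAF) so the LD structure stays
        intact; give up after this many attempts.
    """
    if n < 2 or k < 1:
        raise InputError("need n >= 2 individuals and k >= 1 SNPs")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = _latent_sigma(k, ld_profile or {})
    maf = _maf_targets(k, maf_profile, rng)
    try:
        L = np.linalg.cholesky(sigma + 1e-12 * np.eye(k))
    except np.linalg.LinAlgError as exc:
        raise InputError("latent LD profile is not positive semi-definite") from exc
    thresh = ndtri(maf)

    for _ in range(max_retries):
        latent = rng.standard_normal((2 * n, k)) @ L.T
        alleles = (latent < thresh[None, :]).astype(np.int8)
        G = alleles[:n] + alleles[n:]
        freq = G.mean(axis=0) / 2.0
        flip = freq > 0.5
        if np.any(flip):
            G[:, flip] = 2 - G[:, flip]
            freq = G.mean(axis=0) / 2.0
        if np.all((freq > 0.0) & (freq <= 0.5)):
            ids = tuple(f"snp{i + 1}" for i in range(k))
            return GenotypeMatrix(G, snp_ids=ids)
    raise InputError(
        f"could not draw a polymorphic genotype matrix in {max_retries} attempts "
        f"(n = {n}, min target MAF = {maf.min():.4f})"
    )


def _em_pair_r(x: np.ndarray, y: np.ndarray, n_iter: int = 200, tol: float = 1e-12) -> float:
    """Two-locus EM estimate of the haplotype (allelic) correlation under HWE.

    Phase is ambiguous only for double heterozygotes; the EM splits them
    between the coupling (AB/ab) and repulsion (Ab/aB) phases according to
    the current haplotype frequency estimates.
    """
    n = x.size
    counts = np.zeros((3, 3))
    np.add.at(counts, (x.astype(int), y.astype(int)), 1.0)
    # haplotype freq order: [AB, Ab, aB, ab] with A/B the minor alleles
    pA = x.mean() / 2.0
    pB = y.mean() / 2.0
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    h = np.clip(h, 1e-12, None)
    h /= h.sum()
    n_dh = counts[1, 1]
    # known haplotype contributions from unambiguous genotype cells
    known = np.array(
        [
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],  # AB
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0],  # Ab
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],  # aB
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],  # ab
        ]
    )
    for _ in range(n_iter):
        coup = h[0] * h[3]
        rep = h[1] * h[2]
        w = coup / (coup + rep) if (coup + rep) > 0 else 0.5
        new = known + n_dh * np.array([w, 1 - w, 1 - w, w])
        new /= 2.0 * n
        if np.max(np.abs(new - h)) < tol:
            h = new
            break
        h = new
    pA_hat, pB_hat = h[0] + h[1], h[0] + h[2]
    denom = pA_hat * (1 - pA_hat) * pB_hat * (1 - pB_hat)
    if denom <= 0:
        return 0.0
    D = h[0] - pA_hat * pB_hat
    return float(np.clip(D / math.sqrt(denom), -1.0, 1.0))


def estimate_ld(G: GenotypeMatrix, estimator: str = "composite") -> LDMatrix:
    """Estimate the LD map (allelic correlations) of a genotype matrix.

    ``composite``
        Pearson correlation of the 0/1/2 dosage columns; makes no HWE
        assumption.
    ``em_hwe``
        Pairwise two-locus EM haplotype-frequency estimation under HWE,
        returning ``r = D / sqrt(p_A p_a p_B p_b)``.
    """
    maf = G.maf
    if np.any(maf <= 0.0):
        bad = int(np.flatnonzero(maf <= 0.0)[0])
        raise InputError(f"monomorphic SNP at column {bad}: LD is undefined")
    if estimator == "composite":
        R = np.corrcoef(G.G.astype(float), rowvar=False)
        R = np.atleast_2d(R)
    elif estimator == "em_hwe":
        k = G.k
        R = np.eye(k)
        X = G.G
        for i in range(k):
            for j in range(i + 1, k):
                R[i, j] = R[j, i] = _em_pair_r(X[:, i], X[:, j])
    else:
        raise InputError(f"unknown LD estimator {estimator!r}")
    np.fill_diagonal(R, 1.0)
    return LDMatrix(np.clip(R, -1.0, 1.0), snp_ids=G.snp_ids)


def trend_test(geno: np.ndarray, pheno: np.ndarray) -> float:
    """Two-sided Cochran-Armitage trend test for one SNP.

    Scores the genotypes 0/1/2 and compares the squared standardised trend
    statistic to a chi-square with 1 df (equivalently ``2(1 - Phi(|z|))``).
    Degenerate tables — all individuals in one genotype class or one
    phenotype class — return p = 1.
    """
    p = trend_test_matrix(np.asarray(geno, dtype=float).reshape(-1, 1), np.asarray(pheno))
    return float(p[0, 0])


def trend_test_matrix(G: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorised trend tests for all SNP columns of G against each
    phenotype row of Y; returns an (n_phenotypes, k) matrix of two-sided
    p-values."""
    G = np.asarray(G, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, k = G.shape
    if Y.shape[1] != n:
        raise InputError("phenotype length must match the number of individuals")
    if not np.isin(Y, (0.0, 1.0)).all():
        raise InputError("phenotype must be binary 0/1")
    N = float(n)
    R = Y.sum(axis=1)  # cases per replicate
    Sx = G.sum(axis=0)
    Sxx = (G * G).sum(axis=0)
    T = N * (Y @ G) - R[:, None] * Sx[None, :]
    var = (R * (N - R))[:, None] / N * (N * Sxx - Sx * Sx)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, T / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[var <= 0] = 1.0
    return np.clip(p, 1e-300, 1.0)


def _select_causal(k: int, spec: ScenarioSpec, rng: np.random.Generator) -> np.ndarray:
    """Indices of the causal SNPs for one iteration of a power scenario."""
    if spec.causal == "single":
        return np.array([rng.integers(0, k)])
    pct = 0.05 if spec.causal == "pct5" else 0.20
    m = int(round(k * pct))
    if m < 1:
        warnings.warn(
            f"{spec.causal} of k = {k} SNPs rounds to zero causal SNPs; using 1", stacklevel=2
        )
        m = 1
    if spec.compact:
        limit = max(1, min(int(math.floor(k * (1.0 - pct))), k - m + 1))
        start = int(rng.integers(0, limit))
        return np.arange(start, start + m)
    return np.unique(np.round(np.linspace(0, k - 1, m)).astype(int))


def assign_phenotype(
    G: Union[GenotypeMatrix, np.ndarray],
    spec: ScenarioSpec,
    seed=None,
    causal_idx: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Draw a binary phenotype for the individuals of G under a scenario.

    Under the null the phenotype is iid Bernoulli(0.5).  Otherwise the case
    probability follows a logistic model in the causal SNP dosages, with the
    per-SNP coefficient equal to the effect size (or the effect size divided
    by the number of causal SNPs when ``distributed``) and the intercept set
    to minus the mean linear predictor, so that about half the sample are
    cases.
    """
    X = G.G if isinstance(G, GenotypeMatrix) else np.asarray(G)
    n, k = X.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if spec.causal == "null":
        return rng.binomial(1, 0.5, size=n).astype(np.int8)
    idx = _select_causal(k, spec, rng) if causal_idx is None else np.asarray(causal_idx)
    beta = np.zeros(k)
    beta[idx] = spec.effect_size / idx.size if spec.distributed else spec.effect_size
    eta = X @ beta
    beta0 = -eta.sum() / n
    pi = expit(beta0 + eta)
    return (rng.random(n) < pi).astype(np.int8)


_KEFF_ADJ = ("nyholt", "liji", "gao", "galwey")
_VALID_ADJ = ("none",) + _KEFF_ADJ + ("empirical", "dependent")

#: The method/adjustment panel reported by default: every base combiner
#: unadjusted, keff-adjusted and empirically calibrated, plus the two
#: combiners with a dependence-aware analytic form.
DEFAULT_METHODS = tuple(
    (m, a)
    for m in ("bonferroni", "tippett", "binomial", "fisher", "stouffer")
    for a in ("none",) + _KEFF_ADJ + ("empirical",)
) + (("fisher", "dependent"), ("stouffer", "dependent"))


def run_scenario(
    genes: Union[GenotypeMatrix, Sequence[GenotypeMatrix]],
    spec: ScenarioSpec,
    methods: Iterable = (("bonferroni", "none"), ("fisher", "none"), ("fisher", "dependent")),
    seed=None,
    gene_ids: Optional[Sequence[str]] = None,
    s_empirical: int = 10_000,
    ld_estimator: str = "composite",
    alpha_p: float = 0.05,
    gao_C: float = 0.995,
) -> pd.DataFrame:
    """Monte Carlo rejection rates of method/adjustment pairs over genes.

    For each gene the LD map is estimated once from the original genotypes
    (repaired to the nearest positive-definite correlation matrix when
    needed) and all p-value-independent machinery — keff estimates, the
    Brown moment fit, the Strube variance, empirical null distributions —
    is precomputed.  Each replicate then draws a phenotype (bootstrapping
    ``spec.n`` individuals when requested or when ``spec.n`` differs from
    the gene's sample size), runs the trend tests and combines.  Per-gene
    RNG substreams are spawned from the master seed, so results do not
    depend on gene order or parallel scheduling.

    Returns a tidy table with one row per gene x method x adjustment and
    the rejection rate at ``spec.alpha``.
    """
    if isinstance(genes, GenotypeMatrix):
        genes = [genes]
    methods = list(methods)
    for m, a in methods:
        if a not in _VALID_ADJ:
            raise InputError(f"unknown adjustment {a!r}")
        if a == "dependent" and m not in ("fisher", "stouffer"):
            raise InputError("the dependence adjustment exists only for fisher (Brown) and stouffer (Strube)")
    if gene_ids is None:
        gene_ids = [f"gene{i + 1}" for i in range(len(genes))]
    master = np.random.SeedSequence(seed)
    substreams = master.spawn(len(genes))

    rows = []
    for gene, gid, ss in zip(genes, gene_ids, substreams):
        rng = np.random.default_rng(ss)
        R_raw = estimate_ld(gene, estimator=ld_estimator)
        root = make_sampling_root(R_raw)
        R = root.R_used  # repaired matrix feeds every adjustment

        keffs = {
            est: estimate_keff(R, est, C=gao_C)
            for est in _KEFF_ADJ
            if any(a == est for _, a in methods)
        }
        fit = brown_fit(R) if ("fisher", "dependent") in methods else None
        svar = strube_variance(R) if ("stouffer", "dependent") in methods else None
        nulls = {
            m: build_null(R, m, s=s_empirical, seed=rng, alpha_p=alpha_p)
            for m in {m for m, a in methods if a == "empirical"}
        }

        X0 = gene.G.astype(float)
        bootstrap = spec.bootstrap or spec.n != gene.n
        P = np.empty((spec.reps, gene.k))
        for rep in range(spec.reps):
            if bootstrap:
                X = X0[rng.integers(0, gene.n, size=spec.n)]
            else:
                X = X0
            y = assign_phenotype(
                X,
                spec,
                seed=rng,
                causal_idx=None if spec.reselect_causal else _select_causal(gene.k, spec, rng),
            )
            P[rep] = trend_test_matrix(X, y)[0]

        for m, a in methods:
            if a == "none":
                pc = combine_rows(P, m, alpha_p=alpha_p)
            elif a in _KEFF_ADJ:
                pc = combine_keff_rows(P, keffs[a], m, alpha_p=alpha_p)
            elif a == "empirical":
                pc = nulls[m].lookup(combine_rows(P, m, alpha_p=alpha_p))
            else:  # dependent
                if m == "fisher":
                    x2 = -2.0 * np.log(P).sum(axis=1)
                    pc = stats.chi2.sf(x2 / fit.c, fit.f)
                else:
                    z = -ndtri(np.clip(P, 1e-300, 1 - 1e-16)).sum(axis=1) / np.sqrt(svar)
                    pc = stats.norm.sf(z)
            rows.append(
                {
                    "gene_id": gid,
                    "method": m,
                    "adjustment": a,
                    "n": spec.n,
                    "causal": spec.causal,
                    "effect_size": spec.effect_size,
                    "distributed": spec.distributed,
                    "compact": spec.compact,
                    "reps": spec.reps,
                    "rate": float(np.mean(pc <= spec.alpha)),
                    "ld_repaired": root.repaired,
                }
            )
    return pd.DataFrame(rows)


def gene_characteristics(R: LDMatrix, G: Optional[GenotypeMatrix] = None) -> GeneCharacteristics:
    """Summaries of a gene's LD map (and, optionally, allele frequencies).

    ``srmsc`` is the square root of the mean squared off-diagonal
    correlation: 0 when all SNPs are independent, close to 1 under strong LD
    of either sign.
    """
    k = R.k
    if k > 1:
        iu = np.triu_indices(k, 1)
        off = R.R[iu]
        mean_r = float(np.mean(off))
        sd_r = float(np.std(off, ddof=1)) if off.size > 1 else 0.0
        srmsc = float(np.sqrt(np.mean(off**2)))
    else:
        mean_r = sd_r = srmsc = 0.0
    mean_maf = sd_maf = None
    if G is not None:
        maf = G.maf
        mean_maf = float(np.mean(maf))
        sd_maf = float(np.std(maf, ddof=1)) if maf.size > 1 else 0.0
    return GeneCharacteristics(
        k=k, mean_r=mean_r, sd_r=sd_r, srmsc=srmsc, mean_maf=mean_maf, sd_maf=sd_maf
    )
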