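"""Effective number of independent tests from an LD map, and the
keff-adjusted versions of the five base combiners.

All four estimators start from the eigenvalues of the k x k allelic
correlation matrix.  On an identity matrix (independent SNPs) they return k
(Gao's estimator only when ``k (1 - C) <= 1``); on an all-ones matrix
(perfect LD, the same test repeated k times) they return 1.  Between those
extremes the estimators weigh the eigenvalue spectrum differently and
generally disagree.

The estimated keff then replaces k in each combiner: Bonferroni and Tippett
substitute keff directly; the binomial test rescales the significant count
to ``floor(r * keff / k)`` with ``floor(keff)`` trials; Fisher rescales the
statistic to ``(keff/k) X^2`` against ``2 keff`` degrees of freedom; and
Stouffer shrinks z by ``sqrt(keff/k)``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .combine import zquantile, _clamp
from .datatypes import (
    CombinedResult,
    EffectiveTests,
    InputError,
    LDMatrix,
    PValueSet,
)

__all__ = [
    "keff_nyholt",
    "keff_liji",
    "keff_gao",
    "keff_galwey",
    "estimate_keff",
    "combine_keff",
    "combine_keff_rows",
]


def keff_nyholt(R: LDMatrix, ddof: int = 1) -> EffectiveTests:
    """Cheverud-Nyholt estimator ``1 + (k - 1)(1 - Var(lambda)/k)``.

    ``ddof=1`` (the default) uses the sample variance of the eigenvalues
    with divisor k-1, matching the original proposal; ``ddof=0`` switches to
    the population variance.
    """
    lam = R.eigenvalues()
    k = R.k
    v = float(np.var(lam, ddof=ddof)) if k > 1 else 0.0
    keff = 1.0 + (k - 1) * (1.0 - v / k)
    return EffectiveTests(estimator="nyholt", keff=min(float(keff), float(k)), k=k)


def keff_liji(R: LDMatrix) -> EffectiveTests:
    """Li & Ji estimator ``sum f(|lambda_i|)`` with
    ``f(x) = I(x >= 1) + (x - floor(x))``."""
    lam = np.abs(R.eigenvalues())
    keff = float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    return EffectiveTests(estimator="liji", keff=min(keff, float(R.k)), k=R.k)


def keff_gao(R: LDMatrix, C: float = 0.995) -> EffectiveTests:
    """Gao estimator: the smallest x such that the top-x eigenvalues carry
    more than a fraction ``C`` of the total eigenvalue mass.

    Note that on an identity matrix this returns less than k whenever
    ``k (1 - C) > 1`` (e.g. 299 for k = 300 at the default C = 0.995).
    """
    if not (0.0 < C < 1.0):
        raise InputError("C must be in (0, 1)")
    lam = R.eigenvalues()  # already descending
    frac = np.cumsum(lam) / np.sum(lam)
    idx = np.flatnonzero(frac > C)
    keff = int(idx[0]) + 1 if idx.size else R.k
    return EffectiveTests(estimator="gao", keff=float(keff), k=R.k, C=C)


def keff_galwey(R: LDMatrix) -> EffectiveTests:
    """Galwey estimator ``(sum sqrt(lambda'_i))^2 / sum lambda'_i`` with
    negative eigenvalues floored at zero."""
    lam = np.maximum(R.eigenvalues(), 0.0)
    keff = float(np.sum(np.sqrt(lam)) ** 2 / np.sum(lam))
    return EffectiveTests(estimator="galwey", keff=min(keff, float(R.k)), k=R.k)


_ESTIMATORS = {
    "nyholt": keff_nyholt,
    "liji": keff_liji,
    "gao": keff_gao,
    "galwey": keff_galwey,
}


def estimate_keff(R: LDMatrix, estimator: str, C: float = 0.995) -> EffectiveTests:
    """Estimate the effective number of tests by name."""
    if estimator not in _ESTIMATORS:
        raise InputError(f"unknown estimator {estimator!r}; choose from {sorted(_ESTIMATORS)}")
    if estimator == "gao":
        return keff_gao(R, C=C)
    return _ESTIMATORS[estimator](R)


def combine_keff(
    pset: PValueSet,
    keff: EffectiveTests,
    method: str,
    alpha_p: float = 0.05,
) -> CombinedResult:
    """Combine p-values with the requested method at the effective number of
    tests rather than the raw SNP count.

    ``keff`` may be fractional (Nyholt and Galwey generally are); Bonferroni,
    Tippett, Fisher and Stouffer use it as-is (the chi-square distribution
    accepts non-integer degrees of freedom).  The binomial test needs an
    integer trial count, so keff is floored there — conservative rather than
    liberal.
    """
    if keff.k != pset.k:
        raise InputError(
            f"keff was estimated on a {keff.k}-SNP LD matrix but the p-value set has {pset.k} SNPs"
        )
    ke = float(keff.keff)
    k = pset.k
    adj = f"keff-{keff.estimator}"

    if method == "bonferroni":
        m = float(np.min(pset.p))
        p, stat, name, dof = min(1.0, m * ke), m, "min_p", ke
    elif method == "tippett":
        m = float(np.min(pset.p))
        p = -np.expm1(ke * np.log1p(-m)) if m < 1.0 else 1.0
        p, stat, name, dof = float(min(1.0, max(0.0, p))), m, "min_p", ke
    elif method == "binomial":
        if not (0.0 < alpha_p < 1.0):
            raise InputError("alpha_p must be in (0, 1)")
        ki = int(np.floor(ke))
        r = int(np.sum(pset.p <= alpha_p))
        r_eff = int(np.floor(r * ke / k))
        r_eff = min(r_eff, ki)
        p = 1.0 if r_eff == 0 else float(stats.binom.sf(r_eff - 1, ki, alpha_p))
        stat, name, dof = float(r_eff), "r", float(ki)
    elif method == "fisher":
        x2 = float(-2.0 * np.sum(np.log(_clamp(pset.p))))
        x2_adj = (ke / k) * x2
        p = float(stats.chi2.sf(x2_adj, 2.0 * ke))
        stat, name, dof = x2_adj, "X2", 2.0 * ke
    elif method == "stouffer":
        z = float(np.sum(zquantile(pset.p)) / np.sqrt(k))
        z_adj = np.sqrt(ke / k) * z
        p = float(stats.norm.sf(z_adj))
        stat, name, dof = z_adj, "z", ke
    else:
        raise InputError(f"unknown method {method!r}")

    return CombinedResult(
        gene_id=pset.gene_id,
        method=method,
        adjustment=adj,
        p=p,
        statistic=stat,
        statistic_name=name,
        df_or_keff=dof,
        info={"keff": ke, "estimator": keff.estimator},
    )


def combine_keff_rows(
    P: np.ndarray,
    keff: EffectiveTests,
    method: str,
    alpha_p: float = 0.05,
) -> np.ndarray:
    """Vectorised keff-adjusted combination of an (m, k) matrix of p-values.

    Row-wise counterpart of :func:`combine_keff`, used by the simulation
    harness; semantics match the scalar version exactly.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[1] != keff.k:
        raise InputError("P must be 2-d with one column per SNP of the LD matrix")
    ke = float(keff.keff)
    k = P.shape[1]
    if method == "bonferroni":
        return np.minimum(1.0, ke * P.min(axis=1))
    if method == "tippett":
        m = np.minimum(P.min(axis=1), 1.0 - 1e-16)
        return -np.expm1(ke * np.log1p(-m))
    if method == "binomial":
        ki = int(np.floor(ke))
        r_eff = np.minimum(np.floor((P <= alpha_p).sum(axis=1) * ke / k).astype(int), ki)
        out = np.ones(P.shape[0])
        nz = r_eff > 0
        out[nz] = stats.binom.sf(r_eff[nz] - 1, ki, alpha_p)
        return out
    if method == "fisher":
        x2 = -2.0 * np.log(_clamp(P)).sum(axis=1)
        return stats.chi2.sf((ke / k) * x2, 2.0 * ke)
    if method == "stouffer":
        z = zquantile(P).sum(axis=1) / np.sqrt(k)
        return stats.norm.sf(np.sqrt(ke / k) * z)
    raise InputError(f"unknown method {method!r}")
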