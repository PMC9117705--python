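"""Base methods for combining SNP-level p-values into a gene-level p-value.

All methods except Bonferroni assume the individual tests are independent;
the other modules of this package supply the LD-aware adjustments.  Every
combiner tests the joint null hypothesis that none of the SNPs in the gene
is associated with the phenotype, against the alternative that at least one
is.

p-values are clamped to ``[1e-300, 1 - 1e-16]`` before any log or normal
quantile transform; this changes nothing at reportable precision but keeps
``ln p`` finite and avoids the infinite quantile at p = 1.  The normal
quantile ``Phi^{-1}(1 - p)`` is always evaluated through the lower tail as
``-Phi^{-1}(p)`` so that very small p-values retain full relative accuracy.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .datatypes import CombinedResult, InputError, PValueSet

__all__ = [
    "bonferroni",
    "tippett",
    "binomial_test",
    "fisher",
    "stouffer",
    "combine",
]

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


def _clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _P_FLOOR, _P_CEIL)


def zquantile(p) -> np.ndarray:
    """``Phi^{-1}(1 - p)`` evaluated via the lower tail for accuracy."""
    return -ndtri(_clamp(np.asarray(p, dtype=float)))


def bonferroni(pset: PValueSet) -> CombinedResult:
    """Bonferroni combination: ``p = min(1, k * min(p_i))``.

    Valid under arbitrary dependence among the tests: the familywise type-I
    error rate never exceeds the nominal level, at the cost of growing
    conservativeness when the SNPs are in strong LD.
    """
    m = float(np.min(pset.p))
    return CombinedResult(
        gene_id=pset.gene_id,
        method="bonferroni",
        adjustment="none",
        p=min(1.0, pset.k * m),
        statistic=m,
        statistic_name="min_p",
        df_or_keff=float(pset.k),
    )


def tippett(pset: PValueSet) -> CombinedResult:
    """Tippett / Dunn-Sidak combination: ``p = 1 - (1 - min(p_i))^k``.

    Exact under independence; equals Bonferroni to first order for small
    minimum p-values and is never larger.
    """
    m = float(np.min(pset.p))
    p = -np.expm1(pset.k * np.log1p(-m)) if m < 1.0 else 1.0
    return CombinedResult(
        gene_id=pset.gene_id,
        method="tippett",
        adjustment="none",
        p=float(min(1.0, max(0.0, p))),
        statistic=m,
        statistic_name="min_p",
        df_or_keff=float(pset.k),
    )


def binomial_test(pset: PValueSet, alpha_p: float = 0.05) -> CombinedResult:
    """Test of excess significance: is the count of SNPs significant at
    ``alpha_p`` larger than a Binomial(k, alpha_p) null allows?

    ``r`` counts p-values at or below ``alpha_p`` (ties inclusive) and the
    combined p-value is the upper binomial tail ``P(X >= r)``; ``r = 0``
    yields 1.
    """
    if not (0.0 < alpha_p < 1.0):
        raise InputError("alpha_p must be in (0, 1)")
    r = int(np.sum(pset.p <= alpha_p))
    p = 1.0 if r == 0 else float(stats.binom.sf(r - 1, pset.k, alpha_p))
    return CombinedResult(
        gene_id=pset.gene_id,
        method="binomial",
        adjustment="none",
        p=p,
        statistic=float(r),
        statistic_name="r",
        df_or_keff=float(pset.k),
        info={"alpha_p": alpha_p},
    )


def fisher(pset: PValueSet) -> CombinedResult:
    """Fisher's method: ``X^2 = -2 sum ln p_i`` against chi-square with 2k df."""
    x2 = float(-2.0 * np.sum(np.log(_clamp(pset.p))))
    df = 2 * pset.k
    return CombinedResult(
        gene_id=pset.gene_id,
        method="fisher",
        adjustment="none",
        p=float(stats.chi2.sf(x2, df)),
        statistic=x2,
        statistic_name="X2",
        df_or_keff=float(df),
    )


def stouffer(pset: PValueSet) -> CombinedResult:
    """Stouffer's method: ``z = sum Phi^{-1}(1 - p_i) / sqrt(k)`` against N(0,1)."""
    z = float(np.sum(zquantile(pset.p)) / np.sqrt(pset.k))
    return CombinedResult(
        gene_id=pset.gene_id,
        method="stouffer",
        adjustment="none",
        p=float(stats.norm.sf(z)),
        statistic=z,
        statistic_name="z",
        df_or_keff=None,
    )


_DISPATCH = {
    "bonferroni": bonferroni,
    "tippett": tippett,
    "binomial": binomial_test,
    "fisher": fisher,
    "stouffer": stouffer,
}


def combine(pset: PValueSet, method: str, alpha_p: float = 0.05) -> CombinedResult:
    """Apply one of the five base combiners by name."""
    if method not in _DISPATCH:
        raise InputError(f"unknown method {method!r}; choose from {sorted(_DISPATCH)}")
    if method == "binomial":
        return binomial_test(pset, alpha_p=alpha_p)
    return _DISPATCH[method](pset)


def combine_rows(P: np.ndarray, method: str, alpha_p: float = 0.05) -> np.ndarray:
    """Vectorised row-wise combination of an (m, k) matrix of p-values.

    Used by the empirical-null machinery and the simulation harness, where
    the same combiner is applied to many replicate p-vectors; returns one
    combined p-value per row.  Semantics match the scalar combiners exactly.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2:
        raise InputError("P must be 2-d (replicates x SNPs)")
    k = P.shape[1]
    if method == "bonferroni":
        return np.minimum(1.0, k * P.min(axis=1))
    if method == "tippett":
        return -np.expm1(k * np.log1p(-np.minimum(P.min(axis=1), _P_CEIL)))
    if method == "binomial":
        r = (P <= alpha_p).sum(axis=1)
        out = np.ones(P.shape[0])
        nz = r > 0
        out[nz] = stats.binom.sf(r[nz] - 1, k, alpha_p)
        return out
    if method == "fisher":
        x2 = -2.0 * np.log(_clamp(P)).sum(axis=1)
        return stats.chi2.sf(x2, 2 * k)
    if method == "stouffer":
        z = zquantile(P).sum(axis=1) / np.sqrt(k)
        return stats.norm.sf(z)
    raise InputError(f"unknown method {method!r}")
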