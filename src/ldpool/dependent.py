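"""Dependence-aware combiners: Brown's method and Strube's method.

Both methods model the latent SNP test statistics as multivariate normal
with correlation matrix equal to the LD map R.  Brown's method keeps
Fisher's statistic ``X^2 = -2 sum ln p_i`` but refers it to a moment-matched
scaled chi-square ``c * chi2_f``, where the mean ``E(X^2) = 2k`` and the
variance ``Var(X^2) = 4k + 2 sum_{i<j} Cov(-2 ln p_i, -2 ln p_j)`` absorb
the pairwise dependence.  Strube's method keeps Stouffer's numerator but
inflates its null variance to ``k + 2 sum_{i<j} Cov(Phi^{-1}(1-p_i),
Phi^{-1}(1-p_j))``.

The pairwise covariance of the transformed p-values is a two-dimensional
integral against the bivariate standard normal density with correlation
rho.  For two-sided p-values ``p = 2(1 - Phi(|z|))`` the integrand depends
on |z| only, so the integral is folded into the positive quadrant and
evaluated with panelled Gauss-Legendre quadrature (panels graded toward
zero to absorb the weak singularity of the Stouffer-scale transform).  The
one-sided Fisher integrand is smooth, so a rotated Gauss-Hermite rule is
used there.  Absolute accuracy is below 1e-6 for all |rho| <= 0.999; beyond
that the degenerate closed forms take over.

By default covariances are read from a lazily built lookup table on a
0.001-spaced rho grid with monotone cubic (PCHIP) interpolation — a gene
with k SNPs needs k(k-1)/2 pairwise terms, so per-pair quadrature would be
the bottleneck.  Pass ``exact=True`` to integrate each term directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator
from scipy.special import log_ndtr, ndtr, ndtri

from .combine import zquantile, _clamp
from .datatypes import ComputationError, CombinedResult, InputError, LDMatrix, PValueSet

__all__ = ["cov_term", "cov_terms", "brown", "strube", "brown_fit", "BrownFit"]

# Variance of -2 ln p for p ~ Uniform(0,1): the rho = +/-1 limit on the
# Fisher scales.  The one-sided Fisher kernel at rho = -1 is
# 4 E[ln p ln(1-p)] - 4 = 4(2 - pi^2/6) - 4.
_FISHER_VAR = 4.0
_FISHER1_MIN = 4.0 * (2.0 - np.pi**2 / 6.0) - 4.0

#: Theoretically attainable covariance range per (side, scale); interpolated
#: values are clipped here before summation.
_RANGES = {
    ("two", "fisher"): (0.0, 4.0),
    ("two", "stouffer"): (0.0, 1.0),
    ("one", "fisher"): (_FISHER1_MIN, 4.0),
    ("one", "stouffer"): (-1.0, 1.0),
}

_RHO_SWITCH = 0.999  # beyond this, the degenerate closed form is used
_GRID_STEP = 0.001
_GL_NODES = 48
_PANELS = (0.0, 1e-4, 1e-2, 0.1, 0.5, 1.0, 2.0, 3.5, 5.0, 8.0)


def _log_two_sided(a: np.ndarray) -> np.ndarray:
    """ln(2(1 - Phi(a))) for a >= 0."""
    return np.log(2.0) + log_ndtr(-a)


def _stouffer_two_sided(a: np.ndarray) -> np.ndarray:
    """Phi^{-1}(1 - 2(1 - Phi(a))) = Phi^{-1}(2 Phi(a) - 1) for a >= 0."""
    return ndtri(np.clip(2.0 * ndtr(a) - 1.0, 1e-320, 1.0))


def _panel_rule(n: int = _GL_NODES):
    x, w = np.polynomial.legendre.leggauss(n)
    nodes, wts = [], []
    for lo, hi in zip(_PANELS[:-1], _PANELS[1:]):
        nodes.append(0.5 * (hi - lo) * x + 0.5 * (hi + lo))
        wts.append(0.5 * (hi - lo) * w)
    return np.concatenate(nodes), np.concatenate(wts)


def _quad_two_sided(rho: float, scale: str) -> float:
    """Folded positive-quadrant quadrature for the two-sided kernels."""
    a, wa = _panel_rule()
    h = _log_two_sided(a) if scale == "fisher" else _stouffer_two_sided(a)
    u = wa * h
    A, B = a[:, None], a[None, :]
    s = 1.0 - rho * rho
    c = 1.0 / (2.0 * np.pi * np.sqrt(s))
    # both exponents are <= 0 for |rho| <= 1, so exp never overflows
    fp = np.exp(-(A * A - 2.0 * rho * A * B + B * B) / (2.0 * s))
    fm = np.exp(-(A * A + 2.0 * rho * A * B + B * B) / (2.0 * s))
    dens = 2.0 * c * (fp + fm)
    integral = float(u @ dens @ u)
    if scale == "fisher":
        return 4.0 * integral - 4.0
    return integral


def _quad_one_sided_fisher(rho: float, n: int = 200) -> float:
    """Rotated Gauss-Hermite quadrature for the smooth one-sided kernel."""
    x, w = np.polynomial.hermite_e.hermegauss(n)
    w = w / np.sqrt(2.0 * np.pi)
    u = x * np.sqrt(1.0 + rho)
    v = x * np.sqrt(1.0 - rho)
    zi = (u[:, None] + v[None, :]) / np.sqrt(2.0)
    zj = (u[:, None] - v[None, :]) / np.sqrt(2.0)
    integral = float(np.einsum("i,j,ij->", w, w, log_ndtr(-zi) * log_ndtr(-zj)))
    return 4.0 * integral - 4.0


def _degenerate(rho: float, side: str, scale: str) -> float:
    if side == "two":
        return _FISHER_VAR if scale == "fisher" else 1.0
    if scale == "stouffer":
        return float(np.sign(rho))
    return _FISHER_VAR if rho > 0 else _FISHER1_MIN


def _exact_cov(rho: float, side: str, scale: str) -> float:
    if abs(rho) > _RHO_SWITCH:
        return _degenerate(rho, side, scale)
    if side == "one" and scale == "stouffer":
        return float(rho)  # Phi^{-1}(1-p) is the z statistic itself
    if side == "two":
        return _quad_two_sided(abs(rho), scale)
    return _quad_one_sided_fisher(rho)


_CACHE: dict = {}


def _interpolator(side: str, scale: str) -> PchipInterpolator:
    key = (side, scale)
    if key not in _CACHE:
        if side == "two":
            grid = np.arange(0.0, _RHO_SWITCH + 0.5 * _GRID_STEP, _GRID_STEP)
            vals = np.array([_quad_two_sided(r, scale) for r in grid])
            grid = np.append(grid, 1.0)
            vals = np.append(vals, _degenerate(1.0, side, scale))
        else:  # one-sided fisher
            grid = np.arange(-_RHO_SWITCH, _RHO_SWITCH + 0.5 * _GRID_STEP, _GRID_STEP)
            vals = np.array([_quad_one_sided_fisher(r) for r in grid])
            grid = np.concatenate(([-1.0], grid, [1.0]))
            vals = np.concatenate(([_FISHER1_MIN], vals, [_FISHER_VAR]))
        _CACHE[key] = PchipInterpolator(grid, vals, extrapolate=False)
    return _CACHE[key]


def _check_side_scale(side: str, scale: str) -> None:
    if side not in ("one", "two"):
        raise InputError("side must be 'one' or 'two'")
    if scale not in ("fisher", "stouffer"):
        raise InputError("scale must be 'fisher' or 'stouffer'")


def cov_terms(
    rho,
    side: str = "two",
    scale: str = "fisher",
    exact: bool = False,
) -> np.ndarray:
    """Vectorised pairwise covariance of transformed p-values.

    Parameters
    ----------
    rho : array_like
        Pairwise SNP correlations in [-1, 1].
    side : {'two', 'one'}
        Whether the SNP p-values are two-sided (``p = 2(1 - Phi(|z|))``,
        the GWAS default) or one-sided (``p = 1 - Phi(z)``).
    scale : {'fisher', 'stouffer'}
        Transform whose covariance is required: ``-2 ln p`` (Brown) or
        ``Phi^{-1}(1 - p)`` (Strube).
    exact : bool
        Integrate every term directly instead of reading the interpolation
        table.
    """
    _check_side_scale(side, scale)
    rho = np.asarray(rho, dtype=float)
    if not np.all(np.isfinite(rho)):
        raise InputError("correlations must be finite")
    if np.any(np.abs(rho) > 1.0 + 1e-9):
        raise InputError("correlations must lie in [-1, 1]")
    rho = np.clip(rho, -1.0, 1.0)

    if side == "one" and scale == "stouffer":
        return rho.copy()

    if exact:
        out = np.array([_exact_cov(float(r), side, scale) for r in np.atleast_1d(rho)])
        out = out.reshape(rho.shape)
    else:
        interp = _interpolator(side, scale)
        arg = np.abs(rho) if side == "two" else rho
        out = np.asarray(interp(arg), dtype=float).reshape(rho.shape)
    lo, hi = _RANGES[(side, scale)]
    return np.clip(out, lo, hi)


def cov_term(rho: float, side: str = "two", scale: str = "fisher", exact: bool = False) -> float:
    """Scalar convenience wrapper around :func:`cov_terms`."""
    if not np.isfinite(rho):
        raise InputError("rho must be finite")
    return float(cov_terms(np.array(rho), side=side, scale=scale, exact=exact))


@dataclass(frozen=True)
class BrownFit:
    """Moment-matched scaled chi-square ``X^2 ~ c * chi2_f``.

    Under independence ``c = 1`` and ``f = 2k``; dependence inflates
    ``Var(X^2)`` above ``4k`` which raises c and lowers f.
    """

    c: float
    f: float
    EX2: float
    VarX2: float


def brown_fit(R: LDMatrix, side: str = "two", exact: bool = False) -> BrownFit:
    """Moment-match the null distribution of Fisher's X^2 under the LD map R."""
    k = R.k
    iu = np.triu_indices(k, 1)
    cov_sum = float(np.sum(cov_terms(R.R[iu], side=side, scale="fisher", exact=exact)))
    ex2 = 2.0 * k
    var = 4.0 * k + 2.0 * cov_sum
    if var <= 0.0:
        raise ComputationError(
            f"moment-matched Var(X^2) = {var:.4g} <= 0 for the supplied {k}x{k} LD matrix"
        )
    return BrownFit(c=var / (2.0 * ex2), f=2.0 * ex2**2 / var, EX2=ex2, VarX2=var)


def brown(
    pset: PValueSet,
    R: LDMatrix,
    side: str = "two",
    exact: bool = False,
) -> CombinedResult:
    """Brown's method: Fisher's statistic against a moment-matched scaled
    chi-square that accounts for LD.

    ``side='two'`` (default) uses the two-sided covariance kernel and is the
    correct choice when the SNP p-values come from two-sided tests;
    ``side='one'`` reproduces the original one-sided construction.
    """
    if R.k != pset.k:
        raise InputError(f"LD matrix is {R.k}x{R.k} but the p-value set has {pset.k} SNPs")
    fit = brown_fit(R, side=side, exact=exact)
    x2 = float(-2.0 * np.sum(np.log(_clamp(pset.p))))
    p = float(stats.chi2.sf(x2 / fit.c, fit.f))
    return CombinedResult(
        gene_id=pset.gene_id,
        method="fisher",
        adjustment=f"brown-{side}-sided",
        p=p,
        statistic=x2,
        statistic_name="X2",
        df_or_keff=fit.f,
        info={"c": fit.c, "f": fit.f, "VarX2": fit.VarX2, "side": side},
    )


def strube_variance(R: LDMatrix, exact: bool = False) -> float:
    """Null variance of ``sum Phi^{-1}(1 - p_i)`` under the LD map R."""
    k = R.k
    iu = np.triu_indices(k, 1)
    cov_sum = float(np.sum(cov_terms(R.R[iu], side="two", scale="stouffer", exact=exact)))
    var = k + 2.0 * cov_sum
    if var <= 0.0:
        raise ComputationError(
            f"variance of the Stouffer sum = {var:.4g} <= 0 for the supplied {k}x{k} LD matrix"
        )
    return var


def strube(pset: PValueSet, R: LDMatrix, exact: bool = False) -> CombinedResult:
    """Strube's method: Stouffer's sum with its null variance inflated by the
    pairwise covariances of the normal quantiles under LD."""
    if R.k != pset.k:
        raise InputError(f"LD matrix is {R.k}x{R.k} but the p-value set has {pset.k} SNPs")
    var = strube_variance(R, exact=exact)
    z = float(np.sum(zquantile(pset.p)) / np.sqrt(var))
    return CombinedResult(
        gene_id=pset.gene_id,
        method="stouffer",
        adjustment="strube",
        p=float(stats.norm.sf(z)),
        statistic=z,
        statistic_name="z",
        df_or_keff=None,
        info={"var": var},
    )
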