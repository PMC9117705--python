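"""Pseudo-permutation empirical null distributions.

Instead of permuting raw genotype data (which may not be available), the
joint null of a gene is emulated by sampling rows of correlated standard
normal test statistics ``Z ~ MVN(0, R)`` with R the LD map, converting each
row to two-sided p-values ``P = 2(1 - Phi(|Z|))`` and combining each row
with the chosen base method.  The gene-level p-value is then the fraction
of pseudo-replicates whose combined p-value is at or below the observed one
(ties inclusive):  ``p = sum I(p_j <= p_obs) / s``.

If R is not positive definite it is first projected to the nearest
positive-definite correlation matrix (alternating projections with a unit
diagonal constraint and an eigenvalue floor of 1e-8); the repair is recorded
in the result metadata and the repaired matrix is what gets sampled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import ndtr
from statsmodels.stats.correlation_tools import corr_nearest

from .combine import combine, combine_rows
from .datatypes import CombinedResult, InputError, LDMatrix, PValueSet

__all__ = ["SamplingRoot", "make_sampling_root", "EmpiricalNull", "build_null", "empirical_combine"]

_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class SamplingRoot:
    """A matrix factor ``F`` with ``F F' = R`` suitable for MVN sampling."""

    factor: np.ndarray
    R_used: LDMatrix
    repaired: bool

    def sample(self, s: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``s`` rows of MVN(0, R) statistics."""
        return rng.standard_normal((s, self.factor.shape[1])) @ self.factor.T


def make_sampling_root(R: LDMatrix) -> SamplingRoot:
    """Return a factor of R for multivariate-normal sampling.

    A Cholesky factor is used when R is positive definite.  Otherwise R is
    repaired to the nearest positive-definite correlation matrix first and
    the eigen-factor of the repaired matrix is returned.
    """
    M = R.R
    try:
        L = np.linalg.cholesky(M)
        return SamplingRoot(factor=L, R_used=R, repaired=False)
    except np.linalg.LinAlgError:
        pass
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # corr_nearest warns at its iteration cap
        fixed = np.asarray(corr_nearest(M, threshold=_EIG_FLOOR, n_fact=200))
    fixed = 0.5 * (fixed + fixed.T)
    np.fill_diagonal(fixed, 1.0)
    lam, V = np.linalg.eigh(fixed)
    if lam.min() < _EIG_FLOOR:
        # final exact projection: floor the spectrum, restore the unit diagonal
        lam = np.maximum(lam, _EIG_FLOOR)
        fixed = (V * lam) @ V.T
        d = np.sqrt(np.diag(fixed))
        fixed = fixed / np.outer(d, d)
        fixed = 0.5 * (fixed + fixed.T)
        np.fill_diagonal(fixed, 1.0)
    R_fixed = LDMatrix(fixed, snp_ids=R.snp_ids)
    lam, V = np.linalg.eigh(fixed)
    lam = np.maximum(lam, 0.0)
    F = V * np.sqrt(lam)
    return SamplingRoot(factor=F, R_used=R_fixed, repaired=True)


@dataclass(frozen=True)
class EmpiricalNull:
    """Sorted combined p-values of ``s`` pseudo-replicates under the joint null.

    Built once per (gene, method); locating any number of observed combined
    p-values in it is then a binary search.
    """

    method: str
    null_ps: np.ndarray  # sorted ascending
    s: int
    seed: Optional[int]
    repaired: bool

    def lookup(self, p_obs, plus_one: bool = False):
        """Fraction of null replicates with ``p_j <= p_obs``.

        ``plus_one=True`` returns ``(1 + count) / (1 + s)``, which cannot be
        zero and is convenient on the -log10 scale.
        """
        count = np.searchsorted(self.null_ps, p_obs, side="right")
        if plus_one:
            return (1.0 + count) / (1.0 + self.s)
        return count / self.s


def build_null(
    R: LDMatrix,
    method: str,
    s: int = 100_000,
    seed=None,
    alpha_p: float = 0.05,
) -> EmpiricalNull:
    """Construct the empirical null of a base combiner under the LD map R."""
    if s < 1:
        raise InputError("s must be >= 1")
    if s < 1000:
        warnings.warn(
            f"s = {s} pseudo-replicates is below 1000; the empirical p-value will be coarse",
            stacklevel=2,
        )
    root = make_sampling_root(R)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Z = root.sample(int(s), rng)
    P = 2.0 * ndtr(-np.abs(Z))  # two-sided p-values, vectorised
    np.clip(P, 1e-320, 1.0, out=P)
    null_ps = np.sort(combine_rows(P, method, alpha_p=alpha_p))
    return EmpiricalNull(
        method=method,
        null_ps=null_ps,
        s=int(s),
        seed=seed if not isinstance(seed, np.random.Generator) else None,
        repaired=root.repaired,
    )


def empirical_combine(
    pset: PValueSet,
    R: LDMatrix,
    method: str,
    s: int = 100_000,
    seed=None,
    alpha_p: float = 0.05,
    plus_one: bool = False,
) -> CombinedResult:
    """Combine p-values with a base method and calibrate against the
    pseudo-permutation null.

    Deterministic given ``seed``.  The plain estimator can return exactly 0
    when the observed combined p-value beats every pseudo-replicate; pass
    ``plus_one=True`` for the (1 + count)/(1 + s) variant.
    """
    if R.k != pset.k:
        raise InputError(f"LD matrix is {R.k}x{R.k} but the p-value set has {pset.k} SNPs")
    obs = combine(pset, method, alpha_p=alpha_p)
    null = build_null(R, method, s=s, seed=seed, alpha_p=alpha_p)
    p = float(null.lookup(obs.p, plus_one=plus_one))
    return CombinedResult(
        gene_id=pset.gene_id,
        method=method,
        adjustment="empirical",
        p=p,
        statistic=obs.statistic,
        statistic_name=obs.statistic_name,
        df_or_keff=None,
        info={
            "p_obs": obs.p,
            "s": int(s),
            "seed": null.seed,
            "repaired": null.repaired,
            "plus_one": plus_one,
        },
    )
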