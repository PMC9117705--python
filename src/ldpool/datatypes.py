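"""Core containers shared across the package.

The central objects are :class:`PValueSet` (the SNP-level evidence for one
gene), :class:`LDMatrix` (the pairwise allelic-correlation "LD map" of those
SNPs) and :class:`CombinedResult` (a gene-level p-value with the metadata
needed to reproduce it).  All containers validate their invariants at
construction time so that downstream numerics can assume clean input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "PValueSet",
    "LDMatrix",
    "CombinedResult",
    "EffectiveTests",
    "GenotypeMatrix",
    "ScenarioSpec",
    "GeneCharacteristics",
    "InputError",
    "ComputationError",
]

#: Combiner names recognised throughout the package.
METHODS = ("bonferroni", "tippett", "binomial", "fisher", "stouffer")

#: Effective-number-of-tests estimators.
KEFF_ESTIMATORS = ("nyholt", "liji", "gao", "galwey")

SYMMETRY_TOL = 1e-12


class InputError(ValueError):
    """Raised when user-supplied input violates a documented precondition."""


class ComputationError(RuntimeError):
    """Raised when a computation cannot produce a valid result (e.g. a
    non-positive moment-matched variance)."""


@dataclass(frozen=True)
class PValueSet:
    """Ordered two-sided SNP p-values for one gene.

    Parameters
    ----------
    gene_id : str
        Label for the gene (or any other SNP grouping such as a pathway).
    p : numpy.ndarray
        Two-sided p-values, one per SNP, each in (0, 1].  Zero p-values are
        rejected because ``ln p`` and the normal quantile of ``1 - p`` are
        undefined at 0.
    snp_ids : sequence of str, optional
        SNP labels in the same order as ``p``.
    """

    gene_id: str
    p: np.ndarray
    snp_ids: Optional[tuple] = None

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise InputError("p must be a non-empty 1-d sequence of p-values")
        if not np.all(np.isfinite(p)):
            raise InputError("p-values must be finite")
        if np.any(p <= 0.0) or np.any(p > 1.0):
            raise InputError("p-values must lie in (0, 1]; zero p-values are not representable")
        object.__setattr__(self, "p", p)
        if self.snp_ids is not None:
            ids = tuple(str(s) for s in self.snp_ids)
            if len(ids) != p.size:
                raise InputError("snp_ids length must match the number of p-values")
            object.__setattr__(self, "snp_ids", ids)

    @property
    def k(self) -> int:
        """Number of SNPs."""
        return int(self.p.size)


@dataclass(frozen=True)
class LDMatrix:
    """A k x k matrix of pairwise allelic correlations (an "LD map").

    The matrix is symmetrised on input (tolerance 1e-12), must have a unit
    diagonal and entries in [-1, 1].  Positive definiteness is checked lazily
    from the eigenvalues of the symmetrised matrix.
    """

    R: np.ndarray
    snp_ids: Optional[tuple] = None

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1] or R.shape[0] < 1:
            raise InputError("LD matrix must be square")
        if not np.all(np.isfinite(R)):
            raise InputError("LD matrix entries must be finite")
        if np.max(np.abs(R - R.T)) > SYMMETRY_TOL * max(1.0, np.max(np.abs(R))):
            raise InputError("LD matrix must be symmetric (tolerance 1e-12)")
        R = 0.5 * (R + R.T)
        if np.max(np.abs(np.diag(R) - 1.0)) > 1e-8:
            raise InputError("LD matrix must have a unit diagonal")
        if np.max(np.abs(R)) > 1.0 + 1e-8:
            raise InputError("correlations must lie in [-1, 1]")
        np.fill_diagonal(R, 1.0)
        np.clip(R, -1.0, 1.0, out=R)
        R.setflags(write=False)
        object.__setattr__(self, "R", R)
        if self.snp_ids is not None:
            ids = tuple(str(s) for s in self.snp_ids)
            if len(ids) != R.shape[0]:
                raise InputError("snp_ids length must match matrix dimension")
            object.__setattr__(self, "snp_ids", ids)

    @property
    def k(self) -> int:
        return int(self.R.shape[0])

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the symmetrised matrix, descending."""
        lam = np.linalg.eigvalsh(self.R)
        return lam[::-1]

    @property
    def is_positive_definite(self) -> bool:
        return bool(self.eigenvalues()[-1] > 0.0)

    @classmethod
    def identity(cls, k: int, snp_ids=None) -> "LDMatrix":
        return cls(np.eye(k), snp_ids=snp_ids)


@dataclass(frozen=True)
class CombinedResult:
    """A gene-level combined p-value with provenance metadata.

    ``statistic`` holds the intermediate quantity the method is based on
    (min p, the significant count r, Fisher's X^2, or Stouffer's z) under the
    name in ``statistic_name``.  ``df_or_keff`` carries the chi-square degrees
    of freedom or the effective number of tests where applicable.
    """

    gene_id: str
    method: str
    adjustment: str
    p: float
    statistic: float
    statistic_name: str
    df_or_keff: Optional[float] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise InputError(f"unknown method {self.method!r}")
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ComputationError(f"combined p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class EffectiveTests:
    """An effective number of independent tests derived from an LD map."""

    estimator: str
    keff: float
    k: int
    C: Optional[float] = None

    def __post_init__(self):
        if self.estimator not in KEFF_ESTIMATORS:
            raise InputError(f"unknown keff estimator {self.estimator!r}")
        if not np.isfinite(self.keff) or self.keff < 1.0 - 1e-9:
            raise ComputationError(f"keff estimate {self.keff} below 1")


@dataclass(frozen=True)
class GenotypeMatrix:
    """n individuals x k SNPs of additive minor-allele counts (0/1/2)."""

    G: np.ndarray
    snp_ids: Optional[tuple] = None

    def __post_init__(self):
        G = np.asarray(self.G)
        if G.ndim != 2 or G.shape[0] < 1 or G.shape[1] < 1:
            raise InputError("genotype matrix must be 2-d (individuals x SNPs)")
        if not np.isin(G, (0, 1, 2)).all():
            raise InputError("genotype codes must be 0, 1 or 2")
        G = G.astype(np.int8)
        maf = G.mean(axis=0) / 2.0
        if np.any(maf == 0.0) or np.any(maf == 1.0):
            bad = int(np.flatnonzero((maf == 0.0) | (maf == 1.0))[0])
            raise InputError(f"monomorphic SNP at column {bad}")
        if np.any(maf > 0.5):
            bad = int(np.flatnonzero(maf > 0.5)[0])
            raise InputError(
                f"column {bad} is not oriented to the minor allele (frequency {maf[bad]:.3f} > 0.5)"
            )
        G.setflags(write=False)
        object.__setattr__(self, "G", G)
        if self.snp_ids is not None:
            ids = tuple(str(s) for s in self.snp_ids)
            if len(ids) != G.shape[1]:
                raise InputError("snp_ids length must match number of SNP columns")
            object.__setattr__(self, "snp_ids", ids)

    @property
    def n(self) -> int:
        return int(self.G.shape[0])

    @property
    def k(self) -> int:
        return int(self.G.shape[1])

    @property
    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency (in (0, 0.5] after orientation)."""
        return self.G.mean(axis=0) / 2.0


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid.

    ``causal`` selects the signal layout: ``"null"`` (no association; the
    phenotype is iid Bernoulli(0.5)), ``"single"`` (one randomly chosen SNP),
    ``"pct5"`` / ``"pct20"`` (5% or 20% of SNPs, floor 1).  ``distributed``
    divides the effect size across the selected SNPs; ``compact`` places them
    consecutively (otherwise they are equally spaced).  ``n`` triggers
    bootstrap resampling of individuals when it differs from the gene's
    sample size or when ``bootstrap`` is set.
    """

    n: int = 102
    causal: str = "null"
    effect_size: float = 0.0
    distributed: bool = False
    compact: bool = False
    reps: int = 1000
    alpha: float = 0.05
    bootstrap: bool = False
    reselect_causal: bool = True

    def __post_init__(self):
        if self.causal not in ("null", "single", "pct5", "pct20"):
            raise InputError(f"unknown causal layout {self.causal!r}")
        if self.n < 2 or self.reps < 1:
            raise InputError("n must be >= 2 and reps >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise InputError("alpha must be in (0, 1)")
        if self.causal != "null" and self.effect_size <= 0.0:
            raise InputError("non-null scenarios need a positive effect size")


@dataclass(frozen=True)
class GeneCharacteristics:
    """Summary statistics of a gene's LD map and allele frequencies."""

    k: int
    mean_r: float
    sd_r: float
    srmsc: float
    mean_maf: Optional[float] = None
    sd_maf: Optional[float] = None
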