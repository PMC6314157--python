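"""Quantitative-trait simulation under pedigree-structured covariance.

Traits are drawn from two models:

* null (H0):        ``Y = e``
* alternative (Ha): ``Y = beta_j X_j + e``

with ``e ~ N(0, sigma_g2 * A + sigma_e2 * I)`` where ``A`` is the numerator
relationship matrix (twice the kinship coefficient).  The defaults
``sigma_g2 = sigma_e2 = 1`` give total variance 2 and heritability
``h2 = sigma_g2 / (sigma_g2 + sigma_e2) = 0.5``.  Under Ha the SNP effect
is calibrated to contribute a fixed additive variance ``v_a`` (default
0.01) via ``beta_j = sqrt(v_a / (2 MAF_j (1 - MAF_j)))``, with the genotype
``X_j`` coded as 0/1/2 copies of the minor allele.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .pedigree import RelationshipMatrix

__all__ = ["TraitReplicates", "effect_size", "heritability", "simulate_traits"]


@dataclass
class TraitReplicates:
    """Simulated trait values, one column per replicate."""

    values: np.ndarray  # (n_subjects, n_traits)
    subject_order: list[str]
    model: str  # "H0" or "Ha"
    sigma_g2: float
    sigma_e2: float
    v_a: float
    snp_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.subject_order):
            raise ValueError("trait matrix rows must match subject count")
        if min(self.sigma_g2, self.sigma_e2, self.v_a) < 0:
            raise ValueError("variances must be non-negative")


def effect_size(maf: float, v_a: float) -> float:
    """SNP effect giving additive variance ``v_a``: sqrt(v_a / (2 p (1-p)))."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("MAF must lie in (0, 0.5]")
    if v_a < 0:
        raise ValueError("v_a must be non-negative")
    return math.sqrt(v_a / (2.0 * maf * (1.0 - maf)))


def heritability(sigma_g2: float, sigma_e2: float) -> float:
    """Narrow-sense heritability sigma_g2 / (sigma_g2 + sigma_e2)."""
    total = sigma_g2 + sigma_e2
    if total <= 0:
        raise ValueError("total variance must be positive")
    return sigma_g2 / total


def _covariance_factor(sigma: np.ndarray) -> np.ndarray:
    """Lower-triangular (or symmetric) factor L with L L' = sigma."""
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        warnings.warn(
            "covariance not positive definite; using eigenvalue-clipped factor",
            stacklevel=3,
        )
        w, v = np.linalg.eigh(sigma)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_traits(
    A: RelationshipMatrix | np.ndarray,
    model: str = "H0",
    X: np.ndarray | None = None,
    maf: float | None = None,
    sigma_g2: float = 1.0,
    sigma_e2: float = 1.0,
    v_a: float = 0.01,
    n_traits: int = 10,
    seed: int = 0,
) -> TraitReplicates:
    """Draw ``n_traits`` replicate trait vectors from the H0 or Ha model.

    ``X`` (minor-allele counts 0/1/2) and ``maf`` (the SNP's minor-allele
    frequency, used to calibrate the effect size) are required under Ha.
    Deterministic given ``seed``.
    """
    if isinstance(A, RelationshipMatrix):
        subjects = A.subject_order
        A_mat = A.A
    else:
        A_mat = np.asarray(A, dtype=float)
        subjects = [str(i) for i in range(A_mat.shape[0])]
    n = A_mat.shape[0]
    sigma = sigma_g2 * A_mat + sigma_e2 * np.eye(n)
    L = _covariance_factor(sigma)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    eps = L @ rng.standard_normal((n, n_traits))
    if model == "H0":
        values = eps
        snp_id = None
    elif model == "Ha":
        if X is None or maf is None:
            raise ValueError("Ha model requires the genotype vector X and its MAF")
        X = np.asarray(X, dtype=float)
        if X.shape != (n,):
            raise ValueError("genotype vector length must match A")
        beta = effect_size(maf, v_a)
        values = beta * X[:, None] + eps
        snp_id = None
    else:
        raise ValueError(f"unknown model {model!r} (expected 'H0' or 'Ha')")
    return TraitReplicates(
        values, list(subjects), model,
        sigma_g2=sigma_g2, sigma_e2=sigma_e2, v_a=v_a, snp_id=snp_id, seed=seed,
    )
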