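"""Mixed-model association testing and type-I-error / power aggregation.

The single-SNP test fits ``Y = mu + beta x + e`` with
``e ~ N(0, sigma_g2 * A + sigma_e2 * I)`` by maximum likelihood.  ``A`` is
eigendecomposed once per subject set; rotating by its eigenvectors
diagonalizes the covariance, so the likelihood profiles over the single
variance ratio ``delta = sigma_e2 / sigma_g2`` with a 1-D bounded search on
``log delta``.  The SNP coefficient is assessed by a Wald test against the
normal reference distribution.  Dosages (continuous in [0, 2]) enter the
design directly — no hard-call thresholding and no imputation-quality
filtering.

Aggregation follows the per-SNP-rate convention: for each SNP, the
rejection proportion over trait replicates at a nominal level alpha, then
the unweighted mean of SNP rates within MAF bins.  Null-model traits give
type-I error; alternative-model traits give power.  The first and last
``n_buffer`` sites of the region are excluded from testing, because edge
sites lack flanking panel information and their population-based imputation
is unrepresentative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .metrics import MafBinning
from .pedigree import RelationshipMatrix

__all__ = [
    "KinshipEigen",
    "lmm_test",
    "exclude_buffer",
    "estimate_rates",
]


@dataclass
class KinshipEigen:
    """Cached eigendecomposition of a relationship matrix."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    subject_order: list[str]

    @classmethod
    def from_relationship(cls, A: RelationshipMatrix | np.ndarray) -> "KinshipEigen":
        if isinstance(A, RelationshipMatrix):
            mat, order = A.A, A.subject_order
        else:
            mat = np.asarray(A, dtype=float)
            order = [str(i) for i in range(mat.shape[0])]
        w, v = np.linalg.eigh(mat)
        if w.min() < -1e-8:
            raise ValueError("relationship matrix is not positive semidefinite")
        return cls(np.clip(w, 0.0, None), v, list(order))


def _profile_neg_loglik(
    log_delta: float, lam: np.ndarray, Xr: np.ndarray, yr: np.ndarray
) -> float:
    delta = math.exp(log_delta)
    w = 1.0 / (lam + delta)
    XtW = Xr.T * w
    beta = np.linalg.solve(XtW @ Xr, XtW @ yr)
    resid = yr - Xr @ beta
    n = yr.size
    sigma_g2 = float(resid @ (w * resid)) / n
    return 0.5 * (n * math.log(max(sigma_g2, 1e-300)) + np.log(lam + delta).sum())


def lmm_test(
    y: np.ndarray,
    x: np.ndarray,
    A: RelationshipMatrix | np.ndarray | KinshipEigen,
    log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
) -> tuple[float, float, float]:
    """Wald test of a SNP in a two-variance-component mixed model.

    Returns ``(beta, se, p)``.  Variance components are fit by ML per test
    (profiling over ``delta = sigma_e2 / sigma_g2``); with ``A = I`` the
    estimates and p-values reduce to ordinary least squares.  A constant
    genotype vector returns ``p = 1`` with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x have different lengths")
    if np.ptp(x) == 0.0:
        warnings.warn("constant genotype vector; test undefined", stacklevel=2)
        return 0.0, math.inf, 1.0
    eig = (A if isinstance(A, KinshipEigen)
           else KinshipEigen.from_relationship(A))
    lam, U = eig.eigenvalues, eig.eigenvectors
    X = np.column_stack([np.ones_like(x), x])
    Xr = U.T @ X
    yr = U.T @ y

    res = optimize.minimize_scalar(
        _profile_neg_loglik,
        bounds=log_delta_bounds,
        args=(lam, Xr, yr),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = math.exp(res.x)
    w = 1.0 / (lam + delta)
    XtW = Xr.T * w
    xtwx = XtW @ Xr
    beta_hat = np.linalg.solve(xtwx, XtW @ yr)
    resid = yr - Xr @ beta_hat
    n = yr.size
    # residual-dof variance estimate so the A = I limit reproduces OLS
    sigma_g2 = float(resid @ (w * resid)) / (n - 2)
    cov_beta = sigma_g2 * np.linalg.inv(xtwx)
    beta = float(beta_hat[1])
    se = float(math.sqrt(cov_beta[1, 1]))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, max(p, np.finfo(float).tiny)


def exclude_buffer(snp_ids: Sequence[str], n_buffer: int = 500) -> list[str]:
    """Drop the first and last ``n_buffer`` SNPs (position order assumed)."""
    ids = list(snp_ids)
    if n_buffer == 0:
        return ids
    if 2 * n_buffer >= len(ids):
        raise ValueError("buffer exclusion removes every site")
    return ids[n_buffer:-n_buffer]


def estimate_rates(
    results: pd.DataFrame,
    alphas: Sequence[float] = (0.05, 0.01, 0.001),
    binning: MafBinning = MafBinning(),
) -> pd.DataFrame:
    """Rejection-rate table per (MAF bin, alpha, genotype source, model).

    ``results`` must carry columns snp_id, maf, model ("H0"/"Ha"), source,
    p_value, with one row per (SNP, trait replicate) test.  The rate per
    SNP is the proportion of replicates with ``p < alpha``; bins average
    SNP rates unweighted.  H0 rows yield type-I error, Ha rows power.
    Empty bins are omitted (logged).
    """
    required = {"snp_id", "maf", "model", "source", "p_value"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns {sorted(missing)}")
    rows = []
    grouped = results.groupby(["source", "model", "snp_id"], sort=True)
    per_snp = grouped.agg(
        maf=("maf", "first"),
        n_rep=("p_value", "size"),
        **{f"rate_{a:g}": ("p_value", lambda p, a=a: float((p < a).mean()))
           for a in alphas},
    ).reset_index()
    per_snp["bin"] = binning.assign(per_snp["maf"].to_numpy())
    for (source, model, b), sub in per_snp.groupby(["source", "model", "bin"]):
        if b < 0 or sub.empty:
            continue
        for a in alphas:
            rows.append({
                "source": source,
                "model": model,
                "rate_type": "type_I_error" if model == "H0" else "power",
                "maf_bin": binning.labels[int(b)],
                "alpha": a,
                "rate": float(sub[f"rate_{a:g}"].mean()),
                "n_snps": int(len(sub)),
                "n_tests": int(sub["n_rep"].sum()),
            })
    return pd.DataFrame(rows)
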