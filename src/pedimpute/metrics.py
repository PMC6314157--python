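"""Per-SNP imputation accuracy metrics and summaries.

Two headline metrics are computed per SNP over the imputation-target
subjects:

* **dosage R²** — squared Pearson correlation between true and imputed
  minor-allele dosages; invariant to affine rescaling (count vs fraction
  scale), undefined when either vector is constant;
* **IQS** — the imputation quality score, a kappa-type chance-corrected
  agreement between the imputed genotype-class probabilities and the true
  genotypes.  From the probability-weighted 3x3 contingency table
  ``n_jk = sum_i P_i(imputed = j) 1[true_i = k]``: observed agreement
  ``Po = sum_j n_jj / N``, chance agreement ``Pc = sum_j row_j col_j / N²``,
  and ``IQS = (Po - Pc) / (1 - Pc)``.  Its maximum is 1; it can be
  negative; it is undefined when ``Pc = 1``.

The concordance rate (best-guess agreement) is included for completeness
but, because it is dominated by the easy major-homozygote calls at low MAF,
it is excluded from headline summaries.

Undefined metric values are flagged as NaN and *excluded* from bin means —
never coerced to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import HaplotypePool

__all__ = [
    "effective_sample_size_factor",
    "SnpAccuracyRecord",
    "MafBinning",
    "dosage_r2",
    "iqs",
    "concordance_rate",
    "score_dataset",
    "summarize_by_bin",
    "mean_window_ld",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SnpAccuracyRecord:
    """Accuracy of one SNP; NaN marks an undefined metric."""

    snp_id: str
    true_maf: float
    r2: float
    iqs: float
    cr: float
    n_subjects: int


@dataclass(frozen=True)
class MafBinning:
    """Partition of (0, 0.5] into MAF bins.

    Default edges give (0,0.01), [0.01,0.05), [0.05,0.1), [0.1,0.2),
    [0.2,0.3), [0.3,0.4), [0.4,0.5].
    """

    edges: tuple[float, ...] = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or any(a >= b for a, b in zip(e, e[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if e[0] != 0.0 or e[-1] != 0.5:
            raise ValueError("bins must partition (0, 0.5]")

    @property
    def labels(self) -> list[str]:
        out = []
        for i, (a, b) in enumerate(zip(self.edges, self.edges[1:])):
            left = "(" if i == 0 else "["
            right = "]" if i == len(self.edges) - 2 else ")"
            out.append(f"{left}{a:g},{b:g}{right}")
        return out

    def assign(self, mafs: np.ndarray) -> np.ndarray:
        """Bin index per MAF; -1 for values outside (0, 0.5]."""
        m = np.asarray(mafs, dtype=float)
        idx = np.searchsorted(self.edges, m, side="right") - 1
        idx = np.where(m == 0.5, len(self.edges) - 2, idx)  # closed top bin
        idx = np.where((m <= 0.0) | (m > 0.5), -1, idx)
        return idx


def effective_sample_size_factor(r2: float) -> float:
    """Sample-size inflation needed to offset imperfect imputation.

    Imputing one SNP with accuracy ``r2`` on unrelated subjects loses
    information equivalent to shrinking the sample by a factor ``r2``; the
    study must be ``1 / r2`` times larger to match the power achievable
    with perfect genotypes.
    """
    if not 0.0 < r2 <= 1.0:
        raise ValueError("r2 must lie in (0, 1]")
    return 1.0 / r2


def dosage_r2(true_dosages: np.ndarray, imputed_dosages: np.ndarray) -> float:
    """Squared Pearson correlation of true vs imputed dosage; NaN if constant."""
    t = np.asarray(true_dosages, dtype=float)
    d = np.asarray(imputed_dosages, dtype=float)
    if t.shape != d.shape:
        raise ValueError("dosage vectors have different lengths")
    if t.size < 2 or np.ptp(t) == 0.0 or np.ptp(d) == 0.0:
        return math.nan
    r = np.corrcoef(t, d)[0, 1]
    return float(r * r)


def iqs(true_genotypes: np.ndarray, posteriors: np.ndarray) -> float:
    """Imputation quality score from probability-weighted agreement.

    ``true_genotypes`` in {0,1,2}; ``posteriors`` of shape (N, 3), each row
    a simplex.  Returns NaN when chance agreement is 1 (e.g. a monomorphic
    SNP called monomorphic).
    """
    g = np.asarray(true_genotypes, dtype=np.intp)
    P = np.asarray(posteriors, dtype=float)
    if P.ndim != 2 or P.shape != (g.size, 3):
        raise ValueError("posteriors must have shape (n_subjects, 3)")
    if np.any(P < -1e-9) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("invalid posterior simplex")
    n = g.size
    table = np.zeros((3, 3))
    for k in range(3):
        sel = g == k
        if sel.any():
            table[:, k] = P[sel].sum(axis=0)
    po = np.trace(table) / n
    pc = float(table.sum(axis=1) @ table.sum(axis=0)) / n**2
    if abs(1.0 - pc) < 1e-12:
        return math.nan
    return float((po - pc) / (1.0 - pc))


def concordance_rate(true_genotypes: np.ndarray, posteriors: np.ndarray) -> float:
    """Fraction of best-guess calls (ties to the smaller genotype) matching truth."""
    g = np.asarray(true_genotypes, dtype=np.intp)
    if g.size == 0:
        raise ValueError("empty input")
    P = np.asarray(posteriors, dtype=float)
    best = np.argmax(P, axis=-1)  # argmax takes the first (smaller) index on ties
    return float(np.mean(best == g))


def best_guess_iqs(true_genotypes: np.ndarray, posteriors: np.ndarray) -> float:
    """IQS computed on hard best-guess calls (classic Cohen's kappa)."""
    best = np.argmax(np.asarray(posteriors, dtype=float), axis=-1)
    return iqs(true_genotypes, _one_hot(best))


def _one_hot(g: np.ndarray) -> np.ndarray:
    out = np.zeros((g.size, 3))
    out[np.arange(g.size), g] = 1.0
    return out


def score_dataset(
    dataset,
    result,
    true_mafs: np.ndarray | None = None,
    n_buffer: int = 500,
    exclude_panel: bool = True,
) -> pd.DataFrame:
    """Per-SNP accuracy table for an imputation result on a study dataset.

    Scores only the imputation-target subjects of ``result`` and, by
    default, excludes both the observed GWAS-panel sites and a buffer of
    ``n_buffer`` sites at each end of the region (edge sites lack flanking
    panel information, so their population-based accuracy is not
    representative).  Pass ``n_buffer=0`` to keep edges.  Returns a
    DataFrame with columns snp_id, maf, r2, iqs, cr, n, on_panel,
    in_buffer; excluded sites are retained as rows with their flags set so
    both exclusion sets are visible.
    """
    truth = dataset.truth
    if true_mafs is None:
        true_mafs = dataset.pool_maf
    tgt = truth.subject_index(result.subject_order)
    true_d = truth.dosages()[tgt]
    imp_d = result.dosages
    post = result.posteriors
    S = truth.n_snps
    panel = dataset.panel_mask
    buffer = np.zeros(S, dtype=bool)
    if n_buffer:
        if 2 * n_buffer >= S:
            raise ValueError("buffer exclusion removes every site")
        buffer[:n_buffer] = True
        buffer[-n_buffer:] = True
    rows = []
    for j, sid in enumerate(truth.snp_ids):
        excluded = (exclude_panel and panel[j]) or buffer[j]
        if excluded:
            r2 = iqs_v = cr = math.nan
        else:
            r2 = dosage_r2(true_d[:, j], imp_d[:, j])
            iqs_v = iqs(true_d[:, j], post[:, j, :])
            cr = concordance_rate(true_d[:, j], post[:, j, :])
        rows.append((sid, float(true_mafs[j]), r2, iqs_v, cr,
                     len(result.subject_order), bool(panel[j]), bool(buffer[j])))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "maf", "r2", "iqs", "cr", "n", "on_panel", "in_buffer"],
    )


def summarize_by_bin(
    records: pd.DataFrame | Iterable[SnpAccuracyRecord],
    binning: MafBinning = MafBinning(),
    metrics: Sequence[str] = ("r2", "iqs"),
) -> pd.DataFrame:
    """Mean of each defined metric per MAF bin; undefined values counted apart.

    Accepts the DataFrame from :func:`score_dataset` (excluded sites are
    dropped) or an iterable of :class:`SnpAccuracyRecord`.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records]).rename(
            columns={"true_maf": "maf", "n_subjects": "n"}
        )
    df = records.copy()
    for flag in ("on_panel", "in_buffer"):
        if flag in df.columns:
            df = df[~df[flag]]
    df["bin"] = binning.assign(df["maf"].to_numpy())
    df = df[df["bin"] >= 0]
    out = []
    for b, label in enumerate(binning.labels):
        sub = df[df["bin"] == b]
        row: dict = {"bin": label, "n_snps": len(sub)}
        for mname in metrics:
            vals = sub[mname].to_numpy(dtype=float)
            defined = vals[~np.isnan(vals)]
            row[f"mean_{mname}"] = float(defined.mean()) if defined.size else math.nan
            row[f"n_undefined_{mname}"] = int(np.isnan(vals).sum())
        out.append(row)
    return pd.DataFrame(out)


def mean_window_ld(
    haplotypes: HaplotypePool | np.ndarray, window: int = 100
) -> float:
    """Mean pairwise r² within non-overlapping windows of consecutive SNPs.

    All site pairs within each complete window contribute; the trailing
    partial window is dropped; monomorphic sites are skipped (logged).
    """
    H = haplotypes.haplotypes if isinstance(haplotypes, HaplotypePool) else haplotypes
    H = np.asarray(H, dtype=float)
    n_h, S = H.shape
    if window > S:
        raise ValueError("window larger than the number of sites")
    n_windows = S // window
    n_mono = 0
    vals = []
    for w in range(n_windows):
        block = H[:, w * window : (w + 1) * window]
        sd = block.std(axis=0)
        poly = sd > 0
        n_mono += int((~poly).sum())
        block = block[:, poly]
        if block.shape[1] < 2:
            continue
        r = np.corrcoef(block, rowvar=False)
        iu = np.triu_indices_from(r, k=1)
        vals.append(float(np.mean(r[iu] ** 2)))
    if n_mono:
        log.info("mean_window_ld: skipped %d monomorphic sites", n_mono)
    if not vals:
        return math.nan
    return float(np.mean(vals))
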