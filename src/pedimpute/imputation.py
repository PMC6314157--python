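"""Built-in baseline imputers, result combination, and external-result import.

The package's primary mode for real studies is to export files for external
phasing/imputation software and re-import their VCF output
(:func:`import_external_result`).  The built-in imputers are deliberately
simple, transparent baselines that isolate the two information sources real
tools exploit:

* :func:`impute_allele_frequency` — no information: Hardy-Weinberg
  posteriors from the reference allele frequency (null model);
* :func:`impute_population_ld` — LD only: per-site linear prediction from
  the nearest GWAS-panel sites, trained on the reference subjects;
* :func:`impute_family_kinship` — relationship only: per-site Gaussian
  conditioning of the dosage vector, with mean ``2p`` and covariance
  ``2p(1-p) A`` (``A`` the numerator relationship matrix), on the observed
  reference dosages.

:func:`combine_ped_pop` merges a family- and a population-based result the
way hybrid pipelines do: trust the family call where it is confident (max
posterior above a threshold), otherwise use the population call.

All dosages are on the minor-allele-count scale [0, 2]; a reported
"fraction of minor alleles" is count/2, and squared-correlation accuracy is
invariant to that rescaling.  When only a dosage ``d`` is available,
genotype-class posteriors use the Hardy-Weinberg moment match
``((1-d/2)^2, 2(d/2)(1-d/2), (d/2)^2)``, which agreement metrics such as
IQS require.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genedrop import StudyDataset
from .pedigree import relationship_matrix
from .selection import SelectionResult

__all__ = [
    "ImputationResult",
    "dosage_to_posteriors",
    "estimate_reference_maf",
    "impute_allele_frequency",
    "impute_population_ld",
    "impute_family_kinship",
    "combine_ped_pop",
    "import_external_result",
]

log = logging.getLogger(__name__)

# allele symbols used in every VCF this package writes: REF = major allele
MAJOR_ALLELE = "A"
MINOR_ALLELE = "C"


def dosage_to_posteriors(dosage: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg moment-match from dosage in [0,2] to (P0, P1, P2)."""
    p = np.asarray(dosage, dtype=float) / 2.0
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)


def _hard_call_posteriors(genotypes: np.ndarray) -> np.ndarray:
    out = np.zeros(genotypes.shape + (3,), dtype=float)
    g = np.asarray(genotypes, dtype=np.intp)
    idx = np.indices(g.shape)
    out[(*idx, g)] = 1.0
    return out


@dataclass
class ImputationResult:
    """Per (subject, SNP) genotype posteriors and dosages.

    Invariants: each posterior triple is a simplex (sums to 1 within 1e-6)
    and ``dosage == P1 + 2 P2`` within 1e-6.
    """

    posteriors: np.ndarray  # (N, S, 3)
    subject_order: list[str]
    snp_ids: list[str]
    method_label: str = ""
    provenance: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        n, s, three = self.posteriors.shape
        if three != 3 or n != len(self.subject_order) or s != len(self.snp_ids):
            raise ValueError("posterior array shape inconsistent with labels")
        self.validate()

    def validate(self) -> None:
        if np.any(self.posteriors < -1e-9):
            raise ValueError("negative posterior probability")
        sums = self.posteriors.sum(axis=-1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("posteriors do not sum to 1")

    @property
    def dosages(self) -> np.ndarray:
        """Minor-allele-count dosage, shape (N, S)."""
        return self.posteriors[..., 1] + 2.0 * self.posteriors[..., 2]

    def best_guess(self) -> np.ndarray:
        """Most probable genotype per cell; ties go to the smaller index."""
        return np.argmax(self.posteriors, axis=-1)

    def subset_subjects(self, ids: Sequence[str]) -> "ImputationResult":
        lut = {s: i for i, s in enumerate(self.subject_order)}
        sel = [lut[s] for s in ids]
        return ImputationResult(
            self.posteriors[sel], list(ids), self.snp_ids, self.method_label
        )


def estimate_reference_maf(dataset: StudyDataset) -> np.ndarray:
    """Minor-allele frequency estimated from the reference subjects.

    The minor allele is defined by the founder pool, so the reference-sample
    estimate can stray above 0.5; it is capped there to keep the downstream
    Hardy-Weinberg priors on the minor-allele scale.
    """
    ref = sorted(dataset.reference_subject_ids)
    if not ref:
        raise ValueError("dataset has no reference subjects")
    idx = dataset.truth.subject_index(ref)
    freq = dataset.truth.dosages()[idx].mean(axis=0) / 2.0
    return np.minimum(freq, 0.5)


def _observed_truth_posteriors(
    dataset: StudyDataset, targets: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior array pre-filled with observed panel genotypes.

    Returns (posteriors, imputed_mask) where imputed_mask flags the sites
    each imputer must fill (non-panel sites).
    """
    idx = dataset.truth.subject_index(targets)
    geno = dataset.truth.dosages()[idx]
    post = _hard_call_posteriors(geno)
    panel = dataset.panel_mask
    return post, ~panel


def impute_allele_frequency(
    dataset: StudyDataset, ref_mafs: np.ndarray | None = None
) -> ImputationResult:
    """Null-model baseline: Hardy-Weinberg posteriors from reference MAFs.

    Every unobserved genotype gets posteriors ``((1-p)^2, 2p(1-p), p^2)``
    and dosage ``2p``.  Raises if any frequency falls outside [0, 0.5].
    """
    if ref_mafs is None:
        ref_mafs = estimate_reference_maf(dataset)
    ref_mafs = np.asarray(ref_mafs, dtype=float)
    if np.any((ref_mafs < 0) | (ref_mafs > 0.5)):
        raise ValueError("reference MAFs must lie in [0, 0.5] after polarization")
    targets = dataset.study_subject_ids
    post, fill = _observed_truth_posteriors(dataset, targets)
    hwe = dosage_to_posteriors(2.0 * ref_mafs[fill])
    post[:, fill, :] = hwe[None, :, :]
    return ImputationResult(post, targets, list(dataset.truth.snp_ids),
                            method_label="allele_frequency")


def impute_population_ld(
    dataset: StudyDataset,
    k_flank: int = 10,
    ref_mafs: np.ndarray | None = None,
) -> ImputationResult:
    """LD-only baseline: linear prediction from the nearest panel sites.

    For each unobserved site, an ordinary least-squares predictor of its
    dosage from the ``k_flank`` physically nearest GWAS-panel dosages is fit
    on the reference subjects and applied to the study subjects, then
    clipped to [0, 2].  Sites monomorphic in the reference fall back to the
    allele-frequency baseline (logged).
    """
    if ref_mafs is None:
        ref_mafs = estimate_reference_maf(dataset)
    panel = dataset.panel_mask
    panel_idx = np.flatnonzero(panel)
    if panel_idx.size < k_flank:
        raise ValueError("fewer panel sites than k_flank")
    truth = dataset.truth
    targets = dataset.study_subject_ids
    ref = sorted(dataset.reference_subject_ids)
    if not ref:
        raise ValueError("dataset has no reference subjects")
    D = truth.dosages().astype(float)
    D_ref = D[truth.subject_index(ref)]
    D_tgt = D[truth.subject_index(targets)]
    pos = truth.positions_bp

    post, fill = _observed_truth_posteriors(dataset, targets)
    n_fallback = 0
    for j in np.flatnonzero(fill):
        order = np.argsort(np.abs(pos[panel_idx] - pos[j]), kind="stable")
        near = panel_idx[order[:k_flank]]
        y = D_ref[:, j]
        if np.ptp(y) == 0.0:
            n_fallback += 1
            d_hat = np.full(len(targets), 2.0 * ref_mafs[j])
        else:
            X = np.column_stack([np.ones(len(ref)), D_ref[:, near]])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            Xt = np.column_stack([np.ones(len(targets)), D_tgt[:, near]])
            d_hat = np.clip(Xt @ coef, 0.0, 2.0)
        post[:, j, :] = dosage_to_posteriors(d_hat)
    if n_fallback:
        log.info("population LD imputer: %d sites monomorphic in reference, "
                 "used allele-frequency fallback", n_fallback)
    return ImputationResult(post, targets, list(truth.snp_ids),
                            method_label=f"population_ld(k={k_flank})")


def impute_family_kinship(
    dataset: StudyDataset,
    selection: SelectionResult | None = None,
    ref_mafs: np.ndarray | None = None,
) -> ImputationResult:
    """Relationship-only baseline: Gaussian conditioning on relatives.

    Per site, the dosage vector of a pedigree is modeled with mean ``2p``
    and covariance ``2p(1-p) A``; unobserved dosages are set to the
    conditional expectation given the observed reference dosages,
    ``2p + A_uo A_oo^{-1} (d_obs - 2p)``, clipped to [0, 2].  Subjects with
    no sequenced relative fall back to the prior mean ``2p``.  With
    ``A = I`` this reduces exactly to the allele-frequency baseline.
    """
    if selection is not None:
        dataset.reference_subject_ids = set(selection.selected_ids)
    if ref_mafs is None:
        ref_mafs = estimate_reference_maf(dataset)
    truth = dataset.truth
    targets = dataset.study_subject_ids
    post, fill = _observed_truth_posteriors(dataset, targets)
    fill_idx = np.flatnonzero(fill)
    mu = 2.0 * np.asarray(ref_mafs, dtype=float)[fill_idx]
    D = truth.dosages().astype(float)

    tgt_pos = {s: i for i, s in enumerate(targets)}
    for ped in dataset.pedigrees:
        rel = relationship_matrix(ped)
        ids = rel.subject_order
        obs = [i for i, s in enumerate(ids) if s in dataset.reference_subject_ids]
        unobs = [i for i, s in enumerate(ids) if s not in dataset.reference_subject_ids]
        if not unobs:
            continue
        rows = [tgt_pos[ids[i]] for i in unobs]
        if not obs:
            d_hat = np.broadcast_to(mu, (len(unobs), mu.size))
        else:
            A_oo = rel.A[np.ix_(obs, obs)]
            A_uo = rel.A[np.ix_(unobs, obs)]
            try:
                W = np.linalg.solve(A_oo, A_uo.T).T
            except np.linalg.LinAlgError:
                log.warning("singular observed relationship block in pedigree "
                            "%s; ridge-regularizing", ped.pedigree_id)
                eps = 1e-8
                W = np.linalg.solve(A_oo + eps * np.eye(len(obs)), A_uo.T).T
            obs_rows = truth.subject_index([ids[i] for i in obs])
            resid = D[np.ix_(obs_rows, fill_idx)] - mu
            d_hat = np.clip(mu + W @ resid, 0.0, 2.0)
        post[np.ix_(rows, fill_idx)] = dosage_to_posteriors(d_hat)
    return ImputationResult(post, targets, list(truth.snp_ids),
                            method_label="family_kinship")


def combine_ped_pop(
    family: ImputationResult,
    population: ImputationResult,
    tau: float = 0.8,
) -> ImputationResult:
    """Hybrid combination: family call where confident, else population call.

    A cell uses the family posteriors when the family's maximum genotype
    posterior is at least ``tau``; otherwise the population posteriors.
    ``tau = 0`` reproduces the family result, ``tau > 1`` the population
    result.  Per-cell provenance counts are recorded.
    """
    if (family.subject_order != population.subject_order
            or family.snp_ids != population.snp_ids):
        raise ValueError("family and population results cover different grids")
    conf = family.posteriors.max(axis=-1) >= tau
    post = np.where(conf[..., None], family.posteriors, population.posteriors)
    n_fam = int(conf.sum())
    return ImputationResult(
        post, list(family.subject_order), list(family.snp_ids),
        method_label=f"ped_pop(tau={tau:g})",
        provenance={"family": n_fam, "population": int(conf.size - n_fam)},
    )


def import_external_result(
    vcf_path: str | Path,
    expected_alleles: dict[str, tuple[str, str]] | None = None,
    method_label: str | None = None,
) -> ImputationResult:
    """Read an external imputation VCF with DS and/or GP FORMAT fields.

    GP (genotype probabilities, ordered P(0),P(1),P(2) on the ALT-count
    scale) is used when present, renormalized; otherwise DS with the
    Hardy-Weinberg dosage-to-posterior mapping.  If ``expected_alleles``
    maps a SNP id to the truth's (REF, ALT) pair and the file has them
    swapped, the cell posteriors are reversed (dosage ``d -> 2 - d``).
    Raises if a record carries neither DS nor GP, or if its alleles match
    the expectation in neither orientation.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    snp_ids: list[str] = []
    for var in vcf:
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        flip = False
        if expected_alleles is not None and vid in expected_alleles:
            ref, alt = expected_alleles[vid]
            if var.REF == ref and var.ALT[:1] == [alt]:
                flip = False
            elif var.REF == alt and var.ALT[:1] == [ref]:
                flip = True
            else:
                raise ValueError(
                    f"site {vid}: alleles {var.REF}/{var.ALT} do not match "
                    f"expected {ref}/{alt} in either orientation"
                )
        def _fmt(field: str):
            try:
                return var.format(field)
            except KeyError:
                return None

        gp = _fmt("GP")
        if gp is not None:
            gp = np.asarray(gp, dtype=float)
            gp = gp / gp.sum(axis=1, keepdims=True)
        else:
            ds = _fmt("DS")
            if ds is None:
                raise ValueError(f"site {vid}: neither DS nor GP present")
            ds = np.asarray(ds, dtype=float).reshape(-1)
            gp = dosage_to_posteriors(ds)
        if flip:
            gp = gp[:, ::-1]
        rows.append(gp)
        snp_ids.append(vid)
    post = np.stack(rows, axis=1)  # (N, S, 3)
    return ImputationResult(
        post, samples, snp_ids,
        method_label=method_label or f"external:{Path(vcf_path).name}",
    )
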