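"""File exchange: VCF 4.2, matrix/map TSVs, and trait tables.

Every VCF written here uses the pool's minor-allele polarization: REF is
the major allele (symbol ``A``), ALT the minor allele (``C``), so ALT
counts equal minor-allele counts.  Exported files are what external
phasing/imputation software consumes; their output VCFs (with DS and/or GP
FORMAT fields) come back in through
:func:`pedimpute.imputation.import_external_result`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .genedrop import PhasedGenotypes, StudyDataset
from .imputation import MAJOR_ALLELE, MINOR_ALLELE, ImputationResult
from .synthetic import HaplotypePool

__all__ = [
    "read_phased_vcf",
    "write_phased_vcf",
    "write_imputed_vcf",
    "write_pool_tsv",
    "write_map_tsv",
    "write_panel_list",
    "export_for_external_tools",
    "write_traits_tsv",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=pedimpute
##contig=<ID={contig}>
##INFO=<ID=MAF,Number=1,Type=Float,Description="Pool minor allele frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Minor allele dosage">
##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior probabilities">
"""


def _vcf_open(path: str | Path, samples: Sequence[str], contig: str):
    fh = open(path, "w")
    fh.write(_VCF_HEADER.format(contig=contig))
    fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(samples) + "\n")
    return fh


def write_phased_vcf(
    truth: PhasedGenotypes,
    path: str | Path,
    subjects: Sequence[str] | None = None,
    site_mask: np.ndarray | None = None,
    contig: str = "22",
) -> None:
    """Write phased GT records for the given subjects and sites."""
    subjects = list(subjects) if subjects is not None else list(truth.subject_order)
    idx = truth.subject_index(subjects)
    sites = (np.flatnonzero(site_mask) if site_mask is not None
             else np.arange(truth.n_snps))
    haps = truth.haplotypes[idx]
    with _vcf_open(path, subjects, contig) as fh:
        for j in sites:
            cells = "\t".join(
                f"{haps[i, 0, j]}|{haps[i, 1, j]}" for i in range(len(subjects))
            )
            fh.write(
                f"{contig}\t{truth.positions_bp[j]}\t{truth.snp_ids[j]}\t"
                f"{MAJOR_ALLELE}\t{MINOR_ALLELE}\t.\tPASS\t.\tGT\t{cells}\n"
            )


def read_phased_vcf(path: str | Path) -> PhasedGenotypes:
    """Read a phased-GT VCF back into a :class:`PhasedGenotypes` container."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    positions: list[int] = []
    rows = []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)
        g = np.asarray(var.genotype.array())[:, :2]  # (N, 2) allele indices
        rows.append(g)
    haps = np.stack(rows, axis=2).astype(np.uint8)  # (N, 2, S)
    return PhasedGenotypes(haps, samples, snp_ids, np.asarray(positions))


def write_imputed_vcf(
    result: ImputationResult,
    positions_bp: np.ndarray,
    path: str | Path,
    contig: str = "22",
) -> None:
    """Write an imputation result as VCF with DS and GP FORMAT fields."""
    pos = np.asarray(positions_bp)
    if pos.size != len(result.snp_ids):
        raise ValueError("positions length must match result SNPs")
    ds = result.dosages
    gp = result.posteriors
    with _vcf_open(path, result.subject_order, contig) as fh:
        for j, sid in enumerate(result.snp_ids):
            cells = "\t".join(
                f"{ds[i, j]:.6f}:{gp[i, j, 0]:.6f},{gp[i, j, 1]:.6f},{gp[i, j, 2]:.6f}"
                for i in range(len(result.subject_order))
            )
            fh.write(
                f"{contig}\t{pos[j]}\t{sid}\t{MAJOR_ALLELE}\t{MINOR_ALLELE}\t"
                f".\tPASS\t.\tDS:GP\t{cells}\n"
            )


def write_pool_tsv(pool: HaplotypePool, path: str | Path) -> None:
    """Haplotype matrix as TSV: one row per haplotype, columns are SNP ids."""
    with open(path, "w") as fh:
        fh.write("haplotype\t" + "\t".join(pool.snp_ids) + "\n")
        for i, row in enumerate(pool.haplotypes):
            fh.write(f"h{i}\t" + "\t".join(map(str, row)) + "\n")


def write_map_tsv(
    snp_ids: Sequence[str], positions_bp: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tbp\n")
        for sid, bp in zip(snp_ids, positions_bp):
            fh.write(f"{sid}\t{bp}\n")


def write_panel_list(dataset: StudyDataset, path: str | Path) -> None:
    """GWAS-panel SNP ids, one per line, in position order."""
    with open(path, "w") as fh:
        for sid in dataset.truth.snp_ids:
            if sid in dataset.gwas_snp_ids:
                fh.write(sid + "\n")


def export_for_external_tools(
    dataset: StudyDataset, outdir: str | Path, contig: str = "22"
) -> dict[str, Path]:
    """Write the file set an external imputation tool needs.

    Produces: full-site VCF for the reference subjects, panel-site VCF for
    the study subjects, the PED files, the map TSV, and the panel list.
    """
    from .pedigree import write_ped

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not dataset.reference_subject_ids:
        raise ValueError("dataset has no reference subjects; run selection first")
    files = {
        "reference_vcf": outdir / "reference_full.vcf",
        "study_vcf": outdir / "study_panel.vcf",
        "ped": outdir / "pedigrees.ped",
        "map": outdir / "snp_map.tsv",
        "panel_list": outdir / "panel_snps.txt",
    }
    ref = sorted(dataset.reference_subject_ids)
    write_phased_vcf(dataset.truth, files["reference_vcf"], subjects=ref,
                     contig=contig)
    write_phased_vcf(dataset.truth, files["study_vcf"],
                     subjects=dataset.study_subject_ids,
                     site_mask=dataset.panel_mask, contig=contig)
    write_ped(dataset.pedigrees, files["ped"])
    write_map_tsv(dataset.truth.snp_ids, dataset.truth.positions_bp, files["map"])
    write_panel_list(dataset, files["panel_list"])
    return files


def write_traits_tsv(traits, path: str | Path) -> None:
    """Trait matrix as TSV plus a JSON sidecar of simulation parameters."""
    path = Path(path)
    k = traits.values.shape[1]
    with open(path, "w") as fh:
        fh.write("subject_id\t" + "\t".join(f"trait_{i + 1}" for i in range(k)) + "\n")
        for sid, row in zip(traits.subject_order, traits.values):
            fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")
    sidecar = {
        "model": traits.model,
        "sigma_g2": traits.sigma_g2,
        "sigma_e2": traits.sigma_e2,
        "v_a": traits.v_a,
        "snp_id": traits.snp_id,
        "seed": traits.seed,
        "n_traits": k,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
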