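"""Configuration-driven orchestration of the full imputation experiment.

A single :class:`ExperimentConfig` (read from YAML) drives the chain
simulate -> select -> impute -> score -> test -> report.  Every stage
derives its random stream deterministically from the base seed and the
replicate index, so re-running a config reproduces all outputs, and any
replicate can be regenerated in isolation.  Outputs are TSV tables plus a
JSON manifest recording the config, its hash, and all derived seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import KinshipEigen, estimate_rates, exclude_buffer, lmm_test
from .genedrop import StudyDataset, make_replicates, replicate_seeds
from .imputation import (
    ImputationResult,
    combine_ped_pop,
    estimate_reference_maf,
    import_external_result,
    impute_allele_frequency,
    impute_family_kinship,
    impute_population_ld,
)
from .metrics import MafBinning, mean_window_ld, score_dataset, summarize_by_bin
from .pedigree import Pedigree, block_diag_relationship, read_ped
from .selection import SelectionResult, select
from .synthetic import (
    SCENARIO_PRESETS,
    MafSpectrum,
    ScenarioConfig,
    generate_pedigree_set,
)

log = logging.getLogger(__name__)

BUILTIN_IMPUTERS = ("allele_frequency", "population_ld", "family_kinship", "ped_pop")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class ExperimentConfig:
    """Everything one experiment needs, resolvable from a YAML mapping."""

    scenario: str = "EUR-like"
    scenario_overrides: dict[str, Any] = field(default_factory=dict)
    ped_file: str | None = None
    n_pedigrees: int = 4
    size_range: tuple[int, int] = (10, 40)
    generations_range: tuple[int, int] = (3, 5)
    sibship_range: tuple[int, int] = (1, 11)
    n_replicates: int = 2
    selection_strategy: str = "random"
    selection_fraction: float = 0.2
    imputers: tuple[str, ...] = ("allele_frequency", "family_kinship",
                                 "population_ld", "ped_pop")
    external_results: dict[str, str] = field(default_factory=dict)
    k_flank: int = 10
    ped_pop_tau: float = 0.8
    n_buffer: int = 500
    run_association: bool = False
    n_assoc_snps: int = 20
    n_traits: int = 10
    sigma_g2: float = 1.0
    sigma_e2: float = 1.0
    v_a: float = 0.01
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
    outdir: str = "pedimpute_out"
    base_seed: int = 1

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_PRESETS and not self.scenario_overrides:
            raise ValueError(
                f"unknown scenario preset {self.scenario!r}; "
                f"available: {sorted(SCENARIO_PRESETS)}"
            )
        unknown = set(self.imputers) - set(BUILTIN_IMPUTERS)
        if unknown:
            raise ValueError(f"unknown imputers {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        for key in ("size_range", "generations_range", "sibship_range",
                    "imputers", "alphas"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def scenario_config(self) -> ScenarioConfig:
        base = SCENARIO_PRESETS.get(self.scenario, ScenarioConfig())
        if not self.scenario_overrides:
            return base
        d = asdict(base)
        spec = d.pop("maf_spectrum")
        over = dict(self.scenario_overrides)
        if "maf_spectrum" in over:
            spec.update(over.pop("maf_spectrum"))
        d.update(over)
        return ScenarioConfig(maf_spectrum=MafSpectrum(**spec), **d)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_pedigrees(cfg: ExperimentConfig) -> list[Pedigree]:
    if cfg.ped_file:
        return read_ped(cfg.ped_file)
    ped_seed = replicate_seeds(cfg.base_seed, 1)[0][0] ^ 0x5EED
    return generate_pedigree_set(
        cfg.n_pedigrees, cfg.size_range, cfg.generations_range,
        cfg.sibship_range, seed=ped_seed & 0x7FFFFFFF,
    )


def run_imputers(
    cfg: ExperimentConfig, dataset: StudyDataset
) -> dict[str, ImputationResult]:
    """Run the configured built-in imputers (plus external imports) on one dataset."""
    ref_mafs = estimate_reference_maf(dataset)
    results: dict[str, ImputationResult] = {}
    need_fam = {"family_kinship", "ped_pop"} & set(cfg.imputers)
    need_pop = {"population_ld", "ped_pop"} & set(cfg.imputers)
    if "allele_frequency" in cfg.imputers:
        results["allele_frequency"] = impute_allele_frequency(dataset, ref_mafs)
    fam = impute_family_kinship(dataset, ref_mafs=ref_mafs) if need_fam else None
    pop = (impute_population_ld(dataset, k_flank=cfg.k_flank, ref_mafs=ref_mafs)
           if need_pop else None)
    if "family_kinship" in cfg.imputers:
        results["family_kinship"] = fam
    if "population_ld" in cfg.imputers:
        results["population_ld"] = pop
    if "ped_pop" in cfg.imputers:
        results["ped_pop"] = combine_ped_pop(fam, pop, tau=cfg.ped_pop_tau)
    for label, path in cfg.external_results.items():
        results[label] = import_external_result(path, method_label=label)
    return results


def _association_table(
    cfg: ExperimentConfig,
    dataset: StudyDataset,
    results: dict[str, ImputationResult],
    assoc_seed: int,
) -> pd.DataFrame:
    """Null and alternative LMM tests on a subsample of testable SNPs."""
    from .traits import simulate_traits

    truth = dataset.truth
    targets = dataset.study_subject_ids
    A = block_diag_relationship(dataset.pedigrees).reindex(targets)
    eig = KinshipEigen.from_relationship(A)
    tgt_idx = truth.subject_index(targets)
    true_d = truth.dosages()[tgt_idx].astype(float)

    testable = exclude_buffer(truth.snp_ids, cfg.n_buffer)
    testable = [s for s in testable if s not in dataset.gwas_snp_ids]
    rng = np.random.default_rng(np.random.SeedSequence(assoc_seed))
    lut = {s: j for j, s in enumerate(truth.snp_ids)}
    cand = [s for s in testable if np.ptp(true_d[:, lut[s]]) > 0]
    if not cand:
        raise PipelineError("association: no polymorphic testable SNPs")
    chosen = rng.choice(len(cand), size=min(cfg.n_assoc_snps, len(cand)),
                        replace=False)
    rows = []
    for c in chosen:
        sid = cand[int(c)]
        j = lut[sid]
        maf = float(dataset.pool_maf[j])
        x_true = true_d[:, j]
        for model in ("H0", "Ha"):
            tr = simulate_traits(
                A, model=model,
                X=x_true if model == "Ha" else None,
                maf=maf if model == "Ha" else None,
                sigma_g2=cfg.sigma_g2, sigma_e2=cfg.sigma_e2, v_a=cfg.v_a,
                n_traits=cfg.n_traits,
                seed=int(rng.integers(2**31)),
            )
            sources = {"true": x_true}
            for name, res in results.items():
                sources[name] = res.dosages[:, j]
            for t in range(tr.values.shape[1]):
                y = tr.values[:, t]
                for source, x in sources.items():
                    if np.ptp(x) == 0.0:
                        continue
                    _, _, p = lmm_test(y, x, eig)
                    rows.append({
                        "snp_id": sid, "maf": maf, "model": model,
                        "source": source, "replicate": dataset.replicate_index,
                        "trait": t, "p_value": p,
                    })
    return pd.DataFrame(rows)


def run_pipeline(cfg: ExperimentConfig) -> dict[str, Path]:
    """Run the full experiment; returns the paths of the written outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest: dict[str, Any] = {
        "config": asdict(cfg),
        "config_hash": chash,
        "version": __version__,
        "replicate_seeds": [],
    }

    try:
        peds = load_pedigrees(cfg)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"pedigree stage failed: {exc}") from exc
    manifest["n_pedigrees"] = len(peds)
    manifest["n_subjects"] = sum(len(p) for p in peds)

    scen = cfg.scenario_config()
    try:
        datasets = make_replicates(peds, scen, cfg.n_replicates, cfg.base_seed)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"simulate stage failed: {exc}") from exc
    manifest["replicate_seeds"] = [
        dict(zip(("pool", "drop", "panel"), s))
        for s in replicate_seeds(cfg.base_seed, cfg.n_replicates)
    ]

    sel_seeds = [s[2] ^ 0x1234 for s in
                 replicate_seeds(cfg.base_seed, cfg.n_replicates)]
    per_snp_tables = []
    assoc_tables = []
    for r, ds in enumerate(datasets):
        try:
            selres: SelectionResult = select(
                cfg.selection_strategy, peds, cfg.selection_fraction,
                seed=sel_seeds[r] & 0x7FFFFFFF,
            )
            ds.reference_subject_ids = set(selres.selected_ids)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"select stage failed: {exc}") from exc
        try:
            results = run_imputers(cfg, ds)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"impute stage failed: {exc}") from exc
        try:
            for name, res in results.items():
                tab = score_dataset(ds, res, n_buffer=cfg.n_buffer)
                tab.insert(0, "method", name)
                tab.insert(0, "replicate", r)
                per_snp_tables.append(tab)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"score stage failed: {exc}") from exc
        if cfg.run_association:
            try:
                assoc_tables.append(
                    _association_table(cfg, ds, results,
                                       assoc_seed=(sel_seeds[r] ^ 0x777) & 0x7FFFFFFF)
                )
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(f"assoc stage failed: {exc}") from exc

    def write_tsv(df: pd.DataFrame, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# config_hash={chash}\n")
            df.to_csv(fh, sep="\t", index=False)

    files: dict[str, Path] = {}
    per_snp = pd.concat(per_snp_tables, ignore_index=True)
    files["accuracy_per_snp"] = outdir / "accuracy_per_snp.tsv"
    write_tsv(per_snp, files["accuracy_per_snp"])

    summaries = []
    for name, sub in per_snp.groupby("method"):
        s = summarize_by_bin(sub)
        s.insert(0, "method", name)
        summaries.append(s)
    files["accuracy_by_bin"] = outdir / "accuracy_by_bin.tsv"
    write_tsv(pd.concat(summaries, ignore_index=True), files["accuracy_by_bin"])

    if cfg.run_association and assoc_tables:
        assoc = pd.concat(assoc_tables, ignore_index=True)
        files["association_tests"] = outdir / "association_tests.tsv"
        write_tsv(assoc, files["association_tests"])
        rates = estimate_rates(assoc, alphas=cfg.alphas)
        files["rates"] = outdir / "rates.tsv"
        write_tsv(rates, files["rates"])

    manifest["outputs"] = {k: str(v) for k, v in files.items()}
    files["manifest"] = outdir / "manifest.json"
    files["manifest"].write_text(json.dumps(manifest, indent=1, default=str))
    return files
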