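"""Gene dropping: transmit founder haplotypes through pedigrees with recombination.

Founders draw distinct haplotypes from the pool without replacement (across
all pedigrees of a replicate, since founders are modeled as unrelated draws
from one population).  Each meiosis starts from a randomly chosen parental
haplotype and switches between the parent's two haplotypes between adjacent
sites with probability ``theta = min(0.5, 0.01 * d_cM)`` — a linear
1%-per-centiMorgan rule with no interference, exact at short distances.
The genetic map is uniform: 1 cM per 1000 kb by default.

The resulting phased genotypes are the simulation truth; masking a sparse
GWAS panel on top of them produces a study dataset ready for reference-
subject selection and imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pedigree import Pedigree
from .synthetic import HaplotypePool, ScenarioConfig, generate_founder_pool

__all__ = [
    "GeneticMap",
    "PhasedGenotypes",
    "StudyDataset",
    "drop_haplotypes",
    "mask_gwas_panel",
    "make_replicates",
    "meiosis",
]


@dataclass(frozen=True)
class GeneticMap:
    """Uniform genetic map over a set of physical positions."""

    positions_bp: np.ndarray
    cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions_bp", np.asarray(self.positions_bp, dtype=np.int64)
        )
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")
        if np.any(np.diff(self.positions_bp) < 0):
            raise ValueError("positions must be non-decreasing")

    def interval_cm(self) -> np.ndarray:
        """Genetic length of each adjacent-site interval, in cM."""
        return np.diff(self.positions_bp) / 1_000_000.0 * self.cm_per_mb

    def recombination_fractions(self) -> np.ndarray:
        """Per-interval switch probability: min(0.5, 0.01 * d_cM)."""
        return np.minimum(0.5, 0.01 * self.interval_cm())


@dataclass
class PhasedGenotypes:
    """True phased genotypes for every pedigree member.

    ``haplotypes`` has shape (N, 2, S) of minor-allele indicators; every
    nonfounder haplotype is a mosaic of the corresponding parent's two
    haplotypes, and founder haplotypes are distinct pool rows recorded in
    ``founder_haplotype_labels``.
    """

    haplotypes: np.ndarray  # (N, 2, S) uint8
    subject_order: list[str]
    snp_ids: list[str]
    positions_bp: np.ndarray
    founder_haplotype_labels: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        n, two, s = self.haplotypes.shape
        if two != 2 or n != len(self.subject_order) or s != len(self.snp_ids):
            raise ValueError("haplotype array shape inconsistent with labels")

    @property
    def n_subjects(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """Minor-allele counts, shape (N, S), values in {0, 1, 2}."""
        return self.haplotypes.sum(axis=1).astype(np.int8)

    def subject_index(self, ids: Sequence[str]) -> np.ndarray:
        lut = {s: i for i, s in enumerate(self.subject_order)}
        return np.array([lut[s] for s in ids], dtype=np.intp)


@dataclass
class StudyDataset:
    """One simulated replicate: truth, GWAS panel, and (later) reference set."""

    truth: PhasedGenotypes
    pedigrees: list[Pedigree]
    pool_maf: np.ndarray
    gwas_snp_ids: set[str] = field(default_factory=set)
    reference_subject_ids: set[str] = field(default_factory=set)
    replicate_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        all_snps = set(self.truth.snp_ids)
        if not self.gwas_snp_ids <= all_snps:
            raise ValueError("gwas_snp_ids must be a subset of the SNP ids")
        members = {s for p in self.pedigrees for s in p.subject_ids}
        if not self.reference_subject_ids <= members:
            raise ValueError("reference subjects must be pedigree members")

    @property
    def study_subject_ids(self) -> list[str]:
        """Imputation targets: all members not in the reference set."""
        return [s for s in self.truth.subject_order
                if s not in self.reference_subject_ids]

    @property
    def panel_mask(self) -> np.ndarray:
        """Boolean mask over SNPs: True where the site is on the GWAS panel."""
        return np.array([s in self.gwas_snp_ids for s in self.truth.snp_ids])


def meiosis(
    parent_haps: np.ndarray, thetas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Produce one gamete from a parent's two haplotypes.

    The transmitted haplotype starts from a random parental strand and
    switches strand between adjacent sites with the per-interval
    probabilities ``thetas``.
    """
    s = parent_haps.shape[1]
    switches = rng.random(s - 1) < thetas
    strand = np.empty(s, dtype=np.intp)
    strand[0] = rng.integers(2)
    np.cumsum(switches, out=strand[1:])
    strand[1:] += strand[0]
    strand &= 1
    return parent_haps[strand, np.arange(s)]


def drop_haplotypes(
    peds: Sequence[Pedigree],
    pool: HaplotypePool,
    gmap: GeneticMap | None = None,
    seed: int = 0,
) -> PhasedGenotypes:
    """Drop pool haplotypes through the pedigrees.

    Founder haplotypes are sampled without replacement across *all*
    pedigrees; nonfounders receive one gamete from each parent, generated in
    topological order so parents are always realized first.  Deterministic
    given ``seed``.
    """
    if gmap is None:
        gmap = GeneticMap(pool.positions_bp)
    if gmap.positions_bp.shape[0] != pool.n_snps:
        raise ValueError("genetic map must cover all pool sites")
    n_founders = sum(len(p.founders) for p in peds)
    if pool.n_haplotypes < 2 * n_founders:
        raise ValueError(
            f"pool has {pool.n_haplotypes} haplotypes but "
            f"{2 * n_founders} founder haplotypes are required"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    thetas = gmap.recombination_fractions()

    founder_rows = rng.choice(pool.n_haplotypes, size=2 * n_founders, replace=False)
    subject_order = [s for p in peds for s in p.subject_ids]
    S = pool.n_snps
    haps = np.empty((len(subject_order), 2, S), dtype=np.uint8)
    pos = {s: i for i, s in enumerate(subject_order)}

    labels: dict[str, tuple[int, int]] = {}
    fidx = 0
    for ped in peds:
        for sid in ped.topological_order():
            m = ped.member(sid)
            i = pos[sid]
            if m.is_founder:
                r1, r2 = founder_rows[2 * fidx], founder_rows[2 * fidx + 1]
                fidx += 1
                haps[i, 0] = pool.haplotypes[r1]
                haps[i, 1] = pool.haplotypes[r2]
                labels[sid] = (int(r1), int(r2))
            else:
                haps[i, 0] = meiosis(haps[pos[m.father_id]], thetas, rng)
                haps[i, 1] = meiosis(haps[pos[m.mother_id]], thetas, rng)
    return PhasedGenotypes(
        haps, subject_order, list(pool.snp_ids), pool.positions_bp,
        founder_haplotype_labels=labels,
    )


def mask_gwas_panel(
    truth: PhasedGenotypes,
    peds: Sequence[Pedigree],
    pool_maf: np.ndarray,
    n_panel: int,
    seed: int = 0,
    replicate_index: int = 0,
) -> StudyDataset:
    """Select a uniformly random GWAS panel of ``n_panel`` sites.

    The truth is untouched; the panel is a labelled view that exporters and
    imputers interpret as the sites observed on every study subject.
    """
    if n_panel >= truth.n_snps:
        raise ValueError("n_panel must be smaller than the number of sites")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(truth.n_snps, size=n_panel, replace=False)
    panel = {truth.snp_ids[i] for i in chosen}
    return StudyDataset(
        truth=truth,
        pedigrees=list(peds),
        pool_maf=np.asarray(pool_maf, dtype=float),
        gwas_snp_ids=panel,
        replicate_index=replicate_index,
        seed=seed,
    )


def replicate_seeds(base_seed: int, n_replicates: int) -> list[tuple[int, int, int]]:
    """Derive (pool, drop, panel) integer seeds for each replicate."""
    ss = np.random.SeedSequence(base_seed)
    out = []
    for child in ss.spawn(n_replicates):
        pool_s, drop_s, panel_s = child.generate_state(3) >> 1  # keep < 2**31
        out.append((int(pool_s), int(drop_s), int(panel_s)))
    return out


def make_replicates(
    peds: Sequence[Pedigree],
    cfg: ScenarioConfig,
    n_replicates: int,
    base_seed: int = 0,
) -> list[StudyDataset]:
    """Simulate independent replicate datasets (fresh pool + drop + panel each).

    Per-replicate seeds derive deterministically from ``base_seed`` and the
    replicate index, so any single replicate can be regenerated in isolation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    out: list[StudyDataset] = []
    for r, (pool_s, drop_s, panel_s) in enumerate(
        replicate_seeds(base_seed, n_replicates)
    ):
        pool = generate_founder_pool(cfg.with_seed(pool_s))
        truth = drop_haplotypes(peds, pool, seed=drop_s)
        ds = mask_gwas_panel(
            truth, peds, pool.maf(), cfg.n_gwas_panel,
            seed=panel_s, replicate_index=r,
        )
        out.append(ds)
    return out
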