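"""Shared fixtures: small pedigrees, pools, and study datasets.

Everything is generated programmatically at session scope with fixed seeds,
so the suite needs no data files and is fully reproducible.
"""

from __future__ import annotations

import numpy as np
import pytest

from pedimpute.genedrop import make_replicates
from pedimpute.pedigree import Member, Pedigree
from pedimpute.selection import select_random
from pedimpute.synthetic import (
    MafSpectrum,
    ScenarioConfig,
    generate_founder_pool,
    generate_pedigree_set,
)


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree(
        "trio",
        [Member("dad", sex="male"), Member("mum", sex="female"),
         Member("kid", "dad", "mum", "female")],
    )


@pytest.fixture
def three_generations() -> Pedigree:
    """Grandparents, two married children with spouses, three grandchildren."""
    return Pedigree(
        "g3",
        [
            Member("gf", sex="male"), Member("gm", sex="female"),
            Member("p1", "gf", "gm", "male"), Member("p2", "gf", "gm", "female"),
            Member("s1", sex="female"), Member("s2", sex="male"),
            Member("c1", "p1", "s1", "male"), Member("c2", "p1", "s1", "female"),
            Member("c3", "s2", "p2", "male"),
        ],
    )


@pytest.fixture(scope="session")
def small_peds():
    return generate_pedigree_set(4, (8, 25), (3, 4), (1, 6), seed=11)


@pytest.fixture(scope="session")
def small_cfg() -> ScenarioConfig:
    return ScenarioConfig(
        n_haplotypes=400,
        n_snps=400,
        region_length_bp=260_000,
        maf_spectrum=MafSpectrum(min_maf=0.01),
        ld_strength=0.37,
        n_gwas_panel=40,
        region_label="test-small",
        seed=3,
    )


@pytest.fixture(scope="session")
def small_pool(small_cfg):
    return generate_founder_pool(small_cfg)


@pytest.fixture(scope="session")
def small_dataset(small_peds, small_cfg):
    """One replicate with a 25% random reference selection applied."""
    ds = make_replicates(small_peds, small_cfg, 1, base_seed=5)[0]
    sel = select_random(small_peds, 0.25, seed=9)
    ds.reference_subject_ids = set(sel.selected_ids)
    return ds


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
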