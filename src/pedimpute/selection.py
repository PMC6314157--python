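"""Selection of pedigree members to sequence as the imputation reference panel.

Four strategies are provided, mirroring the study designs compared in
family-based sequencing projects:

* ``random`` — uniform draw within each pedigree;
* ``max_unrelated`` — greedily pick pairwise-unrelated subjects (the goal
  of tools such as PRIMUS);
* ``generation_units`` — pick whole parent-couple units from the oldest
  generations down (the goal of ExomePicks-style designs);
* ``founder_coverage`` — greedily maximize the expected fraction of founder
  genome copies observed in at least one selected subject, estimated by
  Monte-Carlo gene drops of founder-allele labels (a transparent surrogate
  for inheritance-vector-based pickers such as GIGI-Pick).

All strategies spend exactly the same per-pedigree quota for a given
fraction, so downstream accuracy comparisons are like-for-like.  The quota
is round-half-up per pedigree with a largest-remainder correction so the
global total equals ``round(fraction * N_total)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .pedigree import Pedigree, RelationshipMatrix, relationship_matrix

__all__ = [
    "SelectionResult",
    "per_pedigree_quotas",
    "select_random",
    "select_max_unrelated",
    "select_generation_units",
    "select_founder_coverage",
    "select",
]

STRATEGIES = ("random", "max_unrelated", "generation_units", "founder_coverage")


@dataclass
class SelectionResult:
    """Subjects chosen for full sequencing, per pedigree."""

    strategy: str
    selected_ids: set[str]
    fraction: float
    per_pedigree: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.per_pedigree:
            flat = {s for ids in self.per_pedigree.values() for s in ids}
            if flat != self.selected_ids:
                raise ValueError("per_pedigree entries disagree with selected_ids")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pedigree_id\tsubject_id\tstrategy\n")
            for ped_id, ids in self.per_pedigree.items():
                for sid in sorted(ids):
                    fh.write(f"{ped_id}\t{sid}\t{self.strategy}\n")

    def to_id_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for sid in sorted(self.selected_ids):
                fh.write(sid + "\n")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def per_pedigree_quotas(peds: Sequence[Pedigree], fraction: float) -> dict[str, int]:
    """Per-pedigree selection counts.

    Round-half-up of ``fraction * size`` per pedigree, then a deterministic
    largest-remainder adjustment so the total equals
    ``round(fraction * N_total)``.  Ties in remainder are broken by pedigree
    size (desc) then pedigree id.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    sizes = {p.pedigree_id: len(p) for p in peds}
    total_target = _round_half_up(fraction * sum(sizes.values()))
    quotas = {pid: _round_half_up(fraction * n) for pid, n in sizes.items()}
    # fractional remainders drive the correction direction
    frac_part = {pid: fraction * n - np.floor(fraction * n)
                 for pid, n in sizes.items()}
    diff = total_target - sum(quotas.values())
    order_up = sorted(sizes, key=lambda p: (-frac_part[p], -sizes[p], p))
    order_down = sorted(sizes, key=lambda p: (frac_part[p], -sizes[p], p))
    i = 0
    while diff > 0:
        pid = order_up[i % len(order_up)]
        if quotas[pid] < sizes[pid]:
            quotas[pid] += 1
            diff -= 1
        i += 1
    i = 0
    while diff < 0:
        pid = order_down[i % len(order_down)]
        if quotas[pid] > 0:
            quotas[pid] -= 1
            diff += 1
        i += 1
    for pid, q in quotas.items():
        if q == 0:
            warnings.warn(
                f"selection fraction {fraction} yields 0 subjects in "
                f"pedigree {pid!r}", stacklevel=3,
            )
    return quotas


def _result(
    strategy: str, fraction: float, per_ped: dict[str, list[str]]
) -> SelectionResult:
    flat = {s for ids in per_ped.values() for s in ids}
    return SelectionResult(strategy, flat, fraction, per_ped)


def select_random(
    peds: Sequence[Pedigree], fraction: float, seed: int = 0
) -> SelectionResult:
    """Uniformly random subjects within each pedigree, to quota."""
    quotas = per_pedigree_quotas(peds, fraction)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    per_ped = {}
    for ped in peds:
        ids = ped.subject_ids
        take = quotas[ped.pedigree_id]
        chosen = rng.choice(len(ids), size=take, replace=False)
        per_ped[ped.pedigree_id] = [ids[i] for i in sorted(chosen)]
    return _result("random", fraction, per_ped)


def select_max_unrelated(
    peds: Sequence[Pedigree],
    fraction: float,
    kinship_threshold: float = 0.0,
) -> SelectionResult:
    """Greedy maximally-unrelated selection.

    Subjects are scanned in order of increasing total relatedness (row sum
    of the relationship matrix, ties by subject id) and accepted when their
    twice-kinship with every already-selected subject does not exceed
    ``kinship_threshold``.  If fewer compatible subjects exist than the
    quota, the quota is filled with the lowest-total-relatedness leftovers.
    """
    quotas = per_pedigree_quotas(peds, fraction)
    per_ped = {}
    for ped in peds:
        take = quotas[ped.pedigree_id]
        rel = relationship_matrix(ped)
        total = rel.A.sum(axis=0) - np.diag(rel.A)
        ids = rel.subject_order
        order = sorted(range(len(ids)), key=lambda i: (total[i], ids[i]))
        chosen: list[int] = []
        for i in order:
            if len(chosen) == take:
                break
            if all(rel.A[i, j] <= kinship_threshold for j in chosen):
                chosen.append(i)
        if len(chosen) < take and len(ids) <= 20:
            exact = _exact_unrelated_set(rel.A, take, kinship_threshold, ids)
            if exact is not None:
                chosen = exact
        if len(chosen) < take:
            for i in order:
                if len(chosen) == take:
                    break
                if i not in chosen:
                    chosen.append(i)
        per_ped[ped.pedigree_id] = [ids[i] for i in chosen]
    return _result("max_unrelated", fraction, per_ped)


def _exact_unrelated_set(
    A: np.ndarray, take: int, threshold: float, ids: Sequence[str]
) -> list[int] | None:
    """Exhaustive search for a pairwise-compatible set of the given size.

    Used as a fallback on small pedigrees where the greedy scan can miss a
    feasible set; returns the lexicographically first (by subject id) such
    set, or None.
    """
    from itertools import combinations

    order = sorted(range(len(ids)), key=lambda i: ids[i])
    for combo in combinations(order, take):
        ok = all(A[a, b] <= threshold for a, b in combinations(combo, 2))
        if ok:
            return list(combo)
    return None


def _couple_units(ped: Pedigree) -> list[tuple[int, int, str, tuple[str, str]]]:
    """Parent couples as (generation, -n_offspring, couple key, (father, mother))."""
    depth = ped.generation_depth()
    offspring: dict[tuple[str, str], int] = {}
    for m in ped.nonfounders:
        offspring[(m.father_id, m.mother_id)] = (
            offspring.get((m.father_id, m.mother_id), 0) + 1
        )
    units = []
    for (fa, mo), n_off in offspring.items():
        # a married-in founder spouse has depth 0; the couple's generation
        # is that of the lineage member, i.e. the deeper of the two
        gen = max(depth[fa], depth[mo])
        units.append((gen, -n_off, f"{fa}|{mo}", (fa, mo)))
    units.sort()
    return units


def select_generation_units(
    peds: Sequence[Pedigree], fraction: float
) -> SelectionResult:
    """Whole parent-couple units, oldest generation first.

    Units are ranked by generation (oldest first), then by offspring count
    (largest first), then by couple id; members are taken couple by couple
    until the quota, the last couple possibly contributing one member only.
    Any remaining quota (no couples left) is filled by subject id order.
    """
    quotas = per_pedigree_quotas(peds, fraction)
    per_ped = {}
    for ped in peds:
        take = quotas[ped.pedigree_id]
        chosen: list[str] = []
        seen: set[str] = set()
        for _gen, _negoff, _key, (fa, mo) in _couple_units(ped):
            for sid in (fa, mo):
                if len(chosen) < take and sid not in seen:
                    chosen.append(sid)
                    seen.add(sid)
        for sid in sorted(ped.subject_ids):
            if len(chosen) >= take:
                break
            if sid not in seen:
                chosen.append(sid)
                seen.add(sid)
        per_ped[ped.pedigree_id] = chosen[:take]
    return _result("generation_units", fraction, per_ped)


def _label_drops(
    ped: Pedigree, n_drops: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Single-locus gene drops of founder-allele labels.

    Returns an array of shape (n_drops, n_members, 2) holding, per drop, the
    founder-allele label carried on each of the subject's two haplotypes,
    plus the number of distinct founder labels (2 * n_founders).
    """
    order = ped.topological_order()
    idx = {s: i for i, s in enumerate(order)}
    n = len(order)
    lab = np.empty((n_drops, n, 2), dtype=np.int32)
    next_label = 0
    for sid in order:
        m = ped.member(sid)
        i = idx[sid]
        if m.is_founder:
            lab[:, i, 0] = next_label
            lab[:, i, 1] = next_label + 1
            next_label += 2
        else:
            for k, parent in enumerate((m.father_id, m.mother_id)):
                pick = rng.integers(2, size=n_drops)
                lab[:, i, k] = lab[np.arange(n_drops), idx[parent], pick]
    # reorder to the pedigree's member order
    sel = [idx[s] for s in ped.subject_ids]
    return lab[:, sel, :], next_label


def expected_founder_coverage(
    ped: Pedigree, subject_ids: Sequence[str], labels: np.ndarray, n_labels: int
) -> float:
    """Expected fraction of founder genome copies seen in the given subjects."""
    if not subject_ids:
        return 0.0
    lut = {s: i for i, s in enumerate(ped.subject_ids)}
    sel = [lut[s] for s in subject_ids]
    n_drops = labels.shape[0]
    cov = 0.0
    for d in range(n_drops):
        cov += len(set(labels[d, sel, :].ravel())) / n_labels
    return cov / n_drops


def select_founder_coverage(
    peds: Sequence[Pedigree],
    fraction: float,
    n_mc_drops: int = 500,
    seed: int = 0,
) -> SelectionResult:
    """Greedy forward selection maximizing expected founder-genome coverage.

    Coverage of a set is the expected fraction of the ``2f`` founder allele
    copies present in at least one selected subject, estimated over
    ``n_mc_drops`` single-locus label drops.  On small pedigrees the
    optimum is found by exact enumeration over quota-sized subsets (greedy
    marginal gains tie between, e.g., a parent and a child of a nuclear
    family, and the tie matters); larger pedigrees use greedy forward
    selection, whose monotone objective gives the usual (1 - 1/e)
    guarantee.  Ties break by subject id.
    """
    from math import comb
    if n_mc_drops < 100:
        raise ValueError("n_mc_drops must be >= 100 for a stable estimate")
    quotas = per_pedigree_quotas(peds, fraction)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    per_ped = {}
    for ped in peds:
        take = quotas[ped.pedigree_id]
        labels, n_labels = _label_drops(ped, n_mc_drops, rng)
        # per-drop sets as bit masks for speed
        n = len(ped)
        masks = np.zeros((n_mc_drops, n, n_labels), dtype=bool)
        dr = np.arange(n_mc_drops)[:, None]
        su = np.arange(n)[None, :]
        masks[dr, su, labels[:, :, 0]] = True
        masks[dr, su, labels[:, :, 1]] = True
        ids = ped.subject_ids
        id_order = sorted(range(n), key=lambda i: ids[i])
        if 0 < take and comb(n, take) <= 5000:
            from itertools import combinations

            best, best_cov = None, -1.0
            for combo in combinations(id_order, take):
                cov = float(np.logical_or.reduce(masks[:, combo, :],
                                                 axis=1).sum())
                if cov > best_cov + 1e-9:
                    best_cov, best = cov, combo
            chosen = list(best) if best is not None else []
        else:
            covered = np.zeros((n_mc_drops, n_labels), dtype=bool)
            chosen = []
            for _ in range(take):
                best_i, best_gain = None, -1.0
                for i in id_order:
                    if i in chosen:
                        continue
                    gain = float((masks[:, i, :] & ~covered).sum())
                    if gain > best_gain + 1e-9:
                        best_gain, best_i = gain, i
                chosen.append(best_i)
                covered |= masks[:, best_i, :]
        per_ped[ped.pedigree_id] = [ids[i] for i in chosen]
    return _result("founder_coverage", fraction, per_ped)


def select(
    strategy: str,
    peds: Sequence[Pedigree],
    fraction: float,
    seed: int = 0,
    **kwargs,
) -> SelectionResult:
    """Dispatch to one of the named strategies."""
    if strategy == "random":
        return select_random(peds, fraction, seed=seed, **kwargs)
    if strategy == "max_unrelated":
        return select_max_unrelated(peds, fraction, **kwargs)
    if strategy == "generation_units":
        return select_generation_units(peds, fraction, **kwargs)
    if strategy == "founder_coverage":
        return select_founder_coverage(peds, fraction, seed=seed, **kwargs)
    raise ValueError(f"unknown selection strategy {strategy!r}")
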