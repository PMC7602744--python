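"""Host-balanced, project-balanced dataset construction.

Public studies sequence one host each, and project sizes are wildly
uneven, so training sets are balanced twice over: the two host classes
get equal sample counts, and within the over-represented class each
project contributes as evenly as possible.  Quotas are filled round-robin
(water-filling): every project's quota rises one sample per round until
the target is met, projects cap out at their pool size, and a final
partial round goes one sample at a time to the projects with the most
samples remaining (ties broken by project id).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_table import HOSTS


@dataclass
class BalancedDataset:
    """Sample ids per host class plus the provenance of their selection."""

    pet_ids: list[str]
    human_ids: list[str]
    quotas: dict[str, dict[str, int]]  # host -> project -> quota
    replacement: bool
    seed: int
    target_per_class: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.pet_ids) != len(self.human_ids):
            raise ValueError("classes are not balanced")
        if not self.replacement:
            for ids in (self.pet_ids, self.human_ids):
                if len(set(ids)) != len(ids):
                    raise ValueError("duplicate sample ids in without-replacement mode")
        self.target_per_class = len(self.pet_ids)

    @property
    def sample_ids(self) -> list[str]:
        return self.pet_ids + self.human_ids


def project_quotas(pool_sizes: dict[str, int], target: int, replacement: bool = False) -> dict[str, int]:
    """Per-project sample quotas for drawing ``target`` samples as evenly as possible.

    Without replacement, quotas never exceed pool sizes; with replacement
    pools never exhaust and the final partial round favours larger pools.
    """
    projects = sorted(pool_sizes)
    if not projects:
        raise ValueError("no projects to sample from")
    if any(pool_sizes[p] <= 0 for p in projects):
        raise ValueError("every project must have a positive pool size")
    if not replacement and target > sum(pool_sizes.values()):
        raise ValueError(
            f"target {target} exceeds the {sum(pool_sizes.values())} available samples"
        )
    quotas = {p: 0 for p in projects}
    remaining_target = target
    while remaining_target > 0:
        active = [p for p in projects if replacement or quotas[p] < pool_sizes[p]]
        if remaining_target >= len(active):
            for p in active:
                quotas[p] += 1
            remaining_target -= len(active)
        else:
            # partial final round: one at a time to the largest remaining pool
            for _ in range(remaining_target):
                key = (lambda p: (-(pool_sizes[p] - quotas[p]), p)) if not replacement \
                    else (lambda p: (-pool_sizes[p], p))
                p = min(active, key=key)
                quotas[p] += 1
            remaining_target = 0
    return quotas


def _sample_class(
    md: pd.DataFrame, target: int, replacement: bool, rng: np.random.Generator
) -> tuple[list[str], dict[str, int]]:
    pools = {p: sorted(ids) for p, ids in md.groupby("project_id").groups.items()}
    sizes = {p: len(ids) for p, ids in pools.items()}
    quotas = project_quotas(sizes, target, replacement)
    chosen: list[str] = []
    for p in sorted(pools):
        ids = pools[p]
        q = quotas[p]
        if not replacement and q == len(ids):
            chosen.extend(ids)
        else:
            chosen.extend(rng.choice(ids, size=q, replace=replacement).tolist())
    return chosen, quotas


def build_balanced_dataset(
    metadata: pd.DataFrame,
    seed: int = 0,
    replacement: bool = False,
    target_per_class: int | None = None,
) -> BalancedDataset:
    """Equal-sized pet and human sample sets, project-balanced within each class.

    The minority class is taken in full (its quota equals its pool); the
    majority class is down-sampled to the same size with round-robin
    per-project quotas.  With ``replacement=True`` quotas may exceed
    project sizes (used by the learning-curve procedure).
    """
    counts = metadata["host"].value_counts()
    for host in HOSTS:
        if counts.get(host, 0) == 0:
            raise ValueError(f"no samples of host class {host!r}")
    if target_per_class is None:
        target_per_class = int(counts.min())
    rng = np.random.default_rng(seed)
    per_class: dict[str, list[str]] = {}
    quotas: dict[str, dict[str, int]] = {}
    for host in HOSTS:
        md = metadata[metadata["host"] == host]
        per_class[host], quotas[host] = _sample_class(md, target_per_class, replacement, rng)
    return BalancedDataset(
        pet_ids=per_class["pet"],
        human_ids=per_class["human"],
        quotas=quotas,
        replacement=replacement,
        seed=seed,
    )


def build_mixed_sets(
    metadata: pd.DataFrame,
    n_sets: int = 100,
    composition: dict[str, int] | None = None,
    seed: int = 0,
) -> list[list[str]]:
    """Repeatedly drawn mixed-species evaluation sets.

    Default composition mirrors the mixed-class evaluation design: 100
    sets of 200 samples each, 50 cats + 50 dogs + 100 humans; sampling
    within a set is without replacement.
    """
    if composition is None:
        composition = {"cat": 50, "dog": 50, "human": 100}
    pools = {
        sp: sorted(metadata.index[metadata["species"] == sp]) for sp in composition
    }
    for sp, quota in composition.items():
        if quota > len(pools[sp]):
            raise ValueError(
                f"species {sp!r} has {len(pools[sp])} samples, fewer than the quota {quota}"
            )
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        chosen: list[str] = []
        for sp in sorted(composition):
            chosen.extend(rng.choice(pools[sp], size=composition[sp], replace=False).tolist())
        sets.append(chosen)
    return sets


def write_manifest(dataset: BalancedDataset, path) -> None:
    """Sample-id manifest as TSV with provenance header comments."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# balanced dataset: {dataset.target_per_class} samples per class\n")
        fh.write(f"# replacement={dataset.replacement} seed={dataset.seed}\n")
        for host, quotas in dataset.quotas.items():
            fh.write(f"# quotas[{host}]={quotas}\n")
        fh.write("sample_id\thost\n")
        for sid in dataset.pet_ids:
            fh.write(f"{sid}\tpet\n")
        for sid in dataset.human_ids:
            fh.write(f"{sid}\thuman\n")
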