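"""Synthetic multi-project gut-microbiome count tables with known ground truth.

The generator emulates the statistical structure the pipeline assumes in
real cross-study 16S data:

* a shared log-normal baseline composition over a taxonomy with realistic
  rank structure (genera nested in families, orders, classes, phyla);
* per-taxon host effects: a log-fold shift ``delta`` on a planted subset
  of genera (half elevated in humans, half in pets);
* host-exclusive genera with hard zero probability in the other host
  (an Akkermansia-like human-only genus, a Fusobacterium-like pet-only
  genus), present at low baseline abundance so sampling depth makes their
  detection imperfect, as in real data;
* study batch effects: a per-(project, taxon) shift drawn once per
  project from Normal(0, sigma_batch) in log space;
* per-sample noise Normal(0, sigma_sample), and multinomial read counts
  at a fixed depth.

Per sample the log-intensity of taxon t is

    baseline_t + s_host * delta_t / 2 + batch_{project,t} + eps_{sample,t}

with s_host = +1 for humans and -1 for pets; the composition is the
softmax of the intensities and counts are multinomial at ``depth`` reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, validate_metadata
from .taxonomy import SEP

#: Training-design project sizes mirroring the study layout: 5 cat + 7 dog
#: projects (321 samples) and the 10 human projects' train-column sizes.
PAPER_PET_SIZES = (65, 44, 30, 19, 6, 34, 32, 30, 23, 19, 13, 6)
PAPER_PET_SPECIES = ("cat",) * 5 + ("dog",) * 7
PAPER_HUMAN_TRAIN_SIZES = (46, 45, 45, 45, 45, 31, 22, 21, 12, 9)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator."""

    n_genera: int = 60
    n_families: int = 25
    n_orders: int = 18
    n_classes: int = 12
    n_phyla: int = 8
    baseline_sigma: float = 1.0  # spread of baseline log-abundances across genera
    n_planted: int = 8  # genera with a host effect
    effect_size: float = 3.0  # |delta|, log-e fold shift between hosts
    n_human_exclusive: int = 1
    n_pet_exclusive: int = 1
    exclusive_baseline: float = -2.5  # low abundance -> depth-limited detection
    sigma_batch: float = 1.0  # per-(project, taxon) shift SD
    sigma_sample: float = 1.0  # per-(sample, taxon) noise SD
    depth: int = 5000
    pet_project_sizes: tuple[int, ...] = (10, 10, 10, 10)
    pet_project_species: tuple[str, ...] = ("cat", "cat", "dog", "dog")
    human_project_sizes: tuple[int, ...] = (10, 10, 10, 10)

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if min(self.sigma_batch, self.sigma_sample, self.baseline_sigma) < 0:
            raise ValueError("sigma values must be non-negative")
        if self.n_genera < 2:
            raise ValueError("need at least 2 genera")
        if not self.pet_project_sizes or not self.human_project_sizes:
            raise ValueError("each host needs at least one project")
        if len(self.pet_project_species) != len(self.pet_project_sizes):
            raise ValueError("pet species list must match pet project sizes")
        n_special = (
            self.n_planted + self.n_human_exclusive + self.n_pet_exclusive
        )
        if n_special > self.n_genera:
            raise ValueError("planted + exclusive taxa exceed the genus catalogue")


@dataclass
class GeneratedDataset:
    """A synthetic feature table + metadata with full ground truth."""

    table: FeatureTable
    metadata: pd.DataFrame
    truth: dict = field(default_factory=dict)

    @property
    def planted_taxa(self) -> list[str]:
        return self.truth["planted_taxa"]

    @property
    def differential_taxa(self) -> list[str]:
        """All taxa with a real host effect: planted shifts plus exclusives."""
        return (
            self.truth["planted_taxa"]
            + self.truth["human_exclusive"]
            + self.truth["pet_exclusive"]
        )


def make_study_layout(preset: str, **overrides) -> GeneratorConfig:
    """Named project layouts: ``paper_like`` (12 pet + 10 human projects with
    the study's train-design sizes) or ``tiny`` (4+4 projects x 10 samples)."""
    if preset == "paper_like":
        cfg = GeneratorConfig(
            pet_project_sizes=PAPER_PET_SIZES,
            pet_project_species=PAPER_PET_SPECIES,
            human_project_sizes=PAPER_HUMAN_TRAIN_SIZES,
        )
    elif preset == "tiny":
        cfg = GeneratorConfig()
    else:
        raise ValueError(f"unknown preset {preset!r}; expected 'paper_like' or 'tiny'")
    return replace(cfg, **overrides) if overrides else cfg


def _catalogue(config: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    """Deterministic 6-rank lineage strings for the genus catalogue.

    A nested hierarchy is built by assigning each child rank uniformly to
    a parent, so aggregation groupings are fixed by the seed.  The last
    catalogue slots are reserved for the named host-exclusive genera.
    """
    phyla = [f"Phylum{i + 1:02d}" for i in range(config.n_phyla)]
    class_parent = rng.integers(0, config.n_phyla, size=config.n_classes)
    order_parent = rng.integers(0, config.n_classes, size=config.n_orders)
    family_parent = rng.integers(0, config.n_orders, size=config.n_families)
    n_regular = config.n_genera - config.n_human_exclusive - config.n_pet_exclusive
    genus_family = rng.integers(0, config.n_families, size=n_regular)
    lineages = []
    for g, fam in enumerate(genus_family):
        o = family_parent[fam]
        c = order_parent[o]
        p = class_parent[c]
        lineages.append(
            SEP.join(
                [
                    "Bacteria",
                    phyla[p],
                    f"Class{c + 1:02d}",
                    f"Order{o + 1:02d}",
                    f"Family{fam + 1:02d}",
                    f"Genus{g + 1:03d}",
                ]
            )
        )
    for i in range(config.n_human_exclusive):
        suffix = "" if i == 0 else f"_{i + 1}"
        lineages.append(
            SEP.join(
                [
                    "Bacteria", "Verrucomicrobia_like", "Verrucomicrobiae_like",
                    "Verrucomicrobiales_like", "Akkermansiaceae_like",
                    f"Akkermansia_like{suffix}",
                ]
            )
        )
    for i in range(config.n_pet_exclusive):
        suffix = "" if i == 0 else f"_{i + 1}"
        lineages.append(
            SEP.join(
                [
                    "Bacteria", "Fusobacteria_like", "Fusobacteriia_like",
                    "Fusobacteriales_like", "Fusobacteriaceae_like",
                    f"Fusobacterium_like{suffix}",
                ]
            )
        )
    return lineages


def generate(config: GeneratorConfig, seed: int = 0) -> GeneratedDataset:
    """Draw one dataset under ``config``; bit-identical under the same seed."""
    rng = np.random.default_rng(seed)
    taxa = _catalogue(config, rng)
    n_taxa = len(taxa)
    n_regular = n_taxa - config.n_human_exclusive - config.n_pet_exclusive
    human_excl = list(range(n_regular, n_regular + config.n_human_exclusive))
    pet_excl = list(range(n_regular + config.n_human_exclusive, n_taxa))

    baseline = rng.normal(0.0, config.baseline_sigma, size=n_taxa)
    baseline[human_excl] = config.exclusive_baseline
    baseline[pet_excl] = config.exclusive_baseline

    delta = np.zeros(n_taxa)
    planted = rng.choice(n_regular, size=config.n_planted, replace=False)
    planted.sort()
    signs = np.where(np.arange(config.n_planted) % 2 == 0, 1.0, -1.0)
    delta[planted] = signs * config.effect_size

    projects: list[tuple[str, str, str, int]] = []  # (project_id, host, species, size)
    for i, (size, sp) in enumerate(
        zip(config.pet_project_sizes, config.pet_project_species)
    ):
        projects.append((f"pet{i + 1:02d}", "pet", sp, size))
    for i, size in enumerate(config.human_project_sizes):
        projects.append((f"hum{i + 1:02d}", "human", "human", size))

    batch = {
        pid: rng.normal(0.0, config.sigma_batch, size=n_taxa)
        for pid, _, _, _ in projects
    }

    rows, sample_ids, meta_rows = [], [], []
    for pid, host, species, size in projects:
        s_host = 1.0 if host == "human" else -1.0
        for j in range(size):
            noise = rng.normal(0.0, config.sigma_sample, size=n_taxa)
            log_intensity = baseline + s_host * delta / 2.0 + batch[pid] + noise
            mass = np.exp(log_intensity - log_intensity.max())
            excluded = pet_excl if host == "human" else human_excl
            mass[excluded] = 0.0
            counts = rng.multinomial(config.depth, mass / mass.sum())
            sid = f"{pid}_s{j + 1:03d}"
            rows.append(counts)
            sample_ids.append(sid)
            meta_rows.append((sid, host, species, pid))

    table = FeatureTable(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa), level="genus"
    )
    metadata = validate_metadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "host", "species", "project_id"])
    )
    truth = {
        "planted_taxa": [taxa[i] for i in planted],
        "planted_delta": {taxa[i]: float(delta[i]) for i in planted},
        "human_exclusive": [taxa[i] for i in human_excl],
        "pet_exclusive": [taxa[i] for i in pet_excl],
        "baseline": dict(zip(taxa, baseline.tolist())),
        "batch_shifts": {pid: dict(zip(taxa, b.tolist())) for pid, b in batch.items()},
        "seed": seed,
    }
    return GeneratedDataset(table=table, metadata=metadata, truth=truth)
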