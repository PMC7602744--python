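"""Printed study-design bookkeeping: per-project sample counts.

These are the published per-project sample counts of the public datasets
the analysis was designed around (cat, dog and human faecal 16S studies).
They are inputs to dataset-construction bookkeeping — checking that the
balanced set reaches 321 samples per class, that the human per-project
quotas match the published train-column, and that the Mann-Whitney design
is 12 pet projects versus 10 human projects — without requiring any
sequencing data.
"""

from __future__ import annotations

import pandas as pd

#: Training pool: project id -> (species, number of samples).
TRAIN_PET_PROJECTS: dict[str, tuple[str, int]] = {
    "PRJNA504021": ("cat", 65),
    "PRJNA349988": ("cat", 44),
    "PRJNA248757": ("cat", 30),
    "PRJNA338653": ("cat", 19),
    "PRJNA350163": ("cat", 6),
    "PRJNA488105": ("dog", 34),
    "PRJNA525542": ("dog", 32),
    "PRJNA358232": ("dog", 30),
    "PRJNA391562": ("dog", 23),
    "PRJNA493249": ("dog", 19),
    "PRJDB5398": ("dog", 13),
    "PRJNA492898": ("dog", 6),
}

#: Human training pool: project id -> (full size, train-subset size).
TRAIN_HUMAN_PROJECTS: dict[str, tuple[int, int]] = {
    "PMID29795809": (681, 46),
    "PMID25417156": (200, 45),
    "PMID28195358": (115, 45),
    "PMID28179361": (102, 45),
    "PMID31027508": (49, 45),
    "PMID26179554": (31, 31),
    "PMID28429209": (22, 22),
    "qiita_10928": (21, 21),
    "PMID29404425": (12, 12),
    "PMID28191884": (9, 9),
}

#: Held-out projects used only after training: project id -> (species, size).
ADDITIONAL_PROJECTS: dict[str, tuple[str, int]] = {
    "PRJNA470724": ("cat", 74),
    "PMID32078625_cat": ("cat", 46),
    "PMID32078625_dog": ("dog", 192),
    "PRJNA401442": ("dog", 56),
    "PRJNA589580": ("dog", 35),
    "PRJNA592436": ("dog", 29),
    "PRJNA385551": ("human", 284),
    "PRJNA493726": ("human", 74),
}


def train_metadata(human_sizes: str = "full") -> pd.DataFrame:
    """Expand the training-pool design into a per-sample metadata table.

    ``human_sizes`` selects the full published human pools (``"full"``,
    1242 samples) or the published train-subset sizes (``"train"``,
    321 samples).  Sample ids are synthesized per project.
    """
    if human_sizes not in ("full", "train"):
        raise ValueError("human_sizes must be 'full' or 'train'")
    rows = []
    for pid, (species, size) in TRAIN_PET_PROJECTS.items():
        for j in range(size):
            rows.append((f"{pid}_s{j + 1:04d}", "pet", species, pid))
    for pid, (full, train) in TRAIN_HUMAN_PROJECTS.items():
        size = full if human_sizes == "full" else train
        for j in range(size):
            rows.append((f"{pid}_s{j + 1:04d}", "human", "human", pid))
    md = pd.DataFrame(rows, columns=["sample_id", "host", "species", "project_id"])
    return md.set_index("sample_id")


def design_summary() -> dict[str, int]:
    """Headline sample-count bookkeeping of the study design."""
    pet_total = sum(size for _, size in TRAIN_PET_PROJECTS.values())
    human_total = sum(full for full, _ in TRAIN_HUMAN_PROJECTS.values())
    human_train_total = sum(train for _, train in TRAIN_HUMAN_PROJECTS.values())
    additional_pet = sum(
        size for sp, size in ADDITIONAL_PROJECTS.values() if sp in ("cat", "dog")
    )
    additional_human = sum(
        size for sp, size in ADDITIONAL_PROJECTS.values() if sp == "human"
    )
    return {
        "pet_total": pet_total,
        "human_total": human_total,
        "human_train_total": human_train_total,
        "additional_pet": additional_pet,
        "additional_human": additional_human,
        "n_pet_projects": len(TRAIN_PET_PROJECTS),
        "n_human_projects": len(TRAIN_HUMAN_PROJECTS),
    }
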