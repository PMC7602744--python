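"""The project learning curve: held-out-study accuracy vs training-study count.

A classifier trained on few studies can "remember" study-specific batch
signatures instead of host biology.  To quantify this, the pet side of
the training set is fixed (all pet samples) while the human side is
rebuilt from n training projects, for n = 1 .. N-1: for each n, up to
``combo_cap`` distinct project combinations are drawn (min(cap, C(N-1,n))
as in the source protocol), each combination is resampled several times
(project-balanced, WITH replacement, to the fixed per-class size), a
forest with frozen hyperparameters is trained, and plain accuracy is
measured on every human project absent from training.  A flat curve
means no study-level overfitting; a low n=1 value that rises to a
plateau is its signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from ._util import derive_seed
from .datasets import project_quotas


@dataclass
class LearningCurveConfig:
    """Scale and seeding of the learning-curve experiment.

    Desk-scale defaults (cap 20 combinations, 2 resamples) keep the run
    tractable; ``paper_scale()`` restores the full protocol (200, 5).
    """

    combo_cap: int = 20
    resamples: int = 2
    per_class_size: int | None = None  # None -> size of the fixed pet pool
    n_values: tuple[int, ...] | None = None  # None -> 1..N-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.combo_cap < 1 or self.resamples < 1:
            raise ValueError("combo_cap and resamples must be >= 1")

    @classmethod
    def paper_scale(cls, **kw) -> "LearningCurveConfig":
        return cls(combo_cap=200, resamples=5, **kw)


@dataclass
class LearningCurveResult:
    """One row per (n, combination, resample, held-out project)."""

    records: pd.DataFrame
    human_projects: list[str]


def enumerate_combinations(projects, n: int, cap: int = 200, seed: int = 0) -> list[tuple]:
    """Distinct n-project training combinations, min(cap, C(N-1, n)) of them.

    ``projects`` is either a sequence of project ids or an integer N
    (labels 0..N-1).  Combinations are drawn from the first N-1 projects
    (sorted order), so one project is always reserved for testing and the
    test set is never empty.  When C(N-1, n) exceeds the cap, ``cap``
    distinct combinations are sampled uniformly without replacement.
    """
    pool = list(range(projects)) if isinstance(projects, int) else sorted(projects)
    N = len(pool)
    if not 1 <= n <= N - 1:
        raise ValueError(f"n must be in 1..{N - 1}, got {n}")
    eligible = pool[: N - 1]
    total = comb(N - 1, n)
    all_combos = None
    if total <= cap:
        return list(combinations(eligible, n))
    rng = np.random.default_rng(seed)
    if total <= 200_000:
        all_combos = list(combinations(eligible, n))
        idx = rng.choice(total, size=cap, replace=False)
        return [all_combos[i] for i in sorted(idx)]
    chosen: set[tuple] = set()
    while len(chosen) < cap:  # rejection sampling for astronomically many combos
        pick = tuple(sorted(rng.choice(len(eligible), size=n, replace=False)))
        chosen.add(tuple(eligible[i] for i in pick))
    return sorted(chosen)


def run_learning_curve(
    X: pd.DataFrame,
    metadata: pd.DataFrame,
    model_params: dict,
    config: LearningCurveConfig,
) -> LearningCurveResult:
    """Run the full experiment on a pre-assembled design matrix.

    ``X`` is the same samples x features design the classifier uses
    (abundances + Chao), covering every sample; ``metadata`` supplies
    host and project.  Hyperparameters are frozen across all runs.
    """
    md = metadata.loc[X.index]
    pet_ids = sorted(md.index[md["host"] == "pet"])
    human_md = md[md["host"] == "human"]
    human_projects = sorted(human_md["project_id"].unique())
    N = len(human_projects)
    if N < 2:
        raise ValueError("need at least 2 human projects")
    per_class = config.per_class_size or len(pet_ids)
    n_values = config.n_values or tuple(range(1, N))
    project_ids = {
        p: sorted(human_md.index[human_md["project_id"] == p]) for p in human_projects
    }
    Xa = X.to_numpy(dtype=float)
    row_of = {sid: i for i, sid in enumerate(X.index)}
    pet_rows = np.array([row_of[s] for s in pet_ids])
    records = []
    for n in n_values:
        combos = enumerate_combinations(
            human_projects, n, cap=config.combo_cap, seed=derive_seed(config.seed, f"combos:{n}")
        )
        for ci, combo in enumerate(combos):
            sizes = {p: len(project_ids[p]) for p in combo}
            for r in range(config.resamples):
                rng = np.random.default_rng(
                    derive_seed(config.seed, f"resample:{n}:{ci}:{r}")
                )
                quotas = project_quotas(sizes, per_class, replacement=True)
                human_rows = []
                for p in combo:
                    picks = rng.choice(project_ids[p], size=quotas[p], replace=True)
                    human_rows.extend(row_of[s] for s in picks)
                assert len(human_rows) == per_class
                train_rows = np.concatenate([pet_rows, np.array(human_rows)])
                y_train = np.concatenate(
                    [np.zeros(len(pet_rows), dtype=int), np.ones(per_class, dtype=int)]
                )
                clf = RandomForestClassifier(
                    **model_params,
                    random_state=derive_seed(config.seed, f"forest:{n}:{ci}:{r}"),
                    n_jobs=1,
                )
                clf.fit(Xa[train_rows], y_train)
                for p in human_projects:
                    if p in combo:
                        continue
                    rows = np.array([row_of[s] for s in project_ids[p]])
                    acc = float(np.mean(clf.predict(Xa[rows]) == 1))
                    records.append(
                        {
                            "n": n,
                            "combination": "+".join(map(str, combo)),
                            "resample": r,
                            "test_project": p,
                            "accuracy": acc,
                            "n_test_samples": len(rows),
                        }
                    )
    return LearningCurveResult(
        records=pd.DataFrame(records), human_projects=human_projects
    )


def summarize_curve(result: LearningCurveResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean (and SD) accuracy per n, plus a per-held-out-project breakdown."""
    if result.records.empty:
        raise ValueError("empty learning-curve result")
    per_n = (
        result.records.groupby("n")["accuracy"]
        .agg(mean_accuracy="mean", sd_accuracy="std", n_records="size")
        .reset_index()
    )
    per_project = (
        result.records.groupby(["test_project", "n"])["accuracy"]
        .agg(mean_accuracy="mean", n_records="size")
        .reset_index()
    )
    return per_n, per_project
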