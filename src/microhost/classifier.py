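"""Random-forest host classification protocol.

The model input is a samples x features matrix of taxon abundances
(fractions of the sample total, or their CLR transform) plus one column
of mean rarefied Chao1 diversity; the label encodes "human" as class 1.
Hyperparameters are selected in two steps under stratified 5-fold CV:
a full Cartesian coarse grid first, then one-at-a-time fine sweeps of
each parameter with the others frozen at the incumbent optimum.  The
final model is refit several times with different seeds and performance
is reported as mean +/- SD of out-of-bag accuracy/precision/recall/F1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold

from .feature_table import FeatureTable
from .transforms import clr_transform

CHAO_COLUMN = "chao"
FEATURE_MODES = ("all", "mw_holm", "mw_fdr")
#: Printed candidate set for the number of trees.
N_ESTIMATORS_SET = (1, 5, 10, 50, 100, 500, 1000)
PARAM_ORDER = ("max_features", "max_depth", "min_samples_split", "n_estimators")


@dataclass
class ModelConfig:
    """Feature assembly choices plus the hyperparameter search space."""

    level: str = "genus"
    feature_mode: str = "all"
    clr: bool = False
    cv_folds: int = 5
    seed: int = 0
    #: param -> candidate values; None derives the default grids from the
    #: number of feature columns p at search time.
    coarse_grid: dict | None = None
    fine_grid: dict | None = None

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
        for grid in (self.coarse_grid, self.fine_grid):
            if grid is not None and any(len(v) == 0 for v in grid.values()):
                raise ValueError("search grid has an empty candidate list")


@dataclass
class ModelReport:
    """Selected model, its CV history, and OOB performance over refits."""

    params: dict
    cv_table: pd.DataFrame | None
    oob: dict[str, tuple[float, float]]  # metric -> (mean, sd)
    importances: pd.Series
    feature_names: list[str]
    refits: int
    seed: int
    sd_degenerate: bool = False  # True when refits == 1 (SDs are 0 by convention)
    models: list = field(default_factory=list, repr=False)

    def to_json(self, path) -> None:
        payload = {
            "params": self.params,
            "oob": {k: {"mean": m, "sd": s} for k, (m, s) in self.oob.items()},
            "importances": self.importances.to_dict(),
            "refits": self.refits,
            "seed": self.seed,
            "sd_degenerate": self.sd_degenerate,
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def default_coarse_grid(p: int) -> dict:
    """Low-cost grid spanning each search range (step 1)."""
    return {
        "max_features": sorted({2, max(2, round(np.sqrt(p))), p}),
        "max_depth": [2, 12, 32, 52],
        "min_samples_split": [2, 12, 32, 52],
        "n_estimators": [10, 100, 500],
    }


def default_fine_grid(p: int) -> dict:
    """Per-parameter refinement ranges (step 2)."""
    ladder = np.unique(
        np.round(np.geomspace(2, max(2, p), num=25)).astype(int)
    )
    return {
        "max_features": [int(v) for v in ladder if 2 <= v <= p],
        "max_depth": list(range(2, 53)),
        "min_samples_split": list(range(2, 53)),
        "n_estimators": list(N_ESTIMATORS_SET),
    }


def assemble_design(
    table: FeatureTable,
    metadata: pd.DataFrame,
    chao: pd.Series,
    config: ModelConfig,
    mw_features: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (taxa abundances + Chao column) and 0/1 labels.

    Abundances are per-sample fractions, or CLR values when
    ``config.clr`` is set (CLR is applied before any feature
    restriction, and never to the Chao column).  Labels: human = 1.
    """
    if config.feature_mode == "all":
        selected = list(table.counts.columns)
    else:
        if not mw_features:
            raise ValueError(
                f"feature_mode {config.feature_mode!r} needs a non-empty MW feature set"
            )
        missing = [t for t in mw_features if t not in table.counts.columns]
        if missing:
            raise ValueError(f"MW features absent from the table: {missing}")
        selected = list(mw_features)
    if not selected:
        raise ValueError("empty feature set")
    values = clr_transform(table).values if config.clr else table.relative_abundance()
    X = values[selected].copy()
    missing_chao = [s for s in X.index if s not in chao.index]
    if missing_chao:
        raise ValueError(f"samples without a Chao value: {missing_chao[:10]}")
    X[CHAO_COLUMN] = chao.loc[X.index]
    hosts = metadata.loc[X.index, "host"]
    y = (hosts == "human").to_numpy(dtype=int)
    return X, y


def cv_splitter(config: ModelConfig) -> StratifiedKFold:
    return StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)


def _clip_params(params: dict, p: int, n: int) -> dict:
    out = dict(params)
    if isinstance(out.get("max_features"), (int, np.integer)):
        out["max_features"] = int(min(out["max_features"], p))
    if isinstance(out.get("min_samples_split"), (int, np.integer)):
        out["min_samples_split"] = int(min(out["min_samples_split"], n))
    return out


def _cv_accuracy(X: np.ndarray, y: np.ndarray, params: dict, config: ModelConfig) -> float:
    skf = cv_splitter(config)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = RandomForestClassifier(
            **_clip_params(params, X.shape[1], len(train_idx)),
            random_state=config.seed,
            n_jobs=1,
        )
        clf.fit(X[train_idx], y[train_idx])
        accs.append(accuracy_score(y[test_idx], clf.predict(X[test_idx])))
    return float(np.mean(accs))


#: Tie-break toward the simpler model: fewer trees, shallower, larger
#: min-split, fewer candidate features per split.
def _simplicity_key(params: dict) -> tuple:
    return (
        params["n_estimators"],
        params["max_depth"],
        -params["min_samples_split"],
        params["max_features"],
    )


def two_step_param_search(
    X: pd.DataFrame | np.ndarray, y, config: ModelConfig
) -> tuple[dict, pd.DataFrame]:
    """Coarse Cartesian grid, then one-at-a-time fine sweeps.

    Returns the selected hyperparameters and the full CV evaluation table
    (step, parameter values, mean CV accuracy).  Deterministic under
    ``config.seed``: folds, forests, and tie-breaks are all fixed.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=int)
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels are degenerate (single class)")
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples, fewer than {config.cv_folds} folds"
        )
    p = Xa.shape[1]
    coarse = config.coarse_grid or default_coarse_grid(p)
    fine = config.fine_grid or default_fine_grid(p)
    rows = []

    def evaluate(params: dict, step: str) -> float:
        acc = _cv_accuracy(Xa, ya, params, config)
        rows.append({"step": step, **params, "cv_accuracy": acc})
        return acc

    names = list(PARAM_ORDER)
    best_params = None
    best = (-np.inf,)
    for combo in product(*(coarse[k] for k in names)):
        params = dict(zip(names, combo))
        acc = evaluate(params, "coarse")
        key = (acc, tuple(-v for v in _simplicity_key(params)))
        if key > best:
            best, best_params = key, params
    assert best_params is not None

    current = dict(best_params)
    for name in names:
        sweep_best = None
        sweep_key = (-np.inf,)
        candidates = list(fine[name])
        if current[name] not in candidates:
            candidates.append(current[name])
        for value in sorted(set(candidates)):
            params = {**current, name: value}
            acc = evaluate(params, f"fine:{name}")
            key = (acc, tuple(-v for v in _simplicity_key(params)))
            if key > sweep_key:
                sweep_key, sweep_best = key, value
        current[name] = sweep_best
    return current, pd.DataFrame(rows)


def fit_final(
    X: pd.DataFrame, y, params: dict, seed: int = 0, refits: int = 10
) -> ModelReport:
    """Fit the selected forest ``refits`` times and report OOB metrics.

    Each refit differs only by seed; OOB predictions come from trees
    whose bootstrap excluded the sample.  Errors out if any sample is
    never out-of-bag (tree count too small for a stable OOB estimate).
    """
    if refits < 1:
        raise ValueError("refits must be >= 1")
    feature_names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=int)
    metrics: dict[str, list[float]] = {m: [] for m in ("accuracy", "precision", "recall", "f1")}
    importances = []
    models = []
    for r in range(refits):
        clf = RandomForestClassifier(
            **_clip_params(params, Xa.shape[1], len(ya)),
            oob_score=True,
            bootstrap=True,
            random_state=seed + r,
            n_jobs=1,
        )
        clf.fit(Xa, ya)
        oob_proba = clf.oob_decision_function_
        # rows with no OOB votes come back as NaN or all-zero
        no_votes = np.isnan(oob_proba).any(axis=1) | (oob_proba.sum(axis=1) == 0)
        if no_votes.any():
            raise ValueError(
                f"{int(no_votes.sum())} samples are never out-of-bag; "
                "increase n_estimators"
            )
        pred = clf.classes_[np.argmax(oob_proba, axis=1)]
        metrics["accuracy"].append(accuracy_score(ya, pred))
        metrics["precision"].append(precision_score(ya, pred, pos_label=1, zero_division=0))
        metrics["recall"].append(recall_score(ya, pred, pos_label=1, zero_division=0))
        metrics["f1"].append(f1_score(ya, pred, pos_label=1, zero_division=0))
        importances.append(clf.feature_importances_)
        models.append(clf)
    oob = {
        m: (float(np.mean(v)), float(np.std(v, ddof=1)) if refits > 1 else 0.0)
        for m, v in metrics.items()
    }
    imp = np.mean(importances, axis=0)
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(Xa.shape[1])]
    return ModelReport(
        params=dict(params),
        cv_table=None,
        oob=oob,
        importances=pd.Series(imp, index=names),
        feature_names=names,
        refits=refits,
        seed=seed,
        sd_degenerate=(refits == 1),
        models=models,
    )


def importance_overlap(report: ModelReport, mw_set: list[str]) -> float:
    """Fraction of the top-k importance-ranked taxa that lie in the MW set.

    k = |mw_set|; the Chao column is excluded from the ranking.
    """
    if not mw_set:
        raise ValueError("mw_set must be non-empty")
    imp = report.importances.drop(labels=[CHAO_COLUMN], errors="ignore")
    k = len(mw_set)
    top = imp.sort_values(ascending=False, kind="stable").index[:k]
    return float(np.mean([t in set(mw_set) for t in top]))


def predict_scores(report: ModelReport, X_new: pd.DataFrame) -> pd.Series:
    """Class-1 ("human") probability per sample, averaged over refits."""
    if list(X_new.columns) != report.feature_names:
        raise ValueError(
            "feature columns do not match the training design "
            f"(expected {report.feature_names[:5]}..., got {list(X_new.columns)[:5]}...)"
        )
    if not report.models:
        raise ValueError("report carries no fitted models")
    probas = []
    for clf in report.models:
        idx = int(np.where(clf.classes_ == 1)[0][0])
        probas.append(clf.predict_proba(np.asarray(X_new, dtype=float))[:, idx])
    return pd.Series(np.mean(probas, axis=0), index=X_new.index, name="human_score")
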