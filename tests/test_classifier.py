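import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier

from microhost.classifier import (
    CHAO_COLUMN,
    ModelConfig,
    assemble_design,
    cv_splitter,
    fit_final,
    importance_overlap,
    predict_scores,
    two_step_param_search,
)
from microhost.diffabund import run_differential_abundance, select_features
from microhost.diversity import chao_column

SMALL_COARSE = {
    "max_features": [2],
    "max_depth": [4],
    "min_samples_split": [2],
    "n_estimators": [30],
}
SMALL_FINE = {
    "max_features": [2, 4],
    "max_depth": [2, 4, 8],
    "min_samples_split": [2, 8],
    "n_estimators": [10, 30, 50],
}


@pytest.fixture(scope="module")
def tiny_design(tiny_ds):
    chao = chao_column(tiny_ds.table, depth=5000, reps=2, seed=0)
    X, y = assemble_design(tiny_ds.table, tiny_ds.metadata, chao, ModelConfig())
    return X, y, chao


class TestAssembleDesign:
    def test_all_mode_has_taxa_plus_chao_columns(self, tiny_ds, tiny_design):
        X, y, _ = tiny_design
        assert X.shape[1] == tiny_ds.table.n_taxa + 1
        assert X.columns[-1] == CHAO_COLUMN
        # human encoded as class 1
        hosts = tiny_ds.metadata.loc[X.index, "host"]
        assert ((hosts == "human").to_numpy(dtype=int) == y).all()

    def test_mw_mode_restricts_columns(self, tiny_ds, tiny_design):
        _, _, chao = tiny_design
        mw = list(tiny_ds.table.counts.columns[:5])
        X, _ = assemble_design(
            tiny_ds.table, tiny_ds.metadata, chao,
            ModelConfig(feature_mode="mw_fdr"), mw_features=mw,
        )
        assert list(X.columns) == mw + [CHAO_COLUMN]

    def test_clr_applies_to_abundances_only(self, tiny_ds, tiny_design):
        _, _, chao = tiny_design
        X, _ = assemble_design(
            tiny_ds.table, tiny_ds.metadata, chao, ModelConfig(clr=True)
        )
        abund = X.drop(columns=[CHAO_COLUMN])
        assert np.abs(abund.sum(axis=1).to_numpy()).max() < 1e-9
        assert (X[CHAO_COLUMN] > 0).all()

    def test_empty_mw_set_and_missing_chao_rejected(self, tiny_ds, tiny_design):
        _, _, chao = tiny_design
        with pytest.raises(ValueError, match="feature set"):
            assemble_design(
                tiny_ds.table, tiny_ds.metadata, chao,
                ModelConfig(feature_mode="mw_holm"), mw_features=[],
            )
        with pytest.raises(ValueError, match="Chao"):
            assemble_design(
                tiny_ds.table, tiny_ds.metadata, chao.iloc[:10], ModelConfig()
            )


class TestParamSearch:
    def test_deterministic_under_seed(self, tiny_design):
        X, y, _ = tiny_design
        cfg = ModelConfig(seed=3, coarse_grid=SMALL_COARSE, fine_grid=SMALL_FINE)
        p1, t1 = two_step_param_search(X, y, cfg)
        p2, t2 = two_step_param_search(X, y, cfg)
        assert p1 == p2
        pd.testing.assert_frame_equal(t1, t2)

    def test_singleton_coarse_grid_equals_independent_sweeps(self, tiny_design):
        # with a coarse grid of size 1, step 2 reduces to four sequential
        # 1-D sweeps starting from that single configuration
        X, y, _ = tiny_design
        cfg = ModelConfig(seed=0, coarse_grid=SMALL_COARSE, fine_grid=SMALL_FINE)
        params, _ = two_step_param_search(X, y, cfg)

        from microhost.classifier import _cv_accuracy, _simplicity_key

        current = {k: v[0] for k, v in SMALL_COARSE.items()}
        for name in ("max_features", "max_depth", "min_samples_split", "n_estimators"):
            best_val, best_key = None, (-np.inf,)
            cands = set(SMALL_FINE[name]) | {current[name]}
            for v in sorted(cands):
                trial = {**current, name: v}
                acc = _cv_accuracy(np.asarray(X, float), np.asarray(y), trial, cfg)
                key = (acc, tuple(-u for u in _simplicity_key(trial)))
                if key > best_key:
                    best_key, best_val = key, v
            current[name] = best_val
        assert params == current

    def test_separable_classes_reach_perfect_cv(self):
        rng = np.random.default_rng(0)
        n = 40
        X = pd.DataFrame(
            {
                "Bacteria;P;C;O;F;G0": np.r_[rng.normal(0, 0.1, n), rng.normal(5, 0.1, n)],
                "Bacteria;P;C;O;F;G1": rng.normal(size=2 * n),
                CHAO_COLUMN: rng.normal(30, 1, 2 * n),
            }
        )
        y = np.r_[np.zeros(n, int), np.ones(n, int)]
        cfg = ModelConfig(
            seed=1,
            coarse_grid={
                "max_features": [1, 3],
                "max_depth": [2, 8],
                "min_samples_split": [2, 8],
                "n_estimators": [5, 20],
            },
            fine_grid={
                "max_features": [1, 2, 3],
                "max_depth": [2, 4, 8],
                "min_samples_split": [2, 4, 8],
                "n_estimators": [5, 10, 20],
            },
        )
        params, table = two_step_param_search(X, y, cfg)
        assert table["cv_accuracy"].max() == 1.0
        perfect = table[table["cv_accuracy"] == 1.0]
        # tie-break: no perfect configuration is simpler in trees
        assert params["n_estimators"] == perfect["n_estimators"].min()

    def test_degenerate_labels_rejected(self, tiny_design):
        X, _, _ = tiny_design
        with pytest.raises(ValueError):
            two_step_param_search(X, np.zeros(len(X), int), ModelConfig())

    def test_stratified_folds_balance_classes(self, tiny_design):
        X, y, _ = tiny_design
        skf = cv_splitter(ModelConfig(cv_folds=5, seed=0))
        global_frac = y.mean()
        for _, test_idx in skf.split(np.asarray(X), y):
            # per-fold class counts differ from the global proportion by < 1 sample
            assert abs(y[test_idx].sum() - global_frac * len(test_idx)) < 1


PARAMS = {"max_features": 8, "max_depth": 8, "min_samples_split": 2, "n_estimators": 60}


class TestFitFinal:
    def test_refits_give_mean_and_sd(self, tiny_design):
        X, y, _ = tiny_design
        report = fit_final(X, y, PARAMS, seed=0, refits=3)
        for metric, (mean, sd) in report.oob.items():
            assert 0.0 <= mean <= 1.0
            assert sd >= 0.0
        assert not report.sd_degenerate
        assert report.importances.sum() == pytest.approx(1.0)
        assert (report.importances >= 0).all()

    def test_single_refit_flags_degenerate_sd(self, tiny_design):
        X, y, _ = tiny_design
        report = fit_final(X, y, PARAMS, seed=0, refits=1)
        assert report.sd_degenerate
        assert all(sd == 0.0 for _, sd in report.oob.values())

    def test_too_few_trees_for_oob_rejected(self, tiny_design):
        X, y, _ = tiny_design
        with pytest.raises(ValueError, match="out-of-bag"):
            fit_final(X, y, {**PARAMS, "n_estimators": 1}, seed=0, refits=1)

    def test_constant_feature_does_not_change_predictions(self):
        # a constant column never wins a split, so with max_features = p
        # (every split evaluates all features) and deterministic trees the
        # learned forest is identical with or without it
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + 0.3 * rng.normal(size=60) > 0).astype(int)
        Xc = np.hstack([np.ones((60, 1)), X])
        a = RandomForestClassifier(
            random_state=0, max_features=None, bootstrap=False, n_estimators=20
        ).fit(X, y)
        b = RandomForestClassifier(
            random_state=0, max_features=None, bootstrap=False, n_estimators=20
        ).fit(Xc, y)
        assert np.allclose(a.predict_proba(X), b.predict_proba(Xc))


class TestImportanceAndScores:
    def test_overlap_trivial_cases(self, tiny_design):
        X, y, _ = tiny_design
        report = fit_final(X, y, PARAMS, seed=0, refits=1)
        taxa = [c for c in X.columns if c != CHAO_COLUMN]
        assert importance_overlap(report, taxa) == 1.0
        with pytest.raises(ValueError):
            importance_overlap(report, [])

    def test_planted_taxa_top_ranked(self, paper_ds, paper_design):
        report = fit_final(paper_design["X"], paper_design["y"], PARAMS, seed=0, refits=2)
        res = run_differential_abundance(paper_ds.table, paper_ds.metadata)
        mw = select_features(res, "fdr")
        assert importance_overlap(report, mw) >= 0.6

    def test_scores_separate_training_classes(self, paper_design):
        X, y = paper_design["X"], paper_design["y"]
        report = fit_final(X, y, {**PARAMS, "n_estimators": 100}, seed=0, refits=1)
        scores = predict_scores(report, X)
        assert ((scores >= 0.5).to_numpy() == (y == 1)).mean() > 0.98

    def test_column_mismatch_rejected(self, tiny_design):
        X, y, _ = tiny_design
        report = fit_final(X, y, PARAMS, seed=0, refits=1)
        with pytest.raises(ValueError, match="columns"):
            predict_scores(report, X[list(X.columns[::-1])])
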