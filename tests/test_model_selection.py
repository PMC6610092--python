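"""Nested cross-validation, grid orchestration, selection and the ensemble."""

import numpy as np
import pandas as pd
import pytest

from drugwalk.model_selection import (
    EnsembleModel,
    GridSettings,
    ModelRecord,
    ParameterGrid,
    PipelineData,
    ensemble_predict_acl,
    nested_cross_validate,
    results_table,
    run_grid,
    select_models,
)

SETTINGS = GridSettings(400, 0, 0.05, True, "mmc")


@pytest.fixture(scope="module")
def small_matrix(small_pipeline):
    return small_pipeline.labeled_matrix(SETTINGS)


@pytest.fixture(scope="module")
def record(small_matrix):
    return nested_cross_validate(small_matrix, SETTINGS, seed=3)


class TestNestedCV:
    def test_separable_synthetic_data_scores_high(self, record):
        assert record.outer_cv_f1 >= 0.8

    def test_same_seed_reproduces_folds_and_f1(self, small_matrix, record):
        again = nested_cross_validate(small_matrix, SETTINGS, seed=3)
        assert again.outer_cv_f1 == record.outer_cv_f1
        for a, b in zip(again.fold_log, record.fold_log):
            assert a["test_index"] == b["test_index"]

    def test_different_seed_changes_fold_assignment(self, small_matrix, record):
        other = nested_cross_validate(small_matrix, SETTINGS, seed=4)
        assert any(
            a["test_index"] != b["test_index"]
            for a, b in zip(other.fold_log, record.fold_log)
        )

    def test_stratification_within_one_sample(self, small_matrix, record):
        y = small_matrix.y
        global_frac = y.mean()
        for fold in record.fold_log:
            te = np.array(fold["test_index"])
            expected = global_frac * len(te)
            assert abs(y[te].sum() - expected) <= 1.0

    def test_no_outer_test_sample_in_inner_folds(self, record):
        for fold in record.fold_log:
            test = set(fold["test_index"])
            for inner in fold["inner_folds"]:
                assert test.isdisjoint(inner["train_index"])
                assert test.isdisjoint(inner["val_index"])
            assert test.isdisjoint(fold["train_index"])

    def test_too_few_positives_to_stratify_errors(self, small_matrix):
        keep = np.concatenate([np.flatnonzero(small_matrix.y == 1)[:5],
                               np.flatnonzero(small_matrix.y == 0)])
        from drugwalk.classification import LabeledProfileMatrix

        tiny = LabeledProfileMatrix(
            small_matrix.X[keep], small_matrix.y[keep],
            [small_matrix.compound_ids[i] for i in keep], small_matrix.gene_ids,
        )
        with pytest.raises(ValueError, match="stratify"):
            nested_cross_validate(tiny, SETTINGS, seed=0)

    def test_oof_probabilities_cover_all_compounds(self, record, small_matrix):
        assert np.isfinite(record.oof_probability).all()
        assert len(record.oof_probability) == small_matrix.n_compounds


class TestParameterGrid:
    def test_printed_grid_combination_count(self):
        # 8 drug-gene x 6 gene-gene (five thresholds + the unscored-edge
        # level at 999) x 14 c x 2 log flags per classifier
        grid = ParameterGrid(
            gene_gene_thresholds=[400, 600, 700, 800, 850, 999],
            classifier_kinds=["linear_svm"],
        )
        assert len(grid) == 8 * 6 * 14 * 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ParameterGrid(c_values=[])

    def test_settings_hash_deterministic_and_distinct(self):
        a = GridSettings(400, 0, 0.05, True, "mmc")
        b = GridSettings(400, 0, 0.05, True, "mmc")
        c = GridSettings(400, 0, 0.05, False, "mmc")
        assert a.settings_hash() == b.settings_hash() != c.settings_hash()


class TestRunGrid:
    def test_single_point_grid_equals_direct_call(self, small_pipeline, record):
        grid = ParameterGrid(
            gene_gene_thresholds=[400], drug_gene_thresholds=[0],
            c_values=[0.05], log_transform=[True], classifier_kinds=["mmc"],
        )
        result = run_grid(small_pipeline, grid, seed=3)
        assert len(result.records) == 1
        assert result.records[0].outer_cv_f1 == record.outer_cv_f1

    def test_log_flag_reuses_cached_propagation(self, small_dataset):
        data = PipelineData(small_dataset.edges, small_dataset.compounds)
        calls = []
        original = data._propagate_compounds

        def counting(*args, **kwargs):
            calls.append(args[1:])
            return original(*args, **kwargs)

        data._propagate_compounds = counting
        for flag in (True, False):
            data.labeled_matrix(GridSettings(400, 0, 0.05, flag, "mmc"))
        assert len(calls) == 1

    def test_failures_recorded_grid_continues(self, small_pipeline):
        grid = ParameterGrid(
            gene_gene_thresholds=[400], drug_gene_thresholds=[0, 998],
            c_values=[0.05], log_transform=[True], classifier_kinds=["mmc"],
        )
        # threshold 998 leaves no targets -> that point fails, the other runs
        result = run_grid(small_pipeline, grid, seed=3)
        assert len(result.records) == 1
        assert len(result.failures) == 1

    def test_results_table_one_row_per_record(self, small_pipeline, record):
        table = results_table([record])
        assert len(table) == 1
        assert table.loc[0, "outer_cv_f1"] == record.outer_cv_f1


def fake_record(f1, settings=SETTINGS, prob=None):
    class _Stub:
        def __init__(self, p):
            self.p = p

        def predict_acl(self, X):
            return np.full(np.atleast_2d(X).shape[0], self.p)

    return ModelRecord(
        settings=settings, outer_cv_f1=f1, outer_f1_per_fold=[f1],
        per_class_accuracy={"positive": 1.0, "negative": 1.0},
        best_inner_hyperparams={}, trained_final=_Stub(prob if prob is not None else f1),
        fold_log=[], n_compounds=10,
    )


class TestSelectModels:
    def test_default_threshold_selection(self):
        records = [fake_record(f) for f in (0.9, 0.85, 0.8, 0.5)]
        ens = select_models(records)
        assert [m.outer_cv_f1 for m in ens.members] == [0.9, 0.85]
        assert ens.selection_rule == {"min_f1": 0.84}

    def test_all_below_threshold_errors(self):
        with pytest.raises(ValueError, match="relax"):
            select_models([fake_record(0.5)])

    def test_top_n_keeps_highest(self):
        records = [fake_record(f) for f in np.linspace(0.1, 0.99, 10)]
        ens = select_models(records, top_n=3)
        assert len(ens.members) == 3
        assert ens.members[0].outer_cv_f1 == max(r.outer_cv_f1 for r in records)


class TestEnsemblePredict:
    def test_single_member_equals_member_prediction(self, small_pipeline, record):
        ens = EnsembleModel(members=[record], selection_rule={"top_n": 1})
        compounds = small_pipeline.compounds[:5]
        preds = ensemble_predict_acl(ens, compounds, small_pipeline)
        ids, X = small_pipeline._propagate_compounds(compounds, 400, 0, 0.05)
        from drugwalk.target_profiles import log_transform

        direct = record.trained_final.predict_acl(log_transform(X))
        np.testing.assert_allclose(preds["acl"].to_numpy(), direct)
        assert (preds["n_members"] == 1).all()

    def test_unanimous_members_give_unit_probability(self, small_pipeline):
        members = [fake_record(0.9, prob=1.0), fake_record(0.95, prob=1.0)]
        preds = ensemble_predict_acl(
            EnsembleModel(members, {"top_n": 2}), small_pipeline.compounds[:3], small_pipeline
        )
        assert np.allclose(preds["acl"], 1.0)
        assert (preds["n_members"] == 2).all()

    def test_unusable_compound_reported_with_reason(self, small_pipeline, record):
        from drugwalk.target_profiles import CompoundTargets

        ghost = CompoundTargets("ghost", [("NOT_A_GENE", 900)])
        ens = EnsembleModel(members=[record], selection_rule={"top_n": 1})
        preds = ensemble_predict_acl(ens, [ghost], small_pipeline)
        assert preds.loc[0, "n_members"] == 0
        assert np.isnan(preds.loc[0, "acl"])
        assert "no entry points" in preds.loc[0, "reason"]
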