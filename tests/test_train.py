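"""Fold planning, leakage guards, the training loop, and grid search."""

from dataclasses import replace

import numpy as np
import pytest

from thermoresp.losses import LossSpec
from thermoresp.net import build_model
from thermoresp.simulate import BreathingProfile, simulate_sequence
from thermoresp.train import (
    TrainConfig, cross_validate, derive_seeds, evaluate, grid_search,
    kfold_split, train,
)
from thermoresp.windows import sequence_to_clips


class TestKfoldSplit:
    def test_subjects_never_span_folds(self):
        subjects = [f"S{i}" for i in range(10)] * 2  # 10 subjects x 2 recordings
        plan = kfold_split(subjects, k=5, seed=0)
        assert plan.k == 5
        # one fold per subject, and every recording inherits it
        assert len(plan.assignment) == 10
        assert sorted(plan.fold_sizes()) == [2, 2, 2, 2, 2]

    def test_k1_collapses_to_single_fold(self):
        plan = kfold_split(["A", "B", "C"], k=1, seed=0)
        assert set(plan.assignment.values()) == {0}

    def test_46_subjects_round_robin_sizes(self):
        plan = kfold_split([f"S{i}" for i in range(46)], k=5, seed=3)
        assert sorted(plan.fold_sizes(), reverse=True) == [10, 9, 9, 9, 9]

    def test_deterministic_under_seed(self):
        subjects = [f"S{i}" for i in range(12)]
        assert kfold_split(subjects, 4, seed=9).assignment == \
            kfold_split(subjects, 4, seed=9).assignment

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="k=5"):
            kfold_split(["A", "B"], k=5)


class TestDeriveSeeds:
    def test_stable_stage_seeds(self):
        a = derive_seeds(123)
        b = derive_seeds(123)
        assert a == b
        assert set(a) == {"simulator", "folds", "weights", "shuffle"}
        assert all(0 <= v < 2**31 for v in a.values())
        assert derive_seeds(124) != a


class TestTrainingLoop:
    def test_warmup_lr_trace(self, tiny_clips, tiny_train_config):
        cfg = replace(tiny_train_config, warmup_epochs=1, epochs=3,
                      warmup_lr=5e-5, post_warmup_lr=5e-4)
        model = build_model(cfg.net, seed=0)
        _, trace = train(model, tiny_clips, cfg)
        assert trace["lr"][0] == pytest.approx(5e-5)  # warmup epoch
        assert sum(lr == pytest.approx(5e-5) for lr in trace["lr"]) == 1
        assert all(lr <= 5e-4 for lr in trace["lr"][1:])

    def test_zero_epochs_leaves_model_unchanged(self, tiny_clips, tiny_train_config):
        cfg = replace(tiny_train_config, warmup_epochs=0, epochs=0)
        model = build_model(cfg.net, seed=0)
        before = [p.data.copy() for p in model.parameters()]
        model, trace = train(model, tiny_clips, cfg)
        assert trace["epoch_loss"] == []
        for p, b in zip(model.parameters(), before):
            assert (p.data == b).all()

    def test_loss_descends_on_learnable_task(self, tiny_clips, tiny_train_config):
        cfg = replace(tiny_train_config, warmup_epochs=0, epochs=8,
                      post_warmup_lr=2e-3)
        model = build_model(cfg.net, seed=1)
        _, trace = train(model, tiny_clips, cfg)
        assert trace["epoch_loss"][-1] < trace["epoch_loss"][0]

    def test_subject_leakage_raises(self, tiny_clips, tiny_train_config):
        with pytest.raises(ValueError, match="leakage"):
            train(build_model(tiny_train_config.net), tiny_clips,
                  tiny_train_config, val_clips=tiny_clips[:1])

    def test_empty_training_set_rejected(self, tiny_train_config):
        with pytest.raises(ValueError, match="empty"):
            train(build_model(tiny_train_config.net), [], tiny_train_config)

    def test_evaluate_errors_and_identity(self, tiny_clips, tiny_train_config):
        model = build_model(tiny_train_config.net, seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, [])
        model.init_head_bias(tiny_clips[0].label_rr)
        rmse, _ = evaluate(model, tiny_clips[:1])
        assert rmse == pytest.approx(0.0, abs=1e-4)


class TestCrossValidate:
    def _tiny_cohort(self):
        cohort = []
        for i in range(4):
            prof = BreathingProfile(rr_bpm=8.0 + 5 * i, amplitude=600.0,
                                    noise_sd=0.0, seed=i)
            cohort.append(simulate_sequence(prof, 2.0, 8.0, resolution=(16, 16),
                                            subject_id=f"S{i}"))
        return cohort

    def test_partition_and_report_shape(self, tiny_train_config):
        cfg = replace(tiny_train_config, epochs=1, warmup_epochs=0)
        cohort = self._tiny_cohort()
        report = cross_validate(cohort, 2, cfg)
        assert len(report.per_fold_rmse) == 2
        assert report.aggregate_rmse == pytest.approx(
            np.mean([r for r, _ in report.per_fold_rmse]))
        # every subject is validated exactly once across folds
        plan = kfold_split([s.subject_id for s in cohort], 2,
                           seed=derive_seeds(cfg.seed)["folds"])
        folds = [plan.fold_of(s.subject_id) for s in cohort]
        assert sorted(np.bincount(folds)) == [2, 2]


class TestGridSearch:
    @staticmethod
    def _stub_evaluator(config, cohort, k):
        # rank purely by fusion kernel for a predictable ordering
        return float(config.net.fusion_kernel_t), config.net.fusion_kernel_t

    def test_product_enumeration(self, tiny_train_config):
        results = grid_search({"fusionkernels": [15, 5]}, tiny_train_config,
                              cohort=[], evaluator=self._stub_evaluator)
        assert len(results) == 2
        assert results[0]["cell"] == {"fusionkernels": 5}

    def test_product_size_matches_option_counts(self, tiny_train_config):
        space = {"fusionkernels": [5, 7, 9], "dropout": [0.2, 0.4],
                 "warmupepoch": [32, 64, 96]}
        results = grid_search(space, tiny_train_config, cohort=[],
                              evaluator=lambda c, co, k: (1.0, 1))
        assert len(results) == 3 * 2 * 3

    def test_budget_caps_cells(self, tiny_train_config):
        results = grid_search({"fusionkernels": [5, 7, 9, 11, 15]},
                              tiny_train_config, cohort=[], budget=1,
                              evaluator=self._stub_evaluator)
        assert len(results) == 1

    def test_unknown_key_rejected_with_vocabulary(self, tiny_train_config):
        with pytest.raises(ValueError, match="valid keys"):
            grid_search({"learningrate": [0.1]}, tiny_train_config, cohort=[])

    def test_default_evaluator_runs_cross_validation(self, tiny_train_config):
        cfg = replace(tiny_train_config, epochs=1, warmup_epochs=0)
        cohort = TestCrossValidate()._tiny_cohort()
        results = grid_search({"dropout": [0.0]}, cfg, cohort, k=2)
        assert len(results) == 1
        assert np.isfinite(results[0]["rmse"])
        assert results[0]["n_params"] > 0

    def test_tie_break_by_parameter_count(self, tiny_train_config):
        results = grid_search(
            {"fusionkernels": [15, 5]}, tiny_train_config, cohort=[],
            evaluator=lambda c, co, k: (1.0, c.net.fusion_kernel_t))
        assert [r["n_params"] for r in results] == [5, 15]


class TestTrainConfig:
    def test_schedule_shape(self):
        cfg = TrainConfig(warmup_epochs=2, warmup_lr=5e-5, post_warmup_lr=1e-3,
                          epochs=6)
        lrs = [cfg.lr_at(e) for e in range(6)]
        assert lrs[0] == lrs[1] == 5e-5
        assert lrs[2] == pytest.approx(1e-3)  # cosine starts at the peak
        assert lrs[-1] < lrs[2]

    def test_invariants(self):
        with pytest.raises(ValueError):
            TrainConfig(warmup_epochs=10, epochs=5)
        with pytest.raises(ValueError):
            TrainConfig(warmup_lr=0.0)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="lbfgs")
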