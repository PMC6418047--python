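"""PMF training, confidence mapping, the selection rule, and evaluation."""

import numpy as np
import pytest

from qspharm.errors import EvaluationError, TrainingError, ValidationError
from qspharm.interactions import InteractionMatrix
from qspharm.pmf import (
    PMFConfig,
    PMFModel,
    evaluate_heldout,
    predict_confidence,
    select_novel_predictions,
    train_pmf,
)
from qspharm.synthetic import make_study, simulate_interactions


def manual_model(U, V, matrix, score_map="clamp") -> PMFModel:
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    return PMFModel(
        U=U,
        V=V,
        config=PMFConfig(n_factors=U.shape[0], score_map=score_map),
        loss_trace=[0.0],
        drug_ids=list(matrix.drug_ids),
        target_ids=list(matrix.target_ids),
        training_entries=matrix.entries,
        matrix_hash=matrix.entry_hash(),
    )


class TestTraining:
    def test_rank_one_all_ones_matrix_is_reconstructed(self):
        matrix = InteractionMatrix(
            list("abcd"), list("wxyz"), {(i, j) for i in range(4) for j in range(4)}
        )
        config = PMFConfig(
            n_factors=1, neg_ratio=0.0, epochs=2000, learn_rate=0.1, seed=0,
            reg_u=0.0, reg_v=0.0, tol=1e-12,
        )
        model = train_pmf(matrix, config)
        recon = model.U.T @ model.V
        assert np.all(np.abs(recon - 1.0) < 0.05)

    def test_full_observation_reconstruction_error_below_oracle_band(self):
        sim = simulate_interactions(80, 60, 5, 0.10, 0.0, seed=42)
        dense = sim.matrix.to_dense()
        config = PMFConfig(
            n_factors=5, neg_ratio=1e9, epochs=1500, learn_rate=0.1, seed=42,
            tol=1e-10,
        )
        model = train_pmf(sim.matrix, config)
        mse = float(np.mean((np.clip(model.U.T @ model.V, 0, 1) - dense) ** 2))
        oracle_mse = float(np.mean((sim.probabilities - dense) ** 2))
        # the generating probabilities themselves set the scale of the bound
        assert oracle_mse < 0.05
        assert mse < 0.05

    def test_training_is_deterministic(self):
        sim = simulate_interactions(20, 15, 3, 0.2, 0.0, seed=1)
        config = PMFConfig(n_factors=3, epochs=50, seed=9)
        m1 = train_pmf(sim.matrix, config)
        m2 = train_pmf(sim.matrix, config)
        assert np.array_equal(m1.U, m2.U)
        assert np.array_equal(m1.V, m2.V)
        assert m1.loss_trace == m2.loss_trace

    def test_loss_non_increasing_without_negative_resampling(self):
        sim = simulate_interactions(20, 15, 3, 0.2, 0.0, seed=2)
        config = PMFConfig(
            n_factors=3, neg_ratio=0.0, epochs=200, learn_rate=0.05, seed=3
        )
        model = train_pmf(sim.matrix, config)
        trace = np.asarray(model.loss_trace)
        assert np.all(np.diff(trace) <= 1e-6 * trace[:-1])

    def test_divergence_raises_training_error(self):
        sim = simulate_interactions(20, 15, 3, 0.2, 0.0, seed=2)
        config = PMFConfig(n_factors=3, epochs=500, learn_rate=50.0, seed=3)
        with pytest.raises(TrainingError, match="learn_rate"):
            train_pmf(sim.matrix, config)

    def test_checkpoint_round_trip_and_matrix_guard(self, tmp_path, small_matrix):
        config = PMFConfig(n_factors=2, epochs=20, seed=5)
        model = train_pmf(small_matrix, config)
        model.save(tmp_path / "model.json")
        loaded = PMFModel.load(tmp_path / "model.json")
        assert np.allclose(loaded.U, model.U)
        assert loaded.config == model.config
        other = InteractionMatrix(["d1", "d2"], ["t1", "t2"], {(0, 0), (1, 1)})
        with pytest.raises(ValidationError):
            loaded.check_matrix(other)


class TestConfidence:
    def test_clamp_mapping_examples(self, small_matrix):
        matrix = InteractionMatrix(["d1"], ["t1", "t2", "t3"], {(0, 0)})
        model = manual_model([[1.0], [0.0]], [[1.0, 2.0, 0.5], [0.0, 0.0, 0.0]], matrix)
        assert predict_confidence(model, 0, 0) == 1.0
        assert predict_confidence(model, 0, 1) == 1.0  # clamp of 2
        model2 = manual_model([[0.6], [0.0]], [[0.5, 0, 0], [0, 0, 0]], matrix)
        assert predict_confidence(model2, 0, 0) == pytest.approx(0.30)

    def test_out_of_range_index_raises_lookup_error(self, small_matrix):
        model = train_pmf(small_matrix, PMFConfig(n_factors=2, epochs=5, seed=1))
        with pytest.raises(LookupError):
            predict_confidence(model, 99, 0)


class TestSelectionRule:
    def make_fixture(self, scores: list[float]):
        """One drug with one observed target and len(scores) candidates."""
        m = len(scores) + 1
        matrix = InteractionMatrix(
            ["drug"], [f"t{j:02d}" for j in range(m)], {(0, 0)}
        )
        v = np.asarray([[1.0] + scores])
        u = np.asarray([[1.0]])
        return manual_model(u, v, matrix), matrix

    def test_exactly_the_qualifying_candidates_are_kept(self):
        scores = [0.90, 0.85, 0.71, 0.70, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05, 0.02, 0.01]
        model, matrix = self.make_fixture(scores)
        predictions = select_novel_predictions(model, matrix)
        assert len(predictions) == 3  # the exact-0.7 candidate is excluded
        assert all(p.confidence > 0.7 for p in predictions)
        assert [p.rank for p in predictions] == [1, 2, 3]

    def test_boundary_confidence_is_excluded(self):
        model, matrix = self.make_fixture([0.7] * 5)
        assert select_novel_predictions(model, matrix) == []

    def test_ties_keep_lexicographically_smallest_targets(self):
        model, matrix = self.make_fixture([0.9] * 15)
        predictions = select_novel_predictions(model, matrix, top_k=10)
        assert len(predictions) == 10
        kept = [p.target_id for p in predictions]
        assert kept == sorted(matrix.target_ids[1:])[:10]

    def test_predictions_never_duplicate_observed_entries(self):
        study = make_study("pmf_recovery", seed=3)
        config = PMFConfig(n_factors=5, epochs=100, learn_rate=0.05, seed=3)
        model = train_pmf(study.matrix, config)
        predictions = select_novel_predictions(model, study.matrix, min_conf=0.5)
        observed = {
            (study.matrix.drug_ids[i], study.matrix.target_ids[j])
            for i, j in study.matrix.entries
        }
        assert all((p.drug_id, p.target_id) not in observed for p in predictions)
        assert all(0.0 <= p.confidence <= 1.0 for p in predictions)

    def test_cold_start_drugs_are_skipped(self):
        matrix = InteractionMatrix(["d1", "d2"], ["t1", "t2"], {(0, 0)})
        model = manual_model([[1.0, 1.0]], [[1.0, 1.0]], matrix)
        predictions = select_novel_predictions(model, matrix, min_conf=0.5)
        assert {p.drug_id for p in predictions} <= {"d1"}


class TestHeldoutEvaluation:
    def test_perfect_separation_gives_auc_one(self):
        matrix = InteractionMatrix(["d"], ["t0", "t1", "t2", "t3"], {(0, 0)})
        model = manual_model([[1.0]], [[1.0, 0.9, 0.8, 0.1]], matrix)
        ev = evaluate_heldout(model, [(0, 1), (0, 2)], [(0, 3)])
        assert ev.auc == 1.0

    def test_auc_matches_brute_force_pairwise_count(self):
        rng = np.random.default_rng(0)
        m = 30
        matrix = InteractionMatrix(
            ["d"], [f"t{j}" for j in range(m)], {(0, 0)}
        )
        scores = rng.random(m)
        model = manual_model([[1.0]], scores.reshape(1, m), matrix)
        pos = [(0, j) for j in range(1, 11)]
        neg = [(0, j) for j in range(11, 25)]
        ev = evaluate_heldout(model, pos, neg)
        wins = sum(
            (scores[p[1]] > scores[n[1]]) + 0.5 * (scores[p[1]] == scores[n[1]])
            for p in pos
            for n in neg
        )
        assert ev.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_empty_heldout_set_raises(self):
        matrix = InteractionMatrix(["d"], ["t0", "t1"], {(0, 0)})
        model = manual_model([[1.0]], [[1.0, 0.5]], matrix)
        with pytest.raises(EvaluationError):
            evaluate_heldout(model, [], [(0, 1)])

    def test_overlap_with_training_entries_raises(self):
        matrix = InteractionMatrix(["d"], ["t0", "t1"], {(0, 0)})
        model = manual_model([[1.0]], [[1.0, 0.5]], matrix)
        with pytest.raises(EvaluationError):
            evaluate_heldout(model, [(0, 0)], [(0, 1)])

    def test_factor_recovery_on_masked_noise_free_data(self):
        study = make_study("pmf_recovery", seed=42)
        config = PMFConfig(n_factors=5, epochs=500, learn_rate=0.05, seed=42)
        model = train_pmf(
            study.matrix, config, exclude_from_negatives=study.heldout_positives
        )
        ev = evaluate_heldout(model, study.heldout_positives, study.heldout_negatives)
        assert ev.auc >= 0.85
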