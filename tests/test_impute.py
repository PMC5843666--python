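import itertools

import numpy as np
import pytest

from scimpute import (
    CountMatrix,
    ScImpute,
    ZERO_EXPRESSION,
    impute_cell,
    impute_log_matrix,
    learn_cell_weights,
    run_scimpute,
)
from scimpute.impute import impute_log_values
from scimpute.mixture import DropoutProbabilities
from scimpute.neighborhoods import OUTLIER, NeighborhoodAssignment


def nnls_bruteforce(design, response):
    """Exhaustive active-set oracle for small NNLS instances.

    The NNLS optimum is the least-squares solution on some support with
    non-negative coefficients; enumerate every support.
    """
    n = design.shape[1]
    best_obj, best_w = float(np.sum(response**2)), np.zeros(n)
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            sub = design[:, support]
            coef, *_ = np.linalg.lstsq(sub, response, rcond=None)
            if np.any(coef < -1e-12):
                continue
            obj = float(np.sum((sub @ coef - response) ** 2))
            if obj < best_obj:
                best_obj = obj
                best_w = np.zeros(n)
                best_w[list(support)] = coef
    return best_w, best_obj


class TestLearnCellWeights:
    def test_identical_neighbor_gets_unit_weight(self, rng):
        values = np.abs(rng.normal(2, 0.5, size=(5, 5))) + 0.1
        q, _ = np.linalg.qr(rng.normal(size=(5, 3)))
        values[:, 1:4] = np.abs(q) + 2.0  # near-orthogonal neighbor columns
        values[:, 0] = values[:, 3]  # response equals neighbor index 3
        w = learn_cell_weights(values, 0, np.arange(5), np.array([1, 2, 3]))
        assert w[2] == pytest.approx(1.0, abs=1e-6)
        assert w[0] == pytest.approx(0.0, abs=1e-6)
        assert w[1] == pytest.approx(0.0, abs=1e-6)

    def test_zero_response_gives_zero_weights(self, rng):
        values = np.abs(rng.normal(size=(6, 4))) + 0.5
        values[:, 0] = 0.0
        w = learn_cell_weights(values, 0, np.arange(6), np.array([1, 2, 3]))
        np.testing.assert_allclose(w, 0.0, atol=1e-12)

    def test_matches_ols_when_unconstrained_solution_nonnegative(self):
        design = np.array([[1.0, 0.2], [0.1, 1.0], [0.5, 0.5], [0.9, 0.1]])
        true_w = np.array([0.7, 0.4])
        response = design @ true_w
        values = np.column_stack([response, design])
        w = learn_cell_weights(values, 0, np.arange(4), np.array([1, 2]))
        ols, *_ = np.linalg.lstsq(design, response, rcond=None)
        assert np.all(ols >= 0)
        np.testing.assert_allclose(w, ols, atol=1e-8)

    def test_objective_matches_bruteforce_oracle(self, rng):
        for trial in range(20):
            trial_rng = np.random.default_rng(100 + trial)
            n_genes = trial_rng.integers(4, 9)
            n_neighbors = trial_rng.integers(2, 7)
            design = np.abs(trial_rng.normal(size=(n_genes, n_neighbors)))
            response = np.abs(trial_rng.normal(size=n_genes))
            values = np.column_stack([response, design])
            w = learn_cell_weights(
                values, 0, np.arange(n_genes), np.arange(1, n_neighbors + 1)
            )
            obj = float(np.sum((design @ w - response) ** 2))
            _, best_obj = nnls_bruteforce(design, response)
            assert obj == pytest.approx(best_obj, abs=1e-8)

    def test_empty_sets_rejected(self, rng):
        values = np.abs(rng.normal(size=(4, 4)))
        with pytest.raises(ValueError):
            learn_cell_weights(values, 0, np.empty(0, int), np.array([1]))

    def test_underdetermined_warns_but_solves(self, rng):
        values = np.abs(rng.normal(size=(2, 6))) + 0.1
        with pytest.warns(UserWarning, match="underdetermined"):
            w = learn_cell_weights(values, 0, np.arange(2), np.arange(1, 6))
        assert np.all(w >= 0)


class TestImputeCell:
    def test_empty_imputable_set_returns_column_unchanged(self, rng):
        values = rng.normal(size=(6, 4))
        column = impute_cell(
            values, 1, np.empty(0, int), np.arange(6), np.array([0, 2]), np.zeros(2)
        )
        np.testing.assert_array_equal(column, values[:, 1])

    def test_unit_weight_copies_neighbor_values(self, rng):
        values = np.abs(rng.normal(size=(6, 4)))
        A = np.array([0, 3])
        column = impute_cell(
            values, 0, A, np.array([1, 2]), np.array([2, 3]), np.array([0.0, 1.0])
        )
        np.testing.assert_array_equal(column[A], values[A, 3])

    def test_convex_combination(self):
        values = np.array([[0.0, 1.0, 3.0], [1.0, 2.0, 2.0]])
        column = impute_cell(
            values, 0, np.array([0]), np.array([1]), np.array([1, 2]),
            np.array([0.5, 0.5]),
        )
        assert column[0] == pytest.approx(2.0)
        assert column[1] == values[1, 0]


class TestPipeline:
    def test_no_zero_unimodal_matrix_passes_through(self, rng):
        counts = np.round(10 ** rng.normal(2.0, 0.15, size=(40, 30))) + 1.0
        cm = CountMatrix(
            counts, [f"g{i}" for i in range(40)], [f"c{j}" for j in range(30)]
        )
        result = run_scimpute(cm, n_clusters=1, random_state=0)
        # zero-free unimodal genes leave the imputable sets (near) empty
        assert result.imputed_mask.mean() <= 0.005
        untouched = ~result.imputed_mask
        np.testing.assert_allclose(
            result.imputed_counts.values[untouched], counts[untouched], rtol=1e-8
        )

    def test_all_outlier_assignment_returns_input(self, rng):
        values = np.abs(rng.normal(2, 0.5, size=(10, 5)))
        assignment = NeighborhoodAssignment(
            np.full(5, OUTLIER), frozenset(range(5)), [np.empty(0, int)] * 5
        )
        empty = [np.empty(0, int)] * 5
        dropout = DropoutProbabilities(np.zeros((10, 5)), 0.5, empty, empty)
        imputed, mask, weights = impute_log_values(values, assignment, dropout)
        np.testing.assert_array_equal(imputed, values)
        assert mask.sum() == 0 and not weights

    def test_non_imputed_entries_bit_identical_and_outliers_untouched(self, small_sim):
        result = impute_log_matrix(small_sim.raw_log, n_clusters=3, random_state=1)
        raw = small_sim.raw_log
        imputed = result.imputed_log.values
        mask = result.imputed_mask
        assert mask.sum() > 0
        # the method's central promise: untouched means bit-identical
        assert np.array_equal(imputed[~mask], raw[~mask])
        for j in result.assignment.outliers:
            assert np.array_equal(imputed[:, j], raw[:, j])
            assert not mask[:, j].any()

    def test_zero_fraction_never_increases(self, small_sim):
        result = impute_log_matrix(small_sim.raw_log, n_clusters=3, random_state=1)
        floor = ZERO_EXPRESSION + 1e-12
        assert (result.imputed_log.values <= floor).mean() <= (
            small_sim.raw_log <= floor
        ).mean()

    def test_outlier_cells_not_used_for_others(self, small_sim):
        base = impute_log_matrix(small_sim.raw_log, n_clusters=3, random_state=1)
        outliers = sorted(base.assignment.outliers)
        if not outliers:
            pytest.skip("no outlier in this simulation draw")
        # rerun with the outlier columns perturbed but the assignment fixed
        from scimpute.impute import impute_log_values
        from scimpute.mixture import dropout_probabilities, fit_all_mixtures

        perturbed = small_sim.raw_log.copy()
        perturbed[:, outliers] += 3.0
        fits = fit_all_mixtures(perturbed, base.assignment)
        dp = dropout_probabilities(perturbed, fits, base.assignment, 0.5)
        imputed, _, _ = impute_log_values(perturbed, base.assignment, dp)
        keep = [j for j in range(perturbed.shape[1]) if j not in base.assignment.outliers]
        np.testing.assert_array_equal(
            imputed[:, keep], base.imputed_log.values[:, keep]
        )

    def test_seeded_run_deterministic(self, small_sim):
        a = impute_log_matrix(small_sim.raw_log, n_clusters=3, random_state=5)
        b = impute_log_matrix(small_sim.raw_log, n_clusters=3, random_state=5)
        np.testing.assert_array_equal(a.imputed_log.values, b.imputed_log.values)


class TestScImputeEstimator:
    def test_sklearn_interface(self, small_sim):
        model = ScImpute(n_clusters=3, scale="log", random_state=1)
        X = small_sim.raw_log.T
        out = model.fit_transform(X)
        assert out.shape == X.shape
        assert model.imputed_mask_.shape == X.shape
        assert model.cluster_labels_.shape == (X.shape[0],)
        assert set(model.get_params()) >= {
            "n_clusters", "dropout_threshold", "scale", "random_state"
        }

    def test_transform_rejects_other_matrices(self, small_sim):
        model = ScImpute(n_clusters=3, scale="log", random_state=1)
        X = small_sim.raw_log.T
        model.fit(X)
        with pytest.raises(ValueError, match="transductive"):
            model.transform(X + 1.0)

    def test_labels_bypass_clustering(self, small_sim):
        model = ScImpute(scale="log", random_state=1)
        model.fit(small_sim.raw_log.T, y=small_sim.labels())
        non_outlier = model.cluster_labels_ != OUTLIER
        assert len(np.unique(model.cluster_labels_[non_outlier])) == 3

    def test_missing_k_rejected(self, small_sim):
        with pytest.raises(ValueError, match="n_clusters"):
            ScImpute(scale="log").fit(small_sim.raw_log.T)
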