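import itertools

import numpy as np
import pytest

from mcda_hh import (
    Hierarchy,
    RANDOM_INDEX,
    ValidationError,
    aggregate_experts_geometric,
    consistency,
    principal_priorities,
    required_comparison_count,
    row_geometric_mean_priorities,
    synthesize_global_priorities,
    validate_pairwise,
)
from mcda_hh.reports import load_combined_pairwise
from mcda_hh.synthetic import PanelSpec, simulate_pairwise_panel


def consistent_matrix(w):
    w = np.asarray(w, dtype=float)
    return validate_pairwise(np.outer(w, 1.0 / w), raw_scale=False)


CYCLIC_3 = validate_pairwise([[1, 2, "1/2"], ["1/2", 1, 2], [2, "1/2", 1]])


class TestValidatePairwise:
    def test_textbook_reciprocal_pair_accepted(self):
        M = validate_pairwise([[1, 3], ["1/3", 1]])
        assert M.values[1, 0] == pytest.approx(1 / 3)

    def test_reciprocity_violation_names_the_cell(self):
        with pytest.raises(ValidationError, match="item1.*item2"):
            validate_pairwise([[1, 3], ["1/2", 1]])

    def test_published_combined_matrix_is_valid(self):
        M = load_combined_pairwise()
        assert M.n == 7
        assert M.values[0, 6] == pytest.approx(0.25)  # 1/4 parsed exactly
        assert M.labels[0] == "short_time"

    @pytest.mark.parametrize(
        "raw, message",
        [
            ([[1, 2, 3], [0.5, 1, 2]], "square"),
            ([[2, 2], [0.5, 1]], "diagonal"),
            ([[1, -3], ["-1/3", 1]], "not positive"),
            ([[1, 12], ["1/12", 1]], "scale"),
        ],
    )
    def test_malformed_matrices_rejected(self, raw, message):
        with pytest.raises(ValidationError, match=message):
            validate_pairwise(raw)

    def test_off_scale_allowed_for_aggregates(self):
        M = validate_pairwise([[1, 12], ["1/12", 1]], raw_scale=False)
        assert M.values[0, 1] == 12.0


class TestRequiredComparisons:
    @pytest.mark.parametrize("n, expected", [(7, 21), (2, 1), (1, 0)])
    def test_known_counts(self, n, expected):
        assert required_comparison_count(n) == expected

    def test_matches_pair_enumeration(self):
        for n in range(1, 12):
            assert required_comparison_count(n) == len(
                list(itertools.combinations(range(n), 2))
            )

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValidationError):
            required_comparison_count(0)


class TestPrincipalPriorities:
    def test_consistent_matrix_reproduces_generator(self):
        p, lam = principal_priorities(consistent_matrix([0.5, 0.3, 0.2]))
        np.testing.assert_allclose(p, [0.5, 0.3, 0.2], atol=1e-10)
        assert lam == pytest.approx(3.0, abs=1e-9)

    def test_two_by_two_closed_form(self):
        p, lam = principal_priorities(validate_pairwise([[1, 3], ["1/3", 1]]))
        np.testing.assert_allclose(p, [0.75, 0.25], atol=1e-10)
        assert lam == pytest.approx(2.0, abs=1e-9)

    def test_cyclic_matrix_closed_form(self):
        # circulant with a = 2: uniform eigenvector, lambda = 1 + a + 1/a
        p, lam = principal_priorities(CYCLIC_3)
        np.testing.assert_allclose(p, [1 / 3] * 3, atol=1e-10)
        assert lam == pytest.approx(3.5, abs=1e-9)

    def test_agrees_with_dense_eigensolver(self):
        # independent oracle: numpy's full eigendecomposition
        M = load_combined_pairwise()
        p, lam = principal_priorities(M)
        w, v = np.linalg.eig(M.values)
        k = np.argmax(w.real)
        p_ref = np.abs(v[:, k].real)
        p_ref /= p_ref.sum()
        np.testing.assert_allclose(p, p_ref, atol=1e-9)
        assert lam == pytest.approx(float(w[k].real), abs=1e-9)


class TestRowGeometricMean:
    def test_exact_for_consistent_matrices(self):
        p = row_geometric_mean_priorities(consistent_matrix([0.5, 0.3, 0.2]))
        np.testing.assert_allclose(p, [0.5, 0.3, 0.2], atol=1e-12)

    def test_two_by_two_hand_computation(self):
        p = row_geometric_mean_priorities(validate_pairwise([[1, 9], ["1/9", 1]]))
        np.testing.assert_allclose(p, [0.9, 0.1], atol=1e-12)

    def test_near_agreement_with_eigenvector_on_combined_matrix(self):
        # the published combined matrix has CR ~ 0.18, so the two methods
        # agree only loosely there; tight agreement holds for CR < 0.05
        M = load_combined_pairwise()
        p_eig, _ = principal_priorities(M)
        p_gm = row_geometric_mean_priorities(M)
        assert np.abs(p_eig - p_gm).sum() < 0.10


class TestConsistency:
    def test_consistent_matrix_scores_zero(self):
        M = consistent_matrix([0.4, 0.3, 0.2, 0.1])
        rep = consistency(M)
        assert rep.ci == pytest.approx(0.0, abs=1e-9)
        assert rep.cr == pytest.approx(0.0, abs=1e-9)
        assert rep.acceptable

    def test_cyclic_matrix_fails_threshold(self):
        rep = consistency(CYCLIC_3)
        assert rep.ci == pytest.approx(0.25, abs=1e-9)
        assert rep.cr == pytest.approx(0.25 / 0.58, abs=1e-9)
        assert not rep.acceptable

    def test_random_index_lookup(self):
        assert RANDOM_INDEX[7] == 1.32
        rep = consistency(load_combined_pairwise())
        assert rep.ri == 1.32

    def test_order_two_defined_as_zero(self):
        rep = consistency(validate_pairwise([[1, 5], ["1/5", 1]]))
        assert rep.cr == 0.0 and rep.acceptable

    def test_large_order_needs_extended_table(self):
        w = np.linspace(1, 2, 11)
        M = validate_pairwise(np.outer(w, 1 / w), raw_scale=False)
        with pytest.raises(ValidationError, match="extended RI"):
            consistency(M)
        rep = consistency(M, ri_table={11: 1.51})
        assert rep.cr == pytest.approx(0.0, abs=1e-9)


class TestAggregation:
    def test_identical_experts_are_a_fixed_point(self):
        M = validate_pairwise([[1, 3, 5], ["1/3", 1, 2], ["1/5", "1/2", 1]])
        agg = aggregate_experts_geometric([M, M, M])
        np.testing.assert_allclose(agg.values, M.values, atol=1e-12)

    def test_opposite_judgments_cancel(self):
        a = validate_pairwise([[1, 9], ["1/9", 1]])
        b = validate_pairwise([[1, "1/9"], [9, 1]])
        agg = aggregate_experts_geometric([a, b])
        np.testing.assert_allclose(agg.values, np.ones((2, 2)), atol=1e-12)

    def test_aggregate_is_reciprocal_on_random_panels(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            spec = PanelSpec(seed=int(rng.integers(2**31)), n_experts=5,
                             sigma_pairwise=0.5)
            agg = aggregate_experts_geometric(simulate_pairwise_panel(spec))
            np.testing.assert_allclose(agg.values * agg.values.T, 1.0, atol=1e-9)

    def test_aggregation_beats_the_median_expert(self):
        # seed 7, 15 experts: the group eigenvector is closer to the latent
        # weights than the median individual eigenvector
        spec = PanelSpec(seed=7, sigma_pairwise=0.4)
        panel = simulate_pairwise_panel(spec)
        w = spec.weights_array()
        individual = [np.abs(principal_priorities(M)[0] - w).sum() for M in panel]
        group = np.abs(principal_priorities(aggregate_experts_geometric(panel))[0] - w).sum()
        assert group < np.median(individual)

    def test_mismatched_labels_rejected(self):
        a = validate_pairwise([[1, 2], ["1/2", 1]], labels=["x", "y"])
        b = validate_pairwise([[1, 2], ["1/2", 1]], labels=["y", "x"])
        with pytest.raises(ValidationError, match="labels"):
            aggregate_experts_geometric([a, b])


class TestSynthesis:
    def _hierarchy(self, crit_w, locals_):
        crit = consistent_matrix(crit_w)
        alt_mats = {
            label: consistent_matrix(loc)
            for label, loc in zip(crit.labels, locals_)
        }
        return Hierarchy(goal="g", criteria_matrix=crit, alternative_matrices=alt_mats)

    def test_symmetric_locals_balance_out(self):
        H = self._hierarchy([0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]])
        out = synthesize_global_priorities(H)
        np.testing.assert_allclose(
            list(out["global_priorities"].values()), [0.5, 0.5], atol=1e-9
        )

    def test_hand_computed_weighted_sum(self):
        H = self._hierarchy([0.6, 0.4], [[0.9, 0.1], [0.2, 0.8]])
        out = synthesize_global_priorities(H)
        np.testing.assert_allclose(
            list(out["global_priorities"].values()), [0.62, 0.38], atol=1e-9
        )

    def test_globals_sum_to_one_and_survive_criterion_relabeling(self):
        H = self._hierarchy([0.5, 0.3, 0.2],
                            [[0.7, 0.3], [0.5, 0.5], [0.1, 0.9]])
        out = synthesize_global_priorities(H)
        assert sum(out["global_priorities"].values()) == pytest.approx(1.0, abs=1e-9)
        # relabel criteria (same judgments, new names): globals unchanged
        relabeled = Hierarchy(
            goal="g",
            criteria_matrix=validate_pairwise(
                H.criteria_matrix.values, labels=["x", "y", "z"], raw_scale=False
            ),
            alternative_matrices={
                new: H.alternative_matrices[old]
                for new, old in zip(["x", "y", "z"], H.criteria_matrix.labels)
            },
        )
        out2 = synthesize_global_priorities(relabeled)
        np.testing.assert_allclose(
            list(out["global_priorities"].values()),
            list(out2["global_priorities"].values()),
            atol=1e-12,
        )

    def test_missing_alternative_matrix_rejected(self):
        crit = consistent_matrix([0.5, 0.5])
        with pytest.raises(ValidationError, match="no alternative-level matrix"):
            Hierarchy(goal="g", criteria_matrix=crit,
                      alternative_matrices={crit.labels[0]: consistent_matrix([0.5, 0.5])})


class TestStructuralInvariants:
    def test_lambda_max_at_least_n_on_noisy_panels(self):
        spec = PanelSpec(seed=13, n_experts=10, sigma_pairwise=0.6)
        for M in simulate_pairwise_panel(spec):
            _, lam = principal_priorities(M)
            assert lam >= M.n - 1e-9

    def test_transpose_inverts_priorities_of_consistent_matrices(self):
        w = np.array([0.5, 0.3, 0.2])
        M = consistent_matrix(w)
        Mt = validate_pairwise(M.values.T, raw_scale=False)
        p_t, _ = principal_priorities(Mt)
        inv = (1 / w) / (1 / w).sum()
        np.testing.assert_allclose(p_t, inv, atol=1e-9)

    def test_eigen_and_rowgm_agree_for_near_consistent_matrices(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(200):
            n = int(rng.integers(3, 8))
            w = rng.dirichlet(np.ones(n) * 3)
            noise = np.exp(rng.normal(0, 0.1, (n, n)))
            A = np.outer(w, 1 / w) * noise / noise.T  # still reciprocal
            np.fill_diagonal(A, 1.0)
            M = validate_pairwise(A, raw_scale=False)
            p_eig, lam = principal_priorities(M)
            if consistency(M, lam).cr < 0.05:
                p_gm = row_geometric_mean_priorities(M)
                assert np.abs(p_eig - p_gm).sum() < 0.05
                checked += 1
        assert checked > 50
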