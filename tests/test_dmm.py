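import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from scipy.optimize import linear_sum_assignment

from enterochron.dmm import (
    DirichletMultinomialMixture,
    dm_log_likelihood,
    fit_mixture,
    laplace_score,
    select_k,
    assign_enterotypes,
    trajectories,
    component_hessian_logalpha,
    _weighted_neg_objective,
)


def _two_component_sample(n=40, size=400, seed=0):
    rng = np.random.default_rng(seed)
    a1 = np.array([6.0, 1.0, 1.0, 1.0])
    a2 = np.array([1.0, 1.0, 1.0, 6.0])
    X, labels = [], []
    for i in range(n):
        a = a1 if i % 2 == 0 else a2
        X.append(rng.multinomial(size, rng.dirichlet(a)))
        labels.append(i % 2)
    return np.array(X), np.array(labels)


class TestDmLogLikelihood:
    def test_empty_count_vector_has_probability_one(self):
        assert dm_log_likelihood(np.zeros(3), np.array([1.0, 2.0, 3.0])) == 0.0

    def test_single_taxon_degenerate_support(self):
        assert dm_log_likelihood(np.array([17]), np.array([0.4])) == pytest.approx(0.0)

    @pytest.mark.parametrize("S,n", [(2, 3), (2, 5), (3, 4), (3, 5)])
    def test_normalizes_over_compositions(self, S, n):
        alpha = np.array([0.7, 1.3, 2.1])[:S]
        total = sum(
            np.exp(dm_log_likelihood(np.array(c), alpha))
            for c in itertools.product(range(n + 1), repeat=S)
            if sum(c) == n
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            dm_log_likelihood(np.array([1, 2]), np.array([1.0, 0.0]))


class TestFit:
    def test_k1_matches_direct_map_optimization(self):
        X, _ = _two_component_sample(n=20, seed=1)
        fit = fit_mixture(X, 1, seed=0)
        model = DirichletMultinomialMixture(X, 1)
        r = np.ones(X.shape[0])
        # independent route: direct bounded optimization of the same MAP
        # objective from several fresh starts
        best = np.inf
        for start in ([0.0] * 4, [1.0, 0.0, 0.0, 1.0], [-1.0] * 4):
            opt = optimize.minimize(
                _weighted_neg_objective,
                np.array(start),
                args=(model.X, model.totals, r),
                jac=True,
                method="L-BFGS-B",
            )
            best = min(best, opt.fun)
        f_em, _ = _weighted_neg_objective(
            np.log(fit.alphas[0]), model.X, model.totals, r
        )
        assert f_em == pytest.approx(best, abs=1e-6 * abs(best))

    def test_separated_components_recovered(self):
        X, labels = _two_component_sample(n=60, size=600, seed=2)
        fit = fit_mixture(X, 2, seed=3)
        post = fit.posterior().to_numpy().argmax(axis=1)
        acc = max((post == labels).mean(), (post != labels).mean())
        assert acc >= 0.95

    def test_duplicated_dataset_doubles_loglik(self):
        X, _ = _two_component_sample(n=30, seed=4)
        f1 = fit_mixture(X, 2, seed=5)
        f2 = fit_mixture(np.vstack([X, X]), 2, seed=5)
        # the weak concentration prior does not scale with n, so equality
        # is approximate rather than exact sufficiency
        assert f2.log_likelihood == pytest.approx(2 * f1.log_likelihood, rel=1e-3)
        perm = linear_sum_assignment(
            -f1.component_means() @ f2.component_means().T
        )[1]
        np.testing.assert_allclose(
            f1.alphas, f2.alphas[perm], rtol=0.05
        )

    def test_em_trace_is_monotone(self):
        X, _ = _two_component_sample(n=30, seed=6)
        fit = fit_mixture(X, 2, seed=7)
        diffs = np.diff(fit.loglik_trace)
        assert (diffs >= -1e-6 * np.abs(fit.loglik_trace[:-1])).all()

    def test_k_larger_than_samples_rejected(self):
        X, _ = _two_component_sample(n=4, seed=8)
        with pytest.raises(ValueError):
            fit_mixture(X, 5)


class TestLaplace:
    def test_component_hessian_matches_finite_differences(self):
        X, _ = _two_component_sample(n=10, size=50, seed=9)
        X = X[:, [0, 3]]  # tiny 2-taxon problem
        model = DirichletMultinomialMixture(X, 1)
        r = np.full(X.shape[0], 0.7)
        la = np.log(np.array([1.3, 0.8]))
        H = component_hessian_logalpha(model.X, model.totals, np.exp(la), r)
        h = 1e-4  # large enough that roundoff does not swamp the quotient
        H_fd = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                vals = []
                for di, dj in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
                    t = la.copy()
                    t[i] += di * h
                    t[j] += dj * h
                    vals.append(
                        _weighted_neg_objective(t, model.X, model.totals, r)[0]
                    )
                H_fd[i, j] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * h * h)
        np.testing.assert_allclose(H, H_fd, rtol=1e-4)

    def test_added_useless_component_scores_worse(self):
        rng = np.random.default_rng(10)
        X = np.array(
            [rng.multinomial(300, rng.dirichlet([2.0, 2.0, 2.0])) for _ in range(30)]
        )
        f1 = fit_mixture(X, 1, seed=11)
        f2 = fit_mixture(X, 2, seed=11)
        assert f2.laplace() > f1.laplace()

    def test_score_invariant_to_taxon_reordering(self):
        X, _ = _two_component_sample(n=30, seed=12)
        perm = [2, 0, 3, 1]
        f = fit_mixture(X, 2, seed=13)
        fp = fit_mixture(X[:, perm], 2, seed=13)
        assert f.laplace() == pytest.approx(fp.laplace(), rel=1e-6)


class TestSelectK:
    def test_singleton_range_returned_trivially(self):
        X, _ = _two_component_sample(n=20, seed=14)
        fits, best = select_k(X, k_range=[3], n_restarts=2, seed=0)
        assert best == 3 and set(fits) == {3}

    def test_exchangeable_data_prefers_k1(self):
        rng = np.random.default_rng(15)
        X = np.array(
            [rng.multinomial(400, rng.dirichlet([3.0, 3.0, 3.0, 3.0])) for _ in range(40)]
        )
        fits, best = select_k(X, k_range=range(1, 4), n_restarts=3, seed=1)
        assert best == 1

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.eye(3, dtype=int), k_range=[])


class TestAssignment:
    def test_k1_posteriors_are_exactly_one(self):
        X, _ = _two_component_sample(n=10, seed=16)
        fit = fit_mixture(X, 1, seed=0)
        out = assign_enterotypes(fit)
        np.testing.assert_array_equal(out["E1"].to_numpy(), 1.0)
        assert (out["map_label"] == 1).all()

    def test_posterior_rows_sum_to_one(self):
        X, _ = _two_component_sample(n=30, seed=17)
        fit = fit_mixture(X, 2, seed=1)
        post = fit.posterior().to_numpy()
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        X, _ = _two_component_sample(n=10, seed=18)
        fit = fit_mixture(X, 1, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            fit.posterior(np.ones((3, 7)))


class TestTrajectories:
    def test_hand_enumerated_transitions(self):
        assign = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
                "map_label": [1, 1, 2, 1, 2, 2],
            }
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "a3", "b1", "b2", "b3"],
                "pig_id": ["A", "A", "A", "B", "B", "B"],
                "age_weeks": [3, 6, 10, 3, 6, 10],
            }
        )
        summary = trajectories(assign, meta)
        # consecutive pairs: A: 1->1, 1->2; B: 1->2, 2->2
        assert summary.transitions.loc["E1", "E1"] == 1
        assert summary.transitions.loc["E1", "E2"] == 2
        assert summary.transitions.loc["E2", "E2"] == 1
        assert summary.transitions.loc["E2", "E1"] == 0
        props = summary.age_proportions
        np.testing.assert_allclose(props.sum(axis=1), 1.0)
        assert props.loc[3, "E1"] == 1.0
        assert props.loc[10, "E2"] == 1.0

    def test_single_label_degenerate(self):
        assign = pd.DataFrame(
            {"sample_id": ["a1", "a2"], "map_label": [1, 1]}
        )
        meta = pd.DataFrame(
            {
                "sample_id": ["a1", "a2"],
                "pig_id": ["A", "A"],
                "age_weeks": [3, 6],
            }
        )
        summary = trajectories(assign, meta)
        assert (summary.age_proportions["E1"] == 1.0).all()
        assert summary.transitions.to_numpy().sum() == summary.transitions.loc["E1", "E1"]
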