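"""Model core: logit predictions, cross-scale aggregation, likelihood, priors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gravmig.covariates import ModelSpec, build_pair_design
from gravmig.landscape import pairwise_distances
from gravmig.model import (CoarseFlows, CrossScalePosterior, PriorSpec,
                           aggregate_proportions, binomial_loglik,
                           cauchy_logprior, log_posterior, predict_vij,
                           proportion_matrix)

from conftest import random_unit_table


def make_design(units, spec=ModelSpec()):
    return build_pair_design(units, None, pairwise_distances(units), spec)[0]


class TestPredictVij:
    def test_zero_coefficients_give_half(self, toy_units):
        design = make_design(toy_units)
        v = predict_vij(np.zeros(4), design)
        np.testing.assert_allclose(v, 0.5)

    def test_fitted_intercept_magnitude(self, toy_units):
        # a typical fitted intercept around -7.5 maps to roughly 5e-4
        design = make_design(toy_units)
        v = predict_vij(np.array([-7.51, 0.0, 0.0, 0.0]), design)
        np.testing.assert_allclose(v, 1.0 / (1.0 + np.exp(7.51)), rtol=1e-12)
        assert v[0] == pytest.approx(5.473e-4, rel=1e-3)

    def test_monotone_in_covariate_with_positive_coefficient(self, toy_units):
        design = make_design(toy_units)
        beta = np.array([-2.0, 0.0, 1.5, 0.0])
        v = predict_vij(beta, design)
        col = design.frame["POP_j"].to_numpy()
        order = np.argsort(col)
        assert (np.diff(v[order]) >= 0).all()

    def test_dimension_mismatch(self, toy_units):
        with pytest.raises(ValueError, match="length"):
            predict_vij(np.zeros(7), make_design(toy_units))

    def test_values_strictly_inside_unit_interval(self, toy_units):
        design = make_design(toy_units)
        for intercept in (-500.0, 500.0):
            v = predict_vij(np.array([intercept, 0, 0, 0]), design)
            assert (v > 0).all() and (v < 1).all()


class TestAggregateProportions:
    def test_hand_computed_weighted_mean(self):
        units = pd.DataFrame({
            "id": ["i1", "i2", "j1"],
            "coarse_id": ["I", "I", "J"],
            "population": [100.0, 300.0, 50.0],
            "urban_prop": 0.5, "gcp_pc": 1.0, "cx": [0, 1, 2], "cy": [0, 1, 2],
        })
        v = pd.DataFrame(0.0, index=units["id"], columns=units["id"])
        v.loc["i1", "j1"] = 0.01
        v.loc["i2", "j1"] = 0.02
        P = aggregate_proportions(v, units)
        assert P.loc["I", "J"] == pytest.approx(0.0175)

    def test_one_fine_unit_per_coarse_is_identity(self):
        rng = np.random.default_rng(0)
        units = random_unit_table(rng, 4, 1)
        ids = units["id"]
        v = pd.DataFrame(rng.uniform(0, 0.1, (4, 4)), index=ids, columns=ids)
        np.fill_diagonal(v.values, 0.0)
        P = aggregate_proportions(v, units, partition=dict(zip(ids, units["coarse_id"])))
        np.testing.assert_allclose(
            P.to_numpy()[~np.eye(4, dtype=bool)], v.to_numpy()[~np.eye(4, dtype=bool)])

    def test_constant_v_single_destination_units(self):
        units = random_unit_table(np.random.default_rng(1), 3, 1)
        # three coarse units, one member each, all v equal c
        ids = units["id"]
        c = 0.004
        v = pd.DataFrame(c, index=ids, columns=ids)
        P = aggregate_proportions(v, units)
        off = P.to_numpy()[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, c)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        units = random_unit_table(rng, rng.integers(2, 6), rng.integers(1, 5))
        ids = list(units["id"])
        v = pd.DataFrame(rng.uniform(0, 0.05, (len(ids), len(ids))),
                         index=ids, columns=ids)
        P = aggregate_proportions(v, units)
        pop = units.set_index("id")["population"]
        coarse = units.set_index("id")["coarse_id"]
        for I in P.index:
            members_I = [u for u in ids if coarse[u] == I]
            for J in P.columns:
                members_J = [u for u in ids if coarse[u] == J]
                num = sum(pop[i] * v.loc[i, j]
                          for i in members_I for j in members_J if i != j)
                assert P.loc[I, J] == pytest.approx(num / pop[members_I].sum(),
                                                    abs=1e-12)

    def test_invariant_to_unit_ordering(self):
        rng = np.random.default_rng(7)
        units = random_unit_table(rng, 3, 3)
        ids = list(units["id"])
        v = pd.DataFrame(rng.uniform(0, 0.05, (9, 9)), index=ids, columns=ids)
        P1 = aggregate_proportions(v, units)
        perm = rng.permutation(9)
        units2 = units.iloc[perm].reset_index(drop=True)
        v2 = v.iloc[perm, perm]
        P2 = aggregate_proportions(v2, units2)
        np.testing.assert_allclose(P1.loc[P2.index, P2.columns], P2, atol=1e-14)

    def test_literal_denominator_divides_by_destination_count(self):
        rng = np.random.default_rng(8)
        units = random_unit_table(rng, 2, 3)
        ids = list(units["id"])
        v = pd.DataFrame(rng.uniform(0, 0.05, (6, 6)), index=ids, columns=ids)
        P = aggregate_proportions(v, units)
        P_lit = aggregate_proportions(v, units, denominator="literal")
        np.testing.assert_allclose(P_lit.to_numpy(), P.to_numpy() / 3.0)


def single_pair_flows(n, m):
    counts = pd.DataFrame({"origin": ["I"], "dest": ["J"], "count": [m]})
    return CoarseFlows(counts, pd.Series({"I": n}))


class TestBinomialLoglik:
    def test_single_pair_with_constant(self):
        ll = binomial_loglik(np.array([0.3]), single_pair_flows(10, 3),
                             include_constant=True)
        assert ll == pytest.approx(stats.binom.logpmf(3, 10, 0.3), abs=1e-10)
        assert ll == pytest.approx(-1.32115, abs=1e-5)

    def test_zero_count_closed_form(self):
        ll = binomial_loglik(np.array([0.2]), single_pair_flows(15, 0),
                             include_constant=True)
        assert ll == pytest.approx(15 * np.log(0.8), abs=1e-12)

    def test_additivity_over_pairs(self):
        counts = pd.DataFrame({"origin": ["I", "J"], "dest": ["J", "I"],
                               "count": [3, 5]})
        flows = CoarseFlows(counts, pd.Series({"I": 10, "J": 20}))
        ll = binomial_loglik(np.array([0.3, 0.2]), flows, include_constant=True)
        expected = (binomial_loglik(np.array([0.3]), single_pair_flows(10, 3), True)
                    + binomial_loglik(np.array([0.2]), single_pair_flows(20, 5), True))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_invalid_proportion_error_or_neginf(self):
        flows = single_pair_flows(10, 3)
        with pytest.raises(ValueError, match="outside"):
            binomial_loglik(np.array([1.2]), flows)
        assert binomial_loglik(np.array([1.2]), flows, on_invalid="neginf") == -np.inf

    def test_count_exceeding_sample_size_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            single_pair_flows(5, 9)

    def test_matrix_input_matches_vector_input(self):
        counts = pd.DataFrame({"origin": ["I", "J"], "dest": ["J", "I"],
                               "count": [2, 4]})
        flows = CoarseFlows(counts, pd.Series({"I": 30, "J": 40}))
        P = pd.DataFrame([[0.0, 0.1], [0.05, 0.0]], index=["I", "J"],
                         columns=["I", "J"])
        assert binomial_loglik(P, flows) == pytest.approx(
            binomial_loglik(np.array([0.1, 0.05]), flows))


class TestCauchyPrior:
    def test_slope_mode_density(self):
        lp = cauchy_logprior(np.array([0.0, 0.0]), PriorSpec())
        # intercept Cauchy(0,10) plus one slope Cauchy(0,2.5), both at the mode
        assert lp == pytest.approx(-np.log(10 * np.pi) - np.log(2.5 * np.pi), abs=1e-12)
        assert -np.log(2.5 * np.pi) == pytest.approx(-2.06102, abs=1e-5)
        assert -np.log(10 * np.pi) == pytest.approx(-3.44731, abs=1e-5)

    def test_matches_scipy_cauchy(self):
        beta = np.array([-1.3, 0.7, 2.2])
        lp = cauchy_logprior(beta, PriorSpec())
        expected = (stats.cauchy.logpdf(beta[0], scale=10)
                    + stats.cauchy.logpdf(beta[1:], scale=2.5).sum())
        assert lp == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        beta = np.array([1.0, -2.0, 0.5])
        assert cauchy_logprior(beta, PriorSpec()) == pytest.approx(
            cauchy_logprior(-beta, PriorSpec()))


class TestLogPosterior:
    def test_equals_loglik_plus_logprior(self, small_landscape, small_observation):
        units, adj, dist = small_landscape
        flows, _ = small_observation
        design, _ = build_pair_design(units, adj, dist, ModelSpec())
        post = CrossScalePosterior(design, units, flows)
        beta = post.feasible_center() + np.array([0.0, -0.5, 0.1, 0.2])
        assert post(beta) == pytest.approx(post.loglik(beta) + post.logprior(beta))
        composed = log_posterior(beta, design, units, None, flows)
        assert post(beta) == pytest.approx(composed, rel=1e-10)

    def test_prior_tails_dominate(self, small_landscape, small_observation):
        units, adj, dist = small_landscape
        flows, _ = small_observation
        design, _ = build_pair_design(units, adj, dist, ModelSpec())
        post = CrossScalePosterior(design, units, flows)
        center = post.feasible_center()
        vals = []
        # far into the lower tail the likelihood is flat (capped linear
        # predictor) and the proper Cauchy prior drives the decrease
        for mag in (10.0, 40.0, 200.0, 1000.0):
            beta = center.copy()
            beta[0] -= mag
            vals.append(post(beta))
        assert vals[0] > vals[1] > vals[2] > vals[3]

    def test_fine_equals_broad_when_scales_coincide(self):
        """With one fine unit per coarse unit the cross-scale posterior must
        equal the single-level (broad-scale) posterior at any coefficients."""
        rng = np.random.default_rng(21)
        units = random_unit_table(rng, 6, 1)
        design, _ = build_pair_design(units, None, pairwise_distances(units),
                                      ModelSpec())
        sizes = pd.Series((0.1 * units.set_index("id")["population"]).round()
                          .astype(int).values,
                          index=units["coarse_id"].values)
        counts = pd.DataFrame([
            {"origin": ci, "dest": cj, "count": int(rng.integers(0, 5))}
            for ci in units["coarse_id"] for cj in units["coarse_id"] if ci != cj])
        flows = CoarseFlows(counts, sizes)
        fine = CrossScalePosterior(design, units, flows)
        priors = PriorSpec()
        pair_lookup = dict(zip(zip(design.frame["coarse_origin"],
                                   design.frame["coarse_dest"]),
                               range(len(design))))
        for _ in range(50):
            beta = rng.normal(0, 1, 4) - np.array([6.0, 0, 0, 0])
            # broad path: fine proportions ARE the coarse proportions
            v = predict_vij(beta, design)
            p = np.array([v[pair_lookup[(o, d)]]
                          for o, d in counts[["origin", "dest"]].itertuples(index=False)])
            broad = binomial_loglik(p, flows) + cauchy_logprior(beta, priors)
            assert fine(beta) == broad
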