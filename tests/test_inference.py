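"""Parameter learning, exact posterior inference, PPCI and prediction."""

import itertools
import math

import numpy as np
import pytest

from mpchc import (
    CPT,
    BayesianNetwork,
    DAG,
    DiscreteDataset,
    ZeroProbabilityEvidence,
    fit_parameters,
    forward_sample,
    make_random_bn,
    posterior,
    ppci,
    prediction_report,
)

from conftest import joint_from_bn


def _binary_dataset(rows, names):
    return DiscreteDataset(tuple(names), tuple((("0", "1"),) * len(names)), np.asarray(rows))


class TestFitParameters:
    def test_parentless_counts_posterior_predictive(self):
        data = _binary_dataset([[0]] * 3 + [[1]], ("X",))
        bn = fit_parameters(DAG(("X",)), data, alpha_k=1.0)
        assert np.allclose(bn.cpts["X"].table, [[4 / 6, 2 / 6]])

    def test_unseen_parent_configuration_falls_back_to_prior(self):
        # Y's parent X never takes state 1
        data = _binary_dataset([[0, 0], [0, 1]] * 4, ("X", "Y"))
        bn = fit_parameters(DAG(("X", "Y"), [("X", "Y")]), data, alpha_k=1.0)
        assert np.allclose(bn.cpts["Y"].table[1], [0.5, 0.5])

    def test_large_alpha_pulls_toward_uniform(self):
        data = _binary_dataset([[0]] * 30 + [[1]] * 10, ("X",))
        bn = fit_parameters(DAG(("X",)), data, alpha_k=1e9)
        assert np.allclose(bn.cpts["X"].table, [[0.5, 0.5]], atol=1e-6)

    def test_alpha_zero_reproduces_mle(self):
        data = _binary_dataset([[0]] * 3 + [[1]], ("X",))
        bn = fit_parameters(DAG(("X",)), data, alpha_k=0.0)
        assert np.allclose(bn.cpts["X"].table, [[0.75, 0.25]])

    def test_negative_alpha_rejected(self):
        data = _binary_dataset([[0], [1]], ("X",))
        with pytest.raises(ValueError):
            fit_parameters(DAG(("X",)), data, alpha_k=-1.0)

    def test_recovery_loop_random_network(self):
        """Generator -> sampler -> estimator closes: every CPT entry is
        recovered within 3 binomial standard errors at n = 10^4."""
        from mpchc.inference import _config_codes

        bn = make_random_bn(6, max_parents=2, seed=0)
        data = forward_sample(bn, 10_000, seed=100)
        fit = fit_parameters(bn.dag, data, alpha_k=1.0)
        for node in bn.dag.nodes:
            true, est = bn.cpts[node].table, fit.cpts[node].table
            cfg = _config_codes(data, bn.cpts[node].parents)
            n_cfg = np.bincount(cfg, minlength=true.shape[0])
            for r in np.flatnonzero(n_cfg):
                se = np.sqrt(true[r] * (1 - true[r]) / n_cfg[r])
                assert (np.abs(est[r] - true[r]) <= 3 * se + 1e-9).all()


class TestPosterior:
    def test_deterministic_edge_propagates_evidence(self):
        bn = BayesianNetwork(
            DAG(("A", "B"), [("A", "B")]),
            {
                "A": CPT("A", (), [[0.5, 0.5]], np.ones(2)),
                "B": CPT("B", ("A",), [[1.0, 0.0], [0.0, 1.0]], np.ones(2)),
            },
            {"A": ("Low", "High"), "B": ("Low", "High")},
        )
        pred = posterior(bn, "B", {"A": "High"})
        assert np.allclose(pred.probabilities, [0.0, 1.0])
        assert pred.predicted_state == "High"
        assert pred.ppci == pytest.approx(100.0)

    def test_target_independent_of_evidence_equals_marginal(self):
        bn = make_random_bn(2, max_parents=0, seed=3)  # no edges
        v0, v1 = bn.dag.nodes
        pred = posterior(bn, v1, {v0: bn.state_names[v0][0]})
        assert np.allclose(pred.probabilities, bn.cpts[v1].table[0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_joint_enumeration_oracle(self, seed):
        bn = make_random_bn(6, max_parents=3, seed=seed)
        order, joint = joint_from_bn(bn)
        rng = np.random.default_rng(seed)
        nodes = list(order)
        target = nodes[rng.integers(len(nodes))]
        ev_vars = [v for v in nodes if v != target][: 3]
        evidence = {v: bn.state_names[v][rng.integers(bn.cardinality(v))] for v in ev_vars}
        pred = posterior(bn, target, evidence)
        # oracle: slice the joint and renormalise
        sl = [slice(None)] * len(order)
        for v, s in evidence.items():
            sl[order.index(v)] = bn.state_names[v].index(s)
        sub = joint[tuple(sl)]
        axes = tuple(
            i for i, v in enumerate([u for u in order if u not in evidence]) if v != target
        )
        expected = sub.sum(axis=axes) if axes else sub
        expected = expected / expected.sum()
        assert np.allclose(pred.probabilities, expected, atol=1e-12)

    def test_empty_evidence_equals_forward_marginal(self):
        bn = make_random_bn(8, max_parents=2, seed=5)
        order, joint = joint_from_bn(bn)
        target = order[4]
        pred = posterior(bn, target, {})
        axes = tuple(i for i, v in enumerate(order) if v != target)
        assert np.allclose(pred.probabilities, joint.sum(axis=axes), atol=1e-12)

    def test_zero_probability_evidence_signalled(self):
        bn = BayesianNetwork(
            DAG(("A", "B"), [("A", "B")]),
            {
                "A": CPT("A", (), [[1.0, 0.0]], np.ones(2)),
                "B": CPT("B", ("A",), [[1.0, 0.0], [0.0, 1.0]], np.ones(2)),
            },
            {"A": ("Low", "High"), "B": ("Low", "High")},
        )
        with pytest.raises(ZeroProbabilityEvidence):
            posterior(bn, "B", {"A": "High"})

    def test_target_in_evidence_rejected(self):
        bn = make_random_bn(2, seed=0)
        v0, v1 = bn.dag.nodes
        with pytest.raises(ValueError):
            posterior(bn, v0, {v0: bn.state_names[v0][0]})


class TestPpci:
    def test_uniform_posterior_is_zero(self):
        assert ppci([0.5, 0.5]) == pytest.approx(0.0)
        assert ppci([1 / 3] * 3) == pytest.approx(0.0)

    def test_degenerate_posterior_is_hundred(self):
        assert ppci([1.0, 0.0]) == pytest.approx(100.0)
        assert ppci([0.0, 0.0, 1.0]) == pytest.approx(100.0)

    def test_skewed_binary_value(self):
        expected = 100 * (1 + (0.9 * math.log(0.9) + 0.1 * math.log(0.1)) / math.log(2))
        assert ppci([0.9, 0.1]) == pytest.approx(expected)
        assert round(ppci([0.9, 0.1]), 2) == 53.10

    def test_permutation_invariant(self):
        for p in itertools.permutations([0.6, 0.3, 0.1]):
            assert ppci(list(p)) == pytest.approx(ppci([0.6, 0.3, 0.1]))

    def test_strictly_decreasing_in_entropy_on_binary_grid(self):
        grid = np.linspace(0.5, 1.0, 26)
        values = [ppci([p, 1 - p]) for p in grid]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_unnormalised_input_rejected(self):
        with pytest.raises(ValueError):
            ppci([0.9, 0.3])
        with pytest.raises(ValueError):
            ppci([1.0])


class TestPredictionReport:
    def _deterministic_pair(self):
        return BayesianNetwork(
            DAG(("A", "B"), [("A", "B")]),
            {
                "A": CPT("A", (), [[0.5, 0.5]], np.ones(2)),
                "B": CPT("B", ("A",), [[1.0, 0.0], [0.0, 1.0]], np.ones(2)),
            },
            {"A": ("Low", "High"), "B": ("Low", "High")},
        )

    def test_consistent_rows_give_perfect_accuracy(self):
        bn = self._deterministic_pair()
        test = DiscreteDataset(
            ("A", "B"), (("Low", "High"),) * 2, np.array([[0, 0], [1, 1], [0, 0]])
        )
        rep = prediction_report(bn, test, ["A", "B"])
        assert rep["B"].accuracy == 1.0 and rep["A"].accuracy == 1.0
        assert rep["B"].mean_ppci == pytest.approx(100.0)

    def test_disconnected_uniform_target_flagged_with_zero_ppci(self):
        bn = BayesianNetwork(
            DAG(("A", "B")),
            {
                "A": CPT("A", (), [[0.5, 0.5]], np.ones(2)),
                "B": CPT("B", (), [[0.5, 0.5]], np.ones(2)),
            },
            {"A": ("Low", "High"), "B": ("Low", "High")},
        )
        test = DiscreteDataset(("A", "B"), (("Low", "High"),) * 2, np.array([[0, 1], [1, 0]]))
        rep = prediction_report(bn, test, ["B"])
        assert rep["B"].disconnected
        assert rep["B"].mean_ppci == pytest.approx(0.0)

    def test_accuracy_near_bayes_rate_on_known_network(self, mixed8_bn):
        """The fitted-truth predictor must track the Bayes-optimal accuracy
        computed from the true joint by enumeration."""
        order, joint = joint_from_bn(mixed8_bn)
        target = "C"
        t_ax = order.index(target)
        # Bayes rate: E_x max_c P(c | x_-t)
        marg = joint.max(axis=t_ax).sum()
        test = forward_sample(mixed8_bn, 200, seed=77)
        rep = prediction_report(mixed8_bn, test, [target])
        se = math.sqrt(marg * (1 - marg) / 200)
        assert abs(rep[target].accuracy - marg) <= 3 * se + 1e-9

    def test_empty_test_set_rejected(self):
        bn = self._deterministic_pair()
        empty = DiscreteDataset(("A", "B"), (("Low", "High"),) * 2, np.empty((0, 2), dtype=int))
        with pytest.raises(ValueError):
            prediction_report(bn, empty, ["A"])
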