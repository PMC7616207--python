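"""Forward sampling, structure metrics, bootstrap confidence, sensitivity."""

import math

import numpy as np
import pytest

from mpchc import (
    DAG,
    CPT,
    BayesianNetwork,
    benchmark_recovery,
    bootstrap_confidence,
    f1_structure,
    forward_sample,
    make_marker_cohort,
    make_random_bn,
    posterior_shift,
    sensitivity,
    shd,
)
from mpchc.evaluation import _entropy

from conftest import joint_from_bn


class TestForwardSample:
    def test_zero_rows(self, chain_bn):
        out = forward_sample(chain_bn, 0, seed=0)
        assert out.M == 0 and out.variables == ("A", "B", "C")

    def test_root_frequency_within_binomial_bound(self):
        bn = BayesianNetwork(
            DAG(("R",)),
            {"R": CPT("R", (), [[0.3, 0.7]], np.ones(2))},
            {"R": ("a", "b")},
        )
        out = forward_sample(bn, 10_000, seed=1)
        freq = (out.column("R") == 0).mean()
        se = math.sqrt(0.3 * 0.7 / 10_000)
        assert abs(freq - 0.3) < 4 * se

    def test_deterministic_chain_rows_constant(self):
        bn = BayesianNetwork(
            DAG(("A", "B"), [("A", "B")]),
            {
                "A": CPT("A", (), [[0.4, 0.6]], np.ones(2)),
                "B": CPT("B", ("A",), [[1.0, 0.0], [0.0, 1.0]], np.ones(2)),
            },
            {"A": ("x", "y"), "B": ("x", "y")},
        )
        out = forward_sample(bn, 500, seed=2)
        assert np.array_equal(out.column("A"), out.column("B"))

    def test_seed_reproducibility(self, mixed8_bn):
        a = forward_sample(mixed8_bn, 100, seed=5)
        b = forward_sample(mixed8_bn, 100, seed=5)
        assert np.array_equal(a.codes, b.codes)


class TestStructureMetrics:
    def test_identical_dags(self):
        g = DAG("ABC", [("A", "B"), ("B", "C")])
        assert shd(g, g) == 0
        assert f1_structure(g, g) == 1.0

    def test_single_reversal_costs_one(self):
        assert shd(DAG("AB", [("A", "B")]), DAG("AB", [("B", "A")])) == 1

    def test_missing_edges_cost_additions(self):
        truth = DAG("ABC", [("A", "B"), ("B", "C")])
        assert shd(truth, DAG("ABC")) == 2

    def test_shd_symmetric(self):
        g1 = DAG("ABCD", [("A", "B"), ("C", "D")])
        g2 = DAG("ABCD", [("B", "A"), ("B", "C")])
        assert shd(g1, g2) == shd(g2, g1)

    def test_f1_partial_recovery(self):
        truth = DAG("ABC", [("A", "B"), ("B", "C")])
        est = DAG("ABC", [("A", "B")])
        assert f1_structure(truth, est) == pytest.approx(2 / 3)

    def test_f1_disjoint_sets_zero(self):
        assert f1_structure(DAG("AB", [("A", "B")]), DAG("AB", [("B", "A")])) == 0.0

    def test_skeleton_f1_ignores_orientation(self):
        truth = DAG("ABC", [("A", "B"), ("B", "C")])
        est = DAG("ABC", [("B", "A"), ("B", "C")])
        assert f1_structure(truth, est, skeleton=True) == 1.0

    def test_pattern_shd_zero_within_equivalence_class(self):
        chain = DAG("ABC", [("A", "B"), ("B", "C")])
        fork = DAG("ABC", [("B", "A"), ("B", "C")])
        collider = DAG("ABC", [("A", "C"), ("B", "C")])
        assert shd(chain, fork, pattern=True) == 0
        assert shd(chain, collider, pattern=True) > 0

    def test_node_mismatch_rejected(self):
        with pytest.raises(ValueError):
            shd(DAG("AB"), DAG("AC"))


@pytest.fixture(scope="module")
def cohort():
    return make_marker_cohort(150, seed=9)


class TestBootstrap:

    def test_stub_learner_gives_exact_endpoints(self, cohort):
        fixed = DAG(cohort.variables, [("VWM", "VSM")])
        rep = bootstrap_confidence(
            cohort, m=10, n_per_iter=80, learner=lambda d: fixed, seed=4
        )
        assert rep.edge_confidence("VWM", "VSM") == 100.0
        assert rep.edge_confidence("VSM", "VCI") == 0.0
        assert rep.best_dag.edges == fixed.edges

    def test_alternating_stub_gives_exact_fraction(self, cohort):
        e1 = DAG(cohort.variables, [("VWM", "VSM")])
        e2 = DAG(cohort.variables)
        calls = iter([e1, e1, e1, e2])
        rep = bootstrap_confidence(
            cohort, m=4, n_per_iter=50, learner=lambda d: next(calls), seed=4
        )
        assert rep.edge_confidence("VWM", "VSM") == 75.0
        # P_conf * m / 100 is an integer count by construction
        for v in rep.p_conf.values():
            assert (v * rep.m / 100) == int(v * rep.m / 100)

    def test_real_learner_finds_strong_psychology_edges(self, cohort):
        from mpchc import mpc_hc

        rep = bootstrap_confidence(
            cohort, m=8, n_per_iter=400, learner=lambda d: mpc_hc(d)[0], seed=6
        )
        within = rep.edge_confidence("VWM", "VSM") + rep.edge_confidence("VSM", "VWM")
        assert within >= 75.0  # a strong within-block adjacency keeps reappearing

    def test_invalid_m_rejected(self, cohort):
        with pytest.raises(ValueError):
            bootstrap_confidence(cohort, m=0, learner=lambda d: None, seed=0)


class TestSensitivity:
    def _pair(self, p_same: float):
        return BayesianNetwork(
            DAG(("F", "Q"), [("F", "Q")]),
            {
                "F": CPT("F", (), [[0.5, 0.5]], np.ones(2)),
                "Q": CPT("Q", ("F",), [[p_same, 1 - p_same], [1 - p_same, p_same]], np.ones(2)),
            },
            {"F": ("a", "b"), "Q": ("a", "b")},
        )

    def test_independent_pair_is_zero(self):
        bn = make_random_bn(2, max_parents=0, seed=1)
        v0, v1 = bn.dag.nodes
        assert sensitivity(bn, v1, v0).reduction == pytest.approx(0.0, abs=1e-9)

    def test_deterministic_uniform_pair_is_hundred(self):
        assert self._pair(1.0).cpts  # sanity
        assert sensitivity(self._pair(1.0), "Q", "F").reduction == pytest.approx(100.0)

    def test_ninety_percent_coupling_value(self):
        h09 = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1))
        expected = 100 * (math.log(2) - h09) / math.log(2)
        rep = sensitivity(self._pair(0.9), "Q", "F")
        assert rep.reduction == pytest.approx(expected)
        assert round(rep.reduction, 2) == 53.10

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_joint_enumeration_oracle(self, seed):
        bn = make_random_bn(7, max_parents=2, seed=seed)
        order, joint = joint_from_bn(bn)
        q = order[2]
        f_vars = (order[0], order[5])
        rep = sensitivity(bn, q, f_vars)
        # oracle entropies from the exact joint
        qi = order.index(q)
        fi = [order.index(v) for v in f_vars]
        keep = sorted(fi + [qi])
        sub = joint.sum(axis=tuple(i for i in range(len(order)) if i not in keep))
        # axes of sub follow `keep`; move q last
        sub = np.moveaxis(sub, keep.index(qi), -1)
        p_q = sub.sum(axis=tuple(range(sub.ndim - 1)))
        h_q = _entropy(p_q)
        h_cond = 0.0
        flat = sub.reshape(-1, sub.shape[-1])
        for row in flat:
            pf = row.sum()
            if pf > 0:
                h_cond += pf * _entropy(row / pf)
        assert rep.h_target == pytest.approx(h_q, abs=1e-9)
        assert rep.h_given == pytest.approx(h_cond, abs=1e-9)
        assert rep.reduction == pytest.approx(100 * (h_q - h_cond) / h_q, abs=1e-9)

    def test_information_monotone_in_evidence_set(self, mixed8_bn):
        partial = sensitivity(mixed8_bn, "C", ("B",)).reduction
        fuller = sensitivity(mixed8_bn, "C", ("B", "D", "E")).reduction
        every = sensitivity(
            mixed8_bn, "C", tuple(v for v in mixed8_bn.dag.nodes if v != "C")
        ).reduction
        assert partial <= fuller + 1e-9 <= every + 2e-9

    def test_conditioning_never_increases_entropy(self, mixed8_bn):
        rep = sensitivity(mixed8_bn, "F", ("E", "G"))
        assert rep.h_given <= rep.h_target + 1e-12
        assert 0.0 <= rep.reduction <= 100.0

    def test_deterministic_target_signalled(self):
        bn = BayesianNetwork(
            DAG(("F", "Q")),
            {
                "F": CPT("F", (), [[0.5, 0.5]], np.ones(2)),
                "Q": CPT("Q", (), [[1.0, 0.0]], np.ones(2)),
            },
            {"F": ("a", "b"), "Q": ("a", "b")},
        )
        with pytest.raises(ValueError):
            sensitivity(bn, "Q", "F")

    def test_oversized_evidence_rejected(self, mixed8_bn):
        with pytest.raises(ValueError):
            sensitivity(mixed8_bn, "A", tuple("BCDEFGH") + ("B",) * 2)


class TestPosteriorShift:
    def test_empty_evidence_prior_equals_posterior(self, chain_bn):
        prior, post = posterior_shift(chain_bn, "C", "Low", {})
        assert prior == pytest.approx(post)

    def test_matches_enumeration_oracle(self, mixed8_bn):
        order, joint = joint_from_bn(mixed8_bn)
        prior, post = posterior_shift(mixed8_bn, "C", "High", {"B": "High", "D": "High"})
        ci, bi, di = order.index("C"), order.index("B"), order.index("D")
        marg_c = joint.sum(axis=tuple(i for i in range(8) if i != ci))
        assert prior == pytest.approx(marg_c[1], abs=1e-12)
        sl = [slice(None)] * 8
        sl[bi], sl[di] = 1, 1
        sub = joint[tuple(sl)]
        keepi = [i for i in range(8) if i not in (bi, di)]
        cond = sub.sum(axis=tuple(j for j, i in enumerate(keepi) if i != ci))
        cond = cond / cond.sum()
        assert post == pytest.approx(cond[1], abs=1e-12)


class TestBenchmarkRecovery:
    def test_identity_oracle_learner_is_perfect(self, collider_bn):
        table = benchmark_recovery(
            collider_bn, {"oracle": lambda d: collider_bn.dag}, n=50, replicates=3, seed=0
        )
        assert (table["f1"] == 1.0).all()
        assert (table["shd"] == 0).all()
        assert table["i_equivalent"].all()

    def test_collider_recovered_in_most_replicates(self, collider_bn):
        from mpchc import mpc_hc

        table = benchmark_recovery(
            collider_bn, {"mpc-hc": lambda d: mpc_hc(d)[0]}, n=3000, replicates=10, seed=1
        )
        assert (table["shd"] == 0).mean() >= 0.9
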