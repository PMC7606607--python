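"""Counting estimates, EM under block missingness, and parameter recovery."""

import math

import numpy as np
import pytest

from sibbn.bn_core import joint_probability
from sibbn.learning import SurveyTable, em_fit, initialize_cpts, ml_estimate
from sibbn.synthetic_data import (
    apply_missingness,
    default_truth,
    generate,
    recovery_error,
    sample_table,
)
from sibbn.si_model import build_model

from .conftest import make_net


@pytest.fixture
def ab_net():
    states = {"A": ("a0", "a1"), "B": ("b0", "b1")}
    return make_net({
        "A": ((), {(): (0.5, 0.5)}),
        "B": (("A",), {("a0",): (0.5, 0.5), ("a1",): (0.5, 0.5)}),
    }, states)


def _table(rows):
    return SurveyTable([dict(r) for r in rows])


class TestMLEstimate:
    def test_relative_frequency(self, ab_net):
        data = _table([
            {"A": "a0", "B": "b0"}, {"A": "a0", "B": "b0"},
            {"A": "a0", "B": "b1"}, {"A": "a0", "B": "b1"},
        ])
        fitted = ml_estimate(ab_net, data, prior_count=0.0)
        assert fitted.cpts["B"].table[("a0",)][0] == pytest.approx(0.5)

    def test_laplace_smoothed_cell(self, ab_net):
        # 0 of 2 observations in a binary cell, prior 1 -> (0+1)/(2+2)
        data = _table([{"A": "a0", "B": "b1"}, {"A": "a0", "B": "b1"}])
        fitted = ml_estimate(ab_net, data, prior_count=1.0)
        assert fitted.cpts["B"].table[("a0",)][0] == pytest.approx(0.25)

    def test_unseen_row_zero_prior_uniform(self, ab_net):
        data = _table([{"A": "a0", "B": "b0"}])
        fitted = ml_estimate(ab_net, data, prior_count=0.0)
        assert np.allclose(fitted.cpts["B"].table[("a1",)], [0.5, 0.5])

    def test_locked_cpt_untouched(self):
        net = build_model("1A")
        from sibbn.si_model import ENV_NODE
        before = {k: v.copy() for k, v in net.cpts[ENV_NODE].table.items()}
        table = sample_table(default_truth("1A"), 50, seed=0)
        fitted = ml_estimate(net, table, prior_count=1.0)
        for key, vec in before.items():
            assert np.array_equal(fitted.cpts[ENV_NODE].table[key], vec)

    def test_missing_values_rejected(self, ab_net):
        with pytest.raises(ValueError, match="missing"):
            ml_estimate(ab_net, _table([{"A": "a0", "B": None}]))


class TestInitialize:
    def test_uniform_binary(self, ab_net):
        out = initialize_cpts(ab_net, "uniform")
        assert np.allclose(out.cpts["A"].table[()], [0.5, 0.5])

    def test_seed_determinism(self, ab_net):
        a = initialize_cpts(ab_net, "random", seed=11)
        b = initialize_cpts(ab_net, "random", seed=11)
        for name in a.cpts:
            for key in a.cpts[name].table:
                assert np.array_equal(a.cpts[name].table[key],
                                      b.cpts[name].table[key])

    def test_random_rows_normalized(self, ab_net):
        out = initialize_cpts(ab_net, "random", seed=3)
        for cpt in out.cpts.values():
            for vec in cpt.table.values():
                assert vec.sum() == pytest.approx(1.0)
                assert np.all(vec > 0)


class TestEMFit:
    def test_complete_data_equals_ml(self, ab_net):
        data = _table([
            {"A": "a0", "B": "b0"}, {"A": "a1", "B": "b1"},
            {"A": "a0", "B": "b1"}, {"A": "a1", "B": "b1"},
        ])
        ml = ml_estimate(ab_net, data, prior_count=1.0)
        em = em_fit(ab_net, data, prior_count=1.0, init="uniform")
        for name in ml.cpts:
            for key in ml.cpts[name].table:
                assert np.allclose(em.network.cpts[name].table[key],
                                   ml.cpts[name].table[key], atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_loglik_monotone(self, seed):
        bundle = generate("1B", n=120, poc_missing=25, seed=seed)
        fit = em_fit(build_model("1B"), bundle.table, init="random", seed=seed)
        gains = np.diff(fit.loglik_trace)
        assert np.all(gains >= -1e-8)

    def test_fully_hidden_node_is_em_stationary(self, ab_net):
        """With B missing everywhere and zero prior, B's CPT is an EM fixed
        point: the E-step redistributes exactly the current conditional."""
        start = ab_net.copy()
        start.cpts["B"].table[("a0",)] = np.array([0.7, 0.3])
        start.cpts["B"].table[("a1",)] = np.array([0.2, 0.8])
        data = _table([{"A": "a0", "B": None}] * 3 + [{"A": "a1", "B": None}] * 2)
        fit = em_fit(start, data, prior_count=0.0, max_iter=10)
        assert np.allclose(fit.network.cpts["B"].table[("a0",)], [0.7, 0.3],
                           atol=1e-12)
        assert np.allclose(fit.network.cpts["B"].table[("a1",)], [0.2, 0.8],
                           atol=1e-12)

    def test_loglik_is_sum_of_evidence_logs(self, ab_net):
        data = _table([{"A": "a0", "B": None}, {"A": "a1", "B": "b0"}])
        fit = em_fit(ab_net, data, prior_count=0.5, max_iter=5)
        from sibbn.inference import evidence_probability
        want = sum(
            math.log(evidence_probability(
                fit.network, {k: v for k, v in r.items() if v is not None}))
            for r in data.records
        )
        assert fit.loglik == pytest.approx(want, abs=1e-9)

    def test_impossible_record_names_index(self):
        states = {"A": ("a0", "a1")}
        net = make_net({"A": ((), {(): (1.0, 0.0)})}, states)
        data = _table([{"A": "a0"}, {"A": "a1"}])
        with pytest.raises(ValueError, match="record 1"):
            em_fit(net, data, prior_count=0.0)

    def test_locked_cpts_conserved(self):
        from sibbn.si_model import ENV_NODE, STORAGE_NODE
        net = build_model("1B")
        before = {
            n: {k: v.copy() for k, v in net.cpts[n].table.items()}
            for n in (ENV_NODE, STORAGE_NODE)
        }
        bundle = generate("1B", n=150, poc_missing=20, seed=2)
        fit = em_fit(net, bundle.table, init="uniform")
        for n, rows in before.items():
            for key, vec in rows.items():
                assert np.array_equal(fit.network.cpts[n].table[key], vec)

    def test_bad_settings_rejected(self, ab_net):
        data = _table([{"A": "a0", "B": "b0"}])
        with pytest.raises(ValueError):
            em_fit(ab_net, data, tol=0.0)
        with pytest.raises(ValueError):
            em_fit(ab_net, data, max_iter=0)


class TestRecovery:
    def test_error_shrinks_with_sample_size(self):
        """Probability-weighted CPT recovery error decreases from n=250 to
        n=2000 (averaged over seeds)."""
        means = []
        for n in (250, 2000):
            errs = []
            for seed in (0, 1, 2):
                b = generate("1B", n=n, poc_missing=int(0.15 * n), seed=seed)
                fit = em_fit(build_model("1B"), b.table, init="uniform")
                errs.append(recovery_error(b.truth, fit.network))
            means.append(np.mean(errs))
        assert means[1] < means[0]
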