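"""voom / moderated-t chain: definitions, oracles, null behaviour."""

import numpy as np
import pytest
from scipy import stats

import nodalsig as ns
from nodalsig.dge import estimate_prior
from conftest import make_counts


class TestLogCPM:
    def test_offsets_cancel(self):
        """count 0 at library size 999,999 -> log2(0.5e-6 * 1e6) = -1."""
        m = make_counts(np.array([[0], [999_999]]))
        y = ns.logcpm(m)
        assert y[0, 0] == pytest.approx(-1.0)

    def test_definition_at_unit_cpm(self):
        """(c + 0.5)/(R + 1) = 1e-6 gives exactly 0."""
        # R = 1_000_000 - 1 + 1 => choose counts so column sum is 999_999
        m = make_counts(np.array([[0], [999_999]]))
        # gene 0: (0+0.5)/(999_999+1) * 1e6 = 0.5 -> -1; now craft 0.0 case
        m2 = make_counts(np.array([[0], [1_999_999]]))
        y = ns.logcpm(m2)
        assert y[0, 0] == pytest.approx(np.log2(0.5 / 2e6 * 1e6))

    def test_scale_invariance(self, rng):
        """Doubling counts+0.5 and libsize+1 leaves logCPM unchanged."""
        c = rng.integers(0, 50, size=(30, 4))
        m = make_counts(c)
        y1 = ns.logcpm(m)
        lib = m.library_sizes
        manual = np.log2((c + 0.5) / (lib + 1.0) * 1e6)
        doubled = np.log2(2 * (c + 0.5) / (2 * (lib + 1.0)) * 1e6)
        np.testing.assert_allclose(y1, manual)
        np.testing.assert_allclose(manual, doubled)

    def test_zero_library_rejected(self):
        m = make_counts(np.zeros((3, 2), dtype=int))
        with pytest.raises(ValueError):
            ns.logcpm(m)


class TestBHAdjust:
    def test_cumulative_minimum_example(self):
        np.testing.assert_allclose(ns.bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(ns.bh_adjust([0.2]), [0.2])

    def test_matches_brute_force_min_formula(self, rng):
        """BH equals min over j >= i of p_(j) * m / j, restored to order."""
        for _ in range(200):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            adj = ns.bh_adjust(p)
            order = np.argsort(p)
            sorted_p = p[order]
            brute_sorted = [
                min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
                for i in range(m)
            ]
            brute = np.empty(m)
            brute[order] = brute_sorted
            np.testing.assert_allclose(adj, brute, atol=1e-12)
            assert np.all(adj >= p - 1e-12)
            assert np.all((adj >= 0) & (adj <= 1))

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ns.bh_adjust([0.5, 1.2])


class TestVoomWeights:
    def test_weights_positive_and_shapes(self, small_sim):
        _, counts, meta = small_sim
        v = ns.voom_weights(counts, meta.node_status)
        assert v.weights.shape == v.logcpm.shape == counts.counts.shape
        assert np.all(v.weights > 0)
        assert np.all(np.isfinite(v.weights))

    def test_flat_trend_for_homoscedastic_data(self, rng):
        """Equal-variance pseudo-counts give near-constant weights."""
        # constant mean, equal dispersion across genes -> flat mean-variance
        c = rng.poisson(200, size=(800, 12))
        m = make_counts(c)
        groups = ["a"] * 6 + ["b"] * 6
        v = ns.voom_weights(m, groups)
        cv = v.weights.std() / v.weights.mean()
        assert cv < 0.2

    def test_constant_genes_get_finite_weight(self):
        c = np.vstack([np.full((5, 6), 100), np.arange(6)[None, :] * 50 + 10,
                       np.full((4, 6), 2000)])
        m = make_counts(c)
        v = ns.voom_weights(m, ["a"] * 3 + ["b"] * 3)
        assert np.all(np.isfinite(v.weights)) and np.all(v.weights > 0)

    def test_small_group_rejected(self):
        m = make_counts(np.full((10, 3), 50))
        with pytest.raises(ValueError):
            ns.voom_weights(m, ["a", "a", "b"])


class TestModeratedT:
    def _voom_from_logcpm(self, y, weights=None):
        ids = [f"g{i}" for i in range(y.shape[0])]
        sids = [f"s{j}" for j in range(y.shape[1])]
        w = np.ones_like(y) if weights is None else weights
        return ns.VoomResult(y, w, np.array([0.0, 1.0]), np.array([1.0, 1.0]),
                             ids, sids, np.full(y.shape[1], 1e6))

    def test_unit_weight_log2fc_is_mean_difference(self, rng):
        y = rng.normal(size=(50, 10))
        groups = ["a"] * 5 + ["b"] * 5
        res = ns.fit_moderated_t(self._voom_from_logcpm(y), groups)
        expected = y[:, 5:].mean(axis=1) - y[:, :5].mean(axis=1)
        np.testing.assert_allclose(res.table.log2fc.to_numpy(), expected,
                                   atol=1e-12)

    def test_single_gene_fc_one(self):
        y = np.array([[0.0, 0.0, 1.0, 1.0]])
        res = ns.fit_moderated_t(self._voom_from_logcpm(y),
                                 ["a", "a", "b", "b"])
        assert res.table.log2fc.iloc[0] == pytest.approx(1.0)

    def test_prior_disabled_equals_ordinary_weighted_t(self, rng):
        """With moderation off, t matches the per-gene weighted t formula."""
        y = rng.normal(size=(40, 12))
        groups = np.array(["a"] * 6 + ["b"] * 6)
        res = ns.fit_moderated_t(self._voom_from_logcpm(y), groups,
                                 prior=False)
        for g in range(40):
            a, b = y[g, :6], y[g, 6:]
            diff = b.mean() - a.mean()
            s2 = (np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / 10
            t_manual = diff / np.sqrt(s2 * (1 / 6 + 1 / 6))
            assert res.table.t.iloc[g] == pytest.approx(t_manual, rel=1e-9)

    def test_null_pvalues_uniform(self, rng):
        """Permuted labels on null data give ~uniform p-values."""
        y = rng.normal(size=(3000, 14))
        groups = rng.permutation(["a"] * 7 + ["b"] * 7)
        res = ns.fit_moderated_t(self._voom_from_logcpm(y), list(groups))
        ks = stats.kstest(res.table.p_raw, "uniform")
        assert ks.pvalue > 0.01

    def test_needs_two_groups(self):
        y = np.zeros((5, 6))
        with pytest.raises(ValueError):
            ns.fit_moderated_t(self._voom_from_logcpm(y), ["a"] * 6)


class TestPriorEstimation:
    def test_recovers_known_prior(self, rng):
        """Moment matching recovers (d0, s0^2) from scaled chi-square draws."""
        d0, s02, dg = 8.0, 2.0, 6
        # s^2 ~ s0^2 * F(dg, d0) under the inverse-chi-square prior model
        s2 = s02 * stats.f.rvs(dg, d0, size=20000,
                               random_state=np.random.RandomState(1))
        d0_hat, s02_hat = estimate_prior(s2, dg)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s02_hat == pytest.approx(s02, rel=0.1)

    def test_constant_variances_fall_back_to_infinite_prior(self):
        """No excess spread in log s^2 -> d0 = inf and the bias-corrected
        geometric-mean prior variance (log s^2 underestimates log s0^2 by
        psi(d/2) - log(d/2) under the chi-square model)."""
        from scipy.special import digamma
        d0, s02 = estimate_prior(np.full(100, 3.0), 6)
        assert np.isinf(d0)
        expected = np.exp(np.log(3.0) - digamma(3.0) + np.log(3.0))
        assert s02 == pytest.approx(expected, rel=1e-9)


class TestCallDE:
    def test_threshold_arithmetic(self, small_sim):
        """FC 1.87 (log2fc 0.9) fails min_fc=2 even at small p_adj."""
        import pandas as pd
        table = pd.DataFrame(
            {"log2fc": [0.9, -1.2, 2.0], "p_adj": [0.04, 0.04, 0.2]},
            index=["g1", "g2", "g3"],
        )
        res = ns.DGEResult(table, 5.0, 1.0)
        calls = ns.call_de(res, fdr=0.05, min_fc=2)
        assert calls["up"] == []
        assert calls["down"] == ["g2"]
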