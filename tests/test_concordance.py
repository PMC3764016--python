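import numpy as np
import pandas as pd
import pytest
from scipy import stats

import tfsig


def series(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    idx = pd.Index([f"{prefix}{i}" for i in range(values.size)], name="gene_id")
    return pd.Series(values, index=idx)


class TestEvidence:
    def test_expression_evidence_neglog_and_cap(self):
        expr = pd.DataFrame({"gene_id": ["g0", "g1"], "p": [0.01, 1e-30]})
        v = tfsig.expression_evidence(expr, ["g0", "g1", "g2"], cap=16)
        assert v["g0"] == pytest.approx(2.0)
        assert v["g1"] == 16.0
        assert v["g2"] == 0.0  # absent from profile

    def test_binding_evidence_is_probability(self):
        profile = pd.DataFrame({"gene_id": ["g0", "g1"], "S": [2.0, 0.0],
                                "p": [0.95, 0.0], "n": [2, 0]})
        u = tfsig.binding_evidence(profile)
        assert u.tolist() == [0.95, 0.0]


class TestGlobalConcordance:
    def test_contributions_sum_to_global_statistic(self):
        rng = np.random.default_rng(301)
        u, v = series(rng.uniform(size=500)), series(rng.uniform(size=500))
        res = tfsig.grs_concordance(u, v)
        per_gene = tfsig.gene_concordance(u, v, n_draws=1000, seed=1)
        assert per_gene.e.sum() == pytest.approx(res.T, rel=1e-12)

    def test_constant_vector_no_signal(self):
        rng = np.random.default_rng(302)
        u = series(rng.uniform(size=200))
        v = series(np.full(200, 0.7))
        with pytest.warns(UserWarning, match="constant"):
            res = tfsig.grs_concordance(u, v, mode="analytic")
        assert res.z == 0.0 and res.p_global == 0.5
        assert res.T == pytest.approx(res.ET)
        with pytest.warns(UserWarning, match="constant"):
            perm = tfsig.grs_concordance(u, v, mode="permutation", n_perm=100, seed=0)
        assert perm.p_global == 1.0

    def test_strong_bimodal_signal(self):
        """Identical strongly bimodal vectors: closed-form p far below 1e-6."""
        x = np.zeros(10_000)
        x[:500] = 1.0
        u, v = series(x), series(x.copy())
        res = tfsig.grs_concordance(u, v)
        # oracle: plug the moments into the closed form directly
        G = x.size
        ET = x.sum() ** 2 / G
        var = (np.sum((x - x.mean()) ** 2)) ** 2 / (G - 1)
        z = (x @ x - ET) / np.sqrt(var)
        assert res.z == pytest.approx(z, rel=1e-12)
        assert res.p_global < 1e-6

    def test_analytic_close_to_permutation(self):
        rng = np.random.default_rng(303)
        u = series(rng.beta(0.5, 3, size=2000))
        v = series(rng.exponential(1.0, size=2000))
        a = tfsig.grs_concordance(u, v, mode="analytic")
        p = tfsig.grs_concordance(u, v, mode="permutation", n_perm=4000, seed=7)
        se = np.sqrt(p.p_global * (1 - p.p_global) / 4000)
        assert abs(a.p_global - p.p_global) <= 3 * se + 1e-12

    def test_small_universe_fatal(self):
        u = series(np.arange(50.0))
        with pytest.raises(ValueError, match="at least 100"):
            tfsig.grs_concordance(u, u)

    def test_universe_mismatch_fatal(self):
        u = series(np.arange(200.0))
        v = series(np.arange(200.0), prefix="x")
        with pytest.raises(ValueError, match="universe"):
            tfsig.grs_concordance(u, v)


class TestGeneConcordance:
    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(304)
        u, v = series(rng.uniform(size=10)), series(rng.uniform(size=10))
        out = tfsig.gene_concordance(u, v, exact=True)
        ua, va = u.to_numpy(), v.to_numpy()
        for g in range(10):
            e_g = ua[g] * va[g]
            brute = np.mean([ua[x] * va[y] >= e_g for x in range(10) for y in range(10)])
            assert out.p_e.iloc[g] == pytest.approx(brute, rel=1e-12)

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(305)
        u, v = series(rng.uniform(size=50)), series(rng.uniform(size=50))
        exact = tfsig.gene_concordance(u, v, exact=True)
        mc = tfsig.gene_concordance(u, v, n_draws=200_000, seed=9)
        assert np.max(np.abs(exact.p_e - mc.p_e)) < 0.01

    def test_zero_contribution_bottom_of_null(self):
        u = series(np.concatenate([[0.0], np.random.default_rng(1).uniform(size=99)]))
        v = series(np.ones(100))
        out = tfsig.gene_concordance(u, v, n_draws=10_000, seed=2)
        assert out.p_e.iloc[0] > 0.99
        assert out.t.iloc[0] == pytest.approx(0.0, abs=0.01)

    def test_unique_max_product_top_of_null(self):
        u = series(np.concatenate([[10.0], np.ones(99)]))
        v = series(np.concatenate([[10.0], np.ones(99)]))
        out = tfsig.gene_concordance(u, v, exact=True)
        assert out.p_e.iloc[0] == pytest.approx(1 / 100**2)

    def test_removing_top_contributors_weakens_statistic(self):
        """Dropping the highest-|e| genes from both profiles monotonically lowers T."""
        rng = np.random.default_rng(306)
        u, v = series(rng.uniform(size=2000)), series(rng.uniform(size=2000))
        e = (u * v).sort_values(ascending=False)
        T_prev = np.inf
        for k in (0, 50, 100, 200):
            keep = e.index[k:]
            T = float(u[keep] @ v[keep])
            assert T < T_prev or k == 0
            T_prev = T


class TestThresholdEnrichment:
    def _profile(self, regulated, total):
        p = np.where(np.arange(total) < regulated, 0.99, 0.1)
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(total)], "S": p, "p": p,
             "n": np.ones(total, dtype=int)}
        )

    def test_hypergeometric_oracle(self):
        # 2x2 table [[8,2],[2,8]]: one-sided p is the hypergeometric tail
        profile = self._profile(10, 20)
        de = [f"g{i}" for i in range(8)] + ["g12", "g13"]
        res = tfsig.threshold_enrichment(profile, de)
        assert res.table.tolist() == [[8, 2], [2, 8]]
        assert res.p == pytest.approx(2126 / 184756, rel=1e-9)
        assert res.p == pytest.approx(stats.hypergeom.sf(7, 20, 10, 10), rel=1e-9)

    def test_independent_calls_calibrated(self):
        """Fisher p-values under independence are (super-)uniform."""
        rng = np.random.default_rng(307)
        pvals = []
        for _ in range(300):
            total = 1000
            p_g = np.where(rng.uniform(size=total) < 0.2, 0.99, 0.1)
            profile = pd.DataFrame(
                {"gene_id": [f"g{i}" for i in range(total)], "S": p_g, "p": p_g,
                 "n": np.ones(total, dtype=int)}
            )
            de = [f"g{i}" for i in np.flatnonzero(rng.uniform(size=total) < 0.1)]
            pvals.append(tfsig.threshold_enrichment(profile, de).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01 or np.mean(pvals) > 0.5

    def test_degenerate_groups(self):
        profile = self._profile(0, 20)
        with pytest.warns(UserWarning, match="degenerate"):
            res = tfsig.threshold_enrichment(profile, ["g1"])
        assert res.p == 1.0
        profile_all = self._profile(20, 20)
        with pytest.warns(UserWarning, match="degenerate"):
            assert tfsig.threshold_enrichment(profile_all, ["g1"]).p == 1.0

    def test_calls_outside_universe_fatal(self):
        with pytest.raises(ValueError, match="outside"):
            tfsig.threshold_enrichment(self._profile(5, 20), ["nope"])


class TestAdjustBH:
    def test_hand_computation(self):
        q = tfsig.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert tfsig.adjust_bh([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(tfsig.adjust_bh([1.0, 1.0, 1.0]), 1.0)

    def test_order_preserving(self):
        rng = np.random.default_rng(308)
        p = rng.uniform(size=100)
        q = tfsig.adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
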