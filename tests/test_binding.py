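import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import tfsig
from tfsig.binding import DistanceMixture

L = 1_000_000


def links_from(a, intensity=1.0, gamma=np.nan):
    a = np.asarray(a)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(a.size)],
            "peak_index": np.arange(a.size),
            "a": a,
            "intensity": np.broadcast_to(intensity, a.shape).astype(float),
            "gamma": np.broadcast_to(gamma, a.shape).astype(float),
        }
    )


class TestFitDistanceMixture:
    def test_pure_exponential_recovers_rate(self):
        rng = np.random.default_rng(101)
        d = rng.exponential(1e4, size=20_000)  # rate 1e-4
        d = np.minimum(d, L - 1)
        a = d * rng.choice([-1, 1], size=d.size)
        fit = tfsig.fit_distance_mixture(a)
        # oracle: closed-form exponential MLE on the pure sample
        lam_mle = 1.0 / np.abs(a).mean()
        assert fit.pi >= 0.95
        assert fit.lam == pytest.approx(lam_mle, rel=0.05)

    def test_pure_uniform_gives_small_pi(self):
        rng = np.random.default_rng(102)
        a = rng.uniform(-L, L, size=20_000)
        assert tfsig.fit_distance_mixture(a).pi <= 0.05

    def test_mixture_parameter_recovery(self):
        rng = np.random.default_rng(103)
        n = 50_000
        functional = rng.uniform(size=n) < 0.3
        a = np.where(
            functional,
            np.minimum(rng.exponential(1 / 2e-4, size=n), L - 1)
            * rng.choice([-1, 1], size=n),
            rng.uniform(-L, L, size=n),
        )
        fit = tfsig.fit_distance_mixture(a)
        assert 0.28 <= fit.pi <= 0.32
        assert fit.lam == pytest.approx(2e-4, rel=0.05)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(104)
        a = np.concatenate(
            [rng.exponential(5e3, 3000) * rng.choice([-1, 1], 3000),
             rng.uniform(-L, L, 7000)]
        )
        fit = tfsig.fit_distance_mixture(np.clip(a, -L + 1, L - 1))
        assert np.all(np.diff(fit.loglik_trace) >= -1e-8)

    def test_density_integrates_to_one(self):
        fit = DistanceMixture(pi=0.37, lam=3.3e-4, L=L)
        val, _ = integrate.quad(lambda x: fit.density(x), -L, L, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_identical_distances_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            fit = tfsig.fit_distance_mixture(np.full(100, 5000.0))
        assert not fit.converged

    def test_too_few_links_fatal(self):
        with pytest.raises(ValueError, match="at least 10"):
            tfsig.fit_distance_mixture(np.arange(5.0))


class TestPosterior:
    def test_value_at_tss(self):
        model = DistanceMixture(pi=0.5, lam=1e-3, L=1e6)
        # (0.5*5e-4) / (0.5*5e-4 + 0.5*5e-7)
        assert model.posterior(0.0) == pytest.approx(0.999001, abs=1e-6)

    def test_no_functional_component(self):
        model = DistanceMixture(pi=1e-300, lam=1e-3, L=1e6)
        assert model.posterior(np.array([0.0, 1e5]))[1] == pytest.approx(0.0, abs=1e-290)

    def test_balance_point_is_half(self):
        model = DistanceMixture(pi=0.3, lam=1e-4, L=1e6)
        # solve pi*f_E(a*) = (1-pi)*f_U for a*
        a_star = -np.log((1 - model.pi) / (2 * model.L) / (model.pi * model.lam / 2)) / model.lam
        assert model.posterior(a_star) == pytest.approx(0.5, abs=1e-12)

    def test_monotone_nonincreasing_in_abs_distance(self):
        model = DistanceMixture(pi=0.4, lam=2e-4, L=1e6)
        grid = np.linspace(0, 1e6, 2001)
        g = model.posterior(grid)
        assert np.all(np.diff(g) <= 0)
        assert g[-1] == min(g)  # minimum attained at |a| = L

    def test_fills_gamma_column(self):
        model = DistanceMixture(pi=0.5, lam=1e-3)
        links = tfsig.peak_functional_posterior(links_from([0, 1000, 50_000]), model)
        assert links.gamma.notna().all()
        assert links.gamma.is_monotonic_decreasing


class TestBindingScores:
    def _score(self, pairs):
        """pairs: list of (gamma, intensity) for a single gene."""
        links = pd.DataFrame(
            {
                "gene_id": "g1",
                "peak_index": range(len(pairs)),
                "a": 0,
                "intensity": [h for _, h in pairs],
                "gamma": [g for g, _ in pairs],
            }
        )
        genes = pd.DataFrame(
            {"gene_id": ["g1", "g0"], "chrom": "c", "strand": "+", "tss": [0, 10]}
        )
        return tfsig.binding_scores(links, genes).set_index("gene_id")

    def test_direct_formula(self):
        out = self._score([(0.5, 4.0), (0.25, 8.0)])
        assert out.loc["g1", "S"] == pytest.approx(np.log(5.0))
        assert out.loc["g0", "S"] == 0.0 and out.loc["g0", "n"] == 0

    def test_single_unit_peak(self):
        out = self._score([(1.0, np.e - 1.0)])
        assert out.loc["g1", "S"] == pytest.approx(1.0)

    def test_negative_intensity_fatal(self):
        with pytest.raises(ValueError, match="negative"):
            self._score([(1.0, -1.0)])

    def test_matches_brute_force_rescan(self, fitted_pipeline):
        links, genes = fitted_pipeline["links"], fitted_pipeline["ds"].genes
        got = tfsig.binding_scores(links, genes).set_index("gene_id")["S"]
        for gid in genes.gene_id.sample(30, random_state=0):
            sub = links[links.gene_id == gid]
            expected = np.log1p(float((sub.gamma * sub.intensity).sum()))
            assert got[gid] == pytest.approx(expected, rel=1e-12, abs=1e-15)

    def test_planted_genes_score_higher(self, fitted_pipeline):
        """Genes with planted functional peaks dominate background genes in S."""
        profile, truth = fitted_pipeline["profile"], fitted_pipeline["ds"].truth
        merged = profile.merge(truth, on="gene_id")
        s_reg = merged.loc[merged.regulated, "S"]
        s_bg = merged.loc[~merged.regulated, "S"]
        p = stats.mannwhitneyu(s_reg, s_bg, alternative="greater").pvalue
        assert p < 0.01


class TestBaselineScores:
    GENES = pd.DataFrame({"gene_id": ["g1"], "chrom": "c", "strand": "+", "tss": [0]})

    def _links(self):
        return pd.DataFrame(
            {
                "gene_id": "g1",
                "peak_index": [0, 1],
                "a": [400, -600],
                "intensity": [3.0, 7.0],
                "gamma": np.nan,
            }
        )

    def test_mpi_respects_window(self):
        out = tfsig.baseline_scores(self._links(), self.GENES, "mpi", window_bp=1000)
        assert out.score.iloc[0] == 3.0  # only |a| <= 500 qualifies

    def test_uws_sums_within_window(self):
        out = tfsig.baseline_scores(self._links(), self.GENES, "uws", window_bp=2000)
        assert out.score.iloc[0] == 10.0

    def test_lws_linear_weight(self):
        links = self._links().assign(a=[500_000, 2_000_000 // 2], intensity=[10.0, 0.0])
        out = tfsig.baseline_scores(links, self.GENES, "lws", L=1_000_000)
        assert out.score.iloc[0] == pytest.approx(5.0)

    def test_unknown_method_fatal(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            tfsig.baseline_scores(self._links(), self.GENES, "best")
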