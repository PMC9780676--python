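import numpy as np
import pytest
from scipy import integrate, stats

import fnirslat as fl
from fnirslat.sem import (
    FitConfig,
    ModelData,
    Posterior,
    df_prior_logdensity,
    diagnose,
    fit,
    induced_dirichlet_logprior,
    induced_probabilities,
    ordinal_loglik,
    prescale,
    summarize,
)


def _sem_data(n=12, trials=8, seed=0, **cfg_kwargs):
    cfg = fl.SimConfig(n_participants=n, n_trials=trials, seed=seed, **cfg_kwargs)
    m1, items, truth = fl.generate_sem_cohort(cfg)
    fm, sis = items.to_arrays(truth.participant_ids)
    return ModelData.from_arrays(fm, sis, m1, truth.participant_ids), truth


class TestPrescale:
    def test_median_removed_and_mad_unit(self, rng):
        x = rng.standard_t(5, size=(6, 10, 8)) * 3 + 1.5
        scaled, record = prescale(x)
        flat = scaled.reshape(-1, 8)
        assert np.allclose(np.median(flat, axis=0), 0.0, atol=1e-12)
        mad = 1.4826 * np.median(np.abs(flat - np.median(flat, axis=0)), axis=0)
        assert np.allclose(mad, 1.0, atol=1e-12)
        assert record["median"].shape == (8,)

    def test_symmetric_triplet(self):
        x = np.array([-1.0, 0.0, 1.0]).reshape(3, 1, 1).repeat(8, axis=2)
        scaled, _ = prescale(x)
        assert np.allclose(np.median(scaled.reshape(-1, 8), axis=0), 0.0)

    def test_outlier_robustness_vs_moment_scaling(self, rng):
        x = rng.normal(size=(20, 10, 8))
        y = x.copy()
        y[0, 0, :] += 1000.0  # gross outlier trial
        sx, _ = prescale(x)
        sy, _ = prescale(y)
        mask = np.ones_like(x, bool)
        mask[0, 0, :] = False
        # robust scaling barely moves; moment scaling would collapse by ~10x
        assert np.allclose(sx[mask], sy[mask], atol=0.1)
        assert y.std(axis=(0, 1)).min() > 5 * x.std(axis=(0, 1)).max()

    def test_zero_mad_rejected(self):
        x = np.zeros((4, 5, 8))
        with pytest.raises(ValueError, match="pair 1"):
            prescale(x)


class TestDfPrior:
    def test_peak_at_fifteen_by_grid_argmax(self):
        grid = np.arange(0.01, 30.0, 0.01)
        assert grid[np.argmax(df_prior_logdensity(grid))] == pytest.approx(15.0, abs=0.01)

    def test_symmetry(self):
        assert df_prior_logdensity(5.0) == pytest.approx(df_prior_logdensity(25.0))

    def test_integrates_to_one(self):
        val, _ = integrate.quad(lambda d: np.exp(df_prior_logdensity(d)), 0, 30)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_out_of_support(self):
        assert df_prior_logdensity(-1.0) == -np.inf
        assert df_prior_logdensity(31.0) == -np.inf


class TestInducedDirichlet:
    def test_two_categories_symmetric(self):
        probs = induced_probabilities(np.array([0.0]))
        assert np.allclose(probs, [0.5, 0.5])

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(10):
            cuts = np.sort(rng.normal(size=4))
            assert induced_probabilities(cuts).sum() == pytest.approx(1.0)

    def test_non_increasing_cuts_zero_density(self):
        assert induced_dirichlet_logprior(np.array([1.0, 0.0])) == -np.inf

    def test_prior_draws_have_uniform_category_marginals(self):
        """Cutpoints distributed per the induced Dirichlet(1) prior induce
        category probabilities that are uniform on the simplex, so each
        category's mean probability is 1/K."""
        rng = np.random.default_rng(3)
        K = 4
        probs = []
        for _ in range(4000):
            # alpha=1: cutpoints are the order statistics of K-1 standard
            # normal draws (density proportional to the Jacobian)
            cuts = np.sort(rng.normal(size=K - 1))
            probs.append(induced_probabilities(cuts))
        mean_probs = np.mean(probs, axis=0)
        assert np.allclose(mean_probs, 1.0 / K, atol=0.02)


class TestOrdinalLoglik:
    def test_partition_of_unity(self):
        cuts = np.array([-0.8, 0.3, 1.1])
        total = sum(np.exp(ordinal_loglik(k, 0.4, cuts)) for k in range(4))
        assert total == pytest.approx(1.0)

    def test_extreme_mean_top_category(self):
        cuts = np.array([-1.0, 1.0])
        assert np.exp(ordinal_loglik(2, 50.0, cuts)) == pytest.approx(1.0)

    def test_middle_mass_closed_form(self):
        cuts = np.array([-1.0, 1.0])
        expected = stats.norm.cdf(1.0) - stats.norm.cdf(-1.0)
        assert np.exp(ordinal_loglik(1, 0.0, cuts)) == pytest.approx(expected)

    def test_invalid_category(self):
        with pytest.raises(ValueError):
            ordinal_loglik(7, 0.0, np.array([-1.0, 1.0]))


class TestModelData:
    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            ModelData(
                fm=np.zeros((1, 12), int), sis=np.zeros((1, 5), int),
                m1lat=np.zeros((1, 5, 8)), participant_ids=["P01"],
            )

    def test_category_range_enforced(self):
        fm = np.zeros((3, 12), int)
        fm[0, 0] = 5
        with pytest.raises(ValueError, match="FM-12"):
            ModelData(
                fm=fm, sis=np.zeros((3, 5), int),
                m1lat=np.zeros((3, 5, 8)), participant_ids=["a", "b", "c"],
            )

    def test_from_tables_matches_from_arrays(self):
        cfg = fl.SimConfig(n_participants=4, n_trials=5, seed=9)
        m1, items, truth = fl.generate_sem_cohort(cfg)
        lat_rows = []
        for i, pid in enumerate(truth.participant_ids):
            for t in range(5):
                for l in range(8):
                    lat_rows.append(
                        {"participant_id": pid, "lesion_side": truth.lesion_sides[i],
                         "trial": t + 1, "pair_index": l + 1, "m1lat": m1[i, t, l]}
                    )
        import pandas as pd

        a = ModelData.from_tables(items, pd.DataFrame(lat_rows))
        fm, sis = items.to_arrays(truth.participant_ids)
        b = ModelData.from_arrays(fm, sis, m1, truth.participant_ids)
        assert np.allclose(a.m1lat, b.m1lat)
        assert np.array_equal(a.fm, b.fm)


class TestFit:
    def test_same_seed_identical_draws(self):
        data, _ = _sem_data(n=6, trials=5, seed=1)
        cfg = FitConfig(chains=2, warmup=40, draws=40, seed=5)
        a, b = fit(data, cfg), fit(data, cfg)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name])

    def test_constraints_respected(self):
        data, _ = _sem_data(n=8, trials=6, seed=2)
        post = fit(data, FitConfig(chains=2, warmup=100, draws=100, seed=3))
        assert np.all((post.stacked("rho_fm") > 0) & (post.stacked("rho_fm") < 1))
        assert np.all((post.stacked("rho_sis") > 0) & (post.stacked("rho_sis") < 1))
        rm = post.stacked("rho_m1lat")
        assert np.all((rm > -1) & (rm < 1))
        lam = post.stacked("loading")
        assert np.all((lam > 0) & (lam < 1))
        for name in ("latent_df", "trial_df"):
            d = post.stacked(name)
            assert np.all((d > 0) & (d < 30))
        cuts = post.stacked("sis_cutpoints")
        assert np.all(np.diff(cuts, axis=-1) > 0)

    def test_prior_only_df_matches_scaled_beta(self):
        """With the likelihood detached the trial DF posterior is its
        Beta(2,2)-scaled prior."""
        data, _ = _sem_data(n=6, trials=5, seed=4)
        post = fit(
            data, FitConfig(chains=2, warmup=100, draws=400, seed=11, prior_only=True)
        )
        d = post.stacked("trial_df")
        qs = np.quantile(d, [0.25, 0.5, 0.75])
        expected = 30.0 * stats.beta.ppf([0.25, 0.5, 0.75], 2, 2)
        assert np.allclose(qs, expected, atol=1.5)

    def test_prior_only_subtrait_unit_variance(self):
        data, _ = _sem_data(n=6, trials=5, seed=4)
        post = fit(
            data, FitConfig(chains=2, warmup=100, draws=400, seed=12, prior_only=True)
        )
        fm = post.stacked("fm_trait")
        assert fm.var() == pytest.approx(1.0, rel=0.25)

    def test_per_participant_latent_df_switch(self):
        data, _ = _sem_data(n=5, trials=4, seed=6)
        post = fit(
            data,
            FitConfig(chains=1, warmup=30, draws=30, seed=2,
                      per_participant_latent_df=True),
        )
        assert post.draws["latent_df"].shape == (1, 30, 5)

    def test_posterior_dataframe_layout(self):
        data, _ = _sem_data(n=5, trials=4, seed=6)
        post = fit(data, FitConfig(chains=2, warmup=20, draws=25, seed=2))
        df = post.to_dataframe()
        assert len(df) == 2 * 25
        assert {"chain", "iteration", "rho_m1lat", "loading[0]"} <= set(df.columns)


class TestDiagnose:
    def test_identical_iid_chains_pass(self, rng):
        draws = {"theta": rng.normal(size=(4, 600))}
        rep = diagnose(draws, ess_floor=100)
        assert rep.max_rhat < 1.01
        assert rep.min_tail_ess >= 100
        assert rep.passed

    def test_disjoint_chains_fail(self, rng):
        a = rng.normal(size=600)
        draws = {"theta": np.stack([a - 10.0, a + 10.0])}
        rep = diagnose(draws, ess_floor=100)
        assert rep.max_rhat > 1.01
        assert not rep.passed

    def test_single_chain_unusable(self, rng):
        rep = diagnose({"theta": rng.normal(size=(1, 500))})
        assert not rep.usable
        assert not rep.passed

    def test_divergence_count_passthrough(self, rng):
        post = Posterior(
            draws={"theta": rng.normal(size=(2, 300))},
            participant_ids=["a", "b"], config=FitConfig(), n_divergent=3,
        )
        rep = diagnose(post)
        assert rep.n_divergent == 3
        assert not rep.passed


class TestSummarize:
    def _toy_posterior(self, rng):
        n_draw = 500
        rho_fm = rng.uniform(0.3, 0.5, size=(2, n_draw))
        draws = {
            "rho_fm": rho_fm,
            "rho_sis": rho_fm + 0.2,  # perfectly correlated draw-wise
            "rho_m1lat": rng.normal(0.4, 0.1, size=(2, n_draw)),
            "ueif": rng.normal(size=(2, n_draw, 3)),
            "fm_trait": rng.normal(size=(2, n_draw, 3)),
            "sis_trait": rng.normal(size=(2, n_draw, 3)),
            "m1_trait": rng.normal(size=(2, n_draw, 3)),
            "loading": rng.uniform(0.2, 0.8, size=(2, n_draw, 8)),
        }
        return Posterior(
            draws=draws, participant_ids=["a", "b", "c"], config=FitConfig()
        )

    def test_cri_bounds_match_quantile_oracle(self, rng):
        post = self._toy_posterior(rng)
        s = summarize(post)
        x = np.sort(post.stacked("rho_m1lat"))

        def quantile(q):  # sort-based linear-interpolation oracle
            h = (x.size - 1) * q
            lo = int(np.floor(h))
            return x[lo] + (h - lo) * (x[min(lo + 1, x.size - 1)] - x[lo])

        lo95, hi95 = s["correlations"]["rho_m1lat"]["cri95"]
        assert lo95 == pytest.approx(quantile(0.025), abs=1e-12)
        assert hi95 == pytest.approx(quantile(0.975), abs=1e-12)

    def test_cri50_nested_in_cri95(self, rng):
        s = summarize(self._toy_posterior(rng))
        for entry in s["correlations"].values():
            assert entry["cri95"][0] <= entry["cri50"][0]
            assert entry["cri50"][1] <= entry["cri95"][1]

    def test_difference_computed_drawwise(self, rng):
        """rho_sis - rho_fm is constant 0.2 draw-wise even though the
        marginals are wide, so the draw-wise CrI must collapse to 0.2."""
        s = summarize(self._toy_posterior(rng))
        diff = s["correlations"]["rho_sis_minus_rho_fm"]
        assert diff["median"] == pytest.approx(0.2)
        assert diff["cri95"][1] - diff["cri95"][0] < 1e-9

    def test_loading_summary_length(self, rng):
        s = summarize(self._toy_posterior(rng))
        assert len(s["location_loadings"]["median_medial_to_lateral"]) == 8

    def test_empty_posterior_rejected(self):
        post = Posterior(
            draws={"rho_fm": np.zeros((2, 0))}, participant_ids=["a", "b"],
            config=FitConfig(),
        )
        with pytest.raises(ValueError):
            summarize(post)


class TestRecoverySmall:
    def test_strong_link_recovered_on_moderate_cohort(self, sem_cohort):
        """A 20-participant, 12-trial cohort with true rho_M1LAT = 0.6
        yields a posterior concentrating near the truth."""
        m1, items, truth = sem_cohort
        fm, sis = items.to_arrays(truth.participant_ids)
        data = ModelData.from_arrays(fm, sis, m1, truth.participant_ids)
        post = fit(data, FitConfig(chains=2, warmup=400, draws=400, seed=21))
        s = summarize(post)["correlations"]["rho_m1lat"]
        lo, hi = s["cri95"]
        assert lo <= 0.6 <= hi
        assert s["median"] == pytest.approx(0.6, abs=0.3)
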