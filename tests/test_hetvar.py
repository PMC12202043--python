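"""Sampler correctness: method-of-moments and conjugate oracles, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from urbanvar import effects, hetvar, partition, synthetic
from urbanvar.errors import (
    ConfigError,
    DegenerateChainError,
    DesignRankError,
    InsufficientDrawsError,
)
from urbanvar.hetvar import (
    MCMCOptions,
    ModelConfig,
    convergence_check,
    effective_sample_size,
    fit,
    geweke_z,
)


def anova_oracle(table: pd.DataFrame, group: str) -> tuple[float, float]:
    """Balanced one-way ANOVA estimates of (V_i, V_r) for one habitat."""
    sub = table[table["habitat"] == group]
    g = sub.groupby("individual_id")["value"]
    k = int(g.size().iloc[0])
    assert (g.size() == k).all(), "oracle requires balance"
    msw = g.var(ddof=1).mean()
    msb = k * g.mean().var(ddof=1)
    return (msb - msw) / k, msw


@pytest.fixture(scope="module")
def balanced_table():
    spec = synthetic.VarianceSpec(
        family="gaussian",
        intercept={"forest": 10.0, "urban": 10.0},
        v_individual={"forest": 2.0, "urban": 2.0},
        v_residual={"forest": 1.0, "urban": 1.0},
        n_individuals=250,
        repeats_probs={4: 1.0},
    )
    return synthetic.simulate_observations(spec, seed=30)


@pytest.fixture(scope="module")
def balanced_draws(balanced_table):
    config = ModelConfig(
        family="gaussian",
        include_year=False,
        include_observer=False,
        fixed_terms=(),
        group_interactions=False,
        mcmc=MCMCOptions(n_iter=2500, burn_in=800, thin=2, seed=1),
    )
    return fit(balanced_table, config)


class TestGaussianFit:
    def test_matches_anova_oracle(self, balanced_table, balanced_draws):
        for g in ("forest", "urban"):
            vi_hat, vr_hat = anova_oracle(balanced_table, g)
            assert np.mean(balanced_draws.v_individual(g)) == pytest.approx(vi_hat, rel=0.15)
            assert np.mean(balanced_draws.v_residual(g)) == pytest.approx(vr_hat, rel=0.15)

    def test_duplicated_group_lncvr_covers_zero(self):
        spec = synthetic.VarianceSpec(
            family="gaussian",
            intercept={"forest": 10.0, "urban": 10.0},
            v_individual={"forest": 1.5, "urban": 1.5},
            v_residual={"forest": 1.0, "urban": 1.0},
            n_individuals={"forest": 200, "urban": 0},
            repeats_probs={2: 1.0},
            beta_sex=0.3,
        )
        table = synthetic.simulate_observations(spec, seed=6)
        clone = table.copy()
        clone["habitat"] = "urban"
        clone["location_id"] = "urban"
        clone["individual_id"] = clone["individual_id"] + "_dup"
        both = pd.concat([table, clone], ignore_index=True)
        draws = fit(
            both,
            ModelConfig(
                family="gaussian",
                include_year=False,
                include_observer=False,
                mcmc=MCMCOptions(n_iter=2500, burn_in=800, thin=2, seed=2),
            ),
        )
        stream = effects.ln_ratio(draws.v_individual("urban"), draws.v_individual("forest"))
        summary = effects.summarize(0.5 * stream, name="lnCVR_I")
        assert summary.ci_low < 0 < summary.ci_high

    def test_exchangeability_under_row_permutation(self, balanced_table, balanced_draws):
        shuffled = balanced_table.sample(frac=1.0, random_state=99)
        config = ModelConfig(
            family="gaussian",
            include_year=False,
            include_observer=False,
            fixed_terms=(),
            group_interactions=False,
            mcmc=MCMCOptions(n_iter=2500, burn_in=800, thin=2, seed=77),
        )
        other = fit(shuffled, config)
        for g in ("forest", "urban"):
            a = np.median(balanced_draws.v_individual(g))
            b = np.median(other.v_individual(g))
            assert a == pytest.approx(b, rel=0.15)

    @pytest.mark.filterwarnings("ignore:variance group")
    def test_conjugate_scaled_inv_chi2_oracle(self):
        # beta frozen at truth, no random effects: V_r posterior is analytic
        rng = np.random.default_rng(5)
        n = 400
        spec = synthetic.VarianceSpec(
            family="gaussian",
            intercept={"forest": 10.0, "urban": 10.0},
            v_individual={"forest": 0.0, "urban": 0.0},
            v_residual={"forest": 1.3, "urban": 1.3},
            n_individuals=n // 2,
            repeats_probs={1: 1.0},
        )
        table = synthetic.simulate_observations(spec, seed=9)
        config = ModelConfig(
            family="gaussian",
            include_individual=False,
            include_year=False,
            include_observer=False,
            fixed_terms=(),
            group_interactions=False,
            heterogeneous_residual=False,
            fixed_beta=[10.0, 10.0],
            mcmc=MCMCOptions(n_iter=5500, burn_in=500, thin=1, seed=3),
        )
        draws = fit(table, config)
        v = draws.get("V_r")
        design = draws.design
        X = design.encode(table)
        resid = table["value"].to_numpy() - X @ np.array([10.0, 10.0])
        ss = float((resid**2).sum())
        a0, b0 = 0.001, 0.001
        analytic = stats.invgamma(a=a0 + len(table) / 2, scale=b0 + ss / 2)
        d = stats.kstest(v, analytic.cdf)
        assert d.statistic < 0.05

    def test_prior_sensitivity_smoke(self, gauss_table):
        base = ModelConfig(
            family="gaussian",
            mcmc=MCMCOptions(n_iter=2200, burn_in=700, thin=2, seed=4),
        )
        wide = ModelConfig(
            family="gaussian",
            prior_v=2.0,
            mcmc=MCMCOptions(n_iter=2200, burn_in=700, thin=2, seed=4),
        )
        a = fit(gauss_table, base)
        b = fit(gauss_table, wide)
        for g in ("forest", "urban"):
            assert np.mean(a.v_individual(g)) == pytest.approx(
                np.mean(b.v_individual(g)), rel=0.10
            )

    def test_coverage_of_vi_credible_intervals(self):
        covered = 0
        for rep in range(20):
            spec = synthetic.VarianceSpec(
                family="gaussian",
                intercept={"forest": 10.0, "urban": 10.0},
                v_individual={"forest": 1.5, "urban": 1.0},
                v_residual={"forest": 1.0, "urban": 1.0},
                n_individuals=150,
                repeats_probs={2: 1.0},
            )
            table = synthetic.simulate_observations(spec, seed=100 + rep)
            draws = fit(
                table,
                ModelConfig(
                    family="gaussian",
                    include_year=False,
                    include_observer=False,
                    fixed_terms=(),
                    group_interactions=False,
                    mcmc=MCMCOptions(n_iter=2200, burn_in=700, thin=2, seed=rep),
                ),
            )
            v = draws.v_individual("forest")
            lo, hi = np.quantile(v, [0.025, 0.975])
            covered += lo <= 1.5 <= hi
        assert covered >= 18

    def test_scale_equivariance_of_cvs(self, gauss_table):
        config = ModelConfig(
            family="gaussian",
            mcmc=MCMCOptions(n_iter=2200, burn_in=700, thin=2, seed=12),
        )
        scaled = gauss_table.copy()
        scaled["value"] = scaled["value"] * 3.0
        a = fit(gauss_table, config)
        b = fit(scaled, config)
        _, cv_a = partition.decompose(a, gauss_table)
        _, cv_b = partition.decompose(b, scaled)
        for g in ("forest", "urban"):
            ma = cv_a.for_group(g)
            mb = cv_b.for_group(g)
            assert mb["mean"].median() == pytest.approx(3.0 * ma["mean"].median(), rel=0.05)
            assert mb["CV_P"].median() == pytest.approx(ma["CV_P"].median(), rel=0.10)
            assert mb["rpt"].median() == pytest.approx(ma["rpt"].median(), rel=0.10)

    def test_collinear_design_raises_with_names(self, gauss_table):
        table = gauss_table.copy()
        table["sex"] = "M"  # sex dummy becomes an intercept alias
        config = ModelConfig(
            family="gaussian",
            group_interactions=False,
            fixed_terms=("sex",),
            mcmc=MCMCOptions(n_iter=300, burn_in=100, thin=1, seed=0),
        )
        with pytest.raises(DesignRankError, match="aliased"):
            fit(table, config)

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(family="beta")

    def test_group_without_repeats_warns(self):
        spec = synthetic.VarianceSpec(
            family="gaussian",
            intercept={"forest": 10.0, "urban": 10.0},
            v_individual={"forest": 1.0, "urban": 1.0},
            v_residual={"forest": 1.0, "urban": 1.0},
            n_individuals=40,
            repeats_probs={1: 1.0},
        )
        table = synthetic.simulate_observations(spec, seed=1)
        with pytest.warns(UserWarning, match="repeated"):
            fit(
                table,
                ModelConfig(
                    family="gaussian",
                    include_year=False,
                    include_observer=False,
                    fixed_terms=(),  # assay_rank is constant with single assays
                    group_interactions=False,
                    mcmc=MCMCOptions(n_iter=400, burn_in=200, thin=1, seed=0),
                ),
            )


class TestPoissonFit:
    def test_parameter_recovery_20_replicates(self):
        hits = 0
        for rep in range(20):
            spec = synthetic.VarianceSpec(
                family="poisson",
                intercept={"forest": 1.2, "urban": 1.2},
                v_individual={"forest": 0.4, "urban": 0.4},
                v_residual={"forest": 0.2, "urban": 0.2},
                n_individuals=120,
                repeats_probs={3: 1.0},
            )
            table = synthetic.simulate_observations(spec, seed=500 + rep)
            draws = fit(
                table,
                ModelConfig(
                    family="poisson",
                    include_year=False,
                    include_observer=False,
                    fixed_terms=(),
                    group_interactions=False,
                    mcmc=MCMCOptions(n_iter=3200, burn_in=1200, thin=2, seed=rep),
                ),
            )
            v = np.concatenate(
                [draws.v_individual("forest"), draws.v_individual("urban")]
            )
            hits += abs(v.mean() - 0.4) <= 3 * v.std(ddof=1)
        assert hits >= 16


class TestOrdinalFit:
    def test_thresholds_increase_every_draw(self):
        spec = synthetic.VarianceSpec(
            family="ordinal",
            intercept={"forest": 1.0, "urban": 1.4},
            v_individual={"forest": 0.4, "urban": 0.8},
            v_residual={"forest": 1.0, "urban": 1.0},
            n_individuals=150,
            repeats_probs={2: 1.0},
        )
        table = synthetic.simulate_observations(spec, seed=40)
        draws = fit(
            table,
            ModelConfig(
                family="ordinal",
                include_year=False,
                include_observer=False,
                mcmc=MCMCOptions(n_iter=1500, burn_in=500, thin=2, seed=8),
            ),
        )
        cuts = np.column_stack([draws.get(f"cut{k}") for k in range(2, 7)])
        assert np.all(np.diff(np.column_stack([np.zeros(len(cuts)), cuts]), axis=1) > 0)
        # ordinal residual variance is fixed, not sampled
        assert not any(name.startswith("V_r") for name in draws.param_names)
        assert np.all(draws.v_residual("forest") == 1.0)

    def test_variance_draws_positive(self, gauss_draws):
        for name in gauss_draws.param_names:
            if name.startswith("V_"):
                assert np.all(gauss_draws.get(name) > 0)


class TestESS:
    def test_iid_normal(self, rng):
        x = rng.standard_normal(2000)
        ess = effective_sample_size(x)
        assert 1600 <= ess <= 2400

    def test_ar1_closed_form(self, rng):
        rho, n = 0.5, 20_000
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho**2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        expected = n * (1 - rho) / (1 + rho)
        assert effective_sample_size(x) == pytest.approx(expected, rel=0.25)

    def test_constant_chain_error(self):
        with pytest.raises(DegenerateChainError):
            effective_sample_size(np.ones(500))

    def test_too_few_draws(self):
        with pytest.raises(InsufficientDrawsError):
            effective_sample_size(np.arange(50.0))

    def test_posterior_draws_interface(self, gauss_draws):
        ess = effective_sample_size(gauss_draws)
        assert set(ess) == set(gauss_draws.param_names)
        assert all(v > 0 for v in ess.values())


class TestConvergence:
    def test_iid_calibration(self):
        rng = np.random.default_rng(2024)
        passes = sum(abs(geweke_z(rng.standard_normal(2000))) < 2.58 for _ in range(100))
        assert passes >= 99

    def test_mean_shift_flagged(self, rng):
        x = rng.standard_normal(2000)
        x[1000:] += 2.0
        assert abs(geweke_z(x)) > 2.58

    def test_report_on_fit(self, gauss_draws):
        report = convergence_check(gauss_draws, ess_threshold=100)
        assert set(report.table["parameter"]) == set(gauss_draws.param_names)
        assert report.passed == (len(report.failures) == 0)

    def test_empty_failures_means_proceed(self, rng):
        # contract: an all-pass report exposes `passed` for downstream gating
        draws = hetvar.PosteriorDraws(
            rng.standard_normal((2000, 2)),
            ["a", "b"],
            {"family": "gaussian", "groups": ["g"], "design": None},
        )
        report = convergence_check(draws, ess_threshold=100)
        assert report.passed and report.failures == []


class TestPosteriorDrawsIO:
    def test_save_load_roundtrip(self, tmp_path, gauss_draws):
        gauss_draws.save(tmp_path / "post")
        back = hetvar.PosteriorDraws.load(tmp_path / "post")
        np.testing.assert_allclose(back.draws, gauss_draws.draws)
        assert back.param_names == gauss_draws.param_names
        assert back.design.names == gauss_draws.design.names

    def test_n_kept_matches_contract(self, gauss_draws):
        assert gauss_draws.n_kept == (3600 - 1200) // 2
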