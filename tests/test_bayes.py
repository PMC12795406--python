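import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rolepred.bayes import (
    ConvergenceError,
    RegressionSpec,
    build_design,
    compare_loo_stacking,
    fit_beta_hierarchical,
    fit_stimulus_regression,
    pairwise_language_contrasts,
    simulate_records,
    squeeze_to_open_interval,
)
from rolepred.bayes.glmm import _BetaGLMM
from rolepred.bayes.nuts import run_chains, sample_nuts


class TestSqueeze:
    def test_closed_forms(self):
        assert squeeze_to_open_interval(0.0, 100) == pytest.approx(0.005)
        assert squeeze_to_open_interval(1.0, 100) == pytest.approx(0.995)

    @pytest.mark.parametrize("n", [1, 10, 1000])
    def test_half_is_fixed_point(self, n):
        assert squeeze_to_open_interval(0.5, n) == pytest.approx(0.5)

    def test_strictly_inside(self, rng):
        p = rng.random(100)
        p[:5] = 0.0
        p[5:10] = 1.0
        y = squeeze_to_open_interval(p, 100)
        assert np.all((y > 0) & (y < 1))

    def test_identity_approaching(self):
        assert squeeze_to_open_interval(0.3, 10**6) == pytest.approx(0.3, abs=1e-5)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            squeeze_to_open_interval(0.5, 0)


@pytest.fixture
def records():
    return simulate_records(
        400, {"after_argument": 0.5, "after_verb": 0.5, "role": -0.5}, intercept=0.3,
        phi=15.0, group_sd=0.2, seed=0,
        language_offsets={"lang_a": 0.0, "lang_b": 0.4},
    )


class TestBuildDesign:
    def test_combinatorial_column_count(self, records):
        # full treatment-coded basis: prod(levels) columns for all-subsets terms
        factors = ["after_argument", "after_verb", "role", "language"]
        from itertools import combinations

        terms = [":".join(c) for r in range(1, 5) for c in combinations(factors, r)]
        spec = RegressionSpec(fixed_terms=terms)
        design = build_design(records, spec)
        assert design.X.shape[1] == 2 * 2 * 2 * 2  # all factors binary here

    def test_four_way_only_adds_one_column(self, records):
        base = RegressionSpec(fixed_terms=["after_argument", "after_verb", "role", "language"])
        full = RegressionSpec(
            fixed_terms=["after_argument", "after_verb", "role", "language",
                         "after_argument:after_verb:role:language"]
        )
        d_base = build_design(records, base)
        d_full = build_design(records, full)
        assert d_full.X.shape[1] == d_base.X.shape[1] + 1

    def test_single_level_factor_names_factor(self, records):
        df = records.copy()
        df["role"] = "A"
        with pytest.raises(ValueError, match="role"):
            build_design(df, RegressionSpec(fixed_terms=["role"]))

    def test_dropping_term_removes_its_columns(self, records):
        with_vc = RegressionSpec(fixed_terms=["role", "language"])
        without = RegressionSpec(fixed_terms=["role"])
        d1 = build_design(records, with_vc)
        d2 = build_design(records, without)
        removed = set(d1.colnames) - set(d2.colnames)
        assert removed == {"language[lang_b]"}

    def test_row_for_unseen_level(self, records):
        design = build_design(records, RegressionSpec(fixed_terms=["role", "language"]))
        with pytest.raises(KeyError, match="unseen level"):
            design.row_for({"role": "X", "language": "lang_a"})

    def test_reference_level_override(self, records):
        spec = RegressionSpec(fixed_terms=["role"], reference_levels={"role": "P"})
        design = build_design(records, spec)
        assert "role[A]" in design.colnames

    def test_empty_table_rejected(self, records):
        with pytest.raises(ValueError):
            build_design(records.iloc[:0], RegressionSpec(fixed_terms=["role"]))

    def test_group_structure(self, records):
        spec = RegressionSpec(fixed_terms=["after_argument", "role"],
                              group_slopes=["after_argument", "role"])
        design = build_design(records, spec)
        assert design.Z.shape == (len(records), 3)
        assert design.re_names == ["Intercept", "after_argument[True]", "role[P]"]

    def test_interaction_slope_behind_flag(self, records):
        spec = RegressionSpec(fixed_terms=["after_argument", "role"],
                              group_slopes=["after_argument", "role"],
                              group_interaction_slope=True)
        design = build_design(records, spec)
        assert design.re_names[-1] == "interaction"


class TestNutsSampler:
    def test_gaussian_moments(self):
        sd = np.array([0.5, 1.0, 2.0, 4.0])

        def lg(x):
            return -0.5 * np.sum((x / sd) ** 2), -x / sd**2

        chains = run_chains(lg, lambda r: r.standard_normal(4), 4, chains=2,
                            n_warmup=300, n_draws=500, seed=0)
        draws = np.concatenate([c.draws for c in chains])
        assert np.allclose(draws.mean(axis=0), 0.0, atol=0.25)
        assert np.allclose(draws.std(axis=0), sd, rtol=0.15)

    def test_correlated_gaussian(self):
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        prec = np.linalg.inv(cov)

        def lg(x):
            return -0.5 * x @ prec @ x, -prec @ x

        res = sample_nuts(lg, np.zeros(2), 400, 800, np.random.default_rng(0))
        corr = np.corrcoef(res.draws.T)[0, 1]
        assert corr == pytest.approx(0.9, abs=0.05)

    def test_shared_warmup_reuses_tuning(self):
        def lg(x):
            return -0.5 * np.sum(x**2), -x

        chains = run_chains(lg, lambda r: r.standard_normal(3), 3, chains=3,
                            n_warmup=200, n_draws=100, seed=1, shared_warmup=True)
        assert chains[1].step_size == chains[0].step_size
        assert np.array_equal(chains[1].m_inv, chains[0].m_inv)

    def test_non_finite_start_rejected(self):
        def lg(x):
            return -np.inf, x

        with pytest.raises(ValueError):
            sample_nuts(lg, np.zeros(2), 10, 10, np.random.default_rng(0))


class TestBetaGLMM:
    def test_gradient_matches_numeric(self, records):
        spec = RegressionSpec(fixed_terms=["after_argument", "role"], group_slopes=["role"])
        model = _BetaGLMM(build_design(records, spec), spec)
        rng = np.random.default_rng(3)
        theta = 0.2 * rng.standard_normal(model.dim)
        theta[-1] = np.log(8.0)
        lp0, g0 = model.logp_grad(theta)
        idx = rng.choice(model.dim, size=12, replace=False)
        for i in idx:
            eps = 1e-6
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num = (model.logp_grad(tp)[0] - model.logp_grad(tm)[0]) / (2 * eps)
            assert num == pytest.approx(g0[i], rel=2e-3, abs=1e-4)

    def test_response_outside_open_interval_rejected(self, records):
        spec = RegressionSpec(fixed_terms=["role"], group=None)
        design = build_design(records, spec)
        design.y[0] = 1.0
        with pytest.raises(ValueError, match="strictly inside"):
            _BetaGLMM(design, spec)

    def test_intercept_only_symmetric_data(self, rng):
        # responses centered at 0.5 -> posterior cell mean ~ logit^-1(0) = 0.5
        y = np.clip(rng.beta(10, 10, size=500), 1e-6, 1 - 1e-6)
        df = pd.DataFrame({
            "p_correct": y, "role": rng.choice(["A", "P"], 500),
            "sentence_id": [f"s{i}" for i in range(500)],
        })
        spec = RegressionSpec(fixed_terms=["role"], group=None, chains=2,
                              draws=400, warmup=300, seed=0, check_diagnostics=False)
        fit = fit_beta_hierarchical(build_design(df, spec), spec)
        mean = fit.cell_mean_draws({"role": "A"}).mean()
        assert mean == pytest.approx(0.5, abs=0.02)

    def test_prior_predictive_cell_means_cover(self, rng):
        # direct draw from the spec's priors: Normal(0,1) slopes, wide intercept
        spec = RegressionSpec()
        b0 = rng.normal(0, spec.intercept_prior_sd, 2000)
        b1 = rng.normal(0, spec.slope_prior_sd, 2000)
        cell = expit(b0 + b1)
        assert np.all((cell > 0) & (cell < 1))
        assert cell.min() < 0.05 and cell.max() > 0.95

    def test_diagnostics_gate_raises(self, records):
        spec = RegressionSpec(fixed_terms=["role"], group=None, chains=2,
                              draws=40, warmup=100, seed=0)  # far too few draws for ESS > 400
        with pytest.raises(ConvergenceError) as err:
            fit_beta_hierarchical(build_design(records, spec), spec)
        assert not err.value.report.empty

    def test_phi_prior_recorded(self, records):
        spec = RegressionSpec(fixed_terms=["role"], group=None, chains=2, draws=150,
                              warmup=150, seed=0, phi_prior="exponential",
                              check_diagnostics=False)
        fit = fit_beta_hierarchical(build_design(records, spec), spec)
        assert fit.phi_prior == "exponential"
        with pytest.raises(ValueError):
            RegressionSpec(phi_prior="lognormal")


@pytest.fixture(scope="module")
def two_fits():
    df = simulate_records(
        500, {"after_argument": 0.0, "after_verb": 1.0, "role": 0.6}, intercept=0.3,
        phi=15.0, group_sd=0.0, seed=4,
    )
    fits = []
    for terms in (["after_verb", "role"], ["role"]):
        spec = RegressionSpec(fixed_terms=terms, group=None, chains=2, draws=400,
                              warmup=300, seed=4, check_diagnostics=False)
        fits.append(fit_beta_hierarchical(build_design(df, spec), spec))
    return fits


class TestCompare:
    def test_weights_form_simplex(self, two_fits):
        table = compare_loo_stacking(two_fits, names=["full", "reduced"])
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-8)
        assert (table["weight"] >= 0).all()
        assert "pareto_k_max" in table.columns

    def test_true_model_wins(self, two_fits):
        table = compare_loo_stacking(two_fits, names=["full", "reduced"]).set_index("model")
        assert table.loc["full", "elpd_loo"] > table.loc["reduced", "elpd_loo"]
        assert table.loc["full", "weight"] > table.loc["reduced", "weight"]

    def test_duplicate_models_split_without_error(self, two_fits):
        table = compare_loo_stacking([two_fits[0], two_fits[0]], names=["a", "b"])
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-8)

    def test_mismatched_responses_rejected(self, two_fits):
        df2 = simulate_records(500, {"role": 0.2}, intercept=0.0, phi=15.0, seed=9)
        spec = RegressionSpec(fixed_terms=["role"], group=None, chains=2, draws=150,
                              warmup=150, seed=0, check_diagnostics=False)
        other = fit_beta_hierarchical(build_design(df2, spec), spec)
        with pytest.raises(ValueError, match="identical response"):
            compare_loo_stacking([two_fits[0], other])


@pytest.fixture(scope="module")
def lang_fit():
    df = simulate_records(
        800, {"role": 0.8}, intercept=0.4, phi=15.0, group_sd=0.0, seed=5,
        language_offsets={"lang_a": 0.0, "lang_b": 0.5, "lang_c": -0.3},
    )
    spec = RegressionSpec(fixed_terms=["role", "language"], group=None, chains=2,
                          draws=400, warmup=300, seed=5, check_diagnostics=False)
    return fit_beta_hierarchical(build_design(df, spec), spec)


class TestContrasts:
    def test_antisymmetry(self, lang_fit):
        table = pairwise_language_contrasts(lang_fit, [{"role": "A"}])
        t = table.set_index(["language_1", "language_2"])
        for l1, l2 in [("lang_a", "lang_b"), ("lang_b", "lang_c")]:
            assert t.loc[(l1, l2), "mean_diff"] == pytest.approx(-t.loc[(l2, l1), "mean_diff"])
            assert t.loc[(l1, l2), "p_gt0"] == pytest.approx(1 - t.loc[(l2, l1), "p_gt0"])
            assert bool(t.loc[(l1, l2), "suppressed"]) == bool(t.loc[(l2, l1), "suppressed"])

    def test_real_difference_detected_and_direction(self, lang_fit):
        table = pairwise_language_contrasts(lang_fit, [{"role": "A"}]).set_index(
            ["language_1", "language_2"]
        )
        row = table.loc[("lang_b", "lang_a")]
        assert row["mean_diff"] > 0
        assert not row["suppressed"]

    def test_missing_cell_rejected(self, lang_fit):
        with pytest.raises(KeyError):
            pairwise_language_contrasts(lang_fit, [{"role": "Q"}])


class TestPlot:
    def test_interval_plot_written(self, lang_fit, tmp_path):
        from rolepred.bayes.plots import plot_cell_means

        cells = [{"role": r, "language": l}
                 for r in ("A", "P") for l in ("lang_a", "lang_b", "lang_c")]
        cm = lang_fit.cell_means(cells)
        out = tmp_path / "cells.png"
        plot_cell_means(cm, out)
        assert out.stat().st_size > 0


class TestStimulusRegression:
    def test_condition_effect_fit(self):
        rng = np.random.default_rng(6)
        n_items, conds = 8, ["active", "passive"]
        rows = []
        for i in range(n_items):
            for c in conds:
                for role in ("A", "P"):
                    mu = 0.9 if c == "active" else 0.15
                    rows.append({
                        "sentence_id": f"item{i:03d}|{c}",
                        "language": "toy", "role": role,
                        "after_argument": None, "after_verb": None,
                        "nominality": "OTHER", "verb_class": "motion",
                        "p_correct": np.clip(rng.beta(mu * 25, (1 - mu) * 25), 1e-6, 1 - 1e-6),
                        "cond_voice": c,
                    })
        df = pd.DataFrame(rows)
        base = RegressionSpec(chains=2, draws=300, warmup=300, seed=6, check_diagnostics=False)
        fit = fit_stimulus_regression(df, ["voice"], spec=base)
        active = fit.cell_mean_draws({"role": "A", "cond_voice": "active"}).mean()
        passive = fit.cell_mean_draws({"role": "A", "cond_voice": "passive"}).mean()
        assert active > 0.75 and passive < 0.35

    def test_null_condition_effect_ci_covers_zero(self):
        # balanced null: no condition effect; its 95% CI should cover 0 in
        # nearly all replicates (binomial tolerance at 10 seeds)
        covered = 0
        for seed in range(10):
            df = simulate_records(300, {"after_verb": 0.0, "role": 0.4}, intercept=0.2,
                                  phi=15.0, group_sd=0.0, seed=200 + seed)
            spec = RegressionSpec(fixed_terms=["after_verb", "role"], group=None, chains=2,
                                  draws=300, warmup=250, seed=200 + seed,
                                  check_diagnostics=False)
            fit = fit_beta_hierarchical(build_design(df, spec), spec)
            fe = fit.fixed_effects().set_index("term")
            if fe.loc["after_verb[True]", "q2.5"] <= 0.0 <= fe.loc["after_verb[True]", "q97.5"]:
                covered += 1
        assert covered >= 8

    def test_single_item_warns_and_fits_fixed_only(self):
        rng = np.random.default_rng(7)
        rows = [{
            "sentence_id": "item000|a", "language": "toy", "role": r,
            "after_argument": None, "after_verb": None, "nominality": "OTHER",
            "verb_class": "motion",
            "p_correct": float(np.clip(rng.beta(5, 5), 1e-6, 1 - 1e-6)),
            "cond_voice": c,
        } for r in ("A", "P") for c in ("active", "passive") for _ in range(10)]
        df = pd.DataFrame(rows)
        base = RegressionSpec(chains=2, draws=150, warmup=150, seed=7, check_diagnostics=False)
        with pytest.warns(UserWarning, match="single stimulus item"):
            fit = fit_stimulus_regression(df, ["voice"], spec=base)
        assert fit.design.group_codes is None
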