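import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from pulsediv import GeneratorConfig, fit_mixed_model, generate_dataset, rank_correlation


def make_table(rng, n_groups=20, reps=1, beta=(0.5, 1.0, 0.0, 0.0),
               tau=0.0, sigma=0.0):
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, tau) if tau > 0 else 0.0
        for _ in range(reps):
            x = rng.normal(size=3)
            y = beta[0] + beta[1] * x[0] + beta[2] * x[1] + beta[3] * x[2] + u
            if sigma > 0:
                y += rng.normal(0, sigma)
            rows.append(
                dict(experiment_id=f"g{g}", mean_response=x[0],
                     dissimilarity=x[1], divergence=x[2], oev=y)
            )
    return pd.DataFrame(rows)


def per_experiment_truth(truth):
    per = truth.drop_duplicates("experiment_id")
    return per.rename(columns={"true_mean_response": "mean_response"})[
        ["experiment_id", "mean_response", "true_oev"]
    ]


class TestFitMixedModel:
    def test_noise_free_data_recovered_exactly(self, rng):
        table = make_table(rng, beta=(0.5, 1.0, 0.0, 0.0))
        fit = fit_mixed_model(table)
        params = fit.params()
        assert params["intercept"] == pytest.approx(0.5, abs=1e-8)
        assert params["mean_response"] == pytest.approx(1.0, abs=1e-8)
        assert params["dissimilarity"] == pytest.approx(0.0, abs=1e-8)
        assert params["divergence"] == pytest.approx(0.0, abs=1e-8)

    def test_zero_group_variance_matches_ols(self, rng):
        statsmodels = pytest.importorskip("statsmodels.api")
        table = make_table(rng, n_groups=60, reps=1, sigma=0.4)
        fit = fit_mixed_model(table)
        X = statsmodels.add_constant(
            table[["mean_response", "dissimilarity", "divergence"]]
        )
        ols = statsmodels.OLS(table["oev"], X).fit()
        for name, ols_name in [
            ("intercept", "const"), ("mean_response", "mean_response"),
            ("dissimilarity", "dissimilarity"), ("divergence", "divergence"),
        ]:
            assert fit.params()[name] == pytest.approx(ols.params[ols_name], abs=1e-6)

    def test_invariant_to_row_order_and_group_labels(self, rng):
        table = make_table(rng, n_groups=12, reps=3, tau=0.5, sigma=0.8)
        fit1 = fit_mixed_model(table)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["experiment_id"] = shuffled["experiment_id"].map(
            lambda g: f"relabeled-{g}"
        )
        fit2 = fit_mixed_model(shuffled)
        # summation order differs after the shuffle, so agreement is to
        # optimizer precision rather than bitwise
        assert fit1.tau2 == pytest.approx(fit2.tau2, rel=1e-4, abs=1e-6)
        for k in fit1.params():
            assert fit1.params()[k] == pytest.approx(fit2.params()[k], rel=1e-6)

    def test_moderator_rescaling_rescales_coefficient(self, rng):
        table = make_table(rng, n_groups=12, reps=3, tau=0.5, sigma=0.8)
        fit1 = fit_mixed_model(table)
        scaled = table.assign(mean_response=table["mean_response"] * 10.0)
        fit2 = fit_mixed_model(scaled)
        assert fit2.params()["mean_response"] == pytest.approx(
            fit1.params()["mean_response"] / 10.0, rel=1e-6
        )

    def test_rank_deficient_moderators_rejected(self, rng):
        table = make_table(rng, sigma=0.3)
        table["divergence"] = 2.0 * table["dissimilarity"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_mixed_model(table)

    def test_missing_values_rejected(self, rng):
        table = make_table(rng, sigma=0.3)
        table.loc[0, "dissimilarity"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_mixed_model(table)

    def test_reml_matches_metafor_oracle(self, rng, tmp_path):
        """Independent cross-check of the unit-variance random-intercept REML
        fit against R's metafor (rma.mv with V = 1)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        table = make_table(rng, n_groups=8, reps=3, tau=0.6, sigma=1.0)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(metafor))
            d <- read.csv("{csv}")
            fit <- rma.mv(yi = oev, V = 1,
                          mods = ~ mean_response + dissimilarity + divergence,
                          random = ~ 1 | experiment_id, data = d, method = "REML")
            cat(fit$sigma2, coef(fit), fit$se, sep = "\\n")
        """))
        proc = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        if proc.returncode != 0:  # e.g. metafor missing from the R library
            pytest.skip(f"metafor oracle unavailable: {proc.stderr[-200:]}")
        vals = [float(v) for v in proc.stdout.split()]
        tau2_r, beta_r, se_r = vals[0], vals[1:5], vals[5:9]
        fit = fit_mixed_model(table)
        names = ["intercept", "mean_response", "dissimilarity", "divergence"]
        assert fit.tau2 == pytest.approx(tau2_r, abs=1e-5)
        for name, b, s in zip(names, beta_r, se_r):
            assert fit.coefficients[name].estimate == pytest.approx(b, abs=1e-5)
            assert fit.coefficients[name].se == pytest.approx(s, abs=1e-5)

    def test_null_slope_ci_covers_zero(self):
        exps, truth = generate_dataset(
            GeneratorConfig(n_experiments=200, beta1=0.0, seed=1)
        )
        fit = fit_mixed_model(
            per_experiment_truth(truth),
            response="true_oev",
            moderators=("mean_response",),
        )
        lo, hi = fit.confint()["mean_response"]
        assert lo <= 0.0 <= hi

    def test_embedded_slope_coverage(self):
        """95% CI for the embedded instability-vs-mean-response slope covers
        the generator's true value in at least 90% of seeds."""
        n_seeds, covered = 100, 0
        for seed in range(n_seeds):
            exps, truth = generate_dataset(
                GeneratorConfig(n_experiments=200, beta1=0.9, seed=seed)
            )
            fit = fit_mixed_model(
                per_experiment_truth(truth),
                response="true_oev",
                moderators=("mean_response",),
            )
            lo, hi = fit.confint()["mean_response"]
            covered += lo <= 0.9 <= hi
        assert covered >= 0.9 * n_seeds


class TestRankCorrelation:
    def test_monotone_extremes(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        assert rank_correlation(x, np.exp(x)) == pytest.approx(1.0)
        assert rank_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        assert rank_correlation([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            rank_correlation([1, 2], [1, 2])
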