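import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from whistlechain.trends import (fit_all_trends, fit_generation_trend,
                                 fit_interaction_trend,
                                 fit_random_intercept_lmm)
from oracles import ols_slope


def chain_table(rng, n_chains=4, n_gens=10, slope=0.3, chain_sd=1.0,
                noise_sd=0.5, measure="m"):
    rows = []
    for c in range(n_chains):
        offset = rng.normal(0, chain_sd)
        for g in range(1, n_gens + 1):
            rows.append({"chain_id": f"chain{c}", "generation": g,
                         "measure": measure,
                         "value": 1.0 + slope * g + offset
                         + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestGenerationTrend:
    def test_single_chain_perfect_line_uses_ols(self):
        table = pd.DataFrame({"chain_id": "c1", "generation": range(1, 9),
                              "measure": "m",
                              "value": [0.5 * g for g in range(1, 9)]})
        fit = fit_generation_trend(table, "m")
        assert fit.method == "ols"
        assert fit.slope == pytest.approx(0.5, abs=1e-10)

    def test_two_offset_chains_recover_slope_and_variance(self):
        rows = []
        for c, offset in (("a", 0.0), ("b", 5.0)):
            for g in range(1, 11):
                rows.append({"chain_id": c, "generation": g, "measure": "m",
                             "value": 0.5 * g + offset})
        fit = fit_generation_trend(pd.DataFrame(rows), "m")
        assert fit.method == "lmm"
        assert fit.slope == pytest.approx(0.5, abs=1e-8)
        # chain offsets dominate: between-chain variance dwarfs the residual
        assert fit.random_intercept_variance > 1e3 * fit.residual_variance

    def test_slope_equivariance(self, rng):
        table = chain_table(rng)
        shifted = table.copy()
        shifted["value"] = shifted["value"] + 0.7 * shifted["generation"]
        f0 = fit_generation_trend(table, "m")
        f1 = fit_generation_trend(shifted, "m")
        assert f1.slope - f0.slope == pytest.approx(0.7, abs=1e-6)
        assert f1.sem == pytest.approx(f0.sem, rel=1e-5)

    def test_boundary_tau_zero_matches_ols(self, rng):
        # residuals centred within every chain: between-chain variance is
        # below its expectation, so REML lands on the tau^2 = 0 boundary and
        # the GLS fit collapses to ordinary least squares
        table = chain_table(rng, chain_sd=0.0)
        resid = table["value"] - 0.3 * table["generation"]
        table["value"] -= resid.groupby(table["chain_id"]).transform("mean")
        fit = fit_generation_trend(table, "m")
        assert fit.random_intercept_variance == pytest.approx(0.0, abs=1e-10)
        slope, sem = ols_slope(table["generation"], table["value"])
        assert fit.slope == pytest.approx(slope, abs=1e-8)
        assert fit.sem == pytest.approx(sem, rel=1e-6)

    def test_zero_variance_degenerate(self):
        table = pd.DataFrame({"chain_id": ["a"] * 5 + ["b"] * 5,
                              "generation": list(range(1, 6)) * 2,
                              "measure": "m", "value": 3.0})
        fit = fit_generation_trend(table, "m")
        assert fit.degenerate and fit.slope == 0.0

    def test_missing_measure_raises(self, rng):
        with pytest.raises(KeyError):
            fit_generation_trend(chain_table(rng), "nope")


class TestAgainstStatsmodels:
    def test_lmm_matches_statsmodels_reml(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        table = chain_table(rng, n_chains=5, n_gens=8)
        X = np.column_stack([np.ones(len(table)),
                             table["generation"].to_numpy(float)])
        res = fit_random_intercept_lmm(X, table["value"].to_numpy(float),
                                       table["chain_id"].to_numpy())
        md = sm.MixedLM(table["value"].to_numpy(float), X,
                        groups=table["chain_id"].to_numpy())
        mf = md.fit(reml=True, method="lbfgs")
        assert res.beta == pytest.approx(mf.fe_params, rel=1e-5)
        assert np.sqrt(np.diag(res.cov_beta)) == pytest.approx(
            mf.bse_fe, rel=1e-4)
        assert res.sigma2 == pytest.approx(mf.scale, rel=1e-4)
        assert res.tau2 == pytest.approx(float(np.asarray(mf.cov_re)[0, 0]),
                                         rel=1e-3)

    def test_interaction_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        table = chain_table(rng, n_chains=4, n_gens=10)
        table["dataset"] = np.tile(["actual", "shuffled"], len(table) // 2)
        table.loc[table["dataset"] == "shuffled", "value"] += 2.0
        fits = fit_interaction_trend(table, "m")
        gen = table["generation"].to_numpy(float)
        d = (table["dataset"] == "shuffled").to_numpy(float)
        X = np.column_stack([np.ones(len(table)), gen, d, gen * d])
        mf = sm.MixedLM(table["value"].to_numpy(float), X,
                        groups=table["chain_id"].to_numpy()).fit(reml=True)
        assert fits["generation"].slope == pytest.approx(mf.fe_params[1],
                                                         rel=1e-4)
        assert fits["dataset"].slope == pytest.approx(mf.fe_params[2],
                                                      rel=1e-4)
        assert fits["generation:dataset"].slope == pytest.approx(
            mf.fe_params[3], abs=1e-5)


R_SCRIPT = """
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
m <- lmer(value ~ generation + (1 | chain_id), data = d, REML = TRUE)
co <- summary(m)$coefficients["generation", ]
cat(sprintf("%.10f %.10f %.6f %.10g\\n",
            co["Estimate"], co["Std. Error"], co["df"], co["Pr(>|t|)"]))
"""


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not installed")
class TestAgainstLmerTest:
    def test_slope_sem_df_p_match_lmertest(self, rng, tmp_path):
        table = chain_table(rng, n_chains=4, n_gens=10)
        csv = tmp_path / "d.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(R_SCRIPT.format(csv=csv))
        proc = subprocess.run(["Rscript", "--vanilla", str(script)],
                              capture_output=True, text=True, timeout=300)
        if proc.returncode != 0 and "there is no package" in proc.stderr:
            pytest.skip("lmerTest not installed")
        assert proc.returncode == 0, proc.stderr
        b, se, df, p = map(float, proc.stdout.split())
        fit = fit_generation_trend(table, "m")
        assert fit.slope == pytest.approx(b, rel=1e-5)
        assert fit.sem == pytest.approx(se, rel=1e-4)
        assert fit.df == pytest.approx(df, rel=1e-3)
        assert fit.p_value == pytest.approx(p, rel=1e-3)


class TestInteractionTrend:
    def test_planted_dataset_shift_recovered(self, rng):
        table = chain_table(rng, n_chains=4, n_gens=10, noise_sd=0.4)
        shifted = table.copy()
        shifted["value"] += 2.3
        table["dataset"] = "actual"
        shifted["dataset"] = "shuffled"
        full = pd.concat([table, shifted], ignore_index=True)
        fits = fit_interaction_trend(full, "m")
        eff = fits["dataset"]
        assert abs(eff.slope - 2.3) <= 2 * eff.sem + 1e-9
        inter = fits["generation:dataset"]
        assert abs(inter.slope) <= 2 * inter.sem + 1e-9

    def test_identical_datasets_null_effect(self, rng):
        table = chain_table(rng)
        a, b = table.copy(), table.copy()
        a["dataset"], b["dataset"] = "actual", "shuffled"
        b["value"] += rng.normal(0, 1e-3, len(b))
        fits = fit_interaction_trend(pd.concat([a, b], ignore_index=True), "m")
        assert abs(fits["dataset"].slope) < 0.01
        assert fits["dataset"].p_value > 0.05

    def test_nonbinary_dataset_rejected(self, rng):
        table = chain_table(rng)
        table["dataset"] = "only_one"
        with pytest.raises(ValueError, match="binary"):
            fit_interaction_trend(table, "m")


class TestFitAllTrends:
    def test_one_row_per_measure_and_skip_warning(self, rng):
        t1 = chain_table(rng, measure="alpha")
        t2 = chain_table(rng, measure="beta", slope=-0.2)
        t3 = chain_table(rng, n_gens=2, measure="short")
        table = pd.concat([t1, t2, t3], ignore_index=True)
        with pytest.warns(UserWarning, match="short"):
            out = fit_all_trends(table, min_generations=3)
        assert sorted(out["measure"]) == ["alpha", "beta"]
        assert {"b", "sem", "df", "t", "p"} <= set(out.columns)
        beta = out[out["measure"] == "beta"].iloc[0]
        assert beta["b"] == pytest.approx(-0.2, abs=3 * beta["sem"])

    def test_interaction_measures_get_three_terms(self, rng):
        table = chain_table(rng)
        a, b = table.copy(), table.copy()
        a["dataset"], b["dataset"] = "actual", "shuffled"
        b["value"] += 1.0
        full = pd.concat([a, b], ignore_index=True)
        out = fit_all_trends(full, interaction_measures=("m",))
        assert sorted(out["term"]) == ["dataset", "generation",
                                       "generation:dataset"]
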