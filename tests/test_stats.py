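"""Model-comparison ladder, pseudo-R^2, GLMM backends, adjusted alpha."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from gespeech import stats as st
from gespeech.stats import (
    MixedGLM,
    RandomStructure,
    adjusted_alpha,
    build_random_effects,
    kinetic_confound_test,
    ladder_test,
    modality_interaction_ladder,
    ordinal_space_test,
    orthogonal_poly,
    pseudo_r2,
)
from gespeech.synthetic_data import (
    GeneratorConfig,
    simulate_acoustic_study,
    simulate_feature_table,
)

HAVE_RSCRIPT = shutil.which("Rscript") is not None


class TestAdjustedAlpha:
    def test_worked_values(self):
        assert adjusted_alpha(6, 0.283) == 0.014
        assert adjusted_alpha(2, 0.002) == 0.025

    def test_single_test_unchanged(self):
        assert adjusted_alpha(1, 0.0) == 0.05
        assert adjusted_alpha(1, 0.9) == 0.05

    def test_perfect_correlation_no_correction(self):
        assert adjusted_alpha(8, 1.0) == 0.05

    def test_monotone_in_k_and_rbar(self):
        ks = [2, 4, 8, 16]
        vals = [0.05 / k ** (1 - 0.3) for k in ks]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        rs = [0.0, 0.25, 0.5, 0.75]
        vals = [0.05 / 6 ** (1 - r) for r in rs]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_rbar_rejected(self):
        with pytest.raises(ValueError):
            adjusted_alpha(3, 1.2)
        with pytest.raises(ValueError):
            adjusted_alpha(3, -0.1)


class TestOrthogonalPoly:
    def test_orthonormal_zero_mean(self):
        P = orthogonal_poly(np.repeat(np.arange(1, 11), 7), 2)
        np.testing.assert_allclose(P.T @ P, np.eye(2), atol=1e-10)
        np.testing.assert_allclose(P.mean(axis=0), 0.0, atol=1e-12)

    def test_quadratic_column_is_u_shaped(self):
        P = orthogonal_poly(np.arange(1, 11), 2)
        # ends high, middle low (or could be flipped; fix sign by convention)
        assert P[0, 1] > 0 and P[-1, 1] > 0 and P[4, 1] < 0

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            orthogonal_poly(np.ones(10), 2)


class TestPseudoR2:
    class _F:
        def __init__(self, llf):
            self.llf = llf

    def test_null_vs_itself_zero(self):
        f = self._F(-100.0)
        r2c, d, r2lr = pseudo_r2(f, f, 50, (0.0, 1.0, 1.0), (0.0, 1.0, 1.0))
        assert d == 0.0 and r2lr == 0.0

    def test_closed_form_r2lr(self):
        full, null = self._F(-95.0), self._F(-100.0)  # LR = 10
        _, _, r2lr = pseudo_r2(full, null, 100)
        assert r2lr == pytest.approx(1 - np.exp(-0.1))

    def test_variance_share_recovery(self, rng):
        """Simulated mixed data with known variance shares: fitted r2c
        within +-0.05 of the generating ratio."""
        rows = []
        for p in range(30):
            b = rng.normal(0, 1.0)  # var_r = 1
            for g in range(1, 11):
                u = (g - 5.5) / 4.5
                rows.append({"participant": f"p{p}", "dyad": f"d{p // 2}",
                             "grade": g, "y": 2.0 * u + b + rng.normal(0, 1.0)})
        df = pd.DataFrame(rows)
        res = ladder_test(df, "y", family="gaussian",
                          structure=RandomStructure(kind="global"))
        var_f = np.var(2.0 * ((np.arange(1, 11) - 5.5) / 4.5))
        truth = (var_f + 1.0) / (var_f + 1.0 + 1.0)
        assert res.r2c == pytest.approx(truth, abs=0.05)


class TestGaussianLadder:
    def test_quadratic_truth_detected(self, rng):
        cfg = GeneratorConfig(n_dyads=10, seed=21)
        ft = simulate_feature_table(cfg)
        ft["log_size"] = np.log(ft["size"])
        res = ladder_test(ft, "log_size", family="gaussian")
        assert res.significant
        assert res.p < 1e-6 and res.p_vs_linear < 1e-6
        assert res.coefficients["bg2"][0] < 0  # inverted U

    def test_linear_truth_quadratic_step_not_triggered(self, rng):
        rows = []
        for p in range(16):
            b = rng.normal(0, 0.5)
            for g in range(1, 11):
                for _ in range(3):
                    rows.append({"participant": f"p{p}", "dyad": f"d{p // 2}",
                                 "grade": g,
                                 "y": 0.3 * g + b + rng.normal(0, 1.0)})
        res = ladder_test(pd.DataFrame(rows), "y", family="gaussian")
        assert res.p < 0.001             # blur effect present
        assert res.p_vs_linear > 0.05    # but not quadratic
        assert not res.significant

    @pytest.mark.skipif(not HAVE_RSCRIPT, reason="Rscript unavailable")
    def test_matches_lme4_oracle(self, tmp_path):
        """Independent oracle: lme4 ML fits reproduce the LRT chi-square
        and the quadratic coefficient."""
        cfg = GeneratorConfig(n_dyads=6, seed=9)
        ft = simulate_feature_table(cfg)
        ft["log_size"] = np.log(ft["size"])
        res = ladder_test(ft, "log_size", family="gaussian")
        data = st._prepare(ft)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            f"""suppressMessages(library(lme4))
d <- read.csv('{csv}')
m0 <- lmer(log_size ~ 1 + (1|dyad/participant), data=d, REML=FALSE)
m2 <- lmer(log_size ~ bg1 + bg2 + (1|dyad/participant), data=d, REML=FALSE)
cat(as.numeric(2*(logLik(m2)-logLik(m0))), fixef(m2)['bg2'], sep='\\n')
"""
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        chi2_r, bg2_r = (float(x) for x in out.stdout.strip().split("\n"))
        assert res.chi_square == pytest.approx(chi2_r, rel=0.01, abs=0.05)
        assert res.coefficients["bg2"][0] == pytest.approx(bg2_r, rel=0.01)


class TestMixedGLM:
    def test_poisson_rate_recovery(self, rng):
        beta0, beta1, sd = np.log(3.0), 0.5, 0.4
        rows, bs = [], []
        for p in range(40):
            b = rng.normal(0, sd)
            bs.append(b)
            x = rng.uniform(-1, 1, 25)
            lam = np.exp(beta0 + beta1 * x + b)
            for xi, yi in zip(x, rng.poisson(lam)):
                rows.append({"participant": f"p{p}", "x": xi, "y": yi})
        df = pd.DataFrame(rows)
        X = np.column_stack([np.ones(len(df)), df.x])
        fit = MixedGLM(df.y, X, df.participant, "poisson",
                       ["Intercept", "x"]).fit()
        assert fit.fe_params["x"] == pytest.approx(beta1, abs=0.05)
        # the intercept absorbs the realised random-effect sample mean
        assert fit.fe_params["Intercept"] == pytest.approx(
            beta0 + np.mean(bs), abs=0.15
        )
        assert fit.re_sd == pytest.approx(sd, abs=0.12)

    def test_gamma_shape_and_slope_recovery(self, rng):
        alpha, beta1 = 4.0, 0.8
        rows = []
        for p in range(30):
            b = rng.normal(0, 0.3)
            x = rng.uniform(-1, 1, 30)
            mu = np.exp(1.0 + beta1 * x + b)
            y = rng.gamma(alpha, mu / alpha)
            rows.extend({"participant": f"p{p}", "x": xi, "y": yi}
                        for xi, yi in zip(x, y))
        df = pd.DataFrame(rows)
        X = np.column_stack([np.ones(len(df)), df.x])
        fit = MixedGLM(df.y, X, df.participant, "gamma_log",
                       ["Intercept", "x"]).fit()
        assert fit.fe_params["x"] == pytest.approx(beta1, abs=0.06)
        assert np.exp(fit.extra[0]) == pytest.approx(alpha, rel=0.2)

    @pytest.mark.skipif(not HAVE_RSCRIPT, reason="Rscript unavailable")
    def test_gamma_ladder_matches_glmmTMB(self, tmp_path):
        cfg = GeneratorConfig(n_dyads=6, seed=9)
        ft = simulate_feature_table(cfg)
        res = ladder_test(ft, "size", family="gamma_log")
        data = st._prepare(ft)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "m.R"
        script.write_text(
            f"""suppressMessages(library(glmmTMB))
d <- read.csv('{csv}')
g0 <- glmmTMB(size ~ 1 + (1|participant), data=d, family=Gamma(link='log'))
g2 <- glmmTMB(size ~ bg1 + bg2 + (1|participant), data=d, family=Gamma(link='log'))
cat(as.numeric(2*(logLik(g2)-logLik(g0))), fixef(g2)$cond['bg2'], sep='\\n')
"""
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        chi2_r, bg2_r = (float(x) for x in out.stdout.strip().split("\n"))
        # different integration schemes (adaptive GH here, Laplace there)
        assert res.chi_square == pytest.approx(chi2_r, rel=0.10)
        assert res.coefficients["bg2"][0] == pytest.approx(bg2_r, rel=0.05)


class TestRandomEffects:
    def test_gesture_type_variance_retained(self):
        cfg = GeneratorConfig(n_dyads=8, gesture_type_sd=0.5, seed=3)
        ft = simulate_feature_table(cfg)
        ft["log_size"] = np.log(ft["size"])
        s = build_random_effects(ft, "log_size")
        assert s.gesture_type

    def test_zero_variance_keeps_simpler_structure(self):
        cfg = GeneratorConfig(n_dyads=8, gesture_type_sd=0.0, seed=3)
        ft = simulate_feature_table(cfg)
        ft["log_size"] = np.log(ft["size"])
        s = build_random_effects(ft, "log_size")
        assert not s.gesture_type

    def test_degenerate_grouping_falls_back(self, rng):
        """No dyad/participant variance at all: nested fit is singular and
        the builder falls back to (or flags) a simpler structure."""
        rows = [
            {"participant": f"p{i % 6}", "dyad": f"d{i % 3}", "grade": g,
             "gesture_type": "pragmatic", "y": rng.normal(0, 1)}
            for i in range(60) for g in range(1, 6)
        ]
        s = build_random_effects(pd.DataFrame(rows), "y")
        assert s.kind in ("nested", "global")
        assert not s.gesture_type

    def test_too_few_participants_rejected(self):
        df = pd.DataFrame({"participant": ["a"] * 10, "dyad": ["d"] * 10,
                           "grade": list(range(1, 11)), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="participants"):
            build_random_effects(df, "y")


class TestModalityLadder:
    def test_offset_and_interaction_recovered(self):
        cfg = GeneratorConfig(n_dyads=8, seed=4)
        tab = simulate_acoustic_study(cfg)
        lad = modality_interaction_ladder(tab, "mean_intensity_db")
        assert lad["steps"][0].significant          # modality main effect
        assert lad["modality_coefficient"] == pytest.approx(
            cfg.modality_intensity_offset_db, abs=0.4
        )

    def test_pitch_offset_without_blur_effect(self):
        cfg = GeneratorConfig(n_dyads=8, seed=4)
        tab = simulate_acoustic_study(cfg)
        lad = modality_interaction_ladder(tab, "mean_f0_hz")
        assert lad["steps"][0].significant
        assert not lad["steps"][1].significant      # no blur effect on F0
        assert lad["modality_coefficient"] == pytest.approx(
            cfg.modality_f0_offset_hz, abs=0.9
        )


class TestKineticConfound:
    def _table(self, rng, couple=False):
        rows = []
        for p in range(16):
            b = rng.normal(0, 1.0)
            for g in range(1, 11):
                vel = rng.gamma(4.0, 100.0)
                y = 60.0 + b + rng.normal(0, 1.0)
                if couple:
                    y = y + 0.01 * vel
                rows.append({"participant": f"p{p}", "dyad": f"d{p // 2}",
                             "grade": g, "mean_intensity_db": y,
                             "peak_velocity": vel})
        return pd.DataFrame(rows)

    def test_independent_kinetics_not_significant(self, rng):
        res = kinetic_confound_test(self._table(rng), "peak_velocity")
        assert res.p > 0.01

    def test_velocity_driven_intensity_detected(self, rng):
        res = kinetic_confound_test(self._table(rng, couple=True),
                                    "peak_velocity")
        assert res.significant

    def test_constant_covariate_rejected(self, rng):
        tab = self._table(rng)
        tab["peak_velocity"] = 5.0
        with pytest.raises(ValueError, match="constant"):
            kinetic_confound_test(tab, "peak_velocity")


class TestOrdinal:
    @staticmethod
    def _space_table(rng, effect=2.4, sd=0.5, n_participants=12, per_cell=6):
        cats = ["centre-centre", "centre", "periphery", "extra-periphery"]
        rows = []
        for p in range(n_participants):
            b = rng.normal(0, sd)
            for g in range(1, 11):
                u = (g - 5.5) / 4.5
                eta = effect * (1 - u**2) + b
                for _ in range(per_cell):
                    latent = eta + rng.logistic()
                    y = int(np.digitize(latent, [0.5, 1.5, 2.5]))
                    rows.append({"participant": f"p{p}", "dyad": f"d{p // 2}",
                                 "grade": g, "mcneillian_space": cats[y]})
        return pd.DataFrame(rows)

    def test_grade_shift_detected(self, rng):
        res = ordinal_space_test(self._space_table(rng))
        assert res.significant
        assert res.family == "ordinal_cumulative"

    def test_uniform_categories_not_significant(self, rng):
        res = ordinal_space_test(self._space_table(rng, effect=0.0))
        assert res.p > 0.01

    def test_missing_category_merged_with_warning(self, rng):
        tab = self._space_table(rng)
        tab = tab[tab.mcneillian_space != "extra-periphery"]
        with pytest.warns(UserWarning, match="unobserved"):
            res = ordinal_space_test(tab)
        assert np.isfinite(res.chi_square)

    def test_two_category_case_matches_logistic_oracle(self, rng):
        """With two categories and ~zero grouping variance the cumulative
        model reduces to logistic regression (statsmodels Logit oracle)."""
        import statsmodels.api as sm

        rows = []
        for p in range(10):
            for g in range(1, 11):
                u = (g - 5.5) / 4.5
                eta = 1.5 * u
                for _ in range(8):
                    y = "periphery" if rng.logistic() < eta else "centre"
                    rows.append({"participant": f"p{p}", "dyad": f"d{p // 2}",
                                 "grade": g, "mcneillian_space": y})
        tab = pd.DataFrame(rows)
        with pytest.warns(UserWarning):
            res = ordinal_space_test(tab)
        data = st._prepare(tab)
        # cumulative-link convention: positive effect pushes *up* the scale
        ybin = (data["mcneillian_space"] == "periphery").astype(float)
        X = sm.add_constant(data[["bg1", "bg2"]].to_numpy())
        oracle = np.asarray(sm.Logit(ybin, X).fit(disp=0).params)
        assert res.coefficients["bg1"][0] == pytest.approx(
            oracle[1], abs=0.15 * abs(oracle[1]) + 0.05
        )


def test_type_one_error_quick_sample(rng):
    """Small null-resimulation sample: the quadratic-vs-null LRT rejects
    at roughly the nominal rate (full 500-run calibration lives in the
    acceptance suite)."""
    rej = 0
    n_sim = 60
    for _ in range(n_sim):
        rows = []
        for d in range(5):
            for m in range(2):
                b = rng.normal(0, 0.3) + rng.normal(0, 0.3)
                rows.extend(
                    {"participant": f"d{d}p{m}", "dyad": f"d{d}", "grade": g,
                     "y": b + rng.normal(0, 1)}
                    for g in range(1, 11) for _ in range(2)
                )
        res = ladder_test(pd.DataFrame(rows), "y", family="gaussian")
        rej += bool(res.p < 0.05)
    assert 0.005 <= rej / n_sim <= 0.15
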