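"""Polynomial mixed-model comparison ladder and multiplicity correction.

Each response is modelled against an orthogonal second-order polynomial
of blur grade with random effects for dyad/participant (nested) or a
global participant factor, optionally a gesture-type intercept.  Model
steps are compared by maximum-likelihood likelihood-ratio tests: the
quadratic model must beat both the random-effects-only null *and* the
linear-only model to count as a quadratic blur effect.  Explained
variance is reported as conditional R^2 (fixed + random variance over
total), its increment over the null, and the likelihood-ratio R^2
``1 - exp(-LR/n)``.

Families: Gaussian responses use ML linear mixed models (statsmodels
MixedLM).  Poisson, Gamma(log) and cumulative-link ordinal responses use
a native mixed GLM with a single participant random intercept,
integrated by Gauss-Hermite quadrature — the same fallback structure the
Gaussian path switches to when the nested fit is singular.

The multiplicity correction is the correlation-adjusted Bonferroni level
``alpha / k^(1 - r_bar)`` for a family of ``k`` tests with mean pairwise
correlation ``r_bar``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

DEFAULT_ALPHA = 0.05

FAMILIES = ("gaussian", "poisson", "gamma_log", "ordinal_cumulative")

#: family fixed by the response, following the reported model choices
RESPONSE_FAMILY = {
    "submovements": "poisson",
    "peak_velocity": "gamma_log",
    "depth": "gamma_log",
    "size": "gamma_log",
    "npvi": "gamma_log",
    "hold_time": "gamma_log",
    "mcneillian_space": "ordinal_cumulative",
}


# ---------------------------------------------------------------------------
# basics
# ---------------------------------------------------------------------------


def orthogonal_poly(x, degree: int = 2) -> np.ndarray:
    """Orthonormal polynomial basis of ``x`` (R ``poly()`` convention).

    Returns columns 1..degree (the intercept column is dropped), each with
    unit norm and zero mean, pairwise orthogonal over the supplied values.
    """
    x = np.asarray(x, dtype=float)
    if degree < 1:
        return np.empty((x.size, 0))
    if np.ptp(x) == 0:
        raise ValueError("cannot build polynomial contrasts of a constant")
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))
    return Q[:, 1:]


def adjusted_alpha(k: int, r_bar: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Correlation-adjusted Bonferroni level ``alpha / k^(1 - r_bar)``.

    Accounts for both the number of tests in a family and their mean
    pairwise correlation: independent tests (r_bar = 0) recover the plain
    Bonferroni division, perfectly correlated tests (r_bar = 1) need no
    correction.  Rounded to 3 decimals for reporting.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0.0 <= r_bar <= 1.0:
        raise ValueError(f"mean correlation {r_bar} outside [0, 1]")
    return round(alpha / k ** (1.0 - r_bar), 3)


@dataclass
class RandomStructure:
    """Chosen random-effects structure."""

    kind: str = "nested"            # "nested" (dyad/participant) | "global"
    gesture_type: bool = False
    slopes: bool = False
    singular: bool = False
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ModelComparisonResult:
    """One ladder step: LRT statistic, coefficients and pseudo-R^2."""

    label: str
    chi_square: float
    df: int
    p: float
    coefficients: dict            # name -> (beta, se, stat)
    r2c: float = np.nan
    delta_r2c: float = np.nan
    r2lr: float = np.nan
    converged: bool = True
    singular: bool = False
    significant: bool | None = None
    chi_square_vs_linear: float = np.nan
    df_vs_linear: int = 0
    p_vs_linear: float = np.nan
    family: str = "gaussian"

    def as_row(self) -> dict:
        return {
            "model": self.label,
            "chi_square": self.chi_square,
            "df": self.df,
            "p": self.p,
            "chi_square_vs_linear": self.chi_square_vs_linear,
            "p_vs_linear": self.p_vs_linear,
            "r2c": self.r2c,
            "delta_r2c": self.delta_r2c,
            "r2lr": self.r2lr,
            "significant": self.significant,
            "converged": self.converged,
            "singular": self.singular,
            "family": self.family,
        }


# ---------------------------------------------------------------------------
# Gaussian mixed models (statsmodels MixedLM, ML)
# ---------------------------------------------------------------------------


def _prepare(df: pd.DataFrame, grade_col: str = "grade") -> pd.DataFrame:
    """Attach orthogonal polynomial columns bg1/bg2 of the blur grade."""
    out = df.copy().reset_index(drop=True)
    P = orthogonal_poly(out[grade_col].to_numpy(dtype=float), 2)
    out["bg1"], out["bg2"] = P[:, 0], P[:, 1]
    out["_one"] = 1
    return out


def _fit_gaussian(df: pd.DataFrame, fixed: str, structure: RandomStructure):
    """ML MixedLM fit under the requested random structure.

    Returns the fit plus a ``singular`` flag (a variance component
    estimated at ~0).  ``fixed`` is the RHS of the fixed-effects formula.
    """
    formula = f"y ~ {fixed}"
    vc = {}
    if structure.kind == "nested":
        groups, re_formula = "dyad", "1"
        vc["participant"] = "0 + C(participant)"
    else:
        groups, re_formula = "participant", "1"
        if structure.slopes:
            re_formula = "1 + bg1 + bg2"
    if structure.gesture_type:
        # crossed factor: move everything into variance components of a
        # single all-encompassing group
        groups, re_formula = "_one", "0"
        vc = {"gesture_type": "0 + C(gesture_type)"}
        if structure.kind == "nested":
            vc["dyad"] = "0 + C(dyad)"
            vc["participant"] = "0 + C(participant)"
        else:
            vc["participant"] = "0 + C(participant)"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM.from_formula(
            formula,
            data=df,
            groups=groups,
            re_formula=re_formula,
            vc_formula=vc or None,
        )
        # optimisers disagree on difficult likelihoods; keep the best of two
        fits = []
        for method in ("bfgs", "powell"):
            try:
                fits.append(model.fit(reml=False, method=method, maxiter=500))
            except Exception:
                continue
        if not fits:
            fit = model.fit(reml=False, method="lbfgs", maxiter=500)
            fits = [fit]
    fits = [f for f in fits if np.isfinite(f.llf)] or fits
    fit = max(fits, key=lambda f: f.llf)
    agreed = len(fits) > 1 and abs(fits[0].llf - fits[1].llf) < 1e-3
    if not fit.converged and agreed:
        fit.converged = True
    cov = np.concatenate([np.diag(np.atleast_2d(fit.cov_re)), fit.vcomp])
    singular = bool(np.any(cov < 1e-8 * max(fit.scale, 1e-12)))
    return fit, singular


def _gaussian_variances(fit, df: pd.DataFrame, fixed_cols: list[str]):
    """(fixed, random, residual) variance shares for conditional R^2."""
    X = df[fixed_cols].to_numpy(dtype=float) if fixed_cols else None
    if X is None or X.size == 0:
        var_f = 0.0
    else:
        beta = np.array([fit.fe_params[c] for c in fixed_cols])
        var_f = float(np.var(X @ beta))
    var_r = float(np.sum(np.diag(np.atleast_2d(fit.cov_re))) + np.sum(fit.vcomp))
    return var_f, var_r, float(fit.scale)


def pseudo_r2(full_fit, null_fit, n: int, full_varparts=None, null_varparts=None):
    """(r2c, delta_r2c, r2lr) for a full vs null mixed-model pair.

    ``r2c`` follows the variance-components decomposition
    ``(var_fixed + var_random) / (var_fixed + var_random + var_resid)``;
    ``r2lr = 1 - exp(-LR / n)``.  Variance parts may be supplied directly
    (family-specific residual variances) or derived from Gaussian fits.
    """
    lr = max(0.0, 2.0 * (full_fit.llf - null_fit.llf))
    r2lr = float(1.0 - np.exp(-lr / n))
    if full_varparts is None or null_varparts is None:
        return np.nan, np.nan, r2lr
    vf, vr, ve = full_varparts
    r2c_full = (vf + vr) / (vf + vr + ve) if (vf + vr + ve) > 0 else np.nan
    vf0, vr0, ve0 = null_varparts
    r2c_null = (vf0 + vr0) / (vf0 + vr0 + ve0) if (vf0 + vr0 + ve0) > 0 else np.nan
    return float(r2c_full), float(r2c_full - r2c_null), r2lr


def _lrt(full_llf: float, null_llf: float, df: int):
    chi2 = max(0.0, 2.0 * (full_llf - null_llf))
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else np.nan
    return chi2, p


# ---------------------------------------------------------------------------
# native mixed GLM (single random intercept, Gauss-Hermite)
# ---------------------------------------------------------------------------


class MixedGLMResult:
    """Minimal fit container mirroring the statsmodels attributes we use."""

    def __init__(self, params, llf, converged, fe_names, fe_params, fe_se, re_sd,
                 family, extra):
        self.params = params
        self.llf = llf
        self.converged = converged
        self.fe_names = fe_names
        self.fe_params = pd.Series(fe_params, index=fe_names)
        self.bse = pd.Series(fe_se, index=fe_names)
        self.re_sd = re_sd
        self.family = family
        self.extra = extra

    @property
    def singular(self) -> bool:
        return self.re_sd < 1e-4


class MixedGLM:
    """GLMM with one Gaussian random intercept, fitted by ML over a
    Gauss-Hermite grid.

    Supports ``poisson`` (log link), ``gamma_log`` (log link, shape
    estimated) and ``ordinal_cumulative`` (logit link, J-1 thresholds).
    The marginal likelihood integrates the participant intercept with
    ``n_quad`` Hermite nodes, which is accurate for the modest
    random-effect variances of behavioural data.
    """

    def __init__(self, y, X, groups, family: str, fe_names=None, n_quad: int = 21):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        if family not in ("poisson", "gamma_log", "ordinal_cumulative"):
            raise ValueError(f"unsupported family {family!r}")
        self.family = family
        codes, self.group_names = pd.factorize(np.asarray(groups))
        self.groups = codes
        self.n_groups = len(self.group_names)
        self.fe_names = list(fe_names) if fe_names is not None else [
            f"x{i}" for i in range(self.X.shape[1])
        ]
        z, w = np.polynomial.hermite_e.hermegauss(n_quad)
        self.nodes = z
        self.logw = np.log(w) - 0.5 * np.log(2.0 * np.pi)
        if family == "ordinal_cumulative":
            self.n_cat = int(self.y.max()) + 1
            if self.n_cat < 2:
                raise ValueError("ordinal response needs >= 2 categories")
            self.yi = self.y.astype(int)

    # -- per-observation log-likelihood at linear predictor eta --------------
    def _obs_ll(self, eta: np.ndarray, extra: np.ndarray) -> np.ndarray:
        y = self.y[:, None]
        if self.family == "poisson":
            return y * eta - np.exp(eta) - special.gammaln(y + 1.0)
        if self.family == "gamma_log":
            alpha = np.exp(extra[0])
            return (
                alpha * np.log(alpha)
                - special.gammaln(alpha)
                + (alpha - 1.0) * np.log(y)
                - alpha * eta
                - alpha * y * np.exp(-eta)
            )
        # ordinal cumulative logit
        theta = self._thresholds(extra)
        hi = np.where(self.yi < self.n_cat - 1, theta[np.minimum(self.yi, self.n_cat - 2)], np.inf)
        lo = np.where(self.yi > 0, theta[np.maximum(self.yi - 1, 0)], -np.inf)
        p = special.expit(hi[:, None] - eta) - special.expit(lo[:, None] - eta)
        return np.log(np.clip(p, 1e-300, None))

    def _thresholds(self, extra: np.ndarray) -> np.ndarray:
        theta = np.empty(self.n_cat - 1)
        theta[0] = extra[0]
        if self.n_cat > 2:
            theta[1:] = theta[0] + np.cumsum(np.exp(extra[1:]))
        return theta

    def _n_extra(self) -> int:
        if self.family == "poisson":
            return 0
        if self.family == "gamma_log":
            return 1
        return self.n_cat - 1

    def loglike(self, params: np.ndarray) -> float:
        p = self.X.shape[1]
        beta = params[:p]
        sigma = np.exp(params[p])
        extra = params[p + 1 :]
        eta = self.X @ beta
        eta = eta[:, None] + sigma * self.nodes[None, :]
        ll = self._obs_ll(eta, extra)
        gsum = np.zeros((self.n_groups, ll.shape[1]))
        np.add.at(gsum, self.groups, ll)
        return float(special.logsumexp(gsum + self.logw[None, :], axis=1).sum())

    def _start(self):
        p = self.X.shape[1]
        if self.family == "ordinal_cumulative":
            beta0 = np.zeros(p)
            props = np.bincount(self.yi, minlength=self.n_cat) / self.yi.size
            cum = np.clip(np.cumsum(props)[:-1], 1e-3, 1 - 1e-3)
            theta = special.logit(cum)
            extra = np.concatenate(
                [[theta[0]], np.log(np.clip(np.diff(theta), 1e-3, None))]
            )
            return np.concatenate([beta0, [np.log(0.3)], extra])
        fam = sm.families.Poisson() if self.family == "poisson" else sm.families.Gamma(
            link=sm.families.links.Log()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(self.y, self.X, family=fam).fit()
        beta0 = np.asarray(glm.params)
        extra = []
        if self.family == "gamma_log":
            mu = glm.fittedvalues
            resid = (self.y - mu) / mu
            alpha = 1.0 / max(float(np.var(resid)), 1e-3)
            extra = [np.log(alpha)]
        return np.concatenate([beta0, [np.log(0.3)], extra])

    def _fe_se(self, params: np.ndarray, p: int) -> np.ndarray:
        """Fixed-effect standard errors from a central-difference Hessian."""
        d = params.size
        try:
            H = np.empty((d, d))
            h = 1e-4 * (1.0 + np.abs(params))
            f0 = self.loglike(params)
            for i in range(d):
                for j in range(i, d):
                    pp = params.copy(); pp[i] += h[i]; pp[j] += h[j]
                    pm = params.copy(); pm[i] += h[i]; pm[j] -= h[j]
                    mp = params.copy(); mp[i] -= h[i]; mp[j] += h[j]
                    mm = params.copy(); mm[i] -= h[i]; mm[j] -= h[j]
                    H[i, j] = H[j, i] = (
                        self.loglike(pp) - self.loglike(pm)
                        - self.loglike(mp) + self.loglike(mm)
                    ) / (4.0 * h[i] * h[j])
            cov = np.linalg.inv(-H)
            return np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
        except Exception:
            return np.full(p, np.nan)

    def fit(self, start=None) -> MixedGLMResult:
        x0 = self._start() if start is None else np.asarray(start, dtype=float)
        nll = lambda p: -self.loglike(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(nll, x0, method="BFGS",
                                    options={"gtol": 1e-6, "maxiter": 500})
            if not res.success:
                res2 = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                         options={"maxiter": 4000, "fatol": 1e-8})
                if res2.fun <= res.fun:
                    res = res2
        p = self.X.shape[1]
        se = self._fe_se(res.x, p)
        return MixedGLMResult(
            params=res.x,
            llf=-res.fun,
            converged=bool(np.isfinite(res.fun)),
            fe_names=self.fe_names,
            fe_params=res.x[:p],
            fe_se=se,
            re_sd=float(np.exp(res.x[p])),
            family=self.family,
            extra=res.x[p + 1 :],
        )


def _fit_glmm(df: pd.DataFrame, fixed_cols: list[str], family: str,
              response: str = "y") -> MixedGLMResult:
    """Fit the single-intercept GLMM with intercept + given fixed columns."""
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in fixed_cols]
    )
    names = ["Intercept"] + fixed_cols
    if family == "ordinal_cumulative":
        X = X[:, 1:]  # thresholds absorb the intercept
        names = names[1:]
        if not fixed_cols:
            X = np.zeros((len(df), 0))
    model = MixedGLM(
        df[response].to_numpy(), X, df["participant"].to_numpy(), family, names
    )
    return model.fit()


# ---------------------------------------------------------------------------
# random-effects build-up
# ---------------------------------------------------------------------------


def build_random_effects(
    df: pd.DataFrame,
    response: str,
    family: str = "gaussian",
    alpha: float = DEFAULT_ALPHA,
) -> RandomStructure:
    """Choose the random-effects structure by likelihood-ratio build-up.

    Starts from nested dyad/participant intercepts and tests adding a
    gesture-type intercept (chi-square, df 1; ties keep the simpler
    structure).  A singular or non-convergent nested fit falls back to a
    global participant intercept.  Non-Gaussian families use the global
    participant structure directly (their fitter integrates one random
    intercept), recording that in the diagnostics.
    """
    if df["participant"].nunique() < 2:
        raise ValueError("random-effects build-up needs >= 2 participants")
    if family != "gaussian":
        return RandomStructure(
            kind="global",
            gesture_type=False,
            diagnostics={"note": f"{family} family uses a participant intercept"},
        )
    data = _prepare(df).rename(columns={response: "y"})
    has_gt = "gesture_type" in data.columns and data["gesture_type"].nunique() > 1
    base = RandomStructure(kind="nested")
    try:
        fit0, singular0 = _fit_gaussian(data, "1", base)
    except Exception:
        fit0, singular0 = None, True
    if fit0 is None or singular0 or not fit0.converged:
        base = RandomStructure(
            kind="global", diagnostics={"fallback": "nested fit singular"}
        )
        base.singular = True
        fit0, _ = _fit_gaussian(data, "1", base)
    if has_gt:
        cand = RandomStructure(kind=base.kind, gesture_type=True)
        try:
            fit1, singular1 = _fit_gaussian(data, "1", cand)
            chi2, p = _lrt(fit1.llf, fit0.llf, 1)
            if p < alpha and not singular1 and chi2 > 1e-9:
                cand.diagnostics = dict(base.diagnostics, gesture_type_lrt_p=p)
                return cand
            base.diagnostics["gesture_type_lrt_p"] = p
        except Exception as exc:
            base.diagnostics["gesture_type_error"] = str(exc)
    return base


# ---------------------------------------------------------------------------
# ladders
# ---------------------------------------------------------------------------


def _fit_ladder_family(data, fixed_sets, family, structure):
    """Fit a sequence of fixed-effect specifications, sharing the backend."""
    fits = []
    for cols in fixed_sets:
        if family == "gaussian":
            fixed = " + ".join(["1"] + cols)
            fit, singular = _fit_gaussian(data, fixed, structure)
            varparts = _gaussian_variances(fit, data, cols)
            fits.append((fit, singular, varparts, cols))
        else:
            fit = _fit_glmm(data, cols, family)
            fits.append((fit, fit.singular, None, cols))
    return fits


def _coef_table(fit, family) -> dict:
    out = {}
    if family == "gaussian":
        for name in fit.fe_params.index:
            beta = float(fit.fe_params[name])
            se = float(fit.bse_fe.get(name, np.nan))
            out[name] = (beta, se, beta / se if se and np.isfinite(se) and se > 0 else np.nan)
    else:
        for name in fit.fe_params.index:
            beta = float(fit.fe_params[name])
            se = float(fit.bse.get(name, np.nan))
            out[name] = (beta, se, beta / se if se and np.isfinite(se) and se > 0 else np.nan)
    return out


def ladder_test(
    df: pd.DataFrame,
    response: str,
    family: str | None = None,
    structure: RandomStructure | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> ModelComparisonResult:
    """Null / linear / quadratic blur-grade ladder for one response.

    Fits the random-effects-only null, the linear model and the quadratic
    model (orthogonal polynomial of blur grade) and reports the
    quadratic-vs-null LRT together with the quadratic-vs-linear LRT; the
    quadratic effect is declared significant only when **both** pass
    ``alpha``.
    """
    family = family or RESPONSE_FAMILY.get(response, "gaussian")
    data = _prepare(df).rename(columns={response: "y"})
    if structure is None:
        structure = RandomStructure(kind="nested" if family == "gaussian" else "global")
    try:
        fits = _fit_ladder_family(
            data, [[], ["bg1"], ["bg1", "bg2"]], family, structure
        )
    except Exception as exc:
        return ModelComparisonResult(
            label=f"{response} ~ poly(grade,2)",
            chi_square=np.nan, df=2, p=np.nan, coefficients={},
            converged=False, family=family,
        )
    (f0, s0, v0, _), (f1, s1, v1, _), (f2, s2, v2, _) = fits
    chi_qn, p_qn = _lrt(f2.llf, f0.llf, 2)
    chi_ql, p_ql = _lrt(f2.llf, f1.llf, 1)
    r2c, d_r2c, r2lr = pseudo_r2(f2, f0, len(data), v2, v0)
    converged = all(getattr(f, "converged", True) for f in (f0, f1, f2))
    return ModelComparisonResult(
        label=f"{response} ~ poly(grade,2)",
        chi_square=chi_qn,
        df=2,
        p=p_qn if converged else np.nan,
        coefficients=_coef_table(f2, family),
        r2c=r2c,
        delta_r2c=d_r2c,
        r2lr=r2lr,
        converged=converged,
        singular=bool(s2),
        significant=bool(converged and p_qn < alpha and p_ql < alpha),
        chi_square_vs_linear=chi_ql,
        df_vs_linear=1,
        p_vs_linear=p_ql,
        family=family,
    )


def modality_interaction_ladder(
    acoustic_table: pd.DataFrame,
    response: str = "mean_intensity_db",
    structure: RandomStructure | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Sequential modality / blur / interaction tests on acoustic means.

    Steps: (1) modality main effect vs null, (2) + blur polynomial,
    (3) + blur x modality interaction; each step is an ML LRT against the
    previous one.  Returns the per-step results and the final model's
    coefficient table (the ``modality`` coefficient is the
    speech-with-gesture minus speech-only difference in the response's
    units).
    """
    from .io_formats import SPEECH_WITH_GESTURE

    data = _prepare(acoustic_table.dropna(subset=[response]))
    data = data.rename(columns={response: "y"})
    data["modality_gesture"] = (
        data["modality"] == SPEECH_WITH_GESTURE
    ).astype(float)
    data["bg1_mod"] = data["bg1"] * data["modality_gesture"]
    data["bg2_mod"] = data["bg2"] * data["modality_gesture"]
    if structure is None:
        structure = RandomStructure(kind="nested")
    sets = [
        [],
        ["modality_gesture"],
        ["modality_gesture", "bg1", "bg2"],
        ["modality_gesture", "bg1", "bg2", "bg1_mod", "bg2_mod"],
    ]
    labels = ["modality", "blur", "blur_x_modality"]
    fits = _fit_ladder_family(data, sets, "gaussian", structure)
    steps = []
    for i, label in enumerate(labels):
        f_prev, _, v_prev, _ = fits[i]
        f_cur, s_cur, v_cur, cols = fits[i + 1]
        dfree = len(sets[i + 1]) - len(sets[i])
        chi2, p = _lrt(f_cur.llf, f_prev.llf, dfree)
        r2c, d_r2c, r2lr = pseudo_r2(f_cur, fits[0][0], len(data), v_cur, fits[0][2])
        steps.append(
            ModelComparisonResult(
                label=label,
                chi_square=chi2,
                df=dfree,
                p=p,
                coefficients=_coef_table(f_cur, "gaussian"),
                r2c=r2c,
                delta_r2c=d_r2c,
                r2lr=r2lr,
                converged=getattr(f_cur, "converged", True),
                singular=bool(s_cur),
                significant=bool(p < alpha),
            )
        )
    final = fits[-1][0]
    return {
        "steps": steps,
        "final_coefficients": _coef_table(final, "gaussian"),
        "modality_coefficient": float(final.fe_params["modality_gesture"]),
        "modality_se": float(final.bse_fe.get("modality_gesture", np.nan)),
    }


def kinetic_confound_test(
    acoustic_table: pd.DataFrame,
    kinetic_covariate: str,
    response: str = "mean_intensity_db",
    structure: RandomStructure | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> ModelComparisonResult:
    """Does a kinetic predictor explain the blur effect on acoustics?

    LRT of ``response ~ poly(blur,2)`` against
    ``response ~ poly(blur,2) + kinetic``.  A significant result means a
    biomechanical (kinetic-coupling) account of the acoustic change
    cannot be excluded.
    """
    data = _prepare(acoustic_table.dropna(subset=[response, kinetic_covariate]))
    data = data.rename(columns={response: "y"})
    cov = data[kinetic_covariate].to_numpy(dtype=float)
    if np.ptp(cov) == 0:
        raise ValueError(
            f"kinetic covariate {kinetic_covariate!r} is constant (0 df)"
        )
    data["kinetic"] = (cov - cov.mean()) / cov.std()
    if structure is None:
        structure = RandomStructure(kind="nested")
    fits = _fit_ladder_family(
        data, [["bg1", "bg2"], ["bg1", "bg2", "kinetic"]], "gaussian", structure
    )
    (f0, _, v0, _), (f1, s1, v1, _) = fits
    chi2, p = _lrt(f1.llf, f0.llf, 1)
    r2c, d_r2c, r2lr = pseudo_r2(f1, f0, len(data), v1, v0)
    return ModelComparisonResult(
        label=f"+{kinetic_covariate}",
        chi_square=chi2,
        df=1,
        p=p,
        coefficients=_coef_table(f1, "gaussian"),
        r2c=r2c,
        delta_r2c=d_r2c,
        r2lr=r2lr,
        singular=bool(s1),
        significant=bool(p < alpha),
    )


def ordinal_space_test(
    space_table: pd.DataFrame,
    response: str = "mcneillian_space",
    alpha: float = DEFAULT_ALPHA,
) -> ModelComparisonResult:
    """Cumulative-link mixed-model ladder for the gesture-space category.

    Categories with zero observations are merged into their inner
    neighbour (with a warning); the ladder contract is identical to the
    other responses, with likelihood-ratio statistics and z-values
    reported for the coefficients.
    """
    from .kinematics import SPACE_CATEGORIES

    data = space_table.copy()
    cats = [c for c in SPACE_CATEGORIES if (data[response] == c).any()]
    dropped = [c for c in SPACE_CATEGORIES if c not in cats]
    if dropped:
        warnings.warn(
            f"space categor{'y' if len(dropped) == 1 else 'ies'} {dropped} "
            "unobserved; merged out of the ordinal scale",
            stacklevel=2,
        )
    code = {c: i for i, c in enumerate(cats)}
    data["space_code"] = data[response].map(code).astype(int)
    data = data.rename(columns={"space_code": "y"})
    return ladder_test(
        data, "y", family="ordinal_cumulative", alpha=alpha
    )
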