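"""Cox survival modeling: univariable screening, LASSO selection,
concordance, AIC, and model diagnostics.

The prognostic models are built in two stages, mirroring common
radiomics practice: a 10-fold cross-validated L1-penalized Cox
regression selects features (coefficients of uninformative features
shrink to exactly zero), then an unpenalized multivariable Cox model is
refit on the whole cohort restricted to the selected features to report
coefficients, hazard ratios and confidence intervals.  Model fit is
compared by AIC = 2k - 2 log PL (lower preferred) and discrimination by
Harrell's concordance index (0.5 random, 1 perfect) with an asymptotic
95% CI.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "UnivariableResult",
    "LassoResult",
    "ModelFit",
    "ConcordanceResult",
    "univariable_cox",
    "univariable_screen",
    "pearson_correlation_matrix",
    "lasso_cox_cv",
    "refit_cox",
    "concordance_index",
    "aic",
    "aic_ordering",
    "check_log_linearity",
    "check_ph_schoenfeld",
    "external_validate",
]


# --- concordance ------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    c: float
    ci_low: float
    ci_high: float
    n_comparable: int

    def __float__(self) -> float:
        return self.c


def concordance_index(risk, time, event, ci_method: str = "jackknife",
                      n_boot: int = 200, seed: int = 0) -> ConcordanceResult:
    """Harrell's C with a 95% CI.

    A pair (i, j) is comparable when the patient with the shorter
    follow-up time died (t_i < t_j, d_i = 1); it is concordant when the
    shorter-lived patient has the higher risk score, and tied risk
    scores count 0.5.  The default CI uses the delete-one-subject
    jackknife variance of the pair-count U-statistic (computed exactly
    from per-subject pair sums); ``ci_method="bootstrap"`` resamples
    subjects instead.
    """
    r = np.asarray(risk, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(int)
    n = r.size
    if not (t.size == n and d.size == n):
        raise ValueError("risk, time, event must have equal length")
    comp = (t[:, None] < t[None, :]) & (d[:, None] == 1)
    conc = comp & (r[:, None] > r[None, :])
    tie = comp & (r[:, None] == r[None, :])
    m = int(comp.sum())
    if m == 0:
        raise ValueError("no comparable pairs")
    score = conc + 0.5 * tie
    s_total = float(score.sum())
    c = s_total / m

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            cb = comp[np.ix_(idx, idx)]
            if not cb.any():
                continue
            reps.append(float(score[np.ix_(idx, idx)].sum()) / cb.sum())
        lo, hi = np.percentile(reps, [2.5, 97.5])
        return ConcordanceResult(c, float(lo), float(hi), m)

    # jackknife over subjects: leave-one-out C from per-subject pair sums
    m_i = comp.sum(axis=1) + comp.sum(axis=0)
    s_i = score.sum(axis=1) + score.sum(axis=0)
    m_rest = m - m_i
    with np.errstate(invalid="ignore", divide="ignore"):
        c_loo = np.where(m_rest > 0, (s_total - s_i) / np.maximum(m_rest, 1), c)
    var = (n - 1) / n * ((c_loo - c_loo.mean()) ** 2).sum()
    se = float(np.sqrt(var))
    return ConcordanceResult(c, max(c - 1.96 * se, 0.0), min(c + 1.96 * se, 1.0), m)


# --- partial likelihood -----------------------------------------------------

def log_partial_likelihood(lp, time, event) -> float:
    """Cox log partial likelihood (Breslow ties) of a linear predictor."""
    lp = np.asarray(lp, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(bool)
    order = np.argsort(t, kind="stable")
    t, lp, d = t[order], lp[order], d[order]
    # risk set of subject i: all j with t_j >= t_i (suffix sums, tie-shared)
    exp_lp = np.exp(lp - lp.max())
    suffix = np.cumsum(exp_lp[::-1])[::-1]
    first_at_time = np.searchsorted(t, t, side="left")
    log_denom = np.log(suffix[first_at_time]) + lp.max()
    return float((lp[d] - log_denom[d]).sum())


# --- univariable ------------------------------------------------------------

@dataclass(frozen=True)
class UnivariableResult:
    feature: str
    hr: float
    p: float
    hr_ci_low: float
    hr_ci_high: float
    c: float
    c_ci_low: float
    c_ci_high: float
    coef: float = np.nan


def _fit_cox(df: pd.DataFrame, covariates: list[str], penalizer: float = 0.0) -> CoxPHFitter:
    if int(df["event"].sum()) < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df[covariates + ["time", "event"]], duration_col="time",
                    event_col="event")
        except Exception as exc:  # lifelines raises ConvergenceError subclasses
            raise RuntimeError(f"Cox fit failed for {covariates}: {exc}") from exc
    return cph


def univariable_cox(x, time, event, name: str = "feature") -> UnivariableResult:
    """Single-covariate Cox PH fit: HR per unit, Wald p and CI, Harrell's C."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("feature contains non-finite values")
    if x.std() == 0:
        raise ValueError(f"feature {name!r} is constant: no information")
    df = pd.DataFrame({name: x, "time": np.asarray(time, float),
                       "event": np.asarray(event, int)})
    cph = _fit_cox(df, [name])
    s = cph.summary.loc[name]
    lp = x * float(cph.params_[name])
    cres = concordance_index(lp, df["time"], df["event"])
    return UnivariableResult(
        feature=name, hr=float(s["exp(coef)"]), p=float(s["p"]),
        hr_ci_low=float(s["exp(coef) lower 95%"]),
        hr_ci_high=float(s["exp(coef) upper 95%"]),
        c=cres.c, c_ci_low=cres.ci_low, c_ci_high=cres.ci_high,
        coef=float(s["coef"]),
    )


def univariable_screen(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Univariable Cox screen of a cohort table, one row per covariate level.

    Continuous covariates report an HR per unit; categorical covariates
    (object/category dtype) use first-level reference coding, one row
    per non-reference level with a shared Wald p for the block.
    """
    rows = []
    for col in columns:
        series = df[col]
        if series.dtype.kind in "OUSb" or isinstance(series.dtype, pd.CategoricalDtype):
            levels = pd.Categorical(series)
            ref = levels.categories[0]
            dummies = pd.get_dummies(series, prefix=col, drop_first=True).astype(float)
            sub = pd.concat([dummies, df[["time", "event"]]], axis=1)
            cph = _fit_cox(sub, list(dummies.columns))
            rows.append({"feature": col, "level": f"{ref} (reference)", "hr": np.nan,
                         "p": np.nan, "ci_low": np.nan, "ci_high": np.nan})
            for dcol in dummies.columns:
                s = cph.summary.loc[dcol]
                rows.append({"feature": col, "level": dcol.split(f"{col}_", 1)[1],
                             "hr": float(s["exp(coef)"]), "p": float(s["p"]),
                             "ci_low": float(s["exp(coef) lower 95%"]),
                             "ci_high": float(s["exp(coef) upper 95%"])})
        else:
            res = univariable_cox(series.to_numpy(float), df["time"], df["event"], name=col)
            rows.append({"feature": col, "level": "", "hr": res.hr, "p": res.p,
                         "ci_low": res.hr_ci_low, "ci_high": res.hr_ci_high})
    return pd.DataFrame(rows)


def pearson_correlation_matrix(features: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations (symmetric, unit diagonal)."""
    df = pd.DataFrame(features).astype(float)
    if len(df) < 3:
        raise ValueError("need at least 3 patients")
    sd = df.std(ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    return df.corr(method="pearson")


# --- LASSO-Cox --------------------------------------------------------------

@dataclass
class LassoResult:
    selected: list[str]
    coef: dict[str, float]          # on the original feature scale
    coef_std: dict[str, float]      # per-SD scale (as fitted)
    alpha: float
    seed: int
    cv_path: pd.DataFrame = field(repr=False, default=None)


def _stratified_folds(event: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Fold labels stratified by event status."""
    n = event.size
    fold = np.empty(n, dtype=int)
    for flag in (0, 1):
        idx = np.where(event == flag)[0]
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def lasso_cox_cv(X: pd.DataFrame, time, event, n_folds: int = 10,
                 seed: int = 0, n_alphas: int = 50,
                 alpha_min_ratio: float = 0.01,
                 alphas=None) -> LassoResult:
    """10-fold cross-validated LASSO-Cox feature selection.

    Features are standardized internally (selection under L1 is
    scale-sensitive); the penalty is chosen at the maximum of the
    Verweij-Van Houwelingen cross-validated log partial likelihood
    (equivalently, the minimum CV deviance); features with nonzero
    coefficients at that penalty are selected.  An empty selection is a
    valid result, not an error.
    """
    X = pd.DataFrame(X).astype(float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(int)
    n = len(X)
    if int(d.sum()) < n_folds:
        raise ValueError(f"need at least {n_folds} events for {n_folds}-fold CV")
    mu, sd = X.mean(), X.std(ddof=0)
    if (sd == 0).any():
        raise ValueError(f"zero-variance features: {list(sd[sd == 0].index)}")
    Z = ((X - mu) / sd).to_numpy()
    y = Surv.from_arrays(event=d.astype(bool), time=t)

    if alphas is None:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                      alpha_min_ratio=alpha_min_ratio,
                                      normalize=False, fit_baseline_model=False)
    else:
        path = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas),
                                      normalize=False, fit_baseline_model=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path.fit(Z, y)
    alphas = np.asarray(path.alphas_)

    rng = np.random.default_rng((seed, 0xF01D))
    for attempt in range(5):
        fold = _stratified_folds(d, n_folds, rng)
        ok = all(d[fold != k].sum() >= 2 and (fold == k).sum() >= 1
                 for k in range(n_folds))
        if ok:
            break
    else:
        raise RuntimeError("could not build event-balanced CV folds")

    cvpl = np.zeros(alphas.size)
    for k in range(n_folds):
        train = fold != k
        mdl = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                     normalize=False, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mdl.fit(Z[train], Surv.from_arrays(event=d[train].astype(bool),
                                               time=t[train]))
        fitted = np.asarray(mdl.alphas_)
        coefs = mdl.coef_  # shape (p, n_fitted_alphas)
        for a_idx, alpha in enumerate(alphas):
            j = int(np.argmin(np.abs(fitted - alpha)))
            beta = coefs[:, j]
            lp_all = Z @ beta
            # held-out contribution: full-data logPL minus train-only logPL
            cvpl[a_idx] += (log_partial_likelihood(lp_all, t, d)
                            - log_partial_likelihood(lp_all[train], t[train], d[train]))

    best = int(np.argmax(cvpl))
    alpha_star = float(alphas[best])
    beta_std = path.coef_[:, best]
    nz = np.flatnonzero(beta_std)
    selected = [X.columns[i] for i in nz]
    coef = {X.columns[i]: float(beta_std[i] / sd.iloc[i]) for i in nz}
    cv_path = pd.DataFrame({"alpha": alphas, "cv_log_partial_likelihood": cvpl,
                            "deviance": -2.0 * cvpl})
    return LassoResult(selected=selected, coef=coef,
                       coef_std={X.columns[i]: float(beta_std[i]) for i in nz},
                       alpha=alpha_star, seed=seed, cv_path=cv_path)


# --- refit + model container ------------------------------------------------

@dataclass
class ModelFit:
    model_id: str
    features: list[str]
    coef: dict[str, float]
    hr: dict[str, float]
    p: dict[str, float]
    hr_ci: dict[str, tuple[float, float]]
    c_internal: float
    c_internal_ci: tuple[float, float]
    aic: float
    log_partial_likelihood: float
    c_external: float | None = None
    diagnostics: dict = field(default_factory=dict)
    lasso_alpha: float | None = None
    seed: int | None = None

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in X.columns]
        if missing:
            raise KeyError(f"missing feature columns: {missing}")
        lp = np.zeros(len(X))
        for f in self.features:
            lp += X[f].to_numpy(float) * self.coef[f]
        return lp

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["diagnostics"] = _jsonable(payload["diagnostics"])
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    return obj


def refit_cox(X: pd.DataFrame, time, event, features: list[str],
              model_id: str = "model") -> ModelFit:
    """Unpenalized multivariable Cox refit on the selected features."""
    if not features:
        raise ValueError("empty selection: nothing to refit")
    X = pd.DataFrame(X).astype(float)
    df = X[features].copy()
    df["time"] = np.asarray(time, float)
    df["event"] = np.asarray(event, int)
    cph = _fit_cox(df, features)
    summary = cph.summary
    lp = cph.predict_partial_hazard(df[features]).to_numpy()
    cres = concordance_index(np.log(lp), df["time"], df["event"])
    logpl = log_partial_likelihood(
        df[features].to_numpy() @ cph.params_.to_numpy(), df["time"], df["event"])
    k = len(features)
    return ModelFit(
        model_id=model_id,
        features=list(features),
        coef={f: float(cph.params_[f]) for f in features},
        hr={f: float(summary.loc[f, "exp(coef)"]) for f in features},
        p={f: float(summary.loc[f, "p"]) for f in features},
        hr_ci={f: (float(summary.loc[f, "exp(coef) lower 95%"]),
                   float(summary.loc[f, "exp(coef) upper 95%"])) for f in features},
        c_internal=cres.c,
        c_internal_ci=(cres.ci_low, cres.ci_high),
        aic=aic(logpl, k),
        log_partial_likelihood=logpl,
    )


def aic(log_pl: float, k: int) -> float:
    """Akaike information criterion 2k - 2 log PL (lower is preferred)."""
    if not np.isfinite(log_pl):
        raise ValueError("log partial likelihood must be finite")
    return 2.0 * k - 2.0 * log_pl


def aic_ordering(aics: dict[str, float]) -> list[str]:
    """Model ids ordered by ascending AIC: preferred model first."""
    return sorted(aics, key=lambda m: aics[m])


# --- diagnostics ------------------------------------------------------------

def _rcs_basis(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Restricted (natural) cubic spline design matrix, linear column first.

    Knots at quantiles; the curve is linear beyond the boundary knots,
    which keeps skewed covariates from separating the fit.  Returns
    ``n_knots - 1`` columns: x itself plus ``n_knots - 2`` nonlinear
    terms (Harrell's truncated-power construction).
    """
    qs = np.linspace(0.05, 0.95, n_knots)
    knots = np.unique(np.quantile(x, qs))
    if knots.size < 3:
        raise ValueError("covariate too discrete for a spline basis")
    k = knots.size
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    norm = (tk - t1) ** 2

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for tj in knots[:-2]:
        c = (pos3(x - tj)
             - pos3(x - tk1) * (tk - tj) / (tk - tk1)
             + pos3(x - tk) * (tk1 - tj) / (tk - tk1)) / norm
        cols.append(c)
    design = np.column_stack(cols)
    return design[:, design.std(axis=0) > 1e-12]


def check_log_linearity(x, time, event, name: str = "feature",
                        alpha: float = 0.05, df: int = 4) -> dict:
    """Penalized-spline check of the log-linearity of a covariate effect.

    Fits a univariable Cox model on a restricted cubic spline expansion
    of the covariate (``df`` quantile knots, linear beyond the boundary
    knots, light ridge penalty for stability) and compares it to the
    linear fit by a likelihood-ratio test on the nonlinear block.
    Verdict is ``"log-linear"`` when the nonlinear improvement is not
    significant at ``alpha``.  When the effect is nonlinear but linear
    in log(x), a logarithmic transformation is recommended (the
    LN-volume case).
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(int)
    if d.sum() < df + 2:
        raise ValueError("insufficient events for the spline fit")

    def spline_vs_linear(values):
        z = (values - values.mean()) / values.std(ddof=0)
        lin = pd.DataFrame({"z": z, "time": t, "event": d})
        cph_lin = _fit_cox(lin, ["z"])
        ll_lin = log_partial_likelihood(z * float(cph_lin.params_["z"]), t, d)
        basis = _rcs_basis(z, n_knots=df)
        # orthonormalize (span-preserving, so the LRT is unchanged): the
        # truncated-power columns are near-collinear with the linear term
        centered = basis - basis.mean(axis=0)
        q, _ = np.linalg.qr(centered)
        basis = q[:, :np.linalg.matrix_rank(centered)] * np.sqrt(len(z))
        cols = [f"s{i}" for i in range(basis.shape[1])]
        sp = pd.DataFrame(basis, columns=cols)
        sp["time"] = t
        sp["event"] = d
        # light ridge ladder in case the nonlinear block is near-collinear
        for pen in (1e-6, 1e-2, 0.1):
            try:
                cph_sp = _fit_cox(sp, cols, penalizer=pen)
                break
            except RuntimeError:
                if pen == 0.1:
                    raise
        lp_sp = basis @ cph_sp.params_.to_numpy()
        ll_sp = log_partial_likelihood(lp_sp, t, d)
        dof = basis.shape[1] - 1
        stat = max(2.0 * (ll_sp - ll_lin), 0.0)
        p = float(stats.chi2.sf(stat, dof)) if dof >= 1 else 1.0
        return p, (z, lp_sp)

    try:
        p_raw, curve = spline_vs_linear(x)
    except ValueError:
        # covariate too discrete to support a spline: curvature untestable
        z = (x - x.mean()) / x.std(ddof=0)
        return {"feature": name, "verdict": "indeterminate",
                "p_nonlinear": np.nan, "p_nonlinear_log_scale": np.nan,
                "recommend_log_transform": False,
                "curve": pd.DataFrame({"z": np.sort(z),
                                       "spline_log_hazard": np.full(x.size, np.nan)})}
    verdict = "log-linear" if p_raw >= alpha else "non-linear"
    recommend_log = False
    p_log = np.nan
    if verdict == "non-linear" and np.all(x > 0):
        p_log, _ = spline_vs_linear(np.log(x))
        recommend_log = p_log >= alpha
    order = np.argsort(curve[0])
    return {
        "feature": name,
        "verdict": verdict,
        "p_nonlinear": p_raw,
        "p_nonlinear_log_scale": p_log,
        "recommend_log_transform": bool(recommend_log),
        "curve": pd.DataFrame({"z": curve[0][order],
                               "spline_log_hazard": curve[1][order]}),
    }


def check_ph_schoenfeld(X: pd.DataFrame, time, event, features: list[str]) -> dict:
    """Scaled Schoenfeld residuals and the residual-vs-log(time) PH test."""
    d = np.asarray(event).astype(int)
    if d.sum() < 2:
        raise ValueError("need at least 2 events for Schoenfeld residuals")
    df = pd.DataFrame(X)[features].astype(float).copy()
    df["time"] = np.asarray(time, float)
    df["event"] = d
    cph = _fit_cox(df, features)
    resid = cph.compute_residuals(df, kind="scaled_schoenfeld")
    test = proportional_hazard_test(cph, df, time_transform="log")
    pvals = {f: float(test.summary.loc[f, "p"].iloc[0])
             if isinstance(test.summary.loc[f, "p"], pd.Series)
             else float(test.summary.loc[f, "p"]) for f in features}
    event_times = df.loc[df["event"] == 1, "time"].to_numpy()
    resid = resid.copy()
    return {"residuals": resid, "p_values": pvals,
            "log_time": np.log(np.sort(event_times))}


def external_validate(fit: ModelFit, X_val: pd.DataFrame, time, event) -> ConcordanceResult:
    """Harrell's C of the frozen linear predictor on a validation cohort."""
    lp = fit.linear_predictor(pd.DataFrame(X_val))
    return concordance_index(lp, time, event)
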