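"""Analysis pipeline for the simulated (or re-supplied) study data.

Mirrors the study's reported analyses: a linear mixed-effects model of
pre/post block thresholds on test time × talker type with listener random
intercepts and backward elimination of z-scored demographic covariates; a
paired t-test on the AzBio-in-noise change; a multiple regression of that
change on demographic predictors; and the uncorrected correlation /
device-count comparisons.  A Monte-Carlo harness re-runs the whole pipeline
over replicate simulated studies to measure estimator bias and coverage
against the generating values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .listeners import GeneratingParams, ListenerProfile, cohort_frame, sample_cohort
from .protocol import StudyDataset, run_study

DESIGN_TERMS = ("intercept", "test_time", "talker", "test_time:talker")


class DataError(ValueError):
    """Input table violates the analysis schema (unmatched or missing rows)."""


# ---------------------------------------------------------------------------
# data preparation


def _as_cohort_frame(cohort) -> pd.DataFrame:
    if cohort is None:
        raise DataError("cohort demographics are required for this analysis")
    if isinstance(cohort, pd.DataFrame):
        return cohort
    return cohort_frame(cohort)


def prepost_table(dataset: StudyDataset, include_training: bool = False) -> pd.DataFrame:
    """Long table of threshold observations for the mixed model.

    By default only the pre/post blocks enter (4 per listener), matching
    the reported model's denominator degrees of freedom.  With
    ``include_training`` the 15 training blocks are added, coded with
    ``test_time`` equal to the fraction of training completed.
    """
    df = dataset.tc_thresholds.copy()
    pp = df[df["phase"].isin(["pre", "post"])].copy()
    pp["test_time"] = (pp["phase"] == "post").astype(float)
    if include_training:
        tr = df[df["phase"].str.startswith("train")].copy()
        n_train = tr["phase"].str.slice(5).astype(int).max()
        tr["test_time"] = tr["phase"].str.slice(5).astype(int) / n_train
        pp = pd.concat([pp, tr], ignore_index=True)
    pp["talker_novel"] = (pp["talker"] == "novel").astype(float)
    return pp


# ---------------------------------------------------------------------------
# degrees of freedom for the random-intercept model


def _group_blocks(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    out = []
    for g in pd.unique(groups):
        m = groups == g
        out.append((X[m], y[m]))
    return out


def _reml_loglik(theta, blocks, p):
    """REML log-likelihood (up to a constant) for V_g = se2·I + sb2·J."""
    sb2, se2 = theta
    if se2 <= 0 or sb2 < 0:
        return -np.inf
    logdet = 0.0
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    for Xg, yg in blocks:
        n = len(yg)
        c = sb2 / (se2 + n * sb2)
        logdet += (n - 1) * np.log(se2) + np.log(se2 + n * sb2)
        X1 = Xg.sum(axis=0)
        y1 = yg.sum()
        XtViX += (Xg.T @ Xg - c * np.outer(X1, X1)) / se2
        XtViy += (Xg.T @ yg - c * X1 * y1) / se2
        ytViy += (yg @ yg - c * y1 * y1) / se2
    sign, ld_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - beta @ XtViy
    return -0.5 * (logdet + ld_xvx + quad)


def _fe_cov(theta, blocks, p) -> np.ndarray:
    sb2, se2 = theta
    XtViX = np.zeros((p, p))
    for Xg, _ in blocks:
        n = Xg.shape[0]
        c = sb2 / (se2 + n * sb2)
        X1 = Xg.sum(axis=0)
        XtViX += (Xg.T @ Xg - c * np.outer(X1, X1)) / se2
    return np.linalg.inv(XtViX)


def between_within_df(X: np.ndarray, groups: np.ndarray, names: Sequence[str]) -> dict:
    """Containment-style df: within-listener contrasts get N − g − q_within,
    purely between-listener columns (and the intercept) get g − q_between."""
    n_obs, _ = X.shape
    g = len(pd.unique(groups))
    centered = X - pd.DataFrame(X).groupby(groups).transform("mean").to_numpy()
    is_within = np.ptp(centered, axis=0) > 1e-10
    q_within = int(is_within.sum())
    q_between = int((~is_within).sum())
    dfs = {}
    for j, name in enumerate(names):
        dfs[name] = float(n_obs - g - q_within) if is_within[j] else float(g - q_between)
    return dfs


def satterthwaite_df(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray,
    sb2: float, se2: float, names: Sequence[str],
) -> dict:
    """Satterthwaite-type df for each fixed-effect coefficient.

    Uses the observed curvature of the REML surface in the two variance
    parameters: df_j = 2·f² / (∇f' A ∇f) with f = Var(β̂_j) and A the
    inverse negative REML Hessian.  Falls back to containment df when the
    random-intercept variance sits on the boundary or the Hessian is not
    usable.
    """
    fallback = between_within_df(X, groups, names)
    if sb2 <= 1e-8 or se2 <= 1e-10:
        return fallback
    p = X.shape[1]
    blocks = _group_blocks(X, y, groups)
    theta = np.array([sb2, se2], float)
    h = np.maximum(1e-3 * theta, 1e-6)

    def ll(t):
        return _reml_loglik(t, blocks, p)

    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            H[i, j] = (
                ll(theta + ei + ej) - ll(theta + ei - ej)
                - ll(theta - ei + ej) + ll(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        A = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return fallback
    if not np.all(np.isfinite(A)) or np.any(np.diag(A) <= 0):
        return fallback

    dfs = {}
    for j, name in enumerate(names):
        def f(t, j=j):
            return _fe_cov(t, blocks, p)[j, j]

        grad = np.empty(2)
        for i in range(2):
            ei = np.eye(2)[i] * h[i]
            grad[i] = (f(theta + ei) - f(theta - ei)) / (2 * h[i])
        denom = grad @ A @ grad
        if denom <= 0:
            dfs[name] = fallback[name]
        else:
            df = 2 * f(theta) ** 2 / denom
            dfs[name] = float(df) if np.isfinite(df) and df > 0 else fallback[name]
    return dfs


# ---------------------------------------------------------------------------
# linear mixed-effects model


@dataclass
class LMMResult:
    """Fixed effects (estimate/SE/df/t/p), variance components, and fit flags."""

    effects: dict  # name -> {estimate, se, df, t, p}
    var_subject_hat: float
    var_resid_hat: float
    terms_dropped: list
    singular: bool
    unbalanced: bool
    n_obs: int
    n_groups: int
    df_method: str

    def as_dict(self) -> dict:
        return {
            "fixed_effects": self.effects,
            "random_effects": {"subject_variance": self.var_subject_hat,
                               "residual_variance": self.var_resid_hat},
            "terms_dropped": self.terms_dropped,
            "singular": self.singular,
            "unbalanced": self.unbalanced,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "df_method": self.df_method,
        }

    def to_text(self) -> str:
        lines = ["Fixed effects",
                 f"{'':22s}{'Estimate':>10s}{'Std. error':>12s}{'df':>10s}{'t':>8s}{'p':>10s}"]
        label = {"intercept": "Intercept", "test_time": "Test time", "talker": "Talker",
                 "test_time:talker": "Test time x talker"}
        for name, e in self.effects.items():
            lines.append(
                f"{label.get(name, name):22s}{e['estimate']:>10.1f}{e['se']:>12.2f}"
                f"{e['df']:>10.3f}{e['t']:>8.2f}{_fmt_p(e['p']):>10s}"
            )
        lines += ["", "Random effects", f"{'':22s}{'Variance':>10s}",
                  f"{'Subject':22s}{self.var_subject_hat:>10.1f}",
                  f"{'Residual':22s}{self.var_resid_hat:>10.1f}"]
        if self.terms_dropped:
            lines.append(f"\nDropped covariates: {', '.join(self.terms_dropped)}")
        return "\n".join(lines)


def _fmt_p(p: float) -> str:
    return "<0.0001" if p < 1e-4 else f"{p:.3f}"


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x * 0.0


def _mixedlm_fit(y, X, groups, reml):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = sm.MixedLM(y, X, groups=groups)
        return model.fit(reml=reml)


def fit_lmm(
    dataset: StudyDataset,
    cohort=None,
    candidates: Sequence[str] = ("age", "duration_deafness"),
    include_training: bool = False,
    df_method: str = "satterthwaite",
    alpha_drop: float = 0.05,
) -> LMMResult:
    """Mixed model of block thresholds with covariate backward elimination.

    The design terms (test time, talker, their interaction) are always
    retained; only the z-scored demographic candidates are eligible for
    elimination, dropped one at a time (largest p first, ML refits) while
    non-significant at ``alpha_drop``.  The final model is refit by REML;
    t and p use Satterthwaite-type df by default.
    """
    df = prepost_table(dataset, include_training=include_training)
    listeners = df["listener"].unique()
    if len(listeners) < 2:
        raise DataError("need at least 2 listeners")
    cells = df[df["phase"].isin(["pre", "post"])].groupby("listener").size()
    unbalanced = bool((cells != 4).any())

    candidates = list(candidates)
    if candidates:
        co = _as_cohort_frame(cohort).set_index("id")
        for c in candidates:
            if c not in co.columns:
                raise DataError(f"cohort table lacks candidate covariate {c!r}")
            z = _zscore(co[c].astype(float))
            df[c] = df["listener"].map(z)

    def design(cands):
        X = pd.DataFrame({
            "intercept": 1.0,
            "test_time": df["test_time"],
            "talker": df["talker_novel"],
            "test_time:talker": df["test_time"] * df["talker_novel"],
        })
        for c in cands:
            X[c] = df[c]
        return X

    # backward elimination over candidates only (ML refits for comparisons)
    dropped = []
    current = list(candidates)
    while current:
        res = _mixedlm_fit(df["threshold"], design(current), df["listener"], reml=False)
        pvals = {c: 2 * st.norm.sf(abs(res.fe_params[c] / res.bse_fe[c])) for c in current}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] > alpha_drop:
            current.remove(worst)
            dropped.append(worst)
        else:
            break

    X = design(current)
    res = _mixedlm_fit(df["threshold"], X, df["listener"], reml=True)
    var_subject = float(res.cov_re.iloc[0, 0])
    var_resid = float(res.scale)
    # boundary detection is relative: the optimizer stalls at ~1e-6, not 0
    singular = var_subject <= 1e-4 * max(var_resid, 1e-12)
    if singular:
        warnings.warn("random-intercept variance estimated at the boundary; floored at 0")
        var_subject = 0.0

    names = list(X.columns)
    Xa, ya, ga = X.to_numpy(float), df["threshold"].to_numpy(float), df["listener"].to_numpy()
    if df_method == "satterthwaite":
        dfs = satterthwaite_df(Xa, ya, ga, var_subject, var_resid, names)
    elif df_method == "between_within":
        dfs = between_within_df(Xa, ga, names)
    else:
        raise ValueError(f"unknown df method {df_method!r}")

    effects = {}
    for name in names:
        est = float(res.fe_params[name])
        se = float(res.bse_fe[name])
        d = dfs[name]
        t = est / se if se > 0 else np.nan
        p = float(2 * st.t.sf(abs(t), d)) if np.isfinite(t) else np.nan
        effects[name] = {"estimate": est, "se": se, "df": d, "t": float(t), "p": p}

    return LMMResult(
        effects=effects,
        var_subject_hat=var_subject,
        var_resid_hat=var_resid,
        terms_dropped=dropped,
        singular=singular,
        unbalanced=unbalanced,
        n_obs=int(len(df)),
        n_groups=int(len(listeners)),
        df_method=df_method,
    )


# ---------------------------------------------------------------------------
# paired test, change regression, auxiliary comparisons


@dataclass(frozen=True)
class PairedChangeResult:
    mean_change: float
    sd_change: float
    se: float
    t: float
    df: int
    p: float
    n: int

    def as_dict(self) -> dict:
        return dict(vars(self))


def paired_change_test(azbio_scores: pd.DataFrame) -> PairedChangeResult:
    """Paired two-tailed t-test on the AzBio change (post − pre) per listener."""
    wide = azbio_scores.pivot(index="listener", columns="phase", values="score")
    if "pre" not in wide or "post" not in wide or wide[["pre", "post"]].isna().any().any():
        raise DataError("every listener needs matched pre and post AzBio scores")
    change = (wide["post"] - wide["pre"]).to_numpy(float)
    n = len(change)
    mean = float(np.mean(change))
    sd = float(np.std(change, ddof=1))
    se = sd / np.sqrt(n)
    if sd == 0.0:
        t, p = 0.0, 1.0
    else:
        t, p = st.ttest_rel(wide["post"], wide["pre"])
    return PairedChangeResult(mean, sd, float(se), float(t), n - 1, float(p), n)


def listener_threshold_summary(dataset: StudyDataset) -> pd.DataFrame:
    """Per-listener pre/post thresholds by talker, talker averages, and change."""
    df = dataset.tc_thresholds
    pp = df[df["phase"].isin(["pre", "post"])]
    wide = pp.pivot_table(index="listener", columns=["phase", "talker"],
                          values="threshold", aggfunc="mean")
    out = pd.DataFrame(index=wide.index)
    for ph in ("pre", "post"):
        for tk in ("trained", "novel"):
            out[f"{ph}_{tk}"] = wide[(ph, tk)]
        out[f"{ph}_avg"] = (wide[(ph, "trained")] + wide[(ph, "novel")]) / 2
    out["tc_change"] = out["post_avg"] - out["pre_avg"]
    return out


def change_regression(dataset: StudyDataset, cohort) -> pd.DataFrame:
    """OLS of the AzBio change on age, duration of deafness, CNC score, and
    the (talker-averaged) change in time-compression threshold."""
    co = _as_cohort_frame(cohort).set_index("id")
    summ = listener_threshold_summary(dataset)
    az = dataset.azbio_scores.pivot(index="listener", columns="phase", values="score")
    y = (az["post"] - az["pre"]).reindex(summ.index)
    X = pd.DataFrame({
        "age": co["age"].reindex(summ.index),
        "duration_deafness": co["duration_deafness"].reindex(summ.index),
        "cnc_score": co["cnc_score"].reindex(summ.index),
        "tc_change": summ["tc_change"],
    })
    if X.isna().any().any() or y.isna().any():
        raise DataError("regression table has missing listeners")
    if len(y) <= X.shape[1] + 1:
        raise DataError("too few listeners for the multiple regression")
    exog = sm.add_constant(X)
    res = sm.OLS(y, exog).fit()
    if res.condition_number > 1e6:
        warnings.warn(f"ill-conditioned predictor matrix (cond={res.condition_number:.2e})")
    return pd.DataFrame({
        "estimate": res.params, "se": res.bse, "t": res.tvalues, "p": res.pvalues,
    })


@dataclass
class AuxiliaryReport:
    """Six age correlations and seven device-count comparisons, uncorrected."""

    correlations: pd.DataFrame
    ttests: pd.DataFrame

    def as_dict(self) -> dict:
        return {"correlations": self.correlations.to_dict(orient="records"),
                "ttests": self.ttests.to_dict(orient="records")}


def auxiliary_tests(dataset: StudyDataset, cohort) -> AuxiliaryReport:
    """Pearson correlations of age with pre/post thresholds (trained, novel,
    talker average) and equal-variance two-sample t-tests comparing listeners
    with one vs two implants on thresholds, AzBio, and CNC score.  All tests
    are deliberately uncorrected for multiple comparisons."""
    co = _as_cohort_frame(cohort).set_index("id")
    summ = listener_threshold_summary(dataset)
    az = dataset.azbio_scores.pivot(index="listener", columns="phase", values="score")
    age = co["age"].reindex(summ.index).to_numpy(float)

    corr_rows = []
    for ph in ("pre", "post"):
        for tk in ("trained", "novel", "avg"):
            x = summ[f"{ph}_{tk}"].to_numpy(float)
            r, p = st.pearsonr(age, x)
            corr_rows.append({"variable": f"age~{ph}_{tk}", "r": float(r),
                              "p": float(p), "n": len(x), "skipped": False})

    tvars = {
        "pre_trained": summ["pre_trained"], "pre_novel": summ["pre_novel"],
        "post_trained": summ["post_trained"], "post_novel": summ["post_novel"],
        "azbio_pre": az["pre"].reindex(summ.index),
        "azbio_post": az["post"].reindex(summ.index),
        "cnc_score": co["cnc_score"].reindex(summ.index),
    }
    n_cis = co["n_cis"].reindex(summ.index)
    t_rows = []
    for name, series in tvars.items():
        g1 = series[n_cis == 1].to_numpy(float)
        g2 = series[n_cis == 2].to_numpy(float)
        if len(g1) < 2 or len(g2) < 2:
            t_rows.append({"variable": name, "t": np.nan, "p": np.nan,
                           "n1": len(g1), "n2": len(g2), "skipped": True})
            continue
        # degenerate constant groups: mean() of k identical floats can differ
        # in the last ulp across group sizes, so compare with isclose
        if np.ptp(g1) == 0 and np.ptp(g2) == 0:
            same = np.isclose(np.mean(g1), np.mean(g2), rtol=1e-12, atol=1e-12)
            t, p = (0.0, 1.0) if same else (np.inf, 0.0)
        else:
            t, p = st.ttest_ind(g1, g2, equal_var=True)
        t_rows.append({"variable": name, "t": float(t), "p": float(p),
                       "n1": len(g1), "n2": len(g2), "skipped": False})

    return AuxiliaryReport(pd.DataFrame(corr_rows), pd.DataFrame(t_rows))


# ---------------------------------------------------------------------------
# parameter-recovery harness


@dataclass
class RecoveryReport:
    """Replicate-averaged estimates vs generating values."""

    entries: dict  # parameter -> {true, mean, mc_se, bias, coverage}
    n_replicates: int
    seed: int
    n_failures: int
    valid: bool

    def as_dict(self) -> dict:
        return {"parameters": self.entries, "n_replicates": self.n_replicates,
                "seed": self.seed, "n_failures": self.n_failures, "valid": self.valid}


_EFFECT_TO_PARAM = {
    "intercept": "mu",
    "test_time": "delta_time",
    "talker": "delta_talker",
    "test_time:talker": "delta_interaction",
}


def run_recovery(
    params: GeneratingParams = GeneratingParams(),
    n_replicates: int = 200,
    mode: str = "threshold_level",
    rng_seed: int = 0,
    n_listeners: int = 14,
    candidates: Sequence[str] = (),
    df_method: str = "between_within",
    scoring: str = "keyword",
) -> RecoveryReport:
    """Simulate replicate studies and aggregate pipeline estimates.

    Each replicate draws a fresh parametric cohort, runs the full protocol,
    fits the mixed model and the paired AzBio test, and records the point
    estimates and Wald/t intervals.  The report gives replicate means,
    Monte-Carlo SEs, bias, and 95% coverage per generating parameter.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    ss = np.random.SeedSequence(rng_seed)
    child_seeds = ss.generate_state(2 * n_replicates) % (2**31)

    est = {k: [] for k in _EFFECT_TO_PARAM.values()}
    cover = {k: [] for k in _EFFECT_TO_PARAM.values()}
    var_subj, var_resid, az_mean, az_cover = [], [], [], []
    truths = {
        "mu": params.mu, "delta_time": params.delta_time,
        "delta_talker": params.delta_talker, "delta_interaction": params.delta_interaction,
    }
    n_failures = 0
    for r in range(n_replicates):
        try:
            cohort = sample_cohort(n_listeners, params, "parametric", int(child_seeds[2 * r]))
            ds = run_study(cohort, params, rng_seed=int(child_seeds[2 * r + 1]),
                           mode=mode, scoring=scoring)
            res = fit_lmm(ds, cohort=cohort_frame(cohort), candidates=candidates,
                          df_method=df_method)
            pt = paired_change_test(ds.azbio_scores)
        except Exception:
            n_failures += 1
            continue
        for eff, pname in _EFFECT_TO_PARAM.items():
            e = res.effects[eff]
            est[pname].append(e["estimate"])
            half = st.t.ppf(0.975, e["df"]) * e["se"]
            cover[pname].append(abs(e["estimate"] - truths[pname]) <= half)
        var_subj.append(res.var_subject_hat)
        var_resid.append(res.var_resid_hat)
        az_mean.append(pt.mean_change)
        az_cover.append(abs(pt.mean_change - params.azbio_delta)
                        <= st.t.ppf(0.975, pt.df) * pt.se)

    entries = {}

    def _entry(true, values, coverage=None):
        v = np.asarray(values, float)
        return {
            "true": float(true),
            "mean": float(v.mean()),
            "mc_se": float(v.std(ddof=1) / np.sqrt(len(v))),
            "bias": float(v.mean() - true),
            "coverage": None if coverage is None else float(np.mean(coverage)),
        }

    for pname, true in truths.items():
        entries[pname] = _entry(true, est[pname], cover[pname])
    entries["var_subject"] = _entry(params.var_subject, var_subj)
    entries["var_resid"] = _entry(params.sd_resid**2, var_resid)
    entries["azbio_delta"] = _entry(params.azbio_delta, az_mean, az_cover)

    return RecoveryReport(
        entries=entries,
        n_replicates=n_replicates,
        seed=int(rng_seed),
        n_failures=n_failures,
        valid=n_failures <= 0.1 * n_replicates,
    )
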