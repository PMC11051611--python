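"""Disparity tests and adjusted logistic health models.

Two test families quantify disparities between exposure measurements: Welch
two-sample t-tests (between communities, no equal-variance assumption) and
paired-sample t-tests (between settings within the same participants).  The
association between each exposure setting and dichotomized self-rated health
is estimated by adjusted binary logistic regression, one model per setting
per community, with Wald 95% intervals on the exposure coefficient.  No
multiple-testing correction is applied by default (the battery mirrors a
many-settings sensitivity design); a Benjamini–Hochberg switch is available
and recorded in the output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import InferenceError

__all__ = [
    "ComparisonResult",
    "HealthModelResult",
    "paired_t",
    "welch_t",
    "run_comparison_battery",
    "fit_health_model",
    "run_health_battery",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ["age_group", "gender", "income_group", "education_group", "marital_group"]

#: Table-layout pairs for the cross-sensor / resolution comparison family
SENSOR_PAIR_BODIES = [
    ("r010m", "r130m"),
    ("r130m", "r500m"),
    ("b065m", "r130m"),
    ("b250m", "r500m"),
    ("r010m", "r130m_CC"),
    ("b065m", "r130m_CC"),
    ("b250m", "r500m_CC"),
]

#: buffer-radius comparison family
RADIUS_PAIR_BODIES = [("b500m", "b300m"), ("b300m", "b100m")]


@dataclass(frozen=True)
class ComparisonResult:
    """One t-test row: mean difference D, its SE, t, df and two-tailed p."""

    pair_label: str
    D: float
    SE: float
    t: float
    df: float
    p: float
    test: Literal["paired", "welch"]
    n: int
    degenerate: bool = False

    @property
    def stars(self) -> str:
        if self.degenerate or not np.isfinite(self.p):
            return ""
        return "**" if self.p < 0.01 else ("*" if self.p < 0.05 else "")


@dataclass(frozen=True)
class HealthModelResult:
    """Adjusted logistic effect of one exposure setting on being healthy.

    ``beta_exposure`` is the log-odds change per ``exposure_scale`` radiance
    units (default: per 100 nW·cm⁻²·sr⁻¹).
    """

    setting_label: str
    beta_exposure: float
    ci_low: float
    ci_high: float
    p: float
    z: float
    n: int
    covariates: tuple[str, ...]
    exposure_scale: float
    converged: bool = True
    separation: bool = False


def paired_t(x: Sequence[float], y: Sequence[float], label: str = "") -> ComparisonResult:
    """Paired-sample t-test of x − y.

    D = mean(x−y), SE = sd(x−y)/√n, t = D/SE on n−1 df.  Zero-variance
    differences yield a flagged degenerate result instead of an exception so
    a battery can keep running.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InferenceError("paired test needs two equal-length 1-D samples with n >= 2")
    d = x - y
    n = d.size
    D = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return ComparisonResult(label, D, 0.0, float("nan"), n - 1, float("nan"),
                                "paired", n, degenerate=True)
    SE = sd / np.sqrt(n)
    t = D / SE
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return ComparisonResult(label, D, float(SE), float(t), float(n - 1), float(p), "paired", n)


def welch_t(a: Sequence[float], b: Sequence[float], label: str = "") -> ComparisonResult:
    """Welch two-sample t-test of mean(a) − mean(b) (unequal variances).

    Degrees of freedom by Welch–Satterthwaite; rejects zero-variance samples.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise InferenceError("welch test needs two 1-D samples with n >= 2 each")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise InferenceError("welch test: both samples have zero variance")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    D = float(a.mean() - b.mean())
    SE = float(np.sqrt(se2))
    t = D / SE
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ComparisonResult(label, D, SE, float(t), float(df), float(p), "welch", na + nb)


# ---------------------------------------------------------------------------
# comparison battery
# ---------------------------------------------------------------------------

def _wide_by_community(matrix: pd.DataFrame) -> dict[str, pd.DataFrame]:
    out = {}
    for com, sub in matrix.groupby("community"):
        out[com] = sub.pivot_table(index="participant_id", columns="setting", values="value")
    return out


def run_comparison_battery(
    matrix: pd.DataFrame,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """The full disparity battery over an exposure matrix.

    Emits four families: (i) between-community Welch tests per setting,
    (ii) MOM vs RBM paired tests per setting body per community,
    (iii) cross-sensor/resolution paired tests (incl. cross-calibrated and
    matched-buffer pairs), and (iv) buffer-radius paired tests.  Returns one
    tidy DataFrame with family, community, pair, D, SE, t, df, p and stars;
    ``bh_correct`` adds a Benjamini–Hochberg adjusted column per family.
    """
    wide = _wide_by_community(matrix)
    communities = list(wide)
    if len(communities) != 2:
        raise InferenceError(f"between-community tests need exactly 2 communities, got {communities}")
    # brighter community first, so context differences read bright − dark
    communities.sort(key=lambda c: -float(np.nanmean(wide[c].to_numpy())))
    ca, cb = communities
    settings = list(wide[ca].columns)
    results: list[dict] = []

    def _emit(family: str, community: str, res: ComparisonResult) -> None:
        results.append(
            {
                "family": family,
                "community": community,
                "pair": res.pair_label,
                "D": res.D,
                "SE": res.SE,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "test": res.test,
                "n": res.n,
                "degenerate": res.degenerate,
                "stars": res.stars,
            }
        )

    # (i) geographic context: community a vs community b per setting
    for s in settings:
        a = wide[ca][s].dropna()
        b = wide[cb][s].dropna()
        try:
            res = welch_t(a, b, label=s)
        except InferenceError:
            res = ComparisonResult(s, float(a.mean() - b.mean()), 0.0, 0.0,
                                   a.size + b.size - 2, float("nan"), "welch",
                                   a.size + b.size, degenerate=True)
        _emit("context", f"{ca}-{cb}", res)

    def _paired_family(family: str, pairs: list[tuple[str, str]]) -> None:
        for com in communities:
            w = wide[com]
            for left, right in pairs:
                if left not in w.columns or right not in w.columns:
                    raise InferenceError(f"comparison {left} - {right}: missing setting")
                _emit(family, com, paired_t(w[left], w[right], label=f"{left} - {right}"))

    # (ii) approach: M_x vs R_x for every setting body present in both
    bodies = sorted({s[2:] for s in settings if s.startswith("M_")})
    _paired_family("approach", [(f"M_{b}", f"R_{b}") for b in bodies
                               if f"R_{b}" in settings])

    # (iii) sensor/resolution pairs, per approach
    sensor_pairs = [
        (f"{p}_{l}", f"{p}_{r}")
        for p in ("M", "R")
        for l, r in SENSOR_PAIR_BODIES
        if f"{p}_{l}" in settings and f"{p}_{r}" in settings
    ]
    _paired_family("sensor", sensor_pairs)

    # (iv) buffer radius pairs, per approach
    radius_pairs = [
        (f"{p}_{l}", f"{p}_{r}")
        for p in ("M", "R")
        for l, r in RADIUS_PAIR_BODIES
        if f"{p}_{l}" in settings and f"{p}_{r}" in settings
    ]
    _paired_family("radius", radius_pairs)

    df = pd.DataFrame(results)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        adj = np.full(len(df), np.nan)
        for fam, sub in df.groupby("family"):
            ok = sub["p"].notna()
            if ok.any():
                adj_vals = multipletests(sub.loc[ok, "p"], method="fdr_bh")[1]
                adj[sub.index[ok]] = adj_vals
        df["p_bh"] = adj
    return df


# ---------------------------------------------------------------------------
# logistic health models
# ---------------------------------------------------------------------------

def _design_matrix(health: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=health.index)
    for cov in covariates:
        if cov not in health.columns:
            raise InferenceError(f"covariate {cov!r} missing from health records")
        dummies = pd.get_dummies(health[cov].astype("category"), prefix=cov,
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    return X


def fit_health_model(
    exposures: pd.Series | np.ndarray,
    health: pd.DataFrame,
    exposure_scale: float = 100.0,
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
    setting_label: str = "",
    maxiter: int = 200,
) -> HealthModelResult:
    """Adjusted binary logistic regression of `healthy` on one exposure.

    Exposure enters scaled (default per-100 radiance units) alongside
    dummy-coded covariates; the exposure coefficient's Wald 95% CI and
    p-value are reported.  Non-convergence and (quasi-)separation are flagged
    on the result, never silently accepted.
    """
    y = np.asarray(health["healthy"], dtype=float)
    n = y.size
    if len(np.unique(y)) < 2:
        raise InferenceError("outcome has a single class; logistic model is undefined")
    x = np.asarray(exposures, dtype=np.float64) / exposure_scale
    if x.size != n:
        raise InferenceError("exposures and health records differ in length")
    X = _design_matrix(health, covariates)
    X.insert(0, "exposure", x)
    X = sm.add_constant(X, prepend=True)
    if n <= X.shape[1]:
        raise InferenceError(f"n = {n} too small for {X.shape[1]} parameters")
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            # IRLS is markedly more robust than Newton on near-separated
            # small-cohort fits; estimates are the same MLE
            fit = sm.GLM(y, X.to_numpy(dtype=float), family=sm.families.Binomial()).fit(
                maxiter=maxiter)
            converged = bool(getattr(fit, "converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separation = True
            fit = sm.Logit(y, X.to_numpy(dtype=float)).fit_regularized(
                disp=0, alpha=1e-4, maxiter=maxiter)
            converged = False
    k = 1  # exposure column (after the constant)
    beta = float(fit.params[k])
    try:
        se = float(fit.bse[k])
    except Exception:
        se = float("nan")
    if not np.isfinite(se) or se > 1e3:
        separation = True
    zcrit = stats.norm.ppf(0.975)
    z = beta / se if se > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return HealthModelResult(
        setting_label=setting_label,
        beta_exposure=beta,
        ci_low=beta - zcrit * se,
        ci_high=beta + zcrit * se,
        p=float(p),
        z=float(z) if np.isfinite(z) else float("nan"),
        n=n,
        covariates=tuple(covariates),
        exposure_scale=exposure_scale,
        converged=converged,
        separation=separation,
    )


def run_health_battery(
    matrix: pd.DataFrame,
    health: pd.DataFrame,
    exposure_scale: float = 100.0,
    covariates: Sequence[str] = tuple(DEFAULT_COVARIATES),
) -> pd.DataFrame:
    """One adjusted logistic model per setting per community.

    ``health`` must be indexed/joinable by participant_id and carry
    ``healthy`` plus the covariate columns.  Returns a forest-plot-ready
    table: setting, community, logit (beta per scale units), 95% CI, z, p,
    convergence flags.
    """
    hrec = health.set_index("participant_id") if "participant_id" in health.columns else health
    rows = []
    for (com, setting), sub in matrix.groupby(["community", "setting"]):
        sub = sub.set_index("participant_id")
        joined = hrec.loc[sub.index]
        try:
            res = fit_health_model(sub["value"], joined, exposure_scale, covariates,
                                   setting_label=setting)
            err = ""
        except InferenceError as exc:
            res = None
            err = str(exc)
        rows.append(
            {
                "setting": setting,
                "community": com,
                "logit": res.beta_exposure if res else np.nan,
                "ci_low": res.ci_low if res else np.nan,
                "ci_high": res.ci_high if res else np.nan,
                "z": res.z if res else np.nan,
                "p": res.p if res else np.nan,
                "n": res.n if res else len(sub),
                "converged": res.converged if res else False,
                "separation": res.separation if res else False,
                "exposure_scale": exposure_scale,
                "error": err,
            }
        )
    return pd.DataFrame(rows)
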