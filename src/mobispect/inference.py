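"""Statistical layer: group tests, timescale correlations, VIF pruning,
person-day and spectrum-power logistic regressions, mood-fluctuation
summaries, and the Fisher-z sample-size computation.

Person-days are treated as independent observations in the logistic
models (an acknowledged simplification — repeated days within a
participant are correlated; a cluster-robust variance option is
available but off by default).  Tests are two-sided at alpha = .05,
Wald confidence intervals at 95%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelResult",
    "mood_fluctuation_rate",
    "kruskal_wallis",
    "mann_whitney_mean_ranks",
    "correlate_by_timescale",
    "vif_prune",
    "fit_daylevel_logistic",
    "fit_spectrum_logistic",
    "sample_size_correlation",
    "build_person_day_rows",
]

MOOD_ITEMS = ("ema_dep", "ema_mania", "ema_fatigue", "ema_irrit")


# ---------------------------------------------------------------------------
# descriptive


def mood_fluctuation_rate(rows: pd.DataFrame, item: str) -> tuple[float, int, int]:
    """Percentage of scored person-days on which an EMA item exceeds 1.

    Score 1 anchors "not at all"; any higher score marks a
    mood-fluctuation day.  Returns (percentage, count, n_scored).
    """
    scores = rows[item].dropna()
    n = len(scores)
    if n == 0:
        raise ValueError(f"no scored days for item '{item}'")
    count = int((scores > 1).sum())
    return 100.0 * count / n, count, n


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(samples: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df."""
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0  # every observation tied: H is 0 by convention
    h, p = stats.kruskal(*samples)
    return float(h), float(p)


def mann_whitney_mean_ranks(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float, float, float]:
    """Mann-Whitney U (two-sided asymptotic p, tie-corrected, no
    continuity correction) plus both groups' mean pooled mid-ranks."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    ranks = stats.rankdata(np.concatenate([a, b]))
    return (
        float(res.statistic),
        float(res.pvalue),
        float(ranks[: a.size].mean()),
        float(ranks[a.size :].mean()),
    )


# ---------------------------------------------------------------------------
# correlations across timescales

_WINDOW_FREQ = {"daily": "1D", "weekly": "7D", "monthly": "28D", "semiannual": "182D"}


def correlate_by_timescale(
    rows: pd.DataFrame,
    features: list[str],
    ema_item: str = "ema_dep",
    window: str = "daily",
) -> pd.DataFrame:
    """Pearson r between window-averaged features and the EMA item.

    Features and mood are averaged within fixed-length windows per
    participant (windows anchored at each participant's first day),
    pooled, and correlated.  A zero-variance side yields a flagged
    undefined r rather than an error.
    """
    if window not in _WINDOW_FREQ:
        raise ValueError(f"unknown window '{window}'")
    df = rows.dropna(subset=[ema_item]).copy()
    if window == "daily":
        agg = df
    else:
        freq = _WINDOW_FREQ[window]
        parts = []
        for pid, grp in df.groupby("participant_id"):
            g = grp.set_index(pd.to_datetime(grp["date"]))
            res = g[features + [ema_item]].resample(freq, origin="start").mean()
            parts.append(res.dropna(how="all"))
        agg = pd.concat(parts, ignore_index=True)
    out = []
    for feat in features:
        pair = agg[[feat, ema_item]].dropna()
        if len(pair) < 3 or pair[feat].nunique() < 2 or pair[ema_item].nunique() < 2:
            out.append({"feature": feat, "r": np.nan, "p": np.nan, "n": len(pair),
                        "defined": False})
            continue
        r, p = stats.pearsonr(pair[feat], pair[ema_item])
        out.append({"feature": feat, "r": float(r), "p": float(p), "n": len(pair),
                    "defined": True})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# multicollinearity


def _vif(X: np.ndarray, i: int) -> float:
    """VIF_i = 1/(1-R²) from regressing column i on the others."""
    y = X[:, i]
    others = np.delete(X, i, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return math.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return math.inf
    return 1.0 / (1.0 - r2)


def vif_prune(X: pd.DataFrame, threshold: float = 3.0) -> list[str]:
    """Iteratively drop the feature with the largest VIF until all <= threshold.

    Perfectly collinear columns have infinite VIF and are dropped first
    (the later column of a tied pair goes).
    """
    cols = list(X.columns)
    if len(cols) < 2:
        return cols
    while len(cols) > 1:
        M = X[cols].to_numpy(float)
        vifs = [_vif(M, i) for i in range(len(cols))]
        worst = max(vifs)
        if worst <= threshold:
            break
        # drop the last column attaining the maximum (keeps the first of a
        # duplicated pair)
        drop = max(i for i, v in enumerate(vifs) if v == worst)
        cols.pop(drop)
    return cols


# ---------------------------------------------------------------------------
# logistic models


@dataclass(frozen=True)
class ModelResult:
    """Tidy logistic-fit summary: term -> (beta, OR, 95% CI, p)."""

    model_id: str
    n: int
    terms: pd.DataFrame  # index: term; columns beta, or_, ci_low, ci_high, p

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> None:
    for col in X.columns:
        v = X[col].to_numpy(float)
        if v[y == 1].size and v[y == 0].size:
            if v[y == 1].min() > v[y == 0].max() or v[y == 1].max() < v[y == 0].min():
                raise ValueError(f"complete separation on term '{col}'")


def _fit_logit(
    X: pd.DataFrame, y: np.ndarray, model_id: str, cluster: np.ndarray | None = None
) -> ModelResult:
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; both classes required")
    _check_separation(X, y)
    design = sm.add_constant(X.astype(float), has_constant="add")
    model = sm.Logit(y, design)
    try:
        if cluster is not None:
            fit = model.fit(disp=0, cov_type="cluster", cov_kwds={"groups": cluster})
        else:
            fit = model.fit(disp=0)
    except Exception as exc:  # pragma: no cover - statsmodels raise paths vary
        raise ValueError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise ValueError("logistic fit did not converge (possible separation)")
    ci = fit.conf_int(alpha=0.05)
    terms = pd.DataFrame(
        {
            "beta": fit.params,
            "or_": np.exp(fit.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "p": fit.pvalues,
        }
    )
    return ModelResult(model_id=model_id, n=int(len(y)), terms=terms)


def build_person_day_rows(
    day_features: pd.DataFrame, moods: pd.DataFrame, cohort_df: pd.DataFrame
) -> pd.DataFrame:
    """Join daily features, EMA statuses (item > 1) and covariates into the
    analysis-ready person-day table."""
    m = moods.copy()
    for item in MOOD_ITEMS:
        m[item.replace("ema_", "") + "_status"] = (m[item] > 1).astype(float).where(
            m[item].notna()
        )
    keep = ["participant_id", "date"] + [
        c for c in m.columns if c.endswith("_status")
    ]
    rows = day_features.merge(m[keep], on=["participant_id", "date"], how="left")
    cov = cohort_df.copy()
    cov["female"] = (cov["sex"] == "F").astype(float)
    cov["employee_or_student"] = cov["employment"].isin(["employed", "student"]).astype(float)
    cov["antidep"] = cov["antidepressant"].astype(float)
    rows = rows.merge(
        cov[["participant_id", "group", "age", "female", "employee_or_student", "antidep"]],
        on="participant_id",
        how="left",
    )
    if "weekday" not in rows.columns:
        rows["weekday"] = pd.to_datetime(rows["date"]).dt.dayofweek < 5
    return rows


def fit_daylevel_logistic(
    rows: pd.DataFrame,
    stratum: str = "all",
    features: list[str] | None = None,
    vif_threshold: float = 3.0,
    outcome: str = "dep_status",
    cluster_robust: bool = False,
) -> ModelResult:
    """Person-day logistic fit of depressive status on GPS features.

    Strata: ``all`` / ``weekday`` / ``weekend``.  Covariates are female
    sex, age, and the employee-or-student flag; features are pruned at
    VIF > ``vif_threshold`` before entry.  TT and homestay enter as
    fractions in [0, 1].
    """
    from .features import FEATURE_NAMES

    if stratum == "weekday":
        rows = rows.loc[rows["weekday"].astype(bool)]
    elif stratum == "weekend":
        rows = rows.loc[~rows["weekday"].astype(bool)]
    elif stratum != "all":
        raise ValueError("stratum must be all/weekday/weekend")
    feats = list(FEATURE_NAMES) if features is None else list(features)
    data = rows.dropna(subset=[outcome] + feats).copy()
    kept = vif_prune(data[feats], threshold=vif_threshold)
    X = data[["female", "age", "employee_or_student"] + kept]
    cluster = data["participant_id"].to_numpy() if cluster_robust else None
    return _fit_logit(X, data[outcome].to_numpy(float), f"daylevel:{stratum}", cluster)


_MODEL_COVARIATES = {
    1: [],
    2: ["age", "female"],
    3: ["age", "female", "employee_or_student"],
    4: ["age", "female", "employee_or_student", "antidep"],
}


def fit_spectrum_logistic(
    windows: pd.DataFrame,
    predictor: str,
    outcome: str,
    model: int = 1,
    per_sd: bool = False,
) -> ModelResult:
    """Logistic fit of an EMA>1 status on a Fourier maximum power.

    ``windows`` holds one row per participant analysis window with the
    max-power predictor, the status outcome, and covariates.  ``model``
    selects the covariate set: 1 none; 2 age+sex; 3 +employment;
    4 +antidepressants.  ``per_sd`` standardizes the predictor so the OR
    is per SD rather than per raw power unit.
    """
    if model not in _MODEL_COVARIATES:
        raise ValueError("model must be 1, 2, 3 or 4")
    data = windows.dropna(subset=[predictor, outcome]).copy()
    if per_sd:
        sd = data[predictor].std(ddof=0)
        if sd == 0:
            raise ValueError("zero-variance predictor")
        data[predictor] = data[predictor] / sd
    X = data[[predictor] + _MODEL_COVARIATES[model]]
    return _fit_logit(X, data[outcome].to_numpy(float), f"spectrum:model{model}")


# ---------------------------------------------------------------------------
# design


def sample_size_correlation(r: float, alpha: float, power: float) -> int:
    """Required n to detect correlation r (Fisher z method).

    n = ceil(((z_{1-alpha/2} + z_power) / C)^2) + 3 with
    C = 0.5 ln((1+r)/(1-r)).  r = 0.5, alpha = .05, power = .90 -> 38.
    """
    if not (0 < r < 1 and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("require 0 < r < 1, 0 < alpha < 1, 0 < power < 1")
    c = 0.5 * math.log((1 + r) / (1 - r))
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return max(int(math.ceil((z / c) ** 2)), 1) + 3
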