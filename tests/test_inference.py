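"""Statistical layer: worked examples, hand-rolled rank-test oracles,
VIF pruning, logistic-model contracts, and the Fisher-z sample size."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mobispect import inference as inf


# ---------------------------------------------------------------------------
# mood-fluctuation rates


def rows_with_counts(count, total):
    scores = np.ones(total)
    scores[:count] = 3.0
    return pd.DataFrame({"ema_dep": scores})


@pytest.mark.parametrize(
    "count,total,expected",
    [(1577, 3584, 44), (716, 1504, 48), (103, 1148, 9)],
)
def test_mood_fluctuation_rounds_to_printed_percent(count, total, expected):
    pct, c, n = inf.mood_fluctuation_rate(rows_with_counts(count, total), "ema_dep")
    assert (c, n) == (count, total)
    assert round(pct) == expected


def test_mood_fluctuation_all_ones_zero():
    pct, c, n = inf.mood_fluctuation_rate(rows_with_counts(0, 50), "ema_dep")
    assert pct == 0.0 and c == 0


def test_mood_fluctuation_no_scores_raises():
    with pytest.raises(ValueError):
        inf.mood_fluctuation_rate(pd.DataFrame({"ema_dep": [np.nan]}), "ema_dep")


# ---------------------------------------------------------------------------
# rank tests


def kruskal_oracle(samples):
    """Tie-corrected H from the rank formula, written independently."""
    pooled = np.concatenate(samples)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    idx = 0
    h = 0.0
    for s in samples:
        r = ranks[idx : idx + len(s)]
        idx += len(s)
        h += r.sum() ** 2 / len(s)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def test_kruskal_all_equal_h_zero():
    h, p = inf.kruskal_wallis([np.ones(5), np.ones(4), np.ones(3)])
    assert h == 0.0


def test_kruskal_hand_value():
    h, p = inf.kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6]), np.array([7, 8, 9])])
    assert math.isclose(h, 7.2, rel_tol=1e-9)


def test_kruskal_matches_rank_formula_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        samples = [
            rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
            for _ in range(rng.integers(2, 5))
        ]
        if np.ptp(np.concatenate(samples)) == 0:
            continue
        h, _ = inf.kruskal_wallis(samples)
        assert math.isclose(h, kruskal_oracle(samples), rel_tol=1e-9)


def test_kruskal_monotone_transform_invariant():
    rng = np.random.default_rng(1)
    samples = [rng.normal(size=8), rng.normal(1, 1, size=6), rng.normal(size=7)]
    h1, _ = inf.kruskal_wallis(samples)
    h2, _ = inf.kruskal_wallis([np.exp(s) for s in samples])
    assert math.isclose(h1, h2, rel_tol=1e-12)


def test_kruskal_empty_group_raises():
    with pytest.raises(ValueError):
        inf.kruskal_wallis([np.array([1.0]), np.array([])])


def mw_oracle(a, b):
    """U, mean ranks, and the asymptotic tie-corrected p, from scratch."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na, nb = len(a), len(b)
    ra = ranks[:na].sum()
    u_a = ra - na * (na + 1) / 2
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var_u = na * nb / 12.0 * (n + 1 - tie_term)
    mu = na * nb / 2.0
    if var_u == 0:
        p = 1.0
    else:
        z = (u_a - mu) / math.sqrt(var_u)
        p = 2 * stats.norm.sf(abs(z))
    return u_a, min(p, 1.0), ranks[:na].mean(), ranks[na:].mean()


def test_mw_worked_example():
    u, p, ra, rb = inf.mann_whitney_mean_ranks(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
    assert u == 0.0 and ra == 1.5 and rb == 3.5


def test_mw_identical_samples_equal_ranks():
    x = np.array([2.0, 2.0, 5.0])
    _, _, ra, rb = inf.mann_whitney_mean_ranks(x, x)
    assert ra == rb


def test_mw_matches_hand_formula():
    rng = np.random.default_rng(2)
    for _ in range(100):
        a = rng.integers(0, 10, size=rng.integers(3, 15)).astype(float)
        b = rng.integers(0, 10, size=rng.integers(3, 15)).astype(float)
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        u, p, ra, rb = inf.mann_whitney_mean_ranks(a, b)
        ou, op, ora, orb = mw_oracle(a, b)
        # scipy reports U for the first sample
        assert math.isclose(u, ou, abs_tol=1e-9)
        assert math.isclose(p, op, rel_tol=1e-9)
        assert math.isclose(ra, ora) and math.isclose(rb, orb)


def test_mw_rank_sum_identity():
    rng = np.random.default_rng(3)
    for _ in range(50):
        a = rng.normal(size=rng.integers(2, 20))
        b = rng.normal(size=rng.integers(2, 20))
        _, _, ra, rb = inf.mann_whitney_mean_ranks(a, b)
        n = len(a) + len(b)
        assert math.isclose(len(a) * ra + len(b) * rb, n * (n + 1) / 2, rel_tol=1e-12)


# ---------------------------------------------------------------------------
# correlation windows


def test_correlation_linear_pair():
    rows = pd.DataFrame(
        {
            "participant_id": "p",
            "date": pd.date_range("2020-03-02", periods=10),
            "LV": np.arange(10.0),
            "ema_dep": 1.0 + np.arange(10.0) / 3.0,
        }
    )
    out = inf.correlate_by_timescale(rows, ["LV"], "ema_dep", "daily")
    assert math.isclose(out.loc[0, "r"], 1.0, abs_tol=1e-12)


def test_correlation_constant_feature_flagged():
    rows = pd.DataFrame(
        {
            "participant_id": "p",
            "date": pd.date_range("2020-03-02", periods=10),
            "LV": 3.0,
            "ema_dep": np.linspace(1, 5, 10),
        }
    )
    out = inf.correlate_by_timescale(rows, ["LV"], "ema_dep", "daily")
    assert not out.loc[0, "defined"]


def test_weekly_windows_average_before_correlating():
    dates = pd.date_range("2020-03-02", periods=28)
    rows = pd.DataFrame(
        {
            "participant_id": "p",
            "date": dates,
            "LV": np.repeat([0.0, 10.0, 0.0, 10.0], 7) + np.tile(np.arange(7.0), 4) * 0,
            "ema_dep": np.repeat([1.0, 3.0, 1.0, 3.0], 7),
        }
    )
    out = inf.correlate_by_timescale(rows, ["LV"], "ema_dep", "weekly")
    assert out.loc[0, "n"] == 4
    assert math.isclose(out.loc[0, "r"], 1.0, abs_tol=1e-9)


# ---------------------------------------------------------------------------
# VIF


def test_vif_duplicate_column_removed_once():
    rng = np.random.default_rng(4)
    a = rng.normal(size=100)
    X = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=100)})
    kept = inf.vif_prune(X)
    assert sorted(kept) == ["a", "c"]


def test_vif_orthogonal_untouched():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
    assert inf.vif_prune(X) == list("abcd")


def test_vif_matches_regression_oracle():
    rng = np.random.default_rng(6)
    for _ in range(100):
        n = 60
        z = rng.normal(size=n)
        X = pd.DataFrame(
            {
                "a": z + rng.normal(scale=0.5, size=n),
                "b": z + rng.normal(scale=0.5, size=n),
                "c": rng.normal(size=n),
            }
        )
        M = X.to_numpy()
        for i, col in enumerate(X.columns):
            # oracle: R^2 via numpy polyfit-like least squares
            others = np.delete(M, i, axis=1)
            A = np.column_stack([np.ones(n), others])
            coef, *_ = np.linalg.lstsq(A, M[:, i], rcond=None)
            resid = M[:, i] - A @ coef
            r2 = 1 - resid.var() / M[:, i].var()
            oracle = 1.0 / (1.0 - r2)
            assert math.isclose(inf._vif(M, i), oracle, rel_tol=1e-6)


# ---------------------------------------------------------------------------
# logistic contracts


def synth_logit_data(seed=0, n=500):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    logits = -0.3 + 0.8 * x - 0.5 * z
    y = rng.random(n) < 1 / (1 + np.exp(-logits))
    return pd.DataFrame({"x": x, "z": z}), y.astype(float)


def test_logit_rescaling_equivariance():
    X, y = synth_logit_data()
    r1 = inf._fit_logit(X, y, "m")
    X2 = X.assign(x=X["x"] * 100)
    r2 = inf._fit_logit(X2, y, "m")
    assert math.isclose(r1.term("x")["beta"], r2.term("x")["beta"] * 100, rel_tol=1e-6)
    assert math.isclose(r1.term("z")["p"], r2.term("z")["p"], rel_tol=1e-6)


def test_logit_centering_invariance():
    X, y = synth_logit_data(1)
    r1 = inf._fit_logit(X, y, "m")
    X2 = X.assign(z=X["z"] + 50.0)
    r2 = inf._fit_logit(X2, y, "m")
    assert math.isclose(r1.term("x")["or_"], r2.term("x")["or_"], rel_tol=1e-6)


def test_logit_or_is_exp_beta_and_ci_ordered():
    X, y = synth_logit_data(2)
    r = inf._fit_logit(X, y, "m")
    for _, row in r.terms.iterrows():
        assert math.isclose(row["or_"], math.exp(row["beta"]), rel_tol=1e-12)
        assert row["ci_low"] <= row["or_"] <= row["ci_high"]


def test_logit_constant_outcome_raises():
    X, _ = synth_logit_data(3)
    with pytest.raises(ValueError):
        inf._fit_logit(X, np.ones(len(X)), "m")


def test_logit_separation_names_term():
    n = 60
    x = np.concatenate([np.zeros(30), np.ones(30)])
    y = x.copy()
    X = pd.DataFrame({"sep": x, "noise": np.random.default_rng(7).normal(size=n)})
    with pytest.raises(ValueError, match="sep"):
        inf._fit_logit(X, y, "m")


def test_spectrum_model_covariate_sets():
    rng = np.random.default_rng(8)
    n = 300
    df = pd.DataFrame(
        {
            "power": rng.normal(10, 3, n),
            "age": rng.uniform(20, 65, n),
            "female": rng.integers(0, 2, n).astype(float),
            "employee_or_student": rng.integers(0, 2, n).astype(float),
            "antidep": rng.integers(0, 2, n).astype(float),
        }
    )
    df["dep"] = (rng.random(n) < 1 / (1 + np.exp(0.2 * (df["power"] - 10)))).astype(float)
    r1 = inf.fit_spectrum_logistic(df, "power", "dep", model=1)
    r4 = inf.fit_spectrum_logistic(df, "power", "dep", model=4)
    assert set(r1.terms.index) == {"const", "power"}
    assert {"age", "female", "employee_or_student", "antidep"} <= set(r4.terms.index)
    # no confounding in the generator: ORs agree within Monte-Carlo error
    assert abs(r1.term("power")["beta"] - r4.term("power")["beta"]) < 0.1


def test_spectrum_model_per_sd_scaling():
    rng = np.random.default_rng(9)
    n = 400
    df = pd.DataFrame({"power": rng.normal(0, 5, n)})
    df["dep"] = (rng.random(n) < 1 / (1 + np.exp(-0.3 * df["power"]))).astype(float)
    raw = inf.fit_spectrum_logistic(df, "power", "dep", model=1)
    sd = inf.fit_spectrum_logistic(df, "power", "dep", model=1, per_sd=True)
    factor = df["power"].std(ddof=0)
    assert math.isclose(sd.term("power")["beta"], raw.term("power")["beta"] * factor, rel_tol=1e-6)


# ---------------------------------------------------------------------------
# sample size


@pytest.mark.parametrize(
    "r,alpha,power,expected",
    [(0.5, 0.05, 0.90, 38), (0.9999, 0.05, 0.90, 4), (0.5, 0.05, 0.80, 30)],
)
def test_fisher_z_sample_size(r, alpha, power, expected):
    assert inf.sample_size_correlation(r, alpha, power) == expected


def test_fisher_z_domain_errors():
    for bad in [(1.2, 0.05, 0.9), (0.5, 0.0, 0.9), (0.5, 0.05, 1.0)]:
        with pytest.raises(ValueError):
            inf.sample_size_correlation(*bad)
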