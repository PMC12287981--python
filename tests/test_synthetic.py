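"""Generator contracts: determinism, calibration, duty cycle, emission
geometry, and the on-disk dialects."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mobispect.config import CohortConfig, ConfigError
from mobispect import synthetic as syn
from mobispect import preprocessing as pre


# ---------------------------------------------------------------------------
# cohort


def test_cohort_counts_and_groups():
    cfg = CohortConfig(n_hc=15, n_bp=20, n_mdd=27, n_days=28, seed=0)
    cohort = syn.generate_cohort(cfg)
    assert len(cohort) == 62
    assert {p.group for p in cohort} == {"HC", "BP", "MDD"}
    assert sum(p.group == "BP" for p in cohort) == 20


def test_empty_cohort():
    cfg = CohortConfig(n_hc=0, n_bp=0, n_mdd=0, n_days=28, seed=0)
    assert syn.generate_cohort(cfg) == []


def test_cohort_deterministic(small_config):
    a = syn.generate_cohort(small_config)
    b = syn.generate_cohort(small_config)
    assert a == b


def test_cluster_centers_separated(small_cohort):
    for p in small_cohort:
        pts = {}
        for name in ("home", "work", "other"):
            c = getattr(p, name)
            pts[name] = (c.lat * 111320.0, c.lon * 111320.0 * math.cos(math.radians(c.lat)))
        for a in ("home", "work"):
            for b in ("work", "other"):
                if a != b:
                    d = math.dist(pts[a], pts[b])
                    assert d >= 200.0


def test_invalid_config_names_field():
    with pytest.raises(ConfigError, match="n_hc"):
        CohortConfig(n_hc=-1)
    with pytest.raises(ConfigError, match="missing_day_prob"):
        CohortConfig(missing_day_prob=1.5)
    with pytest.raises(ConfigError, match="bp_periods"):
        CohortConfig(n_days=10, bp_periods=(1.0, 9.0))


# ---------------------------------------------------------------------------
# mood


def test_hc_mood_rate_matches_configured_target():
    """Realized EMA>1 fraction in controls sits near the configured 9%."""
    cfg = CohortConfig(n_hc=30, n_bp=0, n_mdd=0, n_days=60, seed=21)
    hits = total = 0
    for p in syn.generate_cohort(cfg):
        m = syn.simulate_mood_series(p, cfg)
        scored = m["ema_dep"].dropna()
        hits += (scored > 1).sum()
        total += len(scored)
    assert total >= 1000
    rate = 100.0 * hits / total
    assert abs(rate - 9.0) <= 3.0


def test_zero_amplitude_zero_noise_constant_mood():
    cfg = CohortConfig(
        n_hc=0, n_bp=1, n_mdd=0, n_days=28, seed=3,
        bp_amplitude=0.0, mood_noise_sd=0.0,
    )
    p = syn.generate_cohort(cfg)[0]
    m = syn.simulate_mood_series(p, cfg)
    assert np.allclose(m["latent_dep"], m["latent_dep"].iloc[0])


def test_bp_four_day_cycle_autocorrelation():
    """A single 4-day mood cycle peaks the autocorrelation at lag 4."""

    def autocorr(x, lag):  # brute-force oracle
        x = x - x.mean()
        return float(np.sum(x[:-lag] * x[lag:]) / np.sum(x * x))

    cfg = CohortConfig(
        n_hc=0, n_bp=1, n_mdd=0, n_days=56, seed=5,
        bp_periods=(4.0,), mood_noise_sd=0.0,
    )
    p = syn.generate_cohort(cfg)[0]
    latent = syn.simulate_mood_series(p, cfg)["latent_dep"].to_numpy()
    acs = {lag: autocorr(latent, lag) for lag in range(2, 15)}
    assert max(acs, key=acs.get) == 4


def test_ema_items_in_range(small_config, small_cohort):
    for p in small_cohort:
        m = syn.simulate_mood_series(p, small_config)
        for item in syn.EMA_ITEMS:
            scored = m[item].dropna()
            assert scored.between(1, 5).all()


def test_depressed_days_have_lower_mobility():
    """Construction validity: with positive mood effects, depressed days
    carry lower LV and TT than non-depressed days."""
    cfg = CohortConfig(n_hc=0, n_bp=6, n_mdd=8, n_days=90, seed=9)
    lv = {True: [], False: []}
    tt = {True: [], False: []}
    for p in syn.generate_cohort(cfg):
        m = syn.simulate_mood_series(p, cfg)
        f = syn.simulate_day_features(p, m, cfg)
        joined = f.merge(m[["date", "ema_dep", "weekday"]], on="date")
        joined = joined.dropna(subset=["ema_dep"])
        wk = joined[joined["weekday_x"].astype(bool)]
        for dep, grp in wk.groupby(wk["ema_dep"] > 1):
            lv[dep].append(grp["LV"].mean())
            tt[dep].append(grp["TT"].mean())
    assert np.mean(lv[True]) < np.mean(lv[False])
    assert np.mean(tt[True]) < np.mean(tt[False])


# ---------------------------------------------------------------------------
# trajectories & duty cycle


def test_zero_mobility_scale_stays_home(small_config):
    p0 = syn.generate_cohort(small_config)[0]
    p = syn.Participant(**{**p0.__dict__, "baseline_mobility_scale": 0.0})
    cfg = small_config.with_(missing_day_prob=0.0, gps_noise_sd=2.0)
    m = syn.simulate_mood_series(p, cfg)
    fx = syn.simulate_day_trajectory(p, m.iloc[0], cfg)
    x, y = syn._latlon_to_xy(fx["lat"], fx["lon"], p.home.lat, p.home.lon)
    r = np.hypot(x, y)
    # within the home stay radius plus a generous noise margin
    assert r.max() < 0.3 * p.home.radius_m + 6 * cfg.gps_noise_sd


def test_hourly_fix_count_matches_duty_cycle(small_config):
    cfg = small_config.with_(
        missing_day_prob=0.0, missing_hour_prob=0.0, gps_noise_sd=0.0
    )
    p = syn.generate_cohort(cfg)[0]
    m = syn.simulate_mood_series(p, cfg)
    fx = syn.simulate_day_trajectory(p, m.iloc[0], cfg)
    # long-run average per hour ~ 327; day total within 24 of 24*327.27
    assert abs(len(fx) / 24.0 - 327.27) <= 1.0


def test_noiseless_round_trip_path_length(small_config):
    """One home->work->home trip: chained fix distances ~ 2x separation."""
    cfg = small_config.with_(gps_noise_sd=0.0, missing_day_prob=0.0, missing_hour_prob=0.0)
    p = syn.generate_cohort(cfg)[0]
    rng = cfg.rng(99)
    wt, wx, wy = syn.build_day_waypoints(p, 0.0, True, cfg, rng)
    ts = syn._on_cycle_times(cfg)
    x = np.interp(ts, wt, wx)
    y = np.interp(ts, wt, wy)
    td = float(np.hypot(np.diff(x), np.diff(y)).sum())
    # waypoints bound the truth: total straight-line tour length
    truth = float(
        np.hypot(np.diff(np.asarray(wx)), np.diff(np.asarray(wy))).sum()
    )
    assert truth > 0
    assert abs(td - truth) / truth < 0.01


def test_accuracy_field_exceeds_50m_at_configured_rate(small_config):
    cfg = small_config.with_(missing_day_prob=0.0, accuracy_exceed_prob=0.1)
    p = syn.generate_cohort(cfg)[0]
    m = syn.simulate_mood_series(p, cfg)
    acc = np.concatenate(
        [
            syn.simulate_day_trajectory(p, m.iloc[d], cfg)["accuracy"].to_numpy()
            for d in range(5)
        ]
    )
    frac = (acc > 50).mean()
    assert abs(frac - 0.1) < 0.02


def test_duty_cycle_no_off_is_identity():
    fixes = pd.DataFrame({"t": np.arange(100.0), "lat": 0.0, "lon": 0.0, "accuracy": 5.0})
    out = syn.apply_duty_cycle(fixes, 60, 0)
    assert len(out) == len(fixes)


def test_duty_cycle_negative_duration_raises():
    fixes = pd.DataFrame({"t": [0.0], "lat": [0.0], "lon": [0.0], "accuracy": [5.0]})
    with pytest.raises(ValueError):
        syn.apply_duty_cycle(fixes, 60, -1)


@given(
    on=st.integers(10, 120),
    off=st.integers(0, 900),
    phase=st.integers(0, 800),
)
def test_duty_cycle_modular_property(on, off, phase):
    """Every retained fix satisfies (t - day_start) mod (on+off) < on."""
    t = np.arange(phase, phase + 3000, 7.0)
    fixes = pd.DataFrame({"t": t, "lat": 0.0, "lon": 0.0, "accuracy": 5.0})
    out = syn.apply_duty_cycle(fixes, on, off, day_start=0.0)
    if off == 0:
        assert len(out) == len(fixes)
    else:
        kept = out["t"].to_numpy()
        assert np.all((kept % (on + off)) < on)
        dropped = np.setdiff1d(t, kept)
        assert np.all((dropped % (on + off)) >= on)


@pytest.mark.parametrize(
    "on,off,rate,expected",
    [(60, 600, 1, 327), (60, 0, 1, 3600), (30, 570, 1, 180)],
)
def test_expected_fix_count(on, off, rate, expected):
    assert syn.expected_fix_count(on, off, rate) == expected


def test_expected_fix_count_invalid():
    with pytest.raises(ValueError):
        syn.expected_fix_count(0, 600, 1)
    with pytest.raises(ValueError):
        syn.expected_fix_count(60, 600, 0)


@given(on=st.integers(10, 120), off=st.integers(0, 900))
def test_duty_cycle_count_matches_expectation(on, off):
    """Retained count over a full day agrees with the expected hourly
    rate within +/-1 fix per hour."""
    t = np.arange(0.0, 86400.0)
    fixes = pd.DataFrame({"t": t, "lat": 0.0, "lon": 0.0, "accuracy": 5.0})
    out = syn.apply_duty_cycle(fixes, on, off, day_start=0.0)
    per_hour = len(out) / 24.0
    # the day's fractional final cycle contributes at most `on` extra
    # fixes spread over 24 h, plus the rounding of the expectation
    assert abs(per_hour - syn.expected_fix_count(on, off, 1)) <= on / 24.0 + 0.5


# ---------------------------------------------------------------------------
# on-disk round trips


def test_gps_csv_round_trip(tmp_path, small_config):
    cfg = small_config.with_(missing_day_prob=0.0)
    p = syn.generate_cohort(cfg)[0]
    m = syn.simulate_mood_series(p, cfg)
    fx = syn.simulate_day_trajectory(p, m.iloc[0], cfg)
    path = tmp_path / "gps.csv"
    syn.write_gps_csv(fx, path)
    back = pre.read_gps_csv(path)
    assert len(back) == len(fx)
    np.testing.assert_allclose(back["lat"], fx["lat"], rtol=0, atol=1e-12)
    np.testing.assert_allclose(back["lon"], fx["lon"], rtol=0, atol=1e-12)
    np.testing.assert_allclose(back["t"], fx["t"], rtol=0, atol=1e-3)
    # n fixes -> n+1 lines
    assert path.read_text().strip().count("\n") == len(fx)


def test_gps_csv_empty(tmp_path):
    path = tmp_path / "empty.csv"
    syn.write_gps_csv(pd.DataFrame(columns=["t", "lat", "lon", "accuracy"]), path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("timestamp,")


def test_ema_csv_round_trip(tmp_path, small_config, small_cohort):
    m = syn.simulate_mood_series(small_cohort[0], small_config)
    path = tmp_path / "ema.csv"
    syn.write_ema_csv(m, path)
    back = pre.read_ema_csv(path)
    assert set(back.columns) == {"participant_id", "date", "prompt", "item", "score"}
    scored_days = m[syn.EMA_ITEMS[0]].notna().sum()
    assert back.groupby("date").ngroups == scored_days
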