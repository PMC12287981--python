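"""Synthetic cohort generator: duty-cycled GPS trajectories and daily mood EMA.

The generator emulates a three-group prospective smartphone study
(healthy controls, bipolar disorder, major depressive disorder) in which
each participant carries a phone that records GPS at 1 Hz for 60 s out of
every 660 s, and answers a daily four-item mood survey (depression,
mania, fatigue, irritability; each 1-5).

Three emission tiers share one latent mood/mobility process:

* :func:`simulate_mood_series` - daily latent mood and discretized EMA
  items.  Bipolar mood follows a sum of sinusoids at configurable
  multi-day periods; unipolar depression follows a bounded aperiodic
  drift; controls are stable.
* :func:`simulate_day_features` / :func:`simulate_hourly_features` -
  day-level mobility features and hourly LV/entropy series emitted
  directly from the latent process (used for statistical-power studies
  where raw 1 Hz emission would be wasteful).
* :func:`simulate_day_trajectory` - raw GPS fixes: a piecewise-linear
  home/work/other excursion path, duty-cycled, with isotropic position
  noise and a lognormal reported-accuracy field.

Depressed mood reduces mobility multiplicatively (excursion rate,
away-time fraction, location diversity), so depressed days have lower
location variance, transition time and entropy by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import CohortConfig, ConfigError

__all__ = [
    "Participant",
    "ClusterSpec",
    "generate_cohort",
    "simulate_mood_series",
    "simulate_day_features",
    "simulate_hourly_features",
    "simulate_day_trajectory",
    "simulate_cohort_tables",
    "apply_duty_cycle",
    "expected_fix_count",
    "write_gps_csv",
    "write_ema_csv",
    "write_cohort_csv",
]

#: study epoch: local midnight of the first follow-up day (a Monday),
#: expressed in UTC seconds.  All participants share one fixed timezone
#: offset (UTC+8; the emulated catchment area has no daylight saving).
STUDY_START_UTC = 1583078400.0
TZ_OFFSET_S = 8 * 3600
START_DATE = pd.Timestamp("2020-03-02")

EMA_ITEMS = ("ema_dep", "ema_mania", "ema_fatigue", "ema_irrit")

DAY_S = 86400.0
M_PER_DEG_LAT = 111320.0

# group-level latent mood anchors (units of mood_noise_sd)
_DEP_BASELINE = {"HC": 0.0, "BP": 1.2, "MDD": 1.2}
_MANIA_BASELINE = {"HC": 0.0, "BP": 1.4, "MDD": 0.25}


@dataclass(frozen=True)
class ClusterSpec:
    """A significant location: center coordinates and a stay radius."""

    lat: float
    lon: float
    radius_m: float


@dataclass(frozen=True)
class Participant:
    index: int
    id: str
    group: str  # HC / BP / MDD
    age: float
    sex: str  # F / M
    employment: str  # unemployed / employed / student / retired
    antidepressant: bool
    home: ClusterSpec
    work: ClusterSpec
    other: ClusterSpec
    baseline_mobility_scale: float
    tz_offset_s: int = TZ_OFFSET_S


# ---------------------------------------------------------------------------
# cohort


def _draw_cluster_layout(rng: np.random.Generator) -> tuple[ClusterSpec, ...]:
    """Home/work/other centers, pairwise >= 200 m apart."""
    home = (25.03 + rng.uniform(-0.05, 0.05), 121.50 + rng.uniform(-0.05, 0.05))
    coslat = math.cos(math.radians(home[0]))

    def offset(dist_m: float, bearing: float) -> tuple[float, float]:
        dy = dist_m * math.cos(bearing)
        dx = dist_m * math.sin(bearing)
        return home[0] + dy / M_PER_DEG_LAT, home[1] + dx / (M_PER_DEG_LAT * coslat)

    while True:
        work = offset(rng.uniform(2000, 8000), rng.uniform(0, 2 * math.pi))
        other = offset(rng.uniform(500, 3000), rng.uniform(0, 2 * math.pi))
        dwork_other = (
            math.hypot(
                (work[0] - other[0]) * M_PER_DEG_LAT,
                (work[1] - other[1]) * M_PER_DEG_LAT * coslat,
            )
        )
        if dwork_other >= 200.0:
            break
    return (
        ClusterSpec(home[0], home[1], 60.0),
        ClusterSpec(work[0], work[1], 80.0),
        ClusterSpec(other[0], other[1], 100.0),
    )


def generate_cohort(config: CohortConfig) -> list[Participant]:
    """Draw the participant roster with demographic covariates.

    Deterministic given ``config.seed``; each participant's covariates
    come from an independent spawned stream, so cohorts of different
    sizes agree on their shared prefix.
    """
    groups = ["HC"] * config.n_hc + ["BP"] * config.n_bp + ["MDD"] * config.n_mdd
    cohort: list[Participant] = []
    counters: dict[str, int] = {}
    for idx, group in enumerate(groups):
        rng = config.rng(idx, 0)
        counters[group] = counters.get(group, 0) + 1
        age = float(np.clip(rng.normal(41.0, 12.0), 20.0, 65.0))
        sex = "F" if rng.random() < 0.65 else "M"
        employment = rng.choice(
            ["unemployed", "employed", "student", "retired"],
            p=[0.21, 0.58, 0.11, 0.10],
        )
        antidep = bool(group != "HC" and rng.random() < 0.7)
        home, work, other = _draw_cluster_layout(rng)
        bms = float(rng.lognormal(0.0, 0.25))
        cohort.append(
            Participant(
                index=idx,
                id=f"{group}{counters[group]:02d}",
                group=group,
                age=age,
                sex=sex,
                employment=str(employment),
                antidepressant=antidep,
                home=home,
                work=work,
                other=other,
                baseline_mobility_scale=bms,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# latent mood


def _bounded_walk(
    rng: np.random.Generator,
    n: int,
    sd: float,
    phi: float = 0.75,
) -> np.ndarray:
    """Bounded aperiodic drift: stationary AR(1) with day-scale memory.

    Mean reversion (memory ~1/(1-phi) days, about a week at the default)
    keeps the drift bounded and models mood episodes of finite duration
    rather than an unbounded wander.
    """
    w = np.empty(n)
    innov = sd * math.sqrt(1.0 - phi * phi)
    x = rng.normal(0.0, sd)
    for i in range(n):
        x = phi * x + rng.normal(0.0, innov)
        w[i] = x
    return w


def _dep_cuts(config: CohortConfig) -> np.ndarray:
    sd = max(config.mood_noise_sd, 1e-9)
    c1 = sd * norm.ppf(1.0 - config.hc_dep_rate)
    return c1 + sd * np.array([0.0, 1.0, 2.0, 3.0])


def _mania_cuts(config: CohortConfig) -> np.ndarray:
    sd = max(config.mood_noise_sd, 1e-9)
    c1 = sd * norm.ppf(1.0 - config.hc_mania_rate)
    return c1 + sd * np.array([0.0, 1.0, 2.0, 3.0])


def _discretize(latent: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    """Monotone 1-5 score: 1 + number of cut-points below the latent value."""
    return 1 + np.searchsorted(cuts, latent, side="left").astype(int)


def simulate_mood_series(participant: Participant, config: CohortConfig) -> pd.DataFrame:
    """Daily latent mood and EMA items for one participant.

    Bipolar latent depressed mood is a baseline plus sinusoids at
    ``bp_periods`` (per-tone amplitude ``bp_amplitude / len(bp_periods)``
    on the latent scale) plus iid noise; unipolar depression a baseline
    plus a bounded random walk; controls baseline plus noise.  EMA items
    are fixed-threshold discretizations of latent mood into 1-5, with the
    lowest cut placed so controls exceed score 1 on a configured fraction
    of days.  Prompt compliance: each day independently loses both
    prompts with ``ema_missing_both_prob``, else the primary prompt with
    ``ema_missing_primary_prob`` (the 17:00 fallback is then used).
    """
    if config.n_days < 1:
        raise ConfigError("invalid field 'n_days': must be >= 1")
    rng = config.rng(participant.index, 1)
    n = config.n_days
    days = np.arange(n)

    disp = config.mood_dispersion
    base_dep = _DEP_BASELINE[participant.group] + (
        rng.normal(0.0, disp) if disp > 0 else 0.0
    )
    base_mania = _MANIA_BASELINE[participant.group] + (
        rng.normal(0.0, disp) if disp > 0 else 0.0
    )

    if participant.group == "BP":
        amp = config.bp_amplitude / max(len(config.bp_periods), 1)
        phases_d = rng.uniform(0, 2 * np.pi, size=len(config.bp_periods))
        phases_m = rng.uniform(0, 2 * np.pi, size=len(config.bp_periods))
        osc_dep = sum(
            amp * np.sin(2 * np.pi * days / T + ph)
            for T, ph in zip(config.bp_periods, phases_d)
        )
        osc_mania = sum(
            amp * np.sin(2 * np.pi * days / T + ph)
            for T, ph in zip(config.bp_periods, phases_m)
        )
    elif participant.group == "MDD":
        osc_dep = _bounded_walk(rng, n, 1.6 * config.mdd_amplitude)
        osc_mania = np.zeros(n)
    else:
        osc_dep = np.zeros(n)
        osc_mania = np.zeros(n)

    sd = config.mood_noise_sd
    latent_dep = base_dep + osc_dep + rng.normal(0.0, sd, size=n)
    latent_mania = base_mania + osc_mania + rng.normal(0.0, sd, size=n)
    latent_fat = 0.7 * latent_dep + rng.normal(0.0, 0.71 * sd, size=n)
    latent_irr = 0.6 * latent_mania + 0.3 * latent_dep + rng.normal(0.0, 0.74 * sd, size=n)

    dep_cuts, mania_cuts = _dep_cuts(config), _mania_cuts(config)
    scores = {
        "ema_dep": _discretize(latent_dep, dep_cuts).astype(float),
        "ema_mania": _discretize(latent_mania, mania_cuts).astype(float),
        "ema_fatigue": _discretize(latent_fat, dep_cuts).astype(float),
        "ema_irrit": _discretize(latent_irr, mania_cuts).astype(float),
    }

    u = rng.random(n)
    prompt = np.where(
        u < config.ema_missing_both_prob,
        "missing",
        np.where(u < config.ema_missing_both_prob + config.ema_missing_primary_prob,
                 "fallback", "primary"),
    )
    for k in scores:
        scores[k] = np.where(prompt == "missing", np.nan, scores[k])

    dates = START_DATE + pd.to_timedelta(days, unit="D")
    return pd.DataFrame(
        {
            "participant_id": participant.id,
            "day": days,
            "date": dates,
            "weekday": dates.dayofweek < 5,
            "latent_dep": latent_dep,
            "latent_mania": latent_mania,
            **scores,
            "prompt": prompt,
        }
    )


# ---------------------------------------------------------------------------
# mobility multipliers


def _multipliers(latent_dep: float, weekday: bool, config: CohortConfig, baseline: float = 0.0):
    """Multiplicative mobility reductions for one day.

    Depressed mood above the person's typical level shrinks excursion
    rate and away-time on weekdays (routine-bound travel) and location
    diversity on weekends.  Coupling to the *deviation* from the
    person's baseline — rather than to absolute severity — models
    behavioral habituation: chronic severity settles into the person's
    routine, while transient worsening suppresses that day's mobility.
    """
    e1, e2, e3 = config.mood_effect
    m = max(float(latent_dep) - baseline, 0.0)
    if weekday:
        return (1 - e1) ** m, (1 - e2) ** m, 1.0
    return 1.0, 1.0, (1 - e3) ** m


# ---------------------------------------------------------------------------
# day-level feature emulator


def simulate_day_features(
    participant: Participant, moods: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Emit the eight daily mobility features directly from latent mood.

    Statistical twin of the full trajectory path: the same multiplicative
    mood couplings act on per-participant baselines, with lognormal /
    Gaussian day-to-day noise.  Entropy is emitted as a fraction of
    ln(NC), so ``entropy <= ln(NC)`` holds by construction.
    """
    rng = config.rng(participant.index, 3)
    bms = participant.baseline_mobility_scale
    # people's activity-space variances span orders of magnitude, so the
    # person-level LV baseline spread is a couple of log-units
    lv_base = 9.0 + 2.0 * math.log(bms + 1e-9) + rng.normal(0.0, 2.0)
    tt_base = 0.15 * bms
    baseline = _DEP_BASELINE[participant.group]
    rows = []
    for rec in moods.itertuples(index=False):
        # mood acts on specific feature families in specific contexts:
        # spatial range (LV) and travel time (TT) on weekdays, location
        # diversity (entropy, NC) on weekends; each family sees the
        # day's mood elevation through its own noisy realization, so
        # the coupled features are correlated mood proxies rather than
        # transforms of one scalar.  The remaining features vary with
        # the person's scale and day noise only.
        def chan(channel_noise_sd: float = 0.4):
            return _multipliers(
                rec.latent_dep + rng.normal(0.0, channel_noise_sd),
                bool(rec.weekday),
                config,
                baseline,
            )

        f_exc, f_away, _ = chan()
        scale_lv = f_exc * f_away
        f_exc, f_away, _ = chan()
        scale_tt = f_exc * f_away
        _, _, f_div = chan()

        lv = lv_base + 2.0 * math.log(scale_lv) + rng.normal(0.0, 0.8)
        tt = float(np.clip(tt_base * scale_tt * rng.lognormal(0.0, 0.35), 0.0, 0.9))
        td = 3000.0 * bms * rng.lognormal(0.0, 0.5)
        sm = 1.2 * rng.lognormal(0.0, 0.25)
        sv = 0.8 * sm * sm * rng.lognormal(0.0, 0.4)
        nc = 1 + rng.poisson(2.5 * f_div)
        if nc > 1:
            frac = float(np.clip(0.55 * f_div + rng.normal(0.0, 0.15), 0.0, 1.0))
            ent = frac * math.log(nc)
        else:
            ent = 0.0
        homestay = float(np.clip(0.55 + 0.25 * (1 - scale_tt) + rng.normal(0.0, 0.10), 0.0, 1.0))
        rows.append(
            {
                "participant_id": participant.id,
                "date": rec.date,
                "weekday": bool(rec.weekday),
                "LV": lv,
                "SM": sm,
                "SV": sv,
                "NC": nc,
                "entropy": ent,
                "homestay": homestay,
                "TT": tt,
                "TD": td,
            }
        )
    return pd.DataFrame(rows)


def simulate_hourly_features(
    participant: Participant,
    config: CohortConfig,
    n_days: int | None = None,
    amplitude: float | None = None,
) -> pd.DataFrame:
    """Hourly LV and entropy series carrying the group rhythm signal.

    Bipolar series are per-tone sinusoids at ``bp_periods`` with
    amplitude ``bp_amplitude`` (entropy scaled by 0.15) over white noise
    ``hourly_noise_sd``; unipolar series replace the tones with a slow
    bounded daily drift whose contribution stays below the white noise,
    so their spectra are flat (aperiodic); control series are noise only.

    ``amplitude`` overrides the group oscillation/drift scale, which lets
    power studies compare groups at a chosen amplitude ratio.
    """
    n_days = config.n_days if n_days is None else n_days
    rng = config.rng(participant.index, 4)
    hours = np.arange(n_days * 24)
    t_days = hours / 24.0
    sd = config.hourly_noise_sd

    if participant.group == "BP":
        amp = config.bp_amplitude if amplitude is None else amplitude
        phases = rng.uniform(0, 2 * np.pi, size=len(config.bp_periods))
        signal = sum(
            amp * np.sin(2 * np.pi * t_days / T + ph)
            for T, ph in zip(config.bp_periods, phases)
        )
    elif participant.group == "MDD":
        amp = config.mdd_amplitude if amplitude is None else amplitude
        # mean-reverting hourly drift (AR(1), ~6 h correlation time):
        # aperiodic with a flat low-frequency spectrum, so no single
        # multi-day bin accumulates the drift's power the way a pure
        # random walk would
        phi = math.exp(-1.0 / 6.0)
        innov_sd = 0.8 * math.sqrt(1.0 - phi * phi)
        drift = np.empty(hours.size)
        val = rng.normal(0.0, 0.8)
        for i in range(hours.size):
            val = phi * val + rng.normal(0.0, innov_sd)
            drift[i] = val
        signal = amp * drift
    else:
        signal = np.zeros_like(t_days)

    lv = 9.0 + signal + rng.normal(0.0, sd, size=hours.size)
    ent = 1.0 + 0.15 * signal + rng.normal(0.0, 0.15 * sd, size=hours.size)
    dates = START_DATE + pd.to_timedelta(hours // 24, unit="D")
    return pd.DataFrame(
        {
            "participant_id": participant.id,
            "hour": hours,
            "date": dates,
            "LV": lv,
            "entropy": ent,
        }
    )


# ---------------------------------------------------------------------------
# trajectory emission


def _latlon_to_xy(lat, lon, ref_lat, ref_lon):
    y = (np.asarray(lat) - ref_lat) * M_PER_DEG_LAT
    x = (np.asarray(lon) - ref_lon) * M_PER_DEG_LAT * math.cos(math.radians(ref_lat))
    return x, y


def _xy_to_latlon(x, y, ref_lat, ref_lon):
    lat = ref_lat + np.asarray(y) / M_PER_DEG_LAT
    lon = ref_lon + np.asarray(x) / (M_PER_DEG_LAT * math.cos(math.radians(ref_lat)))
    return lat, lon


def build_day_waypoints(
    participant: Participant,
    latent_dep: float,
    weekday: bool,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Piecewise-linear day path (times s, x m, y m) relative to home.

    The day is a sequence of stays at home interleaved with excursions to
    work/other clusters; each stay is a fixed point inside the cluster
    radius, travel legs are straight at a sampled speed.  Depressed mood
    multiplicatively thins excursions and shortens away time.
    """
    ref = participant.home
    f_exc, f_away, f_div = _multipliers(
        latent_dep, weekday, config, _DEP_BASELINE[participant.group]
    )
    bms = participant.baseline_mobility_scale

    def cluster_point(c: ClusterSpec) -> tuple[float, float]:
        cx, cy = _latlon_to_xy(c.lat, c.lon, ref.lat, ref.lon)
        r = rng.uniform(0, 0.3 * c.radius_m)
        th = rng.uniform(0, 2 * np.pi)
        return float(cx + r * math.cos(th)), float(cy + r * math.sin(th))

    home_xy = cluster_point(ref)
    n_exc = int(rng.poisson(2.2 * bms * f_exc)) if bms > 0 else 0
    commuter = participant.employment in ("employed", "student")
    if weekday and commuter and bms > 0 and n_exc == 0 and f_exc > 0.55:
        n_exc = 1
    n_exc = min(n_exc, 4)

    times = [0.0]
    xs = [home_xy[0]]
    ys = [home_xy[1]]
    if n_exc > 0:
        window = (8 * 3600.0, 21 * 3600.0)
        slot = (window[1] - window[0]) / n_exc
        for i in range(n_exc):
            if weekday and commuter and i == 0:
                dest = participant.work
            else:
                dest = participant.other if rng.random() < 0.4 + 0.3 * f_div else participant.work
            dest_xy = cluster_point(dest)
            depart = window[0] + i * slot + rng.uniform(0, 0.2 * slot)
            dist = math.hypot(dest_xy[0] - home_xy[0], dest_xy[1] - home_xy[1])
            speed = rng.uniform(6.0, 12.0)
            travel = max(dist / speed, 1.0)
            stay = max(f_away * slot * rng.uniform(0.5, 0.85) - 2 * travel, 300.0)
            arrive = depart + travel
            leave = arrive + stay
            back = leave + travel
            if back >= min(window[0] + (i + 1) * slot, DAY_S - 60):
                back = min(window[0] + (i + 1) * slot, DAY_S - 60)
                leave = back - travel
                arrive = min(arrive, leave)
            times += [depart, arrive, leave, back]
            xs += [home_xy[0], dest_xy[0], dest_xy[0], home_xy[0]]
            ys += [home_xy[1], dest_xy[1], dest_xy[1], home_xy[1]]
    times.append(DAY_S)
    xs.append(home_xy[0])
    ys.append(home_xy[1])
    return np.asarray(times), np.asarray(xs), np.asarray(ys)


def _on_cycle_times(config: CohortConfig) -> np.ndarray:
    step = 1.0 / config.rate_hz
    t = np.arange(0.0, DAY_S, step)
    cycle = config.on_s + config.off_s
    if config.off_s <= 0:
        return t
    return t[(t % cycle) < config.on_s]


def simulate_day_trajectory(
    participant: Participant, mood: pd.Series, config: CohortConfig
) -> pd.DataFrame:
    """Raw GPS fixes for one participant-day.

    Returns a time-sorted frame with columns ``t`` (UTC seconds),
    ``lat``, ``lon``, ``accuracy`` (m).  Whole days and whole clock hours
    drop out at the configured missingness rates; positions carry
    isotropic Gaussian noise and a lognormal accuracy field calibrated so
    ``accuracy_exceed_prob`` of fixes exceed 50 m.
    """
    day = int(mood["day"])
    rng = config.rng(participant.index, 2, day)
    cols = ["t", "lat", "lon", "accuracy"]
    if rng.random() < config.missing_day_prob:
        return pd.DataFrame(columns=cols)

    wt, wx, wy = build_day_waypoints(
        participant, float(mood["latent_dep"]), bool(mood["weekday"]), config, rng
    )
    ts = _on_cycle_times(config)
    hours_missing = rng.random(24) < config.missing_hour_prob
    if hours_missing.any():
        ts = ts[~hours_missing[(ts // 3600).astype(int)]]
    x = np.interp(ts, wt, wx)
    y = np.interp(ts, wt, wy)
    if config.gps_noise_sd > 0:
        x = x + rng.normal(0.0, config.gps_noise_sd, size=ts.size)
        y = y + rng.normal(0.0, config.gps_noise_sd, size=ts.size)
    # lognormal accuracy with configurable exceedance of the 50 m gate
    sigma = 0.6
    mu = math.log(50.0) - sigma * norm.ppf(1.0 - max(config.accuracy_exceed_prob, 1e-12))
    accuracy = rng.lognormal(mu, sigma, size=ts.size)
    lat, lon = _xy_to_latlon(x, y, participant.home.lat, participant.home.lon)
    t_utc = STUDY_START_UTC + day * DAY_S + ts - (participant.tz_offset_s - TZ_OFFSET_S)
    return pd.DataFrame({"t": t_utc, "lat": lat, "lon": lon, "accuracy": accuracy})


def simulate_cohort_tables(config: CohortConfig):
    """Full-cohort convenience wrapper.

    Returns ``(cohort, moods, fixes_by_participant_day)`` where the last
    is a dict ``(participant_id, day) -> fixes`` frame.
    """
    cohort = generate_cohort(config)
    moods = []
    fixes: dict[tuple[str, int], pd.DataFrame] = {}
    for p in cohort:
        m = simulate_mood_series(p, config)
        moods.append(m)
        for _, row in m.iterrows():
            fixes[(p.id, int(row["day"]))] = simulate_day_trajectory(p, row, config)
    return cohort, pd.concat(moods, ignore_index=True), fixes


# ---------------------------------------------------------------------------
# duty cycle


def apply_duty_cycle(
    fixes: pd.DataFrame, on_s: float, off_s: float, day_start: float | None = None
) -> pd.DataFrame:
    """Keep fixes whose offset within each on+off cycle is below ``on_s``.

    Cycles are anchored at ``day_start`` (default: midnight of the first
    fix's day, in the same clock as ``t``).
    """
    if on_s <= 0 or off_s < 0:
        raise ValueError("duty-cycle durations must satisfy on_s > 0, off_s >= 0")
    if fixes.empty or off_s == 0:
        return fixes.copy()
    t = fixes["t"].to_numpy(float)
    anchor = math.floor(t.min() / DAY_S) * DAY_S if day_start is None else day_start
    keep = ((t - anchor) % (on_s + off_s)) < on_s
    return fixes.loc[keep].copy()


def expected_fix_count(on_s: float, off_s: float, rate_hz: float) -> int:
    """Expected fixes per hour under the duty cycle.

    Fractional trailing cycles are credited proportionally, i.e. the
    long-run hourly average ``3600/(on+off) * on * rate`` rounded to the
    nearest integer (60 s on / 600 s off at 1 Hz gives 327).
    """
    if on_s <= 0 or rate_hz <= 0:
        raise ValueError("on_s and rate_hz must be positive")
    if off_s < 0:
        raise ValueError("off_s must be >= 0")
    return int(round(3600.0 / (on_s + off_s) * on_s * rate_hz))


# ---------------------------------------------------------------------------
# on-disk dialects


def write_gps_csv(fixes: pd.DataFrame, path) -> None:
    """Write fixes in the Beiwe-style GPS dialect.

    Columns: ``timestamp`` (ms), ``UTC_time`` (ISO), ``latitude``,
    ``longitude``, ``altitude`` (constant 0), ``accuracy``.  Floats are
    written at full repr precision, so a read round-trips losslessly.
    """
    out = pd.DataFrame(
        {
            "timestamp": (fixes["t"].to_numpy(float) * 1000).round().astype("int64")
            if len(fixes)
            else pd.Series(dtype="int64"),
            "UTC_time": pd.to_datetime(fixes["t"], unit="s").dt.strftime(
                "%Y-%m-%dT%H:%M:%S.%f"
            )
            if len(fixes)
            else pd.Series(dtype=str),
            "latitude": fixes["lat"].to_numpy(float) if len(fixes) else [],
            "longitude": fixes["lon"].to_numpy(float) if len(fixes) else [],
            "altitude": 0.0 if len(fixes) else pd.Series(dtype=float),
            "accuracy": fixes["accuracy"].to_numpy(float) if len(fixes) else [],
        }
    )
    out.to_csv(path, index=False)


def write_ema_csv(moods: pd.DataFrame, path) -> None:
    """Long-format EMA table: participant_id, date, prompt, item, score."""
    rows = []
    for rec in moods.itertuples(index=False):
        for item in EMA_ITEMS:
            score = getattr(rec, item)
            if not pd.isna(score):
                rows.append(
                    {
                        "participant_id": rec.participant_id,
                        "date": pd.Timestamp(rec.date).date().isoformat(),
                        "prompt": rec.prompt,
                        "item": item,
                        "score": int(score),
                    }
                )
    pd.DataFrame(rows, columns=["participant_id", "date", "prompt", "item", "score"]).to_csv(
        path, index=False
    )


def write_cohort_csv(cohort: list[Participant], path) -> None:
    """Participant covariate manifest."""
    pd.DataFrame(
        [
            {
                "participant_id": p.id,
                "group": p.group,
                "age": p.age,
                "sex": p.sex,
                "employment": p.employment,
                "antidepressant": p.antidepressant,
                "home_lat": p.home.lat,
                "home_lon": p.home.lon,
                "tz_offset_s": p.tz_offset_s,
                "baseline_mobility_scale": p.baseline_mobility_scale,
            }
            for p in cohort
        ]
    ).to_csv(path, index=False)
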