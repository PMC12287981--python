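"""The eight daily GPS mobility features, plus hourly series for
frequency-domain analysis.

Feature conventions (natural log throughout):

* ``LV`` — ln(var(x) + var(y) + 1e-6 m²) over the day's stationary
  10-s bins (population variances); low values mean spatially confined
  behavior.
* ``SM`` / ``SV`` — mean and population variance of instantaneous speed,
  one speed per adjacent valid bin step (displacement / 10 s).
* ``NC`` — number of significant stay locations from greedy sequential
  clustering of stationary bins (500 m radius by default).
* ``entropy`` — Shannon entropy (nats) of the dwell-time distribution
  over clusters.
* ``homestay`` — fraction of stationary dwell at the home cluster (the
  cluster with the most dwell between 00:00 and 06:00 local).
* ``TT`` — moving time / (stationary + moving time).
* ``TD`` — summed Euclidean distance between consecutive valid bins.

Stationary-state features (LV, NC, entropy, homestay) use only
stationary bins; TT uses the state partition; TD, SM, SV use all valid
bins regardless of state.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .preprocessing import BIN_S, classify_states

__all__ = [
    "project_to_meters",
    "cluster_locations",
    "location_variance",
    "location_entropy",
    "compute_day_features",
    "features_from_binned_day",
    "day_features_with_imputation",
    "compute_hourly_features",
    "build_feature_series",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("LV", "SM", "SV", "NC", "entropy", "homestay", "TT", "TD")

LV_EPS_M2 = 1e-6
M_PER_DEG_LAT = 111320.0
DAY_S = 86400.0


def project_to_meters(lat, lon, ref_lat: float, ref_lon: float):
    """Equirectangular projection to meters east/north of a reference.

    y = (lat - ref_lat) * 111320;  x = (lon - ref_lon) * 111320 * cos(ref_lat).
    Adequate at the few-kilometer scale of daily mobility.
    """
    lat = np.asarray(lat, float)
    lon = np.asarray(lon, float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    if not (-90 <= ref_lat <= 90 and -180 <= ref_lon <= 180):
        raise ValueError("reference coordinates out of range")
    y = (lat - ref_lat) * M_PER_DEG_LAT
    x = (lon - ref_lon) * M_PER_DEG_LAT * math.cos(math.radians(ref_lat))
    return x, y


def cluster_locations(
    stationary_bins: pd.DataFrame, radius_m: float = 500.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Greedy sequential clustering of stationary bins.

    Bins are scanned in time order; each joins the nearest existing
    cluster if its centroid lies within ``radius_m``, else opens a new
    cluster.  Centroids are running dwell-weighted means (every 10-s bin
    carries equal dwell).  Home is the cluster with maximum dwell during
    00:00–06:00 local, falling back to maximum total dwell when no
    cluster has night-time data.

    Returns ``(clusters, labels)``: a frame with columns ``id``, ``cx``,
    ``cy``, ``dwell_s``, ``is_home`` and the per-bin cluster label.
    """
    n = len(stationary_bins)
    if n == 0:
        return (
            pd.DataFrame(columns=["id", "cx", "cy", "dwell_s", "is_home"]),
            np.array([], dtype=int),
        )
    x = stationary_bins["x"].to_numpy(float)
    y = stationary_bins["y"].to_numpy(float)
    t = stationary_bins["t"].to_numpy(float)
    centroids: list[list[float]] = []  # [cx, cy, count]
    labels = np.empty(n, dtype=int)
    for i in range(n):
        best, best_d = -1, math.inf
        for j, (cx, cy, cnt) in enumerate(centroids):
            d = math.hypot(x[i] - cx, y[i] - cy)
            if d < best_d:
                best, best_d = j, d
        if best >= 0 and best_d <= radius_m:
            cx, cy, cnt = centroids[best]
            centroids[best] = [
                (cx * cnt + x[i]) / (cnt + 1),
                (cy * cnt + y[i]) / (cnt + 1),
                cnt + 1,
            ]
            labels[i] = best
        else:
            centroids.append([x[i], y[i], 1.0])
            labels[i] = len(centroids) - 1

    k = len(centroids)
    dwell = np.bincount(labels, minlength=k) * BIN_S
    tod = t % DAY_S
    night = tod < 6 * 3600
    night_dwell = np.bincount(labels[night], minlength=k) * BIN_S
    home = int(np.argmax(night_dwell)) if night_dwell.any() else int(np.argmax(dwell))
    clusters = pd.DataFrame(
        {
            "id": np.arange(k),
            "cx": [c[0] for c in centroids],
            "cy": [c[1] for c in centroids],
            "dwell_s": dwell,
            "is_home": np.arange(k) == home,
        }
    )
    return clusters, labels


def location_variance(stationary_bins: pd.DataFrame) -> float:
    """ln(var(x) + var(y) + eps) over stationary bins (population vars)."""
    if len(stationary_bins) == 0:
        raise ValueError("location variance requires at least one stationary bin")
    x = stationary_bins["x"].to_numpy(float)
    y = stationary_bins["y"].to_numpy(float)
    return float(np.log(np.var(x) + np.var(y) + LV_EPS_M2))


def location_entropy(dwell_s) -> float:
    """Shannon entropy (nats) of a dwell-time distribution."""
    d = np.asarray(dwell_s, float)
    if np.any(d < 0):
        raise ValueError("dwell durations must be >= 0")
    total = d.sum()
    if total <= 0:
        raise ValueError("entropy undefined for all-zero dwell")
    p = d[d > 0] / total
    return float(-(p * np.log(p)).sum())


def _observed_view(bins: pd.DataFrame) -> pd.DataFrame:
    """Restrict validity to originally observed bins for state labeling.

    State classification must see the duty-cycle gaps (the 75 m / 6 min
    rule resolves them); running it on an imputed completion would label
    interpolated stretches from their synthetic bin-to-bin steps.
    """
    if "observed" in bins.columns:
        return bins.assign(valid=bins["observed"].to_numpy(bool))
    return bins


def _stationary_mask(bins: pd.DataFrame, segments: pd.DataFrame) -> np.ndarray:
    """Valid bins lying inside a stationary segment."""
    t = bins["t"].to_numpy(float)
    mask = np.zeros(len(bins), dtype=bool)
    for seg in segments.itertuples(index=False):
        if seg.state == "stationary":
            mask |= (t >= seg.start) & (t < seg.end)
    return mask & bins["valid"].to_numpy(bool)


def compute_day_features(
    segments: pd.DataFrame,
    bins: pd.DataFrame,
    clusters: pd.DataFrame | None = None,
    labels: np.ndarray | None = None,
    cluster_radius_m: float = 500.0,
) -> dict[str, float]:
    """All eight features for one completed participant-day trajectory."""
    valid = bins["valid"].to_numpy(bool)
    if valid.sum() < 2:
        raise ValueError("invalid day: fewer than 2 valid bins")
    stat_mask = _stationary_mask(bins, segments)
    stationary = bins.loc[stat_mask]
    if clusters is None or labels is None:
        clusters, labels = cluster_locations(stationary, cluster_radius_m)

    durations = (segments["end"] - segments["start"]).to_numpy(float)
    states = segments["state"].to_numpy()
    t_stat = durations[states == "stationary"].sum()
    t_mov = durations[states == "moving"].sum()
    tt = t_mov / (t_stat + t_mov) if (t_stat + t_mov) > 0 else 0.0

    if len(stationary):
        lv = location_variance(stationary)
        nc = len(clusters)
        ent = location_entropy(clusters["dwell_s"]) if nc else 0.0
        home_dwell = float(clusters.loc[clusters["is_home"], "dwell_s"].sum())
        homestay = home_dwell / clusters["dwell_s"].sum() if nc else 0.0
    else:
        lv, nc, ent, homestay = math.log(LV_EPS_M2), 0, 0.0, 0.0

    x = bins["x"].to_numpy(float)[valid]
    y = bins["y"].to_numpy(float)[valid]
    step = np.hypot(np.diff(x), np.diff(y))
    td = float(step.sum())
    # speeds only over adjacent 10-s steps between observed bins; steps
    # into or out of imputed stretches would reflect interpolation, not
    # measured motion
    observed = (
        bins["observed"].to_numpy(bool)
        if "observed" in bins.columns
        else bins["valid"].to_numpy(bool)
    )
    pos = np.flatnonzero(valid)
    adj = (np.diff(pos) == 1) & observed[pos[:-1]] & observed[pos[1:]]
    speeds = step[adj] / BIN_S
    sm = float(speeds.mean()) if speeds.size else 0.0
    sv = float(np.var(speeds)) if speeds.size else 0.0
    return {
        "LV": lv,
        "SM": sm,
        "SV": sv,
        "NC": float(nc),
        "entropy": ent,
        "homestay": float(homestay),
        "TT": float(tt),
        "TD": td,
    }


def features_from_binned_day(
    bins: pd.DataFrame, cluster_radius_m: float = 500.0
) -> dict[str, float]:
    """Classify states, cluster, and compute features for one bin series."""
    segments = classify_states(_observed_view(bins))
    return compute_day_features(segments, bins, cluster_radius_m=cluster_radius_m)


def day_features_with_imputation(
    bin_series: list[pd.DataFrame], cluster_radius_m: float = 500.0
) -> dict[str, float]:
    """Average each feature over the stochastic gap completions."""
    per_sim = [features_from_binned_day(b, cluster_radius_m) for b in bin_series]
    out = {k: float(np.mean([f[k] for f in per_sim])) for k in FEATURE_NAMES}
    out["n_imputations"] = len(per_sim)
    return out


def compute_hourly_features(
    bins: pd.DataFrame, segments: pd.DataFrame | None = None,
    cluster_radius_m: float = 500.0,
) -> pd.DataFrame:
    """Hourly LV and entropy for the spectral input series.

    Day-level clusters are reused so hourly entropy reflects how that
    hour's dwell spreads over the day's significant locations.  Hours
    with no stationary data are missing (NaN).
    """
    if segments is None:
        segments = classify_states(_observed_view(bins))
    stat_mask = _stationary_mask(bins, segments)
    stationary = bins.loc[stat_mask]
    clusters, labels = cluster_locations(stationary, cluster_radius_m)
    t0 = math.floor(bins["t"].min() / DAY_S) * DAY_S
    hour_of = ((stationary["t"].to_numpy(float) - t0) // 3600).astype(int)
    rows = []
    for h in range(24):
        sel = hour_of == h
        if not sel.any():
            rows.append({"hour": h, "LV": np.nan, "entropy": np.nan})
            continue
        sub = stationary.loc[sel]
        lv = location_variance(sub)
        dw = np.bincount(labels[sel], minlength=len(clusters)) * BIN_S
        ent = location_entropy(dw) if dw.sum() > 0 else 0.0
        rows.append({"hour": h, "LV": lv, "entropy": ent})
    return pd.DataFrame(rows)


def build_feature_series(
    table: pd.DataFrame,
    feature: str,
    granularity: str = "hourly",
    window: tuple[int, int] | None = None,
    max_missing_frac: float = 0.25,
) -> tuple[np.ndarray, float, bool]:
    """Regular, gap-free, mean-removed series for spectral analysis.

    ``table`` holds one participant's feature values on a regular grid
    (column ``hour`` for hourly granularity, ``date`` for daily).
    ``window`` selects ``(start, length)`` steps.  Interior missing
    entries are linearly interpolated and edge gaps held at the nearest
    value; a window with more than ``max_missing_frac`` missing entries
    is rejected (flagged, not raised).

    Returns ``(values, step_days, accepted)``.
    """
    if granularity == "hourly":
        order = table.sort_values("hour")
        step_days = 1.0 / 24.0
    elif granularity == "daily":
        order = table.sort_values("date")
        step_days = 1.0
    else:
        raise ValueError("granularity must be 'hourly' or 'daily'")
    v = order[feature].to_numpy(float)
    if window is not None:
        start, length = window
        v = v[start : start + length]
    missing = ~np.isfinite(v)
    if v.size == 0 or missing.mean() > max_missing_frac:
        return v, step_days, False
    if missing.any():
        idx = np.arange(v.size)
        v = np.interp(idx, idx[~missing], v[~missing])
    v = v - v.mean()
    return v, step_days, True
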