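"""Raw GPS cleaning: accuracy gate, 10-s binning, state segmentation,
gap imputation, day-validity, and daily EMA resolution.

The processing chain per participant-day is:

1. drop fixes whose reported accuracy exceeds 50 m;
2. average positions (projected to meters) on a regular 10-s grid
   anchored at local midnight; a grid bin with no fix is missing;
3. label each 10-s step stationary (displacement <= sqrt(10) m) or
   moving (> sqrt(10) m); a step into missing data is unknown, and each
   maximal unknown run resolves to moving iff the displacement across it
   reaches 75 m within some 6-minute span, else stationary;
4. fill interior missing runs by linear interpolation with Gaussian
   jitter, repeated ``n_sim`` times (features downstream are averaged
   over the completions); runs longer than a configurable limit are
   copied from the nearest donor day's same clock bins when available;
5. a day enters the analysis only if at least 6 of its 24 clock hours
   contain data.

Daily mood scores come from the 12:45 prompt, falling back to the 17:00
prompt when the primary one is missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "read_gps_csv",
    "read_ema_csv",
    "filter_accuracy",
    "bin_10s",
    "classify_states",
    "impute_gaps",
    "day_validity",
    "resolve_daily_ema",
    "DayValidity",
    "BIN_S",
    "MOVE_THRESHOLD_M",
    "GAP_DISPLACEMENT_M",
    "GAP_WINDOW_S",
]

BIN_S = 10.0
MOVE_THRESHOLD_M = math.sqrt(10.0)   # per 10-s step
GAP_DISPLACEMENT_M = 75.0            # unknown-run resolution
GAP_WINDOW_S = 360.0                 # ... within any 6-minute span
DAY_S = 86400.0


def read_gps_csv(path) -> pd.DataFrame:
    """Read a Beiwe-style GPS CSV into a time-sorted fix frame.

    Counterpart of :func:`mobispect.synthetic.write_gps_csv`.
    """
    raw = pd.read_csv(path)
    fixes = pd.DataFrame(
        {
            "t": raw["timestamp"].to_numpy(float) / 1000.0,
            "lat": raw["latitude"].to_numpy(float),
            "lon": raw["longitude"].to_numpy(float),
            "accuracy": raw["accuracy"].to_numpy(float),
        }
    )
    return fixes.sort_values("t", kind="stable").reset_index(drop=True)


def read_ema_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"])
    return df


def filter_accuracy(fixes: pd.DataFrame, max_error_m: float = 50.0) -> pd.DataFrame:
    """Retain fixes with reported accuracy <= ``max_error_m`` (order kept)."""
    if fixes.empty:
        return fixes.copy()
    return fixes.loc[fixes["accuracy"].to_numpy(float) <= max_error_m].copy()


def bin_10s(
    points: pd.DataFrame, day_start: float | None = None, n_bins: int | None = None
) -> pd.DataFrame:
    """Average projected positions on a regular 10-s grid.

    ``points`` must carry local-clock seconds ``t`` and projected meters
    ``x, y`` (see :func:`mobispect.features.project_to_meters`).  The grid
    is anchored at local midnight of the first point's day and spans the
    whole day; bins with no fix are invalid and carry no coordinates.
    """
    if points.empty:
        raise ValueError("cannot bin an empty fix set")
    t = points["t"].to_numpy(float)
    anchor = math.floor(t.min() / DAY_S) * DAY_S if day_start is None else day_start
    n = int(DAY_S / BIN_S) if n_bins is None else n_bins
    idx = np.floor((t - anchor) / BIN_S).astype(int)
    ok = (idx >= 0) & (idx < n)
    idx = idx[ok]
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    counts = np.bincount(idx, minlength=n)
    valid = counts > 0
    with np.errstate(invalid="ignore"):
        x[valid] = np.bincount(idx, weights=points["x"].to_numpy(float)[ok], minlength=n)[valid] / counts[valid]
        y[valid] = np.bincount(idx, weights=points["y"].to_numpy(float)[ok], minlength=n)[valid] / counts[valid]
    return pd.DataFrame(
        {"t": anchor + BIN_S * np.arange(n), "x": x, "y": y, "valid": valid}
    )


def _resolve_gap(d: float, duration_s: float) -> str:
    """Resolve an unknown run from the displacement between its flanking bins.

    Under linear motion across the run, the maximum displacement within
    any 6-minute sub-window is ``d * min(1, 360/duration)``.
    """
    max_disp = d * min(1.0, GAP_WINDOW_S / max(duration_s, 1e-9))
    return "moving" if max_disp >= GAP_DISPLACEMENT_M else "stationary"


def classify_states(bins: pd.DataFrame, resolve_unknown: bool = True) -> pd.DataFrame:
    """Segment observed time into stationary / moving (/ unknown) states.

    Returns a frame with ``start``, ``end`` (seconds), ``state``, and the
    centroid ``cx, cy`` of stationary segments.  Segments partition the
    span from the first to the last valid bin; time outside that span is
    unobserved.
    """
    valid_pos = np.flatnonzero(bins["valid"].to_numpy(bool))
    cols = ["start", "end", "state", "cx", "cy"]
    if valid_pos.size == 0:
        return pd.DataFrame(columns=cols)
    t = bins["t"].to_numpy(float)
    x = bins["x"].to_numpy(float)
    y = bins["y"].to_numpy(float)

    if valid_pos.size == 1:
        g = valid_pos[0]
        return pd.DataFrame(
            [[t[g], t[g] + BIN_S, "stationary", x[g], y[g]]], columns=cols
        )

    # one state label per inter-valid-bin interval
    intervals = []  # (start, end, state, member grid bins)
    for g1, g2 in zip(valid_pos[:-1], valid_pos[1:]):
        d = math.hypot(x[g2] - x[g1], y[g2] - y[g1])
        if g2 == g1 + 1:
            state = "moving" if d > MOVE_THRESHOLD_M else "stationary"
        elif resolve_unknown:
            state = _resolve_gap(d, (g2 - g1) * BIN_S)
        else:
            state = "unknown"
        intervals.append((t[g1], t[g2], state, [g1]))
    # credit the final bin's 10 s to the last interval's state
    last = intervals[-1]
    intervals[-1] = (last[0], last[1] + BIN_S, last[2], last[3] + [valid_pos[-1]])

    segments = []
    for start, end, state, members in intervals:
        if segments and segments[-1][2] == state:
            segments[-1][1] = end
            segments[-1][3].extend(members)
        else:
            segments.append([start, end, state, list(members)])
    rows = []
    for start, end, state, members in segments:
        if state == "stationary":
            rows.append([start, end, state, float(np.mean(x[members])), float(np.mean(y[members]))])
        else:
            rows.append([start, end, state, np.nan, np.nan])
    return pd.DataFrame(rows, columns=cols)


def _runs(mask: np.ndarray):
    """Maximal runs of True in ``mask`` as (start, stop) index pairs."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def impute_gaps(
    bins: pd.DataFrame,
    n_sim: int = 10,
    seed: int = 0,
    jitter_sd: float = 5.0,
    max_gap_s: float = 3600.0,
    donor_days: list[pd.DataFrame] | None = None,
) -> list[pd.DataFrame]:
    """Return ``n_sim`` stochastic completions of a binned day.

    Interior missing runs no longer than ``max_gap_s`` are linearly
    interpolated between their flanking valid bins, plus a zero-mean
    Gaussian offset (sd ``jitter_sd``) drawn once per run per
    completion.  A shared offset — rather than iid per-bin noise —
    expresses the positional uncertainty of the interpolated track
    without injecting spurious bin-to-bin displacement, which at
    realistic GPS noise would exceed the sqrt(10) m / 10 s movement
    threshold and turn every imputed stretch into apparent travel.
    Longer runs — and leading/trailing runs — are copied from the
    nearest donor day's same clock bins where the donor is valid
    (``donor_days`` is ordered by preference); with no donor they stay
    invalid.  Valid bins are never altered.  The output frames carry an
    ``observed`` column marking the originally valid bins.
    """
    valid = bins["valid"].to_numpy(bool)
    if valid.sum() < 2:
        raise ValueError("uninterpolatable day: fewer than 2 valid bins")
    t = bins["t"].to_numpy(float)
    x0 = bins["x"].to_numpy(float)
    y0 = bins["y"].to_numpy(float)
    n = valid.size
    first, last = np.flatnonzero(valid)[[0, -1]]

    # donor fill (deterministic, shared across completions)
    donor_x, donor_y = x0.copy(), y0.copy()
    donor_valid = valid.copy()
    for i0, j0 in _runs(~valid):
        interior = i0 > first and j0 - 1 < last
        long_run = (j0 - i0) * BIN_S > max_gap_s
        if interior and not long_run:
            continue
        if donor_days:
            for donor in donor_days:
                dv = donor["valid"].to_numpy(bool)
                m = min(j0, dv.size)
                span = slice(i0, m)
                fill = dv[span] & ~donor_valid[span]
                if fill.any():
                    sel = np.flatnonzero(fill) + i0
                    donor_x[sel] = donor["x"].to_numpy(float)[sel]
                    donor_y[sel] = donor["y"].to_numpy(float)[sel]
                    donor_valid[sel] = True

    base_valid = donor_valid
    rng = np.random.default_rng(seed)
    out = []
    vb = np.flatnonzero(base_valid)
    for _ in range(n_sim):
        x = donor_x.copy()
        y = donor_y.copy()
        filled = base_valid.copy()
        for i0, j0 in _runs(~base_valid):
            # only interior runs have flanking bins to interpolate between
            if not (i0 > vb[0] and j0 - 1 < vb[-1]):
                continue
            if (j0 - i0) * BIN_S > max_gap_s:
                continue
            idx = np.arange(i0, j0)
            x[idx] = np.interp(t[idx], t[vb], donor_x[vb])
            y[idx] = np.interp(t[idx], t[vb], donor_y[vb])
            if jitter_sd > 0:
                x[idx] += rng.normal(0.0, jitter_sd)
                y[idx] += rng.normal(0.0, jitter_sd)
            filled[idx] = True
        out.append(
            pd.DataFrame({"t": t, "x": x, "y": y, "valid": filled, "observed": valid})
        )
    return out


@dataclass(frozen=True)
class DayValidity:
    participant_id: str
    date: object
    valid_hours: int
    included: bool


def day_validity(
    bins: pd.DataFrame,
    threshold_hours: int = 6,
    participant_id: str = "",
    date=None,
) -> DayValidity:
    """Count clock hours containing data; a day needs >= 6 to be analyzed
    (one quarter of the 24 hours)."""
    t = bins["t"].to_numpy(float)
    valid = bins["valid"].to_numpy(bool)
    hours = ((t - math.floor(t.min() / DAY_S) * DAY_S) // 3600).astype(int)
    valid_hours = int(np.unique(hours[valid]).size)
    return DayValidity(participant_id, date, valid_hours, valid_hours >= threshold_hours)


def resolve_daily_ema(prompts: pd.DataFrame) -> dict[str, float]:
    """One score per mood item for a participant-day.

    ``prompts`` holds that day's rows of the long EMA table (columns
    ``prompt`` in {primary, fallback}, ``item``, ``score``).  The primary
    (12:45) score wins; the 17:00 fallback fills a missing primary; else
    the item is missing (NaN).
    """
    if len(prompts) and ((prompts["score"] < 1) | (prompts["score"] > 5)).any():
        raise ValueError("EMA scores must lie in 1..5")
    out: dict[str, float] = {}
    for item, grp in prompts.groupby("item"):
        primary = grp.loc[grp["prompt"] == "primary", "score"]
        fallback = grp.loc[grp["prompt"] == "fallback", "score"]
        if len(primary):
            out[str(item)] = float(primary.iloc[0])
        elif len(fallback):
            out[str(item)] = float(fallback.iloc[0])
    return out
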