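"""Directory-based pipeline: simulate -> preprocess -> features ->
spectral -> analyze, with a JSON manifest for idempotent re-runs.

Each stage reads the previous stage's CSV artifacts from the output
directory and writes its own; outputs are stamped with a hash of the
configuration plus the seed, and an up-to-date stage (same hash, outputs
present) is skipped on re-run.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import inference, preprocessing, spectral, synthetic
from .config import CohortConfig, ConfigError

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "preprocess", "features", "spectral", "analyze")


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    max_error_m: float = 50.0
    min_valid_hours: int = 6
    n_imputations: int = 10
    max_gap_min: float = 60.0
    cluster_radius_m: float = 500.0
    window_days: int = 28
    granularity: str = "hourly"
    taper: str = "boxcar"
    vif_threshold: float = 3.0
    stages: tuple[str, ...] = STAGES

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown field '{sorted(unknown)[0]}'")
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "stages" in d:
            bad = set(d["stages"]) - set(STAGES)
            if bad:
                raise ConfigError(f"unknown field 'stages:{sorted(bad)[0]}'")
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def canonical_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_yaml().encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a pipeline config from YAML; an empty file means all defaults.

    Unknown keys are rejected with the offending key named.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig.from_dict(raw or {})


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: PipelineConfig, out: Path, seed: int) -> list[str]:
    config = cfg.cohort.with_(seed=seed)
    cohort = synthetic.generate_cohort(config)
    gps_dir = out / "gps"
    gps_dir.mkdir(parents=True, exist_ok=True)
    moods = []
    for p in cohort:
        m = synthetic.simulate_mood_series(p, config)
        moods.append(m)
        frames = [
            synthetic.simulate_day_trajectory(p, row, config)
            for _, row in m.iterrows()
        ]
        fixes = pd.concat([f for f in frames if len(f)], ignore_index=True) if any(
            len(f) for f in frames
        ) else pd.DataFrame(columns=["t", "lat", "lon", "accuracy"])
        synthetic.write_gps_csv(fixes, gps_dir / f"{p.id}.csv")
    moods_df = pd.concat(moods, ignore_index=True)
    synthetic.write_ema_csv(moods_df, out / "ema.csv")
    synthetic.write_cohort_csv(cohort, out / "cohort.csv")
    return ["gps", "ema.csv", "cohort.csv"]


def _local_seconds(t_utc: np.ndarray, tz_offset_s: float) -> np.ndarray:
    return t_utc + tz_offset_s - (synthetic.STUDY_START_UTC + synthetic.TZ_OFFSET_S)


def _participant_days(fixes: pd.DataFrame, tz_offset_s: float):
    """Split one participant's fixes into (day_index, local-clock frame)."""
    s = _local_seconds(fixes["t"].to_numpy(float), tz_offset_s)
    day = np.floor(s / 86400.0).astype(int)
    df = fixes.assign(t=s, _day=day)
    for d, grp in df.groupby("_day"):
        yield int(d), grp.drop(columns="_day")


def _stage_preprocess(cfg: PipelineConfig, out: Path, seed: int) -> list[str]:
    cohort_df = pd.read_csv(out / "cohort.csv")
    seg_rows, val_rows = [], []
    for rec in cohort_df.itertuples(index=False):
        path = out / "gps" / f"{rec.participant_id}.csv"
        fixes = preprocessing.read_gps_csv(path)
        fixes = preprocessing.filter_accuracy(fixes, cfg.max_error_m)
        if fixes.empty:
            continue
        x, y = feat.project_to_meters(
            fixes["lat"], fixes["lon"], rec.home_lat, rec.home_lon
        )
        fixes = fixes.assign(x=x, y=y)
        for d, day_fixes in _participant_days(fixes, rec.tz_offset_s):
            bins = preprocessing.bin_10s(day_fixes)
            validity = preprocessing.day_validity(
                bins, cfg.min_valid_hours, rec.participant_id,
                (synthetic.START_DATE + pd.Timedelta(days=d)).date(),
            )
            val_rows.append(asdict_validity(validity, d))
            if not validity.included:
                continue
            segments = preprocessing.classify_states(bins)
            segments = segments.assign(participant_id=rec.participant_id, day=d)
            seg_rows.append(segments)
    segs = (
        pd.concat(seg_rows, ignore_index=True)
        if seg_rows
        else pd.DataFrame(columns=["start", "end", "state", "cx", "cy", "participant_id", "day"])
    )
    segs.to_csv(out / "segments.csv", index=False)
    pd.DataFrame(val_rows).to_csv(out / "validity.csv", index=False)
    return ["segments.csv", "validity.csv"]


def asdict_validity(v: preprocessing.DayValidity, day: int) -> dict:
    return {
        "participant_id": v.participant_id,
        "day": day,
        "date": v.date,
        "valid_hours": v.valid_hours,
        "included": v.included,
    }


def _stage_features(cfg: PipelineConfig, out: Path, seed: int) -> list[str]:
    cohort_df = pd.read_csv(out / "cohort.csv")
    day_rows, hourly_rows = [], []
    for rec in cohort_df.itertuples(index=False):
        path = out / "gps" / f"{rec.participant_id}.csv"
        fixes = preprocessing.read_gps_csv(path)
        fixes = preprocessing.filter_accuracy(fixes, cfg.max_error_m)
        if fixes.empty:
            continue
        x, y = feat.project_to_meters(
            fixes["lat"], fixes["lon"], rec.home_lat, rec.home_lon
        )
        fixes = fixes.assign(x=x, y=y)
        day_bins: dict[int, pd.DataFrame] = {}
        for d, day_fixes in _participant_days(fixes, rec.tz_offset_s):
            if len(day_fixes) < 2:
                continue
            day_bins[d] = preprocessing.bin_10s(day_fixes)
        for d, bins in sorted(day_bins.items()):
            validity = preprocessing.day_validity(bins, cfg.min_valid_hours)
            if not validity.included:
                continue
            donors = [
                day_bins[dd]
                for dd in sorted(day_bins, key=lambda dd: (abs(dd - d), dd))
                if dd != d
            ][:4]
            completions = preprocessing.impute_gaps(
                bins,
                n_sim=cfg.n_imputations,
                seed=seed + 7919 * d + 104729 * int(rec.Index if hasattr(rec, "Index") else 0),
                jitter_sd=cfg.cohort.gps_noise_sd,
                max_gap_s=cfg.max_gap_min * 60.0,
                donor_days=donors,
            )
            row = feat.day_features_with_imputation(completions, cfg.cluster_radius_m)
            date = synthetic.START_DATE + pd.Timedelta(days=d)
            row.update(
                participant_id=rec.participant_id,
                date=date,
                day=d,
                weekday=date.dayofweek < 5,
                valid_hours=validity.valid_hours,
            )
            day_rows.append(row)
            hourly = feat.compute_hourly_features(
                completions[0], cluster_radius_m=cfg.cluster_radius_m
            )
            hourly["participant_id"] = rec.participant_id
            hourly["day"] = d
            hourly["hour"] = hourly["hour"] + 24 * d
            hourly_rows.append(hourly)
    pd.DataFrame(day_rows).to_csv(out / "features.csv", index=False)
    (
        pd.concat(hourly_rows, ignore_index=True)
        if hourly_rows
        else pd.DataFrame(columns=["hour", "LV", "entropy", "participant_id", "day"])
    ).to_csv(out / "hourly.csv", index=False)
    return ["features.csv", "hourly.csv"]


def _stage_spectral(cfg: PipelineConfig, out: Path, seed: int) -> list[str]:
    hourly = pd.read_csv(out / "hourly.csv")
    cohort_df = pd.read_csv(out / "cohort.csv")
    group_of = dict(zip(cohort_df["participant_id"], cohort_df["group"]))
    n_hours = cfg.window_days * 24
    spectra_rows = []
    peak_sets: dict[tuple[str, str], list[spectral.PeakSet]] = {}
    for (pid,), grp in hourly.groupby(["participant_id"]):
        total_hours = int(grp["hour"].max()) + 1 if len(grp) else 0
        full = pd.DataFrame({"hour": np.arange(max(total_hours, n_hours))})
        full = full.merge(grp[["hour", "LV", "entropy"]], on="hour", how="left")
        for feature in ("LV", "entropy"):
            series, step, ok = feat.build_feature_series(
                full, feature, granularity="hourly", window=(0, n_hours)
            )
            if not ok or series.size < n_hours:
                continue
            summary = spectral.window_spectral_summary(
                series, step, participant_id=pid, feature=feature, window=cfg.taper
            )
            spectra_rows.append(summary)
            spec = spectral.periodogram(series, step, window=cfg.taper)
            ps = spectral.top_k_peaks(spec, 5, participant_id=pid, feature=feature)
            peak_sets.setdefault((group_of.get(pid, "?"), feature), []).append(ps)
    (
        pd.concat(spectra_rows, ignore_index=True)
        if spectra_rows
        else pd.DataFrame(
            columns=["participant_id", "feature", "rank", "power", "frequency", "period_days"]
        )
    ).to_csv(out / "spectra.csv", index=False)
    cons_rows = []
    for (group, feature), sets in sorted(peak_sets.items()):
        tab = spectral.cohort_period_consensus(sets)
        tab["group"] = group
        tab["feature"] = feature
        cons_rows.append(tab)
    (
        pd.concat(cons_rows, ignore_index=True)
        if cons_rows
        else pd.DataFrame(columns=["period_days", "count", "rank_sum", "majority", "group", "feature"])
    ).to_csv(out / "consensus.csv", index=False)
    return ["spectra.csv", "consensus.csv"]


def _resolve_ema_wide(ema: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (pid, date), grp in ema.groupby(["participant_id", "date"]):
        scores = preprocessing.resolve_daily_ema(grp)
        scores.update(participant_id=pid, date=date)
        rows.append(scores)
    return pd.DataFrame(rows)


def _stage_analyze(cfg: PipelineConfig, out: Path, seed: int) -> list[str]:
    features_df = pd.read_csv(out / "features.csv", parse_dates=["date"])
    cohort_df = pd.read_csv(out / "cohort.csv")
    ema = preprocessing.read_ema_csv(out / "ema.csv")
    moods = _resolve_ema_wide(ema)
    rows = inference.build_person_day_rows(features_df, moods, cohort_df)

    rate_rows = []
    for item in inference.MOOD_ITEMS:
        col = item.replace("ema_", "") + "_status"
        sub = rows.dropna(subset=[col])
        if len(sub):
            pct = 100.0 * sub[col].mean()
            rate_rows.append(
                {"item": item, "percent": pct, "count": int(sub[col].sum()), "n": len(sub)}
            )
    pd.DataFrame(rate_rows).to_csv(out / "mood_rates.csv", index=False)

    fit_rows = []
    for stratum in ("all", "weekday", "weekend"):
        try:
            res = inference.fit_daylevel_logistic(
                rows, stratum=stratum, vif_threshold=cfg.vif_threshold
            )
        except ValueError:
            continue
        tab = res.terms.reset_index(names="term")
        tab["stratum"] = stratum
        tab["n"] = res.n
        fit_rows.append(tab)
    (
        pd.concat(fit_rows, ignore_index=True)
        if fit_rows
        else pd.DataFrame(columns=["term", "beta", "or_", "ci_low", "ci_high", "p", "stratum", "n"])
    ).to_csv(out / "daylevel_models.csv", index=False)

    # group comparison of ranked powers (patients only), plus spectrum models
    spectra = pd.read_csv(out / "spectra.csv")
    group_of = dict(zip(cohort_df["participant_id"], cohort_df["group"]))
    test_rows = []
    for feature in ("LV", "entropy"):
        sub = spectra.loc[(spectra["feature"] == feature) & (spectra["rank"] == 1)]
        bp = sub.loc[sub["participant_id"].map(group_of) == "BP", "power"].to_numpy()
        mdd = sub.loc[sub["participant_id"].map(group_of) == "MDD", "power"].to_numpy()
        if bp.size and mdd.size:
            u, p, ra, rb = inference.mann_whitney_mean_ranks(bp, mdd)
            test_rows.append(
                {
                    "feature": feature,
                    "statistic": "max_power",
                    "U": u,
                    "p": p,
                    "mean_rank_bp": ra,
                    "mean_rank_mdd": rb,
                }
            )
    pd.DataFrame(test_rows).to_csv(out / "group_tests.csv", index=False)

    # participant-window affective status: majority of scored days in window
    spec_rows = []
    window_days = cfg.window_days
    status_cols = [i.replace("ema_", "") + "_status" for i in inference.MOOD_ITEMS]
    win = rows.loc[rows["day"] < window_days] if "day" in rows else rows
    agg = win.groupby("participant_id")[status_cols].mean()
    for feature in ("LV", "entropy"):
        sub = spectra.loc[
            (spectra["feature"] == feature) & (spectra["rank"] == 1),
            ["participant_id", "power"],
        ].set_index("participant_id")
        table = agg.join(sub, how="inner")
        table = table.join(
            cohort_df.assign(
                female=(cohort_df["sex"] == "F").astype(float),
                employee_or_student=cohort_df["employment"]
                .isin(["employed", "student"])
                .astype(float),
                antidep=cohort_df["antidepressant"].astype(float),
            ).set_index("participant_id")[["age", "female", "employee_or_student", "antidep", "group"]]
        )
        table = table.loc[table["group"].isin(["BP", "MDD"])]
        for col in status_cols:
            table[col + "_bin"] = (table[col] > 0.5).astype(float)
        for outcome in status_cols:
            for model in (1, 2, 3, 4):
                try:
                    res = inference.fit_spectrum_logistic(
                        table.reset_index(), "power", outcome + "_bin", model=model
                    )
                except ValueError:
                    continue
                t = res.term("power")
                spec_rows.append(
                    {
                        "feature": feature,
                        "outcome": outcome,
                        "model": model,
                        "beta": t["beta"],
                        "or": t["or_"],
                        "ci_low": t["ci_low"],
                        "ci_high": t["ci_high"],
                        "p": t["p"],
                        "n": res.n,
                    }
                )
    pd.DataFrame(spec_rows).to_csv(out / "spectrum_models.csv", index=False)
    return ["mood_rates.csv", "daylevel_models.csv", "group_tests.csv", "spectrum_models.csv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "features": _stage_features,
    "spectral": _stage_spectral,
    "analyze": _stage_analyze,
}

_STAGE_INPUTS = {
    "simulate": [],
    "preprocess": ["cohort.csv", "ema.csv"],
    "features": ["cohort.csv"],
    "spectral": ["hourly.csv", "cohort.csv"],
    "analyze": ["features.csv", "cohort.csv", "ema.csv", "spectra.csv"],
}


def run_pipeline(config: PipelineConfig, out_dir, seed: int | None = None) -> dict:
    """Run the enabled stages in dependency order; returns the manifest.

    Re-running with an unchanged config and seed skips stages whose
    outputs already exist.  A missing upstream artifact raises with the
    stage named.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.cohort.seed if seed is None else seed
    stamp = f"{config.hash()}:{seed}"
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": stamp, "seed": seed, "stages": {}}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == stamp:
            manifest = old
    else:
        old = None

    for stage in STAGES:
        if stage not in config.stages:
            continue
        done = manifest["stages"].get(stage)
        if done and all((out / o).exists() for o in done["outputs"]):
            continue
        for req in _STAGE_INPUTS[stage]:
            if not (out / req).exists():
                raise FileNotFoundError(
                    f"stage '{stage}' is missing upstream artifact '{req}'"
                )
        outputs = _STAGE_FN[stage](config, out, seed)
        manifest["stages"][stage] = {"outputs": outputs}
        manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
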