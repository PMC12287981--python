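"""Configuration objects for cohort simulation and the pipeline.

All randomness in the package flows from a single integer seed held by
:class:`CohortConfig`; per-participant / per-day generators are derived
through :func:`numpy.random.SeedSequence` spawn keys so that adding a
participant never perturbs another participant's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

__all__ = ["CohortConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration field violates its invariant."""


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid field '{name}': {msg}")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a simulated cohort.

    The defaults emulate the acquisition protocol of a duty-cycled
    smartphone GPS study with daily mood self-reports: three groups
    (healthy controls, bipolar, unipolar depression), 60 s on / 600 s off
    GPS sampling at 1 Hz, and group-specific latent-mood dynamics
    (bipolar: multi-day sinusoidal cycles; unipolar: slow aperiodic
    drift; controls: stable).
    """

    # cohort composition
    n_hc: int = 15
    n_bp: int = 20
    n_mdd: int = 27
    n_days: int = 28

    # duty cycle
    on_s: float = 60.0
    off_s: float = 600.0
    rate_hz: float = 1.0

    # GPS emission
    gps_noise_sd: float = 5.0          # m, isotropic
    accuracy_exceed_prob: float = 0.05  # P(reported accuracy > 50 m)
    missing_day_prob: float = 0.05
    missing_hour_prob: float = 0.02

    # latent mood -> mobility coupling: multiplicative reductions per unit
    # of elevated depressed mood on (excursion rate, away-time fraction,
    # cluster diversity)
    mood_effect: tuple[float, float, float] = (0.30, 0.25, 0.25)

    # group-specific mood dynamics
    bp_periods: tuple[float, ...] = (1.0, 4.0, 9.0)   # days
    bp_amplitude: float = 2.0      # hourly-feature oscillation amplitude
    mdd_amplitude: float = 0.5     # scale of the bounded aperiodic drift
    mood_noise_sd: float = 1.0     # iid day-level latent-mood noise
    mood_dispersion: float = 0.0   # between-person spread of mood baselines
    hourly_noise_sd: float = 1.0   # white noise on hourly feature series

    # EMA prompt compliance
    ema_missing_primary_prob: float = 0.15
    ema_missing_both_prob: float = 0.05

    # calibration of the EMA>1 day rate in healthy controls
    hc_dep_rate: float = 0.09
    hc_mania_rate: float = 0.08

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hc", "n_bp", "n_mdd"):
            _check(getattr(self, name) >= 0, name, "count must be >= 0")
        _check(self.n_days >= 1, "n_days", "must be >= 1")
        _check(self.on_s > 0, "on_s", "must be > 0")
        _check(self.off_s >= 0, "off_s", "must be >= 0")
        _check(self.rate_hz > 0, "rate_hz", "must be > 0")
        _check(self.gps_noise_sd >= 0, "gps_noise_sd", "must be >= 0")
        for name in (
            "accuracy_exceed_prob",
            "missing_day_prob",
            "missing_hour_prob",
            "ema_missing_primary_prob",
            "ema_missing_both_prob",
            "hc_dep_rate",
            "hc_mania_rate",
        ):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, name, "probability must lie in [0, 1]")
        _check(
            len(self.mood_effect) == 3
            and all(0.0 <= e < 1.0 for e in self.mood_effect),
            "mood_effect",
            "three multiplicative reductions in [0, 1)",
        )
        _check(
            all(0 < p <= self.n_days / 2 for p in self.bp_periods),
            "bp_periods",
            "cycle lengths must lie in (0, n_days/2]",
        )
        _check(self.bp_amplitude >= 0, "bp_amplitude", "must be >= 0")
        _check(self.mdd_amplitude >= 0, "mdd_amplitude", "must be >= 0")

    # --- seed plumbing -------------------------------------------------

    def rng(self, *spawn_key: int) -> np.random.Generator:
        """Deterministic generator for one (participant, day, stream) slot."""
        ss = np.random.SeedSequence(self.seed, spawn_key=spawn_key)
        return np.random.Generator(np.random.PCG64(ss))

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mood_effect"] = list(self.mood_effect)
        d["bp_periods"] = list(self.bp_periods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown field '{sorted(unknown)[0]}'")
        d = dict(d)
        for key in ("mood_effect", "bp_periods"):
            if key in d and isinstance(d[key], Sequence):
                d[key] = tuple(d[key])
        return cls(**d)
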