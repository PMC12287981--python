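"""Fourier power spectra of mobility-feature series and the top-5
peak-ranking consensus across a group.

A feature series (hourly by default, so daily cycles sit below the
Nyquist limit) is transformed with a plain discrete Fourier transform;
the one-sided power spectrum is normalized so that the non-DC power sums
to N x variance (Parseval).  The five highest peaks — highest-power bins
with a one-bin exclusion zone so the shoulder bins of an off-grid tone
are not double-counted — are ranked 1 (maximum) to 5, each carrying a
period equal to the reciprocal of its frequency.  At the group level, a
whole-day cycle length is a consensus period when more than half of the
group carries it in their top 5; summed ranks (lower = stronger) grade
its intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "PeakSet",
    "periodogram",
    "top_k_peaks",
    "window_spectral_summary",
    "cohort_period_consensus",
]


@dataclass(frozen=True)
class Spectrum:
    """One-sided periodogram: frequencies in cycles/day, DC excluded."""

    frequencies: np.ndarray
    power: np.ndarray
    step_days: float
    window_days: float

    def __post_init__(self):
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power lengths differ")

    @property
    def bin_width(self) -> float:
        return 1.0 / self.window_days


@dataclass(frozen=True)
class PeakSet:
    """Up to k ranked (period, power) peaks for one participant window."""

    participant_id: str
    feature: str
    periods_days: tuple[float, ...]
    powers: tuple[float, ...]
    frequencies: tuple[float, ...]
    window_days: float


def periodogram(series: np.ndarray, step_days: float, window: str = "boxcar") -> Spectrum:
    """Discrete Fourier transform of a regular, gap-free series.

    Power is the squared DFT magnitude normalized by the series length,
    one-sided (interior bins doubled), DC excluded.  ``window='hann'``
    applies a Hann taper; the default is the plain (rectangular)
    transform.
    """
    x = np.asarray(series, float)
    if x.size < 8:
        raise ValueError("series too short for a spectrum (need >= 8 points)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains missing values; interpolate upstream")
    if window == "hann":
        x = x * np.hanning(x.size)
    elif window != "boxcar":
        raise ValueError("window must be 'boxcar' or 'hann'")
    n = x.size
    X = np.fft.rfft(x)
    power = (np.abs(X) ** 2) / n
    # one-sided: double interior bins (not DC, not Nyquist when n even)
    power[1 : -1 if n % 2 == 0 else None] *= 2.0
    freqs = np.fft.rfftfreq(n, d=step_days)
    return Spectrum(
        frequencies=freqs[1:],
        power=power[1:],
        step_days=step_days,
        window_days=n * step_days,
    )


def top_k_peaks(
    spectrum: Spectrum,
    k: int = 5,
    participant_id: str = "",
    feature: str = "",
    min_separation: int = 2,
) -> PeakSet:
    """The k strongest spectral peaks, rank 1 = maximum power.

    Candidates are restricted to periods within [2 x step, window/2];
    bins are taken in descending power (exact ties broken toward the
    lower frequency, i.e. the longer period).  Bins within
    ``min_separation`` bins of a selected peak are excluded: an
    off-grid tone spreads over roughly the rectangular window's main
    lobe plus first sidelobe (~2 bins each side), and its leakage
    shoulders must not be reported as separate peaks.
    """
    period = 1.0 / spectrum.frequencies
    eligible = (period >= 2 * spectrum.step_days) & (period <= spectrum.window_days / 2)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        return PeakSet(participant_id, feature, (), (), (), spectrum.window_days)
    order = idx[np.lexsort((spectrum.frequencies[idx], -spectrum.power[idx]))]
    chosen: list[int] = []
    for i in order:
        if len(chosen) == k:
            break
        if any(abs(i - j) <= min_separation for j in chosen):
            continue
        chosen.append(int(i))
    return PeakSet(
        participant_id=participant_id,
        feature=feature,
        periods_days=tuple(float(period[i]) for i in chosen),
        powers=tuple(float(spectrum.power[i]) for i in chosen),
        frequencies=tuple(float(spectrum.frequencies[i]) for i in chosen),
        window_days=spectrum.window_days,
    )


def window_spectral_summary(
    series: np.ndarray,
    step_days: float,
    participant_id: str = "",
    feature: str = "",
    k: int = 5,
    window: str = "boxcar",
) -> pd.DataFrame:
    """Ranked (power, frequency, period) rows for one participant window.

    Row ``rank`` 1 holds the maximum power — the "Fourier spectrum
    power" entering the group comparisons and the affective-status
    regressions.
    """
    spec = periodogram(series, step_days, window=window)
    peaks = top_k_peaks(spec, k=k, participant_id=participant_id, feature=feature)
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "feature": feature,
            "rank": np.arange(1, len(peaks.powers) + 1),
            "power": peaks.powers,
            "frequency": peaks.frequencies,
            "period_days": peaks.periods_days,
        }
    )


def _integer_period(freq: float, bin_width: float, max_period: int) -> int | None:
    """Map a peak to a whole-day cycle length, or None.

    The peak counts as a d-day cycle when 1/d is the nearest integer-day
    frequency and lies within half a frequency bin of the peak — i.e.
    the peak bin is the bin a genuine d-day tone would dominate.  Peaks
    far from every integer-day frequency (e.g. sub-daily noise bins)
    carry no whole-day label.
    """
    best_d, best_err = None, math.inf
    for d in range(1, max_period + 1):
        err = abs(freq - 1.0 / d)
        if err < best_err:
            best_d, best_err = d, err
    if best_d is not None and best_err <= bin_width / 2:
        return best_d
    return None


def cohort_period_consensus(peak_sets: list[PeakSet]) -> pd.DataFrame:
    """Tally whole-day cycle lengths across one group's top-5 peaks.

    Returns one row per integer period carried by at least one
    participant: participant count, summed rank score (lower =
    stronger), and a majority flag at strictly more than half the
    group.
    """
    if not peak_sets:
        return pd.DataFrame(
            columns=["period_days", "count", "rank_sum", "majority"]
        )
    n_group = len(peak_sets)
    counts: dict[int, set] = {}
    rank_sums: dict[int, int] = {}
    for ps in peak_sets:
        bin_width = 1.0 / ps.window_days
        max_period = int(ps.window_days // 2)
        seen: set[int] = set()
        for rank, f in enumerate(ps.frequencies, start=1):
            d = _integer_period(f, bin_width, max_period)
            if d is None or d in seen:
                continue
            seen.add(d)
            counts.setdefault(d, set()).add(ps.participant_id)
            rank_sums[d] = rank_sums.get(d, 0) + rank
    rows = [
        {
            "period_days": d,
            "count": len(counts[d]),
            "rank_sum": rank_sums[d],
            "majority": len(counts[d]) > n_group / 2,
        }
        for d in sorted(counts)
    ]
    return pd.DataFrame(rows)
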