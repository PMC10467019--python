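"""Spike detection, the binary firing-rate series, and ISI variability.

Spikes are threshold crossings of the somatic voltage (default −55 mV, the
first sample of each upward crossing, with events closer than 2 ms merged).
The firing-rate series r(t) is the binary indicator of spike-containing
samples scaled by 1/Δt, so that ∫ r dt equals the spike count.  Interspike
interval (ISI) variability is summarized by the coefficient of variation
(CV = SD/mean, population SD convention) and compared across conditions with
the Feltz–Miller asymptotic two-sample CV test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SpikeTrain",
    "FiringRateSeries",
    "detect_spikes",
    "rate_series",
    "isi_cv",
    "cv_test",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spike times in ms, strictly increasing, within the record span."""

    spike_times_ms: np.ndarray
    span_ms: float
    threshold_mV: float = -55.0
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_ms, dtype=float)
        object.__setattr__(self, "spike_times_ms", t)
        if len(t) and (np.any(np.diff(t) <= 0)):
            raise ValueError("spike times must be strictly increasing")
        if len(t) and (t[0] < 0 or t[-1] > self.span_ms):
            raise ValueError("spike times outside the record span")

    def __len__(self) -> int:
        return len(self.spike_times_ms)

    def isis_ms(self) -> np.ndarray:
        return np.diff(self.spike_times_ms)


@dataclass(frozen=True)
class FiringRateSeries:
    """r(t): 1/Δt (in 1/s) at spike-containing samples, 0 elsewhere."""

    dt_ms: float
    values: np.ndarray

    @property
    def spike_count(self) -> int:
        return int(round(np.sum(self.values) * self.dt_ms * 1e-3))


def detect_spikes(
    v_mV: np.ndarray,
    time_ms: np.ndarray,
    threshold_mV: float = -55.0,
    merge_window_ms: float = 2.0,
) -> SpikeTrain:
    """Upward threshold crossings of a voltage trace.

    A spike time is the first sample k with V[k−1] < thr ≤ V[k]; a sample 0
    already at/above threshold counts as a crossing.  Crossings closer than
    ``merge_window_ms`` are merged into one event (the first kept).
    """
    v = np.asarray(v_mV, dtype=float)
    t = np.asarray(time_ms, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite values")
    above = v >= threshold_mV
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    times = t[crossings]
    if len(times):
        kept = [times[0]]
        for s in times[1:]:
            if s - kept[-1] >= merge_window_ms:
                kept.append(s)
        times = np.array(kept)
    span = len(t) * (t[1] - t[0]) if len(t) > 1 else 0.0
    return SpikeTrain(
        spike_times_ms=times - t[0] if len(times) else times,
        span_ms=span,
        threshold_mV=threshold_mV,
    )


def rate_series(train: SpikeTrain, dt_ms: float) -> FiringRateSeries:
    """Binary firing-rate series at resolution ``dt_ms`` (values in 1/s)."""
    n = round(train.span_ms / dt_ms)
    if abs(n * dt_ms - train.span_ms) > 1e-6 * train.span_ms:
        raise ValueError(f"dt_ms={dt_ms} does not divide span {train.span_ms} ms")
    values = np.zeros(n)
    if len(train):
        idx = np.minimum((train.spike_times_ms / dt_ms).astype(int), n - 1)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("two spikes fall in one rate sample; dt too coarse")
        values[idx] = 1.0 / (dt_ms * 1e-3)
    return FiringRateSeries(dt_ms=dt_ms, values=values)


def _pooled_isis(trains) -> np.ndarray:
    if isinstance(trains, SpikeTrain):
        return trains.isis_ms()
    return np.concatenate([t.isis_ms() for t in trains]) if trains else np.array([])


def isi_cv(trains) -> float:
    """CV of interspike intervals: population SD / mean.

    ``trains`` may be one SpikeTrain or an iterable of them; for ensembles
    the ISIs are pooled across trials before taking the ratio.
    """
    isis = _pooled_isis(trains)
    if len(isis) < 2:
        raise ValueError(f"need at least 2 ISIs, got {len(isis)}")
    return float(np.std(isis) / np.mean(isis))


def cv_test(isis_a: Sequence[float], isis_b: Sequence[float]) -> Dict[str, float]:
    """Feltz–Miller asymptotic test for equality of two coefficients of variation.

    The statistic is asymptotically chi-squared with 1 df under the null of
    equal CVs; the returned p-value is two-sided.  Requires ≥ 5 intervals
    per sample and non-degenerate (nonzero mean and variance) samples.
    """
    a = np.asarray(isis_a, dtype=float)
    b = np.asarray(isis_b, dtype=float)
    for name, x in (("isis_a", a), ("isis_b", b)):
        if len(x) < 5:
            raise ValueError(f"{name}: need at least 5 intervals, got {len(x)}")
        if np.mean(x) == 0 or np.std(x, ddof=1) == 0:
            raise ValueError(f"{name}: degenerate sample (zero mean or variance)")

    def _cv(x):
        return np.std(x, ddof=1) / np.mean(x)

    cvs = np.array([_cv(a), _cv(b)])
    # degrees of freedom per sample
    nu = np.array([len(a) - 1, len(b) - 1], dtype=float)
    # Feltz & Miller (1996): weighted common CV and chi-square statistic
    d = np.sum(nu * cvs) / np.sum(nu)
    denom = d**2 * (0.5 + d**2)
    if denom == 0:
        return {"statistic": 0.0, "p_value": 1.0}
    stat = float(np.sum(nu * (cvs - d) ** 2) / denom)
    p = float(stats.chi2.sf(stat, df=1))
    return {"statistic": stat, "p_value": p}
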