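"""Spike-triggered averages (STA) and monotonicity quantification.

The STA of a signal is its mean over fixed windows ending at spike times.
Only *isolated* spikes — with no earlier spike inside the window and a full
window of recorded data before them — enter the average, so pre-spike
dynamics are not contaminated by preceding spikes.  Applied to the
percentage-contribution traces of individual ionic currents, the STA
describes how each current's share of the inward or outward current evolves
in the moments before spiking.

Monotonicity of a processed STA trace is quantified as the proportion of
difference-quotient samples that are negative (decreasing) or positive
(increasing) after normalizing by the window extremum and smoothing with a
centered 5-point moving average (edge windows shrink symmetrically, matching
the common MATLAB ``smooth`` default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from .decomposition import PercentContribution
from .spikes import SpikeTrain

__all__ = [
    "STAResult",
    "MonotonicityResult",
    "isolated_spikes",
    "sta_signal",
    "sta_contributions",
    "monotonicity",
    "moving_average_smooth",
]


@dataclass
class STAResult:
    """Mean ± SD of a signal over [−window, 0] ms relative to spike times."""

    window_ms: float
    dt_ms: float
    lags_ms: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_spikes: int
    n_trials: int
    signal_name: str = ""
    polarity: str = ""  # for contribution STAs: dominant class of the channel


@dataclass
class MonotonicityResult:
    """Fractions of the processed STA's difference quotient by sign."""

    fraction_increasing: float
    fraction_decreasing: float
    fraction_flat: float
    polarity: str
    smoothing_span: int
    processed: np.ndarray
    diff_quotient: np.ndarray

    def __post_init__(self) -> None:
        total = self.fraction_increasing + self.fraction_decreasing + self.fraction_flat
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")


def isolated_spikes(train: SpikeTrain, window_ms: float) -> SpikeTrain:
    """Spikes with no earlier spike within ``window_ms`` and a full window of data.

    The result is a subset of the input; applying the filter twice is a
    no-op.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    t = train.spike_times_ms
    keep = []
    for i, s in enumerate(t):
        if s < window_ms:
            continue  # incomplete data window before the spike
        if i > 0 and s - t[i - 1] < window_ms:
            continue
        keep.append(s)
    return SpikeTrain(
        spike_times_ms=np.array(keep),
        span_ms=train.span_ms,
        threshold_mV=train.threshold_mV,
        source=train.source,
    )


TrialSignal = Tuple[np.ndarray, SpikeTrain]


def _window_indices(train: SpikeTrain, window_ms: float, dt_ms: float, n: int):
    """Sample-index windows [k−w, k] for each isolated spike (right-edge inclusive)."""
    iso = isolated_spikes(train, window_ms)
    w = round(window_ms / dt_ms)
    idx = []
    for s in iso.spike_times_ms:
        k = int(round(s / dt_ms))
        if k >= w and k < n:
            idx.append((k - w, k + 1))
    return idx, w


def sta_signal(
    trials: Union[TrialSignal, Sequence[TrialSignal]],
    window_ms: float,
    dt_ms: float,
    signal_name: str = "",
) -> STAResult:
    """STA of a signal over isolated spikes, averaged with equal trial weight.

    ``trials`` is one ``(signal, train)`` pair or a sequence of them; the
    per-trial spike-window means are averaged across trials, and the SD
    trace is the across-trial population SD (zero for a single trial).
    """
    if isinstance(trials, tuple) and isinstance(trials[1], SpikeTrain):
        trials = [trials]
    per_trial = []
    n_spikes = 0
    w = round(window_ms / dt_ms)
    for signal, train in trials:
        windows, w = _window_indices(train, window_ms, dt_ms, len(signal))
        if not windows:
            continue
        stack = np.stack([signal[a:b] for a, b in windows])
        per_trial.append(stack.mean(axis=0))
        n_spikes += len(windows)
    if not per_trial:
        raise ValueError(
            f"no isolated spikes with a full {window_ms} ms window in any trial"
        )
    per_trial = np.stack(per_trial)
    return STAResult(
        window_ms=window_ms,
        dt_ms=dt_ms,
        lags_ms=np.linspace(-window_ms, 0.0, w + 1),
        mean=per_trial.mean(axis=0),
        sd=per_trial.std(axis=0),
        n_spikes=n_spikes,
        n_trials=len(per_trial),
        signal_name=signal_name,
    )


def sta_contributions(
    trials: Union[
        Tuple[PercentContribution, SpikeTrain],
        Sequence[Tuple[PercentContribution, SpikeTrain]],
    ],
    window_ms: float,
) -> Dict[str, STAResult]:
    """STA of each channel's percentage contribution before isolated spikes.

    Each channel is averaged in its dominant class over the spike windows
    (a channel flipping class inside a window contributes only its
    dominant-class samples; class-undefined samples are excluded, with the
    per-lag mean renormalized by the count of defined samples).  Channels
    whose dominant-class trace is never defined in any window are dropped
    from the result.
    """
    if isinstance(trials, tuple) and isinstance(trials[1], SpikeTrain):
        trials = [trials]
    first_pc = trials[0][0]
    channels = first_pc.channel_names
    dt = first_pc.dt_ms
    w = round(window_ms / dt)

    # decide dominant class from all windows of all trials
    all_windows = []
    for pc, train in trials:
        windows, _ = _window_indices(train, window_ms, dt, len(pc.time_ms))
        all_windows.append(windows)
    polarity: Dict[str, str] = {}
    for ch in channels:
        mass_in = mass_out = 0.0
        for (pc, _), windows in zip(trials, all_windows):
            for a, b in windows:
                mass_in += pc.pct_in[ch][a:b].sum()
                mass_out += pc.pct_out[ch][a:b].sum()
        polarity[ch] = "inward" if mass_in >= mass_out else "outward"

    out: Dict[str, STAResult] = {}
    for ch in channels:
        per_trial = []
        n_spikes = 0
        for (pc, train), windows in zip(trials, all_windows):
            if not windows:
                continue
            trace = pc.pct_in[ch] if polarity[ch] == "inward" else pc.pct_out[ch]
            defined = pc.in_defined if polarity[ch] == "inward" else pc.out_defined
            sums = np.zeros(w + 1)
            counts = np.zeros(w + 1)
            for a, b in windows:
                seg = trace[a:b]
                mask = defined[a:b]
                sums += np.where(mask, seg, 0.0)
                counts += mask
            if counts.max() == 0:
                continue
            with np.errstate(invalid="ignore"):
                mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            per_trial.append(mean)
            n_spikes += len(windows)
        if not per_trial:
            continue
        stack = np.stack(per_trial)
        out[ch] = STAResult(
            window_ms=window_ms,
            dt_ms=dt,
            lags_ms=np.linspace(-window_ms, 0.0, w + 1),
            mean=np.nanmean(stack, axis=0),
            sd=np.nanstd(stack, axis=0) if len(per_trial) > 1 else np.zeros(w + 1),
            n_spikes=n_spikes,
            n_trials=len(per_trial),
            signal_name=ch,
            polarity=polarity[ch],
        )
    return out


def moving_average_smooth(x: np.ndarray, span: int = 5) -> np.ndarray:
    """Centered moving average with shrinking symmetric windows at the edges.

    Matches the classic MATLAB ``smooth`` default: interior points average
    ``span`` neighbors; points nearer an edge average the largest odd window
    that fits (so the first and last samples pass through unchanged).
    """
    if span % 2 == 0:
        raise ValueError("span must be odd")
    x = np.asarray(x, dtype=float)
    n = len(x)
    half = span // 2
    y = np.empty(n)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        y[i] = x[i - k : i + k + 1].mean()
    return y


def monotonicity(
    sta: STAResult,
    polarity: str = "",
    smoothing_span: int = 5,
    diff_dt_ms: float = 1.0,
) -> MonotonicityResult:
    """Fractions of the processed STA trace that increase/decrease/stay flat.

    The mean trace is normalized by its window maximum (outward polarity) or
    minimum (inward polarity), resampled to ``diff_dt_ms`` (the sign of a
    difference quotient on the raw sub-0.1 ms integration grid reflects
    discretization noise, not trend; 1 ms is comparable to the time scale of
    the averaged contribution dynamics), smoothed with a centered
    ``smoothing_span``-point moving average, and differenced; the fraction
    of negative difference-quotient samples is the decreasing proportion,
    symmetrically for increasing.  A fully monotone contribution has one
    fraction equal to 1.
    """
    polarity = polarity or sta.polarity
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    trace = np.asarray(sta.mean, dtype=float)
    if np.all(trace == 0):
        raise ValueError("all-zero STA trace cannot be normalized")
    step = max(1, round(diff_dt_ms / sta.dt_ms))
    trace = trace[::step]
    dt_ms = sta.dt_ms * step
    if len(trace) < smoothing_span:
        raise ValueError("trace shorter than the smoothing span")
    ref = trace.min() if polarity == "inward" else trace.max()
    if ref == 0:
        raise ValueError(f"normalizing extremum is zero for polarity {polarity!r}")
    processed = moving_average_smooth(trace / ref, smoothing_span)
    dq = np.diff(processed) / (dt_ms * 1e-3)
    n = len(dq)
    frac_inc = float(np.sum(dq > 0) / n)
    frac_dec = float(np.sum(dq < 0) / n)
    frac_flat = float(np.sum(dq == 0) / n)
    return MonotonicityResult(
        fraction_increasing=frac_inc,
        fraction_decreasing=frac_dec,
        fraction_flat=frac_flat,
        polarity=polarity,
        smoothing_span=smoothing_span,
        processed=processed,
        diff_quotient=dq,
    )
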