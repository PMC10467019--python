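"""Orchestration of the frozen-noise experiment across h-current conditions.

A protocol run mirrors the electrophysiological paradigm: for each h-current
scaling (typically 0, 0.5, 1 and 2 times the preset maximal conductance) the
DC offset is calibrated to the target spike count, the same set of noise
realizations (trial i uses seed base_seed + i, identical across conditions)
is injected, and every trial is analyzed: spike detection, frequency-
dependent gain, inward/outward percentage decomposition, spike-triggered
averages of the contributions, and monotonicity statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import neuron_sim
from .decomposition import percent_contributions
from .fdg import (
    FDGCurve,
    FDGEnsemble,
    average_fdg_insilico,
    compare_pointwise,
    compute_fdg,
    fdg_variability,
    find_fdg_peaks,
    normalize_fdg,
)
from .neuron_sim import ModelParams, scale_channel, simulate
from .spikes import SpikeTrain, cv_test, detect_spikes, isi_cv
from .sta import MonotonicityResult, STAResult, monotonicity, sta_contributions, sta_signal
from .stimgen import StimulusSpec, make_frozen_noise

__all__ = [
    "ExperimentConfig",
    "ConditionReport",
    "ProtocolError",
    "run_condition",
    "run_protocol",
    "compare_conditions",
    "calibrate_dc_mean",
]

#: Default prominence (normalized-gain units) above which a local maximum of
#: an averaged normalized FDG counts as a peak.
PEAK_PROMINENCE = 0.1


class ProtocolError(RuntimeError):
    pass


@dataclass
class ExperimentConfig:
    """Full specification of one in-silico experiment."""

    preset: str = "human_like"  # human_like | rodent_like
    channel_scalings: Dict[str, float] = field(default_factory=dict)
    n_trials: int = 30
    base_seed: int = 100
    duration_ms: float = 2500.0
    dt_ms: float = 0.025
    sigma_nA: float = 0.04
    pulse_width_ms: float = 3.0
    dc_policy: str = "calibrate"  # "calibrate" or "fixed"
    dc_nA: Optional[float] = None  # used when dc_policy == "fixed"
    target_spikes: Tuple[int, int] = (12, 15)
    dc_bounds: Tuple[float, float] = (-0.3, 0.7)
    sta_windows_ms: Tuple[float, ...] = (30.0, 100.0, 200.0)
    peak_prominence: float = PEAK_PROMINENCE

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if any(v < 0 for v in self.channel_scalings.values()):
            raise ValueError("channel scalings must be >= 0")
        if self.dc_policy not in ("calibrate", "fixed"):
            raise ValueError("dc_policy must be 'calibrate' or 'fixed'")
        if self.dc_policy == "fixed" and self.dc_nA is None:
            raise ValueError("dc_policy 'fixed' requires dc_nA")

    def model(self) -> ModelParams:
        m = getattr(neuron_sim, self.preset)()
        for name, factor in self.channel_scalings.items():
            m = scale_channel(m, name, factor)
        return m

    def stimulus_spec(self, trial: int = 0, dc_nA: float = 0.0) -> StimulusSpec:
        return StimulusSpec(
            duration_ms=self.duration_ms,
            dt_ms=self.dt_ms,
            sigma_nA=self.sigma_nA,
            pulse_width_ms=self.pulse_width_ms,
            dc_nA=dc_nA,
            seed=self.base_seed + trial,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        for key in ("target_spikes", "dc_bounds", "sta_windows_ms"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ConditionReport:
    """All per-condition analysis artifacts of one protocol run."""

    config: ExperimentConfig
    condition: str
    dc_nA: float
    trains: List[SpikeTrain]
    ensemble: FDGEnsemble              # non-normalized trial curves
    normalized_ensemble: FDGEnsemble   # per-trial min-max normalized curves
    average: FDGCurve
    normalized_average: FDGCurve
    peaks_Hz: List[float]
    isi_cv: float
    spike_counts: List[int]
    sta: Dict[float, Dict[str, STAResult]]            # window -> channel -> STA
    monotonicity: Dict[float, Dict[str, MonotonicityResult]]
    stimulus_sta: Dict[float, STAResult]
    variability: Dict[str, float]
    excluded_trials: List[int]
    seeds: List[int]


def calibrate_dc_mean(
    model: ModelParams,
    config: ExperimentConfig,
    n_calib_trials: int = 5,
    max_iter: int = 30,
) -> float:
    """Calibrate the DC offset against the mean spike count over trial noises.

    Bisection on DC targeting a mean count (over the first ``n_calib_trials``
    trial seeds) inside ``config.target_spikes``; using several of the actual
    trial noises removes the single-realization bias of calibrating on one
    frozen noise.
    """
    lo_t, hi_t = config.target_spikes
    mid_lo, mid_hi = lo_t + 0.5, hi_t - 0.5
    seeds = range(min(n_calib_trials, config.n_trials))

    def mean_count(dc: float) -> float:
        total = 0
        for i in seeds:
            stim = make_frozen_noise(config.stimulus_spec(i, dc))
            sim = simulate(model, stim)
            total += len(detect_spikes(sim.v_mV, sim.time_ms))
        return total / len(list(seeds))

    lo, hi = config.dc_bounds
    n_lo, n_hi = mean_count(lo), mean_count(hi)
    if n_lo > hi_t or n_hi < lo_t:
        raise ProtocolError(
            f"target {config.target_spikes} not bracketed: mean {n_lo} at "
            f"{lo} nA, {n_hi} at {hi} nA"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        n = mean_count(mid)
        if n < mid_lo:
            lo = mid
        elif n > mid_hi:
            hi = mid
        else:
            return mid
    return 0.5 * (lo + hi)


def run_condition(
    config: ExperimentConfig,
    condition: str = "default",
    model: Optional[ModelParams] = None,
) -> ConditionReport:
    """Run all trials of one condition and aggregate the analyses."""
    model = model if model is not None else config.model()
    if config.dc_policy == "fixed":
        dc = float(config.dc_nA)
    else:
        dc = calibrate_dc_mean(model, config)

    trains: List[SpikeTrain] = []
    curves: List[FDGCurve] = []
    norm_curves: List[FDGCurve] = []
    pcs = []
    stim_trials = []
    counts: List[int] = []
    excluded: List[int] = []
    seeds: List[int] = []

    for i in range(config.n_trials):
        spec = config.stimulus_spec(i, dc)
        stim = make_frozen_noise(spec)
        sim = simulate(model, stim)
        train = detect_spikes(sim.v_mV, sim.time_ms)
        if len(train) < 2:
            excluded.append(i)
            continue
        seeds.append(spec.seed)
        counts.append(len(train))
        trains.append(train)
        curve = compute_fdg(stim, train)
        curves.append(curve)
        norm_curves.append(normalize_fdg(curve))
        pcs.append((percent_contributions(sim), train))
        stim_trials.append((stim.samples, train))

    if len(excluded) > config.n_trials / 2:
        raise ProtocolError(
            f"condition {condition!r}: {len(excluded)}/{config.n_trials} "
            "trials excluded (fewer than 2 spikes)"
        )

    ensemble = FDGEnsemble(curves, condition=condition)
    norm_ensemble = FDGEnsemble(norm_curves, condition=condition)
    average = average_fdg_insilico(ensemble)
    normalized_average = average_fdg_insilico(norm_ensemble)

    sta_by_window: Dict[float, Dict[str, STAResult]] = {}
    mono_by_window: Dict[float, Dict[str, MonotonicityResult]] = {}
    stim_sta: Dict[float, STAResult] = {}
    for w in config.sta_windows_ms:
        stas = sta_contributions(pcs, w)
        sta_by_window[w] = stas
        mono_by_window[w] = {}
        for name, st in stas.items():
            try:
                mono_by_window[w][name] = monotonicity(st)
            except ValueError:
                pass  # e.g. all-zero contribution
        try:
            stim_sta[w] = sta_signal(stim_trials, w, config.dt_ms, "stimulus")
        except ValueError:
            pass

    variability = (
        fdg_variability(ensemble) if len(ensemble) >= 2 else {"mean_sd": 0.0, "max_cv": 0.0}
    )

    return ConditionReport(
        config=config,
        condition=condition,
        dc_nA=dc,
        trains=trains,
        ensemble=ensemble,
        normalized_ensemble=norm_ensemble,
        average=average,
        normalized_average=normalized_average,
        peaks_Hz=find_fdg_peaks(normalized_average, config.peak_prominence),
        isi_cv=isi_cv(trains),
        spike_counts=counts,
        sta=sta_by_window,
        monotonicity=mono_by_window,
        stimulus_sta=stim_sta,
        variability=variability,
        excluded_trials=excluded,
        seeds=seeds,
    )


def run_protocol(
    config: ExperimentConfig,
    ih_scalings: Tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
) -> Dict[float, ConditionReport]:
    """Run the full multi-condition experiment over h-current scalings.

    Trial noise is paired across conditions (same seeds); only the h-current
    maximal conductance and the calibrated DC differ.
    """
    base_model = config.model()
    reports = {}
    for s in ih_scalings:
        model = scale_channel(base_model, "Ih", s)
        reports[s] = run_condition(config, condition=f"Ih x {s:g}", model=model)
    return reports


def compare_conditions(report_a: ConditionReport, report_b: ConditionReport) -> Dict:
    """Statistical comparison of two condition reports.

    Pointwise Bonferroni-corrected t-tests on both the raw and normalized
    ensembles, presence/absence of sub-10 Hz normalized-average peaks, and
    the two-sample CV test on the pooled interspike intervals.
    """
    if not np.array_equal(report_a.ensemble.freqs_Hz, report_b.ensemble.freqs_Hz):
        raise ValueError("reports use different frequency grids")
    isis_a = np.concatenate([t.isis_ms() for t in report_a.trains])
    isis_b = np.concatenate([t.isis_ms() for t in report_b.trains])
    low = lambda peaks: [p for p in peaks if p < 10.0]
    return {
        "significant_freqs_raw": compare_pointwise(report_a.ensemble, report_b.ensemble),
        "significant_freqs_normalized": compare_pointwise(
            report_a.normalized_ensemble, report_b.normalized_ensemble
        ),
        "low_freq_peaks_a": low(report_a.peaks_Hz),
        "low_freq_peaks_b": low(report_b.peaks_Hz),
        "isi_cv_a": report_a.isi_cv,
        "isi_cv_b": report_b.isi_cv,
        "cv_test": cv_test(isis_a, isis_b),
    }
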