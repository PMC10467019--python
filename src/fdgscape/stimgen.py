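"""Frozen-noise current stimuli and DC calibration.

The stimulation protocol injects a single fixed ("frozen") realization of
low-pass-filtered Gaussian noise — white noise convolved with a short square
pulse — plus a tonic DC offset.  The DC offset is calibrated per model and
condition so that the neuron emits a target number of spikes over the record,
which keeps mean firing rate comparable across conditions while the noise
component stays identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = [
    "StimulusSpec",
    "StimulusTrace",
    "make_frozen_noise",
    "calibrate_dc",
    "CalibrationError",
]


class CalibrationError(RuntimeError):
    """Raised when no DC offset within the bounds yields the target spike count."""


@dataclass(frozen=True)
class StimulusSpec:
    """Generating statistics of a frozen-noise current stimulus.

    Parameters
    ----------
    duration_ms : float
        Record length in ms (default 2500).
    dt_ms : float
        Sample interval in ms.
    sigma_nA : float
        Target sample standard deviation of the noise component, in nA
        (default 0.04).  The delivered trace is rescaled after filtering so
        its sample SD equals this value exactly.
    pulse_width_ms : float
        Width of the square convolution kernel in ms (default 3).
    dc_nA : float
        Tonic offset added after rescaling.
    seed : int
        Seed of the Gaussian draw; identical specs give bit-identical traces.
    """

    duration_ms: float = 2500.0
    dt_ms: float = 0.025
    sigma_nA: float = 0.04
    pulse_width_ms: float = 3.0
    dc_nA: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be positive, got {self.duration_ms}")
        if self.dt_ms <= 0:
            raise ValueError(f"dt_ms must be positive, got {self.dt_ms}")
        if self.sigma_nA < 0:
            raise ValueError(f"sigma_nA must be non-negative, got {self.sigma_nA}")
        if self.pulse_width_ms < self.dt_ms:
            raise ValueError("pulse_width_ms must be at least dt_ms")

    @property
    def n_samples(self) -> int:
        return round(self.duration_ms / self.dt_ms)

    def with_dc(self, dc_nA: float) -> "StimulusSpec":
        return replace(self, dc_nA=dc_nA)

    def with_seed(self, seed: int) -> "StimulusSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class StimulusTrace:
    """A realized stimulus: current samples in nA on the spec's dt grid."""

    spec: StimulusSpec
    samples: np.ndarray

    def __post_init__(self) -> None:
        if len(self.samples) != self.spec.n_samples:
            raise ValueError(
                f"samples length {len(self.samples)} != spec n_samples {self.spec.n_samples}"
            )

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.spec.n_samples) * self.spec.dt_ms

    @property
    def dt_ms(self) -> float:
        return self.spec.dt_ms


def make_frozen_noise(spec: StimulusSpec) -> StimulusTrace:
    """Generate the frozen-noise stimulus defined by ``spec``.

    I.i.d. standard-normal samples on the dt grid are convolved with a
    unit-area square kernel of width ``pulse_width_ms``; the filtered signal
    is recentred and rescaled so its sample SD equals ``sigma_nA`` exactly,
    then ``dc_nA`` is added.  The Gaussian draw is extended by one kernel
    width so only fully-supported (valid) convolution samples are kept —
    no edge taper enters the record.
    """
    n = spec.n_samples
    kernel_len = max(1, round(spec.pulse_width_ms / spec.dt_ms))
    rng = np.random.default_rng(spec.seed)

    if spec.sigma_nA == 0.0:
        return StimulusTrace(spec=spec, samples=np.full(n, spec.dc_nA))

    white = rng.standard_normal(n + kernel_len - 1)
    kernel = np.full(kernel_len, 1.0 / kernel_len)
    filtered = np.convolve(white, kernel, mode="valid")
    assert len(filtered) == n

    filtered = filtered - filtered.mean()
    sd = filtered.std()
    samples = filtered * (spec.sigma_nA / sd) + spec.dc_nA
    return StimulusTrace(spec=spec, samples=samples)


def calibrate_dc(
    model,
    base_spec: StimulusSpec,
    target_spikes: Tuple[int, int] = (12, 15),
    dc_bounds: Tuple[float, float] = (-0.1, 0.5),
    max_iter: int = 40,
    threshold_mV: float = -55.0,
) -> float:
    """Find a DC offset whose simulated spike count lies in ``target_spikes``.

    Bisection on the DC value, assuming spike count is non-decreasing in DC
    (checked at the bounds; violation raises).  Ties break toward the
    smallest DC achieving the range: once a count in range is found the
    search continues downward while staying in range.
    """
    from .neuron_sim import simulate
    from .spikes import detect_spikes

    lo_target, hi_target = target_spikes
    if lo_target > hi_target:
        raise ValueError("target_spikes range is empty")
    lo, hi = dc_bounds
    if not lo < hi:
        raise ValueError("dc_bounds must satisfy lo < hi")

    def count_at(dc: float) -> int:
        stim = make_frozen_noise(base_spec.with_dc(dc))
        sim = simulate(model, stim)
        return len(detect_spikes(sim.v_mV, sim.time_ms, threshold_mV=threshold_mV))

    n_lo, n_hi = count_at(lo), count_at(hi)
    if n_hi < n_lo:
        raise CalibrationError(
            f"spike count not monotone over dc_bounds: {n_lo} at {lo} nA, {n_hi} at {hi} nA"
        )
    if n_lo > hi_target or n_hi < lo_target:
        raise CalibrationError(
            f"target {target_spikes} not bracketed: {n_lo} spikes at dc={lo} nA, "
            f"{n_hi} spikes at dc={hi} nA"
        )

    best = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        n_mid = count_at(mid)
        if n_mid < lo_target:
            lo = mid
        else:
            # In range or above: shrink from the top to prefer the smallest dc.
            if lo_target <= n_mid <= hi_target:
                best = mid
            hi = mid
    if best is None:
        raise CalibrationError(
            f"no dc in {dc_bounds} reached {target_spikes} spikes within "
            f"{max_iter} bisection steps (bounds now [{lo}, {hi}])"
        )
    return best
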