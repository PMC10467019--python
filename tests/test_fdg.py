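"""Frequency-dependent gain estimation and curve statistics."""

import numpy as np
import pytest

from fdgscape import (
    FDG_GRID_HZ,
    FDGCurve,
    FDGEnsemble,
    SpikeTrain,
    StimulusSpec,
    average_fdg_insilico,
    average_fdg_invitro,
    compare_pointwise,
    compute_fdg,
    fdg_variability,
    find_fdg_peaks,
    make_frozen_noise,
    normalize_fdg,
)
from fdgscape.fdg import DegenerateCurveError
from fdgscape.stimgen import StimulusTrace


def fdg_oracle(samples, train, dt_ms, max_lag_ms=500.0):
    """Independent direct-DFT implementation of the gain estimator.

    Biased correlations computed lag by lag with explicit dot products, a
    triangular lag window, and an explicit complex exponential sum at each
    grid frequency.
    """
    s = samples - samples.mean()
    n = len(s)
    dt_s = dt_ms * 1e-3
    r = np.zeros(n)
    idx = np.minimum((train.spike_times_ms / dt_ms).astype(int), n - 1)
    r[idx] = 1.0 / dt_s
    max_lag = min(round(max_lag_ms / dt_ms), n - 1)
    lags = np.arange(-max_lag, max_lag + 1)
    c_sr = np.empty(len(lags))
    c_ss = np.empty(len(lags))
    for j, tau in enumerate(lags):
        if tau >= 0:
            c_sr[j] = s[: n - tau] @ r[tau:] / n
            c_ss[j] = s[: n - tau] @ s[tau:] / n
        else:
            c_sr[j] = s[-tau:] @ r[: n + tau] / n
            c_ss[j] = s[-tau:] @ s[: n + tau] / n
    w = 1.0 - np.abs(lags) / (max_lag + 1)
    gains = np.empty(len(FDG_GRID_HZ))
    for i, f in enumerate(FDG_GRID_HZ):
        phase = np.exp(-2j * np.pi * f * lags * dt_s)
        gains[i] = abs(np.sum(w * c_sr * phase)) / abs(np.sum(w * c_ss * phase))
    return gains


def poisson_train(rate_hz, span_ms, rng, dead_ms=2.0):
    t = np.sort(rng.uniform(0, span_ms, rng.poisson(rate_hz * span_ms / 1000.0)))
    if len(t) == 0:
        return SpikeTrain(spike_times_ms=t, span_ms=span_ms)
    keep = [t[0]]
    for x in t[1:]:
        if x - keep[-1] >= dead_ms:
            keep.append(x)
    return SpikeTrain(spike_times_ms=np.array(keep), span_ms=span_ms)


def curve(gains):
    return FDGCurve(freqs_Hz=FDG_GRID_HZ.copy(), gains=np.asarray(gains, dtype=float))


class TestComputeFdg:
    def test_matches_direct_dft_oracle(self):
        """FFT pipeline vs the explicit-lag-loop oracle on a 1e4-sample record."""
        spec = StimulusSpec(duration_ms=2500, dt_ms=0.25, seed=17, dc_nA=0.05)
        stim = make_frozen_noise(spec)
        rng = np.random.default_rng(3)
        train = poisson_train(6.0, 2500.0, rng)
        fast = compute_fdg(stim, train).gains
        slow = fdg_oracle(stim.samples, train, 0.25)
        np.testing.assert_allclose(fast, slow, rtol=1e-6)

    def test_stimulus_scaling_identity(self):
        """G(f) -> G(f)/a when the stimulus is scaled by a (|aC_sr|/|a^2 C_ss|)."""
        spec = StimulusSpec(duration_ms=2500, dt_ms=0.1, seed=2)
        stim = make_frozen_noise(spec)
        rng = np.random.default_rng(5)
        train = poisson_train(6.0, 2500.0, rng)
        g1 = compute_fdg(stim, train).gains
        scaled = StimulusTrace(spec=spec, samples=stim.samples * 3.0)
        g3 = compute_fdg(scaled, train).gains
        np.testing.assert_allclose(g3, g1 / 3.0, rtol=1e-9)

    def test_empty_train_rejected(self):
        stim = make_frozen_noise(StimulusSpec(seed=1))
        with pytest.raises(ValueError):
            compute_fdg(stim, SpikeTrain(spike_times_ms=np.array([]), span_ms=2500.0))

    def test_short_record_rejected(self):
        stim = make_frozen_noise(StimulusSpec(duration_ms=500, seed=1))
        with pytest.raises(ValueError):
            compute_fdg(
                stim, SpikeTrain(spike_times_ms=np.array([100.0]), span_ms=500.0)
            )

    def test_grid_is_146_points(self):
        assert len(FDG_GRID_HZ) == 146
        assert FDG_GRID_HZ[0] == 1.0 and FDG_GRID_HZ[-1] == 30.0

    def test_poisson_null_flat_after_averaging(self):
        """Spikes independent of the stimulus: no grid point sticks out."""
        rng = np.random.default_rng(0)
        curves = []
        for i in range(100):
            stim = make_frozen_noise(StimulusSpec(dt_ms=0.1, seed=3000 + i, dc_nA=0.1))
            train = poisson_train(5.5, 2500.0, rng)
            if len(train) < 2:
                continue
            curves.append(normalize_fdg(compute_fdg(stim, train)))
        ens = FDGEnsemble(curves)
        mean = ens.gain_matrix().mean(axis=0)
        sd = ens.gain_matrix().std(axis=0) / np.sqrt(len(curves))
        assert np.all(np.abs(mean - mean.mean()) < 5 * sd.mean() + 0.05)


class TestAveraging:
    def test_single_curve_average_is_itself(self):
        c = curve(np.linspace(1, 3, 146))
        avg = average_fdg_insilico(FDGEnsemble([c]))
        np.testing.assert_allclose(avg.gains, c.gains)

    def test_mean_of_g_and_3g(self):
        g = np.linspace(1, 3, 146)
        avg = average_fdg_insilico(FDGEnsemble([curve(g), curve(3 * g)]))
        np.testing.assert_allclose(avg.gains, 2 * g)

    def test_invitro_weights_neurons_equally(self):
        g = np.ones(146)
        by_neuron = {"n1": [curve(g)], "n2": [curve(3 * g)] * 9}
        avg = average_fdg_invitro(by_neuron)
        np.testing.assert_allclose(avg.gains, 2 * g)  # (1 + 3)/2, not trial-weighted

    def test_invitro_degenerate_normalization_names_neuron(self):
        by_neuron = {"flat": [curve(np.ones(146))]}
        with pytest.raises(DegenerateCurveError, match="flat"):
            average_fdg_invitro(by_neuron, normalize_first=True)


class TestNormalize:
    def test_endpoints_map_to_unit_interval(self):
        c = normalize_fdg(curve(np.linspace(2, 10, 146)))
        assert c.gains.min() == 0.0 and c.gains.max() == 1.0
        assert c.normalized

    def test_affine_invariance(self):
        g = np.abs(np.sin(np.linspace(0, 5, 146))) + 0.5
        a = normalize_fdg(curve(g)).gains
        b = normalize_fdg(curve(4.0 * g + 2.0)).gains
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_curve_rejected(self):
        with pytest.raises(DegenerateCurveError):
            normalize_fdg(curve(np.ones(146)))


class TestVariability:
    def test_duplicates_zero_variability(self):
        c = curve(np.linspace(1, 2, 146))
        out = fdg_variability(FDGEnsemble([c, c]))
        assert out["mean_sd"] == 0.0 and out["max_cv"] == 0.0

    def test_hand_computed_toy(self):
        # curves g and 3g: pointwise population SD = g, mean = 2g -> cv = 0.5
        g = np.linspace(1, 2, 146)
        out = fdg_variability(FDGEnsemble([curve(g), curve(3 * g)]), band_Hz=(1, 30))
        assert out["mean_sd"] == pytest.approx(g.mean())
        assert out["max_cv"] == pytest.approx(0.5)

    def test_band_outside_grid_rejected(self):
        c = curve(np.linspace(1, 2, 146))
        with pytest.raises(ValueError):
            fdg_variability(FDGEnsemble([c, c]), band_Hz=(0.1, 50))


class TestFindPeaks:
    def test_unimodal_peak_location(self):
        g = np.exp(-0.5 * ((FDG_GRID_HZ - 3.0) / 1.0) ** 2)
        assert find_fdg_peaks(curve(g), 0.1) == [3.0]

    def test_two_bumps(self):
        g = np.exp(-0.5 * ((FDG_GRID_HZ - 3.0) / 0.5) ** 2) + 0.8 * np.exp(
            -0.5 * ((FDG_GRID_HZ - 6.0) / 0.5) ** 2
        )
        assert find_fdg_peaks(curve(g), 0.1) == [3.0, 6.0]

    def test_monotone_curve_has_no_peak(self):
        assert find_fdg_peaks(curve(np.linspace(1, 2, 146)), 0.0) == []


class TestComparePointwise:
    def _ensemble(self, rng, offset=None, n=30):
        curves = []
        for _ in range(n):
            g = 10.0 + rng.standard_normal(146)
            if offset is not None:
                g = g + offset
            curves.append(curve(np.abs(g)))
        return FDGEnsemble(curves)

    def test_self_comparison_empty(self):
        rng = np.random.default_rng(1)
        e = self._ensemble(rng)
        assert compare_pointwise(e, e) == []

    def test_planted_effect_at_single_frequency(self):
        rng = np.random.default_rng(2)
        offset = np.zeros(146)
        offset[np.flatnonzero(FDG_GRID_HZ == 5.0)[0]] = 10.0  # 10 x within-SD
        a = self._ensemble(rng)
        # paired design: same curves shifted only at 5 Hz
        b = FDGEnsemble([curve(c.gains + offset) for c in a.curves])
        assert compare_pointwise(a, b) == [5.0]

    def test_familywise_error_rate_controlled(self):
        rng = np.random.default_rng(3)
        false_hits = 0
        n_rep = 200
        for _ in range(n_rep):
            if compare_pointwise(self._ensemble(rng), self._ensemble(rng)):
                false_hits += 1
        assert false_hits / n_rep <= 0.07
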