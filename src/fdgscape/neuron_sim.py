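"""Single-compartment conductance-based neuron with labeled ionic currents.

This is the package's synthetic-data generator: a minimal Hodgkin–Huxley-style
point neuron that emulates the statistical structure the downstream analyses
assume — noisy-current-driven spiking at a few Hz with a subthreshold-active,
slowly-gated, inward h-current.  Two h-current presets are provided: a
"human-like" variant whose activation time constant peaks at several hundred
ms near rest, and a "rodent-like" variant roughly ten times faster.  The
channel parameters are implementation defaults chosen to generate Na/K
spiking plus slow subthreshold resonance; they are not fits to any published
multi-compartment model (trace import exists for that path).

Sign convention: membrane currents are positive outward (hyperpolarizing);
the h-current at subthreshold voltages is therefore negative (inward).

Units: mV, ms, nA, nF, µS throughout (µS · mV = nA; nA · ms / nF = mV).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Dict, List, Optional

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

from .stimgen import StimulusTrace

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "ModelParams",
    "SimResult",
    "simulate",
    "scale_channel",
    "intrinsic_properties",
    "human_like",
    "rodent_like",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """Raised when the membrane integration blows up."""


@dataclass(frozen=True)
class GateSpec:
    """First-order Boltzmann gate.

    steady state:  x_inf(V) = 1 / (1 + exp(-(V - half_mV) / slope_mV))
        slope_mV > 0: opens with depolarization (activation-type)
        slope_mV < 0: opens with hyperpolarization (h-type / inactivation)
    time constant: tau(V) = base_ms + amp_ms * exp(-((V - center_mV)/width_mV)^2)
        a Gaussian bump, strictly positive for all V.
    """

    half_mV: float
    slope_mV: float
    exponent: int = 1
    tau_base_ms: float = 1.0
    tau_amp_ms: float = 0.0
    tau_center_mV: float = -60.0
    tau_width_mV: float = 20.0

    def __post_init__(self) -> None:
        if self.slope_mV == 0:
            raise ValueError("slope_mV must be nonzero")
        if self.exponent < 1:
            raise ValueError("exponent must be >= 1")
        if self.tau_base_ms <= 0 or self.tau_amp_ms < 0:
            raise ValueError("time constant must be positive on [-120, 60] mV")

    def x_inf(self, v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(np.asarray(v) - self.half_mV) / self.slope_mV))

    def tau(self, v: np.ndarray) -> np.ndarray:
        z = (np.asarray(v) - self.tau_center_mV) / self.tau_width_mV
        return self.tau_base_ms + self.tau_amp_ms * np.exp(-z * z)


@dataclass(frozen=True)
class ChannelSpec:
    """One membrane conductance: I = gbar * m^p * h * (V - e_rev), in nA.

    ``act`` and ``inact`` are optional gates; a channel with neither (leak)
    is purely ohmic.
    """

    name: str
    gbar_uS: float
    e_rev_mV: float
    act: Optional[GateSpec] = None
    inact: Optional[GateSpec] = None

    def __post_init__(self) -> None:
        if self.gbar_uS < 0:
            raise ValueError(f"gbar must be >= 0 for channel {self.name!r}")


@dataclass(frozen=True)
class ModelParams:
    """A point-neuron model: capacitance plus a list of labeled channels."""

    capacitance_nF: float = 0.1
    channels: tuple = ()
    species_preset: str = "custom"
    v_init_mV: float = -70.0

    def __post_init__(self) -> None:
        if self.capacitance_nF <= 0:
            raise ValueError("capacitance_nF must be positive")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channel names: {names}")
        if names.count("leak") != 1:
            raise ValueError("exactly one channel must be named 'leak'")

    @property
    def channel_names(self) -> List[str]:
        return [c.name for c in self.channels]

    def channel(self, name: str) -> ChannelSpec:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel named {name!r}")


@dataclass
class SimResult:
    """One trial: voltage plus per-channel currents on the stimulus grid.

    ``currents`` maps channel name → I_c(t) in nA, positive outward.  The
    discrete current balance C*(V[k+1]-V[k])/dt + sum_c I_c[k] = I_inj[k]
    holds exactly by construction of the explicit voltage update.
    """

    time_ms: np.ndarray
    v_mV: np.ndarray
    currents: Dict[str, np.ndarray]
    i_inj_nA: np.ndarray
    params: ModelParams
    dt_ms: float

    @property
    def total_ionic_nA(self) -> np.ndarray:
        return np.sum(list(self.currents.values()), axis=0)

    def balance_residual_nA(self) -> np.ndarray:
        """|C dV/dt + sum I_c − I_inj| using the forward difference, per step."""
        c = self.params.capacitance_nF
        dvdt = np.diff(self.v_mV) / self.dt_ms
        return np.abs(
            c * dvdt + self.total_ionic_nA[:-1] - self.i_inj_nA[:-1]
        )


# ---------------------------------------------------------------------------
# presets

def _ih_channel(gbar_uS: float, tau_base_ms: float, tau_amp_ms: float) -> ChannelSpec:
    # Activation is steep and positioned below rest so that the gate responds
    # strongly to post-spike hyperpolarizations while adding little resting
    # conductance; tau(V) peaks near -80 mV and falls off within ~15 mV, so
    # the gate is slow at rest but relaxes within an interspike interval at
    # depolarized potentials.
    return ChannelSpec(
        name="Ih",
        gbar_uS=gbar_uS,
        e_rev_mV=-45.0,
        act=GateSpec(
            half_mV=-74.0,
            slope_mV=-5.0,  # opens with hyperpolarization
            exponent=1,
            tau_base_ms=tau_base_ms,
            tau_amp_ms=tau_amp_ms,
            tau_center_mV=-80.0,
            tau_width_mV=12.0,
        ),
    )


def _spiking_channels() -> List[ChannelSpec]:
    # Minimal spiking backbone: transient Na and a strong but briefly-
    # deactivating fast K (deep, short afterhyperpolarization), a slow
    # non-inactivating K (negligible by default), an ohmic background cation
    # conductance that carries part of the subthreshold inward current, and
    # leak.  Conductances are sized for a 0.2 nF compartment with a slow
    # (~tens of ms) membrane time constant so that low-frequency components
    # of the noise dominate the subthreshold voltage.
    return [
        ChannelSpec(
            name="NaT",
            gbar_uS=4.0,
            e_rev_mV=50.0,
            act=GateSpec(-38.0, 6.0, 3, 0.04, 0.06, -38.0, 15.0),
            inact=GateSpec(-60.0, -7.0, 1, 0.5, 6.0, -60.0, 20.0),
        ),
        ChannelSpec(
            name="Kfast",
            gbar_uS=3.0,
            e_rev_mV=-85.0,
            act=GateSpec(-30.0, 9.0, 4, 0.8, 5.0, -75.0, 20.0),
        ),
        ChannelSpec(
            name="Kslow",
            gbar_uS=0.001,
            e_rev_mV=-90.0,
            act=GateSpec(-40.0, 5.0, 1, 80.0, 0.0, -60.0, 30.0),
        ),
        ChannelSpec(name="cation", gbar_uS=0.0015, e_rev_mV=0.0),
        ChannelSpec(name="leak", gbar_uS=0.004, e_rev_mV=-90.0),
    ]


def human_like(g_h_uS: float = 0.07) -> ModelParams:
    """Preset with slow h-current kinetics (tau peaking ~400 ms near −80 mV)."""
    return ModelParams(
        capacitance_nF=0.2,
        channels=tuple(_spiking_channels() + [_ih_channel(g_h_uS, 50.0, 350.0)]),
        species_preset="human_like",
        v_init_mV=-70.0,
    )


def rodent_like(g_h_uS: float = 0.07) -> ModelParams:
    """Preset with fast h-current kinetics (tau peaking ~40 ms near −80 mV)."""
    return ModelParams(
        capacitance_nF=0.2,
        channels=tuple(_spiking_channels() + [_ih_channel(g_h_uS, 8.0, 32.0)]),
        species_preset="rodent_like",
        v_init_mV=-70.0,
    )


# ---------------------------------------------------------------------------
# integration

def _pack(params: ModelParams) -> np.ndarray:
    """Channel table for the jit core: one row per channel.

    Columns: gbar, e_rev,
             act(half, slope, exp, tb, ta, tc, tw)  [exp = 0 → gateless],
             inact(half, slope, exp, tb, ta, tc, tw).
    """
    rows = []
    for c in params.channels:
        row = [c.gbar_uS, c.e_rev_mV]
        for g in (c.act, c.inact):
            if g is None:
                row += [0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0]
            else:
                row += [
                    g.half_mV,
                    g.slope_mV,
                    float(g.exponent),
                    g.tau_base_ms,
                    g.tau_amp_ms,
                    g.tau_center_mV,
                    g.tau_width_mV,
                ]
        rows.append(row)
    return np.array(rows, dtype=np.float64)


@njit(cache=True)
def _gate_inf_tau(v, half, slope, tb, ta, tc, tw):
    x_inf = 1.0 / (1.0 + np.exp(-(v - half) / slope))
    z = (v - tc) / tw
    tau = tb + ta * np.exp(-z * z)
    return x_inf, tau


@njit(cache=True)
def _integrate(table, c_nf, v0, dt, i_inj, record):
    """Explicit integration: exponential Euler for gates, forward Euler for V.

    Returns (V, I) with I[c, k] the current of channel c at step k, evaluated
    at the pre-update state, so the discrete balance is exact.  record=False
    skips the current arrays (used for settling).
    """
    nchan = table.shape[0]
    n = i_inj.shape[0]
    v = np.empty(n + 1)
    v[0] = v0
    if record:
        cur = np.empty((nchan, n))
    else:
        cur = np.empty((nchan, 0))

    # gate states initialized at steady state for v0
    m = np.ones(nchan)
    h = np.ones(nchan)
    for c in range(nchan):
        if table[c, 4] > 0.0:
            m[c], _ = _gate_inf_tau(v0, table[c, 2], table[c, 3], table[c, 5], table[c, 6], table[c, 7], table[c, 8])
        if table[c, 11] > 0.0:
            h[c], _ = _gate_inf_tau(v0, table[c, 9], table[c, 10], table[c, 12], table[c, 13], table[c, 14], table[c, 15])

    for k in range(n):
        vk = v[k]
        i_tot = 0.0
        for c in range(nchan):
            g = table[c, 0]
            ec = table[c, 1]
            ic = g * (vk - ec)
            if table[c, 4] > 0.0:
                ic *= m[c] ** int(table[c, 4])
            if table[c, 11] > 0.0:
                ic *= h[c]
            if record:
                cur[c, k] = ic
            i_tot += ic
        v[k + 1] = vk + dt / c_nf * (i_inj[k] - i_tot)
        if np.abs(v[k + 1]) > 200.0:
            return v[: k + 2], cur, k
        # gate update (exponential Euler, using pre-step voltage)
        for c in range(nchan):
            if table[c, 4] > 0.0:
                minf, tau = _gate_inf_tau(vk, table[c, 2], table[c, 3], table[c, 5], table[c, 6], table[c, 7], table[c, 8])
                m[c] = minf + (m[c] - minf) * np.exp(-dt / tau)
            if table[c, 11] > 0.0:
                hinf, tau = _gate_inf_tau(vk, table[c, 9], table[c, 10], table[c, 12], table[c, 13], table[c, 14], table[c, 15])
                h[c] = hinf + (h[c] - hinf) * np.exp(-dt / tau)
    return v, cur, -1


def simulate(
    params: ModelParams,
    stim: StimulusTrace,
    settle_ms: float = 200.0,
) -> SimResult:
    """Integrate the model under a current-clamp stimulus.

    A settling period of ``settle_ms`` at the stimulus's first sample value
    precedes the record and is discarded, so the returned arrays cover
    exactly the stimulus span.  Deterministic: same (params, stim) → same
    result bitwise.
    """
    dt = stim.dt_ms
    if dt > 0.05:
        raise ValueError(f"stimulus dt_ms={dt} too coarse; need <= 0.05 ms")
    table = _pack(params)
    c_nf = params.capacitance_nF

    v0 = params.v_init_mV
    if settle_ms > 0:
        n_settle = round(settle_ms / dt)
        i_settle = np.full(n_settle, stim.samples[0])
        v_s, _, bad = _integrate(table, c_nf, v0, dt, i_settle, False)
        if bad >= 0:
            raise IntegrationError(f"voltage blow-up during settling at step {bad}")
        v0 = v_s[-1]

    v, cur, bad = _integrate(table, c_nf, v0, dt, stim.samples, True)
    if bad >= 0:
        raise IntegrationError(
            f"voltage blow-up at step {bad} (t = {bad * dt:.3f} ms)"
        )
    currents = {c.name: cur[i] for i, c in enumerate(params.channels)}
    return SimResult(
        time_ms=stim.time_ms.copy(),
        v_mV=v[:-1],
        currents=currents,
        i_inj_nA=stim.samples.copy(),
        params=params,
        dt_ms=dt,
    )


def scale_channel(params: ModelParams, name: str, factor: float) -> ModelParams:
    """Return a copy of ``params`` with ``gbar`` of channel ``name`` scaled."""
    if factor < 0:
        raise ValueError("factor must be >= 0")
    if name not in params.channel_names:
        raise KeyError(f"no channel named {name!r}; have {params.channel_names}")
    new = tuple(
        _dc_replace(c, gbar_uS=c.gbar_uS * factor) if c.name == name else c
        for c in params.channels
    )
    return ModelParams(
        capacitance_nF=params.capacitance_nF,
        channels=new,
        species_preset=params.species_preset,
        v_init_mV=params.v_init_mV,
    )


def _steady_state_sim(params: ModelParams, i_nA: float, duration_ms: float, dt_ms: float = 0.025):
    from .stimgen import StimulusSpec, make_frozen_noise

    spec = StimulusSpec(
        duration_ms=duration_ms, dt_ms=dt_ms, sigma_nA=0.0, dc_nA=i_nA, seed=0
    )
    return simulate(params, make_frozen_noise(spec), settle_ms=0.0)


def intrinsic_properties(params: ModelParams, dt_ms: float = 0.025) -> Dict[str, float]:
    """Classical current-clamp characterization of the model.

    Returns resting potential (mV), input resistance (MΩ, from a −0.01 nA
    step), sag ratio for a −0.1 nA 1 s step ((V_min − V_steady)/(V_min −
    V_rest), 0 when no sag), and rheobase (nA, smallest 1 s tonic step
    eliciting a spike, by bisection).
    """
    from .spikes import detect_spikes

    rest = _steady_state_sim(params, 0.0, 5000.0, dt_ms)
    v_tail = rest.v_mV[-round(500 / dt_ms):]
    if v_tail.max() - v_tail.min() > 0.05:
        raise RuntimeError("model does not reach a resting state within 5 s")
    rmp = rest.v_mV[-1]

    # small hyperpolarizing step from rest
    sim = _steady_state_sim_from(params, rmp, -0.01, 3000.0, dt_ms)
    v_steady = sim.v_mV[-1]
    r_in = (v_steady - rmp) / (-0.01)  # mV / nA = MΩ

    sag_sim = _steady_state_sim_from(params, rmp, -0.1, 1000.0, dt_ms)
    v_min = sag_sim.v_mV.min()
    v_sag_steady = sag_sim.v_mV[-1]
    denom = v_min - rmp
    sag = (v_min - v_sag_steady) / denom if abs(denom) > 1e-12 else 0.0

    # rheobase: bisection on 1 s tonic steps
    lo, hi = 0.0, 1.0
    def spikes_at(i_nA: float) -> int:
        s = _steady_state_sim_from(params, rmp, i_nA, 1000.0, dt_ms)
        return len(detect_spikes(s.v_mV, s.time_ms))

    if spikes_at(hi) == 0:
        rheobase = float("nan")
    else:
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            if spikes_at(mid) > 0:
                hi = mid
            else:
                lo = mid
        rheobase = hi

    return {
        "rmp_mV": float(rmp),
        "input_resistance_MOhm": float(r_in),
        "sag_ratio": float(sag),
        "rheobase_nA": float(rheobase),
    }


def _steady_state_sim_from(params: ModelParams, v_start: float, i_nA: float, duration_ms: float, dt_ms: float):
    from .stimgen import StimulusSpec, make_frozen_noise

    p = ModelParams(
        capacitance_nF=params.capacitance_nF,
        channels=params.channels,
        species_preset=params.species_preset,
        v_init_mV=v_start,
    )
    spec = StimulusSpec(
        duration_ms=duration_ms, dt_ms=dt_ms, sigma_nA=0.0, dc_nA=i_nA, seed=0
    )
    return simulate(p, make_frozen_noise(spec), settle_ms=0.0)
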