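"""Currentscape-style inward/outward percentage decomposition.

At each time step every membrane current is classified by its sign —
negative is inward (depolarizing), positive is outward — and expressed as a
percentage of the total magnitude of its class at that step.  The injected
current is excluded; the passive leak is included by default.  Samples where
a class has zero total carry a defined=False mask rather than NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .neuron_sim import SimResult

__all__ = ["PercentContribution", "percent_contributions", "class_flip_report"]


@dataclass
class PercentContribution:
    """Per-channel percentage contributions to the inward/outward class totals.

    ``pct_in[name][k]`` is channel ``name``'s share (0–100) of the total
    inward current magnitude at sample k, 0 where the channel is not inward;
    analogously for ``pct_out``.  ``in_defined`` / ``out_defined`` flag
    samples where the class total is nonzero.
    """

    time_ms: np.ndarray
    dt_ms: float
    pct_in: Dict[str, np.ndarray]
    pct_out: Dict[str, np.ndarray]
    total_inward_nA: np.ndarray
    total_outward_nA: np.ndarray
    in_defined: np.ndarray
    out_defined: np.ndarray

    @property
    def channel_names(self) -> List[str]:
        return list(self.pct_in.keys())


def percent_contributions(
    sim: SimResult, include_passive: bool = True
) -> PercentContribution:
    """Decompose a simulation's membrane currents into class percentages.

    Currents with negative sign at a sample are inward there, positive are
    outward; an exactly-zero sample belongs to neither class.  Percentages
    are 100·|I_c| / Σ_{same class} |I| per sample.
    """
    names = [
        n for n in sim.currents if include_passive or n != "leak"
    ]
    if not names:
        raise ValueError("no channels to decompose")
    cur = np.stack([sim.currents[n] for n in names])  # (nchan, n)
    inward = np.where(cur < 0, -cur, 0.0)
    outward = np.where(cur > 0, cur, 0.0)
    tot_in = inward.sum(axis=0)
    tot_out = outward.sum(axis=0)
    in_def = tot_in > 0
    out_def = tot_out > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        pct_in = np.where(in_def, 100.0 * inward / np.where(in_def, tot_in, 1.0), 0.0)
        pct_out = np.where(out_def, 100.0 * outward / np.where(out_def, tot_out, 1.0), 0.0)

    return PercentContribution(
        time_ms=sim.time_ms.copy(),
        dt_ms=sim.dt_ms,
        pct_in={n: pct_in[i] for i, n in enumerate(names)},
        pct_out={n: pct_out[i] for i, n in enumerate(names)},
        total_inward_nA=tot_in,
        total_outward_nA=tot_out,
        in_defined=in_def,
        out_defined=out_def,
    )


def class_flip_report(
    pc: PercentContribution, channel: str
) -> List[Tuple[float, float, str]]:
    """Maximal intervals of constant class for one channel.

    Returns (start_ms, end_ms, label) triples with label in
    {"inward", "outward", "none"}; "none" covers exactly-zero stretches.
    Intervals are half-open except the last, which includes the final sample.
    """
    if channel not in pc.pct_in:
        raise KeyError(f"unknown channel {channel!r}; have {pc.channel_names}")
    state = np.zeros(len(pc.time_ms), dtype=int)
    state[pc.pct_in[channel] > 0] = -1
    state[pc.pct_out[channel] > 0] = 1
    labels = {-1: "inward", 0: "none", 1: "outward"}
    out = []
    start = 0
    for k in range(1, len(state)):
        if state[k] != state[start]:
            out.append((float(pc.time_ms[start]), float(pc.time_ms[k]), labels[state[start]]))
            start = k
    out.append(
        (float(pc.time_ms[start]), float(pc.time_ms[-1] + pc.dt_ms), labels[state[start]])
    )
    return out
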