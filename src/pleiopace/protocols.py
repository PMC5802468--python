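"""Excitability protocols: f–I curves, rheobase search, pacemaking rate.

Defaults: neuron stimuli are 1 s somatic DC steps with the first 200 ms
of the response excluded from rate measurement (steady firing); SAN
recordings are 20 s with a 2 s settling period discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CellModel,
    IntegrationError,
    SimulationResult,
    StepStimulus,
    detect_spikes,
    integrate_cell,
)

NEURON_SPIKE_THRESHOLD = -20.0   # mV; upward-crossing spike detection
SAN_CYCLE_THRESHOLD = 0.0        # mV; SAN cycle counting
REFRACTORY = 2.0                 # ms


@dataclass(frozen=True)
class FICurve:
    """Firing frequency (Hz) versus injected somatic DC amplitude (nA)."""

    amplitudes: np.ndarray
    frequencies: np.ndarray
    duration: float
    failed: tuple[int, ...] = ()

    def __post_init__(self):
        a = np.asarray(self.amplitudes, float)
        if np.any(np.diff(a) <= 0):
            raise ValueError("amplitudes must be strictly increasing")
        if len(a) != len(self.frequencies):
            raise ValueError("length mismatch")


@dataclass(frozen=True)
class PacemakingSummary:
    """Spontaneous pacemaking rate and (optionally) change from control."""

    frequency: float                  # Hz; 0.0 for quiescent cells
    quiescent: bool = False
    relative_difference: float = math.nan

    def with_control(self, f_ctrl: float) -> "PacemakingSummary":
        rel = (self.frequency - f_ctrl) / f_ctrl if f_ctrl > 0 else math.nan
        return PacemakingSummary(self.frequency, self.quiescent, rel)


def firing_rate(
    model: CellModel,
    amplitude: float,
    duration: float = 1000.0,
    settle: float = 200.0,
    *,
    t_on: float = 100.0,
    dt_record: float = 0.2,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> float:
    """Steady firing rate (Hz) under a somatic DC step."""
    stim = StepStimulus(amplitude, t_on, t_on + duration)
    res = integrate_cell(model, stim, t_on + duration + 50.0,
                         dt_record=dt_record, rtol=rtol, atol=atol)
    spikes = detect_spikes(res, NEURON_SPIKE_THRESHOLD, REFRACTORY)
    window = (t_on + settle, t_on + duration)
    inside = spikes[(spikes >= window[0]) & (spikes <= window[1])]
    if len(inside) < 3:
        return len(inside) / ((window[1] - window[0]) / 1000.0)
    # cycle counting over the steady window: continuous in parameters,
    # agrees with 1/mean ISI for stationary trains
    return (len(inside) - 1) / (inside[-1] - inside[0]) * 1000.0


def fi_curve(
    model: CellModel,
    amplitudes,
    duration: float = 1000.0,
    settle: float = 200.0,
    **kw,
) -> FICurve:
    """f–I curve; integration failures yield NaN entries flagged in ``failed``."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    freqs = np.empty_like(amplitudes)
    failed = []
    for i, a in enumerate(amplitudes):
        try:
            freqs[i] = firing_rate(model, a, duration, settle, **kw)
        except IntegrationError:
            freqs[i] = math.nan
            failed.append(i)
    return FICurve(amplitudes, freqs, duration, tuple(failed))


def spike_count(model: CellModel, amplitude: float, duration: float = 1000.0,
                *, t_on: float = 100.0, dt_record: float = 0.2,
                rtol: float = 1e-8, atol: float = 1e-8) -> int:
    """Number of spikes fired during a DC step from rest."""
    stim = StepStimulus(amplitude, t_on, t_on + duration)
    res = integrate_cell(model, stim, t_on + duration + 100.0,
                         dt_record=dt_record, rtol=rtol, atol=atol)
    spikes = detect_spikes(res, NEURON_SPIKE_THRESHOLD, REFRACTORY)
    return int(np.sum(spikes >= t_on))


def threshold_current(
    model: CellModel,
    bracket: tuple[float, float] = (0.02, 1.5),
    tol: float = 0.001,
    duration: float = 1000.0,
    **kw,
) -> float:
    """Rheobase by bisection: smallest DC eliciting ≥ 1 spike from rest.

    The bracket must straddle the spike/no-spike boundary.  Accuracy
    |ΔI| ≤ ``tol`` (default 1 pA).
    """
    lo, hi = bracket
    if not lo < hi:
        raise ValueError("invalid bracket")
    if spike_count(model, lo, duration, **kw) > 0:
        raise ValueError("lower bracket endpoint already elicits a spike")
    if spike_count(model, hi, duration, **kw) == 0:
        raise ValueError("upper bracket endpoint elicits no spike")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if spike_count(model, mid, duration, **kw) > 0:
            hi = mid
        else:
            lo = mid
    return hi


def pacemaking_frequency(
    model: CellModel,
    record: float = 20000.0,
    settle: float = 2000.0,
    *,
    dt_record: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    result: SimulationResult | None = None,
) -> PacemakingSummary:
    """Spontaneous pacemaking frequency from upward 0 mV crossings.

    frequency = (n−1)/(t_last − t_first) over crossings after settling; a
    cell with fewer than two crossings is reported quiescent (a valid
    outcome, e.g. under silencing), not an error.
    """
    if result is None:
        result = integrate_cell(model, None, record, dt_record=dt_record,
                                rtol=rtol, atol=atol)
    crossings = detect_spikes(result, SAN_CYCLE_THRESHOLD, 20.0)
    crossings = crossings[crossings >= settle]
    if len(crossings) < 2:
        return PacemakingSummary(0.0, quiescent=True)
    f = (len(crossings) - 1) / (crossings[-1] - crossings[0]) * 1000.0
    return PacemakingSummary(f)
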