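"""Downscaling calibration of variant effects.

A literature variant is usually too strong to represent a common
polymorphism.  The calibration finds the largest proportional effect
size c ∈ [0, 1] at which the variant cell still preserves its baseline
behavior class, probing an ascending coarse grid and bisecting to the
first violation from below.

Behavior-preservation conditions:

* neurons — A1–A3: identical spike counts to control under three somatic
  DC stimuli (defaults 0.8×, 1.05×, 1.5× the control rheobase, 1 s; the
  near-rheobase probe sits slightly above threshold because a probe at
  exactly 1.0× is degenerate — any infinitesimal threshold shift would
  flip its spike count);
  A4: steady firing frequency within a relative tolerance; A5: AP peak
  within an absolute mV tolerance and AP half-width within a relative
  tolerance (both at the strong stimulus);
* SAN cells — B1: pacemaking frequency within a relative tolerance;
  B2: AP amplitude and APD50 within relative tolerances.

A candidate that loses the behavior class altogether (no spikes where
control spikes, or quiescence where control paces) fails every condition
and is flagged as a qualitative loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core import CellModel, IntegrationError, ap_metrics, integrate_cell
from .protocols import (
    SAN_CYCLE_THRESHOLD,
    firing_rate,
    pacemaking_frequency,
    spike_count,
    threshold_current,
)
from .variants import VariantApplication, VariantEffect, apply_variant


@dataclass(frozen=True)
class ConditionSet:
    """Tolerances and stimulus specification for behavior preservation."""

    # neuron spike-count stimuli as multiples of control rheobase
    stim_rheobase_factors: tuple[float, ...] = (0.8, 1.05, 1.5)
    stim_duration: float = 1000.0
    max_rate_dev: float = 0.25          # A4 / B1: relative frequency deviation
    max_peak_dev: float = 10.0          # A5: AP peak deviation, mV
    max_width_dev: float = 0.25         # A5 / B2: relative half-width / APD50
    max_amp_dev: float = 0.20           # B2: relative AP amplitude deviation
    san_record: float = 6000.0
    san_settle: float = 2000.0

    def __post_init__(self):
        for v in (self.max_rate_dev, self.max_peak_dev, self.max_width_dev,
                  self.max_amp_dev):
            if v <= 0:
                raise ValueError("all tolerances must be > 0")


@dataclass(frozen=True)
class ConditionResult:
    name: str
    measured: float
    bound: float
    passed: bool
    note: str = ""


@dataclass(frozen=True)
class ConditionReport:
    results: tuple[ConditionResult, ...]
    qualitative_loss: bool = False

    @property
    def passed(self) -> bool:
        return (not self.qualitative_loss
                and all(r.passed for r in self.results))


@dataclass(frozen=True)
class CalibrationResult:
    """Threshold c plus the reports at c and at the first violating scale."""

    c: float
    report_at_c: ConditionReport | None
    first_violation: float | None
    report_at_violation: ConditionReport | None
    n_evaluations: int

    def __post_init__(self):
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("c must lie in [0, 1]")


# ---------------------------------------------------------------------------
# reference measurements (computed once per control model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronReference:
    rheobase: float
    stim_amplitudes: tuple[float, ...]
    spike_counts: tuple[int, ...]
    rate: float
    peak: float
    half_width: float


@dataclass(frozen=True)
class SanReference:
    frequency: float
    amplitude: float
    apd50: float


def neuron_reference(control: CellModel, conditions: ConditionSet) -> NeuronReference:
    rheo = threshold_current(control, duration=conditions.stim_duration)
    amps = tuple(f * rheo for f in conditions.stim_rheobase_factors)
    counts = [spike_count(control, a, conditions.stim_duration)
              for a in amps[:-1]]
    count_last, rate, peak, width = _neuron_probe(control, amps[-1],
                                                  conditions)
    counts.append(count_last)
    return NeuronReference(rheo, amps, tuple(counts), rate, peak, width)


def _neuron_shape(model: CellModel, amplitude: float,
                  conditions: ConditionSet) -> tuple[float, float]:
    from .core import StepStimulus, detect_spikes

    stim = StepStimulus(amplitude, 100.0, 100.0 + conditions.stim_duration)
    res = integrate_cell(model, stim, 100.0 + conditions.stim_duration,
                         dt_record=0.05)
    met = ap_metrics(res, window=(300.0, 100.0 + conditions.stim_duration))
    if not met.has_ap:
        return (math.nan, math.nan)
    return (met.peak, met.half_width)


def san_reference(control: CellModel, conditions: ConditionSet) -> SanReference:
    res = integrate_cell(control, None, conditions.san_record, dt_record=0.5)
    pm = pacemaking_frequency(control, result=res,
                              settle=conditions.san_settle)
    met = ap_metrics(res, window=(conditions.san_settle, conditions.san_record),
                     detect_threshold=SAN_CYCLE_THRESHOLD, refractory=20.0)
    return SanReference(pm.frequency, met.amplitude, met.apd50)


# ---------------------------------------------------------------------------
# condition evaluation
# ---------------------------------------------------------------------------

def evaluate_conditions(
    control: CellModel,
    candidate: CellModel,
    conditions: ConditionSet,
    reference: NeuronReference | SanReference | None = None,
) -> ConditionReport:
    """Evaluate every behavior-preservation condition for a candidate."""
    if control.kind != candidate.kind:
        raise ValueError("control and candidate must be the same cell type")
    if control.kind == "neuron":
        ref = reference or neuron_reference(control, conditions)
        return _evaluate_neuron(candidate, conditions, ref)
    ref = reference or san_reference(control, conditions)
    return _evaluate_san(candidate, conditions, ref)


def _fail_all(names: Sequence[str], note: str) -> ConditionReport:
    return ConditionReport(
        tuple(ConditionResult(n, math.nan, math.nan, False, note)
              for n in names),
        qualitative_loss=True,
    )


def _neuron_probe(model: CellModel, amplitude: float,
                  cond: ConditionSet) -> tuple[int, float, float, float]:
    """One stimulated run → (spike count, steady rate, AP peak, half-width)."""
    from .core import StepStimulus, detect_spikes

    stim = StepStimulus(amplitude, 100.0, 100.0 + cond.stim_duration)
    res = integrate_cell(model, stim, 100.0 + cond.stim_duration + 50.0,
                         dt_record=0.05)
    spikes = detect_spikes(res, -20.0, 2.0)
    count = int(np.sum(spikes >= 100.0))
    inside = spikes[(spikes >= 300.0) & (spikes <= 100.0 + cond.stim_duration)]
    if len(inside) < 3:
        rate = len(inside) / ((cond.stim_duration - 200.0) / 1000.0)
    else:
        rate = (len(inside) - 1) / (inside[-1] - inside[0]) * 1000.0
    met = ap_metrics(res, window=(300.0, 100.0 + cond.stim_duration))
    return count, rate, met.peak, met.half_width


def _evaluate_neuron(candidate: CellModel, cond: ConditionSet,
                     ref: NeuronReference) -> ConditionReport:
    names = [f"A{i + 1}" for i in range(len(ref.stim_amplitudes))] + [
        "A4", "A5-peak", "A5-width"]
    results = []
    try:
        counts = [spike_count(candidate, a, cond.stim_duration)
                  for a in ref.stim_amplitudes[:-1]]
        count_last, rate, peak, width = _neuron_probe(
            candidate, ref.stim_amplitudes[-1], cond)
        counts.append(count_last)
    except IntegrationError:
        return _fail_all(names, "integration failure")
    if max(ref.spike_counts) > 0 and max(counts) == 0:
        return _fail_all(names, "qualitative loss: no spikes")
    for i, (got, want) in enumerate(zip(counts, ref.spike_counts)):
        results.append(ConditionResult(
            f"A{i + 1}", float(got), float(want), got == want,
            f"spike count at {ref.stim_amplitudes[i]:.4f} nA"))
    rel = abs(rate - ref.rate) / ref.rate if ref.rate > 0 else abs(rate)
    results.append(ConditionResult("A4", rel, cond.max_rate_dev,
                                   rel <= cond.max_rate_dev,
                                   "relative firing-rate deviation"))
    dpk = abs(peak - ref.peak)
    results.append(ConditionResult("A5-peak", dpk, cond.max_peak_dev,
                                   bool(dpk <= cond.max_peak_dev),
                                   "AP peak deviation (mV)"))
    dwd = (abs(width - ref.half_width) / ref.half_width
           if ref.half_width > 0 else math.inf)
    results.append(ConditionResult("A5-width", dwd, cond.max_width_dev,
                                   bool(dwd <= cond.max_width_dev),
                                   "relative AP half-width deviation"))
    return ConditionReport(tuple(results))


def _evaluate_san(candidate: CellModel, cond: ConditionSet,
                  ref: SanReference) -> ConditionReport:
    names = ["B1", "B2-amp", "B2-apd50"]
    try:
        res = integrate_cell(candidate, None, cond.san_record, dt_record=0.5)
    except IntegrationError:
        return _fail_all(names, "integration failure")
    pm = pacemaking_frequency(candidate, result=res, settle=cond.san_settle)
    if pm.quiescent and ref.frequency > 0:
        return _fail_all(names, "qualitative loss: quiescent")
    met = ap_metrics(res, window=(cond.san_settle, cond.san_record),
                     detect_threshold=SAN_CYCLE_THRESHOLD, refractory=20.0)
    rel_f = abs(pm.frequency - ref.frequency) / ref.frequency
    rel_a = abs(met.amplitude - ref.amplitude) / ref.amplitude
    rel_d = abs(met.apd50 - ref.apd50) / ref.apd50
    return ConditionReport((
        ConditionResult("B1", rel_f, cond.max_rate_dev,
                        rel_f <= cond.max_rate_dev,
                        "relative pacemaking-frequency deviation"),
        ConditionResult("B2-amp", rel_a, cond.max_amp_dev,
                        rel_a <= cond.max_amp_dev,
                        "relative AP amplitude deviation"),
        ConditionResult("B2-apd50", rel_d, cond.max_width_dev,
                        rel_d <= cond.max_width_dev,
                        "relative APD50 deviation"),
    ))


# ---------------------------------------------------------------------------
# threshold search
# ---------------------------------------------------------------------------

def scan_first_violation(
    violates: Callable[[float], bool],
    coarse_step: float = 0.1,
    resolution: float = 1e-3,
) -> tuple[float, int]:
    """Largest c in [0, 1] below the first violation from below.

    Ascending coarse scan followed by bisection; returns (c, n_evaluations).
    ``violates(0)`` is assumed False (scale zero is the control).
    """
    n_eval = 0
    grid = np.arange(coarse_step, 1.0 + 0.5 * coarse_step, coarse_step)
    lo = 0.0
    hi = None
    for c in grid:
        n_eval += 1
        if violates(float(c)):
            hi = float(c)
            break
        lo = float(c)
    if hi is None:
        return 1.0, n_eval
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        n_eval += 1
        if violates(mid):
            hi = mid
        else:
            lo = mid
    return lo, n_eval


def find_threshold_c(
    control: CellModel,
    effect: VariantEffect,
    conditions: ConditionSet | None = None,
    resolution: float = 1e-3,
    coarse_step: float = 0.1,
    reference: NeuronReference | SanReference | None = None,
) -> CalibrationResult:
    """Calibrate the downscaling threshold c for one variant effect.

    c is the largest probed scale such that all conditions pass at every
    probed magnitude in [0, c] — in both directions (+s and −s), since
    the study protocol applies variants at positive and negative ε and
    both are expected to preserve the behavior class.  An identity effect
    returns c = 1; an effect violating at every probed scale returns
    c = 0.
    """
    conditions = conditions or ConditionSet()
    if reference is None:
        reference = (neuron_reference(control, conditions)
                     if control.kind == "neuron"
                     else san_reference(control, conditions))
    reports: dict[float, ConditionReport] = {}

    def violates(c: float) -> bool:
        for sign in (1.0, -1.0):
            candidate = apply_variant(
                control, VariantApplication(effect, sign, c))
            rep = evaluate_conditions(control, candidate, conditions,
                                      reference)
            if sign > 0:
                reports[c] = rep
            if not rep.passed:
                if sign < 0:
                    reports[c] = rep
                return True
        return False

    c, n_eval = scan_first_violation(violates, coarse_step, resolution)
    viol_scales = sorted(s for s, r in reports.items() if not r.passed)
    first_violation = viol_scales[0] if viol_scales else None
    report_at_c = reports.get(c)
    if report_at_c is None and c > 0.0:
        candidate = apply_variant(control, VariantApplication(effect, 1.0, c))
        report_at_c = evaluate_conditions(control, candidate, conditions,
                                          reference)
        n_eval += 1
    return CalibrationResult(
        c=c,
        report_at_c=report_at_c,
        first_violation=first_violation,
        report_at_violation=reports.get(first_violation)
        if first_violation is not None else None,
        n_evaluations=n_eval,
    )
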