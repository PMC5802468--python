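"""Generic conductance-based cell engine.

Units used throughout the package: membrane potential mV, time ms,
currents nA, conductances µS, capacitance nF, concentrations mM
(cytosolic Ca²⁺ is usually quoted in µM in docs; internally it is mM).

A :class:`CellModel` couples a compiled right-hand side (a function of
``(t, y, params, i_stim)``) with a flat, path-addressable parameter
vector.  Genetic-variant application never edits a model in place: it
produces a new model with a modified copy of the parameter vector, so the
control model always stays intact for paired comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint


class ParameterError(ValueError):
    """Invalid gating or current parameter (e.g. non-positive slope)."""


class IntegrationError(RuntimeError):
    """Solver failure or unphysical state during integration."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingParameters:
    """Boltzmann steady-state gate description.

    ``v_half``/``slope`` are the base half-(in)activation voltage and slope
    factor; ``v_off`` is an additive offset to the half-point (the variant
    targets V_offm / V_offh), ``slope_scale`` and ``tau_scale`` are
    multiplicative factors on the slope and on the voltage-dependent time
    constant.
    """

    v_half: float
    slope: float
    v_off: float = 0.0
    slope_scale: float = 1.0
    tau_scale: float = 1.0
    exponent: int = 1

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ParameterError(f"slope must be > 0, got {self.slope}")
        if self.slope_scale <= 0 or self.tau_scale <= 0:
            raise ParameterError("slope_scale and tau_scale must be > 0")
        if self.exponent < 1:
            raise ParameterError("gate exponent must be >= 1")


@dataclass(frozen=True)
class CurrentParameters:
    """One membrane current: conductance scale, reversal, gating."""

    name: str
    gbar: float
    e_rev: float
    gates: tuple[GatingParameters, ...] = ()
    ca_dependence: float | None = None  # half-inactivation [Ca²⁺] (mM)

    def __post_init__(self) -> None:
        if self.gbar < 0:
            raise ParameterError(f"{self.name}: gbar must be >= 0")


@dataclass(frozen=True)
class CalciumHandling:
    """Intracellular Ca²⁺ machinery parameters (model-specific subset)."""

    p_up: float = 0.0          # maximal SERCA uptake rate (mM/ms)
    k_up: float = 6e-4         # uptake half-activation (mM)
    extras: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.p_up < 0:
            raise ParameterError("p_up must be >= 0")


def boltzmann_gate(v: float, params: GatingParameters, kind: str = "activation") -> float:
    """Steady-state open fraction of a Boltzmann gate.

    Rising sigmoid for activation, falling for inactivation; an additive
    offset ``v_off`` shifts the half-point by exactly that amount.
    """
    if not math.isfinite(v):
        raise ParameterError("membrane potential must be finite")
    k = params.slope * params.slope_scale
    if k <= 0:
        raise ParameterError("effective slope must be > 0")
    x = (v - (params.v_half + params.v_off)) / k
    if kind == "activation":
        return 1.0 / (1.0 + math.exp(-x))
    if kind == "inactivation":
        return 1.0 / (1.0 + math.exp(x))
    raise ValueError(f"unknown gate kind {kind!r}")


# ---------------------------------------------------------------------------
# cell model container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellModel:
    """A named ODE cell model with a path-addressable parameter vector.

    ``rhs(t, y, params, i_stim)`` returns dy/dt; ``i_stim`` is a vector of
    injected currents (nA), one entry per compartment.  ``currents_fn``
    evaluates named membrane currents for recorded states (shape
    ``(n_currents,)`` per state row).
    """

    name: str
    kind: str                      # 'neuron' | 'san' | 'atrial'
    n_comp: int
    state_names: tuple[str, ...]
    param_index: Mapping[str, int]
    params: np.ndarray
    y0: np.ndarray
    rhs: Callable
    current_names: tuple[str, ...] = ()
    currents_fn: Callable | None = None
    additive_paths: frozenset[str] = frozenset()
    provenance: str = ""
    v_index: tuple[int, ...] = (0,)
    conc_states: tuple[int, ...] = ()   # indices that must stay > 0
    gate_states: tuple[int, ...] = ()   # indices that must stay in [0,1]

    def param(self, path: str) -> float:
        return float(self.params[self.param_index[path]])

    def has_param(self, path: str) -> bool:
        return path in self.param_index

    def with_params(self, updates: Mapping[str, float], suffix: str = "") -> "CellModel":
        """Return a new model with replaced parameter values; control untouched."""
        p = self.params.copy()
        for path, value in updates.items():
            if path not in self.param_index:
                raise KeyError(f"{self.name}: unknown parameter path {path!r}")
            p[self.param_index[path]] = value
        return replace(self, params=p, name=self.name + suffix)

    def with_state(self, y0: np.ndarray) -> "CellModel":
        y0 = np.asarray(y0, dtype=float)
        if y0.shape != self.y0.shape:
            raise ValueError("state template shape mismatch")
        return replace(self, y0=y0.copy())

    def parameter_table(self) -> pd.DataFrame:
        """Flat name → value table (diff-able between control and variant)."""
        rows = [(k, float(self.params[i]), k in self.additive_paths)
                for k, i in sorted(self.param_index.items(), key=lambda kv: kv[1])]
        return pd.DataFrame(rows, columns=["parameter", "value", "additive"])


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepStimulus:
    """Piecewise-constant injected current: one rectangular step.

    ``amplitude`` nA into compartment ``compartment`` between ``t_on`` and
    ``t_off`` (ms).
    """

    amplitude: float
    t_on: float
    t_off: float
    compartment: int = 0


def _stim_breakpoints(stimuli: Sequence[StepStimulus], duration: float) -> np.ndarray:
    pts = {0.0, float(duration)}
    for s in stimuli:
        for t in (s.t_on, s.t_off):
            if 0.0 < t < duration:
                pts.add(float(t))
    return np.array(sorted(pts))


def _stim_vector(stimuli: Sequence[StepStimulus], t: float, n_comp: int) -> np.ndarray:
    v = np.zeros(n_comp)
    for s in stimuli:
        if s.t_on <= t < s.t_off:
            v[s.compartment] += s.amplitude
    return v


# ---------------------------------------------------------------------------
# simulation result
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory of a cell integration on a uniform recording grid."""

    t: np.ndarray                    # ms, strictly increasing
    y: np.ndarray                    # (len(t), n_states)
    model: CellModel
    currents: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def v(self) -> np.ndarray:
        """Membrane potential of the first compartment (mV)."""
        return self.y[:, self.model.v_index[0]]

    def voltage(self, compartment: int = 0) -> np.ndarray:
        return self.y[:, self.model.v_index[compartment]]

    def state(self, name: str) -> np.ndarray:
        return self.y[:, self.model.state_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.model.state_names))
        df.insert(0, "time_ms", self.t)
        for k, tr in self.currents.items():
            df[f"i_{k}_nA"] = tr
        return df

    def to_csv(self, path) -> None:
        """Tidy CSV: time + one column per saved variable, units in names."""
        self.to_frame().to_csv(path, index=False)

    def to_parquet(self, path) -> None:
        """Binary tabular container with the same columns as the CSV."""
        self.to_frame().to_parquet(path, index=False)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_cell(
    model: CellModel,
    stimuli: Sequence[StepStimulus] | StepStimulus | None = None,
    duration: float = 1000.0,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    dt_record: float = 0.25,
    y0: np.ndarray | None = None,
    record_currents: bool = False,
    max_step: float = np.inf,
) -> SimulationResult:
    """Integrate a cell model with the LSODA stiff/non-stiff solver.

    The integration is split at stimulus discontinuities so the solver never
    steps across a jump in the injected current.  Re-running with identical
    inputs and tolerances is bit-reproducible (fixed solver, no wall-clock
    dependence).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if stimuli is None:
        stimuli = []
    elif isinstance(stimuli, StepStimulus):
        stimuli = [stimuli]

    y = np.array(model.y0 if y0 is None else y0, dtype=float)
    breaks = _stim_breakpoints(stimuli, duration)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    p = model.params
    n_steps_total = 0

    for a, b in zip(breaks[:-1], breaks[1:]):
        istim = _stim_vector(stimuli, (a + b) / 2.0, model.n_comp)
        n = max(2, int(round((b - a) / dt_record)) + 1)
        tgrid = np.linspace(a, b, n)
        sol, info = odeint(
            model.rhs, y, tgrid, args=(p, istim),
            rtol=rtol, atol=atol, tfirst=True, full_output=True,
            hmax=0.0 if not np.isfinite(max_step) else max_step,
            mxstep=10_000_000,
        )
        if info["message"] != "Integration successful.":
            raise IntegrationError(
                f"{model.name}: solver failed in [{a}, {b}] ms: {info['message']}")
        y = sol[-1].copy()
        n_steps_total += int(info["nst"][-1])
        # drop the duplicated segment-start sample
        if ts:
            tgrid, sol = tgrid[1:], sol[1:]
        ts.append(tgrid)
        ys.append(sol)

    t = np.concatenate(ts)
    Y = np.concatenate(ys)
    _check_state(model, t, Y)

    res = SimulationResult(
        t=t, y=Y, model=model,
        diagnostics={"rtol": rtol, "atol": atol, "n_steps": n_steps_total},
    )
    if record_currents and model.currents_fn is not None:
        traces = np.empty((len(t), len(model.current_names)))
        for i in range(len(t)):
            traces[i] = model.currents_fn(Y[i], p)
        res.currents = {nm: traces[:, j] for j, nm in enumerate(model.current_names)}
    return res


def _check_state(model: CellModel, t: np.ndarray, Y: np.ndarray) -> None:
    for vi in model.v_index:
        col = Y[:, vi]
        if not np.all(np.isfinite(col)):
            raise IntegrationError(
                f"{model.name}: non-finite membrane potential "
                f"'{model.state_names[vi]}'")
        if np.max(np.abs(col)) > 200.0:
            raise IntegrationError(
                f"{model.name}: |V| > 200 mV in state '{model.state_names[vi]}'")
    for ci in model.conc_states:
        if np.min(Y[:, ci]) <= 0.0:
            raise IntegrationError(
                f"{model.name}: non-positive concentration in state "
                f"'{model.state_names[ci]}'")
    if not np.all(np.isfinite(Y)):
        bad = int(np.argwhere(~np.isfinite(Y))[0][1])
        raise IntegrationError(
            f"{model.name}: non-finite state '{model.state_names[bad]}'")


# ---------------------------------------------------------------------------
# spike detection and AP shape metrics
# ---------------------------------------------------------------------------

def detect_spikes(
    result: SimulationResult | None = None,
    threshold: float = -20.0,
    refractory: float = 2.0,
    *,
    t: np.ndarray | None = None,
    v: np.ndarray | None = None,
    compartment: int = 0,
) -> np.ndarray:
    """Upward threshold crossings separated by at least ``refractory`` ms.

    Accepts either a :class:`SimulationResult` or raw ``t``/``v`` arrays.
    Crossing times are linearly interpolated between samples.  An empty
    array is a valid result.
    """
    if result is not None:
        t = result.t
        v = result.voltage(compartment)
    assert t is not None and v is not None
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    times = []
    last = -np.inf
    for i in idx:
        dv = v[i + 1] - v[i]
        frac = 0.0 if dv == 0 else (threshold - v[i]) / dv
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return np.asarray(times)


@dataclass(frozen=True)
class APMetrics:
    """Shape metrics of action potentials in a window.

    ``has_ap`` is False (and the remaining fields NaN) when no action
    potential was found — an explicit no-AP marker, not an exception.
    """

    has_ap: bool
    peak: float = math.nan                  # mV
    mdp: float = math.nan                   # minimum diastolic potential, mV
    amplitude: float = math.nan             # peak − MDP, mV
    half_width: float = math.nan            # width at half amplitude, ms
    apd50: float = math.nan                 # ms
    apd90: float = math.nan                 # ms
    cycle_length: float = math.nan          # mean peak-to-peak interval, ms
    n_ap: int = 0


def _crossing_time(t: np.ndarray, v: np.ndarray, i: int, level: float) -> float:
    """Linear interpolation of the time where v crosses `level` in [i, i+1]."""
    dv = v[i + 1] - v[i]
    if dv == 0:
        return float(t[i])
    return float(t[i] + (level - v[i]) / dv * (t[i + 1] - t[i]))


def ap_metrics(
    result: SimulationResult | None = None,
    window: tuple[float, float] | None = None,
    *,
    t: np.ndarray | None = None,
    v: np.ndarray | None = None,
    detect_threshold: float = -20.0,
    refractory: float = 2.0,
) -> APMetrics:
    """Per-AP shape metrics averaged over complete APs in ``window``.

    Widths (half-width, APD50, APD90) are measured per action potential by
    linear interpolation between samples; levels are referenced to the AP's
    own peak and the preceding minimum diastolic potential.
    """
    if result is not None:
        t, v = result.t, result.v
    assert t is not None and v is not None
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, v = t[m], v[m]
    if len(t) < 3:
        return APMetrics(has_ap=False)

    spikes = detect_spikes(t=t, v=v, threshold=detect_threshold, refractory=refractory)
    if len(spikes) == 0:
        return APMetrics(has_ap=False)

    # segment the trace at upward crossings; each AP spans crossing→crossing,
    # with the rising-edge search extended back before the detection
    # threshold so widths at low repolarization levels are not clipped
    peaks, mdps, hws, apd50s, apd90s, peak_times = [], [], [], [], [], []
    cross_idx = np.searchsorted(t, spikes)
    bounds = list(cross_idx) + [len(t) - 1]
    for k in range(len(cross_idx)):
        i0, i1 = bounds[k], bounds[k + 1]
        if i1 - i0 < 3:
            continue
        lo = bounds[k - 1] if k > 0 else 0
        seg_v = v[lo:i1]
        seg_t = t[lo:i1]
        ip = (i0 - lo) + int(np.argmax(v[i0:i1]))
        peak = float(seg_v[ip])
        # diastolic minimum between this AP and the next
        im = ip + int(np.argmin(seg_v[ip:]))
        mdp = float(seg_v[im])
        if k == 0 and i0 > 0:
            # prefer the minimum preceding the first AP when available
            mdp = min(mdp, float(np.min(v[:i0])))
        amp = peak - mdp
        if amp <= 0:
            continue
        peaks.append(peak)
        mdps.append(mdp)
        peak_times.append(float(seg_t[ip]))
        hws.append(_width_at(seg_t, seg_v, ip, peak - 0.5 * amp))
        apd50s.append(_width_at(seg_t, seg_v, ip, peak - 0.5 * amp))
        apd90s.append(_width_at(seg_t, seg_v, ip, peak - 0.9 * amp))

    if not peaks:
        return APMetrics(has_ap=False)
    cl = math.nan
    if len(peak_times) >= 2:
        cl = float(np.mean(np.diff(peak_times)))
    return APMetrics(
        has_ap=True,
        peak=float(np.mean(peaks)),
        mdp=float(np.mean(mdps)),
        amplitude=float(np.mean(peaks) - np.mean(mdps)),
        half_width=float(np.nanmean(hws)),
        apd50=float(np.nanmean(apd50s)),
        apd90=float(np.nanmean(apd90s)),
        cycle_length=cl,
        n_ap=len(peaks),
    )


def _width_at(seg_t: np.ndarray, seg_v: np.ndarray, ip: int, level: float) -> float:
    """Width of the AP at a repolarization level, interpolated (ms)."""
    # rising crossing before the peak
    t_up = None
    for i in range(ip, 0, -1):
        if seg_v[i - 1] < level <= seg_v[i]:
            t_up = _crossing_time(seg_t, seg_v, i - 1, level)
            break
    if t_up is None:
        t_up = float(seg_t[0])
    # falling crossing after the peak
    for i in range(ip, len(seg_v) - 1):
        if seg_v[i] >= level > seg_v[i + 1]:
            return _crossing_time(seg_t, seg_v, i, level) - t_up
    return math.nan
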