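"""Multicellular propagation: 1-D SANC cable and 2-D monodomain tissue.

1-D: a chain of identical SAN cells coupled by a diffusion constant D
(µm²/ms).  The excitation protocol clamps every cell to a hyperpolarized
potential, then clamps a fraction of the chain to a depolarized potential
and releases; the resulting activation wave yields a conduction velocity.

2-D: an operator-split monodomain sheet (explicit finite differences,
no-flux boundaries) with a central SAN disc embedded in atrial tissue.
SAN nodes run the full pacemaker cell model (sub-stepped reaction);
atrial nodes run the three-variable atrial plug-in.  The diffusion
coefficient is anisotropic and reduced inside the SAN disc, which sets
the source–sink balance between the node and the atrial load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._jit import njit
from .core import CellModel
from .models.atrial import V_REST, atrial_rates
from .models.san import san_rhs


class TissueError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# 1-D cable
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CableConfig:
    """Chain of diffusively coupled SAN cells and its clamp protocol."""

    n_cells: int = 50
    diffusion: float = 6.0e4        # µm²/ms
    cell_length: float = 70.0       # µm (index→distance convention)
    clamp_fraction: float = 0.2
    v_pre: float = -64.0            # mV, pre-clamp
    v_pulse: float = 23.0           # mV, pulse clamp
    t_pre: float = 300.0            # ms
    t_pulse: float = 10.0           # ms
    dt: float = 0.01                # ms, explicit step
    duration: float = 500.0         # ms total

    def __post_init__(self):
        if self.n_cells < 10:
            raise ValueError("cable needs at least 10 cells")
        if self.diffusion < 0:
            raise ValueError("diffusion must be >= 0")
        if not 0.0 < self.clamp_fraction < 1.0:
            raise ValueError("clamp fraction must be in (0, 1)")


@dataclass
class PropagationResult:
    """Probe traces, activation times and pacing/conduction event series."""

    t: np.ndarray
    v_probes: np.ndarray                 # (len(t), n_probes)
    probe_labels: tuple[str, ...]
    positions: np.ndarray | None = None  # µm (cable), per cell
    activation_times: np.ndarray | None = None
    clamped: np.ndarray | None = None
    san_cycles: np.ndarray | None = None
    atrial_activations: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


@njit(cache=True)
def _guard_san_state(y):
    # defensive bounds for explicit tissue stepping: gates and RyR/buffer
    # fractions stay in [0, 1], concentrations stay positive.  Inactive on
    # the single-cell limit cycle; engaged only in strongly driven nodes.
    for q in range(1, 14):
        if y[q] < 0.0:
            y[q] = 0.0
        elif y[q] > 1.0:
            y[q] = 1.0
    for q in range(14, 18):
        if y[q] < 1e-7:
            y[q] = 1e-7
    for q in range(18, 28):
        if y[q] < 0.0:
            y[q] = 0.0
        elif y[q] > 1.0:
            y[q] = 1.0


@njit(cache=True)
def _cable_kernel(Y, p, dt, n_steps, coup, n_clamp, v_pre, v_pulse,
                  i_pre_end, i_pulse_end, rec_stride, Vout):
    n = Y.shape[0]
    zero = np.zeros(1)
    k = 0
    for step in range(n_steps):
        vold = Y[:, 0].copy()
        for i in range(n):
            dy = san_rhs(0.0, Y[i], p, zero)
            for j in range(Y.shape[1]):
                Y[i, j] += dt * dy[j]
            _guard_san_state(Y[i])
            # diffusive coupling on V with no-flux ends
            vl = vold[i - 1] if i > 0 else vold[i]
            vr = vold[i + 1] if i < n - 1 else vold[i]
            Y[i, 0] += dt * coup * (vl - 2.0 * vold[i] + vr)
        if step < i_pre_end:
            for i in range(n):
                Y[i, 0] = v_pre
        elif step < i_pulse_end:
            for i in range(n_clamp):
                Y[i, 0] = v_pulse
        if step % rec_stride == 0:
            for i in range(n):
                Vout[k, i] = Y[i, 0]
            k += 1
    return k


def simulate_cable(config: CableConfig, model: CellModel,
                   duration: float | None = None) -> PropagationResult:
    """Run the 1-D clamp-release protocol and extract activation times."""
    if model.kind != "san":
        raise ValueError("cable cells must be a SAN model")
    duration = config.duration if duration is None else duration
    n = config.n_cells
    Y = np.tile(model.y0, (n, 1))
    coup = config.diffusion / config.cell_length ** 2
    dt = config.dt
    # keep the explicit diffusion update well inside its stability bound
    if coup > 0:
        n_div = max(1, int(math.ceil(coup * dt / 0.2)))
        dt = dt / n_div
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(0.5 / dt)))
    n_rec = n_steps // rec_stride + 1
    Vout = np.full((n_rec, n), np.nan)
    n_clamp = max(1, int(round(config.clamp_fraction * n)))
    i_pre_end = int(round(config.t_pre / dt))
    i_pulse_end = int(round((config.t_pre + config.t_pulse) / dt))
    k = _cable_kernel(Y, model.params, dt, n_steps, coup, n_clamp,
                      config.v_pre, config.v_pulse, i_pre_end, i_pulse_end,
                      rec_stride, Vout)
    Vout = Vout[:k]
    t = np.arange(k) * rec_stride * dt
    if not np.all(np.isfinite(Vout)) or np.max(np.abs(Vout)) > 200.0:
        raise TissueError(
            f"cable integration unstable (dt={dt} ms, D={config.diffusion} "
            "µm²/ms)")

    release = config.t_pre
    thresh = -20.0
    act = np.full(n, np.nan)
    for i in range(n):
        vi = Vout[:, i]
        above = vi >= thresh
        idx = np.flatnonzero(~above[:-1] & above[1:])
        idx = [j for j in idx if t[j] >= release]
        if idx:
            j = idx[0]
            dv = vi[j + 1] - vi[j]
            frac = 0.0 if dv == 0 else (thresh - vi[j]) / dv
            act[i] = t[j] + frac * (t[j + 1] - t[j])
    clamped = np.zeros(n, dtype=bool)
    clamped[:n_clamp] = True
    positions = np.arange(n) * config.cell_length
    probe_idx = (0, n // 2, n - 1)
    return PropagationResult(
        t=t,
        v_probes=Vout[:, probe_idx],
        probe_labels=tuple(f"cell{i}" for i in probe_idx),
        positions=positions,
        activation_times=act,
        clamped=clamped,
        meta={"config": config, "full_v": Vout},
    )


def conduction_velocity(result: PropagationResult,
                        cell_range: tuple[int, int] | None = None) -> float:
    """Conduction velocity (µm/ms) from a least-squares fit of position
    versus activation time, excluding clamped cells and boundary zones."""
    act = result.activation_times
    pos = result.positions
    assert act is not None and pos is not None
    n = len(act)
    mask = ~result.clamped & np.isfinite(act)
    if cell_range is None:
        # default fit window: developed-wave region — skip the wave-launch
        # zone after the clamped segment and the no-flux far boundary zone
        lo = int(np.argmax(~result.clamped)) + max(5, n // 8)
        hi = n - max(8, n // 4)
        sel = np.zeros(n, dtype=bool)
        sel[lo:hi] = True
        mask &= sel
    else:
        sel = np.zeros(n, dtype=bool)
        sel[cell_range[0]:cell_range[1]] = True
        mask &= sel
    if np.sum(mask) < 5:
        raise TissueError("need at least 5 activation times for a fit")
    ts = act[mask]
    xs = pos[mask]
    order = np.diff(ts[np.argsort(xs)])
    if not (np.all(order >= 0) or np.all(order <= 0)):
        raise TissueError("mixed propagation: activation order is not "
                          "monotone in the fit window")
    slope = np.polyfit(ts, xs, 1)[0]
    return float(slope)


# ---------------------------------------------------------------------------
# 2-D monodomain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueConfig:
    """2-D monodomain sheet with a central SAN disc."""

    size_cm: float = 3.0
    n_nodes: int = 76               # per axis ("full" preset: 151)
    dt: float = 0.125               # ms
    d_fiber: float = 1.2            # cm²/s along the monitored fiber (x)
    d_cross: float = 0.25           # cm²/s orthogonal
    san_radius_cm: float = 0.34
    d_san_factor: float = 0.35      # diffusion reduction inside the SAN disc
    peripheral_fraction: float = 0.3   # outer radial fraction of the disc
                                       # with the peripheral phenotype
    peripheral_na_scale: float = 20.0  # fast-Na amplification in that ring
    n_sub: int = 5                  # reaction substeps per diffusion step
    duration: float = 4000.0        # ms

    def __post_init__(self):
        if self.san_radius_cm >= self.size_cm / 2:
            raise ValueError("SAN radius must be below half the domain size")
        dx = self.size_cm / (self.n_nodes - 1)
        dmax = max(self.d_fiber, self.d_cross) * 1e-3
        if self.dt > dx * dx / (2.0 * (self.d_fiber + self.d_cross) * 1e-3):
            raise ValueError(
                f"dt={self.dt} ms unstable for dx={dx:.4f} cm")

    @property
    def dx(self) -> float:
        return self.size_cm / (self.n_nodes - 1)


@njit(cache=True)
def diffusion_step(V, dfx, dfy, dt, dx):
    """One explicit anisotropic diffusion step with no-flux boundaries.

    ``dfx``/``dfy`` are face-centered diffusion coefficients (cm²/ms):
    dfx[i, j] couples V[i, j] and V[i, j+1]; dfy[i, j] couples
    V[i, j] and V[i+1, j].
    """
    ny, nx = V.shape
    out = V.copy()
    r = dt / (dx * dx)
    for i in range(ny):
        for j in range(nx):
            acc = 0.0
            if j < nx - 1:
                acc += dfx[i, j] * (V[i, j + 1] - V[i, j])
            if j > 0:
                acc -= dfx[i, j - 1] * (V[i, j] - V[i, j - 1])
            if i < ny - 1:
                acc += dfy[i, j] * (V[i + 1, j] - V[i, j])
            if i > 0:
                acc -= dfy[i - 1, j] * (V[i, j] - V[i - 1, j])
            out[i, j] = V[i, j] + r * acc
    return out


@njit(cache=True)
def _tissue_kernel(V, gate_v, gate_w, san_iy, san_ix, S, p, p_peri,
                   is_peri, dfx, dfy, dt, dx, n_steps, n_sub,
                   probe_iy, probe_ix, rec_stride, Vprobes, san_max):
    ny, nx = V.shape
    n_san = san_iy.shape[0]
    n_states = S.shape[1] + 1
    y = np.empty(n_states)
    zero = np.zeros(1)
    dt_sub = dt / n_sub
    k = 0
    is_san = np.zeros((ny, nx), dtype=np.int8)
    for s in range(n_san):
        is_san[san_iy[s], san_ix[s]] = 1
    for step in range(n_steps):
        V2 = diffusion_step(V, dfx, dfy, dt, dx)
        for i in range(ny):
            for j in range(nx):
                V[i, j] = V2[i, j]
        # atrial reaction (explicit)
        for i in range(ny):
            for j in range(nx):
                if is_san[i, j] == 0:
                    dv_mv, dv, dw = atrial_rates(V[i, j], gate_v[i, j],
                                                 gate_w[i, j])
                    V[i, j] += dt * dv_mv
                    gate_v[i, j] += dt * dv
                    gate_w[i, j] += dt * dw
        # SAN reaction, sub-stepped
        for s in range(n_san):
            iy = san_iy[s]
            ix = san_ix[s]
            y[0] = V[iy, ix]
            for q in range(n_states - 1):
                y[q + 1] = S[s, q]
            ps = p_peri if is_peri[s] == 1 else p
            for _ in range(n_sub):
                dy = san_rhs(0.0, y, ps, zero)
                for q in range(n_states):
                    y[q] += dt_sub * dy[q]
                _guard_san_state(y)
            V[iy, ix] = y[0]
            for q in range(n_states - 1):
                S[s, q] = y[q + 1]
        if step % rec_stride == 0:
            for q in range(probe_iy.shape[0]):
                Vprobes[k, q] = V[probe_iy[q], probe_ix[q]]
            vmax = -1e9
            for s in range(n_san):
                if V[san_iy[s], san_ix[s]] > vmax:
                    vmax = V[san_iy[s], san_ix[s]]
            san_max[k] = vmax
            k += 1
    return k


def _diastolic_state(model: CellModel) -> np.ndarray:
    from .core import integrate_cell

    res = integrate_cell(model, None, 600.0, dt_record=0.5)
    half = len(res.t) // 2
    i_min = half + int(np.argmin(res.v[half:]))
    return res.y[i_min].copy()


def simulate_tissue_2d(config: TissueConfig, san_model: CellModel,
                       duration: float | None = None) -> PropagationResult:
    """Monodomain SAN-disc-in-atrium simulation.

    Returns probe traces at six sites along the +x axis from the disc
    center to the far atrial border, plus SAN cycle and atrial activation
    time series extracted from the center and distal probes.
    """
    if san_model.kind != "san":
        raise ValueError("SAN tissue requires a SAN cell model")
    duration = config.duration if duration is None else duration
    n = config.n_nodes
    dx = config.dx
    cx = cy = (n - 1) // 2

    xs = (np.arange(n) - cx) * dx
    ys = (np.arange(n) - cy) * dx
    X, Y = np.meshgrid(xs, ys)
    r_grid = np.sqrt(X ** 2 + Y ** 2)
    san_mask = r_grid <= config.san_radius_cm
    san_iy, san_ix = np.nonzero(san_mask)
    r_inner = (1.0 - config.peripheral_fraction) * config.san_radius_cm
    is_peri = (r_grid[san_iy, san_ix] > r_inner).astype(np.int8)
    # peripheral phenotype: strong fast Na (upstroke amplifier toward the
    # atrium) but weaker spontaneous drive than the center, so the ring is
    # driven by the central pacemaker rather than self-oscillating
    peri_model = san_model.with_params({
        "na.gbar": san_model.param("na.gbar") * config.peripheral_na_scale,
        "cal13.gbar": san_model.param("cal13.gbar") * 0.5,
        "cat.gbar": san_model.param("cat.gbar") * 0.5,
        "hcn.gbar": san_model.param("hcn.gbar") * 0.5,
    })

    # face-centered diffusion fields (cm²/ms), reduced inside the SAN
    d_node = np.where(san_mask, config.d_san_factor, 1.0)
    dfx = np.empty((n, n))
    dfy = np.empty((n, n))
    hx = config.d_fiber * 1e-3
    hy = config.d_cross * 1e-3
    dfx[:, :-1] = hx * 0.5 * (d_node[:, :-1] + d_node[:, 1:])
    dfx[:, -1] = 0.0
    dfy[:-1, :] = hy * 0.5 * (d_node[:-1, :] + d_node[1:, :])
    dfy[-1, :] = 0.0

    V = np.full((n, n), V_REST)
    gate_v = np.ones((n, n))
    gate_w = np.ones((n, n))
    # start SAN nodes at the diastolic phase (maximum diastolic potential)
    # of the cell's own cycle so the tissue run begins between beats
    y_dia = _diastolic_state(san_model)
    S = np.tile(y_dia[1:], (len(san_iy), 1))
    V[san_iy, san_ix] = y_dia[0]

    # probes: center → SAN border → atrium, along +x
    r_nodes = int(round(config.san_radius_cm / dx))
    probe_off = [0, r_nodes // 2, r_nodes, r_nodes + 2,
                 (r_nodes + n - 1 - cx) // 2, n - 2 - cx]
    probe_ix = np.array([min(cx + o, n - 2) for o in probe_off])
    probe_iy = np.full_like(probe_ix, cy)
    labels = ("center", "half-radius", "border", "peri-san",
              "mid-atrium", "distal")

    dt = config.dt
    n_steps = int(round(duration / dt))
    rec_stride = max(1, int(round(1.0 / dt)))
    n_rec = n_steps // rec_stride + 1
    Vprobes = np.full((n_rec, len(probe_ix)), np.nan)
    san_max = np.full(n_rec, np.nan)
    k = _tissue_kernel(V, gate_v, gate_w, san_iy.astype(np.int64),
                       san_ix.astype(np.int64), S, san_model.params,
                       peri_model.params, is_peri,
                       dfx, dfy, dt, dx, n_steps, config.n_sub,
                       probe_iy.astype(np.int64), probe_ix.astype(np.int64),
                       rec_stride, Vprobes, san_max)
    Vprobes = Vprobes[:k]
    san_max = san_max[:k]
    t = np.arange(k) * rec_stride * dt
    if not np.all(np.isfinite(Vprobes)) or np.max(np.abs(Vprobes)) > 200.0:
        raise TissueError(
            f"2-D integration unstable (dt={dt} ms, dx={dx:.4f} cm)")

    res = PropagationResult(
        t=t, v_probes=Vprobes, probe_labels=labels,
        meta={"config": config, "final_v": V},
    )
    # SAN cycles from the disc-wide maximum V: robust to shifts of the
    # leading pacemaker site under variants
    res.san_cycles = _upward_crossings(t, san_max, -20.0, 80.0)
    res.atrial_activations = _upward_crossings(t, Vprobes[:, -1], -40.0, 50.0)
    res.meta["san_max"] = san_max
    return res


def _upward_crossings(t, v, threshold, refractory):
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:])
    out = []
    last = -np.inf
    for i in idx:
        if t[i] - last >= refractory:
            out.append(t[i])
            last = t[i]
    return np.asarray(out)


@dataclass(frozen=True)
class ExitBlockReport:
    events: tuple[float, ...]            # SAN cycle times without capture
    intervals: np.ndarray                # beat-to-beat intervals at atrium
    n_san_cycles: int
    n_atrial_beats: int
    silenced: bool


def detect_exit_block(result: PropagationResult,
                      window: float = 200.0,
                      settle: float = 500.0) -> ExitBlockReport:
    """Match SAN cycles to atrial activations.

    An exit-block event is a SAN cycle with no atrial activation within
    ``window`` ms.  Beat-to-beat intervals are measured at the distal
    atrial probe.  ``silenced`` is set when the SAN produces no cycle
    after the settling period.
    """
    assert result.san_cycles is not None
    assert result.atrial_activations is not None
    san = result.san_cycles[result.san_cycles >= settle]
    atr = result.atrial_activations[result.atrial_activations >= settle]
    t_end = result.t[-1]
    events = []
    for tc in san:
        if tc + window > t_end:
            continue        # cannot judge capture at the end of the record
        if not np.any((atr >= tc) & (atr <= tc + window)):
            events.append(float(tc))
    return ExitBlockReport(
        events=tuple(events),
        intervals=np.diff(atr),
        n_san_cycles=len(san),
        n_atrial_beats=len(atr),
        silenced=len(san) == 0,
    )


# ---------------------------------------------------------------------------
# demonstration scenario helpers
# ---------------------------------------------------------------------------

def demo_ca_variant():
    """Synthetic CACNA1C-type demonstration variant for tissue scenarios.

    A strong L-type (Cav1.2) gain-of-function effect (activation shifted
    −20 mV, conductance ×6 at raw strength) standing in for a curated
    literature variant; it is meant to be downscaled by calibration before
    use.  Positive scale = gain of function, negative = loss.
    """
    from .variants import ParameterModification, VariantEffect

    return VariantEffect(
        "CACNA1C-demo", "CACNA1C",
        (
            ParameterModification("cal12.act.v_off", "add", -20.0),
            ParameterModification("cal12.gbar", "mult", 6.0),
        ),
        source="synthetic demonstration variant",
    )


#: SAN–atrium coupling presets.  The intranodal coupling strength is not a
#: measured quantity; the two presets bracket it and expose the two failure
#: modes of sinoatrial conduction: at strong coupling the atrial load can
#: silence a weakened node outright; at weak coupling an accelerated node
#: produces premature beats that fail to capture the atrium (exit block).
COUPLING_PRESETS = {"weak": 0.35, "strong": 0.8}


def tissue_preset(radius_cm: float, coupling: str = "weak",
                  duration: float = 4000.0, **kw) -> TissueConfig:
    """TissueConfig with a named SAN coupling preset."""
    return TissueConfig(san_radius_cm=radius_cm,
                        d_san_factor=COUPLING_PRESETS[coupling],
                        duration=duration, **kw)
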