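"""Reduced cortical layer-V pyramidal cell (L5PC) model.

A two-compartment (somatic + apical-dendritic) conductance-based neuron
carrying the canonical L5PC channel repertoire: transient and persistent
Na⁺, delayed-rectifier and slow (M-type) K⁺, SK-type Ca²⁺-activated K⁺,
high-voltage-activated (L-type) and low-voltage-activated (T-type) Ca²⁺
channels, HCN (I_h) and leak, plus a decaying intracellular Ca²⁺ pool per
compartment with both a passive decay term and a saturable SERCA-like
uptake term parameterized by ``serca.p_up``.

The model substitutes a reduced morphology for the full multicompartment
reconstructions; its intended use is directional (sign/monotonicity)
analysis of variant effects on firing, not absolute current matching.

The SK ↔ Ca²⁺ coupling is the essential mechanism: Ca²⁺ entering through
the voltage-gated Ca²⁺ channels activates the hyperpolarizing SK current,
so a *gain* of Ca²⁺-channel function lowers the steady firing rate.

Gene-facing parameter paths are shared with the SAN models: ``na.*``,
``hcn.*``, ``cal12.*``/``cal13.*`` (both resolve to the single HVA L-type
current here), ``cat.*`` (LVA T-type), ``serca.p_up``.

Units as in :mod:`pleiopace.core`.
"""

from __future__ import annotations

import math

import numpy as np

from .._jit import njit
from ..core import CellModel

_SCALARS = [
    "cm_s", "cm_d", "g_axial",
    "na.e_rev", "k.e_rev", "ca.e_rev", "hcn.e_rev", "leak.e_rev",
    "na.gbar", "nap.gbar", "kdr.gbar", "km.gbar",
    "sk.gbar", "cal12.gbar", "cat.gbar", "hcn.gbar", "leak.gbar",
    "dend.sk", "dend.cal12", "dend.cat", "dend.hcn", "dend.leak",
    "sk.km", "serca.p_up", "serca.k_up",
    "ca.phi", "ca.tau_decay", "ca.rest",
]

_GATES = [
    "na.act", "na.inact", "nap.act", "kdr.act", "km.act",
    "cal12.act", "cal12.inact", "cat.act", "cat.inact", "hcn.act",
]
_GATE_FIELDS = ["v_half", "slope", "v_off", "slope_scale", "tau_scale", "tau_base"]

PARAM_NAMES: list[str] = list(_SCALARS)
for _g in _GATES:
    PARAM_NAMES += [f"{_g}.{_f}" for _f in _GATE_FIELDS]

P = {name: i for i, name in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)

# Cav1.3-targeting modifications resolve onto the single HVA L current
_ALIASES = {
    "cal13.gbar": "cal12.gbar",
    "cal13.act.v_off": "cal12.act.v_off",
    "cal13.act.slope_scale": "cal12.act.slope_scale",
    "cal13.act.tau_scale": "cal12.act.tau_scale",
    "cal13.inact.v_off": "cal12.inact.v_off",
    "cal13.inact.slope_scale": "cal12.inact.slope_scale",
    "cal13.inact.tau_scale": "cal12.inact.tau_scale",
}

ADDITIVE_PATHS = frozenset(
    [f"{g}.v_off" for g in _GATES]
    + ["cal13.act.v_off", "cal13.inact.v_off"]
    + ["na.e_rev", "k.e_rev", "ca.e_rev", "hcn.e_rev", "leak.e_rev"],
)

STATE_NAMES = (
    "v_soma", "v_dend",
    "m_na", "h_na", "p_nap", "n_kdr", "z_km",
    "q_cal", "r_cal", "s_cat", "u_cat", "y_hcn_s", "y_hcn_d",
    "ca_soma", "ca_dend",
)

CURRENT_NAMES = ("na", "nap", "kdr", "km", "sk_s", "cal12_s", "cat_s",
                 "hcn_s", "leak_s", "sk_d", "cal12_d", "cat_d", "hcn_d",
                 "leak_d", "axial")

_GB = {g: P[f"{g}.v_half"] for g in _GATES}
_B_NAA = _GB["na.act"]; _B_NAI = _GB["na.inact"]
_B_NAP = _GB["nap.act"]; _B_KDR = _GB["kdr.act"]; _B_KM = _GB["km.act"]
_B_CALA = _GB["cal12.act"]; _B_CALI = _GB["cal12.inact"]
_B_CATA = _GB["cat.act"]; _B_CATI = _GB["cat.inact"]
_B_HCN = _GB["hcn.act"]


@njit(cache=True)
def _ninf(v, p, base, rising):
    vh = p[base] + p[base + 2]
    k = p[base + 1] * p[base + 3]
    if rising:
        return 1.0 / (1.0 + math.exp(-(v - vh) / k))
    return 1.0 / (1.0 + math.exp((v - vh) / k))


@njit(cache=True)
def _ntau(v, p, base, c0, c1, mu, sig):
    vs = v - p[base + 2]
    z = (vs - mu) / sig
    return p[base + 5] * p[base + 4] * (c0 + c1 * math.exp(-z * z))


@njit(cache=True)
def _sk_open(ca, km):
    # steep Ca dependence of SK activation (Hill coefficient 4)
    x = ca / km
    x4 = x * x * x * x
    return x4 / (1.0 + x4)


@njit(cache=True)
def _neuron_currents(y, p):
    out = np.empty(15)
    vs = y[0]
    vd = y[1]
    ena, ek, eca, eh, el = p[3], p[4], p[5], p[6], p[7]
    m, h, pp, n, z = y[2], y[3], y[4], y[5], y[6]
    q, r, s, u, ys, yd = y[7], y[8], y[9], y[10], y[11], y[12]
    ca_s, ca_d = y[13], y[14]
    sk_s = _sk_open(ca_s, p[22])
    sk_d = _sk_open(ca_d, p[22])
    out[0] = p[8] * m * m * m * h * (vs - ena)           # transient Na
    out[1] = p[9] * pp * (vs - ena)                      # persistent Na
    out[2] = p[10] * n * n * n * n * (vs - ek)           # delayed rectifier
    out[3] = p[11] * z * (vs - ek)                       # M-type K
    out[4] = p[12] * sk_s * (vs - ek)                    # SK soma
    out[5] = p[13] * q * q * r * (vs - eca)              # HVA L-type soma
    out[6] = p[14] * s * s * u * (vs - eca)              # LVA T-type soma
    out[7] = p[15] * ys * (vs - eh)                      # HCN soma
    out[8] = p[16] * (vs - el)                           # leak soma
    out[9] = p[12] * p[17] * sk_d * (vd - ek)            # SK dend
    out[10] = p[13] * p[18] * q * q * r * (vd - eca)     # HVA dend
    out[11] = p[14] * p[19] * s * s * u * (vd - eca)     # LVA dend
    out[12] = p[15] * p[20] * yd * (vd - eh)             # HCN dend
    out[13] = p[16] * p[21] * (vd - el)                  # leak dend
    out[14] = p[2] * (vs - vd)                           # axial (soma→dend)
    return out


@njit(cache=True)
def neuron_rhs(t, y, p, istim):
    dy = np.empty(15)
    vs = y[0]
    vd = y[1]

    m_inf = _ninf(vs, p, _B_NAA, True)
    tau_m = _ntau(vs, p, _B_NAA, 0.05, 0.25, -40.0, 25.0)
    h_inf = _ninf(vs, p, _B_NAI, False)
    tau_h = _ntau(vs, p, _B_NAI, 0.4, 7.0, -60.0, 20.0)
    p_inf = _ninf(vs, p, _B_NAP, True)
    tau_p = _ntau(vs, p, _B_NAP, 1.0, 4.0, -50.0, 20.0)
    n_inf = _ninf(vs, p, _B_KDR, True)
    tau_n = _ntau(vs, p, _B_KDR, 0.8, 4.0, -40.0, 25.0)
    z_inf = _ninf(vs, p, _B_KM, True)
    tau_z = _ntau(vs, p, _B_KM, 60.0, 40.0, -40.0, 25.0)

    q_inf = _ninf(vs, p, _B_CALA, True)
    tau_q = _ntau(vs, p, _B_CALA, 0.8, 1.2, -25.0, 20.0)
    r_inf = _ninf(vs, p, _B_CALI, False)
    tau_r = _ntau(vs, p, _B_CALI, 200.0, 150.0, -40.0, 20.0)
    s_inf = _ninf(vs, p, _B_CATA, True)
    tau_s = _ntau(vs, p, _B_CATA, 2.0, 6.0, -60.0, 20.0)
    u_inf = _ninf(vs, p, _B_CATI, False)
    tau_u = _ntau(vs, p, _B_CATI, 20.0, 60.0, -75.0, 20.0)
    ys_inf = _ninf(vs, p, _B_HCN, False)
    tau_ys = _ntau(vs, p, _B_HCN, 35.0, 200.0, -80.0, 25.0)
    yd_inf = _ninf(vd, p, _B_HCN, False)
    tau_yd = _ntau(vd, p, _B_HCN, 35.0, 200.0, -80.0, 25.0)

    cur = _neuron_currents(y, p)
    i_soma = (cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5] + cur[6]
              + cur[7] + cur[8] + cur[14])
    i_dend = (cur[9] + cur[10] + cur[11] + cur[12] + cur[13] - cur[14])
    dy[0] = (-i_soma + istim[0]) / p[0]
    dy[1] = (-i_dend + istim[1]) / p[1]

    dy[2] = (m_inf - y[2]) / tau_m
    dy[3] = (h_inf - y[3]) / tau_h
    dy[4] = (p_inf - y[4]) / tau_p
    dy[5] = (n_inf - y[5]) / tau_n
    dy[6] = (z_inf - y[6]) / tau_z
    dy[7] = (q_inf - y[7]) / tau_q
    dy[8] = (r_inf - y[8]) / tau_r
    dy[9] = (s_inf - y[9]) / tau_s
    dy[10] = (u_inf - y[10]) / tau_u
    dy[11] = (ys_inf - y[11]) / tau_ys
    dy[12] = (yd_inf - y[12]) / tau_yd

    # intracellular Ca: influx from Ca currents, passive decay + SERCA uptake
    phi = p[25]
    tau_ca = p[26]
    ca0 = p[27]
    pup = p[23]
    kup = p[24]
    ca_s = y[13]
    ca_d = y[14]
    ex_s = ca_s - ca0
    ex_d = ca_d - ca0
    dy[13] = (-phi * (cur[5] + cur[6]) - ex_s / tau_ca
              - pup * ex_s / (kup + ex_s))
    dy[14] = (-phi * (cur[10] + cur[11]) - ex_d / tau_ca
              - pup * ex_d / (kup + ex_d))
    return dy


_DEFAULTS = {
    "cm_s": 0.15, "cm_d": 0.45, "g_axial": 0.04,
    "na.e_rev": 55.0, "k.e_rev": -85.0, "ca.e_rev": 120.0,
    "hcn.e_rev": -45.0, "leak.e_rev": -81.0,
    "na.gbar": 10.0, "nap.gbar": 0.005, "kdr.gbar": 2.0, "km.gbar": 0.10,
    "sk.gbar": 0.2, "cal12.gbar": 0.008, "cat.gbar": 0.006,
    "hcn.gbar": 0.008, "leak.gbar": 0.011,
    "dend.sk": 0.5, "dend.cal12": 0.4, "dend.cat": 1.5, "dend.hcn": 2.0,
    "dend.leak": 1.0,
    "sk.km": 0.00043, "serca.p_up": 2e-4, "serca.k_up": 4e-4,
    "ca.phi": 5e-3, "ca.tau_decay": 120.0, "ca.rest": 5e-5,
}

_GATE_DEFAULTS = {
    # gate: (v_half, slope, tau_base)
    "na.act": (-40.0, 6.0, 1.0),
    "na.inact": (-60.0, 6.5, 1.0),
    "nap.act": (-52.6, 4.6, 1.0),
    "kdr.act": (-15.0, 11.0, 1.0),
    "km.act": (-35.0, 9.0, 1.0),
    "cal12.act": (-15.0, 7.0, 1.0),
    "cal12.inact": (-50.0, 8.0, 0.5),
    "cat.act": (-45.0, 6.0, 1.0),
    "cat.inact": (-78.0, 6.4, 1.0),
    "hcn.act": (-84.0, 9.0, 1.0),
}

_PROVENANCE = (
    "Reduced two-compartment layer-V pyramidal cell with the Hay-type "
    "channel repertoire (transient/persistent Na, delayed-rectifier and "
    "M-type K, SK, HVA-L and LVA-T Ca, HCN, leak, Ca pool with SERCA-like "
    "uptake). Directional substitute for the full multicompartmental "
    "reconstructions; acceptance on this model is sign/monotonicity only."
)


def build_neuron(variant: str = "reduced", morphology=None) -> CellModel:
    """Build the reduced two-compartment L5PC model.

    Only ``variant="reduced"`` is available; the full-morphology variant
    requires an external reconstruction file and is intentionally not
    bundled.
    """
    if variant != "reduced":
        raise ValueError(
            f"neuron variant {variant!r} unavailable: only 'reduced' is "
            "bundled (full-morphology models need external morphology files)")
    pvec = np.zeros(N_PARAMS)
    for k, v in _DEFAULTS.items():
        pvec[P[k]] = v
    for g, (vh, k, tb) in _GATE_DEFAULTS.items():
        pvec[P[f"{g}.v_half"]] = vh
        pvec[P[f"{g}.slope"]] = k
        pvec[P[f"{g}.slope_scale"]] = 1.0
        pvec[P[f"{g}.tau_scale"]] = 1.0
        pvec[P[f"{g}.tau_base"]] = tb

    index = dict(P)
    for alias, target in _ALIASES.items():
        index[alias] = P[target]

    v0 = -72.0
    y0 = np.zeros(len(STATE_NAMES))
    y0[0] = v0
    y0[1] = v0
    rising = {2: _B_NAA, 4: _B_NAP, 5: _B_KDR, 6: _B_KM, 7: _B_CALA,
              9: _B_CATA}
    falling = {3: _B_NAI, 8: _B_CALI, 10: _B_CATI, 11: _B_HCN, 12: _B_HCN}
    for i, base in rising.items():
        y0[i] = _ninf(v0, pvec, base, True)
    for i, base in falling.items():
        y0[i] = _ninf(v0, pvec, base, False)
    y0[13] = _DEFAULTS["ca.rest"]
    y0[14] = _DEFAULTS["ca.rest"]

    return CellModel(
        name="neuron-reduced",
        kind="neuron",
        n_comp=2,
        state_names=STATE_NAMES,
        param_index=index,
        params=pvec,
        y0=y0,
        rhs=neuron_rhs,
        current_names=CURRENT_NAMES,
        currents_fn=_neuron_currents,
        additive_paths=ADDITIVE_PATHS,
        provenance=_PROVENANCE,
        v_index=(0, 1),
        conc_states=(13, 14),
        gate_states=tuple(range(2, 13)),
    )
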