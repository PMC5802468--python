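"""Single-compartment sinoatrial node cell (SANC) models.

Two parameterizations of one shared pacemaker architecture are provided:

* ``san-mouse`` — mouse-type SANC (HCN4-dominated funny current with a very
  negative half-activation of −106.8 mV and a shallow slope of 16.3 mV,
  funny-current reversal near −24 mV, fast intrinsic rate),
* ``san-rabbit`` — rabbit-type SANC (mixed HCN1/HCN4 funny current with
  half-activation −52.5 mV and slope 9.0 mV, reversal near −4 mV, slower
  intrinsic rate).

The architecture follows the Kurata / Maltsev–Lakatta lineage of central
SANC models on which the mouse and rabbit source models are built: a
membrane "voltage clock" (L-type Cav1.2 and Cav1.3 components, T-type Ca²⁺,
funny current, TTX-sensitive Na⁺, rapid and slow delayed-rectifier K⁺,
Na⁺/K⁺ pump, background current) coupled to a sarcoplasmic-reticulum
"calcium clock" (SERCA uptake P_up into the network SR, junctional SR
release through load-gated RyRs into a submembrane space, Na⁺/Ca²⁺
exchange translating submembrane Ca²⁺ into depolarizing inward current).

Units: mV, ms, nA, µS, nF, mM, pL.  Positive current = outward.
"""

from __future__ import annotations

import math

import numpy as np

from .._jit import njit
from ..core import CellModel

# ---------------------------------------------------------------------------
# parameter vector layout
# ---------------------------------------------------------------------------

_SCALARS = [
    "cm", "rate",
    "na.e_rev", "k.e_rev", "ca.e_rev", "hcn.e_rev", "b.e_rev",
    "nai", "cao",
    "cal12.gbar", "cal13.gbar", "cat.gbar", "hcn.gbar", "na.gbar",
    "kr.gbar", "ks.gbar", "b.gbar",
    "nak.imax", "nak.km_na",
    "ncx.k", "ncx.d", "ncx.gamma",
    "serca.p_up", "serca.k_up",
    "ryr.ks", "sr.tau_tr", "sr.tau_dif",
    "ryr.ko_ca", "ryr.ki_ca", "ryr.kom", "ryr.kim",
    "ryr.ec50_sr", "ryr.max_sr", "ryr.min_sr",
    "vol.sub", "vol.cyto", "vol.nsr", "vol.jsr",
    "fca.km", "fca.tau",
]

# per-gate parameters: v_half, slope, v_off (additive), slope_scale,
# tau_scale (both multiplicative), tau_base (model constant)
_GATES = [
    "cal12.act", "cal12.inact", "cal13.act", "cal13.inact",
    "cat.act", "cat.inact", "hcn.act", "na.act", "na.inact",
    "kr.act", "kr.inact", "ks.act",
]
_GATE_FIELDS = ["v_half", "slope", "v_off", "slope_scale", "tau_scale", "tau_base"]

PARAM_NAMES: list[str] = list(_SCALARS)
for _g in _GATES:
    PARAM_NAMES += [f"{_g}.{_f}" for _f in _GATE_FIELDS]

P = {name: i for i, name in enumerate(PARAM_NAMES)}
N_PARAMS = len(PARAM_NAMES)

ADDITIVE_PATHS = frozenset(
    [f"{g}.v_off" for g in _GATES]
    + ["na.e_rev", "k.e_rev", "ca.e_rev", "hcn.e_rev", "b.e_rev"],
)

STATE_NAMES = (
    "v",
    "d_cal12", "f_cal12", "d_cal13", "f_cal13", "f_ca",
    "d_cat", "f_cat", "y_hcn", "m_na", "h_na", "pa_kr", "pi_kr", "n_ks",
    "ca_sub", "ca_i", "ca_nsr", "ca_jsr",
    "ryr_r", "ryr_o", "ryr_i", "ryr_ri",
    "f_tc", "f_tmc", "f_tmm", "f_cmi", "f_cms", "f_cq",
)

CURRENT_NAMES = (
    "cal12", "cal13", "cat", "f", "na", "kr", "ks", "b", "nak", "ncx",
)

# Ca²⁺ buffering constants (troponin, troponin-Mg, calmodulin, calsequestrin)
_KF_TC, _KB_TC = 88.8, 0.446
_KF_TMC, _KB_TMC = 227.7, 0.00751
_KF_TMM, _KB_TMM = 2.277, 0.751
_KF_CM, _KB_CM = 227.7, 0.542
_KF_CQ, _KB_CQ = 0.534, 0.445
_TC_TOT, _TMC_TOT, _CM_TOT, _CQ_TOT = 0.031, 0.062, 0.045, 10.0
_MGI = 2.5
_F = 96.485          # C/mmol — current (nA) / (z·F·vol pL) -> mM/ms
_RTF = 26.73         # mV

# gate index bases inside the parameter vector
_GB = {g: P[f"{g}.v_half"] for g in _GATES}
_B_CAL12A = _GB["cal12.act"]; _B_CAL12I = _GB["cal12.inact"]
_B_CAL13A = _GB["cal13.act"]; _B_CAL13I = _GB["cal13.inact"]
_B_CATA = _GB["cat.act"]; _B_CATI = _GB["cat.inact"]
_B_HCN = _GB["hcn.act"]
_B_NAA = _GB["na.act"]; _B_NAI = _GB["na.inact"]
_B_KRA = _GB["kr.act"]; _B_KRI = _GB["kr.inact"]
_B_KS = _GB["ks.act"]


@njit(cache=True)
def _gate_inf(v, p, base, rising):
    vh = p[base] + p[base + 2]
    k = p[base + 1] * p[base + 3]
    if rising:
        return 1.0 / (1.0 + math.exp(-(v - vh) / k))
    return 1.0 / (1.0 + math.exp((v - vh) / k))


@njit(cache=True)
def _bell(vs, c0, c1, mu, sig):
    z = (vs - mu) / sig
    return c0 + c1 * math.exp(-z * z)


@njit(cache=True)
def _gate_tau(v, p, base, c0, c1, mu, sig):
    vs = v - p[base + 2]
    return p[base + 5] * p[base + 4] * _bell(vs, c0, c1, mu, sig)


@njit(cache=True)
def _san_currents(y, p):
    v = y[0]
    ca_sub = y[14]
    out = np.empty(10)
    eca = p[4]
    ek = p[3]
    fca = y[5]
    out[0] = p[9] * y[1] * y[2] * fca * (v - eca)           # ICaL Cav1.2
    out[1] = p[10] * y[3] * y[4] * fca * (v - eca)          # ICaL Cav1.3
    out[2] = p[11] * y[6] * y[7] * (v - eca)                # ICaT
    out[3] = p[12] * y[8] * (v - p[5])                      # I_f
    out[4] = p[13] * y[9] ** 3 * y[10] * (v - p[2])         # INa
    out[5] = p[14] * y[11] * y[12] * (v - ek)               # IKr
    out[6] = p[15] * y[13] * y[13] * (v - ek)               # IKs
    out[7] = p[16] * (v - p[6])                             # background
    # Na/K pump: Na-dependent, weakly voltage dependent, outward
    nai = p[7]
    out[8] = p[17] / (1.0 + (p[18] / nai) ** 3) / (1.0 + math.exp(-(v + 60.0) / 40.0))
    # Na/Ca exchange on submembrane Ca
    cao = p[8]
    gam = p[21]
    kncx = p[19]
    dncx = p[20]
    nao3 = 140.0 ** 3
    nai3 = nai ** 3
    t1 = nai3 * cao * math.exp(gam * v / _RTF)
    t2 = nao3 * ca_sub * math.exp((gam - 1.0) * v / _RTF)
    out[9] = kncx * (t1 - t2) / (1.0 + dncx * (nao3 * ca_sub + nai3 * cao))
    return out


@njit(cache=True)
def san_rhs(t, y, p, istim):
    dy = np.empty(28)
    v = y[0]

    # --- gating steady states and time constants -------------------------
    dL_inf = _gate_inf(v, p, _B_CAL12A, True)
    tau_dL = _gate_tau(v, p, _B_CAL12A, 0.4, 1.6, -15.0, 15.0)
    fL_inf = _gate_inf(v, p, _B_CAL12I, False)
    tau_fL = _gate_tau(v, p, _B_CAL12I, 25.0, 60.0, -25.0, 14.0)

    dD_inf = _gate_inf(v, p, _B_CAL13A, True)
    tau_dD = _gate_tau(v, p, _B_CAL13A, 0.5, 1.8, -30.0, 18.0)
    fD_inf = _gate_inf(v, p, _B_CAL13I, False)
    tau_fD = _gate_tau(v, p, _B_CAL13I, 30.0, 70.0, -35.0, 14.0)

    dT_inf = _gate_inf(v, p, _B_CATA, True)
    tau_dT = _gate_tau(v, p, _B_CATA, 0.6, 1.5, -40.0, 18.0)
    fT_inf = _gate_inf(v, p, _B_CATI, False)
    tau_fT = _gate_tau(v, p, _B_CATI, 5.0, 25.0, -60.0, 12.0)

    # funny current activates on hyperpolarization (falling sigmoid)
    y_inf = _gate_inf(v, p, _B_HCN, False)
    tau_y = _gate_tau(v, p, _B_HCN, 60.0, 1300.0, -75.0, 25.0)

    m_inf = _gate_inf(v, p, _B_NAA, True)
    tau_m = _gate_tau(v, p, _B_NAA, 0.03, 0.35, -45.0, 15.0)
    h_inf = _gate_inf(v, p, _B_NAI, False)
    tau_h = _gate_tau(v, p, _B_NAI, 0.3, 12.0, -70.0, 12.0)

    pa_inf = _gate_inf(v, p, _B_KRA, True)
    tau_pa = _gate_tau(v, p, _B_KRA, 10.0, 160.0, -55.0, 25.0)
    pi_inf = _gate_inf(v, p, _B_KRI, False)
    tau_pi = _gate_tau(v, p, _B_KRI, 1.5, 0.0, 0.0, 1.0)

    n_inf = _gate_inf(v, p, _B_KS, True)
    tau_n = _gate_tau(v, p, _B_KS, 150.0, 700.0, -25.0, 30.0)

    ca_sub = y[14]
    ca_i = y[15]
    ca_nsr = y[16]
    ca_jsr = y[17]

    fca_inf = p[38] / (p[38] + ca_sub)
    tau_fca = p[39]

    # --- membrane currents ----------------------------------------------
    cur = _san_currents(y, p)
    itot = (cur[0] + cur[1] + cur[2] + cur[3] + cur[4] + cur[5] + cur[6]
            + cur[7] + cur[8] + cur[9])
    dy[0] = (-itot + istim[0]) / p[0]

    dy[1] = (dL_inf - y[1]) / tau_dL
    dy[2] = (fL_inf - y[2]) / tau_fL
    dy[3] = (dD_inf - y[3]) / tau_dD
    dy[4] = (fD_inf - y[4]) / tau_fD
    dy[5] = (fca_inf - y[5]) / tau_fca
    dy[6] = (dT_inf - y[6]) / tau_dT
    dy[7] = (fT_inf - y[7]) / tau_fT
    dy[8] = (y_inf - y[8]) / tau_y
    dy[9] = (m_inf - y[9]) / tau_m
    dy[10] = (h_inf - y[10]) / tau_h
    dy[11] = (pa_inf - y[11]) / tau_pa
    dy[12] = (pi_inf - y[12]) / tau_pi
    dy[13] = (n_inf - y[13]) / tau_n

    # --- RyR release gating (SR-load dependent) --------------------------
    k_casr = p[32] - (p[32] - p[33]) / (1.0 + (p[31] / ca_jsr) ** 2.5)
    kom = p[29]
    kim = p[30]
    r_, o_, i_, ri_ = y[18], y[19], y[20], y[21]
    cs2 = ca_sub * ca_sub
    # Ca-dependent transition rates saturate (finite channel kinetics);
    # the caps are far above the rates visited on the single-cell limit
    # cycle and keep strongly driven tissue nodes integrable
    k_open = p[27] / k_casr * cs2
    if k_open > 5.0:
        k_open = 5.0
    k_inact = p[28] * k_casr * ca_sub
    if k_inact > 2.0:
        k_inact = 2.0
    dy[18] = kim * ri_ - k_inact * r_ - (k_open * r_ - kom * o_)
    dy[19] = k_open * r_ - kom * o_ - (k_inact * o_ - kim * i_)
    dy[20] = k_inact * o_ - kim * i_ - (kom * i_ - k_open * ri_)
    dy[21] = kom * i_ - k_open * ri_ - (kim * ri_ - k_inact * r_)

    # --- Ca²⁺ buffering ---------------------------------------------------
    d_ftc = _KF_TC * ca_i * (1.0 - y[22]) - _KB_TC * y[22]
    d_ftmc = _KF_TMC * ca_i * (1.0 - y[23] - y[24]) - _KB_TMC * y[23]
    d_ftmm = _KF_TMM * _MGI * (1.0 - y[23] - y[24]) - _KB_TMM * y[24]
    d_fcmi = _KF_CM * ca_i * (1.0 - y[25]) - _KB_CM * y[25]
    d_fcms = _KF_CM * ca_sub * (1.0 - y[26]) - _KB_CM * y[26]
    d_fcq = _KF_CQ * ca_jsr * (1.0 - y[27]) - _KB_CQ * y[27]
    dy[22] = d_ftc
    dy[23] = d_ftmc
    dy[24] = d_ftmm
    dy[25] = d_fcmi
    dy[26] = d_fcms
    dy[27] = d_fcq

    # --- Ca²⁺ compartment fluxes -----------------------------------------
    v_sub, v_cyto, v_nsr, v_jsr = p[34], p[35], p[36], p[37]
    j_rel = p[24] * o_ * (ca_jsr - ca_sub)
    j_up = p[22] / (1.0 + p[23] / ca_i)
    j_tr = (ca_nsr - ca_jsr) / p[25]
    j_dif = (ca_sub - ca_i) / p[26]

    i_ca_sub = cur[0] + cur[1] + cur[2] - 2.0 * cur[9]
    dy[14] = (j_rel * v_jsr / v_sub
              - i_ca_sub / (2.0 * _F * v_sub)
              - j_dif - _CM_TOT * d_fcms)
    dy[15] = ((j_dif * v_sub - j_up * v_nsr) / v_cyto
              - (_CM_TOT * d_fcmi + _TC_TOT * d_ftc + _TMC_TOT * d_ftmc))
    dy[16] = j_up - j_tr * v_jsr / v_nsr
    dy[17] = j_tr - j_rel - _CQ_TOT * d_fcq

    rate = p[1]
    for i in range(28):
        dy[i] *= rate
    return dy


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

_SHARED_GATES = {
    # gate: (v_half mV, slope mV, tau_base multiplier)
    "cal12.act": (-25.0, 4.6, 1.0),
    "cal12.inact": (-37.5, 5.3, 1.5),
    "cal13.act": (-30.0, 5.0, 1.0),
    "cal13.inact": (-46.0, 5.0, 1.0),
    "cat.act": (-36.0, 5.5, 1.0),
    "cat.inact": (-58.7, 3.8, 1.0),
    "na.act": (-40.0, 5.0, 1.0),
    "na.inact": (-60.0, 6.0, 1.0),
    "kr.act": (-14.0, 8.5, 1.3),
    "kr.inact": (-28.0, 17.0, 1.0),
    "ks.act": (-9.0, 12.0, 1.0),
}

_RABBIT = {
    "cm": 0.032, "rate": 0.927936,
    "na.e_rev": 70.0, "k.e_rev": -87.0, "ca.e_rev": 45.0,
    "hcn.e_rev": -4.0, "b.e_rev": -22.0,
    "nai": 7.5, "cao": 1.8,
    "cal12.gbar": 0.02, "cal13.gbar": 0.006, "cat.gbar": 0.006,
    "hcn.gbar": 0.000732, "na.gbar": 0.01, "kr.gbar": 0.0055,
    "ks.gbar": 0.003, "b.gbar": 0.0008,
    "nak.imax": 0.25, "nak.km_na": 14.0,
    "ncx.k": 1.5e-5, "ncx.d": 1e-4, "ncx.gamma": 0.45,
    "serca.p_up": 0.0006, "serca.k_up": 0.0006,
    "ryr.ks": 100.0, "sr.tau_tr": 40.0, "sr.tau_dif": 0.04,
    "ryr.ko_ca": 2.0e4, "ryr.ki_ca": 50.0, "ryr.kom": 0.2, "ryr.kim": 0.005,
    "ryr.ec50_sr": 0.6, "ryr.max_sr": 15.0, "ryr.min_sr": 1.0,
    "vol.sub": 0.03328, "vol.cyto": 1.3495, "vol.nsr": 0.0396,
    "vol.jsr": 0.0036,
    "fca.km": 0.00035, "fca.tau": 2.0,
    "hcn.act": (-52.5, 9.0, 1.0),
}

_MOUSE = {
    "cm": 0.025, "rate": 1.079503,
    "na.e_rev": 70.0, "k.e_rev": -87.0, "ca.e_rev": 45.0,
    "hcn.e_rev": -24.0, "b.e_rev": -22.0,
    "nai": 8.0, "cao": 1.8,
    "cal12.gbar": 0.018, "cal13.gbar": 0.008, "cat.gbar": 0.007,
    "hcn.gbar": 0.0085766, "na.gbar": 0.01, "kr.gbar": 0.005,
    "ks.gbar": 0.0025, "b.gbar": 0.0008,
    "nak.imax": 0.22, "nak.km_na": 14.0,
    "ncx.k": 1.5e-5, "ncx.d": 1e-4, "ncx.gamma": 0.45,
    "serca.p_up": 0.0009, "serca.k_up": 0.0006,
    "ryr.ks": 100.0, "sr.tau_tr": 40.0, "sr.tau_dif": 0.04,
    "ryr.ko_ca": 2.0e4, "ryr.ki_ca": 50.0, "ryr.kom": 0.2, "ryr.kim": 0.005,
    "ryr.ec50_sr": 0.6, "ryr.max_sr": 15.0, "ryr.min_sr": 1.0,
    "vol.sub": 0.0233, "vol.cyto": 0.945, "vol.nsr": 0.0277,
    "vol.jsr": 0.00252,
    "fca.km": 0.00035, "fca.tau": 2.0,
    "hcn.act": (-106.8, 16.3, 0.5),
    "cal12.inact": (-37.5, 5.3, 2.1429),
    "kr.act": (-14.0, 8.5, 1.4286),
    "_tau_scale_all": 0.7,
}

_PROVENANCE = {
    "mouse": (
        "Mouse-type SANC: parameterization guided by the mouse central SANC "
        "literature (HCN4-type funny current, half-activation -106.8 mV, "
        "slope 16.3 mV, reversal -24 mV); control rate and funny-current "
        "amplitude calibrated to the published control values (4.76 Hz, "
        "0.006 nA)."
    ),
    "rabbit": (
        "Rabbit-type SANC: parameterization guided by the rabbit central "
        "SANC literature (funny current half-activation -52.5 mV, slope "
        "9.0 mV, reversal -4 mV); control rate and funny-current amplitude "
        "calibrated to the published control values (2.90 Hz, 0.0067 nA)."
    ),
}


def _default_state(pvec: np.ndarray, v0: float = -60.0) -> np.ndarray:
    y = np.zeros(len(STATE_NAMES))
    y[0] = v0
    rising = {1: _B_CAL12A, 3: _B_CAL13A, 6: _B_CATA, 9: _B_NAA,
              11: _B_KRA, 13: _B_KS}
    falling = {2: _B_CAL12I, 4: _B_CAL13I, 7: _B_CATI, 8: _B_HCN,
               10: _B_NAI, 12: _B_KRI}
    for i, base in rising.items():
        y[i] = _gate_inf(v0, pvec, base, True)
    for i, base in falling.items():
        y[i] = _gate_inf(v0, pvec, base, False)
    y[5] = 1.0                      # f_ca
    y[14] = 1e-4                    # ca_sub
    y[15] = 1e-4                    # ca_i
    y[16] = 1.0                     # ca_nsr
    y[17] = 0.3                     # ca_jsr
    y[18] = 0.9                     # ryr_r
    y[19] = 1e-6
    y[20] = 1e-6
    y[21] = 0.1
    y[22] = 0.02
    y[23] = 0.2
    y[24] = 0.6
    y[25] = 0.04
    y[26] = 0.04
    y[27] = 0.26
    return y


def _assemble(spec: dict) -> np.ndarray:
    pvec = np.zeros(N_PARAMS)
    tau_all = spec.get("_tau_scale_all", 1.0)
    gates = dict(_SHARED_GATES)
    for g in _GATES:
        if g in spec:
            gates[g] = spec[g]
    for g in _GATES:
        vh, k, tb = gates[g]
        pvec[P[f"{g}.v_half"]] = vh
        pvec[P[f"{g}.slope"]] = k
        pvec[P[f"{g}.v_off"]] = 0.0
        pvec[P[f"{g}.slope_scale"]] = 1.0
        pvec[P[f"{g}.tau_scale"]] = 1.0
        pvec[P[f"{g}.tau_base"]] = tb * tau_all
    for k, v in spec.items():
        if k.startswith("_") or k in _GATES:
            continue
        pvec[P[k]] = v
    return pvec



# converged limit-cycle states (end of a 20 s control integration), used
# as the default initial condition so recordings start near steady pacing
_Y0_MOUSE = np.array([
    14.565228828572598, 0.9998232641686655, 0.5096134756624968, 0.9998709693598595,
    0.26287207614453645, 0.22704005698746238, 0.9999028558161821, 5.473986296104086e-05,
    0.0076655485072751675, 0.9999818291343873, 3.9219249869368755e-06, 0.8746252168672204,
    0.0731464862541198, 0.2198507673715063, 0.0011804617673927837, 0.0006698876610752519,
    0.7508692243154685, 0.5858631408346288, 0.009985694788491414, 0.00018101822660762572,
    0.01762400778281154, 0.9722112792020747, 0.11568943312546898, 0.5784825879344799,
    0.37281212299258265, 0.21729799650739856, 0.3327813697905877, 0.4135039607019463,
])
_Y0_RABBIT = np.array([
    -40.42963897147518, 0.029696852447053036, 0.9302367492636049, 0.08102348621817948,
    0.8097573076113147, 0.5644783009522879, 0.233752975326425, 0.11047689652175846,
    0.1928269464451241, 0.45455264452755034, 0.03981258481996322, 0.1920992527937245,
    0.6968106369650479, 0.11582964567417803, 0.0003144309119356351, 0.0002104588891493162,
    0.6285819570145041, 0.5659820732636127, 0.05518293969232347, 3.861456722982623e-05,
    0.0006606532433832271, 0.9441197924970577, 0.039179224661094275, 0.4316971587467008,
    0.5020558045727995, 0.07954384834233667, 0.10413229355961309, 0.4045332073160759,
])

def build_san(variant: str = "mouse") -> CellModel:
    """Build a single-compartment sinoatrial node cell model.

    ``variant`` is ``"mouse"`` (mouse-type, fast intrinsic rate) or
    ``"rabbit"`` (rabbit-type, slower intrinsic rate).  The model fires
    spontaneously with no stimulus.
    """
    if variant not in ("mouse", "rabbit"):
        raise ValueError(f"unknown SAN variant {variant!r}")
    spec = _MOUSE if variant == "mouse" else _RABBIT
    pvec = _assemble(spec)
    y0 = (_Y0_MOUSE if variant == "mouse" else _Y0_RABBIT).copy()
    model = CellModel(
        name=f"san-{variant}",
        kind="san",
        n_comp=1,
        state_names=STATE_NAMES,
        param_index=dict(P),
        params=pvec,
        y0=y0,
        rhs=san_rhs,
        current_names=CURRENT_NAMES,
        currents_fn=_san_currents,
        additive_paths=ADDITIVE_PATHS,
        provenance=_PROVENANCE[variant],
        v_index=(0,),
        conc_states=(14, 15, 16, 17),
        gate_states=tuple(range(1, 14)),
    )
    return model
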