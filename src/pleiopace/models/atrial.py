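"""Minimal atrial myocyte plug-in for the tissue module.

A three-variable excitable membrane model of the Fenton–Karma family
(fast inward, slow outward, slow inward currents), rescaled to millivolts
(resting ≈ −85 mV, peak ≈ +15 mV) with time constants set for an
atrial-like action-potential duration of roughly 150–200 ms.  It does not
pace spontaneously; it fires when depolarized past threshold and is cheap
enough to fill a 2-D monodomain grid.

The tissue acceptance checks are qualitative (1:1 conduction, exit block,
silencing), so any published atrial AP model could be substituted; this
three-current formulation is the bundled default.
"""

from __future__ import annotations

import math

from .._jit import njit

# membrane mapping V (mV) <-> u (dimensionless)
V_REST = -85.0
V_SPAN = 100.0

# gating/current parameters (modified Beeler–Reuter-style set, atrial APD)
U_C = 0.10
U_V = 0.04
TAU_V1M = 19.6
TAU_V2M = 1250.0
TAU_VP = 3.33
TAU_WM = 41.0
TAU_WP = 870.0
TAU_D = 0.15
TAU_O = 12.5
TAU_R = 25.0
TAU_SI = 22.0
K_SI = 10.0
U_CSI = 0.85


@njit(cache=True)
def atrial_rates(v_mv, gate_v, gate_w):
    """Return (dV/dt mV/ms, dv/dt, dw/dt) for one atrial node."""
    u = (v_mv - V_REST) / V_SPAN
    p = 1.0 if u >= U_C else 0.0
    q = 1.0 if u >= U_V else 0.0
    tau_vm = q * TAU_V1M + (1.0 - q) * TAU_V2M
    dv = (1.0 - p) * (1.0 - gate_v) / tau_vm - p * gate_v / TAU_VP
    dw = (1.0 - p) * (1.0 - gate_w) / TAU_WM - p * gate_w / TAU_WP
    j_fi = -gate_v * p * (1.0 - u) * (u - U_C) / TAU_D
    j_so = u * (1.0 - p) / TAU_O + p / TAU_R
    j_si = -gate_w * (1.0 + math.tanh(K_SI * (u - U_CSI))) / (2.0 * TAU_SI)
    du = -(j_fi + j_so + j_si)
    return du * V_SPAN, dv, dw
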