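"""Courtemanche-Ramirez-Nattel human atrial ionic model.

State vector (21): V (mV), 15 gates, 5 concentrations (mM):
``[V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca, u, v, w, Nai, Ki, Cai, Caup, Carel]``

Total membrane current is the sum of 12 currents (INa, IK1, Ito, IKur,
IKr, IKs, ICaL, IpCa, INaK, INaCa, IbNa, IbCa), expressed per capacitance
(pA/pF) with Cm = 100 pF. Integration uses Rush-Larsen for gates and
forward Euler for V and concentrations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "N_STATE",
    "GATE_INDICES",
    "crn_initial_state",
    "crn_rhs",
    "step_states",
    "pace_to_steady_state",
]

N_STATE = 21
GATE_INDICES = tuple(range(1, 16))

# physical constants
_R, _T, _F = 8.3143, 310.0, 96.4867
_CM = 100.0  # pF
_VI, _VUP, _VREL = 13668.0, 1109.52, 96.48  # um^3
_KO, _NAO, _CAO = 5.4, 140.0, 1.8
_GNA, _GK1, _GTO = 7.8, 0.09, 0.1652
_GKR, _GKS, _GCAL = 0.029411765, 0.12941176, 0.12375
_GBNA, _GBCA = 0.0006744375, 0.001131
_INAK_MAX, _INACA_MAX, _IPCA_MAX, _IUP_MAX = 0.59933874, 1600.0, 0.275, 0.005
_KQ10 = 3.0
_GAMMA = 0.35
_KM_NAI, _KM_KO = 10.0, 1.5
_KM_NA, _KM_CA, _KSAT = 87.5, 1.38, 0.1
_CAUP_MAX, _KREL, _KUP = 15.0, 30.0, 0.00092
_CMDN_MAX, _TRPN_MAX, _CSQN_MAX = 0.05, 0.07, 10.0
_KM_CMDN, _KM_TRPN, _KM_CSQN = 0.00238, 0.0005, 0.8
_TAU_TR, _TAU_FCA, _TAU_U = 180.0, 2.0, 8.0


def crn_initial_state() -> np.ndarray:
    """Published resting state (quiescent model, V ~ -81.2 mV)."""
    return np.array(
        [
            -81.18,      # V
            2.908e-3,    # m
            9.649e-1,    # h
            9.775e-1,    # j
            3.043e-2,    # oa
            9.992e-1,    # oi
            4.966e-3,    # ua
            9.986e-1,    # ui
            3.296e-5,    # xr
            1.869e-2,    # xs
            1.367e-4,    # d
            9.996e-1,    # f
            7.755e-1,    # fca
            0.0,         # u
            1.0,         # v
            9.992e-1,    # w
            1.117e1,     # Nai
            1.390e2,     # Ki
            1.013e-4,    # Cai
            1.488,       # Caup
            1.488,       # Carel
        ]
    )


@njit(cache=True)
def _derivs(y, dy, ginf, gtau):  # noqa: C901 - single translation of the model
    """Fill dy (all 21), gate inf/tau arrays (index-aligned with y); return
    total ionic current in pA/pF."""
    V = y[0]
    m, h, j = y[1], y[2], y[3]
    oa, oi, ua, ui = y[4], y[5], y[6], y[7]
    xr, xs, d, f, fca = y[8], y[9], y[10], y[11], y[12]
    uu, vv, ww = y[13], y[14], y[15]
    Nai, Ki, Cai, Caup, Carel = y[16], y[17], y[18], y[19], y[20]

    rtf = _R * _T / _F
    ENa = rtf * np.log(_NAO / Nai)
    EK = rtf * np.log(_KO / Ki)
    ECa = 0.5 * rtf * np.log(_CAO / Cai)

    INa = _CM * _GNA * m * m * m * h * j * (V - ENa)
    IK1 = _CM * _GK1 * (V - EK) / (1.0 + np.exp(0.07 * (V + 80.0)))
    Ito = _CM * _GTO * oa * oa * oa * oi * (V - EK)
    gkur = 0.005 + 0.05 / (1.0 + np.exp(-(V - 15.0) / 13.0))
    IKur = _CM * gkur * ua * ua * ua * ui * (V - EK)
    IKr = _CM * _GKR * xr * (V - EK) / (1.0 + np.exp((V + 15.0) / 22.4))
    IKs = _CM * _GKS * xs * xs * (V - EK)
    ICaL = _CM * _GCAL * d * f * fca * (V - 65.0)
    sigma = (np.exp(_NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (
        1.0
        + 0.1245 * np.exp(-0.1 * V / rtf)
        + 0.0365 * sigma * np.exp(-V / rtf)
    )
    INaK = (
        _CM
        * _INAK_MAX
        * fnak
        / (1.0 + (_KM_NAI / Nai) ** 1.5)
        * _KO
        / (_KO + _KM_KO)
    )
    expg = np.exp(_GAMMA * V / rtf)
    expg1 = np.exp((_GAMMA - 1.0) * V / rtf)
    INaCa = (
        _CM
        * _INACA_MAX
        * (expg * Nai**3 * _CAO - expg1 * _NAO**3 * Cai)
        / (
            (_KM_NA**3 + _NAO**3)
            * (_KM_CA + _CAO)
            * (1.0 + _KSAT * expg1)
        )
    )
    IbNa = _CM * _GBNA * (V - ENa)
    IbCa = _CM * _GBCA * (V - ECa)
    IpCa = _CM * _IPCA_MAX * Cai / (0.0005 + Cai)

    Iion = (
        INa + IK1 + Ito + IKur + IKr + IKs + IbNa + IbCa + INaK + IpCa + INaCa + ICaL
    )

    # --- gate rates -------------------------------------------------------
    # m
    dv = V + 47.13
    if abs(dv) < 1e-10:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - np.exp(-0.1 * dv))
    bm = 0.08 * np.exp(-V / 11.0)
    gtau[1] = 1.0 / (am + bm)
    ginf[1] = am * gtau[1]
    # h, j
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + np.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * np.exp(-2.535e-7 * V) / (1.0 + np.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * np.exp(-(V + 80.0) / 6.8)
        bh = 3.56 * np.exp(0.079 * V) + 3.1e5 * np.exp(0.35 * V)
        aj = (
            (-1.2714e5 * np.exp(0.2444 * V) - 3.474e-5 * np.exp(-0.04391 * V))
            * (V + 37.78)
            / (1.0 + np.exp(0.311 * (V + 79.23)))
        )
        bj = 0.1212 * np.exp(-0.01052 * V) / (1.0 + np.exp(-0.1378 * (V + 40.14)))
    gtau[2] = 1.0 / (ah + bh)
    ginf[2] = ah * gtau[2]
    gtau[3] = 1.0 / (aj + bj)
    ginf[3] = aj * gtau[3]
    # oa, oi
    aoa = 0.65 / (np.exp(-(V + 10.0) / 8.5) + np.exp(-(V - 30.0) / 59.0))
    boa = 0.65 / (2.5 + np.exp((V + 82.0) / 17.0))
    gtau[4] = 1.0 / ((aoa + boa) * _KQ10)
    ginf[4] = 1.0 / (1.0 + np.exp(-(V + 20.47) / 17.54))
    aoi = 1.0 / (18.53 + np.exp((V + 113.7) / 10.95))
    boi = 1.0 / (35.56 + np.exp(-(V + 1.26) / 7.44))
    gtau[5] = 1.0 / ((aoi + boi) * _KQ10)
    ginf[5] = 1.0 / (1.0 + np.exp((V + 43.1) / 5.3))
    # ua, ui
    gtau[6] = 1.0 / ((aoa + boa) * _KQ10)  # same alpha/beta family as oa
    ginf[6] = 1.0 / (1.0 + np.exp(-(V + 30.3) / 9.6))
    aui = 1.0 / (21.0 + np.exp(-(V - 185.0) / 28.0))
    bui = np.exp((V - 158.0) / 16.0)
    gtau[7] = 1.0 / ((aui + bui) * _KQ10)
    ginf[7] = 1.0 / (1.0 + np.exp((V - 99.45) / 27.48))
    # xr
    dv = V + 14.1
    if abs(dv) < 1e-10:
        axr = 0.0015
    else:
        axr = 0.0003 * dv / (1.0 - np.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-10:
        bxr = 3.7836118e-4
    else:
        bxr = 7.3898e-5 * dv / (np.exp(dv / 5.1237) - 1.0)
    gtau[8] = 1.0 / (axr + bxr)
    ginf[8] = 1.0 / (1.0 + np.exp(-(V + 14.1) / 6.5))
    # xs
    dv = V - 19.9
    if abs(dv) < 1e-10:
        axs = 6.8e-4
        bxs = 3.15e-4
    else:
        axs = 4e-5 * dv / (1.0 - np.exp(-dv / 17.0))
        bxs = 3.5e-5 * dv / (np.exp(dv / 9.0) - 1.0)
    gtau[9] = 0.5 / (axs + bxs)
    ginf[9] = 1.0 / np.sqrt(1.0 + np.exp(-(V - 19.9) / 12.7))
    # d
    dv = V + 10.0
    if abs(dv) < 1e-10:
        gtau[10] = 1.0 / (0.035 * 2.0 * 6.24)  # L'Hopital limit at V = -10
    else:
        e = np.exp(-dv / 6.24)
        gtau[10] = (1.0 - e) / (0.035 * dv * (1.0 + e))
    ginf[10] = 1.0 / (1.0 + np.exp(-(V + 10.0) / 8.0))
    # f
    gtau[11] = 9.0 / (0.0197 * np.exp(-(0.0337 * (V + 10.0)) ** 2) + 0.02)
    ginf[11] = 1.0 / (1.0 + np.exp((V + 28.0) / 6.9))
    # fca
    gtau[12] = _TAU_FCA
    ginf[12] = 1.0 / (1.0 + Cai / 0.00035)
    # SR release gating (u, v, w) driven by Fn
    Irel = _KREL * uu * uu * vv * ww * (Carel - Cai)
    Fn = 1e-12 * _VREL * Irel - 5e-13 / _F * (0.5 * ICaL - 0.2 * INaCa)
    gtau[13] = _TAU_U
    ginf[13] = 1.0 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    gtau[14] = 1.91 + 2.09 / (1.0 + np.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    ginf[14] = 1.0 - 1.0 / (1.0 + np.exp(-(Fn - 6.835e-14) / 13.67e-16))
    dv = V - 7.9
    if abs(dv) < 1e-10:
        gtau[15] = 6.0 / 6.5
    else:
        e = np.exp(-dv / 5.0)
        gtau[15] = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dv)
    ginf[15] = 1.0 - 1.0 / (1.0 + np.exp(-(V - 40.0) / 17.0))

    # --- concentrations ---------------------------------------------------
    Iup = _IUP_MAX / (1.0 + _KUP / Cai)
    Iupleak = _IUP_MAX * Caup / _CAUP_MAX
    Itr = (Caup - Carel) / _TAU_TR

    dy[0] = -Iion / _CM
    for k in range(1, 16):
        dy[k] = (ginf[k] - y[k]) / gtau[k]
    dy[16] = (-3.0 * INaK - 3.0 * INaCa - IbNa - INa) / (_F * _VI)
    dy[17] = (2.0 * INaK - IK1 - Ito - IKur - IKr - IKs) / (_F * _VI)
    b1 = (2.0 * INaCa - IpCa - ICaL - IbCa) / (2.0 * _F * _VI) + (
        _VUP * (Iupleak - Iup) + Irel * _VREL
    ) / _VI
    b2 = (
        1.0
        + _TRPN_MAX * _KM_TRPN / (Cai + _KM_TRPN) ** 2
        + _CMDN_MAX * _KM_CMDN / (Cai + _KM_CMDN) ** 2
    )
    dy[18] = b1 / b2
    dy[19] = Iup - Iupleak - Itr * _VREL / _VUP
    dy[20] = (Itr - Irel) / (1.0 + _CSQN_MAX * _KM_CSQN / (Carel + _KM_CSQN) ** 2)
    return Iion / _CM


@njit(cache=True)
def step_states(Y, dt, istim):
    """One operator-split reaction step for all nodes (in place).

    ``Y``: (n, 21) state array; ``istim``: depolarizing stimulus per node in
    pA/pF. Rush-Larsen for gates, forward Euler for V and concentrations.
    """
    n = Y.shape[0]
    dy = np.empty(N_STATE)
    ginf = np.empty(N_STATE)
    gtau = np.empty(N_STATE)
    for i in range(n):
        y = Y[i]
        _derivs(y, dy, ginf, gtau)
        y[0] += dt * (dy[0] + istim[i])
        for k in range(1, 16):
            y[k] = ginf[k] + (y[k] - ginf[k]) * np.exp(-dt / gtau[k])
        for k in range(16, N_STATE):
            y[k] += dt * dy[k]


def crn_rhs(state: np.ndarray) -> tuple[float, np.ndarray]:
    """Total ionic current (pA/pF) and full state derivative.

    Raises on non-finite input (integration blow-up guard).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},)")
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite state passed to crn_rhs")
    dy = np.empty(N_STATE)
    ginf = np.empty(N_STATE)
    gtau = np.empty(N_STATE)
    iion = _derivs(y, dy, ginf, gtau)
    return float(iion), dy


@njit(cache=True)
def _pace(Y, n_beats, bcl, dt, stim_amp, stim_dur, last_beat_start):
    steps_per_beat = int(round(bcl / dt))
    stim_steps = int(round(stim_dur / dt))
    istim = np.zeros(1)
    delta = 0.0
    for beat in range(n_beats):
        if beat == n_beats - 1:
            last_beat_start[:] = Y[0]
        for s in range(steps_per_beat):
            istim[0] = stim_amp if s < stim_steps else 0.0
            step_states(Y, dt, istim)
        if beat == n_beats - 1:
            d = 0.0
            for k in range(N_STATE):
                # floor the scale at 0.01 so near-zero gates (range [0, 1])
                # are judged on absolute rather than relative change
                ref = max(abs(last_beat_start[k]), 1e-2)
                d = max(d, abs(Y[0, k] - last_beat_start[k]) / ref)
            delta = d
    return delta


def pace_to_steady_state(
    n_beats: int,
    bcl: float = 1000.0,
    dt: float = 0.01,
    stim_amp: float = 40.0,
    stim_dur: float = 2.0,
    initial: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Pace a single cell; returns (end-diastolic state, convergence metric).

    The metric is the max relative per-variable change across the final
    beat (state at its start vs its end).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    Y = (initial if initial is not None else crn_initial_state()).reshape(1, -1).copy()
    ref = np.empty(N_STATE)
    delta = _pace(Y, n_beats, bcl, dt, stim_amp, stim_dur, ref)
    return Y[0].copy(), float(delta)
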