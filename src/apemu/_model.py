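"""Reduced ventricular cardiomyocyte model with nine scalable current magnitudes.

The membrane model is a Luo–Rudy-1991-style Hodgkin–Huxley formulation extended
with late sodium, transient outward and slow delayed-rectifier currents and
phenomenological Na/Ca-exchanger and Na/K-pump currents, so that exactly nine
current magnitudes (gNa, gNaL, pCa, gto, gKr, gKs, gK1, gNCX, pNaK) can be
scaled relative to baseline.  Gating variables are advanced with the
Rush–Larsen exponential update (analytic solution at frozen voltage); the
membrane potential and intracellular calcium use forward Euler.

For speed, gate steady states and per-step exponential decay factors, together
with all purely voltage-dependent algebraic terms, are pre-tabulated on a fine
voltage grid and linearly interpolated inside the numba-compiled inner loop,
which is therefore free of transcendental calls apart from one logarithm
(calcium reversal potential).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# model constants (baseline magnitudes; the nine scale factors multiply these)
# ---------------------------------------------------------------------------
E_NA = 54.4      # mV
E_K = -77.0      # mV, delayed rectifiers / Ito
E_K1 = -87.2     # mV, inward rectifier
G_NA = 23.0      # mS/cm^2
G_SI = 0.1035    # slow inward (L-type Ca surrogate)
G_KR = 0.3243    # rapid delayed rectifier (x * xi)
G_KS = 0.06      # slow delayed rectifier (xs^2)
G_K1 = 0.907
G_KP = 0.0183    # fixed plateau K current
G_B = 0.03921    # fixed background current
E_B = -59.87
G_NAL = 0.012    # late sodium
G_TO = 0.12      # transient outward
K_NCX = 5.0e-5   # Na/Ca exchange magnitude
CAI_NCX_SAT = 3.6e-3  # mM, Cai saturation of the exchanger
I_NAK_BAR = 1.0  # Na/K pump magnitude (uA/cm^2 at saturation)
RTF = 26.7       # mV

N_GATES = 10     # m h j d f x xs a i hL
N_STATES = 12    # V, 10 gates, Cai

# voltage grid for the lookup tables
V_MIN, V_MAX, DV = -120.0, 80.0, 0.02
N_TAB = int(round((V_MAX - V_MIN) / DV)) + 1

STATE_NAMES = ("V", "m", "h", "j", "d", "f", "x", "xs", "a", "i", "hL", "Cai")


def _safe_exp(z):
    return np.exp(np.clip(z, -500.0, 500.0))


def gate_rates(v: np.ndarray):
    """alpha/beta (1/ms) for the ten gates on a voltage array.

    Returns (alpha, beta), each of shape (N_GATES, len(v)).  For gates
    formulated directly as (inf, tau) the pair (inf/tau, (1-inf)/tau) is
    returned, which is equivalent.
    """
    v = np.asarray(v, dtype=np.float64)
    a = np.empty((N_GATES, v.size))
    b = np.empty((N_GATES, v.size))

    # m -- fast Na activation
    dv = v + 47.13
    am = np.where(np.abs(dv) < 1e-6, 3.2, 0.32 * dv / (1.0 - _safe_exp(-0.1 * dv)))
    a[0] = am
    b[0] = 0.08 * _safe_exp(-v / 11.0)

    # h -- fast Na inactivation
    lo = v < -40.0
    a[1] = np.where(lo, 0.135 * _safe_exp(-(80.0 + v) / 6.8), 0.0)
    b[1] = np.where(
        lo,
        3.56 * _safe_exp(0.079 * v) + 3.1e5 * _safe_exp(0.35 * v),
        1.0 / (0.13 * (1.0 + _safe_exp(-(v + 10.66) / 11.1))),
    )

    # j -- slow Na inactivation
    aj_lo = (
        (-1.2714e5 * _safe_exp(0.2444 * v) - 3.474e-5 * _safe_exp(-0.04391 * v))
        * (v + 37.78)
        / (1.0 + _safe_exp(0.311 * (v + 79.23)))
    )
    a[2] = np.where(lo, aj_lo, 0.0)
    bj_lo = 0.1212 * _safe_exp(-0.01052 * v) / (1.0 + _safe_exp(-0.1378 * (v + 40.14)))
    bj_hi = 0.3 * _safe_exp(-2.535e-7 * v) / (1.0 + _safe_exp(-0.1 * (v + 32.0)))
    b[2] = np.where(lo, bj_lo, bj_hi)

    # d -- Ca activation
    a[3] = 0.095 * _safe_exp(-0.01 * (v - 5.0)) / (1.0 + _safe_exp(-0.072 * (v - 5.0)))
    b[3] = 0.07 * _safe_exp(-0.017 * (v + 44.0)) / (1.0 + _safe_exp(0.05 * (v + 44.0)))

    # f -- Ca inactivation (slow recovery supports reactivation during phase 2/3)
    a[4] = 0.012 * _safe_exp(-0.008 * (v + 28.0)) / (1.0 + _safe_exp(0.15 * (v + 28.0)))
    b[4] = 0.0065 * _safe_exp(-0.02 * (v + 30.0)) / (1.0 + _safe_exp(-0.2 * (v + 30.0)))

    # x -- rapid delayed rectifier activation
    a[5] = 0.0005 * _safe_exp(0.083 * (v + 50.0)) / (1.0 + _safe_exp(0.057 * (v + 50.0)))
    b[5] = 0.0013 * _safe_exp(-0.06 * (v + 20.0)) / (1.0 + _safe_exp(-0.04 * (v + 20.0)))

    # xs -- slow delayed rectifier activation (inf/tau form)
    xs_inf = 1.0 / (1.0 + _safe_exp(-(v + 11.0) / 8.932))
    tau_xs = 400.0 + 500.0 * _safe_exp(-((v + 30.0) / 40.0) ** 2)
    a[6] = xs_inf / tau_xs
    b[6] = (1.0 - xs_inf) / tau_xs

    # a -- transient outward activation (fast)
    a_inf = 1.0 / (1.0 + _safe_exp(-(v - 12.0) / 13.0))
    tau_a = 1.5
    a[7] = a_inf / tau_a
    b[7] = (1.0 - a_inf) / tau_a

    # i -- transient outward inactivation
    i_inf = 1.0 / (1.0 + _safe_exp((v + 43.94) / 5.711))
    tau_i = 6.0 + 25.0 / (1.0 + _safe_exp((v + 30.0) / 10.0))
    a[8] = i_inf / tau_i
    b[8] = (1.0 - i_inf) / tau_i

    # hL -- late Na inactivation (slow)
    hl_inf = 1.0 / (1.0 + _safe_exp((v + 87.61) / 7.488))
    tau_hl = 200.0
    a[9] = hl_inf / tau_hl
    b[9] = (1.0 - hl_inf) / tau_hl

    return a, b


def _misc_tables(v: np.ndarray) -> np.ndarray:
    """Purely voltage-dependent algebraic terms, shape (7, len(v)).

    rows: xi (Kr rectification), K1inf, Kp, fNaK, exp(0.35 V/RTF),
          exp(-0.65 V/RTF), mL_inf (instantaneous late-Na activation).
    """
    out = np.empty((7, v.size))
    dv77 = v + 77.0
    safe_dv77 = np.where(np.abs(dv77) < 1e-6, 1.0, dv77)
    xi = np.where(
        np.abs(dv77) < 1e-6,
        2.837 * 0.04 / _safe_exp(0.04 * (v + 35.0)),
        2.837 * (_safe_exp(0.04 * dv77) - 1.0) / (safe_dv77 * _safe_exp(0.04 * (v + 35.0))),
    )
    out[0] = np.where(v > -100.0, xi, 1.0)

    ak1 = 1.02 / (1.0 + _safe_exp(0.2385 * (v - E_K1 - 59.215)))
    bk1 = (
        0.49124 * _safe_exp(0.08032 * (v - E_K1 + 5.476))
        + _safe_exp(0.06175 * (v - E_K1 - 594.31))
    ) / (1.0 + _safe_exp(-0.5143 * (v - E_K1 + 4.753)))
    out[1] = ak1 / (ak1 + bk1)

    out[2] = 1.0 / (1.0 + _safe_exp((7.488 - v) / 5.98))

    sigma = (np.exp(140.0 / 67.3) - 1.0) / 7.0
    out[3] = 1.0 / (1.0 + 0.1245 * _safe_exp(-0.1 * v / RTF) + 0.0365 * sigma * _safe_exp(-v / RTF))

    out[4] = _safe_exp(0.35 * v / RTF)
    out[5] = _safe_exp(-0.65 * v / RTF)

    out[6] = 1.0 / (1.0 + _safe_exp(-(v + 42.85) / 5.264))
    return out


_V_GRID = np.linspace(V_MIN, V_MAX, N_TAB)
_ALPHA, _BETA = gate_rates(_V_GRID)
_MISC = _misc_tables(_V_GRID)
_GATE_INF = _ALPHA / (_ALPHA + _BETA)
_RATE_SUM = _ALPHA + _BETA


def build_tables(dt: float):
    """(gate_inf, decay, misc) lookup tables for solver step dt (ms)."""
    decay = np.exp(-dt * _RATE_SUM)
    return _GATE_INF, decay, _MISC


# fixed extracellular/intracellular concentrations for the NCX term
_NCX_F1 = 1000.0 * 1.8          # Nai^3 * Cao / 1e3 scale folded into K_NCX
_NCX_F2 = 2.744e6               # Nao^3


@njit(cache=True, fastmath=True)
def integrate(state, g, dt, n_steps, stim_amp, stim_steps, sample_every,
              gate_inf, decay, misc, vm_out):
    """Advance the model n_steps of size dt, recording V every sample_every steps.

    state : (12,) float64, modified in place being returned
    g     : (9,)  scale factors (gNa,gNaL,pCa,gto,gKr,gKs,gK1,gNCX,pNaK)
    vm_out: output buffer of length n_steps//sample_every + 1

    Returns t_fail (ms): negative on success, else the time where the state
    left the valid voltage bracket or became non-finite.
    """
    inv_dv = 1.0 / DV
    k_out = 0
    for step in range(n_steps):
        v = state[0]
        if not (V_MIN < v < V_MAX) or v != v:
            return step * dt
        if step % sample_every == 0:
            vm_out[k_out] = v
            k_out += 1
        # table lookup position
        pos = (v - V_MIN) * inv_dv
        idx = int(pos)
        if idx >= N_TAB - 1:
            idx = N_TAB - 2
        w = pos - idx

        # Rush-Larsen gate updates
        for gidx in range(10):
            inf = gate_inf[gidx, idx] * (1.0 - w) + gate_inf[gidx, idx + 1] * w
            dec = decay[gidx, idx] * (1.0 - w) + decay[gidx, idx + 1] * w
            state[1 + gidx] = inf + (state[1 + gidx] - inf) * dec

        xi = misc[0, idx] * (1.0 - w) + misc[0, idx + 1] * w
        k1inf = misc[1, idx] * (1.0 - w) + misc[1, idx + 1] * w
        kp = misc[2, idx] * (1.0 - w) + misc[2, idx + 1] * w
        fnak = misc[3, idx] * (1.0 - w) + misc[3, idx + 1] * w
        e1 = misc[4, idx] * (1.0 - w) + misc[4, idx + 1] * w
        e2 = misc[5, idx] * (1.0 - w) + misc[5, idx + 1] * w
        ml = misc[6, idx] * (1.0 - w) + misc[6, idx + 1] * w

        m = state[1]; h = state[2]; j = state[3]; d = state[4]; f = state[5]
        x = state[6]; xs = state[7]; ato = state[8]; ito_i = state[9]
        hl = state[10]; cai = state[11]
        if cai < 1e-7:
            cai = 1e-7
            state[11] = cai

        e_si = 7.7 - 13.0287 * np.log(cai)

        i_na = g[0] * G_NA * m * m * m * h * j * (v - E_NA)
        i_nal = g[1] * G_NAL * ml * ml * ml * hl * (v - E_NA)
        i_si = g[2] * G_SI * d * f * (v - e_si)
        i_to = g[3] * G_TO * ato * ito_i * (v - E_K)
        i_kr = g[4] * G_KR * x * xi * (v - E_K)
        i_ks = g[5] * G_KS * xs * xs * (v - E_K)
        i_k1 = g[6] * G_K1 * k1inf * (v - E_K1)
        i_ncx = g[7] * K_NCX * (e1 * _NCX_F1 - e2 * _NCX_F2 * cai) / (1.0 + cai / CAI_NCX_SAT)
        i_nak = g[8] * I_NAK_BAR * fnak
        i_kp = G_KP * kp * (v - E_K1)
        i_b = G_B * (v - E_B)

        i_ion = (i_na + i_nal + i_si + i_to + i_kr + i_ks + i_k1 + i_ncx
                 + i_nak + i_kp + i_b)
        i_stim = stim_amp if step < stim_steps else 0.0

        state[0] = v + dt * (-(i_ion + i_stim))
        state[11] = cai + dt * (-1.0e-4 * i_si + 0.07 * (1.0e-4 - cai))

    v = state[0]
    if not (V_MIN < v < V_MAX) or v != v:
        return n_steps * dt
    if k_out < vm_out.shape[0]:
        vm_out[k_out] = v
    return -1.0


# resting initial state (baseline limit-cycle start refined during calibration;
# see apemu.simulator.DEFAULT_INITIAL_STATE for the shipped values)
RAW_INITIAL_STATE = np.array(
    [-84.5, 0.0017, 0.983, 0.995, 0.003, 0.999, 0.0057, 0.05, 0.0, 1.0, 0.3, 1.0e-4]
)
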