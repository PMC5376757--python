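"""Human ventricular epicardial action-potential model (ten Tusscher &
Panfilov 2006 formulation), with an optional GHK background K₂P current.

The 19-state single-cell model is transcribed here in full and integrated
with the scheme customary for this model family: Rush–Larsen exponential
integration for the Hodgkin–Huxley gates and forward Euler for the membrane
potential, ionic concentrations, and the ryanodine-receptor variable, at a
fixed time step (default 0.01 ms).  The hot loop is compiled with numba.

The background two-pore-domain (K₂P) current added to the membrane equation
is constant-field (GHK) in both K⁺ and Na⁺:

    I_K2P = p_k2p · [ Φ_GHK(K⁺) + α · Φ_GHK(Na⁺) ]   (pA/pF)

with α the relative sodium permeability; α = 0 is an ideally selective leak
and α = 0.2 the sodium-leaky TREK-1 I267T phenotype.  The K⁺ and Na⁺ limbs
feed back on the intracellular K⁺ and Na⁺ balances.

This model serves as a stand-in base: the claims assessed with it are
directional (resting-potential depolarization, upstroke slowing), not tied
to a specific ventricular formulation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# physical constants (model units: mV, ms, mM, pA/pF)
R_GAS = 8314.472
TEMP = 310.0
FARADAY = 96485.3415
RTONF = R_GAS * TEMP / FARADAY  # 26.7137 mV

# external solutions
KO = 5.4
NAO = 140.0
CAO = 2.0

# cell geometry / capacitance
CM = 0.185
VC = 0.016404
VSR = 0.001094
VSS = 0.00005468

# maximal conductances (epicardial)
GK1 = 5.405
GKR = 0.153
GKS = 0.392
GNA = 14.838
GBNA = 0.00029
GCAL = 0.0000398
GBCA = 0.000592
GTO = 0.294
GPCA = 0.1238
KPCA = 0.0005
GPK = 0.0146

# Na/K pump and Na/Ca exchanger
PNAK = 2.724
KMK = 1.0
KMNA = 40.0
KNACA = 1000.0
KMNAI = 87.5
KMCA = 1.38
KSAT = 0.1
N_GAMMA = 0.35
PKNA = 0.03

# SR calcium handling
VMAXUP = 0.006375
KUP = 0.00025
VREL = 0.102
K1P = 0.15
K2P = 0.045
K3 = 0.060
K4 = 0.005
EC_SR = 1.5
MAXSR = 2.5
MINSR = 1.0
VLEAK = 0.00036
VXFER = 0.0038

# buffering
BUFC = 0.2
KBUFC = 0.001
BUFSR = 10.0
KBUFSR = 0.3
BUFSS = 0.4
KBUFSS = 0.00025

N_STATES = 19


def initial_state() -> np.ndarray:
    """Published resting initial conditions of the epicardial variant."""
    y = np.empty(N_STATES)
    y[0] = -86.2      # V (mV)
    y[1] = 7.67       # Nai (mM)
    y[2] = 138.3      # Ki (mM)
    y[3] = 0.00007    # Cai (mM)
    y[4] = 1.3        # CaSR (mM)
    y[5] = 0.00007    # CaSS (mM)
    y[6] = 0.0        # m
    y[7] = 0.75       # h
    y[8] = 0.75       # j
    y[9] = 0.0        # xr1
    y[10] = 1.0       # xr2
    y[11] = 0.0       # xs
    y[12] = 0.0       # r
    y[13] = 1.0       # s
    y[14] = 0.0       # d
    y[15] = 1.0       # f
    y[16] = 1.0       # f2
    y[17] = 1.0       # fcass
    y[18] = 1.0       # Rbar (RyR)
    return y


@njit(cache=False)
def k2p_current(v, p_k2p, alpha, ki, nai, ko, nao):
    """GHK background K₂P current (pA/pF); returns (I_K, I_Na).

    Outward positive; the v → 0 singularity is removed analytically
    (flux → p·(c_in − c_out)).
    """
    u = v / RTONF
    if abs(u) < 1e-9:
        fk = ki - ko
        fna = nai - nao
    else:
        e = math.exp(-u)
        fk = u * (ki - ko * e) / (1.0 - e)
        fna = u * (nai - nao * e) / (1.0 - e)
    return p_k2p * fk, p_k2p * alpha * fna


@njit(cache=False)
def _integrate(y, n_steps, dt, stim_amp, stim_dur, cl, p_k2p, alpha,
               rec_stride, v_out):
    """Advance the model n_steps; record V every rec_stride steps.

    The stimulus (stim_amp pA/pF for stim_dur ms) fires at the start of each
    cycle of length cl.  v_out must have length n_steps // rec_stride + 1.
    """
    k_rec = 0
    for i in range(n_steps + 1):
        if i % rec_stride == 0 and k_rec < v_out.shape[0]:
            v_out[k_rec] = y[0]
            k_rec += 1
        if i == n_steps:
            break
        t_in_cycle = (i * dt) % cl
        istim = stim_amp if t_in_cycle < stim_dur else 0.0

        V = y[0]
        Nai = y[1]
        Ki = y[2]
        Cai = y[3]
        CaSR = y[4]
        CaSS = y[5]
        m = y[6]
        h = y[7]
        j = y[8]
        xr1 = y[9]
        xr2 = y[10]
        xs = y[11]
        r = y[12]
        s = y[13]
        d = y[14]
        f = y[15]
        f2 = y[16]
        fcass = y[17]
        Rbar = y[18]

        Ek = RTONF * math.log(KO / Ki)
        Ena = RTONF * math.log(NAO / Nai)
        Eks = RTONF * math.log((KO + PKNA * NAO) / (Ki + PKNA * Nai))
        Eca = 0.5 * RTONF * math.log(CAO / Cai)

        # inward rectifier
        ak1 = 0.1 / (1.0 + math.exp(0.06 * (V - Ek - 200.0)))
        bk1 = (3.0 * math.exp(0.0002 * (V - Ek + 100.0))
               + math.exp(0.1 * (V - Ek - 10.0))) / (
                   1.0 + math.exp(-0.5 * (V - Ek)))
        xk1 = ak1 / (ak1 + bk1)
        IK1 = GK1 * math.sqrt(KO / 5.4) * xk1 * (V - Ek)

        IKr = GKR * math.sqrt(KO / 5.4) * xr1 * xr2 * (V - Ek)
        IKs = GKS * xs * xs * (V - Eks)
        INa = GNA * m * m * m * h * j * (V - Ena)
        IbNa = GBNA * (V - Ena)

        # L-type Ca current (GHK-like driving term)
        zf = 2.0 * (V - 15.0) * FARADAY / (R_GAS * TEMP)
        if abs(zf) < 1e-7:
            expzf = 1.0 + zf
        else:
            expzf = math.exp(zf)
        ICaL = (GCAL * d * f * f2 * fcass * 4.0 * (V - 15.0)
                * (FARADAY * FARADAY / (R_GAS * TEMP))
                * (0.25 * expzf * CaSS - CAO) / (expzf - 1.0)) if abs(zf) >= 1e-7 \
            else (GCAL * d * f * f2 * fcass * 2.0 * FARADAY
                  * (0.25 * CaSS - CAO))

        vfrt = V * FARADAY / (R_GAS * TEMP)
        INaCa = (KNACA
                 * (math.exp(N_GAMMA * vfrt) * Nai ** 3 * CAO
                    - math.exp((N_GAMMA - 1.0) * vfrt) * NAO ** 3 * Cai * 2.5)
                 / ((KMNAI ** 3 + NAO ** 3) * (KMCA + CAO)
                    * (1.0 + KSAT * math.exp((N_GAMMA - 1.0) * vfrt))))
        INaK = (PNAK * KO * Nai
                / ((KO + KMK) * (Nai + KMNA)
                   * (1.0 + 0.1245 * math.exp(-0.1 * vfrt)
                      + 0.0353 * math.exp(-vfrt))))
        IpCa = GPCA * Cai / (KPCA + Cai)
        IpK = GPK * (V - Ek) / (1.0 + math.exp((25.0 - V) / 5.98))
        IbCa = GBCA * (V - Eca)
        Ito = GTO * r * s * (V - Ek)

        IK2P_K, IK2P_Na = k2p_current(V, p_k2p, alpha, Ki, Nai, KO, NAO)

        Itot = (IK1 + Ito + IKr + IKs + ICaL + INaK + INa + IbNa + INaCa
                + IbCa + IpK + IpCa + IK2P_K + IK2P_Na + istim)

        # SR calcium fluxes
        kcasr = MAXSR - (MAXSR - MINSR) / (1.0 + (EC_SR / CaSR) ** 2)
        k1 = K1P / kcasr
        k2 = K2P * kcasr
        dRbar = K4 * (1.0 - Rbar) - k2 * CaSS * Rbar
        O = k1 * CaSS * CaSS * Rbar / (K3 + k1 * CaSS * CaSS)
        Irel = VREL * O * (CaSR - CaSS)
        Ileak = VLEAK * (CaSR - Cai)
        Iup = VMAXUP / (1.0 + (KUP / Cai) ** 2)
        Ixfer = VXFER * (CaSS - Cai)

        bcai = 1.0 / (1.0 + BUFC * KBUFC / ((Cai + KBUFC) ** 2))
        dCai = bcai * ((Ileak - Iup) * VSR / VC + Ixfer
                       - (IbCa + IpCa - 2.0 * INaCa) * CM
                       / (2.0 * VC * FARADAY))
        bcsr = 1.0 / (1.0 + BUFSR * KBUFSR / ((CaSR + KBUFSR) ** 2))
        dCaSR = bcsr * (Iup - Irel - Ileak)
        bcss = 1.0 / (1.0 + BUFSS * KBUFSS / ((CaSS + KBUFSS) ** 2))
        dCaSS = bcss * (-Ixfer * VC / VSS + Irel * VSR / VSS
                        - ICaL * CM / (2.0 * VSS * FARADAY))

        dNai = -(INa + IbNa + 3.0 * INaK + 3.0 * INaCa + IK2P_Na) * CM / (VC * FARADAY)
        dKi = -(istim + IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK
                + IK2P_K) * CM / (VC * FARADAY)

        # gate steady states and time constants
        m_inf = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
        am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
        bm = (0.1 / (1.0 + math.exp((V + 35.0) / 5.0))
              + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0)))
        tau_m = am * bm

        h_inf = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
        if V >= -40.0:
            ah = 0.0
            bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        else:
            ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
            bh = (2.7 * math.exp(0.079 * V)
                  + 3.1e5 * math.exp(0.3485 * V))
        tau_h = 1.0 / (ah + bh)

        j_inf = h_inf
        if V >= -40.0:
            aj = 0.0
            bj = (0.6 * math.exp(0.057 * V)
                  / (1.0 + math.exp(-0.1 * (V + 32.0))))
        else:
            aj = ((-2.5428e4 * math.exp(0.2444 * V)
                   - 6.948e-6 * math.exp(-0.04391 * V)) * (V + 37.78)
                  / (1.0 + math.exp(0.311 * (V + 79.23))))
            bj = (0.02424 * math.exp(-0.01052 * V)
                  / (1.0 + math.exp(-0.1378 * (V + 40.14))))
        tau_j = 1.0 / (aj + bj)

        xr1_inf = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
        axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
        bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
        tau_xr1 = axr1 * bxr1

        xr2_inf = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
        axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
        bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
        tau_xr2 = axr2 * bxr2

        xs_inf = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
        axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
        bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
        tau_xs = axs * bxs + 80.0

        r_inf = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
        tau_r = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
        s_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
        tau_s = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
                 + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)

        d_inf = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
        ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
        bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
        cd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
        tau_d = ad * bd + cd

        f_inf = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
        tau_f = (1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
                 + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
                 + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0)

        f2_inf = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
        tau_f2 = (562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
                  + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
                  + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0)))

        fcass_inf = 0.6 / (1.0 + (CaSS / 0.05) ** 2) + 0.4
        tau_fcass = 80.0 / (1.0 + (CaSS / 0.05) ** 2) + 2.0

        # forward Euler on V, concentrations, RyR; Rush-Larsen on gates
        y[0] = V - dt * Itot
        y[1] = Nai + dt * dNai
        y[2] = Ki + dt * dKi
        y[3] = Cai + dt * dCai
        y[4] = CaSR + dt * dCaSR
        y[5] = CaSS + dt * dCaSS
        y[6] = m_inf - (m_inf - m) * math.exp(-dt / tau_m)
        y[7] = h_inf - (h_inf - h) * math.exp(-dt / tau_h)
        y[8] = j_inf - (j_inf - j) * math.exp(-dt / tau_j)
        y[9] = xr1_inf - (xr1_inf - xr1) * math.exp(-dt / tau_xr1)
        y[10] = xr2_inf - (xr2_inf - xr2) * math.exp(-dt / tau_xr2)
        y[11] = xs_inf - (xs_inf - xs) * math.exp(-dt / tau_xs)
        y[12] = r_inf - (r_inf - r) * math.exp(-dt / tau_r)
        y[13] = s_inf - (s_inf - s) * math.exp(-dt / tau_s)
        y[14] = d_inf - (d_inf - d) * math.exp(-dt / tau_d)
        y[15] = f_inf - (f_inf - f) * math.exp(-dt / tau_f)
        y[16] = f2_inf - (f2_inf - f2) * math.exp(-dt / tau_f2)
        y[17] = fcass_inf - (fcass_inf - fcass) * math.exp(-dt / tau_fcass)
        y[18] = Rbar + dt * dRbar
    return y


def integrate(
    y: np.ndarray,
    duration_ms: float,
    dt_ms: float,
    stim_amplitude: float,
    stim_duration_ms: float,
    cycle_length_ms: float,
    p_k2p: float = 0.0,
    alpha: float = 0.0,
    record_dt_ms: float = 0.05,
):
    """Pace the model for ``duration_ms``, recording V on a regular grid.

    Returns (time_ms, v_mV, final_state).  The state array is modified in
    place and also returned.
    """
    n_steps = int(round(duration_ms / dt_ms))
    rec_stride = max(1, int(round(record_dt_ms / dt_ms)))
    n_rec = n_steps // rec_stride + 1
    v_out = np.empty(n_rec)
    y = _integrate(
        y, n_steps, dt_ms, stim_amplitude, stim_duration_ms,
        cycle_length_ms, p_k2p, alpha, rec_stride, v_out,
    )
    t_out = np.arange(n_rec) * (rec_stride * dt_ms)
    if not np.all(np.isfinite(v_out)) or abs(y[0]) > 500.0:
        raise RuntimeError(
            f"ventricular AP integration diverged; final state: {y.tolist()}"
        )
    return t_out, v_out, y
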