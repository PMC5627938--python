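"""Compiled numerical kernels shared by the solver, the protocols and the MC reference.

Every piece of model physics (channel rate functions, hazard function, membrane
updates, density transport, synaptic kinetics) is implemented exactly once here
as an ``@njit`` function.  The public modules (:mod:`cbrd_iid.cbrd_core`,
:mod:`cbrd_iid.ion_channels`, ...) are thin wrappers around these kernels, and
the fused network loop :func:`run_network` calls the very same functions, so the
unit-tested operations and the production simulation share one code path.

Parameter vectors
-----------------
Population parameters travel as flat float64 vectors with the index constants
``P_*`` below (one superset layout for both populations; entries that do not
apply to a population are zero).  Shared/protocol scalars use ``S_*`` indices.
Synaptic projections are rows of a ``(6, 4)`` array ordered
``[AMPA_E, NMDA_E, GABA_E, AMPA_I, NMDA_I, GABA_I]`` with columns
``[g_max, tau_rise, tau_decay, tau_s]``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)

# --- population parameter vector layout -------------------------------------
P_C = 0        # membrane capacitance, uF/cm^2
P_GL = 1       # leak conductance, mS/cm^2
P_VREST = 2    # leak reversal, mV
P_VRESET = 3   # post-spike reset voltage, mV
P_DTAP = 4     # spike-window duration, ms
P_VK = 5       # potassium reversal, mV
P_VM = 6       # M-current reversal, mV
P_GAMMA = 7    # dendritic/somatic conductance ratio (E only)
P_ELL = 8      # squared dendritic length ratio (E only)
P_TAUM0 = 9    # resting membrane time constant, ms
P_GDR = 10     # max conductances, mS/cm^2
P_GA = 11
P_GM = 12
P_GAHP = 13
P_GK = 14      # I population delayed rectifier
P_VTHB = 15    # threshold curve: base + amp*exp(-t*/tau)
P_VTHA = 16
P_VTHT = 17
P_SIG0 = 18    # noise amplitude at rest, mV
P_TAUN = 19    # noise correlation time, ms
P_GTOT0 = 20   # resting total conductance, mS/cm^2
P_B = 21       # t* bound, ms
P_AREA = 22    # membrane area, cm^2
NPOP_PARAMS = 23

# --- shared/protocol scalar layout -------------------------------------------
S_DT = 0        # time step, ms
S_VGABA = 1     # GABA-A reversal, mV
S_MG = 2        # [Mg2+], mM
S_GGJ = 3       # gap junction conductance, mS/cm^2
S_OUSIG = 4     # OU current SD, pA (converted to uA/cm^2 at injection)
S_OUTAU = 5     # OU correlation time, ms
S_VHOLD = 6     # virtual clamp holding potential, mV
S_LFPGAIN = 7   # LFP proxy gain
S_DEP_ON = 8    # short-term depression enabled (0/1)
S_FB_ON = 9     # recurrent feedback enabled (0/1)
S_OU_TO_E = 10  # OU drive also injected into E (0/1)
S_TAUGLU = 11   # depression recovery times, ms
S_TAUGABA = 12
S_UGLU = 13     # depression use fractions
S_UGABA = 14
NSHARED = 15

# gate row order for the excitatory population
GE_XDR, GE_YDR, GE_XA, GE_YA, GE_XM, GE_W = 0, 1, 2, 3, 4, 5

# reset constants (boundary conditions at t* = dt_AP)
RESET_XDR = 0.262
RESET_YDR = 0.473
RESET_XA = 0.743
RESET_YA = 0.691
INC_XM = 0.175
INC_W = 0.018
RESET_N = 0.45

# trace channel order written by run_network
TR_TIME, TR_NUE, TR_NUI, TR_UME, TR_UMI = 0, 1, 2, 3, 4
TR_GAMPA_E, TR_GNMDA_E, TR_GGABA_E = 5, 6, 7
TR_GAMPA_I, TR_GNMDA_I, TR_GGABA_I = 8, 9, 10
TR_ICLAMP, TR_LFP, TR_XGLU, TR_XGABA, TR_OU = 11, 12, 13, 14, 15
NCHAN = 16


# ---------------------------------------------------------------------------
# channel rate functions
# ---------------------------------------------------------------------------

@njit(cache=True)
def dr_rates(u):
    """Delayed-rectifier (I_DR) activation/inactivation rates (E population)."""
    a = 0.17 * math.exp((u + 5.0) * 0.090)
    b = 0.17 * math.exp(-(u + 5.0) * 0.022)
    tau_x = 1.0 / (a + b) + 0.8
    x_inf = a / (a + b)
    tau_y = 300.0
    y_inf = 1.0 / (1.0 + math.exp((u + 68.0) * 0.038))
    return tau_x, x_inf, tau_y, y_inf


@njit(cache=True)
def a_rates(u):
    """A-current activation/inactivation rates (E population)."""
    ax = 0.08 * math.exp((u + 41.0) * 0.089)
    bx = 0.08 * math.exp(-(u + 41.0) * 0.016)
    tau_x = 1.0 / (ax + bx) + 1.0
    x_inf = ax / (ax + bx)
    ay = 0.04 * math.exp(-(u + 49.0) * 0.11)
    by = 0.04
    tau_y = 1.0 / (ay + by) + 2.0
    y_inf = ay / (ay + by)
    return tau_x, x_inf, tau_y, y_inf


@njit(cache=True)
def m_rates(u):
    """Slow potassium (I_M) activation rates."""
    a = 0.003 * math.exp((u + 45.0) * 0.135)
    b = 0.003 * math.exp(-(u + 45.0) * 0.090)
    return 1.0 / (a + b) + 8.0, a / (a + b)


@njit(cache=True)
def ahp_rates(u):
    """After-hyperpolarisation (I_AHP) gating rates."""
    tau_w = 2000.0 / (3.3 * math.exp((u + 35.0) / 20.0) + math.exp(-(u + 35.0) / 20.0))
    w_inf = 1.0 / (1.0 + math.exp(-(u + 35.0) / 10.0))
    return tau_w, w_inf


@njit(cache=True)
def kdr_rates(u):
    """Fast-spiking interneuron delayed rectifier (I_K) n-gate rates."""
    tau_n = 0.5 + 2.0 / (1.0 + math.exp(0.045 * (u - 50.0)))
    n_inf = 1.0 / (1.0 + math.exp(-0.045 * (u + 10.0)))
    return tau_n, n_inf


@njit(cache=True)
def nmda_block_scalar(u, mg):
    """Magnesium block factor of the NMDA conductance."""
    return 1.0 / (1.0 + mg / 3.57 * math.exp(-0.062 * u))


# ---------------------------------------------------------------------------
# hazard function
# ---------------------------------------------------------------------------

@njit(cache=True)
def ftilde(t):
    """Drift-term shape function sqrt(2/pi) * exp(-T^2) / (1 + erf(T)).

    For strongly suprathreshold states (T -> -inf) the closed form is the
    ratio of two vanishing quantities; the asymptote sqrt(2)*|T| is used
    below T = -6 where the relative error of the asymptote is < 2%.
    """
    if t < -6.0:
        return SQRT2 * (-t)
    return SQRT_2_OVER_PI * math.exp(-t * t) / math.erfc(-t)


@njit(cache=True)
def threshold_scalar(t_star, base, amp, tau):
    return base + amp * math.exp(-t_star / tau)


@njit(cache=True)
def hazard_scalar(u, dudt, t_star, g_tot, c_m, vth_base, vth_amp, vth_tau,
                  sigma_v, tau_noise, dt_ap, h_max):
    """Instantaneous firing hazard H = A + B for one neuronal state.

    ``A`` is the noise-driven threshold crossing rate (exponential-polynomial
    approximation of the colored-noise first-passage hazard), ``B`` the
    drift-driven crossing rate.  Inside the spike window (t* < dt_AP) the
    voltage is pinned by the boundary conditions and the hazard is zero.
    """
    if t_star < dt_ap:
        return 0.0
    decay = math.exp(-t_star / vth_tau)
    vth = vth_base + vth_amp * decay
    dvth = -(vth_amp / vth_tau) * decay
    denom = SQRT2 * sigma_v
    t_rel = (vth - u) / denom
    if t_rel >= 8.0:
        # far subthreshold: A saturates to zero and exp(-T^2) kills B
        return 0.0
    tau_m = c_m / g_tot
    k = tau_m / tau_noise

    tc = t_rel if t_rel > -3.0 else -3.0
    poly = 0.0061 - 1.12 * tc - 0.257 * tc * tc - 0.072 * tc ** 3 - 0.0117 * tc ** 4
    kfac = 1.0 - math.exp(math.log(1.0 + k) * (-0.71 + 0.0825 * (tc + 3.0)))
    a_term = math.exp(poly) * kfac / tau_m
    if a_term < 0.0:
        a_term = 0.0

    # -dT/dt > 0 only when the state drifts toward threshold
    mdtdt = (dudt - dvth) / denom
    b_term = 2.0 * mdtdt * ftilde(t_rel) if mdtdt > 0.0 else 0.0

    h = a_term + b_term
    if h > h_max:
        h = h_max
    return h


@njit(cache=True)
def hazard_field(h_out, u, u_free, dudt, dudt_free, g_tot, t_star, bin_scales,
                 sigma_v, c_m, vth_base, vth_amp, vth_tau, tau_noise, dt_ap, h_max):
    """Fill the (probe, weight-bin) hazard array.

    Per-bin voltages are the affine map U_x = U_free + (U - U_free) * x and
    likewise for the time derivative.
    """
    n, kbins = h_out.shape
    for i in range(n):
        for kk in range(kbins):
            x = bin_scales[kk]
            ux = u_free[i] + (u[i] - u_free[i]) * x
            dux = dudt_free[i] + (dudt[i] - dudt_free[i]) * x
            h_out[i, kk] = hazard_scalar(ux, dux, t_star[i], g_tot[i], c_m,
                                         vth_base, vth_amp, vth_tau,
                                         sigma_v, tau_noise, dt_ap, h_max)


# ---------------------------------------------------------------------------
# density transport (Lagrangian probes)
# ---------------------------------------------------------------------------

@njit(cache=True)
def density_step(rho, hazard, flux, psi, probe_flux, dt, youngest):
    """Decay probe masses by the hazard sink and accumulate the boundary flux.

    Returns the population firing rate nu = sum_k psi_k sum_i rho_ik H_ik
    (1/ms) evaluated on the pre-decay density.  ``flux`` accumulates the sunk
    mass per weight bin; ``probe_flux`` holds the psi-weighted flux per probe
    (used to locate the release peak t*_p for the incremental resets).
    Mass waiting in the boundary buffer represents neurons at t* in [0, B/N);
    it contributes to nu with the hazard of the ``youngest`` probe (zero
    whenever the buffer lies inside the spike window) and re-enters the
    buffer when it fires, so the buffer mass is unchanged.
    """
    n, kbins = rho.shape
    nu = 0.0
    for i in range(n):
        pf = 0.0
        for kk in range(kbins):
            h = hazard[i, kk]
            if h > 0.0:
                r = rho[i, kk]
                shed = r * (1.0 - math.exp(-h * dt))
                rho[i, kk] = r - shed
                flux[kk] += shed
                pf += psi[kk] * r * h
        probe_flux[i] = pf
        nu += pf
    for kk in range(kbins):
        h = hazard[youngest, kk]
        if h > 0.0 and flux[kk] > 0.0:
            nu += psi[kk] * flux[kk] * h
    return nu


# ---------------------------------------------------------------------------
# membrane updates
# ---------------------------------------------------------------------------

@njit(cache=True)
def step_exc_membrane(u, u_d, gates, drive_prev, t_star, pinned,
                      g_ampa, g_nmda, g_gaba, v_gaba, mg, i_ext,
                      p, dt, dudt_out, gtot_out):
    """One exponential-Euler step of the two-compartment pyramidal membrane.

    GABA acts at the soma, AMPA/NMDA drive the dendrite through the
    transient-sharpening differential operator.  Probes inside the spike
    window (t* < dt_AP) whose ``pinned`` flag is set (i.e. that carry a
    freshly fired cohort) stay pinned at their reset voltages; silently
    recycled probes keep integrating.  ``dudt_out``
    receives the somatic right-hand side before the update (used by the
    drift term of the hazard), ``gtot_out`` the somatic total conductance
    excluding the compartment coupling.
    """
    n = u.shape[0]
    c_m = p[P_C]
    g_l = p[P_GL]
    v_rest = p[P_VREST]
    v_reset = p[P_VRESET]
    dt_ap = p[P_DTAP]
    gamma = p[P_GAMMA]
    ell = p[P_ELL]
    tau_m0 = p[P_TAUM0]
    v_k = p[P_VK]
    v_m = p[P_VM]
    g_cpl_s = 2.0 * gamma / ell * g_l
    g_cpl_d = 2.0 / ell * g_l
    for i in range(n):
        xdr = gates[GE_XDR, i]
        ydr = gates[GE_YDR, i]
        xa = gates[GE_XA, i]
        ya = gates[GE_YA, i]
        xm = gates[GE_XM, i]
        w = gates[GE_W, i]
        ui = u[i]
        g_dr = p[P_GDR] * xdr * ydr
        g_a = p[P_GA] * xa ** 4 * ya ** 3
        g_m = p[P_GM] * xm * xm
        g_ahp = p[P_GAHP] * w
        fn = nmda_block_scalar(ui, mg)
        gn = g_nmda * fn
        gtot_out[i] = g_l + g_dr + g_a + g_m + g_ahp + g_gaba + g_ampa + gn

        if t_star[i] < dt_ap and pinned[i] > 0.5:
            # pinned: voltage fixed at reset, gates frozen; keep the dendritic
            # drive memory in sync so release is smooth
            drive_prev[i] = (g_ampa + gn) * (0.0 - v_reset)
            dudt_out[i] = 0.0
            u[i] = v_reset
            u_d[i] = v_rest
            continue

        drive = (g_ampa + gn) * (0.0 - ui)
        i_dendr = (1.0 + ell / 2.0) * drive \
            + (ell * tau_m0 / 2.0) * (drive - drive_prev[i]) / dt
        drive_prev[i] = drive

        g_sum = g_l + g_dr + g_a + g_m + g_ahp + g_gaba + g_cpl_s
        num = g_l * v_rest + (g_dr + g_a + g_ahp) * v_k + g_m * v_m \
            + g_gaba * v_gaba + g_cpl_s * u_d[i] + i_ext
        dudt_out[i] = (num - g_sum * ui) / c_m
        u_inf = num / g_sum
        u[i] = u_inf + (ui - u_inf) * math.exp(-dt * g_sum / c_m)

        g_sum_d = g_l + g_cpl_d
        num_d = g_l * v_rest + g_cpl_d * ui + i_dendr / gamma
        ud_inf = num_d / g_sum_d
        u_d[i] = ud_inf + (u_d[i] - ud_inf) * math.exp(-dt * g_sum_d / c_m)

        # gate relaxation along the characteristic (exponential Euler)
        tx, xinf, ty, yinf = dr_rates(ui)
        gates[GE_XDR, i] = xinf + (xdr - xinf) * math.exp(-dt / tx)
        gates[GE_YDR, i] = yinf + (ydr - yinf) * math.exp(-dt / ty)
        tx, xinf, ty, yinf = a_rates(ui)
        gates[GE_XA, i] = xinf + (xa - xinf) * math.exp(-dt / tx)
        gates[GE_YA, i] = yinf + (ya - yinf) * math.exp(-dt / ty)
        tm, minf = m_rates(ui)
        gates[GE_XM, i] = minf + (xm - minf) * math.exp(-dt / tm)
        tw, winf = ahp_rates(ui)
        gates[GE_W, i] = winf + (w - winf) * math.exp(-dt / tw)


@njit(cache=True)
def step_inh_membrane(u, n_gate, t_star, pinned,
                      g_ampa, g_nmda, g_gaba, v_gaba, mg,
                      g_gj, u_mean, i_ext, p, dt, dudt_out, gtot_out):
    """One exponential-Euler step of the single-compartment interneuron."""
    n = u.shape[0]
    c_m = p[P_C]
    g_l = p[P_GL]
    v_rest = p[P_VREST]
    v_reset = p[P_VRESET]
    dt_ap = p[P_DTAP]
    v_k = p[P_VK]
    for i in range(n):
        ui = u[i]
        ng = n_gate[i]
        g_k = p[P_GK] * ng ** 4
        fn = nmda_block_scalar(ui, mg)
        gn = g_nmda * fn
        gtot_out[i] = g_l + g_k + g_ampa + gn + g_gaba + g_gj

        if t_star[i] < dt_ap and pinned[i] > 0.5:
            dudt_out[i] = 0.0
            u[i] = v_reset
            continue

        g_sum = g_l + g_k + g_ampa + gn + g_gaba + g_gj
        num = g_l * v_rest + g_k * v_k + g_gaba * v_gaba + g_gj * u_mean + i_ext
        dudt_out[i] = (num - g_sum * ui) / c_m
        u_inf = num / g_sum
        u[i] = u_inf + (ui - u_inf) * math.exp(-dt * g_sum / c_m)

        tn, ninf = kdr_rates(ui)
        n_gate[i] = ninf + (ng - ninf) * math.exp(-dt / tn)


# ---------------------------------------------------------------------------
# synaptic kinetics
# ---------------------------------------------------------------------------

@njit(cache=True)
def synapse_rhs(m, mdot, phi, tau_r, tau_d, tau_s):
    dm = mdot
    dmd = (tau_s * (1.0 - m) * phi - (tau_r + tau_d) * mdot - m) / (tau_r * tau_d)
    return dm, dmd


@njit(cache=True)
def advance_m_scalar(m, mdot, phi, tau_r, tau_d, tau_s, dt):
    """RK4 step of the damped second-order conductance kinetics."""
    k1m, k1d = synapse_rhs(m, mdot, phi, tau_r, tau_d, tau_s)
    k2m, k2d = synapse_rhs(m + 0.5 * dt * k1m, mdot + 0.5 * dt * k1d, phi, tau_r, tau_d, tau_s)
    k3m, k3d = synapse_rhs(m + 0.5 * dt * k2m, mdot + 0.5 * dt * k2d, phi, tau_r, tau_d, tau_s)
    k4m, k4d = synapse_rhs(m + dt * k3m, mdot + dt * k3d, phi, tau_r, tau_d, tau_s)
    m_new = m + dt / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
    md_new = mdot + dt / 6.0 * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)
    if m_new < 0.0:
        m_new = 0.0
    elif m_new > 1.0:
        m_new = 1.0
    return m_new, md_new


@njit(cache=True)
def advance_depression_scalar(x, tau, use, phi, dt):
    """Exact exponential update of dx/dt = (1-x)/tau - U*x*phi for frozen phi."""
    rate = 1.0 / tau + use * phi
    x_inf = (1.0 / tau) / rate
    return x_inf + (x - x_inf) * math.exp(-dt * rate)


@njit(cache=True)
def ou_update(value, tau, sigma, dt, xi):
    """Exact discretisation of the OU process with stationary SD sigma."""
    alpha = math.exp(-dt / tau)
    return value * alpha + sigma * math.sqrt(1.0 - alpha * alpha) * xi


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (shared by all kernels in this process)."""
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# fused network loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def _oldest_other(t_star, skip):
    best = -1
    bt = -1.0
    for j in range(t_star.shape[0]):
        if j != skip and t_star[j] > bt:
            bt = t_star[j]
            best = j
    return best


@njit(cache=True)
def _argmin(a):
    best = 0
    bv = a[0]
    for i in range(1, a.shape[0]):
        if a[i] < bv:
            bv = a[i]
            best = i
    return best


@njit(cache=True)
def _argmax(a):
    best = 0
    bv = a[0]
    for i in range(1, a.shape[0]):
        if a[i] > bv:
            bv = a[i]
            best = i
    return best


@njit(cache=True)
def run_network(n_steps, n_burn, record_stride,
                p_e, p_i, sh, syn, psi, xs,
                tstar_e, rho_e, u_e, ud_e, g_e, uf_e, udf_e, gf_e,
                dprev_e, dprevf_e, flux_e, pin_e,
                tstar_i, rho_i, u_i, n_i, uf_i, nf_i, flux_i, pin_i,
                m_syn, mdot_syn, xdep, misc,
                stim, i_inj_e, i_inj_i, out):
    """Advance the coupled E/I network ``n_steps`` steps of ``sh[S_DT]`` ms.

    Recording starts after ``n_burn`` steps, every ``record_stride`` steps,
    into ``out`` (NCHAN x n_records).  ``misc`` carries the scalar state
    [ou_value, nu_E, nu_I, u_mean_E, u_mean_I] across calls, so repeated
    single-step invocations reproduce a single long call bit for bit
    (the RNG must be seeded once via :func:`seed_rng`).

    Returns 0 on success or the 1-based step index at which a voltage left
    the admissible range (numerical fault).
    """
    dt = sh[S_DT]
    v_gaba = sh[S_VGABA]
    mg = sh[S_MG]
    h_max = 1.0 / dt
    ne = u_e.shape[0]
    ni = u_i.shape[0]
    kbins = psi.shape[0]

    # pA -> uA/cm^2 for the OU current
    pa_to_dens_e = 1.0e-6 / p_e[P_AREA]
    pa_to_dens_i = 1.0e-6 / p_i[P_AREA]
    # mS/cm^2 -> nS for the virtual clamp readout
    ns_per_dens = p_e[P_AREA] * 1.0e6

    dudt_e = np.empty(ne)
    gtot_e = np.empty(ne)
    dudtf_e = np.empty(ne)
    gtotf_e = np.empty(ne)
    h_e = np.empty((ne, kbins))
    pflux_e = np.empty(ne)
    dudt_i = np.empty(ni)
    gtot_i = np.empty(ni)
    dudtf_i = np.empty(ni)
    gtotf_i = np.empty(ni)
    h_i = np.empty((ni, kbins))
    pflux_i = np.empty(ni)

    rec = 0
    for step in range(n_steps):
        ou = misc[0]
        nu_e_prev = misc[1]
        nu_i_prev = misc[2]
        um_e_prev = misc[3]
        um_i_prev = misc[4]

        fb = sh[S_FB_ON] > 0.5
        phi_e = nu_e_prev if fb else 0.0
        phi_i = nu_i_prev if fb else 0.0
        phi_gaba = phi_i + stim[step]

        # --- short-term depression ---------------------------------------
        if sh[S_DEP_ON] > 0.5:
            xdep[0] = advance_depression_scalar(xdep[0], sh[S_TAUGLU], sh[S_UGLU], phi_e, dt)
            xdep[1] = advance_depression_scalar(xdep[1], sh[S_TAUGABA], sh[S_UGABA], phi_gaba, dt)

        # --- synaptic conductance kinetics --------------------------------
        for s in range(6):
            phi = phi_gaba if (s == 2 or s == 5) else phi_e
            m_syn[s], mdot_syn[s] = advance_m_scalar(
                m_syn[s], mdot_syn[s], phi, syn[s, 1], syn[s, 2], syn[s, 3], dt)

        # --- common OU drive ----------------------------------------------
        if sh[S_OUSIG] > 0.0:
            ou = ou_update(ou, sh[S_OUTAU], sh[S_OUSIG], dt, np.random.standard_normal())
        else:
            ou = ou * math.exp(-dt / sh[S_OUTAU])

        g_ampa_e = syn[0, 0] * m_syn[0] * xdep[0]
        g_nmda_e = syn[1, 0] * m_syn[1] * xdep[0]
        g_gaba_e = syn[2, 0] * m_syn[2] * xdep[1]
        g_ampa_i = syn[3, 0] * m_syn[3] * xdep[0]
        g_nmda_i = syn[4, 0] * m_syn[4] * xdep[0]
        g_gaba_i = syn[5, 0] * m_syn[5] * xdep[1]

        i_ext_e = i_inj_e[step] + (ou * pa_to_dens_e if sh[S_OU_TO_E] > 0.5 else 0.0)
        i_ext_i = i_inj_i[step] + ou * pa_to_dens_i

        # --- membranes (driven and free trajectories) ---------------------
        step_exc_membrane(u_e, ud_e, g_e, dprev_e, tstar_e, pin_e,
                          g_ampa_e, g_nmda_e, g_gaba_e, v_gaba, mg, i_ext_e,
                          p_e, dt, dudt_e, gtot_e)
        step_exc_membrane(uf_e, udf_e, gf_e, dprevf_e, tstar_e, pin_e,
                          0.0, 0.0, 0.0, v_gaba, mg, 0.0,
                          p_e, dt, dudtf_e, gtotf_e)
        step_inh_membrane(u_i, n_i, tstar_i, pin_i,
                          g_ampa_i, g_nmda_i, g_gaba_i, v_gaba, mg,
                          sh[S_GGJ], um_i_prev, i_ext_i, p_i, dt, dudt_i, gtot_i)
        step_inh_membrane(uf_i, nf_i, tstar_i, pin_i,
                          0.0, 0.0, 0.0, v_gaba, mg,
                          0.0, um_i_prev, 0.0, p_i, dt, dudtf_i, gtotf_i)

        # --- hazards -------------------------------------------------------
        gsyn_e = g_gaba_e + g_ampa_e + g_nmda_e * nmda_block_scalar(um_e_prev, mg)
        gsyn_i = g_gaba_i + g_ampa_i + g_nmda_i * nmda_block_scalar(um_i_prev, mg)
        # noise amplitude grows with the synaptic drive relative to the
        # momentary total conductance (bounded by 2*sigma_0)
        sig_e = p_e[P_SIG0] * (1.0 + gsyn_e / (p_e[P_GTOT0] + gsyn_e))
        sig_i = p_i[P_SIG0] * (1.0 + gsyn_i / (p_i[P_GTOT0] + gsyn_i))
        hazard_field(h_e, u_e, uf_e, dudt_e, dudtf_e, gtot_e, tstar_e, xs,
                     sig_e, p_e[P_C], p_e[P_VTHB], p_e[P_VTHA], p_e[P_VTHT],
                     p_e[P_TAUN], p_e[P_DTAP], h_max)
        hazard_field(h_i, u_i, uf_i, dudt_i, dudtf_i, gtot_i, tstar_i, xs,
                     sig_i, p_i[P_C], p_i[P_VTHB], p_i[P_VTHA], p_i[P_VTHT],
                     p_i[P_TAUN], p_i[P_DTAP], h_max)

        # --- density transport --------------------------------------------
        nu_e = density_step(rho_e, h_e, flux_e, psi, pflux_e, dt,
                            _argmin(tstar_e))
        nu_i = density_step(rho_i, h_i, flux_i, psi, pflux_i, dt,
                            _argmin(tstar_i))

        ip_e = _argmax(pflux_e)
        ip_i = _argmax(pflux_i)

        # --- probe advance and recycling ----------------------------------
        for i in range(ne):
            tstar_e[i] += dt
            if tstar_e[i] >= p_e[P_B] - 1.0e-9:
                j = _oldest_other(tstar_e, i)
                arriving = 0.0
                for kk in range(kbins):
                    rho_e[j, kk] += rho_e[i, kk]
                    rho_e[i, kk] = flux_e[kk]
                    arriving += flux_e[kk]
                    flux_e[kk] = 0.0
                tstar_e[i] = 0.0
                pin_e[i] = 1.0 if arriving > 1.0e-12 else 0.0
                if arriving > 1.0e-12:
                    # spike-state boundary conditions; slow gates incremented
                    # from the release-peak probe t*_p
                    p_idx = ip_e
                    xm_p = g_e[GE_XM, p_idx]
                    w_p = g_e[GE_W, p_idx]
                    xmf_p = gf_e[GE_XM, p_idx]
                    wf_p = gf_e[GE_W, p_idx]
                    u_e[i] = p_e[P_VRESET]
                    ud_e[i] = p_e[P_VREST]
                    g_e[GE_XDR, i] = RESET_XDR
                    g_e[GE_YDR, i] = RESET_YDR
                    g_e[GE_XA, i] = RESET_XA
                    g_e[GE_YA, i] = RESET_YA
                    g_e[GE_XM, i] = xm_p + INC_XM * (1.0 - xm_p)
                    g_e[GE_W, i] = w_p + INC_W * (1.0 - w_p)
                    uf_e[i] = p_e[P_VRESET]
                    udf_e[i] = p_e[P_VREST]
                    gf_e[GE_XDR, i] = RESET_XDR
                    gf_e[GE_YDR, i] = RESET_YDR
                    gf_e[GE_XA, i] = RESET_XA
                    gf_e[GE_YA, i] = RESET_YA
                    gf_e[GE_XM, i] = xmf_p + INC_XM * (1.0 - xmf_p)
                    gf_e[GE_W, i] = wf_p + INC_W * (1.0 - wf_p)
                    dprev_e[i] = (g_ampa_e + g_nmda_e * nmda_block_scalar(p_e[P_VRESET], mg)) \
                        * (0.0 - p_e[P_VRESET])
                    dprevf_e[i] = 0.0
                # no arriving mass: silent recycling keeps the probe's
                # carried state (no conductance injected, no voltage reset)
        for i in range(ni):
            tstar_i[i] += dt
            if tstar_i[i] >= p_i[P_B] - 1.0e-9:
                j = _oldest_other(tstar_i, i)
                arriving = 0.0
                for kk in range(kbins):
                    rho_i[j, kk] += rho_i[i, kk]
                    rho_i[i, kk] = flux_i[kk]
                    arriving += flux_i[kk]
                    flux_i[kk] = 0.0
                tstar_i[i] = 0.0
                pin_i[i] = 1.0 if arriving > 1.0e-12 else 0.0
                if arriving > 1.0e-12:
                    u_i[i] = p_i[P_VRESET]
                    n_i[i] = RESET_N
                    uf_i[i] = p_i[P_VRESET]
                    nf_i[i] = RESET_N

        # --- population means (psi- and rho-weighted bin voltages) --------
        um_e = 0.0
        mass_e = 0.0
        for i in range(ne):
            for kk in range(kbins):
                x = xs[kk]
                ux = uf_e[i] + (u_e[i] - uf_e[i]) * x
                wgt = psi[kk] * rho_e[i, kk]
                um_e += wgt * ux
                mass_e += wgt
        um_e /= mass_e
        um_i = 0.0
        mass_i = 0.0
        for i in range(ni):
            for kk in range(kbins):
                x = xs[kk]
                ux = uf_i[i] + (u_i[i] - uf_i[i]) * x
                wgt = psi[kk] * rho_i[i, kk]
                um_i += wgt * ux
                mass_i += wgt
        um_i /= mass_i

        misc[0] = ou
        misc[1] = nu_e
        misc[2] = nu_i
        misc[3] = um_e
        misc[4] = um_i

        if not (math.isfinite(um_e) and math.isfinite(um_i)) \
                or abs(um_e) > 200.0 or abs(um_i) > 200.0:
            return step + 1

        # --- recording -----------------------------------------------------
        if step >= n_burn and (step - n_burn) % record_stride == 0:
            if rec < out.shape[1]:
                g_gaba_ns = g_gaba_e * ns_per_dens
                g_ampa_ns = g_ampa_e * ns_per_dens
                g_nmda_ns = g_nmda_e * ns_per_dens
                vh = sh[S_VHOLD]
                i_clamp = g_gaba_ns * (vh - v_gaba) + g_ampa_ns * vh \
                    + g_nmda_ns * nmda_block_scalar(vh, mg) * vh
                # dipole proxy: density-weighted somato-dendritic axial current
                axial = 0.0
                gcpl = 2.0 * p_e[P_GAMMA] / p_e[P_ELL] * p_e[P_GL]
                for i in range(ne):
                    w_i = 0.0
                    for kk in range(kbins):
                        w_i += psi[kk] * rho_e[i, kk]
                    axial += w_i * gcpl * (ud_e[i] - u_e[i])
                out[TR_TIME, rec] = (step - n_burn) * dt
                out[TR_NUE, rec] = nu_e * 1000.0
                out[TR_NUI, rec] = nu_i * 1000.0
                out[TR_UME, rec] = um_e
                out[TR_UMI, rec] = um_i
                out[TR_GAMPA_E, rec] = g_ampa_e
                out[TR_GNMDA_E, rec] = g_nmda_e
                out[TR_GGABA_E, rec] = g_gaba_e
                out[TR_GAMPA_I, rec] = g_ampa_i
                out[TR_GNMDA_I, rec] = g_nmda_i
                out[TR_GGABA_I, rec] = g_gaba_i
                out[TR_ICLAMP, rec] = i_clamp
                out[TR_LFP, rec] = -sh[S_LFPGAIN] * axial
                out[TR_XGLU, rec] = xdep[0]
                out[TR_XGABA, rec] = xdep[1]
                out[TR_OU, rec] = ou
            rec += 1
    return 0


# ---------------------------------------------------------------------------
# Monte-Carlo reference ensemble
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_ensemble_exc(n_steps, dt, p, i_inj, sigma_v, tau_noise,
                     u, u_d, gates, t_sls, noise,
                     spike_n, spike_t):
    """Simulate N individual two-compartment pyramidal neurons.

    Each neuron integrates the same membrane/channel equations as the CBRD
    population under the common injected current ``i_inj`` (uA/cm^2 per
    step) plus an individual colored (OU) noise current whose amplitude
    tracks the neuron's momentary total conductance so that the
    subthreshold voltage SD stays equal to ``sigma_v`` -- the exact
    stochastic premise of the hazard function.  A spike is emitted when the
    voltage crosses the t*-dependent threshold.  Spikes are stored in
    (neuron, time) pairs; returns the number of spikes.
    """
    n = u.shape[0]
    cap = spike_n.shape[0]
    c_m = p[P_C]
    g_l = p[P_GL]
    v_rest = p[P_VREST]
    v_reset = p[P_VRESET]
    dt_ap = p[P_DTAP]
    gamma = p[P_GAMMA]
    ell = p[P_ELL]
    v_k = p[P_VK]
    v_m = p[P_VM]
    g_cpl_s = 2.0 * gamma / ell * g_l
    g_cpl_d = 2.0 / ell * g_l
    alpha = math.exp(-dt / tau_noise)
    beta = math.sqrt(1.0 - alpha * alpha)
    count = 0
    for step in range(n_steps):
        i_com = i_inj[step]
        for i in range(n):
            noise[i] = noise[i] * alpha + beta * np.random.standard_normal()
            if t_sls[i] < dt_ap:
                u[i] = v_reset
                u_d[i] = v_rest
                t_sls[i] += dt
                continue
            ui = u[i]
            g_dr = p[P_GDR] * gates[GE_XDR, i] * gates[GE_YDR, i]
            g_a = p[P_GA] * gates[GE_XA, i] ** 4 * gates[GE_YA, i] ** 3
            g_m = p[P_GM] * gates[GE_XM, i] ** 2
            g_ahp = p[P_GAHP] * gates[GE_W, i]
            g_sum = g_l + g_dr + g_a + g_m + g_ahp + g_cpl_s
            i_noise = sigma_v * g_sum * math.sqrt(1.0 + c_m / g_sum / tau_noise) * noise[i]
            num = g_l * v_rest + (g_dr + g_a + g_ahp) * v_k + g_m * v_m \
                + g_cpl_s * u_d[i] + i_com + i_noise
            u_inf = num / g_sum
            u[i] = u_inf + (ui - u_inf) * math.exp(-dt * g_sum / c_m)
            g_sum_d = g_l + g_cpl_d
            num_d = g_l * v_rest + g_cpl_d * ui
            ud_inf = num_d / g_sum_d
            u_d[i] = ud_inf + (u_d[i] - ud_inf) * math.exp(-dt * g_sum_d / c_m)

            tx, xinf, ty, yinf = dr_rates(ui)
            gates[GE_XDR, i] = xinf + (gates[GE_XDR, i] - xinf) * math.exp(-dt / tx)
            gates[GE_YDR, i] = yinf + (gates[GE_YDR, i] - yinf) * math.exp(-dt / ty)
            tx, xinf, ty, yinf = a_rates(ui)
            gates[GE_XA, i] = xinf + (gates[GE_XA, i] - xinf) * math.exp(-dt / tx)
            gates[GE_YA, i] = yinf + (gates[GE_YA, i] - yinf) * math.exp(-dt / ty)
            tm, minf = m_rates(ui)
            gates[GE_XM, i] = minf + (gates[GE_XM, i] - minf) * math.exp(-dt / tm)
            tw, winf = ahp_rates(ui)
            gates[GE_W, i] = winf + (gates[GE_W, i] - winf) * math.exp(-dt / tw)

            t_sls[i] += dt
            vth = threshold_scalar(t_sls[i], p[P_VTHB], p[P_VTHA], p[P_VTHT])
            if u[i] >= vth:
                if count < cap:
                    spike_n[count] = i
                    spike_t[count] = step * dt
                count += 1
                t_sls[i] = 0.0
                u[i] = v_reset
                u_d[i] = v_rest
                g_e = gates  # alias for brevity
                g_e[GE_XDR, i] = RESET_XDR
                g_e[GE_YDR, i] = RESET_YDR
                g_e[GE_XA, i] = RESET_XA
                g_e[GE_YA, i] = RESET_YA
                g_e[GE_XM, i] = g_e[GE_XM, i] + INC_XM * (1.0 - g_e[GE_XM, i])
                g_e[GE_W, i] = g_e[GE_W, i] + INC_W * (1.0 - g_e[GE_W, i])
    return count


@njit(cache=True)
def run_ensemble_inh(n_steps, dt, p, i_inj, sigma_v, tau_noise, g_gj,
                     u, n_gate, t_sls, noise, spike_n, spike_t):
    """Simulate N individual fast-spiking interneurons with gap junctions.

    Individual conductance-tracked colored noise current realising voltage
    fluctuations of SD ``sigma_v`` as in :func:`run_ensemble_exc`; the
    gap-junction current couples each neuron to the ensemble mean voltage.
    """
    n = u.shape[0]
    cap = spike_n.shape[0]
    c_m = p[P_C]
    g_l = p[P_GL]
    v_rest = p[P_VREST]
    v_reset = p[P_VRESET]
    dt_ap = p[P_DTAP]
    v_k = p[P_VK]
    alpha = math.exp(-dt / tau_noise)
    beta = math.sqrt(1.0 - alpha * alpha)
    count = 0
    for step in range(n_steps):
        i_com = i_inj[step]
        u_mean = 0.0
        for i in range(n):
            u_mean += u[i]
        u_mean /= n
        for i in range(n):
            noise[i] = noise[i] * alpha + beta * np.random.standard_normal()
            if t_sls[i] < dt_ap:
                u[i] = v_reset
                t_sls[i] += dt
                continue
            ui = u[i]
            g_k = p[P_GK] * n_gate[i] ** 4
            g_sum = g_l + g_k + g_gj
            i_noise = sigma_v * g_sum * math.sqrt(1.0 + c_m / g_sum / tau_noise) * noise[i]
            num = g_l * v_rest + g_k * v_k + g_gj * u_mean + i_com + i_noise
            u_inf = num / g_sum
            u[i] = u_inf + (ui - u_inf) * math.exp(-dt * g_sum / c_m)
            tn, ninf = kdr_rates(ui)
            n_gate[i] = ninf + (n_gate[i] - ninf) * math.exp(-dt / tn)
            t_sls[i] += dt
            vth = threshold_scalar(t_sls[i], p[P_VTHB], p[P_VTHA], p[P_VTHT])
            if u[i] >= vth:
                if count < cap:
                    spike_n[count] = i
                    spike_t[count] = step * dt
                count += 1
                t_sls[i] = 0.0
                u[i] = v_reset
                n_gate[i] = RESET_N
    return count
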