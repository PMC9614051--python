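"""Jitted time-stepping loop of the simulation engine.

One call advances the whole network by ``n_steps`` of size dt, mutating all
state arrays in place.  Within a step at nominal time t (= step start):

1. recurrent spikes emitted d earlier are delivered: conductance jumps use
   the pre-step weight values (single-buffer read-before-write);
2. spike-triggered plasticity terms fire (depression via u(t), inhibitory
   presynaptic term via y^E(t)); presynaptic traces x jump by alpha;
3. the potentiation term is integrated in closed form over [t, t+dt);
4. external Poisson input is sampled and delivered (no delay);
5. voltage traces u, v relax toward V(t);
6. membranes integrate; spikes are detected at the ceiling and reset
   (nominal spike time t+dt);
7. conductance states and spike traces decay to t+dt;
8. postsynaptic spike terms of the inhibitory rule fire; y traces jump;
9. emitted spikes enter the delay ring; trigger/normalization bookkeeping.

Parameter packing (float64 vectors) is defined by the builders in
``engine.py``; index constants below must stay in sync with them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .neurons import adex_step, lif_step
from .plasticity import ltd_jump, ltp_row_factor, normalize_rows

# AdEx param vector slots
A_TAU_M, A_E_L, A_DELTA_T, A_VT_REST, A_A_T, A_TAU_T, A_V_RESET, A_V_PEAK, \
    A_REF_STEPS, A_C, A_TAU_A, A_B, A_A_SUB, A_GAMMA = range(14)
# LIF param vector slots
L_TAU_M, L_E_L, L_V_TH, L_V_RESET, L_REF_STEPS, L_C = range(6)
# kernel vector slots
K_TAU_RE, K_TAU_DE, K_TAU_RI, K_TAU_DI, K_E_EXC, K_E_INH, K_C_K = range(7)
# stdp vector slots
S_A_LTD, S_A_LTP, S_TH_LTD, S_TH_LTP, S_TAU_U, S_TAU_V, S_TAU_XEE, \
    S_TAU_XRE, S_ALPHA, S_A_LTD_RE, S_A_LTP_RE = range(11)
# inhibitory plasticity vector slots
I_A_INH, I_OFFSET, I_TAU_Y, I_ALPHA = range(4)
# bounds vector slots
B_EE_MIN, B_EE_MAX, B_EI_MIN, B_EI_MAX, B_RE_MIN, B_RE_MAX = range(6)
# external weight vector slots
X_E_EXC, X_E_INH, X_I, X_S, X_H = range(5)
# clip counter slots
C_EE, C_EI, C_RE, C_NORM = range(4)


@njit(cache=True)
def simulate_chunk(
    n_steps, step0, dt, seed,
    pE, pI, pR, pS, pH, kern, stdp, inh, bounds, w_ext,
    # weights and adjacency
    W_EE, M_EE, W_EI, M_EI, W_IE, M_IE, W_II, M_II, W_RE, w_SR, w_HR,
    K, ee_plastic, ei_plastic, re_plastic, norm_steps,
    # E state
    V_E, VT_E, a_E, ref_E, xrEe, xdEe, xrEi, xdEi, u_E, v_E, xEE, xRE, yE,
    # I state
    V_I, ref_I, xrIe, xdIe, xrIi, xdIi, yI,
    # R state
    V_R, VT_R, a_R, ref_R, xrRe, xdRe, xrRi, xdRi, u_R, v_R,
    # S state
    V_S, VT_S, a_S, ref_S, xrSe, xdSe,
    # H state
    V_H, ref_H, xrHe, xdHe,
    # delay rings (index lists per slot)
    d_steps, histE_idx, histE_n, histI_idx, histI_n,
    histS_idx, histS_n, histH_idx, histH_n,
    # schedule (expected spikes per step per group)
    period_steps, seg_of_step, lam_exc, lam_inh, grp_E,
    g_I, g_S0, g_H,
    # trigger-locked presentation overlay
    trigger_on, trig_decay, trig_thresh, lockout_steps, lam_pres,
    trig_f, trig_i, trig_times, trig_n,
    # recording
    rec_flags, rec_t, rec_gid, rec_n, counts,
    # analog trace recording (selected E neurons, decimated)
    trace_idx, trace_every, tr_V, tr_VT, tr_a, tr_ge, tr_gi, tr_n,
    # outputs
    clips, err,
):
    NE = V_E.shape[0]
    NI = V_I.shape[0]
    NR = V_R.shape[0]
    depth = histE_idx.shape[0]
    offI = NE
    offR = NE + NI
    offS = NE + NI + NR
    offH = NE + NI + 2 * NR
    cap = rec_t.shape[0]

    np.random.seed(seed)

    # precomputed decay factors
    kl_E = np.exp(-dt / pE[A_TAU_M]); kT_E = np.exp(-dt / pE[A_TAU_T]); ka_E = np.exp(-dt / pE[A_TAU_A])
    kl_R = np.exp(-dt / pR[A_TAU_M]); kT_R = np.exp(-dt / pR[A_TAU_T]); ka_R = np.exp(-dt / pR[A_TAU_A])
    kl_S = np.exp(-dt / pS[A_TAU_M]); kT_S = np.exp(-dt / pS[A_TAU_T]); ka_S = np.exp(-dt / pS[A_TAU_A])
    kl_I = np.exp(-dt / pI[L_TAU_M]); kl_H = np.exp(-dt / pH[L_TAU_M])
    k_re = np.exp(-dt / kern[K_TAU_RE]); k_de = np.exp(-dt / kern[K_TAU_DE])
    k_ri = np.exp(-dt / kern[K_TAU_RI]); k_di = np.exp(-dt / kern[K_TAU_DI])
    ge_den = kern[K_C_K] / (kern[K_TAU_DE] - kern[K_TAU_RE])
    gi_den = kern[K_C_K] / (kern[K_TAU_DI] - kern[K_TAU_RI])
    k_u = np.exp(-dt / stdp[S_TAU_U]); k_v = np.exp(-dt / stdp[S_TAU_V])
    k_xEE = np.exp(-dt / stdp[S_TAU_XEE]); k_xRE = np.exp(-dt / stdp[S_TAU_XRE])
    k_y = np.exp(-dt / inh[I_TAU_Y])
    alpha = stdp[S_ALPHA]; alpha_y = inh[I_ALPHA]

    emitE = np.empty(NE, dtype=np.int32)
    emitI = np.empty(NI, dtype=np.int32)
    emitS = np.empty(NR, dtype=np.int32)
    emitH = np.empty(NR, dtype=np.int32)

    for n in range(n_steps):
        abs_n = step0 + n
        seg = seg_of_step[abs_n % period_steps]

        # ------ 1. delivery of delayed recurrent spikes (pre-step weights)
        m_slot = abs_n - d_steps - 1
        nEd = 0; nId = 0; nSd = 0; nHd = 0
        slot = -1
        if m_slot >= 0:
            slot = m_slot % depth
            nEd = histE_n[slot]; nId = histI_n[slot]
            nSd = histS_n[slot]; nHd = histH_n[slot]
            for q in range(nEd):
                j = histE_idx[slot, q]
                for i in range(NE):
                    if M_EE[i, j]:
                        w = W_EE[i, j]
                        xrEe[i] += w; xdEe[i] += w
                for i in range(NI):
                    if M_IE[i, j]:
                        w = W_IE[i, j]
                        xrIe[i] += w; xdIe[i] += w
                for r in range(NR):
                    w = W_RE[r, j]
                    xrRe[r] += w; xdRe[r] += w
            for q in range(nId):
                j = histI_idx[slot, q]
                for i in range(NE):
                    if M_EI[i, j]:
                        w = W_EI[i, j]
                        xrEi[i] += w; xdEi[i] += w
                for i in range(NI):
                    if M_II[i, j]:
                        w = W_II[i, j]
                        xrIi[i] += w; xdIi[i] += w
            for q in range(nSd):
                k = histS_idx[slot, q]
                xrRe[k] += w_SR[k]; xdRe[k] += w_SR[k]
            for q in range(nHd):
                k = histH_idx[slot, q]
                xrRi[k] += w_HR[k]; xdRi[k] += w_HR[k]

        # ------ 2. spike-triggered plasticity + presynaptic trace jumps
        if slot >= 0:
            for q in range(nEd):
                j = histE_idx[slot, q]
                if ee_plastic:
                    for i in range(NE):
                        if M_EE[i, j]:
                            dw = ltd_jump(u_E[i], stdp[S_TH_LTD], stdp[S_A_LTD])
                            if dw != 0.0:
                                w = W_EE[i, j] + dw
                                if w < bounds[B_EE_MIN]:
                                    w = bounds[B_EE_MIN]; clips[C_EE] += 1
                                W_EE[i, j] = w
                if re_plastic:
                    for r in range(NR):
                        dw = ltd_jump(u_R[r], stdp[S_TH_LTD], stdp[S_A_LTD_RE])
                        if dw != 0.0:
                            w = W_RE[r, j] + dw
                            if w < bounds[B_RE_MIN]:
                                w = bounds[B_RE_MIN]; clips[C_RE] += 1
                            W_RE[r, j] = w
                xEE[j] += alpha
                xRE[j] += alpha
            if ei_plastic:
                for q in range(nId):
                    j = histI_idx[slot, q]
                    for i in range(NE):
                        if M_EI[i, j]:
                            w = W_EI[i, j] + inh[I_A_INH] * (yE[i] - inh[I_OFFSET])
                            if w < bounds[B_EI_MIN]:
                                w = bounds[B_EI_MIN]; clips[C_EI] += 1
                            elif w > bounds[B_EI_MAX]:
                                w = bounds[B_EI_MAX]; clips[C_EI] += 1
                            W_EI[i, j] = w

        # ------ 3. closed-form potentiation over [t, t+dt)
        if ee_plastic:
            for i in range(NE):
                if V_E[i] > stdp[S_TH_LTP]:
                    F = ltp_row_factor(V_E[i], v_E[i], dt, stdp[S_TAU_XEE],
                                       stdp[S_TAU_V], stdp[S_TH_LTP],
                                       stdp[S_TH_LTD], stdp[S_A_LTP])
                    if F != 0.0:
                        for j in range(NE):
                            if M_EE[i, j] and xEE[j] > 0.0:
                                w = W_EE[i, j] + F * xEE[j]
                                if w > bounds[B_EE_MAX]:
                                    w = bounds[B_EE_MAX]; clips[C_EE] += 1
                                W_EE[i, j] = w
        if re_plastic:
            for r in range(NR):
                if V_R[r] > stdp[S_TH_LTP]:
                    F = ltp_row_factor(V_R[r], v_R[r], dt, stdp[S_TAU_XRE],
                                       stdp[S_TAU_V], stdp[S_TH_LTP],
                                       stdp[S_TH_LTD], stdp[S_A_LTP_RE])
                    if F != 0.0:
                        for j in range(NE):
                            if xRE[j] > 0.0:
                                w = W_RE[r, j] + F * xRE[j]
                                if w > bounds[B_RE_MAX]:
                                    w = bounds[B_RE_MAX]; clips[C_RE] += 1
                                W_RE[r, j] = w

        # ------ 4. external Poisson drive (delivered without delay)
        for i in range(NE):
            g = grp_E[i]
            lam = lam_exc[seg, g]
            if lam > 0.0:
                c = np.random.poisson(lam)
                if c > 0:
                    w = w_ext[X_E_EXC] * c
                    xrEe[i] += w; xdEe[i] += w
            lam = lam_inh[seg, g]
            if lam > 0.0:
                c = np.random.poisson(lam)
                if c > 0:
                    w = w_ext[X_E_INH] * c
                    xrEi[i] += w; xdEi[i] += w
        lamI = lam_exc[seg, g_I]
        if lamI > 0.0:
            for i in range(NI):
                c = np.random.poisson(lamI)
                if c > 0:
                    w = w_ext[X_I] * c
                    xrIe[i] += w; xdIe[i] += w
        for k in range(NR):
            if trigger_on and trig_i[0] >= 0:
                lam = lam_pres[trig_i[0], k]
            else:
                lam = lam_exc[seg, g_S0 + k]
            if lam > 0.0:
                c = np.random.poisson(lam)
                if c > 0:
                    w = w_ext[X_S] * c
                    xrSe[k] += w; xdSe[k] += w
        lamH = lam_exc[seg, g_H]
        if lamH > 0.0:
            for k in range(NR):
                c = np.random.poisson(lamH)
                if c > 0:
                    w = w_ext[X_H] * c
                    xrHe[k] += w; xdHe[k] += w

        # ------ 5. voltage traces relax toward V(t)
        for i in range(NE):
            u_E[i] = V_E[i] + (u_E[i] - V_E[i]) * k_u
            v_E[i] = V_E[i] + (v_E[i] - V_E[i]) * k_v
        for r in range(NR):
            u_R[r] = V_R[r] + (u_R[r] - V_R[r]) * k_u
            v_R[r] = V_R[r] + (v_R[r] - V_R[r]) * k_v

        # ------ 6. membrane integration + spike detection (time t+dt)
        nEs = 0
        refs_E = int(pE[A_REF_STEPS])
        for i in range(NE):
            ge = ge_den * (xdEe[i] - xrEe[i])
            gi = gi_den * (xdEi[i] - xrEi[i])
            V, VT, a, ref, spk = adex_step(
                V_E[i], VT_E[i], a_E[i], ref_E[i], ge, gi, dt,
                pE[A_TAU_M], pE[A_E_L], pE[A_DELTA_T], pE[A_VT_REST],
                pE[A_A_T], pE[A_V_RESET], pE[A_V_PEAK], refs_E, pE[A_C],
                pE[A_B], pE[A_A_SUB], pE[A_GAMMA],
                kern[K_E_EXC], kern[K_E_INH], kl_E, kT_E, ka_E)
            if not np.isfinite(V):
                err[0] = 1; err[1] = i; err[2] = abs_n
                return
            V_E[i] = V; VT_E[i] = VT; a_E[i] = a; ref_E[i] = ref
            if spk:
                emitE[nEs] = i; nEs += 1; counts[i] += 1
        nIs = 0
        refs_I = int(pI[L_REF_STEPS])
        for i in range(NI):
            ge = ge_den * (xdIe[i] - xrIe[i])
            gi = gi_den * (xdIi[i] - xrIi[i])
            V, ref, spk = lif_step(
                V_I[i], ref_I[i], ge, gi, dt, pI[L_E_L], pI[L_V_TH],
                pI[L_V_RESET], refs_I, pI[L_C],
                kern[K_E_EXC], kern[K_E_INH], kl_I)
            if not np.isfinite(V):
                err[0] = 1; err[1] = offI + i; err[2] = abs_n
                return
            V_I[i] = V; ref_I[i] = ref
            if spk:
                emitI[nIs] = i; nIs += 1; counts[offI + i] += 1
        refs_R = int(pR[A_REF_STEPS])
        nRs = 0
        for r in range(NR):
            ge = ge_den * (xdRe[r] - xrRe[r])
            gi = gi_den * (xdRi[r] - xrRi[r])
            V, VT, a, ref, spk = adex_step(
                V_R[r], VT_R[r], a_R[r], ref_R[r], ge, gi, dt,
                pR[A_TAU_M], pR[A_E_L], pR[A_DELTA_T], pR[A_VT_REST],
                pR[A_A_T], pR[A_V_RESET], pR[A_V_PEAK], refs_R, pR[A_C],
                pR[A_B], pR[A_A_SUB], pR[A_GAMMA],
                kern[K_E_EXC], kern[K_E_INH], kl_R, kT_R, ka_R)
            if not np.isfinite(V):
                err[0] = 1; err[1] = offR + r; err[2] = abs_n
                return
            V_R[r] = V; VT_R[r] = VT; a_R[r] = a; ref_R[r] = ref
            if spk:
                counts[offR + r] += 1
                nRs += 1
                if rec_flags[2] and rec_n[0] < cap:
                    rec_t[rec_n[0]] = abs_n + 1
                    rec_gid[rec_n[0]] = offR + r
                    rec_n[0] += 1
        nSs = 0
        refs_S = int(pS[A_REF_STEPS])
        for k in range(NR):
            ge = ge_den * (xdSe[k] - xrSe[k])
            V, VT, a, ref, spk = adex_step(
                V_S[k], VT_S[k], a_S[k], ref_S[k], ge, 0.0, dt,
                pS[A_TAU_M], pS[A_E_L], pS[A_DELTA_T], pS[A_VT_REST],
                pS[A_A_T], pS[A_V_RESET], pS[A_V_PEAK], refs_S, pS[A_C],
                pS[A_B], pS[A_A_SUB], pS[A_GAMMA],
                kern[K_E_EXC], kern[K_E_INH], kl_S, kT_S, ka_S)
            V_S[k] = V; VT_S[k] = VT; a_S[k] = a; ref_S[k] = ref
            if spk:
                emitS[nSs] = k; nSs += 1; counts[offS + k] += 1
        nHs = 0
        refs_H = int(pH[L_REF_STEPS])
        for k in range(NR):
            ge = ge_den * (xdHe[k] - xrHe[k])
            V, ref, spk = lif_step(
                V_H[k], ref_H[k], ge, 0.0, dt, pH[L_E_L], pH[L_V_TH],
                pH[L_V_RESET], refs_H, pH[L_C],
                kern[K_E_EXC], kern[K_E_INH], kl_H)
            V_H[k] = V; ref_H[k] = ref
            if spk:
                emitH[nHs] = k; nHs += 1; counts[offH + k] += 1

        # ------ 7. decay of conductance states and spike traces
        for i in range(NE):
            xrEe[i] *= k_re; xdEe[i] *= k_de
            xrEi[i] *= k_ri; xdEi[i] *= k_di
            xEE[i] *= k_xEE; xRE[i] *= k_xRE; yE[i] *= k_y
        for i in range(NI):
            xrIe[i] *= k_re; xdIe[i] *= k_de
            xrIi[i] *= k_ri; xdIi[i] *= k_di
            yI[i] *= k_y
        for r in range(NR):
            xrRe[r] *= k_re; xdRe[r] *= k_de
            xrRi[r] *= k_ri; xdRi[r] *= k_di
            xrSe[r] *= k_re; xdSe[r] *= k_de
            xrHe[r] *= k_re; xdHe[r] *= k_de

        # ------ 8. postsynaptic spike terms (nominal time t+dt)
        for q in range(nIs):
            yI[emitI[q]] += alpha_y
        if ei_plastic:
            for q in range(nEs):
                i = emitE[q]
                for j in range(NI):
                    if M_EI[i, j]:
                        w = W_EI[i, j] + inh[I_A_INH] * yI[j]
                        if w > bounds[B_EI_MAX]:
                            w = bounds[B_EI_MAX]; clips[C_EI] += 1
                        elif w < bounds[B_EI_MIN]:
                            w = bounds[B_EI_MIN]; clips[C_EI] += 1
                        W_EI[i, j] = w
        for q in range(nEs):
            yE[emitE[q]] += alpha_y

        # ------ 9. emitted spikes -> delay rings (+ optional recording)
        wslot = abs_n % depth
        histE_n[wslot] = nEs
        for q in range(nEs):
            histE_idx[wslot, q] = emitE[q]
        histI_n[wslot] = nIs
        for q in range(nIs):
            histI_idx[wslot, q] = emitI[q]
        histS_n[wslot] = nSs
        for q in range(nSs):
            histS_idx[wslot, q] = emitS[q]
        histH_n[wslot] = nHs
        for q in range(nHs):
            histH_idx[wslot, q] = emitH[q]
        if rec_flags[0]:
            for q in range(nEs):
                if rec_n[0] < cap:
                    rec_t[rec_n[0]] = abs_n + 1
                    rec_gid[rec_n[0]] = emitE[q]
                    rec_n[0] += 1
                else:
                    err[0] = 2
        if rec_flags[1]:
            for q in range(nIs):
                if rec_n[0] < cap:
                    rec_t[rec_n[0]] = abs_n + 1
                    rec_gid[rec_n[0]] = offI + emitI[q]
                    rec_n[0] += 1
                else:
                    err[0] = 2
        if rec_flags[3]:
            for q in range(nSs):
                if rec_n[0] < cap:
                    rec_t[rec_n[0]] = abs_n + 1
                    rec_gid[rec_n[0]] = offS + emitS[q]
                    rec_n[0] += 1
                else:
                    err[0] = 2
        if rec_flags[4]:
            for q in range(nHs):
                if rec_n[0] < cap:
                    rec_t[rec_n[0]] = abs_n + 1
                    rec_gid[rec_n[0]] = offH + emitH[q]
                    rec_n[0] += 1
                else:
                    err[0] = 2
        if rec_flags[2] and nRs > 0 and rec_n[0] >= cap:
            err[0] = 2

        # ------ 9b. decimated analog traces of selected E neurons
        n_sel = trace_idx.shape[0]
        if n_sel > 0 and (abs_n + 1) % trace_every == 0:
            row = tr_n[0]
            if row < tr_V.shape[0]:
                for q in range(n_sel):
                    i = trace_idx[q]
                    tr_V[row, q] = V_E[i]
                    tr_VT[row, q] = VT_E[i]
                    tr_a[row, q] = a_E[i]
                    tr_ge[row, q] = ge_den * (xdEe[i] - xrEe[i])
                    tr_gi[row, q] = gi_den * (xdEi[i] - xrEi[i])
                tr_n[0] = row + 1

        # ------ 10. clock-phase trigger for read-out presentations
        if trigger_on:
            c0 = 0
            for q in range(nEs):
                if grp_E[emitE[q]] == 0:
                    c0 += 1
            f_prev = trig_f[0]
            f_new = f_prev * trig_decay + c0
            trig_f[0] = f_new
            if trig_i[0] >= 0:
                trig_i[0] += 1
                if trig_i[0] >= lam_pres.shape[0]:
                    trig_i[0] = -1
            if (trig_i[0] < 0 and f_prev < trig_thresh and f_new >= trig_thresh
                    and abs_n - trig_i[1] > lockout_steps):
                trig_i[0] = 0
                trig_i[1] = abs_n
                if trig_n[0] < trig_times.shape[0]:
                    trig_times[trig_n[0]] = abs_n + 1
                    trig_n[0] += 1

        # ------ 11. periodic synaptic normalization (EE)
        if norm_steps > 0 and ee_plastic and (abs_n + 1) % norm_steps == 0:
            clips[C_NORM] += normalize_rows(
                W_EE, M_EE, K, bounds[B_EE_MIN], bounds[B_EE_MAX])

    return
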