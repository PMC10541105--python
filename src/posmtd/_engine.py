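"""Compiled fused loop for belief filtering + TD learning over a session.

This mirrors, step for step, the pure-Python reference orchestrator in
:mod:`posmtd.experiment` (which is itself built from the per-module
operations and validated against the enumeration oracle).  The two paths are
pinned to each other by an equivalence test; this one exists to make the
full study conditions (tens of millions of grid steps) affordable.

All model arrays (``T``, ``D``, ``SURV``, ``V``, ``E``) are mutated in
place so the agent persists across sessions.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _gaussian_kernel(mean_steps, cv_d, dt, d_b, out):
    n_d = out.shape[0]
    mu = mean_steps * dt
    sd = cv_d * mu
    if sd < 1e-12:
        sd = 1e-12
    total = 0.0
    for i in range(n_d):
        z = ((i + 1) * dt - mu) / sd
        v = np.exp(-0.5 * z * z)
        out[i] = v
        total += v
    if total <= 0.0:
        idx = int(round(mean_steps)) - 1
        if idx < 0:
            idx = 0
        if idx >= n_d:
            idx = n_d - 1
        for i in range(n_d):
            out[i] = 0.0
        out[idx] = 1.0
        total = 1.0
    scale = (1.0 - n_d * d_b) / total
    for i in range(n_d):
        out[i] = d_b + out[i] * scale


@njit(cache=True)
def _window_loglik(obs, start, end, T, O, D, SURV, init_state, null_idx):
    """Log observation likelihood of obs[start:end] under one subgraph,
    with a point-mass entry into ``init_state`` at the window start."""
    S = T.shape[0]
    n_d = D.shape[1]
    Wbuf = np.zeros((n_d, S))
    invH = np.zeros(n_d)
    alpha = np.zeros(S)
    u = np.zeros(S)
    b = np.zeros(S)
    total_ll = 0.0
    k_low = 0
    for trel in range(end - start):
        o = obs[start + trel]
        slot = trel % n_d
        if trel == 0:
            for s in range(S):
                Wbuf[slot, s] = 0.0
            Wbuf[slot, init_state] = 1.0
        else:
            for s in range(S):
                acc = 0.0
                for sp in range(S):
                    acc += T[sp, s] * alpha[sp]
                Wbuf[slot, s] = acc
        invH[slot] = 1.0
        if o != null_idx:
            k_low = trel
        if trel - n_d + 1 > k_low:
            k_low = trel - n_d + 1
        for s in range(S):
            u[s] = 0.0
            b[s] = 0.0
        for k in range(k_low, trel + 1):
            ks = k % n_d
            ih = invH[ks]
            di = trel - k
            ok = obs[start + k]
            for s in range(S):
                ow = O[s, ok] * Wbuf[ks, s] * ih
                u[s] += ow * D[s, di]
                b[s] += ow * SURV[s, di]
        c = 0.0
        for s in range(S):
            c += b[s]
        if c < 1e-300:
            c = 1e-300
        total_ll += np.log(c)
        inv_c = 1.0 / c
        for s in range(S):
            alpha[s] = u[s] * inv_c
        for k in range(k_low, trel + 1):
            invH[k % n_d] *= inv_c
    return total_ll


@njit(cache=True)
def run_session_engine(
    obs, rewards,
    T, O, D, SURV, V, E,
    init_state, null_idx, light_idx,
    tau, eta_r, gamma, discount_growth,
    dwell_learning, eta_d, cv_d, dt, d_b,
    upper_learning, iti_idx, ts_idx, eta_t, lesion_floor,
    subT, subO, subD, subSURV, sub_init,
    out_delta,
):
    """One session of filtering + learning; fills out_delta[t] with the total
    prediction error computed in response to the observation at step t."""
    n = obs.shape[0]
    S = T.shape[0]
    n_d = D.shape[1]
    n_blocks = ts_idx.shape[0]

    Wbuf = np.zeros((n_d, S))
    invH = np.zeros(n_d)
    alpha = np.zeros(S)
    u = np.zeros(S)
    b = np.zeros(S)
    ed_num = np.zeros(S)
    pvec = np.zeros(S)
    evnum = np.zeros(S)
    beta = np.zeros(S)
    kern = np.zeros(n_d)
    loglik = np.zeros(n_blocks)

    k_low = 0
    last_obs = -1        # absolute step of last non-empty observation <= t
    prev_light = -1      # absolute step of the current trial's light onset

    for t in range(n):
        o = obs[t]
        slot = t % n_d
        if t == 0:
            for s in range(S):
                Wbuf[slot, s] = 0.0
            Wbuf[slot, init_state] = 1.0
        else:
            for s in range(S):
                acc = 0.0
                for sp in range(S):
                    acc += T[sp, s] * alpha[sp]
                Wbuf[slot, s] = acc
        invH[slot] = 1.0
        if o != null_idx:
            k_low = t
            last_obs = t
        if t - n_d + 1 > k_low:
            k_low = t - n_d + 1

        # forward terms at time t
        for s in range(S):
            u[s] = 0.0
            b[s] = 0.0
            ed_num[s] = 0.0
        for k in range(k_low, t + 1):
            ks = k % n_d
            ih = invH[ks]
            di = t - k
            ok = obs[k]
            dd = float(di + 1)
            for s in range(S):
                ow = O[s, ok] * Wbuf[ks, s] * ih
                du = ow * D[s, di]
                u[s] += du
                b[s] += ow * SURV[s, di]
                ed_num[s] += du * dd
        c = 0.0
        for s in range(S):
            c += b[s]
        if c < 1e-300:
            c = 1e-300
        inv_c = 1.0 / c
        sum_alpha = 0.0
        for s in range(S):
            alpha[s] = u[s] * inv_c
            sum_alpha += alpha[s]
        for k in range(k_low, t + 1):
            invH[k % n_d] *= inv_c

        if t + 1 >= n:
            break
        o_next = obs[t + 1]
        r_next = rewards[t + 1]

        if o_next == light_idx:
            # a trial is about to start: learn the upper-level row from the
            # completed trial, then clear the eligibility trace
            if upper_learning and prev_light >= 0:
                mx = -1.0e308
                for j in range(n_blocks):
                    loglik[j] = _window_loglik(
                        obs, prev_light, t + 1, subT[j], subO[j], subD[j],
                        subSURV[j], sub_init[j], null_idx)
                    if loglik[j] > mx:
                        mx = loglik[j]
                z = 0.0
                for j in range(n_blocks):
                    loglik[j] = np.exp(loglik[j] - mx) * T[iti_idx, ts_idx[j]]
                    z += loglik[j]
                if z > 0.0:
                    rs = 0.0
                    for j in range(n_blocks):
                        tj = T[iti_idx, ts_idx[j]]
                        tj = tj + eta_t * (loglik[j] / z - tj)
                        if lesion_floor > 0.0 and tj < lesion_floor:
                            tj = lesion_floor
                        T[iti_idx, ts_idx[j]] = tj
                        rs += tj
                    if lesion_floor > 0.0:
                        for j in range(n_blocks):
                            T[iti_idx, ts_idx[j]] /= rs
            prev_light = t + 1
            for s in range(S):
                E[s] = 0.0

        # transition posterior and observation marginal for o_{t+1}
        m = 0.0
        for s in range(S):
            pv = 0.0
            ev = 0.0
            for sp in range(S):
                w = T[s, sp] * O[sp, o_next]
                pv += w
                ev += w * V[sp]
            pvec[s] = pv
            evnum[s] = ev
            m += pv * alpha[s]
        if o_next == null_idx:
            rest = 1.0 - sum_alpha
            if rest > 0.0:
                m += rest
        total = 0.0
        if m > 1e-300:
            inv_m = 1.0 / m
            sign = 1.0 if discount_growth else -1.0
            for s in range(S):
                bs = pvec[s] * alpha[s] * inv_m
                beta[s] = bs
                if bs > 0.0 and u[s] > 0.0:
                    g = np.exp(sign * tau * (ed_num[s] / u[s]))
                    ev = evnum[s] / pvec[s]
                    total += bs * (g * (r_next + ev) - V[s])
        else:
            for s in range(S):
                beta[s] = 0.0
        out_delta[t + 1] = total

        # eligibility then value update
        for s in range(S):
            e = gamma * E[s]
            if beta[s] > e:
                e = beta[s]
            E[s] = e
            V[s] += eta_r * e * total

        # dwell-distribution learning at non-empty observations
        if dwell_learning and o_next != null_idx and last_obs >= 0:
            d_obs = float(t + 1 - last_obs)
            _gaussian_kernel(d_obs, cv_d, dt, d_b, kern)
            for s in range(S):
                bs = beta[s]
                if bs > 0.0:
                    f = eta_d * bs
                    for i in range(n_d):
                        D[s, i] += f * (kern[i] - D[s, i])
                    acc = 0.0
                    for i in range(n_d - 1, -1, -1):
                        acc += D[s, i]
                        SURV[s, i] = acc
    return 0
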