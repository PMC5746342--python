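"""Numba kernel: semi-implicit backward-Euler integration on a compartment tree.

One linear solve per time step via tree-ordered (Hines) elimination:
compartments are stored parent-before-child, so a single reverse sweep
eliminates every child into its parent and a forward sweep back-substitutes.
Voltage is treated implicitly; all conductances (Kir open fraction, synaptic
and noise conductances) are frozen at the previous step's voltage / evaluated
at the new time, which keeps the scheme unconditionally stable on stiff
passive trees.

Units: mV, ms, µS, nF, nA.
"""
import numpy as np
from numba import njit

__all__ = ["integrate", "steady_state_picard"]


@njit(cache=True)
def steady_state_picard(parent, a_coup, g_k, g_na, g_kir, e_k, e_na,
                        kir_vhalf, kir_k, i_inj, v, tol, max_iter):
    """Damped Picard iteration to the resistive steady state.

    Kir open fraction frozen at the previous iterate; the linear network is
    solved exactly by tree-ordered elimination each pass.  Returns the
    iteration count (-1 if not converged); ``v`` is updated in place.
    """
    n = parent.shape[0]
    d = np.empty(n)
    r = np.empty(n)
    for it in range(max_iter):
        for i in range(n):
            m = 1.0 / (1.0 + np.exp((v[i] - kir_vhalf) / kir_k))
            gk_tot = g_k[i] + g_kir[i] * m
            d[i] = gk_tot + g_na[i]
            r[i] = gk_tot * e_k + g_na[i] * e_na
        r[0] += i_inj
        for i in range(1, n):
            d[i] += a_coup[i]
            d[parent[i]] += a_coup[i]
        for i in range(n - 1, 0, -1):
            f = a_coup[i] / d[i]
            d[parent[i]] -= f * a_coup[i]
            r[parent[i]] += f * r[i]
        delta = 0.0
        v_new0 = r[0] / d[0]
        if abs(v_new0 - v[0]) > delta:
            delta = abs(v_new0 - v[0])
        v_prev_parent = np.empty(n)
        v_prev_parent[0] = v_new0
        for i in range(1, n):
            v_new = (r[i] + a_coup[i] * v_prev_parent[parent[i]]) / d[i]
            v_prev_parent[i] = v_new
            if abs(v_new - v[i]) > delta:
                delta = abs(v_new - v[i])
        for i in range(n):
            v[i] = 0.5 * (v[i] + v_prev_parent[i])
        if delta < tol:
            return it + 1
    return -1


@njit(cache=True)
def integrate(
    parent,        # (n,) int64, parent index, -1 at root (index 0)
    a_coup,        # (n,) float64, coupling conductance to parent, µS (0 at root)
    cap,           # (n,) float64, nF
    g_k,           # (n,) float64, K leak, µS (scaling already applied)
    g_na,          # (n,) float64, Na leak, µS
    g_kir,         # (n,) float64, maximal Kir, µS (scaling already applied)
    e_k, e_na,     # mV
    kir_vhalf, kir_k,
    syn_comp,      # (ns,) int64
    syn_w,         # (ns,) float64 µS
    syn_tr, syn_td, syn_norm, syn_esyn,  # (ns,) float64
    syn_on_start,  # (ns+1,) int64 — slice bounds into syn_on_times
    syn_on_times,  # (total_onsets,) float64 ms
    noise_comp,    # (nn,) int64
    noise_g,       # (nn,) float64 µS, initial values (mutated)
    noise_g0, noise_sigma, noise_tau, noise_erev,  # (nn,) float64
    normals,       # (nn, n_steps) float64 standard normals
    i_inj,         # (n_steps,) float64 nA injected at soma during each step
    vc_mode,       # bool — ideal somatic voltage clamp
    vcmd,          # (n_steps+1,) float64 command voltage incl. t=0
    v,             # (n,) float64 initial voltages (mutated to final state)
    dt,            # ms
    rec_idx,       # (nr,) int64 compartments to record
):
    n = parent.shape[0]
    n_steps = i_inj.shape[0]
    ns = syn_comp.shape[0]
    nn = noise_comp.shape[0]
    nr = rec_idx.shape[0]

    v_rec = np.empty((n_steps + 1, nr))
    i_clamp = np.zeros(n_steps)
    d = np.empty(n)
    r = np.empty(n)

    if vc_mode:
        v[0] = vcmd[0]
    for k in range(nr):
        v_rec[0, k] = v[rec_idx[k]]

    for step in range(1, n_steps + 1):
        t = step * dt

        # advance OU noise conductances (exact discretization, clipped at 0)
        for j in range(nn):
            rho = np.exp(-dt / noise_tau[j])
            g_new = (noise_g0[j] + (noise_g[j] - noise_g0[j]) * rho
                     + noise_sigma[j] * np.sqrt(1.0 - rho * rho) * normals[j, step - 1])
            noise_g[j] = g_new if g_new > 0.0 else 0.0

        # assemble diagonal and rhs
        for i in range(n):
            m = 1.0 / (1.0 + np.exp((v[i] - kir_vhalf) / kir_k))
            gk_tot = g_k[i] + g_kir[i] * m
            d[i] = cap[i] / dt + gk_tot + g_na[i]
            r[i] = cap[i] / dt * v[i] + gk_tot * e_k + g_na[i] * e_na

        for s in range(ns):
            g = 0.0
            for o in range(syn_on_start[s], syn_on_start[s + 1]):
                ts = t - syn_on_times[o]
                if ts >= 0.0:
                    g += np.exp(-ts / syn_td[s]) - np.exp(-ts / syn_tr[s])
            g = syn_w[s] * g / syn_norm[s]
            ci = syn_comp[s]
            d[ci] += g
            r[ci] += g * syn_esyn[s]

        for j in range(nn):
            ci = noise_comp[j]
            d[ci] += noise_g[j]
            r[ci] += noise_g[j] * noise_erev[j]

        r[0] += i_inj[step - 1]

        for i in range(1, n):
            d[i] += a_coup[i]
            d[parent[i]] += a_coup[i]

        # Hines elimination: children (high index) into parents (low index)
        for i in range(n - 1, 0, -1):
            f = a_coup[i] / d[i]
            d[parent[i]] -= f * a_coup[i]
            r[parent[i]] += f * r[i]

        if vc_mode:
            v[0] = vcmd[step]
        else:
            v[0] = r[0] / d[0]
        for i in range(1, n):
            v[i] = (r[i] + a_coup[i] * v[parent[i]]) / d[i]

        if vc_mode:
            # clamp current: somatic membrane + axial out of soma + capacitive
            v0 = v[0]
            m0 = 1.0 / (1.0 + np.exp((v0 - kir_vhalf) / kir_k))
            i_mem = ((g_k[0] + g_kir[0] * m0) * (v0 - e_k)
                     + g_na[0] * (v0 - e_na))
            for s in range(ns):
                if syn_comp[s] == 0:
                    g = 0.0
                    for o in range(syn_on_start[s], syn_on_start[s + 1]):
                        ts = t - syn_on_times[o]
                        if ts >= 0.0:
                            g += np.exp(-ts / syn_td[s]) - np.exp(-ts / syn_tr[s])
                    i_mem += syn_w[s] * g / syn_norm[s] * (v0 - syn_esyn[s])
            for j in range(nn):
                if noise_comp[j] == 0:
                    i_mem += noise_g[j] * (v0 - noise_erev[j])
            i_ax = 0.0
            for i in range(1, n):
                if parent[i] == 0:
                    i_ax += a_coup[i] * (v0 - v[i])
            i_cap = cap[0] * (vcmd[step] - vcmd[step - 1]) / dt
            i_clamp[step - 1] = i_mem + i_ax + i_cap

        for k in range(nr):
            v_rec[step, k] = v[rec_idx[k]]

        for i in range(n):
            if not np.isfinite(v[i]):
                # signal divergence through a sentinel row; caller raises
                i_clamp[0] = np.nan
                v_rec[min(step, n_steps), 0] = np.nan
                return v_rec, i_clamp, step

    return v_rec, i_clamp, -1
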