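"""Numba-compiled stochastic Heun integrator for the delay-coupled network.

State per region: dendritic potentials (V, dV) of the four populations and
the cortical excitatory axonal field (phi_e, dphi_e).  Delays are handled
with ring buffers over the phi_e and phi_s histories; noise is supplied as a
pregenerated (n_steps, n) array of standard-normal draws.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1


@njit(cache=True, fastmath=False)
def _sig(v, q_max, theta, inv_sigma):
    return q_max / (1.0 + np.exp(-(v - theta) * inv_sigma))


@njit(cache=True, fastmath=False)
def integrate(
    n_steps,
    dt,
    record_every,
    q_max,
    theta,
    sigma_prime,
    alpha_d,
    beta_d,
    gamma_e,
    nu_ee,
    nu_ei,
    nu_es,
    nu_ie,
    nu_ii,
    nu_is,
    nu_re,
    nu_rs,
    nu_se,
    nu_sr,
    nu_sn,
    w_net,          # (n, n) effective long-range matrix, V*s, row j = inputs to j
    d_ct,           # corticothalamic leg delay in steps (t0/2)
    d_net,          # inter-regional delay in steps
    noise,          # (n_steps, n) standard normal draws
    noise_mean,
    noise_std,
    ve0, vi0, vr0, vs0,   # (n,) initial potentials (fixed point)
    guard_v,
    guard_phi,
):
    """Integrate the network and return (status, fail_step, fail_region, rec).

    ``rec`` holds phi_e at every ``record_every``-th step including step 0,
    shape (n_steps // record_every + 1, n).
    """
    n = ve0.shape[0]
    inv_sigma = 1.0 / sigma_prime
    ab = alpha_d * beta_d
    apb = alpha_d + beta_d
    g2 = gamma_e * gamma_e
    sqdt = np.sqrt(dt)

    ve = ve0.copy()
    vi = vi0.copy()
    vr = vr0.copy()
    vs = vs0.copy()
    dve = np.zeros(n)
    dvi = np.zeros(n)
    dvr = np.zeros(n)
    dvs = np.zeros(n)
    phie = np.empty(n)
    dphie = np.zeros(n)
    for j in range(n):
        phie[j] = _sig(ve[j], q_max, theta, inv_sigma)

    d_max = max(d_ct, d_net)
    buf_len = d_max + 2
    bphie = np.empty((buf_len, n))
    bphis = np.empty((buf_len, n))
    for t in range(buf_len):
        for j in range(n):
            bphie[t, j] = phie[j]
            bphis[t, j] = _sig(vs[j], q_max, theta, inv_sigma)

    n_rec = n_steps // record_every + 1
    rec = np.empty((n_rec, n))
    for j in range(n):
        rec[0, j] = phie[j]
    r_i = 1

    # scratch
    pe = np.empty(n)
    pi = np.empty(n)
    pr = np.empty(n)
    ps = np.empty(n)
    k1 = np.empty((10, n))
    st = np.empty((10, n))  # predictor state: ve vi vr vs dve dvi dvr dvs phie dphie
    net_in = np.empty(n)

    for k in range(n_steps):
        i_ct = (k - d_ct) % buf_len
        i_net = (k - d_net) % buf_len

        # --- drive at time k
        if d_net == 0:
            net_src = phie
        else:
            net_src = bphie[i_net]
        net_in[:] = np.dot(w_net, net_src)
        for j in range(n):
            qi = _sig(vi[j], q_max, theta, inv_sigma)
            qr = _sig(vr[j], q_max, theta, inv_sigma)
            qs = _sig(vs[j], q_max, theta, inv_sigma)
            phie_d = bphie[i_ct, j]
            phis_d = bphis[i_ct, j]
            phin = noise_mean + noise_std * noise[k, j] / sqdt
            pe[j] = nu_ee[j] * phie[j] + nu_ei[j] * qi + nu_es[j] * phis_d + net_in[j]
            pi[j] = nu_ie[j] * phie[j] + nu_ii[j] * qi + nu_is[j] * phis_d
            pr[j] = nu_re[j] * phie_d + nu_rs[j] * qs
            ps[j] = nu_se[j] * phie_d + nu_sr[j] * qr + nu_sn[j] * phin

        # --- slopes at time k, Euler predictor
        for j in range(n):
            qe = _sig(ve[j], q_max, theta, inv_sigma)
            k1[0, j] = dve[j]
            k1[1, j] = dvi[j]
            k1[2, j] = dvr[j]
            k1[3, j] = dvs[j]
            k1[4, j] = ab * (pe[j] - ve[j]) - apb * dve[j]
            k1[5, j] = ab * (pi[j] - vi[j]) - apb * dvi[j]
            k1[6, j] = ab * (pr[j] - vr[j]) - apb * dvr[j]
            k1[7, j] = ab * (ps[j] - vs[j]) - apb * dvs[j]
            k1[8, j] = dphie[j]
            k1[9, j] = g2 * (qe - phie[j]) - 2.0 * gamma_e * dphie[j]
            st[0, j] = ve[j] + dt * k1[0, j]
            st[1, j] = vi[j] + dt * k1[1, j]
            st[2, j] = vr[j] + dt * k1[2, j]
            st[3, j] = vs[j] + dt * k1[3, j]
            st[4, j] = dve[j] + dt * k1[4, j]
            st[5, j] = dvi[j] + dt * k1[5, j]
            st[6, j] = dvr[j] + dt * k1[6, j]
            st[7, j] = dvs[j] + dt * k1[7, j]
            st[8, j] = phie[j] + dt * k1[8, j]
            st[9, j] = dphie[j] + dt * k1[9, j]

        # --- drive at time k+1 using predictor state and shifted delays
        i_ct1 = (k + 1 - d_ct) % buf_len
        i_net1 = (k + 1 - d_net) % buf_len
        if d_net == 0:
            net_in[:] = np.dot(w_net, st[8])
        else:
            net_in[:] = np.dot(w_net, bphie[i_net1])
        for j in range(n):
            qi = _sig(st[1, j], q_max, theta, inv_sigma)
            qr = _sig(st[2, j], q_max, theta, inv_sigma)
            qs = _sig(st[3, j], q_max, theta, inv_sigma)
            if d_ct == 0:
                phie_d = st[8, j]
                phis_d = qs
            else:
                phie_d = bphie[i_ct1, j]
                phis_d = bphis[i_ct1, j]
            phin = noise_mean + noise_std * noise[k, j] / sqdt
            pe[j] = nu_ee[j] * st[8, j] + nu_ei[j] * qi + nu_es[j] * phis_d + net_in[j]
            pi[j] = nu_ie[j] * st[8, j] + nu_ii[j] * qi + nu_is[j] * phis_d
            pr[j] = nu_re[j] * phie_d + nu_rs[j] * qs
            ps[j] = nu_se[j] * phie_d + nu_sr[j] * qr + nu_sn[j] * phin

        # --- Heun corrector
        diverged = -1
        for j in range(n):
            qe = _sig(st[0, j], q_max, theta, inv_sigma)
            k2_ve = st[4, j]
            k2_vi = st[5, j]
            k2_vr = st[6, j]
            k2_vs = st[7, j]
            k2_dve = ab * (pe[j] - st[0, j]) - apb * st[4, j]
            k2_dvi = ab * (pi[j] - st[1, j]) - apb * st[5, j]
            k2_dvr = ab * (pr[j] - st[2, j]) - apb * st[6, j]
            k2_dvs = ab * (ps[j] - st[3, j]) - apb * st[7, j]
            k2_phie = st[9, j]
            k2_dphie = g2 * (qe - st[8, j]) - 2.0 * gamma_e * st[9, j]
            h = 0.5 * dt
            ve[j] += h * (k1[0, j] + k2_ve)
            vi[j] += h * (k1[1, j] + k2_vi)
            vr[j] += h * (k1[2, j] + k2_vr)
            vs[j] += h * (k1[3, j] + k2_vs)
            dve[j] += h * (k1[4, j] + k2_dve)
            dvi[j] += h * (k1[5, j] + k2_dvi)
            dvr[j] += h * (k1[6, j] + k2_dvr)
            dvs[j] += h * (k1[7, j] + k2_dvs)
            phie[j] += h * (k1[8, j] + k2_phie)
            dphie[j] += h * (k1[9, j] + k2_dphie)
            if (
                abs(ve[j]) > guard_v
                or abs(vi[j]) > guard_v
                or abs(vr[j]) > guard_v
                or abs(vs[j]) > guard_v
                or abs(phie[j]) > guard_phi
                or not np.isfinite(phie[j])
            ):
                diverged = j
        if diverged >= 0:
            return STATUS_DIVERGED, k + 1, diverged, rec[:r_i]

        # --- push histories for time k+1
        i_next = (k + 1) % buf_len
        for j in range(n):
            bphie[i_next, j] = phie[j]
            bphis[i_next, j] = _sig(vs[j], q_max, theta, inv_sigma)

        if (k + 1) % record_every == 0:
            for j in range(n):
                rec[r_i, j] = phie[j]
            r_i += 1

    return STATUS_OK, n_steps, -1, rec
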