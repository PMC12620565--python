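"""Compiled integration kernels for the differentiable simulator.

The forward pass (coupled neural + hemodynamic Euler-Maruyama steps) and its
reverse-mode adjoint are step loops over small (B, N) state arrays; at desk
scale the work per step is tiny, so the loops are JIT-compiled with numba.
State noise is pregenerated outside the kernels (shape (n_steps, 2, B, N),
excitatory draw first, matching the sequential per-step draws of
:func:`rwwfit.dynamics.integrate` bit for bit).

Inside the kernels every gain is carried as a (B, N) array and the coupling
operator as (B, N, N); the caller broadcasts global parameters up and reduces
gradients back down to the true parameter shapes.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EXP_CLIP = 500.0
_SMALL = 1e-7


@njit(cache=True, inline="always")
def _phi(u, d):
    """Transfer phi(u) = u / (1 - exp(-d*u)) with the u=0 limit 1/d."""
    x = d * u
    if x > _EXP_CLIP:
        x = _EXP_CLIP
    elif x < -_EXP_CLIP:
        x = -_EXP_CLIP
    if abs(x) < _SMALL:
        return 1.0 / d + u / 2.0
    return u / (-np.expm1(-x))


@njit(cache=True, inline="always")
def _dphi(u, d):
    """d(phi)/du with the u=0 limit 1/2."""
    x = d * u
    if x > _EXP_CLIP:
        x = _EXP_CLIP
    elif x < -_EXP_CLIP:
        x = -_EXP_CLIP
    if abs(x) < _SMALL:
        return 0.5 + d * u / 6.0
    ex = np.exp(-x)
    s = -np.expm1(-x)
    return 1.0 / s - u * d * ex / (s * s)


@njit(cache=True)
def forward_kernel(
    E, I, s, f, v, q,            # (B, N) state, updated in place
    g, g_ei, g_ie, g_ee,         # (B, N) gains (broadcast up by caller)
    M,                           # (B, N, N) coupling operator
    noise,                       # (n_steps, 2, B, N) or (0, 2, B, N) if sigma == 0
    sigma_amp,                   # sigma * sqrt(dt)
    dt, n_steps, sample_every,
    tau_e, tau_i, gamma, a_e, b_e, d_e, a_i, b_i, d_i,
    i0, w_e, w_i, i_ext, lam,
    kappa, gamma_h, tau_h, alpha, rho, v0, k1, k2, k3,
    bold,                        # (B, T, N) out
    E_st, I_st, s_st, f_st, v_st, q_st,   # (n_steps+1, B, N) caches (or (1,...) if no cache)
    mask_e, mask_i,              # (n_steps, B, N) uint8 (or (1,...))
    with_cache,
):
    B, N = E.shape
    log_omr = np.log1p(-rho)
    inv_a = 1.0 / alpha
    noisy = sigma_amp > 0.0
    clamps = 0
    m = 0
    if with_cache:
        for b in range(B):
            for n in range(N):
                E_st[0, b, n] = E[b, n]; I_st[0, b, n] = I[b, n]
                s_st[0, b, n] = s[b, n]; f_st[0, b, n] = f[b, n]
                v_st[0, b, n] = v[b, n]; q_st[0, b, n] = q[b, n]
    for t in range(n_steps):
        for b in range(B):
            for n in range(N):
                # balloon step driven by E at step start
                vn = v[b, n]
                fn = f[b, n]
                v1a = vn ** inv_a
                ef = -np.expm1(log_omr / fn)
                s_new = s[b, n] + dt * (E[b, n] - kappa * s[b, n] - gamma_h * (fn - 1.0))
                f_new = fn + dt * s[b, n]
                v_new = vn + (dt / tau_h) * (fn - v1a)
                q_new = q[b, n] + (dt / tau_h) * (fn * ef / rho - v1a * q[b, n] / vn)
                s[b, n] = s_new; f[b, n] = f_new; v[b, n] = v_new; q[b, n] = q_new
            # network input
            for n in range(N):
                cE = 0.0
                for j in range(N):
                    cE += M[b, n, j] * E[b, j]
                x_e = w_e * i0 + g_ee[b, n] * E[b, n] + g[b, n] * cE - g_ie[b, n] * I[b, n]
                x_i = w_i * i0 + g_ei[b, n] * E[b, n] + lam * g[b, n] * cE
                r_e = _phi(a_e * (np.tanh(x_e) + i_ext) - b_e, d_e)
                r_i = _phi(a_i * np.tanh(x_i) - b_i, d_i)
                e_new = E[b, n] + dt * (-E[b, n] / tau_e + (1.0 - E[b, n]) * gamma * r_e)
                i_new = I[b, n] + dt * (-I[b, n] / tau_i + r_i)
                if noisy:
                    e_new += sigma_amp * noise[t, 0, b, n]
                    i_new += sigma_amp * noise[t, 1, b, n]
                me = 1
                mi = 1
                if e_new <= 0.0:
                    e_new = 0.0; me = 0; clamps += 1
                elif e_new >= 1.0:
                    e_new = 1.0; me = 0; clamps += 1
                if i_new <= 0.0:
                    i_new = 0.0; mi = 0; clamps += 1
                if with_cache:
                    mask_e[t, b, n] = me
                    mask_i[t, b, n] = mi
                # write via caches below; stash in mask-independent temporaries
                E_st[(t + 1) if with_cache else 0, b, n] = e_new
                I_st[(t + 1) if with_cache else 0, b, n] = i_new
        # commit neural state for this step
        if with_cache:
            for b in range(B):
                for n in range(N):
                    E[b, n] = E_st[t + 1, b, n]
                    I[b, n] = I_st[t + 1, b, n]
                    s_st[t + 1, b, n] = s[b, n]; f_st[t + 1, b, n] = f[b, n]
                    v_st[t + 1, b, n] = v[b, n]; q_st[t + 1, b, n] = q[b, n]
        else:
            for b in range(B):
                for n in range(N):
                    E[b, n] = E_st[0, b, n]
                    I[b, n] = I_st[0, b, n]
        if (t + 1) % sample_every == 0:
            for b in range(B):
                for n in range(N):
                    bold[b, m, n] = v0 * (k1 * (1.0 - q[b, n])
                                          + k2 * (1.0 - q[b, n] / v[b, n])
                                          + k3 * (1.0 - v[b, n]))
            m += 1
    return clamps


@njit(cache=True)
def backward_kernel(
    d_bold,                      # (B, T, N) upstream gradient
    g, g_ei, g_ie, g_ee, M,
    dt, n_steps, sample_every,
    tau_e, tau_i, gamma, a_e, b_e, d_e, a_i, b_i, d_i,
    i0, w_e, w_i, i_ext, lam,
    kappa, gamma_h, tau_h, alpha, rho, v0, k1, k2, k3,
    E_st, I_st, s_st, f_st, v_st, q_st,
    mask_e, mask_i,
    gr_g, gr_gei, gr_gie, gr_gee,   # (B, N) out, zero-initialized
    gr_C,                            # (B, N, N) out or (B, 0, 0)
    want_gc, laplacian_mode,
):
    B, N = gr_g.shape
    log_omr = np.log1p(-rho)
    inv_a = 1.0 / alpha
    aE = np.zeros((B, N)); aI = np.zeros((B, N))
    as_ = np.zeros((B, N)); af = np.zeros((B, N))
    av = np.zeros((B, N)); aq = np.zeros((B, N))
    n_aE = np.zeros((B, N)); n_aI = np.zeros((B, N))
    a_c = np.zeros((B, N))
    for t in range(n_steps - 1, -1, -1):
        if (t + 1) % sample_every == 0:
            m = (t + 1) // sample_every - 1
            for b in range(B):
                for n in range(N):
                    gy = d_bold[b, m, n]
                    v1 = v_st[t + 1, b, n]
                    q1 = q_st[t + 1, b, n]
                    aq[b, n] += gy * v0 * (-k1 - k2 / v1)
                    av[b, n] += gy * v0 * (k2 * q1 / (v1 * v1) - k3)
        for b in range(B):
            # recompute network input at state t
            for n in range(N):
                cE = 0.0
                for j in range(N):
                    cE += M[b, n, j] * E_st[t, b, j]
                E_ = E_st[t, b, n]; I_ = I_st[t, b, n]
                f_ = f_st[t, b, n]; v_ = v_st[t, b, n]; q_ = q_st[t, b, n]
                # balloon adjoint
                v1am = v_ ** (inv_a - 1.0)
                efac = np.exp(log_omr / f_)
                dh_df = (1.0 - efac + (log_omr / f_) * efac) / rho
                nas = as_[b, n] * (1.0 - kappa * dt) + af[b, n] * dt
                naf = (af[b, n] - as_[b, n] * gamma_h * dt + av[b, n] * (dt / tau_h)
                       + aq[b, n] * (dt / tau_h) * dh_df)
                nav = (av[b, n] * (1.0 - (dt / tau_h) * inv_a * v1am)
                       - aq[b, n] * (dt / tau_h) * (inv_a - 1.0)
                       * v_ ** (inv_a - 2.0) * q_)
                naq = aq[b, n] * (1.0 - (dt / tau_h) * v1am)
                aE_hemo = as_[b, n] * dt
                # neural adjoint
                gEp = aE[b, n] * mask_e[t, b, n]
                gIp = aI[b, n] * mask_i[t, b, n]
                x_e = w_e * i0 + g_ee[b, n] * E_ + g[b, n] * cE - g_ie[b, n] * I_
                x_i = w_i * i0 + g_ei[b, n] * E_ + lam * g[b, n] * cE
                t_e = np.tanh(x_e); t_i = np.tanh(x_i)
                i_e = t_e + i_ext
                u_e = a_e * i_e - b_e
                u_i = a_i * t_i - b_i
                r_e = _phi(u_e, d_e)
                a_xe = gEp * dt * gamma * (1.0 - E_) \
                    * a_e * _dphi(u_e, d_e) * (1.0 - t_e * t_e)
                a_xi = gIp * dt * a_i * _dphi(u_i, d_i) * (1.0 - t_i * t_i)
                gr_gee[b, n] += a_xe * E_
                gr_gie[b, n] += -a_xe * I_
                gr_gei[b, n] += a_xi * E_
                acoup = a_xe + lam * a_xi
                gr_g[b, n] += acoup * cE
                a_c[b, n] = g[b, n] * acoup
                if want_gc:
                    if laplacian_mode:
                        for j in range(N):
                            gr_C[b, n, j] += a_c[b, n] * (E_ - E_st[t, b, j])
                    else:
                        for j in range(N):
                            gr_C[b, n, j] += a_c[b, n] * E_st[t, b, j]
                n_aE[b, n] = (gEp * (1.0 + dt * (-1.0 / tau_e - gamma * r_e))
                              + a_xe * g_ee[b, n] + a_xi * g_ei[b, n] + aE_hemo)
                n_aI[b, n] = gIp * (1.0 - dt / tau_i) - a_xe * g_ie[b, n]
                as_[b, n] = nas; af[b, n] = naf; av[b, n] = nav; aq[b, n] = naq
            # coupling adjoint: n_aE += M^T a_c
            for n in range(N):
                acc = 0.0
                for i2 in range(N):
                    acc += M[b, i2, n] * a_c[b, i2]
                n_aE[b, n] += acc
        for b in range(B):
            for n in range(N):
                aE[b, n] = n_aE[b, n]
                aI[b, n] = n_aI[b, n]
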