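"""Compiled forward-Euler loops shared by all simulation front-ends.

Every kernel integrates in polar coordinates with an *unwrapped* phase:
``phi`` accumulates monotonically and is never reduced modulo 2*pi while the
simulation runs.  This matters because power coupling raises the complex
state to a non-integer exponent ``w_i/w_j``, which is single-valued only on a
tracked continuous phase.

Conventions used throughout:

* radius updates clamp ``r`` at 0 from below; wherever a coupling/forcing
  term divides by ``r`` the divisor is floored at ``R_MIN``;
* adapted natural frequencies are floored at ``OMEGA_MIN`` because power
  coupling divides by ``omega``;
* recording happens every ``stride`` steps plus the final step, so a
  trajectory always contains both the initial and terminal states.
"""

import numpy as np
from numba import njit

R_MIN = 1e-9
OMEGA_MIN = 1e-3
A_MIN = 1e-12

# coupling kinds
KIND_NONE = 0
KIND_REAL = 1
KIND_COMPLEX = 2
KIND_POWER = 3

# forcing kinds
FORCE_NONE = 0
FORCE_REAL = 1
FORCE_COMPLEX = 2


def n_records(n_steps: int, stride: int) -> int:
    """Number of samples a kernel records for ``n_steps`` Euler steps."""
    extra = 1 if n_steps % stride != 0 else 0
    return n_steps // stride + 1 + extra


def record_times(n_steps: int, stride: int, dt: float) -> np.ndarray:
    """Time stamps matching the kernel recording scheme."""
    steps = list(range(0, n_steps + 1, stride))
    if steps[-1] != n_steps:
        steps.append(n_steps)
    return np.asarray(steps, dtype=np.float64) * dt


@njit(cache=True)
def single_oscillator(alpha, beta1, beta2, eps_sat, omega0,
                      r0, phi0, dt, n_steps,
                      force_kind, I0, w_force, ph_force, eps,
                      adapt, omega_rule, stride):
    """One Hopf oscillator, optionally forced, optionally frequency-adaptive.

    ``omega_rule`` selects the form of the frequency update under complex
    forcing: 0 uses the closed sine form, 1 the Re/Im form; the two are
    algebraically identical.
    """
    extra = 1 if n_steps % stride != 0 else 0
    n_rec = n_steps // stride + 1 + extra
    rec_r = np.empty(n_rec)
    rec_p = np.empty(n_rec)
    rec_w = np.empty(n_rec)
    r = r0
    p = phi0
    w = omega0
    k = 0
    for step in range(n_steps + 1):
        if step % stride == 0 or step == n_steps:
            rec_r[k] = r
            rec_p[k] = p
            rec_w[k] = w
            k += 1
        if step == n_steps:
            break
        t = step * dt
        rdiv = r if r > R_MIN else R_MIN
        # radial field: alpha*r + beta1*r^3 + eps_sat*beta2*r^5/(1-eps_sat*r^2)
        dr = alpha * r + beta1 * r ** 3
        if beta2 != 0.0:
            dr += eps_sat * beta2 * r ** 5 / (1.0 - eps_sat * r * r)
        dp = w
        dw = 0.0
        if force_kind == 1:
            val = eps * I0 * np.sin(w_force * t + ph_force)
            dr += val * np.cos(p)
            dp += -val * np.sin(p) / rdiv
            if adapt:
                dw = -eps * I0 * np.sin(w_force * t + ph_force) * np.sin(p)
        elif force_kind == 2:
            arg = w_force * t + ph_force - p
            dr += eps * I0 * np.cos(arg)
            dp += eps * I0 * np.sin(arg) / rdiv
            if adapt:
                if omega_rule == 0:
                    dw = -eps * I0 * np.sin(p - w_force * t - ph_force)
                else:
                    re = I0 * np.cos(w_force * t + ph_force)
                    im = I0 * np.sin(w_force * t + ph_force)
                    dw = -eps * (re * np.sin(p) - im * np.cos(p))
        r = r + dt * dr
        if r < 0.0:
            r = 0.0
        p = p + dt * dp
        if adapt:
            w = w + dt * dw
            if w < OMEGA_MIN:
                w = OMEGA_MIN
    return rec_r, rec_p, rec_w


@njit(cache=True)
def hopf_network(mu, om0, r0, p0, A0, th0, kind,
                 fkind, I0, wf, pf, eps_force,
                 learn_theta, learn_A, learn_omega, tau_w,
                 dt, n_steps, stride, record_theta):
    """Batch of power/complex/real-coupled supercritical Hopf networks.

    Shapes: ``r0, p0, om0`` are (B, N); ``A0, th0`` are (B, N, N) with the
    directed weight (i, j) feeding oscillator i from oscillator j.  All B
    batch members share coupling kind, forcing and learning settings; they
    differ in initial conditions (used for basin scans).
    """
    B, N = r0.shape
    extra = 1 if n_steps % stride != 0 else 0
    n_rec = n_steps // stride + 1 + extra
    rec_r = np.empty((B, n_rec, N))
    rec_p = np.empty((B, n_rec, N))
    rec_w = np.empty((B, n_rec, N))
    n_rec_th = n_rec if record_theta else 1
    rec_th = np.empty((B, n_rec_th, N, N))
    rec_Am = np.empty((B, n_rec_th, N, N))
    r = r0.copy()
    p = p0.copy()
    om = om0.copy()
    A = A0.copy()
    th = th0.copy()
    dr = np.empty(N)
    dp = np.empty(N)
    dw = np.empty(N)
    dth = np.zeros((N, N))
    dA = np.zeros((N, N))
    for b in range(B):
        rb = r[b]
        pb = p[b]
        wb = om[b]
        Ab = A[b]
        thb = th[b]
        k = 0
        for step in range(n_steps + 1):
            if step % stride == 0 or step == n_steps:
                for i in range(N):
                    rec_r[b, k, i] = rb[i]
                    rec_p[b, k, i] = pb[i]
                    rec_w[b, k, i] = wb[i]
                if record_theta:
                    for i in range(N):
                        for j in range(N):
                            rec_th[b, k, i, j] = thb[i, j]
                            rec_Am[b, k, i, j] = Ab[i, j]
                k += 1
            if step == n_steps:
                break
            t = step * dt
            for i in range(N):
                ri = rb[i]
                pi = pb[i]
                wi = wb[i]
                rdiv = ri if ri > R_MIN else R_MIN
                drv = (mu[i] - ri * ri) * ri
                dpv = wi
                if kind == 3:
                    for j in range(N):
                        if j == i:
                            continue
                        a = Ab[i, j]
                        if a == 0.0:
                            continue
                        wj = wb[j]
                        rj = rb[j]
                        if rj < R_MIN:
                            rj = R_MIN
                        amp = a * rj ** (wi / wj)
                        arg = wi * pb[j] / wj - pi + thb[i, j] / wj
                        drv += amp * np.cos(arg)
                        dpv += amp * np.sin(arg) / rdiv
                elif kind == 2:
                    for j in range(N):
                        if j == i:
                            continue
                        a = Ab[i, j]
                        if a == 0.0:
                            continue
                        arg = pb[j] - pi + thb[i, j]
                        drv += a * rb[j] * np.cos(arg)
                        dpv += a * rb[j] * np.sin(arg) / rdiv
                elif kind == 1:
                    for j in range(N):
                        if j == i:
                            continue
                        a = Ab[i, j]
                        if a == 0.0:
                            continue
                        # signed real coefficient W = A*cos(theta)
                        x = a * np.cos(thb[i, j]) * rb[j] * np.cos(pb[j])
                        drv += x * np.cos(pi)
                        dpv += -x * np.sin(pi) / rdiv
                fk = fkind[i]
                dwv = 0.0
                if fk == 1:
                    val = eps_force * I0[i] * np.sin(wf[i] * t + pf[i])
                    drv += val * np.cos(pi)
                    dpv += -val * np.sin(pi) / rdiv
                    if learn_omega:
                        dwv = -eps_force * I0[i] * np.sin(wf[i] * t + pf[i]) * np.sin(pi)
                elif fk == 2:
                    arg = wf[i] * t + pf[i] - pi
                    drv += eps_force * I0[i] * np.cos(arg)
                    dpv += eps_force * I0[i] * np.sin(arg) / rdiv
                    if learn_omega:
                        dwv = -eps_force * I0[i] * np.sin(pi - wf[i] * t - pf[i])
                dr[i] = drv
                dp[i] = dpv
                dw[i] = dwv
            if learn_theta or learn_A:
                for i in range(N):
                    for j in range(N):
                        if i == j:
                            continue
                        a = Ab[i, j]
                        if a == 0.0:
                            continue
                        if kind == 3:
                            wi = wb[i]
                            wj = wb[j]
                            rj = rb[j]
                            if rj < R_MIN:
                                rj = R_MIN
                            amp = rb[i] * rj ** (wi / wj)
                            arg = pb[i] - wi * pb[j] / wj - thb[i, j] / wj
                        else:
                            amp = rb[i] * rb[j]
                            arg = pb[i] - pb[j] - thb[i, j]
                            wj = 1.0
                        if learn_theta:
                            dth[i, j] = wj * amp * np.sin(arg) / (a * tau_w)
                        if learn_A:
                            dA[i, j] = (-a + amp * np.cos(arg)) / tau_w
            for i in range(N):
                rb[i] = rb[i] + dt * dr[i]
                if rb[i] < 0.0:
                    rb[i] = 0.0
                pb[i] = pb[i] + dt * dp[i]
                if learn_omega:
                    wb[i] = wb[i] + dt * dw[i]
                    if wb[i] < OMEGA_MIN:
                        wb[i] = OMEGA_MIN
            if learn_theta or learn_A:
                for i in range(N):
                    for j in range(N):
                        if i == j or Ab[i, j] == 0.0:
                            continue
                        if learn_theta:
                            thb[i, j] = thb[i, j] + dt * dth[i, j]
                        if learn_A:
                            Ab[i, j] = Ab[i, j] + dt * dA[i, j]
                            if Ab[i, j] < A_MIN:
                                Ab[i, j] = A_MIN
        if not record_theta:
            for i in range(N):
                for j in range(N):
                    rec_th[b, 0, i, j] = thb[i, j]
                    rec_Am[b, 0, i, j] = Ab[i, j]
    return rec_r, rec_p, rec_w, rec_th, rec_Am


@njit(cache=True)
def kuramoto_network(om, p0, K, th, kind,
                     fkind, I0, wf, pf,
                     dt, n_steps, stride):
    """Phase-only oscillators; ``kind`` is real (sin of plain phase
    difference) or power (sin of scaled normalized phase difference)."""
    B, N = p0.shape
    extra = 1 if n_steps % stride != 0 else 0
    n_rec = n_steps // stride + 1 + extra
    rec_p = np.empty((B, n_rec, N))
    p = p0.copy()
    dp = np.empty(N)
    for b in range(B):
        pb = p[b]
        k = 0
        for step in range(n_steps + 1):
            if step % stride == 0 or step == n_steps:
                for i in range(N):
                    rec_p[b, k, i] = pb[i]
                k += 1
            if step == n_steps:
                break
            t = step * dt
            for i in range(N):
                wi = om[i]
                dpv = wi
                for j in range(N):
                    if j == i:
                        continue
                    a = K[i, j]
                    if a == 0.0:
                        continue
                    if kind == 3:
                        wj = om[j]
                        dpv += a * np.sin(wi * pb[j] / wj - pb[i] + th[i, j] / wj)
                    else:
                        dpv += a * np.sin(pb[j] - pb[i])
                if fkind[i] == 2:
                    dpv += I0[i] * np.sin(wf[i] * t + pf[i] - pb[i])
                dp[i] = dpv
            for i in range(N):
                pb[i] = pb[i] + dt * dp[i]
    return rec_p


@njit(cache=True)
def reservoir_train(is_complex, D_re, D_im, mu, om0, r0, p0, a0,
                    A0, th0, eps, eta_w, eta_a, tau_w, learn_theta,
                    dt, n_steps, sig_len, stride, record_theta,
                    readout_with_r, comp_a, comp_w, comp_p, t0, idx0):
    """Error-driven reservoir of adaptive-frequency Hopf oscillators.

    The teaching signal ``D`` has ``sig_len`` samples; index wraps around so
    the signal restarts each epoch while oscillator state carries over.
    When ``comp_a`` is non-empty the signal is instead synthesized exactly
    as a sum of sinusoids ``sum_k a_k cos(w_k t + p_k)`` (or complex
    exponentials), which avoids wrap discontinuities for infinite-duration
    periodic teaching signals.  Records omega/alpha traces, output and error
    traces, the final lateral weight angles, and the mean absolute error per
    epoch.
    """
    N = r0.shape[0]
    extra = 1 if n_steps % stride != 0 else 0
    n_rec = n_steps // stride + 1 + extra
    rec_w = np.empty((n_rec, N))
    rec_a = np.empty((n_rec, N))
    rec_r = np.empty((n_rec, N))
    rec_p = np.empty((n_rec, N))
    rec_P = np.empty((n_rec, 2))
    rec_e = np.empty((n_rec, 2))
    n_rec_th = n_rec if record_theta else 1
    rec_th = np.empty((n_rec_th, N, N))
    n_epochs = (n_steps + sig_len - 1) // sig_len
    err_sum = np.zeros(n_epochs)
    err_cnt = np.zeros(n_epochs)
    r = r0.copy()
    p = p0.copy()
    w = om0.copy()
    al = a0.copy()
    A = A0.copy()
    th = th0.copy()
    dr = np.empty(N)
    dp = np.empty(N)
    dw = np.empty(N)
    da = np.empty(N)
    dth = np.zeros((N, N))
    n_comp = comp_a.shape[0]
    k = 0
    for step in range(n_steps + 1):
        # teaching sample: exact synthesis or table lookup with epoch wrap
        if n_comp > 0:
            t_now = t0 + step * dt
            d_re = 0.0
            d_im = 0.0
            if is_complex:
                for c in range(n_comp):
                    ang = comp_w[c] * t_now + comp_p[c]
                    d_re += comp_a[c] * np.cos(ang)
                    d_im += comp_a[c] * np.sin(ang)
            else:
                for c in range(n_comp):
                    d_re += comp_a[c] * np.cos(comp_w[c] * t_now + comp_p[c])
        else:
            idx = (idx0 + step) % sig_len
            d_re = D_re[idx]
            d_im = D_im[idx]
        # readout and error
        P_re = 0.0
        P_im = 0.0
        if is_complex:
            for i in range(N):
                P_re += al[i] * r[i] * np.cos(p[i])
                P_im += al[i] * r[i] * np.sin(p[i])
        elif readout_with_r:
            for i in range(N):
                P_re += al[i] * r[i] * np.cos(p[i])
        else:
            for i in range(N):
                P_re += al[i] * np.cos(p[i])
        e_re = d_re - P_re
        e_im = d_im - P_im if is_complex else 0.0
        if step % stride == 0 or step == n_steps:
            for i in range(N):
                rec_w[k, i] = w[i]
                rec_a[k, i] = al[i]
                rec_r[k, i] = r[i]
                rec_p[k, i] = p[i]
            rec_P[k, 0] = P_re
            rec_P[k, 1] = P_im
            rec_e[k, 0] = e_re
            rec_e[k, 1] = e_im
            if record_theta:
                for i in range(N):
                    for j in range(N):
                        rec_th[k, i, j] = th[i, j]
            k += 1
        if step == n_steps:
            break
        ep = step // sig_len
        err_sum[ep] += np.sqrt(e_re * e_re + e_im * e_im)
        err_cnt[ep] += 1.0
        for i in range(N):
            ri = r[i]
            pi = p[i]
            wi = w[i]
            rdiv = ri if ri > R_MIN else R_MIN
            drv = (mu[i] - ri * ri) * ri
            dpv = wi
            for j in range(N):
                if j == i:
                    continue
                a = A[i, j]
                if a == 0.0:
                    continue
                wj = w[j]
                rj = r[j]
                if rj < R_MIN:
                    rj = R_MIN
                amp = a * rj ** (wi / wj)
                arg = wi * p[j] / wj - pi + th[i, j] / wj
                drv += amp * np.cos(arg)
                dpv += amp * np.sin(arg) / rdiv
            cpi = np.cos(pi)
            spi = np.sin(pi)
            if is_complex:
                drv += eps * (e_re * cpi + e_im * spi)
                dpv += eps * (e_im * cpi - e_re * spi) / rdiv
                dw[i] = -eta_w * (e_re * spi - e_im * cpi)
                da[i] = eta_a * (e_re * ri * cpi + e_im * ri * spi)
            else:
                drv += eps * e_re * cpi
                dpv += -eps * e_re * spi / rdiv
                dw[i] = -eta_w * e_re * spi
                da[i] = eta_a * e_re * ri * cpi
            dr[i] = drv
            dp[i] = dpv
        if learn_theta:
            for i in range(N):
                for j in range(N):
                    if i == j:
                        continue
                    a = A[i, j]
                    if a == 0.0:
                        continue
                    wi = w[i]
                    wj = w[j]
                    rj = r[j]
                    if rj < R_MIN:
                        rj = R_MIN
                    amp = r[i] * rj ** (wi / wj)
                    arg = p[i] - wi * p[j] / wj - th[i, j] / wj
                    dth[i, j] = wj * amp * np.sin(arg) / (a * tau_w)
        for i in range(N):
            r[i] = r[i] + dt * dr[i]
            if r[i] < 0.0:
                r[i] = 0.0
            p[i] = p[i] + dt * dp[i]
            w[i] = w[i] + dt * dw[i]
            if w[i] < OMEGA_MIN:
                w[i] = OMEGA_MIN
            al[i] = al[i] + dt * da[i]
        if learn_theta:
            for i in range(N):
                for j in range(N):
                    if i != j and A[i, j] != 0.0:
                        th[i, j] = th[i, j] + dt * dth[i, j]
    if not record_theta:
        for i in range(N):
            for j in range(N):
                rec_th[0, i, j] = th[i, j]
    epoch_err = err_sum / np.maximum(err_cnt, 1.0)
    return rec_r, rec_p, rec_w, rec_a, rec_P, rec_e, rec_th, epoch_err
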