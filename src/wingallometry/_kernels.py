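"""Compiled log-posterior gradient kernel.

A numba translation of ``_LogPosterior.logp_and_grad_numpy`` operating on the
flat unconstrained vector and the sufficient-statistic arrays. The numpy
implementation in :mod:`wingallometry.model` is the reference; the two are
asserted equal in the test suite, and the model falls back to numpy when
numba is unavailable.

Parameter layout (offsets into q): b0 (J), b1 (J), I0 (S*C), I1 (S*C),
n0 (S), n1 (S), mu0 (C), mu1 (C), m_n0, m_n1, lt0, lt1, lsw, lsn0, lsn1,
ls0 (C), ls1 (C). ``cb``/``ci``/``cn`` select centered parameterizations of
the beta / I / n levels.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is normally present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap

_LOG_2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def logp_grad_kernel(q, J, S, C, cb, ci, cn, prior_only,
                     N, Sz, Szz, Sw, Swz, Sww, G, sp_idx,
                     n_obs, ns2, cs2, log_cs_const):
    ob0 = 0
    ob1 = J
    oI0 = 2 * J
    oI1 = 2 * J + S * C
    on0 = 2 * J + 2 * S * C
    on1 = on0 + S
    omu0 = on1 + S
    omu1 = omu0 + C
    omn0 = omu1 + C
    omn1 = omn0 + 1
    olt0 = omn1 + 1
    olt1 = olt0 + 1
    olsw = olt1 + 1
    olsn0 = olsw + 1
    olsn1 = olsn0 + 1
    ols0 = olsn1 + 1
    ols1 = ols0 + C
    dim = ols1 + C
    grad = np.zeros(dim)

    # off-support guard: extreme log scales would overflow exp(); the block
    # from lt0 to the end of ls1 is exactly the log-scale coordinates
    for i in range(olt0, dim):
        if abs(q[i]) > 50.0:
            return -np.inf, grad

    tau0 = math.exp(q[olt0])
    tau1 = math.exp(q[olt1])
    sigma_w = math.exp(q[olsw])
    s_n0 = math.exp(q[olsn0])
    s_n1 = math.exp(q[olsn1])
    sigma0 = np.empty(C)
    sigma1 = np.empty(C)
    for c in range(C):
        sigma0[c] = math.exp(q[ols0 + c])
        sigma1[c] = math.exp(q[ols1 + c])
    mu0 = q[omu0:omu0 + C]
    mu1 = q[omu1:omu1 + C]
    m_n0 = q[omn0]
    m_n1 = q[omn1]

    I0 = np.empty((S, C))
    I1 = np.empty((S, C))
    for s in range(S):
        for c in range(C):
            if ci:
                I0[s, c] = q[oI0 + s * C + c]
                I1[s, c] = q[oI1 + s * C + c]
            else:
                I0[s, c] = mu0[c] + sigma0[c] * q[oI0 + s * C + c]
                I1[s, c] = mu1[c] + sigma1[c] * q[oI1 + s * C + c]
    n0 = np.empty(S)
    n1 = np.empty(S)
    for s in range(S):
        if cn:
            n0[s] = q[on0 + s]
            n1[s] = q[on1 + s]
        else:
            n0[s] = m_n0 + s_n0 * q[on0 + s]
            n1[s] = m_n1 + s_n1 * q[on1 + s]

    bhat0 = np.empty(J)
    bhat1 = np.empty(J)
    beta0 = np.empty(J)
    beta1 = np.empty(J)
    for j in range(J):
        si = sp_idx[j]
        acc0 = 0.0
        acc1 = 0.0
        for c in range(C):
            acc0 += I0[si, c] * G[j, c]
            acc1 += I1[si, c] * G[j, c]
        bhat0[j] = acc0
        bhat1[j] = acc1
        if cb:
            beta0[j] = q[ob0 + j]
            beta1[j] = q[ob1 + j]
        else:
            beta0[j] = acc0 + tau0 * q[ob0 + j]
            beta1[j] = acc1 + tau1 * q[ob1 + j]

    logp = 0.0
    dbeta0 = np.zeros(J)
    dbeta1 = np.zeros(J)
    dn0s = np.zeros(S)
    dn1s = np.zeros(S)
    dlsw_lik = 0.0
    if not prior_only:
        inv_var = 1.0 / (sigma_w * sigma_w)
        ssr = 0.0
        for j in range(J):
            si = sp_idx[j]
            for sx in range(2):
                a = beta0[j] + (n0[si] if sx == 1 else 0.0)
                b = beta1[j] + (n1[si] if sx == 1 else 0.0)
                rsum = Sw[j, sx] - a * N[j, sx] - b * Sz[j, sx]
                rz = Swz[j, sx] - a * Sz[j, sx] - b * Szz[j, sx]
                ssr += (Sww[j, sx] - 2.0 * a * Sw[j, sx]
                        - 2.0 * b * Swz[j, sx] + a * a * N[j, sx]
                        + 2.0 * a * b * Sz[j, sx] + b * b * Szz[j, sx])
                dlla = rsum * inv_var
                dllb = rz * inv_var
                dbeta0[j] += dlla
                dbeta1[j] += dllb
                if sx == 1:
                    dn0s[si] += dlla
                    dn1s[si] += dllb
        logp += -0.5 * n_obs * _LOG_2PI - n_obs * q[olsw] - 0.5 * ssr * inv_var
        dlsw_lik = -n_obs + ssr * inv_var

    # ---- beta level ----
    dbhat0 = np.empty(J)
    dbhat1 = np.empty(J)
    dlt0_level = 0.0
    dlt1_level = 0.0
    if cb:
        s0 = 0.0
        s1 = 0.0
        for j in range(J):
            rb0 = (beta0[j] - bhat0[j]) / tau0
            rb1 = (beta1[j] - bhat1[j]) / tau1
            s0 += rb0 * rb0
            s1 += rb1 * rb1
            grad[ob0 + j] = dbeta0[j] - rb0 / tau0
            grad[ob1 + j] = dbeta1[j] - rb1 / tau1
            dbhat0[j] = rb0 / tau0
            dbhat1[j] = rb1 / tau1
        logp += (-0.5 * s0 - 0.5 * s1 - J * (q[olt0] + q[olt1])
                 - J * _LOG_2PI)
        dlt0_level = s0 - J
        dlt1_level = s1 - J
    else:
        s0 = 0.0
        s1 = 0.0
        for j in range(J):
            v0 = q[ob0 + j]
            v1 = q[ob1 + j]
            s0 += v0 * v0
            s1 += v1 * v1
            grad[ob0 + j] = -v0 + tau0 * dbeta0[j]
            grad[ob1 + j] = -v1 + tau1 * dbeta1[j]
            dbhat0[j] = dbeta0[j]
            dbhat1[j] = dbeta1[j]
            dlt0_level += dbeta0[j] * v0
            dlt1_level += dbeta1[j] * v1
        dlt0_level *= tau0
        dlt1_level *= tau1
        logp += -0.5 * s0 - 0.5 * s1 - J * _LOG_2PI

    dI0n = np.zeros((S, C))
    dI1n = np.zeros((S, C))
    for j in range(J):
        si = sp_idx[j]
        for c in range(C):
            dI0n[si, c] += dbhat0[j] * G[j, c]
            dI1n[si, c] += dbhat1[j] * G[j, c]

    # ---- I level ----
    dls0 = np.zeros(C)
    dls1 = np.zeros(C)
    dmu0 = np.zeros(C)
    dmu1 = np.zeros(C)
    if ci:
        tot0 = 0.0
        tot1 = 0.0
        for s in range(S):
            for c in range(C):
                r0 = (I0[s, c] - mu0[c]) / sigma0[c]
                r1 = (I1[s, c] - mu1[c]) / sigma1[c]
                tot0 += r0 * r0
                tot1 += r1 * r1
                grad[oI0 + s * C + c] = dI0n[s, c] - r0 / sigma0[c]
                grad[oI1 + s * C + c] = dI1n[s, c] - r1 / sigma1[c]
                dmu0[c] += r0 / sigma0[c]
                dmu1[c] += r1 / sigma1[c]
                dls0[c] += r0 * r0 - 1.0
                dls1[c] += r1 * r1 - 1.0
        lsum = 0.0
        for c in range(C):
            lsum += q[ols0 + c] + q[ols1 + c]
        logp += -0.5 * tot0 - 0.5 * tot1 - S * lsum - S * C * _LOG_2PI
    else:
        tot = 0.0
        for s in range(S):
            for c in range(C):
                v0 = q[oI0 + s * C + c]
                v1 = q[oI1 + s * C + c]
                tot += v0 * v0 + v1 * v1
                grad[oI0 + s * C + c] = -v0 + sigma0[c] * dI0n[s, c]
                grad[oI1 + s * C + c] = -v1 + sigma1[c] * dI1n[s, c]
                dmu0[c] += dI0n[s, c]
                dmu1[c] += dI1n[s, c]
                dls0[c] += sigma0[c] * dI0n[s, c] * v0
                dls1[c] += sigma1[c] * dI1n[s, c] * v1
        logp += -0.5 * tot - S * C * _LOG_2PI

    mus = 0.0
    for c in range(C):
        mus += mu0[c] * mu0[c] + mu1[c] * mu1[c]
        grad[omu0 + c] = dmu0[c] - mu0[c] / ns2
        grad[omu1 + c] = dmu1[c] - mu1[c] / ns2
    logp += -0.5 * mus / ns2 - 2.0 * C * (0.5 * _LOG_2PI + 0.5 * math.log(ns2))

    # ---- n level ----
    dmn0 = 0.0
    dmn1 = 0.0
    dlsn0_level = 0.0
    dlsn1_level = 0.0
    if cn:
        t0 = 0.0
        t1 = 0.0
        for s in range(S):
            rn0 = (n0[s] - m_n0) / s_n0
            rn1 = (n1[s] - m_n1) / s_n1
            t0 += rn0 * rn0
            t1 += rn1 * rn1
            grad[on0 + s] = dn0s[s] - rn0 / s_n0
            grad[on1 + s] = dn1s[s] - rn1 / s_n1
            dmn0 += rn0 / s_n0
            dmn1 += rn1 / s_n1
        logp += (-0.5 * t0 - 0.5 * t1 - S * (q[olsn0] + q[olsn1])
                 - S * _LOG_2PI)
        dlsn0_level = t0 - S
        dlsn1_level = t1 - S
    else:
        t = 0.0
        for s in range(S):
            v0 = q[on0 + s]
            v1 = q[on1 + s]
            t += v0 * v0 + v1 * v1
            grad[on0 + s] = -v0 + s_n0 * dn0s[s]
            grad[on1 + s] = -v1 + s_n1 * dn1s[s]
            dmn0 += dn0s[s]
            dmn1 += dn1s[s]
            dlsn0_level += s_n0 * dn0s[s] * v0
            dlsn1_level += s_n1 * dn1s[s] * v1
        logp += -0.5 * t - S * _LOG_2PI
    logp += (-0.5 * (m_n0 * m_n0 + m_n1 * m_n1) / ns2
             - 2.0 * (0.5 * _LOG_2PI + 0.5 * math.log(ns2)))
    grad[omn0] = dmn0 - m_n0 / ns2
    grad[omn1] = dmn1 - m_n1 / ns2

    # ---- half-Cauchy priors with log Jacobian ----
    logp += log_cs_const - math.log1p(tau0 * tau0 / cs2) + q[olt0]
    grad[olt0] = dlt0_level + 1.0 - 2.0 * tau0 * tau0 / (cs2 + tau0 * tau0)
    logp += log_cs_const - math.log1p(tau1 * tau1 / cs2) + q[olt1]
    grad[olt1] = dlt1_level + 1.0 - 2.0 * tau1 * tau1 / (cs2 + tau1 * tau1)
    logp += log_cs_const - math.log1p(sigma_w * sigma_w / cs2) + q[olsw]
    grad[olsw] = dlsw_lik + 1.0 - 2.0 * sigma_w * sigma_w / (cs2 + sigma_w * sigma_w)
    logp += log_cs_const - math.log1p(s_n0 * s_n0 / cs2) + q[olsn0]
    grad[olsn0] = dlsn0_level + 1.0 - 2.0 * s_n0 * s_n0 / (cs2 + s_n0 * s_n0)
    logp += log_cs_const - math.log1p(s_n1 * s_n1 / cs2) + q[olsn1]
    grad[olsn1] = dlsn1_level + 1.0 - 2.0 * s_n1 * s_n1 / (cs2 + s_n1 * s_n1)
    for c in range(C):
        logp += log_cs_const - math.log1p(sigma0[c] ** 2 / cs2) + q[ols0 + c]
        grad[ols0 + c] = (dls0[c] + 1.0
                          - 2.0 * sigma0[c] ** 2 / (cs2 + sigma0[c] ** 2))
        logp += log_cs_const - math.log1p(sigma1[c] ** 2 / cs2) + q[ols1 + c]
        grad[ols1 + c] = (dls1[c] + 1.0
                          - 2.0 * sigma1[c] ** 2 / (cs2 + sigma1[c] ** 2))
    return logp, grad
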