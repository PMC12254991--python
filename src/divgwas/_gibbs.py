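"""Numba Gibbs-sampler kernels for the BayesB multiple-marker regression.

Two fully scalarized kernels (univariate / bivariate) — the per-locus sweep
runs ~k x n_iter times, so the 2x2 linear algebra is hand-coded to avoid
small-array allocation in the hot loop.

Update order per iteration: missing-residual augmentation, fixed effects
(flat prior), common-litter effects + C, polygenic effects + U, locus sweep
(indicator configuration drawn with the effect integrated out analytically,
then the effect from its Gaussian full conditional; inactive components from
the prior conditional; per-locus G_j from its inverse-Wishart full
conditional), shared-G update (BayesC-like mode), residual covariance R.

Inverse-Wishart convention: IW(nu, Psi) has mean Psi / (nu - p - 1); a
component with prior IW(nu0, Psi0) and q observed outer products has full
conditional IW(nu0 + q, Psi0 + sum of outer products).
"""

import numpy as np
from numba import njit

# indicator configurations, bivariate: 0=(0,0) 1=(1,0) 2=(0,1) 3=(1,1)


@njit(cache=True, inline="always")
def _iw1(df, psi):
    # scalar inverse-Wishart == scaled inverse chi-square: psi / chi2(df)
    return psi / (2.0 * np.random.standard_gamma(0.5 * df))


@njit(cache=True, inline="always")
def _iw2(df, p00, p01, p11):
    # G ~ IW(df, Psi): draw W ~ Wishart(df, Psi^-1) by Bartlett, return W^-1
    det = p00 * p11 - p01 * p01
    v00 = p11 / det
    v01 = -p01 / det
    v11 = p00 / det
    l00 = np.sqrt(v00)
    l10 = v01 / l00
    l11 = np.sqrt(v11 - l10 * l10)
    a00 = np.sqrt(2.0 * np.random.standard_gamma(0.5 * df))
    a11 = np.sqrt(2.0 * np.random.standard_gamma(0.5 * (df - 1.0)))
    a10 = np.random.standard_normal()
    b00 = l00 * a00
    b10 = l10 * a00 + l11 * a10
    b11 = l11 * a11
    w00 = b00 * b00
    w01 = b00 * b10
    w11 = b10 * b10 + b11 * b11
    detw = w00 * w11 - w01 * w01
    return w11 / detw, -w01 / detw, w00 / detw


@njit(cache=True)
def kernel_uni(seed, n_iter, burn_in, thin,
               E, miss,                      # (n,), (n,) uint8
               XT, xtx,                      # (p, n), (p,)
               lit_ptr, lit_rows,            # CSR litter -> record rows
               an_ptr, an_rows, Ainv,        # CSR animal -> record rows; (m, m)
               ZT, zz,                       # (k, n) centered, (k,)
               r0, nu_r, c0, nu_c, u0v, nu_u, g0, nu_g,
               lp0, lp1,                     # log prior mass: excluded / included
               per_locus,
               alpha_s, delta_s, b_s, c_s, u_s, R_s, C_s, U_s, G_s, E_s):
    np.random.seed(seed)
    n = E.shape[0]
    p = XT.shape[0]
    k = ZT.shape[0]
    L = lit_ptr.shape[0] - 1
    m = an_ptr.shape[0] - 1
    b = np.zeros(p)
    c = np.zeros(L)
    u = np.zeros(m)
    al = np.zeros(k)
    dl = np.zeros(k, dtype=np.uint8)
    Gj = np.full(k, g0)
    Rv, Cv, Uv, Gshared = r0, c0, u0v, g0
    s_ix = 0
    for it in range(n_iter):
        Ri = 1.0 / Rv
        # missing augmentation
        sr = np.sqrt(Rv)
        for i in range(n):
            if miss[i]:
                E[i] = sr * np.random.standard_normal()
        # fixed effects, flat prior
        for cx in range(p):
            if xtx[cx] <= 0.0:
                continue
            d = 0.0
            for i in range(n):
                d += XT[cx, i] * E[i]
            rhs = Ri * (d + xtx[cx] * b[cx])
            prec = xtx[cx] * Ri
            newb = rhs / prec + np.random.standard_normal() / np.sqrt(prec)
            diff = newb - b[cx]
            b[cx] = newb
            for i in range(n):
                E[i] -= XT[cx, i] * diff
        # litter effects + C
        if L > 0:
            Ci = 1.0 / Cv
            for l in range(L):
                nl = lit_ptr[l + 1] - lit_ptr[l]
                s = 0.0
                for ii in range(lit_ptr[l], lit_ptr[l + 1]):
                    s += E[lit_rows[ii]]
                s += nl * c[l]
                prec = nl * Ri + Ci
                newc = Ri * s / prec + np.random.standard_normal() / np.sqrt(prec)
                diff = newc - c[l]
                c[l] = newc
                for ii in range(lit_ptr[l], lit_ptr[l + 1]):
                    E[lit_rows[ii]] -= diff
            sc = c0
            for l in range(L):
                sc += c[l] * c[l]
            Cv = _iw1(nu_c + L, sc)
        # polygenic + U
        if m > 0:
            Ui = 1.0 / Uv
            for a in range(m):
                nr = an_ptr[a + 1] - an_ptr[a]
                s = 0.0
                for ii in range(an_ptr[a], an_ptr[a + 1]):
                    s += E[an_rows[ii]]
                s += nr * u[a]
                w = 0.0
                for bx in range(m):
                    w += Ainv[a, bx] * u[bx]
                w -= Ainv[a, a] * u[a]
                prec = nr * Ri + Ainv[a, a] * Ui
                rhs = Ri * s - Ui * w
                newu = rhs / prec + np.random.standard_normal() / np.sqrt(prec)
                diff = newu - u[a]
                u[a] = newu
                for ii in range(an_ptr[a], an_ptr[a + 1]):
                    E[an_rows[ii]] -= diff
            su = u0v
            for a in range(m):
                t0 = 0.0
                for bx in range(m):
                    t0 += Ainv[a, bx] * u[bx]
                su += u[a] * t0
            Uv = _iw1(nu_u + m, su)
        # locus sweep
        acc = 0.0
        for j in range(k):
            g = Gj[j] if per_locus else Gshared
            s = zz[j] * al[j]
            for i in range(n):
                s += ZT[j, i] * E[i]
            uq = Ri * s
            P = zz[j] * Ri + 1.0 / g
            sc1 = lp1 - 0.5 * np.log(g) - 0.5 * np.log(P) + 0.5 * uq * uq / P
            mx = lp0 if lp0 > sc1 else sc1
            w0 = np.exp(lp0 - mx)
            w1 = np.exp(sc1 - mx)
            incl = np.random.random() * (w0 + w1) < w1
            if incl:
                a_draw = uq / P + np.random.standard_normal() / np.sqrt(P)
            else:
                a_draw = np.sqrt(g) * np.random.standard_normal()
            masked = a_draw if incl else 0.0
            dl[j] = 1 if incl else 0
            if masked != al[j]:
                diff = masked - al[j]
                for i in range(n):
                    E[i] -= ZT[j, i] * diff
                al[j] = masked
            if per_locus:
                Gj[j] = _iw1(nu_g + 1.0, g0 + a_draw * a_draw)
            else:
                acc += a_draw * a_draw
        if not per_locus:
            Gshared = _iw1(nu_g + k, g0 + acc)
        # residual variance
        sr2 = r0
        for i in range(n):
            sr2 += E[i] * E[i]
        Rv = _iw1(nu_r + n, sr2)
        # save
        if it + 1 > burn_in and (it + 1 - burn_in) % thin == 0:
            for j in range(k):
                alpha_s[s_ix, j, 0] = al[j]
                delta_s[s_ix, j, 0] = dl[j]
            for cx in range(p):
                b_s[s_ix, cx, 0] = b[cx]
            for l in range(L):
                c_s[s_ix, l, 0] = c[l]
            for a in range(m):
                u_s[s_ix, a, 0] = u[a]
            R_s[s_ix, 0, 0] = Rv
            C_s[s_ix, 0, 0] = Cv
            U_s[s_ix, 0, 0] = Uv
            if per_locus:
                gm = 0.0
                for j in range(k):
                    gm += Gj[j]
                G_s[s_ix, 0, 0] = gm / k if k > 0 else _iw1(nu_g, g0)
            else:
                G_s[s_ix, 0, 0] = Gshared
            for i in range(n):
                E_s[s_ix, i, 0] = E[i]
            s_ix += 1


@njit(cache=True)
def kernel_biv(seed, n_iter, burn_in, thin,
               ET, miss,                     # (2, n), (2, n) uint8
               XT, xtx,
               lit_ptr, lit_rows,
               an_ptr, an_rows, Ainv,
               ZT, zz,
               R0m, nu_r, C0m, nu_c, U0m, nu_u, G0m, nu_g,  # (2,2) each
               lp,                           # (4,) log config mass
               per_locus,
               alpha_s, delta_s, b_s, c_s, u_s, R_s, C_s, U_s, G_s, E_s):
    np.random.seed(seed)
    n = ET.shape[1]
    p = XT.shape[0]
    k = ZT.shape[0]
    L = lit_ptr.shape[0] - 1
    m = an_ptr.shape[0] - 1
    b = np.zeros((p, 2))
    c = np.zeros((L, 2))
    u = np.zeros((m, 2))
    al0 = np.zeros(k)
    al1 = np.zeros(k)
    dl0 = np.zeros(k, dtype=np.uint8)
    dl1 = np.zeros(k, dtype=np.uint8)
    g0_00, g0_01, g0_11 = G0m[0, 0], G0m[0, 1], G0m[1, 1]
    Gj00 = np.full(k, g0_00)
    Gj01 = np.full(k, g0_01)
    Gj11 = np.full(k, g0_11)
    R00, R01, R11 = R0m[0, 0], R0m[0, 1], R0m[1, 1]
    C00, C01, C11 = C0m[0, 0], C0m[0, 1], C0m[1, 1]
    U00, U01, U11 = U0m[0, 0], U0m[0, 1], U0m[1, 1]
    sG00, sG01, sG11 = g0_00, g0_01, g0_11
    lp0, lp1, lp2, lp3 = lp[0], lp[1], lp[2], lp[3]
    s_ix = 0
    for it in range(n_iter):
        detR = R00 * R11 - R01 * R01
        Ri00 = R11 / detR
        Ri01 = -R01 / detR
        Ri11 = R00 / detR
        # missing augmentation from the residual conditional
        lr00 = np.sqrt(R00)
        lr10 = R01 / lr00
        lr11 = np.sqrt(max(R11 - lr10 * lr10, 1e-300))
        for i in range(n):
            m0 = miss[0, i]
            m1 = miss[1, i]
            if m0 and m1:
                z0 = np.random.standard_normal()
                z1 = np.random.standard_normal()
                ET[0, i] = lr00 * z0
                ET[1, i] = lr10 * z0 + lr11 * z1
            elif m0:
                cv = max(R00 - R01 * R01 / R11, 1e-300)
                ET[0, i] = R01 / R11 * ET[1, i] + np.sqrt(cv) * np.random.standard_normal()
            elif m1:
                cv = max(R11 - R01 * R01 / R00, 1e-300)
                ET[1, i] = R01 / R00 * ET[0, i] + np.sqrt(cv) * np.random.standard_normal()
        # fixed effects (each coefficient affects one trait), flat prior
        for cx in range(p):
            if xtx[cx] <= 0.0:
                continue
            for t_ in range(2):
                d0 = 0.0
                d1 = 0.0
                for i in range(n):
                    d0 += XT[cx, i] * ET[0, i]
                    d1 += XT[cx, i] * ET[1, i]
                if t_ == 0:
                    rhs = Ri00 * (d0 + xtx[cx] * b[cx, 0]) + Ri01 * d1
                    prec = xtx[cx] * Ri00
                else:
                    rhs = Ri01 * d0 + Ri11 * (d1 + xtx[cx] * b[cx, 1])
                    prec = xtx[cx] * Ri11
                newb = rhs / prec + np.random.standard_normal() / np.sqrt(prec)
                diff = newb - b[cx, t_]
                b[cx, t_] = newb
                for i in range(n):
                    ET[t_, i] -= XT[cx, i] * diff
        # litter pairs + C
        if L > 0:
            detC = C00 * C11 - C01 * C01
            Ci00 = C11 / detC
            Ci01 = -C01 / detC
            Ci11 = C00 / detC
            for l in range(L):
                nl = lit_ptr[l + 1] - lit_ptr[l]
                s0 = 0.0
                s1 = 0.0
                for ii in range(lit_ptr[l], lit_ptr[l + 1]):
                    i = lit_rows[ii]
                    s0 += ET[0, i]
                    s1 += ET[1, i]
                s0 += nl * c[l, 0]
                s1 += nl * c[l, 1]
                r0_ = Ri00 * s0 + Ri01 * s1
                r1_ = Ri01 * s0 + Ri11 * s1
                P00 = nl * Ri00 + Ci00
                P01 = nl * Ri01 + Ci01
                P11 = nl * Ri11 + Ci11
                detP = P00 * P11 - P01 * P01
                mu0 = (P11 * r0_ - P01 * r1_) / detP
                mu1 = (P00 * r1_ - P01 * r0_) / detP
                q00 = np.sqrt(P11 / detP)
                q10 = (-P01 / detP) / q00
                q11 = np.sqrt(P00 / detP - q10 * q10)
                z0 = np.random.standard_normal()
                z1 = np.random.standard_normal()
                n0 = mu0 + q00 * z0
                n1 = mu1 + q10 * z0 + q11 * z1
                d0 = n0 - c[l, 0]
                d1 = n1 - c[l, 1]
                c[l, 0] = n0
                c[l, 1] = n1
                for ii in range(lit_ptr[l], lit_ptr[l + 1]):
                    i = lit_rows[ii]
                    ET[0, i] -= d0
                    ET[1, i] -= d1
            S00 = C0m[0, 0]
            S01 = C0m[0, 1]
            S11 = C0m[1, 1]
            for l in range(L):
                S00 += c[l, 0] * c[l, 0]
                S01 += c[l, 0] * c[l, 1]
                S11 += c[l, 1] * c[l, 1]
            C00, C01, C11 = _iw2(nu_c + L, S00, S01, S11)
        # polygenic pairs + U
        if m > 0:
            detU = U00 * U11 - U01 * U01
            Ui00 = U11 / detU
            Ui01 = -U01 / detU
            Ui11 = U00 / detU
            for a in range(m):
                nr = an_ptr[a + 1] - an_ptr[a]
                s0 = 0.0
                s1 = 0.0
                for ii in range(an_ptr[a], an_ptr[a + 1]):
                    i = an_rows[ii]
                    s0 += ET[0, i]
                    s1 += ET[1, i]
                s0 += nr * u[a, 0]
                s1 += nr * u[a, 1]
                rd0 = Ri00 * s0 + Ri01 * s1
                rd1 = Ri01 * s0 + Ri11 * s1
                w0 = 0.0
                w1 = 0.0
                for bx in range(m):
                    w0 += Ainv[a, bx] * u[bx, 0]
                    w1 += Ainv[a, bx] * u[bx, 1]
                w0 -= Ainv[a, a] * u[a, 0]
                w1 -= Ainv[a, a] * u[a, 1]
                r0_ = rd0 - (Ui00 * w0 + Ui01 * w1)
                r1_ = rd1 - (Ui01 * w0 + Ui11 * w1)
                P00 = nr * Ri00 + Ainv[a, a] * Ui00
                P01 = nr * Ri01 + Ainv[a, a] * Ui01
                P11 = nr * Ri11 + Ainv[a, a] * Ui11
                detP = P00 * P11 - P01 * P01
                mu0 = (P11 * r0_ - P01 * r1_) / detP
                mu1 = (P00 * r1_ - P01 * r0_) / detP
                q00 = np.sqrt(P11 / detP)
                q10 = (-P01 / detP) / q00
                q11 = np.sqrt(P00 / detP - q10 * q10)
                z0 = np.random.standard_normal()
                z1 = np.random.standard_normal()
                n0 = mu0 + q00 * z0
                n1 = mu1 + q10 * z0 + q11 * z1
                d0 = n0 - u[a, 0]
                d1 = n1 - u[a, 1]
                u[a, 0] = n0
                u[a, 1] = n1
                for ii in range(an_ptr[a], an_ptr[a + 1]):
                    i = an_rows[ii]
                    ET[0, i] -= d0
                    ET[1, i] -= d1
            S00 = U0m[0, 0]
            S01 = U0m[0, 1]
            S11 = U0m[1, 1]
            for a in range(m):
                t0 = 0.0
                t1 = 0.0
                for bx in range(m):
                    t0 += Ainv[a, bx] * u[bx, 0]
                    t1 += Ainv[a, bx] * u[bx, 1]
                S00 += u[a, 0] * t0
                S01 += u[a, 0] * t1
                S11 += u[a, 1] * t1
            U00, U01, U11 = _iw2(nu_u + m, S00, S01, S11)
        # locus sweep: 4-configuration indicator, analytic marginalization
        acc00 = 0.0
        acc01 = 0.0
        acc11 = 0.0
        for j in range(k):
            if per_locus:
                g00 = Gj00[j]
                g01 = Gj01[j]
                g11 = Gj11[j]
            else:
                g00 = sG00
                g01 = sG01
                g11 = sG11
            zzj = zz[j]
            s0 = zzj * al0[j]
            s1 = zzj * al1[j]
            for i in range(n):
                s0 += ZT[j, i] * ET[0, i]
                s1 += ZT[j, i] * ET[1, i]
            uq0 = Ri00 * s0 + Ri01 * s1
            uq1 = Ri01 * s0 + Ri11 * s1
            detG = g00 * g11 - g01 * g01
            P1 = zzj * Ri00 + 1.0 / g00
            sc1 = lp1 - 0.5 * np.log(g00) - 0.5 * np.log(P1) + 0.5 * uq0 * uq0 / P1
            P2 = zzj * Ri11 + 1.0 / g11
            sc2 = lp2 - 0.5 * np.log(g11) - 0.5 * np.log(P2) + 0.5 * uq1 * uq1 / P2
            Q00 = zzj * Ri00 + g11 / detG
            Q01 = zzj * Ri01 - g01 / detG
            Q11 = zzj * Ri11 + g00 / detG
            detQ = Q00 * Q11 - Q01 * Q01
            quad = (Q11 * uq0 * uq0 - 2.0 * Q01 * uq0 * uq1 + Q00 * uq1 * uq1) / detQ
            sc3 = lp3 - 0.5 * np.log(detG) - 0.5 * np.log(detQ) + 0.5 * quad
            sc0 = lp0
            mx = sc0
            if sc1 > mx:
                mx = sc1
            if sc2 > mx:
                mx = sc2
            if sc3 > mx:
                mx = sc3
            w0 = np.exp(sc0 - mx)
            w1 = np.exp(sc1 - mx)
            w2 = np.exp(sc2 - mx)
            w3 = np.exp(sc3 - mx)
            r = np.random.random() * (w0 + w1 + w2 + w3)
            if r < w0:
                cfg = 0
            elif r < w0 + w1:
                cfg = 1
            elif r < w0 + w1 + w2:
                cfg = 2
            else:
                cfg = 3
            if cfg == 0:
                # full prior draw (keeps the G_j full conditional simple)
                l00 = np.sqrt(g00)
                l10 = g01 / l00
                l11 = np.sqrt(max(g11 - l10 * l10, 1e-300))
                z0 = np.random.standard_normal()
                z1 = np.random.standard_normal()
                a0 = l00 * z0
                a1 = l10 * z0 + l11 * z1
                d0 = 0
                d1 = 0
            elif cfg == 1:
                a0 = uq0 / P1 + np.random.standard_normal() / np.sqrt(P1)
                cv = max(g11 - g01 * g01 / g00, 1e-300)
                a1 = g01 / g00 * a0 + np.sqrt(cv) * np.random.standard_normal()
                d0 = 1
                d1 = 0
            elif cfg == 2:
                a1 = uq1 / P2 + np.random.standard_normal() / np.sqrt(P2)
                cv = max(g00 - g01 * g01 / g11, 1e-300)
                a0 = g01 / g11 * a1 + np.sqrt(cv) * np.random.standard_normal()
                d0 = 0
                d1 = 1
            else:
                mu0 = (Q11 * uq0 - Q01 * uq1) / detQ
                mu1 = (Q00 * uq1 - Q01 * uq0) / detQ
                q00 = np.sqrt(Q11 / detQ)
                q10 = (-Q01 / detQ) / q00
                q11 = np.sqrt(max(Q00 / detQ - q10 * q10, 1e-300))
                z0 = np.random.standard_normal()
                z1 = np.random.standard_normal()
                a0 = mu0 + q00 * z0
                a1 = mu1 + q10 * z0 + q11 * z1
                d0 = 1
                d1 = 1
            m0 = a0 if d0 == 1 else 0.0
            m1 = a1 if d1 == 1 else 0.0
            if m0 != al0[j] or m1 != al1[j]:
                df0 = m0 - al0[j]
                df1 = m1 - al1[j]
                for i in range(n):
                    ET[0, i] -= ZT[j, i] * df0
                    ET[1, i] -= ZT[j, i] * df1
                al0[j] = m0
                al1[j] = m1
            dl0[j] = d0
            dl1[j] = d1
            if per_locus:
                Gj00[j], Gj01[j], Gj11[j] = _iw2(
                    nu_g + 1.0, g0_00 + a0 * a0, g0_01 + a0 * a1, g0_11 + a1 * a1
                )
            else:
                acc00 += a0 * a0
                acc01 += a0 * a1
                acc11 += a1 * a1
        if not per_locus:
            sG00, sG01, sG11 = _iw2(nu_g + k, g0_00 + acc00, g0_01 + acc01, g0_11 + acc11)
        # residual covariance
        S00 = R0m[0, 0]
        S01 = R0m[0, 1]
        S11 = R0m[1, 1]
        for i in range(n):
            S00 += ET[0, i] * ET[0, i]
            S01 += ET[0, i] * ET[1, i]
            S11 += ET[1, i] * ET[1, i]
        R00, R01, R11 = _iw2(nu_r + n, S00, S01, S11)
        # save thinned draw
        if it + 1 > burn_in and (it + 1 - burn_in) % thin == 0:
            for j in range(k):
                alpha_s[s_ix, j, 0] = al0[j]
                alpha_s[s_ix, j, 1] = al1[j]
                delta_s[s_ix, j, 0] = dl0[j]
                delta_s[s_ix, j, 1] = dl1[j]
            for cx in range(p):
                b_s[s_ix, cx, 0] = b[cx, 0]
                b_s[s_ix, cx, 1] = b[cx, 1]
            for l in range(L):
                c_s[s_ix, l, 0] = c[l, 0]
                c_s[s_ix, l, 1] = c[l, 1]
            for a in range(m):
                u_s[s_ix, a, 0] = u[a, 0]
                u_s[s_ix, a, 1] = u[a, 1]
            R_s[s_ix, 0, 0] = R00
            R_s[s_ix, 0, 1] = R01
            R_s[s_ix, 1, 0] = R01
            R_s[s_ix, 1, 1] = R11
            C_s[s_ix, 0, 0] = C00
            C_s[s_ix, 0, 1] = C01
            C_s[s_ix, 1, 0] = C01
            C_s[s_ix, 1, 1] = C11
            U_s[s_ix, 0, 0] = U00
            U_s[s_ix, 0, 1] = U01
            U_s[s_ix, 1, 0] = U01
            U_s[s_ix, 1, 1] = U11
            if per_locus and k > 0:
                gm00 = 0.0
                gm01 = 0.0
                gm11 = 0.0
                for j in range(k):
                    gm00 += Gj00[j]
                    gm01 += Gj01[j]
                    gm11 += Gj11[j]
                G_s[s_ix, 0, 0] = gm00 / k
                G_s[s_ix, 0, 1] = gm01 / k
                G_s[s_ix, 1, 0] = gm01 / k
                G_s[s_ix, 1, 1] = gm11 / k
            elif per_locus:
                a00, a01, a11 = _iw2(nu_g, g0_00, g0_01, g0_11)
                G_s[s_ix, 0, 0] = a00
                G_s[s_ix, 0, 1] = a01
                G_s[s_ix, 1, 0] = a01
                G_s[s_ix, 1, 1] = a11
            else:
                G_s[s_ix, 0, 0] = sG00
                G_s[s_ix, 0, 1] = sG01
                G_s[s_ix, 1, 0] = sG01
                G_s[s_ix, 1, 1] = sG11
            for i in range(n):
                E_s[s_ix, i, 0] = ET[0, i]
                E_s[s_ix, i, 1] = ET[1, i]
            s_ix += 1
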