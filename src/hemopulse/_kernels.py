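"""Compiled time-stepping core for the 1-D/0-D circulation model.

One cardiac cycle (or an arbitrary span of steps) is advanced entirely inside
a numba-compiled loop: MacCormack predictor-corrector updates of (A, U) on
every segment, characteristic (Riemann-invariant) boundary closures, Newton
solves of the junction conditions (total-pressure continuity + mass
conservation), Windkessel bed updates, and the 0-D heart/valve ODEs.

Everything here is strict SI.  The characteristic invariants of the
square-root tube law are W± = U ± 4c with c = sqrt(beta sqrt(A)/(2 rho Ad)).

Status codes written to ``stat[0]``: 0 ok; 1 divergence (non-finite or
non-positive area); 2 CFL violation; 3 junction Newton failure.
"""

import math

import numpy as np
from numba import njit

# terminal types
TM_BED = 0
TM_CLOSED = 1
TM_INFLOW = 2
TM_HEART = 3

# hstate layout
HS_V = 0        # V[4] chambers: la, lv, ra, rv
HS_QV = 4       # qv[4] valves: mitral, aortic, tricuspid, pulmonary
HS_ZETA = 8     # zeta[4]
HS_PCH = 12     # previous chamber pressures [4]
HS_PROOT = 16   # aortic-root 1-D pressure seen by the aortic valve
HS_PVEN = 17    # lumped venous compartment pressure (closed loop)
HS_PPULM = 18   # lumped pulmonary compartment pressure (closed loop)
NHSTATE = 19

# hconst layout
HC_PPV = 0
HC_RPV = 1
HC_CVEN = 2
HC_RVEN = 3
HC_CPULM = 4
HC_RPULM = 5
HC_PCK = 6
HC_PCV0 = 7
HC_PCPHI = 8
HC_CLOSED = 9
NHCONST = 10

ZETA_MIN = 1e-4


@njit(cache=True, inline="always")
def _wave_c(a, beta, ad, rho):
    return math.sqrt(beta * math.sqrt(a) / (2.0 * rho * ad))


@njit(cache=True, inline="always")
def _ptube(a, beta, ad, pext):
    return pext + beta / ad * (math.sqrt(a) - math.sqrt(ad))


@njit(cache=True)
def _act_interp(act_tab, c, phase):
    """Periodic linear interpolation of activation table row c at phase [0,1)."""
    k = act_tab.shape[1]
    x = (phase - math.floor(phase)) * k
    i0 = int(x)
    w = x - i0
    i1 = i0 + 1
    if i1 >= k:
        i1 = 0
    return act_tab[c, i0] * (1.0 - w) + act_tab[c, i1] * w


@njit(cache=True)
def _foot_invariant(A, U, Ad, beta, dAd, dbeta, node, sgn, dx, dt, rho, fc):
    """Outgoing Riemann invariant at a boundary node: foot interpolation
    plus the source terms of the characteristic equation.

    sgn=+1 distal end (outgoing W+ = U + 4c), sgn=-1 proximal (W- = U - 4c).
    On a tapered vessel W is not constant along the characteristic:
    DW/Dt = -(1/rho) dP/dx|_A - f +/- 4 (U +/- c) dc/dx|_A, with the
    geometric derivatives taken at fixed area.  Omitting these biases the
    boundary state (and leaks mass) in proportion to the taper."""
    nb = node - int(sgn)  # interior neighbour
    c_b = _wave_c(A[node], beta[node], Ad[node], rho)
    lam = sgn * U[node] + c_b  # speed of the outgoing characteristic
    if lam < 0.0:
        lam = 0.0
    th = lam * dt / dx
    if th > 1.0:
        th = 1.0
    a_f = (1.0 - th) * A[node] + th * A[nb]
    u_f = (1.0 - th) * U[node] + th * U[nb]
    ad_f = (1.0 - th) * Ad[node] + th * Ad[nb]
    be_f = (1.0 - th) * beta[node] + th * beta[nb]
    c_f = _wave_c(a_f, be_f, ad_f, rho)
    w = u_f + sgn * 4.0 * c_f
    # characteristic source terms at the foot
    db = dbeta[node]
    da = dAd[node]
    sq_ad = math.sqrt(ad_f)
    # phi = beta/Ad, psi = beta/sqrt(Ad)
    phi = be_f / ad_f
    dphi = (db * ad_f - be_f * da) / (ad_f * ad_f)
    dpsi = db / sq_ad - be_f * da / (2.0 * ad_f * sq_ad)
    dp_dx_a = dphi * math.sqrt(a_f) - dpsi
    dc_dx_a = c_f * dphi / (2.0 * phi)
    src = (-dp_dx_a / rho - fc * u_f / a_f
           + sgn * 4.0 * (u_f + sgn * c_f) * dc_dx_a)
    return w + dt * src


@njit(cache=True)
def _solve_q_boundary(a0, w, sgn, beta, ad, rho, q_target):
    """Solve A*U = q_target with U = W - sgn*4c(A); returns (A, U).

    Used for prescribed-inflow and heart-inlet closures (sgn=-1 there, so
    U = W + 4c).  Newton from a0."""
    a = a0
    for _ in range(60):
        c = _wave_c(a, beta, ad, rho)
        u = w - sgn * 4.0 * c
        f = a * u - q_target
        df = u - sgn * c  # d(AU)/dA = U + A dU/dA = U - sgn*c
        if df == 0.0:
            break
        da = f / df
        a_new = a - da
        if a_new <= 0.0:
            a_new = 0.5 * a
        if abs(a_new - a) < 1e-15 * a:
            a = a_new
            break
        a = a_new
    c = _wave_c(a, beta, ad, rho)
    return a, w - sgn * 4.0 * c


@njit(cache=True)
def _solve_bed_boundary(a0, w, sgn, beta, ad, pext, rho, r1, pc):
    """Couple a segment end to an RCR bed: P(A) = Pc + R1 * Q_in with
    Q_in = sgn*A*U the flow into the bed.  Returns (A, U)."""
    a = a0
    for _ in range(60):
        c = _wave_c(a, beta, ad, rho)
        u = w - sgn * 4.0 * c
        g = _ptube(a, beta, ad, pext) - pc - r1 * sgn * a * u
        dg = beta / (2.0 * ad * math.sqrt(a)) - r1 * (sgn * u - c)
        if dg == 0.0:
            break
        a_new = a - g / dg
        if a_new <= 0.0:
            a_new = 0.5 * a
        if abs(a_new - a) < 1e-15 * a:
            a = a_new
            break
        a = a_new
    c = _wave_c(a, beta, ad, rho)
    return a, w - sgn * 4.0 * c


@njit(cache=True)
def _solve_junction(ne, aj, w, sgn, betaj, adj, pextj, rho):
    """Newton solve of the junction conditions for ne attached ends.

    Unknowns A_j; U_j = W_j - sgn_j*4c_j.  Residuals: total-pressure
    equality of every end against end ne-1, and sum(sgn_j A_j U_j) = 0.
    Returns 0 on convergence, 1 on failure; solution left in aj."""
    J = np.zeros((6, 6))
    F = np.zeros(6)
    uj = np.zeros(6)
    cj = np.zeros(6)
    ptj = np.zeros(6)
    for it in range(80):
        qmax = 1e-30
        qfloor = 0.0  # round-off floor of A*U given U = W -/+ 4c
        for j in range(ne):
            cj[j] = _wave_c(aj[j], betaj[j], adj[j], rho)
            uj[j] = w[j] - sgn[j] * 4.0 * cj[j]
            ptj[j] = (_ptube(aj[j], betaj[j], adj[j], pextj[j])
                      + 0.5 * rho * uj[j] * uj[j])
            q = abs(aj[j] * uj[j])
            if q > qmax:
                qmax = q
            qf = aj[j] * (abs(uj[j]) + 4.0 * cj[j])
            if qf > qfloor:
                qfloor = qf
        fmass = 0.0
        for j in range(ne):
            fmass += sgn[j] * aj[j] * uj[j]
        fpmax = 0.0
        for k in range(ne - 1):
            F[k] = ptj[k] - ptj[ne - 1]
            if abs(F[k]) > fpmax:
                fpmax = abs(F[k])
        F[ne - 1] = fmass
        if abs(fmass) <= 1e-14 * qmax + 1e-14 * qfloor and fpmax <= 1e-8:
            return 0
        # Jacobian
        for k in range(ne):
            for j in range(ne):
                J[k, j] = 0.0
        for j in range(ne):
            dptj = (betaj[j] / (2.0 * adj[j] * math.sqrt(aj[j]))
                    - rho * uj[j] * sgn[j] * cj[j] / aj[j])
            dqj = sgn[j] * uj[j] - cj[j]
            if j < ne - 1:
                J[j, j] = dptj
            else:
                for k in range(ne - 1):
                    J[k, j] = -dptj
            J[ne - 1, j] = dqj
        # gaussian elimination with partial pivoting on the ne x ne block
        for col in range(ne):
            piv = col
            vmax = abs(J[col, col])
            for r in range(col + 1, ne):
                if abs(J[r, col]) > vmax:
                    vmax = abs(J[r, col])
                    piv = r
            if vmax == 0.0:
                return 1
            if piv != col:
                for cc in range(ne):
                    tmp = J[col, cc]
                    J[col, cc] = J[piv, cc]
                    J[piv, cc] = tmp
                tmp = F[col]
                F[col] = F[piv]
                F[piv] = tmp
            for r in range(col + 1, ne):
                fac = J[r, col] / J[col, col]
                for cc in range(col, ne):
                    J[r, cc] -= fac * J[col, cc]
                F[r] -= fac * F[col]
        for r in range(ne - 1, -1, -1):
            s = F[r]
            for cc in range(r + 1, ne):
                s -= J[r, cc] * F[cc]
            F[r] = s / J[r, r]
        for j in range(ne):
            a_new = aj[j] - F[j]
            if a_new <= 0.0:
                a_new = 0.5 * aj[j]
            aj[j] = a_new
    return 1


@njit(cache=True)
def _valve_step(dp, q, zeta, aann, leff, ko, kc, ideal, rho, dt):
    """One semi-implicit step of the valve state; returns (q_new, zeta_new)."""
    if ideal != 0.0:
        if dp <= 0.0:
            return 0.0, 0.0
        b = rho / (2.0 * aann * aann)
        return math.sqrt(dp / b), 1.0
    if dp > 0.0:
        zeta = zeta + dt * ko * dp * (1.0 - zeta)
    else:
        zeta = zeta + dt * kc * dp * zeta
    if zeta < 0.0:
        zeta = 0.0
    elif zeta > 1.0:
        zeta = 1.0
    if zeta <= ZETA_MIN:
        return 0.0, zeta
    aeff = zeta * aann
    b = rho / (2.0 * aeff * aeff)
    el = rho * leff / aeff
    q_new = (q + dt * dp / el) / (1.0 + dt * b * abs(q) / el)
    return q_new, zeta


@njit(cache=True)
def run_steps(n_steps, t0, dt, t_heart,
              A, U, Ad, beta, dAd, dbeta, pext,
              seg_i0, seg_n, seg_dx,
              rho, fc,
              jn_n, jn_node, jn_sign, jn_dx,
              tm_node, tm_sign, tm_type, tm_dx,
              bd_r1, bd_c, bd_r2, bd_pout, bd_pc,
              inflow_tab, inflow_T,
              heart_on, heart_node, heart_dx,
              hp, act_tab, vl, hstate, hconst,
              site_node, rec_P, rec_Q, rec_U, rec_A, hrec,
              rec_every, stat):
    nn = A.shape[0]
    ns = seg_i0.shape[0]
    nj = jn_n.shape[0]
    nt = tm_node.shape[0]
    nsite = site_node.shape[0]

    P = np.empty(nn)
    Ap = np.empty(nn)
    Up = np.empty(nn)
    Pp = np.empty(nn)
    bnode = np.empty(2 * ns, dtype=np.int64)
    bA = np.empty(2 * ns)
    bU = np.empty(2 * ns)

    aj = np.zeros(6)
    wj = np.zeros(6)
    sj = np.zeros(6)
    bj = np.zeros(6)
    adj = np.zeros(6)
    pxj = np.zeros(6)

    closed_loop = hconst[HC_CLOSED] != 0.0
    courant_max = 0.0
    rec_i = 0

    for step in range(n_steps):
        t = t0 + step * dt
        # --- pressures, sanity, CFL -----------------------------------
        for i in range(nn):
            a = A[i]
            if not (a > 0.0) or not math.isfinite(a) or not math.isfinite(U[i]):
                stat[0] = 1.0
                stat[1] = float(i)
                stat[2] = float(step)
                return
            P[i] = _ptube(a, beta[i], Ad[i], pext[i])
        for s in range(ns):
            i0 = seg_i0[s]
            n = seg_n[s]
            dx = seg_dx[s]
            for i in range(i0, i0 + n):
                cr = (abs(U[i]) + _wave_c(A[i], beta[i], Ad[i], rho)) * dt / dx
                if cr > courant_max:
                    courant_max = cr
        if courant_max > 1.0:
            stat[0] = 2.0
            stat[2] = float(step)
            stat[3] = courant_max
            return

        nb = 0
        ven_inflow = 0.0

        # --- terminals -------------------------------------------------
        for k in range(nt):
            typ = tm_type[k]
            if typ == TM_HEART:
                continue
            node = tm_node[k]
            sgn = tm_sign[k]
            w = _foot_invariant(A, U, Ad, beta, dAd, dbeta, node, sgn,
                                    tm_dx[k], dt, rho, fc)
            if typ == TM_BED:
                pout_eff = hstate[HS_PVEN] if closed_loop else bd_pout[k]
                a_b, u_b = _solve_bed_boundary(
                    A[node], w, sgn, beta[node], Ad[node], pext[node],
                    rho, bd_r1[k], bd_pc[k])
                q_in = sgn * a_b * u_b
                q_out = (bd_pc[k] - pout_eff) / bd_r2[k]
                ven_inflow += q_out
                bd_pc[k] += dt * (q_in - q_out) / bd_c[k]
            elif typ == TM_CLOSED:
                # U = 0  ->  c = sgn*W/4
                c_t = sgn * w / 4.0
                if c_t <= 0.0:
                    c_t = 1e-12
                kk = math.sqrt(beta[node] / (2.0 * rho * Ad[node]))
                a_b = (c_t / kk) ** 4
                u_b = 0.0
            else:  # TM_INFLOW
                ph = (t + dt) / inflow_T
                ph -= math.floor(ph)
                m = inflow_tab.shape[0]
                x = ph * m
                ii = int(x)
                wgt = x - ii
                i1 = ii + 1
                if i1 >= m:
                    i1 = 0
                q_t = inflow_tab[ii] * (1.0 - wgt) + inflow_tab[i1] * wgt
                a_b, u_b = _solve_q_boundary(
                    A[node], w, sgn, beta[node], Ad[node], rho,
                    -sgn * q_t)  # q_t flows INTO the segment
            bnode[nb] = node
            bA[nb] = a_b
            bU[nb] = u_b
            nb += 1

        # --- heart -----------------------------------------------------
        if heart_on != 0:
            vtot = (hstate[HS_V] + hstate[HS_V + 1]
                    + hstate[HS_V + 2] + hstate[HS_V + 3])
            ppc = hconst[HC_PCK] * math.exp(
                (vtot - hconst[HC_PCV0]) / hconst[HC_PCPHI])
            ph = (t / t_heart) - math.floor(t / t_heart)
            pch_new = np.empty(4)
            for c in range(4):
                e = _act_interp(act_tab, c, ph)
                enat = hp[c, 1] + e * (hp[c, 0] - hp[c, 1])
                partner = (c + 2) % 4
                # chamber outflow valve shares the chamber index
                pch_new[c] = (ppc + (enat / hp[c, 4]) * hstate[HS_PCH + partner]
                              + enat * (hstate[HS_V + c] - hp[c, 2])
                              - hp[c, 3] * hstate[HS_QV + c])
            p_la = pch_new[0]
            p_lv = pch_new[1]
            p_ra = pch_new[2]
            p_rv = pch_new[3]
            p_root = P[heart_node]
            # valves: 0 mitral (la->lv), 1 aortic (lv->root),
            #         2 tricuspid (ra->rv), 3 pulmonary (rv->pulm)
            q_mit, z_mit = _valve_step(
                p_la - p_lv, hstate[HS_QV], hstate[HS_ZETA],
                vl[0, 0], vl[0, 1], vl[0, 2], vl[0, 3], vl[0, 4], rho, dt)
            q_av, z_av = _valve_step(
                p_lv - p_root, hstate[HS_QV + 1], hstate[HS_ZETA + 1],
                vl[1, 0], vl[1, 1], vl[1, 2], vl[1, 3], vl[1, 4], rho, dt)
            if closed_loop:
                q_tri, z_tri = _valve_step(
                    p_ra - p_rv, hstate[HS_QV + 2], hstate[HS_ZETA + 2],
                    vl[2, 0], vl[2, 1], vl[2, 2], vl[2, 3], vl[2, 4], rho, dt)
                q_pul, z_pul = _valve_step(
                    p_rv - hstate[HS_PPULM], hstate[HS_QV + 3],
                    hstate[HS_ZETA + 3],
                    vl[3, 0], vl[3, 1], vl[3, 2], vl[3, 3], vl[3, 4], rho, dt)
                q_la_in = (hstate[HS_PPULM] - p_la) / hconst[HC_RPULM]
                q_ra_in = (hstate[HS_PVEN] - p_ra) / hconst[HC_RVEN]
            else:
                q_tri = 0.0
                z_tri = hstate[HS_ZETA + 2]
                q_pul = 0.0
                z_pul = hstate[HS_ZETA + 3]
                q_la_in = (hconst[HC_PPV] - p_la) / hconst[HC_RPV]
                q_ra_in = 0.0
            hstate[HS_V] += dt * (q_la_in - q_mit)
            hstate[HS_V + 1] += dt * (q_mit - q_av)
            if closed_loop:
                hstate[HS_V + 2] += dt * (q_ra_in - q_tri)
                hstate[HS_V + 3] += dt * (q_tri - q_pul)
                hstate[HS_PPULM] += dt * (q_pul - q_la_in) / hconst[HC_CPULM]
                hstate[HS_PVEN] += dt * (ven_inflow - q_ra_in) / hconst[HC_CVEN]
            hstate[HS_QV] = q_mit
            hstate[HS_QV + 1] = q_av
            hstate[HS_QV + 2] = q_tri
            hstate[HS_QV + 3] = q_pul
            hstate[HS_ZETA] = z_mit
            hstate[HS_ZETA + 1] = z_av
            hstate[HS_ZETA + 2] = z_tri
            hstate[HS_ZETA + 3] = z_pul
            for c in range(4):
                hstate[HS_PCH + c] = pch_new[c]
            # 1-D inlet closure with the new aortic-valve flow
            w = _foot_invariant(A, U, Ad, beta, dAd, dbeta, heart_node,
                                -1.0, heart_dx, dt, rho, fc)
            a_b, u_b = _solve_q_boundary(
                A[heart_node], w, -1.0, beta[heart_node], Ad[heart_node],
                rho, q_av)
            hstate[HS_PROOT] = _ptube(a_b, beta[heart_node], Ad[heart_node],
                                      pext[heart_node])
            bnode[nb] = heart_node
            bA[nb] = a_b
            bU[nb] = u_b
            nb += 1

        # --- junctions -------------------------------------------------
        for k in range(nj):
            ne = jn_n[k]
            for j in range(ne):
                node = jn_node[k, j]
                sj[j] = jn_sign[k, j]
                aj[j] = A[node]
                bj[j] = beta[node]
                adj[j] = Ad[node]
                pxj[j] = pext[node]
                wj[j] = _foot_invariant(A, U, Ad, beta, dAd, dbeta, node,
                                        sj[j], jn_dx[k, j], dt, rho, fc)
            ok = _solve_junction(ne, aj, wj, sj, bj, adj, pxj, rho)
            if ok != 0:
                stat[0] = 3.0
                stat[1] = float(k)
                stat[2] = float(step)
                return
            for j in range(ne):
                c = _wave_c(aj[j], bj[j], adj[j], rho)
                bnode[nb] = jn_node[k, j]
                bA[nb] = aj[j]
                bU[nb] = wj[j] - sj[j] * 4.0 * c
                nb += 1

        # --- interior MacCormack update -------------------------------
        for s in range(ns):
            i0 = seg_i0[s]
            n = seg_n[s]
            dx = seg_dx[s]
            r = dt / dx
            # predictor (forward differences)
            for i in range(i0, i0 + n - 1):
                Ap[i] = A[i] - r * (A[i + 1] * U[i + 1] - A[i] * U[i])
                Up[i] = U[i] - dt * (
                    U[i] * (U[i + 1] - U[i]) / dx
                    + (P[i + 1] - P[i]) / (dx * rho)
                    + fc * U[i] / A[i])
                if Ap[i] <= 0.0:
                    stat[0] = 1.0
                    stat[1] = float(i)
                    stat[2] = float(step)
                    return
                Pp[i] = _ptube(Ap[i], beta[i], Ad[i], pext[i])
            # corrector (backward differences on the predicted state)
            ilast = i0 + n - 1
            Ap[ilast] = A[ilast]
            Up[ilast] = U[ilast]
            Pp[ilast] = P[ilast]
            for i in range(i0 + n - 2, i0, -1):
                a_new = 0.5 * (A[i] + Ap[i]
                               - r * (Ap[i] * Up[i] - Ap[i - 1] * Up[i - 1]))
                u_new = 0.5 * (U[i] + Up[i] - dt * (
                    Up[i] * (Up[i] - Up[i - 1]) / dx
                    + (Pp[i] - Pp[i - 1]) / (dx * rho)
                    + fc * Up[i] / Ap[i]))
                A[i] = a_new
                U[i] = u_new

        # --- apply boundary closures ----------------------------------
        for k in range(nb):
            A[bnode[k]] = bA[k]
            U[bnode[k]] = bU[k]

        # --- record ----------------------------------------------------
        if (step + 1) % rec_every == 0:
            rec_i += 1
            for k in range(nsite):
                node = site_node[k]
                rec_A[k, rec_i] = A[node]
                rec_U[k, rec_i] = U[node]
                rec_Q[k, rec_i] = A[node] * U[node]
                rec_P[k, rec_i] = _ptube(A[node], beta[node], Ad[node],
                                         pext[node])
            hrec[0, rec_i] = hstate[HS_V]
            hrec[1, rec_i] = hstate[HS_V + 1]
            hrec[2, rec_i] = hstate[HS_V + 2]
            hrec[3, rec_i] = hstate[HS_V + 3]
            hrec[4, rec_i] = hstate[HS_PCH]       # P_la
            hrec[5, rec_i] = hstate[HS_PCH + 1]   # P_lv
            hrec[6, rec_i] = hstate[HS_QV]        # q_mitral
            hrec[7, rec_i] = hstate[HS_QV + 1]    # q_aortic
            hrec[8, rec_i] = hstate[HS_PROOT]
            hrec[9, rec_i] = hstate[HS_PVEN]

    stat[0] = 0.0
    stat[3] = courant_max
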