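"""Compiled fixed-step RK4 kernel for the chemostat ODE system.

This mirrors, term for term, the readable reference equations in
:mod:`phytopond.physiology` / :mod:`phytopond.optics`; a test asserts the
two agree to machine precision. Parameters are packed into a flat float64
vector so the kernel stays monomorphic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# packed-parameter layout
(P_UM, P_NCMIN, P_NCMAX, P_PCMIN, P_PCMAX, P_KQN, P_KQP, P_CHLCMAX,
 P_CHLFLOOR, P_ALPHA, P_KSN, P_KSP, P_VSCALE, P_RBASAL, P_RGROWTH,
 P_PQSURGE, P_HCEX, P_HUP, P_KCHL, P_KBG, P_EPSCHL,
 P_CLEARCAP) = range(22)

N_PARAMS = 22

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_NEGATIVE_C = 2


def pack_params(p, k_bg: float, eps_chl: float) -> np.ndarray:
    """Flatten a StrainParams plus optics constants into the kernel vector."""
    v = np.empty(N_PARAMS)
    v[P_UM] = p.Um
    v[P_NCMIN] = p.NCmin
    v[P_NCMAX] = p.NCmax
    v[P_PCMIN] = p.PCmin
    v[P_PCMAX] = p.PCmax
    v[P_KQN] = p.KQN
    v[P_KQP] = p.KQP
    v[P_CHLCMAX] = p.ChlCmax
    v[P_CHLFLOOR] = p.ChlC_floor
    v[P_ALPHA] = p.alpha_chl
    v[P_KSN] = p.KsN
    v[P_KSP] = p.KsP
    v[P_VSCALE] = p.Vscale
    v[P_RBASAL] = p.r_basal
    v[P_RGROWTH] = p.r_growth
    v[P_PQSURGE] = p.Pq_surge
    v[P_HCEX] = p.hCex
    v[P_HUP] = p.h_uptake
    v[P_KCHL] = p.kchl_effective
    v[P_KBG] = k_bg
    v[P_EPSCHL] = eps_chl
    from .physiology import CLEARANCE_CAP
    v[P_CLEARCAP] = CLEARANCE_CAP
    return v


@njit(cache=False)
def _deriv(Cb, Nb, Pb, Chl, Sn, Sp, pfd, pp, D, tau, N_in, P_in):
    NC = Nb / Cb
    PC = Pb / Cb
    ChlC = Chl / Cb

    # normalized quota-growth factor for N (photoacclimation control)
    qn = (NC - pp[P_NCMIN]) / (pp[P_NCMAX] - pp[P_NCMIN])
    if qn < 0.0:
        qn = 0.0
    elif qn > 1.0:
        qn = 1.0
    uN = (1.0 + pp[P_KQN]) * qn / (qn + pp[P_KQN])

    # excess-C fraction and surplus-fixation shut-off
    cex = 1.0 - NC / pp[P_NCMAX]
    if cex < 0.0:
        cex = 0.0
    cex_max = 1.0 - pp[P_NCMIN] / pp[P_NCMAX]
    frac = cex / cex_max
    if frac > 1.0:
        frac = 1.0
    pqm = (pp[P_UM] * (1.0 + pp[P_RBASAL]) * pp[P_PQSURGE]
           * (1.0 - frac) ** pp[P_HCEX])

    # depth-integrated Smith photosynthesis
    if pqm > 1e-12 and pfd > 0.0:
        x0 = pfd * pp[P_ALPHA] * ChlC / pqm
        k = pp[P_KBG] + pp[P_EPSCHL] * Chl
        ktau = k * tau
        PS = pqm / ktau * (np.arcsinh(x0) - np.arcsinh(x0 * np.exp(-ktau)))
        lightsat = PS / pqm
    else:
        PS = 0.0
        lightsat = 1.0 if pqm <= 1e-12 else 0.0

    R = pp[P_RBASAL] * pp[P_UM] + pp[P_RGROWTH] * PS

    # satiation-feedback Michaelis-Menten transport
    fqn = (pp[P_NCMAX] - NC) / (pp[P_NCMAX] - pp[P_NCMIN])
    if fqn < 0.0:
        fqn = 0.0
    elif fqn > 1.0:
        fqn = 1.0
    VN = (pp[P_VSCALE] * pp[P_UM] * pp[P_NCMAX] * Sn / (Sn + pp[P_KSN])
          * fqn ** pp[P_HUP])
    vn_cap = pp[P_CLEARCAP] * Sn / Cb
    if VN > vn_cap:
        VN = vn_cap

    fqp = (pp[P_PCMAX] - PC) / (pp[P_PCMAX] - pp[P_PCMIN])
    if fqp < 0.0:
        fqp = 0.0
    elif fqp > 1.0:
        fqp = 1.0
    VP = (pp[P_VSCALE] * pp[P_UM] * pp[P_PCMAX] * Sp / (Sp + pp[P_KSP])
          * fqp ** pp[P_HUP])
    vp_cap = pp[P_CLEARCAP] * Sp / Cb
    if VP > vp_cap:
        VP = vp_cap

    # photoacclimation relaxation
    target = pp[P_CHLCMAX] * uN * (1.0 - lightsat) + pp[P_CHLFLOOR]
    if target > pp[P_CHLCMAX]:
        target = pp[P_CHLCMAX]
    rho = pp[P_KCHL] * (target - ChlC)

    dCb = (PS - R - D) * Cb
    dNb = VN * Cb - D * Nb
    dPb = VP * Cb - D * Pb
    dChl = rho * Cb - D * Chl
    dSn = D * (N_in - Sn) - VN * Cb
    dSp = D * (P_in - Sp) - VP * Cb
    return dCb, dNb, dPb, dChl, dSn, dSp


@njit(cache=False)
def integrate(y0, pfd_half, dt, n_year, n_spinup, stride, pp, D, tau,
              N_in, P_in):
    """Fixed-step RK4 over ``n_spinup + 1`` repeats of a periodic forcing year.

    ``pfd_half`` holds the surface PAR at half-step resolution over one year
    (length 2*n_year + 1, last element equal to the first). Only the final
    year is recorded, every ``stride`` steps plus the endpoint. Returns
    ``(records, status, fail_time)`` where records columns are
    (t, Cb, Nb, Pb, Chl, Sn, Sp) with t in days from the start of the
    recorded year.
    """
    n_rec = n_year // stride + 1
    rec = np.empty((n_rec, 7))
    Cb, Nb, Pb, Chl, Sn, Sp = y0[0], y0[1], y0[2], y0[3], y0[4], y0[5]
    n_total = (n_spinup + 1) * n_year
    start_rec = n_spinup * n_year
    irec = 0
    half = 0.5 * dt
    sixth = dt / 6.0

    for i in range(n_total):
        j = i % n_year
        if i >= start_rec and (i - start_rec) % stride == 0:
            rec[irec, 0] = (i - start_rec) * dt
            rec[irec, 1] = Cb
            rec[irec, 2] = Nb
            rec[irec, 3] = Pb
            rec[irec, 4] = Chl
            rec[irec, 5] = Sn
            rec[irec, 6] = Sp
            irec += 1

        f0 = pfd_half[2 * j]
        f1 = pfd_half[2 * j + 1]
        f2 = pfd_half[2 * j + 2]

        a1, b1, c1, d1, e1, g1 = _deriv(Cb, Nb, Pb, Chl, Sn, Sp, f0, pp, D, tau, N_in, P_in)
        a2, b2, c2, d2, e2, g2 = _deriv(Cb + half * a1, Nb + half * b1, Pb + half * c1,
                                        Chl + half * d1, Sn + half * e1, Sp + half * g1,
                                        f1, pp, D, tau, N_in, P_in)
        a3, b3, c3, d3, e3, g3 = _deriv(Cb + half * a2, Nb + half * b2, Pb + half * c2,
                                        Chl + half * d2, Sn + half * e2, Sp + half * g2,
                                        f1, pp, D, tau, N_in, P_in)
        a4, b4, c4, d4, e4, g4 = _deriv(Cb + dt * a3, Nb + dt * b3, Pb + dt * c3,
                                        Chl + dt * d3, Sn + dt * e3, Sp + dt * g3,
                                        f2, pp, D, tau, N_in, P_in)

        Cb += sixth * (a1 + 2.0 * a2 + 2.0 * a3 + a4)
        Nb += sixth * (b1 + 2.0 * b2 + 2.0 * b3 + b4)
        Pb += sixth * (c1 + 2.0 * c2 + 2.0 * c3 + c4)
        Chl += sixth * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
        Sn += sixth * (e1 + 2.0 * e2 + 2.0 * e3 + e4)
        Sp += sixth * (g1 + 2.0 * g2 + 2.0 * g3 + g4)

        if not (np.isfinite(Cb) and np.isfinite(Nb) and np.isfinite(Pb)
                and np.isfinite(Chl) and np.isfinite(Sn) and np.isfinite(Sp)):
            return rec[:irec], STATUS_NONFINITE, (i + 1) * dt
        if Cb <= 0.0:
            return rec[:irec], STATUS_NEGATIVE_C, (i + 1) * dt

        # overshoot repair, mass-conserving for N and P:
        # uptake overdraft is returned to the cell pool...
        if Sn < 0.0:
            Nb += Sn
            Sn = 0.0
        if Sp < 0.0:
            Pb += Sp
            Sp = 0.0
        # ...and quota overshoot above the replete bound is released back
        # to the medium (night respiration shrinks Cb under replete quotas).
        nmax = pp[P_NCMAX] * Cb
        if Nb > nmax:
            Sn += Nb - nmax
            Nb = nmax
        pmax = pp[P_PCMAX] * Cb
        if Pb > pmax:
            Sp += Pb - pmax
            Pb = pmax
        if Nb < 0.0 or Pb < 0.0:
            return rec[:irec], STATUS_NEGATIVE_C, (i + 1) * dt
        # pigment stays within [0, ChlCmax * Cb]
        if Chl < 0.0:
            Chl = 0.0
        cmax = pp[P_CHLCMAX] * Cb
        if Chl > cmax:
            Chl = cmax

    rec[irec, 0] = n_year * dt
    rec[irec, 1] = Cb
    rec[irec, 2] = Nb
    rec[irec, 3] = Pb
    rec[irec, 4] = Chl
    rec[irec, 5] = Sn
    rec[irec, 6] = Sp
    return rec, STATUS_OK, -1.0
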