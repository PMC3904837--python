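"""Numba kernels: GeoSSE ODE system, adaptive RK integrator, tree traversal.

State vector layout ``y = (E_A, E_B, E_AB, D_A, D_B, D_AB)`` with
A = temperate, B = tropical, AB = widespread.  The parameter vector ``p``
has 9 entries::

    p = (lamA0, lamB0, lamAB, muA, muB, dA, dB, slopeA, slopeB)

where within-biome speciation may vary linearly with time before present,
lamA(t) = lamA0 + slopeA * t (and likewise for B); the other five rates
are constant.  Branches are integrated backward in time, i.e. from the
young end (small t) to the old end (large t).

The integrator is a Dormand-Prince 5(4) pair with standard PI-free step
control; per-branch relative/absolute tolerances are caller-supplied.
"""

import numpy as np
from numba import njit

# status codes returned by kernels
OK = 0
STEP_FAILURE = 1
NONFINITE = 2
ZERO_LIKELIHOOD = 3

# root_mode codes
ROOT_FITZJOHN = 0
ROOT_EQUAL = 1
ROOT_FIXED = 2

_MINUS_INF = -np.inf


@njit(cache=True, inline="always")
def _rhs(t, y, p, out):
    lamA = p[0] + p[7] * t
    lamB = p[1] + p[8] * t
    lamAB = p[2]
    muA = p[3]
    muB = p[4]
    dA = p[5]
    dB = p[6]

    EA, EB, EAB, DA, DB, DAB = y[0], y[1], y[2], y[3], y[4], y[5]

    out[0] = -(lamA + dA + muA) * EA + muA + dA * EAB + lamA * EA * EA
    out[1] = -(lamB + dB + muB) * EB + muB + dB * EAB + lamB * EB * EB
    out[2] = (
        -(lamA + lamB + lamAB + muA + muB) * EAB
        + muA * EB
        + muB * EA
        + lamA * EA * EAB
        + lamB * EB * EAB
        + lamAB * EA * EB
    )
    out[3] = -(lamA + dA + muA) * DA + dA * DAB + 2.0 * lamA * DA * EA
    out[4] = -(lamB + dB + muB) * DB + dB * DAB + 2.0 * lamB * DB * EB
    out[5] = (
        -(lamA + lamB + lamAB + muA + muB) * DAB
        + muA * DB
        + muB * DA
        + lamA * (EA * DAB + EAB * DA)
        + lamB * (EB * DAB + EAB * DB)
        + lamAB * (EA * DB + EB * DA)
    )


@njit(cache=True)
def propagate(y, t0, t1, p, rtol, atol):
    """Integrate the six coupled ODEs from t0 to t1 (t1 > t0) in place.

    Returns ``(status, log_scale)``; on success ``y`` holds the solution
    at t1 with its D components scaled by ``exp(-log_scale)``.  D is
    renormalized on the fly whenever it decays below 0.1 so that the
    absolute-tolerance floor never erodes its relative accuracy (the D
    subsystem is linear in D, so rescaling mid-integration is exact).
    """
    logcomp = 0.0
    if t1 <= t0:
        return OK, logcomp
    span = t1 - t0
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    k5 = np.empty(6)
    k6 = np.empty(6)
    k7 = np.empty(6)
    ytmp = np.empty(6)
    ynew = np.empty(6)

    t = t0
    h = span * 0.1
    _rhs(t, y, p, k1)
    have_k1 = True
    max_steps = 100000
    hmin = span * 1e-14

    for _ in range(max_steps):
        if t >= t1:
            return OK, logcomp
        if h > t1 - t:
            h = t1 - t
        if not have_k1:
            _rhs(t, y, p, k1)
            have_k1 = True

        # Dormand-Prince stages
        for i in range(6):
            ytmp[i] = y[i] + h * (0.2 * k1[i])
        _rhs(t + 0.2 * h, ytmp, p, k2)
        for i in range(6):
            ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
        _rhs(t + 0.3 * h, ytmp, p, k3)
        for i in range(6):
            ytmp[i] = y[i] + h * (
                44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i]
            )
        _rhs(t + 0.8 * h, ytmp, p, k4)
        for i in range(6):
            ytmp[i] = y[i] + h * (
                19372.0 / 6561.0 * k1[i]
                - 25360.0 / 2187.0 * k2[i]
                + 64448.0 / 6561.0 * k3[i]
                - 212.0 / 729.0 * k4[i]
            )
        _rhs(t + 8.0 / 9.0 * h, ytmp, p, k5)
        for i in range(6):
            ytmp[i] = y[i] + h * (
                9017.0 / 3168.0 * k1[i]
                - 355.0 / 33.0 * k2[i]
                + 46732.0 / 5247.0 * k3[i]
                + 49.0 / 176.0 * k4[i]
                - 5103.0 / 18656.0 * k5[i]
            )
        _rhs(t + h, ytmp, p, k6)
        for i in range(6):
            ynew[i] = y[i] + h * (
                35.0 / 384.0 * k1[i]
                + 500.0 / 1113.0 * k3[i]
                + 125.0 / 192.0 * k4[i]
                - 2187.0 / 6784.0 * k5[i]
                + 11.0 / 84.0 * k6[i]
            )
        _rhs(t + h, ynew, p, k7)

        # embedded 4th-order error estimate
        errnorm = 0.0
        for i in range(6):
            e = h * (
                71.0 / 57600.0 * k1[i]
                - 71.0 / 16695.0 * k3[i]
                + 71.0 / 1920.0 * k4[i]
                - 17253.0 / 339200.0 * k5[i]
                + 22.0 / 525.0 * k6[i]
                - 1.0 / 40.0 * k7[i]
            )
            ay = abs(y[i])
            an = abs(ynew[i])
            sc = atol + rtol * (ay if ay > an else an)
            q = e / sc
            errnorm += q * q
        errnorm = np.sqrt(errnorm / 6.0)

        if not np.isfinite(errnorm):
            h *= 0.25
            have_k1 = True  # k1 still valid at t
            if h < hmin:
                return NONFINITE, logcomp
            continue

        if errnorm <= 1.0:
            t += h
            for i in range(6):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL
            # renormalize decayed D (linear subsystem: k1 rescales exactly)
            m = abs(y[3])
            if abs(y[4]) > m:
                m = abs(y[4])
            if abs(y[5]) > m:
                m = abs(y[5])
            if 0.0 < m < 0.1:
                inv = 1.0 / m
                for i in range(3, 6):
                    y[i] *= inv
                    k1[i] *= inv
                logcomp += np.log(m)
            # step-size growth
            if errnorm == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * errnorm ** -0.2
                if fac > 5.0:
                    fac = 5.0
            h *= fac
        else:
            fac = 0.9 * errnorm ** -0.2
            if fac < 0.2:
                fac = 0.2
            h *= fac
            if h < hmin:
                return STEP_FAILURE, logcomp
    return STEP_FAILURE, logcomp


@njit(cache=True, inline="always")
def _combine(p, t, y1, y2, out):
    """Cladogenetic combination of two daughter states at a node of age t.

    Endemic states: D = lam * D_left * D_right.  The widespread state sums
    the three speciation modes, each symmetrized over the left/right
    daughter assignment with a factor 1/2.  E values are averaged (they
    agree up to integration error).
    """
    lamA = p[0] + p[7] * t
    lamB = p[1] + p[8] * t
    lamAB = p[2]
    out[0] = 0.5 * (y1[0] + y2[0])
    out[1] = 0.5 * (y1[1] + y2[1])
    out[2] = 0.5 * (y1[2] + y2[2])
    out[3] = lamA * y1[3] * y2[3]
    out[4] = lamB * y1[4] * y2[4]
    out[5] = 0.5 * (
        lamA * (y1[3] * y2[5] + y1[5] * y2[3])
        + lamB * (y1[4] * y2[5] + y1[5] * y2[4])
        + lamAB * (y1[3] * y2[4] + y1[4] * y2[3])
    )


@njit(cache=True)
def tree_loglik(
    children,
    ages,
    n_tips,
    tip_state,
    f,
    p,
    rtol,
    atol,
    root_mode,
    cond_surv,
    fixed_state,
):
    """Pruning-algorithm log-likelihood over a postorder-indexed tree.

    Returns ``(lnL, status, bad_node)``; ``status != OK`` flags a
    numerical failure at node ``bad_node``.  A structurally impossible
    observation (all root D = 0) returns ``(-inf, OK, root)``.
    """
    n_nodes = children.shape[0]
    state = np.zeros((n_nodes, 6))
    logcomp = 0.0

    for i in range(n_tips):
        s = tip_state[i]
        for k in range(3):
            state[i, k] = 1.0 - f[k]
        state[i, 3 + s] = f[s]

    y1 = np.empty(6)
    y2 = np.empty(6)
    for node in range(n_tips, n_nodes):
        c1 = children[node, 0]
        c2 = children[node, 1]
        t_node = ages[node]
        for i in range(6):
            y1[i] = state[c1, i]
            y2[i] = state[c2, i]
        st, lc1 = propagate(y1, ages[c1], t_node, p, rtol, atol)
        if st != OK:
            return _MINUS_INF, st, c1
        st, lc2 = propagate(y2, ages[c2], t_node, p, rtol, atol)
        if st != OK:
            return _MINUS_INF, st, c2
        logcomp += lc1 + lc2
        for y in (y1, y2):
            for k in range(3):
                if y[k] < 0.0:
                    y[k] = 0.0
                elif y[k] > 1.0:
                    y[k] = 1.0
        _combine(p, t_node, y1, y2, state[node])
        for i in range(6):
            if not np.isfinite(state[node, i]):
                return _MINUS_INF, NONFINITE, node
        m = state[node, 3]
        if state[node, 4] > m:
            m = state[node, 4]
        if state[node, 5] > m:
            m = state[node, 5]
        if m <= 0.0:
            return _MINUS_INF, OK, node
        state[node, 3] /= m
        state[node, 4] /= m
        state[node, 5] /= m
        logcomp += np.log(m)

    root = n_nodes - 1
    d_root = state[root, 3:6]
    e_root = state[root, 0:3]
    w = np.empty(3)
    if root_mode == ROOT_FITZJOHN:
        tot = d_root[0] + d_root[1] + d_root[2]
        if tot <= 0.0:
            return _MINUS_INF, OK, root
        for k in range(3):
            w[k] = d_root[k] / tot
    elif root_mode == ROOT_EQUAL:
        for k in range(3):
            w[k] = 1.0 / 3.0
    else:
        for k in range(3):
            w[k] = 0.0
        w[fixed_state] = 1.0

    lik = w[0] * d_root[0] + w[1] * d_root[1] + w[2] * d_root[2]
    if lik <= 0.0:
        return _MINUS_INF, OK, root

    if cond_surv:
        t_root = ages[root]
        lamA = p[0] + p[7] * t_root
        lamB = p[1] + p[8] * t_root
        lam_eff0 = lamA
        lam_eff1 = lamB
        lam_eff2 = lamA + lamB + p[2]
        denom = (
            w[0] * lam_eff0 * (1.0 - e_root[0]) ** 2
            + w[1] * lam_eff1 * (1.0 - e_root[1]) ** 2
            + w[2] * lam_eff2 * (1.0 - e_root[2]) ** 2
        )
        if denom <= 0.0:
            return _MINUS_INF, OK, root
        lik /= denom

    return np.log(lik) + logcomp, OK, root
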