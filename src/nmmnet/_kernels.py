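"""Numba-compiled inner loops.

The coupled Jansen-Rit network (6N first-order ODEs), its variational
(tangent) system for Lyapunov spectra, the Benettin two-trajectory MLE and
the Wilson-Cowan pair are all integrated here at fixed step.  The public
modules wrap these kernels; the pure-Python step functions in
:mod:`nmmnet.simulate` implement the identical schemes and serve as the
reference path in tests.

Column parameters are passed as a flat float64 array ``P`` in the order
``(A, B, a, b, C1, C2, C3, C4, e0, r, nu0)``; drive as
``(p_bar, delta, f, phase)``.  Topology is CSR ``(indptr, indices, w)``
with ``w_ij = 1/(N_i N_j)``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# flat-parameter indices
_A, _B, _a, _b, _C1, _C2, _C3, _C4, _e0, _r, _nu0 = range(11)

STATUS_OK = 0
STATUS_BLOWUP = 1
STATUS_TANGENT_COLLAPSE = 2


def pack_params(p) -> np.ndarray:
    return np.array(
        [p.A, p.B, p.a, p.b, p.C1, p.C2, p.C3, p.C4, p.e0, p.r, p.nu0], dtype=np.float64
    )


def pack_drive(d) -> np.ndarray:
    return np.array([d.p_bar, d.delta, d.f, d.phase], dtype=np.float64)


@njit(cache=True, fastmath=False)
def _sig(m, e0, r, nu0):
    z = r * (nu0 - m)
    if z > 500.0:
        z = 500.0
    elif z < -500.0:
        z = -500.0
    return 2.0 * e0 / (1.0 + np.exp(z))


@njit(cache=True, fastmath=False)
def _dsig(m, e0, r, nu0):
    z = r * (nu0 - m)
    if z > 500.0:
        z = 500.0
    elif z < -500.0:
        z = -500.0
    e = np.exp(z)
    return 2.0 * e0 * r * e / ((1.0 + e) * (1.0 + e))


@njit(cache=True, fastmath=False)
def _network_rhs(Y, t, P, D, indptr, indices, w, alpha, beta, out):
    """RHS of the coupled network; ``Y`` and ``out`` have shape (n, 6)."""
    n = Y.shape[0]
    e0, r, nu0 = P[_e0], P[_r], P[_nu0]
    A, B, a, b = P[_A], P[_B], P[_a], P[_b]
    C1, C2, C3, C4 = P[_C1], P[_C2], P[_C3], P[_C4]
    ext = D[0] + D[1] * np.sin(2.0 * np.pi * D[2] * t + D[3])

    s_exc = np.empty(n)
    s_inh = np.empty(n)
    for i in range(n):
        s_exc[i] = _sig(Y[i, 1] - Y[i, 2], e0, r, nu0)
        s_inh[i] = _sig(C3 * Y[i, 0], e0, r, nu0)

    for i in range(n):
        pa = 0.0
        pb = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            pa += w[k] * s_exc[j]
            pb += w[k] * s_inh[j]
        pa *= alpha
        pb *= beta
        out[i, 0] = Y[i, 3]
        out[i, 1] = Y[i, 4]
        out[i, 2] = Y[i, 5]
        out[i, 3] = A * a * s_exc[i] - 2.0 * a * Y[i, 3] - a * a * Y[i, 0]
        out[i, 4] = (
            A * a * (ext + C2 * _sig(C1 * Y[i, 0], e0, r, nu0) + pa)
            - 2.0 * a * Y[i, 4]
            - a * a * Y[i, 1]
        )
        out[i, 5] = B * b * (C4 * s_inh[i] + pb) - 2.0 * b * Y[i, 5] - b * b * Y[i, 2]


@njit(cache=True, fastmath=False)
def _finite(Y):
    # blow-up guard: non-finite, or many orders of magnitude beyond the
    # physiological PSP range (the saturating sigmoid keeps a diverging
    # numerical solution finite for a long time)
    for v in Y.flat:
        if not np.isfinite(v) or np.abs(v) > 1e10:
            return False
    return True


@njit(cache=True, fastmath=False)
def integrate_network(
    Y0, t0, dt, n_steps, keep_from, P, D, indptr, indices, w, alpha, beta,
    store_states, use_ab2,
):
    """Fixed-step integration of the coupled network.

    Heun (predictor-corrector) or two-step Adams-Bashforth (bootstrapped by
    one Heun step).  Samples at steps ``keep_from .. n_steps`` inclusive are
    retained.  Returns ``(outputs, states, status, bad_step)`` where
    ``outputs[i, k]`` is ``y1 - y2`` of node ``i`` at retained sample ``k``.
    """
    n = Y0.shape[0]
    n_keep = n_steps - keep_from + 1
    outputs = np.empty((n, n_keep))
    if store_states:
        states = np.empty((n, 6, n_keep))
    else:
        states = np.empty((n, 6, 1))

    Y = Y0.copy()
    f0 = np.empty((n, 6))
    f1 = np.empty((n, 6))
    Yp = np.empty((n, 6))
    f_prev = np.empty((n, 6))

    k_out = 0
    if keep_from == 0:
        for i in range(n):
            outputs[i, 0] = Y[i, 1] - Y[i, 2]
            if store_states:
                for c in range(6):
                    states[i, c, 0] = Y[i, c]
        k_out = 1

    for step in range(n_steps):
        t = t0 + step * dt
        if use_ab2 and step > 0:
            _network_rhs(Y, t, P, D, indptr, indices, w, alpha, beta, f0)
            for i in range(n):
                for c in range(6):
                    Y[i, c] = Y[i, c] + dt * (1.5 * f0[i, c] - 0.5 * f_prev[i, c])
            for i in range(n):
                for c in range(6):
                    f_prev[i, c] = f0[i, c]
        else:
            _network_rhs(Y, t, P, D, indptr, indices, w, alpha, beta, f0)
            for i in range(n):
                for c in range(6):
                    Yp[i, c] = Y[i, c] + dt * f0[i, c]
            _network_rhs(Yp, t + dt, P, D, indptr, indices, w, alpha, beta, f1)
            for i in range(n):
                for c in range(6):
                    Y[i, c] = Y[i, c] + 0.5 * dt * (f0[i, c] + f1[i, c])
            if use_ab2:
                # AB2 bootstrap: remember the derivative at the step start
                for i in range(n):
                    for c in range(6):
                        f_prev[i, c] = f0[i, c]
        if not _finite(Y):
            return outputs[:, :k_out], states, STATUS_BLOWUP, step + 1
        if step + 1 >= keep_from:
            for i in range(n):
                outputs[i, k_out] = Y[i, 1] - Y[i, 2]
                if store_states:
                    for c in range(6):
                        states[i, c, k_out] = Y[i, c]
            k_out += 1

    return outputs, states, STATUS_OK, -1


@njit(cache=True, fastmath=False)
def _network_jacobian(Yflat, P, indptr, indices, w, alpha, beta, J):
    """Dense Jacobian of the coupled RHS at flat state ``Yflat`` (6n,).

    Per-node 6x6 blocks from the operator reduction plus neighbor blocks
    scaled by ``alpha w_ij`` / ``beta w_ij``.  The additive external drive
    is state-independent and contributes nothing.
    """
    n = Yflat.size // 6
    e0, r, nu0 = P[_e0], P[_r], P[_nu0]
    A, B, a, b = P[_A], P[_B], P[_a], P[_b]
    C1, C2, C3, C4 = P[_C1], P[_C2], P[_C3], P[_C4]
    J[:, :] = 0.0
    for i in range(n):
        o = 6 * i
        y0 = Yflat[o + 0]
        y1 = Yflat[o + 1]
        y2 = Yflat[o + 2]
        ds_pyr = _dsig(y1 - y2, e0, r, nu0)
        ds_y0 = _dsig(C1 * y0, e0, r, nu0)
        ds_inh = _dsig(C3 * y0, e0, r, nu0)
        # position rows: dy/dt = v
        J[o + 0, o + 3] = 1.0
        J[o + 1, o + 4] = 1.0
        J[o + 2, o + 5] = 1.0
        # v0' = A a S(y1-y2) - 2 a v0 - a^2 y0
        J[o + 3, o + 1] = A * a * ds_pyr
        J[o + 3, o + 2] = -A * a * ds_pyr
        J[o + 3, o + 0] = -a * a
        J[o + 3, o + 3] = -2.0 * a
        # v1' = A a (ext + C2 S(C1 y0) + p_alpha) - 2 a v1 - a^2 y1
        J[o + 4, o + 0] = A * a * C2 * C1 * ds_y0
        J[o + 4, o + 1] = -a * a
        J[o + 4, o + 4] = -2.0 * a
        # v2' = B b (C4 S(C3 y0) + p_beta) - 2 b v2 - b^2 y2
        J[o + 5, o + 0] = B * b * C4 * C3 * ds_inh
        J[o + 5, o + 2] = -b * b
        J[o + 5, o + 5] = -2.0 * b
        # neighbor blocks
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            oj = 6 * j
            dsp_j = _dsig(Yflat[oj + 1] - Yflat[oj + 2], e0, r, nu0)
            dsi_j = _dsig(C3 * Yflat[oj + 0], e0, r, nu0)
            J[o + 4, oj + 1] += A * a * alpha * w[k] * dsp_j
            J[o + 4, oj + 2] -= A * a * alpha * w[k] * dsp_j
            J[o + 5, oj + 0] += B * b * beta * w[k] * C3 * dsi_j
    return J


@njit(cache=True, fastmath=False)
def _rhs_flat(Yflat, t, P, D, indptr, indices, w, alpha, beta, out_flat):
    n = Yflat.size // 6
    Y = Yflat.reshape(n, 6)
    out = out_flat.reshape(n, 6)
    _network_rhs(Y, t, P, D, indptr, indices, w, alpha, beta, out)


@njit(cache=True, fastmath=False)
def lyapunov_qr(
    Y0flat, t0, dt, n_transient_steps, n_steps, reortho_every, trace_every,
    P, D, indptr, indices, w, alpha, beta,
):
    """Full Lyapunov spectrum by variational QR integration.

    The state is advanced with two-step Adams-Bashforth (Heun bootstrap);
    the tangent basis ``Q`` obeys ``Q' = J(y) Q`` (the additive drive does
    not enter the Jacobian) and is advanced with a history-free Heun
    (trapezoidal predictor-corrector) update using the Jacobians at the old
    and new states, so re-orthonormalization never invalidates multistep
    history.  Every ``reortho_every`` steps ``Q`` is QR-factorized and
    ``log |diag R|`` accumulated; exponents are the accumulated logs over
    the post-transient time.  Returns ``(exponents_sorted_desc, trace,
    status, bad_step)`` with ``trace`` the running largest-exponent
    estimate sampled every ``trace_every`` steps.
    """
    d = Y0flat.size
    y = Y0flat.copy()
    f_prev = np.empty(d)
    f_cur = np.empty(d)
    yp = np.empty(d)
    f1 = np.empty(d)

    # --- transient: state only, AB2 with Heun bootstrap ---
    for step in range(n_transient_steps):
        t = t0 + step * dt
        if step == 0:
            _rhs_flat(y, t, P, D, indptr, indices, w, alpha, beta, f_cur)
            yp[:] = y + dt * f_cur
            _rhs_flat(yp, t + dt, P, D, indptr, indices, w, alpha, beta, f1)
            y[:] = y + 0.5 * dt * (f_cur + f1)
            f_prev[:] = f_cur
        else:
            _rhs_flat(y, t, P, D, indptr, indices, w, alpha, beta, f_cur)
            y[:] = y + dt * (1.5 * f_cur - 0.5 * f_prev)
            f_prev[:] = f_cur
        if not _finite(y):
            return np.zeros(d), np.zeros(1), STATUS_BLOWUP, step + 1

    # --- accumulation phase: co-integrate tangent basis ---
    t_start = t0 + n_transient_steps * dt
    Q = np.eye(d)
    J_cur = np.empty((d, d))
    J_next = np.empty((d, d))
    lyap_sum = np.zeros(d)
    n_trace = max(1, n_steps // max(1, trace_every))
    trace = np.zeros(n_trace)
    trace_k = 0
    steps_since = 0

    _network_jacobian(y, P, indptr, indices, w, alpha, beta, J_cur)
    # state AB2 history restart for the accumulation phase
    bootstrap = True
    for step in range(n_steps):
        t = t_start + step * dt
        if bootstrap:
            _rhs_flat(y, t, P, D, indptr, indices, w, alpha, beta, f_cur)
            yp[:] = y + dt * f_cur
            _rhs_flat(yp, t + dt, P, D, indptr, indices, w, alpha, beta, f1)
            y[:] = y + 0.5 * dt * (f_cur + f1)
            f_prev[:] = f_cur
            bootstrap = False
        else:
            _rhs_flat(y, t, P, D, indptr, indices, w, alpha, beta, f_cur)
            y[:] = y + dt * (1.5 * f_cur - 0.5 * f_prev)
            f_prev[:] = f_cur
        if not _finite(y):
            return np.zeros(d), trace[:max(1, trace_k)], STATUS_BLOWUP, step + 1

        # tangent Heun update with J at the old and new states
        _network_jacobian(y, P, indptr, indices, w, alpha, beta, J_next)
        K1 = J_cur @ Q
        K2 = J_next @ (Q + dt * K1)
        Q = Q + 0.5 * dt * (K1 + K2)
        J_cur[:, :] = J_next

        steps_since += 1
        if steps_since >= reortho_every or step == n_steps - 1:
            Qf, R = np.linalg.qr(Q)
            for m in range(d):
                rmm = R[m, m]
                if rmm == 0.0:
                    return np.zeros(d), trace[:max(1, trace_k)], STATUS_TANGENT_COLLAPSE, step + 1
                lyap_sum[m] += np.log(np.abs(rmm))
                if rmm < 0.0:
                    for row in range(d):
                        Qf[row, m] = -Qf[row, m]
            Q = np.ascontiguousarray(Qf)
            steps_since = 0
        if trace_every > 0 and (step + 1) % trace_every == 0 and trace_k < n_trace:
            elapsed = (step + 1) * dt
            trace[trace_k] = np.max(lyap_sum) / elapsed
            trace_k += 1

    elapsed_total = n_steps * dt
    exponents = np.sort(lyap_sum / elapsed_total)[::-1].copy()
    return exponents, trace[:max(1, trace_k)], STATUS_OK, -1


@njit(cache=True, fastmath=False)
def benettin_mle(
    Y0flat, t0, dt, n_transient_steps, n_steps, renorm_every, d0,
    P, D, indptr, indices, w, alpha, beta,
):
    """Largest Lyapunov exponent by the two-trajectory (Benettin) method.

    Independent of the QR/variational path: integrates a reference and a
    perturbed trajectory with Heun, renormalizing their separation to
    ``d0`` every ``renorm_every`` steps and accumulating ``log(dist/d0)``.
    """
    d = Y0flat.size
    y = Y0flat.copy()
    f0 = np.empty(d)
    f1 = np.empty(d)
    yp = np.empty(d)

    for step in range(n_transient_steps):
        t = t0 + step * dt
        _rhs_flat(y, t, P, D, indptr, indices, w, alpha, beta, f0)
        yp[:] = y + dt * f0
        _rhs_flat(yp, t + dt, P, D, indptr, indices, w, alpha, beta, f1)
        y[:] = y + 0.5 * dt * (f0 + f1)
        if not _finite(y):
            return 0.0, STATUS_BLOWUP, step + 1

    t_start = t0 + n_transient_steps * dt
    y2 = y.copy()
    y2[0] += d0
    acc = 0.0
    g0 = np.empty(d)
    g1 = np.empty(d)
    y2p = np.empty(d)
    for step in range(n_steps):
        t = t_start + step * dt
        _rhs_flat(y, t, P, D, indptr, indices, w, alpha, beta, f0)
        yp[:] = y + dt * f0
        _rhs_flat(yp, t + dt, P, D, indptr, indices, w, alpha, beta, f1)
        _rhs_flat(y2, t, P, D, indptr, indices, w, alpha, beta, g0)
        y2p[:] = y2 + dt * g0
        _rhs_flat(y2p, t + dt, P, D, indptr, indices, w, alpha, beta, g1)
        y[:] = y + 0.5 * dt * (f0 + f1)
        y2[:] = y2 + 0.5 * dt * (g0 + g1)
        if not _finite(y) or not _finite(y2):
            return 0.0, STATUS_BLOWUP, step + 1
        if (step + 1) % renorm_every == 0 or step == n_steps - 1:
            dist = 0.0
            for c in range(d):
                diff = y2[c] - y[c]
                dist += diff * diff
            dist = np.sqrt(dist)
            if dist == 0.0:
                return 0.0, STATUS_TANGENT_COLLAPSE, step + 1
            acc += np.log(dist / d0)
            scale = d0 / dist
            for c in range(d):
                y2[c] = y[c] + (y2[c] - y[c]) * scale
    return acc / (n_steps * dt), STATUS_OK, -1


@njit(cache=True, fastmath=False)
def integrate_wilson_cowan(
    s0, dt, n_steps, keep_from, a, b, c, d, p1, p2, q1, q2, kexc, kinh
):
    """Heun integration of two diffusively coupled Wilson-Cowan oscillators.

    State ordering ``(x1, y1, x2, y2)``; returns the retained trajectory
    with shape ``(4, n_keep)``.
    """
    n_keep = n_steps - keep_from + 1
    traj = np.empty((4, n_keep))
    s = s0.copy()
    f0 = np.empty(4)
    f1 = np.empty(4)
    sp = np.empty(4)

    def _rhs(state, out):
        x1, yy1, x2, yy2 = state[0], state[1], state[2], state[3]
        out[0] = -x1 + 1.0 / (1.0 + np.exp(-(a * x1 - b * yy1 + p1))) + kexc * (x2 - x1)
        out[1] = -yy1 + 1.0 / (1.0 + np.exp(-(c * x1 - d * yy1 + q1))) + kinh * (yy2 - yy1)
        out[2] = -x2 + 1.0 / (1.0 + np.exp(-(a * x2 - b * yy2 + p2))) + kexc * (x1 - x2)
        out[3] = -yy2 + 1.0 / (1.0 + np.exp(-(c * x2 - d * yy2 + q2))) + kinh * (yy1 - yy2)

    k_out = 0
    if keep_from == 0:
        traj[:, 0] = s
        k_out = 1
    for step in range(n_steps):
        _rhs(s, f0)
        sp[:] = s + dt * f0
        _rhs(sp, f1)
        s[:] = s + 0.5 * dt * (f0 + f1)
        if step + 1 >= keep_from:
            traj[:, k_out] = s
            k_out += 1
    return traj
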