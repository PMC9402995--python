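"""Shared inner machinery for MAP estimation of subject random effects.

The per-subject objective is the -2 log joint density of the data and the
random effects,

    L(eta) = sum_j [ (w_j - f_j)^2 / (sigma f_j)^2 + log(2 pi (sigma f_j)^2) ]
             + eta' Omega^{-1} eta + log det(2 pi Omega),

with f_j the model prediction at the j-th measurement time under the
individualized parameters.  The mode is found by damped Newton iteration with
batched central finite differences (all probe points are evaluated in one
vectorized trajectory call), and the final Hessian is reused for the Laplace
correction in the population marginal likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import _GL_NODES, _GL_WEIGHTS, _MAX_PANEL_H, PARAM_NAMES, trajectory_batch

LOG_2PI = math.log(2.0 * math.pi)

_FD_STEP = 1e-4

try:  # compiled kernel for the hot loop; the numpy path below is the reference
    import numba

    @numba.njit(cache=True)
    def _neg2_kernel(  # pragma: no cover - exercised via neg2_joint_batch
        eta, base_theta, re_idx, times, values, sigma, omega_inv, logdet,
        gl_x, gl_w, max_panel,
    ):
        m, d = eta.shape
        out = np.empty(m)
        ln2 = 0.6931471805599453
        for i in range(m):
            th = base_theta.copy()
            for k in range(d):
                e = eta[i, k]
                if e > 500.0:
                    e = 500.0
                th[re_idx[k]] *= math.exp(e)
            b0, p_ss, a_p, t_p, k_ss, m_e, t_e = (
                th[0], th[1], th[2], th[3], th[4], th[5], th[6]
            )
            lam_p = ln2 / t_p
            lam_e = ln2 / t_e
            c = k_ss * m_e / lam_e
            total = logdet
            for r in range(d):
                for s_ in range(d):
                    total += eta[i, r] * omega_inv[r, s_] * eta[i, s_]
            b_prev = b0
            t_prev = 0.0
            e_prev = 0.0
            bad = False
            for j in range(times.size):
                t = times[j]
                if t > t_prev:
                    e_t = k_ss * t - c * (1.0 - math.exp(-lam_e * t))
                    npan = int(math.ceil((t - t_prev) / max_panel))
                    if npan < 1:
                        npan = 1
                    dt = (t - t_prev) / npan
                    integral = 0.0
                    for pnl in range(npan):
                        a = t_prev + pnl * dt
                        half = 0.5 * dt
                        mid = a + half
                        for q in range(gl_x.size):
                            s = mid + half * gl_x[q]
                            e_s = k_ss * s - c * (1.0 - math.exp(-lam_e * s))
                            kprod = p_ss * (1.0 + a_p * math.exp(-lam_p * s))
                            integral += half * gl_w[q] * kprod * math.exp(e_s - e_t)
                    b_prev = b_prev * math.exp(e_prev - e_t) + integral
                    t_prev = t
                    e_prev = e_t
                f = b_prev
                sd = sigma * f
                if not (sd > 0.0 and math.isfinite(sd)):
                    bad = True
                    break
                resid = (values[j] - f) / sd
                total += resid * resid + math.log(2.0 * math.pi * sd * sd)
            if bad or not math.isfinite(total):
                out[i] = np.inf
            else:
                out[i] = total
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass
class SubjectData:
    """Per-subject quantities that stay fixed while eta varies."""

    base_theta: np.ndarray  # (7,) covariate-adjusted typical values
    re_idx: np.ndarray  # indices into PARAM_NAMES of random-effect parameters
    times: np.ndarray  # (T,) measurement PNA, h
    values: np.ndarray  # (T,) observed TSB, umol/l


def make_subject_data(base_theta: np.ndarray, re_names, times, values) -> SubjectData:
    idx = np.array([PARAM_NAMES.index(n) for n in re_names], dtype=int)
    return SubjectData(
        base_theta=np.asarray(base_theta, dtype=float),
        re_idx=idx,
        times=np.asarray(times, dtype=float),
        values=np.asarray(values, dtype=float),
    )


def neg2_joint_batch(
    eta: np.ndarray,
    subj: SubjectData,
    sigma: float,
    omega_inv: np.ndarray,
    logdet_2pi_omega: float,
) -> np.ndarray:
    """-2 log joint density at a batch of eta points, shape (m, d) -> (m,)."""
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    if _HAVE_NUMBA:
        return _neg2_kernel(
            np.ascontiguousarray(eta),
            subj.base_theta,
            subj.re_idx,
            subj.times,
            subj.values,
            sigma,
            np.ascontiguousarray(omega_inv),
            logdet_2pi_omega,
            _GL_NODES,
            _GL_WEIGHTS,
            _MAX_PANEL_H,
        )
    m = eta.shape[0]
    theta = np.tile(subj.base_theta, (m, 1))
    if subj.re_idx.size:
        with np.errstate(over="ignore"):
            theta[:, subj.re_idx] *= np.exp(np.minimum(eta, 500.0))
    prior = np.einsum("md,dk,mk->m", eta, omega_inv, eta) + logdet_2pi_omega
    if subj.times.size == 0:
        return prior
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        f = trajectory_batch(theta, subj.times)  # (m, T)
        sd = sigma * f
        resid = ((subj.values[None, :] - f) / sd) ** 2 + np.log(2.0 * np.pi * sd**2)
        out = resid.sum(axis=1) + prior
    # f underflows to 0 (or overflows) only at absurd eta probed by line
    # searches; treat those points as infinitely improbable
    out[~np.isfinite(out)] = np.inf
    return out


_OFFSET_CACHE: dict[int, np.ndarray] = {}


def _offsets(d: int) -> np.ndarray:
    """Unit probe offsets for central-difference gradient and Hessian."""
    cached = _OFFSET_CACHE.get(d)
    if cached is not None:
        return cached
    rows = [np.zeros(d)]
    for i in range(d):
        for s in (+1, -1):
            p = np.zeros(d)
            p[i] = s
            rows.append(p)
    for i in range(d):
        for j in range(i + 1, d):
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                p = np.zeros(d)
                p[i], p[j] = si, sj
                rows.append(p)
    out = np.array(rows)
    _OFFSET_CACHE[d] = out
    return out


def _fd_points(eta: np.ndarray, h: float) -> np.ndarray:
    """Probe points for central-difference gradient and Hessian at ``eta``."""
    return eta[None, :] + h * _offsets(eta.size)


def grad_hess(fun_batch, eta: np.ndarray, h: float = _FD_STEP):
    """Central-difference gradient and Hessian from one batched evaluation."""
    d = eta.size
    vals = fun_batch(_fd_points(eta, h))
    f0 = vals[0]
    grad = np.empty(d)
    hess = np.empty((d, d))
    for i in range(d):
        fp, fm = vals[1 + 2 * i], vals[2 + 2 * i]
        grad[i] = (fp - fm) / (2.0 * h)
        hess[i, i] = (fp - 2.0 * f0 + fm) / h**2
    k = 1 + 2 * d
    for i in range(d):
        for j in range(i + 1, d):
            fpp, fpm, fmp, fmm = vals[k : k + 4]
            k += 4
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h**2)
    return f0, grad, hess


def newton_map(
    fun_batch,
    d: int,
    eta0: np.ndarray | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
):
    """Minimize a smooth d-dimensional objective by damped Newton iteration.

    Returns ``(eta_hat, value, hessian, converged)``; the Hessian is the
    finite-difference Hessian at the returned point.
    """
    eta = np.zeros(d) if eta0 is None else np.asarray(eta0, dtype=float).copy()
    if d == 0:
        return eta, float(fun_batch(eta[None, :])[0]), np.empty((0, 0)), True
    # the FD gradient carries O(h^2) noise, so convergence is judged on the
    # Newton step length rather than the raw gradient norm
    step_tol = max(tol, 1e-9)
    value, grad, hess = grad_hess(fun_batch, eta)
    converged = False
    for _ in range(maxiter):
        lam = 0.0
        step = None
        for _ in range(12):
            try:
                np.linalg.cholesky(hess + lam * np.eye(d))  # PD check
                step = -np.linalg.solve(hess + lam * np.eye(d), grad)
                break
            except np.linalg.LinAlgError:
                lam = max(1e-6, 10.0 * lam) if lam else 1e-6
        if step is None:
            step = -grad
        if np.max(np.abs(step)) < step_tol:
            converged = True
            break
        # backtracking line search
        alpha = 1.0
        improved = False
        for _ in range(10):
            cand = eta + alpha * step
            v = float(fun_batch(cand[None, :])[0])
            if np.isfinite(v) and v < value:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            # near the mode FD noise masks descent; tiny steps are converged
            converged = np.max(np.abs(step)) < 1e-5
            break
        eta = cand
        value, grad, hess = grad_hess(fun_batch, eta)
        if np.max(np.abs(alpha * step)) < step_tol:
            converged = True
            break
    else:
        converged = False
    return eta, value, hess, converged


def laplace_term(value: float, hess: np.ndarray) -> float:
    """-2 log marginal contribution: L(mode) - d log 2pi + log det(H/2)."""
    d = hess.shape[0]
    if d == 0:
        return value
    h = 0.5 * (hess + hess.T)
    try:
        chol = np.linalg.cholesky(h)
        logdet_half = 2.0 * float(np.sum(np.log(np.diag(chol)))) - d * math.log(2.0)
    except np.linalg.LinAlgError:
        # guard against slightly indefinite FD Hessians at flat modes
        w = np.linalg.eigvalsh(h)
        floor = max(1e-10, 1e-10 * np.max(np.abs(w)))
        w = np.maximum(w, floor)
        logdet_half = float(np.sum(np.log(w / 2.0)))
    return value - d * LOG_2PI + logdet_half
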