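"""Fixed-step classical Runge-Kutta reference integrator.

A deliberately simple, self-contained transcription of the batch-model
mass balances, integrated with the classical fourth-order Runge-Kutta
scheme at a fixed step.  It shares no code with the production stiff
solver in :mod:`mdolsim.well_mixed` and serves as the independent
cross-check for it, and as the generator of pinned regression fixtures.

Being explicit, the scheme is only stable for ``dt`` safely below
``2.8 / alpha1`` (the fastest intracellular relaxation rate); callers are
expected to verify accuracy by step halving.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .params import ModelParams, TOXICITY_FORMS

__all__ = ["rk4_trajectory", "rk4_steady_state", "params_tuple"]


def params_tuple(p: ModelParams) -> tuple:
    """Flatten a ModelParams into the scalar tuple the jitted kernel takes."""
    return (p.alpha1, p.alpha2, p.beta2, p.bg, p.Cp, p.y,
            p.gamma_s, p.gamma_i, p.gamma_p, p.rho,
            p.effective_theta, float(TOXICITY_FORMS.index(p.toxicity_form)))


@njit(cache=True)
def _deriv(y, alpha1, alpha2, beta2, bg, Cp, yld, gs, gi, gp, rho,
           theta, form):
    s1 = y[0] if y[0] > 0.0 else 0.0
    s2 = y[1] if y[1] > 0.0 else 0.0
    i1 = y[2]
    i2 = y[3] if y[3] > 0.0 else 0.0
    p1 = y[4] if y[4] > 0.0 else 0.0
    p2 = y[5] if y[5] > 0.0 else 0.0
    sout, iout, pout = y[6], y[7], y[8]
    x1, x2 = y[9], y[10]

    react1 = alpha1 * s1 / (1.0 + s1)
    react2 = alpha2 * i2 / (beta2 + i2)
    cons1 = Cp * p1 / (bg + p1)
    cons2 = Cp * p2 / (bg + p2)

    if theta == 0.0 or form == 0.0:
        t1 = 1.0
        t2 = 1.0
    elif form == 1.0:  # reciprocal
        t1 = 1.0 / (1.0 + theta * s1)
        t2 = 1.0 / (1.0 + theta * s2)
    elif form == 2.0:  # exponential
        t1 = np.exp(-theta * s1)
        t2 = np.exp(-theta * s2)
    else:  # linear
        t1 = 1.0 - theta * s1
        t2 = 1.0 - theta * s2
        if t1 < 0.0:
            t1 = 0.0
        if t2 < 0.0:
            t2 = 0.0

    crowd = 1.0 - (x1 + x2) / rho

    f = np.empty(13)
    f[0] = -react1 + gs * (sout - y[0])
    f[1] = gs * (sout - y[1])
    f[2] = react1 - gi * (y[2] - iout)
    f[3] = -react2 + gi * (iout - y[3])
    f[4] = -cons1 + gp * (pout - y[4])
    f[5] = react2 - cons2 + gp * (pout - y[5])
    f[6] = -x1 * gs * (sout - y[0]) - x2 * gs * (sout - y[1])
    f[7] = x1 * gi * (y[2] - iout) - x2 * gi * (iout - y[3])
    f[8] = x2 * gp * (y[5] - pout) - x1 * gp * (pout - y[4])
    f[9] = cons1 * yld * t1 * x1 * crowd
    f[10] = cons2 * yld * t2 * x2 * crowd
    f[11] = x2 * react2
    f[12] = x2 * gp * (y[5] - pout)
    return f


@njit(cache=True)
def _rk4_run(y0, dt, n_steps, record_every,
             alpha1, alpha2, beta2, bg, Cp, yld, gs, gi, gp, rho,
             theta, form, stop_rate_tol):
    n_rec = n_steps // record_every + 1
    out_t = np.empty(n_rec)
    out_y = np.empty((13, n_rec))
    y = y0.copy()
    out_t[0] = 0.0
    out_y[:, 0] = y
    rec = 1
    last = 0
    for k in range(1, n_steps + 1):
        k1 = _deriv(y, alpha1, alpha2, beta2, bg, Cp, yld, gs, gi, gp,
                    rho, theta, form)
        k2 = _deriv(y + 0.5 * dt * k1, alpha1, alpha2, beta2, bg, Cp, yld,
                    gs, gi, gp, rho, theta, form)
        k3 = _deriv(y + 0.5 * dt * k2, alpha1, alpha2, beta2, bg, Cp, yld,
                    gs, gi, gp, rho, theta, form)
        k4 = _deriv(y + dt * k3, alpha1, alpha2, beta2, bg, Cp, yld,
                    gs, gi, gp, rho, theta, form)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if k % record_every == 0:
            out_t[rec] = k * dt
            out_y[:, rec] = y
            rec += 1
            last = k
            if stop_rate_tol > 0.0:
                f = _deriv(y, alpha1, alpha2, beta2, bg, Cp, yld, gs, gi,
                           gp, rho, theta, form)
                done = True
                for j in range(11):
                    sc = 1.0 if abs(y[j]) < 1.0 else abs(y[j])
                    if abs(f[j]) >= stop_rate_tol * sc:
                        done = False
                        break
                if done:
                    break
    return out_t[:rec], out_y[:, :rec], last


def rk4_trajectory(params: ModelParams, y0: np.ndarray, dt: float,
                   tau_end: float, record_every: int = 1000
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Integrate to ``tau_end`` at fixed step ``dt``; returns (tau, states)."""
    n_steps = int(round(tau_end / dt))
    t, y, _ = _rk4_run(np.asarray(y0, float), dt, n_steps, record_every,
                       *params_tuple(params), 0.0)
    return t, y


def rk4_steady_state(params: ModelParams, y0: np.ndarray, dt: float,
                     tau_max: float, rate_tol: float = 1e-8,
                     check_every: int = 10_000
                     ) -> tuple[np.ndarray, float, bool]:
    """Run until all state derivatives relax below ``rate_tol`` (scaled).

    Returns (final_state, tau_end, converged).
    """
    n_steps = int(round(tau_max / dt))
    t, y, last = _rk4_run(np.asarray(y0, float), dt, n_steps, check_every,
                          *params_tuple(params), rate_tol)
    return y[:, -1], float(t[-1]), last < n_steps
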