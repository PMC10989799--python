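"""Independent oracles used by the test suite.

The fixed-step RK4 integrator below is written directly from the model's
mass balances, on purpose sharing no code with the package (neither the
production stiff solver nor the package's own reference integrator), so
it can serve as an independent check of both.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _f(y, a1, a2, b2, bg, cp, yy, gs, gi, gp, rho, theta):
    out = np.empty(11)
    s1 = y[0] if y[0] > 0 else 0.0
    s2 = y[1] if y[1] > 0 else 0.0
    i2 = y[3] if y[3] > 0 else 0.0
    p1 = y[4] if y[4] > 0 else 0.0
    p2 = y[5] if y[5] > 0 else 0.0
    v1 = a1 * s1 / (1.0 + s1)
    v2 = a2 * i2 / (b2 + i2)
    w1 = cp * p1 / (bg + p1)
    w2 = cp * p2 / (bg + p2)
    tox1 = 1.0 / (1.0 + theta * s1)
    tox2 = 1.0 / (1.0 + theta * s2)
    room = 1.0 - (y[9] + y[10]) / rho
    out[0] = -v1 + gs * (y[6] - y[0])
    out[1] = gs * (y[6] - y[1])
    out[2] = v1 - gi * (y[2] - y[7])
    out[3] = -v2 + gi * (y[7] - y[3])
    out[4] = -w1 + gp * (y[8] - y[4])
    out[5] = v2 - w2 + gp * (y[8] - y[5])
    out[6] = -y[9] * gs * (y[6] - y[0]) - y[10] * gs * (y[6] - y[1])
    out[7] = y[9] * gi * (y[2] - y[7]) - y[10] * gi * (y[7] - y[3])
    out[8] = y[10] * gp * (y[5] - y[8]) - y[9] * gp * (y[8] - y[4])
    out[9] = w1 * yy * tox1 * y[9] * room
    out[10] = w2 * yy * tox2 * y[10] * room
    return out


@njit(cache=True)
def rk4(y0, dt, n_steps, a1, a2, b2, bg, cp, yy, gs, gi, gp, rho, theta):
    y = y0.copy()
    for _ in range(n_steps):
        k1 = _f(y, a1, a2, b2, bg, cp, yy, gs, gi, gp, rho, theta)
        k2 = _f(y + 0.5 * dt * k1, a1, a2, b2, bg, cp, yy, gs, gi, gp,
                rho, theta)
        k3 = _f(y + 0.5 * dt * k2, a1, a2, b2, bg, cp, yy, gs, gi, gp,
                rho, theta)
        k4 = _f(y + dt * k3, a1, a2, b2, bg, cp, yy, gs, gi, gp, rho, theta)
        y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def rk4_states(params, y0_13, dt, tau_end):
    """Integrate the 11 physical states to tau_end; returns the state."""
    args = (params.alpha1, params.alpha2, params.beta2, params.bg, params.Cp,
            params.y, params.gamma_s, params.gamma_i, params.gamma_p,
            params.rho, params.effective_theta)
    n = int(round(tau_end / dt))
    return rk4(np.asarray(y0_13[:11], dtype=float), dt, n, *args)
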