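"""Well-mixed batch model of a two-strain MDOL consortium.

Eleven coupled ODEs track, in dimensionless form, the intracellular
substrate / intermediate / product concentrations of each strain
(``s1_in, s2_in, i1_in, i2_in, p1_in, p2_in``), the shared extracellular
pools (``s_out, i_out, p_out``) and the two biomasses (``x1`` Detoxifier,
``x2`` Embezzler).  Two auxiliary quadratures accumulate the product
synthesized by, and net-exported from, the Embezzler population so that
product *leakiness* can be computed after the fact.

Kinetics
--------
* Reaction 1 (Detoxifier only):  S -> I at rate ``alpha1*s1_in/(1+s1_in)``.
* Reaction 2 (Embezzler only):   I -> P at rate ``alpha2*i2_in/(beta2+i2_in)``.
* Product consumption (both):    ``Cp*p_in/(bg+p_in)`` per unit biomass.
* Passive transport:             ``gamma*(out - in)`` per species; the
  environment pool changes by the biomass-weighted opposite flux, so
  exchange is antisymmetric and mass-consistent.
* Growth: logistic, ``dx/dtau = Cp*p_in/(bg+p_in) * y * t(s_in) * x *
  (1 - (x1+x2)/rho)`` where ``t`` is the substrate-toxicity factor.

A trajectory is integrated with a stiff implicit solver (Radau with an
analytic Jacobian; both compiled with numba) in geometrically growing
chunks until the composition has demonstrably stopped moving, or until
``tau_max``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import BDF, Radau

from .params import ModelParams, TOXICITY_FORMS

__all__ = [
    "STATE_NAMES", "NSTATE", "SolverProtocol", "SteadyStateResult",
    "Trajectory", "toxicity_factor", "derivatives", "jacobian",
    "initial_state", "simulate_batch", "steady_state_fraction",
    "product_leakiness", "SimulationError",
]

#: Order of the integrated quantities (11 states + 2 auxiliary integrals).
STATE_NAMES = (
    "s1_in", "s2_in", "i1_in", "i2_in", "p1_in", "p2_in",
    "s_out", "i_out", "p_out", "x1", "x2",
    "aux_p_synth", "aux_p_export2",
)
NSTATE = len(STATE_NAMES)
_IDX = {name: k for k, name in enumerate(STATE_NAMES)}


class SimulationError(RuntimeError):
    """Raised when the integrator fails; carries the last valid state."""

    def __init__(self, message: str, tau: float | None = None,
                 state: np.ndarray | None = None):
        super().__init__(message)
        self.tau = tau
        self.state = state


def toxicity_factor(params: ModelParams, s_in):
    """Growth-inhibition factor t(s_in) in (0, 1].

    Equals 1 when toxicity is disabled (theta=0 or form ``none``) and is
    non-increasing in both the intracellular substrate concentration and
    the toxicity degree.  Shapes:

    * ``reciprocal``:  1 / (1 + theta*s_in)   (the default)
    * ``exponential``: exp(-theta*s_in)
    * ``linear``:      max(0, 1 - theta*s_in)
    """
    s_in = np.asarray(s_in, dtype=float)
    if np.any(s_in < 0):
        raise ValueError("intracellular substrate concentration must be >= 0")
    theta = params.effective_theta
    if theta == 0.0:
        return np.ones_like(s_in)[()] if s_in.ndim else 1.0
    form = params.toxicity_form
    if form == "reciprocal":
        out = 1.0 / (1.0 + theta * s_in)
    elif form == "exponential":
        out = np.exp(-theta * s_in)
    else:  # linear
        out = np.maximum(0.0, 1.0 - theta * s_in)
    return out[()] if s_in.ndim == 0 else out


def _tox_and_slope(form: str, theta: float, s: float) -> tuple[float, float]:
    """Toxicity factor and its derivative w.r.t. s_in (scalar fast path)."""
    if theta == 0.0:
        return 1.0, 0.0
    if form == "reciprocal":
        d = 1.0 + theta * s
        return 1.0 / d, -theta / (d * d)
    if form == "exponential":
        t = np.exp(-theta * s)
        return t, -theta * t
    t = 1.0 - theta * s
    return (t, -theta) if t > 0.0 else (0.0, 0.0)


def derivatives(state, params: ModelParams):
    """Right-hand side of the batch model for the 13 tracked quantities.

    Accepts any array-like of length ``NSTATE`` ordered as
    :data:`STATE_NAMES`.  Raises :class:`SimulationError` on NaN/Inf input.
    """
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state encountered", state=y)
    return _rhs(0.0, y, params)


def _pack(p: ModelParams) -> np.ndarray:
    """Parameter vector consumed by the jitted kernels."""
    return np.array([p.alpha1, p.alpha2, p.beta2, p.bg, p.Cp, p.y,
                     p.gamma_s, p.gamma_i, p.gamma_p, p.rho,
                     p.effective_theta,
                     float(TOXICITY_FORMS.index(p.toxicity_form)),
                     p.death_rate])


@njit(cache=True)
def _tox_pair(theta, form, s):
    """(factor, d factor / d s_in) for the configured toxicity shape."""
    if theta == 0.0 or form == 0.0:
        return 1.0, 0.0
    if form == 1.0:  # reciprocal
        d = 1.0 + theta * s
        return 1.0 / d, -theta / (d * d)
    if form == 2.0:  # exponential
        t = np.exp(-theta * s)
        return t, -theta * t
    t = 1.0 - theta * s  # linear
    if t > 0.0:
        return t, -theta
    return 0.0, 0.0


@njit(cache=True)
def _rhs_kernel(y: np.ndarray, pv: np.ndarray) -> np.ndarray:
    alpha1, alpha2, beta2, bg, Cp, yld = pv[0], pv[1], pv[2], pv[3], pv[4], pv[5]
    gs, gi, gp, rho, theta, form, death = (pv[6], pv[7], pv[8], pv[9],
                                           pv[10], pv[11], pv[12])
    s1, s2, i1, i2, p1, p2 = y[0], y[1], y[2], y[3], y[4], y[5]
    sout, iout, pout, x1, x2 = y[6], y[7], y[8], y[9], y[10]
    # The Monod terms are evaluated on the raw values: they are smooth
    # through 0, and clamping would put a derivative kink exactly on the
    # depleted-pool boundary the late trajectory rides, which makes the
    # implicit solvers thrash.  Tolerance-scale negative excursions give
    # tolerance-scale negative rates, which is harmless.
    r1 = alpha1 * s1 / (1.0 + s1)
    r2 = alpha2 * i2 / (beta2 + i2)
    u1 = Cp * p1 / (bg + p1)
    u2 = Cp * p2 / (bg + p2)

    t1, _ = _tox_pair(theta, form, s1)
    t2, _ = _tox_pair(theta, form, s2)
    logistic = 1.0 - (x1 + x2) / rho

    f = np.empty(13)
    f[0] = -r1 + gs * (sout - s1)
    f[1] = gs * (sout - s2)
    f[2] = r1 - gi * (i1 - iout)
    f[3] = -r2 + gi * (iout - i2)
    f[4] = -u1 + gp * (pout - p1)
    f[5] = r2 - u2 + gp * (pout - p2)
    f[6] = -x1 * gs * (sout - s1) - x2 * gs * (sout - s2)
    f[7] = x1 * gi * (i1 - iout) - x2 * gi * (iout - i2)
    f[8] = x2 * gp * (p2 - pout) - x1 * gp * (pout - p1)
    f[9] = u1 * yld * t1 * x1 * logistic - death * x1
    f[10] = u2 * yld * t2 * x2 * logistic - death * x2
    # Auxiliary quadratures: Embezzler-population product synthesis and
    # net export to the environment.
    f[11] = x2 * r2
    f[12] = x2 * gp * (p2 - pout)
    return f


def _rhs(tau: float, y: np.ndarray, p: ModelParams) -> np.ndarray:
    return _rhs_kernel(np.asarray(y, dtype=float), _pack(p))


def jacobian(state, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`derivatives` (13 x 13)."""
    y = np.asarray(state, dtype=float)
    return _jac(0.0, y, params)


@njit(cache=True)
def _jac_kernel(y: np.ndarray, pv: np.ndarray) -> np.ndarray:
    alpha1, alpha2, beta2, bg, Cp, yld = pv[0], pv[1], pv[2], pv[3], pv[4], pv[5]
    gs, gi, gp, rho, theta, form, death = (pv[6], pv[7], pv[8], pv[9],
                                           pv[10], pv[11], pv[12])
    s1, s2, i1, i2, p1, p2 = y[0], y[1], y[2], y[3], y[4], y[5]
    sout, iout, pout, x1, x2 = y[6], y[7], y[8], y[9], y[10]
    dr1 = alpha1 / (1.0 + s1) ** 2
    dr2 = alpha2 * beta2 / (beta2 + i2) ** 2
    u1 = Cp * p1 / (bg + p1)
    u2 = Cp * p2 / (bg + p2)
    du1 = Cp * bg / (bg + p1) ** 2
    du2 = Cp * bg / (bg + p2) ** 2

    t1, dt1 = _tox_pair(theta, form, s1)
    t2, dt2 = _tox_pair(theta, form, s2)
    L = 1.0 - (x1 + x2) / rho
    r2 = alpha2 * i2 / (beta2 + i2)

    J = np.zeros((13, 13))
    # s1_in
    J[0, 0] = -dr1 - gs
    J[0, 6] = gs
    # s2_in
    J[1, 1] = -gs
    J[1, 6] = gs
    # i1_in
    J[2, 0] = dr1
    J[2, 2] = -gi
    J[2, 7] = gi
    # i2_in
    J[3, 3] = -dr2 - gi
    J[3, 7] = gi
    # p1_in
    J[4, 4] = -du1 - gp
    J[4, 8] = gp
    # p2_in
    J[5, 3] = dr2
    J[5, 5] = -du2 - gp
    J[5, 8] = gp
    # s_out
    J[6, 0] = x1 * gs
    J[6, 1] = x2 * gs
    J[6, 6] = -(x1 + x2) * gs
    J[6, 9] = -gs * (sout - s1)
    J[6, 10] = -gs * (sout - s2)
    # i_out
    J[7, 2] = x1 * gi
    J[7, 3] = x2 * gi
    J[7, 7] = -(x1 + x2) * gi
    J[7, 9] = gi * (i1 - iout)
    J[7, 10] = -gi * (iout - i2)
    # p_out
    J[8, 4] = x1 * gp
    J[8, 5] = x2 * gp
    J[8, 8] = -(x1 + x2) * gp
    J[8, 9] = -gp * (pout - p1)
    J[8, 10] = gp * (p2 - pout)
    # x1
    J[9, 0] = u1 * yld * dt1 * x1 * L
    J[9, 4] = du1 * yld * t1 * x1 * L
    J[9, 9] = u1 * yld * t1 * (L - x1 / rho) - death
    J[9, 10] = -u1 * yld * t1 * x1 / rho
    # x2
    J[10, 1] = u2 * yld * dt2 * x2 * L
    J[10, 5] = du2 * yld * t2 * x2 * L
    J[10, 9] = -u2 * yld * t2 * x2 / rho
    J[10, 10] = u2 * yld * t2 * (L - x2 / rho) - death
    # aux_p_synth
    J[11, 3] = x2 * dr2
    J[11, 10] = r2
    # aux_p_export2
    J[12, 5] = x2 * gp
    J[12, 8] = -x2 * gp
    J[12, 10] = gp * (p2 - pout)
    return J


def _jac(tau: float, y: np.ndarray, p: ModelParams) -> np.ndarray:
    return _jac_kernel(np.asarray(y, dtype=float), _pack(p))


def initial_state(params: ModelParams, inoculum_fraction: float = 0.05,
                  detoxifier_share: float = 0.5) -> np.ndarray:
    """1:1 inoculum at 10% of carrying capacity; only s_out starts non-zero.

    The default emulates a fresh batch started by a 1:10 back-dilution of
    a saturated culture (each strain at ``inoculum_fraction`` of rho).
    """
    y0 = np.zeros(NSTATE)
    y0[_IDX["s_out"]] = params.s0
    total = 2.0 * inoculum_fraction * params.rho
    y0[_IDX["x1"]] = total * detoxifier_share
    y0[_IDX["x2"]] = total * (1.0 - detoxifier_share)
    return y0


@dataclass(frozen=True)
class SolverProtocol:
    """Integration and steady-state detection settings.

    ``rate_tol`` bounds the scaled magnitude of every state derivative at
    the endpoint; ``df_tol`` bounds the drift of the Detoxifier fraction
    over a trailing window covering ``window`` of the elapsed time.
    """

    rtol: float = 1e-9
    atol: float = 1e-12
    rate_tol: float = 1e-8
    df_tol: float = 1e-6
    carbon_tol: float = 1e-5
    ratio_rate_tol: float = 1e-10
    #: Without death, composition is frozen once total biomass reaches the
    #: carrying capacity; stopping there skips the (composition-neutral)
    #: tail in which leftover pools drain, at the price of reporting the
    #: auxiliary leakiness integrals up to that point only.
    stop_at_capacity: bool = False
    chunk_step_budget: int = 1500
    window: float = 0.05
    first_chunk: float = 500.0
    chunk_factor: float = 2.0
    # Radau damps the oscillatory stiff modes that appear when the
    # community rides the carrying-capacity boundary; BDF can grind there.
    method: str = "Radau"


#: Looser settings for large parameter sweeps, where only the steady-state
#: composition (a quantity of magnitude 1) is consumed downstream; the
#: compositions match the tight defaults to five decimals.
SWEEP_PROTOCOL = SolverProtocol(rtol=1e-6, atol=1e-9, stop_at_capacity=True)


@dataclass(frozen=True)
class SteadyStateResult:
    """Terminal community structure of a batch run.

    ``df`` is the Detoxifier share of the biomass *formed during the
    batch* (inoculum-subtracted), the composition the degradation episode
    itself produced; when essentially no growth occurred it falls back to
    the total-biomass ratio (the inoculum composition).  ``df_total`` is
    the plain terminal ratio x1/(x1+x2).
    """

    df: float
    df_total: float
    leakiness: float
    s_in_by_strain: tuple[float, float]
    p_in_by_strain: tuple[float, float]
    tau_end: float
    converged: bool


@dataclass
class Trajectory:
    """Solution path of :func:`simulate_batch` with its steady-state summary."""

    tau: np.ndarray
    states: np.ndarray  # shape (NSTATE, len(tau))
    params: ModelParams
    steady_state: SteadyStateResult = field(repr=False, default=None)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[_IDX[name]]

    @property
    def detoxifier_fraction(self) -> np.ndarray:
        tot = self["x1"] + self["x2"]
        return np.divide(self["x1"], tot, out=np.full_like(tot, np.nan),
                         where=tot > 0)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states[:11].T, columns=STATE_NAMES[:11])
        df.insert(0, "tau", self.tau)
        return df

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def summary(self) -> dict:
        ss = self.steady_state
        return {
            "df": ss.df,
            "leakiness": ss.leakiness,
            "s1_in": ss.s_in_by_strain[0], "s2_in": ss.s_in_by_strain[1],
            "p1_in": ss.p_in_by_strain[0], "p2_in": ss.p_in_by_strain[1],
            "tau_end": ss.tau_end,
            "converged": ss.converged,
        }


def _df_at(tau: np.ndarray, x1: np.ndarray, x2: np.ndarray, t: float) -> float:
    k = int(np.searchsorted(tau, t, side="right")) - 1
    k = max(k, 0)
    tot = x1[k] + x2[k]
    return x1[k] / tot if tot > 0 else np.nan


def simulate_batch(params: ModelParams, init: np.ndarray | None = None,
                   tau_max: float = 1e6,
                   protocol: SolverProtocol = SolverProtocol()) -> Trajectory:
    """Integrate the batch model until steady state (or ``tau_max``).

    Returns a :class:`Trajectory` whose ``steady_state`` summarizes the
    terminal composition.  ``converged`` is False when ``tau_max`` was hit
    before the steady-state criterion was met.
    """
    if tau_max <= 0:
        raise ValueError("tau_max must be positive")
    y0 = initial_state(params) if init is None else np.asarray(init, float).copy()
    if y0.shape != (NSTATE,):
        raise ValueError(f"initial state must have length {NSTATE}")
    if np.any(y0[:11] < 0):
        raise ValueError("initial state must be non-negative")

    pv = _pack(params)

    def rhs(t, y_):
        return _rhs_kernel(y_, pv)

    def jac(t, y_):
        return _jac_kernel(y_, pv)

    # Radau and BDF each have (different) parameter corners where their
    # step controller grinds to thousands of tiny steps; a per-chunk step
    # budget detects that and the integration continues with the other
    # method from wherever the stalled attempt got to.
    methods = [protocol.method] + [m for m in ("Radau", "BDF")
                                   if m != protocol.method]
    solver_cls = {"Radau": Radau, "BDF": BDF}
    ts = [np.array([0.0])]
    ys = [y0[:, None]]
    t0, y = 0.0, y0
    chunk = protocol.first_chunk
    converged = False
    while t0 < tau_max:
        t1 = min(t0 + chunk, tau_max)
        solver = solver_cls[methods[0]](rhs, t0, y, t1, jac=jac,
                                        rtol=protocol.rtol,
                                        atol=protocol.atol)
        tt, yy = [], []
        completed = False
        for _ in range(protocol.chunk_step_budget):
            solver.step()
            if solver.status == "failed":
                raise SimulationError(
                    f"stiff solver failed at tau={solver.t}",
                    tau=solver.t, state=solver.y)
            tt.append(solver.t)
            yy.append(solver.y)
            if solver.status == "finished":
                completed = True
                break
        if not completed:  # step controller is grinding: switch methods
            methods.append(methods.pop(0))
        sol_status_partial = not completed
        ts.append(np.asarray(tt))
        ys.append(np.stack(yy, axis=1))
        t0, y = tt[-1], yy[-1]
        # Steady-state test, three routes:
        #  (a) every state derivative has relaxed (true fixed point);
        #  (b) the convertible carbon is exhausted, so no further growth
        #      can move the composition;
        #  (c) the per-capita growth rates of the two strains have
        #      equalized (their difference is what moves the composition;
        #      first-order death cancels in it), so the Detoxifier
        #      fraction is frozen even while both strains still decay.
        # Every route additionally requires the Detoxifier fraction to be
        # flat over the trailing window.
        f = _rhs_kernel(y, pv)
        scale = np.maximum(1.0, np.abs(y[:11]))
        rates_flat = np.all(np.abs(f[:11]) < protocol.rate_tol * scale)
        carbon = (y[6] + y[7] + y[8]
                  + y[9] * (y[0] + y[2] + y[4])
                  + y[10] * (y[1] + y[3] + y[5]))
        carbon_gone = carbon < protocol.carbon_tol * max(params.s0, 1.0)
        ratio_frozen = False
        if y[9] > 0.0 and y[10] > 0.0 and t0 >= 10 * protocol.first_chunk:
            ratio_frozen = abs(f[9] / y[9] - f[10] / y[10]) \
                < protocol.ratio_rate_tol
        # Within 1e-4 of capacity the remaining growth can move the
        # composition by at most ~1e-4 absolute, and the df-stability
        # window below still has to pass.
        at_capacity = (protocol.stop_at_capacity
                       and params.death_rate == 0.0
                       and y[9] + y[10] >= params.rho * (1.0 - 1e-4))
        if rates_flat or carbon_gone or ratio_frozen or at_capacity:
            tau_all = np.concatenate(ts)
            x1_all = np.concatenate([a[9] for a in ys])
            x2_all = np.concatenate([a[10] for a in ys])
            df_now = _df_at(tau_all, x1_all, x2_all, t0)
            df_then = _df_at(tau_all, x1_all, x2_all,
                             t0 * (1.0 - protocol.window))
            if (np.isnan(df_now) and np.isnan(df_then)) or \
                    abs(df_now - df_then) < protocol.df_tol:
                converged = True
                break
        if not sol_status_partial:
            chunk *= protocol.chunk_factor
    tau = np.concatenate(ts)
    states = np.concatenate(ys, axis=1)
    # Clip solver-tolerance negative excursions; anything clearly beyond
    # the local-error scale of the configured tolerances is a bug.
    neg = states[:11].min()
    undershoot = max(1e-6, 10.0 * protocol.rtol * max(1.0, params.s0))
    if neg < -undershoot:
        warnings.warn(f"state went negative beyond tolerance (min={neg:.3e})")
    states[:11] = np.maximum(states[:11], 0.0)

    traj = Trajectory(tau=tau, states=states, params=params)
    yf = states[:, -1]
    tot = yf[9] + yf[10]
    df_total = yf[9] / tot if tot > 0 else np.nan
    # Composition of the newly grown biomass: subtract the inoculum.  When
    # the batch produced essentially no growth the measure falls back to
    # the (unchanged) total-biomass composition.
    grown = tot - (y0[9] + y0[10])
    if grown > 1e-4 * (y0[9] + y0[10]):
        df = (yf[9] - y0[9]) / grown
        df = min(max(df, 0.0), 1.0)
    else:
        df = df_total
    traj.steady_state = SteadyStateResult(
        df=float(df),
        df_total=float(df_total),
        leakiness=product_leakiness(traj),
        s_in_by_strain=(float(yf[0]), float(yf[1])),
        p_in_by_strain=(float(yf[4]), float(yf[5])),
        tau_end=float(tau[-1]),
        converged=converged,
    )
    return traj


def steady_state_fraction(traj: Trajectory) -> float:
    """Detoxifier fraction x1/(x1+x2) at the end of the trajectory."""
    x1 = traj["x1"][-1]
    x2 = traj["x2"][-1]
    if x1 + x2 <= 0:
        raise ZeroDivisionError("total biomass is zero: composition undefined")
    return float(x1 / (x1 + x2))


def product_leakiness(traj: Trajectory) -> float:
    """Cumulative P exported from the Embezzler over cumulative P synthesized.

    Returns 0 when no product was ever synthesized.  The net-export
    quadrature can dip marginally negative (re-import); the ratio is
    clipped to [0, 1].
    """
    synth = traj["aux_p_synth"][-1]
    if synth <= 0.0:
        return 0.0
    export = traj["aux_p_export2"][-1]
    return float(min(max(export / synth, 0.0), 1.0))
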