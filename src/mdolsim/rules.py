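"""Closed-form community-structure rules and their nonlinear fitting.

Three nested Monod-like rules predict the steady-state Detoxifier
fraction ``DF``:

* ``eq1``  DF = Fdmax * s0 / (ks + s0)
  -- substrate concentration alone (no toxicity).
* ``eq2``  DF = eq1 * (1 + Tsmax * theta*s0 / (kt + theta*s0))
  -- toxicity multiplies the attainable fraction by up to (1 + Tsmax).
* ``eq3``  DF = eq2 * [ s0*Ds/(kd1 + s0*Ds) - theta*Ds/(kd2 + theta*Ds) ]
  -- substrate diffusivity Ds has two opposing effects in spatially
  structured colonies: thickening the active layer (first term) versus
  raising the toxic exposure of edge cells (second term).

Constants are estimated by trust-region nonlinear least squares with
multi-start initialization from a seeded Latin hypercube, and goodness of
fit is summarized by the adjusted R^2.  Note that eq2 is unbounded above
1 in the joint large-s0 / large-theta limit; predictions are returned raw
and fits flag any predicted value above 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = ["RuleFit", "predict_fraction", "fit_rule", "adjusted_r2",
           "RULE_PARAM_NAMES"]

RULE_PARAM_NAMES = {
    "eq1": ("fd_max", "ks"),
    "eq2": ("fd_max", "ks", "ts_max", "kt"),
    "eq3": ("fd_max", "ks", "ts_max", "kt", "kd1", "kd2"),
}

# Fitting bounds: fd_max in [0,1]; half-saturation constants span the
# decades a dimensionless substrate axis can occupy; ts_max in [0, 100].
_BOUNDS = {
    "fd_max": (0.0, 1.0),
    "ks": (1e-3, 1e5),
    "ts_max": (0.0, 1e2),
    "kt": (1e-3, 1e5),
    "kd1": (1e-3, 1e5),
    "kd2": (1e-3, 1e5),
}


@dataclass
class RuleFit:
    """Fitted constants of one structure rule plus fit diagnostics."""

    rule_id: str
    params: dict[str, float]
    adjusted_r2: float = np.nan
    r2: float = np.nan
    sse: float = np.nan
    stderr: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray | None = field(default=None, repr=False)
    converged: bool = True
    n_obs: int = 0
    predicted_above_one: bool = False

    def predict(self, s0, theta=0.0, Ds=None):
        return predict_fraction(self, s0, theta=theta, Ds=Ds)

    def confidence_interval(self, name: str, level: float = 0.95
                            ) -> tuple[float, float]:
        """Asymptotic (Wald) confidence interval for one constant."""
        from scipy.stats import t as tdist
        dof = max(self.n_obs - len(self.params), 1)
        half = tdist.ppf(0.5 + level / 2.0, dof) * self.stderr[name]
        est = self.params[name]
        return est - half, est + half

    def to_dict(self) -> dict:
        return {
            "rule_id": self.rule_id,
            **self.params,
            "adjusted_r2": self.adjusted_r2,
            "r2": self.r2,
            "sse": self.sse,
            "stderr": self.stderr,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "predicted_above_one": self.predicted_above_one,
        }


def _rule_values(rule_id: str, p: np.ndarray, s0, theta, Ds):
    s0 = np.asarray(s0, dtype=float)
    base = p[0] * s0 / (p[1] + s0)
    if rule_id == "eq1":
        return base
    theta = np.asarray(theta, dtype=float)
    ts = theta * s0
    tox = 1.0 + p[2] * ts / (p[3] + ts)
    if rule_id == "eq2":
        return base * tox
    Ds = np.asarray(Ds, dtype=float)
    bracket = s0 * Ds / (p[4] + s0 * Ds) - theta * Ds / (p[5] + theta * Ds)
    return base * tox * bracket


def predict_fraction(rule: RuleFit | dict, s0, theta=0.0, Ds=None):
    """Evaluate a structure rule.  No clamping is applied; values above 1
    are possible for eq2/eq3 at extreme (s0, theta)."""
    if isinstance(rule, RuleFit):
        rule_id, params = rule.rule_id, rule.params
    else:
        rule_id, params = rule["rule_id"], rule
    names = RULE_PARAM_NAMES[rule_id]
    p = np.array([params[n] for n in names], dtype=float)
    if rule_id == "eq3" and Ds is None:
        raise ValueError("eq3 requires the substrate diffusivity Ds")
    out = _rule_values(rule_id, p, s0, theta, Ds)
    return out[()] if np.ndim(out) == 0 else out


def adjusted_r2(observed, predicted, n_params: int) -> float:
    """Adjusted coefficient of determination against the mean-only model.

    ``1 - (1 - R^2) * (n - 1) / (n - n_params - 1)``.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    n = obs.size
    if n <= n_params + 1:
        raise ValueError("adjusted R^2 undefined: need n > n_params + 1")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _starts(rule_id: str, n_starts: int, seed: int) -> np.ndarray:
    names = RULE_PARAM_NAMES[rule_id]
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n_starts)
    starts = np.empty_like(u)
    for j, name in enumerate(names):
        lo, hi = _BOUNDS[name]
        if lo > 0:  # half-saturation constants: sample in log space
            starts[:, j] = 10 ** (np.log10(lo) + u[:, j]
                                  * (np.log10(hi) - np.log10(lo)))
        else:
            span = min(hi, 10.0)  # keep additive starts in a sane range
            starts[:, j] = lo + u[:, j] * (span - lo)
    return starts


def fit_rule(observations: pd.DataFrame, rule_id: str,
             n_starts: int = 10, seed: int = 1234) -> RuleFit:
    """Fit one structure rule to observed compositions.

    ``observations`` needs columns ``s0`` and ``df``; ``theta`` (eq2/eq3)
    and ``Ds`` (eq3) where the rule uses them.  Multi-start trust-region
    least squares; the start with the lowest SSE wins.
    """
    if rule_id not in RULE_PARAM_NAMES:
        raise ValueError(f"unknown rule_id {rule_id!r}")
    names = RULE_PARAM_NAMES[rule_id]
    obs = observations
    s0 = np.asarray(obs["s0"], dtype=float)
    df = np.asarray(obs["df"], dtype=float)
    theta = (np.asarray(obs["theta"], dtype=float)
             if "theta" in obs else np.zeros_like(s0))
    if rule_id == "eq3":
        if "Ds" not in obs:
            raise ValueError("eq3 requires a Ds column")
        Ds = np.asarray(obs["Ds"], dtype=float)
    else:
        Ds = None
    n_distinct = len({tuple(r) for r in np.column_stack(
        [s0, theta] + ([Ds] if Ds is not None else []))})
    if n_distinct < len(names) + 1:
        raise ValueError(
            f"need at least {len(names) + 1} distinct observation points, "
            f"got {n_distinct}")

    def resid(p):
        return _rule_values(rule_id, p, s0, theta, Ds) - df

    lo = np.array([_BOUNDS[n][0] for n in names])
    hi = np.array([_BOUNDS[n][1] for n in names])
    best = None
    for p0 in _starts(rule_id, n_starts, seed):
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if res.status > 0 and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise RuntimeError(
            f"nonlinear fit of {rule_id} failed from all {n_starts} starts")

    pred = _rule_values(rule_id, best.x, s0, theta, Ds)
    residuals = df - pred
    sse = float(np.sum(residuals ** 2))
    n, k = df.size, len(names)
    # Asymptotic standard errors from the Jacobian at the optimum.
    stderr = {}
    try:
        _, s, vt = np.linalg.svd(best.jac, full_matrices=False)
        s = s[s > s[0] * np.finfo(float).eps * max(best.jac.shape)]
        cov = (vt[:len(s)].T / s**2) @ vt[:len(s)] * (sse / max(n - k, 1))
        stderr = {nm: float(np.sqrt(cov[j, j])) for j, nm in enumerate(names)}
    except Exception:
        stderr = {nm: np.nan for nm in names}

    ss_tot = float(np.sum((df - df.mean()) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else (1.0 if sse == 0 else -np.inf)
    return RuleFit(
        rule_id=rule_id,
        params={nm: float(v) for nm, v in zip(names, best.x)},
        adjusted_r2=adjusted_r2(df, pred, k) if n > k + 1 else np.nan,
        r2=r2,
        sse=sse,
        stderr=stderr,
        residuals=residuals,
        converged=True,
        n_obs=n,
        predicted_above_one=bool(np.any(pred > 1.0)),
    )
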