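"""Full-factorial parameter sweeps and regression-based sensitivity analysis.

A :class:`ParameterGrid` is the Cartesian product of per-parameter level
lists, in deterministic lexicographic order.  :func:`run_sweep` integrates
the well-mixed batch model once per row and tabulates the steady-state
Detoxifier fraction, product leakiness and intracellular diagnostics.
:func:`fit_multilinear` regresses the composition on scale-normalized
predictors, and :func:`identify_key_parameters` applies the joint
threshold |coefficient| > 0.01 and p < 0.01 used to call a parameter
"key" for community structure.

Predictor normalization: parameters whose levels span at least a decade
(and are strictly positive) are log10-transformed, then every predictor
is min-max scaled to [0, 1], so coefficient magnitudes are comparable and
a single coefficient threshold is meaningful.
"""

from __future__ import annotations

import itertools
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .params import ModelParams
from .well_mixed import (SWEEP_PROTOCOL, SimulationError, SolverProtocol,
                         simulate_batch)

__all__ = ["ParameterGrid", "RegressionReport", "build_grid", "run_sweep",
           "fit_multilinear", "identify_key_parameters"]

log = logging.getLogger(__name__)

RESULT_COLUMNS = ("df", "leakiness", "s1_in", "s2_in", "p1_in", "p2_in",
                  "converged")


@dataclass(frozen=True)
class ParameterGrid:
    """Ordered axes and their full Cartesian product."""

    axes: dict[str, tuple[float, ...]]
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def build_grid(axes: dict) -> ParameterGrid:
    """Cartesian product of the axes, lexicographic in the given axis order."""
    clean: dict[str, tuple[float, ...]] = {}
    for name, levels in axes.items():
        levels = tuple(levels)
        if len(levels) == 0:
            raise ValueError(f"axis {name!r} has no levels")
        if not all(np.isfinite(v) for v in levels):
            raise ValueError(f"axis {name!r} has non-finite levels")
        clean[name] = levels
    rows = pd.DataFrame(itertools.product(*clean.values()),
                        columns=list(clean))
    # validate each row against the parameter invariants
    param_fields = set(ModelParams().as_dict())
    probe_cols = [c for c in clean if c in param_fields]
    if probe_cols:
        for values in {tuple(r) for r in rows[probe_cols].itertuples(index=False)}:
            ModelParams(**dict(zip(probe_cols, values)))  # raises if invalid
    return ParameterGrid(axes=clean, rows=rows)


def run_sweep(grid: ParameterGrid, base: ModelParams | None = None,
              protocol: SolverProtocol = SWEEP_PROTOCOL,
              tau_max: float = 1e6,
              checkpoint: str | pathlib.Path | None = None,
              progress: bool = False) -> pd.DataFrame:
    """One batch simulation per grid row.

    Returns the grid columns plus ``df, leakiness, s1_in, s2_in, p1_in,
    p2_in, converged``.  Solver failures are recorded as NaN rows with
    ``converged=False`` rather than raised.  With ``checkpoint`` set,
    finished rows are appended to that CSV and re-used on restart.
    """
    base = base or ModelParams()
    done: dict[int, dict] = {}
    if checkpoint is not None:
        checkpoint = pathlib.Path(checkpoint)
        if checkpoint.exists():
            prev = pd.read_csv(checkpoint)
            done = {int(r["row"]): r.to_dict() for _, r in prev.iterrows()}
    records = []
    iterator = grid.rows.iterrows()
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, total=len(grid.rows))
    for idx, row in iterator:
        if idx in done:
            records.append(done[idx])
            continue
        params = base.replace(**row.to_dict())
        rec = {"row": idx, **row.to_dict()}
        try:
            traj = simulate_batch(params, tau_max=tau_max, protocol=protocol)
            ss = traj.steady_state
            rec.update(df=ss.df, leakiness=ss.leakiness,
                       s1_in=ss.s_in_by_strain[0], s2_in=ss.s_in_by_strain[1],
                       p1_in=ss.p_in_by_strain[0], p2_in=ss.p_in_by_strain[1],
                       converged=ss.converged)
        except SimulationError as exc:
            log.warning("row %d failed: %s", idx, exc)
            rec.update(df=np.nan, leakiness=np.nan, s1_in=np.nan,
                       s2_in=np.nan, p1_in=np.nan, p2_in=np.nan,
                       converged=False)
        records.append(rec)
        if checkpoint is not None:
            pd.DataFrame([rec]).to_csv(checkpoint, mode="a", index=False,
                                       header=not checkpoint.exists())
    table = pd.DataFrame.from_records(records).drop(columns="row")
    n_bad = int((~table["converged"].astype(bool)).sum())
    if n_bad:
        log.warning("%d of %d sweep rows did not converge", n_bad, len(table))
    return table


@dataclass
class RegressionReport:
    """Per-parameter standardized OLS coefficients and significance."""

    coefficients: dict[str, float]
    p_values: dict[str, float]
    r2: float
    transforms: dict[str, str] = field(default_factory=dict)
    coef_threshold: float = 0.01
    p_threshold: float = 0.01
    n_used: int = 0
    n_dropped: int = 0

    def key_flags(self) -> dict[str, bool]:
        return {
            name: (abs(c) > self.coef_threshold
                   and self.p_values[name] < self.p_threshold)
            for name, c in self.coefficients.items()
        }

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "parameters": {
                name: {
                    "coefficient": self.coefficients[name],
                    "p_value": self.p_values[name],
                    "transform": self.transforms.get(name, "minmax"),
                    "key": self.key_flags()[name],
                }
                for name in self.coefficients
            },
        }

    def to_radar_frame(self) -> pd.DataFrame:
        """Radar-plot-ready table: parameter, coefficient, sign, key flag."""
        flags = self.key_flags()
        return pd.DataFrame({
            "parameter": list(self.coefficients),
            "coefficient": list(self.coefficients.values()),
            "abs_coefficient": [abs(v) for v in self.coefficients.values()],
            "sign": [int(np.sign(v)) for v in self.coefficients.values()],
            "p_value": [self.p_values[n] for n in self.coefficients],
            "key": [flags[n] for n in self.coefficients],
        })


def _transform_predictors(table: pd.DataFrame, predictors: list[str]
                          ) -> tuple[np.ndarray, dict[str, str]]:
    cols, transforms = [], {}
    for name in predictors:
        v = table[name].to_numpy(dtype=float)
        lo, hi = v.min(), v.max()
        if lo > 0 and hi / lo >= 10.0:
            v = np.log10(v)
            lo, hi = v.min(), v.max()
            transforms[name] = "log10+minmax"
        else:
            transforms[name] = "minmax"
        if hi > lo:
            v = (v - lo) / (hi - lo)
        else:
            v = np.zeros_like(v)
        cols.append(v)
    return np.column_stack(cols), transforms


def fit_multilinear(table: pd.DataFrame, predictors: list[str],
                    response: str = "df", coef_threshold: float = 0.01,
                    p_threshold: float = 0.01) -> RegressionReport:
    """OLS of the steady-state composition on normalized predictors.

    Non-converged rows are dropped (with a logged count).  Raises on a
    rank-deficient design, naming the collinear predictors.
    """
    mask = table["converged"].astype(bool) & table[response].notna() \
        if "converged" in table else table[response].notna()
    used = table[mask]
    n_dropped = len(table) - len(used)
    if n_dropped:
        log.warning("dropping %d non-converged rows from regression", n_dropped)
    if len(used) < len(predictors) + 2:
        raise ValueError("not enough converged rows for regression")
    X, transforms = _transform_predictors(used, predictors)
    keep = [j for j in range(X.shape[1]) if X[:, j].std() > 0]
    dropped_const = [predictors[j] for j in range(X.shape[1]) if j not in keep]
    Xk = sm.add_constant(X[:, keep])
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise np.linalg.LinAlgError(
            f"rank-deficient design; check collinearity among {predictors}")
    fit = sm.OLS(used[response].to_numpy(dtype=float), Xk).fit()
    coefs = dict.fromkeys(predictors, 0.0)
    pvals = dict.fromkeys(predictors, 1.0)
    for pos, j in enumerate(keep, start=1):
        coefs[predictors[j]] = float(fit.params[pos])
        pvals[predictors[j]] = float(fit.pvalues[pos])
    for name in dropped_const:
        transforms[name] = "constant (dropped)"
    return RegressionReport(coefficients=coefs, p_values=pvals,
                            r2=float(fit.rsquared), transforms=transforms,
                            coef_threshold=coef_threshold,
                            p_threshold=p_threshold,
                            n_used=len(used), n_dropped=n_dropped)


def identify_key_parameters(report: RegressionReport,
                            coef_threshold: float | None = None,
                            p_threshold: float | None = None
                            ) -> list[tuple[str, float, int]]:
    """Parameters passing both thresholds, ranked by |coefficient| descending.

    Returns (name, coefficient, sign) triples.
    """
    ct = report.coef_threshold if coef_threshold is None else coef_threshold
    pt = report.p_threshold if p_threshold is None else p_threshold
    keys = [(name, c, int(np.sign(c)))
            for name, c in report.coefficients.items()
            if abs(c) > ct and report.p_values[name] < pt]
    return sorted(keys, key=lambda item: abs(item[1]), reverse=True)
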