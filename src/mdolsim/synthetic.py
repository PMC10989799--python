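"""Synthetic observation generator.

Produces data with the statistical structure the downstream analyses
assume, without any wet-lab input: noisy community-composition tables
drawn from the closed-form structure rules (emulating endpoint plate
measurements of a 1:1-inoculated two-strain consortium across a substrate
gradient), mock two-channel fluorescence plates, and small deterministic
sweep fixtures pinned with the fixed-step reference integrator.

Noise model: additive Gaussian on composition fractions (default
sd = 0.02, matching a few-percent replicate spread typical of endpoint
fluorescence ratios), and multiplicative log-normal noise on raw
fluorescence channels.  Generated fractions are clipped to [0, 1]; the
clip count is reported so a design with excessive noise is visible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ModelParams
from .rules import RuleFit, predict_fraction
from . import reference

__all__ = ["SyntheticDesign", "generate_structure_observations",
           "make_fluorescence_plate", "fluorescence_to_fractions",
           "generate_sweep_fixture"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticDesign:
    """True rule constants and the measurement design to emulate.

    Defaults emulate an endpoint composition assay: 8 substrate levels,
    6 replicates per level, noise sd 0.02 on fractions.
    """

    fd_max: float = 0.423
    ks: float = 48.9
    ts_max: float = 3.39
    kt: float = 0.848
    #: The default substrate gradient spans the range over which the rule
    #: with these constants stays a valid fraction (roughly 0.2 to 0.7 at
    #: the default toxicity), like the endpoint assay it emulates.
    s0_levels: tuple[float, ...] = tuple(np.geomspace(30.0, 150.0, 8))
    theta: tuple[float, ...] | float = 0.0032
    replicates: int = 6
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def rule(self) -> RuleFit:
        return RuleFit(rule_id="eq2", params={
            "fd_max": self.fd_max, "ks": self.ks,
            "ts_max": self.ts_max, "kt": self.kt})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=list)


def generate_structure_observations(design: SyntheticDesign
                                    ) -> pd.DataFrame:
    """Composition observations: rule prediction plus Gaussian noise.

    Returns the CSV dialect consumed by :func:`mdolsim.rules.fit_rule`
    (columns ``s0, theta, df, replicate``).  Deterministic per seed.
    The number of clipped fractions is attached as ``frame.attrs["n_clipped"]``.
    """
    rng = np.random.default_rng(design.seed)
    thetas = (design.theta if isinstance(design.theta, (tuple, list))
              else (design.theta,))
    rows = []
    for theta in thetas:
        truth = predict_fraction(design.rule, np.asarray(design.s0_levels),
                                 theta=theta)
        for s0, mu in zip(design.s0_levels, np.atleast_1d(truth)):
            for rep in range(design.replicates):
                rows.append({"s0": s0, "theta": theta,
                             "df": mu + rng.normal(0.0, design.noise_sd),
                             "replicate": rep})
    frame = pd.DataFrame(rows)
    clipped = int(((frame["df"] < 0) | (frame["df"] > 1)).sum())
    if clipped:
        log.info("clipped %d of %d synthetic fractions to [0, 1]",
                 clipped, len(frame))
    frame["df"] = frame["df"].clip(0.0, 1.0)
    frame.attrs["n_clipped"] = clipped
    return frame


def make_fluorescence_plate(fractions, total_intensity: float = 1000.0,
                            background: tuple[float, float] = (50.0, 50.0),
                            noise_cv: float = 0.05, seed: int = 0
                            ) -> pd.DataFrame:
    """Mock two-channel endpoint fluorescence wells from known fractions.

    Channel 1 reports the Detoxifier, channel 2 the Embezzler; both carry
    multiplicative log-normal noise of coefficient of variation
    ``noise_cv`` on top of an additive per-channel background.  Identity
    intensity-to-biomass calibration is assumed.
    """
    rng = np.random.default_rng(seed)
    f = np.asarray(fractions, dtype=float)
    sigma = np.sqrt(np.log1p(noise_cv ** 2))
    ch1 = f * total_intensity * rng.lognormal(-sigma**2 / 2, sigma, f.shape)
    ch2 = (1 - f) * total_intensity * rng.lognormal(-sigma**2 / 2, sigma, f.shape)
    return pd.DataFrame({"well": np.arange(f.size),
                         "channel1": ch1 + background[0],
                         "channel2": ch2 + background[1],
                         "true_fraction": f})


def fluorescence_to_fractions(plate: pd.DataFrame,
                              background: tuple[float, float] = (0.0, 0.0)
                              ) -> pd.DataFrame:
    """Background-subtracted channel-1 share of total intensity.

    Wells with both channels at (or below) background are flagged
    ``undefined`` and get a NaN fraction.
    """
    c1 = plate["channel1"].to_numpy(dtype=float) - background[0]
    c2 = plate["channel2"].to_numpy(dtype=float) - background[1]
    if np.any(c1 < -1e-9) or np.any(c2 < -1e-9):
        raise ValueError("intensities below background")
    c1 = np.maximum(c1, 0.0)
    c2 = np.maximum(c2, 0.0)
    tot = c1 + c2
    undefined = tot <= 0
    frac = np.divide(c1, tot, out=np.full_like(tot, np.nan), where=~undefined)
    return pd.DataFrame({"well": plate["well"], "fraction": frac,
                         "undefined": undefined})


#: Mild-rate kinetics for pinned fixtures: fast convergence and a fast
#: intracellular timescale the explicit reference integrator resolves
#: comfortably at dt ~ 1e-3.
FIXTURE_BASE = ModelParams(alpha1=100.0, alpha2=100.0, beta2=1.0, bg=1.0,
                           Cp=10.0, y=1e-2, gamma_s=1.0, gamma_i=1.0,
                           gamma_p=1.0, rho=1e-2, s0=10.0, theta=0.0,
                           toxicity_form="reciprocal")


def generate_sweep_fixture(axes: dict | None = None, seed: int = 0,
                           dt: float = 1e-3, tau_max: float = 4e4,
                           rate_tol: float = 1e-7,
                           base: ModelParams = FIXTURE_BASE) -> pd.DataFrame:
    """Small deterministic grid with compositions pinned by the fixed-step
    reference integrator (for regression-testing the production solver).

    ``axes`` maps parameter names to level lists; at most 64 rows.
    """
    from .sweep import build_grid
    from .well_mixed import initial_state

    axes = axes or {"s0": (1.0, 10.0), "theta": (0.0, 0.05)}
    grid = build_grid(axes)
    if len(grid) > 64:
        raise ValueError("fixture grids are capped at 64 rows")
    records = []
    for _, row in grid.rows.iterrows():
        p = base.replace(**row.to_dict())
        y0 = initial_state(p)
        yf, tau_end, converged = reference.rk4_steady_state(
            p, y0, dt=dt, tau_max=tau_max, rate_tol=rate_tol)
        records.append({**row.to_dict(),
                        "df": yf[9] / (yf[9] + yf[10]),
                        "tau_end": tau_end, "converged": converged})
    return pd.DataFrame(records)
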