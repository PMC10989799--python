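"""Individual-based 2-D model of MDOL colony range expansion.

Cells are constant-radius discs living on a continuous plane above three
scalar lattice fields (extracellular S, I, P).  Each cell carries its own
intracellular s/i/p pools and a biomass; the per-cell kinetics mirror the
well-mixed batch model (passive exchange with the local lattice site,
Monod reactions, growth proportional to product consumption scaled by
yield and the substrate-toxicity factor).  Fields diffuse by an explicit
five-point stencil with zero-flux boundaries; cells divide at a mass
threshold and overlapping cells are relaxed apart by iterative pairwise
shoving, which drives colony range expansion from a central inoculum.

The substrate is supplied as an initially uniform field with no
replenishment, so during consumption it is highest outside the colony
and penetrates only a thin peripheral "active layer" -- the mechanism
that separates the composition of the inoculated disc from that of the
expanding annulus.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .params import ModelParams

__all__ = [
    "IBParams", "ColonyState", "RegionComposition", "initialize_colony",
    "diffuse_fields", "update_cells", "grow_divide_shove", "run_colony",
    "partition_and_compose", "mixing_index",
]

DETOXIFIER, EMBEZZLER = 0, 1

#: Per-cell kinetics of the colony model: the representative rate
#: constants of the batch model, with a larger biomass yield so that a
#: desk-scale colony expands through enough generations per run.  The
#: Monod conversions are stepped implicitly, so the stiff alpha1 is fine.
IB_KINETICS = ModelParams(alpha1=1.0e4, alpha2=1.0e3, beta2=1.0, bg=1.0,
                          Cp=10.0, y=0.05, gamma_s=1.0, gamma_i=1.0,
                          gamma_p=1.0, rho=1.0, s0=30.0, theta=0.0,
                          toxicity_form="reciprocal")


@dataclass(frozen=True)
class IBParams:
    """Configuration of a colony simulation (lattice units; h is the
    grid spacing, lengths are in units of h by default)."""

    kinetics: ModelParams = IB_KINETICS
    Ds: float = 2.0
    Di: float = 2.0
    Dp: float = 2.0
    L: int = 120          # lattice is L x L sites
    h: float = 1.0
    dt: float = 0.05      # macro time step
    cell_radius: float = 0.45
    division_mass: float = 2.0
    initial_mass: float = 1.0
    shove_iterations: int = 6
    n_inoculum: int = 40
    r0: float = 4.0       # inoculum disc radius
    seed: int = 0
    max_steps: int = 4000
    record_every: int = 50
    substrate_stop_fraction: float = 0.01
    neutral: bool = False  # both strains feed directly on S (control)
    #: Cell cap; the default keeps the colony well clear of a jammed
    #: packing on the default lattice.
    max_cells: int = 2500

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.h <= 0:
            raise ValueError("dt and h must be positive")
        if self.n_inoculum < 1:
            raise ValueError("need at least one inoculated cell")
        # close packing guard for the inoculum disc
        if self.n_inoculum * (self.cell_radius ** 2) > 0.9 * self.r0 ** 2:
            raise ValueError("inoculum denser than close packing in r0")

    @property
    def diffusion_substeps(self) -> int:
        dmax = max(self.Ds, self.Di, self.Dp)
        if dmax == 0:
            return 1
        # explicit stability: d_sub <= h^2 / (4 D); run at half that
        limit = self.h ** 2 / (4.0 * dmax)
        return max(1, int(np.ceil(self.dt / (0.5 * limit))))

    @property
    def cell_substeps(self) -> int:
        # Monod conversions are integrated implicitly (unconditionally
        # stable), so only the passive-exchange rates limit the substep.
        k = self.kinetics
        fastest = max(k.gamma_s, k.gamma_i, k.gamma_p)
        return max(1, int(np.ceil(self.dt * fastest / 0.4)))


@dataclass
class ColonyState:
    """Lattice fields plus the agent population."""

    params: IBParams
    S: np.ndarray
    I: np.ndarray
    P: np.ndarray
    pos: np.ndarray       # (n, 2) continuous positions, lattice units
    ctype: np.ndarray     # (n,) DETOXIFIER / EMBEZZLER
    s_in: np.ndarray
    i_in: np.ndarray
    p_in: np.ndarray
    mass: np.ndarray
    lineage: np.ndarray
    time: float = 0.0
    rng: np.random.Generator = field(default=None, repr=False)
    boundary_contact: bool = False
    # cumulative mass bookkeeping (total converted amounts)
    ledger: dict = field(default_factory=lambda: {
        "s_consumed": 0.0, "i_produced": 0.0, "i_consumed": 0.0,
        "p_produced": 0.0, "p_consumed": 0.0, "biomass_gained": 0.0})

    @property
    def n_cells(self) -> int:
        return len(self.mass)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.params.L * self.params.h / 2.0] * 2)

    def field_totals(self) -> dict[str, float]:
        a = self.params.h ** 2
        return {"S": float(self.S.sum() * a), "I": float(self.I.sum() * a),
                "P": float(self.P.sum() * a)}

    def copy(self) -> "ColonyState":
        return ColonyState(
            params=self.params, S=self.S.copy(), I=self.I.copy(),
            P=self.P.copy(), pos=self.pos.copy(), ctype=self.ctype.copy(),
            s_in=self.s_in.copy(), i_in=self.i_in.copy(),
            p_in=self.p_in.copy(), mass=self.mass.copy(),
            lineage=self.lineage.copy(), time=self.time, rng=self.rng,
            boundary_contact=self.boundary_contact,
            ledger=dict(self.ledger))


def initialize_colony(params: IBParams) -> ColonyState:
    """Seed a 1:1 colony uniformly at random inside the central disc.

    Types alternate through the placement order, so an even inoculum is
    exactly balanced.  The S field starts uniform at ``s0``; I and P at 0.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_inoculum
    # uniform in the disc of radius r0
    r = params.r0 * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    center = params.L * params.h / 2.0
    pos = np.column_stack([center + r * np.cos(phi), center + r * np.sin(phi)])
    ctype = np.arange(n) % 2
    shape = (params.L, params.L)
    return ColonyState(
        params=params,
        S=np.full(shape, params.kinetics.s0, dtype=float),
        I=np.zeros(shape), P=np.zeros(shape),
        pos=pos, ctype=ctype.astype(np.int64),
        s_in=np.zeros(n), i_in=np.zeros(n), p_in=np.zeros(n),
        mass=np.full(n, params.initial_mass, dtype=float),
        lineage=np.arange(n, dtype=np.int64),
        rng=rng,
    )


def _laplacian(F: np.ndarray, h: float) -> np.ndarray:
    # zero-flux (reflecting) boundaries via edge padding; conserves mass
    Fp = np.pad(F, 1, mode="edge")
    return (Fp[:-2, 1:-1] + Fp[2:, 1:-1] + Fp[1:-1, :-2] + Fp[1:-1, 2:]
            - 4.0 * F) / h ** 2


def diffuse_fields(state: ColonyState, dt: float | None = None) -> ColonyState:
    """Explicit five-point diffusion over one macro step (substepped for
    stability); mutates and returns ``state``."""
    p = state.params
    dt = p.dt if dt is None else dt
    nsub = p.diffusion_substeps
    sub = dt / nsub
    for D, F in ((p.Ds, state.S), (p.Di, state.I), (p.Dp, state.P)):
        if D == 0.0:
            continue
        if sub * D > p.h ** 2 / 4.0:
            raise ValueError("diffusion step violates stability limit")
        for _ in range(nsub):
            F += (D * sub) * _laplacian(F, p.h)
    return state


def _site_index(state: ColonyState) -> tuple[np.ndarray, np.ndarray]:
    p = state.params
    ix = np.clip((state.pos[:, 0] / p.h).astype(np.int64), 0, p.L - 1)
    iy = np.clip((state.pos[:, 1] / p.h).astype(np.int64), 0, p.L - 1)
    return iy, ix


def _exchange(field: np.ndarray, local: np.ndarray, internal: np.ndarray,
              mass: np.ndarray, gamma: float, dt: float, h: float,
              iy: np.ndarray, ix: np.ndarray) -> np.ndarray:
    """Passive exchange gamma*(local - internal) per unit biomass over dt.

    The field site is debited/credited with the biomass-weighted flux;
    site-level demand is rescaled so no site is driven below zero.
    Returns the per-cell change of the internal concentration.
    """
    flux = gamma * (local - internal) * dt            # per-cell conc change
    demand = np.zeros_like(field)
    np.add.at(demand, (iy, ix), mass * flux / h ** 2)  # field conc change
    # cap sites whose net withdrawal exceeds their content
    over = demand > field
    if np.any(over):
        scale_site = np.ones_like(field)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale_site[over] = np.where(demand[over] > 0,
                                        field[over] / demand[over], 1.0)
        cell_scale = scale_site[iy, ix]
        flux = flux * np.where(flux > 0, cell_scale, 1.0)
        demand = np.zeros_like(field)
        np.add.at(demand, (iy, ix), mass * flux / h ** 2)
    field -= demand
    np.maximum(field, 0.0, out=field)
    return flux


def _monod_decay(pool: np.ndarray, a: float, b: float, dt: float
                 ) -> np.ndarray:
    """Amount converted by dp/dt = -a*p/(b+p) over dt (implicit Euler).

    The backward-Euler update solves a quadratic with a unique
    non-negative root, so the step is unconditionally stable and never
    drives the pool negative, however stiff the maximum rate ``a``.
    """
    q = b + a * dt - pool
    new = 0.5 * (-q + np.sqrt(q * q + 4.0 * b * pool))
    return pool - np.maximum(new, 0.0)


def update_cells(state: ColonyState, dt: float | None = None) -> ColonyState:
    """Per-cell exchange, intracellular reactions and growth over one
    macro step (substepped); mutates and returns ``state``."""
    p = state.params
    k = p.kinetics
    dt = p.dt if dt is None else dt
    nsub = max(p.cell_substeps, 1)
    sub = dt / nsub
    iy, ix = _site_index(state)
    led = state.ledger
    is_d = state.ctype == DETOXIFIER
    is_e = ~is_d
    theta = k.effective_theta
    for _ in range(nsub):
        if p.neutral:
            # control: both strains feed directly and identically on S
            ds = _exchange(state.S, state.S[iy, ix], state.s_in, state.mass,
                           k.gamma_s, sub, p.h, iy, ix)
            state.s_in += ds
            eaten = _monod_decay(state.s_in, k.Cp, k.bg, sub)
            state.s_in -= eaten
            led["s_consumed"] += float((eaten * state.mass).sum())
            gain = state.mass * eaten * k.y
            state.mass += gain
            led["biomass_gained"] += float(gain.sum())
            continue
        # passive exchange with the local site
        state.s_in += _exchange(state.S, state.S[iy, ix], state.s_in,
                                state.mass, k.gamma_s, sub, p.h, iy, ix)
        state.i_in += _exchange(state.I, state.I[iy, ix], state.i_in,
                                state.mass, k.gamma_i, sub, p.h, iy, ix)
        state.p_in += _exchange(state.P, state.P[iy, ix], state.p_in,
                                state.mass, k.gamma_p, sub, p.h, iy, ix)
        # reaction 1: S -> I inside Detoxifiers
        conv = np.where(is_d, _monod_decay(state.s_in, k.alpha1, 1.0, sub),
                        0.0)
        state.s_in -= conv
        state.i_in += conv
        led["s_consumed"] += float((conv * state.mass).sum())
        led["i_produced"] += float((conv * state.mass).sum())
        # reaction 2: I -> P inside Embezzlers
        conv2 = np.where(is_e, _monod_decay(state.i_in, k.alpha2, k.beta2,
                                            sub), 0.0)
        state.i_in -= conv2
        state.p_in += conv2
        led["i_consumed"] += float((conv2 * state.mass).sum())
        led["p_produced"] += float((conv2 * state.mass).sum())
        # product consumption and growth (toxicity throttles growth only)
        eaten = _monod_decay(state.p_in, k.Cp, k.bg, sub)
        state.p_in -= eaten
        led["p_consumed"] += float((eaten * state.mass).sum())
        if theta > 0.0:
            if k.toxicity_form == "reciprocal":
                tox = 1.0 / (1.0 + theta * state.s_in)
            elif k.toxicity_form == "exponential":
                tox = np.exp(-theta * state.s_in)
            else:
                tox = np.maximum(0.0, 1.0 - theta * state.s_in)
        else:
            tox = 1.0
        gain = state.mass * eaten * k.y * tox
        state.mass += gain
        led["biomass_gained"] += float(gain.sum())
    return state


def grow_divide_shove(state: ColonyState) -> ColonyState:
    """Binary division at the mass threshold, then overlap relaxation."""
    p = state.params
    rng = state.rng
    dividing = np.flatnonzero(state.mass >= p.division_mass)
    if dividing.size:
        phi = 2.0 * np.pi * rng.random(dividing.size)
        offset = np.column_stack([np.cos(phi), np.sin(phi)]) * (p.cell_radius / 2)
        state.mass[dividing] *= 0.5
        new_pos = state.pos[dividing] + offset
        state.pos[dividing] -= offset
        state.pos = np.vstack([state.pos, new_pos])
        for name in ("ctype", "s_in", "i_in", "p_in", "mass", "lineage"):
            arr = getattr(state, name)
            setattr(state, name, np.concatenate([arr, arr[dividing]]))
    _shove(state)
    return state


def _shove(state: ColonyState, overlap_tol: float = 1e-6) -> None:
    p = state.params
    d_min = 2.0 * p.cell_radius
    strict = d_min * (1.0 - overlap_tol)
    # Neighbor lists are rebuilt a few times per call (with a margin);
    # between rebuilds a fixed number of relaxation sweeps runs over the
    # cached pair set.  The summed push on a cell is averaged over its
    # contacts, which keeps dense cores from oscillating.  Divisions only
    # displace daughters by half a radius, so cascades are local and any
    # residual overlap is picked up by the next step's shove.
    n = len(state.pos)
    for rebuild in range(3):
        tree = cKDTree(state.pos)
        pairs = tree.query_pairs(1.2 * d_min, output_type="ndarray")
        if pairs.size == 0:
            return
        i, j = pairs[:, 0], pairs[:, 1]
        contacts = np.maximum(
            np.bincount(i, minlength=n) + np.bincount(j, minlength=n), 1)
        for it in range(p.shove_iterations):
            delta = state.pos[j] - state.pos[i]
            dist = np.linalg.norm(delta, axis=1)
            coincident = dist < 1e-9
            if np.any(coincident):
                jitter = state.rng.normal(size=(int(coincident.sum()), 2))
                delta[coincident] = jitter
                dist[coincident] = np.linalg.norm(jitter, axis=1)
            overlapping = dist < strict
            if not np.any(overlapping):
                return
            push = np.where(overlapping, (d_min - dist) / dist, 0.0)
            shift = delta * push[:, None]
            move = np.zeros_like(state.pos)
            np.add.at(move, i, -shift)
            np.add.at(move, j, shift)
            state.pos += move / contacts[:, None]


@dataclass(frozen=True)
class RegionComposition:
    region: str                      # "inoculated" or "expanding"
    n_detoxifier: int
    n_embezzler: int
    fraction: float                  # Detoxifier fraction; NaN if empty
    flagged_empty: bool = False


def partition_and_compose(state: ColonyState, r0: float | None = None,
                          n_bins: int = 8
                          ) -> tuple[RegionComposition, RegionComposition,
                                     pd.DataFrame]:
    """Split cells into the inoculated disc (< r0 from center) and the
    expanding annulus; also return a radial composition profile."""
    r0 = state.params.r0 if r0 is None else r0
    dist = np.linalg.norm(state.pos - state.center, axis=1)
    out = []
    for region, mask in (("inoculated", dist < r0), ("expanding", dist >= r0)):
        nd = int(np.sum(state.ctype[mask] == DETOXIFIER))
        ne = int(np.sum(state.ctype[mask] == EMBEZZLER))
        tot = nd + ne
        out.append(RegionComposition(
            region=region, n_detoxifier=nd, n_embezzler=ne,
            fraction=nd / tot if tot else float("nan"),
            flagged_empty=tot == 0))
    rmax = max(dist.max(), r0) * 1.0001
    edges = np.linspace(0.0, rmax, n_bins + 1)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    prof = []
    for b in range(n_bins):
        m = which == b
        nd = int(np.sum(state.ctype[m] == DETOXIFIER))
        tot = int(m.sum())
        prof.append({"bin": b, "r_inner": edges[b], "r_outer": edges[b + 1],
                     "n_cells": tot, "n_detoxifier": nd,
                     "fraction": nd / tot if tot else np.nan})
    return out[0], out[1], pd.DataFrame(prof)


def mixing_index(state: ColonyState, k: int = 6) -> float:
    """Mean fraction of opposite-type cells among the k nearest neighbors.

    0 means fully segregated monoclonal domains; for a random (fully
    mixed) 1:1 arrangement the expectation is the opposite-type frequency
    (about 0.5).
    """
    n = state.n_cells
    if n < k + 1:
        raise ValueError(f"mixing index needs at least {k + 1} cells")
    tree = cKDTree(state.pos)
    _, idx = tree.query(state.pos, k=k + 1)
    neigh = state.ctype[idx[:, 1:]]
    return float(np.mean(neigh != state.ctype[:, None]))


def run_colony(params: IBParams, snapshot_times: tuple[float, ...] = (),
               ) -> tuple[ColonyState, pd.DataFrame, dict]:
    """Operator-split colony simulation.

    Per macro step: field diffusion substeps, per-cell update, then
    growth/division/shoving.  Stops when the total extracellular S falls
    below ``substrate_stop_fraction`` of its initial amount, on boundary
    contact, at ``max_cells``, or at ``max_steps``.

    Returns the final state, the region-composition time series and a run
    manifest (resolved parameters, seed, stop reason).
    """
    state = initialize_colony(params)
    s_init = state.field_totals()["S"]
    rows = []
    stop_reason = "max_steps"
    snapshots = {}
    edge = 2.0 * params.h

    def record(t):
        inoc, expa, _ = partition_and_compose(state)
        for rc in (inoc, expa):
            rows.append({"time": t, "region": rc.region,
                         "n_detoxifier": rc.n_detoxifier,
                         "n_embezzler": rc.n_embezzler,
                         "fraction": rc.fraction})

    record(0.0)
    for step in range(1, params.max_steps + 1):
        diffuse_fields(state)
        update_cells(state)
        grow_divide_shove(state)
        state.time = step * params.dt
        if step % params.record_every == 0:
            record(state.time)
        lo = state.pos.min()
        hi = state.pos.max()
        if lo < edge or hi > params.L * params.h - edge:
            state.boundary_contact = True
            warnings.warn("colony reached the domain boundary")
            stop_reason = "boundary_contact"
            break
        if state.field_totals()["S"] < params.substrate_stop_fraction * s_init:
            stop_reason = "substrate_depleted"
            break
        if state.n_cells >= params.max_cells:
            stop_reason = "max_cells"
            break
    if rows[-1]["time"] != state.time:
        record(state.time)
    manifest = {
        "params": {**dataclasses.asdict(params),
                   "kinetics": params.kinetics.as_dict()},
        "seed": params.seed,
        "stop_reason": stop_reason,
        "steps": int(round(state.time / params.dt)),
        "n_cells": state.n_cells,
        "boundary_contact": state.boundary_contact,
    }
    manifest["params"].pop("kinetics", None)
    manifest["kinetics"] = params.kinetics.as_dict()
    return state, pd.DataFrame(rows), manifest


def save_snapshot(state: ColonyState, path) -> None:
    """Render cells (Detoxifier red, Embezzler green) over the S field."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    p = state.params
    ax.imshow(state.S, origin="lower", cmap="Greys",
              extent=(0, p.L * p.h, 0, p.L * p.h), alpha=0.6)
    colors = np.where(state.ctype == DETOXIFIER, "red", "green")
    ax.scatter(state.pos[:, 0], state.pos[:, 1], s=4, c=colors, lw=0)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_title(f"t = {state.time:.1f}, {state.n_cells} cells")
    fig.savefig(path, dpi=120)
    plt.close(fig)
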