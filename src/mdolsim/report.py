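"""Table, figure and manifest export helpers for the analysis stages."""

from __future__ import annotations

import dataclasses
import json
import pathlib
import platform
from typing import Any

import numpy as np
import pandas as pd

from . import __version__ as _version
from .rules import RuleFit, predict_fraction

__all__ = ["write_manifest", "export_tables", "surface_csv", "surface_png",
           "REFERENCE_FITS"]

#: Published best-fit constants of the structure rules for the
#: representative parameter set (y=1e-4, Cp=10, bg=1, alpha1=1e4,
#: alpha2=1e3, beta2=1, gammas=1, rho=1e-2); the `reproduce` report
#: prints them next to the freshly fitted values.
REFERENCE_FITS = {
    "eq1": {"ks": 35.3, "fd_max": 0.417},
    "eq2": {"ks": 48.9, "fd_max": 0.423, "kt": 0.848, "ts_max": 3.39},
}


def write_manifest(outdir: str | pathlib.Path, config: dict[str, Any],
                   seed: int | None = None) -> pathlib.Path:
    """Record everything needed to re-run the stage bit-identically."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "mdolsim",
        "version": _version,
        "python": platform.python_version(),
        "seed": seed,
        "config": _jsonable(config),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def export_tables(results: dict[str, Any], outdir: str | pathlib.Path,
                  formats: tuple[str, ...] = ("csv", "json")
                  ) -> list[pathlib.Path]:
    """Write each named result; DataFrames as CSV, mappings as JSON.

    An empty DataFrame still produces a header-only CSV.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, value in results.items():
        if isinstance(value, pd.DataFrame) and "csv" in formats:
            path = outdir / f"{name}.csv"
            value.to_csv(path, index=False)
            written.append(path)
        elif "json" in formats:
            path = outdir / f"{name}.json"
            if isinstance(value, RuleFit):
                value = value.to_dict()
            path.write_text(json.dumps(_jsonable(value), indent=2) + "\n")
            written.append(path)
    return written


def surface_csv(fit: RuleFit, s0_grid, theta_grid) -> pd.DataFrame:
    """Prediction grid of DF(s0, theta) for surface plotting."""
    rows = []
    for theta in theta_grid:
        for s0 in s0_grid:
            rows.append({"s0": s0, "theta": theta,
                         "df_pred": float(predict_fraction(fit, s0,
                                                           theta=theta))})
    return pd.DataFrame(rows)


def surface_png(fit: RuleFit, path, s0_grid=None, theta_grid=None,
                observations: pd.DataFrame | None = None) -> None:
    """DF(s0, theta) surface in the layout used for composition maps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    s0_grid = np.geomspace(1, 3000, 40) if s0_grid is None else np.asarray(s0_grid)
    theta_grid = (np.concatenate([[0.0], np.geomspace(1e-4, 1e-1, 30)])
                  if theta_grid is None else np.asarray(theta_grid))
    S, T = np.meshgrid(s0_grid, theta_grid)
    Z = predict_fraction(fit, S, theta=T)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(np.log10(S), np.log10(np.maximum(T, 1e-5)), Z,
                    cmap="viridis", alpha=0.85)
    if observations is not None:
        ax.scatter(np.log10(observations["s0"]),
                   np.log10(np.maximum(observations.get("theta", 0.0), 1e-5)),
                   observations["df"], color="green", s=12)
    ax.set_xlabel("log10 s0")
    ax.set_ylabel("log10 theta")
    ax.set_zlabel("Detoxifier fraction")
    fig.savefig(path, dpi=130, bbox_inches="tight")
    plt.close(fig)
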