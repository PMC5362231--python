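"""Gridded occupancy / standard-error surfaces and map-stack export."""

from __future__ import annotations

import json
import pathlib

import pandas as pd

from .model import FitResult, delta_method_se_psi, predict_psi

__all__ = ["predict_surface", "export_map_stack", "read_map_stack"]

GRID_COLUMNS = ("cell_id", "easting", "northing")
ROUND_DECIMALS = 6


def predict_surface(fit: FitResult, grid: pd.DataFrame) -> pd.DataFrame:
    """Attach per-cell occupancy predictions and delta-method SEs to a grid.

    ``grid`` needs cell_id/easting/northing plus the fit's occupancy
    covariate columns, already standardised with the fit's constants.
    """
    missing = [c for c in GRID_COLUMNS if c not in grid.columns]
    if missing:
        raise ValueError(f"grid lacks columns: {missing}")
    if grid.empty:
        raise ValueError("empty prediction grid")
    for term in fit.spec.occupancy_terms:
        if term not in grid.columns:
            bad = grid["cell_id"].iloc[0]
            raise ValueError(f"cell {bad!r}: missing covariate column {term!r}")
    out = grid.copy()
    out["psi"] = predict_psi(fit, grid)
    out["se"] = delta_method_se_psi(fit, grid)
    return out


def export_map_stack(per_year_grids: dict, out_dir, species: str = "", fit_ids=None):
    """Write one CSV per year (cell, easting, northing, psi, se) + manifest.

    Values are rounded to 6 decimals so re-exports of the same fit are
    byte-identical.  Returns the list of written paths.
    """
    if not per_year_grids:
        raise ValueError("no yearly grids to export")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for year in sorted(per_year_grids):
        grid = per_year_grids[year]
        if grid.empty:
            raise ValueError(f"empty grid for year {year}")
        path = out / f"occupancy_map_{year}.csv"
        cols = grid[list(GRID_COLUMNS) + ["psi", "se"]].copy()
        cols[["psi", "se"]] = cols[["psi", "se"]].round(ROUND_DECIMALS)
        cols.to_csv(path, index=False, float_format=f"%.{ROUND_DECIMALS}f")
        written.append(path)
    manifest = {
        "years": [int(y) for y in sorted(per_year_grids)],
        "species": species,
        "fit_ids": list(fit_ids) if fit_ids is not None else [],
        "files": [p.name for p in written],
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return written + [manifest_path]


def read_map_stack(out_dir) -> dict:
    """Re-read an exported stack as {year: DataFrame}."""
    out = pathlib.Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return {
        year: pd.read_csv(out / f"occupancy_map_{year}.csv")
        for year in manifest["years"]
    }
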