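"""Colony-size and score tables.

A *colony table* is a tidy DataFrame with one row per grid position:
``plate_id, row, col, strain, size`` plus optional ``circularity``,
``edge_touching`` and ``empty`` columns.  ``size`` is NaN for absent
colonies — absence (a failed pin) is deliberately distinct from a
zero-size colony (no growth).

A *score table* has one row per query x target with the two per-control
z-scores, their mean, and (after smoothing) the smoothed versions.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from spiscreen.io_cli.layout import EMPTY_TOKEN, PlateLayout


class ColonyTableError(ValueError):
    pass


COLONY_COLUMNS = ["plate_id", "row", "col", "strain", "size"]

SCORE_COLUMNS = [
    "query", "target",
    "z_vs_target_only", "z_vs_gbp_only", "z_mean",
]
SMOOTHED_COLUMNS = ["z_smoothed_target_only", "z_smoothed_gbp_only", "z_smoothed"]


def read_colony_table(path: str | Path, layout: PlateLayout) -> pd.DataFrame:
    """Read a colony-size TSV (plate_id, row, col, size) against a layout.

    Every layout position is present in the result; positions missing from
    the file get ``size = NaN`` with the ``empty`` flag set.  Duplicate
    positions, positions outside the grid, and negative sizes are format
    errors.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"plate_id", "row", "col", "size"}
    if not required.issubset(df.columns):
        raise ColonyTableError(f"colony table must have columns {sorted(required)}")
    if df.duplicated(subset=["plate_id", "row", "col"]).any():
        raise ColonyTableError("duplicate (plate, row, col) entries")
    oob = (df["row"] < 0) | (df["row"] >= layout.n_rows) | \
          (df["col"] < 0) | (df["col"] >= layout.n_cols)
    if oob.any():
        bad = df.loc[oob, ["row", "col"]].iloc[0]
        raise ColonyTableError(f"position ({bad.row}, {bad.col}) outside grid")
    if (df["size"].dropna() < 0).any():
        raise ColonyTableError("negative colony size")

    sizes = {(int(r.row), int(r.col)): float(r.size) for r in df.itertuples()}
    rows = []
    for (r, c), strain in sorted(layout.position_map.items()):
        if strain is None:
            continue
        size = sizes.get((r, c), np.nan)
        rows.append({
            "plate_id": layout.plate_id, "row": r, "col": c, "strain": strain,
            "size": size, "empty": not np.isfinite(size),
        })
    return pd.DataFrame(rows, columns=COLONY_COLUMNS + ["empty"])


def write_colony_table(table: pd.DataFrame, path: str | Path,
                       header_meta: dict | None = None) -> None:
    """Write a colony table TSV; absent sizes are written as NA."""
    path = Path(path)
    cols = [c for c in table.columns]
    with open(path, "w") as fh:
        fh.write("# colony table; 0-based (row, col), row 0 at image top; size NA = absent colony\n")
        if header_meta:
            meta = " ".join(f"{k}={v}" for k, v in sorted(header_meta.items()))
            fh.write(f"# {meta}\n")
        table[cols].to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_raw_colony_table(path: str | Path) -> pd.DataFrame:
    """Read a colony table written by :func:`write_colony_table` verbatim."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "empty" in df.columns:
        df["empty"] = df["empty"].astype(bool)
    return df


def write_score_table(scores: pd.DataFrame, path: str | Path,
                      header_meta: dict | None = None) -> None:
    """Write a score table mirroring the per-control z-score report layout."""
    cols = [c for c in SCORE_COLUMNS + SMOOTHED_COLUMNS if c in scores.columns]
    extra = [c for c in scores.columns if c not in cols]
    with open(path, "w") as fh:
        fh.write("# z-scores per query x target; positive z = growth defect; "
                 "z_mean = average of the two control z-scores\n")
        if header_meta:
            fh.write("# " + " ".join(f"{k}={v}" for k, v in sorted(header_meta.items())) + "\n")
        scores[cols + extra].to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_score_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def colony_grid(table: pd.DataFrame, layout: PlateLayout,
                value: str = "size") -> np.ndarray:
    """Pivot one plate's colony table to an (n_rows, n_cols) array (NaN = absent)."""
    grid = np.full((layout.n_rows, layout.n_cols), np.nan)
    sub = table[table["plate_id"] == layout.plate_id]
    grid[sub["row"].to_numpy(), sub["col"].to_numpy()] = sub[value].to_numpy(dtype=float)
    return grid
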