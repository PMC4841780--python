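"""Cluster 3.0 ``.cdt``/``.gtr``/``.atr`` export (Java TreeView dialect).

Rows and columns are written in dendrogram leaf order; GENE/ARRY ids refer
to the original matrix ordering so the ``.gtr``/``.atr`` node references
resolve.  Values are written to 6 significant figures.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class CdtError(ValueError):
    pass


def _leaf_order_indices(tree, labels: list[str]) -> list[int]:
    order = tree.leaf_order()
    if sorted(order) != sorted(labels):
        raise CdtError("tree leaves are not a permutation of the matrix axis")
    pos = {lab: i for i, lab in enumerate(labels)}
    return [pos[lab] for lab in order]


def _write_tree_file(tree, path: Path, id_prefix: str) -> None:
    n = tree.n_leaves
    with open(path, "w") as fh:
        for k, (a, b, h, _cnt) in enumerate(tree.linkage):
            def ref(idx: float) -> str:
                idx = int(idx)
                return f"{id_prefix}{idx}X" if idx < n else f"NODE{idx - n + 1}X"
            similarity = 1.0 - float(h)
            fh.write(f"NODE{k + 1}X\t{ref(a)}\t{ref(b)}\t{similarity:.6g}\n")


def write_cdt(matrix: pd.DataFrame, row_tree=None, col_tree=None,
              path_prefix: str | Path = "clustered") -> dict[str, Path]:
    """Write ``<prefix>.cdt`` plus ``.gtr``/``.atr`` for the given trees.

    Trees must cover the corresponding axis exactly (a permutation of its
    labels); a tree over the wrong leaf count is an error.
    """
    prefix = Path(path_prefix)
    row_labels = [str(i) for i in matrix.index]
    col_labels = [str(c) for c in matrix.columns]
    written: dict[str, Path] = {}

    if row_tree is not None and row_tree.n_leaves != len(row_labels):
        raise CdtError(f"row tree has {row_tree.n_leaves} leaves, matrix has "
                       f"{len(row_labels)} rows")
    if col_tree is not None and col_tree.n_leaves != len(col_labels):
        raise CdtError(f"column tree has {col_tree.n_leaves} leaves, matrix has "
                       f"{len(col_labels)} columns")

    row_order = _leaf_order_indices(row_tree, row_labels) if row_tree is not None \
        else list(range(len(row_labels)))
    col_order = _leaf_order_indices(col_tree, col_labels) if col_tree is not None \
        else list(range(len(col_labels)))

    values = matrix.to_numpy(dtype=float)
    cdt_path = prefix.with_suffix(".cdt")
    with open(cdt_path, "w") as fh:
        header = ["GID", "UNIQID", "NAME", "GWEIGHT"] + [col_labels[j] for j in col_order]
        fh.write("\t".join(header) + "\n")
        if col_tree is not None:
            fh.write("\t".join(["AID", "", "", ""] +
                               [f"ARRY{j}X" for j in col_order]) + "\n")
        fh.write("\t".join(["EWEIGHT", "", "", ""] + ["1"] * len(col_order)) + "\n")
        for i in row_order:
            cells = [f"GENE{i}X", row_labels[i], row_labels[i], "1"]
            for j in col_order:
                v = values[i, j]
                cells.append("" if not np.isfinite(v) else f"{v:.6g}")
            fh.write("\t".join(cells) + "\n")
    written["cdt"] = cdt_path

    if row_tree is not None:
        gtr = prefix.with_suffix(".gtr")
        _write_tree_file(row_tree, gtr, "GENE")
        written["gtr"] = gtr
    if col_tree is not None:
        atr = prefix.with_suffix(".atr")
        _write_tree_file(col_tree, atr, "ARRY")
        written["atr"] = atr
    return written


def read_cdt(path: str | Path) -> pd.DataFrame:
    """Read back a ``.cdt`` written by :func:`write_cdt` (data rows only)."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n").split("\t") for ln in fh]
    header = lines[0]
    col_names = header[4:]
    data_rows = [ln for ln in lines[1:] if ln and ln[0] not in ("AID", "EWEIGHT")]
    index = [ln[1] for ln in data_rows]
    values = [[float(v) if v != "" else np.nan for v in ln[4:]] for ln in data_rows]
    return pd.DataFrame(values, index=index, columns=col_names)
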