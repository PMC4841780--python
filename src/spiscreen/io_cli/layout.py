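"""Plate layouts, annotation tables and interaction networks.

Grid coordinates are 0-based ``(row, col)`` with row 0 at the image top.
Replicates of one strain occupy contiguous blocks (2x2 by default, matching
384 -> 1536 pinning expansion).  Positions may be explicitly empty (``None``).
Control strains are labelled with the ``CTRL`` prefix so that
control-reference normalization can find them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: the three plate conditions of a dual-control screen
CONDITIONS = ("fusion", "control_target_only", "control_gbp_only")

#: strain labels starting with this prefix mark on-plate control positions
CONTROL_PREFIX = "CTRL"

EMPTY_TOKEN = "-"


class LayoutError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


@dataclass
class PlateLayout:
    """Mapping between grid positions and strain identities for one plate."""

    plate_id: str
    n_rows: int = 32
    n_cols: int = 48
    position_map: dict[tuple[int, int], str | None] = field(default_factory=dict)
    replicate_block: int = 4
    condition: str = "fusion"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise LayoutError(f"unknown condition {self.condition!r}")
        for (r, c) in self.position_map:
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise LayoutError(f"position ({r}, {c}) outside {self.n_rows}x{self.n_cols} grid")

    @classmethod
    def from_strain_blocks(
        cls,
        strains: list[str],
        plate_id: str,
        n_rows: int = 32,
        n_cols: int = 48,
        condition: str = "fusion",
    ) -> "PlateLayout":
        """Arrange strains as 2x2 replicate blocks, block-row major.

        Capacity is ``(n_rows // 2) * (n_cols // 2)`` strains; unfilled
        positions are explicitly empty.
        """
        blocks_per_row = n_cols // 2
        capacity = (n_rows // 2) * blocks_per_row
        if len(strains) > capacity:
            raise LayoutError(f"{len(strains)} strains exceed plate capacity {capacity}")
        pmap: dict[tuple[int, int], str | None] = {
            (r, c): None for r in range(n_rows) for c in range(n_cols)
        }
        for i, s in enumerate(strains):
            br, bc = divmod(i, blocks_per_row)
            for dr in (0, 1):
                for dc in (0, 1):
                    pmap[(2 * br + dr, 2 * bc + dc)] = s
        return cls(plate_id, n_rows, n_cols, pmap, replicate_block=4, condition=condition)

    @classmethod
    def from_strain_runs(
        cls,
        strains: list[str],
        plate_id: str,
        run_length: int = 16,
        n_rows: int = 32,
        n_cols: int = 48,
        condition: str = "fusion",
    ) -> "PlateLayout":
        """Arrange strains as row-major runs of ``run_length`` consecutive
        positions (the 16-replicate retest layout)."""
        capacity = (n_rows * n_cols) // run_length
        if len(strains) > capacity:
            raise LayoutError(f"{len(strains)} strains exceed plate capacity {capacity}")
        pmap: dict[tuple[int, int], str | None] = {
            (r, c): None for r in range(n_rows) for c in range(n_cols)
        }
        for i, s in enumerate(strains):
            for k in range(run_length):
                flat = i * run_length + k
                pmap[divmod(flat, n_cols)] = s
        return cls(plate_id, n_rows, n_cols, pmap, replicate_block=run_length, condition=condition)

    def strain_at(self, row: int, col: int) -> str | None:
        return self.position_map.get((row, col))

    def positions_of(self, strain: str) -> list[tuple[int, int]]:
        return sorted(pos for pos, s in self.position_map.items() if s == strain)

    @property
    def strains(self) -> list[str]:
        seen: dict[str, None] = {}
        for pos in sorted(self.position_map):
            s = self.position_map[pos]
            if s is not None:
                seen.setdefault(s, None)
        return list(seen)

    @property
    def control_positions(self) -> list[tuple[int, int]]:
        return sorted(
            pos
            for pos, s in self.position_map.items()
            if s is not None and s.startswith(CONTROL_PREFIX)
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"plate_id": self.plate_id, "row": r, "col": c,
             "strain": EMPTY_TOKEN if s is None else s}
            for (r, c), s in sorted(self.position_map.items())
        ]
        return pd.DataFrame(rows, columns=["plate_id", "row", "col", "strain"])

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# plate layout; 0-based (row, col), row 0 at image top; "
                     f"'{EMPTY_TOKEN}' marks an empty position\n")
            fh.write(f"# plate_id={self.plate_id} n_rows={self.n_rows} n_cols={self.n_cols} "
                     f"replicate_block={self.replicate_block} condition={self.condition}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "PlateLayout":
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                for token in line[1:].split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"strain": str})
        pmap = {
            (int(r.row), int(r.col)): (None if r.strain == EMPTY_TOKEN else r.strain)
            for r in df.itertuples()
        }
        return cls(
            plate_id=meta.get("plate_id", str(df["plate_id"].iloc[0])),
            n_rows=int(meta.get("n_rows", df["row"].max() + 1)),
            n_cols=int(meta.get("n_cols", df["col"].max() + 1)),
            position_map=pmap,
            replicate_block=int(meta.get("replicate_block", 4)),
            condition=meta.get("condition", "fusion"),
        )


ANNOTATION_COLUMNS = ["protein", "compartment", "abundance", "essential",
                      "validated_gfp", "human_homolog"]


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read a per-protein annotation TSV.

    Columns: protein, compartment, abundance (molecules/cell, may be NA),
    essential, validated_gfp, human_homolog (booleans as 0/1).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation table missing columns {sorted(missing)}")
    if df["protein"].duplicated().any():
        dupes = df.loc[df["protein"].duplicated(), "protein"].tolist()
        raise AnnotationError(f"duplicate protein identifiers: {dupes[:5]}")
    ab = df["abundance"]
    if (ab.dropna() < 0).any():
        raise AnnotationError("negative abundance values")
    for col in ("essential", "validated_gfp", "human_homolog"):
        df[col] = df[col].astype(bool)
    return df[ANNOTATION_COLUMNS]


def write_annotation_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[ANNOTATION_COLUMNS].copy()
    for col in ("essential", "validated_gfp", "human_homolog"):
        out[col] = out[col].astype(int)
    with open(path, "w") as fh:
        fh.write("# per-protein annotations; abundance in molecules/cell, NA if unknown\n")
        out.to_csv(fh, sep="\t", index=False, na_rep="NA")


@dataclass
class InteractionNetwork:
    """Undirected, deduplicated edge list over protein identifiers."""

    edges: pd.DataFrame  # columns: a, b, etype

    @classmethod
    def from_pairs(cls, pairs, etype: str = "physical") -> "InteractionNetwork":
        rows = []
        for item in pairs:
            if len(item) == 3:
                a, b, t = item
            else:
                a, b = item
                t = etype
            if t not in ("physical", "genetic"):
                raise ValueError(f"unknown edge type {t!r}")
            if a == b:
                continue  # self-edges dropped
            a, b = sorted((str(a), str(b)))
            rows.append((a, b, t))
        df = pd.DataFrame(rows, columns=["a", "b", "etype"]).drop_duplicates(
            subset=["a", "b"], keep="first"
        )
        return cls(df.sort_values(["a", "b"]).reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["a"], self.edges["b"]))

    def nodes(self) -> set[str]:
        return set(self.edges["a"]) | set(self.edges["b"])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# undirected edges, endpoints sorted lexicographically\n")
            self.edges.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InteractionNetwork":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        return cls.from_pairs(df[["a", "b", "etype"]].itertuples(index=False))
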