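"""Synthetic screens, plates, images, annotations and fluorescence stacks.

Every generator is deterministic given its seed and returns a ground-truth
record sufficient to score downstream stages (sensitivity, FDR, recovered
intensity) without re-reading the generating spec.

The colony-size model is multiplicative:

    size = base x control_effect(query) x gradient(row, col)
           x (1 - effect)   [fusion condition, planted interactions only]
           x lognormal(0, noise_sigma)

Colony areas are positive and right-skewed, hence lognormal noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial import polynomial as npoly

from spiscreen.io_cli.layout import CONDITIONS, CONTROL_PREFIX, PlateLayout

logger = logging.getLogger(__name__)


class SimSpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimSpec:
    """Parameters of a simulated dual-control colony screen.

    ``gradient_coeffs`` are 2D polynomial coefficients ``c[i][j]`` of a
    multiplier evaluated over normalized coordinates (row/(n_rows-1),
    col/(n_cols-1)); ``None`` means a flat plate (multiplier 1).
    ``spi_set`` maps (query, target) to a fractional size reduction in
    (0, 1] applied to the fusion condition only.
    """

    n_queries: int
    n_targets: int = 1
    replicate_count: int = 4
    gradient_coeffs: list | None = None
    noise_sigma: float = 0.2
    spi_set: dict = field(default_factory=dict)
    control_effects: dict = field(default_factory=dict)
    controls_per_plate: int = 0
    base_size: float = 200.0
    n_rows: int = 32
    n_cols: int = 48
    seed: int = 0

    @property
    def queries(self) -> list[str]:
        return [f"Q{i:05d}" for i in range(self.n_queries)]

    @property
    def targets(self) -> list[str]:
        return [f"T{i:02d}" for i in range(self.n_targets)]

    def gradient(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        if self.gradient_coeffs is None:
            return np.ones(np.shape(rows), dtype=float)
        x = np.asarray(rows, dtype=float) / max(self.n_rows - 1, 1)
        y = np.asarray(cols, dtype=float) / max(self.n_cols - 1, 1)
        return npoly.polyval2d(x, y, np.asarray(self.gradient_coeffs, dtype=float))

    def validate(self) -> None:
        if self.replicate_count != 4:
            raise SimSpecError("screen simulation arranges 2x2 blocks; replicate_count must be 4")
        queries, targets = set(self.queries), set(self.targets)
        for (q, t), eff in self.spi_set.items():
            if q not in queries:
                raise SimSpecError(f"spi_set references unknown query {q!r}")
            if t not in targets:
                raise SimSpecError(f"spi_set references unknown target {t!r}")
            if not (0.0 < eff <= 1.0):
                raise SimSpecError(f"effect {eff} for ({q}, {t}) not in (0, 1]")
        for q in self.control_effects:
            if q not in queries:
                raise SimSpecError(f"control_effects references unknown query {q!r}")
        rr, cc = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        if np.any(self.gradient(rr, cc) <= 0):
            raise SimSpecError("gradient multiplier must be positive over the plate")


@dataclass
class ScreenSim:
    """Result of :func:`simulate_screen`."""

    tables: dict[str, pd.DataFrame]       # condition -> colony table
    truth: pd.DataFrame                   # query, target, effect
    layouts: dict[str, PlateLayout]       # plate_id -> layout
    spec: ScreenSimSpec


def _plate_chunks(items: list[str], capacity: int) -> list[list[str]]:
    return [items[i:i + capacity] for i in range(0, len(items), capacity)]


def simulate_screen(spec: ScreenSimSpec) -> ScreenSim:
    """Simulate fusion + two control colony tables with planted growth defects.

    The same per-query baseline fitness (``control_effects``) and the same
    spatial gradient apply to all three conditions; planted interaction
    effects apply to the fusion condition only.  Noise draws are independent
    per colony and condition.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    capacity = (spec.n_rows // 2) * (spec.n_cols // 2) - spec.controls_per_plate
    if capacity <= 0:
        raise SimSpecError("controls_per_plate leaves no room for queries")

    ctrl_effect = {q: float(spec.control_effects.get(q, 1.0)) for q in spec.queries}
    frames: dict[str, list[pd.DataFrame]] = {cond: [] for cond in CONDITIONS}
    layouts: dict[str, PlateLayout] = {}

    for target in spec.targets:
        for p_idx, chunk in enumerate(_plate_chunks(spec.queries, capacity)):
            controls = [f"{CONTROL_PREFIX}{k:02d}" for k in range(spec.controls_per_plate)]
            strains = chunk + controls
            base_layout = PlateLayout.from_strain_blocks(
                strains, plate_id="tmp", n_rows=spec.n_rows, n_cols=spec.n_cols)
            positions = sorted(
                (pos, s) for pos, s in base_layout.position_map.items() if s is not None)
            rows = np.array([p[0][0] for p in positions])
            cols = np.array([p[0][1] for p in positions])
            strain_arr = np.array([p[1] for p in positions], dtype=object)
            grad = spec.gradient(rows, cols)
            base_mult = np.array([
                spec.base_size * ctrl_effect.get(s, 1.0) for s in strain_arr
            ]) * grad
            for cond in CONDITIONS:
                plate_id = f"{target}_{cond}_p{p_idx:02d}"
                layouts[plate_id] = PlateLayout(
                    plate_id, spec.n_rows, spec.n_cols,
                    dict(base_layout.position_map), replicate_block=4, condition=cond)
                mult = base_mult.copy()
                if cond == "fusion":
                    eff = np.array([
                        1.0 - spec.spi_set.get((s, target), 0.0) for s in strain_arr
                    ])
                    mult = mult * eff
                noise = rng.lognormal(0.0, spec.noise_sigma, size=mult.size) \
                    if spec.noise_sigma > 0 else np.ones(mult.size)
                frames[cond].append(pd.DataFrame({
                    "plate_id": plate_id, "row": rows, "col": cols,
                    "strain": strain_arr, "size": mult * noise,
                    "empty": False, "target": target, "condition": cond,
                }))

    tables = {cond: pd.concat(parts, ignore_index=True) for cond, parts in frames.items()}
    truth = pd.DataFrame(
        [(q, t, e) for (q, t), e in sorted(spec.spi_set.items())],
        columns=["query", "target", "effect"],
    )
    return ScreenSim(tables=tables, truth=truth, layouts=layouts, spec=spec)


def simulate_retest_plate(
    candidates: list[str],
    truth: pd.DataFrame,
    target: str,
    replicate_count: int = 16,
    controls_per_plate: int = 16,
    noise_sigma: float = 0.2,
    base_size: float = 200.0,
    n_rows: int = 32,
    n_cols: int = 48,
    seed: int = 0,
) -> ScreenSim:
    """Simulate the 16-replicate confirmation plates for ranked candidates.

    Candidates carrying a planted effect in ``truth`` keep it; the rest are
    null.  Each plate carries ``controls_per_plate`` neutral control strains;
    candidates overflowing one plate are split across plates (logged).
    """
    if not candidates:
        raise SimSpecError("candidate list is empty")
    rng = np.random.default_rng(seed)
    effects = {
        (r.query, r.target): float(r.effect) for r in truth.itertuples()
    } if len(truth) else {}

    capacity = (n_rows * n_cols) // replicate_count - controls_per_plate
    if capacity <= 0:
        raise SimSpecError("controls_per_plate leaves no room for candidates")
    chunks = _plate_chunks(list(candidates), capacity)
    if len(chunks) > 1:
        logger.info("retest of %d candidates split across %d plates", len(candidates), len(chunks))

    frames: dict[str, list[pd.DataFrame]] = {cond: [] for cond in CONDITIONS}
    layouts: dict[str, PlateLayout] = {}
    for p_idx, chunk in enumerate(chunks):
        controls = [f"{CONTROL_PREFIX}{k:02d}" for k in range(controls_per_plate)]
        strains = chunk + controls
        base_layout = PlateLayout.from_strain_runs(
            strains, "tmp", run_length=replicate_count, n_rows=n_rows, n_cols=n_cols)
        positions = sorted(
            (pos, s) for pos, s in base_layout.position_map.items() if s is not None)
        rows = np.array([p[0][0] for p in positions])
        cols = np.array([p[0][1] for p in positions])
        strain_arr = np.array([p[1] for p in positions], dtype=object)
        for cond in CONDITIONS:
            plate_id = f"{target}_retest_{cond}_p{p_idx:02d}"
            layouts[plate_id] = PlateLayout(
                plate_id, n_rows, n_cols, dict(base_layout.position_map),
                replicate_block=replicate_count, condition=cond)
            if cond == "fusion":
                mult = np.array([1.0 - effects.get((s, target), 0.0) for s in strain_arr])
            else:
                mult = np.ones(strain_arr.size)
            noise = rng.lognormal(0.0, noise_sigma, size=mult.size) \
                if noise_sigma > 0 else np.ones(mult.size)
            frames[cond].append(pd.DataFrame({
                "plate_id": plate_id, "row": rows, "col": cols,
                "strain": strain_arr, "size": base_size * mult * noise,
                "empty": False, "target": target, "condition": cond,
            }))

    tables = {cond: pd.concat(parts, ignore_index=True) for cond, parts in frames.items()}
    sub_truth = pd.DataFrame(
        [(q, target, effects[(q, target)]) for q in candidates if (q, target) in effects],
        columns=["query", "target", "effect"],
    )
    return ScreenSim(tables=tables, truth=sub_truth, layouts=layouts,
                     spec=None)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# plate-image rendering
# ---------------------------------------------------------------------------

def render_plate_image(
    table: pd.DataFrame,
    pitch: float = 20.0,
    origin: tuple[float, float] = (10.0, 10.0),
    radius_scale: float = 0.5,
    foreground: float = 200.0,
    background: float = 30.0,
    noise_sigma: float = 0.0,
    polarity: str = "colonies_bright",
    seed: int = 0,
    dtype=np.uint8,
) -> tuple[np.ndarray, dict]:
    """Rasterize a colony table to a grayscale plate image.

    Colonies are disks of radius ``radius_scale * sqrt(size)`` centred on
    their grid position; disk radius must not exceed half the grid pitch.
    Returns the image and its geometry (origin, pitch, rotation) as truth.
    """
    from skimage.draw import disk

    rng = np.random.default_rng(seed)
    n_rows = int(table["row"].max()) + 1
    n_cols = int(table["col"].max()) + 1
    shape = (int(origin[0] + pitch * n_rows), int(origin[1] + pitch * n_cols))
    img = np.full(shape, background, dtype=float)

    for r in table.itertuples():
        if not np.isfinite(r.size) or r.size <= 0:
            continue
        radius = radius_scale * math.sqrt(r.size)
        if radius > pitch / 2:
            raise ValueError(
                f"colony radius {radius:.1f}px exceeds half the grid pitch ({pitch / 2:.1f}px)")
        cy = origin[0] + (r.row + 0.5) * pitch
        cx = origin[1] + (r.col + 0.5) * pitch
        rr, cc = disk((cy, cx), radius, shape=shape)
        img[rr, cc] = foreground

    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    if polarity == "colonies_dark":
        img = (float(np.iinfo(dtype).max) if np.issubdtype(dtype, np.integer) else 255.0) - img
    info = np.iinfo(dtype) if np.issubdtype(dtype, np.integer) else None
    if info is not None:
        img = np.clip(img, info.min, info.max)
    geometry = {
        "origin_y": origin[0] + pitch / 2, "origin_x": origin[1] + pitch / 2,
        "pitch_y": pitch, "pitch_x": pitch, "rotation_deg": 0.0,
        "n_rows": n_rows, "n_cols": n_cols,
    }
    return img.astype(dtype), geometry


# ---------------------------------------------------------------------------
# fluorescence stacks
# ---------------------------------------------------------------------------

@dataclass
class FocusSimSpec:
    """A 3D stack with diffraction-limited Gaussian foci of known integral."""

    shape: tuple[int, int, int]                  # (z, y, x) voxels
    voxel_size: tuple[float, float, float]       # nm per axis (z, y, x)
    foci: list[dict] = field(default_factory=list)  # center (z,y,x voxels), intensity, sigma_nm
    background: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise SimSpecError("voxel sizes must be positive")
        for f in self.foci:
            if float(f["intensity"]) <= 0:
                raise SimSpecError("focus intensity must be positive")
            c = f["center"]
            if not all(0 <= c[i] < self.shape[i] for i in range(3)):
                raise SimSpecError(f"focus center {c} outside stack bounds {self.shape}")


def simulate_focus_stack(spec: FocusSimSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render Gaussian foci on a flat noisy background.

    Each focus's discrete Gaussian is normalized to unit sum over the stack,
    so its planted integrated intensity is conserved exactly at zero noise.
    Foci whose centres lie closer than three times the larger sigma get an
    ``overlap_warning`` in the truth table.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = np.meshgrid(*(np.arange(s, dtype=float) for s in spec.shape), indexing="ij")
    stack = np.full(spec.shape, float(spec.background))

    records = []
    for i, f in enumerate(spec.foci):
        cz, cy, cx = f["center"]
        sigma = float(f["sigma_nm"])
        vz, vy, vx = spec.voxel_size
        g = np.exp(-0.5 * (((zz - cz) * vz / sigma) ** 2
                           + ((yy - cy) * vy / sigma) ** 2
                           + ((xx - cx) * vx / sigma) ** 2))
        g /= g.sum()
        stack += float(f["intensity"]) * g
        records.append({
            "focus_id": i, "z": cz, "y": cy, "x": cx,
            "intensity": float(f["intensity"]), "sigma_nm": sigma,
            "overlap_warning": False,
        })

    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            d = math.sqrt(sum(
                ((a[k] - b[k]) * v) ** 2
                for k, v in zip(("z", "y", "x"), spec.voxel_size)))
            if d < 3.0 * max(a["sigma_nm"], b["sigma_nm"]):
                records[i]["overlap_warning"] = records[j]["overlap_warning"] = True
                logger.warning("foci %d and %d overlap (separation %.0f nm)", i, j, d)

    if spec.noise_sigma > 0:
        stack = stack + rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    truth = pd.DataFrame(records, columns=[
        "focus_id", "z", "y", "x", "intensity", "sigma_nm", "overlap_warning"])
    return stack, truth


# ---------------------------------------------------------------------------
# annotations and interaction networks
# ---------------------------------------------------------------------------

def simulate_annotations(
    n_proteins: int,
    compartment_probs: dict[str, float],
    abundance_lognorm: tuple[float, float] = (5.0, 1.5),
    spi_queries: list[str] | None = None,
    enriched_compartment: str | None = None,
    enrichment_factor: float = 1.0,
    module_size: int = 0,
    p_in: float = 0.0,
    p_out: float = 0.0,
    essential_prob: float = 0.2,
    validated_prob: float = 0.65,
    homolog_prob: float = 0.56,
    seed: int = 0,
):
    """Generate an annotation table and an interaction network.

    Compartments are drawn multinomially; with ``enrichment_factor > 1`` the
    designated compartment is over-represented among ``spi_queries``.  Edges
    are planted with probability ``p_in`` inside the module (the first
    ``module_size`` proteins) and ``p_out`` elsewhere, to give the
    interaction-density ranking a known signal.
    """
    from spiscreen.io_cli.layout import InteractionNetwork

    probs = np.array(list(compartment_probs.values()), dtype=float)
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise SimSpecError("compartment proportions must sum to 1")
    labels = list(compartment_probs.keys())
    rng = np.random.default_rng(seed)

    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    comp = rng.choice(labels, size=n_proteins, p=probs)
    if spi_queries and enriched_compartment and enrichment_factor != 1.0:
        boosted = probs.copy()
        k = labels.index(enriched_compartment)
        boosted[k] *= enrichment_factor
        boosted /= boosted.sum()
        idx = {p: i for i, p in enumerate(proteins)}
        for q in spi_queries:
            comp[idx[q]] = rng.choice(labels, p=boosted)

    mu, sig = abundance_lognorm
    annotations = pd.DataFrame({
        "protein": proteins,
        "compartment": comp,
        "abundance": rng.lognormal(mu, sig, size=n_proteins),
        "essential": rng.random(n_proteins) < essential_prob,
        "validated_gfp": rng.random(n_proteins) < validated_prob,
        "human_homolog": rng.random(n_proteins) < homolog_prob,
    })

    iu, ju = np.triu_indices(n_proteins, k=1)
    in_module = (iu < module_size) & (ju < module_size)
    p_edge = np.where(in_module, p_in, p_out)
    keep = rng.random(iu.size) < p_edge
    pairs = [(proteins[a], proteins[b]) for a, b in zip(iu[keep], ju[keep])]
    network = InteractionNetwork.from_pairs(pairs, etype="physical")
    return annotations, network
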