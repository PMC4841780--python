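"""Colony sizes -> normalized growth scores.

Stages: per-plate normalization (plate median, or on-plate controls when a
plate is dominated by affected strains), log growth ratios (LGR) against
each of the two controls, robust z-scores per screen x control, and the
spatial smoothing correction that removes plate-position gradients.

Sign convention: positive LGR / z means a growth defect of the fusion
relative to its control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from spiscreen._util import robust_location_scale
from spiscreen.io_cli.layout import CONTROL_PREFIX

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


class ScoreError(ValueError):
    pass


def _ensure_target(table: pd.DataFrame) -> pd.DataFrame:
    if "target" not in table.columns:
        table = table.copy()
        table["target"] = "T00"
    return table


def normalize_plate(table: pd.DataFrame, mode: str = "plate_median") -> pd.DataFrame:
    """Divide each plate's sizes by a per-plate normalizer.

    ``plate_median`` uses the median of all non-absent colonies (needs >= 10);
    ``control_reference`` uses the mean of on-plate control colonies
    (strains labelled ``CTRL*``, needs >= 4) — appropriate when most strains
    on a plate carry an effect and the median itself is shifted.
    """
    if mode not in ("plate_median", "control_reference"):
        raise NormalizationError(f"unknown normalization mode {mode!r}")
    out = []
    for plate_id, sub in table.groupby("plate_id", sort=True):
        sizes = sub["size"].to_numpy(dtype=float)
        finite = sizes[np.isfinite(sizes)]
        if mode == "plate_median":
            if finite.size < 10:
                raise NormalizationError(
                    f"plate {plate_id}: {finite.size} colonies < 10 required for plate-median")
            norm = float(np.median(finite))
        else:
            is_ctrl = sub["strain"].astype(str).str.startswith(CONTROL_PREFIX)
            ctrl = sub.loc[is_ctrl, "size"].to_numpy(dtype=float)
            ctrl = ctrl[np.isfinite(ctrl)]
            if ctrl.size < 4:
                raise NormalizationError(
                    f"plate {plate_id}: {ctrl.size} control colonies < 4 required "
                    "for control-reference normalization")
            norm = float(np.mean(ctrl))
        if not np.isfinite(norm) or norm <= 0:
            raise NormalizationError(f"plate {plate_id}: normalizer {norm} is not positive")
        logger.info("plate %s: %s normalizer = %.4g", plate_id, mode, norm)
        sub = sub.copy()
        sub["size"] = sizes / norm
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def compute_lgr(fusion: pd.DataFrame, control: pd.DataFrame,
                control_name: str) -> pd.DataFrame:
    """Per-strain log growth ratio ln(mean control size / mean fusion size).

    Means are over each strain's non-absent replicates; on-plate control
    strains (``CTRL*``) are reference material and excluded from the output.
    A zero fusion mean yields a ``+inf`` sentinel with the ``lethal`` flag —
    total lethality is informative but must not enter distribution fits.
    """
    fusion = _ensure_target(fusion)
    control = _ensure_target(control)

    def per_strain(df: pd.DataFrame) -> pd.DataFrame:
        g = df.groupby(["target", "strain"])["size"]
        return pd.DataFrame({"mean": g.mean(), "n": g.count()})

    fs = per_strain(fusion)
    cs = per_strain(control)
    joined = fs.join(cs, how="inner", lsuffix="_fusion", rsuffix="_control")
    joined = joined[(joined["n_fusion"] >= 1) & (joined["n_control"] >= 1)]
    joined = joined.reset_index().rename(columns={"strain": "query"})
    joined = joined[~joined["query"].astype(str).str.startswith(CONTROL_PREFIX)]
    if joined.empty:
        raise ScoreError("no shared strains between fusion and control tables")

    fmean = joined["mean_fusion"].to_numpy(dtype=float)
    cmean = joined["mean_control"].to_numpy(dtype=float)
    lgr = np.full(fmean.shape, np.inf)
    ok = fmean > 0
    with np.errstate(divide="ignore"):
        lgr[ok] = np.log(cmean[ok] / fmean[ok])
    return pd.DataFrame({
        "query": joined["query"], "target": joined["target"],
        "control": control_name, "lgr": lgr,
        "n_fusion": joined["n_fusion"].astype(int),
        "n_control": joined["n_control"].astype(int),
        "lethal": ~np.isfinite(lgr),
    })


def compute_z(lgr_target_only: pd.DataFrame, lgr_gbp_only: pd.DataFrame,
              min_finite: int = 30) -> pd.DataFrame:
    """Standardize LGRs and average the two control z-scores.

    z = (lgr - median) / (1.4826 x MAD), fitted per screen (target) and
    control over finite LGRs only; +inf sentinels map to +inf z.  z_mean is
    the mean of the two control z-scores (or the defined one).
    """
    pieces = {}
    for name, df in (("z_vs_target_only", lgr_target_only),
                     ("z_vs_gbp_only", lgr_gbp_only)):
        zs = []
        for target, sub in df.groupby("target", sort=True):
            lgr = sub["lgr"].to_numpy(dtype=float)
            finite = lgr[np.isfinite(lgr)]
            if finite.size < min_finite:
                raise ScoreError(
                    f"screen {target}: {finite.size} finite LGRs < {min_finite} required")
            loc, scale = robust_location_scale(finite)
            if scale <= 0:
                raise ScoreError(f"screen {target}: zero scale in LGR distribution")
            z = (lgr - loc) / scale
            zs.append(pd.DataFrame({
                "query": sub["query"], "target": target, name: z}))
        pieces[name] = pd.concat(zs, ignore_index=True)

    merged = pd.merge(pieces["z_vs_target_only"], pieces["z_vs_gbp_only"],
                      on=["query", "target"], how="outer")
    z_t = merged["z_vs_target_only"].to_numpy(dtype=float)
    z_g = merged["z_vs_gbp_only"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        merged["z_mean"] = np.where(
            np.isnan(z_t), z_g, np.where(np.isnan(z_g), z_t, (z_t + z_g) / 2.0))
    return merged[["query", "target", "z_vs_target_only", "z_vs_gbp_only", "z_mean"]]


# ---------------------------------------------------------------------------
# spatial smoothing
# ---------------------------------------------------------------------------

def _smooth_grid(z_grid: np.ndarray, strain_codes: np.ndarray, w: int,
                 statistic: str) -> tuple[np.ndarray, np.ndarray]:
    """Local-background estimate per grid position.

    The (2w+1)^2 window around each position is truncated at plate edges and
    excludes the centre and every position holding the centre's strain, so a
    strain's own replicates never contribute to its background.  Returns
    (background, no_neighbors flag); background is 0 where no eligible
    neighbour exists.
    """
    n_rows, n_cols = z_grid.shape
    k = 2 * w + 1
    zp = np.full((n_rows + 2 * w, n_cols + 2 * w), np.nan)
    zp[w:n_rows + w, w:n_cols + w] = z_grid
    sp = np.full((n_rows + 2 * w, n_cols + 2 * w), -1, dtype=np.int64)
    sp[w:n_rows + w, w:n_cols + w] = strain_codes

    zw = sliding_window_view(zp, (k, k)).reshape(n_rows, n_cols, k * k).copy()
    sw = sliding_window_view(sp, (k, k)).reshape(n_rows, n_cols, k * k)
    zw[..., (k * k) // 2] = np.nan  # centre never contributes
    same_strain = (sw == strain_codes[..., None]) & (strain_codes[..., None] >= 0)
    zw[same_strain] = np.nan

    no_neighbors = np.all(np.isnan(zw), axis=-1)
    zw_safe = np.where(no_neighbors[..., None], 0.0, zw)
    with np.errstate(all="ignore"):
        if statistic == "median":
            bg = np.nanmedian(zw_safe, axis=-1)
        elif statistic == "mean":
            bg = np.nanmean(zw_safe, axis=-1)
        else:
            raise ScoreError(f"unknown smoothing statistic {statistic!r}")
    bg = np.where(no_neighbors, 0.0, bg)
    return bg, no_neighbors


def smooth_spatial(positions: pd.DataFrame, w: int = 3,
                   statistic: str = "median") -> pd.DataFrame:
    """Subtract a local background from per-position z-scores.

    ``positions`` is a long table with plate_id, row, col, strain, z.
    Positions whose window holds no eligible neighbour keep their z and are
    flagged ``no_neighbors``.
    """
    if w < 1:
        raise ScoreError("window half-width w must be >= 1")
    out = []
    for plate_id, sub in positions.groupby("plate_id", sort=True):
        n_rows = int(sub["row"].max()) + 1
        n_cols = int(sub["col"].max()) + 1
        z_grid = np.full((n_rows, n_cols), np.nan)
        codes = np.full((n_rows, n_cols), -1, dtype=np.int64)
        rr = sub["row"].to_numpy()
        cc = sub["col"].to_numpy()
        z_grid[rr, cc] = sub["z"].to_numpy(dtype=float)
        strain_ids, strain_codes = np.unique(sub["strain"].astype(str), return_inverse=True)
        codes[rr, cc] = strain_codes
        bg, lonely = _smooth_grid(z_grid, codes, w, statistic)
        sub = sub.copy()
        sub["background"] = bg[rr, cc]
        sub["z_smoothed"] = sub["z"] - sub["background"]
        sub["no_neighbors"] = lonely[rr, cc]
        out.append(sub)
    return pd.concat(out, ignore_index=True)


def smooth_scores(scores: pd.DataFrame, fusion_table: pd.DataFrame,
                  w: int = 3, statistic: str = "median") -> pd.DataFrame:
    """Smooth each control's z over plate positions, then re-average.

    Per-strain z-scores are placed at the strain's replicate positions on
    the fusion plates; the smoothed per-strain score is the mean of its
    per-position smoothed values.  Smoothing runs per control condition and
    ``z_smoothed`` is recomputed as the mean of the two smoothed controls,
    so averaging never precedes the spatial correction.
    """
    fusion_table = _ensure_target(fusion_table)
    pos = fusion_table[["plate_id", "row", "col", "strain", "target"]].copy()
    scores = scores.copy()
    for col, out_col in (("z_vs_target_only", "z_smoothed_target_only"),
                         ("z_vs_gbp_only", "z_smoothed_gbp_only")):
        zmap = scores.set_index(["query", "target"])[col]
        key = pd.MultiIndex.from_arrays([pos["strain"], pos["target"]])
        pos_z = pos.copy()
        pos_z["z"] = zmap.reindex(key).to_numpy(dtype=float)
        pos_z.loc[~np.isfinite(pos_z["z"]), "z"] = np.nan
        smoothed = smooth_spatial(pos_z, w=w, statistic=statistic)
        per_strain = smoothed.groupby(["strain", "target"])["z_smoothed"].mean()
        skey = pd.MultiIndex.from_arrays([scores["query"], scores["target"]])
        vals = per_strain.reindex(skey).to_numpy(dtype=float)
        # lethal sentinels bypass smoothing and stay maximal
        raw = scores[col].to_numpy(dtype=float)
        scores[out_col] = np.where(np.isposinf(raw), np.inf, vals)
    z_t = scores["z_smoothed_target_only"].to_numpy(dtype=float)
    z_g = scores["z_smoothed_gbp_only"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        scores["z_smoothed"] = np.where(
            np.isnan(z_t), z_g, np.where(np.isnan(z_g), z_t, (z_t + z_g) / 2.0))
    return scores
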