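"""Sequential-retest confirmation of growth-defect candidates.

Candidates are ranked by smoothed z-score and confirmed in batches of 20
with 16 replicates against both controls.  A batch's FDR is its fraction of
unconfirmed strains; retesting stops once the 3-point moving average of the
batchwise FDR reaches 40%.  Confirmed strains from all processed batches
(including the stopping batch) are the screen's confirmed interactions.

The confirm rule combines an effect-size floor (LGR >= tau) with a
one-sided rank-sum test (exact null for n <= 16), required against *both*
controls by default ("either" is available as a config knob).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.15
DEFAULT_ALPHA = 0.05


def rank_candidates(scores: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Order strains from strongest to weakest growth defect.

    Uses ``z_smoothed`` when present (else ``z_mean``); ties broken by
    ``z_vs_gbp_only`` (descending) then lexicographic query id, so the
    ranking is deterministic and stable across runs.
    """
    if by is None:
        by = "z_smoothed" if "z_smoothed" in scores.columns else "z_mean"
    if by not in scores.columns:
        raise ValueError(f"score column {by!r} not present")
    cols = [by, "z_vs_gbp_only", "query"]
    ascending = [False, False, True]
    present = [c for c in cols if c in scores.columns]
    ranked = scores.sort_values(
        present, ascending=ascending[: len(present)], kind="mergesort"
    ).reset_index(drop=True)
    ranked["rank"] = np.arange(1, len(ranked) + 1)
    return ranked


@dataclass
class ConfirmCall:
    """Outcome of one strain's 16-replicate confirmation."""

    confirmed: bool | None  # None = indeterminate (too few replicates)
    lgr_target_only: float
    lgr_gbp_only: float
    p_target_only: float
    p_gbp_only: float


def _one_sided_ranksum(control: np.ndarray, fusion: np.ndarray) -> float:
    """P(control > fusion) one-sided rank-sum; exact null for n <= 16."""
    method = "exact" if max(control.size, fusion.size) <= 16 else "asymptotic"
    try:
        res = stats.mannwhitneyu(control, fusion, alternative="greater", method=method)
    except ValueError:
        # exact method refuses ties in some scipy versions; fall back
        res = stats.mannwhitneyu(control, fusion, alternative="greater",
                                 method="asymptotic")
    return float(res.pvalue)


def confirm_strain(
    fusion: np.ndarray,
    control_target_only: np.ndarray,
    control_gbp_only: np.ndarray,
    tau: float = DEFAULT_TAU,
    alpha: float = DEFAULT_ALPHA,
    require: str = "both",
    min_replicates: int = 12,
) -> ConfirmCall:
    """Call a retested strain confirmed if it shows a growth defect vs controls.

    Per control: LGR = ln(mean control / mean fusion) must reach ``tau`` and
    the one-sided rank-sum test must reject at ``alpha``.  ``require`` is
    "both" (default) or "either".  Fewer than ``min_replicates`` non-absent
    replicates in any condition yields an indeterminate call.
    """
    if require not in ("both", "either"):
        raise ValueError(f"require must be 'both' or 'either', got {require!r}")
    arrays = []
    for arr in (fusion, control_target_only, control_gbp_only):
        arr = np.asarray(arr, dtype=float)
        arrays.append(arr[np.isfinite(arr)])
    fus, ctrl_a, ctrl_b = arrays
    if min(a.size for a in arrays) < min_replicates:
        logger.warning("indeterminate call: %s replicates per condition (< %d)",
                       [a.size for a in arrays], min_replicates)
        return ConfirmCall(None, np.nan, np.nan, np.nan, np.nan)

    def against(ctrl: np.ndarray) -> tuple[float, float, bool]:
        fmean = float(np.mean(fus))
        lgr = np.inf if fmean <= 0 else float(np.log(np.mean(ctrl) / fmean))
        p = _one_sided_ranksum(ctrl, fus)
        return lgr, p, (lgr >= tau) and (p < alpha)

    lgr_a, p_a, ok_a = against(ctrl_a)
    lgr_b, p_b, ok_b = against(ctrl_b)
    confirmed = (ok_a and ok_b) if require == "both" else (ok_a or ok_b)
    return ConfirmCall(confirmed, lgr_a, lgr_b, p_a, p_b)


def sequential_fdr(
    ranked: list[str],
    retest_source,
    target: str = "T00",
    batch_size: int = 20,
    stop_fdr: float = 0.40,
    tau: float = DEFAULT_TAU,
    alpha: float = DEFAULT_ALPHA,
    require: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confirm ranked candidates batchwise until the FDR trajectory stops.

    ``retest_source(query)`` returns (fusion, control_target_only,
    control_gbp_only) replicate size arrays, or ``None`` if the strain has
    no retest data (skipped with a warning).  Returns (calls, batches):
    calls has one row per retested strain; batches carries the batchwise
    FDR and its 3-point moving average (centred, truncated at the ends to
    the processed batches).

    The stop decision after batch *i* uses the moving average over the
    batches processed so far (i.e. the window truncated at the frontier);
    a first batch already at/above ``stop_fdr`` still reports its confirmed
    strains.
    """
    if not len(ranked):
        raise ValueError("ranked candidate list is empty")
    call_rows = []
    batch_fdrs: list[float] = []
    batch_rows = []
    stopped = False

    batches = [list(ranked[i:i + batch_size]) for i in range(0, len(ranked), batch_size)]
    for b_idx, batch in enumerate(batches):
        n_called = 0
        n_confirmed = 0
        for rank_pos, query in enumerate(batch, start=b_idx * batch_size + 1):
            data = retest_source(query)
            if data is None:
                logger.warning("no retest data for ranked strain %s; skipped", query)
                continue
            call = confirm_strain(*data, tau=tau, alpha=alpha, require=require)
            call_rows.append({
                "query": query, "target": target, "batch": b_idx + 1,
                "rank": rank_pos, "confirmed": call.confirmed,
                "lgr_target_only": call.lgr_target_only,
                "lgr_gbp_only": call.lgr_gbp_only,
                "p_target_only": call.p_target_only,
                "p_gbp_only": call.p_gbp_only,
            })
            if call.confirmed is not None:
                n_called += 1
                n_confirmed += int(call.confirmed)
        fdr = (n_called - n_confirmed) / n_called if n_called else 1.0
        batch_fdrs.append(fdr)
        batch_rows.append({
            "batch": b_idx + 1, "n_retested": n_called,
            "n_confirmed": n_confirmed, "fdr": fdr,
        })
        frontier_ma = float(np.mean(batch_fdrs[max(0, b_idx - 1):b_idx + 1]))
        if frontier_ma >= stop_fdr:
            stopped = True
            break

    fdr_arr = np.array(batch_fdrs)
    for i, row in enumerate(batch_rows):
        lo, hi = max(0, i - 1), min(len(fdr_arr), i + 2)
        row["moving_avg_fdr"] = float(np.mean(fdr_arr[lo:hi]))
        row["stopped_here"] = stopped and (i == len(batch_rows) - 1)

    calls = pd.DataFrame(call_rows, columns=[
        "query", "target", "batch", "rank", "confirmed",
        "lgr_target_only", "lgr_gbp_only", "p_target_only", "p_gbp_only"])
    trajectory = pd.DataFrame(batch_rows, columns=[
        "batch", "n_retested", "n_confirmed", "fdr", "moving_avg_fdr", "stopped_here"])
    return calls, trajectory


def classify_suppression(haploid_confirmed: pd.Series,
                         diploid_confirmed: pd.Series) -> pd.DataFrame:
    """Classify paired haploid/diploid confirmations per strain.

    ``suppressed``: haploid confirmed but diploid not (the untagged copy in
    the heterozygous diploid complements); ``dominant``: confirmed in both;
    ``no_spi``: not confirmed in haploid.
    """
    idx = haploid_confirmed.index.intersection(diploid_confirmed.index)
    hap = haploid_confirmed.loc[idx].astype(bool)
    dip = diploid_confirmed.loc[idx].astype(bool)
    cls = np.where(~hap, "no_spi", np.where(dip, "dominant", "suppressed"))
    return pd.DataFrame({"query": idx, "classification": cls}).reset_index(drop=True)
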