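"""Small shared helpers."""

from __future__ import annotations

import numpy as np

#: consistency constant relating MAD to the standard deviation of a normal
MAD_SCALE = 1.4826


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero to ``ndigits`` decimal places.

    Python's builtin ``round`` uses banker's rounding; printed percentages in
    screen reports conventionally round 0.5 up (away from zero).
    """
    factor = 10.0 ** ndigits
    scaled = x * factor
    rounded = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    out = rounded / factor
    return float(out) if ndigits > 0 else float(int(out)) if np.isfinite(out) else float(out)


def robust_location_scale(values: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based scale (1.4826 x MAD) of finite values."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite values to estimate location/scale")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med)))
    return med, MAD_SCALE * mad


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q
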