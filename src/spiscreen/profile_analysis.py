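"""Downstream analysis of the query x screen score matrix.

Screen-screen Spearman correlation, hierarchical centroid-linkage
clustering of phenotype profiles, SPI frequency and abundance binning,
Fisher/hypergeometric enrichment, interaction-density ranking against a
known-interaction network, and the headline summary proportions.

Missing matrix entries are handled pairwise-complete throughout and never
imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from spiscreen._util import benjamini_hochberg, round_half_away
from spiscreen.io_cli.layout import InteractionNetwork

logger = logging.getLogger(__name__)

#: distance assigned to pairs that cannot be correlated (zero variance or
#: fewer than 2 shared finite entries); the maximum of 1 - r.
MAX_DISTANCE = 2.0


# ---------------------------------------------------------------------------
# correlation and clustering
# ---------------------------------------------------------------------------

def screen_correlation(matrix: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Spearman rank correlation between screens (columns), pairwise-complete.

    Ties get average ranks; pairs sharing fewer than ``min_shared`` finite
    rows are NaN.  The diagonal is exactly 1.
    """
    corr = matrix.corr(method="spearman", min_periods=min_shared)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _pearson_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - centred Pearson r over shared finite entries; MAX_DISTANCE when
    undefined (fewer than 2 shared entries or zero variance)."""
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return MAX_DISTANCE
    va, vb = a[ok], b[ok]
    sa, sb = va.std(), vb.std()
    if sa == 0 or sb == 0:
        return MAX_DISTANCE
    r = float(np.corrcoef(va, vb)[0, 1])
    return 1.0 - r


@dataclass
class Dendrogram:
    """A scipy-convention linkage over named leaves.

    ``linkage`` rows are (id_a, id_b, height, count) with leaves 0..n-1 and
    merged clusters numbered onwards.  Centroid linkage can produce
    inversions (a merge lower than an earlier one); their merge indices are
    recorded in ``inversions`` rather than hidden.
    """

    linkage: np.ndarray
    leaves: list[str]
    inversions: list[int] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    flagged_constant: list[str] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leaf_order(self) -> list[str]:
        """Left-to-right dendrogram flattening (stored child order)."""
        n = self.n_leaves
        if n == 1:
            return list(self.leaves)
        order: list[int] = []
        stack = [int(2 * n - 2)]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                a, b = self.linkage[node - n, 0], self.linkage[node - n, 1]
                stack.append(int(b))
                stack.append(int(a))
        return [self.leaves[i] for i in order]


def cluster_profiles(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Hierarchical centroid-linkage clustering under 1 - Pearson distance.

    Cluster centroids are the nanmean profile of their member rows; at each
    step the pair of clusters with the nearest centroids merges, ties broken
    by smallest cluster id (hence smallest leaf index).  Rows with fewer
    than 2 finite entries are dropped with a warning; constant rows are
    assigned the maximal distance to everything and flagged.
    """
    if axis == "cols":
        matrix = matrix.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")

    data = matrix.to_numpy(dtype=float)
    labels = [str(i) for i in matrix.index]
    finite_counts = np.isfinite(data).sum(axis=1)
    keep = finite_counts >= 2
    dropped = [labels[i] for i in np.where(~keep)[0]]
    if dropped:
        logger.warning("dropping %d rows with < 2 finite entries: %s",
                       len(dropped), dropped[:5])
    data = data[keep]
    labels = [l for l, k in zip(labels, keep) if k]
    n = len(labels)
    if n < 2:
        return Dendrogram(np.empty((0, 4)), labels, dropped=dropped)

    flagged_constant = [
        labels[i] for i in range(n)
        if np.nanstd(data[i][np.isfinite(data[i])]) == 0
    ]

    centroids: dict[int, np.ndarray] = {i: data[i] for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = sorted(centroids)
    dist: dict[tuple[int, int], float] = {}
    for ii, i in enumerate(active):
        for j in active[ii + 1:]:
            dist[(i, j)] = _pearson_distance(centroids[i], centroids[j])

    linkage = np.zeros((n - 1, 4))
    inversions: list[int] = []
    next_id = n
    last_height = -np.inf
    for step in range(n - 1):
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (i, j), h = best
        if h < last_height:
            inversions.append(step)
        last_height = max(last_height, h)
        members[next_id] = members.pop(i) + members.pop(j)
        centroids.pop(i), centroids.pop(j)
        with np.errstate(all="ignore"):
            centroids[next_id] = np.nanmean(data[members[next_id]], axis=0)
        active = [a for a in active if a not in (i, j)]
        dist = {k: v for k, v in dist.items() if i not in k and j not in k}
        for a in active:
            dist[(a, next_id)] = _pearson_distance(centroids[a], centroids[next_id])
        active.append(next_id)
        linkage[step] = [i, j, h, len(members[next_id])]
        next_id += 1

    if inversions:
        logger.warning("centroid linkage produced %d inversion(s) at merges %s",
                       len(inversions), inversions)
    return Dendrogram(linkage, labels, inversions=inversions,
                      dropped=dropped, flagged_constant=flagged_constant)


# ---------------------------------------------------------------------------
# SPI frequency and abundance
# ---------------------------------------------------------------------------

def spi_frequency(calls: pd.DataFrame, frequent_min: int = 10) -> pd.DataFrame:
    """Per-query count of screens with a confirmed interaction.

    ``frequent`` flags queries confirmed against at least ``frequent_min``
    targets.  Returns one row per query that was ever retested.
    """
    confirmed = calls[calls["confirmed"] == True]  # noqa: E712 (None-valued column)
    counts = confirmed.groupby("query")["target"].nunique()
    all_queries = pd.Index(sorted(calls["query"].unique()), name="query")
    out = counts.reindex(all_queries, fill_value=0).rename("n_spi_targets").reset_index()
    out["frequent"] = out["n_spi_targets"] >= frequent_min
    return out


def abundance_binning(annotations: pd.DataFrame, spi_queries: set[str],
                      n_bins: int = 8) -> pd.DataFrame:
    """Equal-count abundance bins and the SPI proportion per bin.

    Proteins with known abundance are sorted ascending and split into
    ``n_bins`` bins of equal count; when the count does not divide evenly
    the remainder goes to the lowest-abundance bins (logged).  Reports per
    bin the fraction of proteins with at least one confirmed interaction,
    alongside the overall fraction as the uniform reference.
    """
    known = annotations.dropna(subset=["abundance"]).sort_values(
        ["abundance", "protein"], kind="mergesort").reset_index(drop=True)
    n = len(known)
    if n < n_bins:
        raise ValueError(f"{n} proteins with abundance < {n_bins} bins")
    base, rem = divmod(n, n_bins)
    sizes = [base + 1 if i < rem else base for i in range(n_bins)]
    if rem:
        logger.info("abundance binning: remainder %d assigned to lowest bins", rem)
    is_spi = known["protein"].isin(spi_queries).to_numpy()
    rows, start = [], 0
    for b, sz in enumerate(sizes):
        sl = slice(start, start + sz)
        rows.append({
            "bin": b, "n_proteins": sz,
            "abundance_min": float(known["abundance"].iloc[sl].min()),
            "abundance_max": float(known["abundance"].iloc[sl].max()),
            "n_spi": int(is_spi[sl].sum()),
            "spi_fraction": float(is_spi[sl].mean()),
        })
        start += sz
    out = pd.DataFrame(rows)
    out["expected_fraction"] = float(is_spi.mean())
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(in_group: tuple[int, int],
                      background: tuple[int, int]) -> tuple[float, float, bool]:
    """One-sided (greater) Fisher exact test on [[a, b], [c, d]].

    ``in_group`` = (hits, non-hits) inside the group, ``background`` =
    (hits, non-hits) outside.  Returns (odds_ratio, p, haldane_flag); the
    sample odds ratio uses the Haldane +0.5 correction when any cell is 0.
    """
    a, b = in_group
    c, d = background
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("all table margins must be positive")
    _, p = stats.fisher_exact(table, alternative="greater")
    flagged = bool((table == 0).any())
    if flagged:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c)
    return float(odds), float(p), flagged


def term_enrichment(gene_set: set[str], annotation_sets: dict[str, set[str]],
                    universe: set[str]) -> pd.DataFrame:
    """Upper hypergeometric tail per annotation term, BH-adjusted.

    Terms with zero overlap are reported with p = 1.  ``gene_set`` and
    every annotation set must be subsets of the universe.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not gene_set <= universe:
        raise ValueError("gene set is not a subset of the universe")
    N, n = len(universe), len(gene_set)
    rows = []
    for term, members in annotation_sets.items():
        members = set(members)
        if not members <= universe:
            raise ValueError(f"annotation set {term!r} is not a subset of the universe")
        K = len(members)
        k = len(gene_set & members)
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "overlap": k, "term_size": K,
                     "set_size": n, "universe_size": N, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = benjamini_hochberg(out["p"].to_numpy()) if len(out) else []
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# interaction density
# ---------------------------------------------------------------------------

@dataclass
class DensityResult:
    curve: pd.DataFrame     # k, density, null_mean, null_sd, z
    k_star: int | None
    p_value: float
    n_perm: int


def interaction_density_rank(
    ranking: list[str],
    network: InteractionNetwork,
    n_perm: int = 199,
    seed: int = 0,
    k_schedule: np.ndarray | None = None,
) -> DensityResult:
    """Known-interaction density among the top-k of a score ranking.

    d(k) = 2 |edges among the top k| / (k (k-1)) on a log-spaced k schedule.
    The null shuffles the ranking ``n_perm`` times (seeded); k* maximises
    the standardized excess z(k) = (d - null mean) / null sd.  Because k* is
    selected by maximizing over the schedule, the empirical p compares the
    observed z(k*) against each permutation's own maximum over k (a
    max-statistic null), keeping p calibrated under random rankings:
    p = (1 + #{permutations with max_k z_perm(k) >= z(k*)}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    pos = {p: i for i, p in enumerate(ranking)}
    n = len(ranking)
    edges = [(pos[a], pos[b]) for a, b in network.edge_set() if a in pos and b in pos]
    if k_schedule is None:
        k_schedule = np.unique(np.round(np.geomspace(2, n, num=min(n, 60))).astype(int))
    ks = np.asarray(k_schedule, dtype=int)
    ks = ks[ks >= 2]
    denom = ks * (ks - 1.0)

    def densities(emax_sorted: np.ndarray) -> np.ndarray:
        counts = np.searchsorted(emax_sorted, ks, side="left")
        return 2.0 * counts / denom

    if not edges:
        curve = pd.DataFrame({"k": ks, "density": 0.0, "null_mean": 0.0,
                              "null_sd": 0.0, "z": 0.0})
        return DensityResult(curve, None, 1.0, n_perm)

    eu = np.array([e[0] for e in edges])
    ev = np.array([e[1] for e in edges])
    obs = densities(np.sort(np.maximum(eu, ev)))

    null = np.empty((n_perm, ks.size))
    for p_idx in range(n_perm):
        perm = rng.permutation(n)
        null[p_idx] = densities(np.sort(np.maximum(perm[eu], perm[ev])))
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(null_sd > 0, (obs - null_mean) / null_sd, -np.inf)
        z_null = np.where(null_sd > 0, (null - null_mean) / null_sd, -np.inf)
    if np.all(~np.isfinite(z)):
        k_star_idx = int(np.argmax(obs))
    else:
        k_star_idx = int(np.argmax(z))
    k_star = int(ks[k_star_idx])
    null_max = z_null.max(axis=1)
    p = (1 + int(np.sum(null_max >= z[k_star_idx]))) / (n_perm + 1)
    curve = pd.DataFrame({"k": ks, "density": obs, "null_mean": null_mean,
                          "null_sd": null_sd, "z": z})
    return DensityResult(curve, k_star, float(p), n_perm)


# ---------------------------------------------------------------------------
# headline summary
# ---------------------------------------------------------------------------

def headline_proportions(counts: dict[str, int]) -> dict[str, dict]:
    """Headline proportions with explicit numerator/denominator provenance.

    ``counts`` supplies the raw tallies (from screen reports or from this
    pipeline's own outputs); every derived figure records which counts it
    divided.  Undefined ratios (zero/missing denominator) are reported as
    ``None``, never as 0.  Percentages round half away from zero to the
    printed precision.
    """
    def ratio(num_key: str, den_key: str, scale: float, ndigits: int):
        num, den = counts.get(num_key), counts.get(den_key)
        if num is None or not den:
            return {"value": None, "numerator": num, "denominator": den}
        return {"value": round_half_away(scale * num / den, ndigits),
                "numerator": num, "denominator": den}

    return {
        "benign_pct": ratio("benign_combinations", "total_combinations", 100.0, 0),
        "colocalized_pct": ratio("colocalized", "scorable_cross_compartment", 100.0, 0),
        "same_compartment_pct": ratio("same_compartment", "scored_combinations", 100.0, 0),
        "mean_spis_per_query": ratio("total_spis", "spi_queries", 1.0, 1),
        "human_homolog_pct": ratio("spi_queries_with_human_homolog", "spi_queries", 100.0, 0),
        "diploid_reproduced_pct": ratio("diploid_reproduced", "nonfrequent_group", 100.0, 0),
    }


def summary_stats(
    spi_calls: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    suppression: pd.DataFrame | None = None,
    counts: dict[str, int] | None = None,
) -> dict[str, dict]:
    """Compute headline proportions from pipeline outputs and/or raw counts.

    Data inputs fill any count not already given in ``counts``: confirmed
    calls give total SPIs and SPI queries, annotations give the
    human-homolog tally over SPI queries, and a suppression classification
    gives the dominant (diploid-reproduced) fraction.
    """
    counts = dict(counts or {})
    if spi_calls is not None:
        confirmed = spi_calls[spi_calls["confirmed"] == True]  # noqa: E712
        counts.setdefault("total_spis", int(len(confirmed)))
        counts.setdefault("spi_queries", int(confirmed["query"].nunique()))
    if annotations is not None and spi_calls is not None:
        confirmed = spi_calls[spi_calls["confirmed"] == True]  # noqa: E712
        queries = set(confirmed["query"])
        hom = annotations.set_index("protein")["human_homolog"]
        known = [q for q in queries if q in hom.index]
        counts.setdefault("spi_queries_with_human_homolog", int(hom.loc[known].sum()))
    if suppression is not None:
        called = suppression[suppression["classification"] != "no_spi"]
        counts.setdefault("nonfrequent_group", int(len(called)))
        counts.setdefault("diploid_reproduced",
                          int((called["classification"] == "dominant").sum()))
    return headline_proportions(counts)


def write_summary(report: dict[str, dict], path) -> None:
    rows = []
    for key, item in report.items():
        rows.append({"statistic": key, "value": item["value"],
                     "numerator": item["numerator"], "denominator": item["denominator"]})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")
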