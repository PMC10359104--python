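"""Permutation comparison of group networks across the density sweep.

Under the null of no group difference the exchangeable unit is the animal:
each permutation shuffles the animals' group labels within the pooled
two-group sample (preserving group sizes) and recomputes the full network
pipeline — residualize, correlate, remove negatives, threshold, measure —
exactly as for the observed labelling.  TBV residualization is fit once on
the pooled sample, since the adjustment is label-free.  One relabelling
drives the whole density sweep, preserving the cross-density dependence
that the consecutive-threshold significance rule exploits.

Empirical two-tailed p-values use the add-one rule on absolute differences,
p = (1 + #{|null| >= |observed|}) / (1 + N), which can never return 0.  A
group difference is declared significant only when p < alpha at ``run_min``
(default 5) or more consecutive density thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .scn_graph import DEFAULT_DENSITIES, edge_count_at_density, rank_edges
from .volumetrics import VolumeTable, residualize_all

__all__ = [
    "DensityProfile",
    "permute_groups",
    "empirical_p",
    "consecutive_run_rule",
    "compare_metric",
    "compare_degree",
    "GLOBAL_METRICS",
]

GLOBAL_METRICS = ("modularity", "transitivity", "mean_distance")


@dataclass
class DensityProfile:
    """One metric's group difference across the density sweep.

    ``observed`` is the group-A-minus-group-B difference per density;
    ``p`` the per-density empirical two-tailed p-value; ``significant``
    whether any run of >= ``run_min`` consecutive densities has p < alpha,
    with the qualifying density intervals in ``runs``.
    """

    metric: str
    node: str  # region name, or "global"
    densities: tuple[float, ...]
    observed: np.ndarray
    p: np.ndarray
    significant: bool
    runs: list[tuple[float, float]]
    n_perm: int
    null_diffs: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        in_run = np.zeros(len(self.densities), dtype=bool)
        for lo, hi in self.runs:
            for i, d in enumerate(self.densities):
                if lo - 1e-9 <= d <= hi + 1e-9:
                    in_run[i] = True
        return pd.DataFrame(
            {
                "metric": self.metric,
                "node": self.node,
                "density": list(self.densities),
                "observed_diff": self.observed,
                "p": self.p,
                "in_significant_run": in_run,
            }
        )


def _permutation_masks(n: int, n_a: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean (n_perm, n) masks selecting the animals relabelled as group A."""
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.permutation(n)[:n_a]] = True
    return masks


def permute_groups(
    table: VolumeTable,
    groups: tuple[str, str],
    n_perm: int,
    seed: int = 0,
) -> Iterator[VolumeTable]:
    """Yield group-label permutations of the pooled two-group table.

    Each draw shuffles which animals carry which label while preserving the
    group sizes.  Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    sub = table.subset(groups)
    n = len(sub.frame)
    if n < 8:
        raise ValueError(
            f"pooled sample of {n} animals is too small for stable correlations (need >= 8)"
        )
    n_a = int((sub.frame["group"] == groups[0]).sum())
    rng = np.random.default_rng(seed)
    for mask in _permutation_masks(n, n_a, n_perm, rng):
        frame = sub.frame.copy()
        frame["group"] = np.where(mask, groups[0], groups[1])
        yield VolumeTable(frame, sub.group_order)


def empirical_p(observed: float, null_sample: Sequence[float]) -> float:
    """Add-one two-tailed empirical p on absolute differences.

    Missing (NaN) null values are dropped with the denominator reduced; if
    every null value is missing the p-value is undefined (NaN), which the
    run rule treats as non-significant.
    """
    null = np.asarray(null_sample, dtype=float)
    if null.size == 0:
        raise ValueError("null sample is empty")
    if not np.isfinite(observed):
        raise ValueError("observed value must be finite")
    null = null[~np.isnan(null)]
    if null.size == 0:
        return float("nan")
    return float((1 + np.sum(np.abs(null) >= abs(observed))) / (1 + null.size))


def consecutive_run_rule(
    p_values: Sequence[float],
    alpha: float = 0.05,
    run_min: int = 5,
    densities: Sequence[float] | None = None,
) -> tuple[bool, list[tuple[float, float]]]:
    """Significance = p < alpha at >= run_min consecutive thresholds.

    Returns the overall verdict and all maximal qualifying runs as
    (first, last) density intervals (indices if ``densities`` is omitted).
    NaN p-values break runs.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if densities is None:
        dens = np.arange(p.size, dtype=float)
    else:
        dens = np.asarray(densities, dtype=float)
        if dens.size != p.size:
            raise ValueError("densities and p-values differ in length")
    below = np.nan_to_num(p, nan=1.0) < alpha
    runs: list[tuple[float, float]] = []
    start = None
    for i, b in enumerate(np.append(below, False)):
        if b and start is None:
            start = i
        elif not b and start is not None:
            if i - start >= run_min:
                runs.append((float(dens[start]), float(dens[i - 1])))
            start = None
    return bool(runs), runs


# ---------------------------------------------------------------------------
# metric sweeps


def _degree_sweep(
    resid: np.ndarray, regions: Sequence[str], ks: np.ndarray
) -> np.ndarray:
    """Degree of every node at every density for one group's residuals.

    The ranked positive edges are nested across densities, so each
    density's degrees come from a prefix of a single ranking.
    """
    r = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(r, 0.0)
    r[r < 0] = 0.0
    ii, jj = rank_edges(r, regions)
    n = len(regions)
    out = np.empty((len(ks), n))
    for d, k in enumerate(ks):
        k = min(int(k), len(ii))
        out[d] = np.bincount(ii[:k], minlength=n) + np.bincount(jj[:k], minlength=n)
    return out


def _global_sweep(
    resid: np.ndarray,
    regions: Sequence[str],
    ks: np.ndarray,
    metric: str,
    steps: int,
) -> np.ndarray:
    r = np.corrcoef(resid, rowvar=False)
    np.fill_diagonal(r, 0.0)
    r[r < 0] = 0.0
    ii, jj = rank_edges(r, regions)
    n = len(regions)
    out = np.empty(len(ks))
    for d, k in enumerate(ks):
        k = min(int(k), len(ii))
        if k == 0:
            out[d] = np.nan
            continue
        g = ig.Graph(n, list(zip(ii[:k].tolist(), jj[:k].tolist())))
        if metric == "transitivity":
            out[d] = g.transitivity_undirected(mode="zero")
        elif metric == "mean_distance":
            out[d] = g.average_path_length(directed=False, unconn=True)
        elif metric == "modularity":
            membership = g.community_walktrap(steps=steps).as_clustering().membership
            out[d] = g.modularity(membership)
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def _sweep(resid, regions, ks, metric, steps):
    if metric == "degree":
        return _degree_sweep(resid, regions, ks)
    return _global_sweep(resid, regions, ks, metric, steps)


def _empirical_p_array(observed: np.ndarray, nulls: np.ndarray) -> np.ndarray:
    """Vectorized add-one two-tailed p; NaN nulls dropped per entry."""
    absn = np.abs(nulls)
    hits = np.nansum(absn >= np.abs(observed)[None], axis=0)
    valid = np.sum(~np.isnan(nulls), axis=0)
    with np.errstate(invalid="ignore"):
        p = (1.0 + hits) / (1.0 + valid)
    p = np.where(valid == 0, np.nan, p)
    return np.where(np.isnan(observed), np.nan, p)


def _prepare(table, groups, densities):
    sub = table.subset(groups)
    n = len(sub.frame)
    if n < 8:
        raise ValueError(
            f"pooled sample of {n} animals is too small for stable correlations (need >= 8)"
        )
    resid = residualize_all(sub).to_numpy()
    mask_obs = (sub.frame["group"] == groups[0]).to_numpy()
    regions = sub.regions
    ks = np.array([edge_count_at_density(d, len(regions)) for d in densities])
    return resid, mask_obs, regions, ks


def _profile_from(metric, node, densities, observed, nulls, n_perm, alpha, run_min,
                  keep_null=False) -> DensityProfile:
    p = _empirical_p_array(observed, nulls)
    significant, runs = consecutive_run_rule(p, alpha, run_min, densities)
    return DensityProfile(
        metric=metric, node=node, densities=tuple(densities),
        observed=observed, p=p, significant=significant, runs=runs,
        n_perm=n_perm, null_diffs=nulls if keep_null else None,
    )


def compare_degree(
    table: VolumeTable,
    groups: tuple[str, str],
    densities: Sequence[float] = DEFAULT_DENSITIES,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    run_min: int = 5,
) -> dict[str, DensityProfile]:
    """Degree-centrality comparison for every node at once.

    Shares the permutation draws across densities and nodes, so per-node
    profiles are mutually consistent.  Returns region -> DensityProfile of
    group-A-minus-group-B degree differences.
    """
    resid, mask_obs, regions, ks = _prepare(table, groups, densities)
    diff = lambda m: _degree_sweep(resid[m], regions, ks) - _degree_sweep(resid[~m], regions, ks)
    observed = diff(mask_obs)
    rng = np.random.default_rng(seed)
    masks = _permutation_masks(len(mask_obs), int(mask_obs.sum()), n_perm, rng)
    nulls = np.stack([diff(m) for m in masks])  # (n_perm, D, R)
    return {
        region: _profile_from(
            "degree", region, densities, observed[:, i], nulls[:, :, i],
            n_perm, alpha, run_min,
        )
        for i, region in enumerate(regions)
    }


def compare_metric(
    table: VolumeTable,
    groups: tuple[str, str],
    metric: str,
    node: str | None = None,
    densities: Sequence[float] = DEFAULT_DENSITIES,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    run_min: int = 5,
    walktrap_steps: int = 4,
    keep_null: bool = False,
) -> DensityProfile:
    """Permutation comparison of one metric across the density sweep.

    ``metric`` is ``"degree"`` (requires ``node``) or one of the global
    measures ``"modularity"`` (the relabelled network is re-partitioned by
    Walktrap on every draw — the partition is part of the statistic),
    ``"transitivity"`` and ``"mean_distance"``.  Densities at which a
    metric is undefined (e.g. an edgeless network) contribute NaN and are
    dropped from the null with the add-one denominator reduced.
    """
    if metric == "degree":
        if node is None:
            raise ValueError("degree comparison requires a node (or use compare_degree)")
        profiles = compare_degree(table, groups, densities, n_perm, seed, alpha, run_min)
        if node not in profiles:
            raise ValueError(f"unknown region {node!r}")
        return profiles[node]
    if metric not in GLOBAL_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    resid, mask_obs, regions, ks = _prepare(table, groups, densities)
    sweep = lambda m: _global_sweep(resid[m], regions, ks, metric, walktrap_steps)
    observed = sweep(mask_obs) - sweep(~mask_obs)
    rng = np.random.default_rng(seed)
    masks = _permutation_masks(len(mask_obs), int(mask_obs.sum()), n_perm, rng)
    nulls = np.stack([sweep(m) - sweep(~m) for m in masks])
    return _profile_from(metric, "global", densities, observed, nulls,
                         n_perm, alpha, run_min, keep_null)
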