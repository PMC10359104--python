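"""Structural covariance networks: construction, thresholding, graph measures.

A group's structural covariance network has one node per region of interest
and edges reflecting the across-animal Pearson correlation of
TBV-residualized regional volumes within that group.  Negative correlations
are zeroed, and a family of unweighted graphs is obtained by retaining the
top d-fraction of strongest positive correlations at each density d of a
sweep (default 0.05-0.40 in 0.01 steps), so compared networks always have
equal edge counts.  Node- and network-level measures (degree, transitivity,
mean shortest-path distance, Newman-Girvan modularity), Walktrap community
detection, and Guimera-Amaral hub cartography (within-community degree
z-score and participation coefficient) are computed on those graphs via
python-igraph.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .volumetrics import VolumeTable, residualize_all

__all__ = [
    "CovarianceMatrix",
    "ThresholdedNetwork",
    "CommunityCartography",
    "build_covariance",
    "threshold_at_density",
    "degree",
    "mean_distance",
    "transitivity",
    "modularity",
    "walktrap_communities",
    "cartography",
    "DEFAULT_DENSITIES",
]

logger = logging.getLogger(__name__)

DEFAULT_DENSITIES: tuple[float, ...] = tuple(
    round(0.05 + 0.01 * i, 2) for i in range(36)
)  # 0.05 .. 0.40


@dataclass
class CovarianceMatrix:
    """Unsigned structural covariance matrix for one group.

    ``r`` holds Pearson correlations of TBV-residualized volumes with
    negative entries set to zero and a zero diagonal (self-correlations are
    never edges).
    """

    group: str
    regions: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        r = np.asarray(self.r, dtype=float)
        n = len(self.regions)
        if r.shape != (n, n):
            raise ValueError("matrix shape does not match region list")
        if not np.allclose(r, r.T):
            raise ValueError("covariance matrix must be symmetric")
        if (r < 0).any() or (r > 1).any():
            raise ValueError("entries must lie in [0, 1] after negative removal")
        if np.diag(r).any():
            raise ValueError("diagonal must be zero")
        self.r = r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=list(self.regions), columns=list(self.regions))


@dataclass
class ThresholdedNetwork:
    """Unweighted, undirected graph of the top-density correlations."""

    density: float
    regions: tuple[str, ...]
    adjacency: np.ndarray
    requested_edges: int = 0
    shortfall: bool = False

    def __post_init__(self) -> None:
        self.regions = tuple(self.regions)
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T) or np.diag(a).any():
            raise ValueError("adjacency must be symmetric with empty diagonal")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def edges(self) -> list[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        return [(self.regions[i], self.regions[j]) for i, j in zip(ii, jj)]

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph.Adjacency(self.adjacency.tolist(), mode="undirected")
        g.vs["name"] = list(self.regions)
        return g


@dataclass
class CommunityCartography:
    """A partition with optional per-node hub cartography.

    ``z_within`` is the within-community degree z-score (standardized over
    each community with population SD; 0 where the SD is 0 or the community
    is a singleton).  ``participation`` is 1 minus the sum of squared
    fractions of a node's links per community (0 for isolated nodes).
    ``hub_label`` classifies each node as provincial (high z, low P),
    connector (high z, high P) or none.
    """

    regions: tuple[str, ...]
    membership: tuple[int, ...]
    modularity: float
    z_within: np.ndarray | None = None
    participation: np.ndarray | None = None
    hub_label: tuple[str, ...] | None = None
    most_prominent: dict[str, dict[int, str]] = field(default_factory=dict)
    note: str = ""

    @property
    def partition(self) -> dict[str, int]:
        return dict(zip(self.regions, self.membership))

    def to_frame(self) -> pd.DataFrame:
        data = {"region": list(self.regions), "community": list(self.membership)}
        if self.z_within is not None:
            data["z_within"] = list(self.z_within)
        if self.participation is not None:
            data["participation"] = list(self.participation)
        if self.hub_label is not None:
            data["hub"] = list(self.hub_label)
        return pd.DataFrame(data)


def build_covariance(
    table: VolumeTable,
    group: str,
    residuals: pd.DataFrame | None = None,
) -> CovarianceMatrix:
    """Correlate TBV-residualized volumes across a group's animals.

    By default residualization is fit within the group's own animals; a
    precomputed residual frame (e.g. pooled-sample residuals shared by a
    permutation scheme) can be supplied instead.  Negative correlations are
    zeroed and the diagonal is cleared.
    """
    sub = table.subset([group])
    if len(sub.frame) < 4:
        raise ValueError(f"group {group!r} has fewer than 4 animals")
    raw_sds = sub.volumes().std(axis=0)
    if (raw_sds == 0).any():
        flat = [r for r, s in zip(table.regions, raw_sds) if s == 0]
        raise ValueError(f"zero residual variance within group {group!r}: {flat}")
    if residuals is None:
        resid = residualize_all(sub).to_numpy()
    else:
        resid = residuals.loc[sub.frame.index, list(table.regions)].to_numpy(float)
    sds = resid.std(axis=0)
    if (sds <= 1e-10 * max(1.0, np.abs(resid).max())).any():
        flat = [r for r, s in zip(table.regions, sds) if s <= 1e-10 * max(1.0, np.abs(resid).max())]
        raise ValueError(f"zero residual variance within group {group!r}: {flat}")
    r = np.corrcoef(resid, rowvar=False)
    r = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return CovarianceMatrix(group=group, regions=table.regions, r=r)


def edge_count_at_density(density: float, n_nodes: int) -> int:
    """Half-up rounding of density x n(n-1)/2 possible edges."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(density * n_pairs + 0.5))


def rank_edges(r: np.ndarray, regions: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Positive entries of the upper triangle, strongest first.

    Ties are broken by the lexicographic order of the (sorted) region-name
    pair so thresholding is deterministic across platforms.  Returns the
    (i, j) index arrays of the ranked edges.
    """
    n = len(regions)
    iu, ju = np.triu_indices(n, 1)
    vals = r[iu, ju]
    keep = vals > 0
    iu, ju, vals = iu[keep], ju[keep], vals[keep]
    name_rank = {name: k for k, name in enumerate(sorted(regions))}
    a_key = np.array([min(name_rank[regions[i]], name_rank[regions[j]]) for i, j in zip(iu, ju)])
    b_key = np.array([max(name_rank[regions[i]], name_rank[regions[j]]) for i, j in zip(iu, ju)])
    order = np.lexsort((b_key, a_key, -vals))
    return iu[order], ju[order]


def threshold_at_density(cov: CovarianceMatrix, density: float) -> ThresholdedNetwork:
    """Keep the k strongest positive correlations as unweighted edges.

    k = round(density x possible pairs), half-up.  If fewer than k positive
    entries exist the network is built from all of them and the shortfall is
    flagged and logged.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = len(cov.regions)
    k = edge_count_at_density(density, n)
    ii, jj = rank_edges(cov.r, cov.regions)
    shortfall = len(ii) < k
    if shortfall:
        logger.warning(
            "density %.2f requests %d edges but only %d positive correlations "
            "are available (group %s)", density, k, len(ii), cov.group,
        )
    ii, jj = ii[:k], jj[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii, jj] = 1
    adj[jj, ii] = 1
    return ThresholdedNetwork(
        density=density, regions=cov.regions, adjacency=adj,
        requested_edges=k, shortfall=shortfall,
    )


def degree(net: ThresholdedNetwork) -> np.ndarray:
    """Per-node edge count."""
    return net.adjacency.sum(axis=0).astype(int)


def mean_distance(net: ThresholdedNetwork) -> float | None:
    """Average shortest-path length over reachable node pairs.

    Unreachable pairs are excluded rather than treated as infinite; a
    network with no edges has no reachable pairs and returns None.
    """
    if net.n_edges == 0:
        logger.info("mean distance undefined: network at density %.2f has no edges", net.density)
        return None
    return float(net.to_igraph().average_path_length(directed=False, unconn=True))


def transitivity(net: ThresholdedNetwork) -> float:
    """Global transitivity: 3 x triangles / connected triples (0 if no triples)."""
    return float(net.to_igraph().transitivity_undirected(mode="zero"))


def modularity(net: ThresholdedNetwork, partition: Mapping[str, int] | Sequence[int]) -> float | None:
    """Newman-Girvan modularity Q of a partition; None on an empty network."""
    membership = _as_membership(net.regions, partition)
    if net.n_edges == 0:
        logger.info("modularity undefined: network at density %.2f has no edges", net.density)
        return None
    return float(net.to_igraph().modularity(membership))


def _as_membership(regions: Sequence[str], partition) -> list[int]:
    if isinstance(partition, Mapping):
        missing = [r for r in regions if r not in partition]
        if missing:
            raise ValueError(f"partition does not cover nodes: {missing}")
        raw = [partition[r] for r in regions]
    else:
        raw = list(partition)
        if len(raw) != len(regions):
            raise ValueError("membership length does not match node count")
    ids = {c: i for i, c in enumerate(dict.fromkeys(raw))}
    return [ids[c] for c in raw]


def walktrap_communities(net: ThresholdedNetwork, steps: int = 4) -> CommunityCartography:
    """Random-walk (Walktrap) communities cut at maximum modularity.

    Agglomerates nodes by short random-walk distance (walk length
    ``steps``) and cuts the resulting dendrogram at the maximum-modularity
    level.  Isolated nodes become singleton communities.  An edgeless
    network yields all singletons with Q = 0 by convention.
    """
    if net.n_edges == 0:
        return CommunityCartography(
            regions=net.regions,
            membership=tuple(range(net.n_nodes)),
            modularity=0.0,
            note="empty network: singleton communities, Q = 0 by convention",
        )
    g = net.to_igraph()
    clustering = g.community_walktrap(steps=steps).as_clustering()
    membership = tuple(int(c) for c in clustering.membership)
    q = modularity(net, membership)
    return CommunityCartography(regions=net.regions, membership=membership, modularity=q)


def cartography(
    net: ThresholdedNetwork,
    partition: Mapping[str, int] | Sequence[int],
    z_hub_min: float = 1.0,
    p_connector_min: float = 0.30,
) -> CommunityCartography:
    """Hub cartography: within-community degree z and participation coefficient.

    z_i standardizes the within-community degree over the node's own
    community (population SD; z = 0 where the SD is 0).  P_i = 1 - sum_c
    (k_ic / k_i)^2 over communities c (0 for isolated nodes).  A node is a
    provincial hub if z >= z_hub_min and P < p_connector_min, a connector
    hub if z >= z_hub_min and P >= p_connector_min.  ``most_prominent``
    records, per community, the highest-z provincial hub and the highest-P
    connector hub.
    """
    membership = np.array(_as_membership(net.regions, partition))
    adj = net.adjacency
    n = net.n_nodes
    comms = np.unique(membership)
    # links from node i into community c
    links = np.zeros((n, len(comms)))
    for ci, c in enumerate(comms):
        links[:, ci] = adj[:, membership == c].sum(axis=1)
    kappa = links[np.arange(n), np.searchsorted(comms, membership)]
    k_total = adj.sum(axis=1).astype(float)

    z = np.zeros(n)
    for c in comms:
        mask = membership == c
        if mask.sum() < 2:
            continue
        mu, sd = kappa[mask].mean(), kappa[mask].std()
        if sd > 0:
            z[mask] = (kappa[mask] - mu) / sd
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(k_total[:, None] > 0, links / np.maximum(k_total[:, None], 1), 0.0)
    participation = np.where(k_total > 0, 1.0 - (frac**2).sum(axis=1), 0.0)

    labels = []
    for zi, pi in zip(z, participation):
        if zi >= z_hub_min and pi >= p_connector_min:
            labels.append("connector")
        elif zi >= z_hub_min:
            labels.append("provincial")
        else:
            labels.append("none")

    most: dict[str, dict[int, str]] = {"provincial": {}, "connector": {}}
    for c in comms:
        idx = np.where(membership == c)[0]
        prov = [i for i in idx if labels[i] == "provincial"]
        conn = [i for i in idx if labels[i] == "connector"]
        if prov:
            most["provincial"][int(c)] = net.regions[max(prov, key=lambda i: z[i])]
        if conn:
            most["connector"][int(c)] = net.regions[max(conn, key=lambda i: participation[i])]

    q = modularity(net, list(membership)) if net.n_edges else 0.0
    return CommunityCartography(
        regions=net.regions,
        membership=tuple(int(c) for c in membership),
        modularity=q if q is not None else 0.0,
        z_within=z,
        participation=participation,
        hub_label=tuple(labels),
        most_prominent=most,
    )
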