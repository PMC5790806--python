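"""Social graphs from friendship nominations: construction, geodesic distances, summary statistics.

A roster-based nomination survey yields a directed binary matrix (row =
nominator, column = nominee).  The analysis graph is undirected and, by
default, keeps only *reciprocated* ties: an edge joins i and j only when
each nominated the other.  Social distance between two people is the
geodesic (shortest-path) distance on that graph, with distances beyond a
cap — and unreachable pairs — collapsed into a single top category
(default "4+").
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "UNREACHABLE",
    "NominationMatrix",
    "DistanceResult",
    "NetworkStats",
    "build_graph",
    "geodesic_distances",
    "network_stats",
]

#: Sentinel used in distance matrices for pairs with no connecting path.
UNREACHABLE = -1

TieRule = Literal["reciprocal", "any"]


@dataclasses.dataclass(frozen=True)
class NominationMatrix:
    """Directed binary who-nominated-whom matrix with subject identifiers."""

    entries: np.ndarray
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries)
        n = len(self.subject_ids)
        if entries.shape != (n, n):
            raise ValueError(
                f"nomination matrix shape {entries.shape} does not match "
                f"{n} subject ids"
            )
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("nomination matrix entries must be 0 or 1")
        if np.diagonal(entries).any():
            raise ValueError("self-nominations are not allowed (nonzero diagonal)")
        object.__setattr__(self, "entries", entries.astype(np.int8))
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclasses.dataclass(frozen=True)
class DistanceResult:
    """All-pairs geodesic distances plus the capped social-distance category.

    ``distances`` holds BFS shortest-path lengths with :data:`UNREACHABLE`
    for disconnected pairs; ``capped_category`` collapses every distance
    ≥ cap (and every unreachable pair) into the cap category.
    """

    distances: np.ndarray
    capped_category: np.ndarray
    cap: int
    subject_ids: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class NetworkStats:
    density_reciprocal: float
    density_any: float
    total_reciprocity: float
    dyad_reciprocity: float
    diameter: int
    connected: bool
    out_degree_stats: dict[str, float]
    in_degree_stats: dict[str, float]


def build_graph(nominations: NominationMatrix, tie_rule: TieRule = "reciprocal") -> nx.Graph:
    """Build the undirected social graph under the given tie rule.

    ``reciprocal`` keeps an edge i–j only when both directed nominations
    exist; ``any`` keeps it when at least one does.
    """
    a = nominations.entries
    if tie_rule == "reciprocal":
        adj = a & a.T
    elif tie_rule == "any":
        adj = a | a.T
    else:
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(nominations.subject_ids)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    ids = nominations.subject_ids
    g.add_edges_from((ids[i], ids[j]) for i, j in zip(ii, jj))
    return g


def geodesic_distances(graph: nx.Graph, cap: int = 4) -> DistanceResult:
    """All-pairs shortest-path (BFS) distances on an undirected social graph.

    Unreachable pairs get :data:`UNREACHABLE` in ``distances`` and fall into
    the top (cap) category of ``capped_category``.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes to compute pairwise distances")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    nodes = list(graph.nodes)
    index = {v: k for k, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), UNREACHABLE, dtype=np.int64)
    np.fill_diagonal(dist, 0)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        i = index[src]
        for dst, d in lengths.items():
            dist[i, index[dst]] = d
    capped = np.where(dist == UNREACHABLE, cap, np.minimum(dist, cap))
    np.fill_diagonal(capped, 0)
    return DistanceResult(
        distances=dist,
        capped_category=capped.astype(np.int64),
        cap=cap,
        subject_ids=tuple(str(v) for v in nodes),
    )


def _degree_stats(deg: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(deg)),
        "sd": float(np.std(deg, ddof=1)) if deg.size > 1 else 0.0,
        "median": float(np.median(deg)),
        "min": float(np.min(deg)),
        "max": float(np.max(deg)),
    }


def network_stats(nominations: NominationMatrix) -> NetworkStats:
    """Descriptive statistics of a nomination network.

    density = |E| / C(N,2) for each undirected graph (reciprocal-tie and
    any-tie rules).  total_reciprocity is the probability that a directed
    nomination is returned; dyad_reciprocity is the probability that a dyad
    with at least one tie has a mutual tie.  The identity
    dyad_reciprocity = density_reciprocal / density_any holds exactly.
    Reciprocities are NaN for an empty network.  Diameter is the maximum
    finite geodesic on the reciprocal-tie graph (disconnected components
    are ignored, flagged via ``connected``).
    """
    a = nominations.entries
    n = nominations.n_subjects
    if n < 2:
        raise ValueError("need at least 2 subjects")
    n_pairs = n * (n - 1) // 2
    mutual = int(np.triu(a & a.T, k=1).sum())
    any_tie = int(np.triu(a | a.T, k=1).sum())
    n_directed = int(a.sum())
    density_rec = mutual / n_pairs
    density_any = any_tie / n_pairs
    total_rec = 2 * mutual / n_directed if n_directed > 0 else float("nan")
    dyad_rec = mutual / any_tie if any_tie > 0 else float("nan")

    g_rec = build_graph(nominations, "reciprocal")
    connected = nx.is_connected(g_rec) if g_rec.number_of_edges() > 0 else False
    dres = geodesic_distances(g_rec) if n >= 2 else None
    finite = dres.distances[dres.distances > 0]
    diameter = int(finite.max()) if finite.size else 0

    return NetworkStats(
        density_reciprocal=density_rec,
        density_any=density_any,
        total_reciprocity=total_rec,
        dyad_reciprocity=dyad_rec,
        diameter=diameter,
        connected=connected,
        out_degree_stats=_degree_stats(a.sum(axis=1)),
        in_degree_stats=_degree_stats(a.sum(axis=0)),
    )


def restrict_distances(dres: DistanceResult, subject_ids: Sequence[str]) -> DistanceResult:
    """Restrict a full-cohort distance result to a subsample of subjects.

    Distances are *not* recomputed on the induced subgraph: geodesics on
    the full network remain valid for any subset of its members (paths may
    run through unsampled individuals).
    """
    index = {v: k for k, v in enumerate(dres.subject_ids)}
    missing = [s for s in subject_ids if s not in index]
    if missing:
        raise KeyError(f"subjects absent from network: {missing}")
    idx = np.array([index[s] for s in subject_ids])
    return DistanceResult(
        distances=dres.distances[np.ix_(idx, idx)],
        capped_category=dres.capped_category[np.ix_(idx, idx)],
        cap=dres.cap,
        subject_ids=tuple(str(s) for s in subject_ids),
    )
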