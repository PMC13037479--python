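"""Protein-sharing genome network: protein clustering, hypergeometric edge
significance, and an in-house Markov Cluster (MCL) partitioner.

The MCL implementation follows the classical scheme: self-loops at the
maximum column weight, column-stochastic normalization, then alternating
expansion (matrix squaring) and inflation (entrywise power + renormalize)
with pruning of entries below ``prune_floor``, until the maximum
entrywise change drops below ``tol``. Clusters are the connected
components of the converged attractor graph. Because MCL never merges
across connected components, the iteration runs per component, which
keeps dense linear algebra tractable on large block-structured graphs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import DataError, GraphError
from .formats_io import HitRecord, stage_log

logger = logging.getLogger("viroturn")

P_FLOOR = 1e-300
WEIGHT_CAP = 300.0


# ---------------------------------------------------------------------------
# Markov clustering


def _gather_components(nodes: Sequence[Hashable], adj: Mapping) -> list[list[Hashable]]:
    seen: set = set()
    components: list[list[Hashable]] = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        components.append(sorted(comp, key=str))
    return components


def _mcl_component(A: np.ndarray, inflation: float, max_iter: int, tol: float,
                   prune_floor: float) -> np.ndarray:
    """Run MCL on one dense symmetric non-negative matrix; returns the converged matrix."""
    n = A.shape[0]
    M = A.astype(float).copy()
    col_max = M.max(axis=0)
    np.fill_diagonal(M, np.where(col_max > 0, col_max, 1.0))
    M /= M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        new = M @ M                 # expansion
        np.power(new, inflation, out=new)   # inflation
        new[new < prune_floor] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        new /= colsum
        change = np.abs(new - M).max()
        M = new
        if change < tol:
            break
    return M


def mcl(
    nodes: Iterable[Hashable],
    edges: Iterable[tuple[Hashable, Hashable, float]],
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    prune_floor: float = 1e-6,
) -> list[list[Hashable]]:
    """Partition a weighted undirected graph with Markov clustering.

    ``edges`` are undirected ``(u, v, weight)`` triples with positive
    weights; if both orientations of a pair appear they must agree
    (:class:`GraphError` otherwise). Isolated nodes become singleton
    clusters. The result is independent of node/edge input order: nodes
    are sorted internally and clusters are returned sorted by
    (descending size, lexicographically smallest member).
    """
    node_list = sorted(set(nodes), key=str)
    weight: dict[tuple[Hashable, Hashable], float] = {}
    adj: dict[Hashable, set] = defaultdict(set)
    known = set(node_list)
    for u, v, w in edges:
        if u not in known or v not in known:
            raise GraphError(f"edge ({u!r}, {v!r}) references an unknown node")
        if u == v:
            continue
        if w <= 0:
            raise GraphError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
        key = (u, v) if str(u) <= str(v) else (v, u)
        if key in weight and abs(weight[key] - w) > 1e-12 * max(1.0, abs(w)):
            raise GraphError(
                f"asymmetric weights for edge {key!r}: {weight[key]} vs {w}"
            )
        weight[key] = w
        adj[u].add(v)
        adj[v].add(u)

    clusters: list[list[Hashable]] = []
    for comp in _gather_components(node_list, adj):
        if len(comp) == 1:
            clusters.append(comp)
            continue
        index = {u: i for i, u in enumerate(comp)}
        A = np.zeros((len(comp), len(comp)))
        for (u, v), w in weight.items():
            if u in index and v in index:
                A[index[u], index[v]] = w
                A[index[v], index[u]] = w
        M = _mcl_component(A, inflation, max_iter, tol, prune_floor)
        # attractor graph: connect i~j when either orientation retains mass
        keep = (M > prune_floor) | (M.T > prune_floor)
        np.fill_diagonal(keep, False)
        sub_adj = {u: {comp[j] for j in np.flatnonzero(keep[i])} for i, u in enumerate(comp)}
        clusters.extend(_gather_components(comp, sub_adj))

    clusters.sort(key=lambda c: (-len(c), str(c[0])))
    return clusters


# ---------------------------------------------------------------------------
# Protein clusters


def protein_similarity_edges(
    hits: Iterable[HitRecord], max_evalue: float = 1e-5
) -> list[tuple[str, str, float]]:
    """Bitscore-weighted protein similarity edges from a hit table.

    Reciprocal hits are collapsed to the maximum bitscore so the graph is
    symmetric by construction.
    """
    best: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.evalue > max_evalue or h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id) if h.query_id <= h.subject_id else (h.subject_id, h.query_id)
        if h.bitscore > best.get(key, 0.0):
            best[key] = h.bitscore
    return [(u, v, w) for (u, v), w in sorted(best.items()) if w > 0]


def cluster_proteins(
    nodes: Iterable[str],
    similarity_edges: Iterable[tuple[str, str, float]],
    inflation: float = 2.0,
    **mcl_kwargs,
) -> dict[str, str]:
    """MCL-partition the protein universe; returns protein_id -> pc_id.

    PC labels are ``PC_00001``... ordered by (descending size, smallest
    member), so the labeling is deterministic.
    """
    parts = mcl(nodes, similarity_edges, inflation=inflation, **mcl_kwargs)
    mapping: dict[str, str] = {}
    for i, members in enumerate(parts, start=1):
        pc_id = f"PC_{i:05d}"
        for m in members:
            mapping[m] = pc_id
    return mapping


# ---------------------------------------------------------------------------
# Hypergeometric edge significance


@lru_cache(maxsize=1_000_000)
def hypergeom_edge(c: int, a: int, b: int, M: int) -> tuple[float, float]:
    """Upper-tail probability of sharing >= c protein clusters by chance.

    ``a`` and ``b`` are the two genomes' PC counts and ``M`` the size of
    the PC universe. Computed in log space:
    ``p = sum_{k=c}^{min(a,b)} C(a,k) C(M-a,b-k) / C(M,b)``.
    Returns ``(p, weight)`` with ``weight = min(-log10(max(p, 1e-300)), 300)``.
    Memoized: a network's edges draw from few distinct (c, a, b, M) combinations.
    """
    if not (0 <= c <= min(a, b) <= M):
        raise ValueError(f"require 0 <= c <= min(a,b) <= M, got c={c}, a={a}, b={b}, M={M}")
    if c == 0:
        return 1.0, 0.0
    ks = np.arange(c, min(a, b) + 1)

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    log_terms = logC(a, ks) + logC(M - a, b - ks) - logC(M, b)
    p = float(np.exp(logsumexp(log_terms)))
    p = min(p, 1.0)
    weight = min(-np.log10(max(p, P_FLOOR)), WEIGHT_CAP)
    return p, float(weight)


# ---------------------------------------------------------------------------
# Genome network


@dataclass
class GenomeNetwork:
    """Genomes as nodes; edges weighted by hypergeometric sharing significance."""

    nodes: list[str]
    edges: list[tuple[str, str, int, float, float]]  # (i, j, shared_pcs, p, weight)
    n_protein_clusters: int = 0


@dataclass
class ViralCluster:
    """One MCL community of the genome network."""

    cluster_id: str
    members: list[str]
    per_library_counts: dict[str, int] = field(default_factory=dict)
    reference_members: list[str] = field(default_factory=list)

    @property
    def n_counted(self) -> int:
        return len(self.members) - len(self.reference_members)


def build_network(
    genome_pcs: Mapping[str, set[str]],
    min_weight: float = 1.0,
    total_pcs: int | None = None,
) -> GenomeNetwork:
    """Hypergeometric protein-sharing network over genomes' PC sets.

    Genomes with zero protein clusters are excluded with a logged
    warning. An edge is kept iff ``weight >= min_weight`` (default 1,
    i.e. p <= 0.1). Node ordering is deterministic (sorted ids).
    """
    nodes = []
    for g in sorted(genome_pcs):
        if genome_pcs[g]:
            nodes.append(g)
        else:
            logger.warning("genome %s has no protein clusters; excluded from network", g)
    M = total_pcs if total_pcs is not None else len(set().union(*genome_pcs.values()) if genome_pcs else set())

    # invert to PC -> genomes to enumerate only pairs that share something
    by_pc: dict[str, list[str]] = defaultdict(list)
    for g in nodes:
        for pc in genome_pcs[g]:
            by_pc[pc].append(g)
    shared: dict[tuple[str, str], int] = defaultdict(int)
    for members in by_pc.values():
        members = sorted(members)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                shared[(members[i], members[j])] += 1

    edges = []
    for (gi, gj), c in sorted(shared.items()):
        p, w = hypergeom_edge(c, len(genome_pcs[gi]), len(genome_pcs[gj]), M)
        if w >= min_weight:
            edges.append((gi, gj, c, p, w))
    stage_log("build_network", len(genome_pcs), len(nodes), edges=len(edges), total_pcs=M)
    return GenomeNetwork(nodes=nodes, edges=edges, n_protein_clusters=M)


def cluster_genomes(
    network: GenomeNetwork,
    inflation: float = 2.0,
    member_library: Mapping[str, str] | None = None,
    reference_ids: Iterable[str] = (),
    **mcl_kwargs,
) -> list[ViralCluster]:
    """MCL-partition the genome network into viral clusters.

    Reference genomes (ids in ``reference_ids``) stay cluster members but
    are excluded from ``per_library_counts``. Clusters are labeled
    ``VC_001``... by decreasing size with lexicographic tie-breaking.
    """
    refs = set(reference_ids)
    member_library = member_library or {}
    if not network.nodes:
        return []
    parts = mcl(
        network.nodes,
        [(u, v, w) for (u, v, _, _, w) in network.edges],
        inflation=inflation,
        **mcl_kwargs,
    )
    clusters = []
    for i, members in enumerate(parts, start=1):
        counts: dict[str, int] = defaultdict(int)
        cluster_refs = []
        for m in members:
            if m in refs:
                cluster_refs.append(m)
            elif member_library:
                if m not in member_library:
                    raise DataError(f"network member {m!r} has no library assignment")
                counts[member_library[m]] += 1
        clusters.append(
            ViralCluster(
                cluster_id=f"VC_{i:03d}",
                members=list(members),
                per_library_counts=dict(counts),
                reference_members=cluster_refs,
            )
        )
    return clusters
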