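"""Marker-protein screening (gp23-like capsid markers, host-linkage filter)
and a neighbor-joining stand-in for marker phylogenies.

The NJ tree is a deliberately simple desk-scale substitute for
maximum-likelihood inference: p-distances on pre-aligned sequences,
classical Q-criterion joins, deterministic tie-breaking.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DataError
from .formats_io import HitRecord, RunConfig

GAP_CHARS = frozenset("-.")


@dataclass(slots=True)
class MarkerHit:
    """Best reference hit of one candidate marker protein."""

    contig_id: str
    protein_id: str
    reference_id: str
    bitscore: float
    evalue: float
    passes: bool


@dataclass(slots=True)
class HostLinkCandidate:
    """Genome-vs-reference comparison for host-linkage screening."""

    query_genome: str
    reference_genome: str
    shared_protein_fraction: float
    mean_aai: float
    mean_coverage: float
    passes: bool = False

    def __post_init__(self) -> None:
        for name in ("shared_protein_fraction", "mean_aai", "mean_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")


def _default_contig(protein_id: str) -> str:
    stem, _, suffix = protein_id.rpartition("_p")
    return stem if stem and suffix.isdigit() else protein_id


def screen_markers(
    hits: Iterable[HitRecord],
    config: RunConfig | None = None,
    protein_to_contig=None,
) -> list[MarkerHit]:
    """Screen proteins for capsid-marker matches at strict printed thresholds.

    One :class:`MarkerHit` per query protein, carrying its best reference
    (max bitscore; ties by smallest e-value, then lexicographic reference
    id). ``passes`` iff ``bitscore > gp23_min_bitscore`` AND
    ``evalue < gp23_max_evalue`` — both strict, exactly as printed.
    """
    config = config or RunConfig()
    to_contig = protein_to_contig or _default_contig
    by_protein: dict[str, list[HitRecord]] = defaultdict(list)
    for h in hits:
        by_protein[h.query_id].append(h)
    out: list[MarkerHit] = []
    for protein_id in sorted(by_protein):
        best = min(by_protein[protein_id], key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        out.append(
            MarkerHit(
                contig_id=to_contig(protein_id),
                protein_id=protein_id,
                reference_id=best.subject_id,
                bitscore=best.bitscore,
                evalue=best.evalue,
                passes=best.bitscore > config.gp23_min_bitscore
                and best.evalue < config.gp23_max_evalue,
            )
        )
    return out


def host_link_filter(
    candidates: Iterable[HostLinkCandidate], config: RunConfig | None = None
) -> list[HostLinkCandidate]:
    """Keep candidates passing all three inclusive thresholds simultaneously
    (shared >= 0.80, AAI >= 0.60, coverage >= 0.95 by default).

    Flags ``passes`` on every candidate in place; returns the passing ones.
    """
    config = config or RunConfig()
    passing = []
    for cand in candidates:
        cand.passes = (
            cand.shared_protein_fraction >= config.host_min_shared
            and cand.mean_aai >= config.host_min_aai
            and cand.mean_coverage >= config.host_min_cov
        )
        if cand.passes:
            passing.append(cand)
    return passing


# ---------------------------------------------------------------------------
# Neighbor-joining stand-in


def p_distance_matrix(sequences: Sequence[tuple[str, str]]) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances (mismatches / shared non-gap positions) on an alignment."""
    names = [name for name, _ in sequences]
    seqs = [seq for _, seq in sequences]
    length = len(seqs[0])
    for name, seq in sequences:
        if len(seq) != length:
            raise DataError(f"sequence {name!r} length {len(seq)} != alignment length {length}")
    arr = np.array([list(s) for s in seqs])
    is_gap = np.isin(arr, list(GAP_CHARS))
    n = len(names)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~(is_gap[i] | is_gap[j])
            total = int(shared.sum())
            if total == 0:
                d = 0.0
            else:
                d = float((arr[i][shared] != arr[j][shared]).sum()) / total
            D[i, j] = D[j, i] = d
    return names, D


def nj_tree(sequences: Sequence[tuple[str, str]]) -> str:
    """Neighbor-joining Newick tree from pre-aligned ``(name, sequence)`` pairs.

    Classical Q-criterion with deterministic tie-breaking (smallest node
    index pair, nodes ordered by sorted input name); negative branch
    lengths are clamped to 0. NJ is exact on additive distance matrices,
    which is the tested guarantee. Requires >= 3 sequences.
    """
    if len(sequences) < 3:
        raise DataError(f"neighbor joining needs >= 3 sequences, got {len(sequences)}")
    ordered = sorted(sequences, key=lambda item: item[0])
    names, D = p_distance_matrix(ordered)
    # active nodes: newick fragment per node; merged nodes get appended
    labels = list(names)
    D = D.copy()
    active = list(range(len(labels)))

    while len(active) > 2:
        n = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (n - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ai, aj = min((int(i), int(j)) for i, j in ties if i < j)
        i_glob, j_glob = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_label = f"({labels[i_glob]}:{li:.6f},{labels[j_glob]}:{lj:.6f})"
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for bk, k_glob in enumerate(active):
            if k_glob in (i_glob, j_glob):
                continue
            new_row[k_glob] = 0.5 * (sub[ai, bk] + sub[aj, bk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        labels.append(new_label)
        active = [k for k in active if k not in (i_glob, j_glob)] + [len(labels) - 1]

    i_glob, j_glob = active
    d = max(D[i_glob, j_glob], 0.0)
    return f"({labels[i_glob]}:{d / 2.0:.6f},{labels[j_glob]}:{d / 2.0:.6f});"
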