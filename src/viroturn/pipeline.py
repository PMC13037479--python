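"""End-to-end orchestration helpers shared by the CLI, tests and reports."""

from __future__ import annotations

from .formats_io import RunConfig
from .progeny_ratio import RatioResult, cluster_ratios
from .protein_network import (
    ViralCluster,
    build_network,
    cluster_genomes,
    cluster_proteins,
    protein_similarity_edges,
)
from .synthetic_community import SimulationResult, SyntheticCommunitySpec
from .viral_consensus import ContigRecord, _protein_contig, build_contig_records


def call_simulated(result: SimulationResult, config: RunConfig | None = None) -> list[ContigRecord]:
    """Consensus-call every simulated contig."""
    config = config or RunConfig()
    return build_contig_records(
        result.metadata, result.evidence, result.hits, config,
        protein_counts=result.protein_counts,
    )


def network_clusters(
    contigs: list[ContigRecord],
    result: SimulationResult,
    config: RunConfig | None = None,
) -> list[ViralCluster]:
    """Protein clustering, hypergeometric network and genome MCL for the
    viral >= network-tier contigs of a simulation."""
    config = config or RunConfig()
    keep = {
        c.contig_id: c.library_id
        for c in contigs
        if c.is_viral and c.length_bp >= config.contig_min_network_bp
    }
    hits = [h for h in result.hits if _protein_contig(h.query_id) in keep]
    proteins = sorted({h.query_id for h in hits} | {h.subject_id for h in hits})
    edges = protein_similarity_edges(hits, max_evalue=config.pc_max_evalue)
    pc_map = cluster_proteins(
        proteins, edges, inflation=config.inflation,
        max_iter=config.max_iter, tol=config.tol, prune_floor=config.prune_floor,
    )
    genome_pcs: dict[str, set[str]] = {c: set() for c in keep}
    for h in hits:
        genome_pcs[_protein_contig(h.query_id)].add(pc_map[h.query_id])
    net = build_network(genome_pcs, min_weight=config.min_edge_weight)
    return cluster_genomes(
        net, inflation=config.inflation, member_library=keep,
        max_iter=config.max_iter, tol=config.tol, prune_floor=config.prune_floor,
    )


def simulated_cluster_ratios(
    result: SimulationResult,
    spec: SyntheticCommunitySpec,
    config: RunConfig | None = None,
    pool_sites: bool = False,
) -> tuple[list[ContigRecord], list[ViralCluster], list[RatioResult]]:
    """Full downstream run on a simulation: calls, clusters, progeny ratios."""
    config = config or RunConfig()
    contigs = call_simulated(result, config)
    clusters = network_clusters(contigs, result, config)
    ratios = cluster_ratios(
        clusters, spec.libraries, n_boot=config.n_boot,
        ci_level=config.ci_level, seed=config.seed, pool_sites=pool_sites,
    )
    return contigs, clusters, ratios
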