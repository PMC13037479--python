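"""Consensus viral calling from multi-detector evidence plus reference-protein confirmation.

A contig is called viral when at least ``min_detectors`` independent
detector channels flag it AND at least ``min_confirming_proteins`` of its
distinct proteins have a reference hit passing the identity/coverage
thresholds. Length tiers at 1500 and 5000 bp (inclusive) drive reporting
and network membership.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError, EvidenceError
from .formats_io import HitRecord, RunConfig, stage_log

TIER_BELOW = "below_1500"
TIER_1500 = "ge_1500"
TIER_5000 = "ge_5000"


def tier_of(length_bp: int) -> str:
    """Length tier with inclusive thresholds: >=5000, >=1500, else below."""
    if length_bp >= 5000:
        return TIER_5000
    if length_bp >= 1500:
        return TIER_1500
    return TIER_BELOW


@dataclass
class ContigRecord:
    """One assembled contig with its evidence and verdict."""

    contig_id: str
    library_id: str
    length_bp: int
    n_proteins: int = 0
    detector_flags: dict[str, bool] = field(default_factory=dict)
    confirmed_hits: int = 0
    verdict: str = "non_viral"
    lineage_id: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise DataError(f"contig {self.contig_id!r} has non-positive length {self.length_bp}")
        if self.confirmed_hits > self.n_proteins:
            raise DataError(
                f"contig {self.contig_id!r}: confirmed_hits {self.confirmed_hits} exceeds "
                f"n_proteins {self.n_proteins}"
            )

    @property
    def tier(self) -> str:
        return tier_of(self.length_bp)

    @property
    def is_viral(self) -> bool:
        return self.verdict == "viral"


def filter_confirming_hits(
    hits: Iterable[HitRecord], min_identity: float = 80.0, min_coverage: float = 0.90
) -> int:
    """Count distinct query proteins with at least one passing hit.

    A hit passes when ``pct_identity >= min_identity`` (percent) and
    query coverage ``aln_length / query_length >= min_coverage``
    (fraction). A protein with several passing hits counts once.
    """
    passing: set[str] = set()
    for hit in hits:
        if hit.query_id in passing:
            continue
        if hit.query_length is None:
            raise DataError(f"hit for query {hit.query_id!r} lacks query_length")
        if hit.pct_identity >= min_identity and hit.coverage >= min_coverage:
            passing.add(hit.query_id)
    return len(passing)


def call_viral(
    contig: ContigRecord,
    detectors: Iterable[str],
    min_detectors: int = 2,
    min_confirming: int = 2,
) -> str:
    """Assign the contig's verdict in place and return it.

    Viral iff the detector quorum and the protein-confirmation quorum
    both pass; a detector missing from ``detector_flags`` is an error.
    """
    n_flags = 0
    for det in detectors:
        if det not in contig.detector_flags:
            raise EvidenceError(f"contig {contig.contig_id!r} lacks detector {det!r} evidence")
        n_flags += bool(contig.detector_flags[det])
    verdict = (
        "viral"
        if n_flags >= min_detectors and contig.confirmed_hits >= min_confirming
        else "non_viral"
    )
    contig.verdict = verdict
    return verdict


def _protein_contig(query_id: str) -> str:
    """Contig id for a protein named ``<contig>_p<N>`` (simulator convention)."""
    stem, _, suffix = query_id.rpartition("_p")
    if stem and suffix.isdigit():
        return stem
    return query_id


def build_contig_records(
    metadata: pd.DataFrame,
    evidence: pd.DataFrame,
    hits: Iterable[HitRecord],
    config: RunConfig | None = None,
    protein_counts: Mapping[str, int] | None = None,
    protein_to_contig=None,
) -> list[ContigRecord]:
    """Assemble contigs from the metadata/evidence/hit tables and call verdicts.

    ``protein_to_contig`` maps a hit's query protein to its contig; the
    default parses the ``<contig>_p<N>`` convention. ``protein_counts``
    supplies per-contig protein totals when known (otherwise the number
    of distinct proteins seen in hits is used as a lower bound).
    """
    config = config or RunConfig()
    to_contig = protein_to_contig or _protein_contig

    per_contig_hits: dict[str, list[HitRecord]] = defaultdict(list)
    for hit in hits:
        per_contig_hits[to_contig(hit.query_id)].append(hit)

    flag_map: dict[str, dict[str, bool]] = defaultdict(dict)
    for row in evidence.itertuples(index=False):
        flag_map[row.contig_id][row.detector] = bool(row.flag)

    contigs: list[ContigRecord] = []
    for row in metadata.itertuples(index=False):
        chits = per_contig_hits.get(row.contig_id, [])
        confirmed = filter_confirming_hits(chits, config.min_identity, config.min_coverage)
        if protein_counts is not None and row.contig_id in protein_counts:
            n_proteins = protein_counts[row.contig_id]
        else:
            n_proteins = len({h.query_id for h in chits})
        contig = ContigRecord(
            contig_id=row.contig_id,
            library_id=row.library_id,
            length_bp=int(row.length_bp),
            n_proteins=max(n_proteins, confirmed),
            detector_flags=flag_map.get(row.contig_id, {}),
            confirmed_hits=confirmed,
            lineage_id=getattr(row, "lineage_id", None),
        )
        call_viral(contig, config.detectors, config.min_detectors, config.min_confirming_proteins)
        contigs.append(contig)
    stage_log(
        "call_viral", len(contigs), sum(c.is_viral for c in contigs),
        min_detectors=config.min_detectors, min_confirming=config.min_confirming_proteins,
    )
    return contigs


def apply_tiers(contigs: Iterable[ContigRecord]) -> pd.DataFrame:
    """Per-library nested tier counts.

    Columns: assembled, assembled_5kb, viral, viral_1500, viral_5kb —
    monotone by construction (viral_5kb <= viral_1500 <= viral).
    """
    rows: dict[str, dict[str, int]] = {}
    for c in contigs:
        r = rows.setdefault(
            c.library_id,
            {"assembled": 0, "assembled_5kb": 0, "viral": 0, "viral_1500": 0, "viral_5kb": 0},
        )
        r["assembled"] += 1
        if c.length_bp >= 5000:
            r["assembled_5kb"] += 1
        if c.is_viral:
            r["viral"] += 1
            if c.length_bp >= 1500:
                r["viral_1500"] += 1
            if c.length_bp >= 5000:
                r["viral_5kb"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "library_id"
    return df


def contigs_to_frame(contigs: Iterable[ContigRecord]) -> pd.DataFrame:
    """Flat per-contig report (one row per contig: verdict, tier, confirmed_hits)."""
    return pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "library_id": c.library_id,
                "length_bp": c.length_bp,
                "n_proteins": c.n_proteins,
                "confirmed_hits": c.confirmed_hits,
                "verdict": c.verdict,
                "tier": c.tier,
            }
            for c in contigs
        ]
    )
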