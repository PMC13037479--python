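"""Per-fraction summary tables and headline percentages.

Rounding follows the printed precision of each statistic: one decimal
for the per-library viral percentage, nearest integer for the multi-hit
and host-lineage fractions — half-up in every case so fixture tables
match print exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .formats_io import round_half_up
from .viral_consensus import ContigRecord, apply_tiers


@dataclass(slots=True)
class FractionSummary:
    """One row of the per-library attrition table."""

    library_id: str
    assembled: int
    assembled_5kb: int
    viral: int
    viral_1500: int
    viral_5kb: int

    @property
    def viral_5kb_pct(self) -> float | None:
        """Percent of >=5 kb assembled contigs assigned viral (1 decimal, half-up)."""
        if self.assembled_5kb == 0:
            return None
        return round_half_up(100.0 * self.viral_5kb / self.assembled_5kb, 1)


def summarize(contigs: Iterable[ContigRecord]) -> list[FractionSummary]:
    """Per-library tier counts and viral percentage, sorted by library id."""
    tiers = apply_tiers(contigs)
    return [
        FractionSummary(
            library_id=str(lib),
            assembled=int(row.assembled),
            assembled_5kb=int(row.assembled_5kb),
            viral=int(row.viral),
            viral_1500=int(row.viral_1500),
            viral_5kb=int(row.viral_5kb),
        )
        for lib, row in tiers.iterrows()
    ]


def summaries_to_frame(summaries: Iterable[FractionSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "library_id": s.library_id,
                "assembled": s.assembled,
                "assembled_5kb": s.assembled_5kb,
                "viral": s.viral,
                "viral_1500": s.viral_1500,
                "viral_5kb": s.viral_5kb,
                "viral_5kb_pct": s.viral_5kb_pct,
            }
            for s in summaries
        ]
    )


def render_markdown(summaries: Iterable[FractionSummary]) -> str:
    """Markdown table mirroring the per-population attrition layout."""
    lines = [
        "| Population | Assembled contigs | Assembled 5 Kb | Viral assigned "
        "| Viral assigned 1.5 Kb | Viral assigned 5 Kb | Viral assigned 5 Kb, % |",
        "|---|---|---|---|---|---|---|",
    ]
    for s in summaries:
        pct = "—" if s.viral_5kb_pct is None else f"{s.viral_5kb_pct:.1f}"
        lines.append(
            f"| {s.library_id} | {s.assembled:,} | {s.assembled_5kb:,} | {s.viral:,} "
            f"| {s.viral_1500:,} | {s.viral_5kb:,} | {pct} |"
        )
    return "\n".join(lines)


def multi_hit_fraction(contigs: Iterable[ContigRecord], min_hits: int = 2) -> int | None:
    """Integer percent of candidate viral contigs (viral, >=1.5 kb) with
    at least ``min_hits`` confirmed reference protein hits.

    Returns None for an empty candidate set.
    """
    candidates = [c for c in contigs if c.is_viral and c.length_bp >= 1500]
    if not candidates:
        return None
    qualifying = sum(1 for c in candidates if c.confirmed_hits >= min_hits)
    return int(round_half_up(100.0 * qualifying / len(candidates), 0))


def lineage_fraction(assignments: Mapping[str, str]) -> tuple[dict[str, int], str]:
    """Integer-rounded percent per lineage and the modal lineage.

    Percents are computed on unrounded fractions and may not sum to 100
    after rounding; the modal lineage is the argmax with lexicographic
    tie-breaking.
    """
    if not assignments:
        raise ValueError("lineage_fraction requires at least one assignment")
    counts = Counter(assignments.values())
    total = sum(counts.values())
    percents = {
        lineage: int(round_half_up(100.0 * n / total, 0)) for lineage, n in counts.items()
    }
    modal = min(counts, key=lambda l: (-counts[l], l))
    return percents, modal
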