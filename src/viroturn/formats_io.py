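"""Readers/writers for the standard formats the pipeline touches, plus run configuration.

Supported formats: FASTA (80-column wrapped on output, any wrapping on
input), 12-column tab-separated protein hit tables (BLAST tabular order),
headered TSV tables, and a YAML/JSON run-configuration file.

Coordinates in hit tables are 1-based inclusive on disk (the tabular
convention); :class:`HitRecord` keeps them as parsed and exposes
``coverage`` as ``aln_length / query_length`` (query-side by default).
"""

from __future__ import annotations

import dataclasses
import decimal
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

from .errors import ConfigError, DataError, FormatError

logger = logging.getLogger("viroturn")

HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
)


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (print convention)."""
    quantum = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(value)).quantize(quantum, rounding=decimal.ROUND_HALF_UP)
    return float(d)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(header, sequence)`` pairs in file order.

    Accepts wrapped and single-line dialects and CRLF line endings. An
    empty file yields an empty list. Duplicate headers raise
    :class:`FormatError`.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            header = rec.description
            if header in seen:
                raise FormatError(f"duplicate FASTA id {header!r} in {path}")
            seen.add(header)
            records.append((header, str(rec.seq)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    """Write ``(header, sequence)`` pairs wrapped at ``width`` columns."""
    path = Path(path)
    seen: set[str] = set()
    with path.open("w") as out:
        for header, seq in records:
            if header in seen:
                raise FormatError(f"duplicate FASTA id {header!r}")
            seen.add(header)
            out.write(f">{header}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hit tables


@dataclass(slots=True)
class HitRecord:
    """One protein alignment hit in 12-column tabular order.

    ``query_length`` comes from an auxiliary table (or the simulator) and is
    required for coverage computation.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int = 0
    gap_opens: int = 0
    qstart: int = 1
    qend: int = 0
    sstart: int = 1
    send: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0
    query_length: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(
                f"pct_identity {self.pct_identity} outside [0, 100] for query {self.query_id}"
            )

    @property
    def coverage(self) -> float:
        """Query-side alignment coverage, ``aln_length / query_length``."""
        if self.query_length is None:
            raise DataError(f"hit for query {self.query_id!r} lacks query_length")
        return self.aln_length / self.query_length


def _looks_like_header(fields: Sequence[str]) -> bool:
    try:
        float(fields[2])
    except ValueError:
        return True
    return False


def read_hits(path: str | Path, query_lengths: dict[str, int] | None = None) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table (no header, or auto-detected header).

    ``query_lengths`` optionally attaches lengths for coverage computation.
    Wrong column counts raise :class:`FormatError` naming the line number.
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            if lineno == 1 and _looks_like_header(fields):
                continue
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if query_lengths is not None:
                hit.query_length = query_lengths.get(hit.query_id)
            hits.append(hit)
    return hits


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in 12-column tabular order, no header."""
    with Path(path).open("w") as out:
        for h in hits:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.qstart,
                        h.qend,
                        h.sstart,
                        h.send,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """All thresholds and numerical parameters of a pipeline run.

    Defaults equal the values used for the reported analyses.
    """

    # consensus viral calling
    min_identity: float = 80.0          # percent
    min_coverage: float = 0.90          # fraction of the query protein
    min_confirming_proteins: int = 2
    min_detectors: int = 2
    detectors: tuple[str, ...] = ("virsorter", "genomad", "checkv")
    contig_min_report_bp: int = 1500
    contig_min_network_bp: int = 5000
    # marker screen
    gp23_min_bitscore: float = 50.0     # strict >
    gp23_max_evalue: float = 1e-10      # strict <
    host_min_shared: float = 0.80
    host_min_aai: float = 0.60
    host_min_cov: float = 0.95
    # protein/genome network
    inflation: float = 2.0
    max_iter: int = 200
    tol: float = 1e-6
    prune_floor: float = 1e-6
    min_edge_weight: float = 1.0
    pc_max_evalue: float = 1e-5
    # bootstrap
    n_boot: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (0.0 <= self.min_identity <= 100.0, "min_identity"),
            (0.0 <= self.min_coverage <= 1.0, "min_coverage"),
            (self.min_confirming_proteins >= 0, "min_confirming_proteins"),
            (self.min_detectors >= 1, "min_detectors"),
            (self.contig_min_report_bp > 0, "contig_min_report_bp"),
            (self.contig_min_network_bp >= self.contig_min_report_bp, "contig_min_network_bp"),
            (0.0 <= self.host_min_shared <= 1.0, "host_min_shared"),
            (0.0 <= self.host_min_aai <= 1.0, "host_min_aai"),
            (0.0 <= self.host_min_cov <= 1.0, "host_min_cov"),
            (self.inflation > 1.0, "inflation"),
            (self.max_iter >= 1, "max_iter"),
            (self.tol > 0, "tol"),
            (self.prune_floor >= 0, "prune_floor"),
            (self.n_boot >= 1, "n_boot"),
            (0.0 < self.ci_level < 1.0, "ci_level"),
        ]
        for ok, name in checks:
            if not ok:
                raise ConfigError(f"configuration field {name!r} out of range")
        if isinstance(self.detectors, list):
            self.detectors = tuple(self.detectors)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys are rejected loudly."""
        with Path(path).open() as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown configuration keys: {', '.join(unknown)}")
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["detectors"] = list(self.detectors)
        with Path(path).open("w") as out:
            if str(path).endswith(".json"):
                json.dump(data, out, indent=2)
            else:
                yaml.safe_dump(data, out, sort_keys=False)


def stage_log(stage: str, n_in: int, n_out: int, **extra: object) -> None:
    """One structured line per pipeline stage so filter attrition is auditable."""
    kv = " ".join(f"{k}={v}" for k, v in extra.items())
    logger.info("stage=%s in=%d out=%d %s", stage, n_in, n_out, kv)
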