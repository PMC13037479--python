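"""Ground-truth community simulator for the four activity-sorted fractions.

Generates lineage reference proteomes, sorts particles into libraries
(viral progeny / pre-existing viruses / active cells / inactive cells)
with per-lineage turnover and activity probabilities, then fragments
sorted particles into annotated contigs with detector evidence and
reference protein hits, so every downstream stage can be tested without
external data.

Randomness model: a single main RNG stream seeded from ``spec.seed`` is
consumed in documented order (lineage proteomes, then sorting, then
contigs per library in roster order). Nucleotide sequences for the
contig FASTA are drawn from an independent child stream so that skipping
sequence emission does not perturb anything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateCommunityError, SpecificationError
from .formats_io import HitRecord, stage_log, write_fasta, write_hits

AMINO_ACIDS = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)

VIRAL_FRACTIONS = ("viral_progeny", "pre_existing_viruses")
CELL_FRACTIONS = ("active_cells", "inactive_cells")
BONCAT_POSITIVE_FRACTIONS = ("viral_progeny", "active_cells")
FRACTIONS = VIRAL_FRACTIONS + CELL_FRACTIONS

METADATA_COLUMNS = ("library_id", "contig_id", "lineage_id", "length_bp", "true_viral", "true_boncat")
EVIDENCE_COLUMNS = ("contig_id", "detector", "flag", "score")


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise SpecificationError(f"field {name!r} must be a probability in [0, 1], got {value}")


@dataclass
class LineageSpec:
    """Ground truth for one viral or host lineage."""

    lineage_id: str
    kind: str  # "viral" | "host"
    relative_abundance: float
    genome_length_bp: int = 40_000
    n_proteins: int = 6
    protein_divergence: float = 0.02
    protein_length_aa: int = 150
    turnover_theta: float = 0.0     # viral lineages: P(virion is newly produced)
    activity_prob: float = 0.0      # host lineages: P(cell is translationally active)
    infection_link: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("viral", "host"):
            raise SpecificationError(f"field 'kind' must be viral|host, got {self.kind!r}")
        _check_prob(self.relative_abundance, "relative_abundance")
        _check_prob(self.turnover_theta, "turnover_theta")
        _check_prob(self.activity_prob, "activity_prob")
        _check_prob(self.protein_divergence, "protein_divergence")
        if self.genome_length_bp <= 0:
            raise SpecificationError(
                f"field 'genome_length_bp' must be positive, got {self.genome_length_bp}"
            )
        if self.n_proteins < 1:
            raise SpecificationError(f"field 'n_proteins' must be >= 1, got {self.n_proteins}")
        if self.protein_length_aa < 1:
            raise SpecificationError(
                f"field 'protein_length_aa' must be >= 1, got {self.protein_length_aa}"
            )


@dataclass
class SortedLibrary:
    """One FACS-sorted pool of particles or cells."""

    library_id: str
    fraction: str
    sorted_depth: int
    site: str = "site1"
    click_minutes: float = 360.0

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise SpecificationError(
                f"field 'fraction' must be one of {FRACTIONS}, got {self.fraction!r}"
            )
        if self.sorted_depth <= 0:
            raise SpecificationError(
                f"field 'sorted_depth' must be positive, got {self.sorted_depth}"
            )
        if self.click_minutes <= 0:
            raise SpecificationError(
                f"field 'click_minutes' must be positive, got {self.click_minutes}"
            )

    @property
    def boncat_positive(self) -> bool:
        return self.fraction in BONCAT_POSITIVE_FRACTIONS

    @property
    def is_viral_fraction(self) -> bool:
        return self.fraction in VIRAL_FRACTIONS


@dataclass
class SyntheticCommunitySpec:
    """Full simulation specification: lineages, libraries, noise and size knobs."""

    lineages: list[LineageSpec]
    libraries: list[SortedLibrary]
    length_log_mean: float = np.log(8000.0)
    length_log_sd: float = 0.35
    detector_sensitivity: float = 0.95
    detector_fpr: float = 0.02
    detectors: tuple[str, ...] = ("virsorter", "genomad", "checkv")
    amplification_dispersion: float = 2.0
    contig_yield: float = 1.0       # P(sorted particle yields an assembled contig)
    contamination: float = 0.0      # P(particle in a viral sort is cellular debris)
    virocell_prob_active: float = 0.0    # P(active-cell contig is viral, i.e. a virocell)
    virocell_prob_inactive: float = 0.0  # P(inactive-cell contig is viral)
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob(self.detector_sensitivity, "detector_sensitivity")
        _check_prob(self.detector_fpr, "detector_fpr")
        _check_prob(self.contig_yield, "contig_yield")
        _check_prob(self.contamination, "contamination")
        _check_prob(self.virocell_prob_active, "virocell_prob_active")
        _check_prob(self.virocell_prob_inactive, "virocell_prob_inactive")
        if self.amplification_dispersion <= 0:
            raise SpecificationError(
                f"field 'amplification_dispersion' must be positive, got "
                f"{self.amplification_dispersion}"
            )
        if self.length_log_sd < 0:
            raise SpecificationError(
                f"field 'length_log_sd' must be non-negative, got {self.length_log_sd}"
            )
        if isinstance(self.detectors, list):
            self.detectors = tuple(self.detectors)
        for kind in ("viral", "host"):
            mass = sum(l.relative_abundance for l in self.lineages if l.kind == kind)
            n = sum(1 for l in self.lineages if l.kind == kind)
            if n and abs(mass - 1.0) > 1e-9:
                raise SpecificationError(
                    f"field 'relative_abundance' over {kind} lineages sums to {mass}, expected 1"
                )
        ids = [l.lineage_id for l in self.lineages]
        if len(set(ids)) != len(ids):
            raise SpecificationError("field 'lineage_id' values must be unique")

    def lineage(self, lineage_id: str) -> LineageSpec:
        for l in self.lineages:
            if l.lineage_id == lineage_id:
                return l
        raise KeyError(lineage_id)


@dataclass
class SimulationResult:
    """In-memory view of everything :func:`fragment_and_annotate` emits."""

    metadata: pd.DataFrame                 # METADATA_COLUMNS
    evidence: pd.DataFrame                 # EVIDENCE_COLUMNS
    hits: list[HitRecord]
    proteins: dict[str, list[tuple[str, str]]]  # contig_id -> [(protein_id, seq)]
    query_lengths: dict[str, int]
    amplification_weights: dict[str, float]
    protein_counts: dict[str, int] = field(default_factory=dict)


def spec_from_dict(data: Mapping) -> SyntheticCommunitySpec:
    """Build a spec from a plain mapping (the YAML config layout)."""
    data = dict(data)
    lineages = [LineageSpec(**l) for l in data.pop("lineages", [])]
    libraries = [SortedLibrary(**l) for l in data.pop("libraries", [])]
    known = {f.name for f in __import__("dataclasses").fields(SyntheticCommunitySpec)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise SpecificationError(f"unknown simulation keys: {', '.join(unknown)}")
    return SyntheticCommunitySpec(lineages=lineages, libraries=libraries, **data)


def spec_from_file(path: str | Path) -> SyntheticCommunitySpec:
    import yaml

    with Path(path).open() as handle:
        data = yaml.safe_load(handle) or {}
    return spec_from_dict(data)


def _main_rng(spec: SyntheticCommunitySpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 0])


def _mutate(reference: np.ndarray, divergence: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Substitute each site independently with probability ``divergence``.

    Substitutions always change the residue, so expected identity to the
    reference is exactly ``1 - divergence``. Returns (variant, n_substitutions).
    """
    n = reference.size
    if divergence == 0.0:
        return reference.copy(), 0
    mask = rng.random(n) < divergence
    k = int(mask.sum())
    if k == 0:
        return reference.copy(), 0
    variant = reference.copy()
    # draw from the 19 residues different from the current one; AMINO_ACIDS is
    # in ascending byte order so searchsorted gives each residue's index
    offsets = rng.integers(1, AMINO_ACIDS.size, size=k)
    cur = np.searchsorted(AMINO_ACIDS, variant[mask])
    variant[mask] = AMINO_ACIDS[(cur + offsets) % AMINO_ACIDS.size]
    return variant, k


def generate_lineages(
    spec: SyntheticCommunitySpec, rng: np.random.Generator | None = None
) -> dict[str, list[np.ndarray]]:
    """Draw the reference proteome of every lineage (uint8 arrays of residues)."""
    rng = _main_rng(spec) if rng is None else rng
    references: dict[str, list[np.ndarray]] = {}
    for lineage in spec.lineages:
        references[lineage.lineage_id] = [
            rng.choice(AMINO_ACIDS, size=lineage.protein_length_aa)
            for _ in range(lineage.n_proteins)
        ]
    return references


def _fraction_weights(spec: SyntheticCommunitySpec, fraction: str) -> tuple[list[str], np.ndarray]:
    """Lineage sampling weights for one sorted fraction (before contamination)."""
    ids: list[str] = []
    weights: list[float] = []
    for l in spec.lineages:
        if fraction == "viral_progeny" and l.kind == "viral":
            w = l.relative_abundance * l.turnover_theta
        elif fraction == "pre_existing_viruses" and l.kind == "viral":
            w = l.relative_abundance * (1.0 - l.turnover_theta)
        elif fraction == "active_cells" and l.kind == "host":
            w = l.relative_abundance * l.activity_prob
        elif fraction == "inactive_cells" and l.kind == "host":
            w = l.relative_abundance * (1.0 - l.activity_prob)
        else:
            continue
        ids.append(l.lineage_id)
        weights.append(w)
    return ids, np.asarray(weights, dtype=float)


def simulate_sorting(
    spec: SyntheticCommunitySpec, rng: np.random.Generator | None = None
) -> dict[str, dict[str, int]]:
    """Multinomially allocate each library's sorted_depth across lineages.

    A virion of lineage ``l`` enters the progeny sort with weight
    ``abundance_l * theta_l`` and the pre-existing sort with weight
    ``abundance_l * (1 - theta_l)``; cells analogously via activity_prob.
    Per-library totals equal ``sorted_depth`` exactly.
    """
    rng = _main_rng(spec) if rng is None else rng
    counts: dict[str, dict[str, int]] = {}
    for lib in spec.libraries:
        ids, weights = _fraction_weights(spec, lib.fraction)
        total = weights.sum()
        if lib.fraction in VIRAL_FRACTIONS and spec.contamination > 0.0:
            host_ids = [l.lineage_id for l in spec.lineages if l.kind == "host"]
            host_w = np.asarray(
                [spec.lineage(h).relative_abundance for h in host_ids], dtype=float
            )
            if total > 0 and host_w.sum() > 0:
                weights = np.concatenate(
                    [weights / total * (1.0 - spec.contamination),
                     host_w / host_w.sum() * spec.contamination]
                )
                ids = ids + host_ids
                total = weights.sum()
        if total <= 0.0:
            raise DegenerateCommunityError(
                f"library {lib.library_id!r} requests fraction {lib.fraction!r} "
                f"with depth {lib.sorted_depth} but the community places zero mass there"
            )
        drawn = rng.multinomial(lib.sorted_depth, weights / total)
        counts[lib.library_id] = {i: int(c) for i, c in zip(ids, drawn)}
    return counts


def _reassign_virocells(
    lineage_counts: dict[str, int],
    spec: SyntheticCommunitySpec,
    p_viro: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Flip each sorted cell into a virocell with probability ``p_viro``.

    A virocell yields a contig from its host's infecting viral lineage
    (the unique viral lineage with ``infection_link`` to that host when
    one exists, otherwise abundance-weighted over viral lineages).
    """
    viral = [l for l in spec.lineages if l.kind == "viral"]
    if not viral:
        return lineage_counts
    out = dict(lineage_counts)
    for host_id in sorted(lineage_counts):
        if spec.lineage(host_id).kind != "host":
            continue
        n = lineage_counts[host_id]
        n_viro = int(rng.binomial(n, p_viro))
        if n_viro == 0:
            continue
        out[host_id] = n - n_viro
        linked = [v for v in viral if v.infection_link == host_id]
        if len(linked) == 1:
            out[linked[0].lineage_id] = out.get(linked[0].lineage_id, 0) + n_viro
        else:
            weights = np.array([v.relative_abundance for v in viral])
            drawn = rng.multinomial(n_viro, weights / weights.sum())
            for v, k in zip(viral, drawn):
                if k:
                    out[v.lineage_id] = out.get(v.lineage_id, 0) + int(k)
    return out


def fragment_and_annotate(
    counts: Mapping[str, Mapping[str, int]],
    spec: SyntheticCommunitySpec,
    references: Mapping[str, Sequence[np.ndarray]] | None = None,
    rng: np.random.Generator | None = None,
    outdir: str | Path | None = None,
) -> SimulationResult:
    """Turn sorted particle counts into contigs with evidence and hit tables.

    One contig per assembled particle (``contig_yield`` thins particles
    binomially). Contig lengths are lognormal; per-particle amplification
    weights are gamma with shape ``amplification_dispersion`` (mean 1);
    detector flags fire with ``detector_sensitivity`` on true viral
    contigs and ``detector_fpr`` otherwise; viral contigs carry hits
    against their lineage reference proteins with identity consistent
    with ``protein_divergence``. With ``outdir`` set, writes contig and
    protein FASTA plus metadata/evidence/hit TSVs.
    """
    if references is None or rng is None:
        raise SpecificationError(
            "fragment_and_annotate requires references and rng from the shared stream; "
            "use simulate() for the one-call interface"
        )
    meta_rows: list[tuple] = []
    evidence_rows: list[tuple] = []
    hits: list[HitRecord] = []
    proteins: dict[str, list[tuple[str, str]]] = {}
    query_lengths: dict[str, int] = {}
    amp_weights: dict[str, float] = {}
    protein_counts: dict[str, int] = {}
    contig_lineage: list[tuple[str, int]] = []  # (contig_id, length) for FASTA emission

    lib_by_id = {lib.library_id: lib for lib in spec.libraries}
    for lib in spec.libraries:
        lineage_counts = dict(counts[lib.library_id])
        if lib.fraction in CELL_FRACTIONS:
            p_viro = (
                spec.virocell_prob_active
                if lib.fraction == "active_cells"
                else spec.virocell_prob_inactive
            )
            if p_viro > 0.0:
                lineage_counts = _reassign_virocells(lineage_counts, spec, p_viro, rng)
        serial = 0
        for lineage_id in sorted(lineage_counts):
            n_particles = lineage_counts[lineage_id]
            if n_particles == 0:
                continue
            lineage = spec.lineage(lineage_id)
            refs = references[lineage_id]
            n_contigs = (
                n_particles
                if spec.contig_yield >= 1.0
                else int(rng.binomial(n_particles, spec.contig_yield))
            )
            if n_contigs == 0:
                continue
            if spec.length_log_sd == 0.0:
                lengths = np.full(n_contigs, int(round(np.exp(spec.length_log_mean))))
            else:
                lengths = np.maximum(
                    1,
                    np.round(
                        rng.lognormal(spec.length_log_mean, spec.length_log_sd, n_contigs)
                    ).astype(int),
                )
            weights = rng.gamma(
                spec.amplification_dispersion, 1.0 / spec.amplification_dispersion, n_contigs
            )
            true_viral = lineage.kind == "viral"
            flag_prob = spec.detector_sensitivity if true_viral else spec.detector_fpr
            flags = rng.random((n_contigs, len(spec.detectors))) < flag_prob
            scores = rng.random((n_contigs, len(spec.detectors)))
            for i in range(n_contigs):
                contig_id = f"{lib.library_id}_c{serial:06d}"
                serial += 1
                meta_rows.append(
                    (
                        lib.library_id,
                        contig_id,
                        lineage_id,
                        int(lengths[i]),
                        true_viral,
                        lib_by_id[lib.library_id].boncat_positive,
                    )
                )
                amp_weights[contig_id] = float(weights[i])
                contig_lineage.append((contig_id, int(lengths[i])))
                for d, det in enumerate(spec.detectors):
                    evidence_rows.append(
                        (contig_id, det, bool(flags[i, d]), float(round(scores[i, d], 4)))
                    )
                contig_prots: list[tuple[str, str]] = []
                protein_counts[contig_id] = lineage.n_proteins
                for j, ref in enumerate(refs):
                    variant, n_sub = _mutate(ref, lineage.protein_divergence, rng)
                    protein_id = f"{contig_id}_p{j}"
                    contig_prots.append((protein_id, variant.tobytes().decode("ascii")))
                    length = ref.size
                    query_lengths[protein_id] = length
                    if true_viral:
                        aln_len = int(round(length * rng.uniform(0.92, 1.0)))
                        aln_len = max(1, aln_len)
                        identity = 100.0 * (1.0 - n_sub / length)
                        bitscore = round(2.0 * aln_len * identity / 100.0, 1)
                        hits.append(
                            HitRecord(
                                query_id=protein_id,
                                subject_id=f"{lineage_id}_ref_p{j}",
                                pct_identity=round(identity, 2),
                                aln_length=aln_len,
                                mismatches=n_sub,
                                gap_opens=0,
                                qstart=1,
                                qend=aln_len,
                                sstart=1,
                                send=aln_len,
                                evalue=1e-50,
                                bitscore=bitscore,
                                query_length=length,
                            )
                        )
                proteins[contig_id] = contig_prots

    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    evidence = pd.DataFrame(evidence_rows, columns=list(EVIDENCE_COLUMNS))
    result = SimulationResult(
        metadata=metadata,
        evidence=evidence,
        hits=hits,
        proteins=proteins,
        query_lengths=query_lengths,
        amplification_weights=amp_weights,
        protein_counts=protein_counts,
    )
    stage_log("fragment_and_annotate", sum(sum(c.values()) for c in counts.values()), len(meta_rows))
    if outdir is not None:
        _write_outputs(result, spec, Path(outdir))
    return result


def _write_outputs(result: SimulationResult, spec: SyntheticCommunitySpec, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    result.evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)
    write_hits(result.hits, outdir / "hits.tsv")
    prot_records = [
        (pid, seq) for contig in sorted(result.proteins) for pid, seq in result.proteins[contig]
    ]
    write_fasta(prot_records, outdir / "proteins.fasta")
    # nucleotide sequences come from an independent child stream so that the
    # main stream is identical whether or not FASTA emission happens
    nt_rng = np.random.default_rng([spec.seed, 1])
    contig_records = []
    for _, row in result.metadata.iterrows():
        seq = nt_rng.choice(NUCLEOTIDES, size=int(row.length_bp)).tobytes().decode("ascii")
        contig_records.append((row.contig_id, seq))
    write_fasta(contig_records, outdir / "contigs.fasta")


def simulate(
    spec: SyntheticCommunitySpec, outdir: str | Path | None = None
) -> tuple[dict[str, list[np.ndarray]], dict[str, dict[str, int]], SimulationResult]:
    """Run the full simulation under one seeded stream; returns (references, counts, result)."""
    rng = _main_rng(spec)
    references = generate_lineages(spec, rng)
    counts = simulate_sorting(spec, rng)
    result = fragment_and_annotate(counts, spec, references, rng, outdir=outdir)
    return references, counts, result
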