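# viroturn

Turnover analysis for activity-sorted virome fractions: from per-library
contig sets (real or simulated) through consensus viral identification,
protein-sharing network clustering, and per-cluster depth-normalized
viral progeny ratios, plus per-fraction summary statistics.

## What it does

A sorting experiment yields four pools: newly produced virions
(label-positive), pre-existing virions (label-negative), active cells and
inactive cells, each with a known sorted particle depth. The pipeline:

1. **`synthetic_community`** — simulates the whole experiment (lineage
   proteomes, per-lineage turnover probabilities, multinomial sorting at
   configurable depths, lognormal contig lengths, detector noise, hit
   tables) so every downstream stage is testable without external data.
2. **`viral_consensus`** — calls contigs viral when a detector quorum
   (default 2 of 3 channels) and a reference-protein confirmation quorum
   (default ≥2 proteins at ≥80% identity, ≥90% query coverage) both pass,
   and assigns 1.5 kb / 5 kb length tiers.
3. **`protein_network`** — clusters proteins with an in-house Markov
   Cluster (MCL) implementation, weights genome pairs by the hypergeometric
   tail probability of their shared protein-cluster count (−log10 p, capped
   at 300), and MCL-partitions the resulting genome network.
4. **`progeny_ratio`** — the core statistic: for each cluster,
   `R = (n_pos/D_pos) / (n_pos/D_pos + n_neg/D_neg)` where `n` are member
   counts from the positive/negative viral sorts and `D` the sorted depths;
   with percentile-bootstrap confidence intervals and an enumeration oracle
   that recovers integer member splits from printed percentages.
5. **`marker_screen`** — gp23-like marker screening (bitscore > 50,
   e-value < 1e-10, both strict), a three-axis host-linkage filter
   (≥80% shared proteins, ≥60% AAI, ≥95% coverage), and a neighbor-joining
   Newick tree stand-in on p-distances.
6. **`fraction_summary`** — per-library attrition tables (assembled /
   viral counts per tier with half-up rounded percentages), the multi-hit
   fraction, and host-lineage fractions.
7. **`formats_io`** — FASTA, 12-column tabular hit tables, TSV, and the
   run configuration (all thresholds, YAML/JSON, unknown keys rejected).

## CLI

```sh
viroturn simulate   --config sim.yaml --outdir out/ [--seed 7]
viroturn call-viral --metadata out/metadata.tsv --evidence out/evidence.tsv \
                    --hits out/hits.tsv --proteins out/proteins.fasta --out calls.tsv
viroturn network    --contigs calls.tsv --hits out/hits.tsv \
                    --out-edges edges.tsv --out-clusters clusters.tsv
viroturn ratio      --clusters clusters.tsv --libraries libs.tsv --out ratios.tsv
viroturn screen     --hits hits.tsv --mode gp23|hostlink --out screen.tsv
viroturn tree       --aligned markers.fasta --out tree.nwk
viroturn summarize  --contigs calls.tsv --out summary.tsv [--markdown]
```

`sim.yaml` describes lineages and libraries (see `tests/test_cli.py` for a
minimal example); `libs.tsv` is a headered TSV with `library_id`,
`fraction`, `sorted_depth` and optional `site` columns.

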