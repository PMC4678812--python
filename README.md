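# sirspread

Genome-wide detection and characterization of secondary (transitive) siRNA
production from miRNA targets, built as a tested, reusable pipeline over
fully synthetic data:

- **Scanning-window counting** — reads counted per 300-nt window
  (150-nt overlap) independently for each read size 19–26 nt.
- **Exact negative-binomial two-group test** — implemented from first
  principles with a common dispersion (variance = μ + φμ²): replicate
  counts are equalized to a common library size, summed within groups, and
  the group sum is tested conditionally on the pooled total; two-sided
  p-values sum all outcomes at most as likely as the observed one.
- **Locus merging and miRNA-target enrichment** — significant windows are
  merged by direction into loci, mapped to genes, and tested for target
  enrichment with an exact Fisher test over genes.
- **Cleavage-site profiling** — cleavage coordinates derived from target
  sites (slicer geometry: cut between target nucleotides paired to small-RNA
  positions 10/11), per-position 5′-end profiles, and classification of
  spreading as 5′-exclusive, 3′-exclusive or bidirectional.
- **Duplex free energy** — nearest-neighbor minimum hybridization energy of
  two free RNA strands (intermolecular pairings only) via dynamic
  programming, with a versioned parameter table, wobble pairs, loop/bulge
  penalties and temperature scaling.
- **Spreading-side prediction** — the fragment least stably paired to the
  miRNA is predicted to spread, with a similarity tolerance that defaults
  ties to the 5′ side, scored by an exact binomial upper tail.
- **3′-RACE tail analysis** — maximal-templated-match extraction of
  non-templated tails against a reference 5′-cleavage fragment and
  per-class summaries.
- **Synthetic data** — a deterministic simulator emits genomes,
  annotations, target sites, per-genotype/replicate alignments
  (four genotypes: SKI2/RDR6, ski2/RDR6, SKI2/rdr6, ski2/rdr6), and RACE
  clones, with a machine-readable truth table used by the recovery tests.

Internal coordinates are 0-based half-open everywhere; GFF3 and the
target-site TSV (1-based closed) are converted at the I/O boundary.
Alignments are read from a 5-column BED-like TSV (`chrom start end strand
sample_id`) or BAM.

## CLI

Run the full pipeline (simulate → count → test → loci/enrichment →
profiles → duplex → predict → racetails) from one YAML config:

```sh
sirspread run -c config.yaml -o outdir --seed 1
```

An empty config gives documented defaults (window 300/150, sizes 19–26,
α 0.05 raw, τ 2.0 kcal/mol, 21 °C). Each stage is also exposed directly:

```sh
sirspread simulate -o sim --seed 1
sirspread windows --alignments sim/alignments.tsv --genome sim/genome.fa -o counts.tsv
sirspread diff --counts counts.tsv --control SKI2_RDR6 --case ski2_RDR6 -o diff.tsv
sirspread loci --results diff.tsv --gff sim/genes.gff3 \
    --sites sim/target_sites.tsv --mirnas sim/mirnas.fa -o loci.tsv
sirspread profile  ... -o calls.tsv
sirspread duplex   ... -o energies.tsv
sirspread predict --energies energies.tsv --calls calls.tsv -o predict.json
sirspread racetails --clones clones.fa --reference frag.fa -o tails.tsv
```

`sirspread run` writes a `MANIFEST.json` with per-stage output digests,
parameters and headline numbers; reruns with the same config and seed are
byte-identical.

## Notes

- The exact NB test defaults to raw P < 0.05 (no multiple-testing
  adjustment) to match the original analysis; Benjamini–Hochberg is
  available via `--adjust BH` and is recommended for rigorous use.
- Duplex energies use bundled Watson–Crick ΔH/ΔS parameters at their
  reference ionic strength; no salt correction is applied. Only the
  *relative* comparison of the two fragment energies feeds predictions,
  which is invariant to uniform offsets.
- Multi-mapping policy: counts are per alignment record, i.e. whatever the
  alignment file contains.
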