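"""Fully synthetic genomes, annotations, small-RNA alignments and RACE clones.

Four genotypes (SKI2_RDR6, ski2_RDR6, SKI2_rdr6, ski2_rdr6) x replicates,
19-26 nt reads with 21-nt dominance at transitive loci, planted low-abundance
siRNA peaks adjacent to cleavage sites with configurable 5'/3'/bidirectional
spreading, negative-binomial replicate noise over a non-differential
degradation background, and RACE clones with configurable trimming and
tailing.  Everything is deterministic under a fixed seed and ships with a
machine-readable truth table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sio import (AlignedRead, ConfigurationError, Gene, GeneAnnotation,
                  TargetSiteRecord, revcomp_dna, to_rna)

GENOTYPES = ("SKI2_RDR6", "ski2_RDR6", "SKI2_rdr6", "ski2_rdr6")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 150_000
    n_genes: int = 100
    gene_length: int = 1_200
    n_target_genes: int = 10
    sites_per_gene: int = 1
    mirna_length: int = 21
    site_mismatches: int = 0
    replicates: int = 2
    # background dominates library size, as in a real genome, so that
    # total-count equalization does not erase planted fold changes
    background_mean: float = 50.0
    dispersion: float = 0.1
    transitive_mean: float = 200.0
    fold_change: float = 16.0
    peak_halfwidth: int = 150
    frac_21: float = 0.8
    size_min: int = 19
    size_max: int = 26
    rdr6_dependence: float = 1.0
    directions: tuple[str, ...] = ("5p", "3p", "both")

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ConfigurationError("need >= 2 replicates for differential testing")
        if not 0.0 <= self.frac_21 <= 1.0:
            raise ConfigurationError("frac_21 must lie in [0, 1]")
        if not 0.0 <= self.rdr6_dependence <= 1.0:
            raise ConfigurationError("rdr6_dependence must lie in [0, 1]")
        if self.fold_change <= 0:
            raise ConfigurationError("fold_change must be positive")
        if any(d not in ("5p", "3p", "both") for d in self.directions):
            raise ConfigurationError("directions must be drawn from {5p, 3p, both}")

    @property
    def samples(self) -> list[str]:
        return [f"{g}_rep{r + 1}" for g in GENOTYPES for r in range(self.replicates)]


@dataclass
class PlantedLocus:
    gene_id: str
    chrom: str
    gene_start: int
    cleavage: int  # genome coordinate, 0-based (first nt of the 3' fragment)
    direction: str
    mirna_name: str
    expected_means: dict[str, float] = field(default_factory=dict)
    is_mirna_target: bool = True


@dataclass
class Reference:
    genome: dict[str, str]
    annotation: GeneAnnotation
    target_sites: list[TargetSiteRecord]


def _planted_mean(config: SimConfig, genotype: str) -> float:
    mean = config.transitive_mean
    if genotype.startswith("SKI2"):
        mean /= config.fold_change
    if genotype.endswith("rdr6"):
        mean *= 1.0 - config.rdr6_dependence
    return mean


def simulate_reference(config: SimConfig) -> tuple[Reference, list[PlantedLocus],
                                                   dict[str, str]]:
    """Build genome, annotation, target sites, truth loci and miRNA set.

    Genes are laid out left to right with even spacing; the first
    ``n_target_genes`` carry planted miRNA sites whose genomic sequence is
    the reverse complement of the miRNA (perfect pairing unless
    ``site_mismatches`` > 0).  Returns (reference, truth, mirnas).
    """
    rng = np.random.default_rng(config.seed)
    spacing = config.chromosome_length // max(
        1, -(-config.n_genes // config.n_chromosomes))
    if spacing < config.gene_length + 2:
        raise ConfigurationError("genes requested exceed genome capacity")

    genome_arrays = {
        f"chr{c + 1}": rng.integers(0, 4, size=config.chromosome_length)
        for c in range(config.n_chromosomes)
    }
    annotation = GeneAnnotation()
    genes: list[Gene] = []
    for i in range(config.n_genes):
        chrom = f"chr{i % config.n_chromosomes + 1}"
        slot = i // config.n_chromosomes
        start = slot * spacing + (spacing - config.gene_length) // 2
        gene = Gene(f"gene{i + 1:04d}", chrom, start, start + config.gene_length, "+")
        annotation.add(gene)
        genes.append(gene)

    mirnas: dict[str, str] = {}
    target_sites: list[TargetSiteRecord] = []
    truth: list[PlantedLocus] = []
    site_len = config.mirna_length
    for i in range(config.n_target_genes):
        gene = genes[i]
        name = f"simMir{i + 1:03d}"
        mirna_dna = "".join(rng.choice(_BASES, size=site_len))
        mirnas[name] = to_rna(mirna_dna)
        direction = config.directions[i % len(config.directions)]
        for s in range(config.sites_per_gene):
            # sites centred in the gene, spaced 60 nt apart for multi-site genes
            centre = config.gene_length // 2 + s * 60
            t_start = centre - site_len // 2  # transcript (gene-relative), 0-based
            site_dna = revcomp_dna(mirna_dna)
            if config.site_mismatches:
                site_dna = _mutate(site_dna, config.site_mismatches, rng)
            g_start = gene.start + t_start
            arr = genome_arrays[gene.chrom]
            arr[g_start:g_start + site_len] = [
                "ACGT".index(b) for b in site_dna]
            target_sites.append(TargetSiteRecord(
                transcript_id=gene.gene_id, mirna_name=name,
                start=t_start, end=t_start + site_len,
                n_sites=config.sites_per_gene, mirna_sequence=mirnas[name]))
            c_transcript = (t_start + site_len) - 10  # first nt of 3' fragment
            truth.append(PlantedLocus(
                gene_id=gene.gene_id, chrom=gene.chrom, gene_start=gene.start,
                cleavage=gene.start + c_transcript, direction=direction,
                mirna_name=name,
                expected_means={g: _planted_mean(config, g) for g in GENOTYPES}))

    genome = {chrom: "".join(_BASES[arr]) for chrom, arr in genome_arrays.items()}
    return Reference(genome, annotation, target_sites), truth, mirnas


def _mutate(seq: str, n: int, rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in rng.choice(len(chars), size=min(n, len(chars)), replace=False):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mean))
    r = 1.0 / phi
    return int(rng.negative_binomial(r, r / (r + mean)))


def _draw_sizes(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    sizes = np.full(n, 21)
    other = rng.random(n) >= config.frac_21
    candidates = [s for s in range(config.size_min, config.size_max + 1) if s != 21]
    if other.any() and candidates:
        sizes[other] = rng.choice(candidates, size=int(other.sum()))
    return sizes


def simulate_reads(reference: Reference, truth: list[PlantedLocus],
                   config: SimConfig) -> tuple[dict[str, list[AlignedRead]],
                                               dict[str, int]]:
    """Emit per-sample alignments and library sizes.

    Background: per gene per sample, NB(background_mean, phi) reads placed
    uniformly inside the gene (both strands) — identical in expectation in
    all genotypes.  Planted signal: NB draws around each locus's
    genotype-specific expected mean, read 5' ends within peak_halfwidth on
    the configured side(s) of the cleavage coordinate.
    """
    rng = np.random.default_rng(config.seed + 1)
    chrom_lengths = {c: len(s) for c, s in reference.genome.items()}
    out: dict[str, list[AlignedRead]] = {}
    for genotype in GENOTYPES:
        for rep in range(config.replicates):
            sample = f"{genotype}_rep{rep + 1}"
            reads: list[AlignedRead] = []
            for gene in reference.annotation:
                n_bg = _nb_draw(rng, config.background_mean, config.dispersion)
                if n_bg:
                    sizes = _draw_sizes(rng, n_bg, config)
                    lo = gene.start
                    hi = gene.end - int(sizes.max())
                    starts = rng.integers(lo, max(lo + 1, hi), size=n_bg)
                    strands = rng.choice(["+", "-"], size=n_bg)
                    for st, sz, sd in zip(starts, sizes, strands):
                        reads.append(AlignedRead(gene.chrom, int(st),
                                                 int(st) + int(sz), str(sd), sample))
            for locus in truth:
                mean = locus.expected_means[genotype]
                n_sig = _nb_draw(rng, mean, config.dispersion)
                if not n_sig:
                    continue
                sizes = _draw_sizes(rng, n_sig, config)
                strands = rng.choice(["+", "-"], size=n_sig)
                if locus.direction == "5p":
                    side = np.zeros(n_sig, dtype=bool)
                elif locus.direction == "3p":
                    side = np.ones(n_sig, dtype=bool)
                else:
                    side = rng.random(n_sig) < 0.5
                offsets = rng.integers(1, config.peak_halfwidth + 1, size=n_sig)
                L = chrom_lengths[locus.chrom]
                for sz, sd, is3, off in zip(sizes, strands, side, offsets):
                    sz = int(sz)
                    # place the 5' end strictly on the chosen side of c
                    p5 = locus.cleavage + int(off) - 1 if is3 else locus.cleavage - int(off)
                    start = p5 if sd == "+" else p5 - sz + 1
                    start = int(np.clip(start, 0, L - sz))
                    reads.append(AlignedRead(locus.chrom, start, start + sz,
                                             str(sd), sample))
            out[sample] = reads
    library_sizes = {s: len(r) for s, r in out.items()}
    return out, library_sizes


def truth_to_frame(truth: list[PlantedLocus]) -> pd.DataFrame:
    rows = []
    for loc in truth:
        row = {"gene_id": loc.gene_id, "chrom": loc.chrom,
               "cleavage": loc.cleavage, "direction": loc.direction,
               "mirna_name": loc.mirna_name,
               "is_mirna_target": loc.is_mirna_target}
        for g in GENOTYPES:
            row[f"mean_{g}"] = loc.expected_means[g]
        rows.append(row)
    return pd.DataFrame(rows)


def write_truth(truth: list[PlantedLocus], path: str | os.PathLike) -> None:
    truth_to_frame(truth).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# 3'-RACE clones
# ---------------------------------------------------------------------------

def simulate_race_clones(fragment_sequence: str, n_clones: int,
                         tail_spectrum: dict[str, float],
                         trim_dist: dict[int, float] | None = None,
                         seed: int = 0) -> tuple[dict[str, str], list[str]]:
    """Clones = (optionally 3'-trimmed) fragment prefix + sampled tail.

    ``tail_spectrum`` maps tail strings (possibly "") to probabilities;
    ``trim_dist`` maps the number of 3' nucleotides removed to probabilities
    (default: no trimming).  Returns (clone FASTA dict, truth tails).
    """
    fragment = to_rna(fragment_sequence)
    if not fragment:
        raise ConfigurationError("empty fragment sequence")
    if not tail_spectrum:
        raise ConfigurationError("tail_spectrum must be non-empty")
    rng = np.random.default_rng(seed)
    tails = list(tail_spectrum)
    t_probs = np.array([tail_spectrum[t] for t in tails], dtype=float)
    t_probs /= t_probs.sum()
    if trim_dist:
        trims = list(trim_dist)
        r_probs = np.array([trim_dist[k] for k in trims], dtype=float)
        r_probs /= r_probs.sum()
    else:
        trims, r_probs = [0], np.array([1.0])

    clones: dict[str, str] = {}
    truth_tails: list[str] = []
    for i in range(n_clones):
        tail = to_rna(tails[int(rng.choice(len(tails), p=t_probs))])
        trim = int(trims[int(rng.choice(len(trims), p=r_probs))])
        if trim >= len(fragment):
            raise ConfigurationError("trim length exceeds fragment length")
        body = fragment[: len(fragment) - trim]
        clones[f"clone{i + 1:04d}"] = body + tail
        truth_tails.append(tail)
    return clones, truth_tails
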