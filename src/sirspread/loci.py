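"""Merge significant windows into loci, attach genes, test target enrichment."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .sio import ConfigurationError, GeneAnnotation, TargetSiteRecord


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    direction: str
    windows: list[tuple[str, int, int, int]] = field(default_factory=list)  # +size
    gene_ids: list[str] = field(default_factory=list)
    is_mirna_target: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    table: tuple[int, int, int, int]  # (a, b, c, d)
    odds_ratio: float  # NaN when undefined
    p_one_sided: float
    p_two_sided: float


def merge_windows(significant: pd.DataFrame, gap: int = 0) -> list[Locus]:
    """Union significant windows of the same direction into loci.

    Windows (across all size classes) merge when their intervals overlap or
    lie within ``gap`` nt; opposite-direction windows never merge.
    """
    loci: list[Locus] = []
    if len(significant) == 0:
        return loci
    sig = significant[significant["significant"]]
    for (chrom, direction), group in sig.groupby(["chrom", "direction"], sort=True):
        intervals = group.sort_values(["start", "end"])
        current: Locus | None = None
        for row in intervals.itertuples():
            if current is not None and row.start <= current.end + gap:
                current.end = max(current.end, row.end)
                current.windows.append((chrom, row.start, row.end, row.size))
            else:
                if current is not None:
                    loci.append(current)
                current = Locus(chrom, row.start, row.end, direction,
                                [(chrom, row.start, row.end, row.size)])
        if current is not None:
            loci.append(current)
    loci.sort(key=lambda l: (l.chrom, l.start, l.direction))
    return loci


def annotate_loci(loci: list[Locus], annotation: GeneAnnotation,
                  target_sites: list[TargetSiteRecord]) -> list[Locus]:
    """Attach overlapping gene ids (any-overlap) and the miRNA-target flag.

    A locus is a miRNA-target locus iff it overlaps >= 1 nt of a gene that
    carries a target-site record.
    """
    target_genes = {ts.transcript_id for ts in target_sites}
    by_chrom: dict[str, list] = {}
    for gene in annotation:
        by_chrom.setdefault(gene.chrom, []).append(gene)
    for locus in loci:
        hits = [g.gene_id for g in by_chrom.get(locus.chrom, [])
                if g.start < locus.end and locus.start < g.end]
        locus.gene_ids = sorted(hits)
        locus.is_mirna_target = any(g in target_genes for g in hits)
    return loci


def enrichment_test(locus_genes: set[str], gene_universe: set[str],
                    target_genes: set[str]) -> EnrichmentResult:
    """Fisher's exact test for miRNA-target enrichment among locus genes.

    2x2 table over genes: a = locus & target, b = locus - target,
    c = target - locus, d = the rest.  One-sided p is the hypergeometric
    upper tail; the two-sided p sums every table (with the same margins)
    whose probability does not exceed the observed one.
    """
    if not gene_universe:
        raise ConfigurationError("empty gene universe")
    if not target_genes <= gene_universe:
        raise ConfigurationError("target genes not contained in universe")
    if not locus_genes <= gene_universe:
        raise ConfigurationError("locus genes not contained in universe")
    a = len(locus_genes & target_genes)
    b = len(locus_genes - target_genes)
    c = len(target_genes - locus_genes)
    d = len(gene_universe) - a - b - c

    n_univ = len(gene_universe)
    n_target = len(target_genes)
    n_locus = len(locus_genes)
    if n_target == 0 or n_locus == 0:
        return EnrichmentResult((a, b, c, d), float("nan"), 1.0, 1.0)

    dist = hypergeom(n_univ, n_target, n_locus)
    p_one = float(dist.sf(a - 1))
    k_lo = max(0, n_locus - (n_univ - n_target))
    k_hi = min(n_target, n_locus)
    support = np.arange(k_lo, k_hi + 1)
    pmf = dist.pmf(support)
    p_obs = dist.pmf(a)
    p_two = float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-10)].sum()))

    odds = float("nan") if b == 0 or c == 0 else (a * d) / (b * c)
    return EnrichmentResult((a, b, c, d), odds, min(p_one, 1.0), p_two)


def loci_to_frame(loci: list[Locus]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.chrom, l.start, l.end, l.direction, ",".join(l.gene_ids),
          l.is_mirna_target) for l in loci],
        columns=["chrom", "start", "end", "direction", "genes", "is_target"])
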