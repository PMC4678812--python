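"""Cleavage coordinates, per-position siRNA profiles and spreading calls.

The cleavage convention is the standard slicer geometry: the small RNA's 5'
end (position 1) pairs the site's 3'-most nucleotide and the scissile bond
lies between the target nucleotides paired to positions 10 and 11, so the
target nucleotide pairing position 10 is the first nucleotide of the 3'
fragment.  A read 5' end exactly at the cleavage coordinate belongs to the
3' side (half-open convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .sio import AlignedRead, ConfigurationError, Gene, TargetSiteRecord


@dataclass(frozen=True)
class CleavageSite:
    transcript_id: str
    mirna_name: str
    cleavage: int  # 0-based transcript index of the first nt of the 3' fragment
    site_start: int
    site_end: int

    def __post_init__(self) -> None:
        if not self.site_start <= self.cleavage < self.site_end:
            raise ValueError("cleavage coordinate outside site interval")
        if self.cleavage <= 0:
            raise ValueError("cleavage coordinate must be > 0")


@dataclass
class CleavageProfile:
    site: CleavageSite
    flank: int
    # per (offset-from-c, size, strand) 5'-end counts; offsets in [-flank, flank)
    counts: dict[tuple[int, int, str], int] = field(default_factory=dict)
    n5: int = 0
    n3: int = 0

    @property
    def total(self) -> int:
        return self.n5 + self.n3

    def normalized(self, library_size: int, per: float = 1e7) -> dict[tuple[int, int, str], float]:
        """Counts rescaled to reads per ``per`` (default 10 million) mapped reads."""
        if library_size <= 0:
            raise ConfigurationError("library size must be positive")
        scale = per / library_size
        return {k: v * scale for k, v in self.counts.items()}


@dataclass(frozen=True)
class DirectionCall:
    call: str  # {"five_prime", "three_prime", "bidirectional", "none"}
    fraction: float  # max(n5, n3) / (n5 + n3); NaN when total = 0
    n5: int
    n3: int
    min_reads: int
    exclusivity: float


def derive_cleavage_site(site: TargetSiteRecord) -> CleavageSite:
    """Place the cleavage coordinate from the site interval.

    With 1-based closed site coordinates [s, e], cleavage falls between
    e - 10 and e - 9, i.e. c (0-based) = e - 10.  The site must cover at
    least small-RNA positions 1..11 (>= 11 nt).
    """
    if site.length < 11:
        raise ConfigurationError(
            f"site on {site.transcript_id} shorter than 11 nt")
    c = site.end - 10  # site.end is the exclusive 0-based bound == 1-based e
    return CleavageSite(site.transcript_id, site.mirna_name, c,
                        site.start, site.end)


def build_profile(alignments: list[AlignedRead], gene: Gene, site: CleavageSite,
                  flank: int = 500) -> CleavageProfile:
    """Per-position 5'-end counts around the cleavage coordinate.

    ``gene`` supplies the transcript-to-genome mapping (unspliced genes:
    identity offset from gene.start).  Reads whose 5' end falls within
    [c - flank, c + flank) in genome space are tallied per offset, size and
    strand; n5 counts 5' ends strictly left of c, n3 the rest.
    """
    if not gene.start <= gene.start + site.cleavage <= gene.end:
        raise ConfigurationError("cleavage site outside transcript interval")
    c_genome = gene.start + site.cleavage
    profile = CleavageProfile(site=site, flank=flank)
    for read in alignments:
        if read.chrom != gene.chrom:
            continue
        offset = read.five_prime - c_genome
        if not -flank <= offset < flank:
            continue
        key = (offset, read.length, read.strand)
        profile.counts[key] = profile.counts.get(key, 0) + 1
        if offset < 0:
            profile.n5 += 1
        else:
            profile.n3 += 1
    return profile


def classify_direction(profile: CleavageProfile, min_reads: int = 10,
                       exclusivity: float = 0.9) -> DirectionCall:
    """Call the side of siRNA spreading from side totals.

    none unless strictly more than ``min_reads`` reads are present;
    five_prime/three_prime when that side holds at least the ``exclusivity``
    fraction; else bidirectional.
    """
    if not 0.5 <= exclusivity <= 1.0:
        raise ConfigurationError("exclusivity must lie in [0.5, 1]")
    total = profile.total
    if total == 0:
        return DirectionCall("none", float("nan"), 0, 0, min_reads, exclusivity)
    frac = max(profile.n5, profile.n3) / total
    if total <= min_reads:
        call = "none"
    elif profile.n5 / total >= exclusivity:
        call = "five_prime"
    elif profile.n3 / total >= exclusivity:
        call = "three_prime"
    else:
        call = "bidirectional"
    return DirectionCall(call, frac, profile.n5, profile.n3, min_reads, exclusivity)


def profile_to_frame(profile: CleavageProfile,
                     library_size: int | None = None) -> pd.DataFrame:
    """Long-form profile table (offset, size, strand, count, normalized)."""
    rows = sorted(profile.counts.items())
    df = pd.DataFrame(
        [(off, size, strand, n) for (off, size, strand), n in rows],
        columns=["offset", "size", "strand", "count"])
    if library_size is not None:
        df["per_10M"] = df["count"] * 1e7 / library_size
    return df


def composite_bounds(sites: list[CleavageSite]) -> tuple[int, int]:
    """Inter-site region bounds for multi-site targets (PHO2-like).

    Returns (5'-most cleavage coordinate, 3'-most cleavage coordinate);
    reads between these bounds belong to the inter-site region and are
    reported separately from per-site profiles.
    """
    if not sites:
        raise ConfigurationError("no sites given")
    coords = [s.cleavage for s in sites]
    return min(coords), max(coords)
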