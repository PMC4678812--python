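"""Genome-wide scanning windows and size-stratified read counting.

Windows are fixed length (default 300 nt) and overlap by ``window_length -
step`` (default 150 nt).  Reads are counted once per window containing their
5'-end coordinate, stratified by read size (default 19-26 nt); with the
default 2x overlap every interior read lands in exactly two windows.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sio import AlignedRead, ConfigurationError


@dataclass(frozen=True)
class WindowConfig:
    window_length: int = 300
    step: int = 150
    size_min: int = 19
    size_max: int = 26

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_length:
            raise ConfigurationError(
                f"require 0 < step <= window_length, got step={self.step}, "
                f"window_length={self.window_length}"
            )
        if self.size_min > self.size_max:
            raise ConfigurationError("size_min must be <= size_max")

    @property
    def sizes(self) -> range:
        return range(self.size_min, self.size_max + 1)


@dataclass
class WindowCountMatrix:
    """Integer counts per (window x read-size x sample) plus library sizes."""

    windows: list[tuple[str, int, int]]
    sizes: list[int]
    samples: list[str]
    counts: np.ndarray  # shape (n_windows, n_sizes, n_samples)
    library_sizes: dict[str, int]
    n_skipped: int = 0
    _window_index: dict[tuple[str, int, int], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.windows), len(self.sizes), len(self.samples)):
            raise ValueError("counts tensor shape inconsistent with axes")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        self._window_index = {w: i for i, w in enumerate(self.windows)}

    def window_id(self, window: tuple[str, int, int]) -> int:
        return self._window_index[window]

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: chrom, start, end, size, one column per sample."""
        rows = []
        for wi, (chrom, start, end) in enumerate(self.windows):
            for si, size in enumerate(self.sizes):
                rows.append((chrom, start, end, size, *self.counts[wi, si, :]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "size", *self.samples])

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write("#library_sizes\t" + "\t".join(
                f"{s}={self.library_sizes[s]}" for s in self.samples) + "\n")
        df.to_csv(path, sep="\t", index=False, mode="a")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "WindowCountMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith("#library_sizes"):
                raise ValueError("missing #library_sizes header")
            library_sizes = {}
            for item in header.split("\t")[1:]:
                name, value = item.rsplit("=", 1)
                library_sizes[name] = int(value)
            df = pd.read_csv(fh, sep="\t")
        samples = [c for c in df.columns if c not in ("chrom", "start", "end", "size")]
        windows = sorted(
            {(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()},
            key=lambda w: (w[0], w[1]),
        )
        sizes = sorted(df["size"].unique().tolist())
        widx = {w: i for i, w in enumerate(windows)}
        sidx = {s: i for i, s in enumerate(sizes)}
        counts = np.zeros((len(windows), len(sizes), len(samples)), dtype=np.int64)
        for row in df.itertuples():
            wi = widx[(row.chrom, int(row.start), int(row.end))]
            si = sidx[int(row.size)]
            for j, sample in enumerate(samples):
                counts[wi, si, j] = getattr(row, sample)
        return cls(windows, sizes, samples, counts, library_sizes)


def make_windows(chrom_lengths: dict[str, int],
                 config: WindowConfig = WindowConfig()) -> list[tuple[str, int, int]]:
    """Tile each chromosome with overlapping windows.

    Starts are 0, step, 2*step, ... while start < L; ends are clipped at L
    (truncated terminal windows retained).
    """
    windows: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length <= 0:
            raise ConfigurationError(f"chromosome {chrom!r} has non-positive length")
        start = 0
        while start < length:
            windows.append((chrom, start, min(start + config.window_length, length)))
            start += config.step
    return windows


def count_reads(alignments: Iterable[AlignedRead],
                windows: Sequence[tuple[str, int, int]],
                config: WindowConfig = WindowConfig(),
                samples: Sequence[str] | None = None,
                warn=None) -> WindowCountMatrix:
    """Count reads per window, read size and sample.

    A read is assigned to every window containing its 5'-end coordinate;
    reads with length outside [size_min, size_max] are excluded from counts
    and library sizes.  Reads on chromosomes absent from the window list are
    skipped with a warning and tallied in ``n_skipped``.
    """
    # window starts lie on the step grid, so containment lookups are O(1)
    chrom_windows: dict[str, dict[int, tuple[int, int]]] = {}
    for wi, (chrom, start, end) in enumerate(windows):
        chrom_windows.setdefault(chrom, {})[start] = (end, wi)

    alignments = list(alignments)
    if samples is None:
        seen = dict.fromkeys(r.sample_id for r in alignments)
        samples = list(seen)
    sample_index = {s: i for i, s in enumerate(samples)}
    sizes = list(config.sizes)
    size_index = {s: i for i, s in enumerate(sizes)}

    counts = np.zeros((len(windows), len(sizes), len(samples)), dtype=np.int64)
    library_sizes = {s: 0 for s in samples}
    n_skipped = 0

    for read in alignments:
        if read.length < config.size_min or read.length > config.size_max:
            continue
        if read.chrom not in chrom_windows:
            n_skipped += 1
            if warn is not None:
                warn(f"read on unknown chromosome {read.chrom!r} skipped")
            continue
        if read.sample_id not in sample_index:
            raise ConfigurationError(f"sample {read.sample_id!r} not in sample list")
        library_sizes[read.sample_id] += 1
        pos = read.five_prime
        si = size_index[read.length]
        sj = sample_index[read.sample_id]
        # windows with start = k*step containing pos: derived directly from
        # k*step <= pos < k*step + window_length
        k_lo = max(0, (pos - config.window_length) // config.step + 1)
        k_hi = pos // config.step
        starts = chrom_windows[read.chrom]
        for k in range(k_lo, k_hi + 1):
            hit = starts.get(k * config.step)
            if hit is not None and pos < hit[0]:
                counts[hit[1], si, sj] += 1

    return WindowCountMatrix(list(windows), sizes, list(samples), counts,
                             library_sizes, n_skipped)
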