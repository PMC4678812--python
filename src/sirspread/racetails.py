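"""Non-templated 3' tails of RACE clones against a reference fragment.

A clone is matched against the expected 5'-cleavage fragment from its 5'
end; the match is maximal-templated (a clone nucleotide identical to the
next reference nucleotide is always called templated), and the remaining
suffix is the tail.  Clones matching fewer than ``min_match`` nucleotides
are off-target (non-fragment), as are clones whose continuation past the
reference 3' end is templated by downstream reference context (uncleaved
mRNA), when such context is provided.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .sio import ConfigurationError, to_rna

TAIL_CLASSES = ("U", "A", "C", "G")


@dataclass(frozen=True)
class RaceClone:
    clone_id: str
    sequence: str  # RNA alphabet
    matched_length: int
    tail: str
    category: str  # {"fragment", "non-fragment"}

    def __post_init__(self) -> None:
        if self.category == "fragment" and self.matched_length + len(self.tail) != len(self.sequence):
            raise ValueError("matched length + tail length must equal clone length")


@dataclass
class TailSummary:
    n_clones: int = 0
    n_fragment_clones: int = 0
    n_tailed: int = 0
    spectrum: dict[str, int] = field(default_factory=dict)
    class_totals: dict[str, int] = field(default_factory=dict)


def extract_tail(clone_seq: str, reference_fragment: str, min_match: int = 20,
                 clone_id: str = "", downstream_context: str = "") -> RaceClone:
    """Split a clone into templated body and non-templated tail."""
    if not clone_seq:
        raise ConfigurationError("empty clone sequence")
    if not reference_fragment:
        raise ConfigurationError("empty reference fragment")
    clone = to_rna(clone_seq)
    reference = to_rna(reference_fragment)
    context = to_rna(downstream_context) if downstream_context else ""

    matched = 0
    limit = min(len(clone), len(reference))
    while matched < limit and clone[matched] == reference[matched]:
        matched += 1
    tail = clone[matched:]

    if matched < min(min_match, len(reference)):
        return RaceClone(clone_id, clone, matched, "", "non-fragment")
    if (context and matched == len(reference) and tail
            and tail == context[: len(tail)]):
        # continuation templated by downstream sequence: uncleaved mRNA
        return RaceClone(clone_id, clone, matched, "", "non-fragment")
    return RaceClone(clone_id, clone, matched, tail, "fragment")


def classify_tail(tail: str) -> str:
    """Class of a non-empty tail: strictly most frequent nucleotide.

    Ties go to the class of the first tail nucleotide.  Multi-nucleotide
    composition without a unique winner other than by the tie rule is the
    'mixed'-free convention used in the summary groupings (e.g. UUA -> U,
    AAC -> A).
    """
    if not tail:
        raise ConfigurationError("empty tail has no class")
    tail = to_rna(tail)
    counts = Counter(tail)
    ranked = counts.most_common()
    if len(ranked) == 1 or ranked[0][1] > ranked[1][1]:
        return ranked[0][0]
    return tail[0]


def summarize(clones: list[RaceClone]) -> TailSummary:
    """Aggregate clone-level results into a Table-1-style summary."""
    summary = TailSummary()
    summary.n_clones = len(clones)
    summary.class_totals = {c: 0 for c in TAIL_CLASSES}
    for clone in clones:
        if clone.category != "fragment":
            continue
        summary.n_fragment_clones += 1
        if clone.tail:
            summary.n_tailed += 1
            summary.spectrum[clone.tail] = summary.spectrum.get(clone.tail, 0) + 1
            summary.class_totals[classify_tail(clone.tail)] += 1
    return summary


def clones_to_frame(clones: list[RaceClone]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.clone_id, c.matched_length, c.tail,
          classify_tail(c.tail) if c.tail else "", c.category) for c in clones],
        columns=["clone_id", "matched_len", "tail", "tail_class", "category"])


def summary_to_frame(summary: TailSummary) -> pd.DataFrame:
    rows = [("n_clones", summary.n_clones),
            ("n_fragment_clones", summary.n_fragment_clones),
            ("n_tailed", summary.n_tailed)]
    rows += [(f"class_{c}", summary.class_totals.get(c, 0)) for c in TAIL_CLASSES]
    rows += [(f"tail:{t}", n) for t, n in sorted(summary.spectrum.items())]
    return pd.DataFrame(rows, columns=["field", "value"])
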