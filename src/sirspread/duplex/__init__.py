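"""Minimum hybridization free energy between two RNA strands.

A dynamic program over intermolecular pairings only (no hairpins): stacks
are scored with nearest-neighbor dH/dS terms, interruptions with bulge and
internal-loop length penalties, helix ends with terminal AU/GU penalties,
plus one duplex initiation term.  If no pairing reaches a negative free
energy the result is "no duplex" (dG = 0, empty trace).

Both strands are given 5'->3'; a pair (i, j) joins strand A position i to
strand B position j, and consecutive stacked pairs are (i, j), (i+1, j-1)
(antiparallel helix).
"""

from __future__ import annotations

from dataclasses import dataclass

from ..sio import ConfigurationError
from .params import GU_PAIRS, WC_PAIRS, NNParameterSet, load_params

__all__ = ["DuplexResult", "FragmentEnergies", "duplex_dG", "fragment_energies",
           "load_params", "NNParameterSet"]

_RNA = set("ACGU")


@dataclass(frozen=True)
class DuplexResult:
    dG: float  # kcal/mol at temperature
    trace: tuple[tuple[int, int], ...]  # paired (i, j), i ascending
    temperature: float  # K

    def __post_init__(self) -> None:
        if self.dG > 0:
            raise ValueError("a reported duplex must have dG <= 0")


@dataclass(frozen=True)
class FragmentEnergies:
    """Pairing energies of the two miRNA halves against the two fragments.

    dG5: miRNA 3' half (positions 11..L) vs the 5'-fragment part of the
    site; dG3: miRNA 5' half (positions 1..10) vs the 3'-fragment part.
    """

    dG5: float
    dG3: float
    temperature: float

    @property
    def delta(self) -> float:
        return self.dG5 - self.dG3


def _check_rna(seq: str, name: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _RNA
    if bad:
        raise ConfigurationError(
            f"non-RNA characters in {name}: {''.join(sorted(bad))}")
    return seq


def _can_pair(x: str, y: str, allow_gu: bool) -> bool:
    if (x, y) in WC_PAIRS:
        return True
    return allow_gu and (x, y) in GU_PAIRS


def duplex_dG(strand_a: str, strand_b: str,
              params: NNParameterSet | None = None,
              temperature: float = 294.15,
              allow_gu: bool = True,
              max_loop: int = 30) -> DuplexResult:
    """Minimum free energy of intermolecular hybridization.

    ``temperature`` in Kelvin (default 294.15 K = 21 C).  Returns the
    optimal energy with one optimal pairing trace; dG = 0 with an empty
    trace when no duplex is favourable.
    """
    if params is None:
        params = load_params()
    a = _check_rna(strand_a, "strand A")
    b = _check_rna(strand_b, "strand B")
    if not a or not b:
        raise ConfigurationError("strands must have length >= 1")
    T = temperature
    n, m = len(a), len(b)
    init = params.init_dG(T)

    INF = float("inf")
    # E[i][j]: best energy of a duplex whose 3'-most pair on A is (i, j),
    # including initiation and the penalty at the helix's other end, but
    # not the terminal penalty at (i, j) itself.
    E = [[INF] * m for _ in range(n)]
    parent: list[list[tuple[int, int] | None]] = [[None] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            if not _can_pair(a[i], b[j], allow_gu):
                continue
            best = init + params.terminal_dG(a[i], b[j], T)
            best_parent = None
            for k in range(max(0, i - max_loop - 1), i):
                row = E[k]
                ga = i - k - 1
                for l in range(j + 1, min(m, j + max_loop + 2)):
                    prev = row[l]
                    if prev == INF:
                        continue
                    gb = l - j - 1
                    if ga == 0 and gb == 0:
                        step = params.stack_dG(a[k] + a[i] + "/" + b[l] + b[j], T)
                    elif ga == 0 or gb == 0:
                        step = params.bulge_dG(ga + gb, T)
                    else:
                        step = params.internal_dG(ga + gb, T)
                    cand = prev + step
                    if cand < best:
                        best = cand
                        best_parent = (k, l)
            E[i][j] = best
            parent[i][j] = best_parent

    best_dg = 0.0
    best_end: tuple[int, int] | None = None
    for i in range(n):
        for j in range(m):
            if E[i][j] == INF:
                continue
            total = E[i][j] + params.terminal_dG(a[i], b[j], T)
            if total < best_dg:
                best_dg = total
                best_end = (i, j)

    if best_end is None:
        return DuplexResult(0.0, (), T)
    trace: list[tuple[int, int]] = []
    node: tuple[int, int] | None = best_end
    while node is not None:
        trace.append(node)
        node = parent[node[0]][node[1]]
    trace.reverse()
    return DuplexResult(best_dg, tuple(trace), T)


def fragment_energies(mirna: str, site_sequence: str, cleavage_offset: int,
                      params: NNParameterSet | None = None,
                      temperature: float = 294.15,
                      allow_gu: bool = True,
                      mode: str = "halves") -> FragmentEnergies:
    """Pairing energies of the miRNA against the two cleavage fragments.

    ``site_sequence`` is the target-site region 5'->3' on the transcript
    and ``cleavage_offset`` the 0-based index (within the site) of the
    first nucleotide of the 3' fragment.  ``mode='halves'`` scores miRNA
    positions 11..L against the 5'-fragment part and positions 1..10
    against the 3'-fragment part; ``mode='full'`` scores the full-length
    miRNA against each part.
    """
    mirna = _check_rna(mirna, "miRNA")
    site = _check_rna(site_sequence, "site")
    if not 0 < cleavage_offset < len(site):
        raise ConfigurationError(
            f"cleavage offset {cleavage_offset} inconsistent with site "
            f"length {len(site)}")
    if len(mirna) < 11:
        raise ConfigurationError("miRNA shorter than 11 nt")
    if mode not in ("halves", "full"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    part5 = site[:cleavage_offset]
    part3 = site[cleavage_offset:]
    if mode == "halves":
        query5 = mirna[10:]  # positions 11..L pair the 5' fragment
        query3 = mirna[:10]  # positions 1..10 pair the 3' fragment
    else:
        query5 = query3 = mirna
    dg5 = duplex_dG(query5, part5, params, temperature, allow_gu).dG
    dg3 = duplex_dG(query3, part3, params, temperature, allow_gu).dG
    return FragmentEnergies(dg5, dg3, temperature)
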