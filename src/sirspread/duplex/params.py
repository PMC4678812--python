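"""Nearest-neighbor parameter set: loading, expansion and energy terms.

The parameter table is a versioned TSV shipped with the package; swapping
tables requires no code change.  Stack free energies are temperature-scaled
via dG(T) = dH - T * dS / 1000; loop and bulge initiation penalties carry
dG37 only and are treated as purely entropic, dG(T) = dG37 * T / T37.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

GAS_CONSTANT = 0.0019872  # kcal / (mol * K)
T37 = 310.15

WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU_PAIRS = {("G", "U"), ("U", "G")}


def _symmetric_key(key: str) -> str:
    # 5'XY3'/3'WZ5' is the same physical stack as 5'ZW3'/3'YX5'
    top, bottom = key.split("/")
    return bottom[::-1] + "/" + top[::-1]


@dataclass
class NNParameterSet:
    """Stacking dH/dS terms plus initiation, terminal and loop penalties."""

    stacks: dict[str, tuple[float, float]]
    wobble_default: tuple[float, float]
    init: tuple[float, float]
    term_au: tuple[float, float]
    bulge_dG37: dict[int, float]
    internal_dG37: dict[int, float]
    provenance: str = ""
    _max_bulge: int = field(init=False, default=0)
    _max_internal: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        expanded = dict(self.stacks)
        for key, value in self.stacks.items():
            expanded.setdefault(_symmetric_key(key), value)
        self.stacks = expanded
        self._max_bulge = max(self.bulge_dG37)
        self._max_internal = max(self.internal_dG37)

    # -- energy terms -------------------------------------------------------

    def stack_dG(self, key: str, temperature: float) -> float:
        """Free energy of the stack 5'XY3'/3'WZ5' at ``temperature`` (K)."""
        if key in self.stacks:
            dh, ds = self.stacks[key]
        else:
            dh, ds = self.wobble_default
        return dh - temperature * ds / 1000.0

    def init_dG(self, temperature: float) -> float:
        dh, ds = self.init
        return dh - temperature * ds / 1000.0

    def terminal_dG(self, x: str, y: str, temperature: float) -> float:
        """Helix-end penalty; applies to AU and GU closing pairs."""
        if (x, y) in WC_PAIRS and x in "GC":
            return 0.0
        dh, ds = self.term_au
        return dh - temperature * ds / 1000.0

    def bulge_dG(self, length: int, temperature: float) -> float:
        scale = temperature / T37
        if length in self.bulge_dG37:
            return self.bulge_dG37[length] * scale
        # Jacobson-Stockmayer extrapolation beyond the tabulated lengths
        base = self.bulge_dG37[self._max_bulge] * scale
        return base + 1.75 * GAS_CONSTANT * temperature * math.log(length / self._max_bulge)

    def internal_dG(self, length: int, temperature: float) -> float:
        scale = temperature / T37
        if length in self.internal_dG37:
            return self.internal_dG37[length] * scale
        base = self.internal_dG37[self._max_internal] * scale
        return base + 1.75 * GAS_CONSTANT * temperature * math.log(length / self._max_internal)


def load_params(path: str | None = None) -> NNParameterSet:
    """Load a parameter TSV; defaults to the bundled table."""
    if path is None:
        ref = resources.files("sirspread.duplex").joinpath("data/nn_params.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()

    stacks: dict[str, tuple[float, float]] = {}
    wobble = init = term = None
    bulge: dict[int, float] = {}
    internal: dict[int, float] = {}
    provenance: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            provenance.append(line.lstrip("# "))
            continue
        if not line.strip() or line.startswith("kind\t"):
            continue
        parts = line.split("\t")
        kind, key, dh_s, ds_s, dg37_s = parts[:5]
        if kind == "stack":
            stacks[key] = (float(dh_s), float(ds_s))
        elif kind == "wobble_default":
            wobble = (float(dh_s), float(ds_s))
        elif kind == "init":
            init = (float(dh_s), float(ds_s))
        elif kind == "term_au":
            term = (float(dh_s), float(ds_s))
        elif kind == "bulge":
            bulge[int(key)] = float(dg37_s)
        elif kind == "internal":
            internal[int(key)] = float(dg37_s)
        else:
            raise ValueError(f"unknown parameter kind {kind!r}")
    if None in (wobble, init, term) or not stacks or not bulge or not internal:
        raise ValueError("incomplete nearest-neighbor parameter table")
    return NNParameterSet(stacks, wobble, init, term, bulge, internal,
                          provenance="\n".join(provenance))
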