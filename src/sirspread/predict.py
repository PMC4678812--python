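"""Predict the side of siRNA spreading from fragment pairing energies.

The predicted side is the cleavage fragment least stably base-paired to the
miRNA (less negative dG).  When the two energies are similar (within the
tolerance tau) the prediction defaults to five_prime, reflecting the
seed-helicity bias of AGO-bound small RNAs that makes computed 3'-fragment
pairing systematically too weak.  Significance of k correct predictions out
of n is the exact binomial upper tail at p0 (default 0.5), computed in
rational arithmetic for n <= 64.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from scipy.stats import binom

from .duplex import FragmentEnergies
from .sio import ConfigurationError

_EXACT_N_MAX = 64


@dataclass(frozen=True)
class PredictConfig:
    tau: float = 2.0  # kcal/mol similarity tolerance
    p0: float = 0.5

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ConfigurationError("tau must be >= 0")
        if not 0 < self.p0 < 1:
            raise ConfigurationError("p0 must lie in (0, 1)")


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    p0: float
    upper_tail: float


def predict_side(energies: FragmentEnergies,
                 config: PredictConfig = PredictConfig()) -> str:
    """Return "five_prime" or "three_prime".

    |dG5 - dG3| <= tau -> five_prime (similarity rule); otherwise the side
    whose fragment is least stably paired (greater, i.e. less negative dG).
    """
    dg5, dg3 = energies.dG5, energies.dG3
    if dg5 is None or dg3 is None or dg5 != dg5 or dg3 != dg3:
        raise ConfigurationError("fragment energies undefined")
    if abs(dg5 - dg3) <= config.tau:
        return "five_prime"
    return "five_prime" if dg5 > dg3 else "three_prime"


def evaluate_predictions(predictions: dict[str, str],
                         observed_calls: dict[str, str],
                         eligible: set[str] | None = None) -> tuple[int, int]:
    """Count correct predictions among eligible transcripts.

    Eligible transcripts are those in ``eligible`` (default: all with a
    prediction) whose observed call is an exclusive direction
    (five_prime/three_prime); bidirectional and none calls are excluded
    from n.  Returns (k, n).
    """
    if eligible is None:
        eligible = set(predictions)
    k = n = 0
    for tid in sorted(eligible):
        call = observed_calls.get(tid)
        if call not in ("five_prime", "three_prime"):
            continue
        if tid not in predictions:
            continue
        n += 1
        if predictions[tid] == call:
            k += 1
    return k, n


def binomial_upper_tail(k: int, n: int, p0: float = 0.5) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p0).

    Rational arithmetic (integer binomial coefficients) for n <= 64,
    floating point beyond.
    """
    if not isinstance(k, int) or not isinstance(n, int):
        raise ConfigurationError("k and n must be integers")
    if not 0 <= k <= n:
        raise ConfigurationError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ConfigurationError("p0 must lie in (0, 1)")
    if n <= _EXACT_N_MAX:
        p = Fraction(p0)
        total = sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))
        return float(total)
    return float(binom.sf(k - 1, n, p0))


def binomial_test(k: int, n: int, p0: float = 0.5) -> BinomialTestResult:
    return BinomialTestResult(k, n, p0, binomial_upper_tail(k, n, p0))


def tau_sensitivity(energy_table: dict[str, FragmentEnergies],
                    observed_calls: dict[str, str],
                    eligible: set[str] | None = None,
                    taus: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0),
                    p0: float = 0.5) -> list[dict]:
    """(k, n, tail probability) across a grid of tau values."""
    rows = []
    for tau in taus:
        config = PredictConfig(tau=tau, p0=p0)
        preds = {tid: predict_side(e, config) for tid, e in energy_table.items()}
        k, n = evaluate_predictions(preds, observed_calls, eligible)
        tail = binomial_upper_tail(k, n, p0) if n > 0 else float("nan")
        rows.append({"tau": tau, "k": k, "n": n, "upper_tail": tail})
    return rows
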