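"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own algorithms: the NB conditional
law is built by enumerating replicate-count compositions with scipy's
nbinom pmf; Fisher probabilities enumerate all 2x2 tables with fixed
margins in exact rational arithmetic; duplex energies enumerate every
non-crossing antiparallel pairing and score it by walking consecutive
pairs.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np
from scipy.stats import nbinom, poisson

from sirspread.duplex.params import GU_PAIRS, WC_PAIRS


# ---------------------------------------------------------------------------
# exact NB test oracle
# ---------------------------------------------------------------------------

def _replicate_pmf(y: np.ndarray, mu: float, phi: float) -> float:
    if phi == 0.0:
        return float(np.prod(poisson.pmf(y, mu)))
    r = 1.0 / phi
    return float(np.prod(nbinom.pmf(y, r, r / (r + mu))))


def nb_conditional_pvalue(counts_a, counts_b, phi: float, mu: float = 3.0) -> float:
    """Two-sided mass-based p-value by exhaustive composition enumeration.

    Enumerates every vector (y_1..y_{nA+nB}) with sum t, weights it by the
    product of iid NB pmfs (any common mu; it cancels on conditioning up to
    numerical error), and aggregates P(S_A = s | t).
    """
    counts_a = np.asarray(counts_a)
    counts_b = np.asarray(counts_b)
    n_a, n_b = len(counts_a), len(counts_b)
    s_obs = int(counts_a.sum())
    t = s_obs + int(counts_b.sum())
    if t == 0:
        return 1.0
    mass = np.zeros(t + 1)
    for y in product(range(t + 1), repeat=n_a + n_b - 1):
        rest = t - sum(y)
        if rest < 0:
            continue
        vec = np.array(y + (rest,))
        mass[int(vec[:n_a].sum())] += _replicate_pmf(vec, mu, phi)
    mass /= mass.sum()
    p_obs = mass[s_obs]
    return float(min(1.0, mass[mass <= p_obs * (1 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# Fisher oracle
# ---------------------------------------------------------------------------

def fisher_enumeration(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """(one-sided upper, two-sided) p by enumerating all tables with the
    observed margins, in exact rational arithmetic."""
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    denom = comb(n, col1)
    k_lo = max(0, col1 - (n - row1))
    k_hi = min(row1, col1)
    probs = {k: Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
             for k in range(k_lo, k_hi + 1)}
    p_obs = probs[a]
    one_sided = sum(p for k, p in probs.items() if k >= a)
    two_sided = sum(p for p in probs.values() if p <= p_obs)
    return float(one_sided), float(min(Fraction(1), two_sided))


# ---------------------------------------------------------------------------
# duplex oracle
# ---------------------------------------------------------------------------

def _pairable(x: str, y: str, allow_gu: bool) -> bool:
    return (x, y) in WC_PAIRS or (allow_gu and (x, y) in GU_PAIRS)


def _score(pairs: list[tuple[int, int]], a: str, b: str, params, T: float) -> float:
    total = params.init_dG(T)
    total += params.terminal_dG(a[pairs[0][0]], b[pairs[0][1]], T)
    total += params.terminal_dG(a[pairs[-1][0]], b[pairs[-1][1]], T)
    for (k, l), (i, j) in zip(pairs, pairs[1:]):
        ga = i - k - 1
        gb = l - j - 1
        if ga == 0 and gb == 0:
            total += params.stack_dG(a[k] + a[i] + "/" + b[l] + b[j], T)
        elif ga == 0 or gb == 0:
            total += params.bulge_dG(ga + gb, T)
        else:
            total += params.internal_dG(ga + gb, T)
    return total


def brute_force_duplex_dG(a: str, b: str, params, temperature: float = 294.15,
                          allow_gu: bool = True) -> float:
    """Minimum energy over all non-crossing antiparallel pairings (<= 0)."""
    n, m = len(a), len(b)
    best = [0.0]

    def extend(pairs: list[tuple[int, int]], i0: int, j0: int) -> None:
        if pairs:
            best[0] = min(best[0], _score(pairs, a, b, params, temperature))
        for i in range(i0, n):
            for j in range(j0, -1, -1):
                if _pairable(a[i], b[j], allow_gu):
                    pairs.append((i, j))
                    extend(pairs, i + 1, j - 1)
                    pairs.pop()

    extend([], 0, m - 1)
    return best[0]


# ---------------------------------------------------------------------------
# binomial oracle
# ---------------------------------------------------------------------------

def binomial_tail_enumeration(k: int, n: int) -> Fraction:
    """P(X >= k) at p = 1/2 by direct outcome counting."""
    return Fraction(sum(comb(n, j) for j in range(k, n + 1)), 2**n)
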