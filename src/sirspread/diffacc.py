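"""Exact two-group negative-binomial test with common dispersion.

The test conditions on the pooled total of a window: with replicate counts
equalized to a common library size, each replicate is modelled NB(mu, phi)
(variance = mu + phi * mu^2).  The group-A sum given the grand total then
follows a beta-binomial-type law obtained by exact convolution of the NB
weights, which for phi = 0 collapses to Binomial(t, nA / (nA + nB)).
Two-sided p-values sum the probability of every outcome at most as likely
as the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .sio import ConfigurationError
from .windows import WindowCountMatrix

_PHI_MAX = 10.0


@dataclass(frozen=True)
class DiffConfig:
    alpha: float = 0.05
    adjust: str = "none"  # {"none", "BH"}
    min_total_count: int = 5
    normalization: str = "total-count"  # {"total-count", "median-of-ratios"}

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.adjust not in ("none", "BH"):
            raise ConfigurationError(f"unknown adjust method {self.adjust!r}")
        if self.normalization not in ("total-count", "median-of-ratios"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    method: str

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


# ---------------------------------------------------------------------------
# normalization / library equalization
# ---------------------------------------------------------------------------

def normalize(counts: np.ndarray, library_sizes: np.ndarray,
              method: str = "total-count") -> np.ndarray:
    """Per-sample scaling factors.

    ``total-count`` returns the library sizes unchanged (they become the
    effective library sizes); ``median-of-ratios`` returns factors with
    geometric mean 1 computed from the median ratio to the row-wise
    geometric-mean reference.
    """
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (library_sizes <= 0).any():
        raise ConfigurationError("every sample needs at least one in-range read")
    if method == "total-count":
        return library_sizes.copy()
    if method != "median-of-ratios":
        raise ConfigurationError(f"unknown normalization {method!r}")
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("median-of-ratios expects a (windows x samples) matrix")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ConfigurationError("no window with all-positive counts for median-of-ratios")
    sub = counts[positive]
    log_ref = np.mean(np.log(sub), axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_ref, axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


def equalize_counts(counts: np.ndarray, library_sizes: np.ndarray) -> np.ndarray:
    """Rescale counts to the geometric-mean library size and round.

    This is the documented stand-in for quantile adjustment: after scaling,
    all samples share one effective library size, as the conditional test
    requires.
    """
    library_sizes = np.asarray(library_sizes, dtype=float)
    if (library_sizes <= 0).any():
        raise ConfigurationError("library sizes must be positive")
    common = np.exp(np.mean(np.log(library_sizes)))
    scaled = np.asarray(counts, dtype=float) * (common / library_sizes)
    return np.rint(scaled).astype(np.int64)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_common_dispersion(counts: np.ndarray, groups: np.ndarray,
                               method: str = "qcml",
                               min_total_count: int = 5) -> DispersionEstimate:
    """Estimate the common NB dispersion phi across windows.

    ``counts`` is (windows x samples), already library-equalized.  The
    ``moments`` method pools method-of-moments estimates across windows and
    groups; ``qcml`` maximizes the summed conditional log-likelihood of
    within-group splits given group totals.  Both estimates are clamped to
    [0, 10].
    """
    counts = np.asarray(counts, dtype=np.int64)
    groups = np.asarray(groups)
    keep = counts.sum(axis=1) >= min_total_count
    counts = counts[keep]
    if counts.shape[0] == 0:
        raise ConfigurationError("all windows removed by min_total_count filter")
    labels = [g for g in dict.fromkeys(groups.tolist()) if (groups == g).sum() >= 2]
    if not labels:
        raise ConfigurationError("need >= 2 replicates in at least one group")

    if method == "moments":
        num = 0.0
        den = 0.0
        for g in labels:
            sub = counts[:, groups == g].astype(float)
            n = sub.shape[1]
            m = sub.mean(axis=1)
            v = sub.var(axis=1, ddof=1)
            w = n - 1
            num += w * np.sum(v - m)
            # m^2 - v/n is an unbiased estimate of mu^2
            den += w * np.sum(np.maximum(m**2 - v / n, 0.0))
        phi = 0.0 if den <= 0 else max(0.0, num / den)
        return DispersionEstimate(min(phi, _PHI_MAX), "moments")

    if method != "qcml":
        raise ConfigurationError(f"unknown dispersion method {method!r}")

    group_counts = [counts[:, groups == g] for g in labels]

    def neg_cll(log_phi: float) -> float:
        phi = np.exp(log_phi)
        r = 1.0 / phi
        total = 0.0
        for sub in group_counts:
            n = sub.shape[1]
            z = sub.sum(axis=1)
            ll = (gammaln(sub + r).sum(axis=1) - n * gammaln(r)
                  + gammaln(n * r) - gammaln(z + n * r)
                  + gammaln(z + 1) - gammaln(sub + 1).sum(axis=1))
            total += ll.sum()
        return -total

    res = minimize_scalar(neg_cll, bounds=(np.log(1e-6), np.log(_PHI_MAX)),
                          method="bounded", options={"xatol": 1e-6})
    phi = float(np.exp(res.x))
    # the bounded optimum at the lower edge means "effectively Poisson"
    if phi <= 2e-6:
        phi = 0.0
    return DispersionEstimate(min(phi, _PHI_MAX), "qcml")


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _conditional_log_pmf(t: int, n_a: int, n_b: int, phi: float) -> np.ndarray:
    """Log pmf of the group-A sum s = 0..t conditional on the grand total t.

    With r = 1/phi per replicate at a common library size, the group sums
    are NB with sizes n_a*r and n_b*r and a shared success probability that
    cancels on conditioning, leaving
    P(s | t) proportional to C(s + rA - 1, s) * C(t - s + rB - 1, t - s).
    phi = 0 is the Poisson limit, Binomial(t, n_a / (n_a + n_b)).
    """
    s = np.arange(t + 1)
    if phi == 0.0:
        p = n_a / (n_a + n_b)
        logw = (gammaln(t + 1) - gammaln(s + 1) - gammaln(t - s + 1)
                + s * np.log(p) + (t - s) * np.log1p(-p))
    else:
        r_a = n_a / phi
        r_b = n_b / phi
        logw = (gammaln(s + r_a) - gammaln(s + 1) - gammaln(r_a)
                + gammaln(t - s + r_b) - gammaln(t - s + 1) - gammaln(r_b))
    return logw - logsumexp(logw)


def exact_nb_test(counts_a: np.ndarray, counts_b: np.ndarray, phi: float) -> float:
    """Two-sided exact test p-value for one window.

    ``counts_a``/``counts_b`` are replicate counts already equalized to a
    common library size.  Replicates are summed within groups; conditional
    on the grand total the two-sided p-value sums P(s) over every s whose
    probability does not exceed the observed one (with a tolerance for
    floating-point ties).  t = 0 gives p = 1 by convention.
    """
    if phi < 0:
        raise ConfigurationError("phi must be >= 0")
    counts_a = np.atleast_1d(np.asarray(counts_a, dtype=np.int64))
    counts_b = np.atleast_1d(np.asarray(counts_b, dtype=np.int64))
    s_obs = int(counts_a.sum())
    t = s_obs + int(counts_b.sum())
    if t == 0:
        return 1.0
    logp = _conditional_log_pmf(t, len(counts_a), len(counts_b), phi)
    mask = logp <= logp[s_obs] + 1e-10
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


@dataclass(frozen=True)
class WindowTestResult:
    chrom: str
    start: int
    end: int
    size: int
    mean_a: float
    mean_b: float
    log2_fc: float
    p_value: float
    p_adjusted: float
    significant: bool
    direction: str  # {"up_in_mutant", "down_in_mutant", ""}


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs passed through)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    out[valid] = adj
    return out


def test_windows(matrix: WindowCountMatrix, control: list[str], case: list[str],
                 config: DiffConfig = DiffConfig(),
                 phi: float | None = None,
                 dispersion_method: str = "qcml") -> pd.DataFrame:
    """Run the exact test for every window x size between two sample groups.

    ``control`` is group A (e.g. SKI2/RDR6), ``case`` group B (e.g.
    ski2/RDR6); fold changes are case over control.  Windows with total
    count below ``min_total_count`` get p = NA and are never significant.
    Returns a tidy frame, one row per window x size.
    """
    for name in (*control, *case):
        if name not in matrix.samples:
            raise ConfigurationError(f"sample {name!r} not in count matrix")
    idx_a = [matrix.samples.index(s) for s in control]
    idx_b = [matrix.samples.index(s) for s in case]
    lib = np.array([matrix.library_sizes[s] for s in control + case], dtype=float)
    raw = matrix.counts[:, :, idx_a + idx_b]  # (W, S, nA+nB)
    n_w, n_s, _ = raw.shape
    flat = raw.reshape(n_w * n_s, -1)
    if config.normalization == "median-of-ratios":
        # factors have geometric mean 1, so equalization rescales each
        # sample by 1/factor onto a common effective library
        factors = normalize(flat.astype(float), lib, "median-of-ratios")
        eq = equalize_counts(flat, factors)
    else:
        eq = equalize_counts(flat, lib)

    if phi is None:
        groups = np.array(["A"] * len(idx_a) + ["B"] * len(idx_b))
        keepable = eq.sum(axis=1) >= config.min_total_count
        if keepable.any():
            phi = estimate_common_dispersion(
                eq, groups, method=dispersion_method,
                min_total_count=config.min_total_count).phi
        else:
            phi = 0.0

    n_a, n_b = len(idx_a), len(idx_b)
    totals = eq.sum(axis=1)
    pvals = np.full(n_w * n_s, np.nan)
    # identical conditional laws recur across windows; cache by (t, s_obs)
    cache: dict[tuple[int, int], float] = {}
    sums_a = eq[:, :n_a].sum(axis=1)
    for i in range(n_w * n_s):
        if totals[i] < config.min_total_count:
            continue
        key = (int(totals[i]), int(sums_a[i]))
        if key not in cache:
            cache[key] = exact_nb_test(eq[i, :n_a], eq[i, n_a:], phi)
        pvals[i] = cache[key]

    adjusted = bh_adjust(pvals) if config.adjust == "BH" else pvals.copy()
    crit = adjusted if config.adjust == "BH" else pvals
    significant = np.where(np.isnan(crit), False, crit < config.alpha)

    mean_a = eq[:, :n_a].mean(axis=1)
    mean_b = eq[:, n_a:].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2((mean_b + 0.5) / (mean_a + 0.5))

    records = []
    for wi in range(n_w):
        chrom, start, end = matrix.windows[wi]
        for si in range(n_s):
            i = wi * n_s + si
            direction = ""
            if mean_b[i] > mean_a[i]:
                direction = "up_in_mutant"
            elif mean_b[i] < mean_a[i]:
                direction = "down_in_mutant"
            records.append((chrom, start, end, matrix.sizes[si],
                            mean_a[i], mean_b[i], log2_fc[i], pvals[i],
                            adjusted[i], bool(significant[i]), direction))
    return pd.DataFrame(records, columns=[
        "chrom", "start", "end", "size", "mean_control", "mean_case",
        "log2_fc", "p_value", "p_adjusted", "significant", "direction"])


def call_significant(results: pd.DataFrame,
                     config: DiffConfig = DiffConfig()) -> pd.DataFrame:
    """Re-flag significance on an existing results frame under ``config``."""
    out = results.copy()
    if config.adjust == "BH":
        out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
        crit = out["p_adjusted"]
    else:
        out["p_adjusted"] = out["p_value"]
        crit = out["p_value"]
    out["significant"] = crit.notna() & (crit < config.alpha)
    return out
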