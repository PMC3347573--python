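"""Exact test of Hardy-Weinberg equilibrium for multiallelic loci.

The test conditions on the observed allele counts: given ``n`` diploid
individuals with genotype counts ``n_ij`` and allele counts ``m_i``, the
probability of a genotype table under HWE is

    P(table | m) = [n! / prod n_ij!] * [prod m_i! / (2n)!] * 2^H,

with ``H`` the number of heterozygotes.  The p-value is the total
probability of tables (with the same allele counts) whose conditional
probability does not exceed the observed one — computed either by complete
enumeration of the fixed-margin table set, or, for many-allele loci where
enumeration explodes, by a Markov chain over gene-copy arrangements.

The chain exploits that ``P(table | m)`` is exactly the push-forward of the
uniform distribution over arrangements of the ``2n`` individual gene copies
into ``n`` ordered pairs: swapping two gene copies between individuals is a
symmetric proposal with uniform stationary law, so every proposal is
accepted and the long-run fraction of steps in the rejection region
estimates the p-value.  The standard error is estimated by batch means.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .strdata import MISSING, GenotypeTable

__all__ = [
    "HWEResult",
    "genotype_counts",
    "conditional_probability",
    "log_conditional_probability",
    "enumerate_tables",
    "hwe_exact_pvalue",
    "bonferroni_threshold",
    "hwe_test_table",
    "deviation_accumulation",
]

#: tables with log-probability within this of the observed one count as ties
_TIE_TOL = 1e-12
#: looser tie tolerance for the incremental log-probability in the chain
_MCMC_TOL = 1e-7


@dataclass
class HWEResult:
    """Outcome of one exact HWE test."""

    p_value: float
    method: str  # {"enumeration", "mcmc", "degenerate"}
    se: float | None = None
    steps: int | None = None
    burn_in: int | None = None
    seed: int | None = None
    population: str | None = None
    locus: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.se is not None and self.se < 0:
            raise ValueError("negative standard error")


def genotype_counts(gt: GenotypeTable, population: str, locus: str):
    """Genotype-count matrix for one (population, locus).

    Returns ``(counts, labels)`` where ``counts[i, j]`` for ``i <= j`` holds
    the number of individuals with allele pair ``(labels[i], labels[j])``;
    the strict lower triangle is zero.
    """
    arr = gt.calls[locus][gt.populations == population]
    arr = arr[arr[:, 0] != MISSING]
    labels = np.unique(arr)
    index = {int(v): i for i, v in enumerate(labels)}
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for a, b in arr:
        i, j = index[int(a)], index[int(b)]
        counts[min(i, j), max(i, j)] += 1
    return counts, labels


def _canonical_counts(counts) -> np.ndarray:
    """Accept a dict {(i, j): count} or square matrix; return upper form."""
    if isinstance(counts, dict):
        k = max(max(i, j) for i, j in counts) + 1
        mat = np.zeros((k, k), dtype=np.int64)
        for (i, j), c in counts.items():
            mat[min(i, j), max(i, j)] += int(c)
        return mat
    mat = np.asarray(counts, dtype=np.int64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("genotype counts must be a square matrix")
    if np.tril(mat, -1).any() and not np.array_equal(mat, mat.T):
        raise ValueError("counts matrix must be upper-triangular or symmetric")
    return np.triu(mat)


def _margins(mat: np.ndarray) -> tuple[int, np.ndarray]:
    n = int(mat.sum())
    k = mat.shape[0]
    m = np.zeros(k, dtype=np.int64)
    for i in range(k):
        for j in range(i, k):
            m[i] += mat[i, j]
            m[j] += mat[i, j]
    return n, m


def log_conditional_probability(counts) -> float:
    """log P(table | allele counts) under HWE (computed in log-space)."""
    mat = _canonical_counts(counts)
    n, m = _margins(mat)
    if n == 0:
        raise ValueError("empty genotype table")
    iu = np.triu_indices(mat.shape[0])
    h = int(mat[iu].sum() - np.diag(mat).sum())
    return float(
        gammaln(n + 1)
        - gammaln(mat[iu] + 1).sum()
        + gammaln(m + 1).sum()
        - gammaln(2 * n + 1)
        + h * log(2.0)
    )


def conditional_probability(counts) -> float:
    """P(table | allele counts); see :func:`log_conditional_probability`."""
    return float(np.exp(log_conditional_probability(counts)))


def enumerate_tables(m: np.ndarray, max_tables: int = 2_000_000):
    """Yield every genotype-count table with allele-count margins ``m``.

    Tables are upper-triangular ``k x k`` integer matrices.  Raises
    ``RuntimeError`` when more than ``max_tables`` tables are generated.
    """
    m = np.asarray(m, dtype=np.int64)
    k = len(m)
    mat = np.zeros((k, k), dtype=np.int64)
    produced = 0

    def rec(i: int, j: int, rem: np.ndarray):
        nonlocal produced
        if i == k:
            produced += 1
            if produced > max_tables:
                raise RuntimeError(
                    f"enumeration exceeded budget of {max_tables} tables; use method='mcmc'"
                )
            yield mat.copy()
            return
        if j == k:
            if rem[i] != 0:
                return
            yield from rec(i + 1, i + 1, rem)
            return
        if i == j:
            top = rem[i] // 2
            for c in range(top + 1):
                mat[i, j] = c
                rem[i] -= 2 * c
                yield from rec(i, j + 1, rem)
                rem[i] += 2 * c
            mat[i, j] = 0
            return
        top = min(rem[i], rem[j])
        for c in range(top + 1):
            mat[i, j] = c
            rem[i] -= c
            rem[j] -= c
            yield from rec(i, j + 1, rem)
            rem[i] += c
            rem[j] += c
        mat[i, j] = 0

    yield from rec(0, 0, m.copy())


def _enumeration_pvalue(mat: np.ndarray, max_tables: int) -> float:
    logp_obs = log_conditional_probability(mat)
    _, m = _margins(mat)
    total = 0.0
    p = 0.0
    for table in enumerate_tables(m, max_tables=max_tables):
        lp = log_conditional_probability(table)
        prob = float(np.exp(lp))
        total += prob
        if lp <= logp_obs + _TIE_TOL:
            p += prob
    if abs(total - 1.0) > 1e-8:
        raise AssertionError(f"enumeration probabilities sum to {total}, not 1")
    return min(p, 1.0)


@njit(cache=True)
def _chain_kernel(pairs, k, logp_obs, steps, burn_in, n_batches, seed):  # pragma: no cover
    np.random.seed(seed)
    n = pairs.shape[0]
    counts = np.zeros((k, k), np.int64)
    for u in range(n):
        a, b = pairs[u, 0], pairs[u, 1]
        i, j = min(a, b), max(a, b)
        counts[i, j] += 1
    # log P up to the margin-constant: H*log2 - sum log n_ij!
    logp = 0.0
    for i in range(k):
        for j in range(i, k):
            logp -= lgamma(counts[i, j] + 1.0)
            if i != j:
                logp += counts[i, j] * 0.6931471805599453
    batch = np.zeros(n_batches)
    kept = steps - burn_in
    batch_len = kept // n_batches
    hit_total = 0
    for step in range(steps):
        u = np.random.randint(0, n)
        v = np.random.randint(0, n)
        if u != v:
            c1 = np.random.randint(0, 2)
            c2 = np.random.randint(0, 2)
            x = pairs[u, c1]
            y = pairs[v, c2]
            if x != y:
                # remove old genotypes of u and v
                for w in (u, v):
                    a, b = pairs[w, 0], pairs[w, 1]
                    i, j = min(a, b), max(a, b)
                    logp += lgamma(counts[i, j] + 1.0) - lgamma(counts[i, j])
                    counts[i, j] -= 1
                    if i != j:
                        logp -= 0.6931471805599453
                pairs[u, c1] = y
                pairs[v, c2] = x
                for w in (u, v):
                    a, b = pairs[w, 0], pairs[w, 1]
                    i, j = min(a, b), max(a, b)
                    counts[i, j] += 1
                    logp -= lgamma(counts[i, j] + 1.0) - lgamma(counts[i, j])
                    if i != j:
                        logp += 0.6931471805599453
        if step >= burn_in:
            idx = step - burn_in
            if idx >= batch_len * n_batches:
                break
            hit = 1 if logp <= logp_obs + 1e-7 else 0
            hit_total += hit
            batch[idx // batch_len] += hit
    p_hat = hit_total / (batch_len * n_batches)
    bm = batch / batch_len
    mean = bm.mean()
    var = 0.0
    for b in range(n_batches):
        var += (bm[b] - mean) ** 2
    var /= (n_batches - 1)
    se = (var / n_batches) ** 0.5
    return p_hat, se


def _pairs_from_counts(mat: np.ndarray) -> np.ndarray:
    rows = []
    k = mat.shape[0]
    for i in range(k):
        for j in range(i, k):
            for _ in range(int(mat[i, j])):
                rows.append((i, j))
    return np.asarray(rows, dtype=np.int64)


def _mcmc_pvalue(
    mat: np.ndarray, steps: int, burn_in: int, seed: int, n_batches: int = 50
) -> tuple[float, float]:
    if steps - burn_in < 10 * n_batches:
        raise ValueError("too few post-burn-in steps for batch-means error estimation")
    # the chain tracks log P only up to the constant term in the margins
    n, m = _margins(mat)
    const = (
        float(gammaln(n + 1) + gammaln(m + 1).sum() - gammaln(2 * n + 1))
    )
    logp_obs = log_conditional_probability(mat) - const
    pairs = _pairs_from_counts(mat)
    p, se = _chain_kernel(
        pairs.copy(), mat.shape[0], logp_obs, steps, burn_in, n_batches, seed
    )
    return float(p), float(se)


def hwe_exact_pvalue(
    counts,
    method: str = "auto",
    steps: int = 100_000,
    burn_in: int = 10_000,
    seed: int = 0,
    max_tables: int = 2_000_000,
    population: str | None = None,
    locus: str | None = None,
) -> HWEResult:
    """Exact HWE p-value for one genotype-count table.

    ``method='auto'`` enumerates for up to 5 alleles and falls back to the
    chain otherwise; ``'enumeration'`` refuses (rather than hangs) when the
    fixed-margin table set exceeds ``max_tables``.
    """
    mat = _canonical_counts(counts)
    k = mat.shape[0]
    n, m = _margins(mat)
    if n == 0:
        raise ValueError("empty genotype table")
    if (m > 0).sum() <= 1:
        return HWEResult(p_value=1.0, method="degenerate", population=population, locus=locus)
    if method == "auto":
        # the fixed-margin table count grows roughly like n^(k(k+1)/2 - k);
        # enumerate only where that stays in the tens of thousands
        if k <= 2 or (k == 3 and n <= 60) or (k == 4 and n <= 25) or (k == 5 and n <= 12):
            method = "enumeration"
        else:
            method = "mcmc"
    if method == "enumeration":
        p = _enumeration_pvalue(mat, max_tables)
        return HWEResult(p_value=p, method="enumeration", population=population, locus=locus)
    if method == "mcmc":
        p, se = _mcmc_pvalue(mat, steps, burn_in, seed)
        return HWEResult(
            p_value=p,
            method="mcmc",
            se=se,
            steps=steps,
            burn_in=burn_in,
            seed=seed,
            population=population,
            locus=locus,
        )
    raise ValueError(f"unknown method {method!r}")


def bonferroni_threshold(alpha: float, m: int, sidak: bool = False) -> float:
    """Per-test significance level for ``m`` tests at family level ``alpha``.

    Bonferroni ``alpha/m`` by default; ``sidak=True`` gives the
    ``1 - (1 - alpha)^(1/m)`` variant.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    if sidak:
        return 1.0 - (1.0 - alpha) ** (1.0 / m)
    return alpha / m


def hwe_test_table(
    gt: GenotypeTable,
    method: str = "auto",
    steps: int = 100_000,
    burn_in: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the exact test for every (population, locus) cell.

    Returns a tidy frame with p-values, chain standard errors where
    applicable, and significance flags before and after Bonferroni
    correction over the number of loci.
    """
    rows = []
    m_tests = len(gt.locus_names)
    thresh = bonferroni_threshold(alpha, m_tests)
    for pi, pop in enumerate(gt.population_ids()):
        for li, locus in enumerate(gt.locus_names):
            mat, _ = genotype_counts(gt, pop, locus)
            if mat.size == 0 or mat.sum() == 0:
                continue
            res = hwe_exact_pvalue(
                mat,
                method=method,
                steps=steps,
                burn_in=burn_in,
                seed=seed + 1_000 * pi + li,
                population=pop,
                locus=locus,
            )
            rows.append(
                {
                    "population": pop,
                    "locus": locus,
                    "p_value": res.p_value,
                    "se": res.se,
                    "method": res.method,
                    "significant": res.p_value < alpha,
                    "significant_bonferroni": res.p_value < thresh,
                }
            )
    return pd.DataFrame(rows)


def deviation_accumulation(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Count of nominal HWE deviations (p < alpha) per population."""
    out = (
        results.assign(dev=results["p_value"] < alpha)
        .groupby("population", sort=False)["dev"]
        .agg(n_deviations="sum", n_tests="count")
        .reset_index()
    )
    out["n_deviations"] = out["n_deviations"].astype(int)
    return out
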