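"""AMOVA-style population differentiation: Fst and Rst with permutation tests.

Gene copies are the units of analysis (two per diploid individual); the
total sum of squared inter-copy distances is partitioned into among- and
within-population components.  Two distance metrics are supported:

* ``identity`` — d(x, y) = 0 if the alleles match, else 1; the resulting
  fixation index is Fst, sensitive to allele-frequency differences alone;
* ``repeat-squared`` — d(x, y)^2 = (x - y)^2 in repeat numbers, the
  stepwise-mutation-aware metric whose index is Rst.

For a set S of gene copies the sum of squares is computed in closed form
from allele counts (identity: ``(|S| - sum_a c_a^2/|S|) / 2``;
repeat-squared: ``sum x^2 - (sum x)^2 / |S|``), which makes the estimator
exact and fast; a brute-force pair-sum oracle is used in the test suite.

Variance components follow the standard two-level decomposition:
``MS_within = SS_w / (N - G)`` estimates sigma^2_w and
``MS_among = SS_a / (G - 1)`` estimates ``sigma^2_w + n' sigma^2_a`` with
``n' = (N - sum n_g^2 / N) / (G - 1)``; the index is
``sigma^2_a / (sigma^2_a + sigma^2_w)``.  The multilocus index sums
components over loci before taking the ratio.  Significance comes from
permuting individuals across populations; p = (hits + 1) / (perms + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .strdata import MISSING, AlleleFrequencyTable, GenotypeTable

__all__ = [
    "AmovaResult",
    "PairwiseMatrix",
    "amova",
    "pairwise_matrix",
    "locuswise_fst",
    "amova_from_frequencies",
]


@dataclass
class AmovaResult:
    """Variance partition for one cohort (possibly multilocus)."""

    fst: float
    sigma_among: float
    sigma_within: float
    metric: str
    p_value: float | None = None
    permutations: int | None = None
    seed: int | None = None
    per_locus: pd.DataFrame | None = None
    negative_components: bool = False


@dataclass
class PairwiseMatrix:
    """Symmetric population x population index matrix with p-values."""

    populations: list[str]
    values: np.ndarray
    p_values: np.ndarray | None
    metric: str

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("pairwise matrix must be symmetric")
        if not np.all(np.diag(v) == 0.0):
            raise ValueError("pairwise matrix diagonal must be exactly 0")

    def to_frame(self, clamp_negative: bool = False) -> pd.DataFrame:
        v = np.maximum(self.values, 0.0) if clamp_negative else self.values
        return pd.DataFrame(v, index=self.populations, columns=self.populations)


def _locus_components(
    arr: np.ndarray, codes: np.ndarray, n_pops: int, metric: str
) -> tuple[float, float] | None:
    """(sigma_among, sigma_within) for one locus; None if undecomposable."""
    valid = arr[:, 0] != MISSING
    v = arr[valid]
    c = codes[valid]
    if len(v) == 0:
        return None
    copy_vals = v.ravel()
    copy_pops = np.repeat(c, 2)
    n_total = copy_vals.size
    present = np.unique(copy_pops)
    g = len(present)
    if g < 2 or n_total - g <= 0:
        return None
    n_g = np.bincount(copy_pops, minlength=n_pops).astype(float)

    if metric == "identity":
        _, allele_idx = np.unique(copy_vals, return_inverse=True)
        k = allele_idx.max() + 1
        tot = np.bincount(allele_idx, minlength=k).astype(float)
        ss_total = 0.5 * (n_total - float(tot @ tot) / n_total)
        cnt = np.zeros((n_pops, k))
        np.add.at(cnt, (copy_pops, allele_idx), 1.0)
        ss_within = 0.0
        for p in present:
            ss_within += 0.5 * (n_g[p] - float(cnt[p] @ cnt[p]) / n_g[p])
    elif metric == "repeat-squared":
        x = copy_vals / 10.0  # tenths -> repeat units
        ss_total = float(np.sum(x * x) - np.sum(x) ** 2 / n_total)
        ss_within = 0.0
        for p in present:
            xp = x[copy_pops == p]
            ss_within += float(np.sum(xp * xp) - np.sum(xp) ** 2 / n_g[p])
    else:
        raise ValueError(f"unknown metric {metric!r}")

    ss_among = ss_total - ss_within
    df_a = g - 1
    df_w = n_total - g
    sigma_w = ss_within / df_w
    n_prime = (n_total - float(np.sum(n_g[present] ** 2)) / n_total) / df_a
    if n_prime <= 0:
        return None
    sigma_a = (ss_among / df_a - sigma_w) / n_prime
    return sigma_a, sigma_w


def _multilocus_fst(
    calls: list[np.ndarray], codes: np.ndarray, n_pops: int, metric: str
) -> tuple[float, list[tuple[float, float]]]:
    comps = []
    num = 0.0
    den = 0.0
    for arr in calls:
        res = _locus_components(arr, codes, n_pops, metric)
        comps.append(res if res is not None else (np.nan, np.nan))
        if res is None:
            continue
        sa, sw = res
        if sa + sw == 0.0:
            continue
        num += sa
        den += sa + sw
    fst = num / den if den > 0 else np.nan
    return fst, comps


def amova(
    gt: GenotypeTable,
    metric: str = "identity",
    permutations: int = 10_000,
    seed: int = 0,
    loci: Sequence[str] | None = None,
) -> AmovaResult:
    """Two-level AMOVA over all populations of ``gt``.

    ``metric='identity'`` yields Fst, ``'repeat-squared'`` yields Rst.
    ``permutations=0`` skips the significance test.
    """
    pops = gt.population_ids()
    if len(pops) < 2:
        raise ValueError("AMOVA needs at least 2 populations")
    code_of = {p: i for i, p in enumerate(pops)}
    codes = np.array([code_of[p] for p in gt.populations], dtype=np.int64)
    names = list(loci) if loci is not None else gt.locus_names
    calls = [gt.calls[name] for name in names]

    fst, comps = _multilocus_fst(calls, codes, len(pops), metric)
    sig_a = float(np.nansum([c[0] for c in comps]))
    sig_w = float(np.nansum([c[1] for c in comps]))
    per_locus = pd.DataFrame(
        {
            "locus": names,
            "sigma_among": [c[0] for c in comps],
            "sigma_within": [c[1] for c in comps],
            "fst": [
                c[0] / (c[0] + c[1]) if np.isfinite(c[0]) and (c[0] + c[1]) != 0 else np.nan
                for c in comps
            ],
        }
    )

    p_value = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(codes)
            f_perm, _ = _multilocus_fst(calls, perm, len(pops), metric)
            if np.isfinite(f_perm) and f_perm >= fst - 1e-15:
                hits += 1
        p_value = (hits + 1) / (permutations + 1)

    return AmovaResult(
        fst=float(fst),
        sigma_among=sig_a,
        sigma_within=sig_w,
        metric=metric,
        p_value=p_value,
        permutations=permutations or None,
        seed=seed,
        per_locus=per_locus,
        negative_components=bool(np.nanmin(per_locus["sigma_among"]) < 0)
        if len(per_locus)
        else False,
    )


def pairwise_matrix(
    gt: GenotypeTable,
    metric: str = "identity",
    permutations: int = 10_000,
    seed: int = 0,
) -> PairwiseMatrix:
    """AMOVA index for every population pair, assembled symmetrically."""
    pops = gt.population_ids()
    k = len(pops)
    vals = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            sub = gt.subset([pops[i], pops[j]])
            res = amova(sub, metric=metric, permutations=permutations, seed=seed + 37 * (i * k + j))
            vals[i, j] = vals[j, i] = res.fst
            if res.p_value is not None:
                pvals[i, j] = pvals[j, i] = res.p_value
    return PairwiseMatrix(pops, vals, pvals if permutations > 0 else None, metric)


def locuswise_fst(
    gt: GenotypeTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    metric: str = "identity",
    permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-locus Fst between two pooled groups, with Monte-Carlo p and SE.

    Reproduces the two-group, locus-by-locus comparison layout (one row per
    locus with the index, the permutation p-value and its standard error).
    """
    pooled = gt.relabel_populations(
        {p: "A" for p in group_a} | {p: "B" for p in group_b}
    ).subset(["A", "B"])
    codes = np.array([0 if p == "A" else 1 for p in pooled.populations], dtype=np.int64)
    rng = np.random.default_rng(seed)
    rows = []
    for name in pooled.locus_names:
        arr = pooled.calls[name]
        res = _locus_components(arr, codes, 2, metric)
        if res is None:
            rows.append({"locus": name, "fst": np.nan, "p": np.nan, "p_se": np.nan})
            continue
        sa, sw = res
        fst = sa / (sa + sw) if (sa + sw) != 0 else np.nan
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(codes)
            r = _locus_components(arr, perm, 2, metric)
            if r is None:
                continue
            f = r[0] / (r[0] + r[1]) if (r[0] + r[1]) != 0 else np.nan
            if np.isfinite(f) and f >= fst - 1e-15:
                hits += 1
        p = (hits + 1) / (permutations + 1)
        rows.append(
            {
                "locus": name,
                "fst": fst,
                "p": p,
                "p_se": float(np.sqrt(p * (1 - p) / permutations)),
            }
        )
    return pd.DataFrame(rows)


def amova_from_frequencies(
    aft: AlleleFrequencyTable,
    populations: Sequence[str] | None = None,
    metric: str = "identity",
) -> AmovaResult:
    """Frequency-only AMOVA point estimate (no permutation test).

    Reconstructs the sums of squares from per-population allele frequencies
    and gene-copy counts.  This ignores within-individual pairing (which the
    two-level decomposition never uses) and supports reference databases
    that publish frequencies but not genotypes; no significance test is
    possible without genotype or frequency resampling.
    """
    pops = list(populations) if populations is not None else aft.populations()
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    num = 0.0
    den = 0.0
    per_rows = []
    for locus in aft.loci():
        cells = [(p, aft.freqs(p, locus)) for p in pops]
        cells = [(p, f) for p, f in cells if f]
        if len(cells) < 2:
            continue
        n_g = np.array([aft.gene_copies(p, locus) for p, _ in cells], dtype=float)
        n_total = float(n_g.sum())
        g = len(cells)
        alleles = sorted({a for _, f in cells for a in f})
        counts = np.array(
            [[f.get(a, 0.0) * n for a in alleles] for (_, f), n in zip(cells, n_g)]
        )
        if metric == "identity":
            tot = counts.sum(axis=0)
            ss_total = 0.5 * (n_total - float(tot @ tot) / n_total)
            ss_within = float(
                np.sum(0.5 * (n_g - np.einsum("ij,ij->i", counts, counts) / n_g))
            )
        elif metric == "repeat-squared":
            x = np.asarray(alleles, dtype=float) / 10.0
            s1 = counts @ x
            s2 = counts @ (x * x)
            ss_total = float(s2.sum() - s1.sum() ** 2 / n_total)
            ss_within = float(np.sum(s2 - s1 * s1 / n_g))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        ss_among = ss_total - ss_within
        df_a, df_w = g - 1, n_total - g
        sigma_w = ss_within / df_w
        n_prime = (n_total - float(np.sum(n_g**2)) / n_total) / df_a
        sigma_a = (ss_among / df_a - sigma_w) / n_prime
        per_rows.append(
            {
                "locus": locus,
                "sigma_among": sigma_a,
                "sigma_within": sigma_w,
                "fst": sigma_a / (sigma_a + sigma_w) if (sigma_a + sigma_w) != 0 else np.nan,
            }
        )
        if sigma_a + sigma_w != 0:
            num += sigma_a
            den += sigma_a + sigma_w
    per_locus = pd.DataFrame(per_rows)
    return AmovaResult(
        fst=num / den if den > 0 else np.nan,
        sigma_among=float(per_locus["sigma_among"].sum()) if len(per_locus) else np.nan,
        sigma_within=float(per_locus["sigma_within"].sum()) if len(per_locus) else np.nan,
        metric=metric,
        per_locus=per_locus,
        negative_components=bool((per_locus["sigma_among"] < 0).any()) if len(per_locus) else False,
    )
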