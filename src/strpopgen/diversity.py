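"""Per-locus and per-population STR variability statistics.

The central quantity is expected heterozygosity (gene diversity)
``He = 1 - sum(p_i^2)``, optionally with the small-sample correction
``n/(n-1)`` over gene copies (the Arlequin/Nei unbiased estimator, the
default here).  Alongside He the module reports observed heterozygosity,
allele counts, and the repeat-number dispersion R = max allele - min allele
in repeat units — for a locus like PentaE with alleles 5 through 23 that is
an 18-repeat span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .strdata import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeTable,
    allele_frequencies,
    parse_allele,
)

logger = logging.getLogger(__name__)

__all__ = [
    "expected_heterozygosity",
    "observed_heterozygosity",
    "repeat_dispersion",
    "n_alleles",
    "DiversitySummary",
    "diversity_summary",
]


def expected_heterozygosity(
    freqs: Mapping | np.ndarray,
    n: int | None = None,
    unbiased: bool = True,
) -> float:
    """Gene diversity 1 - sum(p^2), bias-corrected by n/(n-1) gene copies.

    Parameters
    ----------
    freqs:
        Allele frequency mapping or array; must sum to 1.
    n:
        Gene copies the frequencies were estimated from (2 x individuals);
        required when ``unbiased``.
    unbiased:
        Apply the ``n/(n-1)`` small-sample correction (default).
    """
    p = np.asarray(list(freqs.values()) if isinstance(freqs, Mapping) else freqs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must sum to 1")
    he = 1.0 - float(np.sum(p * p))
    if not unbiased:
        return he
    if n is None or n < 2:
        raise ValueError("unbiased estimator needs n >= 2 gene copies")
    return n / (n - 1.0) * he


def observed_heterozygosity(gt: GenotypeTable, population: str, locus: str) -> float | None:
    """Fraction of non-missing individuals carrying two different alleles."""
    mask = gt.populations == population
    arr = gt.calls[locus][mask]
    arr = arr[arr[:, 0] != MISSING]
    if len(arr) == 0:
        logger.warning("no calls for (%s, %s); Ho undefined", population, locus)
        return None
    return float(np.mean(arr[:, 0] != arr[:, 1]))


def repeat_dispersion(freqs: Mapping[int, float]) -> float:
    """Allele-label range (max - min) in repeat units over observed alleles."""
    alleles = [a for a, f in freqs.items() if f > 0]
    if not alleles:
        raise ValueError("no observed alleles")
    return (max(alleles) - min(alleles)) / 10.0


def n_alleles(freqs: Mapping[int, float]) -> int:
    return sum(1 for f in freqs.values() if f > 0)


@dataclass
class DiversitySummary:
    """Variability tables for a cohort.

    ``per_cell``: tidy rows (population, locus, He, Ho, A, R, n_gene_copies).
    ``per_locus``: one row per locus with the pooled-cohort statistics and
    across-population averages (the panel-variability table layout).
    ``per_population``: average He over loci for each population.
    Averages are arithmetic means over the cells present; an internal
    consistency check re-derives every average from its own cells.
    """

    per_cell: pd.DataFrame
    per_locus: pd.DataFrame
    per_population: pd.DataFrame

    def validate(self) -> None:
        for pop, grp in self.per_cell.groupby("population"):
            want = float(grp["He"].mean())
            got = float(
                self.per_population.set_index("population").loc[pop, "mean_He"]
            )
            if abs(want - got) > 1e-12:
                raise AssertionError(f"per-population average mismatch for {pop}")
        avg = self.per_cell.groupby("locus", sort=False)[["He", "A", "R"]].mean()
        for locus in self.per_locus["locus"]:
            row = self.per_locus.set_index("locus").loc[locus]
            for col, mean_col in (("He", "mean_He"), ("A", "mean_A"), ("R", "mean_R")):
                if abs(avg.loc[locus, col] - row[mean_col]) > 1e-12:
                    raise AssertionError(f"per-locus average mismatch at {locus}/{col}")


def diversity_summary(
    source: GenotypeTable | AlleleFrequencyTable,
    unbiased: bool = True,
    pooled_population: str | None = None,
) -> DiversitySummary:
    """Compute the full variability summary from genotypes or frequencies.

    When given a :class:`GenotypeTable`, observed heterozygosity is included
    and pooled-cohort statistics are computed on the concatenated
    individuals; from an :class:`AlleleFrequencyTable` alone, Ho is absent
    and the pooled column is the gene-copy-weighted frequency pool (or the
    ``pooled_population`` entry of the table if one was precomputed).
    """
    if isinstance(source, GenotypeTable):
        aft = allele_frequencies(source)
        gt: GenotypeTable | None = source
    else:
        aft = source
        gt = None

    pops = [p for p in aft.populations() if p != pooled_population]
    loci = aft.loci()
    cells = []
    for pop in pops:
        for locus in loci:
            freqs = aft.freqs(pop, locus)
            if not freqs:
                continue
            n = aft.gene_copies(pop, locus)
            he = expected_heterozygosity(freqs, n, unbiased=unbiased)
            ho = observed_heterozygosity(gt, pop, locus) if gt is not None else np.nan
            cells.append(
                (pop, locus, he, ho, n_alleles(freqs), repeat_dispersion(freqs), n)
            )
    per_cell = pd.DataFrame(
        cells, columns=["population", "locus", "He", "Ho", "A", "R", "n_gene_copies"]
    )

    # pooled-cohort statistics per locus
    pooled_rows = []
    for locus in loci:
        if gt is not None:
            arr = gt.calls[locus]
            alleles = arr[arr[:, 0] != MISSING].ravel()
            if alleles.size == 0:
                continue
            vals, counts = np.unique(alleles, return_counts=True)
            freqs = {int(v): c / alleles.size for v, c in zip(vals, counts)}
            n = int(alleles.size)
        elif pooled_population is not None:
            freqs = aft.freqs(pooled_population, locus)
            n = aft.gene_copies(pooled_population, locus)
        else:
            # gene-copy-weighted pool over populations
            acc: dict[int, float] = {}
            n = 0
            for pop in pops:
                f = aft.freqs(pop, locus)
                if not f:
                    continue
                m = aft.gene_copies(pop, locus)
                n += m
                for a, v in f.items():
                    acc[a] = acc.get(a, 0.0) + v * m
            freqs = {a: v / n for a, v in acc.items()}
        pooled_rows.append(
            (
                locus,
                expected_heterozygosity(freqs, n, unbiased=unbiased),
                n_alleles(freqs),
                repeat_dispersion(freqs),
            )
        )
    pooled = pd.DataFrame(pooled_rows, columns=["locus", "pooled_He", "pooled_A", "pooled_R"])
    means = (
        per_cell.groupby("locus", sort=False)[["He", "A", "R"]]
        .mean()
        .rename(columns={"He": "mean_He", "A": "mean_A", "R": "mean_R"})
        .reset_index()
    )
    per_locus = pooled.merge(means, on="locus")
    per_population = (
        per_cell.groupby("population", sort=False)["He"]
        .mean()
        .rename("mean_He")
        .reset_index()
    )
    out = DiversitySummary(per_cell, per_locus, per_population)
    out.validate()
    return out
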