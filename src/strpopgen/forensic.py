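"""Forensic identification statistics for STR panels.

Per locus the module reports the standard identification indices:

* MP — matching probability, the chance two random individuals share a
  genotype, ``sum(g_k^2)`` over genotype frequencies ``g_k``;
* PD — power of discrimination, ``1 - MP``;
* PE — power of exclusion, ``h^2 (1 - 2 h H^2)`` from the observed
  heterozygote fraction ``h`` and homozygote fraction ``H = 1 - h``;
* PI — typical paternity index ``1 / (2H)``.

Across a panel MP multiplies over loci (independent unlinked markers), the
reciprocal ``1/MP_total`` is the "1 out of N" headline figure, the combined
PE is ``1 - prod(1 - PE_l)`` and PI multiplies.  Genotype frequencies can
be empirical ("observed", the default, requiring genotype data) or
HWE-expected from allele frequencies ("expected", usable with a
frequency-only reference database).

For casework against a structured reference population the Balding-Nichols
theta-corrected conditional genotype probabilities are provided; they
inflate single-genotype match probabilities to guard against reference /
suspect subpopulation mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .strdata import MISSING, AlleleFrequencyTable, GenotypeTable

__all__ = [
    "matching_probability",
    "power_of_exclusion",
    "paternity_index",
    "locus_summary",
    "combine_loci",
    "forensic_summary",
    "theta_corrected_match",
    "format_reciprocal",
]


def matching_probability(genotype_freqs: Mapping | np.ndarray) -> float:
    """MP = sum of squared genotype frequencies; PD is ``1 - MP``."""
    g = np.asarray(
        list(genotype_freqs.values()) if isinstance(genotype_freqs, Mapping) else genotype_freqs,
        dtype=float,
    )
    if g.size == 0:
        raise ValueError("no genotypes")
    if abs(g.sum() - 1.0) > 1e-9:
        raise ValueError("genotype frequencies must sum to 1")
    return float(np.sum(g * g))


def power_of_exclusion(h: float, H: float | None = None) -> float:
    """PE = h^2 (1 - 2 h H^2) from heterozygote/homozygote fractions."""
    if H is None:
        H = 1.0 - h
    if abs(h + H - 1.0) > 1e-9 or not (0.0 <= h <= 1.0):
        raise ValueError("h and H must be complementary fractions in [0, 1]")
    return h * h * (1.0 - 2.0 * h * H * H)


def paternity_index(H: float) -> float:
    """Typical PI = 1/(2H); an all-heterozygote locus has unbounded PI."""
    if not 0.0 <= H <= 1.0:
        raise ValueError("homozygote fraction must lie in [0, 1]")
    if H == 0.0:
        return float("inf")
    return 1.0 / (2.0 * H)


def _observed_genotype_freqs(gt: GenotypeTable, population: str, locus: str):
    arr = gt.calls[locus][gt.populations == population]
    arr = arr[arr[:, 0] != MISSING]
    if len(arr) == 0:
        return None, None
    pairs, counts = np.unique(arr, axis=0, return_counts=True)
    g = counts / counts.sum()
    het = float(np.mean(arr[:, 0] != arr[:, 1]))
    return g, het


def _expected_genotype_freqs(freqs: Mapping[int, float]):
    p = np.asarray(list(freqs.values()), dtype=float)
    homo = p * p
    g = list(homo)
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            g.append(2.0 * p[i] * p[j])
    g = np.asarray(g)
    het = 1.0 - float(homo.sum())
    return g, het


def locus_summary(
    source: GenotypeTable | AlleleFrequencyTable,
    population: str,
    locus: str,
    mode: str = "observed",
) -> dict[str, float] | None:
    """MP/PD/PE/PI for one (population, locus); ``None`` when no data.

    ``mode='observed'`` uses empirical genotype proportions (needs a
    :class:`GenotypeTable`); ``mode='expected'`` uses HWE genotype
    frequencies derived from allele frequencies.
    """
    if mode == "observed":
        if not isinstance(source, GenotypeTable):
            raise ValueError("observed mode requires genotype data")
        g, het = _observed_genotype_freqs(source, population, locus)
    elif mode == "expected":
        if isinstance(source, GenotypeTable):
            from .strdata import allele_frequencies

            source = allele_frequencies(source)
        freqs = source.freqs(population, locus)
        if not freqs:
            return None
        g, het = _expected_genotype_freqs(freqs)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if g is None:
        return None
    mp = matching_probability(g)
    return {
        "MP": mp,
        "PD": 1.0 - mp,
        "PE": power_of_exclusion(het),
        "PI": paternity_index(1.0 - het),
    }


def combine_loci(rows: pd.DataFrame) -> dict[str, float]:
    """Combine per-locus indices across an unlinked panel."""
    if len(rows) == 0:
        raise ValueError("no loci to combine")
    mp_total = float(np.prod(rows["MP"]))
    return {
        "MP_total": mp_total,
        "reciprocal": 1.0 / mp_total,
        "PD_total": 1.0 - mp_total,
        "PE_total": 1.0 - float(np.prod(1.0 - rows["PE"])),
        "PI_total": float(np.prod(rows["PI"])),
        "n_loci": int(len(rows)),
    }


def format_reciprocal(x: float) -> str:
    """Three-significant-figure scientific form, e.g. ``3.95e+15``."""
    return f"{x:.3g}"


def forensic_summary(
    source: GenotypeTable | AlleleFrequencyTable,
    mode: str = "observed",
    populations: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Identification indices per (population, locus) plus combined rows.

    Returns ``(per_locus, combined)``; ``combined`` has one row per
    population with MP_total, the 1-out-of-N reciprocal (3 significant
    figures), PE_total and PI_total.
    """
    if isinstance(source, GenotypeTable):
        pops = populations or source.population_ids()
        loci = source.locus_names
    else:
        pops = populations or source.populations()
        loci = source.loci()
    per_rows = []
    for pop in pops:
        for locus in loci:
            s = locus_summary(source, pop, locus, mode=mode)
            if s is None:
                continue
            per_rows.append({"population": pop, "locus": locus, **s})
    per_locus = pd.DataFrame(per_rows)
    comb_rows = []
    for pop in pops:
        sub = per_locus[per_locus["population"] == pop]
        if len(sub) == 0:
            continue
        c = combine_loci(sub)
        c["population"] = pop
        c["reciprocal_str"] = format_reciprocal(c["reciprocal"])
        comb_rows.append(c)
    combined = pd.DataFrame(comb_rows)
    if len(combined):
        combined = combined[
            ["population", "MP_total", "reciprocal", "reciprocal_str", "PD_total", "PE_total", "PI_total", "n_loci"]
        ]
    return per_locus, combined


def theta_corrected_match(
    p_a: float, p_b: float | None, theta: float
) -> float:
    """Balding-Nichols conditional genotype match probability.

    For a homozygote AA (``p_b is None``):
        ``[2t + (1-t) p_a][3t + (1-t) p_a] / [(1+t)(1+2t)]``
    For a heterozygote AB:
        ``2 [t + (1-t) p_a][t + (1-t) p_b] / [(1+t)(1+2t)]``

    At ``theta = 0`` these reduce to the HWE products ``p_a^2`` and
    ``2 p_a p_b``; for ``theta > 0`` the homozygote probability strictly
    exceeds ``p_a^2``, which is the conservative direction for casework.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must lie in [0, 1)")
    for p in (p_a,) if p_b is None else (p_a, p_b):
        if not 0.0 <= p <= 1.0:
            raise ValueError("allele frequencies must lie in [0, 1]")
    t = theta
    denom = (1.0 + t) * (1.0 + 2.0 * t)
    if p_b is None:
        return (2.0 * t + (1.0 - t) * p_a) * (3.0 * t + (1.0 - t) * p_a) / denom
    return 2.0 * (t + (1.0 - t) * p_a) * (t + (1.0 - t) * p_b) / denom
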