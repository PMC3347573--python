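"""Bundled reference summary tables.

Published cohort-level summaries for 17 populations of Russia and
neighboring countries genotyped on the 15 autosomal STR loci of the
PowerPlex 16 panel (1,156 individuals).  Three small CSVs ship with the
package:

* ``panel_variability`` — per-locus pooled expected heterozygosity,
  across-population averages, allele counts and repeat-number dispersion;
* ``population_heterozygosity`` — per-locus expected heterozygosity in each
  of the 17 populations;
* ``identification_indices`` — combined 15-locus matching probability (with
  its printed "1 out of N" reciprocal), power of exclusion and paternity
  index per population.

They serve as validation anchors: the package's summary builders must
reproduce the tables' own internal aggregates (column means, extremes,
reciprocals) exactly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "panel_variability",
    "population_heterozygosity",
    "identification_indices",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("strpopgen.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def panel_variability() -> pd.DataFrame:
    """15 loci x (pooled He, per-population means, allele count, dispersion)."""
    return _load("panel_variability.csv")


def population_heterozygosity() -> pd.DataFrame:
    """15 loci x 17 populations of expected heterozygosity."""
    return _load("population_heterozygosity.csv")


def identification_indices() -> pd.DataFrame:
    """Combined forensic indices (MP, printed reciprocal, PE, PI) per population."""
    return _load("identification_indices.csv")
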