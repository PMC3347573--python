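"""Data model and I/O for autosomal STR genotypes and allele-frequency tables.

STR alleles are named by repeat number, with single-digit microvariants such
as ``9.3`` (TH01) common in forensic panels.  To keep microvariants exact,
alleles are stored internally as integer *tenths of a repeat* (``9.3`` -> 93,
``16`` -> 160), never as binary floats.  Labels round-trip canonically:
``"9.30"`` normalizes to ``"9.3"``.

Three containers cover the pipeline's inputs:

* :class:`GenotypeTable` — individuals x loci diploid calls with population
  labels (the raw input, read from CSV or GenePop);
* :class:`AlleleFrequencyTable` — per (population, locus) allele->frequency
  maps with gene-copy counts (the reference-database core);
* :class:`PopulationMeta` — sample sizes, coordinates and group labels.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing gene copy (whole-genotype missing only)
MISSING = -1

__all__ = [
    "MISSING",
    "Locus",
    "Genotype",
    "GenotypeTable",
    "PopulationMeta",
    "AlleleFrequencyTable",
    "parse_allele",
    "format_allele",
    "read_genotypes",
    "read_genotypes_csv",
    "read_genotypes_genepop",
    "write_genotypes_csv",
    "write_genotypes_genepop",
    "allele_frequencies",
    "read_frequency_db",
    "write_frequency_db",
    "read_population_meta",
]


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


class SchemaError(ValueError):
    """Structurally valid file that violates the expected schema."""


def parse_allele(label: str) -> int:
    """Parse an STR allele label into integer tenths of a repeat.

    >>> parse_allele("9.3")
    93
    >>> parse_allele("16")
    160
    """
    s = str(label).strip()
    if not s:
        raise ValueError("empty allele label")
    neg = s.startswith("-")
    if neg:
        raise ValueError(f"negative allele label {label!r}")
    if "." in s:
        whole, frac = s.split(".", 1)
        frac = frac.rstrip("0")
        if frac == "":
            frac = "0"
        if len(frac) > 1 or not frac.isdigit() or not whole.isdigit():
            raise ValueError(f"allele label {label!r} is not a repeat number in tenths")
        return int(whole) * 10 + int(frac)
    if not s.isdigit():
        raise ValueError(f"allele label {label!r} is not a repeat number")
    return int(s) * 10


def format_allele(tenths: int) -> str:
    """Inverse of :func:`parse_allele`: canonical label for an allele."""
    if tenths < 0:
        raise ValueError("cannot format the missing sentinel as an allele")
    whole, frac = divmod(int(tenths), 10)
    return str(whole) if frac == 0 else f"{whole}.{frac}"


@dataclass(frozen=True)
class Locus:
    """One STR marker of a panel.

    Parameters
    ----------
    name:
        Marker name, unique within a panel (e.g. ``"FGA"``).
    repeat_unit:
        Repeat motif length in bases (4 for tetra-, 5 for pentanucleotide
        markers such as PentaD/PentaE).
    """

    name: str
    repeat_unit: int = 4

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("locus name must be nonempty")
        if self.repeat_unit < 1:
            raise ValueError("repeat_unit must be >= 1")


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid call stored canonically with ``a <= b`` (tenths)."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if (self.a == MISSING) != (self.b == MISSING):
            raise ValueError("half-missing genotype calls are rejected")
        if self.a > self.b:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @classmethod
    def from_labels(cls, a: str, b: str) -> "Genotype":
        x, y = parse_allele(a), parse_allele(b)
        return cls(min(x, y), max(x, y))

    @property
    def is_missing(self) -> bool:
        return self.a == MISSING

    @property
    def is_heterozygous(self) -> bool:
        return not self.is_missing and self.a != self.b

    def labels(self) -> tuple[str, str]:
        return format_allele(self.a), format_allele(self.b)


class GenotypeTable:
    """Diploid STR calls for a cohort of individuals.

    Internally each locus is a ``(n_individuals, 2)`` int array of allele
    tenths, with both entries ``MISSING`` for a failed call; alleles within an
    individual are stored sorted, so the pair is unordered by construction.
    """

    def __init__(
        self,
        panel: Sequence[Locus],
        sample_ids: Sequence[str],
        populations: Sequence[str],
        calls: Mapping[str, np.ndarray],
        sex: Sequence[str] | None = None,
    ) -> None:
        self.panel = list(panel)
        self.sample_ids = list(sample_ids)
        self.populations = np.asarray(populations, dtype=object)
        self.sex = None if sex is None else list(sex)
        names = [l.name for l in self.panel]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate locus name in panel")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample_id")
        if any(not p for p in self.populations):
            raise SchemaError("population_id must be nonempty")
        if len(self.populations) != len(self.sample_ids):
            raise SchemaError("populations and sample_ids length mismatch")
        self.calls: dict[str, np.ndarray] = {}
        for name in names:
            if name not in calls:
                raise SchemaError(f"no calls for panel locus {name!r}")
            arr = np.asarray(calls[name], dtype=np.int64)
            if arr.shape != (len(self.sample_ids), 2):
                raise SchemaError(f"calls for {name!r} have shape {arr.shape}")
            half = (arr == MISSING).sum(axis=1) == 1
            if half.any():
                raise SchemaError(f"half-missing call at locus {name!r}")
            self.calls[name] = np.sort(arr, axis=1)
        extra = set(calls) - set(names)
        if extra:
            raise SchemaError(f"calls for unknown loci: {sorted(extra)}")

    # -- basic views ------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.panel]

    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def subset(self, populations: Iterable[str]) -> "GenotypeTable":
        wanted = set(populations)
        mask = np.array([p in wanted for p in self.populations])
        return GenotypeTable(
            self.panel,
            [s for s, m in zip(self.sample_ids, mask) if m],
            self.populations[mask],
            {k: v[mask] for k, v in self.calls.items()},
            None if self.sex is None else [s for s, m in zip(self.sex, mask) if m],
        )

    def relabel_populations(self, mapping: Mapping[str, str]) -> "GenotypeTable":
        """Return a copy with population ids mapped (e.g. pooling cities)."""
        pops = [mapping.get(p, p) for p in self.populations]
        return GenotypeTable(self.panel, self.sample_ids, pops, self.calls, self.sex)

    def genotype(self, i: int, locus: str) -> Genotype:
        a, b = self.calls[locus][i]
        return Genotype(int(a), int(b))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.panel == other.panel
            and self.sample_ids == other.sample_ids
            and list(self.populations) == list(other.populations)
            and all(np.array_equal(self.calls[k], other.calls[k]) for k in self.calls)
        )


@dataclass
class PopulationMeta:
    """Population metadata table: id, display name, N, lat/lon, group label."""

    table: pd.DataFrame

    REQUIRED = ("population_id", "name", "n", "lat", "lon", "group")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise SchemaError(f"population metadata missing columns {missing}")
        t = self.table
        if t["population_id"].duplicated().any():
            raise SchemaError("duplicate population_id in metadata")
        if not ((t["lat"] >= -90) & (t["lat"] <= 90)).all():
            raise SchemaError("latitude out of [-90, 90]")
        if not ((t["lon"] > -180) & (t["lon"] <= 180)).all():
            raise SchemaError("longitude out of (-180, 180]")
        if not (t["n"] >= 1).all():
            raise SchemaError("sample size N must be >= 1")

    def coordinates(self) -> pd.DataFrame:
        return self.table.set_index("population_id")[["lat", "lon"]]


def read_population_meta(path) -> PopulationMeta:
    return PopulationMeta(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Genotype I/O: CSV dialect
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", ".", "./.", "-", "-/-", "0/0", "NA"}


def read_genotypes_csv(path, panel: Sequence[Locus] | None = None) -> GenotypeTable:
    """Read the package's CSV genotype dialect.

    Columns: ``sample_id``, ``population``, optionally ``amelogenin``, then
    one ``a/b`` column per locus (e.g. ``16/17``, ``9.3/9.3``).  Missing
    genotypes are empty cells or ``./.``.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty genotype CSV") from None
        header = [h.strip() for h in header]
        if header[:2] != ["sample_id", "population"]:
            raise SchemaError(
                "genotype CSV must start with columns sample_id,population"
            )
        rest = header[2:]
        has_sex = bool(rest) and rest[0].lower() == "amelogenin"
        locus_cols = rest[1:] if has_sex else rest
        if panel is None:
            panel = [Locus(n, 5 if n.lower().startswith("penta") else 4) for n in locus_cols]
        else:
            known = {l.name for l in panel}
            unknown = [c for c in locus_cols if c not in known]
            if unknown:
                raise SchemaError(f"unknown loci in CSV header: {unknown}")
        sample_ids: list[str] = []
        pops: list[str] = []
        sex: list[str] = []
        rows: list[list[tuple[int, int]]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ParseError(f"line {lineno}: expected {len(header)} fields, got {len(row)}")
            sample_ids.append(row[0].strip())
            pops.append(row[1].strip())
            cells = row[2:]
            if has_sex:
                sex.append(cells[0].strip())
                cells = cells[1:]
            calls_row = []
            for col, cell in zip(locus_cols, cells):
                cell = cell.strip()
                if cell in _MISSING_TOKENS:
                    calls_row.append((MISSING, MISSING))
                    continue
                if "/" not in cell:
                    raise ParseError(f"line {lineno}: genotype {cell!r} at {col} lacks '/'")
                a, b, *extra = cell.split("/")
                if extra:
                    raise ParseError(f"line {lineno}: genotype {cell!r} at {col} has >2 alleles")
                try:
                    g = Genotype.from_labels(a, b)
                except ValueError as e:
                    raise ParseError(f"line {lineno}: {e}") from None
                calls_row.append((g.a, g.b))
            rows.append(calls_row)
    by_name = {l.name: l for l in panel}
    calls = {
        col: np.array([r[j] for r in rows], dtype=np.int64).reshape(len(rows), 2)
        for j, col in enumerate(locus_cols)
    }
    return GenotypeTable(
        [by_name[c] for c in locus_cols],
        sample_ids,
        pops,
        calls,
        sex if has_sex else None,
    )


def write_genotypes_csv(gt: GenotypeTable, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        cols = ["sample_id", "population"]
        if gt.sex is not None:
            cols.append("amelogenin")
        cols += gt.locus_names
        w.writerow(cols)
        for i, sid in enumerate(gt.sample_ids):
            row = [sid, gt.populations[i]]
            if gt.sex is not None:
                row.append(gt.sex[i])
            for name in gt.locus_names:
                a, b = gt.calls[name][i]
                row.append("" if a == MISSING else f"{format_allele(a)}/{format_allele(b)}")
            w.writerow(row)


# ---------------------------------------------------------------------------
# Genotype I/O: GenePop
# ---------------------------------------------------------------------------

def _genepop_code_maps(allele_code_map: Mapping[str, int] | None):
    # label -> code for writing, code -> tenths for reading
    if allele_code_map is None:
        return None, None
    label_to_code = {parse_allele(k): int(v) for k, v in allele_code_map.items()}
    code_to_tenths = {int(v): parse_allele(k) for k, v in allele_code_map.items()}
    if len(code_to_tenths) != len(label_to_code):
        raise ValueError("allele_code_map is not one-to-one")
    return label_to_code, code_to_tenths


def read_genotypes_genepop(
    path,
    allele_code_map: Mapping[str, int] | None = None,
    panel: Sequence[Locus] | None = None,
) -> GenotypeTable:
    """Read a GenePop file (2- or 3-digit allele codes, auto-detected).

    GenePop codes alleles as fixed-width integers and cannot natively encode
    microvariants such as 9.3; files using an ad-hoc code (e.g. ``93``) need
    an explicit ``allele_code_map`` of ``{label: code}`` pairs.  Without a
    map, codes are taken to be whole repeat numbers.
    """
    _, code_to_tenths = _genepop_code_maps(allele_code_map)
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty GenePop file")
    # line 1 is a free title; locus names follow, one per line or comma-joined
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        part = lines[i].strip()
        if part:
            locus_names += [t.strip() for t in part.split(",") if t.strip()]
        i += 1
    if i == len(lines):
        raise ParseError("GenePop file has no 'Pop' line")
    if panel is None:
        panel = [Locus(n, 5 if n.lower().startswith("penta") else 4) for n in locus_names]
    sample_ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_counter = 0
    width: int | None = None
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_counter += 1
            continue
        if "," not in line:
            raise ParseError(f"line {i}: GenePop individual line lacks ','")
        name, _, geno_part = line.partition(",")
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise ParseError(
                f"line {i}: expected {len(locus_names)} genotypes, got {len(tokens)}"
            )
        calls_row = []
        for tok in tokens:
            if width is None:
                if len(tok) in (4, 6):
                    width = len(tok) // 2
                else:
                    raise ParseError(f"line {i}: genotype token {tok!r} is not 4 or 6 digits")
            if len(tok) != 2 * width or not tok.isdigit():
                raise ParseError(f"line {i}: malformed genotype token {tok!r}")
            c1, c2 = int(tok[:width]), int(tok[width:])
            if c1 == 0 or c2 == 0:
                if c1 != c2:
                    raise ParseError(f"line {i}: half-missing genotype {tok!r}")
                calls_row.append((MISSING, MISSING))
                continue
            if code_to_tenths is not None:
                a = code_to_tenths.get(c1, c1 * 10)
                b = code_to_tenths.get(c2, c2 * 10)
            else:
                a, b = c1 * 10, c2 * 10
            calls_row.append((min(a, b), max(a, b)))
        sample_ids.append(name.strip() or f"ind{len(sample_ids) + 1}")
        pops.append(f"pop{pop_counter}")
        rows.append(calls_row)
    if pop_counter == 0 or not rows:
        raise ParseError("GenePop file contains no individuals")
    by_name = {l.name: l for l in panel}
    unknown = [n for n in locus_names if n not in by_name]
    if unknown:
        raise SchemaError(f"unknown loci in GenePop header: {unknown}")
    calls = {
        n: np.array([r[j] for r in rows], dtype=np.int64)
        for j, n in enumerate(locus_names)
    }
    # GenePop has no sample-id uniqueness guarantee; disambiguate if needed
    if len(set(sample_ids)) != len(sample_ids):
        sample_ids = [f"{s}_{k}" for k, s in enumerate(sample_ids)]
    return GenotypeTable([by_name[n] for n in locus_names], sample_ids, pops, calls)


def write_genotypes_genepop(
    gt: GenotypeTable,
    path,
    allele_code_map: Mapping[str, int] | None = None,
    title: str = "strpopgen export",
) -> None:
    """Write GenePop (3-digit codes).  Microvariant alleles require a map."""
    label_to_code, _ = _genepop_code_maps(allele_code_map)

    def code_of(tenths: int) -> int:
        if label_to_code is not None and tenths in label_to_code:
            return label_to_code[tenths]
        if tenths % 10 != 0:
            raise ValueError(
                f"allele {format_allele(tenths)} has no integer GenePop code; "
                "supply an allele_code_map"
            )
        return tenths // 10
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(title + "\n")
        for name in gt.locus_names:
            fh.write(name + "\n")
        for pop in gt.population_ids():
            fh.write("Pop\n")
            idx = [i for i, p in enumerate(gt.populations) if p == pop]
            for i in idx:
                parts = []
                for name in gt.locus_names:
                    a, b = gt.calls[name][i]
                    if a == MISSING:
                        parts.append("000000")
                    else:
                        parts.append(f"{code_of(int(a)):03d}{code_of(int(b)):03d}")
                fh.write(f"{gt.sample_ids[i]} , " + " ".join(parts) + "\n")


def read_genotypes(path, dialect: str = "csv", **kwargs) -> GenotypeTable:
    """Dispatch to the CSV or GenePop reader by ``dialect``."""
    if dialect == "csv":
        return read_genotypes_csv(path, **kwargs)
    if dialect == "genepop":
        return read_genotypes_genepop(path, **kwargs)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) allele->frequency maps with gene-copy counts.

    ``table`` is tidy: population, locus, allele (canonical label),
    frequency (fraction of one), n_gene_copies (2 x individuals typed).
    """

    table: pd.DataFrame
    _tol: float = field(default=1e-9, repr=False)

    COLUMNS = ("population", "locus", "allele", "frequency", "n_gene_copies")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"frequency table missing columns {missing}")
        t = self.table
        if ((t["frequency"] < 0) | (t["frequency"] > 1)).any():
            raise SchemaError("frequencies must lie in [0, 1]")
        sums = t.groupby(["population", "locus"], sort=False)["frequency"].sum()
        bad = sums[(sums - 1.0).abs() > max(self._tol, 1e-6)]
        if len(bad):
            pop, loc = bad.index[0]
            raise SchemaError(
                f"frequencies for ({pop}, {loc}) sum to {bad.iloc[0]:.6f}, not 1"
            )
        n = t.groupby(["population", "locus"], sort=False)["n_gene_copies"].nunique()
        if (n != 1).any():
            raise SchemaError("inconsistent n_gene_copies within a (population, locus)")
        if (t["n_gene_copies"] <= 0).any() or (t["n_gene_copies"] % 2 != 0).any():
            raise SchemaError("n_gene_copies must be even and positive")

    # -- access -----------------------------------------------------------

    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.table["population"]))

    def loci(self, population: str | None = None) -> list[str]:
        t = self.table
        if population is not None:
            t = t[t["population"] == population]
        return list(dict.fromkeys(t["locus"]))

    def freqs(self, population: str, locus: str) -> dict[int, float]:
        """Allele (tenths) -> frequency for one cell; empty dict if absent."""
        t = self.table
        cell = t[(t["population"] == population) & (t["locus"] == locus)]
        return {parse_allele(a): f for a, f in zip(cell["allele"], cell["frequency"])}

    def gene_copies(self, population: str, locus: str) -> int:
        t = self.table
        cell = t[(t["population"] == population) & (t["locus"] == locus)]
        if cell.empty:
            raise KeyError((population, locus))
        return int(cell["n_gene_copies"].iloc[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AlleleFrequencyTable):
            return NotImplemented
        a = self.table.sort_values(list(self.COLUMNS)).reset_index(drop=True)
        b = other.table.sort_values(list(self.COLUMNS)).reset_index(drop=True)
        if len(a) != len(b):
            return False
        same = (
            (a["population"] == b["population"]).all()
            and (a["locus"] == b["locus"]).all()
            and (a["allele"] == b["allele"]).all()
            and (a["n_gene_copies"] == b["n_gene_copies"]).all()
            and np.allclose(a["frequency"], b["frequency"], atol=1e-12, rtol=0)
        )
        return bool(same)


def allele_frequencies(
    gt: GenotypeTable,
    pool: Mapping[str, Sequence[str]] | None = None,
) -> AlleleFrequencyTable:
    """Count allele frequencies per (population, locus).

    ``pool`` optionally maps a merged-population name to the member
    population ids (e.g. ``{"urban_total": [...six cities...]}``); merged
    rows are appended after the per-population rows.  A (population, locus)
    cell with no successful call is omitted with a logged warning.
    """
    records: list[tuple[str, str, str, float, int]] = []

    def _count(pop_name: str, mask: np.ndarray) -> None:
        for locus in gt.locus_names:
            arr = gt.calls[locus][mask]
            alleles = arr[arr[:, 0] != MISSING].ravel()
            if alleles.size == 0:
                logger.warning("no calls for (%s, %s); cell omitted", pop_name, locus)
                continue
            vals, counts = np.unique(alleles, return_counts=True)
            n = int(alleles.size)
            for v, c in zip(vals, counts):
                records.append((pop_name, locus, format_allele(int(v)), c / n, n))

    for pop in gt.population_ids():
        _count(pop, np.asarray(gt.populations == pop))
    if pool:
        for merged, members in pool.items():
            member_set = set(members)
            mask = np.array([p in member_set for p in gt.populations])
            _count(merged, mask)
    return AlleleFrequencyTable(
        pd.DataFrame(records, columns=list(AlleleFrequencyTable.COLUMNS))
    )


def write_frequency_db(aft: AlleleFrequencyTable, path) -> None:
    """Write the tidy reference-database CSV (frequencies at full precision)."""
    t = aft.table.copy()
    t["frequency"] = [repr(float(x)) for x in t["frequency"]]
    t.to_csv(path, index=False)


def read_frequency_db(path) -> AlleleFrequencyTable:
    t = pd.read_csv(path, dtype={"population": str, "locus": str, "allele": str})
    t["frequency"] = t["frequency"].astype(float)
    t["n_gene_copies"] = t["n_gene_copies"].astype(int)
    # canonicalize allele labels ("9.30" -> "9.3")
    t["allele"] = [format_allele(parse_allele(a)) for a in t["allele"]]
    return AlleleFrequencyTable(t)
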