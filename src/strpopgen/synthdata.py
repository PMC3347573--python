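"""Synthetic multi-population STR genotype generator.

The generator emulates a forensic STR study cohort: a set of subpopulations
that diverged from a common ancestral gene pool, genotyped on a multiallelic
panel.  Divergence is modelled with the Balding-Nichols correlated-frequency
model: subpopulation allele frequencies are drawn from a Dirichlet
distribution with parameters ``p_i (1 - theta) / theta`` around the
ancestral vector ``p``, so that ``E[q_i] = p_i`` and
``Var[q_i] = theta p_i (1 - p_i)`` — ``theta`` is the expected Wright
fixation index Fst between subpopulations and the ancestral pool.

Genotypes are then drawn per individual as two gametes i.i.d. from the
subpopulation frequencies, optionally mixing identical-by-descent copies at
rate ``f`` (inbreeding), which depresses heterozygosity by the factor
``(1 - f)``.

Randomness uses one global seed and a documented stream-splitting scheme
(one ``SeedSequence`` spawn key per role x population x locus), so adding
loci or populations never perturbs draws made for earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .strdata import GenotypeTable, Locus, format_allele, parse_allele

__all__ = [
    "LocusSpec",
    "SimulationConfig",
    "SimulationTruth",
    "draw_subpop_frequencies",
    "simulate_genotypes",
    "make_paperlike_panel",
    "make_study_cohort",
    "PAPERLIKE_LOCI",
    "STUDY_POPULATIONS",
]


@dataclass(frozen=True)
class LocusSpec:
    """Panel entry for the simulator.

    ``labels`` are allele labels in tenths of a repeat; ``ancestral`` are the
    ancestral frequencies (same length, summing to 1) or ``None`` to draw
    them from the configured ancestral law at simulation time.
    """

    name: str
    labels: tuple[int, ...]
    ancestral: tuple[float, ...] | None = None
    repeat_unit: int = 4

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError(f"locus {self.name}: need >= 2 alleles")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"locus {self.name}: duplicate allele labels")
        if self.ancestral is not None:
            if len(self.ancestral) != len(self.labels):
                raise ValueError(f"locus {self.name}: ancestral length mismatch")
            if abs(sum(self.ancestral) - 1.0) > 1e-9 or min(self.ancestral) < 0:
                raise ValueError(f"locus {self.name}: ancestral frequencies invalid")

    @property
    def n_alleles(self) -> int:
        return len(self.labels)


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated cohort."""

    n_populations: int
    n_per_population: int | Sequence[int]
    loci: list[LocusSpec]
    theta: float = 0.0
    inbreeding: float = 0.0
    ancestral_law: str = "uniform"  # {"uniform", "triangular"}
    seed: int = 0
    population_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValueError("n_populations must be >= 1")
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must lie in [0, 1)")
        if not 0.0 <= self.inbreeding <= 1.0:
            raise ValueError("inbreeding f must lie in [0, 1]")
        if self.ancestral_law not in ("uniform", "triangular"):
            raise ValueError(f"unknown ancestral law {self.ancestral_law!r}")
        if not self.loci:
            raise ValueError("panel must contain at least one locus")

    def sizes(self) -> list[int]:
        if isinstance(self.n_per_population, int):
            ns = [self.n_per_population] * self.n_populations
        else:
            ns = list(self.n_per_population)
            if len(ns) != self.n_populations:
                raise ValueError("n_per_population length != n_populations")
        if any(n < 1 for n in ns):
            raise ValueError("population sizes must be >= 1")
        return ns

    def pop_names(self) -> list[str]:
        if self.population_names is not None:
            if len(self.population_names) != self.n_populations:
                raise ValueError("population_names length != n_populations")
            return list(self.population_names)
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    # -- YAML round trip --------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "n_populations": self.n_populations,
            "n_per_population": self.n_per_population
            if isinstance(self.n_per_population, int)
            else list(self.n_per_population),
            "theta": float(self.theta),
            "inbreeding": float(self.inbreeding),
            "ancestral_law": self.ancestral_law,
            "seed": int(self.seed),
            "population_names": self.population_names,
            "loci": [
                {
                    "name": l.name,
                    "repeat_unit": l.repeat_unit,
                    "alleles": [format_allele(t) for t in l.labels],
                    "ancestral": None if l.ancestral is None else [float(x) for x in l.ancestral],
                }
                for l in self.loci
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        loci = [
            LocusSpec(
                name=d["name"],
                labels=tuple(parse_allele(str(a)) for a in d["alleles"]),
                ancestral=None if d.get("ancestral") is None else tuple(d["ancestral"]),
                repeat_unit=int(d.get("repeat_unit", 4)),
            )
            for d in doc["loci"]
        ]
        return cls(
            n_populations=int(doc["n_populations"]),
            n_per_population=doc["n_per_population"],
            loci=loci,
            theta=float(doc.get("theta", 0.0)),
            inbreeding=float(doc.get("inbreeding", 0.0)),
            ancestral_law=doc.get("ancestral_law", "uniform"),
            seed=int(doc.get("seed", 0)),
            population_names=doc.get("population_names"),
        )


@dataclass
class SimulationTruth:
    """Latent state of a simulation run: all frequencies plus theta."""

    theta: float
    inbreeding: float
    seed: int
    frequencies: pd.DataFrame  # population, locus, allele, ancestral, subpop

    def to_csv(self, path) -> None:
        head = f"# theta={self.theta} inbreeding={self.inbreeding} seed={self.seed}\n"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(head)
            self.frequencies.to_csv(fh, index=False)


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def draw_subpop_frequencies(
    ancestral: Sequence[float],
    theta: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw one subpopulation frequency vector under Balding-Nichols.

    ``theta = 0`` returns the ancestral vector unchanged (no division by
    zero); alleles with zero ancestral frequency stay at zero.
    """
    p = np.asarray(ancestral, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("ancestral frequencies must be a probability vector")
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must lie in [0, 1)")
    if theta == 0.0:
        return p.copy()
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = rng.dirichlet(p[pos] * (1.0 - theta) / theta)
    return out


def simulate_genotypes(cfg: SimulationConfig) -> tuple[GenotypeTable, SimulationTruth]:
    """Simulate a full cohort; byte-identical output for a fixed seed.

    Stream-splitting scheme (spawn keys off the global seed):
    ``(0, locus)`` ancestral draw, ``(1, pop, locus)`` subpopulation
    frequencies, ``(2, pop, locus)`` gamete sampling, ``(3, pop)``
    inbreeding indicators.
    """
    sizes = cfg.sizes()
    pop_names = cfg.pop_names()
    n_total = sum(sizes)

    # ancestral frequencies per locus
    ancestrals: list[np.ndarray] = []
    for li, spec in enumerate(cfg.loci):
        if spec.ancestral is not None:
            ancestrals.append(np.asarray(spec.ancestral, dtype=float))
            continue
        rng = _rng(cfg.seed, 0, li)
        k = spec.n_alleles
        if cfg.ancestral_law == "uniform":
            ancestrals.append(rng.dirichlet(np.ones(k)))
        else:  # triangular, SMM-like unimodal around the central allele
            center = (k - 1) / 2.0
            w = 1.0 + np.minimum(np.arange(k), k - 1 - np.arange(k))
            ancestrals.append(rng.dirichlet(5.0 * w / w.mean()))

    sample_ids: list[str] = []
    populations: list[str] = []
    for pi, (name, n) in enumerate(zip(pop_names, sizes)):
        sample_ids += [f"{name}_{j + 1:04d}" for j in range(n)]
        populations += [name] * n

    calls: dict[str, np.ndarray] = {}
    truth_rows: list[tuple[str, str, str, float, float]] = []
    for li, spec in enumerate(cfg.loci):
        labels = np.asarray(spec.labels, dtype=np.int64)
        col = np.empty((n_total, 2), dtype=np.int64)
        offset = 0
        for pi, (name, n) in enumerate(zip(pop_names, sizes)):
            q = draw_subpop_frequencies(ancestrals[li], cfg.theta, _rng(cfg.seed, 1, pi, li))
            g_rng = _rng(cfg.seed, 2, pi, li)
            gametes = g_rng.choice(len(labels), size=(n, 2), p=q)
            if cfg.inbreeding > 0.0:
                ibd = _rng(cfg.seed, 3, pi).random(n_total)[offset : offset + n] < cfg.inbreeding
                gametes[ibd, 1] = gametes[ibd, 0]
            col[offset : offset + n] = np.sort(labels[gametes], axis=1)
            offset += n
            for a, pa, qa in zip(spec.labels, ancestrals[li], q):
                truth_rows.append((name, spec.name, format_allele(a), float(pa), float(qa)))
        calls[spec.name] = col

    panel = [Locus(s.name, s.repeat_unit) for s in cfg.loci]
    gt = GenotypeTable(panel, sample_ids, populations, calls)
    truth = SimulationTruth(
        theta=cfg.theta,
        inbreeding=cfg.inbreeding,
        seed=cfg.seed,
        frequencies=pd.DataFrame(
            truth_rows,
            columns=["population", "locus", "allele", "ancestral_frequency", "subpop_frequency"],
        ),
    )
    return gt, truth


# ---------------------------------------------------------------------------
# PowerPlex-16-like panel
# ---------------------------------------------------------------------------

def _labels(*parts) -> tuple[int, ...]:
    out: list[int] = []
    for p in parts:
        if isinstance(p, range):
            out += [x * 10 for x in p]
        else:
            out.append(parse_allele(str(p)))
    return tuple(sorted(out))


# (name, repeat unit, allele labels, target expected heterozygosity)
# Allele counts follow the PowerPlex 16 panel as observed in North-Eurasian
# cohorts: 8,8,17,18,18,9,10,12,9,8,13,10,11,8,20 alleles per locus, with
# plausible ladder ranges and microvariants (TH01 9.3, D21S11 x.2, FGA x.2).
PAPERLIKE_LOCI: list[tuple[str, int, tuple[int, ...], float]] = [
    ("D3S1358", 4, _labels(range(12, 20)), 0.77543),
    ("TH01", 4, _labels(range(5, 10), "9.3", 10, 11), 0.78141),
    ("D21S11", 4, _labels(range(27, 36), "28.2", "29.2", "30.2", "31.2", "32.2", "33.2", "34.2", 36), 0.84974),
    ("D18S51", 4, _labels(range(9, 26), "13.2"), 0.87419),
    ("PentaE", 5, _labels(range(5, 22), 23), 0.91497),
    ("D5S818", 4, _labels(range(7, 16)), 0.73859),
    ("D13S317", 4, _labels(range(7, 17)), 0.79676),
    ("D7S820", 4, _labels(range(6, 17), "9.1"), 0.80174),
    ("D16S539", 4, _labels(range(8, 16), "9.3"), 0.78966),
    ("CSF1PO", 4, _labels(range(7, 15)), 0.73503),
    ("PentaD", 5, _labels("2.2", range(5, 16), 17), 0.82446),
    ("vWA", 4, _labels(range(11, 21)), 0.79355),
    ("D8S1179", 4, _labels(range(8, 19)), 0.79676),
    ("TPOX", 4, _labels(range(6, 14)), 0.61227),
    ("FGA", 4, _labels(range(18, 32), "21.2", "22.2", "23.2", "24.2", "25.2", "26.2"), 0.85811),
]


def _shaped_ancestral(k: int, target_he: float) -> np.ndarray:
    """Unimodal frequency vector with 1 - sum(p^2) equal to ``target_he``.

    Uses the family p_j ∝ exp(-lam |j - center|); lam = 0 is uniform
    (maximal He = 1 - 1/k), large lam concentrates mass on the central
    allele (He -> 0).  Solved by bisection; exact to 1e-12.
    """
    if not 0.0 <= target_he < 1.0 - 1.0 / k:
        raise ValueError(f"target He {target_he} unreachable with {k} alleles")
    j = np.abs(np.arange(k) - (k - 1) / 2.0)

    def he(lam: float) -> float:
        w = np.exp(-lam * j)
        p = w / w.sum()
        return 1.0 - float(np.sum(p * p))

    lo, hi = 0.0, 1.0
    while he(hi) > target_he:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if he(mid) > target_he:
            lo = mid
        else:
            hi = mid
    w = np.exp(-0.5 * (lo + hi) * j)
    p = w / w.sum()
    return p / p.sum()


# study design scale: 17 cohorts, 1,156 individuals in total — six urban
# samples (first six entries) plus eleven ethnic-group samples
STUDY_POPULATIONS: list[tuple[str, int]] = [
    ("Moscow", 60), ("Belgorod", 50), ("Orel", 51), ("Orenburg", 50),
    ("Yaroslavl", 50), ("Tomsk", 185), ("Komi", 50), ("Mari", 52),
    ("Khakas", 92), ("Bashkir", 70), ("Tatar", 61), ("Chuvash", 53),
    ("Dargins", 48), ("Avars", 50), ("Lezgins", 50), ("Ukrainians", 138),
    ("Belorussians", 46),
]


def make_study_cohort(seed: int = 0, theta: float = 0.0267) -> "SimulationConfig":
    """Config at the full study design scale.

    Seventeen named populations with the study's sample sizes (1,156
    individuals) on the 15-locus panel; the default divergence equals the
    cohort's overall among-population fixation index (Fst = 0.0267).
    """
    names = [n for n, _ in STUDY_POPULATIONS]
    sizes = [s for _, s in STUDY_POPULATIONS]
    cfg = make_paperlike_panel(
        seed=seed, n_populations=len(names), n_per_population=sizes, theta=theta
    )
    cfg.population_names = names
    return cfg


def make_paperlike_panel(
    seed: int = 0,
    n_populations: int = 17,
    n_per_population: int | Sequence[int] = 68,
    theta: float = 0.0267,
) -> SimulationConfig:
    """Simulation config emulating a 15-locus PowerPlex-16-style study.

    Fifteen loci with the panel's observed per-locus allele counts; each
    locus's ancestral frequencies are shaped so its expected heterozygosity
    matches the cohort-level values (0.61 at the least polymorphic locus,
    TPOX, up to 0.91 at PentaE).  Defaults mirror the study design scale:
    17 populations averaging 68 individuals (1,156 total) and an
    among-population divergence of theta = 0.0267.
    """
    loci = [
        LocusSpec(
            name=name,
            labels=labels,
            ancestral=tuple(_shaped_ancestral(len(labels), he)),
            repeat_unit=unit,
        )
        for name, unit, labels, he in PAPERLIKE_LOCI
    ]
    return SimulationConfig(
        n_populations=n_populations,
        n_per_population=n_per_population,
        loci=loci,
        theta=theta,
        seed=seed,
    )
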