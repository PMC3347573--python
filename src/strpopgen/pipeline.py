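"""End-to-end orchestration of the STR analysis flow.

One call runs the stages in their natural order — allele frequencies,
diversity summaries, exact HWE tests, forensic indices, AMOVA
differentiation, distance/tree/ordination, and (when population coordinates
are available) the gene-geographic heterozygosity raster — writing every
table-shaped artifact to an output directory together with a manifest of
content hashes, the seed, and the parameters used, so reruns are
verifiably byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_summary
from .differentiation import amova, pairwise_matrix
from .forensic import forensic_summary
from .geomap import ReferencePoint, build_grid, shepard_interpolate, write_esri_ascii
from .hwe import deviation_accumulation, hwe_test_table
from .popstruct import mds, nei_distance_matrix, upgma, write_phylip_distances
from .strdata import (
    GenotypeTable,
    PopulationMeta,
    allele_frequencies,
    read_genotypes,
    read_population_meta,
    write_frequency_db,
)
from .synthdata import SimulationConfig, simulate_genotypes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the partial manifest was written."""


@dataclass
class RunConfig:
    """Inputs and per-stage parameters for one pipeline run."""

    output_dir: str | Path
    genotypes: str | Path | None = None
    dialect: str = "csv"
    simulation: str | Path | SimulationConfig | None = None
    metadata: str | Path | None = None
    seed: int = 0
    permutations: int = 1000
    hwe_steps: int = 100_000
    hwe_burn_in: int = 10_000
    distance_metric: str = "identity"  # AMOVA metric for pairwise matrices
    grid_cols: int = 881
    grid_rows: int = 381
    grid_bounds: tuple[float, float, float, float] = (10.0, 180.0, 35.0, 75.0)
    stages: tuple[str, ...] = (
        "frequencies",
        "diversity",
        "hwe",
        "forensic",
        "differentiation",
        "structure",
        "geomap",
    )

    def __post_init__(self) -> None:
        if (self.genotypes is None) == (self.simulation is None):
            raise ValueError("provide exactly one of genotypes or simulation")
        for p in (self.genotypes, self.metadata):
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")
        if isinstance(self.simulation, (str, Path)) and not Path(self.simulation).exists():
            raise ValueError(f"simulation config does not exist: {self.simulation}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "parameters": {
            "permutations": cfg.permutations,
            "hwe_steps": cfg.hwe_steps,
            "hwe_burn_in": cfg.hwe_burn_in,
            "distance_metric": cfg.distance_metric,
        },
        "stages": {},
        "artifacts": {},
    }

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["artifacts"][name] = _sha256(path)

    def emit_csv(name: str, frame: pd.DataFrame) -> None:
        emit(name, lambda p: frame.to_csv(p, index=False, float_format="%.10g"))

    try:
        # ---- input ------------------------------------------------------
        if cfg.genotypes is not None:
            gt = read_genotypes(cfg.genotypes, dialect=cfg.dialect)
        else:
            sim = (
                cfg.simulation
                if isinstance(cfg.simulation, SimulationConfig)
                else SimulationConfig.from_yaml(cfg.simulation)
            )
            gt, truth = simulate_genotypes(sim)
            emit("simulation_truth.csv", truth.to_csv)
        meta: PopulationMeta | None = (
            read_population_meta(cfg.metadata) if cfg.metadata else None
        )
        pops = gt.population_ids()
        multi_pop = len(pops) >= 2

        # ---- frequencies -------------------------------------------------
        aft = allele_frequencies(gt)
        if "frequencies" in cfg.stages:
            emit("allele_frequencies.csv", lambda p: write_frequency_db(aft, p))
            manifest["stages"]["frequencies"] = "ok"

        # ---- diversity ---------------------------------------------------
        summary = None
        if "diversity" in cfg.stages:
            summary = diversity_summary(gt)
            emit_csv("diversity_cells.csv", summary.per_cell)
            emit_csv("diversity_per_locus.csv", summary.per_locus)
            emit_csv("diversity_per_population.csv", summary.per_population)
            manifest["stages"]["diversity"] = "ok"

        # ---- HWE ---------------------------------------------------------
        if "hwe" in cfg.stages:
            hw = hwe_test_table(
                gt, steps=cfg.hwe_steps, burn_in=cfg.hwe_burn_in, seed=cfg.seed
            )
            emit_csv("hwe_tests.csv", hw)
            emit_csv("hwe_deviations.csv", deviation_accumulation(hw))
            manifest["stages"]["hwe"] = "ok"

        # ---- forensic ----------------------------------------------------
        if "forensic" in cfg.stages:
            per_locus, combined = forensic_summary(gt)
            emit_csv("forensic_per_locus.csv", per_locus)
            emit_csv("forensic_combined.csv", combined)
            manifest["stages"]["forensic"] = "ok"

        # ---- differentiation --------------------------------------------
        if "differentiation" in cfg.stages:
            if not multi_pop:
                logger.warning("single population: differentiation stage skipped")
                manifest["stages"]["differentiation"] = "skipped: single population"
            else:
                res = amova(
                    gt, metric="identity", permutations=cfg.permutations, seed=cfg.seed
                )
                res_r = amova(gt, metric="repeat-squared", permutations=0)
                emit_csv(
                    "amova.csv",
                    pd.DataFrame(
                        [
                            {
                                "metric": "identity",
                                "index": res.fst,
                                "sigma_among": res.sigma_among,
                                "sigma_within": res.sigma_within,
                                "p_value": res.p_value,
                            },
                            {
                                "metric": "repeat-squared",
                                "index": res_r.fst,
                                "sigma_among": res_r.sigma_among,
                                "sigma_within": res_r.sigma_within,
                                "p_value": np.nan,
                            },
                        ]
                    ),
                )
                pw = pairwise_matrix(
                    gt,
                    metric=cfg.distance_metric,
                    permutations=cfg.permutations,
                    seed=cfg.seed,
                )
                emit(
                    "pairwise_fst.csv",
                    lambda p: pw.to_frame().to_csv(p, float_format="%.10g"),
                )
                manifest["stages"]["differentiation"] = "ok"

        # ---- distances / tree / ordination ------------------------------
        if "structure" in cfg.stages:
            if not multi_pop:
                logger.warning("single population: structure stage skipped")
                manifest["stages"]["structure"] = "skipped: single population"
            else:
                dm = nei_distance_matrix(aft)
                emit("nei_distances.phy", lambda p: write_phylip_distances(dm, p))
                tree = upgma(dm)
                emit("upgma.nwk", lambda p: Path(p).write_text(tree.newick() + "\n"))
                if len(pops) > 2:
                    ord_ = mds(dm, dims=2, seed=cfg.seed)
                    frame = ord_.to_frame().reset_index(names="population")
                    frame["stress"] = ord_.stress
                    emit_csv("mds_coordinates.csv", frame)
                manifest["stages"]["structure"] = "ok"

        # ---- gene geography ----------------------------------------------
        if "geomap" in cfg.stages:
            if meta is None:
                logger.warning("no population coordinates: geomap stage skipped")
                manifest["stages"]["geomap"] = "skipped: no metadata"
            else:
                if summary is None:
                    summary = diversity_summary(gt)
                coords = meta.coordinates()
                points = [
                    ReferencePoint(
                        row["population"],
                        float(coords.loc[row["population"], "lat"]),
                        float(coords.loc[row["population"], "lon"]),
                        float(row["mean_He"]),
                    )
                    for _, row in summary.per_population.iterrows()
                    if row["population"] in coords.index
                ]
                grid = build_grid(cfg.grid_bounds, cfg.grid_cols, cfg.grid_rows)
                filled = shepard_interpolate(points, grid)
                emit("heterozygosity_grid.asc", lambda p: write_esri_ascii(filled, p))
                emit(
                    "heterozygosity_legend.csv",
                    lambda p: pd.DataFrame([filled.stats]).to_csv(p, index=False),
                )
                manifest["stages"]["geomap"] = "ok"
    except Exception as e:
        manifest["error"] = str(e)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise PipelineError(str(e)) from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
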