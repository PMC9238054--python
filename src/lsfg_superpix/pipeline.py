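"""End-to-end orchestration: simulate or load, analyze, report.

A pipeline run produces a self-describing output directory::

    out/
      eye_measures.csv      one row per (patient, eye), 3-scan averages
      paired_tests.csv      paired t per measure
      differences.csv       per-patient deltas (long format)
      regressions.csv       slope/p per measure and eye group
      spearman.csv          correlation matrix in long format
      histograms.csv        five-range percentages per eye
      summary.txt           the fitted model's text summary
      figures/*.png         paired scatter, difference bars, trends, heatmap
      manifest.json         seed, config hash, package version, counts
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .model import REGRESSION_MEASURES, CohortFlowModel, CohortFlowResults
from .scan_io import read_cohort, read_scan, write_cohort
from .superpixel import DEFAULT_BIN_EDGES
from .synthetic import CohortGeometry, EffectModel, generate_cohort, to_cohort_patients

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("lsfg_superpix")


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one input mode must be set."""

    # input: either simulate a cohort ...
    simulate: bool = False
    n_patients: int = 25
    seed: int = 0
    effect: EffectModel = field(default_factory=EffectModel)
    geometry: CohortGeometry = field(default_factory=CohortGeometry)
    # ... or load one from disk
    cohort_table: str | None = None
    scan_dir: str | None = None
    # analysis parameters
    n_superpixels: int = 1500
    compactness: float = 50.0
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    exclude_mask_path: str | None = None
    alpha: float = 0.01
    bonferroni: bool = False
    # output
    out_dir: str = "lsfg_out"
    write_figures: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        load_mode = self.cohort_table is not None
        if self.simulate == load_mode:
            raise ValueError(
                "config must select exactly one input mode: simulate=true "
                "or cohort_table=<path>"
            )
        if load_mode and self.scan_dir is None:
            raise ValueError("load mode requires scan_dir")


def load_config(path: str | Path) -> PipelineConfig:
    """Build a config from a YAML mapping (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    effect = EffectModel(**raw.pop("effect", {}))
    geom_raw = raw.pop("geometry", {})
    if "shape" in geom_raw:
        geom_raw["shape"] = tuple(geom_raw["shape"])
    geometry = (
        CohortGeometry(**geom_raw) if geom_raw else CohortGeometry()
    )
    if "bin_edges" in raw:
        raw["bin_edges"] = tuple(raw["bin_edges"])
    return PipelineConfig(effect=effect, geometry=geometry, **raw)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_figures(results: CohortFlowResults, fig_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig_dir.mkdir(parents=True, exist_ok=True)
    for measure in ("mv", "mt", "pct_ge20", "pct_lt5"):
        for kind, plot in (
            ("paired", results.plot_paired),
            ("differences", results.plot_differences),
            ("trend", results.plot_time_trend),
        ):
            ax = plot(measure)
            ax.figure.savefig(fig_dir / f"{kind}_{measure}.png", dpi=120)
            plt.close(ax.figure)
    ax = results.plot_spearman_heatmap()
    ax.figure.savefig(fig_dir / "spearman_heatmap.png", dpi=120)
    plt.close(ax.figure)


def run_pipeline(config: PipelineConfig) -> CohortFlowResults:
    """Execute the configured run and write the full result bundle."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        logger.info("stage simulate: n_patients=%d seed=%d", config.n_patients,
                    config.seed)
        entries = generate_cohort(
            config.n_patients, config.effect, seed=config.seed,
            geometry=config.geometry,
        )
        patients = to_cohort_patients(entries, config.geometry)
    else:
        logger.info("stage load: %s", config.cohort_table)
        patients = read_cohort(config.cohort_table, config.scan_dir)
    logger.info("stage analyze: %d patients, %d scans", len(patients),
                sum(len(s) for p in patients for s in p.scans.values()))

    exclude_mask = None
    if config.exclude_mask_path is not None:
        mask_scan = read_scan(config.exclude_mask_path)
        exclude_mask = mask_scan.valid & (mask_scan.mbr > 0)
        logger.info("exclusion mask: %d pixels excluded", int(exclude_mask.sum()))

    model = CohortFlowModel.from_cohort(
        patients,
        n_superpixels=config.n_superpixels,
        compactness=config.compactness,
        bin_edges=config.bin_edges,
        exclude_mask=exclude_mask,
        seed=config.seed,
    )
    results = model.fit(alpha=config.alpha, bonferroni=config.bonferroni)

    model.measures.to_csv(out_dir / "eye_measures.csv", index=False)
    results.paired_tests.to_csv(out_dir / "paired_tests.csv", index=False)
    results.differences.to_csv(out_dir / "differences.csv", index=False)
    results.regressions.to_csv(out_dir / "regressions.csv", index=False)
    results.spearman.to_long().to_csv(out_dir / "spearman.csv", index=False)
    hist_cols = ["patient_id", "eye", "irradiated",
                 "pct_lt5", "pct_5_10", "pct_10_15", "pct_15_20", "pct_ge20"]
    model.measures[hist_cols].to_csv(out_dir / "histograms.csv", index=False)
    (out_dir / "summary.txt").write_text(results.summary() + "\n")

    if config.write_figures:
        _write_figures(results, out_dir / "figures")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_patients": len(patients),
        "n_scans": sum(len(s) for p in patients for s in p.scans.values()),
        "n_superpixels_target": config.n_superpixels,
        "measures": REGRESSION_MEASURES,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %s", out_dir)
    return results


def simulate_to_disk(config: PipelineConfig, cohort_dir: str | Path,
                     dialect: str = "tiff") -> Path:
    """Generate a synthetic cohort and write scans + metadata to disk."""
    entries = generate_cohort(
        config.n_patients, config.effect, seed=config.seed, geometry=config.geometry
    )
    patients = to_cohort_patients(entries, config.geometry)
    table = write_cohort(patients, cohort_dir, dialect=dialect)
    manifest = {"seed": config.seed, "n_patients": config.n_patients,
                "package_version": __version__,
                "effect": dataclasses.asdict(config.effect)}
    (Path(cohort_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return table
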