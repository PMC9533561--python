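"""End-to-end analysis runner: cohort directory -> tidy result tables.

Reproduces the full analysis flow on any cohort of cell tables: per-ROI
tumor-boundary estimation, 150 µm distance banding into TC/TF/PT, per-region
density quantification for every panel marker, CD68/CD163 macrophage
subtyping, CD8-based immunotype calls, and the Wilcoxon comparison battery
(overall, region contrasts, cross-lesion contrasts, clinical subgroups and
immunotype contrasts).

All outputs are deterministic functions of the inputs and configuration; a
provenance record (configuration + package version) is written beside every
results bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .cellio import Cohort, merge_lesions, read_cohort
from .errors import ConfigurationError, NoTumorRegionError, SpatialTMEError
from .geometry import (
    DEFAULT_BAND_WIDTH_UM,
    DEFAULT_CLOSING_RADIUS_UM,
    DEFAULT_GRID_RESOLUTION_UM,
    assign_regions,
    estimate_boundaries,
)
from .immunotype import call_immunotypes
from .quantify import (
    compute_densities,
    macrophage_profile,
    single_marker_defs,
    subtype_heatmap_matrix,
)
from .stats import run_comparison_battery

logger = logging.getLogger("spatialtme")


@dataclass
class PipelineConfig:
    band_width_um: float = DEFAULT_BAND_WIDTH_UM
    grid_resolution_um: float = DEFAULT_GRID_RESOLUTION_UM
    closing_radius_um: float = DEFAULT_CLOSING_RADIUS_UM
    no_tumor_policy: str = "error"  # "error" | "all_pt"
    pooling: str = "pooled"  # "pooled" | "roi_mean"
    immunotype_marker: str = "CD8"
    immunotype_threshold: float | None = None  # None => cohort median rule
    alpha: float = 0.05
    fdr: bool = False
    merge_metastatic_lesions: bool = True
    strict: bool = False

    def __post_init__(self) -> None:
        for name in ("band_width_um", "grid_resolution_um", "closing_radius_um", "alpha"):
            v = getattr(self, name)
            if name != "band_width_um" and not v > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.band_width_um < 0:
            raise ConfigurationError("band_width_um must be >= 0")
        if self.immunotype_threshold is not None and not self.immunotype_threshold > 0:
            raise ConfigurationError("immunotype_threshold must be positive")


def pipeline_config_from_dict(data: Mapping[str, Any]) -> PipelineConfig:
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**dict(data))


def pipeline_config_from_yaml(path: str | Path) -> PipelineConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError("config file must hold a mapping")
    return pipeline_config_from_dict(data)


def _merge_patient_lesions(cohort: Cohort, config: PipelineConfig) -> list:
    """One sample per (patient, lesion_type); metastatic lesions merged."""
    by_key: dict[tuple[str, str], list] = {}
    for s in cohort.samples:
        by_key.setdefault((s.patient_id, s.lesion_type), []).append(s)
    out = []
    for (pid, lt), group in by_key.items():
        if len(group) == 1:
            out.append(group[0])
        elif config.merge_metastatic_lesions:
            out.append(merge_lesions(group, lesion_id=f"{pid}-{lt.upper()[:3]}"))
        else:
            out.extend(group)
    return out


def run_pipeline(
    cohort: Cohort,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis; optionally write the results bundle.

    Returns a dict with keys ``densities``, ``macrophages``,
    ``macrophage_heatmap``, ``immunotypes`` and ``battery``.  Per-lesion
    failures (e.g. an ROI with no tumor region under the ``error`` policy)
    abort the run in ``strict`` mode and are logged and skipped otherwise.
    """
    config = config or PipelineConfig()
    samples = _merge_patient_lesions(cohort, config)

    density_frames: list[pd.DataFrame] = []
    macro_frames: list[pd.DataFrame] = []
    boundary_features: list[dict] = []
    failures: list[str] = []
    for sample in samples:
        try:
            boundaries = estimate_boundaries(
                sample,
                grid_resolution=config.grid_resolution_um,
                closing_radius=config.closing_radius_um,
                no_tumor_policy=config.no_tumor_policy,
            )
            partition = assign_regions(sample, boundaries, config.band_width_um)
            defs = single_marker_defs(sample.panel)
            density_frames.append(
                compute_densities(sample, partition, defs, config.pooling)
            )
            if "CD68" in sample.panel and "CD163" in sample.panel:
                macro_frames.append(
                    macrophage_profile(sample, partition, config.pooling)
                )
            for roi_id, b in boundaries.items():
                if b is None:
                    continue
                boundary_features.append(
                    {
                        "type": "Feature",
                        "properties": {
                            "patient_id": sample.patient_id,
                            "lesion_type": sample.lesion_type,
                            "lesion_id": sample.lesion_id,
                            "roi_id": roi_id,
                        },
                        "geometry": b.to_geojson(),
                    }
                )
            logger.info(
                "lesion %s/%s: %d cells, regions %s",
                sample.patient_id, sample.lesion_id, sample.n_cells,
                partition.counts(),
            )
        except SpatialTMEError as exc:
            msg = f"lesion {sample.patient_id}/{sample.lesion_id}: {exc}"
            if config.strict:
                raise
            failures.append(msg)
            logger.warning("skipping %s", msg)

    if not density_frames:
        raise SpatialTMEError("no lesion could be quantified")
    densities = pd.concat(density_frames, ignore_index=True)
    macrophages = (
        pd.concat(macro_frames, ignore_index=True) if macro_frames else pd.DataFrame()
    )
    heatmap = (
        subtype_heatmap_matrix(macrophages) if len(macrophages) else pd.DataFrame()
    )
    calls = call_immunotypes(
        densities,
        marker=config.immunotype_marker,
        threshold=config.immunotype_threshold,
    )
    battery = run_comparison_battery(
        densities,
        clinical=cohort.clinical,
        calls=calls,
        alpha=config.alpha,
        fdr=config.fdr,
    )
    results = {
        "densities": densities,
        "macrophages": macrophages,
        "macrophage_heatmap": heatmap,
        "immunotypes": calls,
        "battery": battery,
        "boundaries": {"type": "FeatureCollection", "features": boundary_features},
    }
    if out_dir is not None:
        write_results(results, config, Path(out_dir), failures)
    return results


def write_results(
    results: Mapping[str, pd.DataFrame],
    config: PipelineConfig,
    out_dir: Path,
    failures: list[str] | None = None,
) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    results["densities"].to_csv(out_dir / "densities.csv", index=False)
    results["macrophages"].to_csv(out_dir / "macrophages.csv", index=False)
    if len(results["macrophage_heatmap"]):
        results["macrophage_heatmap"].to_csv(out_dir / "macrophage_heatmap.csv")
    results["immunotypes"].to_csv(out_dir / "immunotypes.csv", index=False)
    results["battery"].to_csv(out_dir / "battery.csv", index=False)
    (out_dir / "boundaries.geojson").write_text(
        json.dumps(results["boundaries"]), encoding="utf-8"
    )
    provenance = {
        "package": "spatialtme",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "skipped_lesions": failures or [],
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=1, sort_keys=True), encoding="utf-8"
    )
    return out_dir


def run_directory(
    cohort_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Convenience wrapper: load a cohort directory and run the pipeline."""
    cohort = read_cohort(cohort_dir)
    return run_pipeline(cohort, config, out_dir)
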