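"""Density quantification and CD68/CD163 macrophage colocalization subtyping.

Immune infiltration is expressed as cell density — phenotype-positive cells
per mm² of regional tissue area — per lesion and region.  A phenotype is a
boolean conjunction over called marker positivity: single-marker phenotypes
("CD8" means CD8-positive regardless of co-expression) and combination
phenotypes (the three macrophage subtypes CD68+CD163+, CD68+CD163-,
CD68-CD163+, which together with double-negatives partition all cells).

Counts are pooled across the 3-5 imaged fields of a lesion and divided by
the summed regional area (sum-counts / sum-areas), which is unbiased under
unequal field areas; an unweighted per-field-mean alternative is exposed
for sensitivity analysis.  Besides TC/TF/PT rows, an ``ALL`` row pools TC
and TF, matching a non-regional (intratumoral) comparison.  Regions with
zero tissue area yield missing densities — never 0 or infinity — which
downstream statistics drop pairwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cellio import CellRecord, SampleMap
from .errors import ConfigurationError, IntegrityError
from .geometry import REGIONS, RegionPartition

DENSITY_COLUMNS = [
    "patient_id", "lesion_type", "region", "phenotype", "count", "area_mm2", "density",
]


@dataclass(frozen=True)
class PhenotypeDef:
    """A phenotype as required-positive and required-negative marker sets."""

    name: str
    required_positive: frozenset[str]
    required_negative: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        pos = frozenset(self.required_positive)
        neg = frozenset(self.required_negative)
        object.__setattr__(self, "required_positive", pos)
        object.__setattr__(self, "required_negative", neg)
        if pos & neg:
            raise ConfigurationError(
                f"phenotype {self.name!r}: markers {sorted(pos & neg)} required "
                "both positive and negative"
            )
        if not pos and not neg:
            raise ConfigurationError(f"phenotype {self.name!r} names no marker")

    @property
    def markers(self) -> frozenset[str]:
        return self.required_positive | self.required_negative


#: CD68 (pan-macrophage) x CD163 (M2-skewed) colocalization subtypes.
MACROPHAGE_SUBTYPES = [
    PhenotypeDef("CD68+CD163+", frozenset({"CD68", "CD163"})),
    PhenotypeDef("CD68+CD163-", frozenset({"CD68"}), frozenset({"CD163"})),
    PhenotypeDef("CD68-CD163+", frozenset({"CD163"}), frozenset({"CD68"})),
]


def single_marker_defs(panel: Sequence[str]) -> list[PhenotypeDef]:
    """One single-marker phenotype per panel marker (positivity only)."""
    return [PhenotypeDef(m, frozenset({m})) for m in panel]


def match_phenotype(cell: CellRecord, phenotype: PhenotypeDef) -> bool:
    """True iff the cell satisfies the phenotype's positivity pattern."""
    for m in phenotype.markers:
        if m not in cell.markers:
            raise ConfigurationError(
                f"phenotype {phenotype.name!r} references marker {m!r} absent "
                "from the cell's panel"
            )
    return all(cell.markers[m] for m in phenotype.required_positive) and not any(
        cell.markers[m] for m in phenotype.required_negative
    )


def phenotype_mask(cells: pd.DataFrame, phenotype: PhenotypeDef) -> np.ndarray:
    """Vectorized :func:`match_phenotype` over a cells frame."""
    for m in phenotype.markers:
        if m not in cells.columns:
            raise ConfigurationError(
                f"phenotype {phenotype.name!r} references marker {m!r} absent "
                "from the panel"
            )
    mask = np.ones(len(cells), dtype=bool)
    for m in phenotype.required_positive:
        mask &= cells[m].to_numpy(dtype=bool)
    for m in phenotype.required_negative:
        mask &= ~cells[m].to_numpy(dtype=bool)
    return mask


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def _density(count: float, area: float) -> float:
    if area > 0:
        return count / area
    if count > 0:
        raise IntegrityError(f"{count} cells counted in a zero-area region")
    return float("nan")


def compute_densities(
    sample: SampleMap,
    partition: RegionPartition,
    defs: Sequence[PhenotypeDef],
    pooling: str = "pooled",
) -> pd.DataFrame:
    """Density table for one lesion: one row per (region, phenotype).

    Regions are TC, TF, PT plus ALL (TC+TF pooled).  ``pooling`` is
    ``"pooled"`` (sum counts / sum areas over ROIs, default) or
    ``"roi_mean"`` (unweighted mean of per-ROI densities over ROIs whose
    region area is positive; counts and areas still report the pooled sums).
    """
    if pooling not in ("pooled", "roi_mean"):
        raise ConfigurationError(f"unknown pooling rule {pooling!r}")
    df = sample.cells
    regions = partition.region_of.reindex(df["cell_id"]).to_numpy()
    region_is = {r: regions == r for r in REGIONS}  # object-compare once
    roi_ids = df["roi_id"].to_numpy()
    roi_area = partition.roi_areas_mm2.pivot(
        index="roi_id", columns="region", values="area_mm2"
    )

    rows = []
    for d in defs:
        mask = phenotype_mask(df, d)
        per_region_counts = {r: int((mask & region_is[r]).sum()) for r in REGIONS}
        per_region_area = {r: partition.areas_mm2.get(r, 0.0) for r in REGIONS}
        densities: dict[str, float] = {}
        if pooling == "pooled":
            for r in REGIONS:
                densities[r] = _density(per_region_counts[r], per_region_area[r])
            all_count = per_region_counts["TC"] + per_region_counts["TF"]
            all_area = per_region_area["TC"] + per_region_area["TF"]
            densities["ALL"] = _density(all_count, all_area)
        else:
            for r in REGIONS + ("ALL",):
                vals = []
                for roi in sample.rois:
                    if roi.roi_id not in roi_area.index:
                        continue
                    in_roi = roi_ids == roi.roi_id
                    if r == "ALL":
                        a = float(roi_area.loc[roi.roi_id, "TC"]) + float(
                            roi_area.loc[roi.roi_id, "TF"]
                        )
                        c = int((mask & in_roi & np.isin(regions, ("TC", "TF"))).sum())
                    else:
                        a = float(roi_area.loc[roi.roi_id, r])
                        c = int((mask & in_roi & (regions == r)).sum())
                    if a > 0:
                        vals.append(c / a)
                    elif c > 0:
                        raise IntegrityError(
                            f"{c} cells in zero-area region {r} of ROI {roi.roi_id!r}"
                        )
                densities[r] = float(np.mean(vals)) if vals else float("nan")
            all_count = per_region_counts["TC"] + per_region_counts["TF"]
            all_area = per_region_area["TC"] + per_region_area["TF"]
        for r in REGIONS:
            rows.append(
                {
                    "patient_id": sample.patient_id,
                    "lesion_type": sample.lesion_type,
                    "region": r,
                    "phenotype": d.name,
                    "count": per_region_counts[r],
                    "area_mm2": per_region_area[r],
                    "density": densities[r],
                }
            )
        rows.append(
            {
                "patient_id": sample.patient_id,
                "lesion_type": sample.lesion_type,
                "region": "ALL",
                "phenotype": d.name,
                "count": all_count,
                "area_mm2": all_area,
                "density": densities["ALL"],
            }
        )
    return pd.DataFrame(rows, columns=DENSITY_COLUMNS)


def macrophage_profile(
    sample: SampleMap, partition: RegionPartition, pooling: str = "pooled"
) -> pd.DataFrame:
    """Densities of the three CD68/CD163 colocalization subtypes per region."""
    for m in ("CD68", "CD163"):
        if m not in sample.panel:
            raise ConfigurationError(
                f"macrophage subtyping needs marker {m!r} in the panel"
            )
    return compute_densities(sample, partition, MACROPHAGE_SUBTYPES, pooling)


def subtype_heatmap_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Median-density matrix over patients, (lesion_type, region) x subtype.

    ``profiles`` is the concatenation of per-lesion :func:`macrophage_profile`
    outputs (or any density table restricted to the subtypes of interest).
    """
    if len(profiles) == 0:
        raise ConfigurationError("no macrophage profiles supplied")
    return profiles.pivot_table(
        index=["lesion_type", "region"],
        columns="phenotype",
        values="density",
        aggfunc="median",
    )
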