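"""Tumor-boundary estimation and distance-banded region partitioning.

The lesion is partitioned into three regions relative to the tumor/stroma
interface:

* **TC** (tumor center): inside the tumor mask (signed distance < 0);
* **TF** (tumor invasive front): the extratumoral band strictly less than
  ``band_width`` (default 150 µm) from the boundary (0 <= d < band_width);
* **PT** (peritumoral region): tissue at distance >= ``band_width``.

The signed distance is measured from the tumor *edge*, negative inside the
mask.  A cell sitting exactly on the boundary (d == 0) is TF; a cell at
exactly the band width is PT, honouring the "< 150 µm" / ">= 150 µm"
convention of the banding scheme.

Because the pipeline starts from a segmented-cell table rather than pixel
masks, the tumor mask is *estimated* from tumor-compartment cell positions:
occupancy is rasterized on a grid, morphologically closed, holes are
filled, and contour polygons are extracted.  Region areas are computed
vectorially (polygon intersections with the ROI rectangle), so the three
region areas sum to the ROI area exactly up to floating-point error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, box
from shapely.ops import unary_union
from skimage import measure

from .cellio import ROI, SampleMap
from .errors import CellTableValidationError, NoTumorRegionError

REGIONS = ("TC", "TF", "PT")
DEFAULT_BAND_WIDTH_UM = 150.0
DEFAULT_GRID_RESOLUTION_UM = 5.0
DEFAULT_CLOSING_RADIUS_UM = 30.0


@dataclass
class TumorBoundary:
    """Estimated tumor mask of one ROI as one or more simple polygons (µm)."""

    polygons: list[Polygon]
    grid_resolution: float

    def __post_init__(self) -> None:
        self.polygons = [p for p in self.polygons if p.area > 0]
        if not self.polygons:
            raise NoTumorRegionError("boundary has no polygon with positive area")
        for p in self.polygons:
            if not p.is_valid:
                raise ValueError("tumor boundary polygons must be simple (valid)")
        self._union = unary_union(self.polygons)
        self._edges = unary_union([p.exterior for p in self.polygons])

    @property
    def union(self) -> shapely.Geometry:
        return self._union

    @property
    def total_area_um2(self) -> float:
        return float(self._union.area)

    def to_geojson(self) -> dict:
        """Boundary as a GeoJSON MultiPolygon dict (coordinates in µm)."""
        return {
            "type": "MultiPolygon",
            "coordinates": [
                [list(map(list, p.exterior.coords))] for p in self.polygons
            ],
        }


@dataclass
class RegionPartition:
    """Per-cell TC/TF/PT labels and per-region tissue areas for one lesion."""

    region_of: pd.Series  # index: cell_id, values in REGIONS
    areas_mm2: dict[str, float]  # aggregated over ROIs
    roi_areas_mm2: pd.DataFrame  # columns: roi_id, region, area_mm2
    band_width_um: float = DEFAULT_BAND_WIDTH_UM

    def counts(self) -> dict[str, int]:
        vc = self.region_of.value_counts()
        return {r: int(vc.get(r, 0)) for r in REGIONS}


# ---------------------------------------------------------------------------
# boundary estimation
# ---------------------------------------------------------------------------

def estimate_boundary(
    sample: SampleMap,
    roi_id: str,
    grid_resolution: float = DEFAULT_GRID_RESOLUTION_UM,
    closing_radius: float = DEFAULT_CLOSING_RADIUS_UM,
) -> TumorBoundary:
    """Estimate the tumor mask of one ROI from tumor-compartment cells.

    Occupancy of tumor-compartment cells is rasterized at ``grid_resolution``
    µm per pixel over the ROI rectangle, closed with a disk of
    ``closing_radius`` µm (bridging gaps between neighbouring cells), holes
    are filled, and iso-contours at the 0.5 level are vectorized into
    polygons.  Deterministic for fixed inputs.

    Raises
    ------
    NoTumorRegionError
        If the ROI contains no tumor-compartment cell.
    """
    roi = sample.roi(roi_id)
    df = sample.cells
    sel = (df["roi_id"] == roi_id) & (df["compartment"] == "tumor")
    x = df.loc[sel, "x"].to_numpy(dtype=float)
    y = df.loc[sel, "y"].to_numpy(dtype=float)
    if len(x) == 0:
        raise NoTumorRegionError(f"ROI {roi_id!r} has no tumor-compartment cells")

    res = float(grid_resolution)
    nx = max(1, int(np.ceil(roi.width / res)))
    ny = max(1, int(np.ceil(roi.height / res)))
    ix = np.clip(((x - roi.x_min) / res).astype(int), 0, nx - 1)
    iy = np.clip(((y - roi.y_min) / res).astype(int), 0, ny - 1)
    mask = np.zeros((ny, nx), dtype=bool)
    mask[iy, ix] = True

    r_px = closing_radius / res
    if r_px > 0 and mask.any():
        # closing with a Euclidean disk via two distance transforms:
        # dilate (distance-to-occupied <= r), then erode (distance-to-
        # complement > r); padding keeps the closing unclipped at the edge
        pad = int(np.ceil(r_px)) + 1
        padded = np.pad(mask, pad, mode="constant")
        d1 = ndimage.distance_transform_edt(~padded)
        dilated = d1 <= r_px
        d2 = ndimage.distance_transform_edt(dilated)
        closed = d2 > r_px
        mask = closed[pad : pad + ny, pad : pad + nx] | mask
    mask = ndimage.binary_fill_holes(mask)

    # contour on a padded float image so components touching the edge close
    img = np.pad(mask.astype(float), 1, mode="constant")
    contours = measure.find_contours(img, level=0.5)
    polys: list[Polygon] = []
    for c in contours:
        # (row, col) -> (x, y); pixel centre of mask[j, i] sits at
        # (x_min + (i + 0.5) res, y_min + (j + 0.5) res); padding offsets by 1
        xs = roi.x_min + (c[:, 1] - 1 + 0.5) * res
        ys = roi.y_min + (c[:, 0] - 1 + 0.5) * res
        if len(xs) < 4:
            continue
        p = Polygon(np.column_stack([xs, ys]))
        if not p.is_valid:
            p = p.buffer(0)
        # contours of a pixel mask are stair-steps at half-pixel scale;
        # collapsing them keeps the boundary within ~res/2 of the raster
        p = p.simplify(0.45 * res, preserve_topology=True)
        if p.is_empty:
            continue
        if p.geom_type == "MultiPolygon":
            polys.extend(g for g in p.geoms if g.area > 0)
        elif p.area > 0:
            polys.append(p)
    # fill_holes ran first, so every contour is the outer shell of one
    # connected component; drop any contour nested inside another (holes
    # that survived rasterization quirks)
    keep: list[Polygon] = []
    for p in polys:
        if not any(q is not p and q.contains(p.representative_point()) and q.area > p.area for q in polys):
            keep.append(p)
    if not keep:
        raise NoTumorRegionError(
            f"ROI {roi_id!r}: tumor occupancy vanished during mask extraction"
        )
    return TumorBoundary(polygons=keep, grid_resolution=res)


def estimate_boundaries(
    sample: SampleMap,
    grid_resolution: float = DEFAULT_GRID_RESOLUTION_UM,
    closing_radius: float = DEFAULT_CLOSING_RADIUS_UM,
    no_tumor_policy: str = "error",
) -> dict[str, TumorBoundary | None]:
    """Estimate a boundary for every ROI of a lesion.

    ``no_tumor_policy`` controls ROIs without tumor cells: ``"error"``
    (default) re-raises, ``"all_pt"`` records an explicit None marker so
    :func:`assign_regions` labels all their cells and area PT.
    """
    if no_tumor_policy not in ("error", "all_pt"):
        raise ValueError(f"unknown no_tumor_policy {no_tumor_policy!r}")
    out: dict[str, TumorBoundary | None] = {}
    for roi in sample.rois:
        try:
            out[roi.roi_id] = estimate_boundary(
                sample, roi.roi_id, grid_resolution, closing_radius
            )
        except NoTumorRegionError:
            if no_tumor_policy == "error":
                raise
            out[roi.roi_id] = None
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def signed_distances(points: np.ndarray, boundary: TumorBoundary) -> np.ndarray:
    """Signed Euclidean distance (µm) of Nx2 points to the tumor edge.

    Negative strictly inside a polygon, positive outside, zero exactly on
    the edge.  Exact for polygonal boundaries.
    """
    pts = shapely.points(np.asarray(points, dtype=float))
    d = shapely.distance(pts, boundary._edges)
    inside = shapely.contains(boundary._union, pts)  # strict interior
    return np.where(inside, -d, d)


def distance_to_boundary(point: Sequence[float], boundary: TumorBoundary) -> float:
    """Scalar convenience wrapper around :func:`signed_distances`."""
    return float(signed_distances(np.asarray([point], dtype=float), boundary)[0])


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def _classify(d: np.ndarray, band_width: float) -> np.ndarray:
    out = np.full(d.shape, "PT", dtype=object)
    out[d < band_width] = "TF"
    out[d < 0] = "TC"
    return out


def _roi_zone_areas(
    roi: ROI, boundary: TumorBoundary | None, band_width: float
) -> dict[str, float]:
    """Areas (mm²) of the three zones inside one ROI rectangle.

    Computed vectorially: TC is the tumor mask clipped to the rectangle, TF
    the clipped ``band_width`` buffer minus TC, PT the remainder, so the
    three sum to the rectangle area exactly.
    """
    rect = box(roi.x_min, roi.y_min, roi.x_max, roi.y_max)
    if boundary is None:
        return {"TC": 0.0, "TF": 0.0, "PT": rect.area / 1e6}
    tumor = boundary.union.intersection(rect)
    if band_width > 0:
        band = boundary.union.buffer(band_width, quad_segs=16).intersection(rect)
    else:
        band = tumor
    tc = tumor.area
    tf = max(band.area - tumor.area, 0.0)
    pt = max(rect.area - band.area, 0.0)
    return {"TC": tc / 1e6, "TF": tf / 1e6, "PT": pt / 1e6}


def assign_regions(
    sample: SampleMap,
    boundaries: Mapping[str, TumorBoundary | None],
    band_width: float = DEFAULT_BAND_WIDTH_UM,
) -> RegionPartition:
    """Label every cell TC/TF/PT and compute per-region tissue areas.

    ``boundaries`` maps roi_id to a :class:`TumorBoundary`, or to None as an
    explicit "no tumor region" marker (all cells and area of that ROI become
    PT).  Every ROI that contains cells must appear in the mapping.
    """
    if band_width < 0:
        raise ValueError("band_width must be >= 0")
    df = sample.cells
    labels = np.empty(len(df), dtype=object)
    for roi in sample.rois:
        sel = (df["roi_id"] == roi.roi_id).to_numpy()
        if not sel.any():
            continue
        if roi.roi_id not in boundaries:
            raise CellTableValidationError(
                f"no boundary (or no-tumor marker) supplied for ROI {roi.roi_id!r}"
            )
        b = boundaries[roi.roi_id]
        if b is None:
            labels[sel] = "PT"
            continue
        pts = df.loc[sel, ["x", "y"]].to_numpy(dtype=float)
        d = signed_distances(pts, b)
        labels[sel] = _classify(d, band_width)

    rows = []
    for roi in sample.rois:
        if roi.roi_id not in boundaries:
            # ROI without cells and without a boundary: treat as unanalyzed
            continue
        zones = _roi_zone_areas(roi, boundaries[roi.roi_id], band_width)
        for region, a in zones.items():
            rows.append({"roi_id": roi.roi_id, "region": region, "area_mm2": a})
    roi_areas = pd.DataFrame(rows, columns=["roi_id", "region", "area_mm2"])
    agg = roi_areas.groupby("region")["area_mm2"].sum()
    areas = {r: float(agg.get(r, 0.0)) for r in REGIONS}

    region_of = pd.Series(labels, index=df["cell_id"].to_numpy(), name="region")
    return RegionPartition(
        region_of=region_of,
        areas_mm2=areas,
        roi_areas_mm2=roi_areas,
        band_width_um=float(band_width),
    )


def region_labeled_cells(sample: SampleMap, partition: RegionPartition) -> pd.DataFrame:
    """The sample's cell table with the TC/TF/PT label appended as ``region``."""
    out = sample.cells.copy()
    out["region"] = partition.region_of.reindex(out["cell_id"]).to_numpy()
    return out
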