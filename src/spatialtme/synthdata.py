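"""Synthetic paired primary/metastasis cohorts of segmented-cell maps.

The generator emulates the data structure of a paired surgical cohort
profiled by multiplex immunofluorescence: 17 patients, each contributing
one primary colorectal tumor and one (or several, later merged) liver
metastasis, with 3-5 imaged 20x fields (ROIs) per lesion.  Each ROI holds a
tumor mask (a disc or smoothed random blob), densely filled with
tumor-compartment cells, and immune cells drawn as independent
inhomogeneous Poisson processes whose intensity is piecewise constant on
the true TC / TF / PT zones of the generative geometry — including the
elevated "immune band" within 150 µm of the tumor boundary.  CD68/CD163
macrophages are drawn as a single process whose cells receive a joint
(CD68, CD163) state from per-region probabilities over the three
colocalization subtypes.

The default configuration encodes the qualitative effect directions the
analysis is designed to detect (for example: invasive-front intensity 3x
the tumor center for CD8 and most lymphoid markers; peritumoral
CD68-CD163+ macrophage intensity 3x higher in metastases than primaries;
CD68-CD163+ dominating the metastatic macrophage pool) without asserting
any real patient's numbers.  True boundaries, zone areas, intensities and
regime labels are returned as a ground-truth record — and written as a
sidecar file, never into the cell tables — so recovery tests cannot
accidentally consume them.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from .cellio import ROI, Cohort, SampleMap, merge_lesions, write_cohort
from .errors import ConfigurationError, SpatialTMEError

REGIONS = ("TC", "TF", "PT")
SUBTYPE_STATES = ("CD68+CD163+", "CD68+CD163-", "CD68-CD163+")


def _paper_like_intensities() -> dict[str, dict[str, dict[str, float]]]:
    """Regional intensities (cells/mm²) for the ten non-macrophage markers.

    Encodes the qualitative orderings of the reference effect pattern:
    TF > TC for the lymphoid/checkpoint markers, TC > TF for CD66b and
    Ki67, PT below TF in primaries, PT ~ TF for several markers in
    metastases, and overall excesses (Foxp3, IFN-g in metastases; CD66b,
    CD56 in primaries).
    """
    def lt(tc, tf, pt):
        return {"TC": tc, "TF": tf, "PT": pt}

    return {
        "CD8":     {"primary": lt(2.0, 6.0, 2.0),  "metastasis": lt(1.5, 4.5, 1.5)},
        "Foxp3":   {"primary": lt(1.0, 3.0, 1.0),  "metastasis": lt(1.5, 4.5, 4.5)},
        "CD20":    {"primary": lt(1.5, 4.5, 1.5),  "metastasis": lt(1.0, 3.0, 3.0)},
        "CD11c":   {"primary": lt(1.0, 3.0, 1.0),  "metastasis": lt(0.8, 2.4, 0.8)},
        "VEGFR-2": {"primary": lt(1.0, 3.0, 1.0),  "metastasis": lt(0.8, 2.4, 2.4)},
        "PD-L1":   {"primary": lt(2.0, 6.0, 2.0),  "metastasis": lt(1.5, 4.5, 4.5)},
        "CD66b":   {"primary": lt(6.0, 3.0, 1.5),  "metastasis": lt(4.0, 2.0, 1.0)},
        "Ki67":    {"primary": lt(5.0, 2.5, 1.2),  "metastasis": lt(4.0, 2.0, 1.0)},
        "IFN-g":   {"primary": lt(1.0, 1.0, 0.5),  "metastasis": lt(1.5, 1.5, 1.5)},
        "CD56":    {"primary": lt(4.0, 2.0, 1.0),  "metastasis": lt(2.0, 2.0, 1.0)},
    }


def _paper_like_macrophages() -> tuple[dict, dict]:
    """Macrophage process intensity and CD68/CD163 joint state probabilities.

    The metastatic peritumoral pool is strongly CD68-CD163+ skewed and its
    CD163 marginal (9.9 cells/mm²) is 3x the primary peritumoral CD163
    marginal (3.3 cells/mm²).
    """
    intensity = {
        "primary":    {"TC": 4.0, "TF": 12.0, "PT": 6.0},
        "metastasis": {"TC": 4.0, "TF": 12.0, "PT": 11.0},
    }
    joint = {
        "primary": {
            "TC": (0.35, 0.45, 0.20),
            "TF": (0.35, 0.45, 0.20),
            "PT": (0.35, 0.45, 0.20),
        },
        "metastasis": {
            "TC": (0.30, 0.25, 0.45),
            "TF": (0.30, 0.25, 0.45),
            "PT": (0.10, 0.05, 0.85),
        },
    }
    return intensity, joint


def _default_regimes() -> dict[str, dict[str, float]]:
    # CD8 intensities (cells/mm²) for well-separated immunotype regimes,
    # relative to a reference threshold of 5 cells/mm²: 10x above / 0.1x.
    return {
        "inflamed": {"TC": 50.0, "TF": 50.0, "PT": 5.0},
        "excluded": {"TC": 0.5, "TF": 50.0, "PT": 5.0},
        "desert":   {"TC": 0.5, "TF": 0.5, "PT": 0.5},
    }


def _default_clinical_model() -> dict[str, Any]:
    # lesion-count distribution mirrors the reference cohort's Table-1 split
    # (10/17 single lesion, 3/17 two, 4/17 three or more); diameter is
    # lognormal with median 3 cm clipped to the observed 0.5-9 cm range.
    return {
        "n_mets_probs": {1: 10 / 17, 2: 3 / 17, 3: 2 / 17, 4: 2 / 17},
        "diameter": {"median_cm": 3.0, "sigma_log": 0.55, "min_cm": 0.5, "max_cm": 9.0},
        "effects": [
            {"marker": "Foxp3", "group": "diameter_ge3", "lesion_type": "both", "factor": 2.0},
            {"marker": "Foxp3", "group": "n_mets_gt1", "lesion_type": "metastasis", "factor": 1.8},
            {"marker": "PD-L1", "group": "n_mets_gt1", "lesion_type": "primary", "factor": 0.5},
            {"marker": "CD66b", "group": "n_mets_gt1", "lesion_type": "primary", "factor": 1.8},
        ],
    }


@dataclass
class SynthConfig:
    """Generative model parameters; identical seed + config => identical cohort."""

    seed: int = 0
    n_patients: int = 17
    rois_per_lesion: tuple[int, int] = (3, 5)
    roi_width_um: float = 1000.0
    roi_height_um: float = 1000.0
    tumor_shape: str = "disc"  # "disc" | "blob"
    tumor_radius_um: tuple[float, float] = (280.0, 360.0)
    tumor_center_jitter_um: float = 30.0
    blob_wobble: float = 0.12  # relative radial modulation for "blob"
    band_width_um: float = 150.0
    tumor_cell_intensity: float = 5000.0  # cells/mm² inside the tumor mask
    intensities: dict = field(default_factory=_paper_like_intensities)
    macrophage_intensity: dict = field(default_factory=lambda: _paper_like_macrophages()[0])
    macrophage_joint: dict = field(default_factory=lambda: _paper_like_macrophages()[1])
    immunotype_mix: dict | None = None  # e.g. {"inflamed": 1/3, "excluded": 1/3, "desert": 1/3}
    immunotype_regimes: dict = field(default_factory=_default_regimes)
    clinical_model: dict = field(default_factory=_default_clinical_model)
    merge_metastatic_lesions: bool = True
    max_cells_per_roi: int = 1_000_000

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        lo, hi = self.rois_per_lesion
        if not (1 <= lo <= hi):
            raise ConfigurationError("rois_per_lesion must be a 1 <= lo <= hi range")
        if self.roi_width_um <= 0 or self.roi_height_um <= 0:
            raise ConfigurationError("ROI dimensions must be positive")
        if self.tumor_shape not in ("disc", "blob"):
            raise ConfigurationError(f"unknown tumor_shape {self.tumor_shape!r}")
        if self.band_width_um < 0:
            raise ConfigurationError("band_width_um must be >= 0")
        for marker, per_lt in self.intensities.items():
            for lt_name, per_region in per_lt.items():
                for region, lam in per_region.items():
                    if lam < 0:
                        raise ConfigurationError(
                            f"negative intensity for {marker}/{lt_name}/{region}"
                        )
        for lt_name, per_region in self.macrophage_joint.items():
            for region, probs in per_region.items():
                if len(probs) != 3 or any(p < 0 for p in probs):
                    raise ConfigurationError("macrophage_joint needs 3 probabilities >= 0")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigurationError(
                        f"macrophage_joint[{lt_name}][{region}] must sum to 1"
                    )
        if self.immunotype_mix is not None:
            if abs(sum(self.immunotype_mix.values()) - 1.0) > 1e-9:
                raise ConfigurationError("immunotype_mix probabilities must sum to 1")
            unknown = set(self.immunotype_mix) - set(self.immunotype_regimes)
            if unknown:
                raise ConfigurationError(f"immunotype_mix names unknown regimes {unknown}")

    @property
    def panel(self) -> list[str]:
        return list(self.intensities.keys()) + ["CD68", "CD163"]

    def marginal_intensity(self, marker: str, lesion_type: str, region: str) -> float:
        """True generative intensity of a marker's marginal positivity."""
        if marker in ("CD68", "CD163"):
            lam = self.macrophage_intensity[lesion_type][region]
            pp, pm, mp = self.macrophage_joint[lesion_type][region]
            return lam * ((pp + pm) if marker == "CD68" else (pp + mp))
        return self.intensities[marker][lesion_type][region]


def paper_like_config(seed: int = 0, **overrides: Any) -> SynthConfig:
    """The default study-conditions preset (explicit alias of SynthConfig())."""
    return SynthConfig(seed=seed, **overrides)


def immunotype_regime_config(seed: int = 0, **overrides: Any) -> SynthConfig:
    """Preset with lesions drawn from well-separated immunotype regimes."""
    mix = overrides.pop("immunotype_mix", {"inflamed": 1 / 3, "excluded": 1 / 3, "desert": 1 / 3})
    return SynthConfig(seed=seed, immunotype_mix=mix, **overrides)


# ---------------------------------------------------------------------------
# geometry of one ROI
# ---------------------------------------------------------------------------

def _make_tumor_polygon(config: SynthConfig, rng: np.random.Generator) -> Polygon:
    w, h = config.roi_width_um, config.roi_height_um
    r = rng.uniform(*config.tumor_radius_um)
    j = config.tumor_center_jitter_um
    cx = w / 2 + rng.uniform(-j, j)
    cy = h / 2 + rng.uniform(-j, j)
    if config.tumor_shape == "disc":
        poly = Point(cx, cy).buffer(r, quad_segs=96)
    else:
        theta = np.linspace(0, 2 * np.pi, 181)[:-1]
        rad = np.full_like(theta, r)
        for k in (2, 3, 5):
            amp = rng.normal(0.0, config.blob_wobble / 2) * r
            rad = rad + amp * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
        rad = np.clip(rad, 0.3 * r, 1.4 * r)
        poly = Polygon(np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)]))
        if not poly.is_valid:
            poly = poly.buffer(0)
    rect = box(0, 0, w, h)
    clipped = poly.intersection(rect)
    if clipped.geom_type == "MultiPolygon":
        clipped = max(clipped.geoms, key=lambda g: g.area)
    return clipped


def _sample_in(polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """n points uniform in a polygon, by vectorized rejection from its bbox."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = polygon.bounds
    frac = polygon.area / ((maxx - minx) * (maxy - miny))
    out: list[np.ndarray] = []
    need = n
    while need > 0:
        batch = max(32, int(need / max(frac, 1e-3) * 1.3))
        xs = rng.uniform(minx, maxx, batch)
        ys = rng.uniform(miny, maxy, batch)
        pts = np.column_stack([xs, ys])
        keep = shapely.covers(polygon, shapely.points(pts))
        got = pts[keep][:need]
        out.append(got)
        need -= len(got)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_roi(
    config: SynthConfig,
    lesion_type: str,
    rng: np.random.Generator,
    roi_id: str = "R1",
    marker_scale: Mapping[str, float] | None = None,
    regime: str | None = None,
) -> tuple[ROI, pd.DataFrame, dict]:
    """Simulate one imaged field; returns (ROI descriptor, cells, truth).

    ``marker_scale`` multiplies selected markers' intensities (clinical
    subgroup effects); ``regime`` overrides the CD8 intensities with an
    immunotype regime.  The truth record carries the generative boundary
    (WKT), zone areas and effective intensities.
    """
    w, h = config.roi_width_um, config.roi_height_um
    roi = ROI(roi_id, 0.0, 0.0, w, h, area_mm2=w * h / 1e6)
    rect = box(0, 0, w, h)
    tumor = _make_tumor_polygon(config, rng)
    band = tumor.buffer(config.band_width_um, quad_segs=64).intersection(rect) \
        if config.band_width_um > 0 else tumor
    zones = {"TC": tumor, "TF": band.difference(tumor), "PT": rect.difference(band)}
    zone_areas_mm2 = {r: zones[r].area / 1e6 for r in REGIONS}

    scale = dict(marker_scale or {})
    lam_of: dict[str, dict[str, float]] = {}
    for marker in config.intensities:
        per = dict(config.intensities[marker][lesion_type])
        if marker == "CD8" and regime is not None:
            per = dict(config.immunotype_regimes[regime])
        f = scale.get(marker, 1.0)
        lam_of[marker] = {r: per[r] * f for r in REGIONS}

    mac_lam = {
        r: config.macrophage_intensity[lesion_type][r] * scale.get("MAC", 1.0)
        for r in REGIONS
    }

    expected = config.tumor_cell_intensity * zone_areas_mm2["TC"] + sum(
        lam_of[m][r] * zone_areas_mm2[r] for m in lam_of for r in REGIONS
    ) + sum(mac_lam[r] * zone_areas_mm2[r] for r in REGIONS)
    if expected > config.max_cells_per_roi:
        raise SpatialTMEError(
            f"configured intensities imply ~{expected:.0f} cells in one ROI "
            f"(> {config.max_cells_per_roi})"
        )

    panel = config.panel
    xs: list[np.ndarray] = []
    comps: list[np.ndarray] = []
    marker_cols: dict[str, list[np.ndarray]] = {m: [] for m in panel}

    def add(points: np.ndarray, compartment_in_tc: bool, positive: Mapping[str, bool]):
        k = len(points)
        if k == 0:
            return
        xs.append(points)
        comps.append(np.full(k, "tumor" if compartment_in_tc else "stroma", dtype=object))
        for m in panel:
            marker_cols[m].append(np.full(k, bool(positive.get(m, False))))

    # structural tumor-compartment cells (marker-negative)
    n_tumor = rng.poisson(config.tumor_cell_intensity * zone_areas_mm2["TC"])
    add(_sample_in(zones["TC"], int(n_tumor), rng), True, {})

    for marker in lam_of:
        for r in REGIONS:
            lam = lam_of[marker][r]
            if lam <= 0 or zone_areas_mm2[r] <= 0:
                continue
            npts = int(rng.poisson(lam * zone_areas_mm2[r]))
            add(_sample_in(zones[r], npts, rng), r == "TC", {marker: True})

    for r in REGIONS:
        if mac_lam[r] <= 0 or zone_areas_mm2[r] <= 0:
            continue
        npts = int(rng.poisson(mac_lam[r] * zone_areas_mm2[r]))
        if npts == 0:
            continue
        pts = _sample_in(zones[r], npts, rng)
        states = rng.choice(3, size=npts, p=list(config.macrophage_joint[lesion_type][r]))
        for s, (cd68, cd163) in enumerate(((True, True), (True, False), (False, True))):
            sel = states == s
            add(pts[sel], r == "TC", {"CD68": cd68, "CD163": cd163})

    if xs:
        pts = np.concatenate(xs)
        cells = pd.DataFrame(
            {
                "cell_id": [f"{roi_id}:c{i}" for i in range(len(pts))],
                "roi_id": roi_id,
                "x": pts[:, 0],
                "y": pts[:, 1],
                "compartment": np.concatenate(comps),
            }
        )
        for m in panel:
            cells[m] = np.concatenate(marker_cols[m])
    else:
        cells = pd.DataFrame(
            {"cell_id": pd.Series(dtype=str), "roi_id": pd.Series(dtype=str),
             "x": pd.Series(dtype=float), "y": pd.Series(dtype=float),
             "compartment": pd.Series(dtype=str)}
        )
        for m in panel:
            cells[m] = pd.Series(dtype=bool)

    truth = {
        "boundary_wkt": tumor.wkt,
        "zone_areas_mm2": zone_areas_mm2,
        "intensities": {m: lam_of[m] for m in lam_of},
        "macrophage_intensity": mac_lam,
        "macrophage_joint": {r: list(config.macrophage_joint[lesion_type][r]) for r in REGIONS},
        "regime": regime,
    }
    return roi, cells, truth


def simulate_lesion(
    config: SynthConfig,
    patient_id: str,
    lesion_type: str,
    lesion_id: str,
    rng: np.random.Generator,
    marker_scale: Mapping[str, float] | None = None,
    regime: str | None = None,
) -> tuple[SampleMap, dict]:
    lo, hi = config.rois_per_lesion
    n_rois = int(rng.integers(lo, hi + 1))
    rois: list[ROI] = []
    frames: list[pd.DataFrame] = []
    roi_truth: dict[str, dict] = {}
    for i in range(n_rois):
        roi_id = f"R{i + 1}"
        roi, cells, truth = simulate_roi(
            config, lesion_type, rng, roi_id, marker_scale, regime
        )
        rois.append(roi)
        frames.append(cells)
        roi_truth[roi_id] = truth
    cells = pd.concat(frames, ignore_index=True)
    sample = SampleMap(
        patient_id=patient_id,
        lesion_type=lesion_type,
        lesion_id=lesion_id,
        panel=config.panel,
        rois=rois,
        cells=cells,
    )
    truth = {"regime": regime, "rois": roi_truth}
    return sample, truth


def _draw_clinical(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    cm = config.clinical_model
    ks = sorted(cm["n_mets_probs"])
    probs = np.array([cm["n_mets_probs"][k] for k in ks], dtype=float)
    probs = probs / probs.sum()
    dia = cm["diameter"]
    rows = {}
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        n_mets = int(rng.choice(ks, p=probs))
        d = float(
            np.clip(
                math.exp(math.log(dia["median_cm"]) + rng.normal(0, dia["sigma_log"])),
                dia["min_cm"],
                dia["max_cm"],
            )
        )
        rows[pid] = {
            "n_liver_metastases": n_mets,
            "max_metastasis_diameter_cm": round(d, 1),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("patient_id")


def _marker_scales(
    config: SynthConfig, clinical: pd.DataFrame
) -> dict[tuple[str, str], dict[str, float]]:
    """Per (patient, lesion_type) multiplicative intensity shifts."""
    out: dict[tuple[str, str], dict[str, float]] = {}
    for pid, row in clinical.iterrows():
        member = {
            "diameter_ge3": row["max_metastasis_diameter_cm"] >= 3,
            "n_mets_gt1": row["n_liver_metastases"] > 1,
        }
        for lt in ("primary", "metastasis"):
            scale: dict[str, float] = {}
            for eff in config.clinical_model.get("effects", []):
                if eff["lesion_type"] not in (lt, "both"):
                    continue
                if member.get(eff["group"], False):
                    scale[eff["marker"]] = scale.get(eff["marker"], 1.0) * eff["factor"]
            out[(str(pid), lt)] = scale
    return out


def simulate_cohort(config: SynthConfig) -> tuple[Cohort, dict]:
    """Simulate the full paired cohort; returns (cohort, ground truth).

    Each patient gets one primary lesion and ``n_liver_metastases``
    metastatic lesions (merged into one per-patient metastasis sample by
    default).  The ground-truth record maps each final lesion to its
    per-ROI generative boundary, zone areas and intensities, under the
    ROI identifiers as they appear in the emitted samples.
    """
    rng = np.random.default_rng(config.seed)
    clinical = _draw_clinical(config, rng)
    scales = _marker_scales(config, clinical)

    regimes: dict[tuple[str, str], str | None] = {}
    if config.immunotype_mix is not None:
        labels = sorted(config.immunotype_mix)
        probs = np.array([config.immunotype_mix[l] for l in labels], dtype=float)
        probs = probs / probs.sum()

    samples: list[SampleMap] = []
    truth_lesions: dict[str, dict] = {}
    for pid in clinical.index:
        pid = str(pid)
        for lt in ("primary", "metastasis"):
            regime = None
            if config.immunotype_mix is not None:
                regime = str(rng.choice(labels, p=probs))
            regimes[(pid, lt)] = regime
            scale = scales[(pid, lt)]
            if lt == "primary":
                sample, truth = simulate_lesion(
                    config, pid, lt, f"{pid}-PRI", rng, scale, regime
                )
                samples.append(sample)
                truth_lesions[f"{pid}:primary"] = truth
            else:
                n_lesions = int(clinical.loc[pid, "n_liver_metastases"])
                parts: list[SampleMap] = []
                part_truths: list[tuple[str, dict]] = []
                for j in range(n_lesions):
                    lid = f"{pid}-MET{j + 1}"
                    s, t = simulate_lesion(config, pid, lt, lid, rng, scale, regime)
                    parts.append(s)
                    part_truths.append((lid, t))
                if config.merge_metastatic_lesions and len(parts) > 1:
                    merged = merge_lesions(parts, lesion_id=f"{pid}-MET")
                    samples.append(merged)
                    rois: dict[str, dict] = {}
                    for lid, t in part_truths:
                        for rid, rt in t["rois"].items():
                            rois[f"{lid}/{rid}"] = rt
                    truth_lesions[f"{pid}:metastasis"] = {"regime": regime, "rois": rois}
                elif config.merge_metastatic_lesions:
                    samples.append(parts[0])
                    truth_lesions[f"{pid}:metastasis"] = part_truths[0][1]
                else:
                    for (lid, t), s in zip(part_truths, parts):
                        samples.append(s)
                        truth_lesions[f"{pid}:metastasis:{lid}"] = t

    truth = {
        "seed": config.seed,
        "immunotype_regimes": {f"{p}:{l}": r for (p, l), r in regimes.items()},
        "marginal_intensities": {
            m: {
                lt: {r: config.marginal_intensity(m, lt, r) for r in REGIONS}
                for lt in ("primary", "metastasis")
            }
            for m in config.panel
        },
        "lesions": truth_lesions,
    }
    return Cohort(samples=samples, clinical=clinical), truth


def write_ground_truth(truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=1, sort_keys=True), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# config (de)serialization
# ---------------------------------------------------------------------------

def synth_config_from_dict(data: Mapping[str, Any]) -> SynthConfig:
    """Build a config from a plain mapping, rejecting unknown keys by name."""
    fields = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s): {', '.join(sorted(unknown))}"
        )
    kwargs = dict(data)
    for key in ("rois_per_lesion", "tumor_radius_um"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return SynthConfig(**kwargs)


def synth_config_from_yaml(path: str | Path) -> SynthConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise ConfigurationError("config file must hold a mapping")
    return synth_config_from_dict(data)


def simulate_to_directory(config: SynthConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and write cell tables, clinical table and truth sidecar."""
    out_dir = Path(out_dir)
    cohort, truth = simulate_cohort(config)
    write_cohort(cohort, out_dir)
    write_ground_truth(truth, out_dir / "ground_truth.json")
    return out_dir
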