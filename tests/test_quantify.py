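"""Phenotype matching, density pooling, macrophage colocalization subtyping."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatialtme.cellio import ROI
from spatialtme.errors import ConfigurationError, IntegrityError
from spatialtme.geometry import RegionPartition
from spatialtme.quantify import (
    MACROPHAGE_SUBTYPES,
    PhenotypeDef,
    compute_densities,
    macrophage_profile,
    match_phenotype,
    single_marker_defs,
    subtype_heatmap_matrix,
)

from conftest import make_sample, random_sample


def make_partition(sample, labels, roi_areas):
    """Partition with explicit labels (list) and per-ROI region areas."""
    region_of = pd.Series(labels, index=sample.cells["cell_id"].to_numpy())
    rows = [
        {"roi_id": rid, "region": reg, "area_mm2": a}
        for rid, per in roi_areas.items()
        for reg, a in per.items()
    ]
    roi_areas_df = pd.DataFrame(rows)
    agg = roi_areas_df.groupby("region")["area_mm2"].sum()
    areas = {r: float(agg.get(r, 0.0)) for r in ("TC", "TF", "PT")}
    return RegionPartition(region_of, areas, roi_areas_df, 150.0)


def cell(**kw):
    kw.setdefault("x", 1.0)
    kw.setdefault("y", 1.0)
    return kw


# -- phenotype matching -----------------------------------------------------

def test_match_phenotype_truth_table():
    panel = ["CD68", "CD163"]
    s = make_sample(
        [cell(CD68=True, CD163=False), cell(CD68=False, CD163=False)], panel
    )
    cells = list(s.iter_cells())
    d = PhenotypeDef("CD68+CD163-", frozenset({"CD68"}), frozenset({"CD163"}))
    assert match_phenotype(cells[0], d) is True
    assert match_phenotype(cells[1], d) is False
    # double negatives match no macrophage subtype
    assert not any(match_phenotype(cells[1], sub) for sub in MACROPHAGE_SUBTYPES)


def test_phenotype_def_rejects_contradiction_and_unknown_marker():
    with pytest.raises(ConfigurationError):
        PhenotypeDef("bad", frozenset({"CD8"}), frozenset({"CD8"}))
    s = make_sample([cell()], ["CD8"])
    with pytest.raises(ConfigurationError, match="CD56"):
        match_phenotype(next(s.iter_cells()), PhenotypeDef("x", frozenset({"CD56"})))


# -- densities --------------------------------------------------------------

def test_density_simple_arithmetic():
    s = make_sample([cell(CD8=True, roi_id="R1") for _ in range(12)], ["CD8"])
    part = make_partition(s, ["TF"] * 12, {"R1": {"TC": 0.3, "TF": 0.5, "PT": 0.2}})
    d = compute_densities(s, part, single_marker_defs(["CD8"]))
    tf = d.query("region == 'TF'").iloc[0]
    assert tf["count"] == 12
    assert tf["density"] == pytest.approx(24.0)
    zero = d.query("region == 'PT'").iloc[0]
    assert zero["count"] == 0 and zero["density"] == 0.0


def test_density_pooling_is_sum_counts_over_sum_areas():
    rois = [ROI("R1", 0, 0, 100, 100, 0.2), ROI("R2", 0, 0, 100, 100, 0.3)]
    cells = [cell(CD8=True, roi_id="R1") for _ in range(3)] + [
        cell(CD8=True, roi_id="R2")
    ]
    s = make_sample(cells, ["CD8"], rois=rois)
    part = make_partition(
        s, ["TC"] * 4,
        {"R1": {"TC": 0.2, "TF": 0.0, "PT": 0.0}, "R2": {"TC": 0.3, "TF": 0.0, "PT": 0.0}},
    )
    pooled = compute_densities(s, part, single_marker_defs(["CD8"]))
    tc = pooled.query("region == 'TC'").iloc[0]
    assert tc["density"] == pytest.approx(4 / 0.5)  # 8, not mean(15, 3.33)
    roi_mean = compute_densities(s, part, single_marker_defs(["CD8"]), pooling="roi_mean")
    assert roi_mean.query("region == 'TC'").iloc[0]["density"] == pytest.approx(
        (3 / 0.2 + 1 / 0.3) / 2
    )


def test_all_region_pools_tc_plus_tf():
    s = make_sample(
        [cell(CD8=True, roi_id="R1") for _ in range(5)], ["CD8"]
    )
    part = make_partition(
        s, ["TC", "TC", "TF", "TF", "PT"], {"R1": {"TC": 0.4, "TF": 0.1, "PT": 0.5}}
    )
    d = compute_densities(s, part, single_marker_defs(["CD8"]))
    alls = d.query("region == 'ALL'").iloc[0]
    assert alls["count"] == 4  # TC + TF only
    assert alls["area_mm2"] == pytest.approx(0.5)
    assert alls["density"] == pytest.approx(8.0)


def test_zero_area_region_gives_missing_density_or_integrity_error():
    s = make_sample([cell(CD8=True)], ["CD8"])
    part_ok = make_partition(s, ["TC"], {"R1": {"TC": 0.5, "TF": 0.0, "PT": 0.0}})
    d = compute_densities(s, part_ok, single_marker_defs(["CD8"]))
    pt = d.query("region == 'PT'").iloc[0]
    assert pt["count"] == 0 and np.isnan(pt["density"])
    part_bad = make_partition(s, ["PT"], {"R1": {"TC": 0.5, "TF": 0.0, "PT": 0.0}})
    with pytest.raises(IntegrityError):
        compute_densities(s, part_bad, single_marker_defs(["CD8"]))


def test_density_invariant_under_roi_split(rng):
    """Splitting one ROI into two leaves pooled densities unchanged."""
    s = random_sample(rng, n_cells=50)
    one_roi = [ROI("R", 0, 0, 1000, 1000, 1.0)]
    cells = s.cells.copy()
    cells["roi_id"] = "R"
    merged = make_sample([], s.panel, rois=one_roi)
    merged.cells = cells.copy()
    merged.rois = one_roi
    labels = list(rng.choice(["TC", "TF", "PT"], size=len(cells)))
    part1 = make_partition(merged, labels, {"R": {"TC": 0.3, "TF": 0.3, "PT": 0.4}})
    d1 = compute_densities(merged, part1, single_marker_defs(s.panel))

    # split: same cells, half the area in each of two ROIs
    split_rois = [ROI("Ra", 0, 0, 1000, 1000, 0.5), ROI("Rb", 0, 0, 1000, 1000, 0.5)]
    cells2 = cells.copy()
    cells2["roi_id"] = np.where(np.arange(len(cells2)) % 2 == 0, "Ra", "Rb")
    split = make_sample([], s.panel, rois=split_rois)
    split.cells = cells2
    split.rois = split_rois
    half = {"TC": 0.15, "TF": 0.15, "PT": 0.2}
    part2 = make_partition(split, labels, {"Ra": half, "Rb": half})
    d2 = compute_densities(split, part2, single_marker_defs(s.panel))
    pd.testing.assert_series_equal(d1["density"], d2["density"])


# -- macrophage subtyping ---------------------------------------------------

def test_macrophage_enumeration_and_partition_identity():
    panel = ["CD68", "CD163"]
    s = make_sample(
        [
            cell(CD68=True, CD163=True),
            cell(CD68=True, CD163=False),
            cell(CD68=False, CD163=True),
            cell(CD68=False, CD163=False),
        ],
        panel,
    )
    part = make_partition(s, ["TF"] * 4, {"R1": {"TC": 0.1, "TF": 0.5, "PT": 0.4}})
    prof = macrophage_profile(s, part)
    tf = prof.query("region == 'TF'").set_index("phenotype")["count"]
    assert tf["CD68+CD163+"] == 1 and tf["CD68+CD163-"] == 1 and tf["CD68-CD163+"] == 1
    assert tf.sum() == 3  # the double negative is in no subtype


def test_macrophage_counts_match_bruteforce_tally(rng):
    """Vector subtype counts equal an independent per-cell loop on 30 samples."""
    for _ in range(30):
        s = random_sample(rng, n_cells=40)
        if "CD68" not in s.panel or "CD163" not in s.panel:
            continue
        labels = list(rng.choice(["TC", "TF", "PT"], size=len(s.cells)))
        areas = {r.roi_id: {"TC": 0.1, "TF": 0.1, "PT": 0.1} for r in s.rois}
        part = make_partition(s, labels, areas)
        prof = macrophage_profile(s, part)
        label_of = dict(zip(s.cells["cell_id"], labels))
        for region in ("TC", "TF", "PT"):
            tallies = {"CD68+CD163+": 0, "CD68+CD163-": 0, "CD68-CD163+": 0}
            for c in s.iter_cells():
                if label_of[c.cell_id] != region:
                    continue
                if c.markers["CD68"] and c.markers["CD163"]:
                    tallies["CD68+CD163+"] += 1
                elif c.markers["CD68"]:
                    tallies["CD68+CD163-"] += 1
                elif c.markers["CD163"]:
                    tallies["CD68-CD163+"] += 1
            got = prof.query("region == @region").set_index("phenotype")["count"]
            assert dict(got) == tallies
        # partition identity: CD68+CD163+ + CD68+CD163- == all CD68+
        all_cd68 = int(s.cells["CD68"].sum())
        per_region = prof[prof["region"].isin(["TC", "TF", "PT"])]
        totals = per_region.groupby("phenotype")["count"].sum()
        assert totals["CD68+CD163+"] + totals["CD68+CD163-"] == all_cd68


def test_macrophage_requires_markers():
    s = make_sample([cell()], ["CD8"])
    part = make_partition(s, ["TC"], {"R1": {"TC": 1.0, "TF": 0.0, "PT": 0.0}})
    with pytest.raises(ConfigurationError, match="CD68"):
        macrophage_profile(s, part)


def test_count_conservation_exhaustive_family(rng):
    """An exhaustive phenotype family's counts sum to the region's cell count."""
    panel = ["CD68", "CD163"]
    family = MACROPHAGE_SUBTYPES + [
        PhenotypeDef("CD68-CD163-", frozenset(), frozenset({"CD68", "CD163"}))
    ]
    s = make_sample(
        [cell(CD68=bool(rng.random() < 0.5), CD163=bool(rng.random() < 0.5))
         for _ in range(60)],
        panel,
    )
    labels = list(rng.choice(["TC", "TF", "PT"], size=60))
    part = make_partition(s, labels, {"R1": {"TC": 0.3, "TF": 0.3, "PT": 0.4}})
    d = compute_densities(s, part, family)
    for region in ("TC", "TF", "PT"):
        total = d.query("region == @region")["count"].sum()
        assert total == labels.count(region)


def test_subtype_heatmap_median():
    rows = []
    for pid, dens in (("P01", 2.0), ("P02", 4.0)):
        rows.append(
            {"patient_id": pid, "lesion_type": "primary", "region": "PT",
             "phenotype": "CD68-CD163+", "count": 1, "area_mm2": 1.0, "density": dens}
        )
    mat = subtype_heatmap_matrix(pd.DataFrame(rows))
    assert mat.loc[("primary", "PT"), "CD68-CD163+"] == pytest.approx(3.0)
    one = subtype_heatmap_matrix(pd.DataFrame(rows[:1]))
    assert one.loc[("primary", "PT"), "CD68-CD163+"] == pytest.approx(2.0)
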