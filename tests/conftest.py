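from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatialtme.cellio import ROI, SampleMap


def make_sample(
    cells: list[dict],
    panel: list[str],
    rois: list[ROI] | None = None,
    patient_id: str = "P01",
    lesion_type: str = "primary",
    lesion_id: str = "L1",
) -> SampleMap:
    """Build a SampleMap from a list of per-cell dicts.

    Each dict may give x, y, roi_id, compartment and any subset of panel
    markers (missing markers default to negative).
    """
    if rois is None:
        rois = [ROI("R1", 0.0, 0.0, 1000.0, 1000.0, 1.0)]
    rows = []
    for i, c in enumerate(cells):
        row = {
            "cell_id": c.get("cell_id", f"c{i}"),
            "roi_id": c.get("roi_id", rois[0].roi_id),
            "x": float(c.get("x", 0.0)),
            "y": float(c.get("y", 0.0)),
            "compartment": c.get("compartment", "stroma"),
        }
        for m in panel:
            row[m] = bool(c.get(m, False))
        rows.append(row)
    columns = ["cell_id", "roi_id", "x", "y", "compartment", *panel]
    df = pd.DataFrame(rows, columns=columns) if rows else pd.DataFrame(
        {c: pd.Series(dtype=object) for c in columns}
    )
    if not rows:
        df = df.astype({"x": float, "y": float})
        for m in panel:
            df[m] = df[m].astype(bool)
    return SampleMap(
        patient_id=patient_id,
        lesion_type=lesion_type,
        lesion_id=lesion_id,
        panel=list(panel),
        rois=rois,
        cells=df,
    )


def random_sample(rng: np.random.Generator, n_cells: int | None = None) -> SampleMap:
    """A randomized SampleMap for round-trip and tally property tests."""
    panel = ["CD8", "CD68", "CD163", "PD-L1"][: int(rng.integers(1, 5))]
    n_rois = int(rng.integers(1, 4))
    rois = [
        ROI(f"R{k}", 0.0, 0.0, 500.0 + 100 * k, 400.0, 0.2 + 0.1 * k)
        for k in range(n_rois)
    ]
    if n_cells is None:
        n_cells = int(rng.integers(0, 60))
    cells = []
    for i in range(n_cells):
        roi = rois[int(rng.integers(0, n_rois))]
        cells.append(
            {
                "cell_id": f"c{i}",
                "roi_id": roi.roi_id,
                "x": float(rng.uniform(roi.x_min, roi.x_max)),
                "y": float(rng.uniform(roi.y_min, roi.y_max)),
                "compartment": "tumor" if rng.random() < 0.4 else "stroma",
                **{m: bool(rng.random() < 0.3) for m in panel},
            }
        )
    return make_sample(cells, panel, rois)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
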