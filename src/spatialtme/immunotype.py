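"""CD8-based immunophenotype classification of lesions.

Each lesion is called **immune-inflamed**, **immune-excluded** or
**immune-desert** from its regional CD8+ T-cell densities, following the
qualitative phenotype concept of cancer-immunity profiling: inflamed tumors
have cytotoxic T cells inside the tumor core, excluded tumors accumulate
them at the invasive margin without infiltration, and desert tumors lack
them in both compartments.

The operational rule uses a density threshold t (cells/mm²):

* inflamed  <=> d_TC >= t
* excluded  <=> d_TC < t and d_TF >= t
* desert    <=> d_TC < t and d_TF < t

No published numeric cutoff exists for this classification, so the default
threshold is data-adaptive — the cohort median CD8 density over the tumor
centers of all lesions — which avoids unit-dependent magic numbers; a fixed
threshold can be supplied instead.  The threshold used is recorded in every
call so results are interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SpatialTMEError, UnclassifiableError

LABELS = ("inflamed", "desert", "excluded")

CALL_COLUMNS = ["patient_id", "lesion_type", "label", "d_tc", "d_tf", "threshold"]


@dataclass(frozen=True)
class ImmunotypeCall:
    patient_id: str
    lesion_type: str
    label: str  # one of LABELS, or "unclassifiable"
    d_tc: float
    d_tf: float
    threshold: float


def classify_immunotype(d_tc: float, d_tf: float, threshold: float) -> str:
    """Deterministic immunotype label from regional CD8 densities.

    Raises :class:`UnclassifiableError` when the call would depend on a
    missing density (d_TC missing, or d_TC below threshold with d_TF
    missing — e.g. a lesion whose invasive front could not be delineated).
    """
    if not threshold > 0:
        raise SpatialTMEError("immunotype threshold must be > 0")
    for name, v in (("d_tc", d_tc), ("d_tf", d_tf)):
        if v is not None and not math.isnan(v) and v < 0:
            raise SpatialTMEError(f"{name} must be >= 0, got {v}")
    tc_missing = d_tc is None or math.isnan(d_tc)
    tf_missing = d_tf is None or math.isnan(d_tf)
    if tc_missing:
        raise UnclassifiableError("tumor-center CD8 density is missing")
    if d_tc >= threshold:
        return "inflamed"
    if tf_missing:
        raise UnclassifiableError(
            "tumor-center density below threshold but invasive-front density missing"
        )
    return "excluded" if d_tf >= threshold else "desert"


def cohort_median_threshold(densities: pd.DataFrame, marker: str = "CD8") -> float:
    """Cohort median of tumor-center densities of ``marker`` over all lesions."""
    sel = (densities["phenotype"] == marker) & (densities["region"] == "TC")
    vals = densities.loc[sel, "density"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise SpatialTMEError(f"no tumor-center {marker} densities in cohort")
    med = float(np.median(vals))
    if med <= 0:
        raise SpatialTMEError(
            f"cohort median tumor-center {marker} density is {med}; "
            "supply a fixed positive threshold"
        )
    return med


def call_immunotypes(
    densities: pd.DataFrame,
    marker: str = "CD8",
    threshold: float | None = None,
    on_unclassifiable: str = "nan",
) -> pd.DataFrame:
    """Classify every lesion in a cohort density table.

    ``threshold`` defaults to :func:`cohort_median_threshold`.  Lesions that
    cannot be classified are labeled ``"unclassifiable"`` (default) or raise
    (``on_unclassifiable="raise"``).  Primary and metastatic lesions are
    classified independently.
    """
    if on_unclassifiable not in ("nan", "raise"):
        raise SpatialTMEError(f"unknown on_unclassifiable {on_unclassifiable!r}")
    thr = cohort_median_threshold(densities, marker) if threshold is None else float(threshold)
    sub = densities[densities["phenotype"] == marker]
    piv = sub.pivot_table(
        index=["patient_id", "lesion_type"], columns="region", values="density",
        aggfunc="first", dropna=False,
    )
    rows = []
    for (pid, lt), r in piv.iterrows():
        d_tc = float(r.get("TC", float("nan")))
        d_tf = float(r.get("TF", float("nan")))
        try:
            label = classify_immunotype(d_tc, d_tf, thr)
        except UnclassifiableError:
            if on_unclassifiable == "raise":
                raise
            label = "unclassifiable"
        rows.append(
            {"patient_id": pid, "lesion_type": lt, "label": label,
             "d_tc": d_tc, "d_tf": d_tf, "threshold": thr}
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def compare_marker_across_immunotypes(
    densities: pd.DataFrame,
    marker: str,
    region: str,
    calls: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of a marker between immunotype groups.

    Run within the stated region, separately for primary and metastatic
    lesions.  Pairs involving an empty group are reported as missing rows
    rather than dropped silently.
    """
    from .stats import _result_row, rank_sum_test  # local import avoids cycle

    rows = []
    for lt in ("primary", "metastasis"):
        sub = calls[calls["lesion_type"] == lt]
        group_of = dict(zip(sub["patient_id"].astype(str), sub["label"]))
        sel = (
            (densities["phenotype"] == marker)
            & (densities["lesion_type"] == lt)
            & (densities["region"] == region)
        )
        v = pd.Series(
            densities.loc[sel, "density"].to_numpy(),
            index=densities.loc[sel, "patient_id"].astype(str).to_numpy(),
        )
        for i, la in enumerate(LABELS):
            for lb in LABELS[i + 1:]:
                va = v[[group_of.get(p) == la for p in v.index]].to_numpy()
                vb = v[[group_of.get(p) == lb for p in v.index]].to_numpy()
                res = rank_sum_test(va, vb, alpha=alpha)
                rows.append(
                    _result_row("immunotype_contrast", marker, lt, region,
                                la, lb, res, "rank_sum")
                )
    from .stats import BATTERY_COLUMNS

    return pd.DataFrame(rows, columns=BATTERY_COLUMNS)
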