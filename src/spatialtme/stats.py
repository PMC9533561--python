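"""Wilcoxon comparison battery with exact small-sample null distributions.

Two nonparametric tests drive every comparison in the pipeline:

* the **Wilcoxon signed-rank test** for paired designs — region-vs-region
  contrasts within lesions and primary-vs-metastasis contrasts within
  patients (the natural pairing of a paired surgical cohort);
* the **Wilcoxon rank-sum (Mann-Whitney U) test** for independent clinical
  subgroups (number of liver metastases 1 vs >1, maximum metastasis
  diameter < 3 vs >= 3 cm).

Both tests use the exact permutation null whenever it is available at small
sample sizes — full enumeration of the 2^n sign assignments (signed-rank,
n <= 25, untied absolute differences) or of the C(m+n, m) group assignments
(rank-sum, m+n <= 20, no ties across groups), computed by dynamic
programming over rank sums — and otherwise the tie-corrected normal
approximation with a 0.5 continuity correction.  Two-sided p-values are
2*min(P(T <= t), P(T >= t)) capped at 1.  Raw p-values are reported without
multiplicity adjustment; an optional Benjamini-Hochberg column can be added
for sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import SpatialTMEError

BATTERY_COLUMNS = [
    "family", "marker", "lesion_type", "region", "group_a", "group_b",
    "test", "method", "n_effective", "statistic", "p", "significant",
    "mean_a", "sd_a", "median_a", "mean_b", "sd_b", "median_b",
]


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float


@dataclass(frozen=True)
class TestResult:
    """Outcome of one Wilcoxon comparison."""

    test: str  # "signed_rank" | "rank_sum"
    statistic: float  # W (sum of positive-difference ranks) or U (group a)
    n_effective: int
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    summary_a: GroupSummary
    summary_b: GroupSummary
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_two_sided < self.alpha)


def _summary(values: np.ndarray) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return GroupSummary(0, float("nan"), float("nan"), float("nan"))
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else float("nan")
    return GroupSummary(len(v), float(np.mean(v)), sd, float(np.median(v)))


# ---------------------------------------------------------------------------
# exact null distributions (dynamic programming over rank sums)
# ---------------------------------------------------------------------------

def signed_rank_null_counts(n: int) -> np.ndarray:
    """Counts of sign assignments by W = sum of positive ranks, W = 0..n(n+1)/2.

    Equivalent to expanding prod_k (1 + z^k) for k = 1..n; total mass 2^n.
    """
    total = n * (n + 1) // 2
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[: total + 1 - k].copy()
    return counts


def rank_sum_null_counts(ranks2: Sequence[int], m: int) -> np.ndarray:
    """Counts of size-m subsets of ``ranks2`` by doubled rank sum.

    ``ranks2`` are the joint mid-ranks multiplied by 2 (integers, so tied
    mid-ranks stay exact).  Entry [s] counts subsets of size m whose doubled
    rank sum is s; total mass C(len(ranks2), m).
    """
    total = int(sum(ranks2))
    dp = np.zeros((m + 1, total + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        # iterate sizes downward so each rank is used at most once
        for size in range(m, 0, -1):
            dp[size, r:] += dp[size - 1, : total + 1 - r]
    return dp[m]


def _two_sided_p(counts: np.ndarray, stat: float) -> float:
    total = counts.sum()
    idx = int(round(stat))
    p_le = counts[: idx + 1].sum() / total
    p_ge = counts[idx:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def signed_rank_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    exact_max_n: int = 25,
) -> TestResult | None:
    """Paired Wilcoxon signed-rank test of ``a`` vs ``b``.

    Pairs with a missing member are dropped (pairwise deletion); zero
    differences are dropped before ranking, so ``n_effective`` is the number
    of nonzero differences.  Returns None when no complete pair remains
    (missing result).  With all differences zero the result is p = 1 at
    ``n_effective`` = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise SpatialTMEError("signed_rank_test needs equal-length paired vectors")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) == 0:
        return None
    sa, sb = _summary(a), _summary(b)
    d = a - b
    nz = d != 0
    n = int(nz.sum())
    if n == 0:
        return TestResult("signed_rank", 0.0, 0, 1.0, "exact", sa, sb, alpha)
    dnz = d[nz]
    absd = np.abs(dnz)
    ranks = sps.rankdata(absd)
    w = float(ranks[dnz > 0].sum())
    has_ties = len(np.unique(absd)) < n
    if n <= exact_max_n and not has_ties:
        counts = signed_rank_null_counts(n)
        p = _two_sided_p(counts, w)
        method = "exact"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(absd, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - float(
            np.sum(tie_counts**3 - tie_counts)
        ) / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = (abs(w - mu) - 0.5) / math.sqrt(var)
            p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
        method = "normal_approx"
    return TestResult("signed_rank", w, n, p, method, sa, sb, alpha)


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    exact_max_n: int = 20,
) -> TestResult | None:
    """Unpaired Wilcoxon rank-sum (Mann-Whitney U) test of ``a`` vs ``b``.

    Missing values are dropped per group; an empty group yields None
    (missing result).  The statistic is U for group ``a``.  Swapping the
    groups leaves the two-sided p unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        return None
    sa, sb = _summary(a), _summary(b)
    joint = np.concatenate([a, b])
    ranks = sps.rankdata(joint)
    ra = float(ranks[:m].sum())
    u = ra - m * (m + 1) / 2.0
    cross_ties = bool(np.intersect1d(np.unique(a), np.unique(b)).size)
    if m + n <= exact_max_n and not cross_ties:
        ranks2 = np.rint(ranks * 2).astype(int)
        counts = rank_sum_null_counts(ranks2, m)
        p = _two_sided_p(counts, ra * 2)
        method = "exact"
    else:
        nn = m + n
        mu = m * n / 2.0
        _, tie_counts = np.unique(joint, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = m * n / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(var)
            p = float(min(1.0, 2.0 * sps.norm.sf(max(z, 0.0))))
        method = "normal_approx"
    return TestResult("rank_sum", u, m + n, p, method, sa, sb, alpha)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate as NaN."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# the comparison battery
# ---------------------------------------------------------------------------

def _result_row(
    family: str,
    marker: str,
    lesion_type: str,
    region: str,
    group_a: str,
    group_b: str,
    res: TestResult | None,
    test_name: str,
) -> dict:
    if res is None:
        return {
            "family": family, "marker": marker, "lesion_type": lesion_type,
            "region": region, "group_a": group_a, "group_b": group_b,
            "test": test_name, "method": "missing", "n_effective": 0,
            "statistic": float("nan"), "p": float("nan"), "significant": False,
            "mean_a": float("nan"), "sd_a": float("nan"), "median_a": float("nan"),
            "mean_b": float("nan"), "sd_b": float("nan"), "median_b": float("nan"),
        }
    return {
        "family": family, "marker": marker, "lesion_type": lesion_type,
        "region": region, "group_a": group_a, "group_b": group_b,
        "test": res.test, "method": res.method, "n_effective": res.n_effective,
        "statistic": res.statistic, "p": res.p_two_sided,
        "significant": res.significant,
        "mean_a": res.summary_a.mean, "sd_a": res.summary_a.sd,
        "median_a": res.summary_a.median,
        "mean_b": res.summary_b.mean, "sd_b": res.summary_b.sd,
        "median_b": res.summary_b.median,
    }


def _density_series(
    densities: pd.DataFrame, marker: str, lesion_type: str, region: str
) -> pd.Series:
    sel = (
        (densities["phenotype"] == marker)
        & (densities["lesion_type"] == lesion_type)
        & (densities["region"] == region)
    )
    sub = densities.loc[sel]
    return pd.Series(sub["density"].to_numpy(), index=sub["patient_id"].to_numpy())


class _DensityIndex:
    """Pre-grouped (marker, lesion_type, region) -> per-patient density series."""

    def __init__(self, densities: pd.DataFrame):
        self._groups: dict[tuple, pd.Series] = {}
        for key, sub in densities.groupby(
            ["phenotype", "lesion_type", "region"], sort=False
        ):
            self._groups[key] = pd.Series(
                sub["density"].to_numpy(), index=sub["patient_id"].astype(str).to_numpy()
            )

    def get(self, marker: str, lesion_type: str, region: str) -> pd.Series:
        return self._groups.get((marker, lesion_type, region), pd.Series(dtype=float))


def run_comparison_battery(
    densities: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    calls: pd.DataFrame | None = None,
    markers: Sequence[str] | None = None,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Run the full comparison battery over a tidy cohort density table.

    Families:

    * ``overall`` — primary vs metastasis per marker on the pooled TC+TF
      (``ALL``) densities, paired signed-rank across patients;
    * ``region_contrast`` — TF vs TC and PT vs TF within each lesion type,
      paired signed-rank across lesions;
    * ``cross_lesion`` — primary vs metastasis within each of TC/TF/PT,
      paired signed-rank;
    * ``clinical_subgroup`` (needs ``clinical``) — 1 vs >1 liver metastases
      and diameter < 3 vs >= 3 cm, per lesion type on ``ALL`` densities,
      unpaired rank-sum;
    * ``immunotype_contrast`` (needs ``calls``) — pairwise rank-sum between
      immunotype groups for each marker/region of interest.

    Patients missing one member of a pair are dropped from that pair; strata
    with no usable data yield rows with ``method == "missing"``.
    """
    if markers is None:
        markers = list(dict.fromkeys(densities["phenotype"]))
    rows: list[dict] = []

    patients = list(dict.fromkeys(densities["patient_id"].astype(str)))
    dix = _DensityIndex(densities)

    def paired(marker, lt_a, region_a, lt_b, region_b):
        va = dix.get(marker, lt_a, region_a).reindex(patients)
        vb = dix.get(marker, lt_b, region_b).reindex(patients)
        return signed_rank_test(va.to_numpy(), vb.to_numpy(), alpha=alpha)

    # (i) overall primary vs metastasis on pooled TC+TF
    for marker in markers:
        res = paired(marker, "primary", "ALL", "metastasis", "ALL")
        rows.append(
            _result_row("overall", marker, "both", "ALL", "primary", "metastasis",
                        res, "signed_rank")
        )

    # (ii) region contrasts within lesion type
    for lt in ("primary", "metastasis"):
        for marker in markers:
            for ra, rb in (("TF", "TC"), ("PT", "TF")):
                res = paired(marker, lt, ra, lt, rb)
                rows.append(
                    _result_row("region_contrast", marker, lt, f"{ra}vs{rb}",
                                ra, rb, res, "signed_rank")
                )

    # (iii) primary vs metastasis within each region
    for region in ("TC", "TF", "PT"):
        for marker in markers:
            res = paired(marker, "primary", region, "metastasis", region)
            rows.append(
                _result_row("cross_lesion", marker, "both", region,
                            "primary", "metastasis", res, "signed_rank")
            )

    # (iv) clinical subgroups (unpaired)
    if clinical is not None:
        groupings = {
            ("n_mets=1", "n_mets>1"): clinical["n_liver_metastases"] == 1,
            ("diam<3cm", "diam>=3cm"): clinical["max_metastasis_diameter_cm"] < 3,
        }
        for (name_a, name_b), in_a in groupings.items():
            pa = set(clinical.index[in_a].astype(str))
            pb = set(clinical.index[~in_a].astype(str))
            for lt in ("primary", "metastasis"):
                for marker in markers:
                    v = dix.get(marker, lt, "ALL")
                    va = v[v.index.isin(pa)].to_numpy()
                    vb = v[v.index.isin(pb)].to_numpy()
                    res = rank_sum_test(va, vb, alpha=alpha)
                    rows.append(
                        _result_row("clinical_subgroup", marker, lt, "ALL",
                                    name_a, name_b, res, "rank_sum")
                    )

    # (v) immunotype contrasts (unpaired across lesions of one type)
    if calls is not None:
        labels = ("inflamed", "desert", "excluded")
        itype_markers = [m for m in ("CD68", "CD163", "Foxp3", "PD-L1", "Ki67")
                         if m in markers]
        for lt in ("primary", "metastasis"):
            sub = calls[calls["lesion_type"] == lt]
            group_of = dict(zip(sub["patient_id"].astype(str), sub["label"]))
            for region in ("TF", "TC"):
                for marker in itype_markers:
                    v = dix.get(marker, lt, region)
                    for i, la in enumerate(labels):
                        for lb in labels[i + 1:]:
                            va = v[[group_of.get(p) == la for p in v.index]].to_numpy()
                            vb = v[[group_of.get(p) == lb for p in v.index]].to_numpy()
                            res = rank_sum_test(va, vb, alpha=alpha)
                            rows.append(
                                _result_row("immunotype_contrast", marker, lt,
                                            region, la, lb, res, "rank_sum")
                            )

    out = pd.DataFrame(rows, columns=BATTERY_COLUMNS)
    if fdr:
        out["p_bh"] = np.nan
        for fam, idx in out.groupby("family").groups.items():
            out.loc[idx, "p_bh"] = bh_adjust(out.loc[idx, "p"])
    return out
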