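"""Exact and approximate Wilcoxon tests and the comparison battery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from spatialtme.errors import SpatialTMEError
from spatialtme.stats import (
    rank_sum_test,
    run_comparison_battery,
    signed_rank_test,
)

from _oracles import enumerate_rank_sum_p, enumerate_signed_rank_p


# -- signed-rank ------------------------------------------------------------

def test_signed_rank_identical_pairs_p1():
    r = signed_rank_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.p_two_sided == 1.0
    assert r.n_effective == 0


def test_signed_rank_five_positive_pairs():
    """All-positive distinct differences: W = 15, exact p = 2/32."""
    r = signed_rank_test([10, 20, 30, 40, 50], [9, 18, 27, 36, 45])
    assert r.statistic == 15.0
    assert r.method == "exact"
    assert r.p_two_sided == pytest.approx(2 / 32)


def test_signed_rank_three_pairs_never_significant():
    """With 3 pairs the exact two-sided p is at least 2/8 = 0.25."""
    vals = [(1.0, 2.0, 3.0)]
    for signs in [(1, 1, 1), (1, 1, -1), (1, -1, -1), (-1, -1, -1)]:
        a = np.array([1.0, 2.0, 3.0]) * signs
        r = signed_rank_test(a, np.zeros(3))
        assert r.p_two_sided >= 0.25


def test_signed_rank_unequal_lengths_rejected():
    with pytest.raises(SpatialTMEError):
        signed_rank_test([1, 2], [1, 2, 3])


def test_signed_rank_all_missing_gives_missing_result():
    assert signed_rank_test([np.nan], [1.0]) is None


def test_signed_rank_exact_matches_enumeration(rng):
    """Exact p equals full 2^n enumeration on 100 random untied instances."""
    for _ in range(100):
        n = int(rng.integers(3, 11))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        r = signed_rank_test(a, b)
        p_oracle, w_oracle = enumerate_signed_rank_p(a, b)
        assert r.method == "exact"
        assert r.statistic == pytest.approx(w_oracle)
        assert r.p_two_sided == pytest.approx(p_oracle, abs=1e-12)


def test_signed_rank_matches_scipy_exact(rng):
    for _ in range(20):
        n = int(rng.integers(6, 16))
        d = rng.normal(size=n)
        r = signed_rank_test(d, np.zeros(n))
        ref = sps.wilcoxon(d, alternative="two-sided", method="exact")
        assert r.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)


def test_signed_rank_normal_approx_close_to_exact(rng):
    """At n = 20 the continuity-corrected normal path is within 0.01 of exact."""
    worst = 0.0
    for _ in range(50):
        a = rng.normal(size=20)
        b = rng.normal(loc=rng.uniform(0, 0.6), size=20)
        exact = signed_rank_test(a, b)
        approx = signed_rank_test(a, b, exact_max_n=0)
        assert exact.method == "exact" and approx.method == "normal_approx"
        worst = max(worst, abs(exact.p_two_sided - approx.p_two_sided))
    assert worst <= 0.01


def test_signed_rank_tied_differences_use_normal_approx():
    r = signed_rank_test([2, 3, 4, 5, 6, 7], [1, 2, 3, 4, 5, 6])
    assert r.method == "normal_approx"  # all |d| tied


# -- rank-sum ---------------------------------------------------------------

def test_rank_sum_separated_groups():
    """a < b completely: U = 0, exact p = 2/C(6,3) = 0.1."""
    r = rank_sum_test([1, 2, 3], [4, 5, 6])
    assert r.statistic == 0.0
    assert r.method == "exact"
    assert r.p_two_sided == pytest.approx(0.1)


def test_rank_sum_identical_multisets_p1():
    r = rank_sum_test([1, 2, 3], [1, 2, 3])
    assert r.p_two_sided == 1.0


def test_rank_sum_empty_group_missing():
    assert rank_sum_test([], [1.0, 2.0]) is None
    assert rank_sum_test([np.nan], [1.0]) is None


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_rank_sum_label_symmetry(data):
    m = data.draw(st.integers(1, 8))
    n = data.draw(st.integers(1, 8))
    a = data.draw(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=m, max_size=m)
    )
    b = data.draw(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=n, max_size=n)
    )
    r1 = rank_sum_test(a, b)
    r2 = rank_sum_test(b, a)
    assert r1.p_two_sided == pytest.approx(r2.p_two_sided, abs=1e-12)


def test_rank_sum_exact_matches_enumeration(rng):
    """Exact p equals full C(m+n, m) enumeration on 100 random instances."""
    for _ in range(100):
        m = int(rng.integers(2, 9))
        n = int(rng.integers(2, 9))
        a = rng.normal(size=m)
        b = rng.normal(size=n)
        r = rank_sum_test(a, b)
        p_oracle, u_oracle = enumerate_rank_sum_p(a, b)
        assert r.method == "exact"
        assert r.statistic == pytest.approx(u_oracle)
        assert r.p_two_sided == pytest.approx(p_oracle, abs=1e-12)


def test_rank_sum_matches_scipy_exact(rng):
    for _ in range(20):
        m = int(rng.integers(3, 9))
        n = int(rng.integers(3, 9))
        a = rng.normal(size=m)
        b = rng.normal(size=n)
        r = rank_sum_test(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert r.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)


def test_rank_sum_normal_approx_close_to_exact(rng):
    worst = 0.0
    for _ in range(50):
        a = rng.normal(size=10)
        b = rng.normal(loc=rng.uniform(0, 0.8), size=10)
        exact = rank_sum_test(a, b)
        approx = rank_sum_test(a, b, exact_max_n=0)
        assert exact.method == "exact" and approx.method == "normal_approx"
        worst = max(worst, abs(exact.p_two_sided - approx.p_two_sided))
    assert worst <= 0.01


def test_rank_sum_cross_group_ties_use_normal_approx():
    r = rank_sum_test([1.0, 2.0, 3.0], [3.0, 4.0, 5.0])
    assert r.method == "normal_approx"


# -- battery ----------------------------------------------------------------

def _density_rows(patient_id, lesion_type, marker, region_values):
    return [
        {"patient_id": patient_id, "lesion_type": lesion_type, "region": r,
         "phenotype": marker, "count": 0, "area_mm2": 1.0, "density": v}
        for r, v in region_values.items()
    ]


def _toy_densities(n_patients=6, constant=5.0):
    rows = []
    for i in range(n_patients):
        pid = f"P{i:02d}"
        for lt in ("primary", "metastasis"):
            rows += _density_rows(
                pid, lt, "CD8",
                {"TC": constant, "TF": constant, "PT": constant, "ALL": constant},
            )
    return pd.DataFrame(rows)


def test_battery_constant_densities_all_p1():
    out = run_comparison_battery(_toy_densities())
    assert (out["p"].dropna() == 1.0).all()
    assert not out["significant"].any()


def test_battery_pairwise_deletion_counts():
    """A patient missing its PT density drops only from PT-based pairs."""
    d = _toy_densities(n_patients=8)
    rng = np.random.default_rng(7)
    d["density"] += rng.normal(0, 1, len(d)).round(3)
    d.loc[(d["patient_id"] == "P00") & (d["region"] == "PT"), "density"] = np.nan
    out = run_comparison_battery(d)
    pt_row = out.query("family == 'cross_lesion' and region == 'PT'").iloc[0]
    tc_row = out.query("family == 'cross_lesion' and region == 'TC'").iloc[0]
    assert pt_row["n_effective"] == 7
    assert tc_row["n_effective"] == 8


def test_battery_clinical_subgroups_and_missing_stratum():
    d = _toy_densities(n_patients=6)
    rng = np.random.default_rng(3)
    d["density"] += rng.normal(0, 1, len(d)).round(3)
    clinical = pd.DataFrame(
        {
            "n_liver_metastases": [1, 1, 1, 1, 1, 1],  # ">1" group empty
            "max_metastasis_diameter_cm": [2.0, 2.5, 2.8, 3.5, 4.0, 5.0],
        },
        index=[f"P{i:02d}" for i in range(6)],
    )
    out = run_comparison_battery(d, clinical=clinical)
    mets = out.query("family == 'clinical_subgroup' and group_a == 'n_mets=1'")
    assert (mets["method"] == "missing").all()
    diam = out.query("family == 'clinical_subgroup' and group_a == 'diam<3cm'")
    assert (diam["method"] != "missing").all()
    assert (diam["test"] == "rank_sum").all()


def test_battery_fdr_column_monotone():
    d = _toy_densities(n_patients=10)
    rng = np.random.default_rng(11)
    d["density"] += rng.normal(0, 1, len(d)).round(3)
    out = run_comparison_battery(d, fdr=True)
    ok = out.dropna(subset=["p", "p_bh"])
    assert (ok["p_bh"] >= ok["p"] - 1e-12).all()
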