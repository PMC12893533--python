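import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from landfrag import (
    AllZeroDifferencesError,
    PairedSample,
    compare_all,
    pair_series,
    wilcoxon_effect_size,
    wilcoxon_signed_rank,
)

import _oracles


def _sample(x, y, metric="np", zone="north"):
    n = len(x)
    return PairedSample(metric=metric, zone=zone, years=tuple(range(n)),
                        x=tuple(float(v) for v in x), y=tuple(float(v) for v in y))


def test_all_positive_differences_n8_exact():
    """Eight same-sign untied differences: W+ = 36, p = 2/2^8 = 0.0078125."""
    d = [1, 2, 3, 4, 5, 6, 7, 8]
    w, p, method = wilcoxon_signed_rank(_sample(d, [0] * 8))
    assert (w, method) == (36.0, "exact")
    assert p == pytest.approx(_oracles.exact_two_sided_p_all_same_sign(8), abs=1e-15)
    assert round(p, 4) == 0.0078


def test_one_negative_difference_exact():
    d = [-1, 2, 3, 4, 5, 6, 7, 8]
    w, p, method = wilcoxon_signed_rank(_sample(d, [0] * 8))
    assert (w, method) == (35.0, "exact")
    assert p == pytest.approx(4 / 256, abs=1e-15)


def test_all_zero_differences_is_an_error():
    with pytest.raises(AllZeroDifferencesError):
        wilcoxon_signed_rank(_sample([1.0, 2.0], [1.0, 2.0]))


def test_zero_differences_dropped():
    # one zero pair drops; remaining 7 all-positive: p = 2/2^7
    d = [0, 1, 2, 3, 4, 5, 6, 7]
    w, p, method = wilcoxon_signed_rank(_sample(d, [0] * 8))
    assert method == "exact"
    assert p == pytest.approx(2 / 128, abs=1e-15)


def test_exact_p_matches_scipy_on_random_untied(rng):
    for _ in range(20):
        n = int(rng.integers(5, 11))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        d = x - y
        if np.unique(np.abs(d)).size < n or (d == 0).any():
            continue
        w, p, method = wilcoxon_signed_rank(_sample(x, y))
        assert method == "exact"
        ref = stats.wilcoxon(x, y, method="exact")
        assert p == pytest.approx(ref.pvalue, rel=1e-12)


def test_tied_differences_use_normal_approximation():
    x = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
    y = [v - 5.0 for v in x]  # all |d| = 5: fully tied
    w, p, method = wilcoxon_signed_rank(_sample(x, y))
    assert method == "approx"
    ref = stats.wilcoxon(x, y, method="approx", correction=False)
    assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_effect_size_values():
    assert wilcoxon_effect_size(36.0, 8) == pytest.approx((18 / math.sqrt(51)) / math.sqrt(8))
    assert round(wilcoxon_effect_size(36.0, 8), 3) == 0.891
    assert wilcoxon_effect_size(0.0, 8) == pytest.approx(wilcoxon_effect_size(36.0, 8))
    assert wilcoxon_effect_size(18.0, 8) == 0.0  # central value n(n+1)/4


@settings(deadline=None, derandomize=True, max_examples=40)
@given(
    st.lists(
        st.floats(min_value=-100, max_value=100, allow_nan=False).filter(lambda v: abs(v) > 1e-6),
        min_size=3,
        max_size=12,
    ),
    st.floats(min_value=0.1, max_value=10),
    st.floats(min_value=-50, max_value=50),
)
def test_sign_flip_and_affine_invariance(diffs, scale, shift):
    """p and r are invariant to negating d and to shared positive affine maps."""
    x = [shift + scale * v for v in diffs]
    y = [shift] * len(diffs)
    w1, p1, m1 = wilcoxon_signed_rank(_sample(x, y))
    w2, p2, m2 = wilcoxon_signed_rank(_sample(y, x))
    assert p1 == pytest.approx(p2, rel=1e-12)
    n = len(diffs)
    assert wilcoxon_effect_size(w1, n) == pytest.approx(wilcoxon_effect_size(w2, n), rel=1e-12)
    # same ranks under a different positive affine map
    x3 = [1.5 * v + 7 for v in x]
    y3 = [1.5 * v + 7 for v in y]
    w3, p3, m3 = wilcoxon_signed_rank(_sample(x3, y3))
    assert p3 == pytest.approx(p1, rel=1e-12)


def _table(source, zones, years, value):
    rows = []
    for zone in zones:
        for i, year in enumerate(years):
            rows.append({"source": source, "zone": zone, "year": year,
                         "np": value(i), "pa_mn_ha": value(i) + 0.5})
    return pd.DataFrame(rows)


def test_pair_series_on_year_intersection():
    maate_years = [1990, 2000, 2008, 2014, 2016, 2018, 2020, 2022]
    mapbiomas_years = list(range(1990, 2023, 2))
    t1 = _table("m1", ["north"], maate_years, lambda i: 10.0 + i)
    t2 = _table("m2", ["north"], mapbiomas_years, lambda i: 5.0 + i)
    sample = pair_series(t1, t2, "np", "north")
    assert sample.years == tuple(maate_years)  # the 8 map years are the intersection
    assert len(sample.x) == 8


def test_pair_series_disjoint_years_error():
    t1 = _table("m1", ["north"], [1990, 2000], lambda i: 1.0 + i)
    t2 = _table("m2", ["north"], [2010, 2020], lambda i: 2.0 + i)
    with pytest.raises(ValueError, match="common years"):
        pair_series(t1, t2, "np", "north")


def test_pair_series_drops_missing_years():
    t1 = _table("m1", ["north"], [1990, 2000, 2008], lambda i: 1.0 + i)
    t2 = _table("m2", ["north"], [1990, 2000, 2008], lambda i: 2.0 + i)
    t2.loc[t2["year"] == 2000, "np"] = float("nan")
    sample = pair_series(t1, t2, "np", "north")
    assert sample.years == (1990, 2008)


def test_compare_all_cardinality_and_pattern():
    zones = ["north", "center", "south"]
    years = [1990, 2000, 2008, 2014, 2016, 2018, 2020, 2022]
    t1 = _table("m1", zones, years, lambda i: 10.0 + i + 0.1 * i * i)
    t2 = _table("m2", zones, years, lambda i: 5.0 + i)
    results = compare_all(t1, t2, ["np", "pa_mn_ha"], zones)
    assert len(results) == 6
    # all-same-sign untied differences at n=8 in every cell
    for res in results:
        assert res.method == "exact"
        assert round(res.p_value, 4) == 0.0078
        assert round(res.r_effect, 3) == 0.891
        assert res.significant


def test_compare_all_reports_identical_tables_without_crashing():
    zones = ["north"]
    years = [1990, 2000]
    t1 = _table("m1", zones, years, lambda i: 1.0 + i)
    results = compare_all(t1, t1.copy(), ["np"], zones)
    assert len(results) == 1
    assert results[0].method == "undefined"
    assert math.isnan(results[0].p_value) and not results[0].significant
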