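import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from swirotome.dataio import Frame, ROIMask
from swirotome.features import (
    FEATURE_NAMES,
    compute_statistics,
    extract_features,
    featurize_frames,
    quantile,
)


# ---------------------------------------------------------------------------
# Independent oracle: naive loop-based statistics with the documented
# quantile convention (linear interpolation at rank (n-1)q).
# ---------------------------------------------------------------------------

def oracle_quantile(values, q):
    v = sorted(float(x) for x in values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def oracle_statistics(values):
    v = [float(x) for x in values]
    med = oracle_quantile(v, 0.5)
    q1 = oracle_quantile(v, 0.25)
    q3 = oracle_quantile(v, 0.75)

    def loc(subset):
        if not subset:
            return med, med
        return sum(subset) / len(subset), oracle_quantile(subset, 0.5)

    mean_iqr, median_iqr = loc([x for x in v if q1 <= x <= q3])
    mean_above, median_above = loc([x for x in v if x > med])
    mean_below, median_below = loc([x for x in v if x < med])
    return {
        "mean_intensity": sum(v) / len(v),
        "median_intensity": med,
        "mean_iqr": mean_iqr,
        "median_iqr": median_iqr,
        "mean_above": mean_above,
        "median_above": median_above,
        "mean_below": mean_below,
        "median_below": median_below,
        "diff_max_median": max(v) - med,
        "diff_median_min": med - min(v),
        "iqr": q3 - q1,
    }


# ---------------------------------------------------------------------------
# quantile
# ---------------------------------------------------------------------------

def test_quantile_worked_example():
    assert quantile([1, 2, 3, 4], 0.25) == pytest.approx(1.75)


def test_quantile_extremes():
    v = [9.0, 1.0, 5.0]
    assert quantile(v, 0.0) == 1.0
    assert quantile(v, 1.0) == 9.0


def test_quantile_single_element():
    for q in (0.0, 0.3, 1.0):
        assert quantile([5.0], q) == 5.0


def test_quantile_empty_errors():
    with pytest.raises(ValueError):
        quantile([], 0.5)


# ---------------------------------------------------------------------------
# extract_features
# ---------------------------------------------------------------------------

def _frame_with_roi(values, shape=(4, 4)):
    px = np.zeros(shape, dtype=np.uint16)
    mask = np.zeros(shape, dtype=bool)
    flat = px.ravel()
    flat[: len(values)] = values
    mask.ravel()[: len(values)] = True
    return Frame(flat.reshape(shape)), ROIMask(mask)


def test_worked_example_1234():
    frame, mask = _frame_with_roi([1, 2, 3, 4])
    fv = extract_features(frame, mask, "set2")
    expected = {
        "mean_intensity": 2.5,
        "median_intensity": 2.5,
        "mean_iqr": 2.5,
        "median_iqr": 2.5,
        "mean_above": 3.5,
        "median_above": 3.5,
        "mean_below": 1.5,
        "median_below": 1.5,
        "diff_max_median": 1.5,
        "diff_median_min": 1.5,
        "iqr": 1.5,
    }
    for key, val in expected.items():
        assert fv[key] == pytest.approx(val), key


def test_uniform_roi_fallbacks():
    frame, mask = _frame_with_roi([7, 7, 7, 7, 7])
    fv = extract_features(frame, mask, "set2")
    for key in FEATURE_NAMES[:8]:
        assert fv[key] == 7.0, key
    for key in ("diff_max_median", "diff_median_min", "iqr"):
        assert fv[key] == 0.0, key


def test_features_ignore_non_roi_pixels():
    frame, mask = _frame_with_roi([10, 20, 30])
    fv1 = extract_features(frame, mask, "set2")
    px = frame.pixels.copy()
    px[~mask.mask] = 12345
    fv2 = extract_features(Frame(px), mask, "set2")
    assert fv1 == fv2


def test_empty_roi_errors():
    frame = Frame(np.zeros((3, 3), dtype=np.uint16))
    with pytest.raises(ValueError, match="empty ROI"):
        extract_features(frame, ROIMask(np.zeros((3, 3), dtype=bool)), "set2")


def test_set1_only_mean():
    frame, mask = _frame_with_roi([2, 4])
    assert extract_features(frame, mask, "set1") == {"mean_intensity": 3.0}


def test_oracle_equivalence_random_multisets():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = int(rng.integers(1, 501))
        v = rng.integers(0, 16384, n).astype(float)
        got = compute_statistics(v)
        want = oracle_statistics(v)
        for key in FEATURE_NAMES:
            np.testing.assert_allclose(got[key], want[key], rtol=1e-9, atol=1e-9)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(st.integers(0, 2000), min_size=1, max_size=60),
    st.floats(0.1, 5.0),
    st.integers(0, 1000),
)
def test_location_scale_equivariance(values, a, b):
    v = np.asarray(values, dtype=float)
    base = compute_statistics(v)
    scaled = compute_statistics(a * v + b)
    for key in FEATURE_NAMES[:8]:
        np.testing.assert_allclose(scaled[key], a * base[key] + b, rtol=1e-9)
    for key in ("diff_max_median", "diff_median_min", "iqr"):
        np.testing.assert_allclose(scaled[key], a * base[key], rtol=1e-9,
                                   atol=1e-9)


def test_permutation_invariance():
    rng = np.random.default_rng(7)
    v = rng.integers(0, 16384, 200).astype(float)
    assert compute_statistics(v) == compute_statistics(rng.permutation(v))


def test_feature_vector_internal_ordering():
    rng = np.random.default_rng(11)
    v = rng.integers(0, 16384, 99).astype(float)
    fv = compute_statistics(v)
    assert fv["diff_max_median"] >= 0
    assert fv["diff_median_min"] >= 0
    assert fv["iqr"] >= 0
    assert fv["mean_below"] <= fv["median_intensity"] <= fv["mean_above"]


# ---------------------------------------------------------------------------
# featurize
# ---------------------------------------------------------------------------

def test_featurize_frames_table_shape():
    rng = np.random.default_rng(0)
    pairs = []
    for i in range(10):
        px = rng.integers(0, 16384, (8, 8)).astype(np.uint16)
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        pairs.append(
            (Frame(px, ear_id=f"E{i}", frame_index=i,
                   label="effusion" if i % 2 else "no_effusion"),
             ROIMask(mask))
        )
    table = featurize_frames(pairs, input_set="set2")
    assert len(table) == 10
    assert list(table.columns[4:]) == list(FEATURE_NAMES)
    assert set(table["label"]) == {"effusion", "no_effusion"}


def test_featurize_drops_empty_roi():
    px = np.full((4, 4), 100, dtype=np.uint16)
    good = (Frame(px, ear_id="a"), ROIMask(np.ones((4, 4), dtype=bool)))
    empty = (Frame(px, ear_id="b"), ROIMask(np.zeros((4, 4), dtype=bool)))
    table = featurize_frames([good, empty])
    assert len(table) == 1
    assert table.attrs["n_dropped_empty_roi"] == 1


def test_cohort_effusion_mean_lower(default_table):
    by_label = default_table.groupby("label")["mean_intensity"].mean()
    assert by_label["effusion"] < by_label["no_effusion"]


def test_featurize_deterministic():
    from swirotome.pipeline import cohort_feature_table
    from swirotome.synthetic import SyntheticConfig

    cfg = SyntheticConfig(n_ears=4, prevalence=0.5, frames_per_ear=(2, 3), seed=8)
    pd.testing.assert_frame_equal(
        cohort_feature_table(cfg), cohort_feature_table(cfg)
    )
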