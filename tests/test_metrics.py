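"""Division counts, top-decile classification, spike-in calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonedyn import (
    ProliferativeClassifier,
    SpikeinCalibrator,
    calibrate_spikeins,
    classify_proliferative,
    estimate_cells,
    log2_divisions,
    summarize_by_group,
)
from clonedyn.metrics import HIGH, LOW


def test_division_count_examples():
    assert log2_divisions([1024])[0] == 10.0
    with pytest.warns(UserWarning, match="dropped"):
        out = log2_divisions([1, 8], drop_singletons=True)
    assert out.tolist() == [3.0]
    assert log2_divisions([2907])[0] == pytest.approx(11.505, abs=1e-3)


def test_division_count_rejects_subunit_sizes():
    with pytest.raises(ValueError):
        log2_divisions([0, 4])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=50))
def test_log2_inverts_powers_of_two(exponents):
    sizes = np.exp2(exponents)
    assert np.allclose(log2_divisions(sizes), exponents)


def test_top_decile_has_exact_count():
    rng = np.random.default_rng(0)
    sizes = rng.integers(1, 1000, 100)
    labels = classify_proliferative(sizes)
    assert (labels == HIGH).sum() == 10
    # the labelled clones are the largest ones
    assert sizes[labels == HIGH].min() >= np.sort(sizes)[-10]


@pytest.mark.parametrize("n", [10, 37, 100, 101])
def test_labelled_count_is_ceiling_rule(n):
    sizes = np.arange(1, n + 1)
    labels = classify_proliferative(sizes, quantile=0.9)
    assert (labels == HIGH).sum() == int(np.ceil(0.1 * n))


def test_ties_broken_by_input_order_with_warning():
    with pytest.warns(UserWarning, match="ties"):
        labels = classify_proliferative(np.full(20, 7.0))
    assert (labels == HIGH).sum() == 2
    assert set(np.where(labels == HIGH)[0]) == {0, 1}


def test_reference_threshold_can_exceed_ten_percent():
    reference = np.arange(1, 101, dtype=float)
    test_sample = reference + 50.0
    labels = classify_proliferative(test_sample, reference=reference)
    assert (labels == HIGH).sum() > 10


def test_too_few_clones_rejected():
    with pytest.raises(ValueError):
        classify_proliferative(np.arange(1, 6))
    with pytest.raises(ValueError):
        classify_proliferative(np.array([]))


def test_classifier_estimator_round_trip():
    clf = ProliferativeClassifier(quantile=0.9).fit(np.arange(1, 101))
    assert clf.threshold_ == 90
    labels = clf.predict([5, 90, 95])
    assert labels.tolist() == [LOW, HIGH, HIGH]


def test_spikein_exact_proportional_calibration():
    cells = np.array([50.0, 500.0, 1000.0])
    cal = calibrate_spikeins(cells, cells * 100.0)
    assert cal.reads_per_cell == pytest.approx(100.0)
    assert cal.intercept == pytest.approx(0.0, abs=1e-9)
    assert cal.fit_r == pytest.approx(1.0)


def test_spikein_replicates_highly_correlated_with_mild_noise():
    rng = np.random.default_rng(1)
    cells = np.array([50.0, 500.0, 500.0, 1000.0])
    reads = cells * 20.0 * (1 + rng.normal(0, 0.01, cells.size))
    cal = calibrate_spikeins(cells, reads)
    assert cal.fit_r >= 0.99


def test_spikein_noisy_slope_recovery():
    """3 levels, 5% noise: median recovered slope within 10% over 50 seeds."""
    cells = np.array([50.0, 500.0, 1000.0])
    slopes = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        reads = cells * 20.0 * (1 + rng.normal(0, 0.05, cells.size))
        slopes.append(calibrate_spikeins(cells, reads).reads_per_cell)
    assert abs(np.median(slopes) - 20.0) / 20.0 < 0.10


def test_single_level_calibration_rejected():
    with pytest.raises(ValueError):
        calibrate_spikeins([500.0, 500.0], [100.0, 110.0])


def test_estimated_cells_floored_with_qc():
    cal = calibrate_spikeins([50.0, 1000.0], [600.0, 10100.0])
    cells, negative = estimate_cells(np.array([40.0, 5100.0]), cal, return_qc=True)
    assert cells[0] == 0.0 and negative[0]
    assert cells[1] == pytest.approx(500.0) and not negative[1]


def test_calibrator_transformer():
    cal = SpikeinCalibrator().fit([50.0, 500.0, 1000.0], [500.0, 5000.0, 10000.0])
    assert np.allclose(cal.transform([1000.0, 2500.0]), [100.0, 250.0])


def _clone_frame(sizes, **cols):
    df = pd.DataFrame({"n_cells": sizes})
    for k, v in cols.items():
        df[k] = v
    return df


def test_group_summary_single_group():
    df = _clone_frame([2, 4, 8], day=8.0)
    out = summarize_by_group(df, "day")
    assert out.loc[0, "mean_divisions"] == pytest.approx(2.0)
    assert out.loc[0, "n_clones"] == 3
    assert out.loc[0, "hist"] == {0: 0, 1: 1, 2: 1, 3: 1}


def test_identical_groups_identical_summaries():
    df = pd.concat(
        [
            _clone_frame([2, 4, 16, 64], day=8.0, replicate=1),
            _clone_frame([2, 4, 16, 64], day=8.0, replicate=2),
        ]
    )
    out = summarize_by_group(df, ["day", "replicate"])
    a, b = out.drop(columns=["replicate"]).iloc[0], out.drop(
        columns=["replicate"]
    ).iloc[1]
    assert a.equals(b)


def test_unknown_group_key_rejected():
    with pytest.raises(ValueError):
        summarize_by_group(_clone_frame([2, 4], day=8.0), ["plate"])
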