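"""Barcode split-experiment simulation and heritability statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonedyn import (
    abundance_correlation,
    growth_rate_distribution,
    null_distribution,
    simulate_split_experiment,
    top_decile_overlap,
)
from clonedyn.heritability import DegenerateSampleError


def test_identical_samples_fully_overlap():
    a = np.arange(1, 101, dtype=float)
    assert top_decile_overlap(a, a) == 1.0


def test_random_rankings_overlap_at_chance():
    """Independent rankings share ~|A|/n = 10% of their top deciles."""
    rng = np.random.default_rng(0)
    base = np.arange(1000, dtype=float)
    overlaps = [
        top_decile_overlap(rng.permutation(base), rng.permutation(base))
        for _ in range(2000)
    ]
    assert np.mean(overlaps) == pytest.approx(0.10, abs=0.01)


def test_overlap_denominator_options():
    a = pd.Series([10, 9, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1])
    b = pd.Series([10, 1, 9, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1])
    per = top_decile_overlap(a, b)  # top-2 sets {0,1} vs {0,2}
    union = top_decile_overlap(a, b, denominator="union")
    assert per == 0.5 and union == pytest.approx(1 / 3)


def test_overlap_requires_shared_universe():
    a = pd.Series([1.0] * 10, index=[f"x{i}" for i in range(10)])
    b = pd.Series([1.0] * 10, index=[f"y{i}" for i in range(10)])
    with pytest.raises(ValueError):
        top_decile_overlap(a, b)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),
        ([1, 2, 3, 4], [3, 2, 1, 0], -1.0),
        ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
    ],
)
def test_pearson_known_values(a, b, expected):
    r, p = abundance_correlation(a, b)
    assert r == pytest.approx(expected, abs=1e-12)
    assert 0.0 <= p <= 1.0


def test_zero_variance_signalled_distinctly():
    with pytest.raises(DegenerateSampleError):
        abundance_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    n=st.integers(min_value=10, max_value=200),
    doublings=st.integers(min_value=1, max_value=6),
    seed=st.integers(min_value=0, max_value=2**31 - 1),
)
def test_binomial_split_conserves_copies(n, doublings, seed):
    exp = simulate_split_experiment(n, doublings, heritable=False, seed=seed)
    totals = exp.initial_copies["A"] + exp.initial_copies["B"]
    assert (totals == 2**doublings).all()


def test_sixteen_copies_from_four_doublings():
    exp = simulate_split_experiment(50, pre_doublings=4, seed=1)
    assert (exp.initial_copies.sum(axis=1) == 16).all()


def test_heritable_noiseless_growth_is_perfectly_correlated():
    dist = growth_rate_distribution("stochastic", np.linspace(1.0, 8.0, 40))
    exp = simulate_split_experiment(
        200, 4, dist, heritable=True, seed=2, exact_split=True
    )
    assert exp.counts["A"].equals(exp.counts["B"])
    r, _ = abundance_correlation(
        np.log2(exp.counts["A"] + 1), np.log2(exp.counts["B"] + 1)
    )
    assert r == pytest.approx(1.0)


def test_heritable_beats_non_heritable_correlation(reference_divisions):
    dist = growth_rate_distribution("stochastic", reference_divisions)
    r_h, _ = abundance_correlation(
        *simulate_split_experiment(2000, 4, dist, heritable=True, seed=3)
        .counts[["A", "B"]].T.values
    )
    r_n, _ = abundance_correlation(
        *simulate_split_experiment(2000, 4, dist, heritable=False, seed=3)
        .counts[["A", "B"]].T.values
    )
    assert r_h > 0.3 > r_n


def test_non_heritable_mean_correlation_near_zero(reference_divisions):
    dist = growth_rate_distribution("stochastic", reference_divisions)
    rs = []
    for seed in range(50):
        exp = simulate_split_experiment(2000, 4, dist, heritable=False, seed=seed)
        r, _ = abundance_correlation(exp.sample_a, exp.sample_b)
        rs.append(r)
    assert abs(np.mean(rs)) < 0.03


@pytest.mark.parametrize("kind", ["unimodal", "bimodal", "stochastic"])
def test_growth_distribution_kinds_track_reference(kind, reference_divisions):
    dist = growth_rate_distribution(kind, reference_divisions)
    rng = np.random.default_rng(8)
    draws = dist.sample(rng, 20_000)
    assert draws.mean() == pytest.approx(reference_divisions.mean(), abs=0.2)
    if kind != "unimodal":
        assert draws.max() <= reference_divisions.max() + 2.0


def test_unknown_growth_distribution_rejected():
    with pytest.raises(ValueError):
        growth_rate_distribution("weird", np.arange(10.0))


def test_empirical_p_uses_add_one_estimator(reference_divisions):
    dist = growth_rate_distribution("stochastic", reference_divisions)
    obs = simulate_split_experiment(1000, 4, dist, heritable=True, seed=5)
    res = null_distribution(
        reference_divisions,
        "stochastic",
        n_replicates=100,
        seed=6,
        n_barcodes=1000,
        observed=(obs.sample_a, obs.sample_b),
    )
    n_ge = int(np.sum(res.null_r >= res.pearson_r))
    assert res.empirical_p == (1 + n_ge) / (1 + res.summary["n_valid"])
    # a strongly heritable observation should beat every null replicate
    assert res.empirical_p == pytest.approx(1 / 101)


def test_constant_reference_degenerates_and_is_counted():
    res = null_distribution(
        np.full(50, 3.0),
        "stochastic",
        n_replicates=100,
        seed=7,
        n_barcodes=20,
        exact_split=True,
    )
    assert res.n_dropped == 100
    assert res.null_r.size == 0


def test_low_replicate_count_warns(reference_divisions):
    with pytest.warns(UserWarning, match="unstable"):
        null_distribution(
            reference_divisions, "stochastic", n_replicates=99, seed=8,
            n_barcodes=100,
        )
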