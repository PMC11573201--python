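"""Synthetic study-data generators: determinism, delegation, round trips."""

import numpy as np
import pytest
from scipy import stats

from clonedyn import (
    SyntheticConfig,
    TwoStateParams,
    abundance_correlation,
    bimodality_coefficient,
    calibrate_spikeins,
    estimate_cells,
    gen_barcode_experiment,
    gen_clone_size_table,
    gen_density_series,
    log2_divisions,
    simulate_ensemble,
    top_decile_overlap,
)
from clonedyn.synthetic import _class_seed


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, frac_highly_proliferative=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, n_clones=0)
    with pytest.raises(ValueError):
        SyntheticConfig(seed=1, reads_per_cell=0.0)


def test_clone_table_layout_and_determinism():
    cfg = SyntheticConfig(seed=11, n_clones=60, days=(2.0, 8.0))
    t1 = gen_clone_size_table(cfg)
    t2 = gen_clone_size_table(SyntheticConfig(seed=11, n_clones=60, days=(2.0, 8.0)))
    assert t1.equals(t2)
    assert t1.to_csv(sep="\t", index=False) == t2.to_csv(sep="\t", index=False)
    assert len(t1) == 120
    assert set(t1.columns) >= {"clone_id", "replicate", "condition", "day", "n_cells"}
    assert (t1["n_cells"] >= 1).all()
    assert (t1["true_class"] == "hp").sum() == 2 * 6  # 10% of 60, both days


def test_single_class_config_delegates_to_ensemble():
    cfg = SyntheticConfig(seed=21, n_clones=80, days=(8.0,),
                          frac_highly_proliferative=1.0)
    tbl = gen_clone_size_table(cfg)
    direct = simulate_ensemble(
        cfg.hp_params, 80, 8.0, seed=_class_seed(21, 0, 0)
    )
    assert np.array_equal(tbl["n_cells"].to_numpy(), direct.sizes)


def test_all_low_class_has_small_size_mass():
    cfg = SyntheticConfig(seed=31, n_clones=300, days=(8.0,),
                          frac_highly_proliferative=0.0)
    tbl = gen_clone_size_table(cfg)
    assert (tbl["true_class"] == "lp").all()
    assert (tbl["n_cells"] <= 8).mean() > 0.1  # arrested clones stay small


def test_default_mixture_is_not_unimodal_at_day8():
    """Two separated size classes push the coefficient above 1/3."""
    above = 0
    for seed in range(10):
        cfg = SyntheticConfig(seed=400 + seed, days=(8.0,))
        sizes = gen_clone_size_table(cfg)["n_cells"].to_numpy()
        div = log2_divisions(sizes[sizes > 1])
        above += bimodality_coefficient(div).coefficient > 1 / 3
    assert above >= 8


def test_barcode_experiment_noiseless_round_trip():
    cfg = SyntheticConfig(
        seed=51, n_clones=150, days=(8.0,), n_barcodes=200,
        read_noise_sigma=0.0, heritable=True,
    )
    reads, truth = gen_barcode_experiment(cfg)
    spike = reads.spikein_true_cells
    cal = calibrate_spikeins(spike.values, reads.counts.loc[spike.index, "A"].values)
    assert cal.reads_per_cell == pytest.approx(cfg.reads_per_cell)
    # calibrated barcode reads invert exactly to the simulated cell counts
    clones = reads.without_spikeins()
    est = estimate_cells(clones.counts["A"].to_numpy(float), cal)
    assert np.allclose(est, truth.counts["A"].to_numpy(float))
    r_reads, _ = abundance_correlation(clones.counts["A"], clones.counts["B"])
    r_truth, _ = abundance_correlation(truth.counts["A"], truth.counts["B"])
    assert r_reads == pytest.approx(r_truth, abs=1e-9)


def test_non_heritable_barcodes_overlap_at_chance():
    overlaps = []
    for seed in range(5):
        cfg = SyntheticConfig(
            seed=600 + seed, n_clones=150, days=(8.0,), n_barcodes=1000,
            heritable=False,
        )
        reads, _ = gen_barcode_experiment(cfg)
        clones = reads.without_spikeins()
        overlaps.append(top_decile_overlap(clones.counts["A"], clones.counts["B"]))
    assert np.mean(overlaps) == pytest.approx(0.10, abs=0.05)


def test_density_series_zero_effect_indistinguishable():
    cfg = SyntheticConfig(seed=71, n_clones=250)
    tbl = gen_density_series(cfg, densities=(100, 1000),
                             density_effect={100: 0.0, 1000: 0.0})
    a = tbl.loc[tbl["density"] == 100, "n_cells"]
    b = tbl.loc[tbl["density"] == 1000, "n_cells"]
    assert stats.ks_2samp(np.log2(a), np.log2(b)).pvalue > 0.01


def test_density_series_monotone_effect_monotone_medians():
    cfg = SyntheticConfig(seed=81, n_clones=250)
    effects = {100: 0.0, 1000: 0.1, 5000: 0.2}
    tbl = gen_density_series(cfg, densities=(100, 1000, 5000),
                             density_effect=effects)
    med = tbl.groupby("density")["n_cells"].median()
    assert med[100] < med[1000] < med[5000]


def test_density_saturation_dips_highest_density():
    cfg = SyntheticConfig(seed=91, n_clones=250)
    effects = {1000: 0.15, 5000: 0.2, 10000: 0.25}
    tbl = gen_density_series(
        cfg, densities=(1000, 5000, 10000), density_effect=effects,
        saturation_capacity=12,
    )
    med = tbl.groupby("density")["n_cells"].median()
    assert med[10000] < med[5000]


def test_density_effect_must_cover_all_densities():
    cfg = SyntheticConfig(seed=95, n_clones=50)
    with pytest.raises(ValueError):
        gen_density_series(cfg, densities=(100, 500), density_effect={100: 0.0})
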