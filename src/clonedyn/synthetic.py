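"""Synthetic study-shaped data generation.

Every analysis stage in the package can be exercised without external data.
The generator reproduces the structure of the study system: a minority
(~10%) of clones grow exponentially (g = 0.75/day, k = 0) while the
majority transition to arrest (g = 0.7/day, k = 0.3/day); clone sizes are
observed at discrete fixation days with independent realizations per day
(plates are fixed and discarded, not followed longitudinally); barcode
experiments expand founders through four doublings, split them binomially
into two samples, and convert final cells to sequencing reads with
multiplicative lognormal noise plus a spike-in ladder of known cell
numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from numpy.random import PCG64, Generator, SeedSequence

from .core import TwoStateParams
from .gillespie import simulate_ensemble
from .heritability import (
    BarcodeCountTable,
    SplitExperiment,
    growth_rate_distribution,
    simulate_split_experiment,
)
from .metrics import log2_divisions

__all__ = [
    "SyntheticConfig",
    "gen_clone_size_table",
    "gen_barcode_experiment",
    "gen_density_series",
]


@dataclass
class SyntheticConfig:
    """Configuration of the synthetic study.

    Defaults mirror the study conditions: ~500 clones per condition,
    fixation days 2/5/8/11, a 10% highly proliferative fraction with
    (g=0.75, k=0) against (g=0.7, k=0.3) for the rest, four pre-split
    doublings for the barcode experiment, a 50/500/500/1000-cell spike-in
    ladder (one level duplicated, as in the assay design), and mild
    multiplicative lognormal read noise.
    """

    seed: int
    n_clones: int = 500
    days: tuple = (2.0, 5.0, 8.0, 11.0)
    frac_highly_proliferative: float = 0.10
    hp_params: TwoStateParams = field(
        default_factory=lambda: TwoStateParams(0.75, 0.0)
    )
    lp_params: TwoStateParams = field(
        default_factory=lambda: TwoStateParams(0.7, 0.3)
    )
    # barcode experiment
    n_barcodes: int = 1000
    pre_doublings: int = 4
    heritable: bool = True
    growth_dist: str = "stochastic"
    # sequencing layer
    spikein_levels: tuple = (50, 500, 500, 1000)
    reads_per_cell: float = 20.0
    read_noise_sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.frac_highly_proliferative <= 1.0:
            raise ValueError("frac_highly_proliferative must be in [0, 1]")
        for name in ("n_clones", "n_barcodes", "pre_doublings"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.reads_per_cell <= 0:
            raise ValueError("reads_per_cell must be positive")
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hp_params"] = vars(self.hp_params).copy()
        d["lp_params"] = vars(self.lp_params).copy()
        return d


def _class_seed(seed: int, day_index: int, class_index: int) -> SeedSequence:
    """Substream for one (day, clone-class) block of the clone table."""
    return SeedSequence(entropy=seed, spawn_key=(day_index, class_index))


def gen_clone_size_table(
    config: SyntheticConfig, replicate: int = 1, condition: str = "synthetic"
) -> pd.DataFrame:
    """Multi-day clone-size table in the standard long format.

    Columns: clone_id, replicate, condition, day, n_cells, true_class.
    Clones 0..n_hp-1 are highly proliferative (n_hp = round(frac * n));
    each requested day is an independent realization of every clone's
    growth, as in a fixed-plate design.
    """
    n_hp = int(round(config.frac_highly_proliferative * config.n_clones))
    n_lp = config.n_clones - n_hp
    frames = []
    for di, day in enumerate(config.days):
        sizes = np.empty(config.n_clones, dtype=np.int64)
        if n_hp:
            sizes[:n_hp] = simulate_ensemble(
                config.hp_params, n_hp, day, seed=_class_seed(config.seed, di, 0)
            ).sizes
        if n_lp:
            sizes[n_hp:] = simulate_ensemble(
                config.lp_params, n_lp, day, seed=_class_seed(config.seed, di, 1)
            ).sizes
        frames.append(
            pd.DataFrame(
                {
                    "clone_id": [f"clone{c:05d}" for c in range(config.n_clones)],
                    "replicate": replicate,
                    "condition": condition,
                    "day": float(day),
                    "n_cells": sizes,
                    "true_class": ["hp"] * n_hp + ["lp"] * n_lp,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def gen_barcode_experiment(
    config: SyntheticConfig, reference=None
) -> tuple[BarcodeCountTable, SplitExperiment]:
    """Paired barcode read tables (samples A/B) with spike-ins and ground truth.

    The growth-rate distribution is built from ``reference`` division counts
    (default: the day-8 log2 sizes of the configured clone table, singleton
    clones dropped — the imaging-derived reference the null simulations
    use).  Cells convert to reads via ``reads_per_cell`` with multiplicative
    lognormal noise; the spike-in ladder is appended at the configured cell
    levels.  Returns the read table and the underlying
    :class:`SplitExperiment` (ground-truth cells and growth rates).
    """
    if reference is None:
        table = gen_clone_size_table(config)
        day8 = table[np.isclose(table["day"], 8.0)]["n_cells"].to_numpy()
        if day8.size == 0:  # day 8 not among config.days: use the last day
            last = table["day"].max()
            day8 = table[table["day"] == last]["n_cells"].to_numpy()
        reference = log2_divisions(day8[day8 > 1])
    dist = growth_rate_distribution(config.growth_dist, reference)
    ss = SeedSequence(entropy=config.seed, spawn_key=(101,))
    split_ss, noise_ss = ss.spawn(2)
    exp = simulate_split_experiment(
        config.n_barcodes,
        config.pre_doublings,
        dist,
        heritable=config.heritable,
        seed=split_ss,
    )
    rng = Generator(PCG64(noise_ss))

    def to_reads(cells: np.ndarray) -> np.ndarray:
        noise = (
            rng.lognormal(0.0, config.read_noise_sigma, cells.size)
            if config.read_noise_sigma > 0
            else np.ones(cells.size)
        )
        return np.floor(cells * config.reads_per_cell * noise + 0.5).astype(
            np.int64
        )

    n_spike = len(config.spikein_levels)
    spike_ids = [f"spike{i:02d}" for i in range(n_spike)]
    spike_cells = np.asarray(config.spikein_levels, dtype=float)
    counts = pd.DataFrame(
        {
            "A": np.concatenate(
                [to_reads(exp.counts["A"].to_numpy(float)), to_reads(spike_cells)]
            ),
            "B": np.concatenate(
                [to_reads(exp.counts["B"].to_numpy(float)), to_reads(spike_cells)]
            ),
        },
        index=pd.Index(list(exp.counts.index) + spike_ids, name="barcode"),
    )
    spike_truth = pd.Series(spike_cells, index=pd.Index(spike_ids, name="barcode"))
    return BarcodeCountTable(counts=counts, spikein_true_cells=spike_truth), exp


def _shift_params(params: TwoStateParams, dg: float, capacity=None) -> TwoStateParams:
    return TwoStateParams(
        max(params.g_x + dg, 0.0),
        params.k_y,
        capacity if capacity is not None else params.capacity,
    )


def gen_density_series(
    config: SyntheticConfig,
    densities=(100, 500, 1000, 5000, 10000),
    density_effect: dict | None = None,
    saturation_capacity: float | None = None,
) -> pd.DataFrame:
    """Clone-size tables across plating densities with a density column.

    ``density_effect`` maps each density to an additive shift of the
    division rate g of both clone classes (zero for all densities when
    omitted) — a monotone effect map yields monotone median clone sizes.
    ``saturation_capacity``, when set, imposes a carrying capacity at the
    highest density only, emulating cultures approaching confluency there.
    """
    densities = list(densities)
    if not densities:
        raise ValueError("densities must be nonempty")
    if density_effect is None:
        density_effect = {d: 0.0 for d in densities}
    unknown = [d for d in densities if d not in density_effect]
    if unknown:
        raise ValueError(f"densities missing from density_effect: {unknown}")
    highest = max(densities)
    frames = []
    for d_i, density in enumerate(densities):
        cap = saturation_capacity if (
            saturation_capacity is not None and density == highest
        ) else None
        cfg = SyntheticConfig(
            seed=int(
                SeedSequence(
                    entropy=config.seed, spawn_key=(202, d_i)
                ).generate_state(1)[0] & 0x7FFFFFFF
            ),
            n_clones=config.n_clones,
            days=(8.0,),
            frac_highly_proliferative=config.frac_highly_proliferative,
            hp_params=_shift_params(config.hp_params, density_effect[density], cap),
            lp_params=_shift_params(config.lp_params, density_effect[density], cap),
        )
        tbl = gen_clone_size_table(cfg, condition=f"density_{density}")
        tbl["density"] = density
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)
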