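"""Distribution-matching inference for the two-state model.

The (g_x, k_y) plane is swept on a grid; at each grid point an ensemble of
clones is simulated to the observation day and its clone-size distribution
is compared with the observed one using the two-sample Kolmogorov-Smirnov
test on log2 sizes (the division-count axis; the KS statistic is invariant
under this monotone transform, the conventional axis is kept for
interpretability).  The best-fit parameters are the grid point with the
lowest KS statistic, ties broken by highest p-value, then by smallest k_y,
then smallest g_x — ranges of near-equivalent fits along g - k ridges make
an explicit tie-break necessary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.random import SeedSequence
from scipy.stats import ks_2samp
from sklearn.base import BaseEstimator

from .core import CloneSizeSample, TwoStateParams
from .gillespie import simulate_ensemble

__all__ = ["SweepResult", "ks_compare", "KSParameterSweep", "parameter_sweep"]

DEFAULT_GRID = np.round(np.arange(0.0, 1.0001, 0.05), 10)


def _as_sizes(sample) -> np.ndarray:
    if isinstance(sample, CloneSizeSample):
        return sample.sizes
    arr = np.asarray(sample)
    if arr.size == 0:
        raise ValueError("sample must be nonempty")
    return arr


def ks_compare(sim, obs) -> tuple[float, float]:
    """Two-sample KS test between simulated and observed clone sizes.

    Returns ``(statistic, p_value)``; the statistic is the supremum absolute
    difference of the two empirical CDFs of log2 sizes, the p-value comes
    from the asymptotic two-sample KS distribution.  Symmetric in its
    arguments.
    """
    a = np.log2(_as_sizes(sim).astype(float))
    b = np.log2(_as_sizes(obs).astype(float))
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SweepResult:
    """KS statistic/p-value surfaces over the (g, k) grid and the best fit."""

    g_grid: np.ndarray
    k_grid: np.ndarray
    ks_stat: np.ndarray     # shape (len(g_grid), len(k_grid))
    ks_pvalue: np.ndarray
    best: TwoStateParams
    n_sim_clones: int
    seed: int

    def to_long_frame(self):
        """Heatmap-ready long-format table (g, k, ks_stat, p_value)."""
        import pandas as pd

        gg, kk = np.meshgrid(self.g_grid, self.k_grid, indexing="ij")
        return pd.DataFrame(
            {
                "g": gg.ravel(),
                "k": kk.ravel(),
                "ks_stat": self.ks_stat.ravel(),
                "p_value": self.ks_pvalue.ravel(),
            }
        )


class KSParameterSweep(BaseEstimator):
    """Grid-sweep estimator of the two-state model parameters.

    Fitting simulates ``n_sim_clones`` clones at every (g, k) grid point with
    a per-point RNG substream and scores each simulated clone-size
    distribution against the observed sample with the two-sample KS test.

    Parameters
    ----------
    g_grid, k_grid : array-like, optional
        Rate grids (1/day).  Default 0 to 1 in steps of 0.05.
    n_sim_clones : int, default 500
        Clones simulated per grid point.
    t_obs : float, default 8.0
        Observation day the simulation runs to.
    common_random_numbers : bool, default False
        Reuse one substream for every grid point, which smooths the KS
        surface at the price of correlated cells.
    random_state : int, default 0
        Master seed; grid-point substreams derive from it.

    Attributes
    ----------
    best_params_ : TwoStateParams
        Grid point with the lowest KS statistic (ties: highest p-value,
        then smallest k_y, then smallest g_x).
    g_x_, k_y_ : float
    result_ : SweepResult
    """

    def __init__(
        self,
        g_grid=None,
        k_grid=None,
        n_sim_clones: int = 500,
        t_obs: float = 8.0,
        common_random_numbers: bool = False,
        random_state: int = 0,
    ):
        self.g_grid = g_grid
        self.k_grid = k_grid
        self.n_sim_clones = n_sim_clones
        self.t_obs = t_obs
        self.common_random_numbers = common_random_numbers
        self.random_state = random_state

    def fit(self, X, y=None):
        """Sweep the grid against the observed clone sizes ``X``.

        ``X`` is a 1-D array of clone sizes or a :class:`CloneSizeSample`.
        """
        if isinstance(X, CloneSizeSample):
            if X.day is not None and not np.isclose(X.day, self.t_obs):
                warnings.warn(
                    f"observed sample was taken at day {X.day} but the sweep "
                    f"simulates to day {self.t_obs}",
                    UserWarning,
                    stacklevel=2,
                )
        obs_sizes = _as_sizes(X)
        g_grid = np.asarray(
            DEFAULT_GRID if self.g_grid is None else self.g_grid, dtype=float
        )
        k_grid = np.asarray(
            DEFAULT_GRID if self.k_grid is None else self.k_grid, dtype=float
        )
        if g_grid.size == 0 or k_grid.size == 0:
            raise ValueError("parameter grids must be nonempty")
        if self.n_sim_clones < 50:
            raise ValueError("n_sim_clones must be >= 50")

        n_cells = g_grid.size * k_grid.size
        children = SeedSequence(self.random_state).spawn(n_cells)
        stat = np.empty((g_grid.size, k_grid.size))
        pval = np.empty_like(stat)
        for i, g in enumerate(g_grid):
            for j, k in enumerate(k_grid):
                idx = 0 if self.common_random_numbers else i * k_grid.size + j
                sim = simulate_ensemble(
                    TwoStateParams(g, k), self.n_sim_clones, self.t_obs,
                    seed=children[idx],
                )
                stat[i, j], pval[i, j] = ks_compare(sim.sizes, obs_sizes)

        bi, bj = _select_best(stat, pval, g_grid, k_grid)
        self.best_params_ = TwoStateParams(float(g_grid[bi]), float(k_grid[bj]))
        self.g_x_ = self.best_params_.g_x
        self.k_y_ = self.best_params_.k_y
        self.ks_stat_ = stat
        self.ks_pvalue_ = pval
        self.result_ = SweepResult(
            g_grid=g_grid, k_grid=k_grid, ks_stat=stat, ks_pvalue=pval,
            best=self.best_params_, n_sim_clones=self.n_sim_clones,
            seed=self.random_state,
        )
        return self


def _select_best(stat, pval, g_grid, k_grid) -> tuple[int, int]:
    """argmin KS statistic; ties by max p, then min k, then min g."""
    flat = np.argwhere(np.isclose(stat, stat.min(), rtol=0, atol=0))
    best = None
    for i, j in flat:
        key = (-pval[i, j], k_grid[j], g_grid[i])
        if best is None or key < best[0]:
            best = (key, (i, j))
    return best[1]


def parameter_sweep(
    obs,
    g_grid=None,
    k_grid=None,
    n_sim_clones: int = 500,
    t_obs: float = 8.0,
    seed: int = 0,
    common_random_numbers: bool = False,
) -> SweepResult:
    """Functional wrapper over :class:`KSParameterSweep`."""
    est = KSParameterSweep(
        g_grid=g_grid, k_grid=k_grid, n_sim_clones=n_sim_clones, t_obs=t_obs,
        common_random_numbers=common_random_numbers, random_state=seed,
    )
    est.fit(obs)
    return est.result_
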