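"""Exact stochastic simulation of the two-state clone growth model.

A clone starts from a single proliferative cell.  Two reactions compete,
each with mass-action propensity:

* division      X -> 2X   at rate ``g_x`` per proliferative cell,
* arrest        X -> Y    at rate ``k_y`` per proliferative cell.

Waiting times are exponential with rate equal to the total propensity and
the firing reaction is chosen proportionally to its propensity (Gillespie's
direct method).  With a carrying capacity K the division propensity carries
the logistic factor ``max(0, 1 - (x + y) / K)``.  Arrested cells never
divide, never die and never re-enter the proliferative state, so the total
cell count x + y is non-decreasing.

Two entry points are provided: :func:`simulate_clone` records the full event
trajectory of one clone, while :func:`simulate_ensemble` runs many clones
through a numba-compiled kernel and returns only final sizes, which is what
distribution-matching inference consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from numpy.random import PCG64, Generator, SeedSequence

from .core import CloneSizeSample, TwoStateParams

__all__ = [
    "GillespieTrajectory",
    "propensities",
    "simulate_clone",
    "simulate_ensemble",
]

#: default guard against runaway supercritical simulations
MAX_CELLS_DEFAULT = 1_000_000


@dataclass
class GillespieTrajectory:
    """Event-resolved history of one simulated clone.

    ``times`` (days) start at 0 with one proliferative cell; each subsequent
    entry is a reaction firing that changes (x, y) by one reaction's
    stoichiometry.  ``terminated_reason`` is ``"absorbed"`` when no
    proliferative cells remain and ``"t_max"`` when the time horizon (or the
    hard cell cap) ended the run first.
    """

    times: np.ndarray
    x_counts: np.ndarray
    y_counts: np.ndarray
    seed: int
    terminated_reason: str

    @property
    def final_size(self) -> int:
        return int(self.x_counts[-1] + self.y_counts[-1])


def propensities(
    x: int, params: TwoStateParams, y: int = 0
) -> tuple[float, float]:
    """Reaction propensities (division, transition) at state (x, y).

    Division propensity is ``g_x * x``, scaled by the logistic factor
    ``max(0, 1 - (x + y) / K)`` when a capacity is set; transition
    propensity is ``k_y * x``.
    """
    if x < 0:
        raise ValueError(f"proliferative cell count must be >= 0, got {x}")
    if y < 0:
        raise ValueError(f"arrested cell count must be >= 0, got {y}")
    a_div = params.g_x * x
    if params.capacity is not None:
        a_div *= max(0.0, 1.0 - (x + y) / params.capacity)
    return a_div, params.k_y * x


def simulate_clone(
    params: TwoStateParams,
    t_max: float,
    seed: int,
    max_cells: int = MAX_CELLS_DEFAULT,
) -> GillespieTrajectory:
    """Simulate one clone from a single founding cell, recording every event.

    Identical ``(params, t_max, seed)`` reproduce the identical trajectory.
    """
    if t_max <= 0:
        raise ValueError(f"t_max must be > 0, got {t_max}")
    rng = Generator(PCG64(seed))
    x, y, t = 1, 0, 0.0
    times, xs, ys = [0.0], [1], [0]
    reason = "t_max"
    while True:
        a_div, a_tr = propensities(x, params, y)
        a_tot = a_div + a_tr
        if a_tot <= 0.0:
            reason = "absorbed" if x == 0 else "t_max"
            break
        t += -np.log(rng.random()) / a_tot
        if t > t_max:
            break
        if rng.random() * a_tot < a_div:
            x += 1
        else:
            x -= 1
            y += 1
        times.append(t)
        xs.append(x)
        ys.append(y)
        if x + y >= max_cells:
            warnings.warn(
                f"clone hit the {max_cells}-cell cap at t={t:.3f}; "
                "treating as horizon-terminated",
                RuntimeWarning,
                stacklevel=2,
            )
            break
    return GillespieTrajectory(
        times=np.asarray(times),
        x_counts=np.asarray(xs, dtype=np.int64),
        y_counts=np.asarray(ys, dtype=np.int64),
        seed=seed,
        terminated_reason=reason,
    )


@njit(cache=True)
def _final_state(rng, g, k, cap, t_max, max_cells):  # pragma: no cover
    x = 1
    y = 0
    t = 0.0
    while x > 0:
        a_div = g * x
        if cap > 0.0:
            f = 1.0 - (x + y) / cap
            if f < 0.0:
                f = 0.0
            a_div *= f
        a_tot = a_div + k * x
        if a_tot <= 0.0:
            break
        t += -np.log(rng.random()) / a_tot
        if t > t_max:
            break
        if rng.random() * a_tot < a_div:
            x += 1
            if x + y >= max_cells:
                break
        else:
            x -= 1
            y += 1
    return x, y


def simulate_ensemble(
    params: TwoStateParams,
    n_clones: int,
    t_obs: float,
    seed: int | SeedSequence,
    max_cells: int = MAX_CELLS_DEFAULT,
    label: str = "",
) -> CloneSizeSample:
    """Simulate ``n_clones`` independent clones and return final sizes.

    Each clone runs on its own RNG substream spawned from the master seed,
    so the ensemble is deterministic given ``seed`` and clone i's outcome
    does not depend on how many clones follow it.  Reported sizes are total
    cells x + y; the per-compartment counts are kept on the returned sample
    for callers that need the proliferative/arrested split.
    """
    if n_clones < 1:
        raise ValueError(f"n_clones must be >= 1, got {n_clones}")
    if t_obs <= 0:
        raise ValueError(f"t_obs must be > 0, got {t_obs}")
    cap = float(params.capacity) if params.capacity is not None else 0.0
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    xs = np.empty(n_clones, dtype=np.int64)
    ys = np.empty(n_clones, dtype=np.int64)
    for i, child in enumerate(ss.spawn(n_clones)):
        xs[i], ys[i] = _final_state(
            Generator(PCG64(child)), params.g_x, params.k_y, cap,
            float(t_obs), max_cells,
        )
    return CloneSizeSample(
        sizes=xs + ys, day=t_obs, label=label, x_counts=xs, y_counts=ys
    )
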