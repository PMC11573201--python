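"""Core domain types shared across the package.

The central objects are the parameter vector of the two-state clone growth
model and the empirical clone-size sample that all inference is carried out
against.  In the two-state model every proliferative cell (X) divides at a
per-capita rate ``g_x`` (1/day) or irreversibly enters a non-proliferative
state (Y) at rate ``k_y`` (1/day); an optional carrying capacity ``capacity``
turns the division rate logistic in the total clone size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TwoStateParams", "CloneSizeSample"]


@dataclass(frozen=True)
class TwoStateParams:
    """Rates of the two-state clone growth model.

    Parameters
    ----------
    g_x : float
        Per-capita division rate of proliferative cells, 1/day.
    k_y : float
        Per-capita rate of transition to the non-proliferative state, 1/day.
        The transition is irreversible and death is neglected.
    capacity : float, optional
        Carrying capacity K in cells.  When set, the division propensity is
        scaled by ``max(0, 1 - (x + y) / K)`` so that growth saturates as the
        clone approaches K.  ``None`` selects the pure two-parameter model.
    """

    g_x: float
    k_y: float
    capacity: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.g_x) or self.g_x < 0:
            raise ValueError(f"g_x must be finite and >= 0, got {self.g_x}")
        if not np.isfinite(self.k_y) or self.k_y < 0:
            raise ValueError(f"k_y must be finite and >= 0, got {self.k_y}")
        if self.capacity is not None:
            if not np.isfinite(self.capacity) or self.capacity <= 0:
                raise ValueError(
                    f"capacity must be a positive number, got {self.capacity}"
                )

    @property
    def doubling_time(self) -> float:
        """Doubling time of the net exponential phase, ln 2 / (g_x - k_y), days.

        Infinite when the net growth rate is non-positive.
        """
        net = self.g_x - self.k_y
        return float(np.log(2) / net) if net > 0 else float("inf")


@dataclass
class CloneSizeSample:
    """Clone sizes (total cells per clone) for one condition and day.

    ``sizes`` are positive integers; ``day`` is the observation day and
    ``label`` a free-form condition tag (e.g. ``"highly_proliferative"``).
    """

    sizes: np.ndarray
    day: float | None = None
    label: str = ""
    # proliferative/arrested split when known (simulated data); optional
    x_counts: np.ndarray | None = field(default=None, repr=False)
    y_counts: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        if self.sizes.size == 0:
            raise ValueError("CloneSizeSample requires at least one clone")
        if np.any(self.sizes < 1):
            raise ValueError("clone sizes must all be >= 1 cell")

    def __len__(self) -> int:
        return int(self.sizes.size)

    def log2_sizes(self) -> np.ndarray:
        """Sizes on the division-count (log2) scale."""
        return np.log2(self.sizes.astype(float))
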