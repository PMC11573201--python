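"""Shared clone-level transforms, classifications and calibrations.

Clone sizes are reported as "number of cell divisions" — log2 of the cell
count — and clones consisting of a single cell are filtered from imaging
analyses.  Clones are classified as highly proliferative when they fall in
the top decile by size, either within-sample (exactly the top 10% by rank)
or against a reference sample's threshold (e.g. a control condition).
Spike-in barcodes at known cell numbers (50/500/1000) calibrate sequencing
reads back to cell counts by a least-squares line.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SpikeinCalibration",
    "log2_divisions",
    "classify_proliferative",
    "ProliferativeClassifier",
    "calibrate_spikeins",
    "SpikeinCalibrator",
    "estimate_cells",
    "summarize_by_group",
]

HIGH = "highly_proliferative"
LOW = "less_proliferative"


def log2_divisions(sizes, drop_singletons: bool = False) -> np.ndarray:
    """log2 cell counts ("number of cell divisions") per clone.

    ``drop_singletons=True`` removes one-cell clones before the transform,
    the convention used for the imaging data.
    """
    sizes = np.asarray(sizes, dtype=float).ravel()
    if sizes.size and np.any(sizes < 1):
        raise ValueError("clone sizes must all be >= 1 cell")
    if drop_singletons:
        n_dropped = int(np.sum(sizes == 1))
        if n_dropped:
            warnings.warn(
                f"dropped {n_dropped} single-cell clone(s)",
                UserWarning,
                stacklevel=2,
            )
        sizes = sizes[sizes > 1]
    return np.log2(sizes)


def _nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Classic nearest-rank quantile: the ceil(q*n)-th order statistic."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    rank = max(math.ceil(q * v.size), 1)
    return float(v[rank - 1])


def classify_proliferative(
    sizes,
    quantile: float = 0.9,
    reference=None,
) -> np.ndarray:
    """Label clones highly vs less proliferative by size.

    Without a reference, exactly ``ceil((1 - quantile) * n)`` clones — the
    within-sample top decile by default — are labelled highly proliferative;
    size ties across the boundary are broken by stable input order with a
    warning.  With a reference sample, the threshold is the reference's
    nearest-rank quantile and any number of clones may exceed it.
    """
    sizes = np.asarray(sizes, dtype=float).ravel()
    if sizes.size == 0:
        raise ValueError("cannot classify an empty sample")
    labels = np.full(sizes.size, LOW, dtype=object)
    if reference is not None:
        thr = _nearest_rank_quantile(np.asarray(reference, dtype=float), quantile)
        labels[sizes >= thr] = HIGH
        return labels
    if quantile >= 0.9 and sizes.size < 10:
        raise ValueError(
            f"need >= 10 clones for quantile={quantile} without a reference"
        )
    n_top = math.ceil((1.0 - quantile) * sizes.size)
    order = np.argsort(-sizes, kind="stable")
    top = order[:n_top]
    boundary = sizes[top[-1]]
    if np.sum(sizes == boundary) > np.sum(sizes[top] == boundary):
        warnings.warn(
            f"size ties at the top-decile boundary ({boundary:g} cells) "
            "broken by input order",
            UserWarning,
            stacklevel=2,
        )
    labels[top] = HIGH
    return labels


class ProliferativeClassifier(BaseEstimator):
    """Reference-thresholded proliferative classifier (sklearn-style).

    ``fit`` learns the nearest-rank quantile threshold from a reference
    sample of clone sizes; ``predict`` labels new clones against it.
    """

    def __init__(self, quantile: float = 0.9):
        self.quantile = quantile

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float).ravel()
        if X.size == 0:
            raise ValueError("reference sample is empty")
        self.threshold_ = _nearest_rank_quantile(X, self.quantile)
        return self

    def predict(self, X) -> np.ndarray:
        sizes = np.asarray(X, dtype=float).ravel()
        labels = np.full(sizes.size, LOW, dtype=object)
        labels[sizes >= self.threshold_] = HIGH
        return labels


@dataclass
class SpikeinCalibration:
    """Least-squares line of reads on known spike-in cell numbers."""

    reads_per_cell: float
    intercept: float
    fit_r: float
    n_points: int


def calibrate_spikeins(true_cells, reads) -> SpikeinCalibration:
    """Fit reads = slope * cells + intercept over the spike-in ladder."""
    true_cells = np.asarray(true_cells, dtype=float).ravel()
    reads = np.asarray(reads, dtype=float).ravel()
    if true_cells.shape != reads.shape:
        raise ValueError("true_cells and reads must have equal length")
    if np.unique(true_cells).size < 2:
        raise ValueError(
            "spike-in calibration needs >= 2 distinct cell levels"
        )
    res = stats.linregress(true_cells, reads)
    return SpikeinCalibration(
        reads_per_cell=float(res.slope),
        intercept=float(res.intercept),
        fit_r=float(res.rvalue),
        n_points=int(true_cells.size),
    )


def estimate_cells(
    reads, calibration: SpikeinCalibration, return_qc: bool = False
):
    """Back-calculate cell numbers from reads; negatives floored at 0.

    With ``return_qc=True`` also returns the mask of barcodes whose raw
    back-calculated value was negative.
    """
    reads = np.asarray(reads, dtype=float)
    if calibration.reads_per_cell <= 0:
        raise ValueError("calibration slope must be positive to invert")
    raw = (reads - calibration.intercept) / calibration.reads_per_cell
    cells = np.maximum(raw, 0.0)
    if return_qc:
        return cells, raw < 0
    return cells


class SpikeinCalibrator(BaseEstimator, TransformerMixin):
    """Reads-to-cells transformer calibrated on spike-in barcodes.

    ``fit(X, y)`` takes known spike-in cell numbers ``X`` and their observed
    reads ``y``; ``transform(reads)`` returns estimated cell numbers.
    """

    def fit(self, X, y):
        self.calibration_ = calibrate_spikeins(np.asarray(X).ravel(), y)
        self.reads_per_cell_ = self.calibration_.reads_per_cell
        self.intercept_ = self.calibration_.intercept
        self.fit_r_ = self.calibration_.fit_r
        return self

    def transform(self, X):
        return estimate_cells(np.asarray(X, dtype=float), self.calibration_)


def summarize_by_group(
    records: pd.DataFrame,
    group_keys,
    size_col: str = "n_cells",
    top_quantile: float = 0.9,
) -> pd.DataFrame:
    """Per-group summaries of division counts.

    For each group: clone count, mean and median divisions, unit-division
    histogram (as a dict column ``hist``), and the top-decile size
    threshold.
    """
    group_keys = [group_keys] if isinstance(group_keys, str) else list(group_keys)
    missing = [k for k in group_keys if k not in records.columns]
    if missing:
        raise ValueError(f"unknown group key(s): {missing}")
    if size_col not in records.columns:
        raise ValueError(f"missing size column {size_col!r}")
    rows = []
    for key, grp in records.groupby(group_keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        div = log2_divisions(grp[size_col].to_numpy())
        edges = np.arange(0, math.floor(div.max()) + 2)
        hist, _ = np.histogram(div, bins=edges)
        rows.append(
            dict(zip(group_keys, key))
            | {
                "n_clones": int(len(grp)),
                "mean_divisions": float(div.mean()),
                "median_divisions": float(np.median(div)),
                "top_decile_threshold": _nearest_rank_quantile(
                    grp[size_col].to_numpy(), top_quantile
                ),
                "hist": {int(e): int(c) for e, c in zip(edges[:-1], hist)},
            }
        )
    return pd.DataFrame(rows)
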