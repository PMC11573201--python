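"""Lineage-barcode heritability analysis.

The experimental design this module models: barcoded founder cells expand
through a fixed number of doublings (default four, ~16 copies per barcode),
the copies are split binomially between two samples, and each
barcode-in-sample then grows clonally.  If the growth phenotype is
heritable, the two samples of a barcode grow at the same rate; if not, each
sample redraws its rate independently.  Heritability is read out as (i) the
overlap of the top-decile largest barcodes between the samples and (ii) the
Pearson correlation of per-barcode abundances, both compared against a
simulated non-heritable null in which sibling cells select growth rates at
random from a reference division-count distribution (unimodal Gaussian
moment match, bimodal smoothed-bootstrap KDE, or stochastic uniform
resampling).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import PCG64, Generator, SeedSequence
from scipy import stats

__all__ = [
    "BarcodeCountTable",
    "SplitExperiment",
    "HeritabilityResult",
    "DegenerateSampleError",
    "growth_rate_distribution",
    "top_decile_overlap",
    "abundance_correlation",
    "simulate_split_experiment",
    "null_distribution",
]


class DegenerateSampleError(ValueError):
    """A correlation was requested on a zero-variance sample."""


@dataclass
class BarcodeCountTable:
    """Barcode-by-sample abundance matrix with optional spike-in annotation.

    ``counts`` is a DataFrame indexed by barcode id with one column per
    sample (reads or cells, nonnegative); ``spikein_true_cells`` maps the
    spike-in barcodes to their known cell numbers.
    """

    counts: pd.DataFrame
    spikein_true_cells: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("barcode counts must be nonnegative")
        if self.spikein_true_cells is not None:
            unknown = self.spikein_true_cells.index.difference(self.counts.index)
            if len(unknown):
                raise ValueError(
                    f"spike-in barcodes absent from the table: {list(unknown)[:5]}"
                )

    @property
    def is_spikein(self) -> pd.Series:
        flags = pd.Series(False, index=self.counts.index)
        if self.spikein_true_cells is not None:
            flags.loc[self.spikein_true_cells.index] = True
        return flags

    def sample(self, name: str) -> pd.Series:
        return self.counts[name]

    def without_spikeins(self) -> "BarcodeCountTable":
        keep = ~self.is_spikein
        return BarcodeCountTable(counts=self.counts.loc[keep], spikein_true_cells=None)


# ---------------------------------------------------------------------------
# growth-rate distributions for the null simulations


class _Unimodal:
    """Gaussian with moment-matched mean and standard deviation."""

    kind = "unimodal"

    def __init__(self, reference: np.ndarray):
        self.mu = float(np.mean(reference))
        self.sigma = float(np.std(reference, ddof=1))

    def sample(self, rng: Generator, size: int) -> np.ndarray:
        return rng.normal(self.mu, self.sigma, size)


class _Bimodal:
    """Smoothed bootstrap of the reference sample (Gaussian-KDE bandwidth).

    Draw a reference point uniformly and add Gaussian noise with the
    rule-of-thumb (Scott) KDE bandwidth — the standard sampler for a
    Gaussian kernel density estimate.
    """

    kind = "bimodal"

    def __init__(self, reference: np.ndarray):
        self.reference = np.asarray(reference, dtype=float)
        kde = stats.gaussian_kde(self.reference)
        self.bandwidth = float(kde.factor * np.std(self.reference, ddof=1))

    def sample(self, rng: Generator, size: int) -> np.ndarray:
        picks = rng.choice(self.reference, size=size, replace=True)
        return picks + rng.normal(0.0, self.bandwidth, size)


class _Stochastic:
    """Uniform draw with replacement from the reference values."""

    kind = "stochastic"

    def __init__(self, reference: np.ndarray):
        self.reference = np.asarray(reference, dtype=float)

    def sample(self, rng: Generator, size: int) -> np.ndarray:
        return rng.choice(self.reference, size=size, replace=True)


class _UniformCapped:
    """Uniform growth rates on [0, cap] divisions; the no-reference default."""

    kind = "uniform"

    def __init__(self, cap: float = 5.0):
        self.cap = cap

    def sample(self, rng: Generator, size: int) -> np.ndarray:
        return rng.uniform(0.0, self.cap, size)


GROWTH_DIST_KINDS = ("unimodal", "bimodal", "stochastic")


def growth_rate_distribution(kind: str, reference=None, cap: float = 5.0):
    """Build a growth-rate distribution for the split-experiment simulation.

    ``reference`` is a sample of observed division counts (log2 clone
    sizes).  Without a reference the assay-length default is uniform draws
    on [0, ``cap``] divisions.
    """
    if reference is None:
        return _UniformCapped(cap)
    reference = np.asarray(reference, dtype=float).ravel()
    if reference.size < 2:
        raise ValueError("reference sample needs at least 2 values")
    if kind == "unimodal":
        return _Unimodal(reference)
    if kind == "bimodal":
        if np.ptp(reference) == 0:
            # zero-bandwidth KDE degenerates to resampling the constant
            return _Stochastic(reference)
        return _Bimodal(reference)
    if kind == "stochastic":
        return _Stochastic(reference)
    raise ValueError(f"unknown growth distribution kind {kind!r}; "
                     f"expected one of {GROWTH_DIST_KINDS}")


# ---------------------------------------------------------------------------
# observed-data statistics


def _aligned_abundances(sample_a, sample_b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common-universe abundance vectors plus tie-break ids."""
    if isinstance(sample_a, pd.Series) and isinstance(sample_b, pd.Series):
        if not sample_a.index.equals(sample_b.index):
            if set(sample_a.index) != set(sample_b.index):
                raise ValueError("samples must share the same barcode universe")
            sample_b = sample_b.reindex(sample_a.index)
        ids = sample_a.index.to_numpy()
        return sample_a.to_numpy(float), sample_b.to_numpy(float), ids
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("samples must share the same barcode universe")
    return a, b, np.arange(a.size)


def top_decile_overlap(
    sample_a,
    sample_b,
    top_frac: float = 0.1,
    denominator: str = "per_sample",
) -> float:
    """Share of top-decile barcodes common to both samples.

    Each sample's top decile holds the ``ceil(top_frac * n)`` most abundant
    barcodes (abundance ties broken by barcode id, so the set is
    deterministic).  ``denominator="per_sample"`` divides the intersection
    by the (equal) top-set size, matching Venn-style percentages;
    ``"union"`` divides by ``|A ∪ B|`` instead.
    """
    a, b, ids = _aligned_abundances(sample_a, sample_b)
    n = a.size
    if n < 10:
        raise ValueError(f"need >= 10 barcodes, got {n}")
    n_top = math.ceil(top_frac * n)

    def top_set(v):
        order = np.lexsort((ids, -v))
        return set(ids[order[:n_top]])

    top_a, top_b = top_set(a), top_set(b)
    inter = len(top_a & top_b)
    if denominator == "per_sample":
        return inter / n_top
    if denominator == "union":
        return inter / len(top_a | top_b)
    raise ValueError("denominator must be 'per_sample' or 'union'")


def abundance_correlation(sample_a, sample_b) -> tuple[float, float]:
    """Pearson correlation of per-barcode abundances with a two-sided p-value.

    Raises :class:`DegenerateSampleError` when either sample has zero
    variance (the correlation is undefined there).
    """
    a, b, _ = _aligned_abundances(sample_a, sample_b)
    if a.size < 3:
        raise ValueError("need >= 3 barcodes for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateSampleError("zero variance in one of the samples")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# split-experiment simulation


@dataclass
class SplitExperiment:
    """Simulated expansion/split/growth experiment.

    ``counts`` are final cells per barcode in samples A and B;
    ``initial_copies`` the binomial split of the pre-expansion copies; and
    ``growth_rates`` the per-barcode division counts drawn for each sample
    (identical columns when the experiment is heritable).
    """

    counts: pd.DataFrame           # columns A, B
    initial_copies: pd.DataFrame   # columns A, B
    growth_rates: pd.DataFrame     # columns A, B
    heritable: bool
    pre_doublings: int
    seed: int | None = None

    @property
    def sample_a(self) -> pd.Series:
        return self.counts["A"]

    @property
    def sample_b(self) -> pd.Series:
        return self.counts["B"]


def simulate_split_experiment(
    n_barcodes: int,
    pre_doublings: int = 4,
    growth_dist=None,
    heritable: bool = False,
    seed: int | SeedSequence = 0,
    exact_split: bool = False,
) -> SplitExperiment:
    """Simulate the barcode expansion/split/growth experiment.

    Every barcode starts as one cell and expands deterministically to
    ``2 ** pre_doublings`` copies; the copies are split Binomial(copies,
    0.5) between samples A and B (or exactly in half with
    ``exact_split=True``, the noise-free variant).  Each barcode-in-sample
    then grows to ``round(initial * 2 ** r)`` cells with the division count
    r drawn from ``growth_dist`` — once per barcode when ``heritable``,
    independently per sample otherwise.  Deterministic given ``seed``.
    """
    if n_barcodes < 10:
        raise ValueError(f"n_barcodes must be >= 10, got {n_barcodes}")
    if pre_doublings < 1:
        raise ValueError("pre_doublings must be >= 1")
    if growth_dist is None:
        growth_dist = _UniformCapped()
    if not hasattr(growth_dist, "sample"):
        raise TypeError(
            "growth_dist must expose .sample(rng, size); build one with "
            "growth_rate_distribution()"
        )
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    rng = Generator(PCG64(ss))
    copies = 2 ** pre_doublings
    if exact_split:
        a_init = np.full(n_barcodes, copies // 2, dtype=np.int64)
    else:
        a_init = rng.binomial(copies, 0.5, n_barcodes)
    b_init = copies - a_init
    r_a = growth_dist.sample(rng, n_barcodes)
    r_b = r_a if heritable else growth_dist.sample(rng, n_barcodes)
    # round half-up; fractional cells are not meaningful
    final_a = np.floor(a_init * np.exp2(r_a) + 0.5).astype(np.int64)
    final_b = np.floor(b_init * np.exp2(r_b) + 0.5).astype(np.int64)
    index = pd.Index(
        [f"bc{i:06d}" for i in range(n_barcodes)], name="barcode"
    )
    return SplitExperiment(
        counts=pd.DataFrame({"A": final_a, "B": final_b}, index=index),
        initial_copies=pd.DataFrame({"A": a_init, "B": b_init}, index=index),
        growth_rates=pd.DataFrame({"A": r_a, "B": r_b}, index=index),
        heritable=heritable,
        pre_doublings=pre_doublings,
        seed=None if isinstance(seed, SeedSequence) else int(seed),
    )


# ---------------------------------------------------------------------------
# non-heritable null


@dataclass
class HeritabilityResult:
    """Observed heritability statistics against a non-heritable null."""

    overlap_fraction: float
    pearson_r: float
    pearson_p: float
    null_r: np.ndarray
    null_overlap: np.ndarray
    empirical_p: float
    empirical_p_overlap: float
    growth_dist_kind: str = ""
    n_dropped: int = 0
    observed_available: bool = True
    summary: dict = field(default_factory=dict)


def null_distribution(
    reference,
    growth_dist_kind: str = "stochastic",
    n_replicates: int = 1000,
    seed: int = 0,
    n_barcodes: int = 1000,
    pre_doublings: int = 4,
    observed: tuple | None = None,
    exact_split: bool = False,
) -> HeritabilityResult:
    """Distribution of r and top-decile overlap under the non-heritable null.

    ``reference`` is a division-count sample (observed day-8 log2 clone
    sizes or a synthetic stand-in) that defines the growth-rate
    distribution via ``growth_dist_kind`` (unimodal / bimodal / stochastic).
    Each replicate simulates a fresh non-heritable split experiment and
    records the Pearson correlation and top-decile overlap between the two
    samples; replicates with undefined (zero-variance) correlation are
    dropped and counted.  When the observed pair of samples is supplied,
    empirical p-values use the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_valid)``.
    """
    if n_replicates < 100:
        warnings.warn(
            f"n_replicates={n_replicates} < 100 gives unstable empirical "
            "p-values",
            UserWarning,
            stacklevel=2,
        )
    dist = growth_rate_distribution(growth_dist_kind, reference)
    children = SeedSequence(seed).spawn(n_replicates)
    null_r, null_overlap = [], []
    n_dropped = 0
    for child in children:
        exp = simulate_split_experiment(
            n_barcodes, pre_doublings, dist, heritable=False, seed=child,
            exact_split=exact_split,
        )
        try:
            r, _ = abundance_correlation(exp.sample_a, exp.sample_b)
        except DegenerateSampleError:
            n_dropped += 1
            continue
        null_r.append(r)
        null_overlap.append(top_decile_overlap(exp.sample_a, exp.sample_b))
    null_r = np.asarray(null_r)
    null_overlap = np.asarray(null_overlap)
    n_valid = null_r.size

    if observed is not None:
        obs_a, obs_b = observed
        obs_r, obs_p = abundance_correlation(obs_a, obs_b)
        obs_overlap = top_decile_overlap(obs_a, obs_b)
        emp_r = (1 + int(np.sum(null_r >= obs_r))) / (1 + n_valid)
        emp_ov = (1 + int(np.sum(null_overlap >= obs_overlap))) / (1 + n_valid)
        available = True
    else:
        obs_r = obs_p = obs_overlap = float("nan")
        emp_r = emp_ov = float("nan")
        available = False

    return HeritabilityResult(
        overlap_fraction=obs_overlap,
        pearson_r=obs_r,
        pearson_p=obs_p,
        null_r=null_r,
        null_overlap=null_overlap,
        empirical_p=emp_r,
        empirical_p_overlap=emp_ov,
        growth_dist_kind=getattr(dist, "kind", growth_dist_kind),
        n_dropped=n_dropped,
        observed_available=available,
        summary={
            "null_r_mean": float(null_r.mean()) if n_valid else float("nan"),
            "null_r_sd": float(null_r.std(ddof=1)) if n_valid > 1 else float("nan"),
            "null_overlap_mean": (
                float(null_overlap.mean()) if n_valid else float("nan")
            ),
            "null_r_q99": (
                float(np.quantile(null_r, 0.99)) if n_valid else float("nan")
            ),
            "n_valid": int(n_valid),
        },
    )
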