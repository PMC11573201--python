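"""Modality analysis of clone-division distributions.

Two complementary tools quantify whether a distribution of division counts
(log2 clone sizes) is uni- or bimodal:

* Sarle's bimodality coefficient, computed from bias-corrected sample
  skewness s and excess kurtosis k_e with the finite-sample correction::

      b = (s^2 + 1) / (k_e + 3 (n-1)^2 / ((n-2)(n-3)))

  Values above 5/9 (the asymptotic value for a uniform distribution)
  suggest bimodality, values below 1/3 (the Gaussian value) suggest
  unimodality, and anything between is called ambiguous.

* A Gaussian mixture model fitted by expectation-maximisation with the
  number of components chosen by the Bayesian Information Criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

__all__ = [
    "ModalityCall",
    "GmmFit",
    "bimodality_coefficient",
    "GmmModalityModel",
    "fit_gmm",
]

BIMODAL_THRESHOLD = 5.0 / 9.0
UNIMODAL_THRESHOLD = 1.0 / 3.0


@dataclass(frozen=True)
class ModalityCall:
    coefficient: float
    call: str  # "bimodal" | "ambiguous" | "unimodal"


def bimodality_coefficient(data) -> ModalityCall:
    """Sarle's bimodality coefficient with the finite-sample correction.

    Requires n >= 4 and nonzero variance.  The coefficient is invariant
    under affine transforms of the data and lies in (0, 1].
    """
    x = np.asarray(data, dtype=float).ravel()
    n = x.size
    if n < 4:
        raise ValueError(f"bimodality coefficient needs n >= 4, got n={n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")
    if np.ptp(x) == 0:
        raise ValueError("bimodality coefficient undefined for zero variance")
    s = stats.skew(x, bias=False)
    k_e = stats.kurtosis(x, fisher=True, bias=False)
    denom = k_e + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    coef = float((s * s + 1.0) / denom)
    if coef > BIMODAL_THRESHOLD:
        call = "bimodal"
    elif coef < UNIMODAL_THRESHOLD:
        call = "unimodal"
    else:
        call = "ambiguous"
    return ModalityCall(coefficient=coef, call=call)


@dataclass
class GmmFit:
    """BIC-selected Gaussian mixture fit of a 1-D division-count sample."""

    n_components: int
    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    bic_by_k: dict[int, float] = field(default_factory=dict)
    seed: int = 0


class GmmModalityModel(BaseEstimator):
    """Gaussian mixture with BIC model selection over component counts.

    EM runs until the log-likelihood gain falls below 1e-6 or 500
    iterations, with 5 seeded k-means restarts per candidate; candidates
    with fewer than ``2 * k`` observations are skipped with a warning.

    Attributes (after ``fit``): ``n_components_``, ``means_``,
    ``variances_``, ``weights_``, ``bic_by_k_``, ``fit_``.
    """

    def __init__(
        self,
        candidate_components=(1, 2, 3),
        n_init: int = 5,
        random_state: int = 0,
    ):
        self.candidate_components = candidate_components
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        n = x.shape[0]
        if n < 10:
            raise ValueError(f"GMM modality fit needs >= 10 observations, got {n}")
        candidates = sorted(set(int(k) for k in self.candidate_components))
        if not candidates or candidates[0] < 1:
            raise ValueError("candidate_components must be positive integers")
        bic_by_k: dict[int, float] = {}
        models: dict[int, GaussianMixture] = {}
        for k in candidates:
            if n < 2 * k:
                warnings.warn(
                    f"skipping k={k}: needs >= {2 * k} observations, have {n}",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            gm = GaussianMixture(
                n_components=k, covariance_type="full", tol=1e-6,
                max_iter=500, n_init=self.n_init,
                random_state=self.random_state,
            ).fit(x)
            bic_by_k[k] = float(gm.bic(x))
            models[k] = gm
        if not bic_by_k:
            raise ValueError("no candidate component count was fittable")
        best_k = min(bic_by_k, key=bic_by_k.get)
        gm = models[best_k]
        order = np.argsort(gm.means_.ravel())
        self.n_components_ = best_k
        self.means_ = gm.means_.ravel()[order]
        self.variances_ = gm.covariances_.reshape(best_k)[order]
        self.weights_ = gm.weights_[order]
        self.bic_by_k_ = bic_by_k
        self.fit_ = GmmFit(
            n_components=best_k, means=self.means_, variances=self.variances_,
            weights=self.weights_, bic_by_k=bic_by_k, seed=self.random_state,
        )
        return self


def fit_gmm(data, candidate_components=(1, 2, 3), seed: int = 0) -> GmmFit:
    """Functional wrapper over :class:`GmmModalityModel`."""
    est = GmmModalityModel(
        candidate_components=candidate_components, random_state=seed
    )
    est.fit(np.asarray(data))
    return est.fit_
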