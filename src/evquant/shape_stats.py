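"""Distribution-shape statistics for edge-distance samples.

Two complementary diagnostics of bimodality:

* Sarle's bimodality coefficient, BC = (g₁² + 1) / (g₂ + 3(n−1)²/((n−2)(n−3))),
  with bias-corrected sample skewness g₁ and excess kurtosis g₂. BC is 5/9 ≈
  0.5556 for the continuous uniform distribution, which serves as the
  conventional decision threshold (0.555): larger values indicate bimodality.
* 1- vs 2-component Gaussian mixture selection by BIC, with
  ΔBIC = BIC(2) − BIC(1); negative ΔBIC favors two components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "BimodalityResult",
    "MixtureFit",
    "MixtureSelectResult",
    "BC_THRESHOLD",
    "bimodality_coefficient",
    "fit_gaussian_mixture_1d",
    "select_mixture_model",
]

#: uniform-distribution benchmark 5/9, printed to three decimals
BC_THRESHOLD: float = 0.555


@dataclass
class BimodalityResult:
    n: int
    skewness: float
    excess_kurtosis: float
    bc: float
    threshold: float
    is_bimodal: bool


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool


@dataclass
class MixtureSelectResult:
    loglik_1: float
    loglik_2: float
    bic_1: float
    bic_2: float
    delta_bic: float
    selected_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray


def bimodality_coefficient(values, threshold: float = BC_THRESHOLD) -> BimodalityResult:
    """Sarle's sample bimodality coefficient with finite-sample correction."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InputError("values must be a 1-D vector")
    n = len(x)
    if n < 4:
        raise UndefinedStatisticError("bimodality coefficient requires n >= 4")
    if np.std(x) == 0:
        raise UndefinedStatisticError("bimodality coefficient undefined at zero variance")
    g1 = float(stats.skew(x, bias=False))
    g2 = float(stats.kurtosis(x, fisher=True, bias=False))
    bc = (g1 * g1 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    return BimodalityResult(
        n=n,
        skewness=g1,
        excess_kurtosis=g2,
        bc=float(bc),
        threshold=threshold,
        is_bimodal=bool(bc > threshold),
    )


def _quantile_split_init(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(lo) == 0 or len(hi) == 0:  # degenerate split on heavy ties
        lo, hi = x, x
    w = np.array([len(lo), len(hi)], dtype=float)
    w /= w.sum()
    means = np.array([[lo.mean()], [hi.mean()]])
    sd = max(float(x.std()), np.finfo(float).tiny)
    precisions = np.full((2, 1, 1), 1.0 / sd**2)
    return w, means, precisions


def fit_gaussian_mixture_1d(
    values,
    k: int,
    n_restarts: int = 10,
    tolerance: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of a 1-D Gaussian mixture, best of several initializations.

    One fit starts from a median-split initialization (k = 2); ``n_restarts``
    further fits use random initializations. The best log-likelihood wins.
    Component variances are regularized by (tolerance·sample sd)² to prevent
    collapse onto single points. Deterministic given ``seed``.
    """
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if k not in (1, 2):
        raise InputError("k must be 1 or 2")
    n = len(x)
    if n < 10 * k:
        raise UndefinedStatisticError(f"mixture fit with k={k} requires n >= {10 * k}")
    if not np.all(np.isfinite(x)):
        raise InputError("values must be finite")
    sd = float(x.std())
    reg = max((tolerance * sd) ** 2, 1e-12)
    common = dict(
        n_components=k,
        covariance_type="full",
        tol=tolerance,
        max_iter=max_iter,
        reg_covar=reg,
    )
    fits: list[GaussianMixture] = []
    if k == 2:
        w, means, precisions = _quantile_split_init(x)
        gm = GaussianMixture(
            **common,
            weights_init=w,
            means_init=means,
            precisions_init=precisions,
            random_state=seed,
        )
        fits.append(gm.fit(x))
    gm = GaussianMixture(
        **common,
        n_init=max(1, n_restarts),
        init_params="random_from_data",
        random_state=seed,
    )
    fits.append(gm.fit(x))
    best = max(fits, key=lambda g: g.score(x))
    if not best.converged_:
        warnings.warn(
            f"Gaussian mixture (k={k}) did not converge in {max_iter} EM "
            "iterations; reporting best-so-far parameters",
            RuntimeWarning,
            stacklevel=2,
        )
    order = np.argsort(best.means_.ravel())
    return MixtureFit(
        k=k,
        weights=best.weights_.ravel()[order],
        means=best.means_.ravel()[order],
        sds=np.sqrt(best.covariances_.reshape(k)[order]),
        loglik=float(best.score(x) * n),
        converged=bool(best.converged_),
    )


def select_mixture_model(
    values, seed: int = 0, n_restarts: int = 10
) -> MixtureSelectResult:
    """Choose between 1 and 2 Gaussian components by BIC.

    BIC_k = −2·loglik + p_k·ln n with p₁ = 2 and p₂ = 5 free parameters;
    two components are selected exactly when ΔBIC = BIC₂ − BIC₁ < 0.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 20:
        raise UndefinedStatisticError("model selection requires n >= 20")
    f1 = fit_gaussian_mixture_1d(x, k=1, n_restarts=n_restarts, seed=seed)
    f2 = fit_gaussian_mixture_1d(x, k=2, n_restarts=n_restarts, seed=seed)
    bic1 = -2.0 * f1.loglik + 2.0 * np.log(n)
    bic2 = -2.0 * f2.loglik + 5.0 * np.log(n)
    delta = bic2 - bic1
    return MixtureSelectResult(
        loglik_1=f1.loglik,
        loglik_2=f2.loglik,
        bic_1=float(bic1),
        bic_2=float(bic2),
        delta_bic=float(delta),
        selected_components=2 if delta < 0 else 1,
        weights=f2.weights,
        means=f2.means,
        sds=f2.sds,
    )
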