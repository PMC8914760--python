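"""Exponential-kernel Gaussian process regression.

The estimator at the heart of the pipeline: a zero-mean GP prior over the
standardized feature space with covariance

    k(xi, xj) = sigma_f^2 * exp(-||xi - xj||^2 / sigma_l)

(the squared inter-point distance divided by a single characteristic
length scale; a ``distance="euclidean"`` switch provides the conventional
exponential kernel exp(-||xi - xj|| / sigma_l), and ``ard=True`` a
per-feature length-scale variant behind the same interface). Observations
carry i.i.d. Gaussian noise with variance sigma_n^2, so the marginal of
the targets is N(0, K + sigma_n^2 I); the predictive mean and variance at
a query x* are

    mean = k(X, x*)^T (K + sigma_n^2 I)^{-1} y
    var  = k(x*, x*) - k(X, x*)^T (K + sigma_n^2 I)^{-1} k(X, x*).

Hyperparameters (theta1 = log sigma_l, theta2 = log sigma_f, log
sigma_n^2) are fitted by maximising the log marginal likelihood with a
multi-start bounded L-BFGS-B search using analytic gradients. Features
and targets are z-scored on the training split; predictions are returned
de-standardized in mmHg.

All linear algebra goes through a Cholesky factorisation with an
escalating jitter (from 1e-10·trace(K)/n up to 1e-4·trace(K)/n) so the
factorisation is robust to near-duplicate rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as _linalg
from scipy import optimize as _optimize

from .errors import FitFailureError, InvalidConfigError, SingularKernelError

__all__ = [
    "KernelParams",
    "TrainingSet",
    "Standardizer",
    "FitOptions",
    "GPRModel",
    "kernel_eval",
    "kernel_matrix",
    "log_marginal_likelihood",
    "fit_gpr",
    "predict",
    "augment",
]

FORMAT_VERSION = 1
_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class KernelParams:
    """Kernel and noise hyperparameters.

    ``sigma_f`` is the signal standard deviation, ``sigma_l`` the
    characteristic length scale, ``sigma_n2`` the observation-noise
    variance. ``length_scales`` (ARD mode) replaces the single
    ``sigma_l`` with one scale per feature.
    """

    sigma_f: float
    sigma_l: float
    sigma_n2: float
    distance: str = "squared"
    length_scales: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.sigma_f <= 0 or self.sigma_l <= 0:
            raise InvalidConfigError("sigma_f and sigma_l must be > 0")
        if self.sigma_n2 < 0:
            raise InvalidConfigError("sigma_n2 must be >= 0")
        if self.distance not in ("squared", "euclidean"):
            raise InvalidConfigError(f"unknown kernel distance {self.distance!r}")
        if self.length_scales is not None:
            object.__setattr__(
                self, "length_scales", np.asarray(self.length_scales, dtype=float)
            )
            if np.any(self.length_scales <= 0):
                raise InvalidConfigError("ARD length scales must be > 0")

    @property
    def theta1(self) -> float:
        """log sigma_l (unconstrained parametrisation)."""
        return float(np.log(self.sigma_l))

    @property
    def theta2(self) -> float:
        """log sigma_f."""
        return float(np.log(self.sigma_f))


@dataclass(frozen=True)
class TrainingSet:
    """Feature matrix and BP targets (standardized or raw)."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        y = np.asarray(self.y, dtype=float).ravel()
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.shape[0] != y.shape[0]:
            raise InvalidConfigError("X and y row counts differ")
        if X.shape[0] < 2:
            raise InvalidConfigError("training requires n >= 2")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise InvalidConfigError("training data must be finite")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class Standardizer:
    """Per-feature and target z-scoring computed on the training split."""

    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray) -> "Standardizer":
        x_mean = X.mean(axis=0)
        x_scale = X.std(axis=0)
        x_scale = np.where(x_scale > 0, x_scale, 1.0)  # constant columns pass through
        y_scale = float(y.std())
        return cls(x_mean, x_scale, float(y.mean()), y_scale if y_scale > 0 else 1.0)

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) / self.x_scale

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_scale


@dataclass(frozen=True)
class FitOptions:
    """Hyperparameter-search settings (deterministic for a fixed seed)."""

    n_restarts: int = 5
    seed: int = 0
    scale_bounds: tuple[float, float] = (-5.0, 5.0)
    noise_bounds: tuple[float, float] = (-10.0, 5.0)
    distance: str = "squared"
    ard: bool = False
    maxiter: int = 200


@dataclass
class GPRModel:
    """A fitted GP: standardized training data, hyperparameters, cached solve."""

    training: TrainingSet
    params: KernelParams
    standardizer: Standardizer
    alpha: np.ndarray = field(repr=False, default=None)
    chol: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.alpha is None or self.chol is None:
            K = kernel_matrix(self.training.X, self.training.X, self.params)
            L = _chol_with_jitter(K + self.params.sigma_n2 * np.eye(self.training.n))
            self.chol = L
            self.alpha = _linalg.cho_solve((L, True), self.training.y)


def _pairwise_sq(X: np.ndarray, Z: np.ndarray, scales: Optional[np.ndarray]) -> np.ndarray:
    Xs, Zs = (X, Z) if scales is None else (X / np.sqrt(scales), Z / np.sqrt(scales))
    d2 = (
        np.sum(Xs**2, axis=1)[:, None]
        + np.sum(Zs**2, axis=1)[None, :]
        - 2.0 * Xs @ Zs.T
    )
    return np.maximum(d2, 0.0)


def kernel_matrix(X: np.ndarray, Z: np.ndarray, params: KernelParams) -> np.ndarray:
    """Covariance matrix k(X, Z) under ``params``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if params.length_scales is not None:
        d2 = _pairwise_sq(X, Z, params.length_scales)
        expo = -d2 if params.distance == "squared" else -np.sqrt(d2)
    else:
        d2 = _pairwise_sq(X, Z, None)
        expo = -d2 / params.sigma_l if params.distance == "squared" else -np.sqrt(d2) / params.sigma_l
    return params.sigma_f**2 * np.exp(expo)


def kernel_eval(xi: Sequence[float], xj: Sequence[float], params: KernelParams) -> float:
    """Covariance between two feature vectors.

    Symmetric in its arguments, equal to sigma_f^2 at xi == xj and bounded
    above by sigma_f^2 everywhere.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape:
        raise InvalidConfigError("kernel arguments must share a length")
    if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(xj))):
        raise InvalidConfigError("kernel arguments must be finite")
    return float(kernel_matrix(xi[None, :], xj[None, :], params)[0, 0])


def _chol_with_jitter(A: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, escalating jitter 1e-10..1e-4 of mean diag."""
    base = float(np.trace(A)) / A.shape[0]
    jitter = 0.0
    for level in [0.0, 1e-10, 1e-9, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4]:
        try:
            return _linalg.cholesky(A + level * base * np.eye(A.shape[0]), lower=True)
        except _linalg.LinAlgError:
            jitter = level
            continue
    raise SingularKernelError(f"factorisation failed at max jitter {jitter:g}")


def log_marginal_likelihood(training: TrainingSet, params: KernelParams) -> float:
    """Zero-mean GP log marginal likelihood of the training targets."""
    K = kernel_matrix(training.X, training.X, params)
    L = _chol_with_jitter(K + params.sigma_n2 * np.eye(training.n))
    alpha = _linalg.cho_solve((L, True), training.y)
    return float(
        -0.5 * training.y @ alpha
        - np.sum(np.log(np.diag(L)))
        - 0.5 * training.n * _LOG2PI
    )


def _lml_and_grad(t: np.ndarray, d2: np.ndarray, y: np.ndarray, distance: str):
    """Objective and analytic gradient over t = (theta1, theta2, log sigma_n2)."""
    theta1, theta2, s = t
    sigma_l = np.exp(theta1)
    sigma_f2 = np.exp(2.0 * theta2)
    sigma_n2 = np.exp(s)
    n = y.shape[0]
    if distance == "squared":
        scaled = d2 / sigma_l
    else:
        scaled = np.sqrt(d2) / sigma_l
    K = sigma_f2 * np.exp(-scaled)
    try:
        L = _chol_with_jitter(K + sigma_n2 * np.eye(n))
    except SingularKernelError:
        return np.inf, np.zeros(3)
    alpha = _linalg.cho_solve((L, True), y)
    lml = -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * n * _LOG2PI
    Kinv = _linalg.cho_solve((L, True), np.eye(n))
    M = np.outer(alpha, alpha) - Kinv  # d lml / dK = M / 2
    dK_dt1 = K * scaled  # d/dtheta1 of exp(-scaled): scaled falls as sigma_l grows
    g1 = 0.5 * np.sum(M * dK_dt1)
    g2 = np.sum(M * K)  # dK/dtheta2 = 2K, halved by the 1/2 in the trace form
    g3 = 0.5 * sigma_n2 * (alpha @ alpha - np.trace(Kinv))
    return -lml, -np.array([g1, g2, g3])


def fit_gpr(training: TrainingSet, options: FitOptions = FitOptions()) -> GPRModel:
    """Standardize, maximise the marginal likelihood, and cache the solve.

    Multi-start bounded quasi-Newton search: the first start is a
    heuristic (length scale at the median inter-point distance, unit
    signal variance, 10% noise); the remaining ``n_restarts - 1`` starts
    are drawn uniformly inside the bounds from a seeded generator, so the
    fit is deterministic given the options.
    """
    std = Standardizer.fit(training.X, training.y)
    Xs = std.transform_x(training.X)
    ys = std.transform_y(training.y)
    if options.ard:
        return _fit_ard(training, Xs, ys, std, options)
    d2 = _pairwise_sq(Xs, Xs, None)
    off = d2[~np.eye(d2.shape[0], dtype=bool)]
    med = float(np.median(off[off > 0])) if np.any(off > 0) else 1.0
    med_stat = med if options.distance == "squared" else float(np.sqrt(med))
    lo, hi = options.scale_bounds
    nlo, nhi = options.noise_bounds
    first = np.array(
        [
            float(np.clip(np.log(med_stat), lo, hi)),
            0.0,
            float(np.clip(np.log(0.1), nlo, nhi)),
        ]
    )
    rng = np.random.default_rng(options.seed)
    starts = [first] + [
        np.array(
            [rng.uniform(lo, hi), rng.uniform(lo, hi), rng.uniform(max(nlo, -6.0), 1.0)]
        )
        for _ in range(max(options.n_restarts - 1, 0))
    ]
    bounds = [(lo, hi), (lo, hi), (nlo, nhi)]
    best = None
    failures = []
    for t0 in starts:
        try:
            res = _optimize.minimize(
                _lml_and_grad,
                t0,
                args=(d2, ys, options.distance),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": options.maxiter},
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append(str(exc))
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError(f"all hyperparameter starts failed: {failures}")
    theta1, theta2, s = best.x
    params = KernelParams(
        sigma_f=float(np.exp(theta2)),
        sigma_l=float(np.exp(theta1)),
        sigma_n2=float(np.exp(s)),
        distance=options.distance,
    )
    return GPRModel(training=TrainingSet(Xs, ys), params=params, standardizer=std)


def _fit_ard(training, Xs, ys, std, options: FitOptions) -> GPRModel:
    """ARD variant: one log length-scale per feature plus signal/noise."""
    n, d = Xs.shape
    diffs2 = (Xs[:, None, :] - Xs[None, :, :]) ** 2  # (n, n, d)
    lo, hi = options.scale_bounds
    nlo, nhi = options.noise_bounds

    def obj(t):
        ell = np.exp(t[:d])
        sigma_f2 = np.exp(2.0 * t[d])
        sigma_n2 = np.exp(t[d + 1])
        scaled = np.tensordot(diffs2, 1.0 / ell, axes=(2, 0))
        if options.distance == "euclidean":
            scaled = np.sqrt(np.maximum(scaled, 0.0))
        K = sigma_f2 * np.exp(-scaled)
        try:
            L = _chol_with_jitter(K + sigma_n2 * np.eye(n))
        except SingularKernelError:
            return np.inf
        alpha = _linalg.cho_solve((L, True), ys)
        return float(
            0.5 * ys @ alpha + np.sum(np.log(np.diag(L))) + 0.5 * n * _LOG2PI
        )

    rng = np.random.default_rng(options.seed)
    starts = [np.concatenate([np.zeros(d), [0.0, np.log(0.1)]])]
    for _ in range(max(options.n_restarts - 1, 0)):
        starts.append(
            np.concatenate(
                [rng.uniform(lo, hi, size=d), [rng.uniform(lo, hi), rng.uniform(-6.0, 1.0)]]
            )
        )
    bounds = [(lo, hi)] * d + [(lo, hi), (nlo, nhi)]
    best = None
    for t0 in starts:
        res = _optimize.minimize(
            obj, t0, method="L-BFGS-B", bounds=bounds, options={"maxiter": options.maxiter}
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise FitFailureError("all ARD starts failed")
    t = best.x
    params = KernelParams(
        sigma_f=float(np.exp(t[d])),
        sigma_l=1.0,
        sigma_n2=float(np.exp(t[d + 1])),
        distance=options.distance,
        length_scales=np.exp(t[:d]),
    )
    return GPRModel(training=TrainingSet(Xs, ys), params=params, standardizer=std)


def predict(model: GPRModel, x_query: Sequence[float]) -> tuple[float, float]:
    """Predictive mean (mmHg) and variance (mmHg^2) at one query vector.

    The query is given in raw feature units; it is standardized with the
    model's frozen standardizer. The standardized predictive variance is
    clipped into [0, sigma_f^2] before de-standardization.
    """
    x = np.asarray(x_query, dtype=float).ravel()
    if x.shape[0] != model.training.X.shape[1]:
        raise InvalidConfigError(
            f"query length {x.shape[0]} != feature dimension {model.training.X.shape[1]}"
        )
    xs = model.standardizer.transform_x(x[None, :])
    kq = kernel_matrix(model.training.X, xs, model.params).ravel()
    mean_s = float(kq @ model.alpha)
    v = _linalg.solve_triangular(model.chol, kq, lower=True)
    var_s = float(model.params.sigma_f**2 - v @ v)
    var_s = float(np.clip(var_s, 0.0, model.params.sigma_f**2))
    std = model.standardizer
    return std.y_mean + std.y_scale * mean_s, std.y_scale**2 * var_s


def predict_batch(model: GPRModel, X_query: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`predict` over rows of ``X_query``."""
    Xq = np.atleast_2d(np.asarray(X_query, dtype=float))
    xs = model.standardizer.transform_x(Xq)
    Kq = kernel_matrix(model.training.X, xs, model.params)
    mean_s = Kq.T @ model.alpha
    V = _linalg.solve_triangular(model.chol, Kq, lower=True)
    var_s = np.clip(model.params.sigma_f**2 - np.sum(V**2, axis=0), 0.0, model.params.sigma_f**2)
    std = model.standardizer
    return std.y_mean + std.y_scale * mean_s, std.y_scale**2 * var_s


def augment(model: GPRModel, X_new: np.ndarray, y_new: np.ndarray) -> GPRModel:
    """New model with extra (raw-unit) pairs appended, hyperparameters frozen.

    The frozen standardizer transforms the new rows; the Cholesky factor
    and alpha are recomputed on the enlarged training set. With zero rows
    the model is returned unchanged.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    y_new = np.asarray(y_new, dtype=float).ravel()
    if X_new.size == 0 or y_new.size == 0:
        return model
    std = model.standardizer
    Xs = np.vstack([model.training.X, std.transform_x(X_new)])
    ys = np.concatenate([model.training.y, std.transform_y(y_new)])
    return GPRModel(training=TrainingSet(Xs, ys), params=model.params, standardizer=std)


def model_to_dict(model: GPRModel) -> dict:
    """JSON-serialisable representation (portable, diffable)."""
    return {
        "format_version": FORMAT_VERSION,
        "params": {
            "sigma_f": model.params.sigma_f,
            "sigma_l": model.params.sigma_l,
            "sigma_n2": model.params.sigma_n2,
            "distance": model.params.distance,
            "length_scales": (
                None
                if model.params.length_scales is None
                else model.params.length_scales.tolist()
            ),
        },
        "standardizer": {
            "x_mean": model.standardizer.x_mean.tolist(),
            "x_scale": model.standardizer.x_scale.tolist(),
            "y_mean": model.standardizer.y_mean,
            "y_scale": model.standardizer.y_scale,
        },
        "X": model.training.X.tolist(),
        "y": model.training.y.tolist(),
    }


def model_from_dict(payload: dict) -> GPRModel:
    from .errors import FormatVersionError

    version = payload.get("format_version")
    if version != FORMAT_VERSION:
        raise FormatVersionError(f"unsupported model format version {version!r}")
    p = payload["params"]
    params = KernelParams(
        sigma_f=p["sigma_f"],
        sigma_l=p["sigma_l"],
        sigma_n2=p["sigma_n2"],
        distance=p.get("distance", "squared"),
        length_scales=p.get("length_scales"),
    )
    s = payload["standardizer"]
    std = Standardizer(
        x_mean=np.asarray(s["x_mean"], dtype=float),
        x_scale=np.asarray(s["x_scale"], dtype=float),
        y_mean=float(s["y_mean"]),
        y_scale=float(s["y_scale"]),
    )
    training = TrainingSet(np.asarray(payload["X"], dtype=float), np.asarray(payload["y"], dtype=float))
    return GPRModel(training=training, params=params, standardizer=std)
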