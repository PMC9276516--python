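"""Classical fuzzy C-means (FCM) by alternate optimization.

The clustering substrate is a 1-D array of scalar gray intensities
(one entry per pixel).  Conventions used throughout the package:

* ``features`` -- shape ``(n,)`` float array of intensities, normally in
  ``[0, 1]`` after image normalization (unnormalized values are allowed).
* ``centers`` -- shape ``(c,)`` float array of cluster-center intensities.
* ``d`` -- shape ``(c, n)`` distance matrix, ``d[i, k] = |centers[i] - x[k]|``.
* ``u`` -- shape ``(c, n)`` membership matrix; every column sums to 1 and
  entries lie in ``[0, 1]``.

The fitted partition minimizes the weighted squared-distance objective

    J(U, V) = sum_i sum_k  u_ik^m  d_ik^2,        m > 1,

by alternating the closed-form center update (membership-weighted mean)
and membership update (inverse-distance-ratio rule), stopping when the
max-absolute change in ``U`` between sweeps drops below ``epsilon`` or
after ``max_iter`` sweeps.  Pixels coinciding exactly with one or more
centers (zero distance) receive all their membership mass, distributed
uniformly over the coincident centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .exceptions import (
    DegenerateClusterError,
    InvalidConfigError,
    InvalidInputError,
    NumericalFailureError,
)

__all__ = [
    "FCMConfig",
    "FCMResult",
    "compute_distances",
    "update_membership",
    "update_centers",
    "objective",
    "fcm_fit",
]

#: Inits accepted by :class:`FCMConfig`.
INIT_MODES = ("random", "pso", "kmeanspp")


@dataclass(frozen=True)
class FCMConfig:
    """Tunables of the alternate-optimization loop.

    Parameters
    ----------
    c : int
        Number of clusters (tissue classes), >= 2.  Default 3 for the
        CSF / gray-matter / white-matter problem.
    m : float
        Fuzzifier exponent on memberships, > 1.  Controls partition
        softness; default 2.
    max_iter : int
        Maximum number of alternate-optimization sweeps ``T``; default 100.
    epsilon : float
        Stop tolerance on the max-absolute change of the membership
        matrix between sweeps; default 1e-4.
    seed : int
        Seed for the initializer.
    init : str
        ``"random"`` (c distinct data values), ``"pso"`` (particle-swarm
        optimized centers) or ``"kmeanspp"``.
    """

    c: int = 3
    m: float = 2.0
    max_iter: int = 100
    epsilon: float = 1e-4
    seed: int = 0
    init: str = "random"

    def __post_init__(self) -> None:
        if self.c < 2:
            raise InvalidConfigError(f"cluster count c must be >= 2, got {self.c}")
        if not self.m > 1:
            raise InvalidConfigError(f"fuzzifier m must be > 1, got {self.m}")
        if self.max_iter < 1:
            raise InvalidConfigError(f"max_iter must be >= 1, got {self.max_iter}")
        if not self.epsilon > 0:
            raise InvalidConfigError(f"epsilon must be > 0, got {self.epsilon}")
        if self.init not in INIT_MODES:
            raise InvalidConfigError(
                f"init must be one of {INIT_MODES}, got {self.init!r}"
            )


@dataclass
class FCMResult:
    """Outcome of a fuzzy C-means fit.

    ``centers`` are reported sorted ascending by intensity so that label
    0/1/2 maps deterministically to darkest -> brightest tissue (the
    CSF < GM < WM convention for T1-like contrast); ``membership`` rows
    and ``labels`` are permuted to match.
    """

    centers: np.ndarray
    membership: np.ndarray
    labels: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    config: FCMConfig
    init_centers: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _as_features(features: Sequence[float] | np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=float).ravel()
    if x.size == 0:
        raise InvalidInputError("feature set is empty")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("feature set contains non-finite values")
    return x


def compute_distances(
    features: Sequence[float] | np.ndarray, centers: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Euclidean distances between each center and each data point.

    For scalar intensities this is ``d[i, k] = |centers[i] - x[k]|``.

    Returns a ``(c, n)`` array.
    """
    x = _as_features(features)
    v = np.asarray(centers, dtype=float).ravel()
    if v.size == 0:
        raise InvalidInputError("centers are empty")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError("centers contain non-finite values")
    return np.abs(v[:, None] - x[None, :])


def update_membership(d: np.ndarray, m: float) -> np.ndarray:
    """Membership update: ``u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))``.

    Columns that contain one or more zero distances are handled by the
    coincident-center rule: membership mass goes entirely to the
    zero-distance clusters, split uniformly among them, and every other
    cluster receives 0.  Every column of the result sums to 1.
    """
    if not m > 1:
        raise InvalidConfigError(f"fuzzifier m must be > 1, got {m}")
    d = np.asarray(d, dtype=float)
    if d.ndim != 2:
        raise InvalidInputError(f"distance matrix must be 2-D, got ndim={d.ndim}")
    if np.any(d < 0):
        raise InvalidInputError("distances must be non-negative")

    p = 2.0 / (m - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.where(d > 0.0, d, 1.0) ** (-p)
    inv[d == 0.0] = np.inf

    # Columns where any d^(-p) overflowed or hit an exact zero distance:
    # treat them all by the uniform-over-closest rule (the exact-zero set
    # H_k, extended to numerically indistinguishable distances).
    singular = ~np.isfinite(inv)
    with np.errstate(invalid="ignore"):
        u = inv / np.sum(inv, axis=0, keepdims=True)
    bad_cols = singular.any(axis=0)
    if bad_cols.any():
        hk = singular[:, bad_cols]
        u[:, bad_cols] = hk / hk.sum(axis=0, keepdims=True)
    return u


def update_centers(
    features: Sequence[float] | np.ndarray, u: np.ndarray, m: float
) -> np.ndarray:
    """Center update: ``c_i = sum_k u_ik^m x_k / sum_k u_ik^m``."""
    if not m > 1:
        raise InvalidConfigError(f"fuzzifier m must be > 1, got {m}")
    x = _as_features(features)
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] != x.size:
        raise InvalidInputError(
            f"membership shape {u.shape} incompatible with {x.size} features"
        )
    w = u**m
    mass = w.sum(axis=1)
    if np.any(mass == 0.0):
        dead = np.flatnonzero(mass == 0.0)
        raise DegenerateClusterError(
            f"cluster(s) {dead.tolist()} have zero membership mass; "
            "retry with a different seed"
        )
    return (w @ x) / mass


def objective(u: np.ndarray, d: np.ndarray, m: float) -> float:
    """FCM objective ``J = sum_i sum_k u_ik^m d_ik^2`` (non-negative)."""
    u = np.asarray(u, dtype=float)
    d = np.asarray(d, dtype=float)
    if u.shape != d.shape:
        raise InvalidInputError(
            f"membership shape {u.shape} != distance shape {d.shape}"
        )
    return float(np.sum(u**m * d * d))


def _init_random(x: np.ndarray, c: int, seed: int) -> np.ndarray:
    """Draw c distinct data values as initial centers (within data range)."""
    uniq = np.unique(x)
    rng = np.random.default_rng(seed)
    if uniq.size >= c:
        return np.sort(rng.choice(uniq, size=c, replace=False))
    raise InvalidInputError(
        f"cannot draw {c} distinct initial centers from "
        f"{uniq.size} distinct feature value(s)"
    )


def _init_kmeanspp(x: np.ndarray, c: int, seed: int) -> np.ndarray:
    from sklearn.cluster import kmeans_plusplus

    centers, _ = kmeans_plusplus(
        x.reshape(-1, 1), n_clusters=c, random_state=seed % (2**31)
    )
    return np.sort(centers.ravel())


def initial_centers(x: np.ndarray, config: FCMConfig) -> np.ndarray:
    """Initial centers for ``config.init`` mode, seeded by ``config.seed``."""
    if config.init == "random":
        return _init_random(x, config.c, config.seed)
    if config.init == "kmeanspp":
        return _init_kmeanspp(x, config.c, config.seed)
    # PSO: deferred import, fcmseg.pso depends on this module.
    from .pso import PSOConfig, pso_init_centers

    return pso_init_centers(x, config.c, PSOConfig(seed=config.seed), m=config.m)


def _alternate_optimize(
    x: np.ndarray,
    config: FCMConfig,
    init: np.ndarray,
    distance_fn: Callable[[np.ndarray], np.ndarray],
    center_features: np.ndarray | None = None,
) -> FCMResult:
    """Shared alternate-optimization loop.

    ``distance_fn`` maps a center vector to the (effective) distance
    matrix used in the membership update and the objective;
    ``center_features`` is the feature vector fed to the center update
    (defaults to ``x``; the spatially regularized variant passes the
    neighborhood-blended intensities so each half-step is an exact
    coordinate-descent minimizer and the objective trace stays
    non-increasing).
    """
    xc = x if center_features is None else center_features
    centers = np.asarray(init, dtype=float).ravel().copy()
    if centers.size != config.c:
        raise InvalidInputError(
            f"expected {config.c} initial centers, got {centers.size}"
        )

    d = distance_fn(centers)
    u = update_membership(d, config.m)
    trace: list[float] = []
    converged = False
    n_iter = 0
    for _ in range(config.max_iter):
        centers = update_centers(xc, u, config.m)
        d = distance_fn(centers)
        u_next = update_membership(d, config.m)
        j = objective(u_next, d, config.m)
        if not np.isfinite(j):
            raise NumericalFailureError(f"objective became non-finite ({j})")
        trace.append(j)
        n_iter += 1
        delta = float(np.max(np.abs(u_next - u)))
        u = u_next
        if delta < config.epsilon:
            converged = True
            break

    # Report centers sorted ascending; permute memberships to match.
    order = np.argsort(centers, kind="stable")
    centers = centers[order]
    u = u[order]
    labels = np.argmax(u, axis=0)  # argmax breaks exact ties toward lowest index
    return FCMResult(
        centers=centers,
        membership=u,
        labels=labels,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        config=config,
        init_centers=np.asarray(init, dtype=float).ravel(),
    )


def fcm_fit(
    features: Sequence[float] | np.ndarray,
    config: FCMConfig | None = None,
    init_centers: Sequence[float] | np.ndarray | None = None,
) -> FCMResult:
    """Fit classical FCM on scalar features by alternate optimization.

    Parameters
    ----------
    features : array-like, shape (n,)
        Gray intensities.
    config : FCMConfig, optional
        Defaults to ``FCMConfig()`` (c=3, m=2, T=100, eps=1e-4).
    init_centers : array-like, shape (c,), optional
        Explicit initial centers; otherwise drawn per ``config.init``.
    """
    config = config or FCMConfig()
    x = _as_features(features)
    if init_centers is None:
        init = initial_centers(x, config)
    else:
        init = np.asarray(init_centers, dtype=float).ravel()
    return _alternate_optimize(
        x, config, init, distance_fn=lambda v: compute_distances(x, v)
    )
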