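"""Comparison arms: multi-level Otsu thresholding and crisp k-means.

Both baselines ignore spatial context entirely, which is what makes the
comparison against the neighborhood-regularized fuzzy method
informative on noisy images.  Labels are always reported in ascending
intensity order (darkest class = 0).
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["baseline_multithreshold", "baseline_kmeans"]


def baseline_multithreshold(image: np.ndarray, c: int = 3) -> np.ndarray:
    """Histogram thresholding with c-1 between-class-variance-optimal cuts.

    Purely histogram based, so the result is invariant to any spatial
    shuffling of pixels.  Raises an invalid-input error when the image
    has fewer distinct gray levels than requested classes.
    """
    from skimage.filters import threshold_multiotsu

    img = np.asarray(image, dtype=float)
    if c < 2:
        raise InvalidInputError(f"need c >= 2 classes, got {c}")
    if np.unique(img).size < c:
        raise InvalidInputError(
            f"image has fewer than {c} distinct gray levels"
        )
    try:
        thresholds = threshold_multiotsu(img, classes=c)
    except ValueError as exc:  # e.g. degenerate histogram
        raise InvalidInputError(str(exc)) from exc
    return np.digitize(img, bins=thresholds).astype(np.intp)


def baseline_kmeans(features: np.ndarray, c: int = 3, seed: int = 0) -> np.ndarray:
    """Crisp k-means (Lloyd) labels on scalar features, seeded.

    Labels are re-indexed so cluster 0 has the lowest center intensity.
    An empty cluster triggers one re-seed before failing.
    """
    from sklearn.cluster import KMeans

    x = np.asarray(features, dtype=float).ravel()
    if c < 2:
        raise InvalidInputError(f"need c >= 2 clusters, got {c}")
    if x.size < c:
        raise InvalidInputError(f"need at least {c} points, got {x.size}")

    last_exc: Exception | None = None
    for attempt_seed in (seed, seed + 1):
        try:
            km = KMeans(n_clusters=c, n_init=5, random_state=attempt_seed % (2**31))
            raw = km.fit_predict(x.reshape(-1, 1))
            centers = km.cluster_centers_.ravel()
            if np.unique(raw).size < c:
                raise RuntimeError("empty cluster")
        except Exception as exc:  # noqa: BLE001 - retried once, then re-raised
            last_exc = exc
            continue
        order = np.argsort(centers, kind="stable")
        relabel = np.empty(c, dtype=np.intp)
        relabel[order] = np.arange(c)
        return relabel[raw]
    raise InvalidInputError(f"k-means failed twice: {last_exc}")
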