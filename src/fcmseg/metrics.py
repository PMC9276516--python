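"""Segmentation evaluation: SB classification accuracy and reconstruction error.

SB is the fraction of pixels whose predicted cluster matches the
reference cluster after the cluster labels have been put into optimal
correspondence,

    SB = sum_i |B_i ∩ C_i| / sum_l |C_l|,

where B_i is the pixel set of predicted cluster i and C_i the pixel set
of reference cluster i.  Because cluster indices are arbitrary, the
correspondence is chosen by maximum-total-overlap assignment over the
c x c contingency table (Hungarian algorithm), which makes SB invariant
to any relabeling of the prediction.

The reconstruction error rate W_RE measures how well the fuzzy
partition summarizes the image: each pixel is rebuilt as the
membership-weighted blend of the cluster centers,

    I_rec(k) = sum_i u_ik^m v_i / sum_i u_ik^m,

and W_RE is the mean squared difference between reconstruction and
original.  A good partition reconstructs the image closely (small W_RE).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import InvalidInputError, NumericalFailureError

__all__ = [
    "match_labels",
    "classification_accuracy_sb",
    "reconstruct_image",
    "reconstruction_error",
    "contingency_table",
]


def _check_label_pair(pred, truth, c: int) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.size == 0 or t.size == 0:
        raise InvalidInputError("label maps are empty")
    if p.shape != t.shape:
        raise InvalidInputError(f"label shapes differ: {p.shape} vs {t.shape}")
    p = p.ravel().astype(np.intp)
    t = t.ravel().astype(np.intp)
    for name, arr in (("pred", p), ("truth", t)):
        if arr.min() < 0 or arr.max() >= c:
            raise InvalidInputError(f"{name} labels must lie in [0, {c})")
    return p, t


def contingency_table(pred, truth, c: int) -> np.ndarray:
    """c x c matrix of pixel counts, rows = predicted, cols = reference."""
    p, t = _check_label_pair(pred, truth, c)
    return np.bincount(p * c + t, minlength=c * c).reshape(c, c)


def match_labels(pred, truth, c: int) -> np.ndarray:
    """Optimal relabeling of predicted clusters onto reference clusters.

    Returns ``perm`` with ``perm[i]`` = the reference label assigned to
    predicted label ``i``, chosen to maximize total overlap.
    """
    table = contingency_table(pred, truth, c)
    rows, cols = linear_sum_assignment(table, maximize=True)
    perm = np.empty(c, dtype=np.intp)
    perm[rows] = cols
    return perm


def classification_accuracy_sb(pred, truth, c: int) -> float:
    """Fraction of pixels correctly classified after optimal label matching."""
    p, t = _check_label_pair(pred, truth, c)
    perm = match_labels(p, t, c)
    return float(np.mean(perm[p] == t))


def reconstruct_image(u: np.ndarray, centers: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Rebuild per-pixel gray values from the fuzzy partition.

    ``I_rec(k) = sum_i u_ik^m v_i / sum_i u_ik^m``; crisp memberships
    reproduce each pixel's own cluster center exactly, and every value
    lies within ``[min(centers), max(centers)]``.  Returns a flat array
    of length n (reshape to the image shape as needed).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(centers, dtype=float).ravel()
    if u.ndim != 2 or u.shape[0] != v.size:
        raise InvalidInputError(
            f"membership shape {u.shape} incompatible with {v.size} centers"
        )
    w = u**m
    denom = w.sum(axis=0)
    if np.any(denom == 0.0):
        raise NumericalFailureError(
            "pixel(s) with zero total membership mass cannot be reconstructed"
        )
    return (v @ w) / denom


def reconstruction_error(original: np.ndarray, recon: np.ndarray) -> float:
    """Mean squared difference between original and reconstructed gray values."""
    a = np.asarray(original, dtype=float)
    b = np.asarray(recon, dtype=float)
    if a.shape != b.shape:
        raise InvalidInputError(f"shapes differ: {a.shape} vs {b.shape}")
    diff = a - b
    return float(np.mean(diff * diff))
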