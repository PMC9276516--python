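"""Naive loop-based reference implementations used as independent oracles.

Everything here is written with explicit Python loops, straight from the
defining formulas, and is deliberately independent of the vectorized
code paths in fcmseg.
"""

import itertools
import math

import numpy as np


def naive_membership(d, m):
    c, n = d.shape
    u = np.zeros((c, n))
    p = 2.0 / (m - 1.0)
    for k in range(n):
        zeros = [i for i in range(c) if d[i, k] == 0.0]
        if zeros:
            for i in zeros:
                u[i, k] = 1.0 / len(zeros)
            continue
        for i in range(c):
            s = 0.0
            for j in range(c):
                s += (d[i, k] / d[j, k]) ** p
            u[i, k] = 1.0 / s
    return u


def naive_centers(x, u, m):
    c, n = u.shape
    v = np.zeros(c)
    for i in range(c):
        num = den = 0.0
        for k in range(n):
            w = u[i, k] ** m
            num += w * x[k]
            den += w
        v[i] = num / den
    return v


def naive_objective(u, d, m):
    c, n = u.shape
    total = 0.0
    for i in range(c):
        for k in range(n):
            total += (u[i, k] ** m) * d[i, k] ** 2
    return total


def naive_fcm(x, c, m, max_iter, eps, init):
    """Reference alternate-optimization loop (unsorted centers)."""
    d = np.abs(np.asarray(init, float)[:, None] - x[None, :])
    u = naive_membership(d, m)
    for _ in range(max_iter):
        v = naive_centers(x, u, m)
        d = np.abs(v[:, None] - x[None, :])
        u_next = naive_membership(d, m)
        delta = np.max(np.abs(u_next - u))
        u = u_next
        if delta < eps:
            break
    return v, u


def mirror(i, n):
    if i < 0:
        return -i - 1
    if i >= n:
        return 2 * n - i - 1
    return i


def naive_neighborhood_weights(img, radius, sigma_g):
    """w[(k, r)] dict keyed by (pixel flat index, neighbor flat index)."""
    rows, cols = img.shape
    out = {}
    for r in range(rows):
        for c in range(cols):
            k = r * cols + c
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    if dr == 0 and dc == 0:
                        continue
                    nr, nc = mirror(r + dr, rows), mirror(c + dc, cols)
                    kr = nr * cols + nc
                    diff = img[r, c] - img[nr, nc]
                    out.setdefault(k, []).append(
                        (kr, math.exp(-(diff**2) / sigma_g**2))
                    )
    return out


def naive_effective_distance(d, img, radius, sigma_g, beta):
    nbrs = naive_neighborhood_weights(img, radius, sigma_g)
    c, n = d.shape
    out = np.zeros_like(d)
    for k in range(n):
        wsum = sum(w for _, w in nbrs[k])
        for i in range(c):
            acc = sum(w * d[i, kr] ** 2 for kr, w in nbrs[k])
            out[i, k] = math.sqrt(
                (1.0 - beta) * d[i, k] ** 2 + beta * acc / wsum
            )
    return out


def naive_reconstruct(u, v, m):
    c, n = u.shape
    out = np.zeros(n)
    for k in range(n):
        num = den = 0.0
        for i in range(c):
            w = u[i, k] ** m
            num += w * v[i]
            den += w
        out[k] = num / den
    return out


def naive_wre(orig, recon):
    a = np.asarray(orig, float).ravel()
    b = np.asarray(recon, float).ravel()
    return sum((x - y) ** 2 for x, y in zip(a, b)) / a.size


def naive_sb(pred, truth, c):
    """Best accuracy over all label permutations (exhaustive)."""
    p = np.asarray(pred).ravel()
    t = np.asarray(truth).ravel()
    best = 0.0
    for perm in itertools.permutations(range(c)):
        perm = np.asarray(perm)
        best = max(best, float(np.mean(perm[p] == t)))
    return best
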