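"""Independent brute-force oracles used by the test-suite only.

These deliberately avoid the code paths they check: the threshold oracle is
an exhaustive scan over all candidate partitions of the intensity histogram,
and the labeling oracle is a plain breadth-first flood fill.
"""

from __future__ import annotations

import numpy as np


def li_cross_entropy(values: np.ndarray, t: float) -> float:
    """Li & Lee minimum-cross-entropy objective for threshold ``t``.

    Foreground is ``values >= t``. Dropping the constant ``sum(x log x)``
    term, the objective is ``-(S0*log(mu0) + S1*log(mu1))`` with S the class
    intensity sums and mu the class means; empty or zero-sum classes
    contribute nothing.
    """
    x = np.asarray(values, dtype=float).ravel()
    lo, hi = x[x < t], x[x >= t]
    obj = 0.0
    for part in (lo, hi):
        s = part.sum()
        if len(part) and s > 0:
            obj -= s * np.log(s / len(part))
    return obj


def brute_force_li(values: np.ndarray) -> float:
    """Exhaustive minimizer of the Li cross-entropy over all candidate
    partitions (midpoints between consecutive unique intensity levels)."""
    x = np.asarray(values, dtype=float).ravel()
    levels = np.unique(x)
    if len(levels) < 2:
        raise ValueError("constant array")
    candidates = (levels[:-1] + levels[1:]) / 2.0
    objs = [li_cross_entropy(x, t) for t in candidates]
    return float(candidates[int(np.argmin(objs))])


def flood_fill_label(binary: np.ndarray) -> np.ndarray:
    """8-connected component labeling by breadth-first flood fill."""
    binary = np.asarray(binary, dtype=bool)
    labels = np.zeros(binary.shape, dtype=np.int32)
    h, w = binary.shape
    next_label = 0
    for i in range(h):
        for j in range(w):
            if binary[i, j] and labels[i, j] == 0:
                next_label += 1
                queue = [(i, j)]
                labels[i, j] = next_label
                while queue:
                    r, c = queue.pop()
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            rr, cc = r + dr, c + dc
                            if (
                                0 <= rr < h and 0 <= cc < w
                                and binary[rr, cc] and labels[rr, cc] == 0
                            ):
                                labels[rr, cc] = next_label
                                queue.append((rr, cc))
    return labels


def blobby_image(rng: np.random.Generator, shape=(64, 64)) -> np.ndarray:
    """A random bimodal test image: dim noisy background plus bright blobs."""
    h, w = shape
    img = rng.normal(20, 5, (h, w))
    rows, cols = np.mgrid[0:h, 0:w]
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.uniform(8, h - 8), rng.uniform(8, w - 8)
        r = rng.uniform(4, 10)
        img[(rows - cy) ** 2 + (cols - cx) ** 2 <= r**2] += rng.uniform(80, 160)
    return np.clip(img, 0, 255)


def bh_adjust_reference(p: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up: p*m/rank, then a running
    minimum from the largest rank down, capped at 1; original order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
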