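"""Brute-force reference implementations used only as test oracles.

These are deliberately naive (linear scans, exhaustive enumeration) and
share no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def flood_watershed_oracle(image, markers, connectivity=4):
    """Marker-controlled watershed by exhaustive priority flooding.

    Same contract as ``orgrowth._watershed.flood_watershed`` (queued-once
    pixels, ascending (value, insertion-order) priority, fixed raster
    neighbor order, conflicts become line pixels = 0) but implemented with a
    plain python list scanned linearly for the minimum at every step.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(markers).astype(int).copy()
    h, w = image.shape
    if connectivity == 4:
        offs = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    else:
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                (1, -1), (1, 0), (1, 1)]
    LINE = -1
    queued = set()
    pending = []  # (value, insertion_order, y, x)
    order = 0

    def push_neighbors(y, x):
        nonlocal order
        for dy, dx in offs:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] == 0 \
                    and (ny, nx) not in queued:
                queued.add((ny, nx))
                pending.append((image[ny, nx], order, ny, nx))
                order += 1

    for y in range(h):
        for x in range(w):
            if labels[y, x] > 0:
                push_neighbors(y, x)

    while pending:
        best = 0
        for i in range(1, len(pending)):
            if (pending[i][0], pending[i][1]) < (pending[best][0], pending[best][1]):
                best = i
        _, _, y, x = pending.pop(best)
        if labels[y, x] != 0:
            continue
        neigh = set()
        for dy, dx in offs:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and labels[ny, nx] > 0:
                neigh.add(int(labels[ny, nx]))
        if len(neigh) == 1:
            labels[y, x] = neigh.pop()
            push_neighbors(y, x)
        else:
            labels[y, x] = LINE
    labels[labels == LINE] = 0
    return labels


def mann_whitney_exact_oracle(a, b, alternative="two_sided"):
    """Exact Mann-Whitney U and p by enumerating all rank assignments.

    Tie-free inputs only. Returns (U of sample a, p). The two-sided p is
    2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    n, m = len(a), len(b)
    pooled = sorted(a + b)
    assert len(set(pooled)) == n + m, "oracle requires tie-free data"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    rank_sum_a = sum(ranks[v] for v in a)
    u_a = rank_sum_a - n * (n + 1) / 2

    # null distribution of U by enumerating positions of sample a
    counts = {}
    for positions in itertools.combinations(range(1, n + m + 1), n):
        u = sum(positions) - n * (n + 1) / 2
        counts[u] = counts.get(u, 0) + 1
    total = comb(n + m, n)
    cdf = sum(c for u, c in counts.items() if u <= u_a) / total
    sf = sum(c for u, c in counts.items() if u >= u_a) / total
    if alternative == "two_sided":
        p = min(1.0, 2.0 * min(cdf, sf))
    elif alternative == "greater":
        p = sf
    else:
        p = cdf
    return u_a, p
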