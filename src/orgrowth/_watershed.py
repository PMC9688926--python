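"""Priority-flood (Meyer) marker-controlled watershed kernel.

Flooding semantics, chosen for determinism and testability against a
brute-force oracle:

* every unlabeled pixel is queued at most once, the first time a labeled
  neighbor appears, with priority ``(image value, insertion order)``;
* pixels are flooded in ascending priority; ties break by insertion order;
* a popped pixel adopts the label of its labeled neighbors when they agree,
  and becomes a watershed-line pixel (label 0) when two or more distinct
  labels meet there; line pixels never propagate;
* neighbors are visited in fixed raster order of their offsets, which pins
  the insertion order exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LINE = -1  # internal marker for watershed-line pixels


@njit(cache=True)
def _less(heap_val, heap_ord, i, j):
    if heap_val[i] < heap_val[j]:
        return True
    if heap_val[i] == heap_val[j] and heap_ord[i] < heap_ord[j]:
        return True
    return False


@njit(cache=True)
def _heap_push(heap_val, heap_ord, heap_pix, size, val, order, pix):
    i = size
    heap_val[i] = val
    heap_ord[i] = order
    heap_pix[i] = pix
    while i > 0:
        parent = (i - 1) // 2
        if _less(heap_val, heap_ord, i, parent):
            heap_val[i], heap_val[parent] = heap_val[parent], heap_val[i]
            heap_ord[i], heap_ord[parent] = heap_ord[parent], heap_ord[i]
            heap_pix[i], heap_pix[parent] = heap_pix[parent], heap_pix[i]
            i = parent
        else:
            break
    return size + 1


@njit(cache=True)
def _heap_pop(heap_val, heap_ord, heap_pix, size):
    top = heap_pix[0]
    size -= 1
    heap_val[0] = heap_val[size]
    heap_ord[0] = heap_ord[size]
    heap_pix[0] = heap_pix[size]
    i = 0
    while True:
        l = 2 * i + 1
        r = l + 1
        smallest = i
        if l < size and _less(heap_val, heap_ord, l, smallest):
            smallest = l
        if r < size and _less(heap_val, heap_ord, r, smallest):
            smallest = r
        if smallest == i:
            break
        heap_val[i], heap_val[smallest] = heap_val[smallest], heap_val[i]
        heap_ord[i], heap_ord[smallest] = heap_ord[smallest], heap_ord[i]
        heap_pix[i], heap_pix[smallest] = heap_pix[smallest], heap_pix[i]
        i = smallest
    return top, size


@njit(cache=True)
def _flood(image, labels, offsets_y, offsets_x):
    h, w = image.shape
    n = h * w
    heap_val = np.empty(n + 1, dtype=np.float64)
    heap_ord = np.empty(n + 1, dtype=np.int64)
    heap_pix = np.empty(n + 1, dtype=np.int64)
    queued = np.zeros(n, dtype=np.uint8)
    size = 0
    order = 0
    nk = offsets_y.shape[0]

    # seed: queue unlabeled neighbors of marker pixels, raster order
    for y in range(h):
        for x in range(w):
            if labels[y, x] > 0:
                for k in range(nk):
                    ny = y + offsets_y[k]
                    nx = x + offsets_x[k]
                    if 0 <= ny < h and 0 <= nx < w:
                        p = ny * w + nx
                        if labels[ny, nx] == 0 and queued[p] == 0:
                            queued[p] = 1
                            size = _heap_push(
                                heap_val, heap_ord, heap_pix,
                                size, image[ny, nx], order, p,
                            )
                            order += 1

    while size > 0:
        pix, size = _heap_pop(heap_val, heap_ord, heap_pix, size)
        y = pix // w
        x = pix % w
        if labels[y, x] != 0:
            continue
        lab = 0
        conflict = False
        for k in range(nk):
            ny = y + offsets_y[k]
            nx = x + offsets_x[k]
            if 0 <= ny < h and 0 <= nx < w:
                nl = labels[ny, nx]
                if nl > 0:
                    if lab == 0:
                        lab = nl
                    elif nl != lab:
                        conflict = True
        if conflict or lab == 0:
            labels[y, x] = LINE
            continue
        labels[y, x] = lab
        for k in range(nk):
            ny = y + offsets_y[k]
            nx = x + offsets_x[k]
            if 0 <= ny < h and 0 <= nx < w:
                p = ny * w + nx
                if labels[ny, nx] == 0 and queued[p] == 0:
                    queued[p] = 1
                    size = _heap_push(
                        heap_val, heap_ord, heap_pix,
                        size, image[ny, nx], order, p,
                    )
                    order += 1


def neighbor_offsets(connectivity: int) -> tuple[np.ndarray, np.ndarray]:
    """Neighbor offsets in fixed raster order for 4- or 8-connectivity."""
    if connectivity == 4:
        off = [(-1, 0), (0, -1), (0, 1), (1, 0)]
    elif connectivity == 8:
        off = [
            (-1, -1), (-1, 0), (-1, 1),
            (0, -1), (0, 1),
            (1, -1), (1, 0), (1, 1),
        ]
    else:
        raise ValueError("connectivity must be 4 or 8")
    oy = np.array([o[0] for o in off], dtype=np.int64)
    ox = np.array([o[1] for o in off], dtype=np.int64)
    return oy, ox


def flood_watershed(
    image: np.ndarray, markers: np.ndarray, connectivity: int = 4
) -> np.ndarray:
    """Flood ``image`` from ``markers``; returns labels with 0 on lines."""
    image = np.ascontiguousarray(image, dtype=np.float64)
    labels = np.ascontiguousarray(markers, dtype=np.int32).copy()
    if labels.shape != image.shape:
        raise ValueError("markers and image shapes differ")
    oy, ox = neighbor_offsets(connectivity)
    _flood(image, labels, oy, ox)
    labels[labels == LINE] = 0
    return labels
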