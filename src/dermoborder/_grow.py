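"""Best-first seeded region growing engine.

The grower maintains a frontier of 4-connected neighbours of the region in a
binary min-heap keyed by (delta, flat index), where delta is the absolute
difference between a pixel's intensity and the running region mean at the
time the pixel entered the heap.  On pop, delta is recomputed against the
*current* mean and used for the admission decision, so stale priorities only
affect ordering, never admission.  A pixel rejected because its delta exceeds
the tolerance is re-queued whenever a neighbouring pixel is later admitted,
which keeps the frontier live while the mean drifts and bounds the total
number of heap pushes by 5N.

The same function is compiled with numba when available; the pure-Python
definitions are the fallback and are semantically identical (same tie-breaks,
same float arithmetic), so masks are byte-identical either way.
"""

from __future__ import annotations

import numpy as np


def _heap_push(pr, ix, n, p, i):
    pr[n] = p
    ix[n] = i
    c = n
    n += 1
    while c > 0:
        parent = (c - 1) // 2
        if pr[parent] > pr[c] or (pr[parent] == pr[c] and ix[parent] > ix[c]):
            pr[parent], pr[c] = pr[c], pr[parent]
            ix[parent], ix[c] = ix[c], ix[parent]
            c = parent
        else:
            break
    return n


def _heap_pop(pr, ix, n):
    top = ix[0]
    n -= 1
    pr[0] = pr[n]
    ix[0] = ix[n]
    c = 0
    while True:
        left = 2 * c + 1
        right = left + 1
        smallest = c
        if left < n and (
            pr[left] < pr[smallest]
            or (pr[left] == pr[smallest] and ix[left] < ix[smallest])
        ):
            smallest = left
        if right < n and (
            pr[right] < pr[smallest]
            or (pr[right] == pr[smallest] and ix[right] < ix[smallest])
        ):
            smallest = right
        if smallest == c:
            break
        pr[smallest], pr[c] = pr[c], pr[smallest]
        ix[smallest], ix[c] = ix[c], ix[smallest]
        c = smallest
    return top, n


# pixel states
_UNSEEN = 0
_QUEUED = 1
_ADMITTED = 2
_REJECTED = 3


def _grow(gray, seed_r, seed_c, tol):
    H, W = gray.shape
    N = H * W
    flat = gray.ravel()
    state = np.zeros(N, dtype=np.uint8)
    mask = np.zeros(N, dtype=np.bool_)
    cap = 5 * N + 8
    pr = np.empty(cap, dtype=np.float64)
    ix = np.empty(cap, dtype=np.int64)
    n = 0

    seed = seed_r * W + seed_c
    n = _heap_push(pr, ix, n, 0.0, seed)
    state[seed] = _QUEUED
    total = 0.0
    count = 0

    while n > 0:
        i, n = _heap_pop(pr, ix, n)
        if state[i] == _ADMITTED:
            continue
        if count > 0:
            delta = abs(flat[i] - total / count)
        else:
            delta = 0.0
        if delta <= tol:
            state[i] = _ADMITTED
            mask[i] = True
            total += flat[i]
            count += 1
            mean = total / count
            r = i // W
            c = i - r * W
            # 4-neighbours in row-major order for deterministic tie-breaks
            for k in range(4):
                if k == 0:
                    nr, nc = r - 1, c
                elif k == 1:
                    nr, nc = r, c - 1
                elif k == 2:
                    nr, nc = r, c + 1
                else:
                    nr, nc = r + 1, c
                if nr < 0 or nr >= H or nc < 0 or nc >= W:
                    continue
                j = nr * W + nc
                if state[j] == _UNSEEN or state[j] == _REJECTED:
                    n = _heap_push(pr, ix, n, abs(flat[j] - mean), j)
                    state[j] = _QUEUED
        else:
            state[i] = _REJECTED

    return mask.reshape(H, W)


_grow_py = _grow

try:  # pragma: no cover - exercised indirectly
    import numba

    _heap_push = numba.njit(cache=False)(_heap_push)
    _heap_pop = numba.njit(cache=False)(_heap_pop)
    _grow = numba.njit(cache=False)(_grow)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


def grow(gray: np.ndarray, seed: tuple[int, int], tolerance: float) -> np.ndarray:
    """Run best-first region growing, preferring the jitted implementation."""
    gray = np.ascontiguousarray(gray, dtype=np.float64)
    try:
        return np.asarray(_grow(gray, int(seed[0]), int(seed[1]), float(tolerance)))
    except Exception:  # jit failure: fall back to the plain-Python twin
        return np.asarray(_grow_py(gray, int(seed[0]), int(seed[1]), float(tolerance)))
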