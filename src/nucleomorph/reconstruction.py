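"""Morphological reconstruction by dilation (fast hybrid algorithm).

Grayscale reconstruction of a *marker* image under a *mask* image is the
largest image pointwise below the mask that can be reached from the marker by
iterated geodesic dilation.  It is the workhorse behind h-dome background
suppression and h-extrema marker generation in the segmentation stage.

The implementation follows the classical fast hybrid scheme: one forward
(raster) sweep propagating from the causal neighborhood, one backward
(anti-raster) sweep propagating from the anti-causal neighborhood while
enqueueing every pixel whose value could still propagate, and a final FIFO
queue propagation phase.  The sweeps and queue loop are JIT-compiled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["reconstruct"]


@njit(cache=False)
def _hybrid_reconstruct(marker: np.ndarray, mask: np.ndarray, conn: int) -> np.ndarray:
    rows, cols = marker.shape
    out = marker.copy()

    # Forward raster sweep: causal (already-visited) neighbors.
    for r in range(rows):
        for c in range(cols):
            v = out[r, c]
            if r > 0:
                if out[r - 1, c] > v:
                    v = out[r - 1, c]
                if conn == 8:
                    if c > 0 and out[r - 1, c - 1] > v:
                        v = out[r - 1, c - 1]
                    if c < cols - 1 and out[r - 1, c + 1] > v:
                        v = out[r - 1, c + 1]
            if c > 0 and out[r, c - 1] > v:
                v = out[r, c - 1]
            if v > mask[r, c]:
                v = mask[r, c]
            out[r, c] = v

    # Backward anti-raster sweep + queue seeding.
    cap = 4 * rows * cols + 16
    queue = np.empty(cap, dtype=np.int64)
    head = 0
    tail = 0
    for r in range(rows - 1, -1, -1):
        for c in range(cols - 1, -1, -1):
            v = out[r, c]
            if r < rows - 1:
                if out[r + 1, c] > v:
                    v = out[r + 1, c]
                if conn == 8:
                    if c > 0 and out[r + 1, c - 1] > v:
                        v = out[r + 1, c - 1]
                    if c < cols - 1 and out[r + 1, c + 1] > v:
                        v = out[r + 1, c + 1]
            if c < cols - 1 and out[r, c + 1] > v:
                v = out[r, c + 1]
            if v > mask[r, c]:
                v = mask[r, c]
            out[r, c] = v
            # Enqueue if some anti-causal neighbor could still receive value.
            enq = False
            if r < rows - 1:
                if out[r + 1, c] < v and out[r + 1, c] < mask[r + 1, c]:
                    enq = True
                if conn == 8 and not enq:
                    if c > 0 and out[r + 1, c - 1] < v and out[r + 1, c - 1] < mask[r + 1, c - 1]:
                        enq = True
                    if c < cols - 1 and out[r + 1, c + 1] < v and out[r + 1, c + 1] < mask[r + 1, c + 1]:
                        enq = True
            if not enq and c < cols - 1:
                if out[r, c + 1] < v and out[r, c + 1] < mask[r, c + 1]:
                    enq = True
            if enq:
                if tail == cap:
                    new_cap = cap * 2
                    new_queue = np.empty(new_cap, dtype=np.int64)
                    new_queue[: tail - head] = queue[head:tail]
                    tail -= head
                    head = 0
                    queue = new_queue
                    cap = new_cap
                queue[tail] = r * cols + c
                tail += 1

    # FIFO propagation.
    while head < tail:
        p = queue[head]
        head += 1
        r = p // cols
        c = p % cols
        v = out[r, c]
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                if conn == 4 and dr != 0 and dc != 0:
                    continue
                nr = r + dr
                nc = c + dc
                if nr < 0 or nr >= rows or nc < 0 or nc >= cols:
                    continue
                q = out[nr, nc]
                if q < v and q < mask[nr, nc]:
                    nv = v if v < mask[nr, nc] else mask[nr, nc]
                    if nv > q:
                        out[nr, nc] = nv
                        if tail == cap:
                            new_cap = cap * 2
                            new_queue = np.empty(new_cap, dtype=np.int64)
                            new_queue[: tail - head] = queue[head:tail]
                            tail -= head
                            head = 0
                            queue = new_queue
                            cap = new_cap
                        queue[tail] = nr * cols + nc
                        tail += 1
    return out


def reconstruct(marker: np.ndarray, mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Grayscale morphological reconstruction of ``marker`` by dilation under ``mask``.

    Parameters
    ----------
    marker, mask
        2-D float arrays of identical shape with ``marker <= mask`` pointwise.
    connectivity
        Structuring element of the geodesic dilation: 8 (default) or 4.

    Returns
    -------
    ndarray
        The reconstruction: the pointwise-largest image ``<= mask`` reachable
        by iterated geodesic dilation of ``marker``.

    Raises
    ------
    ValueError
        If shapes differ, connectivity is invalid, or ``marker > mask``
        anywhere (the first offending pixel is reported).
    """
    marker = np.asarray(marker, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if marker.ndim != 2 or marker.shape != mask.shape:
        raise ValueError(
            f"marker and mask must be 2-D arrays of identical shape, "
            f"got {marker.shape} and {mask.shape}"
        )
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    bad = marker > mask
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"marker exceeds mask (first offending pixel ({r}, {c}): "
            f"marker={marker[r, c]:.6g} > mask={mask[r, c]:.6g})"
        )
    return _hybrid_reconstruct(np.ascontiguousarray(marker), np.ascontiguousarray(mask), connectivity)
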