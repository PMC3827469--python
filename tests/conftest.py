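"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi


def naive_reconstruct(marker: np.ndarray, mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Independent oracle: iterate geodesic dilation until a fixed point."""
    if connectivity == 8:
        fp = np.ones((3, 3), dtype=bool)
    else:
        fp = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    cur = np.asarray(marker, dtype=float).copy()
    mask = np.asarray(mask, dtype=float)
    while True:
        nxt = np.minimum(
            ndi.grey_dilation(cur, footprint=fp, mode="constant", cval=-np.inf), mask
        )
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


def disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def ellipse_mask(shape, center, a, b, theta=0.0) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def object_f1(labels: np.ndarray, truth: np.ndarray, iou_threshold: float = 0.5) -> float:
    """Object-level F1 with greedy IoU matching."""
    K = int(labels.max())
    T = int(truth.max())
    if K == 0 or T == 0:
        return 0.0
    tp = 0
    used: set[int] = set()
    for k in range(1, K + 1):
        m = labels == k
        best_iou, best_t = 0.0, 0
        for t in np.unique(truth[m]):
            if t == 0 or t in used:
                continue
            tm = truth == t
            iou = np.logical_and(m, tm).sum() / np.logical_or(m, tm).sum()
            if iou > best_iou:
                best_iou, best_t = iou, int(t)
        if best_iou >= iou_threshold:
            tp += 1
            used.add(best_t)
    precision = tp / K
    recall = tp / T
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@pytest.fixture(scope="session")
def snr5_tile():
    """One seeded fixture tile: 50 non-overlapping nuclei, contrast/noise >= 5."""
    from nucleomorph import synthetic

    specs = synthetic.sample_population(
        50, (0.4, 0.4, 0.2), seed=0, shape=(512, 512), min_separation=34.0
    )
    return synthetic.render_tile(
        specs, (512, 512), background_gradient=0.08, noise_sd=0.08, seed=100
    )
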