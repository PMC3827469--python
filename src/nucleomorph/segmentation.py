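"""Nucleus segmentation: background normalization, thresholding, watershed.

The stage chain is ``normalize_background -> threshold_foreground ->
split_clumps -> filter_objects``:

1.  The tile is inverted if nuclei are dark (hematoxylin convention), then an
    h-dome transform suppresses slowly varying background: the grayscale
    reconstruction of ``image - h`` under ``image`` is subtracted from the
    image, and the result is anchored at its minimum so a featureless tile
    maps to all zeros.  Background trends wider than nuclei survive
    reconstruction and cancel; nuclear peaks of height ``>= h`` stand out at
    ``~h``.
2.  Otsu (default) or a fixed threshold separates the foreground; small
    interior holes (noise pixels inside nuclei) are filled so the distance
    transform is well behaved.
3.  Touching nuclei are split by a marker-controlled watershed on the negated
    Euclidean distance transform; markers are the regional maxima of the
    distance map after h-maxima suppression (shallow maxima merged).
4.  Objects outside the area band or below the solidity floor are removed and
    the survivors relabeled contiguously.

The module is fully deterministic: no randomness anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage import segmentation as skseg

from nucleomorph.reconstruction import reconstruct

__all__ = [
    "SegmentationConfig",
    "normalize_background",
    "threshold_foreground",
    "split_clumps",
    "filter_objects",
    "segment_tile",
]


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation chain.

    ``hdome_height`` is in intensity units of the [0, 1] image; the area band
    is in pixels at 20X magnification.  ``threshold_method`` is ``"otsu"`` or
    ``"fixed"`` (with ``threshold_value``).
    """

    nuclei_are_dark: bool = True
    smoothing_sigma: float = 1.0  # Gaussian pre-smoothing, px; 0 disables
    hdome_height: float = 0.3
    threshold_method: str = "otsu"
    threshold_value: float = 0.5
    hysteresis: float = 0.5  # low-cut position in (bg mode, otsu); 1 disables
    fill_holes: bool = True
    hminima_depth: float = 2.0  # pixels, on the distance transform
    area_min: int = 30
    area_max: int = 3000
    solidity_min: float = 0.7
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (0.0 <= self.hdome_height < 1.0):
            raise ValueError("hdome_height must be in [0, 1)")
        if self.area_min >= self.area_max:
            raise ValueError("require area_min < area_max")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")

    @property
    def _skconn(self) -> int:
        # scikit-image orthogonal-step connectivity: 1 = 4-neighbors, 2 = 8.
        return 1 if self.connectivity == 4 else 2


def _as_gray(image: np.ndarray) -> np.ndarray:
    """Accept grayscale or RGB(A); RGB is reduced by luminance."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D (or RGB) image, got shape {image.shape}")
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    return img


def normalize_background(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """h-dome foreground map with slowly varying background suppressed.

    Returns ``dome - min(dome)`` where
    ``dome = inv - reconstruct(inv - h, inv)`` and ``inv`` is the (Gaussian
    pre-smoothed, then inverted if nuclei are dark) input.  Pre-smoothing
    keeps single noise pixels from acting as spurious dome summits.  The minimum anchoring makes a flat tile map
    to exactly zero and removes the constant ``h`` pedestal a featureless
    region would otherwise carry.
    """
    img = _as_gray(image)
    if cfg.smoothing_sigma > 0:
        img = ndi.gaussian_filter(img, cfg.smoothing_sigma)
    if cfg.nuclei_are_dark:
        img = 1.0 - img
    h = cfg.hdome_height
    if img.max() - img.min() <= h:
        # no structure taller than h exists; the dome is a constant pedestal
        warnings.warn(
            "h-dome height >= image dynamic range; foreground is empty",
            stacklevel=2,
        )
        return np.zeros_like(img)
    recon = reconstruct(img - h, img, connectivity=cfg.connectivity)
    dome = img - recon
    return dome - dome.min()


def threshold_foreground(image: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Boolean foreground mask of a normalized (h-dome) image.

    Otsu (default) is computed on the nonzero support; a constant image under
    Otsu yields all background with a warning.  When ``cfg.hysteresis < 1``
    the Otsu cut is relaxed by hysteresis: pixels above a low cut placed a
    fraction of the way from the background mode (median of sub-threshold
    support) to the Otsu threshold are kept when connected to a
    super-threshold core, which recovers nucleus edge pixels attenuated by
    pre-smoothing without admitting isolated background noise.  Interior
    holes are filled when ``cfg.fill_holes`` (noise robustness for the
    distance transform).
    """
    img = np.asarray(image, dtype=float)
    if not np.isfinite(img).all():
        raise ValueError("image contains non-finite values")
    if cfg.threshold_method == "fixed":
        fg = img > cfg.threshold_value
    else:
        support = img[img > 0]
        if support.size == 0 or support.max() - support.min() < 1e-12:
            warnings.warn(
                "constant image: Otsu threshold undefined, returning all background",
                stacklevel=2,
            )
            return np.zeros_like(img, dtype=bool)
        t = skfilters.threshold_otsu(support)
        if cfg.hysteresis < 1.0:
            below = support[support <= t]
            bg_mode = float(np.median(below)) if below.size else 0.0
            low = bg_mode + cfg.hysteresis * (t - bg_mode)
            fg = skfilters.apply_hysteresis_threshold(img, low, t)
        else:
            fg = img > t
    if cfg.fill_holes and fg.any():
        fg = ndi.binary_fill_holes(fg)
    return fg


def split_clumps(foreground: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Split touching nuclei by marker-controlled watershed.

    Markers are connected components of the regional maxima of the Euclidean
    distance transform after h-maxima suppression at ``cfg.hminima_depth``
    (shallow maxima within ``depth`` of a ridge are merged, preventing
    oversegmentation).  Foreground components left without a marker are kept
    as single objects.  Empty foreground returns an all-zero label map.
    """
    fg = np.asarray(foreground, dtype=bool)
    labels = np.zeros(fg.shape, dtype=np.int32)
    if not fg.any():
        return labels
    dist = ndi.distance_transform_edt(fg)
    depth = cfg.hminima_depth
    if depth > 0:
        suppressed = reconstruct(dist - depth, dist, connectivity=cfg.connectivity)
    else:
        suppressed = dist
    maxima = skmorph.local_maxima(suppressed, connectivity=cfg._skconn) & fg
    structure = ndi.generate_binary_structure(2, cfg._skconn)
    markers, n_markers = ndi.label(maxima, structure=structure)
    if n_markers > 0:
        labels = skseg.watershed(-dist, markers, mask=fg, connectivity=cfg._skconn).astype(
            np.int32
        )
    # Rescue foreground components that received no marker (e.g. plateaus the
    # maxima detector rejected): one label per leftover component.
    leftover = fg & (labels == 0)
    if leftover.any():
        extra, n_extra = ndi.label(leftover, structure=structure)
        labels = np.where(leftover, extra + labels.max(), labels).astype(np.int32)
    return _relabel_contiguous(labels)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels.astype(np.int32)
    remap = np.zeros(int(ids.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return remap[labels]


def filter_objects(labels: np.ndarray, cfg: SegmentationConfig) -> np.ndarray:
    """Remove objects outside [area_min, area_max] or below solidity_min;
    relabel survivors contiguously (order preserved)."""
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return labels.astype(np.int32)
    out = labels.astype(np.int32).copy()
    for prop in skmeasure.regionprops(out):
        area = prop.area
        keep = cfg.area_min <= area <= cfg.area_max
        if keep and prop.solidity < cfg.solidity_min:
            keep = False
        if not keep:
            out[tuple(prop.coords.T)] = 0
    return _relabel_contiguous(out)


def segment_tile(image: np.ndarray, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Full segmentation chain on one tile; deterministic for fixed inputs."""
    cfg = cfg or SegmentationConfig()
    dome = normalize_background(image, cfg)
    fg = threshold_foreground(dome, cfg)
    labels = split_clumps(fg, cfg)
    return filter_objects(labels, cfg)
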