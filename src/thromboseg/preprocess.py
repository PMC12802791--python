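"""From raw images to the binary masks the network consumes.

The imaging chain gives an RGB frame whose three channels carry the same
radiographic content.  Preprocessing collapses it to one grayscale channel,
clears the burned-in text annotations near the borders, and thresholds two
feature classes apart:

* **dot mask** — the dark stent markers (and, deliberately, the microcatheter
  distractor marker: the network is expected to learn to pass it through);
* **clot mask** — on training-style scenes only, where the clot is rendered
  radiopaque, a mid-gray band isolates it from both markers and background.

Both masks are strictly binary after every operation, including resizing,
which uses nearest-neighbour lookups with a floor convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simulate import _disk_mask, _FOUR_CONN, FluoroScene

__all__ = [
    "ThresholdConfig",
    "MaskPair",
    "ClotExtractionError",
    "to_grayscale",
    "remove_text_annotations",
    "extract_dot_mask",
    "extract_clot_mask",
    "normalize_dot_mask",
    "fill_marker_holes",
    "resize_mask",
    "make_training_pair",
]

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights used by :func:`to_grayscale`.
GRAY_WEIGHTS = (0.299, 0.587, 0.114)


class ClotExtractionError(ValueError):
    """No clot pixels found in the configured grayscale band."""


@dataclass(frozen=True)
class ThresholdConfig:
    """Grayscale thresholds separating markers and (opacified) clot.

    ``marker_threshold`` is inclusive: pixels at or below it are markers.
    ``clot_low``/``clot_high`` bound the mid-gray band of the barium-opacified
    clot, which is darker than background but lighter than the platinum
    markers.  Defaults bracket the simulator's intensity model
    (markers 30, clot 110, background 200) with wide noise margins.
    """

    marker_threshold: int = 70
    clot_low: int = 80
    clot_high: int = 160
    annotation_band_px: int = 12
    target_size: int = 128

    def validate(self) -> None:
        for name in ("marker_threshold", "clot_low", "clot_high"):
            if not 0 <= getattr(self, name) <= 255:
                raise ValueError(f"{name} must be an 8-bit intensity")
        if not self.marker_threshold <= self.clot_low:
            raise ValueError("marker_threshold must not exceed clot_low")
        if self.clot_low > self.clot_high:
            raise ValueError("clot_low must not exceed clot_high")
        if self.annotation_band_px < 0:
            raise ValueError("annotation_band_px must be non-negative")
        if self.target_size < 1:
            raise ValueError("target_size must be positive")


@dataclass
class MaskPair:
    """The unit of training: marker-mask input and clot-mask target."""

    dot_mask: np.ndarray  # (S, S) uint8 in {0, 1}
    clot_mask: np.ndarray  # (S, S) uint8 in {0, 1}
    source_id: str | None = None

    def __post_init__(self) -> None:
        if self.dot_mask.shape != self.clot_mask.shape:
            raise ValueError("dot_mask and clot_mask must have the same shape")
        for name in ("dot_mask", "clot_mask"):
            arr = getattr(self, name)
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"{name} values must be in {{0, 1}}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an 8-bit RGB image to one luminance channel (BT.601 weights).

    Already-gray 2-D input is passed through unchanged; equal-channel RGB is a
    fixed point of the conversion.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8, copy=True)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W) or (H, W, 3) image, got shape {image.shape}")
    gray = image.astype(np.float64) @ np.asarray(GRAY_WEIGHTS)
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def remove_text_annotations(image: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Replace the border band by the image's modal intensity.

    The text burned in by the imaging system always lives in a fixed band
    along the borders; filling that band with the modal (background) level
    removes it without touching any interior pixel.  ``band == 0`` is the
    identity.
    """
    image = np.asarray(image)
    band = cfg.annotation_band_px
    out = image.astype(np.uint8, copy=True)
    if band == 0:
        return out
    if band >= image.shape[0] / 2 or band >= image.shape[1] / 2:
        raise ValueError("annotation_band_px must be smaller than half the image side")
    mode = int(np.bincount(image.ravel(), minlength=256).argmax())
    out[:band, :] = mode
    out[-band:, :] = mode
    out[:, :band] = mode
    out[:, -band:] = mode
    return out


def extract_dot_mask(image: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Binary mask of marker pixels: intensity <= ``marker_threshold``.

    Annotations are cleared first so that dark glyphs cannot masquerade as
    markers.  An empty result is allowed (no stent in the field of view) but
    logged as a warning.
    """
    cfg.validate()
    g = remove_text_annotations(to_grayscale(image), cfg)
    mask = (g <= cfg.marker_threshold).astype(np.uint8)
    if not mask.any():
        logger.warning("extract_dot_mask produced an empty mask")
    return mask


def extract_clot_mask(image: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    """Binary mask of the opacified clot: ``clot_low <= intensity <= clot_high``.

    Only the largest 4-connected component is kept (ties broken by first
    label in scan order).  Raises :class:`ClotExtractionError` when the band
    is empty — e.g. on test-style scenes where the clot is radiolucent.
    """
    cfg.validate()
    g = remove_text_annotations(to_grayscale(image), cfg)
    band = (g >= cfg.clot_low) & (g <= cfg.clot_high)
    labels, n = ndimage.label(band, structure=_FOUR_CONN)
    if n == 0:
        raise ClotExtractionError(
            "no pixels in the clot grayscale band (is this a radiopaque-clot image?)"
        )
    sizes = ndimage.sum_labels(band, labels, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    return (labels == keep).astype(np.uint8)


def normalize_dot_mask(mask: np.ndarray) -> np.ndarray:
    """Replace each marker blob by a disk of its area-equivalent radius.

    Thresholded marker disks carry a halo whose width depends on the local
    surroundings — in particular, markers sitting on an opacified clot come
    out slightly fatter than markers on plain background.  A network trained
    on raw thresholded masks can exploit that intensity leak, which does not
    exist when the clot is radiolucent.  Snapping every 4-connected component
    to a disk of radius ``round(sqrt(area / pi))`` at its centroid removes
    the halo while preserving exactly the two things that matter: marker
    positions (the deformation signal) and the marker/distractor size
    distinction.
    """
    mask = np.asarray(mask)
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    out = np.zeros_like(mask, dtype=np.uint8)
    for k in range(1, n + 1):
        comp = labels == k
        radius = max(1, round(float(np.sqrt(comp.sum() / np.pi))))
        cr, cc = np.argwhere(comp).mean(axis=0)
        out |= _disk_mask(mask.shape, (float(cr), float(cc)), float(radius))
    return out


def fill_marker_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes of a binary mask (4-connectivity).

    The stent markers occlude the opacified clot, so a thresholded clot mask
    has disk-shaped holes where markers overlap it.  The clot itself is
    simply connected; filling interior holes recovers the occluded pixels
    (boundary notches, which are open to the outside, are left alone).
    """
    return ndimage.binary_fill_holes(np.asarray(mask).astype(bool),
                                     structure=_FOUR_CONN).astype(np.uint8)


def resize_mask(mask: np.ndarray, target_size: int) -> np.ndarray:
    """Nearest-neighbour resize to ``target_size`` square; masks stay binary.

    Output pixel ``(i, j)`` copies input pixel ``(floor(i*H/S), floor(j*W/S))``
    — the floor convention, so 0.5-boundary ties resolve toward the
    lower-index source pixel.
    """
    mask = np.asarray(mask)
    H, W = mask.shape
    if (H, W) == (target_size, target_size):
        return mask.astype(np.uint8, copy=True)
    ri = (np.arange(target_size) * H) // target_size
    ci = (np.arange(target_size) * W) // target_size
    return mask[np.ix_(ri, ci)].astype(np.uint8)


def make_training_pair(
    scene_or_image: FluoroScene | np.ndarray,
    cfg: ThresholdConfig,
    *,
    clot_mask: np.ndarray | None = None,
    source_id: str | None = None,
    fill_holes: bool = True,
    normalize_dots: bool = True,
) -> MaskPair:
    """Build the (dot mask, clot mask) pair for one image, at model resolution.

    The dot mask is always extracted from the image by thresholding, then
    (with ``normalize_dots``, on by default) canonicalized via
    :func:`normalize_dot_mask` so that training-style and test-style renders
    of the same geometry produce identical network inputs.  The clot target
    comes from the radiopaque render when available, otherwise from an
    explicit ground-truth mask (``clot_mask`` argument, or the scene's stored
    mask for radiolucent-clot scenes).  ``fill_holes`` (on by default)
    restores marker-occluded interior pixels of a thresholded clot target, so
    that training targets match the full clot extent that evaluation is
    scored against.
    """
    cfg.validate()
    if isinstance(scene_or_image, FluoroScene):
        scene = scene_or_image
        image = scene.image
        if clot_mask is None:
            if scene.meta.config.radiopaque_clot:
                clot_mask = extract_clot_mask(image, cfg)
                if fill_holes:
                    clot_mask = fill_marker_holes(clot_mask)
            else:
                clot_mask = scene.clot_mask
    else:
        image = np.asarray(scene_or_image)
        if clot_mask is None:
            clot_mask = extract_clot_mask(image, cfg)
            if fill_holes:
                clot_mask = fill_marker_holes(clot_mask)
    dot = extract_dot_mask(image, cfg)
    if normalize_dots:
        dot = normalize_dot_mask(dot)
    if dot.shape != clot_mask.shape:
        raise ValueError(
            f"image-derived mask shape {dot.shape} != clot mask shape {clot_mask.shape}"
        )
    return MaskPair(
        dot_mask=resize_mask(dot, cfg.target_size),
        clot_mask=resize_mask(clot_mask, cfg.target_size),
        source_id=source_id,
    )
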