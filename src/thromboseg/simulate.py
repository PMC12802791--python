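"""Synthetic fluoroscopy scene generator.

During stent-retriever thrombectomy the clot itself is radiolucent: the only
X-ray-visible evidence of its shape is the arrangement of the platinum marker
"dots" on the deployed stent, which are locally indented toward the vessel
axis where the clot presses on the stent.  This module renders phantom scenes
with that geometry and known ground truth, so that thresholding, training and
evaluation can all be exercised without access to proprietary bench data.

A scene contains

* a straight projected vessel segment (radiolucent, hence invisible) holding
  a stent with ``n_clusters`` clusters of ``markers_per_cluster`` dark marker
  disks arranged helically (vertical fan plus a small arclength stagger),
* one clot occupying a contiguous sub-span of the stent, rendered as a dark
  region only when ``radiopaque_clot`` is on (the bench-side barium-sulfate
  preparation used to obtain training ground truth),
* optionally one larger "distractor" disk emulating the microcatheter tip
  marker, proximal to the stent, and
* optionally burned-in glyph-like annotations inside a fixed border band.

Fluoroscopy polarity is dark-on-light: dense objects attenuate the beam and
appear dark on a light background.

All randomness flows through one :class:`numpy.random.Generator`.  Every
random quantity is drawn regardless of the enable flags, so two scenes that
share a seed and differ only in ``distractor_enabled`` or
``annotation_enabled`` are otherwise pixel-identical — this is what makes
paired robustness comparisons possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SceneConfig",
    "StentGeometry",
    "SceneMeta",
    "FluoroScene",
    "GenerationError",
    "generate_scene",
    "simulate_scenes",
    "generate_dataset",
    "derive_seed",
]

_MASK64 = (1 << 64) - 1
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


class GenerationError(ValueError):
    """A scene could not be generated under the requested geometry."""


def derive_seed(master_seed: int, index: int) -> int:
    """Per-scene seed from a master seed (splitmix64-style, order independent).

    Scene ``index`` always receives the same seed for a given master seed, no
    matter how many scenes are generated or in which order.
    """
    z = (int(master_seed) + (index + 1) * 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    z ^= z >> 31
    return int(z % (1 << 31))


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic procedure scene.

    Lengths are in pixels of the rendered image; clot sizes are fractions
    (of the stent span for length, of the lumen diameter for thickness).
    Intensity levels are 8-bit grayscale values, dark-on-light polarity.
    """

    image_size: int = 128
    vessel_diameter_px: float = 16.0
    n_clusters: int = 5
    markers_per_cluster: int = 3
    clot_length_range: tuple[float, float] = (0.3, 0.6)
    clot_thickness_range: tuple[float, float] = (0.4, 0.9)
    marker_radius_px: float = 2.0
    cluster_x_spread_px: float = 4.0
    deformation_gain: float = 0.6
    distractor_enabled: bool = True
    annotation_enabled: bool = True
    annotation_band_px: int = 10
    noise_sd: float = 2.0
    blur_sigma_px: float = 0.5
    background_level: int = 200
    marker_level: int = 30
    clot_level: int = 110
    annotation_level: int = 10
    centerline_jitter_px: float = 2.0
    radiopaque_clot: bool = True
    seed: int | None = None

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.markers_per_cluster < 1:
            raise ValueError("markers_per_cluster must be >= 1")
        for name in ("clot_length_range", "clot_thickness_range"):
            lo, hi = getattr(self, name)
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError(f"{name} must satisfy 0 < min <= max <= 1")
        if self.vessel_diameter_px <= 0 or self.marker_radius_px <= 0:
            raise ValueError("vessel_diameter_px and marker_radius_px must be positive")
        if self.noise_sd < 0 or self.blur_sigma_px < 0:
            raise ValueError("noise_sd and blur_sigma_px must be non-negative")
        if not 0 <= self.annotation_band_px < self.image_size // 2:
            raise ValueError("annotation_band_px must be in [0, image_size/2)")
        for name in ("background_level", "marker_level", "clot_level", "annotation_level"):
            if not 0 <= getattr(self, name) <= 255:
                raise ValueError(f"{name} must be an 8-bit intensity")
        # Outermost marker (at 0.35 D from the axis) must fit inside the lumen.
        if self.markers_per_cluster > 1:
            max_off = 0.35 * self.vessel_diameter_px
            if max_off + self.marker_radius_px > 0.5 * self.vessel_diameter_px:
                raise GenerationError(
                    "infeasible geometry: marker disks extend outside the lumen "
                    "(marker_radius_px too large for vessel_diameter_px)"
                )


@dataclass(frozen=True)
class StentGeometry:
    """Stent axis and marker coordinates, before and after clot indentation.

    Coordinates are float ``(row, col)``, 0-based, origin at the top-left.
    ``centerline`` is ordered proximal (left) to distal (right).
    """

    centerline: np.ndarray  # (L, 2) float
    cluster_positions: np.ndarray  # (n_clusters,) arclength fractions of stent span
    marker_coords: np.ndarray  # (n_clusters * markers_per_cluster, 2) float
    undeformed_coords: np.ndarray  # same shape as marker_coords
    stent_x_start: float
    stent_x_end: float


@dataclass(frozen=True)
class SceneMeta:
    geometry: StentGeometry
    clot_x_start: float
    clot_x_end: float
    clot_length_fraction: float
    clot_thickness_fraction: float
    clot_max_half_thickness_px: float
    distractor_center: tuple[float, float]  # (row, col); rendered only when enabled
    distractor_radius_px: float
    seed: int | None
    config: SceneConfig


@dataclass
class FluoroScene:
    """One rendered scene: 8-bit image plus binary ground-truth masks."""

    image: np.ndarray  # (H, W) uint8
    clot_mask: np.ndarray  # (H, W) uint8 in {0, 1}
    dot_mask: np.ndarray  # (H, W) uint8 in {0, 1}; stent markers only
    meta: SceneMeta

    @property
    def distractor_mask(self) -> np.ndarray | None:
        """Binary mask of the microcatheter distractor disk, or None."""
        if not self.meta.config.distractor_enabled:
            return None
        return _disk_mask(
            self.image.shape,
            self.meta.distractor_center,
            self.meta.distractor_radius_px,
        )


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    r0, c0 = round(center[0]), round(center[1])
    rad = int(np.ceil(radius))
    H, W = shape
    out = np.zeros(shape, dtype=np.uint8)
    rr = np.arange(max(0, r0 - rad), min(H, r0 + rad + 1))
    cc = np.arange(max(0, c0 - rad), min(W, c0 + rad + 1))
    if rr.size == 0 or cc.size == 0:
        return out
    d2 = (rr[:, None] - r0) ** 2 + (cc[None, :] - c0) ** 2
    out[np.ix_(rr, cc)] = (d2 <= radius**2).astype(np.uint8)
    return out


def _centerline_row(cols: np.ndarray, cy: float, amp: float, wavelength: float, phase: float,
                    x0: float) -> np.ndarray:
    return cy + amp * np.sin(2.0 * np.pi * (cols - x0) / wavelength + phase)


def generate_scene(config: SceneConfig, seed: int | None = None) -> FluoroScene:
    """Render one scene; bit-identical for a fixed ``(config, seed)``.

    Raises :class:`GenerationError` naming the violated constraint when the
    requested geometry is infeasible (clot longer than the stent span, marker
    disks outside the lumen or overlapping each other).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    H = W = config.image_size
    D = config.vessel_diameter_px
    R = D / 2.0
    m = config.markers_per_cluster
    K = config.n_clusters

    # --- stent axis -------------------------------------------------------
    x0, x1 = 0.12 * W, 0.88 * W
    cy = H / 2.0 + rng.uniform(-1.0, 1.0)
    amp = rng.uniform(0.0, config.centerline_jitter_px)
    wavelength = 1.5 * W
    phase = rng.uniform(0.0, 2.0 * np.pi)
    cl_cols = np.arange(int(np.ceil(x0)), int(np.floor(x1)) + 1, dtype=float)
    cl_rows = _centerline_row(cl_cols, cy, amp, wavelength, phase, x0)
    centerline = np.stack([cl_rows, cl_cols], axis=1)

    def row_at(x):
        return _centerline_row(np.asarray(x, dtype=float), cy, amp, wavelength, phase, x0)

    # Stent occupies the distal 70 % of the visible axis, inset so that the
    # staggered markers of the last cluster stay clear of the border band.
    s0 = x0 + 0.30 * (x1 - x0)
    s1 = x1 - (config.cluster_x_spread_px + config.marker_radius_px + 1.0)
    if s1 <= s0:
        raise GenerationError("infeasible geometry: stent span collapses after border inset")
    span = s1 - s0

    # --- clot -------------------------------------------------------------
    length_frac = rng.uniform(*config.clot_length_range)
    thickness_frac = rng.uniform(*config.clot_thickness_range)
    clot_len = length_frac * span
    if clot_len > span + 1e-9:
        raise GenerationError("infeasible geometry: clot longer than stent span")
    clot_start = s0 + rng.uniform(0.0, span - clot_len)
    clot_end = clot_start + clot_len
    h_max = thickness_frac * R  # half-thickness at the clot's midpoint

    def half_thickness(x):
        """Elliptical half-thickness profile; 0 outside the clot span."""
        x = np.asarray(x, dtype=float)
        t = (x - clot_start) / clot_len
        inside = (t >= 0.0) & (t <= 1.0)
        val = np.zeros_like(x)
        tt = np.clip(t, 0.0, 1.0)
        val[inside] = h_max * np.sqrt(np.clip(1.0 - (2.0 * tt[inside] - 1.0) ** 2, 0.0, 1.0))
        return val

    # --- markers ----------------------------------------------------------
    cluster_fracs = np.linspace(0.0, 1.0, K)
    cluster_x = s0 + cluster_fracs * span
    if m > 1:
        offsets = np.linspace(-0.35 * D, 0.35 * D, m)
        stagger = (np.arange(m) - (m - 1) / 2.0) * config.cluster_x_spread_px
    else:
        offsets = np.zeros(1)
        stagger = np.zeros(1)

    min_off = config.marker_radius_px + 1.0  # keep indented markers apart
    undeformed = np.empty((K * m, 2))
    deformed = np.empty((K * m, 2))
    for k in range(K):
        for j in range(m):
            x = cluster_x[k] + stagger[j]
            base_row = float(row_at(x))
            off = offsets[j]
            h = float(half_thickness(x))
            # Indentation: the clot pushes the stent wall (and its markers)
            # toward the vessel axis, proportionally to local half-thickness,
            # capped so markers neither collide nor cross the axis.
            d = min(config.deformation_gain * h, max(abs(off) - min_off, 0.0))
            new_off = np.sign(off) * (abs(off) - d)
            undeformed[k * m + j] = (base_row + off, x)
            deformed[k * m + j] = (base_row + new_off, x)
            if abs(new_off) + config.marker_radius_px > R + 1e-9:
                raise GenerationError("infeasible geometry: marker pushed outside lumen")

    geometry = StentGeometry(
        centerline=centerline,
        cluster_positions=cluster_fracs,
        marker_coords=deformed,
        undeformed_coords=undeformed,
        stent_x_start=s0,
        stent_x_end=s1,
    )

    # --- distractor (microcatheter tip marker) -----------------------------
    # Uniform over the proximal third of the axis, kept clear of the stent.
    dist_rad = 2.0 * config.marker_radius_px
    lo = x0 + dist_rad + 1.0
    hi = min(x0 + (x1 - x0) / 3.0,
             s0 - config.cluster_x_spread_px - config.marker_radius_px - 2.0 * dist_rad)
    if hi <= lo:
        raise GenerationError("infeasible geometry: no room for distractor proximal to stent")
    dist_x = rng.uniform(lo, hi)
    dist_center = (float(row_at(dist_x)), float(dist_x))

    # --- annotations (drawn only inside the border band) --------------------
    band = config.annotation_band_px
    ann_mask = np.zeros((H, W), dtype=bool)
    glyph_h = max(2, band - 4)
    n_top = int(rng.integers(4, 9))
    start_top = int(rng.integers(2, max(3, W // 3)))
    n_bot = int(rng.integers(4, 9))
    start_bot = int(rng.integers(max(3, W // 2), W - 2))
    if band > 0:
        for g in range(n_top):
            c = start_top + g * 5
            if c + 3 >= W - 2:
                break
            ann_mask[2:2 + glyph_h, c:c + 3] = True
        for g in range(n_bot):
            c = start_bot - g * 5
            if c - 3 < 2:
                break
            ann_mask[H - 2 - glyph_h:H - 2, c - 3:c] = True

    # --- masks --------------------------------------------------------------
    grid_cols = np.arange(W, dtype=float)
    rowc = row_at(grid_cols)
    h_cols = half_thickness(grid_cols)
    h_cols[h_cols < 1.0] = 0.0  # drop sub-pixel clot tips (keeps one 4-connected blob)
    rows = np.arange(H, dtype=float)[:, None]
    clot_mask = (np.abs(rows - rowc[None, :]) <= h_cols[None, :]) & (h_cols[None, :] > 0)
    clot_mask = clot_mask.astype(np.uint8)

    dot_mask = np.zeros((H, W), dtype=np.uint8)
    for r, c in deformed:
        dot_mask |= _disk_mask((H, W), (r, c), config.marker_radius_px)

    # --- invariant checks ----------------------------------------------------
    n_clot, _ = _label_count(clot_mask)
    if n_clot != 1:
        raise GenerationError(
            f"generated clot mask is not one 4-connected component (got {n_clot})"
        )
    n_dots, _ = _label_count(dot_mask)
    if n_dots != K * m:
        raise GenerationError(
            f"marker overlap: expected {K * m} marker components, got {n_dots}"
        )

    # --- render ---------------------------------------------------------------
    img = np.full((H, W), float(config.background_level), dtype=np.float64)
    if config.radiopaque_clot:
        img[clot_mask.astype(bool)] = config.clot_level
    if config.annotation_enabled:
        img[ann_mask] = config.annotation_level
    if config.distractor_enabled:
        dmask = _disk_mask((H, W), dist_center, dist_rad).astype(bool)
        img[dmask] = config.marker_level
    img[dot_mask.astype(bool)] = config.marker_level

    if config.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, config.blur_sigma_px)
    noise = rng.standard_normal((H, W))  # drawn unconditionally: keeps streams aligned
    if config.noise_sd > 0:
        img = img + config.noise_sd * noise
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    meta = SceneMeta(
        geometry=geometry,
        clot_x_start=float(clot_start),
        clot_x_end=float(clot_end),
        clot_length_fraction=float(length_frac),
        clot_thickness_fraction=float(thickness_frac),
        clot_max_half_thickness_px=float(h_max),
        distractor_center=dist_center,
        distractor_radius_px=float(dist_rad),
        seed=seed,
        config=config,
    )
    return FluoroScene(image=image, clot_mask=clot_mask, dot_mask=dot_mask, meta=meta)


def _label_count(mask: np.ndarray) -> tuple[int, np.ndarray]:
    labels, n = ndimage.label(mask, structure=_FOUR_CONN)
    return n, labels


def simulate_scenes(config: SceneConfig, n: int, seed: int) -> list[FluoroScene]:
    """Generate ``n`` scenes with per-scene seeds derived from ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [generate_scene(config, derive_seed(seed, i)) for i in range(n)]


def generate_dataset(
    config: SceneConfig,
    n: int,
    seed: int,
    out_dir: str | Path,
) -> tuple[list[FluoroScene], pd.DataFrame]:
    """Generate ``n`` scenes and write images, masks and a CSV manifest.

    Layout under ``out_dir``::

        scene_0000.png            8-bit grayscale image
        scene_0000_clot.png       clot ground truth, {0, 255} on disk
        scene_0000_dots.png       marker ground truth, {0, 255} on disk
        manifest.csv              id, image_path, clot_mask_path,
                                  dot_mask_path, seed, clot_start, clot_end

    Paths in the manifest are relative to ``out_dir``.
    """
    from . import io as tio  # local import: io depends on nothing here

    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"unwritable output directory {out_dir}: {exc}") from exc

    scenes = simulate_scenes(config, n, seed)
    rows = []
    for i, scene in enumerate(scenes):
        sid = f"scene_{i:04d}"
        img_p, clot_p, dot_p = f"{sid}.png", f"{sid}_clot.png", f"{sid}_dots.png"
        tio.write_image_png(out_dir / img_p, scene.image)
        tio.write_mask_png(out_dir / clot_p, scene.clot_mask)
        tio.write_mask_png(out_dir / dot_p, scene.dot_mask)
        rows.append(
            {
                "id": sid,
                "image_path": img_p,
                "clot_mask_path": clot_p,
                "dot_mask_path": dot_p,
                "seed": scene.meta.seed,
                "clot_start": scene.meta.clot_x_start,
                "clot_end": scene.meta.clot_x_end,
            }
        )
    manifest = pd.DataFrame(rows)
    tio.write_manifest(out_dir / "manifest.csv", manifest)
    tio.write_provenance(
        out_dir / "provenance.json",
        stage="simulate",
        seed=seed,
        config=dataclasses.asdict(config),
    )
    return scenes, manifest
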