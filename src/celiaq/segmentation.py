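"""Rule-based segmentation stand-in: mask and cell table from a pseudo-IHC render.

This module recovers the two inputs of the downstream morphometry — a tissue-class
mask and a per-cell table — from an RGB image, replacing the (commercial,
non-redistributable) CNN tissue classifier and nuclei-segmentation plug-in with a
deterministic pipeline:

1. H-DAB stain unmixing with the standard published optical-density stain vectors
   (hematoxylin marks all nuclei, DAB marks CD3+ cells);
2. tissue classification of unstained pixels by nearest base tint, with
   stain-covered pixels filled from their nearest unstained neighbour and
   connected components below a minimum object size merged into their
   dominant neighbour class;
3. nuclei detection as Laplacian-of-Gaussian blob maxima on the hematoxylin
   channel, CD3 status from mean DAB optical density around each nucleus, and
   compartment lookup from the class mask at the nucleus centroid.

Coordinates are 0-based, (row, column) = (y, x).  Ties at equal optical density are
broken by scan order (row-major, lowest index wins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import hed2rgb, rgb2hed
from skimage.feature import blob_log

from .containers import CLASS_NAMES, ClassMask, make_cell_table
from .errors import DependencyError, FormatError, UnclassifiedPixelError
from . import synthetic

logger = logging.getLogger(__name__)

#: Default tint rules: reference RGB per class (the generator's base tints).
DEFAULT_TINT_RULES: dict[str, tuple[int, int, int]] = {
    name: tuple(synthetic.CLASS_TINTS[code])
    for code, name in (
        (1, "villous_epithelium"),
        (2, "crypt_epithelium"),
        (3, "lamina_propria"),
        (4, "submucosa"),
        (0, "white_space"),
    )
}


@dataclass
class SegmentationConfig:
    """Thresholds and rules for the rule-based segmentation stand-in.

    ``dab_threshold`` and ``hematoxylin_threshold`` are optical-density thresholds
    (calibrated on the package's own synthetic renders); ``min_object_um2`` is the
    minimum connected-component size kept by the tissue classifier;
    ``analysis_resolution_um_per_px`` is the physical pixel size of the input.
    """

    dab_threshold: float = 0.45
    hematoxylin_threshold: float = 0.30
    min_object_um2: float = 200.0
    analysis_resolution_um_per_px: float = 2.0
    tint_class_rules: dict = field(default_factory=lambda: dict(DEFAULT_TINT_RULES))
    max_tint_distance: float = 60.0  # 8-bit RGB Euclidean distance
    nucleus_radius_um: float = synthetic.NUCLEUS_RADIUS_UM
    cd3_measure_radius_um: float = 2.0

    def __post_init__(self):
        if self.dab_threshold < 0 or self.hematoxylin_threshold < 0:
            raise ValueError("stain thresholds must be >= 0")
        if self.min_object_um2 < 0:
            raise ValueError("min_object_um2 must be >= 0")
        missing = set(CLASS_NAMES) - set(self.tint_class_rules)
        if missing:
            raise ValueError(f"tint_class_rules missing classes: {sorted(missing)}")


def _require_rgb(rgb: np.ndarray) -> np.ndarray:
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise FormatError(f"expected an RGB image (H, W, 3), got shape {arr.shape}")
    return arr


# rgb2hed normalizes by log(1e-6), i.e. 6 decades; rescale so channels are true
# base-10 optical densities (a unit stain deposit reads 1.0).
_OD10_SCALE = 6.0


def unmix_hdab(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Separate an RGB image into (hematoxylin, DAB) optical-density channels.

    Uses the standard published H-DAB stain vectors; assumes the white-background
    convention (255 = no stain).  Channels are in base-10 OD units and clipped at
    zero so both are nonnegative.
    """
    arr = _require_rgb(rgb)
    hed = rgb2hed(arr) * _OD10_SCALE
    return np.maximum(hed[..., 0], 0.0), np.maximum(hed[..., 2], 0.0)


def remix_hdab(h_od: np.ndarray, d_od: np.ndarray) -> np.ndarray:
    """Recompose an RGB uint8 image from hematoxylin/DAB OD channels (eosin = 0)."""
    hed = np.stack([h_od, np.zeros_like(h_od), d_od], axis=-1) / _OD10_SCALE
    return (np.clip(hed2rgb(hed), 0, 1) * 255).round().astype(np.uint8)


def _stain_mask(rgb: np.ndarray, config: SegmentationConfig) -> np.ndarray:
    h_od, d_od = unmix_hdab(rgb)
    return (h_od > config.hematoxylin_threshold) | (d_od > config.dab_threshold)


def _merge_small_objects(labels: np.ndarray, min_px: int) -> np.ndarray:
    """Merge connected components smaller than ``min_px`` into their dominant neighbour."""
    if min_px <= 1:
        return labels
    out = labels.copy()
    for code in np.unique(labels):
        comp, n = ndimage.label(out == code)
        if n == 0:
            continue
        sizes = np.bincount(comp.ravel())
        for cid in range(1, n + 1):
            if sizes[cid] >= min_px:
                continue
            region = comp == cid
            ring = ndimage.binary_dilation(region) & ~region
            if not ring.any():
                continue  # component fills the image
            neighbour_codes, counts = np.unique(out[ring], return_counts=True)
            out[region] = neighbour_codes[np.argmax(counts)]
    return out


def classify_tissue(rgb: np.ndarray, config: SegmentationConfig | None = None) -> ClassMask:
    """Assign every pixel one of the five tissue classes.

    Unstained pixels are classified by nearest reference tint (within
    ``max_tint_distance``); pixels under nuclear/DAB stain are filled from their
    nearest unstained neighbour; components smaller than ``min_object_um2`` are
    merged into their dominant neighbour class.

    Raises
    ------
    UnclassifiedPixelError
        If any unstained pixel matches no tint rule, with the offending count.
    """
    config = config or SegmentationConfig()
    arr = _require_rgb(rgb).astype(float)
    px = config.analysis_resolution_um_per_px

    names = list(config.tint_class_rules)
    refs = np.asarray([config.tint_class_rules[n] for n in names], dtype=float)
    # distance of every pixel to every reference tint
    d2 = ((arr[..., None, :] - refs[None, None, :, :]) ** 2).sum(axis=-1)
    nearest = np.argmin(d2, axis=-1)
    mindist = np.sqrt(np.take_along_axis(d2, nearest[..., None], axis=-1)[..., 0])

    stained = _stain_mask(arr.astype(np.uint8), config)
    uncovered = (~stained) & (mindist > config.max_tint_distance)
    if uncovered.any():
        raise UnclassifiedPixelError(int(uncovered.sum()))

    name_to_code = {"villous_epithelium": 1, "crypt_epithelium": 2, "lamina_propria": 3,
                    "submucosa": 4, "white_space": 0}
    code_lut = np.asarray([name_to_code[n] for n in names])
    labels = code_lut[nearest].astype(np.uint8)

    if stained.any():
        # Stain sits on cells and cells sit in tissue, so stained pixels are
        # filled from the nearest unstained *tissue* pixel when one is within a
        # nucleus diameter; otherwise from the nearest unstained pixel of any
        # class.  Without the tissue preference, cells at the luminal edge of
        # the epithelial band drain into white space.
        cap_px = 2 * config.nucleus_radius_um / px + 2
        tissue_source = ~stained & (labels != name_to_code["white_space"])
        _, (jy, jx) = ndimage.distance_transform_edt(stained, return_indices=True)
        filled = labels[jy, jx]
        if tissue_source.any():
            dist, (iy, ix) = ndimage.distance_transform_edt(
                ~tissue_source, return_indices=True)
            use_tissue = stained & (dist <= cap_px)
            filled = np.where(use_tissue, labels[iy, ix], filled)
        labels = np.where(stained, filled, labels).astype(np.uint8)

    min_px = int(round(config.min_object_um2 / px**2))
    labels = _merge_small_objects(labels, min_px)
    return ClassMask(labels=labels, pixel_size_um=px)


def detect_cells(h_od: np.ndarray, d_od: np.ndarray,
                 config: SegmentationConfig | None = None,
                 mask: ClassMask | None = None):
    """Detect nuclei and call CD3 status; returns a cell table.

    Nuclei are Laplacian-of-Gaussian blob maxima on the hematoxylin channel whose
    optical density exceeds ``hematoxylin_threshold``; a cell is CD3-positive iff
    the mean DAB OD within ``cd3_measure_radius_um`` of its centroid exceeds
    ``dab_threshold``.  The compartment is the class-mask value at the centroid.

    Raises
    ------
    DependencyError
        If ``mask`` is missing (compartments cannot be assigned).
    """
    config = config or SegmentationConfig()
    if mask is None:
        raise DependencyError("detect_cells requires the ClassMask for compartment lookup")
    h_od = np.asarray(h_od, dtype=float)
    d_od = np.asarray(d_od, dtype=float)
    if h_od.shape != d_od.shape or h_od.shape != mask.shape:
        raise FormatError("h_od, d_od and mask must share one shape")

    px = config.analysis_resolution_um_per_px
    r_nuc = max(1.0, config.nucleus_radius_um / px)
    sigma = r_nuc / np.sqrt(2.0)
    blobs = blob_log(h_od, min_sigma=sigma * 0.85, max_sigma=sigma * 1.35,
                     num_sigma=3, threshold=0.08, overlap=0.6)
    if blobs.size == 0:
        return make_cell_table([], [], [], [])

    ys = np.clip(blobs[:, 0].astype(int), 0, h_od.shape[0] - 1)
    xs = np.clip(blobs[:, 1].astype(int), 0, h_od.shape[1] - 1)
    sig = blobs[:, 2]

    keep = h_od[ys, xs] > config.hematoxylin_threshold
    ys, xs, sig = ys[keep], xs[keep], sig[keep]

    # deterministic scan order: row-major, lowest index wins on any tie
    order = np.lexsort((xs, ys))
    ys, xs, sig = ys[order], xs[order], sig[order]

    if (sig >= sigma * 1.35 - 1e-9).any():
        logger.warning("detect_cells: %d blob(s) saturated the scale search; "
                       "possible merged (crowded) nuclei", int((sig >= sigma * 1.35 - 1e-9).sum()))
    if len(ys) > 1:
        from scipy.spatial import cKDTree

        dmin, _ = cKDTree(np.column_stack([ys, xs])).query(
            np.column_stack([ys, xs]), k=2)
        close = dmin[:, 1] < r_nuc
        if close.any():
            logger.warning("detect_cells: %d nuclei closer than one nucleus radius; "
                           "crowded-cell calls may be unreliable", int(close.sum()))

    r_meas = max(1, round(config.cd3_measure_radius_um / px))
    yy, xx = np.mgrid[-r_meas:r_meas + 1, -r_meas:r_meas + 1]
    offsets = np.column_stack([yy.ravel(), xx.ravel()])
    offsets = offsets[(offsets**2).sum(axis=1) <= r_meas**2]

    Hh, Ww = d_od.shape
    py = np.clip(ys[:, None] + offsets[None, :, 0], 0, Hh - 1)
    pxs = np.clip(xs[:, None] + offsets[None, :, 1], 0, Ww - 1)
    mean_dab = d_od[py, pxs].mean(axis=1)
    cd3 = np.where(mean_dab > config.dab_threshold, "positive", "negative")

    comp = [mask.class_at(y, x) for y, x in zip(ys, xs)]
    return make_cell_table(xs, ys, comp, cd3)


def segment_image(rgb: np.ndarray, config: SegmentationConfig | None = None):
    """Full stand-in: RGB render -> (ClassMask, cell table)."""
    config = config or SegmentationConfig()
    mask = classify_tissue(rgb, config)
    h_od, d_od = unmix_hdab(rgb)
    cells = detect_cells(h_od, d_od, config, mask=mask)
    return mask, cells
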