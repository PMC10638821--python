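"""Synthetic duodenal-mucosa cross-sections with ground truth.

Generates 2-D specimens parameterized by modified Marsh type: a five-class tissue
mask (villous epithelium, crypt epithelium, lamina propria, submucosa incl.
Brunner's glands, white space), a per-cell table with CD3 status, and a pseudo-IHC
RGB render (DAB-brown CD3+ cells, hematoxylin-blue nuclei, pale compartment tints
on a white background).

Geometry model
--------------
A submucosal band sits at the bottom of the canvas; above it a mucosal band of
depth ``crypt_depth_um`` holds lamina propria pierced by straight crypt tubes;
villi rise from the mucosal surface as parallel fingers with rounded, sinusoidally
perturbed tips.  The luminal border of the tissue carries an epithelial band of
thickness ``epithelial_band_um`` (villous epithelium); crypt tubes are crypt
epithelium.  Shapes are deliberately simple so the three downstream area ratios
(VE/LP, CE/VE, VE/CE) are controlled by the height/depth/width parameters.

Cellularity model
-----------------
Epithelial nuclei sit on a jittered hexagonal grid of pitch
``enterocyte_spacing_um`` restricted to the epithelial bands.  Each epithelial
cell is CD3+ with probability r/(100+r) where r = ``iel_per_100_enterocytes``, so
positives per 100 CD3-negative enterocytes target r.  Lamina-propria lymphocytes
(all CD3+) are placed at ``lp_lymphocyte_density`` per mm²; they exist precisely
so compartment-restricted counting can be shown to exclude them.

All randomness flows from one seeded generator per specimen.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import distance_transform_edt
from skimage.draw import disk as draw_disk

from .containers import (
    CODE_CE,
    CODE_LP,
    CODE_SUBMUCOSA,
    CODE_VE,
    CODE_WHITE,
    ClassMask,
    make_cell_table,
    save_cell_table,
)
from .errors import CategoryError, DimensionError
from .mls import normalize_marsh

# --------------------------------------------------------------------------------
# Per-Marsh-type geometry defaults (µm except where noted).  Calibrated to the
# qualitative ordering of the disease spectrum: villus height falls and crypt
# depth/width rise with severity; Type 1 (lymphocytosis with preserved
# architecture) is given marginally blunter villi / deeper crypts than Type 0 so
# that cohort medians order strictly.  All values are configurable.
MARSH_GEOMETRY: dict[str, dict] = {
    "0": dict(villus_height_um=400.0, crypt_depth_um=130.0, crypt_width_um=45.0,
              iel_per_100_enterocytes=15.0),
    "1": dict(villus_height_um=380.0, crypt_depth_um=150.0, crypt_width_um=45.0,
              iel_per_100_enterocytes=55.0),
    "2": dict(villus_height_um=400.0, crypt_depth_um=260.0, crypt_width_um=50.0,
              iel_per_100_enterocytes=55.0),
    "3a": dict(villus_height_um=250.0, crypt_depth_um=300.0, crypt_width_um=55.0,
               iel_per_100_enterocytes=60.0),
    "3b": dict(villus_height_um=120.0, crypt_depth_um=350.0, crypt_width_um=58.0,
               iel_per_100_enterocytes=60.0),
    "3c": dict(villus_height_um=30.0, crypt_depth_um=400.0, crypt_width_um=60.0,
               iel_per_100_enterocytes=60.0),
}

#: Parameters shared across types.
SHARED_DEFAULTS = dict(
    n_villi=6,
    villus_width_um=140.0,
    epithelial_band_um=30.0,
    lp_lymphocyte_density=800.0,  # per mm²
    enterocyte_spacing_um=12.0,
    pixel_size_um=2.0,
    canvas_px=(520, 800),
    submucosa_um=120.0,
)

#: Relative jitter applied when drawing per-type parameters (seeded).
LENGTH_JITTER = 0.05
IEL_JITTER = 0.15

#: Amplitude of the sinusoidal villus-tip height perturbation.
TIP_PERTURBATION = 0.05

# Pseudo-IHC base tints per class (RGB, 0-255): pale, mutually distant colors.
CLASS_TINTS: dict[int, tuple[int, int, int]] = {
    CODE_VE: (246, 210, 216),  # pale pink
    CODE_CE: (228, 205, 242),  # pale purple
    CODE_LP: (214, 236, 214),  # pale green
    CODE_SUBMUCOSA: (247, 222, 198),  # pale tan
    CODE_WHITE: (255, 255, 255),
}

# Stain rendering constants: disc radii (µm) and peak optical densities.  Discs are
# kept small relative to the enterocyte spacing so neighbouring cells do not fuse.
NUCLEUS_RADIUS_UM = 3.0
DAB_RADIUS_UM = 5.0
HEMATOXYLIN_OD = 1.0
DAB_OD = 1.0


@dataclass(frozen=True)
class MucosaParams:
    """Full parameterization of one synthetic specimen."""

    marsh_type: str
    n_villi: int
    villus_height_um: float
    villus_width_um: float
    crypt_depth_um: float
    crypt_width_um: float
    epithelial_band_um: float
    lp_lymphocyte_density: float
    iel_per_100_enterocytes: float
    enterocyte_spacing_um: float
    pixel_size_um: float
    canvas_px: tuple[int, int]
    seed: int
    submucosa_um: float = 120.0

    def __post_init__(self):
        object.__setattr__(self, "marsh_type", normalize_marsh(self.marsh_type))
        object.__setattr__(self, "canvas_px", tuple(int(v) for v in self.canvas_px))
        for name in ("villus_width_um", "crypt_depth_um", "crypt_width_um",
                     "epithelial_band_um", "enterocyte_spacing_um", "pixel_size_um",
                     "submucosa_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.villus_height_um < 0 or self.iel_per_100_enterocytes < 0:
            raise ValueError("villus_height_um and iel_per_100_enterocytes must be >= 0")
        if self.n_villi < 1:
            raise ValueError("need at least one villus")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canvas_px"] = list(self.canvas_px)
        return d


@dataclass
class SpecimenTruth:
    """Ground-truth container: parameters, class mask and cell table."""

    params: MucosaParams
    mask: ClassMask
    cells: pd.DataFrame


def default_params_for_marsh(marsh_type: str, seed: int, **overrides) -> MucosaParams:
    """Draw seeded specimen parameters from the per-type default ranges.

    Lengths are jittered ±5% and the IEL target ±15% around the type's center
    values; any field can be pinned via keyword override.

    Raises
    ------
    CategoryError
        For an unknown Marsh type.
    """
    mt = normalize_marsh(marsh_type)  # raises CategoryError on bad input
    if mt not in MARSH_GEOMETRY:  # pragma: no cover - normalize_marsh guards this
        raise CategoryError(f"no geometry defaults for Marsh type {marsh_type!r}")
    rng = np.random.default_rng(seed)
    base = dict(SHARED_DEFAULTS, **MARSH_GEOMETRY[mt])
    drawn = {}
    for key in ("villus_height_um", "crypt_depth_um", "crypt_width_um",
                "villus_width_um", "epithelial_band_um"):
        drawn[key] = base[key] * rng.uniform(1 - LENGTH_JITTER, 1 + LENGTH_JITTER)
    drawn["iel_per_100_enterocytes"] = base["iel_per_100_enterocytes"] * rng.uniform(
        1 - IEL_JITTER, 1 + IEL_JITTER
    )
    params = dict(
        marsh_type=mt,
        n_villi=base["n_villi"],
        lp_lymphocyte_density=base["lp_lymphocyte_density"],
        enterocyte_spacing_um=base["enterocyte_spacing_um"],
        pixel_size_um=base["pixel_size_um"],
        canvas_px=base["canvas_px"],
        submucosa_um=base["submucosa_um"],
        seed=seed,
        **drawn,
    )
    params.update(overrides)
    return MucosaParams(**params)


# --------------------------------------------------------------------------------
# Mask construction


def _build_mask(params: MucosaParams, rng: np.random.Generator) -> ClassMask:
    px = params.pixel_size_um
    H, W = params.canvas_px
    subm_px = max(1, round(params.submucosa_um / px))
    crypt_px = max(1, round(params.crypt_depth_um / px))
    band_px = max(1, round(params.epithelial_band_um / px))
    villus_h_px = params.villus_height_um / px
    w2 = params.villus_width_um / (2 * px)

    needed_um = (params.submucosa_um + params.crypt_depth_um
                 + params.villus_height_um * (1 + TIP_PERTURBATION)
                 + params.epithelial_band_um + 10 * px)
    if needed_um > H * px:
        raise DimensionError(
            f"geometry needs {needed_um:.0f} µm of height but canvas offers {H * px:.0f} µm"
        )
    if params.n_villi * params.villus_width_um > W * px:
        raise DimensionError(
            f"{params.n_villi} villi of width {params.villus_width_um} µm exceed canvas width"
        )

    y_base = H - subm_px          # top row of submucosa
    surf = y_base - crypt_px      # mucosal surface (top of crypt zone)

    yy = np.arange(H)[:, None]
    villus = np.zeros((H, W), dtype=bool)
    phase = rng.uniform(0, 2 * np.pi)
    pitch = W / params.n_villi
    for i in range(params.n_villi):
        cx = (i + 0.5) * pitch
        h_i = villus_h_px * (1 + TIP_PERTURBATION * np.sin(2 * np.pi * cx / W + phase))
        if h_i < 1:
            continue
        x0, x1 = int(np.floor(cx - w2)), int(np.ceil(cx + w2))
        x0, x1 = max(0, x0), min(W, x1)
        dx = (np.arange(x0, x1) - cx) / w2  # -1..1 across the villus
        r_cap = min(w2, h_i)
        # rounded tip: full height at the axis, dropping by r_cap at the flanks
        top = surf - (h_i - r_cap * (1 - np.sqrt(np.clip(1 - dx**2, 0, 1))))
        col_mask = (yy[:, : x1 - x0] >= top[None, :]) & (yy[:, : x1 - x0] < surf)
        villus[:, x0:x1] |= col_mask

    solid = villus | (np.arange(H)[:, None] >= surf)

    # luminal epithelial band: pixels of the solid within band_px of air
    pad = band_px + 2
    padded = np.pad(solid, pad, mode="edge")
    dist = distance_transform_edt(padded)[pad:-pad, pad:-pad]
    ve_band = solid & (dist <= band_px)

    labels = np.full((H, W), CODE_WHITE, dtype=np.uint8)
    labels[surf:y_base, :] = CODE_LP
    labels[y_base:, :] = CODE_SUBMUCOSA
    labels[villus] = CODE_LP  # villus cores
    labels[ve_band] = CODE_VE

    # crypt tubes between villus bases, opening at the surface
    cw2 = params.crypt_width_um / (2 * px)
    for j in range(params.n_villi + 1):
        cx = j * pitch
        x0, x1 = int(round(cx - cw2)), int(round(cx + cw2))
        x0, x1 = max(0, x0), min(W, x1)
        if x1 > x0:
            labels[surf:y_base, x0:x1] = CODE_CE

    return ClassMask(labels=labels, pixel_size_um=px)


# --------------------------------------------------------------------------------
# Cell placement


def _hex_grid(H: int, W: int, pitch: float, rng: np.random.Generator,
              jitter_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Jittered hexagonal grid of points covering the canvas; returns (ys, xs)."""
    row_step = pitch * np.sqrt(3) / 2
    oy = rng.uniform(0, row_step)
    ox = rng.uniform(0, pitch)
    ys_rows = np.arange(oy, H, row_step)
    ys, xs = [], []
    for k, y in enumerate(ys_rows):
        shift = (k % 2) * pitch / 2
        x_row = np.arange(ox + shift, W, pitch)
        xs.append(x_row)
        ys.append(np.full_like(x_row, y))
    ys = np.concatenate(ys) if ys else np.empty(0)
    xs = np.concatenate(xs) if xs else np.empty(0)
    if jitter_px > 0 and len(ys):
        ys = ys + rng.uniform(-jitter_px, jitter_px, len(ys))
        xs = xs + rng.uniform(-jitter_px, jitter_px, len(xs))
    ys = np.clip(np.round(ys).astype(int), 0, H - 1)
    xs = np.clip(np.round(xs).astype(int), 0, W - 1)
    return ys, xs


def _place_cells(params: MucosaParams, mask: ClassMask,
                 rng: np.random.Generator) -> pd.DataFrame:
    px = params.pixel_size_um
    H, W = mask.shape
    labels = mask.labels

    # epithelial nuclei on a jittered hex grid restricted to the epithelium
    pitch = max(2.0, params.enterocyte_spacing_um / px)
    ys, xs = _hex_grid(H, W, pitch, rng, jitter_px=0.5)
    keep = np.isin(labels[ys, xs], (CODE_VE, CODE_CE))
    ys, xs = ys[keep], xs[keep]
    comp = np.where(labels[ys, xs] == CODE_VE, "villous_epithelium", "crypt_epithelium")
    r = params.iel_per_100_enterocytes
    p_pos = r / (100.0 + r)
    cd3 = np.where(rng.random(len(ys)) < p_pos, "positive", "negative")

    # lamina-propria lymphocytes (all CD3+) at the requested areal density
    if params.lp_lymphocyte_density > 0:
        pitch_lp = np.sqrt(1e6 / params.lp_lymphocyte_density) / px  # px between cells
        ys_lp, xs_lp = _hex_grid(H, W, pitch_lp, rng, jitter_px=pitch_lp / 3.5)
        keep = labels[ys_lp, xs_lp] == CODE_LP
        ys_lp, xs_lp = ys_lp[keep], xs_lp[keep]
        ys = np.concatenate([ys, ys_lp])
        xs = np.concatenate([xs, xs_lp])
        comp = np.concatenate([comp, np.full(len(ys_lp), "lamina_propria")])
        cd3 = np.concatenate([cd3, np.full(len(ys_lp), "positive")])

    return make_cell_table(xs, ys, comp, cd3)


def generate_specimen(params: MucosaParams) -> SpecimenTruth:
    """Generate one specimen (mask + cells) deterministically from its parameters."""
    rng = np.random.default_rng(params.seed)
    mask = _build_mask(params, rng)
    cells = _place_cells(params, mask, rng)
    return SpecimenTruth(params=params, mask=mask, cells=cells)


# --------------------------------------------------------------------------------
# Pseudo-IHC rendering


def _stain_vectors() -> tuple[np.ndarray, np.ndarray]:
    """Hematoxylin and DAB optical-density direction vectors (standard H-DAB basis)."""
    from skimage.color import rgb_from_hed

    return rgb_from_hed[0], rgb_from_hed[2]


def stain_od_images(truth: SpecimenTruth) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel hematoxylin and DAB optical densities implied by the cell table."""
    H, W = truth.mask.shape
    px = truth.params.pixel_size_um
    h_od = np.zeros((H, W))
    d_od = np.zeros((H, W))
    r_nuc = max(1.2, NUCLEUS_RADIUS_UM / px)
    r_dab = max(r_nuc + 0.8, DAB_RADIUS_UM / px)
    for row in truth.cells.itertuples(index=False):
        center = (row.y_px, row.x_px)
        rr, cc = draw_disk(center, r_nuc, shape=(H, W))
        h_od[rr, cc] = HEMATOXYLIN_OD
        if row.cd3 == "positive":
            rr, cc = draw_disk(center, r_dab, shape=(H, W))
            d_od[rr, cc] = DAB_OD
    return h_od, d_od


def render_ihc(truth: SpecimenTruth, noise_sd: float = 0.0, seed: int | None = None) -> np.ndarray:
    """Render a pseudo-CD3-IHC RGB image (uint8) of a specimen.

    Compartments receive distinct pale base tints; every nucleus absorbs
    hematoxylin and every CD3+ cell additionally a larger DAB disc, composited by
    Beer-Lambert attenuation of the tint.  Deterministic for a given (truth,
    seed); ``noise_sd`` adds seeded Gaussian noise in 8-bit units.
    """
    v_h, v_d = _stain_vectors()
    tint_lut = np.zeros((max(CLASS_TINTS) + 1, 3))
    for code, rgb in CLASS_TINTS.items():
        tint_lut[code] = np.asarray(rgb) / 255.0
    base = tint_lut[truth.mask.labels]

    h_od, d_od = stain_od_images(truth)
    od = h_od[..., None] * v_h[None, None, :] + d_od[..., None] * v_d[None, None, :]
    rgb = base * np.power(10.0, -od)

    if noise_sd > 0:
        rng = np.random.default_rng(truth.params.seed if seed is None else seed)
        rgb = rgb + rng.normal(0, noise_sd / 255.0, rgb.shape)
    return (np.clip(rgb, 0, 1) * 255).round().astype(np.uint8)


# --------------------------------------------------------------------------------
# Disk output


def save_specimen(truth: SpecimenTruth, out_dir, stem: str,
                  render: bool = False, noise_sd: float = 0.0) -> dict:
    """Write mask PNG + JSON sidecar, cell CSV and (optionally) the RGB render."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mask_path = out_dir / f"{stem}_mask.png"
    truth.mask.save(mask_path, sidecar={"seed": truth.params.seed,
                                        "params": truth.params.to_dict()})
    cells_path = out_dir / f"{stem}_cells.csv"
    save_cell_table(truth.cells, cells_path)
    paths = {"mask": str(mask_path), "sidecar": str(mask_path.with_suffix(".json")),
             "cells": str(cells_path)}
    if render:
        img = render_ihc(truth, noise_sd=noise_sd)
        render_path = out_dir / f"{stem}_ihc.png"
        Image.fromarray(img).save(render_path)
        paths["render"] = str(render_path)
    return paths


# --------------------------------------------------------------------------------
# Lightweight feature-cohort simulator (no images)

#: Anchor feature triples (ve_lp_ratio, ce_ve_ratio, pct_cd3_ve) per Marsh type,
#: consistent with the geometry defaults above; used for fast regression
#: experiments where rendering whole specimens would be wasteful.
FEATURE_ANCHORS: dict[str, tuple[float, float, float]] = {
    "0": (0.63, 0.19, 15.0),
    "1": (0.58, 0.23, 55.0),
    "2": (0.43, 0.42, 55.0),
    "3a": (0.35, 0.71, 60.0),
    "3b": (0.25, 1.22, 60.0),
    "3c": (0.18, 2.00, 60.0),
}


def simulate_feature_cohort(n: int, seed: int) -> tuple[pd.DataFrame, list[str]]:
    """Draw ``n`` plausible (ve_lp_ratio, ce_ve_ratio, pct_cd3_ve) rows with types.

    Types are sampled uniformly; each feature is the type's anchor times a
    ±15% uniform factor.  Returns (features frame, marsh categories).
    """
    rng = np.random.default_rng(seed)
    types = list(FEATURE_ANCHORS)
    picks = rng.choice(len(types), size=n)
    rows, cats = [], []
    for k in picks:
        mt = types[k]
        ve, ce, pct = FEATURE_ANCHORS[mt]
        f = rng.uniform(0.85, 1.15, 3)
        rows.append({"ve_lp_ratio": ve * f[0], "ce_ve_ratio": ce * f[1],
                     "pct_cd3_ve": pct * f[2]})
        cats.append(mt)
    return pd.DataFrame(rows), cats
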