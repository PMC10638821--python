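"""Quantitative features from a tissue-class mask and cell table.

Three surrogate features drive the downstream score:

* ``ve_lp_ratio`` — villous epithelium area / lamina propria area, a surrogate for
  villus height (falls with villus blunting);
* ``ce_ve_ratio`` — crypt epithelium area / villous epithelium area, a surrogate
  for crypt hyperplasia (rises with crypt expansion);
* ``pct_cd3_ve`` — CD3+ intraepithelial lymphocytes per 100 villous enterocytes,
  the intraepithelial-lymphocytosis measure (>40 is the conventional cut-off).

Areas are reported in mm².  The %CD3 denominator defaults to the CD3-negative
epithelial cells of the compartment ("enterocytes"), matching the per-100-enterocytes
convention of IEL counting; an ``all_cells`` mode is available.  Features whose
denominator is zero are carried as missing with a reason code, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CLASS_NAMES, ClassMask
from .errors import UndefinedFeatureError

EPITHELIAL_COMPARTMENTS = ("villous_epithelium", "crypt_epithelium")
DENOMINATOR_MODES = ("enterocytes", "all_cells")


def class_areas(mask: ClassMask) -> dict[str, float]:
    """Per-class areas in mm²: pixel count x (pixel_size_um)² / 10⁶."""
    px_area_mm2 = mask.pixel_size_um**2 / 1e6
    return {name: n * px_area_mm2 for name, n in mask.pixel_counts().items()}


def pct_cd3(cells: pd.DataFrame, compartment: str, denominator_mode: str = "enterocytes") -> float:
    """Percent CD3-positive cells within one epithelial compartment.

    ``enterocytes`` mode (default): 100 x positives / negatives — positives per 100
    enterocytes, the IEL convention (may exceed 100).  ``all_cells`` mode:
    100 x positives / (positives + negatives).  CD3+ cells outside the requested
    compartment (e.g. lamina-propria T cells) are never counted.

    Raises
    ------
    UndefinedFeatureError
        If the denominator is zero, naming the compartment.
    """
    if compartment not in EPITHELIAL_COMPARTMENTS:
        raise ValueError(f"pct_cd3 is defined for {EPITHELIAL_COMPARTMENTS}, got {compartment!r}")
    if denominator_mode not in DENOMINATOR_MODES:
        raise ValueError(f"denominator_mode must be one of {DENOMINATOR_MODES}")
    sub = cells[cells["compartment"] == compartment]
    n_pos = int((sub["cd3"] == "positive").sum())
    n_neg = int((sub["cd3"] == "negative").sum())
    denom = n_neg if denominator_mode == "enterocytes" else n_pos + n_neg
    if denom == 0:
        raise UndefinedFeatureError(
            f"pct_cd3_{'ve' if compartment == 'villous_epithelium' else 'ce'}",
            f"no {'CD3-negative ' if denominator_mode == 'enterocytes' else ''}cells in {compartment}",
        )
    return 100.0 * n_pos / denom


@dataclass
class FeatureVector:
    """All per-specimen quantitative features.

    Ratio/percent fields are ``None`` when undefined; the reason is recorded in
    ``missing`` under the feature name.
    """

    area_mm2: dict[str, float]
    total_tissue_area_mm2: float
    ve_lp_ratio: float | None
    ce_ve_ratio: float | None
    ve_ce_ratio: float | None
    pct_cd3_ve: float | None
    pct_cd3_ce: float | None
    n_cells: dict[str, dict[str, int]]  # compartment -> {"positive": n, "negative": n}
    denominator_mode: str = "enterocytes"
    missing: dict[str, str] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {f"area_mm2_{k}": v for k, v in self.area_mm2.items()}
        row["total_tissue_area_mm2"] = self.total_tissue_area_mm2
        for name in ("ve_lp_ratio", "ce_ve_ratio", "ve_ce_ratio", "pct_cd3_ve", "pct_cd3_ce"):
            row[name] = getattr(self, name)
        for comp, d in self.n_cells.items():
            row[f"n_{comp}_positive"] = d["positive"]
            row[f"n_{comp}_negative"] = d["negative"]
        return row


def _ratio(num: float, den: float, name: str, missing: dict[str, str]) -> float | None:
    if den == 0:
        missing[name] = "zero denominator"
        return None
    return num / den


def compute_features(
    mask: ClassMask, cells: pd.DataFrame, denominator_mode: str = "enterocytes"
) -> FeatureVector:
    """Compute the full feature vector for one specimen.

    The mask and cell table must share a coordinate frame (0-based row/column).
    Undefined ratios are carried as missing with a reason, not dropped or zeroed.
    """
    areas = class_areas(mask)
    total = sum(v for k, v in areas.items() if k != "white_space")
    missing: dict[str, str] = {}

    ve, ce, lp = (areas[k] for k in ("villous_epithelium", "crypt_epithelium", "lamina_propria"))
    ve_lp = _ratio(ve, lp, "ve_lp_ratio", missing)
    ce_ve = _ratio(ce, ve, "ce_ve_ratio", missing)
    ve_ce = _ratio(ve, ce, "ve_ce_ratio", missing)

    pct = {}
    for comp, name in zip(EPITHELIAL_COMPARTMENTS, ("pct_cd3_ve", "pct_cd3_ce")):
        try:
            pct[name] = pct_cd3(cells, comp, denominator_mode)
        except UndefinedFeatureError as e:
            pct[name] = None
            missing[name] = e.reason

    n_cells = {}
    for comp in CLASS_NAMES:
        sub = cells[cells["compartment"] == comp]
        n_cells[comp] = {
            "positive": int((sub["cd3"] == "positive").sum()),
            "negative": int((sub["cd3"] == "negative").sum()),
        }

    return FeatureVector(
        area_mm2=areas,
        total_tissue_area_mm2=total,
        ve_lp_ratio=ve_lp,
        ce_ve_ratio=ce_ve,
        ve_ce_ratio=ve_ce,
        pct_cd3_ve=pct["pct_cd3_ve"],
        pct_cd3_ce=pct["pct_cd3_ce"],
        n_cells=n_cells,
        denominator_mode=denominator_mode,
        missing=missing,
    )


def features_to_frame(features: list[FeatureVector], ids=None) -> pd.DataFrame:
    """One-specimen-per-row table of feature vectors (for CSV export)."""
    rows = [f.as_row() for f in features]
    df = pd.DataFrame(rows)
    if ids is not None:
        df.insert(0, "specimen_id", list(ids))
    return df
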