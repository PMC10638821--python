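"""Shared data containers: tissue-class masks and per-cell tables.

Coordinate convention (used everywhere in this package): 0-based, (row, column) =
(y, x); ``x_px`` indexes columns, ``y_px`` indexes rows.  A mask pixel for a cell at
(x_px, y_px) is ``mask.labels[y_px, x_px]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import FormatError

#: The five tissue classes, in canonical order.  Submucosa includes Brunner's glands.
CLASS_NAMES: tuple[str, ...] = (
    "villous_epithelium",
    "crypt_epithelium",
    "lamina_propria",
    "submucosa",
    "white_space",
)

#: Fixed label codes.  white_space is 0 so a zero-initialized canvas is "empty slide".
CODE_WHITE = 0
CODE_VE = 1
CODE_CE = 2
CODE_LP = 3
CODE_SUBMUCOSA = 4

DEFAULT_CLASS_MAP: dict[int, str] = {
    CODE_VE: "villous_epithelium",
    CODE_CE: "crypt_epithelium",
    CODE_LP: "lamina_propria",
    CODE_SUBMUCOSA: "submucosa",
    CODE_WHITE: "white_space",
}

CELL_COLUMNS = ("x_px", "y_px", "compartment", "cd3")


@dataclass
class ClassMask:
    """Single-channel tissue-class label image with physical pixel size.

    Every pixel carries exactly one of the five class codes; ``class_map`` is a
    bijection code -> class name; ``pixel_size_um`` is micrometres per pixel.
    """

    labels: np.ndarray
    pixel_size_um: float
    class_map: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_CLASS_MAP))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError(f"class mask must be 2-D, got shape {self.labels.shape}")
        if self.pixel_size_um <= 0:
            raise FormatError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        names = sorted(self.class_map.values())
        if names != sorted(CLASS_NAMES):
            raise FormatError(f"class_map must cover exactly {CLASS_NAMES}, got {names}")
        codes = set(self.class_map)
        present = set(np.unique(self.labels).tolist())
        if not present <= codes:
            raise FormatError(f"mask contains codes {present - codes} absent from class_map")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def code_for(self, class_name: str) -> int:
        for code, name in self.class_map.items():
            if name == class_name:
                return code
        raise KeyError(class_name)

    def class_at(self, y_px: int, x_px: int) -> str:
        return self.class_map[int(self.labels[y_px, x_px])]

    def pixel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=max(self.class_map) + 1)
        return {name: int(counts[code]) for code, name in self.class_map.items()}

    # ---- disk round trip: 8-bit PNG + JSON sidecar -------------------------------
    def save(self, png_path, sidecar: dict | None = None) -> None:
        png_path = Path(png_path)
        Image.fromarray(self.labels.astype(np.uint8), mode="L").save(png_path)
        meta = {
            "class_map": {str(k): v for k, v in self.class_map.items()},
            "pixel_size_um": self.pixel_size_um,
            "coordinates": "0-based, (row, column) = (y, x)",
        }
        if sidecar:
            meta.update(sidecar)
        png_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, png_path) -> "ClassMask":
        png_path = Path(png_path)
        sidecar = png_path.with_suffix(".json")
        if not sidecar.exists():
            raise FormatError(f"mask sidecar {sidecar} not found")
        meta = json.loads(sidecar.read_text())
        labels = np.asarray(Image.open(png_path), dtype=np.uint8)
        class_map = {int(k): v for k, v in meta["class_map"].items()}
        return cls(labels=labels, pixel_size_um=float(meta["pixel_size_um"]), class_map=class_map)


def empty_cell_table() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                         zip(CELL_COLUMNS, (int, int, str, str))})


def make_cell_table(x_px, y_px, compartment, cd3) -> pd.DataFrame:
    """Assemble a cell table; ``cd3`` entries are 'positive' or 'negative'."""
    df = pd.DataFrame(
        {"x_px": np.asarray(x_px, dtype=int), "y_px": np.asarray(y_px, dtype=int),
         "compartment": list(compartment), "cd3": list(cd3)}
    )
    bad = set(df["cd3"].unique()) - {"positive", "negative"}
    if bad:
        raise FormatError(f"cd3 column must be 'positive'/'negative', found {bad}")
    bad = set(df["compartment"].unique()) - set(CLASS_NAMES)
    if bad:
        raise FormatError(f"unknown compartments in cell table: {bad}")
    return df


def save_cell_table(cells: pd.DataFrame, csv_path) -> None:
    """CSV with header x_px,y_px,compartment,cd3; coordinates are 0-based (y=row, x=column)."""
    cells.loc[:, list(CELL_COLUMNS)].to_csv(csv_path, index=False)


def load_cell_table(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, comment="#")
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"cell table {csv_path} missing columns {sorted(missing)}")
    return make_cell_table(df["x_px"], df["y_px"], df["compartment"], df["cd3"])
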