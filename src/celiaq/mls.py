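"""The combined-feature machine learning score (MLS) for celiac-disease histology.

The modified Marsh (Marsh-Oberhuber) classification grades duodenal biopsies on an
ordinal scale 0, 1, 2, 3a, 3b, 3c by combining intraepithelial lymphocytosis, crypt
hyperplasia and villus blunting.  The MLS condenses three quantitative surrogates of
those features into one continuous score via an affine model::

    MLS = b0 + b1 * (VE/LP area ratio) + b2 * (CE/VE area ratio) + b3 * (%CD3 VE / 100)

where VE = villous epithelium, CE = crypt epithelium, LP = lamina propria and
%CD3 VE is the density of CD3+ intraepithelial lymphocytes per 100 villous
enterocytes.  The published constants are (0.872, -1.03, +0.20, +3.92); the %CD3
term enters as a proportion (percent / 100), which is the only scale at which the
published coefficient produces scores on the Marsh grid (3.92 * 0.419 = 1.64, versus
an absurd 164 on the percent scale).

Sub-grades 3a/3b/3c map to the numeric grid 3.0 / 3.333 / 3.666; a continuous score
is converted back to an ordinal category by nearest grid value (exact ties go to the
lower, less-diseased category).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import CategoryError, FitError, ScoringError

#: Canonical Marsh categories in severity order.
MARSH_CATEGORIES: tuple[str, ...] = ("0", "1", "2", "3a", "3b", "3c")

#: Numeric grid for the six categories.  The 3-decimal constants 3.333 / 3.666 are
#: used verbatim (not 10/3, 11/3) so ordinal-conversion boundaries are exact.
MARSH_NUMERIC: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 3.333, 3.666)

_CATEGORY_TO_NUMERIC = dict(zip(MARSH_CATEGORIES, MARSH_NUMERIC))


def normalize_marsh(category: str) -> str:
    """Return the canonical lowercase form of a Marsh category, validating it."""
    cat = str(category).strip().lower()
    if cat not in _CATEGORY_TO_NUMERIC:
        raise CategoryError(
            f"unknown modified Marsh category {category!r}; expected one of {MARSH_CATEGORIES}"
        )
    return cat


def marsh_to_numeric(category: str) -> float:
    """Map a modified Marsh category to its numeric grid value.

    0 -> 0.0, 1 -> 1.0, 2 -> 2.0, 3a -> 3.0, 3b -> 3.333, 3c -> 3.666.
    """
    return _CATEGORY_TO_NUMERIC[normalize_marsh(category)]


def to_ordinal(mls_value: float) -> str:
    """Convert a continuous MLS to the nearest Marsh category on the numeric grid.

    Exact ties are broken toward the lower (less diseased) category.

    Raises
    ------
    ValueError
        If ``mls_value`` is not finite.
    """
    v = float(mls_value)
    if not np.isfinite(v):
        raise ValueError(f"cannot convert non-finite MLS {mls_value!r} to an ordinal grade")
    dist = np.abs(np.asarray(MARSH_NUMERIC) - v)
    return MARSH_CATEGORIES[int(np.argmin(dist))]  # argmin takes the first (lower) on ties


@dataclass(frozen=True)
class FitDiagnostics:
    """OLS diagnostics for a fitted MLS model."""

    r_squared: float
    f_statistic: float
    df_model: int
    df_resid: int
    p_values: dict  # term name -> two-sided p-value
    std_errors: dict  # term name -> coefficient standard error
    n: int


@dataclass(frozen=True)
class MLSModel:
    """Affine MLS model: intercept plus coefficients on the three surrogate features.

    ``coef_pct_cd3_ve`` is per unit *proportion* (the scorer divides percent input
    by 100 before applying it).
    """

    intercept: float
    coef_ve_ratio: float
    coef_ce_ratio: float
    coef_pct_cd3_ve: float
    provenance: str = "published"  # "published" | "fitted"
    diagnostics: FitDiagnostics | None = field(default=None, compare=False)

    def coefficients(self) -> np.ndarray:
        return np.array([self.coef_ve_ratio, self.coef_ce_ratio, self.coef_pct_cd3_ve])

    def to_dict(self) -> dict:
        d = {
            "intercept": self.intercept,
            "coefficients": {
                "ve_lp_ratio": self.coef_ve_ratio,
                "ce_ve_ratio": self.coef_ce_ratio,
                "pct_cd3_ve": self.coef_pct_cd3_ve,
            },
            "provenance": self.provenance,
        }
        if self.diagnostics is not None:
            d["diagnostics"] = {
                "r_squared": self.diagnostics.r_squared,
                "f_statistic": self.diagnostics.f_statistic,
                "df": [self.diagnostics.df_model, self.diagnostics.df_resid],
                "p_values": self.diagnostics.p_values,
                "std_errors": self.diagnostics.std_errors,
                "n": self.diagnostics.n,
            }
        return d


def published_model() -> MLSModel:
    """The published MLS constants: intercept 0.872, coefficients -1.03, +0.20, +3.92."""
    return MLSModel(
        intercept=0.872,
        coef_ve_ratio=-1.03,
        coef_ce_ratio=0.20,
        coef_pct_cd3_ve=3.92,
        provenance="published",
    )


_FEATURE_NAMES = ("ve_lp_ratio", "ce_ve_ratio", "pct_cd3_ve")


def _extract_features(features) -> tuple[float, float, float]:
    """Pull (ve_lp_ratio, ce_ve_ratio, pct_cd3_ve) from a FeatureVector or mapping."""
    vals = []
    for name in _FEATURE_NAMES:
        if isinstance(features, Mapping):
            v = features.get(name)
        else:
            v = getattr(features, name, None)
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            raise ScoringError(f"cannot score: feature '{name}' is missing or undefined")
        vals.append(float(v))
    return tuple(vals)


def score(model: MLSModel, features) -> float:
    """Continuous MLS for one specimen.

    ``features`` may be a ``FeatureVector`` or any mapping exposing ``ve_lp_ratio``,
    ``ce_ve_ratio`` and ``pct_cd3_ve``.  ``pct_cd3_ve`` is expected on the percent
    scale (e.g. 41.9) and is divided by 100 internally.  Scores may be negative;
    no clamping is applied.
    """
    ve, ce, pct = _extract_features(features)
    return (
        model.intercept
        + model.coef_ve_ratio * ve
        + model.coef_ce_ratio * ce
        + model.coef_pct_cd3_ve * (pct / 100.0)
    )


def fit_mls(feature_rows, marsh_numeric_targets: Sequence[float]) -> MLSModel:
    """Fit the MLS model by ordinary least squares with intercept.

    Parameters
    ----------
    feature_rows
        Sequence of FeatureVectors / mappings with the three features (``pct_cd3_ve``
        on the percent scale), or an (n, 3) array already on the model scale
        *except* that column 2 is percent and is divided by 100 here.
    marsh_numeric_targets
        Numeric Marsh grid values (see :func:`marsh_to_numeric`), one per row.

    Returns an :class:`MLSModel` with provenance ``"fitted"`` and populated
    diagnostics: R^2, overall F with (3, n-4) degrees of freedom, and two-sided
    coefficient p-values.
    """
    import statsmodels.api as sm

    rows = [_extract_features(r) for r in feature_rows] if not isinstance(
        feature_rows, np.ndarray
    ) else [tuple(r) for r in np.asarray(feature_rows, dtype=float)]
    X = np.asarray(rows, dtype=float)
    y = np.asarray(marsh_numeric_targets, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise FitError(f"expected 3 features per row, got shape {X.shape}")
    if len(y) != len(X):
        raise FitError(f"{len(X)} feature rows but {len(y)} targets")
    n = len(X)
    if n < 5:
        raise FitError(f"need at least 5 rows to fit 4 parameters, got {n}")
    X = X.copy()
    X[:, 2] = X[:, 2] / 100.0  # percent -> proportion, the model's internal scale

    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("design matrix is rank deficient; features are collinear")
    res = sm.OLS(y, design).fit()
    names = ("intercept",) + _FEATURE_NAMES
    diag = FitDiagnostics(
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p_values={k: float(p) for k, p in zip(names, res.pvalues)},
        std_errors={k: float(s) for k, s in zip(names, res.bse)},
        n=n,
    )
    b = res.params
    return MLSModel(
        intercept=float(b[0]),
        coef_ve_ratio=float(b[1]),
        coef_ce_ratio=float(b[2]),
        coef_pct_cd3_ve=float(b[3]),
        provenance="fitted",
        diagnostics=diag,
    )
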