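"""Statistical evaluation: grouped comparisons, confusion matrices and the
paired-biopsy response-alignment analysis.

The paired analysis asks whether the direction of change of the continuous MLS
between a pre- and a post-intervention biopsy agrees with the manual modified
Marsh response.  The alignment rule: a pair is *aligned* when

* the Marsh grade improved and the MLS decreased, or
* the Marsh grade worsened and the MLS increased, or
* the Marsh grade is unchanged and |ΔMLS| ≤ tol (default 0.333, one Marsh
  sub-step on the numeric grid).

Group comparisons use the classic pooled-variance (Student) unpaired two-tailed
t-test by default (Welch available), with the effect size reported as
eta squared = t² / (t² + df).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CategoryError, InsufficientDataError, IntegrityError
from .mls import MARSH_CATEGORIES, marsh_to_numeric, normalize_marsh

#: sha256 of the packaged paired-biopsy fixture (integrity-checked on load).
TABLE3_SHA256 = "5824451605e54b21e4e826cfa66fad538d44154db3c3522fdd3e5cf4b8dc6f6f"

DEFAULT_ALIGNMENT_TOL = 0.333


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------------
# Grouped comparison


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison result (t-test, CI, medians, eta squared)."""

    grouping_name: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    mean_diff: float
    mean_diff_ci95: tuple[float, float]
    t_statistic: float
    df: float
    p_two_sided: float
    eta_squared: float


def group_compare(values, group_labels, grouping_name: str = "",
                  welch: bool = False) -> GroupComparison:
    """Unpaired two-tailed t-test between two groups of values.

    Groups are identified by the two distinct labels in order of first
    appearance (group a first); the reported difference is mean(a) - mean(b).
    Pooled-variance (Student) by default; ``welch=True`` switches to the
    Welch unequal-variance test.  eta squared = t²/(t²+df).
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if len(values) != len(group_labels):
        raise ValueError("values and group_labels must have equal length")
    uniq = list(pd.unique(group_labels))
    if len(uniq) != 2:
        raise InsufficientDataError(f"need exactly 2 groups, got {len(uniq)}")
    a = values[group_labels == uniq[0]]
    b = values[group_labels == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs at least 2 values")

    na, nb = len(a), len(b)
    diff = a.mean() - b.mean()
    if welch:
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        se = np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
    if se == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
    else:
        t = diff / se
    p = 2 * stats.t.sf(abs(t), df) if np.isfinite(t) else 0.0
    tcrit = stats.t.ppf(0.975, df)
    ci = (diff - tcrit * se, diff + tcrit * se)
    eta2 = t**2 / (t**2 + df) if np.isfinite(t) else 1.0
    return GroupComparison(
        grouping_name=grouping_name or f"{uniq[0]} vs {uniq[1]}",
        n_a=na, n_b=nb,
        median_a=float(np.median(a)), median_b=float(np.median(b)),
        mean_diff=float(diff), mean_diff_ci95=(float(ci[0]), float(ci[1])),
        t_statistic=float(t), df=float(df), p_two_sided=float(p),
        eta_squared=float(eta2),
    )


# --------------------------------------------------------------------------------
# Confusion matrix


def confusion_matrix(marsh_categories, ordinal_mls_categories) -> pd.DataFrame:
    """6x6 count matrix: rows = manual Marsh type, columns = ordinal MLS grade.

    Both axes are ordered 0, 1, 2, 3a, 3b, 3c; counts sum to n.
    """
    truth = [normalize_marsh(c) for c in marsh_categories]
    pred = [normalize_marsh(c) for c in ordinal_mls_categories]
    if len(truth) != len(pred):
        raise CategoryError("category vectors must have equal length")
    cats = list(MARSH_CATEGORIES)
    tab = pd.crosstab(pd.Categorical(truth, categories=cats),
                      pd.Categorical(pred, categories=cats), dropna=False)
    tab = tab.reindex(index=cats, columns=cats, fill_value=0)
    tab.index.name = "marsh"
    tab.columns.name = "mls_ordinal"
    return tab


# --------------------------------------------------------------------------------
# Paired-biopsy analysis


@dataclass(frozen=True)
class PairedRecord:
    """One pre/post biopsy pair with its response and alignment verdict."""

    pair_id: str
    pre_marsh: str
    post_marsh: str
    pre_mls: float
    post_mls: float
    marsh_response: str  # improved | unchanged | worsened
    mls_direction: str  # decreased | increased | stable-within-tol
    aligned: bool
    tol: float


def classify_pair(pre_marsh: str, post_marsh: str, pre_mls: float, post_mls: float,
                  tol: float = DEFAULT_ALIGNMENT_TOL, pair_id: str = "") -> PairedRecord:
    """Derive the Marsh response, MLS direction and alignment verdict for one pair."""
    pre_n = marsh_to_numeric(pre_marsh)
    post_n = marsh_to_numeric(post_marsh)
    delta = float(post_mls) - float(pre_mls)
    if post_n < pre_n:
        response = "improved"
    elif post_n > pre_n:
        response = "worsened"
    else:
        response = "unchanged"
    if abs(delta) <= tol:
        direction = "stable-within-tol"
    else:
        direction = "decreased" if delta < 0 else "increased"
    aligned = (
        (response == "improved" and delta < 0)
        or (response == "worsened" and delta > 0)
        or (response == "unchanged" and abs(delta) <= tol)
    )
    return PairedRecord(
        pair_id=str(pair_id),
        pre_marsh=normalize_marsh(pre_marsh), post_marsh=normalize_marsh(post_marsh),
        pre_mls=float(pre_mls), post_mls=float(post_mls),
        marsh_response=response, mls_direction=direction, aligned=aligned, tol=tol,
    )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level summary of a paired-biopsy analysis."""

    n_pairs: int
    n_responders: int
    n_aligned: int
    n_aligned_responders: int
    aligned_overall_pct: float
    aligned_among_responders_pct: float | None
    median_pre_mls: float
    median_post_mls: float
    range_pre_mls: tuple[float, float]
    range_post_mls: tuple[float, float]
    tol: float


def cohort_summary(records: list[PairedRecord]) -> CohortSummary:
    """Summarize paired records: alignment percentages (half-up to one decimal),
    mid-rank medians and (min, max) ranges of the continuous scores."""
    if not records:
        raise InsufficientDataError("cohort_summary needs at least one paired record")
    n = len(records)
    responders = [r for r in records if r.marsh_response == "improved"]
    aligned = [r for r in records if r.aligned]
    aligned_resp = [r for r in responders if r.aligned]
    pre = np.array([r.pre_mls for r in records])
    post = np.array([r.post_mls for r in records])
    return CohortSummary(
        n_pairs=n,
        n_responders=len(responders),
        n_aligned=len(aligned),
        n_aligned_responders=len(aligned_resp),
        aligned_overall_pct=_round_half_up(100.0 * len(aligned) / n),
        aligned_among_responders_pct=(
            _round_half_up(100.0 * len(aligned_resp) / len(responders))
            if responders else None
        ),
        median_pre_mls=float(np.median(pre)),
        median_post_mls=float(np.median(post)),
        range_pre_mls=(float(pre.min()), float(pre.max())),
        range_post_mls=(float(post.min()), float(post.max())),
        tol=records[0].tol,
    )


def evaluate_pairs(pairs: pd.DataFrame, tol: float = DEFAULT_ALIGNMENT_TOL
                   ) -> tuple[list[PairedRecord], CohortSummary]:
    """Classify every pair of a pairs table and summarize the cohort.

    Expects columns pair_id, pre_marsh, post_marsh, pre_mls, post_mls.
    """
    records = [
        classify_pair(row.pre_marsh, row.post_marsh, row.pre_mls, row.post_mls,
                      tol=tol, pair_id=row.pair_id)
        for row in pairs.itertuples(index=False)
    ]
    return records, cohort_summary(records)


# --------------------------------------------------------------------------------
# Packaged fixture


def load_paired_fixture() -> pd.DataFrame:
    """Load the packaged 28-pair paired-biopsy dataset, verifying its checksum."""
    try:
        raw = resources.files("celiaq.data").joinpath("table3_pairs.csv").read_bytes()
    except FileNotFoundError as e:  # pragma: no cover
        raise IntegrityError("packaged fixture table3_pairs.csv is missing") from e
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE3_SHA256:
        raise IntegrityError(
            f"table3_pairs.csv checksum mismatch: {digest} != {TABLE3_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), comment="#")
    df["pre_marsh"] = df["pre_marsh"].astype(str)
    df["post_marsh"] = df["post_marsh"].astype(str)
    return df


# --------------------------------------------------------------------------------
# Per-feature directional concordance


#: Direction each surrogate feature moves on mucosal recovery.
RECOVERY_DIRECTION = {"ve_lp_ratio": +1, "ce_ve_ratio": -1, "pct_cd3_ve": -1}


def feature_deltas(pre_features, post_features) -> dict[str, float | None]:
    """Signed post-minus-pre change of each surrogate feature (None if missing)."""
    out = {}
    for name in RECOVERY_DIRECTION:
        pre = pre_features.get(name) if isinstance(pre_features, dict) else getattr(pre_features, name, None)
        post = post_features.get(name) if isinstance(post_features, dict) else getattr(post_features, name, None)
        out[name] = None if pre is None or post is None else float(post) - float(pre)
    return out


def feature_direction_audit(paired_feature_rows) -> dict[str, dict[str, int]]:
    """Directional concordance of each surrogate feature among responder pairs.

    ``paired_feature_rows`` is an iterable of (pre_features, post_features,
    marsh_response) triples; features may be FeatureVectors or mappings.  For
    pairs whose Marsh grade improved, a feature is *concordant* when it moved in
    the recovery direction (VE/LP ratio up, CE/VE ratio down, %CD3 VE down).
    Pairs with a missing feature are excluded from that feature's counts and
    reported under ``missing``.
    """
    counts = {name: {"concordant": 0, "discordant": 0, "missing": 0}
              for name in RECOVERY_DIRECTION}
    for pre_f, post_f, response in paired_feature_rows:
        if response != "improved":
            continue
        deltas = feature_deltas(pre_f, post_f)
        for name, sign in RECOVERY_DIRECTION.items():
            d = deltas[name]
            if d is None:
                counts[name]["missing"] += 1
            elif d * sign > 0:
                counts[name]["concordant"] += 1
            else:
                counts[name]["discordant"] += 1
    return counts
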