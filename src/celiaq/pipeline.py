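"""Pipeline orchestration: simulate -> (render + segment) -> features -> score ->
evaluate, plus the one-command reproduction of the paired-biopsy analysis."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .containers import ClassMask
from .errors import ConfigError
from .evaluation import (
    DEFAULT_ALIGNMENT_TOL,
    confusion_matrix,
    evaluate_pairs,
    load_paired_fixture,
)
from .mls import MLSModel, published_model, score, to_ordinal
from .morphometry import compute_features, features_to_frame
from .segmentation import segment_image
from .synthetic import default_params_for_marsh, generate_specimen, render_ihc

logger = logging.getLogger(__name__)


def specimen_seed(base_seed: int, index: int) -> int:
    """Deterministic per-specimen seed (< 2^31) derived from the run seed."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def model_from_source(source: str) -> MLSModel:
    """Resolve ``model_source``: the published constants or a model-JSON path."""
    if source == "published":
        return published_model()
    path = Path(source)
    if not path.exists():
        raise ConfigError(f"model_source {source!r} is neither 'published' nor an existing file")
    d = json.loads(path.read_text())
    c = d["coefficients"]
    return MLSModel(
        intercept=float(d["intercept"]),
        coef_ve_ratio=float(c["ve_lp_ratio"]),
        coef_ce_ratio=float(c["ce_ve_ratio"]),
        coef_pct_cd3_ve=float(c["pct_cd3_ve"]),
        provenance=d.get("provenance", "fitted"),
    )


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute the full analysis workflow on synthetic specimens.

    For every Marsh type in ``config.marsh_types``, ``config.n_per_type``
    specimens are generated.  In ``truth`` mode features come straight from the
    generator's mask and cells; in ``segmentation`` mode each specimen is
    rendered to pseudo-IHC and re-segmented first.  Every specimen is scored with
    the configured model and converted to an ordinal grade; a confusion matrix
    against the generating Marsh types closes the run.

    Returns a bundle dict with feature/score frames, the confusion matrix and
    provenance; with ``write=True`` all artifacts are also written under
    ``config.out_dir``.
    """
    model = model_from_source(config.model_source)
    seg_cfg = config.segmentation_config()

    feature_vectors, ids, types, mls_values, ordinals = [], [], [], [], []
    index = 0
    for mt in config.marsh_types:
        overrides = config.generator_overrides(mt)
        for k in range(config.n_per_type):
            seed = specimen_seed(config.seed, index)
            index += 1
            params = default_params_for_marsh(mt, seed, **overrides)
            truth = generate_specimen(params)
            if config.mode == "segmentation":
                img = render_ihc(truth, noise_sd=config.noise_sd)
                mask, cells = segment_image(img, seg_cfg)
                mask = ClassMask(labels=mask.labels, pixel_size_um=params.pixel_size_um,
                                 class_map=mask.class_map)
            else:
                mask, cells = truth.mask, truth.cells
            fv = compute_features(mask, cells, config.denominator_mode)
            feature_vectors.append(fv)
            ids.append(f"{mt}_{k:02d}")
            types.append(mt)
            mls = score(model, fv)
            mls_values.append(mls)
            ordinals.append(to_ordinal(mls))

    features = features_to_frame(feature_vectors, ids=ids)
    features.insert(1, "marsh_type", types)
    scores = pd.DataFrame(
        {"specimen_id": ids, "marsh_type": types, "mls": mls_values, "mls_ordinal": ordinals}
    )
    confusion = confusion_matrix(types, ordinals)

    provenance = {
        "seed": config.seed,
        "config_hash": config.hash(),
        "version": __version__,
        "mode": config.mode,
        "denominator_mode": config.denominator_mode,
        "model_provenance": model.provenance,
    }
    bundle = {
        "features": features,
        "scores": scores,
        "confusion": confusion,
        "feature_vectors": feature_vectors,
        "provenance": provenance,
    }
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features.to_csv(out / "features.csv", index=False)
        scores.to_csv(out / "scores.csv", index=False)
        confusion.to_csv(out / "confusion.csv")
        report = {
            "provenance": provenance,
            "n_specimens": len(ids),
            "model": model.to_dict(),
        }
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "features.meta.json").write_text(json.dumps(
            {"denominator_mode": config.denominator_mode, **provenance}, indent=2))
    return bundle


# --------------------------------------------------------------------------------
# Paired-biopsy reproduction

#: Reference values the paired-biopsy analysis is checked against.
PAIRED_REFERENCE = {
    "aligned_overall_pct": 96.4,
    "aligned_among_responders_pct": 100.0,
    "n_responders": 27,
    "median_pre_mls": 2.72,
    "median_post_mls": 0.78,
    "range_pre_mls": (0.82, 4.28),
    "min_post_mls": -1.23,
}

_MEDIAN_TOL = 0.01


def reproduce_paired_analysis(tol: float = DEFAULT_ALIGNMENT_TOL) -> dict:
    """Recompute the paired-biopsy cohort summary from the packaged 28-pair
    dataset and compare it with the reference values.

    Returns a report dict with the computed summary, per-quantity pass/fail
    comparisons, and an overall ``all_match`` flag.
    """
    pairs = load_paired_fixture()
    records, summary = evaluate_pairs(pairs, tol=tol)

    computed = {
        "aligned_overall_pct": summary.aligned_overall_pct,
        "aligned_among_responders_pct": summary.aligned_among_responders_pct,
        "n_responders": summary.n_responders,
        "median_pre_mls": summary.median_pre_mls,
        "median_post_mls": summary.median_post_mls,
        "range_pre_mls": summary.range_pre_mls,
        "min_post_mls": summary.range_post_mls[0],
    }
    checks = {}
    for key, ref in PAIRED_REFERENCE.items():
        got = computed[key]
        if key.startswith("median"):
            ok = abs(got - ref) <= _MEDIAN_TOL
        elif key == "range_pre_mls":
            ok = tuple(round(v, 2) for v in got) == ref
        else:
            ok = got == ref
        checks[key] = {"computed": got, "reference": ref, "match": bool(ok)}

    return {
        "tol": tol,
        "n_pairs": summary.n_pairs,
        "summary": {
            **computed,
            "n_aligned": summary.n_aligned,
            "range_post_mls": summary.range_post_mls,
        },
        "records": [r.__dict__ for r in records],
        "checks": checks,
        "all_match": all(c["match"] for c in checks.values()),
    }
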