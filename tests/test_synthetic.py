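"""The synthetic specimen generator: geometry, cellularity, determinism, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from celiaq import (
    ClassMask,
    compute_features,
    default_params_for_marsh,
    generate_specimen,
    make_cell_table,
    render_ihc,
)
from celiaq.containers import CODE_VE
from celiaq.errors import CategoryError, DimensionError
from celiaq.segmentation import unmix_hdab
from celiaq.synthetic import MucosaParams, SpecimenTruth

SMALL = dict(villus_height_um=150.0, crypt_depth_um=150.0, canvas_px=(260, 400), n_villi=3)


def test_default_params_reflect_marsh_definitions():
    p0 = default_params_for_marsh("0", seed=1)
    assert p0.villus_height_um > p0.crypt_depth_um
    assert p0.iel_per_100_enterocytes < 25
    p3c = default_params_for_marsh("3c", seed=1)
    assert p3c.villus_height_um < 0.2 * p3c.crypt_depth_um


def test_default_params_seeded_determinism_and_category_error():
    a = default_params_for_marsh("3b", seed=7)
    b = default_params_for_marsh("3b", seed=7)
    assert a == b
    with pytest.raises(CategoryError):
        default_params_for_marsh("3d", seed=7)


def test_specimen_covers_all_five_classes_and_cells_sit_on_their_compartment():
    truth = generate_specimen(default_params_for_marsh("3a", seed=21))
    present = {truth.mask.class_map[c] for c in np.unique(truth.mask.labels)}
    assert present == set(truth.mask.class_map.values())
    looked_up = [truth.mask.class_at(r.y_px, r.x_px)
                 for r in truth.cells.itertuples(index=False)]
    assert looked_up == list(truth.cells["compartment"])


def test_zero_iel_rate_gives_no_epithelial_positives():
    p = default_params_for_marsh("0", seed=4, iel_per_100_enterocytes=0.0, **SMALL)
    truth = generate_specimen(p)
    epi = truth.cells[truth.cells["compartment"].isin(
        ["villous_epithelium", "crypt_epithelium"])]
    assert (epi["cd3"] == "negative").all()
    lp = truth.cells[truth.cells["compartment"] == "lamina_propria"]
    assert len(lp) > 0 and (lp["cd3"] == "positive").all()


def test_specimen_determinism():
    p = default_params_for_marsh("2", seed=9)
    a, b = generate_specimen(p), generate_specimen(p)
    assert np.array_equal(a.mask.labels, b.mask.labels)
    pd.testing.assert_frame_equal(a.cells, b.cells)


def test_geometry_that_cannot_fit_raises():
    with pytest.raises(DimensionError):
        generate_specimen(default_params_for_marsh("0", seed=1, canvas_px=(120, 400)))


def test_type0_area_ratio_ordering():
    truth = generate_specimen(default_params_for_marsh("0", seed=30))
    fv = compute_features(truth.mask, truth.cells)
    assert fv.ve_lp_ratio > fv.ce_ve_ratio


def test_realized_iel_rate_is_binomially_consistent():
    """Per specimen, the positive count lies in the central 99% binomial band."""
    for seed in range(8):
        p = default_params_for_marsh("3b", seed=50 + seed,
                                     iel_per_100_enterocytes=40.0, **SMALL)
        truth = generate_specimen(p)
        epi = truth.cells[truth.cells["compartment"].isin(
            ["villous_epithelium", "crypt_epithelium"])]
        n = len(epi)
        k = int((epi["cd3"] == "positive").sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 40.0 / 140.0)
        assert lo <= k <= hi


def test_mean_realized_rate_tracks_target_over_many_specimens():
    """Across 200 seeded specimens at target 40/100 the mean realized
    positives-per-100-enterocytes concentrates within 2 of the target."""
    rates = []
    for seed in range(200):
        p = default_params_for_marsh("1", seed=1000 + seed,
                                     iel_per_100_enterocytes=40.0,
                                     lp_lymphocyte_density=1e-9, **SMALL)
        truth = generate_specimen(p)
        ve = truth.cells[truth.cells["compartment"] == "villous_epithelium"]
        n_pos = (ve["cd3"] == "positive").sum()
        n_neg = (ve["cd3"] == "negative").sum()
        rates.append(100.0 * n_pos / n_neg)
    assert abs(np.mean(rates) - 40.0) < 2.0


def test_cohort_medians_order_with_severity():
    """VE/LP falls and CE/VE rises monotonically from Type 0 to 3c."""
    med_ve_lp, med_ce_ve = [], []
    for t, mt in enumerate(("0", "1", "2", "3a", "3b", "3c")):
        vals = []
        for s in range(6):
            truth = generate_specimen(default_params_for_marsh(mt, seed=600 + 10 * t + s))
            fv = compute_features(truth.mask, truth.cells)
            vals.append((fv.ve_lp_ratio, fv.ce_ve_ratio))
        arr = np.array(vals)
        med_ve_lp.append(np.median(arr[:, 0]))
        med_ce_ve.append(np.median(arr[:, 1]))
    assert all(a > b for a, b in zip(med_ve_lp, med_ve_lp[1:]))
    assert all(a < b for a, b in zip(med_ce_ve, med_ce_ve[1:]))


# ---- rendering ---------------------------------------------------------------


def _sparse_truth(n_pos=4, n_neg=5):
    """Hand-built specimen with well-separated cells for exact disc counting."""
    labels = np.full((120, 120), CODE_VE, dtype=np.uint8)
    mask = ClassMask(labels, pixel_size_um=2.0)
    ys, xs = np.mgrid[20:120:30, 20:120:30]
    ys, xs = ys.ravel()[: n_pos + n_neg], xs.ravel()[: n_pos + n_neg]
    cd3 = ["positive"] * n_pos + ["negative"] * n_neg
    cells = make_cell_table(xs, ys, ["villous_epithelium"] * len(ys), cd3)
    params = MucosaParams(marsh_type="0", n_villi=1, villus_height_um=50,
                          villus_width_um=50, crypt_depth_um=30, crypt_width_um=20,
                          epithelial_band_um=20, lp_lymphocyte_density=0,
                          iel_per_100_enterocytes=0, enterocyte_spacing_um=12,
                          pixel_size_um=2.0, canvas_px=(120, 120), seed=0)
    return SpecimenTruth(params=params, mask=mask, cells=cells)


def test_render_counts_discs_exactly():
    truth = _sparse_truth(n_pos=4, n_neg=5)
    img = render_ihc(truth)
    h_od, d_od = unmix_hdab(img)
    _, n_nuclei = ndimage.label(h_od > 0.5)
    _, n_dab = ndimage.label(d_od > 0.5)
    assert n_nuclei == 9
    assert n_dab == 4


def test_render_of_cell_free_truth_has_no_stain():
    truth = _sparse_truth(0, 0)
    img = render_ihc(truth)
    h_od, d_od = unmix_hdab(img)
    assert h_od.max() < 0.25 and d_od.max() < 0.25  # tint background only


def test_render_is_deterministic_even_with_noise():
    truth = generate_specimen(default_params_for_marsh("3c", seed=5, **SMALL))
    a = render_ihc(truth, noise_sd=2.0, seed=3)
    b = render_ihc(truth, noise_sd=2.0, seed=3)
    assert np.array_equal(a, b)
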