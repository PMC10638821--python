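"""Group comparisons, confusion matrices and the paired-biopsy alignment analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from celiaq import (
    classify_pair,
    cohort_summary,
    compute_features,
    confusion_matrix,
    default_params_for_marsh,
    evaluate_pairs,
    feature_direction_audit,
    generate_specimen,
    group_compare,
    load_paired_fixture,
)
from celiaq.errors import CategoryError, InsufficientDataError, IntegrityError
from celiaq.evaluation import feature_deltas

# ---- group comparison ----------------------------------------------------------


def test_group_compare_identical_groups():
    gc = group_compare([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
    assert gc.t_statistic == pytest.approx(0.0)
    assert gc.eta_squared == pytest.approx(0.0)
    assert gc.p_two_sided == pytest.approx(1.0)


def test_group_compare_hand_worked_example():
    """{1,2,3} vs {4,5,6}: pooled SE = sqrt(2/3), t = -3/SE, eta² = t²/(t²+4)."""
    gc = group_compare([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
    assert gc.t_statistic == pytest.approx(-3.674, abs=1e-3)
    assert gc.df == 4
    assert gc.eta_squared == pytest.approx(0.771, abs=5e-4)
    assert gc.median_a == 2.0 and gc.median_b == 5.0


def test_group_compare_matches_first_principles_oracle(rng):
    """t, p, CI and eta² agree with independently computed values to 1e-10."""
    for _ in range(30):
        na, nb = rng.integers(3, 12), rng.integers(3, 12)
        a = rng.normal(0, 2, na)
        b = rng.normal(1, 3, nb)
        gc = group_compare(np.concatenate([a, b]), [0] * na + [1] * nb)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert gc.t_statistic == pytest.approx(t_ref, abs=1e-10)
        assert gc.p_two_sided == pytest.approx(p_ref, abs=1e-10)
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / na + 1 / nb))
        tcrit = stats.t.ppf(0.975, df)
        diff = a.mean() - b.mean()
        assert gc.mean_diff_ci95[0] == pytest.approx(diff - tcrit * se, abs=1e-10)
        assert gc.mean_diff_ci95[1] == pytest.approx(diff + tcrit * se, abs=1e-10)
        assert gc.eta_squared == pytest.approx(t_ref**2 / (t_ref**2 + df), abs=1e-10)


def test_group_compare_permutation_and_affine_invariance(rng):
    vals = rng.normal(0, 1, 12)
    labs = np.array([0] * 6 + [1] * 6)
    gc1 = group_compare(vals, labs)
    perm = np.concatenate([rng.permutation(vals[:6]), rng.permutation(vals[6:])])
    gc2 = group_compare(perm, labs)
    assert gc1.t_statistic == pytest.approx(gc2.t_statistic, abs=1e-12)
    # eta² is invariant under affine rescaling of the values
    gc3 = group_compare(3.5 * vals - 2.0, labs)
    assert gc3.eta_squared == pytest.approx(gc1.eta_squared, abs=1e-12)


def test_group_compare_insufficient_data():
    with pytest.raises(InsufficientDataError):
        group_compare([1, 2, 3], ["a", "a", "b"])
    with pytest.raises(InsufficientDataError):
        group_compare([1, 2, 3], ["a", "a", "a"])


def test_group_compare_welch_differs_under_unequal_variance(rng):
    a = rng.normal(0, 0.5, 8)
    b = rng.normal(0, 5.0, 20)
    vals = np.concatenate([a, b])
    labs = [0] * 8 + [1] * 20
    student = group_compare(vals, labs)
    welch = group_compare(vals, labs, welch=True)
    assert welch.df != student.df


# ---- confusion matrix ------------------------------------------------------------


def test_confusion_matrix_identity_and_row_sums():
    cats = ["0", "1", "2", "3a", "3b", "3c"]
    cm = confusion_matrix(cats, cats)
    assert (np.diag(cm.to_numpy()) == 1).all()
    assert cm.to_numpy().sum() == 6
    cm2 = confusion_matrix(["0", "0", "3b"], ["1", "0", "3b"])
    assert cm2.loc["0"].sum() == 2 and cm2.loc["3b"].sum() == 1
    with pytest.raises(CategoryError):
        confusion_matrix(["0"], ["4"])


# ---- paired analysis -------------------------------------------------------------


def test_classify_pair_improved_and_unchanged_examples():
    r1 = classify_pair("3b", "0", 3.95, 1.63)
    assert r1.marsh_response == "improved" and r1.aligned
    r5 = classify_pair("3a", "3a", 2.46, 3.49)
    assert r5.marsh_response == "unchanged" and not r5.aligned
    r = classify_pair("0", "0", 1.00, 1.00, tol=0.0)
    assert r.marsh_response == "unchanged" and r.aligned


@given(
    pre=st.sampled_from(["0", "1", "2", "3a", "3b", "3c"]),
    post=st.sampled_from(["0", "1", "2", "3a", "3b", "3c"]),
    pre_mls=st.floats(-2, 5, allow_nan=False),
    post_mls=st.floats(-2, 5, allow_nan=False),
)
def test_classify_pair_antisymmetry(pre, post, pre_mls, post_mls):
    fwd = classify_pair(pre, post, pre_mls, post_mls)
    rev = classify_pair(post, pre, post_mls, pre_mls)
    flip = {"improved": "worsened", "worsened": "improved", "unchanged": "unchanged"}
    assert rev.marsh_response == flip[fwd.marsh_response]
    flip_dir = {"decreased": "increased", "increased": "decreased",
                "stable-within-tol": "stable-within-tol"}
    assert rev.mls_direction == flip_dir[fwd.mls_direction]
    assert rev.aligned == fwd.aligned


def test_cohort_summary_single_pair_and_empty_error():
    rec = classify_pair("3b", "1", 2.5, 0.5)
    s = cohort_summary([rec])
    assert s.aligned_overall_pct == 100.0 and s.n_responders == 1
    with pytest.raises(InsufficientDataError):
        cohort_summary([])


def test_paired_fixture_reproduces_cohort_numbers():
    pairs = load_paired_fixture()
    records, s = evaluate_pairs(pairs)
    assert s.n_pairs == 28
    assert s.n_responders == 27
    assert s.aligned_overall_pct == 96.4
    assert s.aligned_among_responders_pct == 100.0
    assert s.median_pre_mls == pytest.approx(2.725, abs=1e-9)
    assert s.median_post_mls == pytest.approx(0.78, abs=1e-9)
    assert s.range_pre_mls == (0.82, 4.28)
    assert s.range_post_mls[0] == -1.23
    not_aligned = [r for r in records if not r.aligned]
    assert [r.pair_id for r in not_aligned] == ["5"]


def test_fixture_checksum_guard(monkeypatch):
    import celiaq.evaluation as ev

    monkeypatch.setattr(ev, "TABLE3_SHA256", "0" * 64)
    with pytest.raises(IntegrityError):
        ev.load_paired_fixture()


# ---- feature direction audit ------------------------------------------------------


def test_audit_counts_consistent_pair_and_missing():
    pre = {"ve_lp_ratio": 0.2, "ce_ve_ratio": 1.5, "pct_cd3_ve": 55.0}
    post = {"ve_lp_ratio": 0.6, "ce_ve_ratio": 0.4, "pct_cd3_ve": 12.0}
    counts = feature_direction_audit([(pre, post, "improved")])
    assert all(c["concordant"] == 1 for c in counts.values())
    post_missing = dict(post, ce_ve_ratio=None)
    counts = feature_direction_audit([(pre, post_missing, "improved")])
    assert counts["ce_ve_ratio"]["missing"] == 1
    assert counts["ve_lp_ratio"]["concordant"] == 1


def test_feature_deltas_antisymmetric():
    pre = {"ve_lp_ratio": 0.2, "ce_ve_ratio": 1.5, "pct_cd3_ve": 55.0}
    post = {"ve_lp_ratio": 0.6, "ce_ve_ratio": 0.4, "pct_cd3_ve": 12.0}
    fwd = feature_deltas(pre, post)
    rev = feature_deltas(post, pre)
    for k in fwd:
        assert rev[k] == pytest.approx(-fwd[k])


def test_synthetic_responder_cohort_is_ve_concordant():
    """Specimens regenerated from Type 3b (pre) to Type 0 (post) geometry always
    recover the villus surrogate."""
    rows = []
    for s in range(6):
        pre_t = generate_specimen(default_params_for_marsh("3b", seed=700 + s))
        post_t = generate_specimen(default_params_for_marsh("0", seed=800 + s))
        pre = compute_features(pre_t.mask, pre_t.cells)
        post = compute_features(post_t.mask, post_t.cells)
        rows.append((pre, post, "improved"))
    counts = feature_direction_audit(rows)
    assert counts["ve_lp_ratio"]["concordant"] == 6
    assert counts["pct_cd3_ve"]["concordant"] == 6
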