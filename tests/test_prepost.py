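import warnings

import numpy as np
import pytest
from scipy import stats

from rackstack import (
    ValidationError,
    align_prepost,
    difficulty_crossplot,
    infant_design,
    rack,
    simulate_prepost,
    stack,
    wilcoxon_signed_rank,
)
from rackstack.prepost import summarize_effects

from oracles import brute_force_signed_rank_p


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_three_positive_differences():
    res = wilcoxon_signed_rank([1.0, 2.0, 3.0])
    assert res.w_plus == 6 and res.method == "exact"
    assert res.p_two_sided == pytest.approx(0.25, abs=1e-12)


def test_wilcoxon_sign_symmetry():
    res = wilcoxon_signed_rank([-1.0, -2.0, -3.0])
    assert res.w_plus == 0
    assert res.p_two_sided == pytest.approx(0.25, abs=1e-12)


def test_wilcoxon_zeros_dropped():
    res = wilcoxon_signed_rank([0.0, 0.0, 1.0, -2.0, 3.0])
    assert res.n_nonzero == 3


def test_wilcoxon_all_zero_errors():
    with pytest.raises(ValidationError):
        wilcoxon_signed_rank([0.0, 0.0])


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("n", [4, 6, 8, 10])
def test_wilcoxon_exact_matches_scipy_without_ties(n, seed):
    rng = np.random.default_rng(seed)
    d = rng.choice([-1, 1], n) * np.arange(1.0, n + 1)
    res = wilcoxon_signed_rank(d)
    ref = stats.wilcoxon(d, method="exact")
    assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)


@pytest.mark.parametrize("d", [
    [1.0, 1.0, -1.0, 2.0],          # tied magnitudes across signs
    [2.0, 2.0, 2.0, -1.0, 1.0],
    [-3.0, 3.0, -3.0, 3.0, 1.0],
])
def test_wilcoxon_exact_with_midranks_matches_enumeration(d):
    res = wilcoxon_signed_rank(d)
    w_ref, p_ref = brute_force_signed_rank_p(np.asarray(d))
    assert res.w_plus == pytest.approx(w_ref)
    assert res.p_two_sided == pytest.approx(p_ref, abs=1e-12)


def test_wilcoxon_normal_approximation_matches_scipy():
    rng = np.random.default_rng(11)
    for _ in range(25):
        d = np.round(rng.normal(0, 1, 20), 1)
        d = d[d != 0]
        if d.size <= 12:
            continue
        res = wilcoxon_signed_rank(d)
        assert res.method == "normal-approximation"
        ref = stats.wilcoxon(d, correction=True, method="approx")
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)


@pytest.mark.parametrize("n", [5, 9, 15])
def test_wilcoxon_label_swap_invariance(n):
    rng = np.random.default_rng(n)
    d = rng.normal(0.4, 1.0, n)
    a, b = wilcoxon_signed_rank(d), wilcoxon_signed_rank(-d)
    mu = a.n_nonzero * (a.n_nonzero + 1) / 4
    assert abs(a.w_plus - mu) == pytest.approx(abs(b.w_plus - mu))
    assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-12)


# ---------------------------------------------------------------------------
# summary arithmetic
# ---------------------------------------------------------------------------

def _flat_summary(kind, n, mean_pre, mean_post):
    ids = [f"e{i}" for i in range(n)]
    rng = np.random.default_rng(0)
    spread = rng.normal(0, 0.5, n)
    spread -= spread.mean()
    return summarize_effects(kind, ids, mean_pre + spread, mean_post + spread)


@pytest.mark.parametrize("kind,mean_pre,mean_post,diff", [
    ("person", 0.36, 3.04, 2.68),   # infant-instrument ability gain
    ("person", 0.30, 3.64, 3.34),   # toddler-instrument ability gain
    ("item", 1.01, -2.06, -3.07),   # toddler-instrument difficulty drop
])
def test_group_summary_arithmetic(kind, mean_pre, mean_post, diff):
    s = _flat_summary(kind, 41, mean_pre, mean_post)
    assert s.mean_difference == pytest.approx(diff, abs=1e-9)
    assert s.mean_difference == pytest.approx(s.mean_post - s.mean_pre, abs=1e-9)
    np.testing.assert_allclose(s.differences(), np.full(41, diff), atol=1e-9)


def test_summary_swap_negates_differences():
    rng = np.random.default_rng(4)
    pre = rng.normal(0, 1, 20)
    post = pre + rng.normal(1, 0.5, 20)
    ids = [f"e{i}" for i in range(20)]
    a = summarize_effects("person", ids, pre, post)
    b = summarize_effects("person", ids, post, pre)
    assert b.mean_difference == pytest.approx(-a.mean_difference)
    assert b.test.p_two_sided == pytest.approx(a.test.p_two_sided, abs=1e-12)


# ---------------------------------------------------------------------------
# stacking and racking
# ---------------------------------------------------------------------------

def test_stack_structure_and_shared_items(infant_sim):
    pre, post, _ = infant_sim
    design = align_prepost(pre, post)
    s = stack(design)
    assert s.entity_kind == "person"
    assert len(s.records) == 41
    cal = s.calibration
    # stacked frame: 2N occasion-tagged person rows, single shared item set
    assert cal.params.person_ids[:41] == ["P" + p for p in pre.person_ids]
    assert cal.params.person_ids[41:] == ["0" + p for p in pre.person_ids]
    assert cal.params.item_ids == pre.item_ids
    assert [i for i, _ in s.co_measures] == pre.item_ids


def test_rack_structure_and_shared_persons(infant_sim):
    pre, post, _ = infant_sim
    design = align_prepost(pre, post)
    r = rack(design)
    assert r.entity_kind == "item"
    assert len(r.records) == pre.n_items
    cal = r.calibration
    # racked frame: 2I occasion-tagged item columns, single shared person set
    assert cal.params.item_ids[:pre.n_items] == ["P" + i for i in pre.item_ids]
    assert cal.params.item_ids[pre.n_items:] == ["0" + i for i in pre.item_ids]
    assert cal.params.person_ids == pre.person_ids


def test_identical_occasions_give_zero_differences(infant_sim):
    pre, _, _ = infant_sim
    design = align_prepost(pre, pre.copy())
    with pytest.warns(RuntimeWarning, match="zero"):
        s = stack(design)
    assert s.test is None
    np.testing.assert_allclose(s.differences(), 0.0, atol=1e-12)
    r = rack(design)
    np.testing.assert_allclose(r.differences(), 0.0, atol=1e-9)


def test_stack_detects_training_effect(infant_sim):
    # single-replicate sanity check: a 2.7-logit gain is detected as a large,
    # significant positive shift (the sharp multi-seed recovery bound lives in
    # the acceptance suite)
    pre, post, truth = infant_sim
    s = stack(align_prepost(pre, post))
    assert s.mean_difference > 2.0
    assert s.test.p_two_sided < 0.01


def test_rack_difficulty_drop_sign():
    # a uniform ability gain shows up in racking as negative (easier) items
    pre, post, _ = simulate_prepost(infant_design(seed=3))
    r = rack(align_prepost(pre, post))
    assert r.mean_difference < -1.0


def test_null_stacking_keeps_type_one_error():
    rng_seeds = range(40)
    ps = []
    for seed in rng_seeds:
        pre, post, _ = simulate_prepost(
            infant_design(seed=seed, effect=0.0, sigma_effect=0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = stack(align_prepost(pre, post))
        ps.append(s.test.p_two_sided if s.test is not None else 1.0)
    assert np.mean(np.asarray(ps) > 0.05) >= 0.85


# ---------------------------------------------------------------------------
# difficulty cross-plot
# ---------------------------------------------------------------------------

def test_crossplot_flags_relatively_harder_items():
    ids = [f"i{k}" for k in range(6)]
    pre = np.array([-1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
    post = pre - 2.0
    post[5] = pre[5] + 0.5  # this item barely improved
    table = difficulty_crossplot(summarize_effects("item", ids, pre, post))
    assert bool(table.loc[table["id"] == "i5", "above_line"].iloc[0])
    assert table["above_line"].sum() == 1


def test_crossplot_identity_line_gives_no_flags():
    ids = [f"i{k}" for k in range(4)]
    pre = np.array([-1.0, 0.0, 1.0, 2.0])
    table = difficulty_crossplot(summarize_effects("item", ids, pre, pre - 1.5))
    assert not table["above_line"].any()


def test_crossplot_requires_item_summary():
    s = _flat_summary("person", 10, 0.0, 1.0)
    with pytest.raises(ValidationError):
        difficulty_crossplot(s)
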