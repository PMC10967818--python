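"""Perimeter gating, H fractions and the two group-comparison tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from opdcyto.classify import LogisticModel, ThresholdModel
from opdcyto.cohort import (
    compare_groups,
    h_fraction,
    make_cohort_sample,
    perimeter_gate,
    two_proportion_test,
    two_sample_t,
)
from opdcyto.phantom import (
    CohortParams,
    H_FEATURE_MEANS as H_FEATURE_MEANS_,
    L_FEATURE_MEANS as L_FEATURE_MEANS_,
    sample_cohort_features,
)


def frame_with_perimeters(perims):
    return pd.DataFrame({"perimeter_um": perims,
                         "dry_mass_pg": np.full(len(perims), 50.0)})


# ------------------------------------------------------------------ gate

def test_gate_linear_interpolation_percentiles():
    """Reference 1..100: 5th pct = 5.95, 95th = 95.05 (linear rule), so of
    perimeters {2, 50, 99} only 50 survives."""
    ref = np.arange(1, 101, dtype=float)
    assert np.percentile(ref, 5) == pytest.approx(5.95)
    assert np.percentile(ref, 95) == pytest.approx(95.05)
    kept = perimeter_gate(frame_with_perimeters([2.0, 50.0, 99.0]), ref)
    assert kept["perimeter_um"].tolist() == [50.0]


def test_gate_keeps_interior_cells():
    ref = np.linspace(10, 90, 200)
    cells = frame_with_perimeters(np.linspace(30, 70, 17))
    assert len(perimeter_gate(cells, ref)) == 17


def test_gate_degenerate_single_reference():
    kept = perimeter_gate(frame_with_perimeters([42.0]), [42.0])
    assert len(kept) == 1
    with pytest.raises(ValueError):
        perimeter_gate(frame_with_perimeters([1.0]), [])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0, 10), st.floats(90, 100))
def test_gate_monotone_in_band_width(seed, lo, hi):
    """Widening the percentile band never removes previously kept cells."""
    rng = np.random.default_rng(seed)
    ref = rng.uniform(10, 90, 150)
    cells = frame_with_perimeters(rng.uniform(0, 100, 60))
    narrow = perimeter_gate(cells, ref, lo_pct=max(lo, 5), hi_pct=min(hi, 95))
    wide = perimeter_gate(cells, ref, lo_pct=min(lo, 5), hi_pct=max(hi, 95))
    assert set(narrow["perimeter_um"]).issubset(set(wide["perimeter_um"]))


# ------------------------------------------------------------- fractions

def test_h_fraction_all_l():
    model = ThresholdModel("dry_mass", 73.0, 10, 10, 1.0)
    df = pd.DataFrame({"dry_mass_pg": np.full(50, 96.0)})
    frac, n_h, n = h_fraction(df, model)
    assert (frac, n_h, n) == (0.0, 0, 50)
    with pytest.raises(ValueError):
        h_fraction(df.iloc[:0], model)


def bayes_model():
    """Analytic near-optimal 2-feature discriminator for the default
    class distributions (equal-variance Gaussian boundary)."""
    mu_h = np.array([59.0, 120.0])
    mu_l = np.array([96.0, 200.0])
    sd = (0.15 * mu_h + 0.15 * mu_l) / 2
    mu = (mu_h + mu_l) / 2
    coef = (mu_h - mu_l) / sd  # positive score = H side
    return LogisticModel(
        feature_columns=["dry_mass_pg", "avg_opd_nm"],
        coef=list(coef), intercept=0.0, mu=list(mu), sigma=list(sd),
        cv_folds=0, cv_accuracy=float("nan"), rng_seed=0)


@pytest.mark.parametrize("group,w,n", [("BBD", 0.20, 400), ("MDS", 0.04, 438)])
def test_h_fraction_binomial_bound(group, w, n):
    """The observed H fraction of a synthetic cohort stays within 3
    binomial sigmas of its expectation.

    Even a near-optimal classifier misassigns a few percent of cells under
    the default class overlap, so the expectation is the mixing weight
    adjusted by the model's class-conditional error rates, measured
    independently on large pure-class samples.
    """
    model = bayes_model()
    rng = np.random.default_rng(100)
    pure = {}
    for label, means in (("H", H_FEATURE_MEANS_), ("L", L_FEATURE_MEANS_)):
        params = CohortParams(n_cells=20_000, h_fraction=1.0 if label == "H" else 0.0,
                              rng_seed=int(rng.integers(2**31)))
        big = sample_cohort_features(params)
        pure[label] = (model.predict(big) == "H").mean()
    expected = w * pure["H"] + (1 - w) * pure["L"]
    df = sample_cohort_features(
        CohortParams(group_label=group, n_cells=n, h_fraction=w, rng_seed=0))
    frac, _, _ = h_fraction(df, model)
    band = 3 * np.sqrt(expected * (1 - expected) / n)
    assert abs(frac - expected) <= band


# ----------------------------------------------------------------- tests

def test_t_identical_samples():
    t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0 and p == 1.0


def test_t_hand_computed_pooled():
    """{1..5} vs {6..10}: pooled s = 1.581, t = -5, p = 0.00105."""
    t, p = two_sample_t([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], pooled=True)
    assert t == pytest.approx(-5.0, abs=1e-9)
    assert p == pytest.approx(0.0010528, abs=2e-6)


def test_t_degenerate_variance():
    with pytest.raises(ValueError):
        two_sample_t([1.0, 1.0], [2.0, 2.0])
    with pytest.raises(ValueError):
        two_sample_t([1.0], [2.0, 3.0])


def test_proportions_closed_form_counts():
    """77/384 vs 18/438 (the pooled ~20% vs ~4.1% scenario): z ~ 7.133."""
    z, p = two_proportion_test(77, 384, 18, 438)
    pool = 95 / 822
    se = np.sqrt(pool * (1 - pool) * (1 / 384 + 1 / 438))
    z_hand = (77 / 384 - 18 / 438) / se
    assert z == pytest.approx(z_hand, abs=1e-12)
    assert z == pytest.approx(7.133, abs=1e-3)
    assert p < 1e-10


def test_proportions_cross_checked_against_statsmodels():
    from statsmodels.stats.proportion import proportions_ztest

    z, p = two_proportion_test(30, 200, 55, 300)
    z_sm, p_sm = proportions_ztest([30, 55], [200, 300])
    assert z == pytest.approx(z_sm, abs=1e-10)
    assert p == pytest.approx(p_sm, abs=1e-10)


def test_proportions_equal_and_invalid():
    z, p = two_proportion_test(40, 400, 40, 400)
    assert z == 0.0 and p == 1.0
    with pytest.raises(ValueError):
        two_proportion_test(-1, 10, 2, 10)
    with pytest.raises(ValueError):
        two_proportion_test(11, 10, 2, 10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 400), st.integers(0, 400))
def test_proportions_symmetry(x1, x2):
    """Swapping arms negates z and preserves p."""
    z1, p1 = two_proportion_test(x1, 400, x2, 400)
    z2, p2 = two_proportion_test(x2, 400, x1, 400)
    assert z1 == pytest.approx(-z2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


# ---------------------------------------------------------- group compare

def _samples(seed=0, w_bbd=0.20, w_mds=0.04):
    out = []
    ref = sample_cohort_features(
        CohortParams(group_label="BBD", n_cells=171, h_fraction=0.45,
                     rng_seed=seed + 99))["perimeter_um"].to_numpy()
    for i, (group, w, n) in enumerate(
            [("BBD", w_bbd, 192), ("BBD", w_bbd, 192),
             ("MDS", w_mds, 219), ("MDS", w_mds, 219)]):
        df = sample_cohort_features(
            CohortParams(group_label=group, n_cells=n, h_fraction=w,
                         rng_seed=seed * 10 + i))
        out.append(make_cohort_sample(f"{group}-{i}", group, df, ref))
    return out


def test_compare_groups_detects_mds_deficit():
    """Default 20% vs 4% mixing at ~400 cells/group: p < 0.001."""
    samples = _samples(seed=1)
    model = bayes_model()
    res = compare_groups(samples, model)
    assert res.p_value < 1e-3
    assert res.group_fractions["BBD"] > res.group_fractions["MDS"]
    assert res.significant


def test_compare_groups_pooled_fraction_is_weighted_mean():
    samples = _samples(seed=2)
    res = compare_groups(samples, bayes_model())
    per = res.per_sample
    for group in ("BBD", "MDS"):
        sub = per[per.group == group]
        weighted = (sub.h_fraction * sub.n).sum() / sub.n.sum()
        assert res.group_fractions[group] == pytest.approx(weighted, abs=1e-12)


def test_compare_groups_single_group_errors():
    samples = [s for s in _samples() if s.group == "BBD"]
    with pytest.raises(ValueError):
        compare_groups(samples, bayes_model())


def test_gating_bookkeeping_monotone():
    df = sample_cohort_features(CohortParams(n_cells=100, rng_seed=5))
    ref = df["perimeter_um"].to_numpy()
    cs = make_cohort_sample("s", "BBD", df, ref)
    assert cs.n_after_gate <= cs.n_before_gate
    assert len(cs.cells) == cs.n_after_gate


def test_null_pvalues_uniform():
    """Equal mixing in both groups: p-values follow U(0,1) (KS, alpha 0.01)."""
    rng = np.random.default_rng(17)
    pvals = []
    for _ in range(300):
        x1 = rng.binomial(400, 0.12)
        x2 = rng.binomial(400, 0.12)
        pvals.append(two_proportion_test(x1, 400, x2, 400)[1])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
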