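"""Beta-binomial error model: fitting, site testing, FDR and hard filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import betaln, gammaln

from rnamosaic.error_model import (
    FALLBACK_ALPHA,
    FALLBACK_BETA,
    SUBSTITUTION_CLASSES,
    BetaBinomialErrorModel,
    call_sample,
    fdr_adjust,
    fit_error_model,
    single_sample_filter,
    site_pvalue,
    substitution_class,
    upper_tail_pvalues,
)


# -- substitution classes --------------------------------------------------


@pytest.mark.parametrize("ref,alt,expected", [
    ("A", "C", "A>C"), ("A", "T", "A>T"), ("A", "G", "A>G"),
    ("C", "A", "C>A"), ("C", "T", "C>T"), ("C", "G", "C>G"),
    ("G", "A", "C>T"), ("G", "T", "C>A"), ("G", "C", "C>G"),
    ("T", "A", "A>T"), ("T", "C", "A>G"), ("T", "G", "A>C"),
])
def test_strand_collapse_mapping(ref, alt, expected):
    assert substitution_class(ref, alt) == expected


def test_strand_collapse_involutive():
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for r in "ACGT":
        for a in "ACGT":
            if r == a:
                continue
            assert substitution_class(r, a) == substitution_class(comp[r], comp[a])


def test_non_snv_rejected():
    with pytest.raises(ValueError):
        substitution_class("C", "C")
    with pytest.raises(ValueError):
        substitution_class("N", "A")


# -- fitting ---------------------------------------------------------------


def _sim_hom_ref(rng, n, a, b, cov=100, ref="C", alt="T"):
    p = rng.beta(a, b, n)
    k = rng.binomial(cov, p)
    return pd.DataFrame({"ref": ref, "alt": alt, "alt_count": k,
                         "coverage": np.full(n, cov)})


def test_fit_covers_all_six_classes():
    rng = np.random.default_rng(0)
    frames = []
    pairs = [("A", "C"), ("A", "T"), ("A", "G"), ("C", "A"), ("C", "T"), ("C", "G")]
    for r, a in pairs:
        frames.append(_sim_hom_ref(rng, 600, 2, 998, ref=r, alt=a))
    model = fit_error_model(pd.concat(frames))
    assert set(model.params_) == set(SUBSTITUTION_CLASSES)
    assert not model.fallback_classes_
    for cls in SUBSTITUTION_CLASSES:
        a, b = model.params_[cls]
        assert a > 0 and b > 0 and np.isfinite(a) and np.isfinite(b)
        assert 0 < model.mean_error_rate(cls) < 0.5


def test_fit_all_zero_alt_counts_uses_fallback():
    df = pd.DataFrame({"ref": "C", "alt": "T", "alt_count": 0,
                       "coverage": 100}, index=range(600))
    model = fit_error_model(df)
    assert model.params_["C>T"] == (FALLBACK_ALPHA, FALLBACK_BETA)
    assert "C>T" in model.fallback_classes_


def test_fit_empty_input_warns_and_falls_back():
    with pytest.warns(UserWarning):
        model = fit_error_model(pd.DataFrame())
    assert all(model.params_[c] == (FALLBACK_ALPHA, FALLBACK_BETA)
               for c in SUBSTITUTION_CLASSES)


def test_moments_fit_recovers_simulated_error_distribution():
    # 10,000 sites at coverage 100 with per-read error ~ Beta(2, 998):
    # fitted mean within 20% of the true 0.002 and overdispersion detected
    rng = np.random.default_rng(42)
    model = fit_error_model(_sim_hom_ref(rng, 10_000, 2, 998))
    mean = model.mean_error_rate("C>T")
    assert abs(mean - 0.002) / 0.002 < 0.20
    a, b = model.params_["C>T"]
    assert a + b < 10 * 1000  # concentration of the true Beta(2, 998)


def test_mle_refinement_close_to_moments():
    rng = np.random.default_rng(1)
    df = _sim_hom_ref(rng, 3000, 2, 998)
    mom = fit_error_model(df, method="moments")
    mle = fit_error_model(df, method="mle")
    assert abs(mle.mean_error_rate("C>T") - mom.mean_error_rate("C>T")) < 5e-4


def test_under_populated_class_gets_fallback():
    rng = np.random.default_rng(2)
    model = fit_error_model(_sim_hom_ref(rng, 100, 2, 998), min_fit_sites=500)
    assert model.params_["C>T"] == (FALLBACK_ALPHA, FALLBACK_BETA)


# -- site p-values ---------------------------------------------------------


def _uniform_model():
    m = BetaBinomialErrorModel()
    m.params_ = {c: (1.0, 1.0) for c in SUBSTITUTION_CLASSES}
    m.n_sites_used_ = {c: 0 for c in SUBSTITUTION_CLASSES}
    m.fallback_classes_ = set()
    return m


def test_pvalue_is_one_for_zero_alt(obs_factory):
    model = _uniform_model()
    p, flag = site_pvalue(obs_factory(ref_fwd=50, ref_rev=50), model)
    assert p == 1.0 and flag == ""


def test_pvalue_zero_coverage_flagged(obs_factory):
    p, flag = site_pvalue(obs_factory(ref_fwd=0, ref_rev=0), _uniform_model())
    assert p == 1.0 and flag == "no_expression"


def test_pvalue_uniform_beta_binomial(obs_factory):
    # Beta(1,1) makes the count uniform on 0..10: P(X >= 5) = 6/11
    obs = obs_factory(alt_fwd=3, alt_rev=2, ref_fwd=3, ref_rev=2)
    p, _ = site_pvalue(obs, _uniform_model())
    assert p == pytest.approx(6 / 11, abs=1e-12)


def _betabinom_pmf_direct(k, n, a, b):
    # independent pmf: C(n,k) B(k+a, n-k+b) / B(a, b)
    return np.exp(
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + betaln(k + a, n - k + b) - betaln(a, b)
    )


def test_pvalue_matches_brute_force_summation(obs_factory):
    model = BetaBinomialErrorModel()
    model.params_ = {c: (2.0, 998.0) for c in SUBSTITUTION_CLASSES}
    obs = obs_factory(alt_fwd=2, alt_rev=2, ref_fwd=48, ref_rev=48)
    p, _ = site_pvalue(obs, model)
    brute = sum(_betabinom_pmf_direct(k, 100, 2.0, 998.0) for k in range(4, 101))
    assert p == pytest.approx(brute, rel=1e-9)


def test_pvalue_monotone_in_alt_count(obs_factory):
    model = BetaBinomialErrorModel()
    model.params_ = {c: (2.0, 998.0) for c in SUBSTITUTION_CLASSES}
    cov = 60
    ps = []
    for alt in range(0, 20):
        obs = obs_factory(alt_fwd=alt, alt_rev=0, ref_fwd=cov - alt, ref_rev=0)
        ps.append(site_pvalue(obs, model)[0])
    assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


def test_vectorized_tail_agrees_with_scipy():
    rng = np.random.default_rng(3)
    n = rng.integers(1, 200, 500)
    k = rng.integers(0, 30, 500)
    k = np.minimum(k, n)
    a = rng.uniform(0.5, 5, 500)
    b = rng.uniform(100, 5000, 500)
    ours = upper_tail_pvalues(k, n, a, b)
    ref = stats.betabinom.sf(k - 1, n, a, b)
    np.testing.assert_allclose(ours, ref, rtol=1e-8, atol=1e-12)


def test_null_pvalues_super_uniform():
    # sites simulated from the fitted null: ecdf of p at 0.05 is <= 0.06
    rng = np.random.default_rng(11)
    model = fit_error_model(_sim_hom_ref(rng, 5000, 2, 998))
    a, b = model.params_["C>T"]
    cov = np.full(10_000, 100)
    k = stats.betabinom.rvs(100, a, b, size=10_000, random_state=12)
    p = upper_tail_pvalues(k, cov, np.full(10_000, a), np.full(10_000, b))
    assert (p <= 0.05).mean() <= 0.06
    q = fdr_adjust(p)
    assert (q < 0.05).mean() <= 0.05


# -- FDR -------------------------------------------------------------------


def test_bh_closed_form_equal_spacing():
    np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_single_p_unchanged():
    assert fdr_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_empty():
    assert fdr_adjust([]).size == 0


def test_bh_order_preserving_and_dominates_p():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=200)
    q = fdr_adjust(p)
    assert np.all(q >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)


def test_bh_controls_false_discovery_under_null():
    # all-null uniform p-values: average realized FDP at q < 0.05 stays <= 0.05
    rng = np.random.default_rng(6)
    n_rep = 200
    fdps = []
    for _ in range(n_rep):
        p = rng.uniform(size=10_000)
        rej = fdr_adjust(p) < 0.05
        fdps.append(1.0 if rej.any() else 0.0)  # all null: FDP is 0 or 1
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert np.mean(fdps) <= 0.05 + 2 * se


def test_invalid_pvalues_rejected():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.5])


# -- hard filters ----------------------------------------------------------


def test_filter_min_alt_count(obs_factory):
    obs = obs_factory(alt_fwd=2, alt_rev=1, ref_fwd=24, ref_rev=23)
    passed, reasons = single_sample_filter(obs, q=0.001)
    assert not passed and "min_alt_count" in reasons


def test_filter_min_coverage(obs_factory):
    obs = obs_factory(alt_fwd=2, alt_rev=2, ref_fwd=3, ref_rev=2)
    passed, reasons = single_sample_filter(obs, q=0.001)
    assert not passed and "min_coverage" in reasons


def test_filter_boundary_pass(obs_factory):
    # 6/120 alt (VAF exactly 5%), balanced strands, highly significant
    obs = obs_factory(alt_fwd=3, alt_rev=3, ref_fwd=57, ref_rev=57)
    passed, reasons = single_sample_filter(obs, q=1e-6)
    assert passed and reasons == ()


def test_filter_zero_coverage_reason(obs_factory):
    obs = obs_factory(ref_fwd=0, ref_rev=0)
    passed, reasons = single_sample_filter(obs, q=1e-6)
    assert not passed and reasons == ("no_expression",)


def test_filter_strand_bias(obs_factory):
    obs = obs_factory(alt_fwd=12, alt_rev=0, ref_fwd=50, ref_rev=50)
    passed, reasons = single_sample_filter(obs, q=1e-6)
    assert not passed and "strand_bias" in reasons


def test_filter_proximity_fails_both_sites():
    # two significant candidates 15 bp apart both fail the 20-bp rule
    rows = []
    for pos in (1000, 1015):
        rows.append(dict(chrom="chr1", pos=pos, ref="C", alt="T",
                         ref_fwd=40, ref_rev=40, alt_fwd=10, alt_rev=10,
                         alt_bq20=20))
    # background of clean sites so BH keeps the two candidates significant
    for i in range(50):
        rows.append(dict(chrom="chr2", pos=5000 + 40 * i, ref="C", alt="T",
                         ref_fwd=50, ref_rev=50, alt_fwd=0, alt_rev=0,
                         alt_bq20=0))
    model = BetaBinomialErrorModel()
    model.params_ = {c: (1.0, 1000.0) for c in SUBSTITUTION_CLASSES}
    out = call_sample(pd.DataFrame(rows), model)
    prox = out[out["pos"].isin([1000, 1015])]
    assert (~prox["pass_"]).all()
    assert all("proximity" in r for r in prox["reasons"])


def test_call_sample_passes_clear_variant():
    rows = [dict(chrom="chr1", pos=1000, ref="C", alt="T",
                 ref_fwd=40, ref_rev=40, alt_fwd=10, alt_rev=10, alt_bq20=20)]
    for i in range(50):
        rows.append(dict(chrom="chr2", pos=5000 + 40 * i, ref="C", alt="T",
                         ref_fwd=50, ref_rev=50, alt_fwd=0, alt_rev=0,
                         alt_bq20=0))
    model = BetaBinomialErrorModel()
    model.params_ = {c: (1.0, 1000.0) for c in SUBSTITUTION_CLASSES}
    out = call_sample(pd.DataFrame(rows), model)
    assert bool(out.loc[out["pos"] == 1000, "pass_"].iloc[0])
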