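"""3D genotype array: re-genotyping, germline subtraction, cohort filters,
and lossless serialization."""

import numpy as np
import pandas as pd
import pytest

from rnamosaic.error_model import SUBSTITUTION_CLASSES, BetaBinomialErrorModel
from rnamosaic.genotype_array import (
    CallState,
    GenotypeArray,
    cohort_filters,
    load_bed,
    load_germline_vcf,
    read_array,
    recall_sites,
    subtract_germline,
    write_array,
)


def _model(a=1.0, b=1000.0):
    m = BetaBinomialErrorModel()
    m.params_ = {c: (a, b) for c in SUBSTITUTION_CLASSES}
    m.n_sites_used_ = {c: 0 for c in SUBSTITUTION_CLASSES}
    m.fallback_classes_ = set()
    return m


def _cell(chrom, pos, ind, tis, ref="C", alt="T", ref_n=0, alt_n=0):
    return dict(chrom=chrom, pos=pos, ref=ref, alt=alt, individual=ind,
                tissue=tis, ref_fwd=ref_n // 2, ref_rev=ref_n - ref_n // 2,
                alt_fwd=alt_n // 2, alt_rev=alt_n - alt_n // 2)


@pytest.fixture
def tiny_array():
    """Two sites x two tissues x two individuals with all four states."""
    rows = [
        _cell("chr1", 100, "I1", "T1", ref_n=80, alt_n=20),   # PASS
        _cell("chr1", 100, "I1", "T2", ref_n=0, alt_n=0),     # NO_EXPRESSION
        _cell("chr1", 100, "I2", "T1", ref_n=100, alt_n=0),   # HOM_REF
        _cell("chr1", 100, "I2", "T2", ref_n=98, alt_n=2),    # LOW_QUALITY
        _cell("chr1", 200, "I1", "T1", ref_n=100, alt_n=0),
        _cell("chr1", 200, "I1", "T2", ref_n=100, alt_n=0),
        _cell("chr1", 200, "I2", "T1", ref_n=60, alt_n=40),   # PASS
        # I2/T2 at site 200 is absent -> MISSING
    ]
    counts = pd.DataFrame(rows)
    models = {(i, t): _model() for i in ("I1", "I2") for t in ("T1", "T2")}
    cand = counts[["chrom", "pos", "ref", "alt"]].drop_duplicates()
    return recall_sites(cand, counts, models)


def test_recall_assigns_all_four_states_and_missing(tiny_array):
    a = tiny_array
    i1, i2 = a.individual_index("I1"), a.individual_index("I2")
    t1, t2 = a.tissue_index("T1"), a.tissue_index("T2")
    assert a.states[0, t1, i1] == CallState.PASS
    assert a.states[0, t2, i1] == CallState.NO_EXPRESSION
    assert a.states[0, t1, i2] == CallState.HOM_REF
    assert a.states[0, t2, i2] == CallState.LOW_QUALITY
    assert a.states[1, t2, i2] == CallState.MISSING
    # counts stored for non-missing cells
    assert a.alt_counts[0, t1, i1] == 20
    assert a.ref_counts[0, t1, i1] == 80


def test_recall_is_idempotent_at_state_level(tiny_array, noise_free_cohort):
    co = noise_free_cohort
    from rnamosaic.pipeline import fit_sample_models, step1_candidates

    bg = (co.sites["kind"] == "background").to_numpy()
    models = fit_sample_models(
        co.counts, background_mask=bg[co.counts["site_id"].to_numpy()],
        min_fit_sites=40)
    cand = step1_candidates(co.counts, models)
    sites = cand[["chrom", "pos", "ref", "alt"]].astype({"pos": int})
    a1 = recall_sites(sites, co.counts, models)
    a2 = recall_sites(a1.sites, co.counts, models)
    np.testing.assert_array_equal(a1.states, a2.states)


def test_step1_pass_recalls_as_pass(noise_free_cohort):
    # re-call criteria are a strict subset of step-1 criteria
    from rnamosaic.pipeline import fit_sample_models, step1_candidates

    co = noise_free_cohort
    bg = (co.sites["kind"] == "background").to_numpy()
    models = fit_sample_models(
        co.counts, background_mask=bg[co.counts["site_id"].to_numpy()],
        min_fit_sites=40)
    cand = step1_candidates(co.counts, models)
    array = recall_sites(cand[["chrom", "pos", "ref", "alt"]].astype({"pos": int}),
                         co.counts, models)
    keys = {k: i for i, k in enumerate(array.site_keys())}
    for _, row in cand.iterrows():
        s = keys[(str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))]
        tj = array.tissue_index(str(row["tissue"]))
        ij = array.individual_index(str(row["individual"]))
        assert array.states[s, tj, ij] == CallState.PASS


def test_recall_empty_candidates_rejected(tiny_array):
    with pytest.raises(ValueError):
        recall_sites(pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
                     pd.DataFrame(), {})


# -- germline subtraction --------------------------------------------------


def test_germline_in_one_individual_removes_site_cohort_wide(tiny_array):
    out = subtract_germline(tiny_array, {"I1": {("chr1", 100, "C", "T")}})
    assert out.n_sites == 1
    assert out.sites.iloc[0]["pos"] == 200
    assert out.filter_reasons[("chr1", 100, "C", "T")] == "germline"


def test_empty_germline_leaves_array_unchanged(tiny_array):
    out = subtract_germline(tiny_array, {"I1": set()})
    assert out.n_sites == tiny_array.n_sites


def test_germline_matching_is_allele_aware(tiny_array):
    # same position, different alt allele: retained (position-only matching
    # would wrongly remove it)
    out = subtract_germline(tiny_array, {"I1": {("chr1", 100, "C", "G")}})
    assert out.n_sites == 2
    naive_positions = {(c, p) for c, p, *_ in [("chr1", 100, "C", "G")]}
    naive_keep = [
        (k[0], k[1]) not in naive_positions for k in tiny_array.site_keys()
    ]
    assert naive_keep == [False, True]  # the naive oracle would differ


def test_malformed_germline_record_warns(tiny_array):
    with pytest.warns(UserWarning):
        out = subtract_germline(tiny_array, {"I1": {("chr1",)}})
    assert out.n_sites == 2


def test_load_germline_vcf_roundtrip(tmp_path):
    from rnamosaic.simdata import write_germline_vcf

    germ = {"I1": {("chr1", 100, "C", "T"), ("chr2", 55, "A", "G")}}
    path = tmp_path / "g.vcf"
    write_germline_vcf(germ, path)
    assert load_germline_vcf(path) == germ["I1"]


# -- cohort filters --------------------------------------------------------


def _array_with_pass_pattern(n_ind=5, pass_inds=(0, 1, 2), states_extra=None):
    tissues = ["T1", "T2"]
    inds = [f"I{j}" for j in range(n_ind)]
    sites = pd.DataFrame([{"chrom": "chr1", "pos": 100, "ref": "C", "alt": "T"}])
    states = np.full((1, 2, n_ind), CallState.HOM_REF.value, dtype=np.int8)
    for j in pass_inds:
        states[0, 0, j] = CallState.PASS.value
    ref = np.full((1, 2, n_ind), 90, dtype=np.int32)
    alt = np.zeros((1, 2, n_ind), dtype=np.int32)
    alt[0, 0, list(pass_inds)] = 10
    return GenotypeArray(sites, tissues, inds, states, ref, alt)


def test_site_passing_in_three_individuals_removed():
    arr = _array_with_pass_pattern(pass_inds=(0, 1, 2))
    out = cohort_filters(arr, max_individuals=2)
    assert out.n_sites == 0
    assert "recurrent_call" in out.filter_reasons[("chr1", 100, "C", "T")]


def test_site_passing_in_two_individuals_kept():
    arr = _array_with_pass_pattern(pass_inds=(0, 1))
    assert cohort_filters(arr, max_individuals=2).n_sites == 1


def test_pop_af_boundary_inclusive():
    arr = _array_with_pass_pattern(pass_inds=(0,))
    out = cohort_filters(arr, pop_af={("chr1", 100, "C", "T"): 0.01})
    assert out.n_sites == 0
    kept = cohort_filters(arr, pop_af={("chr1", 100, "C", "T"): 0.009})
    assert kept.n_sites == 1


def test_empty_resources_leave_array_unchanged():
    arr = _array_with_pass_pattern(pass_inds=(0,))
    out = cohort_filters(arr)
    assert out.n_sites == 1
    np.testing.assert_array_equal(out.states, arr.states)


def test_ubiquitous_site_removed():
    arr = _array_with_pass_pattern(n_ind=3, pass_inds=(0, 1, 2))
    arr.states[0, 1, :] = CallState.PASS.value  # PASS in every expressed cell
    out = cohort_filters(arr, max_individuals=10)
    assert "ubiquitous" in out.filter_reasons[("chr1", 100, "C", "T")]


def test_editing_and_interval_filters(tmp_path):
    arr = _array_with_pass_pattern(pass_inds=(0,))
    out = cohort_filters(arr, editing_sites={("chr1", 100, "C", "T")})
    assert out.n_sites == 0
    bed = tmp_path / "rep.bed"
    bed.write_text("chr1\t90\t110\n")
    out2 = cohort_filters(arr, repeat_trees=load_bed(bed))
    assert "repeat" in out2.filter_reasons[("chr1", 100, "C", "T")]
    bed2 = tmp_path / "rep2.bed"
    bed2.write_text("chr1\t100\t110\n")  # 0-based: starts after pos 100
    assert cohort_filters(arr, repeat_trees=load_bed(bed2)).n_sites == 1


def test_filters_are_order_independent(tmp_path):
    arr = _array_with_pass_pattern(n_ind=6, pass_inds=(0, 1, 2, 3))
    af = {("chr1", 100, "C", "T"): 0.05}
    ed = {("chr1", 100, "C", "T")}
    a = cohort_filters(cohort_filters(arr, pop_af=af), editing_sites=ed)
    b = cohort_filters(cohort_filters(arr, editing_sites=ed), pop_af=af)
    c = cohort_filters(arr, pop_af=af, editing_sites=ed)
    assert a.n_sites == b.n_sites == c.n_sites


def test_counts_conserved_through_filtering():
    arr = _array_with_pass_pattern(pass_inds=(0,))
    out = cohort_filters(arr, max_individuals=2)
    surviving = out.site_keys()
    for k in surviving:
        s_old = arr.site_keys().index(k)
        s_new = surviving.index(k)
        np.testing.assert_array_equal(out.alt_counts[s_new], arr.alt_counts[s_old])


def test_invalid_bed_line_reports_line_number(tmp_path):
    bed = tmp_path / "bad.bed"
    bed.write_text("chr1\t10\t20\nchr1\t30\tx\n")
    with pytest.raises(ValueError, match="line 2"):
        load_bed(bed)


# -- serialization ---------------------------------------------------------


def test_write_read_round_trip(tiny_array, tmp_path):
    path = tmp_path / "array.tsv"
    write_array(tiny_array, path)
    back = read_array(path)
    np.testing.assert_array_equal(back.states, tiny_array.states)
    np.testing.assert_array_equal(back.alt_counts, tiny_array.alt_counts)
    np.testing.assert_array_equal(back.ref_counts, tiny_array.ref_counts)
    assert back.tissues == tiny_array.tissues
    assert back.individuals == tiny_array.individuals


def test_pass_serializes_as_alt_base_and_na_for_no_expression(tiny_array, tmp_path):
    path = tmp_path / "array.tsv"
    write_array(tiny_array, path)
    wide = pd.read_csv(path, sep="\t", keep_default_na=False)
    assert wide.loc[0, "I1|T1"] == "T"     # PASS -> alt base letter
    assert wide.loc[0, "I1|T2"] == "NA"    # NO_EXPRESSION
    assert wide.loc[0, "I2|T1"] == "."     # HOM_REF
    assert wide.loc[1, "I2|T2"] == ""      # never-assayed cell stays blank


def test_missing_cell_distinguished_from_na_on_round_trip(tiny_array, tmp_path):
    path = tmp_path / "array.tsv"
    write_array(tiny_array, path)
    back = read_array(path)
    t2, i2 = back.tissue_index("T2"), back.individual_index("I2")
    t2_, i1 = back.tissue_index("T2"), back.individual_index("I1")
    assert back.states[1, t2, i2] == CallState.MISSING
    assert back.states[0, t2_, i1] == CallState.NO_EXPRESSION


def test_unknown_state_token_errors_with_coordinates(tiny_array, tmp_path):
    path = tmp_path / "array.tsv"
    write_array(tiny_array, path)
    companion = path.with_suffix(path.suffix + ".counts.tsv")
    txt = companion.read_text().replace("HOM_REF", "BOGUS", 1)
    companion.write_text(txt)
    with pytest.raises(ValueError, match="BOGUS"):
        read_array(path)
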