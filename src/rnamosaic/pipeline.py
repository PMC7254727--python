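"""End-to-end orchestration: fit error models, call, re-genotype, filter,
classify, and score against a simulated truth.

The per-sample reference implementation lives in :mod:`rnamosaic.error_model`
(:func:`call_sample`); this module provides an equivalent vectorized driver
for cohort-scale runs plus the truth-evaluation used by the simulation
studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import error_model as em
from . import genotype_array as ga
from . import lineage as lin
from .simdata import SimulatedCohort

SUB_CLASSES = list(em.SUBSTITUTION_CLASSES)


def fit_sample_models(counts: pd.DataFrame, *, background_mask=None,
                      method: str = "moments", min_fit_sites: int = 500) -> dict:
    """Fit one beta-binomial error model per (individual, tissue) sample.

    ``background_mask`` selects the putatively homozygous-reference rows used
    for fitting (default: all rows).
    """
    df = counts if background_mask is None else counts[background_mask]
    df = df.copy()
    df["alt_count"] = df["alt_fwd"] + df["alt_rev"]
    df["coverage"] = df["ref_fwd"] + df["ref_rev"] + df["alt_fwd"] + df["alt_rev"]
    df["cls"] = em.classify_substitutions(df["ref"].astype(str), df["alt"].astype(str)).to_numpy()
    models = {}
    for (ind, tis), sub in df.groupby(["individual", "tissue"], observed=True):
        models[(ind, tis)] = em.BetaBinomialErrorModel(
            method=method, min_fit_sites=min_fit_sites
        ).fit(sub)
    return models


def step1_candidates(
    counts: pd.DataFrame,
    models: dict,
    *,
    min_alt: int = 4,
    min_cov: int = 10,
    min_vaf: float = 0.05,
    min_dist: int = 20,
    q_threshold: float = 0.05,
    strand_bias_threshold: float = 0.01,
) -> pd.DataFrame:
    """Vectorized single-sample calling over a cohort count table.

    Equivalent to running :func:`rnamosaic.error_model.call_sample` per
    sample (property-tested against it); returns the rows that pass in at
    least one sample, annotated with p, q and the sample.
    """
    df = counts.copy()
    df["alt_count"] = df["alt_fwd"] + df["alt_rev"]
    df["coverage"] = df["ref_fwd"] + df["ref_rev"] + df["alt_fwd"] + df["alt_rev"]
    df["vaf"] = np.where(df["coverage"] > 0,
                         df["alt_count"] / df["coverage"].replace(0, 1), 0.0)
    cls = em.classify_substitutions(df["ref"].astype(str), df["alt"].astype(str))
    cls_code = cls.map({c: k for k, c in enumerate(SUB_CLASSES)}).to_numpy()

    sample_key = (df["individual"].astype(str) + "|" + df["tissue"].astype(str))
    sample_codes, sample_names = pd.factorize(sample_key)
    A = np.empty((len(sample_names), len(SUB_CLASSES)))
    B = np.empty_like(A)
    for si, name in enumerate(sample_names):
        ind, tis = name.split("|")
        m = models[(ind, tis)]
        for ci, c in enumerate(SUB_CLASSES):
            A[si, ci], B[si, ci] = m.class_params(c)

    alpha = A[sample_codes, cls_code]
    beta = B[sample_codes, cls_code]
    df["p"] = em.upper_tail_pvalues(
        df["alt_count"].to_numpy(), df["coverage"].to_numpy(), alpha, beta)

    q = np.ones(len(df))
    order = np.argsort(sample_codes, kind="stable")
    p_sorted = df["p"].to_numpy()[order]
    bounds = np.searchsorted(sample_codes[order], np.arange(len(sample_names) + 1))
    for si in range(len(sample_names)):
        lo, hi = bounds[si], bounds[si + 1]
        if hi > lo:
            q[order[lo:hi]] = em.fdr_adjust(p_sorted[lo:hi])
    df["q"] = q

    sig = (
        (df["q"] < q_threshold)
        & (df["alt_bq20"] >= min_alt)
        & (df["coverage"] >= min_cov)
        & (df["vaf"] >= min_vaf)
    ).to_numpy()

    # strand-bias test on the surviving candidates only
    sb_ok = sig.copy()
    for i in np.flatnonzero(sig):
        p_sb = em.strand_bias_pvalue(
            int(df["ref_fwd"].iat[i]), int(df["ref_rev"].iat[i]),
            int(df["alt_fwd"].iat[i]), int(df["alt_rev"].iat[i]))
        if p_sb < strand_bias_threshold:
            sb_ok[i] = False

    # proximity rule within (sample, chrom): both neighbours fail
    keep = sb_ok.copy()
    cand = df[sb_ok][["chrom", "pos"]].assign(
        _i=np.flatnonzero(sb_ok), _s=sample_codes[sb_ok])
    for (_, _), sub in cand.groupby(["_s", "chrom"], observed=True):
        pos = sub["pos"].to_numpy()
        idx = sub["_i"].to_numpy()
        srt = np.argsort(pos)
        pos, idx = pos[srt], idx[srt]
        close = np.diff(pos) < min_dist
        for j in np.flatnonzero(close):
            keep[idx[j]] = keep[idx[j + 1]] = False

    return df[keep].reset_index(drop=True)


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    array: ga.GenotypeArray          # after all cohort filters
    calls: pd.DataFrame              # classified mosaic calls
    metrics: dict


def rf_filter_candidates(candidates: pd.DataFrame, cohort: SimulatedCohort,
                         *, n_estimators: int = 500) -> pd.DataFrame:
    """Apply the RF call filter to step-1 candidate calls.

    A model is trained on labeled calls simulated under the cohort's own
    noise conditions; candidate calls whose response does not exceed the
    max-F1 threshold are dropped (a site survives if any of its calls do).
    """
    from . import rf_filter as rf
    from . import simdata

    labeled = simdata.simulate_labeled_calls(cohort.config)
    train, _ = rf.build_train_test(labeled, seed=cohort.config.seed + 7)
    model = rf.train_rf(train, seed=cohort.config.seed + 11,
                        n_estimators=n_estimators)
    feats = candidates.copy()
    feats["strand_bias"] = [
        em.strand_bias_pvalue(int(a), int(b), int(c), int(d))
        for a, b, c, d in zip(feats["ref_fwd"], feats["ref_rev"],
                              feats["alt_fwd"], feats["alt_rev"])
    ]
    feats["blacklisted_gene"] = False
    if "mean_alt_bq" not in feats.columns:
        feats["mean_alt_bq"] = 37.0
    keep = model.response(feats) > model.threshold_
    return candidates[keep].reset_index(drop=True)


def run_cohort_pipeline(
    cohort: SimulatedCohort,
    *,
    method: str = "moments",
    min_fit_sites: int = 500,
    min_tissues: int = 10,
    max_individuals: int = 2,
    lq_frac: float = 0.05,
    use_rf: bool = True,
    rf_estimators: int = 500,
) -> PipelineResult:
    """Run call -> RF filter -> re-genotype -> subtract/filter -> classify."""
    counts = cohort.counts
    bg = (cohort.sites["kind"] == "background").to_numpy()
    bg_mask = bg[counts["site_id"].to_numpy()]
    models = fit_sample_models(counts, background_mask=bg_mask,
                               method=method, min_fit_sites=min_fit_sites)
    candidates = step1_candidates(counts, models)
    if use_rf and not candidates.empty and not cohort.config.deterministic_counts:
        candidates = rf_filter_candidates(candidates, cohort,
                                          n_estimators=rf_estimators)
    if candidates.empty:
        return PipelineResult(candidates, None, pd.DataFrame(), {
            "n_candidates": 0, "n_calls": 0})

    array = ga.recall_sites(
        candidates[["chrom", "pos", "ref", "alt"]].astype({"pos": int}),
        counts, models)
    array = ga.subtract_germline(array, cohort.germline)
    array = ga.cohort_filters(
        array,
        pop_af=cohort.pop_af,
        editing_sites=cohort.editing_sites,
        systematic_sites=cohort.systematic_sites,
        max_individuals=max_individuals,
        lq_frac=lq_frac,
    )
    calls = lin.classify_array(array, cohort.tree, min_tissues=min_tissues)
    metrics = evaluate_against_truth(calls, cohort)
    return PipelineResult(candidates, array, calls, metrics)


def evaluate_against_truth(calls: pd.DataFrame, cohort: SimulatedCohort,
                           vaf_min: float = 0.1) -> dict:
    """Sensitivity, false-discovery proportion and class accuracy vs truth.

    Sensitivity counts planted mutations with truth VAF >= ``vaf_min`` that
    are expressed (>= 1 carrier tissue with coverage >= 10); the
    raw-denominator variant is also reported.  Class accuracy is computed on
    recovered mutations.
    """
    truth = cohort.truth
    truth_keys = {
        (r["chrom"], int(r["pos"]), r["ref"], r["alt"], r["individual"]):
            r["klass_truth"]
        for _, r in truth.iterrows()
    }
    called = calls[~calls["klass"].isin(["EXCLUDED_INDIVIDUAL"])]
    n_calls = len(called)
    hits, correct, false_pos = 0, 0, 0
    recovered = set()
    for _, c in called.iterrows():
        key = (c["chrom"], int(c["pos"]), c["ref"], c["alt"], c["individual"])
        if key in truth_keys:
            recovered.add(key)
            hits += 1
            if c["klass"] == truth_keys[key]:
                correct += 1
        else:
            false_pos += 1

    expressed = truth[truth["n_carrier_covered"] >= 1]
    det = expressed[expressed["vaf"] >= vaf_min]
    det_keys = {
        (r["chrom"], int(r["pos"]), r["ref"], r["alt"], r["individual"])
        for _, r in det.iterrows()
    }
    raw = truth[truth["vaf"] >= vaf_min]
    raw_keys = {
        (r["chrom"], int(r["pos"]), r["ref"], r["alt"], r["individual"])
        for _, r in raw.iterrows()
    }
    return {
        "n_candidates": None,
        "n_calls": n_calls,
        "n_truth": len(truth),
        "sensitivity": len(det_keys & recovered) / len(det_keys) if det_keys else None,
        "sensitivity_raw": len(raw_keys & recovered) / len(raw_keys) if raw_keys else None,
        "fdr": false_pos / n_calls if n_calls else 0.0,
        "klass_accuracy": correct / hits if hits else None,
        "n_recovered": hits,
    }
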