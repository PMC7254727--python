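"""Mosaic mutation-rate estimation and tissue-specific somatic rates.

Rates are estimated on constitutively expressed gene sets (genes above a TPM
or coverage threshold in more than 75% of samples), as mutations per base and
individual over the total interrogated exonic length L:

    rate = n_mutations / (L * n_individuals)

The per-nucleotide rate is extrapolated to a 45-Mbp exome and optionally
corrected for calling performance (x precision / sensitivity).  Confidence
intervals come from a percentile bootstrap over individuals.

Tissue-specific postnatal somatic rates (mutations per callable site,
coverage >= 10) are corrected for technical confounders with an OLS model

    rate ~ duplicates + cohort + RIN + TRISCHD + DP_median

and the residuals are tested per tissue for association with donor age
(Spearman, BH-corrected across tissues).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .error_model import fdr_adjust

EXOME_BP = 4.5e7
DEFAULT_PRECISION = 0.85
DEFAULT_SENSITIVITY = 0.71


@dataclass
class GeneSet:
    """A constitutively-expressed gene set with its interrogated length."""

    genes: list[str]
    lengths: dict[str, float]
    metric: str = ""
    threshold: float = 0.0
    fraction: float = 0.75

    @property
    def L(self) -> float:
        return float(sum(self.lengths[g] for g in self.genes))


def select_constitutive_genes(
    expression: pd.DataFrame,
    metric: str,
    threshold: float,
    lengths: dict[str, float],
    fraction: float = 0.75,
) -> GeneSet:
    """Genes with metric >= threshold in strictly more than ``fraction`` of samples.

    ``expression`` is a gene x sample table of the given metric (e.g. the
    TPM matrix or the mean-coverage matrix, selected by the caller);
    ``metric`` is recorded on the result and must be "TPM" or "COV".
    """
    if metric not in ("TPM", "COV"):
        raise ValueError(f"unknown expression metric: {metric!r}")
    if expression.empty:
        raise ValueError("empty expression table")
    frac_above = (expression >= threshold).mean(axis=1)
    genes = sorted(expression.index[frac_above > fraction])
    missing = [g for g in genes if g not in lengths]
    if missing:
        raise ValueError(f"no exonic length for gene(s): {missing[:5]}")
    return GeneSet(genes=genes, lengths={g: lengths[g] for g in genes},
                   metric=metric, threshold=threshold, fraction=fraction)


@dataclass
class RateEstimate:
    n_mutations: int
    L: float
    n_individuals: int
    rate: float
    ci_low: float
    ci_high: float
    exome_count: float
    corrected_count: float | None = None


def extrapolate(rate: float, exome_bp: float = EXOME_BP) -> float:
    """Expected exome-wide mutation count from a per-nucleotide rate."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return rate * exome_bp


def correct_for_performance(count: float, precision: float = DEFAULT_PRECISION,
                            sensitivity: float = DEFAULT_SENSITIVITY) -> float:
    """Adjust an expected count for calling performance (x precision / sensitivity)."""
    if not (0 < precision <= 1) or not (0 < sensitivity <= 1):
        raise ValueError("precision and sensitivity must lie in (0, 1]")
    return count * precision / sensitivity


def mutation_rate(
    mutations_per_individual,
    gene_set: GeneSet | float,
    n_individuals: int,
    *,
    n_boot: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
    precision: float | None = None,
    sensitivity: float | None = None,
) -> RateEstimate:
    """Per-nucleotide, per-individual mutation rate with bootstrap CI.

    ``mutations_per_individual`` is a sequence of per-individual mutation
    counts inside the gene set (length may be < n_individuals; missing
    individuals count 0).  ``gene_set`` may be a GeneSet or the interrogated
    length L in bp.  The CI is a seeded percentile bootstrap over
    individuals.
    """
    L = gene_set.L if isinstance(gene_set, GeneSet) else float(gene_set)
    if L <= 0:
        raise ValueError("interrogated length L must be > 0")
    if n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    counts = np.zeros(n_individuals, dtype=float)
    obs = np.asarray(list(mutations_per_individual), dtype=float)
    counts[: len(obs)] = obs
    n = int(counts.sum())
    rate = n / (L * n_individuals)
    if n == 0:
        lo = hi = 0.0
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_individuals, size=(n_boot, n_individuals))
        boots = counts[idx].sum(axis=1) / (L * n_individuals)
        a = (1 - ci) / 2
        lo, hi = np.quantile(boots, [a, 1 - a])
    exome = extrapolate(rate)
    corrected = None
    if precision is not None and sensitivity is not None:
        corrected = correct_for_performance(exome, precision, sensitivity)
    return RateEstimate(n, L, n_individuals, rate, float(lo), float(hi),
                        exome, corrected)


def lemm_rate(
    per_tissue_counts: dict,
    per_tissue_L: dict,
    n_individuals: int,
    n_tissues: int | None = None,
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Per-tissue LEMM rates and the summed per-individual exome expectation.

    ``per_tissue_counts`` maps tissue -> per-individual count vector;
    ``per_tissue_L`` maps tissue -> interrogated length for that tissue's
    expressed gene set.  The total is the mean per-tissue exome count times
    the number of examined tissues.
    """
    if n_tissues is None:
        n_tissues = len(per_tissue_counts)
    if n_tissues == 0:
        raise ValueError("n_tissues must be > 0")
    rows = []
    for k, tissue in enumerate(sorted(per_tissue_counts)):
        est = mutation_rate(
            per_tissue_counts[tissue], per_tissue_L[tissue], n_individuals,
            n_boot=n_boot, seed=seed + k,
        )
        rows.append({
            "tissue": tissue, "n_mutations": est.n_mutations, "L": est.L,
            "rate": est.rate, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "exome_count": est.exome_count,
        })
    df = pd.DataFrame(rows)
    total = float(df["exome_count"].mean() * n_tissues) if len(df) else 0.0
    return df, total


# -- tissue-specific somatic rates -----------------------------------------

QC_DEFAULTS = dict(
    max_duplicates_quantile=0.95,
    callable_quantiles=(0.01, 0.99),
    min_rin_quantile=0.01,
    max_rate_quantile=0.99,
    cultured_tissues=("cells-EBV-transformed_lymphocytes",
                      "cells-transformed_fibroblasts"),
    min_samples_per_tissue=50,
)


def qc_filter_samples(records: pd.DataFrame, **overrides) -> pd.DataFrame:
    """Sample-level QC for tissue-rate analysis.

    Drops: top-5% duplicate rates; top/bottom-1% callable sites per tissue;
    bottom-1% RIN per tissue; top-1% raw rate per tissue; cultured-cell
    tissues; cancer-affected individuals (boolean ``cancer`` column); and
    tissues left with fewer than 50 samples.
    """
    cfg = {**QC_DEFAULTS, **overrides}
    df = records.copy()
    if "cancer" in df.columns:
        df = df[~df["cancer"].astype(bool)]
    df = df[~df["tissue"].isin(cfg["cultured_tissues"])]
    df = df[df["duplicates"] <= df["duplicates"].quantile(cfg["max_duplicates_quantile"])]

    def tissue_mask(sub):
        lo, hi = cfg["callable_quantiles"]
        m = pd.Series(True, index=sub.index)
        if "callable_sites" in sub:
            m &= sub["callable_sites"].between(
                sub["callable_sites"].quantile(lo), sub["callable_sites"].quantile(hi)
            )
        if "RIN" in sub:
            m &= sub["RIN"] >= sub["RIN"].quantile(cfg["min_rin_quantile"])
        m &= sub["raw_rate"] <= sub["raw_rate"].quantile(cfg["max_rate_quantile"])
        return m

    masks = [tissue_mask(sub) for _, sub in df.groupby("tissue")]
    keep = pd.concat(masks) if masks else pd.Series(dtype=bool)
    df = df.loc[keep[keep].index]
    sizes = df.groupby("tissue")["raw_rate"].size()
    df = df[df["tissue"].isin(sizes[sizes >= cfg["min_samples_per_tissue"]].index)]
    return df.reset_index(drop=True)


def residual_rates(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """OLS residuals of raw rates against technical confounders.

    Fits ``raw_rate ~ duplicates + C(cohort) + RIN + TRISCHD + DP_median``;
    returns the records with a ``residual`` column and the fitted
    coefficients.  A rank-deficient design raises an error naming the
    collinear terms.
    """
    needed = ["raw_rate", "duplicates", "cohort", "RIN", "TRISCHD", "DP_median"]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    df = records.reset_index(drop=True).copy()

    numeric = ["duplicates", "RIN", "TRISCHD", "DP_median"]
    varying = [c for c in numeric if df[c].nunique() > 1]
    terms = list(varying)
    if df["cohort"].nunique() > 1:
        terms.append("C(cohort)")
    if not terms:
        # intercept-only fit: residuals are the centered raw rates
        df["residual"] = df["raw_rate"] - df["raw_rate"].mean()
        return df, pd.Series({"Intercept": df["raw_rate"].mean()})

    import patsy

    formula = "raw_rate ~ " + " + ".join(terms)
    X = patsy.dmatrix(" + ".join(terms), df, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        collinear = [
            c for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear term(s): {collinear}")
    fit = smf.ols(formula, data=df).fit()
    df["residual"] = fit.resid
    return df, fit.params


def age_association(records: pd.DataFrame, min_samples: int = 3) -> pd.DataFrame:
    """Per-tissue Spearman correlation of rate residuals with age.

    BH correction is applied across tissues (not within).  Tissues with
    constant residuals are flagged undefined and excluded from correction.
    """
    rows = []
    for tissue, sub in records.groupby("tissue"):
        if len(sub) < min_samples:
            continue
        x = sub["residual"].to_numpy(float)
        y = sub["age"].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append({"tissue": tissue, "rho": np.nan, "p": np.nan,
                         "n": len(sub), "undefined": True})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"tissue": tissue, "rho": float(rho), "p": float(p),
                     "n": len(sub), "undefined": False})
    df = pd.DataFrame(rows, columns=["tissue", "rho", "p", "n", "undefined"])
    df["q"] = np.nan
    ok = ~df["undefined"].astype(bool) if len(df) else []
    if len(df) and np.any(ok):
        df.loc[ok, "q"] = fdr_adjust(df.loc[ok, "p"].to_numpy())
    return df
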