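"""Beta-binomial sequencing-error model and single-sample variant calling.

Alternative-allele counts at homozygous-reference positions are modelled as

    alt_count ~ Binomial(coverage, error_rate)
    error_rate ~ Beta(alpha, beta)

i.e. a beta-binomial, fitted independently for each of the six strand-collapsed
nucleotide changes (A>C, A>T, A>G, C>A, C>T, C>G).  A site is a variant
candidate when its alternative-allele count falls significantly above the
fitted error distribution (upper-tail test, BH-corrected across the sample),
and it additionally clears a set of hard filters: minimum alt count with good
base quality, minimum coverage, minimum VAF, no strand bias, and a minimum
distance to the next candidate in the same sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six strand-collapsed substitution classes (reference base A or C).
SUBSTITUTION_CLASSES = ("A>C", "A>T", "A>G", "C>A", "C>T", "C>G")

#: Fallback weakly-informative prior: ~0.1% mean error rate.
FALLBACK_ALPHA = 1.0
FALLBACK_BETA = 1000.0


def classify_substitutions(ref, alt) -> pd.Series:
    """Vectorized substitution-class mapping for ref/alt columns."""
    pairs = pd.Series(ref).str.upper() + ">" + pd.Series(alt).str.upper()
    out = pairs.map(PAIR_TO_CLASS)
    if out.isna().any():
        bad = pairs[out.isna()].unique()
        raise ValueError(f"not SNV substitutions: {list(bad)[:5]}")
    return out


def substitution_class(ref: str, alt: str) -> str:
    """Map a (ref, alt) SNV to its strand-collapsed substitution class.

    Changes with a G or T reference are mapped through the reverse
    complement, so the collapse is involutive:
    class(ref, alt) == class(revcomp(ref), revcomp(alt)).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"not a SNV: {ref}>{alt}")
    if ref in "GT":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


#: All 12 (ref>alt) SNV patterns mapped to their strand-collapsed class.
PAIR_TO_CLASS = {
    f"{r}>{a}": None for r in "ACGT" for a in "ACGT" if r != a
}
for _pair in list(PAIR_TO_CLASS):
    _r, _a = _pair.split(">")
    PAIR_TO_CLASS[_pair] = substitution_class(_r, _a)
del _pair, _r, _a


@dataclass
class SiteObservation:
    """Strand-resolved pileup counts for one site in one sample.

    Positions are 1-based (VCF convention).  ``alt_bq`` holds the Phred base
    qualities of the alternative reads; coverage is the sum of the four
    strand-resolved counts.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    individual: str = ""
    tissue: str = ""
    ref_fwd: int = 0
    ref_rev: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    alt_bq: list[int] = field(default_factory=list)

    @property
    def coverage(self) -> int:
        return self.ref_fwd + self.ref_rev + self.alt_fwd + self.alt_rev

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def ref_count(self) -> int:
        return self.ref_fwd + self.ref_rev

    @property
    def vaf(self) -> float:
        cov = self.coverage
        return self.alt_count / cov if cov > 0 else 0.0

    @property
    def substitution_class(self) -> str:
        return substitution_class(self.ref, self.alt)


def _moments_from_sums(sum_k, sum_n, ssq, sum_nn1):
    """Beta-binomial method-of-moments from grouped sums.

    Given per-class totals of alt counts (``sum_k``), coverages (``sum_n``),
    squared residuals around the pooled mean (``ssq``) and ``sum n*(n-1)``,
    returns (alpha, beta).  Works on scalars or aligned arrays.  Classes with
    zero or degenerate signal get non-finite output and must be handled by
    the caller.
    """
    sum_k = np.asarray(sum_k, dtype=float)
    sum_n = np.asarray(sum_n, dtype=float)
    ssq = np.asarray(ssq, dtype=float)
    sum_nn1 = np.asarray(sum_nn1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = sum_k / sum_n
        pq = p * (1.0 - p)
        rho = (ssq - pq * sum_n) / (pq * sum_nn1)
        # rho <= 0 means no detectable overdispersion: use a near-binomial
        # concentration; rho >= 1 is maximal overdispersion.
        rho = np.clip(rho, 1.0 / (1.0 + 1e6), 1.0 - 1e-9)
        conc = 1.0 / rho - 1.0
        alpha = p * conc
        beta = (1.0 - p) * conc
    return alpha, beta


def _mle_refine(k, n, alpha0, beta0):
    """Maximum-likelihood beta-binomial fit, seeded from the moments fit."""
    from scipy.optimize import minimize
    from scipy.special import betaln

    k = np.asarray(k, float)
    n = np.asarray(n, float)

    def nll(theta):
        a, b = np.exp(theta)
        return -np.sum(betaln(k + a, n - k + b) - betaln(a, b))

    res = minimize(nll, np.log([alpha0, beta0]), method="Nelder-Mead")
    a, b = np.exp(res.x)
    if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
        return alpha0, beta0
    return float(a), float(b)


class BetaBinomialErrorModel:
    """Per-sample beta-binomial error model, one (alpha, beta) per class.

    Parameters
    ----------
    method : {"moments", "mle"}
        Fitting method.  ``moments`` is the closed-form default; ``mle``
        refines the moments fit by maximum likelihood and falls back to the
        moments estimate when the optimum is non-finite.
    min_fit_sites : int
        Minimum number of homozygous-reference sites per substitution class;
        classes below this receive the fallback prior (alpha=1, beta=1000).
    """

    def __init__(self, method: str = "moments", min_fit_sites: int = 500):
        if method not in ("moments", "mle"):
            raise ValueError(f"unknown method: {method!r}")
        self.method = method
        self.min_fit_sites = min_fit_sites

    # -- fitting -----------------------------------------------------------

    def fit(self, observations) -> "BetaBinomialErrorModel":
        """Fit from putatively homozygous-reference observations.

        ``observations`` may be an iterable of :class:`SiteObservation` or a
        DataFrame with columns ``ref``, ``alt``, ``alt_count``, ``coverage``
        (or strand-resolved count columns).
        """
        df = _as_count_frame(observations)
        self.params_: dict[str, tuple[float, float]] = {}
        self.n_sites_used_: dict[str, int] = {}
        self.fallback_classes_: set[str] = set()
        if df.empty:
            warnings.warn("no observations: fallback error model for all classes")
            for cls in SUBSTITUTION_CLASSES:
                self.params_[cls] = (FALLBACK_ALPHA, FALLBACK_BETA)
                self.n_sites_used_[cls] = 0
                self.fallback_classes_.add(cls)
            return self

        classes = (
            df["cls"] if "cls" in df.columns
            else classify_substitutions(df["ref"], df["alt"])
        )
        for cls in SUBSTITUTION_CLASSES:
            sub = df[classes == cls]
            k = sub["alt_count"].to_numpy(float)
            n = sub["coverage"].to_numpy(float)
            ok = n > 0
            k, n = k[ok], n[ok]
            self.n_sites_used_[cls] = int(len(k))
            if len(k) < self.min_fit_sites or k.sum() == 0:
                self.params_[cls] = (FALLBACK_ALPHA, FALLBACK_BETA)
                self.fallback_classes_.add(cls)
                continue
            p = k.sum() / n.sum()
            ssq = float(np.sum((k - n * p) ** 2))
            a, b = _moments_from_sums(k.sum(), n.sum(), ssq, np.sum(n * (n - 1.0)))
            a, b = float(a), float(b)
            if not (np.isfinite(a) and np.isfinite(b) and a > 0 and b > 0):
                self.params_[cls] = (FALLBACK_ALPHA, FALLBACK_BETA)
                self.fallback_classes_.add(cls)
                continue
            if self.method == "mle":
                a, b = _mle_refine(k, n, a, b)
            self.params_[cls] = (a, b)
        return self

    # -- querying ----------------------------------------------------------

    def class_params(self, cls: str) -> tuple[float, float]:
        if cls not in self.params_:
            raise KeyError(f"unknown substitution class: {cls!r}")
        return self.params_[cls]

    def mean_error_rate(self, cls: str) -> float:
        a, b = self.class_params(cls)
        return a / (a + b)

    def sf(self, alt_count, coverage, cls: str):
        """Upper-tail probability P(X >= alt_count | coverage, alpha, beta)."""
        a, b = self.class_params(cls)
        return stats.betabinom.sf(np.asarray(alt_count) - 1, coverage, a, b)


def fit_error_model(hom_ref_observations, method: str = "moments",
                    min_fit_sites: int = 500) -> BetaBinomialErrorModel:
    """Fit a :class:`BetaBinomialErrorModel` (thin functional wrapper)."""
    return BetaBinomialErrorModel(method=method, min_fit_sites=min_fit_sites).fit(
        hom_ref_observations
    )


def _as_count_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        df = observations.copy()
    else:
        rows = [
            {
                "ref": o.ref,
                "alt": o.alt,
                "alt_count": o.alt_count,
                "coverage": o.coverage,
            }
            for o in observations
        ]
        df = pd.DataFrame(rows, columns=["ref", "alt", "alt_count", "coverage"])
    if df.empty:
        return df
    if "alt_count" not in df.columns:
        df["alt_count"] = df["alt_fwd"] + df["alt_rev"]
    if "coverage" not in df.columns:
        df["coverage"] = df["ref_fwd"] + df["ref_rev"] + df["alt_fwd"] + df["alt_rev"]
    return df


# -- site testing ----------------------------------------------------------


def site_pvalue(obs: SiteObservation, model: BetaBinomialErrorModel):
    """Upper-tail beta-binomial p-value for one site.

    Returns ``(p, flag)`` where flag is ``"no_expression"`` for zero-coverage
    sites (p defined as 1) and ``""`` otherwise.
    """
    if obs.coverage == 0:
        return 1.0, "no_expression"
    cls = substitution_class(obs.ref, obs.alt)
    p = float(model.sf(obs.alt_count, obs.coverage, cls))
    return min(max(p, 0.0), 1.0), ""


def upper_tail_pvalues(alt, cov, alpha, beta):
    """Vectorized P(X >= alt | cov, alpha, beta) for per-cell parameters.

    Computes 1 - sum_{j<alt} pmf(j), looping over j up to max(alt); cheap
    because observed alt counts are small.  Zero-coverage cells get p = 1.
    """
    alt = np.asarray(alt, dtype=np.int64)
    cov = np.asarray(cov, dtype=np.int64)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    p = np.ones(alt.shape, dtype=float)
    active = (alt > 0) & (cov > 0)
    if not active.any():
        return p
    cdf = np.zeros(alt.shape, dtype=float)
    kmax = int(alt[active].max())
    for j in range(kmax):
        todo = active & (alt > j) & (cov >= j)
        if not todo.any():
            break
        cdf[todo] += stats.betabinom.pmf(j, cov[todo], alpha[todo], beta[todo])
    p[active] = np.clip(1.0 - cdf[active], 0.0, 1.0)
    return p


def fdr_adjust(pvalues):
    """Benjamini-Hochberg adjusted q-values (order-preserving, q >= p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def strand_bias_pvalue(ref_fwd, ref_rev, alt_fwd, alt_rev) -> float:
    """Fisher exact p for the 2x2 strand table (ref fwd/rev vs alt fwd/rev)."""
    table = [[ref_fwd, ref_rev], [alt_fwd, alt_rev]]
    return float(stats.fisher_exact(table)[1])


def single_sample_filter(
    obs: SiteObservation,
    q: float,
    neighbors=(),
    *,
    min_alt: int = 4,
    min_bq: int = 20,
    min_cov: int = 10,
    min_vaf: float = 0.05,
    min_dist: int = 20,
    q_threshold: float = 0.05,
    strand_bias_threshold: float = 0.01,
    alt_bq20: int | None = None,
):
    """Apply the single-sample hard filters to one tested site.

    ``neighbors`` are the positions of the other candidate sites on the same
    chromosome in the same sample.  Returns ``(passed, reasons)`` where
    ``reasons`` is a tuple of codes for every failed criterion; degenerate
    inputs always yield a fail with a reason rather than an error.
    """
    reasons = []
    cov = obs.coverage
    if cov == 0:
        return False, ("no_expression",)
    if not (q < q_threshold):
        reasons.append("not_significant")
    n_good_alt = (
        alt_bq20
        if alt_bq20 is not None
        else sum(1 for b in obs.alt_bq if b >= min_bq)
    )
    if n_good_alt < min_alt:
        reasons.append("min_alt_count")
    if cov < min_cov:
        reasons.append("min_coverage")
    if obs.vaf < min_vaf:
        reasons.append("min_vaf")
    if strand_bias_pvalue(obs.ref_fwd, obs.ref_rev, obs.alt_fwd, obs.alt_rev) < strand_bias_threshold:
        reasons.append("strand_bias")
    if any(abs(int(n) - obs.pos) < min_dist for n in neighbors):
        reasons.append("proximity")
    return (len(reasons) == 0), tuple(reasons)


# -- per-sample driver -----------------------------------------------------


def call_sample(
    counts: pd.DataFrame,
    model: BetaBinomialErrorModel,
    *,
    min_alt: int = 4,
    min_bq: int = 20,
    min_cov: int = 10,
    min_vaf: float = 0.05,
    min_dist: int = 20,
    q_threshold: float = 0.05,
    strand_bias_threshold: float = 0.01,
) -> pd.DataFrame:
    """Step-1 single-sample calling for one sample's pileup count table.

    Expects columns ``chrom, pos, ref, alt, ref_fwd, ref_rev, alt_fwd,
    alt_rev`` plus either ``alt_bq`` (comma string or list of Phred ints) or a
    precomputed ``alt_bq20`` column (number of alt reads with BQ >= 20).
    Returns the table with ``p``, ``q``, ``pass_`` and ``reasons`` columns.
    """
    df = counts.copy().reset_index(drop=True)
    df["alt_count"] = df["alt_fwd"] + df["alt_rev"]
    df["coverage"] = df["ref_fwd"] + df["ref_rev"] + df["alt_fwd"] + df["alt_rev"]
    df["vaf"] = np.where(df["coverage"] > 0, df["alt_count"] / df["coverage"].replace(0, 1), 0.0)
    if "alt_bq20" not in df.columns:
        df["alt_bq20"] = [
            _count_bq(bq, min_bq) for bq in df.get("alt_bq", [""] * len(df))
        ]
    cls = [substitution_class(r, a) for r, a in zip(df["ref"], df["alt"])]
    ab = np.array([model.class_params(c) for c in cls], dtype=float)
    df["p"] = upper_tail_pvalues(
        df["alt_count"].to_numpy(), df["coverage"].to_numpy(), ab[:, 0], ab[:, 1]
    ) if len(df) else np.array([])
    df["q"] = fdr_adjust(df["p"].to_numpy()) if len(df) else np.array([])

    sig = (
        (df["q"] < q_threshold)
        & (df["alt_bq20"] >= min_alt)
        & (df["coverage"] >= min_cov)
        & (df["vaf"] >= min_vaf)
    )
    # strand bias only evaluated on otherwise-passing candidates (cheap)
    sb_fail = np.zeros(len(df), dtype=bool)
    for i in np.flatnonzero(sig.to_numpy()):
        r = df.iloc[i]
        if strand_bias_pvalue(r["ref_fwd"], r["ref_rev"], r["alt_fwd"], r["alt_rev"]) < strand_bias_threshold:
            sb_fail[i] = True
    cand = sig.to_numpy() & ~sb_fail
    # proximity: candidates within min_dist of each other both fail
    prox_fail = np.zeros(len(df), dtype=bool)
    cand_idx = np.flatnonzero(cand)
    by_chrom: dict[str, list[int]] = {}
    for i in cand_idx:
        by_chrom.setdefault(df.at[i, "chrom"], []).append(i)
    for idxs in by_chrom.values():
        poss = sorted(idxs, key=lambda i: df.at[i, "pos"])
        for a, b in zip(poss, poss[1:]):
            if abs(int(df.at[b, "pos"]) - int(df.at[a, "pos"])) < min_dist:
                prox_fail[a] = prox_fail[b] = True

    reasons = []
    for i in range(len(df)):
        r = []
        if df.at[i, "coverage"] == 0:
            reasons.append("no_expression")
            continue
        if not (df.at[i, "q"] < q_threshold):
            r.append("not_significant")
        if df.at[i, "alt_bq20"] < min_alt:
            r.append("min_alt_count")
        if df.at[i, "coverage"] < min_cov:
            r.append("min_coverage")
        if df.at[i, "vaf"] < min_vaf:
            r.append("min_vaf")
        if sb_fail[i]:
            r.append("strand_bias")
        if prox_fail[i]:
            r.append("proximity")
        reasons.append(",".join(r))
    df["reasons"] = reasons
    df["pass_"] = [rs == "" for rs in reasons]
    return df


def _count_bq(bq, min_bq: int) -> int:
    if isinstance(bq, str):
        vals = [int(x) for x in bq.split(",") if x.strip()]
    elif bq is None or (np.isscalar(bq) and pd.isna(bq)):
        vals = []
    else:
        vals = list(bq)
    return sum(1 for v in vals if v >= min_bq)


# -- pileup TSV I/O --------------------------------------------------------

PILEUP_COLUMNS = [
    "chrom", "pos", "ref", "alt", "individual", "tissue",
    "ref_fwd", "ref_rev", "alt_fwd", "alt_rev", "alt_bq",
]


def read_pileup_tsv(path) -> pd.DataFrame:
    """Read a pileup count table (1-based positions, VCF convention)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt_bq": str})
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns and c != "alt_bq"]
    if missing:
        raise ValueError(f"pileup table missing columns: {missing}")
    if "alt_bq" in df.columns:
        df["alt_bq"] = df["alt_bq"].fillna("")
    elif "alt_bq20" not in df.columns:
        raise ValueError("pileup table needs an alt_bq or alt_bq20 column")
    return df


def write_pileup_tsv(df: pd.DataFrame, path) -> None:
    cols = [c for c in PILEUP_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)
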