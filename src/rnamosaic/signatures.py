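"""96-context mutation catalogs and mutational-signature refitting.

Catalogs follow the COSMIC convention: 6 pyrimidine-reference substitutions
(C>A, C>G, C>T, T>A, T>C, T>G) x 16 trinucleotide contexts, purine-reference
mutations reverse-complemented into the pyrimidine frame.  Refitting against
a known reference signature matrix is done by nonnegative least squares with
a simplex cap (weights >= 0, sum <= 1) — a deterministic convex program
rather than iterative forward selection.  Only weights above a display
threshold (default 0.1) appear in the report view; raw weights are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
COSMIC_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"

#: Fixed catalog index order: substitution-major, then 5' base, then 3' base,
#: e.g. "A[C>A]A", "A[C>A]C", ..., "T[T>G]T".
CONTEXT_LABELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in COSMIC_SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}


def context_label(ref: str, alt: str, five: str, three: str) -> str:
    """COSMIC-frame label for one mutation with its flanking bases."""
    ref, alt, five, three = (x.upper() for x in (ref, alt, five, three))
    for b in (ref, alt, five, three):
        if b not in _COMPLEMENT:
            raise ValueError(f"invalid base {b!r}")
    if ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref in "AG":  # purine reference: flip into the pyrimidine frame
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return f"{five}[{ref}>{alt}]{three}"


@dataclass
class MutationCatalog:
    """96-vector of context counts; ``n_dropped`` counts N-context losses."""

    counts: np.ndarray
    n_dropped: int = 0

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty mutation catalog")
        return self.counts / total

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS), name="count")


def build_catalog(mutations: pd.DataFrame) -> MutationCatalog:
    """Count mutations into the 96-context catalog.

    ``mutations`` needs columns ``ref``, ``alt``, ``five``, ``three`` (the 5'
    and 3' flanking bases).  Mutations with an N in any base are dropped and
    counted in ``n_dropped``; all others are conserved.
    """
    counts = np.zeros(96, dtype=float)
    dropped = 0
    for ref, alt, five, three in zip(
        mutations["ref"], mutations["alt"], mutations["five"], mutations["three"]
    ):
        try:
            lab = context_label(ref, alt, five, three)
        except ValueError:
            dropped += 1
            continue
        counts[_LABEL_INDEX[lab]] += 1
    return MutationCatalog(counts, dropped)


@dataclass
class SignatureWeights:
    weights: pd.Series          # raw nonnegative weights, sum <= 1
    residual_norm: float
    min_weight: float = 0.1

    def report(self) -> pd.Series:
        """Display view: weights <= min_weight zeroed (raw values retained)."""
        w = self.weights.copy()
        w[w <= self.min_weight] = 0.0
        return w


def refit(catalog: MutationCatalog, reference: pd.DataFrame,
          min_weight: float = 0.1) -> SignatureWeights:
    """Express a catalog as a nonnegative mixture of reference signatures.

    Minimizes ||normalize(catalog) - R w||_2 subject to w >= 0 and
    sum(w) <= 1.  Reference columns must each sum to 1 (96 rows).  The plain
    NNLS solution is used when already feasible; otherwise the simplex-capped
    optimum is found with SLSQP from the rescaled NNLS start.
    """
    R = reference.to_numpy(dtype=float)
    if R.shape[0] != 96:
        raise ValueError("reference signature matrix must have 96 rows")
    colsums = R.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("reference signature columns must each sum to 1")
    b = catalog.normalized()

    w, _ = nnls(R, b)
    if w.sum() > 1.0 + 1e-9:
        from scipy.optimize import minimize

        w0 = w / w.sum()

        def obj(x):
            r = R @ x - b
            return float(r @ r)

        def grad(x):
            return 2.0 * R.T @ (R @ x - b)

        res = minimize(
            obj, w0, jac=grad, method="SLSQP",
            bounds=[(0.0, None)] * R.shape[1],
            constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                          "jac": lambda x: -np.ones_like(x)}],
            options={"ftol": 1e-14, "maxiter": 500},
        )
        w = np.clip(res.x, 0.0, None)
    resid = float(np.linalg.norm(R @ w - b))
    return SignatureWeights(
        pd.Series(w, index=list(reference.columns), name="weight"),
        resid, min_weight,
    )


def compare_exposures(weights_a, weights_b) -> float:
    """Two-sided Mann-Whitney U p-value on per-sample signature weights."""
    a = np.asarray(list(weights_a), dtype=float)
    b = np.asarray(list(weights_b), dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 samples per group")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


# -- signature matrix I/O --------------------------------------------------


def read_signature_matrix(path) -> pd.DataFrame:
    """Signature TSV: 96 rows (context labels in the documented order) x K columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [l for l in CONTEXT_LABELS if l not in df.index]
    if missing:
        raise ValueError(f"signature matrix missing context row(s): {missing[:3]}")
    return df.loc[list(CONTEXT_LABELS)]


def write_signature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="context")
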