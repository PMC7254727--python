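"""Random-forest filtering of RNA-seq variant calls (RF-RNAmut).

A random forest separates true from false variant calls using six features:
alternative allele count, coverage, VAF, strand bias (Fisher p-value of the
strand 2x2 table), blacklisted-gene membership, and mean alternative base
quality.  Training data are balanced between true and false calls and across
VAF bins, with low-VAF (< 10%) training records doubled to boost low-VAF
sensitivity.  The response threshold is chosen as the maximum-F1 point on the
training set; calls whose response strictly exceeds it are kept.  The printed
threshold of any one data set is dataset-specific and is always recomputed.
"""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score

FEATURES = [
    "alt_count", "coverage", "vaf", "strand_bias", "blacklisted_gene",
    "mean_alt_bq",
]


def featurize(ref_fwd, ref_rev, alt_fwd, alt_rev, mean_alt_bq,
              blacklisted_gene=False) -> dict:
    """Compute the six classifier features from strand-resolved counts."""
    from .error_model import strand_bias_pvalue

    alt = alt_fwd + alt_rev
    cov = ref_fwd + ref_rev + alt
    return {
        "alt_count": alt,
        "coverage": cov,
        "vaf": alt / cov if cov else 0.0,
        "strand_bias": strand_bias_pvalue(ref_fwd, ref_rev, alt_fwd, alt_rev),
        "blacklisted_gene": bool(blacklisted_gene),
        "mean_alt_bq": float(mean_alt_bq),
    }


def _validate_features(X: pd.DataFrame) -> np.ndarray:
    missing = [c for c in FEATURES if c not in X.columns]
    if missing:
        raise ValueError(f"feature vector missing field(s): {missing}")
    M = X[FEATURES].astype(float).to_numpy()
    if not np.isfinite(M).all():
        bad = [FEATURES[j] for j in np.unique(np.argwhere(~np.isfinite(M))[:, 1])]
        raise ValueError(f"non-finite values in feature(s): {bad}")
    return M


class RandomForestCallFilter(BaseEstimator, ClassifierMixin):
    """sklearn-style wrapper: forest + max-F1 response threshold.

    Parameters follow sklearn conventions; fitted attributes carry a
    trailing underscore (``forest_``, ``threshold_``, ``train_f1_``).
    """

    def __init__(self, n_estimators: int = 500, random_state: int | None = None,
                 threshold_step: float = 0.01, max_features: str = "sqrt"):
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.threshold_step = threshold_step
        self.max_features = max_features

    def fit(self, X: pd.DataFrame, y) -> "RandomForestCallFilter":
        M = _validate_features(X)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            max_features=self.max_features,
            n_jobs=1,
        ).fit(M, y)
        resp = self.forest_.predict_proba(M)[:, 1]
        grid = np.arange(0.0, 1.0 + 1e-9, self.threshold_step)
        f1s = np.array([f1_score(y, resp > t, zero_division=0) for t in grid])
        # tie -> lowest threshold
        self.threshold_ = float(grid[int(np.argmax(f1s))])
        self.train_f1_ = float(f1s.max())
        self.classes_ = self.forest_.classes_
        return self

    def response(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest_.predict_proba(_validate_features(X))[:, 1]

    def predict_proba(self, X):
        return self.forest_.predict_proba(_validate_features(X))

    def predict(self, X) -> np.ndarray:
        # strict "exceeding": response exactly at threshold is rejected
        return (self.response(X) > self.threshold_).astype(int)


def train_rf(train: pd.DataFrame, seed: int | None = None,
             n_estimators: int = 500) -> RandomForestCallFilter:
    """Train the call filter on a labeled table (thin wrapper)."""
    if train.empty:
        raise ValueError("empty training set")
    return RandomForestCallFilter(
        n_estimators=n_estimators, random_state=seed
    ).fit(train, train["label"].to_numpy())


def classify(calls: pd.DataFrame, model: RandomForestCallFilter) -> pd.DataFrame:
    """Return the confident-call subset with response values attached."""
    out = calls.copy()
    if out.empty:
        out["response"] = np.array([], dtype=float)
        return out
    out["response"] = model.response(out)
    return out[out["response"] > model.threshold_].reset_index(drop=True)


# -- training-set construction ---------------------------------------------


def build_train_test(
    labeled: pd.DataFrame,
    seed: int,
    *,
    n_bins: int = 10,
    low_vaf: float = 0.10,
    balance_tol: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Balanced, VAF-uniform train/test split of labeled calls.

    Records are binned by VAF (``n_bins`` bins on [0, 1)); within each label
    the per-bin count is capped at the smallest populated bin so that the VAF
    histogram is approximately uniform, then the label counts are equalized.
    Records are split 50/50; training records with VAF < ``low_vaf`` are then
    duplicated once.  Fully seed-reproducible.
    """
    df = labeled.reset_index(drop=True).copy()
    if "label" not in df.columns:
        raise ValueError("labeled calls need a 'label' column")
    rng = np.random.default_rng(seed)
    df["_bin"] = np.clip((df["vaf"] * n_bins).astype(int), 0, n_bins - 1)
    if df["_bin"].nunique() < 2:
        raise ValueError("need >= 2 populated VAF strata")

    picked = []
    for label, sub in df.groupby("label"):
        counts = sub.groupby("_bin").size()
        # flatten the VAF histogram: dense bins are downsampled to the
        # median populated-bin size
        cap = max(1, int(np.median(counts)))
        for _, bin_sub in sub.groupby("_bin"):
            idx = rng.permutation(bin_sub.index.to_numpy())[:cap]
            picked.append(idx)
    sel = df.loc[np.concatenate(picked)]

    n_true = int((sel["label"] == 1).sum())
    n_false = int((sel["label"] == 0).sum())
    n_keep = min(n_true, n_false)
    if n_keep < 2:
        raise ValueError(
            f"cannot balance labels: {n_true} true vs {n_false} false records "
            "after VAF-uniform selection"
        )
    parts = []
    for label, sub in sel.groupby("label"):
        idx = rng.permutation(sub.index.to_numpy())[:n_keep]
        parts.append(sel.loc[idx])
    sel = pd.concat(parts)
    ratio = n_keep / n_keep  # balanced by construction
    assert abs(ratio - 1) <= balance_tol

    order = rng.permutation(sel.index.to_numpy())
    half = len(order) // 2
    train = sel.loc[order[:half]].drop(columns="_bin")
    test = sel.loc[order[half:]].drop(columns="_bin")
    dup = train[train["vaf"] < low_vaf]
    train = pd.concat([train, dup]).reset_index(drop=True)
    return train, test.reset_index(drop=True)


# -- evaluation ------------------------------------------------------------


def evaluate(test: pd.DataFrame, model: RandomForestCallFilter,
             vaf_split: float = 0.35) -> dict:
    """Precision/recall overall and per VAF stratum.

    Strata: germline-like (truth VAF >= ``vaf_split``) vs somatic-like
    (truth VAF < ``vaf_split``).  Empty strata report metrics as None
    (undefined), never 0.  Confusion counts are returned for audit.
    """
    y = test["label"].to_numpy().astype(int)
    yhat = model.predict(test)
    truth_vaf = test.get("truth_vaf", test["vaf"]).to_numpy()

    def metrics(mask):
        yy, hh = y[mask], yhat[mask]
        tp = int(((yy == 1) & (hh == 1)).sum())
        fp = int(((yy == 0) & (hh == 1)).sum())
        fn = int(((yy == 1) & (hh == 0)).sum())
        tn = int(((yy == 0) & (hh == 0)).sum())
        return {
            "precision": tp / (tp + fp) if tp + fp else None,
            "recall": tp / (tp + fn) if tp + fn else None,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn, "n": int(mask.sum()),
        }

    return {
        "overall": metrics(np.ones(len(y), dtype=bool)),
        "germline_like": metrics(truth_vaf >= vaf_split),
        "somatic_like": metrics(truth_vaf < vaf_split),
        "threshold": model.threshold_,
    }


def permutation_null_f1(
    train: pd.DataFrame,
    test: pd.DataFrame,
    *,
    n_perm: int = 100,
    seed: int = 0,
    n_estimators: int = 500,
) -> np.ndarray:
    """Held-out F1 of forests retrained on label-permuted training data.

    The features stay fixed; only training labels are permuted.  Used as the
    null distribution against which the real model's test F1 is compared.
    """
    rng = np.random.default_rng(seed)
    y_test = test["label"].to_numpy().astype(int)
    out = np.empty(n_perm)
    perm_train = train.copy()
    for i in range(n_perm):
        perm_train["label"] = rng.permutation(train["label"].to_numpy())
        if perm_train["label"].nunique() < 2:  # pathological tiny inputs
            out[i] = 0.0
            continue
        m = RandomForestCallFilter(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31))
        ).fit(perm_train, perm_train["label"].to_numpy())
        out[i] = f1_score(y_test, m.predict(test), zero_division=0)
    return out


# -- model persistence -----------------------------------------------------


def save_model(model: RandomForestCallFilter, path) -> None:
    path = Path(path)
    with open(path, "wb") as fh:
        pickle.dump(model, fh)
    meta = {
        "threshold": model.threshold_,
        "train_f1": model.train_f1_,
        "n_estimators": model.n_estimators,
        "random_state": model.random_state,
        "features": FEATURES,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def load_model(path) -> RandomForestCallFilter:
    with open(path, "rb") as fh:
        return pickle.load(fh)
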