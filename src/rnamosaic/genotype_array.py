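"""The 3D genotype array: multi-sample re-genotyping and cohort filters.

Candidate sites that were significant in at least one sample are re-evaluated
in *every* sample (tissue x individual) with relaxed post-filters (no strand
bias test, no proximity rule), producing one of four call states per cell:
NO_EXPRESSION, HOM_REF, LOW_QUALITY or PASS.  Cells for samples that were
never assayed are kept distinct from NO_EXPRESSION.  Exact reference and
alternative counts are retained for every non-missing cell.

Cohort-level filters then remove germline variants (cohort-wide), common
population variants, RNA-editing sites, repeat/low-complexity overlaps,
systematic-error sites, ubiquitous calls, recurrent low-quality sites, and
sites called in more than ``max_individuals`` individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd

from .error_model import classify_substitutions, fdr_adjust, upper_tail_pvalues


class CallState(IntEnum):
    MISSING = -1          # sample never assayed / site absent from its table
    NO_EXPRESSION = 0
    HOM_REF = 1
    LOW_QUALITY = 2
    PASS = 3


_STATE_NAMES = {s.value: s.name for s in CallState}

SITE_COLUMNS = ["chrom", "pos", "ref", "alt"]


def site_key(row) -> tuple:
    return (str(row["chrom"]), int(row["pos"]), str(row["ref"]), str(row["alt"]))


@dataclass
class GenotypeArray:
    """site x tissue x individual array of call states and counts."""

    sites: pd.DataFrame            # columns chrom,pos,ref,alt (+ flag columns)
    tissues: list[str]
    individuals: list[str]
    states: np.ndarray             # (S, T, I) int8 of CallState values
    ref_counts: np.ndarray         # (S, T, I) int32
    alt_counts: np.ndarray         # (S, T, I) int32
    significant: np.ndarray | None = None   # (S, T, I) bool, q < threshold
    filter_reasons: dict[tuple, str] = field(default_factory=dict)

    def __post_init__(self):
        s, t, i = len(self.sites), len(self.tissues), len(self.individuals)
        assert self.states.shape == (s, t, i), "state array shape mismatch"

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> list[tuple]:
        return [site_key(r) for _, r in self.sites.iterrows()]

    def tissue_index(self, tissue: str) -> int:
        return self.tissues.index(tissue)

    def individual_index(self, individual: str) -> int:
        return self.individuals.index(individual)

    def vaf(self) -> np.ndarray:
        cov = self.ref_counts + self.alt_counts
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(cov > 0, self.alt_counts / np.maximum(cov, 1), 0.0)
        return v

    def subset_sites(self, mask) -> "GenotypeArray":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeArray(
            sites=self.sites.loc[mask].reset_index(drop=True),
            tissues=list(self.tissues),
            individuals=list(self.individuals),
            states=self.states[mask],
            ref_counts=self.ref_counts[mask],
            alt_counts=self.alt_counts[mask],
            significant=None if self.significant is None else self.significant[mask],
            filter_reasons=dict(self.filter_reasons),
        )


# -- re-genotyping ---------------------------------------------------------


def recall_sites(
    candidates: pd.DataFrame,
    all_samples: pd.DataFrame,
    models: dict,
    *,
    c_expr: int = 5,
    q_threshold: float = 0.05,
    min_alt: int = 3,
    min_vaf: float = 0.05,
) -> GenotypeArray:
    """Re-genotype candidate sites in every sample into a 3D genotype array.

    Parameters
    ----------
    candidates : DataFrame with chrom,pos,ref,alt (unique sites).
    all_samples : long-format count table with columns chrom,pos,ref,alt,
        individual,tissue,ref_fwd,ref_rev,alt_fwd,alt_rev.  Samples present
        in this table define the assayed (individual, tissue) pairs; a site
        absent from an assayed sample's rows stays MISSING.
    models : {(individual, tissue): BetaBinomialErrorModel}.

    Cell rules: coverage < ``c_expr`` -> NO_EXPRESSION; significant at
    q < ``q_threshold`` with alt >= ``min_alt`` and VAF >= ``min_vaf`` ->
    PASS; alt >= 2 or significant-but-below-thresholds -> LOW_QUALITY;
    otherwise HOM_REF.  Significance is BH-adjusted per sample across its
    candidate cells.
    """
    if candidates.empty:
        raise ValueError("candidate site list is empty")
    cand = candidates[SITE_COLUMNS].drop_duplicates().reset_index(drop=True)
    keys = {site_key(r): i for i, (_, r) in enumerate(cand.iterrows())}

    samples = (
        all_samples[["individual", "tissue"]].drop_duplicates().itertuples(index=False)
    )
    sample_list = sorted((s.individual, s.tissue) for s in samples)
    tissues = sorted({t for _, t in sample_list})
    individuals = sorted({i for i, _ in sample_list})
    t_idx = {t: j for j, t in enumerate(tissues)}
    i_idx = {i: j for j, i in enumerate(individuals)}

    S, T, I = len(cand), len(tissues), len(individuals)
    states = np.full((S, T, I), CallState.MISSING.value, dtype=np.int8)
    refc = np.zeros((S, T, I), dtype=np.int32)
    altc = np.zeros((S, T, I), dtype=np.int32)
    signif = np.zeros((S, T, I), dtype=bool)

    df = all_samples.merge(cand, on=SITE_COLUMNS, how="inner")
    df = df.copy()
    df["alt_count"] = df["alt_fwd"] + df["alt_rev"]
    df["coverage"] = df["ref_fwd"] + df["ref_rev"] + df["alt_fwd"] + df["alt_rev"]
    df["cls"] = classify_substitutions(df["ref"], df["alt"]).to_numpy()

    for (ind, tis), sub in df.groupby(["individual", "tissue"], sort=False, observed=True):
        model = models[(ind, tis)]
        ab = np.array([model.class_params(c) for c in sub["cls"]], dtype=float)
        alt = sub["alt_count"].to_numpy()
        cov = sub["coverage"].to_numpy()
        p = upper_tail_pvalues(alt, cov, ab[:, 0], ab[:, 1])
        q = fdr_adjust(p)
        vaf = np.where(cov > 0, alt / np.maximum(cov, 1), 0.0)
        sig = q < q_threshold
        cell_states = np.where(
            cov < c_expr,
            CallState.NO_EXPRESSION.value,
            np.where(
                sig & (alt >= min_alt) & (vaf >= min_vaf),
                CallState.PASS.value,
                np.where(
                    (alt >= 2) | sig,
                    CallState.LOW_QUALITY.value,
                    CallState.HOM_REF.value,
                ),
            ),
        ).astype(np.int8)
        rows = np.array([keys[k] for k in map(site_key, sub.to_dict("records"))])
        tj, ij = t_idx[tis], i_idx[ind]
        states[rows, tj, ij] = cell_states
        refc[rows, tj, ij] = (sub["ref_fwd"] + sub["ref_rev"]).to_numpy()
        altc[rows, tj, ij] = alt
        signif[rows, tj, ij] = sig

    return GenotypeArray(cand, tissues, individuals, states, refc, altc,
                         significant=signif)


# -- germline subtraction --------------------------------------------------


def subtract_germline(array: GenotypeArray, germline: dict) -> GenotypeArray:
    """Remove sites germline in ANY individual, for ALL individuals.

    ``germline`` maps individual -> set of (chrom, pos, ref, alt) tuples.
    Matching is allele-aware: a germline record with a different alt allele
    does not remove the site.
    """
    union: set[tuple] = set()
    for recs in germline.values():
        for rec in recs:
            try:
                chrom, pos, ref, alt = rec
                union.add((str(chrom), int(pos), str(ref), str(alt)))
            except (TypeError, ValueError):
                warnings.warn(f"skipping malformed germline record: {rec!r}")
    keep = np.array([k not in union for k in array.site_keys()], dtype=bool)
    out = array.subset_sites(keep)
    for k, kept in zip(array.site_keys(), keep):
        if not kept:
            out.filter_reasons[k] = "germline"
    return out


def load_germline_vcf(path) -> set[tuple]:
    """Read SNV records from a (plain-text or bgzipped) VCF via cyvcf2."""
    from cyvcf2 import VCF

    out: set[tuple] = set()
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            if len(rec.REF) == 1 and len(alt) == 1:
                out.add((str(rec.CHROM), int(rec.POS), rec.REF, alt))
    return out


# -- annotation resources --------------------------------------------------


def load_bed(path):
    """Load a BED file (0-based half-open) into per-chromosome interval trees."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if start < 0 or end <= start:
                    raise ValueError
            except (IndexError, ValueError):
                raise ValueError(f"{path}: invalid BED record at line {ln}: {line!r}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _in_intervals(trees, chrom: str, pos: int) -> bool:
    """pos is 1-based; BED trees are 0-based half-open."""
    tree = trees.get(chrom) if trees else None
    return bool(tree is not None and tree.overlaps(pos - 1))


def load_site_list(path) -> set[tuple]:
    """Site-list TSV (chrom, pos[, ref, alt]) -> set of keys.

    Two-column lists match by position only; four-column lists by allele.
    """
    sites: set[tuple] = set()
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = list(df.columns)
    for _, r in df.iterrows():
        if len(cols) >= 4:
            sites.add((str(r[cols[0]]), int(r[cols[1]]), str(r[cols[2]]), str(r[cols[3]])))
        else:
            sites.add((str(r[cols[0]]), int(r[cols[1]])))
    return sites


def _site_in_list(key: tuple, sites: set) -> bool:
    return key in sites or key[:2] in sites


# -- cohort filters --------------------------------------------------------


def cohort_filters(
    array: GenotypeArray,
    *,
    pop_af: dict | None = None,
    editing_sites: set | None = None,
    repeat_trees=None,
    lowcomplexity_trees=None,
    systematic_sites: set | None = None,
    max_individuals: int = 2,
    pop_af_max: float = 0.01,
    lq_frac: float = 0.05,
) -> GenotypeArray:
    """Apply cohort-level artifact filters; drops whole sites, never counts.

    Removal criteria (order-independent):

    - population allele frequency >= ``pop_af_max`` (boundary inclusive)
    - known RNA-editing site
    - overlap with a repeat or low-complexity interval
    - known systematic-error site
    - PASS in every expressed cell of the cohort (ubiquitous call)
    - LOW_QUALITY calls in more than ``lq_frac`` of individuals
    - PASS in more than ``max_individuals`` individuals
    """
    pop_af = pop_af or {}
    editing_sites = editing_sites or set()
    systematic_sites = systematic_sites or set()
    keys = array.site_keys()
    st = array.states
    expressed = st >= CallState.HOM_REF.value
    is_pass = st == CallState.PASS.value
    is_lq = st == CallState.LOW_QUALITY.value
    n_ind = len(array.individuals)

    reasons: list[str] = []
    for s, key in enumerate(keys):
        r = []
        af = pop_af.get(key, pop_af.get(key[:2]))
        if af is not None and af >= pop_af_max:
            r.append("pop_af")
        if _site_in_list(key, editing_sites):
            r.append("editing")
        if _in_intervals(repeat_trees, key[0], key[1]):
            r.append("repeat")
        if _in_intervals(lowcomplexity_trees, key[0], key[1]):
            r.append("low_complexity")
        if _site_in_list(key, systematic_sites):
            r.append("systematic_error")
        n_expr = int(expressed[s].sum())
        if n_expr > 0 and int(is_pass[s].sum()) == n_expr:
            r.append("ubiquitous")
        # LQ recurrence counts individuals with *significant* low-quality
        # signal but no PASS call: carriers of a true mosaic often show
        # marginal LQ cells in their own low-coverage tissues, and isolated
        # alt>=2 noise cells are not artifact recurrence either
        lq_sig = is_lq[s]
        if array.significant is not None:
            lq_sig = lq_sig & array.significant[s]
        lq_only = lq_sig.any(axis=0) & ~is_pass[s].any(axis=0)
        ind_with_lq = int(lq_only.sum())
        if n_ind > 0 and ind_with_lq >= 2 and ind_with_lq / n_ind > lq_frac:
            r.append("recurrent_lq")
        ind_with_pass = int((is_pass[s].any(axis=0)).sum())
        if ind_with_pass > max_individuals:
            r.append("recurrent_call")
        reasons.append(",".join(r))

    keep = np.array([r == "" for r in reasons], dtype=bool)
    out = array.subset_sites(keep)
    for key, r in zip(keys, reasons):
        if r:
            out.filter_reasons[key] = r
    return out


# -- serialization ---------------------------------------------------------


def write_array(array: GenotypeArray, path) -> None:
    """Write the array as a wide call table plus a long counts companion.

    The call table has one row per site and one column per
    ``individual|tissue`` cell: PASS cells carry the alternative allele
    letter, HOM_REF and LOW_QUALITY carry ".", NO_EXPRESSION carries "NA",
    and never-assayed cells are left empty.  The companion
    ``<path>.counts.tsv`` carries the full state names and exact counts, so
    the round trip is lossless.
    """
    path = Path(path)
    cols = {}
    for tj, t in enumerate(array.tissues):
        for ij, i in enumerate(array.individuals):
            col = f"{i}|{t}"
            tokens = []
            for s in range(array.n_sites):
                st = array.states[s, tj, ij]
                if st == CallState.MISSING:
                    tokens.append("")
                elif st == CallState.NO_EXPRESSION:
                    tokens.append("NA")
                elif st == CallState.PASS:
                    tokens.append(str(array.sites.at[s, "alt"]))
                else:
                    tokens.append(".")
            cols[col] = tokens
    wide = pd.concat([array.sites.reset_index(drop=True), pd.DataFrame(cols)], axis=1)
    wide.to_csv(path, sep="\t", index=False)

    rows = []
    nz = np.argwhere(array.states != CallState.MISSING.value)
    for s, tj, ij in nz:
        rows.append(
            {
                "chrom": array.sites.at[s, "chrom"],
                "pos": array.sites.at[s, "pos"],
                "ref": array.sites.at[s, "ref"],
                "alt": array.sites.at[s, "alt"],
                "individual": array.individuals[ij],
                "tissue": array.tissues[tj],
                "state": _STATE_NAMES[int(array.states[s, tj, ij])],
                "ref_count": int(array.ref_counts[s, tj, ij]),
                "alt_count": int(array.alt_counts[s, tj, ij]),
            }
        )
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "individual", "tissue",
                 "state", "ref_count", "alt_count"],
    ).to_csv(path.with_suffix(path.suffix + ".counts.tsv"), sep="\t", index=False)


def read_array(path) -> GenotypeArray:
    """Read an array written by :func:`write_array` (lossless round trip)."""
    path = Path(path)
    wide = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    cell_cols = [c for c in wide.columns if "|" in c]
    site_cols = [c for c in wide.columns if "|" not in c]
    sites = wide[site_cols].copy()
    sites["pos"] = sites["pos"].astype(int)
    individuals = sorted({c.split("|")[0] for c in cell_cols})
    tissues = sorted({c.split("|")[1] for c in cell_cols})
    S, T, I = len(sites), len(tissues), len(individuals)
    states = np.full((S, T, I), CallState.MISSING.value, dtype=np.int8)
    refc = np.zeros((S, T, I), dtype=np.int32)
    altc = np.zeros((S, T, I), dtype=np.int32)

    name_to_state = {s.name: s.value for s in CallState}
    long = pd.read_csv(
        path.with_suffix(path.suffix + ".counts.tsv"),
        sep="\t",
        dtype={"chrom": str},
    )
    key_to_row = {site_key(r): i for i, (_, r) in enumerate(sites.iterrows())}
    t_idx = {t: j for j, t in enumerate(tissues)}
    i_idx = {i: j for j, i in enumerate(individuals)}
    for _, r in long.iterrows():
        k = site_key(r)
        if k not in key_to_row:
            raise ValueError(f"counts companion references unknown site {k}")
        s = key_to_row[k]
        tj, ij = t_idx[r["tissue"]], i_idx[r["individual"]]
        if r["state"] not in name_to_state:
            raise ValueError(
                f"unknown state token {r['state']!r} at site {k}, "
                f"individual {r['individual']}, tissue {r['tissue']}"
            )
        states[s, tj, ij] = name_to_state[r["state"]]
        refc[s, tj, ij] = int(r["ref_count"])
        altc[s, tj, ij] = int(r["alt_count"])

    # cross-check the wide dialect for unknown tokens
    for c in cell_cols:
        for s, tok in enumerate(wide[c]):
            if tok not in ("", ".", "NA") and tok != str(sites.at[s, "alt"]):
                raise ValueError(
                    f"unknown call token {tok!r} at site row {s}, cell {c}"
                )
    return GenotypeArray(sites, tissues, individuals, states, refc, altc)
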