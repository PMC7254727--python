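"""Synthetic cohort generator: lineage-placed mosaic mutations with
beta-binomial sequencing noise, expression dropout and planted artifacts.

The generator emulates every input of the calling pipeline so that the whole
package is testable without external data:

- Mutations are placed on the embryogenesis tree.  A mutation at division
  ``d`` under symmetric cell contributions has cell fraction ``0.5**d`` in
  descendant tissues and (diploid, heterozygous, no allele-specific
  expression) VAF ``0.5**(d+1)``.  Tissue-to-tissue variability in early-cell
  contributions is modelled by a per-tissue carriage pattern (and an optional
  gamma-weighted asymmetric-contribution mode), which is what makes
  zygote-stage mutations detectable in *most* but not all expressed tissues.
- Read counts: coverage is negative binomial (variance mu + phi mu^2);
  sequencing errors draw one error propensity per site from the
  class-specific Beta(alpha, beta), shared across samples — error hotspots
  are a property of the site, so they recur across individuals exactly like
  the systematic artifacts the cohort filters remove.
- Planted artifacts: per-individual germline variants (written to VCF),
  recurrent RNA-editing sites, recurrent error hotspots and common
  population variants, each visible to the corresponding filter.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .lineage import LineageTree, default_tree

_BASES = "ACGT"
# 12 SNV patterns, two per strand-collapsed class
_PATTERNS = [(r, a) for r in _BASES for a in _BASES if r != a]


@dataclass
class SimConfig:
    """Study conditions for a simulated multi-tissue cohort."""

    seed: int = 0
    n_individuals: int = 10
    n_tissues: int | None = None       # None: all 49 tree leaves
    # region model
    n_genes: int = 50
    gene_length: int = 1500
    n_background_sites: int = 3000     # hom-ref sites used for error fitting
    # planted mutations per individual
    n_eemm: int = 2
    n_memm: int = 2
    n_lemm: int = 2
    n_somatic: int = 2
    #: genome-wide mutations per cell per division during early embryogenesis
    mutations_per_division: float = 3.0
    genome_bp: float = 3.2e9
    # read-count model
    coverage_mean: float = 100.0
    coverage_dispersion: float = 0.3   # var = mu + phi mu^2; 0 = fixed coverage
    error_alpha: float = 1.0
    error_beta: float = 3000.0
    expression_dropout: float = 0.15   # per gene x tissue x individual
    mean_bq: float = 37.0              # base quality of true variant reads
    bq_sd: float = 2.0
    err_bq: float = 26.0               # miscalled bases carry lower quality
    err_bq_sd: float = 6.0
    # lineage propagation
    carriage_prob: float = 0.7         # per-tissue carriage below the origin
    dirichlet_alpha: float | None = None  # asymmetric-contribution strength
    # planted artifacts
    n_germline: int = 5                # per individual
    n_editing: int = 5
    n_recurrent: int = 3
    n_popaf: int = 3

    def noise_free(self) -> "SimConfig":
        """Deterministic variant: fixed coverage, exact counts, no errors."""
        return replace(self, coverage_dispersion=0.0, error_beta=1e9,
                       expression_dropout=0.0)

    @property
    def deterministic_counts(self) -> bool:
        return self.coverage_dispersion == 0.0 and self.error_beta >= 1e8


def select_tissues(tree: LineageTree, n: int | None) -> list[str]:
    """A germ-layer-balanced, deterministic subset of tree leaves."""
    if n is None or n >= len(tree.leaves):
        return sorted(tree.leaves)
    by_layer: dict[str, list[str]] = {}
    for leaf in sorted(tree.leaves):
        by_layer.setdefault(tree.germ_layer_of(leaf) or "other", []).append(leaf)
    layers = [by_layer[g] for g in ("ectoderm", "mesoderm", "endoderm") if g in by_layer]
    out: list[str] = []
    i = 0
    while len(out) < n:
        pool = layers[i % len(layers)]
        if pool:
            out.append(pool.pop(0))
        i += 1
        if not any(layers):
            break
    return sorted(out)


@dataclass
class SimulatedCohort:
    """Everything the pipeline consumes, plus the ground truth."""

    config: SimConfig
    tree: LineageTree
    tissues: list[str]
    individuals: list[str]
    genes: pd.DataFrame            # gene, chrom, start, length
    sites: pd.DataFrame            # site_id, chrom, pos, ref, alt, gene, kind
    truth: pd.DataFrame            # one row per planted mutation x individual
    counts: pd.DataFrame           # long pileup table for every cell
    expression: dict               # {"TPM": gene x sample df, "COV": ...}
    germline: dict                 # individual -> set of site keys
    editing_sites: set
    pop_af: dict
    systematic_sites: set = field(default_factory=set)


# -- mutation placement ----------------------------------------------------


def _carriage_pattern(rng, tissues_in_scope, all_tissues, tree, klass,
                      carriage_prob, max_tries: int = 200):
    """Draw carrier tissues for one mutation, honouring its class pattern."""
    scope = list(tissues_in_scope)
    for _ in range(max_tries):
        carriers = [t for t in scope if rng.random() < carriage_prob]
        if klass == "EEMM":
            branches = {
                tree.root_branch_of(t)
                for t in carriers if t not in tree.adrenal_tissues
            }
            if len(branches) < 2:
                continue
            if len(carriers) >= len(all_tissues):   # must miss >= 1 tissue
                continue
            if not _coherent_pattern(carriers, all_tissues, tree, tree.root):
                continue
            return carriers
        if klass == "MEMM":
            if len(carriers) < 2:
                continue
            node = tree.lca(carriers)
            if node == tree.root:
                continue
            if not _coherent_pattern(carriers, all_tissues, tree, node):
                continue
            return carriers
    raise RuntimeError(f"could not draw a valid {klass} carriage pattern")


def _coherent_pattern(carriers, all_tissues, tree, node, f_min=0.2):
    cset, aset = set(carriers), set(all_tissues)
    for child in tree.children[node]:
        leaves = tree.subtree_leaves(child)
        np_, ne = len(cset & leaves), len(aset & leaves)
        if np_ and ne > 1 and np_ / ne < f_min:
            return False
    return True


def simulate_lineage_mutations(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    tree: LineageTree | None = None,
    tissues: list[str] | None = None,
    genes: pd.DataFrame | None = None,
    expressed=None,
) -> pd.DataFrame:
    """Place mosaic mutations on the lineage tree for every individual.

    Returns the truth table with one row per (mutation, individual): origin
    node, division index, per-tissue VAF (dict column ``tissue_vaf``), and
    the class implied by the origin.  ``expressed`` is an optional
    (gene, tissue, individual) -> bool lookup used to plant single-tissue
    mutations in expressed genes.
    """
    rng = rng or np.random.default_rng(config.seed)
    tree = tree or default_tree()
    tissues = tissues or select_tissues(tree, config.n_tissues)
    genes = genes if genes is not None else make_gene_table(config)
    individuals = [f"IND{j:03d}" for j in range(config.n_individuals)]
    lemm_ok = [
        t for t in tissues
        if t not in tree.clonal_expansion_tissues and t not in tree.adrenal_tissues
    ]

    def gene_for(tissue_list, ind):
        # prefer genes expressed in the relevant tissues of this individual
        cand = genes["gene"].tolist()
        if expressed is not None:
            cand = [
                g for g in cand
                if all(expressed(g, t, ind) for t in tissue_list)
            ] or genes["gene"].tolist()
        return cand[rng.integers(len(cand))]

    rows = []
    mut_id = 0
    for ind in individuals:
        specs = (
            [("EEMM", None)] * config.n_eemm
            + [("MEMM", None)] * config.n_memm
            + [("LEMM", None)] * config.n_lemm
            + [("SOMATIC", None)] * config.n_somatic
        )
        for klass, _ in specs:
            if klass == "EEMM":
                division = int(rng.choice([1, 2]))
                carriers = _carriage_pattern(
                    rng, tissues, tissues, tree, "EEMM", config.carriage_prob)
                origin = tree.root
            elif klass == "MEMM":
                division = int(rng.choice([2, 3]))
                branch = ["ectoderm", "mesendoderm"][int(rng.integers(2))]
                scope = [t for t in tissues
                         if tree.root_branch_of(t) == branch]
                carriers = _carriage_pattern(
                    rng, scope, tissues, tree, "MEMM", config.carriage_prob)
                origin = tree.lca(carriers)
            elif klass == "LEMM":
                division = 1
                carriers = [lemm_ok[rng.integers(len(lemm_ok))]]
                origin = carriers[0]
            else:  # postnatal somatic: single tissue, sub-LEMM cell fraction
                division = 3
                carriers = [tissues[rng.integers(len(tissues))]]
                origin = carriers[0]
            base_vaf = 0.5 ** (division + 1)
            tissue_vaf = {}
            for t in carriers:
                v = base_vaf
                if config.dirichlet_alpha is not None:
                    a = config.dirichlet_alpha
                    v = min(0.5, v * rng.gamma(a, 1.0 / a))
                tissue_vaf[t] = v
            gene = gene_for(carriers, ind)
            rows.append({
                "mutation_id": mut_id,
                "individual": ind,
                "klass_truth": klass,
                "origin_node": origin,
                "division": division,
                "vaf": base_vaf,
                "gene": gene,
                "carrier_tissues": ",".join(sorted(carriers)),
                "tissue_vaf": tissue_vaf,
            })
            mut_id += 1
    return pd.DataFrame(rows)


def expected_mutations_per_region(config: SimConfig, region_bp: float,
                                  n_divisions: int) -> float:
    """Expected mutation count in a region over the modelled divisions,
    scaling the genome-wide per-division burden down to the region."""
    per_division = config.mutations_per_division * region_bp / config.genome_bp
    return per_division * n_divisions


def make_gene_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for g in range(config.n_genes):
        chrom = f"chr{g % 22 + 1}"
        start = 10_000 + (g // 22) * (config.gene_length + 5_000)
        rows.append({"gene": f"GENE{g:04d}", "chrom": chrom, "start": start,
                     "length": config.gene_length})
    return pd.DataFrame(rows)


# -- count simulation ------------------------------------------------------


def _nb_coverage(rng, mu, phi, size):
    if phi <= 0:
        return np.full(size, int(round(mu)), dtype=np.int32)
    # gamma-poisson mixture: var = mu + phi mu^2
    shape = 1.0 / phi
    lam = rng.gamma(shape, mu / shape, size=size)
    return rng.poisson(lam).astype(np.int32)


def simulate_cohort(config: SimConfig, tree: LineageTree | None = None) -> SimulatedCohort:
    """Generate a full cohort: truth, pileup counts, expression, artifacts."""
    rng = np.random.default_rng(config.seed)
    tree = tree or default_tree()
    tissues = select_tissues(tree, config.n_tissues)
    individuals = [f"IND{j:03d}" for j in range(config.n_individuals)]
    genes = make_gene_table(config)
    G, T, I = len(genes), len(tissues), len(individuals)

    # expression dropout per gene x tissue x individual
    drop = rng.random((G, T, I)) < config.expression_dropout
    gidx = {g: i for i, g in enumerate(genes["gene"])}
    tidx = {t: i for i, t in enumerate(tissues)}
    iidx = {i_: j for j, i_ in enumerate(individuals)}

    def expressed(g, t, ind):
        return not drop[gidx[g], tidx[t], iidx[ind]]

    truth = simulate_lineage_mutations(
        config, rng, tree, tissues, genes, expressed=expressed)

    # -- site table --------------------------------------------------------
    site_rows: list[dict] = []
    positions_used: dict[str, int] = {}

    def new_site(gene_row, ref, alt, kind):
        chrom = gene_row["chrom"]
        offset = positions_used.get(gene_row["gene"], 0)
        pos = int(gene_row["start"]) + offset
        positions_used[gene_row["gene"]] = offset + 31  # clear of the 20bp rule
        site_rows.append({
            "site_id": len(site_rows), "chrom": chrom, "pos": pos,
            "ref": ref, "alt": alt, "gene": gene_row["gene"], "kind": kind,
        })
        return len(site_rows) - 1

    gene_lookup = genes.set_index("gene")

    # background hom-ref sites, class-balanced
    bg_per_pattern = max(1, config.n_background_sites // len(_PATTERNS))
    for pi, (ref, alt) in enumerate(_PATTERNS):
        for k in range(bg_per_pattern):
            g = genes.iloc[(pi * bg_per_pattern + k) % G]
            new_site(g, ref, alt, "background")

    # one site per planted mutation
    truth_site_ids = []
    for _, m in truth.iterrows():
        ref, alt = _PATTERNS[rng.integers(len(_PATTERNS))]
        g = pd.concat([gene_lookup.loc[[m["gene"]]].reset_index()]).iloc[0]
        truth_site_ids.append(new_site(g, ref, alt, "mutation"))
    truth = truth.assign(site_id=truth_site_ids)

    # artifacts
    germline: dict[str, set] = {ind: set() for ind in individuals}
    for ind in individuals:
        for _ in range(config.n_germline):
            ref, alt = _PATTERNS[rng.integers(len(_PATTERNS))]
            g = genes.iloc[rng.integers(G)]
            s = new_site(g, ref, alt, "germline")
            r = site_rows[s]
            germline[ind].add((r["chrom"], r["pos"], r["ref"], r["alt"]))

    editing_sites: set = set()
    editing_ids = []
    for _ in range(config.n_editing):
        ref, alt = ("A", "G") if rng.random() < 0.8 else ("T", "C")
        g = genes.iloc[rng.integers(G)]
        s = new_site(g, ref, alt, "editing")
        r = site_rows[s]
        editing_sites.add((r["chrom"], r["pos"], r["ref"], r["alt"]))
        editing_ids.append(s)

    recurrent_ids = []
    for _ in range(config.n_recurrent):
        ref, alt = _PATTERNS[rng.integers(len(_PATTERNS))]
        g = genes.iloc[rng.integers(G)]
        recurrent_ids.append(new_site(g, ref, alt, "recurrent"))

    pop_af: dict = {}
    popaf_ids = []
    for _ in range(config.n_popaf):
        ref, alt = _PATTERNS[rng.integers(len(_PATTERNS))]
        g = genes.iloc[rng.integers(G)]
        s = new_site(g, ref, alt, "popaf")
        r = site_rows[s]
        pop_af[(r["chrom"], r["pos"], r["ref"], r["alt"])] = 0.05
        popaf_ids.append(s)

    sites = pd.DataFrame(site_rows)
    S = len(sites)

    # -- per-cell VAF matrix ----------------------------------------------
    vaf = np.zeros((S, T, I), dtype=np.float32)
    for _, m in truth.iterrows():
        ij = iidx[m["individual"]]
        for t, v in m["tissue_vaf"].items():
            vaf[m["site_id"], tidx[t], ij] = v
    for ind, recs in germline.items():
        ij = iidx[ind]
        for s, r in enumerate(site_rows):
            if r["kind"] == "germline" and (r["chrom"], r["pos"], r["ref"], r["alt"]) in recs:
                vaf[s, :, ij] = 0.5
    if editing_ids:
        # editing: recurrent across individuals in a fixed tissue subset
        for s in editing_ids:
            tsub = rng.random(T) < 0.6
            vaf[s, tsub, :] = 0.3
    if popaf_ids:
        for s in popaf_ids:
            carriers = rng.random(I) < 0.3
            vaf[s, :, carriers] = 0.5

    # -- error propensities ------------------------------------------------
    # iid beta draw per cell (the beta-binomial noise model); planted
    # systematic hotspots get a site-level propensity shared across samples
    if config.deterministic_counts:
        p_err = np.zeros((S, T, I))
    else:
        p_err = rng.beta(config.error_alpha, config.error_beta, size=(S, T, I))
    for s in recurrent_ids:
        p_err[s] = np.maximum(p_err[s], 0.03)

    # -- counts ------------------------------------------------------------
    gene_of_site = sites["gene"].map(gidx).to_numpy()
    site_drop = drop[gene_of_site]               # (S, T, I)
    cov = _nb_coverage(rng, config.coverage_mean, config.coverage_dispersion,
                       (S, T, I))
    cov[site_drop] = 0
    if config.deterministic_counts:
        alt = np.round(cov * vaf).astype(np.int32)
        alt_fwd = alt // 2
        ref_n = cov - alt
        ref_fwd = ref_n // 2
        alt_bq20 = alt.copy()
        mean_bq = np.full(alt.shape, config.mean_bq, dtype=np.float32)
    else:
        # true variant reads and miscalled error reads, with distinct base
        # qualities: miscalls carry systematically lower BQ
        alt_true = rng.binomial(cov, vaf).astype(np.int32)
        alt_err = rng.binomial(cov - alt_true, p_err).astype(np.int32)
        alt = alt_true + alt_err
        alt_fwd = rng.binomial(alt, 0.5).astype(np.int32)
        ref_n = cov - alt
        ref_fwd = rng.binomial(ref_n, 0.5).astype(np.int32)
        from scipy.stats import norm

        p20_true = float(norm.sf(19.5, config.mean_bq, config.bq_sd))
        p20_err = float(norm.sf(19.5, config.err_bq, config.err_bq_sd))
        alt_bq20 = (
            rng.binomial(alt_true, p20_true) + rng.binomial(alt_err, p20_err)
        ).astype(np.int32)
        bq_t = rng.normal(config.mean_bq, config.bq_sd, size=alt.shape)
        bq_e = rng.normal(config.err_bq, config.err_bq_sd, size=alt.shape)
        with np.errstate(invalid="ignore"):
            mean_bq = np.where(
                alt > 0,
                np.clip((alt_true * bq_t + alt_err * bq_e) / np.maximum(alt, 1), 2, 42),
                config.mean_bq,
            ).astype(np.float32)

    counts = _counts_long(sites, tissues, individuals, cov, alt, alt_fwd,
                          ref_n, ref_fwd, alt_bq20, mean_bq)

    # -- expression tables -------------------------------------------------
    sample_cols = [f"{ind}|{t}" for ind in individuals for t in tissues]
    base_tpm = np.exp(rng.normal(np.log(50.0), 0.8, size=G))
    tpm = np.empty((G, len(sample_cols)))
    covm = np.empty_like(tpm)
    for j, col in enumerate(sample_cols):
        ind, t = col.split("|")
        mask = ~drop[:, tidx[t], iidx[ind]]
        tpm[:, j] = np.where(mask, base_tpm, 0.0)
        covm[:, j] = np.where(mask, base_tpm / 50.0 * config.coverage_mean, 0.0)
    expression = {
        "TPM": pd.DataFrame(tpm, index=genes["gene"], columns=sample_cols),
        "COV": pd.DataFrame(covm, index=genes["gene"], columns=sample_cols),
    }

    # detectability annotation for the truth table
    n_cov = []
    for _, m in truth.iterrows():
        ij = iidx[m["individual"]]
        n_cov.append(sum(
            1 for t in m["tissue_vaf"]
            if cov[m["site_id"], tidx[t], ij] >= 10
        ))
    truth = truth.assign(n_carrier_covered=n_cov)
    truth = truth.merge(
        sites[["site_id", "chrom", "pos", "ref", "alt"]], on="site_id")

    return SimulatedCohort(
        config=config, tree=tree, tissues=tissues, individuals=individuals,
        genes=genes, sites=sites, truth=truth, counts=counts,
        expression=expression, germline=germline,
        editing_sites=editing_sites, pop_af=pop_af,
    )


def _counts_long(sites, tissues, individuals, cov, alt, alt_fwd, ref_n,
                 ref_fwd, alt_bq20, mean_bq) -> pd.DataFrame:
    S, T, I = cov.shape
    rep_site = np.repeat(np.arange(S), T * I)
    tile_t = np.tile(np.repeat(np.arange(T), I), S)
    tile_i = np.tile(np.arange(I), S * T)
    df = pd.DataFrame({
        "chrom": pd.Categorical.from_codes(
            pd.factorize(sites["chrom"])[0][rep_site],
            pd.factorize(sites["chrom"])[1]),
        "pos": sites["pos"].to_numpy()[rep_site],
        "ref": pd.Categorical.from_codes(
            pd.factorize(sites["ref"])[0][rep_site],
            pd.factorize(sites["ref"])[1]),
        "alt": pd.Categorical.from_codes(
            pd.factorize(sites["alt"])[0][rep_site],
            pd.factorize(sites["alt"])[1]),
        "gene": pd.Categorical.from_codes(
            pd.factorize(sites["gene"])[0][rep_site],
            pd.factorize(sites["gene"])[1]),
        "site_id": rep_site,
        "individual": pd.Categorical.from_codes(tile_i, individuals),
        "tissue": pd.Categorical.from_codes(tile_t, tissues),
        "ref_fwd": ref_fwd.reshape(-1),
        "ref_rev": (ref_n - ref_fwd).reshape(-1),
        "alt_fwd": alt_fwd.reshape(-1),
        "alt_rev": (alt - alt_fwd).reshape(-1),
        "alt_bq20": alt_bq20.reshape(-1),
        "mean_alt_bq": mean_bq.reshape(-1),
    })
    return df


# -- labeled calls for the RF ----------------------------------------------


def wes_truth_label(truth_vaf: float, truth_reads: int) -> int:
    """Truth rule for labeled calls: true iff VAF >= 5% with >= 2 reads."""
    return int(truth_vaf >= 0.05 and truth_reads >= 2)


def simulate_labeled_calls(config: SimConfig, n_true: int = 1000,
                           n_false: int = 1000) -> pd.DataFrame:
    """Labeled call features emulating WES-anchored training data.

    True calls are carrier sites with VAF spread over (0.02, 0.5); false
    calls are error-driven with low VAF, lower base quality, occasional
    strand bias and more blacklisted genes.  Labels follow the truth rule:
    true iff truth VAF >= 0.05 and >= 2 truth-supporting reads.  Features
    are computed with :func:`rf_filter.featurize`.
    """
    from .rf_filter import featurize

    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(n_true + n_false):
        is_true = i < n_true
        cov = max(10, int(_nb_coverage(rng, config.coverage_mean,
                                       max(config.coverage_dispersion, 1e-9), 1)[0]))
        if is_true:
            truth_vaf = float(rng.uniform(0.02, 0.5))
            alt = int(rng.binomial(cov, truth_vaf))
            alt_fwd = int(rng.binomial(alt, 0.5))
            bq = float(np.clip(rng.normal(config.mean_bq, config.bq_sd), 2, 42))
            blacklisted = rng.random() < 0.02
            truth_reads = int(rng.binomial(60, truth_vaf))
        elif rng.random() < 0.4:
            # high-VAF false call: editing/alignment artifact absent from the
            # truth data, strand-skewed, low BQ, often in a blacklisted gene
            truth_vaf = 0.0
            art_vaf = float(rng.uniform(0.05, 0.6))
            alt = int(rng.binomial(cov, art_vaf))
            alt_fwd = int(rng.binomial(alt, 0.85))
            bq = float(np.clip(rng.normal(config.err_bq + 4, config.err_bq_sd), 2, 42))
            blacklisted = rng.random() < 0.4
            truth_reads = 0
        else:
            truth_vaf = 0.0
            # low-VAF false call: sequencing error at ~10x the class mean
            # error rate; scales with the configured noise level
            p_err = float(rng.beta(2.0, max(config.error_beta / 10.0, 1.0)))
            alt = int(rng.binomial(cov, p_err))
            strand_skew = 0.9 if rng.random() < 0.3 else 0.5
            alt_fwd = int(rng.binomial(alt, strand_skew))
            bq = float(np.clip(rng.normal(config.err_bq, config.err_bq_sd), 2, 42))
            blacklisted = rng.random() < 0.25
            truth_reads = 0
        ref_n = cov - alt
        ref_fwd = int(rng.binomial(ref_n, 0.5))
        feats = featurize(ref_fwd, ref_n - ref_fwd, alt_fwd, alt - alt_fwd,
                          bq, blacklisted)
        feats["truth_vaf"] = truth_vaf
        feats["label"] = wes_truth_label(truth_vaf, truth_reads)
        rows.append(feats)
    return pd.DataFrame(rows)


# -- signature sampling ----------------------------------------------------


def simulate_signature_catalog(weights, reference: pd.DataFrame, n: int,
                               seed: int = 0):
    """Multinomial catalog of ``n`` mutations from reference . weights."""
    from .signatures import MutationCatalog

    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    probs = reference.to_numpy(dtype=float) @ w
    probs = probs / probs.sum()
    return MutationCatalog(rng.multinomial(n, probs).astype(float))


def synthetic_signature_matrix(n_signatures: int = 4, seed: int = 0,
                               concentration: float = 0.05) -> pd.DataFrame:
    """A synthetic stand-in reference signature matrix (96 x K).

    Columns are sparse Dirichlet draws (well-separated support), each summing
    to 1, labelled SIG1..SIGK.  This is a synthetic construction for tests
    and demonstrations, not a published signature catalog.
    """
    from .signatures import CONTEXT_LABELS

    rng = np.random.default_rng(seed)
    cols = {}
    for k in range(n_signatures):
        cols[f"SIG{k + 1}"] = rng.dirichlet(np.full(96, concentration))
    return pd.DataFrame(cols, index=list(CONTEXT_LABELS))


# -- covariate records for tissue-rate analysis ----------------------------


def simulate_rate_records(
    n_samples: int = 400,
    n_tissues: int = 5,
    seed: int = 0,
    *,
    age_effect_tissues: tuple = (),
    age_slope: float = 1e-9,
    noise_sd: float = 5e-9,
    coefficients: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-sample raw rates as a linear function of technical covariates.

    Returns (records, true_coefficients); tissues named TIS00.. with donor
    ages; tissues in ``age_effect_tissues`` get a true age slope on top of
    the technical signal.
    """
    rng = np.random.default_rng(seed)
    coef = {
        "Intercept": 5e-8, "duplicates": 8e-8, "RIN": -1e-9,
        "TRISCHD": 2e-11, "DP_median": -5e-11, "cohort_B": 1e-8,
    }
    coef.update(coefficients or {})
    df = pd.DataFrame({
        "sample": [f"S{i:04d}" for i in range(n_samples)],
        "tissue": [f"TIS{i % n_tissues:02d}" for i in range(n_samples)],
        "duplicates": rng.uniform(0.05, 0.6, n_samples),
        "cohort": rng.choice(["A", "B"], n_samples),
        "RIN": rng.uniform(5, 10, n_samples),
        "TRISCHD": rng.uniform(0, 1200, n_samples),
        "DP_median": rng.uniform(20, 200, n_samples),
        "age": rng.integers(20, 71, n_samples).astype(float),
    })
    rate = (
        coef["Intercept"]
        + coef["duplicates"] * df["duplicates"]
        + coef["RIN"] * df["RIN"]
        + coef["TRISCHD"] * df["TRISCHD"]
        + coef["DP_median"] * df["DP_median"]
        + coef["cohort_B"] * (df["cohort"] == "B")
        + rng.normal(0, noise_sd, n_samples)
    )
    for t in age_effect_tissues:
        mask = df["tissue"] == t
        rate[mask] += age_slope * (df.loc[mask, "age"] - 45)
    df["raw_rate"] = rate
    return df, coef


# -- fixture writers -------------------------------------------------------


def write_germline_vcf(germline: dict, path) -> None:
    """Write the per-individual germline sets as one minimal multi-sample VCF."""
    recs = sorted({rec for s in germline.values() for rec in s})
    lines = [
        "##fileformat=VCFv4.2",
        "##source=rnamosaic-simdata",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for chrom, pos, ref, alt in recs:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(cohort: SimulatedCohort, out_dir) -> dict:
    """Materialize a cohort as plain-text pipeline inputs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "truth": out / "truth.tsv",
        "expression_tpm": out / "expression_tpm.tsv",
        "germline_vcf": out / "germline.vcf",
        "editing": out / "editing_sites.tsv",
        "pop_af": out / "pop_af.tsv",
    }
    counts = cohort.counts.copy()
    counts.to_csv(paths["counts"], sep="\t", index=False)
    cohort.truth.drop(columns=["tissue_vaf"]).to_csv(
        paths["truth"], sep="\t", index=False)
    cohort.expression["TPM"].to_csv(paths["expression_tpm"], sep="\t")
    write_germline_vcf(cohort.germline, paths["germline_vcf"])
    pd.DataFrame(sorted(cohort.editing_sites),
                 columns=["chrom", "pos", "ref", "alt"]).to_csv(
        paths["editing"], sep="\t", index=False)
    pd.DataFrame(
        [(c, p, r, a, af) for (c, p, r, a), af in sorted(cohort.pop_af.items())],
        columns=["chrom", "pos", "ref", "alt", "af"],
    ).to_csv(paths["pop_af"], sep="\t", index=False)
    return paths
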