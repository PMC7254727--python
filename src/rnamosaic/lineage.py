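"""Embryogenesis lineage tree and timing classification of mosaic calls.

Every surviving mosaic mutation is mapped onto a rooted developmental tree
(zygote -> {ectoderm, mesendoderm} -> germ layers -> sub-lineages -> tissue
leaves).  The most likely ancestral node is the lowest common ancestor (LCA)
of the tissues carrying the variant, and the call is classified by timing:

- EEMM: ancestral node is the zygote (the variant spans both the ectoderm
  and the mesendoderm branch), mean VAF < 0.35, and it is not carried by all
  expressed tissues.  The adrenal gland (dual ectoderm/mesoderm origin) is
  excluded from this determination.
- MEMM: >= 2 carrier tissues confined to one side of the root with a
  non-zygote ancestral node and a coherent distribution on the tree.
- LEMM: a single carrier tissue with >= 5 supporting reads and VAF >= 0.2,
  outside tissues with known clonal expansions (sun-exposed skin,
  esophagus mucosa, whole blood).
- SOMATIC: everything else; DENOVO_SUSPECT: carried by all expressed
  tissues or mean VAF >= 0.35 (possible germline de novo variant).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_array import CallState, GenotypeArray

GERM_LAYERS = ("ectoderm", "mesoderm", "endoderm")

#: Tissues excluded from LEMM calling (known postnatal clonal expansions).
CLONAL_EXPANSION_TISSUES = frozenset(
    {"skin-sun_exposed_lower_leg", "esophagus-mucosa", "whole_blood"}
)
#: Tissues of dual germ-layer origin, excluded from EEMM determination.
ADRENAL_TISSUES = frozenset({"adrenal_gland"})


class LineageTree:
    """Rooted embryogenesis tree with a tissue -> leaf mapping.

    Built from a nested config ``{"name": ..., "children": [...]}`` where
    leaves are nodes without children; each analyzed tissue must map to
    exactly one leaf (leaf names are the tissue names).
    """

    def __init__(self, config: dict,
                 adrenal_tissues=ADRENAL_TISSUES,
                 clonal_expansion_tissues=CLONAL_EXPANSION_TISSUES):
        self.root = config["name"]
        self.children: dict[str, list[str]] = {}
        self.parent: dict[str, str | None] = {self.root: None}
        self.depth: dict[str, int] = {self.root: 0}
        self._walk(config)
        self.leaves = [n for n in self.children if not self.children[n]]
        dup = {n for n in self.leaves if self.leaves.count(n) > 1}
        if dup:
            raise ValueError(f"duplicate leaf tissue(s): {sorted(dup)}")
        self.adrenal_tissues = frozenset(adrenal_tissues) & set(self.leaves)
        self.clonal_expansion_tissues = (
            frozenset(clonal_expansion_tissues) & set(self.leaves)
        )
        self._config = config

    def _walk(self, node: dict):
        name = node["name"]
        if name in self.children:
            raise ValueError(f"duplicate node name: {name!r}")
        kids = node.get("children", [])
        self.children[name] = [k["name"] for k in kids]
        for k in kids:
            self.parent[k["name"]] = name
            self.depth[k["name"]] = self.depth[name] + 1
            self._walk(k)

    # -- topology ----------------------------------------------------------

    def is_leaf(self, name: str) -> bool:
        return name in self.children and not self.children[name]

    def path_to_root(self, name: str) -> list[str]:
        if name not in self.parent:
            raise KeyError(f"tissue {name!r} maps to no tree node")
        path = [name]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path

    def lca(self, names) -> str:
        names = list(names)
        if not names:
            raise ValueError("LCA of an empty tissue set")
        paths = [set(self.path_to_root(n)) for n in names]
        common = set.intersection(*paths)
        return max(common, key=lambda n: self.depth[n])

    def subtree_leaves(self, node: str) -> set[str]:
        out, stack = set(), [node]
        while stack:
            n = stack.pop()
            if self.is_leaf(n):
                out.add(n)
            stack.extend(self.children[n])
        return out

    def germ_layer_of(self, tissue: str) -> str | None:
        """Nearest ancestor among ectoderm / mesoderm / endoderm, if any."""
        for n in self.path_to_root(tissue):
            if n in GERM_LAYERS:
                return n
        return None

    def root_branch_of(self, tissue: str) -> str:
        """Which child of the root (e.g. ectoderm vs mesendoderm) holds it."""
        path = self.path_to_root(tissue)
        return path[-2] if len(path) >= 2 else tissue

    # -- serialization -----------------------------------------------------

    def to_config(self) -> dict:
        return self._config

    @classmethod
    def from_json(cls, path, **kw) -> "LineageTree":
        with open(path) as fh:
            return cls(json.load(fh), **kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self._config, fh, indent=1)

    def to_newick(self) -> str:
        def render(name: str) -> str:
            kids = self.children[name]
            if not kids:
                return name
            return "(" + ",".join(render(k) for k in kids) + ")" + name

        return render(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, **kw) -> "LineageTree":
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")

        def convert(node) -> dict:
            label = node.taxon.label if node.taxon else node.label
            return {
                "name": (label or "").replace(" ", "_"),
                "children": [convert(c) for c in node.child_nodes()],
            }

        return cls(convert(tree.seed_node), **kw)


# -- bundled default tree --------------------------------------------------

_BRAIN = [
    "brain-amygdala", "brain-anterior_cingulate_cortex_BA24",
    "brain-caudate_basal_ganglia", "brain-cerebellar_hemisphere",
    "brain-cerebellum", "brain-cortex", "brain-frontal_cortex_BA9",
    "brain-hippocampus", "brain-hypothalamus",
    "brain-nucleus_accumbens_basal_ganglia", "brain-putamen_basal_ganglia",
    "brain-spinal_cord_cervical_c-1", "brain-substantia_nigra",
]


def _leaves(names):
    return [{"name": n, "children": []} for n in names]


DEFAULT_TREE_CONFIG = {
    "name": "zygote",
    "children": [
        {
            "name": "ectoderm",
            "children": [
                {"name": "neural", "children": _leaves(
                    _BRAIN + ["pituitary", "nerve-tibial"])},
                {"name": "surface_ectoderm", "children": _leaves([
                    "skin-sun_exposed_lower_leg",
                    "skin-not_sun_exposed_suprapubic",
                    "breast-mammary_tissue", "minor_salivary_gland"])},
            ],
        },
        {
            "name": "mesendoderm",
            "children": [
                {
                    "name": "mesoderm",
                    "children": [
                        {"name": "hematopoietic", "children": _leaves([
                            "whole_blood", "cells-EBV-transformed_lymphocytes",
                            "spleen"])},
                        {"name": "cardiovascular", "children": _leaves([
                            "heart-atrial_appendage", "heart-left_ventricle",
                            "artery-aorta", "artery-coronary",
                            "artery-tibial"])},
                        {"name": "urogenital", "children": _leaves([
                            "kidney-cortex", "ovary", "testis", "uterus"])},
                        {"name": "soft_tissue", "children": _leaves([
                            "adipose-subcutaneous", "adipose-visceral_omentum",
                            "muscle-skeletal", "cells-transformed_fibroblasts",
                            "adrenal_gland"])},
                    ],
                },
                {
                    "name": "endoderm",
                    "children": [
                        {"name": "foregut", "children": _leaves([
                            "esophagus-mucosa",
                            "esophagus-gastroesophageal_junction",
                            "esophagus-muscularis", "stomach", "liver",
                            "pancreas", "lung", "thyroid"])},
                        {"name": "midgut_hindgut", "children": _leaves([
                            "colon-sigmoid", "colon-transverse",
                            "small_intestine-terminal_ileum", "prostate",
                            "vagina"])},
                    ],
                },
            ],
        },
    ],
}


def default_tree() -> LineageTree:
    """The bundled 49-tissue human embryogenesis tree."""
    return LineageTree(DEFAULT_TREE_CONFIG)


def load_tree(config) -> LineageTree:
    """Build a validated LineageTree from a nested config dict or JSON path."""
    if isinstance(config, (str, bytes)) or hasattr(config, "read"):
        return LineageTree.from_json(config)
    return LineageTree(config)


# -- per-call operations ---------------------------------------------------


def ancestral_node(pass_tissues, tree: LineageTree, exclude_adrenal: bool = True) -> str:
    """LCA of the carrier-tissue leaves.

    With ``exclude_adrenal`` the dual-origin adrenal gland is dropped from
    the LCA computation whenever the full set spans both root branches and
    at least one non-adrenal carrier remains.
    """
    tissues = list(pass_tissues)
    if not tissues:
        raise ValueError("ancestral node of a call with zero carrier tissues")
    node = tree.lca(tissues)
    if exclude_adrenal and node == tree.root:
        rest = [t for t in tissues if t not in tree.adrenal_tissues]
        if rest and len(rest) < len(tissues):
            node = tree.lca(rest)
    return node


def coherence(pass_tissues, expressed_tissues, node: str, tree: LineageTree,
              f_min: float = 0.2) -> bool:
    """Single-origin coherence of a call's tissue distribution.

    Coherent iff every child subtree of ``node`` holding >= 1 carrier tissue
    has detection fraction (carriers / expressed tissues in that subtree)
    >= ``f_min``, or holds exactly one expressed tissue.
    """
    pass_set = set(pass_tissues)
    expr_set = set(expressed_tissues) | pass_set
    for child in tree.children[node]:
        leaves = tree.subtree_leaves(child)
        n_pass = len(pass_set & leaves)
        if n_pass == 0:
            continue
        n_expr = len(expr_set & leaves)
        if n_expr == 1:
            continue
        if n_pass / n_expr < f_min:
            return False
    return True


@dataclass
class MosaicCall:
    """One classified mosaic mutation in one individual."""

    chrom: str
    pos: int
    ref: str
    alt: str
    individual: str
    klass: str
    ancestral_node: str
    mean_vaf: float
    n_pass: int
    n_expressed: int
    coherent: bool
    pass_tissues: tuple = ()
    max_alt_count: int = 0


def individual_included(expressed_tissues, tree: LineageTree,
                        min_tissues: int = 10) -> bool:
    """Cohort inclusion: >= min_tissues assayed, and >= 2 germ layers each
    represented by >= 2 tissues."""
    tissues = set(expressed_tissues)
    if len(tissues) < min_tissues:
        return False
    per_layer = {g: 0 for g in GERM_LAYERS}
    for t in tissues:
        g = tree.germ_layer_of(t)
        if g:
            per_layer[g] += 1
    return sum(1 for g in GERM_LAYERS if per_layer[g] >= 2) >= 2


def classify_call(
    pass_tissues: dict,
    expressed_tissues,
    tree: LineageTree,
    *,
    denovo_vaf: float = 0.35,
    lemm_min_alt: int = 5,
    lemm_min_vaf: float = 0.2,
    f_min: float = 0.2,
    alt_counts: dict | None = None,
) -> tuple[str, str, bool]:
    """Classify one call; returns (klass, ancestral_node, coherent).

    ``pass_tissues`` maps carrier tissue -> VAF; ``expressed_tissues`` lists
    every tissue with expression (carriers included); ``alt_counts`` maps
    carrier tissue -> alt read count (needed for the LEMM support rule).
    """
    alt_counts = alt_counts or {}
    tissues = list(pass_tissues)
    if not tissues:
        raise ValueError("cannot classify a call with zero carrier tissues")
    expressed = set(expressed_tissues) | set(tissues)
    mean_vaf = float(np.mean(list(pass_tissues.values())))
    node = ancestral_node(tissues, tree)

    if set(tissues) >= expressed:
        return "DENOVO_SUSPECT", node, True

    if len(tissues) == 1:
        t = tissues[0]
        if (
            t not in tree.clonal_expansion_tissues
            and pass_tissues[t] >= lemm_min_vaf
            and alt_counts.get(t, 0) >= lemm_min_alt
        ):
            return "LEMM", node, True
        return "SOMATIC", node, True

    if mean_vaf >= denovo_vaf:
        return "DENOVO_SUSPECT", node, True

    non_adrenal = [t for t in tissues if t not in tree.adrenal_tissues]
    branches = {tree.root_branch_of(t) for t in non_adrenal}
    all_branches = {tree.root_branch_of(t) for t in tissues}
    if node == tree.root and len(branches) >= 2 and mean_vaf < denovo_vaf:
        return "EEMM", node, True

    coh = coherence(tissues, expressed, node, tree, f_min=f_min)
    if node != tree.root and len(all_branches) == 1 and coh:
        return "MEMM", node, coh
    return "SOMATIC", node, coh


def classify_array(
    array: GenotypeArray,
    tree: LineageTree,
    *,
    min_tissues: int = 10,
    denovo_vaf: float = 0.35,
    lemm_min_alt: int = 5,
    lemm_min_vaf: float = 0.2,
    f_min: float = 0.2,
) -> pd.DataFrame:
    """Classify every (site, individual) with >= 1 PASS cell.

    Individuals failing the inclusion rule are skipped (their calls appear
    with klass ``EXCLUDED_INDIVIDUAL`` for auditability).
    """
    rows = []
    vaf = array.vaf()
    st = array.states
    for ij, ind in enumerate(array.individuals):
        assayed = {
            array.tissues[tj]
            for tj in range(len(array.tissues))
            if (st[:, tj, ij] != CallState.MISSING.value).any()
        }
        included = individual_included(assayed, tree, min_tissues=min_tissues)
        for s in np.flatnonzero((st[:, :, ij] == CallState.PASS.value).any(axis=1)):
            pass_t, alt_n = {}, {}
            expressed = []
            for tj, t in enumerate(array.tissues):
                state = st[s, tj, ij]
                if state >= CallState.HOM_REF.value:
                    expressed.append(t)
                if state == CallState.PASS.value:
                    pass_t[t] = float(vaf[s, tj, ij])
                    alt_n[t] = int(array.alt_counts[s, tj, ij])
            if not included:
                klass, node, coh = "EXCLUDED_INDIVIDUAL", "", True
            else:
                klass, node, coh = classify_call(
                    pass_t, expressed, tree,
                    denovo_vaf=denovo_vaf, lemm_min_alt=lemm_min_alt,
                    lemm_min_vaf=lemm_min_vaf, f_min=f_min,
                    alt_counts=alt_n,
                )
            rows.append(
                {
                    "chrom": array.sites.at[s, "chrom"],
                    "pos": int(array.sites.at[s, "pos"]),
                    "ref": array.sites.at[s, "ref"],
                    "alt": array.sites.at[s, "alt"],
                    "individual": ind,
                    "klass": klass,
                    "ancestral_node": node,
                    "mean_vaf": float(np.mean(list(pass_t.values()))),
                    "n_pass": len(pass_t),
                    "n_expressed": len(expressed),
                    "coherent": coh,
                    "pass_tissues": ",".join(sorted(pass_t)),
                    "max_alt_count": max(alt_n.values()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "individual", "klass",
                 "ancestral_node", "mean_vaf", "n_pass", "n_expressed",
                 "coherent", "pass_tissues", "max_alt_count"],
    )


def vaf_tissue_correlation(calls: pd.DataFrame, tree: LineageTree | None = None):
    """Spearman correlations of mean VAF with carrier-tissue count, and of
    ancestral-node depth with mean VAF.

    Returns a dict with (rho, p) pairs; constant inputs are flagged with
    rho=None.
    """
    if len(calls) < 3:
        raise ValueError("need >= 3 calls for a rank correlation")

    def spear(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return {"rho": None, "p": None, "undefined": True}
        rho, p = stats.spearmanr(x, y)
        return {"rho": float(rho), "p": float(p), "undefined": False}

    out = {"vaf_vs_n_tissues": spear(calls["n_pass"], calls["mean_vaf"])}
    if tree is not None and "ancestral_node" in calls:
        depth = [tree.depth.get(n, np.nan) for n in calls["ancestral_node"]]
        out["depth_vs_vaf"] = spear(depth, calls["mean_vaf"])
    return out
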