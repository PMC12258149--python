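"""Classify rooted gametolog gene trees into evolutionary scenarios.

For a gene with Z and W copies in the focal species, an ortholog in the
sister species and an outgroup, three informative topologies exist after
rooting on the outgroup: Z and W are sisters (recombination stopped after
the species split), the sister species groups with Z (the ancestral W copy
was lost), or the sister species groups with W (loss of the ancestral Z).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import pandas as pd

log = logging.getLogger("zwscan")

CLASSES = ("ZW_sister", "W_loss", "Z_loss", "unclassifiable")


@dataclass
class GeneTreeRecord:
    tree_id: str
    newick: str
    tree_class: str


class MissingTaxonError(ValueError):
    pass


def _leaf_set(node):
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def classify_gametolog_tree(tree, labels: dict) -> str:
    """Classify one gene tree.

    ``tree`` is a Newick string or dendropy Tree; ``labels`` must provide
    'z', 'w', 'sister_species' and 'outgroup' taxon names. Extra taxa are
    pruned away before classification. Polytomies that leave the z/w/sister
    relationship unresolved give 'unclassifiable'.
    """
    if isinstance(tree, str):
        t = dendropy.Tree.get(data=tree, schema="newick",
                              preserve_underscores=True)
    else:
        t = tree.clone(depth=1)
    for key in ("z", "w", "sister_species", "outgroup"):
        if key not in labels:
            raise MissingTaxonError(f"labels missing key {key!r}")
    z, w, sis, out = (labels["z"], labels["w"], labels["sister_species"],
                      labels["outgroup"])
    if out in (z, w, sis):
        raise MissingTaxonError("outgroup label must differ from focal labels")
    present = {lf.taxon.label for lf in t.leaf_node_iter()}
    for name in (z, w, sis, out):
        if name not in present:
            raise MissingTaxonError(f"taxon {name!r} absent from tree")
    keep = [tx for tx in t.taxon_namespace if tx.label in {z, w, sis, out}]
    t.retain_taxa(keep)

    og = t.find_node_with_taxon_label(out)
    t.reroot_at_edge(og.edge, update_bipartitions=False)
    t.update_bipartitions(suppress_unifurcations=True)

    # smallest clade containing z and w
    zw_mrca = t.mrca(taxon_labels=[z, w])
    if sis not in _leaf_set(zw_mrca):
        return "ZW_sister"
    zs_mrca = t.mrca(taxon_labels=[z, sis])
    ws_mrca = t.mrca(taxon_labels=[w, sis])
    zs_leaves = _leaf_set(zs_mrca)
    ws_leaves = _leaf_set(ws_mrca)
    if w not in zs_leaves and zs_leaves == {z, sis}:
        return "W_loss"
    if z not in ws_leaves and ws_leaves == {w, sis}:
        return "Z_loss"
    return "unclassifiable"


def classify_trees(trees, labels: dict) -> pd.DataFrame:
    rows = []
    for i, tr in enumerate(trees):
        nwk = tr if isinstance(tr, str) else tr.as_string(schema="newick").strip()
        rows.append((f"tree{i+1:04d}", nwk, classify_gametolog_tree(tr, labels)))
    return pd.DataFrame(rows, columns=["tree_id", "newick", "tree_class"])


def summarize_topologies(classes) -> pd.DataFrame:
    """Counts and whole-percent frequencies per topology class."""
    if isinstance(classes, pd.DataFrame):
        classes = classes["tree_class"]
    classes = list(classes)
    if not classes:
        raise ValueError("no gene-tree records to summarize")
    total = len(classes)
    rows = []
    for cls in CLASSES:
        n = sum(1 for c in classes if c == cls)
        if n == 0 and cls == "unclassifiable":
            continue
        rows.append((cls, n, round(100.0 * n / total)))
    return pd.DataFrame(rows, columns=["tree_class", "count", "percent"])
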