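"""Readers and writers for the TSV / newick / GraphML formats, plus
cross-input alignment of table, tree and metadata."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from skbio import TreeNode

from .datamodel import (
    AssociationNetwork,
    CountTable,
    PhyloTree,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger("microtempo")

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_sample_table",
    "write_sample_table",
    "read_tree",
    "write_tree",
    "read_network",
    "write_network",
    "align_inputs",
    "AlignedBundle",
]


def read_count_table(
    path,
    provenance: str = "raw",
    orientation: str = "auto",
    sample_ids=None,
) -> CountTable:
    """Read a tab-separated count table.

    ``orientation`` is ``"samples"`` (rows are samples), ``"asvs"`` (rows
    are ASVs) or ``"auto"``: with ``sample_ids`` given (e.g. from a
    metadata table) the axis matching them wins, otherwise rows are
    assumed to be samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"empty table in {path}")
    df.index.name = None
    df.columns.name = None
    if orientation == "auto":
        if sample_ids is not None:
            ids = set(sample_ids)
            rows = len(ids & set(df.index))
            cols = len(ids & set(df.columns))
            orientation = "samples" if rows >= cols else "asvs"
        else:
            orientation = "samples"
    if orientation == "asvs":
        df = df.T
    return CountTable(df, provenance=provenance)


def write_count_table(table: CountTable, path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", index_col=0))


def write_sample_table(meta: SampleTable, path) -> None:
    df = meta.data.copy()
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%d")
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> PhyloTree:
    """Read a rooted newick tree; tips without branch lengths get length 0
    (warned)."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise ValidationError(f"unparseable newick in {path}: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


_SIGN = {"+": 1, "-": -1, "1": 1, "-1": -1, 1: 1, -1: -1}


def read_network(path, node_attrs: pd.DataFrame | None = None) -> AssociationNetwork:
    """Read a static association network.

    Accepts an edge-list TSV with columns (node1, node2, sign, weight,
    cooccurrence_score) — sign written as ``+``/``-`` — or a GraphML file
    (suffix ``.graphml``). ``node_attrs`` optionally supplies
    ``domain_marker`` / ``size_fraction`` per node for edge-list input.
    """
    path = str(path)
    if path.endswith(".graphml"):
        g = nx.read_graphml(path)
        g = nx.Graph(g)
        for _, _, d in g.edges(data=True):
            d["sign"] = int(d["sign"])
        return AssociationNetwork(g)
    df = pd.read_csv(path, sep="\t")
    g = nx.Graph()
    for row in df.itertuples(index=False):
        u, v, sign, weight, score = row[:5]
        if u == v:
            raise ValidationError(f"self-loop edge on {u!r}")
        if sign not in _SIGN:
            raise ValidationError(f"edge sign must be + or -, got {sign!r}")
        g.add_edge(
            u,
            v,
            sign=_SIGN[sign],
            weight=float(weight),
            cooccurrence_score=float(score),
        )
    if node_attrs is not None:
        missing = set(g.nodes()) - set(node_attrs.index)
        if missing:
            raise ValidationError(
                f"edge endpoints missing from node table: {sorted(missing)}"
            )
        for n in g.nodes():
            g.nodes[n].update(node_attrs.loc[n].to_dict())
    return AssociationNetwork(g)


def write_network(net: AssociationNetwork, path) -> None:
    path = str(path)
    if path.endswith(".graphml"):
        nx.write_graphml(net.graph, path)
        return
    rows = [
        {
            "node1": u,
            "node2": v,
            "sign": "+" if d["sign"] > 0 else "-",
            "weight": d.get("weight", 0.0),
            "cooccurrence_score": d.get("cooccurrence_score", float("nan")),
        }
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["node1", "node2", "sign", "weight", "cooccurrence_score"]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class AlignedBundle:
    """Mutually consistent table / metadata / tree, plus a report of what
    alignment dropped."""

    table: CountTable
    meta: SampleTable
    tree: PhyloTree | None
    report: dict

    @property
    def phylo_table(self) -> CountTable:
        """Table restricted to ASVs present in the tree — the input for
        phylogeny-dependent analyses."""
        if self.tree is None:
            return self.table
        keep = [a for a in self.table.asv_ids if a in set(self.tree.tip_names)]
        return self.table.select_asvs(keep)


def align_inputs(
    table: CountTable,
    meta: SampleTable,
    tree: PhyloTree | None = None,
) -> AlignedBundle:
    """Intersect samples between table and metadata and reconcile taxa
    with the tree.

    The table keeps only samples present in the metadata. The tree is
    pruned to ASVs in the table; ASVs absent from the tree stay in the
    table (taxonomic analyses use them) but are excluded from
    phylogeny-dependent analyses via :attr:`AlignedBundle.phylo_table`,
    with a logged count. Idempotent.
    """
    common = [s for s in table.sample_ids if s in set(meta.sample_ids)]
    if not common:
        raise ValidationError("no samples shared between table and metadata")
    dropped_samples = [s for s in table.sample_ids if s not in set(common)]
    table = table.select_samples(common)
    meta = SampleTable(meta.data.loc[common].copy())

    report = {
        "samples_kept": len(common),
        "samples_dropped": len(dropped_samples),
        "tips_pruned": 0,
        "asvs_without_tip": 0,
    }
    if tree is not None:
        tips = set(tree.tip_names)
        asvs = set(table.asv_ids)
        in_both = [a for a in table.asv_ids if a in tips]
        if not in_both:
            raise ValidationError("no ASVs shared between table and tree")
        extra_tips = tips - asvs
        if extra_tips:
            tree = tree.prune_to(in_both)
            report["tips_pruned"] = len(extra_tips)
            logger.info("%d tips pruned from tree", len(extra_tips))
        orphans = asvs - tips
        if orphans:
            report["asvs_without_tip"] = len(orphans)
            logger.warning(
                "%d ASVs absent from tree; excluded from phylogenetic "
                "analyses",
                len(orphans),
            )
    return AlignedBundle(table=table, meta=meta, tree=tree, report=report)
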