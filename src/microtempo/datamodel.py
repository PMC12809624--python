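"""Core in-memory containers shared by every analysis stage.

The universal objects are a sample-by-ASV count table, a sample metadata
table, a rooted phylogeny whose tips are ASV ids, and a signed static
association network. All are thin, validated wrappers around the field's
canonical containers (pandas DataFrames, a scikit-bio ``TreeNode``, a
networkx ``Graph``) so that downstream code can use those libraries
directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("microtempo")

__all__ = [
    "CountTable",
    "SampleTable",
    "PhyloTree",
    "AssociationNetwork",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input violates a structural invariant (duplicate ids, negative
    counts, malformed network...)."""


@dataclass
class CountTable:
    """Reads per (sample, ASV).

    ``data`` is samples-as-rows. ``provenance`` records the processing
    state: ``raw`` and ``rarefied`` tables hold non-negative integers,
    ``clr`` tables hold real values (centred log-ratios).
    """

    data: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("empty count table")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated ASV ids: {dups}")
        if self.provenance != "clr":
            arr = df.to_numpy()
            if not np.all(np.isfinite(arr)):
                raise ValidationError("non-finite counts")
            if (arr < 0).any():
                r, c = np.argwhere(arr < 0)[0]
                raise ValidationError(
                    f"negative count {arr[r, c]!r} at sample "
                    f"{df.index[r]!r}, ASV {df.columns[c]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count {arr[r, c]!r} at sample "
                    f"{df.index[r]!r}, ASV {df.columns[c]!r}"
                )
            self.data = df.astype(np.int64)

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances f_ij."""
        tot = self.data.sum(axis=1)
        if (tot == 0).any():
            bad = tot.index[tot == 0].tolist()
            raise ValidationError(f"samples with zero total: {bad}")
        return self.data.div(tot, axis=0)

    def select_samples(self, ids) -> "CountTable":
        return CountTable(self.data.loc[list(ids)], provenance=self.provenance)

    def select_asvs(self, ids) -> "CountTable":
        return CountTable(self.data[list(ids)], provenance=self.provenance)


@dataclass
class SampleTable:
    """Per-sample metadata: date, site, size fraction, marker gene, and
    named environmental variables (any extra numeric column)."""

    data: pd.DataFrame

    CORE = ("date", "site", "size_fraction")

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids in metadata: {dups}")
        if "date" in df.columns:
            try:
                df["date"] = pd.to_datetime(df["date"], format="ISO8601")
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"unparseable dates: {exc}") from exc

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    def env_columns(self) -> list:
        skip = set(self.CORE) | {"domain_marker"}
        return [
            c
            for c in self.data.columns
            if c not in skip and pd.api.types.is_numeric_dtype(self.data[c])
        ]

    def months_since_start(self) -> pd.Series:
        """Decimal months since the first sample (mean Julian month,
        30.436875 days) — the continuous time axis used by the
        periodogram on unevenly sampled series."""
        d = pd.to_datetime(self.data["date"])
        days = (d - d.min()).dt.total_seconds() / 86400.0
        return days / 30.436875


@dataclass
class PhyloTree:
    """Rooted, branch-length-bearing tree whose tips are ASV ids."""

    tree: TreeNode

    def __post_init__(self) -> None:
        tips = list(self.tree.tips())
        if len(tips) < 2:
            raise ValidationError("tree must have at least 2 tips")
        names = [t.name for t in tips]
        if len(set(names)) != len(names):
            raise ValidationError("duplicated tip labels in tree")
        n_missing = 0
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise ValidationError(
                    f"negative branch length at node {node.name!r}"
                )
        if n_missing:
            logger.warning(
                "%d branches without lengths set to 0", n_missing
            )

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def prune_to(self, names) -> "PhyloTree":
        keep = set(names)
        sub = self.tree.shear(keep)
        sub.prune()
        return PhyloTree(sub)

    def cophenetic(self) -> pd.DataFrame:
        """Patristic (sum of branch lengths along the path) distances
        between all tip pairs."""
        dm = self.tree.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))

    def total_branch_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self.tree.traverse(include_self=False)
        )

    def to_newick(self) -> str:
        return str(self.tree)


@dataclass
class AssociationNetwork:
    """Undirected signed association network.

    Nodes carry ``domain_marker`` and ``size_fraction`` attributes; edges
    carry ``sign`` (+1/-1), ``weight`` (association score) and
    ``cooccurrence_score`` (fraction of samples where both endpoints were
    detected).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    def __post_init__(self) -> None:
        g = self.graph
        for u, v in g.edges():
            if u == v:
                raise ValidationError(f"self-loop on node {u!r}")
        for _, _, d in g.edges(data=True):
            if d.get("sign") not in (1, -1):
                raise ValidationError(
                    f"edge sign must be +1 or -1, got {d.get('sign')!r}"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positive_edges(self):
        return [
            (u, v, d)
            for u, v, d in self.graph.edges(data=True)
            if d["sign"] > 0
        ]

    def copy(self) -> "AssociationNetwork":
        return AssociationNetwork(self.graph.copy())
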