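"""Temporal co-occurrence subnetworks and their topology.

A static signed association network (inferred upstream; here an input
or a planted fixture) is filtered by joint-detection frequency, then
approximated in time by monthly subnetworks: a node is present in a
month iff its abundance that month is above zero, and an edge is present
iff both endpoints are and the edge exists in the static network. Each
subnetwork is summarised by the standard global topology metrics and the
metric series are correlated with environmental variables (Spearman,
Holm-corrected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .datamodel import AssociationNetwork, CountTable, SampleTable, ValidationError

logger = logging.getLogger("microtempo")

__all__ = [
    "clr_transform",
    "cooccurrence_filter",
    "monthly_subnetworks",
    "network_metrics",
    "metric_env_correlations",
    "correlation_network",
    "SubnetworkSeries",
]

METRICS = (
    "n_nodes",
    "n_edges",
    "edge_density",
    "mean_degree",
    "transitivity",
    "average_path_length",
    "assortativity_degree",
    "assortativity_domain",
    "assortativity_size_fraction",
    "mean_positive_strength",
)


def clr_transform(table: CountTable, pseudocount: float = 1.0) -> CountTable:
    """Centred log-ratio transform per sample:
    y_i = ln(x_i + pc) − mean_j ln(x_j + pc)."""
    logs = np.log(table.counts.astype(float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return CountTable(
        pd.DataFrame(clr, index=table.sample_ids, columns=table.asv_ids),
        provenance="clr",
    )


def cooccurrence_filter(
    net: AssociationNetwork,
    detection: pd.DataFrame,
    min_score: float = 0.5,
) -> AssociationNetwork:
    """Drop edges whose endpoints are jointly detected in fewer than
    ``min_score`` of samples, then remove isolated nodes.

    ``detection`` is a samples × nodes table (counts or booleans; > 0
    means detected). The joint-detection frequency is stored on every
    surviving edge as ``cooccurrence_score``.
    """
    missing = set(net.graph.nodes()) - set(detection.columns)
    if missing:
        raise ValidationError(
            f"nodes missing from detection matrix: {sorted(missing)[:5]}"
        )
    det = detection.to_numpy() > 0
    col = {c: i for i, c in enumerate(detection.columns)}
    g = net.graph.copy()
    drop = []
    for u, v, d in g.edges(data=True):
        score = float(np.mean(det[:, col[u]] & det[:, col[v]]))
        d["cooccurrence_score"] = score
        if score < min_score:
            drop.append((u, v))
    g.remove_edges_from(drop)
    isolated = list(nx.isolates(g))
    g.remove_nodes_from(isolated)
    logger.info(
        "co-occurrence filter: %d edges and %d isolated nodes removed",
        len(drop),
        len(isolated),
    )
    return AssociationNetwork(g)


@dataclass
class SubnetworkSeries:
    """Monthly subnetworks plus their metric table (rows = months)."""

    subnetworks: dict  # month key -> AssociationNetwork
    metrics: pd.DataFrame


def monthly_subnetworks(
    net: AssociationNetwork,
    table: CountTable,
    meta: SampleTable,
) -> SubnetworkSeries:
    """Induced monthly subgraphs of the static network.

    Months are the distinct calendar (year, month) values of the
    metadata. A node is detected in a month iff its abundance is > 0 in
    that month's sample(s) of its own size-fraction (falling back to any
    sample of the month when the node carries no fraction attribute).
    """
    mdf = meta.data.loc[table.sample_ids]
    keys = pd.to_datetime(mdf["date"]).dt.strftime("%Y-%m")
    subs: dict[str, AssociationNetwork] = {}
    rows = []
    for month in sorted(keys.unique()):
        sids = keys.index[keys == month]
        sub_table = table.data.loc[sids]
        detected = set()
        for node, attrs in net.graph.nodes(data=True):
            if node not in sub_table.columns:
                continue
            frac = attrs.get("size_fraction")
            if frac is not None and "size_fraction" in mdf.columns:
                rows_sel = sub_table.index[
                    mdf.loc[sids, "size_fraction"] == frac
                ]
                if len(rows_sel) == 0:
                    rows_sel = sub_table.index
            else:
                rows_sel = sub_table.index
            if (sub_table.loc[rows_sel, node] > 0).any():
                detected.add(node)
        g = net.graph.subgraph(detected).copy()
        subs[month] = AssociationNetwork(g)
        m = network_metrics(subs[month])
        m["month"] = month
        rows.append(m)
    if not rows:
        raise ValidationError("no months with samples")
    metrics = pd.DataFrame(rows).set_index("month")
    return SubnetworkSeries(subnetworks=subs, metrics=metrics)


def _mean_shortest_path(g: nx.Graph) -> float:
    """Mean shortest-path length over connected ordered pairs; signs and
    weights ignored."""
    n = g.number_of_nodes()
    if n < 2 or g.number_of_edges() == 0:
        return float("nan")
    total, pairs, disconnected = 0.0, 0, 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        total += sum(lengths.values())
        pairs += len(lengths) - 1  # drop the self pair
    disconnected = n * (n - 1) - pairs
    if disconnected:
        logger.info("%d ordered node pairs disconnected", disconnected)
    if pairs == 0:
        return float("nan")
    return total / pairs


def network_metrics(net: AssociationNetwork) -> dict:
    """Global topology metrics of one (sub)network.

    Undefined values (assortativity with a single category or uniform
    degrees, path length of an edgeless graph, positive strength with no
    positive edges) are reported as NaN.
    """
    g = net.graph
    n, m = g.number_of_nodes(), g.number_of_edges()
    out: dict[str, float] = {"n_nodes": n, "n_edges": m}
    out["edge_density"] = m / (n * (n - 1) / 2) if n > 1 else float("nan")
    out["mean_degree"] = 2 * m / n if n else float("nan")
    out["transitivity"] = nx.transitivity(g) if n else float("nan")
    out["average_path_length"] = _mean_shortest_path(g)

    def safe(fn):
        try:
            with np.errstate(all="ignore"):
                v = fn()
            return float(v) if np.isfinite(v) else float("nan")
        except (ZeroDivisionError, ValueError, nx.NetworkXError, KeyError):
            return float("nan")

    out["assortativity_degree"] = (
        safe(lambda: nx.degree_assortativity_coefficient(g)) if m else float("nan")
    )
    for attr, name in (
        ("domain_marker", "assortativity_domain"),
        ("size_fraction", "assortativity_size_fraction"),
    ):
        have = all(attr in g.nodes[v] for v in g.nodes())
        out[name] = (
            safe(lambda: nx.attribute_assortativity_coefficient(g, attr))
            if m and n and have
            else float("nan")
        )
    pos = [abs(d["weight"]) for _, _, d in g.edges(data=True) if d.get("sign", 1) > 0]
    out["mean_positive_strength"] = float(np.mean(pos)) if pos else float("nan")
    return out


def metric_env_correlations(
    metric_series: pd.DataFrame,
    env: pd.DataFrame,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of every (metric, environmental variable)
    pair on pairwise-complete observations, Holm-adjusted over the whole
    family."""
    rows = []
    for metric in metric_series.columns:
        for var in env.columns:
            x = metric_series[metric]
            y = env[var].reindex(metric_series.index)
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs:
                rows.append(
                    {
                        "metric": metric,
                        "variable": var,
                        "n": int(ok.sum()),
                        "rho": np.nan,
                        "p": np.nan,
                        "note": f"fewer than {min_pairs} complete pairs",
                    }
                )
                continue
            rho, p = spearmanr(x[ok], y[ok])
            rows.append(
                {
                    "metric": metric,
                    "variable": var,
                    "n": int(ok.sum()),
                    "rho": float(rho),
                    "p": float(p),
                    "note": "",
                }
            )
    out = pd.DataFrame(rows)
    mask = out["p"].notna()
    out["p_holm"] = np.nan
    if mask.any():
        out.loc[mask, "p_holm"] = multipletests(
            out.loc[mask, "p"], method="holm"
        )[1]
    return out


def correlation_network(
    clr_table: CountTable,
    min_abs_r: float = 0.7,
    node_attrs: pd.DataFrame | None = None,
) -> AssociationNetwork:
    """Baseline static-network construction for synthetic end-to-end
    runs: threshold the Pearson correlation of CLR profiles at
    |r| >= ``min_abs_r``. Deliberately simple plumbing — real studies
    infer their static networks with dedicated tools and pass them in.
    """
    X = clr_table.data
    corr = np.corrcoef(X.to_numpy().T)
    ids = list(X.columns)
    g = nx.Graph()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) >= min_abs_r:
                g.add_edge(
                    ids[i],
                    ids[j],
                    sign=1 if r > 0 else -1,
                    weight=float(round(r, 6)),
                    cooccurrence_score=1.0,
                )
    if node_attrs is not None:
        for v in g.nodes():
            if v in node_attrs.index:
                g.nodes[v].update(node_attrs.loc[v].to_dict())
    return AssociationNetwork(g)
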