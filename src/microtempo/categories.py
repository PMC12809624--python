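"""Classifying ASVs by their distribution across two observatories.

Four categories: *common* (shared, occurring in more than half of each
site's samples), *site-indicator* (statistically associated with one
site by the group-equalised indicator value, IndVal.g), *site-exclusive*
(detected at exactly one site) and *background* (none of the above).
Exclusive ASVs can simultaneously be indicators; the headline label
follows the priority common > indicator > exclusive and the overlap is
kept as a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datamodel import CountTable, ValidationError

logger = logging.getLogger("microtempo")

__all__ = [
    "shared_unique",
    "occupancy",
    "common_asvs",
    "indval",
    "assign_categories",
]


def shared_unique(table_a: CountTable, table_b: CountTable) -> pd.DataFrame:
    """Partition of detected ASVs into A-only / B-only / shared.

    ASVs with zero counts at both sites are excluded (warned). Returns a
    frame indexed by ASV id with boolean columns in_a, in_b and a
    ``membership`` column in {A-only, B-only, shared}.
    """
    if list(table_a.asv_ids) != list(table_b.asv_ids):
        raise ValidationError("tables must share one ASV id space")
    in_a = table_a.data.sum(axis=0) > 0
    in_b = table_b.data.sum(axis=0) > 0
    absent = ~(in_a | in_b)
    if absent.any():
        logger.warning(
            "%d ASVs with zero counts everywhere excluded", int(absent.sum())
        )
    out = pd.DataFrame({"in_a": in_a, "in_b": in_b})[~absent]
    out["membership"] = np.select(
        [out.in_a & out.in_b, out.in_a], ["shared", "A-only"], default="B-only"
    )
    return out


def occupancy(table: CountTable) -> pd.Series:
    """Fraction of samples where each ASV is detected (> 0)."""
    return (table.data > 0).mean(axis=0)


def common_asvs(
    shared: pd.DataFrame,
    occ_a: pd.Series,
    occ_b: pd.Series,
    min_occ: float = 0.5,
) -> pd.Index:
    """Shared ASVs with occurrence strictly above ``min_occ`` at both
    sites."""
    shared_ids = shared.index[shared["membership"] == "shared"]
    mask = (occ_a.loc[shared_ids] > min_occ) & (occ_b.loc[shared_ids] > min_occ)
    return shared_ids[mask]


def indval(
    table: CountTable,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Group-equalised indicator value (IndVal.g) with permutation test.

    For ASV i and group g: specificity A_ig = mean abundance of i in g
    divided by the sum of its per-group mean abundances; fidelity B_ig =
    fraction of g's samples where i is detected; the statistic is
    max_g sqrt(A_ig · B_ig), and p comes from permuting group labels,
    p = (#{stat* >= stat} + 1)/(n_perm + 1).
    """
    groups = groups.loc[table.sample_ids]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    if (groups.value_counts() < 2).any():
        raise ValidationError("every group needs at least 2 samples")
    counts = table.counts.astype(float)
    gidx = [np.flatnonzero((groups == g).to_numpy()) for g in levels]

    def stat(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        means = np.stack([c[ix].mean(axis=0) for ix in gidx])  # (G, T)
        pres = np.stack([(c[ix] > 0).mean(axis=0) for ix in gidx])
        tot = means.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.where(tot > 0, means / np.where(tot > 0, tot, 1.0), 0.0)
        iv = np.sqrt(A * pres)
        return iv.max(axis=0), iv.argmax(axis=0)

    if not np.any(counts.sum(axis=0) > 0):
        raise ValidationError("all-zero table")
    obs, best = stat(counts)
    rng = np.random.default_rng(seed)
    ge = np.zeros(counts.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(counts.shape[0])
        s, _ = stat(counts[perm])
        ge += s >= obs - 1e-12
    p = (ge + 1.0) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "stat": obs,
            "group": [levels[b] for b in best],
            "p": p,
        },
        index=table.asv_ids,
    )


def assign_categories(
    shared: pd.DataFrame,
    common: pd.Index,
    indval_res: pd.DataFrame,
    site_a: str = "A",
    site_b: str = "B",
    stat_min: float = 0.7,
    p_max: float = 0.01,
) -> pd.DataFrame:
    """Headline category per detected ASV with overlap flags.

    Priority for the single label: common > indicator > exclusive >
    background; an exclusive ASV that also passes the indicator test is
    labelled indicator with its exclusive flag retained.
    """
    ids = shared.index
    iv = indval_res.reindex(ids)
    is_common = ids.isin(common)
    is_indicator = (iv["stat"] > stat_min) & (iv["p"] < p_max)
    is_indicator = is_indicator.fillna(False).to_numpy()
    membership = shared["membership"].to_numpy()
    is_exclusive = membership != "shared"
    if np.any(is_common & is_exclusive):
        raise ValidationError("an ASV cannot be both common and exclusive")

    exc_label = np.where(
        membership == "A-only", f"exclusive-{site_a}", f"exclusive-{site_b}"
    )
    ind_label = np.array(
        [f"indicator-{g}" if pd.notna(g) else "" for g in iv["group"]]
    )
    category = np.select(
        [is_common, is_indicator, is_exclusive],
        ["common", ind_label, exc_label],
        default="background",
    )
    return pd.DataFrame(
        {
            "category": category,
            "membership": membership,
            "common": is_common,
            "indicator": is_indicator,
            "exclusive": is_exclusive,
            "indval_stat": iv["stat"].to_numpy(),
            "indval_group": iv["group"].to_numpy(),
            "indval_p": iv["p"].to_numpy(),
        },
        index=ids,
    )
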