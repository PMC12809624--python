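"""Alpha and beta diversity: rarefaction, Shannon/Pielou/richness/Faith
PD, rank-abundance curves, Bray–Curtis dissimilarity, distance-based
variance partitioning (PERMANOVA, adonis2-style sequential R²) and
time-decay pairs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import faith_pd

from .datamodel import CountTable, PhyloTree, SampleTable, ValidationError

logger = logging.getLogger("microtempo")

__all__ = [
    "rarefy",
    "alpha_diversity",
    "rank_abundance",
    "bray_curtis",
    "DistanceMatrix",
    "permanova",
    "PermanovaResult",
    "time_decay",
]


def rarefy(
    table: CountTable, depth: int, seed: int, drop_shallow: bool = False
) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth``
    reads (one multivariate-hypergeometric draw per sample, the single
    ``rrarefy``-style draw).

    Samples with fewer than ``depth`` reads raise unless ``drop_shallow``
    is set, in which case they are removed with a warning.
    """
    totals = table.totals()
    shallow = totals.index[totals < depth].tolist()
    data = table.data
    if shallow:
        if not drop_shallow:
            raise ValidationError(
                f"samples below rarefaction depth {depth}: {shallow}"
            )
        logger.warning(
            "dropping %d samples below depth %d", len(shallow), depth
        )
        data = data.drop(index=shallow)
        if data.shape[0] == 0:
            raise ValidationError("no samples at or above rarefaction depth")
    rng = np.random.default_rng(seed)
    out = np.empty_like(data.to_numpy())
    for r, row in enumerate(data.to_numpy()):
        if row.sum() == depth:
            out[r] = row
        else:
            out[r] = rng.multivariate_hypergeometric(row, depth)
    return CountTable(
        pd.DataFrame(out, index=data.index, columns=data.columns),
        provenance="rarefied",
    )


def alpha_diversity(
    table: CountTable, tree: PhyloTree | None = None
) -> pd.DataFrame:
    """Per-sample richness, Shannon H (natural log), Pielou J = H/ln S,
    and Faith PD (branch length of the subtree spanning the present taxa
    and the root; requires ``tree``).

    J is reported missing for single-taxon samples (ln S = 0).
    """
    rel = table.relative().to_numpy()
    richness = (table.counts > 0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(rel > 0, np.log(np.where(rel > 0, rel, 1.0)), 0.0)
        shannon = -(rel * logf).sum(axis=1)
        pielou = np.where(richness > 1, shannon / np.log(richness), np.nan)
    out = pd.DataFrame(
        {"richness": richness, "shannon": shannon, "pielou": pielou},
        index=table.data.index,
    )
    if tree is not None:
        ids = table.asv_ids
        missing = set(ids) - set(tree.tip_names)
        if missing:
            raise ValidationError(
                f"{len(missing)} table ASVs absent from tree; align inputs first"
            )
        out["faith_pd"] = [
            faith_pd(row, taxa=ids, tree=tree.tree)
            for row in table.counts
        ]
    return out


def rank_abundance(table: CountTable) -> pd.DataFrame:
    """Descending per-sample relative abundances with ranks normalised to
    (0, 1]; ties broken by ASV id order."""
    rel = table.relative()
    rows = []
    for sid, row in rel.iterrows():
        row = row[row > 0]
        ordered = row.sort_index().sort_values(ascending=False, kind="stable")
        n = len(ordered)
        for rank, (asv, f) in enumerate(ordered.items(), start=1):
            rows.append(
                {
                    "sample_id": sid,
                    "rank": rank,
                    "rank_norm": rank / n,
                    "asv_id": asv,
                    "rel_abundance": f,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DistanceMatrix:
    ids: list
    data: np.ndarray
    metric: str = "braycurtis"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """BC(j,k) = Σ|f_ij − f_ik| / Σ(f_ij + f_ik) on per-sample relative
    abundances."""
    rel = table.relative().to_numpy()
    d = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(ids=table.sample_ids, data=d, metric="braycurtis")


# ---------------------------------------------------------------------------
# PERMANOVA (McArdle & Anderson partitioning with sequential terms)


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # term, df, SumOfSqs, R2, F, p
    n_perm: int
    term_order: list

    def r2(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def _model_matrix(meta: pd.DataFrame, term: str) -> np.ndarray:
    col = meta[term]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None]
    d = pd.get_dummies(col, drop_first=True)
    if d.shape[1] == 0:
        raise ValidationError(f"term {term!r} has a single level")
    return d.to_numpy(dtype=float)


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


def permanova(
    dist: DistanceMatrix,
    meta: SampleTable | pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
    permutations: str | None = None,
) -> PermanovaResult:
    """Sequential distance-based variance partitioning.

    Gower-centres the squared distance matrix and partitions its total
    sum of squares over the ``terms`` in the given order (Type-I-like,
    the adonis2 default). The p-value for each term comes from free
    permutation of sample labels, p = (#{F* >= F} + 1)/(n_perm + 1);
    ``permutations="exhaustive"`` enumerates all n! label permutations
    (small n only) and then p = #{F* >= F}/n! with the identity included.
    """
    mdf = meta.data if isinstance(meta, SampleTable) else meta
    ids = list(dist.ids)
    if not set(ids) <= set(mdf.index):
        raise ValidationError("distance ids missing from metadata")
    mdf = mdf.loc[ids]
    n = len(ids)
    if n < len(terms) + 2:
        raise ValidationError("fewer samples than terms + 2")

    D2 = np.asarray(dist.data, dtype=float) ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ D2 @ J
    ss_total = np.trace(G)

    # sequential hat matrices: H_k projects onto intercept + terms 1..k
    X = np.ones((n, 1))
    hats = [np.ones((n, n)) / n]
    dfs = []
    for term in terms:
        Xt = _model_matrix(mdf, term)
        X = np.hstack([X, Xt])
        H = _hat(X)
        dfs.append(int(round(np.trace(H) - np.trace(hats[-1]))))
        hats.append(H)
    H_full = hats[-1]
    df_res = n - int(round(np.trace(H_full)))
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")

    def term_stats(Gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss_terms = np.array(
            [np.sum((hats[k + 1] - hats[k]) * Gm) for k in range(len(terms))]
        )
        ss_res = np.sum((np.eye(n) - H_full) * Gm)
        # a residual that is pure floating-point noise (perfectly
        # separated groups) is treated as exactly zero, giving F = inf
        if abs(ss_res) < 1e-10 * max(abs(ss_total), 1e-300):
            ss_res = 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_terms / np.array(dfs)) / (ss_res / df_res)
        return ss_terms, F

    ss_terms, F_obs = term_stats(G)
    ss_res = ss_total - ss_terms.sum()

    if permutations == "exhaustive":
        perms = list(itertools.permutations(range(n)))
        count = np.zeros(len(terms))
        for p in perms:
            idx = np.array(p)
            _, Fp = term_stats(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - 1e-12
        pvals = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros(len(terms))
        for _ in range(n_perm):
            idx = rng.permutation(n)
            _, Fp = term_stats(G[np.ix_(idx, idx)])
            count += Fp >= F_obs - 1e-12
        pvals = (count + 1.0) / (n_perm + 1.0)
        n_used = n_perm

    rows = [
        {
            "term": t,
            "df": dfs[k],
            "SumOfSqs": ss_terms[k],
            "R2": ss_terms[k] / ss_total,
            "F": F_obs[k],
            "p": pvals[k],
        }
        for k, t in enumerate(terms)
    ]
    rows.append(
        {
            "term": "Residual",
            "df": df_res,
            "SumOfSqs": ss_res,
            "R2": ss_res / ss_total,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return PermanovaResult(
        table=pd.DataFrame(rows), n_perm=n_used, term_order=list(terms)
    )


def time_decay(
    dist: DistanceMatrix,
    meta: SampleTable,
    group_cols: tuple[str, ...] = ("site", "size_fraction"),
) -> pd.DataFrame:
    """All within-group sample pairs as (Δt months, dissimilarity) rows —
    the community similarity decay with time lag."""
    mdf = meta.data.loc[dist.ids]
    months = meta.months_since_start().loc[dist.ids].to_numpy()
    ids = list(dist.ids)
    cols = [c for c in group_cols if c in mdf.columns]
    groups = mdf[cols].astype(str).agg("|".join, axis=1).to_numpy() if cols else np.array(["all"] * len(ids))
    rows = []
    for j in range(len(ids)):
        for k in range(j + 1, len(ids)):
            if groups[j] != groups[k]:
                continue
            rows.append(
                {
                    "sample_j": ids[j],
                    "sample_k": ids[k],
                    "group": groups[j],
                    "delta_months": abs(months[k] - months[j]),
                    "dissimilarity": dist.data[j, k],
                }
            )
    return pd.DataFrame(rows)
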