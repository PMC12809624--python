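"""Quantifying temporal community assembly processes with phylogenetic
and taxonomic null models.

The procedure classifies every within-dataset pair of communities into
one of five assembly processes:

1.  Phylogenetic turnover between a pair is the abundance-weighted beta
    mean nearest taxon distance,

        βMNTD(j,k) = ½ [ Σ_{i∈j} f_ij · min_{i'∈k} d(i,i')
                       + Σ_{i'∈k} f_i'k · min_{i∈j} d(i,i') ]

    with f the within-sample relative abundances and d the cophenetic
    (patristic) distance. A null distribution is built by shuffling taxa
    labels across the cophenetic matrix (regional-pool null) and
    recomputing; the z-score of the observation against the null is the
    beta nearest taxon index, βNTI.

2.  Taxonomic turnover beyond the phylogenetic signal is judged by the
    Raup–Crick metric on Bray–Curtis dissimilarities (RCbray): null
    communities preserve each sample's observed richness and total count,
    drawing taxa by occurrence frequency and individuals by mean relative
    abundance, and the observed Bray–Curtis value is ranked within the
    null ensemble and rescaled to [-1, 1].

3.  Thresholds: βNTI > 2 → heterogeneous selection; βNTI < -2 →
    homogeneous selection; otherwise RCbray > 0.95 → historical
    contingency (non-selective high turnover), RCbray < -0.95 →
    non-selective low turnover, |RCbray| <= 0.95 → ecological drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CountTable, PhyloTree, SampleTable, ValidationError

logger = logging.getLogger("microtempo")

__all__ = [
    "PROCESSES",
    "cophenetic_distances",
    "beta_mntd",
    "bnti",
    "raup_crick_bray",
    "classify_processes",
    "process_fractions",
    "assembly_analysis",
    "AssemblyResult",
]

PROCESSES = (
    "heterogeneous selection",
    "homogeneous selection",
    "historical contingency",
    "non-selective low turnover",
    "ecological drift",
)


def cophenetic_distances(tree: PhyloTree) -> pd.DataFrame:
    """Patristic distances between all tip pairs (sum of branch lengths
    along the connecting path)."""
    return tree.cophenetic()


def _check_aligned(table: CountTable, dists: pd.DataFrame) -> np.ndarray:
    taxa = table.asv_ids
    missing = set(taxa) - set(dists.index)
    if missing:
        raise ValidationError(
            f"{len(missing)} table taxa missing from distance matrix"
        )
    return dists.loc[taxa, taxa].to_numpy(dtype=float)


def _beta_mntd_from_arrays(
    F: np.ndarray, present: np.ndarray, D: np.ndarray
) -> np.ndarray:
    """βMNTD for all sample pairs.

    F: (S, T) relative abundances; present: (S, T) boolean; D: (T, T).
    For each sample k, mind[:, k][i] = min over taxa present in k of
    d(i, i'); then M = F @ mind and βMNTD = ½(M + Mᵀ).
    """
    S, T = F.shape
    mind = np.empty((T, S))
    for k in range(S):
        cols = present[k]
        if not cols.any():
            raise ValidationError("empty sample in beta_mntd")
        mind[:, k] = D[:, cols].min(axis=1)
    M = F @ mind
    return 0.5 * (M + M.T)


def beta_mntd(
    table: CountTable,
    dists: pd.DataFrame,
    abundance_weighted: bool = True,
) -> pd.DataFrame:
    """Abundance-weighted beta mean nearest taxon distance for every
    sample pair. A taxon present in both samples contributes 0 (its
    nearest relative in the other community is itself)."""
    D = _check_aligned(table, dists)
    counts = table.counts.astype(float)
    present = counts > 0
    if abundance_weighted:
        F = counts / counts.sum(axis=1, keepdims=True)
    else:
        F = present / present.sum(axis=1, keepdims=True)
    out = _beta_mntd_from_arrays(F, present, D)
    return pd.DataFrame(out, index=table.sample_ids, columns=table.sample_ids)


@dataclass
class NullSummary:
    mean: pd.DataFrame
    sd: pd.DataFrame


def bnti(
    table: CountTable,
    tree: PhyloTree | pd.DataFrame,
    n_null: int = 999,
    seed: int = 0,
    abundance_weighted: bool = True,
    per_pair: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, NullSummary]:
    """Beta nearest taxon index for every sample pair.

    Each null replicate applies ONE taxa-label permutation to the whole
    cophenetic matrix — shared by all pairs within the replicate — and
    recomputes βMNTD; βNTI = (obs − null mean)/null sd. ``per_pair=True``
    draws an independent permutation per pair per replicate instead
    (sensitivity analysis).

    Pairs whose null sd is 0 (e.g. star phylogenies, identical
    communities) get βNTI = 0 with the degenerate flag set, so that
    classification falls through to the taxonomic (RCbray) branch.

    Returns (βNTI matrix, degenerate-flag matrix, null summary).
    """
    if n_null < 2:
        raise ValidationError("n_null must be >= 2")
    dists = tree.cophenetic() if isinstance(tree, PhyloTree) else tree
    D = _check_aligned(table, dists)
    counts = table.counts.astype(float)
    present = counts > 0
    F = (
        counts / counts.sum(axis=1, keepdims=True)
        if abundance_weighted
        else present / present.sum(axis=1, keepdims=True)
    )
    S, T = F.shape
    obs = _beta_mntd_from_arrays(F, present, D)

    rng = np.random.default_rng(seed)
    acc = np.zeros((S, S))
    acc2 = np.zeros((S, S))
    if not per_pair:
        for _ in range(n_null):
            perm = rng.permutation(T)
            Dp = D[np.ix_(perm, perm)]
            b = _beta_mntd_from_arrays(F, present, Dp)
            acc += b
            acc2 += b * b
    else:
        for _ in range(n_null):
            b = np.zeros((S, S))
            for j in range(S):
                for k in range(j + 1, S):
                    perm = rng.permutation(T)
                    Dp = D[np.ix_(perm, perm)]
                    sub = _beta_mntd_from_arrays(
                        F[[j, k]], present[[j, k]], Dp
                    )
                    b[j, k] = b[k, j] = sub[0, 1]
            acc += b
            acc2 += b * b
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean**2, 0.0)
    sd = np.sqrt(var * n_null / max(n_null - 1, 1))

    degenerate = sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(degenerate, 0.0, (obs - mean) / np.where(degenerate, 1.0, sd))
    np.fill_diagonal(z, 0.0)
    ids = table.sample_ids
    summary = NullSummary(
        mean=pd.DataFrame(mean, index=ids, columns=ids),
        sd=pd.DataFrame(sd, index=ids, columns=ids),
    )
    return (
        pd.DataFrame(z, index=ids, columns=ids),
        pd.DataFrame(degenerate, index=ids, columns=ids),
        summary,
    )


def _null_community(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occ_freq: np.ndarray,
    mean_rel: np.ndarray,
) -> np.ndarray:
    """One richness- and abundance-preserving null community.

    Taxa are drawn without replacement with probability proportional to
    occurrence frequency; each drawn taxon receives one individual and
    the remaining ``total - richness`` individuals are assigned
    multinomially with probability proportional to dataset-wide mean
    relative abundance restricted to the drawn taxa.
    """
    T = occ_freq.size
    chosen = rng.choice(T, size=richness, replace=False, p=occ_freq / occ_freq.sum())
    x = np.zeros(T, dtype=np.int64)
    x[chosen] = 1
    rem = total - richness
    if rem > 0:
        w = mean_rel[chosen]
        wsum = w.sum()
        p = np.full(richness, 1.0 / richness) if wsum <= 0 else w / wsum
        x[chosen] += rng.multinomial(rem, p)
    return x


def _bc_pair(a: np.ndarray, b: np.ndarray) -> float:
    fa = a / a.sum()
    fb = b / b.sum()
    return float(np.abs(fa - fb).sum() / (fa + fb).sum())


def raup_crick_bray(
    table: CountTable,
    n_null: int = 999,
    seed: int = 0,
    occ_freq: np.ndarray | None = None,
    mean_rel: np.ndarray | None = None,
) -> pd.DataFrame:
    """Raup–Crick metric on Bray–Curtis dissimilarities for every sample
    pair, in [-1, 1].

    Null ensembles are generated per sample per replicate; replicate r of
    sample j is paired with replicate r of sample k (samples' nulls are
    independent, so this is distributionally equivalent to regenerating
    per pair). The observed value is ranked in the null ensemble with
    half weight on ties:

        RCbray = 2·[(#{BC_null < BC_obs} + ½·#{BC_null = BC_obs})/n_null] − 1

    The regional pool defaults to the analysed table itself (per-group
    pools when called per site × fraction); ``occ_freq`` / ``mean_rel``
    override it with occupancy counts and mean relative abundances from
    a wider sample set.
    """
    counts = table.counts
    if table.provenance == "clr":
        raise ValidationError("raup_crick_bray requires integer counts")
    S, T = counts.shape
    if occ_freq is None:
        occ_freq = (counts > 0).sum(axis=0).astype(float)
    if mean_rel is None:
        rel = counts / counts.sum(axis=1, keepdims=True)
        mean_rel = rel.mean(axis=0)
    occ_freq = np.asarray(occ_freq, dtype=float)
    mean_rel = np.asarray(mean_rel, dtype=float)
    if occ_freq.size != T or mean_rel.size != T:
        raise ValidationError("pool arrays must match the table's taxa")
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)

    rng = np.random.default_rng(seed)
    obs = np.zeros((S, S))
    for j in range(S):
        for k in range(j + 1, S):
            obs[j, k] = obs[k, j] = _bc_pair(counts[j], counts[k])

    below = np.zeros((S, S))
    equal = np.zeros((S, S))
    nulls = np.empty((S, T), dtype=np.int64)
    for _ in range(n_null):
        for s in range(S):
            nulls[s] = _null_community(
                rng, int(richness[s]), int(totals[s]), occ_freq, mean_rel
            )
        fn = nulls / nulls.sum(axis=1, keepdims=True)
        num = np.abs(fn[:, None, :] - fn[None, :, :]).sum(axis=2)
        den = (fn[:, None, :] + fn[None, :, :]).sum(axis=2)
        bc_null = num / den
        below += bc_null < obs - 1e-12
        equal += np.abs(bc_null - obs) <= 1e-12
    rc = 2.0 * ((below + 0.5 * equal) / n_null) - 1.0
    np.fill_diagonal(rc, 0.0)
    ids = table.sample_ids
    return pd.DataFrame(rc, index=ids, columns=ids)


def classify_processes(
    bnti_mat: pd.DataFrame,
    rc_mat: pd.DataFrame,
    degenerate: pd.DataFrame | None = None,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> pd.DataFrame:
    """Per-pair five-process labels from the βNTI / RCbray thresholds.

    Degenerate-flagged pairs (null sd = 0) carry βNTI = 0, so they fall
    through to the RCbray branch; the flag is propagated in the output.
    Returns a tidy frame: sample_j, sample_k, bnti, rcbray, degenerate,
    process.
    """
    if list(bnti_mat.index) != list(rc_mat.index):
        raise ValidationError("βNTI and RCbray matrices on different samples")
    ids = list(bnti_mat.index)
    rows = []
    for j in range(len(ids)):
        for k in range(j + 1, len(ids)):
            b = float(bnti_mat.iloc[j, k])
            r = float(rc_mat.iloc[j, k])
            if b > bnti_threshold:
                proc = "heterogeneous selection"
            elif b < -bnti_threshold:
                proc = "homogeneous selection"
            elif r > rc_threshold:
                proc = "historical contingency"
            elif r < -rc_threshold:
                proc = "non-selective low turnover"
            else:
                proc = "ecological drift"
            rows.append(
                {
                    "sample_j": ids[j],
                    "sample_k": ids[k],
                    "bnti": b,
                    "rcbray": r,
                    "degenerate": bool(degenerate.iloc[j, k])
                    if degenerate is not None
                    else False,
                    "process": proc,
                }
            )
    return pd.DataFrame(rows)


def process_fractions(
    labels: pd.DataFrame, grouping: pd.Series | None = None
) -> pd.DataFrame:
    """Fraction of pairs assigned to each process, per group (fractions
    sum to 1 within each group)."""
    df = labels.copy()
    if grouping is not None:
        gj = df["sample_j"].map(grouping)
        gk = df["sample_k"].map(grouping)
        df = df[gj.eq(gk)].assign(group=gj[gj.eq(gk)])
    else:
        df = df.assign(group="all")
    if df.empty:
        raise ValidationError("no within-group pairs to summarise")
    rows = []
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        counts = sub["process"].value_counts()
        row = {"group": g, "n_pairs": n}
        for proc in PROCESSES:
            row[proc] = counts.get(proc, 0) / n
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class AssemblyResult:
    pairs: pd.DataFrame
    fractions: pd.DataFrame


def assembly_analysis(
    table: CountTable,
    tree: PhyloTree,
    meta: SampleTable | None = None,
    group_cols: tuple[str, ...] = ("site", "size_fraction"),
    n_null: int = 999,
    seed: int = 0,
) -> AssemblyResult:
    """Full per-group pipeline: βNTI + RCbray + classification + process
    fractions, restricted to within-group (site × fraction) pairs."""
    if meta is not None:
        cols = [c for c in group_cols if c in meta.data.columns]
        groups = meta.data.loc[table.sample_ids, cols].astype(str).agg(
            "|".join, axis=1
        )
    else:
        groups = pd.Series("all", index=table.sample_ids)
    all_pairs = []
    rng = np.random.default_rng(seed)
    dists = tree.cophenetic()
    for g in sorted(groups.unique()):
        sids = groups.index[groups == g]
        sub = table.select_samples(sids)
        keep = [a for a in sub.asv_ids if sub.data[a].sum() > 0]
        sub = sub.select_asvs(keep)
        s1, s2 = int(rng.integers(2**31)), int(rng.integers(2**31))
        z, flags, _ = bnti(sub, dists.loc[keep, keep], n_null=n_null, seed=s1)
        rc = raup_crick_bray(sub, n_null=n_null, seed=s2)
        pairs = classify_processes(z, rc, degenerate=flags)
        pairs.insert(0, "group", g)
        all_pairs.append(pairs)
    pairs = pd.concat(all_pairs, ignore_index=True)
    fractions = process_fractions(pairs.drop(columns="group"), grouping=groups)
    return AssemblyResult(pairs=pairs, fractions=fractions)
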