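"""Synthetic two-observatory community time series with known assembly
regimes.

The generator produces everything the downstream stages consume: a Yule
phylogeny whose tips carry Brownian-motion environmental optima (so
phylogenetically close taxa prefer similar conditions — the niche
conservatism that the βNTI null model presupposes), sinusoidal or flat
environmental forcing, and a discrete-generation community process that
mixes neutral drift, immigration from a regional pool, and Gaussian
environmental filtering:

    w_i(t) ∝ [ (1-m)·x_i(t-1)/N + m·π_i ] · exp( -(E(t) - μ_i)² / (2σ_sel²) )
    x(t) ~ Multinomial(N, w(t)/Σw(t))

With σ_sel → ∞ (or a flat environment) the exponential factor is inert
and the model collapses to neutral drift with immigration; with small
σ_sel and a strongly seasonal E(t) the community tracks the environment,
which is exactly the contrast between a temperate-like and a
tropical-like observatory that the scenario encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datamodel import AssociationNetwork, CountTable, PhyloTree, SampleTable

import networkx as nx

__all__ = [
    "ScenarioConfig",
    "simulate_tree",
    "evolve_traits",
    "make_environment",
    "simulate_communities",
    "make_scenario",
    "make_planted_seasonal_table",
    "make_static_network",
    "ScenarioBundle",
]


@dataclass
class ScenarioConfig:
    """Parameters of one site's community process.

    σ_sel is the selection width in trait units: the niche breadth of the
    Gaussian environmental filter. Small values mean strong selection;
    values much larger than the environmental range make the process
    effectively neutral.
    """

    n_taxa: int = 150
    n_months: int = 41          # monthly sampling over ~3.4 years
    pop_size: int = 2000        # individuals (reads) per sample, N
    immigration: float = 0.1    # m, fraction replaced from the regional pool
    selection_width: float = 0.5      # σ_sel, trait units
    env_amplitude: float = 3.0        # seasonal forcing amplitude, trait units
    env_mean: float = 0.0
    env_period: float = 12.0          # months
    env_noise_sd: float = 0.1
    trait_diffusion: float = 1.0      # σ_BM, trait units per sqrt(branch length)
    pool: str = "uniform"             # regional pool π: "uniform" | "logseries"
    emulate_depth_variation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_months < 1 or self.pop_size < 1:
            raise ValueError("counts must be >= 1 (n_taxa >= 2)")
        if not 0.0 <= self.immigration <= 1.0:
            raise ValueError("immigration m must be in [0, 1]")
        if self.selection_width <= 0:
            raise ValueError("selection_width must be > 0")


def simulate_tree(n_tips: int, seed: int) -> PhyloTree:
    """Ultrametric pure-birth (Yule) tree with ``n_tips`` labelled tips.

    Lineages split at unit rate per lineage; after the last split every
    extant lineage is extended to the present, so all tip depths are
    equal.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    active = [root]
    birth = {id(root): 0.0}
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        node.length = t - birth[id(node)] if node.parent is not None else None
        left, right = TreeNode(), TreeNode()
        node.extend([left, right])
        birth[id(left)] = birth[id(right)] = t
        active.extend([left, right])
    t += rng.exponential(1.0 / len(active))
    for i, tip in enumerate(sorted(active, key=lambda n: birth[id(n)])):
        tip.length = t - birth[id(tip)]
    for i, tip in enumerate(root.tips()):
        tip.name = f"asv{i + 1:04d}"
    return PhyloTree(root)


def evolve_traits(
    tree: PhyloTree, sigma_bm: float, root_value: float, seed: int
) -> pd.Series:
    """Brownian-motion environmental optima along the tree.

    Each branch adds an independent N(0, σ_BM²·length) increment, so the
    variance of the difference between two tips equals σ_BM² times their
    cophenetic distance.
    """
    if sigma_bm < 0:
        raise ValueError("sigma_bm must be >= 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.tree): root_value}
    out = {}
    for node in tree.tree.preorder(include_self=False):
        step = rng.normal(0.0, sigma_bm * np.sqrt(max(node.length, 0.0)))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out, name="trait").loc[tree.tip_names]


def make_environment(
    amplitude: float,
    mean: float,
    period: float,
    n_months: int,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """E(t) = mean + amplitude·sin(2πt/period) + N(0, noise_sd²),
    t = 0..n_months-1."""
    if period <= 0:
        raise ValueError("period must be > 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_months, dtype=float)
    env = mean + amplitude * np.sin(2 * np.pi * t / period)
    if noise_sd > 0:
        env = env + rng.normal(0.0, noise_sd, n_months)
    return env


def _regional_pool(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    if config.pool == "uniform":
        return np.full(config.n_taxa, 1.0 / config.n_taxa)
    if config.pool == "logseries":
        # log-series ranked abundances, a skewed but standard SAD
        k = np.arange(1, config.n_taxa + 1, dtype=float)
        p = 0.98**k / k
        rng.shuffle(p)
        return p / p.sum()
    raise ValueError(f"unknown pool model {config.pool!r}")


def simulate_communities(
    tree: PhyloTree,
    traits: pd.Series,
    env: np.ndarray,
    config: ScenarioConfig,
    site: str = "site",
    size_fraction: str = "small",
    start_date: str = "2013-04-15",
) -> tuple[CountTable, SampleTable]:
    """Run the drift + immigration + selection process for one site.

    Returns one sample per month plus its metadata row (date on a
    monthly grid, site label, environment value).
    """
    taxa = tree.tip_names
    if list(traits.index) != taxa:
        traits = traits.loc[taxa]
    if len(env) != config.n_months:
        raise ValueError("env length must equal n_months")
    rng = np.random.default_rng(config.seed)
    n, N = config.n_taxa, config.pop_size
    mu = traits.to_numpy()
    pi = _regional_pool(config, rng)
    m = config.immigration
    sig2 = 2.0 * config.selection_width**2

    x = rng.multinomial(N, np.full(n, 1.0 / n))
    rows = np.empty((config.n_months, n), dtype=np.int64)
    for t in range(config.n_months):
        if t > 0:
            w = ((1.0 - m) * x / N + m * pi) * np.exp(
                -((env[t] - mu) ** 2) / sig2
            )
            total = w.sum()
            if total <= 0 or not np.isfinite(total):
                raise ValueError(
                    "all selection weights vanished; increase "
                    "selection_width (σ_sel)"
                )
            x = rng.multinomial(N, w / total)
        depth = N
        if config.emulate_depth_variation:
            depth = int(rng.integers(int(0.8 * N), int(1.2 * N) + 1))
        if depth != N:
            # re-draw the sample at the emulated sequencing depth
            f = x / x.sum()
            rows[t] = rng.multinomial(depth, f)
        else:
            rows[t] = x
    dates = pd.date_range(start=start_date, periods=config.n_months, freq="MS") + pd.Timedelta(days=14)
    sample_ids = [f"{site}_{size_fraction}_{t + 1:02d}" for t in range(config.n_months)]
    table = CountTable(
        pd.DataFrame(rows, index=sample_ids, columns=taxa), provenance="raw"
    )
    meta = SampleTable(
        pd.DataFrame(
            {
                "date": dates.strftime("%Y-%m-%d"),
                "site": site,
                "size_fraction": size_fraction,
                "temperature": env,
            },
            index=sample_ids,
        )
    )
    return table, meta


@dataclass
class ScenarioBundle:
    """Everything one end-to-end synthetic study needs."""

    table: CountTable
    meta: SampleTable
    tree: PhyloTree
    traits: pd.Series
    truth: dict = field(default_factory=dict)

    def site_table(self, site: str, size_fraction: str | None = None) -> CountTable:
        m = self.meta.data["site"] == site
        if size_fraction is not None:
            m &= self.meta.data["size_fraction"] == size_fraction
        return self.table.select_samples(self.meta.data.index[m])


def make_scenario(
    config: ScenarioConfig | None = None,
    two_fractions: bool = False,
) -> ScenarioBundle:
    """Two observatories sharing one phylogeny and regional pool.

    The "temperate" site keeps the configured seasonal amplitude; the
    "tropical" site runs the same process with amplitude 0 and an
    effectively neutral selection width, emulating weak, aseasonal
    abiotic forcing. Truth labels record the generating regime per site.
    """
    config = config or ScenarioConfig()
    base = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_taxa, seed=int(base.integers(2**31)))
    traits = evolve_traits(
        tree, config.trait_diffusion, root_value=config.env_mean,
        seed=int(base.integers(2**31)),
    )
    sites = {
        "temperate": replace(
            config, seed=int(base.integers(2**31))
        ),
        "tropical": replace(
            config,
            env_amplitude=0.0,
            selection_width=100.0 * config.selection_width,
            seed=int(base.integers(2**31)),
        ),
    }
    tables, metas = [], []
    truth = {}
    for site, cfg in sites.items():
        env = make_environment(
            cfg.env_amplitude,
            cfg.env_mean,
            cfg.env_period,
            cfg.n_months,
            cfg.env_noise_sd,
            seed=int(base.integers(2**31)),
        )
        fractions = ("small", "large") if two_fractions else ("small",)
        for frac in fractions:
            cfg_f = replace(cfg, seed=int(base.integers(2**31)))
            tbl, meta = simulate_communities(
                tree, traits, env, cfg_f, site=site, size_fraction=frac
            )
            tables.append(tbl.data)
            metas.append(meta.data)
        truth[site] = {
            "regime": "seasonal-selection" if cfg.env_amplitude > 0 else "neutral-drift",
            "env_amplitude": cfg.env_amplitude,
            "selection_width": cfg.selection_width,
        }
    table = CountTable(pd.concat(tables), provenance="raw")
    meta = SampleTable(pd.concat(metas))
    return ScenarioBundle(table=table, meta=meta, tree=tree, traits=traits, truth=truth)


def make_planted_seasonal_table(
    n_seasonal: int = 30,
    n_aperiodic: int = 70,
    n_months: int = 41,
    baseline: float = 200.0,
    rel_amplitude: float = 0.75,
    seed: int = 0,
    start_date: str = "2013-04-15",
) -> tuple[CountTable, SampleTable, pd.Series]:
    """Count table with known seasonal structure for power/size checks.

    Seasonal ASVs follow a 12-month sinusoidal expected abundance with a
    random phase (Poisson counts around it; at the default baseline the
    sinusoid's amplitude is many Poisson standard deviations, i.e. a
    signal-to-noise ratio well above 2); aperiodic ASVs are Poisson
    around a constant. Returns (table, metadata, truth) with truth a
    boolean per-ASV "seasonal" series.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_months, dtype=float)
    cols, data, truth = [], [], {}
    for i in range(n_seasonal):
        phase = rng.uniform(0, 12)
        lam = baseline * (1 + rel_amplitude * np.sin(2 * np.pi * (t + phase) / 12.0))
        data.append(rng.poisson(np.clip(lam, 1e-9, None)))
        name = f"seasonal{i + 1:03d}"
        cols.append(name)
        truth[name] = True
    for i in range(n_aperiodic):
        lam = baseline * rng.uniform(0.5, 1.5)
        data.append(rng.poisson(np.full(n_months, lam)))
        name = f"aperiodic{i + 1:03d}"
        cols.append(name)
        truth[name] = False
    table = CountTable(
        pd.DataFrame(
            np.column_stack(data),
            index=[f"s{j + 1:02d}" for j in range(n_months)],
            columns=cols,
        )
    )
    dates = pd.date_range(start=start_date, periods=n_months, freq="MS") + pd.Timedelta(days=14)
    meta = SampleTable(
        pd.DataFrame(
            {
                "date": dates.strftime("%Y-%m-%d"),
                "site": "planted",
                "size_fraction": "small",
            },
            index=table.sample_ids,
        )
    )
    return table, meta, pd.Series(truth, name="seasonal")


def make_static_network(
    nodes,
    edge_density: float,
    positive_fraction: float,
    seed: int,
    node_attrs: pd.DataFrame | None = None,
) -> AssociationNetwork:
    """Erdős–Rényi-style random signed network over the supplied nodes —
    a structural fixture for the subnetwork machinery, not an inferred
    association network."""
    if not 0.0 < edge_density <= 1.0:
        raise ValueError("edge_density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    nodes = list(nodes)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if rng.random() < edge_density:
                sign = 1 if rng.random() < positive_fraction else -1
                g.add_edge(
                    u,
                    v,
                    sign=sign,
                    weight=sign * round(rng.uniform(0.1, 1.0), 6),
                    cooccurrence_score=1.0,
                )
    if node_attrs is not None:
        for n in g.nodes():
            if n in node_attrs.index:
                g.nodes[n].update(node_attrs.loc[n].to_dict())
    return AssociationNetwork(g)
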