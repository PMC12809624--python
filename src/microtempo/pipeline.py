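"""Stage orchestration: run each analysis stage with a shared flat
config, write tidy TSV outputs plus a provenance manifest, and provide a
one-command synthetic end-to-end demonstration contrasting a
temperate-like and a tropical-like observatory."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import CountTable, SampleTable, ValidationError
from . import assembly as asm
from . import categories as cat
from . import diversity as dv
from . import networks as nw
from . import seasonality as sn
from .io import (
    align_inputs,
    read_count_table,
    read_network,
    read_sample_table,
    read_tree,
    write_count_table,
    write_network,
    write_sample_table,
    write_tree,
)
from .synthetic import ScenarioConfig, make_scenario

logger = logging.getLogger("microtempo")

STAGES = (
    "simulate",
    "diversity",
    "assembly",
    "seasonality",
    "categories",
    "networks",
    "demo",
)

__all__ = ["RunConfig", "run_stage", "run_demo", "STAGES"]


@dataclass
class RunConfig:
    """Flat run configuration; defaults are the study thresholds."""

    # inputs (stage-dependent; unused keys ignored by each stage)
    count_table: str | None = None
    sample_table: str | None = None
    tree: str | None = None
    network: str | None = None
    orientation: str = "auto"

    # stage parameters
    rarefaction_depth: int | None = None
    n_null: int = 999
    n_perm: int = 999
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    pn_min: float = 0.2
    p_max: float = 0.01
    period_window: tuple[float, float] = (10.0, 14.0)
    occupancy_min: float = 0.10
    occurrence_min: float = 0.5
    indval_stat_min: float = 0.7
    indval_p_max: float = 0.01
    cooccurrence_min: float = 0.5
    corr_cutoff: float = 0.7
    permanova_terms: tuple[str, ...] = ("site",)

    # scenario (simulate/demo)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    two_fractions: bool = False

    seed: int = 0
    outdir: str = "microtempo_out"
    fidelity: str = "paper"  # "paper" (999 nulls) | "demo" (199)

    def __post_init__(self) -> None:
        if self.fidelity not in ("paper", "demo"):
            raise ValidationError("fidelity must be 'paper' or 'demo'")
        if self.fidelity == "demo":
            self.n_null = min(self.n_null, 199)
            self.n_perm = min(self.n_perm, 199)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scen = raw.pop("scenario", {})
        unknown = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if scen:
            cfg.scenario = ScenarioConfig(**scen)
        return cfg

    def digest(self) -> str:
        # hash only analysis-relevant parameters, not file locations
        d = asdict(self)
        for key in ("count_table", "sample_table", "tree", "network", "outdir"):
            d.pop(key, None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, config: RunConfig, outputs: dict) -> None:
    manifest = {
        "stage": stage,
        "config_hash": config.digest(),
        "seed": config.seed,
        "microtempo_version": __version__,
        "outputs": {k: {"path": Path(v[0]).name, "rows": v[1]} for k, v in outputs.items()},
    }
    (outdir / f"{stage}_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _tsv(df: pd.DataFrame, path: Path, index: bool = False, label=None) -> tuple:
    df.to_csv(path, sep="\t", index=index, index_label=label, float_format="%.10g")
    return path, len(df)


def _load_inputs(config: RunConfig, need_tree: bool = False):
    if config.count_table is None or config.sample_table is None:
        raise ValidationError("count_table and sample_table inputs required")
    meta = read_sample_table(config.sample_table)
    table = read_count_table(
        config.count_table,
        orientation=config.orientation,
        sample_ids=meta.sample_ids,
    )
    tree = read_tree(config.tree) if config.tree else None
    if need_tree and tree is None:
        raise ValidationError("this stage requires a tree input")
    return align_inputs(table, meta, tree)


def _maybe_rarefy(table: CountTable, config: RunConfig) -> CountTable:
    if config.rarefaction_depth:
        return dv.rarefy(
            table, config.rarefaction_depth, seed=config.seed, drop_shallow=True
        )
    return table


def _groups(meta: SampleTable, ids) -> pd.Series:
    cols = [c for c in ("site", "size_fraction") if c in meta.data.columns]
    if not cols:
        return pd.Series("all", index=ids)
    return meta.data.loc[ids, cols].astype(str).agg("|".join, axis=1)


# --------------------------------------------------------------------------
# stages


def _stage_simulate(config: RunConfig, outdir: Path) -> dict:
    scen = replace(config.scenario, seed=config.seed)
    bundle = make_scenario(scen, two_fractions=config.two_fractions)
    outputs = {}
    outputs["counts"] = _tsv(
        bundle.table.data, outdir / "counts.tsv", index=True, label="sample_id"
    )
    write_sample_table(bundle.meta, outdir / "samples.tsv")
    outputs["samples"] = (outdir / "samples.tsv", len(bundle.meta.data))
    write_tree(bundle.tree, outdir / "tree.nwk")
    outputs["tree"] = (outdir / "tree.nwk", len(bundle.tree.tip_names))
    outputs["traits"] = _tsv(
        bundle.traits.rename_axis("asv_id").reset_index(), outdir / "traits.tsv"
    )
    (outdir / "truth.json").write_text(
        json.dumps(bundle.truth, indent=2, sort_keys=True) + "\n"
    )
    outputs["truth"] = (outdir / "truth.json", len(bundle.truth))
    return outputs


def _stage_diversity(config: RunConfig, outdir: Path) -> dict:
    bundle = _load_inputs(config)
    table = _maybe_rarefy(bundle.table, config)
    outputs = {}
    alpha = dv.alpha_diversity(
        bundle.phylo_table if bundle.tree else table,
        tree=bundle.tree,
    )
    outputs["alpha"] = _tsv(alpha, outdir / "alpha.tsv", index=True, label="sample_id")
    outputs["rank_abundance"] = _tsv(
        dv.rank_abundance(table), outdir / "rank_abundance.tsv"
    )
    bc = dv.bray_curtis(table)
    outputs["bray_curtis"] = _tsv(
        bc.to_frame(), outdir / "bray_curtis.tsv", index=True, label="sample_id"
    )
    terms = [t for t in config.permanova_terms if t in bundle.meta.data.columns]
    if terms:
        res = dv.permanova(
            bc, bundle.meta, terms, n_perm=config.n_perm, seed=config.seed
        )
        outputs["permanova"] = _tsv(res.table, outdir / "permanova.tsv")
    outputs["time_decay"] = _tsv(
        dv.time_decay(bc, bundle.meta), outdir / "time_decay.tsv"
    )
    return outputs


def _stage_assembly(config: RunConfig, outdir: Path) -> dict:
    bundle = _load_inputs(config, need_tree=True)
    table = _maybe_rarefy(bundle.phylo_table, config)
    res = asm.assembly_analysis(
        table,
        bundle.tree,
        meta=bundle.meta,
        n_null=config.n_null,
        seed=config.seed,
    )
    # attach time lags to pairs
    months = bundle.meta.months_since_start()
    res.pairs["delta_months"] = (
        months.loc[res.pairs["sample_k"]].to_numpy()
        - months.loc[res.pairs["sample_j"]].to_numpy()
    ).__abs__()
    outputs = {}
    outputs["pairs"] = _tsv(res.pairs, outdir / "assembly_pairs.tsv")
    outputs["fractions"] = _tsv(res.fractions, outdir / "process_fractions.tsv")
    return outputs


def _stage_seasonality(config: RunConfig, outdir: Path) -> dict:
    bundle = _load_inputs(config)
    table = _maybe_rarefy(bundle.table, config)
    groups = _groups(bundle.meta, table.sample_ids)
    frames = []
    rng = np.random.default_rng(config.seed)
    for g in sorted(groups.unique()):
        sub = table.select_samples(groups.index[groups == g])
        rec = sn.seasonal_analysis(
            sub,
            bundle.meta,
            min_frac=config.occupancy_min,
            n_perm=config.n_perm,
            seed=int(rng.integers(2**31)),
            pn_min=config.pn_min,
            p_max=config.p_max,
            period_window=config.period_window,
        )
        rec.insert(0, "group", g)
        frames.append(rec)
    out = pd.concat(frames, ignore_index=True)
    return {"seasonality": _tsv(out, outdir / "seasonality.tsv")}


def _stage_categories(config: RunConfig, outdir: Path) -> dict:
    bundle = _load_inputs(config)
    table = _maybe_rarefy(bundle.table, config)
    if "site" not in bundle.meta.data.columns:
        raise ValidationError("categories stage needs a 'site' metadata column")
    sites = sorted(bundle.meta.data["site"].unique())
    if len(sites) != 2:
        raise ValidationError("categories stage expects exactly two sites")
    ids = bundle.meta.data.index
    ta = table.select_samples(ids[bundle.meta.data["site"] == sites[0]])
    tb = table.select_samples(ids[bundle.meta.data["site"] == sites[1]])
    shared = cat.shared_unique(ta, tb)
    common = cat.common_asvs(
        shared,
        cat.occupancy(ta),
        cat.occupancy(tb),
        min_occ=config.occurrence_min,
    )
    detected = table.select_asvs(shared.index)
    iv = cat.indval(
        detected,
        bundle.meta.data["site"],
        n_perm=config.n_perm,
        seed=config.seed,
    )
    result = cat.assign_categories(
        shared,
        common,
        iv,
        site_a=sites[0],
        site_b=sites[1],
        stat_min=config.indval_stat_min,
        p_max=config.indval_p_max,
    )
    venn = shared["membership"].value_counts().rename_axis("membership").reset_index(name="n")
    outputs = {}
    outputs["categories"] = _tsv(
        result, outdir / "categories.tsv", index=True, label="asv_id"
    )
    outputs["venn"] = _tsv(venn, outdir / "venn_counts.tsv")
    return outputs


def _stage_networks(config: RunConfig, outdir: Path) -> dict:
    bundle = _load_inputs(config)
    table = bundle.table  # networks use unrarefied counts (CLR inside)
    if config.network:
        net = read_network(config.network)
    else:
        clr = nw.clr_transform(table)
        net = nw.correlation_network(clr, min_abs_r=config.corr_cutoff)
        logger.info(
            "no static network supplied; baseline CLR-correlation network "
            "with %d nodes / %d edges",
            net.n_nodes,
            net.n_edges,
        )
    net = nw.cooccurrence_filter(
        net, table.data, min_score=config.cooccurrence_min
    )
    series = nw.monthly_subnetworks(net, table, bundle.meta)
    env_cols = bundle.meta.env_columns()
    env = (
        bundle.meta.data.assign(
            month=pd.to_datetime(bundle.meta.data["date"]).dt.strftime("%Y-%m")
        )
        .groupby("month")[env_cols]
        .mean()
    )
    corr = nw.metric_env_correlations(series.metrics, env)
    outputs = {}
    write_network(net, outdir / "static_network.tsv")
    outputs["static_network"] = (outdir / "static_network.tsv", net.n_edges)
    outputs["subnetwork_metrics"] = _tsv(
        series.metrics.reset_index(), outdir / "subnetwork_metrics.tsv"
    )
    outputs["metric_env_correlations"] = _tsv(
        corr, outdir / "metric_env_correlations.tsv"
    )
    return outputs


def run_stage(stage: str, config: RunConfig) -> Path:
    """Run one stage; returns the output directory. Outputs are tidy TSV
    plus a JSON manifest recording config hash, seed and row counts."""
    if stage not in STAGES:
        raise ValidationError(
            f"unknown stage {stage!r}; valid stages: {', '.join(STAGES)}"
        )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "demo":
        return run_demo(config)
    fn = {
        "simulate": _stage_simulate,
        "diversity": _stage_diversity,
        "assembly": _stage_assembly,
        "seasonality": _stage_seasonality,
        "categories": _stage_categories,
        "networks": _stage_networks,
    }[stage]
    outputs = fn(config, outdir)
    _write_manifest(outdir, stage, config, outputs)
    return outdir


DEMO_SCENARIO = ScenarioConfig(n_taxa=100, pop_size=1000, seed=0)


def run_demo(config: RunConfig | None = None, seed: int | None = None) -> Path:
    """End-to-end synthetic demonstration.

    Simulates the two-observatory scenario, then runs every analysis
    stage on the files the simulation wrote, and summarises the
    temperate-vs-tropical contrast (process fractions, seasonal ASV
    counts, category counts, network-environment correlations) in
    ``summary.json``.
    """
    if config is None:
        config = RunConfig(fidelity="demo", scenario=DEMO_SCENARIO)
    if seed is not None:
        config = replace(config, seed=seed)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim = replace(config, outdir=str(outdir / "simulate"))
    Path(sim.outdir).mkdir(exist_ok=True)
    _stage_simulate(sim, Path(sim.outdir))
    _write_manifest(Path(sim.outdir), "simulate", sim, {})

    shared = replace(
        config,
        count_table=str(outdir / "simulate" / "counts.tsv"),
        sample_table=str(outdir / "simulate" / "samples.tsv"),
        tree=str(outdir / "simulate" / "tree.nwk"),
    )
    summary: dict = {"seed": config.seed, "fidelity": config.fidelity}
    for stage in ("diversity", "assembly", "seasonality", "categories", "networks"):
        stage_cfg = replace(shared, outdir=str(outdir / stage))
        run_stage(stage, stage_cfg)

    fractions = pd.read_csv(outdir / "assembly" / "process_fractions.tsv", sep="\t")
    summary["process_fractions"] = {
        row["group"]: {p: row[p] for p in asm.PROCESSES}
        for _, row in fractions.iterrows()
    }
    seas = pd.read_csv(outdir / "seasonality" / "seasonality.tsv", sep="\t")
    summary["seasonal_asvs"] = {
        g: int(sub["seasonal"].sum()) for g, sub in seas.groupby("group")
    }
    cats = pd.read_csv(outdir / "categories" / "categories.tsv", sep="\t")
    summary["category_counts"] = (
        cats["category"].value_counts().sort_index().to_dict()
    )
    corr = pd.read_csv(
        outdir / "networks" / "metric_env_correlations.tsv", sep="\t"
    )
    sig = corr[corr["p_holm"] < 0.05]
    summary["significant_metric_env_correlations"] = [
        {"metric": r["metric"], "variable": r["variable"], "rho": r["rho"]}
        for _, r in sig.iterrows()
    ]
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    return outdir


def configure_logging(verbose: bool = False, logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
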