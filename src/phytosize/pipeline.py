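"""End-to-end orchestration: metrics -> trends -> partition -> turnover -> drivers.

``run_pipeline`` takes a configuration (dict or YAML path), either loading
observation/environment tables or realizing a synthetic scenario, and
writes a versioned CSV bundle (species_trends, community_trends,
small_fraction_trends, partition, anosim, correlations, clusters,
partial_effects, shapley) plus a JSON run log with seeds and a config
hash.  Re-running the same configuration reproduces the bundle
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as community_mod
from . import data as data_mod
from . import drivers as drivers_mod
from . import shapley as shapley_mod
from . import simulate as sim_mod
from . import size_metrics as sm
from . import trends as trends_mod
from .partition import partition_community_change, scenario_classify

log = logging.getLogger(__name__)

DEFAULT_FACTORS = ["temperature", "PO4", "DIN", "salinity", "chla"]

DEFAULT_CONFIG = {
    "scenario": {},            # ScenarioConfig overrides; ignored if paths given
    "observations": None,      # path to observation CSV
    "environment": None,       # path to environment CSV
    "seed": 0,
    "alpha": 0.05,
    "period": 12,
    "window_months": 36,       # width of the first/last partition windows
    "n_perm": 199,
    "anosim_max_samples": 120,
    "factors": DEFAULT_FACTORS,
    "top_counts": None,        # e.g. {"diatom": 10, ...}; None = adaptive
    "shapley_background": 100,
    "shapley_explain": 100,
    "outdir": "results/pipeline",
}


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def _adaptive_top_counts(obs: pd.DataFrame) -> dict:
    sizes = obs.groupby("group", observed=True)["species_id"].nunique()
    want = sm.DEFAULT_TOP_COUNTS
    return {g: min(k, int(sizes.get(g, 0))) for g, k in want.items() if sizes.get(g, 0) > 0}


def run_pipeline(config=None) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of the output tables (plus 'scenario' and 'log').
    """
    cfg = _load_config(config)
    seed = int(cfg["seed"])
    alpha = float(cfg["alpha"])
    period = int(cfg["period"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    # ---------------------------------------------------------------- load
    if cfg["observations"]:
        obs, obs_rej = data_mod.read_observations(cfg["observations"])
        env, env_rej = data_mod.read_environment(cfg["environment"])
    else:
        scen = sim_mod.ScenarioConfig(**{**cfg["scenario"], "seed": seed})
        ds = sim_mod.generate_dataset(scen, seed)
        obs, env = ds.observations, ds.environment
    origin = obs["date"].min()
    months = data_mod.lagged_month(obs["date"].max(), origin) + 1

    # ------------------------------------------------------------- metrics
    metrics = _stage("metrics")(_metrics)(obs, cfg)
    small_set, comm, smallfrac, top = metrics

    # -------------------------------------------------------------- trends
    tables = _stage("trends")(_trends)(obs, comm, smallfrac, top, alpha, period, origin)
    species_trends, community_trends, small_trends = tables

    # ----------------------------------------------------------- partition
    w = min(int(cfg["window_months"]), months // 2)
    windows = ((0, w), (months - w, months))
    part_rows = []
    scopes = [("region", None)] + [("station", s) for s in sorted(obs["station_id"].unique())]
    for scope, sid in scopes:
        pr = _stage("partition")(partition_community_change)(obs, *windows, scope=scope, scope_id=sid, origin=origin)
        part_rows.append(
            {
                "scope": scope, "scope_id": pr.scope_id,
                "window0": f"{windows[0][0]}-{windows[0][1]}",
                "window1": f"{windows[1][0]}-{windows[1][1]}",
                "c0": pr.c0, "c1": pr.c1, "delta_c": pr.delta_c,
                "within_species": pr.within_species, "composition": pr.composition,
                "residual": pr.residual,
            }
        )
    partition_df = pd.DataFrame(part_rows)

    # -------------------------------------------------------------- anosim
    anosim_df = _stage("anosim")(community_mod.anosim_by_factors)(
        obs, n_perm=int(cfg["n_perm"]), seed=seed, max_samples=cfg["anosim_max_samples"]
    )

    # ------------------------------------------------------------- drivers
    driver_tables = _stage("drivers")(_drivers)(obs, env, top, cfg, seed, alpha)
    correlations, clusters, partial_effects, shapley_df = driver_tables

    # ------------------------------------------------------------ scenario
    scen_rows = []
    region_species_classes = species_trends.query("method == 'lm'")["class"].tolist()
    for station in sorted(obs["station_id"].unique()):
        sp_cls = _station_species_classes(obs, station, alpha, origin)
        small_cls = _one_class(small_trends, "station", station)
        comm_cls = _one_class(community_trends, "station", station)
        res = scenario_classify(sp_cls, small_cls, comm_cls, scope=f"station:{station}")
        scen_rows.append(
            {
                "scope": res.scope, "species_summary": res.species_summary,
                "small_class": res.small_class, "community_class": res.community_class,
                "scenario": res.scenario,
            }
        )
    region = scenario_classify(
        region_species_classes,
        _one_class(small_trends, "region", "all"),
        _one_class(community_trends, "region", "all"),
        scope="region",
    )
    scen_rows.append(
        {
            "scope": "region", "species_summary": region.species_summary,
            "small_class": region.small_class, "community_class": region.community_class,
            "scenario": region.scenario,
        }
    )
    scenario_df = pd.DataFrame(scen_rows)

    # --------------------------------------------------------------- write
    outputs = {
        "species_trends": species_trends,
        "community_trends": community_trends,
        "small_fraction_trends": small_trends,
        "partition": partition_df,
        "anosim": anosim_df,
        "correlations": correlations.reset_index().rename(columns={"index": "species_id"}),
        "clusters": clusters,
        "partial_effects": partial_effects,
        "shapley": shapley_df,
        "scenario": scenario_df,
    }
    for name, df in outputs.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    run_log = {
        "config": {k: v for k, v in cfg.items()},
        "config_hash": _config_hash(cfg),
        "seed": seed,
        "n_observations": int(len(obs)),
        "n_species": int(obs["species_id"].nunique()),
        "n_stations": int(obs["station_id"].nunique()),
        "months": int(months),
        "small_threshold_um3": small_set.threshold,
        "windows": [list(windows[0]), list(windows[1])],
    }
    (outdir / "run_log.json").write_text(json.dumps(run_log, indent=2, default=str))
    outputs["log"] = run_log
    log.info("pipeline complete: %s", outdir)
    return outputs


def _one_class(trend_df: pd.DataFrame, scope: str, sid: str) -> str:
    sub = trend_df[(trend_df["scope"] == scope) & (trend_df["id"] == sid) & (trend_df["method"] == "lm")]
    return sub["class"].iloc[0] if len(sub) else "none"


def _metrics(obs, cfg):
    small_set = sm.classify_small_species(obs)
    comm = sm.community_size_table(obs)
    smallfrac = sm.small_fraction_table(obs, small_set)
    counts = cfg["top_counts"] or _adaptive_top_counts(obs)
    top = sm.select_top_species(obs, counts)
    return small_set, comm, smallfrac, top


def _trends(obs, comm, smallfrac, top, alpha, period, origin):
    sp_series, sp_ids = [], []
    for sp in top["species_id"]:
        sp_series.append(sm.species_size_series(obs, sp, scope="region", origin=origin))
        sp_ids.append(sp)
    species_trends = trends_mod.trend_table(sp_series, sp_ids, alpha=alpha, period=period)
    species_trends.insert(0, "scope", "region")

    def per_scope_trends(table, value_col):
        series, ids, scopes = [], [], []
        for st, g in table.groupby("station_id"):
            series.append((g["lagged_month"].to_numpy(float), g[value_col].to_numpy(float)))
            ids.append(st)
            scopes.append("station")
        regional = table.groupby("lagged_month")[value_col].mean().reset_index()
        series.append((regional["lagged_month"].to_numpy(float), regional[value_col].to_numpy(float)))
        ids.append("all")
        scopes.append("region")
        df = trends_mod.trend_table(series, ids, alpha=alpha, period=period)
        scope_map = dict(zip(ids, scopes))
        df.insert(0, "scope", df["id"].map(scope_map))
        return df

    community_trends = per_scope_trends(comm, "community_mean_size")
    small_trends = per_scope_trends(smallfrac, "small_fraction")
    return species_trends, community_trends, small_trends


def _station_species_classes(obs, station, alpha, origin):
    classes = []
    sub = obs[obs["station_id"] == station]
    for sp in sub["species_id"].unique():
        try:
            series = sm.species_size_series(sub, sp, scope="station", scope_id=station, origin=origin)
            if len(series.data) < 3:
                continue
            classes.append(trends_mod.classify_trend(trends_mod.linear_trend(series), alpha))
        except ValueError:
            continue
    return classes or ["none"]


def _drivers(obs, env, top, cfg, seed, alpha):
    factors = list(cfg["factors"])
    factors = [f for f in factors if f in env.columns]
    corr, _ = drivers_mod.species_env_correlations(obs, env, top["species_id"], factors)
    clusters = drivers_mod.cluster_response_groups(corr, k=min(4, len(corr)))

    table = drivers_mod.species_table(obs, env)
    tsr = drivers_mod.tsr_test(
        table, top["species_id"], covariates=[f for f in ("PO4", "DIN") if f in factors],
        alpha=alpha,
    )
    tsr.insert(0, "response", "log_biovolume")
    tsr.insert(1, "focal", "temperature")

    small_set = sm.classify_small_species(obs)
    smallfrac = sm.small_fraction_table(obs, small_set)
    joined = smallfrac.merge(env, on=["station_id", "date"], how="inner").dropna(subset=factors)
    pe_rows = []
    for focal in ("temperature", "PO4"):
        covs = [f for f in factors if f != focal]
        res = drivers_mod.partial_effect(joined, "small_fraction", focal, covs, group_var="station_id")
        pe_rows.append(
            {
                "response": "small_fraction", "focal": focal, "species_id": "",
                "coefficient": res.coefficient, "se": res.se, "p": res.p, "n": res.n,
                "class": "",
            }
        )
    partial_effects = pd.concat([tsr.rename(columns={})], ignore_index=True)
    partial_effects = pd.concat([partial_effects, pd.DataFrame(pe_rows)], ignore_index=True)

    # Shapley attribution of the seasonally adjusted Small% via a bagged-tree fit
    from sklearn.ensemble import RandomForestRegressor

    from . import trends as trends_mod

    adj = trends_mod.seasonally_adjust_table(joined, "small_fraction")
    x = adj[factors].to_numpy(float)
    y = adj["small_fraction_adj"].to_numpy(float)
    model = RandomForestRegressor(n_estimators=100, min_samples_leaf=2, random_state=seed, n_jobs=1)
    model.fit(x, y)
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(x), size=min(int(cfg["shapley_background"]), len(x)), replace=False)
    ex_idx = rng.choice(len(x), size=min(int(cfg["shapley_explain"]), len(x)), replace=False)
    phi = shapley_mod.shapley_values(
        model.predict, x[ex_idx], x[bg_idx], mode="exact", feature_names=factors
    )
    long = phi.values.copy()
    long["sample"] = ex_idx
    shapley_df = long.melt(id_vars="sample", var_name="feature", value_name="shap_value")
    feat_vals = pd.DataFrame(x[ex_idx], columns=factors)
    feat_vals["sample"] = ex_idx
    fv = feat_vals.melt(id_vars="sample", var_name="feature", value_name="feature_value")
    shapley_df = shapley_df.merge(fv, on=["sample", "feature"])
    return corr, clusters, partial_effects, shapley_df
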