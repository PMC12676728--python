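"""Desk-scale validation suites: exactness, oracles, parameter recovery.

Each function runs the package end-to-end on synthetic inputs with known
truth and returns measured quantities (identity residuals, oracle gaps,
recovery rates).  They are shared by the test suite and the acceptance
script, which assert on / report the same numbers.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import community as cm
from . import drivers as dr
from . import shapley as sh
from . import size_metrics as sm
from . import trends as tr
from .partition import partition_community_change
from .simulate import (
    ScenarioConfig,
    generate_dataset,
    generate_environment,
    generate_observations,
    generate_species_pool,
)

FACTORS = ["temperature", "PO4", "DIN", "salinity", "chla"]


def null_tsr_config(seed: int) -> ScenarioConfig:
    """Reduced null scenario for TSR calibration: no temperature-size
    effect, no intrinsic trend, no composition drift, so temperature
    rejections are pure type-I errors."""
    return ScenarioConfig(
        n_stations=2, months=48, n_diatom=3, n_dinoflagellate=2, n_other=1,
        beta_mean=0.0, beta_sd=0.0, gamma_mean=0.0, gamma_sd=0.0,
        delta=0.0, po4_small_coupling=0.0, bloom_prob=0.0, seed=seed,
    )


def offset_config(seed: int) -> ScenarioConfig:
    """Offset scenario: universal species miniaturization (all beta < 0,
    all gamma < 0) with composition drift toward large species
    (delta < 0), the configuration where community mean size need not
    decline despite every species shrinking."""
    return ScenarioConfig(
        beta_mean=-0.02, beta_sd=0.005, gamma_mean=-8e-4, gamma_sd=1e-4,
        delta=-0.002, seed=seed,
    )


# ------------------------------------------------------------------ criterion 1

def partition_identity_suite(n_instances: int = 1000, seed: int = 0) -> dict:
    """Random two-window instances; the mid-point partition must satisfy
    within + composition = Delta C to < 1e-9 relative, and match a
    brute-force recomputation from the definitions."""
    rng = np.random.default_rng(seed)
    max_rel = 0.0
    max_oracle_gap = 0.0
    for _ in range(n_instances):
        n_sp = rng.integers(4, 12)
        rows = []
        for w, months in ((0, (0, 6)), (1, (6, 12))):
            for t in range(*months):
                present = rng.random(n_sp) > 0.2
                for i in np.nonzero(present)[0]:
                    rows.append(
                        {
                            "station_id": "S1", "wcz": "Z1",
                            "date": pd.Period("2000-01") + t,
                            "species_id": f"sp{i}", "group": "diatom",
                            "abundance": rng.lognormal(3, 1),
                            "cell_biovolume": rng.lognormal(5, 2),
                        }
                    )
        obs = pd.DataFrame(rows)
        res = partition_community_change(obs, (0, 6), (6, 12))
        scale = max(abs(res.delta_c), 1e-12)
        max_rel = max(max_rel, abs(res.residual) / scale)
        # independent recomputation from the definitions
        within_o, comp_o, delta_o = _partition_oracle(obs)
        gap = max(
            abs(res.within_species - within_o), abs(res.composition - comp_o),
            abs(res.delta_c - delta_o),
        ) / max(abs(delta_o), 1.0)
        max_oracle_gap = max(max_oracle_gap, gap)
    return {"max_rel_residual": max_rel, "max_oracle_gap": max_oracle_gap}


def _partition_oracle(obs: pd.DataFrame):
    """Slow, index-free recomputation of the two-window decomposition."""
    from .data import add_lagged_month

    df = add_lagged_month(obs)
    species = sorted(df["species_id"].unique())
    stats = {}
    for w, (a, b) in enumerate(((0, 6), (6, 12))):
        sub = df[(df["lagged_month"] >= a) & (df["lagged_month"] < b)]
        total = sub["abundance"].sum()
        p, v = {}, {}
        for s in species:
            rows = sub[sub["species_id"] == s]
            cells = rows["abundance"].sum()
            p[s] = cells / total
            v[s] = (
                (rows["abundance"] * rows["cell_biovolume"]).sum() / cells
                if cells > 0 else None
            )
        stats[w] = (p, v)
    p0, v0 = stats[0]
    p1, v1 = stats[1]
    within = comp = 0.0
    for s in species:
        va = v0[s] if v0[s] is not None else v1[s]
        vb = v1[s] if v1[s] is not None else v0[s]
        within += (p0[s] + p1[s]) / 2 * (vb - va)
        comp += (va + vb) / 2 * (p1[s] - p0[s])
    c0 = sum(p0[s] * (v0[s] if v0[s] is not None else v1[s]) for s in species)
    c1 = sum(p1[s] * (v1[s] if v1[s] is not None else v0[s]) for s in species)
    return within, comp, c1 - c0


def shapley_axiom_suite(seed: int = 0) -> dict:
    """Efficiency, dummy and symmetry axioms in exact mode."""
    rng = np.random.default_rng(seed)
    p = 6
    beta = rng.normal(size=p)
    beta[3] = 0.0  # dummy feature

    def f(x):
        x = np.asarray(x)
        return x @ beta + 0.5 * x[:, 0] * x[:, 1]

    x = rng.normal(size=(15, p))
    bg = rng.normal(size=(25, p))
    res = sh.shapley_values(f, x, bg, mode="exact")
    efficiency = float(np.abs(res.efficiency_residual).max())
    dummy = float(np.abs(res.values.iloc[:, 3]).max())

    # exchangeable features on symmetric inputs get equal attributions
    def g(x):
        x = np.asarray(x)
        return x[:, 0] + x[:, 1] + 0.3 * x[:, 0] * x[:, 1]

    xs = rng.normal(size=(10, 1))
    x_sym = np.hstack([xs, xs])           # x0 == x1 per sample
    bg_sym = np.zeros((1, 2))
    res_sym = sh.shapley_values(g, x_sym, bg_sym, mode="exact")
    symmetry = float(np.abs(res_sym.values.iloc[:, 0] - res_sym.values.iloc[:, 1]).max())
    return {"efficiency": efficiency, "dummy": dummy, "symmetry": symmetry}


def stl_reconstruction_error(seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    t = np.arange(96)
    y = 0.2 * t + 2 * np.cos(2 * np.pi * t / 12) + rng.normal(0, 0.5, len(t))
    d = tr.stl_decompose((t, y))
    return float(np.abs(d.trend + d.seasonal + d.residual - d.observed).max())


def bh_exhaustive_gap(max_m: int = 10, n_vectors: int = 200, seed: int = 0) -> float:
    """Max disagreement between {q <= alpha} and the textbook step-up
    rejection set over random p-vectors of every length up to max_m."""
    rng = np.random.default_rng(seed)
    worst = 0
    for m in range(1, max_m + 1):
        for _ in range(n_vectors):
            p = rng.random(m)
            alpha = rng.random()
            q = tr.bh_adjust(p)
            rejected = set(np.nonzero(q <= alpha)[0])
            # textbook step-up: largest k with p_(k) <= k*alpha/m; reject smallest k
            order = np.argsort(p, kind="mergesort")
            ks = [k for k in range(1, m + 1) if p[order[k - 1]] <= k * alpha / m]
            textbook = set(order[: max(ks)] if ks else [])
            worst = max(worst, len(rejected ^ textbook))
    return float(worst)


# ------------------------------------------------------------------ criterion 2

def ols_oracle_gap(n_series: int = 100, seed: int = 0) -> dict:
    """linear_trend vs. brute-force normal equations + t-test on random series."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    max_slope = max_p = 0.0
    for _ in range(n_series):
        n = rng.integers(10, 80)
        t = np.sort(rng.choice(300, size=n, replace=False)).astype(float)
        y = rng.normal(0, 1, n) + rng.normal(0, 0.01) * t
        res = tr.linear_trend(t, y)
        x = np.column_stack([t, np.ones(n)])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(x.T @ x)[0, 0])
        p = 2 * stats.t.sf(abs(beta[0] / se), n - 2)
        max_slope = max(max_slope, abs(res.slope_per_month - beta[0]))
        max_p = max(max_p, abs(res.p - p))
    return {"max_slope_gap": max_slope, "max_p_gap": max_p}


def partial_effect_oracle_gap(n_designs: int = 50, seed: int = 0) -> float:
    """partial_effect coefficient vs. normal equations on random full-rank designs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_designs):
        n = int(rng.integers(40, 120))
        k = int(rng.integers(2, 5))
        x = rng.normal(size=(n, k))
        groups = rng.integers(0, 3, n)
        beta = rng.normal(size=k)
        y = x @ beta + np.take(rng.normal(size=3), groups) + rng.normal(0, 0.5, n)
        df = pd.DataFrame(x, columns=[f"c{j}" for j in range(k)])
        df["y"] = y
        df["g"] = groups.astype(str)
        res = dr.partial_effect(df, "y", "c0", [f"c{j}" for j in range(1, k)], "g")
        dummies = pd.get_dummies(df["g"], dtype=float).to_numpy()
        design = np.hstack([x, dummies])
        bhat = np.linalg.solve(design.T @ design, design.T @ y)
        worst = max(worst, abs(res.coefficient - bhat[0]))
    return float(worst)


def anosim_enumeration_gap(seed: int = 0, n_perm: int = 20000) -> float:
    """Sampled permutation p vs. exact enumeration on all <=6-sample cases
    (two and three groups); the gap is bounded by Monte-Carlo error."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    cases = [
        np.array(["a", "a", "b", "b"]),
        np.array(["a", "a", "a", "b", "b"]),
        np.array(["a", "a", "b", "b", "c", "c"]),
        np.array(["a", "a", "a", "b", "b", "b"]),
    ]
    for groups in cases:
        n = len(groups)
        x = rng.lognormal(1, 1, size=(n, 8))
        d = cm.bray_curtis(x)
        exact = cm.anosim(d, groups, method="exact")
        sampled = cm.anosim(d, groups, n_perm=n_perm, seed=seed)
        worst = max(worst, abs(sampled.p - exact.p))
    return float(worst)


def mc_shapley_rel_rms(seed: int = 0, n_samples: int = 4096) -> float:
    """Monte-Carlo Shapley error relative to exact enumeration at p=5."""
    rng = np.random.default_rng(seed)

    def f(x):
        x = np.asarray(x)
        return (
            x[:, 0] + 0.8 * x[:, 1] ** 2 + 0.6 * x[:, 2] * x[:, 3]
            + 0.4 * np.sin(x[:, 4]) + 0.3 * x[:, 0] * x[:, 2]
        )

    x = rng.normal(size=(20, 5))
    bg = rng.normal(size=(30, 5))
    exact = sh.shapley_values(f, x, bg, mode="exact").values.to_numpy()
    mc = sh.shapley_values(f, x, bg, mode="montecarlo", n_samples=n_samples, seed=seed + 1)
    err = mc.values.to_numpy() - exact
    return float(np.sqrt((err ** 2).mean()) / np.sqrt((exact ** 2).mean()))


# ------------------------------------------------------------------ criterion 3

def slope_recovery_suite(n_seeds: int = 20, cfg: ScenarioConfig | None = None, base_seed: int = 0) -> dict:
    """Default scenario, n_seeds realizations: compare the median estimated
    species log-size slope (region scope) with the median injected slope,
    and check the Small% trend sign against sign(delta) at every station."""
    ratios = []
    sign_ok = 0
    sign_total = 0
    for i in range(n_seeds):
        seed = base_seed + i
        scen = replace(cfg or ScenarioConfig(), seed=seed)
        ds = generate_dataset(scen, seed)
        obs = ds.observations
        origin = obs["date"].min()
        truth = ds.truth.species.query("station_id == 'region'").set_index("species_id")["log_size_slope"]
        est = {}
        for sp in truth.index:
            s = sm.species_size_series(obs, sp, scope="region", origin=origin)
            est[sp] = tr.linear_trend(s.t, np.log(s.y)).slope_per_month
        est = pd.Series(est)
        ratios.append(est.median() / truth.median())
        small = sm.classify_small_species(obs)
        sf = sm.small_fraction_table(obs, small)
        for _, g in sf.groupby("station_id"):
            fit = tr.linear_trend(g["lagged_month"].to_numpy(float), g["small_fraction"].to_numpy(float))
            sign_ok += int(np.sign(fit.slope_per_month) == np.sign(scen.delta))
            sign_total += 1
    return {
        "median_slope_ratio": float(np.median(ratios)),
        "small_sign_match_rate": sign_ok / sign_total,
        "n_seeds": n_seeds,
    }


def tsr_type1_suite(n_seeds: int = 200, base_seed: int = 0) -> dict:
    """Rejection rate of the TSR test at injected beta = 0."""
    rejected = total = 0
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = null_tsr_config(seed)
        env = generate_environment(cfg, seed)
        pool = generate_species_pool(cfg, seed)
        obs = generate_observations(pool, env, cfg, seed, presence_threshold=0.0)
        table = dr.species_table(obs, env)
        res = dr.tsr_test(table, pool["species_id"])
        rejected += int((res["p"] < 0.05).sum())
        total += len(res)
    return {"type1_rate": rejected / total, "n_tests": total}


def driver_ranking_suite(n_seeds: int = 20, cfg: ScenarioConfig | None = None, base_seed: int = 0) -> dict:
    """End-to-end attribution: fit boosted trees to species size anomalies
    and bagged trees to Small%, then rank factors by mean |phi| (exact
    Shapley).  Temperature should rank first for size; PO4 in the top two
    for Small%."""
    from sklearn.ensemble import RandomForestRegressor
    from xgboost import XGBRegressor

    temp_first = po4_top2 = 0
    for i in range(n_seeds):
        seed = base_seed + i
        scen = replace(cfg or ScenarioConfig(), seed=seed)
        ds = generate_dataset(scen, seed)
        obs, env = ds.observations, ds.environment
        rng = np.random.default_rng(seed)

        tab = dr.species_table(obs, env)
        tab["anom"] = tab["log_biovolume"] - tab.groupby("species_id")["log_biovolume"].transform("mean")
        x = tab[FACTORS].to_numpy(float)
        y = tab["anom"].to_numpy(float)
        model = XGBRegressor(
            n_estimators=150, max_depth=4, learning_rate=0.1,
            random_state=seed, n_jobs=1, verbosity=0,
        )
        model.fit(x, y)
        bg = x[rng.choice(len(x), 50, replace=False)]
        ex = x[rng.choice(len(x), 80, replace=False)]
        imp = sh.global_importance(
            sh.shapley_values(model.predict, ex, bg, mode="exact", feature_names=FACTORS)
        )
        temp_first += int(imp.index[0] == "temperature")

        small = sm.classify_small_species(obs)
        sf = sm.small_fraction_table(obs, small)
        # attribute the seasonally adjusted Small% so co-cyclic factors
        # cannot claim purely seasonal variance
        sf = tr.seasonally_adjust_table(sf, "small_fraction")
        joined = sf.merge(env, on=["station_id", "date"])
        x2 = joined[FACTORS].to_numpy(float)
        y2 = joined["small_fraction_adj"].to_numpy(float)
        rf = RandomForestRegressor(n_estimators=100, min_samples_leaf=2, random_state=seed, n_jobs=1)
        rf.fit(x2, y2)
        bg2 = x2[rng.choice(len(x2), 50, replace=False)]
        ex2 = x2[rng.choice(len(x2), 80, replace=False)]
        imp2 = sh.global_importance(
            sh.shapley_values(rf.predict, ex2, bg2, mode="exact", feature_names=FACTORS)
        )
        po4_top2 += int("PO4" in imp2.index[:2])
    return {
        "temperature_top1_rate": temp_first / n_seeds,
        "po4_top2_rate": po4_top2 / n_seeds,
        "n_seeds": n_seeds,
    }


# ------------------------------------------------------------------ criterion 4

def offset_scenario_suite(n_seeds: int = 5, alpha: float = 0.05, base_seed: int = 0) -> dict:
    """Universal species miniaturization with drift toward large species:
    community trends should be non-significant at most stations and the
    region should classify as the uncertain/offset scenario (ii)."""
    from .partition import scenario_classify

    nonsig_fracs = []
    region_ii = 0
    for i in range(n_seeds):
        seed = base_seed + i
        cfg = offset_config(seed)
        ds = generate_dataset(cfg, seed)
        obs = ds.observations
        origin = obs["date"].min()
        comm = sm.community_size_table(obs, origin)
        comm_classes = {}
        for st, g in comm.groupby("station_id"):
            fit = tr.linear_trend(g["lagged_month"].to_numpy(float), g["community_mean_size"].to_numpy(float))
            comm_classes[st] = tr.classify_trend(fit, alpha)
        nonsig_fracs.append(np.mean([c == "none" for c in comm_classes.values()]))

        truth = ds.truth.species.query("station_id == 'region'").set_index("species_id")
        sp_classes = []
        for sp in truth.index:
            s = sm.species_size_series(obs, sp, scope="region", origin=origin)
            sp_classes.append(tr.classify_trend(tr.linear_trend(s), alpha))
        small = sm.classify_small_species(obs)
        sf = sm.small_fraction_table(obs, small)
        reg = sf.groupby("lagged_month")["small_fraction"].mean().reset_index()
        small_cls = tr.classify_trend(
            tr.linear_trend(reg["lagged_month"].to_numpy(float), reg["small_fraction"].to_numpy(float)), alpha
        )
        comm_reg = comm.groupby("lagged_month")["community_mean_size"].mean().reset_index()
        comm_cls = tr.classify_trend(
            tr.linear_trend(comm_reg["lagged_month"].to_numpy(float), comm_reg["community_mean_size"].to_numpy(float)),
            alpha,
        )
        res = scenario_classify(sp_classes, small_cls, comm_cls)
        region_ii += int(res.scenario == "ii")
    return {
        "mean_frac_stations_community_nonsig": float(np.mean(nonsig_fracs)),
        "region_scenario_ii_rate": region_ii / n_seeds,
        "n_seeds": n_seeds,
    }
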