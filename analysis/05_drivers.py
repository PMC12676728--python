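#!/usr/bin/env python
"""Environmental driver attribution for species size and Small%.

Pearson screening + response-group clustering of the top species, the
temperature-size-rule partial-effects test, a five-learner tournament on
held-out data, Shapley importance ranking for both responses, and the
temperature x phosphate interaction on Small%.
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from phytosize import data, drivers as dr, shapley as sh, size_metrics as sm, trends as tr  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"
FACTORS = ["temperature", "PO4", "DIN", "salinity", "chla"]
SEED = 0


def main():
    warnings.filterwarnings("ignore")
    obs = data.read_observations(DATA / "observations.csv").records
    env = data.read_environment(DATA / "environment.csv").records
    rng = np.random.default_rng(SEED)

    top = sm.select_top_species(obs, {"diatom": 10, "dinoflagellate": 10, "other": 5})
    corr, support = dr.species_env_correlations(obs, env, top["species_id"], FACTORS)
    corr.to_csv(OUT / "correlations.csv")
    clusters = dr.cluster_response_groups(corr)
    clusters.to_csv(OUT / "clusters.csv", index=False)
    print("response groups of the top 25 species (clustered on correlation profiles):")
    print(clusters.groupby("label")["species_id"].count().to_string())

    table = dr.species_table(obs, env)
    tsr = dr.tsr_test(table, top["species_id"])
    tsr.to_csv(OUT / "tsr_test.csv", index=False)
    n_follow = (tsr["class"] == "follows_tsr").sum()
    print(f"TSR partial-effects test: {n_follow}/{len(tsr)} species follow the temperature-size "
          f"rule; {(tsr['class'] == 'anti_tsr').sum()} significantly positive")
    print(f"  median temperature coefficient: {tsr['coefficient'].median():+.4f} per degC on log biovolume")

    # Small%: seasonally adjusted response, tournament, Shapley
    small = sm.classify_small_species(obs)
    sf = sm.small_fraction_table(obs, small)
    sf = tr.seasonally_adjust_table(sf, "small_fraction")
    joined = sf.merge(env, on=["station_id", "date"]).dropna(subset=FACTORS)
    x = joined[FACTORS].to_numpy(float)
    y = joined["small_fraction_adj"].to_numpy(float)
    tour = dr.model_tournament(x, y, dr.default_learners(seed=SEED), seed=SEED)
    tour.scores.to_csv(OUT / "tournament_smallpct.csv", index=False)
    print(f"learner tournament on Small% (held-out 20%): winner = {tour.winner}")
    print(tour.scores.round(3).to_string(index=False))

    from sklearn.ensemble import RandomForestRegressor

    model = RandomForestRegressor(n_estimators=100, min_samples_leaf=2, random_state=SEED, n_jobs=1)
    model.fit(x, y)
    bg = x[rng.choice(len(x), 100, replace=False)]
    ex = x[rng.choice(len(x), 100, replace=False)]
    phi = sh.shapley_values(model.predict, ex, bg, mode="exact", feature_names=FACTORS)
    imp = sh.global_importance(phi)
    imp.rename("mean_abs_shap").to_csv(OUT / "shap_importance_smallpct.csv")
    print("Small% driver ranking (mean |phi|):")
    print(imp.round(5).to_string())
    inter = sh.shapley_interaction(model.predict, ex, ("temperature", "PO4"), bg,
                                   feature_names=FACTORS)
    pd.DataFrame({"sample": np.arange(len(inter)), "interaction": inter}).to_csv(
        OUT / "shap_interaction_t_po4.csv", index=False
    )
    print(f"temperature x PO4 interaction on Small%: mean |value| = {inter.abs().mean():.2e}, "
          f"max |value| = {inter.abs().max():.2e}")

    # species size anomaly driver ranking (fit on the full joined table)
    table["anom"] = table["log_biovolume"] - table.groupby("species_id")["log_biovolume"].transform("mean")
    from xgboost import XGBRegressor

    xgb = XGBRegressor(n_estimators=150, max_depth=4, learning_rate=0.1, random_state=SEED,
                       n_jobs=1, verbosity=0)
    xs, ys = table[FACTORS].to_numpy(float), table["anom"].to_numpy(float)
    xgb.fit(xs, ys)
    bg2 = xs[rng.choice(len(xs), 100, replace=False)]
    ex2 = xs[rng.choice(len(xs), 100, replace=False)]
    imp2 = sh.global_importance(sh.shapley_values(xgb.predict, ex2, bg2, mode="exact", feature_names=FACTORS))
    imp2.rename("mean_abs_shap").to_csv(OUT / "shap_importance_size.csv")
    print("species size-anomaly driver ranking (mean |phi|):")
    print(imp2.round(5).to_string())


if __name__ == "__main__":
    main()
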