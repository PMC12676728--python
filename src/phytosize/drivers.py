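"""Environmental driver attribution.

Pearson screening of species size series against environmental factors,
hierarchical clustering into temperature/nutrient response groups, partial
effects via grouped-intercept least squares (the temperature-size rule
test holds all other measured factors constant), and a pluggable learner
tournament scored on a held-out split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .data import add_lagged_month


# ---------------------------------------------------------------- correlations

def species_env_correlations(
    obs: pd.DataFrame,
    environment: pd.DataFrame,
    species_ids,
    factors,
    min_support: int = 3,
):
    """Pearson r between each species' station-month biovolume and each factor.

    Cells with fewer than ``min_support`` paired observations, or a constant
    factor/series, are missing.  Returns (r matrix, support-count matrix).
    """
    if len(list(factors)) == 0:
        raise ValueError("empty factor list")
    merged = obs.merge(environment, on=["station_id", "date"], how="inner")
    r = pd.DataFrame(np.nan, index=list(species_ids), columns=list(factors))
    support = pd.DataFrame(0, index=list(species_ids), columns=list(factors))
    for sp in species_ids:
        sub = merged[merged["species_id"] == sp]
        for f in factors:
            pair = sub[["cell_biovolume", f]].dropna()
            support.loc[sp, f] = len(pair)
            if len(pair) < min_support:
                continue
            x, y = pair[f].to_numpy(), pair["cell_biovolume"].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue  # zero variance
            r.loc[sp, f] = stats.pearsonr(x, y)[0]
    return r, support


def cluster_response_groups(
    corr: pd.DataFrame,
    k: int = 4,
    temp_col: str = "temperature",
    nutrient_cols=("PO4", "DIN"),
    threshold: float = 0.1,
    method: str = "average",
) -> pd.DataFrame:
    """Agglomerative clustering of species on their correlation profiles.

    Euclidean distance between correlation rows (missing entries imputed to
    0 and flagged), average linkage, cut at ``k`` clusters.  Each cluster is
    labelled by the sign of its mean temperature correlation (T+/T-) and,
    when the mean nutrient correlation magnitude exceeds ``threshold``, a
    nutrient sign suffix (e.g. 'T- & N+').
    """
    if k > len(corr):
        raise ValueError(f"k={k} exceeds species count {len(corr)}")
    x = corr.to_numpy(dtype=float)
    imputed = ~np.isfinite(x)
    x = np.where(imputed, 0.0, x)
    if len(corr) == k:
        clusters = np.arange(1, k + 1)
    else:
        z = linkage(pdist(x, metric="euclidean"), method=method)
        clusters = fcluster(z, t=k, criterion="maxclust")
    out = pd.DataFrame(
        {
            "species_id": corr.index,
            "cluster": clusters,
            "imputed": imputed.any(axis=1),
        }
    )
    nutrient_cols = [c for c in nutrient_cols if c in corr.columns]
    labels = {}
    for c in np.unique(clusters):
        rows = corr.loc[out.loc[out["cluster"] == c, "species_id"]]
        t_mean = np.nan_to_num(rows[temp_col].to_numpy(dtype=float)).mean()
        label = "T+" if t_mean >= 0 else "T-"
        if nutrient_cols:
            n_mean = np.nan_to_num(rows[nutrient_cols].to_numpy(dtype=float)).mean()
            if abs(n_mean) > threshold:
                label += " & N+" if n_mean > 0 else " & N-"
        labels[c] = label
    out["label"] = out["cluster"].map(labels)
    return out


# -------------------------------------------------------------- partial effects

@dataclass
class PartialEffectResult:
    response: str
    focal: str
    coefficient: float
    se: float
    p: float
    covariates: list
    group_var: str | None
    n: int
    group_intercepts: dict = field(default_factory=dict)


def partial_effect(
    table: pd.DataFrame,
    response: str,
    focal: str,
    covariates=(),
    group_var: str | None = None,
) -> PartialEffectResult:
    """Least-squares partial effect of a focal factor on a response.

    Fits response ~ focal + covariates (+ one intercept per level of
    ``group_var``) and reports the focal coefficient with its standard
    error and two-sided t-test p-value.  Raises on rank-deficient designs,
    naming the collinear columns.
    """
    covariates = list(covariates)
    cols = [response, focal] + covariates + ([group_var] if group_var else [])
    df = table[cols].dropna()
    y = df[response].to_numpy(dtype=float)
    names = [focal] + covariates
    x_parts = [df[c].to_numpy(dtype=float)[:, None] for c in names]
    if group_var:
        dummies = pd.get_dummies(df[group_var], dtype=float)
        x_parts.append(dummies.to_numpy())
        names = names + [f"{group_var}={lvl}" for lvl in dummies.columns]
    else:
        x_parts.append(np.ones((len(df), 1)))
        names = names + ["intercept"]
    x = np.hstack(x_parts)
    n, k = x.shape
    if n <= k + 2:
        raise ValueError(f"too few rows ({n}) for {k} parameters")
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        bad = _collinear_columns(x, names)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    se = np.sqrt(np.diag(cov))
    tstat = beta[0] / se[0] if se[0] > 0 else np.inf * np.sign(beta[0])
    p = float(2 * stats.t.sf(abs(tstat), dof)) if np.isfinite(tstat) else 0.0
    intercepts = {}
    if group_var:
        for nm, b in zip(names, beta):
            if nm.startswith(f"{group_var}="):
                intercepts[nm.split("=", 1)[1]] = float(b)
    return PartialEffectResult(
        response, focal, float(beta[0]), float(se[0]), p, covariates, group_var, n, intercepts
    )


def _collinear_columns(x, names):
    """Columns whose removal restores full rank (diagnostic only)."""
    full = np.linalg.matrix_rank(x)
    bad = []
    for j in range(x.shape[1]):
        reduced = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            bad.append(names[j])
    return bad or names


def species_table(obs: pd.DataFrame, environment: pd.DataFrame, log_size: bool = True) -> pd.DataFrame:
    """Joined per-(species, station, month) analysis table with environment."""
    merged = obs.merge(environment, on=["station_id", "date"], how="inner")
    merged = add_lagged_month(merged, obs["date"].min())
    if log_size:
        merged["log_biovolume"] = np.log(merged["cell_biovolume"])
    return merged


def tsr_test(
    table: pd.DataFrame,
    species_ids,
    response: str = "log_biovolume",
    focal: str = "temperature",
    covariates=("PO4", "DIN"),
    group_var: str | None = "station_id",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Temperature-size-rule test per species via partial effects.

    'follows_tsr' when the temperature coefficient is significantly
    negative (size shrinks with warming), 'anti_tsr' when significantly
    positive, otherwise 'none'.
    """
    rows = []
    for sp in species_ids:
        sub = table[table["species_id"] == sp]
        gv = group_var if group_var and sub[group_var].nunique() > 1 else None
        res = partial_effect(sub, response, focal, covariates, gv)
        if res.coefficient < 0 and res.p < alpha:
            cls = "follows_tsr"
        elif res.coefficient > 0 and res.p < alpha:
            cls = "anti_tsr"
        else:
            cls = "none"
        rows.append(
            {
                "species_id": sp, "coefficient": res.coefficient, "se": res.se,
                "p": res.p, "n": res.n, "class": cls,
            }
        )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ tournament

@dataclass
class TournamentResult:
    scores: pd.DataFrame       # learner, r2, rmse
    winner: str
    split_seed: int
    test_frac: float


class _SklearnAdapter:
    """Learner contract: a name plus fit/predict."""

    def __init__(self, name, factory):
        self.name = name
        self._factory = factory
        self._model = None

    def fit(self, x, y):
        self._model = self._factory()
        self._model.fit(x, y)
        return self

    def predict(self, x):
        return self._model.predict(x)


def default_learners(seed: int = 0, fast: bool = False):
    """Five learner families: penalized linear, bagged trees, boosted trees,
    small feed-forward network, kernel regressor."""
    from sklearn.ensemble import RandomForestRegressor
    from sklearn.linear_model import Ridge
    from sklearn.neural_network import MLPRegressor
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVR
    from xgboost import XGBRegressor

    n_trees = 50 if fast else 200
    return [
        _SklearnAdapter("ridge", lambda: make_pipeline(StandardScaler(), Ridge(alpha=1.0))),
        _SklearnAdapter(
            "random_forest",
            lambda: RandomForestRegressor(
                n_estimators=n_trees, min_samples_leaf=2, random_state=seed, n_jobs=1
            ),
        ),
        _SklearnAdapter(
            "xgboost",
            lambda: XGBRegressor(
                n_estimators=n_trees, max_depth=4, learning_rate=0.1,
                random_state=seed, n_jobs=1, verbosity=0,
            ),
        ),
        _SklearnAdapter(
            "neural_net",
            lambda: make_pipeline(
                StandardScaler(),
                MLPRegressor(hidden_layer_sizes=(32, 16), max_iter=200 if fast else 500,
                             random_state=seed),
            ),
        ),
        _SklearnAdapter("svm", lambda: make_pipeline(StandardScaler(), SVR(C=1.0))),
    ]


def model_tournament(x, y, learners, test_frac: float = 0.2, seed: int = 0) -> TournamentResult:
    """Fit each learner on one seeded random train/test split and score on
    the held-out 20%; the winner has maximal held-out R^2 (ties break by
    registration order)."""
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_test = int(round(n * test_frac))
    if n_test < 5:
        raise ValueError("test split would have fewer than 5 samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    ss_tot = ((y[test_idx] - y[test_idx].mean()) ** 2).sum()
    rows = []
    for lr in learners:
        lr.fit(x[train_idx], y[train_idx])
        pred = np.asarray(lr.predict(x[test_idx]), dtype=float)
        resid = y[test_idx] - pred
        r2 = 1.0 - (resid @ resid) / ss_tot if ss_tot > 0 else np.nan
        rows.append({"learner": lr.name, "r2": float(r2), "rmse": float(np.sqrt((resid @ resid) / n_test))})
    scores = pd.DataFrame(rows)
    winner = scores.loc[scores["r2"].idxmax(), "learner"]
    return TournamentResult(scores, winner, seed, test_frac)
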