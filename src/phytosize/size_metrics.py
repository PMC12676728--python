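"""Species- and community-level size metrics.

Community mean size C is the abundance-weighted mean cell biovolume of one
sample (total biovolume / total cell abundance).  "Small species" are the
bottom quartile of all species ranked by their average biovolume across
all communities; Small% is the share of individuals (cells) belonging to
them.  ESD converts biovolume to equivalent spherical diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import add_lagged_month

DEFAULT_TOP_COUNTS = {"diatom": 10, "dinoflagellate": 10, "other": 5}


@dataclass
class SizeSeries:
    """Ordered (lagged_month, value) series at a declared scope."""

    scope: str                 # station | wcz | region
    scope_id: str
    metric: str                # species_biovolume | community_mean | small_fraction
    data: pd.DataFrame         # columns: lagged_month, value

    @property
    def t(self) -> np.ndarray:
        return self.data["lagged_month"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.data["value"].to_numpy()


@dataclass
class SmallSpeciesSet:
    members: frozenset
    q: float
    threshold: float           # average biovolume of the largest member, um^3
    scope: str


def _scope_filter(obs: pd.DataFrame, scope: str, scope_id: str | None) -> pd.DataFrame:
    if scope == "region":
        return obs
    if scope in ("station", "wcz"):
        col = "station_id" if scope == "station" else "wcz"
        sub = obs[obs[col] == scope_id]
        if sub.empty:
            raise ValueError(f"no observations for {scope} {scope_id!r}")
        return sub
    raise ValueError(f"unknown scope {scope!r}")


def species_size_series(
    obs: pd.DataFrame, species_id: str, scope: str = "region", scope_id: str | None = None,
    origin=None,
) -> SizeSeries:
    """Monthly biovolume series of one species within a scope.

    At station scope the value is the sample's mean cell biovolume; at
    wcz/region scope it is the unweighted mean over stations reporting the
    species that month.  Months where the species is absent are missing,
    not zero.
    """
    origin = origin if origin is not None else obs["date"].min()
    sub = _scope_filter(obs, scope, scope_id)
    sub = sub[sub["species_id"] == species_id]
    if sub.empty:
        raise ValueError(f"no observations for species {species_id!r} in scope")
    sub = add_lagged_month(sub, origin)
    series = (
        sub.groupby("lagged_month", sort=True)["cell_biovolume"].mean().rename("value").reset_index()
    )
    return SizeSeries(scope, scope_id or "all", "species_biovolume", series)


def community_size_table(obs: pd.DataFrame, origin=None) -> pd.DataFrame:
    """Per-sample community mean size for every (station, date) sample.

    C = sum(n_i v_i) / sum(n_i); also returns total abundance and biovolume.
    """
    origin = origin if origin is not None else obs["date"].min()
    df = obs.copy()
    df["biovolume"] = df["abundance"] * df["cell_biovolume"]
    g = df.groupby(["station_id", "wcz", "date"], sort=True, observed=True).agg(
        total_abundance=("abundance", "sum"), total_biovolume=("biovolume", "sum")
    )
    g = g.reset_index()
    with np.errstate(invalid="ignore"):
        g["community_mean_size"] = np.where(
            g["total_abundance"] > 0, g["total_biovolume"] / g["total_abundance"], np.nan
        )
    return add_lagged_month(g, origin)


def community_mean_size(obs_at_sample: pd.DataFrame) -> float:
    """C for the records of a single sample; NaN when total abundance is 0."""
    n = obs_at_sample["abundance"].to_numpy(dtype=float)
    v = obs_at_sample["cell_biovolume"].to_numpy(dtype=float)
    total = n.sum()
    if not total > 0:
        return float("nan")
    return float((n * v).sum() / total)


def average_species_biovolume(obs: pd.DataFrame) -> pd.Series:
    """Unweighted mean of a species' cell biovolume over all samples where present."""
    return obs.groupby("species_id")["cell_biovolume"].mean()


def classify_small_species(obs: pd.DataFrame, q: float = 0.25, scope: str = "region") -> SmallSpeciesSet:
    """Bottom-``q`` quartile of species ranked ascending by average biovolume.

    The smallest ``floor(S*q)`` species (at least one) form the set; ties at
    the cut are broken by species id (lexicographically smaller included).
    """
    means = average_species_biovolume(obs)
    s = len(means)
    if s < 4:
        raise ValueError(f"need at least 4 species, got {s}")
    n_small = max(1, int(np.floor(s * q)))
    ranked = means.reset_index().sort_values(
        ["cell_biovolume", "species_id"], kind="mergesort"
    )
    members = ranked["species_id"].iloc[:n_small].tolist()
    threshold = float(ranked["cell_biovolume"].iloc[n_small - 1])
    return SmallSpeciesSet(frozenset(members), q, threshold, scope)


def small_fraction_table(
    obs: pd.DataFrame, small: SmallSpeciesSet, mode: str = "abundance", origin=None
) -> pd.DataFrame:
    """Small% per (station, date) sample.

    ``mode='abundance'`` (default): share of cells belonging to small
    species.  ``mode='richness'``: share of species present that are small.
    """
    if mode not in ("abundance", "richness"):
        raise ValueError("mode must be 'abundance' or 'richness'")
    origin = origin if origin is not None else obs["date"].min()
    df = obs.copy()
    df["is_small"] = df["species_id"].isin(small.members)
    if mode == "abundance":
        g = df.groupby(["station_id", "wcz", "date"], sort=True, observed=True).apply(
            lambda x: np.nan
            if not x["abundance"].sum() > 0
            else x.loc[x["is_small"], "abundance"].sum() / x["abundance"].sum(),
            include_groups=False,
        )
    else:
        g = df.groupby(["station_id", "wcz", "date"], sort=True, observed=True).apply(
            lambda x: x["is_small"].mean(), include_groups=False
        )
    out = g.rename("small_fraction").reset_index()
    return add_lagged_month(out, origin)


def small_fraction(obs_at_sample: pd.DataFrame, small: SmallSpeciesSet, mode: str = "abundance") -> float:
    """Small% for the records of a single sample."""
    n = obs_at_sample["abundance"].to_numpy(dtype=float)
    is_small = obs_at_sample["species_id"].isin(small.members).to_numpy()
    if mode == "richness":
        return float(is_small.mean()) if len(is_small) else float("nan")
    total = n.sum()
    if not total > 0:
        return float("nan")
    return float(n[is_small].sum() / total)


def esd_from_biovolume(v):
    """Equivalent spherical diameter (um) of a cell of biovolume v (um^3)."""
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr <= 0):
        raise ValueError("biovolume must be positive")
    esd = (6.0 * v_arr / np.pi) ** (1.0 / 3.0)
    return float(esd) if np.isscalar(v) else esd


def select_top_species(obs: pd.DataFrame, counts: dict | None = None) -> pd.DataFrame:
    """Most abundant species per group by total cell abundance over all samples.

    Default request mirrors the monitoring analysis: top 10 diatoms, top 10
    dinoflagellates, top 5 of other groups.  Ties break by species id.
    """
    counts = counts or DEFAULT_TOP_COUNTS
    totals = (
        obs.groupby(["group", "species_id"], observed=True)["abundance"].sum().reset_index()
    )
    out = []
    for grp, k in counts.items():
        sub = totals[totals["group"] == grp]
        if len(sub) < k:
            raise ValueError(f"group {grp!r} has only {len(sub)} species, {k} requested")
        sub = sub.sort_values(["abundance", "species_id"], ascending=[False, True], kind="mergesort")
        top = sub.head(k).copy()
        top["rank"] = np.arange(1, k + 1)
        out.append(top)
    return pd.concat(out, ignore_index=True)[["group", "species_id", "abundance", "rank"]]
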