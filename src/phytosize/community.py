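"""Community turnover: Bray-Curtis dissimilarity and ANOSIM, from scratch.

ANOSIM follows Clarke's rank formulation: all M = n(n-1)/2 pairwise
dissimilarities are ranked (mid-ranks for ties) and
R = (mean between-group rank - mean within-group rank) / (M/2),
tested by permuting group labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None
    grouping: str
    n_samples: int
    n_pairs: int


def abundance_matrix(obs: pd.DataFrame, index=("station_id", "date")) -> pd.DataFrame:
    """Samples x species abundance matrix (absent species are 0)."""
    return (
        obs.pivot_table(
            index=list(index), columns="species_id", values="abundance",
            aggfunc="sum", fill_value=0.0,
        )
        .sort_index()
    )


def bray_curtis(x) -> np.ndarray | pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sample rows.

    BC(j,k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik); a pair of all-zero
    samples is 0 by convention (with a warning).
    """
    import warnings

    is_df = isinstance(x, pd.DataFrame)
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 sample rows")
    if np.any(a < 0):
        raise ValueError("abundances must be non-negative")
    num = np.abs(a[:, None, :] - a[None, :, :]).sum(axis=2)
    den = (a[:, None, :] + a[None, :, :]).sum(axis=2)
    zero = den == 0
    if zero.any() and (~np.eye(len(a), dtype=bool) & zero).any():
        warnings.warn("pair(s) of all-zero samples; dissimilarity set to 0 by convention")
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    np.fill_diagonal(d, 0.0)
    if is_df:
        return pd.DataFrame(d, index=x.index, columns=x.index)
    return d


def _anosim_r(rank_matrix: np.ndarray, groups: np.ndarray) -> float:
    n = len(groups)
    within = groups[:, None] == groups[None, :]
    iu = np.triu_indices(n, k=1)
    ranks = rank_matrix[iu]
    w = within[iu]
    rw = ranks[w].mean()
    rb = ranks[~w].mean()
    return float((rb - rw) / (n * (n - 1) / 4.0))


def anosim(
    d, groups, n_perm: int = 999, seed: int | None = 0,
    grouping: str = "group", method: str = "permutation",
) -> AnosimResult:
    """ANOSIM R with a one-sided permutation (or exact enumeration) test.

    ``method='exact'`` enumerates all distinct label permutations (small n
    only); otherwise ``n_perm`` random label permutations are drawn and
    p = (#{R_perm >= R_obs} + 1) / (n_perm + 1).
    A constant dissimilarity matrix has no rank structure: R is reported
    missing.
    """
    d = np.asarray(d, dtype=float) if not isinstance(d, pd.DataFrame) else d.to_numpy()
    groups = np.asarray(groups)
    n = len(groups)
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix and groups have mismatched sizes")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        small = labels[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 samples; too small: {small}")
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    n_pairs = len(vals)
    if np.ptp(vals) == 0:
        return AnosimResult(float("nan"), float("nan"), 0, seed, grouping, n, n_pairs)
    rank_matrix = np.zeros_like(d)
    rank_matrix[iu] = rankdata(vals)  # mid-ranks for ties
    rank_matrix = rank_matrix + rank_matrix.T

    r_obs = _anosim_r(rank_matrix, groups)

    if method == "exact":
        seen_count = 0
        total = 0
        for perm in set(permutations(groups.tolist())):
            total += 1
            if _anosim_r(rank_matrix, np.asarray(perm)) >= r_obs - 1e-12:
                seen_count += 1
        return AnosimResult(r_obs, seen_count / total, total, None, grouping, n, n_pairs)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _anosim_r(rank_matrix, perm) >= r_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return AnosimResult(r_obs, p, n_perm, seed, grouping, n, n_pairs)


def anosim_by_factors(
    obs: pd.DataFrame, factors=("year", "month", "station", "wcz"),
    n_perm: int = 999, seed: int = 0, max_samples: int | None = None,
) -> pd.DataFrame:
    """Run ANOSIM on one pooled sample x species matrix for each grouping
    factor in turn (temporal: year, month; spatial: station, WCZ).

    ``max_samples`` optionally subsamples rows (seeded) to bound the O(n^2)
    dissimilarity cost.
    """
    mat = abundance_matrix(obs)
    meta = mat.index.to_frame(index=False)
    meta["year"] = pd.PeriodIndex(meta["date"], freq="M").year
    meta["month"] = pd.PeriodIndex(meta["date"], freq="M").month
    meta["station"] = meta["station_id"]
    wcz_map = obs.drop_duplicates("station_id").set_index("station_id")["wcz"]
    meta["wcz"] = meta["station_id"].map(wcz_map)
    if max_samples is not None and len(mat) > max_samples:
        rng = np.random.default_rng(seed)
        keep = np.sort(rng.choice(len(mat), size=max_samples, replace=False))
        mat = mat.iloc[keep]
        meta = meta.iloc[keep]
    d = bray_curtis(mat.to_numpy())
    rows = []
    for f in factors:
        res = anosim(d, meta[f].to_numpy(), n_perm=n_perm, seed=seed, grouping=f)
        rows.append(
            {
                "grouping": f, "R": res.r, "p": res.p, "n_permutations": res.n_permutations,
                "n_samples": res.n_samples, "n_pairs": res.n_pairs, "seed": seed,
            }
        )
    return pd.DataFrame(rows)
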