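"""Model-agnostic Shapley-value attribution, implemented from first principles.

A trained predictor f and a finite background set define a coalition value
for each explained sample x:

    v(S) = mean over background rows b of f(z),  z_j = x_j if j in S else b_j

(interventional "absent feature" semantics: absent features are replaced by
background values and averaged).  The Shapley value of feature j is the
classic weighted average of marginal contributions v(S u {j}) - v(S) over
all coalitions S not containing j; exact mode enumerates them, Monte-Carlo
mode averages marginal contributions along random feature permutations.
Pairwise Shapley interaction indices use the second-difference
v(S u {i,j}) - v(S u {i}) - v(S u {j}) + v(S).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd


@dataclass
class ShapleyMatrix:
    """Per-sample per-feature attributions with baseline and efficiency check.

    ``baseline`` is the mean prediction over the background set (v of the
    empty coalition).  ``efficiency_residual[i]`` is
    sum_j phi[i, j] + baseline - f(x_i); in exact mode it is zero to
    numerical tolerance by the efficiency axiom.
    """

    values: pd.DataFrame        # rows = samples, columns = features
    baseline: float
    efficiency_residual: np.ndarray
    mode: str


def _as_array(x, name):
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    return a


def _coalition_value(predict_fn, x_mat, background, mask):
    """v(S) for every explained row, vectorized over the background set."""
    nx = len(x_mat)
    nb = len(background)
    z = np.repeat(background[None, :, :], nx, axis=0)  # (nx, nb, p)
    if mask.any():
        z[:, :, mask] = x_mat[:, None, mask]
    preds = np.asarray(predict_fn(z.reshape(nx * nb, -1)), dtype=float)
    return preds.reshape(nx, nb).mean(axis=1)


def _all_coalition_values(predict_fn, x_mat, background, p):
    v = np.empty((1 << p, len(x_mat)))
    for code in range(1 << p):
        mask = np.array([(code >> j) & 1 for j in range(p)], dtype=bool)
        v[code] = _coalition_value(predict_fn, x_mat, background, mask)
    return v


def shapley_values(
    predict_fn,
    x,
    background,
    mode: str = "exact",
    exact_limit: int = 12,
    n_samples: int = 2048,
    seed: int = 0,
    feature_names=None,
) -> ShapleyMatrix:
    """Shapley attributions phi for each explained sample and feature.

    Parameters
    ----------
    predict_fn : callable
        Maps an (n, p) array to n predictions.
    x : array-like, (n, p) or (p,)
        Samples to explain.
    background : array-like, (m, p)
        Reference rows defining absent-feature values.
    mode : {'exact', 'montecarlo'}
        Exact enumeration of all coalitions (p <= ``exact_limit``) or
        averaging over ``n_samples`` random feature permutations.
    """
    if isinstance(x, pd.DataFrame):
        feature_names = feature_names or list(x.columns)
    x_mat = _as_array(x, "x")
    bg = _as_array(background, "background")
    nx, p = x_mat.shape
    if bg.shape[1] != p:
        raise ValueError("background and x have different feature counts")
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(p)]

    fx = np.asarray(predict_fn(x_mat), dtype=float)
    baseline_vec = _coalition_value(predict_fn, x_mat, bg, np.zeros(p, dtype=bool))
    baseline = float(baseline_vec.mean())

    phi = np.zeros((nx, p))
    if mode == "exact":
        if p > exact_limit:
            raise ValueError(
                f"p={p} exceeds exact_limit={exact_limit}; use mode='montecarlo'"
            )
        v = _all_coalition_values(predict_fn, x_mat, bg, p)
        weights = [factorial(s) * factorial(p - s - 1) / factorial(p) for s in range(p)]
        for j in range(p):
            bit = 1 << j
            for code in range(1 << p):
                if code & bit:
                    continue
                s = bin(code).count("1")
                phi[:, j] += weights[s] * (v[code | bit] - v[code])
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        cache = {}

        def value(code, mask):
            if code not in cache:
                cache[code] = _coalition_value(predict_fn, x_mat, bg, mask)
            return cache[code]

        counts = np.zeros(p, dtype=int)
        for _ in range(n_samples):
            perm = rng.permutation(p)
            code = 0
            mask = np.zeros(p, dtype=bool)
            prev = value(0, mask)
            for j in perm:
                code |= 1 << j
                mask[j] = True
                cur = value(code, mask.copy())
                phi[:, j] += cur - prev
                counts[j] += 1
                prev = cur
            mask[:] = False
        phi /= counts[None, :]
    else:
        raise ValueError("mode must be 'exact' or 'montecarlo'")

    residual = phi.sum(axis=1) + baseline_vec - fx
    values = pd.DataFrame(phi, columns=names)
    return ShapleyMatrix(values, baseline, residual, mode)


def shapley_interaction(
    predict_fn, x, pair, background, exact_limit: int = 10, feature_names=None
) -> pd.Series:
    """Pairwise Shapley interaction index, by exact enumeration.

    For features (i, j):
    phi_ij = sum over S excluding i,j of
    |S|! (p - |S| - 2)! / (p - 1)!  *  [v(S+{i,j}) - v(S+{i}) - v(S+{j}) + v(S)].
    Symmetric in the pair; zero for additively separable predictors.
    """
    if isinstance(x, pd.DataFrame):
        feature_names = feature_names or list(x.columns)
    if any(isinstance(f, str) for f in pair):
        if feature_names is None:
            raise ValueError("named pair requires feature_names or a DataFrame")
        pair = tuple(
            list(feature_names).index(f) if isinstance(f, str) else f for f in pair
        )
    x_mat = _as_array(x, "x")
    bg = _as_array(background, "background")
    p = x_mat.shape[1]
    i, j = pair
    if i == j:
        raise ValueError("interaction pair must be two distinct features")
    if p > exact_limit:
        raise ValueError(f"p={p} exceeds exact_limit={exact_limit}")
    rest = [k for k in range(p) if k not in (i, j)]
    out = np.zeros(len(x_mat))
    for code in range(1 << len(rest)):
        members = [rest[k] for k in range(len(rest)) if (code >> k) & 1]
        s = len(members)
        w = factorial(s) * factorial(p - s - 2) / factorial(p - 1)
        base = np.zeros(p, dtype=bool)
        base[members] = True
        m_ij = base.copy(); m_ij[[i, j]] = True
        m_i = base.copy(); m_i[i] = True
        m_j = base.copy(); m_j[j] = True
        out += w * (
            _coalition_value(predict_fn, x_mat, bg, m_ij)
            - _coalition_value(predict_fn, x_mat, bg, m_i)
            - _coalition_value(predict_fn, x_mat, bg, m_j)
            + _coalition_value(predict_fn, x_mat, bg, base)
        )
    name = None
    if feature_names is not None:
        name = f"{feature_names[i]}*{feature_names[j]}"
    return pd.Series(out, name=name)


def global_importance(phi: ShapleyMatrix) -> pd.Series:
    """Features ranked by mean |phi| (descending; ties by feature name)."""
    if len(phi.values) == 0:
        raise ValueError("empty attribution matrix")
    imp = phi.values.abs().mean(axis=0)
    return imp.sort_index().sort_values(ascending=False, kind="mergesort")
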