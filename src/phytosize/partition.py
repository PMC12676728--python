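"""Exact partition of community mean-size change and scenario classification.

Between two time windows, the change in community mean cell size
Delta C = C(1) - C(0), with C(w) = sum_i pbar_i(w) vbar_i(w) over species
(pbar = share of total cells in the window, vbar = mean cell biovolume),
splits exactly into a within-species (size-shift) term and a composition
(species-shift) term using mid-point (Bennet) weights:

    within      = sum_i (pbar_i(0) + pbar_i(1))/2 * (vbar_i(1) - vbar_i(0))
    composition = sum_i (vbar_i(0) + vbar_i(1))/2 * (pbar_i(1) - pbar_i(0))
    within + composition = Delta C        (no cross term)

Species present in only one window contribute through p = 0 (and, by
convention, their observed-window vbar) in the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import add_lagged_month


@dataclass
class PartitionResult:
    scope: str
    scope_id: str
    window0: tuple
    window1: tuple
    c0: float
    c1: float
    delta_c: float
    within_species: float      # size-shift component
    composition: float         # species-shift component
    residual: float            # within + composition - delta_c
    per_species: pd.DataFrame


@dataclass
class ScenarioClass:
    scope: str
    species_summary: str       # majority trend class over species
    small_class: str
    community_class: str
    scenario: str              # 'i' | 'ii' | 'none'


def _window_profile(obs: pd.DataFrame) -> pd.DataFrame:
    """Per-species cell share pbar and mean cell biovolume vbar in a window.

    pbar is the species' share of total cells summed over the window;
    vbar is the cell-weighted mean biovolume, so C = sum pbar*vbar equals
    the window's total biovolume / total abundance.
    """
    g = obs.groupby("species_id", observed=True).apply(
        lambda x: pd.Series(
            {
                "cells": x["abundance"].sum(),
                "biovolume": (x["abundance"] * x["cell_biovolume"]).sum(),
            }
        ),
        include_groups=False,
    )
    total = g["cells"].sum()
    if not total > 0:
        raise ValueError("window has zero total abundance")
    g["pbar"] = g["cells"] / total
    g["vbar"] = np.where(g["cells"] > 0, g["biovolume"] / np.where(g["cells"] > 0, g["cells"], 1.0), np.nan)
    return g[["pbar", "vbar"]]


def partition_community_change(
    obs: pd.DataFrame,
    window0,
    window1,
    scope: str = "region",
    scope_id: str | None = None,
    origin=None,
) -> PartitionResult:
    """Exact two-component partition of Delta C between two lagged-month
    windows ``[start, stop)`` within a scope."""
    origin = origin if origin is not None else obs["date"].min()
    df = add_lagged_month(obs, origin)
    if scope == "station":
        df = df[df["station_id"] == scope_id]
    elif scope == "wcz":
        df = df[df["wcz"] == scope_id]
    elif scope != "region":
        raise ValueError(f"unknown scope {scope!r}")

    w0 = df[(df["lagged_month"] >= window0[0]) & (df["lagged_month"] < window0[1])]
    w1 = df[(df["lagged_month"] >= window1[0]) & (df["lagged_month"] < window1[1])]
    if w0.empty or w1.empty:
        raise ValueError("both windows must contain at least one sample")

    prof = _window_profile(w0).join(_window_profile(w1), how="outer", lsuffix="_0", rsuffix="_1")
    prof[["pbar_0", "pbar_1"]] = prof[["pbar_0", "pbar_1"]].fillna(0.0)
    # species absent from one window: carry the observed window's vbar so the
    # within term vanishes and the composition term uses a defined size
    prof["vbar_0"] = prof["vbar_0"].fillna(prof["vbar_1"])
    prof["vbar_1"] = prof["vbar_1"].fillna(prof["vbar_0"])

    p0, p1 = prof["pbar_0"].to_numpy(), prof["pbar_1"].to_numpy()
    v0, v1 = prof["vbar_0"].to_numpy(), prof["vbar_1"].to_numpy()
    c0 = float((p0 * v0).sum())
    c1 = float((p1 * v1).sum())
    within = float(((p0 + p1) / 2.0 * (v1 - v0)).sum())
    composition = float(((v0 + v1) / 2.0 * (p1 - p0)).sum())
    delta = c1 - c0
    prof["within"] = (p0 + p1) / 2.0 * (v1 - v0)
    prof["composition"] = (v0 + v1) / 2.0 * (p1 - p0)
    return PartitionResult(
        scope, scope_id or "all", tuple(window0), tuple(window1),
        c0, c1, delta, within, composition, within + composition - delta,
        prof.reset_index(),
    )


def scenario_classify(species_trend_classes, small_class: str, community_class: str,
                      scope: str = "region") -> ScenarioClass:
    """Map trend classes onto the two community size-change scenarios.

    Scenario i (community miniaturization): species sizes declining while
    Small% increases or is stable.  Scenario ii (uncertain/offset): both
    species size and Small% declining, so composition change can offset
    species miniaturization at the community level.
    """
    classes = list(species_trend_classes)
    if not classes:
        raise ValueError("empty species class list")
    counts = pd.Series(classes).value_counts()
    species_summary = counts.index[0]
    if species_summary == "decline" and small_class in ("increase", "none"):
        scenario = "i"
    elif species_summary == "decline" and small_class == "decline":
        scenario = "ii"
    else:
        scenario = "none"
    return ScenarioClass(scope, species_summary, small_class, community_class, scenario)
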