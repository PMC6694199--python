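"""Whole-plant phenotyping equations.

The yield potential of a plant grown free of interplant competition is
split into two spatially robust components:

* the plant yield index ``pYI = (x / x_r)**2`` -- the plant's trait value
  relative to the mean of its moving complete replicate, which contains
  every entry exactly once and therefore acts as a local control;
* the stability index ``SI = (mean / sd)**2`` of the plant's sibling line
  -- the squared inverse coefficient of variation, a unitless measure of
  homeostasis across the micro-environments sampled by the line's
  triangular grid.

Their product is the plant phenotyping (prognostic) equation
``pPE = pYI * SI`` used to rank individual plants, while sibling lines are
ranked by ``sPE = SI * mean(pYI)`` over the line's members.  All equations
accept any non-negative single-plant trait (fresh pod weight, fodder or
root biomass, in grams).
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .design import EdgePolicy, Layout, replicate_table

__all__ = [
    "ring_mean",
    "plant_yield_index",
    "stability_index",
    "plant_phenotyping_equation",
    "sibling_phenotyping_equation",
    "score_trial",
    "percent_of_best",
]

PLANT_SCORE_COLUMNS = [
    "plant_id", "code", "line_id", "x", "ring_mean", "pYI", "SI", "pPE",
    "complete_replicate", "scored",
]
# pPE of a singleton (D0 pseudo-)line falls back to pYI; its SI stays NaN.
LINE_SCORE_COLUMNS = ["line_id", "n", "mean", "sd", "SI", "mean_pYI", "sPE", "note"]


def _as_value_series(layout: Layout, values) -> pd.Series:
    pids = layout.plant_ids
    if isinstance(values, pd.Series):
        s = values.reindex(pids).astype(float)
    elif isinstance(values, Mapping):
        s = pd.Series({p: values.get(p, np.nan) for p in pids}, dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(pids),):
            raise ValueError("values must map plant_id -> trait value")
        s = pd.Series(arr, index=pids)
    arr = s.to_numpy()
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("trait values must be non-negative")
    return s


def ring_mean(layout: Layout, values, plant: int) -> float:
    """Mean trait value over the plant's moving complete replicate (centre
    included).  Members with missing values are dropped and the mean is
    taken over the remaining members."""
    s = _as_value_series(layout, values)
    tab = replicate_table(layout)
    pids = layout.plant_ids
    where = np.flatnonzero(pids == plant)
    if where.size == 0:
        raise KeyError(f"plant {plant} not in layout")
    member_rows = tab["members"][int(where[0])]
    vals = s.to_numpy()[member_rows]
    if np.all(np.isnan(vals)):
        raise ValueError(f"no trait values among replicate members of plant {plant}")
    return float(np.nanmean(vals))


def plant_yield_index(x: float, ring_mean: float) -> float:
    """``(x / ring_mean)**2``; unitless and invariant to a global rescaling
    of all trait values."""
    if ring_mean <= 0:
        raise ValueError("ring mean must be positive")
    if x < 0:
        raise ValueError("trait value must be non-negative")
    return (x / ring_mean) ** 2


def stability_index(values) -> float:
    """``(mean / sd)**2`` with the sample (n-1) standard deviation.

    Raises on fewer than two values or on an all-identical (zero-sd)
    sample, which signals a degenerate line.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("stability index requires at least two values")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise ValueError("zero standard deviation: degenerate line")
    return (float(np.mean(arr)) / sd) ** 2


def plant_phenotyping_equation(pYI: float, SI: float) -> float:
    """``pPE = pYI * SI`` -- the per-plant selection criterion."""
    if pYI < 0 or SI < 0:
        raise ValueError("pYI and SI must be non-negative")
    return pYI * SI


def sibling_phenotyping_equation(SI: float, mean_pYI: float) -> float:
    """``sPE = SI * mean(pYI)`` -- the per-line selection criterion."""
    if SI < 0 or mean_pYI < 0:
        raise ValueError("SI and mean pYI must be non-negative")
    return SI * mean_pYI


def score_trial(
    layout: Layout,
    values,
    line_map: Mapping[int, object] | pd.Series | None = None,
    *,
    edge_policy: EdgePolicy = "nearest_per_code",
    singleton_lines: Literal["raise", "pyi"] = "raise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every plant and every sibling line of a trial.

    Parameters
    ----------
    layout
        The honeycomb layout the plants were grown on.
    values
        Mapping / Series of plant_id -> trait value (grams).  ``NaN`` marks
        a missing plant: it is dropped from its own scoring and from its
        neighbours' ring means (which renormalise over the remaining
        members).
    line_map
        plant_id -> sibling-line identifier; defaults to the entry code.
    edge_policy
        Under ``exclude_incomplete``, border plants whose replicate radius
        exceeds 1.5x the interior radius are left unscored.
    singleton_lines
        ``"raise"`` (default) errors on lines with fewer than two scored
        members; ``"pyi"`` leaves their SI undefined and falls back to
        ``pPE = pYI`` (the convention for unreplicated D0 trials).

    Returns
    -------
    (plants, lines)
        Per-plant scores (``pYI``, ``pPE`` ...) and per-line scores
        (``SI``, ``mean_pYI``, ``sPE`` ...).  A line whose members are all
        identical has an undefined SI; the error is surfaced in the line
        table's ``note`` column rather than raised.
    """
    s = _as_value_series(layout, values)
    pids = layout.plant_ids
    codes = layout.codes
    if line_map is None:
        lines = pd.Series(codes, index=pids)
    elif isinstance(line_map, pd.Series):
        lines = line_map.reindex(pids)
    else:
        lines = pd.Series({p: line_map[p] for p in pids})

    tab = replicate_table(layout)
    vals = s.to_numpy()
    ring_vals = vals[tab["members"]]
    present = ~np.isnan(ring_vals)
    n_present = present.sum(axis=1)
    ring_means = np.where(
        n_present > 0,
        np.nansum(np.where(present, ring_vals, 0.0), axis=1) / np.maximum(n_present, 1),
        np.nan,
    )

    scored = ~np.isnan(vals)
    if edge_policy == "exclude_incomplete":
        scored &= tab["complete"]
    elif edge_policy != "nearest_per_code":
        raise ValueError(f"unknown edge_policy {edge_policy!r}")

    pyi = np.full(len(pids), np.nan)
    ok = scored & (ring_means > 0)
    pyi[ok] = (vals[ok] / ring_means[ok]) ** 2

    plants = pd.DataFrame(
        {
            "plant_id": pids,
            "code": codes,
            "line_id": lines.to_numpy(),
            "x": vals,
            "ring_mean": ring_means,
            "pYI": pyi,
            "complete_replicate": tab["complete"],
            "scored": scored,
        }
    )

    line_rows = []
    si_by_line: dict = {}
    for line_id, grp in plants[plants["scored"]].groupby("line_id", sort=True):
        x = grp["x"].to_numpy()
        note = ""
        n_members = len(x)
        if n_members < 2:
            if singleton_lines == "raise":
                raise ValueError(
                    f"line {line_id!r} has fewer than two scored members"
                )
            si = np.nan
            mean = float(x.mean()) if n_members else np.nan
            sd = np.nan
            note = "singleton"
        else:
            mean = float(x.mean())
            sd = float(np.std(x, ddof=1))
            if sd == 0:
                si = np.nan
                note = "zero standard deviation: SI undefined"
            else:
                si = (mean / sd) ** 2
        mean_pyi = float(np.nanmean(grp["pYI"].to_numpy()))
        spe = si * mean_pyi if np.isfinite(si) else np.nan
        si_by_line[line_id] = si
        line_rows.append(
            {
                "line_id": line_id,
                "n": n_members,
                "mean": mean,
                "sd": sd,
                "SI": si,
                "mean_pYI": mean_pyi,
                "sPE": spe,
                "note": note,
            }
        )
    line_scores = pd.DataFrame(line_rows, columns=LINE_SCORE_COLUMNS)

    plant_si = plants["line_id"].map(si_by_line).astype(float)
    if singleton_lines == "pyi":
        plant_si = plant_si.fillna(1.0)
    plants["SI"] = plants["line_id"].map(si_by_line).astype(float)
    plants["pPE"] = plants["pYI"] * plant_si
    plants = plants[PLANT_SCORE_COLUMNS]
    return plants, line_scores


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.where(values >= 0, np.floor(values + 0.5), np.ceil(values - 0.5))


def percent_of_best(values) -> np.ndarray:
    """Each value as an integer percentage of the best (largest) value in
    the trial, rounded half away from zero; the best entry shows 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percent_of_best of an empty collection")
    best = np.nanmax(arr)
    if not best > 0:
        raise ValueError("percent_of_best requires a positive maximum")
    return _round_half_away(100.0 * arr / best).astype(int)
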