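"""Reading, writing and reporting of trial tables.

A trial-year table is one CSV per year with the columns::

    plant_id, year, row, pos, x_m, y_m, code, line_id, mother_plant_id,
    treatment, [pod_h1 ... pod_hK,] pod_total, fodder, root

Harvest columns are optional; when present ``pod_total`` must equal their
sum.  Missing measurements are empty cells and surface as NaN.  Units are
grams for weights and metres for coordinates throughout.  Cross-year joins
go through the pedigree file, because design codes are year-local.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotyping import percent_of_best

__all__ = [
    "TrialValidationError",
    "read_trial",
    "write_trial",
    "summary_report",
    "multi_trait_report",
]

REQUIRED_COLUMNS = ["plant_id", "code"]


class TrialValidationError(ValueError):
    """A trial table violated a structural invariant."""


def validate_trial(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError(f"trial table missing columns: {missing}")
    if df["plant_id"].duplicated().any():
        dupes = df.loc[df["plant_id"].duplicated(), "plant_id"].tolist()
        raise TrialValidationError(f"duplicate plant ids: {dupes[:5]}")
    weight_cols = [
        c
        for c in df.columns
        if c in ("pod_total", "fodder", "root", "pod_g", "fodder_g", "root_g")
        or c.startswith("pod_h")
    ]
    for col in weight_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[vals < 0, "plant_id"]
        if len(bad):
            raise TrialValidationError(
                f"negative {col} for plants {bad.tolist()[:5]}"
            )
    harvest_cols = sorted(c for c in df.columns if c.startswith("pod_h"))
    if harvest_cols and "pod_total" in df.columns:
        total = df[harvest_cols].sum(axis=1, skipna=False)
        stated = df["pod_total"]
        both = total.notna() & stated.notna()
        off = both & ~np.isclose(total, stated, rtol=1e-6, atol=1e-6)
        if off.any():
            plant = df.loc[off, "plant_id"].iloc[0]
            raise TrialValidationError(
                f"pod_total does not equal the sum of harvests for plant {plant}"
            )


def read_trial(path, validate: bool = True) -> pd.DataFrame:
    """Read a trial-year table; empty cells become NaN (flagged missing)."""
    df = pd.read_csv(path)
    if validate:
        validate_trial(df)
    return df


def write_trial(df: pd.DataFrame, path) -> None:
    """Write a trial-year table; round-trips all numeric fields exactly."""
    validate_trial(df)
    df.to_csv(path, index=False)


def summary_report(
    line_scores: pd.DataFrame,
    top: int | None = 3,
    control=None,
) -> pd.DataFrame:
    """Comparative per-line summary: mean, SI and sPE, each with a percent
    of the best line in the trial.

    Percentages are taken against the best value among *all* lines before
    any subsetting, so a control outside the displayed top rows keeps its
    true percent.  Rows are sorted by sPE (best first) and limited to the
    ``top`` lines plus the control, which is always included.
    """
    if len(line_scores) == 0:
        raise ValueError("no scored lines to report")
    df = line_scores.copy()
    df["pct_best_mean"] = percent_of_best(df["mean"].to_numpy())
    finite_si = df["SI"].where(np.isfinite(df["SI"]))
    finite_spe = df["sPE"].where(np.isfinite(df["sPE"]))
    df["pct_best_SI"] = (
        percent_of_best(finite_si.fillna(0.0).to_numpy())
        if finite_si.notna().any()
        else 0
    )
    df["pct_best_sPE"] = (
        percent_of_best(finite_spe.fillna(0.0).to_numpy())
        if finite_spe.notna().any()
        else 0
    )
    df = df.sort_values("sPE", ascending=False, kind="mergesort")
    if top is not None:
        keep = df.head(top)
        if control is not None and control not in keep["line_id"].tolist():
            keep = pd.concat([keep, df[df["line_id"] == control]])
        df = keep
    cols = [
        "line_id", "n", "mean", "pct_best_mean", "SI", "pct_best_SI",
        "sPE", "pct_best_sPE",
    ]
    return df[cols].reset_index(drop=True)


def multi_trait_report(
    line_scores_by_trait: dict[str, pd.DataFrame],
    top: int | None = None,
    control=None,
) -> pd.DataFrame:
    """Side-by-side sPE (with percent of best) for several traits, in the
    style of a pod / fodder / root comparison table.

    Rows follow the sPE order of the first trait given.
    """
    if not line_scores_by_trait:
        raise ValueError("no traits given")
    out = None
    first_trait = next(iter(line_scores_by_trait))
    for trait, scores in line_scores_by_trait.items():
        df = scores[["line_id", "sPE"]].copy()
        df[f"pct_best_{trait}"] = percent_of_best(
            df["sPE"].where(np.isfinite(df["sPE"])).fillna(0.0).to_numpy()
        )
        df = df.rename(columns={"sPE": f"sPE_{trait}"})
        out = df if out is None else out.merge(df, on="line_id", how="outer")
    out = out.sort_values(f"sPE_{first_trait}", ascending=False, kind="mergesort")
    if top is not None:
        keep = out.head(top)
        if control is not None and control not in keep["line_id"].tolist():
            keep = pd.concat([keep, out[out["line_id"] == control]])
        out = keep
    return out.reset_index(drop=True)
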