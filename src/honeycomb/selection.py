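"""Selection, code assignment and pedigree tracking across cycles.

Each year the plants with the highest pPE are advanced; every selected
plant founds a sibling line (a group of plants sharing the same mother) in
the next year's trial, and one design code is reserved for the control.
Design codes are year-local, so lineages are traced through explicit
mother links rather than through codes.  Plants are identified globally by
``"<year>:<plant_id>"`` strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec

__all__ = [
    "PedigreeNode",
    "SelectionConfig",
    "select_top",
    "selection_pressure",
    "advance_generation",
    "trace_lineage",
    "make_uid",
]

PEDIGREE_COLUMNS = ["plant_id", "year", "line_code", "mother_plant_id", "role"]

Role = Literal["selection", "control_bulk", "control_single"]
ControlPolicy = Literal["bulk_remnant", "single_plant_progeny"]


def make_uid(year: int, plant_id: int) -> str:
    return f"{year}:{plant_id}"


@dataclass(frozen=True)
class PedigreeNode:
    """One plant in the multi-year pedigree.

    ``line_code`` is the design code the plant's line carried *that year*;
    founders have no mother.
    """

    plant_id: str
    year: int
    line_code: int
    mother_plant_id: str | None
    role: Role


def pedigree_frame(nodes: Iterable[PedigreeNode]) -> pd.DataFrame:
    return pd.DataFrame([vars(n) for n in nodes], columns=PEDIGREE_COLUMNS)


@dataclass(frozen=True)
class SelectionConfig:
    """Either an absolute number of plants to advance or a selection
    pressure (percent of scorable plants); exactly one of the two."""

    n_select: int | None = None
    pressure: float | None = None
    rank_trait: str = "pPE"

    def __post_init__(self) -> None:
        if (self.n_select is None) == (self.pressure is None):
            raise ValueError("give exactly one of n_select / pressure")
        if self.n_select is not None and self.n_select < 1:
            raise ValueError("n_select must be positive")
        if self.pressure is not None and not (0 < self.pressure <= 100):
            raise ValueError("pressure must lie in (0, 100]")

    def resolve_n(self, n_scorable: int) -> int:
        if self.n_select is not None:
            return self.n_select
        return max(1, int(round(self.pressure / 100.0 * n_scorable)))


def select_top(plant_scores: pd.DataFrame, config: SelectionConfig) -> list:
    """The ids of the top plants by pPE.

    Ties are broken by higher raw trait value, then by smaller plant id, so
    the result is deterministic and independent of input order.  Plants
    without a pPE (missing value, excluded border plant) are not eligible.
    """
    if len(plant_scores) == 0:
        raise ValueError("no plant scores given")
    trait = config.rank_trait
    eligible = plant_scores[np.isfinite(plant_scores[trait].astype(float))]
    k = config.resolve_n(len(eligible))
    if k > len(eligible):
        raise ValueError(
            f"cannot select {k} plants: only {len(eligible)} are scorable"
        )
    ordered = eligible.sort_values(
        by=[trait, "x", "plant_id"], ascending=[False, False, True], kind="mergesort"
    )
    return ordered["plant_id"].head(k).tolist()


def selection_pressure(n_selected: int, n_total: int) -> float:
    """Percentage of evaluated plants advanced, to one decimal."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 < n_selected <= n_total):
        raise ValueError("need 0 < n_selected <= n_total")
    pct = 100.0 * n_selected / n_total
    return float(np.floor(pct * 10 + 0.5) / 10)


def advance_generation(
    selected: Sequence,
    plant_scores: pd.DataFrame,
    line_scores: pd.DataFrame | None,
    next_spec: DesignSpec,
    control: ControlPolicy = "bulk_remnant",
    *,
    allow_pad: bool = False,
) -> pd.DataFrame:
    """Assign next-year design codes to the selected plants and the control.

    Selected plants are ordered by the sPE of their mother line (best
    first), then by their own pPE; codes 1..k go to the selections and the
    last code to the control.  The next design must have exactly
    ``k + 1`` entries unless ``allow_pad`` is set, in which case surplus
    codes repeat the best selections as pseudo-entries.

    Returns a frame with columns ``code, mother_plant_id, role``.
    """
    selected = list(selected)
    k = len(selected)
    n = next_spec.n_entries
    if k + 1 > n:
        raise ValueError(f"{k} selections + control exceed {n} design codes")
    if k + 1 < n and not allow_pad:
        raise ValueError(
            f"{k} selections + control underfill a D{n} design "
            "(pass allow_pad=True to repeat selections as pseudo-entries)"
        )
    scores = plant_scores.set_index("plant_id")
    missing = [p for p in selected if p not in scores.index]
    if missing:
        raise KeyError(f"selected plants absent from scores: {missing}")
    if line_scores is not None and len(line_scores):
        spe = line_scores.set_index("line_id")["sPE"]
        mother_spe = scores.loc[selected, "line_id"].map(spe).astype(float)
    else:
        mother_spe = pd.Series(np.nan, index=selected)
    order = pd.DataFrame(
        {
            "plant": selected,
            "mother_spe": mother_spe.fillna(-np.inf).to_numpy(),
            "ppe": scores.loc[selected, "pPE"].fillna(-np.inf).to_numpy(),
        }
    ).sort_values(by=["mother_spe", "ppe", "plant"], ascending=[False, False, True])

    ranked = order["plant"].tolist()
    rows = []
    for i in range(n - 1):
        rows.append(
            {
                "code": i + 1,
                "mother_plant_id": ranked[i % k],
                "role": "selection",
            }
        )
    control_role = "control_bulk" if control == "bulk_remnant" else "control_single"
    rows.append({"code": n, "mother_plant_id": None, "role": control_role})
    out = pd.DataFrame(rows, columns=["code", "mother_plant_id", "role"])
    # keep mother ids intact (no float coercion of the control's None)
    out["mother_plant_id"] = pd.array(
        [r["mother_plant_id"] for r in rows], dtype=object
    )
    return out


def trace_lineage(pedigree: pd.DataFrame, terminal) -> pd.DataFrame:
    """Mother-chain of a plant back to its founder, ordered founder-first.

    ``pedigree`` is a frame with columns ``plant_id, year, line_code,
    mother_plant_id, role``.  Raises on an unknown terminal or a broken
    chain (a mother referenced but absent from the pedigree).
    """
    ped = pedigree.set_index("plant_id")
    if terminal not in ped.index:
        raise KeyError(f"plant {terminal!r} not in pedigree")
    chain = []
    current = terminal
    seen = set()
    while current is not None:
        if current in seen:
            raise ValueError(f"pedigree cycle at {current!r}")
        seen.add(current)
        if current not in ped.index:
            raise ValueError(f"broken pedigree chain: missing mother {current!r}")
        rec = ped.loc[current]
        chain.append(
            {
                "plant_id": current,
                "year": int(rec["year"]),
                "line_code": int(rec["line_code"]),
                "role": rec["role"],
            }
        )
        mother = rec["mother_plant_id"]
        current = None if mother is None or (isinstance(mother, float) and np.isnan(mother)) else mother
    chain.reverse()
    return pd.DataFrame(chain, columns=["plant_id", "year", "line_code", "role"])
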