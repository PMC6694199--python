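"""Honeycomb selection-design layouts.

Honeycomb designs (Dn) place plants on a triangular (hexagonal) lattice so
that the n entries of a trial tile the field in symmetrical, moving patterns.
Two properties make the arrangement useful for single-plant evaluation:

* every plant is the centre of a *moving complete replicate* -- the set of
  nearest plants containing each entry exactly once -- whose mean yield
  provides a local, spatially matched denominator for that plant;
* plants of the same entry form a triangular sublattice whose points are
  sqrt(n) plant-spacings apart (possible exactly when n is a Loeschian
  number: 3, 7, 19, ...), so each entry samples the whole field evenly.

Rows are staggered alternately by half a within-row spacing.  Codes are
assigned by a cyclic rule that is linear in the *axial* lattice coordinates
``(row, q)`` with ``q = pos - row // 2``::

    code = ((q + row * shift) mod n) + 1

which is equivalent to letting the starting code advance alternately by
``shift`` and ``shift + 1`` from row to row.  For a suitable ``shift``
(found by exhaustive search) this realises the equilateral same-code
sublattice of index n whenever one exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "DesignSpec",
    "Layout",
    "MovingReplicate",
    "LayoutReport",
    "hex_coordinates",
    "assign_code",
    "choose_shift",
    "min_same_code_distance",
    "interior_replicate_radius",
    "generate_layout",
    "moving_replicate",
    "verify_layout",
]

#: ratio between-row / within-row spacing of an ideal hexagonal lattice
IDEAL_ROW_RATIO = math.sqrt(3.0) / 2.0

#: neighbours kept in the moving ring of an unreplicated (D0) layout;
#: two full hexagonal rings around the central plant
D0_RING_SIZE = 18

#: a replicate is flagged incomplete when its radius exceeds this multiple
#: of the interior-replicate radius
COMPLETENESS_FACTOR = 1.5

EdgePolicy = Literal["nearest_per_code", "exclude_incomplete"]

LAYOUT_COLUMNS = ["plant_id", "row", "pos", "x_m", "y_m", "code"]


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of a Dn honeycomb layout.

    ``n_entries == 1`` denotes the unreplicated D0 design in which every
    plant is its own entry; ``reps_per_code`` is then the total plant count.
    """

    n_entries: int
    reps_per_code: int
    within_row_spacing: float = 1.0
    between_row_spacing: float = 0.9
    shift: int | str = "auto"
    n_rows: int | None = None
    n_cols: int | None = None

    def __post_init__(self) -> None:
        if self.n_entries < 1:
            raise ValueError("n_entries must be a positive integer")
        if self.reps_per_code < 1:
            raise ValueError("reps_per_code must be a positive integer")
        if self.within_row_spacing <= 0 or self.between_row_spacing <= 0:
            raise ValueError("plant spacings must be strictly positive")
        if self.shift != "auto":
            if self.n_entries < 2:
                raise ValueError("an explicit shift requires n_entries >= 2")
            if not (1 <= int(self.shift) <= self.n_entries - 1):
                raise ValueError(
                    f"shift must lie in [1, {self.n_entries - 1}], got {self.shift}"
                )
        for name in ("n_rows", "n_cols"):
            value = getattr(self, name)
            if value is not None and value < 1:
                raise ValueError(f"{name} must be positive when given")

    @property
    def n_plants(self) -> int:
        if self.n_entries == 1:
            return self.reps_per_code
        return self.n_entries * self.reps_per_code


def hex_coordinates(row: int, pos: int, spec: DesignSpec) -> tuple[float, float]:
    """Field coordinates (metres) of the plant at ``(row, pos)``.

    Odd rows are offset by half a within-row spacing, producing the
    staggered arrangement of a hexagonal lattice.
    """
    if row < 0 or pos < 0:
        raise ValueError("row and pos must be non-negative")
    dx = spec.within_row_spacing
    x = pos * dx + (row % 2) * dx / 2.0
    y = row * spec.between_row_spacing
    return (x, y)


def assign_code(row: int, pos: int, n: int, shift: int) -> int:
    """Entry code (1-based) of the plant at ``(row, pos)`` for a Dn design.

    The rule is cyclic along each row and advances the starting code
    alternately by ``shift`` and ``shift + 1`` between consecutive rows,
    i.e. it is linear in the axial coordinate ``q = pos - row // 2``.  This
    is what makes same-code plants form a triangular grid on the staggered
    lattice.
    """
    if n < 2:
        raise ValueError("assign_code requires n >= 2 (D0 uses pseudo-codes)")
    if not (1 <= shift <= n - 1):
        raise ValueError(f"shift must lie in [1, {n - 1}], got {shift}")
    if row < 0 or pos < 0:
        raise ValueError("row and pos must be non-negative")
    q = pos - row // 2
    return int((q + row * shift) % n) + 1


def _same_code_min_dist_sq(n: int, shift: int, dx: float, dy: float) -> float:
    """Squared min distance between same-code plants on an infinite lattice."""
    best = math.inf
    window = 2 * n + 2
    for drow in range(-window, window + 1):
        for dq in range(-window, window + 1):
            if drow == 0 and dq == 0:
                continue
            if (dq + shift * drow) % n:
                continue
            d2 = (dq + drow / 2.0) ** 2 * dx * dx + (drow * dy) ** 2
            if d2 < best:
                best = d2
    return best


@lru_cache(maxsize=None)
def min_same_code_distance(
    n: int, shift: int, within: float = 1.0, between: float | None = None
) -> float:
    """Minimum distance between same-code plants on an idealised infinite
    lattice (``between = sqrt(3)/2 * within`` unless given)."""
    if between is None:
        between = IDEAL_ROW_RATIO * within
    return math.sqrt(_same_code_min_dist_sq(n, shift, within, between))


@lru_cache(maxsize=None)
def choose_shift(n: int, within: float = 1.0, between: float | None = None) -> int:
    """Exhaustively pick the shift maximising the minimum same-code distance
    on the ideal lattice.  Ties are broken by the smallest shift."""
    if n < 2:
        raise ValueError("choose_shift requires n >= 2")
    best_shift, best_dist = 1, -1.0
    for s in range(1, n):
        d = min_same_code_distance(n, s, within, between)
        if d > best_dist + 1e-12:
            best_shift, best_dist = s, d
    return best_shift


@lru_cache(maxsize=None)
def interior_replicate_radius(
    n: int, shift: int, within: float, between: float
) -> float:
    """Radius of the moving complete replicate of a plant deep inside a Dn
    layout: the largest, over the n-1 other codes, of the distance to the
    nearest plant of that code on the infinite lattice."""
    if n < 2:
        raise ValueError("interior_replicate_radius requires n >= 2")
    best: dict[int, float] = {}
    window = 2 * n + 2
    for drow in range(-window, window + 1):
        for dq in range(-window, window + 1):
            if drow == 0 and dq == 0:
                continue
            c = (dq + shift * drow) % n
            if c == 0:
                continue
            d2 = (dq + drow / 2.0) ** 2 * within * within + (drow * between) ** 2
            if c not in best or d2 < best[c]:
                best[c] = d2
    return math.sqrt(max(best.values()))


@lru_cache(maxsize=None)
def _knn_interior_radius(k: int, within: float, between: float) -> float:
    """Distance to the k-th nearest lattice point, for D0 moving rings."""
    window = max(8, int(math.isqrt(k)) + 4)
    dists = []
    for drow in range(-window, window + 1):
        for dq in range(-window, window + 1):
            if drow == 0 and dq == 0:
                continue
            d2 = (dq + drow / 2.0) ** 2 * within * within + (drow * between) ** 2
            dists.append(d2)
    dists.sort()
    return math.sqrt(dists[min(k, len(dists)) - 1])


@dataclass(frozen=True)
class MovingReplicate:
    """The moving complete replicate centred on one plant.

    ``members`` maps each entry code to the plant chosen as that code's
    nearest representative; the centre serves as its own code's member.
    """

    center: int
    members: Mapping[int, int]
    radius: float
    complete: bool
    excluded: bool = False

    @property
    def member_ids(self) -> tuple[int, ...]:
        return tuple(self.members[c] for c in sorted(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Layout:
    """A realised honeycomb layout: the design spec, the chosen shift and a
    table of plant positions (columns ``plant_id,row,pos,x_m,y_m,code``)."""

    spec: DesignSpec
    shift: int | None
    plants: pd.DataFrame

    _replicates: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def coords(self) -> np.ndarray:
        return self.plants[["x_m", "y_m"]].to_numpy(float)

    @property
    def codes(self) -> np.ndarray:
        return self.plants["code"].to_numpy(int)

    @property
    def plant_ids(self) -> np.ndarray:
        return self.plants["plant_id"].to_numpy(int)

    def to_csv(self, path) -> None:
        self.plants.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Layout":
        """Rebuild a layout from its CSV form.

        The design spec is inferred: distinct codes give ``n_entries``,
        coordinate differences give the spacings and the code difference
        between the first plants of rows 0 and 1 gives the shift.
        """
        df = pd.read_csv(path)
        missing = set(LAYOUT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"layout CSV missing columns: {sorted(missing)}")
        df = df[LAYOUT_COLUMNS].sort_values("plant_id").reset_index(drop=True)
        if df["plant_id"].duplicated().any():
            raise ValueError("duplicate plant_id in layout CSV")
        n = int(df["code"].nunique())
        counts = df["code"].value_counts()
        reps = int(counts.min())
        row0 = df[df["row"] == 0].sort_values("pos")
        within = float(np.diff(row0["x_m"].to_numpy()).min()) if len(row0) > 1 else 1.0
        ys = np.sort(df["y_m"].unique())
        between = float(np.diff(ys).min()) if len(ys) > 1 else IDEAL_ROW_RATIO * within
        shift = None
        if n > 1 and df["row"].max() > 0:
            c00 = df[(df.row == 0) & (df.pos == 0)]
            c10 = df[(df.row == 1) & (df.pos == 0)]
            if len(c00) and len(c10):
                shift = int((int(c10.code.iloc[0]) - int(c00.code.iloc[0])) % n)
                if not (1 <= shift <= n - 1):
                    shift = None
        spec = DesignSpec(
            n_entries=n if counts.max() > 1 else (1 if n == len(df) else n),
            reps_per_code=reps if counts.max() > 1 else len(df),
            within_row_spacing=within,
            between_row_spacing=between,
            shift=shift if shift is not None else "auto",
            n_rows=int(df["row"].max()) + 1,
            n_cols=int(df["pos"].max()) + 1,
        )
        return cls(spec=spec, shift=shift, plants=df)


def _near_square_grid(total: int, multiple: int) -> tuple[int, int]:
    """Pick (n_rows, n_cols) with n_rows*n_cols == total and multiple | n_cols,
    minimising |n_rows - n_cols| (ties: more rows than columns)."""
    best = None
    for cols in range(multiple, total + 1, multiple):
        if total % cols:
            continue
        rows = total // cols
        key = (abs(rows - cols), -rows)
        if best is None or key < best[0]:
            best = (key, rows, cols)
    if best is None:
        raise ValueError(
            f"cannot split {total} plants into rows x cols with {multiple} | cols"
        )
    return best[1], best[2]


def generate_layout(spec: DesignSpec) -> Layout:
    """Generate the full plant table of a Dn honeycomb layout.

    With equal replication the grid is chosen so that each row holds whole
    cycles of the n codes, guaranteeing exactly ``reps_per_code`` plants per
    code.  D0 (``n_entries == 1``) assigns each plant a distinct pseudo-code.
    """
    n, reps = spec.n_entries, spec.reps_per_code
    total = spec.n_plants
    if spec.n_rows is not None and spec.n_cols is not None:
        n_rows, n_cols = spec.n_rows, spec.n_cols
        if n_rows * n_cols != total:
            raise ValueError(
                f"{n_rows} rows x {n_cols} cols cannot hold {total} plants"
            )
        if n > 1 and n_cols % n:
            raise ValueError(
                "equal replication requires the number of columns to be a "
                f"multiple of n_entries ({n})"
            )
    else:
        n_rows, n_cols = _near_square_grid(total, max(n, 1))

    rows = np.repeat(np.arange(n_rows), n_cols)
    poss = np.tile(np.arange(n_cols), n_rows)
    dx, dy = spec.within_row_spacing, spec.between_row_spacing
    x = poss * dx + (rows % 2) * (dx / 2.0)
    y = rows * dy

    if n == 1:
        shift = None
        codes = np.arange(1, total + 1)
    else:
        shift = spec.shift if spec.shift != "auto" else choose_shift(n)
        q = poss - rows // 2
        codes = (q + rows * int(shift)) % n + 1

    plants = pd.DataFrame(
        {
            "plant_id": np.arange(1, total + 1),
            "row": rows,
            "pos": poss,
            "x_m": x,
            "y_m": y,
            "code": codes,
        }
    )
    layout = Layout(spec=spec, shift=None if shift is None else int(shift), plants=plants)
    if n > 1:
        counts = plants["code"].value_counts()
        if counts.nunique() != 1 or counts.iloc[0] != reps:
            raise ValueError("infeasible layout: unequal per-code counts")
    return layout


def _interior_radius_for(layout: Layout) -> float:
    spec = layout.spec
    n = spec.n_entries
    dx, dy = spec.within_row_spacing, spec.between_row_spacing
    if n == 1:
        k = min(D0_RING_SIZE, layout.n_plants - 1)
        return _knn_interior_radius(k, dx, dy) if k > 0 else 0.0
    shift = layout.shift if layout.shift is not None else choose_shift(n)
    return interior_replicate_radius(n, shift, dx, dy)


def replicate_table(layout: Layout) -> dict:
    """Member indices, radii and completeness flags of every plant's moving
    replicate (cached on the layout).

    Returns a dict with ``members`` (N x m array of row indices into the
    plant table; for Dn, column c holds the nearest plant of code c+1),
    ``radius`` (N,), ``complete`` (N,) and ``interior_radius``.
    """
    if layout._replicates is not None:
        return layout._replicates
    coords = layout.coords
    codes = layout.codes
    N = layout.n_plants
    D = cdist(coords, coords)
    Dr = np.round(D, 9)  # stabilise distance ties so smallest id wins
    n = layout.spec.n_entries
    if n == 1:
        k = min(D0_RING_SIZE, N - 1)
        order = np.argsort(Dr, axis=1, kind="stable")
        members = order[:, : k + 1]
    else:
        members = np.empty((N, n), dtype=int)
        for c in range(1, n + 1):
            idx = np.flatnonzero(codes == c)
            if idx.size == 0:
                raise ValueError(f"code {c} absent from layout")
            members[:, c - 1] = idx[np.argmin(Dr[:, idx], axis=1)]
    radius = np.take_along_axis(D, members, axis=1).max(axis=1)
    interior = _interior_radius_for(layout)
    complete = radius <= COMPLETENESS_FACTOR * interior * (1 + 1e-9)
    layout._replicates = {
        "members": members,
        "radius": radius,
        "complete": complete,
        "interior_radius": interior,
    }
    return layout._replicates


def moving_replicate(
    layout: Layout, plant: int, edge_policy: EdgePolicy = "nearest_per_code"
) -> MovingReplicate:
    """The moving complete replicate centred on ``plant``.

    For each code the nearest plant of that code is taken (distance ties
    broken by smallest plant id; the centre represents its own code).  Under
    ``exclude_incomplete`` a border plant whose replicate radius exceeds
    1.5x the interior radius is flagged for exclusion from scoring.
    """
    if edge_policy not in ("nearest_per_code", "exclude_incomplete"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")
    tab = replicate_table(layout)
    pids = layout.plant_ids
    where = np.flatnonzero(pids == plant)
    if where.size == 0:
        raise KeyError(f"plant {plant} not in layout")
    i = int(where[0])
    row_members = tab["members"][i]
    codes = layout.codes
    members = {int(codes[j]): int(pids[j]) for j in row_members}
    complete = bool(tab["complete"][i])
    return MovingReplicate(
        center=int(plant),
        members=members,
        radius=float(tab["radius"][i]),
        complete=complete,
        excluded=(edge_policy == "exclude_incomplete" and not complete),
    )


@dataclass(frozen=True)
class LayoutReport:
    """Diagnostics from :func:`verify_layout`."""

    n_plants: int
    per_code_counts: pd.Series
    min_same_code_distance: float
    complete_fraction: float
    interior_radius: float

    def as_dict(self) -> dict:
        return {
            "n_plants": self.n_plants,
            "per_code_counts": self.per_code_counts.to_dict(),
            "min_same_code_distance": self.min_same_code_distance,
            "complete_fraction": self.complete_fraction,
            "interior_radius": self.interior_radius,
        }

    def __str__(self) -> str:
        counts = self.per_code_counts
        return (
            f"plants: {self.n_plants}\n"
            f"codes: {len(counts)} (counts {counts.min()}..{counts.max()})\n"
            f"min same-code distance: {self.min_same_code_distance:.4g} m\n"
            f"interior replicate radius: {self.interior_radius:.4g} m\n"
            f"complete replicates: {100 * self.complete_fraction:.1f}%"
        )


def verify_layout(layout: Layout) -> LayoutReport:
    """Diagnostic report: per-code counts, observed minimum same-code
    distance and the fraction of plants with complete interior replicates.
    Never raises on degenerate layouts."""
    plants = layout.plants
    counts = plants["code"].value_counts().sort_index()
    min_dist = math.inf
    for _, group in plants.groupby("code"):
        if len(group) > 1:
            d = pdist(group[["x_m", "y_m"]].to_numpy(float)).min()
            min_dist = min(min_dist, d)
    tab = replicate_table(layout)
    return LayoutReport(
        n_plants=layout.n_plants,
        per_code_counts=counts,
        min_same_code_distance=float(min_dist),
        complete_fraction=float(np.mean(tab["complete"])),
        interior_radius=float(tab["interior_radius"]),
    )
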