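"""Synthetic honeycomb field trials with known ground truth.

The generator emulates the structure of a single-plant selection trial:

* a smooth multiplicative fertility surface (planar gradient plus Gaussian
  patches), normalised to mean one over the field;
* contiguous row-block treatment zones (e.g. plastic ground cover versus
  different fertigation levels) with per-zone multipliers;
* per-line genetic effects ``G_i`` (multiplicative merits) and per-line
  lognormal dispersion ``sigma_i``, whose inverse is the line's true
  stability;
* multiplicative lognormal plant noise, so single-plant yields are
  positive and right-skewed like real unselected material.

A plant of line *i* at position *p* in zone *z* yields

    y_p = base * G_i * F(x_p, y_p) * T_z * exp(eps_p),   eps_p ~ N(0, sigma_i)

for the directly selected trait (fresh pod weight).  Fodder and root
biomass derive from the implied total biomass partitioned by the line's
allocation fractions, with higher-merit lines allocating more to pod.

:func:`simulate_program` chains trials into a multi-year selection
program: each cycle scores plants by pPE, advances the best, and founds
next-year sibling lines whose effect is the mother line's realised effect
perturbed by lognormal segregation noise (the heritable transmission that
lets selection respond), while the control is propagated unselected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DesignSpec, Layout, generate_layout
from .phenotyping import score_trial
from .selection import (
    SelectionConfig,
    advance_generation,
    make_uid,
    select_top,
)
from .gain import GainEstimate, GainModel

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "TrialData",
    "CycleSpec",
    "ProgramResult",
    "fertility_surface",
    "treatment_zones",
    "generate_trial",
    "simulate_program",
    "default_schedule",
]

TRIAL_COLUMNS = [
    "plant_id", "year", "row", "pos", "x_m", "y_m", "code", "line_id",
    "mother_plant_id", "treatment", "pod_g", "fodder_g", "root_g",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative parameters of a synthetic trial.

    Defaults are tuned to the order of magnitude of an unselected cowpea
    landrace grown at nil-competition spacings: a few hundred grams of
    fresh pods per plant, right-skewed single-plant yields, and fertility
    swings of a few tens of percent across the field.
    """

    base_yield: float = 400.0  # g, trial-mean pod yield scale
    line_effects: tuple[float, ...] | None = None  # per-line G_i, mean ~1
    line_sigma: float | tuple[float, ...] = 0.35  # lognormal scale per line
    gradient_strength: float = 0.4  # log-range of the planar trend
    gradient_angle: float | None = None  # radians; None -> drawn from seed
    n_bumps: int = 3
    bump_amplitude: float = 0.15  # sd of log-amplitude of fertility patches
    treatment_multipliers: tuple[float, ...] = (1.25, 1.0, 0.85)
    heritability_tau: float = 0.10  # sd of log segregation noise
    founder_g_sigma: float = 0.25  # sd of log founder merits
    sigma_inherit_noise: float = 0.10  # sd of log noise on inherited sigma
    allocation: tuple[float, float, float] = (0.40, 0.45, 0.15)  # pod/fodder/root
    allocation_coupling: float = 0.08  # pod-fraction shift per unit of (G-1)
    trait_noise: float = 0.08  # extra lognormal noise on fodder/root
    noise_model: str = "lognormal"  # or "normal" (additive)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_yield <= 0:
            raise ValueError("base_yield must be positive")
        if self.line_effects is not None and np.any(np.asarray(self.line_effects) <= 0):
            raise ValueError("line effects must be positive multiplicative factors")
        sig = np.asarray(self.line_sigma, dtype=float)
        if np.any(sig < 0):
            raise ValueError("line sigma must be non-negative")
        if np.any(np.asarray(self.treatment_multipliers) <= 0):
            raise ValueError("treatment multipliers must be positive")
        if self.noise_model not in ("lognormal", "normal"):
            raise ValueError("noise_model must be 'lognormal' or 'normal'")
        frac = np.asarray(self.allocation, dtype=float)
        if frac.shape != (3,) or np.any(frac <= 0):
            raise ValueError("allocation must be three positive fractions")

    def replace(self, **kw) -> "SimulationParams":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """True generative state of a trial, for recovery tests."""

    line_effects: pd.Series  # line_id -> G
    line_sigma: pd.Series  # line_id -> sigma
    fertility: pd.Series  # plant_id -> F
    zone: pd.Series  # plant_id -> treatment zone (1-based)


@dataclass
class TrialData:
    """A generated trial: the plant table plus its layout and truth."""

    table: pd.DataFrame
    layout: Layout
    truth: GroundTruth


def fertility_surface(
    layout: Layout, params: SimulationParams, rng: np.random.Generator | None = None
) -> pd.Series:
    """Multiplicative fertility factor per plant, mean one over the layout.

    ``F = exp(planar gradient + sum of Gaussian patches)``; the gradient
    direction, patch centres and patch log-amplitudes are drawn from the
    params seed, so the surface is deterministic given ``(params, seed)``.
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    coords = layout.coords
    span = coords.max(axis=0) - coords.min(axis=0)
    span[span == 0] = 1.0
    unit = (coords - coords.min(axis=0)) / span  # in [0, 1]^2

    angle = (
        rng.uniform(0, 2 * np.pi)
        if params.gradient_angle is None
        else params.gradient_angle
    )
    proj = (unit[:, 0] - 0.5) * np.cos(angle) + (unit[:, 1] - 0.5) * np.sin(angle)
    log_f = params.gradient_strength * proj

    width = 0.25  # patch width as a fraction of the field span
    for _ in range(params.n_bumps):
        centre = rng.uniform(0, 1, size=2)
        amp = rng.normal(0, params.bump_amplitude)
        r2 = ((unit - centre) ** 2).sum(axis=1)
        log_f = log_f + amp * np.exp(-r2 / (2 * width**2))

    f = np.exp(log_f)
    f = f / f.mean()
    return pd.Series(f, index=layout.plant_ids)


def treatment_zones(layout: Layout, n_zones: int) -> pd.Series:
    """Assign contiguous row-block treatment zones (1-based).

    Rows are split into ``n_zones`` consecutive blocks of as equal a
    number of rows as possible, mirroring a field divided into covered /
    uncovered thirds without disturbing the plant arrangement.
    """
    if n_zones < 1:
        raise ValueError("n_zones must be positive")
    rows = np.sort(layout.plants["row"].unique())
    blocks = np.array_split(rows, n_zones)
    zone_of_row = {int(r): i + 1 for i, block in enumerate(blocks) for r in block}
    zones = layout.plants["row"].map(zone_of_row).to_numpy()
    return pd.Series(zones, index=layout.plant_ids)


def _allocation_fractions(params: SimulationParams, g: np.ndarray) -> np.ndarray:
    """Per-line pod/fodder/root fractions; pod share grows with merit."""
    pod0, fodder0, root0 = params.allocation
    total0 = pod0 + fodder0 + root0
    pod = np.clip(pod0 / total0 + params.allocation_coupling * (g - 1.0), 0.10, 0.80)
    rest = 1.0 - pod
    fodder = rest * fodder0 / (fodder0 + root0)
    root = rest - fodder
    return np.stack([pod, fodder, root], axis=1)


def generate_trial(
    spec: DesignSpec | Layout,
    params: SimulationParams,
    *,
    rng: np.random.Generator | None = None,
    year: int = 1,
    line_effects: Mapping[int, float] | None = None,
    line_sigma: Mapping[int, float] | None = None,
    line_ids: Mapping[int, object] | None = None,
    mothers: Mapping[int, object] | None = None,
) -> TrialData:
    """Generate one trial (pod, fodder and root values per plant).

    ``line_effects`` / ``line_sigma`` map entry codes to true merits and
    dispersions; defaults come from ``params`` (all lines equal when
    ``params.line_effects`` is None).  Reproducible given the params seed.
    """
    layout = spec if isinstance(spec, Layout) else generate_layout(spec)
    n = layout.spec.n_entries
    rng = np.random.default_rng(params.seed) if rng is None else rng

    n_lines = layout.n_plants if n == 1 else n
    codes = layout.codes if n > 1 else np.arange(1, n_lines + 1)

    if line_effects is None:
        if params.line_effects is not None:
            if len(params.line_effects) != n_lines:
                raise ValueError(
                    f"need {n_lines} line effects, got {len(params.line_effects)}"
                )
            g_by_code = np.asarray(params.line_effects, dtype=float)
        else:
            g_by_code = np.ones(n_lines)
    else:
        g_by_code = np.array([line_effects[c] for c in range(1, n_lines + 1)], float)

    if line_sigma is None:
        sig = np.asarray(params.line_sigma, dtype=float)
        sigma_by_code = np.full(n_lines, float(sig)) if sig.ndim == 0 else sig.astype(float)
        if sigma_by_code.shape != (n_lines,):
            raise ValueError(f"need {n_lines} line sigmas")
    else:
        sigma_by_code = np.array([line_sigma[c] for c in range(1, n_lines + 1)], float)

    fert = fertility_surface(layout, params, rng)
    zones = treatment_zones(layout, len(params.treatment_multipliers))
    t_mult = np.asarray(params.treatment_multipliers, float)[zones.to_numpy() - 1]

    code_idx = codes - 1 if n > 1 else np.arange(layout.n_plants)
    g_plant = g_by_code[code_idx]
    sigma_plant = sigma_by_code[code_idx]

    mean_pod = params.base_yield * g_plant * fert.to_numpy() * t_mult
    eps = rng.normal(0, 1, size=layout.n_plants)
    if params.noise_model == "lognormal":
        pod = mean_pod * np.exp(sigma_plant * eps)
    else:
        pod = np.maximum(mean_pod * (1.0 + sigma_plant * eps), 0.0)

    frac = _allocation_fractions(params, g_plant)
    total = pod / frac[:, 0]
    noise_f = np.exp(rng.normal(0, params.trait_noise, size=layout.n_plants))
    noise_r = np.exp(rng.normal(0, params.trait_noise, size=layout.n_plants))
    fodder = total * frac[:, 1] * noise_f
    root = total * frac[:, 2] * noise_r

    if line_ids is None:
        line_ids_arr = codes
    else:
        line_ids_arr = np.array([line_ids[c] for c in codes], dtype=object)
    if mothers is None:
        mothers_arr = np.full(layout.n_plants, None, dtype=object)
    else:
        mothers_arr = np.array([mothers.get(c) for c in codes], dtype=object)

    table = pd.DataFrame(
        {
            "plant_id": layout.plant_ids,
            "year": year,
            "row": layout.plants["row"].to_numpy(),
            "pos": layout.plants["pos"].to_numpy(),
            "x_m": layout.plants["x_m"].to_numpy(),
            "y_m": layout.plants["y_m"].to_numpy(),
            "code": codes,
            "line_id": line_ids_arr,
            "mother_plant_id": mothers_arr,
            "treatment": zones.to_numpy(),
            "pod_g": pod,
            "fodder_g": fodder,
            "root_g": root,
        }
    )
    line_index = pd.Index(range(1, n_lines + 1), name="code")
    truth = GroundTruth(
        line_effects=pd.Series(g_by_code, index=line_index),
        line_sigma=pd.Series(sigma_by_code, index=line_index),
        fertility=fert,
        zone=zones,
    )
    return TrialData(table=table, layout=layout, truth=truth)


@dataclass(frozen=True)
class CycleSpec:
    """One year of a simulated program: the design grown and the number of
    plants advanced at the end of the year (0 for the final year)."""

    year: int
    design: DesignSpec
    n_select: int = 0


def default_schedule(
    years: int = 9,
    founders: int = 60,
    entries: int = 7,
    reps: int = 10,
    n_select: int | None = None,
    within: float = 1.0,
    between: float = 0.9,
) -> list[CycleSpec]:
    """A compact program: a D0 founder year followed by Dn sibling-line
    years, always advancing ``entries - 1`` plants so the next design is
    exactly filled (the last code is the control)."""
    if years < 2:
        raise ValueError("a program needs at least two years")
    k = entries - 1 if n_select is None else n_select
    schedule = [
        CycleSpec(
            year=1,
            design=DesignSpec(1, founders, within, between),
            n_select=k,
        )
    ]
    for y in range(2, years + 1):
        schedule.append(
            CycleSpec(
                year=y,
                design=DesignSpec(entries, reps, within, between),
                n_select=k if y < years else 0,
            )
        )
    return schedule


@dataclass
class ProgramResult:
    """Everything a simulated multi-year program produced."""

    params: SimulationParams
    schedule: Sequence[CycleSpec]
    trials: dict[int, TrialData]
    scores: dict[int, tuple[pd.DataFrame, pd.DataFrame]]
    selected: dict[int, list[str]]
    pedigree: pd.DataFrame
    line_truth: pd.DataFrame  # year, code, line_id, G, sigma, mother, role

    def records(self) -> pd.DataFrame:
        """All plant records across years as one table (uids as plant_id)."""
        return pd.concat(
            [t.table for t in self.trials.values()], ignore_index=True
        )

    def selection_records(self) -> pd.DataFrame:
        """(year, pod_g) for every plant of the selected (non-control)
        sibling families in the years after the founder year -- the input
        of the gain regression."""
        frames = []
        for cycle in self.schedule[1:]:
            table = self.trials[cycle.year].table
            roles = self.line_truth.query("year == @cycle.year").set_index("code")["role"]
            sel_codes = roles[roles == "selection"].index
            frames.append(table[table["code"].isin(sel_codes)][["year", "pod_g"]])
        if not frames:
            raise ValueError("program has no post-founder years")
        return pd.concat(frames, ignore_index=True)

    def control_grand_mean(self) -> float:
        frames = []
        for cycle in self.schedule[1:]:
            table = self.trials[cycle.year].table
            roles = self.line_truth.query("year == @cycle.year").set_index("code")["role"]
            ctl = roles[roles.str.startswith("control")].index
            frames.append(table[table["code"].isin(ctl)]["pod_g"])
        if not frames:
            raise ValueError("program has no control plants")
        return float(pd.concat(frames).mean())

    def gain(self) -> GainEstimate:
        records = self.selection_records()
        model = GainModel.from_dataframe(records)
        return model.fit(self.control_grand_mean())


def simulate_program(
    schedule: Sequence[CycleSpec],
    params: SimulationParams,
    selection: SelectionConfig | None = None,
) -> ProgramResult:
    """Run a multi-year honeycomb selection program on synthetic data.

    Year 1 grows founders (each plant a unique entry when the design is
    D0) with lognormal merits of scale ``founder_g_sigma``; every later
    year grows the sibling lines founded by the previous year's selections
    plus a control.  A child line inherits its mother line's realised
    effect times lognormal segregation noise of scale ``heritability_tau``
    and its dispersion times noise of scale ``sigma_inherit_noise``; the
    bulk-remnant control keeps the base-population effect of one.
    """
    if len(schedule) < 1:
        raise ValueError("empty schedule")
    rng = np.random.default_rng(params.seed)

    trials: dict[int, TrialData] = {}
    scores: dict[int, tuple[pd.DataFrame, pd.DataFrame]] = {}
    selected: dict[int, list[str]] = {}
    ped_rows: list[dict] = []
    truth_rows: list[dict] = []

    base_sigma = float(np.asarray(params.line_sigma, float).mean())

    # founder year: one entry per plant
    first = schedule[0]
    n_founders = first.design.n_plants
    founder_g = np.exp(rng.normal(0, params.founder_g_sigma, size=n_founders))
    line_effects = {c + 1: float(founder_g[c]) for c in range(n_founders)}
    line_sigma = {c + 1: base_sigma for c in range(n_founders)}
    mothers: dict[int, str | None] = {c + 1: None for c in range(n_founders)}
    roles = {c + 1: "selection" for c in range(n_founders)}

    for i, cycle in enumerate(schedule):
        year = cycle.year
        trial = generate_trial(
            cycle.design,
            params,
            rng=rng,
            year=year,
            line_effects=line_effects,
            line_sigma=line_sigma,
            line_ids={c: f"{year}L{c}" for c in line_effects},
            mothers=mothers,
        )
        trials[year] = trial
        n_lines = len(line_effects)
        for c in range(1, n_lines + 1):
            truth_rows.append(
                {
                    "year": year,
                    "code": c,
                    "line_id": f"{year}L{c}",
                    "G": line_effects[c],
                    "sigma": line_sigma[c],
                    "mother_plant_id": mothers[c],
                    "role": roles[c],
                }
            )
        values = pd.Series(
            trial.table["pod_g"].to_numpy(), index=trial.table["plant_id"].to_numpy()
        )
        singleton = "pyi" if cycle.design.n_entries == 1 else "raise"
        plant_scores, line_scores = score_trial(
            trial.layout, values, singleton_lines=singleton
        )
        scores[year] = (plant_scores, line_scores)
        for pid, code in zip(trial.table["plant_id"], trial.table["code"]):
            ped_rows.append(
                {
                    "plant_id": make_uid(year, int(pid)),
                    "year": year,
                    "line_code": int(code),
                    "mother_plant_id": mothers[int(code)],
                    "role": roles[int(code)],
                }
            )

        if i == len(schedule) - 1 or cycle.n_select == 0:
            break

        config = selection if selection is not None else SelectionConfig(
            n_select=cycle.n_select
        )
        picked = select_top(plant_scores, config)
        selected[year] = [make_uid(year, int(p)) for p in picked]

        next_spec = schedule[i + 1].design
        control_policy = "bulk_remnant"
        assignment = advance_generation(
            picked,
            plant_scores,
            line_scores if cycle.design.n_entries > 1 else None,
            next_spec,
            control=control_policy,
        )

        code_of_plant = trial.table.set_index("plant_id")["code"]
        new_effects: dict[int, float] = {}
        new_sigma: dict[int, float] = {}
        new_mothers: dict[int, str | None] = {}
        new_roles: dict[int, str] = {}
        for rec in assignment.itertuples(index=False):
            code = int(rec.code)
            if rec.role == "selection":
                mother_pid = int(rec.mother_plant_id)
                mother_code = int(code_of_plant.loc[mother_pid])
                g_mother = line_effects[mother_code]
                s_mother = line_sigma[mother_code]
                new_effects[code] = float(
                    g_mother * np.exp(rng.normal(0, params.heritability_tau))
                )
                new_sigma[code] = float(
                    s_mother * np.exp(rng.normal(0, params.sigma_inherit_noise))
                )
                new_mothers[code] = make_uid(year, mother_pid)
            else:
                new_effects[code] = 1.0
                new_sigma[code] = base_sigma
                new_mothers[code] = None
            new_roles[code] = rec.role
        line_effects, line_sigma, mothers, roles = (
            new_effects,
            new_sigma,
            new_mothers,
            new_roles,
        )

    pedigree = pd.DataFrame(
        ped_rows,
        columns=["plant_id", "year", "line_code", "mother_plant_id", "role"],
    )
    line_truth = pd.DataFrame(
        truth_rows,
        columns=["year", "code", "line_id", "G", "sigma", "mother_plant_id", "role"],
    )
    return ProgramResult(
        params=params,
        schedule=list(schedule),
        trials=trials,
        scores=scores,
        selected=selected,
        pedigree=pedigree,
        line_truth=line_truth,
    )
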