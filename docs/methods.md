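# Methods

## Design geometry

Plants sit on staggered rows: plant `(row, pos)` is at
`x = pos·dx + (row mod 2)·dx/2`, `y = row·dy`, with `dx` the within-row and
`dy` the between-row spacing (metres). When `dy = (√3/2)·dx` this is an
ideal triangular lattice; the field spacings supported in practice
(1.0 × 0.9 m and 2.0 × 1.8 m, ratio 0.9) are near-ideal, and all geometric
invariants are asserted on the idealised lattice while real spacings are
used for coordinates and distances.

Entry codes follow a cyclic rule that is linear in the axial lattice
coordinates `(row, q)` with `q = pos − ⌊row/2⌋`:

```
code = ((q + row·shift) mod n) + 1
```

equivalently, the starting code advances alternately by `shift` and
`shift+1` from row to row. Linearity in axial coordinates is what makes
the same-code set a true sublattice of index n of the triangular lattice.
The shift is chosen by exhaustive search over `1..n−1`, maximising the
minimum same-code distance on the ideal lattice (ties to the smallest
shift). For Löschian n — expressible as `a² + ab + b²`, e.g. 3, 7, 19 —
the optimum attains exactly `√n·dx`. A one-generator cyclic rule cannot
reach the index-9 equilateral sublattice (its quotient group Z₃×Z₃ is not
cyclic), so D9 layouts attain `√7·dx`; that is the best any cyclic
honeycomb rule can do for nine entries.

A naive rule that is linear in `(row, pos)` directly (ignoring the
half-spacing stagger) tops out at `2·dx` for n = 7 and was rejected: it
breaks the triangular moving grids that the designs are defined by.

## Moving replicates and edge policy

The moving replicate of a plant takes, for each code, the nearest plant of
that code (the centre stands for its own code; distance ties, stabilised
by rounding squared distances to 9 decimals, go to the smallest plant id).
On an interior D7 plant this is the centre plus its six first-ring
neighbours; on D19 the centre plus the first two rings. The *interior
replicate radius* is computed on the infinite lattice; a plant whose
replicate radius exceeds 1.5× that radius is flagged incomplete. Under the
default `nearest_per_code` policy every plant is scored but auditable via
the flag; under `exclude_incomplete` border plants are left unscored.
Unreplicated (D0) layouts, where every plant is its own entry, use the 18
nearest neighbours (two hexagonal rings) as the moving ring so that
first-cycle selection is still spatially adjusted.

## Phenotyping equations

`pYI = (x/x̄_r)²` with `x̄_r` the mean over the replicate members (centre
included — a complete replicate contains the centre's code; excluding it
is supported through the replicate object). `SI = (x̄/s)²` uses the sample
(n−1) standard deviation of the plant's sibling line, the plant itself
included. `pPE = pYI·SI`, `sPE = SI·mean(pYI)`. All equations accept any
non-negative single-plant trait in grams (pod, fodder, root). Missing
plants (dead, unharvested) are dropped from their own scoring and from
their neighbours' ring means, which renormalise over the remaining
members. A line whose scored values are identical has an undefined SI;
that is surfaced per line in the score table rather than raised, so one
degenerate line does not abort a trial. Singleton lines (D0) either raise
or fall back to `pPE = pYI`, by explicit option.

Percent-of-best columns are `100·v/max` rounded half away from zero, with
the maximum taken over **all** lines in the trial, not only displayed
ones. Selection pressure is reported to one decimal. Selection ties break
by higher raw trait value, then smaller plant id, making selection
deterministic and order-independent; next-cycle codes are assigned to
selected plants in order of their mother line's sPE, then their own pPE,
with the last code reserved for the control.

## Gain estimation

The rate of gain is the OLS slope (statsmodels) of single-plant yields of
the selected families on calendar year — individual replications, not
yearly means, so the fit is weighted by the plants actually grown.
`relative gain = 100·slope/control grand mean` (% per year). Student and
Welch two-sample t statistics and the adjusted Fisher–Pearson skewness are
provided for distribution-shift and control comparisons; both are
cross-checked in the tests against hand-computed formulas.

## Synthetic trials

A plant of line *i* at position *p* in treatment zone *z* yields

```
y_p = base · G_i · F(x_p, y_p) · T_z · exp(ε_p),   ε_p ~ N(0, σ_i)
```

* `base` — trial yield scale, default 400 g: the order of an unselected
  cowpea-type landrace at nil-competition spacings.
* `G_i` — multiplicative line merits (founders: lognormal, log-sd 0.25).
* `σ_i` — per-line lognormal dispersion, default 0.35; its inverse is the
  line's true stability. Multiplicative noise keeps single-plant yields
  positive and right-skewed, as unselected material is; additive Gaussian
  noise is available as an option.
* `F` — fertility surface: `exp(planar gradient + Gaussian patches)`,
  normalised to mean 1 over the layout; gradient log-range default 0.4
  (≈ ±20% around the mean), patch log-amplitude sd 0.15. Drawn
  deterministically from the seed.
* `T_z` — treatment-zone multipliers (default 1.25/1.00/0.85 for ground
  cover / standard / reduced fertigation) on contiguous row-block zones:
  thirds of the rows, so a 30-row D19 field splits 190/190/190.
* Fodder and root derive from the implied total biomass partitioned by
  per-line allocation fractions (default 0.40/0.45/0.15 pod/fodder/root);
  the pod share rises by 0.08 per unit of `G_i − 1`, so selection for pod
  yield shifts allocation away from fodder and root, qualitatively
  reproducing the indirect response seen in such programs. Small
  (log-sd 0.08) independent noise is added to both.

Across cycles a selected plant founds a sibling line whose effect is its
mother line's realised effect times `exp(N(0, τ))` with transmission
(heritability) scale τ = 0.10, and whose dispersion is inherited with
log-sd 0.10 noise; the bulk-remnant control keeps the base-population
effect of 1. No explicit genetics (loci, selfing) is modelled — lognormal
transmission is the simplest mechanism that yields sustained response and
sibling-line divergence. Within a year the generator draws no common year
effect, so the null program (equal merits, τ = 0) has a flat expected
yield trajectory.

What the generator does **not** emulate: interplant competition (the
designs assume nil-competition spacings, so none is simulated), harvest-
by-harvest phenology, pest/weather shocks, seed-supply constraints, and
genotype-specific treatment interactions beyond the multiplicative model.
Passing tests therefore validate the pipeline's arithmetic and its
statistical behaviour under the stated generative model, not field
performance.

## Simulation studies and problem sizes

* **Oracle equivalence** — 100 random small trials (n ∈ {3,4,5,7}, 3–6
  reps, random spacings, occasional missing plants) scored both by the
  vectorised pipeline and by an independent nested-loop recomputation;
  agreement to 1e−12 relative tolerance.
* **Zone composition of selections** — D7 × 21 (147 plants), gradient
  log-range 1.2 aligned with three row-block zones, equal merits, top 5
  plants per seed over 100 seeds, chi-square against eligible-plant
  proportions. Result: raw-yield selection piles into the high-fertility
  zone (χ² ≈ 730); pYI-ranked selection is zone-neutral (p ≈ 0.1); pPE
  suppresses the raw bias by an order of magnitude but retains a residual
  *anti*-fertility tilt (χ² ≈ 87). The mechanism is a conditioning
  artifact: with the field gradient dominating within-line dispersion, a
  line attains a high SI precisely when its high-fertility plants drew low
  noise, so that line's best-pYI members sit in the low zones. The effect
  vanishes at zero gradient and grows monotonically with gradient
  strength; it is a real property of the pPE estimator under gradient-
  dominated dispersion, documented here rather than hidden by weaker test
  conditions.
* **Gain recovery** — nine-cycle programs (D0 with 60 founders, then
  D7 × 10 advancing 6 plants per year), 100 seeds per arm. With heritable
  effects the fitted slope is positive in ≈ 97–99% of runs; with heritable
  variance removed the mean slope over runs sits within two standard
  errors of zero. These sizes keep the full suite within a few minutes on
  one CPU while leaving the conclusions stable across seeds.

## Known limitations

* D9 (and any non-Löschian n) cannot achieve the `√n` same-code grid under
  a cyclic rule; replicates are still complete, just slightly less
  compact.
* The completeness flag compares against the infinite-lattice interior
  radius; in narrow fields (e.g. a single row) all plants of wide designs
  are flagged incomplete, which is intended.
* SI requires ≥ 2 siblings and non-identical values; first-cycle (D0)
  ranking is effectively by pYI alone.
* The pPE zone-composition artifact above means pPE selection under very
  strong gradients is not perfectly spatially neutral even though pYI is;
  users evaluating extremely heterogeneous fields may wish to compare
  pYI- and pPE-based rankings.
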