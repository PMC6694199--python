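# honeycomb-selection

Single-plant field phenotyping and non-stop selection analytics for plant
breeders: honeycomb selection designs, the plant and sibling-line
phenotyping equations, multi-year selection with pedigree tracking, and
genetic-gain estimation — with a synthetic field-trial generator so every
stage can be exercised and validated against known ground truth.

## The problem

When plants are evaluated one by one (landraces, early segregating
generations, any material without enough seed for plot replication), soil
heterogeneity masks genetic merit and interplant competition favours the
wrong plants. Honeycomb selection designs answer both problems: plants are
grown on a wide-spaced triangular (hexagonal) lattice, the n entries of a
trial are arranged so that

* every plant is the centre of a **moving complete replicate** — its
  nearest neighbours containing each entry exactly once — which provides a
  local control mean `x̄_r`, and
* plants of the same entry form a triangular sublattice with same-entry
  distance `sqrt(n)` plant spacings (exactly, when n is a Löschian number:
  3, 7, 19, …), so every entry samples the whole field evenly.

Plants are ranked by the **plant phenotyping (prognostic) equation**

```
pPE = (x / x̄_r)² · (x̄ / s)²  =  pYI · SI
```

where `pYI = (x/x̄_r)²` is the spatially adjusted plant yield index and
`SI = (x̄/s)²` is the stability index (squared inverse coefficient of
variation) of the plant's sibling line — the plants sharing its mother.
Sibling lines are ranked by `sPE = SI · mean(pYI)` over the line's
members. The rate of genetic gain across selection cycles is the OLS slope
of single-plant yields of the selected families on calendar year, and the
relative gain divides that slope by the grand mean of the control.

## Worked example

```python
import pandas as pd
import honeycomb as hc

# a D19 design, 30 plants per entry, at 2.0 m x 1.8 m spacings
layout = hc.generate_layout(hc.DesignSpec(19, 30, 2.0, 1.8))
print(hc.verify_layout(layout))

# a synthetic trial on that field, then score it
trial = hc.generate_trial(layout, hc.SimulationParams(seed=42))
values = pd.Series(trial.table.pod_g.values, index=trial.table.plant_id.values)
plants, lines = hc.score_trial(layout, values)
print(hc.summary_report(lines, top=3, control=19).to_string(index=False))
```

prints

```
plants: 570
codes: 19 (counts 30..30)
min same-code distance: 8.773 m
interior replicate radius: 4.118 m
complete replicates: 83.5%
 line_id  n       mean  pct_best_mean        SI  pct_best_SI       sPE  pct_best_sPE
      11 30 422.620639             87 10.670046          100 11.240446           100
      13 30 459.796130             95  9.067519           85 11.082928            99
      14 30 468.038460             96  8.193247           77  9.669793            86
      19 30 377.854015             78  4.728992           44  3.743167            33
```

The 570 plants carry each of the 19 entry codes exactly 30 times; plants
of one entry are at least `sqrt(19) x 2.0 m ≈ 8.7 m` apart, so each entry
tiles the whole field. Line 11 is not the highest yielding on the raw mean
(87% of best), but its high stability (best SI) gives it the top sPE —
exactly the kind of re-ranking the equations exist for. Line 19 here is
the unselected control: competitive on mean yield, but far less stable.

A whole multi-year program runs off one call:

```python
schedule = hc.default_schedule(years=9, founders=60, entries=7, reps=10)
result = hc.simulate_program(schedule, hc.SimulationParams(seed=42))
print(result.gain().summary())
```

```
Rate-of-gain regression (OLS, yield ~ year)
  n observations     480
  slope              48.16 g/plant/year (SE 6)
  intercept          554.3 g
  R-squared          0.119
  p(slope)           7.79e-15
  control grand mean 431.2 g
  relative gain      11.17 % per year
```

A positive, highly significant slope: pPE selection with heritable line
effects produces sustained gain, here about 11% of the control mean per
year. `result.pedigree` holds every plant's mother link, so
`hc.trace_lineage` can follow any terminal line back to its founder plant.

There is also a CLI mirroring the library:
`honeycomb design | verify | score | select | advance | gain | simulate |
report` (see `honeycomb --help`).

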