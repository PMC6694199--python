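import numpy as np
import pandas as pd
import pytest

from honeycomb import (
    DesignSpec,
    SelectionConfig,
    SimulationParams,
    advance_generation,
    default_schedule,
    select_top,
    selection_pressure,
    simulate_program,
    trace_lineage,
)


def _scores(rng, n=50):
    return pd.DataFrame(
        {
            "plant_id": np.arange(1, n + 1),
            "line_id": rng.integers(1, 8, n),
            "x": rng.lognormal(6, 0.4, n),
            "pPE": rng.lognormal(0, 1, n),
        }
    )


class TestSelectTop:
    def test_matches_sort_then_slice(self, rng):
        scores = _scores(rng)
        picked = select_top(scores, SelectionConfig(n_select=12))
        oracle = (
            scores.sort_values(["pPE", "x", "plant_id"], ascending=[False, False, True])
            .head(12)["plant_id"]
            .tolist()
        )
        assert picked == oracle

    def test_order_invariance(self, rng):
        scores = _scores(rng)
        shuffled = scores.sample(frac=1.0, random_state=7).reset_index(drop=True)
        cfg = SelectionConfig(n_select=10)
        assert select_top(scores, cfg) == select_top(shuffled, cfg)

    def test_all_equal_ties_go_to_smallest_ids(self):
        scores = pd.DataFrame(
            {"plant_id": [5, 3, 9, 1], "x": 10.0, "pPE": 2.0}
        )
        assert select_top(scores, SelectionConfig(n_select=2)) == [1, 3]

    def test_yield_breaks_ppe_ties(self):
        scores = pd.DataFrame(
            {"plant_id": [1, 2, 3], "x": [5.0, 9.0, 7.0], "pPE": [2.0, 2.0, 2.0]}
        )
        assert select_top(scores, SelectionConfig(n_select=1)) == [2]

    def test_pressure_config_and_errors(self, rng):
        scores = _scores(rng, 100)
        assert len(select_top(scores, SelectionConfig(pressure=5.0))) == 5
        with pytest.raises(ValueError):
            select_top(scores, SelectionConfig(n_select=101))
        with pytest.raises(ValueError):
            SelectionConfig(n_select=5, pressure=5.0)
        with pytest.raises(ValueError):
            SelectionConfig()

    def test_pressure_monotonicity(self, rng):
        """Selecting fewer plants never lowers the minimum selected pPE."""
        scores = _scores(rng)
        indexed = scores.set_index("plant_id")["pPE"]
        last = -np.inf
        for k in (20, 10, 5, 1):
            m = indexed.loc[select_top(scores, SelectionConfig(n_select=k))].min()
            assert m >= last
            last = m

    def test_unscorable_plants_not_eligible(self):
        scores = pd.DataFrame(
            {"plant_id": [1, 2, 3], "x": [1.0, 2.0, 3.0], "pPE": [np.nan, 1.0, 2.0]}
        )
        assert select_top(scores, SelectionConfig(n_select=2)) == [3, 2]
        with pytest.raises(ValueError):
            select_top(scores, SelectionConfig(n_select=3))


class TestSelectionPressure:
    def test_first_year_value(self):
        assert selection_pressure(12, 315) == 3.8

    def test_bounds(self):
        assert selection_pressure(100, 100) == 100.0
        assert selection_pressure(1, 100) == 1.0
        with pytest.raises(ValueError):
            selection_pressure(0, 100)
        with pytest.raises(ValueError):
            selection_pressure(5, 0)


class TestAdvanceGeneration:
    def _scored(self, k):
        plants = pd.DataFrame(
            {
                "plant_id": np.arange(1, k + 1),
                "line_id": np.arange(1, k + 1),
                "x": np.linspace(200, 100, k),
                "pPE": np.linspace(20, 10, k),
            }
        )
        lines = pd.DataFrame(
            {"line_id": np.arange(1, k + 1), "sPE": np.linspace(9, 4, k)}
        )
        return plants, lines

    def test_eighteen_selections_plus_control_fill_d19(self):
        plants, lines = self._scored(18)
        out = advance_generation(
            plants["plant_id"].tolist(), plants, lines, DesignSpec(19, 30)
        )
        assert list(out["code"]) == list(range(1, 20))
        assert (out["role"].iloc[:18] == "selection").all()
        assert out["role"].iloc[18] == "control_bulk"
        # ordered by mother-line sPE: plant 1 had the best line
        assert out["mother_plant_id"].iloc[0] == 1

    def test_two_selections_single_plant_control_d3(self):
        plants, lines = self._scored(2)
        out = advance_generation(
            [1, 2], plants, lines, DesignSpec(3, 78), control="single_plant_progeny"
        )
        assert list(out["code"]) == [1, 2, 3]
        assert out["role"].iloc[2] == "control_single"

    def test_underfill_errors_unless_padded(self):
        plants, lines = self._scored(1)
        with pytest.raises(ValueError):
            advance_generation([1], plants, lines, DesignSpec(3, 10))
        out = advance_generation([1], plants, lines, DesignSpec(3, 10), allow_pad=True)
        assert list(out["mother_plant_id"]) == [1, 1, None]

    def test_overfill_errors(self):
        plants, lines = self._scored(5)
        with pytest.raises(ValueError):
            advance_generation([1, 2, 3, 4, 5], plants, lines, DesignSpec(3, 10))


@pytest.fixture(scope="module")
def program():
    schedule = default_schedule(years=4, founders=24, entries=3, reps=8)
    return simulate_program(schedule, SimulationParams(seed=9))


class TestPedigree:
    def test_every_terminal_traces_to_a_founder(self, program):
        ped = program.pedigree
        last_year = max(program.trials)
        terminals = ped[(ped.year == last_year) & (ped.role == "selection")][
            "plant_id"
        ].head(10)
        for t in terminals:
            chain = trace_lineage(ped, t)
            assert chain["year"].iloc[0] == 1
            assert list(chain["year"]) == sorted(chain["year"])
            assert chain["plant_id"].iloc[-1] == t

    def test_non_founder_mothers_were_selected(self, program):
        ped = program.pedigree
        for year, uids in program.selected.items():
            next_year = year + 1
            mothers = set(
                ped[(ped.year == next_year) & (ped.role == "selection")][
                    "mother_plant_id"
                ]
            )
            assert mothers <= set(uids)

    def test_sibling_divergence(self):
        ped = pd.DataFrame(
            {
                "plant_id": ["1:1", "2:1", "2:2", "3:1", "3:2"],
                "year": [1, 2, 2, 3, 3],
                "line_code": [1, 1, 1, 1, 2],
                "mother_plant_id": [None, "1:1", "1:1", "2:1", "2:2"],
                "role": ["selection"] * 5,
            }
        )
        a = trace_lineage(ped, "3:1")
        b = trace_lineage(ped, "3:2")
        assert a["plant_id"].iloc[0] == b["plant_id"].iloc[0] == "1:1"
        assert a["plant_id"].iloc[-1] != b["plant_id"].iloc[-1]

    def test_founder_single_element_trace(self, program):
        founders = program.pedigree[program.pedigree.year == 1]["plant_id"]
        chain = trace_lineage(program.pedigree, founders.iloc[0])
        assert len(chain) == 1

    def test_broken_chain_raises(self):
        ped = pd.DataFrame(
            {
                "plant_id": ["2:1"],
                "year": [2],
                "line_code": [1],
                "mother_plant_id": ["1:99"],
                "role": ["selection"],
            }
        )
        with pytest.raises(ValueError):
            trace_lineage(ped, "2:1")
        with pytest.raises(KeyError):
            trace_lineage(ped, "9:9")
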