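import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from honeycomb import (
    DesignSpec,
    SimulationParams,
    generate_layout,
    generate_trial,
    moving_replicate,
    percent_of_best,
    plant_phenotyping_equation,
    plant_yield_index,
    ring_mean,
    score_trial,
    sibling_phenotyping_equation,
    stability_index,
    treatment_zones,
)
from oracles import brute_force_scores


def _values(layout, fill=1.0):
    return pd.Series(fill, index=layout.plant_ids, dtype=float)


class TestRingMean:
    def test_uniform_field(self, d7_layout):
        vals = _values(d7_layout, 3.5)
        for pid in d7_layout.plant_ids[:5]:
            assert ring_mean(d7_layout, vals, int(pid)) == pytest.approx(3.5)

    def test_center_eight_neighbours_one(self, d7_layout):
        plants = d7_layout.plants
        mid = int(plants[(plants.row == 3) & (plants.pos == 3)]["plant_id"].iloc[0])
        rep = moving_replicate(d7_layout, mid)
        vals = _values(d7_layout, 1.0)
        vals.loc[mid] = 8.0
        assert ring_mean(d7_layout, vals, mid) == pytest.approx(2.0)
        assert len(rep) == 7

    def test_matches_brute_force(self, d7_layout, rng):
        vals = pd.Series(
            rng.lognormal(6, 0.4, d7_layout.n_plants), index=d7_layout.plant_ids
        )
        per_plant, _ = brute_force_scores(
            d7_layout.plants.to_dict("records"), vals.to_dict()
        )
        for pid in d7_layout.plant_ids:
            assert ring_mean(d7_layout, vals, int(pid)) == pytest.approx(
                per_plant[pid]["ring_mean"], rel=1e-12
            )


class TestIndices:
    def test_plant_yield_index(self):
        assert plant_yield_index(5.0, 5.0) == pytest.approx(1.0)
        assert plant_yield_index(10.0, 5.0) == pytest.approx(4.0)
        with pytest.raises(ValueError):
            plant_yield_index(1.0, 0.0)

    @given(
        x=st.floats(0.1, 1e4),
        ring=st.floats(0.1, 1e4),
        c=st.floats(0.01, 1e3),
    )
    def test_pyi_scale_invariant(self, x, ring, c):
        assert plant_yield_index(c * x, c * ring) == pytest.approx(
            plant_yield_index(x, ring), rel=1e-9
        )

    def test_stability_index_forced_arithmetic(self):
        assert stability_index([2.0, 4.0]) == pytest.approx(4.5)

    def test_stability_index_degenerate(self):
        with pytest.raises(ValueError):
            stability_index([3.0, 3.0])
        with pytest.raises(ValueError):
            stability_index([3.0])

    def test_stability_index_matches_two_pass(self, rng):
        vals = rng.lognormal(0, 0.5, 30)
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        assert stability_index(vals) == pytest.approx(mean**2 / var, rel=1e-12)

    def test_equation_products(self):
        assert plant_phenotyping_equation(1.0, 7.3) == pytest.approx(7.3)
        assert plant_phenotyping_equation(4.0, 2.5) == pytest.approx(10.0)
        assert sibling_phenotyping_equation(4.5, 2.0) == pytest.approx(9.0)
        with pytest.raises(ValueError):
            plant_phenotyping_equation(-1.0, 1.0)


class TestScoreTrial:
    def test_matches_brute_force_oracle(self, d7_layout, rng):
        vals = pd.Series(
            rng.lognormal(6, 0.4, d7_layout.n_plants), index=d7_layout.plant_ids
        )
        plants, lines = score_trial(d7_layout, vals)
        pp, pl = brute_force_scores(
            d7_layout.plants.to_dict("records"), vals.to_dict()
        )
        for rec in plants.itertuples(index=False):
            assert rec.pYI == pytest.approx(pp[rec.plant_id]["pYI"], rel=1e-12)
            assert rec.pPE == pytest.approx(pp[rec.plant_id]["pPE"], rel=1e-12)
        for rec in lines.itertuples(index=False):
            assert rec.SI == pytest.approx(pl[rec.line_id]["SI"], rel=1e-12)
            assert rec.sPE == pytest.approx(pl[rec.line_id]["sPE"], rel=1e-12)

    def test_spe_identity(self, d7_layout, rng):
        vals = pd.Series(
            rng.lognormal(6, 0.3, d7_layout.n_plants), index=d7_layout.plant_ids
        )
        _, lines = score_trial(d7_layout, vals)
        np.testing.assert_allclose(lines["sPE"], lines["SI"] * lines["mean_pYI"], rtol=1e-12)

    def test_uniform_field_si_undefined(self, d7_layout):
        plants, lines = score_trial(d7_layout, _values(d7_layout, 5.0))
        assert np.allclose(plants["pYI"], 1.0)
        assert lines["SI"].isna().all()
        assert (lines["note"] == "zero standard deviation: SI undefined").all()

    def test_missing_values_renormalise_ring_means(self, d7_layout, rng):
        vals = pd.Series(
            rng.lognormal(6, 0.4, d7_layout.n_plants), index=d7_layout.plant_ids
        )
        dead = int(d7_layout.plant_ids[10])
        vals.loc[dead] = np.nan
        plants, _ = score_trial(d7_layout, vals)
        assert not plants.set_index("plant_id").loc[dead, "scored"]
        assert np.isnan(plants.set_index("plant_id").loc[dead, "pYI"])
        values_or_none = {
            int(k): (None if np.isnan(v) else float(v)) for k, v in vals.items()
        }
        pp, _ = brute_force_scores(
            d7_layout.plants.to_dict("records"), values_or_none
        )
        for rec in plants.itertuples(index=False):
            if rec.plant_id == dead:
                continue
            assert rec.ring_mean == pytest.approx(
                pp[rec.plant_id]["ring_mean"], rel=1e-12
            )

    def test_singleton_lines_raise_or_fall_back(self):
        d0 = generate_layout(DesignSpec(1, 24))
        vals = pd.Series(
            np.linspace(100, 500, 24), index=d0.plant_ids
        )
        with pytest.raises(ValueError):
            score_trial(d0, vals)
        plants, lines = score_trial(d0, vals, singleton_lines="pyi")
        # pPE falls back to pYI when a plant has no siblings
        np.testing.assert_allclose(plants["pPE"], plants["pYI"])
        assert (lines["note"] == "singleton").all()

    def test_trait_genericity_three_traits(self, d7_layout):
        params = SimulationParams(seed=11)
        trial = generate_trial(d7_layout, params)
        t = trial.table.set_index("plant_id")
        for col in ("pod_g", "fodder_g", "root_g"):
            plants, lines = score_trial(d7_layout, t[col])
            assert len(lines) == 7
            assert plants["pYI"].notna().all()

    def test_gradient_suppression(self):
        """With a strong multiplicative gradient and equal merits, pYI varies
        far less across field zones than the raw trait does."""
        layout = generate_layout(DesignSpec(7, 21))
        params = SimulationParams(
            gradient_strength=1.2,
            gradient_angle=np.pi / 2,
            n_bumps=0,
            treatment_multipliers=(1.0, 1.0, 1.0),
            seed=5,
        )
        trial = generate_trial(layout, params)
        vals = pd.Series(
            trial.table["pod_g"].to_numpy(), index=trial.table["plant_id"].to_numpy()
        )
        plants, _ = score_trial(layout, vals, edge_policy="exclude_incomplete")
        df = plants[plants["scored"]].copy()
        df["zone"] = trial.truth.zone.loc[df["plant_id"]].to_numpy()
        zone_raw = df.groupby("zone")["x"].mean() / df["x"].mean()
        zone_pyi = df.groupby("zone")["pYI"].mean() / df["pYI"].mean()
        assert zone_pyi.var() < 0.05 * zone_raw.var()


class TestPercentOfBest:
    def test_printed_2010_examples(self):
        means = np.array([398, 382, 344, 276], dtype=float)
        assert list(percent_of_best(means)) == [100, 96, 86, 69]
        si = np.array([7.99, 6.43, 7.53, 4.57])
        assert list(percent_of_best(si)) == [100, 80, 94, 57]
        spe = np.array([11.6, 8.6, 8.1, 3.18])
        assert list(percent_of_best(spe)) == [100, 74, 70, 27]

    def test_round_half_away_from_zero(self):
        assert list(percent_of_best([151.0, 200.0])) == [76, 100]

    def test_errors(self):
        with pytest.raises(ValueError):
            percent_of_best([])
        with pytest.raises(ValueError):
            percent_of_best([0.0, 0.0])
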