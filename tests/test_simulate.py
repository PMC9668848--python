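"""Compartment model, exact tracer solution and dataset generation."""

import numpy as np
import pandas as pd
import pytest

from pulsetrace import constants as k
from pulsetrace.simulate import (
    COMPARTMENTS,
    CompartmentModel,
    NoiseModel,
    StudyDesign,
    default_model,
    generate_dataset,
    solve_tracer,
)


def _chain_model(rates_13c, pulse=100.0):
    return CompartmentModel(
        rates_13c=rates_13c,
        rates_15n={("soil_mineral_N", "n2o_efflux"): 0.1},
        pool_carbon={"shoot": 100.0},
        pool_nitrogen={"soil_mineral_N": 1.0},
        pulse_13C=pulse,
    )


def _euler_chain(k1, k2, pulse, t_end, dt=1e-4):
    """Independent brute-force integration of shoot -> root -> CO2."""
    shoot, root, co2 = pulse, 0.0, 0.0
    steps = int(round(t_end / dt))
    for _ in range(steps):
        d_shoot = -k1 * shoot
        d_root = k1 * shoot - k2 * root
        d_co2 = k2 * root
        shoot += dt * d_shoot
        root += dt * d_root
        co2 += dt * d_co2
    return shoot, root, co2


class TestSolveTracer:
    def test_no_transfer_identity(self):
        m = _chain_model({})
        # no 13C edges at all: shoot retains the full pulse forever
        m = CompartmentModel(
            rates_13c={("shoot", "co2_efflux"): 0.0},
            rates_15n={("soil_mineral_N", "n2o_efflux"): 0.1},
            pool_carbon={"shoot": 100.0},
            pool_nitrogen={"soil_mineral_N": 1.0},
            pulse_13C=100.0,
        )
        with pytest.raises(ValueError):
            # zero-rate edge leaves the shoot with no path to an efflux
            solve_tracer(m, [0, 1], "13C")
        m2 = _chain_model({("shoot", "co2_efflux"): 1e-12})
        tr = solve_tracer(m2, [0, 1, 2, 20], "13C")
        assert np.allclose(tr["shoot"], 100.0, rtol=1e-9)

    def test_exponential_decay_closed_form(self):
        rate = 0.8
        m = _chain_model({("shoot", "co2_efflux"): rate})
        tr = solve_tracer(m, [0, 1, 2, 5], "13C")
        for day in (0, 1, 2, 5):
            assert tr.loc[day, "shoot"] == pytest.approx(100.0 * np.exp(-rate * day), rel=1e-12)

    def test_two_stage_chain_matches_euler_oracle(self):
        k1 = k2 = 0.5
        m = _chain_model({("shoot", "root"): k1, ("root", "co2_efflux"): k2})
        tr = solve_tracer(m, [0, 2], "13C")
        shoot_e, root_e, co2_e = _euler_chain(k1, k2, 100.0, 2.0)
        assert tr.loc[2, "shoot"] == pytest.approx(shoot_e, rel=1e-3)
        assert tr.loc[2, "root"] == pytest.approx(root_e, rel=1e-3)
        assert tr.loc[2, "co2_efflux"] == pytest.approx(co2_e, rel=1e-3)
        # equal-rate two-stage closed form: x2(t) = pulse * k t e^(-k t)
        assert tr.loc[2, "root"] == pytest.approx(100.0 * k1 * 2 * np.exp(-k1 * 2), rel=1e-12)

    def test_mass_conservation_default_model(self):
        m = default_model()
        for element in ("13C", "15N"):
            tr = solve_tracer(m, [0, 1, 2, 5, 10, 20], element)
            totals = tr.sum(axis=1)
            assert np.allclose(totals, m.pulse(element), rtol=1e-9)

    def test_rejects_mass_creating_matrix(self):
        m = _chain_model({("shoot", "root"): 0.5, ("root", "co2_efflux"): 0.2})
        bad = np.array(m.matrix("13C"))

        class Broken(CompartmentModel):
            def matrix(self, element):
                mm = super().matrix(element)
                mm[0, 0] += 0.3  # inject net mass creation
                return mm

        broken = Broken(
            rates_13c=m.rates_13c, rates_15n=m.rates_15n,
            pool_carbon=m.pool_carbon, pool_nitrogen=m.pool_nitrogen,
        )
        with pytest.raises(ValueError, match="creates tracer mass|non-dissipative"):
            broken.validate("13C")
        assert bad.sum(axis=0).max() < 1e-12

    def test_rejects_negative_rate_and_unsorted_days(self):
        with pytest.raises(ValueError):
            _chain_model({("shoot", "co2_efflux"): -0.1}).matrix("13C")
        m = _chain_model({("shoot", "co2_efflux"): 0.1})
        with pytest.raises(ValueError):
            solve_tracer(m, [2, 1], "13C")

    def test_monotone_effect_propagation(self):
        """Scaling a donor->receiver rate up increases receiver content at small t."""
        base = default_model()
        up = base.with_multipliers({"shoot->root": 1.05})
        t_small = [0, 0.5]
        low = solve_tracer(base, t_small, "13C").loc[0.5, "root"]
        high = solve_tracer(up, t_small, "13C").loc[0.5, "root"]
        assert high > low


class TestStudyDesign:
    def test_factorial_has_36_plots(self):
        design = StudyDesign()
        table = design.plot_table()
        assert len(table) == 36 == design.n_plots
        assert table["plot_id"].is_unique
        cell_sizes = table.groupby(["site", "management", "treatment"]).size()
        assert (cell_sizes == 3).all()

    def test_every_plot_sampled_every_day(self, noiseless_dataset):
        counts = noiseless_dataset.pools.groupby("plot_id")["day"].nunique()
        assert (counts == 6).all()

    def test_multiplier_composition(self):
        design = StudyDesign()
        mult = design.cell_multipliers("intensive", "drought")
        assert mult["pulse_13C"] == pytest.approx(0.71 * 0.9)


class TestGenerateDataset:
    def test_same_seed_identical_tables(self):
        a = generate_dataset(StudyDesign(seed=42))
        b = generate_dataset(StudyDesign(seed=42))
        for name in a._TABLES:
            assert getattr(a, name).to_csv() == getattr(b, name).to_csv()

    def test_zero_noise_zero_effect_makes_treatments_identical(self):
        design = StudyDesign(
            seed=1,
            noise=NoiseModel.zero(),
            management_multipliers={},
            treatment_multipliers={},
        )
        ds = generate_dataset(design)
        piv = ds.pools.pivot_table(
            index=["site", "management", "day", "pool"],
            columns="treatment",
            values="d13C_permil",
        )
        assert np.allclose(piv["control"], piv["drought"])

    def test_shoot_excess_declines_from_day_zero(self, noiseless_dataset):
        truth = noiseless_dataset.truth_excess
        shoot = truth.query("compartment == 'shoot' and element == '13C'")
        for _, sub in shoot.groupby("plot_id"):
            vals = sub.sort_values("day")["atom_percent_excess"].to_numpy()
            assert vals[0] == vals.max()
            assert np.all(np.diff(vals) < 0)

    def test_calibrated_shoot_enrichment_scale(self, noiseless_dataset):
        """Extensive control shoots: ~0.5 atom % at day 0, ~0.12 at day 1."""
        truth = noiseless_dataset.truth_excess.merge(
            noiseless_dataset.plots[["plot_id", "management", "treatment"]], on="plot_id"
        )
        ext = truth.query(
            "compartment == 'shoot' and element == '13C' "
            "and management == 'extensive' and treatment == 'control'"
        )
        day0 = ext.query("day == 0")["atom_percent_excess"].mean()
        day1 = ext.query("day == 1")["atom_percent_excess"].mean()
        assert 0.4 < day0 < 0.6
        assert 0.09 < day1 < 0.16

    def test_baseline_cores_four_per_field(self, noiseless_dataset):
        per_field = noiseless_dataset.baseline_pools.groupby("field")["core"].nunique()
        assert (per_field == 4).all()
        assert len(per_field) == 6  # 3 sites x 2 managements
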