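"""Simulator: limiting cases, conservation, dilution, observation model."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from befpipe.assays import CalibrationModel, CONTROL_ID
from befpipe.design import Community, IsolatePool, Isolate
from befpipe.simulate import (
    ObsNoise,
    apply_dilution,
    default_params,
    make_scenario,
    observe,
    simulate_microcosm,
)

POOL4 = IsolatePool(
    [
        Isolate("a", "Testus", 101),
        Isolate("b", "Testus", 102),
        Isolate("c", "Testus", 103),
        Isolate("d", "Testus", 103),  # shares a fragment with c
    ]
)


def params4(**kwargs):
    p = default_params(POOL4, seed=0)
    for key, val in kwargs.items():
        setattr(p, key, val)
    return p


class TestLimitingCases:
    def test_starvation_decay_and_zero_co2(self):
        """With no resources the population decays at the death rate and
        respires nothing."""
        p = params4(c_labile0=0.0, c_recal0=0.0, stock_labile=0.0,
                    stock_recal=0.0)
        truth = simulate_microcosm(
            Community("m", frozenset({"a"})), p, sample_days=(7,)
        )
        # discrete Euler decay: (1 - m*dt)^(steps)
        expect = 500.0 * (1 - p.death_rate * p.dt) ** 70
        assert truth.total_cells[0] == pytest.approx(expect, rel=1e-9)
        assert truth.co2_cumulative[0] == 0.0

    def test_non_interacting_disjoint_members_match_monocultures(self):
        """alpha = 0 + private pools + per-member inocula: each member's
        trajectory in the pair equals its monoculture trajectory."""
        p = params4(resource_mode="disjoint", inoculum_mode="per_member")
        p.alpha[:] = 0.0
        pair = simulate_microcosm(
            Community("p", frozenset({"a", "b"})), p, sample_days=(7, 28)
        )
        for iso in ("a", "b"):
            mono = simulate_microcosm(
                Community("m", frozenset({iso})), p, sample_days=(7, 28)
            )
            k = pair.members.index(iso)
            assert pair.cells[:, k] == pytest.approx(
                mono.cells[:, 0], rel=1e-9
            )
            assert pair.co2_interval[:, k] == pytest.approx(
                mono.co2_interval[:, 0], rel=1e-9
            )

    def test_strong_antagonism_underyields_monoculture_sum(self):
        """Strongly negative symmetric interactions depress total day-7
        CO2 below the sum of the two monocultures."""
        p = params4()
        p.alpha[:] = 0.0
        p.alpha[0, 1] = p.alpha[1, 0] = -5e-5
        pair = simulate_microcosm(
            Community("p", frozenset({"a", "b"})), p, sample_days=(7,)
        )
        mono_sum = sum(
            simulate_microcosm(
                Community("m", frozenset({iso})), p, sample_days=(7,)
            ).co2_cumulative[0]
            for iso in ("a", "b")
        )
        assert pair.co2_cumulative[0] < mono_sum


class TestConservation:
    @pytest.mark.parametrize("members", [{"a"}, {"a", "b"}, {"a", "b", "c", "d"}])
    def test_mass_balance_shared(self, members):
        truth = simulate_microcosm(
            Community("m", frozenset(members)), params4(), sample_days=(7, 28, 49)
        )
        assert truth.mass_balance_error < 1e-9

    def test_mass_balance_disjoint(self):
        p = params4(resource_mode="disjoint")
        truth = simulate_microcosm(
            Community("m", frozenset({"a", "b"})), p, sample_days=(7, 49)
        )
        assert truth.mass_balance_error < 1e-9

    def test_cumulative_co2_non_decreasing(self):
        truth = simulate_microcosm(
            Community("m", frozenset({"a", "b"})), params4(),
            sample_days=(7, 28, 49),
        )
        assert np.all(np.diff(truth.co2_cumulative) >= 0)
        assert np.all(truth.cells >= 0)


class TestDilution:
    def test_exact_fractions(self):
        p = params4()
        cells = np.array([1000.0, 2000.0])
        common, priv = 10.0, np.array([1.0, 2.0])
        recal = np.array([20.0])
        new_cells, (new_common, new_priv), new_recal, necro, rem, add = (
            apply_dilution(cells, (common, priv), recal, 0.5, p)
        )
        keep, feed = 580.0 / 880.0, 300.0 / 880.0
        assert new_cells == pytest.approx(cells * keep, rel=1e-12)
        assert necro == pytest.approx(0.5 * keep)
        assert new_common == pytest.approx(
            common * keep + feed * p.stock_labile * (1 - p.niche_fraction)
        )
        assert new_recal[0] == pytest.approx(
            recal[0] * keep + feed * p.stock_recal
        )
        # ledger entries match what actually moved
        assert rem == pytest.approx(
            (1 - keep) * (common + priv.sum() + recal.sum()
                          + cells.sum() / p.yield_cells + 0.5)
        )
        assert add == pytest.approx(
            (new_common - keep * common)
            + (new_priv - keep * priv).sum()
            + (new_recal - keep * recal).sum()
        )


class TestObservation:
    def test_zero_noise_absorbance_round_trips(self):
        p = params4()
        truth = simulate_microcosm(
            Community("m", frozenset({"a", "b"})), p, sample_days=(7, 28)
        )
        meas = observe([truth], POOL4, p, noise=ObsNoise.zero())
        cal = CalibrationModel()
        ctrl = meas[meas["microcosm_id"] == CONTROL_ID].set_index("day")["value"]
        dlam = meas[
            (meas["microcosm_id"] == "m") & (meas["assay"] == "dlambda572")
        ].set_index("day")["value"]
        for d_i, day in enumerate(truth.sample_days):
            mass_mg = float(cal.co2_mass_mg(dlam[day] - ctrl[day]))
            assert mass_mg * 1000 == pytest.approx(
                truth.co2_interval[d_i].sum(), rel=1e-9
            )

    def test_collision_pooling_yields_single_full_fragment(self):
        p = params4()
        truth = simulate_microcosm(
            Community("m", frozenset({"c", "d"})), p, sample_days=(7,)
        )
        meas = observe([truth], POOL4, p, noise=ObsNoise.zero())
        trf = meas[meas["assay"].str.startswith("trf:")]
        assert list(trf["assay"]) == ["trf:103"]
        assert trf["value"].iloc[0] == pytest.approx(1.0)

    def test_noise_is_seed_deterministic(self):
        p = params4()
        truth = simulate_microcosm(
            Community("m", frozenset({"a", "b", "c"})), p, sample_days=(7,)
        )
        m1 = observe([truth], POOL4, p, noise_seed=42)
        m2 = observe([truth], POOL4, p, noise_seed=42)
        m3 = observe([truth], POOL4, p, noise_seed=43)
        pd.testing.assert_frame_equal(m1, m2)
        assert not m1["value"].equals(m3["value"])


class TestScenarios:
    def test_tiny_shape(self):
        scn = make_scenario("tiny", seed=0)
        per_partition = scn.design_frame.groupby("partition_id").size()
        assert list(per_partition) == [7, 7]

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_scenario("bogus", seed=0)

    def test_paper_default_shape(self, paper_run):
        scn = paper_run.scenario
        assert len(scn.truths) == 93
        assert scn.sample_days == (7, 28, 49)
        n_days = (
            scn.measurements[scn.measurements["microcosm_id"] != CONTROL_ID]
            .groupby("microcosm_id")["day"]
            .nunique()
        )
        assert (n_days == 3).all()
        assert (scn.params.alpha.mean()) < 0

    def test_paper_default_emulates_lab_regime(self, paper_run):
        """Emergent scales sit in the plausible wet-lab ranges: cell
        densities around 1e4-2e5 per ml, a few ug CO2 per day, and day-7
        per-capita respiration inside the 0.5-50 pg/cell/day bracket."""
        func = paper_run.functioning
        day7 = func[func["day"] == 7]
        assert 0.5 < day7["per_capita_pg_cell_day"].mean() < 50
        assert day7["cells_per_ml"].between(1e3, 3e5).all()
        assert 1.0 < day7["co2_rate_ug_day"].mean() < 11.0
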