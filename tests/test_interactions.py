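"""Response-ratio inference: hand-computed toys, oracle recomputation,
classification and summaries."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from befpipe.interactions import (
    InteractionError,
    classify_pair,
    observed_contributions,
    pairwise_expand,
    predict_functioning,
    response_ratios,
    succession_summary,
)

# the two-isolate worked example used throughout: monocultures 10 and 30,
# observed mixture functioning 15, measured shares 0.4/0.6
TOY_M = {"i1": 10.0, "i2": 30.0}
TOY_RA = {"i1": 0.4, "i2": 0.6}
TOY_P_OBS = 15.0


def toy_frames():
    design = pd.DataFrame(
        [
            {"microcosm_id": "P1.R1.1.r1", "partition_id": 1, "replicate": 1,
             "community_id": "P1.R1.1", "richness": 1, "members": "i1"},
            {"microcosm_id": "P1.R1.2.r1", "partition_id": 1, "replicate": 1,
             "community_id": "P1.R1.2", "richness": 1, "members": "i2"},
            {"microcosm_id": "P1.R2.1.r1", "partition_id": 1, "replicate": 1,
             "community_id": "P1.R2.1", "richness": 2, "members": "i1;i2"},
        ]
    )
    functioning = pd.DataFrame(
        [
            {"microcosm_id": "P1.R1.1.r1", "day": 7,
             "per_capita_pg_cell_day": TOY_M["i1"]},
            {"microcosm_id": "P1.R1.2.r1", "day": 7,
             "per_capita_pg_cell_day": TOY_M["i2"]},
            {"microcosm_id": "P1.R2.1.r1", "day": 7,
             "per_capita_pg_cell_day": TOY_P_OBS},
        ]
    )
    abundance = pd.DataFrame(
        [
            {"microcosm_id": "P1.R2.1.r1", "day": 7, "isolate_id": "i1",
             "relative_abundance": TOY_RA["i1"]},
            {"microcosm_id": "P1.R2.1.r1", "day": 7, "isolate_id": "i2",
             "relative_abundance": TOY_RA["i2"]},
        ]
    )
    return design, functioning, abundance


class TestPredictFunctioning:
    def test_equal_abundance_model(self):
        total, per = predict_functioning(["i1", "i2"], TOY_M)
        assert total == pytest.approx(20.0)
        assert per == pytest.approx({"i1": 5.0, "i2": 15.0})

    def test_sum_model(self):
        total, per = predict_functioning(["i1", "i2"], TOY_M, model="sum")
        assert total == pytest.approx(40.0)
        assert per == pytest.approx(TOY_M)

    def test_monoculture_identical_under_both_models(self):
        for model in ("equal_abundance", "sum"):
            total, _ = predict_functioning(["i1"], TOY_M, model=model)
            assert total == pytest.approx(10.0)

    def test_missing_monoculture_names_isolate(self):
        with pytest.raises(InteractionError, match="i3"):
            predict_functioning(["i1", "i3"], TOY_M)


class TestObservedContributions:
    def test_toy_split(self):
        assert observed_contributions(TOY_P_OBS, TOY_RA) == pytest.approx(
            {"i1": 6.0, "i2": 9.0}
        )

    def test_degenerate_composition(self):
        assert observed_contributions(15.0, {"i1": 1.0, "i2": 0.0}) == (
            pytest.approx({"i1": 15.0, "i2": 0.0})
        )

    def test_conservation(self):
        out = observed_contributions(TOY_P_OBS, TOY_RA)
        assert sum(out.values()) == pytest.approx(TOY_P_OBS, rel=1e-12)


class TestResponseRatios:
    def test_toy_log_ratios(self):
        design, functioning, abundance = toy_frames()
        table = response_ratios(functioning, abundance, design)
        by_iso = table.set_index("isolate_id")
        assert by_iso.loc["i1", "log_rr"] == pytest.approx(
            math.log(6.0 / 5.0), rel=1e-9
        )
        assert by_iso.loc["i2", "log_rr"] == pytest.approx(
            math.log(9.0 / 15.0), rel=1e-9
        )
        assert by_iso["community_log_rr"].iloc[0] == pytest.approx(
            math.log(15.0 / 20.0), rel=1e-9
        )

    def test_independent_oracle_recomputation(self):
        """Brute-force the N=2 log ratios from the raw tables by a
        separate code path and compare."""
        design, functioning, abundance = toy_frames()
        table = response_ratios(functioning, abundance, design)
        func = functioning.set_index("microcosm_id")["per_capita_pg_cell_day"]
        for iso, other_mid in (("i1", "P1.R1.1.r1"), ("i2", "P1.R1.2.r1")):
            ra = abundance.set_index("isolate_id").loc[iso,
                                                       "relative_abundance"]
            oracle = math.log(
                (ra * func["P1.R2.1.r1"]) / (func[other_mid] / 2.0)
            )
            got = table.set_index("isolate_id").loc[iso, "log_rr"]
            assert got == pytest.approx(oracle, rel=1e-12)

    def test_scale_invariance(self):
        design, functioning, abundance = toy_frames()
        base = response_ratios(functioning, abundance, design)
        scaled_f = functioning.copy()
        scaled_f["per_capita_pg_cell_day"] *= 2.0
        scaled = response_ratios(scaled_f, abundance, design)
        assert scaled["log_rr"].values == pytest.approx(
            base["log_rr"].values, rel=1e-12
        )

    def test_zero_contribution_floored_and_flagged(self):
        design, functioning, abundance = toy_frames()
        abundance.loc[abundance["isolate_id"] == "i1",
                      "relative_abundance"] = 0.0
        abundance.loc[abundance["isolate_id"] == "i2",
                      "relative_abundance"] = 1.0
        table = response_ratios(functioning, abundance, design)
        row = table.set_index("isolate_id").loc["i1"]
        assert row["floored"]
        assert np.isfinite(row["log_rr"])


class TestPairwise:
    def test_toy_pair_is_exploitation(self):
        design, functioning, abundance = toy_frames()
        pairs = pairwise_expand(
            response_ratios(functioning, abundance, design), epsilon=0.05
        )
        assert len(pairs) == 1
        assert pairs["class"].iloc[0] == "exploitation"

    def test_neutral_band(self):
        assert classify_pair(0.0, 0.0, 0.05) == "neutral"
        assert classify_pair(-0.04, -0.3, 0.05) == "neutral"
        assert classify_pair(-0.2, -0.3, 0.05) == "antagonism"
        assert classify_pair(0.2, 0.3, 0.05) == "mutualism"
        assert classify_pair(0.2, -0.3, 0.05) == "exploitation"

    def test_richness_four_yields_six_pairs(self):
        inter = pd.DataFrame(
            {
                "microcosm_id": ["m"] * 4,
                "day": [7] * 4,
                "richness": [4] * 4,
                "isolate_id": list("abcd"),
                "log_rr": [-0.2, -0.3, 0.1, -0.4],
            }
        )
        pairs = pairwise_expand(inter)
        assert len(pairs) == 6


class TestSuccessionSummary:
    def test_identical_values_zero_variance(self):
        pairs = pd.DataFrame(
            {
                "microcosm_id": ["m1", "m2"],
                "day": [7, 7],
                "richness": [2, 2],
                "isolate_i": ["a", "c"],
                "isolate_j": ["b", "d"],
                "log_rr_i": [-0.5, -0.5],
                "log_rr_j": [-0.5, -0.5],
                "class": ["antagonism", "antagonism"],
            }
        )
        summary = succession_summary(pairs)
        assert summary["var_log_rr"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert summary["mean_log_rr"].iloc[0] == pytest.approx(-0.5)
        assert summary["freq_antagonism"].iloc[0] == 1.0

    def test_too_few_pairs_rejected(self):
        pairs = pd.DataFrame(
            {
                "microcosm_id": ["m1"],
                "day": [7],
                "richness": [2],
                "isolate_i": ["a"],
                "isolate_j": ["b"],
                "log_rr_i": [np.nan],
                "log_rr_j": [np.nan],
                "class": ["neutral"],
            }
        )
        with pytest.raises(InteractionError):
            succession_summary(pairs)


class TestOnSimulatedData:
    def test_conservation_every_row(self, paper_run):
        """Per-isolate contributions rebuild the observed community
        functioning exactly."""
        inter = paper_run.interactions
        total = inter.groupby(["microcosm_id", "day"]).agg(
            s=("p_obs", "sum"), p=("p_obs_community", "first")
        )
        assert total["s"].values == pytest.approx(
            total["p"].values, rel=1e-9
        )

    def test_equal_abundance_prediction_is_monoculture_mean(self, paper_run):
        inter = paper_run.interactions
        grp = inter.groupby(["microcosm_id", "day"]).agg(
            pred=("p_pred_community", "first"),
            mean_m=("p_pred", "mean"),
            n=("isolate_id", "count"),
        )
        # sum of M_i/N equals N * mean(M_i/N) = mean(M_i)
        assert grp["pred"].values == pytest.approx(
            (grp["mean_m"] * grp["n"]).values, rel=1e-9
        )

    def test_antagonism_recovered_then_attenuates(self, paper_run):
        """The simulated regime has negative mean interactions early and
        weaker ones at the end: inference recovers both the sign at day 7
        and the decline in magnitude by day 49."""
        summary = paper_run.summary.set_index("day")
        assert paper_run.scenario.params.alpha.mean() < 0
        assert summary.loc[7, "mean_log_rr"] < 0
        assert abs(summary.loc[49, "mean_log_rr"]) < abs(
            summary.loc[7, "mean_log_rr"]
        )

    def test_neutral_scenario_classifies_few_antagonisms(self, neutral_run):
        summary = neutral_run.summary
        assert (summary["freq_antagonism"] < 0.25).all()
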