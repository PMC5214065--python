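"""Two-source mixing model: baselines, littoral reliance, trophic position."""

import numpy as np
import pandas as pd
import pytest

from trophont import isotope as iso
from trophont import simulate as sim
from trophont.exceptions import DegenerateBaselineError, ValidationError


class TestAggregateBaseline:
    def test_habitat_means(self):
        samples = pd.DataFrame(
            {
                "lake_id": ["L"] * 4,
                "habitat": ["littoral", "littoral", "pelagic", "pelagic"],
                "d13C": [-20.0, -22.0, -30.0, -30.0],
                "d15N": [4.0, 6.0, 4.0, 4.0],
            }
        )
        b = iso.aggregate_baseline(samples, "L")
        assert b.littoral[:2] == (-21.0, 5.0)
        assert b.pelagic[:2] == (-30.0, 4.0)
        assert b.littoral[2] == 2

    def test_missing_habitat_errors(self):
        samples = pd.DataFrame(
            {"lake_id": ["L"], "habitat": ["littoral"], "d13C": [-20.0], "d15N": [4.0]}
        )
        with pytest.raises(ValidationError, match="pelagic"):
            iso.aggregate_baseline(samples, "L")

    def test_degenerate_end_members(self):
        samples = pd.DataFrame(
            {
                "lake_id": ["L", "L"],
                "habitat": ["littoral", "pelagic"],
                "d13C": [-25.0, -25.0],
                "d15N": [4.0, 5.0],
            }
        )
        with pytest.raises(DegenerateBaselineError):
            iso.aggregate_baseline(samples, "L")


class TestMixingModel:
    @pytest.mark.parametrize(
        "d13c, expected",
        [(-20.0, 1.0), (-30.0, 0.0), (-25.0, 0.5)],
    )
    def test_end_member_identities(self, baseline, d13c, expected):
        assert iso.littoral_reliance(d13c, baseline) == pytest.approx(expected)

    def test_one_step_above_littoral(self, baseline):
        # consumer on the littoral end-member, one fractionation step up
        tp = iso.trophic_position(-20.0, 3.0 + 3.4, baseline)
        assert tp == pytest.approx(3.0)

    def test_consumer_at_baseline_mixture(self, baseline):
        alpha = 0.37
        d13c, d15n = iso.forward_isotopes(2.0, alpha, baseline)
        assert iso.trophic_position(d13c, d15n, baseline) == pytest.approx(2.0)

    def test_inversion_grid(self, baseline):
        tps, alphas = np.meshgrid(np.linspace(2, 4.5, 12), np.linspace(0, 1, 11))
        d13c, d15n = iso.forward_isotopes(tps.ravel(), alphas.ravel(), baseline)
        back_a = iso.littoral_reliance(d13c, baseline)
        back_tp = iso.trophic_position(d13c, d15n, baseline)
        np.testing.assert_allclose(back_a, alphas.ravel(), atol=1e-9)
        np.testing.assert_allclose(back_tp, tps.ravel(), atol=1e-9)

    def test_monotone_in_d15n(self, baseline):
        d15n = np.linspace(2.0, 15.0, 40)
        tp = iso.trophic_position(np.full_like(d15n, -24.0), d15n, baseline)
        assert np.all(np.diff(tp) > 0)

    def test_clamping_outside_interval(self, baseline):
        # consumers beyond either end-member clamp to alpha in {0, 1}
        assert iso.littoral_reliance(-18.0, baseline) == 1.0
        assert iso.littoral_reliance(-33.0, baseline) == 0.0
        tp = iso.trophic_position(-18.0, 8.0, baseline)
        assert np.isfinite(tp)

    def test_shift_invariance_in_d15n(self, baseline):
        # adding a constant to consumer and both baseline d15N leaves TP fixed
        shifted = iso.BaselineSet(
            "lake",
            littoral=(-20.0, 3.0 + 5.0, 8),
            pelagic=(-30.0, 4.0 + 5.0, 8),
        )
        tp0 = iso.trophic_position(-24.0, 9.0, baseline)
        tp1 = iso.trophic_position(-24.0, 9.0 + 5.0, shifted)
        assert tp1 == pytest.approx(tp0)


class TestEstimator:
    def test_fit_transform(self, baseline):
        samples = pd.DataFrame(
            {
                "lake_id": ["L"] * 4,
                "habitat": ["littoral", "littoral", "pelagic", "pelagic"],
                "d13C": [-19.0, -21.0, -30.0, -30.0],
                "d15N": [3.0, 3.0, 4.0, 4.0],
            }
        )
        m = iso.TwoSourceMixingModel().fit(samples)
        out = m.transform(np.array([[-20.0, 6.4], [-30.0, 4.0]]))
        np.testing.assert_allclose(out[0], [1.0, 3.0])
        np.testing.assert_allclose(out[1], [0.0, 2.0])

    def test_multi_lake_requires_lake_id(self):
        samples = pd.DataFrame(
            {
                "lake_id": ["A", "A", "B", "B"],
                "habitat": ["littoral", "pelagic"] * 2,
                "d13C": [-20.0, -30.0, -19.0, -29.0],
                "d15N": [3.0, 4.0, 3.0, 4.0],
            }
        )
        with pytest.raises(ValidationError):
            iso.TwoSourceMixingModel().fit(samples)
        m = iso.TwoSourceMixingModel().fit(samples, lake_id="B")
        assert m.baseline_.littoral[0] == -19.0


class TestTpTable:
    def test_missing_baseline_names_lake(self, baseline):
        fish = pd.DataFrame(
            {
                "fish_id": ["f1"],
                "lake_id": ["unknown_lake"],
                "community_type": ["x"],
                "d13C": [-24.0],
                "d15N": [8.0],
            }
        )
        with pytest.raises(ValidationError, match="unknown_lake"):
            iso.tp_table(fish, {"lake": baseline})

    def test_single_fish_sd_zero_with_flag(self, baseline):
        fish = pd.DataFrame(
            {
                "fish_id": ["f1"],
                "lake_id": ["lake"],
                "community_type": ["x"],
                "d13C": [-24.0],
                "d15N": [8.0],
            }
        )
        _, summary = iso.tp_table(fish, {"lake": baseline})
        row = summary[summary["group_by"] == "lake_id"].iloc[0]
        assert row["tp_sd"] == 0.0
        assert bool(row["n1_flag"])

    def test_group_mean_matches_generating_truth_without_noise(self, scenarios):
        sc = sim.noise_free(scenarios["two_species"])
        ds = sim.simulate_community(sc, "L1", seed=5)
        baselines = {"L1": iso.aggregate_baseline(ds.baselines, "L1")}
        per_fish, summary = iso.tp_table(ds.fish, baselines)
        merged = per_fish.merge(ds.truth, on="fish_id")
        np.testing.assert_allclose(merged["tp"], merged["true_tp"], atol=1e-9)
        lake_row = summary[summary["group_by"] == "lake_id"].iloc[0]
        assert lake_row["tp_mean"] == pytest.approx(ds.truth["true_tp"].mean())
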