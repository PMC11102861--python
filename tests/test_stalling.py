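import numpy as np
import pytest

import deadkin as dk
from deadkin.kinetics import RateProfile
from deadkin.stalling import (
    RemovalTimeProfile,
    no_stall_baseline,
    removal_times,
    stalling_effect,
)


def times_profile(z_values):
    z = np.asarray(z_values, dtype=float)
    return RemovalTimeProfile(z, np.isfinite(z))


class TestRemovalTimes:
    def test_reciprocal(self):
        prof = removal_times(RateProfile([0.5, 2.0]))
        assert prof.at(1) == pytest.approx(2.0)
        assert prof.at(2) == pytest.approx(0.5)

    def test_inverse_scaling(self, rng):
        lam = rng.uniform(0.1, 3.0, 10)
        z1 = removal_times(RateProfile(lam)).z
        z2 = removal_times(RateProfile(2 * lam)).z
        np.testing.assert_allclose(z2, z1 / 2)

    def test_zero_rate_marked_unavailable(self):
        prof = removal_times(np.array([0.5, 0.0, 1.0]))
        assert not prof.available[1]
        with pytest.raises(ValueError, match="unavailable"):
            prof.at(2)
        assert prof.at(3) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            removal_times(np.zeros(5))


class TestBaseline:
    def test_identical_profiles_recover_control(self, rng):
        z = rng.uniform(0.5, 4.0, 20)
        zm, zc = times_profile(z), times_profile(z.copy())
        out = no_stall_baseline(zm, zc, anchor=7)
        assert out["b"] == pytest.approx(1.0)
        for i in (-2, -1, 0):
            assert out["z_null"][i] == pytest.approx(z[7 + i - 1])

    def test_uniform_scaling_gives_b_two(self, rng):
        z = rng.uniform(0.5, 4.0, 20)
        out = no_stall_baseline(times_profile(2 * z), times_profile(z), anchor=7)
        assert out["b"] == pytest.approx(2.0)
        for i in (-2, -1, 0):
            assert out["z_null"][i] == pytest.approx(2 * z[7 + i - 1])

    def test_flat_control_limit(self):
        # no gradual slowdown in the control: eps vanishes and the baseline
        # is the mixed profile's calibration value
        z_mixed = times_profile([1, 1, 1, 2.0, 5, 6, 7, 1, 2.5])
        z_flat = times_profile(np.full(9, 3.0))
        with pytest.warns(UserWarning, match="flat control"):
            out = no_stall_baseline(z_mixed, z_flat, anchor=7)
        assert all(v == 0 for v in out["eps"].values())
        for i in (-2, -1, 0):
            assert out["z_null"][i] == pytest.approx(2.0)  # z(-3) = z at position 4

    def test_zero_denominator_rejected(self):
        # control equal at the calibration anchors but not flat elsewhere
        zc = times_profile([1, 1, 1, 3.0, 1, 2, 1, 1, 3.0])
        zm = times_profile(np.arange(1.0, 10.0))
        with pytest.raises(ValueError, match="calibration"):
            no_stall_baseline(zm, zc, anchor=7)

    def test_anchor_must_be_non_a(self, rng):
        z = rng.uniform(1, 2, 20)
        with pytest.raises(ValueError, match="adenosine"):
            no_stall_baseline(
                times_profile(z), times_profile(z), anchor=8,
                substrate=dk.preset("A20G"),
            )

    def test_calibration_inside_window_rejected(self, rng):
        z = rng.uniform(1, 2, 20)
        with pytest.raises(ValueError, match="outside"):
            no_stall_baseline(times_profile(z), times_profile(z), 7, calibration=(-1, 2))


class TestZeta:
    def test_no_stalling_is_one_adenosine(self):
        assert stalling_effect([2.0, 3.0, 4.0], [2.0, 3.0, 4.0]) == pytest.approx(1.0)

    def test_uniform_twofold_slowdown_is_four(self):
        assert stalling_effect([4.0, 6.0, 8.0], [2.0, 3.0, 4.0]) == pytest.approx(4.0)

    def test_direct_ratio_evaluation(self):
        # ratios (1, 3, 2) -> 1 + 3 + 2 - 2 = 4
        assert stalling_effect([1.0, 3.0, 2.0], [1.0, 1.0, 1.0]) == pytest.approx(4.0)

    def test_scale_invariance(self, rng):
        z = rng.uniform(0.5, 5.0, 3)
        z0 = rng.uniform(0.5, 5.0, 3)
        c = float(rng.uniform(0.1, 10.0))
        assert stalling_effect(c * z, c * z0) == pytest.approx(stalling_effect(z, z0))

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            stalling_effect([1, 2, 3], [1, 0, 1])
        with pytest.raises(ValueError):
            stalling_effect([1, -2, 3], [1, 1, 1])


class TestAssess:
    def test_end_to_end_recovery(self, wildtype_a20g_pair):
        # noise-free pipeline: fit mixed + control, build the baseline,
        # compute zeta; must match the generator's analytic value closely
        pair = wildtype_a20g_pair
        out = dk.assess_stalling(
            pair["mixed"].rate_profile(),
            pair["control"].rate_profile(),
            dk.preset("A20G"),
        )
        assert [a.anchor for a in out] == [7, 14]
        for a in out:
            true = dk.analytic_zeta(pair["scenario"], a.anchor)
            assert a.zeta == pytest.approx(true, rel=1e-4)
            assert a.residue == "G"
            assert a.b == pytest.approx(1.0, abs=1e-4)

    def test_delta_method_se_is_finite(self, wildtype_a20g_pair):
        pair = wildtype_a20g_pair
        out = dk.assess_stalling(
            pair["mixed"].rate_profile(),
            pair["control"].rate_profile(),
            dk.preset("A20G"),
            anchor=7,
            propagate_se=True,
        )
        assert out[0].zeta_se is not None and np.isfinite(out[0].zeta_se)

    def test_pure_substrate_rejected(self, wildtype_a20g_pair):
        pair = wildtype_a20g_pair
        with pytest.raises(ValueError, match="non-A"):
            dk.assess_stalling(
                pair["control"].rate_profile(),
                pair["control"].rate_profile(),
                dk.preset("A20"),
            )


class TestAggregate:
    def test_single_replicate(self):
        out = dk.aggregate_replicates([{"residue": "G", "variant": "wt", "zeta": 5.0}])
        assert out.loc[0, "mean_zeta"] == 5.0
        assert np.isnan(out.loc[0, "sem_zeta"])
        assert out.loc[0, "n"] == 1

    def test_two_point_sem(self):
        reps = [
            {"residue": "G", "variant": "wt", "zeta": 4.0},
            {"residue": "G", "variant": "wt", "zeta": 6.0},
        ]
        out = dk.aggregate_replicates(reps)
        assert out.loc[0, "mean_zeta"] == pytest.approx(5.0)
        assert out.loc[0, "sem_zeta"] == pytest.approx(1.0)

    def test_identical_replicates_zero_sem(self):
        reps = [{"residue": "U", "variant": "wt", "zeta": 7.0}] * 3
        out = dk.aggregate_replicates(reps)
        assert out.loc[0, "sem_zeta"] == 0.0

    def test_groups_kept_separate(self):
        reps = [
            {"residue": "G", "variant": "wt", "anchor": 7, "zeta": 5.0},
            {"residue": "G", "variant": "wt", "anchor": 14, "zeta": 6.0},
        ]
        out = dk.aggregate_replicates(reps, by=("residue", "variant", "anchor"))
        assert len(out) == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dk.aggregate_replicates([])


class TestEffectiveTailLength:
    @pytest.mark.parametrize(
        "residue,zeta,expected",
        [("G", 6.0, 150.0), ("U", 8.0, 170.0), ("C", 11.0, 200.0)],
    )
    def test_designed_hundred_nt_tail(self, residue, zeta, expected):
        eff, fold = dk.effective_tail_length(100, {residue: 10}, {residue: zeta})
        assert eff == expected
        assert fold == expected / 100

    def test_pure_tail_identity(self):
        eff, fold = dk.effective_tail_length(20, {}, {})
        assert eff == 20.0 and fold == 1.0

    def test_additive_over_residues(self):
        eff, _ = dk.effective_tail_length(
            100, {"G": 5, "C": 5}, {"G": 6.0, "C": 11.0}
        )
        assert eff == 90 + 5 * 6 + 5 * 11

    def test_close_spacing_warns(self):
        with pytest.warns(UserWarning, match="within 2 nt"):
            dk.effective_tail_length(20, {"G": 2}, {"G": 6.0}, positions=[7, 9])

    def test_sub_unity_zeta_warns(self):
        with pytest.warns(UserWarning, match="zeta"):
            dk.effective_tail_length(20, {"G": 1}, {"G": 0.5})

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            dk.effective_tail_length(10, {"G": -1}, {"G": 6.0})
        with pytest.raises(ValueError):
            dk.effective_tail_length(5, {"G": 6}, {"G": 6.0})
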