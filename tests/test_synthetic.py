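import numpy as np
import pytest

import deadkin as dk
from deadkin.synthetic import COMPLEX_VARIANTS, BaselineShape, GroundTruthScenario


class TestRateProfiles:
    def test_unit_factors_reduce_to_baseline(self):
        sc = dk.scenario("A20G", "wild_type").with_(
            stall_factors={"G": (1.0, 1.0, 1.0)}
        )
        base = dk.scenario("A20", "wild_type")
        np.testing.assert_allclose(
            dk.make_rate_profile(sc).rates, dk.make_rate_profile(base).rates
        )

    def test_factor_hits_penultimate_positions(self):
        sc = dk.scenario("A20G", "wild_type").with_(
            stall_factors={"G": (1.0, 0.2, 1.0)}
        )
        lam = dk.make_rate_profile(sc).rates
        base = dk.scenario("A20", "wild_type")
        lam0 = dk.make_rate_profile(base).rates
        # -1 positions of the residues at 7 and 14 are tail positions 6 and 13
        assert lam[5] == pytest.approx(0.2 * lam0[5])
        assert lam[12] == pytest.approx(0.2 * lam0[12])
        untouched = [p for p in range(20) if p not in (5, 12)]
        np.testing.assert_allclose(lam[untouched], lam0[untouched])

    def test_analytic_zeta_flat_baseline(self):
        # flat baseline: zeta reduces to sum(1/f) - 2 and the full
        # baseline construction on the ground-truth rates agrees
        flat = BaselineShape(peak=1.0, floor=1.0, start_frac=1.0)
        sc = GroundTruthScenario(
            substrate=dk.preset("A20G"),
            baseline=flat,
            stall_factors={"G": (0.5, 0.2, 0.5)},
        )
        assert dk.analytic_zeta(sc, 7) == pytest.approx(2 + 5 + 2 - 2)
        zm = dk.removal_times(dk.make_rate_profile(sc))
        zc = dk.removal_times(
            dk.make_rate_profile(sc.with_(stall_factors={"G": (1, 1, 1)}))
        )
        with pytest.warns(UserWarning, match="flat control"):
            base = dk.no_stall_baseline(zm, zc, anchor=7)
        z = {i: zm.relative(7, i) for i in (-2, -1, 0)}
        assert dk.stalling_effect(z, base["z_null"]) == pytest.approx(7.0)

    def test_analytic_zeta_nonflat_baseline_consistency(self):
        sc = dk.scenario("A20U", "caf1_only")
        zm = dk.removal_times(dk.make_rate_profile(sc))
        zc = dk.removal_times(
            dk.make_rate_profile(dk.scenario("A20", "caf1_only"))
        )
        for r in (7, 14):
            base = dk.no_stall_baseline(zm, zc, anchor=r)
            z = {i: zm.relative(r, i) for i in (-2, -1, 0)}
            assert dk.stalling_effect(z, base["z_null"]) == pytest.approx(
                dk.analytic_zeta(sc, r)
            )

    def test_clipped_window_warns(self):
        sub = dk.TailSubstrate("edge", tail="AAAAAAAAAAAAAAAAAAGA")  # non-A at p=2
        sc = dk.scenario("A20", "wild_type").with_(
            substrate=sub, stall_factors={"G": (0.5, 0.5, 0.5)}
        )
        with pytest.warns(UserWarning, match="clipped"):
            dk.make_rate_profile(sc)

    def test_invalid_factors_rejected(self):
        with pytest.raises(ValueError):
            dk.scenario("A20G", "wild_type").with_(stall_factors={"G": (0.5, 1.5, 0.5)})


class TestNoisyAssay:
    def test_sigma_zero_is_clean(self):
        sc = dk.scenario("A20", "wild_type", noise_sigma=0.0)
        tc, truth = dk.simulate_noisy_assay(sc)
        np.testing.assert_array_equal(tc.values, truth["clean"].values)

    def test_seed_determinism(self):
        sc = dk.scenario("A20G", "wild_type", noise_sigma=0.05, seed=42)
        a, _ = dk.simulate_noisy_assay(sc)
        b, _ = dk.simulate_noisy_assay(sc)
        np.testing.assert_array_equal(a.values, b.values)

    def test_noise_model_calibration(self):
        # mean per-cell log-ratio to truth ~ N(0, sigma^2 / n_cells) per
        # seed; its seed-average stays within 3 sigma / sqrt(20 n_cells)
        sigma = 0.05
        ratios = []
        for seed in range(20):
            sc = dk.scenario("A20", "wild_type", noise_sigma=sigma, seed=seed)
            tc, truth = dk.simulate_noisy_assay(sc)
            keep = truth["clean"].values > 1e-12
            ratios.append(np.log(tc.values[keep] / truth["clean"].values[keep]))
        all_ratios = np.concatenate(ratios)
        assert abs(all_ratios.mean()) <= 3 * sigma / np.sqrt(all_ratios.size)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            dk.scenario("A20", "wild_type", noise_sigma=-0.1)


class TestLaneRendering:
    def test_single_species_single_band(self):
        vals = np.zeros((21, 1))
        vals[4, 0] = 2.0
        tc = dk.TimeCourseMatrix(vals, [2.0])
        lanes, _, centers = dk.render_lanes(tc)
        peak_row = np.argmax(lanes[0].intensity)
        assert abs(peak_row - centers[4]) <= 1

    def test_zero_matrix_flat_profiles(self):
        tc = dk.TimeCourseMatrix(np.zeros((5, 2)), [1.0, 2.0])
        lanes, _, _ = dk.render_lanes(tc)
        for lane in lanes:
            assert np.ptp(lane.intensity) == 0

    def test_unresolvable_spacing_warns(self):
        tc = dk.TimeCourseMatrix(np.ones((5, 1)), [1.0])
        with pytest.warns(UserWarning, match="unresolvable"):
            dk.render_lanes(tc, spacing=4.0, sigma_band=3.0)

    def test_round_trip_relative_intensities(self):
        # render -> segment -> quantify must recover relative band
        # intensities within 5% at >= 4 sigma separation
        sc = dk.scenario("A20G", "wild_type", noise_sigma=0.0)
        tc, _ = dk.simulate_noisy_assay(sc)
        lanes, _, _ = dk.render_lanes(tc, spacing=16.0, sigma_band=4.0)
        q = dk.BandQuantifier(expected_bands=21).fit(
            dk.LaneProfile(sum(l.intensity for l in lanes))
        )
        recovered = q.transform(list(lanes))
        for j in range(tc.n_times):
            truth_col = tc.values[:, j]
            rec_col = recovered[:, j]
            keep = truth_col > 0.05 * truth_col.max()
            rel_truth = truth_col[keep] / truth_col[keep].max()
            rel_rec = rec_col[keep] / rec_col[keep].max()
            np.testing.assert_allclose(rel_rec, rel_truth, rtol=0.05)


class TestPresetSignatures:
    def test_guanosine_accumulates_at_penultimate_species(self):
        # column-normalized heatmap of the wild-type A20G assay lights up
        # species 6 and 13 (the -1 positions): each is the brightest band
        # of some intermediate column, after the reaction has left the
        # intact substrate behind
        sc = dk.scenario("A20G", "wild_type", noise_sigma=0.0)
        tc, _ = dk.simulate_noisy_assay(sc)
        cn = dk.normalize_columns(tc).values
        for s in (6, 13):
            cols = np.flatnonzero(cn[s - 1] > 0.999)
            assert cols.size, f"species {s} never dominates a column"
            assert cols.min() >= 1  # not the first time point

    def test_pyrimidines_accumulate_over_three_positions(self):
        for name in ("A20U", "A20C"):
            sc = dk.scenario(name, "wild_type", noise_sigma=0.0)
            tc, _ = dk.simulate_noisy_assay(sc)
            cn = dk.normalize_columns(tc).values
            # all of species 5, 6, 7 (and 12, 13, 14) matter somewhere
            for s in (5, 6, 7, 12, 13, 14):
                assert cn[s - 1].max() > 0.5, (name, s)

    def test_ccr4_only_preset_is_incomplete_by_design(self):
        sc = dk.scenario("A20", "ccr4_only", noise_sigma=0.0)
        tc, _ = dk.simulate_noisy_assay(sc)
        # the tailless body stays essentially unpopulated at 48 min
        assert tc.values[-1, -1] < 0.05

    def test_variant_tables_qualitative_structure(self):
        # overall pyrimidine stalling exceeds guanosine stalling for every
        # complex variant (zeta ordering C > U > G)
        for variant in COMPLEX_VARIANTS:
            zetas = {
                res: dk.analytic_zeta(dk.scenario(f"A20{res}", variant), 7)
                for res in "GUC"
            }
            assert zetas["C"] > zetas["U"] > zetas["G"], variant
        wt = COMPLEX_VARIANTS["wild_type"]["factors"]
        ccr4 = COMPLEX_VARIANTS["ccr4_only"]["factors"]
        # wild-type pyrimidines hit the -2 and 0 positions harder than G
        for res in ("U", "C"):
            assert wt[res][0] < wt["G"][0] and wt[res][2] < wt["G"][2]
        # CCR4-only barely stalls guanosine at -2
        assert ccr4["G"][0] > 0.8
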