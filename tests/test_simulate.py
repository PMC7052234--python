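"""Forward model: scene geometry, spectral/temporal signatures, photon
statistics of the cube simulator and the FCS trace simulator."""

import math

import numpy as np
import pytest
from scipy import ndimage

from sflimfret import (FLUOROPHORES, FretPairSpec, SceneSpec,
                       emission_channel_probs, fret_modified_donor,
                       ground_truth_pattern, sensitized_decay_shape,
                       simulate_cube, simulate_fcs_photons, structure_map)
from sflimfret.instrument import InstrumentConfig
from sflimfret.simulate import (SceneStructure, cross_fraction_for_tau_int,
                                label_brightness, scene_from_dict)


class TestStructureMap:
    def test_zero_count_gives_empty_map(self):
        assert not structure_map("puncta", (64, 64), {"count": 0}, 1).any()

    @pytest.mark.parametrize("kind", ["puncta", "filaments", "blobs"])
    def test_deterministic_given_seed(self, kind):
        a = structure_map(kind, (48, 48), {"count": 4}, 7)
        b = structure_map(kind, (48, 48), {"count": 4}, 7)
        np.testing.assert_array_equal(a, b)
        assert 0.0 <= a.min() and a.max() <= 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown structure kind"):
            structure_map("spirals", (32, 32), {}, 0)

    def test_filaments_are_connected(self):
        m = structure_map("filaments", (128, 128), {"count": 5}, 3)
        support = m > 0
        has_neighbour = ndimage.convolve(support.astype(int),
                                         np.ones((3, 3)), mode="constant") > 1
        frac = (support & has_neighbour).sum() / support.sum()
        assert frac >= 0.95


class TestEmissionSpectra:
    def test_peak_channel_matches_emission_center(self, config):
        fl = FLUOROPHORES["alexa488"]  # centered at 520 nm
        probs = emission_channel_probs(fl, config)
        assert probs.argmax() == 1  # channel covering 508.75-527.5 nm
        assert probs.sum() == pytest.approx(1.0)

    def test_notch_attenuates_only_its_channel(self, config):
        no_notch = InstrumentConfig(notch=None)
        fl = FLUOROPHORES["alexa546"]
        with_n = emission_channel_probs(fl, config)
        without = emission_channel_probs(fl, no_notch)
        # un-normalized ratio: channel 3 reduced by the notch transmission
        raw_with = with_n / with_n[0]
        raw_without = without / without[0]
        ratio = raw_with / raw_without
        np.testing.assert_allclose(np.delete(ratio, 3), 1.0, rtol=1e-9)
        assert ratio[3] == pytest.approx(0.2, rel=1e-9)

    def test_narrow_emission_collapses_to_one_channel(self, config):
        from dataclasses import replace
        fl = replace(FLUOROPHORES["alexa488"], emission_sigma=0.01)
        probs = emission_channel_probs(fl, config)
        assert probs[1] == pytest.approx(1.0)

    def test_out_of_range_emission_rejected(self, config):
        from dataclasses import replace
        fl = replace(FLUOROPHORES["alexa488"], emission_center=400.0,
                     emission_sigma=2.0)
        with pytest.raises(ValueError, match="no overlap"):
            emission_channel_probs(fl, config)


class TestFretModifiedDonor:
    def test_zero_efficiency_is_identity(self):
        donor = FLUOROPHORES["alexa488"]
        assert fret_modified_donor(donor, 0.0) == donor

    def test_lifetimes_scale_by_one_minus_E(self):
        donor = FLUOROPHORES["alexa488"]
        quenched = fret_modified_donor(donor, 0.171875)
        # 3.84 ns * (1 - 0.171875) = 3.18 ns, the measured quenched value
        assert quenched.decay_components[0][1] == pytest.approx(3.18)
        assert quenched.brightness == pytest.approx(donor.brightness * 0.828125)

    def test_efficiency_bounds(self):
        donor = FLUOROPHORES["alexa488"]
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                fret_modified_donor(donor, bad)


class TestSensitizedDecay:
    def test_normalized(self, config, irf):
        s = sensitized_decay_shape(1.2, 3.5, 0, config, irf)
        assert s.sum() == pytest.approx(1.0)
        assert (s >= 0).all()

    def test_rise_time_peak_position(self, config, irf):
        tau_da, tau_a = 1.5, 3.5
        s = sensitized_decay_shape(tau_da, tau_a, 0, config, irf)
        t_star = math.log(tau_a / tau_da) / (1 / tau_da - 1 / tau_a)
        peak_ns = (s.argmax() + 0.5) * config.tcspc_bin_ns
        # peak shifted by the IRF center (0.25 ns); tolerance of a few bins
        assert peak_ns == pytest.approx(t_star + 0.25, abs=0.1)
        # slower donor quench -> later rise
        s2 = sensitized_decay_shape(2.5, tau_a, 0, config, irf)
        assert s2.argmax() > s.argmax()

    def test_instant_rise_limit_matches_pure_acceptor_decay(self, config, irf):
        from sflimfret.simulate import _multi_exp_shape
        s = sensitized_decay_shape(1e-4, 3.5, 0, config, irf)
        pure = _multi_exp_shape(((1.0, 3.5),), 0, config, irf)
        assert np.abs(s - pure).max() < 1e-3

    def test_equal_lifetimes_rejected_with_guidance(self, config, irf):
        with pytest.raises(ValueError, match="limit"):
            sensitized_decay_shape(3.5, 3.5, 0, config, irf)


class TestGroundTruthPattern:
    def test_pattern_is_probability_distribution(self, config, irf):
        for label in (FLUOROPHORES["alexa488"],
                      FretPairSpec(donor=FLUOROPHORES["alexa488"],
                                   acceptor=FLUOROPHORES["alexa546"],
                                   efficiency=0.5)):
            p = ground_truth_pattern(label, config, irf)
            assert p.p.sum() == pytest.approx(1.0)
            assert (p.p >= 0).all()

    def test_single_laser_dye_emits_in_its_epoch_only(self, config, irf):
        from dataclasses import replace
        fl = replace(FLUOROPHORES["alexa488"], excitation_efficiency=(1.0, 0.0))
        p = ground_truth_pattern(fl, config, irf).p.reshape(2, 8, 512)
        # all mass in epoch 0 except the periodic tail wrapped into epoch 1:
        # excitation at 0.25 ns (IRF center), epoch 1 spans 12.25-24.75 ns
        # after the pulse, periodic decay normalized over the 25 ns period
        assert p[0].sum() > 0.9
        tau = 3.84
        tail = ((math.exp(-12.25 / tau) - math.exp(-24.75 / tau))
                / (1 - math.exp(-25.0 / tau)))
        assert p[1].sum() == pytest.approx(tail, rel=0.02)

    def test_fret_fingerprint_acceptor_band_mass_in_donor_epoch(self, config, irf):
        donor = FLUOROPHORES["alexa488"]
        pair = FretPairSpec(donor=donor, acceptor=FLUOROPHORES["alexa546"],
                            efficiency=0.5)
        p_pair = ground_truth_pattern(pair, config, irf).p.reshape(2, 8, 512)
        p_donor = ground_truth_pattern(donor, config, irf).p.reshape(2, 8, 512)
        acceptor_band = slice(4, 8)  # channels red of the 565 nm edge
        assert (p_pair[0, acceptor_band].sum()
                > p_donor[0, acceptor_band].sum() + 0.05)

    def test_quenching_deepens_monotonically_with_E(self, config, irf):
        donor, acc = FLUOROPHORES["alexa488"], FLUOROPHORES["alexa546"]
        tau, band = [], []
        for E in (0.1, 0.3, 0.5, 0.7):
            pair = FretPairSpec(donor=donor, acceptor=acc, efficiency=E)
            tau.append(pair.ensemble_tau_int())
            p = ground_truth_pattern(pair, config, irf).p.reshape(2, 8, 512)
            band.append(p[0, 4:].sum() / p[0].sum())
        assert all(a > b for a, b in zip(tau, tau[1:]))
        assert all(a < b for a, b in zip(band, band[1:]))

    def test_cross_fraction_solver_reproduces_target(self):
        donor = FLUOROPHORES["alexa488"]
        phi = cross_fraction_for_tau_int(donor, 0.8, 3.18)
        pair = FretPairSpec(donor=donor, acceptor=FLUOROPHORES["alexa546"],
                            efficiency=0.8, cross_fraction=phi)
        assert pair.ensemble_tau_int() == pytest.approx(3.18, abs=1e-9)


@pytest.fixture(scope="module")
def one_pixel_scene():
    return SceneSpec(shape=(1, 1), seed=0, background=0.0, structures=[
        SceneStructure(kind="puncta", params={"count": 1, "radius": 0.01},
                       label=FLUOROPHORES["alexa488"], brightness=300.0)])


class TestSimulateCube:
    def test_zero_exposure_gives_empty_cube(self, one_pixel_scene, small_config, small_irf):
        cube, _ = simulate_cube(one_pixel_scene, small_config, small_irf, 0.0, 1)
        assert cube.total_counts == 0

    def test_negative_exposure_rejected(self, one_pixel_scene, small_config, small_irf):
        with pytest.raises(ValueError):
            simulate_cube(one_pixel_scene, small_config, small_irf, -1.0, 1)

    def test_seed_determinism(self, one_pixel_scene, small_config, small_irf):
        a, _ = simulate_cube(one_pixel_scene, small_config, small_irf, 1.0, 42)
        b, _ = simulate_cube(one_pixel_scene, small_config, small_irf, 1.0, 42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_counts_match_poisson_law(self, one_pixel_scene, small_config, small_irf):
        """Replicate one pixel: the bin means follow lambda*pattern and the
        total counts have unit index of dispersion."""
        n_rep = 200
        hists, totals = [], []
        for seed in range(n_rep):
            cube, truth = simulate_cube(one_pixel_scene, small_config,
                                        small_irf, 1.0, seed)
            hists.append(cube.pixel_histograms()[0])
            totals.append(cube.total_counts)
        hists = np.array(hists, dtype=float)
        lam = truth.expected[0, 0, 0] * truth.patterns[0].p
        mean = hists.mean(axis=0)
        se = np.sqrt(np.maximum(lam, 1e-12) / n_rep)
        big = lam > 0.5  # compare well-populated bins
        assert (np.abs(mean[big] - lam[big]) <= 4 * se[big]).mean() > 0.99
        disp = np.var(totals) / np.mean(totals)
        assert 0.8 < disp < 1.25

    def test_scene_spec_round_trip_from_dict(self):
        scene = scene_from_dict({
            "shape": [32, 32], "background": 1.0, "seed": 5,
            "structures": [
                {"kind": "blobs", "params": {"count": 3},
                 "label": {"type": "fluorophore", "name": "alexa488"}},
                {"kind": "filaments",
                 "label": {"type": "fret_pair", "donor": "alexa488",
                           "acceptor": "alexa546", "efficiency": 0.5}},
            ]})
        assert scene.shape == (32, 32)
        assert scene.structures[1].label.efficiency == 0.5

    def test_scene_spec_errors_name_the_field(self):
        with pytest.raises(ValueError, match="shape"):
            scene_from_dict({"structures": []})
        with pytest.raises(ValueError, match="label.donor"):
            scene_from_dict({"shape": [8, 8], "structures": [
                {"kind": "blobs", "label": {"type": "fret_pair"}}]})


class TestSimulateFcs:
    def test_zero_brightness_gives_pure_background(self):
        dt, bg = 1e-4, 5000.0
        trace = simulate_fcs_photons(1e-9, 10.0, 0.3, 5.0, brightness=0.0,
                                     background=bg, duration=5.0, dt=dt, seed=3)
        mean = trace.mean()
        assert mean == pytest.approx(bg * dt, rel=0.05)
        assert np.var(trace) / mean == pytest.approx(1.0, rel=0.1)

    def test_seed_determinism(self):
        kw = dict(concentration=5e-8, D=100.0, w0=0.25, kappa=3.0,
                  brightness=5e4, background=0.0, duration=0.05, dt=5e-6)
        a = simulate_fcs_photons(**kw, seed=9)
        b = simulate_fcs_photons(**kw, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_coarse_time_step_rejected(self):
        with pytest.raises(ValueError, match="dt too coarse"):
            simulate_fcs_photons(1e-9, 400.0, 0.3, 5.0, brightness=1e4,
                                 background=0.0, duration=1.0, dt=1e-3, seed=0)

    def test_small_box_rejected(self):
        with pytest.raises(ValueError, match="box"):
            simulate_fcs_photons(1e-9, 100.0, 0.3, 5.0, brightness=1e4,
                                 background=0.0, duration=0.1, dt=5e-6, seed=0,
                                 box_lateral=1.0)

    def test_mean_rate_matches_gaussian_volume_integral(self):
        """Mean detected rate = brightness * C * N_A * (pi/2)^{3/2} w0^2 z0."""
        C, w0, kappa, D, bright = 1e-7, 0.2, 3.0, 100.0, 1e5
        dt = 0.99 * (w0 / 4) ** 2 / (2 * D)
        trace = simulate_fcs_photons(C, D, w0, kappa, brightness=bright,
                                     background=0.0, duration=0.4, dt=dt, seed=11)
        z0 = kappa * w0
        integral_l = (math.pi / 2) ** 1.5 * w0 ** 2 * z0 * 1e-15
        expect = bright * C * 6.02214076e23 * integral_l * dt
        assert trace.mean() == pytest.approx(expect, rel=0.1)


def test_label_brightness_accounts_for_all_emission_paths(config):
    donor, acc = FLUOROPHORES["alexa488"], FLUOROPHORES["alexa546"]
    pair = FretPairSpec(donor=donor, acceptor=acc, efficiency=0.5,
                        sensitized_fraction=0.75, cross_fraction=0.6)
    e_d, e_a = sum(donor.excitation_efficiency), sum(acc.excitation_efficiency)
    expect = (e_d * (1 - 0.6)            # unquenched donors
              + e_d * 0.6 * 0.5          # quenched donor emission
              + e_d * 0.6 * 0.5 * 0.75   # sensitized acceptor emission
              + e_a)                     # direct acceptor excitation
    assert label_brightness(pair, config) == pytest.approx(expect)
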