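"""Synthetic experiment generator: ground truth, geometry, damage."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from ssrox.crystal import PointGroup, UnitCell, d_spacing
from ssrox.simulate import (
    DamageModel,
    FrameGeometry,
    HeavyAtomSite,
    SimConfig,
    generate_ground_truth,
    reflections_in_wedge,
    simulate_experiment,
    simulate_frame,
)

from conftest import true_intensity_lookup


def direct_sum_intensities(truth):
    """Oracle: re-derive Bijvoet intensities by explicit direct summation
    over all symmetry mates, independently of the GroundTruth internals."""
    rng = np.random.default_rng(truth.seed)
    xyz = rng.random((20, 3))  # matches n_dummy_atoms=20 of the small fixture
    R = truth.pg.op_array
    out_p, out_m = [], []
    for hkl, cen in zip(truth.hkl, truth.centric):
        s2 = (1.0 / d_spacing(hkl, truth.cell)) ** 2
        deb = math.exp(-20.0 * s2 / 4.0)

        def F(h):
            f = 0.0 + 0.0j
            for Rm in R:
                for x in xyz:
                    f += 6.0 * deb * np.exp(2j * np.pi * (h @ (Rm @ x)))
                for site in truth.sites:
                    fc = site.f0 + site.f_prime + 1j * site.f_double_prime
                    f += (
                        site.occupancy
                        * fc
                        * math.exp(-site.b_iso * s2 / 4.0)
                        * np.exp(2j * np.pi * (h @ (Rm @ np.asarray(site.frac_xyz))))
                    )
            return f

        out_p.append(abs(F(np.asarray(hkl))) ** 2)
        out_m.append(abs(F(-np.asarray(hkl))) ** 2)
    return np.array(out_p), np.array(out_m)


class TestGroundTruth:
    def test_no_sites_means_no_anomalous_signal(self, small_cell, pg222):
        truth = generate_ground_truth(small_cell, pg222, 2.0, [], seed=3, n_dummy_atoms=15)
        ip, im = truth.intensities()
        np.testing.assert_allclose(ip, im, rtol=1e-12)

    def test_centric_bijvoet_difference_is_exactly_zero(self, small_truth):
        dI = small_truth.bijvoet_true()
        assert np.abs(dI[small_truth.centric]).max() == 0.0

    def test_acentrics_carry_anomalous_signal(self, small_truth):
        dI = small_truth.bijvoet_true()
        assert np.abs(dI[~small_truth.centric]).max() > 0

    def test_direct_summation_oracle(self, small_truth):
        ip, im = small_truth.intensities()
        op, om = direct_sum_intensities(small_truth)
        np.testing.assert_allclose(ip, op, rtol=1e-8)
        acen = ~small_truth.centric
        np.testing.assert_allclose(im[acen], om[acen], rtol=1e-8)

    def test_deterministic_under_seed(self, small_cell, pg222, sites):
        a = generate_ground_truth(small_cell, pg222, 2.0, sites, seed=9, n_dummy_atoms=10)
        b = generate_ground_truth(small_cell, pg222, 2.0, sites, seed=9, n_dummy_atoms=10)
        np.testing.assert_array_equal(a.hkl, b.hkl)
        np.testing.assert_array_equal(a.f_protein, b.f_protein)

    def test_tiny_dmin_rejected(self, small_cell, pg222):
        with pytest.raises(ValueError):
            generate_ground_truth(small_cell, pg222, 0.3, [])

    def test_friedel_phase_conjugation(self, small_truth):
        # protein-only component: F(-h) = conj(F(h)) by construction
        assert np.allclose(np.angle(np.conj(small_truth.f_protein)), -small_truth.phases)


class TestDamage:
    def test_half_dose_definition(self, small_cell, pg222):
        site = HeavyAtomSite(frac_xyz=(0.1, 0.2, 0.3))
        truth = generate_ground_truth(
            small_cell, pg222, 2.0, [site], seed=1, n_dummy_atoms=10,
            damage=DamageModel(half_dose_site=5.0),
        )
        occ = truth.site_occupancies(5.0)
        assert occ[0] == pytest.approx(1.0 / math.e)

    def test_global_decay_is_resolution_dependent(self, small_cell, pg222):
        truth = generate_ground_truth(
            small_cell, pg222, 2.0, [], seed=1, n_dummy_atoms=10,
            damage=DamageModel(b_per_dose=1.0),
        )
        ip0, _ = truth.intensities(0.0)
        ip1, _ = truth.intensities(10.0)
        ratio = ip1 / ip0
        d = d_spacing(truth.hkl, truth.cell)
        # highest-resolution reflections decay the most
        assert ratio[np.argmin(d)] < ratio[np.argmax(d)]
        np.testing.assert_allclose(ratio, np.exp(-1.0 * 10.0 / d**2 / 2.0), rtol=1e-12)

    def test_bijvoet_difference_decays_with_dose(self, small_cell, pg222):
        truth = generate_ground_truth(
            small_cell, pg222, 2.0, [HeavyAtomSite(frac_xyz=(0.1, 0.2, 0.3))], seed=1,
            n_dummy_atoms=10, damage=DamageModel(half_dose_site=5.0),
        )
        norms = [np.abs(truth.bijvoet_true(d)).max() for d in (0.0, 2.0, 5.0, 10.0, 20.0)]
        assert all(a > b for a, b in zip(norms, norms[1:]))


class TestWedgeGeometry:
    def geom(self, seed=0, delta_phi=0.5):
        U = Rotation.random(random_state=np.random.default_rng(seed)).as_matrix()
        return FrameGeometry(orientation=U, phi_start=0.0, delta_phi=delta_phi)

    def test_fully_swept_reflections_have_unit_partiality(self, truth):
        # with a 2 deg wedge and 0.03 deg mosaicity most crossings are full
        refl = reflections_in_wedge(truth, self.geom(delta_phi=2.0), 0.03)
        assert len(refl) > 0
        full = np.isclose(refl["partiality"], 1.0, atol=1e-3)
        assert full.mean() > 0.8
        assert refl["partiality"].max() <= 1.0

    def test_wider_wedge_emits_superset_count(self, truth):
        for seed in range(3):
            n_narrow = len(reflections_in_wedge(truth, self.geom(seed, 0.25), 0.03))
            n_wide = len(reflections_in_wedge(truth, self.geom(seed, 0.5), 0.03))
            assert n_wide >= n_narrow

    def test_partiality_in_unit_interval(self, truth):
        refl = reflections_in_wedge(truth, self.geom(3), 0.03)
        p = refl["partiality"].to_numpy()
        assert np.all(p > 0) and np.all(p <= 1.0)

    def test_still_uses_rocking_profile(self, truth):
        refl = reflections_in_wedge(truth, self.geom(4, 0.0), 0.03)
        # stills catch far fewer reflections than a wedge
        wedge = reflections_in_wedge(truth, self.geom(4, 0.5), 0.03)
        assert 0 < len(refl) < len(wedge)


class TestSimulateFrame:
    def test_identity_pipeline_recovers_truth(self, truth):
        """Noise off, dose 0, scale 1: I_obs / (p·L) equals i_true exactly."""
        geom = FrameGeometry(
            orientation=Rotation.random(random_state=np.random.default_rng(2)).as_matrix(),
            delta_phi=0.5,
        )
        cfg = SimConfig(n_frames=1, noise_b0=0.0, poisson_gain=0.0, seed=0)
        frame, obs = simulate_frame(truth, geom, cfg, crystal_scale=1.0)
        assert len(obs) > 0
        lookup = true_intensity_lookup(truth)
        refl = reflections_in_wedge(truth, geom, cfg.mosaicity_deg)
        refl = refl[refl["lorentz_inv"] >= 1e-3].reset_index(drop=True)
        # same emission order: undo partiality and Lorentz per observation
        undone = obs["intensity"].to_numpy() * refl["lorentz_inv"].to_numpy() / obs[
            "peak_fraction"
        ].to_numpy()
        from ssrox.crystal import asu_map

        H_asu, sign = asu_map(obs[["h", "k", "l"]].to_numpy(), truth.pg)
        expect = np.array(
            [lookup[(h, k, l, s)] for (h, k, l), s in zip(map(tuple, H_asu), sign)]
        )
        np.testing.assert_allclose(undone, expect, rtol=1e-9)

    def test_mean_observed_over_true_tracks_crystal_scale(self, truth):
        rng = np.random.default_rng(0)
        cfg = SimConfig(n_frames=1, noise_b0=500.0, seed=0)
        lookup = true_intensity_lookup(truth)
        ratios, weights = [], []
        for seed in range(150):
            geom = FrameGeometry(
                orientation=Rotation.random(random_state=rng).as_matrix(), delta_phi=0.5
            )
            frame, obs = simulate_frame(
                truth, geom, cfg, crystal_scale=1.6, rng=rng, frame_id=seed
            )
            if not len(obs):
                continue
            from ssrox.crystal import asu_map

            H_asu, sign = asu_map(obs[["h", "k", "l"]].to_numpy(), truth.pg)
            i_true = np.array(
                [lookup[(h, k, l, s)] for (h, k, l), s in zip(map(tuple, H_asu), sign)]
            )
            refl = reflections_in_wedge(truth, geom, cfg.mosaicity_deg)
            refl = refl[refl["lorentz_inv"] >= 1e-3]
            pred = i_true * refl["partiality"].to_numpy() / refl["lorentz_inv"].to_numpy()
            ratios.append(obs["intensity"].sum() / pred.sum())
            weights.append(len(obs))
        mean_ratio = np.average(ratios, weights=weights)
        se = np.std(ratios) / np.sqrt(len(ratios))
        assert abs(mean_ratio - 1.6) < 3 * se + 1e-3

    def test_negative_dose_rejected(self, truth):
        geom = FrameGeometry(orientation=np.eye(3))
        with pytest.raises(ValueError):
            simulate_frame(truth, geom, SimConfig(n_frames=1), accumulated_dose=-1.0)


class TestSimulateExperiment:
    def test_zero_hit_fraction_gives_empty_frames(self, truth):
        cfg = SimConfig(n_frames=30, hit_fraction=0.0, seed=1)
        frames, obs = simulate_experiment(truth, cfg)
        assert len(obs) == 0 and all(f.n_obs == 0 for f in frames)

    def test_hit_rate_binomial(self, truth):
        frames, _ = simulate_experiment(
            truth, SimConfig(n_frames=2000, hit_fraction=0.4, seed=2)
        )
        rate = np.mean([f.crystal_id >= 0 for f in frames])
        assert abs(rate - 0.4) < 3 * math.sqrt(0.4 * 0.6 / 2000)

    def test_determinism(self, truth):
        cfg = SimConfig(n_frames=25, hit_fraction=0.6, seed=13)
        f1, o1 = simulate_experiment(truth, cfg)
        f2, o2 = simulate_experiment(truth, cfg)
        pd.testing.assert_frame_equal(o1, o2)
        assert [f.true_scale for f in f1] == [f.true_scale for f in f2]

    def test_symmetry_mates_consistent_on_frame(self, truth):
        """Noise-free observations of symmetry mates differ only by p×L."""
        cfg = SimConfig(n_frames=60, hit_fraction=1.0, crystal_scale_sigma=0.0,
                        noise_b0=0.0, poisson_gain=0.0, seed=21)
        _, obs = simulate_experiment(truth, cfg)
        from ssrox.corrections import lorentz_inverse_array
        from ssrox.crystal import asu_map

        H_asu, sign = asu_map(obs[["h", "k", "l"]].to_numpy(), truth.pg)
        linv = lorentz_inverse_array(obs[["s1x", "s1y", "s1z"]].to_numpy(), (0, 1, 0), (0, 0, 1))
        norm = obs["intensity"].to_numpy() * linv / obs["peak_fraction"].to_numpy()
        df = pd.DataFrame(
            {"frame": obs["frame_id"], "h": H_asu[:, 0], "k": H_asu[:, 1],
             "l": H_asu[:, 2], "sign": sign, "norm": norm}
        )
        g = df.groupby(["frame", "h", "k", "l", "sign"])["norm"]
        spread = (g.max() - g.min()) / g.mean().abs()
        multi = g.size() > 1
        if multi.any():
            assert spread[multi].max() < 1e-6
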