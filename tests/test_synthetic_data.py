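"""Synthetic generator tests: phantoms, noise, denoising, cohorts."""

import numpy as np
import pytest
from scipy import ndimage, stats

from desst2.cohort_stats import condition_table, linear_assoc
from desst2.roi_analysis import nerve_angle_from_b0
from desst2.signal_models import dess_signals_analytic, TissueRelaxation
from desst2.synthetic_data import (
    CohortSpec,
    NoiseSpec,
    PhantomSpec,
    Structure,
    add_rician_noise,
    add_rician_noise_pair,
    default_phantom_spec,
    make_phantom,
    simulate_cohort,
    simulate_dess,
    simulate_nerve_tracks,
    surrogate_denoise,
)
from desst2.t2_mapping import VolumeGrid, compute_dess_t2_map


class TestPhantom:
    def test_cylinder_volume_within_10_percent(self):
        spec = PhantomSpec(
            shape=(64, 64, 10),
            structures=(
                Structure("cylinder", dict(center_mm=(9.6, 9.6), radius_mm=1.5),
                          label=1, tissue_class="nerve", t1_ms=1600.0, t2_ms=35.0),
            ),
        )
        maps = make_phantom(spec)
        n = int((maps.labels.labels == 1).sum())
        vox_vol = 0.3 * 0.3 * 1.6
        expected = np.pi * 1.5**2 * 16.0 / vox_vol
        assert abs(n - expected) / expected < 0.10

    def test_overlap_precedence_later_wins(self):
        spec = PhantomSpec(
            shape=(32, 32, 4),
            structures=(
                Structure("box", dict(x_min_mm=0.6, x_max_mm=9.0, y_min_mm=0.6,
                                      y_max_mm=9.0, z_min_mm=0.0, z_max_mm=6.4),
                          label=1, tissue_class="muscle", t1_ms=1400.0, t2_ms=27.0),
                Structure("cylinder", dict(center_mm=(4.8, 4.8), radius_mm=1.2),
                          label=2, tissue_class="nerve", t1_ms=1600.0, t2_ms=35.0),
            ),
        )
        maps = make_phantom(spec)
        cyl = maps.labels.labels == 2
        assert cyl.any()
        assert np.all(maps.t2.values[cyl] == 35.0)

    def test_structure_outside_grid_rejected(self):
        spec = PhantomSpec(
            shape=(16, 16, 4),
            structures=(
                Structure("cylinder", dict(center_mm=(0.0, 2.4), radius_mm=1.2),
                          label=1, tissue_class="nerve", t1_ms=1600.0, t2_ms=35.0),
            ),
        )
        with pytest.raises(ValueError):
            make_phantom(spec)

    def test_default_demo_phantom_tissues(self):
        maps = make_phantom(default_phantom_spec())
        t2_by_label = {
            lab: maps.t2.values[maps.labels.labels == lab][0]
            for lab in maps.labels.present_labels()
        }
        assert t2_by_label == {1: 27.0, 2: 38.0, 3: 35.0, 4: 76.0}
        assert maps.labels.t1_ms[3] == 1600.0 and maps.labels.t1_ms[1] == 1400.0


class TestSimulateDess:
    def test_zero_proton_density_gives_zero(self):
        spec = PhantomSpec(shape=(8, 8, 2), structures=())
        sp, sm = simulate_dess(make_phantom(spec), acq=_acq())
        assert not sp.values.any() and not sm.values.any()

    def test_voxel_matches_analytic_model(self):
        maps = make_phantom(default_phantom_spec())
        acq = _acq()
        sp, sm = simulate_dess(maps, acq)
        vox = tuple(np.argwhere(maps.labels.labels == 4)[0])
        pair = dess_signals_analytic(TissueRelaxation(1600.0, 76.0), acq)
        assert sp.values[vox] == pytest.approx(pair.s_plus, rel=1e-12)
        assert sm.values[vox] == pytest.approx(pair.s_minus, rel=1e-12)

    def test_doubling_pd_scales_echoes_not_t2(self):
        acq = _acq()
        maps = make_phantom(default_phantom_spec())
        sp1, sm1 = simulate_dess(maps, acq)
        maps.proton_density.values *= 2.0
        sp2, sm2 = simulate_dess(maps, acq)
        assert np.allclose(sp2.values, 2 * sp1.values)
        m1 = compute_dess_t2_map(sp1, sm1, maps.labels, acq)
        m2 = compute_dess_t2_map(sp2, sm2, maps.labels, acq)
        assert np.array_equal(m1.values[np.isfinite(m1.values)],
                              m2.values[np.isfinite(m2.values)])


class TestRicianNoise:
    def test_sigma_zero_is_identity(self):
        vol = VolumeGrid(np.random.default_rng(0).random((6, 6, 3)))
        out = add_rician_noise(vol, NoiseSpec(sigma=0.0, seed=1))
        assert np.array_equal(out.values, vol.values)

    def test_zero_signal_region_has_rayleigh_mean(self):
        sigma = 0.3
        vol = VolumeGrid(np.zeros((40, 40, 20)))
        out = add_rician_noise(vol, NoiseSpec(sigma=sigma, seed=2))
        n = vol.values.size
        expected = sigma * np.sqrt(np.pi / 2)
        se = sigma * np.sqrt((4 - np.pi) / 2) / np.sqrt(n)
        assert abs(out.values.mean() - expected) < 3 * se

    def test_high_snr_bias_matches_rician_expansion(self):
        a, sigma = 2.0, 0.1  # A/sigma = 20
        vol = VolumeGrid(np.full((40, 40, 20), a))
        out = add_rician_noise(vol, NoiseSpec(sigma=sigma, seed=3))
        bias = out.values.mean() - a
        se = sigma / np.sqrt(vol.values.size)
        assert abs(bias - sigma**2 / (2 * a)) < 3 * se

    def test_snr_resolution_and_validation(self):
        maps = make_phantom(default_phantom_spec())
        sp, sm = simulate_dess(maps, _acq())
        noise = NoiseSpec(snr=20.0, seed=4)
        sigma = noise.resolve_sigma(sp, maps.labels)
        muscle = np.isin(maps.labels.labels, [1, 2])
        assert sigma == pytest.approx(sp.values[muscle].mean() / 20.0)
        with pytest.raises(ValueError):
            NoiseSpec(sigma=1.0, snr=20.0)
        with pytest.raises(ValueError):
            NoiseSpec(sigma=-1.0)
        with pytest.raises(ValueError):
            NoiseSpec()


class TestSurrogateDenoise:
    def test_noiseless_uniform_volume_unchanged(self):
        vol = VolumeGrid(np.full((16, 16, 8), 2.5))
        out = surrogate_denoise(vol)
        assert np.allclose(out.values, 2.5, rtol=1e-9)

    @pytest.mark.parametrize("method", ["gaussian", "nonlocal"])
    def test_noise_sd_halved_mean_preserved(self, method):
        rng = np.random.default_rng(5)
        vol = VolumeGrid(1.0 + 0.1 * rng.standard_normal((32, 32, 12)))
        out = surrogate_denoise(vol, method=method)
        interior = out.values[4:-4, 4:-4, 3:-3]
        assert interior.std() <= 0.5 * vol.values.std()
        assert abs(interior.mean() - 1.0) < 0.01

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            surrogate_denoise(VolumeGrid(np.ones((4, 4, 2))), method="dlr")

    def test_bias_direction_on_muscle_roi(self):
        """Rician noise inflates mapped T2; denoising moves it back toward
        the noiseless value (the direction the study saw with DLR)."""
        acq = _acq()
        maps = make_phantom(_muscle_only_spec())
        sp, sm = simulate_dess(maps, acq)
        truth = 27.0
        nsp, nsm = add_rician_noise_pair(sp, sm, NoiseSpec(snr=20.0, seed=6), maps.labels)
        noisy = compute_dess_t2_map(nsp, nsm, maps.labels, acq)
        dsp, dsm = surrogate_denoise(nsp), surrogate_denoise(nsm)
        den = compute_dess_t2_map(dsp, dsm, maps.labels, acq)
        roi = ndimage.binary_erosion(
            maps.labels.labels == 1, structure=np.ones((3, 3, 1), bool), iterations=5
        )
        t2_noisy = np.nanmean(noisy.values[roi])
        t2_den = np.nanmean(den.values[roi])
        assert t2_noisy > truth
        assert abs(t2_den - truth) < abs(t2_noisy - truth)


class TestCohort:
    def test_fixed_seed_reproduces_table(self):
        a = simulate_cohort(CohortSpec(seed=11))
        b = simulate_cohort(CohortSpec(seed=11))
        assert a.equals(b)
        c = simulate_cohort(CohortSpec(seed=12))
        assert not a["t2_ms"].equals(c["t2_ms"])

    def test_schema(self):
        df = simulate_cohort(CohortSpec(n_subjects=4, seed=0))
        assert list(df.columns) == [
            "subject_id", "condition", "recon", "rater", "t2_ms",
            "mur_grade", "fp_psw_grade", "angle_deg",
        ]
        assert len(df) == 4 * 4 * 2 * 2
        assert df[df.condition.str.endswith("muscle")]["angle_deg"].isna().all()
        assert df["mur_grade"].between(0, 3).all()
        assert df["fp_psw_grade"].between(0, 4).all()

    def test_abnormal_muscle_moments_at_large_n(self):
        df = simulate_cohort(CohortSpec(n_subjects=10_000, seed=13))
        tab = condition_table(df, "muscle")
        x = tab["abnormal_dlr"]
        n = len(x)
        assert abs(x.mean() - 37.71) < 3 * 9.11 / np.sqrt(n) + 0.02
        # rater averaging keeps the SD within 2% of the configured 9.11
        assert abs(x.std() - 9.11) / 9.11 < 0.02 + 3 / np.sqrt(2 * n)

    def test_all_condition_moments_match_design(self):
        """Every condition's rater-averaged mean/SD matches the configured
        marginals; the SD carries the declared rater-noise inflation
        sqrt(1 + (1-r)/(2r)) ~ 1.3% at the default inter-rater r = 0.95."""
        n = 10_000
        df = simulate_cohort(CohortSpec(n_subjects=n, seed=14))
        from desst2.synthetic_data import TABLE3_CONDITIONS

        inflation = np.sqrt(1 + (1 - 0.95) / (2 * 0.95))
        for tissue in ("nerve", "muscle"):
            tab = condition_table(df, tissue)
            for col in tab.columns:
                group, recon = col.rsplit("_", 1)
                mu, sd = TABLE3_CONDITIONS[(tissue, group, recon)]
                assert abs(tab[col].mean() - mu) < 3 * sd * inflation / np.sqrt(n)
                expected_sd = sd * inflation
                assert abs(tab[col].std() - expected_sd) < 3 * expected_sd / np.sqrt(2 * n)

    def test_mur_slope_recovered_within_ci(self):
        df = simulate_cohort(CohortSpec(n_subjects=2000, seed=15))
        sub = df[(df.condition == "abnormal_muscle") & (df.recon == "dlr")]
        res = stats.linregress(sub.mur_grade, sub.t2_ms)
        assert abs(res.slope - 9.10) < 1.96 * res.stderr
        la = linear_assoc(sub.t2_ms, sub.mur_grade)
        assert la.slope == pytest.approx(res.slope)

    def test_inter_rater_correlation_near_target(self):
        df = simulate_cohort(CohortSpec(n_subjects=5000, seed=16))
        sub = df[(df.condition == "normal_muscle") & (df.recon == "dlr")]
        wide = sub.pivot(index="subject_id", columns="rater", values="t2_ms")
        r = np.corrcoef(wide[1], wide[2])[0, 1]
        assert abs(r - 0.95) < 0.02

    def test_impossible_specs_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(inter_rater_r=1.5)
        with pytest.raises(ValueError):
            CohortSpec(rho_recon=1.2)
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=1)
        with pytest.raises(ValueError):
            # uniform grades put more variance into the slope term than the
            # configured abnormal-muscle SD allows
            simulate_cohort(CohortSpec(grade_probs=(0.25, 0.25, 0.25, 0.25), seed=0))


class TestNerveTracks:
    def test_unit_norm_and_round_trip(self):
        tracks = simulate_nerve_tracks(200, seed=17)
        for v, angle in tracks:
            assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-12)
            assert abs(nerve_angle_from_b0(v) - angle) < 1e-6
            assert 6.14 <= angle <= 46.10

    def test_zero_angle_gives_b0_axis(self):
        (v, angle), = simulate_nerve_tracks(1, angle_range_deg=(0.0, 0.0), seed=0)
        assert angle == 0.0
        assert abs(v[2]) == pytest.approx(1.0)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_nerve_tracks(5, angle_range_deg=(-5.0, 20.0))


def _acq():
    from desst2.signal_models import AcquisitionParams

    return AcquisitionParams()


def _muscle_only_spec() -> PhantomSpec:
    return PhantomSpec(
        shape=(48, 48, 8),
        structures=(
            Structure("box", dict(x_min_mm=1.2, x_max_mm=13.2, y_min_mm=1.2,
                                  y_max_mm=13.2, z_min_mm=0.0, z_max_mm=12.8),
                      label=1, tissue_class="muscle", t1_ms=1400.0, t2_ms=27.0),
        ),
    )
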