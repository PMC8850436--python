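"""Generator ground truth: geometry, rendering, formants, ratings."""

import numpy as np
import pytest

from vtmod import synthetic as syn
from vtmod.acoustics import DomainError, compute_avtl
from vtmod.core import GeometryError, RigidTransform, polyline_length
from vtmod.fpca import resample_contour


class TestContourGeometry:
    def test_zero_params_give_template(self, template_outline):
        again = syn.make_vocal_tract_contour(syn.ShapeParams())
        assert np.array_equal(again.points, template_outline.points)

    def test_contour_is_simple_across_extremes(self):
        for p in [
            syn.ShapeParams(),
            syn.ShapeParams(larynx_height=1.0),
            syn.ShapeParams(larynx_height=-1.0),
            syn.ShapeParams(tongue_position=1.0, tongue_shape=1.0),
            syn.ShapeParams(tongue_position=-1.0, tongue_shape=-1.0, curvature=1.0),
            syn.ShapeParams(body_scale=1.2, curvature=-1.0),
        ]:
            assert syn.make_vocal_tract_contour(p).is_simple()

    def test_larynx_excursion_changes_centerline_by_30mm(self):
        lo = polyline_length(syn.make_centerline(syn.ShapeParams(larynx_height=-1.0)))
        hi = polyline_length(syn.make_centerline(syn.ShapeParams(larynx_height=+1.0)))
        assert lo - hi == pytest.approx(2 * syn.MAX_LARYNX_EXCURSION_MM, abs=1e-9)

    def test_larynx_leaves_oral_points_unchanged(self):
        a = syn.make_vocal_tract_contour(syn.ShapeParams(larynx_height=-1.0))
        b = syn.make_vocal_tract_contour(syn.ShapeParams(larynx_height=+1.0))
        # points on the palate and tongue walls (oral segment) are identical
        oral_a = a.points[a.points[:, 1] < syn.BEND_CENTRE[1] - 10]
        oral_b = b.points[b.points[:, 1] < syn.BEND_CENTRE[1] - 10]
        assert np.allclose(oral_a, oral_b, atol=1e-12)

    def test_body_scale_doubles_distance_from_origin(self, template_outline):
        scaled = syn.make_vocal_tract_contour(syn.ShapeParams(body_scale=2.0))
        origin = np.asarray(syn.ORIGIN)
        d1 = np.linalg.norm(template_outline.points - origin, axis=1)
        d2 = np.linalg.norm(scaled.points - origin, axis=1)
        assert np.allclose(d2, 2 * d1, atol=1e-9)

    def test_analytic_centerline_matches_numeric(self):
        for p in [syn.ShapeParams(), syn.ShapeParams(larynx_height=0.4, curvature=0.5, body_scale=1.1)]:
            assert syn.centerline_length_mm(p) == pytest.approx(
                polyline_length(syn.make_centerline(p)), rel=2e-4
            )

    def test_out_of_range_params_name_field(self):
        with pytest.raises(DomainError, match="larynx_height"):
            syn.ShapeParams(larynx_height=1.5)
        with pytest.raises(DomainError, match="body_scale"):
            syn.ShapeParams(body_scale=-1.0)

    def test_single_param_families_are_monotone_manifolds(self):
        # pairwise curve distances increase with parameter separation
        # within the near-linear regime the generator samples from
        for field in ("tongue_position", "larynx_height", "curvature"):
            values = np.linspace(-0.5, 0.5, 7)
            curves = [
                resample_contour(
                    syn.make_vocal_tract_contour(syn.ShapeParams(**{field: float(v)})),
                    100,
                ).concat()
                for v in values
            ]
            ref = curves[0]
            dists = [np.linalg.norm(c - ref) for c in curves]
            assert all(np.diff(dists) > 0)


class TestRendering:
    def test_noiseless_air_and_determinism(self, template_outline):
        from scipy import ndimage

        f1 = syn.render_frame(template_outline, noise_sd=0.0)
        air = syn.rasterize_air_mask(template_outline)
        interior = ndimage.binary_erosion(air)
        assert np.allclose(f1.intensities[interior], syn.DEFAULT_GEOMETRY.air)
        f2 = syn.render_frame(template_outline, noise_sd=5.0, seed=7)
        f3 = syn.render_frame(template_outline, noise_sd=5.0, seed=7)
        assert np.array_equal(f2.intensities, f3.intensities)
        assert not np.array_equal(f1.intensities, f2.intensities)

    def test_monte_carlo_mean_matches_noiseless(self, template_outline):
        base = syn.render_frame(template_outline).intensities
        acc = np.zeros_like(base)
        n = 300
        for s in range(n):
            acc += syn.render_frame(template_outline, noise_sd=5.0, seed=s).intensities
        dev = np.abs(acc / n - base)
        assert dev.mean() < 0.5

    def test_out_of_fov_raises(self, template_outline):
        with pytest.raises(GeometryError):
            syn.render_frame(template_outline, rigid=RigidTransform(0.0, (150.0, 0.0)))


class TestSessions:
    def test_null_modulator_constant_params(self):
        prof = syn.SpeakerProfile(
            "p", modulation_amplitude=0.0, trial_jitter_sd=0.0,
            tongue_jitter_sd=0.0, scale_jitter_sd=0.0, curvature_jitter_sd=0.0,
            frame_noise_sd=0.0,
        )
        design = syn.TrialDesign.rtmri(n_trials_per_condition=1, frames_per_trial=1)
        _, gt = syn.simulate_speaker_session(prof, design, seed=0)
        # within each word the vt conditions produce identical parameters
        for _, g in gt.frames.groupby("word"):
            assert g["larynx_height"].nunique() == 1
            assert g["true_vtl_cm"].nunique() == 1

    def test_amplitude_ratio_recovered_from_truth(self):
        lengths = {}
        design = syn.TrialDesign.rtmri(n_trials_per_condition=1, frames_per_trial=1)
        for amp in (0.2, 0.8):
            prof = syn.SpeakerProfile(
                f"a{amp}", modulation_amplitude=amp, trial_jitter_sd=0.0,
                tongue_jitter_sd=0.0, scale_jitter_sd=0.0, curvature_jitter_sd=0.0,
                frame_noise_sd=0.0,
            )
            _, gt = syn.simulate_speaker_session(prof, design, seed=0)
            lengths[amp] = gt.takes["true_vtl_cm"].max() - gt.takes["true_vtl_cm"].min()
        assert lengths[0.8] / lengths[0.2] == pytest.approx(4.0, rel=0.01)

    def test_fixed_seed_reproducible(self):
        prof = syn.SpeakerProfile("p", modulation_amplitude=0.5)
        design = syn.TrialDesign.rtmri(n_trials_per_condition=1, frames_per_trial=1)
        _, gt1 = syn.simulate_speaker_session(prof, design, seed=11)
        _, gt2 = syn.simulate_speaker_session(prof, design, seed=11)
        assert gt1.frames.equals(gt2.frames)

    def test_amplitude_bound_enforced(self):
        with pytest.raises(DomainError):
            syn.SpeakerProfile(
                "p",
                baseline_params=syn.ShapeParams(larynx_height=0.5),
                modulation_amplitude=0.8,
            )


class TestFormants:
    def test_quarter_wave_no_coloring(self):
        t = syn.simulate_formants(17.5, coloring=False, noise_cv=0.0)
        assert np.allclose(t.formants_hz, [500.0, 1500.0, 2500.0, 3500.0])

    def test_halving_length_doubles_formants(self):
        a = syn.simulate_formants(16.0, coloring=False, noise_cv=0.0)
        b = syn.simulate_formants(8.0, coloring=False, noise_cv=0.0)
        assert np.allclose(b.formants_hz, 2 * a.formants_hz)

    def test_noise_cv_calibrated(self):
        f1 = np.array(
            [
                syn.simulate_formants(15.0, noise_cv=0.03, seed=s).f1_hz
                for s in range(4000)
            ]
        )
        cv = f1.std() / f1.mean()
        assert cv == pytest.approx(0.03, abs=0.005)

    def test_avtl_recovers_length_without_coloring(self):
        for L in (12.0, 15.0, 17.5, 20.0):
            t = syn.simulate_formants(L, coloring=False, noise_cv=0.0)
            assert compute_avtl(t) == pytest.approx(L, rel=0.01)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(DomainError):
            syn.simulate_formants(-3.0)


class TestAcousticSession:
    def test_perfect_imitator_hits_targets(self):
        prof = syn.SpeakerProfile(
            "p", acoustic_fidelity=1.0, f0_fidelity=1.0, vtl_jitter_cv=0.0,
            baseline_vtl_cm=15.0,
        )
        takes, truth = syn.simulate_acoustic_session(
            prof, session="rtmri", n_takes=1, noise_cv=0.0
        )
        for t, row in zip(takes, truth.itertuples()):
            expected = 15.0 * 2 ** (-t.condition.vtl_shift_st / 12)
            assert row.true_vtl_cm == pytest.approx(expected)

    def test_half_fidelity_halves_ratio(self):
        prof = syn.SpeakerProfile(
            "p", acoustic_fidelity=0.5, vtl_jitter_cv=0.0, baseline_vtl_cm=15.0
        )
        takes, truth = syn.simulate_acoustic_session(
            prof, session="rtmri", n_takes=1, noise_cv=0.0
        )
        big = truth[truth.vtl_shift_st == -4]["true_vtl_cm"].iloc[0]
        assert big == pytest.approx(15.0 * 2 ** (2 / 12))


class TestPlantedModes:
    def test_decorrelated_draws_and_shares(self):
        z, curves, sd = syn.sample_shape_dataset(200, seed=0)
        assert len(curves) == 200
        C = np.cov(z.T)
        # off-diagonals vanish by construction (exact decorrelation)
        off = C - np.diag(np.diag(C))
        assert np.abs(off).max() < 1e-10

    def test_canonical_deformations_match_param_directions(self):
        refs = syn.canonical_deformations(100)
        modes = syn.shape_mode_curves(100)
        assert np.allclose(refs["shorten"], modes[1])
        assert np.allclose(refs["front"], modes[0])


class TestPerceptionRatings:
    def _stimuli(self, sexes=("female",)):
        rows = []
        for sex in sexes:
            for grp in ("good", "poor"):
                for vt, f0 in [("baseline", 0), ("small", 4), ("small", -4), ("large", 4), ("large", -4)]:
                    rows.append(
                        {
                            "speaker_id": f"{sex}_{grp}",
                            "voice_sex": sex,
                            "skill_group": grp,
                            "word": "bead",
                            "vt_condition": vt,
                            "f0_modulation_st": f0,
                        }
                    )
        import pandas as pd

        return pd.DataFrame(rows)

    def test_null_model_gives_grand_mean(self):
        trials = syn.simulate_perception_ratings(
            self._stimuli(), syn.RatingEffects.null(165.0), n_listeners=3, seed=0
        )
        assert np.allclose(trials["rating_cm"], 165.0)

    def test_vt_effect_recovered_in_means(self):
        eff = syn.RatingEffects.null(165.0)
        eff.vt_effect_cm = {"small": 0.0, "baseline": 0.0, "large": 3.0}
        eff.listener_sd_cm = 1.0
        eff.residual_sd_cm = 2.0
        trials = syn.simulate_perception_ratings(
            self._stimuli(), eff, n_listeners=200, seed=0
        )
        large = trials[trials.vt_condition == "large"]["rating_cm"].mean()
        base = trials[trials.vt_condition == "baseline"]["rating_cm"].mean()
        assert large - base == pytest.approx(3.0, abs=0.3)

    def test_male_ratings_clipped_to_slider(self):
        eff = syn.RatingEffects()
        eff.grand_mean_cm["male"] = 188.0
        eff.residual_sd_cm = 10.0
        trials = syn.simulate_perception_ratings(
            self._stimuli(sexes=("male",)), eff, n_listeners=50, seed=0
        )
        assert trials["rating_cm"].max() <= 190.0
        assert trials["rating_cm"].min() >= 155.0

    def test_missing_effect_term_raises(self):
        stim = self._stimuli()
        eff = syn.RatingEffects.null()
        eff.vt_effect_cm = {"baseline": 0.0}
        with pytest.raises(KeyError):
            syn.simulate_perception_ratings(stim, eff, n_listeners=2, seed=0)

    def test_geometry_acoustics_consistency(self):
        """aVTL computed from noiseless formants equals the session truth."""
        prof = syn.SpeakerProfile("p", baseline_vtl_cm=16.0, vtl_jitter_cv=0.0)
        takes, truth = syn.simulate_acoustic_session(
            prof, session="rtmri", n_takes=1, noise_cv=0.0, coloring=False
        )
        for t, row in zip(takes, truth.itertuples()):
            assert compute_avtl(t) == pytest.approx(row.true_vtl_cm, rel=0.01)
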