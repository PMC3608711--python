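"""Phantom generator: calibration, geometry, determinism, forward model."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import norm

from darklung import (
    GROUP_CONTROL,
    GROUP_EMPHYSEMA,
    PhantomParams,
    StepScan,
    forward_project,
    generate_cohort,
    make_lung_phantom,
    rescale_thickness,
    retrieve_signals,
)
from darklung.phantom import (
    PhantomParameterError,
    QuantileMap,
    build_group_maps,
    phantom_geometry,
)


class TestParams:
    def test_defaults_valid(self):
        p = PhantomParams()
        assert p.specimen_ids() == ("E1", "E2", "E3", "C1", "C2", "C3")
        assert p.group_of("E2") == GROUP_EMPHYSEMA
        assert p.group_of("C1") == GROUP_CONTROL

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_steps=2),
            dict(reference_visibility=0.0),
            dict(reference_visibility=1.5),
            dict(noise_model="gaussian"),
            dict(group_T_quantiles={
                GROUP_EMPHYSEMA: (1.17, 1.11, 1.07),
                GROUP_CONTROL: (1.04, 1.06, 1.10),
            }),
            # median T below exp(c): u not positive on typical lung pixels
            dict(group_T_quantiles={
                GROUP_EMPHYSEMA: (1.001, 1.01, 1.02),
                GROUP_CONTROL: (1.04, 1.06, 1.10),
            }, container_log_offset=0.02),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises((PhantomParameterError, ValueError)):
            PhantomParams(**kwargs)


class TestCalibration:
    @pytest.mark.parametrize("group", [GROUP_EMPHYSEMA, GROUP_CONTROL])
    def test_marginal_quartiles_match_configuration(self, group):
        """With spatial correlation off, 1e5 lung-pixel draws reproduce
        the configured quartiles of exp(u+c) and s within 1% relative."""
        params = PhantomParams(spatial_sigma=0.0, seed=3)
        u_map, s_map = build_group_maps(params, group)
        rng = np.random.default_rng(42)
        n = 100_000
        u = u_map.transform(rng.standard_normal(n))
        s = s_map.transform(rng.standard_normal(n))
        T = np.exp(u + params.container_log_offset)
        for sample, target in (
            (T, params.group_T_quantiles[group]),
            (s, params.group_S_quantiles[group]),
        ):
            got = np.percentile(sample, [25, 50, 75])
            assert np.allclose(got, target, rtol=0.01)

    @pytest.mark.parametrize("group", [GROUP_EMPHYSEMA, GROUP_CONTROL])
    def test_darkfield_median_emerges_at_target(self, group):
        """The tail-calibrated scatter marginal makes the emergent
        dark-field median exp(-median(s*u)) land on the configured
        value in both groups."""
        params = PhantomParams(seed=3)
        u_map, s_map = build_group_maps(params, group)
        rng = np.random.default_rng(5)
        n = 400_000
        V = np.exp(
            -s_map.transform(rng.standard_normal(n))
            * u_map.transform(rng.standard_normal(n))
        )
        assert np.median(V) == pytest.approx(params.group_V_median, rel=0.01)

    def test_degenerate_quantiles_give_constant_field(self):
        params = PhantomParams(
            group_T_quantiles={
                GROUP_EMPHYSEMA: (1.11, 1.11, 1.11),
                GROUP_CONTROL: (1.06, 1.06, 1.06),
            },
            group_S_quantiles={
                GROUP_EMPHYSEMA: (4.9, 4.9, 4.9),
                GROUP_CONTROL: (10.8, 10.8, 10.8),
            },
        )
        truth = make_lung_phantom(params, "E1", 0)
        u = truth.u_map[truth.lung_mask]
        s = truth.s_map[truth.lung_mask]
        assert np.allclose(u, np.log(1.11) - 0.02)
        assert np.allclose(s, 4.9)

    def test_quantile_map_monotone(self):
        qm = QuantileMap((4.1, 4.9, 5.8), tail_lo=0.4)
        z = np.linspace(-6, 6, 2001)
        x = qm.transform(z)
        assert np.all(np.diff(x) > 0)
        # cdf inverts the transform
        assert np.allclose(qm.log_cdf(np.log(x)), norm.cdf(z), atol=1e-12)


class TestTruth:
    def test_masks_disjoint_and_fields_positive_on_lung(self, small_truth):
        t = small_truth
        assert not (t.lung_mask & t.formalin_roi).any()
        assert not (t.lung_mask & t.water_roi).any()
        assert not (t.formalin_roi & t.water_roi).any()
        assert (t.u_map[t.lung_mask] > 0).all()
        assert (t.s_map[t.lung_mask] > 0).all()
        assert (t.u_map[~t.lung_mask] == 0).all()
        assert (t.s_map[~t.lung_mask] == 0).all()

    def test_lung_rotates_with_projection(self, small_params):
        g0 = phantom_geometry(small_params.image_shape, 0, 11)
        g3 = phantom_geometry(small_params.image_shape, 3, 11)
        assert (g0["lung_mask"] != g3["lung_mask"]).any()

    def test_same_seed_bit_identical(self, small_params):
        a = make_lung_phantom(small_params, "C1", 1)
        b = make_lung_phantom(small_params, "C1", 1)
        assert np.array_equal(a.u_map, b.u_map)
        assert np.array_equal(a.s_map, b.s_map)

    def test_spatial_smoothing_preserves_quartiles(self):
        """Rank-preserving correlation: smoothed and unsmoothed phantoms
        share the same marginal quartiles (within sampling error)."""
        base = dict(image_shape=(192, 192), seed=9)
        smooth = make_lung_phantom(PhantomParams(**base), "E1", 0)
        rough = make_lung_phantom(
            PhantomParams(spatial_sigma=0.0, **base), "E1", 0
        )
        qs = np.percentile(smooth.s_map[smooth.lung_mask], [25, 50, 75])
        qr = np.percentile(rough.s_map[rough.lung_mask], [25, 50, 75])
        assert np.allclose(qs, qr, rtol=0.06)


class TestForwardModel:
    def test_water_pixels_identical_to_reference(self, small_params, small_truth):
        params = dataclasses.replace(small_params, noise_model="none")
        sample, reference = forward_project(small_truth, params)
        w = small_truth.water_roi
        assert np.array_equal(sample.frames[:, w], reference.frames[:, w])

    def test_formalin_ratio_is_container_offset(self, small_params, small_truth):
        params = dataclasses.replace(small_params, noise_model="none")
        sample, reference = forward_project(small_truth, params)
        f = small_truth.formalin_roi
        ratio = sample.frames[:, f] / reference.frames[:, f]
        assert np.allclose(ratio, np.exp(params.container_log_offset))

    def test_retrieved_signals_match_closed_form(self, small_params):
        """Noise off, u=0.0844 and s=4.9 everywhere on the lung: the
        retrieval must return T = exp(0.1044) ~ 1.110 and
        V = exp(-0.4136) ~ 0.661 exactly."""
        params = dataclasses.replace(
            small_params,
            noise_model="none",
            spatial_sigma=0.0,
            group_T_quantiles={
                GROUP_EMPHYSEMA: tuple([np.exp(0.0844 + 0.02)] * 3),
                GROUP_CONTROL: (1.04, 1.06, 1.10),
            },
            group_S_quantiles={
                GROUP_EMPHYSEMA: (4.9, 4.9, 4.9),
                GROUP_CONTROL: (7.5, 10.8, 14.7),
            },
        )
        truth = make_lung_phantom(params, "E1", 0)
        triplet = retrieve_signals(*forward_project(truth, params))
        lung = truth.lung_mask
        assert np.allclose(triplet.T_map[lung], np.exp(0.1044), rtol=1e-10)
        assert np.allclose(
            triplet.V_map[lung], np.exp(-4.9 * 0.0844), rtol=1e-10
        )

    def test_thickness_rescaling_moves_T_V_not_s(self, small_truth):
        lam = np.full(small_truth.u_map.shape, 1.7)
        scaled = rescale_thickness(small_truth, lam)
        lung = small_truth.lung_mask
        assert np.array_equal(scaled.s_map, small_truth.s_map)
        assert np.allclose(scaled.u_map[lung], 1.7 * small_truth.u_map[lung])
        T0 = small_truth.true_transmission(0.02)
        T1 = scaled.true_transmission(0.02)
        V0 = small_truth.true_visibility()
        V1 = scaled.true_visibility()
        assert (T1[lung] > T0[lung]).all()
        assert (V1[lung] < V0[lung]).all()
        # true normalized scatter -ln(V)/(ln(T)-c) is invariant
        s0 = -np.log(V0[lung]) / (np.log(T0[lung]) - 0.02)
        s1 = -np.log(V1[lung]) / (np.log(T1[lung]) - 0.02)
        assert np.allclose(s0, s1, rtol=1e-9)

    def test_poisson_noise_gives_integer_counts(self, small_scan_pair):
        sample, reference = small_scan_pair
        assert np.array_equal(sample.frames, np.round(sample.frames))
        assert (sample.frames >= 0).all()


class TestCohort:
    def test_default_cohort_counts(self):
        params = PhantomParams(image_shape=(32, 32))
        n = sum(1 for _ in generate_cohort(params))
        assert n == 6 * 11

    def test_minimal_cohort_counts(self):
        params = PhantomParams(
            image_shape=(32, 32), n_per_group=1, n_projections=1
        )
        assert sum(1 for _ in generate_cohort(params)) == 2

    def test_cohort_deterministic_under_seed(self, small_params):
        def checksum():
            return [
                (t.specimen_id, float(s.frames.sum()), float(r.frames.sum()))
                for t, s, r in generate_cohort(small_params)
            ]

        assert checksum() == checksum()


class TestStepScan:
    def test_frame_step_mismatch_rejected(self):
        with pytest.raises(ValueError, match="step fractions"):
            StepScan(
                frames=np.zeros((4, 8, 8)),
                step_fractions=np.arange(3) / 3,
                is_reference=False,
            )

    def test_step_fractions_must_stay_in_period(self):
        with pytest.raises(ValueError, match="increasing"):
            StepScan(
                frames=np.zeros((3, 4, 4)),
                step_fractions=np.array([0.0, 0.5, 1.0]),
                is_reference=False,
            )
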