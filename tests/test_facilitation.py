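"""Lateral-facilitation line completion: masks, summation, recombination."""

import math

import numpy as np
import pytest

from angiovis import Frame, ParameterError, load_config
from angiovis.facilitation import (AdditiveSignalSpec, additive_mask,
                                   collinear_sum, compute_lf_stack,
                                   induce_additive, percentile_soft_threshold,
                                   recombine_orientations,
                                   recombine_polarities, recombine_scales)
from angiovis.gabor import compute_edge_stack

ORIENTS = np.arange(8) * 22.5


def make_spec(**kw):
    defaults = dict(sigma_x=0.05, sigma_y=0.05, strength=1.0, rf_radius=3.0,
                    pixel_scale=128.0)
    defaults.update(kw)
    return AdditiveSignalSpec(**defaults)


class TestAdditiveMask:
    def test_horizontal_mask_symmetry(self):
        spec = make_spec(sigma_x=0.1, sigma_y=0.02)
        m = additive_mask(0.0, spec)
        np.testing.assert_array_equal(m, m[::-1, :])      # mirror in y
        np.testing.assert_array_equal(m, m[:, ::-1])      # even in x
        # elongated along x: larger spread across columns than rows
        h, w = m.shape
        y, x = np.mgrid[:h, :w] - np.array([[h // 2]], dtype=float)[..., None]
        assert (m * x * x).sum() > 4 * (m * y * y).sum()

    def test_rotation_by_90_transposes(self):
        spec = make_spec(sigma_x=0.1, sigma_y=0.03)
        m0 = additive_mask(0.0, spec)
        m90 = additive_mask(90.0, spec)
        np.testing.assert_allclose(m90, m0.T, atol=1e-10)

    def test_unit_sum_and_zero_center_disk(self):
        spec = make_spec()
        m = additive_mask(45.0, spec)
        assert math.isclose(m.sum(), 1.0, rel_tol=1e-12)
        h = m.shape[0] // 2
        y, x = np.mgrid[-h:h + 1, -h:h + 1]
        assert np.all(m[np.hypot(y, x) <= spec.rf_radius] == 0)

    def test_rf_radius_swallows_support(self, caplog):
        spec = make_spec(sigma_x=0.01, sigma_y=0.01, rf_radius=50.0)
        with caplog.at_level("WARNING"):
            m = additive_mask(0.0, spec)
        assert np.all(m == 0)
        assert "empty" in caplog.text

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            make_spec(sigma_x=-1)
        with pytest.raises(ParameterError):
            make_spec(support=10)


class TestInduceAdditive:
    def test_zero_response_zero_fields(self):
        spec = make_spec()
        fields = induce_additive(np.zeros((32, 32)), np.zeros((32, 32), int),
                                 spec, ORIENTS)
        assert np.all(fields == 0)

    def test_zero_strength_zero_fields(self, rng):
        spec = make_spec(strength=0.0)
        fields = induce_additive(rng.random((32, 32)),
                                 rng.integers(0, 8, (32, 32)), spec, ORIENTS)
        assert np.all(fields == 0)

    def test_single_pixel_impulse_response(self):
        """One active pixel at angle theta spreads a * R * mask around it."""
        spec = make_spec(strength=2.0, sigma_x=0.04, sigma_y=0.04,
                         rf_radius=2.0, pixel_scale=64.0)
        r = np.zeros((63, 63))
        r[31, 31] = 0.5
        angle = np.full((63, 63), 3)
        fields = induce_additive(r, angle, spec, ORIENTS)
        mask = additive_mask(ORIENTS[3], spec)
        half = mask.shape[0] // 2
        expected = 2.0 * 0.5 * mask
        np.testing.assert_allclose(
            fields[3][31 - half:31 + half + 1, 31 - half:31 + half + 1],
            expected, atol=1e-12)
        others = [i for i in range(8) if i != 3]
        assert np.all(fields[others] == 0)


class TestCollinearSum:
    @staticmethod
    def _lf_for(segments, theta_idx=0, size=64):
        """LF field for unit responses on the given pixel segments, all
        assigned the same orientation channel."""
        r = np.zeros((size, size))
        for rows, cols in segments:
            r[rows, cols] = 1.0
        angle = np.full((size, size), theta_idx)
        spec = make_spec(sigma_x=0.08, sigma_y=0.08, rf_radius=4.0,
                         pixel_scale=size)
        fields = induce_additive(r, angle, spec, ORIENTS)
        return collinear_sum(r, angle, fields)

    def test_flanker_raises_gap_lf(self):
        """A collinear flanker strictly raises LF in the gap between bars
        over what the isolated bar produces there (superposition)."""
        one_bar = self._lf_for([(32, slice(10, 26))])
        two_bar = self._lf_for([(32, slice(10, 26)), (32, slice(38, 54))])
        gap = (32, slice(28, 36))
        assert np.all(two_bar[0][gap] > one_bar[0][gap])

    def test_orthogonal_flanker_contributes_nothing_to_channel(self):
        """A second bar of a different preferred orientation lives in another
        channel: the first bar's channel LF in the gap is unchanged."""
        one_bar = self._lf_for([(32, slice(10, 26))])
        r = np.zeros((64, 64))
        r[32, 10:26] = 1.0
        r[20:36, 45] = 1.0
        angle = np.full((64, 64), 0)
        angle[20:36, 45] = 4   # orthogonal preference
        spec = make_spec(sigma_x=0.08, sigma_y=0.08, rf_radius=4.0,
                         pixel_scale=64)
        fields = induce_additive(r, angle, spec, ORIENTS)
        mixed = collinear_sum(r, angle, fields)
        gap = (32, slice(28, 36))
        np.testing.assert_allclose(mixed[0][gap], one_bar[0][gap], atol=1e-12)


class TestPercentileSoftThreshold:
    def test_all_zero_stays_zero(self):
        out, thr = percentile_soft_threshold(np.zeros((3, 8, 8)), 97.0)
        assert np.all(out == 0) and thr == 0.0

    def test_99th_percentile_keeps_only_top_value(self):
        lf = np.arange(1.0, 101.0).reshape(1, 10, 10)
        out, thr = percentile_soft_threshold(lf, 99.0)
        # only the maximum sits above thr, so only it gets H > 0.5
        assert np.sum(out > 0.5 * lf) == 1
        assert out.flat[-1] > 0.5 * 100.0

    def test_hard_limit_recovers_indicator_gate(self, rng):
        lf = rng.random((2, 16, 16))
        out, thr = percentile_soft_threshold(lf, 80.0, steepness=math.inf)
        np.testing.assert_array_equal(out, np.where(lf > thr, lf, 0.0))

    def test_constant_field_halved(self, caplog):
        lf = np.full((1, 8, 8), 0.4)
        with caplog.at_level("WARNING"):
            out, thr = percentile_soft_threshold(lf, 96.0)
        assert thr == 0.4
        np.testing.assert_allclose(out, 0.2)
        assert "constant" in caplog.text

    def test_invalid_gamma(self):
        with pytest.raises(ParameterError):
            percentile_soft_threshold(np.zeros((1, 4, 4)), 100.0)


class TestRecombination:
    def test_polarity_difference_identity(self, rng):
        pos, neg = rng.random((2, 4, 8, 8))
        np.testing.assert_array_equal(recombine_polarities(pos, neg), pos - neg)

    def test_orientation_m1_1_plain_sum(self, rng):
        signed = rng.normal(size=(8, 6, 6))
        np.testing.assert_allclose(recombine_orientations(signed, 1),
                                   signed.sum(axis=0), atol=1e-12)

    def test_orientation_single_channel_inverse_pair(self, rng):
        signed = np.zeros((8, 5, 5))
        signed[2] = rng.normal(size=(5, 5))
        for m1 in (1, 2, 3):
            np.testing.assert_allclose(recombine_orientations(signed, m1),
                                       signed[2], atol=1e-12)

    def test_orientation_m1_2_example(self):
        signed = np.zeros((2, 1, 1))
        signed[0], signed[1] = 0.3, -0.1
        out = recombine_orientations(signed, 2)
        np.testing.assert_allclose(out[0, 0], math.sqrt(0.08), rtol=1e-12)

    def test_orientation_power_keeps_agreeing_sign(self, rng):
        signed = np.abs(rng.normal(size=(8, 6, 6)))   # all channels positive
        for m1 in (2, 3):
            assert np.all(recombine_orientations(signed, m1) >= 0)

    def test_scales_single_scale_inverse_pair(self, rng):
        t = rng.normal(size=(16, 16))
        _, _, te = recombine_scales([t], [1.0], 2, 1 / 8, (16, 16))
        np.testing.assert_allclose(te, t / 8, atol=1e-12)

    def test_scales_all_zero(self):
        _, _, te = recombine_scales([np.zeros((8, 8))] * 3, [1.0] * 3, 2,
                                    1 / 8, (8, 8))
        assert np.all(te == 0)

    def test_scales_two_equal_values_example(self):
        t = [np.full((8, 8), 0.2), np.full((8, 8), 0.2)]
        _, compound, te = recombine_scales(t, [1.0, 1.0], 2, 1 / 8, (8, 8))
        np.testing.assert_allclose(compound, 0.08, rtol=1e-12)
        np.testing.assert_allclose(te, math.sqrt(0.08) / 8, rtol=1e-12)

    def test_scales_homogeneous(self, rng):
        t = [np.abs(rng.normal(size=(12, 12))) for _ in range(3)]
        _, _, te1 = recombine_scales(t, [1.0] * 3, 2, 1 / 8, (12, 12))
        scaled = [3.5 * x for x in t]
        _, _, te2 = recombine_scales(scaled, [1.0] * 3, 2, 1 / 8, (12, 12))
        np.testing.assert_allclose(te2, 3.5 * te1, rtol=1e-10)

    def test_literal_power_variant(self):
        t = [np.full((4, 4), 0.2)]
        _, _, te = recombine_scales(t, [1.0], 2, 1 / 8, (4, 4),
                                    literal_te_power=True)
        # literal reading: TE = gamma * T^m2 with T = 0.2^2 = 0.04
        np.testing.assert_allclose(te, 0.04 ** 2 / 8, rtol=1e-12)


class TestPipelineStage:
    def test_zero_edge_stack_zero_texture(self):
        """Constant frame -> zero edges -> TE identically zero at every
        intermediate stage."""
        cfg = load_config()
        frame = Frame(np.full((64, 64), 0.5))
        pyramid, _, edges = compute_edge_stack(frame, cfg)
        lf = compute_lf_stack(pyramid, edges, cfg)
        for j in range(pyramid.n_scales):
            for pol in ("pos", "neg"):
                assert np.all(lf.lf[j][pol] == 0)
                assert np.all(lf.lf_thr[j][pol] == 0)
            assert np.all(lf.t_per_scale[j] == 0)
        assert np.all(lf.texture == 0)

    def test_noise_only_suppression_fraction(self):
        """With the hard gate, the surviving fraction at scale j is bounded
        by the percentile complement."""
        cfg = load_config({"lf": {"soft_step_steepness": math.inf}})
        noise = np.random.default_rng(3).random((128, 128))
        pyramid, _, edges = compute_edge_stack(Frame(noise), cfg)
        lf = compute_lf_stack(pyramid, edges, cfg)
        for j in range(pyramid.n_scales):
            if not edges.active[j]:
                continue
            gamma_j = cfg.per_scale("lf.gamma_percentile", j + 1)
            for pol in ("pos", "neg"):
                frac = np.mean(lf.lf_thr[j][pol] > 0)
                assert frac <= (100.0 - gamma_j) / 100.0 + 0.02
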