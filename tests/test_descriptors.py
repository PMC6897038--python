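import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

import oracles
from nodulefuse.descriptors import (
    ExHOGDescriptor,
    HOGDescriptor,
    LBPDescriptor,
    compute_gradients,
    exhog,
    hog,
    lbp,
)

patches_12 = arrays(np.float64, (12, 12),
                    elements=st.floats(0.0, 1.0, allow_nan=False, width=32))


class TestGradients:
    def test_constant_patch_zero_field(self):
        field = compute_gradients(np.full((10, 10), 0.6))
        np.testing.assert_array_equal(field.magnitude, 0.0)
        np.testing.assert_array_equal(field.theta_signed, 0.0)
        np.testing.assert_array_equal(field.theta_unsigned, 0.0)

    def test_horizontal_ramp_closed_form(self):
        width = 16
        patch = np.tile(np.arange(width) / width, (width, 1))
        field = compute_gradients(patch)
        interior = field.ix[1:-1, 1:-1]
        np.testing.assert_allclose(interior, 2.0 / width, atol=1e-15)
        np.testing.assert_allclose(field.iy, 0.0, atol=1e-15)
        np.testing.assert_allclose(field.theta_unsigned[1:-1, 1:-1], 0.0, atol=1e-15)

    def test_matches_per_pixel_loop_oracle(self, rng):
        patch = rng.uniform(0, 1, (8, 8))
        field = compute_gradients(patch)
        ix, iy, mag, theta = oracles.gradients_oracle(patch)
        np.testing.assert_allclose(field.ix, ix, atol=1e-12)
        np.testing.assert_allclose(field.iy, iy, atol=1e-12)
        np.testing.assert_allclose(field.magnitude, mag, atol=1e-12)
        np.testing.assert_allclose(field.theta_signed, theta, atol=1e-12)

    def test_unsigned_is_signed_mod_pi(self, rng):
        field = compute_gradients(rng.uniform(0, 1, (9, 9)))
        np.testing.assert_allclose(
            field.theta_unsigned, np.mod(field.theta_signed, np.pi), atol=1e-12)

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            compute_gradients(np.zeros((2, 5)))


class TestHOG:
    def test_canonical_length_and_nonnegativity(self, rng):
        vec = hog(rng.uniform(0, 1, (28, 28)))
        assert vec.shape == (1296,)
        assert (vec >= 0).all()

    def test_constant_patch_all_zero(self):
        np.testing.assert_array_equal(hog(np.full((28, 28), 0.3)), 0.0)

    def test_wrong_size_rejected(self, rng):
        with pytest.raises(ValueError):
            hog(rng.uniform(0, 1, (27, 27)))

    def test_vertical_step_edge_dominates_horizontal_bin(self):
        """A vertical step edge has unsigned orientation 0 in every crossing cell."""
        patch = np.zeros((28, 28))
        patch[:, 14:] = 1.0
        cells = HOGDescriptor().transform(patch[None]).reshape(6, 6, 2, 2, 9)
        # middle block columns contain the edge; bin 0 holds angle 0
        for by in range(6):
            for cy in range(2):
                cell = cells[by, 3, cy, 0]
                if cell.sum() > 0:
                    assert cell.argmax() == 0

    def test_matches_loop_oracle_on_random_patches(self, rng):
        desc = HOGDescriptor(patch_size=12)
        for _ in range(5):
            patch = rng.uniform(0, 1, (12, 12))
            np.testing.assert_allclose(
                desc.transform(patch[None])[0], oracles.hog_oracle(patch), atol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(patch=patches_12, shift=st.floats(-0.5, 0.5))
    def test_invariant_to_constant_intensity_shift(self, patch, shift):
        desc = HOGDescriptor(patch_size=12)
        np.testing.assert_allclose(desc.transform(patch[None]),
                                   desc.transform(patch[None] + shift), atol=1e-9)

    def test_scale_covariance_of_normalised_blocks(self, rng):
        patch = rng.uniform(0, 1, (28, 28))
        np.testing.assert_allclose(hog(patch), hog(3.7 * patch), atol=1e-9)


class TestExHOG:
    def test_canonical_length_and_nonnegativity(self, rng):
        vec = exhog(rng.uniform(0, 1, (28, 28)))
        assert vec.shape == (648,)
        assert (vec >= 0).all()

    def test_constant_patch_all_zero(self):
        np.testing.assert_array_equal(exhog(np.full((28, 28), 0.8)), 0.0)

    def test_fold_identity_against_signed_histogram_oracle(self, rng):
        """Folded bins are |h(j) - h(j+9)| then h(j) + h(j+9) of the raw histogram."""
        desc = ExHOGDescriptor()
        patch = rng.uniform(0, 1, (28, 28))
        ours = desc.signed_histograms(patch[None])[0]
        ref = oracles.exhog_signed_hist_oracle(patch)
        np.testing.assert_allclose(ours, ref, atol=1e-10)
        folded = desc.transform(patch[None])[0].reshape(6, 6, 18)
        for cy in range(6):
            for cx in range(6):
                h = ref[cy, cx]
                raw = np.concatenate([np.abs(h[:9] - h[9:]), h[:9] + h[9:]])
                norm = np.linalg.norm(raw)
                expect = raw / norm if norm > 1e-12 else raw
                expect = np.minimum(expect, 0.2)
                expect = expect / np.linalg.norm(expect) if norm > 1e-12 else expect
                np.testing.assert_allclose(folded[cy, cx], expect, atol=1e-10)

    def test_matches_loop_oracle_on_random_patches(self, rng):
        desc = ExHOGDescriptor(patch_size=12)
        for _ in range(5):
            patch = rng.uniform(0, 1, (12, 12))
            np.testing.assert_allclose(
                desc.transform(patch[None])[0], oracles.exhog_oracle(patch), atol=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(patch=patches_12, shift=st.floats(-0.5, 0.5))
    def test_invariant_to_constant_intensity_shift(self, patch, shift):
        desc = ExHOGDescriptor(patch_size=12)
        np.testing.assert_allclose(desc.transform(patch[None]),
                                   desc.transform(patch[None] + shift), atol=1e-9)


class TestLBP:
    def test_histogram_length_and_normalisation(self, rng):
        vec = lbp(rng.uniform(0, 1, (28, 28)))
        assert vec.shape == (256,)
        assert vec.sum() == pytest.approx(1.0)

    def test_constant_patch_codes_255(self):
        vec = lbp(np.full((10, 10), 0.5))
        assert vec[255] == 1.0
        assert vec.sum() == 1.0

    def test_known_3x3_code(self):
        # centre 5; clockwise from top-left: 6,7,8,4,3,2,1,5 -> bits 0,1,2,7
        patch = np.array([[6.0, 7.0, 8.0],
                          [5.0, 5.0, 4.0],
                          [1.0, 2.0, 3.0]])
        codes = LBPDescriptor().codes(patch[None])
        assert codes.ravel().tolist() == [135]

    def test_matches_loop_oracle_on_random_patches(self, rng):
        for _ in range(5):
            patch = rng.uniform(0, 1, (12, 12))
            np.testing.assert_allclose(lbp(patch), oracles.lbp_oracle(patch),
                                       atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        # dyadic intensities and factors keep the affine map exact in floats,
        # so the comparison-based invariance must hold bit-for-bit
        patch=arrays(np.float64, (12, 12),
                     elements=st.integers(0, 64).map(lambda v: v / 64.0)),
        scale=st.sampled_from([0.5, 1.0, 2.0, 3.0]),
        shift=st.sampled_from([-8.0, -1.0, 0.0, 0.25, 16.0]),
    )
    def test_exact_invariance_to_positive_affine_maps(self, patch, scale, shift):
        np.testing.assert_array_equal(lbp(patch), lbp(scale * patch + shift))

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            lbp(np.zeros((2, 2)))
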