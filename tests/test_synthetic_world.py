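"""The synthetic world: generative invariants, determinism, serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neurodefend as nd
from neurodefend.synthetic_world import reference_embedding

# Monte-Carlo oracle (200 train samples, world seed 0): mean cosine between
# matched image and caption embeddings. Frozen as a regression constant.
MATCHED_PAIR_MEAN_COS = 0.682612483756376


class TestMakeWorld:
    def test_same_seed_bitwise_identical(self):
        w1, w2 = nd.make_world(0), nd.make_world(0)
        assert np.array_equal(w1.G, w2.G)
        assert np.array_equal(w1.token_table, w2.token_table)

    def test_different_seed_differs(self):
        assert not np.array_equal(nd.make_world(0).G, nd.make_world(1).G)

    def test_G_orthonormal_columns(self, world):
        gtg = world.G.T @ world.G
        assert np.allclose(gtg, np.eye(world.D), atol=1e-6)

    def test_token_rows_unit_norm(self, world):
        assert np.allclose(np.linalg.norm(world.token_table, axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(D=4), dict(D=32, H=2, W=2), dict(D=32, vocab_size=10)],
    )
    def test_dimension_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            nd.make_world(0, **kwargs)


class TestSampleDataset:
    def test_sizes_and_unique_ids(self, world):
        ds = nd.sample_dataset(world, 10, "train", 0)
        ids = [s.id for s in ds.samples]
        assert len(ds) == 10 and len(set(ids)) == 10

    def test_sample_invariants(self, small_train):
        for s in small_train.samples[:10]:
            assert abs(np.linalg.norm(s.z) - 1) < 1e-6
            assert abs(np.linalg.norm(s.brain_feature) - 1) < 1e-6
            assert s.pixels.min() >= 0 and s.pixels.max() <= 1
            assert len(s.caption) == small_train.world.caption_len

    def test_noise_free_pixels_reproduce_linear_map(self, world):
        ds = nd.sample_dataset(world, 3, "train", 0, pixel_noise_std=0.0)
        for s in ds.samples:
            expected = np.clip(
                0.5 + 0.5 * (world.G @ s.z).reshape(world.H, world.W, 3), 0, 1
            )
            assert np.allclose(s.pixels, expected, atol=1e-12)

    def test_caption_is_descending_nearest_tokens(self, world):
        ds = nd.sample_dataset(world, 5, "train", 0)
        for s in ds.samples:
            scores = world.token_table @ s.z
            brute = list(np.argsort(-scores, kind="stable")[: world.caption_len])
            assert s.caption == [int(t) for t in brute]

    def test_regeneration_bit_identical(self, world):
        d1 = nd.sample_dataset(world, 8, "train", 0)
        d2 = nd.sample_dataset(world, 8, "train", 0)
        for a, b in zip(d1.samples, d2.samples):
            assert np.array_equal(a.pixels, b.pixels)
            assert np.array_equal(a.brain_feature, b.brain_feature)
            assert a.caption == b.caption

    def test_prefix_stability_under_larger_n(self, world):
        """Per-sample streams are hashed by index: drawing more samples never
        changes the earlier ones."""
        d1 = nd.sample_dataset(world, 5, "train", 0)
        d2 = nd.sample_dataset(world, 12, "train", 0)
        for a, b in zip(d1.samples, d2.samples[:5]):
            assert np.array_equal(a.pixels, b.pixels)

    def test_invalid_n_rejected(self, world):
        with pytest.raises(ValueError):
            nd.sample_dataset(world, 0, "train", 0)
        with pytest.raises(ValueError):
            nd.sample_dataset(world, 10**7, "train", 0)

    def test_matched_pair_cosine_margin(self, world, encoder):
        """Mean matched image-caption cosine matches the frozen oracle run."""
        ds = nd.sample_dataset(world, 200, "train", 0)
        m = np.mean(
            [
                nd.cosine_sim(encoder.image_encode(s.pixels), encoder.text_encode(s.caption))
                for s in ds.samples
            ]
        )
        assert m > 0.5  # a clear positive margin
        assert m == pytest.approx(MATCHED_PAIR_MEAN_COS, rel=1e-6)


class TestSimulateBrainFeature:
    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6, 0.85, 1.0])
    def test_exact_fidelity(self, rho, rng):
        f = rng.standard_normal(32)
        f /= np.linalg.norm(f)
        fb = nd.simulate_brain_feature(f, rho, 7)
        assert nd.cosine_sim(fb, f) == pytest.approx(rho, abs=1e-6)
        assert abs(np.linalg.norm(fb) - 1) < 1e-6

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        rho=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**16),
        dim_seed=st.integers(0, 2**16),
    )
    def test_fidelity_property_any_vector(self, rho, seed, dim_seed):
        """cos(simulate(f, rho), f) == rho for arbitrary unit f and rho."""
        g = np.random.default_rng(dim_seed).standard_normal(24)
        f = g / np.linalg.norm(g)
        fb = nd.simulate_brain_feature(f, rho, seed)
        assert nd.cosine_sim(fb, f) == pytest.approx(rho, abs=1e-6)

    def test_rho_one_returns_input(self, rng):
        f = rng.standard_normal(16)
        f /= np.linalg.norm(f)
        assert np.array_equal(nd.simulate_brain_feature(f, 1.0, 0), f)

    def test_invalid_inputs_rejected(self):
        f = np.zeros(8)
        with pytest.raises(ValueError):
            nd.simulate_brain_feature(f, 0.5, 0)
        g = np.eye(8)[0]
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                nd.simulate_brain_feature(g, bad, 0)

    def test_brain_feature_invariant_to_pixel_perturbation(self, world, small_train):
        """The stored brain feature is derived from the clean image only:
        perturbing pixels afterwards cannot change it (attack invariance)."""
        s = small_train.samples[0]
        stored = s.brain_feature.copy()
        _ = np.clip(s.pixels + 2 / 255, 0, 1)  # perturbed view, never fed back
        regen = nd.sample_dataset(world, 1, "train", 0).samples[0]
        assert np.array_equal(regen.brain_feature, stored)


class TestSerialization:
    def test_roundtrip(self, world, tmp_path):
        ds = nd.sample_dataset(world, 4, "test", 0)
        nd.save_dataset(ds, tmp_path)
        back = nd.load_dataset(tmp_path)
        assert back.split == "test"
        assert [s.id for s in back.samples] == [s.id for s in ds.samples]
        for a, b in zip(ds.samples, back.samples):
            assert a.caption == b.caption
            assert np.allclose(a.z, b.z)
            assert np.allclose(a.brain_feature, b.brain_feature)
            # PNG is 8-bit: pixels agree to quantization accuracy
            assert np.max(np.abs(a.pixels - b.pixels)) <= 0.5 / 255 + 1e-9

    def test_world_regenerates_from_config(self, world):
        w2 = nd.WorldSpec.from_config(world.to_config())
        assert np.array_equal(world.G, w2.G)
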