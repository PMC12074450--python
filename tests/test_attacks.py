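"""Attack contracts: projections, best-iterate, efficacy, perceptibility."""

import math
import warnings

import numpy as np
import pytest

import neurodefend as nd
from neurodefend.attacks import _apgd_checkpoints

# Seeded oracle run (50 test samples, world seed 0, pgd eps=2/255, 20 iters):
PGD50_CLEAN_MEAN = 0.6727753775541889
PGD50_FINAL_MEAN = -0.018871973910564895


@pytest.fixture(scope="module")
def attack_bed(world, encoder):
    ds = nd.sample_dataset(world, 12, "test", 0)
    return world, encoder, ds.samples


class TestAttackContracts:
    def test_epsilon_zero_returns_clean(self, attack_bed):
        _, enc, samples = attack_bed
        s = samples[0]
        with pytest.warns(UserWarning):
            res = nd.attack(enc, s.pixels, s.caption, nd.AttackConfig(epsilon=0.0))
        assert np.array_equal(res.x_adv, s.pixels)
        clean = nd.cosine_sim(enc.image_encode(s.pixels), enc.text_encode(s.caption))
        assert res.final_cos == pytest.approx(clean)

    @pytest.mark.parametrize("name", ["pgd", "apgd", "cw"])
    @pytest.mark.parametrize("eps", [1 / 255, 2 / 255])
    @pytest.mark.parametrize("random_start", [False, True])
    def test_ball_and_box_containment(self, attack_bed, name, eps, random_start):
        _, enc, samples = attack_bed
        for s in samples[:4]:
            cfg = nd.AttackConfig(name=name, epsilon=eps, n_iter=10,
                                  random_start=random_start, seed=5)
            res = nd.attack(enc, s.pixels, s.caption, cfg)
            assert res.linf <= eps + 1e-6
            assert np.max(np.abs(res.x_adv - s.pixels)) <= eps + 1e-6
            assert res.x_adv.min() >= 0 and res.x_adv.max() <= 1

    @pytest.mark.parametrize("name", ["pgd", "apgd", "cw"])
    def test_best_iterate_is_trace_minimum(self, attack_bed, name):
        _, enc, samples = attack_bed
        for s in samples[:4]:
            res = nd.attack(enc, s.pixels, s.caption, nd.AttackConfig(name=name))
            assert res.final_cos == pytest.approx(min(res.objective_trace), abs=1e-12)
            clean = nd.cosine_sim(enc.image_encode(s.pixels), enc.text_encode(s.caption))
            assert res.final_cos <= clean + 1e-12

    def test_determinism_without_random_start(self, attack_bed):
        _, enc, samples = attack_bed
        s = samples[0]
        cfg = nd.AttackConfig(name="pgd", epsilon=2 / 255)
        r1 = nd.attack(enc, s.pixels, s.caption, cfg)
        r2 = nd.attack(enc, s.pixels, s.caption, cfg)
        assert np.array_equal(r1.x_adv, r2.x_adv)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            nd.AttackConfig(name="fgsm")
        with pytest.raises(ValueError):
            nd.AttackConfig(epsilon=-0.1)
        with pytest.raises(ValueError):
            nd.AttackConfig(n_iter=0)


class TestAttackEfficacy:
    def test_pgd_regression_against_oracle(self, world, encoder):
        """Mean attacked objective over the frozen 50-sample oracle bed."""
        ds = nd.sample_dataset(world, 50, "test", 0)
        cfg = nd.AttackConfig(name="pgd", epsilon=2 / 255)
        res = [nd.attack(encoder, s.pixels, s.caption, cfg) for s in ds.samples]
        clean = np.mean([r.objective_trace[0] for r in res])
        final = np.mean([r.final_cos for r in res])
        assert final < clean  # strictly more adversarial than clean
        assert clean == pytest.approx(PGD50_CLEAN_MEAN, rel=1e-6)
        assert final == pytest.approx(PGD50_FINAL_MEAN, rel=1e-5, abs=1e-8)

    def test_apgd_not_worse_than_pgd_on_most_samples(self, world, encoder):
        ds = nd.sample_dataset(world, 50, "test", 0)
        wins = 0
        for s in ds.samples:
            p = nd.attack(encoder, s.pixels, s.caption,
                          nd.AttackConfig(name="pgd", epsilon=2 / 255))
            a = nd.attack(encoder, s.pixels, s.caption,
                          nd.AttackConfig(name="apgd", epsilon=2 / 255))
            wins += a.final_cos <= p.final_cos + 1e-9
        assert wins / len(ds.samples) >= 0.6

    def test_apgd_checkpoint_schedule(self):
        ck = _apgd_checkpoints(20)
        assert ck[0] == math.ceil(0.22 * 20)
        assert all(c2 > c1 for c1, c2 in zip(ck, ck[1:]))
        assert all(0 < c < 20 for c in ck)


class TestPerceptibility:
    def test_psnr_identical_is_infinite(self, rng):
        x = rng.uniform(0, 1, (16, 16, 3))
        assert math.isinf(nd.psnr(x, x))

    # 20*log10(255/delta_255): 42.1102 dB at delta=2/255, 48.1308 at 1/255
    @pytest.mark.parametrize("delta,expected", [(2 / 255, 42.1102), (1 / 255, 48.1308)])
    def test_psnr_uniform_perturbation_closed_form(self, delta, expected):
        x = np.full((32, 32, 3), 0.4)
        assert nd.psnr(x, x + delta) == pytest.approx(expected, abs=1e-3)

    def test_psnr_shape_mismatch(self):
        with pytest.raises(ValueError):
            nd.psnr(np.zeros((8, 8, 3)), np.zeros((9, 8, 3)))

    def test_ssim_identical_is_one(self, rng):
        x = rng.uniform(0, 1, (16, 16, 3))
        assert nd.ssim(x, x) == pytest.approx(1.0, abs=1e-9)

    def test_ssim_inverted_below_one(self, rng):
        x = rng.uniform(0.2, 0.8, (16, 16, 3))
        assert nd.ssim(x, 1 - x) < 1.0

    def test_ssim_constant_pair_closed_form(self):
        """Two constant images: contrast/structure terms are 1, luminance
        term = (2 m1 m2 + C1) / (m1^2 + m2^2 + C1)."""
        a = np.full((32, 32, 3), 0.2)
        b = np.full((32, 32, 3), 0.7)
        c1 = 0.01**2
        expected = (2 * 0.2 * 0.7 + c1) / (0.2**2 + 0.7**2 + c1)
        assert nd.ssim(a, b) == pytest.approx(expected, abs=1e-6)

    def test_ssim_too_small_rejected(self):
        with pytest.raises(ValueError):
            nd.ssim(np.zeros((5, 5, 3)), np.zeros((5, 5, 3)))


class TestAuditAttack:
    def test_epsilon_zero_audit_passes(self, world, encoder):
        ds = nd.sample_dataset(world, 3, "test", 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = nd.audit_attack(ds, encoder, nd.AttackConfig(epsilon=0.0))
        row = table.iloc[0]
        assert math.isinf(row["mean_psnr_db"])
        assert row["mean_ssim"] == pytest.approx(1.0)
        assert bool(row["imperceptible"])

    def test_one_row_per_attack(self, world, encoder):
        ds = nd.sample_dataset(world, 3, "test", 0)
        cfgs = [nd.AttackConfig(name=n, epsilon=2 / 255, n_iter=5) for n in ("pgd", "cw")]
        table = nd.audit_attack(ds, encoder, cfgs)
        assert list(table["attack"]) == ["pgd", "cw"]

    def test_empty_dataset_rejected(self, world, encoder):
        ds = nd.sample_dataset(world, 1, "test", 0)
        ds.samples = []
        with pytest.raises(ValueError):
            nd.audit_attack(ds, encoder, nd.AttackConfig())
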