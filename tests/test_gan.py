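import numpy as np
import pytest

from biplanar3d import drr, gan, nn, phantom
from biplanar3d.evaluation import build_cases


@pytest.fixture(scope="module")
def desk_cases(desk_spec):
    phantoms = phantom.generate_dataset(4, desk_spec, seed=11)
    return build_cases(phantoms, "enhanced", scale=0.25)


@pytest.mark.parametrize("scale, expected", [
    (0.25, (32, 32, 64)),
    (0.5, (64, 64, 128)),
    (1.0, (128, 128, 256)),
])
def test_generator_output_shape_contract(scale, expected):
    cfg = gan.GeneratorConfig(scale=scale)
    cfg.validate()
    assert cfg.scaled_output_shape == expected
    gen = gan.build_generator(cfg, seed=0)
    rows, cols = cfg.input_image_shape
    ap = np.random.default_rng(0).random((1, 1, rows, cols),
                                         dtype=np.float32)
    out = gen(ap, ap, train=False)
    assert out.shape == (1, 1) + expected
    assert out.data.min() > 0.0 and out.data.max() < 1.0


@pytest.mark.parametrize("bad", [
    dict(scale=0.3),
    dict(encoder_channels=(64, 64, 64)),
    dict(bottleneck_shape=(4, 8, 8, 4)),
    dict(output_shape=(128, 128, 128)),
])
def test_generator_config_validation(bad):
    with pytest.raises(ValueError):
        gan.GeneratorConfig(**bad).validate()


def test_generator_rejects_wrong_image_shape():
    gen = gan.build_generator(gan.GeneratorConfig(scale=0.25), seed=0)
    with pytest.raises(ValueError, match="input images"):
        gen(np.zeros((1, 1, 32, 32)), np.zeros((1, 1, 32, 32)))


def test_discriminator_patch_grid_and_conditioning():
    disc = gan.build_discriminator(gan.DiscriminatorConfig(), seed=0)
    cand = nn.Tensor(np.zeros((2, 1, 32, 32, 64), dtype=np.float32))
    cond = nn.Tensor(np.zeros((2, 2, 32, 32, 64), dtype=np.float32))
    scores = disc(cand, cond, train=True)
    assert scores.shape == (2, 1, 2, 2, 4)      # stride-2 chain of 4
    # unbounded real scores: no final activation
    assert scores.data.dtype == np.float32


def test_discriminator_rejects_small_input():
    disc = gan.build_discriminator(gan.DiscriminatorConfig(), seed=0)
    cand = nn.Tensor(np.zeros((1, 1, 8, 8, 8), dtype=np.float32))
    cond = nn.Tensor(np.zeros((1, 2, 8, 8, 8), dtype=np.float32))
    with pytest.raises(ValueError, match="receptive field"):
        disc(cand, cond)


def test_conditional_volume_has_two_tiled_channels(desk_cases):
    pair, seg = desk_cases[0]
    cond = gan.conditional_volume(pair, (32, 32, 64))
    assert cond.shape == (2, 32, 32, 64)
    # AP channel is constant along y, Lat channel constant along x
    assert np.ptp(cond[0], axis=1).max() == 0
    assert np.ptp(cond[1], axis=0).max() == 0


@pytest.mark.parametrize("d_real, d_fake, expected", [
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 1.0),
    (0.5, 0.5, 0.25),
])
def test_lsgan_discriminator_loss_values(d_real, d_fake, expected):
    real = np.full((2, 3), d_real)
    fake = np.full((2, 3), d_fake)
    assert gan.lsgan_d_loss(real, fake) == pytest.approx(expected)


@pytest.mark.parametrize("d_fake, expected", [
    (1.0, 0.0), (0.0, 0.5), (0.5, 0.125),
])
def test_lsgan_generator_loss_values(d_fake, expected):
    assert gan.lsgan_g_loss(np.full(5, d_fake)) == pytest.approx(expected)


def test_loss_brute_force_equivalence(rng):
    """Vectorized losses equal scalar sums over all patch scores."""
    real = rng.normal(size=(2, 1, 2, 2, 4))
    fake = rng.normal(size=(2, 1, 2, 2, 4))
    d_ref = 0.5 * sum((v - 1) ** 2 for v in real.ravel()) / real.size \
        + 0.5 * sum(v ** 2 for v in fake.ravel()) / fake.size
    g_ref = 0.5 * sum((v - 1) ** 2 for v in fake.ravel()) / fake.size
    assert gan.lsgan_d_loss(real, fake) == pytest.approx(d_ref, abs=1e-6)
    assert gan.lsgan_g_loss(fake) == pytest.approx(g_ref, abs=1e-6)


def test_reconstruction_and_total_loss():
    y = np.array([1.0, 0.0, 1.0, 0.0])
    g = np.array([0.5, 0.5, 0.5, 0.5])
    assert gan.reconstruction_loss(y, g) == pytest.approx(0.25)
    assert gan.reconstruction_loss(y, y) == 0.0
    w = gan.LossWeights()                     # lambda1=2, lambda2=100
    assert gan.total_g_loss(0.5, 0.01, w) == pytest.approx(2.0)
    assert gan.total_g_loss(0.0, 0.0, w) == 0.0
    assert gan.total_g_loss(0.3, 5.0, gan.LossWeights(lambda2=0.0)) == \
        pytest.approx(0.6)
    with pytest.raises(ValueError):
        gan.lsgan_d_loss(np.zeros(3), np.zeros(4))


class _StubGenerator:
    """Constant-probability generator for threshold semantics."""

    def __init__(self, p):
        self.p = p

    def __call__(self, ap, lat, train=False):
        return nn.Tensor(np.full((1, 1, 4, 4, 8), self.p))


def _dummy_pair():
    img = np.zeros((8, 4), dtype=np.float32)
    return drr.DRRPair(img, img, geometry=())


@pytest.mark.parametrize("p, expect_all", [(0.41, 1), (0.40, 1), (0.39, 0)])
def test_predict_threshold_semantics(p, expect_all):
    seg = gan.predict(_StubGenerator(p), _dummy_pair(), threshold=0.4)
    assert set(np.unique(seg.mask)) == {expect_all}


def test_train_is_deterministic(desk_cases):
    gcfg = gan.GeneratorConfig(scale=0.25)
    tcfg = gan.TrainConfig(epochs=1, batch_size=2, seed=5)
    runs = []
    for _ in range(2):
        gen, hist = gan.train(desk_cases[:2], gcfg,
                              gan.DiscriminatorConfig(), gan.LossWeights(),
                              tcfg, val_dataset=desk_cases[2:3])
        runs.append((hist, [p.data.copy() for p in gen.params()]))
    assert runs[0][0].equals(runs[1][0])
    assert all(np.array_equal(a, b)
               for a, b in zip(runs[0][1], runs[1][1]))
    assert np.isfinite(runs[0][0].val_loss.iloc[-1])


def test_train_preconditions(desk_cases):
    gcfg = gan.GeneratorConfig(scale=0.25)
    with pytest.raises(ValueError):
        gan.train([], gcfg, gan.DiscriminatorConfig(), gan.LossWeights(),
                  gan.TrainConfig(epochs=1))
    with pytest.raises(ValueError):
        gan.TrainConfig(epochs=0).validate()


def test_generator_update_decreases_total_loss(desk_cases):
    """One small Adam step on a fixed batch lowers the combined objective."""
    gcfg = gan.GeneratorConfig(scale=0.25)
    gen = gan.build_generator(gcfg, seed=2)
    disc = gan.build_discriminator(gan.DiscriminatorConfig(), seed=3)
    w = gan.LossWeights()
    pair, seg = desk_cases[0]
    ap = pair.ap[None, None]
    lat = pair.lat[None, None]
    gt = seg.mask[None, None].astype(np.float32)
    cond = nn.Tensor(gan.conditional_volume(pair, (32, 32, 64))[None])

    def loss_tensor():
        fake = gen(ap, lat, train=True)
        scores = disc(fake, cond, train=True)
        return gan.total_g_loss(gan.lsgan_g_loss(scores),
                                gan.reconstruction_loss(gt, fake), w)

    before = loss_tensor()
    opt = nn.Adam(gen.params(), lr=1e-4)
    before.backward()
    opt.step()
    after = loss_tensor()
    assert float(after.data) < float(before.data)


def test_trained_generator_uses_conditioning(desk_spec):
    """Outputs differ between phantoms with different vertebra counts."""
    from dataclasses import replace
    few = phantom.generate_phantom(replace(desk_spec, n_vertebrae=3, seed=1))
    many = phantom.generate_phantom(replace(desk_spec, n_vertebrae=9, seed=1))
    cases = build_cases([few, many], "enhanced", scale=0.25)
    gcfg = gan.GeneratorConfig(scale=0.25)
    gen, _ = gan.train(cases, gcfg, gan.DiscriminatorConfig(),
                       gan.LossWeights(), gan.TrainConfig(epochs=3,
                                                          batch_size=2,
                                                          seed=0))
    out = [gen(p.ap[None, None], p.lat[None, None], train=False).data
           for p, _ in cases]
    frac_diff = np.mean(np.abs(out[0] - out[1]) > 1e-6)
    assert frac_diff > 0.01


def test_generator_checkpoint_roundtrip(tmp_path, desk_cases):
    gcfg = gan.GeneratorConfig(scale=0.25)
    gen, _ = gan.train(desk_cases[:2], gcfg, gan.DiscriminatorConfig(),
                       gan.LossWeights(),
                       gan.TrainConfig(epochs=1, batch_size=2, seed=9))
    path = tmp_path / "gen.ckpt.npz"
    gan.save_generator(gen, path)
    loaded = gan.load_generator(path)
    pair, _ = desk_cases[0]
    a = gen(pair.ap[None, None], pair.lat[None, None], train=False).data
    b = loaded(pair.ap[None, None], pair.lat[None, None], train=False).data
    assert np.array_equal(a, b)
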