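"""Conditional 2D-to-3D GAN for spine reconstruction.

The generator encodes the AP and Lat radiographs with two weight-
independent ResNet-style 2D convolutional encoders (eight blocks,
channels 64,64,64,64,32,16,8,4; first kernel 7x7, then 4x4; max pooling,
batch norm and ReLU between blocks; in-block residual additions where
channel counts allow).  At the bottleneck each view's 4-channel feature
map is reinterpreted as a one-channel 3D volume — the 2D channel axis
becomes the spatial axis the projection lost (y for AP, x for Lat) — the
two volumes are axis-permuted to a common (x, y, z) order and averaged.
A central decoder of 3D nearest-neighbour-upsample + convolution blocks
grows this 4x4x8 seed to the output volume; per-view 2D decoders (fed by
skip connections from the last four encoder blocks) supply feature maps
that are tiled along their projection axis and averaged into every
central stage.  A final sigmoid yields a probability volume, binarized
at 0.4 for inference.

The discriminator is a 3D Patch-GAN: the candidate volume is
concatenated with a two-channel conditional volume (the AP and Lat
radiographs tiled along their projection axes), passed through four
stride-2 4x4x4 convolutions (channels 32,64,128,256, LeakyReLU 0.2,
batch norm after the first block) and a final 1-channel convolution,
giving an unbounded patch-score grid scored with least-squares (LSGAN)
objectives plus a lambda2-weighted voxel MSE reconstruction term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .drr import DRRPair
from .phantom import SegmentationVolume

__all__ = [
    "GeneratorConfig", "DiscriminatorConfig", "LossWeights", "TrainConfig",
    "Generator", "Discriminator", "build_generator", "build_discriminator",
    "conditional_volume", "lsgan_d_loss", "lsgan_g_loss",
    "reconstruction_loss", "total_g_loss", "train", "predict",
    "save_generator", "load_generator",
]

_VALID_SCALES = (1.0, 0.5, 0.25)

#: central-decoder stages larger than this run without a 3D convolution
#: (upsample + fusion only); the final 1x1x1 convolution mixes channels
_CONV3D_MAX_VOXELS = 16 * 16 * 32


@dataclass(frozen=True)
class GeneratorConfig:
    encoder_channels: tuple = (64, 64, 64, 64, 32, 16, 8, 4)
    first_kernel: int = 7
    other_kernel: int = 4
    bottleneck_shape: tuple = (4, 4, 8, 4)      # (x, y, z, channels)
    view_decoder_ups: int = 4
    central_decoder_ups: int = 5
    scale: float = 1.0
    output_shape: tuple = (128, 128, 256)
    # per-stage channel schedules; the last n entries are used when the
    # upsampling chain is truncated at reduced scale
    view_decoder_channels: tuple = (32, 16, 8, 4)
    central_decoder_channels: tuple = (32, 16, 8, 4, 4)

    def validate(self) -> None:
        if len(self.encoder_channels) != 8:
            raise ValueError("encoder_channels must have 8 entries")
        if self.scale not in _VALID_SCALES:
            raise ValueError(f"scale must be one of {_VALID_SCALES}")
        bx, by, bz, bc = self.bottleneck_shape
        if self.encoder_channels[-1] != bc:
            raise ValueError("last encoder channel must equal the "
                             "bottleneck channel count")
        if bc != by:
            raise ValueError("bottleneck channels stand in for the missing "
                             "spatial axis and must equal its size")
        ups = self.n_ups
        if ups < 1:
            raise ValueError("scaled output too small for the decoder chain")
        sx, sy, sz = self.scaled_output_shape
        if (sx, sy, sz) != (bx << ups, by << ups, bz << ups):
            raise ValueError(
                f"output shape {self.scaled_output_shape} is not the "
                f"bottleneck {self.bottleneck_shape[:3]} grown by 2^{ups}")

    @property
    def scaled_output_shape(self) -> tuple:
        out = tuple(int(round(s * self.scale)) for s in self.output_shape)
        if any(abs(s * self.scale - o) > 1e-9
               for s, o in zip(self.output_shape, out)):
            raise ValueError("output_shape * scale must be integral")
        return out

    @property
    def n_ups(self) -> int:
        return self.central_decoder_ups + int(round(np.log2(self.scale)))

    @property
    def input_image_shape(self) -> tuple:
        sx, sy, sz = self.scaled_output_shape
        return (sz, sx)          # (rows, cols); Lat shares it since sx == sy


@dataclass(frozen=True)
class DiscriminatorConfig:
    channels: tuple = (32, 64, 128, 256)
    kernel: int = 4
    leaky_slope: float = 0.2
    final_channels: int = 1

    def validate(self) -> None:
        if list(self.channels) != sorted(set(self.channels)):
            raise ValueError("channels must be strictly increasing")
        if self.kernel < 2:
            raise ValueError("kernel must be >= 2")


@dataclass(frozen=True)
class LossWeights:
    lambda1: float = 2.0
    lambda2: float = 100.0

    def validate(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 4
    learning_rate: float = 2e-4
    optimizer_betas: tuple = (0.5, 0.999)
    seed: int = 0
    binarize_threshold: float = 0.4

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 < self.binarize_threshold < 1.0):
            raise ValueError("binarize_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# generator

class _EncoderBlock:
    def __init__(self, c_in, c_out, kernel, pool, rng):
        self.conv = nn.Conv(c_in, c_out, (kernel, kernel), stride=1, rng=rng)
        self.bn = nn.BatchNorm(c_out)
        self.pool = nn.MaxPool2x() if pool else None
        self.residual = c_in == c_out

    def __call__(self, x, train):
        h = nn.relu(self.bn(self.conv(x), train))
        if self.residual:
            h = nn.add(h, x)
        if self.pool is not None:
            h = self.pool(h)
        return h

    def params(self):
        return self.conv.params() + self.bn.params()


class _UpBlock:
    """Nearest-neighbour x2 upsample + conv (+BN+ReLU); 2D or 3D by kernel."""

    def __init__(self, c_in, c_out, nd, rng, bias_init=0.0):
        self.up = nn.UpsampleNearest()
        self.conv = nn.Conv(c_in, c_out, (3,) * nd, stride=1, rng=rng,
                            bias_init=bias_init)
        self.bn = nn.BatchNorm(c_out)

    def __call__(self, x, train, skip=None):
        h = self.up(x)
        if skip is not None:
            h = nn.concat([h, skip], axis=1)
        return nn.relu(self.bn(self.conv(h), train))

    def params(self):
        return self.conv.params() + self.bn.params()


class Generator:
    """Dual-view 2D encoder + fused 3D decoder; see the module docstring."""

    def __init__(self, config: GeneratorConfig, rng=None):
        config.validate()
        self.config = config
        rng = rng or np.random.default_rng(0)
        ch = config.encoder_channels
        ups = config.n_ups
        n_view = min(config.view_decoder_ups, ups)
        vch = config.view_decoder_channels[-n_view:] if n_view else ()
        cch = config.central_decoder_channels[-ups:]

        def encoder():
            blocks = []
            c_prev = 1
            for i, c in enumerate(ch):
                k = config.first_kernel if i == 0 else config.other_kernel
                blocks.append(_EncoderBlock(c_prev, c, k, pool=i < ups,
                                            rng=rng))
                c_prev = c
            return blocks

        self.enc_ap = encoder()
        self.enc_lat = encoder()

        skip_ch = sum(ch[4:])           # last four encoder blocks
        def view_decoder():
            blocks, c_prev = [], skip_ch
            for c in vch:
                blocks.append(_UpBlock(c_prev, c, nd=2, rng=rng))
                c_prev = c
            return blocks

        self.dec_ap = view_decoder()
        self.dec_lat = view_decoder()

        self.central_in = nn.Conv(1, cch[0], (3, 3, 3), stride=1, rng=rng)
        self.central_in_bn = nn.BatchNorm(cch[0])
        # 3D convolutions are placed at the coarse stages only; past
        # _CONV3D_MAX_VOXELS the stage is pure upsample + fused-feature
        # concatenation, and a final 1x1x1 convolution mixes the
        # accumulated multi-resolution channels (the fine-scale detail is
        # carried by the 2D view decoders, which stay at full resolution).
        bx, by, bz, _ = config.bottleneck_shape
        self.central = []
        c_prev = cch[0]
        for j, c in enumerate(cch):
            voxels = (bx << (j + 1)) * (by << (j + 1)) * (bz << (j + 1))
            c_in = c_prev + (vch[j] if j < n_view else 0)
            if voxels <= _CONV3D_MAX_VOXELS:
                self.central.append(_UpBlock(c_in, c, nd=3, rng=rng))
                c_prev = c
            else:
                self.central.append(None)
                c_prev = c_in
        # output bias starts at the foreground-prior logit so the initial
        # probability map is near-empty rather than near-0.5
        self.out_conv = nn.Conv(c_prev, 1, (1, 1, 1), stride=1, rng=rng,
                                bias_init=float(np.log(0.05 / 0.95)))
        self.n_view = n_view

    def params(self):
        ps = []
        for blocks in (self.enc_ap, self.enc_lat, self.dec_ap, self.dec_lat,
                       self.central):
            for b in blocks:
                if b is not None:
                    ps += b.params()
        ps += self.central_in.params() + self.central_in_bn.params()
        ps += self.out_conv.params()
        return ps

    def batchnorms(self):
        bns = []
        for blocks in (self.enc_ap, self.enc_lat, self.dec_ap, self.dec_lat,
                       self.central):
            for b in blocks:
                if b is not None:
                    bns.append(b.bn)
        bns.append(self.central_in_bn)
        return bns

    def _encode(self, img, blocks, train):
        h = img
        skips = []
        for i, b in enumerate(blocks):
            h = b(h, train)
            if i >= 4:
                skips.append(h)
        return h, nn.concat(skips, axis=1)

    @staticmethod
    def _ap_to_volume(f):
        # (N, C, h=z, w=x) -> (N, 1, x, y=C, z)
        v = nn.permute(f, (0, 3, 1, 2))        # (N, w, C, h)
        n, x, y, z = v.shape
        return nn.reshape(v, (n, 1, x, y, z))

    @staticmethod
    def _lat_to_volume(f):
        # (N, C, h=z, w=y) -> (N, 1, x=C, y, z)
        v = nn.permute(f, (0, 1, 3, 2))        # (N, C, w, h)
        n, x, y, z = v.shape
        return nn.reshape(v, (n, 1, x, y, z))

    @staticmethod
    def _tile_ap(f, y_size):
        # (N, c, h=z, w=x) -> (N, c, x, y, z)
        return nn.tile_along(nn.permute(f, (0, 1, 3, 2)), 3, y_size)

    @staticmethod
    def _tile_lat(f, x_size):
        # (N, c, h=z, w=y) -> (N, c, x, y, z)
        return nn.tile_along(nn.permute(f, (0, 1, 3, 2)), 2, x_size)

    def __call__(self, ap: np.ndarray, lat: np.ndarray,
                 train: bool = True) -> nn.Tensor:
        """Map image batches (N, 1, rows, cols) to a probability volume
        (N, 1, x, y, z) with values strictly in (0, 1)."""
        expect = self.config.input_image_shape
        if ap.shape[2:] != expect or lat.shape[2:] != expect:
            raise ValueError(
                f"input images must be {expect}, got {ap.shape[2:]} / "
                f"{lat.shape[2:]}")
        # unflip rows so the internal row axis ascends with volume z
        tap = nn.Tensor(np.ascontiguousarray(
            np.asarray(ap, dtype=np.float32)[:, :, ::-1]))
        tlat = nn.Tensor(np.ascontiguousarray(
            np.asarray(lat, dtype=np.float32)[:, :, ::-1]))

        bap, skip_ap = self._encode(tap, self.enc_ap, train)
        blat, skip_lat = self._encode(tlat, self.enc_lat, train)

        seed = nn.average([self._ap_to_volume(bap),
                           self._lat_to_volume(blat)])
        h = nn.relu(self.central_in_bn(self.central_in(seed), train))

        f_ap, f_lat = skip_ap, skip_lat
        up = nn.UpsampleNearest()
        for j, block in enumerate(self.central):
            fused = None
            if j < self.n_view:
                f_ap = self.dec_ap[j](f_ap, train)
                f_lat = self.dec_lat[j](f_lat, train)
                y_size = h.shape[3] * 2
                x_size = h.shape[2] * 2
                fused = nn.average([self._tile_ap(f_ap, y_size),
                                    self._tile_lat(f_lat, x_size)])
            if block is not None:
                h = block(h, train, skip=fused)
            else:
                h = up(h)
                if fused is not None:
                    h = nn.concat([h, fused], axis=1)
        return nn.sigmoid(self.out_conv(h))


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    return Generator(config, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# discriminator

class Discriminator:
    """3D Patch-GAN over (candidate volume, conditional volume)."""

    def __init__(self, config: DiscriminatorConfig, rng=None):
        config.validate()
        self.config = config
        rng = rng or np.random.default_rng(0)
        k = config.kernel
        self.blocks = []
        c_prev = 3                     # candidate + tiled AP + tiled Lat
        for i, c in enumerate(config.channels):
            conv = nn.Conv(c_prev, c, (k, k, k), stride=2, rng=rng)
            bn = nn.BatchNorm(c) if i > 0 else None
            self.blocks.append((conv, bn))
            c_prev = c
        self.final = nn.Conv(c_prev, config.final_channels, (k, k, k),
                             stride=1, rng=rng)
        self.min_size = 2 ** len(config.channels)

    def params(self):
        ps = []
        for conv, bn in self.blocks:
            ps += conv.params()
            if bn is not None:
                ps += bn.params()
        return ps + self.final.params()

    def __call__(self, candidate: nn.Tensor, cond: nn.Tensor,
                 train: bool = True) -> nn.Tensor:
        if candidate.shape != cond.shape[:1] + (1,) + cond.shape[2:]:
            raise ValueError("candidate and conditional volumes must share "
                             "the spatial grid")
        if any(s < self.min_size for s in candidate.shape[2:]):
            raise ValueError("input smaller than the discriminator's "
                             "receptive field")
        h = nn.concat([candidate, cond], axis=1)
        for conv, bn in self.blocks:
            h = conv(h)
            if bn is not None:
                h = bn(h, train)
            h = nn.leaky_relu(h, self.config.leaky_slope)
        return self.final(h)


def build_discriminator(config: DiscriminatorConfig,
                        seed: int = 0) -> Discriminator:
    return Discriminator(config, rng=np.random.default_rng(seed))


def conditional_volume(pair: DRRPair, out_shape: tuple) -> np.ndarray:
    """Tile the AP and Lat radiographs along their projection axes into a
    (2, x, y, z) conditional volume matching the generator output grid."""
    x, y, z = out_shape
    # image row 0 is superior; volume z runs inferior->superior, so rows
    # are unflipped before tiling
    ap = np.asarray(pair.ap, dtype=np.float32)[::-1]    # (rows=z, cols=x)
    lat = np.asarray(pair.lat, dtype=np.float32)[::-1]  # (rows=z, cols=y)
    if ap.shape != (z, x) or lat.shape != (z, y):
        raise ValueError("radiograph shape inconsistent with volume grid")
    ap_v = np.broadcast_to(ap.T[:, None, :], (x, y, z))     # y tiled
    lat_v = np.broadcast_to(lat.T[None, :, :], (x, y, z))   # x tiled
    return np.stack([ap_v, lat_v])


# ---------------------------------------------------------------------------
# losses

def _pair_shapes(a, b):
    if np.shape(a) != np.shape(b):
        raise ValueError("score grids must share a shape")


def lsgan_d_loss(d_real, d_fake):
    """LSGAN discriminator objective: 0.5 E[(D(x)-1)^2] + 0.5 E[D(G(z))^2]."""
    if isinstance(d_real, nn.Tensor):
        return nn.scale(nn.add(nn.mean_sq(d_real, 1.0), nn.mean_sq(d_fake)),
                        0.5)
    _pair_shapes(d_real, d_fake)
    return 0.5 * float(np.mean((np.asarray(d_real) - 1.0) ** 2)) + \
        0.5 * float(np.mean(np.asarray(d_fake) ** 2))


def lsgan_g_loss(d_fake):
    """LSGAN generator objective: 0.5 E[(D(G(z))-1)^2]."""
    if isinstance(d_fake, nn.Tensor):
        return nn.scale(nn.mean_sq(d_fake, 1.0), 0.5)
    return 0.5 * float(np.mean((np.asarray(d_fake) - 1.0) ** 2))


def reconstruction_loss(y, g):
    """Voxelwise mean squared error between ground truth and generation."""
    if isinstance(g, nn.Tensor):
        return nn.mean_sq_diff(g, np.asarray(y, dtype=g.data.dtype))
    _pair_shapes(y, g)
    return float(np.mean((np.asarray(y, dtype=np.float64)
                          - np.asarray(g, dtype=np.float64)) ** 2))


def total_g_loss(lsgan_g, l_re, w: LossWeights):
    """Combined generator objective: lambda1 * LSGAN + lambda2 * MSE."""
    w.validate()
    if isinstance(lsgan_g, nn.Tensor) or isinstance(l_re, nn.Tensor):
        return nn.add(nn.scale(lsgan_g, w.lambda1), nn.scale(l_re, w.lambda2))
    return w.lambda1 * float(lsgan_g) + w.lambda2 * float(l_re)


# ---------------------------------------------------------------------------
# training

def _batch_arrays(items, out_shape):
    aps, lats, gts, conds = [], [], [], []
    for pair, seg in items:
        aps.append(pair.ap[None])
        lats.append(pair.lat[None])
        gts.append(seg.mask[None].astype(np.float32))
        conds.append(conditional_volume(pair, out_shape))
    return (np.stack(aps), np.stack(lats), np.stack(gts),
            np.stack(conds).astype(np.float32))


def train(dataset, gcfg: GeneratorConfig, dcfg: DiscriminatorConfig,
          w: LossWeights, tcfg: TrainConfig, val_dataset=None,
          generator: Generator | None = None):
    """Alternating LSGAN training of the generator/discriminator pair.

    ``dataset`` is a list of (DRRPair, SegmentationVolume).  Fully
    reproducible for a given ``tcfg.seed``.  Returns (generator, history)
    where history is a DataFrame with per-epoch generator, discriminator
    and validation losses.
    """
    tcfg.validate()
    w.validate()
    if not dataset:
        raise ValueError("dataset must be nonempty")
    out_shape = gcfg.scaled_output_shape
    for pair, seg in dataset:
        if tuple(seg.mask.shape) != out_shape:
            raise ValueError("ground-truth grid does not match the "
                             "generator output shape")
    rng = np.random.default_rng(tcfg.seed)
    gen = generator or Generator(gcfg, rng=rng)
    disc = Discriminator(dcfg, rng=rng)
    opt_g = nn.Adam(gen.params(), lr=tcfg.learning_rate,
                    betas=tcfg.optimizer_betas)
    opt_d = nn.Adam(disc.params(), lr=tcfg.learning_rate,
                    betas=tcfg.optimizer_betas)

    history = []
    n = len(dataset)
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        g_losses, d_losses = [], []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            ap, lat, gt, cond = _batch_arrays([dataset[i] for i in idx],
                                              out_shape)
            cond_t = nn.Tensor(cond)

            fake = gen(ap, lat, train=True)

            # discriminator step on real and detached fake
            opt_d.zero_grad()
            d_real = disc(nn.Tensor(gt), cond_t, train=True)
            d_fake = disc(nn.Tensor(fake.data.copy()), cond_t, train=True)
            d_loss = lsgan_d_loss(d_real, d_fake)
            d_loss.backward()
            opt_d.step()

            # generator step through the updated discriminator
            opt_g.zero_grad()
            opt_d.zero_grad()
            d_fake_g = disc(fake, cond_t, train=True)
            g_loss = total_g_loss(lsgan_g_loss(d_fake_g),
                                  reconstruction_loss(gt, fake), w)
            g_loss.backward()
            opt_g.step()
            opt_d.zero_grad()

            gl, dl = float(g_loss.data), float(d_loss.data)
            if not (np.isfinite(gl) and np.isfinite(dl)):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch start {start}: "
                    f"g={gl}, d={dl}")
            g_losses.append(gl)
            d_losses.append(dl)

        val_loss = np.nan
        if val_dataset:
            vls = []
            for pair, seg in val_dataset:
                prob = gen(pair.ap[None, None], pair.lat[None, None],
                           train=False)
                vls.append(reconstruction_loss(
                    seg.mask[None, None].astype(np.float32), prob.data))
            val_loss = float(np.mean(vls))
        history.append({"epoch": epoch, "g_loss": float(np.mean(g_losses)),
                        "d_loss": float(np.mean(d_losses)),
                        "val_loss": val_loss})
    return gen, pd.DataFrame(history)


def save_generator(gen: Generator, path) -> None:
    """Single-file checkpoint: config JSON + parameters + BN statistics."""
    import json

    cfg = gen.config
    meta = {k: getattr(cfg, k) for k in (
        "encoder_channels", "first_kernel", "other_kernel",
        "bottleneck_shape", "view_decoder_ups", "central_decoder_ups",
        "scale", "output_shape", "view_decoder_channels",
        "central_decoder_channels")}
    arrays = {f"p{i}": p.data for i, p in enumerate(gen.params())}
    for i, bn in enumerate(gen.batchnorms()):
        arrays[f"rm{i}"] = bn.running_mean
        arrays[f"rv{i}"] = bn.running_var
    np.savez_compressed(str(path), meta=json.dumps(meta, default=list),
                        **arrays)


def load_generator(path) -> Generator:
    import json

    with np.load(str(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        for k in ("encoder_channels", "bottleneck_shape", "output_shape",
                  "view_decoder_channels", "central_decoder_channels"):
            meta[k] = tuple(meta[k])
        gen = Generator(GeneratorConfig(**meta))
        for i, p in enumerate(gen.params()):
            p.data = data[f"p{i}"]
        for i, bn in enumerate(gen.batchnorms()):
            bn.running_mean = data[f"rm{i}"]
            bn.running_var = data[f"rv{i}"]
    return gen


def predict(generator: Generator, pair: DRRPair, threshold: float = 0.4,
            spacing_mm: tuple = (1.0, 1.0, 1.0)) -> SegmentationVolume:
    """Binarize the generator's probability map: voxel = 1 iff p >= t."""
    prob = generator(pair.ap[None, None], pair.lat[None, None], train=False)
    binary = (prob.data[0, 0] >= threshold).astype(np.uint8)
    return SegmentationVolume(binary, spacing_mm)
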