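"""Encoder-decoder generator and random-patch critic for lead reconstruction.

The generator maps 1 or 2 input leads to the remaining 7 or 6 independent
leads of an 8-lead record (time length preserved).  It is a 1-D U-Net: six
stride-2 convolution blocks with leaky rectifier activations on the way down,
six upsample+convolution blocks with plain rectifiers on the way up, skip
connections joining down-block ``i`` to up-block ``6-i``, dropout on the three
deepest up blocks, reflection padding throughout, and a final hyperbolic
tangent whose output is scaled by ``amplitude_scale`` microvolts.

The discriminator is a critic over randomly positioned 8-channel x
``patch_samples`` windows: seven stride-2 convolutions with leaky rectifiers
and a linear head, optionally sigmoid-squashed (the unsquashed head is the
one used with the Wasserstein gradient-penalty objective).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .nn import Adam, Conv1d, Dense, Dropout, LeakyReLU, Param, ReLU, Tanh, Upsample2


class ModelConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    input_leads: int = 1
    output_leads: int = 7
    down_channels: tuple = (32, 64, 128, 256, 512, 512)
    up_channels: tuple = (512, 256, 128, 64, 32, 32)
    kernel_size: int = 15
    stride: int = 2
    lrelu_slope: float = 0.2
    #: indices (0-based, 0 = deepest) of up blocks that get dropout
    dropout_layers: tuple = (0, 1, 2)
    dropout_p: float = 0.5
    amplitude_scale: float = 6000.0   # uV mapped to tanh's (-1, 1)
    skip_connections: bool = True
    #: weight scale multiplier for the final convolution (small start keeps
    #: early reconstructions near the baseline instead of amplified noise)
    final_init_scale: float = 1e-3

    def __post_init__(self):
        if self.input_leads + self.output_leads != 8:
            raise ModelConfigError(
                f"input_leads + output_leads must be 8, got "
                f"{self.input_leads} + {self.output_leads}")
        if len(self.down_channels) != 6 or len(self.up_channels) != 6:
            raise ModelConfigError("exactly 6 down and 6 up layers required")
        if len(set(self.dropout_layers)) != 3:
            raise ModelConfigError("dropout applies to exactly 3 layers")
        if self.amplitude_scale <= 0:
            raise ModelConfigError("amplitude_scale must be > 0")


def desk_generator_config(input_leads: int = 1) -> GeneratorConfig:
    """Small-capacity preset for CPU-scale experiments.

    Deliberately narrow: within the desk training budget a small generator
    settles into its information-limited optimum — reproducing the
    population-typical waveform timed by the input lead — rather than the
    amplitude-copying transient that wider desk generators pass through
    before converging.
    """
    return GeneratorConfig(
        input_leads=input_leads, output_leads=8 - input_leads,
        down_channels=(4, 6, 8, 8, 8, 8),
        up_channels=(8, 8, 8, 6, 4, 4),
        kernel_size=9)


@dataclass(frozen=True)
class DiscriminatorConfig:
    channels: tuple = (32, 64, 128, 256, 512, 512, 512)
    kernel_size: int = 15
    stride: int = 2
    lrelu_slope: float = 0.2
    sigmoid_head: bool = False        # False = unbounded critic (WGAN-GP)
    patch_channels: int = 8
    patch_samples: int = 800

    def __post_init__(self):
        if len(self.channels) != 7:
            raise ModelConfigError("discriminator has exactly 7 conv layers")
        if self.patch_channels > 8:
            raise ModelConfigError("patch_channels must be <= 8")


def desk_discriminator_config() -> DiscriminatorConfig:
    return DiscriminatorConfig(channels=(16, 24, 32, 32, 48, 48, 48),
                               kernel_size=9)


class Generator:
    """1-D U-Net reconstruction function.  See module docstring."""

    MIN_SAMPLES = 2 ** 6

    def __init__(self, config: GeneratorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.down_convs: List[Conv1d] = []
        self.down_acts: List[LeakyReLU] = []
        prev = c.input_leads
        for ch in c.down_channels:
            self.down_convs.append(Conv1d(prev, ch, c.kernel_size, c.stride, rng))
            self.down_acts.append(LeakyReLU(c.lrelu_slope))
            prev = ch
        # skip channel counts seen by up block j (deepest first): down outputs
        # 5,4,3,2,1 then the raw input
        skip_ch = list(c.down_channels[-2::-1]) + [c.input_leads]
        self.up = []
        for j, ch in enumerate(c.up_channels):
            cin = prev + (skip_ch[j] if c.skip_connections else 0)
            conv = Conv1d(cin, ch, c.kernel_size, 1, rng)
            drop = Dropout(c.dropout_p if j in c.dropout_layers else 0.0)
            self.up.append((Upsample2(), conv, ReLU(), drop))
            prev = ch
        self.final_conv = Conv1d(prev, c.output_leads, c.kernel_size, 1, rng,
                                 weight_scale=c.final_init_scale *
                                 np.sqrt(2.0 / (prev * c.kernel_size)))
        self.final_act = Tanh()
        self._cache = None

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> List[Param]:
        out = []
        for conv in self.down_convs:
            out += conv.params
        for _, conv, _, _ in self.up:
            out += conv.params
        out += self.final_conv.params
        return out

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params)

    def state(self):
        return nn.get_state(self.params)

    def load_state(self, state):
        nn.set_state(self.params, state)

    # -- computation --------------------------------------------------------
    def forward_norm(self, x: np.ndarray, train: bool = False,
                     rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Map normalized input [B, input_leads, N] to normalized output in (-1, 1)."""
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim != 3 or x.shape[1] != self.config.input_leads:
            raise ModelConfigError(
                f"expected input shape [batch, {self.config.input_leads}, N], got {x.shape}")
        if x.shape[2] < self.MIN_SAMPLES:
            raise ModelConfigError(
                f"signal length {x.shape[2]} incompatible with the 6-level stride-2 "
                f"ladder; at least {self.MIN_SAMPLES} samples required")
        skips = [x]
        h = x
        for conv, act in zip(self.down_convs, self.down_acts):
            h = act.forward(conv.forward(h))
            skips.append(h)
        crops = []
        for j, (ups, conv, act, drop) in enumerate(self.up):
            u = ups.forward(h)
            skip = skips[5 - j]
            crops.append(u.shape[2] - skip.shape[2])
            u = u[:, :, :skip.shape[2]]
            if self.config.skip_connections:
                u = np.concatenate([u, skip], axis=1)
            h = drop.forward(act.forward(conv.forward(u)), train=train, rng=rng)
        y = self.final_act.forward(self.final_conv.forward(h))
        self._cache = crops
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        """Backprop through the last forward; accumulates parameter grads."""
        crops = self._cache
        g = self.final_conv.backward(self.final_act.backward(gy))
        skip_grads = [None] * 7
        for j in reversed(range(6)):
            ups, conv, act, drop = self.up[j]
            g = conv.backward(act.backward(drop.backward(g)))
            if self.config.skip_connections:
                n_up = g.shape[1] - (self.down_convs[4 - j].c_out if j < 5
                                     else self.config.input_leads)
                gu, gskip = g[:, :n_up], g[:, n_up:]
            else:
                gu, gskip = g, None
            if gskip is not None:
                idx = 5 - j
                skip_grads[idx] = gskip if skip_grads[idx] is None else skip_grads[idx] + gskip
            if crops[j]:
                gu = np.pad(gu, ((0, 0), (0, 0), (0, crops[j])))
            g = ups.backward(gu)
        # g is now the gradient w.r.t. the deepest down output (skips[6])
        for i in reversed(range(6)):
            g = self.down_convs[i].backward(self.down_acts[i].backward(g))
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
        return g

    # -- user-facing reconstruction -----------------------------------------
    def reconstruct(self, inputs_uv: np.ndarray) -> np.ndarray:
        """Reconstruct missing leads from input leads, both in microvolts.

        ``inputs_uv`` may be [input_leads, N] or [batch, input_leads, N].
        """
        x = np.asarray(inputs_uv, dtype=float)
        single = x.ndim == 2
        if single:
            x = x[None]
        scale = self.config.amplitude_scale
        y = self.forward_norm(x / scale, train=False) * scale
        return np.asarray(y[0] if single else y, dtype=float)

    __call__ = reconstruct


class Critic:
    """Patch discriminator / Wasserstein critic with gradient-penalty support.

    The network is piecewise linear up to the optional sigmoid, which makes an
    exact double-backprop for the gradient penalty cheap: for a fixed
    activation pattern the score is affine in the input, so the parameter
    gradient of ``g . v`` (``g`` the input gradient, ``v`` an arbitrary
    direction) is obtained by propagating ``v`` forward through the
    frozen-mask network and correlating with the cached backprop signals.
    """

    def __init__(self, config: DiscriminatorConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.convs: List[Conv1d] = []
        self.acts: List[LeakyReLU] = []
        prev = config.patch_channels
        length = config.patch_samples
        for ch in config.channels:
            self.convs.append(Conv1d(prev, ch, config.kernel_size, config.stride, rng))
            self.acts.append(LeakyReLU(config.lrelu_slope))
            prev = ch
            length = -(-length // config.stride)
        self.head = Dense(prev * length, 1, rng)
        self._head_shape = (prev, length)
        self._deltas = None

    @property
    def params(self) -> List[Param]:
        out = []
        for conv in self.convs:
            out += conv.params
        return out + self.head.params

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params)

    def state(self):
        return nn.get_state(self.params)

    def load_state(self, state):
        nn.set_state(self.params, state)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        """Scores, shape (batch,)."""
        x = np.asarray(x, dtype=nn.DTYPE)
        if x.ndim != 3 or x.shape[1] != self.config.patch_channels:
            raise ModelConfigError(
                f"critic expects [batch, {self.config.patch_channels}, "
                f"{self.config.patch_samples}], got {x.shape}")
        h = x
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h, cache=cache), cache=cache)
        s = self.head.forward(h.reshape(h.shape[0], -1), cache=cache)[:, 0]
        if self.config.sigmoid_head:
            s = 1.0 / (1.0 + np.exp(-s))
            self._sig = s
        return s

    score = forward
    __call__ = forward

    def backward(self, gs: np.ndarray, accumulate: bool = True,
                 store_deltas: bool = False) -> np.ndarray:
        """Backprop scores gradient ``gs`` (batch,) to the input."""
        gs = np.asarray(gs, dtype=nn.DTYPE)
        if self.config.sigmoid_head:
            gs = gs * self._sig * (1.0 - self._sig)
        g = self.head.backward(gs[:, None], accumulate=accumulate)
        g = g.reshape(g.shape[0], *self._head_shape)
        deltas = []
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            g = act.backward(g)          # grad w.r.t. conv output
            if store_deltas:
                deltas.append(g)
            g = conv.backward(g, accumulate=accumulate)
        if store_deltas:
            self._deltas = deltas[::-1]  # per conv layer, bottom-up
        return g

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Per-item gradient of the score w.r.t. the input (no param grads)."""
        self.forward(x, cache=True)
        return self.backward(np.ones(x.shape[0]), accumulate=False,
                             store_deltas=False)

    def gp_accumulate(self, v: np.ndarray):
        """Add the gradient-penalty parameter gradient for direction ``v``.

        Requires a preceding ``forward`` + ``backward(..., store_deltas=True)``
        on the interpolated batch; ``v`` carries the per-item penalty
        coefficients.  Valid for the unsquashed critic head.
        """
        if self.config.sigmoid_head:
            raise ModelConfigError("gradient penalty expects the unsquashed critic head")
        vt = np.asarray(v, dtype=nn.DTYPE)
        for conv, act, delta in zip(self.convs, self.acts, self._deltas):
            z, win = conv.forward_nobias(vt)
            conv.accumulate_weight_grad(delta, win)
            vt = z * act.mask
        self.head.accumulate_weight_grad(
            np.ones((vt.shape[0], 1), dtype=nn.DTYPE), vt.reshape(vt.shape[0], -1))


def build_generator(config: GeneratorConfig, seed: int = 0) -> Generator:
    """Construct the reconstruction function for a configuration."""
    return Generator(config, seed=seed)


def build_discriminator(config: DiscriminatorConfig, seed: int = 0) -> Critic:
    return Critic(config, seed=seed)


def random_patch(real: np.ndarray, fake: np.ndarray, patch_samples: int,
                 rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray, int]:
    """One shared random time window for a training batch.

    A single offset is drawn per call, uniform over the valid range, and the
    identical full-channel slice is taken from both batches so the critic sees
    aligned real/fake patches.
    """
    if real.shape != fake.shape:
        raise ModelConfigError(f"real {real.shape} and fake {fake.shape} differ")
    n = real.shape[2]
    if patch_samples > n:
        raise ModelConfigError(f"patch of {patch_samples} samples exceeds signal length {n}")
    offset = int(rng.integers(0, n - patch_samples + 1))
    sl = slice(offset, offset + patch_samples)
    return real[:, :, sl], fake[:, :, sl], offset
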