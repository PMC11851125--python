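"""The basecaller encoder: convolution front-end, time-step masking,
Squeezeformer temporal U-Net, and the log-softmax output head.

The raw current chunk is first passed through three stride-1 1-D
convolution layers (kernels 5/5/19, paddings 1/1/10, output channels
4/16/model_width), each followed by LayerNorm and GELU.  During training a
fraction of the resulting time steps is masked wav2vec2.0-style: start
indices are sampled without replacement and each start hides
``mask_time_length`` consecutive frames behind a single learned feature
vector shared by all masked positions.

The temporal U-Net holds 2N Squeezeformer blocks: blocks 1..N-1 run at the
full frame rate, a stride-2 depthwise-conv pooling layer halves the rate,
blocks N..2N-1 run at half rate, and the last block runs after
nearest-neighbour upsampling plus a pointwise projection and a residual
connection from the pre-pooling states, restoring the original length.
Each block is an FMCF stack — feed-forward, multi-head self-attention,
convolution module, feed-forward — every sublayer residual with
post-layer-norm and macaron 0.5 scaling on both feed-forwards.

A fully connected layer plus log-softmax converts the final hidden states
to per-frame log-probabilities over (A, C, G, T, blank); the blank symbol
occupies the last class index throughout the project.
"""

from __future__ import annotations
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

__all__ = [
    "N_CLASSES", "BLANK",
    "EncoderConfig", "EncoderOutput", "SqueezeCallModel",
    "conv_output_length", "frame_sample_centers", "min_chunk_len",
    "sample_time_mask", "count_parameters",
    "save_checkpoint", "load_checkpoint",
]

N_CLASSES = 5   # A, C, G, T, blank
BLANK = 4       # blank is always the last class

DEFAULT_CONV_SPECS = ((5, 1, 1, 4), (5, 1, 1, 16), (19, 10, 1, 512))


@dataclass
class EncoderConfig:
    """All architecture hyperparameters of the encoder.

    ``conv_specs`` is a sequence of (kernel, padding, stride, out_channels)
    for the front-end; the final layer's out_channels must equal
    ``model_width``.  ``n_half`` is N: the U-Net holds 2N blocks.
    """

    conv_specs: tuple = DEFAULT_CONV_SPECS
    model_width: int = 512
    n_half: int = 4
    heads: int = 8
    ff_expansion: int = 4
    dropout: float = 0.1
    mask_time_prob: float = 0.05
    mask_time_length: int = 5
    conv_module_kernel: int = 31
    tap_blocks: tuple = ()     # empty -> default tap at block N

    def __post_init__(self):
        self.conv_specs = tuple(tuple(s) for s in self.conv_specs)
        if self.conv_specs[-1][3] != self.model_width:
            raise ValueError("last conv layer's out_channels must equal model_width")
        if not (0.0 <= self.mask_time_prob <= 1.0):
            raise ValueError("mask_time_prob must be in [0, 1]")
        if self.mask_time_length < 1:
            raise ValueError("mask_time_length must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.model_width % self.heads:
            raise ValueError("model_width must be divisible by heads")
        self.tap_blocks = tuple(self.tap_blocks)
        if not self.tap_blocks:
            self.tap_blocks = (self.n_half,)
        if any(not (1 <= t <= 2 * self.n_half) for t in self.tap_blocks):
            raise ValueError("tap block indices must lie in [1, 2N]")

    @classmethod
    def preset(cls, name: str) -> "EncoderConfig":
        """Named model sizes: 'tiny' (desk-scale), 'M' (8 blocks), 'L' (10)."""
        if name == "tiny":
            # desk-scale preset: dropout off and lean feed-forwards — at this
            # model size and data volume they only slow convergence; time
            # masking still regularizes
            return cls(conv_specs=((5, 1, 1, 4), (5, 1, 1, 16), (19, 10, 1, 64)),
                       model_width=64, n_half=2, heads=4, conv_module_kernel=9,
                       ff_expansion=2, dropout=0.0)
        if name == "M":
            return cls(n_half=4)
        if name == "L":
            return cls(n_half=5)
        raise ValueError(f"unknown preset {name!r} (expected tiny/M/L)")


@dataclass
class EncoderOutput:
    """Forward-pass products the losses and decoder consume."""

    final_states: Tensor                    # (B, T, D)
    intermediate_states: dict               # block index -> (B, T, D) Tensor
    mask_positions: np.ndarray              # bool (B, T): frames that were masked
    half_length: int                        # frame count of the half-rate stage
    length: int = field(default=0)

    def __post_init__(self):
        self.length = self.final_states.shape[1]


# ---------------------------------------------------------------------------
# length bookkeeping for the convolution front-end

def conv_output_length(conv_specs, length: int) -> int:
    """Frame count after the conv front-end: per layer floor((L+2p-k)/s)+1."""
    for k, p, s, _c in conv_specs:
        length = (length + 2 * p - k) // s + 1
        if length < 1:
            raise ValueError("input too short for the convolution stack")
    return length


def min_chunk_len(conv_specs=DEFAULT_CONV_SPECS) -> int:
    """Receptive field of the conv stack: shortest admissible input."""
    rf, jump = 1, 1
    for k, _p, s, _c in conv_specs:
        rf += (k - 1) * jump
        jump *= s
    return rf


def frame_sample_centers(conv_specs, length: int) -> np.ndarray:
    """Sample position at the centre of each output frame's receptive stride.

    Back-maps output frame indices through the conv stack with the affine
    rule c_in = s * c_out + (k-1)/2 - p per layer.  Used to convert
    per-sample base labels to per-frame labels for the KL loss.
    """
    t_out = conv_output_length(conv_specs, length)
    centers = np.arange(t_out, dtype=float)
    for k, p, s, _c in reversed(conv_specs):
        centers = s * centers + (k - 1) / 2.0 - p
    return centers


def frame_stride(conv_specs) -> int:
    """Total temporal subsampling factor of the conv front-end."""
    out = 1
    for _k, _p, s, _c in conv_specs:
        out *= s
    return out


# ---------------------------------------------------------------------------
# time-step masking

def sample_time_mask(n_frames: int, prob: float, span: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sample wav2vec2.0-style mask positions for one sequence.

    Returns (start_indices, boolean mask of length n_frames).  Exactly
    round(prob * n_frames) start indices are drawn uniformly without
    replacement; each masks min(span, remaining) consecutive frames.
    Overlapping spans only reduce the total masked fraction, never raise it
    above prob * span.
    """
    n_starts = int(round(prob * n_frames))
    mask = np.zeros(n_frames, dtype=bool)
    if n_starts == 0:
        return np.empty(0, dtype=int), mask
    starts = rng.choice(n_frames, size=n_starts, replace=False)
    for s in starts:
        mask[s:s + span] = True
    return np.sort(starts), mask


# ---------------------------------------------------------------------------
# parameterized layers

class _Layers:
    """Base for anything that owns named parameters."""

    def __init__(self):
        self._params: list[tuple[str, Tensor]] = []

    def param(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(data, dtype=np.float32), requires_grad=True, name=name)
        self._params.append((name, t))
        return t

    def named_parameters(self):
        return list(self._params)

    def parameters(self):
        return [t for _n, t in self._params]


def _xavier(rng, fan_in, fan_out, shape):
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


class SqueezeCallModel(_Layers):
    """The full encoder plus output heads, with explicit seeded init."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        d = config.model_width

        # conv front-end
        self.conv_front = []
        cin = 1
        for i, (k, p, s, cout) in enumerate(config.conv_specs):
            w = self.param(f"conv{i}.w", _xavier(rng, k * cin, cout, (k, cin, cout)))
            b = self.param(f"conv{i}.b", np.zeros(cout))
            g = self.param(f"conv{i}.ln.g", np.ones(cout))
            bb = self.param(f"conv{i}.ln.b", np.zeros(cout))
            self.conv_front.append((w, b, g, bb, s, p))
            cin = cout

        # learned mask vector, initialized uniform on [0, 1)
        self.mask_vec = self.param("mask_vec", rng.uniform(0.0, 1.0, size=d))

        # U-Net blocks
        self.blocks = [self._make_block(rng, f"block{i}") for i in range(2 * config.n_half)]

        # pooling (stride-2 depthwise conv, kernel 3, pad 1 -> ceil(T/2))
        self.pool_w = self.param("pool.w", _xavier(rng, 3, 1, (3, d)))
        self.pool_b = self.param("pool.b", np.zeros(d))

        # upsampling pointwise projection
        self.up_w = self.param("up.w", _xavier(rng, d, d, (d, d)))
        self.up_b = self.param("up.b", np.zeros(d))

        # output heads: final + one per intermediate tap
        self.head_w = self.param("head.w", _xavier(rng, d, N_CLASSES, (d, N_CLASSES)))
        self.head_b = self.param("head.b", np.zeros(N_CLASSES))
        self.tap_heads = {}
        for t in config.tap_blocks:
            tw = self.param(f"tap{t}.w", _xavier(rng, d, N_CLASSES, (d, N_CLASSES)))
            tb = self.param(f"tap{t}.b", np.zeros(N_CLASSES))
            self.tap_heads[t] = (tw, tb)

    # -- sub-structures --------------------------------------------------
    def _make_block(self, rng, prefix):
        cfg = self.config
        d, e = cfg.model_width, cfg.ff_expansion

        def lin(name, fi, fo):
            return (self.param(f"{prefix}.{name}.w", _xavier(rng, fi, fo, (fi, fo))),
                    self.param(f"{prefix}.{name}.b", np.zeros(fo)))

        def ln(name):
            return (self.param(f"{prefix}.{name}.g", np.ones(d)),
                    self.param(f"{prefix}.{name}.b", np.zeros(d)))

        block = {
            "ff1": (lin("ff1.in", d, e * d), lin("ff1.out", e * d, d)),
            "ff2": (lin("ff2.in", d, e * d), lin("ff2.out", e * d, d)),
            "attn": {"q": lin("attn.q", d, d), "k": lin("attn.k", d, d),
                     "v": lin("attn.v", d, d), "o": lin("attn.o", d, d)},
            "conv": {"pw1": lin("conv.pw1", d, 2 * d),
                     "dw": (self.param(f"{prefix}.conv.dw.w",
                                       _xavier(rng, cfg.conv_module_kernel, 1,
                                               (cfg.conv_module_kernel, d))),
                            self.param(f"{prefix}.conv.dw.b", np.zeros(d))),
                     "ln": ln("conv.ln"),
                     "pw2": lin("conv.pw2", d, d)},
            "ln1": ln("ln1"), "ln2": ln("ln2"), "ln3": ln("ln3"), "ln4": ln("ln4"),
        }
        return block

    # -- forward pieces --------------------------------------------------
    @staticmethod
    def _linear(x, wb):
        w, b = wb
        return ag.add(ag.matmul(x, w), b)

    def _ff(self, x, ff, rng):
        inner = ag.gelu(self._linear(x, ff[0]))
        inner = ag.dropout(inner, self.config.dropout, rng)
        return ag.dropout(self._linear(inner, ff[1]), self.config.dropout, rng)

    def _attn(self, x, attn, rng):
        cfg = self.config
        b_sz, t, d = x.shape
        h, dh = cfg.heads, d // cfg.heads

        def split(z):
            return ag.transpose(ag.reshape(z, (b_sz, t, h, dh)), (0, 2, 1, 3))

        q = split(self._linear(x, attn["q"]))
        k = split(self._linear(x, attn["k"]))
        v = split(self._linear(x, attn["v"]))
        scores = ag.scale(ag.matmul(q, ag.transpose(k, (0, 1, 3, 2))), 1.0 / np.sqrt(dh))
        p = ag.dropout(ag.softmax(scores, axis=-1), cfg.dropout, rng)
        o = ag.transpose(ag.matmul(p, v), (0, 2, 1, 3))
        o = ag.reshape(o, (b_sz, t, d))
        return ag.dropout(self._linear(o, attn["o"]), cfg.dropout, rng)

    def _conv_module(self, x, conv, rng):
        cfg = self.config
        d = cfg.model_width
        z = self._linear(x, conv["pw1"])
        a, b = z[..., :d], z[..., d:]
        z = ag.mul(a, ag.sigmoid(b))                      # GLU
        kk = cfg.conv_module_kernel
        z = ag.depthwise_conv1d(z, conv["dw"][0], conv["dw"][1],
                                stride=1, padding=(kk - 1) // 2)
        z = ag.layer_norm(z, conv["ln"][0], conv["ln"][1])
        z = ag.mul(z, ag.sigmoid(z))                      # Swish
        return ag.dropout(self._linear(z, conv["pw2"]), cfg.dropout, rng)

    def _block_forward(self, x, block, rng):
        # FMCF order; post-layer-norm residual sublayers, macaron 0.5 on FFs
        x = ag.layer_norm(ag.add(x, ag.scale(self._ff(x, block["ff1"], rng), 0.5)),
                          *block["ln1"])
        x = ag.layer_norm(ag.add(x, self._attn(x, block["attn"], rng)), *block["ln2"])
        x = ag.layer_norm(ag.add(x, self._conv_module(x, block["conv"], rng)),
                          *block["ln3"])
        x = ag.layer_norm(ag.add(x, ag.scale(self._ff(x, block["ff2"], rng), 0.5)),
                          *block["ln4"])
        return x

    # -- public API ------------------------------------------------------
    _pe_cache: dict = {}

    def _positional_encoding(self, t: int, dtype) -> np.ndarray:
        """Sinusoidal absolute positional encoding, cached per (T, D)."""
        d = self.config.model_width
        key = (t, d)
        if key not in SqueezeCallModel._pe_cache:
            pos = np.arange(t)[:, None]
            dim = np.arange(0, d, 2)[None, :]
            angles = pos / np.power(10000.0, dim / d)
            pe = np.zeros((t, d), dtype=np.float32)
            pe[:, 0::2] = np.sin(angles)
            pe[:, 1::2] = np.cos(angles)
            SqueezeCallModel._pe_cache[key] = pe
        return SqueezeCallModel._pe_cache[key].astype(dtype, copy=False)

    def conv_forward(self, signal: np.ndarray | Tensor) -> Tensor:
        """Front-end convolutions on a (B, L) signal batch -> (B, T, D)."""
        if not isinstance(signal, Tensor):
            signal = Tensor(np.asarray(signal, dtype=np.float32))
        if signal.ndim != 2:
            raise ValueError("expected a (batch, samples) signal array")
        if signal.shape[1] < min_chunk_len(self.config.conv_specs):
            raise ValueError(
                f"chunk of {signal.shape[1]} samples is shorter than the "
                f"receptive field ({min_chunk_len(self.config.conv_specs)})")
        x = ag.reshape(signal, (*signal.shape, 1))
        for w, b, g, bb, s, p in self.conv_front:
            x = ag.conv1d(x, w, b, stride=s, padding=p)
            x = ag.layer_norm(x, g, bb)
            x = ag.gelu(x)
        return x

    def apply_time_mask(self, frames: Tensor, seed: int | None,
                        training: bool) -> tuple[Tensor, np.ndarray]:
        """Replace sampled time spans by the learned mask vector (training only)."""
        b_sz, t, _d = frames.shape
        positions = np.zeros((b_sz, t), dtype=bool)
        cfg = self.config
        if not training or cfg.mask_time_prob == 0.0:
            return frames, positions
        rng = np.random.default_rng(seed)
        for i in range(b_sz):
            _starts, positions[i] = sample_time_mask(
                t, cfg.mask_time_prob, cfg.mask_time_length, rng)
        m = positions[:, :, None].astype(frames.data.dtype)
        masked = ag.add(ag.mul(frames, Tensor(1.0 - m)),
                        ag.mul(self.mask_vec, Tensor(m)))
        return masked, positions

    def unet_forward(self, frames: Tensor, rng=None) -> EncoderOutput:
        """Temporal U-Net over (B, T, D) frames; restores length T."""
        cfg = self.config
        t_full = frames.shape[1]
        if t_full < 2:
            raise ValueError("U-Net needs at least 2 frames")
        n = cfg.n_half
        taps_raw: dict[int, Tensor] = {}
        x = frames
        for i in range(n - 1):                       # blocks 1..N-1, full rate
            x = self._block_forward(x, self.blocks[i], rng)
            if (i + 1) in cfg.tap_blocks:
                taps_raw[i + 1] = x
        pre_pool = x
        x = ag.depthwise_conv1d(x, self.pool_w, self.pool_b, stride=2, padding=1)
        half_len = x.shape[1]                        # == ceil(T/2)
        for i in range(n - 1, 2 * n - 1):            # blocks N..2N-1, half rate
            x = self._block_forward(x, self.blocks[i], rng)
            if (i + 1) in cfg.tap_blocks:
                taps_raw[i + 1] = x
        x = ag.repeat_time(x, 2, t_full)
        x = self._linear(x, (self.up_w, self.up_b))
        x = ag.add(x, pre_pool)                      # residual skip across the valley
        x = self._block_forward(x, self.blocks[2 * n - 1], rng)
        if 2 * n in cfg.tap_blocks:
            taps_raw[2 * n] = x
        taps = {idx: (ag.repeat_time(z, 2, t_full) if z.shape[1] != t_full else z)
                for idx, z in taps_raw.items()}
        return EncoderOutput(final_states=x, intermediate_states=taps,
                             mask_positions=np.zeros((frames.shape[0], t_full), bool),
                             half_length=half_len)

    def head_logprobs(self, states: Tensor, tap: int | None = None) -> Tensor:
        """Affine map to 5 logits then log-softmax (rows are log-distributions)."""
        wb = (self.head_w, self.head_b) if tap is None else self.tap_heads[tap]
        return ag.log_softmax(self._linear(states, wb), axis=-1)

    def encode(self, signal, training: bool = False,
               seed: int | None = None) -> EncoderOutput:
        """Full forward: conv front-end, (train-only) masking, U-Net."""
        rng = np.random.default_rng(seed) if (training and self.config.dropout > 0) else None
        frames = self.conv_forward(signal)
        frames, positions = self.apply_time_mask(
            frames, None if seed is None else seed + 1, training)
        # absolute positions for the attention sublayers
        frames = ag.add(frames, Tensor(
            self._positional_encoding(frames.shape[1], frames.data.dtype)))
        out = self.unet_forward(frames, rng)
        out.mask_positions = positions
        return out

    def basecall_logprobs(self, signal) -> np.ndarray:
        """Eval-mode posteriorgrams for a (B, L) batch, as a NumPy array."""
        with ag.no_grad():
            out = self.encode(signal, training=False)
            return self.head_logprobs(out.final_states).data


def count_parameters(config: EncoderConfig) -> int:
    """Exact trainable-parameter count of the assembled model."""
    return sum(p.data.size for p in SqueezeCallModel(config, seed=0).parameters())


# ---------------------------------------------------------------------------
# checkpoints: one .npz archive holding weights + the config as JSON text

def save_checkpoint(model: SqueezeCallModel, path) -> None:
    arrays = {name: t.data for name, t in model.named_parameters()}
    cfg = asdict(model.config)
    arrays["__config__"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8).copy()
    np.savez(path, **arrays)


def load_checkpoint(path) -> SqueezeCallModel:
    with np.load(path) as archive:
        cfg_json = bytes(archive["__config__"]).decode()
        cfg = EncoderConfig(**json.loads(cfg_json))
        model = SqueezeCallModel(cfg, seed=0)
        for name, t in model.named_parameters():
            if name not in archive:
                raise ValueError(f"checkpoint missing parameter {name!r}")
            if archive[name].shape != t.data.shape:
                raise ValueError(f"checkpoint/config mismatch for {name!r}")
            t.data = archive[name].astype(np.float32)
    return model
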