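"""Single-process training loop: Adam with linear warmup/decay over chunks.

The learning rate warms linearly to its peak (default 0.0005 over the
first 1,000 updates) and then decays linearly to zero at ``total_steps``.
Each update draws a shuffled batch of fixed-length chunks, evaluates the
combined CTC / intermediate-CTC / KL loss, backpropagates, clips the
global gradient norm at 5 (standard for CTC stability) and applies Adam
(beta1 0.9, beta2 0.999, eps 1e-8).  All shuffling, masking and dropout
randomness derives from the config seed, so a run is fully reproducible on
one machine.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _autograd as ag
from .basecall_eval import chunk_match_rate
from .chunking_io import Chunk, attach_frame_labels, chunk_read
from .encoder_model import (SqueezeCallModel, frame_sample_centers, frame_stride,
                            save_checkpoint)
from .objectives import LossWeights, ctc_feasible
from .ctc_decode import greedy_decode
from .squiggle_sim import SquiggleDataset

__all__ = ["TrainConfig", "TrainReport", "lr_at", "train",
           "evaluate_checkpoint", "prepare_chunks", "Adam"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters; ``total_steps`` must always be given."""

    total_steps: int
    peak_lr: float = 0.0005
    warmup_steps: int = 1000
    batch_size: int = 64
    seed: int = 0
    chunk_len: int = 3600
    val_fraction: float = 0.05
    eval_every: int = 0           # 0: evaluate only at the end
    grad_clip: float = 5.0
    log_path: str | None = None

    def __post_init__(self):
        if self.total_steps < 0 or self.warmup_steps < 0:
            raise ValueError("step counts must be nonnegative")
        if self.warmup_steps > self.total_steps:
            raise ValueError("warmup_steps must not exceed total_steps")
        if self.peak_lr <= 0 or self.batch_size < 1 or self.chunk_len < 1:
            raise ValueError("peak_lr, batch_size and chunk_len must be positive")


@dataclass
class TrainReport:
    """Per-step losses and validation history of one training run."""

    steps: list = field(default_factory=list)       # dicts: step, lr, losses
    validation: list = field(default_factory=list)  # (step, median match rate)
    n_train_chunks: int = 0
    n_val_chunks: int = 0

    @property
    def final_match_rate(self) -> float | None:
        return self.validation[-1][1] if self.validation else None


def lr_at(step: int, config: TrainConfig) -> float:
    """Linear warmup to peak_lr at warmup_steps, linear decay to 0 at total_steps."""
    if not 0 <= step <= config.total_steps:
        raise ValueError("step out of [0, total_steps]")
    if step <= config.warmup_steps:
        if config.warmup_steps == 0:
            return config.peak_lr
        return config.peak_lr * step / config.warmup_steps
    return config.peak_lr * (config.total_steps - step) / \
        (config.total_steps - config.warmup_steps)


class Adam:
    """Plain Adam over a list of parameter Tensors."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def clip_global_norm(params, max_norm: float) -> float:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return float(norm)


def prepare_chunks(dataset: SquiggleDataset, model: SqueezeCallModel,
                   chunk_len: int) -> list[Chunk]:
    """Chunk every read, attach per-frame labels, drop CTC-infeasible chunks."""
    specs = model.config.conv_specs
    centers = frame_sample_centers(specs, chunk_len)
    n_frames = len(centers)
    chunks: list[Chunk] = []
    for read in dataset.reads:
        chunks.extend(chunk_read(read, chunk_len, mode="train"))
    attach_frame_labels(chunks, centers, window=float(frame_stride(specs)))
    return [c for c in chunks if ctc_feasible(n_frames, c.label)]


def _split(chunks: list[Chunk], val_fraction: float, rng: np.random.Generator):
    order = rng.permutation(len(chunks))
    n_val = max(1, int(round(val_fraction * len(chunks)))) if len(chunks) > 1 else 0
    val_idx = set(order[:n_val].tolist())
    train = [chunks[i] for i in order if i not in val_idx]
    val = [chunks[i] for i in sorted(val_idx)]
    return train, val


def batch_loss(model: SqueezeCallModel, batch: list[Chunk],
               weights: LossWeights, seed: int | None):
    """Mean combined loss over a batch; returns (Tensor, component means).

    Equivalent to averaging :func:`squeezecall.objectives.combined_loss`
    over the chunks, but evaluated with the batched CTC/KL kernels (one
    lattice sweep for the whole batch).
    """
    from .objectives import ctc_loss_batch, kl_loss_batch

    signals = np.stack([c.signal for c in batch])
    labels = [c.label for c in batch]
    out = model.encode(signals, training=True, seed=seed)
    final_lp = model.head_logprobs(out.final_states)
    n = len(batch)
    terms = []
    ctc_vec = ctc_loss_batch(final_lp, labels)
    ctc_mean = ag.scale(ag.tsum(ctc_vec), 1.0 / n)
    terms.append(ag.scale(ctc_mean, weights.gamma))
    tap_means = []
    for idx, states in out.intermediate_states.items():
        tap_lp = model.head_logprobs(states, tap=idx)
        tap_means.append(ag.scale(ag.tsum(ctc_loss_batch(tap_lp, labels)), 1.0 / n))
    inter_mean = tap_means[0]
    for extra in tap_means[1:]:
        inter_mean = ag.add(inter_mean, extra)
    inter_mean = ag.scale(inter_mean, 1.0 / len(tap_means))
    terms.append(ag.scale(inter_mean, weights.beta))
    kl_mean = kl_loss_batch(final_lp, np.stack([c.frame_labels for c in batch]))
    terms.append(ag.scale(kl_mean, weights.kl_weight))
    total = terms[0]
    for term in terms[1:]:
        total = ag.add(total, term)
    comps = np.array([float(ctc_mean.data), float(inter_mean.data),
                      float(kl_mean.data)])
    return total, comps


def train(model: SqueezeCallModel, dataset: SquiggleDataset,
          train_config: TrainConfig, loss_weights: LossWeights = LossWeights(),
          checkpoint_path: str | Path | None = None) -> TrainReport:
    """Run the optimization loop; returns the training report.

    With ``total_steps`` 0 the model is returned untouched and the report
    is empty.  Training aborts with RuntimeError if the loss goes
    non-finite (divergence guard).
    """
    report = TrainReport()
    if train_config.total_steps == 0:
        return report
    if len(dataset.reads) == 0:
        raise ValueError("dataset is empty")
    chunks = prepare_chunks(dataset, model, train_config.chunk_len)
    if not chunks:
        raise ValueError("no usable training chunks (reads too short?)")
    rng = np.random.default_rng(train_config.seed)
    train_chunks, val_chunks = _split(chunks, train_config.val_fraction, rng)
    if not train_chunks:
        raise ValueError("no chunks left for training after the validation split")
    report.n_train_chunks, report.n_val_chunks = len(train_chunks), len(val_chunks)

    opt = Adam(model.parameters())
    log_rows = []
    step = 0
    while step < train_config.total_steps:
        for idx_start in range(0, len(train_chunks), train_config.batch_size):
            if step >= train_config.total_steps:
                break
            batch = train_chunks[idx_start:idx_start + train_config.batch_size]
            step += 1
            lr = lr_at(step, train_config)
            fwd_seed = int(rng.integers(0, 2 ** 31 - 1))
            loss, comps = batch_loss(model, batch, loss_weights, fwd_seed)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(f"training diverged at step {step}: loss={value}")
            opt.zero_grad()
            loss.backward()
            clip_global_norm(opt.params, train_config.grad_clip)
            opt.step(lr)
            row = {"step": step, "lr": lr, "ctc": comps[0], "inter": comps[1],
                   "kl": comps[2], "total": value}
            report.steps.append(row)
            log_rows.append(row)
            if train_config.eval_every and step % train_config.eval_every == 0 \
                    and val_chunks:
                report.validation.append(
                    (step, evaluate_checkpoint(model, val_chunks)))
        # reshuffle between epochs
        order = rng.permutation(len(train_chunks))
        train_chunks = [train_chunks[i] for i in order]
    if val_chunks and (not report.validation
                       or report.validation[-1][0] != step):
        report.validation.append((step, evaluate_checkpoint(model, val_chunks)))
    if train_config.log_path:
        _write_log(train_config.log_path, log_rows)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path)
    return report


def _write_log(path, rows):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["step", "lr", "ctc", "inter",
                                                "kl", "total"])
        writer.writeheader()
        writer.writerows(rows)


def evaluate_checkpoint(model: SqueezeCallModel, chunks: list[Chunk],
                        batch_size: int = 32) -> float:
    """Median match rate of greedy basecalls over validation chunks.

    Each chunk is decoded greedily, globally aligned to its label and
    scored as matches / alignment length; the median over chunks is
    returned.
    """
    if not chunks:
        raise ValueError("no chunks to evaluate")
    calls = []
    for start in range(0, len(chunks), batch_size):
        batch = chunks[start:start + batch_size]
        logprobs = model.basecall_logprobs(np.stack([c.signal for c in batch]))
        calls.extend(greedy_decode(lp) for lp in logprobs)
    return chunk_match_rate(calls, [c.label for c in chunks])
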