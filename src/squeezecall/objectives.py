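"""Training objective: CTC, intermediate CTC, and label-smoothed KL losses.

The final loss is the weighted combination

    Loss = gamma * L_CTC(final head) + beta * L_inter + (1 - gamma - beta) * L_KL

with defaults gamma = 0.3 and beta = 0.35.  L_CTC is the negative
log-likelihood of the label under the per-frame categorical head, summing
over all blank-augmented alignments with the standard collapse-repeats
convention.  L_inter averages the same CTC loss over intermediate encoder
blocks, each read through its own projection head.  L_KL is the mean
frame-wise KL divergence from a label-smoothed one-hot target (smoothing
factor 0.1) to the predicted distribution: KL(label_smooth(y_t) || p_t).

The CTC forward/backward recursions run in log space in float64; the
analytic gradient with respect to the input log-probabilities is
-sum_{s: symbol(s)=k} exp(alpha_t(s) + beta_t(s) - log P), exposed to the
autograd engine so the whole network trains through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .encoder_model import BLANK, N_CLASSES
from .squiggle_sim import BASES

__all__ = [
    "LossWeights", "SmoothedTarget", "InfeasibleLabelError",
    "label_smooth", "ctc_loss", "ctc_loglik", "intermediate_ctc",
    "kl_loss", "combined_loss",
]

NEG_INF = -np.inf


class InfeasibleLabelError(ValueError):
    """The label cannot be emitted in the available frames (loss = +inf)."""


@dataclass(frozen=True)
class LossWeights:
    """Weights of the combined objective (CTC, intermediate; KL gets the rest)."""

    gamma: float = 0.3
    beta: float = 0.35

    def __post_init__(self):
        if self.gamma < 0 or self.beta < 0 or self.gamma + self.beta > 1 + 1e-12:
            raise ValueError("need gamma >= 0, beta >= 0, gamma + beta <= 1")

    @property
    def kl_weight(self) -> float:
        return 1.0 - self.gamma - self.beta


@dataclass(frozen=True)
class SmoothedTarget:
    """A label-smoothed categorical target distribution."""

    probs: np.ndarray
    class_index: int
    factor: float


def label_smooth(class_index: int, n_classes: int = N_CLASSES,
                 factor: float = 0.1) -> SmoothedTarget:
    """Label smoothing: 1 - factor on the class, factor/(K-1) elsewhere.

    For the 5-class base alphabet with factor 0.1 and class 1 the target is
    (0.025, 0.9, 0.025, 0.025, 0.025).
    """
    if not 0 <= class_index < n_classes:
        raise ValueError("class_index out of range")
    if not 0.0 <= factor < 1.0:
        raise ValueError("smoothing factor must be in [0, 1)")
    probs = np.full(n_classes, factor / (n_classes - 1))
    probs[class_index] = 1.0 - factor
    return SmoothedTarget(probs=probs, class_index=class_index, factor=factor)


# ---------------------------------------------------------------------------
# CTC core

def _label_ids(label) -> np.ndarray:
    if isinstance(label, str):
        try:
            return np.array([BASES.index(b) for b in label], dtype=np.int64)
        except ValueError as exc:
            raise ValueError(f"label contains a non-ACGT character: {label!r}") from exc
    return np.asarray(label, dtype=np.int64)


def _extended_states(ids: np.ndarray) -> np.ndarray:
    """Blank-augmented state sequence: blank, y1, blank, y2, ..., blank."""
    ext = np.full(2 * len(ids) + 1, BLANK, dtype=np.int64)
    ext[1::2] = ids
    return ext


def ctc_feasible(n_frames: int, label) -> bool:
    """Whether the label fits into n_frames (repeats need a separating blank)."""
    ids = _label_ids(label)
    repeats = int(np.sum(ids[1:] == ids[:-1])) if len(ids) > 1 else 0
    return n_frames >= len(ids) + repeats


def _ctc_alpha_beta(logp: np.ndarray, ext: np.ndarray):
    """Log-space forward/backward variables over the extended state lattice."""
    T, S = logp.shape[0], len(ext)
    emit = logp[:, ext]                               # (T, S)
    allow_skip = np.zeros(S, dtype=bool)
    allow_skip[2:] = (ext[2:] != BLANK) & (ext[2:] != ext[:-2])

    alpha = np.full((T, S), NEG_INF)
    alpha[0, 0] = emit[0, 0]
    if S > 1:
        alpha[0, 1] = emit[0, 1]
    for t in range(1, T):
        prev = alpha[t - 1]
        step = np.full(S, NEG_INF)
        step[1:] = prev[:-1]
        skip = np.full(S, NEG_INF)
        skip[2:] = np.where(allow_skip[2:], prev[:-2], NEG_INF)
        alpha[t] = _lse3(prev, step, skip) + emit[t]

    beta = np.full((T, S), NEG_INF)
    beta[T - 1, S - 1] = 0.0
    if S > 1:
        beta[T - 1, S - 2] = 0.0
    skip_from = np.zeros(S, dtype=bool)
    skip_from[:-2] = allow_skip[2:]
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1] + emit[t + 1]
        step = np.full(S, NEG_INF)
        step[:-1] = nxt[1:]
        skip = np.full(S, NEG_INF)
        skip[:-2] = np.where(skip_from[:-2], nxt[2:], NEG_INF)
        beta[t] = _lse3(nxt, step, skip)

    loglik = _lse2(alpha[T - 1, S - 1], alpha[T - 1, S - 2] if S > 1 else NEG_INF)
    return alpha, beta, float(loglik)


def _lse2(a, b):
    return np.logaddexp(a, b)


def _lse3(a, b, c):
    return np.logaddexp(np.logaddexp(a, b), c)


def ctc_loglik(logp: np.ndarray, label) -> float:
    """log P_CTC(label | posteriorgram), by the forward algorithm."""
    logp = np.asarray(logp, dtype=np.float64)
    ids = _label_ids(label)
    if not ctc_feasible(logp.shape[0], ids):
        raise InfeasibleLabelError(
            f"label of {len(ids)} bases cannot fit in {logp.shape[0]} frames")
    ext = _extended_states(ids)
    _alpha, _beta, loglik = _ctc_alpha_beta(logp, ext)
    return loglik


def _ctc_value_and_grad(logp: np.ndarray, ids: np.ndarray):
    ext = _extended_states(ids)
    alpha, beta, loglik = _ctc_alpha_beta(logp, ext)
    T = logp.shape[0]
    occ = alpha + beta - loglik                       # log state occupancies
    grad = np.zeros_like(logp)
    for k in range(logp.shape[1]):
        cols = np.flatnonzero(ext == k)
        if len(cols):
            with np.errstate(divide="ignore"):
                grad[:, k] = -np.exp(_logsumexp_rows(occ[:, cols]))
    return -loglik, grad


def _logsumexp_rows(x: np.ndarray) -> np.ndarray:
    m = x.max(axis=1)
    safe = np.where(np.isfinite(m), m, 0.0)
    out = safe + np.log(np.exp(x - safe[:, None]).sum(axis=1))
    return np.where(np.isfinite(m), out, NEG_INF)


def _ctc_batch_value_and_grad(logp: np.ndarray, ids_list):
    """Vectorized CTC over a batch: one lattice sweep for all items.

    ``logp`` is (B, T, K); labels may differ in length — extended-state
    lattices are right-padded and padded states never leave -inf.
    Returns (losses (B,), grads (B, T, K)).
    """
    B, T, K = logp.shape
    sizes = [2 * len(ids) + 1 for ids in ids_list]
    S = max(sizes)
    ext = np.full((B, S), BLANK, dtype=np.int64)
    valid = np.zeros((B, S), dtype=bool)
    for b, ids in enumerate(ids_list):
        ext[b, 1:sizes[b]:2] = ids
        valid[b, :sizes[b]] = True
    emit = np.take_along_axis(logp, ext[:, None, :].repeat(T, axis=1), axis=2)
    emit = np.where(valid[:, None, :], emit, NEG_INF)       # (B, T, S)
    allow_skip = np.zeros((B, S), dtype=bool)
    allow_skip[:, 2:] = (ext[:, 2:] != BLANK) & (ext[:, 2:] != ext[:, :-2]) \
        & valid[:, 2:]

    def shift1(x):
        out = np.full_like(x, NEG_INF)
        out[:, 1:] = x[:, :-1]
        return out

    def shift2(x):
        out = np.full_like(x, NEG_INF)
        out[:, 2:] = x[:, :-2]
        return out

    alpha = np.full((B, T, S), NEG_INF)
    alpha[:, 0, 0] = emit[:, 0, 0]
    if S > 1:
        alpha[:, 0, 1] = emit[:, 0, 1]
    for t in range(1, T):
        prev = alpha[:, t - 1]
        skip = np.where(allow_skip, shift2(prev), NEG_INF)
        alpha[:, t] = _lse3(prev, shift1(prev), skip) + emit[:, t]

    beta = np.full((B, T, S), NEG_INF)
    rows = np.arange(B)
    last = np.array(sizes) - 1
    beta[rows, T - 1, last] = 0.0
    beta[rows, T - 1, np.maximum(last - 1, 0)] = 0.0
    skip_from = np.zeros((B, S), dtype=bool)
    skip_from[:, :-2] = allow_skip[:, 2:]

    def unshift1(x):
        out = np.full_like(x, NEG_INF)
        out[:, :-1] = x[:, 1:]
        return out

    def unshift2(x):
        out = np.full_like(x, NEG_INF)
        out[:, :-2] = x[:, 2:]
        return out

    for t in range(T - 2, -1, -1):
        nxt = beta[:, t + 1] + emit[:, t + 1]
        skip = np.where(skip_from, unshift2(nxt), NEG_INF)
        beta[:, t] = _lse3(nxt, unshift1(nxt), skip)

    loglik = np.logaddexp(alpha[rows, T - 1, last],
                          np.where(last >= 1, alpha[rows, T - 1, np.maximum(last - 1, 0)],
                                   NEG_INF))
    occ = alpha + beta - loglik[:, None, None]
    grads = np.zeros_like(logp)
    with np.errstate(divide="ignore"):
        for k in range(K):
            sel = np.where((ext == k) & valid, 0.0, NEG_INF)  # (B, S)
            masked = occ + sel[:, None, :]
            m = masked.max(axis=2)
            safe = np.where(np.isfinite(m), m, 0.0)
            s = safe + np.log(np.exp(masked - safe[:, :, None]).sum(axis=2))
            grads[:, :, k] = -np.exp(np.where(np.isfinite(m), s, NEG_INF))
    return -loglik, grads


def ctc_loss_batch(post, labels):
    """Per-item CTC losses for a (B, T, K) posteriorgram batch.

    Returns a (B,) array, or a (B,) Tensor wired with the batched analytic
    gradient when given a Tensor.  Raises on any infeasible label.
    """
    ids_list = [_label_ids(lab) for lab in labels]
    is_tensor = isinstance(post, Tensor)
    data = post.data if is_tensor else np.asarray(post)
    for ids in ids_list:
        if not ctc_feasible(data.shape[1], ids):
            raise InfeasibleLabelError(
                f"label of {len(ids)} bases cannot fit in {data.shape[1]} frames")
    losses, grads = _ctc_batch_value_and_grad(data.astype(np.float64), ids_list)
    if not is_tensor:
        return losses
    return ag._make(losses, (post,), lambda g: (g[:, None, None] * grads,))


def kl_loss_batch(post, frame_labels, factor: float = 0.1):
    """Mean (over batch) of per-item mean frame KL; one graph node.

    ``frame_labels`` is (B, T) with -1 marking unknown frames.
    """
    frame_labels = np.asarray(frame_labels, dtype=np.int64)
    is_tensor = isinstance(post, Tensor)
    data = post.data if is_tensor else np.asarray(post)
    B, T, K = data.shape
    if frame_labels.shape != (B, T):
        raise ValueError("frame_labels must be (batch, frames)")
    base = np.stack([label_smooth(c, K, factor).probs for c in range(K)])
    valid = frame_labels >= 0
    q = np.where(valid[:, :, None], base[np.clip(frame_labels, 0, K - 1)], 0.0)
    counts = np.maximum(valid.sum(axis=1), 1)           # per-item frame counts
    weights = q / counts[:, None, None] / B
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = float(np.sum(np.where(q > 0, q * np.log(np.maximum(q, 1e-300)), 0.0)
                               / counts[:, None, None]) / B)
    if not is_tensor:
        return entropy - float(np.sum(weights * data))
    cross = ag.tsum(ag.mul(post, Tensor(weights.astype(data.dtype))))
    return ag.add(ag.scale(cross, -1.0), Tensor(np.float64(entropy)))


def ctc_loss(post, label):
    """CTC negative log-likelihood of ``label`` under a (T, 5) posteriorgram.

    Accepts a plain array (returns a float) or an autograd Tensor (returns a
    scalar Tensor wired with the analytic gradient).  Raises
    :class:`InfeasibleLabelError` when the label cannot fit in T frames.
    """
    ids = _label_ids(label)
    is_tensor = isinstance(post, Tensor)
    data = post.data if is_tensor else np.asarray(post)
    if not ctc_feasible(data.shape[0], ids):
        raise InfeasibleLabelError(
            f"label of {len(ids)} bases cannot fit in {data.shape[0]} frames")
    loss, grad = _ctc_value_and_grad(data.astype(np.float64), ids)
    if not is_tensor:
        return float(loss)
    return ag._make(np.float64(loss), (post,), lambda g: (g * grad,))


def intermediate_ctc(taps: dict, label, tap_set=None):
    """Mean CTC loss over tapped blocks, each through its own posteriorgram.

    ``taps`` maps block index -> (T, 5) log-probabilities (already projected
    by that tap's own head).
    """
    if tap_set is None:
        tap_set = tuple(sorted(taps))
    if not tap_set:
        raise ValueError("tap_set must be nonempty")
    missing = [t for t in tap_set if t not in taps]
    if missing:
        raise KeyError(f"missing intermediate tap(s): {missing}")
    losses = [ctc_loss(taps[t], label) for t in tap_set]
    if isinstance(losses[0], Tensor):
        total = losses[0]
        for term in losses[1:]:
            total = ag.add(total, term)
        return ag.scale(total, 1.0 / len(losses))
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# frame-level KL loss

def kl_loss(post, frame_labels, factor: float = 0.1):
    """Mean per-frame KL(label_smooth(y_t) || p_t) over labelled frames.

    ``frame_labels`` holds one class index in [0, 4] per frame; frames
    marked -1 (unknown) are skipped and the normalizer shrinks accordingly.
    """
    frame_labels = np.asarray(frame_labels, dtype=np.int64)
    is_tensor = isinstance(post, Tensor)
    data = post.data if is_tensor else np.asarray(post)
    if data.shape[0] != len(frame_labels):
        raise ValueError("frame_labels length must equal the frame count")
    valid = np.flatnonzero(frame_labels >= 0)
    if len(valid) == 0:
        return ag._make(np.float64(0.0), (post,), lambda g: (np.zeros_like(data),)) \
            if is_tensor else 0.0
    targets = np.stack([label_smooth(int(c), data.shape[1], factor).probs
                        for c in frame_labels[valid]])
    entropy = float(np.sum(targets * np.log(targets)))  # sum_t sum_j q log q
    n = len(valid)
    if not is_tensor:
        cross = float(np.sum(targets * data[valid]))
        return (entropy - cross) / n
    picked = post[valid]                                # (n, K) via autograd getitem
    cross = ag.tsum(ag.mul(picked, Tensor(targets.astype(data.dtype))))
    return ag.add(ag.scale(cross, -1.0 / n), Tensor(np.float64(entropy / n)))


# ---------------------------------------------------------------------------
# combination

def combined_loss(final_post, taps: dict, frame_labels, label,
                  weights: LossWeights = LossWeights(), tap_set=None,
                  smooth_factor: float = 0.1):
    """gamma * CTC(final) + beta * mean tapped CTC + (1-gamma-beta) * KL."""
    terms = []
    if weights.gamma:
        terms.append(ag.scale(_ensure_tensorable(ctc_loss(final_post, label)), weights.gamma))
    if weights.beta:
        terms.append(ag.scale(_ensure_tensorable(
            intermediate_ctc(taps, label, tap_set)), weights.beta))
    if weights.kl_weight > 1e-12:
        terms.append(ag.scale(_ensure_tensorable(
            kl_loss(final_post, frame_labels, smooth_factor)), weights.kl_weight))
    total = terms[0]
    for term in terms[1:]:
        total = ag.add(total, term)
    if isinstance(final_post, Tensor):
        return total
    return float(total.data)


def _ensure_tensorable(x):
    return x if isinstance(x, Tensor) else Tensor(np.float64(x))
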