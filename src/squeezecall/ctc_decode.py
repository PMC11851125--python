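"""CTC decoding: greedy collapse, prefix beam search, and an exhaustive oracle.

Prefix beam search keeps, per surviving label prefix, two log masses: paths
ending in blank and paths ending in the prefix's last symbol.  Extending a
prefix with its own last symbol is only allowed from blank-ending paths
(otherwise the repeat collapses), which is exactly the CTC collapse rule.
All bookkeeping is in log space with logsumexp merging — probability-space
arithmetic underflows at realistic frame counts.

Tie-breaking is fixed everywhere: higher total mass first, then shorter
prefix, then lexicographic order; the beam (at unlimited width) therefore
agrees exactly with the exhaustive enumeration oracle.
"""

from __future__ import annotations

import itertools

import numpy as np

from .encoder_model import BLANK
from .objectives import ctc_loglik
from .squiggle_sim import BASES

__all__ = ["greedy_decode", "beam_search", "exhaustive_best", "phred_qualities"]

NEG_INF = -np.inf
DEFAULT_BEAM_WIDTH = 5


def _lse(a: float, b: float) -> float:
    if a == NEG_INF:
        return b
    if b == NEG_INF:
        return a
    m = a if a > b else b
    return m + np.log(np.exp(a - m) + np.exp(b - m))


def greedy_decode(post: np.ndarray, return_frames: bool = False):
    """Best-path decoding: per-frame argmax, collapse repeats, drop blanks.

    With ``return_frames`` also returns the frame index at which each base
    was first emitted (used for quality heuristics).
    """
    post = np.asarray(post)
    if post.ndim != 2:
        raise ValueError("expected a (T, n_classes) posteriorgram")
    path = post.argmax(axis=1)
    out, frames = [], []
    prev = BLANK
    for t, c in enumerate(path):
        if c != BLANK and c != prev:
            out.append(BASES[c])
            frames.append(t)
        prev = c
    seq = "".join(out)
    return (seq, frames) if return_frames else seq


def _rank_key(item):
    prefix, (pb, pnb) = item
    return (-_lse(pb, pnb), len(prefix), prefix)


def beam_search(post: np.ndarray, width: int = DEFAULT_BEAM_WIDTH) -> tuple[str, float]:
    """Prefix beam search; returns (sequence, log P_CTC estimate).

    The returned score is the accumulated mass of the winning prefix; it is
    exact whenever the beam never pruned an ancestor of the winner (always
    true at sufficient width).
    """
    if width < 1:
        raise ValueError("beam width must be >= 1")
    post = np.asarray(post, dtype=np.float64)
    beams: dict[tuple, list[float]] = {(): [0.0, NEG_INF]}   # prefix -> [pb, pnb]
    for frame in post:
        new: dict[tuple, list[float]] = {}

        def mass(prefix):
            return new.setdefault(prefix, [NEG_INF, NEG_INF])

        for prefix, (pb, pnb) in beams.items():
            total = _lse(pb, pnb)
            # emit blank: prefix unchanged, ends in blank
            entry = mass(prefix)
            entry[0] = _lse(entry[0], total + frame[BLANK])
            for c in range(len(BASES)):
                lp = frame[c]
                if prefix and prefix[-1] == c:
                    # repeat symbol: staying on the same base collapses...
                    entry = mass(prefix)
                    entry[1] = _lse(entry[1], pnb + lp)
                    # ...extending needs a blank-ending path in between
                    ext = mass(prefix + (c,))
                    ext[1] = _lse(ext[1], pb + lp)
                else:
                    ext = mass(prefix + (c,))
                    ext[1] = _lse(ext[1], _lse(pb, pnb) + lp)
        ranked = sorted(new.items(), key=_rank_key)
        beams = dict(ranked[:width])
    best_prefix, (pb, pnb) = min(beams.items(), key=_rank_key)
    return "".join(BASES[c] for c in best_prefix), _lse(pb, pnb)


def exhaustive_best(post: np.ndarray, max_len: int | None = None) -> tuple[str, float]:
    """Enumerate every label string up to ``max_len`` and return the exact
    argmax of P_CTC; the test-oracle counterpart of :func:`beam_search`.

    Guarded to T <= 8 (the search space is 4^max_len strings).  Ties break
    as in the beam: higher probability, then shorter, then lexicographic.
    """
    post = np.asarray(post, dtype=np.float64)
    T = post.shape[0]
    if T > 8:
        raise ValueError("exhaustive search is limited to T <= 8 frames")
    if max_len is None or max_len > T:
        max_len = T
    best: tuple[float, int, str] | None = None
    for length in range(0, max_len + 1):
        for ids in itertools.product(range(len(BASES)), repeat=length):
            label = "".join(BASES[i] for i in ids)
            try:
                score = ctc_loglik(post, label)
            except ValueError:
                continue
            key = (-score, length, label)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[2], -best[0]


def phred_qualities(post: np.ndarray, sequence: str) -> np.ndarray:
    """Per-base Phred qualities from the posteriorgram consumed by a call.

    Heuristic: run the CTC forward/backward over the called sequence and
    take, for each base, its peak state-occupancy probability across
    frames; quality = -10 log10(1 - p), clipped to [1, 40].  Falls back to
    quality 10 for every base if the sequence is infeasible for T frames.
    """
    from .objectives import _ctc_alpha_beta, _extended_states, _label_ids, ctc_feasible

    if not sequence:
        return np.zeros(0, dtype=int)
    post = np.asarray(post, dtype=np.float64)
    ids = _label_ids(sequence)
    if not ctc_feasible(post.shape[0], ids):
        return np.full(len(ids), 10, dtype=int)
    ext = _extended_states(ids)
    alpha, beta, loglik = _ctc_alpha_beta(post, ext)
    occ = alpha + beta - loglik
    quals = []
    for b in range(len(ids)):
        p = float(np.exp(occ[:, 2 * b + 1]).max())
        p = min(p, 1.0 - 1e-4)
        quals.append(int(np.clip(-10.0 * np.log10(1.0 - p), 1, 40)))
    return np.asarray(quals, dtype=int)
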