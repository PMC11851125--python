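"""Basecall evaluation: alignment, error rates, identity, polymer accuracy.

Reads are aligned to their references with a unit-cost global edit-distance
DP (match 0, mismatch/indel 1) and a deterministic traceback that prefers
match/mismatch, then deletion, then insertion.  Indel orientation is
relative to the reference: a read base absent from the reference is an
insertion, a reference base absent from the read a deletion.

Rates follow the usual basecalling bookkeeping: deletion, insertion and
mismatch rates are the respective counts divided by the alignment length,
the error rate is their sum, and the identity rate is matches divided by
the basecalled read length.  Homopolymer (single-base run) and
heteropolymer (tandem 2-mer repeat) accuracies score each maximal
reference run of a given length as correct iff the read segment aligned to
it reproduces the run exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignmentReport", "ErrorRates", "NoRunsError",
    "align", "error_rates", "identity_rate",
    "polymer_accuracy", "find_runs", "chunk_match_rate",
]


class NoRunsError(ValueError):
    """No repeat runs of the requested unit/length exist in the references."""


@dataclass
class AlignmentReport:
    """Counts and operation string of one read-to-reference alignment.

    ``ops`` runs along the alignment: M match, X mismatch, I insertion
    (read base absent in reference), D deletion (reference base absent in
    read).
    """

    matches: int
    mismatches: int
    insertions: int
    deletions: int
    ops: str

    def __post_init__(self):
        if min(self.matches, self.mismatches, self.insertions, self.deletions) < 0:
            raise ValueError("negative alignment counts")
        if len(self.ops) != self.alignment_length:
            raise ValueError("ops string inconsistent with counts")

    @property
    def alignment_length(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def read_length(self) -> int:
        return self.matches + self.mismatches + self.insertions

    @property
    def ref_length(self) -> int:
        return self.matches + self.mismatches + self.deletions

    @property
    def edit_distance(self) -> int:
        return self.mismatches + self.insertions + self.deletions


@dataclass(frozen=True)
class ErrorRates:
    deletion: float
    insertion: float
    mismatch: float

    @property
    def error(self) -> float:
        return self.deletion + self.insertion + self.mismatch


def _edit_dp(read: str, ref: str, free_start: bool = False) -> np.ndarray:
    """Full unit-cost edit-distance DP table, rows = read prefix length.

    ``free_start`` zeroes the first row (unpenalized leading reference gap,
    used by semiglobal alignment).
    """
    m, n = len(read), len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    dp = np.empty((m + 1, n + 1), dtype=np.int32)
    dp[0] = 0 if free_start else np.arange(n + 1)
    cols = np.arange(n + 1)
    for i in range(1, m + 1):
        sub = (ref_arr != ord(read[i - 1])).astype(np.int32)
        v = np.minimum(dp[i - 1, :-1] + sub, dp[i - 1, 1:] + 1)
        v = np.concatenate(([np.int32(i)], v))
        # resolve the left-to-right dependency curr[j] = min(v[j], curr[j-1]+1)
        # via a running min of (v[j] - j):  curr[j] = j + min_{j'<=j}(v[j'] - j')
        dp[i] = cols + np.minimum.accumulate(v - cols)
    return dp


def align(read: str, reference: str, mode: str = "global") -> AlignmentReport:
    """Edit-distance alignment of a basecalled read to its reference.

    ``mode='global'`` aligns both sequences end to end (the right choice for
    complete simulated reads); ``mode='semiglobal'`` leaves reference
    flanks unpenalized for clipped reads.  Traceback ties prefer
    match/mismatch, then deletion, then insertion, so reports are
    reproducible.
    """
    if not reference:
        raise ValueError("reference must be nonempty")
    if mode not in ("global", "semiglobal"):
        raise ValueError("mode must be 'global' or 'semiglobal'")
    semi = mode == "semiglobal"
    dp = _edit_dp(read, reference, free_start=semi)
    m, n = len(read), len(reference)
    # semiglobal: unpenalized reference flanks, end column chosen by score
    j = int(np.argmin(dp[m])) if semi else n
    i = m
    ops = []
    counts = {"M": 0, "X": 0, "I": 0, "D": 0}
    while i > 0 or j > 0:
        if semi and i == 0:
            break
        if i > 0 and j > 0:
            sub = 0 if read[i - 1] == reference[j - 1] else 1
            if dp[i, j] == dp[i - 1, j - 1] + sub:
                ops.append("M" if sub == 0 else "X")
                counts["M" if sub == 0 else "X"] += 1
                i, j = i - 1, j - 1
                continue
        if j > 0 and dp[i, j] == dp[i, j - 1] + 1:
            ops.append("D")
            counts["D"] += 1
            j -= 1
            continue
        ops.append("I")
        counts["I"] += 1
        i -= 1
    return AlignmentReport(matches=counts["M"], mismatches=counts["X"],
                           insertions=counts["I"], deletions=counts["D"],
                           ops="".join(reversed(ops)))


def error_rates(report: AlignmentReport) -> ErrorRates:
    """Deletion/insertion/mismatch rates (each count / alignment length)."""
    n = report.alignment_length
    if n == 0:
        raise ValueError("alignment length is zero")
    return ErrorRates(deletion=report.deletions / n,
                      insertion=report.insertions / n,
                      mismatch=report.mismatches / n)


def identity_rate(report: AlignmentReport) -> float:
    """Matches divided by the basecalled read length."""
    if report.read_length == 0:
        raise ValueError("read length is zero")
    return report.matches / report.read_length


def find_runs(reference: str, unit: str, length: int) -> list[tuple[int, int]]:
    """Maximal runs of ``unit`` repeated to exactly ``length`` bases.

    For a 1-base unit these are classic homopolymer runs; for a 2-base unit
    (distinct characters, e.g. "AC") maximal perfect tandem repeats, with
    length counted in bases.  A run is maximal when the periodic pattern
    does not continue on either side.
    """
    p = len(unit)
    if p not in (1, 2):
        raise ValueError("unit must be 1 or 2 bases")
    if p == 2 and unit[0] == unit[1]:
        raise ValueError("a 2-base unit must have distinct characters")
    if length < p or length % p:
        raise ValueError("length must be a positive multiple of the unit size")
    runs = []
    i, n = 0, len(reference)
    while i <= n - p:
        if reference[i:i + p] != unit:
            i += 1
            continue
        j = i
        while reference[j:j + p] == unit:
            j += p
        # [i, j) is a maximal whole-period repeat of the unit (a trailing
        # partial period does not extend a tandem repeat)
        if j - i == length:
            runs.append((i, j))
        i = j
    return runs


def _aligned_segment(read: str, ref_start: int, ref_end: int, ops: str) -> str:
    """Read bases aligned to reference interval [ref_start, ref_end).

    Matches/mismatches inside the interval contribute their read base;
    insertions strictly inside (after entering, before leaving) do too.
    """
    i = j = 0
    out = []
    for op in ops:
        if op in "MX":
            if ref_start <= j < ref_end:
                out.append(read[i])
            i += 1
            j += 1
        elif op == "D":
            j += 1
        else:  # insertion: sits between ref j-1 and j
            if ref_start < j < ref_end:
                out.append(read[i])
            i += 1
    return "".join(out)


def polymer_accuracy(pairs, unit: str, length: int, reports=None) -> float:
    """Fraction of reference repeat runs reproduced exactly by the reads.

    ``pairs`` is a list of (read, reference) strings; ``reports`` may carry
    precomputed global alignments (same order) to avoid re-aligning.
    Homopolymer lengths below 3 are rejected — shorter runs are not
    meaningful repeat contexts.
    """
    if len(unit) == 1 and length < 3:
        raise ValueError("homopolymer length must be >= 3")
    total = correct = 0
    for idx, (read, ref) in enumerate(pairs):
        report = reports[idx] if reports is not None else align(read, ref)
        for a, b in find_runs(ref, unit, length):
            total += 1
            if _aligned_segment(read, a, b, report.ops) == ref[a:b]:
                correct += 1
    if total == 0:
        raise NoRunsError(f"no {unit!r}-runs of length {length} in the references")
    return correct / total


def chunk_match_rate(calls, labels) -> float:
    """Median over chunks of matches / alignment length.

    An empty label scores 1.0 against an empty call and 0.0 otherwise; with
    an even chunk count the median is the mean of the two middle rates.
    """
    calls, labels = list(calls), list(labels)
    if len(calls) != len(labels) or not calls:
        raise ValueError("need equal, nonzero numbers of calls and labels")
    rates = []
    for call, label in zip(calls, labels):
        if not label:
            rates.append(1.0 if not call else 0.0)
            continue
        report = align(call, label)
        rates.append(report.matches / report.alignment_length)
    return float(np.median(rates))
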