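"""Signal normalization, fixed-length chunking and sequence-format I/O.

Raw reads are normalized per read with the robust med-MAD transform, then
sliced into non-overlapping fixed-length chunks (default 3,600 samples,
the standard training granularity for nanopore basecallers).  Each chunk
carries the subsequence of bases whose signal lies inside it and,
optionally, one base-class label per encoder output frame for the
frame-level KL term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .squiggle_sim import BASES, SimulatedRead

__all__ = [
    "DEFAULT_CHUNK_LEN",
    "Chunk",
    "normalize",
    "chunk_read",
    "attach_frame_labels",
    "write_fastq",
    "read_fastq",
    "read_fasta",
]

DEFAULT_CHUNK_LEN = 3600
MAD_CONSISTENCY = 1.4826  # makes MAD estimate sigma for Gaussian data
UNKNOWN_FRAME = -1        # frame whose base label cannot be determined


@dataclass
class Chunk:
    """One fixed-length slice of a normalized read."""

    signal: np.ndarray                 # float32, length == chunk_len (zero-padded if partial)
    label: str                         # bases whose dwell midpoint falls inside the chunk
    valid_len: int                     # number of real (non-padded) samples
    sample_classes: np.ndarray | None = None   # int8 per valid sample: class of its base
    frame_labels: np.ndarray | None = field(default=None, repr=False)
    read_id: str = ""
    chunk_start: int = 0               # sample offset of this chunk within the read


def normalize(signal: np.ndarray) -> np.ndarray:
    """Med-MAD normalize a signal: (x - median) / (1.4826 * MAD).

    If the MAD is zero (constant signal) the scale divisor falls back to 1,
    so a constant signal maps to all zeros.
    """
    signal = np.asarray(signal, dtype=np.float32)
    if signal.size == 0:
        raise ValueError("cannot normalize an empty signal")
    med = np.median(signal)
    mad = np.median(np.abs(signal - med))
    scale = MAD_CONSISTENCY * mad
    if scale == 0:
        scale = 1.0
    return ((signal - med) / scale).astype(np.float32)


def _base_midpoints(base_index: np.ndarray, n_bases: int) -> np.ndarray:
    """Midpoint sample position of each base's dwell (-inf if never observed)."""
    mids = np.full(n_bases, -np.inf)
    starts = np.flatnonzero(np.diff(base_index, prepend=base_index[0] - 1))
    ends = np.append(starts[1:], len(base_index))
    for s, e in zip(starts, ends):
        mids[base_index[s]] = (s + e - 1) / 2.0
    return mids


def chunk_read(read: SimulatedRead, chunk_len: int = DEFAULT_CHUNK_LEN,
               mode: str = "train") -> list[Chunk]:
    """Cut a read into non-overlapping chunks of ``chunk_len`` samples.

    The signal is med-MAD normalized per read before slicing so chunk
    boundaries cannot change levels.  A base belongs to the chunk that
    contains the midpoint of its dwell, so every base lands in exactly one
    chunk.  In ``train`` mode the trailing partial chunk is dropped; in
    ``infer`` mode it is zero-padded with its true length recorded in
    ``valid_len``.
    """
    if chunk_len < 1:
        raise ValueError("chunk_len must be >= 1")
    if mode not in ("train", "infer"):
        raise ValueError("mode must be 'train' or 'infer'")
    sig = normalize(read.signal)
    n = len(sig)
    mids = _base_midpoints(read.base_index, len(read.sequence))
    seq_classes = np.array([BASES.index(b) for b in read.sequence], dtype=np.int8)
    per_sample = seq_classes[read.base_index]
    n_full = n // chunk_len
    chunks: list[Chunk] = []
    bounds = [(i * chunk_len, (i + 1) * chunk_len) for i in range(n_full)]
    if mode == "infer" and n % chunk_len:
        bounds.append((n_full * chunk_len, n))
    for start, end in bounds:
        in_chunk = np.flatnonzero((mids >= start) & (mids < end))
        label = "".join(read.sequence[b] for b in in_chunk)
        seg = sig[start:end]
        valid = len(seg)
        if valid < chunk_len:
            seg = np.pad(seg, (0, chunk_len - valid))
        chunks.append(Chunk(signal=seg.astype(np.float32), label=label,
                            valid_len=valid,
                            sample_classes=per_sample[start:end].copy(),
                            read_id=read.read_id, chunk_start=start))
    return chunks


def attach_frame_labels(chunks: list[Chunk], centers: np.ndarray,
                        window: float = 1.0) -> None:
    """Derive one base-class label per encoder frame for each chunk.

    ``centers`` gives, for each encoder output frame, the sample position
    (chunk-local) at the centre of its receptive stride; ``window`` is the
    stride width in samples.  The frame label is the majority base among the
    samples inside that window, encoded as the base's class index (A=0, C=1,
    G=2, T=3).  Frames whose window falls entirely in zero-padding are
    marked unknown (-1) and skipped by the KL loss.  With stride-1
    convolutions the window is a single sample, so majority vote reduces to
    a nearest-sample lookup.
    """
    half = max(window / 2.0, 0.5)
    centers = np.asarray(centers, dtype=float)
    for chunk in chunks:
        if chunk.sample_classes is None:
            raise ValueError("chunk has no sample_classes; was it made by chunk_read?")
        labels = np.full(len(centers), UNKNOWN_FRAME, dtype=np.int64)
        classes = chunk.sample_classes
        if half <= 0.5:
            # stride-1 window: nearest-sample lookup, fully vectorized
            idx = np.rint(centers).astype(int)
            ok = (idx >= 0) & (idx < chunk.valid_len)
            labels[ok] = classes[idx[ok]]
        else:
            for f, c in enumerate(centers):
                lo = max(int(np.ceil(c - half)), 0)
                hi = min(int(np.floor(c + half)), chunk.valid_len - 1)
                if hi < lo:
                    continue
                labels[f] = int(np.bincount(classes[lo:hi + 1], minlength=4).argmax())
        chunk.frame_labels = labels
    return None


def write_fastq(reads, path) -> None:
    """Write (id, sequence, qualities) records as 4-line FASTQ.

    ``qualities`` may be None (written as '!' placeholders) or an iterable
    of Phred scores (encoded Phred+33, clipped to [0, 93]).  Record ids must
    not contain whitespace.
    """
    with open(path, "w") as fh:
        for rid, seq, quals in reads:
            if any(ch.isspace() for ch in rid):
                raise ValueError(f"FASTQ id may not contain whitespace: {rid!r}")
            if quals is None:
                qstr = "!" * len(seq)
            else:
                qstr = "".join(chr(33 + int(np.clip(q, 0, 93))) for q in quals)
                if len(qstr) != len(seq):
                    raise ValueError("quality length != sequence length")
            fh.write(f"@{rid}\n{seq}\n+\n{qstr}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read 4-line FASTQ records as (id, sequence, quality-string)."""
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines) - 3, 4):
        out.append((lines[i][1:].split()[0], lines[i + 1], lines[i + 3]))
    return out


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence)."""
    out: list[tuple[str, list[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                out.append((line[1:].split()[0], []))
            else:
                out[-1][1].append(line)
    return [(rid, "".join(parts)) for rid, parts in out]
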