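"""Synthetic nanopore squiggle simulation with exact signal-to-base alignment.

A nanopore reports an electrical current whose level is dominated by the
k-mer resident in the pore.  The simulator draws one mean level per k-mer
(a "pore model"), walks a DNA sequence k-mer by k-mer, holds each level for
a random integer dwell and adds white Gaussian noise.  Because the dwell of
every k-mer is known, each sample carries the index of the base that
produced it — the exact analogue of the per-sample labels a resquiggling
tool recovers from real reads, which is what supervised basecaller training
needs.

All randomness flows through explicit integer seeds; there is no global
random state anywhere in this module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "BASES",
    "PoreModel",
    "SimulatedRead",
    "SquiggleDataset",
    "make_pore_model",
    "random_sequence",
    "simulate_read",
    "make_dataset",
    "load_dataset",
    "write_fasta",
]

BASES = "ACGT"
_MAX_K = 6  # 4^6 = 4096 levels; larger tables are a config mistake


@dataclass(frozen=True)
class PoreModel:
    """Mapping from k-mers to expected current levels plus noise/dwell model.

    Levels are standardized (mean 0, sd 1 across the table) in arbitrary
    pA-like units; ``noise_sd`` is per-sample Gaussian noise on that scale;
    dwells are drawn uniformly from the integer interval
    [dwell_min, dwell_max] samples per k-mer position.
    """

    k: int
    level_table: dict[str, float]
    noise_sd: float
    dwell_min: int
    dwell_max: int

    def __post_init__(self):
        if len(self.level_table) != 4 ** self.k:
            raise ValueError(f"level_table must have 4^{self.k} entries")
        if not (0 < self.dwell_min <= self.dwell_max):
            raise ValueError("dwell bounds must satisfy 0 < dwell_min <= dwell_max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class SimulatedRead:
    """A simulated read: sequence, raw signal, and per-sample base index."""

    sequence: str
    signal: np.ndarray            # float32, shape (n_samples,)
    base_index: np.ndarray        # int32, shape (n_samples,), non-decreasing
    read_id: str = "read"

    def __post_init__(self):
        if len(self.signal) != len(self.base_index):
            raise ValueError("signal and base_index must have equal length")


@dataclass
class SquiggleDataset:
    """In-memory collection of simulated reads plus the generating model."""

    reads: list[SimulatedRead]
    model: PoreModel
    seed: int | None = None
    path: Path | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.reads)


def make_pore_model(k: int, seed: int, noise_sd: float = 0.1,
                    dwell_min: int = 5, dwell_max: int = 10) -> PoreModel:
    """Draw a random pore model: one standardized level per k-mer.

    Levels come from a seeded standard normal and are re-standardized to
    mean 0, sd 1 across the 4^k table so signal scale is comparable for
    any k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > _MAX_K:
        raise ValueError(f"k > {_MAX_K} rejected (table size 4^k)")
    rng = np.random.default_rng(seed)
    levels = rng.standard_normal(4 ** k)
    levels = (levels - levels.mean()) / levels.std()
    kmers = ("".join(p) for p in itertools.product(BASES, repeat=k))
    table = {kmer: float(level) for kmer, level in zip(kmers, levels)}
    return PoreModel(k=k, level_table=table, noise_sd=float(noise_sd),
                     dwell_min=int(dwell_min), dwell_max=int(dwell_max))


def random_sequence(length: int, seed: int) -> str:
    """Uniform random DNA sequence of the given length."""
    if length < 0:
        raise ValueError("length must be nonnegative")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length)) if length else ""


def simulate_read(sequence: str, model: PoreModel, seed: int,
                  read_id: str = "read") -> SimulatedRead:
    """Simulate the squiggle of one read.

    Each of the len(sequence) - k + 1 k-mer positions contributes a block of
    ``dwell`` samples at the k-mer's table level plus Gaussian noise.  The
    per-sample base label is the central base of the resident k-mer
    (position + k // 2; for even k the right-of-centre base).
    """
    n_pos = len(sequence) - model.k + 1
    if n_pos < 1:
        raise ValueError("sequence shorter than k")
    rng = np.random.default_rng(seed)
    dwells = rng.integers(model.dwell_min, model.dwell_max + 1, size=n_pos)
    levels = np.array([model.level_table[sequence[i:i + model.k]] for i in range(n_pos)])
    signal = np.repeat(levels, dwells)
    if model.noise_sd > 0:
        signal = signal + rng.normal(0.0, model.noise_sd, size=signal.shape)
    base_index = np.repeat(np.arange(n_pos, dtype=np.int32) + model.k // 2, dwells)
    return SimulatedRead(sequence=sequence,
                         signal=signal.astype(np.float32),
                         base_index=base_index.astype(np.int32),
                         read_id=read_id)


def make_dataset(n_reads: int, read_length: int, model: PoreModel, seed: int,
                 out_path: str | Path | None = None) -> SquiggleDataset:
    """Simulate a dataset of reads; optionally persist it to disk.

    When ``out_path`` is given the container (HDF5) is written there and a
    sidecar FASTA of the reference sequences appears at ``<out_path>.fasta``.
    Per-read seeds are spawned deterministically from ``seed``.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    root = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        seq_seed, sig_seed = root.integers(0, 2 ** 31 - 1, size=2)
        seq = random_sequence(read_length, int(seq_seed))
        reads.append(simulate_read(seq, model, int(sig_seed), read_id=f"read_{i:06d}"))
    ds = SquiggleDataset(reads=reads, model=model, seed=seed)
    if out_path is not None:
        save_dataset(ds, out_path)
    return ds


def save_dataset(ds: SquiggleDataset, out_path: str | Path) -> Path:
    """Write the dataset container.

    Layout: one HDF5 group per read (``/reads/<read_id>``) holding
    ``signal`` (float32), ``base_index`` (int32) and ``sequence`` (utf-8
    scalar); pore-model parameters as root attributes; the level table as
    ``/pore_model/levels`` aligned with ``/pore_model/kmers``.
    """
    out_path = Path(out_path)
    with h5py.File(out_path, "w") as fh:
        fh.attrs["k"] = ds.model.k
        fh.attrs["noise_sd"] = ds.model.noise_sd
        fh.attrs["dwell_min"] = ds.model.dwell_min
        fh.attrs["dwell_max"] = ds.model.dwell_max
        if ds.seed is not None:
            fh.attrs["seed"] = ds.seed
        pm = fh.create_group("pore_model")
        kmers = sorted(ds.model.level_table)
        pm.create_dataset("kmers", data=[k.encode() for k in kmers])
        pm.create_dataset("levels", data=np.array([ds.model.level_table[k] for k in kmers]))
        grp = fh.create_group("reads")
        for read in ds.reads:
            g = grp.create_group(read.read_id)
            g.create_dataset("signal", data=read.signal.astype(np.float32))
            g.create_dataset("base_index", data=read.base_index.astype(np.int32))
            g.create_dataset("sequence", data=read.sequence)
    write_fasta(((r.read_id, r.sequence) for r in ds.reads),
                out_path.with_name(out_path.name + ".fasta"))
    ds.path = out_path
    return out_path


def load_dataset(path: str | Path) -> SquiggleDataset:
    """Reload a dataset container written by :func:`save_dataset`."""
    path = Path(path)
    with h5py.File(path, "r") as fh:
        kmers = [k.decode() for k in fh["pore_model/kmers"][()]]
        levels = fh["pore_model/levels"][()]
        model = PoreModel(k=int(fh.attrs["k"]),
                          level_table=dict(zip(kmers, map(float, levels))),
                          noise_sd=float(fh.attrs["noise_sd"]),
                          dwell_min=int(fh.attrs["dwell_min"]),
                          dwell_max=int(fh.attrs["dwell_max"]))
        reads = []
        for rid in sorted(fh["reads"]):
            g = fh["reads"][rid]
            seq = g["sequence"][()]
            reads.append(SimulatedRead(
                sequence=seq.decode() if isinstance(seq, bytes) else str(seq),
                signal=g["signal"][()],
                base_index=g["base_index"][()],
                read_id=rid))
        seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
    return SquiggleDataset(reads=reads, model=model, seed=seed, path=path)


def write_fasta(records, path: str | Path, width: int = 80) -> Path:
    """Write (id, sequence) records as FASTA wrapped at ``width`` columns."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path
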