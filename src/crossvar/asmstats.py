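"""Assembly contiguity statistics and k-mer-spectrum genome-size estimation.

Scaffold-level draft assemblies are summarised by the usual contiguity
measures (N50/L50, N90/L90, size, N content).  Scaffolds can be broken into
contigs at runs of undetermined bases (N) of a configurable minimum length
before computing the same statistics at contig level.  Genome size is
estimated from a k-mer multiplicity spectrum by locating the homozygous
coverage peak and dividing the total k-mer mass above the error region by
the peak depth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AssemblyStats",
    "KmerHistogram",
    "GenomeSizeEstimate",
    "break_scaffolds",
    "contiguity_stats",
    "estimate_genome_size",
    "count_n_bases",
]


@dataclass(frozen=True)
class AssemblyStats:
    """Contiguity and size summary of a set of sequences."""

    n_sequences: int
    total_bp: int
    n_bp: int
    pct_n: float
    n50: int
    n90: int
    l50: int
    l90: int
    min_length: int
    max_length: int
    mean_length: float

    def as_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "total_bp": self.total_bp,
            "n_bp": self.n_bp,
            "pct_n": self.pct_n,
            "N50": self.n50,
            "N90": self.n90,
            "L50": self.l50,
            "L90": self.l90,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "mean_length": self.mean_length,
        }


@dataclass(frozen=True)
class KmerHistogram:
    """k-mer multiplicity spectrum: (depth, number of distinct k-mers at that depth)."""

    depths: tuple
    counts: tuple

    def __post_init__(self):
        d = np.asarray(self.depths)
        c = np.asarray(self.counts)
        if d.size != c.size or d.size == 0:
            raise ValueError("depths and counts must be non-empty and equal length")
        if not np.all(np.diff(d) > 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "KmerHistogram":
        pairs = sorted(pairs)
        return cls(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


@dataclass(frozen=True)
class GenomeSizeEstimate:
    genome_size: float
    peak_depth: int
    total_kmers: int


class SpectrumError(ValueError):
    """Raised when a k-mer spectrum has no usable coverage peak."""


def count_n_bases(seq: str) -> int:
    """Number of undetermined (N/n) bases in ``seq``."""
    return seq.count("N") + seq.count("n")


_N_RUN_CACHE: dict = {}


def break_scaffolds(sequences: Iterable[str], min_n_run: int = 10) -> list[int]:
    """Break scaffolds into contigs at N-runs of length >= ``min_n_run``.

    Contigs are the maximal stretches of sequence between gap-sized N runs;
    N runs shorter than ``min_n_run`` remain inside a contig.  Lowercase n
    is treated as N; all other letters (including IUPAC ambiguity codes)
    count as ordinary bases.  Returns contig lengths in input order, left
    to right.  Empty input yields an empty list.
    """
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    pat = _N_RUN_CACHE.get(min_n_run)
    if pat is None:
        pat = _N_RUN_CACHE[min_n_run] = re.compile("[Nn]{%d,}" % min_n_run)
    lengths: list[int] = []
    for seq in sequences:
        for piece in pat.split(seq):
            if piece:
                lengths.append(len(piece))
    return lengths


def contiguity_stats(lengths: Sequence[int], n_bp: int = 0) -> AssemblyStats:
    """Compute N50/N90-style contiguity statistics for a list of lengths.

    Nx is the length of the sequence at which the cumulative sum of
    descending lengths first reaches x% of the total (inclusive: a
    cumulative sum hitting exactly x% at a sequence boundary assigns that
    sequence's length to Nx).  Lx is the number of sequences needed to
    reach it.
    """
    arr = np.asarray(lengths, dtype=np.int64)
    if arr.size == 0:
        raise ValueError("lengths must be non-empty")
    if np.any(arr <= 0):
        raise ValueError("all lengths must be > 0")
    desc = np.sort(arr)[::-1]
    total = int(desc.sum())
    cum = np.cumsum(desc)

    def _nx(frac: float) -> tuple[int, int]:
        target = frac * total
        idx = int(np.searchsorted(cum, target, side="left"))
        return int(desc[idx]), idx + 1

    n50, l50 = _nx(0.5)
    n90, l90 = _nx(0.9)
    return AssemblyStats(
        n_sequences=int(arr.size),
        total_bp=total,
        n_bp=int(n_bp),
        pct_n=100.0 * n_bp / total,
        n50=n50,
        n90=n90,
        l50=l50,
        l90=l90,
        min_length=int(desc[-1]),
        max_length=int(desc[0]),
        mean_length=total / arr.size,
    )


def assembly_stats(sequences: Iterable[str], break_at_n: int | None = None) -> AssemblyStats:
    """Contiguity statistics for FASTA sequences, optionally broken at N-runs."""
    seqs = list(sequences)
    n_bp = sum(count_n_bases(s) for s in seqs)
    if break_at_n is None:
        lengths = [len(s) for s in seqs]
    else:
        lengths = break_scaffolds(seqs, break_at_n)
        # the broken-out gap bases no longer belong to any sequence
        n_bp = sum(count_n_bases(s) for s in seqs) - (
            sum(len(s) for s in seqs) - sum(lengths)
        )
    return contiguity_stats(lengths, n_bp=n_bp)


def estimate_genome_size(hist: KmerHistogram, min_depth_for_peak: int = 4) -> GenomeSizeEstimate:
    """Estimate genome size from a k-mer spectrum by the coverage-peak method.

    The spectrum of a shotgun dataset shows an error spike at depth ~1 and a
    roughly Poisson-shaped peak at the sequencing depth; genome size is the
    total number of k-mer observations above the error region divided by the
    peak depth.  ``min_depth_for_peak`` excludes the error spike from peak
    detection and from the k-mer mass.

    Raises :class:`SpectrumError` if no local maximum exists at depth >=
    ``min_depth_for_peak`` (e.g. a monotone-decreasing error-only spectrum).
    """
    depths = np.asarray(hist.depths, dtype=np.int64)
    counts = np.asarray(hist.counts, dtype=np.float64)
    sel = depths >= min_depth_for_peak
    if not np.any(sel):
        raise SpectrumError(
            f"no spectrum entries at depth >= {min_depth_for_peak}"
        )
    d_sel = depths[sel]
    c_sel = counts[sel]
    i = int(np.argmax(c_sel))
    peak_depth = int(d_sel[i])
    # require a genuine local maximum: the left neighbour (if present in the
    # full spectrum) must not exceed the candidate peak
    j = int(np.searchsorted(depths, peak_depth))
    left_ok = j == 0 or counts[j - 1] <= counts[j]
    right_ok = j == depths.size - 1 or counts[j + 1] <= counts[j]
    if not (left_ok and right_ok):
        raise SpectrumError(
            "spectrum is monotone around depth "
            f"{peak_depth}; no coverage peak above min_depth_for_peak="
            f"{min_depth_for_peak} (error-dominated spectrum?)"
        )
    mass = float(np.sum(d_sel * c_sel))
    return GenomeSizeEstimate(
        genome_size=mass / peak_depth,
        peak_depth=peak_depth,
        total_kmers=int(mass),
    )
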