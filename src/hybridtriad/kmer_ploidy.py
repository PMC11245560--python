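"""Canonical k-mer spectra and diploid-signature ploidy calls.

A genome sequenced at depth D yields a 17-mer depth-frequency histogram whose
homozygous k-mers pile up near D while k-mers overlapping heterozygous sites
appear on only one haplotype and pile up near D/2: a diploid with appreciable
heterozygosity therefore shows a bimodal spectrum with peaks in a 2:1 position
ratio, a haploid a single peak.  Counting is exact (hash-based over 2-bit
integer codes) and canonical: each k-mer is identified with the lexicographic
minimum of itself and its reverse complement, so the spectrum is
strand-invariant.  k must be odd so no k-mer equals its own reverse
complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

_CODE = np.full(256, 254, dtype=np.uint8)  # 254: non-ACGT base, 255: read separator
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


class ParameterError(ValueError):
    pass


@dataclass
class KmerSpectrum:
    """Multiplicity -> distinct-k-mer-count histogram of canonical k-mers."""

    k: int
    histogram: dict  # multiplicity (int >= 1) -> count of distinct k-mers
    n_occurrences: int = 0   # total counted k-mer occurrences
    n_skipped: int = 0       # occurrences skipped for non-ACGT bases
    error_cutoff: int | None = None

    def dense(self, max_multiplicity: int | None = None) -> np.ndarray:
        """Histogram as a dense array indexed by multiplicity (index 0 unused)."""
        if not self.histogram:
            return np.zeros(1)
        mmax = max_multiplicity or max(self.histogram)
        out = np.zeros(mmax + 1)
        for m, c in self.histogram.items():
            if m <= mmax:
                out[m] = c
        return out

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tcount\n")
            for m in sorted(self.histogram):
                fh.write(f"{m}\t{self.histogram[m]}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, k: int = 17) -> "KmerSpectrum":
        hist = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                m, c = line.split()
                hist[int(m)] = int(c)
        return cls(k=k, histogram=hist,
                   n_occurrences=sum(m * c for m, c in hist.items()))


@dataclass
class Peak:
    position: float
    height: float
    prominence: float


@dataclass
class PloidyCall:
    peaks: list
    call: str  # haploid-like | diploid-like | indeterminate
    peak_position_ratio: float | None = None


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _iter_read_arrays(reads, chunk_bases: int = 20_000_000):
    """Yield uint8 code-array chunks (0-3 bases, 254 non-ACGT, 255 read
    separator); chunk boundaries always fall on read boundaries so windows
    never span chunks."""
    from .synthetic_data import ReadSet
    if isinstance(reads, ReadSet):
        m = reads.matrix
        rows_per_chunk = max(1, chunk_bases // (m.shape[1] + 1))
        for start in range(0, m.shape[0], rows_per_chunk):
            block = m[start:start + rows_per_chunk]
            codes = np.full((block.shape[0], block.shape[1] + 1), 255, dtype=np.uint8)
            codes[:, :-1] = _CODE[block]
            yield codes.ravel()
        return
    if isinstance(reads, (str, Path)):
        reads = _read_sequences(reads)
    buf = bytearray()
    for seq in reads:
        buf.extend(seq.encode())
        buf.append(0)  # placeholder separator byte, remapped below
        if len(buf) >= chunk_bases:
            codes = _CODE[np.frombuffer(bytes(buf), dtype=np.uint8)].copy()
            codes[np.frombuffer(bytes(buf), dtype=np.uint8) == 0] = 255
            yield codes
            buf = bytearray()
    if buf:
        raw = np.frombuffer(bytes(buf), dtype=np.uint8)
        codes = _CODE[raw].copy()
        codes[raw == 0] = 255
        yield codes


def _read_sequences(path) -> Iterable[str]:
    from Bio import SeqIO
    p = str(path)
    fmt = "fastq" if p.endswith(("fastq", "fq")) else "fasta"
    for rec in SeqIO.parse(p, fmt):
        yield str(rec.seq)


def _window_codes(codes: np.ndarray, k: int):
    """Canonical integer codes of all valid k-length windows in ``codes``.

    Returns ``(canonical codes of windows free of invalid bases and
    separators, count of within-read windows skipped for non-ACGT bases)``.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), 0
    invalid = codes >= 254
    sep = codes == 255
    ones = np.ones(k, dtype=np.int32)
    bad = np.convolve(invalid.astype(np.int32), ones, mode="valid") > 0
    crosses_sep = np.convolve(sep.astype(np.int32), ones, mode="valid") > 0
    n_skipped = int((bad & ~crosses_sep).sum())
    b = codes.astype(np.uint64)
    b[invalid] = 0
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | b[j:j + n]
        rev |= (np.uint64(3) - b[j:j + n]) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[~bad], n_skipped


def count_kmers(reads, k: int = 17) -> KmerSpectrum:
    """Count canonical k-mers of a read set (or FASTA/FASTQ path, or iterable
    of sequences) and histogram their multiplicities.

    k must be odd and >= 3 (even k admits reverse-complement palindromes,
    making the canonical form ambiguous).  Windows containing non-ACGT bases
    are skipped and counted.
    """
    if k < 3 or k % 2 == 0:
        raise ParameterError("k must be odd and >= 3")
    if k > 31:
        raise ParameterError("k > 31 exceeds the 2-bit integer code width")
    chunks = []
    n_skipped = 0
    for codes in _iter_read_arrays(reads):
        vals, skipped = _window_codes(codes, k)
        n_skipped += skipped
        chunks.append(vals)
    if not chunks:
        return KmerSpectrum(k=k, histogram={})
    allvals = np.concatenate(chunks)
    uniq, counts = np.unique(allvals, return_counts=True)
    mult, mcount = np.unique(counts, return_counts=True)
    hist = {int(m): int(c) for m, c in zip(mult, mcount)}
    return KmerSpectrum(k=k, histogram=hist, n_occurrences=int(allvals.size),
                        n_skipped=n_skipped)


def genome_kmer_set(sequences, k: int = 31, unique_only: bool = False) -> np.ndarray:
    """Sorted array of the distinct canonical k-mer codes of a genome.

    With ``unique_only`` k-mers occurring more than once in the genome are
    excluded (a repeat mask for containment scoring).
    """
    if isinstance(sequences, dict):
        sequences = list(sequences.values())
    chunks = []
    for codes in _iter_read_arrays(iter(sequences)):
        vals, _ = _window_codes(codes, k)
        chunks.append(vals)
    if not chunks:
        return np.empty(0, dtype=np.uint64)
    allvals = np.concatenate(chunks)
    uniq, counts = np.unique(allvals, return_counts=True)
    return uniq[counts == 1] if unique_only else uniq


# ---------------------------------------------------------------------------
# peaks and the ploidy call
# ---------------------------------------------------------------------------

def detect_peaks(spectrum: KmerSpectrum, smooth_window: int = 3,
                 min_prominence_fraction: float = 0.1,
                 error_cutoff: int | None = None) -> list[Peak]:
    """Local maxima of the (smoothed) spectrum beyond the error region.

    The histogram is smoothed by a centered moving average of width
    ``smooth_window`` (odd).  The low-multiplicity error region — up to the
    first local minimum, unless ``error_cutoff`` is given — is excluded.
    Peaks must exceed ``min_prominence_fraction`` x the global maximum of the
    retained region.  Positions are read on the smoothed histogram, heights
    on the raw one.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ParameterError("smooth_window must be a positive odd integer")
    if not spectrum.histogram:
        raise ParameterError("empty spectrum")
    raw = spectrum.dense()
    # smooth over multiplicities >= 1 with edge padding so the moving average
    # has no boundary dip (index 0 is structural, not data)
    kernel = np.ones(smooth_window) / smooth_window
    padded = np.pad(raw[1:], smooth_window // 2, mode="edge")
    smooth = np.concatenate([[0.0], np.convolve(padded, kernel, mode="valid")])

    cutoff = error_cutoff if error_cutoff is not None else spectrum.error_cutoff
    if cutoff is None:
        cutoff = 1
        while cutoff + 1 < len(smooth) and smooth[cutoff + 1] < smooth[cutoff]:
            cutoff += 1
    if cutoff >= len(smooth) - 1:
        warnings.warn("all spectrum mass lies below the error cutoff", stacklevel=2)
        return []
    region = smooth[cutoff:]
    if region.max() <= 0:
        warnings.warn("no spectrum mass beyond the error cutoff", stacklevel=2)
        return []
    idx, props = find_peaks(region, prominence=min_prominence_fraction * region.max())
    peaks = [Peak(position=float(cutoff + i),
                  height=float(raw[cutoff + i]),
                  prominence=float(p))
             for i, p in zip(idx, props["prominences"])]
    return sorted(peaks, key=lambda p: p.position)


def call_ploidy(peaks: Sequence[Peak], tolerance: float = 0.2) -> PloidyCall:
    """Diploid-like iff exactly two peaks whose position ratio is within
    ``tolerance`` of 2; haploid-like iff one peak; else indeterminate."""
    peaks = sorted(peaks, key=lambda p: p.position)
    if len(peaks) == 1:
        return PloidyCall(peaks=list(peaks), call="haploid-like")
    if len(peaks) == 2:
        ratio = peaks[1].position / peaks[0].position
        if 2 * (1 - tolerance) <= ratio <= 2 * (1 + tolerance):
            return PloidyCall(peaks=list(peaks), call="diploid-like",
                              peak_position_ratio=ratio)
        return PloidyCall(peaks=list(peaks), call="indeterminate",
                          peak_position_ratio=ratio)
    return PloidyCall(peaks=list(peaks), call="indeterminate")
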