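"""Canonical k-mer counting, spectrum peaks, and genome-size estimation.

The multiplicity histogram of canonical k-mers (k = 17 by default) from
whole-genome reads of a diploid shows a characteristic shape: an error spike
at multiplicity 1–2, a heterozygous peak at the per-haplotype k-mer depth c,
and a homozygous peak at 2c. Genome size follows from the classical
peak-depth method:

    haploid bp  = (total k-mers above the error cutoff) / hom_peak
    diploid bp  = (same numerator) / het_peak        (2x haploid if no het peak)

Counting is exact (hash of canonical 2-bit codes), strand-invariant, and
vectorised; k-mers containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy.signal import find_peaks

from .util import encode_seq


class NoPeakError(ValueError):
    """Raised when no spectrum peak rises above the error cutoff (coverage too low)."""


@dataclass
class KmerSpectrum:
    """Histogram of canonical k-mer multiplicities.

    ``multiplicities`` and ``counts`` are aligned arrays: ``counts[i]`` distinct
    canonical k-mers occur exactly ``multiplicities[i]`` times.
    """

    k: int
    multiplicities: np.ndarray
    counts: np.ndarray

    @property
    def total_kmers(self) -> int:
        """Total k-mers processed = sum(multiplicity x count)."""
        return int((self.multiplicities.astype(np.int64) * self.counts).sum())

    def dense(self) -> np.ndarray:
        """Histogram as a dense array indexed by multiplicity (index 0 unused)."""
        out = np.zeros(int(self.multiplicities.max()) + 1 if self.multiplicities.size else 1, dtype=np.int64)
        out[self.multiplicities] = self.counts
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("multiplicity\tcount\n")
            for m, c in zip(self.multiplicities, self.counts):
                fh.write(f"{m}\t{c}\n")


@dataclass
class PeakSet:
    """Detected spectrum peaks. ``het_peak`` is None for a homozygous genome."""

    error_cutoff: int
    hom_peak: int
    het_peak: int | None
    hom_peak_refined: float
    het_peak_refined: float | None


@dataclass
class GenomeSizeEstimate:
    haploid_bp: float
    diploid_bp: float
    peaks: PeakSet
    k: int
    unstable: bool = False


def _codes_from_input(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode_seq(seq)
    return np.asarray(seq, dtype=np.uint8)


def count_kmers(sequences, k: int = 17, batch_bases: int = 8_000_000) -> KmerSpectrum:
    """Count canonical k-mers over strings, code arrays, or a read matrix.

    k must be odd (a canonical form is ambiguous for palindromic even k) and
    within [3, 31] so a 2-bit code fits an int64. Windows containing N are
    skipped. Counting is canonical: a k-mer and its reverse complement pool
    into the lexicographically smaller code.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes palindromes canonically ambiguous)")
    if not 3 <= k <= 31:
        raise ValueError("k must lie in [3, 31]")

    fwd_pow = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rev_pow = 4 ** np.arange(k, dtype=np.int64)

    chunks: list[np.ndarray] = []

    def process(cat: np.ndarray) -> None:
        """Count canonical codes in one sentinel-joined block."""
        n = cat.size
        if n < k:
            return
        valid_base = cat < 4
        # a window is valid iff all k of its bases are valid
        bad = (~valid_base).astype(np.int32)
        cbad = np.concatenate([[0], np.cumsum(bad)])
        window_ok = (cbad[k:] - cbad[:-k]) == 0
        codes = np.zeros(n - k + 1, dtype=np.int64)
        rcodes = np.zeros(n - k + 1, dtype=np.int64)
        safe = np.where(valid_base, cat, 0).astype(np.int64)
        comp = 3 - safe
        for j in range(k):
            codes += safe[j : n - k + 1 + j] * fwd_pow[j]
            rcodes += comp[j : n - k + 1 + j] * rev_pow[j]
        canon = np.minimum(codes, rcodes)[window_ok]
        if canon.size:
            chunks.append(canon)

    if isinstance(sequences, np.ndarray) and sequences.ndim == 2:
        # read matrix: join rows with a sentinel column, chunked
        n_rows, row_len = sequences.shape
        rows_per = max(1, batch_bases // (row_len + 1))
        for i in range(0, n_rows, rows_per):
            chunk = sequences[i : i + rows_per]
            block = np.full((chunk.shape[0], row_len + 1), 4, dtype=np.uint8)
            block[:, :row_len] = chunk
            process(block.ravel())
    else:
        if isinstance(sequences, (str, np.ndarray)):
            sequences = [sequences]
        buf: list[np.ndarray] = []
        buf_len = 0
        sentinel = np.array([4], dtype=np.uint8)
        for seq in sequences:
            arr = _codes_from_input(seq)
            buf.append(arr)
            buf.append(sentinel)
            buf_len += arr.size + 1
            if buf_len >= batch_bases:
                process(np.concatenate(buf))
                buf, buf_len = [], 0
        if buf:
            process(np.concatenate(buf))

    if not chunks:
        return KmerSpectrum(k, np.array([], dtype=np.int64), np.array([], dtype=np.int64))
    allc = np.concatenate(chunks)
    del chunks
    _, mult = np.unique(allc, return_counts=True)
    multiplicities, counts = np.unique(mult, return_counts=True)
    return KmerSpectrum(k, multiplicities.astype(np.int64), counts.astype(np.int64))


def count_kmers_in_file(path, k: int = 17) -> KmerSpectrum:
    """Count canonical k-mers from a FASTA/FASTQ file (optionally gzipped)."""
    import gzip

    from Bio import SeqIO

    p = str(path)
    opener = gzip.open if p.endswith(".gz") else open
    stem = p[:-3] if p.endswith(".gz") else p
    fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    with opener(p, "rt") as fh:
        return count_kmers((str(rec.seq) for rec in SeqIO.parse(fh, fmt)), k=k)


def _refine(dense_sm: np.ndarray, m: int) -> float:
    """Sub-bin peak position: centroid over the peak bin and its neighbours."""
    lo, hi = max(1, m - 2), min(dense_sm.size - 1, m + 2)
    idx = np.arange(lo, hi + 1)
    w = dense_sm[lo : hi + 1].astype(float)
    return float((idx * w).sum() / w.sum()) if w.sum() > 0 else float(m)


def find_spectrum_peaks(
    spectrum: KmerSpectrum, smooth_window: int = 5, min_rel_height: float = 0.05
) -> PeakSet:
    """Locate the error cutoff and the (het, hom) or single peak.

    The dense histogram is smoothed with a centred moving average; the error
    cutoff is the first local minimum after multiplicity 1, and peaks are
    local maxima above the cutoff reaching at least ``min_rel_height`` of the
    tallest maximum (which suppresses the small bump of two-copy repeats at
    twice the main depth). Two surviving peaks whose depth ratio is ~2
    (within [1.6, 2.4]) are reported as (het, hom); otherwise the dominant
    maximum is the homozygous peak.
    """
    if spectrum.multiplicities.size == 0:
        raise NoPeakError("empty spectrum")
    dense = spectrum.dense().astype(float)
    if dense.size < 4:
        raise NoPeakError("spectrum too narrow for peak detection")
    w = max(1, int(smooth_window))
    kernel = np.ones(w) / w
    sm = np.convolve(dense, kernel, mode="same")

    # first local minimum after multiplicity 1 (error/signal trough)
    cutoff = None
    for m in range(2, sm.size - 1):
        if sm[m] <= sm[m - 1] and sm[m] <= sm[m + 1]:
            cutoff = m
            break
    if cutoff is None:
        raise NoPeakError("no local minimum after multiplicity 1: monotone spectrum")

    region = sm[cutoff:]
    peaks_idx, props = find_peaks(region, height=0)
    peaks_idx = peaks_idx + cutoff
    if peaks_idx.size == 0:
        raise NoPeakError("no peak above the error cutoff (coverage too low?)")
    heights = sm[peaks_idx]
    keep = heights >= min_rel_height * heights.max()
    peaks_idx, heights = peaks_idx[keep], heights[keep]
    # the two tallest surviving maxima, in multiplicity order
    top = peaks_idx[np.argsort(heights)[::-1][:2]]
    top.sort()
    if top.size == 2:
        lo_m, hi_m = int(top[0]), int(top[1])
        ratio = hi_m / lo_m
        if 1.6 <= ratio <= 2.4:
            return PeakSet(
                error_cutoff=cutoff,
                hom_peak=hi_m,
                het_peak=lo_m,
                hom_peak_refined=_refine(sm, hi_m),
                het_peak_refined=_refine(sm, lo_m),
            )
    hom = int(peaks_idx[np.argmax(heights)])
    return PeakSet(cutoff, hom, None, _refine(sm, hom), None)


def estimate_genome_size(spectrum: KmerSpectrum, peaks: PeakSet) -> GenomeSizeEstimate:
    """Peak-depth genome size: k-mers above the error cutoff over peak depth."""
    mask = spectrum.multiplicities > peaks.error_cutoff
    numer = float(
        (spectrum.multiplicities[mask].astype(np.int64) * spectrum.counts[mask]).sum()
    )
    unstable = peaks.hom_peak <= peaks.error_cutoff + 1
    haploid = numer / peaks.hom_peak_refined
    if peaks.het_peak_refined is not None:
        diploid = numer / peaks.het_peak_refined
    else:
        diploid = 2.0 * haploid
    return GenomeSizeEstimate(haploid, diploid, peaks, spectrum.k, unstable)
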