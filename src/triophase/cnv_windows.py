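"""Windowed log2 copy-ratio profiles between two read sets.

CNV-Seq-style comparison of a test sample (a parent) against a reference
sample (the F1 individual): reads are binned into fixed windows (1 Mb by
default) by their leftmost coordinate, counts are normalised by each sample's
genome-wide total, and the per-window statistic is

    log2( ((n_test + p) / N_test) / ((n_ref + p) / N_ref) )

with a symmetric Haldane pseudocount p = 0.5 keeping the ratio finite on empty
windows and the track exactly antisymmetric under sample exchange. Windows
beyond +-threshold (0.6 ~= a 1.5-fold change, by default) are flagged as gain
or loss. The original CNV-Seq sliding-window significance model is not
reproduced; the flag is a plain ratio cutoff.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd


def window_counts(
    placements_test: pd.DataFrame,
    placements_ref: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window read counts for both samples.

    Placements carry ``scaffold`` and 0-based ``start`` columns; each read
    lands in exactly one window. A start at or past the scaffold end is an
    error naming the record.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    rows = []
    counts = {}
    for name, df in (("test", placements_test), ("ref", placements_ref)):
        per = {}
        for scaf, grp in df.groupby("scaffold"):
            if scaf not in scaffold_lengths:
                raise KeyError(f"placement on unknown scaffold {scaf!r}")
            length = scaffold_lengths[scaf]
            starts = grp["start"].to_numpy()
            bad = (starts < 0) | (starts >= length)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"{name} placement at {scaf}:{int(starts[i])} outside scaffold of length {length}"
                )
            n_win = -(-length // window)
            per[scaf] = np.bincount(starts // window, minlength=n_win)
        counts[name] = per
    for scaf, length in scaffold_lengths.items():
        n_win = -(-length // window)
        ct = counts["test"].get(scaf, np.zeros(n_win, dtype=np.int64))
        cr = counts["ref"].get(scaf, np.zeros(n_win, dtype=np.int64))
        for w in range(n_win):
            rows.append(
                {
                    "scaffold": scaf,
                    "start": w * window,
                    "end": min(length, (w + 1) * window),
                    "count_test": int(ct[w]),
                    "count_ref": int(cr[w]),
                }
            )
    return pd.DataFrame(rows)


def log2_ratio_track(
    counts: pd.DataFrame,
    pseudocount: float = 0.5,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Library-size-normalised log2 ratios with gain/loss flags.

    Totals are taken over the whole frame per sample; both must be positive.
    ``flag`` is 'gain' at ratio >= +threshold, 'loss' at <= -threshold, else
    'neutral'.
    """
    n_test = int(counts["count_test"].sum())
    n_ref = int(counts["count_ref"].sum())
    if n_test == 0 or n_ref == 0:
        raise ValueError("both samples need at least one read for normalisation")
    out = counts.copy()
    ratio = ((out["count_test"] + pseudocount) / n_test) / (
        (out["count_ref"] + pseudocount) / n_ref
    )
    out["log2_ratio"] = np.log2(ratio)
    out["flag"] = np.select(
        [out["log2_ratio"] >= threshold, out["log2_ratio"] <= -threshold],
        ["gain", "loss"],
        default="neutral",
    )
    return out


def read_placements_tsv(path) -> pd.DataFrame:
    """3-column placement TSV: scaffold, start (0-based), [anything]."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["scaffold", "start"])
    return df


def read_placements_alignments(path) -> pd.DataFrame:
    """Leftmost coordinates of mapped reads from a SAM/BAM/CRAM file."""
    import pysam

    scafs, starts = [], []
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.reference_start is None:
                continue
            scafs.append(aln.reference_name)
            starts.append(aln.reference_start)
    return pd.DataFrame({"scaffold": scafs, "start": starts})
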