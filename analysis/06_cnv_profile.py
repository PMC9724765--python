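#!/usr/bin/env python
"""Windowed CNV log2-ratio profiling with injected truth events.

Places 30x read starts over a 10-Mb reference for a test and a reference
sample, injects one 1-Mb copy-number-4 gain and one 1-Mb homozygous deletion
into the test sample, and computes the 1-Mb log2 copy-ratio track (pseudocount
0.5, flag threshold 0.6). A separate same-genome null comparison over 50
windows measures the false-flag rate.
"""

import json
from pathlib import Path

from triophase.cnv_windows import log2_ratio_track, window_counts
from triophase.trio_sim import CnvEvent, inject_cnv, simulate_read_placements

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lengths = {"chrA": 10_000_000}
    base = {
        "test": simulate_read_placements(lengths, 30, 150, SEED),
        "ref": simulate_read_placements(lengths, 30, 150, SEED + 1),
    }
    events = [
        CnvEvent("chrA", 2_000_000, 3_000_000, 4, "test"),
        CnvEvent("chrA", 7_000_000, 8_000_000, 0, "test"),
    ]
    placed, truth = inject_cnv(base, events, lengths, seed=SEED + 2)
    counts = window_counts(placed["test"], placed["ref"], lengths, window=1_000_000)
    track = log2_ratio_track(counts, threshold=0.6)
    track.to_csv(RESULTS / "cnv_track.tsv", sep="\t", index=False)

    null_lengths = {"chrA": 25_000_000, "chrB": 25_000_000}
    null = log2_ratio_track(
        window_counts(
            simulate_read_placements(null_lengths, 30, 150, SEED + 3),
            simulate_read_placements(null_lengths, 30, 150, SEED + 4),
            null_lengths,
            window=1_000_000,
        ),
        threshold=0.6,
    )

    gain = track[track["start"] == 2_000_000].iloc[0]
    loss = track[track["start"] == 7_000_000].iloc[0]
    out = {
        "gain_window_log2": round(float(gain["log2_ratio"]), 3),
        "gain_flag": gain["flag"],
        "loss_window_log2": round(float(loss["log2_ratio"]), 3),
        "loss_flag": loss["flag"],
        "n_flagged_total": int((track["flag"] != "neutral").sum()),
        "null_windows": int(len(null)),
        "null_flagged_pct": round(float((null["flag"] != "neutral").mean() * 100), 3),
    }
    with open(RESULTS / "cnv_summary.json", "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
    for k, v in out.items():
        print(f"{k}: {v}")
    print("\nThe copy-4 gain reads close to log2 = +1 (a two-fold density step), the")
    print("deletion strongly negative, and the same-genome null comparison flags no")
    print("windows at the 0.6 threshold.")


if __name__ == "__main__":
    main()
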