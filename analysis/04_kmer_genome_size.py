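#!/usr/bin/env python
"""k-mer spectrum genome-size estimation on synthetic read sets.

Two experiments with canonical 17-mers:

* a homozygous 500-kb genome at 40x error-free reads — single spectrum peak,
  haploid size recovered by total-kmers/peak-depth;
* a diploid with 1.8% heterozygosity at 60x per haplotype with 1% read error
  — heterozygous and homozygous peaks at a ~2:1 depth ratio, giving both
  haploid and diploid size estimates (the spectrum shape reported for the
  hybrid grape F1, whose peaks at 111/225 gave 493.0/999.2 Mb).
"""

import json
from pathlib import Path

import numpy as np

from triophase.kmer_profile import count_kmers, estimate_genome_size, find_spectrum_peaks
from triophase.trio_sim import SimParams, simulate_reads_from_seqs, simulate_trio

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    out = {}

    rng = np.random.default_rng(SEED)
    genome = rng.integers(0, 4, 500_000, dtype=np.uint8)
    reads = simulate_reads_from_seqs([genome], 40, 150, 0.0, SEED)
    spectrum = count_kmers(reads.matrix, k=17)
    peaks = find_spectrum_peaks(spectrum)
    est = estimate_genome_size(spectrum, peaks)
    out["homozygous_500kb_40x"] = {
        "truth_bp": 500_000,
        "hom_peak": peaks.hom_peak,
        "haploid_estimate_bp": round(est.haploid_bp),
        "error_pct": round(100 * (est.haploid_bp / 500_000 - 1), 2),
    }

    diploid = simulate_trio(
        SimParams(ancestor_length=250_000, n_chromosomes=1, het_parent_a=0.0,
                  het_parent_b=0.0, parental_divergence=0.018,
                  scaffold_n50=250_000, seed=SEED)
    )
    seqs = [h for pair in diploid.f1_haplotypes for h in pair]
    reads = simulate_reads_from_seqs(seqs, 60, 150, 0.01, SEED + 1)
    spectrum = count_kmers(reads.matrix, k=17)
    peaks = find_spectrum_peaks(spectrum)
    est = estimate_genome_size(spectrum, peaks)
    out["diploid_250kb_60x_het1.8pct"] = {
        "truth_haploid_bp": 250_000,
        "het_peak": peaks.het_peak,
        "hom_peak": peaks.hom_peak,
        "peak_depth_ratio": round(peaks.hom_peak_refined / peaks.het_peak_refined, 3),
        "haploid_estimate_bp": round(est.haploid_bp),
        "diploid_estimate_bp": round(est.diploid_bp),
    }

    with open(RESULTS / "kmer_estimates.json", "w") as fh:
        json.dump(out, fh, indent=2)
        fh.write("\n")
    for name, d in out.items():
        print(f"{name}:")
        for k, v in d.items():
            print(f"  {k}: {v}")
    print("\nHaploid size recovered within a few percent; het/hom peak depth ratio ~2,")
    print("the diploid signature used to read heterozygosity off a k-mer spectrum.")


if __name__ == "__main__":
    main()
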