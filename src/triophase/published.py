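"""Published summary statistics of the 'Shine Muscat' assembly.

These printed values from the study of the interspecific table-grape hybrid
('Shine Muscat' = Akitsu-21 x 'Hakunan') are *inputs* here: the package
recomputes the derived quantities — category percentages, determined fraction,
conservation sums, gene-class partition — from them at run time, exercising
the same summary arithmetic used on synthetic data.
"""

#: VSMph_r1.0 phased assembly: scaffold count and total length (bp).
PHASED_SCAFFOLD_COUNT = 15_650
PHASED_TOTAL_LENGTH_BP = 1_004_717_561

#: Donor-category scaffold counts of the phased assembly.
DONOR_CATEGORY_COUNTS = {
    "donor_a_high": 183,  # Akitsu-21, high confidence
    "donor_a_low": 560,
    "donor_b_high": 516,  # 'Hakunan', high confidence
    "donor_b_low": 454,
    "undetermined": 690,
    "not_investigated": 13_247,
}

#: Donor-category total lengths (bp).
DONOR_CATEGORY_LENGTHS_BP = {
    "donor_a_high": 113_484_905,
    "donor_a_low": 240_237_600,
    "donor_b_high": 185_520_858,
    "donor_b_low": 216_512_960,
    "undetermined": 155_251_616,
    "not_investigated": 93_709_622,
}

#: Published percentages of the assembly total, for reference in reports.
DONOR_CATEGORY_PERCENTS = {
    "donor_a_total": 35.2,
    "donor_b_total": 40.0,
    "undetermined": 15.5,
    "not_investigated": 9.3,
    "determined_total": 75.2,
}

#: Merged gene set (Iso-Seq ORF + ab initio predictions) class counts.
GENE_CLASS_COUNTS = {"HC": 32_827, "LC": 22_705, "TE": 19_627}
GENE_TOTAL_MERGED = 75_159

#: k-mer spectrum of the F1 short reads (k = 17): heterozygous and homozygous
#: peak multiplicities and the derived genome-size estimates.
KMER_HET_PEAK = 111
KMER_HOM_PEAK = 225
HAPLOID_SIZE_MB = 493.0
DIPLOID_SIZE_MB = 999.2
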