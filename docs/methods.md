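# Methods

This note documents the models, parameter choices and numerical decisions
behind `triophase`. The package re-implements, as tested library code, the
trio-based QC analyses applied to a phased assembly of an interspecific
hybrid grape ('Shine Muscat' = Akitsu-21 × 'Hakunan'), exercised end-to-end
on a synthetic trio with known truth.

## 1. The synthetic trio (`trio_sim`)

### Mutation model

A shared ancestor sequence (i.i.d. uniform bases) is split into
`n_chromosomes` near-equal chromosomes. Each base independently becomes one
of four site classes (substitutions only; indels are out of scope because
every downstream rule is allele-class based):

| class | rate | parent A | parent B |
|---|---|---|---|
| fixed-in-A | `parental_divergence`/2 | derived/derived | anc/anc |
| fixed-in-B | `parental_divergence`/2 | anc/anc | derived/derived |
| het-in-A | `het_parent_a` | derived on hap 1 only | anc/anc |
| het-in-B | `het_parent_b` | anc/anc | derived on hap 1 only |

The F1 receives haplotype 1 of each parent, unrecombined: scaffold-level
donor assignment treats scaffolds as single-donor, so recombination
breakpoints would only blur the unit of analysis without changing the rules
(a v2 extension). Placing each parent's heterozygous derived alleles on the
*transmitted* haplotype emulates the structure of a wide hybrid whose F1
inherits the divergent (labruscana-like) haplotype. This choice is what makes
the published donor rules coherent: on its own scaffolds the hybrid parent is
heterozygous — never reference-homozygous at sites where its untransmitted
haplotype differs — while the other parent is alt-homozygous, matching the
reported absence of ref-homo calls for the hybrid parent on its own
haplotype sequences.

Defaults are the study conditions: 10 Mb over 5 chromosomes, heterozygosity
0.0185 (parent A) and 0.0132 (parent B) — the GenomeScope values reported for
the two parents — 1% fixed divergence, ~50 kb scaffold N50 (giving ≥ 200
scaffolds on 10 Mb), 30× depth, 150-bp reads. Realized heterozygosity is
binomial around the requested rate (±10% relative is many σ at ≥ 1 Mb).

### Scaffolds

Both F1 haplotypes are cut into scaffolds by exponential piece lengths with
mean `N50_target/1.678` (the length-weighted median of exponential pieces is
the median of a Gamma(2) variable, ≈ 1.678 μ), which lands the realized N50
within 2× of target. Pieces partition each haplotype exactly; each scaffold
carries its true donor. A target above the chromosome length degrades to one
scaffold per haplotype-chromosome (logged).

### Genotypes, depth, quality

A VCF record is emitted wherever at least one parent carries a non-reference
allele relative to the scaffold (both haplotype copies of every site appear,
once per phased scaffold). Noise knobs, all off by default in unit fixtures
and set to small realistic values in the demo pipeline:

- *miscalls*: each sample-site genotype is replaced by one of the other two
  allele classes with probability `miscall_rate`;
- *DP* ~ Poisson(depth) per sample; DP = 0 forces a missing call;
- *GQ*: N(70, 15) for true calls, N(35, 15) for miscalled ones, clipped to
  [0, 99] — GQ is stochastically lower for miscalls without being
  deterministically tied to the miscall rate (a hard coupling would push all
  GQ below the 20 floor at 5% miscalls and empty the filtered set);
- *spurious sites*: a fraction `noise_site_rate` of extra sites with QUAL
  drawn below the caller cap of 999; true sites carry QUAL = 999. The
  QUAL ≥ 999 filter is exactly the mechanism that removes them.

### Reads, placements, CNV truth, gene evidence

Sequenced reads have uniform start positions over the diploid (total bases ≈
depth × diploid length) and i.i.d. substitution errors. For windowed CNV
work the package simulates read *placements* (start coordinates only) — the
windowed statistic never looks at base content, and a 50-window null at 30×
would otherwise require ~1.5 Gbp of sequence. `inject_cnv` rescales placement
density inside an event by copy_number/2: Bernoulli thinning for losses, a
Poisson top-up for gains; copy number 2 is a byte-level no-op. Gene fixtures
place non-overlapping genes (0.5–5 kb) on scaffolds, draw evidence that
recovers the intended HC/LC/TE label by construction (default mix
0.437/0.302/0.261, the published class proportions), and emit a configurable
fraction of loci (default 0.3) in both prediction sources with jittered
coordinates and different ORF lengths so the merge step is exercised.

Determinism: one global seed fans out to stage seeds via a CRC-32 hash of the
stage name; identical parameters give byte-identical files.

## 2. Variant filter

A record passes iff QUAL ≥ 999 **and** every sample has DP ≥ 20 and GQ ≥ 20
**and** the missing-genotype fraction ≤ 0 (call rate 1). Decisions:

- "QUAL = 999" is implemented as ≥ 999: callers cap QUAL at 999, where
  equality and ≥ coincide, and ≥ is robust to dialects emitting `999.0`.
- vcftools `max-missing = 1` means *no missing genotypes allowed*; the
  parameter is exposed as `max_missing_fraction = 0` because the vcftools
  name inverts intuition.
- DP/GQ are per-sample FORMAT fields (site-level INFO/DP is ignored): the
  donor logic is per-parent. Records lacking DP or GQ fail and are counted.
- Multiallelic records are kept whole; the allele class is computed on the
  GT as a pair (`1/2` is heterozygous).

## 3. Donor assignment

Per scaffold and parent, allele-class fractions are taken over that parent's
non-missing calls (missingness is moot at the default call-rate-1 filter but
matters if relaxed). The rule sets (inclusive ≥, threshold 0.70, valid range
(0.5, 1] so two classes can never both qualify):

- parent A: het ≥ t ⟹ DonorA; alt ≥ t ⟹ DonorB;
- parent B: alt ≥ t ⟹ DonorA; ref ≥ t ⟹ DonorB.

Combination: equal donors ⟹ that donor, High; donor + undetermined ⟹ that
donor, Low; both undetermined ⟹ Undetermined. Contradictory donors — a case
the source rules never mention — resolve to Undetermined with an audit flag
rather than an invented tie-break, preserving the category partition.
Percentages are computed against the full assembly length (including
not-investigated scaffolds; with them the published percentages sum to 100)
and rounded half-up to one decimal, the printed precision. Scaffold lengths
come from the FASTA index; N bases count toward length. No minimum-variant
floor by default (none is stated); `min_variants` exists because one-variant
scaffolds trivially reach 100% ratios.

### Why determinations are partial at the default conditions

On a parent-A scaffold the expected discriminating fraction (parent B's
alt-homo) is (d + hA)/(d + hA + hB); symmetrically for B-scaffolds (parent
B's ref-homo). At hA = 0.0185, hB = 0.0132, d = 0.01 this is ≈ 0.683 — just
*below* the 0.70 rule — so determinations come from scaffolds whose realized
composition crosses the threshold, and every above-threshold call points at
the true donor (the wrong-direction classes sit at ≤ 0.56). This is the
honest behaviour of the rule set at these heterozygosities: the source study
itself determined only 75.2% of assembly length, with the hybrid parent
mostly at low confidence. At d ≳ 1.5% the expectation crosses 0.70 and
nearly every scaffold is determined (see `analysis/03_assign_donors.py`);
the hybrid parent's own het fraction hA/(d + hA + hB) can essentially never
reach 0.70, which is why its scaffolds are determined through the other
parent's evidence — at low confidence — throughout.

A consequence worth naming: the "swap the parent labels, calls swap" symmetry
does **not** hold for this rule set. Parent A's rules contain no ref-homo
clause, so a scaffold determined through parent B's ref-homo evidence becomes
undetermined (not swapped) after a label swap. The tests assert the symmetry
that does hold: a swap never yields the *opposite* donor, and the alt-homo
core rules swap exactly.

## 4. k-mer spectra and genome size

Counting is canonical (lexicographic minimum of a k-mer's 2-bit code and its
reverse complement's), exact, and vectorised; windows containing N are
skipped; k must be odd (palindrome ambiguity) and ≤ 31 (int64 codes). Peaks:
the dense histogram is smoothed with a centred moving average (window 5
multiplicities); the error cutoff is the first local minimum after
multiplicity 1; candidate peaks are local maxima above the cutoff reaching ≥
5% of the tallest (suppressing the two-copy-repeat bump at twice the main
depth); two peaks with depth ratio in [1.6, 2.4] are (het, hom). Peak
positions are refined to sub-bin precision by a 5-bin centroid: at 40× the
integer-bin discretisation alone is a 1–3% size error. Size:
`haploid = Σ_{m>cutoff} m·count(m) / hom_peak`; `diploid` divides by the het
peak (or doubles). Read-edge and error losses cancel between numerator and
peak depth; the residual bias on synthetic data is ~2%, within the 5%
recovery contract. The full GenomeScope mixture model (and its
heterozygosity estimation) is out of scope; only peak-depth sizing is
implemented.

## 5. Gene triage

Merging: genes from the two sources are "identical" when on the same scaffold
and strand with reciprocal span overlap ≥ 0.9 (the source does not define
identity; reciprocal overlap is the standard conservative choice, and is
configurable). The longer ORF wins; ties keep the transcript-evidence member
(empirical evidence outranks ab initio). Same-source overlaps are kept with a
warning. Classification: TE (transposon-associated best UniProtKB hit) takes
precedence over everything — TEs are excluded from the high-confidence set no
matter how expressed; then HC if *any* of TPM > 0.5 (strict), domain hit, or
a UniProtKB/NR/V. vinifera-12X hit (the conditions read as alternatives; an
AND reading would contradict the size of the published HC set, and a strict
`hc_mode="all"` is available for sensitivity analysis); else LC. The
similarity-search thresholds that produce the boolean flags (DIAMOND mapped
length and E-value cutoffs, etc.) belong to the upstream search tools; this
module consumes flags. Density: non-overlapping 1-Mb tiles ("sliding window"
with step = width, one value per region as published; step configurable);
cover ratio is union coverage over window length, final partial window
normalised by its real length.

## 6. CNV windows

Reads are binned by leftmost coordinate into fixed windows (1 Mb default);
counts are normalised by each sample's genome-wide total; the statistic is
`log2(((n_t+p)/N_t)/((n_r+p)/N_r))` with a symmetric Haldane pseudocount
p = 0.5, keeping empty windows finite and the track exactly antisymmetric
under sample exchange. Flags are a plain cutoff at ±0.6 (≈ 1.5-fold) — a
declared choice, not a published parameter; the original CNV-Seq
significance model is deliberately not reproduced, as the downstream
interpretation reads the log2 track directly. Note that library-size
normalisation makes a genome-wide uniform gain invisible by construction and
shifts event windows slightly (a 1-Mb copy-4 gain on a 10-Mb genome reads
log2 ≈ 0.86, not 1.0, unless balanced by a loss).

## 7. Problem sizes and what the tests show

The test and acceptance runs use a 10-Mb trio (donor recovery), 500-kb /
250-kb genomes at 40–60× (k-mer sizing), 10–50 Mb of placements (CNV), and
hundreds of genes — sizes chosen so the whole suite completes in minutes
while every statistical contract (binomial bands, Poisson nulls, threshold
crossings) is many σ away from its bound. The generator emulates allele-class
geometry, depth/quality noise and density changes, not read mapping,
alignment artefacts, repeat structure or indels: passing tests demonstrate
the correctness of the decision rules and estimators under their stated
models, not the behaviour of upstream callers on real data.

## Known limitations

- No recombination in F1 gametes; sub-scaffold donor mosaicism is invisible.
- The genotype model emits calls directly rather than simulating the
  mapping/calling pipeline (ploidy priors, mapping filters are unstated
  upstream anyway).
- Donor-rule behaviour near the 0.70 boundary is inherently stochastic at
  low variant counts; `min_variants` is the guard.
- Peak detection assumes a unimodal-per-component spectrum; heavily
  repetitive genomes would need a repeat-aware model.
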