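"""Synthetic parent/parent/F1 trio generator with known ground truth.

Emulates the data structure behind a phased interspecific-hybrid assembly: a
highly heterozygous hybrid parent (``A``, Akitsu-21-like), a less heterozygous
parent (``B``, 'Hakunan'-like) and an F1 whose two phased haplotypes each
descend intact from one parent (no recombination; scaffold-level donor
assignment treats scaffolds as single-donor). Every downstream stage — variant
filtering, donor assignment, k-mer profiling, CNV windows, gene triage — can be
exercised against the recorded truth without any external data.

Mutation model
--------------
Substitutions only, at four site classes drawn per base of a shared ancestor:

* fixed-in-A (rate ``parental_divergence/2``): both A haplotypes carry the
  derived allele, B is ancestral;
* fixed-in-B (rate ``parental_divergence/2``): the mirror image;
* het-in-A (rate ``het_parent_a``): the derived allele sits on A's haplotype 1
  only — the haplotype transmitted to the F1;
* het-in-B (rate ``het_parent_b``): likewise on B's haplotype 1.

Placing the parent-specific heterozygous alleles on the transmitted haplotype
mirrors the structure of a wide hybrid in which the F1 inherits the divergent
(*V. labruscana*-like) haplotype: on its own scaffolds the hybrid parent then
genotypes as heterozygous and never as reference-homozygous at sites where its
untransmitted haplotype differs, while the other parent is alt-homozygous —
exactly the allele-ratio geometry the scaffold donor rules key on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .util import decode_seq, derive_seed, n50, write_fasta, write_fastq

logger = logging.getLogger(__name__)

# site classes
FIXED_A, FIXED_B, HET_A, HET_B = 0, 1, 2, 3

#: genotype codes used in truth tables
GT_REF, GT_HET, GT_ALT = 0, 1, 2
_GT_STRINGS = {GT_REF: "0/0", GT_HET: "0/1", GT_ALT: "1/1"}

# exponential fragment lengths: the length-weighted median of Exp(mu) pieces
# is ~1.678*mu (median of a Gamma(2) variable), so mu = N50 / 1.678.
_EXP_N50_FACTOR = 1.678


@dataclass(frozen=True)
class SimParams:
    """Study-condition parameters for the synthetic trio.

    Defaults encode the conditions of the hybrid-grape trio: parental
    heterozygosities 1.85% and 1.32%, 1% fixed parental divergence, a 10-Mb
    genome fragmented to a ~50-kb scaffold N50 and 30x short reads.
    """

    ancestor_length: int = 10_000_000
    n_chromosomes: int = 5
    het_parent_a: float = 0.0185
    het_parent_b: float = 0.0132
    parental_divergence: float = 0.01
    scaffold_n50: int = 50_000
    read_depth: float = 30.0
    read_length: int = 150
    base_error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_parent_a", "het_parent_b", "parental_divergence", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.ancestor_length < 170:  # 10 k-mers of the default k=17
            raise ValueError("ancestor_length too short for downstream k-mer profiling")
        for name in ("n_chromosomes", "scaffold_n50", "read_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be strictly positive")
        if self.het_parent_a + self.het_parent_b + self.parental_divergence > 1.0:
            raise ValueError("total per-base mutation probability exceeds 1")


@dataclass
class TrioDataset:
    """A simulated trio plus every piece of recorded truth.

    ``sites`` has one row per polymorphic ancestor position with columns
    ``chrom`` (index), ``pos`` (0-based), ``klass`` (site class above) and
    ``derived``/``anc`` allele codes. ``scaffolds`` partitions both F1
    haplotypes into donor-labelled pieces (0-based half-open coordinates).
    """

    params: SimParams
    chrom_lengths: list[int]
    ancestor: list[np.ndarray]
    sites: pd.DataFrame
    f1_haplotypes: list[tuple[np.ndarray, np.ndarray]]
    scaffolds: pd.DataFrame = field(default_factory=pd.DataFrame)

    # ---- sequence access -------------------------------------------------
    def parent_haplotypes(self, role: str, chrom: int) -> tuple[np.ndarray, np.ndarray]:
        """Return the two haplotype arrays of parent ``role`` ('A' or 'B')."""
        if role not in ("A", "B"):
            raise ValueError("role must be 'A' or 'B'")
        fixed = FIXED_A if role == "A" else FIXED_B
        het = HET_A if role == "A" else HET_B
        s = self.sites[self.sites["chrom"] == chrom]
        hap1 = self.ancestor[chrom].copy()
        hap2 = self.ancestor[chrom].copy()
        fx = s[s["klass"] == fixed]
        ht = s[s["klass"] == het]
        for h in (hap1, hap2):
            h[fx["pos"].to_numpy()] = fx["derived"].to_numpy()
        hap1[ht["pos"].to_numpy()] = ht["derived"].to_numpy()
        return hap1, hap2

    def realized_heterozygosity(self, role: str) -> float:
        diff = total = 0
        for c in range(len(self.chrom_lengths)):
            h1, h2 = self.parent_haplotypes(role, c)
            diff += int((h1 != h2).sum())
            total += h1.size
        return diff / total

    def scaffold_sequence(self, row) -> np.ndarray:
        return self.f1_haplotypes[row.chrom][row.hap][row.start : row.end]

    def scaffold_lengths(self) -> dict[str, int]:
        return dict(zip(self.scaffolds["scaffold_id"], self.scaffolds["length"]))

    def diploid_length(self) -> int:
        return 2 * sum(self.chrom_lengths)

    # ---- FASTA emission --------------------------------------------------
    def write_f1_fasta(self, path) -> None:
        recs = []
        for c in range(len(self.chrom_lengths)):
            for h in (0, 1):
                recs.append((f"chr{c + 1:02d}_hap{h + 1}", decode_seq(self.f1_haplotypes[c][h])))
        write_fasta(path, recs)

    def write_scaffolds_fasta(self, path) -> None:
        recs = [
            (row.scaffold_id, decode_seq(self.scaffold_sequence(row)))
            for row in self.scaffolds.itertuples()
        ]
        write_fasta(path, recs)


def simulate_trio(params: SimParams) -> TrioDataset:
    """Simulate ancestor, parents and F1, then fragment the F1 into scaffolds.

    Identical ``params`` yield byte-identical outputs. Realized parental
    heterozygosity is binomial around the requested rate (within +-10%
    relative for genomes >= 1 Mb with overwhelming probability).
    """
    rng = np.random.default_rng(derive_seed(params.seed, "trio"))
    base = params.ancestor_length // params.n_chromosomes
    lengths = [base] * (params.n_chromosomes - 1)
    lengths.append(params.ancestor_length - base * (params.n_chromosomes - 1))

    rates = np.array(
        [
            params.parental_divergence / 2,
            params.parental_divergence / 2,
            params.het_parent_a,
            params.het_parent_b,
        ]
    )
    cuts = np.cumsum(rates)

    ancestor, site_frames, f1 = [], [], []
    for c, L in enumerate(lengths):
        anc = rng.integers(0, 4, size=L, dtype=np.uint8)
        u = rng.random(L)
        klass = np.searchsorted(cuts, u, side="right")  # 4 => monomorphic
        pos = np.flatnonzero(klass < 4)
        kl = klass[pos].astype(np.uint8)
        anc_alleles = anc[pos]
        derived = ((anc_alleles + rng.integers(1, 4, size=pos.size)) % 4).astype(np.uint8)
        site_frames.append(
            pd.DataFrame(
                {
                    "chrom": np.full(pos.size, c, dtype=np.int32),
                    "pos": pos.astype(np.int64),
                    "klass": kl,
                    "anc": anc_alleles,
                    "derived": derived,
                }
            )
        )
        hap_a = anc.copy()
        sel_a = (kl == FIXED_A) | (kl == HET_A)
        hap_a[pos[sel_a]] = derived[sel_a]
        hap_b = anc.copy()
        sel_b = (kl == FIXED_B) | (kl == HET_B)
        hap_b[pos[sel_b]] = derived[sel_b]
        ancestor.append(anc)
        f1.append((hap_a, hap_b))

    sites = pd.concat(site_frames, ignore_index=True)
    ds = TrioDataset(params, lengths, ancestor, sites, f1)
    ds.scaffolds = fragment_into_scaffolds(ds, params.scaffold_n50, derive_seed(params.seed, "scaffolds"))
    return ds


def fragment_into_scaffolds(dataset: TrioDataset, n50_target: int, seed: int) -> pd.DataFrame:
    """Cut both F1 haplotypes into scaffolds with exponential piece lengths.

    Pieces partition each haplotype exactly (no overlap, no loss); the realized
    N50 lands within 2x of ``n50_target``. A target longer than the longest
    chromosome degrades to one scaffold per haplotype-chromosome.
    """
    rng = np.random.default_rng(seed)
    if n50_target > max(dataset.chrom_lengths):
        logger.warning(
            "scaffold N50 target %d exceeds longest chromosome; one scaffold per haplotype-chromosome",
            n50_target,
        )
    mu = n50_target / _EXP_N50_FACTOR
    rows = []
    idx = 0
    for c, L in enumerate(dataset.chrom_lengths):
        for hap, donor in ((0, "A"), (1, "B")):
            start = 0
            while start < L:
                size = max(1, int(rng.exponential(mu))) if n50_target < L else L
                end = min(L, start + size)
                rows.append(
                    {
                        "scaffold_id": f"scf{idx:05d}",
                        "chrom": c,
                        "hap": hap,
                        "start": start,
                        "end": end,
                        "length": end - start,
                        "donor": donor,
                    }
                )
                idx += 1
                start = end
    return pd.DataFrame(rows)


def scaffold_n50(scaffolds: pd.DataFrame) -> int:
    return n50(scaffolds["length"])


# ---------------------------------------------------------------------------
# parental genotype simulation
# ---------------------------------------------------------------------------

# Truth genotype of (parent A, parent B) for each (scaffold hap, site class),
# relative to the scaffold sequence as reference. On an A-donated scaffold the
# reference carries A's transmitted alleles, so A is REF-homozygous at fixed
# differences and heterozygous at its own het sites, while B is ALT-homozygous
# wherever the reference carries a non-B allele.
_TRUTH_GT = {
    (0, FIXED_A): (GT_REF, GT_ALT),
    (0, FIXED_B): (GT_REF, GT_ALT),
    (0, HET_A): (GT_HET, GT_ALT),
    (0, HET_B): (GT_REF, GT_HET),
    (1, FIXED_A): (GT_ALT, GT_REF),
    (1, FIXED_B): (GT_ALT, GT_REF),
    (1, HET_A): (GT_HET, GT_REF),
    (1, HET_B): (GT_ALT, GT_HET),
}

# classes at which the scaffold reference carries the derived allele, per hap
_REF_IS_DERIVED = {0: (FIXED_A, HET_A), 1: (FIXED_B, HET_B)}


@dataclass
class GenotypeSim:
    """Emitted two-sample genotype table plus the noise-free truth."""

    table: pd.DataFrame  # one row per emitted VCF record
    truth: pd.DataFrame  # scaffold_id, pos (0-based), klass, gt_a, gt_b
    sample_a: str
    sample_b: str


def simulate_parental_genotypes(
    dataset: TrioDataset,
    depth: float = 30.0,
    miscall_rate: float = 0.0,
    missing_rate: float = 0.0,
    noise_site_rate: float = 0.0,
    seed: int = 0,
    sample_a: str = "parent_a",
    sample_b: str = "parent_b",
) -> GenotypeSim:
    """Genotype both parents against every scaffold of the phased F1.

    A record is emitted wherever at least one parent carries a non-reference
    allele. Noise: genotypes are miscalled (replaced by one of the two other
    allele classes) with ``miscall_rate``; DP ~ Poisson(depth) per sample; GQ
    is drawn lower for miscalled genotypes; genotypes go missing at
    ``missing_rate`` or when DP = 0; ``noise_site_rate`` adds spurious sites
    with QUAL < 999 (true sites carry the caller's QUAL cap of 999).
    """
    for name, v in (("miscall", miscall_rate), ("missing", missing_rate), ("noise_site", noise_site_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} rate outside [0, 1]")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(derive_seed(seed, "genotypes"))
    scaffolds = dataset.scaffolds

    frames = []
    for hap in (0, 1):
        sc = scaffolds[scaffolds["hap"] == hap]
        sites = dataset.sites
        for chrom, group in sc.groupby("chrom"):
            s = sites[sites["chrom"] == chrom]
            if s.empty:
                continue
            bounds = group["start"].to_numpy()
            which = np.searchsorted(bounds, s["pos"].to_numpy(), side="right") - 1
            sub = pd.DataFrame(
                {
                    "scaffold_id": group["scaffold_id"].to_numpy()[which],
                    "pos": s["pos"].to_numpy() - group["start"].to_numpy()[which],
                    "klass": s["klass"].to_numpy(),
                    "anc": s["anc"].to_numpy(),
                    "derived": s["derived"].to_numpy(),
                }
            )
            ref_derived = np.isin(sub["klass"], _REF_IS_DERIVED[hap])
            sub["ref"] = np.where(ref_derived, sub["derived"], sub["anc"]).astype(np.uint8)
            sub["alt"] = np.where(ref_derived, sub["anc"], sub["derived"]).astype(np.uint8)
            gt = np.array([_TRUTH_GT[(hap, k)] for k in sub["klass"]], dtype=np.int8)
            sub["gt_a"], sub["gt_b"] = gt[:, 0], gt[:, 1]
            frames.append(sub)

    truth = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scaffold_id", "pos", "klass", "anc", "derived", "ref", "alt", "gt_a", "gt_b"]
    )

    table = truth.copy()
    n = len(table)
    table["qual"] = 999
    for s in ("a", "b"):
        true_gt = table[f"gt_{s}"].to_numpy(dtype=np.int8)
        miscalled = rng.random(n) < miscall_rate
        shift = rng.integers(1, 3, size=n)
        called = np.where(miscalled, (true_gt + shift) % 3, true_gt).astype(np.int8)
        dp = rng.poisson(depth, size=n)
        gq = np.where(
            miscalled,
            rng.normal(35.0, 15.0, size=n),
            rng.normal(70.0, 15.0, size=n),
        )
        gq = np.clip(np.rint(gq), 0, 99).astype(np.int16)
        missing = (rng.random(n) < missing_rate) | (dp == 0)
        table[f"call_{s}"] = called
        table[f"dp_{s}"] = dp
        table[f"gq_{s}"] = gq
        table[f"missing_{s}"] = missing

    n_noise = int(round(noise_site_rate * n))
    if n_noise:
        lens = scaffolds["length"].to_numpy()
        pick = rng.choice(len(scaffolds), size=n_noise, p=lens / lens.sum())
        pos = (rng.random(n_noise) * lens[pick]).astype(np.int64)
        ref = rng.integers(0, 4, size=n_noise, dtype=np.uint8)
        alt = ((ref + rng.integers(1, 4, size=n_noise)) % 4).astype(np.uint8)
        noise = pd.DataFrame(
            {
                "scaffold_id": scaffolds["scaffold_id"].to_numpy()[pick],
                "pos": pos,
                "klass": -1,
                "anc": ref,
                "derived": alt,
                "ref": ref,
                "alt": alt,
                "gt_a": -1,
                "gt_b": -1,
                "qual": rng.integers(30, 999, size=n_noise),
            }
        )
        for s in ("a", "b"):
            noise[f"call_{s}"] = rng.integers(0, 3, size=n_noise).astype(np.int8)
            noise[f"dp_{s}"] = rng.poisson(depth, size=n_noise)
            noise[f"gq_{s}"] = np.clip(
                np.rint(rng.normal(70.0, 15.0, size=n_noise)), 0, 99
            ).astype(np.int16)
            noise[f"missing_{s}"] = noise[f"dp_{s}"] == 0
        table = pd.concat([table, noise], ignore_index=True)

    order = {sid: i for i, sid in enumerate(scaffolds["scaffold_id"])}
    table = table.sort_values(
        ["scaffold_id", "pos"], key=lambda col: col.map(order) if col.name == "scaffold_id" else col
    ).reset_index(drop=True)
    return GenotypeSim(table, truth, sample_a, sample_b)


def write_genotypes_vcf(sim: GenotypeSim, scaffold_lengths: Mapping[str, int], path) -> None:
    """Emit the simulated genotype table as a two-sample VCF v4.2 (1-based)."""
    bases = "ACGT"
    lines = [
        "##fileformat=VCFv4.2",
        "##source=triophase-trio-sim",
    ]
    for sid, length in scaffold_lengths.items():
        lines.append(f"##contig=<ID={sid},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sim.sample_a}\t{sim.sample_b}",
    ]
    t = sim.table
    cols = [
        t["scaffold_id"].to_numpy(),
        t["pos"].to_numpy() + 1,
        t["ref"].to_numpy(),
        t["alt"].to_numpy(),
        t["qual"].to_numpy(),
    ]
    sample_cols = {}
    for s in ("a", "b"):
        gts = np.where(
            t[f"missing_{s}"].to_numpy(),
            "./.",
            pd.Series(t[f"call_{s}"]).map(_GT_STRINGS).to_numpy(),
        )
        sample_cols[s] = (gts, t[f"dp_{s}"].to_numpy(), t[f"gq_{s}"].to_numpy())
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        out = []
        ga, gb = sample_cols["a"], sample_cols["b"]
        for i in range(len(t)):
            out.append(
                f"{cols[0][i]}\t{cols[1][i]}\t.\t{bases[cols[2][i]]}\t{bases[cols[3][i]]}"
                f"\t{cols[4][i]}\t.\t.\tGT:DP:GQ"
                f"\t{ga[0][i]}:{ga[1][i]}:{ga[2][i]}\t{gb[0][i]}:{gb[1][i]}:{gb[2][i]}"
            )
        fh.write("\n".join(out) + ("\n" if out else ""))


# ---------------------------------------------------------------------------
# sequencing reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSet:
    """Simulated single-end reads held as a (n_reads, read_length) code matrix."""

    matrix: np.ndarray
    source_seq: np.ndarray  # index of the originating sequence
    start: np.ndarray  # 0-based start on that sequence

    def sequences(self) -> list[str]:
        return [decode_seq(row) for row in self.matrix]

    def total_bases(self) -> int:
        return int(self.matrix.size)

    def to_fastq(self, path) -> None:
        names = [f"read{i}" for i in range(self.matrix.shape[0])]
        write_fastq(path, names, self.sequences())


def simulate_reads_from_seqs(
    seqs: Sequence[np.ndarray],
    depth: float,
    read_length: int,
    error_rate: float,
    seed: int,
) -> ReadSet:
    """Uniform random-start reads over a set of sequences.

    Total emitted bases ~= depth x total sequence length (exact up to one
    read's rounding); per-base substitution errors at ``error_rate``.
    """
    lens = np.array([s.size for s in seqs], dtype=np.int64)
    if (lens < read_length).any():
        raise ValueError("read_length exceeds a template sequence length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * lens.sum() / read_length))
    starts_per_seq = lens - read_length + 1
    cum = np.cumsum(starts_per_seq)
    flat = rng.integers(0, cum[-1], size=n_reads)
    seq_idx = np.searchsorted(cum, flat, side="right")
    start = flat - (cum[seq_idx] - starts_per_seq[seq_idx])
    offs = np.arange(read_length)
    mat = np.empty((n_reads, read_length), dtype=np.uint8)
    for i, s in enumerate(seqs):
        sel = seq_idx == i
        if sel.any():
            mat[sel] = s[start[sel, None] + offs]
    if error_rate > 0:
        err = rng.random(mat.shape) < error_rate
        mat[err] = (mat[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
    return ReadSet(mat, seq_idx, start)


def simulate_reads(
    dataset: TrioDataset,
    depth: float | None = None,
    read_length: int | None = None,
    error_rate: float | None = None,
    seed: int | None = None,
) -> ReadSet:
    """Reads over the diploid F1 (both haplotypes of every chromosome)."""
    p = dataset.params
    seqs = [h for pair in dataset.f1_haplotypes for h in pair]
    return simulate_reads_from_seqs(
        seqs,
        p.read_depth if depth is None else depth,
        p.read_length if read_length is None else read_length,
        p.base_error_rate if error_rate is None else error_rate,
        derive_seed(p.seed if seed is None else seed, "reads"),
    )


# ---------------------------------------------------------------------------
# read placements and CNV injection
# ---------------------------------------------------------------------------


def simulate_read_placements(
    scaffold_lengths: Mapping[str, int],
    depth: float,
    read_length: int,
    seed: int,
) -> pd.DataFrame:
    """Uniform read start positions (no sequence) for windowed counting."""
    ids = list(scaffold_lengths)
    lens = np.array([scaffold_lengths[i] for i in ids], dtype=np.int64)
    if (lens < read_length).any():
        raise ValueError("read_length exceeds a scaffold length")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * lens.sum() / read_length))
    starts_per = lens - read_length + 1
    cum = np.cumsum(starts_per)
    flat = rng.integers(0, cum[-1], size=n_reads)
    idx = np.searchsorted(cum, flat, side="right")
    start = flat - (cum[idx] - starts_per[idx])
    return pd.DataFrame({"scaffold": np.array(ids, dtype=object)[idx], "start": start})


@dataclass(frozen=True)
class CnvEvent:
    scaffold: str
    start: int
    end: int
    copy_number: float
    carrier: str


def inject_cnv(
    placements: Mapping[str, pd.DataFrame],
    events: Iterable[CnvEvent],
    scaffold_lengths: Mapping[str, int],
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Rescale read density inside event regions of the carrier sample.

    Density over an event is scaled by copy_number/2 (thinning for losses,
    Poisson top-up for gains); copy number 2 leaves the sample untouched,
    byte for byte. Overlapping events on one carrier are rejected.
    """
    events = list(events)
    by_carrier: dict[str, list[CnvEvent]] = {}
    for ev in events:
        if ev.copy_number < 0:
            raise ValueError("copy_number must be >= 0")
        if ev.scaffold not in scaffold_lengths:
            raise ValueError(f"event on unknown scaffold {ev.scaffold!r}")
        if not (0 <= ev.start < ev.end <= scaffold_lengths[ev.scaffold]):
            raise ValueError(f"event {ev} outside scaffold bounds")
        if ev.carrier not in placements:
            raise ValueError(f"carrier {ev.carrier!r} has no placements")
        by_carrier.setdefault(ev.carrier, []).append(ev)
    for carrier, evs in by_carrier.items():
        per_scaf: dict[str, list[CnvEvent]] = {}
        for ev in evs:
            per_scaf.setdefault(ev.scaffold, []).append(ev)
        for scaf, group in per_scaf.items():
            group.sort(key=lambda e: e.start)
            for a, b in zip(group, group[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping events on carrier {carrier!r}, scaffold {scaf!r}")

    rng = np.random.default_rng(seed)
    out = {name: df for name, df in placements.items()}
    for carrier, evs in by_carrier.items():
        df = out[carrier]
        keep = np.ones(len(df), dtype=bool)
        extra_frames = []
        scaf_col = df["scaffold"].to_numpy()
        start_col = df["start"].to_numpy()
        for ev in evs:
            if ev.copy_number == 2:
                continue
            in_ev = (scaf_col == ev.scaffold) & (start_col >= ev.start) & (start_col < ev.end)
            n_in = int(in_ev.sum())
            factor = ev.copy_number / 2.0
            if factor < 1.0:
                keep[in_ev] &= rng.random(n_in) < factor
            elif n_in:
                n_extra = rng.poisson(n_in * (factor - 1.0))
                if n_extra:
                    extra_frames.append(
                        pd.DataFrame(
                            {
                                "scaffold": ev.scaffold,
                                "start": rng.integers(ev.start, ev.end, size=n_extra),
                            }
                        )
                    )
        if extra_frames or not keep.all():
            out[carrier] = pd.concat([df[keep], *extra_frames], ignore_index=True)
    truth = pd.DataFrame([vars(ev) for ev in events]) if events else pd.DataFrame(
        columns=["scaffold", "start", "end", "copy_number", "carrier"]
    )
    return out, truth


# ---------------------------------------------------------------------------
# gene-evidence fixtures
# ---------------------------------------------------------------------------

#: HC/LC/TE mix of the published merged gene set (32,827 / 22,705 / 19,627).
DEFAULT_CLASS_MIX = (0.437, 0.302, 0.261)


@dataclass
class GeneSim:
    """Two prediction sets with evidence and intended class labels."""

    iso: pd.DataFrame
    ab_initio: pd.DataFrame
    evidence: pd.DataFrame
    truth: pd.DataFrame  # locus_id, label


def simulate_gene_evidence(
    scaffold_lengths: Mapping[str, int],
    n_genes: int,
    class_mix: tuple[float, float, float] = DEFAULT_CLASS_MIX,
    duplicated_fraction: float = 0.3,
    seed: int = 0,
) -> GeneSim:
    """Place genes on scaffolds and draw evidence recovering the intended class.

    ``class_mix`` gives the HC/LC/TE proportions; a ``duplicated_fraction`` of
    loci is predicted by both sources (jittered coordinates, different ORF
    lengths) so the merge step has real work to do.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.min() < 0 or abs(mix.sum() - 1.0) > 1e-6:
        raise ValueError("class_mix must be non-negative and sum to 1")
    rng = np.random.default_rng(derive_seed(seed, "genes"))

    ids = list(scaffold_lengths)
    lens = np.array([scaffold_lengths[i] for i in ids], dtype=np.int64)
    order = np.argsort(lens)[::-1]

    loci = []
    i = 0
    while len(loci) < n_genes and i < len(ids):
        scaf = ids[order[i]]
        L = int(lens[order[i]])
        cursor = int(rng.integers(0, 200)) if L > 200 else 0
        while len(loci) < n_genes:
            glen = int(rng.integers(500, 5001))
            if cursor + glen + 1 >= L:
                break
            loci.append((scaf, cursor, cursor + glen))
            cursor += glen + int(rng.integers(200, 2001))
        i += 1
    if len(loci) < n_genes:
        raise ValueError("scaffolds too short to place the requested number of genes")

    labels = rng.choice(np.array(["HC", "LC", "TE"]), size=n_genes, p=mix)
    dup = rng.random(n_genes) < duplicated_fraction
    src = rng.choice(np.array(["isoseq_orf", "ab_initio"]), size=n_genes)

    iso_rows, ab_rows, ev_rows, truth_rows = [], [], [], []
    for g in range(n_genes):
        scaf, start, end = loci[g]
        locus = f"g{g + 1:06d}"
        strand = "+" if rng.random() < 0.5 else "-"
        orf = int(rng.integers(300, min(3000, end - start) + 1))
        members = []
        if dup[g]:
            orf2 = orf + int(rng.integers(3, 300)) * (1 if rng.random() < 0.5 else -1)
            orf2 = max(150, orf2)
            jit = int(rng.integers(0, 21))
            members.append((f"{locus}.iso", "isoseq_orf", start, end, orf))
            members.append((f"{locus}.ab", "ab_initio", max(0, start - jit), end - jit, orf2))
        else:
            suffix = ".iso" if src[g] == "isoseq_orf" else ".ab"
            members.append((f"{locus}{suffix}", src[g], start, end, orf))
        label = labels[g]
        for gid, source, s0, e0, olen in members:
            row = {
                "gene_id": gid,
                "scaffold": scaf,
                "start": s0 + 1,  # GFF3 1-based inclusive
                "end": e0,
                "strand": strand,
                "orf_length": olen,
                "source": source,
            }
            (iso_rows if source == "isoseq_orf" else ab_rows).append(row)
            tpm = float(rng.exponential(5.0))
            flags = rng.random(4) < 0.5
            if label == "TE":
                ev = dict(tpm=tpm, has_domain=bool(flags[0]), hit_uniprot=True,
                          hit_nr=bool(flags[1]), hit_vv12x=bool(flags[2]), uniprot_te_flag=True)
            elif label == "HC":
                ev = dict(tpm=tpm, has_domain=bool(flags[0]), hit_uniprot=bool(flags[1]),
                          hit_nr=bool(flags[2]), hit_vv12x=bool(flags[3]), uniprot_te_flag=False)
                if tpm <= 0.5 and not any(ev[k] for k in ("has_domain", "hit_uniprot", "hit_nr", "hit_vv12x")):
                    ev["has_domain"] = True
            else:  # LC: no qualifying evidence at all
                ev = dict(tpm=float(rng.uniform(0.0, 0.5)), has_domain=False, hit_uniprot=False,
                          hit_nr=False, hit_vv12x=False, uniprot_te_flag=False)
            ev_rows.append({"gene_id": gid, **ev})
            truth_rows.append({"gene_id": gid, "locus_id": locus, "label": label})

    cols = ["gene_id", "scaffold", "start", "end", "strand", "orf_length", "source"]
    iso = pd.DataFrame(iso_rows, columns=cols).sort_values(["scaffold", "start"]).reset_index(drop=True)
    ab = pd.DataFrame(ab_rows, columns=cols).sort_values(["scaffold", "start"]).reset_index(drop=True)
    return GeneSim(iso, ab, pd.DataFrame(ev_rows), pd.DataFrame(truth_rows))
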