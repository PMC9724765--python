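"""End-to-end synthetic pipeline: simulate -> filter -> donor -> k-mer -> genes -> CNV.

A single :class:`RunConfig` (YAML-serialisable) drives every stage; one global
seed fans out to per-stage seeds through a stage-name hash, so each stage is
independently reproducible and a rerun with the same config regenerates every
output byte for byte. Every threshold actually applied is echoed into the run
report.

The default configuration runs a demonstration-scale trio (1 Mb over two
chromosomes); the full study-condition genome lives in the
:class:`~triophase.trio_sim.SimParams` defaults and is exercised by the
analysis drivers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import donor_assign, gene_triage, kmer_profile, trio_sim
from .cnv_windows import log2_ratio_track, window_counts
from .trio_sim import CnvEvent, SimParams
from .util import derive_seed
from .variant_filter import FilterThresholds, filter_vcf_file, read_vcf


@dataclass
class GenotypeParams:
    depth: float = 30.0
    miscall_rate: float = 0.002
    missing_rate: float = 0.001
    noise_site_rate: float = 0.02


@dataclass
class DonorParams:
    threshold: float = 0.70
    min_variants: int = 0
    sample_a: str = "parent_a"
    sample_b: str = "parent_b"


@dataclass
class KmerParams:
    k: int = 17
    depth: float = 20.0
    read_length: int = 150
    error_rate: float = 0.002


@dataclass
class GeneParams:
    n_genes: int = 300
    class_mix: tuple[float, float, float] = trio_sim.DEFAULT_CLASS_MIX
    duplicated_fraction: float = 0.3
    density_window: int = 1_000_000


@dataclass
class CnvParams:
    window: int = 100_000
    depth: float = 30.0
    read_length: int = 150
    pseudocount: float = 0.5
    threshold: float = 0.6
    events: list[CnvEvent] = field(
        default_factory=lambda: [
            CnvEvent("chr01", 200_000, 300_000, 4, "parent_a"),
            CnvEvent("chr02", 100_000, 200_000, 0, "parent_b"),
        ]
    )


def _demo_sim() -> SimParams:
    return SimParams(ancestor_length=1_000_000, n_chromosomes=2, scaffold_n50=20_000)


@dataclass
class RunConfig:
    seed: int = 0
    sim: SimParams = field(default_factory=_demo_sim)
    genotype: GenotypeParams = field(default_factory=GenotypeParams)
    filter: FilterThresholds = field(default_factory=FilterThresholds)
    donor: DonorParams = field(default_factory=DonorParams)
    kmer: KmerParams = field(default_factory=KmerParams)
    genes: GeneParams = field(default_factory=GeneParams)
    cnv: CnvParams = field(default_factory=CnvParams)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kw = {}
        sections = {
            "sim": SimParams,
            "genotype": GenotypeParams,
            "filter": FilterThresholds,
            "donor": DonorParams,
            "kmer": KmerParams,
            "genes": GeneParams,
            "cnv": CnvParams,
        }
        for key, typ in sections.items():
            if key in raw:
                sub = dict(raw[key])
                if key == "genes" and "class_mix" in sub:
                    sub["class_mix"] = tuple(sub["class_mix"])
                if key == "cnv" and "events" in sub:
                    sub["events"] = [CnvEvent(**ev) for ev in sub["events"]]
                kw[key] = typ(**sub)
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        return cls(**kw)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input fingerprint."""


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages into ``outdir``; return (and write) the run report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "thresholds": {
        "filter": dataclasses.asdict(config.filter),
        "donor_threshold": config.donor.threshold,
        "donor_min_variants": config.donor.min_variants,
        "cnv_flag_threshold": config.cnv.threshold,
        "cnv_pseudocount": config.cnv.pseudocount,
        "gene_tpm_min": gene_triage.TPM_MIN,
    }}
    config.to_yaml(out / "config.yaml")

    stage = "simulate"
    try:
        sim_params = dataclasses.replace(config.sim, seed=derive_seed(config.seed, "sim"))
        ds = trio_sim.simulate_trio(sim_params)
        ds.write_f1_fasta(out / "f1_haplotypes.fasta")
        ds.write_scaffolds_fasta(out / "scaffolds.fasta")
        ds.scaffolds.to_csv(out / "scaffold_truth.tsv", sep="\t", index=False)
        report[stage] = {
            "n_scaffolds": int(len(ds.scaffolds)),
            "scaffold_n50": trio_sim.scaffold_n50(ds.scaffolds),
            "genome_haploid_bp": int(sum(ds.chrom_lengths)),
            "het_parent_a_realized": ds.realized_heterozygosity("A"),
            "het_parent_b_realized": ds.realized_heterozygosity("B"),
        }

        stage = "genotypes"
        gsim = trio_sim.simulate_parental_genotypes(
            ds,
            depth=config.genotype.depth,
            miscall_rate=config.genotype.miscall_rate,
            missing_rate=config.genotype.missing_rate,
            noise_site_rate=config.genotype.noise_site_rate,
            seed=derive_seed(config.seed, "genotypes"),
            sample_a=config.donor.sample_a,
            sample_b=config.donor.sample_b,
        )
        lengths = ds.scaffold_lengths()
        trio_sim.write_genotypes_vcf(gsim, lengths, out / "genotypes.vcf")
        report[stage] = {"n_sites_emitted": int(len(gsim.table)),
                         "n_sites_true": int(len(gsim.truth))}

        stage = "filter"
        stats = filter_vcf_file(out / "genotypes.vcf", out / "filtered.vcf", config.filter)
        report[stage] = stats.as_dict()

        stage = "donor"
        ratios = donor_assign.tabulate_allele_ratios(
            read_vcf(out / "filtered.vcf"), lengths, config.donor.sample_a, config.donor.sample_b
        )
        calls = donor_assign.assign_donors(ratios, config.donor.threshold, config.donor.min_variants)
        calls.to_csv(out / "donor_calls.tsv", sep="\t", index=False)
        summary = donor_assign.summarize_donors(calls)
        summary.to_csv(out / "donor_summary.tsv", sep="\t", index=False)
        truth_map = dict(zip(ds.scaffolds["scaffold_id"], ds.scaffolds["donor"]))
        ev = donor_assign.evaluate_against_truth(calls, truth_map)
        report[stage] = {
            "summary": summary.to_dict(orient="records"),
            "n_determined": ev.n_determined,
            "accuracy_determined": ev.accuracy_determined,
        }

        stage = "kmer"
        reads = trio_sim.simulate_reads(
            ds,
            depth=config.kmer.depth,
            read_length=config.kmer.read_length,
            error_rate=config.kmer.error_rate,
            seed=derive_seed(config.seed, "reads"),
        )
        spectrum = kmer_profile.count_kmers(reads.matrix, k=config.kmer.k)
        spectrum.to_tsv(out / "kmer_spectrum.tsv")
        try:
            peaks = kmer_profile.find_spectrum_peaks(spectrum)
            est = kmer_profile.estimate_genome_size(spectrum, peaks)
            report[stage] = {
                "error_cutoff": peaks.error_cutoff,
                "het_peak": peaks.het_peak,
                "hom_peak": peaks.hom_peak,
                "haploid_bp": est.haploid_bp,
                "diploid_bp": est.diploid_bp,
                "true_haploid_bp": int(sum(ds.chrom_lengths)),
            }
        except kmer_profile.NoPeakError as exc:
            report[stage] = {"error": str(exc)}

        stage = "genes"
        gene_sim = trio_sim.simulate_gene_evidence(
            lengths,
            n_genes=config.genes.n_genes,
            class_mix=config.genes.class_mix,
            duplicated_fraction=config.genes.duplicated_fraction,
            seed=derive_seed(config.seed, "genes"),
        )
        merged = gene_triage.merge_predictions(gene_sim.iso, gene_sim.ab_initio)
        ev_indexed = gene_sim.evidence.set_index("gene_id")
        labels = gene_triage.classify_genes(ev_indexed.loc[merged["gene_id"]])
        labels.index = merged["gene_id"]
        gene_triage.write_gff3(merged, out / "genes_merged.gff3", class_labels=labels.to_dict())
        counts = labels.value_counts().to_dict()
        truth_labels = gene_sim.truth.set_index("gene_id")["label"]
        recovery = float((labels.to_numpy() == truth_labels.loc[merged["gene_id"]].to_numpy()).mean())
        density = gene_triage.gene_density_track(merged, lengths, config.genes.density_window)
        gene_triage.write_density_bed(density, out / "gene_density.bed")
        report[stage] = {
            "n_merged": int(len(merged)),
            "class_counts": {k: int(v) for k, v in sorted(counts.items())},
            "class_recovery": recovery,
            "mean_cover_ratio": float(density["cover_ratio"].mean()),
        }

        stage = "cnv"
        chrom_lengths = {f"chr{c + 1:02d}": L for c, L in enumerate(ds.chrom_lengths)}
        base = {
            name: trio_sim.simulate_read_placements(
                chrom_lengths, config.cnv.depth, config.cnv.read_length,
                derive_seed(config.seed, f"cnv-{name}"),
            )
            for name in (config.donor.sample_a, config.donor.sample_b, "f1")
        }
        placed, cnv_truth = trio_sim.inject_cnv(
            base, config.cnv.events, chrom_lengths, seed=derive_seed(config.seed, "cnv-events")
        )
        tracks = {}
        for parent in (config.donor.sample_a, config.donor.sample_b):
            counts_df = window_counts(placed[parent], placed["f1"], chrom_lengths, config.cnv.window)
            tracks[parent] = log2_ratio_track(counts_df, config.cnv.pseudocount, config.cnv.threshold)
            tracks[parent].to_csv(out / f"cnv_{parent}.tsv", sep="\t", index=False)
        cnv_truth.to_csv(out / "cnv_truth.tsv", sep="\t", index=False)
        report[stage] = {
            parent: {
                "n_windows": int(len(tr)),
                "n_gain": int((tr["flag"] == "gain").sum()),
                "n_loss": int((tr["flag"] == "loss").sum()),
            }
            for parent, tr in tracks.items()
        }
    except Exception as exc:
        fingerprint = f"seed={config.seed}"
        raise StageError(f"stage {stage!r} failed ({fingerprint}): {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_markdown_report(report, out / "report.md")
    return report


def _write_markdown_report(report: dict, path) -> None:
    lines = ["# triophase synthetic pipeline report", ""]
    lines.append(f"Seed: {report['seed']}")
    lines.append("")
    lines.append("## Donor summary")
    lines.append("")
    lines.append("| category | scaffolds | length (bp) | % of assembly |")
    lines.append("|---|---|---|---|")
    for row in report["donor"]["summary"]:
        lines.append(
            f"| {row['category']} | {row['n_scaffolds']} | {row['total_length_bp']} "
            f"| {row['percent_of_assembly']} |"
        )
    lines.append("")
    acc = report["donor"]["accuracy_determined"]
    lines.append(f"Determined scaffolds: {report['donor']['n_determined']}; "
                 f"accuracy vs truth: {acc if acc is not None else 'n/a'}")
    lines.append("")
    if "haploid_bp" in report.get("kmer", {}):
        k = report["kmer"]
        lines.append("## k-mer genome size")
        lines.append("")
        lines.append(
            f"Peaks at {k['het_peak']} (het) / {k['hom_peak']} (hom); haploid estimate "
            f"{k['haploid_bp'] / 1e6:.2f} Mb (truth {k['true_haploid_bp'] / 1e6:.2f} Mb)."
        )
        lines.append("")
    g = report["genes"]
    lines.append("## Gene triage")
    lines.append("")
    lines.append(
        f"{g['n_merged']} merged genes; classes {g['class_counts']}; "
        f"label recovery {g['class_recovery']:.3f}; mean gene cover ratio {g['mean_cover_ratio']:.3f}."
    )
    lines.append("")
    lines.append("## CNV windows")
    lines.append("")
    for parent, c in report["cnv"].items():
        lines.append(f"- {parent}: {c['n_windows']} windows, {c['n_gain']} gain, {c['n_loss']} loss")
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
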