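"""Simulator ground-truth contracts: determinism, conservation, rate recovery."""

import numpy as np
import pandas as pd
import pytest

from triophase.trio_sim import (
    HET_A,
    CnvEvent,
    SimParams,
    fragment_into_scaffolds,
    inject_cnv,
    scaffold_n50,
    simulate_gene_evidence,
    simulate_parental_genotypes,
    simulate_read_placements,
    simulate_reads,
    simulate_reads_from_seqs,
    simulate_trio,
    write_genotypes_vcf,
)
from triophase.util import decode_seq


class TestSimParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"het_parent_a": -0.1},
            {"het_parent_b": 1.5},
            {"parental_divergence": 2.0},
            {"ancestor_length": 100},
            {"read_depth": 0},
            {"n_chromosomes": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimParams(**{"ancestor_length": 10_000, "n_chromosomes": 1, **kwargs})


class TestSimulateTrio:
    def test_no_mutation_identity(self):
        p = SimParams(
            ancestor_length=50_000, n_chromosomes=2, het_parent_a=0.0, het_parent_b=0.0,
            parental_divergence=0.0, scaffold_n50=50_000, seed=4,
        )
        ds = simulate_trio(p)
        assert len(ds.sites) == 0
        for c in range(2):
            assert np.array_equal(ds.f1_haplotypes[c][0], ds.ancestor[c])
            assert np.array_equal(ds.f1_haplotypes[c][1], ds.ancestor[c])
        gsim = simulate_parental_genotypes(ds, seed=4)
        assert len(gsim.table) == 0

    def test_heterozygosity_recovers_requested_rate(self):
        # binomial expectation 18,500 het sites in parent A over 1 Mb (+-10%)
        p = SimParams(ancestor_length=1_000_000, n_chromosomes=1, scaffold_n50=100_000, seed=1)
        ds = simulate_trio(p)
        het_a = ds.realized_heterozygosity("A")
        het_b = ds.realized_heterozygosity("B")
        assert 16_650 <= het_a * 1_000_000 <= 20_350
        assert 0.9 * 0.0132 <= het_b <= 1.1 * 0.0132

    def test_same_seed_byte_identical_fasta(self, tmp_path):
        p = SimParams(ancestor_length=100_000, n_chromosomes=2, scaffold_n50=20_000, seed=7)
        paths = []
        for name in ("a", "b"):
            ds = simulate_trio(p)
            path = tmp_path / f"{name}.fasta"
            ds.write_scaffolds_fasta(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_f1_haplotypes_are_transmitted_parental_haplotypes(self, small_trio):
        for c in range(len(small_trio.chrom_lengths)):
            a1, _ = small_trio.parent_haplotypes("A", c)
            b1, _ = small_trio.parent_haplotypes("B", c)
            assert np.array_equal(small_trio.f1_haplotypes[c][0], a1)
            assert np.array_equal(small_trio.f1_haplotypes[c][1], b1)


class TestFragmentation:
    def test_partition_conservation(self, small_trio):
        sc = small_trio.scaffolds
        assert sc["length"].sum() == 2 * sum(small_trio.chrom_lengths)
        for (c, h), grp in sc.groupby(["chrom", "hap"]):
            grp = grp.sort_values("start")
            assert grp["start"].iloc[0] == 0
            assert grp["end"].iloc[-1] == small_trio.chrom_lengths[c]
            assert (grp["end"].to_numpy()[:-1] == grp["start"].to_numpy()[1:]).all()

    def test_n50_within_band_against_sort_accumulate_oracle(self):
        p = SimParams(ancestor_length=1_000_000, n_chromosomes=1, scaffold_n50=100_000, seed=3)
        ds = simulate_trio(p)
        lengths = sorted(ds.scaffolds["length"], reverse=True)
        total = sum(lengths)
        acc = 0
        for L in lengths:  # independent sort-and-accumulate N50
            acc += L
            if acc >= total / 2:
                oracle = L
                break
        assert oracle == scaffold_n50(ds.scaffolds)
        assert 50_000 <= oracle <= 200_000

    def test_target_beyond_chromosome_gives_single_scaffolds(self, small_trio):
        sc = fragment_into_scaffolds(small_trio, n50_target=10_000_000, seed=0)
        assert len(sc) == 2 * len(small_trio.chrom_lengths)
        assert (sc["start"] == 0).all()

    def test_donor_labels_follow_haplotype(self, small_trio):
        sc = small_trio.scaffolds
        assert (sc.loc[sc["hap"] == 0, "donor"] == "A").all()
        assert (sc.loc[sc["hap"] == 1, "donor"] == "B").all()


class TestGenotypes:
    def test_zero_noise_matches_truth_table(self, clean_genotypes):
        t = clean_genotypes.table
        assert (t["call_a"] == t["gt_a"]).all()
        assert (t["call_b"] == t["gt_b"]).all()
        assert (t["qual"] == 999).all()

    def test_hybrid_parent_never_ref_homo_where_untransmitted_hap_differs(self, clean_genotypes):
        """On parent-A scaffolds, A is het at its own het sites (labruscana-like
        haplotype transmission), mirroring the absence of ref-homo calls for
        the hybrid parent on its own genome."""
        t = clean_genotypes.truth
        het_a_sites = t[t["klass"] == HET_A]
        assert len(het_a_sites) > 0
        assert (het_a_sites["gt_a"] == 1).all()

    def test_miscall_fraction_within_binomial_band(self, small_trio):
        gsim = simulate_parental_genotypes(small_trio, miscall_rate=0.01, seed=5)
        t = gsim.table
        assert len(t) >= 10_000
        frac = ((t["call_a"] != t["gt_a"]).sum() + (t["call_b"] != t["gt_b"]).sum()) / (2 * len(t))
        assert 0.005 <= frac <= 0.015

    def test_vcf_roundtrip_preserves_genotypes(self, small_trio, clean_genotypes, tmp_path):
        from triophase.variant_filter import AlleleClass, read_vcf

        path = tmp_path / "g.vcf"
        write_genotypes_vcf(clean_genotypes, small_trio.scaffold_lengths(), path)
        want = {AlleleClass.REF_HOMO: 0, AlleleClass.HET: 1, AlleleClass.ALT_HOMO: 2}
        n = 0
        table = clean_genotypes.table
        for rec, row in zip(read_vcf(path), table.itertuples()):
            assert rec.scaffold_id == row.scaffold_id
            assert rec.position == row.pos + 1
            assert want[rec.allele_class("parent_a")] == row.call_a
            assert want[rec.allele_class("parent_b")] == row.call_b
            n += 1
            if n > 2_000:
                break
        assert n > 1_000


class TestReads:
    def test_error_free_reads_are_exact_substrings(self):
        p = SimParams(ancestor_length=20_000, n_chromosomes=1, scaffold_n50=20_000, seed=2)
        ds = simulate_trio(p)
        reads = simulate_reads(ds, depth=3, read_length=100, error_rate=0.0, seed=2)
        haps = [decode_seq(h) for pair in ds.f1_haplotypes for h in pair]
        for row in reads.matrix[:200]:
            s = decode_seq(row)
            assert any(s in h for h in haps)

    def test_total_bases_match_depth(self):
        p = SimParams(ancestor_length=100_000, n_chromosomes=1, scaffold_n50=100_000, seed=2)
        ds = simulate_trio(p)
        reads = simulate_reads(ds, depth=30, read_length=150, error_rate=0.0, seed=2)
        ratio = reads.total_bases() / ds.diploid_length()
        assert 28.5 <= ratio <= 31.5

    def test_same_seed_identical_fastq(self, tmp_path):
        p = SimParams(ancestor_length=20_000, n_chromosomes=1, scaffold_n50=20_000, seed=9)
        ds = simulate_trio(p)
        outs = []
        for name in ("x", "y"):
            reads = simulate_reads(ds, depth=2, read_length=100, error_rate=0.01, seed=9)
            path = tmp_path / f"{name}.fastq"
            reads.to_fastq(path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_read_length_longer_than_template_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads_from_seqs([np.zeros(50, dtype=np.uint8)], 10, 100, 0.0, 1)


class TestCnvInjection:
    @pytest.fixture
    def flat_placements(self):
        lengths = {"s1": 3_000_000}
        pl = simulate_read_placements(lengths, depth=30, read_length=150, seed=4)
        return lengths, {"test": pl}

    def test_neutral_copy_number_is_identity(self, flat_placements):
        lengths, pl = flat_placements
        out, _ = inject_cnv(pl, [CnvEvent("s1", 0, 1_000_000, 2, "test")], lengths, seed=1)
        pd.testing.assert_frame_equal(out["test"], pl["test"])

    def test_homozygous_deletion_removes_all_reads(self, flat_placements):
        lengths, pl = flat_placements
        out, _ = inject_cnv(pl, [CnvEvent("s1", 1_000_000, 2_000_000, 0, "test")], lengths, seed=1)
        s = out["test"]["start"]
        assert ((s >= 1_000_000) & (s < 2_000_000)).sum() == 0

    def test_duplication_doubles_window_density(self, flat_placements):
        lengths, pl = flat_placements
        out, _ = inject_cnv(pl, [CnvEvent("s1", 1_000_000, 2_000_000, 4, "test")], lengths, seed=1)
        s = out["test"]["start"].to_numpy()
        n_event = ((s >= 1_000_000) & (s < 2_000_000)).sum()
        n_flank = (s < 1_000_000).sum()
        assert 1.8 <= n_event / n_flank <= 2.2

    def test_overlapping_events_rejected(self, flat_placements):
        lengths, pl = flat_placements
        events = [
            CnvEvent("s1", 0, 1_000_000, 4, "test"),
            CnvEvent("s1", 500_000, 1_500_000, 0, "test"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            inject_cnv(pl, events, lengths, seed=1)

    def test_out_of_bounds_event_rejected(self, flat_placements):
        lengths, pl = flat_placements
        with pytest.raises(ValueError):
            inject_cnv(pl, [CnvEvent("s1", 0, 9_000_000, 4, "test")], lengths, seed=1)


class TestGeneEvidenceSim:
    def test_pure_hc_mix_satisfies_hc_conditions(self):
        sim = simulate_gene_evidence({"s1": 2_000_000}, 50, class_mix=(1, 0, 0), seed=1)
        ev = sim.evidence
        assert not ev["uniprot_te_flag"].any()
        qualifies = (ev["tpm"] > 0.5) | ev[["has_domain", "hit_uniprot", "hit_nr", "hit_vv12x"]].any(axis=1)
        assert qualifies.all()

    def test_pure_te_mix_carries_te_hits(self):
        sim = simulate_gene_evidence({"s1": 2_000_000}, 50, class_mix=(0, 0, 1), seed=1)
        assert sim.evidence["uniprot_te_flag"].all()

    def test_classifier_recovers_intended_labels(self):
        from triophase.gene_triage import classify_genes

        sim = simulate_gene_evidence({"s1": 20_000_000}, 1000, class_mix=(0.44, 0.30, 0.26), seed=2)
        labels = classify_genes(sim.evidence.set_index("gene_id"))
        truth = sim.truth.set_index("gene_id")["label"]
        assert (labels.loc[truth.index] == truth).mean() == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_gene_evidence({"s1": 1_000_000}, 0, seed=1)
        with pytest.raises(ValueError):
            simulate_gene_evidence({"s1": 1_000_000}, 10, class_mix=(0.5, 0.5, 0.5), seed=1)
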