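"""Donor rules, confidence tiers, summary arithmetic and truth recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triophase import published
from triophase.donor_assign import (
    Confidence,
    Verdict,
    assign_donors,
    combine_verdicts,
    evaluate_against_truth,
    summarize_donors,
    summarize_from_category_table,
    tabulate_allele_ratios,
    verdict_from_parent,
)

from .conftest import make_record


class TestVerdictFromParent:
    @pytest.mark.parametrize(
        "ratios,role,expected",
        [
            ((0.0, 0.80, 0.20), "A", Verdict.DONOR_A),  # het-rich on hybrid parent
            ((0.10, 0.15, 0.75), "A", Verdict.DONOR_B),
            ((0.75, 0.15, 0.10), "B", Verdict.DONOR_B),  # ref-rich on the other parent
            ((0.10, 0.15, 0.75), "B", Verdict.DONOR_A),
            ((0.30, 0.40, 0.30), "A", Verdict.UNDETERMINED),
            ((0.30, 0.40, 0.30), "B", Verdict.UNDETERMINED),
            ((0.30, 0.70, 0.00), "A", Verdict.DONOR_A),  # inclusive boundary
            ((0.70, 0.30, 0.00), "B", Verdict.DONOR_B),
        ],
    )
    def test_rule_table(self, ratios, role, expected):
        assert verdict_from_parent(*ratios, role=role) is expected

    @pytest.mark.parametrize("threshold", [0.5, 0.49, 1.1, 0.0])
    def test_threshold_outside_half_one_rejected(self, threshold):
        with pytest.raises(ValueError):
            verdict_from_parent(0.0, 1.0, 0.0, "A", threshold)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            verdict_from_parent(0, 1, 0, "C")


class TestCombineVerdicts:
    @pytest.mark.parametrize(
        "sub_a,sub_b,verdict,conf,conflict",
        [
            (Verdict.DONOR_A, Verdict.DONOR_A, Verdict.DONOR_A, Confidence.HIGH, False),
            (Verdict.DONOR_B, Verdict.DONOR_B, Verdict.DONOR_B, Confidence.HIGH, False),
            (Verdict.DONOR_B, Verdict.UNDETERMINED, Verdict.DONOR_B, Confidence.LOW, False),
            (Verdict.UNDETERMINED, Verdict.DONOR_A, Verdict.DONOR_A, Confidence.LOW, False),
            (Verdict.UNDETERMINED, Verdict.UNDETERMINED, Verdict.UNDETERMINED, Confidence.NA, False),
            (Verdict.DONOR_A, Verdict.DONOR_B, Verdict.UNDETERMINED, Confidence.NA, True),
        ],
    )
    def test_combination_table(self, sub_a, sub_b, verdict, conf, conflict):
        assert combine_verdicts(sub_a, sub_b) == (verdict, conf, conflict)


class TestTabulate:
    def test_hand_counted_fractions(self):
        recs = [make_record(position=i + 1, gt_a="0/1" if i < 8 else "1/1", gt_b="1/1")
                for i in range(10)]
        ratios = tabulate_allele_ratios(recs, {"scf00000": 1000}, "parent_a", "parent_b")
        row = ratios.iloc[0]
        assert row["n_variants"] == 10
        assert row["a_het"] == pytest.approx(0.8)
        assert row["a_alt_homo"] == pytest.approx(0.2)
        assert row["b_alt_homo"] == pytest.approx(1.0)

    def test_missing_calls_excluded_from_denominator(self):
        recs = [make_record(position=i + 1, gt_a="0/1" if i < 2 else "./.", gt_b="1/1")
                for i in range(4)]
        ratios = tabulate_allele_ratios(recs, {"scf00000": 1000}, "parent_a", "parent_b")
        assert ratios.iloc[0]["a_het"] == pytest.approx(1.0)

    def test_variant_free_scaffold_flagged_not_investigated(self):
        recs = [make_record()]
        ratios = tabulate_allele_ratios(recs, {"scf00000": 1000, "scf00001": 500},
                                        "parent_a", "parent_b")
        calls = assign_donors(ratios)
        by_id = calls.set_index("scaffold_id")
        assert by_id.loc["scf00001", "verdict"] == Verdict.NOT_INVESTIGATED.value
        assert by_id.loc["scf00001", "confidence"] == Confidence.NA.value

    def test_unknown_scaffold_in_records_is_an_error(self):
        with pytest.raises(KeyError, match="scf00000"):
            tabulate_allele_ratios([make_record()], {"other": 100}, "parent_a", "parent_b")


def _brute_force_assign(counts_a, counts_b, threshold=0.70):
    """Independent re-statement of both rule sets plus combination."""
    def frac(c):
        t = sum(c)
        return None if t == 0 else tuple(x / t for x in c)

    fa, fb = frac(counts_a), frac(counts_b)
    sub_a = sub_b = "U"
    if fa:
        ra, ha, aa = fa
        sub_a = "A" if ha >= threshold else ("B" if aa >= threshold else "U")
    if fb:
        rb, hb, ab = fb
        sub_b = "A" if ab >= threshold else ("B" if rb >= threshold else "U")
    pair = {sub_a, sub_b}
    if pair == {"A"}:
        return "DonorA", "High"
    if pair == {"B"}:
        return "DonorB", "High"
    if pair == {"A", "U"}:
        return "DonorA", "Low"
    if pair == {"B", "U"}:
        return "DonorB", "Low"
    return "Undetermined", "NA"


class TestExhaustiveOracle:
    def test_all_small_count_combinations_match_brute_force(self):
        """Every allele-class composition with <= 5 calls per parent."""
        compositions = sorted({(a, b, n - a - b) for n in range(1, 6)
                               for a in range(n + 1) for b in range(n + 1 - a)})
        for ca in compositions:
            for cb in compositions:
                na, nb = sum(ca), sum(cb)
                ratios = pd.DataFrame(
                    [{
                        "scaffold_id": "s", "scaffold_length": 100,
                        "n_variants": max(na, nb),
                        "a_ref_homo": ca[0] / na, "a_het": ca[1] / na, "a_alt_homo": ca[2] / na,
                        "b_ref_homo": cb[0] / nb, "b_het": cb[1] / nb, "b_alt_homo": cb[2] / nb,
                    }]
                )
                calls = assign_donors(ratios)
                want_v, want_c = _brute_force_assign(ca, cb)
                assert calls.iloc[0]["verdict"] == want_v, (ca, cb)
                assert calls.iloc[0]["confidence"] == want_c, (ca, cb)


class TestThresholdMonotonicity:
    def test_raising_threshold_never_determines_an_undetermined_scaffold(self, rng):
        for _ in range(200):
            fr = rng.dirichlet(np.ones(3))
            for role in ("A", "B"):
                v1 = verdict_from_parent(*fr, role=role, threshold=0.70)
                v2 = verdict_from_parent(*fr, role=role, threshold=0.85)
                if v1 is Verdict.UNDETERMINED:
                    assert v2 is Verdict.UNDETERMINED


class TestSummaries:
    def test_published_category_table_percentages(self):
        summary = summarize_from_category_table(
            published.DONOR_CATEGORY_LENGTHS_BP,
            published.DONOR_CATEGORY_COUNTS,
            published.PHASED_TOTAL_LENGTH_BP,
        )
        pct = summary.set_index("category")["percent_of_assembly"]
        assert pct["donor_a_total"] == 35.2
        assert pct["donor_b_total"] == 40.0
        assert pct["undetermined"] == 15.5
        assert pct["not_investigated"] == 9.3
        assert pct["determined_total"] == 75.2

    def test_published_counts_and_lengths_conserve_assembly_totals(self):
        summary = summarize_from_category_table(
            published.DONOR_CATEGORY_LENGTHS_BP,
            published.DONOR_CATEGORY_COUNTS,
            published.PHASED_TOTAL_LENGTH_BP,
        )
        leaf = summary[summary["category"].isin(
            ["donor_a_total", "donor_b_total", "undetermined", "not_investigated"])]
        assert leaf["n_scaffolds"].sum() == published.PHASED_SCAFFOLD_COUNT
        assert leaf["total_length_bp"].sum() == published.PHASED_TOTAL_LENGTH_BP

    def test_single_scaffold_summary(self):
        calls = pd.DataFrame(
            [{"scaffold_id": "s", "scaffold_length": 1234,
              "verdict": "DonorA", "confidence": "High"}]
        )
        summary = summarize_donors(calls).set_index("category")
        assert summary.loc["donor_a_total", "n_scaffolds"] == 1
        assert summary.loc["donor_a_total", "percent_of_assembly"] == 100.0
        assert summary.loc["determined_total", "total_length_bp"] == 1234

    def test_mismatched_total_warns(self):
        calls = pd.DataFrame(
            [{"scaffold_id": "s", "scaffold_length": 100,
              "verdict": "DonorB", "confidence": "Low"}]
        )
        with pytest.warns(UserWarning, match="assembly_total_length"):
            summarize_donors(calls, assembly_total_length=500)

    def test_category_partition_on_synthetic_calls(self, rng):
        n = 200
        verdicts = rng.choice(["DonorA", "DonorB", "Undetermined", "NotInvestigated"], n)
        conf = np.where(
            np.isin(verdicts, ["DonorA", "DonorB"]), rng.choice(["High", "Low"], n), "NA"
        )
        calls = pd.DataFrame(
            {"scaffold_id": [f"s{i}" for i in range(n)],
             "scaffold_length": rng.integers(1_000, 100_000, n),
             "verdict": verdicts, "confidence": conf}
        )
        summary = summarize_donors(calls).set_index("category")
        leaf = ["donor_a_total", "donor_b_total", "undetermined", "not_investigated"]
        assert summary.loc[leaf, "n_scaffolds"].sum() == n
        assert summary.loc[leaf, "total_length_bp"].sum() == calls["scaffold_length"].sum()


@pytest.fixture(scope="module")
def noise_free_calls(small_trio, clean_genotypes, tmp_path_factory):
    from triophase.trio_sim import write_genotypes_vcf
    from triophase.variant_filter import filter_variants, read_vcf

    lengths = small_trio.scaffold_lengths()
    path = tmp_path_factory.mktemp("donor") / "g.vcf"
    write_genotypes_vcf(clean_genotypes, lengths, path)
    ratios = tabulate_allele_ratios(filter_variants(read_vcf(path)), lengths,
                                    "parent_a", "parent_b")
    return assign_donors(ratios)


class TestTruthRecovery:
    def test_noise_free_determined_calls_all_correct(self, small_trio, noise_free_calls):
        truth = dict(zip(small_trio.scaffolds["scaffold_id"], small_trio.scaffolds["donor"]))
        ev = evaluate_against_truth(noise_free_calls, truth)
        assert ev.n_determined > 0
        assert ev.accuracy_determined == 1.0

    def test_missing_truth_counted_not_crashing(self, noise_free_calls):
        ev = evaluate_against_truth(noise_free_calls, {})
        assert ev.n_missing_truth == len(noise_free_calls)
        assert ev.accuracy_determined is None

    def test_label_swap_never_produces_the_opposite_donor(self, small_trio, noise_free_calls):
        """The rule sets are parent-specific, so a sample swap may turn a
        determined scaffold undetermined — but it must never flip a scaffold
        to the same donor name (which would now mean the other parent)."""
        swapped_ratios = noise_free_calls.rename(
            columns={
                "a_ref_homo": "b_ref_homo", "a_het": "b_het", "a_alt_homo": "b_alt_homo",
                "b_ref_homo": "a_ref_homo", "b_het": "a_het", "b_alt_homo": "a_alt_homo",
            }
        )[["scaffold_id", "scaffold_length", "n_variants",
           "a_ref_homo", "a_het", "a_alt_homo", "b_ref_homo", "b_het", "b_alt_homo"]]
        swapped = assign_donors(swapped_ratios)
        both = noise_free_calls.merge(swapped, on="scaffold_id", suffixes=("_orig", "_swap"))
        donors = {Verdict.DONOR_A.value, Verdict.DONOR_B.value}
        determined_both = both[
            both["verdict_orig"].isin(donors) & both["verdict_swap"].isin(donors)
        ]
        assert (determined_both["verdict_orig"] != determined_both["verdict_swap"]).all()
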