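"""Scaffold donor-parent assignment from parental allele-class ratios.

Each scaffold of a phased F1 assembly descends from one parent. Given filtered
two-sample genotype calls of the parents against the scaffolds, the fractions
of reference-homozygous / heterozygous / alt-homozygous calls per parent carry
the donor signal, read through two parent-specific rule sets (threshold 70%,
inclusive):

* from the hybrid parent's calls (role A, Akitsu-21-like): Het >= 70% => the
  scaffold is A's; AltHomo >= 70% => it is B's;
* from the other parent's calls (role B, 'Hakunan'-like): AltHomo >= 70% =>
  it is A's; RefHomo >= 70% => it is B's.

Agreeing sub-verdicts give a high-confidence call; one verdict plus one
undetermined gives low confidence; scaffolds with no variants at all are "not
investigated". The summary reproduces the published table shape: per-category
scaffold counts, total lengths and percentages of the assembly total.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .util import round_half_up
from .variant_filter import AlleleClass, VariantRecord


class Verdict(str, Enum):
    DONOR_A = "DonorA"
    DONOR_B = "DonorB"
    UNDETERMINED = "Undetermined"
    NOT_INVESTIGATED = "NotInvestigated"


class Confidence(str, Enum):
    HIGH = "High"
    LOW = "Low"
    NA = "NA"


RATIO_COLUMNS = ["a_ref_homo", "a_het", "a_alt_homo", "b_ref_homo", "b_het", "b_alt_homo"]


def tabulate_allele_ratios(
    records: Iterable[VariantRecord],
    scaffold_lengths: Mapping[str, int],
    sample_a: str,
    sample_b: str,
) -> pd.DataFrame:
    """Per-scaffold allele-class fractions for both parents.

    Fractions are taken over each parent's non-missing calls on that scaffold.
    Scaffolds absent from the records (no variants) get ``n_variants = 0`` and
    NaN ratios; a record on a scaffold missing from ``scaffold_lengths`` is an
    error.
    """
    counts: dict[str, np.ndarray] = {}
    for rec in records:
        if rec.scaffold_id not in scaffold_lengths:
            raise KeyError(f"scaffold {rec.scaffold_id!r} absent from length table")
        c = counts.setdefault(rec.scaffold_id, np.zeros(7, dtype=np.int64))
        c[6] += 1
        for offset, sample in ((0, sample_a), (3, sample_b)):
            klass = rec.allele_class(sample)
            if klass is AlleleClass.REF_HOMO:
                c[offset] += 1
            elif klass is AlleleClass.HET:
                c[offset + 1] += 1
            elif klass is AlleleClass.ALT_HOMO:
                c[offset + 2] += 1

    rows = []
    for sid, length in scaffold_lengths.items():
        c = counts.get(sid)
        row: dict[str, object] = {"scaffold_id": sid, "scaffold_length": int(length)}
        if c is None:
            row["n_variants"] = 0
            row.update({col: np.nan for col in RATIO_COLUMNS})
        else:
            row["n_variants"] = int(c[6])
            for offset, prefix in ((0, "a"), (3, "b")):
                denom = c[offset : offset + 3].sum()
                for j, klass in enumerate(("ref_homo", "het", "alt_homo")):
                    row[f"{prefix}_{klass}"] = c[offset + j] / denom if denom else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def verdict_from_parent(
    ref_homo: float, het: float, alt_homo: float, role: str, threshold: float = 0.70
) -> Verdict:
    """Sub-verdict from one parent's allele-class fractions (inclusive >=)."""
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]; two classes could qualify at <= 0.5")
    if role == "A":
        if het >= threshold:
            return Verdict.DONOR_A
        if alt_homo >= threshold:
            return Verdict.DONOR_B
    elif role == "B":
        if alt_homo >= threshold:
            return Verdict.DONOR_A
        if ref_homo >= threshold:
            return Verdict.DONOR_B
    else:
        raise ValueError("role must be 'A' or 'B'")
    return Verdict.UNDETERMINED


def combine_verdicts(sub_a: Verdict, sub_b: Verdict) -> tuple[Verdict, Confidence, bool]:
    """Combine per-parent sub-verdicts into (verdict, confidence, conflict flag).

    Matching donors => high confidence; one donor + one undetermined => low;
    both undetermined => undetermined; contradictory donors => undetermined
    with the conflict flag raised (conservative: the categories stay a
    partition and no tie-break is invented).
    """
    donors = {Verdict.DONOR_A, Verdict.DONOR_B}
    if sub_a in donors and sub_b in donors:
        if sub_a is sub_b:
            return sub_a, Confidence.HIGH, False
        return Verdict.UNDETERMINED, Confidence.NA, True
    if sub_a in donors:
        return sub_a, Confidence.LOW, False
    if sub_b in donors:
        return sub_b, Confidence.LOW, False
    return Verdict.UNDETERMINED, Confidence.NA, False


def assign_donors(
    ratios: pd.DataFrame, threshold: float = 0.70, min_variants: int = 0
) -> pd.DataFrame:
    """Donor call per scaffold from the ratio table.

    Scaffolds with zero variants are NotInvestigated; ``min_variants`` (default
    0, i.e. no floor) additionally pushes thinly-supported scaffolds to
    Undetermined because single-variant scaffolds trivially reach 100% ratios.
    """
    out = ratios.copy()
    sub_a, sub_b, verdicts, confidences, conflicts = [], [], [], [], []
    for row in ratios.itertuples():
        if row.n_variants == 0:
            sa = sb = Verdict.UNDETERMINED
            v, conf, cfl = Verdict.NOT_INVESTIGATED, Confidence.NA, False
        else:
            sa = verdict_from_parent(row.a_ref_homo, row.a_het, row.a_alt_homo, "A", threshold)
            sb = verdict_from_parent(row.b_ref_homo, row.b_het, row.b_alt_homo, "B", threshold)
            if row.n_variants < min_variants:
                v, conf, cfl = Verdict.UNDETERMINED, Confidence.NA, False
            else:
                v, conf, cfl = combine_verdicts(sa, sb)
        sub_a.append(sa.value)
        sub_b.append(sb.value)
        verdicts.append(v.value)
        confidences.append(conf.value)
        conflicts.append(cfl)
    out["sub_verdict_a"] = sub_a
    out["sub_verdict_b"] = sub_b
    out["verdict"] = verdicts
    out["confidence"] = confidences
    out["conflict"] = conflicts
    return out


#: summary row order, mirroring the published donor table
SUMMARY_CATEGORIES = [
    "donor_a_high",
    "donor_a_low",
    "donor_a_total",
    "donor_b_high",
    "donor_b_low",
    "donor_b_total",
    "undetermined",
    "not_investigated",
]


def summarize_donors(
    calls: pd.DataFrame, assembly_total_length: int | None = None
) -> pd.DataFrame:
    """Category counts, summed lengths and percentages of the assembly total.

    Percentages are computed against ``assembly_total_length`` (default: the
    sum of all scaffold lengths, which includes the not-investigated
    scaffolds) and rounded half-up to one decimal. The appended
    ``determined_total`` row aggregates both donor categories.
    """
    total_len = int(calls["scaffold_length"].sum())
    if assembly_total_length is None:
        assembly_total_length = total_len
    elif assembly_total_length != total_len:
        import warnings

        warnings.warn(
            f"assembly_total_length {assembly_total_length} != sum of scaffold lengths {total_len}",
            stacklevel=2,
        )

    def bucket(row) -> str:
        if row.verdict == Verdict.NOT_INVESTIGATED.value:
            return "not_investigated"
        if row.verdict == Verdict.UNDETERMINED.value:
            return "undetermined"
        side = "a" if row.verdict == Verdict.DONOR_A.value else "b"
        tier = "high" if row.confidence == Confidence.HIGH.value else "low"
        return f"donor_{side}_{tier}"

    groups = {cat: [0, 0] for cat in SUMMARY_CATEGORIES}
    for row in calls.itertuples():
        cat = bucket(row)
        groups[cat][0] += 1
        groups[cat][1] += int(row.scaffold_length)
    for side in ("a", "b"):
        groups[f"donor_{side}_total"] = [
            groups[f"donor_{side}_high"][0] + groups[f"donor_{side}_low"][0],
            groups[f"donor_{side}_high"][1] + groups[f"donor_{side}_low"][1],
        ]
    rows = [
        {
            "category": cat,
            "n_scaffolds": groups[cat][0],
            "total_length_bp": groups[cat][1],
            "percent_of_assembly": round_half_up(100.0 * groups[cat][1] / assembly_total_length),
        }
        for cat in SUMMARY_CATEGORIES
    ]
    det_n = groups["donor_a_total"][0] + groups["donor_b_total"][0]
    det_len = groups["donor_a_total"][1] + groups["donor_b_total"][1]
    rows.append(
        {
            "category": "determined_total",
            "n_scaffolds": det_n,
            "total_length_bp": det_len,
            "percent_of_assembly": round_half_up(100.0 * det_len / assembly_total_length),
        }
    )
    return pd.DataFrame(rows)


def summarize_from_category_table(
    category_lengths: Mapping[str, int],
    category_counts: Mapping[str, int],
    assembly_total_length: int,
) -> pd.DataFrame:
    """Recompute the summary percentages from printed per-category totals.

    Builds one pseudo-scaffold per category carrying the published count and
    length, then runs the ordinary summariser — so the percentage arithmetic
    exercised on synthetic data is the same arithmetic applied to published
    numbers.
    """
    verdict_map = {
        "donor_a_high": (Verdict.DONOR_A, Confidence.HIGH),
        "donor_a_low": (Verdict.DONOR_A, Confidence.LOW),
        "donor_b_high": (Verdict.DONOR_B, Confidence.HIGH),
        "donor_b_low": (Verdict.DONOR_B, Confidence.LOW),
        "undetermined": (Verdict.UNDETERMINED, Confidence.NA),
        "not_investigated": (Verdict.NOT_INVESTIGATED, Confidence.NA),
    }
    rows = []
    for cat, (v, conf) in verdict_map.items():
        if cat not in category_lengths:
            continue
        rows.append(
            {
                "scaffold_id": cat,
                "scaffold_length": category_lengths[cat],
                "verdict": v.value,
                "confidence": conf.value,
            }
        )
    calls = pd.DataFrame(rows)
    summary = summarize_donors(calls, assembly_total_length)
    count_map = dict(category_counts)
    for side in ("a", "b"):
        count_map[f"donor_{side}_total"] = count_map.get(f"donor_{side}_high", 0) + count_map.get(
            f"donor_{side}_low", 0
        )
    count_map["determined_total"] = count_map["donor_a_total"] + count_map["donor_b_total"]
    summary["n_scaffolds"] = summary["category"].map(count_map)
    return summary


@dataclass
class TruthEvaluation:
    n_determined: int
    n_correct: int
    accuracy_determined: float | None
    n_missing_truth: int
    confusion: pd.DataFrame


def evaluate_against_truth(calls: pd.DataFrame, truth: Mapping[str, str]) -> TruthEvaluation:
    """Confusion of verdicts vs true donors; accuracy among determined scaffolds.

    ``truth`` maps scaffold_id -> 'A' | 'B'. Scaffolds without truth are
    excluded and counted.
    """
    want = {Verdict.DONOR_A.value: "A", Verdict.DONOR_B.value: "B"}
    n_det = n_ok = n_missing = 0
    cells: dict[tuple[str, str], int] = {}
    for row in calls.itertuples():
        t = truth.get(row.scaffold_id)
        if t is None:
            n_missing += 1
            continue
        cells[(t, row.verdict)] = cells.get((t, row.verdict), 0) + 1
        if row.verdict in want:
            n_det += 1
            if want[row.verdict] == t:
                n_ok += 1
    confusion = (
        pd.Series(cells).rename_axis(["true_donor", "verdict"]).unstack(fill_value=0)
        if cells
        else pd.DataFrame()
    )
    return TruthEvaluation(
        n_determined=n_det,
        n_correct=n_ok,
        accuracy_determined=(n_ok / n_det) if n_det else None,
        n_missing_truth=n_missing,
        confusion=confusion,
    )
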