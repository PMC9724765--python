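"""Gene-prediction merging, HC/LC/TE evidence triage, and gene-density tracks.

Two prediction sets — transcript-evidence ORFs (Iso-Seq) and ab initio models
— are merged by collapsing genes that occupy the same locus (same scaffold and
strand, reciprocal span overlap >= 90% by default) to the member with the
longer ORF. Merged genes are then classified from evidence flags:

* TE: the best UniProtKB hit is transposon-associated (takes precedence —
  transposon-like genes are excluded from the high-confidence set no matter
  how strongly expressed);
* HC: any of — TPM > 0.5 (strict), a protein-domain hit, or a hit in
  UniProtKB, NCBI NR, or the V. vinifera 12X gene set;
* LC: everything else.

Gene density is the fraction of window bases covered by the union of gene
intervals, in non-overlapping 1-Mb tiles by default.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

HC_EVIDENCE_FLAGS = ["has_domain", "hit_uniprot", "hit_nr", "hit_vv12x"]
TPM_MIN = 0.5


def classify_gene(evidence: Mapping) -> str:
    """Class label for one gene's evidence (see module docstring for the rules)."""
    if evidence["uniprot_te_flag"]:
        return "TE"
    if evidence["tpm"] > TPM_MIN or any(bool(evidence[f]) for f in HC_EVIDENCE_FLAGS):
        return "HC"
    return "LC"


def classify_genes(evidence: pd.DataFrame, hc_mode: str = "any") -> pd.Series:
    """Vectorised classification; ``hc_mode`` 'any' (default) or 'all'.

    'any' treats the HC conditions as alternatives (one suffices); 'all'
    requires every condition, for sensitivity analysis.
    """
    flags = evidence[HC_EVIDENCE_FLAGS].astype(bool)
    expressed = evidence["tpm"] > TPM_MIN
    if hc_mode == "any":
        hc = expressed | flags.any(axis=1)
    elif hc_mode == "all":
        hc = expressed & flags.all(axis=1)
    else:
        raise ValueError("hc_mode must be 'any' or 'all'")
    label = np.where(evidence["uniprot_te_flag"].astype(bool), "TE", np.where(hc, "HC", "LC"))
    return pd.Series(label, index=evidence.index, name="label")


def _reciprocal_overlap(s1: int, e1: int, s2: int, e2: int) -> float:
    """Smaller of the two mutual overlap fractions (0 if disjoint)."""
    ov = min(e1, e2) - max(s1, s2) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (e1 - s1 + 1), ov / (e2 - s2 + 1))


def merge_predictions(
    set_iso: pd.DataFrame,
    set_ab: pd.DataFrame,
    min_reciprocal_overlap: float = 0.9,
) -> pd.DataFrame:
    """Collapse cross-source duplicates to the longer-ORF member.

    Genes are "identical" when on the same scaffold and strand with reciprocal
    span overlap >= ``min_reciprocal_overlap``. Ties on ORF length keep the
    transcript-evidence (Iso-Seq) member. Duplicates within one source are
    kept (with a warning); all non-identical genes pass through.
    """
    import warnings

    for name, df in (("iso", set_iso), ("ab_initio", set_ab)):
        dup = _same_source_overlaps(df, min_reciprocal_overlap)
        if dup:
            warnings.warn(f"{dup} overlapping same-source gene pairs in {name} set kept as-is",
                          stacklevel=2)

    iso = set_iso.sort_values(["scaffold", "start"]).reset_index(drop=True)
    ab = set_ab.sort_values(["scaffold", "start"]).reset_index(drop=True)
    drop_iso: set[int] = set()
    drop_ab: set[int] = set()
    for scaf, strand in {(r.scaffold, r.strand) for r in iso.itertuples()}:
        ii = iso[(iso["scaffold"] == scaf) & (iso["strand"] == strand)]
        aa = ab[(ab["scaffold"] == scaf) & (ab["strand"] == strand)]
        if aa.empty:
            continue
        a_starts = aa["start"].to_numpy()
        a_ends = aa["end"].to_numpy()
        for r in ii.itertuples():
            # candidate partners: any ab gene whose span intersects this one
            cand = np.flatnonzero((a_starts <= r.end) & (a_ends >= r.start))
            best_j, best_ov = -1, 0.0
            for j in cand:
                if aa.index[j] in drop_ab:
                    continue
                ov = _reciprocal_overlap(r.start, r.end, int(a_starts[j]), int(a_ends[j]))
                if ov > best_ov:
                    best_j, best_ov = j, ov
            if best_j >= 0 and best_ov >= min_reciprocal_overlap:
                ab_row = aa.iloc[best_j]
                if ab_row["orf_length"] > r.orf_length:
                    drop_iso.add(r.Index)
                else:  # longer ORF wins; Iso-Seq wins ties (transcript evidence)
                    drop_ab.add(aa.index[best_j])
    merged = pd.concat(
        [iso.drop(index=list(drop_iso)), ab.drop(index=list(drop_ab))], ignore_index=True
    )
    return merged.sort_values(["scaffold", "start", "gene_id"]).reset_index(drop=True)


def _same_source_overlaps(df: pd.DataFrame, min_ov: float) -> int:
    n = 0
    s = df.sort_values(["scaffold", "strand", "start"])
    prev = None
    for r in s.itertuples():
        if prev is not None and r.scaffold == prev.scaffold and r.strand == prev.strand:
            if _reciprocal_overlap(prev.start, prev.end, r.start, r.end) >= min_ov:
                n += 1
        prev = r
    return n


def gene_density_track(
    genes: pd.DataFrame,
    scaffold_lengths: Mapping[str, int],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Per-window fraction of bases covered by >= 1 gene (union semantics).

    Windows tile each scaffold (0-based half-open); the final partial window
    is normalised by its actual length. Gene coordinates are 1-based inclusive
    as in GFF3. Zero-length scaffolds are skipped with a warning.
    """
    import warnings

    rows = []
    by_scaf = dict(tuple(genes.groupby("scaffold"))) if len(genes) else {}
    for scaf, length in scaffold_lengths.items():
        if length <= 0:
            warnings.warn(f"zero-length scaffold {scaf!r} skipped", stacklevel=2)
            continue
        g = by_scaf.get(scaf)
        if g is not None:
            starts0 = np.clip(g["start"].to_numpy() - 1, 0, length)
            ends0 = np.clip(g["end"].to_numpy(), 0, length)  # half-open end
            # coverage via interval boundary differences
            delta = np.zeros(length + 1, dtype=np.int32)
            np.add.at(delta, starts0, 1)
            np.add.at(delta, ends0, -1)
            covered = (np.cumsum(delta[:-1]) > 0)
        else:
            covered = np.zeros(length, dtype=bool)
        for w0 in range(0, length, window):
            w1 = min(length, w0 + window)
            rows.append(
                {
                    "scaffold": scaf,
                    "start": w0,
                    "end": w1,
                    "cover_ratio": float(covered[w0:w1].mean()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GFF3 / TSV I/O
# ---------------------------------------------------------------------------


def write_gff3(genes: pd.DataFrame, path, class_labels: Mapping[str, str] | None = None) -> None:
    """Emit gene rows as GFF3 (one ``gene`` feature per row)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            attrs = f"ID={r.gene_id};orf_length={r.orf_length};prediction_source={r.source}"
            if class_labels and r.gene_id in class_labels:
                attrs += f";gene_class={class_labels[r.gene_id]}"
            fh.write(
                f"{r.scaffold}\ttriophase\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Read gene features from GFF3 into the merge/triage frame layout."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            {
                "gene_id": feat.id,
                "scaffold": feat.seqid,
                "start": feat.start,
                "end": feat.end,
                "strand": feat.strand,
                "orf_length": int(feat.attributes.get("orf_length", [feat.end - feat.start + 1])[0]),
                "source": feat.attributes.get("prediction_source", ["unknown"])[0],
            }
        )
    return pd.DataFrame(rows).sort_values(["scaffold", "start"]).reset_index(drop=True)


def write_density_bed(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False,
                 columns=["scaffold", "start", "end", "cover_ratio"], float_format="%.6f")
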