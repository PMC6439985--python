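"""Evaluation metrics for spliced alignments and orthology groupings.

All metrics are precision / recall / f-score triples:

* exon-extremity metrics compare the exon boundaries a set of spliced
  alignments induces against one of three references: real CDS exon
  extremities (A), real gene exon extremities (B), or canonical gene
  splice sites (C, the subset of annotated intron boundaries carrying
  GT..AG dinucleotides);
* alignment-pair metrics compare the set of aligned nucleotide pairs of
  a computed alignment against a true alignment;
* clustering metrics compare co-clustered CDS pairs of a computed
  orthology grouping against the true groups.

Precision is ``None`` (undefined) when nothing was predicted; the
f-score is the harmonic mean 2pr/(p+r) and is ``None`` whenever either
component is undefined or their sum is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import (
    CDSSequenceRecord,
    GeneRecord,
    SplicedAlignment,
    alignment_introns,
)

__all__ = [
    "PRF",
    "exon_extremity_prf",
    "alignment_pair_prf",
    "clustering_prf",
    "summarize",
]


@dataclass(frozen=True)
class PRF:
    """Precision / recall / f-score, any of which may be undefined."""

    precision: Optional[float]
    recall: Optional[float]

    @property
    def fscore(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2.0 * p * r / (p + r)

    @staticmethod
    def from_sets(predicted: set, reference: set) -> "PRF":
        tp = len(predicted & reference)
        precision = tp / len(predicted) if predicted else None
        recall = tp / len(reference) if reference else None
        return PRF(precision, recall)


def _canonical_reference(gene: GeneRecord) -> set[tuple[str, int]]:
    """Gene positions bounding annotated introns with GT..AG ends."""
    out = set()
    seq = gene.sequence
    for b, a in gene.known_introns():
        if seq[b : b + 2] == "GT" and seq[a - 3 : a - 1] == "AG":
            out.add((gene.id, b))
            out.add((gene.id, a))
    return out


def exon_extremity_prf(
    alignments: Iterable[SplicedAlignment],
    cds_records: Mapping[str, CDSSequenceRecord],
    gene_records: Mapping[str, GeneRecord],
    reference: str = "cds",
    *,
    tolerance: int = 0,
) -> PRF:
    """Compare inferred exon extremities against a reference set.

    ``reference`` is ``"cds"`` (A: CDS-side block boundaries vs real CDS
    exon extremities), ``"gene"`` (B: gene-side block boundaries vs real
    gene exon extremities) or ``"canonical"`` (C: induced intron
    boundaries vs canonical annotated splice sites).  Matching is exact
    coordinate equality unless a +/- ``tolerance`` is given.
    """
    if reference not in ("cds", "gene", "canonical"):
        raise ValueError(f"unknown reference {reference!r}")
    predicted: set[tuple[str, int]] = set()
    used_cds: set[str] = set()
    used_genes: set[str] = set()
    for aln in alignments:
        used_cds.add(aln.cds_id)
        used_genes.add(aln.gene_id)
        if reference == "cds":
            for b in aln.conserved_blocks():
                predicted.add((aln.cds_id, b.k))
                predicted.add((aln.cds_id, b.l))
        elif reference == "gene":
            for b in aln.conserved_blocks():
                predicted.add((aln.gene_id, b.a))
                predicted.add((aln.gene_id, b.b))
        else:
            for b, a in alignment_introns(aln):
                predicted.add((aln.gene_id, b))
                predicted.add((aln.gene_id, a))

    ref: set[tuple[str, int]] = set()
    if reference == "cds":
        for cid in used_cds:
            for k, l in cds_records[cid].local_exons:
                ref.add((cid, k))
                ref.add((cid, l))
    elif reference == "gene":
        for gid in used_genes:
            for e in gene_records[gid].exon_set:
                ref.add((gid, e.start))
                ref.add((gid, e.end))
    else:
        for gid in used_genes:
            ref |= _canonical_reference(gene_records[gid])

    if tolerance == 0:
        return PRF.from_sets(predicted, ref)
    tp_pred = sum(
        1
        for key, pos in predicted
        if any(k2 == key and abs(p2 - pos) <= tolerance for k2, p2 in ref)
    )
    tp_ref = sum(
        1
        for key, pos in ref
        if any(k2 == key and abs(p2 - pos) <= tolerance for k2, p2 in predicted)
    )
    precision = tp_pred / len(predicted) if predicted else None
    recall = tp_ref / len(ref) if ref else None
    return PRF(precision, recall)


def alignment_pair_prf(
    predicted: SplicedAlignment, truth: SplicedAlignment
) -> PRF:
    """Aligned-nucleotide-pair precision/recall of one computed alignment
    against the true alignment of the same (CDS, gene) pair."""
    if (predicted.cds_id, predicted.gene_id) != (truth.cds_id, truth.gene_id):
        raise ValueError("alignments are not on the same (CDS, gene) pair")
    return PRF.from_sets(predicted.pair_coordinates(), truth.pair_coordinates())


def _co_pairs(groups: Iterable[Iterable[str]]) -> set[frozenset[str]]:
    pairs = set()
    for group in groups:
        members = sorted(group)
        for i, u in enumerate(members):
            for v in members[i + 1 :]:
                pairs.add(frozenset((u, v)))
    return pairs


def clustering_prf(
    predicted_groups: Iterable[Iterable[str]],
    true_groups: Iterable[Iterable[str]],
) -> PRF:
    """Pair-based precision/recall of a CDS clustering against the truth.

    Precision is undefined (``None``) when the computed clustering
    co-clusters no pair at all.  Both clusterings must partition the
    same CDS universe.
    """
    pred = [set(g) for g in predicted_groups]
    true = [set(g) for g in true_groups]
    u_pred = set().union(*pred) if pred else set()
    u_true = set().union(*true) if true else set()
    if u_pred != u_true:
        raise ValueError("clusterings cover different CDS universes")
    return PRF.from_sets(_co_pairs(pred), _co_pairs(true))


def summarize(results: Sequence[Mapping[str, object]]) -> dict:
    """Aggregate per-run metric dicts into mean +/- population SD.

    ``results`` is a sequence of flat dicts; non-numeric or ``None``
    values are skipped.  Entries sharing the keys ``mode`` and
    ``dataset`` (when present) are grouped together.
    """
    if not results:
        raise ValueError("nothing to summarize")
    grouped: dict[tuple, list[Mapping[str, object]]] = {}
    for row in results:
        key = (row.get("mode"), row.get("dataset"))
        grouped.setdefault(key, []).append(row)
    report: dict = {}
    for (mode, dataset), rows in sorted(grouped.items(), key=str):
        metrics: dict[str, dict[str, float]] = {}
        for name in sorted({k for r in rows for k in r} - {"mode", "dataset"}):
            vals = [
                float(r[name])
                for r in rows
                if isinstance(r.get(name), (int, float))
                and math.isfinite(float(r[name]))
            ]
            if vals:
                arr = np.asarray(vals)
                metrics[name] = {
                    "mean": float(arr.mean()),
                    "sd": float(arr.std()),  # population SD
                    "n": len(vals),
                }
        label = "/".join(str(x) for x in (mode, dataset) if x is not None) or "all"
        report[label] = metrics
    return report
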