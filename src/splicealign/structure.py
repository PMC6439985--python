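"""Preliminary stage: infer splicing structures from sequences alone.

When exon annotations are not provided, the exon chain of each CDS is
recovered by spliced-aligning the CDS against its own gene at 100%
identity: the chain must spell the CDS sequence exactly.  Because the
identity requirement is exact, the search is an exact multi-split
string search rather than a run of the heuristic aligner.

Among the (possibly many) exact chains, the search prefers chains whose
introns carry canonical GT..AG ends (a first, constrained pass), then
fewer/longer exons (matches are extended maximally first), then the
leftmost placement.  The returned chain always round-trips: extracting
its exon sequences reproduces the input CDS exactly.
"""

from __future__ import annotations

import warnings
from typing import Optional

from .core import CDSChain, Exon, GeneRecord, normalize_dna

__all__ = ["StructureInferenceError", "infer_structure", "build_family_structures"]


class StructureInferenceError(ValueError):
    """No exact exon chain spells the CDS within its own gene."""


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _search(
    cds: str, gene: str, min_intron: int, canonical: bool
) -> Optional[list[tuple[int, int]]]:
    """DFS for an exon chain (0-based, end-exclusive intervals) spelling
    ``cds`` inside ``gene``; longest-exon-first, leftmost-start-first."""
    m, n = len(cds), len(gene)
    dead: set[tuple[int, int]] = set()  # (cds_pos, exon_start) with no chain

    def from_position(i: int, p: int) -> Optional[list[tuple[int, int]]]:
        if (i, p) in dead:
            return None
        match = _lcp(cds[i:], gene[p:])
        if i + match == m:
            return [(p, p + match)]
        for e in range(match, 0, -1):
            if canonical and gene[p + e : p + e + 2] != "GT":
                continue
            tail = cds[i + e]
            q = p + e + min_intron
            limit = n - (m - i - e)
            while q <= limit:
                q = gene.find(tail, q, limit + 1)
                if q < 0:
                    break
                if not canonical or gene[q - 2 : q] == "AG":
                    rest = from_position(i + e, q)
                    if rest is not None:
                        return [(p, p + e)] + rest
                q += 1
        dead.add((i, p))
        return None

    limit = n - m
    p = -1
    while True:
        p = gene.find(cds[0], p + 1, limit + 1)
        if p < 0:
            return None
        chain = from_position(0, p)
        if chain is not None:
            return chain


def infer_structure(
    cds_seq: str,
    own_gene_seq: str,
    *,
    cds_id: str = "cds",
    min_intron: int = 4,
) -> CDSChain:
    """Infer the exon chain of a CDS on its own gene (exact, PID 100).

    A canonical-splice-site pass runs first; if no chain with GT..AG
    introns exists, the donor/acceptor constraint is dropped.  Raises
    :class:`StructureInferenceError` when no exact chain exists at all.
    """
    cds_seq = normalize_dna(cds_seq)
    own_gene_seq = normalize_dna(own_gene_seq)
    if not cds_seq:
        raise ValueError("empty CDS sequence")
    if len(cds_seq) > len(own_gene_seq):
        raise StructureInferenceError(
            f"CDS {cds_id!r} is longer than its own gene"
        )
    chain = _search(cds_seq, own_gene_seq, min_intron, canonical=True)
    if chain is None:
        chain = _search(cds_seq, own_gene_seq, min_intron, canonical=False)
    if chain is None:
        raise StructureInferenceError(
            f"no exact spliced occurrence of CDS {cds_id!r} in its own gene"
        )
    exons = tuple(Exon(start + 1, end) for start, end in chain)
    return CDSChain(id=cds_id, exons=exons)


def build_family_structures(
    genes: list[tuple[str, str, list[tuple[str, str]]]],
    *,
    min_intron: int = 4,
) -> list[GeneRecord]:
    """Infer structures for a whole family.

    ``genes`` is a list of (gene_id, gene_seq, [(cds_id, cds_seq), ...])
    with each CDS paired with its own gene.  CDS whose structure cannot
    be inferred are skipped with a warning; the gene's exon set is the
    union of the inferred chains.
    """
    out = []
    for gene_id, gene_seq, cds_list in genes:
        chains = []
        for cds_id, cds_seq in cds_list:
            try:
                chains.append(
                    infer_structure(
                        cds_seq, gene_seq, cds_id=cds_id, min_intron=min_intron
                    )
                )
            except StructureInferenceError as exc:
                warnings.warn(f"structure inference failed: {exc}")
        out.append(GeneRecord(id=gene_id, sequence=gene_seq, cds_set=chains))
    return out
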