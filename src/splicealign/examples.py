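"""Small synthetic worked examples used in tests and documentation."""

from __future__ import annotations

from .core import CDSChain, Exon, GeneRecord

__all__ = ["toy_gene"]


def toy_gene() -> GeneRecord:
    """A synthetic 63-nt gene with two overlapping isoform chains.

    The gene carries two CDS chains sharing exon material:
    ``c1 = {(9,12), (18,29), (49,56)}`` with CDS sequence
    ``ATGCAAGCAGGTCTGGGGGAATGA`` and
    ``c2 = {(4,12), (18,23), (35,43), (49,60)}``, inducing a gene exon
    set of 7 distinct exons.  All introns carry canonical GT..AG ends
    (the donor of c2's second intron falls inside c1's second exon,
    whose sequence happens to provide the GT), so structure inference
    recovers both chains exactly.
    """
    parts = [
        "CCCCCCCC",      # 1-8   5' flank
        "ATGC",          # 9-12  c1 exon 1 (inside c2 exon 1 = 4..12)
        "GTCAG",         # 13-17 intron (GT..AG)
        "AAGCAGGTCTGG",  # 18-29 c1 exon 2; c2 exon 2 = 18..23
        "GTCAG",         # 30-34 intron for c1; 30-31 also c2 donor
        "TACCATTAC",     # 35-43 c2 exon 3
        "GTCAG",         # 44-48 intron
        "GGGAATGA",      # 49-56 c1 exon 3 (inside c2 exon 4 = 49..60)
        "CTTT",          # 57-60 tail of c2 exon 4
        "CCC",           # 61-63 3' flank
    ]
    sequence = "".join(parts)
    assert len(sequence) == 63
    c1 = CDSChain(id="c1", exons=(Exon(9, 12), Exon(18, 29), Exon(49, 56)))
    c2 = CDSChain(
        id="c2", exons=(Exon(4, 12), Exon(18, 23), Exon(35, 43), Exon(49, 60))
    )
    return GeneRecord(id="g", sequence=sequence, cds_set=[c1, c2])
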