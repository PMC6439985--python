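"""Core model: chains, blocks, alignments and their derived quantities."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from splicealign.core import (
    AlignmentError,
    Block,
    CDSChain,
    ChainError,
    CoordinateError,
    Exon,
    GeneRecord,
    SplicedAlignment,
    alignment_introns,
    alignment_junctions,
    cds_coverage,
    complete_chain,
    extract_cds_sequence,
    induced_introns,
    percent_identity,
)


# ---------------------------------------------------------------- validation


def test_exon_and_chain_validation():
    with pytest.raises(ChainError):
        Exon(5, 3)
    with pytest.raises(CoordinateError):
        Exon(0, 3)
    with pytest.raises(ChainError):
        CDSChain(id="c", exons=(Exon(1, 10), Exon(10, 20)))  # overlap
    with pytest.raises(CoordinateError):
        GeneRecord(
            id="g",
            sequence="ACGT",
            cds_set=[CDSChain(id="c", exons=(Exon(1, 10),))],
        )


def test_alignment_chain_invariants():
    with pytest.raises(AlignmentError):  # first block must start at 1
        SplicedAlignment("c", "g", [Block(2, 5, 1, 4)])
    with pytest.raises(AlignmentError):  # blocks must tile the CDS
        SplicedAlignment("c", "g", [Block(1, 4, 1, 4), Block(6, 8, 10, 12)])
    with pytest.raises(AlignmentError):  # gene intervals must increase
        SplicedAlignment("c", "g", [Block(1, 4, 10, 13), Block(5, 8, 2, 5)])


# ------------------------------------------------------- CDS extraction


def test_extract_cds_sequence_toy(toy):
    rec = extract_cds_sequence(toy, toy.cds_set[0])
    assert rec.sequence == "ATGCAAGCAGGTCTGGGGGAATGA"
    assert rec.local_exons == ((1, 4), (5, 16), (17, 24))
    assert rec.junctions() == frozenset({4, 16})


def test_extract_single_exon_is_prefix():
    gene = GeneRecord(id="g", sequence="ACGTACGTACGT")
    chain = CDSChain(id="c", exons=(Exon(1, 7),))
    rec = extract_cds_sequence(gene, chain)
    assert rec.sequence == gene.sequence[:7]
    assert rec.local_exons == ((1, 7),)


def test_extract_matches_slicing_oracle():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 200))
    gene = GeneRecord(id="g", sequence=seq)
    bounds = sorted(rng.choice(np.arange(1, 201), size=6, replace=False))
    exons = tuple(Exon(int(bounds[i]), int(bounds[i + 1]) - 1) for i in (0, 2, 4))
    chain = CDSChain(id="c", exons=exons)
    rec = extract_cds_sequence(gene, chain)
    oracle = "".join(seq[e.start - 1 : e.end] for e in exons)
    assert rec.sequence == oracle
    assert len(rec.sequence) == sum(len(e) for e in exons)


def test_gene_exon_set_is_union_of_chains(toy):
    assert sorted((e.start, e.end) for e in toy.exon_set) == [
        (4, 12), (9, 12), (18, 23), (18, 29), (35, 43), (49, 56), (49, 60),
    ]


# ------------------------------------------------------------- introns


def test_induced_introns_toy(toy):
    assert induced_introns(toy.cds_set[0]) == frozenset({(12, 18), (29, 49)})
    single = CDSChain(id="s", exons=(Exon(3, 9),))
    assert induced_introns(single) == frozenset()


def test_induced_intron_count_and_order():
    rng = np.random.default_rng(1)
    pos = np.cumsum(rng.integers(2, 9, size=8))
    exons = tuple(Exon(int(pos[i]), int(pos[i + 1]) - 1) for i in range(0, 6, 2))
    introns = induced_introns(CDSChain(id="c", exons=exons))
    assert len(introns) == len(exons) - 1
    assert all(b < a for b, a in introns)


def _five_block_alignment():
    # deleted, conserved, deleted, conserved, conserved
    return SplicedAlignment(
        "c",
        "g",
        [
            Block(1, 3, 0, 0),
            Block(4, 8, 10, 14),
            Block(9, 11, 0, 0),
            Block(12, 15, 30, 33),
            Block(16, 20, 50, 54),
        ],
    )


def test_alignment_introns_skip_deleted_blocks():
    aln = _five_block_alignment()
    # only the successive conserved pair A[4], A[5] induces an intron
    assert alignment_introns(aln) == frozenset({(33, 50)})
    assert alignment_junctions(aln) == frozenset({15})


def test_alignment_introns_all_conserved():
    aln = SplicedAlignment(
        "c",
        "g",
        [Block(1, 4, 1, 4), Block(5, 9, 20, 24), Block(10, 12, 40, 42)],
    )
    assert len(alignment_introns(aln)) == 2
    assert len(alignment_junctions(aln)) == 2


def test_all_deleted_alignment_has_no_introns():
    aln = SplicedAlignment("c", "g", [Block(1, 9, 0, 0)])
    assert alignment_introns(aln) == frozenset()
    assert alignment_junctions(aln) == frozenset()
    assert cds_coverage(aln) == 0.0
    assert percent_identity(aln) is None


# ----------------------------------------------------- identity & coverage


def test_percent_identity_examples():
    full = SplicedAlignment(
        "c", "g", [Block(1, 4, 1, 4, cds_aln="ACGT", gene_aln="ACGT")]
    )
    assert percent_identity(full) == 100.0
    partial = SplicedAlignment(
        "c", "g", [Block(1, 4, 1, 4, cds_aln="ACGT", gene_aln="ACGA")]
    )
    assert percent_identity(partial) == 75.0


def test_percent_identity_counts_gap_columns_by_default():
    aln = SplicedAlignment(
        "c", "g", [Block(1, 4, 1, 6, cds_aln="AC--GT", gene_aln="ACTAGT")]
    )
    assert percent_identity(aln) == pytest.approx(100 * 4 / 6)
    assert percent_identity(aln, exclude_gap_columns=True) == 100.0


def test_percent_identity_random_block_matches_column_count():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(4, 12))
        row1 = "".join(rng.choice(list("ACGT-"), n))
        row2 = "".join(rng.choice(list("ACGT-"), n))
        # avoid all-gap / double-gap columns at the block bookkeeping level
        row1 = row1 if row1.strip("-") else "A" * n
        row2 = row2 if row2.strip("-") else "C" * n
        nc = len(row1.replace("-", ""))
        ng = len(row2.replace("-", ""))
        if nc == 0 or ng == 0:
            continue
        b = Block(1, nc, 5, 4 + ng, cds_aln=row1, gene_aln=row2)
        aln = SplicedAlignment("c", "g", [b])
        hand = sum(1 for x, y in zip(row1, row2) if x == y and x != "-")
        assert percent_identity(aln) == pytest.approx(100 * hand / n)


def test_cds_coverage_fractions():
    aln = _five_block_alignment()
    covered = (8 - 4 + 1) + (15 - 12 + 1) + (20 - 16 + 1)
    assert cds_coverage(aln) == pytest.approx(covered / 20)
    full = SplicedAlignment("c", "g", [Block(1, 10, 1, 10)])
    assert cds_coverage(full) == 1.0


def test_replacing_deleted_block_raises_coverage_and_identity():
    before = SplicedAlignment(
        "c",
        "g",
        [Block(1, 4, 1, 4, cds_aln="ACGT", gene_aln="ACGT"), Block(5, 8, 0, 0)],
    )
    after = SplicedAlignment(
        "c",
        "g",
        [
            Block(1, 4, 1, 4, cds_aln="ACGT", gene_aln="ACGT"),
            Block(5, 8, 10, 13, cds_aln="AAAA", gene_aln="ATTT"),
        ],
    )
    assert cds_coverage(after) > cds_coverage(before)
    assert percent_identity(after) is not None


# --------------------------------------------------------------- properties


@st.composite
def random_alignments(draw):
    n_blocks = draw(st.integers(1, 6))
    blocks = []
    k = 1
    a = 1
    for _ in range(n_blocks):
        length = draw(st.integers(1, 5))
        deleted = draw(st.booleans())
        if deleted:
            blocks.append(Block(k, k + length - 1, 0, 0))
        else:
            gap = draw(st.integers(0, 7))
            blocks.append(Block(k, k + length - 1, a + gap, a + gap + length - 1))
            a = a + gap + length
        k += length
    return SplicedAlignment("c", "g", blocks)


@given(random_alignments())
def test_blocks_tile_cds_exactly_once(aln):
    positions = [p for b in aln.blocks for p in range(b.k, b.l + 1)]
    assert positions == list(range(1, aln.blocks[-1].l + 1))


@given(random_alignments())
def test_intron_identity_when_all_conserved(aln):
    if all(b.is_conserved for b in aln.blocks):
        assert (
            len(alignment_introns(aln))
            == len(alignment_junctions(aln))
            == len(aln) - 1
        )
    else:
        assert len(alignment_introns(aln)) <= len(aln) - 1


def test_complete_chain_fills_gaps():
    aln = complete_chain([Block(5, 8, 10, 13)], 12, "c", "g")
    kinds = [b.is_deleted for b in aln.blocks]
    assert kinds == [True, False, True]
    assert aln.blocks[0].k == 1 and aln.blocks[-1].l == 12
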