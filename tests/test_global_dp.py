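"""Global spliced DP: reductions, planted introns, chain-enumeration oracle."""

from functools import lru_cache

import numpy as np
import pytest
from Bio import Align

from splicealign.core import Block, CDSSequenceRecord, GeneRecord, cds_coverage
from splicealign.global_dp import (
    DPSizeError,
    ScoringScheme,
    accept_fragment,
    run_global_stage,
    spliced_dp,
)
from splicealign.core import complete_chain


def _nw_aligner(scheme):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap
    aligner.extend_gap_score = scheme.gap
    return aligner


def chain_oracle(cds, gene, scheme, cds_junctions=frozenset(),
                 known_introns=frozenset(), donor_sites=frozenset(),
                 acceptor_sites=frozenset()):
    """Independent objective maximizer: enumerate chains of conserved
    blocks (gene gaps between blocks are introns of allowed length),
    score each block with an off-the-shelf global aligner, add the three
    structure bonuses per intron, and take the maximum."""
    m, n = len(cds), len(gene)
    aligner = _nw_aligner(scheme)
    allowed_jumps = {(b, a - 1) for b, a in known_introns}

    @lru_cache(maxsize=None)
    def nw(i, i2, j, j2):
        return aligner.score(cds[i:i2], gene[j:j2])

    def intron_bonus(i, jp, j):
        s = scheme.splicesignals(gene, jp, j + 1)
        if jp in donor_sites:
            s += scheme.site_known
        if (j + 1) in acceptor_sites:
            s += scheme.site_known
        if i in cds_junctions:
            s += scheme.exon_junction
        return s

    @lru_cache(maxsize=None)
    def best(i, j):
        # best score completing the alignment from (i consumed, j consumed)
        out = float("-inf")
        for i2 in range(i + 1, m + 1):
            for j2 in range(j + 1, n + 1):
                s = nw(i, i2, j, j2)
                if i2 == m:
                    if j2 == n:
                        out = max(out, s)
                    continue
                for j3 in range(j2 + 1, n):
                    length = j3 - j2
                    ok = scheme.imin <= length <= scheme.imax or (
                        (j2, j3) in allowed_jumps
                    )
                    if ok:
                        out = max(out, s + intron_bonus(i2, j2, j3) + best(i2, j3))
        return out

    return best(0, 0)


def test_reduces_to_plain_global_alignment_without_introns():
    rng = np.random.default_rng(0)
    scheme = ScoringScheme(imin=10_000, imax_span=0)
    aligner = _nw_aligner(scheme)
    for _ in range(40):
        m, n = int(rng.integers(1, 10)), int(rng.integers(1, 14))
        c = "".join(rng.choice(list("ACGT"), m))
        g = "".join(rng.choice(list("ACGT"), n))
        score, blocks = spliced_dp(c, g, scheme)
        assert score == pytest.approx(aligner.score(c, g))
        assert len(blocks) == 1  # no intron can be opened


def test_planted_intron_recovered_at_planted_boundaries():
    e1, e2 = "ATGGCA", "GATTAC"
    intron = "GT" + "C" * 8 + "AG"
    gene = e1 + intron + e2
    scheme = ScoringScheme(imin=5, imax_span=10)
    score, blocks = spliced_dp(e1 + e2, gene, scheme, cds_junctions=frozenset({6}))
    assert [(b.k, b.l, b.a, b.b) for b in blocks] == [(1, 6, 1, 6), (7, 12, 19, 24)]
    # the jump collected the canonical-signal and junction bonuses
    signal = scheme.donor_score("GT") + scheme.acceptor_score("AG")
    assert score == pytest.approx(12 * scheme.match + signal + scheme.exon_junction)


def test_dp_equals_chain_enumeration_oracle_small_sweep():
    rng = np.random.default_rng(42)
    for _ in range(40):
        m = int(rng.integers(2, 8))
        n = int(rng.integers(4, 14))
        c = "".join(rng.choice(list("ACGT"), m))
        g = "".join(rng.choice(list("ACGT"), n))
        scheme = ScoringScheme(imin=2, imax_span=3)
        junc = frozenset({int(rng.integers(1, m))}) if m > 1 else frozenset()
        known = frozenset()
        if n >= 6 and rng.random() < 0.5:
            b = int(rng.integers(1, n - 3))
            a = int(rng.integers(b + 2, n))
            known = frozenset({(b, a)})
        donors = frozenset(b for b, _ in known)
        acceptors = frozenset(a for _, a in known)
        score, _ = spliced_dp(
            c, g, scheme, cds_junctions=junc, known_introns=known,
            donor_sites=donors, acceptor_sites=acceptors,
        )
        expect = chain_oracle(c, g, scheme, junc, known, donors, acceptors)
        assert score == pytest.approx(expect), (c, g, junc, known)


def test_positive_known_junction_never_decreases_optimum():
    rng = np.random.default_rng(17)
    for _ in range(25):
        m, n = int(rng.integers(3, 8)), int(rng.integers(8, 14))
        c = "".join(rng.choice(list("ACGT"), m))
        g = "".join(rng.choice(list("ACGT"), n))
        scheme = ScoringScheme(imin=2, imax_span=4)
        bare, _ = spliced_dp(c, g, scheme)
        junc = frozenset({int(rng.integers(1, m))})
        boosted, _ = spliced_dp(c, g, scheme, cds_junctions=junc)
        assert boosted >= bare - 1e-9


def test_size_cap_refuses_oversized_problems():
    with pytest.raises(DPSizeError):
        spliced_dp("A" * 100, "C" * 100, ScoringScheme(), max_cells=1000)


def test_accept_fragment_thresholds():
    perfect = Block(1, 4, 1, 4, cds_aln="ACGT", gene_aln="ACGT")
    exact30 = Block(5, 14, 5, 14, cds_aln="ACGTACGTAC", gene_aln="ACGAAAAAAA")
    zero = Block(15, 18, 20, 23, cds_aln="AAAA", gene_aln="CCCC")
    out = accept_fragment([perfect, exact30, zero], beta=30.0)
    assert out[0].is_conserved
    assert out[1].is_conserved  # identity exactly beta is kept (>= rule)
    assert out[2].is_deleted


def _gene_with_structures(seq, chains):
    return GeneRecord(id="h", sequence=seq, cds_set=chains)


def test_global_stage_recovers_missing_middle_exon():
    rng = np.random.default_rng(3)
    e1 = "".join(rng.choice(list("ACGT"), 18))
    e2 = "".join(rng.choice(list("ACGT"), 12))
    e3 = "".join(rng.choice(list("ACGT"), 18))
    i1 = "GT" + "".join(rng.choice(list("ACGT"), 16)) + "AG"
    i2 = "GT" + "".join(rng.choice(list("ACGT"), 16)) + "AG"
    gene_seq = e1 + i1 + e2 + i2 + e3
    gene = _gene_with_structures(gene_seq, [])
    cds = CDSSequenceRecord(
        id="c",
        sequence=e1 + e2 + e3,
        local_exons=((1, 18), (19, 30), (31, 48)),
    )
    # anchors cover exons 1 and 3 only
    anchors = [
        Block(1, 18, 1, 18, cds_aln=e1, gene_aln=e1),
        Block(31, 48, 59, 76, cds_aln=e3, gene_aln=e3),
    ]
    partial = complete_chain(anchors, 48, "c", "h")
    scheme = ScoringScheme(imin=10, imax_span=30)
    out = run_global_stage(partial, gene, cds, scheme, beta=30.0)
    middle = [b for b in out.blocks if b.k == 19]
    assert middle and middle[0].is_conserved
    assert (middle[0].a, middle[0].b) == (39, 50)
    assert cds_coverage(out) == 1.0


def test_global_stage_noop_when_all_exons_touched():
    cds = CDSSequenceRecord(id="c", sequence="ACGTACGT",
                            local_exons=((1, 4), (5, 8)))
    gene = _gene_with_structures("ACGTACGTACGTACGT", [])
    blocks = [Block(1, 4, 1, 4, cds_aln="ACGT", gene_aln="ACGT"),
              Block(5, 8, 9, 12, cds_aln="ACGT", gene_aln="ACGT")]
    partial = complete_chain(blocks, 8, "c", "h")
    out = run_global_stage(partial, gene, cds, ScoringScheme(), beta=30.0)
    assert out is partial


def test_global_stage_with_no_anchors_runs_single_dp():
    rng = np.random.default_rng(9)
    e1 = "".join(rng.choice(list("ACGT"), 15))
    e2 = "".join(rng.choice(list("ACGT"), 15))
    i1 = "GT" + "".join(rng.choice(list("ACGT"), 20)) + "AG"
    gene_seq = e1 + i1 + e2
    gene = _gene_with_structures(gene_seq, [])
    cds = CDSSequenceRecord(id="c", sequence=e1 + e2,
                            local_exons=((1, 15), (16, 30)))
    partial = complete_chain([], 30, "c", "h")
    scheme = ScoringScheme(imin=10, imax_span=30)
    out = run_global_stage(partial, gene, cds, scheme, beta=30.0)
    assert cds_coverage(out) == 1.0
    direct_score, direct_blocks = spliced_dp(
        cds.sequence, gene_seq, scheme,
        cds_junctions=frozenset({15}),
    )
    assert [(b.k, b.l, b.a, b.b) for b in out.conserved_blocks()] == [
        (b.k, b.l, b.a, b.b) for b in direct_blocks
    ]
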