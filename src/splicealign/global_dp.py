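"""Stage 3: global spliced alignment by dynamic programming.

The DP aligns a CDS segment against a gene segment and may, between two
aligned blocks, jump over a gene region interpreted as an intron.  An
intron jump is rewarded according to three structure terms on top of the
nucleotide similarity:

* splice signals - canonical donor/acceptor dinucleotides (GT..AG, with
  reduced bonuses for the rarer GC..AG and AT..AC pairs) at the intron
  extremities;
* splice sites - intron extremities coinciding with annotated exon
  boundaries of the gene;
* exon junction - the CDS-side junction coinciding with a real exon
  junction of the CDS.

Jumps are allowed either onto an annotated intron of the gene (no length
constraint) or over any gene region whose length falls in the window
``[imin, imax]``.  Gap scoring is linear.  The donor and acceptor
contributions are additive, which keeps the length-window case amenable
to a sliding-window maximum and the whole DP quadratic.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, replace
from typing import Iterable

from .core import (
    Block,
    CDSSequenceRecord,
    GeneRecord,
    SplicedAlignment,
    block_identity,
    complete_chain,
)

__all__ = [
    "ScoringScheme",
    "DPSizeError",
    "spliced_dp",
    "accept_fragment",
    "run_global_stage",
]

NEG = float("-inf")


class DPSizeError(ValueError):
    """The DP matrix would exceed the configured safety cap."""


@dataclass(frozen=True)
class ScoringScheme:
    """Score components of the structure-aware spliced alignment objective.

    Nucleotide-level scores are linear-gap.  ``donor_signal`` and
    ``acceptor_signal`` score the intron-terminal dinucleotides; a fully
    canonical GT..AG intron collects 2 + 2 = 4, the rarer pairs less,
    and unrecognized dinucleotides nothing.  Signal bonuses are kept
    small relative to the annotation-based terms: raw dinucleotides are
    weak evidence and large values would reward fabricating introns at
    pseudo-sites.  ``site_known`` is granted
    per intron extremity that coincides with an annotated gene exon
    boundary (both ends known = 8, one = 4, none = 0), and
    ``exon_junction`` when the CDS-side junction is a real exon junction
    of the CDS.  ``imax`` is tied to ``imin`` through the configured
    window span ``imax_span`` (default 5000).
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0
    donor_signal: tuple[tuple[str, float], ...] = (("GT", 2.0), ("GC", 1.0), ("AT", 1.0))
    acceptor_signal: tuple[tuple[str, float], ...] = (("AG", 2.0), ("AC", 1.0))
    site_known: float = 4.0
    exon_junction: float = 8.0
    imin: int = 30
    imax_span: int = 5000

    def __post_init__(self) -> None:
        if self.imin < 1 or self.imax_span < 0:
            raise ValueError("imin must be >= 1 and imax_span >= 0")

    @property
    def imax(self) -> int:
        return self.imin + self.imax_span

    def substitution(self, x: str, y: str) -> float:
        return self.match if x == y else self.mismatch

    def donor_score(self, dinuc: str) -> float:
        return dict(self.donor_signal).get(dinuc, 0.0)

    def acceptor_score(self, dinuc: str) -> float:
        return dict(self.acceptor_signal).get(dinuc, 0.0)

    def splicesignals(self, gene_seq: str, b: int, a: int) -> float:
        """Signal score of an intron (b, a): nucleotides b+1..a-1 of
        ``gene_seq`` (1-based), donor dinucleotide at b+1..b+2, acceptor
        at a-3..a-1 exclusive of a."""
        donor = gene_seq[b : b + 2]
        acceptor = gene_seq[a - 3 : a - 1]
        return self.donor_score(donor) + self.acceptor_score(acceptor)


# DP states track what was consumed since the last intron jump (or the
# start): bit 1 = >=1 gene char, bit 2 = >=1 CDS char.  Jumps are only
# allowed from state 3 and land in state 0, which guarantees that every
# block between two introns aligns at least one CDS and one gene
# character (i.e. is a genuine conserved block).


def spliced_dp(
    cds_seg: str,
    gene_seg: str,
    scheme: ScoringScheme,
    *,
    cds_junctions: frozenset[int] = frozenset(),
    known_introns: frozenset[tuple[int, int]] = frozenset(),
    donor_sites: frozenset[int] = frozenset(),
    acceptor_sites: frozenset[int] = frozenset(),
    max_cells: int = 2_000_000,
    free_gene_prefix: bool = False,
    free_gene_suffix: bool = False,
) -> tuple[float, list[Block]]:
    """Optimal global spliced alignment of a CDS segment vs a gene segment.

    All coordinates in the keyword sets are segment-local and 1-based:
    ``cds_junctions`` holds CDS positions ending a real exon (other than
    the last), ``known_introns`` holds annotated introns as (b, a) pairs
    of flanking exonic positions, ``donor_sites``/``acceptor_sites`` the
    annotated exon end/start positions of the gene.  Returns the optimal
    score and the block chain (blocks carry their gapped rows).

    ``free_gene_prefix``/``free_gene_suffix`` let leading/trailing gene
    characters go unconsumed at no cost: the inter-anchor stage uses
    this because a window between two anchored blocks starts and ends
    inside the introns that connect to those anchors, and intron
    material must not be charged as alignment gaps.
    """
    m, n = len(cds_seg), len(gene_seg)
    if m == 0 or n == 0:
        raise ValueError("both segments must be non-empty")
    if m * n > max_cells:
        raise DPSizeError(
            f"DP matrix {m} x {n} exceeds the safety cap of {max_cells} cells"
        )

    gap = scheme.gap
    imin, imax = scheme.imin, scheme.imax
    # jump pairs (j', j): intron occupies gene positions j'+1 .. j, the
    # block after the jump resumes at j+1.  Annotated introns (b, a)
    # correspond to the jump (b, a-1).
    known_jumps: dict[int, list[int]] = {}
    for b, a in known_introns:
        if 1 <= b < a - 1 <= n - 1:
            known_jumps.setdefault(a - 1, []).append(b)

    def donor_part(jp: int) -> float:
        s = scheme.donor_score(gene_seg[jp : jp + 2])
        if jp in donor_sites:
            s += scheme.site_known
        return s

    def acceptor_part(j: int) -> float:
        s = scheme.acceptor_score(gene_seg[j - 2 : j])
        if (j + 1) in acceptor_sites:
            s += scheme.site_known
        return s

    def junction_part(i: int) -> float:
        return scheme.exon_junction if i in cds_junctions else 0.0

    # S[s][i][j]; rows kept as full matrices (needed for traceback and
    # because jumps stay within one CDS row i but read arbitrary j').
    S = [[[NEG] * (n + 1) for _ in range(m + 1)] for _ in range(4)]
    S[0][0][0] = 0.0
    if free_gene_prefix:
        # unconsumed leading gene characters (intron tail of the
        # upstream anchor); they do not count as consumed block material
        for j in range(1, n + 1):
            S[0][0][j] = 0.0
    for j in range(1, n + 1):
        S[1][0][j] = j * gap
    for i in range(1, m + 1):
        S[2][i][0] = i * gap

    for i in range(1, m + 1):
        ci = cds_seg[i - 1]
        S0, S1, S2, S3 = S[0][i], S[1][i], S[2][i], S[3][i]
        P0, P1, P2, P3 = S[0][i - 1], S[1][i - 1], S[2][i - 1], S[3][i - 1]
        jump_open = 1 <= i <= m - 1
        junc = junction_part(i) if jump_open else 0.0
        window: deque[tuple[int, float]] = deque()  # (j', W) decreasing W
        for j in range(1, n + 1):
            sub = scheme.substitution(ci, gene_seg[j - 1])
            # state 3: diagonal from any state, vertical from states with
            # the gene bit set, horizontal from states with the CDS bit.
            diag = max(P0[j - 1], P1[j - 1], P2[j - 1], P3[j - 1]) + sub
            up = max(P1[j], P3[j]) + gap
            left = max(S2[j - 1], S3[j - 1]) + gap
            S3[j] = max(diag, up, left)
            # state 2: vertical moves only since the last jump/start
            S2[j] = max(P0[j], P2[j]) + gap
            # state 1: horizontal moves only since the last jump/start
            S1[j] = max(S0[j - 1], S1[j - 1]) + gap
            # state 0: land an intron jump at (i, j)
            if jump_open and j <= n - 1:
                best = NEG
                for jp in known_jumps.get(j, ()):
                    v = S3[jp] + donor_part(jp) + acceptor_part(j) + junc
                    if v > best:
                        best = v
                # sliding-window maximum over j' in [j - imax, j - imin]
                jp_new = j - imin
                if jp_new >= 1:
                    w = S3[jp_new] + donor_part(jp_new)
                    while window and window[-1][1] <= w:
                        window.pop()
                    window.append((jp_new, w))
                while window and window[0][0] < j - imax:
                    window.popleft()
                if window and window[0][1] > NEG:
                    v = window[0][1] + acceptor_part(j) + junc
                    if v > best:
                        best = v
                S0[j] = best

    if free_gene_suffix:
        end_j = max(range(1, n + 1), key=lambda j: S[3][m][j])
    else:
        end_j = n
    score = S[3][m][end_j]
    blocks = _traceback(
        S,
        cds_seg,
        gene_seg,
        scheme,
        known_jumps,
        donor_part,
        acceptor_part,
        junction_part,
        end_j=end_j,
        free_gene_prefix=free_gene_prefix,
    )
    return score, blocks


def _traceback(S, cds_seg, gene_seg, scheme, known_jumps, donor_part,
               acceptor_part, junction_part, *, end_j=None,
               free_gene_prefix=False):
    """Rebuild the optimal chain by local recomputation of the recurrence.

    Preference order on ties: diagonal, then known-intron jump, then
    length-window jump, then CDS gap (vertical), then gene gap
    (horizontal); jump sources prefer the annotated reading and the
    rightmost donor (shortest intron)."""
    m, n = len(cds_seg), len(gene_seg)
    gap = scheme.gap
    imin, imax = scheme.imin, scheme.imax
    i, j, state = m, (n if end_j is None else end_j), 3
    moves: list[tuple] = []  # reversed order
    eps = 1e-9

    def close(x, y):
        return abs(x - y) <= eps

    while i > 0 or j > 0:
        if free_gene_prefix and i == 0 and state == 0:
            break  # remaining gene prefix is free intron material
        val = S[state][i][j]
        if state == 3:
            sub = scheme.substitution(cds_seg[i - 1], gene_seg[j - 1]) if i and j else None
            moved = False
            if i >= 1 and j >= 1:
                for s in (3, 2, 1, 0):
                    if close(val, S[s][i - 1][j - 1] + sub):
                        moves.append(("diag",))
                        i, j, state = i - 1, j - 1, s
                        moved = True
                        break
            if not moved and i >= 1:
                for s in (3, 1):
                    if close(val, S[s][i - 1][j] + gap):
                        moves.append(("up",))
                        i, state = i - 1, s
                        moved = True
                        break
            if not moved and j >= 1:
                for s in (3, 2):
                    if close(val, S[s][i][j - 1] + gap):
                        moves.append(("left",))
                        j, state = j - 1, s
                        moved = True
                        break
            if not moved:
                raise AssertionError("traceback failed in state 3")
        elif state == 2:
            for s in (2, 0):
                if i >= 1 and close(val, S[s][i - 1][j] + gap):
                    moves.append(("up",))
                    i, state = i - 1, s
                    break
            else:
                raise AssertionError("traceback failed in state 2")
        elif state == 1:
            for s in (1, 0):
                if j >= 1 and close(val, S[s][i][j - 1] + gap):
                    moves.append(("left",))
                    j, state = j - 1, s
                    break
            else:
                raise AssertionError("traceback failed in state 1")
        else:  # state 0: undo the jump that landed here
            junc = junction_part(i)
            src = None
            for jp in sorted(known_jumps.get(j, ()), reverse=True):
                if close(val, S[3][i][jp] + donor_part(jp) + acceptor_part(j) + junc):
                    src = jp
                    break
            if src is None:
                for jp in range(j - imin, max(0, j - imax) - 1, -1):
                    if jp >= 1 and close(
                        val, S[3][i][jp] + donor_part(jp) + acceptor_part(j) + junc
                    ):
                        src = jp
                        break
            if src is None:
                raise AssertionError("traceback failed in state 0")
            moves.append(("jump", src, j))
            j, state = src, 3

    moves.reverse()
    return _moves_to_blocks(moves, cds_seg, gene_seg, j_start=j)


def _moves_to_blocks(moves, cds_seg, gene_seg, j_start=0) -> list[Block]:
    blocks: list[Block] = []
    i, j = 0, j_start  # consumed so far
    cur_cds: list[str] = []
    cur_gene: list[str] = []
    k_start = a_start = None

    def flush():
        nonlocal cur_cds, cur_gene, k_start, a_start
        if cur_cds:
            blocks.append(
                Block(
                    k=k_start,
                    l=k_start + len([c for c in cur_cds if c != "-"]) - 1,
                    a=a_start,
                    b=a_start + len([g for g in cur_gene if g != "-"]) - 1,
                    cds_aln="".join(cur_cds),
                    gene_aln="".join(cur_gene),
                )
            )
        cur_cds, cur_gene, k_start, a_start = [], [], None, None

    for mv in moves:
        if mv[0] == "jump":
            flush()
            j = mv[2]
            continue
        if mv[0] == "diag":
            i += 1
            j += 1
            c, g = cds_seg[i - 1], gene_seg[j - 1]
        elif mv[0] == "up":
            i += 1
            c, g = cds_seg[i - 1], "-"
        else:
            j += 1
            c, g = "-", gene_seg[j - 1]
        if k_start is None:
            k_start = i if c != "-" else i + 1
            a_start = j if g != "-" else j + 1
        cur_cds.append(c)
        cur_gene.append(g)
    flush()
    return blocks


def accept_fragment(blocks: Iterable[Block], beta: float) -> list[Block]:
    """Demote conserved blocks with identity below beta to deleted blocks.

    Identity is compared with >= beta, consistent with the extension
    stage.  Kept blocks are returned unchanged.
    """
    out = []
    for b in blocks:
        if b.is_conserved and block_identity(b) < beta:
            out.append(Block(b.k, b.l, 0, 0))
        else:
            out.append(b)
    return out


def run_global_stage(
    partial: SplicedAlignment,
    gene: GeneRecord,
    cds: CDSSequenceRecord,
    scheme: ScoringScheme,
    beta: float = 30.0,
    *,
    max_cells: int = 2_000_000,
) -> SplicedAlignment:
    """Align every completely-unaligned CDS exon of ``partial`` by DP.

    Runs of consecutive unaligned exons are aligned in one DP against
    the gene region between their flanking anchored blocks, which
    divides the quadratic DP space.  Fragments below the identity
    threshold beta are demoted to deleted blocks.  Oversized windows are
    skipped with a warning and left as deleted blocks.
    """
    conserved = partial.conserved_blocks()
    unaligned = []
    for idx, (ek, el) in enumerate(cds.local_exons):
        if not any(b.k <= el and b.l >= ek for b in conserved):
            unaligned.append(idx)
    if not unaligned:
        return partial

    runs: list[list[int]] = [[unaligned[0]]]
    for idx in unaligned[1:]:
        if idx == runs[-1][-1] + 1:
            runs[-1].append(idx)
        else:
            runs.append([idx])

    exon_ends = {e.end for e in gene.exon_set}
    exon_starts = {e.start for e in gene.exon_set}
    new_blocks: list[Block] = list(conserved)
    for run in runs:
        ks = cds.local_exons[run[0]][0]
        le = cds.local_exons[run[-1]][1]
        prev = [b for b in conserved if b.l < ks]
        nxt = [b for b in conserved if b.k > le]
        gene_lo = prev[-1].b + 1 if prev else 1
        gene_hi = nxt[0].a - 1 if nxt else len(gene.sequence)
        if gene_lo > gene_hi:
            continue  # empty window; completion emits a deleted block
        cds_seg = cds.sequence[ks - 1 : le]
        gene_seg = gene.sequence[gene_lo - 1 : gene_hi]
        loc = lambda g: g - gene_lo + 1
        local_known = frozenset(
            (loc(b), loc(a))
            for b, a in gene.known_introns()
            if gene_lo <= b < a <= gene_hi
        )
        local_donors = frozenset(loc(p) for p in exon_ends if gene_lo <= p <= gene_hi)
        local_acceptors = frozenset(
            loc(p) for p in exon_starts if gene_lo <= p <= gene_hi
        )
        local_junctions = frozenset(
            l - ks + 1 for l in cds.junctions() if ks <= l < le
        )
        try:
            _, frag = spliced_dp(
                cds_seg,
                gene_seg,
                scheme,
                cds_junctions=local_junctions,
                known_introns=local_known,
                donor_sites=local_donors,
                acceptor_sites=local_acceptors,
                max_cells=max_cells,
                free_gene_prefix=bool(prev),
                free_gene_suffix=bool(nxt),
            )
        except DPSizeError as exc:
            warnings.warn(
                f"global stage skipped for {cds.id!r} vs {gene.id!r}: {exc}"
            )
            continue
        frag = accept_fragment(frag, beta)
        for b in frag:
            if b.is_conserved:
                new_blocks.append(
                    replace(b, k=b.k + ks - 1, l=b.l + ks - 1,
                            a=b.a + gene_lo - 1, b=b.b + gene_lo - 1)
                )
    return complete_chain(new_blocks, len(cds.sequence), cds.id, gene.id)
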