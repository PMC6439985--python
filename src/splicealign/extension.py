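"""Stage 2: gapped extension of anchors toward their exon boundaries.

Each anchor is extended independently on its left and right side until
it reaches the boundary of the CDS exon it belongs to (or the edge of a
neighboring anchor).  An extension may open with a run of gaps on either
sequence; the run length must be a multiple of 3 (to preserve the coding
frame) and at most ``alpha``.  After the opening run the extension is an
ungapped column-by-column pairing.  The candidate with the highest
identity over the newly added columns is applied iff that identity is at
least ``beta`` percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .core import Block

__all__ = ["ExtensionConfig", "ExtensionCandidate", "extend_anchor"]


@dataclass(frozen=True)
class ExtensionConfig:
    """Parameters of the gapped extension stage.

    alpha: maximum number of gaps opening an extension (multiple of 3).
    beta: minimum percent identity of the added columns for an extension
    to be accepted.
    """

    alpha: int = 21
    beta: float = 30.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.alpha % 3 != 0:
            raise ValueError("alpha must be a non-negative multiple of 3")
        if not 0.0 <= self.beta <= 100.0:
            raise ValueError("beta must be a percentage in [0, 100]")


@dataclass(frozen=True)
class ExtensionCandidate:
    """One enumerated extension configuration.

    config: "a" (no opening gaps), "b" (gap run on the gene row) or "c"
    (gap run on the CDS row); gaps: opening-run length; the rows are the
    added columns only, and ``gene_used`` is the number of gene
    nucleotides they consume.
    """

    config: str
    gaps: int
    cds_row: str
    gene_row: str
    gene_used: int

    @property
    def identity(self) -> float:
        if not self.cds_row:
            return 0.0
        ident = sum(
            1 for c, g in zip(self.cds_row, self.gene_row) if c == g and c != "-"
        )
        return 100.0 * ident / len(self.cds_row)

    def rank(self) -> tuple:
        # higher identity first; ties prefer (a) over (b) over (c), then
        # smaller gap counts
        return (-self.identity, "abc".index(self.config), self.gaps)


def _candidates_right(
    cds_seq: str,
    gene_seq: str,
    block: Block,
    cds_limit: int,
    gene_limit: int,
    alpha: int,
) -> list[ExtensionCandidate]:
    ext_len = cds_limit - block.l
    if ext_len <= 0:
        return []
    cds_ext = cds_seq[block.l : block.l + ext_len]
    out = []
    # (a) ungapped
    if block.b + ext_len <= gene_limit:
        gene_ext = gene_seq[block.b : block.b + ext_len]
        out.append(ExtensionCandidate("a", 0, cds_ext, gene_ext, ext_len))
    for gaps in range(3, alpha + 1, 3):
        # (b) gap run on the gene row, adjacent to the anchor: the first
        # `gaps` CDS characters face gaps, the rest pair ungapped.
        if gaps <= ext_len and block.b + ext_len - gaps <= gene_limit:
            gene_ext = "-" * gaps + gene_seq[block.b : block.b + ext_len - gaps]
            out.append(ExtensionCandidate("b", gaps, cds_ext, gene_ext, ext_len - gaps))
        # (c) gap run on the CDS row, adjacent to the anchor: `gaps` gene
        # characters face gaps first, then the full CDS flank pairs
        # ungapped.
        if block.b + ext_len + gaps <= gene_limit:
            cds_row = "-" * gaps + cds_ext
            gene_row = gene_seq[block.b : block.b + ext_len + gaps]
            out.append(ExtensionCandidate("c", gaps, cds_row, gene_row, ext_len + gaps))
    return out


def _candidates_left(
    cds_seq: str,
    gene_seq: str,
    block: Block,
    cds_limit: int,
    gene_limit: int,
    alpha: int,
) -> list[ExtensionCandidate]:
    ext_len = block.k - cds_limit
    if ext_len <= 0:
        return []
    cds_ext = cds_seq[block.k - 1 - ext_len : block.k - 1]
    out = []
    if block.a - ext_len >= gene_limit:
        gene_ext = gene_seq[block.a - 1 - ext_len : block.a - 1]
        out.append(ExtensionCandidate("a", 0, cds_ext, gene_ext, ext_len))
    for gaps in range(3, alpha + 1, 3):
        # (b) gap run on the gene row adjacent to the anchor (rightmost
        # columns of the left extension).
        if gaps <= ext_len and block.a - (ext_len - gaps) >= gene_limit:
            gene_ext = (
                gene_seq[block.a - 1 - (ext_len - gaps) : block.a - 1] + "-" * gaps
            )
            out.append(ExtensionCandidate("b", gaps, cds_ext, gene_ext, ext_len - gaps))
        # (c) gap run on the CDS row adjacent to the anchor.
        if block.a - (ext_len + gaps) >= gene_limit:
            cds_row = cds_ext + "-" * gaps
            gene_row = gene_seq[block.a - 1 - (ext_len + gaps) : block.a - 1]
            out.append(ExtensionCandidate("c", gaps, cds_row, gene_row, ext_len + gaps))
    return out


def _block_rows(block: Block, cds_seq: str, gene_seq: str) -> tuple[str, str]:
    if block.cds_aln is not None:
        return block.cds_aln, block.gene_aln
    return (
        cds_seq[block.k - 1 : block.l],
        gene_seq[block.a - 1 : block.b],
    )


def extend_anchor(
    block: Block,
    exon: tuple[int, int],
    cds_seq: str,
    gene_seq: str,
    cfg: ExtensionConfig,
    *,
    cds_left_limit: Optional[int] = None,
    gene_left_limit: int = 1,
    cds_right_limit: Optional[int] = None,
    gene_right_limit: Optional[int] = None,
) -> Block:
    """Extend one anchor block left and right within its exon.

    ``exon`` is the (k', l') interval of the CDS exon the block belongs
    to; the ``*_limit`` arguments tighten the extension window when a
    neighboring anchor is closer than the exon boundary or the gene end.
    The left side is evaluated before the right side.  Each side applies
    the best-identity candidate iff its identity is >= beta; otherwise
    the block is unchanged on that side.
    """
    kp, lp = exon
    if not (kp <= block.k and block.l <= lp):
        raise ValueError(f"block {block} not inside its exon {exon}")
    cds_left = max(kp, cds_left_limit if cds_left_limit is not None else kp)
    cds_right = min(lp, cds_right_limit if cds_right_limit is not None else lp)
    gene_right = (
        len(gene_seq) if gene_right_limit is None else min(gene_right_limit, len(gene_seq))
    )
    gene_left = max(1, gene_left_limit)
    if gene_left > block.a or gene_right < block.b:
        raise ValueError("neighbor bounds overlap the anchor itself")

    k, l, a, b = block.k, block.l, block.a, block.b
    cds_row, gene_row = _block_rows(block, cds_seq, gene_seq)

    left = _candidates_left(
        cds_seq, gene_seq, Block(k, l, a, b), cds_left, gene_left, cfg.alpha
    )
    if left:
        best = min(left, key=ExtensionCandidate.rank)
        if best.identity >= cfg.beta:
            k = cds_left
            a = a - best.gene_used
            cds_row = best.cds_row + cds_row
            gene_row = best.gene_row + gene_row

    right = _candidates_right(
        cds_seq, gene_seq, Block(k, l, a, b), cds_right, gene_right, cfg.alpha
    )
    if right:
        best = min(right, key=ExtensionCandidate.rank)
        if best.identity >= cfg.beta:
            l = cds_right
            b = b + best.gene_used
            cds_row = cds_row + best.cds_row
            gene_row = gene_row + best.gene_row

    if (k, l, a, b) == (block.k, block.l, block.a, block.b):
        return block
    return Block(k, l, a, b, cds_aln=cds_row, gene_aln=gene_row)
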