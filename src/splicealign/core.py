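"""Core objects of the spliced-alignment model.

A *gene* is a DNA sequence carrying a set of exons, grouped into CDS
chains (one chain per transcript isoform).  The concatenation of a
chain's exon sequences is the *CDS sequence*.  A *spliced alignment*
pairs a CDS sequence with a gene sequence as an ordered chain of blocks
``(k, l, a, b)``: CDS interval ``[k, l]`` against gene interval
``[a, b]`` (a *conserved* block), or against nothing when ``a == b == 0``
(a *deleted* block).  Gene segments between successive conserved blocks
are the induced introns.

All coordinates are 1-based and inclusive on both the CDS and the gene;
conversion to 0-based half-open happens only at I/O boundaries.
Sequences are normalized to uppercase DNA (U -> T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "Exon",
    "CDSChain",
    "GeneRecord",
    "CDSSequenceRecord",
    "Block",
    "SplicedAlignment",
    "ChainError",
    "CoordinateError",
    "AlignmentError",
    "normalize_dna",
    "extract_cds_sequence",
    "induced_introns",
    "alignment_introns",
    "alignment_junctions",
    "percent_identity",
    "cds_coverage",
    "block_identity",
    "complete_chain",
]

_DNA = set("ACGTN")


class ChainError(ValueError):
    """An exon chain violates ordering/overlap constraints."""


class CoordinateError(ValueError):
    """A coordinate falls outside the sequence it refers to."""


class AlignmentError(ValueError):
    """A spliced alignment violates its chain invariants."""


def normalize_dna(seq: str, *, allow_n: bool = True) -> str:
    """Uppercase a sequence and map RNA U to DNA T; reject other letters."""
    s = seq.upper().replace("U", "T")
    allowed = _DNA if allow_n else _DNA - {"N"}
    bad = set(s) - allowed
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True, order=True)
class Exon:
    """A gene exon, as a pair of 1-based inclusive coordinates (start, end)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(f"exon coordinates must be >= 1: {self}")
        if self.start > self.end:
            raise ChainError(f"exon start > end: {self}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CDSChain:
    """An ordered chain of non-overlapping gene exons forming one CDS."""

    id: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise ChainError(f"CDS chain {self.id!r} has no exons")
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if prev.end >= nxt.start:
                raise ChainError(
                    f"CDS chain {self.id!r}: exon {prev} not strictly before {nxt}"
                )

    def __len__(self) -> int:
        return len(self.exons)

    def __getitem__(self, i: int) -> Exon:
        return self.exons[i]


@dataclass
class GeneRecord:
    """A gene sequence together with its known CDS chains.

    The gene's exon set is the union of the exons of all its chains.
    """

    id: str
    sequence: str
    cds_set: list[CDSChain] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize_dna(self.sequence)
        for chain in self.cds_set:
            self.validate_chain(chain)

    def validate_chain(self, chain: CDSChain) -> None:
        if chain.exons[-1].end > len(self.sequence):
            raise CoordinateError(
                f"chain {chain.id!r} exceeds gene {self.id!r} "
                f"(end {chain.exons[-1].end} > length {len(self.sequence)})"
            )

    @property
    def exon_set(self) -> frozenset[Exon]:
        return frozenset(e for c in self.cds_set for e in c.exons)

    def known_introns(self) -> frozenset[tuple[int, int]]:
        """All introns (b, a) induced by the gene's annotated chains."""
        return frozenset(p for c in self.cds_set for p in induced_introns(c))

    def exon_slice(self, exon: Exon) -> str:
        return self.sequence[exon.start - 1 : exon.end]


@dataclass
class CDSSequenceRecord:
    """A spliced CDS sequence with its local exon intervals.

    ``local_exons`` are 1-based inclusive ``(k, l)`` intervals on the CDS
    sequence itself; they tile ``[1, len(sequence)]`` contiguously.
    ``gene_id``/``source_chain`` record where the sequence came from when
    it was extracted from an annotated gene.
    """

    id: str
    sequence: str
    local_exons: tuple[tuple[int, int], ...]
    gene_id: Optional[str] = None
    source_chain: Optional[CDSChain] = None

    def __post_init__(self) -> None:
        self.sequence = normalize_dna(self.sequence)
        self.local_exons = tuple((int(k), int(l)) for k, l in self.local_exons)
        pos = 1
        for k, l in self.local_exons:
            if k != pos or l < k:
                raise ChainError(
                    f"local exons of {self.id!r} do not tile the sequence: {self.local_exons}"
                )
            pos = l + 1
        if pos != len(self.sequence) + 1:
            raise ChainError(
                f"local exons of {self.id!r} do not cover the full sequence"
            )

    def junctions(self) -> frozenset[int]:
        """CDS positions l that end an exon other than the last one."""
        return frozenset(l for _, l in self.local_exons[:-1])

    def exon_of(self, pos: int) -> int:
        """Index of the local exon containing CDS position ``pos``."""
        for i, (k, l) in enumerate(self.local_exons):
            if k <= pos <= l:
                return i
        raise CoordinateError(f"position {pos} outside CDS {self.id!r}")


@dataclass
class Block:
    """One spliced-alignment block (k, l, a, b).

    A deleted block has ``a == b == 0``.  Conserved blocks may carry the
    pair of gapped aligned strings (CDS row, gene row) used to compute
    identity; ungapped blocks of equal segment lengths may omit them.
    """

    k: int
    l: int
    a: int
    b: int
    cds_aln: Optional[str] = None
    gene_aln: Optional[str] = None

    def __post_init__(self) -> None:
        if self.k < 1 or self.k > self.l:
            raise AlignmentError(f"bad CDS interval in block {self}")
        if not self.is_deleted and not (1 <= self.a <= self.b):
            raise AlignmentError(f"bad gene interval in block {self}")
        if (self.cds_aln is None) != (self.gene_aln is None):
            raise AlignmentError("both or neither aligned strings must be set")
        if self.cds_aln is not None:
            if len(self.cds_aln) != len(self.gene_aln):
                raise AlignmentError("aligned strings differ in length")
            if len(self.cds_aln.replace("-", "")) != self.l - self.k + 1:
                raise AlignmentError("CDS row inconsistent with (k, l)")
            if not self.is_deleted and len(
                self.gene_aln.replace("-", "")
            ) != self.b - self.a + 1:
                raise AlignmentError("gene row inconsistent with (a, b)")

    @property
    def is_deleted(self) -> bool:
        return self.a == 0 and self.b == 0

    @property
    def is_conserved(self) -> bool:
        return not self.is_deleted

    def aligned_rows(self) -> tuple[str, str]:
        """Gapped rows of the block; ungapped blocks synthesize them lazily.

        Only valid for conserved blocks whose segments have equal length
        when no explicit rows are stored.
        """
        if self.cds_aln is not None:
            return self.cds_aln, self.gene_aln  # type: ignore[return-value]
        raise AlignmentError(f"block {self} carries no aligned strings")

    def pair_coordinates(self) -> list[tuple[int, int]]:
        """(CDS position, gene position) pairs of non-gap columns."""
        if self.is_deleted:
            return []
        if self.cds_aln is None:
            if (self.l - self.k) != (self.b - self.a):
                raise AlignmentError(
                    f"block {self} has unequal segments and no aligned strings"
                )
            return [(self.k + t, self.a + t) for t in range(self.l - self.k + 1)]
        pairs = []
        i, j = self.k - 1, self.a - 1
        for cc, gc in zip(self.cds_aln, self.gene_aln):
            ci = cc != "-"
            gi = gc != "-"
            if ci:
                i += 1
            if gi:
                j += 1
            if ci and gi:
                pairs.append((i, j))
        return pairs


@dataclass
class SplicedAlignment:
    """An ordered chain of blocks tiling a CDS sequence against a gene."""

    cds_id: str
    gene_id: str
    blocks: list[Block]
    cds_length: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.blocks:
            raise AlignmentError("spliced alignment needs >= 1 block")
        if self.blocks[0].k != 1:
            raise AlignmentError("first block must start at CDS position 1")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.k != prev.l + 1:
                raise AlignmentError(
                    f"blocks do not tile the CDS: {prev} then {nxt}"
                )
        conserved = [b for b in self.blocks if b.is_conserved]
        for prev, nxt in zip(conserved, conserved[1:]):
            if prev.b >= nxt.a:
                raise AlignmentError(
                    f"gene intervals not increasing: {prev} then {nxt}"
                )
        if self.cds_length is not None and self.blocks[-1].l != self.cds_length:
            raise AlignmentError(
                f"last block ends at {self.blocks[-1].l}, CDS length is {self.cds_length}"
            )

    def __len__(self) -> int:
        return len(self.blocks)

    def __getitem__(self, i: int) -> Block:
        return self.blocks[i]

    def conserved_blocks(self) -> list[Block]:
        return [b for b in self.blocks if b.is_conserved]

    def pair_coordinates(self) -> set[tuple[int, int]]:
        out: set[tuple[int, int]] = set()
        for b in self.blocks:
            out.update(b.pair_coordinates())
        return out


# ---------------------------------------------------------------------------
# derived quantities


def extract_cds_sequence(gene: GeneRecord, cds: CDSChain) -> CDSSequenceRecord:
    """Concatenate a chain's exon sequences into a CDS sequence record."""
    gene.validate_chain(cds)
    parts = [gene.exon_slice(e) for e in cds.exons]
    local = []
    pos = 1
    for p in parts:
        local.append((pos, pos + len(p) - 1))
        pos += len(p)
    return CDSSequenceRecord(
        id=cds.id,
        sequence="".join(parts),
        local_exons=tuple(local),
        gene_id=gene.id,
        source_chain=cds,
    )


def induced_introns(cds: CDSChain) -> frozenset[tuple[int, int]]:
    """Introns (b_i, a_{i+1}) induced by successive exons of a chain."""
    return frozenset(
        (prev.end, nxt.start) for prev, nxt in zip(cds.exons, cds.exons[1:])
    )


def alignment_introns(aln: SplicedAlignment) -> frozenset[tuple[int, int]]:
    """Introns (b, a) between *successive conserved* blocks.

    A deleted block between two conserved blocks breaks their adjacency,
    so no intron is induced there.
    """
    out = set()
    for prev, nxt in zip(aln.blocks, aln.blocks[1:]):
        if prev.is_conserved and nxt.is_conserved:
            out.add((prev.b, nxt.a))
    return frozenset(out)


def alignment_junctions(aln: SplicedAlignment) -> frozenset[int]:
    """CDS junction positions l between successive conserved blocks."""
    out = set()
    for prev, nxt in zip(aln.blocks, aln.blocks[1:]):
        if prev.is_conserved and nxt.is_conserved:
            out.add(prev.l)
    return frozenset(out)


def _block_columns(block: Block) -> tuple[int, int]:
    """(identical columns, total columns) of a conserved block with rows."""
    ident = sum(
        1
        for c, g in zip(block.cds_aln, block.gene_aln)
        if c == g and c != "-"
    )
    return ident, len(block.cds_aln)


def block_identity(block: Block, cds_seq: str = None, gene_seq: str = None) -> float:
    """Percent identity of one conserved block.

    When the block stores no aligned rows, the ungapped pairing of the
    two segments is reconstructed from ``cds_seq``/``gene_seq``.
    """
    if block.is_deleted:
        return 0.0
    if block.cds_aln is not None:
        ident, total = _block_columns(block)
        return 100.0 * ident / total
    if cds_seq is None or gene_seq is None:
        raise AlignmentError("need sequences to score an ungapped block")
    if (block.l - block.k) != (block.b - block.a):
        raise AlignmentError(f"ungapped block {block} has unequal segments")
    c = cds_seq[block.k - 1 : block.l]
    g = gene_seq[block.a - 1 : block.b]
    ident = sum(1 for x, y in zip(c, g) if x == y)
    return 100.0 * ident / len(c)


def percent_identity(
    aln: SplicedAlignment,
    cds_seq: Optional[str] = None,
    gene_seq: Optional[str] = None,
    *,
    exclude_gap_columns: bool = False,
) -> Optional[float]:
    """Percent identity over the columns of all conserved blocks.

    Deleted blocks are excluded.  By default the denominator counts every
    alignment column of the conserved blocks, gap columns included; with
    ``exclude_gap_columns`` only columns pairing two nucleotides count
    (the convention used by some spliced aligners).  Returns ``None``
    when the alignment has no conserved block.
    """
    ident = 0
    total = 0
    for block in aln.conserved_blocks():
        if block.cds_aln is not None:
            rows = zip(block.cds_aln, block.gene_aln)
        else:
            if cds_seq is None or gene_seq is None:
                raise AlignmentError(
                    "alignment has ungapped blocks without stored rows; "
                    "pass cds_seq and gene_seq"
                )
            if (block.l - block.k) != (block.b - block.a):
                raise AlignmentError(
                    f"ungapped block {block} has unequal segments"
                )
            rows = zip(
                cds_seq[block.k - 1 : block.l], gene_seq[block.a - 1 : block.b]
            )
        for c, g in rows:
            if exclude_gap_columns and ("-" in (c, g)):
                continue
            total += 1
            if c == g and c != "-":
                ident += 1
    if total == 0:
        return None
    return 100.0 * ident / total


def complete_chain(
    conserved: Iterable[Block], cds_length: int, cds_id: str, gene_id: str
) -> SplicedAlignment:
    """Build a valid alignment by filling uncovered CDS intervals with
    deleted blocks around the given conserved blocks."""
    blocks: list[Block] = []
    pos = 1
    for b in sorted((b for b in conserved if b.is_conserved), key=lambda x: x.k):
        if b.k > pos:
            blocks.append(Block(pos, b.k - 1, 0, 0))
        blocks.append(b)
        pos = b.l + 1
    if pos <= cds_length:
        blocks.append(Block(pos, cds_length, 0, 0))
    if not blocks:
        blocks = [Block(1, cds_length, 0, 0)]
    return SplicedAlignment(cds_id=cds_id, gene_id=gene_id, blocks=blocks,
                            cds_length=cds_length)


def cds_coverage(aln: SplicedAlignment) -> float:
    """Fraction of CDS positions covered by conserved blocks, in [0, 1]."""
    length = aln.blocks[-1].l
    covered = sum(b.l - b.k + 1 for b in aln.conserved_blocks())
    return covered / length
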