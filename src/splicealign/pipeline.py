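"""End-to-end CDS-to-gene spliced alignment in four accumulating modes.

* ``LOCAL`` - translated local anchors only;
* ``EXTEND`` - anchors followed by gapped extension toward exon
  boundaries (the default mode: the global stage buys little accuracy
  for a quadratic-DP cost);
* ``GLOBAL`` - extension followed by the structure-aware global DP on
  the still-unaligned exons;
* ``EXTEND_WS`` - like ``EXTEND`` but the splicing structures of the
  inputs are first inferred from the sequences themselves.

Uncovered CDS intervals are materialized as deleted blocks so every
returned alignment is a valid chain tiling the CDS.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .anchoring import (
    AssignmentError,
    LocalHit,
    assign_and_trim,
    filter_hits,
    translated_local_hits,
)
from .core import (
    Block,
    CDSSequenceRecord,
    GeneRecord,
    SplicedAlignment,
    complete_chain,
    extract_cds_sequence,
)
from .extension import ExtensionConfig, extend_anchor
from .global_dp import ScoringScheme, run_global_stage
from .structure import build_family_structures, infer_structure

__all__ = ["AlignMode", "PipelineConfig", "FamilyAlignments", "align", "align_family"]


class AlignMode(enum.Enum):
    """The accumulating pipeline modes."""

    LOCAL = "local"
    EXTEND = "extended"
    GLOBAL = "global"
    EXTEND_WS = "extended_ws"

    @classmethod
    def parse(cls, text: str) -> "AlignMode":
        key = text.strip().lower().replace("-", "_")
        for mode in cls:
            if key == mode.value:
                return mode
        raise ValueError(
            f"unknown mode {text!r}; expected one of "
            f"{[m.value for m in cls]}"
        )


@dataclass
class PipelineConfig:
    """Tunable parameters of the aligner.

    ``evalue`` bounds anchor significance; ``alpha``/``beta`` drive the
    gapped extension; ``scheme`` carries the global-DP score components;
    ``dp_max_cells`` caps the quadratic DP; ``min_intron`` is the
    smallest intron the structure-inference search will open.
    """

    evalue: float = 1e-7
    alpha: int = 21
    beta: float = 30.0
    word_size: int = 3
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    dp_max_cells: int = 2_000_000
    min_intron: int = 4

    def extension(self) -> ExtensionConfig:
        return ExtensionConfig(alpha=self.alpha, beta=self.beta)


def _self_alignment(
    cds: CDSSequenceRecord, gene: GeneRecord
) -> Optional[SplicedAlignment]:
    """Exact alignment of a CDS against its own gene via its own chain.

    When the target gene is the gene the CDS was extracted from, its
    annotated chain *is* the spliced alignment (identity 100), so the
    block chain is emitted directly.
    """
    if cds.gene_id != gene.id:
        return None
    chain = cds.source_chain
    if chain is None:
        for c in gene.cds_set:
            if c.id == cds.id:
                chain = c
                break
    if chain is None:
        return None
    if extract_cds_sequence(gene, chain).sequence != cds.sequence:
        return None
    blocks = []
    for (k, l), exon in zip(cds.local_exons, chain.exons):
        seg = cds.sequence[k - 1 : l]
        blocks.append(Block(k, l, exon.start, exon.end, cds_aln=seg, gene_aln=seg))
    return SplicedAlignment(
        cds_id=cds.id, gene_id=gene.id, blocks=blocks, cds_length=len(cds.sequence)
    )


def _anchor_blocks(
    cds: CDSSequenceRecord, gene: GeneRecord, cfg: PipelineConfig
) -> list[tuple[Block, int]]:
    """Stage 1: anchors as conserved blocks tagged with their exon index."""
    hits = translated_local_hits(
        cds.sequence,
        gene.sequence,
        cfg.evalue,
        word_size=cfg.word_size,
    )
    tagged: list[LocalHit] = []
    for h in hits:
        try:
            tagged.append(assign_and_trim(h, cds))
        except AssignmentError as exc:
            warnings.warn(str(exc))
    anchors = filter_hits(tagged)
    out = []
    for h in anchors.all_hits():
        rows = (cds.sequence[h.k - 1 : h.l], gene.sequence[h.a - 1 : h.b])
        out.append(
            (Block(h.k, h.l, h.a, h.b, cds_aln=rows[0], gene_aln=rows[1]),
             h.exon_index)
        )
    return out


def _extend_blocks(
    tagged: list[tuple[Block, int]],
    cds: CDSSequenceRecord,
    gene: GeneRecord,
    cfg: PipelineConfig,
) -> list[tuple[Block, int]]:
    """Stage 2: left-to-right gapped extension with neighbor bounds."""
    ext_cfg = cfg.extension()
    blocks = [b for b, _ in tagged]
    exons = [e for _, e in tagged]
    for i, (block, exon_index) in enumerate(zip(blocks, exons)):
        ek, el = cds.local_exons[exon_index]
        prev_b = blocks[i - 1] if i > 0 else None
        next_b = blocks[i + 1] if i + 1 < len(blocks) else None
        try:
            blocks[i] = extend_anchor(
                block,
                (ek, el),
                cds.sequence,
                gene.sequence,
                ext_cfg,
                cds_left_limit=max(ek, prev_b.l + 1) if prev_b else ek,
                gene_left_limit=prev_b.b + 1 if prev_b else 1,
                cds_right_limit=min(el, next_b.k - 1) if next_b else el,
                gene_right_limit=next_b.a - 1 if next_b else len(gene.sequence),
            )
        except ValueError as exc:
            warnings.warn(f"extension skipped for block {block}: {exc}")
    return list(zip(blocks, exons))


def align(
    cds: CDSSequenceRecord,
    gene: GeneRecord,
    mode: AlignMode = AlignMode.EXTEND,
    cfg: Optional[PipelineConfig] = None,
    *,
    own_gene_seq: Optional[str] = None,
) -> SplicedAlignment:
    """Spliced-align one CDS sequence against one gene sequence.

    For ``EXTEND_WS`` the CDS's local exon structure is first inferred
    against its own gene sequence (``own_gene_seq``, defaulting to the
    target gene when the CDS came from it).
    """
    cfg = cfg or PipelineConfig()
    if mode is AlignMode.EXTEND_WS:
        src = own_gene_seq
        if src is None and cds.gene_id == gene.id:
            src = gene.sequence
        if src is None:
            raise ValueError("EXTEND_WS needs the CDS's own gene sequence")
        chain = infer_structure(
            cds.sequence, src, cds_id=cds.id, min_intron=cfg.min_intron
        )
        local = []
        pos = 1
        for e in chain.exons:
            local.append((pos, pos + len(e) - 1))
            pos += len(e)
        cds = CDSSequenceRecord(
            id=cds.id,
            sequence=cds.sequence,
            local_exons=tuple(local),
            gene_id=cds.gene_id,
            source_chain=chain if cds.gene_id == gene.id else cds.source_chain,
        )
        mode = AlignMode.EXTEND

    exact = _self_alignment(cds, gene)
    if exact is not None:
        return exact

    tagged = _anchor_blocks(cds, gene, cfg)
    if mode in (AlignMode.EXTEND, AlignMode.GLOBAL):
        tagged = _extend_blocks(tagged, cds, gene, cfg)
    partial = complete_chain(
        [b for b, _ in tagged], len(cds.sequence), cds.id, gene.id
    )
    if mode is AlignMode.GLOBAL:
        partial = run_global_stage(
            partial, gene, cds, cfg.scheme, cfg.beta, max_cells=cfg.dp_max_cells
        )
    return partial


@dataclass
class FamilyAlignments:
    """All CDS x gene alignments of a family, plus per-pair failures."""

    alignments: dict[tuple[str, str], SplicedAlignment]
    failures: dict[tuple[str, str], str]
    cds_records: dict[str, CDSSequenceRecord]
    genes: dict[str, GeneRecord]


def align_family(
    genes: list[GeneRecord],
    mode: AlignMode = AlignMode.EXTEND,
    cfg: Optional[PipelineConfig] = None,
) -> FamilyAlignments:
    """Align every CDS of a family against every gene of the family.

    Pairs are processed in lexicographic (gene id, CDS id) order; a
    failing pair is recorded and the run continues.  In ``EXTEND_WS``
    mode the given structures are ignored and re-inferred from the
    sequences before running the ``EXTEND`` pipeline.
    """
    cfg = cfg or PipelineConfig()
    if not genes:
        raise ValueError("need at least one gene")
    if mode is AlignMode.EXTEND_WS:
        raw = [
            (
                g.id,
                g.sequence,
                [(c.id, extract_cds_sequence(g, c).sequence) for c in g.cds_set],
            )
            for g in genes
        ]
        genes = build_family_structures(raw, min_intron=cfg.min_intron)
        mode = AlignMode.EXTEND

    gene_map = {g.id: g for g in sorted(genes, key=lambda g: g.id)}
    cds_records: dict[str, CDSSequenceRecord] = {}
    for g in gene_map.values():
        for chain in g.cds_set:
            if chain.id in cds_records:
                raise ValueError(f"duplicate CDS id {chain.id!r} in family")
            cds_records[chain.id] = extract_cds_sequence(g, chain)

    alignments: dict[tuple[str, str], SplicedAlignment] = {}
    failures: dict[tuple[str, str], str] = {}
    for gene_id, gene in gene_map.items():
        for cds_id in sorted(cds_records):
            cds = cds_records[cds_id]
            try:
                alignments[(cds_id, gene_id)] = align(cds, gene, mode, cfg)
            except Exception as exc:  # noqa: BLE001 - per-pair isolation
                failures[(cds_id, gene_id)] = f"{type(exc).__name__}: {exc}"
                warnings.warn(
                    f"alignment failed for {cds_id!r} vs {gene_id!r}: {exc}"
                )
    return FamilyAlignments(
        alignments=alignments,
        failures=failures,
        cds_records=cds_records,
        genes=gene_map,
    )
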