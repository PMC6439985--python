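"""Readers and writers for the on-disk formats.

Sequences travel as FASTA (via Biopython), splicing structures as a
4-column TSV (gene_id, cds_id, start, end) or a strict GFF3 subset (CDS
features grouped by their ``Parent`` transcript attribute, seqid = gene
id), and spliced alignments as a block-per-row TSV.  All coordinates on
disk are 1-based inclusive, matching the in-memory model; writers emit
deterministic, sorted output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    Block,
    CDSChain,
    Exon,
    SplicedAlignment,
    block_identity,
    normalize_dna,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_structures",
    "write_structures",
    "read_alignments",
    "write_alignments",
    "write_alignment",
    "write_groups",
    "read_groups",
    "write_family",
]

_ALN_COLUMNS = (
    "cds_id",
    "gene_id",
    "k",
    "l",
    "a",
    "b",
    "block_type",
    "identity",
    "cds_row",
    "gene_row",
)


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase-DNA mapping."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        try:
            out[rec.id] = normalize_dna(str(rec.seq))
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r} in {path}: {exc}") from exc
    return out


def write_fasta(records: Mapping[str, str], path) -> None:
    seq_records = [
        SeqRecord(Seq(records[name]), id=name, description="")
        for name in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_structures(path, dialect: str = "tsv") -> dict[str, list[CDSChain]]:
    """Read exon chains grouped by gene; validates chain invariants."""
    rows: list[tuple[str, str, int, int]] = []
    text = Path(path).read_text()
    if dialect == "tsv":
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 TSV columns")
            rows.append((parts[0], parts[1], int(parts[2]), int(parts[3])))
    elif dialect == "gff3":
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _, ftype, start, end, _, _, _, attrs = parts
            if ftype != "CDS":
                continue
            parent = None
            for item in attrs.split(";"):
                if item.startswith("Parent="):
                    parent = item[len("Parent=") :]
            if parent is None:
                raise ValueError(f"{path}:{lineno}: CDS feature without Parent")
            rows.append((seqid, parent, int(start), int(end)))
    else:
        raise ValueError(f"unknown structure dialect {dialect!r}")

    grouped: dict[str, dict[str, list[Exon]]] = {}
    for gene_id, cds_id, start, end in rows:
        grouped.setdefault(gene_id, {}).setdefault(cds_id, []).append(
            Exon(start, end)
        )
    out: dict[str, list[CDSChain]] = {}
    for gene_id in sorted(grouped):
        chains = []
        for cds_id in sorted(grouped[gene_id]):
            exons = tuple(sorted(grouped[gene_id][cds_id]))
            chains.append(CDSChain(id=cds_id, exons=exons))  # validates chain
        out[gene_id] = chains
    return out


def write_structures(
    structures: Mapping[str, list[CDSChain]], path, dialect: str = "tsv"
) -> None:
    lines = []
    if dialect == "tsv":
        for gene_id in sorted(structures):
            for chain in sorted(structures[gene_id], key=lambda c: c.id):
                for e in chain.exons:
                    lines.append(f"{gene_id}\t{chain.id}\t{e.start}\t{e.end}")
    elif dialect == "gff3":
        lines.append("##gff-version 3")
        for gene_id in sorted(structures):
            for chain in sorted(structures[gene_id], key=lambda c: c.id):
                for i, e in enumerate(chain.exons, 1):
                    lines.append(
                        f"{gene_id}\tsplicealign\tCDS\t{e.start}\t{e.end}\t.\t+\t.\t"
                        f"ID={chain.id}.cds{i};Parent={chain.id}"
                    )
    else:
        raise ValueError(f"unknown structure dialect {dialect!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_alignments(alignments: Iterable[SplicedAlignment], path) -> None:
    lines = ["\t".join(_ALN_COLUMNS)]
    for aln in alignments:
        for b in aln.blocks:
            kind = "deleted" if b.is_deleted else "conserved"
            if b.is_conserved and (
                b.cds_aln is not None or (b.l - b.k) == (b.b - b.a)
            ):
                ident = f"{block_identity(b):.2f}" if b.cds_aln is not None else ""
            else:
                ident = ""
            lines.append(
                "\t".join(
                    [
                        aln.cds_id,
                        aln.gene_id,
                        str(b.k),
                        str(b.l),
                        str(b.a),
                        str(b.b),
                        kind,
                        ident,
                        b.cds_aln or "",
                        b.gene_aln or "",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_alignment(aln: SplicedAlignment, path) -> None:
    write_alignments([aln], path)


def read_alignments(path) -> list[SplicedAlignment]:
    """Read a block TSV back into validated spliced alignments."""
    text = Path(path).read_text().splitlines()
    if not text or text[0].split("\t") != list(_ALN_COLUMNS):
        raise ValueError(f"{path}: missing or malformed alignment header")
    grouped: dict[tuple[str, str], list[Block]] = {}
    order: list[tuple[str, str]] = []
    for lineno, line in enumerate(text[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_ALN_COLUMNS):
            raise ValueError(f"{path}:{lineno}: truncated alignment row")
        cds_id, gene_id, k, l, a, b, kind, _, cds_row, gene_row = parts
        block = Block(
            int(k),
            int(l),
            int(a),
            int(b),
            cds_aln=cds_row or None,
            gene_aln=gene_row or None,
        )
        if (kind == "deleted") != block.is_deleted:
            raise ValueError(f"{path}:{lineno}: block type inconsistent")
        key = (cds_id, gene_id)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(block)
    return [
        SplicedAlignment(cds_id=c, gene_id=g, blocks=grouped[(c, g)])
        for c, g in order
    ]


def write_groups(groups: Iterable[Iterable[str]], path) -> None:
    """One (cds_id, group_id) row per CDS, deterministically numbered."""
    lines = ["cds_id\tgroup_id"]
    ordered = sorted((sorted(g) for g in groups), key=lambda g: g[0])
    for gi, members in enumerate(ordered, 1):
        for cds_id in members:
            lines.append(f"{cds_id}\tgroup{gi}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_groups(path) -> list[frozenset[str]]:
    text = Path(path).read_text().splitlines()
    if not text or text[0] != "cds_id\tgroup_id":
        raise ValueError(f"{path}: missing groups header")
    grouped: dict[str, set[str]] = {}
    for line in text[1:]:
        if not line.strip():
            continue
        cds_id, group_id = line.split("\t")
        grouped.setdefault(group_id, set()).add(cds_id)
    return sorted(
        (frozenset(v) for v in grouped.values()), key=lambda g: sorted(g)[0]
    )


def write_family(truth, outdir, *, manifest_extra: Optional[dict] = None) -> Path:
    """Write one simulated family (sequences, structures, truth) to a
    directory; returns the directory path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta({g.id: g.sequence for g in truth.genes}, out / "genes.fasta")
    write_fasta(
        {cid: rec.sequence for cid, rec in sorted(truth.cds_records.items())},
        out / "cds.fasta",
    )
    structures = {g.id: list(g.cds_set) for g in truth.genes}
    write_structures(structures, out / "structures.tsv", dialect="tsv")
    write_structures(structures, out / "structures.gff3", dialect="gff3")
    write_alignments(
        (truth.true_alignments[k] for k in sorted(truth.true_alignments)),
        out / "true_alignments.tsv",
    )
    write_groups(truth.true_groups, out / "true_groups.tsv")
    (out / "events.json").write_text(json.dumps(truth.events, indent=1))
    manifest = {
        "family": truth.name,
        "n_genes": truth.n_genes,
        "n_cds": truth.n_cds,
        "exon_ancestry": {k: list(v) for k, v in sorted(truth.exon_ancestry.items())},
    }
    manifest.update(manifest_extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
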