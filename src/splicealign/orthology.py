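"""Splicing-orthology inference from spliced alignments.

Two CDS from homologous genes are *splicing orthologs* when their
spliced alignment shows that they share the same splicing structure:

1. they have the same number of exons;
2. the alignment of the first CDS against the second CDS's gene induces
   exactly the introns of the second CDS (same gene coordinates);
3. corresponding exons have lengths congruent modulo 3, so both CDS are
   read in the same codon phase exon by exon.

An alignment containing a deleted block cannot support orthology: a
deleted block means some exon of the first CDS has no counterpart on
the gene, so no one-to-one exon correspondence exists.

Pairwise relations form an orthology graph over the family's CDS; the
orthology relation is closed transitively, so the CDS orthology groups
are the connected components of that graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .core import (
    CDSChain,
    SplicedAlignment,
    alignment_introns,
    induced_introns,
)

__all__ = [
    "OrthologyGraph",
    "is_splicing_ortholog",
    "pairwise_orthology",
    "orthology_groups",
    "build_orthology_graph",
]


def is_splicing_ortholog(
    c1: CDSChain,
    c2: CDSChain,
    a1: SplicedAlignment,
    *,
    tolerance: int = 0,
) -> bool:
    """Does alignment ``a1`` (of c1's sequence vs c2's gene) support the
    splicing orthology of ``c1`` and ``c2``?

    ``tolerance`` allows a +/- slack (in nucleotides, default 0: exact)
    when matching induced intron coordinates against annotated ones,
    for noisy inputs.
    """
    if any(b.is_deleted for b in a1.blocks):
        return False
    if len(c1) != len(c2):
        return False
    induced = alignment_introns(a1)
    annotated = induced_introns(c2)
    if tolerance == 0:
        if induced != annotated:
            return False
    else:
        if len(induced) != len(annotated):
            return False
        used: set[tuple[int, int]] = set()
        for b, a in sorted(induced):
            hit = next(
                (
                    (bb, aa)
                    for bb, aa in sorted(annotated - used)
                    if abs(bb - b) <= tolerance and abs(aa - a) <= tolerance
                ),
                None,
            )
            if hit is None:
                return False
            used.add(hit)
    return all(
        (len(e1) - len(e2)) % 3 == 0 for e1, e2 in zip(c1.exons, c2.exons)
    )


@dataclass
class OrthologyGraph:
    """CDS nodes, supported orthology edges, and their evidence."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)

    def evidence(self, u: str, v: str) -> list[str]:
        return self.graph.edges[u, v].get("evidence", [])

    def groups(self) -> list[frozenset[str]]:
        comps = [frozenset(c) for c in nx.connected_components(self.graph)]
        return sorted(comps, key=lambda c: sorted(c)[0])


def pairwise_orthology(
    chains: dict[str, tuple[str, CDSChain]],
    alignments: dict[tuple[str, str], SplicedAlignment],
    *,
    reciprocal: bool = False,
    tolerance: int = 0,
) -> list[tuple[str, str, list[str]]]:
    """Evaluate the orthology test for every unordered CDS pair.

    ``chains`` maps cds_id -> (gene_id, chain); ``alignments`` maps
    (cds_id, gene_id) -> spliced alignment.  By default an edge needs
    support from at least one direction; with ``reciprocal`` both
    directions must support it (pairs missing an alignment for a
    required direction are skipped with a warning).  Returns
    (cds1, cds2, evidence) triples.
    """
    edges = []
    ids = sorted(chains)
    for idx, id1 in enumerate(ids):
        g1, c1 = chains[id1]
        for id2 in ids[idx + 1 :]:
            g2, c2 = chains[id2]
            support = []
            missing = []
            for (ca, cb, gb) in ((id1, id2, g2), (id2, id1, g1)):
                aln = alignments.get((ca, gb))
                if aln is None:
                    missing.append((ca, gb))
                    continue
                ha, hb = chains[ca][1], chains[cb][1]
                if is_splicing_ortholog(ha, hb, aln, tolerance=tolerance):
                    support.append(f"{ca}->{gb}")
            if reciprocal:
                if missing:
                    warnings.warn(
                        f"pair ({id1}, {id2}) skipped: missing alignment(s) "
                        f"{missing} under reciprocal orthology"
                    )
                    continue
                if len(support) == 2:
                    edges.append((id1, id2, support))
            elif support:
                edges.append((id1, id2, support))
    return edges


def build_orthology_graph(
    chains: dict[str, tuple[str, CDSChain]],
    alignments: dict[tuple[str, str], SplicedAlignment],
    *,
    reciprocal: bool = False,
    tolerance: int = 0,
) -> OrthologyGraph:
    """Construct the family orthology graph (all CDS appear as nodes)."""
    og = OrthologyGraph()
    og.graph.add_nodes_from(chains)
    for u, v, ev in pairwise_orthology(
        chains, alignments, reciprocal=reciprocal, tolerance=tolerance
    ):
        og.graph.add_edge(u, v, evidence=ev)
    return og


def orthology_groups(graph: OrthologyGraph) -> list[frozenset[str]]:
    """CDS orthology groups: connected components under transitive
    closure of the pairwise relation (singletons included)."""
    return graph.groups()
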