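"""Gene-family evolution simulator with splicing-structure ground truth.

An ancestral gene (exon-intron structure plus an initial set of
alternative-transcript CDS) is generated at the root of a gene tree and
evolved along its branches.  Two levels of evolution are simulated:

* gene level - structural events on the splicing structure (exon
  duplication, exon gain, exon loss) and sequence events on coding
  exons at codon granularity (substitutions through a codon kernel that
  avoids stop codons, insertions and deletions in codon multiples);
* transcript level - isoform creation (a new combination of exons
  becomes a transcript) and isoform loss.

Every codon carries a homology label inherited through descent and
every exon an ancestry identifier (forked on duplication, fresh on
gain), so the simulator can emit exact ground truth: the true spliced
alignment of every CDS against every gene of the family, and the true
splicing-orthology groups (two CDS are true orthologs iff their exon
lists are in ancestry bijection).

Branch lengths act as evolutionary rates; the ``small`` / ``medium`` /
``large`` presets scale the same tree to low, medium and high rates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional

import dendropy
import numpy as np

from .core import (
    Block,
    CDSChain,
    CDSSequenceRecord,
    Exon,
    GeneRecord,
    SplicedAlignment,
    extract_cds_sequence,
)

__all__ = [
    "SimConfig",
    "FamilyTruth",
    "PRESET_SCALES",
    "generate_root_gene",
    "evolve_branch",
    "evolve_family",
    "emit_truth",
    "generate_family",
    "generate_dataset",
    "mean_pairwise_cds_identity",
]

_NUCS = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = tuple(
    a + b + c
    for a in _NUCS
    for b in _NUCS
    for c in _NUCS
    if a + b + c not in _STOPS
)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: branch-length multipliers of the three rate presets, calibrated once so
#: the mean pairwise CDS identity of generated families lands near the
#: low/medium/high divergence levels the presets are meant to emulate
#: (roughly 78% / 42% / 11% under the default root model)
PRESET_SCALES = {"small": 0.04, "medium": 0.15, "large": 0.65}

_DEFAULT_TREE = "((g1:1.0,g2:1.0):1.0,(g3:1.0,(g4:1.0,g5:1.0):1.0):1.0);"


@dataclass(frozen=True)
class SimConfig:
    """All tunable parameters of the simulator.

    Rates are per unit branch length; event counts per branch are
    Poisson with mean rate x length.  Exon lengths are kept in codon
    multiples so every emitted CDS length is divisible by 3.  The root
    distributions aim at vertebrate-like scales (exons around 150 nt,
    about 8 exons, introns 60-2000 nt, 1-4 initial isoforms).
    """

    tree_newick: str = _DEFAULT_TREE
    branch_scale: float = 1.0
    # root model
    n_exons_mean: float = 8.0
    n_exons_range: tuple[int, int] = (2, 15)
    exon_codons_mean: float = 50.0
    exon_codons_sigma: float = 0.35
    exon_codons_range: tuple[int, int] = (10, 100)
    intron_len_range: tuple[int, int] = (60, 2000)
    max_init_isoforms: int = 4
    isoform_exon_keep_prob: float = 0.75
    flank_len: int = 30
    # structural event rates (per unit branch length)
    exon_duplication_rate: float = 0.2
    exon_gain_rate: float = 0.2
    exon_loss_rate: float = 0.2
    isoform_creation_rate: float = 0.3
    isoform_loss_rate: float = 0.2
    # sequence evolution
    substitution_rate: float = 1.0  # per codon
    indel_rate: float = 0.02  # per codon
    intron_substitution_rate: float = 1.0  # per nucleotide, scaled /3
    # dataset shaping
    cds_total_range: tuple[int, int] = (5, 17)

    def scaled(self, scale: float) -> "SimConfig":
        return dc_replace(self, branch_scale=scale)


@dataclass
class SimExon:
    """One exon lineage: ancestry id, codons, and per-codon homology labels."""

    ancestry: str
    codons: list[str]
    labels: list[int]

    def copy(self) -> "SimExon":
        return SimExon(self.ancestry, list(self.codons), list(self.labels))

    @property
    def length_nt(self) -> int:
        return 3 * len(self.codons)

    @property
    def sequence(self) -> str:
        return "".join(self.codons)


@dataclass
class SimGene:
    """Evolving gene: exon chain, intron sequences, isoform exon subsets."""

    exons: list[SimExon]
    introns: list[str]  # len(exons) - 1
    isoforms: dict[str, tuple[int, ...]]  # isoform id -> exon indices

    def copy(self) -> "SimGene":
        return SimGene(
            [e.copy() for e in self.exons],
            list(self.introns),
            dict(self.isoforms),
        )


class _Labeler:
    """Mints unique codon homology labels and ancestry/isoform ids."""

    def __init__(self) -> None:
        self._label = itertools.count(1)
        self._gain = itertools.count(1)
        self._dup = itertools.count(1)
        self._iso = itertools.count(1)

    def labels(self, n: int) -> list[int]:
        return [next(self._label) for _ in range(n)]

    def gain_id(self) -> str:
        return f"G{next(self._gain)}"

    def dup_id(self, parent: str) -> str:
        return f"{parent}.d{next(self._dup)}"

    def iso_id(self) -> str:
        return f"iso{next(self._iso)}"


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [_CODONS[i] for i in rng.integers(0, len(_CODONS), size=n)]


def _random_intron(rng: np.random.Generator, cfg: SimConfig) -> str:
    lo, hi = cfg.intron_len_range
    length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    length = max(lo, min(hi, length))
    body = "".join(_NUCS[i] for i in rng.integers(0, 4, size=length - 4))
    return "GT" + body + "AG"


def _mutate_codon(rng: np.random.Generator, codon: str) -> str:
    for _ in range(10):
        pos = int(rng.integers(0, 3))
        old = codon[pos]
        if rng.random() < 0.5:
            new = _TRANSITION[old]
        else:
            new = rng.choice([n for n in _NUCS if n != old and n != _TRANSITION[old]])
        cand = codon[:pos] + new + codon[pos + 1 :]
        if cand not in _STOPS:
            return cand
    return codon


def _random_subset(
    rng: np.random.Generator, n_exons: int, keep_prob: float
) -> tuple[int, ...]:
    subset = tuple(i for i in range(n_exons) if rng.random() < keep_prob)
    if not subset:
        subset = (int(rng.integers(0, n_exons)),)
    return subset


def generate_root_gene(
    cfg: SimConfig, rng: np.random.Generator, labeler: Optional[_Labeler] = None
) -> tuple[SimGene, _Labeler]:
    """Generate the ancestral gene with structure and initial isoforms."""
    labeler = labeler or _Labeler()
    lo, hi = cfg.n_exons_range
    if hi < 1 or cfg.n_exons_mean <= 0:
        raise ValueError("infeasible root configuration: no exons")
    n_exons = int(rng.geometric(1.0 / cfg.n_exons_mean))
    n_exons = max(lo, min(hi, n_exons))
    exons = []
    for i in range(n_exons):
        ncod = int(
            round(
                math.exp(
                    rng.normal(math.log(cfg.exon_codons_mean), cfg.exon_codons_sigma)
                )
            )
        )
        ncod = max(cfg.exon_codons_range[0], min(cfg.exon_codons_range[1], ncod))
        exons.append(
            SimExon(f"E{i + 1}", _random_codons(rng, ncod), labeler.labels(ncod))
        )
    introns = [_random_intron(rng, cfg) for _ in range(n_exons - 1)]
    isoforms: dict[str, tuple[int, ...]] = {labeler.iso_id(): tuple(range(n_exons))}
    n_iso = int(rng.integers(1, cfg.max_init_isoforms + 1))
    seen = set(isoforms.values())
    for _ in range(n_iso - 1):
        subset = _random_subset(rng, n_exons, cfg.isoform_exon_keep_prob)
        if subset not in seen:
            seen.add(subset)
            isoforms[labeler.iso_id()] = subset
    return SimGene(exons, introns, isoforms), labeler


def _shift_isoforms(
    isoforms: dict[str, tuple[int, ...]], at: int, delta: int
) -> dict[str, tuple[int, ...]]:
    return {
        iso: tuple(i + delta if i >= at else i for i in subset)
        for iso, subset in isoforms.items()
    }


def _insert_exon(
    gene: SimGene, pos: int, exon: SimExon, rng: np.random.Generator, cfg: SimConfig
) -> None:
    """Insert ``exon`` so it becomes chain index ``pos``."""
    gene.isoforms = _shift_isoforms(gene.isoforms, pos, 1)
    gene.exons.insert(pos, exon)
    if len(gene.exons) > 1:
        at = min(max(pos - 1, 0), len(gene.exons) - 2)
        gene.introns.insert(at, _random_intron(rng, cfg))


def _delete_exon(gene: SimGene, pos: int) -> None:
    gene.exons.pop(pos)
    if gene.introns:
        gene.introns.pop(min(pos, len(gene.introns) - 1))
    new_isoforms = {}
    for iso, subset in gene.isoforms.items():
        kept = tuple(i for i in subset if i != pos)
        kept = tuple(i - 1 if i > pos else i for i in kept)
        if kept:
            new_isoforms[iso] = kept
    gene.isoforms = new_isoforms


def evolve_branch(
    parent: SimGene,
    branch_length: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    labeler: _Labeler,
    events: Optional[list] = None,
) -> SimGene:
    """Evolve one gene along one branch; returns the child gene.

    Structural events first (counts Poisson in rate x length), then
    codon-level substitutions and indels, then intron drift (the
    GT..AG intron ends are preserved).  Events that would leave the gene
    without exons or without isoforms are skipped and logged.
    """
    t = branch_length * cfg.branch_scale
    child = parent.copy()
    log = events if events is not None else []

    def note(kind: str, **info) -> None:
        log.append({"event": kind, **info})

    if t <= 0:
        return child

    for _ in range(int(rng.poisson(cfg.exon_duplication_rate * t))):
        i = int(rng.integers(0, len(child.exons)))
        src = child.exons[i]
        copy = SimExon(labeler.dup_id(src.ancestry), list(src.codons), list(src.labels))
        _insert_exon(child, i + 1, copy, rng, cfg)
        for iso, subset in list(child.isoforms.items()):
            if i in subset and rng.random() < 0.5:
                child.isoforms[iso] = tuple(sorted(set(subset) | {i + 1}))
        note("exon_duplication", source=src.ancestry, copy=copy.ancestry)

    for _ in range(int(rng.poisson(cfg.exon_gain_rate * t))):
        pos = int(rng.integers(0, len(child.exons) + 1))
        ncod = max(
            cfg.exon_codons_range[0],
            min(
                cfg.exon_codons_range[1],
                int(round(math.exp(rng.normal(math.log(cfg.exon_codons_mean),
                                              cfg.exon_codons_sigma)))),
            ),
        )
        gained = SimExon(labeler.gain_id(), _random_codons(rng, ncod),
                         labeler.labels(ncod))
        _insert_exon(child, pos, gained, rng, cfg)
        took = False
        for iso, subset in list(child.isoforms.items()):
            if rng.random() < 0.5:
                child.isoforms[iso] = tuple(sorted(set(subset) | {pos}))
                took = True
        if not took and child.isoforms:
            iso = sorted(child.isoforms)[int(rng.integers(0, len(child.isoforms)))]
            child.isoforms[iso] = tuple(sorted(set(child.isoforms[iso]) | {pos}))
        note("exon_gain", ancestry=gained.ancestry, position=pos)

    for _ in range(int(rng.poisson(cfg.exon_loss_rate * t))):
        if len(child.exons) < 2:
            note("exon_loss_skipped", reason="single exon")
            continue
        pos = int(rng.integers(0, len(child.exons)))
        trial = child.copy()
        _delete_exon(trial, pos)
        if not trial.isoforms:
            note("exon_loss_skipped", reason="no isoform would survive")
            continue
        lost = child.exons[pos].ancestry
        child = trial
        note("exon_loss", ancestry=lost)

    for _ in range(int(rng.poisson(cfg.isoform_creation_rate * t))):
        subset = _random_subset(rng, len(child.exons), cfg.isoform_exon_keep_prob)
        if subset in set(child.isoforms.values()):
            note("isoform_creation_skipped", reason="duplicate combination")
            continue
        iso = labeler.iso_id()
        child.isoforms[iso] = subset
        note("isoform_creation", isoform=iso)

    for _ in range(int(rng.poisson(cfg.isoform_loss_rate * t))):
        if len(child.isoforms) < 2:
            note("isoform_loss_skipped", reason="last isoform")
            continue
        iso = sorted(child.isoforms)[int(rng.integers(0, len(child.isoforms)))]
        del child.isoforms[iso]
        note("isoform_loss", isoform=iso)

    # codon-level sequence evolution
    p_sub = 1.0 - math.exp(-cfg.substitution_rate * t)
    for exon in child.exons:
        for ci in range(len(exon.codons)):
            if rng.random() < p_sub:
                exon.codons[ci] = _mutate_codon(rng, exon.codons[ci])
        for _ in range(int(rng.poisson(cfg.indel_rate * t * len(exon.codons)))):
            size = int(rng.integers(1, 3))
            if rng.random() < 0.5 and len(exon.codons) - size >= 2:
                at = int(rng.integers(0, len(exon.codons) - size + 1))
                del exon.codons[at : at + size]
                del exon.labels[at : at + size]
            else:
                at = int(rng.integers(0, len(exon.codons) + 1))
                exon.codons[at:at] = _random_codons(rng, size)
                exon.labels[at:at] = labeler.labels(size)

    p_int = 1.0 - math.exp(-cfg.intron_substitution_rate * t / 3.0)
    for ii, intron in enumerate(child.introns):
        body = list(intron[2:-2])
        for bi in range(len(body)):
            if rng.random() < p_int:
                body[bi] = _NUCS[int(rng.integers(0, 4))]
        child.introns[ii] = intron[:2] + "".join(body) + intron[-2:]
    return child


def _layout(
    gene_id: str, sim: SimGene, rng: np.random.Generator, cfg: SimConfig
) -> tuple[GeneRecord, list[Exon]]:
    """Place a SimGene on coordinates: flanks, exons and introns."""
    flank5 = "".join(_NUCS[i] for i in rng.integers(0, 4, size=cfg.flank_len))
    flank3 = "".join(_NUCS[i] for i in rng.integers(0, 4, size=cfg.flank_len))
    parts = [flank5]
    pos = cfg.flank_len + 1
    coords: list[Exon] = []
    for i, exon in enumerate(sim.exons):
        parts.append(exon.sequence)
        coords.append(Exon(pos, pos + exon.length_nt - 1))
        pos += exon.length_nt
        if i < len(sim.introns):
            parts.append(sim.introns[i])
            pos += len(sim.introns[i])
    parts.append(flank3)
    chains = [
        CDSChain(
            id=f"{gene_id}.{iso}",
            exons=tuple(coords[i] for i in subset),
        )
        for iso, subset in sorted(sim.isoforms.items())
    ]
    record = GeneRecord(id=gene_id, sequence="".join(parts), cds_set=chains)
    return record, coords


def evolve_family(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, SimGene], list[dict]]:
    """Evolve a root gene over the configured tree; returns leaf genes."""
    tree = dendropy.Tree.get(data=cfg.tree_newick, schema="newick")
    root, labeler = generate_root_gene(cfg, rng)
    events: list[dict] = []
    leaves: dict[str, SimGene] = {}

    def walk(node, gene: SimGene) -> None:
        for child in node.child_nodes():
            length = child.edge.length if child.edge.length is not None else 0.0
            evolved = evolve_branch(gene, length, cfg, rng, labeler, events)
            if child.is_leaf():
                name = child.taxon.label if child.taxon else f"leaf{len(leaves) + 1}"
                leaves[name.replace(" ", "_")] = evolved
            else:
                walk(child, evolved)

    walk(tree.seed_node, root)
    return leaves, events


@dataclass
class FamilyTruth:
    """Simulated family with full splicing-structure ground truth."""

    name: str
    genes: list[GeneRecord]
    cds_records: dict[str, CDSSequenceRecord]
    true_alignments: dict[tuple[str, str], SplicedAlignment]
    true_groups: list[frozenset[str]]
    exon_ancestry: dict[str, tuple[str, ...]]  # gene id -> ancestry per chain pos
    cds_ancestry: dict[str, tuple[str, ...]]  # cds id -> ancestry per exon
    events: list[dict] = field(default_factory=list, repr=False)
    sim_genes: dict[str, SimGene] = field(default_factory=dict, repr=False)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cds(self) -> int:
        return len(self.cds_records)


def _label_pairing(e1: SimExon, e2: SimExon) -> list[tuple[int, int]]:
    """Order-preserving pairing of two exons' codons by shared labels."""
    pos2 = {lab: i for i, lab in enumerate(e2.labels)}
    pairs = []
    last = -1
    for i, lab in enumerate(e1.labels):
        j = pos2.get(lab)
        if j is not None and j > last:
            pairs.append((i, j))
            last = j
    return pairs


def _paired_rows(e1: SimExon, e2: SimExon) -> tuple[str, str]:
    """Gapped nucleotide rows aligning two homologous exons by labels."""
    pairs = _label_pairing(e1, e2)
    rows1: list[str] = []
    rows2: list[str] = []
    i = j = 0
    for pi, pj in pairs + [(len(e1.codons), len(e2.codons))]:
        while i < pi:
            rows1.append(e1.codons[i])
            rows2.append("---")
            i += 1
        while j < pj:
            rows1.append("---")
            rows2.append(e2.codons[j])
            j += 1
        if pi < len(e1.codons):
            rows1.append(e1.codons[pi])
            rows2.append(e2.codons[pj])
            i, j = pi + 1, pj + 1
    return "".join(rows1), "".join(rows2)


def emit_truth(
    name: str,
    leaves: dict[str, SimGene],
    cfg: SimConfig,
    rng: np.random.Generator,
    events: Optional[list[dict]] = None,
) -> FamilyTruth:
    """Turn evolved leaf genes into records plus exact ground truth."""
    genes: list[GeneRecord] = []
    coords: dict[str, list[Exon]] = {}
    for gene_id in sorted(leaves):
        rec, cs = _layout(gene_id, leaves[gene_id], rng, cfg)
        genes.append(rec)
        coords[gene_id] = cs

    cds_records: dict[str, CDSSequenceRecord] = {}
    cds_meta: dict[str, tuple[str, tuple[int, ...]]] = {}
    for rec in genes:
        sim = leaves[rec.id]
        for iso, subset in sorted(sim.isoforms.items()):
            cid = f"{rec.id}.{iso}"
            chain = next(c for c in rec.cds_set if c.id == cid)
            cds_records[cid] = extract_cds_sequence(rec, chain)
            cds_meta[cid] = (rec.id, subset)

    exon_ancestry = {
        g.id: tuple(e.ancestry for e in leaves[g.id].exons) for g in genes
    }
    cds_ancestry = {
        cid: tuple(leaves[gid].exons[i].ancestry for i in subset)
        for cid, (gid, subset) in cds_meta.items()
    }

    true_alignments: dict[tuple[str, str], SplicedAlignment] = {}
    for cid, (gid, subset) in cds_meta.items():
        src_sim = leaves[gid]
        cds = cds_records[cid]
        for target in genes:
            tgt_sim = leaves[target.id]
            anc_index = {e.ancestry: i for i, e in enumerate(tgt_sim.exons)}
            blocks: list[Block] = []
            for (k, l), ei in zip(cds.local_exons, subset):
                exon = src_sim.exons[ei]
                ti = anc_index.get(exon.ancestry)
                if ti is None:
                    blocks.append(Block(k, l, 0, 0))
                    continue
                tgt_exon = tgt_sim.exons[ti]
                tgt_coord = coords[target.id][ti]
                row1, row2 = _paired_rows(exon, tgt_exon)
                blocks.append(
                    Block(k, l, tgt_coord.start, tgt_coord.end,
                          cds_aln=row1, gene_aln=row2)
                )
            true_alignments[(cid, target.id)] = SplicedAlignment(
                cds_id=cid,
                gene_id=target.id,
                blocks=blocks,
                cds_length=len(cds.sequence),
            )

    # true orthology: exon lists in ancestry bijection
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(cds_ancestry)
    ids = sorted(cds_ancestry)
    for i, c1 in enumerate(ids):
        for c2 in ids[i + 1 :]:
            if cds_ancestry[c1] == cds_ancestry[c2]:
                graph.add_edge(c1, c2)
    groups = sorted(
        (frozenset(c) for c in nx.connected_components(graph)),
        key=lambda c: sorted(c)[0],
    )

    return FamilyTruth(
        name=name,
        genes=genes,
        cds_records=cds_records,
        true_alignments=true_alignments,
        true_groups=groups,
        exon_ancestry=exon_ancestry,
        cds_ancestry=cds_ancestry,
        events=list(events or []),
        sim_genes=dict(leaves),
    )


def _clamp_cds_total(
    leaves: dict[str, SimGene],
    cfg: SimConfig,
    rng: np.random.Generator,
    labeler_hint: Optional[_Labeler],
    events: list[dict],
) -> None:
    """Enforce the configured family-wide CDS count range in place."""
    lo, hi = cfg.cds_total_range

    def total() -> int:
        return sum(len(g.isoforms) for g in leaves.values())

    guard = 0
    while total() > hi and guard < 200:
        guard += 1
        gid = max(sorted(leaves), key=lambda g: len(leaves[g].isoforms))
        gene = leaves[gid]
        if len(gene.isoforms) <= 1:
            break
        iso = sorted(gene.isoforms)[int(rng.integers(0, len(gene.isoforms)))]
        del gene.isoforms[iso]
        events.append({"event": "clamp_isoform_drop", "gene": gid, "isoform": iso})
    counter = itertools.count(1)
    while total() < lo and guard < 400:
        guard += 1
        gid = sorted(leaves)[int(rng.integers(0, len(leaves)))]
        gene = leaves[gid]
        subset = _random_subset(rng, len(gene.exons), cfg.isoform_exon_keep_prob)
        if subset in set(gene.isoforms.values()):
            continue
        iso = f"isoX{next(counter)}"
        gene.isoforms[iso] = subset
        events.append({"event": "clamp_isoform_add", "gene": gid, "isoform": iso})


def generate_family(
    name: str, cfg: SimConfig, rng: np.random.Generator
) -> FamilyTruth:
    """Simulate one family end to end (evolution, clamping, truth)."""
    leaves, events = evolve_family(cfg, rng)
    _clamp_cds_total(leaves, cfg, rng, None, events)
    return emit_truth(name, leaves, cfg, rng, events)


def generate_dataset(
    preset: str = "small",
    n_families: int = 36,
    seed: int = 0,
    *,
    config: Optional[SimConfig] = None,
) -> list[FamilyTruth]:
    """Generate a dataset of simulated families under a rate preset.

    The preset (small/medium/large) fixes the branch-length scale of
    the shared 5-leaf gene tree; ``config`` overrides the remaining
    parameters.  The same (preset, n_families, seed) triple reproduces
    the dataset exactly.
    """
    key = preset.strip().lower()
    if key not in PRESET_SCALES:
        raise ValueError(f"unknown preset {preset!r}; use one of {sorted(PRESET_SCALES)}")
    base = config or SimConfig()
    cfg = base.scaled(PRESET_SCALES[key])
    preset_index = sorted(PRESET_SCALES).index(key)
    out = []
    for fam in range(n_families):
        rng = np.random.default_rng([int(seed) % (2**31), preset_index, fam])
        out.append(generate_family(f"{key}_{fam + 1:03d}", cfg, rng))
    return out


def mean_pairwise_cds_identity(family: FamilyTruth) -> float:
    """Mean percent identity over cross-gene CDS pairs, computed from the
    simulator's homology labels (identical paired codons over the union
    of codons of the two CDS)."""
    ids = sorted(family.cds_records)
    vals = []
    for i, c1 in enumerate(ids):
        g1 = family.cds_records[c1].gene_id
        for c2 in ids[i + 1 :]:
            g2 = family.cds_records[c2].gene_id
            if g1 == g2:
                continue
            vals.append(_pair_identity(family, c1, c2))
    return float(np.mean(vals)) if vals else float("nan")


def _pair_identity(family: FamilyTruth, c1: str, c2: str) -> float:
    sim1 = family.sim_genes[family.cds_records[c1].gene_id]
    sim2 = family.sim_genes[family.cds_records[c2].gene_id]
    sub1 = [sim1.exons[i] for i in _subset_of(family, c1)]
    sub2 = [sim2.exons[i] for i in _subset_of(family, c2)]
    by_anc2 = {e.ancestry: e for e in sub2}
    n1 = sum(len(e.codons) for e in sub1)
    n2 = sum(len(e.codons) for e in sub2)
    ident = 0
    matched = 0
    for e1 in sub1:
        e2 = by_anc2.get(e1.ancestry)
        if e2 is None:
            continue
        for i, j in _label_pairing(e1, e2):
            matched += 1
            if e1.codons[i] == e2.codons[j]:
                ident += 1
    union = n1 + n2 - matched
    return 100.0 * ident / union if union else 0.0


def _subset_of(family: FamilyTruth, cds_id: str) -> tuple[int, ...]:
    gid = family.cds_records[cds_id].gene_id
    anc = family.cds_ancestry[cds_id]
    index = {e.ancestry: i for i, e in enumerate(family.sim_genes[gid].exons)}
    return tuple(index[a] for a in anc)
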