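"""Stage 1: translated local anchors between a CDS and a gene.

Conserved coding segments are found by comparing the two sequences in
amino-acid space over all translation-frame pairs (seed-and-extend with
a BLOSUM62 matrix and a Karlin-Altschul style E-value), so that anchors
survive silent mutations and small frame differences.  Hits are then
assigned to the CDS exon they cover most, trimmed so they never cross an
exon boundary, and filtered down to a pairwise-compatible subset by
increasing E-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .core import CDSSequenceRecord, normalize_dna

__all__ = [
    "LocalHit",
    "AnchorSet",
    "AssignmentError",
    "translated_local_hits",
    "assign_and_trim",
    "filter_hits",
    "hits_compatible",
]

# Ungapped Karlin-Altschul parameters for BLOSUM62.
_LAMBDA = 0.3176
_K = 0.134

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = set(_BLOSUM62.alphabet)


def _aa_score(x: str, y: str) -> float:
    if x in _ALPHABET and y in _ALPHABET:
        return _BLOSUM62[x, y]
    return -4.0


class AssignmentError(ValueError):
    """A hit overlaps no CDS exon and cannot be assigned."""


@dataclass(frozen=True)
class LocalHit:
    """An ungapped translated local alignment, in nucleotide coordinates.

    ``(k, l)`` is the CDS interval, ``(a, b)`` the gene interval (both
    1-based inclusive); the two intervals have equal length.
    ``frame_pair`` records the translation frames (0/1/2) on CDS and
    gene.  Lower E-value means a more significant hit.
    """

    k: int
    l: int
    a: int
    b: int
    score: float
    evalue: float
    frame_pair: tuple[int, int]
    exon_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.k > self.l or self.a > self.b:
            raise ValueError(f"bad hit intervals: {self}")
        if (self.l - self.k) != (self.b - self.a):
            raise ValueError(f"hit intervals differ in length: {self}")
        if self.evalue < 0 or not math.isfinite(self.score):
            raise ValueError(f"bad hit statistics: {self}")

    @property
    def length(self) -> int:
        return self.l - self.k + 1

    def sort_key(self) -> tuple:
        # Increasing E-value; ties: higher raw score, leftmost CDS start,
        # leftmost gene start.
        return (self.evalue, -self.score, self.k, self.a)


@dataclass
class AnchorSet:
    """Filtered anchors, grouped per CDS exon and ordered along the CDS."""

    per_exon: dict[int, list[LocalHit]] = field(default_factory=dict)

    def all_hits(self) -> list[LocalHit]:
        out = [h for hits in self.per_exon.values() for h in hits]
        out.sort(key=lambda h: h.k)
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self.per_exon.values())


def _translate_frames(seq: str) -> list[str]:
    peps = []
    for f in range(3):
        sub = seq[f:]
        sub = sub[: len(sub) - len(sub) % 3]
        peps.append(str(Seq(sub).translate()) if sub else "")
    return peps


def _extend_seed(pep_q: str, pep_s: str, qi: int, si: int, word: int, xdrop: float):
    """Extend an exact word match ungapped in both directions with X-drop.

    Returns (qstart, qend, sstart, send, score) in 0-based aa coordinates
    (end exclusive).
    """
    score = sum(_aa_score(pep_q[qi + t], pep_s[si + t]) for t in range(word))
    # right extension
    best = score
    best_right = word
    cur = score
    t = word
    while qi + t < len(pep_q) and si + t < len(pep_s):
        cur += _aa_score(pep_q[qi + t], pep_s[si + t])
        t += 1
        if cur > best:
            best, best_right = cur, t
        if best - cur > xdrop:
            break
    # left extension
    cur = best
    best_left = 0
    t = 1
    while qi - t >= 0 and si - t >= 0:
        cur += _aa_score(pep_q[qi - t], pep_s[si - t])
        if cur > best:
            best, best_left = cur, t
        if best - cur > xdrop:
            break
        t += 1
    return qi - best_left, qi + best_right, si - best_left, si + best_right, best


def translated_local_hits(
    cds_seq: str,
    gene_seq: str,
    evalue_threshold: float = 1e-7,
    *,
    word_size: int = 3,
    xdrop: float = 20.0,
    min_word_score: float = 11.0,
) -> list[LocalHit]:
    """Find translated local alignments between a CDS and a gene sequence.

    All 3x3 forward frame pairs are compared (inputs are assumed to be in
    coding orientation).  Only hits with E-value at or below
    ``evalue_threshold`` are returned, ordered by increasing E-value.
    """
    cds_seq = normalize_dna(cds_seq)
    gene_seq = normalize_dna(gene_seq)
    if not cds_seq or not gene_seq:
        raise ValueError("both sequences must be non-empty")
    peps_q = _translate_frames(cds_seq)
    peps_s = _translate_frames(gene_seq)
    space = float(len(cds_seq)) * float(len(gene_seq))

    found: dict[tuple, LocalHit] = {}
    for fq, pep_q in enumerate(peps_q):
        if len(pep_q) < word_size:
            continue
        for fs, pep_s in enumerate(peps_s):
            if len(pep_s) < word_size:
                continue
            index: dict[str, list[int]] = {}
            for i in range(len(pep_s) - word_size + 1):
                index.setdefault(pep_s[i : i + word_size], []).append(i)
            seen_spans: set[tuple[int, int]] = set()
            for qi in range(len(pep_q) - word_size + 1):
                word = pep_q[qi : qi + word_size]
                if word not in index:
                    continue
                if sum(_aa_score(c, c) for c in word) < min_word_score:
                    continue
                for si in index[word]:
                    diag = qi - si
                    qs, qe, ss, se, score = _extend_seed(
                        pep_q, pep_s, qi, si, word_size, xdrop
                    )
                    span = (diag, qs)
                    if span in seen_spans:
                        continue
                    seen_spans.add(span)
                    evalue = _K * space * math.exp(-_LAMBDA * score)
                    if evalue > evalue_threshold:
                        continue
                    hit = LocalHit(
                        k=fq + 3 * qs + 1,
                        l=fq + 3 * qe,
                        a=fs + 3 * ss + 1,
                        b=fs + 3 * se,
                        score=score,
                        evalue=evalue,
                        frame_pair=(fq, fs),
                    )
                    key = (fq, fs, hit.k, hit.l, hit.a)
                    prev = found.get(key)
                    if prev is None or hit.score > prev.score:
                        found[key] = hit
    hits = sorted(found.values(), key=LocalHit.sort_key)
    return _merge_nested(hits)


def _merge_nested(hits: list[LocalHit]) -> list[LocalHit]:
    """Drop hits fully contained in a better hit on the same diagonal."""
    kept: list[LocalHit] = []
    for h in hits:
        redundant = False
        for g in kept:
            if (
                g.frame_pair == h.frame_pair
                and (g.k - g.a) == (h.k - h.a)
                and g.k <= h.k
                and h.l <= g.l
            ):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def assign_and_trim(hit: LocalHit, cds: CDSSequenceRecord) -> LocalHit:
    """Assign a hit to the CDS exon it covers most and trim it to that exon.

    Trimming removes the same number of alignment columns from the CDS
    and the gene side (hits are ungapped), so the trimmed hit never
    crosses the boundary of its exon.  Ties in overlap go to the
    lower-index exon.
    """
    best_i, best_overlap = None, 0
    for i, (ek, el) in enumerate(cds.local_exons):
        overlap = min(hit.l, el) - max(hit.k, ek) + 1
        if overlap > best_overlap:
            best_i, best_overlap = i, overlap
    if best_i is None:
        raise AssignmentError(f"hit {hit} overlaps no CDS exon of {cds.id!r}")
    ek, el = cds.local_exons[best_i]
    new_k = max(hit.k, ek)
    new_l = min(hit.l, el)
    dl = new_k - hit.k
    dr = hit.l - new_l
    return replace(
        hit,
        k=new_k,
        l=new_l,
        a=hit.a + dl,
        b=hit.b - dr,
        exon_index=best_i,
    )


def hits_compatible(h1: LocalHit, h2: LocalHit) -> bool:
    """Two hits are compatible iff their CDS intervals are disjoint, their
    gene intervals are disjoint, and their order is the same on both
    sequences (they are chainable)."""
    if h1.k > h2.k:
        h1, h2 = h2, h1
    return h1.l < h2.k and h1.b < h2.a


def filter_hits(hits: Iterable[LocalHit]) -> AnchorSet:
    """Keep a pairwise-compatible subset of exon-tagged hits, greedily by
    increasing E-value: first within each exon, then across exons."""
    by_exon: dict[int, list[LocalHit]] = {}
    for h in hits:
        if h.exon_index is None:
            raise ValueError("hits must be exon-tagged (run assign_and_trim)")
        by_exon.setdefault(h.exon_index, []).append(h)

    # step ii: within-exon compatibility
    survivors: list[LocalHit] = []
    for exon_index in sorted(by_exon):
        kept_exon: list[LocalHit] = []
        for h in sorted(by_exon[exon_index], key=LocalHit.sort_key):
            if all(hits_compatible(h, g) for g in kept_exon):
                kept_exon.append(h)
        survivors.extend(kept_exon)

    # step iii: cross-exon compatibility
    kept: list[LocalHit] = []
    for h in sorted(survivors, key=LocalHit.sort_key):
        if all(hits_compatible(h, g) for g in kept):
            kept.append(h)

    # step iv: group per exon, ordered along the CDS
    out = AnchorSet()
    for h in sorted(kept, key=lambda x: x.k):
        out.per_exon.setdefault(h.exon_index, []).append(h)
    return out
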