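# Methods

## Problem and model

`splicealign` computes spliced alignments of full coding sequences (CDS)
against unspliced gene sequences within a gene family, and infers CDS
splicing-orthology groups from those alignments.  The distinguishing
feature is that the optimization objective uses the *splicing
structures* of both inputs — the exon boundaries of the CDS and the
exon-intron boundaries of the gene — on top of nucleotide similarity
and raw GT-AG splice signals.

A spliced alignment is a chain of blocks `(k, l, a, b)` pairing CDS
interval `[k, l]` with gene interval `[a, b]`; `a = b = 0` marks a
deleted block (a CDS segment with no gene counterpart).  Blocks tile
the CDS; conserved blocks are strictly ordered on the gene.  Gene
segments between successive conserved blocks are the induced introns;
a deleted block between two conserved blocks breaks their adjacency,
so no intron is induced across it.  The objective maximized by the
global stage is

```
sum_blocks sim(block)
+ sum_introns  splicesignals(intron)
+ sum_introns  splicesites(intron)          # annotated-boundary term
+ sum_junctions exonjunction(junction)      # annotated-CDS-junction term
```

where `sim` is a linear-gap nucleotide alignment score.

## The aligner

The pipeline accumulates three stages, each exposed as a mode:

1. **LOCAL** — translated local anchors.  The CDS and gene are compared
   in amino-acid space over all 3x3 forward frame pairs (inputs are
   assumed in coding orientation; reverse-strand handling is out of
   scope).  Seeds are exact 3-aa words with BLOSUM62 self-score >= 11,
   extended ungapped with an X-drop of 20; significance is an ungapped
   Karlin-Altschul E-value (lambda 0.3176, K 0.134) over the
   nucleotide search space, thresholded at 1e-7.  Each hit is assigned
   to the CDS exon it covers most (ties to the lower index) and trimmed
   so it never crosses that exon's boundary; a pairwise-compatible
   subset is then kept greedily by increasing E-value, first within
   each exon, then across exons.  Two hits are compatible iff their CDS
   intervals are disjoint, their gene intervals are disjoint, and their
   order is the same on both sequences.  Note the significance floor:
   a perfect hit on a very short exon (< roughly 12 codons in a
   megabase-scale search space, less in small ones) cannot reach
   E <= 1e-7, so very short exons are invisible to this stage by
   design of the threshold.
2. **EXTEND** (default) — gapped extension of anchors toward exon
   boundaries.  Each side of an anchor is extended to the exon boundary
   (or the nearest neighboring anchor) in one of three configurations:
   (a) ungapped, (b) opening with a gap run on the gene row, (c)
   opening with a gap run on the CDS row; gap runs are multiples of 3
   up to `alpha = 21` so the coding frame is preserved.  The best
   candidate by identity over the *added columns only* is applied iff
   that identity is >= `beta = 30` percent (ties prefer (a) over (b)
   over (c), then fewer gaps; the left side is evaluated before the
   right).
3. **GLOBAL** — structure-aware DP over the still-unaligned exons.
   Runs of completely-unaligned CDS exons are aligned against the gene
   window between their flanking anchors, which divides the quadratic
   DP space.  The recurrence has five cases: match/mismatch, CDS gap,
   gene gap, a jump onto an annotated intron of the gene, and a jump
   over any gene region of length in `[imin, imax]`
   (`imax - imin = 5000`, `imin = 30` by default; the window exists
   because candidate introns must be long enough to splice yet bounded
   for tractability).  New blocks below `beta` identity are demoted to
   deleted blocks.

The fourth mode, **EXTEND_WS**, is EXTEND preceded by structure
inference when no annotations are given: each CDS is spliced-aligned
against its own gene at 100% identity by an exact multi-split string
search (a first pass requires GT..AG intron ends, a fallback pass does
not; matches are extended maximally and placed leftmost).  The
inferred chain always round-trips to the input CDS exactly.  When a
CDS is aligned against the very gene it came from, the pipeline emits
the alignment directly from its (annotated or inferred) chain — that
alignment is exact by construction.

### Scoring defaults and their rationale

The objective's orderings are fixed by the model; the concrete values
are implementation defaults, all configurable via `ScoringScheme`:
match +2, mismatch -1, gap -2 (linear; the recurrence is linear-gap by
design).  Splice-signal bonuses are decomposed additively per intron
end — donor GT +2, GC +1, AT +1; acceptor AG +2, AC +1 — giving pair
totals GT-AG 4 > GC-AG 3 > AT-AC 2 > none 0.  Additivity is what makes
the length-window jump case O(1) amortized (a sliding-window maximum
over `S(i, j') + donor(j')`), keeping the DP quadratic.  The signal
bonuses are deliberately small: raw dinucleotides occur everywhere by
chance, and large bonuses reward fabricating introns at pseudo-sites.
The annotation terms carry the structural weight instead: +4 per
intron end on an annotated exon boundary and +8 for a CDS-side
junction at a real exon junction.

Two structural constraints are made explicit in the DP state machine:
at least one CDS and one gene character must be consumed between two
jumps (and before the first/after the last), so every intron the score
counts really lies between two conserved blocks.  The DP is verified
against an independent oracle that enumerates block chains exhaustively
and scores blocks with Biopython's global aligner.

When an inter-anchor window is bounded by an anchor on a side, the
window's outermost gene characters on that side belong to the intron
connecting to that anchor; the inter-anchor DP therefore leaves them
unconsumed at no cost (free end semantics) instead of charging them as
alignment gaps.  The stand-alone DP is strictly global.

Percent identity (PID) of an alignment is computed over all columns of
conserved blocks, gap columns included in the denominator (a switch
selects the gapless-column convention); deleted blocks are excluded,
and PID is undefined for an all-deleted alignment.  CDS coverage is the
fraction of CDS positions in conserved blocks.

## Orthology inference

Two CDS `c1` (on gene g) and `c2` (on gene h) are splicing orthologs
when the spliced alignment of `c1`'s sequence against h shows the two
splicing structures coincide: (1) equal exon counts; (2) the alignment
induces exactly the introns of `c2` (exact gene-coordinate equality by
default; a +/- tolerance exists for noisy inputs); (3) corresponding
exon lengths congruent modulo 3 (same codon phase).  An alignment
containing any deleted block cannot support orthology, because a
deleted block breaks the one-to-one exon correspondence.  By default
one supporting direction suffices; a reciprocal variant requires both.
Pairwise relations are closed transitively: the orthology groups are
the connected components of the orthology graph (networkx), singletons
included.

## Simulator

The simulator generates a gene family along a rooted gene tree whose
branch lengths act as evolutionary rates.  The root gene has a
geometric exon count (mean 8, clamped to [2, 15]), log-normal exon
lengths in codons (median 50, sigma 0.35, clamped to [10, 100] — about
150 nt, vertebrate-like), log-uniform intron lengths in [60, 2000] nt
with canonical GT..AG ends, 30-nt random flanks, and 1-4 initial
isoforms (the full chain plus random exon subsets at keep-probability
0.75).  Exon lengths are kept in codon multiples so every emitted CDS
length is divisible by 3.

Along each branch of length t (times the preset scale), event counts
are Poisson with mean rate x t: exon duplication (0.2; the copy is
inserted adjacently with a forked ancestry id), exon gain (0.2; fresh
ancestry, random codons, canonical splice ends), exon loss (0.2;
removed from the gene and from every isoform, isoforms left empty are
dropped; events that would leave no exon or no isoform are skipped and
logged), isoform creation (0.3) and isoform loss (0.2).  Sequence
evolution is codon-level: each codon substitutes with probability
1 - exp(-t) through a kernel biased to single-nucleotide changes with
transition preference that never produces a stop codon, and indels of
1-2 codons hit exons at rate 0.02 per codon.  Introns drift by
substitution only (ends pinned); intron length evolution is not
modeled.  Every codon carries a homology label inherited through
descent (insertions mint fresh labels), so the emitted ground truth is
exact: true spliced alignments pair codons of same-ancestry exons by
shared labels, and two CDS are true orthologs iff their exon lists are
in ancestry bijection.

The three presets scale the same balanced 5-leaf tree.  Their scales
(small 0.04, medium 0.15, large 0.65) were calibrated once so the mean
pairwise CDS identity of generated families lands near the low /
medium / high divergence levels the presets emulate (about 78%, 42%
and 11% under the default root model).  A dataset is 36 independent
families of 5 genes; family-wide CDS totals are clamped to [5, 17]
(dropping or adding random isoforms, logged as clamp events).  All
randomness flows from one integer seed; identical seeds reproduce
datasets byte-for-byte.

### What the simulator does and does not emulate

It reproduces the structural phenomena the aligner exploits: conserved
exon boundaries across divergent sequences, alternative exon usage,
structure-changing events decoupled from sequence divergence, and
canonical splice signals.  It does not model intron length evolution,
splice-site erosion, non-canonical real splice sites, GC/codon-usage
heterogeneity, or any empirical codon rate matrix — the substitution
kernel is a stylized stand-in.  Passing tests therefore demonstrate
correctness of the algorithms under idealized splicing structure, not
performance on real annotations.

## Evaluation metrics

All metrics are precision / recall / f-score with
`f = 2pr / (p + r)`; precision is undefined (`None`, printed as N/A)
when nothing is predicted, and the f-score is undefined when either
component is.  Exon-extremity metrics compare block boundaries of the
predictions against (A) real CDS exon extremities, (B) real gene exon
extremities, or (C) canonical splice sites — defined as the boundaries
of annotated gene introns whose terminal dinucleotides are GT..AG;
matching is exact-coordinate with an optional +/- tolerance.
Alignment-pair metrics compare sets of (CDS position, gene position)
pairs from non-gap columns of conserved blocks.  Clustering metrics
compare co-clustered CDS pairs.  Summaries report mean and population
standard deviation per (mode, dataset) group.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive everywhere in memory and on disk;
  0-based conversions live only at I/O boundaries.
* `beta` comparisons are `>=` in both the extension and the global
  stage; E-value filtering is `<=` the threshold.
* Traceback ties prefer diagonal, then annotated-intron jumps, then
  window jumps (shortest intron), then CDS gaps, then gene gaps, making
  output deterministic.
* The quadratic DP refuses matrices above a configurable cell cap
  (default 2e6); the inter-anchor stage skips such windows with a
  warning, leaving the exons as deleted blocks.
* An all-deleted alignment is valid (coverage 0, PID undefined); empty
  anchor sets produce it rather than an error.
* A CDS that does not occur exactly in its own gene makes structure
  inference fail loudly; there is no fallback to sub-100% identity.
* Sequences are normalized to uppercase DNA (U -> T); characters
  outside ACGTN are rejected with the offending record named.

## Problem sizes used by the test suite

Alignment-heavy tests use a compact generator configuration (2-6 exons
of 24-120 nt, introns 60-200 nt; genes around 0.5-1 kb) chosen as the
package's test scale; generation-only and zero-event-recovery checks
run at the full default scale.  The DP-vs-oracle equivalence suite
runs 200 random instances with CDS <= 12 nt against the exhaustive
enumeration oracle.

## Known limitations

* Anchoring searches forward frames only and has the short-exon
  significance floor described above; SFA-style recovery of such exons
  requires the global stage.
* The global stage is quadratic per window and is not banded; its cost
  is why EXTEND, not GLOBAL, is the default mode.
* Orthology condition (2) is exact by default; real annotation noise
  requires the tolerance parameter.
* The simulator's truth pairs codons only within same-ancestry exons;
  homology created by exon duplication across different exon lineages
  is deliberately not counted as alignable truth.
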