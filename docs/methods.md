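# Methods

This note documents the models and procedures implemented in `plantmir`,
the defaults and why they were chosen, what the synthetic benchmark does
and does not demonstrate, and the numerical conventions that matter for
reproducing outputs.

## Discovery pipeline

**Homology seeding.** Candidate loci are windows of the genome within a
Hamming distance (default <= 3, configurable) of a known mature miRNA, on
either strand. Ungapped matching replaces a gapped local-alignment search
deliberately: mature miRNAs are 19-25 nt, too short for gapped seeds to
add sensitivity, and an exact Hamming scan is deterministic and directly
checkable against a sliding-window oracle. Windows extend +-336 nt (one
maximum repeat extent) around each seed and are merged when overlapping.

**Inverted-repeat detection.** Each window is locally aligned against its
own reverse complement (Smith-Waterman, match +3, mismatch -4, linear gap
penalty 12 per gap position — the einverted tool's documented scoring),
keeping non-overlapping alignments with score >= 25 whose span does not
exceed 336 nt and whose arms are separated by at least 3 nt of loop. Ties
are broken by score, then leftmost start, then shortest extent. The score
threshold and maximum repeat extent are the published screen settings; the
per-position scoring values are the tool defaults because only the
threshold and maximum repeat are stated in the source protocol. The
dynamic program is row-vectorized in numpy; repeated extraction masks the
positions of previously reported repeats. A pathological corner exists in
masked re-runs (a multi-position gap can bridge a masked column); it
cannot affect the first, highest-scoring repeat, which is the one the
exhaustive arm-pair oracle checks.

**Folding and descriptors.** The folding engine is pluggable:

* `vienna` — ViennaRNA bindings; MFE and partition-function quantities in
  kcal/mol at 37 degC. Used automatically when importable (`auto`).
* `fallback` — a built-in model used when no thermodynamic engine is
  configured: every admissible pair (Watson-Crick or G:U, hairpin loops
  >= 3 nt) scores -1 and every stacked pair a further -1. The MFE
  structure is found by dynamic programming with a deterministic
  traceback that prefers pairing the 5'-most base with its nearest
  admissible partner. Ensemble quantities (Z, pair probabilities,
  diversity) come from an exact inside/outside partition function over
  the same energy model at RT = 0.61633 kcal/mol, and are refused above
  30 nt, where a thermodynamic engine should be used. Its energies are
  dimensionless scores, not kcal/mol; every output row carries the engine
  name so fallback numbers cannot be mistaken for thermodynamic ones.

Descriptors follow the standard plant-miRNA definitions: AMFE = MFE/L x
100; MFEI = |AMFE| / GC%. The magnitude convention for MFEI is used
because it reproduces the 0.7-1.7 scale on which plant precursors are
reported; the alternative reading of the formula (multiplying by 100
twice) is dimensionally inconsistent with that scale. MFEE = -RT ln Z;
frequency of the MFE structure = exp((MFEE - MFE)/RT); ensemble diversity
is the expected base-pair distance, sum of 2 p(1-p) over pair
probabilities. Base composition is computed over non-N residues with
ratios reported as missing on zero denominators.

**Mature placement.** The terminal loop is the unpaired run enclosed by
the innermost pair of the deepest stem (stem depth = the unbranched chain
of enclosing pairs; bulges allowed). A mature must lie entirely on one
side of that loop (5p left, 3p right); placements spanning the loop are
invalid, and structures with more than one stem of depth >= 3 are rejected
as ambiguous rather than resolved heuristically.

**Filter cascade.** Filters run in a fixed order — length, GC window, MFE
sign, MFEI, mature placement, mature homology, blocklist — and all
failures are recorded, not just the first, under a closed vocabulary of
reason codes. Boundaries are inclusive: GC exactly 20 or 65 passes, MFEI
exactly 0.7 passes. Defaults: length window [60, 338] nt (bracketing the
observed 68-338 nt with slack at the low end), GC in [20, 65], MFE < 0
(no deeper cutoff is published for the energy filter itself), MFEI >= 0.7
(the lower edge of the reported 0.7-1.7 range; the protocol does not print
its threshold), mature homology <= 3 mismatches (a declared choice; the
tolerance is likewise unpublished). Repeat and ncRNA masking is consumed
as precomputed interval blocklists (any 1-nt overlap rejects) rather than
by running the external maskers. Overlapping accepted candidates on one
strand collapse to a single locus: lowest MFE, then longest, then
leftmost. Families are assigned by minimum mismatch count to the
reference set (ties to the lexicographically smallest family) and named
`ccp-MIR<family><letter>` in genomic order.

**Genomic context.** A locus is genic iff it overlaps any gene feature by
>= 1 nt, strand-agnostically — gene-level features only, since the target
report is a binary genic/intergenic label. Clusters chain consecutive
precursors (sorted by start) whose boundary gap (next start minus previous
end) is <= 10,000 nt inclusive; the anchor-point convention is a declared
choice since "distance between two miRNAs" admits several readings.
Singletons are not clusters; a cluster containing both strands is flagged
antiparallel.

## Machinery classification

AGO queries are globally aligned (BLOSUM62, gap open 10 / extend 0.5) to a
reference carrying the canonical PIWI anchors at AtAGO1 numbering (D760,
D845, H986 triad; auxiliary H798); the query residues at the mapped
columns form the motif string (e.g. `DDH/H`, `DDH/S`), with `?` and
`evaluable=false` when an anchor aligns to a gap. Because the natural
reference sequences are external database objects, the bundled references
are *synthetic scaffolds*: deterministic random proteins with the
canonical residues planted at the literature positions. Anchor mapping is
exact on proteins derived from these scaffolds (the synthetic benchmark);
on divergent natural AGOs the mapping inherits pairwise-alignment
uncertainty and may shift by a few residues. DCL proteins are read per
annotated RNase III (RIBOc) domain against an RNase III scaffold with the
E-D-D-E quartet; fewer than two RIBOc domains flags a partial protein.
RDRs use a deterministic pattern scan — `D[LF]DGD` for the polymerase
motif (leftmost match wins, with matches inside an annotated RdRP domain
taking precedence) and `[CA]SG[SG]` within the 30 residues upstream — in
place of a stochastic motif-discovery tool; for two fixed motifs the scan
is exact and fully checkable. Domain-architecture completeness compares
the observed domain multiset against family templates (DCL: DExD,
Helicase-C, DUF283, PAZ, 2x RIBOc, up to 2x optional DSRM; AGO: optional
Gly-rich, ArgoN, PAZ, optional ArgoMid, Piwi; RDR: RdRP); `missing`
reports every deficit against the full template while `complete` requires
only the mandatory domains.

## Phylogenetics

Distances: Kimura two-parameter for nucleotide alignments
(d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]; saturated pairs flagged infinite),
p-distance or Poisson correction (-ln(1-p)) for proteins. The protein
choice is a deliberate substitution for maximum-likelihood JTT distances:
at the divergence scales involved the NJ topology is robust to the
distance flavour, and the substitution is recorded in tree metadata so no
output can silently claim JTT. Gap handling defaults to complete deletion
(columns containing any gap removed before analysis), matching the
published tree legends; pairwise deletion is available per distance.

Neighbor joining is the standard Saitou-Nei agglomeration with
deterministic tie-breaking (lowest index pair) and negative branch
lengths clamped to zero (deficit recorded in metadata). Bootstrap
consensus resamples alignment columns with replacement, builds one NJ
tree per replicate, converts bipartition frequencies to percentage
supports, and greedily assembles the majority-rule consensus, collapsing
internal branches below 50%; replicates whose distance matrix saturates
contribute no splits. Consensus branch lengths are means over the
replicates containing each split (leaf branches: means over all
replicates) — a pragmatic convention, since a consensus tree has no
canonical length assignment. Supports attach to leaf-set bipartitions and
are therefore invariant to taxon input order and rooting.

## Target scoring

Expectation = sum of per-position penalties over the antiparallel duplex,
positions counted from the miRNA 5' end: mismatch 1.0, G:U wobble 0.5,
gap 2.0 per gap position, all doubled inside positions 2-13. At most one
gap per duplex (the published settings do not state the tool's gap
behaviour; one bulge is the declared default), best placement taken.
Sites with expectation <= 2.0 are kept; among overlapping sites of one
miRNA on one transcript the best, then leftmost, wins. Inhibition is
translational iff a non-paired position falls wholly inside miRNA
positions 9-11, else cleavage. The complementarity window equals the
mature length (19-25 nt); the 20-nt `hspsize` floor is recorded in the
parameters and only matters for miRNAs shorter than the floor, which are
still scored over their full length. Target-site accessibility (UPE,
cutoff 25) is a pass-through field on hits, not computed — reproducing it
requires an RNA-accessibility energy model outside this package's scope.

## Synthetic data: what it emulates and what it does not

`generate_genome` plants fold-back precursors (arm 45-60 nt, loop 8-15
nt, arm + loop + reverse-complement arm) in an i.i.d. background of
configurable GC (default 0.38, a typical plant genome-wide value). Mature
sequences are 19-25 nt with an exact length histogram in the ratio
2:3:8:3:2:1:1 (mode 21 nt) and a 0.8 probability of a 5' U, matching the
size profile and first-nucleotide bias reported for plant miRNA sets.
Each planted family contributes a "known ortholog" to the reference set
differing from the planted mature by <= 1 substitution. Defaults: 3
chromosomes of 50 kb, 20 plants, 2 mismatches per opposite arm (natural
stems are imperfect), genic fraction 0.2 realized exactly by constructed
gene models (plus background genes), and 5 transposon-like decoy inverted
repeats that carry a real planted mature — so they pass every sequence
filter and are rejected only by the blocklist, which is exactly the role
repeat masking plays on real genomes. All randomness flows through one
seeded generator; outputs are byte-identical per seed.

Not emulated: higher-order background composition (k-mer structure,
isochores), multi-loop or branched precursors, sequencing error,
expression levels, and genome-scale repeat families. Consequences worth
stating plainly: perfect or near-perfect planted stems fold much more
stably than natural precursors, so synthetic MFEI values (~2) sit above
the natural 0.7-1.7 band, and the 50-kb chromosomes make 10-kb clustering
far denser than in a real genome. Passing the synthetic benchmark
demonstrates correctness of the machinery (seeding, scanning, folding
arithmetic, cascade logic, bookkeeping), not real-genome sensitivity or
specificity, which depend on engine energies and the unpublished homology
cutoffs of the original protocol.

`generate_protein_set` builds AGO/DCL/RDR proteins from the synthetic
scaffolds with random N-terminal padding (exercising the alignment
mapping) and named corruption rules ("H798->S", "RIBOc1:E1->Q",
"DLDGD->DFDGD", ...), emitting the expected classifier reports alongside.

## Numerical and scale choices

Internal coordinates are 0-based half-open; all reports are 1-based
inclusive. DNA is the storage alphabet (RNA normalized on read, re-emitted
as RNA only in miRNA-facing FASTA). Pseudochromosomes of unplaced
scaffolds are ordinary chromosomes. Problem sizes in the test suite and
acceptance script — 200 scan windows <= 40 nt against the O(n^4) arm-pair
oracle, 100 sequences <= 30 nt against full structure enumeration
(structure-rich draws above 200k structures are redrawn), 500 duplexes,
additive trees of 4-8 taxa against the all-topology least-squares oracle,
200 bootstrap replicates — were chosen so each oracle comparison is
exhaustive at its scale while the whole suite runs in minutes on one CPU.
Floating-point comparisons in the dynamic programs use 1e-9 slack;
energies from ViennaRNA are single precision.

## Known limitations

* Fallback-engine energies are not thermodynamic; MFEI/AMFE from it are
  only internally comparable (the engine label travels with every row).
* The H798-equivalence for natural AGOs depends on one global pairwise
  alignment; divergent paralogs may map a few residues off.
* Bootstrap consensus branch lengths are means over replicates, not a
  least-squares fit.
* Target scoring implements the penalty schema without the accessibility
  (UPE) term; hits on open versus occluded sites are not distinguished.
* Alignment construction (MSA) is out of scope; the phylogenetics module
  consumes pre-aligned FASTA.
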