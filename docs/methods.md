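# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind `retrodyn`, and the limits of what its synthetic benchmark
demonstrates.

## 1. The synthetic study design

Every stage is exercised against genomes built by `retrodyn.simdata`, which
plants full-length LTR retrotransposons with complete ground truth:

- **Background**: i.i.d. nucleotides at a configurable GC content (default
  0.40, typical of plant euchromatin). There are no background repeats by
  default, which makes recall/precision accounting exact; decoy repeats can
  be added by planting extra subfamilies.
- **Elements**: each copy is `TSD + 5'LTR + internal + 3'LTR + TSD`. LTRs
  carry the canonical `TG...CA` termini; the TSD (default 5 bp) is the host
  sequence duplicated at the insertion point, exactly as a real
  integration leaves it. The internal region carries GAG, RT (copia- or
  gypsy-type) and integrase coding blocks in frame.
- **Subfamily structure**: each subfamily has a private LTR and internal
  template. The domain coding blocks of a subfamily are its own variant of
  the shared domain consensus, mutated at 0.25 substitutions/site, so
  subfamilies are recognisably homologous in protein space but well
  separated in nucleotide space (inter-subfamily coding identity ~60%,
  below both the 85% detector similarity threshold and the 70%
  classification identity floor). Real subfamilies likewise differ
  throughout their coding regions; without this separation, chance pairings
  between neighbouring copies of *different* subfamilies would be
  structurally indistinguishable from real elements.
- **Ages**: a copy of age `T` (in MY) receives LTR divergence `k = 2rT`
  under the clock rate `r` (default 4.72e-9 /site/year). Substitutions
  are applied *independently to each LTR copy* at `k/2` expected events
  per site via a Kimura-type jump process (Poisson multiple hits,
  transition:transversion 2:1), so the K2P estimator applied to a planted
  pair is statistically consistent for `k`. Truncated copies keep both
  LTRs but carry random internal sequence (no domains), modelling
  internally deleted elements.
- **Reads**: uniform paired-end sampling; exactly
  `floor(depth x genome_length / (2 x read_length))` pairs; mate 2 is the
  reverse-complemented fragment end; per-base substitution errors at the
  configured rate (default 1e-3). No indels and no quality-score model —
  the mapper contract is ungapped, so indel errors would only shift the
  mapped fraction, not the relative abundances.
- **Second genome**: derived from the same background by keeping each
  insertion with probability `shared_fraction` (dropping an insertion
  seamlessly restores the single host TSD) and optionally planting
  B-specific copies. Shared sites therefore have *identical* flank
  context in both genomes, the idealised case for flank-based site
  matching.

Everything is deterministic under the config seed; per-stage seeds are
derived from the global seed so stages can be rerun in isolation.

**What passing these tests shows — and does not.** Recovery at 100% recall
with zero false positives reflects a clean substrate: no nested
insertions, no solo LTRs, no segmental duplications, substitution-only
divergence, and a reference library identical to the planting templates.
Real genomes add all of those; the numbers from the synthetic study
characterise the implementation, not expected field performance.

## 2. Structural detector

LTRharvest-style detection at desk scale, re-implemented:

1. exact k-mer self-anchoring (k = 20; k-mers occurring > 100 times
   skipped): position pairs of a repeated k-mer at separations compatible
   with an element become anchors on a diagonal;
2. anchors on one diagonal are chained (max gap 300 bp, ≥ 2 anchors);
   clusters on diagonals within 15 bp of each other merge;
3. ungapped X-drop extension (drop 12) on the diagonal, then boundary
   snapping to paired `TG`/`CA` termini within ±6 bp when present;
4. the repeat pair is accepted if the LTR length is in [100, 2000] bp,
   the element span in [1, 16] kb, and the *global-alignment* percent
   identity of the two LTRs (match +1, mismatch −1, gap open −5, extend
   −1; identity over all alignment columns) reaches the threshold
   (default 85%);
5. TSD annotation: exact flanking duplication of 4–6 bp (5 preferred);
   `TG...CA` termini flag.

**Overlap resolution** keeps, among mutually overlapping candidates:
TSD-bearing first, then highest LTR similarity, then longest, then
leftmost. TSD presence outranks similarity because two same-subfamily
copies within element-span distance of each other offer a chance repeat
pairing (LTR of one copy against LTR of the next) whose similarity equals
a genuine pair's; the TSD is the structural evidence that discriminates a
real insertion, and a chance 5-bp duplication at a spurious boundary has
probability ~1/1000.

The test-suite oracle is an exhaustive diagonal scan (every separation,
sliding-window identity) — quadratic, index-free, and independent of the
detector's anchoring and extension heuristics.

## 3. Domain filter

Internal regions are translated in all six frames and scored against
packaged position-specific score matrices built from single consensus
blocks (BLOSUM62 rows) for GAG, integrase, RT-copia and RT-gypsy. The
blocks are synthetic stand-ins written around the canonical motifs of each
family and are documented as such; curated alignments can be substituted.
Thresholds are set by calibration: the maximum best-window score of 1000
random 500-aa peptides, times 1.5, floored at 30% of the profile
self-score (the floor dominates; random best-window scores sit near zero
while self-scores are 600–1100). The packaged thresholds are frozen from
that procedure at seed 0 and re-checked by the test suite; 300 fresh
random peptides score below every threshold, supporting the ≥ 0.999
specification. An element is kept if any domain passes; superfamily is
the better-scoring RT variant when either RT passes, else `unknown`.

## 4. Library classification

Element-vs-reference comparison is a seeded ungapped search (16-mer
anchors, per-diagonal sliding 50-bp window identity ≥ 60% marks covered
reference positions; both query strands tried). Per reference this yields
an identity (over covered positions) and a reference coverage fraction.
Statuses:

- `classified` — exactly one reference with coverage ≥ 0.8 at identity
  ≥ 70%, and no second reference with a substantial hit;
- `partial_hit` — one substantial hit (coverage ≥ 0.3) below full
  coverage;
- `multi_hit` — ≥ 2 substantial hits (merged/chimeric elements);
- `no_hit` — nothing above the floors.

The 0.8 coverage cutoff operationalises "full-length match"; 0.3 is the
floor at which a second reference counts as evidence of a chimera (a
half-and-half chimera scores ~0.5 coverage on each parent). Family-level
abundance uses classified elements only.

## 5. Read mapping and RPKM

The mapper implements a Bowtie-1-like contract: a read maps iff it has an
ungapped end-to-end alignment on either strand with ≤ 2 mismatches
(pigeonhole seeding with seeds of length `read_length // (mismatches+1)`,
full Hamming verification; exhaustive within the contract, verified
against a brute-force all-offsets oracle). Each mapped read increments
exactly one target; ties at the best mismatch count are broken uniformly
under the run seed, so totals are conserved and within-family ambiguity
cancels in family sums. `N` comes from a separate genome pass; element
counts from an element-set pass. Per-element RPKM = `c*1e8/(L*N)` with
`L` the element length in bases (the 1e8 constant contains the kb
conversion of the "per kilobase per hundred thousand" definition); the
element value is the mean of the two mate passes, run as independent
single-end datasets because paired-end constraints would lose coverage on
elements shorter than the insert size.

Zero handling in log2 comparisons: both zero → ratio 0, unflagged;
exactly one zero → ±inf recorded, flagged only if the nonzero value is
≥ 0.1 RPKM (below that, a zero is indistinguishable from sampling noise).

## 6. Dating

Divergence is computed from a global LTR–LTR alignment (same scoring as
the detector) with gap columns excluded entirely; < 50 ungapped columns
triggers a low-confidence warning. Models: p-distance, JC69
(−¾ ln(1−4p/3)), K2P (−½ ln((1−2P−Q)√(1−2Q))); saturation (log argument
≤ 0) is an error naming the element. K2P is the default — the
conventional choice for LTR dating, correcting multiple hits and ts/tv
bias; the alternatives are selectable to probe model sensitivity.
`T = k/(2r)` in years; histogram bins are left-closed, right-open, 2 MY
wide by default.

Expected precision: a 400-bp LTR pair at 1 MY carries ~4 substitutions,
so *per-copy* age estimates have ~50% relative noise; means over ≥ 100
copies at 1-kb LTRs recover planted ages within a few percent (the suite
asserts 15%).

## 7. Landscape and insertion sites

LTR queries are located by the same seeded ungapped search (identity
≥ 80%, query coverage ≥ 0.8, both strands; overlapping hits of one query
keep the best identity). Each element contributes its two LTR loci —
counts are LTR-locus counts, not element counts, which also captures solo
LTRs when present. Window counts assign each locus to the window holding
its start; the final partial window is kept.

Site matching is keyed on flank context, not coordinates, because
assemblies differ: a site is homologous iff a same-subfamily site in the
other genome matches both ±200 bp flanks at ≥ 80% global-alignment
identity over ≥ 100 aligned bases. Matching is greedy by mean flank
identity, deterministic, and one-to-one (one locus cannot make several
counterpart loci homologous). `homologous + specific = mapped` holds per
genome by construction.

## 8. Lineage trees

Pairwise protein distances are 1 − identity over non-gap columns of a
global BLOSUM62 alignment (open −11, extend −1). Neighbor joining is the
classical Q-criterion algorithm with deterministic tie-breaking by label
order and negative branch lengths clamped to zero (count noted on the
tree); it is exact on additive matrices, which the suite verifies against
exhaustive topology search with least-squares branch fitting for n ≤ 6.
Copia and gypsy peptides are always clustered in separate trees. A query
takes the lineage of the smallest enclosing clade containing references;
mixed-lineage clades fall back to nearest-reference-by-path and are
flagged ambiguous. The packaged lineage exemplars are synthetic
stand-ins (superfamily RT consensus mutated at 35% at lineage-specific
positions); real exemplar peptides can be passed in their place, and
published lineage counts for real genomes are not reproducible with the
stand-ins — only the procedure is.

## 9. Pipeline, problem sizes, determinism

`run_pipeline` derives one sub-seed per stage from the global seed, so
stages rerun identically in isolation; reports are byte-identical across
reruns of the same config, and the config hash covers the scientific
parameters (not the output path). Percentages in summary tables use
half-up rounding to one decimal.

Standard problem sizes, chosen to make the full suite and the acceptance
script each complete in a couple of minutes on a single core while
keeping ≥ 20 plantable copies per study: 300-kb genomes, 4 subfamilies,
8–10x depth, 100-bp reads; the pipeline smoke config uses 150 kb at 4x.
All sizes scale up linearly via the config.

## 10. Known limitations

- No indels in mutation or sequencing-error models; the detector's
  alignment scoring handles indels, but the classifier's and locator's
  ungapped search assumes substitution-dominated divergence.
- No nested insertions, solo-LTR recombination events, or segmental
  duplications in the generator; detector behaviour on those is untested.
- Domain profiles and lineage exemplars are synthetic stand-ins, adequate
  for discrimination on synthetic data, not curated biology.
- The mapper is exact within its ungapped ≤ 2-mismatch contract but is
  not a general-purpose aligner (no gapped, clipped or quality-aware
  modes).
- Absolute copy numbers are out of scope: RPKM is a relative,
  depth-normalised proxy and is not calibrated to genome size.
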