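# retrodyn

Genome-wide analysis of LTR retrotransposons (LTR-RTs): structural
discovery, relative copy-number profiling from resequencing reads,
insertion-time dating, chromosomal distribution, and cross-genome
insertion-site comparison — with a first-class synthetic-data generator
that plants elements with known ground truth, so every stage is testable
end to end without external databases or aligners.

## Who this is for

Plant and comparative genomicists studying transposable-element dynamics:
how many copies of each LTR-RT subfamily a genome carries, how abundances
differ between accessions or species, when elements inserted, and which
insertion sites are shared between two genomes (ancestral) versus
lineage-specific.

## The methods at the core

**Structural discovery.** A full-length LTR-RT is a pair of
near-identical long terminal repeats (LTRs) flanking an internal region
with GAG, reverse-transcriptase (RT) and integrase coding domains, the
whole insertion bracketed by a short target-site duplication (TSD).
`retrodyn` finds candidate elements by exact k-mer self-anchoring (repeat
pairs at element-compatible separations), scores the LTR pair by global
alignment at a configurable similarity threshold (default 85%), filters
candidates by six-frame protein-domain profiles (packaged PSSMs for
GAG/INT/RT, calibrated so random peptides essentially never pass), and
classifies survivors against a reference retroelement library
(classified = exactly one reference hit covering ≥ 80% of the reference
at ≥ 70% identity).

**Relative copy number.** Reads are mapped ungapped end-to-end with
≤ 2 mismatches, each mate file as an independent single-end pass, and
per-element abundance is

```
RPKM = c × 10⁸ / (L × N)
```

reads mapped to the element (`c`) per kilobase of element (`L` in bases)
per hundred thousand reads mapped to the reference genome (`N`); the
element value averages the two mate passes, and family abundance is the
sum over the family's classified members. Accessions are compared per
family on |log₂ ratio| ≥ 2 (four-fold); the top-10 families per accession,
union-ed across accessions, form the high-copy set.

**Insertion dating.** The two LTRs are identical at insertion and diverge
afterwards at the neutral rate, so under a molecular clock

```
T = k / (2 r)
```

with `k` the LTR–LTR divergence (Kimura two-parameter by default;
JC69 and raw p-distance selectable) and `r` the substitution rate
(default 4.72 × 10⁻⁹ /site/year).

**Insertion sites.** LTR queries are located on two genomes; a site is
*homologous* when a same-subfamily site in the other genome matches both
±200 bp flanks (≥ 80% identity over ≥ 100 aligned bases, one-to-one
greedy matching), otherwise *specific*. Loci are also binned into 1-Mb
windows for distribution profiles.

**Lineage assignment.** RT peptides of high-copy subfamilies are placed
in a neighbor-joining tree (authored implementation, deterministic
tie-breaking) together with exemplars of the named copia lineages (Ivana,
Ale, Maximus, TAR, Bianca, Angela) and gypsy lineages (Tekay, CRM,
Athila, Tat, Galadriel, Reina), one tree per superfamily; each query
takes the lineage of its smallest enclosing reference clade.

## Worked example

```python
from retrodyn.simdata import SimConfig, SubfamilySpec, simulate_genome
from retrodyn.discover import (find_ltr_candidates, filter_by_domains,
                               classify_subfamilies)
from retrodyn.dating import date_elements

cfg = SimConfig(
    genome_length=120_000,
    subfamilies=(
        SubfamilySpec(name="CopiaA", superfamily="copia", copy_number=3,
                      age_my=1.0),
        SubfamilySpec(name="GypsyB", superfamily="gypsy", copy_number=2,
                      age_my=2.5),
    ),
    seed=7,
)
genome, truth = simulate_genome(cfg)
candidates = find_ltr_candidates(genome)
elements = filter_by_domains(candidates, genome)
library = {n: ltr + i + ltr for n, (ltr, i) in truth.templates.items()}
assignments = classify_subfamilies(elements, library)
ages = date_elements(elements, genome)
print(f"planted {len(truth)} copies -> {len(candidates)} candidates, "
      f"{len(elements)} with protein domains")
for a, t in zip(assignments, ages):
    print(f"{a.element_id}: {a.subfamily} ({a.identity:.1f}% id), "
          f"k = {t.k:.4f}, T = {t.t_my:.2f} MY")
```

prints

```
planted 5 copies -> 5 candidates, 5 with protein domains
chr1.ltr0: GypsyB (98.9% id), k = 0.0126, T = 1.34 MY
chr1.ltr1: CopiaA (99.6% id), k = 0.0126, T = 1.34 MY
chr1.ltr2: CopiaA (99.7% id), k = 0.0076, T = 0.80 MY
chr1.ltr3: CopiaA (99.5% id), k = 0.0294, T = 3.11 MY
chr1.ltr4: GypsyB (99.1% id), k = 0.0306, T = 3.25 MY
```

All five planted copies are recovered and classified to their true
subfamilies at the expected identities; the per-copy age estimates
scatter around the planted 1.0 / 2.5 MY values with the sampling noise
expected from 400-bp LTRs (a handful of substitutions per pair).

The same chain runs from a shell via the `retrodyn` CLI
(`simulate | discover | abundance | date | landscape | lineage | run`);
`retrodyn run --config cfg.yaml` executes everything from one YAML config
and writes per-stage TSV/BED/FASTA outputs plus a consolidated
`report.json` stamped with the config hash and seed.

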