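# Methods

## The counting model

A query sequence q (a read or an assembled contig; contigs count as single
sequences no matter how many reads built them, so counts must not be read
as abundances) is summarised by the set T(q) of taxa tied at its best
alignment bitscore after an e-value significance filter. At a clade level
r ∈ {species, genus, family, division} each taxid in T(q) is mapped to its
ancestor (or itself) with rank r; taxa whose lineage has no node of rank r
drop out. Writing k for the number of distinct clade taxa that remain:

* k = 1: the taxon's unique count increases by 1;
* k ≥ 2: each taxon's fractional sum increases by 1/k and its ambiguous-
  sequence tally by 1;
* k = 0: the query is excluded at level r (tallied per report).

This gives exact mass conservation at every level: Σ unique + Σ fractional
+ excluded = number of assigned queries. The *first-taxon* report applies
the same tie logic with identity resolution (the counted taxon is the
alignment's own taxid), so nothing is ever excluded; it is the level at
which viruses are read, since viral taxonomy entries frequently carry
"no rank" and have no species/genus ancestors. The *legacy* report merges
the split back into a single total per taxon, total = unique + fractional,
which is what earlier hit-counting pipelines reported.

Detection defaults to unique count > 0. Since unique > 0 implies
total > 0, detections under the unique rule are a subset of those under
the legacy total > 0 rule on any fixed run; the suppressed calls are
precisely the fractional-only taxa, which on simulated data are dominated
by false positives from conserved genes. This set inclusion is asserted as
an invariant in the test suite.

### Numerical choices

Fractional shares are accumulated as `fractions.Fraction`, so per-query
contributions are exactly 1/k, report totals are independent of query
order, and the legacy identity total ≡ unique + fractional holds exactly
rather than to float tolerance. TSV reports render fractions with 4
decimal places. Report rows are ordered by descending
(unique, fractional, taxid) for stable diffs.

Ties are defined as exact bitscore equality by default
(`tie_tolerance=0`); a relative tolerance is available for score formats
with limited precision. Hits are ranked by bitscore, not e-value, because
bitscore is database-size independent. Multiple hits from one query to the
same subject collapse to the best one before tie analysis so a single
subject cannot vote twice. The default significance cutoff is
e-value ≤ 1e-5. Paired-end mates are treated as independent single reads
throughout.

When some tied taxa lack the counted rank, the default renormalises k over
the resolvable taxa (a bacterium/virus tie at species level becomes a
unique bacterial hit). The alternative — excluding the whole query whenever
any tied taxon lacks the rank — is a documented switch
(`exclude_partial_queries=True`); which behaviour older pipelines used is
not well defined, so both are implemented and the more informative one is
the default.

Retired taxids (present in alignments, absent from the taxonomy and its
merged map) drop the affected hit with a logged warning and a diagnostics
tally rather than failing the run, since reference databases and
taxonomies routinely drift apart.

### The related-virus post-filter

Without genome-level taxonomy, closely related viruses (e.g. two
*Clostridium phage* entries) can both attract alignments from one true
source. The filter removes, within each related pair, the member whose
total is at least `ratio_threshold` (default 10) times lower. Pairs are
processed in descending order of the larger member's total, and a removed
taxon cannot itself remove anything, making cascades deterministic. Pairs
with equal totals are never touched. Relatedness is supplied either as an
explicit pair list or by a name heuristic (names agreeing on every token
up to and including the first "phage"/"virus"). The filter is off by
default: it automates a judgement that has historically been made by
manual inspection, and the heuristic is a proxy, not a phylogeny.

## The synthetic benchmark

The simulator emulates an RNAseq metatranscriptome experiment over a
three-kingdom community at desk scale. Defaults (chosen once, as the
package's standard study conditions):

| parameter | default | meaning |
| --- | --- | --- |
| reference size | 20 bacteria / 12 fungi / 8 viruses | organism pool (~40 organisms) |
| genes per organism | 8, lengths U[300, 900] bp | transcript complement |
| conserved fraction | 0.2 | genes descending from a family-level ancestor (2% divergence per organism) |
| strain fraction | 0.5 | bacterial/fungal species carrying two strain variants, 0.5% divergence each |
| community | 10 bacteria / 6 fungi / 5 viruses | selected without replacement |
| gene selection | 25% bacteria / 50% fungi / 100% virus | fraction of genes expressed, ceil-rounded |
| relative abundance | 1 (fixed) or U[1, 20] (variable) | per organism |
| expression | 1 (fixed) or log-uniform [1, 1000] (variable) | per gene; 1000:1 maximum dynamic range by construction |
| read length | 100 bp fixed (or per-read U[min, max]) | unidirectional, forward strand |
| error rate | 0.01 | i.i.d. substitutions, alternative base uniform |
| host fraction | 0.0 (0.95 in the host-subtraction scenario) | fraction of total depth from the host organism |

Sequencing depth is usually specified through a per-kingdom coverage
target; coverage = (reads × read length) / (total selected transcript
bases in the kingdom), and depth splits equally (fixed mode) or
proportionally to abundance and expression (variable mode) using
largest-remainder rounding, which conserves the configured depth exactly
and breaks ties by ascending taxid/gene id. All randomness flows from one
seeded Mersenne Twister per step; identical configs and seeds give
byte-identical outputs.

The log-uniform expression law is a deliberate choice: the only hard
constraints adopted are the [1, 1000] range and the 1000:1 maximum ratio,
and log-uniform is the simplest heavy-tailed law satisfying them. The
distribution is pluggable.

What the generator deliberately reproduces: cross-species ambiguity
through conserved gene families, strain-level ties that collapse to unique
species hits, viral lineages invisible to species/genus reports, host
admixture, and coverage starvation of low-abundance organisms in variable
mode. What it does not reproduce: indels and quality-score error
structure, chimeric reads, assembly artifacts, rRNA carryover, database
incompleteness (every simulated organism is in the reference), and real
phylogenetic sequence divergence (conservation is modelled as uniform
substitution distance). Perfect scores on the benchmark therefore bound
the method's behaviour under its own assumptions; they do not promise
equivalent accuracy on real libraries, where database gaps dominate.

### The fixture aligner

End-to-end runs need alignments, and alignment itself is out of scope
(megaBLAST/DIAMOND territory). The bundled fixture aligner scores each
read against every reference transcript with edlib semi-global edit
distance, reports hits at ≥ 90% identity with a score of +2 per match and
−4 per edit, and derives a nominal e-value from that score. Equal-error
placements tie exactly, which is the property the counting scheme needs.
It is a testing device for fixture-scale references, not a BLAST
replacement, and external aligners can be plugged into the pipeline as
command templates instead.

### Evaluation

Bacteria and fungi are scored at species and genus level, viruses at the
first-taxon level. A detected taxon is attributed to a kingdom by
division-level resolution (default label "superkingdom"; configurable to
"kingdom" or "phylum" for taxonomies that split elsewhere); detections
outside the configured kingdoms are kept in an "other" bucket so
false-positive accounting loses nothing. TPR and FDR are left absent when
their denominators are empty. TN is undefined and never reported.

The benchmark suite runs the full chain (generate → select → allocate →
simulate → align → reduce → count → score) at coverage 4 in fixed mode for
the scheme comparison, and in variable mode at coverages 4 vs 0.25 for the
coverage-criticality property: with variable abundance, coverage 0.25
starves the rarest organisms of reads entirely and the unique-rule TPR
drops strictly below the high-coverage value. Fixed mode is not used for
that contrast because equal splits at these community sizes leave every
organism at least a few reads and detection does not degrade. Problem
sizes (~2,000 reads against ~480 transcripts per run) keep the whole suite
in the tens of seconds while leaving every per-organism effect visible.

## Pipeline stages

Host subtraction removes reads whose alignment against host references
meets identity (default ≥ 90%) and length (default ≥ 40 bp) thresholds;
with the fixture's identity structure (host transcripts unrelated to
microbial ones) thresholds of 95% / 50 bp remove ≥ 99% of tagged host
reads while touching ≤ 0.1% of microbial reads, which the pipeline tests
assert. Assembly and alignment are hooks — a command template with
`{input}`/`{output}` placeholders, or precomputed artifacts, or (for
alignment) the fixture aligner — so the core is fully testable without
external binaries; a pass-through "assembler" (reads are the contigs) is
the default. The aligner stage is integrity-checked: a hit table
mentioning queries outside the contig set aborts the run. No stage mutates
its inputs; per-stage counts are collected in a manifest and written
alongside the TSV/JSON reports.

## Known limitations

* Counts are evidence tallies, not abundances: expression and assembly
  both confound any abundance reading, and none is offered.
* The virus-relatedness heuristic keys on names only.
* The tie definition assumes the upstream aligner reports comparable
  bitscores; mixing aligners in one hit table is undefined behaviour.
* The simulator's conserved-gene model induces ambiguity within families
  only; real horizontal transfer crosses larger distances.
* Detection thresholds are deliberately simple (unique > 0); no FDR
  control across taxa is attempted.
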