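# Methods

## The problem

Read-level metagenomic classifiers run with default parameters report
far more species than a sample contains. On single-species insect
libraries analysed by mitochondrial metagenomics, an alignment-based
pipeline (BLASTn followed by MEGAN6's LCA) reports tens of species and a
k-mer pipeline (Kraken2) hundreds, where exactly one is present. Most of
the spurious species carry very few reads, and — crucially — two
classifiers with different matching strategies rarely misassign the
*same* read to the *same* wrong species. `taxensemble` exploits both
facts: it intersects (or unions) the two classifiers' per-read
assignments and then applies a relative-abundance detection limit.

## Species-level resolution

Both classifiers place some reads above the species rank (the LCA of
disagreeing matches) and, depending on the reference taxonomy, some
below it (strain or subspecies nodes). All assignments are normalised
before merging:

* a species-rank taxid maps to itself;
* a node below species rank is **promoted** to its nearest species
  ancestor — the read's species identity is unchanged, and discarding it
  would throw away signal;
* a node at or above genus rank, or a rankless node with no species
  ancestor, maps to *not assigned* (NA), as does Kraken2's taxid 0;
* species identity is compared by taxid only, never by name: classifier
  rank flags are untrusted (MEGAN can flag a species *group* as rank
  "S"), so the taxonomy table's rank column is authoritative.

Resolution is idempotent and its image is exactly {NA} ∪ {species
taxids}, both asserted by property tests.

## The merge rules

For one read *r* with species-resolved assignments (a_p, a_q):

| a_p | a_q | union | intersection |
|-----|-----|-------|--------------|
| NA  | NA  | NA    | NA |
| s   | NA  | s     | NA |
| NA  | s   | s     | NA |
| s   | n≠s | NA    | NA |
| s   | s   | s     | s  |

The read universe is the union of both tables' read ids; a read absent
from one table is NA for that classifier (MEGAN's r2c format omits
unassigned reads, Kraken2 lists them with status `U`; both tools saw the
same input reads). The merge is symmetric, strictly pairwise, and never
invents a species absent from both inputs (asserted at run time).

A consequence worth knowing: the union's species list is *not* a
superset of each base list. A species supported only by reads on which
the other classifier chose a different species loses those reads to the
conflict rule, so union richness can dip slightly below the richer base
classifier. The tests therefore assert the true containments
(intersection ⊆ each base ∩ union; union ⊆ base ∪ base) rather than a
richness ordering.

## Detection limit

A species enters a sample's list only if its relative abundance —
assigned reads over **total QC-passed reads** in the sample, the same
denominator as the sample-level RPIR — is **greater than or equal to**
the threshold ε. The inclusive comparison is deliberate: the reference
per-library false-positive lists bundled in `taxensemble.datasets`
include a species at printed abundance 0.001 that survives the ε = 0.001
column, and species at 0.0001 that survive ε = 0.0001, so only `>=`
reproduces every reported count. An assigned-reads denominator is
available as a non-default option (`denominator="assigned"`).

Filtering keeps counts and `total_reads` unchanged, hence it is
idempotent at fixed ε and monotone in ε (richness non-increasing). It is
applied *before* TP/FP counting, so reads of filtered species count
neither as true nor as false positives — precision rises with ε while
recall is untouched (the focal species always sits far above the
thresholds considered; if it ever fell below ε the method would simply
score TP = 0).

## Benchmark metrics

On a single-species library every read's true origin is the focal
species. Per method (base classifier, union, or intersection):

* **TP** — reads assigned to the focal species (post-filter);
* **FP** — reads assigned to any other surviving species;
* **FN** — |U| − TP floored at 0, where U is the set of reads assigned
  to the focal species by *at least one* of the two base classifiers.
  Most reads are nuclear DNA that cannot map onto a mitogenome, so
  "unassigned" is usually uninformative; U is the set demonstrably
  recoverable by some tool. The same U serves base and merged methods,
  which is what makes recall comparable across methods.
* **True negatives are not computed**: an unassigned read may be
  exogenous DNA, an artefact, or a database gap, indistinguishably.

Derived: richness (surviving species count, focal included), RPIR =
(TP+FP)/total reads, precision = TP/(TP+FP), recall = TP/(TP+FN);
undefined on a zero denominator (`None`, never 0). Known contaminant
species — cross-contamination from the lab or field — are removed from
all tables before any counting and tallied separately.

Recall ordering union ≥ base ≥ intersection is a *statistical* property,
not a pointwise theorem: a read with p = focal, q = other species is TP
for p but discarded by the union. It holds on every simulated sample we
test because focal-vs-wrong conflicts are far rarer than reads assigned
by only one classifier.

Across-sample aggregation reports mean and sample standard deviation
(n−1), with undefined values excluded pairwise under a warning. Display
convention: 1 decimal for richness, 4 for RPIR, 3 for precision/recall.

## Bundled reference benchmark

`taxensemble.datasets` encodes, for 21 single-species insect libraries
classified against 1934 insect mitogenomes, the false-positive species
reported under the intersection merge with their per-species RPIRs and
congener status (11 libraries have none). Abundances published only as
"below 0.0001" are encoded as 0.00005; any value strictly below 0.0001
gives identical filtering outcomes. Since the source listing identifies
species by name, taxids are synthetic placeholders derived
deterministically from the names. Profiles are materialised over a
100 000-read denominator (every published abundance is a multiple of
1e-5, so the counts are exact) with the focal species at a nominal
abundance of 0.005, far above every threshold considered. Recomputing
from these lists reproduces the published per-library counts at
ε ∈ {0, 0.0001, 0.001}, the intersection richness aggregates
(2.3 ± 1.9, 2.1 ± 1.5, 1.5 ± 1.1), the 11/21 and 16/21 zero-FP library
counts, and the ≈0.5 mean false positives per sample at ε = 0.001.

## The simulator

`taxensemble.synthetic` emulates two classifiers applied to one
single-species sample at the assignment level — no sequences, k-mers or
alignments. Per read and classifier: assigned with probability
`assign_prob`; an assigned read is wrong with probability `error_prob`;
wrong targets are drawn from a fixed species pool in which congeners of
the focal species weigh `congener_weight` (default 10) times a
non-congener, mirroring the observed predominance of congeneric false
positives. When both classifiers err on one read, with probability
`error_correlation` they share a single wrong draw, taken from the mean
of the two weight distributions so the simulator stays symmetric in
(p, q); otherwise the draws are independent. Default study-scale
conditions used by the acceptance script: 200 000 reads, assign_prob
0.007 for both classifiers (the mitochondrial fraction), error_prob 0.01
for the precise classifier and 0.24 for the sloppy one, a 50-species
pool with 10 congeners, correlation 0.

Randomness: one `numpy` `SeedSequence` per sample, spawned into one
substream per classifier plus one for the correlation coin, so
reconfiguring one classifier never perturbs the other's draws; identical
configs are byte-for-byte reproducible. Wrong-target indices are drawn
for every read whether used or not, keeping each substream's consumption
a fixed function of its own classifier.

The closed-form intersection FP expectation

    E[FP reads] = n · a_p a_q · e_p e_q · (c + (1−c) Σ_s w_p(s) w_q(s))

is checked against the simulator within 3σ over 50 seeded replicates,
and against an independent per-read rejection simulator.

What the simulator does **not** model: database incompleteness, chimeric
reads, length- or GC-dependent assignment bias, contamination, and any
sequence-level effect. Passing simulator-based tests shows the merge and
metric machinery is correct under the stated error model, not that the
error model describes any particular real dataset.

## Numerical and degenerate-input choices

* Duplicate read ids in classifier output are a parse error, not
  last-wins: the upstream tools emit one line per read.
* Profile output is fixed at 6 significant digits, ordered by descending
  count with ascending-taxid tie-break, for reproducible diffs.
* MEGAN c2c counts may be fractional under weighted LCA; they are
  rounded to the nearest integer.
* Problem sizes in the test suite (≤ 50 000-read simulations, 50
  replicates) keep the full suite under ~10 s while leaving every
  statistical band at 3σ.

## Known limitations

Strictly pairwise: no k > 2 ensembles, voting, or probabilistic
weighting. No BLAST tabular or binary RMA parsing; the upstream tools
must be run separately. No merged/deleted-taxid remapping. Absolute
read-count thresholds, genome-coverage filters and negative-control
subtraction are out of scope.
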