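# taxensemble

Ensemble post-processing of two metagenomic read classifiers for
species-level identification.

Read-level classifiers run with default parameters report many species
that are not in the sample: on single-species insect libraries analysed
by mitochondrial metagenomics, BLASTn+MEGAN6 reports tens of species and
Kraken2 hundreds. Different classifiers, however, rarely misassign the
*same read* to the *same wrong species*. `taxensemble` merges the
per-read assignments of two such classifiers — **union** keeps a read's
species if either classifier assigns it (unless they conflict),
**intersection** only if both agree — and then filters the species
profile with an analytic detection limit ε (species with relative
abundance below ε are dropped). Intersection plus ε = 0.001 removes
nearly all false-positive species at a modest cost in assigned reads.

For each read *r* with species-resolved assignments (a_p, a_q):

| a_p | a_q | union | intersection |
|-----|-----|-------|--------------|
| NA  | NA  | NA    | NA |
| s   | NA  | s     | NA |
| NA  | s   | s     | NA |
| s   | n≠s | NA    | NA |
| s   | s   | s     | s  |

On single-species benchmark libraries each method is scored read-wise:
TP = reads on the focal species, FP = reads on any other surviving
species, FN = |U| − TP with U the reads assigned to the focal species by
*either* base classifier; precision = TP/(TP+FP), recall = TP/(TP+FN),
richness = surviving species count, RPIR = (TP+FP)/total QC-passed
reads. See `docs/methods.md` for the full model and its assumptions.

Intended users: anyone running two read-level classifiers (Kraken2 and a
BLAST/MEGAN pipeline, or any tools that can emit per-read taxid
assignments) on metabarcoding/metagenomics samples and wanting a
conservative, easily-audited species list.

## Worked example

Kraken2 per-read output (`k2.txt`, 5 columns) and MEGAN6
`rma2info -r2c` output (`megan.txt`, 2 columns) for five reads of a
*Drosophila melanogaster* sample, with a small taxonomy table:

```sh
$ taxensemble merge --p k2.txt --p-format kraken2 \
    --q megan.txt --q-format megan_r2c \
    --policy intersection --taxonomy tax.tsv --out inter.tsv
2 of 5 reads assigned under intersection
$ cat inter.tsv
read_id	taxid
r1	7227
r2	7227
r3	NA
r4	NA
r5	NA
```

Reads r1 and r2 were assigned to taxid 7227 (*D. melanogaster*) by both
classifiers and survive. r3 was a species conflict (7240 vs 7244), r4
was a genus-level assignment (ignored: species level only), r5 was
unclassified. Scoring the intersection against the known focal species:

```sh
$ taxensemble evaluate --p k2.txt --p-format kraken2 \
    --q megan.txt --q-format megan_r2c --method intersection \
    --focal 7227 --total-reads 1000 --epsilon 0.001 \
    --taxonomy tax.tsv --out metrics.json
{
  "method": "intersection",
  "sample_id": "",
  "epsilon": 0.001,
  "tp": 2,
  "fp": 0,
  "fn": 0,
  "richness": 1,
  "rpir": 0.002,
  "precision": 1.0,
  "recall": 1.0
}
```

Both agreed-upon reads are true positives (tp = 2); no surviving species
other than the focal one (fp = 0, richness = 1); no read was assigned to
the focal species by a classifier without ending up a TP here (fn = 0);
2 of the 1000 sample reads were informative (rpir = 0.002).

`taxensemble profile` builds and filters a species profile from one
assignment file, and `taxensemble simulate` generates synthetic
two-classifier samples with a controllable error model (see
`docs/methods.md`). Everything is also available as a library:

```python
from taxensemble import MergePolicy, merge_assignments
merged = merge_assignments(table_p, table_q, MergePolicy.INTERSECTION)
```

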