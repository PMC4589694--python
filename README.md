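# amplimine

In-silico PCR amplicon mining with panels of GMO detection methods.

Control laboratories screen food and feed for genetically modified
organisms with validated qPCR assays: *event*-specific methods target the
unique junction between a transgene insert and the host genome,
*construct*-specific methods target artificial joins between elements of
a transgenic construct, *element*-specific methods target single genetic
elements (promoters, terminators, marker genes) shared across GMOs, and
*taxon*-specific methods target endogenous species genes. `amplimine`
turns such a method panel loose on nucleotide sequence collections: it
predicts, for every (record, method) combination, which amplicons the
assay would produce, annotates them (primer edits, probe annealing,
species, dataset of origin), collapses them into non-redundant sets, and
summarizes the detection patterns per dataset and method class. The same
machinery supports the unauthorized-GMO triage workflow: given positive
and negative screening calls, shortlist the sequence records whose
predicted detection pattern explains them.

## The in-silico PCR model

A primer *P* of length *m* binds a target window *w* when the full primer
aligns end-to-end to *w* (target ends free) with at most *n* mismatches
and at most *g* indels. For every window the engine computes the
minimal-edit alignment — ranked by total edits (mismatches + gaps), then
by gaps — among alignments with at most *g* indels, and applies the
bounds to that alignment. Shadow windows (the same alignment padded by an
extra target base, costing a gap) are suppressed by any overlapping
strictly cheaper candidate, so a clean site yields exactly one hit while
genuinely distinct overlapping loci (e.g. tandem repeats) are all kept.
IUPAC ambiguity codes in primers match their base sets at zero cost; an
`N` in the target never matches.

Forward and reverse primer sites on opposite strands are paired in
convergent orientation with non-overlapping footprints; a pair whose
outer-to-outer span lies in the product window [*d*min, *d*max] becomes
an amplicon if the edits summed over both primers do not exceed a
combined cap. Defaults follow the canonical screening configuration:
*d* 50–500 bp, *n* = 2, *g* = 2, combined cap 2.

TaqMan probes are verified inside each amplicon by Smith–Waterman/Gotoh
local alignment (match +1, mismatch −2, gap open −2, extend −1, both
strands); an amplicon is `perfect` only with full probe coverage and zero
edits. Non-redundant sets come from exact sequence identity and from
greedy longest-first clustering at ≥ 90% identity with ≥ 90% alignment
coverage of both sequences (the cd-hit-style -aL/-aS convention).

## Worked example

Everything runs on synthetic data with planted primer/probe sites — no
downloads. Generate a small three-class corpus, scan it, cluster and
summarize:

```
$ amplimine synth -o demo --seed 7 --n-transgenic 4 --n-plant 3 --n-patent 1 --redundancy 3
$ amplimine scan transgenic_like=demo/transgenic_like.fasta \
      plant_like=demo/plant_like.fasta patent_like=demo/patent_like.fasta \
      -m demo/methods.tsv --species-map demo/species_map.tsv -o demo/amplicons.tsv
INFO total amplicons: 13 (records 10, methods 15)
$ amplimine cluster -t demo/amplicons.tsv -o demo/clusters.tsv --fasta demo/nr.fasta
INFO 13 amplicons -> 11 exact clusters
$ amplimine matrix transgenic_like=demo/transgenic_like.fasta \
      plant_like=demo/plant_like.fasta patent_like=demo/patent_like.fasta \
      -t demo/amplicons.tsv -m demo/methods.tsv -o demo/summary.tsv
```

`demo/amplicons.tsv` is the 18-column TAB table; its first data row

```
TGN0001  transgenic_like  QT-EVE-01  event  +  61  164  104  0 0 0 0 0  perfect  0 0  Zea mays  TGGTG...
```

reads: on record `TGN0001`, event-specific method `QT-EVE-01` produces a
104 bp product at positions 61–164 of the forward strand, with zero
primer mismatches/gaps and a perfectly annealing probe, in a *Zea mays*
record. The 13 amplicons collapse to 11 exact-identity groups because
the three patent-like copies of one construct yield identical products.
The summary table shows the expected class signatures, e.g.:

```
dataset_label    specificity  methods_detecting_fraction  records_detected_fraction  amplicon_count  record_count  amplicons_per_record
plant_like       event        0.0                         0.0                        0               0
plant_like       taxon        0.5                         0.667                      2               2             1.0
transgenic_like  event        0.667                       1.0                        4               4             1.0
```

GM-specific methods are silent on plant-genomic records, taxon methods
are silent on transgenic records, and event-specific methods detect each
transgenic record exactly once (the 1:1 amplicon:record relationship of
junction assays).

The same operations are available as library functions
(`amplimine.simulate_pcr`, `annotate_probe`, `assign_species`,
`dedup_identical`, `greedy_cluster`, `build_matrix`, `summarize`,
`candidate_events`); the CLI is a thin wrapper over them.

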