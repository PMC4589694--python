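# Methods

## Scope and model

`amplimine` predicts PCR amplification in sequence collections under a
bounded-edit primer-binding model and derives annotated amplicon tables,
non-redundant amplicon sets and screening consistency summaries from the
predictions. Amplification is treated purely combinatorially: a method
amplifies wherever its primers can anneal within the edit tolerances in
convergent orientation at a product size inside the configured window.
No thermodynamics (melting temperature, primer dimers, 3′-anchor
stability) enters the model; a mismatch near the 3′ end counts exactly
like any other mismatch. This is the standard trade-off for screening
large collections, where the goal is an enriched candidate set rather
than a quantitative amplification efficiency.

## Primer-site search

**Contract.** A site of primer *P* (length *m*) is a target window
aligned to the full primer, target ends free, ranked per window by the
lexicographic edit cost (mismatches + gaps, then gaps) among alignments
with at most `g_max` indel positions. The window is a hit when the
minimal-cost alignment has ≤ `n_max` mismatches. Bounds apply to the
*minimal* alignment: a window whose best alignment is over budget is not
rescued by a worse alignment that happens to fit the bounds (three
substitutions are three substitutions, not one substitution dodged by
two gaps). IUPAC codes in the primer match their base sets at zero cost;
a target `N` never matches any primer base, which suppresses spurious
hits inside the N-runs of draft records.

**Shadow suppression.** Any clean alignment generates shadow windows —
the same alignment padded by one flanking target base at the cost of one
gap. A candidate window is therefore suppressed when an overlapping
candidate (same primer, same strand) has strictly lexicographically
smaller (total, gaps). Equal-cost overlapping candidates are all kept:
tandem copies of a primer sequence are genuinely distinct loci.
Suppression is evaluated before the mismatch bound is applied, and only
candidates with total ≤ `n_max + g_max` can participate (nothing
costlier can pass the bounds or dominate something that does).

**Implementation.** The search is an anchored dynamic program over all
window starts simultaneously: `G[i, k, g]` = minimal mismatches aligning
the first *i* primer bases to exactly *k* target bases from each start,
with at most *g* gaps, vectorized over starts with numpy and banded to
|k − i| ≤ `g_max`. Costs are O(m · g_max²) vector operations per
primer/strand regardless of edit parameters. The test suite checks the
hit sets against an independently written per-window DP oracle across
the full (n, g) ∈ {0, 1, 2}² grid; a word-seeding accelerator was
considered and not implemented, as the vectorized scan already handles
the intended scale.

**Pairing.** Forward-primer sites on one strand are paired with
reverse-primer sites on the other; the forward match must lie strictly
upstream of the reverse match in amplicon orientation with
non-overlapping footprints, and the outer-to-outer span must lie in
[`d_min`, `d_max`]. Both orientations are searched. An amplicon is kept
when the mismatches and gaps summed over both primers do not exceed
`total_edit_max`; the probe is deliberately excluded from this cap
(probe quality only matters for the strict screening filter downstream).
Duplicate (start, end, strand) products from alternative supporting
pairs are reported once, keeping the minimal-edit pair. Extracted
sequences are reverse-complemented for minus-strand products so they
always read forward-primer → reverse-primer.

**Parameters and defaults.** `d_min=50`, `d_max=500` bp, `n_max=2`,
`g_max=2` per primer, `total_edit_max=2` combined — the canonical
screening configuration this pipeline emulates. All surface on the CLI
as `-d MIN-MAX`, `-n`, `-g`, `--total-edits`.

## Probe verification

Probes are aligned to the amplicon by local (Smith–Waterman) alignment
with affine gaps: match +1, mismatch −2, gap open −2, gap extend −1
(open charged on the first gapped position of a run). Both amplicon
strands are tried, since TaqMan probes may be designed on either.
Because co-optimal local alignments can differ in edit composition, the
optimum is ranked by (score desc, gap positions asc, mismatches asc,
identities desc); the four levels are packed into one integer so the DP
runs in plain int arithmetic, and the packing is valid to ~500 nt per
side — ample, as amplicons are capped at `d_max`. An alignment must
cover ≥ 50% of the probe (`min_coverage`, configurable) to be reported
at all; below that, or with no positive-scoring alignment, the probe is
`not_found`. `perfect` requires full coverage with zero mismatches and
gaps; anything else reported is `mismatched`. Annotation never filters
amplicons — filtering is the screening matrix's job.

The scoring scheme and coverage floor are package defaults (the
emulated pipelines do not publish theirs); they only serve to produce
stable edit annotations, not similarity statistics, so no E-values are
computed.

## Species assignment

An offline record→species TSV replaces live taxonomy queries, keeping
runs reproducible and network-free. Without a map, `[organism]`-style
bracketed tokens in FASTA descriptions are used; records resolved by
neither are `unknown`. Assignment is total, idempotent, and touches only
the species field.

## Clustering

Exact mode partitions amplicons by sequence string (first occurrence is
the representative). Approximate mode is greedy incremental clustering
in the cd-hit style: sequences visited longest-first (ties keep input
order, the documented tie-break source), each joining the first
representative it matches at identity ≥ 0.9 with alignment coverage
≥ 0.9 of the longer (`aL`) and of the shorter (`aS`) sequence, else
founding a new cluster. Matching uses the same local alignment as probe
verification; identity is matches / alignment columns, coverage is the
aligned span on each sequence over its length. cd-hit's word-filter
heuristics are not reproduced — correctness, not throughput, is the
contract at this scale, and the explicit-alignment definition removes
the variant ambiguity in word-based identity estimates.

## Screening matrix and summaries

The matrix counts amplicons per (record, dataset) × method. Strict mode
counts only perfect predictions: zero primer edits and a probe that is
`perfect` or absent. Summaries per (dataset, specificity class) report
the fraction of the class's methods with ≥ 1 amplicon, the fraction of
the dataset's records detected, amplicon and detected-record counts and
their ratio. `record_count` counts *detected* records, so
amplicons_per_record is the amplicon:target-record ratio; empty
denominators yield absent values rather than zeros, keeping bar-chart
style summaries honest. `candidate_events` formalizes screening triage:
records whose strict-mode pattern covers all observed positive calls,
ranked by how many observed negatives they also satisfy.

## Synthetic data

The generator emulates the composition of public collections at desk
scale: `transgenic_like` records each carry one event-specific site
(hence an analytically forced 1:1 event amplicon:record ratio) plus
element/construct sites on alternating records and never a taxon site;
`plant_like` records carry at most one taxon site; `patent_like`
constructs are emitted in near-identical copies differing only at
background positions outside the amplicon span, so all copies yield
string-identical amplicons and exact dedup collapses them to one group
per construct. Planted sites assemble the forward primer copy, a spacer
(hosting the probe when the method has one) and the reverse complement
of the reverse primer copy, with substitutions at interior positions and
indels at the primer midpoint — end placements would make ground-truth
edit counts ambiguous, and probe substitutions stay ≥ 4 bases from the
probe ends so the optimal local alignment provably spans the full probe
and counts every planted edit.

Backgrounds are i.i.d. at configurable GC (default 0.44, a plant-like
base composition) and rejection-sampled: a segment is redrawn when any
panel primer matches a window at ≥ m − 4 positions in an ungapped
sliding comparison on either strand. The screen is deliberately not the
engine itself (that would make generator/engine cross-validation
circular); the conservative margin makes an engine-acceptable site in a
screened background astronomically unlikely, and the redraw loop
terminates with overwhelming probability at these lengths (a hard cap of
100 attempts raises rather than loops). Generation is deterministic for
a fixed seed, down to byte-identical output files.

What the fixtures do **not** emulate: real promoter/terminator sequence
content, homology between related constructs, sequencing error,
low-complexity and repetitive regions, or the sheer scale and redundancy
structure of public collections. Passing the recovery tests therefore
demonstrates the pipeline's correctness on its own model (planted sites
with known edits), not field performance on public databases.

## Numerical and degenerate-input choices

- Edit-count ties at one window resolve to fewest total edits, then
  fewest gaps; a mismatch is preferred over the equivalent two-gap
  re-spelling.
- Enlarging any tolerance (n, g, total cap, product window) never
  removes a fixture amplicon. In adversarial low-complexity sequence a
  larger `g_max` can, in principle, lower a suppressor window's minimal
  cost and shadow a previously reported neighbour; the fixtures' clean
  backgrounds exclude this configuration by construction, and the
  engine–oracle equivalence tests pin the behaviour either way.
- Empty FASTA files parse to empty record lists; empty method tables
  produce header-only outputs; empty datasets yield absent (not zero)
  summary fractions.
- Primers shorter than 10 nt and probes shorter than 10 nt are rejected
  outright rather than searched.
- Lowercase (soft-masked) bases are uppercased and treated as ordinary
  bases.
- Coordinates are 1-based inclusive on the forward strand of the input
  record everywhere in the TAB output, regardless of amplicon strand.

## Problem sizes

The test suite validates engine–oracle equivalence on 216 instances
(24 random scenarios — targets 120–220 bp plus one 1.2 kb, primers
15–30 nt, planted edit budgets 0–2 per primer — across the full
(n, g) ∈ {0,1,2}² grid), planted recovery across edit budgets 0–3 and
product sizes straddling the 50–500 window on both strands, probe-count
equivalence on 110 random pairs, and exact dedup on 10,000 random
amplicons. The acceptance script's corpus is 47 records × 15 methods.
These sizes were chosen so the exhaustive pure-Python oracles stay
practical while every code path (both strands, all edit types, in- and
out-of-bounds budgets) is exercised.

## Known limitations

- No 3′-anchor rule and no thermodynamic filtering: predicted amplicons
  are an upper bound on what would amplify efficiently in vitro.
- The greedy cluster count depends on the longest-first visiting order,
  as in the tool convention it follows; only exact-mode group counts are
  permutation-invariant.
- The combined-edit cap excludes the probe; pipelines that fold probe
  edits into selection would report fewer amplicons. The choice is
  localized in `simulate_pcr`/`build_matrix` and the strict filter.
- Species assignment is only as complete as the supplied mapping; no
  taxonomic lineage resolution is attempted.
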