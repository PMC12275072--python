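# Methods

## Annotation model

A chromatin interaction is a pair of genomic anchors; loop callers emit
them as fixed-width bins (typically 5 kb) with a per-loop statistic
(contact strength or q-value). The engine treats an interaction as evidence
linking everything in one anchor to everything in the other: a peak
overlapping anchor *i* is assigned to every gene whose promoter window
overlaps anchor *j ≠ i*. Both orientations of every interaction are tested,
and a (peak, gene, interaction-row) triple is emitted at most once, so a
peak sitting in both anchors of a self-looping promoter region yields a
single annotation. Peaks inside one gene's promoter window still receive
interaction annotations to *other* genes — promoter–promoter links are
real and are only filtered at the visualization stage (the
`skip_promoter_promoter` option).

The interaction evidence is blind below the caller's bin resolution and
minimum loop distance, so proximity annotation (closest TSS by absolute
midpoint distance, ties broken toward the lexicographically smaller gene
symbol) supplements it for peaks whose nearest TSS lies closer than the
interaction threshold. When the same (peak, gene) pair is supported both
ways, the interaction record wins and the proximal duplicate is dropped:
the loop carries strictly more information (a score and a supporting row).

### Parameters

| parameter | default | meaning |
|---|---|---|
| `promoter_window` | 2,500 bp | half-width of the promoter interval around each TSS |
| `bin_size` | inferred | anchor bin width; modal anchor width over both anchors, ties to the smallest |
| `interaction_threshold` | 2 × bin size | below this closest-TSS distance the proximity fallback applies |
| `close_peak_type/value` | off | pad the peak-side anchor by bp (`distance`) or bins (`bin`) |
| `close_promoter_type/value` | off | same on the promoter side |
| `multiple_anno` | concat | one comma-joined row per peak, vs. `keep`: one row per annotation |

Distances are signed from the floor of the peak midpoint, negative
upstream of the gene (sign flips on the minus strand). Peak midpoint
rather than peak edge was chosen because it matches the convention of the
standard closest-TSS annotators this package's proximity mode mirrors; the
threshold compares |distance| only, so strand never affects eligibility.
Anchor padding is monotone: growing `close_*_value` can only add
annotations. Trans (inter-chromosomal) interaction rows are kept and
annotate normally; their peak–gene distance is undefined and left empty.

## Regulatory-domain distance limits

Two proximity schemes get per-gene theoretical reach limits:

* **closest-TSS**: the reach toward each neighbor is half the TSS-to-TSS
  distance (floor division), so facing limits of adjacent genes partition
  the gap exactly (±1 bp). Terminal genes reach the chromosome boundary
  when sizes are supplied, and are otherwise marked unbounded and excluded
  from medians — a flag-controlled choice, since an unbounded side would
  otherwise dominate the direction-free maximum.
* **basal-plus-extension**: a strand-aware basal domain (−5 kb/+1 kb
  around the TSS by default) extended per side to the nearest other gene's
  basal boundary, at most 1 Mb from the TSS (the scheme's published
  default; the benchmark protocols that raise it to 2–3 Mb do so via the
  `extension_cap` argument) and clipped to the chromosome. Extension never
  shrinks the basal domain, so overlapping basal domains are permitted.
  Curated regulatory regions that the original web tool adds from its
  internal database are not modelled — no public flat file is bundled —
  so genome-wide medians computed here will diverge from that tool's
  exactly where curated domains apply.

Summaries report the median upstream, downstream and per-gene maximum
limits, and additionally the median of the pooled directional limits,
because "median distance threshold" is ambiguous between the two; both are
emitted so either convention can be compared. Medians of even-length
samples are the mean of the central pair.

## Co-occupancy and differential integration

Membership of multiple peak sets is evaluated either over fixed bins
(tiled from coordinate 0 per chromosome) or over consensus regions (union
of inputs with strictly overlapping intervals merged; bookended intervals
stay separate, matching half-open overlap semantics everywhere else).
Combination counts are split into promoter-resident and distal regions and
always sum to the number of retained regions. Link tables list (dataset,
distal region, gene) from interaction-type annotations; the activating /
repressive call for a distal element requires a significantly
differentially expressed target gene (padj < 0.05, |log2FC| > 1 by
default, the conventional cutoffs) and classifies by sign concordance of
the element's occupancy change with the gene's expression change — the
category names imply exactly this rule, which is this package's
interpretation. Everything else (non-significant gene, missing expression
entry, zero or missing peak change) is unresolved, so the three categories
partition the annotations.

## Benchmark protocol

Validated enhancer–gene pairs are filtered before scoring: pairs beyond
3 Mb from the target TSS (the maximum loop-calling distance), and elements
inside promoter windows or gene bodies, are excluded; FDR < 0.05 marks a
pair functional. A truth pair counts as identified when any annotated peak
overlaps the element by ≥ 1 bp and is assigned to that gene — overlap
rather than coordinate equality, because validated elements and
accessibility peaks are trimmed differently. Precision averages per gene
first and then across genes, with a pooled variant also reported. The
"proximity-only" comparator is the pipeline run with interactions
withheld, i.e. closest-TSS annotation under the interaction-threshold
rule; raw unthresholded closest-TSS annotation is available separately via
`annotate_by_proximity`. Interaction-score stratification keeps the top
`floor(fraction · n)` loops (minimum one), with a flag for whether larger
or smaller scores rank higher, since callers emit both contact strengths
and q-values.

## Synthetic fixtures

The generator builds the conditions the engine is validated under: one or
more chromosomes (1 Mb by default) with genes spaced at least 4 bins
apart, bin-aligned anchors of a fixed 5 kb width mimicking loop-caller
output, and peak widths drawn uniformly from 200–1,000 bp (typical ATAC
summit scale). Each planted link places a peak inside a distal anchor —
at least the interaction threshold away from every TSS and outside every
promoter window — whose partner anchor is the bin containing the gene's
TSS. Distractor loops touch no promoter window; background peaks overlap
no anchor and lie beyond the threshold from every TSS. Under these
constraints the combined engine output equals the planted truth exactly,
which is what the closure tests assert. All randomness flows from a single
seed; identical specs produce byte-identical files.

What the generator does *not* emulate: contact-frequency distance decay,
anchor merging by the caller (heterogeneous anchor widths), overlapping or
nested peaks, unmappable regions, and trans contacts. Passing the closure
tests therefore demonstrates correctness of the annotation logic, not
robustness to the noise structure of real loop calls; the random-problem
oracle tests (arbitrary anchor widths and placements, both chromosomes,
random option settings) cover the logic under less curated geometry.

## Numerical and determinism choices

Interval overlap is half-open everywhere; bookended intervals never touch.
Midpoints and half-distances use floor division. Query results, annotation
tables and all written files have fixed sort orders ((chrom, start, end,
name) for peaks; (peak, type, gene) for annotations) and carry no
timestamps, so every mode is byte-reproducible. Degenerate inputs fail
early with contextual errors: zero-width intervals, negative coordinates,
invalid strands, malformed BED/bedpe rows (reported with their line
number), an empty interaction list when a bin size must be inferred.

## Test problem sizes

The oracle-equivalence suite uses 100 random problems of up to 50 peaks,
50 loops and 20 genes against an O(peaks × loops × genes) enumeration, and
planted-link recovery uses 100 generated fixtures — sizes at which the
brute-force reference is itself trivially auditable while still exercising
every code path; the full suite and the acceptance script each run in
seconds.

## Known limitations

* Proximity annotation assigns exactly one gene per peak; co-equal
  closest TSSs are broken lexicographically rather than reported jointly.
* Bin-size inference assumes the modal anchor width is the caller's bin
  size; heavily merged anchor sets should pass `bin_size` explicitly.
* The benchmark harness consumes pre-filtered pair tables; it does not
  recompute screen statistics.
* Plotting (UpSet/Circos/violin graphics) is out of scope; the exported
  tables are the deliverables and feed the usual plotting libraries.
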