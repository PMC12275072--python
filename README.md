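# loopanno

Chromatin-interaction-based annotation of regulatory elements to their
target genes.

Most peak-to-gene assignment is done by linear proximity (closest TSS, or
basal-plus-extension regulatory domains), which is bounded by local gene
density: the reach of a gene under closest-TSS annotation is half the
distance to its neighbors, yet functional enhancers routinely act over
100–500 kb. `loopanno` instead assigns a peak (ATAC/ChIP region) to a gene
when the peak overlaps one anchor of a chromatin interaction (HiChIP,
PLAC-seq, Hi-C loops in bedpe format) whose other anchor overlaps the
gene's promoter window (TSS ± 2,500 bp by default). Because loop callers
report anchors as fixed-width bins and apply a minimum loop distance, peaks
closer to a TSS than the *interaction threshold* (default 2 × bin size)
cannot be resolved by loops; for those, closest-TSS proximity annotation is
applied in addition. Anchors can optionally be expanded by a distance or a
number of bins to admit neighboring interactions.

The package is aimed at regulatory-genomics analysts who have peak sets and
called loops in hand: it covers peak- and interaction-centric annotation,
per-gene theoretical annotation-distance limits (closest-TSS and
basal-plus-extension rules), multi-dataset co-occupancy summaries
(UpSet-style combination counts, Circos-style link tables), integration
with differential gene expression (activating/repressive element calls,
Cytoscape xGMML export), a benchmark harness against functionally
validated (CRISPRi-style) enhancer–gene pairs, and a deterministic
synthetic-fixture generator.

## The annotation rule

For a peak *p*, interactions *I* with anchors *(a₁, a₂)*, and genes *g*
with promoter window *W(g) = [TSS − w, TSS + w)*:

* **interaction annotation**: emit *(p, g)* whenever *p ∩ aᵢ ≠ ∅* and
  *W(g) ∩ aⱼ ≠ ∅* for *{i, j} = {1, 2}* (both orientations; anchors
  optionally padded). The annotation carries the signed midpoint–TSS
  distance, the supporting bedpe row and its score.
* **proximity fallback**: the closest-TSS assignment of *p* is kept only
  when *|d(p, TSS)| < t* with *t = 2 × bin size*, and dropped when the
  same *(p, g)* pair is already loop-supported.

All coordinates are BED-style 0-based half-open; distances are measured
from the floor of the peak midpoint, signed negative upstream of the gene.

## Worked example

The repository ships a small hand-checkable fixture
(`examples/fixtures/t1/`): one 1 Mb chromosome with genes G1 (+, TSS
100,000), G2 (−, TSS 300,000), G3 (+, TSS 900,000), four peaks and three
5 kb-binned loops, two of which are promoter-anchored.

```
loopanno --mode basic \
    --peaks examples/fixtures/t1/peaks.bed \
    --interactions examples/fixtures/t1/interactions.bedpe \
    --tss examples/fixtures/t1/tss.tsv \
    --score-col 7 --multiple_anno keep --outdir out/
```

`out/peaks.annotated.tsv` then contains:

```
peak_chrom  peak_start  peak_end  peak_name  gene_symbol  entrez_id  distance_to_tss  annotation_type  interaction_score  interaction_row
chrT        46000       46500     P1         G1           1001       -53750           interaction      12.0               0
chrT        99000       99400     P2         G1           1001       -800             proximal
chrT        502000      502300    P3         G2           1002       -202150          interaction      8.0                1
```

P1 sits in a loop anchor whose partner anchor covers G1's promoter, 53.75
kb upstream — invisible to closest-TSS-with-threshold annotation but
recovered through the loop. P2 is 800 bp from G1's TSS, below the 10 kb
interaction threshold (2 × 5 kb bins), so the proximity fallback applies.
P3 is annotated to G2 from 202 kb away through the second loop. P4
overlaps an anchor of a loop with no promoter on the other side and ends
up in `out/peaks.unannotated.txt`; `out/peaks.genes.txt` lists `G1, G2`.

The same objects are available programmatically:

```python
import loopanno as la

t1 = la.fixture_t1()
res = la.annotate_peaks(t1.peaks, t1.interactions, t1.tss)
res.gene_list()                  # ['G1', 'G2']
[p.label for p in res.unannotated]  # ['P4']
```

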