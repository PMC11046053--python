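# insertmap

Locating and characterizing randomly integrated transgene constructs in
engineered genomes from paired-end whole-genome sequencing.

When a therapeutic-protein expression vector is integrated at random into a
production cell line's genome (the standard route in CHO cell line
development), the resulting locus is rarely a clean single insert: vectors
concatemerize, cassettes are duplicated or inverted, flanking host sequence
is rearranged and regionally amplified. `insertmap` reimplements the
desk-scale computational workflow for dissecting such a locus from short
paired-end reads, together with the bioprocess arithmetic used to quantify
its phenotype. It is a library for computational biologists working on cell
line characterization, with an examples/ directory of narrative scripts and
a thin `insertmap` command-line wrapper.

Everything runs on synthetic integrant genomes with exact known truth, so
each stage can be validated closed-loop.

## What it does

* **Synthetic integrant genomes** — multi-contig two-copy host background;
  an engineered allele carrying an intact construct copy, a truncated copy
  lacking the selection-marker (GS) and heavy-chain (HC) cassettes, extra
  light-chain (LC) copies including an inversion, a short fragment borrowed
  from an unrelated contig, and a tandemly amplified upstream region;
  paired-end reads with configurable coverage, insert distribution and
  substitution error rate; batch-culture and qPCR table simulators.
* **Read mapping** — a built-in seed-and-vote mapper producing CIGARs with
  soft clips; all co-optimal placements are reported and flagged ambiguous.
  SAM read/write (via pysam) lets any external mapper substitute.
* **Informative-read classification** — each pair becomes *isolateral*
  (both mates construct-only), *flanking* (mates split between construct
  and host), *chimeric* (one read split across references via a soft clip),
  *homologous* (ambiguous through sequence shared by construct and host,
  e.g. the GS gene) or non-informative; host contigs are ranked by
  flanking+chimeric support to nominate integration contigs.
* **Junction resolution** — soft-clipped fragments are re-aligned to all
  references and clustered into fusion-junction calls at single-base
  resolution, including host–host fusions and inverted-repeat fold-backs,
  with micro-homology-aware breakpoint canonicalization.
* **Genome walking** — iterative cycles of re-mapping all reads to the
  growing contig, recruiting reads (and their mates, mapped or not) from
  the terminal 200 bp window, greedy exact-overlap assembly, and splicing;
  the finished contig is placed genome-wide by chunked alignment.
* **Copy number** — windowed depth normalized to twice the genome-wide
  modal window depth, so a region present at *c* copies against a two-copy
  background sits at *c*/4 (one copy → 0.25, background → 0.50); integer
  calls are `round(4·d̂)`. qPCR relative copy number by the ΔΔCT method:
  `fold = 2^−ΔΔCT` with `ΔCT = CT(target) − CT(reference)`.
* **Sliding-window scoring** — 249 bp windows at stride 1 scored by a
  pluggable window scorer (a GC-content toy scorer ships; any window-level
  sequence model fits the same callable contract), aggregated per base as
  mean/min/max.
* **Bioprocess quantitation** — integral viable cell density
  (IVCD, cell·day/mL, trapezoidal), specific productivity
  `q_p = Δtiter / IVCD` (pg/cell/day), maximum titer `P_max`, fold changes
  and per-copy normalized expression.

## Worked example

Call every engineered junction of the default scenario and check the copy
numbers (condensed from `examples/03_call_junctions.py` and
`examples/05_copy_number.py`):

```python
import insertmap as im
from insertmap.junctions import call_junctions, extract_softclips, realign_clips
from insertmap.pipeline import align_all, compare_to_truth, primary_alignments

scenario = im.default_scenario(seed=1)
reads = im.simulate_reads(scenario.integrant, coverage=30, error_rate=0.0, seed=1)
index = im.ReferenceIndex(scenario.reference.records, k=21)
primaries = primary_alignments(align_all(reads, index))
clips = extract_softclips(primaries, min_clip=20)
calls = call_junctions(realign_clips(clips, scenario.reference.records), min_support=3)
print(compare_to_truth(calls, scenario.truth, tolerance=0))
```

prints

```
{'tp': 7, 'fp': 0, 'fn': 0, 'precision': 1.0, 'recall': 1.0}
```

— all seven engineered junctions (host–construct, the host–host fusion, the
construct-internal truncation junctions and the inverted-LC fold-back) are
recovered at the exact base. The depth route on the same alignments prints

```
           label reference  start   end  normalized_depth  copies
              HC construct    600  2400          0.250884       1
              LC construct   2600  4000          1.000620       4
amplified-region     chr_1  16000 20000          1.887281       8
```

i.e. one heavy-chain copy at normalized depth ~0.25, four light-chain
copies at ~1.0, and the 4-fold (8-copy) amplified upstream region — the
1:4 HC:LC ratio and regional amplification the scenario engineers. Each
`examples/*.py` script walks one capability the same way (simulation truth,
classification, junctions, walking, copy number, window scoring,
productivity).

## Layout

```
src/insertmap/      library (records, synth, align, classify, junctions,
                    walk, depth, windows, quant, pipeline, samio, cli)
examples/           one narrative script per capability
tests/              pytest suite incl. acceptance-level checks
scripts/acceptance.py
docs/methods.md     models, conventions, parameter choices, limitations
```
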