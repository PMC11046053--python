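# Methods

This note records the models behind each module, the parameter choices that
matter, and what the synthetic data do and do not emulate. Coordinates are
0-based half-open everywhere inside the library; SAM output is 1-based as
required by the format.

## Synthetic integrant genomes

`simulate_host_genome` draws host contigs uniformly over {A,C,G,T}
(expected GC 0.50) with a diploid-like background: each contig carries a
copy count of 2 used by the read simulator.

`apply_integration` expands an `IntegrationPlan` into the engineered
("modified") allele: host sequence up to the insertion point, optional
tandem copies of an amplified upstream region, an ordered list of inserted
segments (construct or host intervals, forward or reverse-complement), then
the remaining host sequence. The modified allele becomes its own record at
copy 1 and the unmodified homolog is kept at copy 1, so the locus stays
diploid overall; unrelated contigs stay at copy 2. With amplification
factor *f* the modified allele carries 2f−1 tandem region copies, making
the total copy count 2f — an f-fold gain over the diploid baseline, which
is also what the qPCR simulator reproduces (e.g. f=4 → 8 vs 2 copies).

Every adjacent-segment boundary that is not sequence-continuous becomes a
truth junction. A junction is stored as an unordered pair of breakends
(reference, position, retained side L/R); equal sides mean the downstream
segment is inverted. Because a fused sequence with micro-homology at the
breakpoint admits several equivalent breakpoint representations, all truth
junctions (and all calls, see below) are canonicalized to the smallest
representative of their equivalence orbit; without this, "exact breakpoint
recovery" would be ill-defined.

The default scenario (`data/default_scenario.yaml`) uses three host contigs
(40/12/10 kb) and an 8 kb construct with promoter, HC (1.8 kb), LC
(1.4 kb) and GS (1.4 kb) cassettes. The engineered allele carries: a 4 kb
upstream region amplified 4-fold, a 240 bp fragment of the second contig in
front of the insert (creating a host–host fusion junction), one intact
construct copy, a truncated copy lacking GS and HC, one extra forward and
one inverted LC copy, then the downstream host flank. The extra LC copies
are carried with 200 bp of flanking construct context so every LC copy sits
in identical sequence and read depth is flat across the cassette rather
than shouldered by junction soft-clipping. Net cassette copy numbers: HC 1,
LC 4, GS 3 (one vector copy plus the diploid host homolog planted on the
third contig — the homolog is what makes read origins ambiguous and
exercises the homologous read class). Contig and cassette sizes are set so
that desk-scale runs finish in seconds while each depth estimate retains
enough reads for integer rounding to be reliable at 30×; they are not
calibrated to any particular genome beyond the structural motif they
emulate.

`simulate_reads` draws fragment positions uniformly within each record,
weighted by copy count (interval-level overrides via features are
supported; fragments are not split at interval boundaries, so hemizygous
regions built this way show a soft depth ramp at their 5' edge — when flat
one-copy depth is needed, `simulate_hemizygous_genome` builds explicit
full/deleted haplotypes instead). Pair count is
`round(coverage × total_length / (2 × read_len))`; insert sizes are
Gaussian with bounded resampling below the read length; errors are i.i.d.
substitutions (default rate 0.001, no indels or quality values — the
dominant short-read error mode, and the assumption the gapless mapper
matches). What passing tests on these reads do **not** show: robustness to
indel errors, coverage bias, chimeric library artifacts, or repeat content
beyond the engineered duplications.

`simulate_culture` uses closed-form logistic growth from a 0.3×10⁶
cells/mL seed; the titer increment per day equals q_p times the trapezoidal
viable-cell integral of that day, so the productivity estimator recovers
q_p exactly on noiseless series by construction (a round-trip contract, not
an empirical claim). `simulate_qpcr` assumes 100% amplification efficiency:
Ct = base − log₂(copies) plus Gaussian noise, reference gene constant.

## Read mapping

The mapper indexes all reference k-mers (default k=21, concatenated with
separator symbols so no k-mer spans records) and aligns a read by sampling
eight seed offsets per strand, voting on diagonals, and scoring each
candidate diagonal with a best-scoring-segment scan (match +1, mismatch −3)
— a gapless placement model matched to the substitution-only simulator.
The unextendable read ends become soft clips. Block ends are trimmed until
their terminal 10 bases are mismatch-free: a block may absorb interior
sequencing errors, but a boundary scored through a mismatch run would shift
a soft-clip breakpoint by a few bases, which junction calling cannot
repair. All co-optimal placements are reported and flagged ambiguous —
never broken arbitrarily — because the homologous read class is defined by
that ambiguity. Reads shorter than k, or all-N, are unmapped. Mapping
quality is not calibrated; MAPQ in SAM output is 60/0 (unique/ambiguous).

`local_align` is an exact Smith–Waterman with linear gap penalty used for
small sequence-vs-sequence problems and as the contract for clip
re-alignment; it is deliberately independent of the mapper.

## Classification and junction calling

Precedence when several criteria fire: CHIMERIC > FLANKING > HOMOLOGOUS >
ISOLATERAL > NON_INFORMATIVE — split reads carry base-resolution evidence
and must not be absorbed into coarser pair-level classes. "Uniquely" means
the ambiguity flag is unset. The chimeric criterion requires a terminal
soft clip of ≥ 20 bp (`min_clip`) whose re-alignment lands uniquely on a
different reference; shorter clips re-align spuriously.

Junction calling re-aligns every clip ≥ 20 bp from unambiguous anchors
(k=13 index), requires ≥ 0.95 identity over ≥ 20 bases, discards clips
with co-optimal targets (ambiguity-safe), canonicalizes each candidate
junction under micro-homology, clusters by breakend pair within a 2 bp
tolerance, takes the modal coordinate, and keeps clusters supported by ≥ 3
distinct reads. Same-reference, same-orientation pairs closer than a read
length are internal soft-clip noise and dropped; inverted self-junctions
are kept at any distance because inverted repeats legitimately fold back on
themselves (the inverted-LC junction sits at distance zero). None of these
thresholds is sensitive near its default on error-free data; they matter
once the error rate grows.

## Genome walking

Each cycle: re-map all reads to the current contig, recruit reads whose
alignment overlaps the terminal 200 bp window on the growing end plus their
mates (mate rescue — unmapped mates are what reach into uncharted
sequence), assemble the recruits, and splice the best-extending assembled
contig onto the end. The 200 bp window applies every cycle; the 1 kb
construct window is used only to seed the first contig. The assembler is a
greedy overlap–layout–consensus over exact suffix/prefix overlaps
(min_overlap 30 bp, both orientations, containment absorbed, deterministic
tie-breaking by overlap length then sequence); it is intended for
near-error-free desk-scale recruits — the contract is the reconstructed
sequence, not assembler sophistication, and a de Bruijn assembler could be
substituted behind the same function. Splicing anchors the contig's
terminal 31-mer inside the candidate and accepts the longest exact terminal
overlap, so candidates may reach past the contig into diverging repeat
branches. The walk stops after n_cycles (default 12), when no candidate
extends the contig (stalled), or when >90% of an extension's 31-mers
already occur in the contig (circular — the repeat guard that fires when
the downstream walk re-enters tandem construct copies). With 150 bp reads
and 500±50 bp inserts at 40×, upstream extension runs at roughly an insert
length (~500 bp) per cycle, so 12 cycles comfortably exceed 5 kb.

`place_contig` maps the contig in 250 bp chunks, chains consistent
diagonals, and refines each placement base-by-base along its diagonal, so a
fusion-spanning contig yields two placements whose boundary is the fusion
junction at base precision.

## Copy number

Per-base depth is accumulated from the M/D blocks of primary alignments,
averaged over 500 bp windows, and normalized by **twice the genome-wide
modal window depth**, chosen so the two-copy background sits at 0.5 and a
region at c copies at c/4 — the convention that puts one/two/three-copy
peaks at 0.25/0.50/0.75. The mode is estimated by mean-shift (repeatedly
replacing the estimate with the mean of windows within ±20%) because a raw
histogram argmax over a few hundred windows carries several percent of
noise, enough to flip integer rounding. Feature estimates use per-base
depth restricted to the feature interval; integer copies are
`round(4 × mean normalized depth)`. Multi-mapping caveat: reads wholly
inside sequence shared between references (the GS homolog) are assigned
deterministically to the first reference by (id, position), so depth over
such intervals is not meaningful and the GS cassette is excluded from
depth-based copy tables.

ΔΔCT: ΔCt = mean Ct(target) − mean Ct(reference) per sample,
fold = 2^−(ΔCt_sample − ΔCt_control), with efficiency fixed at 100%. With
triplicate wells and 0.1-cycle noise a single plate estimates a 4-fold gain
with ~8% relative scatter; summary values therefore average several
independently simulated plates (the acceptance script uses ten), mirroring
the practice of reporting the mean of independent experiments.

## Window scoring

A window's score is assigned to **all** bases it covers (not the window
center); per-base mean/min/max over covering windows is what produces the
min/max envelope around the mean track — a center-assignment scheme cannot.
Edge bases keep their partial coverage (1 window at the first base) rather
than being trimmed. Aggregation is O(window) vector operations, linear in
sequence length. The scorer is a callable `scores = scorer(windows)`; the
shipped GC scorer is a stand-in for any trained window-level sequence
model, and no claim is made about the biology of scored sequences.

## Quantitation

Units are fixed: VCD cells/mL, titer µg/mL, q_p pg/cell/day ("pcd"), IVCD
cell·day/mL, with 1 µg/mL = 10⁶ pg/mL. IVCD is the trapezoidal integral of
VCD (endpoints interpolated linearly when they fall between samples);
q_p = Δtiter·10⁶ / IVCD. The "exponential phase" is always a caller-chosen
interval and is reported alongside every summary; a detector for the
longest log-linear stretch (R² ≥ 0.98) is provided but never applied
silently. Rounding is half-to-even and applied only at presentation
(`fold_change`).

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy Generator);
pipelines, the assembler and the walk have total-order tie-breaking, so
end-to-end runs are byte-reproducible. Default study sizes — a ~150 kb
engineered scenario at 30×, a 500 kb genome for depth-peak work, a 24 kb
walking scenario at 40× — are the package's chosen desk scale: large
enough that each estimator's sampling error is well inside its decision
margin, small enough for second-to-minute runs.

## Known limitations

* The mapper is gapless; indel-containing reads soft-clip instead of
  aligning through the indel. Use SAM interop with an external gapped
  mapper for real libraries.
* The greedy assembler assumes near-error-free reads; consensus does not
  correct errors within an overlap.
* Breakpoint micro-homology is canonicalized, but non-templated insertions
  at junctions are not modelled or characterized.
* Depth-based calls assume uniform coverage (no GC bias or mappability
  correction) and a predominantly two-copy background for the modal
  normalization.
* The copy-weighted read simulator thins fragment starts rather than
  splitting haplotypes; use the explicit-haplotype generators when exact
  junction physics matters.
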