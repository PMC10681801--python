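# Methods

This note documents the models, parameters and numerical conventions
behind `ptetools`: what each stage computes, what the synthetic-data
generator does and does not emulate, and the design choices made where the
procedure was genuinely open.

## Coordinate and data conventions

All coordinates are 0-based half-open. Coverage tracks are dense per-base
`float64` vectors per chromosome (~8 bytes/bp — a 10-Mb fixture costs
80 MB per track), read from and written to bedGraph with run-length
encoding. Chromosome names pass through verbatim; mismatches raise errors
naming the offenders. bedGraph records may not overlap, since the per-base
value would be ambiguous.

## Synthetic study design

The generator plants a known truth and emulates the signal structure the
analysis assumes; its defaults are the package's reference study
conditions.

**Genome.** 4 chromosomes × 2 Mb, background GC 0.41 i.i.d. Loci are laid
out on evenly spaced slots with bounded jitter (so overlap is impossible by
construction; impossible geometries raise a configuration error):

* **PTE loci (24).** A 1-kb core generated by a first-order Markov chain
  whose A→A and T→T transition probabilities are raised by 0.15 — this
  boosts AA/TT di-nucleotide frequency (~+0.06 over background) while
  leaving overall A+T content near background, mimicking poly(dA:dT)-rich
  but not grossly AT-rich elements. Each core carries one embedded
  `AAACGAAA` instance at N(0, 100 bp) from the centre on a random strand,
  and 12 five-base homopolymer tracts at oriented offsets −500…+2000 bp,
  each poly(dA)₅ with probability 0.85 (else poly(dT)₅) *in the orientation
  that points at the target gene* — planting the oriented strand bias. The
  core is flanked by two 2-kb CpG-island-like segments (GC 0.65). When the
  target gene lies left of the peak the whole fragment is inserted
  reverse-complemented, so orientation-aware statistics see a consistent
  picture. Each locus gets a planted amplitude uniform in [1000, 4000]
  (a 4× dynamic range) and one designated target gene with TSS 0.5–7 kb
  away on a random side; decoy genes are kept ≥25 kb from any locus.
* **PRC2-only loci (12).** A 2-kb CpG-rich segment, no motif, no PRC1
  signal — the "standalone PRC2" negative control.

**Tracks.** Expected depth per assay: MEL18 (and BMI1/RING2) are Gaussian
peaks (sd 250 bp) at the planted positions, height proportional to the
planted amplitude; SUZ12 is the sum of two flat-topped kernels centred on
the flanking CpG islands (the "offset to the sides" pattern) plus domains
at PRC2-only loci; H3K27me3 is a broad (±8 kb) soft-edged domain over both
locus types; input is flat. Peak centres are jittered independently per
replicate with sd 120 bp. Counts are drawn per base either Poisson or
gamma-Poisson (negative binomial, dispersion 0.3 — the default, since
ChIP-seq counts are overdispersed). Each track is then normalized so its
genome-wide sum is 1e9; interpreting values as reads starting per bp, this
is the RPKM of a 1-bp bin, and the sum satisfies
`Σx × (1/10³)/10⁶ = 1` per track. A single global seed fans out to
per-(assay, replicate) seeds through fixed assay codes, so adding an assay
never changes another's draws. Truth-derived "significant region" BED
files (min length 1 kb, centred on each replicate's jittered positions)
are emitted per replicate; a minimal Poisson/Benjamini-Hochberg caller is
also provided so the pipeline can run without any external peak caller,
but it is deliberately simple plumbing.

**RNA counts** are log-normal (meanlog 4, sdlog 1.6); each PTE target gene
is instead drawn from a low tail (meanlog 0.5, sdlog 0.8) with probability
0.82, reflecting that most Polycomb targets are silent.

What the generator does **not** emulate: read-level artefacts
(mappability, GC bias, duplicates), diploidy, chromatin-state
heterogeneity, correlated noise between replicates, or realistic gene
density. Passing tests therefore demonstrate correctness of the
*procedure* under the stated signal model, not performance on real
libraries.

## Region scoring

The binding score of a region is the maximal 1000-bp window sum of the
normalized signal (leftmost window on ties; regions shorter than the
window use themselves). Scores scale linearly with the track
normalization, so thresholds must live on the same scale as the tracks.
Replicate concordance keeps a region iff its summit window overlaps (≥1 bp)
a significant region of the other replicate, symmetrically; the kept
intervals are merged, re-summited on the replicate-mean track and scored
on each replicate over that shared window. Region grouping is
single-linkage chaining with gap ≤ 100 kb (edge-to-edge distance; overlap
counts as 0), never across chromosomes. Standalone PRC2 regions are SUZ12
regions overlapping H3K27me3 whose nearest MEL18 region is farther than a
parameter distance — 100 kb for the strict definition, 10 kb for the
permissive census; both are the same operation.

## Peak refinement

Smoothing is locally weighted polynomial regression (tricube weights on
the nearest ⌈span·n⌉ positions, degree 2, one iteration, no robustness
reweighting), applied **per bound region** — smoothing across a whole
multi-region group would average over the empty space between regions and
wash out sharp peaks — while the relative-amplitude filter references the
maximum peak score of the whole group. `span` is a fraction of the
region's positions (the smoother's native semantics). For regions longer
than 200 kb the signal is block-averaged into 10-bp bins before smoothing
and re-expanded by interpolation (a runtime guard; configurable).

Extrema are strict local maxima/minima of the smoothed signal with
plateaus collapsed to their midpoint, each scored by the edge-truncated
9-position mean. Filtering keeps peaks ≥ `peak_fraction` × (group's top
peak score); adjacent kept peaks merge unless some intervening valley
scores ≤ (1 − `valley_depth`) × the *weaker* flanking peak — the most
literal reading of "deeper than X% of the flanking peaks"; a mean-of-flanks
variant would be a one-line change. Merged runs are represented by their
highest-scoring member. The filter runs over the 6-combination grid
{0.50, 0.55, 0.60} × {0.30, 0.35}; consensus keeps peaks of the strictest
combination that have a counterpart within 50 bp in every other
combination (50 bp is below the tightest pairing scale of interest, and
this construction makes the output monotone: enlarging the grid can only
remove peaks).

Replicate pairing is mutual nearest neighbour (deterministic,
order-independent, one-to-one; optimal for well-separated peaks, unlike
greedy matching), performed within region groups; unmatched peaks are
returned, never silently dropped. Each pair yields
position = ⌊(p₁+p₂)/2⌋ and accuracy = |p₁−p₂|/2. Final scores are 9-bp
raw-signal sums per replicate (windows clipped at chromosome edges are
flagged); the replicate mean drives quartile assignment by stable rank
(Q4 = top, sizes balanced within one, ties resolved by position order).
Two different peak scores are thus in play by design: the smoothed
9-position mean only for filtering, the raw 9-bp sum as the reported
score.

## Screens

The reference-locus screen takes a table of summit-window scores for
MEL18/SUZ12 in the discovery line and a second line, with thresholds
either absolute (defaults 3000/2000, appropriate for SPMR-normalized human
data where the 1000-bp summit sum *is* the per-kb value) or derived from a
named reference locus via `ScreenParams.from_reference` (fractions of the
reference scores and its MEL18/SUZ12 ratio) — necessary on synthetic
scales, and closer to the screen's spirit of "comparable to the reference
element". A zero SUZ12 score makes the ratio +∞ and passes the ratio
criterion. The screen is monotone: raising any threshold never adds
candidates. High-confidence PTEs are Q4/Q3 peaks with accuracy ≤ 300 bp
("better than ±301 bp" in integer base pairs).

## Target genes and transcription groups

Distances are point-to-point (consensus-peak position to TSS). A TSS is
H3K27me3-marked iff ±1 kb around it overlaps a significant H3K27me3
region (promoter-scale; configurable). Decision: closer TSS marked →
closer gene; else farther marked → farther gene; else closer gene. One
gene per PTE is emitted (multi-gene targets are out of scope). Every peak
appears in the output, assigned or explicitly unassigned. Transcription
groups are quartiles of rank over the full gene universe with ties sharing
the lower group (an all-zero universe is entirely G1). The cross-line
overlap fraction is |A∩B| / min(|A|,|B|) — the fraction of the smaller
cohort recovered in the other — reported alongside a G-group transition
table.

## Sequence features

All sliding statistics use step 1. Di-nucleotide maps average per-window
frequencies (denominator = non-N di-nucleotides in the window; all-N
windows masked) over the peak set and subtract the control-set mean;
controls are seeded, non-overlapping random windows excluding peak
fragments. Homopolymer tracts are counted with overlaps (an A₆ run holds
two A₅ tracts — the sensitive convention; the generator's planted tracts
are non-overlapping so either convention recovers them) and a tract counts
toward a window only when fully inside it. Sequences are oriented
(reverse-complemented when the target gene lies left) before tract
counting. PWM scanning uses log₂ odds against a background (default
uniform), both strands, threshold 5.0; the single best match per sequence
(plus strand, then leftmost, on ties) contributes one count at its match
centre. Centrality profiles are normalized per quartile (so the quartile
curves are directly comparable; global normalization — each quartile
summing to its share of all matches — is available as an option) and
smoothed with a centred rolling mean of 500 positions. The column-swap
control exchanges two PWM rows (e.g. the C and G positions) leaving the
rest intact. Note that on A-rich cores the swapped PWM still finds genuine
near-matches, so its profile is compared against the true PWM's enrichment
rather than expected to be perfectly flat. Metaprofiles are per-offset
means over region centres, optionally strand-flipped; regions whose window
leaves the chromosome are excluded and counted.

## Pipeline

Stages (`simulate`, `regions`, `peaks`, `screen`, `assign`, `seqfeat`,
`all`) operate on one output directory with fixed file names and a single
YAML config; flags override the config and all randomness flows from one
seed. Each stage writes a manifest (parameters, SHA-256 of inputs, seed);
reruns are bit-identical apart from timestamps. The simulate stage builds
two "cell lines" from one genome — line A with every PTE occupied, line B
with a 60 % subset and its own seed — to feed the second-line screen
criteria and the cross-line overlap. Coverage tracks are not written by
default: a noisy 1-bp track of 8 Mb run-length-encodes to hundreds of MB,
and since track simulation is a pure function of (truth, seed) later
stages regenerate them in memory; `write_tracks: true` emits bedGraphs.
Missing inputs fail fast with the offending path; parameters validate
before any compute.

## Problem sizes and tolerances

The default study (4 × 2 Mb, 24 + 12 loci) was chosen so each score
quartile holds ≥4 peaks while a full pipeline run stays under a minute;
the pairing-distance statistics use a 56-locus variant. Oracle-equivalence
tests run ≥100 random small instances per operation against brute-force
re-implementations kept inside the test suite. Floating-point comparisons
use `atol = 1e-9` where exactness is expected (window sums, frequency
algebra) and looser, explicitly stated bounds where two different
estimator implementations are compared (e.g. our degree-1 loess vs an
external lowess, `atol = 0.02` on interior points of a smooth signal).

## Known limitations

* The stand-in significance caller is intentionally naive (fixed bins,
  global/input Poisson rate, BH) and should not be used on real data in
  place of a production broad-peak caller; the pipeline accepts external
  region BEDs for that reason.
* Pairing is defined for exactly two replicates; more replicates would
  need IDR-style machinery, which is out of scope.
* Scores inherit the track normalization scale; absolute screen thresholds
  are only portable between identically normalized tracks.
* The synthetic genome's i.i.d./Markov composition makes motif-control
  contrasts cleaner on purpose-built fixtures than on the genome itself
  (see Sequence features above).
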