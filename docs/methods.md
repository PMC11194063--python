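# Methods

## Scope and data model

The package implements the computational arc of a joint ChIP-seq / RNA-seq
co-occupancy study in *S. cerevisiae*, starting from fixed-bin coverage
tracks and gene×sample count tables (read alignment, batch adjustment of
counts, and external database queries are out of scope; batch labels are
carried through untouched). All internal coordinates are 0-based,
half-open; conversion to 1-based GTF happens only at I/O. Each gene is a
single-transcript model: a CDS span covered by ordered exons whose gaps are
introns. Landmarks (CDS start/end, last-intron 3′ end) are reported in
transcription orientation; "the last intron" is the intron whose 3′ splice
site lies nearest the transcription 3′ end. A gene is IC (intron-containing)
iff it has ≥1 annotated intron; RP membership is an input list (or an `rp`
GTF attribute), not inferred from names, because ribosomal-protein status is
a curated property.

## Peak calling

The caller is a deliberately simple Poisson model operating on the same
fixed-bin grid as the tracks. For each IP bin with count $x$, the expected
background rate is $\lambda = \max(\text{local control mean},
\text{genome-wide control mean}) \cdot \ell$, where the local mean is a
1 kb moving average of the control and $\ell$ is the IP/control
library-size ratio. The upper tail $P(\mathrm{Pois}(\lambda) \ge x)$ is
corrected genome-wide by Benjamini–Hochberg; bins with $q \le$ FDR
(default 0.05) are merged when separated by ≤ `merge_gap` (default 300 bp,
the fragment scale) and merged intervals narrower than `min_width`
(default 50 bp) are dropped. The summit is the leftmost maximal IP bin
(deterministic tie-break); fold enrichment is the ratio of mean IP CPM to
mean control CPM over the peak, so library sizes cancel. On pure background
the discrete Poisson p-values make BH conservative: the realized
false-discovery proportion is far below the nominal target, which the
acceptance checks treat as "consistent with" the FDR bound.

Replicate reconciliation follows the study design filter: pooled peaks are
chained by ≥1 bp overlap (half-open intervals; the overlap criterion is a
declared choice, the design leaves it open); a chain is retained iff every
replicate contributes a peak *and* the maximum fold enrichment is strictly
greater than the threshold (default 2). The output interval is the union
extent of the chain. HCR masking removes any peak overlapping a
hyper-ChIPable interval by ≥1 bp; both partitions are returned for audit.

## Peak-to-gene curation

Candidates are all genes whose span overlaps the peak extended by ±500 bp.
Two-gene regions are classified geometrically: intron-embedded (one gene
inside an intron of the other), overlapping 3′-exons (transcription-final
exons overlap on opposite strands), parallel (same strand), otherwise
convergent. The first three resolve to the candidate containing the peak
summit; overlapping-3′-exon regions drop dubious-ORF candidates; anything
else is flagged unresolved for manual review. Curation then removes genes
whose peak is entirely downstream of the CDS end (oriented), overlaps an
HCR, belongs to a disallowed feature class, or is wider than
`broad_width_threshold` (default 2000 bp — a reproducible proxy for the
"broad diffuse peak" judgement, which has no quantitative definition in the
underlying study). The rules are mutually independent, so the curated set
is order-invariant; each removed gene carries the first reason by a fixed
priority.

## Occupancy profiles

Metagene matrices are genes×positions CPM tables, orientation-flipped so
downstream is rightward. Fixed-window modes anchor at a landmark; the
minus-strand column mapping is chosen so a point mass at oriented offset
$+o$ receives the same column label on both strands (mirror symmetry of the
half-open bin grid). Scaled mode rescales each CDS onto 100 columns by
cumulative-sum mean pooling, which conserves row totals exactly, with
fixed-width flanks. The summit offset is the (leftmost) argmax of the
column-mean profile after a centred moving average of 7 bins (70 bp). The
smoothing width matters: the expected profile is a Gaussian of ≈130 bp
standard deviation (fragment smoothing), so its top is flat relative to
bin-level Poisson noise and an unsmoothed argmax wanders by ±30–40 bp on
a 50-gene cohort; a 70 bp window is still far below the signal's intrinsic
scale and does not shift the maximum, but suppresses that wander to within
one or two bins. Replicates are pooled row-wise before estimating cohort
summits.

k-means (k-means++ initialization, best of 10 restarts, seeded) operates on
row-max-normalized feature blocks, one block per experiment, so no single
experiment dominates the Euclidean metric; the normalization applied before
clustering is a declared choice, as the underlying study does not state
one. The transition index per gene and time point is
$\log_2((\text{3′ mean} + c)/(\text{promoter mean} + c))$ with pseudo-count
$c = 0.5$ CPM, using windows $[-500, 0)$ around the CDS start and
$[-200, +300)$ around the CDS end (the study shows heatmaps but defines no
windows; these are explicit, tunable proxies). Cohort medians per time
point summarize the promoter→3′ transition.

## Enrichment

Class over-representation is the one-sided hypergeometric upper tail
(equivalently Fisher exact in the enrichment direction), computed via
`logsf` so that tails of order $10^{-150}$ — the magnitude the printed
study values reach — stay representable; results carry both `p_value` and
`log10_p`. The population size $N$ and category sizes $K$ are explicit
inputs (annotation-version dependent), never hard-coded. Percentages are
printed with half-away-from-zero rounding alongside exact values.

## Splicing and expression

The IC filtering cascade retains genes with at least one intron of ≥25 bp,
whole-gene counts ≥75 in **every** sample (a per-mean switch is exposed;
the per-sample reading is the default since the study's wording does not
say), and no HCR association; zero intron reads never disqualify. The
splice ratio is $s = \mathrm{clamp}(1 - (I/L_i)/(E/L_e), 0, 1)$ with
$I = \max(G - E, 0)$; $G < E$ artifacts of real counters are clamped with a
logged count, $E = 0$ yields an undefined (NaN) value excluded from
averages, and multi-intron genes pool intron length and intron reads (the
counting scheme cannot resolve individual introns). Library normalization
scales each sample to the mean library size. Group comparisons average
replicates within time points, pair by gene, and use the two-sided paired
t-test; groups smaller than 3 are flagged rather than tested, all-zero
difference vectors report $t = 0, p = 1$, and constant non-zero differences
are reported as the degenerate infinite-$t$ case.

## Synthetic data generator

The generator emulates the statistical structure of the study's data, not
its sequences. Genes are packed without overlap on ≥2 chromosomes with
1.4–2.2 kb spacing so ±500 bp flanks are unambiguous outside deliberately
constructed two-gene regions (all four overlap geometries constructible on
demand). IC genes have a short 5′ exon (60–150 bp), one intron (60–400 bp)
and a 300–390 bp final exon, so the planted 3′ summit (+250 bp downstream
of the last-intron 3′ end) also lies ~50–140 bp upstream of the CDS end —
matching both anchor offsets the study reports for the 3′-exon signal.

ChIP coverage is Poisson around background (0.10 reads/bp) plus Gaussian
bumps (σ = 130 bp, emulating ~300 bp fragment smoothing; the Gaussian gives
the expected profile a unique argmax). The Mediator-like factor follows a
four-point amplitude schedule — promoter 10→7→3.5→0.4, 3′-exon
0.8→1.6→3.5→8 expected counts/bin for co-occupied genes — encoding the
promoter-to-3′ transition across the growth phases; the Lsm3-like factor is
a time-invariant 3′-exon bump, stronger at co-occupied than Lsm3-only
genes. Replicates share the expected profile and differ only in the noise
stream; the control track is background-only.

RNA-seq counts are Poisson with exon-only counts
$E \sim \mathrm{Pois}(e f_j L_e / 1000)$ and intron reads
$I \sim \mathrm{Pois}(e f_j (1 - s) L_i / 1000)$, $G = E + I$, so intron
read density is exactly $(1-s)$ times exon density in expectation and the
splice-ratio estimator is consistent; its small negative bias scales as
$(1-s)/\mathbb{E}[E]$ and vanishes with depth. Default design mirrors the
study: 24 replicates at 0 h, 6 at 2/4/6 h; log-normal library factors
(σ = 0.15). Occupancy groups default to the study's 72/45/17/7 proportions
among IC genes; co-occupied genes carry baseline splice ratios of
0.85–0.97 with a planted 0.10 drop at 6 h and high, declining expression
(800→400 exon reads/kb); the unbound group has lower, stable ratios
(0.55–0.90) and constant expression (350 reads/kb). Expression levels are
set so every grouped gene's expected depth clears the 75-read filter with
margin — Poisson dips should not erode the planted group sizes. Noise is
Poisson, not negative binomial: sufficient for estimator-recovery tests;
overdispersion is left as a config hook.

What the generator does **not** emulate: realistic sequence content,
read-level artifacts (GC/mappability bias, multimapping), overdispersed
biological replicate variability, correlated gene neighbourhoods, or
isoform complexity. Passing tests therefore demonstrate correctness of the
estimators and bookkeeping under the declared noise model, not robustness
to every artifact of real libraries. One such gap is visible by
construction: with total-count library normalization, a small synthetic
cohort dominated by strongly down-regulated genes shows a composition
effect that shifts "unchanged" genes' normalized expression between time
points; splice ratios, being within-sample density ratios, are immune.

## Fixtures

Two constructed fixtures (both labelled synthetic) reproduce the study's
bookkeeping arithmetic by design: `make_curation_fixture` plants 127 called
regions, 11 overlapping HCRs, and 33 two-gene regions so that masking and
curation yield 116 regions, 149 candidate genes and 116 curated genes with
an 81/17/14/4 class partition (9 of the 11 HCR-removed genes RP, all 11
IC); `make_cooccupancy_lists` builds a 6600-gene population (376 IC, 138
RP, 90 IC–RP) with 725 Mediator and 116 Lsm3 genes overlapping in 86, of
which 82 RP, 76 IC and 73 IC–RP. These stand in for curated supplementary
gene lists; the arithmetic performed on them (intersection, class shares,
enrichment) is the package's own.

## Numerical choices and problem sizes

Deterministic seeds flow through `numpy.random.SeedSequence`; all
generators are pure functions of (parameters, seed). Summit ties break
leftmost; BH is the standard monotone step-up; clamps and undefined values
are logged, never silent. Test and acceptance problem sizes — 50–200 gene
cohorts, 1–3 Mb background genomes, 10-seed repetition for the stochastic
detection checks, 50 seeds for false-discovery calibration — were chosen so
each check isolates one property at desk scale while keeping Monte Carlo
noise well inside the asserted tolerances.

## Known limitations

- One transcript model per gene; no GFF3 phase handling or isoforms.
- The peak caller is not a reimplementation of any external tool; numerical
  agreement with published peak coordinates is not a goal.
- Exact reproduction of the study's printed enrichment p-values is not
  attempted: the population behind them is unstated, and the magnitudes
  (e.g. $10^{-148}$ for 82/86 RP genes) depend strongly on $N$; with the
  6600-gene synthetic background the same arithmetic yields $\sim 10^{-145}$.
- "Broad diffuse" removal is a width threshold, an explicit proxy for a
  manual judgement.
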