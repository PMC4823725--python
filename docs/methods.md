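# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic generators do and do not emulate,
and the known limitations.

## Genomic intervals

Peaks are BED-style 0-based half-open intervals `[start, end)`. All overlap
arithmetic is half-open: intervals abutting at a shared coordinate never
overlap, and edge-to-edge gaps are measured as `next.start − prev.end`.

**Input subtraction** removes a sample peak when it shares at least one base
pair with any control (input-chromatin) peak. A single shared base suffices;
the operation is idempotent.

**Overlap / proximity counts** between two conditions classify each peak of
set A as *overlapping* (≥ 1 shared bp with some B peak) or *proximal*
(non-overlapping, nearest B peak within a configurable edge-to-edge gap,
200 nt by default). The categories are disjoint by construction. Whether
"overlap" should instead require a reciprocal fraction is a design choice;
≥ 1 bp is the default and the proximity distance is exposed.

**Feature annotation** assigns exactly one category per peak —
promoter > exon > intron > intergenic — decided by the peak midpoint. A
single-label rule is required to produce the standard fraction-per-category
tables; the midpoint is robust to peak length and makes the precedence rule
order-independent. The promoter is a window around the transcription start
site, strand-oriented: 2000 nt upstream and 200 nt downstream by default
(a common UCSC-style convention; the study does not define one, so both
margins are configurable and reported with the results). Peaks are
unstranded; gene strand is used only to place the TSS. Ties between genes in
the same category break deterministically on (txStart, gene name).

## Motif scanning

Degenerate repeat-quantified motifs are written in a small grammar: an IUPAC
letter or bracketed base set followed by an optional quantifier `{min,max}`,
`{min,}` (unbounded) or `{n}`. The two motifs quoted throughout are the
SATB1 binding site `[AT]{3,6}C[AT]{3,}` and the G-quadruplex
`G{3,}N{1,20}G{3,}N{1,20}G{3,}N{1,20}G{3,}`. The shipped default library
(SATB1, TC2-3AT, G-quadruplex, and an `[AT]{10,}` AT-island proxy for
origin-of-replication/S/MAR rules) is a synthetic stand-in for a full
matrix-attachment-region rule set; production scans should pass a curated
motif file.

Matching is leftmost, greedy, non-overlapping — the semantics of a
backtracking regular-expression engine, which the test suite uses as an
independent oracle (exhaustively for short sequences, and on random 2-kb
sequences for the full patterns). With unbounded quantifiers, overlapping
occurrence counts are ill-defined; the non-overlap policy makes counts
reproducible and oracle-checkable. Both strands are scanned by default:
minus-strand hits are located on the reverse complement and reported in
forward coordinates, and hits with identical coordinates on both strands
count once. An input `N` is treated conservatively: it matches only the
fully degenerate class, never a concrete base.

The **weighted motifs-per-peak** statistic is `w_i = 100·m_i / L_i` — hits
per 100 nt of peak — so peak sets with very different length distributions
(e.g. ~150-nt vs ~480-nt mean peaks) can be compared. The factor of 100
reproduces the magnitude of values reported for real peak sets (≈ 1 for a
few hundred nt with a few hits); the alternative reading `m_i/(100·L_i)`
yields values four orders of magnitude smaller and is rejected.

## Inter-peak spacing

Distances are taken between successive peak start coordinates within each
chromosome (start-to-start is robust to unequal peak lengths; midpoint and
gap references are available). Chromosomes never mix; chromosomes with
fewer than two peaks contribute nothing. Quantiles are the standard type-7
(linear interpolation) estimator.

The spacing density is a Gaussian KDE restricted to `[0, 4.0 Mb]`:
distances beyond the bound are dropped and the density renormalized to unit
mass on the grid (512 points by default). The bandwidth is
`smoothing × h_Silverman` with `smoothing = 0.5` by default;
`h_Silverman = 0.9·min(sd, IQR/1.34)·n^(−1/5)` of the truncated sample. The
0.5 multiplier interpretation of the smoothing setting is a documented
choice — the original statistical package's bandwidth convention is not
recoverable — and it is exposed in configuration. Truncate-then-renormalize
has a known bias within about one bandwidth of zero; no boundary-correction
kernel is applied.

A **mode** (regular spacing signal) is an interior local maximum of the
density that (a) has topographic prominence at least 10% of the density
maximum and (b) stands at least twice the density of *both* featureless
reference profiles at that position: the uniform density `1/upper_bound`
and an exponential density with scale equal to the sample mean spacing (the
Poisson-process null for randomly placed peaks). Requirement (b) is what
lets the estimator say "no regular spacing": a finite sample from a flat
profile shows locally prominent wiggle, and truncating a decaying gap
distribution at zero always creates a spurious near-boundary maximum —
neither rises meaningfully above its own null curve, whereas a genuinely
preferred spacing does. With 500 distances, a Normal(125 kb, 10 kb) spacing
yields a single mode within ±10 kb of truth, and uniform and
exponential-gap nulls are reported mode-free (the exponential null retains
a ~5–10% false-positive rate per sample; the mode grid resolution is
`upper_bound/511 ≈ 7.8 kb`).

## Super-resolution localization analysis

Localizations are 2-D points (x, y in nm) per channel inside a rectangular
ROI; axial information is unsupported.

**Dot co-localization.** The threshold is two thirds of the smallest
effective labelled-protein size; with the 60-nm primary+secondary antibody
estimate used for both proteins this is 40 nm. A localization is
co-localized when its nearest neighbour in the other channel is within the
threshold. The headline fraction pools both channels (union denominator);
per-channel fractions are reported alongside because the denominator choice
is a genuine design freedom.

**Pixel co-localization** rasterizes each channel to a binary occupancy
grid (20 nm pixels by default), optionally dilates each mask by
`ceil(dilation/pixel_size)` 8-connected iterations, and reports co-occupied
pixels as a percentage of pixels occupied in either channel. The percentage
is monotone non-decreasing in dilation.

**OPTICS clustering** is implemented from scratch. Core distance of a point
is the distance to its min_pts-th closest point (counting itself) when at
least min_pts points lie within eps, matching the common library
convention; the test suite cross-checks reachability values and extracted
partitions against an independent library implementation. Points are
processed in order of smallest current reachability, with ties and fresh
starts resolved by ascending input index for determinism. Cluster
extraction at a reachability cut follows the standard DBSCAN-style rule: a
point whose reachability exceeds the cut starts a new cluster if its own
core distance is within the cut and is noise otherwise (a literal
"runs-only" reading would mislabel the first point of every cluster, whose
reachability is inherited from outside it). Extracted clusters smaller than
min_pts are demoted to noise. Defaults min_pts = 5, eps = 100 nm,
reach_cut = 50 nm suit typical single-molecule localization densities; all
three are required knobs for real data. Cluster size is the maximum
pairwise member distance; cluster spacing uses all pairwise centroid
distances.

**Spectral periodicity.** Pairwise inter-cluster distances are histogrammed
at 10-nm bins from zero, the counts mean-subtracted, and the magnitude of
the real FFT taken and normalized to its maximum over non-zero frequencies.
Up to the two largest interior spectral maxima with normalized magnitude
≥ 0.2 and period inside the resolvable range (2×bin width, histogram span)
are reported in increasing period; for clustered patterns the shorter
period reflects the cluster-size scale and the longer the inter-cluster
spacing. Regular spacing is declared only when the spectrum's global
non-DC maximum is itself one of these interior peaks: a periodic
arrangement concentrates power at its fundamental, whereas an irregular
arrangement's spectrum is dominated by the broad low-frequency envelope of
the distance distribution. On a 20-point 106-nm lattice with 5-nm jitter
the fundamental is recovered within one bin; recovery degrades once jitter
exceeds roughly 10% of the spacing, because pair-distance smearing (√2
times the per-point jitter) suppresses the fundamental below the noise
floor. A histogram-autocorrelation construction was considered as an
alternative signal; the histogram-FFT realization was kept because its
period axis is directly interpretable and its null behaviour is testable.

## ΔΔCt quantification

ChIP enrichment over the IgG mock control uses arithmetic means of Ct in
cycles:

    ΔΔCt = (mean Ct_ChIP − mean Ct_input) − (mean Ct_IgG − mean Ct_input)
    fold = 2^(−ΔΔCt)

RT-qPCR relative expression normalizes target to reference (GAPDH) and a
control condition the same way. Amplification efficiency is assumed exactly
2 per cycle (efficiency was verified separately in the assays this models;
efficiency correction is out of scope), no replicate outlier rejection is
performed, and means are taken on the Ct (cycle) scale, not on linearized
quantities — matching the formula as printed on reports. Identities that
follow from the algebra (unit fold for equal ChIP/IgG means, reciprocity
under ChIP↔IgG swap, invariance to adding a constant to every Ct) are
enforced by tests.

## Synthetic data

Every generator draws from one explicit seed (no global state), returns a
truth sidecar, and writes the same text formats the readers consume, so
identical seeds give byte-identical files.

* **Peak sets**: lengths Normal(170, 40) truncated at 20 nt (the scale of
  observed ChIP-seq peak length means, 130–490 nt); `periodic` spacing
  places successive starts at `period + N(0, jitter_sd)` (defaults 125 kb ±
  5 kb, the spacing scale the KDE analysis targets), `poisson` draws
  exponential gaps sized to the chromosome. Peaks are apportioned across
  chromosomes proportional to size.
* **Sequences**: i.i.d. background at 41% GC (human genome average) with
  non-overlapping planted motif realizations at recorded positions; a ≥2-nt
  background margin separates plants so greedy scanning cannot merge two
  plants and a lone separator base cannot complete a site on the reverse
  strand. A G/C-only background (gc_fraction = 1) makes A/T-rich pattern
  counts exactly equal planted truth.
* **Localizations**: cluster centroids on a jittered 1-D lattice (106-nm
  default spacing, 5-nm placement jitter) or uniformly scattered;
  Poisson-distributed molecules (mean 30, minimum 1) with 15-nm isotropic
  spread per cluster; optional uniform background. Passing shared centroids
  to a second channel emulates co-localized structures.
* **Ct tables**: input at 20 cycles, IgG 5 cycles later, ChIP shifted by
  −log2(true fold), plus optional Normal replicate noise.
* **Gene models**: non-overlapping genes on equal slots per chromosome,
  alternating exon/intron structure, random strand.

What the generators do *not* emulate — and therefore what passing tests do
not show about real data: read-level noise and peak-caller artifacts,
chromatin-state-dependent sequence composition, centromere/assembly gaps in
spacing, localization blinking/overcounting and drift, and qPCR efficiency
differences between primer pairs. Conclusions about real datasets require
the real upstream processing these stages deliberately exclude.

## Problem sizes

Stochastic checks use 20-seed batches (KDE recovery, periodicity, nulls),
100-seed batches (OPTICS blob recovery), 100-peak planted-motif sets, 500
distances per KDE sample, and 2-kb random sequences for scanner/oracle
agreement — sizes at which every targeted effect is comfortably resolved
while the full suite runs in minutes.

## Known limitations

* KDE mode positions are quantized to the evaluation grid (~7.8 kb at the
  default 4-Mb bound and 512 points).
* The exponential-spacing null is intrinsically hard near the boundary;
  its per-sample false-positive rate is ~5–10% rather than zero.
* The OPTICS selection loop is quadratic in point count; fields beyond a
  few tens of thousands of localizations will be slow.
* Periodicity detection assumes a single dominant lattice constant; mixed
  periods are reported only through the two-peak summary.
* Motif scanning is exact-match over base classes; no PWM scoring or
  mismatch tolerance.
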