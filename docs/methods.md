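# Methods

## The assay being modelled

Methyltransferase-based single-molecule footprinting reads nucleosome
occupancy at one locus, one molecule at a time. Intact chromatin is treated
with a GpC methyltransferase (M.CviPI-style), which methylates every
*accessible* GpC cytosine; DNA is then bisulfite-converted and individual
PCR clones are sequenced. On each clone, a methylated (C) GpC means the site
was accessible, an unmethylated (T) GpC means it was protected — typically
by a nucleosome. Because human DNA carries no endogenous GpC methylation
outside GpCpG context, the same clone simultaneously reports endogenous CpG
methylation at CpG sites, so one read yields both the methylation state and
the chromatin state of a single molecule. Cytosines in GpCpG context are
excluded from both readouts: enzyme-applied and endogenous methylation
overlap there and cannot be told apart. Both the GpC call and the CpG call
at such an overlap are dropped.

The locus of interest is a bidirectional L1 promoter: a sense TSS
transcribing into the element and an antisense TSS (the ASP) transcribing
outwards, far enough apart that each start site has its own +1 nucleosome
between the two TSSs. The silent promoter is tetranucleosomal (−1 and +1 at
both TSSs); the active promoter keeps only the two +1 nucleosomes, leaving
nucleosome-free regions upstream of both TSSs.

## Coordinates and site classification

All user-facing coordinates are 1-based inclusive (browser-span style;
`interval_length = end − start + 1`). A site's position is the position of
the C of its dinucleotide on the top strand, and only the top strand is
analysed — locus-specific bisulfite PCR amplifies one converted strand per
clone. `N` voids any context it touches. Classification is per cytosine:
GpCpG → excluded; CpG (not preceded by G) → endogenous-methylation site;
GpC (not followed by G) → accessibility site; all other Cs are
context-free and serve as conversion controls.

## The synthetic-data generator

The generator emulates the full experimental chain with known ground truth.

**Reference locus.** The default locus is a deterministic 16-bp tiling
(720 bp) carrying one GpC, one CpG and one context-free C per tile, i.e.
informative GpCs every 16 bp (~9 per 147-bp nucleosome window, comfortably
above the ≥8 needed for reliable window calls), with the sense TSS at
position 200 and the antisense TSS at 515 — exactly two 147-bp nucleosomes
plus a 20-bp linker between them, and room for a −1 nucleosome outside
each TSS. A regular site lattice is deliberate: it makes footprint-edge
uncertainty uniform and the round-trip tests exact. Real loci have ragged
site spacing; see Limitations.

**Molecules.** Each molecule draws an occupancy state from a configurable
mixture (default 50/50 tetra/di, the two states the promoter actually
adopts; `open` is available for controls). Footprints are 147-bp core
particles placed immediately up-/downstream of the TSSs. Endogenous CpG
methylation is biphasic — each strand fully methylated or fully
unmethylated — matching the observed all-or-none strand patterns; by
default it is tied to the chromatin state (tetra = methylated, di/open =
unmethylated), or drawn Bernoulli(w) per strand when a mixture weight `w`
is given.

**Enzyme and conversion.** Each accessible GpC is marked with probability
`enzyme_efficiency` (default 0.85); GpCs under a footprint are never marked
(steric protection is absolute). Every unmethylated C then converts to T
with probability `conversion_rate` (default 0.99). Both defaults reflect
typical wet-lab performance of a short methyltransferase treatment followed
by bisulfite conversion. Sequencing error is not modelled separately from
conversion failure: clones are Sanger-quality and a single noise channel
keeps the model identifiable. Reads are always reference-length (no
indels).

One seeded generator drives every draw, and the *number* of draws is
independent of parameter values (each GpC consumes one uniform whether or
not it is protected; each C consumes one whether or not it is marked).
Identical seeds therefore give byte-identical datasets, and runs that
differ only in a rate parameter are common-random-number comparable — the
accuracy-vs-efficiency monotonicity test relies on this.

**Cohorts.** Per-sample methylation/expression tables with groups N
(normal, cancer-free), CN (histologically normal, tumor-bearing organ) and
T (tumor). Group defaults — N: n=19, 85 ± 8% methylation, 1.0 ± 0.5
relative expression; CN: n=30, 45 ± 18%, 5 ± 2.5; T: n=30, 25 ± 15%,
8 ± 4; within-group methylation–expression coupling −0.8 — encode the
direction and rough magnitude of the clinical contrast (hypomethylation
with ectopic expression in CN and T) at realistic cohort sizes; they are
not fits to any published cohort, whose per-patient values are not
available. Methylation is clipped to [0, 100], expression floored at 0.

**MNase.** Partial digestion cuts each inter-nucleosome linker
independently with probability `p_cut`; a fragment's class is the number of
nucleosomes it spans. With three linkers per tetranucleosome the eight cut
patterns are exhaustively enumerable, which the tests use as an oracle.

## Methylation calling and statistics

Clone reads must align ungapped and co-linearly (equal length); reads whose
context-free positions disagree with the fully converted reference at >10%
of positions are rejected as foreign clones. Clone QC measures conversion
efficiency as the T-fraction at context-free cytosines and removes clones
below 0.95 by default. A conversion failure at an informative site is
indistinguishable from methylation on a single molecule, so no per-cell
correction is attempted — QC is the only guard, as in standard
clone-sequencing practice.

Per-site percent methylation is `100 · M/(M+U)` with missing cells ignored;
the locus summary is the *unweighted mean over sites* (the convention when
an assay reports the average of its 2–4 designed CpG sites). Sites with no
informative cell are flagged and excluded. PUR (percent fully unmethylated
strands) drops molecules with missing cells in the chosen subset. The
strand histogram uses 10% bins with the exact-0 and exact-100 masses
reported separately, since biphasic claims concern exactly-all-or-none
strands. Two assays reading different site subsets of the same samples are
compared by Pearson correlation. Technical replicates are not modelled:
each sample contributes one value per assay, already averaged over the
assay's sites.

## Footprint inference

Protected patches are maximal runs of protected GpCs. Missing calls are
neutral — absence of evidence neither breaks nor extends a run. A patch's
span extends to the midpoint between its terminal protected sites and the
flanking accessible sites (or to the amplicon edge), a symmetric treatment
of inter-site uncertainty. Spans within [120, 200] bp are `nucleosome`
class (core particle ± linker/resolution slack), below `sub-nucleosomal`,
above `super-nucleosomal`; all bounds configurable. An optional smoothing
parameter `k` absorbs up to k isolated accessible calls per patch
(default 0 — no smoothing; raising k trades false fragmentation for false
merging and is left to the user).

**Promoter-state classification.** Four windows are defined: −1 and +1
(147 bp each) at both TSSs, with +1 downstream in each TSS's transcription
direction. A window is *occupied* when footprint spans cover ≥
`min_window_coverage` bp of it (default 98 bp, two thirds). Coverage —
rather than requiring a single nucleosome-sized footprint, or vetoing on
any footprint — is what makes the call robust to both noise channels of
the assay: an enzyme miss adds only a small spurious patch in an open
region (~one inter-site gap of coverage), and a conversion failure splits
a genuine patch into two pieces whose spans still cover the window.
Single-footprint-overlap variants evaluated during development recovered
only 88–98% of states and were not monotone in enzyme efficiency;
the coverage rule recovers ≥99% at the default noise levels and is
monotone across the 0.5–1.0 efficiency grid.

The rules, in order: any window with zero informative GpC calls → `other`
("uninformative window"); protected fraction ≥ 0.9 overall *or* all four
windows occupied → `tetranucleosomal` (the fraction clause matters because
linkers between abutting nucleosomes may carry no informative GpC, merging
all four footprints into one patch); both +1 windows occupied and both −1
windows accessible-and-unoccupied → `dinucleosomal`; protected fraction
≤ 0.1 → `open`; otherwise `other`. Note that at enzyme efficiency 0.85 a
truly open molecule has an expected protected fraction of 0.15 and is
deliberately reported `other`, not `open` — the open call asserts evidence
of accessibility, not absence of a pattern.

A population is summarised as per-state counts and fractions; no cutoff is
imposed for declaring a promoter tetra- or dinucleosomal at the population
level — that judgement is left to the user.

## Cohort statistics

Mann–Whitney U uses mid-ranks on ties. With n₁+n₂ ≤ 16 and no ties the
two-sided p is exact, by full enumeration of the C(n₁+n₂, n₁) rank
assignments (p = probability of a U at least as far from n₁n₂/2 as
observed; the enumeration cutoff balances fidelity against runtime, and
the two paths agree to within 0.03 in the overlap zone). Otherwise a
normal approximation with tie correction and a continuity correction is
used; the method taken is recorded in the result. All p-values are
two-sided (figure-star convention) and unadjusted; a Bonferroni option
exists but defaults off. Stars: *** p<0.001, ** p<0.01, * p<0.05.

ROC curves sweep the unique scores as thresholds; tied scores produce
diagonal segments, so the trapezoidal AUC credits ties 0.5 and equals
U/(n₁·n₂) exactly — a property-tested identity. The positive-class
direction is a required, explicit parameter (`low` for methylation:
hypomethylation is the disease signal); silent sign errors are the main
failure mode of ROC analyses on methylation data. The site subset fed into
the ROC (2-site vs 4-site averages) is likewise a parameter.

## What the tests do and do not show

The test suite and acceptance script measure the pipeline against its own
generator: exact round-trips at zero noise, ≥95% state recovery and ≤5 pp
mixture error at efficiency 0.85/conversion 0.99, <1 pp percent-methylation
bias at 500 clones, PUR recovery of a 50/50 biphasic mixture within
binomial error, a calibrated 5% test size, and exact agreement of the rank
statistics with enumeration oracles. These validate the *inference
machinery*. They do not validate the generator against real chromatin:
real loci have irregular GpC spacing (sometimes zero informative sites in
a window — such molecules are reported `other`, not guessed), nucleosomes
are mobile rather than fixed at canonical positions, enzyme efficiency
varies with chromatin context, PCR can duplicate clones, and patient
cohorts carry structure no three-Gaussian mixture captures. Published
patient-level quantities (AUCs, assay-concordance R, p-values) depend on
undeposited clinical data and are structural templates here, not
reproduction targets.

## Numerical and degenerate-input conventions

Midpoint spans use floor division; ties in rank statistics use mid-ranks;
a Mann–Whitney with zero pooled variance returns p = 1. Empty groups, empty
site subsets, zero-variance correlation inputs, all-failing QC and
malformed intervals raise explicit `DataError`s naming the offending
record. Coincident sense/antisense TSS annotations are accepted with a
logged warning. Sampling problem sizes in the tests (500–10,000 molecules
or replicates, 40–48 Monte Carlo repetitions) were chosen to keep each
statistical bound at least ~3 standard errors wide at desk-scale runtimes.
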