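# Methods

This note documents the models, parameter choices and numerical conventions
behind `mirquiescent`, and what the synthetic-data calibration does and does
not establish about real cohorts.

## Relative quantification

The comparative threshold-cycle model assumes perfect doubling per cycle and
equal PCR efficiency for target and reference, so relative expression is
fold = 2^−ΔΔCT exactly; no efficiency correction is implemented. The
reference is a small RNA present in every sample (default `U6`); a missing
reference CT in any sample is a hard error naming the sample. The control
baseline per miRNA is the arithmetic mean of control ΔCTs (the standard
comparative-CT convention; a median option exists for robustness analyses).
miRNAs with fewer than two control ΔCT values have no interpretable
baseline and are excluded with a warning rather than aborting the run.

"No amplification" wells are a dedicated missing value (NaN) end to end —
never coded as CT 40 or infinity — so detection logic stays explicit.
Detection is decided per condition: a miRNA is detected when its **median**
CT over the condition's samples is below the cut-off (default 35 cycles),
with missing wells counting as at/above the cut-off. The median was chosen
over "any well" or "all wells" because with 8–10 samples it tolerates a
single failed or contaminated reaction in either direction; both
alternatives remain available (`policy="any"/"all"`). A miRNA enters
relative analysis for a condition only if detected both there and in
controls, since a fold change against an undetected baseline is meaningless.

## The dispersion-derived cut-off

Per-miRNA, per-condition standard deviations of patient log-folds
(n−1 denominator) are pooled across the four disease × state conditions —
controls are the reference and do not contribute — into mean_Disp and
SD_Disp, and the dysregulation magnitude threshold is
|mean_Disp + m·SD_Disp| with m = 0.5 by default. The threshold is compared
against the **mean** patient log-fold per (miRNA, condition), strictly
(|mean| must exceed the cut-off); per-patient exceedance is not required.
Cells with fewer than two values are skipped and logged; a pool with a
single SD reports SD_Disp = 0 with a warning.

Significance uses the two-sided Mann-Whitney U test of the condition's
patient log-folds against the control log-folds (equivalent, up to a
per-miRNA constant, to testing ΔCT against control ΔCT). The exact null
distribution is used when n+m ≤ 16 and the data are tie-free; otherwise the
tie-corrected normal approximation with continuity correction. Ties are
handled by midranks; two identical groups return p = 1 by convention. No
multiple-testing correction is applied by default — the procedure is raw
p ≤ 0.05 with the magnitude filter carrying the stringency — but a
Benjamini–Hochberg flag (`bh_correct`) exposes the modern alternative.
Set partitioning over the significant calls is direction-aware throughout:
a miRNA up in one condition and down in another is never "common".

## Co-regulation clustering

Patient-level log-fold vectors (one 8-dimensional point per miRNA, within
one condition) are clustered by k-means with k = 20, k-means++
initialisation, 10 restarts scored by within-cluster sum of squares, and a
fixed seed; with fewer points than k the effective k drops to the point
count, so exactly min(k, n) clusters are non-empty. Distance is Euclidean on
raw (unstandardised) log-folds by default — the alteration magnitude is part
of the signal — with a row-standardisation flag for shape-only clustering.
Patient-level vectors (not mean profiles) are clustered so that concerted
regulation must show in the patients, not just in the averages. Cross-
condition co-membership reports, for a query set, the largest subset sharing
one label per condition and the largest subset whose label tuple is
identical across **all** conditions; results are invariant to cluster
relabelling.

## Classification

Marker score: signal-to-noise (μ_a − μ_b)/(σ_a + σ_b) on log-folds, each
class SD floored at max(0.2·|μ|, 0.2) to guard against vanishing
within-class variance; ranking by |score|, ties by id. Panels are a forced
set (by default the six miRNAs with significantly distinct UC/CD alteration:
mir-150, -196b, -199a-3p, -199b-5p, -223, -320a) plus the top-ranked
remainder. The classifier is k-nearest-neighbour (k = 3, Euclidean,
1/(d+ε) distance weighting; all three are config keys written into the
output) evaluated by leave-one-out cross-validation. Features are z-scored
with training-fold statistics only, so the left-out patient leaks nothing
into the scaler. Confidence is the winning class's share of the summed
neighbour weights, in (0, 1]; an exact tie falls back to the single nearest
neighbour with confidence 0.5.

## Genomic context

Coordinates are 1-based inclusive internally (miRBase/GFF convention);
BED-style inputs shift +1 on start at load and back on write. Duplexes
(2 genes) and clusters (≥3) are defined by shared (chromosome, cytogenetic
band), strand-agnostic — band organisation, not base-pair distance, is the
unit of co-localization. Susceptibility-locus overlap expands each gene by a
symmetric window (default 250 kb, always reported, since "vicinity" has no
canonical definition) and intersects with the locus intervals. The chance
model places genes uniformly over the genome: window-expanded loci are
unioned per chromosome before measuring (duplicates never double-count),
covered fraction f = union bp / genome bp, expected hits = n·f, and the
enrichment p-value is the binomial tail P(X ≥ observed). A Monte-Carlo mode
re-derives the expectation by random placement as an internal cross-check.
No correction is made for gene density, assay design or linkage structure.

## Target-set logic

The miRNA → gene catalog is consumed as a flat file (PITA-style: the
interaction-energy model behind it is upstream provenance, not recomputed
here; duplicate pairs collapse to the best score). A gene is *strictly
down-regulated* for an over-expressed set U when, restricted to a chosen
miRNA universe, all of its catalogued interactions are with members of U and
at least one exists. The universe defaults to every catalog miRNA; passing
the measured panel instead stops unmeasured miRNAs from vetoing strictness —
both semantics are exposed because published gene counts of this kind are
not reproducible without the exact catalog snapshot. Per-process summaries
are raw counts (a gene counts once per process; unmapped genes tally under
`unannotated`); no enrichment statistics are attached.

## The synthetic cohort generator

The generator emulates the study design the analysis assumes: a 321-miRNA
panel plus U6 row; 10 controls (alternating right/left colon, grades 0–1);
8 UC and 8 CD subjects with paired quiescent (grades 0–1) and inflamed
(grades 2–4) biopsies; U6 CT ≈ N(20, 0.25); per-miRNA baseline ΔCT uniform
on 2–12 cycles, with a 40% detection tail at ΔCT 17.5–21 so those rows sit
beyond CT 35 (matching panels where roughly 170–200 of 321 miRNAs are
expressed in colonic mucosa); CTs above 40 are recorded as no amplification.

**Dispersion model.** The population of measured per-miRNA SDs of log-fold
(n = 8 patients) must land on 6.3 ± 1.4 (10×log10 units). The sample SD of
n = 8 *normal* draws is itself so variable (SD ≈ 0.26·σ ≈ 1.65 at σ = 6.3)
that no between-miRNA distribution can bring the pooled SD-of-SDs down to
1.4 — the target is unreachable under normal noise. Patient noise is
therefore uniform (bounded support, SD of the n = 8 sample SD ≈ 0.19·σ),
which is also a reasonable description of biological variation that does not
produce extreme outliers. Per-miRNA dispersions come from a gamma
distribution whose moments are corrected by the uniform sample-SD constants
(E[S] = 0.9816·σ, SD[S] = 0.1910·σ at n = 8, obtained by moment matching)
so the *measured* pooled statistics, not the latent ones, hit the targets.
The dispersion is assigned to disease patients; controls carry only small
technical noise (1 log-unit SD ≈ 0.33 cycles), because the SD statistic is
defined across disease patients and the controls act as the homogeneous
reference baseline.

**Planted structure.** Effects are ΔCT shifts of −log_fold/(10·log10 2)
cycles for a (miRNA, condition); quiescent effects carry over to the paired
inflamed state (optionally with an extra shift), mirroring the observed
quiescent/inflamed overlap. The default plant is study-scale: 8 miRNAs up in
both diseases, 6 down in UC only, 15 up in CD only, magnitudes 9–18
log-units. The common-up set is a *co-regulated block*: its members share
one planted magnitude and mix a shared patient profile into their noise
(share 0.8 of the variance), because concerted regulation means tracking
together across patients, which is precisely what the co-membership stage
detects. Generators for the genome annotation (planted duplexes, clusters,
loci overlapping known genes) and the target catalog (a known strict-down
gene subset) return their ground truth alongside.

**What passing tests show — and don't.** Calibration and recovery on this
generator demonstrate that the *procedure* behaves as specified under the
study's dispersion, censoring and sample sizes. The generator does not model
plate/batch effects, PCR efficiency differences, cell-type composition
shifts between inflamed and quiescent tissue, correlated detection dropout,
or non-uniform genomic gene density — conclusions about those failure modes
cannot be drawn from these tests.

**Recovery operating characteristics.** The recovery experiment plants
effects of exactly ±10 log-units on clearly expressed miRNAs (baseline ΔCT
2–8; otherwise down-shifts push lowly expressed miRNAs past CT 35 and the
experiment measures the detection filter rather than the caller). Under the
calibrated dispersion the magnitude filter alone caps sensitivity: the SE of
an n = 8 mean at dispersion 6.3 is 2.23, so P(mean > 7 | effect 10) ≈ 0.91,
and with Mann-Whitney power the dual criterion recovers ≈ 0.88 of such
effects, at specificity ≈ 0.998. Effects of ±15 (the middle of the observed
magnitude range) are recovered essentially always. The null false-call rate
is ≈ 0.2–0.3% of (miRNA, condition) pairs — the 5-fold magnitude filter,
not the p-value, carries the stringency.

## Problem sizes and determinism

Default analyses run on the full 321 × 42 cohort in seconds. The replicated
experiments use 50 replicates of a 60-miRNA cohort (recovery) and one
200-miRNA null cohort — sizes at which the Monte-Carlo error of the reported
rates is a few tenths of a percent. Every stochastic component (generators,
k-means restarts, Monte-Carlo placement) takes an explicit seed, and a fixed
config + seed reproduces every artefact byte for byte; seeds are recorded in
the run report.
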