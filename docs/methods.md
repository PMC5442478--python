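# Methods

`chromdyn` analyses two-condition chromatin experiments of the
MNase-seq / nucleosome-resolution ChIP-seq kind: condition A and condition B
are two cell states (e.g. a stem cell population and its differentiated
derivative), and the package quantifies how nucleosome positions, promoter
histone-modification states and TF binding change between them. All
coordinates are 0-based half-open; all strand-relative distances are
oriented so positive means downstream of transcription.

## Nucleosome calling

Single-end reads sequence only the border of mononucleosomal DNA, so each
read is shifted 73 bp interior to its 5′ end to estimate the dyad (the
centre of the 147 bp of wrapped DNA): a `+` read contributes
`start + 73`, a `−` read `(end − 1) − 73`. Dyad counts are smoothed with a
Gaussian kernel,

    s(x) = Σ_d count(d) · exp(−(x − d)² / 2σ²),   σ = 20 bp,

and nucleosomes are called greedily: the highest remaining position
(leftmost on ties) becomes a call and suppresses all positions within
< 147 bp (the exclusion zone), so successive midpoints differ by ≥ 147 bp —
the steric minimum for non-overlapping nucleosomes. A call's supporting
dyads are those within ±73 bp of its midpoint; calls with fewer than 6
supporting reads are dropped, and each call's *fuzziness* is the population
standard deviation of its supporting dyad coordinates (population rather
than sample SD so a single-read call has a well-defined spread of 0).

Two numerical choices matter here. First, the kernel is truncated at the
radius where the Gaussian underflows to exactly 0.0 in double precision
(773 bp at σ = 20) rather than at a small multiple of σ, and contributions
are accumulated in ascending dyad order; the smoothed track is therefore
bit-identical to a literal per-base summation, and the test suite verifies
the production caller against an exhaustive per-base greedy oracle with
exact equality. Second, candidate positions are all bases with `s(x) > 0`;
positions with zero signal could only ever produce zero-support calls,
which the minimum-count filter removes, so this restriction provably does
not change the filtered output.

## Positioning dynamics

Calls from the two conditions are matched by symmetric nearest-neighbour on
midpoints within a chromosome. A pair at identical midpoints is one *fixed*
nucleosome; a call whose nearest partner lies ≥ 107 bp away (or has no
partner) is a *loss* (A-only) or *gain* (B-only); everything else *shifts*.
Exact midpoint equality is fragile when both conditions are independently
resampled — positional jitter of a few bp converts fixed pairs into short
shifts — so `classify_dynamics` exposes `fixed_tol` (default 0, i.e. the
strict rule). Labels partition the union of both call sets: the label count
equals |A| + |B| − (number of fixed pairs).

## TSS profiles and NDR detection

The composite profile extends each read to the 147-bp nucleosome footprint,
takes the midpoint of the extension (equivalent to the 73-bp dyad shift),
accumulates counts by strand-oriented distance to every TSS within ±2 kb,
normalises per million mapped reads, bins at 10 bp and smooths with a 5-bin
moving average whose window shrinks at the edges (padding would fabricate
signal at ±2 kb). Before smoothing, the binned profile conserves read
counts exactly; the tests assert this.

The NDR (nucleosome depletion region) metric is the RPKM-normalised dyad
count in the strand-oriented window −150..+50 bp of the TSS (200 bp,
half-open). *NDR formation* selects genes whose window is occupied in
condition A (occupancy ≥ `occ_high`) and depleted in B (≤ `occ_low`). The
thresholds are explicit because no principled universal values exist: a
percentile helper (60th of A, 20th of B) is provided for exploratory use,
but it degenerates when a majority of promoters have near-zero window
occupancy — the normal situation for well-formed NDRs. Recovery
experiments against planted truth therefore threshold at half the planted
occupancy amplitude for presence and a quarter for absence, which is how
the acceptance checks are run. The NDR–expression link is summarised with
Spearman rank correlation (robust to the highly skewed occupancy
distribution).

## Promoter chromatin states

A mark (H3K4me3, H3K9ac, H3K27me3) is *present* at a promoter
(TSS ± 500 bp) when at least one retained nucleosome call for that mark has
its midpoint inside the window; retained means the call's read count,
expressed as RPKM over its 147-bp footprint against the mark sample's total
mapped reads, exceeds 1. The promoter's class is the subset of present
marks — eight classes from the three single marks, three pairs (including
the bivalent H3K4me3/H3K27me3), the triple, and none. Transitions between
conditions are tabulated as an 8×8 count matrix whose margins equal the
per-condition class counts. The midpoint rule (rather than footprint
overlap) matches the rule used for genomic-class assignment of nucleosome
calls, so the two analyses cannot disagree about what lies "in" a promoter.

## HMI, ROC and differential enrichment

Per-gene promoter occupancy fold changes use a pseudocount of 0.5 RPKM so
zero occupancies stay finite (two zeros give a fold change of exactly 1).
The Histone Modification Index is

    HMI = log2(fc H3K9ac, B/A) − log2(fc H3K27me3, B/A),

antisymmetric under swapping conditions; genes are stratified at
HMI ≤ −1 / ≥ +1 and each extreme stratum is compared with the middle by a
two-sided Mann–Whitney rank-sum test on log2 expression changes (the
rank-sum test makes no distributional assumption about expression noise).
Under a simulation with zero chromatin–expression coupling the test's
rejection rate at α = 0.05 is calibrated, which the acceptance suite checks
over 200 seeds.

ROC curves sweep every distinct score value as a threshold (ties collapse
to one point), with TPR/FPR accumulated from the sorted scores and AUC by
the trapezoid rule; the implementation is cross-checked in tests against
scikit-learn's AUC and against the binormal closed form Φ(Δ/√2).

Differential enrichment is a deliberately simple scan: fixed-width sliding
windows (1000 bp every 100 bp for broad histone marks; 250 bp every 50 bp
for TF data, matching the ~250-bp sheared-fragment size) scored by the
exact Poisson upper tail of the treatment count under
`λ = max(genome-wide treatment rate, control count × depth ratio)`, with
windows below the p cutoff (1e-5 for marks, 1e-4 for TF) merged when gapped
by ≤ one step. No multiple-testing correction is applied by default —
the raw-p design is intentional and matches standard peak-calling practice
at these cutoffs. This is *not* a re-implementation of any specific peak
caller's internals; what matters downstream is the differential design
(which condition is treatment) and the thresholds. TF peaks additionally
require fold enrichment ≥ 10 (inclusive) over λ.

Chromatin remodeling regions (CRRs) are the merged union of
H3K9ac-gain regions (B as treatment) and H3K27me3-loss regions (A as
treatment), each first filtered to > 1 RPKM occupancy of its own mark in
its treatment sample. Region–compartment enrichment assigns each region by
midpoint to promoter / genic / intergenic (promoter wins on overlap) and
normalises counts by compartment length.

## Synthetic data

The generator is the package's test-bed and defines its study conditions.
Defaults: 400 genes on alternating strands at a 6-kb pitch (800 genes /
~5 Mb with ~10⁶ reads for end-to-end runs), gene length 2 kb, phased
nucleosome arrays at 180-bp spacing with upstream dyads at −590/−410/−230
and the +1 nucleosome at +130 relative to the TSS, an NDR spanning
−150..+50, per-nucleosome positional jitter of SD 10 bp, mean coverage 30
reads per nucleosome (20 for the larger end-to-end genome), and a uniform
background of 0.002 reads/bp. 20% of genes carry a nucleosome at the NDR
(dyad at −50) in condition A that is absent in B; 5% of intergenic
nucleosomes reposition by 30 bp in B (30 bp keeps arrays ≥ 147 bp apart, so
the planted truth never violates the steric exclusion the caller enforces).
Reads are emitted so the 73-bp interior shift recovers the jittered dyad
exactly: 49-bp single-end reads, `+` starting at dyad − 73 or `−` ending at
dyad + 74. Histone-mark reads are emitted at promoter nucleosome dyads of
genes carrying the mark (presence probability 0.4–0.6 per mark in A, with
10–20% gain/loss turnover into B, H3K9ac biased toward gain and H3K27me3
toward loss, as expected on differentiation); TF and input reads follow a
250-bp sheared-fragment model around planted sites (60 A-specific, 40
B-specific, 10 common at 50 reads/site). Expression couples to the truth:
log2 expression = baseline N(5, 1.5), −1.5 per occupied NDR, +2 per net
activating promoter mark (H3K9ac positive, H3K27me3 negative), plus
N(0, 0.7²/2) noise per condition; genes with |log2 fold change| ≥ 1 are
labelled up/down. Each sample draws from an RNG stream keyed by
(master seed, CRC32 of sample name), so outputs are reproducible and adding
a sample never perturbs the others.

What the generator does **not** emulate: sequence-level effects
(mappability, GC and MNase digestion bias), PCR duplicates, fragment-length
heterogeneity for nucleosomal reads, chromatin-state heterogeneity within a
cell population beyond Gaussian positional jitter, distance decay of
mark–expression coupling, and replicate structure. Passing tests therefore
demonstrate that the algorithms recover planted structure under controlled
noise, not that they are robust to every artefact of real libraries.

A lighter occupancy-level generator (`simulate_hmi_experiment`) draws
promoter occupancies directly from state-dependent lognormals
(30 RPKM marked vs 1 RPKM background, lognormal σ = 0.4) without read
emission; it backs the HMI calibration experiments, where 200 independent
datasets are needed.

## Known limitations

- The enrichment scan's region boundaries are window-quantised (±1 window);
  length distributions are accordingly coarse.
- With strict midpoint equality, independently resampled conditions label
  most unchanged nucleosomes as small shifts rather than fixed; `fixed_tol`
  exists for that reason but defaults to the strict rule.
- The percentile NDR-threshold helper is unreliable when most promoters
  have empty NDRs (see above); thresholds should be set from the data's
  occupancy scale.
- `eviction_overlap`'s TSS-proximity statistic uses a configurable ±2 kb
  flank; no attempt is made to deconvolve promoter-proximal from genic
  eviction.
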