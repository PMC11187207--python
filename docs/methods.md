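# Methods

This note records the models, the defaults and the numerical choices
behind `embryort`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Copy-ratio model and QC

Shallow single-cell WGS of an S-phase cell yields binned counts whose
expectation is proportional to local copy state: replicated bins carry
twice the unreplicated signal. All inference runs on the depth- and
reference-normalised copy ratio

    x_cb = (n_cb / Σ_b n_cb) / (r_b / Σ_b r_b),

where the reference profile `r` is the per-bin mean over an external
cohort of non-replicating (G1) cells after per-cell depth
normalisation (a per-bin median is available as an option). Using a
*non-replicating* reference is essential: a reference built from the
assay cohort itself absorbs the replication program (early bins are
over-represented in the cohort mean) and flattens the very signal
being measured.

**GC/amplification correction.** The residual GC trend is estimated
once from the reference cohort's own ratio profiles — a local-median
regression in which usable bins are split into `round(1/span)`
GC-quantile strata (default span 0.25 → 4 strata) and the trend is the
stratum median — and this fixed trend is divided out of every assay
cell. Two deliberate choices here:

* *Trend from the reference, not per cell.* A stratum median of a
  bimodal S-phase profile snaps unstably to one of the two copy modes,
  so a per-cell fit scrambles the 1x/2x separation. Per-cell
  correction (`gc_correct`) remains available and is appropriate for
  flat (G1-like) profiles.
* *Stratified medians, not a smoother.* The piecewise-constant median
  trend is exactly idempotent — correcting corrected data returns it
  unchanged — which no local smoother guarantees, and it is robust to
  the heavy right tail of amplified counts. The span parameter trades
  smoothness against flexibility; strong, nearly noise-free trends
  warrant a finer span (e.g. 0.05).

**MAD score and phase.** Cell quality and phase use the raw median
absolute deviation of `x` from its median, without the 1.4826
consistency factor: flat G1 profiles sit at the counting-noise floor,
bimodal mid-S profiles score higher. The conventional cutoffs (G1
below 0.3; S within 0.4–0.8; otherwise excluded) are kept as the
literal defaults of `classify_phase`, but the MAD scale depends on
depth, bin size and amplification noise, so the recommended path
calibrates the G1/S cut from the reference cohort itself: the Tukey
far-out fence (Q3 + 3·IQR) of the reference cells' MADs. Any assay
cell more variable than non-replicating cells ever are is called S.
Cells at the very start or end of S phase are nearly flat and
unavoidably classified G1 by any MAD rule; they drop out of RT
aggregation by design, and this is the main caveat for downstream
copy-number calling (below).

## Replication-timing inference

**Binarisation.** Each informative S cell is split into
replicated/unreplicated bins. The default method fits the log ratios
with a two-component Gaussian mixture whose component means are
constrained exactly log 2 apart — the known 1x/2x structure — with a
shared variance (counting noise is multiplicative). Three parameters
(location, sigma, weight) are fitted by EM from a small set of
deterministic starts: one seeded by the exact 1-D 2-means split of the
ratios, plus the two label assignments of a single dominant cluster.
The highest-likelihood fit wins; ties keep the earliest start. Bins
are called by posterior, which places the decision boundary closer to
the minority component for cells early or late in S phase — the
regime where a midpoint rule mis-splits the dominant cluster.

The classic scale-free alternative (`method="sse"`): exact 1-D 2-means
by prefix-sum search (always the global SSE optimum, equal to
exhaustive threshold enumeration) with the threshold at the midpoint
of the two centers. It is retained both as a cross-check and because
its behaviour is assumption-free.

A cell whose two 2-means centers are separated by less than `min_sep`
(default 0.3 ratio units) carries no usable replication contrast and
is dropped as non-informative rather than forced to 0 %/100 %.
Binarisation requires at least 100 usable bins.

**Aggregation.** The replication percentage of a bin is the fraction
of informative S cells with a replicated call, over cells with a
non-missing state at that bin. Early regions are > 50 % replicated,
late regions < 50 %; a bin at exactly 50 % is a third, `boundary`,
class excluded from comparisons (both defining inequalities are
strict). The tie is decided on integer counts (2k vs n), not floats.
Cells are displayed in ascending order of percent genome replicated,
ties broken by cell id.

## Copy-number segmentation and break sites

Per chromosome, the changepoint set minimises

    Σ_segments SSE + λ · log(n_bins) · σ̂² · (#changepoints)

over all partitions with segments of at least `min_seg_bins` (default
5) bins, found exactly by dynamic programming over the last
changepoint. The search runs on log ratios (variance-stabilising: a
doubled segment is not penalised as noisier), with σ̂² estimated
robustly from the median absolute successive difference
(σ̂ = MAD(diff)/0.6745/√2), per chromosome, so a few true changepoints
do not inflate it. The default λ = 3 is a BIC-like factor: the largest
spurious single-split gain in pure noise grows like 2·σ²·log n, so
λ = 3 sits above it with margin while a one-copy event of 20 bins
(gain ≈ 20·(log 2)²/4 per unit σ²) clears it easily. An exact DP
(rather than greedy recursive bisection) matters: a single binary
split cannot isolate a short interior event whose two flanks average
out, no matter the penalty. `max_changepoints` restricts the search
space exactly, which is used by the enumeration cross-checks.

Copy number is called by scaling segment means so the length-weighted
median equals the baseline (default 2); `cn_integer` rounds half up. A
break site is annotated at the shared boundary of adjacent
same-chromosome segments when the *continuous* copy numbers differ by
strictly more than 1 — rounding first would hide e.g. a 1.4-copy
change, and a change of exactly one copy never qualifies. The reported
position is the genomic start of the right segment; chromosome ends
never emit. Karyotypes call a chromosome gain/loss when ≥ 80 % of its
segmented length is above/below baseline, segmental when it carries
any break site, else euploid.

Copy-number calling is meaningful only for non-replicating cells: an
S-phase cell's replication intermediates are genuine 2x segments and
would be annotated as gains. The pipeline therefore segments
G1-classified cells only; residual S cells misclassified into that set
(the near-flat S-phase entry/exit cells) are the dominant source of
spurious break sites, and their calls concentrate at replication-front
boundaries. On synthetic cohorts, true G1 cells yield no spurious
sites at default settings; break-site catalogues from mixed cohorts
should be treated as candidates pending orthogonal phase evidence.

## Enrichment statistics

Random-region nulls are matched in count and length to the query set
and sampled uniformly over all positions where the interval fits
entirely within one maximal unmasked stretch (stretches weighted by
their number of valid starts — exactly uniform over valid positions,
no rejection loop). Lamina association uses any-bp overlap by default
(a minimum-overlap-fraction option exists); the OE denominator is the
LAD coverage fraction of the unmasked genome, so point sites sampled
uniformly give OE ≈ 1 and finite-length sites acquire a small positive
edge bias of order (#LAD intervals · site length / genome). A
Monte-Carlo expectation (mean over sampled null sets) is available
where the analytic denominator is not wanted. Compartment labels
follow the eigenvector sign (positive A, negative B, zero or missing
unassigned).

Mann-Whitney U delegates to scipy: the exact permutation distribution
when both groups have ≤ 8 observations and the pooled values are
untied, otherwise the normal approximation with tie and continuity
corrections. One-way ANOVA is computed from the classical sums of
squares with an explicit degenerate-input error when both within- and
between-group variance vanish. No multiple-testing correction is
applied across feature panels; p-values are per comparison.

## DNA-fiber arithmetic

Lengths in µm convert to kb at 2.59 kb/µm (the standard stretching
factor). Fork speed is track length / pulse duration (default 30 min)
per single-label track; dual-label averaging is an option. Origins
enter as midpoints of divergent sister-fork pairs; inter-origin
distances are adjacent differences along each fiber, pooled across
fibers (per-group pooling is the default; fibers with fewer than two
origins contribute nothing). Group comparisons reuse the rank/ANOVA
machinery above.

## The synthetic-data generator

`make_rt_truth` draws a per-chromosome Gaussian random field, smooths
it (`correlation_length_bins`, default 20 bins = 2 Mb), and maps it
through its empirical CDF to the scheduled replication time t ∈ [0,1].
Coupled tracks: LADs by thresholding a second smooth field tilted by
κ·(t−0.5) (contiguous Mb-scale domains, probability of lamina
association increasing with t); a compartment eigenvector −κ·(t−0.5)
plus smooth noise; origins and genes as inhomogeneous point processes
with intensity ∝ exp(−κ·t); gene lengths log-normal (median 30 kb)
with a heavy tail supplying the occasional > 500 kb gene. κ (default
2) sets how strongly late replication is lamina-associated, B-compartment
and origin/gene-poor; κ = 0 decouples everything.

`simulate_cells`: an S cell at S-phase fraction f ~ U(0.05, 0.95)
replicates bin b iff t_b ≤ f; states flip independently with
probability `flip_rate` (default 0). Expected counts are
(1+state) · exp(N(0, amp_noise_sd)) · exp(gc_coeff·(gc−mean gc)),
rescaled to `mean_reads_per_cell` (default 10⁶ over 2,000 bins,
i.e. ≈ 500 reads per 100 kb bin), and drawn negative-binomially with
variance μ + μ²/dispersion (default dispersion 10, ≈ 32 % CV per bin —
heavy WGA-scale noise; ∞ recovers Poisson). Defaults: amplification
noise sd 0.1, GC coefficient 0.3. Copy-number events multiply counts
by (baseline+Δ)/baseline with stochastic re-rounding so expectations
are exact.

What the generator does *not* emulate: mappability and
sequence-context bias beyond a smooth GC field, per-cell GC response
differences, chimeric/duplicate reads, allelic (maternal/paternal)
structure, replication-fork spatial dynamics, and cell-cycle structure
beyond the single S fraction. Passing tests therefore demonstrate the
estimators' correctness and their noise behaviour under a realistic
counting model — not robustness to every artefact of real libraries.

**Intrinsic accuracy limit.** At dispersion 10 and 500 reads/bin the
per-bin CV is ≈ 0.32 against a 2x contrast; the best achievable
per-bin, per-cell threshold classification (oracle threshold chosen
with knowledge of the truth) reaches ≈ 0.88 mean accuracy on this
data, and the constrained-mixture binarisation reaches ≈ 0.85–0.87.
Per-bin accuracy well above that would require spatial smoothing of
states, which is deliberately out of scope; the cohort-level profile
is far more accurate than any single cell (aggregate-vs-truth
correlation ≈ 0.97 with 150 cells) because per-bin errors average out.

## Numerical and design details

* Coordinates are 0-based half-open throughout; 1-based inputs are
  converted at the boundary. Chromosome names match exactly; an alias
  table handles naming dialects.
* The short terminal bin of each chromosome is masked by default
  (unequal exposure); masked bins propagate as missing through
  normalisation, binarisation (neither numerator nor denominator) and
  segmentation (excluded from segments).
* Interval-to-bin counting assigns an interval to the bin containing
  its midpoint, preventing double counting of features spanning a bin
  edge; coverage and score modes use exact overlap lengths.
* bedGraph output is written at 6 significant digits and round-trips
  through the reader to that precision; all writers emit sorted,
  tab-separated, newline-terminated records, making pipeline reruns
  byte-identical under a fixed seed.
* 2-means (1-D) is computed exactly via sorted prefix sums — no
  iterative clustering, no initialisation sensitivity.
* The EM binariser floors sigma at 10⁻³ and clips weights to
  [10⁻³, 1−10⁻³]; the boundary formula m + log2/2 + (σ²/log2)·ln(w/(1−w))
  is the equal-posterior point for equal variances.
* Weighted medians (copy-number scaling) take the lower value at an
  even split; integer copy number rounds half up (floor(x+0.5)).
* Random sampling uses `numpy.random.default_rng` with explicit seeds
  everywhere; identical configs reproduce identical outputs bit for
  bit.

## Problem sizes used in the bundled analyses

The packaged tests and the acceptance script run on the desk-scale
genome (2 chromosomes × 100 Mb at 100 kb bins = 2,000 bins) with
cohorts of 30 G1 + 150 S cells (RT recovery), 50 cells with one
injected segmental event each (break-rule fidelity), 100 random 60-bin
profiles (segmentation oracle), 1,000 random site sets (OE
calibration) and 10,000 null draws (rank-test calibration). These
sizes give stable estimates for every reported quantity while keeping
a full run under a minute on one CPU; the estimators themselves are
linear or n log n in bins and cells and scale to full genomes
unchanged.

## Known limitations

* Phase classification by MAD cannot see the first and last few
  percent of S phase; those cells contaminate the G1 pool and, through
  it, break-site catalogues (see above). A replication-aware phase
  classifier is the natural extension.
* The ΔCN > 1 rule on continuous copy number inherits segment-mean
  noise: near-threshold events (|Δ| ≈ 1) are called stochastically.
  The rule is exact only given exact segments.
* The OE statistic's any-overlap definition is length-sensitive;
  compare like-for-like site lengths or use the Monte-Carlo
  expectation.
* Haplotype-resolved RT, HMM state smoothing, sub-bin breakpoint
  refinement and micronucleus-specific handling are out of scope.
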