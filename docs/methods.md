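# Methods

This note documents the models implemented in `hicks`, the parameters that
matter with their defaults, the synthetic-data generators the package is
validated against, and the numerical and design choices made where the
methods literature leaves the details open. Every empirical number quoted
here is computed by the test suite or by `scripts/acceptance.py`.

## Coordinates and binning

All internal coordinates are 0-based, half-open `[start, end)`; 4DN `.pairs`
positions (1-based on disk) are converted on read. Chromosome order is
always the order of the chrom.sizes file, never lexicographic, so matrix
layouts match the input genome. Bins are fixed-width, non-overlapping, the
last bin of each chromosome possibly short; global bin indices are
contiguous in chromosome order.

## Contact matrices and iterative correction

Matrices are dense, symmetric, non-negative, with a per-bin validity mask;
masked rows/columns are zero. This targets desk-scale genomes (up to a few
thousand bins); the COO text interchange format keeps files small and
diffable.

**Low-coverage masking.** Bins with zero marginal are always masked;
additionally the lowest `fraction` (default 0.02) of nonzero marginals are
masked before balancing. The quantile is a conventional choice — only "bins
with no valid interaction data" is dictated by the biology — and is exposed
as a parameter.

**ICE balancing.** Iterative correction repeatedly divides the working
matrix by its normalised marginals until the variance of the unmasked
marginals over their squared mean falls below `tol` (default 1e-8, maximum
200 iterations; an unconverged run is flagged and warned, not failed). The
returned bias vector satisfies `balanced = raw / outer(bias, bias)` exactly
and is normalised to geometric mean 1 over unmasked bins, so the balanced
matrix keeps the raw matrix's overall scale; equal row sums are the fixed
point. The variance tolerance maps to a relative row-sum spread of roughly
its square root, so runs that need row sums equal to 1e-6 relative should
pass `tol=1e-14` (convergence is fast on desk-scale matrices; the
self-calibration experiments use `max_iter=5000, tol=1e-14` and measure
worst-case spreads below 1e-7).

A caveat quantified during development: on a distance-banded expectation the
maximum-visibility interpretation of ICE folds deterministic chromosome-edge
effects into the bias estimate, so planted-bias recovery is asserted on a
flat-decay simulation where the planted bias is the only row-wise factor
(r > 0.99 there; r ≈ 0.98 with decay plus edge effects, which is a property
of the estimand, not an implementation error).

**Map resolution.** The smallest candidate bin size at which at least 80%
of bins collect ≥ 1000 contacts (both thresholds parameters). Fully empty
bins count in the denominator by default (`include_empty_bins=False` to
exclude them); the choice is documented because the rule's standard
formulation does not state it.

## Distance decay and the IDE

The decay curve averages balanced cis values over all unmasked pairs at each
separation, pooling chromosomes (per-chromosome curves on request); the
diagonal is excluded throughout, since self-ligation artifacts dominate
intra-bin counts. The IDE is the OLS slope of log₁₀ frequency on log₁₀
distance inside a fit range, default [2 bins, 10 Mb]: the lower cutoff
avoids the diagonal's shadow, the upper avoids sparse long-range strata. At
least 3 positive-frequency points are required.

**Z-score and subtractive matrices.** Each cis diagonal stratum is
standardised per chromosome (Crane-style); pooling chromosomes would
conflate different chromosome lengths. A numerically constant stratum
(spread below 1e-10 relative) counts as zero-variance and maps to z = 0 —
without this guard, floating-point jitter of order machine epsilon turns
constant strata into spurious ±1 z-scores. Trans entries are standardised
as a single stratum. The subtractive matrix z₁ − z₂ is antisymmetric under
sample swap by construction.

## A/B compartments

Per chromosome: the balanced cis block is divided by its per-separation mean
(O/E), the Pearson correlation matrix of the O/E rows is formed over
unmasked bins, and its leading eigenvector is extracted. PC1's sign is
arbitrary, so it is oriented per chromosome to correlate positively with an
activity track — gene density by default, GC content as a fallback —
making positive PC1 the gene-dense A compartment. Calls are per whole
chromosome; a per-arm mode would need centromere coordinates, which the
package does not ship (an optional centromere BED can be supplied upstream
by splitting chromosomes). Chromosomes with fewer than 10 unmasked bins, or
a zero-variance correlation matrix, come back all-NA (an error when the
chromosome was requested explicitly). Calls where PC1 explains < 5% of
variance are warning-flagged: on sparse toys the leading eigenvector can be
meaningless. Differential compartments are exactly the bins with non-NA,
unequal labels in the two conditions, with A→B / B→A direction counts.

## TADs and insulation

The insulation score of bin *i* is log₂ of the mean contact in the square
`(i−s…i−1) × (i+1…i+s)` over the chromosome-wide mean of that statistic, so
uniform matrices score 0 and global rescaling cancels. The square is 10 bins
(400 kb at the conventional 40-kb TAD bin size) by default — the canonical
choice of the insulation-score method, exposed as a flag since published
analyses rarely state it. Bins within one square of a chromosome edge are
masked; chromosomes shorter than 2s+1 bins are fully masked with a warning.

Boundaries are local minima whose strength — the lower of the two flanking
maxima within `delta_window` (3) bins minus the minimum — reaches
`min_strength` (0.1 log₂ units); domains are the intervals between
consecutive boundaries and the chromosome ends. These two thresholds are the
insulation method's conventions; because they are not dictated by the
biology, absolute TAD counts on real data are parameter-dependent and are
not treated as reproducible targets.

**Differential insulation** slides an 11-bin window by 1 bin and computes
the Pearson r between the two tracks per window; a bin is differential only
if *every* window covering it has r < 0.6, and maximal runs are reported
with their minimum window r. A window in which either track is constant is
assigned r = 1 ("not different"): constant equal insulation is agreement,
and the rule prevents spurious edge regions. The construction makes the
operation symmetric in its two inputs.

## Significant interactions

The cis expected model stratifies in-range (20 kb ≤ d ≤ 2 Mb) bin pairs
into 200 distance strata of near-equal total contact occupancy, estimates a
per-pair contact probability per stratum, smooths across strata by isotonic
(monotone non-increasing) regression — parameter-free and verifiable by
brute force, unlike a spline — and renormalises so the prior sums to 1 over
all tested pairs. Pass 2 removes pairs called significant by pass 1 and
refits, so strong point interactions do not inflate their own expectation;
probabilities for a distance class emptied by removal are interpolated from
neighbours. P values are binomial upper tails `P(X ≥ k)` with the total
in-range contact count as the number of trials; q values are
Benjamini–Hochberg over all tested pairs; a call is significant iff
P < 0.01 ∧ q < 0.01 ∧ count ≥ 3 ("more than 2" read as integers). Raw,
unbalanced counts are tested — the counting model is defined on counts —
and bias-aware testing is out of scope. Trans pairs get a uniform prior
(1 / number of possible unmasked trans pairs), the distance-free convention
for inter-chromosomal tests. Self-consistency: on counts drawn from the
fitted model itself the measured q < 0.01 call rate is ~0 (≤ 0.02 over 10
seeds), and a pair boosted 20× over expectation is called in 10/10 seeds.

**Homoeolog fractions.** For chromosome c with duplication partner h, the
fraction is (trans contacts between c and h) / (all trans contacts of c),
reported per chromosome with the min–max range. Chromosomes absent from the
pairing are excluded with a warning.

## FIREs

A bin's local sum pools its balanced cis contacts to partners 15–200 kb away
(the lower edge excludes self and adjacent bins); sums are z-scored across
all unmasked bins genome-wide and assigned one-sided normal P values
(significant at P < 0.05). Bins whose band is truncated by a chromosome end
keep their partial sums and are flagged. Scores are computed in
single-sample mode, without cross-replicate quantile normalisation, since
replicates are pooled before analysis in the intended workflow. Enrichment
against compartments (A membership) and TAD boundaries (within
`boundary_slack` coarse bins) uses two-sided Fisher exact tests on 2×2
tables; coarser grids are mapped onto the FIRE grid, requiring divisible bin
sizes.

## NG-model Ks and WGD dating

Site counting follows the yn00 NG convention: at each codon position the
synonymous site fraction is the share of synonymous changes among the
single-nucleotide changes that do not create a stop codon, so every codon
contributes exactly 3 sites split between S and N; per-pair sites average
the two sequences. Codons differing at k positions are resolved by
averaging synonymous/nonsynonymous step counts over all k! minimal
substitution pathways, excluding pathways through intermediate stop codons;
in the rare case that every pathway is blocked, all pathways are averaged
with stop transitions counted as nonsynonymous. Proportions pS = Sd/S and
pN = Nd/N are corrected with Jukes–Cantor K = −¾ ln(1 − 4p/3), which
saturates at p ≥ ¾ (a SaturationError naming the proportion). The
implementation agrees exactly with an independent pathway-enumeration oracle
on all 61 × 61 sense-codon pairs. Alignments are cleaned pairwise: codon
columns containing gaps or ambiguous bases are dropped from both sequences
and counted; internal stops are rejected.

Ks distributions use a Gaussian KDE (Silverman bandwidth by default) over
values in (0, 3); peaks are local density maxima above 10% of the global
maximum — duplication-event peaks are broad, and the floor suppresses
ripple. Ages follow T = Ks / (2r) with r = 8×10⁻⁹ synonymous substitutions
per site per year by default; Ks = 0.08 dates to 5.0 Myr, Ks = 0.256 to
16 Myr.

## Transcript–metabolite networks

Edges connect gene–metabolite pairs whose Pearson r passes the threshold:
|r| > 0.8 by default (`mode="absolute"`), because anti-correlations are
biologically informative; `mode="signed"` honours the literal r > 0.8
reading. Constant features yield no edges and are counted. At least 3
samples are required — with only two pooled conditions a per-gene Pearson
correlation is degenerate, so the module refuses rather than fabricate. The
candidate gate keeps genes with r² > 0.96 against at least one focus
metabolite (or all of them with `require_all=True`).

## Synthetic data

The generators define the conditions every recovery experiment runs under.
The cis expectation for bins i, j at separation d (bins) is

    E[c_ij] ∝ b_i b_j f(d) (1 + δ s_i s_j) τ_ij

with f(d) = d^α off the diagonal and f(0) = 1, s the ±1 compartment state,
δ the checkerboard contrast, and τ_ij = τ for same-TAD-block pairs.
Expectations are normalised to the requested depth and sampled cell-wise
Poisson; records get uniform positions within bins. Trans expectations are
uniform × bias × a homoeolog boost. Default α = −0.9 sits between typical
measured plant genome-wide IDEs. The off-diagonal kernel is an exact power
law — rather than the softened (1+d)^α form — so the planted exponent is
identifiable by the standard log-log fit; the d = 0 singularity the softened
kernel avoids never enters because the diagonal is excluded from decay
fitting everywhere in the package. Noise is Poisson, not negative binomial,
keeping closed-form oracles (stratum means, standard errors) exact.

Two-condition simulation shares condition 1's expectations and differs only
by planted changes: compartment-state flips, TAD boundary additions/
removals, and sparse strong rewiring inside perturbed blocks — each in-block
cis pair is, with probability 0.1, boosted ×5 or suppressed ÷5. Sparse and
strong is deliberate: per-separation z-scoring standardises each stratum, so
a dense or stratum-wide change inflates the stratum spread and hides itself,
whereas a few strongly rewired pairs stand out as genuine outliers — the
biological analogue is gain/loss of specific strong contacts. Condition 1's
stream depends only on the base seed and is bitwise isolated from
condition-2 parameters.

Codon-pair simulation mutates third positions of four-fold-degenerate
family-box codons (GGx, GCx, CCx, ACx, GTx) whose first two positions admit
no synonymous change, so every difference is synonymous, S equals the codon
count exactly, and the expected pS equals the per-site mutation probability.
Omics simulation generates planted genes as ρ × metabolite profile +
√(1−ρ²) × Gaussian noise, giving population correlation ρ.

**What the generators do not emulate** — and hence what passing recovery
tests do not show about real data: restriction-fragment geometry and
ligation artifacts (inputs are assumed pre-filtered valid pairs),
overdispersed counts, mappability/GC bias beyond a multiplicative per-bin
factor, centromere/telomere contact enrichment, nested or hierarchical TADs,
more than two compartment states, and batch structure in omics tables.
Recovery numbers quantify correctness of the estimators under their stated
noise model, not field performance.

## Self-calibration conditions

`hicks.evaluate` fixes the simulation sizes used by the acceptance
experiments, chosen to exercise each estimator well inside a one-CPU desk
budget: 50 random 200-bin matrices for balancing; a 20-Mb toy genome at
40-kb bins with 5×10⁵ cis contacts and 10 seeds for IDE recovery (planted
α = −0.85, mean |error| ≈ 0.002); two 10-Mb chromosomes at 100-kb bins,
δ = 0.3, for compartment accuracy and 6-bin flip recall; an 8-Mb chromosome
at 40-kb bins, τ = 2, 3×10⁵ contacts for boundary recall/precision; a 70-bin
track with a 30-bin phase-inverted segment for differential insulation; a
2-Mb chromosome at 10-kb bins for null FDR and a 3-Mb one for boosted-pair
power; 200 genes × 12 samples with a planted 20-gene ρ = 0.95 module for
network F1.

## Known limitations

- Dense matrices bound practical genome size to a few thousand bins; larger
  genomes need a sparse backend.
- Compartment calls are single-eigenvector, two-state; sub-compartments and
  histone-mark-based orientation are out of scope.
- The interaction caller tests raw counts with no bias refactoring;
  bias-aware significance is a deliberate non-goal.
- Absolute TAD and FIRE counts depend on thresholds the method literature
  does not fix; only planted-truth recovery, not count reproduction, is
  asserted.
- NG86 is a counting estimator; codon-frequency and transition/transversion
  corrections (ML variants) are not implemented.
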