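# Methods

This note records the models, estimators and numerical choices behind
`smrlink`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem left them open.

## The measurement model

A cell transiting an SMR cantilever produces a transient drop in resonant
frequency proportional to its buoyant mass. `smrlink` models the trace as

    f(t) = baseline + noise − (m(t) / calibration) · 1[cell in channel]

with `calibration` in pg per Hz of peak depth. Peak detection estimates the
baseline as the per-trace median (transits are sparse, so the median sits on
the baseline; detection is therefore invariant to any constant offset), then
takes each contiguous run of samples whose depth below baseline exceeds the
threshold as one transit, with mass = calibration × maximal depth and apex
time at the maximal-depth sample.

**Trajectory matching** is greedy and in-order: a trajectory whose last peak
is at time *t* accepts the earliest unclaimed peak on the next cantilever
inside `t + expected_transit ± tolerance`. When the earliest candidate in a
window is already claimed by another trajectory, two cells are competing for
one slot — both trajectories are flagged `doublet_suspect` and the earlier
claimant keeps the peak (earliest-candidate-wins; deterministic and
auditable). A trajectory with an empty window is flagged `failed_match` and
stops. Flagged trajectories are excluded from every downstream statistic.

**MAR** is the ordinary-least-squares slope of mass (pg) against time
(hours); OLS was chosen over robust alternatives and is stated here
deliberately — no robust fit is silently substituted. Storage stays in
seconds; conversion to hours happens only inside the fit. `final_mass` is
the last peak's mass (the measurement closest to lysis) and growth
efficiency is MAR / final mass. The OLS standard error is reported per
trajectory.

**Linking**: each clean trajectory is matched to the collection-log record
whose release time is nearest its final peak time, within a tolerance
defaulting to half the release spacing (15 s at the standard 30 s cadence —
the largest unambiguous nearest-neighbour window). Wells attracting zero or
two-plus trajectories, and wells missing from the expression matrix, are
excluded with reasons; the simulator and analysis share one clock, and
real-data adapters must document any offset between the detection computer
and the motor log.

## Expression preprocessing

Analyses run on ln(TPM+1). `to_tpm` scales each cell to one million; given
gene lengths it length-normalizes first, otherwise it is CPM-as-TPM, which
is exact for the synthetic generator (whose counts carry no length bias).
Cell QC keeps cells that strictly *exceed* a per-dataset complexity
threshold (4000 detected genes for L1210/FL5.12-like lymphoblasts, 2000 for
CD8+ T cells, 1000 for BT159-like glioblastoma PDCL cells); gene inclusion
keeps genes detected in strictly more than 5% of cells. "Detected" means
value > 0 (the zero pattern is identical across counts/TPM/logTPM layers).
Filters run cells-then-genes — cell QC precedes gene inclusion, mirroring
the order the workflow describes them in — and are idempotent; whether the
original analysis applied the 5% filter before or after cell QC is not
stated anywhere, so the order here is a documented decision, not fact. The
tests pin the one fixture where the order changes the outcome (a gene seen
only by a removed low-complexity cell).

## Correlation ranking and the shuffle null

Gene-wise coefficients are Spearman by default (Pearson available; both are
computed for the ranked output since the two give similar rankings on this
kind of data). The implementation ranks the matrix once (mid-ranks for
ties), standardizes rows to unit norm, and computes all coefficients as one
matrix–vector product; tests verify it against `scipy.stats.spearmanr` and
a hand-rolled rank-then-Pearson oracle.

The null distribution mismatches biophysical and expression data: the
covariate vector is permuted across cells and all gene coefficients are
recomputed, 10,000 iterations by default. Permuting the single covariate
rather than the matrix gives the identical null at a fraction of the cost.
The pooled mean and SD over all gene × iteration coefficients define
significance: |ρ − μ₀| > 2σ₀, direction by sign(ρ − μ₀). Pooling is the
default (the per-gene option exists behind a flag) because the procedure
being reproduced pools the average mean and SD of the coefficient
distributions; for exchangeable cells the per-gene nulls differ only by
Monte-Carlo noise. On pure noise the rule flags ≈ 2Φ(−2) ≈ 4.6% of genes,
and the pooled SD matches the analytic Spearman null SD ≈ 1/√(n−1).
Seeds are mandatory for every stochastic step and are recorded in the
output objects.

**PC–biophysics testing** applies the same machinery with principal
components in place of genes: PCA on the top-k genes by dispersion
(variance/mean; k = 2000 by default), centered and unit-scaled, ten
components by default; each PC's cell coordinates are Spearman-correlated
with the covariate and called by the same two-SD shuffle rule (null pooled
over PCs and iterations). The upstream variable-gene selector of the
original toolchain is not reproduced bit-exactly; no bit-level PCA
equivalence is promised.

## Differential expression and the U test

The Mann-Whitney U engine is written here rather than delegated. For two
groups both of size ≤ 8 it enumerates all C(n, n_a) assignments and counts
|U − μ_U| at least as extreme (two-sided permutation p; with ties this is
done on mid-ranks). Larger groups use a normal approximation refined by an
Edgeworth expansion: the rank sum of group A is a finite-population sample
sum, whose exact second, third and fourth central moments follow from power
sums of the centered mid-ranks and falling-factorial inclusion
probabilities; the skewness and kurtosis terms plus a 0.5 continuity
correction bring the approximation within 0.01 of exact enumeration for
any size pair with at least one group ≥ 5 (at 3v3–4v4 the exact
distribution's atoms exceed 0.05, so no smooth approximation can do better
there — which is why those sizes always take the exact branch).
`wilcoxon_de` applies the same engine per gene, reports the natural-log
fold change as the difference of group means on the ln(TPM+1) scale, and
Bonferroni-corrects over the genes tested. Degenerate all-tied input yields
p = 1.

## Phase scores and preranked enrichment

A panel score is the per-cell mean of the panel genes' z-scores (each gene
centered and scaled across cells); it is invariant to affine rescaling of
any single gene, and zero-variance genes are dropped with a warning. Phase
calls take the larger of the G1/S and G2/M scores when it clears a margin
(default 0); ties and below-margin cells are `unassigned`. The assignment
rule is exposed as configuration because the original procedure does not
state one. Call accuracy is assessed over assigned cells — an abstention is
not an error — consistent with downstream comparisons that condition on a
phase having been called. Panels ship as editable GMT inputs, not
hardcoded truth; the bundled synthetic panels name the construct (G1/S,
G2/M, the 29-gene-scale mitosis panel), and real analyses should supply
published cell-cycle gene lists.

Preranked enrichment implements the weighted Kolmogorov–Smirnov running
sum: over the descending-ranked list, hits advance the sum by |score|^p
(normalized over hits; p = 1 default, p = 0 gives the exactly-analyzable
unweighted case) and misses retreat by 1/(N − N_h); the ES is the deviation
of maximal magnitude (positive extremum wins a numerical tie, tolerance
1e-12). The implementation evaluates only the hit positions (extrema occur
at hits); a dense full-list walk serves as the test oracle. Null sets are
gene-label permutations — random same-size draws from the ranked universe —
cached per set size. NES divides ES by the mean |permuted ES| of matching
sign; the permutation p is the sign-matched tail fraction with add-one
smoothing (conservative: P(p ≤ α) ≤ α + 1/n_perm); FDR q compares each NES
to the pooled sign-matched permutation NES distribution, in the preranked
convention. A set equal to the whole universe (or intersecting it in fewer
than two genes) is degenerate and skipped with a warning. Reversing the
ranked list negates the ES exactly for any p.

## The synthetic-data generator

The generator defines the study conditions for all property tests.

**Population.** Phase positions are uniform on [0, 1); birth mass is
log-normal (mean 40 pg, CV 12%, the scale of murine lymphoblasts) and mass
is birth mass × 2^phase (exponential doubling). MAR follows the linear
mass–growth coupling observed in proliferating lymphoblasts:
MAR = 0.05 h⁻¹ × mass + N(0, 0.6 pg/h), planting a mass–MAR Spearman
≈ 0.75 at the defaults — the same regime as the ρ ≈ 0.56–0.67 measured in
real lymphoblast lines. Cells enter the array every 30 s (the device's
release cadence), 200 cells per run by default.

**Device.** Ten cantilevers; serpentine transit times are truncated normal,
20 ± 0.5 s per gap. The jitter is a small fraction of the transit time
because the fluidics hold cells at fixed spacing; larger jitter would let
independent neighbours drift into each other's matching windows over ten
sensors, which the real device's spacing control prevents. Each transit is
a rectangular dip of 0.5 s whose depth tracks the cell's instantaneous mass
sample by sample; optional white noise is parameterized in pg-equivalents.
With probability `doublet_rate` (2% default) a cell co-releases with its
successor: the pair shares transit-delay draws 2 s apart (they travel
together), occupies one collection well, and produces a single log record
flagged `co_release` — giving the matcher's competition rule and the
linker's multiplet exclusion real work, with labelled ground truth.
Intermediate peaks can be lost at `peak_loss_rate` (0 by default so the
count-conservation invariant is exact).

**Expression.** 1000 genes; panels of 43 (G1/S), 54 (G2/M) and 29
(mitosis) genes — the scale of published phase panels and of the 29-gene
mitosis panel used for mass-correlated scoring. Gene base rates are
log-normal; panel genes draw from a higher-located distribution because
cycle-regulated programs are moderately-to-highly expressed. Log-rates are
modulated linearly in phase (negatively for G1/S, positively for G2/M;
quadratically rising for mitosis, which peaks just before division) with
amplitude `phase_effect = 2.0` — about 7-fold over the cycle, the strong
end of the 2–10× dynamic range of cyclins and histones, chosen so that the
planted program is recoverable through the full pipeline at the default
sample size, which is the regime the downstream recovery guarantees are
stated for. Counts are gamma-Poisson (dispersion 0.3) around
library-size-scaled proportions (library sizes log-normal, location
ln 5×10⁴, scale 0.3), thinned by uniform Bernoulli dropout (rate 0.2),
emulating transcript capture inefficiency. Per-gene ground truth (panel
membership and expected correlation sign) is returned alongside.

**What the generator does not emulate** — and what passing tests therefore
do not show about real data: realistic cantilever noise spectra and
pressure-controller fluid dynamics; expression-dependent dropout
(capture failure is uniform here, so lowly-expressed genes are not
penalized extra); batch effects, amplification noise and gene–gene
correlation beyond the shared phase driver; gene-length bias (so CPM = TPM
exactly); and the compositional closure of TPM is *present* — planting a
positive program induces weak negative correlations in unmodulated genes,
visible as significant-negative background calls — but its magnitude is
tied to the planted amplitude, not calibrated to any real library.

## Numerical conventions and degenerate inputs

Ties take mid-ranks everywhere. Constant vectors make correlation undefined
(NaN with a warning) and are excluded from pooled nulls. A zero null SD
makes every deviation significant, with a warning. All-zero cells survive
TPM scaling unscaled but flagged. Time units are seconds internally, hours
only inside MAR fitting; masses are pg throughout, MAR pg/h, growth
efficiency 1/h. All generators and permutation engines take explicit seeds;
identical seed and configuration give bit-identical output.

## Problem sizes

Property tests run the full pipeline at the default 200-cell, 1000-gene
configuration over 20 seeds, with 10,000-iteration nulls and
1000-permutation enrichment; the type-I check uses 1000 × 100 noise
matrices over 20 seeds. These sizes put Monte-Carlo error well below every
asserted margin while keeping the whole suite fast on one CPU.

## Known limitations

The matcher is greedy, not globally optimal (no Kalman-style tracking); a
lost intermediate peak ends a trajectory rather than bridging the gap.
Exact U-test enumeration is limited to both groups ≤ 8 (12,870 assignments
at 8v8). The preranked FDR follows the permutation-pool convention and is
not the multilevel split-sampling estimator of newer enrichment tools.
PCA-based testing depends on the dispersion-based variable-gene selection
described above; other selectors will shift PC loadings. tSNE visualization,
KNN clustering and proprietary pathway analysis are out of scope.
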