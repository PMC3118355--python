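# Methods

## The problem

Normalization removes array-level technical variation so that downstream
differential-expression (DE) statistics reflect biology. Global methods
encode a symmetry assumption: loess normalization forces the local mean of
M (the target-vs-reference log2 difference) to zero at every intensity A,
and quantile normalization forces every array onto the common empirical
distribution. When DE is one-sided — a sizeable group of genes regulated in
the same direction — both operations mistake the DE signal for technical
bias: the null genes are pushed off the zero line by roughly the mean DE
offset, and true fold changes are compressed.

The package's premise is that on the (A, M) plane the null genes form the
single densest cluster, because they agree across arrays while DE genes are
displaced and more dispersed. A bivariate kernel density estimate therefore
provides a *soft* invariant-set criterion: how deeply a probe is embedded
in the null cluster.

## Density model

For one array against the common reference (the per-probe mean of log2
intensities over all arrays, computed once per run), the density at (x, y)
is the product-Gaussian kernel estimate

    f̂(x, y) = 1/(n·h_A·h_M) · Σ_i φ((x − A_i)/h_A) · φ((y − M_i)/h_M)

with φ the standard normal pdf and no cross term. The A coordinate is the
reference itself, not the pairwise (target + reference)/2 average — with a
fixed A axis the null cluster occupies the same A positions on every
array's plot, which is what makes the density field comparable across
arrays.

Bandwidths default to the two-dimensional normal-reference (Scott) rule per
margin, h = σ̂·n^(−1/6) with σ̂ the sample standard deviation. Any
deterministic rule scaling as n^(−1/6) behaves equivalently here; this one
is the recorded default, and both bandwidths are overridable. Evaluation is
exact (O(n·k), chunked to bound memory). A fast path (`kde2d_grid`: linear
binning onto a 1024² mesh, discrete Gaussian smoothing, bilinear read-back)
agrees with exact evaluation to ~1e-3 relative error for n up to several
thousand and is opt-in only — the normalizers always use the exact path.

## KDL

Per array: estimate f̂ at every probe's own (A, M); raise it to the
multiplicity (default 4) as the probe's prior weight; fit a weighted loess
curve c(A) of M on A; subtract: x ← x − c(A).

The loess engine is the classic configuration — degree-1 local fits,
tricube distance weights over the k = ceil(span·n) nearest neighbours
(span 0.2 by default), prior weights multiplying the tricube weights — with
no robustness iterations: the density weights are the sole reweighting
mechanism. Boundary ties in |x − x0| are all included; a neighbourhood
whose points share one x falls back to the weighted mean; a neighbourhood
whose tricube×prior weights vanish (priors alive only on the boundary)
falls back to prior-only weights. Prediction at new points refits local
neighbourhoods rather than interpolating stored fits.

The multiplicity trades robustness against efficiency: 0 is plain loess;
4 suppresses a cluster at 40% of the null density to (0.4)⁴ ≈ 2.6% relative
weight. Residual attraction to DE clusters that overlap the null cluster
(fold changes comparable to the replicate noise) is the method's intrinsic
limit: a small-fold-change gene is statistically indistinguishable from a
null gene on a single array and no weighting scheme can fully exclude it.

If M is exactly constant for an array (e.g. identical arrays), the curve is
that constant and the density step is skipped — the local linear fit of a
constant is the constant for any weights.

## KDQ

1. **Selection.** Densities are estimated per array against the common
   reference, exactly as in KDL. The per-array scores of each probe are
   summed and the top ceil(proportion·n) probes form the invariant set
   (ties broken toward smaller total |M|, then smaller index, for full
   determinism). The pooled combination keeps the *actual* retained
   fraction equal to the nominal proportion, matching the guidance that
   the proportion should sit just below the expected fraction of null
   probes. The alternative `selection="intersection"` (intersect per-array
   top sets) is retained; note its effective proportion shrinks rapidly
   with the number of arrays (8 arrays at nominal 0.5 retain ~6% of
   probes), which makes the parameter hard to interpret.
2. **Anchoring.** Standard quantile normalization of the invariant
   submatrix: sort each column, average across columns rank-wise, map back;
   ties within a column receive the mean of the rank averages they span.
3. **Scoring.** Within each array, ties among invariant intensities are
   collapsed (averaging their normalized values); probes inside the
   invariant range are linearly interpolated between bracketing anchors,
   so invariant probes map exactly to their quantile-normalized values.
   Outside the range, the value is shifted by the mean offset of the
   outermost min(m_boundary, n_inv) anchor pairs: y_a + (x − x_a) above,
   mirrored below. No slope is extrapolated — only the average shift —
   which keeps the tails monotone and conservative. The low-end rule
   mirrors the high-end one by construction.

Defaults: proportion 0.5 (suitable when around half the probes can be
trusted as null; a warning is emitted above 0.85), m_boundary 100 (clamped
to the invariant-set size so small data stay valid). A run fails if the
invariant set would drop below max(2, 1% of probes).

## Baselines, summarization, probe-level wrapping

Plain loess normalization is definitionally KDL with multiplicity 0 (the
same code path, so the equivalence is exact). Global quantile
normalization is KDQ with proportion 1. Probe sets are summarized by the
median or by Tukey's median polish (rows first, then columns, at most 10
sweeps or until the sum of |residuals| changes by ≤1e-6; the summary per
array is overall + column effect, excluding probe effects, as in
median-polish-based expression summaries). The probe-level wrapper
normalizes the per-probe-set medians and reconstructs each probe as
normalized median + (probe − original median), preserving within-probe-set
offsets exactly; the CLI's `--level both` chains a probe-level pass,
median-polish summarization, and a second post-summary pass.

## Evaluation

Gene scores: log2 fold change = mean(group A) − mean(group B); the
two-sample pooled-variance t with n_A+n_B−2 df and two-sided p. A gene
whose pooled variance is zero carries no information for the t-test and is
assigned p = 1 with an undefined t — this keeps truncated/flat probe sets
in the ranking at the bottom instead of silently dropping them. Welch's t
was not used because the zero-variance convention is defined for the
pooled form and group variances are exchangeable by design here.

ROC curves rank by decreasing |log2 fc| or increasing p (ties share a
threshold); the AUC is the trapezoid area, identical to the Mann–Whitney
U statistic with half-credit ties (cross-checked against a pairwise oracle
in the tests). The |·| ranking keeps symmetric and one-sided designs on
the same footing. The compression slope is the OLS slope of observed on
designed log2 fold change over genes with designed (raw) fold change > 1;
the filter is on the raw scale, the regression on the log2 scale, both
configurable in principle but fixed here. Empty probe sets are excluded
from evaluation unless explicitly included; the primary protocol drops
them before normalization as well.

Null-gene diagnostics come in two forms: `null_ma_bias` (the worst
per-array |median M| of null genes against the recomputed common
reference — the direct "is the null cluster on the zero line" check) and
`null_bias` (the median observed condition-difference of null genes, which
accumulates the per-array offsets of both conditions and is therefore
roughly twice as large under symmetric distortion).

## Synthetic designs

**Two-condition spike-in layout.** Counts default to the classic
asymmetric design: 2535 equal-concentration genes, 1331 up-only genes,
10144 empty probe sets, 3 replicates per condition. Per gene, a log2
baseline ~ Normal(8, 2); per array, a technical offset ~ Normal(0, 0.1);
per (gene, array), noise ~ Normal(0, 0.25); up genes add log2(fc) on the
S arrays with fc drawn from {1.2, 1.5, 2, 3, 4} (optionally biased so
higher-baseline genes receive larger fold changes, emulating the
concentration/fold-change confounding of such designs). Empty probe sets
sit at a common low level (log2 = 4) with small noise, forming the second,
disjoint null population that breaks single-cluster assumptions when
included. All randomness flows from the single design seed.

**Effect-spiking simulation.** A null pool of n_genes × n_controls
(default 2000 × 8) raw intensities is built from the same
baseline/offset/noise model; the arrays are split at random 4 vs 4 into
simulated control and treatment groups; round(prop_significant·n) genes
are declared significant; each receives a log2 shift of S_i·d_i on its
treatment arrays, where S_i is the gene's observed control-group standard
deviation and d_i an effect size drawn from effect_scale·t(12) — absolute
values in the asymmetric variant, making every effect an up-regulation —
and the matrix is returned to the raw scale as 2^(·). The t distribution's
12 df match a small two-group comparison; the scale (default 3) reflects
that effect sizes borrowed from a genuinely affected case/control
comparison are several-fold overdispersed relative to a null t — at unit
scale the median planted effect would be ~0.1 log2 units and essentially
undetectable at these sample sizes. Non-significant genes are bit-identical
between the null pool and the output, which the tests verify.

**What the generators do not emulate.** Probe-sequence effects (GC
content, cross-hybridization), intensity-dependent variance, background
correction artifacts (low-end truncation), and correlated noise across
genes. Passing benchmarks on these generators demonstrates the asymmetry
mechanics — that density-anchored normalization centres the null genes
where global methods cannot — not performance on any particular real
platform.

## Problem sizes and numerical choices

The benchmark protocols run at 5000 genes × 6 arrays (asymmetric
two-condition comparison) and 2000 genes × 8 arrays (effect-spiking
sweeps, 5 seeds for the symmetric comparison, 3 for the proportion sweep);
these sizes give stable AUC/slope estimates while keeping a full
simulate→normalize→evaluate panel in the tens of seconds on one CPU.
Matrix TSVs are written with shortest-round-trip floats so write→read is
lossless; report files round to 9 significant digits. Degenerate inputs
are rejected loudly rather than patched: constant margins in the density
step, neighbourhoods with all-zero prior weights, invariant sets that
collapse, single-class truth tables. Per-array normalization failures
abort the whole matrix (with the array named) — a silently skipped array
would corrupt every downstream comparison.

## Known limitations

- Small fold changes (≲ the replicate noise) contaminate both the density
  weights and the invariant set; KDL/KDQ reduce, but cannot eliminate,
  the resulting bias (~0.03–0.04 log2 units per array in the asymmetric
  benchmark, versus ~0.16 for global methods).
- The exact KDE is O(n²) per array; beyond ~50k probes the grid fast path
  or subsampling would be needed.
- KDQ's tail extrapolation is shift-only; arrays with genuine slope
  differences beyond the invariant range are better served by KDL, which
  fits every probe.
- The pooled-variance t with the p = 1 zero-variance rule is the only
  built-in test statistic; moderated or nonparametric statistics are out
  of scope.
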