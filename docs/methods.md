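# Methods

## Model

Each gene's normalized expression over the ordered cells is modelled as a
smooth function of pseudotime plus i.i.d. Gaussian noise:

    y_i = f(t_i) + ε_i,   ε_i ~ N(0, σ²)

with *f* represented by a cubic regression spline.  The basis has df + 1
columns (constants lie in its span): for df = 3 this is the cubic
polynomial span; larger df adds interior knots at pseudotime quantiles.
Coefficients are estimated by least squares, so the fit is a linear
smoother; scaling the fitted values to mean 0, sd 1 (sample sd, n − 1
denominator) makes trajectories comparable across genes regardless of
expression level and dynamic range.

The Gaussian response is appropriate because the pipeline consumes
*normalized* expression — log-normalized counts, scaled imputed values, or
similar — not raw counts.  Filtering, normalization and pseudotime
estimation are upstream of this package by design.

### Temporal variation test

The per-gene test compares the spline model against the intercept-only
model with the Gaussian likelihood-ratio statistic

    Λ = N · log(RSS₀ / RSS₁)   ~   χ²(df)

where df is the number of basis columns beyond the constant.  The χ²
reference is asymptotic; at N = 300 the measured type-I error at the 0.05
level is ≈ 0.046 (the acceptance script recomputes it over 2,000 null
genes).  An exactly constant gene short-circuits to p = 1; a numerically
failing fit is assigned p = 1 with a warning rather than aborting a run.
P-values are BH-adjusted across all fitted genes and retention uses a
strict q < alpha cut (default 0.05).

### Switch points and patterns

On the scaled fitted trajectory x, a switch point is an index i (1-based)
with x_i·x_{i+1} < 0.  Exact zeros would defeat the strict product, so runs
of exact zeros are collapsed: if the nonzero neighbours flanking a zero run
have opposite signs, one switch is recorded at the last index before the
run.  This preserves "crosses zero" semantics under floating point; for
trajectories without exact zeros the rule reduces to the plain product
scan, and the test suite checks exact equality with a naive scan there.

Positions are reported both as indices and as fractions i/N.  All
cross-sample arithmetic uses fractions, because samples generally have
different cell counts.

The pattern is the alternating sign string of the segments delimited by the
switch points; each segment's sign is taken from its entry of largest
absolute value, which is robust to near-zero entries at segment
boundaries.  Labels: "−+" increasing, "+−" decreasing, "−+−" up_down,
"+−+" down_up, anything else complex(k) with k switch points.  A scaled
(mean-0) trajectory virtually always crosses zero; the no-switch case is
possible only with exact zeros and is labelled complex(0) with a warning.

### Cascade ordering

Genes are sorted by (1) pattern complexity ascending — monotone patterns
before non-monotone; (2) sign string, with "−" ordered before "+", so
increasing precedes decreasing and up_down precedes down_up; (3) first
switch position ascending; (4) gene identifier.  The final tie-break makes
the order total and reruns byte-reproducible.  Steps 2 and 4 are this
package's conventions where any fixed convention would do.

### Multiple samples

Each sample is fitted, filtered, scaled and classified on its own cells.  A
gene is *consistent* when it is retained in every sample with an identical
sign string.  For switch ordinal k of a consistent gene, the per-sample
fractional positions give mean ± 2·(sd/√n_samples); intervals are clipped
to [0, 1].  The consensus cascade orders genes by mean first-switch
fraction (the multi-sample row order is otherwise unspecified; this is our
convention).

A limitation worth knowing: the ± 2 SE interval quantifies
*between-sample* variability only.  Smoothing bias — any spline smoother
shifts a sharp transition's zero crossing slightly toward the trajectory
centre — is shared by all samples and therefore does not enter the SE.
With very tight between-sample variability the interval can sit entirely on
the biased side of the true transition.  The acceptance check of the CI
machinery injects known per-sample fractions (Normal(t*, 0.03²)) for
exactly this reason: it separates interval construction, which the package
controls, from smoothing bias, which is intrinsic to any smoother-based
switch estimate.

### Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ count) with population = background, successes = term ∩ background,
draws = query.  The background is the set of significance-retained genes
that appear in the annotation universe — the least biased reference for
asking "what distinguishes this pattern/stage *within* the trajectory".

GeneRatio is count divided by the number of background genes annotated to
the term (term coverage).  This is deliberately not the common
count-over-query-size convention; it rewards terms captured nearly in full
by a pattern or window.  q-values are BH within each query (per pattern, or
per window), consistent with the gene-level filter.  Only
over-representation is tested, no depletion.

Temporal enrichment partitions one pattern group's cascade order into
n_windows contiguous windows (size = ⌈G/n_windows⌉, non-overlapping by
default; an overlap is configurable, and a step larger than the window size
is rejected because it would leave genes untested).  The displayed term set
is the union across windows of each window's top-5 terms by GeneRatio,
filtered to q < 0.05.  Because the hypergeometric is discrete and window
queries are small, the raw per-window test is conservative: under a random
annotation the measured rejection rate at the 0.05 level falls below the
nominal level rather than at it.

## Synthetic data

The generator produces the statistical structure the analysis assumes, on
the normalized-expression scale:

- increasing genes: amplitude·sigmoid((t − c)/w); decreasing genes are the
  mirror image;
- up_down / down_up genes: (inverted) Gaussian bumps with two crossings;
- null genes: a constant level plus noise;
- Gaussian noise of sd `noise_sd` on every gene.

The sigmoid centre c is calibrated by bisection so that the mean-centred
noiseless curve crosses zero exactly at the planted fraction t*.  This
matters: centring shifts a sigmoid's crossing away from its centre by
roughly w·log((1−c)/c), and the crossing of a width-w sigmoid observed on
(0, 1) is confined to a central band (about (0.17, 0.83) at the default
w = 0.05 — a width chosen so that sharp, localizable switches across
(0.2, 0.8) remain representable).  Fractions outside the feasible band
raise an error rather than silently landing elsewhere; cross-sample jitter
(Normal(t*, jitter²)) is truncated to the same band.  Ground truth records
the exact crossing fractions of each noiseless centred signal on the cell
grid, so downstream scoring never re-reads generator internals.

Reference study conditions (the defaults): 300 cells, 150 increasing, 150
decreasing, 100 up_down, 100 down_up, 100 null genes, amplitude 1, noise
sd 0.3, planted switch fractions uniform on (0.2, 0.8), bump centres on
(0.35, 0.65) with sd 0.12.  All randomness flows from a single seed through
per-(gene, sample) substreams, so datasets are bit-reproducible.

What the generator does *not* emulate: count noise (dropout, library-size
variation), pseudotime estimation error, correlated genes, branching
trajectories.  Passing tests therefore demonstrate correctness of the
pipeline's statistics on its stated input — smooth signals in Gaussian
noise on an ordered axis — not robustness to raw scRNA-seq artefacts,
which are upstream concerns.

## Numerical choices and degenerate inputs

- Spline basis built on pseudotime rescaled to [0, 1]; B-spline design via
  banded evaluation, least squares via LAPACK lstsq (rank-deficient safe).
- RSS₁ ≤ 10⁻¹⁴·RSS₀ is treated as a perfect fit (p = 0) to avoid log of a
  denormal; an exactly constant input returns p = 1 before fitting.
- scale_fitted refuses zero-variance input (callers filter such genes).
- Pseudotime must be strictly increasing; ties are an error at parse time,
  after sorting two-column input by time.
- Cells present in the matrix but absent from the ordering are dropped with
  a logged count (orderings from trajectory tools often cover one branch);
  ordering cells missing from the matrix are an error.
- Heatmap colour scales are symmetric about 0 and capped at ±3 scaled
  units; every figure writes a sidecar TSV (row order, colour limits, CI
  coordinates) so tests assert figure content without image diffing, and
  SVG output is byte-deterministic under a fixed hash salt.

## Parameter guidance

| parameter | default | meaning |
| --- | --- | --- |
| `spline_df` | 3 | spline basis dimension beyond the constant; 3 captures monotone and single-bump shapes, raise to 5–6 for wigglier dynamics (needs N ≥ 2·(df+1)) |
| `alpha` | 0.05 | BH q-value cut for retaining genes |
| `n_windows` | 10 | temporal-enrichment windows per pattern group |
| `top_k` | 10 / 5 | terms shown per pattern / per window |
| `min_cells_per_sample` | 10 | guard against meaningless per-sample fits |
| heatmap `cap` | 3.0 | colour-scale limit in scaled units |

## Known limitations

- Single linear orderings only: no branch- or tree-structured
  trajectories, and no alignment of pseudotime scales across samples beyond
  the fraction normalization.
- The significance test ignores uncertainty in the pseudotime itself and
  autocorrelation of residuals along the trajectory; with strongly
  correlated noise the type-I error can exceed nominal.
- Switch localization inherits smoothing bias (see above), growing toward
  the ends of the trajectory and with sharper transitions relative to the
  basis flexibility.
- Flat gene-set annotations only; no GO DAG propagation, no
  hierarchy-aware (elim/weight) or rank-based (GSEA) testing.
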