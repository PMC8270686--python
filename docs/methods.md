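# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the design decisions behind `thydex`.

## The analysis model

### QC gate

Arrays are retained only if every rule holds, with strict inequalities:
maxbg < 190, percent-present > 37.5, scaling factor < 4, actin 3′/5′ < 5,
GAPDH 3′/5′ < 4, spike-in quartet strictly increasing
(bioB < bioC < bioD < cre), −0.25 < median RLE < 0.25 and
0.8 < median NUSE < 1.2. The scanner metrics are *consumed* from a QC
table (computing them requires probe-level present-call machinery that is
out of scope); RLE and NUSE are *computed*: RLE(g, s) is the expression
minus the across-sample gene median, and NUSE(g, s) is the median-polish
standard error divided by the across-sample median SE. A verdict lists
every violated rule; a missing metric fails the array with
`missing_metric:<name>`. The gate runs on the raw probe-level matrix,
before normalization — quantile normalization would mask exactly the
array-level shifts RLE exists to catch.

### Normalization

Quantile normalization maps each array's values to the per-rank means of
the sorted columns. Ties within a column receive the mean of the target
values over the tied span. Means are computed about the first sorted
column, so the mean of identical values is exactly that value; this makes
the operation bit-exactly idempotent and leaves all columns with an
identical sorted vector. In the pipeline, quantile normalization is
applied **within each sample group**: the four groups originate from
separately processed array datasets, and normalizing across groups
distorts unregulated genes wherever the groups' true intensity
distributions differ (direction-asymmetric regulation shifts the pooled
quantiles, which manifests as spurious moderate p-values for null genes
and a depressed π₀). The standalone `quantile_normalize` operation remains
global.

Summarization is two-way Tukey median polish per probeset, row-first
sweeps, even-count medians as the mean of the two central values,
convergence when the total absolute residual changes by < 1 % relative
(tol 0.01), at most 10 sweeps — the dialect of the classic reference
implementation. The probeset summary per sample is overall + column
effect, which removes probe affinity offsets; the SE per probeset and
sample is the residual MAD (×1.4826) of that sample's column divided by
√(probe count). Single-probe probesets have zero residuals and hence zero
SE; they are excluded from NUSE.

### Moderated differential expression

For a two-group contrast with nₐ and n_b samples, the per-feature pooled
residual variance s² has df = nₐ + n_b − 2. The empirical-Bayes prior
s² ~ s₀²·F(df, d₀) is fitted by method of moments on z = log s², using
E[z] and Var[z] expressed through digamma/trigamma; the trigamma inverse
is solved by Newton iteration. The posterior variance is
s̃² = (d₀s₀² + df·s²)/(d₀ + df), the moderated
t = logFC/(s̃·√(1/nₐ + 1/n_b)) is two-sidedly referred to t with df + d₀
degrees of freedom (normal when d₀ = ∞, which occurs when the observed
spread of log s² does not exceed its sampling component). Setting d₀ = 0
recovers the classical pooled t exactly. Features with zero residual
variance are floored at the smallest positive s² and flagged. With fewer
than 10 features the prior cannot be fitted usefully and moderation is
disabled with a warning.

### Local FDR

π₀ is Storey's estimate #{p > 0.5}/(0.5·n), capped at 1 and floored at
1/n. The p-value density is the Grenander estimator — the slope of the
least concave majorant of the empirical CDF, computed by a weighted
pool-adjacent-violators pass over the raw ECDF slopes with the support
extended to [0, 1] — and lfdr(p) = min(1, π₀/f̂(p)), which is
non-decreasing in p because f̂ is non-increasing. This formulation is
deterministic and dependency-free; the classification threshold
(lfdr > 0.95 ⇒ *unchanged*) is kept at the conventional value. With
fewer than 100 p-values the density estimate is unstable and
lfdr = min(1, π₀) is returned with a warning.

### Gene status and precedence

Per comparison: *DE_UP/DE_DOWN* (adjusted p < α and |log₂FC| ≥ 1,
"at least twofold" read inclusively), *SIGNIFICANT* (adjusted p < α
only), *UNCHANGED* (lfdr > 0.95), *UNCERTAIN* otherwise. The rules can
overlap; precedence DE > SIGNIFICANT > UNCHANGED > UNCERTAIN makes the
partition exhaustive and deterministic, and the number of DE/UNCHANGED
conflicts is reported rather than hidden. Collapsing features to genes
keeps the feature with the smallest adjusted p (ties: largest |logFC|,
then lexicographic id); the twofold rule is applied at feature level
before collapsing.

### Signatures and patterns

Set predicates over gene-level statuses. "Downregulated or not
differentially expressed" is read **leniently** by default (any non-DE
status qualifies) with a strict UNCHANGED-only mode, because a gene that
is significant-but-sub-twofold in the tissue-mix comparison should not be
disqualified from a thyroid-specific list. Patterns:

| pattern | comp4 (ET−EM) | comp3 (AM−EM) | comp1 (AT−ET) |
|---|---|---|---|
| I   | DE_UP     | DE_DOWN or UNCHANGED | DE_UP |
| II  | DE_UP     | DE_DOWN or UNCHANGED | UNCHANGED |
| III | DE_UP     | DE_DOWN or UNCHANGED | DE_DOWN |
| IV  | UNCHANGED | DE_DOWN or UNCHANGED | DE_UP |

The eligible comparison-3 set is a parameter (`eligible_down_set`); the
patterns are mutually exclusive by construction and anything else maps to
NONE.

### Enrichment

Subcluster references are unions of member-term gene sets (a term may
belong to at most two superclusters and contributes to each). The overlap
test is the one-sided hypergeometric upper tail P(X ≥ k) with population =
universe, successes = reference, draws = query; the universe defaults to
the genes on the (collapsed) array, not the genome. "Benjamini" correction
is Benjamini–Hochberg step-up across the tested subclusters. Odds ratios
are sample odds ratios with a 0.5 continuity substitute applied for
reporting only when a table cell is zero.

### Multivariate layer

PCA treats samples as observations, centers and scales variables, and
uses SVD of the standardized matrix; zero-variance features are dropped
and counted, and signs are fixed by making each loading vector's
largest-magnitude entry positive. Clustering is complete-linkage over
Euclidean distances (the only paper-anchored options; other linkages are
accepted but untested), with optional row scaling to mean 0/sd 1 as
heatmap drawing conventionally applies, and leaf order fixed by optimal
leaf ordering — the deterministic counterpart of the weighted-mean
dendrogram reordering heatmap functions perform.

## The synthetic-data generator

The generator emulates a four-group log-normal expression study with
planted classes; it defines the study conditions all stochastic tests run
under.

**Expression model.** Probe value = gene baseline N(7, 2²) + probe
affinity N(0, 0.5²) (constant across samples, so summarization must
remove it) + group effect + stage term + N(0, σ_g²), with
σ_g² ~ scaled-inverse-χ²(d₀ = 4, s₀² = 0.25) — the moderation model's own
family, making the shrinkage target analytically known. Each gene is one
probeset of 1–3 probes. Group sizes default to AT 5, ET 9, AM 20, EM 9.
Only three contrasts are free; comp2 = comp1 + comp4 − comp3 is enforced
through the group means (EM is the baseline).

**Classes** (defaults in parentheses; effect magnitudes e ~ U[1.5, 3]):

* `thyroid_identity` (400): comp1 = comp3 = 0, comp4 = +e′ with
  e′ = 2e — identity genes carry much larger fold changes than ordinary
  regulated genes, as the hallmark thyroid genes do (several-hundred-fold
  in real data);
* `shared_developmental` (250): comp1 = comp3 = +e, comp4 = 0;
* `pattern_I..IV` (50 each): the table above with comp3 planted as −e or
  exactly 0 with equal probability (both arms of "down or not
  differentially expressed");
* `at_specific` (50): comp1 = comp4 = 0, comp3 = −e (so comp2 = +e
  without satisfying the pattern IV predicate);
* `et_specific` (50): comp1 = 0, comp3 = comp4 = +e (comp2 = 0; the
  comparison-3 up-course keeps it out of patterns I–III);
* `null`: all effects exactly 0.

The truth table records the class, the four signed effects, and the
pattern implied by the effect signature (`true_pattern`): a
thyroid-identity gene genuinely satisfies the pattern II predicate, so
recovery and contamination are scored against the implied pattern, not the
class name.

**Gestational stage.** ET samples carry stage_weeks evenly spaced over
7–11. Genes regulated across thyroid development (patterns I/III/IV)
traverse 70 % of their adult-embryonic difference within the window
(thyroid functional differentiation happens in exactly these weeks);
shared developmental genes traverse 10 % (the window is ~10 % of
gestation); thyroid-identity genes consolidate during the window —
each trends with stage at 80 % of its amplitude, approaching its
established level from below or above with equal probability, so the
group means (and comp1 = 0) are preserved and the net drift of an
embryonic sample along any group-contrast axis cancels. All stage terms
are zero-mean across the ET group, leaving planted group effects intact.

**Bad arrays.** When requested, the last AM samples are engineered to
violate exactly one rule each, cycling through a +1 log₂ global shift
(RLE), doubled residual noise (NUSE), and a swapped bioB/bioC spike pair
(spike order). All other QC metrics are drawn inside the passing windows.

**qPCR panel.** An idealized Ct table in which a planted effect e on the
matching comparison lowers the sample-group Ct by e cycles, so the ΔΔCt
ratio is exactly 2^e; the two reference genes have constant Ct, and a
reference with a planted effect is reported as a warning.

**What the generator does not emulate.** Real probe-intensity
distributions (log-normal is an assumption), batch/scanner effects,
probe-sequence (GC) effects, present/absent detection calls, correlated
genes (all noise is independent across genes), and non-linear stage
trajectories. Passing tests therefore demonstrate the pipeline's internal
correctness and its behaviour under a faithful statistical caricature of
the study design — not performance on real arrays.

## Problem sizes and numerical choices

Stochastic checks run at 10,000 genes with the class counts above
(5,000 genes, two groups of 5, for the null-calibration check), sizes at
which every quantity of interest is stable across seeds while a full
pipeline run takes seconds. The exact-oracle checks sweep all
hypergeometric tables with universe ≤ 60, 1,000 random p-vectors for the
BH step-up, and 100 random ≤ 5×5 matrices for the median polish.
Tolerances: 1e-12 for the exact oracles (floating-point summation of
exact binomial terms), 1e-8 for median polish against an independently
coded reference, 1e-10 for the moderation limits. Medians of even counts
are always the mean of the two central values; all tie-breaks
(quantile-normalization spans, collapse representative, most-variable
selection) are deterministic and documented at the operation.

The embryonic-thyroid stage-ordering check clusters the ET samples on the
300 most variable genes of the comparison-4 DE signature with row scaling
— the heatmap recipe (most-variable selection, row scaling, complete
linkage) applied to the embryonic-thyroid signature — and requires the
leaf order to equal the gestational-age order up to reversal.

## Known limitations

* The RMA convolution background-correction model is not implemented;
  inputs are assumed background-handled (an optional percentile-shift
  correction is provided for linear-scale input).
* Two-group contrasts only; no covariates, no batch terms.
* The local-FDR estimator is the Grenander/Storey formulation, not a
  re-implementation of any specific package's internals; the 0.95
  threshold is unchanged.
* Term-level GO enrichment (the job of dedicated annotation tools) is out
  of scope; only the subcluster-level overlap layer is implemented, with
  a small editable example taxonomy shipped as data.
* Group sizes below ~5 per group leave the moderated test with little
  power at twofold effects; the status calls remain valid but the
  *uncertain* gray area grows.
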