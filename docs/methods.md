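# Methods

This note documents the statistical procedures implemented in `ntsom`,
the assumptions behind them, the tunable parameters, and what the
synthetic data generator does and does not emulate.

## Data model

A campaign is a samples × compounds matrix of chromatographic peak
areas (arbitrary detector units, non-negative) with aligned metadata:
per sample the site, site type (urban / industrial / blank), dilution
level (concentrated or 1:10 diluted) and replicate number; per compound
the m/z, retention time, optional annotation and its 1–5 confidence
level. The confidence level is carried as inert metadata — it plays no
role in any computation. Missing areas are not representable; upstream
feature extraction is assumed to have gap-filled, with absence encoded
as zero.

## Screening filters

Applied in order blank → dilution t-test → Correctness; each filter
reports its discards and the pipeline combines the bookkeeping.

**Blank filter** (`factor`, default 5). A compound is background iff in
*any* sample its area is strictly less than `factor` times the mean
area of that site's sequence blanks. The mean (not the max) of the two
sequence blanks is used; a compound absent from every blank is always
retained. The inequality is strict, so an area of exactly 5× the blank
mean survives.

**Dilution t-test** (`alpha` 0.05, `method` paired, `scale` log10). A
compound whose concentrated and diluted areas are not statistically
different shows no area–concentration relationship and is discarded
(p > alpha). The default is a paired test on log10(area + 1): each
concentrated replicate is paired with the same site's diluted replicate
of the same replicate number, which makes the 1:10 dilution a constant
additive offset on the log scale and keeps the test's power independent
of between-site intensity differences (on the raw scale, order-of-
magnitude site differences swamp the within-pair dilution effect and
the pooled test loses essentially all power for exactly the compounds
that carry site structure). The pooled unequal-variance Welch test and
the raw scale remain available as options. Degenerate columns (zero
variance, equal means) are treated as p = 1 and discarded. No
multiple-testing correction is applied, matching standard practice for
this screening step.

**Correctness filter.** Per compound and site, a dummy is 1 iff the
diluted replicate mean is strictly below the concentrated replicate
mean; the compound is retained iff the median of the dummies across
sites is ≥ 1. With ten sites this tolerates up to four sites violating
the expectation. The rule compares only within-site means, so it is
invariant to any strictly increasing affine per-compound rescaling —
running it before or after z-scoring is equivalent.

**z-score transform.** Per compound, `z = (area − mean)/sd` with the
sample standard deviation (n − 1). Constant compounds cannot be scaled;
they are recorded in the scaling model and dropped on application.
Scaled tables carry the scaling model's id so that downstream models
can verify projection data were scaled consistently.

## Unknown-common selection

The screened table is z-scored (all non-blank samples) and clustered on
both axes with Euclidean distance and Ward's linkage in the Ward.D2
convention (merge cost = increase in total within-cluster sum of
squares, heights on the distance scale; scipy's `ward`). Heights are
monotone by construction; the implementation is cross-checked in the
test suite against an O(n³) Lance–Williams oracle.

The compound dendrogram is cut into `k` clusters (default 5) and a
cluster is *industrial-peculiar* iff

    max over industrial sites of
        (mean z within that site − mean z over all urban samples)

exceeds `delta` (default 2.0 z-units), computed over the cluster's
compounds. Unknown commons are the union of non-peculiar clusters. The
rule is deliberately one-sided: a cluster *lacking* in industrial
samples is not peculiar, because the models are meant to detect foreign
material, and missing urban markers already surface as projection
error. In the original visual workflow this selection is a manual
reading of the heatmap; `manual_discard_ids` (CLI `--manual`) bypasses
the automatic rule with an explicit discard list.

Defaults were chosen from the geometry of the problem. Per-column
z-scoring saturates: any compound that is strongly and specifically
elevated in one site's few samples looks nearly identical in z-space
regardless of magnitude, with a site elevation around 2.5; clusters of
compounds moderately elevated at *all* industrial sites score around
1.3–1.6. `delta = 2.0` sits centrally in that gap, and `k = 5` matches
the natural cluster structure (a commons core, an industrially elevated
commons block, and one block per exclusive-hosting site). With a much
coarser cut (k = 2) the exclusive blocks fail to separate from the
commons branch.

## Batch SOM

A from-scratch batch Self-Organizing Map on a hexagonal sheet lattice.
Node coordinates: odd rows offset by +0.5, row pitch √3/2, so every
nearest neighbor is at planar distance exactly 1; nodes are indexed
row-major, 1-based in all outputs.

**Sizing.** `munits = ceil(5·√n)` ("regular") or `ceil(5/4·√n)`
("small"); `ydim = round(√(munits/ratio))`, `xdim = round(munits/ydim)`
with half-away-from-zero rounding and sides swapped to keep
`xdim ≥ ydim`, where `ratio = √(λ1/λ2)` of the training covariance
(reported to one decimal). The half-away-from-zero convention is what
turns 7 units at ratio 1.4 into a 4×2 map. Explicit dimensions bypass
the heuristics; the pipeline's default working map is 4×3 (12 nodes),
and a Table-style quality report is produced for the regular, small and
configured candidate maps.

**Training.** Deterministic batch algorithm: the codebook is
initialized linearly on the plane of the first two principal components
(sign-fixed so the result does not depend on sample order), then two
phases of batch updates — rough: radius `max(1, xdim/2) → max(1,
xdim/8)` over 50 epochs; fine-tune: `→ 1` over 100 epochs; linear decay
per epoch; Gaussian neighborhood `h = exp(−d²/(2σ²))` on the planar
grid distances. Each epoch assigns every sample to its BMU (ties →
lowest node index) and replaces each node by the neighborhood-weighted
mean of all samples; a node with numerically zero weight keeps its
previous value. Updates are convex combinations of the data, so the
codebook stays inside the data's convex hull, and the algorithm is
sample-order-free and reproducible bit-for-bit. There is no online
mode. Note that with the final neighborhood radius of 1 the map remains
deliberately smoothed — nodes are local averages rather than cluster
memorizers, which is the behavior of the standard SOM toolboxes this
follows.

**Quality metrics.** QE: mean distance of samples to their BMUs. TE:
fraction of samples whose first and second BMUs are not grid-adjacent
(planar distance > 1.01). Dead nodes: nodes with zero hits. DME
(distribution matching error): the toolbox lineage reports a
distribution-matching error without a published formula, so it is
operationalized here as the fraction of variables whose two-sample
Kolmogorov–Smirnov statistic between the data column and the
hit-weighted codebook column exceeds the asymptotic α = 0.05 critical
value.

**Projection and outliers.** A projected sample gets the nearest node
(BMU) and its distance (QE). The outlier threshold is the maximum
training-sample QE times a configurable multiplier (default 1.0); a
sample is an outlier iff its QE strictly exceeds the threshold, so
training samples are never flagged. Outputs include log10(QE) for the
usual log-scale bar plot.

**Node signatures.** Because the SOM keeps the original variables, a
node vector is inverted through the scaling model (`area = z·sd +
mean`, clipped at zero) and emitted as an rt-sorted stick table — a
reconstructed pseudo-chromatogram of the recurrent urban signature,
something a PCA model cannot provide.

## PCA baseline

SVD-based PCA of the already z-scored urban block (no re-centering).
Component count by Kaiser's rule — retain eigenvalues above the mean of
the positive eigenvalues — or an explicit integer. Distances per
sample: SD = Σ t²ₖ/λₖ (Mahalanobis in score space) and OD = ‖x − PPᵀx‖²
(squared orthogonal residual); they satisfy OD + ‖PPᵀx‖² = ‖x‖²
exactly. Both axes get moment-matched scaled chi-square limits
estimated from the training distances (the data-driven
degrees-of-freedom approach of SIMCA-style software): N = max(1,
round(2·mean²/var)), scale u0 = mean; the *extreme* limit is the 1 − α
quantile and the *outlier* limit the (1 − γ)^(1/n) quantile (per-object
correction for the training-set size). A sample is an outlier when
either axis exceeds its outlier limit. With α = γ = 0.05 roughly 5% of
campaigns will show one urban training sample beyond the outlier limit
— that is the designed family-wise rate, not a defect. The
distance–distance plot export normalizes each axis by its extreme limit
(a sample at the limit sits at 1.0) and log10-converts for display.

## Synthetic data generator

The generator emulates the campaign design so every stage is testable:
6 urban + 4 industrial sites × 2 replicates × 2 dilution levels = 40
samples, plus 2 sequence blanks per site. Peak areas are log-normal: a
per-compound log10 baseline ~ N(6.0, 0.5), multiplied by log-normal
replicate noise with CV 0.15; diluted samples are the concentrated
level times 0.1.

Compound classes (defaults: 300 / 60 / 40 / 30):

* **common** — present at every site. Half of them additionally carry a
  *shared industrial load*: the same compounds are elevated at every
  industrial site by a per-compound N(0.9, 0.1) log10 offset (about
  8-fold) plus a small site-idiosyncratic N(0, 0.1) log10 term. An
  optional per-site fingerprint term (`site_log10_sd`) exists but
  defaults to 0.
* **industrial_exclusive** — log10 level 2 (near-zero relative to 10⁶)
  everywhere except one assigned industrial site; partitioned among 3
  of the 4 industrial sites, mirroring campaigns where only some
  industrial plants show exclusive chemistry.
* **background** — identical in every sample and dilution-invariant,
  with blanks carrying 50% of the sample level, so the 5× rule must
  remove them.
* **artifact** — dilution-ignoring, with diluted replicates biased 1.25×
  above concentrated and a deterministic fix-up guaranteeing the
  diluted site mean exceeds the concentrated one at every site, so the
  dilution filters must remove them.

The shared-load design is what reconciles two requirements that a
zero-mean, site-independent industrial offset cannot satisfy
simultaneously. First, a 1:10-diluted foreign sample only exceeds the
maximum urban training QE if some retained compounds are elevated
roughly an order of magnitude in industrial samples — on the raw-area
z-scale, dilution compresses a diluted row's deviations by the dilution
factor while the QE threshold is set by concentrated-sample replicate
scatter. Second, compounds spiked that strongly in a *single* site are,
after z-saturation, observationally equivalent to industrial-exclusive
compounds and are removed by the clustering step. An elevation shared
by all industrial sites threads the needle: in the pooled (40-sample)
z-geometry used for selection its clusters score below `delta`, while
in the urban-only z-geometry used by the models even diluted industrial
samples deviate far beyond urban scatter. At the defaults, across 24
random seeds, screening plus selection recovered the ground-truth
common class with sensitivity and specificity 1.00 and both models
flagged exactly the 16 industrial samples.

What the generator does *not* emulate: chromatographic reality (peak
shape, co-elution, adducts/isotopes), heavy-tailed abundance
distributions, between-batch drift, missingness, correlated compound
families within urban sites, and partially overlapping industrial
sources. Passing tests therefore demonstrate the pipeline's mechanics
and its qualitative behavior under the designed effect sizes, not
performance guarantees on real campaigns — in real data the boundary
between "common with industrial elevation" and "industrial-peculiar" is
precisely the judgement call the heatmap reading (or the `k`/`delta`
knobs) must make.

## Numerical choices and edge cases

* Strict inequalities exactly as specified for the 5× blank rule,
  the Correctness dummy and the outlier thresholds.
* Filters that would discard every compound raise a validation error
  (a feature table cannot be empty); the pipeline reports the failing
  stage.
* CSV writers use 17-significant-digit floats and readers parse with
  round-trip precision, so read→write→read is the identity and
  identical runs are byte-identical.
* Ties: BMU and nearest-pair ties resolve to the lowest index; the
  Welch/paired degenerate cases (zero variance) map to p = 1 (equal
  means) or p = 0.
* Problem sizes: the shipped defaults (40 samples × 430 compounds,
  4×3 map, 150 epochs) make a full pipeline run take about two
  seconds; all randomness flows from a single integer seed.

## Known limitations

* The DME formula is an operationalization (per-variable KS at α =
  0.05); the original toolchain's exact definition is unpublished.
* Component selection uses Kaiser's rule only; no scree inspection or
  cross-validation is automated.
* The automatic peculiar-cluster rule is a proxy for a visual,
  expert-driven selection; `--manual` exists for the expert path.
* Online SOM training, rectangular lattices, U-matrix rendering and
  growing map variants are out of scope.
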