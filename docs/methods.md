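# Methods

This note documents the statistical model behind `trbdyn`, the numerical
choices made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Background and model

T-cell receptor β-chain (TRB) genes are assembled by V(D)J recombination.
Because junctional nucleotides are inserted essentially at random, roughly
one rearrangement in three keeps an open reading frame.  A peripheral T
cell therefore carries either one productive rearrangement with the second
allele in germ-line configuration, or one productive plus one
non-productive rearrangement.  Deep sequencing of rearranged TRB genes
from blood gives, per sample, a table of unique nucleotide sequences with
copy counts — and two views of T-cell population structure:

- **Status Diversity** — the evenness of the two-class split of copies
  into productive vs non-productive rearrangements.  A drop means
  productive copies dominate more, i.e. cells with a germ-line second
  allele have expanded relative to cells carrying a non-productive
  rearrangement.
- **Sequence Diversity** — the evenness of the clone-size distribution
  (clone = identical nucleotide sequence), restricted to productive
  clones.  A drop means a more clonal repertoire.

Both are Pielou evenness indices `J = H / ln S` with the bias-corrected
Shannon entropy

```
H = − Σ p_i ln p_i − (S − 1) / (2 N),
```

where `p_i` are class frequencies, `S` the number of classes and `N` the
total copy count.  The `(S−1)/(2N)` term removes the leading
finite-sample bias of the plug-in entropy; without it, shallowly
sequenced samples systematically look more even.  `H` and `J` are clamped
at zero (the subtraction can push degenerate cases negative; the raw
value is kept as a diagnostic).  For the status scheme `S` is fixed at 2
even when one class is empty; for the sequence scheme `S` is the observed
clone count — no unseen-species correction is applied, because the
downstream models normalize by observed classes.

## Curation

Sample level: repertoires lacking donor age or sex are excluded, and
samples with extreme total copy counts are screened with a *generalized
boxplot* suited to the strongly right-skewed depth distribution.  The
sample quantile function is modelled as an affine Tukey g-and-h transform
of standard normal quantiles, `Q(p) ≈ A + B·T_{g,h}(z_p)` with
`T_{g,h}(z) = (e^{gz}−1)/g · e^{hz²/2}`.  `g` (skewness) is estimated from
the ratio of upper to lower half-spreads — exact for this family and
independent of `h` — and `h` (tail weight) with the scale `B` from a
log-linear fit of the full spreads, using only quantiles between the
second order statistic and the 30% level so that a lone extreme sample
cannot drag the fit.  Fences are the fitted quantile function at
tail probabilities `α/2` and `1−α/2`; the default `α = 0.007` makes the
fences equivalent in coverage to the classical 1.5·IQR boxplot on
Gaussian data.  Flagging is two-sided.  Both `α` and the bulk range are
configurable; at least 8 samples are required, otherwise the screen must
be skipped explicitly.

Sequence level, in fixed attribution order: orphon V call; unresolved V;
unresolved J; indexing error (annotated non-templated N2 region starting
before the CDR3 start — both annotations must be present, since the rule
compares two annotated positions); V or J outside the functional
reference set; V on the exclusion list (TRBV03-01, excluded for extreme
rarity — exclusion wins over functional membership).  A record is charged
to the first rule it violates, so per-rule removed copies plus retained
copies equal the input exactly.  Records are collapsed into clones
(identical nucleotide sequence, copies summed) only after filtering.

The bundled gene reference is a constructed IMGT-style snapshot (43
functional V including the excluded TRBV03-01, 13 J, 2 D) — see
`data/trb_gene_reference_synthetic.json`; users with a current IMGT
export should load their own via `GeneReference.from_json`.

## Resampling

Both Monte-Carlo procedures draw **without replacement** from the finite
observed copy pool (multivariate hypergeometric over clones): this
matches finite-pool semantics and makes full-depth subsampling the exact
identity.  Replicates (default 100) use independent RNG streams spawned
from one recorded master seed; all outputs are bit-reproducible.

*Depth subsampling*: each repertoire is reduced to fixed coverages
(default 10⁴, 8×10⁴, 1.5×10⁵, 5×10⁵, 10⁶, 2×10⁶, 4×10⁶ copies); samples
shallower than a target are skipped at that depth and recorded.

*Whole-blood reconstitution*: sorted CD4/CD8 sub-repertoires of a donor
are merged according to the blood CD4/CD8 ratio r.  If the observed copy
ratio exceeds r, CD4 is overrepresented and `round(r·n_CD8)` copies are
drawn from it (all of CD8 kept); otherwise `round(n_CD4/r)` copies are
drawn from CD8.  Rounding is nearest-integer, ties to even (unbiased over
ratios).  The merged CD4 copy fraction equals `r/(1+r)` up to that
rounding.  Each replicate is re-collapsed (and optionally re-curated)
before the evenness indices are computed; the replicate means are the
final estimates.

## Cross-sectional models

Evenness is regressed on age by weighted least squares with per-sample
total copy counts as weights (deep samples carry more information).  The
full model is `J = β0 + β1·AGE + β2·SEX + β3·AGE·SEX` with men as
reference; model search is backward elimination on BIC respecting
marginality.  BIC is computed from the weighted Gaussian log-likelihood
with weights normalized to mean one and counts the residual variance as a
parameter (`k + 1` estimated quantities), matching the convention of
standard statistical software; this likelihood is invariant to weight
rescaling, so the criterion is scale-stable across subgroups.

The piecewise analysis brute-forces every age split (younger group =
ages ≤ split; integer years; minimum 5 samples per side), runs the BIC
selection within each side, and keeps the split with the minimal BIC sum;
ties go to the youngest split age.  Subgroups can make terms collinear
(single-sex or single-age strata); such terms are demoted, interactions
first, before selection starts.  Slope equality between two fits is
tested with `t = (β1a − β1b)/√(SE²a + SE²b)` and Welch–Satterthwaite
degrees of freedom from the two residual dfs.

The WLS solution, standard errors, F test and log-likelihood are computed
in closed form (the breakpoint scan refits thousands of small models);
the test suite pins the results to statsmodels OLS/WLS to 10⁻¹⁰.
Reported alongside each fit: the overall-F p-value, per-term t p-values,
and the unweighted Pearson correlation between age and the response.

## Longitudinal models

Repeated measures (six donors, three timepoints about a decade apart) are
fitted with linear mixed-effects models via statsmodels MixedLM:
fixed age, sex and age×sex (plus cell type and age×cell type for the
sorted-compartment analysis; references are men and CD4), a per-donor
random intercept, and for the compartment analysis an additional
per-donor CD8 intercept offset modelled as a variance component.
Estimation is by maximum likelihood, not REML, so likelihood-ratio
comparisons between fixed-effect structures are valid.  Backward
selection drops, one at a time, the removable fixed term with the largest
deletion p-value above α = 0.05 (configurable).

Two small-sample refinements matter at these design sizes (18–36
observations) and are deliberate package choices:

- Deletion p-values use the exact Gaussian identity
  `LR = n·ln(1 + F/df₂)` to refer the statistic to `F(1, df₂)` with
  `df₂ = n − p − q` (fixed effects + random-effect dimension), instead of
  χ²(1).  The χ² reference rejects a true null ~10% of the time at
  nominal 5% here; the F form is exact in the fixed-effects-only limit
  and close to nominal with random intercepts.
- Confidence intervals use t quantiles with containment degrees of
  freedom: between-donor terms (intercept, sex) against
  `n_donors − 2`, within-donor terms (anything involving age or cell
  type) against `n − n_donors − 2`.  Normal quantiles cover ~85–90% at
  this size; the containment-t intervals are close to nominal.

Boundary variance estimates produce a warning (component pinned near
zero), not an error; optimizers are cascaded (L-BFGS, Powell,
Nelder–Mead) because a boundary can make one optimizer's Hessian
singular.

Derived summaries are pure arithmetic on a coefficient table and work
identically on a fresh fit and on an imported table: a donor's *initial*
diversity is the model intercept at age zero (fixed intercept + sex
offset + predicted donor offset, plus the donor's CD8 offset when
summarizing CD8), summarized as mean ± SD (n−1) over each sex's donors;
the per-year group slope is `β1 + β3·[female] + β4·[CD8]`.  Reporting is
rounded to 4 decimals.  The intraclass correlation of a grouping is its
variance share of the total (all components plus residual, one shared
denominator).  A reference coefficient table for the six-donor design is
bundled for the worked example and regression tests.

## Synthetic data

The generator produces data with exactly the structure the models assume,
at the level each consumer needs.

*Status trend*: the target status evenness follows a two-segment age law —
each segment has its own intercept and slope, the form the piecewise
regression fits — plus a Gaussian per-donor effect truncated to keep J in
(0, 1).  Defaults: young segment `0.6817 − 0.0060·age` up to the
breakpoint at 18, old segment `0.6227 − 0.0003·age`, donor SD 0.025.
The segment magnitudes are the fitted cross-sectional values; the donor
SD is calibrated so the young-segment age–evenness correlation (~0.75)
sits at the strong end of the observed 0.6–0.7 band, which makes the
breakpoint reliably identifiable at cohort scale (with a donor SD of
0.04 the recovered split scatters over ±6 years).  The target is
inverted to a productive-copy fraction by bisection on the two-class
evenness (tolerance 10⁻¹⁰) and realized as a binomial draw at the
sample's depth — so depth-dependent sampling noise is genuine, not
added.

*Sequence trend*: clone sizes follow a discretized power law
`w_i ∝ i^(−s)`; the exponent is obtained from the target evenness by
inversion on a cached monotone grid.  The default cohort law uses 20,000
clones and a linear target `0.9519 − 0.0014·age` (donor SD 0.03),
spanning roughly 0.89–0.97 over the age range.  Realized values are
multinomial draws over the law at the sample's productive copy count,
evaluated with the observed clone count, exactly as the estimator sees
real records.

*Depths*: log-uniform over 5×10⁵–8×10⁶ copies by default, the observed
coverage range.  Ages are uniform integers over 1–74 by default (the
observed range; the real cohort is adult-skewed, which the generator does
not reproduce unless given explicit ages).  Sex is Bernoulli(0.47
female).

*Single-repertoire defaults* (used by the coverage study): 6×10⁵ copies,
productive fraction 0.84 (status J ≈ 0.63), 300 clones at exponent 0.57
(sequence J ≈ 0.95).  The richness is deliberately coarse so the
shallowest study coverage still samples every clone ~30 times on
average; in that regime the corrected evenness is comparable across
depths (observed drift < 0.01 across 10⁴–5×10⁵).  Real repertoires are
far richer; at depths where many clones are seen zero or one time the
index genuinely shifts, which is why the depth study exists.

*Contamination*: records violating each curation rule can be injected at
target copy fractions (each category violates exactly its own rule, so
attribution is testable); the default profile mirrors the filtration
shares seen in vendor whole-blood exports, with unresolved V calls
dominating (~22%).

*Longitudinal*: three men and three women, start ages uniform on 24–45,
three timepoints 10 years apart; donor (and CD8-offset) effects Gaussian;
residual SD 0.005 on the J scale; blood CD4/CD8 ratio lognormal around 2.
Table-level generation samples the evenness values at a configurable
depth (default 2×10⁵ copies, 5,000 clones — scaled below the study's
~2×10⁶ to keep replicate simulation fast); repertoire-level generation
emits sorted CD4/CD8 pairs whose reconstituted merge follows the embedded
whole-blood model.

What passing tests on this generator do **not** show about real data:
V(D)J junction sequences are placeholders (no biological sequence
structure, no shared clones between donors, no naive/memory compartment
structure); the clone law is a single-parameter power law rather than the
heavier, mixture-like distributions of real repertoires; metadata
missingness and batch effects are not modelled.

## Numerical choices and degenerate inputs

- Entropy uses natural logs throughout; `0·ln 0 = 0`.
- Evenness undefined for a single class (error), clamped to [0, 1]
  otherwise.
- Gene names are canonicalized (vendor prefix, zero-padding, allele
  suffix stripped for matching, orphon suffix preserved) before set
  membership tests; unresolved calls use an explicit sentinel.
- Sequence indices are 0-based half-open internally; AIRR columns are
  converted from 1-based on read.
- Subsampling to the full depth is the identity; a zero draw from a
  compartment (extreme blood ratio) yields the other compartment exactly.
- BIC ties in the piecewise scan break toward the youngest split age;
  BIC ties in backward elimination break by the fixed term order.
- Empty post-curation repertoires are flagged in the report, not raised,
  so cohort runs continue.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to exercise the claimed
property while keeping the suite fast: breakpoint recovery uses 200
cohorts of 480 donors with 2,000-clone laws at depths 5×10⁴–2×10⁵;
mixed-model coverage uses 200 replicates of the 6×3 table-level design;
the depth study uses the default single repertoire with 100 replicates
per coverage.  These are the package's standard validation sizes and are
reproduced by `scripts/acceptance.py`.

## Known limitations

- The generalized-boxplot parameters (α, bulk range) are defaults chosen
  for classical-boxplot-equivalent coverage, not values fitted to any
  particular cohort.
- The mixed models use random intercepts only (no random slopes), as in
  the analysis they implement.
- Breakpoint search considers exactly one split and reports the argmin;
  no uncertainty interval for the split age is produced.
- The per-donor initial-diversity SD treats predicted random intercepts
  (BLUPs) as observations; shrinkage makes this an underestimate of the
  population SD when the residual variance is large.
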