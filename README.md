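# trbdyn

Age- and sex-specific dynamics of the human peripheral T-cell repertoire,
from deep-sequenced rearranged TRB (T-cell receptor β-chain) genes.

`trbdyn` is for immunologists and computational biologists who have
immunoSEQ-style or AIRR-standard rearrangement tables (one row per unique
nucleotide sequence, with copy counts, V/D/J gene calls and frame status)
and want to ask how T-lymphocyte proliferation and clonality change with
age, and whether men and women differ.  It provides, as a tested
library + CLI pipeline:

- **Curation** — sample-level filters (missing age/sex; depth outliers via
  a generalized boxplot for skewed distributions) and sequence-level
  filters (orphon V genes, unresolved calls, indexing errors,
  non-functional/ORF genes, the excluded TRBV03-01), with a per-filter
  copy-conserving report.
- **Diversity** — two evenness summaries per sample, both Pielou indices
  `J = H/ln S` with bias-corrected Shannon entropy
  `H = −Σ pᵢ ln pᵢ − (S−1)/(2N)`:
  *Status Diversity* (S = 2: productive vs non-productive copy counts,
  tracking the balance of cells that needed one vs two rearrangement
  attempts) and *Sequence Diversity* (S = number of clones, tracking
  clonality).
- **Resampling** — subsampling to fixed coverages (hypergeometric,
  without replacement, 100 replicates averaged) to show depth robustness,
  and "reconstitution" of whole-blood repertoires from sorted CD4/CD8
  samples using the blood CD4/CD8 ratio.
- **Cross-sectional models** — weighted linear regression of evenness on
  age (weights = total copy counts), BIC backward selection over
  age/sex/interaction, brute-force piecewise breakpoint search (min 5 per
  subgroup), and slope-equality t-tests.
- **Longitudinal models** — linear mixed-effects models (ML) with donor
  (and donor×cell-type) random intercepts, likelihood-ratio backward
  selection, intraclass correlations, and the derived per-group "initial
  diversity mean ± SD" and per-year slope summaries.
- **Synthetic cohorts** — a generator that embeds known age/sex laws in
  realistic repertoire structure, so the whole pipeline is validated by
  parameter recovery without any external download.

## Worked example

The bundled reference coefficient table describes the final longitudinal
mixed model for Status Diversity in six donors (three men, three women,
sampled three times about a decade apart):

```python
from trbdyn import (load_reference_coefficients,
                    summarize_initial_diversity, slope_for_group)
from trbdyn.synthetic import CohortParams, simulate_cohort
from trbdyn.regression import ModelSpec, piecewise_search

status = load_reference_coefficients("status", "whole_blood")
for sex in ("female", "male"):
    s = summarize_initial_diversity(status, sex)
    print(f"{sex:>6}: initial Status Diversity {s.mean_initial:.4f} "
          f"+/- {s.sd_initial:.4f}, slope {slope_for_group(status, sex):+.4f} per year")

table, truth = simulate_cohort(CohortParams(n_donors=487), seed=1)
pw = piecewise_search(table, ModelSpec(response="status_J"), min_group=5)
print(f"best age split: {pw.split_age} (BIC sum {pw.bic_sum:.1f})")
print(f"younger fit: J = {pw.younger.params['Intercept']:.4f} "
      f"{pw.younger.params['AGE']:+.4f} * age  (n={pw.n_younger})")
print(f"older fit:   J = {pw.older.params['Intercept']:.4f} "
      f"{pw.older.params.get('AGE', 0.0):+.5f} * age  (n={pw.n_older})")
```

prints

```
female: initial Status Diversity 0.6652 +/- 0.0108, slope -0.0007 per year
  male: initial Status Diversity 0.5823 +/- 0.0558, slope +0.0004 per year
best age split: 18 (BIC sum -2002.6)
younger fit: J = 0.7056 -0.0090 * age  (n=107)
older fit:   J = 0.6197 -0.00023 * age  (n=380)
```

Reading: women start adult life with a higher and much less variable
productive/non-productive balance than men (0.6652 ± 0.0108 vs
0.5823 ± 0.0558) and their Status Diversity declines slowly
(−0.0007/year) while men's is flat-to-rising (+0.0004/year).  On the
synthetic cross-sectional cohort — generated with a steep evenness
decline up to age 18 and near-stability afterwards — the brute-force
piecewise search recovers the age-18 breakpoint: a strong negative young
slope and an essentially flat adult slope.

The same stages are available from a shell:

```bash
trbdyn simulate cohort --out demo --seed 1 --n-donors 30 --depth 50000 --n-clones 2000
trbdyn diversity demo/manifest.tsv --out demo/diversity.tsv
trbdyn curate demo/manifest.tsv --out demo/curation.json --no-outlier-screen
```

and the full cross-sectional / longitudinal pipelines run from a YAML
config via `trbdyn fit-cross-sectional` / `trbdyn fit-longitudinal`.

## Documentation

`docs/methods.md` documents the estimators, the regression and
mixed-model conventions (including the small-sample choices), what the
synthetic generator emulates and what it deliberately does not, and known
limitations.
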