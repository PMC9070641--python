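# Methods

## Model and procedure

`pcgrn` infers a layered TF → target hierarchy from a normalized
genes × samples expression matrix by a triple-gene screen:

1. **Co-expression.** For every unordered pair of genes in the current
   bottom layer, compute the sample Pearson correlation r_xy over all
   samples and its two-sided p-value from t = r·√((n−2)/(1−r²)) with n−2
   degrees of freedom. A pair passes when r_xy ≥ `cc_min` (default 0.8) and
   p < `cc_pval_max` (default 0.001).
2. **Breaking.** For each passing pair (x, y) and each candidate regulator
   z, compute the first-order partial correlation
   r_xy|z = (r_xy − r_xz·r_yz)/(√(1−r_xz²)·√(1−r_yz²)). The candidate
   breaks the pair when |r_xy|z| < `pcc_max` (default 0.3): the pair's
   shared behavior is accounted for by z.
3. **Layer assembly.** Every candidate breaking ≥ `min_pairs_broken`
   (default 1) pairs is assigned to the next layer up, with edges to the
   members of each pair it broke. Assigned regulators leave the candidate
   pool (layers are disjoint), become the new bottom, and the procedure
   repeats until `n_layers` (default 3) layers exist or a round assigns
   nobody — then construction stops gracefully with the layers found.

The underlying assumption is linear co-regulation: two targets of the same
TF inherit its profile, so they correlate marginally but decorrelate once
the TF is partialled out. Only adjacent-layer, downward edges are modeled;
within-layer and layer-skipping regulation is knowingly outside the model.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `cc_min` | 0.8 | minimum Pearson r for a co-expressed pair (unitless, signed) |
| `cc_pval_max` | 0.001 | raw two-sided p-value cut for pairs; no multiplicity correction by design |
| `pcc_max` | 0.3 | partial-correlation magnitude below which a pair counts as broken |
| `use_absolute_cc` | off | screen on \|r\| instead of r (captures strong repression) |
| `use_absolute_pcc` | on | breaking judged on \|r_xy\|z\| — "destroyed" co-expression is about magnitude |
| `min_pairs_broken` | 1 | pairs a TF must break to be assigned; raise for stringency |
| `n_layers` | 3 | hierarchy depth attempted |
| `epsilon_degenerate` | 1e-8 | collinearity guard on 1 − r² denominators |

All samples (time points × replicates) are treated as independent
observations for the correlation test. This is deliberate: with ~5 time
points and 3 replicates, n = 15 observations make p < 0.001 attainable at
r ≈ 0.8, whereas replicate-averaged time points (n = 5, df = 3) could
essentially never reach it.

Expression values are assumed already normalized between samples (e.g.
TMM-scaled log-CPM); correlations are invariant to per-gene affine scaling,
so no within-gene normalization is needed. A counts-per-million prefilter
(`cpm_filter`, inclusive boundary, CPM ≥ 1 in ≥ 1 sample by default) is
provided for raw counts.

## Degenerate conditioning: the collinear limit rule

The partial-correlation formula is 0/0 when a pair member is exactly
collinear with the conditioning gene. The pure-numeric `partial_cc`
returns an undefined marker there. The data-driven breaking test instead
resolves the limit: if x = αz exactly, then r_xy = r_xz·r_yz identically
and adding infinitesimal independent noise to x drives r_xy|z → 0, so the
test reports pcc = 0 and the pair as broken — the candidate fully explains
that member. Without this rule a noiseless single-parent target could
never be attributed to its regulator.

## The synthetic benchmark

`generate_planted_network` samples a layered DAG (default layer sizes
(2, 4, 12), fan-out 3): each regulator picks `fan_out` distinct targets in
the next layer; a repair pass gives every orphan one random parent.
Weights are uniform on (0.5, 1.5) — moderate, positive, bounded away from
zero, so regulation is activating and the signed co-expression screen is
the natural default.

`simulate_expression` gives top-layer genes random smooth time profiles
(low-order polynomial + sinusoid), Gram–Schmidt-orthonormalized so they
are linearly independent, then standardized over samples. Every other
gene's observed profile is the weighted sum of its parents' **observed**
profiles plus replicate-level white noise with sd = `noise_sd` × sd of its
signal. Defaults: 8 time points × 3 replicates (n = 24; a time course of
about five points and three replicates is the emulated design, but a
slightly longer course gives the p < 0.001 screen realistic power at
r ≈ 0.8) and relative noise 0.1.

Children reading their parents' *noisy* profiles (rather than noise-free
signals) is the biologically sensible replicate model — variation in the
TF's actual expression propagates to its targets — and it is what makes
*direct* regulation identifiable: conditioning on the direct parent
removes the shared replicate noise; conditioning on a grandparent leaves
it, keeping the pair correlated.

What the simulator does **not** emulate: count-level sampling and
library-size effects, nonlinear or combinatorial (AND/OR) regulation,
feedback, within-layer regulation, and confounding covariates. Passing
recovery tests therefore demonstrate correctness of the screen under its
own linear assumptions, not performance on real RNA-seq.

## What recovery the method can and cannot achieve

Two limits are intrinsic, not implementation artifacts:

- **Noise-free rank collapse.** With k top-layer genes and zero noise the
  whole matrix has rank k. For k = 2, conditioning on any gene leaves
  rank-≤1 residuals, so every defined partial correlation is ±1 and only
  exact-collinearity limits break; moreover a single-parent middle TF is
  *exactly* collinear with its top parent and the two are
  information-theoretically indistinguishable. Exact noise-free recovery
  of a three-layer hierarchy with a 2-gene top layer is therefore
  impossible in principle; the corresponding check in the acceptance
  suite documents this as a failing expectation.
- **Grandparent absorption.** A top TF whose signal reaches bottom genes
  through a middle TF often breaks at least one bottom pair itself
  (first-order conditioning cannot always separate parent from
  grandparent). With `min_pairs_broken` = 1 it is then absorbed into the
  first inferred TF layer. Across 20 simulated replicates at noise 0.1
  this caps mean layer-membership accuracy near 16/18 ≈ 0.89 while mean
  TF → structural edge recall stays near 0.89. Raising
  `min_pairs_broken` trades this confound against sensitivity.

Measured, not asserted: both figures are recomputed by
`scripts/acceptance.py` and the acceptance tests on every run.

## Numerical and design choices

- Pearson r is computed on normalized centered vectors (exact ±1.0 under
  exact linear dependence) and clipped to [−1, 1]; p = 0 exactly at
  |r| = 1.
- All loops iterate in lexicographic gene-id order; outputs are
  deterministic across platforms and byte-stable for a fixed seed.
  Serialized floats use 6 significant digits in report files and 10–17 in
  expression tables (full round-trip fidelity).
- The correlation matrix for a layer inference round is computed once for
  bottom ∪ candidates; the per-pair API (`find_breaking_regulators`) uses
  the same decision helper so both routes agree.
- Zero-variance profiles and n < 3 are errors naming the offender;
  a bottom layer with < 2 genes yields an empty assignment with a warning.
- The catalog forbids a gene from being both regulator and structural, so
  a bottom gene can never re-enter as a candidate; candidates are checked
  against pair membership anyway.

## Known limitations

- Edge precision is modest by construction: a TF that breaks a pair is
  credited with *both* members, including ones it does not directly
  regulate. Evidence counts (`n_supporting_pairs`, `min_abs_pcc`) are
  exported so users can post-filter.
- Only first-order conditioning is implemented; pairs co-driven by two
  regulators are never broken (no higher-order partial correlations, no
  Gaussian graphical model).
- The p-value treats replicate samples as independent observations; the
  effective degrees of freedom are somewhat lower.
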