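# Methods

## Ontology model and information content

The ontology is restricted to `is_a` edges and treated as a set of
disjoint rooted sub-DAGs, one per semantic aspect; a root is any term with
no parent, and every term must reach exactly one root (violations raise
structural errors naming a cycle member or an unrooted term). Obsolete
terms are dropped at parse time and `alt_id`s map onto canonical ids.

Term specificity is intrinsic (descendant-count) information content:
`IC(t) = 1 − log(hypo(t)+1) / log(maxnodes)` with `hypo(t)` the number of
descendants including the term itself. Two conventions needed fixing:

* **maxnodes scope.** By default `maxnodes` counts the term's aspect
  sub-ontology, matching the per-aspect similarity computation; a
  whole-ontology count is available via `compute_ic(..., per_aspect=False)`
  for ontologies treated as one namespace.
* **Root clamping.** As written the formula gives the root a slightly
  negative value (`hypo(root)+1 > maxnodes`). We clamp at 0 so IC stays in
  [0, 1] and SimGIC keeps its bounds; the raw value is retained in
  `ic_raw` and `compute_ic(..., clamp=False)` disables clamping.

Ancestor closures are reflexive (`t ∈ A(t)`), the standard MICA convention;
it makes `sim(t, t) = IC(t)` and identical annotation sets maximally
similar. Closures are cached per graph; the cache is observationally
equivalent to recomputation because graphs are immutable once built (the
test suite checks the cached path against a cache-free naive oracle).

## Similarity measures

SimGIC uses extended (direct + inherited) annotation sets; the Resnik
variants use direct sets, the field-standard choice for pairwise measures
(both configurable via `annotation_mode`). An entity with no annotations
in an aspect scores 0 in that aspect; pairs unannotated in *every* aspect
must be removed beforehand by the annotation filter (`filter_pairs`), which
keeps a pair only when both entities have at least one direct annotation in
at least one aspect. The best-match-average form is
`Σ_{t₁} max_{t₂} sim / 2|GO(p₁)| + Σ_{t₂} max_{t₁} sim / 2|GO(p₂)|`;
empty sets score 0.

## GP combiner

A vanilla generational tree-GP system in regression mode: 0/1 labels are
numeric targets, raw fitness is RMSE, and selection uses the penalized
value `RMSE + c·(node count)` with parsimony coefficient `c = 10⁻⁵`
(reported fitness stays unpenalized). Headline parameters: population 500,
50 generations, function set `{add, sub, mul, div, max, min}` (all binary;
division is protected — returns 1 when |denominator| ≤ 10⁻³). The remaining
machinery follows the conventional defaults of vanilla GP systems and is
fully exposed in `GPParams`:

| parameter | default | note |
|---|---|---|
| tournament size | 20 | with replacement, penalized fitness |
| initialization | ramped half-and-half, depths 2–6 | terminals: variables and ephemeral constants, constant picked with probability 1/(n_vars+1) |
| crossover | 0.9 | donor from a second tournament; crossover/mutation points drawn with the 90/10 internal-node weighting |
| subtree mutation | 0.01 | grafts a full ramped program |
| hoist mutation | 0.01 | lifts a random sub-subtree |
| point mutation | 0.01 | per-node replacement probability 0.05 |
| constants | uniform on [−1, 1] | `constant_range=None` disables |
| size cap | 512 nodes | oversized offspring are replaced by their parent |

The best-ever individual by penalized fitness is returned (elitist
bookkeeping), so the recorded best-fitness trajectory is non-increasing by
construction. Classification applies a strict cutoff: raw output > 0.5 ⇒
class 1; exactly 0.5 resolves to class 0. Single-class training labels
raise by default (`on_single_class="constant"` returns a constant model
with a warning instead).

**Simplification** is deliberately conservative: constant folding (with
protected-division semantics), additive/multiplicative identities and
annihilators, `x − x = 0`, and max/min idempotence, iterated to a fixed
point. No distribution laws are applied, so every rewrite is an exact
pointwise equality — verified by random probing on the unit cube. Model
statistics (node count, per-variable share of variable leaves) are intended
for simplified models; node count is taken after simplification.

## Baselines

Static combinations (BP, CC, MF, Avg, Max) learn their classification
threshold on the training set by scanning 0.00–1.00 in steps of 0.01
(finer than the grid search, cheap, reproducible) and keeping the smallest
WAF-maximizing threshold. The exhaustive search enumerates weight triples
on a 0.1 grid (11³ − 1 = 1330, the all-zero triple is excluded as the
weighted average `Σwᵢsᵢ/Σwᵢ` is undefined there) × 21 thresholds on a 0.05
grid, classifying by strict threshold exceedance; ties resolve to the first
candidate in lexicographic (w_BP, w_CC, w_MF, threshold) order so the
result is deterministic under a fixed enumeration order. The decision tree
is the standard CART implementation with default parameters — a comparison
baseline, not a contribution.

## Evaluation protocol

Pairs are unordered throughout (canonical sorted storage), which makes
(A, B) and (B, A) the same pair for within-dataset deduplication (exact
duplicate rows are dropped at load with a logged count) and for cross-
dataset overlap removal. `dedup_across` removes overlap from the training
side by default, preserving the integrity of the reported test set.

WAF is the support-weighted mean of per-class F-measures; a class with no
true and no predicted members contributes F = 0 (standard zero-division
convention). Cross-validation is stratified 10-fold with folds pinned by a
seed, so the same folds serve every method; when a class has fewer members
than k the split still partitions the data with a logged warning (some
folds then miss that class). Method comparison uses the two-sample form of
the Kruskal–Wallis test on fold scores at α = 0.01; identical constant
score vectors short-circuit to (statistic 0, not significant) since the
rank test is undefined there. The cross-dataset protocol trains once per
seed for stochastic methods and once in total for deterministic ones.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes:

* **Ontology** — per aspect, a rooted DAG grown by attaching each new term
  to 1..`max_parents` existing terms; acyclic by construction. Defaults: 3
  aspects × 100 terms, `max_parents` 2.
* **Annotations** — per entity and aspect, annotation occurs with a
  configurable probability (sparsity control; lowering one aspect's
  probability reproduces the degradation of that aspect's single-aspect
  baseline seen on sparsely-annotated organisms); direct terms (2–4 by
  default) are drawn with weight ∝ IC + 0.01, biasing toward leaves so
  that entity similarities spread over [0, 1] instead of clustering near
  zero. Entities that come out empty everywhere are resampled.
* **Pairs** — candidate unordered pairs are shuffled and scored; the label
  is a ground-truth rule written in the same expression language as the
  evolved models (default `max(BP, CC)` with threshold 0.6), then flipped
  with the label-noise probability (default 0.05). Unbalanced sampling
  draws negatives uniformly; balanced sampling greedily matches per-entity
  occurrence counts between classes (strictly — no entity ends up with
  more negative than positive occurrences — so the negative set can come
  up short when the pool is exhausted; exact matching is NP-hard in
  general). Defaults: 120 entities, 1000 pairs — enough distinct unordered
  pairs to sample without replacement.

What the generator does **not** emulate: real GO topology (term-depth
distributions, DAG density), annotation evidence codes, species structure,
or the bimodal similarity distributions of curated interaction datasets —
synthetic labels derive from the similarity scores themselves, so score
mass sits near the decision boundary in a way real PPI data need not.
Passing tests therefore demonstrate internal correctness and
recoverability, not real-data performance.

## Problem sizes and numerical choices

The test suite and acceptance script run on deliberately small worlds
(30–100 terms per aspect, 20–120 entities, 150–1000 pairs; GP at
population 200 / 30 generations, 3 seeded runs) — sizes at which the
brute-force oracles remain exactly computable and the full suite completes
in well under a minute apart from the recovery experiment. Floating-point
comparisons against the oracles use 1e-12 absolute tolerance; probe-based
simplification equivalence uses 1e-9 over 1000 points; grid values are
rounded to 10 decimals before comparison so 0.1-step grids are exact.

## Known limitations

* The GP threshold-rule recovery experiment (truth `1[max(BP,CC) > 0.6]`,
  5% noise) plateaus at a pooled median test WAF of roughly 0.80–0.90
  rather than converging to the 0.95 noise ceiling. The cause is a
  property of the method itself: the plain `max(X0, X1)` model is a strong
  RMSE attractor (a linear ramp crossing the 0.5 cutoff at 0.6 classifies
  far better but has *worse* RMSE, so selection rejects it), and the only
  lower-RMSE region — saturating step-like compositions — is rarely
  reached at desk-scale budgets. The engine itself is validated: it solves
  `x₀² − x₁² + x₁ − 1` exactly within ten generations, and all recovery
  runs comfortably beat the uninformative single-aspect baseline.
* IC descendant counts use per-node graph traversal; fine for ontologies
  up to tens of thousands of terms, not optimized for much larger graphs.
* GAF parsing accepts all evidence codes by default (an evidence filter is
  available but no curated defaults are shipped).
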