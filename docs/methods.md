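# Methods

## The heterogeneous network

The method operates on a tripartite structure: an entity (lncRNA)
similarity network **L**, a partner (protein) interaction network **P**,
and a bipartite association matrix **A** connecting the two node sets.
All matrices are carried with explicit ordered identifier lists; axes
follow first-appearance order in the input files, which makes every
downstream matrix, ranking and report deterministic for given inputs.

**Similarity network.** L[i,j] = max(0, PCC) of the two entities'
expression profiles. Negative correlations are clamped to zero rather
than kept as magnitudes: the walk requires non-negative weights and an
anti-correlated pair is weak, not strong, evidence of shared function
under the co-expression assumption (`negative="abs"` is available for
users who prefer the magnitude convention). Zero-variance profiles get
similarity 0 everywhere. By default each entity keeps only its 50
strongest neighbours, after which the matrix is re-symmetrized by
elementwise max; at genome scale the bulk of a dense PCC matrix is
noise, and sparsification changes nothing on inputs with fewer than ~50
entities. `top_k=None` disables it.

**Partner network.** Raw edge confidences are rescaled by the maximum
observed weight and thresholded at 0.4 by default — the conventional
"medium confidence" cut for STRING-style scores, where weights are
integers up to ~1000. A binary mode sets surviving edges to 1.

**Associations.** Interaction evidence contributes entries of 1.
Multi-source co-expression is first aggregated per pair as
C = 1 − ∏(1 − Cₖ) over the sources where the pair is *positively*
correlated (negative scores are excluded from the product entirely);
pairs at or above the aggregation threshold (default 0.5 — the
association call needs a cutoff and 0.5 marks a pair better-than-even
under the noisy-OR reading of the aggregate) enter A as 1 in the
default binary mode, or as C in weighted mode. The binary default
reflects A's role as a membership matrix of known associations; both
evidence channels are recorded in a provenance matrix.

## The bi-random walk

Both networks are normalized symmetrically, M_N = D⁻¹ᐟ² M D⁻¹ᐟ², with
d_i the row sums and the 0/0 := 0 convention for isolated nodes. The
symmetric form follows the bi-random-walk lineage this method belongs
to and keeps the propagation operator's spectral radius at most 1; a
row-stochastic option (D⁻¹M) exists behind `normalization="row"`. The
seed A₀ = A / ΣA is a single probability mass over all known
associations — global-sum, not per-row, normalization — and serves as
both the initial state and the restart term (a raw-A restart is
available for sensitivity analysis only).

The update is

    R_L = α · L_N · R_{t−1} + (1 − α) · A₀     while t ≤ l
    R_P = α · R_{t−1} · P_N + (1 − α) · A₀     while t ≤ r

with R_t the unweighted average of whichever states were computed that
step, and exactly max(l, r) iterations run: the step caps are the
termination rule, not a convergence tolerance, because the caps — not
the fixed point — bound the circular-bigraph length being scored. The
averaging rule for the asymmetric tail (when one cap is exhausted, the
surviving walk's state is taken alone) is the single most consequential
reconstruction choice in the package; the test suite pins it against an
independent dense implementation of the same recurrences.

Parameter defaults: α = 0.8 (decay; dampens long paths), l = r = 2
(short circular bigraphs capture most true associations), all unitless.
`alpha=0` degenerates to the normalized seed exactly; `alpha=1` removes
the restart.

## Annotation transfer

For each entity the N = 47 highest-scoring partners are selected
(descending score, ties broken by partner id; zero-score partners are
excluded even if N is unfilled, since their transfer weight would be
zero anyway). A term T scores the sum of the selected neighbours'
normalized weights, Σᵢ Sᵢ/Σⱼ Sⱼ · Indᵢ(T). A neighbour without
annotations still contributes to the denominator — the printed form of
the weighting sums over all N selected neighbours — which conservatively
dilutes scores for entities whose neighbourhood is poorly annotated; the
alternative (renormalizing over annotated neighbours only) would inflate
them. Scores therefore lie in (0, 1], reaching 1 exactly when every
selected neighbour carries the term. Terms are flat labels: there is no
propagation to GO ancestors and no DAG-aware credit anywhere in scoring
or evaluation. Aspect (P/F/C) and evidence-code filtering are options of
the GAF reader, both off by default.

## Evaluation

Per entity, Pr_i(t) and Rc_i(t) are set precision/recall of the terms
scoring ≥ t against the truth set. Averaged precision Pr(t) runs over
the z(t) entities with at least one prediction at the threshold;
averaged recall Rc(t) runs over all N benchmark entities. Fmax is the
maximum over thresholds of 2·Pr·Rc/(Pr+Rc), with F := 0 where both
vanish. Membership uses the closed comparison (score ≥ t) so t = 1 can
return perfect predictions; a strict mode exists. The default grid is
101 evenly spaced thresholds plus every distinct predicted score, which
guarantees the true maximum is attained; among ties the smallest
optimal threshold is reported. Coverage counts entities with at least
one *correct* term at the Fmax threshold. When z(t) = 0, Pr(t) is
reported as 0 (no entity to average over).

The ablation driver retains a uniformly random ⌊E·f⌋ of the partner
edges (seeded) and reruns the entire pipeline; f = 0 leaves every
partner isolated, so the right walk contributes only its restart term.

## The synthetic data generator

The generator emulates the statistical structure the method assumes —
functional modules spanning both node sets — and nothing else. Entities
and partners are partitioned into `n_modules` contiguous blocks; each
module has a latent standard-normal condition profile, and every
expression row is `within_module_corr · latent + noise_sd · ε`
(defaults 0.7 and 0.3, giving within-module PCC ≈ 0.85). Co-expression
sources are independent noisy re-realizations of the same latent
structure. Partner edges are dense within modules (p = 0.3, confidence
600–999) and sparse between (p = 0.02, confidence 150–399), so the
default 0.4 confidence cut removes cross-module noise edges.
Associations are sampled within modules at density 0.15 and a fixed
20% of them withheld as link-recovery truth; each module owns a
disjoint block of GO terms (60 terms over 6 modules), partners carry 4
terms sampled from their block, and the benchmark assigns each entity
its module's full block. Defaults: 120 entities, 120 partners, 24
conditions.

Two deliberate simplifications matter for interpreting results. First,
degree distributions, tissue-specific expression and GO DAG topology
are not modelled, so passing tests demonstrate correctness of the
machinery, not expected performance on real data, where the
module-signal is far weaker and confounded. Second, the generated
co-expression sources reflect the same latent modules that planted the
hidden associations; feeding them into the association matrix would
leak the withheld links, so the bundled pipeline adapter excludes them
from recovery and ablation studies by default (`include_coexpr=True`
opts in). AUROC negatives are sampled cross-module, which the
generative model guarantees are true negatives.

The reference study sizes used by the test suite and the acceptance
script — 120×120 nodes, 6 modules, 20 seeded replicates — are the
package's chosen balance between statistical stability of the seed
means and a suite that runs in about a minute.

## Numerical choices

* 0/0 := 0 throughout normalization; isolated nodes neither emit nor
  absorb mass.
* Walk output is clipped at 0 to remove negative float dust; term
  scores are capped at 1 for the same reason.
* All rankings break ties by id lexicographic order; writers emit 12
  significant digits, which round-trips exactly through the readers.
* Transpose symmetry of the walk (swap L↔P, A↔Aᵀ, l↔r) holds to
  machine rounding, not bitwise, because matmul summation order differs
  between the two orientations.
* Conflicting duplicate edge weights are hard errors, not last-wins.

## Known limitations

* No GO hierarchy: ancestors are neither propagated nor partially
  credited.
* The walk stores dense u×v score matrices; at 10⁵×10⁴ scale the score
  matrix itself (not the sparse networks) becomes the memory bound.
* The association aggregation treats all co-expression sources as
  exchangeable; there is no per-source reliability weighting.
* Entities absent from the expression matrix cannot be scored, and
  partners absent from all inputs are silently outside the universe.
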