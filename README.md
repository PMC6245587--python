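# lncwalk

Function prediction for long non-coding RNAs (lncRNAs) by bi-random walk
on a global heterogeneous network.

Most lncRNAs have no experimentally characterized function. Because
lncRNAs that are co-expressed with, or physically associated to,
protein-coding genes tend to share their biology ("guilt by
association"), a practical route to annotation is to score how strongly
each lncRNA is linked to each *protein* in a joint network, and then
transfer the proteins' Gene Ontology (GO) terms to the lncRNA. `lncwalk`
implements that pipeline end to end for anyone working on lncRNA
functional genomics: build the network from expression and interaction
data, propagate, transfer, evaluate.

## The model

Three matrices define a global heterogeneous network:

* **L** (u×u) — lncRNA similarity, from pairwise Pearson correlation of
  expression profiles (negative correlations clamped to zero);
* **P** (v×v) — protein–protein interactions, from a weighted edge list
  (e.g. STRING-style confidence scores rescaled to [0, 1]);
* **A** (u×v) — known lncRNA–protein associations, assembled from
  interaction evidence and multi-source co-expression aggregated as
  C(l,p) = 1 − ∏ₖ(1 − Cₖ(l,p)) over positively correlated sources.

With L_N and P_N the symmetrically degree-normalized networks
(D⁻¹ᐟ² M D⁻¹ᐟ²) and A₀ = A / ΣA the normalized seed, the bi-random walk
iterates, for t = 1 … max(l, r):

    R_L = α · L_N · R_{t−1} + (1 − α) · A₀        (left walk,  while t ≤ l)
    R_P = α · R_{t−1} · P_N + (1 − α) · A₀        (right walk, while t ≤ r)

averaging the active walks into R_t. The decay factor α weighs
propagation against restart; the per-side step caps l and r bound the
length of the circular-bigraph paths the walk can credit. Defaults are
α = 0.8, l = r = 2.

Each lncRNA then inherits GO terms from its top N = 47 scoring proteins:
term T scores P(T) = Σᵢ wᵢ·Indᵢ(T), with wᵢ the neighbour's normalized
relevance score and Indᵢ(T) indicating annotation. Predictions are
evaluated with threshold-averaged precision/recall, their maximum
F-measure (Fmax), and coverage (entities with ≥ 1 correct term).

## Worked example

A fully synthetic study with planted lncRNA/protein modules (the package
generates its own data; no downloads):

```python
import lncwalk as lw
from lncwalk.simulate import to_pipeline_inputs

dataset = lw.generate(lw.SynthConfig(seed=1))       # 120 lncRNAs, 120 proteins, 6 modules
inputs = to_pipeline_inputs(dataset)
scores, predictions = lw.run_pipeline(inputs)        # build -> walk -> transfer

print("recovery AUC", lw.recovery_auc(scores, dataset.truth, seed=1))
result = lw.fmax(predictions, dataset.truth.benchmark)
print("Fmax", result.fmax, "at t =", result.fmax_threshold)
print("coverage", result.coverage_fraction)
```

prints

```
recovery AUC 0.9972760775516745
Fmax 0.9891456205607029 at t = 0.1191519395669062
coverage 1.0
```

The recovery AUC says the walk ranks the 20% of associations that were
withheld from A far above random cross-module pairs; Fmax ≈ 0.99 at
threshold ≈ 0.12 and coverage 1.0 say the transferred GO terms recover
each lncRNA's module-level functions for every benchmark entity. Real
expression and interaction data are noisier than this planted-module
simulation, so these numbers characterize the implementation, not
expected field performance.

The same pipeline is scriptable from a shell via the `lncwalk` command
(`simulate`, `build`, `walk`, `annotate`, `evaluate`, `sweep`), driven
by one YAML config; see `lncwalk --help`.

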