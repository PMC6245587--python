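"""Fully in-silico inputs with planted module structure.

The generator partitions entities (lncRNAs) and partners (proteins) into
shared functional modules and lets each observable reflect that single
planted signal:

* entity expression rows mix their module's latent condition profile with
  i.i.d. Gaussian noise, so within-module co-expression is high;
* several co-expression score sets are produced from independent noisy
  realizations of the same latent profiles;
* partner-partner interactions are dense within modules and sparse
  between them, with STRING-style integer confidence weights;
* entity-partner associations are sampled within modules, and a fixed
  fraction of them is withheld as hidden link-recovery truth;
* each module owns a disjoint block of GO terms; partners are annotated
  with a sample from their module's block and the benchmark assigns each
  entity its module's full block.

Degree distributions, tissue-specific expression and GO DAG topology are
deliberately not emulated: the modules are the one signal every pipeline
stage must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from .containers import ScoreMatrix
from .evaluate import Benchmark
from .io import (
    AnnotationTable,
    EdgeList,
    ExpressionProfiles,
    write_annotations,
    write_edge_list,
    write_expression,
)
from .networks import CoexpressionSource
from .pipeline import PipelineInputs, PipelineOptions

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthDataset",
    "generate",
    "recovery_auc",
    "write_dataset",
    "to_pipeline_inputs",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults describe a medium-hard recovery problem: 120 entities and 120
    partners in 6 modules observed over 24 conditions, within-module latent
    weight 0.7 against noise of SD 0.3 (within-module expression
    correlation around 0.85), association density 0.15 inside modules with
    20% of associations withheld, and 60 GO terms split into per-module
    blocks of 10 with 4 terms sampled per partner.
    """

    n_entities: int = 120
    n_partners: int = 120
    n_conditions: int = 24
    n_modules: int = 6
    within_module_corr: float = 0.7
    noise_sd: float = 0.3
    assoc_density: float = 0.15
    hidden_fraction: float = 0.2
    terms_per_partner: int = 4
    n_terms: int = 60
    n_coexpr_sources: int = 3
    ppi_within: float = 0.3
    ppi_between: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_entities, self.n_partners, self.n_conditions) < 1:
            raise ValueError("entity/partner/condition counts must be positive")
        if self.n_modules < 1 or self.n_modules > min(self.n_entities, self.n_partners):
            raise ValueError("n_modules must fit within both node sets")
        if not (0.0 < self.within_module_corr < 1.0):
            raise ValueError("within_module_corr must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 < self.assoc_density < 1.0):
            raise ValueError("assoc_density must lie in (0, 1)")
        if not (0.0 <= self.hidden_fraction < 1.0):
            raise ValueError("hidden_fraction must lie in [0, 1)")
        if self.n_entities * self.n_partners * self.assoc_density < 1:
            raise ValueError("expected association count below 1; densify")
        if self.n_terms < self.n_modules:
            raise ValueError("need at least one GO term per module")
        if self.terms_per_partner < 1:
            raise ValueError("terms_per_partner must be positive")


@dataclass
class SynthTruth:
    """What the generator planted: module labels, withheld associations,
    and the module-derived GO benchmark."""

    entity_modules: dict[str, int]
    partner_modules: dict[str, int]
    hidden_associations: list[tuple[str, str]]
    benchmark: Benchmark


@dataclass
class SynthDataset:
    expression: ExpressionProfiles
    coexpr_sources: list[CoexpressionSource]
    ppi_edges: EdgeList
    assoc_edges: EdgeList
    annotations: AnnotationTable
    truth: SynthTruth


def _block_assign(n: int, m: int) -> np.ndarray:
    """Contiguous near-equal block labels 0..m-1 for n items."""
    return (np.arange(n) * m) // n


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return Xc / norms


def generate(config: SynthConfig) -> SynthDataset:
    """Draw one complete synthetic dataset, reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    u, v, c, m = (
        config.n_entities,
        config.n_partners,
        config.n_conditions,
        config.n_modules,
    )
    entity_ids = [f"L{i + 1:04d}" for i in range(u)]
    partner_ids = [f"P{j + 1:04d}" for j in range(v)]
    term_ids = [f"GO:{t + 1:07d}" for t in range(config.n_terms)]

    mod_e = _block_assign(u, m)
    mod_p = _block_assign(v, m)
    latent = rng.standard_normal((m, c))
    w, sd = config.within_module_corr, config.noise_sd

    expr_values = w * latent[mod_e] + sd * rng.standard_normal((u, c))
    expression = ExpressionProfiles(
        entity_ids, [f"cond{k + 1:02d}" for k in range(c)], expr_values
    )

    # independent noisy re-realizations of the same latent structure give
    # the multi-source co-expression score sets
    sources: list[CoexpressionSource] = []
    for k in range(config.n_coexpr_sources):
        Ze = _standardize_rows(w * latent[mod_e] + sd * rng.standard_normal((u, c)))
        Zp = _standardize_rows(w * latent[mod_p] + sd * rng.standard_normal((v, c)))
        C = np.clip(Ze @ Zp.T, -1.0, 1.0)
        scores = {
            (entity_ids[i], partner_ids[j]): float(C[i, j])
            for i in range(u)
            for j in range(v)
        }
        sources.append(CoexpressionSource(label=f"source{k + 1}", scores=scores))

    ppi_records: list[tuple[str, str, float]] = []
    for i in range(v):
        for j in range(i + 1, v):
            if mod_p[i] == mod_p[j]:
                if rng.random() < config.ppi_within:
                    weight = float(rng.integers(600, 1000))
                    ppi_records.append((partner_ids[i], partner_ids[j], weight))
            elif rng.random() < config.ppi_between:
                weight = float(rng.integers(150, 400))
                ppi_records.append((partner_ids[i], partner_ids[j], weight))
    ppi_edges = EdgeList(ppi_records)

    assoc_pairs: list[tuple[str, str]] = []
    for i in range(u):
        for j in range(v):
            if mod_e[i] == mod_p[j] and rng.random() < config.assoc_density:
                assoc_pairs.append((entity_ids[i], partner_ids[j]))
    if not assoc_pairs:
        raise ValueError("no associations sampled; raise assoc_density")
    n_hidden = int(round(config.hidden_fraction * len(assoc_pairs)))
    n_hidden = min(n_hidden, len(assoc_pairs) - 1)  # keep >=1 observed
    hidden_idx = set(
        rng.choice(len(assoc_pairs), size=n_hidden, replace=False).tolist()
    )
    hidden = [assoc_pairs[i] for i in sorted(hidden_idx)]
    observed = [
        (e, p, 1.0) for i, (e, p) in enumerate(assoc_pairs) if i not in hidden_idx
    ]
    assoc_edges = EdgeList(observed)

    block_of_term = _block_assign(config.n_terms, m)
    module_blocks = [
        [term_ids[t] for t in range(config.n_terms) if block_of_term[t] == b]
        for b in range(m)
    ]
    partner_terms: dict[str, set[str]] = {}
    for j in range(v):
        block = module_blocks[mod_p[j]]
        k = min(config.terms_per_partner, len(block))
        chosen = rng.choice(len(block), size=k, replace=False)
        partner_terms[partner_ids[j]] = {block[t] for t in chosen}
    annotations = AnnotationTable(partner_terms)

    benchmark = Benchmark(
        {entity_ids[i]: set(module_blocks[mod_e[i]]) for i in range(u)}
    )
    truth = SynthTruth(
        entity_modules=dict(zip(entity_ids, mod_e.tolist())),
        partner_modules=dict(zip(partner_ids, mod_p.tolist())),
        hidden_associations=hidden,
        benchmark=benchmark,
    )
    return SynthDataset(expression, sources, ppi_edges, assoc_edges, annotations, truth)


def recovery_auc(scores: ScoreMatrix, truth: SynthTruth, seed: int = 0) -> float:
    """AUROC separating hidden associations from cross-module non-pairs.

    Positives are the walk scores of the withheld associations; negatives
    are an equal-sized seeded sample of cross-module pairs, which under the
    generative model are guaranteed never to be associated.
    """
    if not truth.hidden_associations:
        raise ValueError("no hidden associations to recover")
    ei = {e: i for i, e in enumerate(scores.entity_ids)}
    pi = {p: i for i, p in enumerate(scores.partner_ids)}
    pos = []
    for e, p in truth.hidden_associations:
        if e not in ei or p not in pi:
            raise KeyError(f"score matrix does not cover hidden pair ({e!r}, {p!r})")
        pos.append(scores.R[ei[e], pi[p]])

    mod_e = np.array([truth.entity_modules[e] for e in scores.entity_ids])
    mod_p = np.array([truth.partner_modules[p] for p in scores.partner_ids])
    cross = np.argwhere(mod_e[:, None] != mod_p[None, :])
    if len(cross) < len(pos):
        raise ValueError("not enough cross-module pairs to sample negatives")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(cross), size=len(pos), replace=False)
    neg = [scores.R[i, j] for i, j in cross[pick]]

    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return float(roc_auc_score(y, np.concatenate([pos, neg])))


def to_pipeline_inputs(
    dataset: SynthDataset,
    options: PipelineOptions | None = None,
    include_coexpr: bool = False,
) -> PipelineInputs:
    """Bundle a synthetic dataset for :func:`lncwalk.pipeline.run_pipeline`.

    Co-expression sources are excluded by default: in this generator they
    reflect the same latent modules that planted the hidden associations,
    so feeding them into the association matrix would leak the very links
    the recovery benchmark withholds.
    """
    return PipelineInputs(
        expression=dataset.expression,
        ppi_edges=dataset.ppi_edges,
        assoc_edges=dataset.assoc_edges,
        annotations=dataset.annotations,
        benchmark=dataset.truth.benchmark,
        coexpr_sources=list(dataset.coexpr_sources) if include_coexpr else [],
        options=options or PipelineOptions(),
    )


def write_dataset(dataset: SynthDataset, outdir) -> dict[str, str]:
    """Write every generated artifact in the tool's on-disk formats.

    Returns a name -> path manifest.  Hidden associations and the benchmark
    are written alongside the observable inputs so a synthetic run can be
    evaluated from files alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _register(name: str, filename: str) -> Path:
        p = outdir / filename
        paths[name] = str(p)
        return p

    write_expression(dataset.expression, _register("expression", "expression.tsv"))
    write_edge_list(dataset.ppi_edges, _register("ppi", "ppi.tsv"))
    write_edge_list(dataset.assoc_edges, _register("associations", "associations.tsv"))
    write_annotations(dataset.annotations, _register("annotations", "annotations.tsv"))
    from .networks import write_coexpression

    for src in dataset.coexpr_sources:
        write_coexpression(src, _register(src.label, f"coexpr_{src.label}.tsv"))
    with open(_register("benchmark", "benchmark.tsv"), "w") as fh:
        for entity in dataset.truth.benchmark.truth:
            for term in sorted(dataset.truth.benchmark.truth[entity]):
                fh.write(f"{entity}\t{term}\n")
    with open(_register("hidden", "hidden_associations.tsv"), "w") as fh:
        for e, p in dataset.truth.hidden_associations:
            fh.write(f"{e}\t{p}\n")
    return paths
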