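"""End-to-end orchestration: networks -> walk -> annotation transfer.

This is the shared engine behind the command-line subcommands and the
ablation driver.  It fixes the identifier universes once — entities from
the expression matrix, partners from the PPI edge list, then the
association list, then the annotation table, in first-appearance order —
so every matrix in the run shares consistent axes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .annotate import AnnotParams, TermScoreTable, annotate_all
from .birw import BiRWParams, bi_random_walk, laplacian_normalize
from .containers import PartnerNet, ScoreMatrix
from .evaluate import Benchmark
from .io import AnnotationTable, EdgeList, ExpressionProfiles
from .networks import (
    CoexpressionSource,
    aggregate_coexpression,
    assemble_associations,
    build_partner_net,
    pearson_similarity,
)

__all__ = ["PipelineOptions", "PipelineInputs", "partner_universe", "run_pipeline"]


@dataclass(frozen=True)
class PipelineOptions:
    """Network-construction and walk settings with the defaults used
    throughout: alpha=0.8, l=r=2, N=47, similarity negatives clamped,
    associations binarized."""

    birw: BiRWParams = field(default_factory=BiRWParams)
    annot: AnnotParams = field(default_factory=AnnotParams)
    min_conditions: int = 3
    similarity_negative: str = "clamp"
    similarity_top_k: int | None = 50
    coexpr_threshold: float = 0.5
    assoc_mode: str = "binary"
    ppi_weight_mode: str = "confidence"
    ppi_confidence_cutoff: float = 0.4
    normalization: str = "symmetric"
    restart: str = "normalized"


@dataclass
class PipelineInputs:
    """Everything one run consumes, already in memory."""

    expression: ExpressionProfiles
    ppi_edges: EdgeList
    assoc_edges: EdgeList
    annotations: AnnotationTable
    benchmark: Benchmark | None = None
    coexpr_sources: list[CoexpressionSource] = field(default_factory=list)
    options: PipelineOptions = field(default_factory=PipelineOptions)

    def replace(self, **changes) -> "PipelineInputs":
        return dataclasses.replace(self, **changes)


def partner_universe(
    ppi_edges: EdgeList, assoc_edges: EdgeList, annotations: AnnotationTable
) -> list[str]:
    """Partner ids in first-appearance order across PPI, associations,
    annotations."""
    seen: dict[str, None] = {}
    for p in ppi_edges.node_ids():
        seen.setdefault(p)
    for _, p, _w in assoc_edges.records:
        seen.setdefault(p)
    for p in annotations.partner_terms:
        seen.setdefault(p)
    return list(seen)


def run_pipeline(inputs: PipelineInputs) -> tuple[ScoreMatrix, TermScoreTable]:
    """Build the heterogeneous network, walk it, and transfer GO terms."""
    opts = inputs.options
    entity_ids = list(inputs.expression.entity_ids)
    partner_ids = partner_universe(
        inputs.ppi_edges, inputs.assoc_edges, inputs.annotations
    )

    L = pearson_similarity(
        inputs.expression,
        min_conditions=opts.min_conditions,
        negative=opts.similarity_negative,
        top_k=opts.similarity_top_k,
    )
    if inputs.ppi_edges.records:
        P = build_partner_net(
            inputs.ppi_edges,
            weight_mode=opts.ppi_weight_mode,
            confidence_cutoff=opts.ppi_confidence_cutoff,
            partner_ids=partner_ids,
        )
    else:
        # fully ablated partner network: isolated partners only
        P = PartnerNet(partner_ids, np.zeros((len(partner_ids), len(partner_ids))))

    coexpr = (
        aggregate_coexpression(inputs.coexpr_sources) if inputs.coexpr_sources else {}
    )
    A = assemble_associations(
        inputs.assoc_edges,
        coexpr,
        entity_ids,
        partner_ids,
        coexpr_threshold=opts.coexpr_threshold,
        mode=opts.assoc_mode,
    )

    L_N = laplacian_normalize(L, method=opts.normalization)
    P_N = laplacian_normalize(P, method=opts.normalization)
    scores = bi_random_walk(L_N, P_N, A, opts.birw, restart=opts.restart)
    predictions = annotate_all(scores, inputs.annotations, opts.annot)
    return scores, predictions
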