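"""Guilt-by-association GO term transfer from top-ranked partners.

Each query entity inherits terms from its N highest-scoring partners.
With S(i) the relevance score of neighbour i, a term T scores

    P(T) = sum_i  S(i) / sum_j S(j)  *  Ind_i(T)

where Ind_i(T) is 1 iff neighbour i is annotated with T.  Scores therefore
lie in (0, 1], with 1 attained exactly when every selected neighbour
carries the term.  Neighbours without annotations still count in the
denominator; neighbours with score exactly 0 are never selected (their
weight would vanish anyway).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .containers import ScoreMatrix
from .io import FLOAT_FMT, AnnotationTable

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotParams",
    "TermScoreTable",
    "top_partners",
    "score_terms",
    "annotate_all",
    "write_predictions",
    "read_predictions",
]


@dataclass(frozen=True)
class AnnotParams:
    """top_n: number N of neighbouring partners consulted (default 47);
    min_score: relevance floor below which partners are ignored (default 0,
    i.e. any positive score qualifies)."""

    top_n: int = 47
    min_score: float = 0.0

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


@dataclass
class TermScoreTable:
    """Per-entity GO term scores in (0, 1]; zero-score terms are omitted."""

    per_entity: dict[str, dict[str, float]] = field(default_factory=dict)

    def entities(self) -> list[str]:
        return list(self.per_entity)


def top_partners(
    scores: ScoreMatrix, entity: str, params: AnnotParams
) -> list[tuple[str, float]]:
    """The N highest-scoring partners of ``entity``, descending score.

    Ties are broken by partner id lexicographic order.  Partners scoring 0
    (or below ``min_score``) are excluded, so fewer than N may be returned.
    Unknown entities are a hard error.
    """
    row = scores.row(entity)  # raises KeyError for unknown entity
    floor = max(params.min_score, 0.0)
    candidates = [(p, s) for p, s in row.items() if s > 0 and s >= floor]
    candidates.sort(key=lambda ps: (-ps[1], ps[0]))
    return candidates[: params.top_n]


def score_terms(
    neighbors: list[tuple[str, float]], annotations: AnnotationTable
) -> dict[str, float]:
    """Score GO terms over a fixed neighbour list by normalized weight sums.

    Returns an empty map (entity unannotatable) when the neighbour scores
    sum to zero.
    """
    total = sum(s for _, s in neighbors)
    if total <= 0:
        return {}
    term_scores: dict[str, float] = {}
    for partner, s in neighbors:
        w = s / total
        for term in annotations.partner_terms.get(partner, ()):
            term_scores[term] = term_scores.get(term, 0.0) + w
    # sums of weights can overshoot 1 by float dust
    return {t: min(v, 1.0) for t, v in term_scores.items() if v > 0}


def annotate_all(
    scores: ScoreMatrix, annotations: AnnotationTable, params: AnnotParams
) -> TermScoreTable:
    """Apply top-partner selection and term scoring to every entity."""
    table = TermScoreTable()
    n_empty = 0
    for entity in scores.entity_ids:
        neighbors = top_partners(scores, entity, params)
        terms = score_terms(neighbors, annotations)
        table.per_entity[entity] = terms
        if not terms:
            n_empty += 1
    if n_empty:
        logger.info("%d of %d entities received no annotation", n_empty, len(scores.entity_ids))
    return table


def write_predictions(table: TermScoreTable, path) -> None:
    """TSV (entity id, GO id, score), descending score per entity."""
    with open(path, "w") as fh:
        for entity in table.per_entity:
            items = sorted(
                table.per_entity[entity].items(), key=lambda ts: (-ts[1], ts[0])
            )
            for term, score in items:
                fh.write(f"{entity}\t{term}\t{FLOAT_FMT.format(score)}\n")


def read_predictions(path) -> TermScoreTable:
    table = TermScoreTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            entity, term, score = fields[0], fields[1], float(fields[2])
            table.per_entity.setdefault(entity, {})[term] = score
    return table
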