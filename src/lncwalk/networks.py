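"""Construction of the three layers of the global heterogeneous network.

* the entity (lncRNA) similarity network L, from expression correlation,
* the partner (protein) interaction network P, from a weighted edge list,
* the cross-network association matrix A, from known interactions and
  aggregated multi-source co-expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import AssocMatrix, PartnerNet, SimilarityNet
from .io import EdgeList, ExpressionProfiles

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionSource",
    "read_coexpression",
    "write_coexpression",
    "pearson_similarity",
    "aggregate_coexpression",
    "assemble_associations",
    "build_partner_net",
]

PROV_NONE, PROV_INTERACTION, PROV_COEXPRESSION, PROV_BOTH = 0, 1, 2, 3


@dataclass
class CoexpressionSource:
    """One pre-computed co-expression score set.

    ``scores`` maps (entity id, partner id) -> Pearson correlation in
    [-1, 1].  Each pair appears at most once per source.
    """

    label: str
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        for pair, c in self.scores.items():
            if not (-1.0 - 1e-12 <= c <= 1.0 + 1e-12):
                raise ValueError(
                    f"source {self.label!r}: correlation {c} for pair {pair} "
                    "outside [-1, 1]"
                )


def read_coexpression(path, label: str | None = None) -> CoexpressionSource:
    """Read a 3-column TSV of (entity, partner, correlation) triples.

    A pair appearing twice in one source is a hard error.
    """
    from pathlib import Path

    label = label if label is not None else Path(path).stem
    scores: dict[tuple[str, str], float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            pair = (fields[0], fields[1])
            if pair in scores:
                raise ValueError(f"{path}:{lineno}: duplicate pair {pair}")
            scores[pair] = float(fields[2])
    src = CoexpressionSource(label=label, scores=scores)
    src.validate()
    return src


def write_coexpression(source: CoexpressionSource, path) -> None:
    from .io import FLOAT_FMT

    with open(path, "w") as fh:
        for (e, p), c in source.scores.items():
            fh.write(f"{e}\t{p}\t{FLOAT_FMT.format(c)}\n")


def pearson_similarity(
    expr: ExpressionProfiles,
    min_conditions: int = 3,
    negative: str = "clamp",
    top_k: int | None = 50,
) -> SimilarityNet:
    """Entity similarity network from pairwise Pearson correlation.

    ``L[i, j] = max(0, PCC(row_i, row_j))`` for i != j; with
    ``negative="abs"`` the absolute correlation is kept instead.  Rows with
    zero variance get similarity 0 against every other row, and the diagonal
    is forced to 0.

    ``top_k`` keeps only each entity's k strongest neighbours and then
    re-symmetrizes by elementwise max (pass ``None`` for the dense,
    unsparsified network).  Genome-scale similarity matrices are nearly
    noise off the top of each row, so this is the default.
    """
    if len(expr.entity_ids) < 2:
        raise ValueError("need at least 2 entities for a similarity network")
    if len(expr.condition_ids) < min_conditions:
        raise ValueError(
            f"need at least {min_conditions} conditions, "
            f"got {len(expr.condition_ids)}"
        )
    X = expr.values
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    ok = norms > 0
    denom = np.where(ok, norms, 1.0)
    Z = Xc / denom[:, None]
    C = Z @ Z.T
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    if negative == "abs":
        C = np.abs(C)
    elif negative == "clamp":
        C = np.maximum(C, 0.0)
    else:
        raise ValueError(f"unknown negative-correlation mode {negative!r}")
    np.clip(C, 0.0, 1.0, out=C)
    np.fill_diagonal(C, 0.0)
    C = 0.5 * (C + C.T)  # exact symmetry against floating-point drift

    if top_k is not None and top_k < C.shape[0] - 1:
        kept = np.zeros_like(C)
        for i in range(C.shape[0]):
            nz = np.argsort(C[i])[::-1][:top_k]
            kept[i, nz] = C[i, nz]
        C = np.maximum(kept, kept.T)
    return SimilarityNet(list(expr.entity_ids), C)


def aggregate_coexpression(
    sources: list[CoexpressionSource],
) -> dict[tuple[str, str], float]:
    """Combine per-source correlations into C = 1 - prod_k (1 - C_k).

    The product runs only over sources where the pair is *positively*
    correlated; negative correlation scores are excluded, and a pair with no
    positive score in any source is absent from the result.  The aggregate
    therefore always lies in (0, 1] and never decreases when a positively
    correlated source is added.
    """
    if not sources:
        raise ValueError("need at least one co-expression source")
    for src in sources:
        src.validate()
    complement: dict[tuple[str, str], float] = {}
    for src in sources:
        for pair, c in src.scores.items():
            if c > 0:
                complement[pair] = complement.get(pair, 1.0) * (1.0 - c)
    return {pair: 1.0 - rest for pair, rest in complement.items()}


def assemble_associations(
    interactions: EdgeList,
    coexpr: dict[tuple[str, str], float],
    entity_ids: list[str],
    partner_ids: list[str],
    coexpr_threshold: float = 0.5,
    mode: str = "binary",
) -> AssocMatrix:
    """Assemble the association matrix A from interactions and co-expression.

    Known interaction pairs get entry 1.0.  Co-expression pairs at or above
    ``coexpr_threshold`` get 1.0 in ``binary`` mode (default) or their
    aggregated correlation in ``weighted`` mode.  Pairs supported by both
    sources take the maximum and are flagged as such in the provenance
    matrix.  Ids outside the given axis universes are logged and skipped.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"unknown association mode {mode!r}")
    ei = {e: i for i, e in enumerate(entity_ids)}
    pi = {p: i for i, p in enumerate(partner_ids)}
    A = np.zeros((len(entity_ids), len(partner_ids)))
    prov = np.zeros_like(A, dtype=np.uint8)

    for a, b, _w in interactions.records:
        if a not in ei or b not in pi:
            logger.info("skipping interaction (%r, %r): unknown id", a, b)
            continue
        A[ei[a], pi[b]] = 1.0
        prov[ei[a], pi[b]] |= PROV_INTERACTION

    for (e, p), c in coexpr.items():
        if c < coexpr_threshold:
            continue
        if e not in ei or p not in pi:
            logger.info("skipping co-expression pair (%r, %r): unknown id", e, p)
            continue
        value = 1.0 if mode == "binary" else c
        A[ei[e], pi[p]] = max(A[ei[e], pi[p]], value)
        prov[ei[e], pi[p]] |= PROV_COEXPRESSION

    if not np.any(A):
        raise ValueError("association matrix has no nonzero entries")
    return AssocMatrix(list(entity_ids), list(partner_ids), A, prov)


def build_partner_net(
    edges: EdgeList,
    weight_mode: str = "confidence",
    confidence_cutoff: float = 0.4,
    partner_ids: list[str] | None = None,
) -> PartnerNet:
    """Partner interaction network from a weighted edge list.

    In ``confidence`` mode raw weights are rescaled to [0, 1] by the maximum
    observed weight and entries below ``confidence_cutoff`` are zeroed; in
    ``binary`` mode surviving edges are set to 1.  An edge listed twice with
    conflicting weights is a hard error.  ``partner_ids`` may extend the
    node universe beyond the edge list (isolated partners get zero rows).
    """
    if weight_mode not in ("confidence", "binary"):
        raise ValueError(f"unknown weight mode {weight_mode!r}")
    if not edges.records:
        raise ValueError("partner edge list is empty")

    weights: dict[tuple[str, str], float] = {}
    for a, b, w in edges.records:
        key = (a, b) if a <= b else (b, a)
        if key in weights and weights[key] != w:
            raise ValueError(
                f"conflicting weights for edge {key}: {weights[key]} vs {w}"
            )
        weights[key] = w

    if partner_ids is None:
        ids = edges.node_ids()
    else:
        ids = list(partner_ids)
        known = set(ids)
        missing = [n for n in edges.node_ids() if n not in known]
        if missing:
            raise ValueError(f"edge node {missing[0]!r} not in partner_ids")
    idx = {p: i for i, p in enumerate(ids)}

    wmax = max(weights.values())
    if wmax <= 0:
        raise ValueError("all partner edge weights are zero")
    P = np.zeros((len(ids), len(ids)))
    for (a, b), w in weights.items():
        scaled = w / wmax
        if scaled < confidence_cutoff:
            continue
        value = 1.0 if weight_mode == "binary" else scaled
        P[idx[a], idx[b]] = value
        P[idx[b], idx[a]] = value
    return PartnerNet(ids, P)
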