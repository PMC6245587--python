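"""Shared matrix containers for the heterogeneous lncRNA-protein network.

Every matrix travels with the explicit, ordered identifier lists that label
its axes.  Positional indices never cross module boundaries on their own:
the lncRNA (entity) and protein (partner) index sets come from heterogeneous
sources and are only joinable by name.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SquareNet",
    "SimilarityNet",
    "PartnerNet",
    "AssocMatrix",
    "NormalizedNet",
    "ScoreMatrix",
    "check_unique_ids",
]


def check_unique_ids(ids, what: str = "id") -> None:
    """Raise ``ValueError`` naming the first duplicated identifier."""
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class SquareNet:
    """A symmetric, non-negative, zero-diagonal network over one id set."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        check_unique_ids(self.ids)
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} ids")
        if not np.all(np.isfinite(m)):
            raise ValueError("network matrix contains non-finite entries")
        if np.any(m < 0):
            raise ValueError("network matrix contains negative entries")
        if not np.allclose(m, m.T):
            raise ValueError("network matrix is not symmetric")
        if np.any(np.diagonal(m) != 0):
            raise ValueError("network matrix has a nonzero diagonal")
        self.matrix = m

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}


class SimilarityNet(SquareNet):
    """Entity (lncRNA) similarity network L, entries in [0, 1]."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.matrix > 1.0 + 1e-12):
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def entity_ids(self) -> list[str]:
        return self.ids


class PartnerNet(SquareNet):
    """Partner (protein) interaction network P."""

    @property
    def partner_ids(self) -> list[str]:
        return self.ids


@dataclass
class AssocMatrix:
    """Cross-network associations A (entities x partners).

    The walk's seed and restart prior.  ``provenance`` codes each entry:
    0 = none, 1 = interaction, 2 = co-expression, 3 = both.
    """

    entity_ids: list[str]
    partner_ids: list[str]
    A: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        check_unique_ids(self.entity_ids, "entity id")
        check_unique_ids(self.partner_ids, "partner id")
        a = np.asarray(self.A, dtype=float)
        if a.shape != (len(self.entity_ids), len(self.partner_ids)):
            raise ValueError("association matrix shape does not match id lists")
        if not np.all(np.isfinite(a)):
            raise ValueError("association matrix contains non-finite entries")
        if np.any(a < 0) or np.any(a > 1.0 + 1e-12):
            raise ValueError("association entries must lie in [0, 1]")
        self.A = a


@dataclass
class NormalizedNet:
    """A degree-normalized network ready for propagation.

    ``matrix`` is sparse CSR; ``degree`` holds the raw row sums, so that
    zero-degree nodes (all-zero rows/columns after normalization) remain
    identifiable.
    """

    ids: list[str]
    matrix: sp.csr_array
    degree: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class ScoreMatrix:
    """Converged relevance scores R between every entity-partner pair."""

    entity_ids: list[str]
    partner_ids: list[str]
    R: np.ndarray
    iterations_run: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.R, dtype=float)
        if r.shape != (len(self.entity_ids), len(self.partner_ids)):
            raise ValueError("score matrix shape does not match id lists")
        if not np.all(np.isfinite(r)):
            raise ValueError("score matrix contains non-finite entries")
        if np.any(r < 0):
            raise ValueError("score matrix contains negative entries")
        self.R = r

    def row(self, entity: str) -> dict[str, float]:
        """Partner -> score map for one entity; raises on unknown entity."""
        try:
            i = self.entity_ids.index(entity)
        except ValueError:
            raise KeyError(f"unknown entity: {entity!r}") from None
        return dict(zip(self.partner_ids, self.R[i]))
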