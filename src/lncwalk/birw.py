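"""Bi-random walk on the heterogeneous entity-partner network.

The walk propagates the normalized association seed simultaneously along
the entity similarity network (left walk) and the partner interaction
network (right walk):

    R_L = alpha * L_N @ R_{t-1} + (1 - alpha) * A0
    R_P = alpha * R_{t-1} @ P_N + (1 - alpha) * A0

with per-side step caps ``l`` and ``r`` and decay factor ``alpha``.  At
each step the states of whichever walks are still active are averaged.
The iteration runs exactly max(l, r) steps — the step caps, not a
convergence tolerance, terminate the walk — scoring circular-bigraph
patterns of bounded length around the known associations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .containers import AssocMatrix, NormalizedNet, ScoreMatrix, SquareNet

__all__ = ["BiRWParams", "laplacian_normalize", "normalize_seed", "bi_random_walk"]


@dataclass(frozen=True)
class BiRWParams:
    """Walk hyper-parameters.

    alpha
        Decay factor in [0, 1]: weight of the propagated term against the
        restart (seed) term in each update.  Default 0.8.
    left_steps, right_steps
        Maximal iteration counts l and r for the walk on the entity and
        partner network respectively.  Default (2, 2): short circular
        bigraphs capture most real associations.
    """

    alpha: float = 0.8
    left_steps: int = 2
    right_steps: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.left_steps < 0 or self.right_steps < 0:
            raise ValueError("step counts must be non-negative")
        if self.left_steps + self.right_steps < 1:
            raise ValueError("need at least one walk step (l + r >= 1)")


def laplacian_normalize(net: SquareNet, method: str = "symmetric") -> NormalizedNet:
    """Degree-normalize a symmetric non-negative network.

    ``symmetric`` (default) computes D^{-1/2} M D^{-1/2} with d_i the row
    sums; ``row`` computes the row-stochastic D^{-1} M.  Zero-degree nodes
    follow the 0/0 := 0 convention and keep all-zero rows and columns, so
    isolated nodes neither emit nor absorb probability mass.
    """
    M = net.matrix
    if np.any(M < 0):
        raise ValueError("network matrix contains negative entries")
    d = M.sum(axis=1)
    with np.errstate(divide="ignore"):
        if method == "symmetric":
            inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
            MN = inv_sqrt[:, None] * M * inv_sqrt[None, :]
        elif method == "row":
            inv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
            MN = inv[:, None] * M
        else:
            raise ValueError(f"unknown normalization method {method!r}")
    return NormalizedNet(list(net.ids), sp.csr_array(MN), d)


def normalize_seed(A: AssocMatrix) -> ScoreMatrix:
    """Global-sum normalization of the association matrix.

    R_0 = A / sum(A) so the seed is a probability mass over all known
    associations; it serves both as the walk's initial state and as its
    restart term.  An all-zero A is a hard error.
    """
    total = A.A.sum()
    if total <= 0:
        raise ValueError("association matrix is all-zero; nothing to propagate")
    return ScoreMatrix(list(A.entity_ids), list(A.partner_ids), A.A / total)


def bi_random_walk(
    L_N: NormalizedNet,
    P_N: NormalizedNet,
    A: AssocMatrix,
    params: BiRWParams,
    restart: str = "normalized",
) -> ScoreMatrix:
    """Run the bi-random walk and return the relevance score matrix.

    At step t the left walk runs while t <= l and the right walk while
    t <= r; the states of the active walks are averaged into R_t.  The
    restart term is the globally normalized seed by default
    (``restart="raw"`` substitutes the unnormalized A, for sensitivity
    analysis only).
    """
    u, v = len(A.entity_ids), len(A.partner_ids)
    if L_N.n != u:
        raise ValueError(f"entity network is {L_N.n}x{L_N.n}, A has {u} entities")
    if P_N.n != v:
        raise ValueError(f"partner network is {P_N.n}x{P_N.n}, A has {v} partners")
    if list(L_N.ids) != list(A.entity_ids):
        raise ValueError("entity id order differs between network and associations")
    if list(P_N.ids) != list(A.partner_ids):
        raise ValueError("partner id order differs between network and associations")

    alpha = params.alpha
    l, r = params.left_steps, params.right_steps
    A0 = normalize_seed(A).R
    seed = A0 if restart == "normalized" else A.A
    if restart not in ("normalized", "raw"):
        raise ValueError(f"unknown restart mode {restart!r}")

    L = L_N.matrix
    P = P_N.matrix
    R = A0
    for t in range(1, max(l, r) + 1):
        states = []
        if t <= l:
            states.append(alpha * (L @ R) + (1 - alpha) * seed)
        if t <= r:
            states.append(alpha * (R @ P) + (1 - alpha) * seed)
        R = states[0] if len(states) == 1 else 0.5 * (states[0] + states[1])
    R = np.maximum(np.asarray(R), 0.0)  # clip float dust below zero
    return ScoreMatrix(
        list(A.entity_ids), list(A.partner_ids), R, iterations_run=max(l, r)
    )
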