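"""Threshold-averaged precision/recall, Fmax and coverage.

For a benchmark of N entities with truth sets T_i and prediction sets
P_i(t) = {terms scoring >= t}:

    Pr_i(t) = |P_i(t) & T_i| / |P_i(t)|      (entities with |P_i(t)| >= 1)
    Rc_i(t) = |P_i(t) & T_i| / |T_i|

Averaged precision Pr(t) runs over the z(t) entities that received at
least one prediction above the threshold; averaged recall Rc(t) runs over
all N benchmark entities.  Fmax is the maximum over thresholds of the
harmonic mean of Pr(t) and Rc(t); coverage is the number (and fraction)
of entities with at least one *correct* predicted term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import TermScoreTable
from .io import GO_ID_PATTERN

__all__ = [
    "Benchmark",
    "EvalResult",
    "read_benchmark",
    "pr_rc_at_threshold",
    "fmax",
    "coverage",
    "default_grid",
    "ablation_run",
]


@dataclass
class Benchmark:
    """Truth sets T_i per entity plus the GO term universe O."""

    truth: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.truth:
            raise ValueError("benchmark is empty")
        union: set[str] = set()
        for entity, terms in self.truth.items():
            if not terms:
                raise ValueError(f"benchmark entity {entity!r} has an empty truth set")
            union |= terms
        if not self.universe:
            self.universe = union
        elif not union <= self.universe:
            raise ValueError("benchmark truth terms must be a subset of the universe")

    @property
    def n_entities(self) -> int:
        return len(self.truth)


def read_benchmark(path) -> Benchmark:
    """Read a 2-column TSV (entity id, GO id), multiple rows per entity."""
    truth: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not GO_ID_PATTERN.match(fields[1]):
                raise ValueError(f"{path}:{lineno}: expected (entity, GO id) columns")
            truth.setdefault(fields[0], set()).add(fields[1])
    return Benchmark(truth)


@dataclass
class EvalResult:
    thresholds: list[float]
    pr_curve: list[float]
    rc_curve: list[float]
    z: list[int]
    fmax: float
    fmax_threshold: float
    coverage_count: int
    coverage_fraction: float


def _prediction_set(
    predictions: TermScoreTable, entity: str, t: float, strict: bool
) -> set[str]:
    terms = predictions.per_entity.get(entity, {})
    if strict:
        return {f for f, s in terms.items() if s > t}
    return {f for f, s in terms.items() if s >= t}


def pr_rc_at_threshold(
    predictions: TermScoreTable, bench: Benchmark, t: float, strict: bool = False
) -> tuple[float, float, int]:
    """(Pr(t), Rc(t), z(t)) at a single threshold.

    Membership in P_i(t) uses score >= t by default, so a threshold of 1
    can still return perfect predictions; ``strict`` switches to score > t.
    When no entity has a prediction above t, Pr(t) is reported as 0.
    """
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {t}")
    pr_sum, rc_sum, z = 0.0, 0.0, 0
    for entity, T_i in bench.truth.items():
        P_i = _prediction_set(predictions, entity, t, strict)
        hits = len(P_i & T_i)
        if P_i:
            z += 1
            pr_sum += hits / len(P_i)
        rc_sum += hits / len(T_i)
    pr = pr_sum / z if z else 0.0
    rc = rc_sum / bench.n_entities
    return pr, rc, z


def default_grid(predictions: TermScoreTable, n_points: int = 101) -> list[float]:
    """Evenly spaced thresholds plus every distinct predicted score.

    Including the distinct scores guarantees the grid attains the true
    maximum of F(t).
    """
    grid = set(np.linspace(0.0, 1.0, n_points).round(12).tolist())
    for terms in predictions.per_entity.values():
        for s in terms.values():
            if 0.0 <= s <= 1.0:
                grid.add(float(s))
    return sorted(grid)


def fmax(
    predictions: TermScoreTable,
    bench: Benchmark,
    grid: list[float] | None = None,
    strict: bool = False,
) -> EvalResult:
    """Evaluate Pr/Rc over a threshold grid and locate Fmax.

    F(t) := 0 where Pr(t) + Rc(t) = 0.  Among thresholds attaining the
    maximum, the smallest is reported.  Coverage is evaluated at the Fmax
    threshold.
    """
    if grid is None:
        grid = default_grid(predictions)
    if not grid:
        raise ValueError("threshold grid is empty")
    for t in grid:
        if not (0.0 <= t <= 1.0):
            raise ValueError(f"grid threshold {t} outside [0, 1]")
    grid = sorted(grid)
    pr_curve, rc_curve, zs, f_curve = [], [], [], []
    for t in grid:
        pr, rc, z = pr_rc_at_threshold(predictions, bench, t, strict)
        f = 2 * pr * rc / (pr + rc) if pr + rc > 0 else 0.0
        pr_curve.append(pr)
        rc_curve.append(rc)
        zs.append(z)
        f_curve.append(f)
    best = int(np.argmax(f_curve))  # argmax takes the first = smallest t
    count, fraction = coverage(predictions, bench, grid[best], strict)
    return EvalResult(
        thresholds=list(grid),
        pr_curve=pr_curve,
        rc_curve=rc_curve,
        z=zs,
        fmax=f_curve[best],
        fmax_threshold=grid[best],
        coverage_count=count,
        coverage_fraction=fraction,
    )


def coverage(
    predictions: TermScoreTable, bench: Benchmark, t: float, strict: bool = False
) -> tuple[int, float]:
    """Entities with at least one correct predicted term at threshold t."""
    count = 0
    for entity, T_i in bench.truth.items():
        if _prediction_set(predictions, entity, t, strict) & T_i:
            count += 1
    return count, count / bench.n_entities


def ablation_run(inputs, ppi_fraction: float, seed: int) -> EvalResult:
    """Re-run the whole pipeline with a random fraction of PPI edges kept.

    ``inputs`` is a :class:`lncwalk.pipeline.PipelineInputs`.  A uniformly
    random ``floor(E * ppi_fraction)`` of the partner edges are retained
    (seeded); fraction 0 empties the partner network entirely, so the right
    walk contributes only the restart term.
    """
    from .io import EdgeList
    from .pipeline import run_pipeline

    if not (0.0 <= ppi_fraction <= 1.0):
        raise ValueError("ppi_fraction must lie in [0, 1]")
    records = inputs.ppi_edges.records
    if ppi_fraction >= 1.0:
        kept = list(records)
    else:
        n_keep = int(np.floor(len(records) * ppi_fraction))
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(records), size=n_keep, replace=False)
        kept = [records[i] for i in sorted(idx)]
    ablated = inputs.replace(ppi_edges=EdgeList(kept))
    _, predictions = run_pipeline(ablated)
    return fmax(predictions, inputs.benchmark)
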