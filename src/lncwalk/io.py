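"""Readers and writers for every external file the tool touches.

Formats
-------
* expression profiles: TSV, header row = condition ids, first column = entity ids
* interactions / associations: 2- or 3-column TSV edge lists (no header)
* co-expression scores: 3-column TSV triples (entity, partner, correlation)
* annotations: GAF 2.1/2.2 (17 tab-separated columns, ``!`` comments) or a
  2-column TSV fallback (partner id, GO id)
* relevance scores and term predictions: long-format TSV

All identifiers keep first-appearance order, so downstream matrix axes are
deterministic for a given input file.  Real values are written with 12
significant digits, which round-trips through the matching readers.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ScoreMatrix, check_unique_ids

logger = logging.getLogger(__name__)

GO_ID_PATTERN = re.compile(r"^GO:\d{7}$")

#: text representation used by every writer for real values
FLOAT_FMT = "{:.12g}"

__all__ = [
    "ExpressionProfiles",
    "EdgeList",
    "AnnotationTable",
    "read_expression",
    "write_expression",
    "read_edge_list",
    "write_edge_list",
    "read_gaf",
    "write_annotations",
    "write_scores",
    "read_scores",
    "write_square_net",
    "read_square_net",
    "write_assoc",
    "read_assoc",
    "GO_ID_PATTERN",
]


@dataclass
class ExpressionProfiles:
    """Entity expression levels across conditions (tissues/cell types)."""

    entity_ids: list[str]
    condition_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        check_unique_ids(self.entity_ids, "entity id")
        check_unique_ids(self.condition_ids, "condition id")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.entity_ids), len(self.condition_ids)):
            raise ValueError("expression matrix shape does not match id lists")
        if not np.all(np.isfinite(v)):
            raise ValueError("expression values must all be finite")
        self.values = v


@dataclass
class EdgeList:
    """Weighted undirected edge records (id_a, id_b, weight >= 0)."""

    records: list[tuple[str, str, float]] = field(default_factory=list)

    def node_ids(self) -> list[str]:
        """Node identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for a, b, _ in self.records:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class AnnotationTable:
    """Partner -> GO term sets plus the term universe O."""

    partner_terms: dict[str, set[str]]
    term_universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        union: set[str] = set()
        for partner, terms in self.partner_terms.items():
            for t in terms:
                if not GO_ID_PATTERN.match(t):
                    raise ValueError(
                        f"malformed GO id {t!r} for partner {partner!r}"
                    )
            union |= terms
        # the universe is definitionally the union of the per-partner sets
        self.term_universe = union


def read_expression(path) -> ExpressionProfiles:
    """Read an entities-by-conditions TSV expression matrix.

    The header row holds condition ids; the first column holds entity ids.
    Duplicate ids and non-numeric cells are hard errors; file row order is
    preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no entities (header-only file)")
    entity_ids = [str(i) for i in df.index]
    dupes = [i for i, c in Counter(entity_ids).items() if c > 1]
    if dupes:
        raise ValueError(f"{path}: duplicate entity id {dupes[0]!r}")
    condition_ids = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.index[converted.isna() & df[col].notna()]
        if len(bad) > 0:
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} "
                f"at row {bad[0]!r}, column {col!r}"
            )
        if converted.isna().any():
            row = converted.index[converted.isna()][0]
            raise ValueError(f"{path}: missing value at row {row!r}, column {col!r}")
        values[:, j] = converted.to_numpy(dtype=float)
    return ExpressionProfiles(entity_ids, condition_ids, values)


def write_expression(expr: ExpressionProfiles, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(expr.condition_ids) + "\n")
        for eid, row in zip(expr.entity_ids, expr.values):
            fh.write(eid + "\t" + "\t".join(FLOAT_FMT.format(v) for v in row) + "\n")


def read_edge_list(path) -> EdgeList:
    """Read a 2- or 3-column TSV edge list.

    The weight column defaults to 1.0 when absent.  Self-loops are dropped
    with a warning; negative weights are hard errors.
    """
    records: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns")
            a, b = fields[0], fields[1]
            if len(fields) >= 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric weight {fields[2]!r}"
                    ) from None
            else:
                w = 1.0
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"{path}:{lineno}: invalid weight {w}")
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, a)
                continue
            records.append((a, b, w))
    return EdgeList(records)


def write_edge_list(edges: EdgeList, path) -> None:
    with open(path, "w") as fh:
        for a, b, w in edges.records:
            fh.write(f"{a}\t{b}\t{FLOAT_FMT.format(w)}\n")


def _parse_gaf_lines(lines, aspects, evidence_codes):
    """Yield (partner, term) from GAF 2.x content; skip NOT and bad rows."""
    aspect_counts: Counter = Counter()
    n_used = 0
    out = []
    for lineno, line in lines:
        fields = line.split("\t")
        if len(fields) < 15:
            logger.warning("skipping unparseable GAF line %d", lineno)
            continue
        partner, qualifier, term = fields[1], fields[3], fields[4]
        aspect = fields[8] if len(fields) > 8 else ""
        evidence = fields[6] if len(fields) > 6 else ""
        if "NOT" in qualifier.split("|"):
            continue
        if not GO_ID_PATTERN.match(term):
            logger.warning("skipping GAF line %d: bad GO id %r", lineno, term)
            continue
        aspect_counts[aspect] += 1
        if aspects is not None and aspect not in aspects:
            continue
        if evidence_codes is not None and evidence not in evidence_codes:
            continue
        out.append((partner, term))
        n_used += 1
    logger.info("GAF aspect counts: %s", dict(aspect_counts))
    return out


def read_gaf(path, aspects=None, evidence_codes=None) -> AnnotationTable:
    """Read partner GO annotations from GAF 2.x or a 2-column TSV.

    Rows whose qualifier contains ``NOT`` are skipped.  ``aspects`` may be a
    set drawn from {"P", "F", "C"} to keep only those ontology aspects
    (default: keep all); ``evidence_codes`` optionally whitelists GAF
    evidence codes (default: no filtering).  Unparseable lines are skipped
    with a logged line number; zero usable rows is a hard error.
    """
    data_lines: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            data_lines.append((lineno, line))
    if not data_lines:
        raise ValueError(f"{path}: no usable annotation rows")

    is_gaf = any(len(line.split("\t")) >= 15 for _, line in data_lines)
    pairs: list[tuple[str, str]] = []
    if is_gaf:
        pairs = _parse_gaf_lines(data_lines, aspects, evidence_codes)
    else:
        for lineno, line in data_lines:
            fields = line.split("\t")
            if len(fields) < 2 or not GO_ID_PATTERN.match(fields[1]):
                logger.warning("skipping unparseable annotation line %d", lineno)
                continue
            pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"{path}: no usable annotation rows")

    partner_terms: dict[str, set[str]] = {}
    for partner, term in pairs:
        partner_terms.setdefault(partner, set()).add(term)
    return AnnotationTable(partner_terms)


def write_annotations(table: AnnotationTable, path) -> None:
    """Write a 2-column TSV (partner id, GO id), sorted for determinism."""
    with open(path, "w") as fh:
        for partner in sorted(table.partner_terms):
            for term in sorted(table.partner_terms[partner]):
                fh.write(f"{partner}\t{term}\n")


def write_scores(scores: ScoreMatrix, path) -> None:
    """Write relevance scores as long-format TSV (entity, partner, score).

    Rows are grouped by entity in axis order; within an entity partners are
    sorted by descending score, ties broken by partner id, so output is
    deterministic.  Values use 12 significant digits and round-trip through
    :func:`read_scores`.
    """
    with open(path, "w") as fh:
        for i, entity in enumerate(scores.entity_ids):
            row = scores.R[i]
            order = sorted(
                range(len(scores.partner_ids)),
                key=lambda j: (-row[j], scores.partner_ids[j]),
            )
            for j in order:
                fh.write(
                    f"{entity}\t{scores.partner_ids[j]}\t{FLOAT_FMT.format(row[j])}\n"
                )


def read_scores(path) -> ScoreMatrix:
    """Read a long-format score TSV back into a dense :class:`ScoreMatrix`.

    Entity order follows first appearance; partner order is lexicographic
    (the writer's per-entity descending-score order is not a global axis
    order).
    """
    entities: dict[str, None] = {}
    partners: set[str] = set()
    triples: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            e, p, s = fields[0], fields[1], float(fields[2])
            entities.setdefault(e)
            partners.add(p)
            triples.append((e, p, s))
    if not triples:
        raise ValueError(f"{path}: empty score file")
    entity_ids = list(entities)
    partner_ids = sorted(partners)
    ei = {e: i for i, e in enumerate(entity_ids)}
    pi = {p: i for i, p in enumerate(partner_ids)}
    R = np.zeros((len(entity_ids), len(partner_ids)))
    for e, p, s in triples:
        R[ei[e], pi[p]] = s
    return ScoreMatrix(entity_ids, partner_ids, R)


# ---------------------------------------------------------------------------
# sparse network caches (intermediate files between the build and walk steps)
# ---------------------------------------------------------------------------
#
# Line-oriented TSV: "N<TAB>id" declares a node in axis order ("R"/"C" for
# the two axes of an association matrix), "E<TAB>i<TAB>j<TAB>w" declares a
# nonzero entry by positional index.  Symmetric matrices store the upper
# triangle only.


def write_square_net(ids, matrix, path) -> None:
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"N\t{i}\n")
        for a in range(matrix.shape[0]):
            for b in range(a + 1, matrix.shape[1]):
                if matrix[a, b] != 0:
                    fh.write(f"E\t{a}\t{b}\t{FLOAT_FMT.format(matrix[a, b])}\n")


def read_square_net(path) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    entries: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "N":
                ids.append(fields[1])
            elif fields[0] == "E":
                entries.append((int(fields[1]), int(fields[2]), float(fields[3])))
            elif fields[0]:
                raise ValueError(f"{path}:{lineno}: unknown record {fields[0]!r}")
    M = np.zeros((len(ids), len(ids)))
    for a, b, w in entries:
        M[a, b] = w
        M[b, a] = w
    return ids, M


def write_assoc(assoc, path) -> None:
    with open(path, "w") as fh:
        for e in assoc.entity_ids:
            fh.write(f"R\t{e}\n")
        for p in assoc.partner_ids:
            fh.write(f"C\t{p}\n")
        A = assoc.A
        for i in range(A.shape[0]):
            for j in range(A.shape[1]):
                if A[i, j] != 0:
                    fh.write(f"E\t{i}\t{j}\t{FLOAT_FMT.format(A[i, j])}\n")


def read_assoc(path):
    from .containers import AssocMatrix

    rows: list[str] = []
    cols: list[str] = []
    entries: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "R":
                rows.append(fields[1])
            elif fields[0] == "C":
                cols.append(fields[1])
            elif fields[0] == "E":
                entries.append((int(fields[1]), int(fields[2]), float(fields[3])))
            elif fields[0]:
                raise ValueError(f"{path}:{lineno}: unknown record {fields[0]!r}")
    A = np.zeros((len(rows), len(cols)))
    for i, j, w in entries:
        A[i, j] = w
    return AssocMatrix(rows, cols, A)
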