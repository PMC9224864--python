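"""Readers and in-memory containers for associations, expression weights and disease DAGs.

Input dialects are deliberately minimal, plain tab-separated text:

* association list — two columns ``miRNA_id<TAB>disease_id``;
* expression table — ``miRNA_id<TAB>value`` (per-miRNA, broadcast across
  diseases) or ``miRNA_id<TAB>condition_id<TAB>value`` (per pair);
* disease DAG — either a parent/child edge list or a MeSH-style
  ``id<TAB>tree.number`` file where an edge links each tree-number prefix to
  its one-level extension.

Lines starting with ``#`` are comments in every dialect.  Row and column
order of all matrices is the sorted lexicographic order of the ids, so the
same files always produce identically indexed matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "WeightMatrix",
    "DiseaseDAG",
    "ExpressionTable",
    "read_association_pairs",
    "write_association_pairs",
    "build_weight_matrix",
    "read_disease_dag",
]


@dataclass
class AssociationMatrix:
    """Binary miRNA x disease association matrix.

    ``y[i, j] = 1`` iff miRNA ``mirna_ids[i]`` has a known association with
    disease ``disease_ids[j]``.  Ids are unique and sorted.
    """

    mirna_ids: list[str]
    disease_ids: list[str]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        p, q = len(self.mirna_ids), len(self.disease_ids)
        if p < 1 or q < 1:
            raise ValueError("association matrix needs at least one miRNA and one disease")
        if self.y.shape != (p, q):
            raise ValueError(f"y has shape {self.y.shape}, expected {(p, q)}")
        if len(set(self.mirna_ids)) != p or len(set(self.disease_ids)) != q:
            raise ValueError("duplicate ids in association matrix axes")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("association matrix entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.y.shape

    def mirna_index(self, mirna: str) -> int:
        try:
            return self.mirna_ids.index(mirna)
        except ValueError:
            raise KeyError(f"unknown miRNA id: {mirna!r}") from None

    def disease_index(self, disease: str) -> int:
        try:
            return self.disease_ids.index(disease)
        except ValueError:
            raise KeyError(f"unknown disease id: {disease!r}") from None

    @classmethod
    def from_pairs(cls, pairs: "list[tuple[str, str]]") -> "AssociationMatrix":
        """Build from (miRNA, disease) pairs; duplicates collapse to one 1."""
        if not pairs:
            raise ValueError("no associations")
        mirnas = sorted({m for m, _ in pairs})
        diseases = sorted({d for _, d in pairs})
        y = np.zeros((len(mirnas), len(diseases)))
        mi = {m: i for i, m in enumerate(mirnas)}
        di = {d: j for j, d in enumerate(diseases)}
        for m, d in pairs:
            y[mi[m], di[d]] = 1.0
        return cls(mirnas, diseases, y)

    def to_pairs(self) -> list[tuple[str, str]]:
        return [
            (self.mirna_ids[i], self.disease_ids[j])
            for i, j in zip(*np.nonzero(self.y))
        ]


@dataclass
class WeightMatrix:
    """Per-entry confidence weights for the factorization loss.

    ``w`` is index-aligned with an :class:`AssociationMatrix`: 1 on the
    support of ``y`` (observed associations carry full weight) and the
    normalized expression-derived confidence elsewhere.  ``unobserved``
    retains the expression weight of *every* entry, including observed ones,
    which cross-validation needs when it flips an observed entry to
    unobserved.
    """

    w: np.ndarray
    unobserved: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.unobserved is not None:
            self.unobserved = np.asarray(self.unobserved, dtype=float)
            if self.unobserved.shape != self.w.shape:
                raise ValueError("unobserved weights shape mismatch")
        if np.any(self.w < 0) or np.any(self.w > 1):
            raise ValueError("weights must lie in [0, 1]")


@dataclass
class ExpressionTable:
    """miRNA expression records, optionally stratified by condition/disease.

    Stored as a DataFrame with columns ``mirna``, ``condition`` (may be all
    NaN for the per-miRNA dialect) and ``value``.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"mirna", "condition", "value"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"expression table must have columns {sorted(required)}")
        vals = self.records["value"].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError("expression values must be finite")

    @property
    def has_conditions(self) -> bool:
        return self.records["condition"].notna().any()

    @classmethod
    def from_arrays(
        cls,
        mirnas: "list[str]",
        values: "np.ndarray",
        conditions: "list[str] | None" = None,
    ) -> "ExpressionTable":
        df = pd.DataFrame(
            {
                "mirna": mirnas,
                "condition": conditions if conditions is not None else [None] * len(mirnas),
                "value": np.asarray(values, dtype=float),
            }
        )
        return cls(df)

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionTable":
        """Read a 2-column (mirna, value) or 3-column (mirna, condition, value) table."""
        rows = []
        for lineno, fields in _iter_tsv(path):
            if len(fields) == 2:
                rows.append((fields[0], None, _parse_float(fields[1], path, lineno)))
            elif len(fields) == 3:
                rows.append((fields[0], fields[1], _parse_float(fields[2], path, lineno)))
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {len(fields)}"
                )
        if not rows:
            raise ValueError(f"{path}: empty expression table")
        df = pd.DataFrame(rows, columns=["mirna", "condition", "value"])
        return cls(df)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for row in self.records.itertuples(index=False):
                if row.condition is None or (isinstance(row.condition, float) and np.isnan(row.condition)):
                    fh.write(f"{row.mirna}\t{row.value:.10g}\n")
                else:
                    fh.write(f"{row.mirna}\t{row.condition}\t{row.value:.10g}\n")

    def normalized(self) -> pd.DataFrame:
        """Records with values min-max normalized to [0, 1] over the whole table."""
        vals = self.records["value"].to_numpy(dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            raise ValueError("degenerate normalization: all expression values identical")
        out = self.records.copy()
        out["value"] = (vals - lo) / (hi - lo)
        return out


@dataclass
class DiseaseDAG:
    """Disease hierarchy as a parent->child DAG with a semantic decay factor delta."""

    nodes: frozenset[str]
    parent_edges: frozenset[tuple[str, str]]
    delta: float
    _graph: nx.DiGraph | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not (0 < self.delta <= 1):
            raise ValueError(f"delta must lie in (0, 1], got {self.delta}")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.parent_edges)
        if not set(g.nodes) <= set(self.nodes):
            raise ValueError("edge endpoints must be listed in nodes")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"disease DAG contains a cycle: {cycle}")
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        assert self._graph is not None
        return self._graph

    def __contains__(self, disease: str) -> bool:
        return disease in self.nodes

    def ancestors(self, disease: str) -> set[str]:
        """T(D): all ancestors of ``disease`` including itself."""
        if disease not in self.nodes:
            raise KeyError(f"disease not in DAG: {disease!r}")
        return nx.ancestors(self.graph, disease) | {disease}

    def children(self, disease: str) -> set[str]:
        return set(self.graph.successors(disease))


def _iter_tsv(path: str | Path):
    """Yield (lineno, fields) for non-empty, non-comment lines of a TSV file."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_float(text: str, path, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: not a number: {text!r}") from None


def read_association_pairs(path: str | Path) -> AssociationMatrix:
    """Read a two-column miRNA/disease pair list into a binary matrix.

    Duplicate pairs collapse to a single 1.  Ids are deduplicated and sorted
    so the index ordering is deterministic across runs.
    """
    pairs = []
    for lineno, fields in _iter_tsv(path):
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ValueError(f"{path}: no associations")
    return AssociationMatrix.from_pairs(pairs)


def write_association_pairs(assoc: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m, d in assoc.to_pairs():
            fh.write(f"{m}\t{d}\n")


def build_weight_matrix(
    assoc: AssociationMatrix,
    expr: ExpressionTable,
    missing_default: float | None = None,
) -> WeightMatrix:
    """Turn an expression table into per-entry confidence weights.

    Unobserved entries (``y = 0``) get the min-max-normalized expression
    value for their (miRNA, disease) pair — or the miRNA's single value
    broadcast across all diseases when the table has no condition column.
    Observed entries keep full weight 1.

    miRNAs absent from the table raise unless ``missing_default`` (in
    ``[0, 1]``) supplies a fallback weight for their unobserved entries.
    """
    norm = expr.normalized()
    p, q = assoc.shape
    unobserved = np.full((p, q), np.nan)

    if expr.has_conditions:
        lut = {
            (r.mirna, r.condition): r.value
            for r in norm.itertuples(index=False)
            if r.condition is not None
        }
        for i, m in enumerate(assoc.mirna_ids):
            for j, d in enumerate(assoc.disease_ids):
                if (m, d) in lut:
                    unobserved[i, j] = lut[(m, d)]
        # per-miRNA rows mixed into a 3-column file still broadcast
        per_mirna = {
            r.mirna: r.value for r in norm.itertuples(index=False) if r.condition is None
        }
        for i, m in enumerate(assoc.mirna_ids):
            row = unobserved[i]
            if m in per_mirna:
                row[np.isnan(row)] = per_mirna[m]
    else:
        per_mirna = {r.mirna: r.value for r in norm.itertuples(index=False)}
        for i, m in enumerate(assoc.mirna_ids):
            if m in per_mirna:
                unobserved[i, :] = per_mirna[m]

    missing = np.isnan(unobserved)
    if missing.any():
        if missing_default is None:
            bad = [assoc.mirna_ids[i] for i in sorted(set(np.nonzero(missing)[0]))]
            raise ValueError(
                f"miRNAs without expression values and no default policy: {bad}"
            )
        if not (0 <= missing_default <= 1):
            raise ValueError("missing_default must lie in [0, 1]")
        logger.warning(
            "%d entries lack expression values; using default weight %g",
            int(missing.sum()),
            missing_default,
        )
        unobserved[missing] = missing_default

    w = np.where(assoc.y == 1, 1.0, unobserved)
    return WeightMatrix(w=w, unobserved=unobserved)


def read_disease_dag(
    path: str | Path,
    delta: float = 0.5,
    dialect: str = "edges",
) -> DiseaseDAG:
    """Read a disease hierarchy.

    ``dialect="edges"`` — two columns ``parent<TAB>child``.
    ``dialect="treenum"`` — two columns ``disease_id<TAB>tree.number``; an
    edge is created from the owner of each tree-number prefix to the owner
    of its one-level dot extension (e.g. ``C04`` -> ``C04.588``).
    """
    if dialect not in ("edges", "treenum"):
        raise ValueError(f"unknown DAG dialect: {dialect!r}")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    if dialect == "edges":
        for lineno, fields in _iter_tsv(path):
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            parent, child = fields
            nodes.update((parent, child))
            edges.add((parent, child))
    else:
        owner: dict[str, str] = {}  # tree number -> disease id
        for lineno, fields in _iter_tsv(path):
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                )
            disease, treenum = fields
            owner[treenum] = disease
            nodes.add(disease)
        for treenum, disease in owner.items():
            if "." in treenum:
                prefix = treenum.rsplit(".", 1)[0]
                if prefix in owner:
                    edges.add((owner[prefix], disease))
    if not nodes:
        raise ValueError(f"{path}: empty DAG file")
    return DiseaseDAG(nodes=frozenset(nodes), parent_edges=frozenset(edges), delta=delta)
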