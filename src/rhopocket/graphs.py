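"""Molecular graphs: pocket atoms as nodes, covalent-range contacts as edges.

Atoms closer than 2 Å are connected — this captures all covalent bonds
(typical bond lengths 1.2–1.8 Å) and yields a sparse graph.  Edges carry a
scalar weight derived from the interatomic distance, by default 1/d, so
shorter (stronger) bonds weigh more.  Because the graph depends on the
geometry only through pairwise distances, everything downstream is
invariant under rigid motions of the input structure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .structure import Structure

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Default distance cutoff in Å (strict inequality).
EDGE_CUTOFF = 2.0


def edge_weight(d: float | np.ndarray) -> float | np.ndarray:
    """Edge weight for a bond of length ``d`` Å: 1/d (strictly decreasing)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("edge_weight: distance must be positive")
    out = 1.0 / d
    return float(out) if out.ndim == 0 else out


@dataclass
class MolecularGraph:
    """Node features + symmetric directed edge list with positive weights."""

    node_features: np.ndarray           # (N, F)
    edges: np.ndarray                   # (E, 2) int, both directions stored
    edge_weights: np.ndarray            # (E,) positive
    label: float | None = None          # λmax in nm, if known
    graph_id: str = ""

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        n = self.n_nodes
        if self.edges.size:
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-edges are not allowed")
            if self.edges.min() < 0 or self.edges.max() >= n:
                raise ValueError("edge endpoint out of range")
            fwd = {(int(i), int(j)): w for (i, j), w in zip(self.edges, self.edge_weights)}
            for (i, j), w in fwd.items():
                if (j, i) not in fwd or not np.isclose(fwd[(j, i)], w):
                    raise ValueError("edge set must be symmetric with equal weights")
        if np.any(self.edge_weights <= 0):
            raise ValueError("edge weights must be positive")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_directed_edges(self) -> int:
        return self.edges.shape[0]

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize to the documented JSON container (0-based indices)."""
        payload = {
            "schema_version": SCHEMA_VERSION,
            "graph_id": self.graph_id,
            "nodes": self.node_features.tolist(),
            "edges": [
                [int(i), int(j), float(w)]
                for (i, j), w in zip(self.edges, self.edge_weights)
            ],
            "label": self.label,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MolecularGraph":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported graph schema version {payload.get('schema_version')}")
        edges = np.array([[e[0], e[1]] for e in payload["edges"]], dtype=int).reshape(-1, 2)
        weights = np.array([e[2] for e in payload["edges"]], dtype=float)
        return cls(
            node_features=np.array(payload["nodes"], dtype=float),
            edges=edges,
            edge_weights=weights,
            label=payload.get("label"),
            graph_id=payload.get("graph_id", ""),
        )


def build_graph(
    pocket: Structure,
    features: np.ndarray,
    cutoff: float = EDGE_CUTOFF,
    weight_fn: Callable[[np.ndarray], np.ndarray] = edge_weight,
    label: float | None = None,
    graph_id: str | None = None,
) -> MolecularGraph:
    """Connect atom pairs strictly closer than ``cutoff`` Å.

    ``features`` is the (already normalized) node-feature matrix aligned
    with the pocket's atom order.  Isolated nodes are kept (and logged):
    they still contribute to the mean readout.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] != pocket.n_atoms:
        raise ValueError(
            f"feature rows ({features.shape[0]}) must equal atom count ({pocket.n_atoms})"
        )
    coords = pocket.coords()
    pairs = cKDTree(coords).query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        strict = d < cutoff  # query_pairs is inclusive of boundary within fp noise
        pairs, d = pairs[strict], d[strict]
    if pairs.size:
        w = weight_fn(d)
        edges = np.vstack([pairs, pairs[:, ::-1]])
        weights = np.concatenate([w, w])
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        edges, weights = edges[order], weights[order]
    else:
        edges = np.empty((0, 2), dtype=int)
        weights = np.empty(0)
    degree = np.zeros(pocket.n_atoms, dtype=int)
    if edges.size:
        np.add.at(degree, edges[:, 0], 1)
    n_isolated = int((degree == 0).sum())
    if n_isolated:
        logger.info("%s: %d isolated node(s) kept", graph_id or pocket.source_id, n_isolated)
    return MolecularGraph(
        node_features=features,
        edges=edges,
        edge_weights=weights,
        label=label,
        graph_id=graph_id or pocket.source_id,
    )
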