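"""The weighted, undirected network container used throughout the package.

A :class:`WeightedNetwork` holds one subject's connectivity graph: a
symmetric, nonnegative adjacency matrix with a zero diagonal and weights in
[0, 1] (absolute correlations).  All downstream stages (global metrics, null
models, the experiment pipeline) consume this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class WeightedNetwork:
    """Symmetric weighted graph with zero diagonal and weights in [0, 1].

    Parameters
    ----------
    adjacency
        Square ``(n, n)`` array.  Must be exactly symmetric with a zero
        diagonal; entries are edge weights (0 means "no edge").
    node_ids
        Optional node labels; defaults to ``"n0" .. "n{n-1}"``.
    """

    adjacency: np.ndarray
    node_ids: list[str] = field(default=None)  # type: ignore[assignment]
    validate: bool = True

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if self.validate:
            if a.ndim != 2 or a.shape[0] != a.shape[1]:
                raise ValueError(f"adjacency must be square, got shape {a.shape}")
            if not np.array_equal(a, a.T):
                raise ValueError("adjacency must be exactly symmetric")
            if np.any(np.diag(a) != 0.0):
                raise ValueError("adjacency diagonal must be exactly zero")
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError("edge weights must lie in [0, 1]")
            if not np.all(np.isfinite(a)):
                raise ValueError("edge weights must be finite")
        self.adjacency = a
        if self.node_ids is None:
            self.node_ids = [f"n{i}" for i in range(a.shape[0])]
        elif len(self.node_ids) != a.shape[0]:
            raise ValueError("node_ids length must match adjacency size")

    # -- basic structure ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    def degrees(self) -> np.ndarray:
        """Binary degree of every node."""
        iu, iv, _ = self.edge_array()
        return np.bincount(
            np.concatenate([iu, iv]), minlength=self.n_nodes
        ).astype(int)

    def strengths(self) -> np.ndarray:
        """Weighted degree (sum of incident edge weights) of every node."""
        return self.adjacency.sum(axis=1)

    def edge_array(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Edges as ``(u, v, w)`` arrays with ``u < v`` (cached)."""
        cached = getattr(self, "_edge_cache", None)
        if cached is None:
            iu, iv = np.nonzero(np.triu(self.adjacency, k=1))
            cached = (iu, iv, self.adjacency[iu, iv])
            self._edge_cache = cached
        return cached

    def is_connected(self) -> bool:
        from scipy.sparse import csr_matrix
        from scipy.sparse.csgraph import connected_components

        n, _ = connected_components(csr_matrix(self.adjacency), directed=False)
        return n == 1

    # -- construction ------------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: np.ndarray,
        weights: np.ndarray,
        node_ids: list[str] | None = None,
    ) -> "WeightedNetwork":
        """Build a network from an ``(m, 2)`` edge index array and weights.

        The result is symmetric and zero-diagonal by construction, so
        per-entry validation is skipped (weights are range-checked).
        """
        e = np.asarray(edges, dtype=int)
        w = np.asarray(weights, dtype=float)
        if len(e) and (np.any(w < 0) or np.any(w > 1) or not np.all(np.isfinite(w))):
            raise ValueError("edge weights must be finite and lie in [0, 1]")
        if len(e) and np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-loops are not allowed")
        a = np.zeros((n_nodes, n_nodes))
        a[e[:, 0], e[:, 1]] = w
        a[e[:, 1], e[:, 0]] = w
        return cls(a, node_ids=node_ids, validate=False)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the adjacency as a square TSV headered by node ids."""
        pd.DataFrame(self.adjacency, index=self.node_ids, columns=self.node_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path) -> "WeightedNetwork":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), node_ids=[str(c) for c in df.columns])

    def edge_list_frame(self) -> pd.DataFrame:
        iu, iv, w = self.edge_array()
        ids = np.asarray(self.node_ids)
        return pd.DataFrame(
            {"node_a": ids[iu], "node_b": ids[iv], "weight": w}
        )
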