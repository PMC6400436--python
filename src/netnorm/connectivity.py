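"""From node time series to a significance-thresholded weighted graph.

The stages mirror a standard resting-state functional-connectivity recipe:
drop the first few volumes (magnetization equilibrium), high-pass filter
each node's series (discrete-cosine basis, default 100 s cutoff), take the
absolute Pearson correlation between every node pair as the edge weight,
and zero out edges whose correlation is not significant after Bonferroni
correction over all node pairs at alpha = 0.05.

Image-domain preprocessing (motion correction, ICA denoising, smoothing)
is out of scope: inputs are assumed to be clean node-by-time matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import WeightedNetwork


@dataclass
class BoldTimeSeries:
    """A node-by-time matrix of BOLD-like signals for one subject."""

    matrix: np.ndarray
    tr_seconds: float = 2.0
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValueError("time series must be a 2-D node-by-time matrix")
        if not np.all(np.isfinite(m)):
            raise ValueError("time series contains non-finite values")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path) -> None:
        """Rows = nodes, columns = timepoints."""
        pd.DataFrame(self.matrix).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(cls, path, tr_seconds: float = 2.0, subject_id: str = "subject"):
        m = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        return cls(m, tr_seconds=tr_seconds, subject_id=subject_id)


def drop_initial_volumes(ts: BoldTimeSeries, n_drop: int = 5) -> BoldTimeSeries:
    """Remove the first ``n_drop`` timepoints (default 5)."""
    if n_drop < 0:
        raise ValueError("n_drop must be nonnegative")
    if n_drop >= ts.n_timepoints:
        raise ValueError(
            f"cannot drop {n_drop} of {ts.n_timepoints} timepoints"
        )
    return BoldTimeSeries(ts.matrix[:, n_drop:], ts.tr_seconds, ts.subject_id)


def _dct_basis(n_timepoints: int, n_components: int) -> np.ndarray:
    """Orthonormal DCT-II low-frequency regressors (excluding the constant)."""
    t = np.arange(n_timepoints)
    basis = np.cos(
        np.pi * (t[:, None] + 0.5) * np.arange(1, n_components + 1)[None, :] / n_timepoints
    )
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def high_pass_filter(ts: BoldTimeSeries, cutoff_seconds: float = 100.0) -> BoldTimeSeries:
    """Remove slow drifts below ``1 / cutoff_seconds`` Hz from every node.

    Implemented as least-squares removal of the discrete-cosine basis
    functions with period longer than the cutoff, plus the row mean.  If
    the record is too short to contain even one such basis function, only
    the mean is removed (with a warning).
    """
    if cutoff_seconds <= 2 * ts.tr_seconds:
        raise ValueError("cutoff must exceed twice the repetition time")
    record_seconds = ts.n_timepoints * ts.tr_seconds
    x = ts.matrix - ts.matrix.mean(axis=1, keepdims=True)
    n_comp = int(np.floor(2.0 * record_seconds / cutoff_seconds))
    if n_comp < 1:
        warnings.warn(
            "record shorter than half the cutoff period; mean removal only"
        )
        return BoldTimeSeries(x, ts.tr_seconds, ts.subject_id)
    basis = _dct_basis(ts.n_timepoints, n_comp)
    coef = x @ basis  # orthonormal basis: projection = basis @ coef.T
    filtered = x - coef @ basis.T
    return BoldTimeSeries(filtered, ts.tr_seconds, ts.subject_id)


def correlation_edges(ts: BoldTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson r and two-sided p-values between node time series.

    p-values come from the exact t transform with ``T - 2`` degrees of
    freedom, correct down to short records.
    """
    if ts.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    sd = ts.matrix.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if len(bad):
        raise ValueError(f"zero-variance time series at node index {bad[0]}")
    r = np.corrcoef(ts.matrix)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    dof = ts.n_timepoints - 2
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        tstat = np.abs(r) * np.sqrt(dof / np.maximum(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(tstat, dof)
    np.fill_diagonal(p, 0.0)
    return r, p


def build_graph(
    r: np.ndarray, p: np.ndarray, alpha: float = 0.05, node_ids: list[str] | None = None
) -> WeightedNetwork:
    """Absolute-correlation graph with Bonferroni significance filtering.

    An edge keeps weight ``|r|`` iff its p-value passes ``alpha / m`` where
    ``m = n (n - 1) / 2`` is the number of node pairs tested per subject.
    """
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape or r.ndim != 2 or r.shape[0] != r.shape[1]:
        raise ValueError("r and p must be conformable square matrices")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = r.shape[0]
    m = n * (n - 1) // 2
    keep = p <= alpha / m
    a = np.where(keep, np.abs(r), 0.0)
    a = (a + a.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(a, 0.0)
    return WeightedNetwork(a, node_ids=node_ids)


def critical_r(n_timepoints: int, n_nodes: int, alpha: float = 0.05) -> float:
    """Smallest |r| that passes the Bonferroni-corrected two-sided t test.

    The per-pair level is ``alpha / m`` with ``m = n (n - 1) / 2``; the
    t statistic is monotone in |r|, so thresholding p-values at
    ``alpha / m`` is identical to thresholding |r| at this value.
    """
    dof = n_timepoints - 2
    m = n_nodes * (n_nodes - 1) // 2
    t_crit = stats.t.isf(alpha / m / 2.0, dof)
    return float(t_crit / np.sqrt(dof + t_crit**2))


def timeseries_to_network(
    ts: BoldTimeSeries,
    n_drop: int = 5,
    cutoff_seconds: float = 100.0,
    alpha: float = 0.05,
) -> WeightedNetwork:
    """The full common pipeline: drop volumes, filter, correlate, threshold.

    Equivalent to ``build_graph(*correlation_edges(...), alpha)`` but
    thresholds |r| directly at the critical value (one inverse-t call
    instead of a p-value per node pair).
    """
    ts = drop_initial_volumes(ts, n_drop=n_drop)
    ts = high_pass_filter(ts, cutoff_seconds=cutoff_seconds)
    sd = ts.matrix.std(axis=1)
    bad = np.nonzero(sd == 0)[0]
    if len(bad):
        raise ValueError(f"zero-variance time series at node index {bad[0]}")
    # standardized rows + symmetric rank-k product: half the flops of a
    # generic matmul, identical result to np.corrcoef up to rounding
    from scipy.linalg.blas import dsyrk

    xm = ts.matrix - ts.matrix.mean(axis=1, keepdims=True)
    xm /= np.linalg.norm(xm, axis=1, keepdims=True)
    r = dsyrk(1.0, xm)
    r = r + np.triu(r, k=1).T
    r = np.clip(r, -1.0, 1.0)
    r_crit = critical_r(ts.n_timepoints, ts.n_nodes, alpha)
    a = np.where(np.abs(r) >= r_crit, np.abs(r), 0.0)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return WeightedNetwork(a, validate=False)


def edge_table(net: WeightedNetwork, r: np.ndarray, p: np.ndarray) -> pd.DataFrame:
    """Edge list with weight, signed r and p for the surviving edges."""
    iu, iv, w = net.edge_array()
    ids = np.asarray(net.node_ids)
    return pd.DataFrame(
        {
            "node_a": ids[iu],
            "node_b": ids[iv],
            "weight": w,
            "r": r[iu, iv],
            "p": p[iu, iv],
        }
    )
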