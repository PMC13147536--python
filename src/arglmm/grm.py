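"""Implicit branch-GRM products and the generative effect simulator.

The branch GRM ``B = Z Sigma_A Z^T`` is never formed.  Products ``B w``
are computed by one sweep along the genome (see :mod:`arglmm._kernels`),
assigning each sub-edge the weight ``A_e * S_e`` where ``S_e`` is the sum
of input weights over the samples below it (the "up" quantity), and
pushing the weights back down to the samples; complexity is
O(N + E log N) per column.  Submatrix products ``B[rows, cols] w``
scatter onto the column set, run the full product, and gather the rows.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .arg import ArgData

__all__ = ["BranchGRMOperator", "grm_matvec", "simulate_genetic_values"]


class BranchGRMOperator:
    """Matrix-free individual-level branch GRM for one ARG.

    Parameters
    ----------
    arg:
        The ARG with its individual grouping.
    centered:
        If True the operator is ``P_N B P_N`` with
        ``P_N = I - (1/N) 1 1^T`` (centering over all N individuals,
        also when restricted to a submatrix).
    scale:
        Scalar multiplier applied to every product; the simulation
        workflow uses ``1 / (4 * total_root_area)`` so that variance
        components are O(1).
    rows, cols:
        Optional index sets restricting the operator to
        ``B[rows, cols]``; defaults to all individuals.
    """

    def __init__(self, arg: ArgData, centered=False, scale=1.0, rows=None, cols=None):
        self.arg = arg
        self.centered = bool(centered)
        self.scale = float(scale)
        n = arg.num_individuals
        self.rows = _check_index(rows, n)
        self.cols = _check_index(cols, n)
        ts = arg.ts
        tables = ts.tables
        self._args = (
            ts.num_nodes,
            tables.nodes.time,
            tables.edges.left,
            tables.edges.right,
            tables.edges.parent.astype(np.int64),
            tables.edges.child.astype(np.int64),
            tables.indexes.edge_insertion_order.astype(np.int64),
            tables.indexes.edge_removal_order.astype(np.int64),
            ts.sequence_length,
        )
        self._time_desc = np.argsort(-tables.nodes.time, kind="stable").astype(np.int64)

    @property
    def shape(self):
        return (len(self.rows), len(self.cols))

    @property
    def dim(self):
        if len(self.rows) != len(self.cols):
            raise ValueError("operator is rectangular")
        return len(self.rows)

    def matmat(self, W: np.ndarray) -> np.ndarray:
        """Product with a (len(cols), k) block of column vectors."""
        W = np.asarray(W, dtype=float)
        single = W.ndim == 1
        if single:
            W = W[:, None]
        if W.shape[0] != len(self.cols):
            raise ValueError(
                f"weight block has {W.shape[0]} rows, expected {len(self.cols)}"
            )
        if not np.all(np.isfinite(W)):
            raise ValueError("non-finite weights")
        n = self.arg.num_individuals
        full = np.zeros((n, W.shape[1]))
        np.add.at(full, self.cols, W)
        if self.centered:
            full -= full.mean(axis=0, keepdims=True)
        nodes = self.arg.individual_expand(full)
        out_nodes = _kernels.matvec_sweep(*self._args, nodes, self._time_desc)
        out = self.arg.individual_reduce(out_nodes)
        if self.centered:
            out -= out.mean(axis=0, keepdims=True)
        out = self.scale * out[self.rows]
        return out[:, 0] if single else out

    __call__ = matmat

    def matvec(self, w: np.ndarray) -> np.ndarray:
        return self.matmat(w)


def _check_index(index, n) -> np.ndarray:
    if index is None:
        return np.arange(n)
    index = np.asarray(index, dtype=np.intp)
    if index.size and (index.min() < 0 or index.max() >= n):
        raise IndexError(f"individual index out of range [0, {n})")
    return index


def grm_matvec(
    arg: ArgData,
    w: np.ndarray,
    centered: bool = False,
    rows=None,
    cols=None,
    scale: float = 1.0,
) -> np.ndarray:
    """Exact product ``B[rows, cols] @ w`` (or its centered variant).

    Thin functional wrapper over :class:`BranchGRMOperator`.
    """
    return BranchGRMOperator(arg, centered=centered, scale=scale, rows=rows, cols=cols).matmat(w)


def simulate_genetic_values(
    arg: ArgData, tau2: float, seed: int, n_replicates: int = 1
) -> np.ndarray:
    """Draw genetic values ``g = Z u`` with ``u_e ~ N(0, tau2 * A_e)``.

    Independent Gaussian effects per sub-edge are generated during the
    same genome sweep used for matrix-vector products, so the draw costs
    O(N + E log N) per replicate and ``Cov(g) = tau2 * B`` exactly at the
    individual level.  Returns shape (N,) or (N, n_replicates).
    """
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    if not 0 <= int(seed) < 2**32:
        raise ValueError("seed must fit in 32 bits")
    op = BranchGRMOperator(arg)
    nodes = _kernels.simulate_sweep(
        *op._args, float(tau2), int(n_replicates), int(seed), op._time_desc
    )
    g = arg.individual_reduce(nodes)
    return g[:, 0] if n_replicates == 1 else g
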