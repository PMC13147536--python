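"""ARG containers and desk-scale (dense / brute-force) branch-GRM oracles.

An ancestral recombination graph (ARG) is held in the succinct tree
sequence encoding: a node table (times in generations, increasing into
the past) and an edge table of inherited genome segments ``[left, right)``
in 0-based half-open base-pair coordinates.  The quantitative-genetic
object derived from it is the *branch GRM*

    B = Z Sigma_A Z^T,

where columns of the (never materialized) dosage matrix ``Z`` are indexed
by *sub-edges* — maximal edge fragments whose descendant sample set is
constant — and ``Sigma_A`` is diagonal with sub-edge areas
``A_e = span * (t_parent - t_child)`` (bp * generations).

Everything in this module is intended for oracles and small fixtures; the
production matrix-vector products live in :mod:`arglmm.grm` and never
form sub-edges or ``B`` explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import tskit

__all__ = [
    "ArgData",
    "ArgStructureError",
    "SubEdge",
    "subedge_decompose",
    "dense_branch_grm",
    "total_root_area",
    "DENSE_GRM_GUARD",
]

#: refuse to build a dense GRM above this many individuals
DENSE_GRM_GUARD = 2000


class ArgStructureError(ValueError):
    """A node/edge table violates the ARG invariants."""


@dataclass(frozen=True)
class SubEdge:
    """An edge fragment with a constant descendant sample set.

    ``area`` is the fragment's mutational opportunity,
    ``(right - left) * (t_parent - t_child)`` in bp * generations.
    """

    parent: int
    child: int
    left: float
    right: float
    area: float


class ArgData:
    """An ARG plus the grouping of its sample nodes into individuals.

    Wraps a :class:`tskit.TreeSequence`.  ``sample_sets[i]`` holds the
    sample node ids of individual ``i`` (2 per individual for diploids);
    weights enter the GRM product replicated over an individual's nodes
    and node-level results are summed back per individual, which realizes
    the {0,1,2} dosage without forming it.
    """

    def __init__(self, ts: tskit.TreeSequence, sample_sets: Sequence[np.ndarray] | None = None):
        if sample_sets is None:
            sample_sets = _default_sample_sets(ts)
        self._ts = ts
        self.sample_sets = [np.asarray(s, dtype=np.int32) for s in sample_sets]
        flags = ts.tables.nodes.flags
        for group in self.sample_sets:
            if len(group) == 0:
                raise ArgStructureError("individual with no sample nodes")
            if not np.all(flags[group] & tskit.NODE_IS_SAMPLE):
                raise ArgStructureError(
                    f"individual references non-sample nodes: {group.tolist()}"
                )
        self._validate_edges()
        # node -> individual map (-1 for non-sample nodes)
        self.node_individual = np.full(ts.num_nodes, -1, dtype=np.int32)
        for i, group in enumerate(self.sample_sets):
            self.node_individual[group] = i

    # -- constructors -------------------------------------------------

    @classmethod
    def from_tree_sequence(cls, ts: tskit.TreeSequence) -> "ArgData":
        return cls(ts)

    @classmethod
    def from_tables(
        cls,
        node_times: Sequence[float],
        node_sample_flags: Sequence[bool],
        edges: Iterable[tuple[float, float, int, int]],
        sequence_length: float,
        individuals: Sequence[Sequence[int]] | None = None,
    ) -> "ArgData":
        """Build from raw tables: edges are ``(left, right, parent, child)``."""
        tables = tskit.TableCollection(sequence_length=sequence_length)
        for t, is_sample in zip(node_times, node_sample_flags, strict=True):
            tables.nodes.add_row(
                flags=tskit.NODE_IS_SAMPLE if is_sample else 0, time=t
            )
        for left, right, parent, child in edges:
            tables.edges.add_row(left=left, right=right, parent=parent, child=child)
        try:
            tables.sort()
            ts = tables.tree_sequence()
        except (tskit.LibraryError, ValueError) as err:
            raise ArgStructureError(f"malformed ARG tables: {err}") from err
        sample_sets = None
        if individuals is not None:
            sample_sets = [np.asarray(g, dtype=np.int32) for g in individuals]
        return cls(ts, sample_sets)

    @classmethod
    def load(cls, path: str) -> "ArgData":
        return cls(tskit.load(path))

    # -- views --------------------------------------------------------

    @property
    def ts(self) -> tskit.TreeSequence:
        return self._ts

    @property
    def num_individuals(self) -> int:
        return len(self.sample_sets)

    @property
    def sequence_length(self) -> float:
        return self._ts.sequence_length

    @property
    def node_times(self) -> np.ndarray:
        return self._ts.tables.nodes.time

    def individual_reduce(self, node_values: np.ndarray) -> np.ndarray:
        """Sum node-level values (nodes first axis) per individual."""
        out = np.zeros((self.num_individuals,) + node_values.shape[1:])
        for i, group in enumerate(self.sample_sets):
            out[i] = node_values[group].sum(axis=0)
        return out

    def individual_expand(self, values: np.ndarray) -> np.ndarray:
        """Replicate individual-level values onto each sample node."""
        out = np.zeros((self._ts.num_nodes,) + values.shape[1:])
        for i, group in enumerate(self.sample_sets):
            out[group] = values[i]
        return out

    # -- validation ---------------------------------------------------

    def _validate_edges(self) -> None:
        ts = self._ts
        times = ts.tables.nodes.time
        edges = ts.tables.edges
        bad = np.nonzero(times[edges.parent] <= times[edges.child])[0]
        if bad.size:
            e = int(bad[0])
            raise ArgStructureError(
                f"edge {e} ({edges.parent[e]}->{edges.child[e]}): "
                "parent time not greater than child time"
            )
        if np.any(edges.left < 0) or np.any(edges.right > ts.sequence_length):
            e = int(
                np.nonzero((edges.left < 0) | (edges.right > ts.sequence_length))[0][0]
            )
            raise ArgStructureError(f"edge {e}: span outside [0, sequence_length)")


def _default_sample_sets(ts: tskit.TreeSequence) -> list[np.ndarray]:
    """Group sample nodes by tskit individual; fall back to one node each."""
    samples = ts.samples()
    individual = ts.tables.nodes.individual
    if np.all(individual[samples] >= 0) and ts.num_individuals > 0:
        groups: dict[int, list[int]] = {}
        for s in samples:
            groups.setdefault(int(individual[s]), []).append(int(s))
        return [np.array(groups[k], dtype=np.int32) for k in sorted(groups)]
    return [np.array([s], dtype=np.int32) for s in samples]


# ----------------------------------------------------------------------
# sub-edge decomposition (oracle / test construct)
# ----------------------------------------------------------------------


def subedge_decompose(arg: ArgData) -> list[SubEdge]:
    """Split every edge into fragments with a constant descendant sample set.

    Brute force by design: iterates local trees, records the sample set
    below each edge's child per tree, and merges genomically adjacent
    tree-spans of an edge while the set is unchanged.  Production code
    never calls this; it defines the semantics the implicit algorithms
    must reproduce.
    """
    ts = arg.ts
    # open fragments keyed by edge id: [left, right, frozenset(samples)]
    open_frag: dict[int, list] = {}
    out: list[SubEdge] = []
    times = arg.node_times
    for tree in ts.trees():
        present = set()
        for edge_id in _tree_edge_ids(tree):
            present.add(edge_id)
            edge = ts.edge(edge_id)
            below = frozenset(tree.samples(edge.child))
            frag = open_frag.get(edge_id)
            if frag is not None and frag[2] == below:
                frag[1] = tree.interval.right
            else:
                if frag is not None:
                    out.append(_close(frag, edge, times))
                open_frag[edge_id] = [
                    tree.interval.left,
                    tree.interval.right,
                    below,
                    edge_id,
                ]
        for edge_id in list(open_frag):
            if edge_id not in present:
                out.append(_close(open_frag.pop(edge_id), ts.edge(edge_id), times))
    for edge_id, frag in open_frag.items():
        out.append(_close(frag, ts.edge(edge_id), times))
    out.sort(key=lambda s: (s.parent, s.child, s.left))
    return out


def _close(frag, edge, times) -> SubEdge:
    left, right = frag[0], frag[1]
    dt = times[edge.parent] - times[edge.child]
    return SubEdge(
        parent=edge.parent,
        child=edge.child,
        left=left,
        right=right,
        area=(right - left) * dt,
    )


def _tree_edge_ids(tree: tskit.Tree) -> list[int]:
    ids = []
    for u in tree.nodes():
        e = tree.edge(u)
        if e != tskit.NULL:
            ids.append(e)
    return ids


# ----------------------------------------------------------------------
# dense oracles
# ----------------------------------------------------------------------


def dense_branch_grm(
    arg: ArgData,
    centered: bool = False,
    level: str = "individual",
    engine: str = "bruteforce",
) -> np.ndarray:
    """Dense branch GRM ``B = Z Sigma_A Z^T`` (oracle; guarded small N).

    With ``centered=True`` returns ``P_N B P_N`` where
    ``P_N = I - (1/N) 1 1^T``.  ``level`` selects individual-level
    (dosages in {0,1,2}) or haplotype/node-level rows.

    ``engine="bruteforce"`` accumulates rank-1 terms tree by tree
    (transparent but slow beyond ~100 samples on recombining ARGs);
    ``engine="tskit"`` materializes columns through tskit's independent
    C implementation of the branch-relatedness product.
    """
    ts = arg.ts
    if level == "individual":
        n = arg.num_individuals
        index = arg.node_individual
    elif level == "node":
        n = ts.num_samples
        index = np.full(ts.num_nodes, -1, dtype=np.int32)
        index[ts.samples()] = np.arange(ts.num_samples)
    else:
        raise ValueError(f"unknown level {level!r}")
    if n > DENSE_GRM_GUARD:
        raise ValueError(
            f"dense GRM refused for N={n} > {DENSE_GRM_GUARD}; "
            "use the implicit products in arglmm.grm"
        )
    if engine == "tskit":
        B = _dense_grm_tskit(arg, level, n, index)
        if centered:
            B = B - B.mean(axis=0)
            B = B - B.mean(axis=1, keepdims=True)
        return B
    if engine != "bruteforce":
        raise ValueError(f"unknown engine {engine!r}")
    times = arg.node_times
    B = np.zeros((n, n))
    # per-tree accumulation is a refinement of the sub-edge partition and
    # sums to the same B
    for tree in ts.trees():
        span = tree.interval.right - tree.interval.left
        if span == 0:
            continue
        for u in tree.nodes():
            p = tree.parent(u)
            if p == tskit.NULL:
                continue
            z = np.zeros(n)
            for s in tree.samples(u):
                if index[s] >= 0:
                    z[index[s]] += 1.0
            area = span * (times[p] - times[u])
            B += area * np.outer(z, z)
    if centered:
        B = B - B.mean(axis=0)
        B = B - B.mean(axis=1, keepdims=True)
    return B


def _dense_grm_tskit(arg: ArgData, level: str, n: int, index: np.ndarray) -> np.ndarray:
    """Columns of B through tskit's C branch-relatedness product.

    tskit normalizes by window span, hence the sequence-length factor.
    """
    ts = arg.ts
    samples = ts.samples()
    if level == "individual":
        Wnode = np.zeros((ts.num_samples, n))
        Wnode[np.arange(ts.num_samples), index[samples]] = 1.0
    else:
        Wnode = np.eye(n)
    out = ts.genetic_relatedness_vector(Wnode, mode="branch", centre=False)
    out *= ts.sequence_length
    if level == "individual":
        B = np.zeros((n, n))
        np.add.at(B, index[samples], out)
    else:
        B = out
    return (B + B.T) / 2


def total_root_area(arg: ArgData) -> float:
    """Sum over local trees of span * root time (bp * generations).

    Trees with several roots contribute span * root time for each root;
    isolated sample roots contribute their own (zero-height) time.
    """
    total = 0.0
    times = arg.node_times
    for tree in arg.ts.trees():
        span = tree.interval.right - tree.interval.left
        for root in tree.roots:
            total += span * times[root]
    return total
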