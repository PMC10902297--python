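"""Density-matched binarisation and multiplex participation metrics.

Weighted layers are binarised by keeping the ``floor(density * possible
edges)`` strongest edges, so that every layer of a subject's multiplex
network carries exactly the same edge density -- the density itself is
conventionally the minimum structural density observed in the older
group (22% in the reference cohort).  The multiplex participation
coefficient of node *i* over M layers is

    p_i = M / (M - 1) * [1 - sum_a (k_i^[a] / o_i)^2]

with k_i^[a] the degree of *i* in layer *a* and o_i = sum_a k_i^[a] the
overlapping degree.  p_i = 1 when the node engages both layers equally,
0 when a single layer holds all of its edges (and, by convention, for an
isolated node, where the formula is 0/0).
"""

from __future__ import annotations

import numpy as np

from .datatypes import ConnectivityMatrix, MultiplexNetwork, ParticipationResult
from .errors import TooSparseError

#: Default edge density: the minimum structural density of the older group.
DEFAULT_DENSITY = 0.22


def matrix_density(
    w: ConnectivityMatrix | np.ndarray,
    presence_threshold: float = 0.0,
    *,
    directed: bool | None = None,
) -> float:
    """Fraction of possible edges with weight above ``presence_threshold``.

    Possible edges are ``n(n-1)/2`` for undirected matrices and
    ``n(n-1)`` for directed ones; the diagonal never counts.
    """
    if isinstance(w, ConnectivityMatrix):
        values, is_dir = w.values, w.directed
    else:
        values = np.asarray(w, dtype=float)
        is_dir = bool(directed)
    n = values.shape[0]
    if values.ndim != 2 or values.shape[1] != n:
        raise ValueError("matrix must be square")
    if n < 2:
        return 0.0
    if is_dir:
        mask = ~np.eye(n, dtype=bool)
        count = int(np.sum(values[mask] > presence_threshold))
        possible = n * (n - 1)
    else:
        iu = np.triu_indices(n, k=1)
        count = int(np.sum(values[iu] > presence_threshold))
        possible = n * (n - 1) // 2
    return count / possible


def min_group_density(
    matrices: list[ConnectivityMatrix], presence_threshold: float = 0.0
) -> float:
    """Minimum ``matrix_density`` over a group of same-shaped matrices."""
    if not matrices:
        raise ValueError("empty matrix list")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"mixed matrix shapes: {sorted(shapes)}")
    return min(matrix_density(m, presence_threshold) for m in matrices)


def _edge_count(n: int, density: float, directed: bool) -> int:
    possible = n * (n - 1) if directed else n * (n - 1) // 2
    return int(np.floor(density * possible))


def binarize_to_density(
    w: ConnectivityMatrix | np.ndarray,
    density: float,
    *,
    directed: bool | None = None,
) -> np.ndarray:
    """Keep exactly the ``floor(density * possible)`` strongest edges.

    Ties at the cut are broken by lexicographic node-pair order, making
    the result deterministic; the edge set is invariant to multiplying
    all weights by a positive constant.

    Raises
    ------
    TooSparseError
        If the matrix has fewer strictly positive weights than the target
        edge count.
    """
    if isinstance(w, ConnectivityMatrix):
        values, is_dir = w.values, w.directed
    else:
        values = np.asarray(w, dtype=float)
        is_dir = bool(directed)
    n = values.shape[0]
    if not 0 < density <= 1:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    e = _edge_count(n, density, is_dir)
    if e == 0:
        raise ValueError(f"density {density} keeps zero edges on {n} nodes")

    if is_dir:
        ii, jj = np.where(~np.eye(n, dtype=bool))
    else:
        ii, jj = np.triu_indices(n, k=1)
    vals = values[ii, jj]
    if int(np.sum(vals > 0)) < e:
        raise TooSparseError(
            f"matrix too sparse for target density: {int(np.sum(vals > 0))} "
            f"positive weights < {e} target edges"
        )
    # primary key: descending weight; ties resolved by (i, j) ascending
    order = np.lexsort((jj, ii, -vals))
    keep = order[:e]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[ii[keep], jj[keep]] = 1
    if not is_dir:
        adj |= adj.T
    return adj


def build_multiplex(
    structural: ConnectivityMatrix,
    functional: ConnectivityMatrix,
    density: float = DEFAULT_DENSITY,
    direction_mode: str = "undirected",
) -> MultiplexNetwork:
    """Assemble the two-layer structure-function multiplex network.

    Both layers are binarised at the same density.  With
    ``direction_mode`` 'inward' or 'outward' the functional matrix must
    be directed (TE); it is thresholded over the ``n(n-1)`` ordered pairs
    and node degree later counts suprathreshold couplings directed toward
    (columns) or away from (rows) each node.
    """
    if structural.values.shape != functional.values.shape:
        raise ValueError("structural and functional layers differ in node count")
    if list(structural.labels) != list(functional.labels):
        raise ValueError("structural and functional node labels disagree")
    if direction_mode == "undirected":
        if functional.directed:
            raise ValueError(
                "directed functional matrix requires direction_mode 'inward' or 'outward'"
            )
    elif direction_mode in ("inward", "outward"):
        if not functional.directed:
            raise ValueError(f"direction_mode {direction_mode!r} requires a directed matrix")
    else:
        raise ValueError(f"unknown direction_mode {direction_mode!r}")

    a_struct = binarize_to_density(structural, density)
    a_func = binarize_to_density(functional, density)
    return MultiplexNetwork(
        layers=[a_struct, a_func],
        layer_tags=[
            f"{structural.modality}:{structural.band}",
            f"{functional.modality}:{functional.band}",
        ],
        density=density,
        direction_mode=direction_mode,
        directed_flags=[False, functional.directed],
        labels=list(structural.labels),
    )


def participation(mx: MultiplexNetwork) -> ParticipationResult:
    """Multiplex participation coefficient and degree metrics per node."""
    k = mx.degrees().astype(float)
    o = k.sum(axis=0)
    m = mx.n_layers
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios_sq = np.where(o > 0, (k / np.where(o > 0, o, 1.0)) ** 2, 0.0)
        p = m / (m - 1) * (1.0 - ratios_sq.sum(axis=0))
    p = np.where(o > 0, p, 0.0)  # isolated nodes participate in no layer
    p = np.clip(p, 0.0, 1.0)
    return ParticipationResult(
        k=k, o=o, p=p, d=k.sum(axis=1), labels=list(mx.labels)
    )


def layer_degree(mx: MultiplexNetwork, layer: int) -> np.ndarray:
    """Per-node degree of one layer (diagonal excluded)."""
    if not 0 <= layer < mx.n_layers:
        raise IndexError(f"layer index {layer} out of range for {mx.n_layers} layers")
    return mx.degrees()[layer]
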