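"""In-memory containers shared across the pipeline.

These are thin, validated dataclasses around numpy arrays; the heavier
tabular objects (cohort tables, results tables) are plain pandas
DataFrames with documented column dictionaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Connectivity modalities handled by the package.
MODALITIES = ("FA", "PLV", "wPLI", "TE")

#: Direction modes for the functional layer of a multiplex network.
DIRECTION_MODES = ("undirected", "inward", "outward")


@dataclass
class RoiTimeSeriesSet:
    """Multichannel ROI time series for a single subject.

    Parameters
    ----------
    data:
        Array of shape ``(n_samples, n_rois)``; rows are samples.
    labels:
        One label per ROI column.
    fs_hz:
        Sampling rate in Hz.
    subject_id:
        Free-form subject identifier.
    iaf_true_hz:
        Ground-truth individual alpha frequency when the set was simulated,
        ``None`` for real data.
    meta:
        Arbitrary provenance (seeds, generator parameters, ...).
    """

    data: np.ndarray
    labels: Sequence[str]
    fs_hz: float
    subject_id: str = "sub-00"
    iaf_true_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x ROIs)")
        if len(self.labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[1]} ROI columns"
            )
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = list(self.labels)

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


@dataclass
class ConnectivityMatrix:
    """One weighted connectivity layer (FA, PLV, wPLI or TE).

    The diagonal is forced to zero: auto-correlations between a region and
    itself are excluded from every analysis.  Undirected modalities must be
    symmetric; TE is the only directed modality.
    """

    values: np.ndarray
    modality: str
    band: str = "broadband"
    directed: bool = False
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.directed and self.modality != "TE":
            raise ValueError(f"{self.modality} is an undirected modality")
        if self.labels is None:
            from .atlas import generic_labels

            self.labels = generic_labels(self.n_nodes)
        elif len(self.labels) != self.n_nodes:
            raise ValueError("label count does not match matrix size")
        self.labels = list(self.labels)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        """Raise if the matrix violates its modality's invariants."""
        if np.any(self.values < -atol):
            raise ValueError(f"{self.modality} weights must be nonnegative")
        if not self.directed and not np.allclose(self.values, self.values.T, atol=atol):
            raise ValueError(f"undirected {self.modality} matrix is asymmetric")
        if self.modality in ("PLV", "wPLI") and np.any(self.values > 1 + atol):
            raise ValueError(f"{self.modality} values must lie in [0, 1]")


@dataclass
class MultiplexNetwork:
    """Two (or more) binary adjacency layers over a shared node set.

    All layers are binarised at the same density.  A directed functional
    layer stores the thresholded directed adjacency; ``direction_mode``
    decides whether node degree counts inward (column) or outward (row)
    suprathreshold couplings.
    """

    layers: list[np.ndarray]
    layer_tags: list[str]
    density: float
    direction_mode: str = "undirected"
    directed_flags: list[bool] | None = None
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if len(self.layers) < 2:
            raise ValueError("a multiplex network needs at least 2 layers")
        if self.direction_mode not in DIRECTION_MODES:
            raise ValueError(f"unknown direction_mode {self.direction_mode!r}")
        n = self.layers[0].shape[0]
        self.layers = [np.asarray(a, dtype=np.int8) for a in self.layers]
        for a in self.layers:
            if a.shape != (n, n):
                raise ValueError("all layers must share the node set")
            if np.any(np.diag(a) != 0):
                raise ValueError("layer adjacency has nonzero diagonal")
        if self.directed_flags is None:
            self.directed_flags = [False] * len(self.layers)
        if self.labels is None:
            from .atlas import generic_labels

            self.labels = generic_labels(n)
        self.labels = list(self.labels)

    @property
    def n_nodes(self) -> int:
        return self.layers[0].shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def degrees(self) -> np.ndarray:
        """Per-layer nodal degrees ``k_i^[alpha]``, shape ``(M, n)``.

        Undirected layers use row sums; a directed layer uses column sums
        under ``inward`` mode and row sums under ``outward`` mode.
        """
        out = np.empty((self.n_layers, self.n_nodes), dtype=np.int64)
        for m, (a, is_dir) in enumerate(zip(self.layers, self.directed_flags)):
            if is_dir and self.direction_mode == "inward":
                out[m] = a.sum(axis=0)
            else:
                out[m] = a.sum(axis=1)
        return out


@dataclass
class ParticipationResult:
    """Nodal multiplex degree metrics.

    ``k`` holds the per-layer degrees (shape ``(M, n)``), ``o`` the
    overlapping degree ``o_i = sum_a k_i^[a]``, ``p`` the multiplex
    participation coefficient and ``d`` the per-layer total degree.
    """

    k: np.ndarray
    o: np.ndarray
    p: np.ndarray
    d: np.ndarray
    labels: Sequence[str]

    def to_frame(self):
        import pandas as pd

        cols = {f"k_layer{m + 1}": self.k[m] for m in range(self.k.shape[0])}
        cols["overlapping_degree"] = self.o
        cols["participation"] = self.p
        return pd.DataFrame(cols, index=list(self.labels))
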