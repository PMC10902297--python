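"""Synthetic cohorts with planted ground truth.

Everything downstream of raw data acquisition is testable against this
module: it emulates (i) source-level ROI oscillations with a per-subject
alpha peak and controllable phase coupling and lagged directed
influence, (ii) FA-like weighted structural matrices with a tunable
edge-overlap against the functional coupling pattern, and (iii) a cohort
table whose cognition scores carry a planted linear dependence on
regional multiplex participation.

Oscillator model
----------------
ROI *i* of a subject is a noisy phase oscillator

    x_i(t) = cos(phi_i(t)) + directed influence terms + observation noise
    phi_i(t) = 2*pi*IAF*t + delta_i + sigma_phi * B_i(t)

where B_i is a standard Brownian phase with *correlated increments*: the
increment correlation between ROIs i and j equals the requested coupling
c_ij (after projection onto the nearest valid correlation matrix).  The
relative phase of a pair is then itself Brownian with diffusion
``2*sigma_phi^2*(1 - c_ij)``, which makes the phase-locking value ground
truth closed-form in the coupling: coupling 1 gives identical phases
(PLV exactly 1) and coupling 0 gives independently drifting phases whose
PLV decays toward the finite-sample floor.  Lagged directed influence is
a linear autoregressive term added on top of the oscillatory carrier, so
transfer entropy ground truth is nonzero exactly where the influence
matrix is.

Cohort model
------------
Functional coupling follows a random module partition per subject; the
module sizes are chosen once per configuration so the within-module pair
count equals the density-matched edge budget exactly, which pins the
binarised functional layer (and its degrees) to the planted truth.  The
structural layer realises a prescribed degree sequence

    k_s(i) ~ k_f(i) + (1 - alignment_i) * imbalance_i

with a symmetric random imbalance, preferring functional pairs with
probability ``structural_overlap``.  Because the multiplex participation
coefficient depends only on per-layer degrees, group effects are planted
through the *alignment*: raising it pulls a node's structural degree
toward its functional degree (participation -> 1), lowering it pushes
them apart.  The sign-symmetric imbalance leaves each node's marginal
degree distribution unchanged, so alignment effects are visible only to
joint (multiplex) statistics, not to unimodal contrasts.  The alignment
shift needed for a requested standardised effect size is calibrated once
per configuration by an internal Monte Carlo over the generator's own
randomness (fixed internal seed, no signals involved).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .atlas import generic_labels
from .datatypes import ConnectivityMatrix, RoiTimeSeriesSet
from .multiplex import _edge_count

__all__ = [
    "OscillatorSpec",
    "CohortSpec",
    "SyntheticCohort",
    "gen_oscillators",
    "gen_structural",
    "gen_cohort",
    "plv_ground_truth",
]

_CALIBRATION_SEED = 715517  # the alignment->effect-size map is a pure function of the spec
_IMBALANCE_RATIO = 3.0  # structural/functional degree ratio at alignment 0


@dataclass
class OscillatorSpec:
    """Generative parameters for one subject's ROI oscillations.

    coupling:
        Symmetric zero-diagonal matrix of pairwise phase-coupling
        strengths in [0, 1] (increment correlations).
    phase_lag:
        Matrix of imposed phase offsets in radians; entry (i, j), i < j,
        requests ``phase(j) - phase(i)``.  Offsets are realised as
        per-node phase potentials fitted by least squares, so mutually
        inconsistent lag matrices are approximated.
    directed_influence:
        Zero-diagonal matrix of lagged linear influence coefficients;
        entry (i, j) adds ``coef * carrier_i(t - influence_lag)`` to ROI j.
    noise_sd:
        SD of additive white observation noise (carrier amplitude is 1).
    phase_noise_sd:
        Phase diffusion scale sigma_phi in rad/sqrt(s); uncoupled ROI
        pairs decorrelate on a timescale ~1/sigma_phi^2.
    """

    n_rois: int
    iaf_hz: float = 10.0
    fs_hz: float = 250.0
    duration_s: float = 60.0
    coupling: np.ndarray | None = None
    phase_lag: np.ndarray | None = None
    directed_influence: np.ndarray | None = None
    influence_lag: int = 1
    noise_sd: float = 0.3
    phase_noise_sd: float = 3.0
    seed: int = 0
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be positive")
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValueError("sampling rate and duration must be positive")
        if self.duration_s < 10.0:
            raise ValueError("record must be at least 10 s long")
        n = self.n_rois
        if self.coupling is None:
            self.coupling = np.zeros((n, n))
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (n, n):
            raise ValueError("coupling matrix shape mismatch")
        if not np.allclose(self.coupling, self.coupling.T):
            raise ValueError("coupling must be symmetric")
        if np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling diagonal must be zero")
        if np.any(self.coupling < 0) or np.any(self.coupling > 1):
            raise ValueError("coupling strengths must lie in [0, 1]")
        if self.phase_lag is None:
            self.phase_lag = np.zeros((n, n))
        self.phase_lag = np.asarray(self.phase_lag, dtype=float)
        if self.phase_lag.shape != (n, n):
            raise ValueError("phase_lag matrix shape mismatch")
        if self.directed_influence is None:
            self.directed_influence = np.zeros((n, n))
        self.directed_influence = np.asarray(self.directed_influence, dtype=float)
        if self.directed_influence.shape != (n, n):
            raise ValueError("directed_influence matrix shape mismatch")
        if np.any(np.diag(self.directed_influence) != 0):
            raise ValueError("directed_influence diagonal must be zero")
        if self.influence_lag < 1:
            raise ValueError("influence_lag must be >= 1 sample")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.labels is None:
            self.labels = generic_labels(n)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs_hz * self.duration_s))


@dataclass
class CohortSpec:
    """Cohort-level generative parameters with planted ground truth.

    target_nodes:
        Node indices carrying the planted group effect in participation.
    effect_size_d:
        Standardised (Cohen's d) old-minus-young difference in true
        participation at target nodes; realised by shifting the
        degree alignment of the old group's target nodes.
    cognition_slope:
        Linear coefficient tying the planted cognition score to the
        first target node's true participation in the old group.
    structural_overlap:
        Probability that a functional edge compatible with the
        structural degree budget is adopted as a structural edge (the
        edge-identity overlap of the binarised layers).
    degree_alignment:
        Baseline alignment in [0, 1] between structural and functional
        nodal degrees; 1 collapses the imbalance entirely
        (participation -> 1), 0 leaves it at full strength.
    degree_alignment_old:
        When set, replaces the baseline alignment at every node of old
        subjects -- a "multiplex-only" group effect that shifts the
        joint degree profile while preserving per-node marginals.
    """

    n_young: int = 46
    n_old: int = 46
    target_nodes: tuple[int, ...] = (2, 11)
    effect_size_d: float = 0.0
    cognition_slope: float = 0.0
    structural_overlap: float = 0.65
    degree_alignment: float = 0.4
    degree_alignment_old: float | None = None
    density: float = 0.22
    score: str = "VSTM"
    score_noise_sd: float = 0.05
    module_rho: float = 0.998
    node_phase_spread: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 2 or self.n_old < 2:
            raise ValueError("need at least 2 subjects per group")
        if not 0 <= self.structural_overlap <= 1:
            raise ValueError("structural_overlap must lie in [0, 1]")
        if not 0 <= self.degree_alignment <= 1:
            raise ValueError("degree_alignment must lie in [0, 1]")
        if self.degree_alignment_old is not None and not (
            0 <= self.degree_alignment_old <= 1
        ):
            raise ValueError("degree_alignment_old must lie in [0, 1]")
        if not 0 < self.density <= 1:
            raise ValueError("density must lie in (0, 1]")
        self.target_nodes = tuple(int(t) for t in self.target_nodes)


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth it was planted with.

    ``truth`` maps: ``participation`` -> (n_subjects, n_rois) true
    multiplex participation; ``alignment_shifted`` -> calibrated
    alignment applied at old-group target nodes; ``k_functional`` /
    ``k_structural`` -> true per-layer degrees; plus the spec echoes.
    """

    timeseries: list[RoiTimeSeriesSet]
    structural: list[ConnectivityMatrix]
    table: pd.DataFrame
    truth: dict


# ---------------------------------------------------------------------------
# oscillators


def _mixing_from_coupling(coupling: np.ndarray) -> np.ndarray:
    """Factor A with A A^T = nearest-PSD increment correlation matrix."""
    n = coupling.shape[0]
    corr = np.eye(n) + coupling - np.diag(np.diag(coupling))
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    a = v * np.sqrt(w)
    norms = np.sqrt((a**2).sum(axis=1))
    norms[norms == 0] = 1.0
    return a / norms[:, None]


def _offsets_from_lags(phase_lag: np.ndarray) -> np.ndarray:
    """Per-node phase potentials realising pairwise lags (least squares)."""
    n = phase_lag.shape[0]
    ii, jj = np.nonzero(np.triu(phase_lag, k=1))
    if ii.size == 0:
        return np.zeros(n)
    rows = np.zeros((ii.size + 1, n))
    rhs = np.zeros(ii.size + 1)
    for r, (i, j) in enumerate(zip(ii, jj)):
        rows[r, j] = 1.0
        rows[r, i] = -1.0
        rhs[r] = phase_lag[i, j]
    rows[-1, :] = 1.0  # anchor: potentials sum to zero
    delta, *_ = np.linalg.lstsq(rows, rhs, rcond=None)
    return delta


def gen_oscillators(spec: OscillatorSpec) -> RoiTimeSeriesSet:
    """Simulate one subject's ROI time series from an OscillatorSpec.

    Pure function of the spec (seed included): identical specs yield
    byte-identical output.  Phase integration and mixing run in single
    precision, which keeps whole-cohort simulation cheap; the phase
    statistics that matter live far above float32 resolution.
    """
    rng = np.random.default_rng(spec.seed)
    n, n_samples = spec.n_rois, spec.n_samples
    dt = 1.0 / spec.fs_hz

    mixing = _mixing_from_coupling(spec.coupling).astype(np.float32)
    increments = rng.standard_normal((n_samples, n), dtype=np.float32) @ mixing.T
    phases = np.cumsum(increments, axis=0, out=increments)
    phases *= np.float32(spec.phase_noise_sd * np.sqrt(dt))
    t = (np.arange(n_samples, dtype=np.float64) * dt)[:, None]
    phases += (2.0 * np.pi * spec.iaf_hz * t).astype(np.float32)
    phases += _offsets_from_lags(spec.phase_lag).astype(np.float32)[None, :]

    # the carrier overwrites the phase buffer; directed influence reads
    # other columns only (zero diagonal), so in-place updates are safe
    data = np.cos(phases, out=phases)
    lag = spec.influence_lag
    src, dst = np.nonzero(spec.directed_influence)
    if src.size:
        carrier = data.copy()
        for i, j in zip(src, dst):
            data[lag:, j] += (
                np.float32(spec.directed_influence[i, j]) * carrier[:-lag, i]
            )
    if spec.noise_sd > 0:
        noise = rng.standard_normal((n_samples, n), dtype=np.float32)
        noise *= np.float32(spec.noise_sd)
        data += noise

    return RoiTimeSeriesSet(
        data=data,
        labels=list(spec.labels),
        fs_hz=spec.fs_hz,
        iaf_true_hz=spec.iaf_hz,
        meta={"seed": spec.seed, "phase_noise_sd": spec.phase_noise_sd},
    )


def plv_ground_truth(
    coupling: float, phase_noise_sd: float, duration_s: float
) -> float:
    """Closed-form RMS phase-locking value implied by the phase model.

    The relative phase of a pair with increment correlation ``coupling``
    diffuses with coefficient ``D = 2*sigma_phi^2*(1-coupling)``; the
    expected squared modulus of the time-averaged phasor over a record of
    length T is ``(2/(aT)) * (1 - (1 - exp(-aT))/(aT))`` with a = D/2.
    """
    d = 2.0 * phase_noise_sd**2 * (1.0 - coupling)
    a = d / 2.0
    at = a * duration_s
    if at < 1e-12:
        return 1.0
    mean_sq = (2.0 / at) * (1.0 - (1.0 - np.exp(-at)) / at)
    return float(np.sqrt(mean_sq))


# ---------------------------------------------------------------------------
# module partitions and structural graphs


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


@lru_cache(maxsize=32)
def _partition_sizes(n: int, n_edges: int) -> tuple[int, ...]:
    """Module sizes whose within-module pair count hits the edge budget.

    Local search over size vectors (moving one node between modules at a
    time, trying nearby module counts) minimising
    ``|sum_m size*(size-1)/2 - n_edges|``; an exact hit pins the
    binarised functional layer to the module structure.  Deterministic.
    """
    rng = np.random.default_rng(12321)
    best: tuple[int, ...] | None = None
    best_err = np.inf
    k0 = max(2, int(round(n * n / (2 * n_edges + n))))
    for k in sorted({max(2, k0 - 1), k0, k0 + 1, k0 + 2}):
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        err = abs(int(np.sum(sizes * (sizes - 1) // 2)) - n_edges)
        for _ in range(4000):
            if err == 0:
                break
            a, b = rng.integers(0, k, size=2)
            if a == b or sizes[a] <= 2:
                continue
            sizes[a] -= 1
            sizes[b] += 1
            new_err = abs(int(np.sum(sizes * (sizes - 1) // 2)) - n_edges)
            if new_err <= err:
                err = new_err
            else:
                sizes[a] += 1
                sizes[b] -= 1
        if err < best_err:
            best_err = err
            best = tuple(int(s) for s in np.sort(sizes)[::-1])
        if best_err == 0:
            break
    return best


def _assign_modules(rng: np.random.Generator, n: int, sizes: tuple[int, ...]) -> np.ndarray:
    return rng.permutation(np.repeat(np.arange(len(sizes)), sizes))


def _within_module_edges(modules: np.ndarray) -> np.ndarray:
    n = modules.size
    iu, ju = _pair_index(n)
    same = modules[iu] == modules[ju]
    return np.column_stack([iu[same], ju[same]])


def _functional_truth(
    rng: np.random.Generator, n: int, n_edges: int, modules: np.ndarray
) -> np.ndarray:
    """True suprathreshold functional edge set (within-module pairs).

    When the partition misses the budget by a few pairs the set is
    trimmed or padded with random pairs so it always holds ``n_edges``.
    """
    within = _within_module_edges(modules)
    if len(within) == n_edges:
        return within
    if len(within) > n_edges:
        return within[rng.choice(len(within), size=n_edges, replace=False)]
    iu, ju = _pair_index(n)
    in_w = np.zeros((n, n), dtype=bool)
    in_w[within[:, 0], within[:, 1]] = True
    pool = np.flatnonzero(~in_w[iu, ju])
    pick = rng.choice(pool, size=n_edges - len(within), replace=False)
    return np.vstack([within, np.column_stack([iu[pick], ju[pick]])])


def _structural_degree_targets(
    rng: np.random.Generator,
    k_f: np.ndarray,
    alignment: np.ndarray,
    n_edges: int,
) -> np.ndarray:
    """Prescribed structural degrees: functional degrees + damped imbalance.

    The imbalance magnitude is drawn per node and damped by the node's
    alignment; its sign is symmetric, so marginal degree distributions do
    not depend on the alignment.  Randomised rounding keeps the mean
    response continuous in the alignment; the sequence is then nudged to
    sum to ``2 * n_edges``.
    """
    n = k_f.size
    # ratio-symmetric imbalance: k_s = k_f * r^(+/-1) with r shrinking to 1
    # as alignment -> 1.  Participation 4r/(1+r)^2 is then (up to rounding)
    # the same for both signs, so the alignment controls the mean tightly.
    # The up-branch probability 1/(r+1) makes E[k_s | k_f] = k_f exactly,
    # keeping marginal degree distributions centred independently of the
    # alignment; the handshake-sum residual is absorbed smoothly by the
    # exact-edge-count graph realisation.
    ratio = _IMBALANCE_RATIO ** (1.0 - np.clip(alignment, 0.0, 1.0))
    q_up = 1.0 / (ratio + 1.0)
    # balanced branch assignment: within each alignment stratum exactly
    # ~q*n nodes go up (random identity).  Each node's marginal branch
    # probability stays q, but the subject-level sum of prescriptions is
    # nearly deterministic, so the normalisation below no longer couples
    # nodes (a noisy per-subject scale would shift every node of a
    # subject together and leak group variance differences into
    # non-target nodes).
    up = np.zeros(n, dtype=bool)
    for q_val in np.unique(q_up):
        stratum = np.flatnonzero(q_up == q_val)
        expected = q_val * stratum.size
        n_up = int(np.floor(expected))
        n_up += rng.random() < (expected - n_up)
        if n_up > 0:
            up[rng.choice(stratum, size=n_up, replace=False)] = True
    raw = np.maximum(k_f, 1.0) * np.where(up, ratio, 1.0 / ratio)
    # the expected handshake sum already matches the edge budget
    # (E[r^s] = 1 per node and the strata are count-balanced); the small
    # residual is absorbed by the exact-edge-count realisation, which
    # preferentially shorts the most extreme prescription
    k_des = np.floor(raw).astype(np.int64)
    k_des += rng.random(n) < (raw - k_des)
    return np.clip(k_des, 1, n - 1)


def _realize_structural_edges(
    rng: np.random.Generator,
    n: int,
    n_edges: int,
    k_des: np.ndarray,
    f_edges: np.ndarray,
    overlap: float,
) -> np.ndarray:
    """Edge set with ~prescribed degrees, preferring functional pairs.

    Functional edges compatible with both endpoints' remaining degree
    budget are adopted with probability ``overlap``; leftover degree is
    filled by random stub pairing.  The result always holds exactly
    ``n_edges`` edges (a few final edges may bend the degree
    prescription when the pairing deadlocks).
    """
    adj = np.zeros((n, n), dtype=bool)
    remaining = k_des.astype(np.int64).copy()
    edges = []

    order = rng.permutation(len(f_edges))
    coins = rng.random(len(f_edges))
    for idx, coin in zip(order, coins):
        i, j = f_edges[idx]
        if remaining[i] > 0 and remaining[j] > 0 and coin < overlap:
            adj[i, j] = adj[j, i] = True
            remaining[i] -= 1
            remaining[j] -= 1
            edges.append((i, j))

    guard = 0
    while len(edges) < n_edges and guard < 50 * n_edges:
        guard += 1
        open_nodes = np.flatnonzero(remaining > 0)
        if open_nodes.size >= 2:
            i = open_nodes[int(np.argmax(remaining[open_nodes]))]
            partners = open_nodes[(open_nodes != i) & ~adj[i, open_nodes]]
            if partners.size:
                j = int(partners[rng.integers(0, partners.size)])
                adj[i, j] = adj[j, i] = True
                remaining[i] -= 1
                remaining[j] -= 1
                edges.append((min(i, j), max(i, j)))
                continue
        # deadlock: place the remaining budget anywhere
        iu, ju = _pair_index(n)
        free = np.flatnonzero(~adj[iu, ju])
        pick = rng.choice(free, size=n_edges - len(edges), replace=False)
        for p in pick:
            adj[iu[p], ju[p]] = adj[ju[p], iu[p]] = True
            edges.append((int(iu[p]), int(ju[p])))
        break
    return np.asarray(edges[:n_edges], dtype=np.int64)


def _fa_weights(
    rng: np.random.Generator,
    n: int,
    edges: np.ndarray,
    *,
    strong_range: tuple[float, float] = (0.45, 0.75),
    weak_range: tuple[float, float] = (0.05, 0.40),
    weak_fraction_range: tuple[float, float] = (0.0, 0.08),
) -> np.ndarray:
    """FA-like weighted matrix whose top edges are exactly ``edges``.

    Strong (tract-bearing) pairs draw weights from ``strong_range``; a
    random sprinkling of weak background pairs draws from ``weak_range``
    (disjoint below the strong range, so density-matched binarisation
    recovers the edge set exactly); everything else is 0, mimicking
    pairs with no reconstructed tract.
    """
    if strong_range[0] <= weak_range[1]:
        raise ValueError("strong and weak weight ranges must be disjoint")
    if min(strong_range + weak_range) < 0:
        raise ValueError("FA weights must be nonnegative")
    w = np.zeros((n, n))
    w[edges[:, 0], edges[:, 1]] = rng.uniform(*strong_range, size=len(edges))
    iu, ju = _pair_index(n)
    empty = np.flatnonzero((w[iu, ju] == 0) & (w[ju, iu] == 0))
    lo = int(weak_fraction_range[0] * empty.size)
    hi = max(lo, int(weak_fraction_range[1] * empty.size))
    n_weak = rng.integers(lo, hi + 1)
    if n_weak > 0:
        pick = rng.choice(empty, size=n_weak, replace=False)
        w[iu[pick], ju[pick]] = rng.uniform(*weak_range, size=n_weak)
    return w + w.T


def _participation_from_degrees(kf: np.ndarray, ks: np.ndarray) -> np.ndarray:
    o = kf + ks
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2.0 * (1.0 - (kf**2 + ks**2) / np.where(o > 0, o, 1) ** 2)
    return np.where(o > 0, p, 0.0)


def gen_structural(
    spec: OscillatorSpec,
    cohort: CohortSpec,
    functional_reference: ConnectivityMatrix,
) -> ConnectivityMatrix:
    """FA-like structural matrix with tunable overlap to a functional layer.

    Each suprathreshold functional edge is kept as a structural edge
    with probability ``cohort.structural_overlap`` and the remaining
    budget is filled with random non-functional pairs, so the fraction
    of shared top-density edges approaches the requested overlap
    (exactly 1 and 0 at the extremes).
    """
    if functional_reference.directed:
        raise ValueError("functional reference must be undirected")
    n = functional_reference.n_nodes
    if n != spec.n_rois:
        raise ValueError("node count mismatch between spec and functional reference")
    from .multiplex import binarize_to_density

    rng = np.random.default_rng(spec.seed)
    e = _edge_count(n, cohort.density, directed=False)
    adj = binarize_to_density(functional_reference, cohort.density)
    iu, ju = _pair_index(n)
    on = np.flatnonzero(adj[iu, ju])
    f_edges = np.column_stack([iu[on], ju[on]])

    kept = f_edges[rng.random(len(f_edges)) < cohort.structural_overlap]
    n_fill = e - len(kept)
    if n_fill > 0:
        in_f = np.zeros((n, n), dtype=bool)
        in_f[f_edges[:, 0], f_edges[:, 1]] = True
        pool = np.flatnonzero(~in_f[iu, ju])
        if n_fill > pool.size:
            raise ValueError("graph too dense to avoid the functional edge set")
        pick = rng.choice(pool, size=n_fill, replace=False)
        edges = np.vstack([kept, np.column_stack([iu[pick], ju[pick]])])
    else:
        edges = kept[:e]
    w = _fa_weights(rng, n, edges)
    return ConnectivityMatrix(
        values=w, modality="FA", band="broadband", labels=list(spec.labels)
    )


# ---------------------------------------------------------------------------
# alignment calibration


def _virtual_subject_p(
    rng: np.random.Generator,
    n: int,
    n_edges: int,
    sizes: tuple[int, ...],
    alignment: np.ndarray,
    overlap: float,
    probe: int,
) -> float:
    """True participation at one node for a signal-free virtual subject."""
    modules = _assign_modules(rng, n, sizes)
    f_edges = _functional_truth(rng, n, n_edges, modules)
    kf = np.bincount(f_edges.ravel(), minlength=n).astype(float)
    k_des = _structural_degree_targets(rng, kf, alignment, n_edges)
    s_edges = _realize_structural_edges(rng, n, n_edges, k_des, f_edges, overlap)
    ks = np.bincount(s_edges.ravel(), minlength=n).astype(float)
    return float(_participation_from_degrees(kf, ks)[probe])


@lru_cache(maxsize=64)
def _alignment_response(
    n: int,
    n_edges: int,
    base_alignment: float,
    overlap: float,
    n_virtual: int = 400,
) -> tuple[tuple[float, ...], tuple[float, ...], float, float]:
    """Monte-Carlo map: target-node alignment -> mean true participation.

    Returns (alignment grid, monotone mean participation per grid point,
    baseline mean, baseline SD).  Runs on a fixed internal seed so the
    calibration is a pure function of the configuration.
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    sizes = _partition_sizes(n, n_edges)
    grid = np.linspace(0.0, 1.0, 9)
    means = []
    base_mean = base_sd = 0.0
    for a in grid:
        alignment = np.full(n, base_alignment)
        alignment[0] = a
        vals = [
            _virtual_subject_p(rng, n, n_edges, sizes, alignment, overlap, probe=0)
            for _ in range(n_virtual)
        ]
        means.append(float(np.mean(vals)))
    means = np.maximum.accumulate(means)  # response is monotone; smooth MC noise
    base_vals = [
        _virtual_subject_p(
            rng, n, n_edges, sizes, np.full(n, base_alignment), overlap, probe=0
        )
        for _ in range(n_virtual)
    ]
    base_mean = float(np.mean(base_vals))
    base_sd = float(np.std(base_vals, ddof=1))
    return tuple(grid), tuple(float(m) for m in means), base_mean, base_sd


def _calibrated_alignment(
    n: int, n_edges: int, base_alignment: float, overlap: float, d: float
) -> tuple[float, float, float]:
    """Target-node alignment achieving a standardised effect of ~ d.

    Returns (alignment, baseline mean participation, baseline SD).  The
    requested shift is clipped to the achievable response range.
    """
    grid, means, base_mean, base_sd = _alignment_response(
        n, n_edges, round(base_alignment, 6), round(overlap, 6)
    )
    if d == 0.0:
        return base_alignment, base_mean, base_sd
    wanted = base_mean + d * base_sd
    means = np.asarray(means)
    grid = np.asarray(grid)
    wanted = float(np.clip(wanted, means[0], means[-1]))
    alignment = float(np.interp(wanted, means, grid))
    return alignment, base_mean, base_sd


#: Table-style score baselines: (young mean, young sd, old mean, old sd).
_SCORE_BASELINES = {
    "MMSE": (29.5, 0.86, 28.9, 1.17),
    "VSTM": (0.5, 0.088, 0.4, 0.069),
    "Cattell": (37.8, 3.63, 30.5, 6.29),
    "Hotel_Num_rows": (4.7, 0.59, 4.3, 1.01),
    "Hotel_Time": (227.7, 119.8, 326.9, 194.3),
}


def gen_cohort(ospec: OscillatorSpec, cspec: CohortSpec) -> SyntheticCohort:
    """Generate a full synthetic cohort with planted ground truth.

    Returns a :class:`SyntheticCohort` holding per-subject ROI time
    series, FA-like structural matrices, the cohort table (demographics,
    covariates, cognition scores) and the ground-truth record.  The
    old-group true participation at target nodes differs from the young
    group by approximately ``effect_size_d`` baseline standard
    deviations (clipped to the generator's achievable response range),
    and the planted cognition score of old subjects depends linearly on
    the first target node's true participation with slope
    ``cognition_slope``.
    """
    n = ospec.n_rois
    for tnode in cspec.target_nodes:
        if not 0 <= tnode < n:
            raise IndexError(f"target node {tnode} out of range for {n} ROIs")
    e = _edge_count(n, cspec.density, directed=False)
    master = np.random.default_rng(cspec.seed)
    sizes = _partition_sizes(n, e)

    align_young = cspec.degree_alignment
    align_old = (
        cspec.degree_alignment_old
        if cspec.degree_alignment_old is not None
        else cspec.degree_alignment
    )
    align_target, p_ref, p_sd = _calibrated_alignment(
        n, e, align_old, cspec.structural_overlap, cspec.effect_size_d
    )

    groups = ["young"] * cspec.n_young + ["old"] * cspec.n_old
    timeseries: list[RoiTimeSeriesSet] = []
    structural: list[ConnectivityMatrix] = []
    rows = []
    p_true = np.zeros((len(groups), n))
    kf_true = np.zeros((len(groups), n))
    ks_true = np.zeros((len(groups), n))

    for s_idx, group in enumerate(groups):
        rng = np.random.default_rng(master.integers(2**31))
        old = group == "old"
        iaf = float(np.clip(rng.normal(9.4 if old else 10.2, 0.8), 8.6, 12.4))

        modules = _assign_modules(rng, n, sizes)
        f_edges = _functional_truth(rng, n, e, modules)
        kf = np.bincount(f_edges.ravel(), minlength=n).astype(float)

        coupling = np.zeros((n, n))
        coupling[f_edges[:, 0], f_edges[:, 1]] = cspec.module_rho
        coupling += coupling.T
        np.clip(coupling, 0.0, 1.0, out=coupling)
        offsets = rng.uniform(-cspec.node_phase_spread, cspec.node_phase_spread, n)
        lag_matrix = np.triu(offsets[None, :] - offsets[:, None], k=1)

        sspec = OscillatorSpec(
            n_rois=n,
            iaf_hz=iaf,
            fs_hz=ospec.fs_hz,
            duration_s=ospec.duration_s,
            coupling=coupling,
            phase_lag=lag_matrix,
            directed_influence=ospec.directed_influence,
            influence_lag=ospec.influence_lag,
            noise_sd=ospec.noise_sd,
            phase_noise_sd=ospec.phase_noise_sd,
            seed=int(rng.integers(2**31)),
            labels=ospec.labels,
        )
        ts = gen_oscillators(sspec)
        ts.subject_id = f"sub-{s_idx:03d}"
        ts.meta.update(group=group, modules=modules.tolist())
        timeseries.append(ts)

        alignment = np.full(n, align_old if old else align_young)
        if old and cspec.effect_size_d != 0.0:
            alignment[list(cspec.target_nodes)] = align_target
        k_des = _structural_degree_targets(rng, kf, alignment, e)
        s_edges = _realize_structural_edges(
            rng, n, e, k_des, f_edges, cspec.structural_overlap
        )
        # the old group carries fewer weak background tracts, so the
        # group-minimum structural density (the study's thresholding
        # convention) is realised in the old group
        weak_frac = (0.0, 0.04) if old else (0.04, 0.10)
        w = _fa_weights(rng, n, s_edges, weak_fraction_range=weak_frac)
        structural.append(
            ConnectivityMatrix(
                values=w, modality="FA", band="broadband", labels=list(ospec.labels)
            )
        )

        ks = np.bincount(s_edges.ravel(), minlength=n).astype(float)
        p_true[s_idx] = _participation_from_degrees(kf, ks)
        kf_true[s_idx], ks_true[s_idx] = kf, ks

        row = {
            "subject_id": ts.subject_id,
            "group": group,
            "age": float(
                np.clip(rng.normal(64.5, 2.5), 60, 69)
                if old
                else np.clip(rng.normal(26.5, 2.0), 22, 29)
            ),
            "sex": "F" if rng.random() < 29 / 46 else "M",
            "education": float(rng.normal(19.1 if old else 22.2, 3.0)),
            "grey_matter_volume": float(rng.normal(5.6e5 if old else 6.1e5, 4.5e4)),
            "total_intracranial_volume": float(rng.normal(1.5e6, 1.2e5)),
            "iaf_true_hz": iaf,
        }
        for score, (ym, ysd, om, osd) in _SCORE_BASELINES.items():
            if score == cspec.score:
                base = om if old else ym
                noise = rng.normal(0.0, cspec.score_noise_sd)
                planted = (
                    cspec.cognition_slope
                    * (p_true[s_idx, cspec.target_nodes[0]] - p_ref)
                    if old
                    else 0.0
                )
                row[score] = base + planted + noise
            else:
                row[score] = float(rng.normal(om if old else ym, osd if old else ysd))
        rows.append(row)

    table = pd.DataFrame(rows)
    truth = {
        "participation": p_true,
        "k_functional": kf_true,
        "k_structural": ks_true,
        "alignment_shifted": align_target,
        "participation_baseline_mean": p_ref,
        "participation_baseline_sd": p_sd,
        "effect_size_d": cspec.effect_size_d,
        "cognition_slope": cspec.cognition_slope,
        "density": cspec.density,
        "target_nodes": cspec.target_nodes,
        "module_sizes": sizes,
        "score": cspec.score,
        "seed": cspec.seed,
    }
    return SyntheticCohort(
        timeseries=timeseries, structural=structural, table=table, truth=truth
    )
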