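"""Pairwise functional connectivity: PLV, wPLI and transfer entropy.

PLV (phase-locking value) is the modulus of the time-averaged unit phasor
of the phase difference between two analytic signals: 1 for a constant
phase difference, ~1/sqrt(N) for independent phases.  wPLI (weighted
phase-lag index) weights phase-lag consistency by the imaginary
cross-spectrum and is therefore blind to zero-lag (volume-conduction
like) coupling.  Transfer entropy quantifies how much the past of a
source series improves prediction of a target's next sample beyond the
target's own past; here it is estimated with plug-in entropies on
uniformly amplitude-binned signals (default 4 bins, history 1, lag 1),
reported in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import ConnectivityMatrix
from .errors import UnderdeterminedEstimateError
from .spectral import AnalyticRoiSignals


@dataclass
class DirectedNodeProfile:
    """Nodal aggregates of a directed coupling matrix.

    ``inward[i]`` sums couplings directed toward node *i* (receiver
    role), ``outward[i]`` sums couplings from node *i* to the rest of the
    network (sender role).
    """

    inward: np.ndarray
    outward: np.ndarray
    labels: list[str]


def _unit_phasors(z: np.ndarray, max_zero_frac: float) -> np.ndarray:
    """Normalise an analytic signal to unit phasors, dropping dead samples."""
    amp = np.abs(z)
    dead = amp == 0.0
    n_dead = int(dead.sum())
    if n_dead > max_zero_frac * z.size:
        raise ValueError(
            f"{n_dead}/{z.size} zero-amplitude samples: phase undefined on "
            f"more than the tolerated fraction ({max_zero_frac:.0%})"
        )
    out = np.empty_like(z)
    np.divide(z, amp, out=out, where=~dead)
    out[dead] = 0.0  # dead samples contribute nothing to the average
    return out, z.size - n_dead


def plv(x: np.ndarray, y: np.ndarray, *, max_zero_frac: float = 0.01) -> float:
    """Phase-locking value of two analytic signals, in [0, 1].

    Invariant to amplitude rescaling of either input and to adding a
    constant phase to either input.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    px, nx = _unit_phasors(x, max_zero_frac)
    py, ny = _unit_phasors(y, max_zero_frac)
    n_eff = min(nx, ny)
    if n_eff < 2:
        raise ValueError("too few live samples for PLV")
    return float(min(1.0, np.abs(np.sum(px * np.conj(py))) / n_eff))


def wpli(x: np.ndarray, y: np.ndarray) -> float:
    """Weighted phase-lag index of two analytic signals, in [0, 1].

    Computed as ``|mean(imag S_xy)| / mean(|imag S_xy|)`` with ``S_xy``
    the per-sample cross-spectrum.  Exactly 0 (with a warning) when every
    cross-spectral imaginary part vanishes, i.e. when all coupling is at
    zero lag -- the insensitivity to volume conduction that motivates the
    wPLI control analysis.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    cross = x * np.conj(y)
    imag_cross = np.imag(cross)
    denom = np.mean(np.abs(imag_cross))
    scale = np.mean(np.abs(cross))
    # imaginary parts at rounding level = zero-lag coupling only
    if scale == 0.0 or denom <= 1e-9 * scale:
        warnings.warn(
            "all cross-spectral imaginary parts are zero (zero-lag only); wPLI = 0",
            stacklevel=2,
        )
        return 0.0
    return float(min(1.0, np.abs(np.mean(imag_cross)) / denom))


def _bin_uniform(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Uniform amplitude binning onto 0..n_bins-1; a constant maps to bin 0."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.shape, dtype=np.int64)
    idx = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def _plugin_entropy(codes: np.ndarray) -> float:
    """Plug-in (maximum-likelihood) entropy in bits of integer symbols."""
    counts = np.bincount(codes)
    counts = counts[counts > 0]
    p = counts / codes.size
    return float(-np.sum(p * np.log2(p)))


def transfer_entropy(
    source: np.ndarray,
    target: np.ndarray,
    history: int = 1,
    lag: int = 1,
    n_bins: int = 4,
    *,
    min_samples_per_state: float = 5.0,
) -> float:
    """Transfer entropy from ``source`` to ``target`` in bits.

    TE = H(future | target past) - H(future | target past, source past),
    with plug-in entropies on uniformly binned amplitudes.  The target
    past is its ``history`` most recent samples; the source enters with a
    single sample at ``lag``.  Nonnegative up to estimator bias and
    deterministic given inputs and parameters.

    Raises
    ------
    UnderdeterminedEstimateError
        When the series is too short to populate the joint state space
        (fewer than ``min_samples_per_state`` samples per possible state).
    """
    if history < 1 or lag < 1:
        raise ValueError("history and lag must be >= 1")
    s = np.asarray(source, dtype=float).ravel()
    t = np.asarray(target, dtype=float).ravel()
    if np.iscomplexobj(source) or np.iscomplexobj(target):
        raise ValueError("transfer entropy expects real-valued series")
    if s.shape != t.shape:
        raise ValueError("inputs must have equal length")
    n = s.size
    n_states = n_bins ** (history + 2)
    n_obs = n - max(history, lag)
    if n_obs < min_samples_per_state * n_states:
        raise UnderdeterminedEstimateError(
            f"underdetermined estimate: {n_obs} usable samples for "
            f"{n_states} joint states (need >= {min_samples_per_state}/state)"
        )

    sb = _bin_uniform(s, n_bins)
    tb = _bin_uniform(t, n_bins)
    start = max(history, lag)

    future = tb[start:]
    past_cols = [tb[start - 1 - h : n - 1 - h] for h in range(history)]
    src = sb[start - lag : n - lag]

    tp = np.zeros_like(future)
    for col in past_cols:
        tp = tp * n_bins + col

    base_tp = n_bins**history
    code_ftp = future * base_tp + tp
    code_tps = tp * n_bins + src
    code_ftps = code_ftp * n_bins + src

    te = (
        _plugin_entropy(code_ftp)
        + _plugin_entropy(code_tps)
        - _plugin_entropy(tp)
        - _plugin_entropy(code_ftps)
    )
    return float(te)


def connectivity_matrix(
    signals: AnalyticRoiSignals,
    modality: str,
    *,
    te_history: int = 1,
    te_lag: int = 1,
    te_bins: int = 4,
    max_zero_frac: float = 0.01,
) -> ConnectivityMatrix:
    """Assemble the full pairwise connectivity matrix for one band.

    PLV/wPLI produce symmetric matrices (upper triangle computed once);
    TE fills all ordered pairs and is generally asymmetric.  TE operates
    on the real part of the analytic signal, i.e. the band-pass filtered
    series itself rather than phase alone.
    """
    z = signals.signals
    n = z.shape[0]
    if n < 2:
        raise ValueError("need at least 2 ROIs")
    band_name = f"{signals.band[0]:g}-{signals.band[1]:g}Hz"
    w = np.zeros((n, n))

    if modality == "PLV":
        phasors = np.stack(
            [_unit_phasors(z[i], max_zero_frac)[0] for i in range(n)]
        )
        gram = phasors @ phasors.conj().T
        w = np.abs(gram) / z.shape[1]
        np.clip(w, 0.0, 1.0, out=w)
    elif modality == "wPLI":
        for i in range(n):
            for j in range(i + 1, n):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    w[i, j] = w[j, i] = wpli(z[i], z[j])
    elif modality == "TE":
        x = z.real
        for i in range(n):
            for j in range(n):
                if i != j:
                    w[i, j] = max(
                        0.0,
                        transfer_entropy(
                            x[i], x[j], history=te_history, lag=te_lag, n_bins=te_bins
                        ),
                    )
    else:
        raise ValueError(f"unsupported functional modality {modality!r}")

    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        values=w,
        modality=modality,
        band=band_name,
        directed=(modality == "TE"),
        labels=list(signals.labels),
    )


def directed_profiles(te: ConnectivityMatrix) -> DirectedNodeProfile:
    """Inward/outward nodal simplification of a directed TE matrix.

    ``inward[i]`` aggregates entries ``te(j -> i)`` (column sums) and
    ``outward[i]`` entries ``te(i -> j)`` (row sums), diagonal excluded.
    On a symmetric matrix the two profiles coincide.
    """
    if not te.directed:
        raise ValueError("directed_profiles requires a directed matrix")
    w = te.values.copy()
    np.fill_diagonal(w, 0.0)
    return DirectedNodeProfile(
        inward=w.sum(axis=0), outward=w.sum(axis=1), labels=list(te.labels)
    )
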