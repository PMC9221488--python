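"""Corticomuscular functional network construction and graph metrics.

From a Kendall-tau (or Granger) weight matrix: per-block min-max
normalization of |weights| (EEG-EEG, EMG-EMG and EEG-EMG cells are scaled
separately, since same-modality dependence is systematically stronger than
cross-modality dependence), binarization at a threshold selected by the
average-node-degree rule K >= 2 ln N scanned over thresholds 0..1 in steps
of 0.05, and the standard binary-graph metrics: characteristic path length
L (mean shortest-path length over connected ordered pairs), clustering
coefficient C_i = 2 E_i / (K_i (K_i - 1)), and core nodes (maximum degree).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .copulas import empirical_kendall_tau

__all__ = [
    "ConnectivityGraph",
    "tau_matrix",
    "normalize_blocks",
    "threshold_select",
    "select_threshold_from_curve",
    "degree_curve",
    "binarize",
    "graph_metrics",
    "core_nodes",
]


def tau_matrix(U, diagonal: float = 0.0) -> np.ndarray:
    """Pairwise empirical Kendall tau of the columns of ``U``.

    ``diagonal=1.0`` gives the heatmap convention; the default 0 is the
    adjacency convention used downstream.
    """
    U = np.asarray(U, dtype=float)
    n, p = U.shape
    if p < 2:
        raise ValueError("need at least two columns")
    for j in range(p):
        if np.ptp(U[:, j]) == 0:
            raise ValueError(f"column {j} is constant; Kendall tau undefined")
    M = np.full((p, p), float(diagonal))
    for i in range(p):
        for j in range(i + 1, p):
            M[i, j] = M[j, i] = empirical_kendall_tau(U[:, i], U[:, j])
    return M


def _block_masks(modalities):
    mod = np.asarray(modalities)
    eeg = mod == "EEG"
    emg = mod == "EMG"
    if not (eeg | emg).all():
        raise ValueError("modalities must be 'EEG' or 'EMG'")
    p = mod.size
    off = ~np.eye(p, dtype=bool)
    m_ee = np.outer(eeg, eeg) & off
    m_mm = np.outer(emg, emg) & off
    m_cross = np.outer(eeg, emg) | np.outer(emg, eeg)
    return [m_ee, m_mm, m_cross]


def normalize_blocks(W, modalities) -> np.ndarray:
    """Min-max scale |W| to [0,1] separately within the EEG-EEG, EMG-EMG and
    EEG-EMG blocks (off-diagonal entries only); diagonal forced to 0.

    A degenerate block (max == min) is set to zero with a warning.
    """
    W = np.abs(np.asarray(W, dtype=float))
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-12):
        raise ValueError("W must be symmetric")
    Wn = np.zeros_like(W)
    for mask in _block_masks(modalities):
        if not mask.any():
            continue
        vals = W[mask]
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            warnings.warn("degenerate block (max == min); setting block to 0")
            continue
        Wn[mask] = (W[mask] - lo) / (hi - lo)
    np.fill_diagonal(Wn, 0.0)
    return Wn


def binarize(Wn, threshold: float) -> np.ndarray:
    """A_ij = 1 iff Wn_ij >= threshold (i != j)."""
    Wn = np.asarray(Wn, dtype=float)
    A = (Wn >= threshold).astype(int)
    np.fill_diagonal(A, 0)
    return A


def degree_curve(Wn_list, step: float = 0.05):
    """Mean node degree, averaged across the given networks, as a function
    of the binarization threshold.  Returns (thresholds, mean K, sd K)."""
    Wn_list = [np.asarray(W, dtype=float) for W in Wn_list]
    if not Wn_list:
        raise ValueError("need at least one matrix")
    N = Wn_list[0].shape[0]
    for W in Wn_list:
        if W.shape != (N, N):
            raise ValueError("all matrices must share the node count")
    ts = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    ks = np.empty((len(Wn_list), ts.size))
    for m, W in enumerate(Wn_list):
        for i, t in enumerate(ts):
            ks[m, i] = binarize(W, t).sum(axis=1).mean()
    return ts, ks.mean(axis=0), ks.std(axis=0)


def select_threshold_from_curve(curve: dict, n_nodes: int) -> float:
    """Largest threshold whose average node degree satisfies K >= 2 ln N.

    ``curve`` maps threshold -> average node degree.  Returns 0.0 with a
    warning when no threshold qualifies.
    """
    kmin = 2.0 * math.log(n_nodes)
    ok = [t for t, k in curve.items() if k >= kmin]
    if not ok:
        warnings.warn("no threshold satisfies K >= 2 ln N; returning 0.0")
        return 0.0
    return float(max(ok))


def threshold_select(Wn_list, step: float = 0.05):
    """Scan thresholds 0..1, average the node degree over the networks, and
    return (threshold, curve dict, sd dict) with the K >= 2 ln N rule."""
    ts, kmean, ksd = degree_curve(Wn_list, step=step)
    curve = {float(t): float(k) for t, k in zip(ts, kmean)}
    sd = {float(t): float(s) for t, s in zip(ts, ksd)}
    N = np.asarray(Wn_list[0]).shape[0]
    thr = select_threshold_from_curve(curve, N)
    return thr, curve, sd


def graph_metrics(A) -> dict:
    """Binary-graph metrics.

    L averages shortest-path lengths over *connected* ordered pairs;
    disconnected pairs are excluded from numerator and denominator and
    reported in ``n_disconnected_pairs``.  C_i = 2 E_i / (K_i (K_i-1)),
    zero for nodes of degree < 2; C is the mean of C_i.
    """
    A = np.asarray(A)
    N = A.shape[0]
    if A.shape != (N, N) or not np.array_equal(A, A.T) or np.any(np.diag(A)):
        raise ValueError("A must be a symmetric binary matrix with zero diagonal")
    if not np.isin(A, (0, 1)).all():
        raise ValueError("A must be binary")
    G = nx.from_numpy_array(A)
    deg = A.sum(axis=1)

    total, npairs = 0.0, 0
    for src, lengths in nx.all_pairs_shortest_path_length(G):
        for dst, d in lengths.items():
            if dst != src:
                total += d
                npairs += 1
    n_disc = N * (N - 1) - npairs
    L = total / npairs if npairs else float("nan")

    Ci = np.zeros(N)
    for i in range(N):
        k = deg[i]
        if k >= 2:
            nbrs = np.flatnonzero(A[i])
            Ei = A[np.ix_(nbrs, nbrs)].sum() / 2
            Ci[i] = 2.0 * Ei / (k * (k - 1))
    return {
        "L": float(L),
        "C": float(Ci.mean()) if N else 0.0,
        "C_i": Ci,
        "K_i": deg,
        "n_disconnected_pairs": int(n_disc),
    }


def core_nodes(A) -> list:
    """All nodes attaining the maximum degree (ties returned together)."""
    A = np.asarray(A)
    deg = A.sum(axis=1)
    return sorted(np.flatnonzero(deg == deg.max()).tolist())


@dataclass
class ConnectivityGraph:
    """A corticomuscular network: raw weights, block-normalized weights,
    binary adjacency at ``threshold``, and the graph metrics."""

    node_labels: list
    modalities: list
    W: np.ndarray
    Wn: np.ndarray
    A: np.ndarray
    threshold: float
    metrics: dict = field(default_factory=dict)

    @classmethod
    def build(cls, W, modalities, threshold, node_labels=None) -> "ConnectivityGraph":
        W = np.asarray(W, dtype=float)
        p = W.shape[0]
        node_labels = list(node_labels) if node_labels else [str(i) for i in range(p)]
        Wn = normalize_blocks(W, modalities)
        A = binarize(Wn, threshold)
        return cls(
            node_labels=node_labels,
            modalities=list(modalities),
            W=W,
            Wn=Wn,
            A=A,
            threshold=float(threshold),
            metrics=graph_metrics(A),
        )

    @property
    def core_nodes(self) -> list:
        return [self.node_labels[i] for i in core_nodes(self.A)]

    def edge_list(self):
        p = len(self.node_labels)
        return [
            (self.node_labels[i], self.node_labels[j], float(self.Wn[i, j]))
            for i in range(p)
            for j in range(i + 1, p)
            if self.A[i, j]
        ]

    def to_dot(self) -> str:
        lines = ["graph cmcnet {"]
        for a, b, w in self.edge_list():
            lines.append(f'  "{a}" -- "{b}" [weight={w:.3f}];')
        lines.append("}")
        return "\n".join(lines)
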