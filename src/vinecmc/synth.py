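"""Ground-truth scenario generator.

Because no matched EEG/sEMG recordings are distributable, every pipeline
stage is validated on synthetic multichannel data whose dependence structure
and marginal dynamics are known exactly.  A Scenario couples

* a tree-1 R-vine truth: EEG channels on a chain, EMG channels on a chain,
  one EEG-EMG bridge edge, Gaussian pair copulas at the requested Kendall
  taus (within-modality tau > cross-modality tau, mirroring the empirical
  pattern that same-type channels co-vary far more strongly), independence
  in all higher trees; and
* per-channel AR(1)+GJR-GARCH(1,1)-t marginal dynamics.

Dependence is injected at the innovation level: vine-sampled uniforms are
mapped through the unit-variance t quantile and driven through the GARCH
recursion.  This is exactly the model class the inference path assumes, so
parameter and structure recovery are well-posed end-to-end tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .copulas import PairCopula, params_from_tau
from .garch import simulate_garch
from .network import ConnectivityGraph, normalize_blocks, threshold_select
from .preproc import ChannelMatrix
from .rvine import VineEdge, VineModel, max_spanning_tree

__all__ = ["Scenario", "make_scenario", "simulate", "true_network", "DEFAULT_GARCH"]

# Marginal dynamics used for every synthetic channel: mild AR(1) memory,
# strongly persistent but stationary volatility (persistence 0.925) with a
# small leverage term, moderately heavy tails.
DEFAULT_GARCH = (0.0, 0.2, 0.05, 0.05, 0.85, 0.05, 8.0)


@dataclass
class Scenario:
    n_eeg: int
    n_emg: int
    tau_within: float
    tau_cross: float
    vine_truth: VineModel
    garch_truth: list
    fs: float = 1000.0
    n_samples: int = 3000
    seed: int = 0
    bridge: tuple = (0, 0)

    @property
    def n_channels(self) -> int:
        return self.n_eeg + self.n_emg

    @property
    def channel_ids(self) -> list:
        return [f"EEG{i + 1}" for i in range(self.n_eeg)] + [
            f"EMG{i + 1}" for i in range(self.n_emg)
        ]

    @property
    def modalities(self) -> list:
        return ["EEG"] * self.n_eeg + ["EMG"] * self.n_emg

    def true_tau_matrix(self) -> np.ndarray:
        """Analytic Kendall tau between every channel pair.

        Tree-1-only Gaussian dependence makes the joint copula a Gaussian
        Markov tree: the correlation of any pair is the product of edge
        correlations along the tree path, and tau = (2/pi) arcsin(rho).
        """
        p = self.n_channels
        rho_edge = {}
        adj = {i: [] for i in range(p)}
        for e in self.vine_truth.trees[0]:
            a, b = e.cond
            rho = e.copula.params[0] if e.copula.params else 0.0
            rho_edge[(a, b)] = rho_edge[(b, a)] = rho
            adj[a].append(b)
            adj[b].append(a)
        tau = np.zeros((p, p))
        for src in range(p):
            # BFS accumulating path products
            rho_acc = {src: 1.0}
            stack = [src]
            while stack:
                k = stack.pop()
                for nb in adj[k]:
                    if nb not in rho_acc:
                        rho_acc[nb] = rho_acc[k] * rho_edge[(k, nb)]
                        stack.append(nb)
            for dst, r in rho_acc.items():
                if dst != src:
                    tau[src, dst] = 2.0 / math.pi * math.asin(r)
        return tau

    def true_tree1_edges(self) -> list:
        return sorted(e.cond for e in self.vine_truth.trees[0])


def _fill_independence_trees(tree1, p):
    """Extend a spanning tree to a full R-vine with independence copulas in
    trees 2..p-1, choosing each tree by the deterministic MST tie-break."""
    trees = [tree1]
    for level in range(2, p):
        prev = trees[-1]
        m = len(prev)
        info = {}
        for ia in range(m):
            for ib in range(ia + 1, m):
                e1, e2 = prev[ia], prev[ib]
                shared = e1.complete & e2.complete
                if len(shared) != len(e1.complete) - 1:
                    continue
                a, b = sorted(e1.complete ^ e2.complete)
                info[(ia, ib)] = ((a, b), frozenset(shared))
        W = np.zeros((m, m))
        mst = max_spanning_tree(W, allowed=list(info))
        tree = [
            VineEdge(
                cond=info[tuple(sorted(e))][0],
                given=info[tuple(sorted(e))][1],
                copula=PairCopula("independence"),
                level=level,
            )
            for e in sorted(tuple(sorted(e)) for e in mst)
        ]
        trees.append(tree)
    return trees


def make_scenario(
    n_eeg: int = 8,
    n_emg: int = 6,
    tau_within: float = 0.5,
    tau_cross: float = 0.15,
    n_samples: int = 3000,
    fs: float = 1000.0,
    seed: int = 0,
    garch_params=None,
) -> Scenario:
    """Build the chain+bridge ground truth.

    The EEG chain is 0-1-...-(n_eeg-1), the EMG chain follows, and one
    bridge edge joins EEG node min(2, n_eeg-1) (the C3-like position) to the
    first EMG node.  ``tau_cross = 0`` makes the bridge an independence edge.
    """
    if not (0.0 <= tau_cross < 1.0 and 0.0 < tau_within < 1.0):
        raise ValueError("need 0 <= tau_cross < 1 and 0 < tau_within < 1")
    if tau_cross >= tau_within:
        raise ValueError("tau_cross must be smaller than tau_within")
    if n_eeg < 1 or n_emg < 1:
        raise ValueError("need at least one channel per modality")
    p = n_eeg + n_emg

    def gauss_pc(tau):
        if tau == 0.0:
            return PairCopula("independence")
        return PairCopula("gaussian", params_from_tau("gaussian", tau))

    tree1 = []
    for i in range(n_eeg - 1):
        tree1.append(VineEdge((i, i + 1), frozenset(), gauss_pc(tau_within), 1))
    for i in range(n_eeg, p - 1):
        tree1.append(VineEdge((i, i + 1), frozenset(), gauss_pc(tau_within), 1))
    bridge = (min(2, n_eeg - 1), n_eeg)
    tree1.append(VineEdge(bridge, frozenset(), gauss_pc(tau_cross), 1))
    tree1.sort(key=lambda e: e.cond)

    trees = _fill_independence_trees(tree1, p) if p > 2 else [tree1]
    vine = VineModel(trees, p)
    gp = tuple(garch_params) if garch_params is not None else DEFAULT_GARCH
    return Scenario(
        n_eeg=n_eeg,
        n_emg=n_emg,
        tau_within=float(tau_within),
        tau_cross=float(tau_cross),
        vine_truth=vine,
        garch_truth=[gp] * p,
        fs=fs,
        n_samples=int(n_samples),
        seed=int(seed),
        bridge=bridge,
    )


def simulate(sc: Scenario, burn: int = 500):
    """Simulate the scenario.

    Returns ``(cm, truth)`` where ``cm`` is the ChannelMatrix of simulated
    signals and ``truth`` carries the innovation uniforms actually used (the
    post-burn-in rows), the analytic tau matrix and the tree-1 edge list.
    """
    rng = np.random.default_rng(sc.seed)
    U = sc.vine_truth.sample(sc.n_samples + burn, seed=rng)
    p = sc.n_channels
    data = np.empty((p, sc.n_samples))
    for ch in range(p):
        data[ch] = simulate_garch(
            sc.garch_truth[ch], sc.n_samples, innovations=U[:, ch], burn=burn
        )
    cm = ChannelMatrix(
        channel_ids=sc.channel_ids,
        modalities=sc.modalities,
        fs=sc.fs,
        data=data,
    )
    truth = {
        "U": U[burn:],
        "tau_matrix": sc.true_tau_matrix(),
        "tree1_edges": sc.true_tree1_edges(),
        "garch_params": list(sc.garch_truth),
        "bridge": sc.bridge,
    }
    return cm, truth


def true_network(sc: Scenario, threshold=None, step: float = 0.05) -> ConnectivityGraph:
    """The network the pipeline should recover: analytic tau matrix pushed
    through block normalization and (unless given) the K >= 2 ln N rule."""
    tau = sc.true_tau_matrix()
    if threshold is None:
        Wn = normalize_blocks(tau, sc.modalities)
        threshold, _, _ = threshold_select([Wn], step=step)
    return ConnectivityGraph.build(
        tau, sc.modalities, threshold, node_labels=sc.channel_ids
    )
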