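"""Regular-vine (R-vine) copula: structure selection, fitting, density, sampling.

The structure is selected tree by tree: tree 1 is the maximum spanning tree
on |Kendall tau| weights between the uniform columns (Prim's algorithm with a
deterministic lexicographic tie-break); each selected edge gets a bivariate
copula chosen by AIC/BIC among the candidate families; conditional
pseudo-observations for the next tree come from the fitted h-functions.
Trees 2..p-1 repeat the construction on the pseudo-observations, with
candidate edges restricted by the proximity condition (an edge of tree j+1
may only join two edges of tree j that share a node), which is what makes the
object a valid vine and its density a proper factorization into pair-copula
terms.

Sampling inverts the construction: variables are put in a sampling order by
peeling the vine from its top tree, and each new variable is obtained by
chaining inverse h-functions (inverse Rosenblatt transform).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .copulas import (
    DEFAULT_FAMILIES,
    PairCopula,
    empirical_kendall_tau,
    fit_pair_copula,
    hfunc,
    hinv,
)

__all__ = [
    "VineEdge",
    "VineModel",
    "RVineCopula",
    "RVineResults",
    "max_spanning_tree",
    "build_rvine",
    "vine_log_density",
    "sample_rvine",
    "first_tree_summary",
]


# ---------------------------------------------------------------------------
# maximum spanning tree (Prim), deterministic ties
# ---------------------------------------------------------------------------


def _components(n, allowed):
    seen = set()
    comps = []
    adj = {i: set() for i in range(n)}
    for (i, j) in allowed:
        adj[i].add(j)
        adj[j].add(i)
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k] - comp)
        seen |= comp
        comps.append(sorted(comp))
    return comps


def max_spanning_tree(weights, allowed=None):
    """Maximum-weight spanning tree of a symmetric nonnegative weight matrix.

    ``allowed`` optionally restricts the usable edges (iterable of index
    pairs).  Ties are broken towards the lexicographically smallest edge, so
    the result is deterministic.  Raises if the allowed edges do not connect
    all nodes, naming the components.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n):
        raise ValueError("weight matrix must be square")
    if n == 1:
        return []
    if allowed is None:
        allowed = {(i, j) for i in range(n) for j in range(i + 1, n)}
    else:
        allowed = {tuple(sorted(e)) for e in allowed}

    in_tree = {0}  # fixed start node keeps the tie-break deterministic
    edges = []
    while len(in_tree) < n:
        best = None
        for (i, j) in allowed:
            if (i in in_tree) == (j in in_tree):
                continue
            cand = (-W[i, j], i, j)
            if best is None or cand < best:
                best = cand
        if best is None:
            comps = _components(n, allowed)
            raise ValueError(
                f"allowed edge set does not connect the nodes; components: {comps}"
            )
        _, i, j = best
        edges.append((i, j))
        in_tree.add(i)
        in_tree.add(j)
    return edges


# ---------------------------------------------------------------------------
# vine containers
# ---------------------------------------------------------------------------


@dataclass
class VineEdge:
    """One pair-copula edge: conditioned pair ``cond`` (a, b) with a < b,
    conditioning set ``given`` (empty in tree 1), at tree ``level``."""

    cond: tuple
    given: frozenset
    copula: PairCopula
    level: int
    tau_emp: float = float("nan")
    # node indices within the level's node list (structure bookkeeping)
    nodes: tuple = field(default=(), repr=False)

    @property
    def complete(self) -> frozenset:
        return frozenset(self.cond) | self.given


class VineModel:
    """Structure + copulas of an R-vine on ``n_vars`` uniform variables."""

    def __init__(self, trees, n_vars):
        self.trees = [list(t) for t in trees]
        self.n_vars = int(n_vars)
        self.validate()

    # -- structural validation ---------------------------------------------
    def validate(self):
        p = self.n_vars
        if len(self.trees) != p - 1:
            raise ValueError(f"expected {p - 1} trees, got {len(self.trees)}")
        for j, tree in enumerate(self.trees, start=1):
            if len(tree) != p - j:
                raise ValueError(f"tree {j} must have {p - j} edges, has {len(tree)}")
            for e in tree:
                a, b = e.cond
                if a == b or a in e.given or b in e.given:
                    raise ValueError(f"malformed edge {e}")
                if len(e.given) != j - 1:
                    raise ValueError(
                        f"edge at level {j} must condition on {j - 1} variables"
                    )
        # tree 1 spans the variables
        comps = _components(p, [e.cond for e in self.trees[0]])
        if len(comps) != 1:
            raise ValueError(f"tree 1 is not spanning; components {comps}")
        # proximity: each level-(j+1) edge joins two level-j edges sharing a node
        for j in range(1, len(self.trees)):
            prev = self.trees[j - 1]
            complete_prev = [e.complete for e in prev]
            for e in self.trees[j]:
                parents = [
                    c for c in complete_prev if c <= e.complete and len(c & set(e.cond)) == 1
                ]
                ok = False
                for ia in range(len(prev)):
                    for ib in range(ia + 1, len(prev)):
                        ca, cb = complete_prev[ia], complete_prev[ib]
                        if ca | cb == e.complete and len(ca & cb) == len(ca) - 1:
                            ok = True
                if not ok:
                    raise ValueError(
                        f"edge {e.cond}|{sorted(e.given)} violates the proximity condition"
                    )

    # -- density ------------------------------------------------------------
    def log_density(self, u) -> np.ndarray:
        """Log copula density at points ``u`` (p-vector or n x p matrix).

        Marginal density terms are excluded: the model lives on the uniform
        scale of the PIT series.
        """
        U = np.atleast_2d(np.asarray(u, dtype=float))
        if U.shape[1] != self.n_vars:
            raise ValueError(f"expected {self.n_vars} columns, got {U.shape[1]}")
        if np.any((U <= 0) | (U >= 1)):
            raise ValueError("points must lie in the open unit hypercube")
        pseudo = {(i, frozenset()): U[:, i] for i in range(self.n_vars)}
        total = np.zeros(U.shape[0])
        for tree in self.trees:
            for e in tree:
                a, b = e.cond
                ua = pseudo[(a, e.given)]
                ub = pseudo[(b, e.given)]
                fam_log = _edge_logpdf(e.copula, ua, ub)
                total += fam_log
                _push_pseudo(pseudo, e, ua, ub)
        return total if np.asarray(u).ndim > 1 else float(total[0])

    # -- sampling ------------------------------------------------------------
    def sample(self, n, seed=None) -> np.ndarray:
        """Draw ``n`` i.i.d. vectors from the vine (inverse Rosenblatt)."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        order, chains = _sampling_order(self.trees, self.n_vars)
        p = self.n_vars
        w = rng.uniform(size=(int(n), p))
        u = np.empty((int(n), p))
        pseudo = {}

        def refresh(done_vars):
            # compute every h-pseudo-observation derivable from sampled vars
            changed = True
            while changed:
                changed = False
                for tree in self.trees:
                    for e in tree:
                        a, b = e.cond
                        ka, kb = (a, e.given), (b, e.given)
                        if ka in pseudo and kb in pseudo:
                            out_a = (a, e.given | {b})
                            if out_a not in pseudo:
                                pseudo[out_a] = hfunc(
                                    e.copula, pseudo[ka], pseudo[kb], cond_on=2
                                )
                                changed = True
                            out_b = (b, e.given | {a})
                            if out_b not in pseudo:
                                pseudo[out_b] = hfunc(
                                    e.copula, pseudo[ka], pseudo[kb], cond_on=1
                                )
                                changed = True

        for k, v in enumerate(order):
            if k == 0:
                u[:, v] = w[:, 0]
            else:
                chain = chains[v]
                z = w[:, k]
                for e in reversed(chain):
                    a, b = e.cond
                    s = b if a == v else a
                    t = pseudo[(s, e.given)]
                    if a == v:
                        z = hinv(e.copula, z, t, cond_on=2)
                    else:
                        z = hinv(e.copula, z, t, cond_on=1)
                u[:, v] = z
            pseudo[(v, frozenset())] = u[:, v]
            refresh(order[: k + 1])
        return u

    # -- reporting ------------------------------------------------------------
    def first_tree_summary(self, modalities=None, labels=None) -> dict:
        """Tree-1 edge list with labels, the set of maximum-degree (core)
        nodes, and the EEG-EMG bridge edges."""
        p = self.n_vars
        labels = list(labels) if labels is not None else [str(i) for i in range(p)]
        modalities = list(modalities) if modalities is not None else ["?"] * p
        deg = np.zeros(p, dtype=int)
        edges = []
        for e in self.trees[0]:
            a, b = e.cond
            deg[a] += 1
            deg[b] += 1
            edges.append(
                {
                    "pair": (labels[a], labels[b]),
                    "modalities": (modalities[a], modalities[b]),
                    "family": e.copula.family,
                    "tau": e.copula.tau,
                }
            )
        mx = deg.max()
        core = [labels[i] for i in range(p) if deg[i] == mx]
        bridges = [
            ed["pair"] for ed in edges if ed["modalities"][0] != ed["modalities"][1]
        ]
        return {
            "edges": edges,
            "degrees": dict(zip(labels, deg.tolist())),
            "core_nodes": core,
            "bridge_edges": bridges,
        }

    # -- (de)serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_vars": self.n_vars,
            "trees": [
                [
                    {
                        "cond": list(e.cond),
                        "given": sorted(e.given),
                        "level": e.level,
                        "tau_emp": e.tau_emp,
                        "copula": e.copula.to_dict(),
                    }
                    for e in tree
                ]
                for tree in self.trees
            ],
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    @classmethod
    def from_dict(cls, d) -> "VineModel":
        trees = [
            [
                VineEdge(
                    cond=tuple(e["cond"]),
                    given=frozenset(e["given"]),
                    copula=PairCopula.from_dict(e["copula"]),
                    level=e["level"],
                    tau_emp=e.get("tau_emp", float("nan")),
                )
                for e in tree
            ]
            for tree in d["trees"]
        ]
        return cls(trees, d["n_vars"])

    def tree1_dot(self, labels=None) -> str:
        labels = labels or [str(i) for i in range(self.n_vars)]
        lines = ["graph tree1 {"]
        for e in self.trees[0]:
            a, b = e.cond
            lines.append(
                f'  "{labels[a]}" -- "{labels[b]}" '
                f'[label="{e.copula.family}, tau={e.copula.tau:.2f}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def _edge_logpdf(pc, ua, ub):
    from .copulas import get_family

    fam = get_family(pc.family)
    with np.errstate(all="ignore"):
        lp = fam.logpdf(np.clip(ua, 1e-12, 1 - 1e-12), np.clip(ub, 1e-12, 1 - 1e-12), pc.params)
    return np.asarray(lp, dtype=float)


def _push_pseudo(pseudo, e, ua, ub):
    a, b = e.cond
    pseudo[(a, e.given | {b})] = hfunc(e.copula, ua, ub, cond_on=2)
    pseudo[(b, e.given | {a})] = hfunc(e.copula, ua, ub, cond_on=1)


def _sampling_order(trees, p):
    """Peel the vine from the top tree to obtain a sampling order and, for
    each variable, its chain of edges (one per level, nested conditioning)."""
    remaining = [set(range(len(t))) for t in trees]
    order = [None] * p
    chains = {}
    assigned = set()
    for pos in range(p - 1, 0, -1):
        top = pos - 1  # 0-based index of highest level still populated
        idxs = sorted(remaining[top])
        assert len(idxs) == 1, "top tree should have exactly one remaining edge"
        e_top = trees[top][idxs[0]]
        v = max(x for x in e_top.cond if x not in assigned)
        chain = []
        for lev in range(top + 1):
            hits = [
                i
                for i in remaining[lev]
                if v in trees[lev][i].cond
            ]
            assert len(hits) == 1, "variable must sit in exactly one edge per level"
            chain.append(trees[lev][hits[0]])
            remaining[lev].discard(hits[0])
        # conditioning sets must nest: given_j == {partners at lower levels}
        partners = set()
        for e in chain:
            assert e.given == frozenset(partners), "chain conditioning sets must nest"
            a, b = e.cond
            partners.add(b if a == v else a)
        order[pos] = v
        chains[v] = chain
        assigned.add(v)
    last = set(range(p)) - assigned
    order[0] = last.pop()
    return order, chains


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class RVineCopula:
    """Model object: uniform data matrix + candidate family menu.

    ``fit`` runs the sequential MST construction and returns
    :class:`RVineResults` carrying the fitted :class:`VineModel` and fit
    statistics.
    """

    def __init__(self, U, candidates=DEFAULT_FAMILIES, criterion="aic"):
        U = np.asarray(U, dtype=float)
        if U.ndim != 2 or U.shape[1] < 2:
            raise ValueError("U must be an n x p matrix with p >= 2")
        if U.shape[0] < 30:
            raise ValueError("need at least 30 rows")
        for j in range(U.shape[1]):
            if np.ptp(U[:, j]) == 0:
                raise ValueError(f"column {j} is constant; cannot build a vine")
        if np.any((U <= 0) | (U >= 1)):
            U = np.clip(U, 1e-10, 1 - 1e-10)
        self.U = U
        self.candidates = tuple(candidates)
        self.criterion = criterion

    def fit(self, trunc_level=None) -> "RVineResults":
        U = self.U
        n, p = U.shape
        trunc = p - 1 if trunc_level is None else max(1, int(trunc_level))

        pseudo = {(i, frozenset()): U[:, i] for i in range(p)}
        trees = []

        # ---- tree 1 -------------------------------------------------------
        tauM = np.zeros((p, p))
        for i in range(p):
            for j in range(i + 1, p):
                tauM[i, j] = tauM[j, i] = empirical_kendall_tau(U[:, i], U[:, j])
        mst = max_spanning_tree(np.abs(tauM))
        tree = []
        for (i, j) in sorted(tuple(sorted(e)) for e in mst):
            cop = self._fit_edge(pseudo[(i, frozenset())], pseudo[(j, frozenset())], 1)
            e = VineEdge(
                cond=(i, j),
                given=frozenset(),
                copula=cop,
                level=1,
                tau_emp=float(tauM[i, j]),
            )
            _push_pseudo(pseudo, e, U[:, i], U[:, j])
            tree.append(e)
        trees.append(tree)

        # ---- trees 2..p-1 -------------------------------------------------
        for level in range(2, p):
            prev = trees[-1]
            m = len(prev)
            cand = []
            for ia in range(m):
                for ib in range(ia + 1, m):
                    e1, e2 = prev[ia], prev[ib]
                    shared = e1.complete & e2.complete
                    if len(shared) != len(e1.complete) - 1:
                        continue  # proximity condition
                    given = frozenset(shared)
                    a, b = sorted(e1.complete ^ e2.complete)
                    cand.append(((ia, ib), (a, b), given))
            nodes = m
            W = np.zeros((nodes, nodes))
            info = {}
            for (ia, ib), (a, b), given in cand:
                ka, kb = (a, given), (b, given)
                ta = pseudo.get(ka)
                tb = pseudo.get(kb)
                if ta is None or tb is None:
                    continue
                t = empirical_kendall_tau(ta, tb)
                W[ia, ib] = W[ib, ia] = abs(t)
                info[(ia, ib)] = ((a, b), given, t)
            mst = max_spanning_tree(W, allowed=list(info))
            tree = []
            for (ia, ib) in sorted(tuple(sorted(e)) for e in mst):
                (a, b), given, t = info[(ia, ib)]
                ua, ub = pseudo[(a, given)], pseudo[(b, given)]
                if level <= trunc:
                    cop = self._fit_edge(ua, ub, level)
                else:
                    cop = PairCopula(
                        "independence", (), loglik=0.0, aic=0.0, bic=0.0, n_obs=n
                    )
                e = VineEdge(
                    cond=(a, b), given=given, copula=cop, level=level, tau_emp=float(t)
                )
                _push_pseudo(pseudo, e, ua, ub)
                tree.append(e)
            trees.append(tree)

        model = VineModel(trees, p)
        ll = sum(e.copula.loglik for tr in trees for e in tr)
        k = sum(len(e.copula.params) for tr in trees for e in tr)
        return RVineResults(
            model=model,
            loglik=float(ll),
            n_params=k,
            aic=-2.0 * ll + 2.0 * k,
            bic=-2.0 * ll + k * math.log(n),
            nobs=n,
            trunc_level=trunc,
        )

    def _fit_edge(self, ua, ub, level) -> PairCopula:
        return fit_pair_copula(ua, ub, candidates=self.candidates, criterion=self.criterion)


@dataclass
class RVineResults:
    model: VineModel
    loglik: float
    n_params: int
    aic: float
    bic: float
    nobs: int
    trunc_level: int

    @property
    def trees(self):
        return self.model.trees

    def log_density(self, u):
        return self.model.log_density(u)

    def sample(self, n, seed=None):
        return self.model.sample(n, seed=seed)

    def first_tree_summary(self, modalities=None, labels=None):
        return self.model.first_tree_summary(modalities=modalities, labels=labels)

    def summary(self) -> str:
        lines = [
            f"R-vine copula: {self.model.n_vars} variables, "
            f"{sum(len(t) for t in self.trees)} pair copulas",
            f"loglik {self.loglik:.2f}  AIC {self.aic:.2f}  BIC {self.bic:.2f}  "
            f"nobs {self.nobs}",
        ]
        for j, tree in enumerate(self.trees, 1):
            fams = ", ".join(
                f"{e.cond[0]},{e.cond[1]}|{','.join(map(str, sorted(e.given))) or '-'}:"
                f"{e.copula.family}"
                for e in tree
            )
            lines.append(f"  tree {j}: {fams}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def build_rvine(U, candidates=DEFAULT_FAMILIES, criterion="aic", trunc_level=None):
    """Sequential MST + AIC/BIC construction; returns :class:`RVineResults`."""
    return RVineCopula(U, candidates=candidates, criterion=criterion).fit(
        trunc_level=trunc_level
    )


def vine_log_density(vm, u):
    model = vm.model if isinstance(vm, RVineResults) else vm
    return model.log_density(u)


def sample_rvine(vm, n, seed=None):
    model = vm.model if isinstance(vm, RVineResults) else vm
    return model.sample(n, seed=seed)


def first_tree_summary(vm, modalities=None, labels=None):
    model = vm.model if isinstance(vm, RVineResults) else vm
    return model.first_tree_summary(modalities=modalities, labels=labels)
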