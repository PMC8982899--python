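"""Balance tree over OMUs, ILR balances and the ILR -> GRmax linear model.

OMU activity vectors are compositional: only relative activity is meaningful,
and the vectors are sparse.  Following the balance-tree approach from
compositional data analysis, OMUs are hierarchically clustered by their mean
GRmax; each internal node of the tree contrasts the OMUs of its left subtree
(oriented toward lower mean GRmax, i.e. cell death) against its right
subtree via the isometric log-ratio

    b = sqrt(nL * nR / (nL + nR)) * ln( g(left) / g(right) )

with g the geometric mean over the *positive* components on each side and
nL, nR the counts of those positive components (sparse vectors carry exact
zeros, which a log-ratio cannot absorb; restricting to the positive part
keeps every vector usable without imputation -- a pseudocount mode is
available for sensitivity analysis).  A balance is undefined when a side has
no positive component.  The internal node whose balances correlate best with
GRmax across drugs is selected, and an ordinary least squares fit of GRmax
on the balance gives the predictive linear model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy import stats

from .io_formats import GRTable
from .omu import OMUSystem, OMUVector

logger = logging.getLogger("omu_synergy")


@dataclass
class BalanceNode:
    """Internal node: left/right leaf index sets over the OMU system order."""

    node_id: int
    left: tuple[int, ...]   # leaf positions, centroid <= right centroid
    right: tuple[int, ...]
    centroid: float         # mean of member OMUs' mean GRmax
    depth: int              # root has depth 0


@dataclass
class BalanceTree:
    nodes: list[BalanceNode]  # all internal nodes, root first
    leaf_omu_ids: list[int]   # OMU id per leaf position

    @property
    def root(self) -> BalanceNode:
        return self.nodes[0]

    def node(self, node_id: int) -> BalanceNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(f"no internal node {node_id}")


@dataclass
class LinearModel:
    """OLS fit of GRmax on the ILR balance at the chosen node."""

    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    node_id: int
    n_obs: int = 0

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.slope, self.intercept, self.pearson_r])):
            raise ValueError("non-finite linear model coefficients")

    def predict(self, balance: float) -> float:
        return self.intercept + self.slope * balance

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "r_squared": self.r_squared,
            "node_id": self.node_id,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            slope=float(d["slope"]), intercept=float(d["intercept"]),
            pearson_r=float(d["pearson_r"]), r_squared=float(d["r_squared"]),
            node_id=int(d["node_id"]), n_obs=int(d.get("n_obs", 0)),
        )


def cluster_omus(system: OMUSystem, linkage: str = "average") -> BalanceTree:
    """Hierarchical clustering of OMUs by |difference in mean GRmax|.

    Deterministic: OMUs are pre-sorted by (mean GRmax, OMU id) so permuting
    the input order cannot change the tree; at every internal node the left
    subtree is the one with the smaller centroid.
    """
    if len(system) < 2:
        raise ValueError("need at least 2 OMUs to build a balance tree")
    order = sorted(
        range(len(system)),
        key=lambda i: (system.omus[i].mean_grmax, system.omus[i].omu_id),
    )
    values = np.asarray([system.omus[i].mean_grmax for i in order], dtype=float)
    z = hierarchy.linkage(values[:, None], method=linkage, metric="euclidean")

    n = len(values)
    # leaves of the scipy tree are positions into `order`; convert every
    # cluster to system-order leaf positions
    clusters: dict[int, list[int]] = {i: [order[i]] for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, _, _) in enumerate(z):
        node = n + k
        clusters[node] = clusters[int(a)] + clusters[int(b)]
        children[node] = (int(a), int(b))

    mean_gr = {i: system.omus[i].mean_grmax for i in range(len(system))}

    def centroid(leaves: list[int]) -> float:
        return float(np.mean([mean_gr[i] for i in leaves]))

    nodes: list[BalanceNode] = []

    def visit(node: int, depth: int) -> None:
        if node < n:
            return
        a, b = children[node]
        la, lb = clusters[a], clusters[b]
        if centroid(la) <= centroid(lb):
            left, right = la, lb
        else:
            left, right = lb, la
        nodes.append(
            BalanceNode(
                node_id=node,
                left=tuple(sorted(left)),
                right=tuple(sorted(right)),
                centroid=centroid(clusters[node]),
                depth=depth,
            )
        )
        visit(a, depth + 1)
        visit(b, depth + 1)

    visit(2 * n - 2, 0)
    leaf_ids = [system.omus[i].omu_id for i in range(len(system))]
    return BalanceTree(nodes=nodes, leaf_omu_ids=leaf_ids)


def ilr_balance(
    v: OMUVector | np.ndarray,
    node: BalanceNode,
    pseudocount: float = 0.0,
) -> float | None:
    """ILR balance of a vector at an internal node; None when undefined.

    With ``pseudocount`` > 0 every component in the contrast gets the
    pseudocount added and all components count, which removes undefinedness
    at the cost of an arbitrary imputation scale.
    """
    values = v.values if isinstance(v, OMUVector) else np.asarray(v, dtype=float)
    total = values.sum()
    if total <= 0:
        raise ValueError("vector has no positive component")
    values = values / total  # proportions; the log-ratio itself is scale-free
    left = values[list(node.left)]
    right = values[list(node.right)]
    if pseudocount > 0:
        left = left + pseudocount
        right = right + pseudocount
    else:
        left = left[left > 0]
        right = right[right > 0]
    if left.size == 0 or right.size == 0:
        return None
    n_l, n_r = left.size, right.size
    coef = np.sqrt(n_l * n_r / (n_l + n_r))
    return float(coef * (np.log(left).mean() - np.log(right).mean()))


def select_balance_point(
    tree: BalanceTree,
    vectors: dict[str, OMUVector],
    gr: GRTable,
    centroid_bounds: tuple[float, float] = (-0.5, 0.5),
    min_fraction: float = 0.9,
    pseudocount: float = 0.0,
    use_root: bool = False,
    min_side: int = 2,
) -> tuple[BalanceNode, dict[str, float], float]:
    """Pick the internal node whose balances best correlate with GRmax.

    Candidates are internal nodes with centroid mean GRmax inside
    ``centroid_bounds``, at least ``min_side`` OMUs on each side (a contrast
    against a single OMU is fragile, especially for scoring combined
    vectors), and a defined balance for at least ``min_fraction`` of the
    samples; the side-size floor is waived when no node satisfies it.
    Returns (node, per-sample balances at that node, Pearson r); samples with
    undefined balance at the winner are excluded and logged.  Ties in |r| go
    to the deeper node, then the smaller node id.  With ``use_root=True`` the
    root is used unconditionally (the reading that includes every OMU in the
    contrast).
    """
    lo, hi = centroid_bounds
    if use_root:
        candidates = [tree.root]
    else:
        candidates = [n for n in tree.nodes if lo <= n.centroid <= hi]
        wide = [n for n in candidates
                if len(n.left) >= min_side and len(n.right) >= min_side]
        if wide:
            candidates = wide
    if not candidates:
        raise ValueError(
            "no internal node has centroid mean GRmax within "
            f"[{lo}, {hi}]; widen the bounds or use the root"
        )
    best = None
    for node in candidates:
        ilrs = {}
        for sample, vec in vectors.items():
            b = ilr_balance(vec, node, pseudocount=pseudocount)
            if b is not None:
                ilrs[sample] = b
        if len(ilrs) < max(3, int(np.ceil(min_fraction * len(vectors)))) and not use_root:
            continue
        if len(ilrs) < 3:
            continue
        xs = np.asarray(list(ilrs.values()))
        ys = np.asarray([gr[s] for s in ilrs])
        if xs.std() == 0 or ys.std() == 0:
            continue
        r = float(stats.pearsonr(xs, ys)[0])
        key = (abs(r), node.depth, -node.node_id)
        if best is None or key > best[0]:
            best = (key, node, ilrs, r)
    if best is None:
        raise ValueError(
            "no candidate balance point with enough defined balances; "
            "lower min_fraction, use a pseudocount, or widen the centroid bounds"
        )
    _, node, ilrs, r = best
    excluded = sorted(set(vectors) - set(ilrs))
    if excluded:
        logger.info("select_balance_point: excluded sample(s) %s (undefined balance)",
                    excluded)
    return node, ilrs, r


def fit_linear_model(ilrs: dict[str, float], gr: GRTable, node_id: int = -1) -> LinearModel:
    """Ordinary least squares of GRmax on the ILR balance."""
    if len(ilrs) < 3:
        raise ValueError("need at least 3 paired observations")
    xs = np.asarray(list(ilrs.values()), dtype=float)
    ys = np.asarray([gr[s] for s in ilrs], dtype=float)
    if xs.std() == 0:
        raise ValueError("zero variance in ILR values; cannot fit")
    fit = stats.linregress(xs, ys)
    return LinearModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        node_id=node_id,
        n_obs=len(xs),
    )
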