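"""Differential-network comparison and differential gene modules.

A drug-treated regulatory network is compared against the untreated control in
three steps:

1. partition the control network into communities (bipartite modularity),
2. form the differential modularity matrix D: how much each TF->gene edge in
   the treated network exceeds its expectation under the control network's
   community structure (floored at zero),
3. aggregate the positive entries of D into edge-disjoint differential
   modules with a seeded community search; each edge carries its D score and
   a module's weight is the sum of its edge scores.

The expectation in step 2 is the control edge weight rescaled by the ratio of
treated to control total weight within the edge's baseline community pair, so
a network compared with itself yields an exactly zero matrix and scaling both
networks by a constant scales D by that constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .community import Partition, detect_communities
from .grn import WeightedGRN

logger = logging.getLogger("omu_synergy")

Edge = tuple[str, str]


@dataclass
class DifferentialModule:
    """A drug-altered regulatory program: TF->gene edges with D scores."""

    sample_id: str
    index: int
    edges: list[Edge]
    edge_scores: dict[Edge, float]

    def __post_init__(self) -> None:
        if not self.edges:
            raise ValueError("differential module must have at least one edge")
        if set(self.edges) != set(self.edge_scores):
            raise ValueError("edges and edge_scores disagree")

    @property
    def module_weight(self) -> float:
        return float(sum(self.edge_scores.values()))

    @property
    def edge_set(self) -> frozenset[Edge]:
        return frozenset(self.edges)

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_id,
            "index": self.index,
            "edges": [[t, g] for t, g in self.edges],
            "scores": [self.edge_scores[e] for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DifferentialModule":
        edges = [(t, g) for t, g in d["edges"]]
        return cls(
            sample_id=d["sample"],
            index=int(d["index"]),
            edges=edges,
            edge_scores=dict(zip(edges, map(float, d["scores"]))),
        )


def shift_nonnegative(*matrices: np.ndarray) -> list[np.ndarray]:
    """Shift matrices jointly so the global minimum maps to zero.

    Modularity assumes non-negative weights; z-scored networks are shifted by
    subtracting the common minimum, which preserves the ordering of weights
    and treats both conditions identically.
    """
    lo = min(float(m.min()) for m in matrices)
    if lo >= 0:
        return [np.asarray(m, dtype=float) for m in matrices]
    return [m - lo for m in matrices]


def baseline_partition(grn: WeightedGRN, seed: int = 1) -> Partition:
    """Community structure of the untreated (control) network."""
    (w,) = shift_nonnegative(grn.weights)
    return detect_communities(w, grn.tf_ids, grn.gene_ids, seed=seed)


def _check_same_nodes(treated: WeightedGRN, control: WeightedGRN) -> None:
    dt = set(treated.tf_ids) ^ set(control.tf_ids)
    dg = set(treated.gene_ids) ^ set(control.gene_ids)
    if dt or dg:
        raise ValueError(
            f"node sets differ between networks: TFs {sorted(dt)}, genes {sorted(dg)}"
        )
    if treated.tf_ids != control.tf_ids or treated.gene_ids != control.gene_ids:
        raise ValueError("node orderings differ between networks")


def differential_modularity_matrix(
    treated: WeightedGRN, control: WeightedGRN, base: Partition
) -> np.ndarray:
    """Per-edge differential modularity of treated relative to control.

    D[t, g] = max(0, w_treated[t, g] - E[t, g]) where the expectation E is the
    control edge weight scaled by the treated/control weight ratio of the
    baseline community pair (community of t, community of g).  Community pairs
    with no control weight fall back to the global ratio.
    """
    _check_same_nodes(treated, control)
    wt, wc = shift_nonnegative(treated.weights, control.weights)
    n_comm = base.n_communities
    tc = base.tf_community
    gc = base.gene_community

    # total treated/control weight per (TF-community, gene-community) pair
    st = np.zeros((n_comm, n_comm))
    sc = np.zeros((n_comm, n_comm))
    for r in range(n_comm):
        rows = tc == r
        if not rows.any():
            continue
        for s in range(n_comm):
            cols = gc == s
            if not cols.any():
                continue
            st[r, s] = wt[np.ix_(rows, cols)].sum()
            sc[r, s] = wc[np.ix_(rows, cols)].sum()
    total_c = wc.sum()
    global_ratio = wt.sum() / total_c if total_c > 0 else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sc > 0, st / np.where(sc > 0, sc, 1.0), global_ratio)

    expectation = wc * ratio[np.ix_(tc, gc)]
    return np.maximum(0.0, wt - expectation)


def extract_differential_modules(
    d_matrix: np.ndarray,
    tf_ids: list[str],
    gene_ids: list[str],
    sample_id: str,
    seed: int = 1,
    min_edges: int = 2,
    score_tol: float = 1e-12,
    denoise_quantile: float = 0.8,
    init: Partition | None = None,
) -> list[DifferentialModule]:
    """Aggregate positive differential-modularity mass into modules.

    Aggregation warm-starts from the baseline partition when ``init`` is
    given, so differential communities grow out of the control network's
    module structure rather than from scratch.

    Because D is a floored difference of dense weight matrices, about half of
    its entries are small positive noise; edges at or below the
    ``denoise_quantile`` quantile of the strictly positive scores are
    discarded first, keeping the strong upper tail where genuine rewiring
    concentrates.  The seeded community search then runs on the surviving
    graph; each community's edges become one module (communities with fewer
    than ``min_edges`` edges are dropped as singleton artifacts).  Modules
    are edge-disjoint within a sample and sorted by module weight descending.
    An (effectively) all-zero D means treated and control are
    indistinguishable and yields an empty list.
    """
    d_matrix = np.asarray(d_matrix, dtype=float)
    if d_matrix.min() < 0:
        raise ValueError("differential modularity matrix must be non-negative")
    masked = np.where(d_matrix > score_tol, d_matrix, 0.0)
    if masked.sum() <= 0:
        return []
    if denoise_quantile > 0:
        positive = masked[masked > 0]
        cutoff = np.quantile(positive, denoise_quantile)
        masked = np.where(masked > cutoff, masked, 0.0)
        if masked.sum() <= 0:
            return []
    part = detect_communities(masked, tf_ids, gene_ids, seed=seed, init=init)
    modules: list[DifferentialModule] = []
    for c in range(part.n_communities):
        rows = np.asarray(part.tf_community) == c
        cols = np.asarray(part.gene_community) == c
        if not rows.any() or not cols.any():
            continue
        sub = masked[np.ix_(rows, cols)]
        tfs = [t for t, keep in zip(tf_ids, rows) if keep]
        genes = [g for g, keep in zip(gene_ids, cols) if keep]
        edges: list[Edge] = []
        scores: dict[Edge, float] = {}
        for i, t in enumerate(tfs):
            for j, g in enumerate(genes):
                if sub[i, j] > 0:
                    edges.append((t, g))
                    scores[(t, g)] = float(sub[i, j])
        if len(edges) >= min_edges:
            modules.append(
                DifferentialModule(sample_id=sample_id, index=-1, edges=edges,
                                   edge_scores=scores)
            )
    modules.sort(key=lambda m: (-m.module_weight, min(m.edges)))
    for i, mod in enumerate(modules):
        mod.index = i
    logger.info("extract_differential_modules(%s): %d module(s)", sample_id, len(modules))
    return modules


def differential_modules_for_sample(
    treated: WeightedGRN,
    control: WeightedGRN,
    base: Partition,
    seed: int = 1,
    min_edges: int = 2,
    denoise_quantile: float = 0.8,
) -> list[DifferentialModule]:
    """Convenience wrapper: D matrix then module extraction for one drug."""
    d = differential_modularity_matrix(treated, control, base)
    return extract_differential_modules(
        d, treated.tf_ids, treated.gene_ids, treated.condition, seed=seed,
        min_edges=min_edges, denoise_quantile=denoise_quantile, init=base,
    )
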