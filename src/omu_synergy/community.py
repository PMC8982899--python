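"""Community detection on weighted bipartite TF x gene networks.

Modularity is Barber's bipartite form

    Q = (1/m) * sum_{t,g} [ w_tg - k_t * d_g / m ] * delta(c_t, c_g)

with m the total edge weight, k_t the TF strength (row sum) and d_g the gene
strength (column sum); communities mix TFs and genes.  Maximization runs a
fast multilevel (Louvain-style) pass via igraph on the symmetrized graph to
get an initial partition, then refines it with greedy single-node moves that
directly maximize Barber's Q.  All randomness is reduced to a seeded
permutation of the node visit order, so a fixed seed gives identical results.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np


@dataclass
class Partition:
    """Joint community assignment for the TF and gene sides of a bipartite net."""

    tf_ids: list[str]
    gene_ids: list[str]
    tf_community: np.ndarray  # int index per TF
    gene_community: np.ndarray  # int index per gene
    modularity: float = 0.0

    @property
    def n_communities(self) -> int:
        if len(self.tf_community) == 0:
            return 0
        return int(max(self.tf_community.max(), self.gene_community.max())) + 1

    def membership(self) -> dict[str, int]:
        """Node id -> community; TF ids take precedence on (rare) collisions."""
        out = {g: int(c) for g, c in zip(self.gene_ids, self.gene_community)}
        out.update({t: int(c) for t, c in zip(self.tf_ids, self.tf_community)})
        return out

    def community_nodes(self, idx: int) -> tuple[list[str], list[str]]:
        tfs = [t for t, c in zip(self.tf_ids, self.tf_community) if c == idx]
        genes = [g for g, c in zip(self.gene_ids, self.gene_community) if c == idx]
        return tfs, genes


def barber_modularity(
    weights: np.ndarray, tf_comm: np.ndarray, gene_comm: np.ndarray
) -> float:
    """Barber bipartite modularity of a (non-negative) weight matrix."""
    m = weights.sum()
    if m <= 0:
        return 0.0
    k = weights.sum(axis=1)
    d = weights.sum(axis=0)
    n_comm = int(max(tf_comm.max(initial=0), gene_comm.max(initial=0))) + 1
    q = 0.0
    for c in range(n_comm):
        trows = tf_comm == c
        gcols = gene_comm == c
        if not trows.any() or not gcols.any():
            continue
        q += weights[np.ix_(trows, gcols)].sum() - k[trows].sum() * d[gcols].sum() / m
    return q / m


def _igraph_init(weights: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Initial partition from igraph's multilevel algorithm.

    The seed permutes vertex order (the only nondeterminism the backend is
    sensitive to), so identical seeds give identical partitions.
    """
    n_tf, n_gene = weights.shape
    n = n_tf + n_gene
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    inv = np.argsort(perm)

    rows, cols = np.nonzero(weights)
    edges = [(inv[t], inv[n_tf + g]) for t, g in zip(rows, cols)]
    ws = weights[rows, cols].tolist()
    g = ig.Graph(n=n, edges=edges, directed=False)
    if not edges:
        return np.arange(n_tf), n_tf + np.arange(n_gene)
    ig.set_random_number_generator(random.Random(int(seed)))
    clustering = g.community_multilevel(weights=ws)
    ig.set_random_number_generator(random)
    member = np.asarray(clustering.membership)[inv]
    return member[:n_tf].copy(), member[n_tf:].copy()


def _refine(
    weights: np.ndarray,
    tf_comm: np.ndarray,
    gene_comm: np.ndarray,
    seed: int,
    max_sweeps: int = 50,
    anchored: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy single-node moves maximizing Barber modularity (seeded order).

    With ``anchored=True`` a node may only move while it has zero link weight
    to its current community: the starting partition acts as a backbone and
    only orphaned nodes are re-aggregated.
    """
    n_tf, n_gene = weights.shape
    m = weights.sum()
    if m <= 0:
        return tf_comm, gene_comm
    k = weights.sum(axis=1)
    d = weights.sum(axis=0)
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n_tf + n_gene)
    n_comm = int(max(tf_comm.max(initial=0), gene_comm.max(initial=0))) + 1
    eps = 1e-12 * max(m, 1.0)
    for _ in range(max_sweeps):
        moved = False
        k_per = np.bincount(tf_comm, weights=k, minlength=n_comm)
        d_per = np.bincount(gene_comm, weights=d, minlength=n_comm)
        for node in order:
            if node < n_tf:
                t = node
                link = np.bincount(gene_comm, weights=weights[t], minlength=n_comm)
                score = link - k[t] * d_per / m
                best = int(np.argmax(score))
                cur = tf_comm[t]
                if anchored and link[cur] > 0:
                    continue
                if score[best] > score[cur] + eps:
                    tf_comm[t] = best
                    k_per[cur] -= k[t]
                    k_per[best] += k[t]
                    moved = True
            else:
                g = node - n_tf
                link = np.bincount(tf_comm, weights=weights[:, g], minlength=n_comm)
                score = link - d[g] * k_per / m
                best = int(np.argmax(score))
                cur = gene_comm[g]
                if anchored and link[cur] > 0:
                    continue
                if score[best] > score[cur] + eps:
                    gene_comm[g] = best
                    d_per[cur] -= d[g]
                    d_per[best] += d[g]
                    moved = True
        if not moved:
            break
    return tf_comm, gene_comm


def _merge_pass(
    weights: np.ndarray, tf_comm: np.ndarray, gene_comm: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Merge community pairs whose union does not lower Barber modularity.

    Exact modularity ties (e.g. a uniform biclique, where every partition
    scores zero) are resolved toward the coarsest partition, which local
    moves alone cannot reach.
    """
    m = weights.sum()
    if m <= 0:
        return tf_comm, gene_comm
    k = weights.sum(axis=1)
    d = weights.sum(axis=0)
    eps = 1e-12 * m
    merged = True
    while merged:
        merged = False
        labels = sorted(set(tf_comm) | set(gene_comm))
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                ta, ga = tf_comm == a, gene_comm == a
                tb, gb = tf_comm == b, gene_comm == b
                cross = (weights[np.ix_(ta, gb)].sum()
                         + weights[np.ix_(tb, ga)].sum())
                expected = (k[ta].sum() * d[gb].sum()
                            + k[tb].sum() * d[ga].sum()) / m
                if cross - expected >= -eps:
                    tf_comm[tb] = a
                    gene_comm[gb] = a
                    merged = True
                    break
            if merged:
                break
    return tf_comm, gene_comm


def _canonicalize(
    tf_ids: list[str],
    gene_ids: list[str],
    tf_comm: np.ndarray,
    gene_comm: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Contiguous indices ordered by (community size desc, smallest node id)."""
    labels = sorted(set(tf_comm) | set(gene_comm))
    keyed = []
    for lab in labels:
        names = [t for t, c in zip(tf_ids, tf_comm) if c == lab]
        names += [g for g, c in zip(gene_ids, gene_comm) if c == lab]
        keyed.append((-(len(names)), min(names), lab))
    remap = {lab: i for i, (_, _, lab) in enumerate(sorted(keyed))}
    return (
        np.asarray([remap[c] for c in tf_comm], dtype=int),
        np.asarray([remap[c] for c in gene_comm], dtype=int),
    )


def detect_communities(
    weights: np.ndarray,
    tf_ids: list[str],
    gene_ids: list[str],
    seed: int = 1,
    init: "Partition | None" = None,
) -> Partition:
    """Seeded bipartite community detection on a non-negative weight matrix.

    ``init`` warm-starts the greedy refinement from an existing partition
    (e.g. the baseline network's communities when aggregating a differential
    matrix); the initial partition then serves as a backbone and only nodes
    with no weight inside their starting community are re-aggregated, so
    partitions of related weight matrices stay comparable.  Without ``init``
    the multilevel pass provides the starting point and refinement is
    unconstrained.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0 or weights.sum() <= 0:
        raise ValueError("empty network: nothing to partition")
    if weights.min() < 0:
        raise ValueError("community detection expects non-negative weights")
    if init is not None:
        if init.tf_ids != list(tf_ids) or init.gene_ids != list(gene_ids):
            raise ValueError("init partition is over different nodes")
        tf_comm = init.tf_community.copy()
        gene_comm = init.gene_community.copy()
    else:
        tf_comm, gene_comm = _igraph_init(weights, seed)
    tf_comm, gene_comm = _refine(weights, tf_comm, gene_comm, seed,
                                 anchored=init is not None)
    if init is None:  # keep the backbone partition intact in anchored mode
        tf_comm, gene_comm = _merge_pass(weights, tf_comm, gene_comm)
    tf_comm, gene_comm = _canonicalize(tf_ids, gene_ids, tf_comm, gene_comm)
    q = barber_modularity(weights, tf_comm, gene_comm)
    return Partition(
        tf_ids=list(tf_ids),
        gene_ids=list(gene_ids),
        tf_community=tf_comm,
        gene_community=gene_comm,
        modularity=q,
    )
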