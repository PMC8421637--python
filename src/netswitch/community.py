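"""Temporal community detection by multilayer modularity optimization.

The dynamic network is a stack of L symmetric nonnegative layers over the
same n nodes. A joint partition assigns every node-layer vertex (i, s) a
module label, and its quality is the multilayer modularity

    Q = (1/2mu) * sum_{ijsr} [ (A_ijs - gamma * k_is k_js / 2m_s) delta_sr
                               + delta_ij * C_jsr ] * delta(g_is, g_jr)

with a Newman-Girvan null model per layer (k_is = strength of node i in
layer s, 2m_s = total strength of layer s), resolution gamma, and ordinal
coupling C_jsr = omega between a node and itself in adjacent layers.
2mu is the total edge weight: sum_s 2m_s plus all coupling weights counted
in both directions.

Optimization is a generalized Louvain: greedy local moves on the
supra-modularity matrix (node-layer vertices, null-adjusted intra-layer
weights, omega couplings) in seed-shuffled vertex order, followed by
community aggregation, repeated until no move improves Q. Labels are
globally meaningful across layers — the same integer denotes the same
community in every layer — which is what makes per-node label changes
between consecutive layers ("switches") well defined downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .connectivity import LayerStack

__all__ = [
    "MultilayerParams",
    "PartitionStack",
    "multilayer_modularity",
    "optimize_partition",
    "repeat_partitions",
    "canonicalize_labels",
]


class NegativeWeightError(ValueError):
    """Stack has negative weights; apply zero_negative before partitioning."""


@dataclass(frozen=True)
class MultilayerParams:
    """Parameters of the multilayer modularity optimization.

    gamma : intra-layer resolution (> 0); larger values favor smaller modules.
    omega : inter-layer coupling weight (>= 0) between a node and itself in
        ordinally adjacent layers; larger values favor temporally persistent
        labels.
    coupling : only ``'ordinal'`` (adjacent layers) is supported.
    n_repetitions : independent optimization restarts whose derived switching
        rates are averaged downstream (default 100).
    seed : master seed; repetition k runs with seed + k.
    max_sweeps : cap on local-move sweeps per aggregation level.
    tolerance : minimum Q improvement (in Q units) for a move to be accepted.
    """

    gamma: float = 1.0
    omega: float = 1.0
    coupling: str = "ordinal"
    n_repetitions: int = 100
    seed: int = 0
    max_sweeps: int = 100
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.omega < 0:
            raise ValueError(f"omega must be >= 0, got {self.omega}")
        if self.coupling != "ordinal":
            raise ValueError("only ordinal (adjacent-layer) coupling is supported")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class PartitionStack:
    """Node x layer integer module assignments with their quality Q.

    Labels are canonical: modules are numbered 0..K-1 by order of first
    appearance scanning nodes (outer) then layers (inner), so outputs are
    comparable across runs.
    """

    labels: np.ndarray  # (n_nodes, n_layers) int
    quality: float
    n_modules: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be node x layer")

    @property
    def n_nodes(self) -> int:
        return self.labels.shape[0]

    @property
    def n_layers(self) -> int:
        return self.labels.shape[1]


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 0..K-1 by first appearance, node-major then layer."""
    labels = np.asarray(labels)
    flat = labels.ravel()  # C order: node-major
    _, first = np.unique(flat, return_index=True)
    old_in_order = flat[np.sort(first)]
    mapping = np.empty(flat.max() + 1, dtype=int)
    mapping[old_in_order] = np.arange(old_in_order.size)
    return mapping[flat].reshape(labels.shape)


def _check_stack(stack: LayerStack) -> None:
    if stack.n_layers == 0:
        raise ValueError("empty layer stack")
    if stack.layers.min() < 0:
        raise NegativeWeightError(
            "layer stack contains negative weights; apply zero_negative first"
        )


def _layer_null_terms(stack: LayerStack):
    """Per-layer strengths k, total strengths 2m, and the grand 2mu."""
    k = stack.layers.sum(axis=2)  # (L, n)
    two_m = k.sum(axis=1)  # (L,)
    return k, two_m


def multilayer_modularity(
    stack: LayerStack, labels: np.ndarray, params: MultilayerParams
) -> float:
    """Multilayer modularity Q of a given joint partition.

    For a single layer this reduces exactly to weighted Newman-Girvan
    modularity at resolution gamma (the coupling term is empty).
    """
    _check_stack(stack)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (stack.n_nodes, stack.n_layers):
        raise ValueError(
            f"labels shape {labels.shape} does not match stack "
            f"({stack.n_nodes}, {stack.n_layers})"
        )
    k, two_m = _layer_null_terms(stack)
    L, n = stack.n_layers, stack.n_nodes
    total = 0.0
    for s in range(L):
        lab = labels[:, s]
        A = stack.layers[s]
        for c in np.unique(lab):
            idx = np.flatnonzero(lab == c)
            a_sum = A[np.ix_(idx, idx)].sum()
            if two_m[s] > 0:
                null = params.gamma * k[s, idx].sum() ** 2 / two_m[s]
            else:
                null = 0.0  # empty layer contributes no null term
            total += a_sum - null
    if L > 1 and params.omega > 0:
        agree = (labels[:, 1:] == labels[:, :-1]).sum()
        total += 2.0 * params.omega * agree
    two_mu = two_m.sum() + 2.0 * params.omega * n * (L - 1)
    if two_mu == 0:
        return 0.0
    return float(total / two_mu)


def _supra_matrix(stack: LayerStack, gamma: float, omega: float) -> sp.csr_matrix:
    """Supra-modularity matrix over node-layer vertices v = s * n + i.

    Intra-layer blocks hold A_s - gamma * k k^T / 2m_s (dense because of the
    null term); omega couplings sit on the +/- n off-diagonals. Memory is
    proportional to L * n^2 plus the couplings.
    """
    k, two_m = _layer_null_terms(stack)
    blocks = []
    for s in range(stack.n_layers):
        B = stack.layers[s].copy()
        if two_m[s] > 0:
            B -= gamma * np.outer(k[s], k[s]) / two_m[s]
        blocks.append(sp.csr_matrix(B))
    supra = sp.block_diag(blocks, format="csr")
    if stack.n_layers > 1 and omega > 0:
        n_total = stack.n_nodes * stack.n_layers
        off = np.full(n_total - stack.n_nodes, omega)
        supra = supra + sp.diags(
            [off, off], [stack.n_nodes, -stack.n_nodes], format="csr"
        )
    return sp.csr_matrix(supra)


def _local_move_sweeps(
    W: sp.csr_matrix,
    labels: np.ndarray,
    rng: np.random.Generator,
    gain_tol: float,
    max_sweeps: int,
) -> bool:
    """Greedy local moves in seed-shuffled vertex order; mutates labels.

    A vertex moves to the candidate community with the largest gain in
    within-community weight (ties: first encountered in a seed-shuffled
    candidate order), provided the gain exceeds gain_tol. Leaving for a
    fresh singleton community is always a candidate. Returns True if any
    move was made.
    """
    indptr, indices, data = W.indptr, W.indices, W.data
    n = labels.size
    next_label = int(labels.max()) + 1
    any_move = False
    for _ in range(max_sweeps):
        moved = False
        for v in rng.permutation(n):
            lo, hi = indptr[v], indptr[v + 1]
            nbr = indices[lo:hi]
            w = data[lo:hi]
            self_mask = nbr != v
            if not self_mask.all():
                nbr = nbr[self_mask]
                w = w[self_mask]
            cur = labels[v]
            if nbr.size == 0:
                continue
            cand, inv = np.unique(labels[nbr], return_inverse=True)
            w_to = np.bincount(inv, weights=w)
            pos = np.searchsorted(cand, cur)
            w_cur = (
                w_to[pos] if pos < cand.size and cand[pos] == cur else 0.0
            )
            # candidate 0-weight slot: moving out into an empty community
            gains = np.concatenate([w_to, [0.0]]) - w_cur
            order = rng.permutation(gains.size)
            best = order[int(np.argmax(gains[order]))]
            if gains[best] <= gain_tol:
                continue
            new = next_label if best == cand.size else int(cand[best])
            if new == cur:
                continue
            if best == cand.size:
                next_label += 1
            labels[v] = new
            moved = True
            any_move = True
        if not moved:
            break
    return any_move


def _aggregate(W: sp.csr_matrix, labels: np.ndarray) -> tuple[sp.csr_matrix, np.ndarray]:
    """Collapse communities into super-vertices; returns (W', compact labels)."""
    compact, inv = np.unique(labels, return_inverse=True)
    k = compact.size
    S = sp.csr_matrix(
        (np.ones(labels.size), (np.arange(labels.size), inv)),
        shape=(labels.size, k),
    )
    W2 = sp.csr_matrix(S.T @ W @ S)
    return W2, inv


def optimize_partition(
    stack: LayerStack, params: MultilayerParams, seed: int | None = None
) -> PartitionStack:
    """Generalized Louvain optimization of multilayer modularity.

    Runs local-move sweeps then aggregation on the supra-modularity graph
    until no move improves Q by more than the tolerance. Deterministic given
    the seed. The returned quality is recomputed from the final labels with
    :func:`multilayer_modularity` (self-consistency by construction).
    """
    _check_stack(stack)
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    W = _supra_matrix(stack, params.gamma, params.omega)
    n_total = W.shape[0]
    k_strength, two_m = _layer_null_terms(stack)
    two_mu = two_m.sum() + 2.0 * params.omega * stack.n_nodes * (stack.n_layers - 1)
    gain_tol = params.tolerance * max(two_mu, 1.0) / 2.0  # Q units -> weight units

    assignment = np.arange(n_total)  # original vertex -> current community
    while True:
        level_labels = np.arange(W.shape[0])
        moved = _local_move_sweeps(W, level_labels, rng, gain_tol, params.max_sweeps)
        if not moved:
            break
        new_W, compact = _aggregate(W, level_labels)
        assignment = compact[assignment]
        if new_W.shape[0] in (W.shape[0], 1):
            break
        W = new_W

    labels = assignment.reshape(stack.n_layers, stack.n_nodes).T
    labels = canonicalize_labels(labels)
    q = multilayer_modularity(stack, labels, params)
    return PartitionStack(
        labels=labels, quality=q, n_modules=int(labels.max()) + 1
    )


def repeat_partitions(
    stack: LayerStack, params: MultilayerParams
) -> list[PartitionStack]:
    """Independent optimization restarts with per-repetition seeds.

    Repetition k uses seed ``(params.seed + k) mod 2**31``, so the list is
    order-stable and extending n_repetitions never perturbs earlier entries.
    """
    return [
        optimize_partition(stack, params, seed=(params.seed + k) % 2**31)
        for k in range(params.n_repetitions)
    ]
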