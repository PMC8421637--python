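"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (brute-force
summation, exhaustive partition enumeration, textbook formulas) kept
independent of the library code paths they check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from netswitch.connectivity import LayerStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_triangles() -> LayerStack:
    """Single layer: two disconnected unit-weight triangles on 6 nodes."""
    a = np.zeros((6, 6))
    for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        a[i, j] = a[j, i] = 1.0
    return LayerStack(
        layers=a[None],
        window_starts=np.array([0]),
        node_ids=[f"n{i}" for i in range(6)],
        nonnegative=True,
    )


def random_stack(rng, n_nodes: int, n_layers: int) -> LayerStack:
    """Random symmetric nonnegative stack with zero diagonals."""
    raw = np.abs(rng.normal(size=(n_layers, n_nodes, n_nodes)))
    layers = (raw + raw.transpose(0, 2, 1)) / 2
    for t in range(n_layers):
        np.fill_diagonal(layers[t], 0.0)
    return LayerStack(
        layers=layers,
        window_starts=np.arange(n_layers),
        node_ids=[f"n{i}" for i in range(n_nodes)],
        nonnegative=True,
    )


def brute_force_q(stack: LayerStack, labels: np.ndarray, gamma: float, omega: float) -> float:
    """Direct summation of the multilayer quality over all (i, j, s, r)."""
    n, L = labels.shape
    k = stack.layers.sum(axis=2)  # (L, n)
    two_m = k.sum(axis=1)
    total = 0.0
    for s in range(L):
        for r in range(L):
            for i in range(n):
                for j in range(n):
                    if labels[i, s] != labels[j, r]:
                        continue
                    if s == r:
                        a = stack.layers[s, i, j]
                        null = (
                            gamma * k[s, i] * k[s, j] / two_m[s]
                            if two_m[s] > 0
                            else 0.0
                        )
                        total += a - null
                    elif i == j and abs(s - r) == 1:
                        total += omega
    two_mu = two_m.sum() + 2.0 * omega * n * (L - 1)
    return total / two_mu if two_mu else 0.0


def set_partitions(n: int):
    """All set partitions of range(n) as label vectors (restricted growth)."""
    labels = [0] * n

    def rec(i: int, k: int):
        if i == n:
            yield tuple(labels)
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1) if n > 1 else iter([(0,)])


def exhaustive_best_q(stack: LayerStack, gamma: float, omega: float):
    """Maximum multilayer Q over every partition of the node-layer vertices.

    Vertices are flattened layer-major (v = s * n + i), matching no internal
    layout on purpose: any flattening enumerates the same partition set.
    """
    from netswitch.community import MultilayerParams, multilayer_modularity

    n, L = stack.n_nodes, stack.n_layers
    params = MultilayerParams(gamma=gamma, omega=omega)
    best = -np.inf
    best_labels = None
    for flat in set_partitions(n * L):
        labels = np.asarray(flat).reshape(L, n).T
        q = multilayer_modularity(stack, labels, params)
        if q > best:
            best, best_labels = q, labels
    return best, best_labels


def partition_sets(labels_column: np.ndarray) -> frozenset:
    """Label-invariant representation of one layer's partition."""
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels_column):
        groups.setdefault(int(lab), []).append(idx)
    return frozenset(frozenset(g) for g in groups.values())
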