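"""Node, subnetwork, and global network switching rates.

The switching rate of node i is f_i = n_i / N, where n_i counts the
transitions between consecutive layers at which the node's module label
changes and N = n_layers - 1 is the maximum possible number of switches.
Rates lie in [0, 1]; higher values mean lower temporal stability of the
node's community affiliation. Subnetwork and global rates are unweighted
means of node rates, and because community detection is stochastic, profiles
from repeated optimizations are averaged at the rate level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .community import PartitionStack

__all__ = [
    "SUBNETWORKS",
    "AtlasMap",
    "SwitchingProfile",
    "node_switch_counts",
    "switching_rates",
    "average_profiles",
]

# the six canonical large-scale subnetworks of the 160-node functional atlas
SUBNETWORKS = (
    "default-mode",
    "occipital",
    "cingulo-opercular",
    "fronto-parietal",
    "sensorimotor",
    "cerebellar",
)


@dataclass(frozen=True)
class AtlasMap:
    """Node id -> subnetwork label mapping (each node mapped exactly once)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.mapping:
            raise ValueError("atlas map is empty")

    def subnetworks(self) -> list[str]:
        """Distinct subnetwork labels in canonical order, then alphabetical."""
        present = set(self.mapping.values())
        ordered = [s for s in SUBNETWORKS if s in present]
        ordered += sorted(present - set(SUBNETWORKS))
        return ordered

    def members(self, subnetwork: str) -> list[str]:
        return [n for n, s in self.mapping.items() if s == subnetwork]


@dataclass
class SwitchingProfile:
    """Per-node, per-subnetwork, and global switching rates.

    node_rates : f_i per node, in [0, 1] (averaged over repetitions).
    n_switch : per-node mean switch count n_i over repetitions.
    n_max : N, the number of consecutive-layer transitions (layers - 1).
    subnet_rates : unweighted mean of member-node rates per subnetwork.
    global_rate : unweighted mean over all nodes.
    n_repetitions : how many partitions were averaged.
    """

    node_ids: Sequence[str]
    node_rates: np.ndarray
    n_switch: np.ndarray
    n_max: int
    subnet_rates: dict[str, float]
    global_rate: float
    n_repetitions: int = 1
    atlas: AtlasMap | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.node_rates = np.asarray(self.node_rates, dtype=float)
        self.n_switch = np.asarray(self.n_switch, dtype=float)
        if np.any((self.node_rates < 0) | (self.node_rates > 1)):
            raise ValueError("node rates must lie in [0, 1]")


def node_switch_counts(partition: PartitionStack) -> np.ndarray:
    """n_i: number of consecutive-layer label changes per node.

    Raises if the stack has a single layer (no transitions, N would be 0).
    """
    if partition.n_layers < 2:
        raise ValueError(
            "switch counts need at least 2 layers "
            f"(got {partition.n_layers})"
        )
    return (partition.labels[:, 1:] != partition.labels[:, :-1]).sum(axis=1)


def _aggregate(
    node_ids: Sequence[str], rates: np.ndarray, atlas: AtlasMap
) -> tuple[dict[str, float], float]:
    index = {n: i for i, n in enumerate(node_ids)}
    subnet_rates = {}
    for s in atlas.subnetworks():
        members = [index[n] for n in atlas.members(s) if n in index]
        if members:
            subnet_rates[s] = float(rates[members].mean())
    return subnet_rates, float(rates.mean())


def switching_rates(
    partition: PartitionStack, atlas: AtlasMap, node_ids: Sequence[str]
) -> SwitchingProfile:
    """Switching profile of a single partition: f_i = n_i / N plus aggregates.

    Raises
    ------
    ValueError
        If the atlas does not cover every node; the message lists the
        unmapped node ids.
    """
    if len(node_ids) != partition.n_nodes:
        raise ValueError(
            f"{len(node_ids)} node ids for a {partition.n_nodes}-node partition"
        )
    unmapped = [n for n in node_ids if n not in atlas.mapping]
    if unmapped:
        raise ValueError(f"atlas does not map nodes: {unmapped}")
    n_i = node_switch_counts(partition)
    n_max = partition.n_layers - 1
    rates = n_i / n_max
    subnet_rates, global_rate = _aggregate(node_ids, rates, atlas)
    return SwitchingProfile(
        node_ids=list(node_ids),
        node_rates=rates,
        n_switch=n_i.astype(float),
        n_max=n_max,
        subnet_rates=subnet_rates,
        global_rate=global_rate,
        n_repetitions=1,
        atlas=atlas,
    )


def average_profiles(profiles: Sequence[SwitchingProfile]) -> SwitchingProfile:
    """Element-wise mean of profiles from repeated community detections.

    Node rates and switch counts are averaged per node; subnetwork and global
    aggregates are recomputed from the averaged node rates, which equals
    averaging the aggregates by linearity.
    """
    if not profiles:
        raise ValueError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if list(p.node_ids) != list(first.node_ids):
            raise ValueError("profiles have heterogeneous node sets")
        if p.n_max != first.n_max:
            raise ValueError("profiles have differing layer counts")
    rates = np.mean([p.node_rates for p in profiles], axis=0)
    counts = np.mean([p.n_switch for p in profiles], axis=0)
    atlas = first.atlas
    if atlas is not None:
        subnet_rates, global_rate = _aggregate(first.node_ids, rates, atlas)
    else:
        subnet_rates, global_rate = {}, float(rates.mean())
    return SwitchingProfile(
        node_ids=list(first.node_ids),
        node_rates=rates,
        n_switch=counts,
        n_max=first.n_max,
        subnet_rates=subnet_rates,
        global_rate=global_rate,
        n_repetitions=sum(p.n_repetitions for p in profiles),
        atlas=atlas,
    )
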