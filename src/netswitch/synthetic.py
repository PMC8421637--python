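"""Seeded synthetic scans and cohorts with planted module-switching structure.

Real resting-state scans behind this kind of analysis are rarely shareable,
so every downstream stage is exercised against synthetic data whose dynamic
community structure is known by construction. A planted design assigns each
node a module label at every volume (a schedule of partitions plus sparse
per-node switch events); nodes in the same module load on a shared
band-limited latent signal, so windowed correlations — and hence the
recovered temporal communities — carry the planted structure. Ground-truth
switching rates are computable directly from the design, which gives the
pipeline something objective to be checked against.

Signal model: x_i(t) = sqrt(c) * u_m(i,t)(t) + noise_sd * eta_i(t), with
u_m and eta_i independent unit-variance band-limited Gaussian series and
c = within_module_corr. The expected correlation of two same-module nodes is
c / (c + noise_sd^2); the default noise_sd = sqrt(1 - c) makes it exactly c.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .connectivity import SlidingWindowConfig, TimeSeriesScan, mean_fd, sliding_windows
from .stats import Cohort
from .switching import SUBNETWORKS, AtlasMap

__all__ = [
    "PlantedDesign",
    "SyntheticSubject",
    "generate_scan",
    "generate_motion",
    "generate_cohort",
    "planted_switch_rate",
    "module_timeline",
    "default_atlas",
    "TABLE1_LIKE",
]

# group-wise covariate/score distributions (mean, sd) the default cohort draws
# from, chosen to resemble a small two-arm substance-dependence study
TABLE1_LIKE: dict[str, dict[str, tuple[float, float]]] = {
    "dependent": {
        "age": (23.54, 3.87),
        "education": (15.13, 1.73),
        "BQDS": (7.42, 1.86),
        "BDI": (10.58, 6.68),
        "BAI": (28.50, 6.20),
        "duration": (7.75, 4.28),
    },
    "control": {
        "age": (24.50, 1.48),
        "education": (16.00, 0.00),
        "BDI": (4.04, 4.65),
        "BAI": (23.27, 2.68),
    },
}


class ScheduleError(ValueError):
    """Partition schedule does not tile the scan or misses nodes."""


@dataclass(frozen=True)
class PlantedDesign:
    """Ground-truth dynamic modular structure for one synthetic scan.

    partition_schedule : tuple of ((start, end), labels)
        Half-open volume intervals tiling [0, n_volumes), each with a
        per-node module labeling (length n_nodes).
    switch_events : tuple of (node, volume, new_module)
        Persistent overrides: from `volume` onward node `node` belongs to
        `new_module`, until a later event reassigns it again.
    within_module_corr : target correlation of same-module node pairs at the
        default noise level, in [0, 1).
    noise_sd : idiosyncratic noise scale; None means sqrt(1 - c) so realized
        within-module correlation equals within_module_corr.
    band : (low, high) Hz pass-band of all generated signals.
    """

    n_nodes: int = 160
    n_volumes: int = 250
    sampling_interval: float = 2.0
    partition_schedule: tuple = ()
    within_module_corr: float = 0.6
    noise_sd: Optional[float] = None
    band: tuple[float, float] = (0.01, 0.10)
    switch_events: tuple = ()

    def __post_init__(self) -> None:
        if not (0 <= self.within_module_corr < 1):
            raise ScheduleError("within_module_corr must be in [0, 1)")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ScheduleError("noise_sd must be > 0")
        if not self.partition_schedule:
            raise ScheduleError("partition_schedule is empty")
        covered = 0
        for (start, end), labels in self.partition_schedule:
            if start != covered or end <= start:
                raise ScheduleError(
                    "schedule intervals must tile [0, n_volumes) in order "
                    f"(got [{start}, {end}) after {covered})"
                )
            if len(labels) != self.n_nodes:
                raise ScheduleError(
                    f"interval [{start}, {end}) labels {len(labels)} nodes, "
                    f"expected {self.n_nodes}"
                )
            covered = end
        if covered != self.n_volumes:
            raise ScheduleError(
                f"schedule covers [0, {covered}), scan has {self.n_volumes} volumes"
            )
        for node, volume, _ in self.switch_events:
            if not (0 <= node < self.n_nodes):
                raise ScheduleError(f"switch event for unknown node {node}")
            if not (0 <= volume < self.n_volumes):
                raise ScheduleError(f"switch event at out-of-range volume {volume}")

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return float(np.sqrt(1.0 - self.within_module_corr))

    @property
    def node_ids(self) -> list[str]:
        return [f"n{i:03d}" for i in range(self.n_nodes)]

    @classmethod
    def static(
        cls,
        n_nodes: int = 160,
        n_modules: int = 6,
        n_volumes: int = 250,
        **kwargs,
    ) -> "PlantedDesign":
        """Single static partition of contiguous, near-equal module blocks."""
        labels = tuple(int(i * n_modules / n_nodes) for i in range(n_nodes))
        return cls(
            n_nodes=n_nodes,
            n_volumes=n_volumes,
            partition_schedule=(((0, n_volumes), labels),),
            **kwargs,
        )

    def with_events(self, events: Sequence[tuple[int, int, int]]) -> "PlantedDesign":
        return replace(self, switch_events=self.switch_events + tuple(events))


def module_timeline(design: PlantedDesign) -> np.ndarray:
    """Effective node x volume module labels: schedule plus event overrides.

    Events are applied in order of their volume (ties: list order), so a
    node's label at volume t is its most recent override at or before t —
    independent of how the event list happens to be ordered.
    """
    timeline = np.empty((design.n_nodes, design.n_volumes), dtype=int)
    for (start, end), labels in design.partition_schedule:
        timeline[:, start:end] = np.asarray(labels, dtype=int)[:, None]
    for node, volume, new_module in sorted(
        design.switch_events, key=lambda e: e[1]
    ):
        timeline[node, volume:] = new_module
    return timeline


def _band_limited(
    rng: np.random.Generator,
    n_series: int,
    n_volumes: int,
    sampling_interval: float,
    band: tuple[float, float],
) -> np.ndarray:
    """Unit-variance Gaussian series with spectral support only in `band`."""
    freqs = np.fft.rfftfreq(n_volumes, d=sampling_interval)
    keep = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not keep.any():
        raise ValueError(f"band {band} Hz contains no resolvable frequency")
    white = rng.standard_normal((n_series, n_volumes))
    spectrum = np.fft.rfft(white, axis=1)
    spectrum[:, ~keep] = 0.0
    x = np.fft.irfft(spectrum, n=n_volumes, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x


def generate_motion(
    n_volumes: int, seed: int | np.random.SeedSequence, step_sd: float = 0.01
) -> np.ndarray:
    """Small-amplitude random-walk rigid-body trace (mm, mm, mm, deg x3)."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, size=(n_volumes, 6))
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


def _scan_seeds(seed: int | np.random.SeedSequence):
    """Two stateless child seeds (signal, motion) for one scan.

    Children are derived by extending the spawn key rather than by
    SeedSequence.spawn(), which is stateful: repeated calls here always
    return the same pair.
    """
    if isinstance(seed, np.random.SeedSequence):
        entropy, base_key = seed.entropy, tuple(seed.spawn_key)
    else:
        entropy, base_key = seed, ()
    return [
        np.random.SeedSequence(entropy, spawn_key=base_key + (k,)) for k in (0, 1)
    ]


def generate_scan(design: PlantedDesign, seed: int | np.random.SeedSequence) -> TimeSeriesScan:
    """Realize one synthetic scan from a planted design, deterministically.

    Same-module nodes share a band-limited latent source with loading
    sqrt(within_module_corr); each node adds independent band-limited noise
    scaled by noise_sd. A motion trace rides along for FD bookkeeping.
    """
    sig_ss, mot_ss = _scan_seeds(seed)
    rng = np.random.default_rng(sig_ss)
    timeline = module_timeline(design)
    modules = np.unique(timeline)
    latents = _band_limited(
        rng, modules.size, design.n_volumes, design.sampling_interval, design.band
    )
    noise = _band_limited(
        rng, design.n_nodes, design.n_volumes, design.sampling_interval, design.band
    )
    module_row = np.searchsorted(modules, timeline)  # (n_nodes, n_volumes)
    shared = latents[module_row, np.arange(design.n_volumes)[None, :]]
    c = design.within_module_corr
    values = np.sqrt(c) * shared + design.effective_noise_sd * noise
    motion = generate_motion(design.n_volumes, mot_ss)
    return TimeSeriesScan(
        values=values,
        node_ids=design.node_ids,
        sampling_interval=design.sampling_interval,
        motion=motion,
    )


def _window_majorities(
    node_labels: np.ndarray, starts: np.ndarray, width: int
) -> np.ndarray:
    """Majority label per window; ties go to the earliest-appearing label."""
    uniq, first = np.unique(node_labels, return_index=True)
    order = np.argsort(first)  # labels by first appearance
    uniq = uniq[order]
    counts = np.empty((uniq.size, starts.size))
    for row, lab in enumerate(uniq):
        csum = np.concatenate([[0], np.cumsum(node_labels == lab)])
        counts[row] = csum[starts + width] - csum[starts]
    return uniq[np.argmax(counts, axis=0)]  # argmax keeps earliest on ties


def planted_switch_rate(
    design: PlantedDesign, window: SlidingWindowConfig | None = None
) -> np.ndarray:
    """Ground-truth per-node switching rate implied by a planted design.

    For each sliding window the node's scheduled module is summarized by the
    majority label over the window's volumes; the rate is the fraction of
    consecutive-window transitions at which that majority changes. This is
    the quantity the full pipeline is expected to recover.
    """
    window = window or SlidingWindowConfig()
    intervals = sliding_windows(design.n_volumes, window)
    if len(intervals) < 2:
        return np.zeros(design.n_nodes)
    starts = np.array([a for a, _ in intervals]) + window.trim_initial
    timeline = module_timeline(design)
    rates = np.zeros(design.n_nodes)
    for i in range(design.n_nodes):
        row = timeline[i]
        if (row == row[0]).all():
            continue
        maj = _window_majorities(row, starts, window.width)
        rates[i] = np.count_nonzero(maj[1:] != maj[:-1]) / (len(intervals) - 1)
    return rates


@dataclass
class SyntheticSubject:
    """One simulated participant: designs, lazy scans, covariates, scores."""

    subject_id: str
    group: str
    design_pre: PlantedDesign
    design_post: PlantedDesign
    scan_seed_pre: np.random.SeedSequence
    scan_seed_post: np.random.SeedSequence
    age: float
    education: float
    mean_fd: float
    scores: dict[str, float]
    planted_rate: np.ndarray  # per-node, pre scan
    planted_rate_post: np.ndarray

    @cached_property
    def scan_pre(self) -> TimeSeriesScan:
        return generate_scan(self.design_pre, self.scan_seed_pre)

    @cached_property
    def scan_post(self) -> TimeSeriesScan:
        return generate_scan(self.design_post, self.scan_seed_post)


def default_atlas(node_ids: Sequence[str]) -> AtlasMap:
    """Round-robin assignment of nodes to the six canonical subnetworks."""
    return AtlasMap(
        {n: SUBNETWORKS[i % len(SUBNETWORKS)] for i, n in enumerate(node_ids)}
    )


def _random_events(
    rng: np.random.Generator, design: PlantedDesign, k: int, window: SlidingWindowConfig
) -> list[tuple[int, int, int]]:
    """k switch events placed where a sliding-window majority can flip."""
    timeline = module_timeline(design)
    modules = np.unique(timeline)
    lo = window.trim_initial + window.width // 2
    hi = design.n_volumes - window.width // 2
    if hi <= lo:
        lo, hi = 1, design.n_volumes
    events = []
    current = timeline.copy()
    # per node, events are placed at strictly increasing volumes at least one
    # window width apart: each event then flips exactly one window majority,
    # and appended events can never erase earlier ones
    last: dict[int, int] = {}
    for node, volume, _ in design.switch_events:
        last[node] = max(last.get(node, -10**9), volume)
    for _ in range(k):
        node, volume = None, None
        for _attempt in range(100):
            cand_node = int(rng.integers(design.n_nodes))
            cand_vol = int(rng.integers(lo, hi))
            if cand_vol >= last.get(cand_node, -10**9) + window.width:
                node, volume = cand_node, cand_vol
                break
        if node is None:
            node = int(rng.integers(design.n_nodes))
            volume = int(rng.integers(lo, hi))
        others = modules[modules != current[node, volume]]
        if others.size == 0:
            continue
        new = int(rng.choice(others))
        current[node, volume:] = new
        last[node] = max(last.get(node, -10**9), volume)
        events.append((node, volume, new))
    return events


def generate_cohort(
    n_per_group: int | tuple[int, int],
    design_by_condition: Optional[Mapping[str, PlantedDesign]] = None,
    effect: float = 0.0,
    seed: int = 0,
    *,
    window: SlidingWindowConfig | None = None,
    events_mean: Optional[float] = None,
    events_sd: Optional[float] = None,
    score_rate_corr: Optional[Mapping[str, float]] = None,
    outcome_noise_sd: float = 0.02,
    levels: Sequence[str] = ("global",),
    atlas: Optional[AtlasMap] = None,
) -> Cohort:
    """Two-group, two-scan synthetic cohort with planted switching structure.

    Each subject's pre-exposure design is the group's base design plus a
    subject-specific number of random switch events (heterogeneity that
    clinical scores can correlate with); the post-exposure design adds
    ``round(effect * n_nodes * (n_windows - 1))`` further events, raising the
    mean planted rate by approximately ``effect``. Outcome values attached to
    the cohort are the exact planted rates plus Gaussian measurement noise of
    scale ``outcome_noise_sd`` (a stand-in for finite-repetition pipeline
    estimates; `netswitch.pipeline.run_pipeline` replaces them with measured
    ones).

    score_rate_corr maps score name -> Gaussian-copula correlation between
    the score and the subject's planted pre-exposure rate (default:
    {'BQDS': 0.5} in the dependent group).

    Deterministic given ``seed``; per-subject random streams use fixed spawn
    keys, so enlarging the cohort never perturbs earlier subjects.
    """
    if isinstance(n_per_group, (tuple, list)):
        n_dep, n_ctl = n_per_group
    else:
        n_dep = n_ctl = int(n_per_group)
    if min(n_dep, n_ctl) < 2:
        raise ValueError("need at least 2 subjects per group")
    window = window or SlidingWindowConfig()
    designs = dict(design_by_condition or {})
    for g in ("dependent", "control"):
        designs.setdefault(g, PlantedDesign.static())
    if score_rate_corr is None:
        score_rate_corr = {"BQDS": 0.5}
    master = np.random.SeedSequence(seed)

    subjects_rows = []
    outcome_rows = []
    details = []
    for g_idx, (group, n_g) in enumerate(
        [("dependent", n_dep), ("control", n_ctl)]
    ):
        base = designs[group]
        n_windows = len(sliding_windows(base.n_volumes, window))
        if n_windows < 2:
            raise ValueError("window config yields fewer than 2 windows")
        rate_quantum = 1.0 / (base.n_nodes * (n_windows - 1))
        ev_mean = events_mean if events_mean is not None else 0.05 / rate_quantum
        ev_sd = events_sd if events_sd is not None else 0.25 * ev_mean
        k_extra = int(round(effect / rate_quantum))
        node_ids = base.node_ids
        cohort_atlas = atlas or default_atlas(node_ids)
        for j in range(n_g):
            sid = f"{'bq' if group == 'dependent' else 'hc'}{j:03d}"
            sub_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(g_idx, j, 0))
            )
            z_rate = sub_rng.standard_normal()
            k_pre = max(0, int(round(ev_mean + ev_sd * z_rate)))
            ev_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(g_idx, j, 1))
            )
            design_pre = base.with_events(_random_events(ev_rng, base, k_pre, window))
            design_post = design_pre.with_events(
                _random_events(ev_rng, design_pre, k_extra, window)
            )
            rate_pre = planted_switch_rate(design_pre, window)
            rate_post = planted_switch_rate(design_post, window)

            dists = TABLE1_LIKE[group]
            row: dict = {"subject_id": sid, "group": group}
            for name in ("age", "education"):
                m, sd = dists[name]
                row[name] = m + sd * sub_rng.standard_normal()
            scores: dict[str, float] = {}
            for name in ("BQDS", "BDI", "BAI", "duration"):
                if name not in dists:
                    scores[name] = np.nan
                    continue
                m, sd = dists[name]
                rho = float(score_rate_corr.get(name, 0.0))
                z = rho * z_rate + np.sqrt(1 - rho**2) * sub_rng.standard_normal()
                scores[name] = m + sd * z
            row.update(scores)

            seed_pre = np.random.SeedSequence(seed, spawn_key=(g_idx, j, 2))
            seed_post = np.random.SeedSequence(seed, spawn_key=(g_idx, j, 3))
            motion = generate_motion(base.n_volumes, _scan_seeds(seed_pre)[1])
            row["mean_fd"] = mean_fd(motion)
            subjects_rows.append(row)

            noise_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(g_idx, j, 4))
            )
            for scan_name, rates in (("pre", rate_pre), ("post", rate_post)):
                orow: dict = {"subject_id": sid, "scan": scan_name}
                if "global" in levels:
                    orow["global"] = float(rates.mean()) + noise_rng.normal(
                        0, outcome_noise_sd
                    )
                if "subnetwork" in levels:
                    for s in cohort_atlas.subnetworks():
                        members = [
                            node_ids.index(nid) for nid in cohort_atlas.members(s)
                        ]
                        orow[f"subnet:{s}"] = float(
                            rates[members].mean()
                        ) + noise_rng.normal(0, outcome_noise_sd)
                if "node" in levels:
                    for i, nid in enumerate(node_ids):
                        orow[f"node:{nid}"] = float(rates[i]) + noise_rng.normal(
                            0, outcome_noise_sd
                        )
                outcome_rows.append(orow)

            details.append(
                SyntheticSubject(
                    subject_id=sid,
                    group=group,
                    design_pre=design_pre,
                    design_post=design_post,
                    scan_seed_pre=seed_pre,
                    scan_seed_post=seed_post,
                    age=row["age"],
                    education=row["education"],
                    mean_fd=row["mean_fd"],
                    scores=scores,
                    planted_rate=rate_pre,
                    planted_rate_post=rate_post,
                )
            )

    subjects = pd.DataFrame(subjects_rows).set_index("subject_id")
    outcomes = pd.DataFrame(outcome_rows).set_index(["subject_id", "scan"])
    return Cohort(subjects=subjects, outcomes=outcomes, subjects_detail=details)
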