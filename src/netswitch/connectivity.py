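"""Sliding-window functional connectivity and signal conditioning.

A scan is a node x time matrix of regional BOLD-like signals. This module
turns it into a time-ordered stack of windowed connectivity layers: the
series is optionally residualized against nuisance regressors, band-pass
filtered, trimmed, segmented into overlapping windows, and each window's
pairwise Pearson correlations are Fisher z-transformed into a symmetric
zero-diagonal matrix. Head-motion bookkeeping (mean framewise displacement,
gross-motion QC) lives here too because it is consumed as a per-scan scalar
covariate downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SlidingWindowConfig",
    "TimeSeriesScan",
    "LayerStack",
    "sliding_windows",
    "window_connectivity",
    "zero_negative",
    "regress_nuisance",
    "bandpass",
    "mean_fd",
    "motion_qc",
]

# clip |r| below 1 so atanh stays finite; modularity needs finite weights
R_CLIP = 1.0 - 1e-7


class ConfigurationError(ValueError):
    """Window/filter configuration incompatible with the data."""


class DegenerateInputError(ValueError):
    """Input segment carries no usable signal (e.g. zero variance)."""


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Rectangular sliding-window scheme.

    Parameters
    ----------
    width : int
        Window length in volumes (default 50; 100 s at a 2 s sampling
        interval).
    step : int
        Offset between consecutive window starts, in volumes (default 1).
    trim_initial : int
        Leading volumes dropped before windowing, emulating the removal of
        initial non-steady-state frames (default 10).
    """

    width: int = 50
    step: int = 1
    trim_initial: int = 10

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ConfigurationError(f"window width must be >= 2, got {self.width}")
        if self.step < 1:
            raise ConfigurationError(f"step must be >= 1, got {self.step}")
        if self.trim_initial < 0:
            raise ConfigurationError(
                f"trim_initial must be >= 0, got {self.trim_initial}"
            )

    def n_windows(self, series_length: int) -> int:
        """Number of windows for a raw series of `series_length` volumes."""
        effective = series_length - self.trim_initial
        if self.width > effective:
            raise ConfigurationError(
                f"window width {self.width} exceeds post-trim length {effective}"
            )
        return (effective - self.width) // self.step + 1


@dataclass
class TimeSeriesScan:
    """One scan: node x time signal matrix plus acquisition metadata.

    Attributes
    ----------
    values : ndarray, shape (n_nodes, n_volumes)
    node_ids : sequence of str
    sampling_interval : float
        Seconds per volume (TR).
    motion : ndarray or None, shape (n_volumes, 6)
        Rigid-body trace: 3 translations (mm) then 3 rotations (degrees by
        convention; see `mean_fd`).
    """

    values: np.ndarray
    node_ids: Sequence[str]
    sampling_interval: float = 2.0
    motion: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D node x time matrix")
        n_nodes, n_time = self.values.shape
        if n_nodes < 2:
            raise ValueError("a scan needs at least 2 nodes")
        if n_time < 2:
            raise ValueError("a scan needs at least 2 time points")
        if np.isnan(self.values).any():
            raise ValueError("scan contains missing values")
        if len(self.node_ids) != n_nodes:
            raise ValueError(
                f"{len(self.node_ids)} node ids for {n_nodes} rows"
            )
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.ndim != 2 or self.motion.shape[1] != 6:
                raise ValueError("motion trace must be time x 6")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass
class LayerStack:
    """Time-ordered stack of symmetric node x node connectivity matrices."""

    layers: np.ndarray  # (n_layers, n_nodes, n_nodes)
    window_starts: np.ndarray  # post-trim volume index of each window start
    node_ids: Sequence[str]
    nonnegative: bool = False

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        self.window_starts = np.asarray(self.window_starts, dtype=int)
        if self.layers.ndim != 3 or self.layers.shape[1] != self.layers.shape[2]:
            raise ValueError("layers must be (n_layers, n, n)")
        if self.layers.shape[0] != self.window_starts.shape[0]:
            raise ValueError("one window start per layer required")

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


def sliding_windows(
    series_length: int, config: SlidingWindowConfig
) -> list[tuple[int, int]]:
    """Half-open [start, end) window intervals in post-trim volume indices.

    The count obeys floor((L - width) / step) + 1 with
    L = series_length - trim_initial.
    """
    n = config.n_windows(series_length)
    return [
        (k * config.step, k * config.step + config.width) for k in range(n)
    ]


def window_connectivity(
    scan: TimeSeriesScan, config: SlidingWindowConfig
) -> LayerStack:
    """Fisher z-transformed Pearson connectivity within each sliding window.

    Each layer t holds atanh(r_ij) of the Pearson correlation of nodes i, j
    over window t, with the diagonal set to zero and |r| clipped just below
    one so the transform stays finite.

    Raises
    ------
    DegenerateInputError
        If any node has zero variance within some window (correlation
        undefined there); the message names the node and window.
    """
    intervals = sliding_windows(scan.n_volumes, config)
    data = scan.values[:, config.trim_initial:]
    n = scan.n_nodes
    layers = np.empty((len(intervals), n, n))
    for t, (a, b) in enumerate(intervals):
        seg = data[:, a:b]
        sd = seg.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise DegenerateInputError(
                f"node {scan.node_ids[bad]!r} has zero variance in window {t} "
                f"(post-trim volumes [{a}, {b}))"
            )
        r = np.corrcoef(seg)
        np.clip(r, -R_CLIP, R_CLIP, out=r)
        z = np.arctanh(r)
        np.fill_diagonal(z, 0.0)
        layers[t] = (z + z.T) / 2.0  # enforce exact symmetry
    return LayerStack(
        layers=layers,
        window_starts=np.array([a for a, _ in intervals]),
        node_ids=list(scan.node_ids),
    )


def zero_negative(stack: LayerStack) -> LayerStack:
    """Set all negative connectivity entries to zero (idempotent)."""
    return LayerStack(
        layers=np.maximum(stack.layers, 0.0),
        window_starts=stack.window_starts.copy(),
        node_ids=list(stack.node_ids),
        nonnegative=True,
    )


def regress_nuisance(
    scan: TimeSeriesScan, regressors: Optional[np.ndarray] = None
) -> TimeSeriesScan:
    """Residualize every node series against [intercept | regressors].

    With no regressors this mean-centers each series. The operation is a
    projection: applying it twice equals applying it once.

    Raises
    ------
    ValueError
        If the design matrix (with intercept) is rank deficient.
    """
    t = scan.n_volumes
    if regressors is None:
        design = np.ones((t, 1))
    else:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim == 1:
            regressors = regressors[:, None]
        if regressors.shape[0] != t:
            raise ValueError(
                f"regressors have {regressors.shape[0]} rows, scan has {t} volumes"
            )
        design = np.column_stack([np.ones(t), regressors])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("nuisance design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(design, scan.values.T, rcond=None)
    resid = scan.values.T - design @ beta
    return replace(scan, values=resid.T)


def bandpass(scan: TimeSeriesScan, low: float, high: float) -> TimeSeriesScan:
    """Zero-phase frequency-domain band-pass filter.

    Retains Fourier components with frequency in [low, high] Hz (inclusive)
    and zeroes the rest, including the DC term when low > 0. Exactly bounded:
    out-of-band gain is identically zero.
    """
    nyquist = 0.5 / scan.sampling_interval
    if not (0 <= low < high <= nyquist + 1e-12):
        raise ValueError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyquist} Hz"
        )
    t = scan.n_volumes
    freqs = np.fft.rfftfreq(t, d=scan.sampling_interval)
    spectrum = np.fft.rfft(scan.values, axis=1)
    keep = (freqs >= low) & (freqs <= high)
    if low > 0:
        keep &= freqs > 0
    spectrum[:, ~keep] = 0.0
    return replace(scan, values=np.fft.irfft(spectrum, n=t, axis=1))


def mean_fd(motion: np.ndarray, rotation_unit: str = "degrees") -> float:
    """Mean framewise displacement of a time x 6 rigid-body trace.

    Per frame (from the second on), FD is the sum of absolute translation
    increments plus 50 mm times the sum of absolute rotation increments in
    radians — the displacement of a point on a 50 mm sphere. Rotations are
    assumed stored in degrees unless ``rotation_unit='radians'``.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be time x 6")
    if motion.shape[0] < 2:
        raise ValueError("mean FD needs at least 2 frames")
    if rotation_unit not in ("degrees", "radians"):
        raise ValueError(f"unknown rotation unit {rotation_unit!r}")
    delta = np.abs(np.diff(motion, axis=0))
    rot = delta[:, 3:]
    if rotation_unit == "degrees":
        rot = np.deg2rad(rot)
    fd = delta[:, :3].sum(axis=1) + 50.0 * rot.sum(axis=1)
    return float(fd.mean())


def motion_qc(
    motion: np.ndarray,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> tuple[bool, Optional[str]]:
    """Gross-motion screen: translations > 2 mm or rotations > 2 degrees fail.

    The trace is read as displacement from the reference frame; the check is
    a strict inequality on the per-axis maximum absolute value.

    Returns
    -------
    (passed, offending_axis)
        ``offending_axis`` names the first failing column
        (trans_x/y/z, rot_x/y/z) or is None on pass.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion trace must be time x 6")
    axes = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    limits = [max_translation_mm] * 3 + [max_rotation_deg] * 3
    peak = np.abs(motion).max(axis=0)
    for name, limit, value in zip(axes, limits, peak):
        if value > limit:
            return False, name
    return True, None
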