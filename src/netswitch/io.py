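"""Plain-text readers and writers for the pipeline's file formats.

Scans are TSV with one row per volume and a header row of node ids; motion
traces are 6-column TSV (trans_x/y/z in mm, rot_x/y/z in degrees); the atlas
is a two-column TSV (node_id, subnetwork); cohort tables are CSV. Partition
stacks and switching profiles are written with JSON sidecars carrying the
parameters and seeds needed to reproduce them. Numeric output uses 12
significant digits so reruns are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community import PartitionStack
from .connectivity import TimeSeriesScan
from .switching import AtlasMap, SwitchingProfile

__all__ = [
    "write_scan",
    "read_scan",
    "write_motion",
    "read_motion",
    "write_atlas",
    "read_atlas",
    "write_partition",
    "read_partition",
    "write_profile",
    "write_cohort_table",
    "read_cohort_table",
]

FLOAT_FMT = "%.12g"


def write_scan(scan: TimeSeriesScan, path: str | Path) -> None:
    df = pd.DataFrame(scan.values.T, columns=list(scan.node_ids))
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_scan(
    path: str | Path,
    sampling_interval: float = 2.0,
    motion_path: str | Path | None = None,
) -> TimeSeriesScan:
    df = pd.read_csv(path, sep="\t")
    motion = read_motion(motion_path) if motion_path else None
    return TimeSeriesScan(
        values=df.to_numpy().T,
        node_ids=list(df.columns),
        sampling_interval=sampling_interval,
        motion=motion,
    )


MOTION_COLS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_motion(motion: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(np.asarray(motion), columns=MOTION_COLS).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_motion(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")[MOTION_COLS].to_numpy()


def write_atlas(atlas: AtlasMap, path: str | Path) -> None:
    rows = sorted(atlas.mapping.items())
    pd.DataFrame(rows, columns=["node_id", "subnetwork"]).to_csv(
        path, sep="\t", index=False
    )


def read_atlas(path: str | Path) -> AtlasMap:
    df = pd.read_csv(path, sep="\t")
    return AtlasMap(dict(zip(df["node_id"].astype(str), df["subnetwork"])))


def write_partition(
    partition: PartitionStack,
    node_ids: Sequence[str],
    path: str | Path,
    *,
    gamma: float,
    omega: float,
    seed: int,
) -> None:
    """TSV of integer labels (rows = nodes, columns = windows) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        partition.labels,
        index=list(node_ids),
        columns=[f"w{t:03d}" for t in range(partition.n_layers)],
    )
    df.to_csv(path, sep="\t", index_label="node_id")
    sidecar = {
        "Q": round(partition.quality, 12),
        "gamma": gamma,
        "omega": omega,
        "seed": seed,
        "n_modules": partition.n_modules,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_partition(path: str | Path) -> tuple[PartitionStack, list[str]]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col="node_id")
    meta = json.loads(path.with_suffix(".json").read_text())
    partition = PartitionStack(
        labels=df.to_numpy(dtype=int),
        quality=meta["Q"],
        n_modules=meta["n_modules"],
    )
    return partition, [str(i) for i in df.index]


def write_profile(profile: SwitchingProfile, path: str | Path) -> None:
    """CSV (node_id, subnetwork, n_switch, rate) + JSON aggregate summary."""
    path = Path(path)
    subnet = (
        [profile.atlas.mapping.get(n, "") for n in profile.node_ids]
        if profile.atlas
        else [""] * len(profile.node_ids)
    )
    pd.DataFrame(
        {
            "node_id": list(profile.node_ids),
            "subnetwork": subnet,
            "n_switch": profile.n_switch,
            "rate": profile.node_rates,
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)
    summary = {
        "global": round(profile.global_rate, 12),
        "subnetworks": {k: round(v, 12) for k, v in profile.subnet_rates.items()},
        "n_max": profile.n_max,
        "n_repetitions": profile.n_repetitions,
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2) + "\n")


def write_cohort_table(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, float_format=FLOAT_FMT)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")
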