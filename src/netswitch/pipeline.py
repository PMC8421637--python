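"""End-to-end orchestration: simulate -> connect -> partition -> switching -> stats.

A run is driven by a RunConfig (loadable from YAML). Every stage's outputs
land under the run's output directory together with a JSON manifest listing
inputs, parameters, per-scan seeds, package versions, and per-stage timing,
which makes a run bit-reproducible given the same config. Stage failures
abort with the stage name and subject id; partial outputs are kept next to a
FAILED marker file.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as nsio
from .community import MultilayerParams, repeat_partitions
from .connectivity import (
    SlidingWindowConfig,
    TimeSeriesScan,
    bandpass,
    mean_fd,
    motion_qc,
    regress_nuisance,
    window_connectivity,
    zero_negative,
)
from .stats import Cohort, run_study_stats
from .switching import average_profiles, switching_rates

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "PipelineError"]

log = logging.getLogger("netswitch")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: BaseException):
        self.stage = stage
        self.subject = subject
        who = f" (subject {subject})" if subject else ""
        super().__init__(f"stage {stage!r} failed{who}: {cause}")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    cohort_csv must have columns group, scan_pre, scan_post (TSV paths,
    relative to the CSV's directory), optional motion_pre/motion_post, the
    covariates age/education (mean_fd is computed from motion when present),
    and any score columns. simulate, when set, generates these inputs first.
    """

    out_dir: str = "netswitch_run"
    cohort_csv: Optional[str] = None
    atlas_tsv: Optional[str] = None
    sampling_interval: float = 2.0
    window: SlidingWindowConfig = field(default_factory=SlidingWindowConfig)
    multilayer: MultilayerParams = field(default_factory=MultilayerParams)
    band: tuple[float, float] = (0.01, 0.10)
    gsr: bool = True
    levels: Sequence[str] = ("global",)
    seed: int = 0
    log_level: str = "INFO"
    simulate: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in raw:
            raw["window"] = SlidingWindowConfig(**raw["window"])
        if "multilayer" in raw:
            raw["multilayer"] = MultilayerParams(**raw["multilayer"])
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = list(self.band)
        d["levels"] = list(self.levels)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _scan_paths(config: RunConfig) -> tuple[pd.DataFrame, Path]:
    base = Path(config.cohort_csv).parent
    table = nsio.read_cohort_table(config.cohort_csv)
    return table, base


def _load_scan(
    base: Path, table: pd.DataFrame, sid: str, scan: str, config: RunConfig
) -> TimeSeriesScan:
    row = table.loc[sid]
    motion_col = f"motion_{scan}"
    motion = (
        base / str(row[motion_col])
        if motion_col in table.columns and pd.notna(row[motion_col])
        else None
    )
    return nsio.read_scan(
        base / str(row[f"scan_{scan}"]),
        sampling_interval=config.sampling_interval,
        motion_path=motion,
    )


def validate_inputs(config: RunConfig) -> list[dict]:
    """Machine-readable pre-flight checks; reports issues, never raises."""
    issues: list[dict] = []

    def issue(kind: str, message: str, **extra) -> None:
        issues.append({"kind": kind, "message": message, **extra})

    if config.cohort_csv is None:
        if config.simulate is None:
            issue("config", "no cohort_csv and no simulate block")
        return issues
    if not Path(config.cohort_csv).exists():
        issue("missing_file", f"cohort table not found: {config.cohort_csv}")
        return issues
    table, base = _scan_paths(config)
    atlas = None
    if config.atlas_tsv:
        if not Path(config.atlas_tsv).exists():
            issue("missing_file", f"atlas not found: {config.atlas_tsv}")
        else:
            atlas = nsio.read_atlas(config.atlas_tsv)
    for sid, row in table.iterrows():
        for scan in ("pre", "post"):
            col = f"scan_{scan}"
            if col not in table.columns or pd.isna(row.get(col)):
                issue(
                    "missing_scan",
                    f"subject {sid} lacks the {scan} scan; excluded from paired analyses",
                    subject=str(sid),
                )
                continue
            path = base / str(row[col])
            if not path.exists():
                issue("missing_file", f"scan file not found: {path}", subject=str(sid))
                continue
            scan_obj = nsio.read_scan(path, config.sampling_interval)
            try:
                config.window.n_windows(scan_obj.n_volumes)
            except Exception as exc:
                issue("shape", f"subject {sid} {scan}: {exc}", subject=str(sid))
            if atlas is not None:
                missing = [n for n in scan_obj.node_ids if n not in atlas.mapping]
                if missing:
                    issue(
                        "atlas",
                        f"subject {sid} {scan}: atlas misses nodes {missing[:5]}",
                        subject=str(sid),
                    )
            mcol = f"motion_{scan}"
            if mcol in table.columns and pd.notna(row.get(mcol)):
                motion = nsio.read_motion(base / str(row[mcol]))
                ok, axis = motion_qc(motion)
                if not ok:
                    issue(
                        "motion_qc",
                        f"subject {sid} {scan}: motion exceeds limits on {axis}",
                        subject=str(sid),
                        axis=axis,
                    )
        for cov in ("age", "education"):
            if cov not in table.columns or pd.isna(row.get(cov)):
                issue("covariate", f"subject {sid} missing {cov}", subject=str(sid))
    return issues


def _simulate_stage(config: RunConfig, data_dir: Path) -> None:
    from .synthetic import PlantedDesign, default_atlas, generate_cohort

    spec = dict(config.simulate or {})
    design = PlantedDesign.static(
        n_nodes=int(spec.get("n_nodes", 20)),
        n_modules=int(spec.get("n_modules", 4)),
        n_volumes=int(spec.get("n_volumes", 250)),
    )
    cohort = generate_cohort(
        tuple(spec.get("n_per_group", (3, 3))),
        {"dependent": design, "control": design},
        effect=float(spec.get("effect", 0.0)),
        seed=config.seed,
        window=config.window,
        levels=config.levels,
    )
    data_dir.mkdir(parents=True, exist_ok=True)
    table = cohort.subjects.copy()
    for col in ("scan_pre", "scan_post", "motion_pre", "motion_post"):
        table[col] = ""
    for sub in cohort.subjects_detail:
        for scan_name in ("pre", "post"):
            scan = getattr(sub, f"scan_{scan_name}")
            sname = f"{sub.subject_id}_{scan_name}.tsv"
            mname = f"{sub.subject_id}_{scan_name}_motion.tsv"
            nsio.write_scan(scan, data_dir / sname)
            nsio.write_motion(scan.motion, data_dir / mname)
            table.loc[sub.subject_id, f"scan_{scan_name}"] = sname
            table.loc[sub.subject_id, f"motion_{scan_name}"] = mname
    nsio.write_cohort_table(table, data_dir / "cohort.csv")
    nsio.write_atlas(default_atlas(design.node_ids), data_dir / "atlas.tsv")
    config.cohort_csv = str(data_dir / "cohort.csv")
    config.atlas_tsv = str(data_dir / "atlas.tsv")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "versions": _versions(),
        "stages": [],
        "seed": config.seed,
    }
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    timings = {"simulate": 0.0, "connect": 0.0, "partition": 0.0, "switching": 0.0, "stats": 0.0}
    extras: dict[str, dict] = {name: {} for name in timings}

    try:
        t0 = time.time()
        if config.simulate is not None:
            _simulate_stage(config, out / "data")
            extras["simulate"]["cohort_csv"] = config.cohort_csv
        else:
            extras["simulate"]["skipped"] = True
        timings["simulate"] = time.time() - t0

        issues = validate_inputs(config)
        (out / "validation.json").write_text(json.dumps(issues, indent=2) + "\n")
        manifest["validation_issues"] = len(issues)

        table, base = _scan_paths(config)
        atlas = nsio.read_atlas(config.atlas_tsv)
        profiles_dir = out / "profiles"
        partitions_dir = out / "partitions"
        profiles_dir.mkdir(exist_ok=True)
        partitions_dir.mkdir(exist_ok=True)

        outcome_rows = []
        scan_seeds = {}
        layer_counts = {}
        scan_jobs = [
            (sid, scan)
            for sid in table.index
            for scan in ("pre", "post")
            if f"scan_{scan}" in table.columns and pd.notna(table.loc[sid, f"scan_{scan}"])
        ]
        for idx, (sid, scan_name) in enumerate(scan_jobs):
            key = f"{sid}_{scan_name}"
            stage = "connect"
            try:
                t0 = time.time()
                scan = _load_scan(base, table, sid, scan_name, config)
                if config.gsr:
                    scan = regress_nuisance(scan, scan.values.mean(axis=0))
                else:
                    scan = regress_nuisance(scan)
                scan = bandpass(scan, *config.band)
                stack = zero_negative(window_connectivity(scan, config.window))
                layer_counts[key] = stack.n_layers
                timings["connect"] += time.time() - t0

                stage = "partition"
                t0 = time.time()
                # per-scan seeds pre-assigned from the master seed, so runs
                # are reproducible regardless of execution order
                seed = int(
                    np.random.SeedSequence(
                        config.seed, spawn_key=(idx,)
                    ).generate_state(1)[0]
                    % 2**31
                )
                scan_seeds[key] = seed
                params = MultilayerParams(
                    gamma=config.multilayer.gamma,
                    omega=config.multilayer.omega,
                    n_repetitions=config.multilayer.n_repetitions,
                    seed=seed,
                    max_sweeps=config.multilayer.max_sweeps,
                    tolerance=config.multilayer.tolerance,
                )
                partitions = repeat_partitions(stack, params)
                nsio.write_partition(
                    partitions[0],
                    stack.node_ids,
                    partitions_dir / f"{key}.tsv",
                    gamma=params.gamma,
                    omega=params.omega,
                    seed=seed,
                )
                timings["partition"] += time.time() - t0

                stage = "switching"
                t0 = time.time()
                profile = average_profiles(
                    [switching_rates(p, atlas, stack.node_ids) for p in partitions]
                )
                nsio.write_profile(profile, profiles_dir / f"{key}.csv")
                row = {"subject_id": str(sid), "scan": scan_name}
                if "global" in config.levels:
                    row["global"] = profile.global_rate
                if "subnetwork" in config.levels:
                    for s, v in profile.subnet_rates.items():
                        row[f"subnet:{s}"] = v
                if "node" in config.levels:
                    for nid, v in zip(profile.node_ids, profile.node_rates):
                        row[f"node:{nid}"] = v
                if scan.motion is not None:
                    row["mean_fd"] = mean_fd(scan.motion)
                outcome_rows.append(row)
                timings["switching"] += time.time() - t0
            except Exception as exc:
                raise PipelineError(stage, f"{sid}/{scan_name}", exc)
        extras["connect"]["layer_counts"] = layer_counts
        extras["partition"]["seeds"] = scan_seeds
        extras["switching"]["n_scans"] = len(outcome_rows)

        t0 = time.time()
        outcomes = pd.DataFrame(outcome_rows).set_index(["subject_id", "scan"])
        subjects = table.drop(
            columns=[c for c in table.columns if c.startswith(("scan_", "motion_"))]
        )
        if "mean_fd" not in subjects.columns and "mean_fd" in outcomes.columns:
            subjects = subjects.join(
                outcomes.xs("pre", level="scan")["mean_fd"].rename("mean_fd")
            )
        value_cols = [c for c in outcomes.columns if c != "mean_fd"]
        cohort = Cohort(subjects=subjects, outcomes=outcomes[value_cols])
        results = []
        for level in config.levels:
            results.append(run_study_stats(cohort, level))
        all_results = pd.concat(results, ignore_index=True)
        all_results.to_csv(out / "stats.csv", index=False, float_format="%.12g")
        timings["stats"] = time.time() - t0
        extras["stats"]["n_tests"] = len(all_results)

        manifest["stages"] = [
            {"name": name, "seconds": round(timings[name], 3), **extras[name]}
            for name in ("simulate", "connect", "partition", "switching", "stats")
        ]
    except PipelineError:
        failed_marker.write_text("see manifest.json\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise
    except Exception as exc:
        failed_marker.write_text(f"{exc}\n")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "netswitch": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
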