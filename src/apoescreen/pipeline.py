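"""End-to-end orchestration: simulate → consensus → shape-combine →
intersect → interactions → flip/trajectory, with machine-readable reports.

Every stage writes plain TSV/JSON under the output directory; the run report
echoes the exact configuration, so identical config + seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .consensus import (
    build_consensus_table,
    combine_shape_queries,
    consensus_frame,
    correlation_diagnostics,
    enrichment,
    intersect_hitlists,
    kd_triage,
    HitList,
)
from .geometry import classify_flip, flip_fraction, protein_axis, rmsd_series
from .interactions import build_checklist, persistence_profile
from .io import write_kd_table, write_pdb, write_score_table
from .synthetic import (
    PoseSpec,
    ScreenSpec,
    TrajectorySpec,
    build_pose_complex,
    build_trp_residue,
    gen_flip_trajectory,
    gen_screen,
)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "RunReport", "run_pipeline"]

STAGES = ("simulate", "consensus", "shape-combine", "intersect", "interactions", "traj")


class ConfigError(ValueError):
    """Configuration schema violation (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 1); names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "apoescreen-run"
    # synthetic screen conditions
    n_decoys: int = 1250
    n_actives: int = 8
    holo_coupling: float = 0.95
    free_coupling: float = -0.65
    kd_range_um: tuple[float, float] = (1.0, 1000.0)
    detection_floor_um: float = 5.0
    noise_sd: float = 0.25
    # category map may override/extend the synthetic one for external scores
    categories: dict[str, str] = field(default_factory=dict)
    # thresholds
    kd_activity_um: float = 30.0
    top_n: int = 25
    flip_threshold_deg: float = 45.0
    hbond_d_max: float = 3.5
    pistack_d_max: float = 5.5
    pistack_angle_max: float = 30.0
    occupancy_cutoff: float = 4.5
    correlation_method: str = "spearman"
    n_frames: int = 1000
    frame_interval_ns: float = 0.1

    def validate(self) -> None:
        from .consensus import CATEGORIES

        if self.correlation_method not in {"pearson", "spearman", "kendall"}:
            raise ConfigError(f"unknown correlation_method {self.correlation_method!r}")
        for sid, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise ConfigError(
                    f"category map: unknown category {cat!r} for structure {sid!r}")
        for name in ("kd_activity_um", "flip_threshold_deg", "hbond_d_max",
                     "pistack_d_max", "occupancy_cutoff", "frame_interval_ns"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "kd_range_um" in raw:
            raw["kd_range_um"] = tuple(raw["kd_range_um"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def screen_spec(self) -> ScreenSpec:
        return ScreenSpec(
            seed=self.seed,
            n_decoys=self.n_decoys,
            n_actives=self.n_actives,
            holo_coupling=self.holo_coupling,
            free_coupling=self.free_coupling,
            kd_range_um=self.kd_range_um,
            detection_floor_um=self.detection_floor_um,
            noise_sd=self.noise_sd,
        )


@dataclass
class RunReport:
    version: str
    config: dict[str, Any]
    seed: int
    stages: dict[str, dict[str, Any]]
    wall_time_s: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run all stages on synthetic inputs and write outputs under ``out_dir``.

    Raises :class:`ConfigError` on schema problems and :class:`StageError`
    (naming the stage) if a stage fails.
    """
    config.validate()
    t0 = time.perf_counter()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict[str, Any]] = {}

    def run_stage(name, fn):
        try:
            stages[name] = fn()
        except (ConfigError,):
            raise
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    state: dict[str, Any] = {}

    def simulate():
        screen = gen_screen(config.screen_spec())
        unknown = set(config.categories) - set(screen.matrix.values.columns)
        if unknown:
            raise ConfigError(
                f"category map names unknown structure ids: {sorted(unknown)}")
        state["screen"] = screen
        write_score_table(screen.matrix, out / "scores.tsv")
        write_kd_table(screen.kd, out / "kd.tsv")
        (out / "actives.txt").write_text("\n".join(screen.actives) + "\n")
        for q, table in screen.shape_tables.items():
            table.rename("score").rename_axis("ligand_id").reset_index().to_csv(
                out / f"shape_{q}.tsv", sep="\t", index=False)
        return {"outputs": ["scores.tsv", "kd.tsv", "actives.txt",
                            *(f"shape_{q}.tsv" for q in screen.shape_tables)],
                "n_ligands": len(screen.ligand_ids)}

    def consensus_stage():
        screen = state["screen"]
        entries = build_consensus_table(screen.matrix)
        state["entries"] = entries
        df = consensus_frame(entries)
        df.to_csv(out / "consensus.tsv", sep="\t", index=False)
        diag = correlation_diagnostics(screen.matrix, screen.kd,
                                       method=config.correlation_method)
        top_fraction = config.top_n / len(entries)
        enr = enrichment(entries, screen.actives, top_fraction)
        payload = {
            "per_structure_correlation": diag.per_structure,
            "consensus_correlation": diag.consensus,
            "method": diag.method,
            "kd_policy": diag.kd_policy,
            "enrichment": asdict(enr),
        }
        (out / "diagnostics.json").write_text(json.dumps(payload, indent=2, default=_jsonify))
        state["docking_hits"] = HitList(
            entries=[(e.ligand_id, -e.consensus_score)
                     for e in sorted(entries, key=lambda e: e.consensus_rank)])
        return {"outputs": ["consensus.tsv", "diagnostics.json"],
                "consensus_correlation": diag.consensus,
                "enrichment_factor": enr.enrichment_factor}

    def shape_combine():
        screen = state["screen"]
        hits = combine_shape_queries(list(screen.shape_tables.values()))
        state["shape_hits"] = hits
        with open(out / "shape_hits.tsv", "w") as fh:
            fh.write("ligand_id\tcombined_score\n")
            for lig, score in hits.entries:
                fh.write(f"{lig}\t{score:.6g}\n")
        return {"outputs": ["shape_hits.tsv"], "n_ligands": len(hits.entries)}

    def intersect():
        common = intersect_hitlists(state["docking_hits"], state["shape_hits"],
                                    n=config.top_n)
        binders = kd_triage(state["screen"].kd, config.kd_activity_um)
        (out / "common_hits.txt").write_text("\n".join(common) + "\n")
        return {"outputs": ["common_hits.txt"], "common_hits": common,
                "n_kd_binders": len(binders)}

    def interactions_stage():
        pose_spec = PoseSpec(
            hbond_requests=(("ASP35", 2.9), ("ASP153", 3.0)),
            pistack_request=(3.7, 10.0),
            occupancy_request=3,
            seed=config.seed,
        )
        pose = build_pose_complex(pose_spec)
        axis = protein_axis(pose.protein)
        flip = classify_flip(pose.protein, 34, axis,
                             threshold=config.flip_threshold_deg)
        record = build_checklist(
            pose, flip, ligand_id="toy-ligand",
            hbond_d_max=config.hbond_d_max,
            occupancy_cutoff=config.occupancy_cutoff,
        )
        from .io import write_interaction_table
        write_interaction_table([record], out / "checklist.tsv")
        write_pdb(pose.protein, out / "pose_protein.pdb")
        write_pdb(pose.ligand, out / "pose_ligand.pdb")
        return {"outputs": ["checklist.tsv", "pose_protein.pdb", "pose_ligand.pdb"],
                "all_key_interactions": record.all_key_interactions,
                "trp34_orientation": record.trp34_orientation}

    def traj_stage():
        spec = TrajectorySpec(seed=config.seed, n_frames=config.n_frames,
                              frame_interval_ns=config.frame_interval_ns)
        traj = gen_flip_trajectory(spec)
        frac = flip_fraction(traj.series)
        # RMSD observable: jittered copies of the trajectory's first residue
        rng = np.random.default_rng(config.seed + 1)
        base = traj.residue(0)
        names = sorted(base)
        ref = np.array([base[n] for n in names])
        n_rmsd = min(config.n_frames, 200)
        lig_frames, bb_frames = [], []
        for _ in range(n_rmsd):
            jitter = rng.normal(0.0, 0.3, size=ref.shape)
            frame = ref + jitter
            lig_frames.append(frame)
            bb_frames.append(frame)
        rmsd = rmsd_series(lig_frames, bb_frames,
                           time_ns=np.arange(n_rmsd) * config.frame_interval_ns)
        with open(out / "trajectory.tsv", "w") as fh:
            fh.write("frame\ttime_ns\tchi1_deg\tchi2_deg\tstate\n")
            s = traj.series
            for i in range(len(s)):
                fh.write(f"{i}\t{s.time_ns[i]:.4f}\t{s.chi1_deg[i]:.2f}\t"
                         f"{s.chi2_deg[i]:.2f}\t{s.state[i]}\n")
        with open(out / "rmsd.tsv", "w") as fh:
            fh.write("time_ns\tligand_rmsd_A\tbackbone_rmsd_A\n")
            for t, lr, br in zip(rmsd.time_ns, rmsd.ligand_rmsd_A, rmsd.backbone_rmsd_A):
                fh.write(f"{t:.4f}\t{lr:.4f}\t{br:.4f}\n")
        return {"outputs": ["trajectory.tsv", "rmsd.tsv"],
                "flip_in_fraction": frac,
                "mean_ligand_rmsd_A": float(rmsd.ligand_rmsd_A.mean())}

    run_stage("simulate", simulate)
    run_stage("consensus", consensus_stage)
    run_stage("shape-combine", shape_combine)
    run_stage("intersect", intersect)
    run_stage("interactions", interactions_stage)
    run_stage("traj", traj_stage)

    report = RunReport(
        version=__version__,
        config=asdict(config),
        seed=config.seed,
        stages=stages,
        wall_time_s=time.perf_counter() - t0,
    )
    (out / "report.json").write_text(report.to_json())
    return report
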