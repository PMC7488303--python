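"""End-to-end simulation pipeline and its configuration.

Stages: build the structure library (coarse-grained PDB structures and/or
synthetic fixtures, plus optional filament and membrane) -> place copies
at random in the box -> pack under the force field -> extract per-structure
poses -> render the density map -> add noise at each requested SNR ->
optionally run DoG picking against the emitted ground truth.  Every run
writes its artifacts plus an echo of the resolved configuration, so a run
is reproducible from the echoed config and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import mrcio
from .dynamics import ForceFieldParams, Scene, Trajectory, place_structures, run_packing
from .fixtures import fixture_structure_library
from .groundtruth import GroundTruthEntry, write_truth
from .picking import match_picks, pick_volume
from .pose import Pose, extract_pose
from .structures import Structure, coarse_grain, parse_pdb_atoms
from .volume import (
    DEFAULT_RESOLUTION,
    DEFAULT_VOXEL_SIZE,
    NoiseParams,
    add_noise,
    compose_scene_map,
)

__all__ = ["RunConfig", "run_pipeline", "extract_scene_poses", "build_ground_truth"]


@dataclass
class RunConfig:
    """Serializable description of one simulation run."""

    # structure sources: real PDB files and/or the synthetic fixture library
    pdb_paths: list[str] = field(default_factory=list)
    fixture_rigid: int = 5
    fixture_atoms: int = 12000
    fixture_extent: float = 140.0
    include_filament: bool = False
    include_membrane: bool = False
    copies_per_type: int = 1
    # scene and packing
    box: tuple[float, float, float] = (500.0, 500.0, 500.0)
    max_steps: int = 2000
    snapshot_every: int = 200
    force_field: dict = field(default_factory=dict)
    # rendering
    render: bool = True
    voxel_size: float = DEFAULT_VOXEL_SIZE
    resolution: float = DEFAULT_RESOLUTION
    snr: list[float] = field(default_factory=lambda: [1000.0, 200.0])
    # picking (None disables)
    pick_sigma1: list[float] | None = None
    pick_ratio: float = 1.1
    pick_t: float = 5.0
    pick_top_k: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.box = tuple(float(b) for b in self.box)  # type: ignore[assignment]
        self.snr = [float(s) for s in self.snr]
        if self.pick_sigma1 is not None:
            self.pick_sigma1 = [float(s) for s in self.pick_sigma1]

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["box"] = list(data["box"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def extract_scene_poses(scene: Scene) -> list[Pose]:
    """Initial-to-final pose of every structure in a packed scene."""
    return [
        extract_pose(
            scene.structure_positions(i, initial=True),
            scene.structure_positions(i),
            deformable=s.deformable,
        )
        for i, s in enumerate(scene.structures)
    ]


def build_ground_truth(scene: Scene, poses: list[Pose]) -> list[GroundTruthEntry]:
    """Ground-truth rows; deformables carry zero Euler angles."""
    entries = []
    for i, (s, pose) in enumerate(zip(scene.structures, poses)):
        euler = (0.0, 0.0, 0.0) if s.deformable else tuple(
            float(np.degrees(a)) for a in pose.euler_zyz
        )
        entries.append(
            GroundTruthEntry(
                label=s.label or f"structure{i}",
                kind=s.kind,
                centroid=pose.centroid_final,
                displacement=pose.displacement,
                euler_deg=euler,  # type: ignore[arg-type]
                bounding_radius=s.bounding_radius(
                    centers=scene.structure_positions(i)
                ),
            )
        )
    return entries


def _build_library(config: RunConfig) -> list[Structure]:
    lib: list[Structure] = []
    for p in config.pdb_paths:
        cloud = parse_pdb_atoms(Path(p).read_text(), source_id=Path(p).stem)
        lib.append(coarse_grain(cloud, seed=config.seed))
    if config.fixture_rigid or config.include_filament or config.include_membrane:
        lib.extend(
            fixture_structure_library(
                n_rigid=config.fixture_rigid,
                n_atoms=config.fixture_atoms,
                extent=config.fixture_extent,
                seed=config.seed,
                include_filament=config.include_filament,
                include_membrane=config.include_membrane,
            )
        )
    if not lib:
        raise ValueError("no structure sources configured")
    return lib


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full simulation; returns the run directory.

    Artifacts: ``config.yaml`` (echo), ``scene.xyz`` (trajectory),
    ``truth.csv``/``truth.json``, ``clean.mrc``, ``tomo_snr<X>.mrc`` per
    SNR, ``picking.json`` when picking is enabled, and ``log.txt``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, **info) -> None:
        log_lines.append(" ".join([stage] + [f"{k}={v}" for k, v in info.items()]))

    try:
        library = _build_library(config)
        log("library", n_types=len(library),
            balls=sum(s.n_balls for s in library))

        params = ForceFieldParams(**config.force_field)
        scene = place_structures(
            library, [config.copies_per_type] * len(library),
            box=config.box, seed=config.seed,
        )
        log("place", structures=len(scene.structures), balls=scene.n_balls)

        traj = run_packing(scene, params, max_steps=config.max_steps,
                           snapshot_every=config.snapshot_every)
        log("pack", steps=traj.frames[-1][0], frames=len(traj.frames))
        traj.write_xyz(out / "scene.xyz")

        poses = extract_scene_poses(scene)
        truth = build_ground_truth(scene, poses)
        write_truth(truth, csv_path=out / "truth.csv", json_path=out / "truth.json")
        log("pose", entries=len(truth))

        if not config.render:
            config.to_yaml(out / "config.yaml")
            (out / "log.txt").write_text("\n".join(log_lines) + "\n")
            return out

        clean = compose_scene_map(scene, poses, voxel_size=config.voxel_size,
                                  resolution=config.resolution)
        mrcio.write_mrc(clean, out / "clean.mrc")
        log("render", shape="x".join(map(str, clean.shape)))

        noisy_volumes = {}
        for i, snr in enumerate(config.snr):
            vol = add_noise(clean, NoiseParams(snr=snr, seed=config.seed + 1 + i))
            name = f"tomo_snr{snr:g}.mrc"
            mrcio.write_mrc(vol, out / name)
            noisy_volumes[snr] = vol
            log("noise", snr=snr, file=name)

        if config.pick_sigma1:
            report = {}
            centers = np.array([t.centroid for t in truth])
            radii = np.array([t.bounding_radius for t in truth])
            target = noisy_volumes[config.snr[0]] if config.snr else clean
            for sigma1 in config.pick_sigma1:
                res = pick_volume(
                    target, sigma1, ratio=config.pick_ratio, t=config.pick_t,
                    top_k=len(truth) if config.pick_top_k else None,
                )
                peaks_world = target.voxel_centers_world(res.peaks)
                score = match_picks(peaks_world, centers, radii)
                report[f"sigma1={sigma1:g}"] = {
                    **score.as_dict(),
                    "n_peaks": int(len(res.peaks)),
                    "peaks": peaks_world.tolist(),
                }
                log("pick", sigma1=sigma1, fscore=round(score.fscore, 4))
            with open(out / "picking.json", "w") as fh:
                json.dump(report, fh, indent=1)
    except Exception as exc:
        stage = log_lines[-1].split()[0] if log_lines else "library"
        (out / "log.txt").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out
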