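"""End-to-end analysis pipeline: annotate → cluster → encode → FES →
mechanism, driven by a single declarative configuration.

Every stage reads its inputs from, and writes its outputs to, the run
directory, so running the stages one at a time (as the command-line
interface does) produces byte-identical artifacts to the monolithic
:func:`run_pipeline` call.  All randomness flows from the single config
seed; every JSON artifact carries the config hash and package version.

Output units are stated in column headers: nm for distances, ns for
times, kJ/mol for free energies, degrees for angles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotators import (
    HBondCriteria,
    HBondDefinition,
    TurnDefinition,
    assign_secondary_structure,
    hbond_tracks,
    residue_propensities,
    turn_track,
)
from .clustering import cluster_daura, representative_structure
from .landscape import (
    BasinLabeling,
    BasinRegion,
    StateCodingScheme,
    build_fes,
    label_basins,
    encode_states,
    regions_around_minima,
)
from .mechanism import (
    MechanismReport,
    conditional_hbond_given_no_turn,
    default_path_catalog,
    enumerate_transition_paths,
    occurrence_table,
)
from .model_io import (
    AnnotationTrack,
    HairpinPathError,
    read_bool_tracks,
    read_ss_assignment,
    read_trajectory,
    write_bool_tracks,
    write_ss_assignment,
    write_trajectory,
)
from .superposition import export_rmsd_series_csv, pairwise_rmsd_matrix, rmsd_series
from .synthetic import (
    CONDITION_HBONDS,
    CONDITION_TURNS,
    MechanismScript,
    alpha_syn12_topology,
    generate_transition_trajectory,
)

logger = logging.getLogger("hairpinpath")


class ConfigError(HairpinPathError):
    pass


@dataclass
class PipelineConfig:
    """Declarative description of one analysis run.

    ``condition`` selects the default turn/H-bond definitions
    (physiological → Turn_9-6 with HB_9-6, HB_6-9, HB_11-4, HB_4-11;
    acidic → Turn_8-5 with HB_8-5, HB_5-8, HB_10-3, HB_3-10, HB_12-1);
    explicit ``turn``/``hbonds`` labels override them.  Either a
    trajectory file or a synthetic-simulation block must be given.
    """

    condition: str = "physiological"
    trajectory: str | None = None
    trajectory_dialect: str = "frame-array"
    simulate_mode: str | None = None  # turn_first | hbond_first | two_path
    n_frames: int = 5000
    seed: int = 0
    noise_sigma: float | None = None
    turn: str | None = None
    hbonds: list[str] | None = None
    hbond_max_distance: float = 0.25
    hbond_min_angle: float = 135.0
    cluster_cutoff: float = 0.1
    cluster_max_frames: int = 2000
    fes_bin_width: float = 0.01
    temperature: float = 300.0
    basin_regions: list[dict] | None = None
    path_catalog: list[list[str]] | None = None
    output_dir: str = "hairpinpath_out"

    def __post_init__(self):
        if self.condition not in CONDITION_TURNS and self.turn is None:
            raise ConfigError(
                f"unknown condition {self.condition!r} and no explicit turn"
            )
        if self.trajectory is None and self.simulate_mode is None:
            raise ConfigError("need either a trajectory path or simulate_mode")
        if self.fes_bin_width <= 0:
            raise ConfigError("fes_bin_width must be positive")
        if self.cluster_cutoff <= 0:
            raise ConfigError("cluster_cutoff must be positive")
        # Overlap errors surface at validation time, before any compute.
        self.basin_labeling()

    # -- derived objects --------------------------------------------------

    @property
    def turn_definition(self) -> TurnDefinition:
        if self.turn is not None:
            return TurnDefinition.from_label(self.turn)
        return CONDITION_TURNS[self.condition]

    @property
    def hbond_definitions(self) -> tuple[HBondDefinition, ...]:
        if self.hbonds is not None:
            return tuple(HBondDefinition.from_label(h) for h in self.hbonds)
        return CONDITION_HBONDS[self.condition]

    @property
    def criteria(self) -> HBondCriteria:
        return HBondCriteria(self.hbond_max_distance, self.hbond_min_angle)

    def basin_labeling(self) -> BasinLabeling | None:
        if self.basin_regions is None:
            return None
        return BasinLabeling(
            [
                BasinRegion(
                    r["name"], float(r["x_min"]), float(r["x_max"]),
                    tuple(int(y) for y in r["y_levels"]),
                )
                for r in self.basin_regions
            ]
        )

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.trajectory is not None and not Path(cfg.trajectory).exists():
            raise ConfigError(f"trajectory file not found: {cfg.trajectory}")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash, "version": __version__}


def _out(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _log_stage(name: str, t0: float, n_frames: int) -> None:
    logger.info(
        "stage %-10s done in %.2f s (%d frames)", name, time.time() - t0,
        n_frames,
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_simulate(config: PipelineConfig):
    """Generate the synthetic trajectory and write it (plus ground truth)
    into the run directory."""
    t0 = time.time()
    out = _out(config)
    factory = {
        "turn_first": MechanismScript.turn_first,
        "hbond_first": MechanismScript.hbond_first,
        "two_path": MechanismScript.two_path,
    }
    if config.simulate_mode not in factory:
        raise ConfigError(f"unknown simulate mode {config.simulate_mode!r}")
    kwargs = {}
    if config.noise_sigma is not None:
        kwargs["noise_sigma"] = config.noise_sigma
    script = factory[config.simulate_mode](
        n_frames=config.n_frames, seed=config.seed,
        condition=config.condition, **kwargs,
    )
    synth = generate_transition_trajectory(script)
    write_trajectory(synth.frames, out / "trajectory.dat", "frame-array")
    write_bool_tracks(
        [synth.turn_track, *synth.hbond_tracks], out / "truth_tracks.csv"
    )
    pd.DataFrame({"frame": np.arange(len(synth.basin_labels)),
                  "basin": synth.basin_labels}).to_csv(
        out / "truth_basins.csv", index=False
    )
    with open(out / "script.json", "w") as fh:
        json.dump(
            {
                "mode": script.mode,
                "seed": script.seed,
                "noise_sigma_nm": script.noise_sigma,
                "n_frames": script.n_frames,
                "path_mixture": list(script.path_mixture),
                "basin_regions": [
                    dataclasses.asdict(r) for r in synth.regions.regions
                ],
                **_provenance(config),
            },
            fh,
            indent=2,
        )
    _log_stage("simulate", t0, synth.frames.n_frames)
    return synth


def _load_frames(config: PipelineConfig):
    topo = alpha_syn12_topology(
        config.condition if config.condition in CONDITION_TURNS else "custom"
    )
    out = _out(config)
    path = config.trajectory or out / "trajectory.dat"
    return read_trajectory(path, topo, config.trajectory_dialect)


def stage_annotate(config: PipelineConfig):
    """Secondary structure, turn and H-bond tracks, residue propensities."""
    t0 = time.time()
    out = _out(config)
    frames = _load_frames(config)
    codes = assign_secondary_structure(frames, criteria=config.criteria)
    ss_tracks = [
        AnnotationTrack(f"ss_res_{r + 1}", codes[:, r])
        for r in range(codes.shape[1])
    ]
    write_ss_assignment(ss_tracks, out / "ss_tracks.csv")
    residue_propensities(codes).to_csv(out / "propensities.csv", index=False)
    turn = turn_track(frames, config.turn_definition)
    bonds = hbond_tracks(
        frames, list(config.hbond_definitions), config.criteria
    )
    write_bool_tracks([turn, *bonds], out / "tracks.csv")
    _log_stage("annotate", t0, frames.n_frames)
    return frames, turn, bonds, codes


def stage_cluster(config: PipelineConfig):
    """Daura clustering; writes the cluster table, the most clustered
    structure (PDB), and the RMSD series against it."""
    t0 = time.time()
    out = _out(config)
    frames = _load_frames(config)
    n = frames.n_frames
    if n > config.cluster_max_frames:
        # Even stride subsample for the pairwise matrix; deterministic.
        pick = np.linspace(0, n - 1, config.cluster_max_frames).astype(int)
    else:
        pick = np.arange(n)
    sub = frames.with_frames(pick)
    matrix = pairwise_rmsd_matrix(sub)
    result = cluster_daura(matrix, config.cluster_cutoff)
    table = result.to_frame(sub.times)
    table["center_frame"] = pick[table["center_frame"]]
    table.to_csv(out / "clusters.csv", index=False)
    center = representative_structure(sub, result, 1)
    ref_set = frames.with_frames([pick[result.centers[0]]])
    write_trajectory(ref_set, out / "most_clustered.pdb", "multi-model-pdb")
    series = rmsd_series(frames, center)
    export_rmsd_series_csv(frames.times, series, out / "rmsd_series.csv")
    _log_stage("cluster", t0, n)
    return result, center, series


def stage_fes(config: PipelineConfig):
    """State encoding and free-energy surface from the annotate/cluster
    artifacts."""
    t0 = time.time()
    out = _out(config)
    tracks = {t.name: t for t in read_bool_tracks(out / "tracks.csv")}
    turn_def = config.turn_definition
    bonds = config.hbond_definitions
    scheme = StateCodingScheme(turn_def, tuple(bonds))
    series = pd.read_csv(out / "rmsd_series.csv")["rmsd_nm"].to_numpy()
    states = encode_states(
        tracks[turn_def.label], [tracks[b.label] for b in bonds],
        series, scheme,
    )
    fes = build_fes(states, config.fes_bin_width, config.temperature)
    fes.to_frame().to_csv(out / "fes.csv", index=False)
    pd.DataFrame(
        fes.minima, columns=["x_nm", "y_level", "depth_kJ_per_mol"]
    ).to_csv(out / "minima.csv", index=False)
    pd.DataFrame(
        {"frame": np.arange(len(states)), "rmsd_nm": states.rmsd,
         "ycode": states.ycode}
    ).to_csv(out / "states.csv", index=False)
    _log_stage("fes", t0, len(states))
    return states, fes


def _resolve_regions(config: PipelineConfig, fes) -> BasinLabeling:
    regions = config.basin_labeling()
    if regions is not None:
        return regions
    out = _out(config)
    script_file = out / "script.json"
    if script_file.exists():
        with open(script_file) as fh:
            meta = json.load(fh)
        return BasinLabeling(
            [
                BasinRegion(
                    r["name"], r["x_min"], r["x_max"],
                    tuple(r["y_levels"]),
                )
                for r in meta["basin_regions"]
            ]
        )
    # Fall back to rectangles around the deepest minima; the folded basin
    # is the one nearest the reference structure (smallest x).
    minima = sorted(fes.minima, key=lambda m: m[2])[:3]
    by_x = sorted(minima, key=lambda m: m[0])
    names = {}
    names[by_x[0]] = "F"
    for k, m in enumerate(m for m in minima if m != by_x[0]):
        names[m] = f"U{k + 1}"
    ordered = sorted(names.items(), key=lambda kv: kv[1])
    return regions_around_minima(
        [m for m, _n in ordered], [n for _m, n in ordered]
    )


def stage_mechanism(config: PipelineConfig):
    """Occurrences, conditionals, transition paths, combined report."""
    t0 = time.time()
    out = _out(config)
    tracks = {t.name: t for t in read_bool_tracks(out / "tracks.csv")}
    turn_def = config.turn_definition
    bonds = config.hbond_definitions
    turn = tracks[turn_def.label]
    hb = [tracks[b.label] for b in bonds]

    occ = occurrence_table([turn, *hb])
    occ.to_csv(out / "occurrences.csv", index=False)
    cond = conditional_hbond_given_no_turn([turn], hb)
    cond.table.to_csv(out / "conditionals.csv", index=False)

    states_df = pd.read_csv(out / "states.csv")
    minima = pd.read_csv(out / "minima.csv").to_numpy().tolist()
    from .landscape import StateSeries

    states = StateSeries(
        states_df["rmsd_nm"].to_numpy(), states_df["ycode"].to_numpy()
    )
    fes_stub = type("fes", (), {"minima": [tuple(m) for m in minima]})
    regions = _resolve_regions(config, fes_stub)
    labels = label_basins(states, regions)
    unfolded = [n for n in regions.names if n != "F"]
    catalog = (
        [tuple(p) for p in config.path_catalog]
        if config.path_catalog
        else default_path_catalog(unfolded, "F")
        if len(unfolded) >= 2
        else [(u, "F") for u in unfolded]
    )
    paths = enumerate_transition_paths(labels, unfolded, "F", catalog)
    paths.table.to_csv(out / "paths.csv", index=False)

    cluster_pops = []
    cl_file = out / "clusters.csv"
    if cl_file.exists():
        cluster_pops = pd.read_csv(cl_file)["population"].tolist()

    report = MechanismReport(
        condition=config.condition,
        occurrences=occ,
        conditionals=cond,
        paths=paths,
        minima=[tuple(m) for m in minima],
        cluster_populations=cluster_pops,
    )
    with open(out / "report.json", "w") as fh:
        json.dump({**report.to_dict(), **_provenance(config)}, fh, indent=2)
    _log_stage("mechanism", t0, len(states_df))
    return report


def run_pipeline(config: PipelineConfig) -> MechanismReport:
    """Execute all stages in order and return the combined report.

    Stage errors abort the run, naming the failing stage.
    """
    stages = []
    if config.simulate_mode is not None and config.trajectory is None:
        stages.append(("simulate", stage_simulate))
    stages += [
        ("annotate", stage_annotate),
        ("cluster", stage_cluster),
        ("fes", stage_fes),
        ("mechanism", stage_mechanism),
    ]
    result = None
    for name, fn in stages:
        try:
            result = fn(config)
        except HairpinPathError as e:
            raise HairpinPathError(f"stage {name!r} failed: {e}") from e
    return result
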