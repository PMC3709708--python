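"""Peptide/trajectory data model and file formats.

Containers
----------
:class:`PeptideTopology`
    Atom and residue bookkeeping for a linear peptide backbone
    (N, H, CA, C, O per residue; residue 1 carries no amide hydrogen).
:class:`TrajectoryFrameSet`
    Ordered Cartesian snapshots (nm) with timestamps (ns).
:class:`AnnotationTrack`
    Per-frame boolean or categorical labels.

Formats
-------
PDB (single and multi-model) is read and written through biotite; the PDB
boundary is the only place Angstrom/nm conversion happens.  Two plain-text
dialects are native:

``frame-array``
    One row of ``3 * n_atoms`` floats per frame, ``%.17g`` precision (so
    float64 round-trips bit-exactly), with a small ``#``-comment header
    carrying atom/frame counts and optional timestamps.

``csv-track``
    ``frame,residue,code`` for secondary-structure assignments and
    ``frame,track,value`` for boolean tracks.

Externally computed STRIDE and DSSP per-residue reports are parsed into
categorical tracks with the reduced alphabet {H, E, T, C}.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from . import geometry

ALPHA_SYN12_SEQUENCE = "MDVFMKGLSKAK"

BACKBONE_ATOMS = ("N", "H", "CA", "C", "O")

PROTONATION_LABELS = ("physiological", "acidic", "alkaline", "custom")

DEFAULT_FRAME_SPACING_NS = 0.05

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA_1TO3 = {v: k for k, v in _AA_3TO1.items()}


class HairpinPathError(Exception):
    """Base class for package errors."""


class StructureError(HairpinPathError):
    pass


class TrajectoryError(HairpinPathError):
    pass


class TrackError(HairpinPathError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the peptide; ``residue_index`` is 1-based."""

    name: str
    element: str
    residue_index: int
    backbone: bool = True
    reconstructed: bool = False


@dataclass
class PeptideTopology:
    residue_names: list[str]
    atom_records: list[AtomRecord]
    protonation_label: str = "custom"

    def __post_init__(self):
        if self.protonation_label not in PROTONATION_LABELS:
            raise StructureError(
                f"unknown protonation label {self.protonation_label!r}"
            )
        n_res = len(self.residue_names)
        if n_res < 4:
            raise StructureError(
                f"need at least 4 residues for turn analysis, got {n_res}"
            )
        seen = set()
        for rec in self.atom_records:
            if not (1 <= rec.residue_index <= n_res):
                raise StructureError(
                    f"atom {rec.name} has residue index {rec.residue_index} "
                    f"outside 1..{n_res}"
                )
            key = (rec.residue_index, rec.name)
            if key in seen:
                raise StructureError(f"duplicate atom {rec.name} in residue "
                                     f"{rec.residue_index}")
            seen.add(key)
        for i in range(2, n_res + 1):
            if (i, "H") not in seen:
                raise StructureError(
                    f"residue {i} ({self.residue_names[i - 1]}) lacks an "
                    f"amide H record"
                )
        self._index = {
            (rec.residue_index, rec.name): k
            for k, rec in enumerate(self.atom_records)
        }

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_sequence(
        cls, sequence: str, protonation_label: str = "custom"
    ) -> "PeptideTopology":
        """Backbone-only topology for a 1-letter sequence."""
        res_names = []
        records = []
        for i, aa in enumerate(sequence, start=1):
            try:
                res_names.append(_AA_1TO3[aa.upper()])
            except KeyError:
                raise StructureError(f"unknown residue code {aa!r}") from None
            for name in BACKBONE_ATOMS:
                if name == "H" and i == 1:
                    continue
                records.append(AtomRecord(name, name[0], i))
        return cls(res_names, records, protonation_label)

    # -- queries ----------------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_records)

    @property
    def sequence(self) -> str:
        return "".join(_AA_3TO1.get(r, "X") for r in self.residue_names)

    def atom_index(self, residue_index: int, name: str) -> int:
        """0-based position of atom ``name`` of 1-based residue."""
        try:
            return self._index[(residue_index, name)]
        except KeyError:
            raise StructureError(
                f"no atom {name} in residue {residue_index}"
            ) from None

    def has_atom(self, residue_index: int, name: str) -> bool:
        return (residue_index, name) in self._index

    @property
    def ca_indices(self) -> np.ndarray:
        return np.array(
            [self.atom_index(i, "CA") for i in range(1, self.n_residues + 1)]
        )

    def backbone_index_map(self) -> dict[str, np.ndarray]:
        """Per-atom-kind index arrays of length R; -1 where absent."""
        out = {}
        for name in BACKBONE_ATOMS:
            out[name] = np.array(
                [
                    self._index.get((i, name), -1)
                    for i in range(1, self.n_residues + 1)
                ]
            )
        return out


@dataclass
class TrajectoryFrameSet:
    topology: PeptideTopology
    coordinates: np.ndarray  # (frames, atoms, 3), nm
    times: np.ndarray  # (frames,), ns
    source_label: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError(
                f"coordinates must be (frames, atoms, 3), got "
                f"{self.coordinates.shape}"
            )
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"coordinate atom count {self.coordinates.shape[1]} does not "
                f"match topology ({self.topology.n_atoms} atoms)"
            )
        if self.times.shape != (self.coordinates.shape[0],):
            raise TrajectoryError("times length must equal frame count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("times must be strictly increasing")
        if np.isnan(self.coordinates).any():
            raise TrajectoryError("coordinates contain NaN")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coordinates[i]

    def backbone_arrays(self) -> dict[str, np.ndarray]:
        """(F, R, 3) arrays per backbone atom kind; NaN where absent
        (residue 1 has no amide H)."""
        idx = self.topology.backbone_index_map()
        out = {}
        for name, ind in idx.items():
            arr = np.full(
                (self.n_frames, self.topology.n_residues, 3), np.nan
            )
            present = ind >= 0
            arr[:, present] = self.coordinates[:, ind[present]]
            out[name] = arr
        return out

    def with_frames(self, frame_indices) -> "TrajectoryFrameSet":
        frame_indices = np.asarray(frame_indices)
        return replace(
            self,
            coordinates=self.coordinates[frame_indices],
            times=self.times[frame_indices],
        )


@dataclass
class AnnotationTrack:
    name: str
    values: np.ndarray
    frame_count: int = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.frame_count is None:
            self.frame_count = len(self.values)
        if len(self.values) != self.frame_count:
            raise TrackError(
                f"track {self.name}: {len(self.values)} values for "
                f"{self.frame_count} frames"
            )

    @property
    def is_boolean(self) -> bool:
        return self.values.dtype == bool

    def mean(self) -> float:
        if not self.is_boolean:
            raise TrackError(f"track {self.name} is not boolean")
        return float(np.mean(self.values))


def frameset_from_backbone(
    topology: PeptideTopology,
    backbone: dict[str, np.ndarray],
    times: np.ndarray | None = None,
    source_label: str = "",
) -> TrajectoryFrameSet:
    """Assemble a frame set from per-kind backbone arrays (F, R, 3)."""
    any_arr = next(iter(backbone.values()))
    if any_arr.ndim == 2:
        backbone = {k: v[None] for k, v in backbone.items()}
        any_arr = backbone["CA"]
    n_frames = any_arr.shape[0]
    coords = np.empty((n_frames, topology.n_atoms, 3))
    idx = topology.backbone_index_map()
    for name, ind in idx.items():
        present = ind >= 0
        coords[:, ind[present]] = backbone[name][:, present]
    if times is None:
        times = np.arange(n_frames) * DEFAULT_FRAME_SPACING_NS
    return TrajectoryFrameSet(topology, coords, times, source_label)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------


def _topology_from_atom_array(atoms: struc.AtomArray) -> tuple[
    PeptideTopology, np.ndarray, list[int]
]:
    """Build a topology from one biotite model.

    Returns (topology, coordinates_nm (A, 3), file_atom_order) where
    file_atom_order maps our atom order to indices into ``atoms`` (-1 for
    reconstructed hydrogens).
    """
    res_ids = np.unique(atoms.res_id)
    if res_ids.size == 0:
        raise StructureError("no residues found in structure")
    res_names = []
    records: list[AtomRecord] = []
    order: list[int] = []
    missing: list[str] = []
    for new_id, rid in enumerate(res_ids, start=1):
        mask = atoms.res_id == rid
        sub_idx = np.flatnonzero(mask)
        names = atoms.atom_name[sub_idx]
        res_names.append(str(atoms.res_name[sub_idx[0]]))
        by_name = {}
        for k, n in zip(sub_idx, names):
            by_name.setdefault(str(n), int(k))
        for bb in ("N", "CA", "C", "O"):
            if bb not in by_name:
                missing.append(f"residue {new_id} ({res_names[-1]}): {bb}")
        for bb in BACKBONE_ATOMS:
            if bb == "H" and new_id == 1:
                continue
            if bb in by_name:
                records.append(AtomRecord(bb, bb[0], new_id))
                order.append(by_name[bb])
            elif bb == "H":
                records.append(AtomRecord("H", "H", new_id,
                                          reconstructed=True))
                order.append(-1)
        for name in map(str, names):
            if name not in BACKBONE_ATOMS:
                records.append(AtomRecord(
                    name, str(atoms.element[by_name[name]]) or name[0],
                    new_id, backbone=False,
                ))
                order.append(by_name[name])
    if missing:
        raise StructureError(
            "missing backbone atoms: " + "; ".join(missing)
        )
    topo = PeptideTopology(res_names, records)
    coords = np.zeros((topo.n_atoms, 3))
    order_arr = np.asarray(order)
    present = order_arr >= 0
    coords[present] = atoms.coord[order_arr[present]] / 10.0  # A -> nm
    if not present.all():
        bb = {
            k: np.full((topo.n_residues, 3), np.nan)
            for k in ("N", "CA", "C")
        }
        idx = topo.backbone_index_map()
        for k in bb:
            bb[k] = coords[idx[k]]
        H = geometry.reconstruct_amide_hydrogens(bb["N"], bb["CA"], bb["C"])
        for r in range(2, topo.n_residues + 1):
            ai = topo.atom_index(r, "H")
            if not present[ai]:
                coords[ai] = H[r - 1]
    return topo, coords, order


def read_structure(path, dialect: str = "pdb") -> tuple[
    PeptideTopology, TrajectoryFrameSet
]:
    """Read a single-structure PDB into a topology plus 1-frame set.

    Coordinates are converted from Angstrom to nm.  Amide hydrogens absent
    from the file are reconstructed geometrically and flagged on their
    :class:`AtomRecord`.  Non-backbone atoms are retained with
    ``backbone=False``.
    """
    if dialect != "pdb":
        raise ValueError(f"unknown structure dialect {dialect!r}")
    pfile = pdb.PDBFile.read(str(path))
    atoms = pfile.get_structure(model=1)
    topo, coords, _ = _topology_from_atom_array(atoms)
    frames = TrajectoryFrameSet(
        topo, coords[None], np.array([0.0]), source_label=str(path)
    )
    return topo, frames


def _atom_array_template(topology: PeptideTopology) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.full(n, "A")
    arr.res_id = np.array([r.residue_index for r in topology.atom_records])
    arr.res_name = np.array(
        [topology.residue_names[r.residue_index - 1]
         for r in topology.atom_records]
    )
    arr.atom_name = np.array([r.name for r in topology.atom_records])
    arr.element = np.array([r.element for r in topology.atom_records])
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_trajectory(
    frames: TrajectoryFrameSet, path, dialect: str = "frame-array"
) -> None:
    """Write frames in the ``frame-array`` or ``multi-model-pdb`` dialect."""
    if dialect == "frame-array":
        _write_frame_array(frames, path)
    elif dialect == "multi-model-pdb":
        template = _atom_array_template(frames.topology)
        stack = struc.AtomArrayStack(frames.n_frames, frames.topology.n_atoms)
        for annot in ("chain_id", "res_id", "res_name", "atom_name",
                      "element", "hetero"):
            stack.set_annotation(annot, getattr(template, annot))
        stack.coord = frames.coordinates * 10.0  # nm -> A
        pfile = pdb.PDBFile()
        pfile.set_structure(stack)
        pfile.write(str(path))
    else:
        raise ValueError(f"unknown trajectory dialect {dialect!r}")


def read_trajectory(
    path, topology: PeptideTopology, dialect: str = "frame-array",
    frame_spacing_ns: float = DEFAULT_FRAME_SPACING_NS,
) -> TrajectoryFrameSet:
    """Read a trajectory against a known topology.

    Times default to uniform ``frame_spacing_ns`` spacing when the file
    carries no time metadata.
    """
    if dialect == "frame-array":
        return _read_frame_array(path, topology)
    if dialect != "multi-model-pdb":
        raise ValueError(f"unknown trajectory dialect {dialect!r}")
    pfile = pdb.PDBFile.read(str(path))
    stack = pfile.get_structure()
    if stack.array_length() != topology.n_atoms:
        raise TrajectoryError(
            f"atom count mismatch: file has {stack.array_length()}, "
            f"topology has {topology.n_atoms}"
        )
    # Map file atoms onto topology order by (residue, atom name).
    order = np.empty(topology.n_atoms, dtype=int)
    lookup = {
        (int(r), str(n)): k
        for k, (r, n) in enumerate(zip(stack.res_id, stack.atom_name))
    }
    for k, rec in enumerate(topology.atom_records):
        try:
            order[k] = lookup[(rec.residue_index, rec.name)]
        except KeyError:
            raise TrajectoryError(
                f"atom {rec.name} of residue {rec.residue_index} missing "
                f"from trajectory file"
            ) from None
    coords = stack.coord[:, order] / 10.0
    times = np.arange(coords.shape[0]) * frame_spacing_ns
    return TrajectoryFrameSet(topology, coords, times, source_label=str(path))


# ---------------------------------------------------------------------------
# frame-array dialect
# ---------------------------------------------------------------------------


def _write_frame_array(frames: TrajectoryFrameSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("# hairpinpath frame-array v1\n")
        fh.write(f"# atoms {frames.topology.n_atoms}\n")
        fh.write(f"# frames {frames.n_frames}\n")
        fh.write(
            "# times_ns "
            + " ".join(format(t, ".17g") for t in frames.times)
            + "\n"
        )
        flat = frames.coordinates.reshape(frames.n_frames, -1)
        np.savetxt(fh, flat, fmt="%.17g")


def _read_frame_array(path, topology: PeptideTopology) -> TrajectoryFrameSet:
    times = None
    n_atoms = None
    data_lines = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("atoms"):
                    n_atoms = int(body.split()[1])
                elif body.startswith("times_ns"):
                    times = np.array(
                        [float(x) for x in body.split()[1:]]
                    )
                continue
            data_lines.append(line)
    if not data_lines:
        raise TrajectoryError(f"no frames in {path}")
    flat = np.loadtxt(io.StringIO("\n".join(data_lines)), ndmin=2)
    if n_atoms is not None and flat.shape[1] != 3 * n_atoms:
        raise TrajectoryError(
            f"frame width {flat.shape[1]} inconsistent with header atom "
            f"count {n_atoms}"
        )
    if flat.shape[1] != 3 * topology.n_atoms:
        raise TrajectoryError(
            f"atom count mismatch at frame 0: file rows have "
            f"{flat.shape[1] // 3} atoms, topology has {topology.n_atoms}"
        )
    coords = flat.reshape(flat.shape[0], topology.n_atoms, 3)
    if times is None or times.size != coords.shape[0]:
        times = np.arange(coords.shape[0]) * DEFAULT_FRAME_SPACING_NS
    return TrajectoryFrameSet(topology, coords, times, source_label=str(path))


# ---------------------------------------------------------------------------
# secondary-structure assignment files and csv tracks
# ---------------------------------------------------------------------------

_SS_REDUCE_STRIDE = {
    "H": "H", "G": "H", "I": "H",
    "E": "E", "B": "E", "b": "E",
    "T": "T",
    "C": "C", "-": "C",
}
_SS_REDUCE_DSSP = {
    "H": "H", "G": "H", "I": "H",
    "E": "E",
    "T": "T",
    "S": "C", "B": "C",  # bend-like codes, counted separately
    "C": "C", "-": "C", " ": "C", "P": "C",
}
_DSSP_BEND_CODES = {"S", "B"}
_VALID_REDUCED = {"H", "E", "T", "C"}


class SSAssignment(list):
    """List of per-residue categorical tracks with a bend counter."""

    bend_count: int = 0


def _tracks_from_table(rows: list[tuple[int, int, str]]) -> SSAssignment:
    """rows: (frame, residue 1-based, reduced code)."""
    frames = sorted({r[0] for r in rows})
    residues = sorted({r[1] for r in rows})
    frame_pos = {f: i for i, f in enumerate(frames)}
    res_pos = {r: i for i, r in enumerate(residues)}
    grid = np.full((len(frames), len(residues)), "", dtype=object)
    for f, r, c in rows:
        grid[frame_pos[f], res_pos[r]] = c
    if (grid == "").any():
        raise TrackError("file rows do not cover every (frame, residue)")
    out = SSAssignment(
        AnnotationTrack(f"ss_res_{r}", grid[:, res_pos[r]].astype("U1"))
        for r in residues
    )
    return out


def read_ss_assignment(path, dialect: str) -> SSAssignment:
    """Parse a secondary-structure assignment into per-residue tracks.

    Supported dialects: ``stride-output`` and ``dssp-output`` (single
    structure per file) and the multi-frame ``csv-track`` format
    (``frame,residue,code`` columns).  Codes are reduced to {H, E, T, C};
    bend-like DSSP codes map to C and are tallied on ``.bend_count``.
    """
    rows: list[tuple[int, int, str]] = []
    bend = 0
    if dialect == "stride-output":
        with open(path) as fh:
            for line in fh:
                if not line.startswith("ASG"):
                    continue
                parts = line.split()
                code = parts[5]
                if code not in _SS_REDUCE_STRIDE:
                    raise TrackError(f"unknown STRIDE code {code!r}")
                rows.append((0, int(parts[3]), _SS_REDUCE_STRIDE[code]))
    elif dialect == "dssp-output":
        with open(path) as fh:
            in_table = False
            for line in fh:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_table = True
                    continue
                if not in_table or len(line) < 17 or line[13] == "!":
                    continue
                code = line[16] if line[16] != " " else "C"
                if code not in _SS_REDUCE_DSSP:
                    raise TrackError(f"unknown DSSP code {code!r}")
                if code in _DSSP_BEND_CODES:
                    bend += 1
                rows.append((0, int(line[5:10]), _SS_REDUCE_DSSP[code]))
    elif dialect == "csv-track":
        df = pd.read_csv(path)
        need = {"frame", "residue", "code"}
        if not need.issubset(df.columns):
            raise TrackError(
                f"csv-track needs columns {sorted(need)}, got "
                f"{list(df.columns)}"
            )
        bad = set(df["code"].astype(str)) - _VALID_REDUCED
        if bad:
            raise TrackError(f"unknown code(s) {sorted(bad)}")
        rows = [
            (int(f), int(r), str(c))
            for f, r, c in zip(df["frame"], df["residue"], df["code"])
        ]
    else:
        raise ValueError(f"unknown ss dialect {dialect!r}")
    if not rows:
        raise TrackError(f"no assignment rows found in {path}")
    out = _tracks_from_table(rows)
    out.bend_count = bend
    return out


def write_ss_assignment(tracks, path) -> None:
    """Write per-residue categorical tracks in the csv-track dialect."""
    recs = []
    for track in tracks:
        res = int(str(track.name).rsplit("_", 1)[-1])
        for f, code in enumerate(track.values):
            recs.append((f, res, str(code)))
    pd.DataFrame(recs, columns=["frame", "residue", "code"]).to_csv(
        path, index=False
    )


def write_bool_tracks(tracks, path) -> None:
    """Boolean tracks as ``frame,track,value`` CSV (value 0/1)."""
    recs = []
    for track in tracks:
        for f, v in enumerate(track.values):
            recs.append((f, track.name, int(v)))
    pd.DataFrame(recs, columns=["frame", "track", "value"]).to_csv(
        path, index=False
    )


def read_bool_tracks(path) -> list[AnnotationTrack]:
    df = pd.read_csv(path)
    need = {"frame", "track", "value"}
    if not need.issubset(df.columns):
        raise TrackError(
            f"bool-track csv needs columns {sorted(need)}, got "
            f"{list(df.columns)}"
        )
    out = []
    for name, sub in df.groupby("track", sort=False):
        sub = sub.sort_values("frame")
        out.append(AnnotationTrack(str(name), sub["value"].to_numpy() != 0))
    return out
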