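"""Per-frame structural annotation: hydrogen bonds, secondary structure,
β-turns, and per-residue propensities.

Hydrogen bonds use the geometric criterion common to GROMOS-family analysis
tools: donor–hydrogen–acceptor angle strictly greater than 135° and
hydrogen–acceptor distance strictly less than 0.25 nm.  A bond is named
``HB_d-a`` for the amide N–H of residue ``d`` donating to the backbone
carbonyl O of residue ``a`` (1-based).

Secondary structure comes from a transparent geometric assigner over the
reduced alphabet {H, E, T, C} (helix, strand, turn, coil); externally
computed STRIDE/DSSP assignments can be supplied instead through
:func:`hairpinpath.model_io.read_ss_assignment`.  A β-turn ``Turn_(i+3)-i``
(written later-residue-first) spans residues i..i+3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .model_io import (
    AnnotationTrack,
    PeptideTopology,
    TrajectoryFrameSet,
    HairpinPathError,
)


class AnnotationError(HairpinPathError):
    pass


@dataclass(frozen=True)
class HBondDefinition:
    """Backbone H-bond: amide N–H of ``donor_residue`` to carbonyl O of
    ``acceptor_residue`` (both 1-based)."""

    donor_residue: int
    acceptor_residue: int

    def __post_init__(self):
        if self.donor_residue == self.acceptor_residue:
            raise AnnotationError("H-bond donor equals acceptor")

    @property
    def label(self) -> str:
        return f"HB_{self.donor_residue}-{self.acceptor_residue}"

    @classmethod
    def from_label(cls, label: str) -> "HBondDefinition":
        body = label.removeprefix("HB_")
        d, a = body.split("-")
        return cls(int(d), int(a))


@dataclass(frozen=True)
class HBondCriteria:
    max_h_acceptor_distance: float = 0.25  # nm
    min_dha_angle: float = 135.0  # degrees

    def __post_init__(self):
        if self.max_h_acceptor_distance <= 0:
            raise AnnotationError("distance cutoff must be positive")
        if not (0 < self.min_dha_angle < 180):
            raise AnnotationError("angle cutoff must be in (0, 180)")


@dataclass(frozen=True)
class TurnDefinition:
    """β-turn over residues start..start+3, labelled later-residue-first
    (e.g. ``Turn_9-6`` for residues 6–9)."""

    start_residue: int

    @property
    def end_residue(self) -> int:
        return self.start_residue + 3

    @property
    def label(self) -> str:
        return f"Turn_{self.end_residue}-{self.start_residue}"

    @classmethod
    def from_label(cls, label: str) -> "TurnDefinition":
        body = label.removeprefix("Turn_")
        end, start = (int(x) for x in body.split("-"))
        if end != start + 3:
            raise AnnotationError(f"turn label {label!r} does not span i..i+3")
        return cls(start)


DEFAULT_CRITERIA = HBondCriteria()

# Native assigner parameters (overridable per call).
HELIX_PHI_CENTER = -57.0
HELIX_PSI_CENTER = -47.0
HELIX_WINDOW = 30.0
TURN_CA_CUTOFF = 0.7  # nm, d(CAi, CAi+3)
STRAND_SUPPORT_SEPARATION = 3  # min |donor - acceptor| for inter-strand bonds
STRAND_SUPPORT_RANGE = 2  # residue distance to a supporting H-bond


def _hbond_geometry(
    frames: TrajectoryFrameSet, hbond: HBondDefinition
) -> tuple[np.ndarray, np.ndarray]:
    """(distance H..O, angle N-H-O) arrays over frames."""
    topo = frames.topology
    r = topo.n_residues
    for res, what in ((hbond.donor_residue, "donor"),
                      (hbond.acceptor_residue, "acceptor")):
        if not (1 <= res <= r):
            raise AnnotationError(f"{what} residue {res} outside peptide")
    if not topo.has_atom(hbond.donor_residue, "H"):
        raise AnnotationError(
            f"residue {hbond.donor_residue} has no amide H to donate "
            f"(N-terminus); supply a custom atom naming if needed"
        )
    h = frames.coordinates[:, topo.atom_index(hbond.donor_residue, "H")]
    n = frames.coordinates[:, topo.atom_index(hbond.donor_residue, "N")]
    o = frames.coordinates[:, topo.atom_index(hbond.acceptor_residue, "O")]
    return geometry.distance(h, o), geometry.angle(n, h, o)


def hbond_mask(
    frames: TrajectoryFrameSet,
    hbond: HBondDefinition,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> np.ndarray:
    """Boolean per-frame presence of one hydrogen bond (strict inequalities
    at both thresholds)."""
    dist, ang = _hbond_geometry(frames, hbond)
    return (dist < criteria.max_h_acceptor_distance) & (
        ang > criteria.min_dha_angle
    )


def detect_hbond(
    frame: np.ndarray,
    topology: PeptideTopology,
    hbond: HBondDefinition,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> bool:
    """Single-frame hydrogen-bond test."""
    frames = TrajectoryFrameSet(
        topology, np.asarray(frame)[None], np.array([0.0])
    )
    return bool(hbond_mask(frames, hbond, criteria)[0])


def hbond_tracks(
    frames: TrajectoryFrameSet,
    definitions: list[HBondDefinition],
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> list[AnnotationTrack]:
    """One boolean track per H-bond definition."""
    return [
        AnnotationTrack(d.label, hbond_mask(frames, d, criteria))
        for d in definitions
    ]


def _backbone_hbond_partner_mask(
    frames: TrajectoryFrameSet, criteria: HBondCriteria
) -> np.ndarray:
    """(F, R) boolean: residue participates in a non-local backbone H-bond
    (|donor - acceptor| >= STRAND_SUPPORT_SEPARATION)."""
    topo = frames.topology
    r = topo.n_residues
    partner = np.zeros((frames.n_frames, r), dtype=bool)
    for d in range(2, r + 1):
        for a in range(1, r + 1):
            if abs(d - a) < STRAND_SUPPORT_SEPARATION:
                continue
            m = hbond_mask(frames, HBondDefinition(d, a), criteria)
            partner[m, d - 1] = True
            partner[m, a - 1] = True
    return partner


def assign_secondary_structure(
    frames: TrajectoryFrameSet | np.ndarray,
    topology: PeptideTopology | None = None,
    criteria: HBondCriteria = DEFAULT_CRITERIA,
) -> np.ndarray:
    """Per-residue codes {H, E, T, C}, shape (F, R) (or (R,) for one frame).

    Geometric rules, precedence H > E > T > C:

    - ``H``: φ,ψ of residues i-1..i+1 all within ±30° of (−57°, −47°).
    - ``E``: φ ∈ [−180°, −45°] and ψ ∈ [90°, 180°] ∪ [−180°, −150°], with a
      non-local backbone H-bond within 2 residues.
    - ``T``: residues i..i+3 when d(Cαi, Cαi+3) < 0.7 nm and i+1, i+2 are
      not helical.

    Terminal residues with undefined dihedrals can only be E (if supported)
    or default to C.
    """
    single = False
    if not isinstance(frames, TrajectoryFrameSet):
        if topology is None:
            raise AnnotationError("topology required with bare coordinates")
        coords = np.asarray(frames, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
            single = True
        frames = TrajectoryFrameSet(
            topology, coords, np.arange(coords.shape[0], dtype=float)
        )
    topo = frames.topology
    r = topo.n_residues
    bb = frames.backbone_arrays()
    phi, psi = geometry.backbone_dihedrals(bb["N"], bb["CA"], bb["C"])

    with np.errstate(invalid="ignore"):
        in_helix_region = (
            (np.abs(phi - HELIX_PHI_CENTER) <= HELIX_WINDOW)
            & (np.abs(psi - HELIX_PSI_CENTER) <= HELIX_WINDOW)
        )
        in_beta_region = (
            (phi >= -180.0) & (phi <= -45.0)
            & (((psi >= 90.0) & (psi <= 180.0))
               | ((psi >= -180.0) & (psi <= -150.0)))
        )
    in_helix_region &= ~np.isnan(phi) & ~np.isnan(psi)
    in_beta_region &= ~np.isnan(phi) & ~np.isnan(psi)

    helix = np.zeros_like(in_helix_region)
    helix[:, 1:-1] = (
        in_helix_region[:, :-2]
        & in_helix_region[:, 1:-1]
        & in_helix_region[:, 2:]
    )

    partner = _backbone_hbond_partner_mask(frames, criteria)
    support = np.zeros_like(partner)
    for off in range(-STRAND_SUPPORT_RANGE, STRAND_SUPPORT_RANGE + 1):
        lo, hi = max(0, off), min(r, r + off)
        support[:, lo - off:hi - off] |= partner[:, lo:hi]
    strand = in_beta_region & support & ~helix

    ca = bb["CA"]
    turn = np.zeros((frames.n_frames, r), dtype=bool)
    close = geometry.distance(ca[:, :-3], ca[:, 3:]) < TURN_CA_CUTOFF
    for w in range(r - 3):
        ok = close[:, w] & ~helix[:, w + 1] & ~helix[:, w + 2]
        turn[ok, w:w + 4] = True

    codes = np.full((frames.n_frames, r), "C", dtype="U1")
    codes[turn] = "T"
    codes[strand] = "E"
    codes[helix] = "H"
    return codes[0] if single else codes


def turn_window_mask(
    frames: TrajectoryFrameSet,
    turn: TurnDefinition,
    codes: np.ndarray | None = None,
) -> np.ndarray:
    """Native per-frame turn criterion for one i..i+3 window:
    d(Cαi, Cαi+3) < 0.7 nm with the two inner residues non-helical."""
    topo = frames.topology
    if not (1 <= turn.start_residue and turn.end_residue <= topo.n_residues):
        raise AnnotationError(
            f"turn window {turn.label} outside peptide of "
            f"{topo.n_residues} residues"
        )
    if codes is None:
        codes = assign_secondary_structure(frames)
    i = turn.start_residue - 1
    ca = frames.coordinates[:, topo.ca_indices]
    close = geometry.distance(ca[:, i], ca[:, i + 3]) < TURN_CA_CUTOFF
    not_helix = (codes[:, i + 1] != "H") & (codes[:, i + 2] != "H")
    return close & not_helix


def turn_track(
    frames: TrajectoryFrameSet | None,
    turn: TurnDefinition,
    ss_source: str = "native",
    ss_tracks=None,
) -> AnnotationTrack:
    """Boolean track for one β-turn.

    ``ss_source="native"`` applies the geometric window criterion;
    ``"external"`` requires all four residues of the window to carry code T
    in the supplied per-residue tracks (e.g. parsed STRIDE output).
    """
    if ss_source == "native":
        if frames is None:
            raise AnnotationError("native turn assignment needs frames")
        values = turn_window_mask(frames, turn)
    elif ss_source == "external":
        if ss_tracks is None:
            raise AnnotationError("external turn assignment needs ss tracks")
        by_res = {
            int(str(t.name).rsplit("_", 1)[-1]): np.asarray(t.values)
            for t in ss_tracks
        }
        try:
            window = [
                by_res[i]
                for i in range(turn.start_residue, turn.end_residue + 1)
            ]
        except KeyError as e:
            raise AnnotationError(
                f"turn window {turn.label} outside supplied tracks"
            ) from e
        values = np.logical_and.reduce([w == "T" for w in window])
    else:
        raise ValueError(f"unknown ss_source {ss_source!r}")
    return AnnotationTrack(turn.label, values)


def residue_propensities(codes: np.ndarray) -> pd.DataFrame:
    """Per-residue occurrence probabilities of turn (T) and strand (E).

    ``codes`` is the (F, R) array from :func:`assign_secondary_structure`
    (or assembled from external tracks).
    """
    codes = np.atleast_2d(np.asarray(codes))
    if codes.shape[0] < 1:
        raise AnnotationError("no frames")
    return pd.DataFrame(
        {
            "residue": np.arange(1, codes.shape[1] + 1),
            "P_turn": np.mean(codes == "T", axis=0),
            "P_strand": np.mean(codes == "E", axis=0),
        }
    )


def occurrence_probability(track: AnnotationTrack) -> float:
    """Fraction of frames on which a boolean track is true."""
    if track.frame_count == 0:
        raise AnnotationError(f"track {track.name} has no frames")
    return track.mean()
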