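"""Synthetic 12-residue backbone trajectories with programmed folding
mechanisms.

Every analysis stage in this package is exercised against trajectories
whose ground truth is known by construction.  Conformations live in
dihedral space: a small library of templates (α-helix, turn-formed
intermediate, partially bonded intermediate, full β-hairpin, and an
open-loop state with outer bonds but no turn) is built per condition by
constrained least-squares over backbone (φ, ψ), and frames are rebuilt
from ideal internal coordinates, so every frame — including any
interpolated one — is a chemically sane backbone.  Isotropic Gaussian
coordinate noise (truncated at 3σ) is added after the rebuild.

Programmed mechanisms:

``turn_first``
    helix → turn-only → partial bonds → full hairpin cycles; no native
    hydrogen-bond geometry exists on any turn-absent frame, so the
    conditional P(H-bond | turn absent) is exactly zero — the zipper
    signature.
``hbond_first``
    helix → open-loop (outer bonds formed, turn open) → hairpin cycles;
    outer-bond conditionals are far from zero.
``two_path``
    repeated folding events routed through the turn-only basin (U1) or the
    partially bonded basin (U2) with a programmed mixture.

Template validation is strict: registry bonds must satisfy the detection
criteria with margin and all other bonds must miss them with margin, or
construction fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from . import geometry
from .annotators import HBondDefinition, TurnDefinition, turn_window_mask
from .landscape import BasinLabeling, BasinRegion
from .model_io import (
    AnnotationTrack,
    HairpinPathError,
    PeptideTopology,
    TrajectoryFrameSet,
    ALPHA_SYN12_SEQUENCE,
    frameset_from_backbone,
)
from .superposition import superpose


class ConstructionError(HairpinPathError):
    pass


HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0
# Canonical 2:2 hairpin guess: (phi, psi) offsets relative to the first
# turn residue, chosen so both turn-closing bonds and the outer ladder
# rung are simultaneously near their ideal geometry.
HAIRPIN_GUESS = {
    -3: (None, 112.0),
    -2: (-127.8, 141.5),
    -1: (-125.0, 136.3),
    0: (-139.1, 152.3),
    1: (-18.6, -43.1),
    2: (-148.6, 27.5),
    3: (-121.5, 149.4),
    4: (-152.7, 110.8),
    5: (-131.6, 147.8),
}

DEFAULT_NOISE_SIGMA = 0.005  # nm
DEFAULT_N_FRAMES = 5000

# Margins used when validating templates against the bond criteria.
_BOND_MAX_D = 0.235  # nm, tighter than the 0.25 detection cutoff
_BOND_MIN_ANG = 150.0  # deg, above the 135 detection cutoff
_NOBOND_MIN_D = 0.30
_NOBOND_MAX_ANG = 120.0

CONDITION_TURNS = {
    "physiological": TurnDefinition(6),
    "acidic": TurnDefinition(5),
}
CONDITION_HBONDS = {
    "physiological": tuple(
        HBondDefinition(*p) for p in ((9, 6), (6, 9), (11, 4), (4, 11))
    ),
    "acidic": tuple(
        HBondDefinition(*p) for p in ((8, 5), (5, 8), (10, 3), (3, 10), (12, 1))
    ),
}


def alpha_syn12_topology(
    protonation_label: str = "physiological",
) -> PeptideTopology:
    """Backbone topology of the α-syn12 peptide (MDVFMKGLSKAK)."""
    return PeptideTopology.from_sequence(
        ALPHA_SYN12_SEQUENCE, protonation_label
    )


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _bond_geometry(bb: dict[str, np.ndarray], bond: HBondDefinition):
    h = bb["H"][bond.donor_residue - 1]
    n = bb["N"][bond.donor_residue - 1]
    o = bb["O"][bond.acceptor_residue - 1]
    return geometry.distance(h, o), geometry.angle(n, h, o)


def _hinge(x):
    return np.maximum(0.0, x)


class _TemplateObjective:
    """Vectorised violation score for candidate (φ, ψ) sets.

    A score of zero means every constraint is satisfied with margin
    (comfortably inside the detection thresholds used at validation time).
    """

    def __init__(
        self,
        n_res: int,
        target_bonds: tuple[HBondDefinition, ...] = (),
        forbidden_bonds: tuple[HBondDefinition, ...] = (),
        close_turns: tuple[TurnDefinition, ...] = (),
        open_turns: tuple[TurnDefinition, ...] = (),
        far_pairs: tuple[tuple[int, int, float], ...] = (),
    ):
        self.n_res = n_res
        self.target_bonds = target_bonds
        self.forbidden_bonds = forbidden_bonds
        self.close_turns = close_turns
        self.open_turns = open_turns
        # (residue_i, residue_j, min CA-CA distance): conformational
        # separation constraints, e.g. splaying strand ends apart.
        self.far_pairs = far_pairs

    def __call__(self, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """phi, psi: (K, R) candidate stacks -> (K,) scores."""
        bb = geometry.build_backbone(phi, psi)
        score = np.zeros(phi.shape[0])
        for bond in self.target_bonds:
            d, ang = _stack_bond_geometry(bb, bond)
            score += _hinge((d - 0.215) / 0.005)
            score += _hinge((155.0 - ang) / 2.0)
        for bond in self.forbidden_bonds:
            d, ang = _stack_bond_geometry(bb, bond)
            score += np.minimum(
                _hinge((0.32 - d) / 0.01), _hinge((ang - 115.0) / 3.0)
            )
        ca = bb["CA"]
        for turn in self.close_turns:
            i = turn.start_residue - 1
            d = geometry.distance(ca[:, i], ca[:, i + 3])
            score += _hinge((d - 0.62) / 0.005)
        for turn in self.open_turns:
            i = turn.start_residue - 1
            d = geometry.distance(ca[:, i], ca[:, i + 3])
            score += _hinge((0.75 - d) / 0.005)
        for ri, rj, dmin in self.far_pairs:
            d = geometry.distance(ca[:, ri - 1], ca[:, rj - 1])
            score += _hinge((dmin - d) / 0.005)
        # Steric sanity: keep nonlocal CA pairs apart.
        for i in range(self.n_res):
            for j in range(i + 3, self.n_res):
                score += _hinge(
                    (0.36 - geometry.distance(ca[:, i], ca[:, j])) / 0.01
                )
        return score

    def residual_stack(
        self, xs: np.ndarray, x0: np.ndarray, reg: np.ndarray | None = None
    ) -> np.ndarray:
        """Smooth residual vectors for a (K, 2R) stack of candidates.

        The "bond absent" condition (far OR badly aligned) uses the square
        root of a hinge product, which vanishes smoothly once either side
        is satisfied.
        """
        xs = np.atleast_2d(xs)
        phi = xs[:, : self.n_res]
        psi = xs[:, self.n_res:]
        bb = geometry.build_backbone(phi, psi)
        res = []
        for bond in self.target_bonds:
            d, ang = _stack_bond_geometry(bb, bond)
            # One-sided: no pull once safely inside the detection margins.
            res.append(_hinge((d - 0.205) / 0.003))
            res.append(_hinge((158.0 - ang) / 1.5))
        for bond in self.forbidden_bonds:
            d, ang = _stack_bond_geometry(bb, bond)
            res.append(np.sqrt(
                _hinge((0.34 - d) / 0.01) * _hinge((ang - 113.0) / 3.0)
            ))
        ca = bb["CA"]
        for turn in self.close_turns:
            i = turn.start_residue - 1
            d = geometry.distance(ca[:, i], ca[:, i + 3])
            res.append(_hinge(d - 0.60) / 0.005)
        for turn in self.open_turns:
            i = turn.start_residue - 1
            d = geometry.distance(ca[:, i], ca[:, i + 3])
            res.append(_hinge(0.78 - d) / 0.005)
        for ri, rj, dmin in self.far_pairs:
            d = geometry.distance(ca[:, ri - 1], ca[:, rj - 1])
            res.append(_hinge((dmin + 0.03) - d) / 0.005)
        for i in range(self.n_res):
            for j in range(i + 3, self.n_res):
                res.append(
                    _hinge(0.37 - geometry.distance(ca[:, i], ca[:, j]))
                    / 0.01
                )
        res = np.stack(res, axis=1)
        if reg is None:
            reg = np.full(2 * self.n_res, 80.0)
        return np.concatenate([res, (xs - x0) / reg], axis=1)

    def refine(
        self,
        phi0: np.ndarray,
        psi0: np.ndarray,
        name: str,
        hold: list[int] | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic template search from an initial guess.

        Least-squares over smooth residuals — optionally staged, first
        holding the parameter indices in ``hold`` (0..R-1 for φ,
        R..2R-1 for ψ) near their guess values, then releasing them.  If
        any validation-margin violation survives, a seeded wide random
        multi-start follows.  Construction fails loudly if the margins
        cannot all be met.
        """
        x0 = np.concatenate([phi0, psi0])
        n_par = 2 * self.n_res

        def polish(x_start: np.ndarray, reg: np.ndarray | None = None):
            fun = lambda x: self.residual_stack(x[None], x_start, reg)[0]

            def jac(x):
                h = 1e-4
                steps = np.concatenate(
                    [x + h * np.eye(n_par), x - h * np.eye(n_par)]
                )
                f = self.residual_stack(steps, x_start, reg)
                return (f[:n_par] - f[n_par:]).T / (2 * h)

            sol = least_squares(fun, x_start, jac=jac, max_nfev=200)
            p, s = sol.x[: self.n_res], sol.x[self.n_res:]
            return float(self(p[None], s[None])[0]), p, s

        if hold:
            reg = np.full(n_par, 80.0)
            reg[np.asarray(hold)] = 0.05
            stage, p, s = polish(x0, reg)
            best, best_phi, best_psi = stage, p, s
            if stage > 0.0:
                cand, p2, s2 = polish(np.concatenate([p, s]))
                if cand < best:
                    best, best_phi, best_psi = cand, p2, s2
        else:
            best, best_phi, best_psi = polish(x0)
        if best > 0.0:
            # Multi-start: sample widely around the guess, polish the most
            # promising candidates.
            rng = np.random.default_rng(20130524)  # templates are constants
            k = 40000
            phis = phi0 + rng.normal(0.0, 50.0, (k, self.n_res))
            psis = psi0 + rng.normal(0.0, 50.0, (k, self.n_res))
            scores = self(phis, psis)
            for ib in np.argsort(scores)[:10]:
                cand, p, s = polish(
                    np.concatenate([phis[ib], psis[ib]])
                )
                if cand < best:
                    best, best_phi, best_psi = cand, p, s
                if best == 0.0:
                    break
        if best > 0.0:
            raise ConstructionError(
                f"template {name!r}: could not satisfy geometric "
                f"constraints (residual violation {best:.3g})"
            )
        return best_phi, best_psi


def _stack_bond_geometry(bb: dict[str, np.ndarray], bond: HBondDefinition):
    h = bb["H"][:, bond.donor_residue - 1]
    n = bb["N"][:, bond.donor_residue - 1]
    o = bb["O"][:, bond.acceptor_residue - 1]
    return geometry.distance(h, o), geometry.angle(n, h, o)


@dataclass(frozen=True)
class Template:
    """A reference conformation plus its programmed ground truth."""

    name: str
    phi: np.ndarray
    psi: np.ndarray
    turn_present: bool
    bonds_present: tuple[HBondDefinition, ...]
    basin: str | None  # None -> unassigned

    def backbone(self) -> dict[str, np.ndarray]:
        return geometry.build_backbone(self.phi, self.psi)


def _helix_dihedrals(n_res: int) -> tuple[np.ndarray, np.ndarray]:
    return np.full(n_res, HELIX_PHI), np.full(n_res, HELIX_PSI)


def _hairpin_guess(
    n_res: int, turn: TurnDefinition
) -> tuple[np.ndarray, np.ndarray]:
    phi = np.full(n_res, STRAND_PHI)
    psi = np.full(n_res, STRAND_PSI)
    i = turn.start_residue - 1  # 0-based first turn residue
    for rel, (p, s) in HAIRPIN_GUESS.items():
        k = i + rel
        if 0 <= k < n_res:
            if p is not None:
                phi[k] = p
            psi[k] = s
    return phi, psi


def _validate_template(
    topology: PeptideTopology,
    template: Template,
    registry: tuple[HBondDefinition, ...],
    turn: TurnDefinition,
) -> None:
    bb = template.backbone()
    frames = frameset_from_backbone(topology, bb)
    present = set(template.bonds_present)
    for bond in registry:
        d, ang = _bond_geometry(bb, bond)
        if bond in present:
            if not (d < _BOND_MAX_D and ang > _BOND_MIN_ANG):
                raise ConstructionError(
                    f"template {template.name}: bond {bond.label} not "
                    f"formed with margin (d={d:.3f} nm, angle={ang:.1f} deg)"
                )
        else:
            if not (d > _NOBOND_MIN_D or ang < _NOBOND_MAX_ANG):
                raise ConstructionError(
                    f"template {template.name}: bond {bond.label} too close "
                    f"to forming (d={d:.3f} nm, angle={ang:.1f} deg)"
                )
    has_turn = bool(turn_window_mask(frames, turn)[0])
    if has_turn != template.turn_present:
        raise ConstructionError(
            f"template {template.name}: turn {turn.label} present={has_turn},"
            f" expected {template.turn_present}"
        )


_TEMPLATE_CACHE: dict[tuple, dict[str, Template]] = {}


def build_template_library(
    topology: PeptideTopology,
    turn: TurnDefinition,
    registry: tuple[HBondDefinition, ...],
) -> dict[str, Template]:
    """Templates for one condition: helix, turn_only, partial, folded,
    open_loop.  Validated against the annotators; cached."""
    key = (topology.sequence, turn.start_residue,
           tuple((b.donor_residue, b.acceptor_residue) for b in registry))
    if key in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[key]
    n_res = topology.n_residues
    registry = tuple(registry)
    for b in registry:
        if not topology.has_atom(b.donor_residue, "H"):
            raise ConstructionError(
                f"bond {b.label}: donor residue {b.donor_residue} has no "
                f"amide H"
            )
    closing = tuple(
        b for b in registry
        if {b.donor_residue, b.acceptor_residue}
        == {turn.start_residue, turn.end_residue}
    )
    outer = tuple(b for b in registry if b not in closing)
    if not closing or not outer:
        raise ConstructionError(
            "registry must contain the turn-closing pair and at least one "
            "outer bond"
        )

    phi_h, psi_h = _helix_dihedrals(n_res)
    guess_phi, guess_psi = _hairpin_guess(n_res, turn)

    # Hold the turn window (φ, ψ of residues i..i+3) during the first fit
    # stage so strand alignment cannot trade away the closing bonds.
    i0 = turn.start_residue - 1
    window_params = [i0 + k for k in range(4)] + [
        n_res + i0 + k for k in range(4)
    ]
    folded_phi, folded_psi = _TemplateObjective(
        n_res, target_bonds=registry, close_turns=(turn,),
    ).refine(guess_phi, guess_psi, "folded", hold=window_params)

    # Turn-only template: a distorted (non-bond-forming) turn with the
    # strands splayed apart.
    turn_phi, turn_psi = _TemplateObjective(
        n_res, forbidden_bonds=registry, close_turns=(turn,),
    ).refine(np.full(n_res, -95.0), np.full(n_res, 110.0), "turn_only")

    # Partial intermediate: closing bonds only, with the outer strand ends
    # splayed well apart so the conformation is distinct from the folded
    # hairpin (and from it on the RMSD axis).
    partial_phi, partial_psi = _TemplateObjective(
        n_res, target_bonds=closing, forbidden_bonds=outer,
        close_turns=(turn,),
        far_pairs=(
            (outer[0].donor_residue, outer[0].acceptor_residue, 0.80),
        ),
    ).refine(guess_phi, guess_psi, "partial")

    # Open loop: outer-ladder bonds formed, driving turn held wide open.
    open_phi, open_psi = _TemplateObjective(
        n_res, target_bonds=outer, forbidden_bonds=closing,
        open_turns=(turn,),
    ).refine(np.full(n_res, STRAND_PHI), np.full(n_res, STRAND_PSI),
             "open_loop")

    templates = {
        "helix": Template("helix", phi_h, psi_h, False, (), None),
        "turn_only": Template(
            "turn_only", turn_phi, turn_psi, True, (), "U1"
        ),
        "partial": Template(
            "partial", partial_phi, partial_psi, True, closing, "U2"
        ),
        "folded": Template(
            "folded", folded_phi, folded_psi, True, registry, "F"
        ),
        "open_loop": Template(
            "open_loop", open_phi, open_psi, False, outer, "U1"
        ),
    }
    for t in templates.values():
        _validate_template(topology, t, registry, turn)
    _TEMPLATE_CACHE[key] = templates
    return templates


def make_ideal_helix(topology: PeptideTopology) -> np.ndarray:
    """Ideal α-helix frame (φ=−57°, ψ=−47°, ω=180°), coordinates in nm."""
    phi, psi = _helix_dihedrals(topology.n_residues)
    bb = geometry.build_backbone(phi, psi)
    return frameset_from_backbone(topology, bb).frame(0)


def make_ideal_hairpin(
    topology: PeptideTopology,
    turn: TurnDefinition,
    hbond_registry,
) -> np.ndarray:
    """β-hairpin frame with the given turn and bond registry satisfied
    under the default detection criteria (construction fails loudly if the
    registry is geometrically inconsistent with the turn placement)."""
    lib = build_template_library(topology, turn, tuple(hbond_registry))
    bb = lib["folded"].backbone()
    return frameset_from_backbone(topology, bb).frame(0)


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------


@dataclass
class MechanismScript:
    """Programmed schedule of template dwells.

    ``basin_schedule`` holds (template name, frame count) segments in
    order.  ``path_mixture`` records the routing probabilities of
    ``two_path`` scripts; ``ramp_frames`` linearly interpolates dihedrals
    over the first frames of each segment (0 keeps every scheduled onset
    exact).
    """

    mode: str
    basin_schedule: list[tuple[str, int]]
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0
    path_mixture: tuple[float, ...] = ()
    ramp_frames: int = 0
    condition: str = "physiological"

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ConstructionError("noise_sigma must be >= 0")
        if any(n <= 0 for _s, n in self.basin_schedule):
            raise ConstructionError("segment lengths must be positive")
        if self.path_mixture and not np.isclose(sum(self.path_mixture), 1.0):
            raise ConstructionError("path mixture must sum to 1")

    @property
    def n_frames(self) -> int:
        return sum(n for _s, n in self.basin_schedule)

    def onset_frames(
        self, templates: dict[str, Template], turn: TurnDefinition
    ) -> tuple[int | None, dict[str, int]]:
        """(turn onset, per-bond onset) — first scheduled frame on which
        each feature is present."""
        turn_onset = None
        bond_onsets: dict[str, int] = {}
        frame = 0
        for name, n in self.basin_schedule:
            t = templates[name]
            if t.turn_present and turn_onset is None:
                turn_onset = frame
            for b in t.bonds_present:
                bond_onsets.setdefault(b.label, frame)
            frame += n
        return turn_onset, bond_onsets

    # -- preset factories -------------------------------------------------

    @classmethod
    def turn_first(
        cls,
        n_frames: int = DEFAULT_N_FRAMES,
        seed: int = 0,
        noise_sigma: float = DEFAULT_NOISE_SIGMA,
        condition: str = "physiological",
    ) -> "MechanismScript":
        rng = np.random.default_rng(seed)
        schedule = []
        total = 0
        while total < n_frames:
            for name, lo, hi in (
                ("helix", 20, 40),
                ("turn_only", 10, 25),
                ("partial", 10, 25),
                ("folded", 30, 60),
            ):
                n = int(rng.integers(lo, hi + 1))
                n = min(n, n_frames - total)
                if n > 0:
                    schedule.append((name, n))
                    total += n
                if total >= n_frames:
                    break
        return cls("turn_first", schedule, noise_sigma, seed,
                   condition=condition)

    @classmethod
    def hbond_first(
        cls,
        n_frames: int = DEFAULT_N_FRAMES,
        seed: int = 0,
        noise_sigma: float = DEFAULT_NOISE_SIGMA,
        condition: str = "physiological",
    ) -> "MechanismScript":
        rng = np.random.default_rng(seed)
        schedule = []
        total = 0
        while total < n_frames:
            for name, lo, hi in (
                ("helix", 15, 30),
                ("open_loop", 15, 30),
                ("folded", 30, 60),
            ):
                n = int(rng.integers(lo, hi + 1))
                n = min(n, n_frames - total)
                if n > 0:
                    schedule.append((name, n))
                    total += n
                if total >= n_frames:
                    break
        return cls("hbond_first", schedule, noise_sigma, seed,
                   condition=condition)

    @classmethod
    def two_path(
        cls,
        n_frames: int = DEFAULT_N_FRAMES,
        seed: int = 0,
        noise_sigma: float = DEFAULT_NOISE_SIGMA,
        mixture: tuple[float, float] = (0.7, 0.3),
        n_events: int = 200,
        condition: str = "physiological",
    ) -> "MechanismScript":
        """Folding events routed through U1 (turn-only) with probability
        ``mixture[0]`` and U2 (partial) with ``mixture[1]``.

        ``n_events`` is capped so the schedule stays within ``n_frames``
        (each event needs at least 6 frames).
        """
        rng = np.random.default_rng(seed)
        n_events = min(n_events, max(1, n_frames // 6))
        per_event = max(6, n_frames // n_events)
        n_helix = max(1, per_event // 4)
        n_basin = max(2, per_event // 3)
        n_fold = per_event - n_helix - n_basin
        schedule = []
        for _ in range(n_events):
            via = "turn_only" if rng.random() < mixture[0] else "partial"
            schedule.append(("helix", n_helix))
            schedule.append((via, n_basin))
            schedule.append(("folded", n_fold))
        return cls("two_path", schedule, noise_sigma, seed,
                   path_mixture=tuple(mixture), condition=condition)

    @classmethod
    def with_turn_occupancy(
        cls,
        occupancy: float,
        n_frames: int = DEFAULT_N_FRAMES,
        seed: int = 0,
        noise_sigma: float = DEFAULT_NOISE_SIGMA,
        block: int = 5,
        condition: str = "physiological",
    ) -> "MechanismScript":
        """Two-state script whose programmed turn occupancy is
        ``occupancy``: blocks of frames are folded with that probability,
        helical otherwise."""
        rng = np.random.default_rng(seed)
        schedule = []
        total = 0
        while total < n_frames:
            n = min(block, n_frames - total)
            name = "folded" if rng.random() < occupancy else "helix"
            schedule.append((name, n))
            total += n
        return cls("occupancy", schedule, noise_sigma, seed,
                   condition=condition)


@dataclass
class SyntheticTrajectory:
    """Generated frames plus the programmed ground truth."""

    frames: TrajectoryFrameSet
    turn_track: AnnotationTrack
    hbond_tracks: list[AnnotationTrack]
    basin_labels: np.ndarray
    regions: BasinLabeling
    script: MechanismScript
    turn: TurnDefinition
    hbond_registry: tuple[HBondDefinition, ...]
    templates: dict[str, Template] = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def folded_reference(self) -> np.ndarray:
        bb = self.templates["folded"].backbone()
        return frameset_from_backbone(
            self.frames.topology, bb
        ).frame(0)


def _truncated_noise(rng, shape, sigma: float) -> np.ndarray:
    """Isotropic Gaussian displacements with per-atom norm clipped at 3σ."""
    eps = rng.normal(0.0, sigma, size=shape)
    if sigma == 0:
        return eps
    norms = np.linalg.norm(eps, axis=-1, keepdims=True)
    limit = 3.0 * sigma
    scale = np.where(norms > limit, limit / np.maximum(norms, 1e-300), 1.0)
    return eps * scale


def default_basin_regions(
    topology: PeptideTopology,
    templates: dict[str, Template],
    registry: tuple[HBondDefinition, ...],
    half_width: float = 0.08,
) -> BasinLabeling:
    """Basin rectangles centred on each template's RMSD to the folded
    reference at its programmed code level."""
    folded = frameset_from_backbone(
        topology, templates["folded"].backbone()
    ).frame(0)
    ca = topology.ca_indices
    n = len(registry)

    def rmsd_to_folded(t: Template) -> float:
        frame = frameset_from_backbone(topology, t.backbone()).frame(0)
        return superpose(frame, folded, ca).rmsd

    x_u1 = rmsd_to_folded(templates["turn_only"])
    x_u2 = rmsd_to_folded(templates["partial"])
    regions = [
        BasinRegion("F", 0.0, 0.12, (n - 1, n)),
        BasinRegion("U1", x_u1 - half_width, x_u1 + half_width, (0,)),
        BasinRegion(
            "U2", x_u2 - half_width, x_u2 + half_width,
            (len(templates["partial"].bonds_present),),
        ),
    ]
    return BasinLabeling(regions)


def generate_transition_trajectory(
    script: MechanismScript,
    topology: PeptideTopology | None = None,
    n_frames: int | None = None,
) -> SyntheticTrajectory:
    """Realise a mechanism script as a noisy backbone trajectory.

    Returns the frames together with ground-truth turn/H-bond tracks and
    per-frame basin labels; fully reproducible from ``script.seed``.
    """
    if topology is None:
        topology = alpha_syn12_topology(
            script.condition
            if script.condition in ("physiological", "acidic")
            else "custom"
        )
    turn = CONDITION_TURNS[script.condition]
    registry = CONDITION_HBONDS[script.condition]
    templates = build_template_library(topology, turn, registry)
    if n_frames is not None and n_frames != script.n_frames:
        raise ConstructionError(
            f"schedule covers {script.n_frames} frames, asked for {n_frames}"
        )
    total = script.n_frames
    n_res = topology.n_residues

    phi = np.empty((total, n_res))
    psi = np.empty((total, n_res))
    turn_truth = np.empty(total, dtype=bool)
    bond_truth = {b.label: np.zeros(total, dtype=bool) for b in registry}
    basins = np.full(total, "unassigned", dtype=object)

    frame = 0
    prev: Template | None = None
    for name, n in script.basin_schedule:
        t = templates[name]
        sl = slice(frame, frame + n)
        phi[sl] = t.phi
        psi[sl] = t.psi
        if script.ramp_frames > 0 and prev is not None:
            k = min(script.ramp_frames, n)
            w = np.linspace(0.0, 1.0, k + 2)[1:-1, None]
            phi[frame:frame + k] = (1 - w) * prev.phi + w * t.phi
            psi[frame:frame + k] = (1 - w) * prev.psi + w * t.psi
        turn_truth[sl] = t.turn_present
        for b in t.bonds_present:
            bond_truth[b.label][sl] = True
        if t.basin is not None:
            basins[sl] = t.basin
        frame += n
        prev = t

    bb = geometry.build_backbone(phi, psi)
    frames = frameset_from_backbone(
        topology, bb, source_label=f"synthetic:{script.mode}:{script.seed}"
    )
    rng = np.random.default_rng(script.seed)
    frames.coordinates = frames.coordinates + _truncated_noise(
        rng, frames.coordinates.shape, script.noise_sigma
    )

    regions = default_basin_regions(topology, templates, registry)
    return SyntheticTrajectory(
        frames=frames,
        turn_track=AnnotationTrack(turn.label, turn_truth),
        hbond_tracks=[
            AnnotationTrack(b.label, bond_truth[b.label]) for b in registry
        ],
        basin_labels=basins,
        regions=regions,
        script=script,
        turn=turn,
        hbond_registry=registry,
        templates=templates,
    )
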