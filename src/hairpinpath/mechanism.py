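"""Mechanism statistics: occurrence probabilities, turn-conditional
hydrogen-bond probabilities, and basin-to-basin transition paths.

The mechanistic question is whether the β-turn forms before the
inter-strand hydrogen bonds (turn-directed / zipper folding) or the other
way around (collapse-first).  The discriminating statistic is
P(H-bond present | turn absent): a zipper mechanism forces it to zero for
the driving turn, because the bonds only exist while the turn holds.

Transition paths are counted on the per-frame basin labels: the label
series is compressed to its sequence of visited basins (unassigned frames
and repeats dropped), and each maximal segment that starts in an unfolded
basin and ends at the folded basin is one folding event.  Non-folding
inter-basin moves in the trailing (never-folding) part of the series are
counted as no-fold events.  This segmentation — and the default six-path
catalog — is a documented convention of this package, configurable by the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import UNASSIGNED
from .model_io import AnnotationTrack, HairpinPathError


class MechanismError(HairpinPathError):
    pass


TURN_FIRST_CONDITIONAL_TOLERANCE = 0.01


def occurrence_table(
    tracks: list[AnnotationTrack],
    trajectory_labels: list[str] | None = None,
    track_groups: list[list[AnnotationTrack]] | None = None,
) -> pd.DataFrame:
    """Per-track occurrence probabilities (mean of each boolean track).

    With ``track_groups`` (one list of aligned tracks per trajectory), a
    per-trajectory row is emitted for each group plus a frame-weighted
    pooled row; otherwise a single pooled row covers ``tracks``.
    """
    if track_groups is None:
        track_groups = [tracks]
        trajectory_labels = trajectory_labels or ["pooled"]
    elif trajectory_labels is None:
        trajectory_labels = [
            f"trajectory {i + 1}" for i in range(len(track_groups))
        ]
    rows = []
    names = [t.name for t in track_groups[0]]
    totals = {n: 0.0 for n in names}
    frames_total = 0
    for label, group in zip(trajectory_labels, track_groups):
        row = {"trajectory": label}
        for t in group:
            if t.frame_count == 0:
                raise MechanismError(f"track {t.name} has no frames")
            row[t.name] = t.mean()
            totals[t.name] += float(np.sum(t.values))
        frames_total += group[0].frame_count
        rows.append(row)
    if len(track_groups) > 1:
        pooled = {"trajectory": "pooled"}
        for n in names:
            pooled[n] = totals[n] / frames_total
        rows.append(pooled)
    return pd.DataFrame(rows)


@dataclass
class ConditionalReport:
    """P(H-bond | turn absent) per (turn, bond) pair.

    ``probability`` is NaN with ``defined=False`` when the turn is never
    absent (no conditioning frames) — undefined, not zero.
    """

    table: pd.DataFrame  # turn, hbond, probability, n_conditioning_frames, defined

    def max_defined(self) -> float:
        d = self.table[self.table["defined"]]
        if d.empty:
            raise MechanismError("no defined conditionals")
        return float(d["probability"].max())

    def turn_precedes_hbonds(
        self, tol: float = TURN_FIRST_CONDITIONAL_TOLERANCE
    ) -> bool:
        """Zipper verdict: every defined conditional below ``tol``."""
        return self.max_defined() < tol


def conditional_hbond_given_no_turn(
    turn_tracks: list[AnnotationTrack],
    hbond_tracks: list[AnnotationTrack],
) -> ConditionalReport:
    """Fraction of turn-absent frames on which each H-bond is present."""
    rows = []
    for turn in turn_tracks:
        t = np.asarray(turn.values, dtype=bool)
        absent = ~t
        n_cond = int(absent.sum())
        for hb in hbond_tracks:
            v = np.asarray(hb.values, dtype=bool)
            if len(v) != len(t):
                raise MechanismError(
                    f"tracks {turn.name} and {hb.name} are not aligned"
                )
            if n_cond == 0:
                prob, defined = np.nan, False
            else:
                prob, defined = float(v[absent].mean()), True
            rows.append(
                {
                    "turn": turn.name,
                    "hbond": hb.name,
                    "probability": prob,
                    "n_conditioning_frames": n_cond,
                    "defined": defined,
                }
            )
    return ConditionalReport(pd.DataFrame(rows))


@dataclass
class PathReport:
    table: pd.DataFrame  # path, count, probability
    n_events: int

    def probability(self, path_label: str) -> float:
        row = self.table[self.table["path"] == path_label]
        if row.empty:
            raise MechanismError(f"no path {path_label!r} in report")
        return float(row["probability"].iloc[0])


def path_label(sequence: list[str] | tuple[str, ...]) -> str:
    return "->".join(sequence)


def default_path_catalog(
    unfolded: list[str] = ("U1", "U2"), folded: str = "F"
) -> list[tuple[str, ...]]:
    """Six-bar catalog: direct and two-step folding paths plus the two
    no-fold interconversions."""
    u1, u2 = unfolded
    return [
        (u1, folded),
        (u2, folded),
        (u1, u2, folded),
        (u2, u1, folded),
        (u1, u2),
        (u2, u1),
    ]


def compress_labels(labels: np.ndarray) -> list[str]:
    """Sequence of visited basins: unassigned frames dropped, consecutive
    repeats collapsed."""
    out: list[str] = []
    for lab in labels:
        lab = str(lab)
        if lab == UNASSIGNED:
            continue
        if not out or out[-1] != lab:
            out.append(lab)
    return out


def enumerate_transition_paths(
    basin_labels: np.ndarray,
    unfolded_labels: list[str],
    folded_label: str,
    path_catalog: list[tuple[str, ...]] | None = None,
    first_passage_only: bool = False,
) -> PathReport:
    """Count folding events against a path catalog.

    Each maximal compressed segment running from an unfolded basin to the
    folded basin is one event; its path is the visited basin sequence.
    Sequences absent from the catalog are pooled under ``"other"``.  With
    ``first_passage_only`` only the first folding event of the series is
    counted (no-fold events are then ignored).
    """
    if path_catalog is None:
        path_catalog = default_path_catalog(unfolded_labels, folded_label)
    if not path_catalog:
        raise MechanismError("empty path catalog")
    seq = compress_labels(np.asarray(basin_labels))

    events: list[tuple[str, ...]] = []
    segment: list[str] = []
    for lab in seq:
        if lab == folded_label:
            if segment:
                events.append(tuple(segment) + (folded_label,))
                if first_passage_only:
                    break
            segment = []
        else:
            segment.append(lab)
    if not first_passage_only and len(segment) >= 2:
        # Trailing never-folding stretch: count inter-basin moves.
        for a, b in zip(segment[:-1], segment[1:]):
            events.append((a, b))

    counts: dict[str, int] = {path_label(p): 0 for p in path_catalog}
    counts["other"] = 0
    for ev in events:
        lab = path_label(ev)
        if lab in counts:
            counts[lab] += 1
        else:
            counts["other"] += 1
    n_events = len(events)
    table = pd.DataFrame(
        {
            "path": list(counts.keys()),
            "count": list(counts.values()),
        }
    )
    table["probability"] = (
        table["count"] / n_events if n_events else np.nan
    )
    return PathReport(table, n_events)


@dataclass
class MechanismReport:
    """Combined result surface of one analysis condition."""

    condition: str
    occurrences: pd.DataFrame
    conditionals: ConditionalReport
    paths: PathReport | None
    minima: list = field(default_factory=list)
    cluster_populations: list = field(default_factory=list)

    @property
    def verdict(self) -> str:
        try:
            turn_first = self.conditionals.turn_precedes_hbonds()
        except MechanismError:
            return "undetermined (turn never absent)"
        return (
            "turn precedes H-bonds" if turn_first
            else "H-bonds occur without the turn"
        )

    def to_dict(self) -> dict:
        out = {
            "condition": self.condition,
            "verdict": self.verdict,
            "occurrences": self.occurrences.to_dict(orient="records"),
            "conditionals": self.conditionals.table.to_dict(orient="records"),
            "minima": [
                {"x_nm": x, "y_level": y, "depth_kJ_per_mol": d}
                for x, y, d in self.minima
            ],
            "cluster_populations": list(map(float, self.cluster_populations)),
        }
        if self.paths is not None:
            out["paths"] = self.paths.table.to_dict(orient="records")
            out["n_transition_events"] = self.paths.n_events
        return out
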