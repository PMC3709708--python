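"""Discrete reaction coordinate, 2D free-energy surface and basin labels.

The transition is projected onto two coordinates: the Cα RMSD from the most
clustered (folded) structure on the X axis, and a discrete code on the Y
axis built from the driving β-turn and an ordered set of native hydrogen
bonds:

    -1        the turn is absent,
     0        the turn is present but none of the set bonds are,
     k (1..n) the turn is present and exactly k of the n set bonds are.

The surface is F = −kT ln P over (X bins × Y levels), shifted so the
lowest sampled bin is zero; unsampled bins are flagged rather than set to
infinity.  Local minima are sampled bins strictly below all of their
sampled 8-neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotators import HBondDefinition, TurnDefinition
from .model_io import AnnotationTrack, HairpinPathError

GAS_CONSTANT_KJ_PER_MOL_K = 0.0083145
DEFAULT_TEMPERATURE_K = 300.0
DEFAULT_X_BIN_WIDTH_NM = 0.01
UNASSIGNED = "unassigned"


class LandscapeError(HairpinPathError):
    pass


@dataclass(frozen=True)
class StateCodingScheme:
    turn: TurnDefinition
    hbond_set: tuple[HBondDefinition, ...]

    def __post_init__(self):
        if len(self.hbond_set) < 1:
            raise LandscapeError("need at least one hydrogen bond in the set")

    @property
    def code_levels(self) -> np.ndarray:
        """All possible codes: -1 .. n."""
        return np.arange(-1, len(self.hbond_set) + 1)


@dataclass
class StateSeries:
    rmsd: np.ndarray  # nm, vs most clustered structure
    ycode: np.ndarray
    scheme: StateCodingScheme | None = None

    def __post_init__(self):
        self.rmsd = np.asarray(self.rmsd, dtype=float)
        self.ycode = np.asarray(self.ycode, dtype=int)
        if self.rmsd.shape != self.ycode.shape:
            raise LandscapeError("rmsd and ycode lengths differ")
        if self.scheme is not None:
            levels = self.scheme.code_levels
            if self.ycode.size and (
                self.ycode.min() < levels.min()
                or self.ycode.max() > levels.max()
            ):
                raise LandscapeError("ycode outside scheme range")

    def __len__(self) -> int:
        return len(self.rmsd)


def encode_states(
    turn_track: AnnotationTrack,
    hbond_tracks: list[AnnotationTrack],
    rmsd_series: np.ndarray,
    scheme: StateCodingScheme | None = None,
) -> StateSeries:
    """Per-frame (RMSD, discrete code) pairs.

    The code counts only the designated hydrogen-bond set (the tracks
    passed here); any other bond is ignored by construction.
    """
    turn = np.asarray(turn_track.values, dtype=bool)
    n = len(turn)
    rmsd_series = np.asarray(rmsd_series, dtype=float)
    if len(rmsd_series) != n:
        raise LandscapeError("rmsd series length does not match tracks")
    counts = np.zeros(n, dtype=int)
    for t in hbond_tracks:
        v = np.asarray(t.values, dtype=bool)
        if len(v) != n:
            raise LandscapeError(
                f"track {t.name} length {len(v)} does not match {n}"
            )
        counts += v
    ycode = np.where(turn, counts, -1)
    return StateSeries(rmsd_series, ycode, scheme)


@dataclass
class FreeEnergySurface:
    x_edges: np.ndarray  # nm
    y_levels: np.ndarray  # integer codes
    F: np.ndarray  # (n_x, n_y) kJ/mol, NaN where unsampled
    kT: float  # kJ/mol
    minima: list = field(default_factory=list)  # (x_center, y_level, depth)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def sampled(self) -> np.ndarray:
        return ~np.isnan(self.F)

    def to_frame(self) -> pd.DataFrame:
        """Long-format grid (x_center_nm, y_level, F_kJ_per_mol or NA)."""
        xs, ys = np.meshgrid(self.x_centers, self.y_levels, indexing="ij")
        return pd.DataFrame(
            {
                "x_center_nm": xs.ravel(),
                "y_level": ys.ravel().astype(int),
                "F_kJ_per_mol": self.F.ravel(),
            }
        )


def build_fes(
    series: StateSeries,
    x_bin_width: float = DEFAULT_X_BIN_WIDTH_NM,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> FreeEnergySurface:
    """Histogram the state series and convert to free energies.

    F = −kT ln P with kT = R·T (R = 0.0083145 kJ·mol⁻¹·K⁻¹), shifted so the
    global sampled minimum is zero.  The Y axis is categorical (one level
    per code, no binning); X bins have uniform ``x_bin_width`` (nm).
    """
    if len(series) == 0:
        raise LandscapeError("cannot build a surface from zero frames")
    if x_bin_width <= 0:
        raise LandscapeError("x_bin_width must be positive")
    kT = GAS_CONSTANT_KJ_PER_MOL_K * temperature
    if series.scheme is not None:
        y_levels = series.scheme.code_levels
    else:
        y_levels = np.arange(series.ycode.min(), series.ycode.max() + 1)
    n_bins = max(1, int(np.ceil(series.rmsd.max() / x_bin_width + 1e-12)))
    x_edges = np.arange(n_bins + 1) * x_bin_width
    ix = np.clip(
        np.floor(series.rmsd / x_bin_width).astype(int), 0, n_bins - 1
    )
    iy = series.ycode - y_levels[0]
    counts = np.zeros((n_bins, len(y_levels)))
    np.add.at(counts, (ix, iy), 1.0)
    with np.errstate(divide="ignore"):
        F = -kT * np.log(counts / counts.sum())
    F[counts == 0] = np.nan
    F -= np.nanmin(F)
    fes = FreeEnergySurface(x_edges, y_levels, F, kT)
    fes.minima = find_minima(fes)
    return fes


def find_minima(fes: FreeEnergySurface) -> list[tuple[float, int, float]]:
    """Local minima of the surface as (x_center, y_level, depth).

    A sampled bin is a minimum when its F is strictly smaller than every
    sampled 8-neighbor (bins on a plateau are therefore not minima).
    Depths are relative to the global minimum (which has depth 0); the
    list is sorted by ascending depth, global minimum first.
    """
    F = fes.F
    sampled = fes.sampled
    nx, ny = F.shape
    minima = []
    for i in range(nx):
        for j in range(ny):
            if not sampled[i, j]:
                continue
            is_min = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0:
                        continue
                    a, b = i + di, j + dj
                    if 0 <= a < nx and 0 <= b < ny and sampled[a, b]:
                        if not (F[i, j] < F[a, b]):
                            is_min = False
            if is_min:
                minima.append(
                    (
                        float(fes.x_centers[i]),
                        int(fes.y_levels[j]),
                        float(F[i, j]),
                    )
                )
    minima.sort(key=lambda m: m[2])
    return minima


@dataclass(frozen=True)
class BasinRegion:
    """Axis-aligned rectangle in (x, ycode) space."""

    name: str
    x_min: float
    x_max: float
    y_levels: tuple[int, ...]

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (
            (x >= self.x_min)
            & (x < self.x_max)
            & np.isin(y, self.y_levels)
        )


@dataclass
class BasinLabeling:
    regions: list[BasinRegion]

    def __post_init__(self):
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                x_overlap = a.x_min < b.x_max and b.x_min < a.x_max
                y_overlap = set(a.y_levels) & set(b.y_levels)
                if x_overlap and y_overlap:
                    raise LandscapeError(
                        f"basin regions {a.name!r} and {b.name!r} overlap"
                    )

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]


def regions_around_minima(
    minima: list[tuple[float, int, float]],
    names: list[str],
    half_width: float = 0.05,
) -> BasinLabeling:
    """Default basin rectangles: ±``half_width`` nm in X around each
    minimum at its exact Y level."""
    regions = [
        BasinRegion(name, x - half_width, x + half_width, (y,))
        for name, (x, y, _depth) in zip(names, minima)
    ]
    return BasinLabeling(regions)


def label_basins(series: StateSeries, regions: BasinLabeling) -> np.ndarray:
    """Per-frame basin name, or ``"unassigned"`` outside all regions."""
    labels = np.full(len(series), UNASSIGNED, dtype=object)
    for region in regions.regions:
        inside = region.contains(series.rmsd, series.ycode)
        labels[inside] = region.name
    return labels


def plot_fes(fes: FreeEnergySurface, ax=None, contour_interval: float = 1.0):
    """Filled contour plot with 1 kJ/mol contour spacing; unsampled bins
    are left blank."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots()
    fmax = np.nanmax(fes.F)
    levels = np.arange(0.0, fmax + contour_interval, contour_interval)
    xs, ys = np.meshgrid(fes.x_centers, fes.y_levels, indexing="ij")
    ax.contourf(xs, ys, np.ma.masked_invalid(fes.F), levels=levels)
    ax.set_xlabel("RMSD$_{C\\alpha}$ from most clustered structure (nm)")
    ax.set_ylabel("turn / hydrogen-bond code")
    ax.set_yticks(fes.y_levels)
    return ax
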