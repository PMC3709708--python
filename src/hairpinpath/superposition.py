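"""Optimal rigid-body superposition and Cα RMSD.

The pipeline measures conformational distance exclusively as the RMSD of
Cα positions after least-squares rigid superposition (rotation +
translation, reflections excluded).  Two independent algorithms are
provided: the Kabsch SVD construction (:func:`superpose`) and the
Horn quaternion eigenvalue method (:func:`rmsd_quaternion`), which agree to
numerical precision and serve as mutual cross-checks.

All distances are in nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_io import TrajectoryFrameSet, HairpinPathError


class DegenerateGeometryError(HairpinPathError):
    pass


@dataclass
class RmsdResult:
    rmsd: float
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,), applied after rotation
    atom_selection: np.ndarray

    def transform(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted rigid transform to an (N, 3) array."""
        return coords @ self.rotation.T + self.translation


def _check_selection(coords: np.ndarray, selection: np.ndarray) -> None:
    sel = coords[selection]
    if sel.shape[0] < 3:
        raise DegenerateGeometryError(
            f"need at least 3 atoms to superpose, got {sel.shape[0]}"
        )
    centered = sel - sel.mean(axis=0)
    # Collinear selections leave the rotation under-determined.
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise DegenerateGeometryError("selection is collinear")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> RmsdResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    ``mobile`` and ``reference`` are (A, 3) single frames; ``selection``
    is the atom-index list the fit and the RMSD use (default: all atoms).
    The returned rotation is proper — the reflection branch of the Kabsch
    solution is rejected by a determinant sign correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.arange(mobile.shape[0])
    selection = np.asarray(selection)
    if selection.size >= 3 and (
        mobile.shape[0] <= selection.max()
        or reference.shape[0] <= selection.max()
    ):
        raise DegenerateGeometryError("selection exceeds atom count")
    _check_selection(mobile, selection)
    _check_selection(reference, selection)

    x = mobile[selection]
    y = reference[selection]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    cov = x0.T @ y0
    u, s, vt = np.linalg.svd(cov)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.array([1.0, 1.0, sign])
    rotation = vt.T @ np.diag(d) @ u.T
    translation = yc - rotation @ xc
    diff = x0 @ rotation.T - y0
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return RmsdResult(rmsd, rotation, translation, selection)


def rmsd_quaternion(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> float:
    """Minimum RMSD via Horn's quaternion eigenvalue method.

    Independent of the SVD route in :func:`superpose`; used as a
    cross-check oracle.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.arange(mobile.shape[0])
    selection = np.asarray(selection)
    _check_selection(mobile, selection)
    _check_selection(reference, selection)
    x = mobile[selection] - mobile[selection].mean(axis=0)
    y = reference[selection] - reference[selection].mean(axis=0)
    n = x.shape[0]
    m = x.T @ y
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    g = np.sum(x**2) + np.sum(y**2)
    return float(np.sqrt(max(0.0, (g - 2.0 * lam)) / n))


def _centered_selected(
    coordinates: np.ndarray, selection: np.ndarray
) -> np.ndarray:
    sel = coordinates[:, selection, :]
    return sel - sel.mean(axis=1, keepdims=True)


def _stacked_min_rmsd(
    x: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Minimum RMSD between paired stacks of centered frames (..., A, 3)."""
    gx = np.sum(x**2, axis=(-2, -1))
    gy = np.sum(y**2, axis=(-2, -1))
    cov = np.swapaxes(x, -2, -1) @ y
    s = np.linalg.svd(cov, compute_uv=False)
    det = np.linalg.det(cov)
    trace = s[..., 0] + s[..., 1] + np.where(det < 0, -s[..., 2], s[..., 2])
    n = x.shape[-2]
    msd = np.maximum(0.0, (gx + gy - 2.0 * trace) / n)
    return np.sqrt(msd)


def rmsd_series(
    frames: TrajectoryFrameSet,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame minimum RMSD against a reference frame (A, 3)."""
    if selection is None:
        selection = frames.topology.ca_indices
    selection = np.asarray(selection)
    if frames.n_frames == 0:
        return np.zeros(0)
    _check_selection(frames.coordinates[0], selection)
    _check_selection(np.asarray(reference, dtype=float), selection)
    x = _centered_selected(frames.coordinates, selection)
    ref = np.asarray(reference, dtype=float)[selection]
    y = (ref - ref.mean(axis=0))[None]
    return _stacked_min_rmsd(x, np.broadcast_to(y, x.shape))


def pairwise_rmsd_matrix(
    frames: TrajectoryFrameSet,
    selection: np.ndarray | None = None,
    block_size: int = 512,
) -> np.ndarray:
    """Symmetric matrix of mutual minimum RMSD values.

    Computed in blocks of frame pairs; results are identical to calling
    :func:`superpose` on every pair.
    """
    if selection is None:
        selection = frames.topology.ca_indices
    selection = np.asarray(selection)
    n = frames.n_frames
    if n == 0:
        return np.zeros((0, 0))
    _check_selection(frames.coordinates[0], selection)
    x = _centered_selected(frames.coordinates, selection)
    out = np.zeros((n, n))
    for i0 in range(0, n, block_size):
        i1 = min(i0 + block_size, n)
        for j0 in range(i0, n, block_size):
            j1 = min(j0 + block_size, n)
            block = _stacked_min_rmsd(
                x[i0:i1, None, :, :], x[None, j0:j1, :, :]
            )
            out[i0:i1, j0:j1] = block
            out[j0:j1, i0:i1] = block.T
    np.fill_diagonal(out, 0.0)
    return out


def export_rmsd_series_csv(times_ns, rmsd_nm, path) -> None:
    """Two-column CSV (time ns, rmsd nm)."""
    import pandas as pd

    pd.DataFrame({"time_ns": times_ns, "rmsd_nm": rmsd_nm}).to_csv(
        path, index=False
    )
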