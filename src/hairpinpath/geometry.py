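"""Backbone geometry primitives.

All coordinates are in nanometres, all angles in degrees unless a function
says otherwise.  Every routine is vectorised over a leading ``frames`` axis:
a "point" argument has shape ``(..., 3)`` and broadcasting applies.

The peptide model is the standard backbone (N, H, CA, C, O per residue,
residue 1 carrying no amide hydrogen).  Chains are (re)built from internal
coordinates with ideal bond lengths and bond angles by the natural-extension
reference-frame construction, so any dihedral vector corresponds to a
chemically sane backbone.
"""

from __future__ import annotations

import numpy as np

# Ideal backbone internal coordinates (nm / degrees), standard peptide values.
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
BOND_N_H = 0.100  # reconstructed amide hydrogen

ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distance between two point arrays (broadcasting)."""
    return np.linalg.norm(np.asarray(a) - np.asarray(b), axis=-1)


def angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Interior angle a-b-c in degrees."""
    u = _unit(np.asarray(a) - np.asarray(b))
    v = _unit(np.asarray(c) - np.asarray(b))
    cosang = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    return np.degrees(np.arctan2(y, x))


def place_atom(a, b, c, bond: float, theta: float, chi) -> np.ndarray:
    """Place atom D bonded to C with |CD| = ``bond``, angle B-C-D = ``theta``
    and dihedral A-B-C-D = ``chi`` (degrees).  Vectorised over frames; ``chi``
    may be an array broadcastable against the frame axis."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    chi = np.asarray(chi, dtype=float)
    th = np.radians(theta)
    ch = np.radians(chi)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.broadcast_to(np.cos(th), ch.shape),
            bond * np.sin(th) * np.cos(ch),
            -bond * np.sin(th) * np.sin(ch),
        ],
        axis=-1,
    )
    return c + (
        d_local[..., 0:1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n
    )


def build_backbone(
    phi: np.ndarray, psi: np.ndarray, omega: np.ndarray | None = None
) -> dict[str, np.ndarray]:
    """Build backbone Cartesian coordinates from dihedrals.

    Parameters
    ----------
    phi, psi:
        Arrays of shape ``(R,)`` or ``(F, R)`` in degrees.  ``phi[0]`` is
        unused (no preceding carbonyl); ``psi[R-1]`` orients the C-terminal
        carbonyl oxygen only.
    omega:
        Peptide-bond dihedrals, same shape; defaults to 180 (trans).

    Returns
    -------
    dict with keys ``"N", "H", "CA", "C", "O"``, each ``(F, R, 3)`` (or
    ``(R, 3)`` for 1-D input).  ``H[:, 0]`` is NaN: residue 1 carries no
    amide hydrogen in this model.
    """
    single = np.asarray(phi).ndim == 1
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    if omega is None:
        omega = np.full_like(phi, 180.0)
    else:
        omega = np.atleast_2d(np.asarray(omega, dtype=float))
    n_frames, n_res = phi.shape
    if psi.shape != phi.shape or omega.shape != phi.shape:
        raise ValueError("phi, psi, omega must share a shape")
    if n_res < 2:
        raise ValueError("need at least 2 residues")

    N = np.empty((n_frames, n_res, 3))
    CA = np.empty_like(N)
    C = np.empty_like(N)

    # Seed residue 1 in a canonical pose.
    N[:, 0] = 0.0
    CA[:, 0] = np.array([BOND_N_CA, 0.0, 0.0])
    th = np.radians(ANGLE_N_CA_C)
    C[:, 0] = CA[:, 0] + BOND_CA_C * np.array([-np.cos(th), np.sin(th), 0.0])

    for i in range(n_res - 1):
        N[:, i + 1] = place_atom(
            N[:, i], CA[:, i], C[:, i], BOND_C_N, ANGLE_CA_C_N, psi[:, i]
        )
        CA[:, i + 1] = place_atom(
            CA[:, i], C[:, i], N[:, i + 1], BOND_N_CA, ANGLE_C_N_CA, omega[:, i]
        )
        C[:, i + 1] = place_atom(
            C[:, i], N[:, i + 1], CA[:, i + 1], BOND_CA_C, ANGLE_N_CA_C, phi[:, i + 1]
        )

    # Carbonyl oxygens: sp2 carbon, O anti to the CA/N-next bisector.
    O = np.empty_like(N)
    for i in range(n_res - 1):
        u1 = _unit(CA[:, i] - C[:, i])
        u2 = _unit(N[:, i + 1] - C[:, i])
        O[:, i] = C[:, i] - BOND_C_O * _unit(u1 + u2)
    O[:, -1] = place_atom(
        N[:, -1], CA[:, -1], C[:, -1], BOND_C_O, ANGLE_CA_C_O, psi[:, -1] + 180.0
    )

    # Amide hydrogens (residues 2..R): in the peptide plane, anti to the
    # preceding carbonyl for a trans peptide bond.
    H = np.full_like(N, np.nan)
    for i in range(1, n_res):
        u1 = _unit(C[:, i - 1] - N[:, i])
        u2 = _unit(CA[:, i] - N[:, i])
        H[:, i] = N[:, i] - BOND_N_H * _unit(u1 + u2)

    out = {"N": N, "H": H, "CA": CA, "C": C, "O": O}
    if single:
        out = {k: v[0] for k, v in out.items()}
    return out


def backbone_dihedrals(
    N: np.ndarray, CA: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Measure (phi, psi) from backbone coordinates of shape (F, R, 3).

    Returns arrays of shape (F, R) with NaN where the dihedral is undefined
    (phi of residue 1, psi of residue R).
    """
    n_frames, n_res = N.shape[0], N.shape[1]
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)
    if n_res >= 2:
        phi[:, 1:] = dihedral(C[:, :-1], N[:, 1:], CA[:, 1:], C[:, 1:])
        psi[:, :-1] = dihedral(N[:, :-1], CA[:, :-1], C[:, :-1], N[:, 1:])
    return phi, psi


def reconstruct_amide_hydrogens(
    N: np.ndarray, CA: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Geometric amide-H positions for residues 2..R (NaN for residue 1).

    H sits 0.1 nm from N in the peptide plane, anti to the preceding carbonyl
    (the bisector rule below is equivalent for a trans peptide bond).
    """
    H = np.full_like(N, np.nan)
    u1 = _unit(C[..., :-1, :] - N[..., 1:, :])
    u2 = _unit(CA[..., 1:, :] - N[..., 1:, :])
    H[..., 1:, :] = N[..., 1:, :] - BOND_N_H * _unit(u1 + u2)
    return H
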