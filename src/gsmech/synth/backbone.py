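"""Internal-coordinate backbone construction (NeRF chain extension).

Builds poly-backbone chains (N, H, CA, C, O per residue) from phi/psi
torsion profiles with standard bond lengths and angles. Used by the
helix/coil ensemble generator; side chains are deliberately absent
because secondary-structure assignment reads only the backbone.
"""

from __future__ import annotations

import numpy as np

# standard backbone internal coordinates (Angstrom, degrees)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_N_H = 1.010
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
OMEGA = 180.0

ALPHA_PHI = -57.0
ALPHA_PSI = -47.0
EXTENDED_PHI = -135.0
EXTENDED_PSI = 135.0


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg_: float, torsion_deg: float,
) -> np.ndarray:
    """Position atom d with bond |c-d|, angle b-c-d and torsion a-b-c-d."""
    angle = np.radians(angle_deg_)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi: np.ndarray, psi: np.ndarray
) -> dict[str, np.ndarray]:
    """Build an n-residue backbone from per-residue phi/psi.

    phi[0] and psi[-1] are formally undefined for a chain; they are still
    consumed to keep the arrays aligned (psi[-1] orients the terminal
    carbonyl). Returns arrays of shape (n, 3) for N, CA, C, O and H; the
    first residue has no amide H (NaN row).
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have equal length")
    if n_res < 2:
        raise ValueError("need at least two residues")

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))

    # seed triad for residue 0
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [B_N_CA, 0.0, 0.0]
    ang = np.radians(180.0 - A_N_CA_C)
    C[0] = CA[0] + B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0]) * -1
    C[0] = place_atom(np.array([-1.0, 1.0, 0.0]), N[0], CA[0],
                      B_CA_C, A_N_CA_C, -60.0)

    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1],
                          B_C_N, A_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i],
                           B_N_CA, A_C_N_CA, OMEGA)
        C[i] = place_atom(C[i - 1], N[i], CA[i],
                          B_CA_C, A_N_CA_C, phi[i])

    O = np.zeros((n_res, 3))
    for i in range(n_res):
        # carbonyl O is anti to the following amide N: torsion psi + 180
        O[i] = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi[i] + 180.0)

    H = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        u1 = N[i] - C[i - 1]
        u2 = N[i] - CA[i]
        d = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
        H[i] = N[i] + B_N_H * d / np.linalg.norm(d)

    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}
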