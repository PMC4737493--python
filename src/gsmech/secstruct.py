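"""Helix/loop secondary-structure assignment.

Backbone hydrogen bonds are scored with the electrostatic criterion

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol,

a bond existing when E < -0.5 kcal/mol. A residue is assigned
alpha-helix (H) when both i -> i+4 turns flanking it are intact (the
turn at its predecessor and its own), 3-10 helix (G) analogously from
i -> i+3 turns, and loop (L) otherwise. Only the helix-versus-loop
contrast is modelled: strand and turn classes are deliberately out of
scope, and by default 3-10 helix counts as non-loop (switchable).

Amide hydrogens absent from the structure are reconstructed on the
N-C(alpha)/N-C(prev) bisector at 1.01 A.
"""

from __future__ import annotations

import warnings

import numpy as np

from .stats import ReplicateStatistic
from .topology import Ensemble, Frame, Topology

KS_COUPLING = 0.084 * 332.0      # kcal/mol * Angstrom
KS_BOND_CUTOFF = -0.5            # kcal/mol

HELIX = "H"
HELIX_310 = "G"
LOOP = "L"


def _backbone_rows(topology: Topology) -> list[dict[str, int | None]]:
    """Per-residue backbone atom indices (None where missing)."""
    rows = []
    for key, idx in topology.residue_atom_indices().items():
        entry: dict[str, int | None] = {"N": None, "CA": None, "C": None,
                                        "O": None, "H": None}
        for a in idx:
            name = str(topology.atom_names[a]).upper()
            if name in entry and entry[name] is None:
                entry[name] = int(a)
        entry["chain"] = key[0]
        entry["res_id"] = key[1]
        rows.append(entry)
    return rows


def _amide_hydrogen(
    coords: np.ndarray, rows: list[dict], i: int
) -> np.ndarray | None:
    row = rows[i]
    if row["H"] is not None:
        return coords[row["H"]]
    if i == 0 or rows[i - 1]["chain"] != row["chain"]:
        return None
    prev_c = rows[i - 1]["C"]
    n, ca = row["N"], row["CA"]
    if prev_c is None or n is None or ca is None:
        return None
    u1 = coords[n] - coords[prev_c]
    u2 = coords[n] - coords[ca]
    d = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
    return coords[n] + 1.01 * d / np.linalg.norm(d)


def hbond_energy_ks(
    c: np.ndarray, o: np.ndarray, n: np.ndarray, h: np.ndarray
) -> float:
    """Backbone H-bond energy between an acceptor C=O and a donor N-H."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9           # clashing geometry: treat as bonded (standard cap)
    return float(KS_COUPLING * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn))


def assign_ss(topology: Topology, frame: Frame) -> np.ndarray:
    """Per-residue class array in {H, G, L} for one frame."""
    rows = _backbone_rows(topology)
    n_res = len(rows)
    coords = frame.coords

    def turn(i: int, span: int) -> bool:
        """Is there an i -> i+span bond (C=O of i to N-H of i+span)?"""
        j = i + span
        if i < 0 or j >= n_res:
            return False
        if rows[i]["chain"] != rows[j]["chain"]:
            return False
        c_idx, o_idx = rows[i]["C"], rows[i]["O"]
        n_idx = rows[j]["N"]
        if c_idx is None or o_idx is None or n_idx is None:
            return False
        h = _amide_hydrogen(coords, rows, j)
        if h is None:
            return False
        e = hbond_energy_ks(coords[c_idx], coords[o_idx], coords[n_idx], h)
        return e < KS_BOND_CUTOFF

    classes = np.full(n_res, LOOP, dtype="U1")
    incomplete = [
        i for i, r in enumerate(rows)
        if r["N"] is None or r["CA"] is None or r["C"] is None or r["O"] is None
    ]
    if incomplete:
        warnings.warn(f"residues missing backbone atoms forced to loop: {incomplete}")
    for j in range(n_res):
        if j in incomplete:
            continue
        if turn(j - 1, 4) and turn(j, 4):
            classes[j] = HELIX
        elif turn(j - 1, 3) and turn(j, 3):
            classes[j] = HELIX_310
    return classes


def assign_ss_ensemble(ensemble: Ensemble) -> dict[str, np.ndarray]:
    """(n_frames, n_residues) class arrays per replicate."""
    out = {}
    for label in ensemble.labels:
        frames = [assign_ss(ensemble.topology, f) for f in ensemble.frames(label)]
        out[label] = np.stack(frames)
    return out


def loop_probability(
    ensemble: Ensemble,
    residues: np.ndarray | range | None = None,
    count_310_as_loop: bool = False,
) -> tuple[np.ndarray, list[ReplicateStatistic]]:
    """Per-residue loop fraction with SEM across replicates.

    ``residues`` selects residue serials (all residues when None).
    Returns the selected serials and, aligned with them, one
    ReplicateStatistic per residue.
    """
    assignments = assign_ss_ensemble(ensemble)
    rows = _backbone_rows(ensemble.topology)
    serials = np.asarray([r["res_id"] for r in rows])
    if residues is None:
        sel = np.arange(len(serials))
    else:
        wanted = np.asarray(list(residues))
        sel = np.flatnonzero(np.isin(serials, wanted))
        if sel.size == 0:
            raise ValueError("no matching residues")
    loop_classes = (LOOP, HELIX_310) if count_310_as_loop else (LOOP,)
    stats_out = []
    for i in sel:
        per_rep = [
            float(np.mean(np.isin(assignments[label][:, i], loop_classes)))
            for label in ensemble.labels
        ]
        stats_out.append(ReplicateStatistic(per_rep))
    return serials[sel], stats_out
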