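"""Body-bar constraint networks and their construction from structures."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..criteria import HBondCriteria, angle_deg
from ..topology import Frame, Topology

#: Bar multiplicities by interaction type (molecular body-bar convention).
BARS_COVALENT_ROTATABLE = 5
BARS_COVALENT_LOCKED = 6
BARS_HBOND = 5
BARS_HYDROPHOBIC = 2

_VDW_RADII = {"C": 1.70, "S": 1.80, "N": 1.55, "O": 1.52, "P": 1.80, "H": 1.20}


@dataclass(frozen=True)
class Bar:
    """A multi-bar connection between two bodies.

    ``energy`` is meaningful only for hydrogen-bond-type bars (kcal/mol,
    nonpositive); covalent and hydrophobic bars are never removed during
    thermal unfolding.
    """

    i: int
    j: int
    multiplicity: int
    origin: str = "covalent"            # covalent | hbond | hydrophobic
    energy: float | None = None
    attach_i: tuple[float, float, float] | None = None
    attach_j: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("self-bars are not allowed")
        if not 1 <= self.multiplicity <= 6:
            raise ValueError("bar multiplicity must lie in 1..6")
        if self.origin == "hbond":
            if self.energy is None or not np.isfinite(self.energy) or self.energy > 0:
                raise ValueError("hbond bars require a finite energy <= 0")


@dataclass
class ConstraintNetwork:
    """Bodies plus bars. Bodies are indexed 0..n_bodies-1 and may carry
    labels (e.g. residue serials) used by stability maps."""

    n_bodies: int
    bars: list[Bar] = field(default_factory=list)
    body_labels: list | None = None

    def __post_init__(self) -> None:
        if self.n_bodies < 1:
            raise ValueError("network needs at least one body")
        for bar in self.bars:
            if not (0 <= bar.i < self.n_bodies and 0 <= bar.j < self.n_bodies):
                raise ValueError(f"bar {bar} references a missing body")
        if self.body_labels is None:
            self.body_labels = list(range(self.n_bodies))
        elif len(self.body_labels) != self.n_bodies:
            raise ValueError("body_labels length mismatch")

    def retained_at_cutoff(self, cutoff: float) -> "ConstraintNetwork":
        """Sub-network keeping hbond bars with |energy| >= cutoff.

        Covalent and hydrophobic bars are always retained.
        """
        bars = [
            b for b in self.bars
            if b.origin != "hbond" or abs(b.energy) >= cutoff
        ]
        return ConstraintNetwork(self.n_bodies, bars, list(self.body_labels))


def mayo_hbond_energy(
    donor: np.ndarray,
    hydrogen: np.ndarray | None,
    acceptor: np.ndarray,
    well_depth: float = -8.0,
    r0: float = 2.8,
) -> float:
    """Distance/angle-modulated hydrogen-bond energy (kcal/mol, <= 0).

    A 12-10 radial well in the heavy-atom donor-acceptor distance with
    depth ``well_depth`` at ``r0``, modulated by the squared cosine of the
    donor-H-acceptor angular deviation from linearity. Ideal geometry
    (r = r0, angle = 180 deg) scores the well depth exactly; the value is
    clamped to be nonpositive.
    """
    r = float(np.linalg.norm(np.asarray(donor, float) - np.asarray(acceptor, float)))
    if r <= 0:
        raise ValueError("coincident donor and acceptor")
    radial = 5.0 * (r0 / r) ** 12 - 6.0 * (r0 / r) ** 10   # -1 at r = r0
    if hydrogen is None:
        angular = 1.0
    else:
        theta = angle_deg(donor, hydrogen, acceptor)
        angular = np.cos(np.radians(180.0 - theta)) ** 2
    energy = well_depth * (-radial) * angular
    return float(min(energy, 0.0))


_DONOR_ELEMENTS = {"N", "O", "S"}
_ACCEPTOR_ELEMENTS = {"N", "O", "S"}
_BASIC_ATOMS = {"NZ", "NH1", "NH2", "NE", "ND1", "NE2"}
_ACIDIC_ATOMS = {"OD1", "OD2", "OE1", "OE2"}
_SALT_BRIDGE_ENERGY = -10.0   # below the 0..6 unfolding ladder: never removed


def _attached_hydrogens(
    topology: Topology, coords: np.ndarray, heavy_index: int, max_bond: float = 1.3
) -> list[int]:
    res_mask = (
        (topology.res_ids == topology.res_ids[heavy_index])
        & (topology.chain_ids == topology.chain_ids[heavy_index])
        & (topology.elements == "H")
    )
    out = []
    for h in np.flatnonzero(res_mask):
        if np.linalg.norm(coords[h] - coords[heavy_index]) <= max_bond:
            out.append(int(h))
    return out


def build_network(
    topology: Topology,
    frame: Frame,
    mode: str = "residue",
    criteria: HBondCriteria | None = None,
    min_sequence_separation: int = 2,
    hbond_energies: list[tuple[int, int, float]] | None = None,
) -> ConstraintNetwork:
    """Build a residue-level body-bar network from one structure.

    Each residue becomes one rigid body. Consecutive residues in a chain
    are joined by a rotatable covalent connection (5 bars). Hydrogen bonds
    between residues at sequence separation >= ``min_sequence_separation``
    are scored with :func:`mayo_hbond_energy` (5 bars); salt bridges
    (basic N within 4.0 A of acidic O) get 5 bars with an energy below the
    unfolding ladder; hydrophobic C/S contacts within the van der Waals sum
    plus 0.25 A get 2 bars.

    ``hbond_energies`` optionally supplies precomputed (residue_index_i,
    residue_index_j, energy) triples, replacing geometric detection.
    """
    if mode != "residue":
        raise ValueError("only residue-coarse mode is implemented")
    criteria = criteria or HBondCriteria()
    coords = frame.coords
    res_index = topology.residue_atom_indices()
    keys = list(res_index)
    body_of_key = {k: b for b, k in enumerate(keys)}
    n_bodies = len(keys)
    labels = [k[1] if len({c for c, _ in keys}) == 1 else k for k in keys]
    bars: list[Bar] = []

    def body_of_atom(a: int) -> int:
        return body_of_key[(str(topology.chain_ids[a]), int(topology.res_ids[a]))]

    # backbone covalent links between consecutive residues of a chain
    for (ch1, r1), (ch2, r2) in zip(keys[:-1], keys[1:]):
        if ch1 == ch2:
            a = res_index[(ch1, r1)][0]
            b = res_index[(ch2, r2)][0]
            bars.append(Bar(
                body_of_key[(ch1, r1)], body_of_key[(ch2, r2)],
                BARS_COVALENT_ROTATABLE, "covalent",
                attach_i=tuple(coords[a]), attach_j=tuple(coords[b]),
            ))

    if hbond_energies is not None:
        for bi, bj, energy in hbond_energies:
            bars.append(Bar(int(bi), int(bj), BARS_HBOND, "hbond",
                            energy=float(energy)))
        return ConstraintNetwork(n_bodies, bars, labels)

    is_h = topology.elements == "H"
    heavy = np.flatnonzero(~is_h)
    names = np.char.upper(topology.atom_names)

    # hydrogen bonds (Mayo-scored) and salt bridges
    donors = [
        a for a in heavy
        if topology.elements[a] in _DONOR_ELEMENTS
        and _attached_hydrogens(topology, coords, a)
    ]
    acceptors = [a for a in heavy if topology.elements[a] in _ACCEPTOR_ELEMENTS]
    seen_pairs: set[tuple[int, int]] = set()
    for d in donors:
        hd = _attached_hydrogens(topology, coords, d)
        for a in acceptors:
            if a == d:
                continue
            bd, ba = body_of_atom(d), body_of_atom(a)
            if bd == ba or abs(bd - ba) < min_sequence_separation:
                continue
            dist = np.linalg.norm(coords[d] - coords[a])
            if dist > criteria.d_weak:
                continue
            angles_ok = any(
                angle_deg(coords[d], coords[h], coords[a]) >= criteria.angle_min
                for h in hd
            )
            if not angles_ok:
                continue
            key = (min(bd, ba), max(bd, ba))
            if key in seen_pairs:
                continue
            best_h = max(hd, key=lambda h: angle_deg(coords[d], coords[h], coords[a]))
            energy = mayo_hbond_energy(coords[d], coords[best_h], coords[a])
            if energy >= 0.0:
                continue
            is_salt = (
                str(names[d]) in _BASIC_ATOMS and str(names[a]) in _ACIDIC_ATOMS
                and dist < criteria.salt_bridge_cut
            )
            seen_pairs.add(key)
            bars.append(Bar(
                bd, ba, BARS_HBOND, "hbond",
                energy=_SALT_BRIDGE_ENERGY if is_salt else energy,
                attach_i=tuple(coords[d]), attach_j=tuple(coords[a]),
            ))

    # hydrophobic tethers
    hydrophobic = [
        a for a in heavy
        if topology.elements[a] in ("C", "S") and not str(names[a]) in
        ("C", "CA", "N", "O")
    ]
    seen_hydro: set[tuple[int, int]] = set()
    for ii, a in enumerate(hydrophobic):
        for b in hydrophobic[ii + 1:]:
            ba_, bb_ = body_of_atom(a), body_of_atom(b)
            if ba_ == bb_ or abs(ba_ - bb_) < min_sequence_separation:
                continue
            key = (min(ba_, bb_), max(ba_, bb_))
            if key in seen_hydro or key in seen_pairs:
                continue
            cut = (_VDW_RADII[str(topology.elements[a])]
                   + _VDW_RADII[str(topology.elements[b])] + 0.25)
            if np.linalg.norm(coords[a] - coords[b]) <= cut:
                seen_hydro.add(key)
                bars.append(Bar(
                    ba_, bb_, BARS_HYDROPHOBIC, "hydrophobic",
                    attach_i=tuple(coords[a]), attach_j=tuple(coords[b]),
                ))

    return ConstraintNetwork(n_bodies, bars, labels)
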