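"""Core domain containers: Topology, Frame, Ensemble.

All coordinates are in Angstrom; frame times in picoseconds. Atom order is
fixed by the topology and must be identical across every frame of an
ensemble — that invariant is what makes per-atom statistics (RMSF, density
grids, bridge searches) well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Residue names recognized as water (configurable via Topology.water_names).
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

_ELEMENT_TWO_LETTER = {
    "CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CA", "CU", "SE", "NI", "CO",
}


def infer_element(atom_name: str, element_field: str = "") -> str:
    """Infer a chemical element symbol for an atom.

    The explicit element field (PDB columns 77-78) wins when present;
    otherwise fall back to the leading letters of the atom name, stripping
    digits and greek-position remnants ("1HG2" -> H, "NH1" -> N).
    """
    el = element_field.strip()
    if el:
        return el.capitalize()
    name = atom_name.strip()
    if not name:
        raise ValueError("cannot infer element from empty atom name")
    # leading digits (e.g. 1HG2) mean hydrogen naming
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in _ELEMENT_TWO_LETTER and len(stripped) >= 2 and stripped[1].islower():
        return two.capitalize()
    return stripped[0].upper()


@dataclass
class Topology:
    """Static atom bookkeeping shared by every frame of an ensemble.

    Parameters are parallel arrays over atoms. Residue serials are the
    1-based author numbering of the source PDB; they must be unique within
    a chain but need not be contiguous.
    """

    atom_names: np.ndarray          # str
    elements: np.ndarray            # str, capitalized symbols
    res_ids: np.ndarray             # int, 1-based serials
    res_names: np.ndarray           # str
    chain_ids: np.ndarray           # str
    charges: np.ndarray | None = None      # partial charges, e
    box: np.ndarray | None = None          # orthorhombic lengths, Angstrom
    water_names: frozenset = WATER_RESIDUE_NAMES

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for attr in ("elements", "res_ids", "res_names", "chain_ids"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr} length mismatch")
        self.atom_names = np.asarray(self.atom_names, dtype="U6")
        self.elements = np.asarray(self.elements, dtype="U2")
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.res_names = np.asarray(self.res_names, dtype="U5")
        self.chain_ids = np.asarray(self.chain_ids, dtype="U4")
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if len(self.charges) != n:
                raise ValueError("charges length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def is_water(self) -> np.ndarray:
        return np.isin(self.res_names, sorted(self.water_names))

    def residue_keys(self) -> list[tuple[str, int]]:
        """Ordered unique (chain, res_id) keys."""
        seen: dict[tuple[str, int], None] = {}
        for ch, ri in zip(self.chain_ids, self.res_ids):
            seen.setdefault((str(ch), int(ri)), None)
        return list(seen)

    def residue_atom_indices(self) -> dict[tuple[str, int], np.ndarray]:
        keys = self.residue_keys()
        out: dict[tuple[str, int], list[int]] = {k: [] for k in keys}
        for i, (ch, ri) in enumerate(zip(self.chain_ids, self.res_ids)):
            out[(str(ch), int(ri))].append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def subset(self, indices: np.ndarray) -> "Topology":
        indices = np.asarray(indices, dtype=int)
        return Topology(
            atom_names=self.atom_names[indices],
            elements=self.elements[indices],
            res_ids=self.res_ids[indices],
            res_names=self.res_names[indices],
            chain_ids=self.chain_ids[indices],
            charges=None if self.charges is None else self.charges[indices],
            box=self.box,
            water_names=self.water_names,
        )


@dataclass
class Frame:
    """One snapshot: (n_atoms, 3) Angstrom coordinates plus a time offset."""

    coords: np.ndarray
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coordinates must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("frame contains non-finite coordinates")


@dataclass
class Ensemble:
    """Replicated conformational ensembles over a shared topology.

    ``replicates`` maps a replicate label to an (n_frames, n_atoms, 3)
    coordinate array. Replicate SEM statistics treat each replicate's
    per-frame mean as one observation.
    """

    topology: Topology
    replicates: dict[str, np.ndarray] = field(default_factory=dict)
    frame_interval_ps: float = 20.0

    def __post_init__(self) -> None:
        clean = {}
        for label, coords in self.replicates.items():
            coords = np.asarray(coords, dtype=float)
            if coords.ndim != 3 or coords.shape[2] != 3:
                raise ValueError(f"replicate {label!r}: coords must be (n_frames, n_atoms, 3)")
            if coords.shape[1] != self.topology.n_atoms:
                raise ValueError(
                    f"replicate {label!r}: {coords.shape[1]} atoms vs "
                    f"{self.topology.n_atoms} in topology"
                )
            clean[str(label)] = coords
        if not clean:
            raise ValueError("ensemble requires at least one replicate")
        self.replicates = clean

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @property
    def labels(self) -> list[str]:
        return list(self.replicates)

    def n_frames(self, label: str | None = None) -> int:
        if label is None:
            label = self.labels[0]
        return self.replicates[label].shape[0]

    def frames(self, label: str) -> Iterable[Frame]:
        coords = self.replicates[label]
        for i in range(coords.shape[0]):
            yield Frame(coords[i], time_ps=i * self.frame_interval_ps)

    def times_ns(self, label: str | None = None) -> np.ndarray:
        n = self.n_frames(label)
        return np.arange(n) * self.frame_interval_ps / 1000.0

    @classmethod
    def from_frames(
        cls,
        topology: Topology,
        frames: Sequence[Frame] | np.ndarray,
        label: str = "rep1",
        frame_interval_ps: float = 20.0,
    ) -> "Ensemble":
        if isinstance(frames, np.ndarray):
            coords = frames
        else:
            coords = np.stack([f.coords for f in frames])
        return cls(topology, {label: coords}, frame_interval_ps)

    def equilibrated(self, discard_fraction: float = 0.2) -> "Ensemble":
        """Drop the leading ``discard_fraction`` of frames from each replicate.

        Mirrors restricting analysis to the post-equilibration interval of a
        production run. The default removes the first 20% of frames.
        """
        if not 0.0 <= discard_fraction < 1.0:
            raise ValueError("discard_fraction must be in [0, 1)")
        reps = {}
        for label, coords in self.replicates.items():
            start = int(np.floor(discard_fraction * coords.shape[0]))
            reps[label] = coords[start:]
        return Ensemble(self.topology, reps, self.frame_interval_ps)
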