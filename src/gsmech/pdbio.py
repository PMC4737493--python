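"""Multi-model PDB reading and writing.

Parsing and formatting of the fixed-width v3.3 records is delegated to
biotite; this module adds the ensemble bookkeeping the rest of the package
relies on (model-count validation with a useful error, element inference
fallback, altloc policy) and converts to/from the package's own containers.
"""

from __future__ import annotations

import warnings
from os import PathLike

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .topology import Ensemble, Frame, Topology, infer_element


def _validate_model_atom_counts(lines: list[str]) -> None:
    """Raise if MODEL blocks disagree in atom count, naming the offender."""
    counts: list[tuple[int, int]] = []  # (model number, atom count)
    current: int | None = None
    n = 0
    for line in lines:
        rec = line[:6].strip()
        if rec == "MODEL":
            if current is not None:
                counts.append((current, n))
            try:
                current = int(line.split()[1])
            except (IndexError, ValueError):
                current = (counts[-1][0] + 1) if counts else 1
            n = 0
        elif rec in ("ATOM", "HETATM"):
            n += 1
    if current is not None:
        counts.append((current, n))
    if len(counts) > 1:
        ref_model, ref_n = counts[0]
        for model, cnt in counts[1:]:
            if cnt != ref_n:
                raise ValueError(
                    f"model {model} has {cnt} atoms but model {ref_model} "
                    f"has {ref_n}; all models of an ensemble must share the topology"
                )


def read_pdb(
    path: str | PathLike,
    model_policy: str = "all",
    frame_interval_ps: float = 20.0,
) -> Ensemble:
    """Read a (multi-model) PDB file into a single-replicate Ensemble.

    Parameters
    ----------
    path : path to a PDB file
    model_policy : "all" keeps every MODEL as a frame; "first" keeps one.

    Waters and hetero groups are retained. Alternate locations keep
    conformer A (warning emitted if others were dropped).
    """
    if model_policy not in ("all", "first"):
        raise ValueError(f"unknown model_policy {model_policy!r}")
    pdb = PDBFile.read(str(path))
    _validate_model_atom_counts(pdb.lines)

    altloc_chars = {
        line[16]
        for line in pdb.lines
        if line[:6].strip() in ("ATOM", "HETATM") and len(line) > 16
    }
    if altloc_chars - {" ", "A"}:
        warnings.warn("alternate locations present; keeping altloc A, dropping others")

    if model_policy == "first" or pdb.get_model_count() == 1:
        atoms = pdb.get_structure(model=1, altloc="first")
        stack_coords = atoms.coord[np.newaxis]
        first = atoms
    else:
        stack = pdb.get_structure(model=None, altloc="first")
        stack_coords = stack.coord
        first = stack[0]

    elements = []
    for el, name in zip(first.element, first.atom_name):
        elements.append(infer_element(str(name), str(el)))

    box = None
    if first.box is not None:
        b = np.asarray(first.box, dtype=float)
        diag = np.diagonal(b)
        if np.allclose(b, np.diag(diag)) and np.all(diag > 0):
            box = diag.copy()

    topology = Topology(
        atom_names=np.asarray(first.atom_name, dtype="U6"),
        elements=np.asarray(elements, dtype="U2"),
        res_ids=np.asarray(first.res_id, dtype=int),
        res_names=np.asarray(first.res_name, dtype="U5"),
        chain_ids=np.asarray(first.chain_id, dtype="U4"),
        box=box,
    )
    return Ensemble(
        topology,
        {"rep1": np.asarray(stack_coords, dtype=float)},
        frame_interval_ps=frame_interval_ps,
    )


def _to_atom_array(topology: Topology, coords: np.ndarray) -> struc.AtomArray:
    n = topology.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.atom_name = topology.atom_names
    arr.element = np.char.upper(topology.elements)
    arr.res_id = topology.res_ids
    arr.res_name = topology.res_names
    arr.chain_id = topology.chain_ids
    arr.hetero = topology.is_water()
    return arr


def write_pdb(ensemble: Ensemble, path: str | PathLike) -> None:
    """Write an ensemble as a multi-model PDB file.

    Replicates are concatenated in label order into consecutive MODEL
    blocks; the round trip through :func:`read_pdb` preserves atom names,
    residue serials and coordinates to the fixed-width 3-decimal precision.
    Atom serial overflow beyond 99999 atoms switches to hybrid-36 numbering.
    """
    all_coords = np.concatenate([ensemble.replicates[l] for l in ensemble.labels])
    if all_coords.size == 0:
        raise ValueError("cannot write an empty ensemble")
    topo = ensemble.topology
    n_frames = all_coords.shape[0]
    stack = struc.AtomArrayStack(n_frames, topo.n_atoms)
    template = _to_atom_array(topo, all_coords[0])
    for category in template.get_annotation_categories():
        stack.set_annotation(category, template.get_annotation(category))
    stack.coord = np.asarray(all_coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack, hybrid36=topo.n_atoms > 99999)
    pdb.write(str(path))


def ensemble_to_frames(ensemble: Ensemble, label: str | None = None) -> list[Frame]:
    if label is None:
        label = ensemble.labels[0]
    return list(ensemble.frames(label))
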