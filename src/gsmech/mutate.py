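"""Structure perturbation: alanine-scan side-chain truncation.

Truncating a residue to alanine deletes every side-chain atom beyond the
beta carbon while leaving backbone and Cbeta coordinates untouched. This
mimics removing all noncovalent interactions of one side chain from an
otherwise identical structure — the perturbation used to probe how a single
residue's contacts propagate through a stability map.
"""

from __future__ import annotations

import numpy as np

from .topology import Frame, Topology

# Atoms retained in an alanine residue. Hydrogens on N, CA and CB are kept.
_ALA_HEAVY = {"N", "CA", "C", "O", "OXT", "CB"}
_ALA_HYDROGEN = {"H", "HN", "HA", "H1", "H2", "H3", "HB1", "HB2", "HB3", "HB"}


def _is_kept(name: str) -> bool:
    name = name.upper()
    return name in _ALA_HEAVY or name in _ALA_HYDROGEN


def mutate_to_alanine(
    topology: Topology,
    frame: Frame,
    res_id: int,
    chain: str | None = None,
) -> tuple[Topology, Frame]:
    """Return a copy of (topology, frame) with one residue truncated to ALA.

    Raises
    ------
    ValueError
        If the residue does not exist, is a glycine (no Cbeta to keep), or
        the residue id is ambiguous across chains and no chain is given.
    """
    in_res = topology.res_ids == res_id
    if chain is not None:
        in_res &= topology.chain_ids == chain
    if not in_res.any():
        raise ValueError(f"residue {res_id} not found"
                         + (f" in chain {chain}" if chain else ""))
    chains_hit = set(topology.chain_ids[in_res])
    if chain is None and len(chains_hit) > 1:
        raise ValueError(
            f"residue {res_id} occurs in chains {sorted(chains_hit)}; specify one")

    res_name = str(topology.res_names[in_res][0]).upper()
    if res_name == "GLY":
        raise ValueError("cannot truncate glycine to alanine: no beta carbon")
    if res_name == "ALA":
        return topology, frame

    names = np.char.upper(topology.atom_names)
    drop = in_res & ~np.isin(names, sorted(_ALA_HEAVY | _ALA_HYDROGEN))
    keep = ~drop

    new_res_names = topology.res_names.copy()
    new_res_names[in_res] = "ALA"
    new_topo = Topology(
        atom_names=topology.atom_names[keep],
        elements=topology.elements[keep],
        res_ids=topology.res_ids[keep],
        res_names=new_res_names[keep],
        chain_ids=topology.chain_ids[keep],
        charges=None if topology.charges is None else topology.charges[keep],
        box=topology.box,
        water_names=topology.water_names,
    )
    new_frame = Frame(frame.coords[keep].copy(), time_ps=frame.time_ps)
    return new_topo, new_frame
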