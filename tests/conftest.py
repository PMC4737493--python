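import numpy as np
import pytest

from gsmech.topology import Ensemble, Frame, Topology


@pytest.fixture
def mini_topology() -> Topology:
    """A 7-atom serine-like residue."""
    return Topology(
        atom_names=np.array(["N", "CA", "C", "O", "CB", "OG", "HG"]),
        elements=np.array(["N", "C", "C", "O", "C", "O", "H"]),
        res_ids=np.array([1] * 7),
        res_names=np.array(["SER"] * 7),
        chain_ids=np.array(["A"] * 7),
    )


@pytest.fixture
def mixed_topology() -> Topology:
    """50 atoms across residues, chains, waters — selection playground."""
    rng = np.random.default_rng(0)
    n = 50
    res_ids, res_names, chains, names, elements = [], [], [], [], []
    for i in range(n):
        res = i // 5 + 1
        res_ids.append(res)
        if res <= 6:
            res_names.append(["ALA", "ARG", "SER", "CYS", "GLY", "ASP"][res - 1])
            chains.append("A" if res <= 3 else "B")
            names.append(["N", "CA", "C", "O", "CB"][i % 5])
            elements.append(["N", "C", "C", "O", "C"][i % 5])
        else:
            res_names.append("HOH")
            chains.append("W")
            names.append(["O", "H1", "H2", "O", "H1"][i % 5])
            elements.append(["O", "H", "H", "O", "H"][i % 5])
    return Topology(
        atom_names=np.array(names), elements=np.array(elements),
        res_ids=np.array(res_ids), res_names=np.array(res_names),
        chain_ids=np.array(chains),
    )


@pytest.fixture
def ca_chain():
    """30-residue CA trace topology plus reference frame."""
    n = 30
    topo = Topology(
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        res_ids=np.arange(1, n + 1),
        res_names=np.array(["ALA"] * n),
        chain_ids=np.array(["A"] * n),
    )
    t = np.arange(n)
    coords = np.stack([2.3 * np.cos(t * 0.6), 2.3 * np.sin(t * 0.6), 1.5 * t], axis=1)
    return topo, Frame(coords)


def make_static_ensemble(topology: Topology, coords: np.ndarray,
                         n_frames: int = 5, n_replicates: int = 1) -> Ensemble:
    reps = {f"rep{r+1}": np.repeat(coords[None], n_frames, axis=0)
            for r in range(n_replicates)}
    return Ensemble(topology, reps)
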