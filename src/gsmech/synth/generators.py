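"""Synthetic ensembles with machine-readable ground truth.

Every generator draws from a stream derived by stable hashing of
(seed, generator name, replicate index), so identical specs reproduce
bitwise-identical output and adding a generator never perturbs another.
The generators emulate the statistical structure the analyses consume —
designed fluctuation amplitudes, designed bridge occupancies, designed
loop probabilities, designed energy means/drifts — not the physics of a
solvated protein.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from ..energetics import EffectiveEnergySeries
from ..rigidity.network import Bar, ConstraintNetwork
from ..topology import Ensemble, Frame, Topology
from .backbone import ALPHA_PHI, ALPHA_PSI, build_backbone


@dataclass(frozen=True)
class GeneratorSpec:
    """Common generator parameters; identical spec -> identical output."""

    seed: int
    n_frames: int = 100
    n_replicates: int = 1
    frame_interval_ps: float = 20.0

    def rng(self, generator_name: str, replicate: int = 0) -> np.random.Generator:
        stream = zlib.crc32(generator_name.encode())
        return np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, stream, replicate]))


# ---------------------------------------------------------------------------
# harmonic fluctuation ensembles

def gen_harmonic_ensemble(
    spec: GeneratorSpec,
    reference_topology: Topology,
    reference_frame: Frame,
    sigma_per_atom: np.ndarray,
) -> tuple[Ensemble, dict]:
    """Frames = reference + iid isotropic Gaussian displacement.

    Per-coordinate standard deviation sigma_i gives an expected RMSF of
    sigma_i * sqrt(3) per atom.
    """
    sigma = np.asarray(sigma_per_atom, dtype=float)
    if sigma.shape != (reference_topology.n_atoms,):
        raise ValueError("sigma list must have one entry per atom")
    if np.any(sigma < 0):
        raise ValueError("sigma must be nonnegative")
    reps = {}
    for r in range(spec.n_replicates):
        rng = spec.rng("harmonic", r)
        noise = rng.normal(size=(spec.n_frames, len(sigma), 3)) * sigma[None, :, None]
        reps[f"rep{r + 1}"] = reference_frame.coords[None] + noise
    ens = Ensemble(reference_topology, reps, spec.frame_interval_ps)
    truth = {"sigma": sigma.tolist(),
             "expected_rmsf": (sigma * np.sqrt(3.0)).tolist()}
    return ens, truth


# ---------------------------------------------------------------------------
# water-bridge binding-site fixture

def _bridge_topology(n_bridge: int, n_decoy: int) -> Topology:
    names, elements, res_ids, res_names, chains = [], [], [], [], []

    def add(name, el, rid, rname, ch):
        names.append(name); elements.append(el)
        res_ids.append(rid); res_names.append(rname); chains.append(ch)

    # donor endpoint: serine-like hydroxyl
    add("CB", "C", 1, "DON", "A")
    add("OG", "O", 1, "DON", "A")
    add("HG", "H", 1, "DON", "A")
    # acceptor endpoint: phosphate-like triad
    add("P", "P", 2, "PO4", "A")
    add("O1", "O", 2, "PO4", "A")
    add("O2", "O", 2, "PO4", "A")
    add("O3", "O", 2, "PO4", "A")
    rid = 3
    for _ in range(n_bridge + n_decoy):
        add("O", "O", rid, "HOH", "W")
        add("H1", "H", rid, "HOH", "W")
        add("H2", "H", rid, "HOH", "W")
        rid += 1
    return Topology(
        atom_names=np.array(names), elements=np.array(elements),
        res_ids=np.array(res_ids), res_names=np.array(res_names),
        chain_ids=np.array(chains),
    )


def gen_bridge_site(
    spec: GeneratorSpec,
    gap: float = 7.5,
    occupancy: float = 0.31,
    n_bridge_waters: int = 2,
    decoy_waters: int = 4,
    d_strong: float = 2.8,
) -> tuple[Ensemble, dict]:
    """Two hydrogen-bonding endpoints with a designed bridge occupancy.

    A hydroxyl-like donor and a phosphate-like acceptor triad sit ``gap``
    Angstrom apart. In a Bernoulli(occupancy) subset of frames,
    ``n_bridge_waters`` waters form a geometrically exact strong-criteria
    chain between the endpoints (colinear donors, equal spacing); in the
    remaining frames the same waters are swung far off axis. Decoy waters
    sit permanently out of hydrogen-bonding range of the chain.
    Ground truth: the per-frame, per-replicate bridge labels.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must lie in [0, 1]")
    if n_bridge_waters < 1:
        raise ValueError("need at least one bridge water")
    spacing = gap / (n_bridge_waters + 1)
    if spacing > d_strong:
        raise ValueError(
            f"gap {gap} A cannot be bridged by {n_bridge_waters} waters "
            f"under the {d_strong} A strong criterion (link length {spacing:.2f} A)")

    topo = _bridge_topology(n_bridge_waters, decoy_waters)
    base = np.zeros((topo.n_atoms, 3))
    og = np.array([0.0, 0.0, 0.0])
    base[0] = og + [-1.43, 0.0, 0.0]            # CB
    base[1] = og                                # OG
    # HG points along the chain axis toward the first water
    base[2] = og + [0.96, 0.0, 0.0]
    o1 = np.array([gap, 0.0, 0.0])
    base[4] = o1                                # O1 chain acceptor
    base[3] = o1 + [1.5, 0.0, 0.0]              # P
    base[5] = o1 + [2.0, 1.2, 0.0]              # O2
    base[6] = o1 + [2.0, -1.2, 0.0]             # O3

    chain_positions = [og + [(k + 1) * spacing, 0.0, 0.0]
                       for k in range(n_bridge_waters)]

    truth_labels: dict[str, list[bool]] = {}
    reps = {}
    for r in range(spec.n_replicates):
        rng = spec.rng("bridge", r)
        bridged = rng.random(spec.n_frames) < occupancy
        coords = np.repeat(base[None], spec.n_frames, axis=0)
        for w in range(n_bridge_waters):
            atom0 = 7 + 3 * w
            on_pos = np.asarray(chain_positions[w], float)
            off_pos = on_pos + np.array([0.0, 8.0 + 1.5 * w, 0.0])
            for f in range(spec.n_frames):
                pos = on_pos if bridged[f] else off_pos
                coords[f, atom0] = pos
                # one H donated along the chain axis, one pointing up
                coords[f, atom0 + 1] = pos + [0.96, 0.0, 0.0]
                coords[f, atom0 + 2] = pos + [-0.24, 0.93, 0.0]
        for d in range(decoy_waters):
            atom0 = 7 + 3 * (n_bridge_waters + d)
            pos = np.array([spacing * d, -6.0 - 1.2 * d, 0.0])
            jitter = rng.normal(scale=0.05, size=(spec.n_frames, 3))
            coords[:, atom0] = pos[None] + jitter
            coords[:, atom0 + 1] = coords[:, atom0] + [0.96, 0.0, 0.0]
            coords[:, atom0 + 2] = coords[:, atom0] + [-0.24, 0.93, 0.0]
        reps[f"rep{r + 1}"] = coords
        truth_labels[f"rep{r + 1}"] = bridged.tolist()

    ens = Ensemble(topo, reps, spec.frame_interval_ps)
    truth = {
        "occupancy": occupancy,
        "gap": gap,
        "n_bridge_waters": n_bridge_waters,
        "bridged": truth_labels,
        "endpoint_a": "resname DON and name OG",
        "endpoint_b": "resname PO4 and element O",
    }
    return ens, truth


# ---------------------------------------------------------------------------
# helix/coil switching ensembles

def gen_helix_coil_ensemble(
    spec: GeneratorSpec,
    n_res: int,
    loop_prob: float | np.ndarray,
) -> tuple[Ensemble, dict]:
    """Backbone ensembles with a designed per-residue loop probability.

    Frames start from an ideal alpha-helix (phi = -57, psi = -47). A
    per-residue toggle displaces that residue's carbonyl group far off
    the helix, destroying every helical hydrogen bond it accepts. Under
    the two-turn helix rule (a residue is helical when both flanking
    i -> i+4 turns are intact) an interior residue is a loop exactly when
    its own or its predecessor's toggle fired, so the toggle rate q is
    calibrated as q = 1 - sqrt(1 - p) to make the marginal per-residue
    loop probability equal the designed p. Ground truth: realized
    per-frame, per-residue loop labels.
    """
    if n_res < 6:
        raise ValueError("helix assignment needs i+4 partners: n_res >= 6")
    p = np.broadcast_to(np.asarray(loop_prob, dtype=float), (n_res,)).copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("loop probabilities must lie in [0, 1]")
    q = 1.0 - np.sqrt(1.0 - p)

    bb = build_backbone(np.full(n_res, ALPHA_PHI), np.full(n_res, ALPHA_PSI))
    names, elements, res_ids, res_names, chains, coords0 = [], [], [], [], [], []
    atom_rows: dict[tuple[int, str], int] = {}
    for i in range(n_res):
        for name in ("N", "H", "CA", "C", "O"):
            if name == "H" and i == 0:
                continue
            atom_rows[(i, name)] = len(names)
            names.append(name)
            elements.append(name[0])
            res_ids.append(i + 1)
            res_names.append("ALA")
            chains.append("A")
            coords0.append(bb[name][i])
    topo = Topology(
        atom_names=np.array(names), elements=np.array(elements),
        res_ids=np.array(res_ids), res_names=np.array(res_names),
        chain_ids=np.array(chains),
    )
    base = np.asarray(coords0)

    # displace broken carbonyls radially outward from the helix axis so the
    # moved atoms land far from every amide group and no spurious hydrogen
    # bond can form
    ca = bb["CA"]
    centroid = ca.mean(axis=0)
    axis = np.linalg.svd(ca - centroid)[2][0]
    radial_dirs = np.empty((n_res, 3))
    for i in range(n_res):
        v = ca[i] - centroid
        v = v - np.dot(v, axis) * axis
        norm = np.linalg.norm(v)
        if norm < 1e-6:
            v = np.cross(axis, [1.0, 0.0, 0.0])
            norm = np.linalg.norm(v)
        radial_dirs[i] = v / norm

    reps = {}
    truth_frames: dict[str, list[list[bool]]] = {}
    for r in range(spec.n_replicates):
        rng = spec.rng("helix_coil", r)
        toggles = rng.random((spec.n_frames, n_res)) < q[None, :]
        coords = np.repeat(base[None], spec.n_frames, axis=0)
        for f in range(spec.n_frames):
            for i in np.flatnonzero(toggles[f]):
                shift = 12.0 * radial_dirs[i]
                coords[f, atom_rows[(i, "C")]] += shift
                coords[f, atom_rows[(i, "O")]] += shift
        reps[f"rep{r + 1}"] = coords
        # realized truth under the two-turn rule: interior residue j is a
        # loop iff toggle j-1 or j fired (turn j needs the carbonyl of j,
        # turn j-1 the carbonyl of j-1)
        labels = np.ones((spec.n_frames, n_res), dtype=bool)   # loop by default
        for j in range(1, n_res - 4):
            labels[:, j] = toggles[:, j - 1] | toggles[:, j]
        truth_frames[f"rep{r + 1}"] = labels.tolist()

    ens = Ensemble(topo, reps, spec.frame_interval_ps)
    truth = {
        "designed_loop_prob": p.tolist(),
        "toggle_rate": q.tolist(),
        "interior_residues": list(range(2, n_res - 3)),   # 1-based serials
        "loop_labels": truth_frames,
    }
    return ens, truth


# ---------------------------------------------------------------------------
# effective-energy series

def gen_energy_series(
    spec: GeneratorSpec,
    mean: float,
    slope: float = 0.0,
    noise_sd: float = 0.0,
) -> tuple[list[EffectiveEnergySeries], dict]:
    """value(t) = mean + slope * t + N(0, noise_sd), t in ns."""
    if spec.n_frames < 2:
        raise ValueError("need at least two frames")
    out = []
    for r in range(spec.n_replicates):
        rng = spec.rng("energy", r)
        t = np.arange(spec.n_frames) * spec.frame_interval_ps / 1000.0
        values = mean + slope * t
        if noise_sd > 0:
            values = values + rng.normal(scale=noise_sd, size=spec.n_frames)
        out.append(EffectiveEnergySeries(values, t, label=f"rep{r + 1}"))
    truth = {"mean": mean, "slope": slope, "noise_sd": noise_sd}
    return out, truth


# ---------------------------------------------------------------------------
# body-bar networks

def gen_bar_network(
    spec: GeneratorSpec,
    n_bodies: int,
    bar_spec: list[tuple] | None = None,
    random_density: float | None = None,
) -> tuple[ConstraintNetwork, dict]:
    """Body-bar networks with generic (seeded random) attachments.

    ``bar_spec`` entries are (i, j, multiplicity) or
    (i, j, multiplicity, origin, energy). With ``random_density`` given
    instead, each unordered body pair receives a bar with that
    probability and a random multiplicity in 1..6.
    """
    rng = spec.rng("bar_network")
    bars: list[Bar] = []
    if bar_spec is not None:
        for entry in bar_spec:
            if len(entry) == 3:
                i, j, mult = entry
                origin, energy = "covalent", None
            else:
                i, j, mult, origin, energy = entry
            bars.append(Bar(int(i), int(j), int(mult), origin, energy))
    elif random_density is not None:
        for i in range(n_bodies):
            for j in range(i + 1, n_bodies):
                if rng.random() < random_density:
                    bars.append(Bar(i, j, int(rng.integers(1, 7))))
    else:
        raise ValueError("provide bar_spec or random_density")
    net = ConstraintNetwork(n_bodies, bars)
    truth = {"n_bodies": n_bodies,
             "total_bars": sum(b.multiplicity for b in bars)}
    return net, truth
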