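"""Water structure analysis: density grids, radial distributions, and
water-mediated hydrogen-bond bridges.

The bridge search is the discriminating analysis between a serine and a
cysteine at the mutated position: a chain of hydrogen bonds through one
to three waters connects two solute endpoints, and the chain counts only
when every link satisfies the distance/angle criteria of the requested
class. Strong-class chains are by construction a subset of weak-class
chains.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np

from .criteria import GEOMETRY_EPS, HBondCriteria, angle_deg
from .stats import ReplicateStatistic, superpose
from .topology import Ensemble, Topology


# ---------------------------------------------------------------------------
# density grids

@dataclass
class DensityGrid:
    """Water-oxygen incidence counts on a cubic lattice."""

    origin: np.ndarray       # Angstrom
    spacing: float
    counts: np.ndarray       # integer (nx, ny, nz)
    n_frames: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def density_grid(
    ensemble: Ensemble,
    water_selection: np.ndarray,
    region: tuple[np.ndarray, np.ndarray],
    spacing: float = 0.33,
    fit_selection: np.ndarray | None = None,
) -> dict[str, DensityGrid]:
    """Count water-oxygen incidences on a cubic grid, per replicate.

    ``region`` is an (lower, upper) corner pair in Angstrom; the origin is
    snapped down to a multiple of the spacing for reproducibility. When a
    fit selection is given, every frame is first superposed on the first
    frame of its replicate using those atoms.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    lo = np.asarray(region[0], dtype=float)
    hi = np.asarray(region[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("region has nonpositive volume")
    origin = np.floor(lo / spacing) * spacing
    shape = tuple(int(np.ceil((h - o) / spacing)) for h, o in zip(hi, origin))
    sel = np.asarray(water_selection, dtype=int)

    out = {}
    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        counts = np.zeros(shape, dtype=int)
        ref = coords[0]
        for f in range(coords.shape[0]):
            frame = coords[f]
            if fit_selection is not None and f > 0:
                sup = superpose(frame, ref, np.asarray(fit_selection, int))
                frame = sup.apply(frame)
            if sel.size == 0:
                continue
            pts = frame[sel]
            cells = np.floor((pts - origin) / spacing).astype(int)
            ok = np.all((cells >= 0) & (cells < np.asarray(shape)), axis=1)
            for cx, cy, cz in cells[ok]:
                counts[cx, cy, cz] += 1
        out[label] = DensityGrid(origin, spacing, counts, coords.shape[0])
    return out


def isopleth_threshold(
    grid: DensityGrid, fraction: float = 0.8
) -> tuple[float, np.ndarray]:
    """Occupancy threshold at ``fraction`` of the maximum cell count.

    Returns the threshold and the boolean mask of cells at or above it —
    the cells an isopleth drawn at that level encompasses.
    """
    if grid.counts.max() == 0:
        raise ValueError("all-zero density grid")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    threshold = fraction * float(grid.counts.max())
    return threshold, grid.counts >= threshold


def write_opendx(grid: DensityGrid, path: str | PathLike) -> None:
    """Write a density grid as an OpenDX scalar field."""
    nx, ny, nz = grid.shape
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}",
        f"delta {grid.spacing:.6f} 0 0",
        f"delta 0 {grid.spacing:.6f} 0",
        f"delta 0 0 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.counts.astype(float).ravel(order="C")
    for i in range(0, len(flat), 3):
        chunk = flat[i:i + 3]
        lines.append(" ".join(f"{v:.6e}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# radial distribution functions

@dataclass
class RDFProfile:
    bin_centers: np.ndarray
    g_mean: np.ndarray
    g_sem: np.ndarray
    per_replicate: dict[str, np.ndarray]
    reference_density: float     # Angstrom^-3


def rdf(
    ensemble: Ensemble,
    center: np.ndarray,
    water_oxygens: np.ndarray,
    dr: float = 0.1,
    r_max: float = 8.0,
) -> RDFProfile:
    """g(r) of water oxygens around a single center atom.

    Normalization: with an orthorhombic box on the topology the reference
    density is N_waters / V_box (periodic convention, minimum-image not
    applied — fixtures keep waters within half a box length); otherwise
    the count-matched density of the enclosing r_max sphere is used, so
    an ideal-gas fixture integrates to g = 1.
    """
    center = np.asarray(center, dtype=int)
    if center.size != 1:
        raise ValueError("rdf requires exactly one center atom")
    if dr <= 0:
        raise ValueError("dr must be positive")
    waters = np.asarray(water_oxygens, dtype=int)
    edges = np.arange(0.0, r_max + dr, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    box = ensemble.topology.box
    per = {}
    rho_used = 0.0
    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        hist = np.zeros(len(centers))
        n_inside = 0
        for f in range(coords.shape[0]):
            d = np.linalg.norm(coords[f, waters] - coords[f, center[0]], axis=1)
            hist += np.histogram(d, bins=edges)[0]
            n_inside += int(np.sum(d < r_max))
        n_frames = coords.shape[0]
        if box is not None:
            rho = len(waters) / float(np.prod(box))
        else:
            rho = (n_inside / n_frames) / (4.0 / 3.0 * np.pi * r_max ** 3)
        rho_used = rho
        with np.errstate(divide="ignore", invalid="ignore"):
            g = hist / n_frames / (rho * shell_vol) if rho > 0 else np.zeros_like(hist)
        per[label] = g
    arr = np.stack(list(per.values()))
    mean = arr.mean(axis=0)
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
           if arr.shape[0] > 1 else np.zeros_like(mean))
    return RDFProfile(centers, mean, sem, per, rho_used)


# ---------------------------------------------------------------------------
# water-mediated bridges

@dataclass
class BridgeChain:
    """endpoint_a -> water oxygens -> endpoint_b, all links valid."""

    atoms: list[int]          # [a, w1, ..., wk, b]
    hbond_class: str
    frame: int
    replicate: str = ""

    @property
    def n_waters(self) -> int:
        return len(self.atoms) - 2


def _water_oxygens(topology: Topology) -> np.ndarray:
    return np.flatnonzero(topology.is_water() & (topology.elements == "O"))


def _hydrogens_by_heavy(topology: Topology, coords: np.ndarray) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    hyd = np.flatnonzero(topology.elements == "H")
    heavy = np.flatnonzero(topology.elements != "H")
    for h in hyd:
        same = heavy[
            (topology.res_ids[heavy] == topology.res_ids[h])
            & (topology.chain_ids[heavy] == topology.chain_ids[h])
        ]
        if same.size == 0:
            continue
        d = np.linalg.norm(coords[same] - coords[h], axis=1)
        nearest = same[np.argmin(d)]
        if d.min() <= 1.3:
            out.setdefault(int(nearest), []).append(int(h))
    return out


def _link_ok(
    x: int, y: int, coords: np.ndarray,
    hydrogens: dict[int, list[int]],
    criteria: HBondCriteria, hbond_class: str,
) -> bool:
    d = np.linalg.norm(coords[x] - coords[y])
    if d > criteria.distance_cut(hbond_class) + GEOMETRY_EPS:
        return False
    hx = hydrogens.get(x, [])
    hy = hydrogens.get(y, [])
    if not hx and not hy:
        return True   # distance-only fallback
    for h in hx:
        if angle_deg(coords[x], coords[h], coords[y]) >= criteria.angle_min - GEOMETRY_EPS:
            return True
    for h in hy:
        if angle_deg(coords[y], coords[h], coords[x]) >= criteria.angle_min - GEOMETRY_EPS:
            return True
    return False


def find_bridges(
    topology: Topology,
    coords: np.ndarray,
    endpoint_a: np.ndarray,
    endpoint_b: np.ndarray,
    criteria: HBondCriteria | None = None,
    hbond_class: str = "strong",
    max_waters: int = 3,
    frame: int = 0,
    replicate: str = "",
) -> list[BridgeChain]:
    """All simple water chains linking two endpoint groups in one frame.

    Chains run endpoint_a -> w1 -> ... -> wk -> endpoint_b with
    1 <= k <= max_waters distinct waters, every link satisfying the
    requested hydrogen-bond class. Roles (donor vs acceptor) per link are
    decided by which side carries hydrogens; a link with no hydrogens on
    either side degrades to the distance-only test.
    """
    if max_waters < 1:
        raise ValueError("max_waters must be >= 1")
    criteria = criteria or HBondCriteria()
    ea = np.asarray(endpoint_a, dtype=int)
    eb = np.asarray(endpoint_b, dtype=int)
    if np.intersect1d(ea, eb).size:
        raise ValueError("endpoint selections must be disjoint")
    waters = _water_oxygens(topology)
    hydrogens = _hydrogens_by_heavy(topology, coords)

    # prefilter waters anywhere near the endpoints' joint bounding sphere
    cut = criteria.distance_cut(hbond_class)
    anchor = coords[np.concatenate([ea, eb])].mean(axis=0)
    span = max(np.linalg.norm(coords[np.concatenate([ea, eb])] - anchor, axis=1).max(),
               1.0)
    reach = span + cut * (max_waters + 1)
    near = waters[np.linalg.norm(coords[waters] - anchor, axis=1) <= reach]

    chains: list[BridgeChain] = []

    def extend(path: list[int], used: set[int]) -> None:
        last = path[-1]
        if len(path) - 1 >= 1:   # at least one water in the path
            for b in eb:
                if _link_ok(last, int(b), coords, hydrogens, criteria, hbond_class):
                    chains.append(BridgeChain(path + [int(b)], hbond_class,
                                              frame, replicate))
        if len(path) - 1 >= max_waters:
            return
        for w in near:
            w = int(w)
            if w in used:
                continue
            if _link_ok(last, w, coords, hydrogens, criteria, hbond_class):
                extend(path + [w], used | {w})

    for a in ea:
        extend([int(a)], set())
    return chains


def bridge_frequency(
    ensemble: Ensemble,
    endpoint_a: np.ndarray,
    endpoint_b: np.ndarray,
    criteria: HBondCriteria | None = None,
    hbond_class: str = "strong",
    max_waters: int = 3,
) -> ReplicateStatistic:
    """Fraction of frames with at least one valid bridge, per replicate."""
    criteria = criteria or HBondCriteria()
    per = []
    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        hits = 0
        for f in range(coords.shape[0]):
            found = find_bridges(
                ensemble.topology, coords[f], endpoint_a, endpoint_b,
                criteria, hbond_class, max_waters, frame=f, replicate=label)
            if found:
                hits += 1
        per.append(hits / coords.shape[0])
    return ReplicateStatistic(per)
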