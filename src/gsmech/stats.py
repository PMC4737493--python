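"""Geometric ensemble statistics.

Replicate bookkeeping follows the three-independent-trajectories
convention: each replicate's per-frame mean is one observation, summaries
are reported as grand mean +/- SEM over replicates, and replicate-mean
comparisons use the two-sided Student t-test (Welch where stated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .criteria import GEOMETRY_EPS, HBondCriteria, angle_deg
from .topology import Ensemble, Frame


@dataclass
class ReplicateStatistic:
    """Grand mean +/- SEM over per-replicate means."""

    per_replicate_means: list[float]
    grand_mean: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self) -> None:
        means = np.asarray(self.per_replicate_means, dtype=float)
        self.grand_mean = float(means.mean())
        if len(means) > 1:
            self.sem = float(means.std(ddof=1) / np.sqrt(len(means)))
        else:
            self.sem = 0.0

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate_means)


@dataclass
class SuperposeResult:
    rotation: np.ndarray      # 3x3, det = +1
    translation: np.ndarray   # applied after rotation
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray | Frame,
    reference: np.ndarray | Frame,
    selection: np.ndarray | None = None,
) -> SuperposeResult:
    """Least-squares rigid superposition (Kabsch).

    Returns the rotation/translation minimizing the RMSD of the selected
    atoms of ``mobile`` onto ``reference``, together with that minimal
    RMSD. Requires at least three non-collinear selected atoms.
    """
    mob = mobile.coords if isinstance(mobile, Frame) else np.asarray(mobile, float)
    ref = reference.coords if isinstance(reference, Frame) else np.asarray(reference, float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        mob_s, ref_s = mob[sel], ref[sel]
    else:
        mob_s, ref_s = mob, ref
    if len(mob_s) < 3:
        raise ValueError("superposition needs at least three atoms")
    mc = mob_s.mean(axis=0)
    rc = ref_s.mean(axis=0)
    a = mob_s - mc
    b = ref_s - rc
    if np.linalg.matrix_rank(a, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    moved = a @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
    return SuperposeResult(rotation=rot, translation=trans, rmsd=rmsd)


def rmsd_series(
    ensemble: Ensemble,
    fit_selection: np.ndarray,
    measure_selection: np.ndarray | None = None,
    reference: Frame | np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], ReplicateStatistic]:
    """Per-frame RMSD after fitting each frame on ``fit_selection``.

    The measured atom set may differ from the fitted one (e.g. ligand
    RMSD after a protein fit). The reference defaults to the first frame
    of the first replicate. Returns per-replicate series plus the
    replicate statistic of the series means.
    """
    fit_sel = np.asarray(fit_selection, dtype=int)
    if fit_sel.size == 0:
        raise ValueError("empty fit selection")
    meas_sel = fit_sel if measure_selection is None else np.asarray(measure_selection, int)
    if meas_sel.size == 0:
        raise ValueError("empty measure selection")
    if reference is None:
        ref = ensemble.replicates[ensemble.labels[0]][0]
    else:
        ref = reference.coords if isinstance(reference, Frame) else np.asarray(reference)

    series = {}
    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        vals = np.empty(coords.shape[0])
        for f in range(coords.shape[0]):
            sup = superpose(coords[f], ref, fit_sel)
            moved = sup.apply(coords[f][meas_sel])
            vals[f] = np.sqrt(np.mean(np.sum((moved - ref[meas_sel]) ** 2, axis=1)))
        series[label] = vals
    stat = ReplicateStatistic([float(v.mean()) for v in series.values()])
    return series, stat


def _iterated_mean_fit(
    coords: np.ndarray, selection: np.ndarray, n_iter: int = 2
) -> np.ndarray:
    """Superpose all frames onto their iterated mean structure."""
    fitted = coords.copy()
    for _ in range(n_iter):
        mean_ref = fitted.mean(axis=0)
        for f in range(fitted.shape[0]):
            sup = superpose(fitted[f], mean_ref, selection)
            fitted[f] = sup.apply(fitted[f])
    return fitted


def rmsf(
    ensemble: Ensemble,
    selection: np.ndarray | None = None,
    per: str = "atom",
    fit_iterations: int = 2,
) -> tuple[dict[str, np.ndarray], list[ReplicateStatistic]]:
    """Root mean-square fluctuation about the ensemble mean.

    Each replicate is superposed onto its iterated mean structure before
    fluctuations are measured. ``per="residue"`` averages atomic RMSF
    within each residue (order of residues follows the topology). Returns
    per-replicate profiles and a per-unit ReplicateStatistic list.
    """
    topo = ensemble.topology
    sel = np.arange(topo.n_atoms) if selection is None else np.asarray(selection, int)
    if sel.size == 0:
        raise ValueError("empty selection")
    profiles = {}
    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        if coords.shape[0] < 2:
            raise ValueError("RMSF needs at least two frames")
        fitted = _iterated_mean_fit(coords, sel, fit_iterations)
        mean_pos = fitted.mean(axis=0)
        fluct = np.sqrt(np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0))
        per_atom = fluct[sel]
        if per == "atom":
            profiles[label] = per_atom
        elif per == "residue":
            keys = []
            seen = {}
            for a in sel:
                k = (str(topo.chain_ids[a]), int(topo.res_ids[a]))
                if k not in seen:
                    seen[k] = []
                    keys.append(k)
                seen[k].append(a)
            res_vals = [float(np.mean(fluct[np.asarray(seen[k])])) for k in keys]
            profiles[label] = np.asarray(res_vals)
        else:
            raise ValueError(f"unknown per mode {per!r}")
    arr = np.stack(list(profiles.values()))
    stats_out = [ReplicateStatistic(list(arr[:, i])) for i in range(arr.shape[1])]
    return profiles, stats_out


def core_region(
    rmsf_per_residue: np.ndarray,
    residue_serials: np.ndarray | None = None,
    keep_fraction: float = 0.9,
) -> np.ndarray:
    """Serials of the lowest-RMSF ``keep_fraction`` of residues.

    Ties are broken by ascending residue serial so the core region is
    deterministic.
    """
    vals = np.asarray(rmsf_per_residue, dtype=float)
    if vals.size == 0:
        raise ValueError("empty RMSF input")
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    serials = (np.arange(1, len(vals) + 1) if residue_serials is None
               else np.asarray(residue_serials))
    n_keep = int(np.floor(keep_fraction * len(vals)))
    order = np.lexsort((serials, vals))
    kept = serials[np.sort(order[:n_keep])]
    return kept


def distance_series(
    ensemble: Ensemble,
    group_a: np.ndarray,
    group_b: np.ndarray,
    mode: str = "centroid",
) -> tuple[dict[str, np.ndarray], ReplicateStatistic]:
    """Per-frame distance between two atom groups.

    ``centroid`` measures centroid-to-centroid; ``min`` the closest pair.
    Overlapping groups are legal but warned about.
    """
    ga = np.asarray(group_a, dtype=int)
    gb = np.asarray(group_b, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("distance groups must be non-empty")
    if np.intersect1d(ga, gb).size:
        warnings.warn("distance groups overlap; distance still computed")
    series = {}
    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        if mode == "centroid":
            ca = coords[:, ga].mean(axis=1)
            cb = coords[:, gb].mean(axis=1)
            series[label] = np.linalg.norm(ca - cb, axis=1)
        elif mode == "min":
            diff = coords[:, ga, None, :] - coords[:, None, gb, :]
            series[label] = np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))
        else:
            raise ValueError(f"unknown distance mode {mode!r}")
    stat = ReplicateStatistic([float(v.mean()) for v in series.values()])
    return series, stat


@dataclass(frozen=True)
class HBondEvent:
    donor: int
    hydrogen: int | None
    acceptor: int
    frame: int
    replicate: str
    hbond_class: str          # "strong" or "weak" (strong events nest in weak)


def _donor_hydrogens(topology, coords0, donors: np.ndarray) -> dict[int, list[int]]:
    hyd = np.flatnonzero(topology.elements == "H")
    out: dict[int, list[int]] = {int(d): [] for d in donors}
    for d in donors:
        same_res = (
            (topology.res_ids[hyd] == topology.res_ids[d])
            & (topology.chain_ids[hyd] == topology.chain_ids[d])
        )
        for h in hyd[same_res]:
            if np.linalg.norm(coords0[h] - coords0[d]) <= 1.3:
                out[int(d)].append(int(h))
    return out


def hbond_events(
    ensemble: Ensemble,
    donors: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria | None = None,
) -> list[HBondEvent]:
    """Enumerate hydrogen-bond events between donor and acceptor atoms.

    An event requires heavy-atom donor-acceptor distance <= the class
    cutoff (inclusive) and donor-H-acceptor angle >= the angle cutoff
    (inclusive). Every strong event is also emitted as a weak event, so
    the strong set nests inside the weak set. Donors without attached
    hydrogens fall back to the distance-only test with a warning.
    """
    criteria = criteria or HBondCriteria()
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    topo = ensemble.topology
    first = ensemble.replicates[ensemble.labels[0]][0]
    dh = _donor_hydrogens(topo, first, donors)
    if any(len(v) == 0 for v in dh.values()):
        warnings.warn("donor(s) without attached hydrogens: distance-only test")

    events: list[HBondEvent] = []
    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        for f in range(coords.shape[0]):
            c = coords[f]
            for d in donors:
                for a in acceptors:
                    if a == d:
                        continue
                    dist = np.linalg.norm(c[d] - c[a])
                    if dist > criteria.d_weak + GEOMETRY_EPS:
                        continue
                    hs = dh[int(d)]
                    best_h: int | None = None
                    if hs:
                        ok = [h for h in hs
                              if angle_deg(c[d], c[h], c[a])
                              >= criteria.angle_min - GEOMETRY_EPS]
                        if not ok:
                            continue
                        best_h = ok[0]
                    cls = ("strong" if dist <= criteria.d_strong + GEOMETRY_EPS
                           else "weak")
                    events.append(HBondEvent(int(d), best_h, int(a), f, label, cls))
    return events


def occupancy(
    events: list[HBondEvent] | dict[str, np.ndarray],
    n_frames: int,
    labels: list[str] | None = None,
    strong_only: bool = False,
) -> ReplicateStatistic:
    """Fraction of frames with at least one qualifying event, per replicate.

    Accepts either an HBondEvent list or a per-replicate boolean frame
    series. Strong events count toward weak occupancy (nesting).
    """
    if n_frames <= 0:
        raise ValueError("n_frames must be positive")
    if isinstance(events, dict):
        return ReplicateStatistic(
            [float(np.mean(np.asarray(v, dtype=bool))) for v in events.values()])
    if labels is None:
        labels = sorted({e.replicate for e in events}) or ["rep1"]
    per = []
    for label in labels:
        present = {
            e.frame for e in events
            if e.replicate == label and (not strong_only or e.hbond_class == "strong")
        }
        per.append(len(present) / n_frames)
    return ReplicateStatistic(per)


def salt_bridge_occupancy(
    ensemble: Ensemble,
    basic_group: np.ndarray,
    acidic_group: np.ndarray,
    cutoff: float = 4.0,
) -> ReplicateStatistic:
    """Occupancy of the distance-only salt-bridge criterion (strictly <)."""
    ga = np.asarray(basic_group, dtype=int)
    gb = np.asarray(acidic_group, dtype=int)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("groups must be non-empty")
    per = []
    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        diff = coords[:, ga, None, :] - coords[:, None, gb, :]
        dmin = np.sqrt((diff ** 2).sum(-1)).min(axis=(1, 2))
        per.append(float(np.mean(dmin < cutoff)))
    return ReplicateStatistic(per)


def _degenerate_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float] | None:
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    return None


def t_test_two_sided(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Student t-test (equal variances pooled)."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per sample")
    deg = _degenerate_two_sample(a, b)
    if deg is not None:
        return deg
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def welch_test(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Welch t-test (Welch-Satterthwaite degrees of freedom)."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per sample")
    deg = _degenerate_two_sample(a, b)
    if deg is not None:
        return deg
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def one_sample_t(sample, mu0: float = 0.0) -> tuple[float, float]:
    """Two-sided one-sample t-test against ``mu0``."""
    a = np.asarray(sample, float)
    if len(a) < 2:
        raise ValueError("need at least two values")
    if np.allclose(a, a[0]):
        if np.isclose(a.mean(), mu0):
            return 0.0, 1.0
        raise ValueError("zero variance with mean differing from mu0")
    t, p = sps.ttest_1samp(a, mu0)
    return float(t), float(p)
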