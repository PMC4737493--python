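"""Effective binding-energy aggregation and relative binding energies.

Implements the single-trajectory aggregation contract: per-frame effective
binding energies (gas-phase interaction plus solvation terms) are averaged
per replicate, replicate SEMs are combined by root-sum-square error
propagation, and mutant-minus-wild-type differences are tested against
zero with a one-sample t-test. A drift diagnostic (least-squares slope of
energy versus time) guards against unequilibrated series.

The built-in "toy" energy model is a screened Coulomb term (uniform
interior dielectric of 4), a Lennard-Jones term, and a surface-area
nonpolar term gamma * dSASA; a numerical Poisson-Boltzmann solver is out
of scope, and solver output can be supplied as per-frame component tables
instead ("table" model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .topology import Ensemble

COULOMB_CONSTANT = 332.0637      # kcal/mol * Angstrom / e^2
INTERIOR_DIELECTRIC = 4.0
GAMMA_SASA = 0.00542             # kcal / (mol * Angstrom^2)
BETA_SASA = 0.92                 # kcal/mol; species-independent, cancels in dG
GAS_CONSTANT = 1.9872e-3         # kcal / (mol * K)

#: Lennard-Jones parameters by element: (rmin/2 in Angstrom, epsilon kcal/mol)
DEFAULT_LJ = {
    "H": (0.6000, 0.0157),
    "C": (1.9080, 0.1094),
    "N": (1.8240, 0.1700),
    "O": (1.6612, 0.2100),
    "S": (2.0000, 0.2500),
    "P": (2.1000, 0.2000),
}


@dataclass
class EffectiveEnergySeries:
    """Per-frame effective energies (kcal/mol) on a ns time axis."""

    values: np.ndarray
    times_ns: np.ndarray
    components: dict[str, np.ndarray] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        if self.values.shape != self.times_ns.shape:
            raise ValueError("values and times must be aligned")
        if len(self.times_ns) > 1 and not np.all(np.diff(self.times_ns) > 0):
            raise ValueError("time axis must be strictly increasing")
        if self.components:
            total = sum(np.asarray(v, float) for v in self.components.values())
            if not np.allclose(total, self.values, atol=1e-6):
                raise ValueError("components do not sum to the total energy")

    @property
    def n_frames(self) -> int:
        return len(self.values)


@dataclass
class BindingEnergyResult:
    """One replicate's aggregate: mean, SEM, drift."""

    mean: float
    sem: float
    drift_slope: float          # kcal/mol/ns
    n_frames: int
    label: str = ""


@dataclass
class AggregateBindingEnergy:
    """All replicates of one system, combined by error propagation."""

    per_replicate: list[BindingEnergyResult]
    mean: float = field(init=False)
    sem: float = field(init=False)

    def __post_init__(self) -> None:
        means = [r.mean for r in self.per_replicate]
        self.mean = float(np.mean(means))
        self.sem = float(np.sqrt(sum(r.sem ** 2 for r in self.per_replicate)))


@dataclass
class RelativeBindingEnergy:
    """Mutant-minus-wild-type effective binding energy with propagated SEM.

    Positive ddg means weaker binding in the mutant.
    """

    ddg: float
    sem_total: float
    p: float
    per_replicate_ddg: list[float]
    mutant_label: str = "mutant"
    wildtype_label: str = "wildtype"


def _toy_frame_energy(
    coords: np.ndarray,
    charges: np.ndarray,
    elements: np.ndarray,
    receptor: np.ndarray,
    ligand: np.ndarray,
    lj_params: dict[str, tuple[float, float]],
    sasa_term: bool,
) -> tuple[float, float, float]:
    """(coulomb, lennard_jones, nonpolar) receptor-ligand cross terms."""
    rc = coords[receptor]
    lc = coords[ligand]
    diff = rc[:, None, :] - lc[None, :, :]
    r = np.sqrt(np.sum(diff ** 2, axis=-1))
    r = np.maximum(r, 1e-6)

    qq = charges[receptor][:, None] * charges[ligand][None, :]
    e_coul = float(np.sum(COULOMB_CONSTANT * qq / (INTERIOR_DIELECTRIC * r)))

    rmin_h = np.array([lj_params[e][0] for e in elements])
    eps = np.array([lj_params[e][1] for e in elements])
    rmin_ij = rmin_h[receptor][:, None] + rmin_h[ligand][None, :]
    eps_ij = np.sqrt(eps[receptor][:, None] * eps[ligand][None, :])
    frac = (rmin_ij / r) ** 6
    e_lj = float(np.sum(eps_ij * (frac ** 2 - 2.0 * frac)))

    e_np = 0.0
    if sasa_term:
        e_np = GAMMA_SASA * _delta_sasa(coords, elements, receptor, ligand)
    return e_coul, e_lj, e_np


def _delta_sasa(coords, elements, receptor, ligand) -> float:
    import biotite.structure as struc

    def sasa_of(indices: np.ndarray) -> float:
        arr = struc.AtomArray(len(indices))
        arr.coord = np.asarray(coords[indices], dtype=np.float32)
        arr.element = np.char.upper(np.asarray(elements)[indices])
        arr.atom_name = arr.element
        arr.res_id = np.ones(len(indices), dtype=int)
        arr.res_name = np.full(len(indices), "UNK")
        arr.chain_id = np.full(len(indices), "A")
        vals = struc.sasa(arr, vdw_radii="Single", point_number=200)
        return float(np.nansum(vals))

    both = np.concatenate([receptor, ligand])
    return sasa_of(both) - sasa_of(receptor) - sasa_of(ligand)


def effective_energy_series(
    ensemble: Ensemble,
    receptor_selection: np.ndarray,
    ligand_selection: np.ndarray,
    model: str = "toy",
    tables: dict[str, pd.DataFrame | str | PathLike] | None = None,
    lj_params: dict[str, tuple[float, float]] | None = None,
    sasa_term: bool = True,
) -> dict[str, EffectiveEnergySeries]:
    """Per-frame effective binding energies for every replicate.

    In the toy model each frame contributes
    dG_frame = E(complex) - E(receptor) - E(ligand), which reduces to the
    receptor-ligand Coulomb/LJ cross terms plus gamma * dSASA. The table
    model passes externally computed per-frame components through after
    validation.
    """
    receptor = np.asarray(receptor_selection, dtype=int)
    ligand = np.asarray(ligand_selection, dtype=int)
    if len(receptor) == 0 or len(ligand) == 0:
        raise ValueError("receptor and ligand selections must be non-empty")
    if np.intersect1d(receptor, ligand).size:
        raise ValueError("receptor and ligand selections overlap")

    out: dict[str, EffectiveEnergySeries] = {}
    if model == "table":
        if not tables:
            raise ValueError("table model requires per-replicate component tables")
        for label in ensemble.labels:
            tab = tables[label]
            if not isinstance(tab, pd.DataFrame):
                tab = pd.read_csv(tab)
            required = {"frame", "time_ns", "e_mm", "g_polar", "g_nonpolar"}
            if not required.issubset(tab.columns):
                raise ValueError(f"component table missing columns {required - set(tab.columns)}")
            if len(tab) != ensemble.n_frames(label):
                raise ValueError(
                    f"table for {label!r} has {len(tab)} rows but the replicate "
                    f"has {ensemble.n_frames(label)} frames")
            comps = {k: tab[k].to_numpy(float) for k in ("e_mm", "g_polar", "g_nonpolar")}
            out[label] = EffectiveEnergySeries(
                values=sum(comps.values()),
                times_ns=tab["time_ns"].to_numpy(float),
                components=comps,
                label=label,
            )
        return out

    if model != "toy":
        raise ValueError(f"unknown energy model {model!r}")
    topo = ensemble.topology
    if topo.charges is None:
        raise ValueError("toy energy model requires partial charges on the topology")
    lj = dict(DEFAULT_LJ)
    if lj_params:
        lj.update(lj_params)
    missing = set(topo.elements[np.concatenate([receptor, ligand])]) - set(lj)
    if missing:
        raise ValueError(f"no Lennard-Jones parameters for elements {missing}")

    for label in ensemble.labels:
        coords = ensemble.replicates[label]
        comps = {"e_mm": [], "g_polar": [], "g_nonpolar": []}
        for f in range(coords.shape[0]):
            e_coul, e_lj, e_np = _toy_frame_energy(
                coords[f], topo.charges, topo.elements, receptor, ligand,
                lj, sasa_term)
            comps["e_mm"].append(e_coul + e_lj)
            comps["g_polar"].append(0.0)   # screening is folded into e_mm
            comps["g_nonpolar"].append(e_np)
        comps = {k: np.asarray(v) for k, v in comps.items()}
        out[label] = EffectiveEnergySeries(
            values=comps["e_mm"] + comps["g_polar"] + comps["g_nonpolar"],
            times_ns=ensemble.times_ns(label),
            components=comps,
            label=label,
        )
    return out


def drift_slope(series: EffectiveEnergySeries) -> float:
    """Ordinary least-squares slope of energy versus time (kcal/mol/ns)."""
    if series.n_frames < 2:
        raise ValueError("drift needs at least two frames")
    t = series.times_ns
    if np.ptp(t) == 0:
        raise ValueError("constant time axis")
    return float(np.polyfit(t, series.values, 1)[0])


def _series_sem(values: np.ndarray, estimator: str, n_blocks: int) -> float:
    if estimator == "naive":
        return float(np.std(values, ddof=1) / np.sqrt(len(values)))
    if estimator != "block":
        raise ValueError(f"unknown SEM estimator {estimator!r}")
    n = len(values)
    if n < 2 * n_blocks:
        return float(np.std(values, ddof=1) / np.sqrt(n))
    usable = n - n % n_blocks
    block_means = values[:usable].reshape(n_blocks, -1).mean(axis=1)
    if np.allclose(block_means, block_means[0]):
        return 0.0
    return float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))


def mean_binding_energy(
    series: dict[str, EffectiveEnergySeries] | Sequence[EffectiveEnergySeries],
    sem_estimator: str = "block",
    n_blocks: int = 5,
) -> AggregateBindingEnergy:
    """Replicate means and SEMs, combined by root-sum-square propagation.

    Per-replicate SEMs default to block averaging (five blocks), which
    respects the autocorrelation of consecutive frames; set
    ``sem_estimator="naive"`` for the iid formula.
    """
    if isinstance(series, dict):
        items = list(series.values())
    else:
        items = list(series)
    if not items:
        raise ValueError("need at least one replicate")
    per = [
        BindingEnergyResult(
            mean=float(np.mean(s.values)),
            sem=_series_sem(s.values, sem_estimator, n_blocks),
            drift_slope=drift_slope(s) if s.n_frames >= 2 else 0.0,
            n_frames=s.n_frames,
            label=s.label,
        )
        for s in items
    ]
    return AggregateBindingEnergy(per)


def delta_delta_g(
    mutant: AggregateBindingEnergy,
    wildtype: AggregateBindingEnergy,
    mutant_label: str = "mutant",
    wildtype_label: str = "wildtype",
) -> RelativeBindingEnergy:
    """Relative effective binding energy with propagated SEM.

    Replicates are matched by index; the mean over per-replicate
    differences is tested against zero with a one-sample t-test, and
    sem_total = sqrt(sem_mutant^2 + sem_wildtype^2).
    """
    if len(mutant.per_replicate) != len(wildtype.per_replicate):
        raise ValueError("replicate count mismatch between mutant and wild type")
    diffs = [m.mean - w.mean
             for m, w in zip(mutant.per_replicate, wildtype.per_replicate)]
    sem_total = float(np.sqrt(mutant.sem ** 2 + wildtype.sem ** 2))
    if len(diffs) >= 2 and not np.allclose(diffs, diffs[0]):
        _, p = stats.ttest_1samp(diffs, 0.0)
        p = float(p)
    else:
        p = 1.0 if np.allclose(diffs, 0.0) else 0.0
    return RelativeBindingEnergy(
        ddg=float(np.mean(diffs)),
        sem_total=sem_total,
        p=p,
        per_replicate_ddg=[float(d) for d in diffs],
        mutant_label=mutant_label,
        wildtype_label=wildtype_label,
    )


@dataclass
class KassocChange:
    fold: float          # factor by which the association constant changes
    log10_units: float


def kassoc_change(ddg: float, temperature: float = 300.0) -> KassocChange:
    """Convert a relative binding energy to an association-constant change.

    fold = exp(ddg / RT); log10 units = ddg / (ln 10 * R * T). A positive
    ddg (weaker binding in the mutant) gives fold > 1, read as an
    x-fold *decrease* of the association constant.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rt = GAS_CONSTANT * temperature
    return KassocChange(
        fold=float(np.exp(ddg / rt)),
        log10_units=float(ddg / (np.log(10.0) * rt)),
    )
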