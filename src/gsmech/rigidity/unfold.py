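"""Thermal unfolding and residue-pair stability maps.

Unfolding removes hydrogen-bond bars in order of increasing strength: at
cutoff c only bars with |E| >= c survive (covalent and hydrophobic bars
always do). The stability map entry rc_ij is the largest cutoff at which
residues i and j are still part of one rigid cluster; pairs that are
never co-rigid carry a NaN sentinel, kept out of all arithmetic. A
difference map compares two structural ensembles pair by pair with a
Welch test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .network import ConstraintNetwork
from .pebble import RigidClusterDecomposition, pebble_game

#: Energy-cutoff ladder: 0.0 to 6.0 kcal/mol in 0.1 steps.
DEFAULT_CUTOFFS = np.round(np.arange(0.0, 6.0 + 1e-9, 0.1), 10)


@dataclass
class StabilityMap:
    """Symmetric rc_ij matrix on a cutoff grid; NaN = never co-rigid."""

    labels: list
    rc: np.ndarray
    cutoffs: np.ndarray

    def __post_init__(self) -> None:
        self.rc = np.asarray(self.rc, dtype=float)
        if self.rc.shape != (len(self.labels), len(self.labels)):
            raise ValueError("rc matrix shape mismatch with labels")

    def value(self, i: int, j: int) -> float:
        return float(self.rc[i, j])


@dataclass
class DifferenceStabilityMap:
    """Per-pair mean rc difference (reference minus perturbed) with Welch
    p-values and a significance mask at ``alpha``."""

    labels: list
    delta: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float


def thermal_unfolding(
    network: ConstraintNetwork,
    cutoffs: np.ndarray = DEFAULT_CUTOFFS,
) -> tuple[list[RigidClusterDecomposition], StabilityMap]:
    """Decompose the network along the cutoff ladder and build rc_ij."""
    cutoffs = np.sort(np.asarray(cutoffs, dtype=float))
    if any(
        b.origin == "hbond" and b.energy is None for b in network.bars
    ):
        raise ValueError("hbond bars must carry energies for thermal unfolding")
    n = network.n_bodies
    rc = np.full((n, n), np.nan)
    decomps = []
    for c in cutoffs:
        dec = pebble_game(network.retained_at_cutoff(float(c)))
        decomps.append(dec)
        # co-rigid pairs at this cutoff keep (at least) rc = c
        for cluster in dec.clusters():
            idx = np.asarray(cluster, dtype=int)
            if len(idx) > 1:
                rc[np.ix_(idx, idx)] = c
    np.fill_diagonal(rc, cutoffs[-1])
    return decomps, StabilityMap(list(network.body_labels), rc, cutoffs)


def ensemble_stability_map(
    networks: Sequence[ConstraintNetwork],
    cutoffs: np.ndarray = DEFAULT_CUTOFFS,
) -> tuple[StabilityMap, np.ndarray, list[StabilityMap]]:
    """Per-structure maps plus their element-wise mean.

    Returns (mean map, per-pair contributing-structure counts, per-structure
    maps). Sentinel (never co-rigid) entries are excluded from the mean;
    a pair with no contributing structure stays NaN.
    """
    if len(networks) < 1:
        raise ValueError("need at least one structure")
    labels = list(networks[0].body_labels)
    maps = []
    for net in networks:
        if list(net.body_labels) != labels:
            raise ValueError("all structures must share the residue universe")
        maps.append(thermal_unfolding(net, cutoffs)[1])
    stack = np.stack([m.rc for m in maps])
    counts = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean_rc = np.where(counts > 0, np.nansum(stack, axis=0)
                           / np.maximum(counts, 1), np.nan)
    return StabilityMap(labels, mean_rc, maps[0].cutoffs), counts, maps


def difference_map(
    reference: Sequence[StabilityMap],
    perturbed: Sequence[StabilityMap],
    alpha: float = 0.05,
    max_sentinel_fraction: float = 0.5,
) -> DifferenceStabilityMap:
    """Welch-tested per-pair stability difference, reference minus perturbed.

    Positive delta means the pair is more stably connected in the
    reference ensemble. Pairs with sentinels in more than
    ``max_sentinel_fraction`` of either ensemble's structures are masked
    (delta and p set to NaN), as are pairs with fewer than two valid
    observations on a side.
    """
    labels = list(reference[0].labels)
    for m in list(reference) + list(perturbed):
        if list(m.labels) != labels:
            raise ValueError("stability maps live on different residue universes")
    ref = np.stack([m.rc for m in reference])
    per = np.stack([m.rc for m in perturbed])

    ref_valid = np.sum(~np.isnan(ref), axis=0)
    per_valid = np.sum(~np.isnan(per), axis=0)
    testable = (
        (ref_valid >= max(2, int(np.ceil((1 - max_sentinel_fraction) * ref.shape[0]))))
        & (per_valid >= max(2, int(np.ceil((1 - max_sentinel_fraction) * per.shape[0]))))
    )

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # near-identical samples trigger a scipy precision warning; the
        # degenerate case is handled explicitly below
        _warnings.simplefilter("ignore", RuntimeWarning)
        delta = np.nanmean(ref, axis=0) - np.nanmean(per, axis=0)
        tstat, p = stats.ttest_ind(ref, per, axis=0, equal_var=False,
                                   nan_policy="omit")
    p = np.asarray(p, dtype=float)
    # identical zero-variance samples: equal means -> no difference (p = 1)
    both_const = np.isnan(p) & testable & np.isclose(
        np.nanvar(ref, axis=0), 0) & np.isclose(np.nanvar(per, axis=0), 0)
    p[both_const & np.isclose(delta, 0.0)] = 1.0
    delta = np.where(testable, delta, np.nan)
    p = np.where(testable, p, np.nan)
    significant = testable & (p < alpha)
    return DifferenceStabilityMap(labels, delta, p, significant, alpha)
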