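"""Rigidity-matrix reference decomposition for body-bar frameworks.

This is the slow, linear-algebra route used to cross-check the pebble
game: build the rigidity matrix at (random, generic) bar attachment
points, take its rank and null space, and read rigid clusters off the
null space — two bodies are co-rigid when every infinitesimal flex
assigns them the same rigid motion.

A body's instantaneous motion is a twist (omega, v) about the global
origin; the velocity of a material point p is v + omega x p. A bar
between attachment points a_i (on body i) and a_j (on body j) with unit
direction u contributes the row

    u . (v_i + omega_i x a_i) - u . (v_j + omega_j x a_j) = 0.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import null_space

from .network import ConstraintNetwork
from .pebble import RigidClusterDecomposition


def rigidity_matrix(
    network: ConstraintNetwork, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Generic body-bar rigidity matrix (one row per unit bar).

    Bars carrying explicit attachment points use them only as a locality
    hint; every unit bar receives fresh random generic attachments so that
    multiplicities up to six between one body pair stay independent.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    n = network.n_bodies
    centers = rng.normal(scale=5.0, size=(n, 3))
    for bar in network.bars:
        for _ in range(bar.multiplicity):
            a_i = centers[bar.i] + rng.normal(scale=1.0, size=3)
            a_j = centers[bar.j] + rng.normal(scale=1.0, size=3)
            u = a_j - a_i
            norm = np.linalg.norm(u)
            if norm < 1e-9:       # pathological draw; nudge
                u = rng.normal(size=3)
                norm = np.linalg.norm(u)
            u = u / norm
            row = np.zeros(6 * n)
            row[6 * bar.i: 6 * bar.i + 3] = np.cross(a_i, u)   # omega_i
            row[6 * bar.i + 3: 6 * bar.i + 6] = u              # v_i
            row[6 * bar.j: 6 * bar.j + 3] = -np.cross(a_j, u)
            row[6 * bar.j + 3: 6 * bar.j + 6] = -u
            rows.append(row)
    if not rows:
        return np.zeros((0, 6 * n))
    return np.vstack(rows)


def rank_oracle_decomposition(
    network: ConstraintNetwork,
    rng: np.random.Generator | None = None,
    tol: float = 1e-8,
) -> RigidClusterDecomposition:
    """Decomposition via rank and null space of the rigidity matrix."""
    rng = rng or np.random.default_rng(0)
    n = network.n_bodies
    mat = rigidity_matrix(network, rng)
    if mat.shape[0] == 0:
        rank = 0
        flex = np.eye(6 * n)
    else:
        rank = int(np.linalg.matrix_rank(mat, tol=tol * max(1.0, np.abs(mat).max())))
        flex = null_space(mat, rcond=tol)

    # per-body twists for each flex basis vector: (n_flex, n_bodies, 6)
    twists = flex.T.reshape(-1, n, 6) if flex.size else np.zeros((0, n, 6))
    scale = max(1.0, float(np.abs(twists).max())) if twists.size else 1.0

    labels = np.full(n, -1, dtype=int)
    reps: list[int] = []
    next_label = 0
    for body in range(n):
        assigned = False
        for rep in reps:
            diff = twists[:, body, :] - twists[:, rep, :]
            if twists.shape[0] == 0 or np.abs(diff).max() < 1e-6 * scale:
                labels[body] = labels[rep]
                assigned = True
                break
        if not assigned:
            labels[body] = next_label
            reps.append(body)
            next_label += 1

    return RigidClusterDecomposition(
        labels=labels,
        n_independent=rank,
        dof_internal=6 * n - 6 - rank,
        n_redundant=sum(b.multiplicity for b in network.bars) - rank,
    )
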