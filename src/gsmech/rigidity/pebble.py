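"""The (6,6) body-bar pebble game.

Each body carries six pebbles (its six rigid-body degrees of freedom). A
bar is independent if seven pebbles can be gathered on its two endpoints;
accepting it consumes one pebble. By Tay's theorem the accepted count
equals the generic rank of the body-bar framework, so the internal
degree-of-freedom count and the rigid-cluster partition agree with the
rigidity-matrix rank computed at generic bar placements.

Two bodies are co-rigid when a hypothetical extra bar between them would
be redundant, i.e. seven pebbles cannot be gathered on the pair. Because
every body moves as a full rigid unit, pairwise co-rigidity is an
equivalence relation and yields a partition of the bodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Bar, ConstraintNetwork

_K = 6          # pebbles per body
_NEEDED = 7     # pebbles required on a pair to accept a bar


@dataclass
class RigidClusterDecomposition:
    labels: np.ndarray          # cluster id per body, numbered by first member
    n_independent: int          # generic rank of the framework
    dof_internal: int           # 6B - 6 - rank (>= 0 for a connected framework)
    n_redundant: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def clusters(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(self.n_clusters)]
        for body, lab in enumerate(self.labels):
            out[lab].append(body)
        return out

    def co_rigid(self, i: int, j: int) -> bool:
        return bool(self.labels[i] == self.labels[j])


class _PebbleGame:
    def __init__(self, n: int):
        self.n = n
        self.pebbles = [_K] * n
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]

    def _find_pebble(self, sources: tuple[int, ...]) -> list[int] | None:
        """DFS along edge orientations for a vertex outside ``sources`` with a
        free pebble; returns the path from a source to it."""
        parent: dict[int, int] = {s: -1 for s in sources}
        stack = list(sources)
        while stack:
            v = stack.pop()
            for w, cnt in self.out[v].items():
                if cnt <= 0 or w in parent:
                    continue
                parent[w] = v
                if self.pebbles[w] > 0 and w not in sources:
                    path = [w]
                    while parent[path[-1]] != -1:
                        path.append(parent[path[-1]])
                    path.reverse()
                    return path
                stack.append(w)
        return None

    def _reverse_path(self, path: list[int]) -> None:
        for a, b in zip(path[:-1], path[1:]):
            self.out[a][b] -= 1
            if self.out[a][b] == 0:
                del self.out[a][b]
            self.out[b][a] = self.out[b].get(a, 0) + 1

    def gather(self, u: int, v: int, needed: int = _NEEDED) -> bool:
        """Try to accumulate ``needed`` pebbles on {u, v} (mutates
        orientations only; the independent set is unchanged)."""
        while self.pebbles[u] + self.pebbles[v] < needed:
            # only anchor the search at an endpoint that can still hold a
            # pebble (per-body capacity is six)
            sources = tuple(s for s in (u, v) if self.pebbles[s] < _K) or (u, v)
            path = self._find_pebble(sources)
            if path is None:
                return False
            self._reverse_path(path)
            self.pebbles[path[-1]] -= 1
            self.pebbles[path[0]] += 1
        return True

    def insert(self, u: int, v: int) -> bool:
        """Insert one unit bar; True if independent."""
        if not self.gather(u, v):
            return False
        tail = u if self.pebbles[u] > 0 else v
        head = v if tail == u else u
        self.pebbles[tail] -= 1
        self.out[tail][head] = self.out[tail].get(head, 0) + 1
        return True


def _bar_sort_key(bar: Bar):
    return (min(bar.i, bar.j), max(bar.i, bar.j), bar.origin,
            bar.energy if bar.energy is not None else 0.0)


def pebble_game(network: ConstraintNetwork) -> RigidClusterDecomposition:
    """Rigid-cluster decomposition of a body-bar network.

    Bars are processed in a sorted canonical order so the result is
    independent of insertion order (the accepted count is a matroid rank
    and the partition is orientation-independent).
    """
    n = network.n_bodies
    game = _PebbleGame(n)
    n_independent = 0
    n_redundant = 0

    # connected components (co-rigid bodies are necessarily connected)
    comp = list(range(n))

    def comp_find(x: int) -> int:
        while comp[x] != x:
            comp[x] = comp[comp[x]]
            x = comp[x]
        return x

    for bar in sorted(network.bars, key=_bar_sort_key):
        comp[comp_find(bar.i)] = comp_find(bar.j)
        for _ in range(bar.multiplicity):
            if game.insert(bar.i, bar.j):
                n_independent += 1
            else:
                n_redundant += 1

    labels = np.full(n, -1, dtype=int)
    reps: list[int] = []
    next_label = 0
    for body in range(n):
        assigned = False
        for rep in reps:
            if comp_find(rep) != comp_find(body):
                continue
            if not game.gather(rep, body):
                labels[body] = labels[rep]
                assigned = True
                break
        if not assigned:
            labels[body] = next_label
            reps.append(body)
            next_label += 1

    return RigidClusterDecomposition(
        labels=labels,
        n_independent=n_independent,
        dof_internal=_K * n - _K - n_independent,
        n_redundant=n_redundant,
    )
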