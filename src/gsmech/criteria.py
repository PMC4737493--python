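"""Hydrogen-bond and salt-bridge geometric criteria.

Strong and weak hydrogen bonds share the 120 degree donor-H-acceptor angle
cutoff and differ only in the heavy-atom donor-acceptor distance (2.8 vs
3.2 Angstrom). The distance is measured between the two heavy atoms, not to
the hydrogen — the angle test is what involves the hydrogen. Distance and
angle cutoffs are inclusive; the salt-bridge criterion is distance-only and
strict (< 4.0 Angstrom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HBondCriteria:
    d_strong: float = 2.8       # heavy-atom donor-acceptor distance, Angstrom
    d_weak: float = 3.2
    angle_min: float = 120.0    # donor-H-acceptor angle, degrees
    salt_bridge_cut: float = 4.0

    def __post_init__(self) -> None:
        if not 0 < self.d_strong <= self.d_weak:
            raise ValueError("require 0 < d_strong <= d_weak")
        if not 0 <= self.angle_min <= 180:
            raise ValueError("angle_min must lie in [0, 180] degrees")

    def distance_cut(self, hbond_class: str) -> float:
        if hbond_class == "strong":
            return self.d_strong
        if hbond_class == "weak":
            return self.d_weak
        raise ValueError(f"unknown hydrogen-bond class {hbond_class!r}")


#: Absolute slack on inclusive geometric cutoffs, so that a pair placed
#: exactly at the boundary is not excluded by floating-point round-off.
GEOMETRY_EPS = 1e-9


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1 = np.asarray(a, float) - np.asarray(b, float)
    v2 = np.asarray(c, float) - np.asarray(b, float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate angle: coincident atoms")
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def hbond_satisfied(
    donor: np.ndarray,
    acceptor: np.ndarray,
    hydrogens: list[np.ndarray] | None,
    criteria: HBondCriteria,
    hbond_class: str,
) -> bool:
    """Test one donor/acceptor pair against a criteria class.

    ``hydrogens`` are the coordinates of hydrogens covalently attached to
    the donor; if empty or None the angle test degrades to distance-only
    (the caller is responsible for warning about that fallback).
    """
    d = float(np.linalg.norm(np.asarray(donor, float) - np.asarray(acceptor, float)))
    if d > criteria.distance_cut(hbond_class) + GEOMETRY_EPS:
        return False
    if not hydrogens:
        return True
    for h in hydrogens:
        if angle_deg(donor, h, acceptor) >= criteria.angle_min - GEOMETRY_EPS:
            return True
    return False
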