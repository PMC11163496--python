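"""Domain model for MLC beams: control points, beams, error specifications.

Coordinate convention: signed isocenter-plane X positions in millimetres.
``bank_a`` is the left (X1) bank, ``bank_b`` the right (X2) bank, and
``bank_a[i] <= bank_b[i]`` always holds (no crossed leaves).  Leaves are
1 cm wide at the isocenter, so pair ``i`` of ``n`` covers the Y interval
``[-5n + 10i, -5n + 10(i+1)]`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

LEAF_WIDTH_MM = 10.0

#: class labels in the fixed order used throughout the package
ERROR_FAMILIES = ("shift", "random", "error_free", "opening", "closing")

#: error magnitudes (mm) per family, two levels each
FAMILY_MAGNITUDES = {
    "shift": (2.0, 3.0),
    "opening": (1.0, 2.0),
    "closing": (1.0, 2.0),
    "random": (1.0, 2.0),
}


class PlanError(ValueError):
    """Raised when a beam description violates the domain invariants."""


@dataclass(frozen=True)
class ControlPoint:
    """One MLC snapshot: two leaf banks plus cumulative meterset fraction."""

    bank_a: np.ndarray
    bank_b: np.ndarray
    meterset_weight: float

    def __post_init__(self) -> None:
        a = np.asarray(self.bank_a, dtype=float)
        b = np.asarray(self.bank_b, dtype=float)
        object.__setattr__(self, "bank_a", a)
        object.__setattr__(self, "bank_b", b)
        if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
            raise PlanError("leaf banks must be 1-D arrays of equal length")
        if np.any(a > b + 1e-9):
            raise PlanError("crossed leaves: bank_a must not exceed bank_b")
        if not (-1e-9 <= self.meterset_weight <= 1 + 1e-9):
            raise PlanError("meterset_weight must lie in [0, 1]")

    @property
    def n_leaf_pairs(self) -> int:
        return int(self.bank_a.shape[0])

    @property
    def gaps(self) -> np.ndarray:
        """Per-pair leaf openings (mm), always >= 0."""
        return self.bank_b - self.bank_a

    def leaf_y_edges(self) -> np.ndarray:
        """Y edges (mm) of the leaf rows, centered on the beam axis."""
        n = self.n_leaf_pairs
        return -0.5 * LEAF_WIDTH_MM * n + LEAF_WIDTH_MM * np.arange(n + 1)


@dataclass(frozen=True)
class Beam:
    """An ordered control-point sequence belonging to one plan."""

    beam_id: str
    plan_id: str
    control_points: tuple[ControlPoint, ...]

    def __post_init__(self) -> None:
        cps = tuple(self.control_points)
        object.__setattr__(self, "control_points", cps)
        if len(cps) < 2:
            raise PlanError(f"beam {self.beam_id}: needs >= 2 control points")
        n = cps[0].n_leaf_pairs
        if any(cp.n_leaf_pairs != n for cp in cps):
            raise PlanError(f"beam {self.beam_id}: inconsistent leaf-pair count")
        weights = [cp.meterset_weight for cp in cps]
        if any(w2 < w1 - 1e-9 for w1, w2 in zip(weights, weights[1:])):
            raise PlanError(f"beam {self.beam_id}: meterset weights not monotone")
        if abs(weights[-1] - 1.0) > 1e-6:
            raise PlanError(f"beam {self.beam_id}: final meterset weight must be 1")

    @property
    def n_leaf_pairs(self) -> int:
        return self.control_points[0].n_leaf_pairs

    def with_control_points(self, cps: Iterable[ControlPoint]) -> "Beam":
        return replace(self, control_points=tuple(cps))


@dataclass(frozen=True)
class ErrorSpec:
    """Which error family was injected, at what magnitude, with what seed.

    ``family`` doubles as the classification label; the two magnitudes of a
    family share one label.  ``seed`` is required for (and only for) the
    random family; ``shift_direction`` applies to shift only.
    """

    family: str
    magnitude_mm: float = 0.0
    shift_direction: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ERROR_FAMILIES:
            raise PlanError(f"unknown error family {self.family!r}")
        if self.family == "error_free":
            if self.magnitude_mm != 0.0:
                raise PlanError("error_free spec must have magnitude 0")
        else:
            allowed = FAMILY_MAGNITUDES[self.family]
            if self.magnitude_mm not in allowed:
                raise PlanError(
                    f"{self.family} magnitude must be one of {allowed}, "
                    f"got {self.magnitude_mm}"
                )
        if (self.seed is not None) != (self.family == "random"):
            raise PlanError("seed must be present iff family == 'random'")
        if self.shift_direction not in (-1, 1):
            raise PlanError("shift_direction must be +1 or -1")

    @property
    def label(self) -> str:
        return self.family


def validate_beam(beam: Beam) -> None:
    """Re-run all invariants; raises PlanError on violation."""
    Beam(beam.beam_id, beam.plan_id, beam.control_points)


def beams_equal(a: Beam, b: Beam, tol_mm: float = 0.0) -> bool:
    if len(a.control_points) != len(b.control_points):
        return False
    for ca, cb in zip(a.control_points, b.control_points):
        if ca.meterset_weight != cb.meterset_weight:
            return False
        if tol_mm == 0.0:
            if not (np.array_equal(ca.bank_a, cb.bank_a)
                    and np.array_equal(ca.bank_b, cb.bank_b)):
                return False
        else:
            if (np.max(np.abs(ca.bank_a - cb.bank_a)) > tol_mm
                    or np.max(np.abs(ca.bank_b - cb.bank_b)) > tol_mm):
                return False
    return True
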