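"""Transparent fluence-convolution dose engine and synthetic plan generator.

The engine stands in for a treatment planning system plus a 2D ion-chamber
array measurement: for each control point it rasterizes the MLC aperture as
unit fluence (with a constant leaf-transmission floor outside the opening),
accumulates control points weighted by the meterset delivered since the
previous one, blurs the sum with a Gaussian penumbra kernel, and
box-averages the result over the 10 x 10 mm cells of a 27 x 27 detector
grid.  The "measured" arm optionally adds multiplicative Gaussian noise.

Geometry: the fine fluence grid spans +/-135 mm around the isocenter at
1 mm pitch (270 x 270 pixels), covering the detector exactly; detector cell
(i, j) averages the 10 x 10 fine-pixel block at the same location.  Aperture
rectangles use exact partial-pixel coverage, so rasterized aperture area
matches the analytic ``sum(gap) * leaf_width`` to float precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from qaerr.plans import Beam, ControlPoint, LEAF_WIDTH_MM

log = logging.getLogger(__name__)

FINE_PITCH_MM = 1.0
FINE_EXTENT_MM = 135.0
FINE_N = int(2 * FINE_EXTENT_MM / FINE_PITCH_MM)  # 270
DETECTOR_N = 27
DETECTOR_PITCH_MM = 10.0


@dataclass(frozen=True)
class EngineParams:
    """Dose-engine knobs.

    penumbra_sigma_mm
        Width of the Gaussian beam-penumbra kernel (mm).  3 mm gives a
        realistic ~8 mm 80-20 penumbra for a 6 MV beam.
    transmission
        Leaf transmission fraction in [0, 1); the fluence floor under closed
        leaves.  A nonzero floor keeps the low-dose gamma threshold
        meaningful.
    noise_sd_fraction
        Relative SD of the multiplicative Gaussian noise applied by
        :func:`measure` (the detector arm).
    """

    penumbra_sigma_mm: float = 3.0
    transmission: float = 0.02
    noise_sd_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.penumbra_sigma_mm < 0 or self.noise_sd_fraction < 0:
            raise ValueError("engine parameters must be non-negative")
        if not (0 <= self.transmission < 1):
            raise ValueError("transmission must lie in [0, 1)")


@dataclass(frozen=True)
class FluenceGrid:
    """Fine-resolution fluence plane (1 mm pitch, +/-135 mm extent)."""

    values: np.ndarray
    pixel_mm: float = FINE_PITCH_MM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (FINE_N, FINE_N):
            raise ValueError(f"fluence grid must be {FINE_N}x{FINE_N}")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("fluence must be finite and non-negative")


@dataclass(frozen=True)
class DoseGrid:
    """Detector-resolution dose plane: 27 x 27 cells at 10 mm pitch."""

    values: np.ndarray
    pixel_mm: float = DETECTOR_PITCH_MM

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (DETECTOR_N, DETECTOR_N):
            raise ValueError(f"dose grid must be {DETECTOR_N}x{DETECTOR_N}")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("dose must be finite and non-negative")


def _interval_coverage(edges_lo: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Covered fraction of unit cells [e, e+1) by the interval [lo, hi]."""
    return np.clip(np.minimum(hi, edges_lo + 1.0) - np.maximum(lo, edges_lo), 0.0, 1.0)


def aperture_fluence(cp: ControlPoint, params: EngineParams) -> FluenceGrid:
    """Rasterize one control point's aperture as a fluence plane.

    Fluence is 1 inside the union of per-pair open rectangles (leaf gap wide
    in X, one leaf width tall in Y) and ``params.transmission`` elsewhere,
    with exact partial-pixel coverage at the edges.
    """
    edges = -FINE_EXTENT_MM + FINE_PITCH_MM * np.arange(FINE_N)
    open_frac = np.zeros((FINE_N, FINE_N))
    y_edges = cp.leaf_y_edges()
    any_inside = False
    for i in range(cp.n_leaf_pairs):
        a, b = cp.bank_a[i], cp.bank_b[i]
        if b - a <= 0:
            continue
        cov_x = _interval_coverage(edges, a, b)
        cov_y = _interval_coverage(edges, y_edges[i], y_edges[i + 1])
        if cov_x.any() and cov_y.any():
            any_inside = True
            open_frac += np.outer(cov_y, cov_x)
    if not any_inside and np.any(cp.gaps > 0):
        log.warning("aperture entirely outside the fluence grid")
    open_frac = np.clip(open_frac, 0.0, 1.0)
    values = params.transmission + (1.0 - params.transmission) * open_frac
    return FluenceGrid(values)


def beam_dose(beam: Beam, params: EngineParams, mu: float = 1.0) -> DoseGrid:
    """Render a beam's dose plane on the detector grid.

    Each control point contributes its aperture fluence weighted by the
    meterset fraction delivered since the previous control point (the first
    carries its own cumulative weight).  The fluence sum is blurred with the
    penumbra kernel and box-averaged to detector resolution.  ``mu`` scales
    the total meterset linearly.
    """
    weights = np.diff([0.0] + [cp.meterset_weight for cp in beam.control_points])
    fine = np.zeros((FINE_N, FINE_N))
    for w, cp in zip(weights, beam.control_points):
        if w <= 0:
            continue
        fine += w * aperture_fluence(cp, params).values
    fine *= mu
    if params.penumbra_sigma_mm > 0:
        fine = gaussian_filter(fine, params.penumbra_sigma_mm / FINE_PITCH_MM,
                               mode="nearest")
    block = int(DETECTOR_PITCH_MM / FINE_PITCH_MM)
    coarse = fine.reshape(DETECTOR_N, block, DETECTOR_N, block).mean(axis=(1, 3))
    return DoseGrid(np.clip(coarse, 0.0, None))


def measure(dose: DoseGrid, params: EngineParams) -> DoseGrid:
    """Detector arm: apply multiplicative Gaussian noise, clipped at zero."""
    if params.noise_sd_fraction == 0:
        return dose
    rng = np.random.default_rng(params.seed)
    noisy = dose.values * (1.0 + rng.normal(0.0, params.noise_sd_fraction,
                                            dose.values.shape))
    return DoseGrid(np.clip(noisy, 0.0, None))


# ---------------------------------------------------------------------------
# Synthetic plan generator
# ---------------------------------------------------------------------------

def _synth_control_points(rng: np.random.Generator, n_cp: int,
                          n_pairs: int) -> list[ControlPoint]:
    idx = np.arange(n_pairs)
    mid = (n_pairs - 1) / 2.0
    # envelope biases central leaves open, outer leaves closed
    envelope = np.exp(-((idx - mid) ** 2) / (2 * (n_pairs / 5.0) ** 2))
    base_gap = rng.uniform(40.0, 90.0) * envelope
    gap = np.clip(base_gap + rng.normal(0, 5.0, n_pairs), 0.0, 200.0)
    gap[envelope < 0.15] = 0.0
    center = rng.normal(0.0, 10.0, n_pairs) * envelope

    # monotone meterset weights ending at 1, starting at 0
    incr = rng.uniform(0.5, 1.5, n_cp - 1)
    weights = np.concatenate([[0.0], np.cumsum(incr) / incr.sum()])
    weights[-1] = 1.0

    cps = []
    for k in range(n_cp):
        if k > 0:  # per-leaf random walk across control points
            gap = np.clip(gap + rng.normal(0, 8.0, n_pairs), 0.0, 200.0)
            gap[envelope < 0.15] = 0.0
            center = center + rng.normal(0, 5.0, n_pairs) * (envelope > 0.15)
        a = np.clip(center - gap / 2.0, -100.0, 100.0)
        b = np.clip(center + gap / 2.0, -100.0, 100.0)
        cps.append(ControlPoint(a, np.maximum(a, b), float(weights[k])))
    return cps


def synthesize_plan(n_beams: int, n_control_points: int = 5,
                    n_leaf_pairs: int = 27, seed: int = 0,
                    plan_id: str = "synth") -> list[Beam]:
    """Generate clinically-plausible synthetic beams for one plan.

    Apertures are smooth per-leaf gap random walks across control points,
    with central leaf pairs biased open and outer pairs closed, emulating
    the modulated segments of step-and-shoot IMRT fields.  Deterministic
    for a fixed seed.
    """
    if min(n_beams, n_control_points, n_leaf_pairs) < 1:
        raise ValueError("all counts must be >= 1")
    if n_control_points < 2:
        raise ValueError("beams need >= 2 control points")
    rng = np.random.default_rng(seed)
    return [
        Beam(f"b{k:03d}", plan_id,
             tuple(_synth_control_points(rng, n_control_points, n_leaf_pairs)))
        for k in range(n_beams)
    ]


def synthesize_cohort(n_plans: int, beams_per_plan: int = 3,
                      n_control_points: int = 5, n_leaf_pairs: int = 27,
                      seed: int = 0) -> list[Beam]:
    """Generate a multi-plan cohort; plan seeds derive from ``seed``."""
    beams: list[Beam] = []
    for p in range(n_plans):
        beams.extend(
            synthesize_plan(beams_per_plan, n_control_points, n_leaf_pairs,
                            seed=seed * 100_003 + p, plan_id=f"plan{p:03d}")
        )
    return beams


# ---------------------------------------------------------------------------
# DoseGrid I/O
# ---------------------------------------------------------------------------

def write_dose_csv(dose: DoseGrid, path: str | Path) -> None:
    np.savetxt(path, dose.values, delimiter=",")


def read_dose_csv(path: str | Path) -> DoseGrid:
    return DoseGrid(np.loadtxt(path, delimiter=","))
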