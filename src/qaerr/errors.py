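"""Injection of MLC positional-error families into control-point sequences.

Four families are modelled, each applied to every control point of a beam:

* **shift** — all leaves of both banks displaced by the same signed amount,
  leaving every aperture width unchanged;
* **opening** — each bank moved away from the beam axis, growing every
  per-pair gap by twice the magnitude;
* **closing** — each bank moved toward the axis; pairs that would cross are
  clamped to their common midpoint (gap 0), which preserves the pair's
  centroid;
* **random** — independent zero-mean Gaussian displacement per leaf, per
  bank, per control point, with the closing clamp applied to crossings.

All operators are pure: the input beam is never mutated.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from qaerr.plans import (
    Beam,
    ControlPoint,
    ErrorSpec,
    FAMILY_MAGNITUDES,
    PlanError,
)


def _rebuild(beam: Beam, banks: list[tuple[np.ndarray, np.ndarray]]) -> Beam:
    cps = [
        ControlPoint(a, b, cp.meterset_weight)
        for (a, b), cp in zip(banks, beam.control_points)
    ]
    return beam.with_control_points(cps)


def _clamp_crossings(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp crossed pairs to their common midpoint."""
    crossed = a > b
    if np.any(crossed):
        mid = 0.5 * (a + b)
        a = np.where(crossed, mid, a)
        b = np.where(crossed, mid, b)
    return a, b


def inject_shift(beam: Beam, magnitude_mm: float, direction: int = 1) -> Beam:
    """Displace every leaf of both banks by ``direction * magnitude_mm``.

    Field sizes are identical to the input; only the aperture position
    changes.  A shift can never cross leaves.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    d = direction * magnitude_mm
    banks = [(cp.bank_a + d, cp.bank_b + d) for cp in beam.control_points]
    return _rebuild(beam, banks)


def inject_opening(beam: Beam, magnitude_mm: float) -> Beam:
    """Move both banks away from the beam axis by ``magnitude_mm`` each.

    Every per-pair gap grows by ``2 * magnitude_mm``; the X field size grows
    by the same amount.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    banks = [
        (cp.bank_a - magnitude_mm, cp.bank_b + magnitude_mm)
        for cp in beam.control_points
    ]
    return _rebuild(beam, banks)


def inject_closing(beam: Beam, magnitude_mm: float) -> Beam:
    """Move both banks toward the beam axis by ``magnitude_mm`` each.

    Gaps shrink by ``min(2 * magnitude_mm, gap)``: pairs that would cross are
    clamped to their midpoint, so the result never has negative openings.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    banks = []
    for cp in beam.control_points:
        a = cp.bank_a + magnitude_mm
        b = cp.bank_b - magnitude_mm
        banks.append(_clamp_crossings(a, b))
    return _rebuild(beam, banks)


def inject_random(beam: Beam, sigma_mm: float, seed: int) -> Beam:
    """Displace each leaf independently by an N(0, sigma_mm^2) draw.

    Draws are independent per leaf, per bank and per control point;
    crossings are midpoint-clamped.  Deterministic for a fixed seed.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    rng = np.random.default_rng(seed)
    banks = []
    for cp in beam.control_points:
        a = cp.bank_a + rng.normal(0.0, sigma_mm, cp.n_leaf_pairs)
        b = cp.bank_b + rng.normal(0.0, sigma_mm, cp.n_leaf_pairs)
        banks.append(_clamp_crossings(a, b))
    return _rebuild(beam, banks)


def apply_error(beam: Beam, spec: ErrorSpec) -> Beam:
    """Dispatch an ErrorSpec onto the matching injection operator."""
    if spec.family == "error_free":
        return beam
    if spec.family == "shift":
        return inject_shift(beam, spec.magnitude_mm, spec.shift_direction)
    if spec.family == "opening":
        return inject_opening(beam, spec.magnitude_mm)
    if spec.family == "closing":
        return inject_closing(beam, spec.magnitude_mm)
    if spec.family == "random":
        return inject_random(beam, spec.magnitude_mm, spec.seed)
    raise PlanError(f"unknown family {spec.family!r}")


def manifest_specs(beam: Beam, base_seed: int = 0) -> list[ErrorSpec]:
    """The nine per-beam variants: error-free plus 2 magnitudes x 4 families.

    The random-family seed is derived deterministically from the beam
    identity and ``base_seed`` so a manifest is reproducible across runs.
    """
    specs = [ErrorSpec("error_free")]
    for family in ("shift", "opening", "closing", "random"):
        for k, mag in enumerate(FAMILY_MAGNITUDES[family]):
            if family == "random":
                tag = f"{beam.plan_id}/{beam.beam_id}/{k}".encode()
                seed = base_seed * 1_000_003 + zlib.crc32(tag) % 1_000_003
                specs.append(ErrorSpec("random", mag, seed=seed))
            else:
                specs.append(ErrorSpec(family, mag))
    return specs


def build_manifest(beams: list[Beam], base_seed: int = 0) -> pd.DataFrame:
    """Enumerate all labelled plan variants as a dataset manifest.

    Returns a DataFrame with one row per (beam, error variant): columns
    ``plan_id, beam_id, family, magnitude_mm, shift_direction, seed, label``.
    Each beam contributes exactly 9 rows, so ``len(manifest) == 9 * n_beams``
    and every error family has ``2 * n_beams`` rows.
    """
    if not beams:
        raise ValueError("beams must be non-empty")
    seen = set()
    rows = []
    for beam in beams:
        key = (beam.plan_id, beam.beam_id)
        if key in seen:
            raise PlanError(f"duplicate (plan_id, beam_id): {key}")
        seen.add(key)
        for spec in manifest_specs(beam, base_seed):
            rows.append(
                {
                    "plan_id": beam.plan_id,
                    "beam_id": beam.beam_id,
                    "family": spec.family,
                    "magnitude_mm": spec.magnitude_mm,
                    "shift_direction": spec.shift_direction,
                    "seed": spec.seed if spec.seed is not None else -1,
                    "label": spec.label,
                }
            )
    return pd.DataFrame(rows)


def spec_from_row(row) -> ErrorSpec:
    """Reconstruct the ErrorSpec encoded in one manifest row."""
    seed = int(row["seed"])
    return ErrorSpec(
        family=row["family"],
        magnitude_mm=float(row["magnitude_mm"]),
        shift_direction=int(row["shift_direction"]),
        seed=seed if row["family"] == "random" else None,
    )
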