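"""Dose-difference and signed gamma maps for QA error classification.

Both map types compare a *reference* dose plane (the predicted dose, with or
without an injected MLC error) against an *evaluated* plane (the error-free
measured dose) on the 27 x 27 detector grid, and are normalized to [-1, 1]
for use as classifier channels:

* the **DD map** is the pointwise ``evaluated - reference`` difference as a
  percentage of the global reference maximum, clipped to +/-10% and scaled;
* the **signed gamma map** is the Low gamma index under a global
  dose-difference / distance-to-agreement criterion, evaluated only where
  the reference exceeds a low-dose threshold, and given the *sign* of the
  local dose difference: positive marks hot spots (evaluated above
  reference), negative cold spots.  Magnitudes are clipped at 1.5 and
  scaled to [-1, 1].

The gamma search bilinearly upsamples the evaluated plane (default 10x,
i.e. 1 mm steps for the 10 mm detector pitch) and minimizes over all
upsampled positions within a search radius (default three times the DTA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from qaerr.dose import DoseGrid, DETECTOR_PITCH_MM


@dataclass(frozen=True)
class GammaParams:
    """Gamma-criterion settings: ``dose_criterion_pct``%/``dta_mm`` mm,
    global normalization, with a low-dose threshold and a clip ceiling."""

    dose_criterion_pct: float
    dta_mm: float
    threshold_pct: float = 10.0
    clip: float = 1.5
    search_radius_mm: float | None = None
    fine_factor: int = 10

    def __post_init__(self) -> None:
        if self.search_radius_mm is None:
            object.__setattr__(self, "search_radius_mm", 3.0 * self.dta_mm)
        if min(self.dose_criterion_pct, self.dta_mm, self.threshold_pct) <= 0:
            raise ValueError("gamma criteria must be positive")
        if self.clip < 1:
            raise ValueError("clip must be >= 1")
        if self.search_radius_mm < self.dta_mm:
            raise ValueError("search_radius_mm must cover at least one DTA")


GAMMA_3_2 = GammaParams(3.0, 2.0)
GAMMA_2_1 = GammaParams(2.0, 1.0)


def _check_pair(reference: np.ndarray, evaluated: np.ndarray) -> None:
    if reference.shape != evaluated.shape:
        raise ValueError("reference/evaluated shape mismatch")
    if not (np.all(np.isfinite(reference)) and np.all(np.isfinite(evaluated))):
        raise ValueError("non-finite dose values")


def dd_map(reference: DoseGrid | np.ndarray, evaluated: DoseGrid | np.ndarray,
           clip_pct: float = 10.0) -> np.ndarray:
    """Normalized dose-difference map in [-1, 1].

    ``(evaluated - reference)`` as percent of the global reference maximum,
    clipped to ``+/-clip_pct`` and linearly scaled.  Positive = hot spot.
    """
    ref = reference.values if isinstance(reference, DoseGrid) else np.asarray(reference, float)
    ev = evaluated.values if isinstance(evaluated, DoseGrid) else np.asarray(evaluated, float)
    _check_pair(ref, ev)
    gmax = ref.max()
    if gmax <= 0:
        raise ValueError("all-zero reference: normalization undefined")
    pct = 100.0 * (ev - ref) / gmax
    return np.clip(pct, -clip_pct, clip_pct) / clip_pct


def _upsample(values: np.ndarray, factor: int) -> np.ndarray:
    """Corner-aligned bilinear upsampling: node (i, j) maps to
    (factor*i, factor*j) exactly."""
    n, m = values.shape
    rows = np.linspace(0.0, n - 1, (n - 1) * factor + 1)
    cols = np.linspace(0.0, m - 1, (m - 1) * factor + 1)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(values, [rr, cc], order=1, mode="nearest")


def gamma_magnitude(reference: np.ndarray, evaluated: np.ndarray,
                    params: GammaParams,
                    pitch_mm: float = DETECTOR_PITCH_MM) -> np.ndarray:
    """Unsigned, unclipped gamma index at every reference grid point.

    Sub-threshold reference points are returned as NaN.  The evaluated
    distribution is upsampled ``fine_factor``-fold and the Low formula is
    minimized over all fine positions within ``search_radius_mm`` of each
    reference point.
    """
    ref = np.asarray(reference, float)
    ev = np.asarray(evaluated, float)
    _check_pair(ref, ev)
    gmax = ref.max()
    if gmax <= 0:
        raise ValueError("all-zero reference: normalization undefined")

    f = params.fine_factor
    step_mm = pitch_mm / f
    fine = _upsample(ev, f)
    n, m = ref.shape
    fn, fm = fine.shape

    dd_tol = params.dose_criterion_pct / 100.0 * gmax
    r_steps = int(np.floor(params.search_radius_mm / step_mm))
    offs = np.arange(-r_steps, r_steps + 1)
    du, dv = np.meshgrid(offs, offs, indexing="ij")
    d2 = (du.astype(float) ** 2 + dv.astype(float) ** 2) * step_mm**2
    keep = d2 <= params.search_radius_mm**2 + 1e-12
    du, dv, d2 = du[keep], dv[keep], d2[keep]

    ii = f * np.arange(n)[:, None]
    jj = f * np.arange(m)[None, :]
    best = np.full((n, m), np.inf)
    for k in range(du.size):
        ui = ii + du[k]
        vj = jj + dv[k]
        valid = ((ui >= 0) & (ui < fn)) & ((vj >= 0) & (vj < fm))
        if not valid.any():
            continue
        ui_c = np.clip(ui, 0, fn - 1)
        vj_c = np.clip(vj, 0, fm - 1)
        cand = d2[k] / params.dta_mm**2 + (
            (fine[ui_c, vj_c] - ref) / dd_tol) ** 2
        best = np.where(valid, np.minimum(best, cand), best)

    gamma = np.sqrt(best)
    gamma[ref < params.threshold_pct / 100.0 * gmax] = np.nan
    return gamma


def signed_gamma_map(reference: DoseGrid | np.ndarray,
                     evaluated: DoseGrid | np.ndarray,
                     params: GammaParams,
                     pitch_mm: float = DETECTOR_PITCH_MM) -> np.ndarray:
    """Signed, clipped, [-1, 1]-scaled gamma map.

    Sign follows the local dose difference at the reference point (hot = +,
    cold = -, exact equality kept +); sub-threshold points are encoded 0.
    """
    ref = reference.values if isinstance(reference, DoseGrid) else np.asarray(reference, float)
    ev = evaluated.values if isinstance(evaluated, DoseGrid) else np.asarray(evaluated, float)
    gamma = gamma_magnitude(ref, ev, params, pitch_mm)
    sign = np.where(ev - ref < 0, -1.0, 1.0)
    signed = np.where(np.isnan(gamma), 0.0, sign * np.nan_to_num(gamma))
    return np.clip(signed, -params.clip, params.clip) / params.clip


def threshold_mask(reference: DoseGrid | np.ndarray,
                   threshold_pct: float = 10.0) -> np.ndarray:
    """Validity mask: True where the reference exceeds the low-dose cutoff."""
    ref = reference.values if isinstance(reference, DoseGrid) else np.asarray(reference, float)
    return ref >= threshold_pct / 100.0 * ref.max()


def resize_bilinear(map27: np.ndarray, out_size: int = 224) -> np.ndarray:
    """Corner-aligned bilinear resize of a square map.

    Constants stay constant, the four corners are preserved exactly, and
    output values never leave the input's [min, max] range.
    """
    arr = np.asarray(map27, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite input")
    n, m = arr.shape
    rows = np.linspace(0.0, n - 1, out_size)
    cols = np.linspace(0.0, m - 1, out_size)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(arr, [rr, cc], order=1, mode="nearest")


CHANNEL_NAMES = ("dd", "gamma32", "gamma21")


@dataclass(frozen=True)
class MapStack:
    """Classifier input: resized DD + two gamma channels with provenance."""

    channels: np.ndarray  # (size, size, 3), order: DD, gamma 3%/2mm, gamma 2%/1mm
    label: str
    plan_id: str = ""
    beam_id: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.channels, dtype=np.float32)
        object.__setattr__(self, "channels", c)
        if c.ndim != 3 or c.shape[0] != c.shape[1] or c.shape[2] != 3:
            raise ValueError("channels must be (size, size, 3)")
        if np.abs(c).max() > 1 + 1e-6:
            raise ValueError("channels must lie in [-1, 1]")

    @property
    def size(self) -> int:
        return self.channels.shape[0]

    @property
    def pixel_mm(self) -> float:
        return DETECTOR_PITCH_MM * 27 / self.size

    def channel(self, name: str) -> np.ndarray:
        """Single-channel extraction for ablation runs (shape size,size,1)."""
        idx = CHANNEL_NAMES.index(name)
        return self.channels[:, :, idx:idx + 1]


def make_stack(predicted: DoseGrid, measured: DoseGrid, label: str = "",
               plan_id: str = "", beam_id: str = "", size: int = 224,
               gamma_params: tuple[GammaParams, GammaParams] = (GAMMA_3_2, GAMMA_2_1),
               dd_clip_pct: float = 10.0) -> MapStack:
    """Full map pipeline: DD + two gamma criteria, resized and stacked.

    The predicted dose is the gamma/DD *reference*, the measured dose the
    *evaluated* distribution.
    """
    dd = dd_map(predicted, measured, dd_clip_pct)
    g32 = signed_gamma_map(predicted, measured, gamma_params[0])
    g21 = signed_gamma_map(predicted, measured, gamma_params[1])
    channels = np.stack(
        [resize_bilinear(ch, size) for ch in (dd, g32, g21)], axis=-1
    )
    return MapStack(channels.astype(np.float32), label, plan_id, beam_id)
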