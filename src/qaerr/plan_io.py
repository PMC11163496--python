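"""Reading and writing MLC beam descriptions.

Two on-disk forms are supported:

* **DICOM RT PLAN** — ``BeamSequence -> ControlPointSequence ->
  BeamLimitingDevicePositionSequence`` with device type ``MLCX``.
  ``LeafJawPositions`` holds the A bank followed by the B bank (2N values,
  bank A <= bank B per pair).  On rewrite only leaf positions are touched;
  every other element is preserved untouched.
* **JSON plan fixture** — a light dialect for tests and synthetic cohorts:
  ``{"plan_id": ..., "beams": [{"beam_id", "n_leaf_pairs",
  "control_points": [{"bank_a": [...], "bank_b": [...],
  "meterset_weight": w}]}]}``.

DICOM control points that omit the MLC position sequence (static segments)
inherit the most recent positions, per the DICOM RT convention.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from qaerr.plans import Beam, ControlPoint, PlanError

RT_PLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"


# ---------------------------------------------------------------------------
# JSON fixture dialect
# ---------------------------------------------------------------------------

def read_plan_json(path: str | Path) -> list[Beam]:
    with open(path) as fh:
        doc = json.load(fh)
    plan_id = doc["plan_id"]
    beams = []
    for bdoc in doc["beams"]:
        n = int(bdoc["n_leaf_pairs"])
        cps = []
        for cdoc in bdoc["control_points"]:
            a = np.asarray(cdoc["bank_a"], dtype=float)
            b = np.asarray(cdoc["bank_b"], dtype=float)
            if a.shape != (n,) or b.shape != (n,):
                raise PlanError(
                    f"beam {bdoc['beam_id']}: bank length != n_leaf_pairs"
                )
            cps.append(ControlPoint(a, b, float(cdoc["meterset_weight"])))
        beams.append(Beam(bdoc["beam_id"], plan_id, tuple(cps)))
    return beams


def write_plan_json(beams: list[Beam], path: str | Path) -> None:
    if not beams:
        raise ValueError("beams must be non-empty")
    plan_ids = {b.plan_id for b in beams}
    if len(plan_ids) != 1:
        raise ValueError("one JSON fixture holds exactly one plan")
    doc = {
        "plan_id": beams[0].plan_id,
        "beams": [
            {
                "beam_id": b.beam_id,
                "n_leaf_pairs": b.n_leaf_pairs,
                "control_points": [
                    {
                        "bank_a": cp.bank_a.tolist(),
                        "bank_b": cp.bank_b.tolist(),
                        "meterset_weight": cp.meterset_weight,
                    }
                    for cp in b.control_points
                ],
            }
            for b in beams
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


# ---------------------------------------------------------------------------
# DICOM RT PLAN
# ---------------------------------------------------------------------------

def _find_mlcx(cp_item: Dataset) -> Dataset | None:
    for pos in getattr(cp_item, "BeamLimitingDevicePositionSequence", []):
        if pos.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
            return pos
    return None


def read_plan_dicom(path: str | Path) -> list[Beam]:
    ds = pydicom.dcmread(str(path))
    plan_id = str(getattr(ds, "RTPlanLabel", getattr(ds, "SOPInstanceUID", "plan")))
    beams: list[Beam] = []
    for beam_ds in ds.BeamSequence:
        beam_id = str(getattr(beam_ds, "BeamName", beam_ds.BeamNumber))
        final_w = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", 1.0))
        cps: list[ControlPoint] = []
        prev: tuple[np.ndarray, np.ndarray] | None = None
        for cp_item in beam_ds.ControlPointSequence:
            mlc = _find_mlcx(cp_item)
            if mlc is not None:
                vals = np.asarray([float(v) for v in mlc.LeafJawPositions])
                if vals.size % 2:
                    raise PlanError(f"beam {beam_id}: odd LeafJawPositions length")
                n = vals.size // 2
                prev = (vals[:n].copy(), vals[n:].copy())
            if prev is None:
                raise PlanError(f"beam {beam_id}: first control point lacks MLC")
            w = float(cp_item.CumulativeMetersetWeight) / final_w if final_w else 0.0
            cps.append(ControlPoint(prev[0], prev[1], w))
        if any(c.n_leaf_pairs != cps[0].n_leaf_pairs for c in cps):
            raise PlanError(f"beam {beam_id}: bank length mismatch across CPs")
        ws = [c.meterset_weight for c in cps]
        if any(b < a - 1e-9 for a, b in zip(ws, ws[1:])):
            raise PlanError(f"beam {beam_id}: non-monotone meterset weights")
        beams.append(Beam(beam_id, plan_id, tuple(cps)))
    if not beams:
        raise PlanError("no beams in RT PLAN")
    return beams


def rewrite_plan_dicom(src: str | Path, beams: list[Beam], dst: str | Path) -> None:
    """Copy an RT PLAN, replacing only the MLC leaf positions.

    ``beams`` must match the source beam order; all elements other than
    ``LeafJawPositions`` are carried over untouched, so vendor-private and
    unsupported elements survive the round trip.
    """
    ds = pydicom.dcmread(str(src))
    if len(ds.BeamSequence) != len(beams):
        raise PlanError("beam count mismatch between source plan and beams")
    for beam_ds, beam in zip(ds.BeamSequence, beams):
        cp_items = [c for c in beam_ds.ControlPointSequence if _find_mlcx(c)]
        if len(cp_items) != len(beam.control_points):
            raise PlanError(
                f"beam {beam.beam_id}: control-point count mismatch "
                f"({len(cp_items)} with MLC vs {len(beam.control_points)})"
            )
        for cp_item, cp in zip(cp_items, beam.control_points):
            mlc = _find_mlcx(cp_item)
            mlc.LeafJawPositions = [
                f"{v:.2f}" for v in np.concatenate([cp.bank_a, cp.bank_b])
            ]
    ds.save_as(str(dst))


def write_plan_dicom(beams: list[Beam], path: str | Path) -> None:
    """Serialize beams as a minimal, standards-shaped RT PLAN file."""
    if not beams:
        raise ValueError("beams must be non-empty")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_PLAN_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RT_PLAN_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = beams[0].plan_id

    beam_seq = []
    for num, beam in enumerate(beams, start=1):
        bd = Dataset()
        bd.BeamNumber = num
        bd.BeamName = beam.beam_id
        bd.FinalCumulativeMetersetWeight = 1.0
        bd.NumberOfControlPoints = len(beam.control_points)
        cp_seq = []
        for idx, cp in enumerate(beam.control_points):
            ci = Dataset()
            ci.ControlPointIndex = idx
            ci.CumulativeMetersetWeight = cp.meterset_weight
            mlc = Dataset()
            mlc.RTBeamLimitingDeviceType = "MLCX"
            mlc.LeafJawPositions = [
                f"{v:.2f}" for v in np.concatenate([cp.bank_a, cp.bank_b])
            ]
            ci.BeamLimitingDevicePositionSequence = [mlc]
            cp_seq.append(ci)
        bd.ControlPointSequence = cp_seq
        beam_seq.append(bd)
    ds.BeamSequence = beam_seq
    ds.save_as(str(path), enforce_file_format=True)


def read_plan(path: str | Path) -> list[Beam]:
    """Dispatch on suffix: ``.json`` fixture dialect, otherwise DICOM."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_plan_json(path)
    return read_plan_dicom(path)


def write_plan(beams: list[Beam], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        write_plan_json(beams, path)
    else:
        write_plan_dicom(beams, path)
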