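"""Shared fixtures: small phantoms, random plans, DICOM fixture builders."""

from __future__ import annotations

import numpy as np
import pytest

from imrtqa.dose_metrics import DoseGrid, StructureMask
from imrtqa.plan_model import Beam, MLCSegment, Plan
from imrtqa.synthetic_data import PhantomSpec


@pytest.fixture
def small_phantom() -> PhantomSpec:
    """9x9x9 cm phantom, chamber at mid-depth: symmetric lattice, 30^3 voxels."""
    return PhantomSpec(size=(9.0, 9.0, 9.0), chamber_depth_cm=4.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20133)


def random_plan(seed: int, n_beams: int = 3, n_segments: int = 4) -> Plan:
    """Small random plan with irregular (but valid) apertures, for property tests."""
    r = np.random.default_rng(seed)
    beams = []
    for j in range(n_beams):
        segs = []
        for _ in range(n_segments):
            n_leaves = 8
            center = r.uniform(-2, 2, size=n_leaves)
            gap = r.uniform(0.0, 4.0, size=n_leaves)
            segs.append(
                MLCSegment(
                    left_positions=tuple(center + gap / 2),
                    right_positions=tuple(center - gap / 2),
                    mu_weight=float(r.uniform(1.0, 20.0)),
                )
            )
        beams.append(Beam.from_segments(r.uniform(0, 360), segs))
    return Plan(plan_id=f"rand-{seed}", beams=tuple(beams))


def uniform_grid(value: float, dims=(4, 4, 4), spacing=(1.0, 1.0, 1.0)) -> DoseGrid:
    return DoseGrid(origin=(0, 0, 0), spacing=spacing, values=np.full(dims, float(value)))


def full_mask(grid: DoseGrid, name: str = "struct") -> StructureMask:
    return StructureMask(
        name=name,
        origin=grid.origin,
        spacing=grid.spacing,
        voxels=np.ones(grid.dims, dtype=bool),
    )


def build_rtplan(path, beams):
    """Write a minimal DICOM-RTPLAN file.

    *beams* is a list of dicts: {"meterset": MU, "gantry": deg,
    "control_points": [(cumulative_weight, mlc_mm_array), ...]} where
    mlc_mm_array stacks bank X1 then bank X2 (DICOM order, mm).
    """
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.5")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = "fixture"

    fg = Dataset()
    fg.ReferencedBeamSequence = []
    ds.BeamSequence = []
    for num, spec in enumerate(beams, start=1):
        ref = Dataset()
        ref.ReferencedBeamNumber = num
        ref.BeamMeterset = spec["meterset"]
        fg.ReferencedBeamSequence.append(ref)

        b = Dataset()
        b.BeamNumber = num
        b.BeamName = f"beam{num}"
        b.TreatmentDeliveryType = "TREATMENT"
        b.FinalCumulativeMetersetWeight = spec["control_points"][-1][0]
        b.ControlPointSequence = []
        for k, (w, mlc) in enumerate(spec["control_points"]):
            cp = Dataset()
            cp.ControlPointIndex = k
            cp.CumulativeMetersetWeight = w
            if k == 0:
                cp.GantryAngle = spec["gantry"]
                cp.BeamLimitingDeviceAngle = 0.0
                cp.PatientSupportAngle = 0.0
            if mlc is not None:
                bld = Dataset()
                bld.RTBeamLimitingDeviceType = "MLCX"
                bld.LeafJawPositions = [float(x) for x in mlc]
                cp.BeamLimitingDevicePositionSequence = [bld]
            b.ControlPointSequence.append(cp)
        ds.BeamSequence.append(b)
    ds.FractionGroupSequence = [fg]
    ds.save_as(str(path), enforce_file_format=True)
    return path
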