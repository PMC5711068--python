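"""IMRT plan representation: beams, MLC segments, monitor units.

A plan is a list of beams; each beam is an ordered list of static MLC
apertures (segments) with monitor-unit weights.  Dynamic (sliding-window)
deliveries are discretized into segments at control points on read.
Leaf coordinates are in cm projected to the isocenter plane, signed so
that the aperture opening of leaf pair ``a`` is ``left[a] - right[a] >= 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MLCSegment",
    "Beam",
    "Plan",
    "PlanError",
    "read_rtplan",
    "read_plan_json",
    "write_plan_json",
    "collapse_plan",
]

_REL_TOL = 1e-9


class PlanError(ValueError):
    """Structured error for invalid or unparseable plan data."""


@dataclass(frozen=True)
class MLCSegment:
    """One static MLC aperture with its monitor-unit weight.

    ``left_positions[a] >= right_positions[a]`` for every leaf pair; the
    opening of pair ``a`` is the difference of the two coordinates.
    """

    left_positions: tuple[float, ...]
    right_positions: tuple[float, ...]
    mu_weight: float

    def __post_init__(self) -> None:
        left = np.asarray(self.left_positions, dtype=float)
        right = np.asarray(self.right_positions, dtype=float)
        if left.ndim != 1 or left.size < 1:
            raise PlanError("segment needs at least one leaf pair")
        if left.shape != right.shape:
            raise PlanError(
                f"left/right leaf banks differ in length: {left.size} vs {right.size}"
            )
        if not (np.all(np.isfinite(left)) and np.all(np.isfinite(right))):
            raise PlanError("non-finite leaf position")
        if np.any(left < right):
            bad = int(np.argmax(left < right))
            raise PlanError(
                f"leaf pair {bad}: left ({left[bad]}) < right ({right[bad]}); "
                "aperture opening must be non-negative"
            )
        if not np.isfinite(self.mu_weight) or self.mu_weight < 0:
            raise PlanError(f"segment mu_weight must be finite and >= 0, got {self.mu_weight}")
        object.__setattr__(self, "left_positions", tuple(float(x) for x in left))
        object.__setattr__(self, "right_positions", tuple(float(x) for x in right))
        object.__setattr__(self, "mu_weight", float(self.mu_weight))

    @property
    def n_leaf_pairs(self) -> int:
        return len(self.left_positions)

    def openings(self) -> np.ndarray:
        """Per-leaf aperture opening (cm), always >= 0."""
        return np.asarray(self.left_positions) - np.asarray(self.right_positions)


@dataclass(frozen=True)
class Beam:
    """One treatment beam: gantry angle plus an ordered segment sequence."""

    gantry_deg: float
    segments: tuple[MLCSegment, ...]
    beam_mu: float
    collimator_deg: float = 0.0  # carried through, used by no metric
    couch_deg: float = 0.0

    def __post_init__(self) -> None:
        segments = tuple(self.segments)
        if not segments:
            raise PlanError("beam has no segments")
        counts = {s.n_leaf_pairs for s in segments}
        if len(counts) != 1:
            raise PlanError(f"segments disagree on leaf count: {sorted(counts)}")
        if not np.isfinite(self.beam_mu) or self.beam_mu <= 0:
            raise PlanError(f"beam_mu must be > 0, got {self.beam_mu}")
        total = sum(s.mu_weight for s in segments)
        if abs(total - self.beam_mu) > _REL_TOL * max(abs(self.beam_mu), 1.0):
            raise PlanError(
                f"beam_mu {self.beam_mu} != sum of segment weights {total}"
            )
        object.__setattr__(self, "segments", segments)
        object.__setattr__(self, "gantry_deg", float(self.gantry_deg) % 360.0)
        object.__setattr__(self, "beam_mu", float(self.beam_mu))

    @classmethod
    def from_segments(
        cls,
        gantry_deg: float,
        segments: Sequence[MLCSegment],
        **kwargs,
    ) -> "Beam":
        mu = float(sum(s.mu_weight for s in segments))
        return cls(gantry_deg=gantry_deg, segments=tuple(segments), beam_mu=mu, **kwargs)

    @property
    def n_leaf_pairs(self) -> int:
        return self.segments[0].n_leaf_pairs


@dataclass(frozen=True)
class Plan:
    """A multi-beam IMRT plan."""

    plan_id: str
    beams: tuple[Beam, ...]
    plan_mu: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        beams = tuple(self.beams)
        if not beams:
            raise PlanError("plan has no beams")
        total = sum(b.beam_mu for b in beams)
        mu = total if self.plan_mu is None else float(self.plan_mu)
        if abs(total - mu) > _REL_TOL * max(abs(mu), 1.0):
            raise PlanError(f"plan_mu {mu} != sum of beam MUs {total}")
        object.__setattr__(self, "beams", beams)
        object.__setattr__(self, "plan_mu", mu)

    @property
    def n_beams(self) -> int:
        return len(self.beams)


def collapse_plan(plan: Plan, target_angle: float = 0.0) -> Plan:
    """Return the single-gantry-angle (collapsed/SGAC) version of *plan*.

    Every beam's gantry angle is set to *target_angle*; segments, leaf
    positions and all MU weights are untouched, so complexity scores and
    total MU are preserved exactly.
    """
    beams = tuple(replace(b, gantry_deg=float(target_angle) % 360.0) for b in plan.beams)
    return Plan(plan_id=plan.plan_id, beams=beams, plan_mu=plan.plan_mu)


# ---------------------------------------------------------------------------
# JSON fixture dialect
#
# {"plan_id": str,
#  "beams": [{"gantry_deg": f, "beam_mu": f, "collimator_deg": f, "couch_deg": f,
#             "segments": [{"left_positions": [...], "right_positions": [...],
#                           "mu_weight": f}, ...]}, ...]}
# ---------------------------------------------------------------------------

def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise PlanError(f"plan JSON: missing field '{key}' in {context}")
    return mapping[key]


def read_plan_json(path: str | Path) -> Plan:
    """Read a plan from the JSON fixture dialect (see module docstring)."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise PlanError("plan JSON: top level must be an object")
    plan_id = _require(data, "plan_id", "plan")
    beams_raw = _require(data, "beams", "plan")
    beams = []
    for j, braw in enumerate(beams_raw):
        segs = []
        for i, sraw in enumerate(_require(braw, "segments", f"beam {j}")):
            segs.append(
                MLCSegment(
                    left_positions=tuple(_require(sraw, "left_positions", f"beam {j} segment {i}")),
                    right_positions=tuple(_require(sraw, "right_positions", f"beam {j} segment {i}")),
                    mu_weight=_require(sraw, "mu_weight", f"beam {j} segment {i}"),
                )
            )
        beams.append(
            Beam(
                gantry_deg=_require(braw, "gantry_deg", f"beam {j}"),
                segments=tuple(segs),
                beam_mu=_require(braw, "beam_mu", f"beam {j}"),
                collimator_deg=braw.get("collimator_deg", 0.0),
                couch_deg=braw.get("couch_deg", 0.0),
            )
        )
    return Plan(plan_id=str(plan_id), beams=tuple(beams))


def write_plan_json(plan: Plan, path: str | Path) -> None:
    """Write *plan* to the JSON fixture dialect; read_plan_json round-trips."""
    data = {
        "plan_id": plan.plan_id,
        "beams": [
            {
                "gantry_deg": b.gantry_deg,
                "beam_mu": b.beam_mu,
                "collimator_deg": b.collimator_deg,
                "couch_deg": b.couch_deg,
                "segments": [
                    {
                        "left_positions": list(s.left_positions),
                        "right_positions": list(s.right_positions),
                        "mu_weight": s.mu_weight,
                    }
                    for s in b.segments
                ],
            }
            for b in plan.beams
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# DICOM-RTPLAN reading
# ---------------------------------------------------------------------------

def _beam_metersets(ds) -> dict[int, float]:
    """BeamNumber -> BeamMeterset from the fraction group."""
    out: dict[int, float] = {}
    for fg in getattr(ds, "FractionGroupSequence", []):
        for ref in getattr(fg, "ReferencedBeamSequence", []):
            if hasattr(ref, "BeamMeterset"):
                out[int(ref.ReferencedBeamNumber)] = float(ref.BeamMeterset)
    return out


def _mlc_positions(cp, beam_label: str) -> np.ndarray | None:
    for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
        if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
            return np.asarray([float(x) for x in bld.LeafJawPositions])
    return None


def read_rtplan(path: str | Path) -> Plan:
    """Read a DICOM-RTPLAN file into a :class:`Plan`.

    Each pair of consecutive control points becomes one segment whose leaf
    positions are the mean of the two control points and whose MU weight is
    the cumulative-meterset-weight difference times the beam meterset.
    DICOM millimetres are converted to cm; MLC banks are ordered so that
    ``left - right`` is the aperture opening.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    metersets = _beam_metersets(ds)
    beams: list[Beam] = []
    for beam_ds in getattr(ds, "BeamSequence", []):
        label = str(getattr(beam_ds, "BeamName", getattr(beam_ds, "BeamNumber", "?")))
        if getattr(beam_ds, "TreatmentDeliveryType", "TREATMENT") != "TREATMENT":
            continue
        beam_mu = metersets.get(int(beam_ds.BeamNumber), 0.0)
        if beam_mu <= 0:
            raise PlanError(f"beam '{label}': zero or missing beam meterset")
        cps = list(beam_ds.ControlPointSequence)
        if len(cps) < 2:
            raise PlanError(f"beam '{label}': fewer than two control points")
        gantry = float(getattr(cps[0], "GantryAngle", 0.0))
        coll = float(getattr(cps[0], "BeamLimitingDeviceAngle", 0.0))
        couch = float(getattr(cps[0], "PatientSupportAngle", 0.0))
        final_w = float(getattr(beam_ds, "FinalCumulativeMetersetWeight", 1.0))
        if final_w <= 0:
            raise PlanError(f"beam '{label}': non-positive final cumulative meterset weight")

        positions: list[np.ndarray] = []
        weights: list[float] = []
        last = None
        for cp in cps:
            mlc = _mlc_positions(cp, label)
            if mlc is None:
                mlc = last
            if mlc is None:
                raise PlanError(f"beam '{label}': control point without MLC positions")
            last = mlc
            positions.append(mlc)
            weights.append(float(cp.CumulativeMetersetWeight))

        n = positions[0].size
        if n % 2 != 0 or any(p.size != n for p in positions):
            raise PlanError(f"beam '{label}': inconsistent MLC leaf counts")
        half = n // 2

        # DICOM MLCX: first half is bank B (X1 side), second half bank A (X2).
        # Normalize so 'left' is the larger coordinate (aperture = left - right).
        segs = []
        for k in range(len(positions) - 1):
            mid = 0.5 * (positions[k] + positions[k + 1]) / 10.0  # mm -> cm
            bank1, bank2 = mid[:half], mid[half:]
            if np.sum(bank2 - bank1) >= 0:
                right, left = bank1, bank2
            else:
                right, left = bank2, bank1
            # tolerate sub-micron closed-pair crossings from averaging
            left = np.maximum(left, right)
            mu = (weights[k + 1] - weights[k]) / final_w * beam_mu
            if mu < 0:
                raise PlanError(f"beam '{label}': decreasing cumulative meterset weight")
            segs.append(MLCSegment(tuple(left), tuple(right), mu))
        total = sum(s.mu_weight for s in segs)
        if abs(total - beam_mu) > 1e-6 * beam_mu:
            raise PlanError(
                f"beam '{label}': segment MUs ({total}) do not sum to beam meterset ({beam_mu})"
            )
        # absorb float round-off so the Beam invariant holds exactly
        if segs and total != beam_mu:
            adj = segs[-1]
            segs[-1] = MLCSegment(
                adj.left_positions, adj.right_positions, adj.mu_weight + (beam_mu - total)
            )
        beams.append(
            Beam(gantry_deg=gantry, segments=tuple(segs), beam_mu=beam_mu,
                 collimator_deg=coll, couch_deg=couch)
        )
    if not beams:
        raise PlanError("RTPLAN contains no treatment beams")
    plan_id = str(getattr(ds, "RTPlanLabel", getattr(ds, "SOPInstanceUID", "rtplan")))
    return Plan(plan_id=plan_id, beams=tuple(beams))
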