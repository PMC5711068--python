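"""Modulation complexity score (MCS) and its constituents.

The MCS of a plan is the MU-weighted mean over beams of the MU-weighted
mean over segments of AAV x LSV, where

* AAV (aperture area variability) compares a segment's aperture area to
  the maximal per-leaf aperture the beam ever opens, and
* LSV (leaf sequence variability) measures how ragged the open leaf
  front is relative to the open-leaf position range (posmax).

All scores live in [0, 1]; 1 means an unmodulated rectangular delivery
and lower values mean more complex modulation.  A leaf pair counts as
"open" when its gap exceeds ``gap_threshold`` (default 0.05 cm) so that
closed pairs parked behind the jaws do not dominate the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plan_model import Beam, MLCSegment, Plan

__all__ = [
    "ComplexityScores",
    "NoOpenLeavesError",
    "DEFAULT_GAP_THRESHOLD",
    "open_leaf_mask",
    "segment_posmax",
    "segment_lsv",
    "segment_aav",
    "beam_aperture_maxima",
    "beam_mcs",
    "plan_mcs",
    "plan_complexity",
]

DEFAULT_GAP_THRESHOLD = 0.05  # cm


class NoOpenLeavesError(ValueError):
    """Raised when a per-segment score is requested for a fully closed segment."""


def open_leaf_mask(segment: MLCSegment, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> np.ndarray:
    """Boolean mask of leaf pairs whose opening exceeds *gap_threshold* cm."""
    return segment.openings() > gap_threshold


def segment_posmax(bank_positions: np.ndarray, open_mask: np.ndarray) -> float:
    """Range (max - min) of one bank's leaf coordinates over the open leaves."""
    pos = np.asarray(bank_positions, dtype=float)[np.asarray(open_mask, dtype=bool)]
    if pos.size == 0:
        raise NoOpenLeavesError("posmax undefined: no open leaves in bank")
    return float(pos.max() - pos.min())


def _bank_lsv_factor(bank_positions: np.ndarray, open_mask: np.ndarray) -> float:
    pos = np.asarray(bank_positions, dtype=float)[np.asarray(open_mask, dtype=bool)]
    n = pos.size
    if n == 0:
        raise NoOpenLeavesError("LSV undefined: no open leaves in bank")
    posmax = float(pos.max() - pos.min())
    if n == 1 or posmax == 0.0:
        # singleton or perfectly aligned bank: maximally regular
        return 1.0
    diffs = np.abs(np.diff(pos))
    return float(np.sum(posmax - diffs) / ((n - 1) * posmax))


def segment_lsv(
    segment: MLCSegment,
    open_mask: np.ndarray | None = None,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> float:
    """Leaf sequence variability of one segment: product of per-bank factors.

    Each bank contributes ``sum_{adjacent open pairs}(posmax - |p_n - p_{n+1}|)
    / ((N-1) * posmax)``; aligned (posmax = 0) or single-leaf banks contribute
    factor 1.
    """
    if open_mask is None:
        open_mask = open_leaf_mask(segment, gap_threshold)
    left = _bank_lsv_factor(np.asarray(segment.left_positions), open_mask)
    right = _bank_lsv_factor(np.asarray(segment.right_positions), open_mask)
    return left * right


def beam_aperture_maxima(beam: Beam) -> tuple[np.ndarray, np.ndarray]:
    """Per-leaf maximal opening coordinates over all segments of *beam*.

    Returns ``(max_left, min_right)``: for the left bank the largest
    coordinate ever reached, for the right bank the smallest (its opening
    direction is negative), so their difference is each leaf pair's maximal
    opening over the beam.
    """
    lefts = np.stack([np.asarray(s.left_positions) for s in beam.segments])
    rights = np.stack([np.asarray(s.right_positions) for s in beam.segments])
    return lefts.max(axis=0), rights.min(axis=0)


def segment_aav(
    segment: MLCSegment,
    beam_max_left: np.ndarray,
    beam_max_right: np.ndarray,
) -> float:
    """Aperture area variability: segment aperture over the beam's maximal aperture."""
    num = float(np.sum(segment.openings()))
    den = float(np.sum(np.asarray(beam_max_left) - np.asarray(beam_max_right)))
    if den <= 0:
        raise ValueError("AAV undefined: beam never opens any leaf pair")
    return num / den


def _segment_score(
    segment: MLCSegment,
    bml: np.ndarray,
    bmr: np.ndarray,
    gap_threshold: float,
) -> tuple[float, float]:
    """(AAV, LSV) for one segment; a fully closed segment scores (0, 1)."""
    mask = open_leaf_mask(segment, gap_threshold)
    aav = segment_aav(segment, bml, bmr)
    if not mask.any():
        return aav, 1.0  # AAV is ~0; LSV moot for a closed aperture
    return aav, segment_lsv(segment, mask)


def beam_mcs(beam: Beam, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> float:
    """MU-weighted mean of AAV x LSV over the segments of one beam."""
    bml, bmr = beam_aperture_maxima(beam)
    total = 0.0
    for i, seg in enumerate(beam.segments):
        try:
            aav, lsv = _segment_score(seg, bml, bmr, gap_threshold)
        except ValueError as exc:
            raise ValueError(f"segment {i}: {exc}") from exc
        total += aav * lsv * seg.mu_weight
    return total / beam.beam_mu


def plan_mcs(plan: Plan, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> float:
    """MU-weighted mean of beam MCS values over the plan (gantry-independent)."""
    return sum(
        beam_mcs(b, gap_threshold) * b.beam_mu for b in plan.beams
    ) / plan.plan_mu


@dataclass(frozen=True)
class ComplexityScores:
    """Per-segment, per-beam and per-plan modulation complexity scores."""

    lsv_per_segment: tuple[tuple[float, ...], ...]  # [beam][segment]
    aav_per_segment: tuple[tuple[float, ...], ...]
    mcs_beam: tuple[float, ...]
    mcs_plan: float


def plan_complexity(plan: Plan, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> ComplexityScores:
    """Full complexity breakdown of *plan* (used by the CLI and reports)."""
    lsv_all, aav_all, mcs_b = [], [], []
    for beam in plan.beams:
        bml, bmr = beam_aperture_maxima(beam)
        scores = [_segment_score(s, bml, bmr, gap_threshold) for s in beam.segments]
        aav_all.append(tuple(a for a, _ in scores))
        lsv_all.append(tuple(l for _, l in scores))
        mcs_b.append(
            sum(a * l * s.mu_weight for (a, l), s in zip(scores, beam.segments)) / beam.beam_mu
        )
    total = sum(m * b.beam_mu for m, b in zip(mcs_b, plan.beams)) / plan.plan_mu
    return ComplexityScores(
        lsv_per_segment=tuple(lsv_all),
        aav_per_segment=tuple(aav_all),
        mcs_beam=tuple(mcs_b),
        mcs_plan=total,
    )
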