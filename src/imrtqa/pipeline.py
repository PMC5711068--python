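"""Per-patient rotated-vs-collapsed QA comparison and cohort summaries.

``run_comparison`` binds the package together for one patient: complexity
scores on the plan, DVH/HI/COIN and intersection metrics on the summed
per-beam dose grids, combined per-beam uncertainty, the small-field
correction factor from water-sphere / chamber-cavity dose quadruples, and
percent differences of the computed dose against the (pseudo-)measured
chamber dose before and after correction.  ``cohort_summary`` aggregates a
list of such reports into per-mode means, sample standard deviations and
percent relative RMS differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dose_metrics as dm
from .complexity import DEFAULT_GAP_THRESHOLD, plan_mcs
from .correction import KFactorInputs, k_qclin
from .synthetic_data import (
    PhantomSpec,
    SyntheticCase,
    chamber_mask,
    reference_field_beam,
    toy_beam_dose,
    water_sphere_mask,
)

__all__ = [
    "AnalysisConfig",
    "ModeMetrics",
    "QAReport",
    "CohortSummary",
    "run_comparison",
    "cohort_summary",
    "reports_to_dataframe",
]

MODES = ("rotated", "collapsed")


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and conventions of the QA analysis."""

    gap_threshold_cm: float = DEFAULT_GAP_THRESHOLD
    shell_margin_cm: float = 1.5
    intersect_frac_of_max: float = 0.5
    hi_threshold: float = 0.05  # below this the correction stays within ~1% of unity
    collapsed_angle_deg: float = 0.0


@dataclass(frozen=True)
class ModeMetrics:
    """All per-delivery-mode metrics of one patient."""

    hi: float
    coin: float
    mcs_plan: float
    intersection_fraction: float
    chamber_mean_dose_gy: float
    combined_uncertainty_pct: float
    hi_below_threshold: bool
    k_qclin: float | None = None
    diff_uncorrected_pct: float | None = None  # computed vs measured
    diff_corrected_pct: float | None = None    # computed vs k-corrected measured


@dataclass(frozen=True)
class QAReport:
    """Per-patient metric bundle for both delivery modes."""

    plan_id: str
    modes: Mapping[str, ModeMetrics]
    missing_modes: tuple[str, ...] = ()


def _percent_diff(computed: float, reference: float) -> float:
    return (computed - reference) / reference * 100.0


def _mode_metrics(
    plan,
    beam_doses: Sequence[dm.DoseGrid],
    chamber: dm.StructureMask,
    shell: dm.StructureMask,
    sphere: dm.StructureMask,
    ref_quadruple: tuple[float, float] | None,
    measurement: float | None,
    config: AnalysisConfig,
) -> ModeMetrics:
    total = dm.sum_beam_doses(beam_doses)
    hi = dm.homogeneity_index(total, chamber)
    coin = dm.conformity_index(total, chamber, shell)
    mcs = plan_mcs(plan, config.gap_threshold_cm)
    ifrac = dm.intersection_fraction(
        beam_doses,
        chamber,
        config.intersect_frac_of_max,
        gantry_angles_deg=[b.gantry_deg for b in plan.beams],
    )
    chamber_mean = float(total.values[chamber.voxels].mean())
    per_beam_u = [
        bd.rel_uncertainty_pct for bd in beam_doses if bd.rel_uncertainty_pct is not None
    ]
    combined = (
        dm.combined_uncertainty(per_beam_u) if len(per_beam_u) == len(beam_doses) else float("nan")
    )

    k = diff_unc = diff_cor = None
    if ref_quadruple is not None:
        dw_ref, dair_ref = ref_quadruple
        dw_clin = float(total.values[sphere.voxels].mean())
        k = k_qclin(
            KFactorInputs(
                dw_clin=dw_clin, dair_clin=chamber_mean, dw_ref=dw_ref, dair_ref=dair_ref
            )
        ).value
        if measurement is not None:
            diff_unc = _percent_diff(dw_clin, measurement)
            diff_cor = _percent_diff(dw_clin, measurement * k)
    return ModeMetrics(
        hi=hi,
        coin=coin,
        mcs_plan=mcs,
        intersection_fraction=ifrac,
        chamber_mean_dose_gy=chamber_mean,
        combined_uncertainty_pct=combined,
        hi_below_threshold=hi < config.hi_threshold,
        k_qclin=k,
        diff_uncorrected_pct=diff_unc,
        diff_corrected_pct=diff_cor,
    )


def reference_field_doses(spec: PhantomSpec) -> tuple[float, float]:
    """(water-sphere, chamber-cavity) mean doses of the 10x10 reference field."""
    ref = toy_beam_dose(reference_field_beam(), spec)
    sphere = water_sphere_mask(spec)
    chamber = chamber_mask(spec)
    return (
        float(ref.values[sphere.voxels].mean()),
        float(ref.values[chamber.voxels].mean()),
    )


def run_comparison(
    case: SyntheticCase,
    config: AnalysisConfig | None = None,
    ref_quadruple: tuple[float, float] | None = None,
) -> QAReport:
    """Compute the full rotated-vs-collapsed QA report of one synthetic case.

    The correction-factor quadruple uses the water-sphere mean dose as the
    computed dose to water, the chamber-contour mean as the cavity dose,
    and the 10x10 reference field doses (computed once per phantom unless
    passed in via *ref_quadruple*).
    """
    config = config or AnalysisConfig()
    spec = case.config.phantom
    chamber = chamber_mask(spec)
    shell = dm.expand_mask(chamber, config.shell_margin_cm)
    sphere = water_sphere_mask(spec)
    if ref_quadruple is None:
        ref_quadruple = reference_field_doses(spec)

    modes: dict[str, ModeMetrics] = {}
    missing: list[str] = []
    mode_inputs = {
        "rotated": (case.plan, case.rotated_beam_doses, case.pseudo_measurement_rotated),
        "collapsed": (
            case.collapsed_plan,
            case.collapsed_beam_doses,
            case.pseudo_measurement_collapsed,
        ),
    }
    for mode, (plan, doses, meas) in mode_inputs.items():
        if not doses:
            missing.append(mode)
            continue
        modes[mode] = _mode_metrics(
            plan, doses, chamber, shell, sphere, ref_quadruple, meas, config
        )
    return QAReport(plan_id=case.plan.plan_id, modes=modes, missing_modes=tuple(missing))


@dataclass(frozen=True)
class CohortSummary:
    """Per-mode cohort statistics of the computed-vs-measured differences."""

    n: int
    mean_diff_pct: Mapping[str, Mapping[str, float]]        # [mode][corrected|uncorrected]
    sd_diff_pct: Mapping[str, Mapping[str, float | None]]   # sample SD, None when n < 2
    rms_pct: Mapping[str, Mapping[str, float]]
    median_hi: Mapping[str, float] = field(default_factory=dict)
    median_coin: Mapping[str, float] = field(default_factory=dict)
    mean_mcs: Mapping[str, float] = field(default_factory=dict)
    mean_intersection_fraction: Mapping[str, float] = field(default_factory=dict)


def cohort_summary(reports: Sequence[QAReport]) -> CohortSummary:
    """Aggregate per-patient reports into the cohort table.

    Percent-difference statistics use the sample standard deviation (n-1);
    the percent relative RMS is taken over patients per mode and
    correction status.
    """
    if not reports:
        raise ValueError("need at least one report")
    mean_d: dict[str, dict[str, float]] = {}
    sd_d: dict[str, dict[str, float | None]] = {}
    rms: dict[str, dict[str, float]] = {}
    med_hi: dict[str, float] = {}
    med_coin: dict[str, float] = {}
    mean_mcs: dict[str, float] = {}
    mean_if: dict[str, float] = {}
    for mode in MODES:
        mms = [r.modes[mode] for r in reports if mode in r.modes]
        if not mms:
            continue
        med_hi[mode] = float(np.median([m.hi for m in mms]))
        med_coin[mode] = float(np.median([m.coin for m in mms]))
        mean_mcs[mode] = float(np.mean([m.mcs_plan for m in mms]))
        mean_if[mode] = float(np.mean([m.intersection_fraction for m in mms]))
        mean_d[mode], sd_d[mode], rms[mode] = {}, {}, {}
        for status, attr in (
            ("uncorrected", "diff_uncorrected_pct"),
            ("corrected", "diff_corrected_pct"),
        ):
            diffs = [getattr(m, attr) for m in mms if getattr(m, attr) is not None]
            if not diffs:
                continue
            arr = np.asarray(diffs)
            mean_d[mode][status] = float(arr.mean())
            sd_d[mode][status] = float(arr.std(ddof=1)) if arr.size >= 2 else None
            rms[mode][status] = float(np.sqrt(np.mean(arr**2)))
    return CohortSummary(
        n=len(reports),
        mean_diff_pct=mean_d,
        sd_diff_pct=sd_d,
        rms_pct=rms,
        median_hi=med_hi,
        median_coin=med_coin,
        mean_mcs=mean_mcs,
        mean_intersection_fraction=mean_if,
    )


def reports_to_dataframe(reports: Sequence[QAReport]) -> pd.DataFrame:
    """Flat per-patient, per-mode table of all metrics (CSV export)."""
    rows = []
    for r in reports:
        for mode, m in r.modes.items():
            rows.append(
                {
                    "plan_id": r.plan_id,
                    "mode": mode,
                    "hi": m.hi,
                    "coin": m.coin,
                    "mcs_plan": m.mcs_plan,
                    "intersection_fraction": m.intersection_fraction,
                    "chamber_mean_dose_gy": m.chamber_mean_dose_gy,
                    "combined_uncertainty_pct": m.combined_uncertainty_pct,
                    "hi_below_threshold": m.hi_below_threshold,
                    "k_qclin": m.k_qclin,
                    "diff_uncorrected_pct": m.diff_uncorrected_pct,
                    "diff_corrected_pct": m.diff_corrected_pct,
                }
            )
    return pd.DataFrame(rows)
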