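"""Small-field output correction (Alfonso formalism) and MC efficiency.

A chamber calibrated in a 10x10 cm^2 reference field over-responds or
under-responds in small, irregular IMRT fields because stopping-power
ratios and perturbation factors shift.  The correction factor

    k_Qclin = (Dw_clin / Dair_clin) / (Dw_ref / Dair_ref)

is the double ratio of dose to a water sphere (equal in volume to the
chamber's air cavity) and dose to the cavity itself, in the clinical and
reference fields.  Applied to a corrected reading M it converts to dose
to water: D = M * N_D,w * k_Q,Q0 * k_Qclin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "KFactorInputs",
    "ChamberReading",
    "KQclin",
    "k_qclin",
    "dose_to_water_from_reading",
    "mc_efficiency",
]


@dataclass(frozen=True)
class KFactorInputs:
    """The four cavity/water doses entering the k_Qclin double ratio.

    All doses in Gy and > 0; optional relative uncertainties in percent
    are combined in quadrature (independence assumed).
    """

    dw_clin: float   # water sphere, clinical field
    dair_clin: float  # chamber air cavity, clinical field
    dw_ref: float    # water sphere, 10x10 reference field
    dair_ref: float  # chamber air cavity, reference field
    u_dw_clin_pct: float | None = None
    u_dair_clin_pct: float | None = None
    u_dw_ref_pct: float | None = None
    u_dair_ref_pct: float | None = None

    def __post_init__(self) -> None:
        for name in ("dw_clin", "dair_clin", "dw_ref", "dair_ref"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def uncertainties_pct(self) -> tuple[float, float, float, float] | None:
        us = (self.u_dw_clin_pct, self.u_dair_clin_pct, self.u_dw_ref_pct, self.u_dair_ref_pct)
        if all(u is None for u in us):
            return None
        return tuple(0.0 if u is None else float(u) for u in us)  # type: ignore[return-value]


class KQclin(NamedTuple):
    """k_Qclin value with its propagated relative uncertainty (%), if any."""

    value: float
    rel_uncertainty_pct: float | None = None

    def __float__(self) -> float:
        return self.value


def k_qclin(inputs: KFactorInputs) -> KQclin:
    """Small-field correction factor from the four-dose double ratio.

    Scale-invariant (multiplying all four doses by c > 0 changes nothing)
    and exactly 1 when the clinical field equals the reference field.
    Uncertainty, when per-dose values are provided, is their quadrature sum.
    """
    value = (inputs.dw_clin / inputs.dair_clin) / (inputs.dw_ref / inputs.dair_ref)
    us = inputs.uncertainties_pct
    unc = math.sqrt(sum(u * u for u in us)) if us is not None else None
    return KQclin(value=value, rel_uncertainty_pct=unc)


@dataclass(frozen=True)
class ChamberReading:
    """Chamber reading corrected for influence quantities, with calibration."""

    m_corrected: float  # nC, corrected for T/P, polarity, recombination
    nd_w: float         # Gy/nC absorbed-dose-to-water calibration coefficient
    kq_q0: float        # beam quality correction relative to Q0 (e.g. Co-60)

    def __post_init__(self) -> None:
        for name in ("m_corrected", "nd_w", "kq_q0"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")


def dose_to_water_from_reading(reading: ChamberReading, kq_clin: float) -> float:
    """Dose to water (Gy) in the clinical field: M * N_D,w * k_Q,Q0 * k_Qclin."""
    k = float(kq_clin)
    if not (math.isfinite(k) and k > 0):
        raise ValueError(f"kq_clin must be finite and > 0, got {k}")
    return reading.m_corrected * reading.nd_w * reading.kq_q0 * k


def mc_efficiency(cpu_seconds: float, sigma_pct: float) -> float:
    """Monte Carlo efficiency eps = 1 / (T * sigma^2), in 1/(s * %^2)."""
    if not (math.isfinite(cpu_seconds) and cpu_seconds > 0):
        raise ValueError(f"cpu_seconds must be > 0, got {cpu_seconds}")
    if not (math.isfinite(sigma_pct) and sigma_pct > 0):
        raise ValueError(f"sigma_pct must be > 0, got {sigma_pct}")
    return 1.0 / (cpu_seconds * sigma_pct**2)
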