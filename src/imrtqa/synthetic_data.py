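"""Synthetic deliveries: random MLC plans, a toy dose engine, pseudo-measurements.

The generator emulates the study conditions of chamber-based IMRT QA in a
virtual water phantom: a 30x30x17 cm^3 box with 0.3 cm dose voxels, a
Farmer-type cylindrical chamber (0.65 cc) at isocenter at 8.5 cm depth and
100 cm SAD, multi-beam step-and-shoot-style plans with controllable
modulation, and paired rotated (planned gantry angles) vs collapsed
(single angle) deliveries with noisy scalar chamber pseudo-measurements.

The dose engine is a deliberately simple divergent-aperture model — primary
photon fluence through the MLC aperture with a Gaussian penumbra, a single
effective exponential attenuation in water and inverse-square falloff.  It
models no scatter, no leaf transmission and no electron transport; it is a
deterministic stand-in that reproduces the geometric structure of beam
deliveries (crossfire averaging, depth gradients, penumbrae), not a
dosimetric engine.

Gantry convention: IEC-style rotation about the y axis, isocenter at the
coordinate origin; at gantry 0 the source sits at (0, 0, +SAD) and the beam
points down -z.  MLC leaves run along x (leaf travel) and are stacked
along y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from .dose_metrics import DoseGrid, StructureMask
from .plan_model import Beam, MLCSegment, Plan, collapse_plan

__all__ = [
    "PhantomSpec",
    "SimulationConfig",
    "SyntheticCase",
    "phantom_grid",
    "chamber_mask",
    "water_sphere_mask",
    "reference_field_beam",
    "generate_plan",
    "toy_beam_dose",
    "simulate_patient",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Virtual water phantom, chamber and toy-engine physics parameters.

    Defaults reproduce the QA setup the package emulates: 30x30x17 cm^3
    solid-water box, 0.3 cm voxels, 100 cm SAD, chamber at 8.5 cm depth
    (the phantom's mid-plane), Farmer-like cylinder of 0.3 cm radius and
    2.3 cm length (~0.65 cc) with its axis along the gantry rotation axis.
    """

    size: tuple[float, float, float] = (30.0, 30.0, 17.0)  # cm (x, y, z)
    voxel_cm: float = 0.3
    sad_cm: float = 100.0
    chamber_depth_cm: float = 8.5    # below the z+ entrance surface
    chamber_radius_cm: float = 0.3
    chamber_length_cm: float = 2.3   # axis along y
    attenuation_mu: float = 0.049    # 1/cm, 6 MV-like effective value
    penumbra_sigma_cm: float = 0.3
    noise_sd_pct: float = 0.5        # pseudo-measurement reproducibility

    def __post_init__(self) -> None:
        if self.voxel_cm <= 0 or self.sad_cm <= 0:
            raise ValueError("voxel_cm and sad_cm must be > 0")
        for s in self.size:
            n = s / self.voxel_cm
            if abs(n - round(n)) > 1.0:
                raise ValueError(f"voxel {self.voxel_cm} does not tile extent {s}")
        # chamber must sit fully inside the phantom
        if not (
            self.chamber_radius_cm < self.size[0] / 2
            and self.chamber_length_cm / 2 < self.size[1] / 2
            and self.chamber_radius_cm < min(self.chamber_depth_cm,
                                             self.size[2] - self.chamber_depth_cm)
        ):
            raise ValueError("chamber does not fit inside the phantom")

    @property
    def origin(self) -> tuple[float, float, float]:
        """Grid corner in cm; isocenter (= chamber center) is at (0, 0, 0)."""
        return (
            -self.size[0] / 2.0,
            -self.size[1] / 2.0,
            self.chamber_depth_cm - self.size[2],
        )

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(round(s / self.voxel_cm)) for s in self.size)

    @property
    def chamber_volume_cc(self) -> float:
        return math.pi * self.chamber_radius_cm**2 * self.chamber_length_cm


def phantom_grid(spec: PhantomSpec, values: np.ndarray | None = None) -> DoseGrid:
    """Empty (or filled) dose grid on the phantom lattice."""
    if values is None:
        values = np.zeros(spec.dims)
    return DoseGrid(origin=spec.origin, spacing=(spec.voxel_cm,) * 3, values=values)


def _voxel_centers(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    o, v = spec.origin, spec.voxel_cm
    return tuple(o[i] + (np.arange(spec.dims[i]) + 0.5) * v for i in range(3))


def chamber_mask(spec: PhantomSpec) -> StructureMask:
    """Cylindrical chamber contour at isocenter, axis along y."""
    xs, ys, zs = _voxel_centers(spec)
    xx = xs[:, None, None]
    yy = ys[None, :, None]
    zz = zs[None, None, :]
    inside = (xx**2 + zz**2 <= spec.chamber_radius_cm**2 + 1e-12) & (
        np.abs(yy) <= spec.chamber_length_cm / 2.0 + 1e-12
    )
    return StructureMask(
        name="chamber", origin=spec.origin, spacing=(spec.voxel_cm,) * 3, voxels=inside
    )


def water_sphere_mask(spec: PhantomSpec) -> StructureMask:
    """Water sphere at isocenter with volume equal to the chamber cavity."""
    radius = (3.0 * spec.chamber_volume_cc / (4.0 * math.pi)) ** (1.0 / 3.0)
    xs, ys, zs = _voxel_centers(spec)
    rr = xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
    return StructureMask(
        name="water_sphere",
        origin=spec.origin,
        spacing=(spec.voxel_cm,) * 3,
        voxels=rr <= radius**2 + 1e-12,
    )


# ---------------------------------------------------------------------------
# Toy divergent-aperture dose engine
# ---------------------------------------------------------------------------

# MLC bank layout used by the generator and the engine: leaf pairs stacked
# along y with fixed width; leaf travel (left/right coordinates) along x.
DEFAULT_N_LEAF_PAIRS = 20
DEFAULT_LEAF_WIDTH_CM = 0.5


def _beam_geometry(gantry_deg: float, spec: PhantomSpec):
    """Per-voxel isocenter-plane projection (u, w), water depth and distance.

    u is the leaf-travel coordinate, w the leaf-stack coordinate, both
    projected to the isocenter plane along the diverging ray from the
    source through each voxel center.
    """
    theta = math.radians(gantry_deg)
    sad = spec.sad_cm
    src = np.array([sad * math.sin(theta), 0.0, sad * math.cos(theta)])
    e_axis = -np.array([math.sin(theta), 0.0, math.cos(theta)])  # source -> iso
    e_u = np.array([math.cos(theta), 0.0, -math.sin(theta)])

    xs, ys, zs = _voxel_centers(spec)
    dx = xs[:, None, None] - src[0]
    dy = np.broadcast_to(ys[None, :, None] - src[1], spec.dims)
    dz = zs[None, None, :] - src[2]

    denom = dx * e_axis[0] + dz * e_axis[2]  # dy has no axis component (axis_y = 0)
    denom = np.maximum(denom, 1e-6)
    scale = sad / denom
    # projected point minus iso = src + scale*d - iso; src - iso = -sad*e_axis
    u = scale * (dx * e_u[0] + dz * e_u[2])  # e_u is orthogonal to (src - iso)
    w = scale * dy

    dist = np.sqrt(dx**2 + dy**2 + dz**2)

    # water depth: distance from phantom entry to the voxel along the ray
    lo = np.asarray(spec.origin)
    hi = lo + np.asarray(spec.size)
    s_entry = np.zeros(spec.dims)
    for d, axis in ((dx, 0), (dy, 1), (dz, 2)):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (lo[axis] - src[axis]) / d
            t2 = (hi[axis] - src[axis]) / d
        t_near = np.fmin(t1, t2)
        t_near = np.where(np.isfinite(t_near), t_near, 0.0)
        s_entry = np.maximum(s_entry, t_near)
    depth = dist * np.clip(1.0 - s_entry, 0.0, None)

    return u, w, depth, dist


def toy_beam_dose(
    beam: Beam,
    spec: PhantomSpec,
    leaf_width_cm: float = DEFAULT_LEAF_WIDTH_CM,
) -> DoseGrid:
    """Deterministic toy dose of one beam on the phantom grid.

    Per segment, each voxel receives ``mu_weight * fluence * exp(-mu * depth)
    * (SAD / source-distance)^2`` where the fluence is the aperture
    indicator of the voxel's leaf pair smoothed along the leaf-travel
    direction with a Gaussian penumbra of ``penumbra_sigma_cm``.
    """
    u, w, depth, dist = _beam_geometry(beam.gantry_deg, spec)
    attn = np.exp(-spec.attenuation_mu * depth) * (spec.sad_cm / dist) ** 2

    n_pairs = beam.n_leaf_pairs
    half_span = n_pairs * leaf_width_cm / 2.0
    leaf_idx = np.floor((w + half_span) / leaf_width_cm).astype(int)
    in_bank = (leaf_idx >= 0) & (leaf_idx < n_pairs)
    leaf_idx = np.clip(leaf_idx, 0, n_pairs - 1)

    sigma = spec.penumbra_sigma_cm
    sq2s = math.sqrt(2.0) * sigma
    dose = np.zeros(spec.dims)
    for seg in beam.segments:
        if seg.mu_weight == 0.0:
            continue
        left = np.asarray(seg.left_positions)[leaf_idx]
        right = np.asarray(seg.right_positions)[leaf_idx]
        fluence = 0.5 * (erf((left - u) / sq2s) - erf((right - u) / sq2s))
        dose += seg.mu_weight * np.where(in_bank, fluence, 0.0)
    return phantom_grid(spec, values=dose * attn * 1e-2)  # ~cGy/MU -> Gy scale


def reference_field_beam(
    gantry_deg: float = 0.0,
    mu: float = 100.0,
    n_leaf_pairs: int = DEFAULT_N_LEAF_PAIRS,
    leaf_width_cm: float = DEFAULT_LEAF_WIDTH_CM,
    half_width_cm: float = 5.0,
) -> Beam:
    """The 10x10 cm^2 open reference field as a single-segment beam."""
    seg = MLCSegment(
        left_positions=(half_width_cm,) * n_leaf_pairs,
        right_positions=(-half_width_cm,) * n_leaf_pairs,
        mu_weight=mu,
    )
    return Beam(gantry_deg=gantry_deg, segments=(seg,), beam_mu=mu)


# ---------------------------------------------------------------------------
# Random plan generator
# ---------------------------------------------------------------------------

def generate_plan(
    n_beams: int,
    n_segments: int,
    modulation: float,
    seed: int,
    n_leaf_pairs: int = DEFAULT_N_LEAF_PAIRS,
    base_half_width_cm: float = 4.0,
    plan_id: str | None = None,
) -> Plan:
    """Random multi-beam step-and-shoot plan with controllable modulation.

    Beams sit at evenly spaced gantry angles covering the full circle.
    ``modulation`` in [0, 1] controls aperture irregularity: 0 produces a
    static rectangular field (MCS exactly 1); larger values shrink, offset
    and jag the apertures and randomly close leaf pairs, driving the MCS
    down.  Identical arguments give bit-identical plans.
    """
    if n_beams < 1 or n_segments < 1:
        raise ValueError("need at least one beam and one segment")
    if not 0.0 <= modulation <= 1.0:
        raise ValueError("modulation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    m = modulation
    beams = []
    for j in range(n_beams):
        gantry = (360.0 * j) / n_beams
        segs = []
        for _ in range(n_segments):
            mu = float(rng.uniform(5.0, 15.0))
            if m == 0.0:
                left = np.full(n_leaf_pairs, base_half_width_cm)
                right = np.full(n_leaf_pairs, -base_half_width_cm)
            else:
                center = rng.uniform(-3.0 * m, 3.0 * m)
                half = base_half_width_cm * (1.0 - 0.7 * m * rng.uniform())
                left = center + half + m * 1.5 * rng.standard_normal(n_leaf_pairs)
                right = center - half + m * 1.5 * rng.standard_normal(n_leaf_pairs)
                closed = rng.uniform(size=n_leaf_pairs) < 0.3 * m
                mid = 0.5 * (left + right)
                crossed = left < right
                left = np.where(closed | crossed, mid, left)
                right = np.where(closed | crossed, mid, right)
            segs.append(MLCSegment(tuple(left), tuple(right), mu))
        beams.append(Beam.from_segments(gantry, segs))
    return Plan(
        plan_id=plan_id or f"synthetic-{seed}-m{modulation:g}",
        beams=tuple(beams),
    )


# ---------------------------------------------------------------------------
# Paired rotated / collapsed patient simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic QA patient."""

    n_beams: int = 9
    n_segments: int = 6
    modulation: float = 0.5
    collapsed_angle_deg: float = 0.0
    base_uncertainty_pct: float = 0.3  # Type-A surrogate for a well-hit chamber
    phantom: PhantomSpec = field(default_factory=PhantomSpec)


@dataclass(frozen=True)
class SyntheticCase:
    """One synthetic patient: plan, per-beam doses in both modes, measurements."""

    plan: Plan
    collapsed_plan: Plan
    rotated_beam_doses: tuple[DoseGrid, ...]
    collapsed_beam_doses: tuple[DoseGrid, ...]
    pseudo_measurement_rotated: float
    pseudo_measurement_collapsed: float
    seed: int
    config: SimulationConfig


def _beam_uncertainty_pct(
    beam_dose: DoseGrid, chamber: StructureMask, plan_mean: float, u0: float
) -> float:
    """Type-A uncertainty surrogate: grows as the beam misses the chamber.

    Emulates Monte Carlo statistics where fewer histories contribute to the
    cavity: u = u0 * sqrt(plan-mean chamber dose / this beam's chamber
    dose), capped at 5%.
    """
    mean = float(beam_dose.values[chamber.voxels].mean())
    if mean <= 0 or plan_mean <= 0:
        return 5.0
    return float(min(u0 * math.sqrt(plan_mean / mean), 5.0))


def simulate_patient(config: SimulationConfig, seed: int) -> SyntheticCase:
    """Build one paired rotated/collapsed synthetic QA case, fully seeded.

    The pseudo-measurement per mode is the mean dose over the chamber
    contour of the mode's total dose, perturbed by Gaussian noise of
    ``noise_sd_pct`` (the chamber reading already converted with the
    reference-field calibration, i.e. without the small-field correction).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20133]))
    plan = generate_plan(
        n_beams=config.n_beams,
        n_segments=config.n_segments,
        modulation=config.modulation,
        seed=int(rng.integers(0, 2**31 - 1)),
        plan_id=f"patient-{seed}",
    )
    collapsed = collapse_plan(plan, config.collapsed_angle_deg)
    spec = config.phantom
    chamber = chamber_mask(spec)

    def mode_doses(p: Plan) -> tuple[tuple[DoseGrid, ...], float]:
        doses = [toy_beam_dose(b, spec) for b in p.beams]
        means = [float(d.values[chamber.voxels].mean()) for d in doses]
        plan_mean = float(np.mean(means))
        doses = [
            replace(
                d,
                rel_uncertainty_pct=_beam_uncertainty_pct(
                    d, chamber, plan_mean, config.base_uncertainty_pct
                ),
            )
            for d in doses
        ]
        return tuple(doses), float(np.sum(means))

    rotated_doses, rot_total = mode_doses(plan)
    collapsed_doses, col_total = mode_doses(collapsed)
    noise = spec.noise_sd_pct / 100.0
    meas_rot = rot_total * (1.0 + noise * rng.standard_normal())
    meas_col = col_total * (1.0 + noise * rng.standard_normal())
    return SyntheticCase(
        plan=plan,
        collapsed_plan=collapsed,
        rotated_beam_doses=rotated_doses,
        collapsed_beam_doses=collapsed_doses,
        pseudo_measurement_rotated=meas_rot,
        pseudo_measurement_collapsed=meas_col,
        seed=seed,
        config=config,
    )
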