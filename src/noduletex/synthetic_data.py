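"""Synthetic CT phantom cohorts with known ground truth.

Every stage of the analysis pipeline is testable without patient data: the
generator produces CT volumes containing a single ellipsoidal nodule on an
aerated-lung background (-800 HU, below the -450 HU inclusion bound, so
segmentation of the phantom is exact by construction), optionally with an
attached vessel whose HU lies inside the inclusion interval to exercise
structure subtraction.

Texture model
-------------
Nodule voxel HU values are drawn i.i.d. from a two-component Gaussian
mixture in standardized form,

    X ~ (1 - p) * body  +  p * N(d, tau^2),

where the *body* is either a flat plateau (uniform on [-sqrt(3), sqrt(3)];
benign "homogeneous stable tissue") or a narrow spike (standard normal;
malignant "dense proteinaceous soft tissue"), and the secondary component
models dispersed dense material (micro-calcification flecks in stable
nodules; heterogeneous vascularised tissue in malignant ones).  All four
raw moments of the mixture are closed-form, so (p, d, tau) can be solved to
hit any feasible per-nodule (skewness, kurtosis) target, and the analytic
moments serve as an independent oracle in tests.  The standardized draw is
then mapped to HU by a location/scale pair; malignant defaults concentrate
mass in the 0-100 HU soft-tissue band.

Per-nodule (SKW*, KUR*) targets are drawn from class-level truncated
Gaussians whose proposal parameters were calibrated (by iterated simulation
of the full generate-segment-measure pipeline, then frozen) so that default
cohorts reproduce the reference cohort means: benign SKW 1.73 / KUR 3.37,
malignant SKW 2.07 / KUR 5.88.  A small "atypical" fraction of each class
uses the other class's body structure, mirroring the minority of benign
nodules with peaked histograms and malignant nodules with plateaus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import truncnorm

from .segmentation import DEFAULT_HU_INTERVAL
from .volume_io import CTVolume, quantize_12bit

SQRT3 = math.sqrt(3.0)

#: feasibility margin above the universal bound KUR >= SKW^2 - 2
KURTOSIS_MARGIN = 0.2

#: mixture-weight grids tried in order when solving (p, d, tau)
P_GRID_FLAT = (0.02, 0.04, 0.06, 0.10, 0.15, 0.25)
P_GRID_SPIKE = (0.05, 0.08, 0.12, 0.18, 0.25)


# ---------------------------------------------------------------------------
# Texture family: structured body + secondary Gaussian component
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureParams:
    """Distribution-family parameters for one nodule's voxel HU values."""

    skew: float            # target skewness of the standardized family
    kurt: float            # target excess kurtosis
    loc_hu: float          # location of the HU distribution
    scale_hu: float        # scale (SD) of the HU distribution
    body: str = "spike"    # "flat" (plateau body) | "spike" (normal body)


def _raw_body_moments(body: str) -> tuple[float, float]:
    """(E[B^2], E[B^4]) for the unit-variance, symmetric body component."""
    if body == "flat":
        return 1.0, 9.0 / 5.0       # uniform on [-sqrt3, sqrt3]
    if body == "spike":
        return 1.0, 3.0             # standard normal
    raise ValueError(f"unknown body: {body!r}")


def mixture_moments(p: float, d: float, tau: float, body: str):
    """Mean and central moments (mu2, mu3, mu4) of the mixture."""
    b2, b4 = _raw_body_moments(body)
    m = p * d
    a1, a2 = -m, d - m
    mu2 = (1 - p) * (b2 + a1 ** 2) + p * (tau ** 2 + a2 ** 2)
    mu3 = (1 - p) * (a1 ** 3 + 3 * a1 * b2) + p * (a2 ** 3 + 3 * a2 * tau ** 2)
    mu4 = ((1 - p) * (a1 ** 4 + 6 * a1 ** 2 * b2 + b4)
           + p * (a2 ** 4 + 6 * a2 ** 2 * tau ** 2 + 3 * tau ** 4))
    return m, mu2, mu3, mu4


def mixture_skew_kurt(p: float, d: float, tau: float, body: str):
    """Analytic (skewness, excess kurtosis) of the mixture; oracle-friendly."""
    _, mu2, mu3, mu4 = mixture_moments(p, d, tau, body)
    return mu3 / mu2 ** 1.5, mu4 / mu2 ** 2 - 3.0


def solve_mixture(skew: float, kurt: float, body: str) -> tuple[float, float, float]:
    """Find (p, d, tau) whose mixture has the target skewness and kurtosis.

    The mixture weight p is scanned over a small grid (preferring sparse
    secondary components for the flat body and small spike contamination for
    the spike body); (d, log tau) are solved by least squares.  Raises
    ValueError when the target is infeasible for the family.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        grid = P_GRID_FLAT if body == "flat" else P_GRID_SPIKE
        for p in grid:
            for tau0, d0 in ((2.0, 3.0), (0.7, 4.0), (3.5, 2.0), (1.0, 6.0)):
                def resid(x, p=p):
                    s, k = mixture_skew_kurt(p, x[0], math.exp(x[1]), body)
                    return [s - skew, k - kurt]
                try:
                    sol = least_squares(resid, [d0, math.log(tau0)],
                                        method="lm", max_nfev=400)
                except Exception:
                    continue
                d, tau = sol.x[0], math.exp(sol.x[1])
                s, k = mixture_skew_kurt(p, d, tau, body)
                if (abs(s - skew) < 1e-7 and abs(k - kurt) < 1e-7
                        and abs(d) < 60 and tau < 60):
                    return p, d, tau
    raise ValueError(
        f"(skew={skew:.3f}, kurt={kurt:.3f}) infeasible for body={body!r}")


def sample_standardized(
    p: float, d: float, tau: float, body: str, n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n standardized (zero-mean, unit-variance) mixture samples."""
    if body == "flat":
        x = rng.uniform(-SQRT3, SQRT3, n)
    else:
        x = rng.standard_normal(n)
    sel = rng.random(n) < p
    x[sel] = d + tau * rng.standard_normal(int(sel.sum()))
    m, mu2, _, _ = mixture_moments(p, d, tau, body)
    return (x - m) / math.sqrt(mu2)


# ---------------------------------------------------------------------------
# Phantom specification and rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselSpec:
    direction: tuple[float, float, float]   # unit-ish vector, (x, y, z)
    radius_mm: float = 1.3
    hu: float = 60.0
    length_mm: float = 12.0


@dataclass(frozen=True)
class PhantomSpec:
    label: str                                  # "benign" | "malignant"
    center: tuple[int, int, int]                # (x, y, z) voxel coordinates
    radius_mm: float                            # (0, 15]; SPN: diameter <= 3 cm
    texture: TextureParams
    axis_ratios: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = -800.0
    background_noise_sd: float = 30.0
    vessel: VesselSpec | None = None
    rng_seed: int = 0
    shape: tuple[int, int, int] = (48, 48, 48)  # lattice (nx, ny, nz)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        if self.label not in ("benign", "malignant"):
            raise ValueError("label must be 'benign' or 'malignant'")
        if not (0 < self.radius_mm <= 15.0):
            raise ValueError("radius_mm must lie in (0, 15] (SPN definition)")
        for axis in range(3):
            r_vox = self.radius_mm * self.axis_ratios[axis] / self.spacing[axis]
            if (self.center[axis] - r_vox < 0
                    or self.center[axis] + r_vox >= self.shape[axis]):
                raise ValueError("nodule does not fit inside the lattice")


@dataclass
class PhantomTruth:
    volume: CTVolume
    mask: np.ndarray          # ground-truth nodule voxels, [z, y, x]
    vessel_mask: np.ndarray   # attached-structure voxels, disjoint from mask
    label: str
    spec: PhantomSpec


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    cx, cy, cz = spec.center
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    rx, ry, rz = (spec.radius_mm * a for a in spec.axis_ratios)
    return (((xx - cx) * dx / rx) ** 2 + ((yy - cy) * dy / ry) ** 2
            + ((zz - cz) * dz / rz) ** 2) <= 1.0


def _vessel_mask(spec: PhantomSpec, nodule: np.ndarray) -> np.ndarray:
    v = spec.vessel
    direction = np.asarray(v.direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    rel = np.stack([(xx - spec.center[0]) * dx,
                    (yy - spec.center[1]) * dy,
                    (zz - spec.center[2]) * dz], axis=-1)
    along = rel @ direction
    perp = np.linalg.norm(rel - along[..., None] * direction, axis=-1)
    reach = spec.radius_mm * max(spec.axis_ratios) + v.length_mm
    cylinder = (along >= 0) & (along <= reach) & (perp <= v.radius_mm)
    return cylinder & ~nodule


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render a phantom CT volume with ground-truth nodule and vessel masks.

    Deterministic for a fixed spec (including rng_seed).  Background noise
    is clipped to stay below the segmentation inclusion interval, so the
    background can never leak into a default segmentation.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    nx, ny, nz = spec.shape
    lo, hi = DEFAULT_HU_INTERVAL

    voxels = np.full((nz, ny, nx), float(spec.background_hu))
    if spec.background_noise_sd > 0:
        voxels += rng.normal(0.0, spec.background_noise_sd, voxels.shape)
        voxels = np.minimum(voxels, lo - 10.0)  # keep background out of interval

    nodule = _ellipsoid_mask(spec)
    vessel = (_vessel_mask(spec, nodule) if spec.vessel is not None
              else np.zeros_like(nodule))
    if spec.vessel is not None:
        voxels[vessel] = spec.vessel.hu + rng.normal(0.0, 5.0, int(vessel.sum()))

    t = spec.texture
    p, d, tau = solve_mixture(t.skew, t.kurt, t.body)
    x = sample_standardized(p, d, tau, t.body, int(nodule.sum()), rng)
    hu = t.loc_hu + t.scale_hu * x
    voxels[nodule] = np.clip(hu, lo + 1.0, hi - 1.0)

    volume = quantize_12bit(CTVolume(voxels, spec.spacing,
                                     spec.spacing[2], {"phantom": spec.label}))
    # quantisation rounds the vessel/nodule values but cannot push them out
    # of the open interval; re-derive the vessel mask after rounding
    return PhantomTruth(volume=volume, mask=nodule, vessel_mask=vessel,
                        label=spec.label, spec=spec)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassProfile:
    """Hyperdistribution of per-nodule texture targets for one class.

    ``mu_skew``/``mu_kurt`` are *proposal* means of the truncated Gaussians;
    they were calibrated by simulation so that the realized cohort means of
    the measured statistics land on the reference targets (see
    docs/methods.md), which truncation to the feasible region and
    finite-voxel moment bias would otherwise shift.
    """

    mu_skew: float
    sd_skew: float
    mu_kurt: float
    sd_kurt: float
    body: str                          # typical body structure
    loc_hu: tuple[float, float]        # (mean, sd) of the HU location
    scale_hu: tuple[float, float]      # (mean, sd) of the HU scale
    atypical_fraction: float = 0.12    # uses the other class's structure


BENIGN_PROFILE = ClassProfile(
    mu_skew=1.60, sd_skew=0.94, mu_kurt=-2.5, sd_kurt=3.0,
    body="flat", loc_hu=(35.0, 10.0), scale_hu=(55.0, 8.0))
MALIGNANT_PROFILE = ClassProfile(
    mu_skew=1.96, sd_skew=1.01, mu_kurt=0.5, sd_kurt=4.0,
    body="spike", loc_hu=(50.0, 8.0), scale_hu=(22.0, 4.0),
    atypical_fraction=0.07)

#: structure-specific location/scale used when a nodule is atypical
_ATYPICAL_LOC_SCALE = {
    "flat": ((40.0, 10.0), (50.0, 8.0)),
    "spike": ((50.0, 8.0), (25.0, 5.0)),
}

RADIUS_RANGE_MM = (5.3, 9.3)
AXIS_RATIO_RANGE = (0.92, 1.08)
VESSEL_PROBABILITY = 0.35


def _draw_truncated(rng, mu, sd, lo, hi) -> float:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def draw_phantom_spec(
    label: str, rng: np.random.Generator, rng_seed: int,
    profile: ClassProfile | None = None,
) -> PhantomSpec:
    """Draw one phantom specification from a class hyperdistribution."""
    if profile is None:
        profile = BENIGN_PROFILE if label == "benign" else MALIGNANT_PROFILE
    atypical = rng.random() < profile.atypical_fraction
    body = ({"flat": "spike", "spike": "flat"}[profile.body]
            if atypical else profile.body)
    skew = _draw_truncated(rng, profile.mu_skew, profile.sd_skew, 0.2, 4.5)
    kurt = _draw_truncated(rng, profile.mu_kurt, profile.sd_kurt,
                           skew * skew - 2.0 + KURTOSIS_MARGIN, 30.0)
    # nudge infeasible targets upward until the family can realize them
    for _ in range(8):
        try:
            solve_mixture(skew, kurt, body)
            break
        except ValueError:
            kurt += 0.5

    loc_ms, scale_ms = ((profile.loc_hu, profile.scale_hu) if not atypical
                        else _ATYPICAL_LOC_SCALE[body])
    loc = float(rng.normal(*loc_ms))
    scale = float(max(rng.normal(*scale_ms), 12.0))

    radius = float(rng.uniform(*RADIUS_RANGE_MM))
    ratios = tuple(float(rng.uniform(*AXIS_RATIO_RANGE)) for _ in range(3))
    center = tuple(int(24 + rng.integers(-2, 3)) for _ in range(3))

    vessel = None
    if rng.random() < VESSEL_PROBABILITY:
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        vessel = VesselSpec(direction=tuple(float(c) for c in direction),
                            radius_mm=float(rng.uniform(1.0, 1.6)),
                            hu=float(rng.normal(60.0, 8.0)))

    texture = TextureParams(skew=skew, kurt=kurt, loc_hu=loc,
                            scale_hu=scale, body=body)
    return PhantomSpec(label=label, center=center, radius_mm=radius,
                       texture=texture, axis_ratios=ratios,
                       vessel=vessel, rng_seed=rng_seed)


def _child_rng(master_seed: int, index: int):
    """Counter-based seed splitting: reproducible independent of order."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(index,))
    seed = int(ss.generate_state(1)[0])
    return np.random.default_rng(ss), seed


def generate_cohort(
    n_benign: int = 50, n_malignant: int = 50, master_seed: int = 0,
) -> list[PhantomTruth]:
    """Generate a labelled phantom cohort with default class calibrations.

    Per-nodule texture targets, geometry, and vessel attachments are drawn
    from class-level hyperdistributions; per-phantom seeds derive from
    ``master_seed`` by counter-based splitting so the cohort is reproducible
    and order-independent.
    """
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("need at least one phantom per class")
    cohort = []
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    for i, label in enumerate(labels):
        rng, seed = _child_rng(master_seed, i)
        spec = draw_phantom_spec(label, rng, rng_seed=seed)
        cohort.append(generate_phantom(spec))
    return cohort


def generate_growth_pair(
    spec: PhantomSpec, vdt_days: float, delta_t_days: float,
) -> tuple[PhantomTruth, PhantomTruth]:
    """Two phantoms of the same nodule whose volume ratio encodes a volume
    doubling time: V2/V1 = 2^(delta_t / VDT).  An infinite VDT gives an
    identical nodule volume."""
    if not (vdt_days > 0):
        raise ValueError("vdt_days must be positive (or math.inf)")
    if delta_t_days <= 0:
        raise ValueError("delta_t_days must be positive")
    ratio = 1.0 if math.isinf(vdt_days) else 2.0 ** (delta_t_days / vdt_days)
    r2 = spec.radius_mm * ratio ** (1.0 / 3.0)
    spec2 = replace(spec, radius_mm=r2)
    try:
        spec2.validate()
    except ValueError as exc:
        raise ValueError(f"growth exceeds lattice: {exc}") from exc
    return generate_phantom(spec), generate_phantom(spec2)
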