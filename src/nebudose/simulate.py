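"""Synthetic SEM-like deposition images with exactly known ground truth.

Real deposition micrographs are scarce and never come with a known deposited
mass, so every downstream stage here is validated against simulated fields
whose ground truth is exact by construction.  The generator supports the two
deposition regimes seen for stable vs unstable nebulized suspensions:

* **homogeneous** — particle centers follow a uniform (binomial/Poisson)
  spatial point process, the pattern a well-dispersed suspension leaves;
* **clustered** — centers follow a Thomas process (Poisson parents,
  isotropic-Gaussian offspring of scale ``cluster_radius_nm``), emulating
  the small and large aggregates an unstable suspension deposits.

Either mode can additionally **stack** particles: with probability
``stacking_prob`` a particle lands on top of an existing one, incrementing
that center's multiplicity — mass increases but projected area does not.
This is exactly the regime in which an area-based monolayer dose model
underestimates, and the simulator makes that bias measurable.

Particles are rendered as filled disks of the primary diameter (a pixel is
particle if its center falls inside a disk); overlapping disks merge, as
touching particles do in a real micrograph.  Gaussian read noise is added
and the image quantized to the requested bit depth.  Identical parameters
and seed give bit-identical images and ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .dosimetry import ParticleSpec
from .image import ImageCalibration, SEMImage
from . import units

__all__ = [
    "DepositionParams",
    "DepositionGroundTruth",
    "EndpointReadouts",
    "simulate_deposition",
    "simulate_endpoint_readouts",
    "write_ground_truth",
]

#: 10 µm × 10 µm field at 1024² px — ~9.8 nm pixel pitch, so a 100 nm
#: particle spans ~10 px across.
DEFAULT_FIELD = ImageCalibration(
    scan_width_nm=10_000.0, scan_height_nm=10_000.0, pixels_x=1024, pixels_y=1024
)


@dataclass(frozen=True)
class DepositionParams:
    """Parameters of one simulated deposition field.

    Exactly one of ``target_dose_ug_cm2`` (expected areal dose; the particle
    count is drawn Poisson to match) or ``n_particles`` (exact count) must
    be given.  Intensity defaults: 8-bit, background 40, particle 200,
    noise sd 2% of the dynamic range.
    """

    particle: ParticleSpec
    mode: str = "homogeneous"  # homogeneous | clustered
    target_dose_ug_cm2: float | None = None
    n_particles: int | None = None
    field: ImageCalibration = DEFAULT_FIELD
    cluster_rate_per_um2: float | None = None  # parent density; derived if None
    mean_cluster_size: float = 10.0
    cluster_radius_nm: float = 200.0
    stacking_prob: float = 0.0
    noise_sd: float = 5.1
    background_level: int = 40
    particle_level: int = 200
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "clustered"):
            raise ValueError(f"mode must be 'homogeneous' or 'clustered', got {self.mode!r}")
        if (self.target_dose_ug_cm2 is None) == (self.n_particles is None):
            raise ValueError("give exactly one of target_dose_ug_cm2 or n_particles")
        if self.target_dose_ug_cm2 is not None and self.target_dose_ug_cm2 < 0:
            raise ValueError("target_dose_ug_cm2 must be >= 0")
        if self.n_particles is not None and self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if not 0.0 <= self.stacking_prob <= 1.0:
            raise ValueError(f"stacking_prob must be in [0, 1], got {self.stacking_prob!r}")
        max_intensity = 2**self.bit_depth - 1
        if not 0 <= self.background_level <= max_intensity:
            raise ValueError("background_level outside bit-depth range")
        if not 0 <= self.particle_level <= max_intensity:
            raise ValueError("particle_level outside bit-depth range")
        if self.particle_level <= self.background_level:
            raise ValueError("particle_level must exceed background_level")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mean_cluster_size <= 0 or self.cluster_radius_nm <= 0:
            raise ValueError("cluster parameters must be > 0")


@dataclass(frozen=True)
class DepositionGroundTruth:
    """Exact ground truth of a simulated field.

    ``centers_nm`` holds one (x, y) per rendered disk; ``multiplicity``
    counts how many particles sit at each center (stacking).  Mass and dose
    follow exactly from the total particle count and the sphere mass.
    """

    centers_nm: np.ndarray  # shape (k, 2)
    multiplicity: np.ndarray  # shape (k,), int
    n_particles: int
    true_mass_ug: float
    true_dose_ug_cm2: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "centers_nm": np.asarray(self.centers_nm).tolist(),
            "multiplicity": np.asarray(self.multiplicity).tolist(),
            "n_particles": int(self.n_particles),
            "true_mass_ug": self.true_mass_ug,
            "true_dose_ug_cm2": self.true_dose_ug_cm2,
            "seed": int(self.seed),
        }


def _draw_centers(params: DepositionParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n candidate centers (nm) on the field under the chosen process."""
    w = params.field.scan_width_nm
    h = params.field.scan_height_nm
    if n == 0:
        return np.empty((0, 2))
    if params.mode == "homogeneous":
        return rng.uniform((0.0, 0.0), (w, h), size=(n, 2))
    # Thomas process conditioned on total count: Poisson parents, each
    # particle assigned to a uniform parent with isotropic Gaussian offset.
    area_um2 = params.field.field_area_um2
    if params.cluster_rate_per_um2 is not None:
        parent_rate = params.cluster_rate_per_um2
    else:
        parent_rate = n / (params.mean_cluster_size * area_um2)
    n_parents = max(1, rng.poisson(parent_rate * area_um2))
    parents = rng.uniform((0.0, 0.0), (w, h), size=(n_parents, 2))
    assignment = rng.integers(0, n_parents, size=n)
    offsets = rng.normal(0.0, params.cluster_radius_nm, size=(n, 2))
    centers = parents[assignment] + offsets
    # wrap torus-fashion so every particle stays on the field and the
    # ground-truth mass balance is exact
    centers[:, 0] %= w
    centers[:, 1] %= h
    return centers


def _apply_stacking(
    centers: np.ndarray, stacking_prob: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Reassign each candidate (after the first) onto an existing center
    with probability stacking_prob; returns (kept centers, multiplicities)."""
    if len(centers) == 0:
        return centers, np.zeros(0, dtype=int)
    kept: list[np.ndarray] = [centers[0]]
    mult: list[int] = [1]
    for candidate in centers[1:]:
        if stacking_prob > 0 and rng.random() < stacking_prob:
            mult[rng.integers(0, len(kept))] += 1
        else:
            kept.append(candidate)
            mult.append(1)
    return np.asarray(kept), np.asarray(mult, dtype=int)


def _render(params: DepositionParams, centers: np.ndarray, rng: np.random.Generator) -> SEMImage:
    cal = params.field
    radius_nm = params.particle.primary_diameter_nm / 2.0
    if params.particle.primary_diameter_nm < max(cal.pixel_width_nm, cal.pixel_height_nm):
        raise ValueError(
            f"particle diameter {params.particle.primary_diameter_nm} nm is below one "
            f"pixel ({cal.pixel_width_nm:.3g} × {cal.pixel_height_nm:.3g} nm); use a "
            "finer calibration (smaller scan field or more pixels)"
        )
    mask = np.zeros((cal.pixels_y, cal.pixels_x), dtype=bool)
    px_w, px_h = cal.pixel_width_nm, cal.pixel_height_nm
    for cx, cy in centers:
        # pixel-center grid window around the disk, clipped at field edges
        j0 = max(int((cx - radius_nm) / px_w) - 1, 0)
        j1 = min(int((cx + radius_nm) / px_w) + 2, cal.pixels_x)
        i0 = max(int((cy - radius_nm) / px_h) - 1, 0)
        i1 = min(int((cy + radius_nm) / px_h) + 2, cal.pixels_y)
        if j0 >= j1 or i0 >= i1:
            continue
        xs = (np.arange(j0, j1) + 0.5) * px_w
        ys = (np.arange(i0, i1) + 0.5) * px_h
        dist2 = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2
        mask[i0:i1, j0:j1] |= dist2 <= radius_nm**2
    img = np.full(mask.shape, float(params.background_level))
    img[mask] = float(params.particle_level)
    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    max_intensity = 2**params.bit_depth - 1
    img = np.clip(np.rint(img), 0, max_intensity)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return SEMImage(intensities=img.astype(dtype), bit_depth=params.bit_depth, calibration=cal)


def simulate_deposition(
    params: DepositionParams,
) -> tuple[SEMImage, DepositionGroundTruth]:
    """Simulate one deposition field; returns the image and its ground truth.

    Deterministic: the same parameters and seed give bit-identical results.
    A target dose whose expected particle count is below one triggers a
    warning and yields an empty (background + noise) field.
    """
    rng = np.random.default_rng(params.seed)
    mass_ug = params.particle.mass_ug
    if params.n_particles is not None:
        n = params.n_particles
    else:
        expected = params.target_dose_ug_cm2 * params.field.field_area_cm2 / mass_ug
        if expected < 1.0:
            warnings.warn(
                f"expected particle count {expected:.3g} < 1 for target dose "
                f"{params.target_dose_ug_cm2} µg/cm²; producing an empty field",
                stacklevel=2,
            )
            n = 0
        else:
            n = int(rng.poisson(expected))
    candidates = _draw_centers(params, n, rng)
    centers, multiplicity = _apply_stacking(candidates, params.stacking_prob, rng)
    n_total = int(multiplicity.sum())
    true_mass = n_total * mass_ug
    truth = DepositionGroundTruth(
        centers_nm=centers,
        multiplicity=multiplicity,
        n_particles=n_total,
        true_mass_ug=true_mass,
        true_dose_ug_cm2=true_mass / params.field.field_area_cm2,
        seed=params.seed,
    )
    return _render(params, centers, rng), truth


def write_ground_truth(
    truth: DepositionGroundTruth, params: DepositionParams, path: str | Path
) -> None:
    """Write the ground truth (plus a parameter echo) as a JSON sidecar."""
    payload = truth.to_dict()
    payload["params"] = {
        "mode": params.mode,
        "particle": params.particle.name,
        "primary_diameter_nm": params.particle.primary_diameter_nm,
        "density_g_cm3": params.particle.density_g_cm3,
        "target_dose_ug_cm2": params.target_dose_ug_cm2,
        "n_particles": params.n_particles,
        "stacking_prob": params.stacking_prob,
        "mean_cluster_size": params.mean_cluster_size,
        "cluster_radius_nm": params.cluster_radius_nm,
        "noise_sd": params.noise_sd,
        "background_level": params.background_level,
        "particle_level": params.particle_level,
        "bit_depth": params.bit_depth,
        "field": params.field.to_dict(),
        "seed": params.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass(frozen=True)
class EndpointReadouts:
    """Simulated plate-reader readouts for one exposure group.

    Viability signals are fluorescence-like: blank + gain × true fraction +
    Gaussian noise.  Basolateral tracer concentrations come through the same
    linear calibration and are clipped so the mass balance
    C_Bl × V_Bl ≤ C0 × V_Ap always holds.
    """

    sample_signals: np.ndarray
    control_signals: np.ndarray
    blank_signal: float
    basolateral_concentrations: np.ndarray
    c0: float
    apical_volume_ml: float
    basolateral_volume_ml: float
    seed: int


def simulate_endpoint_readouts(
    true_viability: float,
    true_passage: float,
    noise_sd: float = 10.0,
    n_replicates: int = 3,
    seed: int = 0,
    blank: float = 50.0,
    gain: float = 1000.0,
    c0: float = 0.4,
    apical_volume_ml: float = 0.5,
    basolateral_volume_ml: float = 1.5,
) -> EndpointReadouts:
    """Simulate viability and tracer-passage readouts with known truth.

    ``true_viability`` is the viable fraction relative to control (1.0 =
    unaffected); ``true_passage`` is the fraction of the full-equilibration
    passage actually crossing.  With ``noise_sd = 0`` the readouts are
    exactly blank + gain × effect.
    """
    if true_viability < 0 or true_passage < 0:
        raise ValueError("true effects must be >= 0")
    if not 0 <= true_passage <= 1:
        raise ValueError(f"true_passage must be in [0, 1], got {true_passage!r}")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    sample = blank + gain * true_viability + rng.normal(0, noise_sd, n_replicates)
    control = blank + gain * 1.0 + rng.normal(0, noise_sd, n_replicates)
    # mass-balance ceiling: all tracer crossed, C_Bl = C0 V_Ap / V_Bl
    c_bl_max = c0 * apical_volume_ml / basolateral_volume_ml
    c_bl_true = true_passage * c_bl_max
    signal = blank + gain * c_bl_true + rng.normal(0, noise_sd, n_replicates)
    c_bl = np.clip((signal - blank) / gain, 0.0, c_bl_max)
    return EndpointReadouts(
        sample_signals=sample,
        control_signals=control,
        blank_signal=blank,
        basolateral_concentrations=c_bl,
        c0=c0,
        apical_volume_ml=apical_volume_ml,
        basolateral_volume_ml=basolateral_volume_ml,
        seed=seed,
    )
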