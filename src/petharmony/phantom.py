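"""Digital activity phantoms and reconstruction-setting simulation.

A reconstruction setting is modeled as its *effective* resolution: the
ground-truth uptake map is blurred with an isotropic Gaussian point-spread
kernel (FWHM per setting), resampled onto the setting's output grid, and
perturbed with seeded signal-proportional noise. Sinogram-level physics
(attenuation, scatter, iterative reconstruction) is deliberately not
modeled; the blur + noise abstraction captures the partial-volume and
noise behavior that drives uptake quantification differences between
reconstruction settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .volumes import GridGeometry, RegionMask, VoxelGrid, _as3

__all__ = [
    "Organ",
    "PhantomSpec",
    "ReconProfile",
    "StudyMeta",
    "SyntheticStudy",
    "CohortConfig",
    "default_profiles",
    "build_phantom",
    "simulate_reconstruction",
    "nema_iq_preset",
    "generate_cohort",
    "blurred_sphere_center_value",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 0.42466

#: NEMA IQ fillable-sphere inner diameters (mm).
NEMA_SPHERE_DIAMETERS_MM = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)


@dataclass(frozen=True)
class Organ:
    """A uniform-uptake shape primitive.

    ``size_mm`` holds full extents per axis: a sphere has three equal
    entries (the diameter); an ellipsoid its three axis lengths; a
    cylinder (axis along z) its two in-plane diameters and its length.
    """

    role: str
    shape: str  # "sphere" | "ellipsoid" | "cylinder"
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, float, float]
    uptake: float
    index: int | None = None

    def __post_init__(self):
        if self.shape not in ("sphere", "ellipsoid", "cylinder"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.uptake < 0:
            raise ValueError("uptake must be >= 0")
        object.__setattr__(self, "center_mm", _as3(self.center_mm))
        object.__setattr__(self, "size_mm", _as3(self.size_mm))
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("size_mm must be positive")

    def contains(self, x, y, z) -> np.ndarray:
        """Boolean membership for world-coordinate arrays (broadcastable)."""
        cx, cy, cz = self.center_mm
        ax, ay, az = (s / 2.0 for s in self.size_mm)
        if self.shape == "cylinder":
            return (((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0) & (
                np.abs(z - cz) <= az
            )
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0

    @property
    def volume_mm3(self) -> float:
        ax, ay, az = (s / 2.0 for s in self.size_mm)
        if self.shape == "cylinder":
            return float(np.pi * ax * ay * 2 * az)
        return float(4.0 / 3.0 * np.pi * ax * ay * az)

    @property
    def label(self) -> str:
        if self.index is not None:
            return f"{self.role}_{self.index}"
        return self.role


@dataclass
class PhantomSpec:
    """Ground-truth phantom: field of view, grid resolution, organs."""

    field_of_view_mm: tuple[float, float, float]
    organs: list[Organ] = field(default_factory=list)
    background_uptake: float = 0.0
    voxel_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.field_of_view_mm = _as3(self.field_of_view_mm)
        self.voxel_mm = _as3(self.voxel_mm)
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("voxel_mm must be positive")
        if self.background_uptake < 0:
            raise ValueError("background_uptake must be >= 0")
        half = np.asarray(self.field_of_view_mm) / 2.0
        for organ in self.organs:
            lo = np.asarray(organ.center_mm) - np.asarray(organ.size_mm) / 2.0
            hi = np.asarray(organ.center_mm) + np.asarray(organ.size_mm) / 2.0
            if np.any(lo < -half) or np.any(hi > half):
                raise ValueError(
                    f"organ {organ.label!r} extends outside the field of view"
                )

    @property
    def grid(self) -> GridGeometry:
        fov = np.asarray(self.field_of_view_mm)
        vox = np.asarray(self.voxel_mm)
        shape = tuple(int(round(f / v)) for f, v in zip(fov, vox))
        origin = tuple(-fov / 2.0 + vox / 2.0)  # world coords centered on the FOV
        return GridGeometry(shape, tuple(vox), origin)


@dataclass(frozen=True)
class ReconProfile:
    """A named reconstruction setting reduced to its effective behavior."""

    name: str
    psf_fwhm_mm: float
    noise_cv: float = 0.0
    matrix: tuple[int, int] = (192, 192)
    pixel_mm: float = 3.64
    slice_mm: float = 2.79
    descriptive_metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.psf_fwhm_mm <= 0:
            raise ValueError("psf_fwhm_mm must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if min(self.matrix) < 32:
            raise ValueError("matrix must be >= 32 per axis")
        if self.pixel_mm <= 0 or self.slice_mm <= 0:
            raise ValueError("pixel_mm and slice_mm must be > 0")

    def output_grid(self, fov_z_mm: float, origin_like: str = "centered") -> GridGeometry:
        nz = int(round(fov_z_mm / self.slice_mm))
        shape = (self.matrix[0], self.matrix[1], nz)
        spacing = (self.pixel_mm, self.pixel_mm, self.slice_mm)
        fov = np.asarray(shape) * np.asarray(spacing)
        origin = tuple(-fov / 2.0 + np.asarray(spacing) / 2.0)
        return GridGeometry(shape, spacing, origin)


def default_profiles(noise_cv: float = 0.10) -> dict[str, ReconProfile]:
    """The three study settings.

    ``earl_lower`` and ``earl_upper`` are OSEM reconstructions at the lower
    and upper bound of the EARL recovery-coefficient band (7 and 5 mm
    Gaussian post-filter, 192 matrix at 3.64 mm). ``qclear`` emulates a
    BSREM (Q.Clear, beta 500) reconstruction on a 256 matrix at 2.73 mm;
    BSREM is not a linear filter, so its resolution is represented by an
    effective 4 mm FWHM — sharper than both EARL settings, matching its
    higher small-lesion recovery. Slice thickness is 2.79 mm throughout.
    """
    return {
        "earl_lower": ReconProfile(
            "earl_lower", psf_fwhm_mm=7.0, noise_cv=noise_cv,
            matrix=(192, 192), pixel_mm=3.64,
            descriptive_metadata={"algorithm": "OSEM", "iterations": 3, "subsets": 8,
                                  "post_filter_fwhm_mm": 7.0},
        ),
        "earl_upper": ReconProfile(
            "earl_upper", psf_fwhm_mm=5.0, noise_cv=noise_cv,
            matrix=(192, 192), pixel_mm=3.64,
            descriptive_metadata={"algorithm": "OSEM", "iterations": 4, "subsets": 16,
                                  "post_filter_fwhm_mm": 5.0},
        ),
        "qclear": ReconProfile(
            "qclear", psf_fwhm_mm=4.0, noise_cv=noise_cv,
            matrix=(256, 256), pixel_mm=2.73,
            descriptive_metadata={"algorithm": "BSREM", "beta": 500},
        ),
    }


# ---------------------------------------------------------------------------
# Phantom rasterization


def build_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, dict[str, RegionMask]]:
    """Rasterize a phantom onto its ground-truth grid.

    Each voxel takes the uptake of the innermost (smallest-volume) shape
    whose membership test contains the voxel center, else the background.
    One exact mask is returned per organ; where shapes nest, a voxel
    belongs to the innermost shape's mask only, so masks are disjoint.
    """
    grid = spec.grid
    x = grid.voxel_centers(0)[:, None, None]
    y = grid.voxel_centers(1)[None, :, None]
    z = grid.voxel_centers(2)[None, None, :]
    values = np.full(grid.shape, float(spec.background_uptake))
    claimed = np.zeros(grid.shape, dtype=bool)
    masks: dict[str, RegionMask] = {}
    # paint large shapes first so smaller (inner) shapes override them
    order = sorted(range(len(spec.organs)), key=lambda i: -spec.organs[i].volume_mm3)
    inside_by_organ = {}
    for i in order:
        organ = spec.organs[i]
        inside = organ.contains(x, y, z)
        values[inside] = organ.uptake
        inside_by_organ[i] = inside
    # innermost ownership: subtract any strictly smaller shape painted later
    for rank, i in enumerate(order):
        owned = inside_by_organ[i].copy()
        for j in order[rank + 1:]:
            owned &= ~inside_by_organ[j]
        organ = spec.organs[i]
        label = organ.label
        if label in masks:
            raise ValueError(f"duplicate organ label {label!r}")
        masks[label] = RegionMask(
            organ.role, owned, grid.spacing_mm, grid.origin_mm, index=organ.index
        )
    masks = {spec.organs[i].label: masks[spec.organs[i].label] for i in range(len(spec.organs))}
    return VoxelGrid(values, grid.spacing_mm, grid.origin_mm, "suv"), masks


# ---------------------------------------------------------------------------
# Reconstruction simulation


def blurred_sphere_center_value(
    radius_mm: float, uptake: float, background: float, fwhm_mm: float
) -> float:
    """Closed-form center value of a uniform sphere after isotropic Gaussian blur.

    Convolving a sphere of radius R (uptake A on background B) with an
    isotropic Gaussian of width sigma gives, at the sphere center,
    ``B + (A - B) * [erf(R / (sigma sqrt 2)) - sqrt(2/pi) (R/sigma) exp(-R^2 / 2 sigma^2)]``
    — the probability mass of a 3-D Gaussian inside radius R.
    """
    sigma = fwhm_mm * FWHM_TO_SIGMA
    r = radius_mm / sigma
    frac = erf(r / np.sqrt(2.0)) - np.sqrt(2.0 / np.pi) * r * np.exp(-(r**2) / 2.0)
    return float(background + (uptake - background) * frac)


def simulate_reconstruction(
    truth: VoxelGrid,
    profile: ReconProfile,
    seed: int,
    grid: GridGeometry | None = None,
) -> VoxelGrid:
    """Render ground truth through a reconstruction setting.

    Blur with the profile's isotropic PSF on the fine truth grid, resample
    (linear) onto the output grid, then add zero-mean Gaussian noise with
    standard deviation ``noise_cv * signal`` per voxel. Deterministic for a
    fixed seed; with ``noise_cv = 0`` total activity is conserved by the
    blur exactly and by the resampling to within a small tolerance.
    """
    if grid is None:
        grid = profile.output_grid(truth.geometry.fov_mm[2])
    src = truth.geometry
    t_lo = grid.edge_origin_mm
    t_hi = t_lo + grid.fov_mm
    s_lo = src.edge_origin_mm
    s_hi = s_lo + src.fov_mm
    if np.any(t_lo < s_lo - 1e-6) or np.any(t_hi > s_hi + 1e-6):
        raise ValueError(
            f"truth volume (extent {s_lo}..{s_hi} mm) does not cover the "
            f"requested output grid ({t_lo}..{t_hi} mm)"
        )
    if profile.psf_fwhm_mm < min(profile.pixel_mm, profile.slice_mm):
        warnings.warn(
            f"profile {profile.name!r}: PSF FWHM {profile.psf_fwhm_mm} mm is below "
            "one output voxel; the blur is under-resolved on the output grid",
            stacklevel=2,
        )
    sigma_vox = [profile.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in src.spacing_mm]
    blurred = ndimage.gaussian_filter(truth.values, sigma_vox, mode="constant", cval=0.0)
    blurred_grid = VoxelGrid(blurred, src.spacing_mm, src.origin_mm, truth.value_kind)

    from .volumes import regrid  # local import to avoid cycle at module load

    out = regrid(blurred_grid, grid, "linear")
    if profile.noise_cv > 0:
        rng = np.random.default_rng(seed)
        out.values = out.values + rng.standard_normal(out.values.shape) * (
            profile.noise_cv * out.values
        )
    return out


# ---------------------------------------------------------------------------
# NEMA image-quality preset


def nema_iq_preset(
    contrast: float = 10.0,
    background_uptake: float = 1.0,
    voxel_mm: float = 2.0,
    ring_radius_mm: float = 57.2,
) -> PhantomSpec:
    """NEMA IQ phantom: six hot spheres (10-37 mm) in a torso-shaped background.

    Spheres sit on a 114.4 mm-diameter ring in the central slice of an
    elliptical body compartment; sphere uptake is ``contrast`` times the
    background. The ground-truth grid defaults to 2 mm because of the
    large body FOV; pass ``voxel_mm=1.0`` for oracle-grade rasterization.
    """
    organs = [
        Organ("body", "cylinder", (0.0, 0.0, 0.0), (300.0, 230.0, 180.0),
              background_uptake)
    ]
    for i, diam in enumerate(NEMA_SPHERE_DIAMETERS_MM):
        angle = 2.0 * np.pi * i / 6.0
        center = (ring_radius_mm * np.cos(angle), ring_radius_mm * np.sin(angle), 0.0)
        organs.append(
            Organ("sphere", "sphere", center, (diam, diam, diam),
                  contrast * background_uptake, index=i + 1)
        )
    return PhantomSpec(
        field_of_view_mm=(320.0, 250.0, 200.0),
        organs=organs,
        background_uptake=0.0,
        voxel_mm=(voxel_mm, voxel_mm, voxel_mm),
    )


# ---------------------------------------------------------------------------
# Synthetic cohort


@dataclass
class StudyMeta:
    """Injection/acquisition metadata needed for SUV normalization."""

    injected_activity_MBq: float
    body_weight_kg: float
    injection_time_min: float = 0.0
    acquisition_time_min: float = 60.0
    radionuclide_half_life_min: float = 109.77  # F-18

    def __post_init__(self):
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected_activity_MBq must be > 0")
        if self.body_weight_kg <= 0:
            raise ValueError("body_weight_kg must be > 0")
        if self.acquisition_time_min < self.injection_time_min:
            raise ValueError("acquisition must not precede injection")

    @property
    def uptake_time_min(self) -> float:
        return self.acquisition_time_min - self.injection_time_min


@dataclass
class SyntheticStudy:
    """One simulated examination rendered under several settings."""

    study_id: str
    true_phantom: PhantomSpec
    volumes: dict[str, VoxelGrid]
    masks: dict[str, RegionMask]
    meta: StudyMeta
    true_uptakes: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortConfig:
    """Distributional description of a synthetic examination cohort.

    Defaults mirror a lymphoma therapy-response cohort: 54 examinations,
    liver uptake 2.2 +/- 0.3 SUV, mediastinal blood pool 1.7 +/- 0.2 SUV
    (both truncated at 0.5), a single focal lesion per study with diameter
    10-40 mm and true uptake spanning roughly 0.5-4x liver so that all
    Deauville boundaries are exercised.
    """

    n_studies: int = 54
    lesion_diameter_range_mm: tuple[float, float] = (10.0, 40.0)
    lesion_uptake_range: tuple[float, float] = (1.1, 8.8)
    liver_uptake_mean: float = 2.2
    liver_uptake_sd: float = 0.3
    bloodpool_uptake_mean: float = 1.7
    bloodpool_uptake_sd: float = 0.2
    uptake_floor: float = 0.5
    background_uptake: float = 0.7
    noise_cv: float = 0.10
    n_lesions: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        for name in ("lesion_diameter_range_mm", "lesion_uptake_range"):
            lo, hi = getattr(self, name)
            if not hi > lo:
                raise ValueError(f"{name} must be a non-degenerate interval")
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")


#: Compact torso-section FOV holding liver, thoracic aorta and lesion sites.
_COHORT_FOV_MM = (150.0, 110.0, 100.0)
_LESION_SITES = ((42.0, -28.0, 0.0), (48.0, 20.0, -28.0), (25.0, -35.0, 30.0))


def _study_phantom(cfg: CohortConfig, rng: np.random.Generator) -> tuple[PhantomSpec, dict]:
    trunc = lambda v: max(cfg.uptake_floor, v)
    liver_suv = trunc(rng.normal(cfg.liver_uptake_mean, cfg.liver_uptake_sd))
    blood_suv = trunc(rng.normal(cfg.bloodpool_uptake_mean, cfg.bloodpool_uptake_sd))
    organs = [
        Organ("liver", "ellipsoid", (-35.0, 0.0, 0.0), (70.0, 60.0, 56.0), liver_suv),
        # thoracic aorta: 32 mm caliber so a 3-voxel erosion leaves a core
        Organ("blood_pool", "cylinder", (30.0, 15.0, 0.0), (32.0, 32.0, 70.0), blood_suv),
    ]
    true_uptakes = {"liver": liver_suv, "blood_pool": blood_suv}
    for k in range(cfg.n_lesions):
        diam = rng.uniform(*cfg.lesion_diameter_range_mm)
        uptake = rng.uniform(*cfg.lesion_uptake_range)
        site = np.asarray(_LESION_SITES[k % len(_LESION_SITES)])
        center = tuple(site + rng.uniform(-3.0, 3.0, size=3))
        organs.append(
            Organ("lesion", "sphere", center, (diam, diam, diam), uptake, index=k + 1)
        )
        true_uptakes[f"lesion_{k + 1}"] = uptake
    spec = PhantomSpec(_COHORT_FOV_MM, organs, background_uptake=cfg.background_uptake)
    return spec, true_uptakes


def _cohort_grid(profile: ReconProfile, fov_mm) -> GridGeometry:
    spacing = (profile.pixel_mm, profile.pixel_mm, profile.slice_mm)
    shape = tuple(int(np.floor(f / s)) for f, s in zip(fov_mm, spacing))
    fov = np.asarray(shape) * np.asarray(spacing)
    origin = tuple(-fov / 2.0 + np.asarray(spacing) / 2.0)
    return GridGeometry(shape, spacing, origin)


def generate_cohort(
    cfg: CohortConfig, profiles: dict[str, ReconProfile] | None = None
) -> list[SyntheticStudy]:
    """Simulate a cohort of examinations under all reconstruction settings.

    Per-study randomness is drawn from a counter-based substream
    (``SeedSequence(cfg.seed, spawn_key=(i,))``) so study i is identical
    regardless of cohort size. Output volumes are SUV-scaled; each study
    carries plausible injection metadata (4 MBq/kg, ~60 min uptake).
    """
    if profiles is None:
        profiles = default_profiles(noise_cv=cfg.noise_cv)
    studies = []
    for i in range(cfg.n_studies):
        ss = np.random.SeedSequence(cfg.seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        spec, true_uptakes = _study_phantom(cfg, rng)
        truth, masks = build_phantom(spec)
        weight = float(np.clip(rng.normal(79.0, 16.0), 45.0, 140.0))
        meta = StudyMeta(
            injected_activity_MBq=4.0 * weight,
            body_weight_kg=weight,
            acquisition_time_min=float(rng.normal(62.0, 4.0)),
        )
        volumes = {}
        for j, (name, profile) in enumerate(sorted(profiles.items())):
            seed_j = int(
                np.random.default_rng(
                    np.random.SeedSequence(cfg.seed, spawn_key=(i, j + 1))
                ).integers(0, 2**31)
            )
            grid = _cohort_grid(profile, spec.field_of_view_mm)
            volumes[name] = simulate_reconstruction(truth, profile, seed_j, grid=grid)
        studies.append(
            SyntheticStudy(
                study_id=f"study_{i + 1:04d}",
                true_phantom=spec,
                volumes=volumes,
                masks=masks,
                meta=meta,
                true_uptakes=true_uptakes,
            )
        )
    return studies
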