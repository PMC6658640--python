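"""SUV normalization and regional uptake metrics (SUVmax / SUVpeak / RC).

Measurement follows the harmonized protocol: every reconstruction's
volume is resampled onto a common fine grid (the sharpest setting's
pixel size), masks follow by nearest-neighbor, reference-organ masks are
box-eroded by 3 voxels to avoid organ edges, and lesion masks are left
un-eroded (they are drawn to include the lesion maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import StudyMeta
from .volumes import GridGeometry, RegionMask, VoxelGrid, erode_mask, regrid

__all__ = [
    "UptakeMeasurement",
    "suv_scale",
    "suv_max",
    "suv_peak",
    "sphere_mean_map",
    "measure_study",
    "measurements_table",
    "recovery_coefficients",
]

ORGAN_ROLES = ("liver", "blood_pool")


@dataclass
class UptakeMeasurement:
    """Uptake summary for one region under one reconstruction setting."""

    region_role: str
    suv_max: float | None
    suv_peak: float | None
    suv_mean: float | None = None
    n_voxels: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        if (
            self.suv_peak is not None
            and self.suv_max is not None
            and self.suv_peak > self.suv_max + 1e-9
        ):
            raise ValueError("suv_peak cannot exceed suv_max")

    def value(self, metric: str) -> float | None:
        return {"suv_max": self.suv_max, "suv_peak": self.suv_peak,
                "suv_mean": self.suv_mean}[metric]


def suv_scale(volume: VoxelGrid, meta: StudyMeta) -> VoxelGrid:
    """Convert activity concentration (kBq/mL) to body-weight SUV.

    SUV = C * body_weight_g / A(t), with the injected activity decay-
    corrected from injection to acquisition time:
    A(t) = A0 * 2**(-uptake_time / half_life).
    """
    if volume.value_kind != "concentration":
        raise ValueError("suv_scale expects a concentration volume")
    decay = 2.0 ** (-meta.uptake_time_min / meta.radionuclide_half_life_min)
    activity_kBq = meta.injected_activity_MBq * 1000.0 * decay
    factor = meta.body_weight_kg * 1000.0 / activity_kBq
    return VoxelGrid(volume.values * factor, volume.spacing_mm, volume.origin_mm, "suv")


def _check_aligned(volume: VoxelGrid, mask: RegionMask) -> None:
    if not mask.aligned_with(volume):
        raise ValueError(
            f"mask {mask.label!r} is not aligned with the volume "
            f"({mask.values.shape} vs {volume.values.shape})"
        )


def suv_max(volume: VoxelGrid, mask: RegionMask) -> float:
    """Maximum voxel value within the mask."""
    _check_aligned(volume, mask)
    if mask.n_voxels == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    return float(volume.values[mask.values].max())


def _sphere_kernel(spacing_mm, sphere_volume_ml: float) -> np.ndarray:
    radius = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half = [int(np.floor(radius / s)) for s in spacing_mm]
    offs = [np.arange(-h, h + 1) * s for h, s in zip(half, spacing_mm)]
    dx, dy, dz = np.meshgrid(*offs, indexing="ij")
    return (dx**2 + dy**2 + dz**2 <= radius**2).astype(float)


def sphere_mean_map(volume: VoxelGrid, sphere_volume_ml: float = 1.0):
    """Sphere-mean image plus validity map for SUVpeak candidates.

    The mean is over voxels whose *centers* fall inside a sphere of the
    stated volume centered on the candidate voxel center. A candidate is
    valid only where the sphere's bounding box lies inside the volume.
    """
    kernel = _sphere_kernel(volume.spacing_mm, sphere_volume_ml)
    means = ndimage.convolve(volume.values, kernel / kernel.sum(), mode="constant")
    valid = np.zeros(volume.values.shape, dtype=bool)
    half = [(k - 1) // 2 for k in kernel.shape]
    inner = tuple(
        slice(h, n - h if h else None) for h, n in zip(half, volume.values.shape)
    )
    if all(n - 2 * h > 0 for h, n in zip(half, volume.values.shape)):
        valid[inner] = True
    return means, valid


def suv_peak(
    volume: VoxelGrid,
    mask: RegionMask,
    sphere_volume_ml: float = 1.0,
    _precomputed=None,
) -> float | None:
    """Peak SUV: maximum 1 mL spherical mean centered within the region.

    Candidate centers are the masked voxels; the averaging sphere may
    extend beyond the mask but not beyond the volume bounds. Returns None
    (flagged by callers) when no candidate admits a full sphere. The
    result is capped at the region SUVmax so the (peak, max) pair stays
    coherent even when the sphere spills onto hotter neighbors.
    """
    _check_aligned(volume, mask)
    if mask.n_voxels == 0:
        raise ValueError(f"mask {mask.label!r} is empty")
    means, valid = (
        _precomputed if _precomputed is not None
        else sphere_mean_map(volume, sphere_volume_ml)
    )
    candidates = mask.values & valid
    if not candidates.any():
        return None
    return min(float(means[candidates].max()), suv_max(volume, mask))


def _measure_region(
    volume: VoxelGrid,
    mask: RegionMask,
    peak_map,
    flags: list[str],
) -> UptakeMeasurement:
    vmax = suv_max(volume, mask)
    vpeak = suv_peak(volume, mask, _precomputed=peak_map)
    if vpeak is None:
        flags = flags + ["peak_undefined"]
    return UptakeMeasurement(
        region_role=mask.label,
        suv_max=vmax,
        suv_peak=vpeak,
        suv_mean=float(volume.values[mask.values].mean()),
        n_voxels=mask.n_voxels,
        flags=flags,
    )


def measure_study(
    volumes: dict[str, VoxelGrid],
    masks: dict[str, RegionMask],
    meta: StudyMeta | None = None,
    erosion_voxels: int = 3,
    sphere_volume_ml: float = 1.0,
    target: GridGeometry | None = None,
) -> dict[str, dict[str, UptakeMeasurement]]:
    """Measure SUVmax/SUVpeak per region under each reconstruction setting.

    All volumes are regridded to a common measurement grid (by default the
    geometry of the setting with the smallest voxel, i.e. the sharp
    reconstruction's 2.73 mm grid), masks are moved there by nearest-
    neighbor, and liver/blood-pool masks are eroded by ``erosion_voxels``
    on that grid. Lesion masks are never eroded. Organ masks that erode to
    empty carry no values and an ``eroded_empty`` flag.
    """
    if not volumes:
        raise ValueError("no volumes supplied")
    if target is None:
        target = min(
            (v.geometry for v in volumes.values()),
            key=lambda g: np.prod(g.spacing_mm),
        )
    import warnings as _warnings

    masks_t: dict[str, RegionMask] = {}
    mask_flags: dict[str, list[str]] = {}
    for label, mask in masks.items():
        m = regrid(mask, target, "nearest")
        flags: list[str] = []
        if mask.role in ORGAN_ROLES and erosion_voxels > 0:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                m, _ = erode_mask(m, erosion_voxels)
            if m.n_voxels == 0:
                flags.append("eroded_empty")
        elif m.n_voxels == 0:
            flags.append("empty_after_regrid")
        masks_t[label] = m
        mask_flags[label] = flags

    results: dict[str, dict[str, UptakeMeasurement]] = {}
    for name, vol in volumes.items():
        v = regrid(vol, target, "linear")
        if v.value_kind == "concentration":
            if meta is None:
                raise ValueError(f"volume {name!r} is in concentration units; meta required")
            v = suv_scale(v, meta)
        peak_map = sphere_mean_map(v, sphere_volume_ml)
        per_role: dict[str, UptakeMeasurement] = {}
        for label, m in masks_t.items():
            flags = list(mask_flags[label])
            if m.n_voxels == 0:
                per_role[label] = UptakeMeasurement(
                    region_role=label, suv_max=None, suv_peak=None,
                    suv_mean=None, n_voxels=0, flags=flags,
                )
                continue
            per_role[label] = _measure_region(v, m, peak_map, flags)
        results[name] = per_role
    return results


def measurements_table(
    per_study: dict[str, dict[str, dict[str, UptakeMeasurement]]]
) -> pd.DataFrame:
    """Flatten {study -> profile -> role -> measurement} into a tidy table."""
    rows = []
    for study_id, per_profile in per_study.items():
        for profile, per_role in per_profile.items():
            for role, m in per_role.items():
                for metric in ("suv_max", "suv_peak", "suv_mean"):
                    rows.append(
                        {
                            "study_id": study_id,
                            "profile": profile,
                            "role": role,
                            "metric": metric,
                            "value": m.value(metric),
                            "n_voxels": m.n_voxels,
                            "flags": ";".join(m.flags),
                        }
                    )
    return pd.DataFrame(rows)


def recovery_coefficients(
    recon: VoxelGrid,
    truth_masks: dict[str, RegionMask],
    truth_uptakes: dict[str, float],
    limits: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-sphere recovery coefficients against known phantom truth.

    rc_max is the hottest reconstructed voxel inside the true sphere mask
    divided by the true uptake; rc_mean uses the mean over the mask. When
    an accreditation limits table {label: (lo, hi)} is supplied, each
    sphere is checked against its rc_max band; otherwise compliance is
    left blank.
    """
    rows = []
    for label, mask in truth_masks.items():
        if label not in truth_uptakes:
            continue
        m = mask if mask.aligned_with(recon) else regrid(mask, recon.geometry, "nearest")
        if m.n_voxels == 0:
            continue
        true = float(truth_uptakes[label])
        vals = recon.values[m.values]
        row = {
            "region": label,
            "rc_max": float(vals.max()) / true,
            "rc_mean": float(vals.mean()) / true,
            "n_voxels": m.n_voxels,
        }
        if limits is not None and label in limits:
            lo, hi = limits[label]
            row["within_limits"] = bool(lo <= row["rc_max"] <= hi)
        rows.append(row)
    return pd.DataFrame(rows)
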