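"""SUL conversion, liver background measurement, and PERCIST thresholds.

FDG-PET activity is expressed here as SUL: the standardized uptake value
normalized to lean body mass (LBM) rather than total body weight,

    SUL = tissue activity concentration [MBq/g] / (injected dose [MBq] / LBM [g]),

which is the quantity PERCIST 1.0 bases response assessment on.  The liver
background is summarized by the mean and sample standard deviation of SUL
inside a 3-cm-diameter spherical ROI placed in normal liver; two thresholds
derive from it:

* measurability gate: ``1.5 * mean + 2 * sd`` — a lesion qualifies as
  measurable only if its SUL_max reaches this level;
* segmentation threshold: ``mean + 2 * sd`` — the lower bound of the
  lesion volume of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class LbmFormula(str, Enum):
    """Lean-body-mass estimator.

    Janmahasatian is the PERCIST-community standard and the default; the
    older James formula is kept behind this switch for comparability.
    """

    JANMAHASATIAN = "janmahasatian"
    JAMES = "james"


@dataclass(frozen=True)
class ScanSession:
    """Injection and anthropometric metadata for one PET acquisition."""

    injected_dose_mbq: float
    body_weight_kg: float
    height_cm: float
    sex: Sex
    uptake_time_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.injected_dose_mbq <= 0:
            raise ValueError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.height_cm <= 0:
            raise ValueError("height must be positive")

    @property
    def lean_body_mass_kg(self) -> float:
        return lean_body_mass(self.body_weight_kg, self.height_cm, self.sex)


@dataclass
class SulVolume:
    """A 3-D scalar grid of SUL values with physical geometry.

    ``origin`` is the world-mm coordinate of the *center* of voxel
    ``(0, 0, 0)`` (the NIfTI convention); the center of voxel ``i`` along an
    axis is ``origin + i * spacing``.  A voxel belongs to a region iff its
    center does.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("SUL volume must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("SUL values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-center world coordinates (mm)."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        )  # type: ignore[return-value]

    def sphere_mask(self, center_mm, radius_mm: float) -> np.ndarray:
        """Boolean mask of voxels whose centers lie within the sphere."""
        cx, cy, cz = self.voxel_centers_mm()
        c = np.asarray(center_mm, dtype=float)
        d2 = (
            (cx - c[0])[:, None, None] ** 2
            + (cy - c[1])[None, :, None] ** 2
            + (cz - c[2])[None, None, :] ** 2
        )
        return d2 <= radius_mm**2


@dataclass
class OrganLabelMap:
    """Integer organ labels on the same grid as a companion :class:`SulVolume`."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label map must be 3-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label map must be integer-valued")


@dataclass(frozen=True)
class LiverBackground:
    """Liver-ROI summary: mean and sample SD of SUL in the background sphere."""

    mean_sul: float
    sd_sul: float
    roi_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    roi_diameter_mm: float = 30.0
    n_voxels: int = 0

    def __post_init__(self) -> None:
        if self.sd_sul < 0:
            raise ValueError("liver SD must be non-negative")


def lean_body_mass(weight_kg: float, height_cm: float, sex: Sex | str,
                   formula: LbmFormula | str = LbmFormula.JANMAHASATIAN) -> float:
    """Estimate lean body mass in kg.

    Janmahasatian (default):
        male:   9270 * W / (6680 + 216 * BMI)
        female: 9270 * W / (8780 + 244 * BMI)
    with BMI = W / height_m**2.

    James (legacy):
        male:   1.10 * W - 128 * (W / height_cm)**2
        female: 1.07 * W - 148 * (W / height_cm)**2
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    sex = Sex(sex)
    formula = LbmFormula(formula)
    if formula is LbmFormula.JANMAHASATIAN:
        bmi = weight_kg / (height_cm / 100.0) ** 2
        if sex is Sex.MALE:
            return 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)
        return 9270.0 * weight_kg / (8780.0 + 244.0 * bmi)
    # James
    r = weight_kg / height_cm
    if sex is Sex.MALE:
        return 1.10 * weight_kg - 128.0 * r**2
    return 1.07 * weight_kg - 148.0 * r**2


def activity_to_sul(activity_mbq_per_g: np.ndarray,
                    session: ScanSession,
                    spacing: tuple[float, float, float],
                    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
                    lbm_formula: LbmFormula | str = LbmFormula.JANMAHASATIAN,
                    ) -> SulVolume:
    """Convert an activity-concentration volume (MBq/g) to SUL.

    Each voxel is scaled by ``LBM[g] / dose[MBq]``; the result is
    dimensionless.  Decay correction is assumed to have been applied to the
    input already.
    """
    activity = np.asarray(activity_mbq_per_g, dtype=float)
    if np.any(activity < 0):
        raise ValueError("activity concentrations must be non-negative")
    lbm_g = 1000.0 * lean_body_mass(
        session.body_weight_kg, session.height_cm, session.sex, lbm_formula
    )
    scale = lbm_g / session.injected_dose_mbq
    return SulVolume(values=activity * scale, spacing=spacing, origin=origin)


def liver_background(vol: SulVolume,
                     center_mm,
                     diameter_mm: float = 30.0,
                     exclusion_mask: Optional[np.ndarray] = None,
                     ) -> LiverBackground:
    """Measure liver background SUL in a spherical ROI.

    The ROI must lie entirely inside the volume and, when an exclusion mask
    (e.g. known liver metastases) is supplied, must not intersect it — the
    caller re-sites the sphere in that case, mirroring how a reader moves
    the ROI away from obvious lesions.
    """
    center = np.asarray(center_mm, dtype=float)
    radius = diameter_mm / 2.0
    for a in range(3):
        lo = vol.origin[a] - vol.spacing[a] / 2.0
        hi = vol.origin[a] + (vol.shape[a] - 0.5) * vol.spacing[a]
        if center[a] - radius < lo or center[a] + radius > hi:
            raise ValueError("liver ROI sphere extends outside the volume")
    mask = vol.sphere_mask(center, radius)
    if exclusion_mask is not None and np.any(mask & np.asarray(exclusion_mask, bool)):
        raise ValueError("liver ROI intersects the exclusion mask; re-site the sphere")
    vals = vol.values[mask]
    if vals.size == 0:
        raise ValueError("liver ROI contains no voxel centers")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return LiverBackground(
        mean_sul=float(np.mean(vals)),
        sd_sul=sd,
        roi_center_mm=tuple(center),
        roi_diameter_mm=float(diameter_mm),
        n_voxels=int(vals.size),
    )


def measurability_threshold(bg: LiverBackground, strict_parse: bool = False) -> float:
    """SUL_max gate for a lesion to count as measurable.

    PERCIST 1.0 reading (default): ``1.5 * mean + 2 * sd``.  The alternative
    parse ``1.5 * (mean + 2 * sd)`` is available behind ``strict_parse`` for
    sensitivity analyses.
    """
    if strict_parse:
        return 1.5 * (bg.mean_sul + 2.0 * bg.sd_sul)
    return 1.5 * bg.mean_sul + 2.0 * bg.sd_sul


def segmentation_threshold(bg: LiverBackground) -> float:
    """Lower SUL bound of lesion VOIs: ``mean + 2 * sd`` of the liver ROI."""
    return bg.mean_sul + 2.0 * bg.sd_sul
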