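"""Synthetic SUL phantoms with known ground truth.

A phantom is a uniform soft-tissue background carrying (a) a spherical liver
region whose voxels are drawn i.i.d. from a normal distribution with known
mean/SD — emulating the normal hepatic FDG pool that PERCIST uses as the
reference background — and (b) ellipsoidal lesions at known peak SUL across
labeled organs.  The default lesion profile is a uniform plateau at the peak
SUL, which makes SUL_mean, MTV and TLG analytically checkable; a Gaussian
falloff profile is available for less idealized shapes.

Follow-up phantoms apply a per-lesion multiplicative response factor to the
peak SUL (0 = complete resolution) and may add new lesions, so the ground
truth of a paired baseline/follow-up experiment is fully known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sul import OrganLabelMap, SulVolume

LIVER_LABEL_DEFAULT = 1


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion: center/radii in mm, peak SUL, organ label."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_sul: float
    organ_label: int
    id: str
    profile: str = "plateau"  # or "gaussian"

    def __post_init__(self) -> None:
        if self.peak_sul <= 0:
            raise ValueError(f"lesion {self.id}: peak SUL must be positive")
        if any(r <= 0 for r in self.radii_mm):
            raise ValueError(f"lesion {self.id}: radii must be positive")
        if self.profile not in ("plateau", "gaussian"):
            raise ValueError(f"lesion {self.id}: unknown profile {self.profile!r}")


@dataclass(frozen=True)
class LiverRegionSpec:
    center_mm: tuple[float, float, float]
    radius_mm: float
    mean_sul: float
    sd_sul: float
    label: int = LIVER_LABEL_DEFAULT

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("liver radius must be positive")
        if self.sd_sul < 0:
            raise ValueError("liver SD must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic SUL volume."""

    grid_shape: tuple[int, int, int]
    voxel_spacing_mm: tuple[float, float, float]
    background_sul: float = 0.5
    noise_sd: float = 0.0
    liver_region: Optional[LiverRegionSpec] = None
    lesions: tuple[LesionSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.background_sul < 0:
            raise ValueError("background SUL must be non-negative")
        object.__setattr__(self, "lesions", tuple(self.lesions))


@dataclass(frozen=True)
class FollowupSpec:
    """Per-lesion multiplicative response factors plus optional new lesions.

    ``factors`` maps baseline lesion id -> factor on peak SUL; a factor of 0
    removes the lesion entirely (complete resolution).  Lesions absent from
    the mapping keep factor 1.
    """

    factors: dict[str, float] = field(default_factory=dict)
    new_lesions: tuple[LesionSpec, ...] = ()
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if any(f < 0 for f in self.factors.values()):
            raise ValueError("response factors must be non-negative")
        object.__setattr__(self, "new_lesions", tuple(self.new_lesions))


def _ellipsoid_mask(shape, spacing, center, radii) -> np.ndarray:
    axes = [np.arange(shape[a]) * spacing[a] for a in range(3)]
    t = [
        ((axes[a] - center[a]) / radii[a]) ** 2 for a in range(3)
    ]
    return (t[0][:, None, None] + t[1][None, :, None] + t[2][None, None, :]) <= 1.0


def _check_inside(shape, spacing, center, radii, what: str) -> None:
    for a in range(3):
        lo = -spacing[a] / 2.0
        hi = (shape[a] - 0.5) * spacing[a]
        if center[a] - radii[a] < lo or center[a] + radii[a] > hi:
            raise ValueError(f"{what} extends outside the phantom grid")


def make_phantom(spec: PhantomSpec) -> tuple[SulVolume, OrganLabelMap, pd.DataFrame]:
    """Render a phantom and return (SUL volume, organ labels, ground truth).

    Ground truth is one row per lesion with its id, organ label, peak SUL,
    voxel count, voxelized volume (mm^3 and cm^3) and center.  Rendering is
    deterministic given ``spec.rng_seed``: Gaussian noise (truncated at 0)
    is drawn for the whole grid first, then liver voxels are redrawn from
    the liver distribution, so two calls with the same seed are
    bit-identical regardless of downstream use.
    """
    shape, sp = spec.grid_shape, spec.voxel_spacing_mm
    rng = np.random.default_rng(spec.rng_seed)

    vol = np.full(shape, spec.background_sul, dtype=float)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
    labels = np.zeros(shape, dtype=np.int32)
    legend: dict[int, str] = {0: "background"}

    if spec.liver_region is not None:
        lv = spec.liver_region
        _check_inside(shape, sp, lv.center_mm, (lv.radius_mm,) * 3, "liver region")
        lmask = _ellipsoid_mask(shape, sp, lv.center_mm, (lv.radius_mm,) * 3)
        n = int(lmask.sum())
        vol[lmask] = rng.normal(lv.mean_sul, lv.sd_sul, size=n) if lv.sd_sul > 0 else lv.mean_sul
        labels[lmask] = lv.label
        legend[lv.label] = "liver"

    claimed = np.zeros(shape, dtype=np.int32)  # organ label claiming each lesion voxel
    rows = []
    for les in spec.lesions:
        _check_inside(shape, sp, les.center_mm, les.radii_mm, f"lesion {les.id}")
        mask = _ellipsoid_mask(shape, sp, les.center_mm, les.radii_mm)
        overlap = claimed[mask]
        if np.any((overlap != 0) & (overlap != les.organ_label)):
            raise ValueError(
                f"lesion {les.id} overlaps a lesion with a different organ label"
            )
        if les.profile == "plateau":
            vol[mask] = les.peak_sul
        else:  # gaussian falloff: peak at center, sigma = radius / 2 per axis
            axes = [np.arange(shape[a]) * sp[a] for a in range(3)]
            qa = [((axes[a] - les.center_mm[a]) / (les.radii_mm[a] / 2.0)) ** 2
                  for a in range(3)]
            q = qa[0][:, None, None] + qa[1][None, :, None] + qa[2][None, None, :]
            prof = les.peak_sul * np.exp(-0.5 * q)
            vol[mask] = np.maximum(vol[mask], prof[mask])
        claimed[mask] = les.organ_label
        labels[mask] = les.organ_label
        legend.setdefault(les.organ_label, f"organ_{les.organ_label}")
        nvox = int(mask.sum())
        rows.append({
            "id": les.id,
            "organ_label": les.organ_label,
            "peak_sul": les.peak_sul,
            "n_voxels": nvox,
            "volume_mm3": nvox * float(np.prod(sp)),
            "volume_cm3": nvox * float(np.prod(sp)) / 1000.0,
            "center_x_mm": les.center_mm[0],
            "center_y_mm": les.center_mm[1],
            "center_z_mm": les.center_mm[2],
        })

    np.clip(vol, 0.0, None, out=vol)
    truth = pd.DataFrame(
        rows,
        columns=["id", "organ_label", "peak_sul", "n_voxels", "volume_mm3",
                 "volume_cm3", "center_x_mm", "center_y_mm", "center_z_mm"],
    )
    return (
        SulVolume(values=vol, spacing=sp),
        OrganLabelMap(labels=labels, legend=legend),
        truth,
    )


def make_followup(baseline: PhantomSpec, fu: FollowupSpec
                  ) -> tuple[SulVolume, OrganLabelMap, pd.DataFrame]:
    """Render the follow-up phantom implied by per-lesion response factors.

    The follow-up lesion set is the baseline set with each peak SUL scaled
    by its factor (factor 0 removes the lesion) plus any new lesions, which
    appear only here.  Ground-truth lesion ids are preserved, so pairing
    follow-up output back to baseline truth is exact.
    """
    known = {les.id for les in baseline.lesions}
    unknown = set(fu.factors) - known
    if unknown:
        raise ValueError(f"response factors refer to unknown lesion ids: {sorted(unknown)}")
    lesions: list[LesionSpec] = []
    for les in baseline.lesions:
        f = fu.factors.get(les.id, 1.0)
        if f == 0.0:
            continue
        lesions.append(replace(les, peak_sul=les.peak_sul * f))
    lesions.extend(fu.new_lesions)
    seed = baseline.rng_seed if fu.rng_seed is None else fu.rng_seed
    spec = replace(baseline, lesions=tuple(lesions), rng_seed=seed)
    return make_phantom(spec)
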