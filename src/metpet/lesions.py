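"""Lesion segmentation, per-lesion metrics, target selection and matching.

Measurable lesions are 26-connected components of voxels at or above the
segmentation threshold (liver mean + 2 SD) whose SUL_max clears the
measurability gate (1.5 x liver mean + 2 SD).  Per lesion we report
SUL_max, SUL_mean, metabolic tumor volume (MTV, cm^3 = voxel count x voxel
volume) and total lesion glycolysis (TLG = SUL_mean x MTV, g).

Target lesions follow the study rule: up to five measurably hottest
lesions, no more than two per organ, scanned greedily in descending
SUL_max.  Cross-timepoint matching is a deterministic proxy for a reader
re-identifying "the same five lesions": greedy nearest-centroid pairing
within a radius, requiring organ agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .sul import (
    LiverBackground,
    OrganLabelMap,
    SulVolume,
    measurability_threshold,
    segmentation_threshold,
)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LesionVOI:
    """One connected above-threshold lesion region and its metrics."""

    id: str
    organ_label: int
    sul_max: float
    sul_mean: float
    mtv_cm3: float
    tlg_g: float
    centroid_mm: tuple[float, float, float]
    n_voxels: int
    voxel_indices: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sul_mean > self.sul_max + 1e-12:
            raise ValueError("lesion mean SUL cannot exceed its max")


def _sort_key(les: LesionVOI):
    # hottest first; ties broken by larger MTV, then smallest centroid (mm, lexicographic)
    return (-les.sul_max, -les.mtv_cm3, les.centroid_mm)


@dataclass
class TargetLesionSet:
    """Ordered lesion collection with summed burden metrics."""

    lesions: tuple[LesionVOI, ...]

    def __init__(self, lesions: Iterable[LesionVOI]):
        self.lesions = tuple(lesions)

    @property
    def sum_sul(self) -> float:
        return float(sum(l.sul_max for l in self.lesions))

    @property
    def sum_mtv_cm3(self) -> float:
        return float(sum(l.mtv_cm3 for l in self.lesions))

    @property
    def sum_tlg_g(self) -> float:
        return float(sum(l.tlg_g for l in self.lesions))

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    def to_frame(self) -> pd.DataFrame:
        return lesions_to_frame(self.lesions)


@dataclass(frozen=True)
class LesionCorrespondence:
    """Baseline/follow-up pairing with leftovers on both sides."""

    pairs: tuple[tuple[str, str], ...]
    unmatched_baseline: tuple[str, ...]
    unmatched_followup: tuple[str, ...]


def find_lesions(vol: SulVolume,
                 organs: OrganLabelMap,
                 bg: LiverBackground,
                 exclude_labels: Sequence[int] = (),
                 strict_parse: bool = False,
                 id_prefix: str = "L",
                 ) -> list[LesionVOI]:
    """Segment measurable lesions from a SUL volume.

    Voxels at or above the segmentation threshold (excluding
    physiologic-uptake organ labels) are grouped into 26-connected
    components; a component is kept only if its SUL_max clears the
    measurability gate.  The component's organ is the majority organ label
    of its voxels.  Lesion ids are assigned in descending SUL_max order.
    """
    if vol.values.shape != organs.labels.shape:
        raise ValueError("SUL volume and organ label map are misaligned")
    seg_thr = segmentation_threshold(bg)
    meas_thr = measurability_threshold(bg, strict_parse=strict_parse)

    mask = vol.values >= seg_thr
    if exclude_labels:
        mask &= ~np.isin(organs.labels, np.asarray(list(exclude_labels)))
    comp, ncomp = ndimage.label(mask, structure=_STRUCT_26)

    centers = vol.voxel_centers_mm()
    vox_cm3 = vol.voxel_volume_mm3 / 1000.0
    found: list[LesionVOI] = []
    for k in range(1, ncomp + 1):
        idx = np.argwhere(comp == k)
        vals = vol.values[idx[:, 0], idx[:, 1], idx[:, 2]]
        sul_max = float(vals.max())
        if sul_max < meas_thr:
            continue
        labs = organs.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        uniq, counts = np.unique(labs, return_counts=True)
        organ = int(uniq[np.argmax(counts)])
        mtv = len(idx) * vox_cm3
        sul_mean = float(vals.mean())
        centroid = tuple(
            float(np.mean(centers[a][idx[:, a]])) for a in range(3)
        )
        found.append(LesionVOI(
            id="",  # assigned after sorting
            organ_label=organ,
            sul_max=sul_max,
            sul_mean=sul_mean,
            mtv_cm3=mtv,
            tlg_g=sul_mean * mtv,
            centroid_mm=centroid,  # type: ignore[arg-type]
            n_voxels=len(idx),
            voxel_indices=idx,
        ))
    found.sort(key=_sort_key)
    return [
        LesionVOI(id=f"{id_prefix}{i + 1:03d}", organ_label=l.organ_label,
                  sul_max=l.sul_max, sul_mean=l.sul_mean, mtv_cm3=l.mtv_cm3,
                  tlg_g=l.tlg_g, centroid_mm=l.centroid_mm,
                  n_voxels=l.n_voxels, voxel_indices=l.voxel_indices)
        for i, l in enumerate(found)
    ]


def hottest_lesion(lesions: Sequence[LesionVOI]) -> LesionVOI:
    """The measurably hottest lesion (max SUL_max; ties: larger MTV, then
    smallest centroid in lexicographic mm order)."""
    if not lesions:
        raise ValueError("no measurable lesion")
    return min(lesions, key=_sort_key)


def select_targets(lesions: Sequence[LesionVOI],
                   max_lesions: int = 5,
                   max_per_organ: int = 2) -> TargetLesionSet:
    """Greedy target-lesion selection: hottest first, organ cap, stop at 5.

    Invariant to input order; an empty input yields an empty set with zero
    sums.
    """
    chosen: list[LesionVOI] = []
    per_organ: dict[int, int] = {}
    for les in sorted(lesions, key=_sort_key):
        if len(chosen) >= max_lesions:
            break
        if per_organ.get(les.organ_label, 0) >= max_per_organ:
            continue
        chosen.append(les)
        per_organ[les.organ_label] = per_organ.get(les.organ_label, 0) + 1
    return TargetLesionSet(chosen)


def match_lesions(baseline: TargetLesionSet | Sequence[LesionVOI],
                  followup_lesions: Sequence[LesionVOI],
                  match_radius_mm: float = 20.0) -> LesionCorrespondence:
    """Pair baseline target lesions with follow-up lesions.

    Greedy nearest-centroid pairing in ascending distance; a pair is
    accepted only within the match radius and with identical organ label.
    Unmatched follow-up lesions are candidate new lesions; unmatched
    baseline lesions are candidates for complete resolution.
    """
    base = list(baseline)
    fu = list(followup_lesions)
    candidates = []
    for b in base:
        for f in fu:
            if b.organ_label != f.organ_label:
                continue
            d = float(np.linalg.norm(np.subtract(b.centroid_mm, f.centroid_mm)))
            if d <= match_radius_mm:
                candidates.append((d, b.id, f.id))
    candidates.sort()
    used_b: set[str] = set()
    used_f: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for _, bid, fid in candidates:
        if bid in used_b or fid in used_f:
            continue
        pairs.append((bid, fid))
        used_b.add(bid)
        used_f.add(fid)
    return LesionCorrespondence(
        pairs=tuple(pairs),
        unmatched_baseline=tuple(b.id for b in base if b.id not in used_b),
        unmatched_followup=tuple(f.id for f in fu if f.id not in used_f),
    )


def detect_new_lesions(corr: LesionCorrespondence) -> tuple[bool, tuple[str, ...]]:
    """New-lesion flag: any measurable follow-up lesion without a baseline match."""
    return bool(corr.unmatched_followup), corr.unmatched_followup


def lesions_to_frame(lesions: Sequence[LesionVOI]) -> pd.DataFrame:
    """Tabulate lesions (one row each) for CSV export."""
    return pd.DataFrame([
        {
            "id": l.id,
            "organ_label": l.organ_label,
            "sul_max": l.sul_max,
            "sul_mean": l.sul_mean,
            "mtv_cm3": l.mtv_cm3,
            "tlg_g": l.tlg_g,
            "centroid_x_mm": l.centroid_mm[0],
            "centroid_y_mm": l.centroid_mm[1],
            "centroid_z_mm": l.centroid_mm[2],
            "n_voxels": l.n_voxels,
        }
        for l in lesions
    ], columns=["id", "organ_label", "sul_max", "sul_mean", "mtv_cm3", "tlg_g",
                "centroid_x_mm", "centroid_y_mm", "centroid_z_mm", "n_voxels"])


def lesions_from_frame(df: pd.DataFrame) -> list[LesionVOI]:
    """Rebuild lesion objects from a table written by :func:`lesions_to_frame`."""
    out = []
    for _, r in df.iterrows():
        out.append(LesionVOI(
            id=str(r["id"]),
            organ_label=int(r["organ_label"]),
            sul_max=float(r["sul_max"]),
            sul_mean=float(r["sul_mean"]),
            mtv_cm3=float(r["mtv_cm3"]),
            tlg_g=float(r["tlg_g"]),
            centroid_mm=(float(r["centroid_x_mm"]), float(r["centroid_y_mm"]),
                         float(r["centroid_z_mm"])),
            n_voxels=int(r["n_voxels"]),
        ))
    return out
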