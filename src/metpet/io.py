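"""NIfTI volume I/O and report serialization."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np

from . import __version__
from .sul import OrganLabelMap, SulVolume

# serialization rounding policy: percents to 1 decimal, SUL to 2 decimals
_PCT_KEYS = {"delta_sul_pct", "dsum_sul_pct", "dsum_mtv_pct", "dsum_tlg_pct",
             "sensitivity", "specificity", "ppv", "npv", "accuracy",
             "disease_control_rate"}
_SUL_KEYS = {"baseline_hottest_sul", "followup_hottest_sul", "bsum_sul",
             "mean_sul", "sd_sul", "sul_max", "sul_mean"}


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: SulVolume | OrganLabelMap, path: str | Path,
                 spacing=None, origin=(0.0, 0.0, 0.0)) -> None:
    """Write a SUL volume or label map as NIfTI-1, geometry in the affine.

    Label maps carry no geometry of their own; pass the companion volume's
    ``spacing``/``origin`` so both files share one grid.
    """
    if isinstance(vol, SulVolume):
        data = vol.values.astype(np.float64)
        aff = _affine(vol.spacing, vol.origin)
    else:
        data = vol.labels.astype(np.int32)
        aff = _affine(spacing if spacing is not None else (1.0, 1.0, 1.0), origin)
    nib.save(nib.Nifti1Image(data, aff), str(path))


def read_sul_volume(path: str | Path) -> SulVolume:
    """Read a NIfTI-1 SUL volume, honoring its affine for spacing/origin."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    aff = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(aff)[:3]))
    origin = tuple(float(o) for o in aff[:3, 3])
    return SulVolume(values=data, spacing=spacing, origin=origin)


def read_label_map(path: str | Path, companion: SulVolume | None = None) -> OrganLabelMap:
    """Read a NIfTI-1 integer label map; checked against a companion grid."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    labels = np.rint(data).astype(np.int32)
    if not np.allclose(data, labels):
        raise ValueError(f"{path}: label map is not integer-valued")
    if companion is not None and labels.shape != companion.shape:
        raise ValueError(
            f"{path}: label map shape {labels.shape} does not match "
            f"volume shape {companion.shape}"
        )
    return OrganLabelMap(labels=labels)


def _round_value(key: str, value: Any) -> Any:
    if isinstance(value, float):
        if key in _PCT_KEYS:
            return round(value, 1)
        if key in _SUL_KEYS:
            return round(value, 2)
        return value
    if isinstance(value, dict):
        return {k: _round_value(k, v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_round_value(key, v) for v in value]
    return value


def write_report(results: dict, path: str | Path) -> None:
    """Serialize a results dict as JSON with a version stamp.

    Rounding (percents to 1 decimal, SUL to 2) is applied only here, at
    serialization; in-memory values keep full precision.  Re-serializing a
    written report is idempotent.
    """
    payload = {"metpet_version": __version__}
    payload.update({k: _round_value(k, v) for k, v in results.items()})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
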