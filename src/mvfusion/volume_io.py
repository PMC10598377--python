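"""Reading, normalising and assembling multi-view volumetric cases.

Supported inputs
----------------
* stacked-slice arrays (``.npy``), one ``(slices, H, W)`` array per view per
  case — the layout used by public knee-MRI releases such as MRNet-v1.0;
* DICOM series directories (one 2-D slice per file, sorted by slice
  position);
* NIfTI volumes (``.nii`` / ``.nii.gz``).

All loaders return a :class:`ViewVolume` whose array is indexed
``(depth, height, width)``, 0-based.  Raw intensities are preserved at load
time; :func:`preprocess` harmonises shape and applies per-volume z-score
normalisation.  Patient-identifying DICOM header fields are never retained
on the returned object.

A dataset on disk is described by a *case manifest*: a CSV with columns
``case_id``, ``label`` and one path column per view (column order fixes the
canonical view order).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger("mvfusion")

__all__ = [
    "VolumeFormatError",
    "ViewVolume",
    "Case",
    "DatasetSplit",
    "read_slice_stack",
    "read_nifti",
    "read_dicom_series",
    "preprocess",
    "assemble_case",
    "write_manifest",
    "read_manifest",
]


class VolumeFormatError(ValueError):
    """A volume file or series violates the expected layout."""


@dataclass
class ViewVolume:
    """One view's 3-D intensity array with axis/spacing metadata.

    ``data`` is indexed ``(depth, height, width)``; ``spacing`` holds the
    voxel spacing along the same axes (mm where known, 1.0 otherwise).
    """

    view_id: str
    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"view {self.view_id!r}: expected a 3-D (depth,height,width) array, "
                f"got {self.data.ndim} dimensions {self.data.shape}"
            )
        d, h, w = self.data.shape
        if d < 1:
            raise VolumeFormatError(f"view {self.view_id!r}: depth {d} < 1")
        if h < 8 or w < 8:
            raise VolumeFormatError(
                f"view {self.view_id!r}: in-plane size {h}x{w} below minimum 8x8"
            )

    @property
    def depth(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]


@dataclass
class Case:
    """An ordered set of views for one patient plus a binary label.

    ``label`` is 1 for the ACL-tear-positive class, 0 otherwise.  View
    order is canonical and must be identical across all cases of a dataset.
    """

    case_id: str
    views: list[ViewVolume]
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if len(self.views) < 1:
            raise ValueError(f"case {self.case_id!r} has no views")
        ids = [v.view_id for v in self.views]
        if len(set(ids)) != len(ids):
            raise ValueError(f"case {self.case_id!r} has duplicate view_ids: {ids}")

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def view_ids(self) -> list[str]:
        return [v.view_id for v in self.views]


@dataclass
class DatasetSplit:
    """Train/validation/test partitions with disjoint case ids."""

    train: list[Case]
    validation: list[Case]
    test: list[Case]

    def __post_init__(self):
        seen: dict[str, str] = {}
        for name, part in (
            ("train", self.train),
            ("validation", self.validation),
            ("test", self.test),
        ):
            for case in part:
                if case.case_id in seen:
                    raise ValueError(
                        f"case {case.case_id!r} appears in both "
                        f"{seen[case.case_id]} and {name}"
                    )
                seen[case.case_id] = name

    @property
    def all_cases(self) -> list[Case]:
        return self.train + self.validation + self.test


# ---------------------------------------------------------------------------
# loaders


def read_slice_stack(path, view_id: str) -> ViewVolume:
    """Load one view from a stacked-slice ``.npy`` array of shape (D, H, W).

    Raw intensities are preserved; no normalisation is applied here.
    """
    arr = np.load(path, allow_pickle=False)
    if arr.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected 3-D stacked slices, got {arr.ndim}-D array "
            f"of shape {arr.shape}"
        )
    return ViewVolume(view_id=view_id, data=arr)


def read_nifti(path, view_id: str) -> ViewVolume:
    """Load a NIfTI volume; the slowest-varying (k) axis becomes depth."""
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 3:
        raise VolumeFormatError(
            f"{path}: expected a 3-D NIfTI volume, got shape {arr.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    # NIfTI arrays are (i,j,k); present k (slice) first
    data = np.transpose(arr, (2, 0, 1))
    spacing = (float(zooms[2]), float(zooms[0]), float(zooms[1]))
    return ViewVolume(view_id=view_id, data=data, spacing=spacing)


def _slice_position(ds) -> float | None:
    pos = getattr(ds, "ImagePositionPatient", None)
    if pos is not None and len(pos) == 3:
        return float(pos[2])
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return float(loc)
    return None


def read_dicom_series(directory, view_id: str) -> ViewVolume:
    """Load one DICOM series directory into a (D, H, W) volume.

    Slices are sorted by slice position; if no position attribute is
    present anywhere in the series, filename order is used and a warning is
    logged.  Only pixel data and voxel spacing are retained — no
    patient-identifying header fields survive on the returned object.

    Raises
    ------
    VolumeFormatError
        for an empty directory, mixed series UIDs, or inconsistent slice
        sizes.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    if not files:
        raise VolumeFormatError(f"{directory}: no DICOM files found")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise VolumeFormatError(
            f"{directory}: mixed SeriesInstanceUIDs in one directory ({len(uids)})"
        )

    positions = [_slice_position(ds) for ds in datasets]
    if all(p is not None for p in positions):
        order = np.argsort(positions, kind="stable")
        datasets = [datasets[i] for i in order]
        positions = [positions[i] for i in order]
    else:
        logger.warning(
            "%s: no slice-position attribute; falling back to filename order",
            directory,
        )

    shapes = {ds.pixel_array.shape for ds in datasets}
    if len(shapes) > 1:
        raise VolumeFormatError(
            f"{directory}: inconsistent slice sizes {sorted(shapes)}"
        )
    data = np.stack([ds.pixel_array.astype(np.float32) for ds in datasets])

    ps = getattr(datasets[0], "PixelSpacing", [1.0, 1.0])
    if len(datasets) > 1 and positions[0] is not None:
        dz = abs(float(positions[1]) - float(positions[0])) or 1.0
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    return ViewVolume(
        view_id=view_id, data=data, spacing=(dz, float(ps[0]), float(ps[1]))
    )


# ---------------------------------------------------------------------------
# preprocessing


def _zscore_nonpad(data: np.ndarray, view_id: str) -> np.ndarray:
    """Z-score over voxels of slices that are not identically zero.

    All-zero slices are treated as padding and left untouched, which makes
    the whole preprocessing pipeline idempotent: a volume that is already
    normalised and zero-padded maps to itself.
    """
    nonpad = np.array([bool(np.any(s)) for s in data])
    if not nonpad.any():
        logger.warning("view %r: volume is all zeros after resampling", view_id)
        return np.zeros_like(data)
    vox = data[nonpad]
    sd = float(vox.std())
    if sd == 0.0:
        logger.warning(
            "view %r: constant-intensity volume, normalised to zeros", view_id
        )
        return np.zeros_like(data)
    mean = float(vox.mean())
    out = data.copy()
    out[nonpad] = (data[nonpad] - mean) / sd
    return out


def preprocess(v: ViewVolume, target_depth: int, target_hw: int) -> ViewVolume:
    """Normalise a view volume to shape ``(target_depth, target_hw, target_hw)``.

    Steps, in order:

    1. in-plane trilinear resampling to ``target_hw`` x ``target_hw``;
    2. per-volume z-score (mean 0, sd 1 over non-padding voxels); a
       constant-intensity volume becomes all zeros with a logged warning;
    3. depth harmonisation by symmetric centre-crop (depth too large) or
       symmetric zero-padding (depth too small).  Padding happens after
       normalisation so pad values sit at the volume mean; an odd
       remainder places the extra slice (cropped or padded) at the
       trailing end.
    """
    if target_depth < 1:
        raise ValueError(f"target_depth must be >= 1, got {target_depth}")
    if target_hw < 8:
        raise ValueError(f"target_hw must be >= 8, got {target_hw}")

    data = v.data.astype(np.float32)
    d, h, w = data.shape
    sz, sy, sx = v.spacing

    if (h, w) != (target_hw, target_hw):
        factors = (1.0, target_hw / h, target_hw / w)
        data = ndimage.zoom(data, factors, order=1, mode="nearest", grid_mode=True)
        if data.shape[1:] != (target_hw, target_hw):  # guard against rounding
            data = data[:, :target_hw, :target_hw]
            pad_h = target_hw - data.shape[1]
            pad_w = target_hw - data.shape[2]
            data = np.pad(data, ((0, 0), (0, pad_h), (0, pad_w)), mode="edge")
        sy, sx = sy * h / target_hw, sx * w / target_hw

    data = _zscore_nonpad(data, v.view_id)

    if d > target_depth:
        start = (d - target_depth) // 2  # extra removed slice at trailing end
        data = data[start : start + target_depth]
    elif d < target_depth:
        lead = (target_depth - d) // 2  # extra pad slice at trailing end
        trail = target_depth - d - lead
        data = np.pad(data, ((lead, trail), (0, 0), (0, 0)))

    return ViewVolume(view_id=v.view_id, data=data, spacing=(sz, sy, sx))


def assemble_case(
    volumes: Sequence[ViewVolume],
    label: int,
    case_id: str,
    view_order: Sequence[str] | None = None,
) -> Case:
    """Bundle preprocessed views into a labelled case in canonical view order.

    All volumes must share one shape and carry distinct view ids.  When
    ``view_order`` is given (the dataset config's canonical order), views
    are reordered to match it; filesystem or argument order is never
    trusted as canon on its own.
    """
    ids = [v.view_id for v in volumes]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"case {case_id!r}: duplicate view_id(s) {sorted(dupes)}")
    shapes = {v.data.shape for v in volumes}
    if len(shapes) > 1:
        raise ValueError(
            f"case {case_id!r}: views have mismatched shapes {sorted(shapes)}"
        )
    vols = list(volumes)
    if view_order is not None:
        by_id = {v.view_id: v for v in vols}
        missing = [i for i in view_order if i not in by_id]
        extra = [i for i in by_id if i not in view_order]
        if missing or extra:
            raise ValueError(
                f"case {case_id!r}: views {sorted(by_id)} do not match "
                f"canonical order {list(view_order)}"
            )
        vols = [by_id[i] for i in view_order]
    return Case(case_id=case_id, views=vols, label=int(label))


# ---------------------------------------------------------------------------
# case manifest (CSV + per-view stacked-slice arrays)


def write_manifest(cases: Sequence[Case], out_dir) -> Path:
    """Write cases as per-view ``.npy`` stacks plus a ``manifest.csv``.

    The CSV columns are ``case_id``, ``label``, then one path column per
    view in canonical order.  Returns the manifest path.
    """
    if not cases:
        raise ValueError("no cases to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    view_ids = cases[0].view_ids
    rows = []
    for case in cases:
        if case.view_ids != view_ids:
            raise ValueError(
                f"case {case.case_id!r} view order {case.view_ids} differs "
                f"from canonical {view_ids}"
            )
        row = {"case_id": case.case_id, "label": case.label}
        for v in case.views:
            fname = f"{case.case_id}_{v.view_id}.npy"
            np.save(out_dir / fname, v.data)
            row[v.view_id] = fname
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["case_id", "label", *view_ids]).to_csv(
        manifest, index=False
    )
    return manifest


def read_manifest(manifest_path) -> list[Case]:
    """Read a case manifest back into labelled cases (canonical view order)."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype={"case_id": str})
    required = {"case_id", "label"}
    if not required.issubset(df.columns):
        raise VolumeFormatError(
            f"{manifest_path}: manifest must have columns {sorted(required)}"
        )
    view_ids = [c for c in df.columns if c not in required]
    if not view_ids:
        raise VolumeFormatError(f"{manifest_path}: no view columns")
    base = manifest_path.parent
    cases = []
    for row in df.to_dict("records"):
        views = [
            read_slice_stack(base / row[vid], view_id=vid) for vid in view_ids
        ]
        cases.append(
            assemble_case(views, int(row["label"]), str(row["case_id"]), view_ids)
        )
    return cases
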