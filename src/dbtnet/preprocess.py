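"""Preprocessing of annotated DBT volumes into model-ready slice patches.

The pipeline is: orientation standardization (all breasts left-oriented),
bounding-box ROI extraction with a 10-pixel context margin on every side,
symmetric Z-window slice sampling around the annotated center slice,
per-crop min-max normalization, resizing to 224x224, and optional
training-time augmentation (random rotation and shifts).

Coordinate conventions: volumes are indexed ``(slice z, row y, column x)``;
bounding boxes are ``(x, y, width, height)`` with 0-based top-left corner and
half-open extents, matching the BCS-DBT annotation CSV dialect
(columns ``PatientID, StudyUID, View, Slice, X, Y, Width, Height, Class``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize, rotate

PATCH_SIDE = 224
ROI_MARGIN = 10

BENIGN, MALIGNANT = "benign", "malignant"
ANNOTATION_COLUMNS = ["PatientID", "StudyUID", "View", "Slice",
                      "X", "Y", "Width", "Height", "Class"]


@dataclass
class GrayVolume:
    """A grayscale tomosynthesis volume with physical voxel spacing."""

    voxels: np.ndarray            # (z, y, x), float intensities in [0, 1]
    spacing_xy: float = 0.085     # mm per pixel in-plane
    spacing_z: float = 1.0        # mm per slice
    view: str = ""                # e.g. "LCC", "RMLO"; leading letter = laterality

    def __post_init__(self):
        if self.voxels.ndim != 3 or self.voxels.shape[0] < 1:
            raise ValueError("volume must be a 3-D (z, y, x) stack")
        if self.spacing_xy <= 0 or self.spacing_z <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass(frozen=True)
class LesionAnnotation:
    """One annotated lesion: identity, class, center slice and bounding box."""

    patient_id: str
    view: str
    label: str                    # "benign" | "malignant"
    center_slice: int             # 0-based
    x: int
    y: int
    width: int
    height: int
    study_uid: str = ""

    def __post_init__(self):
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError("label must be 'benign' or 'malignant'")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("bounding box must have positive extent")

    @property
    def image_id(self) -> str:
        return f"{self.patient_id}_{self.view}"

    @property
    def label_int(self) -> int:
        return 1 if self.label == MALIGNANT else 0

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        return (self.x, self.y, self.width, self.height)


@dataclass(frozen=True)
class SliceWindowSpec:
    """Z-window size and the adjacent-slice radius m used at prediction time
    (2m+1 slices symmetric about the center slice)."""

    total_slices: int = 10
    m: int = 1

    def __post_init__(self):
        if self.total_slices < 1:
            raise ValueError("window must contain at least one slice")
        if 2 * self.m + 1 > self.total_slices:
            raise ValueError("2m+1 must not exceed the window size")


@dataclass
class PatchRecord:
    """A model-ready 224x224 grayscale patch with provenance."""

    patient_id: str
    image_id: str
    slice_index: int
    patch: np.ndarray             # (224, 224) float in [0, 1]
    label: int                    # 0 benign, 1 malignant


# ---------------------------------------------------------------------------
# Annotation table I/O (BCS-DBT dialect)
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> list[LesionAnnotation]:
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return [
        LesionAnnotation(patient_id=str(r.PatientID), view=str(r.View),
                         label=str(r.Class).lower(), center_slice=int(r.Slice),
                         x=int(r.X), y=int(r.Y), width=int(r.Width),
                         height=int(r.Height), study_uid=str(r.StudyUID))
        for r in df.itertuples()
    ]


def write_annotations(annotations: list[LesionAnnotation],
                      path: str | Path) -> None:
    df = pd.DataFrame([{
        "PatientID": a.patient_id, "StudyUID": a.study_uid, "View": a.view,
        "Slice": a.center_slice, "X": a.x, "Y": a.y, "Width": a.width,
        "Height": a.height, "Class": a.label} for a in annotations],
        columns=ANNOTATION_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def load_volume(path: str | Path, view: str = "",
                spacing_xy: float = 0.085, spacing_z: float = 1.0) -> GrayVolume:
    """Load a volume from a ``.npy``/``.npz`` stack or a DICOM series directory."""
    path = Path(path)
    if path.is_dir():
        import pydicom
        files = sorted(path.glob("*.dcm"))
        if not files:
            raise FileNotFoundError(f"no DICOM files in {path}")
        datasets = [pydicom.dcmread(str(f)) for f in files]
        datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
        stack = np.stack([d.pixel_array.astype(np.float64) for d in datasets])
        lo, hi = stack.min(), stack.max()
        voxels = (stack - lo) / (hi - lo) if hi > lo else np.zeros_like(stack)
        return GrayVolume(voxels, spacing_xy, spacing_z, view)
    if path.suffix == ".npz":
        with np.load(path) as data:
            voxels = data[data.files[0]]
    else:
        voxels = np.load(path)
    return GrayVolume(np.asarray(voxels, dtype=np.float64),
                      spacing_xy, spacing_z, view)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------

def mirror_bbox(ann: LesionAnnotation, image_width: int) -> LesionAnnotation:
    """Remap a bounding box under a horizontal mirror: x' = W - x - w."""
    return replace(ann, x=image_width - ann.x - ann.width)


def _breast_on_right(volume: GrayVolume) -> bool:
    mid = volume.voxels.shape[2] // 2
    return volume.voxels[:, :, mid:].sum() > volume.voxels[:, :, :mid].sum()


def standardize_orientation(
        volume: GrayVolume,
        annotations: list[LesionAnnotation] | None = None,
) -> tuple[GrayVolume, list[LesionAnnotation]]:
    """Flip right-lateral volumes about the vertical axis so breast tissue sits
    on the left of every slice; bounding boxes are remapped consistently.

    Without a laterality tag the side is inferred from the intensity centroid
    (a warning is emitted).
    """
    annotations = list(annotations or [])
    view = volume.view.upper()
    if view.startswith("L"):
        flip = False
    elif view.startswith("R"):
        flip = True
    else:
        flip = _breast_on_right(volume)
        warnings.warn("no laterality tag; orientation inferred from the "
                      "intensity centroid")
    if not flip:
        return volume, annotations
    width = volume.voxels.shape[2]
    flipped = GrayVolume(volume.voxels[:, :, ::-1].copy(), volume.spacing_xy,
                         volume.spacing_z, volume.view)
    return flipped, [mirror_bbox(a, width) for a in annotations]


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi(slice2d: np.ndarray, ann: LesionAnnotation,
                slice_index: int | None = None,
                margin: int = ROI_MARGIN, out_side: int = PATCH_SIDE) -> PatchRecord:
    """Crop the expanded bounding box, normalize and resize to 224x224.

    The box is expanded by ``margin`` pixels on each of the four sides
    (20 px total per dimension) and clipped to the image bounds.  Intensities
    are min-max normalized per crop; the crop is resized with bilinear
    interpolation (anti-aliased on downscale).
    """
    h, w = slice2d.shape
    x0, y0 = ann.x - margin, ann.y - margin
    x1, y1 = ann.x + ann.width + margin, ann.y + ann.height + margin
    if ann.x >= w or ann.y >= h or ann.x + ann.width <= 0 or \
            ann.y + ann.height <= 0:
        raise ValueError("bounding box lies fully outside the image")
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    crop = np.asarray(slice2d[y0:y1, x0:x1], dtype=np.float64)
    lo, hi = crop.min(), crop.max()
    if hi > lo:
        crop = (crop - lo) / (hi - lo)
    else:
        warnings.warn("zero-dynamic-range crop normalized to all-zeros")
        crop = np.zeros_like(crop)
    downscale = crop.shape[0] > out_side or crop.shape[1] > out_side
    patch = resize(crop, (out_side, out_side), order=1,
                   anti_aliasing=downscale, mode="reflect",
                   preserve_range=True)
    patch = np.clip(patch, 0.0, 1.0).astype(np.float32)
    return PatchRecord(ann.patient_id, ann.image_id,
                       ann.center_slice if slice_index is None else slice_index,
                       patch, ann.label_int)


# ---------------------------------------------------------------------------
# Slice sampling
# ---------------------------------------------------------------------------

def sample_slices(volume: GrayVolume, ann: LesionAnnotation,
                  spec: SliceWindowSpec = SliceWindowSpec()) -> list[int]:
    """Return the contiguous Z-window of ``spec.total_slices`` indices around
    the annotated center slice (split -5/+4 for the default 10), shifted
    minimally to stay within the volume.

    A volume shorter than the window yields all its slices with a warning.
    """
    n = volume.n_slices
    if not 0 <= ann.center_slice < n:
        raise ValueError("center slice outside the volume")
    total = spec.total_slices
    if n < total:
        warnings.warn("volume shorter than the slice window; using all slices")
        return list(range(n))
    lo = ann.center_slice - total // 2
    lo = min(max(lo, 0), n - total)
    return list(range(lo, lo + total))


def prediction_slices(window: list[int], center_slice: int, m: int) -> list[int]:
    """Select the 2m+1 indices symmetric about the center slice, shifted
    minimally to remain inside the window."""
    count = 2 * m + 1
    if count > len(window):
        raise ValueError("2m+1 exceeds the window size")
    lo = center_slice - m
    lo = min(max(lo, window[0]), window[-1] - count + 1)
    return list(range(lo, lo + count))


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def augment(record: PatchRecord, rng_seed: int,
            angle_range: tuple[float, float] = (10.0, 30.0),
            max_shift_frac: float = 0.10) -> PatchRecord:
    """Training-time augmentation: rotation by an angle drawn uniformly from
    +/-[10, 30] degrees and integer shifts up to 10% of the side, zero-filled.

    Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(rng_seed)
    angle = rng.uniform(*angle_range) * rng.choice([-1.0, 1.0])
    out = rotate(record.patch, angle, order=1, mode="constant", cval=0.0,
                 preserve_range=True)
    max_shift = int(round(max_shift_frac * record.patch.shape[0]))
    dy, dx = rng.integers(-max_shift, max_shift + 1, size=2)
    shifted = np.zeros_like(out)
    h, w = out.shape
    ys, yd = (0, dy) if dy >= 0 else (-dy, 0)
    xs, xd = (0, dx) if dx >= 0 else (-dx, 0)
    shifted[yd:h - ys, xd:w - xs] = out[ys:h - yd, xs:w - xd]
    return PatchRecord(record.patient_id, record.image_id, record.slice_index,
                       np.clip(shifted, 0.0, 1.0), record.label)


# ---------------------------------------------------------------------------
# Volume -> patch records
# ---------------------------------------------------------------------------

def patches_from_volume(volume: GrayVolume, ann: LesionAnnotation,
                        spec: SliceWindowSpec = SliceWindowSpec(),
                        ) -> list[PatchRecord]:
    """Standardize orientation, sample the Z-window and extract one patch per
    slice."""
    volume, anns = standardize_orientation(volume, [ann])
    ann = anns[0]
    return [extract_roi(volume.voxels[z], ann, slice_index=z)
            for z in sample_slices(volume, ann, spec)]
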