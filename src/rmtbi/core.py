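"""Core containers and volume/atlas I/O.

All analyses in this package operate on atlas-aligned volumes: a 3D integer
label map segments the brain into areas, areas are organised into anatomical
region groups (thalamus, hippocampus, basal ganglia, cerebellum, cerebrum),
and per-area summary timecourses are the unit passed to the statistical
stages.  Voxel coordinates are 0-based array indices throughout; no
world-coordinate transforms are applied, since inputs are assumed
co-registered to a common atlas space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HEMISPHERES = frozenset({"left", "right", "midline"})

REGION_CSV_COLUMNS = ["label_id", "area_name", "hemisphere", "region_group"]


@dataclass
class LabelAtlas:
    """3D integer label map plus a region table.

    Parameters
    ----------
    labels : ndarray of int, shape (X, Y, Z)
        Voxelwise area labels; 0 is background and never appears in the
        region table.
    regions : pandas.DataFrame
        One row per area with columns ``label_id`` (positive int, unique),
        ``area_name``, ``hemisphere`` (left/right/midline) and
        ``region_group`` (anatomical cluster the area belongs to).
    """

    labels: np.ndarray
    regions: pd.DataFrame
    voxel_size_mm: np.ndarray = field(
        default_factory=lambda: np.ones(3, dtype=float)
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"label map must be 3D, got {self.labels.ndim}D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("atlas voxel values are not integers")
            self.labels = as_int
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must be 3 positive values")
        missing = set(REGION_CSV_COLUMNS) - set(self.regions.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        ids = self.regions["label_id"].to_numpy()
        if np.any(ids <= 0):
            raise ValueError("label ids must be positive; 0 is background")
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate label ids in region table")
        bad_hemi = set(self.regions["hemisphere"]) - HEMISPHERES
        if bad_hemi:
            raise ValueError(f"unknown hemisphere values: {sorted(bad_hemi)}")
        in_map = set(np.unique(self.labels)) - {0}
        in_table = set(int(i) for i in ids)
        orphans = in_map - in_table
        if orphans:
            raise ValueError(
                f"labels present in map but absent from region table: {sorted(orphans)}"
            )

    @property
    def label_ids(self) -> np.ndarray:
        return self.regions["label_id"].to_numpy()

    def group_of(self, label_id: int) -> str:
        row = self.regions.loc[self.regions["label_id"] == label_id]
        if row.empty:
            raise KeyError(f"label {label_id} not in region table")
        return str(row["region_group"].iloc[0])


@dataclass
class VolumeSeries:
    """A 3D volume or 4D series with voxel geometry and acquisition times.

    ``times_s`` is empty for a 3D volume; for a 4D series it is strictly
    increasing with one entry per volume (e.g. 0..199 s for a 200-repetition
    TR = 1 s BOLD run).
    """

    data: np.ndarray
    voxel_size_mm: np.ndarray = field(
        default_factory=lambda: np.ones(3, dtype=float)
    )
    times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume must be 3D or 4D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        self.voxel_size_mm = np.asarray(self.voxel_size_mm, dtype=float)
        if self.voxel_size_mm.shape != (3,) or np.any(self.voxel_size_mm <= 0):
            raise ValueError("voxel_size_mm must be 3 positive values")
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.data.ndim == 4:
            if self.times_s.shape != (self.data.shape[3],):
                raise ValueError(
                    "times_s must have one entry per volume of a 4D series"
                )
            if np.any(np.diff(self.times_s) <= 0):
                raise ValueError("times_s must be strictly increasing")
        elif self.times_s.size:
            raise ValueError("times_s must be empty for a 3D volume")

    @property
    def n_volumes(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])


@dataclass
class RegionTimecourse:
    """Per-region intensity summaries over time for one subject.

    Both the mean and the median over the region's voxels are kept; their
    difference is a cheap skewness diagnostic of the regional intensity
    distribution.
    """

    subject_id: str
    label_id: int
    mean_intensity: np.ndarray
    median_intensity: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        self.mean_intensity = np.atleast_1d(np.asarray(self.mean_intensity, float))
        self.median_intensity = np.atleast_1d(
            np.asarray(self.median_intensity, float)
        )
        if self.mean_intensity.shape != self.median_intensity.shape:
            raise ValueError("mean and median vectors must share length")
        if self.n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")

    @property
    def skew_diagnostic(self) -> np.ndarray:
        """mean - median per time point; positive for right-skewed regions."""
        return self.mean_intensity - self.median_intensity


def _region_csv_path(nifti_path: Path) -> Path:
    stem = nifti_path.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return nifti_path.parent / f"{stem}_regions.csv"


def read_region_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    missing = set(REGION_CSV_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: region CSV missing columns {sorted(missing)}")
    return table[REGION_CSV_COLUMNS]


def read_labeled_volume(
    path: str | Path,
    kind: str = "image",
    region_csv: str | Path | None = None,
) -> LabelAtlas | VolumeSeries:
    """Read a NIfTI volume as an image series or a label atlas.

    Parameters
    ----------
    path : path to a ``.nii``/``.nii.gz`` file.
    kind : {"image", "atlas"}
        Atlases additionally require a sibling region CSV named
        ``<stem>_regions.csv`` (or pass ``region_csv`` explicitly) with
        columns ``label_id,area_name,hemisphere,region_group``.
    region_csv : optional explicit path to the region table.

    For 4D images the repetition time is taken from the NIfTI header's
    fourth zoom and acquisition times are ``0, TR, 2 TR, ...``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind not in ("atlas", "image"):
        raise ValueError(f"kind must be 'atlas' or 'image', got {kind!r}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    zooms = img.header.get_zooms()
    voxel_size = np.asarray(zooms[:3], dtype=float)

    if kind == "atlas":
        csv_path = Path(region_csv) if region_csv else _region_csv_path(path)
        if not csv_path.exists():
            raise FileNotFoundError(
                f"atlas {path} needs a sibling region table {csv_path}"
            )
        table = read_region_table(csv_path)
        as_int = np.round(data).astype(np.int64)
        if not np.allclose(data, as_int, atol=0, rtol=0):
            raise ValueError(f"{path}: atlas contains non-integer voxel values")
        atlas = LabelAtlas(labels=as_int, regions=table, voxel_size_mm=voxel_size)
        return atlas

    data = np.asarray(data, dtype=float)
    if data.ndim == 4:
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        times = np.arange(data.shape[3], dtype=float) * tr
    else:
        times = np.empty(0)
    return VolumeSeries(data=data, voxel_size_mm=voxel_size, times_s=times)


def write_volume(
    vol: VolumeSeries | LabelAtlas, path: str | Path, region_csv: bool = True
) -> Path:
    """Write a VolumeSeries or LabelAtlas to NIfTI (atlas: + region CSV)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(vol, LabelAtlas):
        affine = np.diag(list(vol.voxel_size_mm) + [1.0])
        img = nib.Nifti1Image(vol.labels.astype(np.int16), affine)
        img.header.set_zooms(tuple(vol.voxel_size_mm))
        nib.save(img, str(path))
        if region_csv:
            vol.regions.to_csv(_region_csv_path(path), index=False)
        return path
    affine = np.diag(list(vol.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float64), affine)
    if vol.data.ndim == 4:
        dt = np.diff(vol.times_s)
        tr = float(dt[0]) if dt.size else 1.0
        img.header.set_zooms(tuple(vol.voxel_size_mm) + (tr,))
    else:
        img.header.set_zooms(tuple(vol.voxel_size_mm))
    nib.save(img, str(path))
    return path


def extract_region_series(
    image: VolumeSeries, atlas: LabelAtlas, subject_id: str = "subject"
) -> list[RegionTimecourse]:
    """Summarise an image over every atlas region.

    Returns one :class:`RegionTimecourse` per region present in the atlas
    table, with the voxelwise mean and median at each time point.  Regions
    with zero voxels in the label map are skipped with a warning so that
    reduced-resolution phantoms remain usable.
    """
    if image.grid_shape != tuple(atlas.labels.shape):
        raise ValueError(
            f"image grid {image.grid_shape} != atlas grid {atlas.labels.shape}"
        )
    data = image.data if image.data.ndim == 4 else image.data[..., None]
    out: list[RegionTimecourse] = []
    for label_id in atlas.label_ids:
        mask = atlas.labels == label_id
        n_vox = int(mask.sum())
        if n_vox == 0:
            warnings.warn(
                f"region {label_id} has zero voxels and is omitted", stacklevel=2
            )
            continue
        vox = data[mask, :]  # (n_vox, T)
        out.append(
            RegionTimecourse(
                subject_id=subject_id,
                label_id=int(label_id),
                mean_intensity=vox.mean(axis=0),
                median_intensity=np.median(vox, axis=0),
                n_voxels=n_vox,
            )
        )
    return out


def region_series_frame(series: list[RegionTimecourse]) -> pd.DataFrame:
    """Long-format table: one row per subject x region x time point."""
    rows = []
    for tc in series:
        for t in range(tc.mean_intensity.size):
            rows.append(
                {
                    "subject_id": tc.subject_id,
                    "label_id": tc.label_id,
                    "time_index": t,
                    "mean_intensity": tc.mean_intensity[t],
                    "median_intensity": tc.median_intensity[t],
                    "n_voxels": tc.n_voxels,
                }
            )
    return pd.DataFrame(rows)


def b1_zaxis_correct(
    image: VolumeSeries, phantom_profile: np.ndarray
) -> VolumeSeries:
    """Correct B1 coil-sensitivity gain along the slice (Z) axis.

    A homogeneous phantom tube scanned alongside the subject measures the
    coil's sensitivity profile along Z.  Under a purely multiplicative gain
    model each z-slice is divided by ``profile[z] / mean(profile)``, so a
    flat profile leaves the image untouched and the whole-image intensity
    scale is preserved.
    """
    profile = np.asarray(phantom_profile, dtype=float).ravel()
    nz = image.data.shape[2]
    if profile.size != nz:
        raise ValueError(
            f"profile length {profile.size} != number of slices {nz}"
        )
    if np.any(profile <= 0):
        raise ValueError("phantom profile entries must be positive")
    gain = profile / profile.mean()
    shape = [1, 1, nz] + ([1] if image.data.ndim == 4 else [])
    corrected = image.data / gain.reshape(shape)
    return VolumeSeries(
        data=corrected,
        voxel_size_mm=image.voxel_size_mm.copy(),
        times_s=image.times_s.copy(),
    )
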