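"""Atlas parcellation of registered lesion masks.

Converts 3-D binary lesion masks plus a bilateral labelled atlas into
region-wise lesion-load counts, laterality labels, and the log-transformed
patients x (2 * n_regions) lesion matrix that feeds the atom decomposition.

Masks must already live on the atlas grid (registration happens upstream);
a grid or affine mismatch is an error, never silently resampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    FormatError,
    GeometryError,
    SchemaError,
)

logger = logging.getLogger(__name__)

HEMISPHERES = ("L", "R")

#: tolerance for affine agreement between mask and atlas (mm)
AFFINE_ATOL = 1e-4


@dataclass
class AtlasParcellation:
    """A bilateral labelled atlas volume plus its region table.

    Parameters
    ----------
    labels
        3-D integer array; 0 is background, positive integers are region
        labels.
    affine
        4x4 voxel-to-world affine of the label volume.
    region_table
        One row per region with columns ``label``, ``name``, ``hemisphere``
        ("L" or "R") and ``homolog_label`` (the label of the mirrored region
        in the other hemisphere). Homolog pairs must be mutual and both
        hemispheres must contain the same number of regions.
    """

    labels: np.ndarray
    affine: np.ndarray
    region_table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not np.issubdtype(np.asarray(self.labels).dtype, np.integer):
            raise FormatError("atlas label volume must be an integer array")
        required = {"label", "name", "hemisphere", "homolog_label"}
        missing = required - set(self.region_table.columns)
        if missing:
            raise SchemaError(f"region table missing columns: {sorted(missing)}")
        table = self.region_table
        if table["label"].duplicated().any():
            raise SchemaError("duplicate labels in region table")
        bad_hemi = set(table["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise SchemaError(f"unknown hemisphere codes: {sorted(bad_hemi)}")
        known = set(table["label"])
        in_volume = set(np.unique(self.labels)) - {0}
        unknown = in_volume - known
        if unknown:
            raise SchemaError(
                f"labels present in volume but absent from region table: {sorted(unknown)}"
            )
        homolog = dict(zip(table["label"], table["homolog_label"]))
        for a, b in homolog.items():
            if b not in homolog or homolog[b] != a:
                raise SchemaError(f"homolog pairing is not mutual for label {a}")
        n_left = (table["hemisphere"] == "L").sum()
        n_right = (table["hemisphere"] == "R").sum()
        if n_left != n_right:
            raise SchemaError(
                f"hemispheres have unequal region counts ({n_left} L vs {n_right} R)"
            )

    @property
    def n_regions_per_hemisphere(self) -> int:
        return int((self.region_table["hemisphere"] == "L").sum())

    def labels_of(self, hemisphere: str) -> np.ndarray:
        """Region labels of one hemisphere, in region-table order."""
        t = self.region_table
        return t.loc[t["hemisphere"] == hemisphere, "label"].to_numpy()

    def region_sizes(self) -> pd.Series:
        """Voxel count of every region in the label volume."""
        flat = np.bincount(self.labels.ravel())
        sizes = {
            int(lab): int(flat[lab]) if lab < len(flat) else 0
            for lab in self.region_table["label"]
        }
        return pd.Series(sizes, name="n_voxels")

    def column_names(self) -> list[str]:
        """Lesion-matrix column names: all left regions then all right."""
        t = self.region_table
        cols = []
        for hemi in HEMISPHERES:
            sub = t[t["hemisphere"] == hemi]
            cols.extend(f"{hemi}_{name}" for name in sub["name"])
        return cols

    def to_files(self, volume_path: str | Path, table_path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int32), self.affine)
        nib.save(img, str(volume_path))
        self.region_table.to_csv(table_path, sep="\t", index=False)


def load_atlas(volume_path: str | Path, table_path: str | Path) -> AtlasParcellation:
    """Read an atlas volume (NIfTI) and region table (TSV) and validate them."""
    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise FormatError(f"atlas volume {volume_path} is not integer-valued")
    table = pd.read_csv(table_path, sep="\t")
    return AtlasParcellation(
        labels=data.astype(np.int64), affine=np.asarray(img.affine), region_table=table
    )


@dataclass
class RegionLesionLoad:
    """Per-patient lesioned-voxel counts per atlas region.

    ``counts`` is indexed by region label; ``background`` holds lesioned
    voxels that fell outside every atlas region.
    """

    patient_id: str
    counts: pd.Series
    background: int = 0

    def __post_init__(self) -> None:
        if (self.counts < 0).any():
            raise FormatError("negative lesion-load count")

    def total_volume(self, include_background: bool = False) -> int:
        total = int(self.counts.sum())
        return total + self.background if include_background else total


def _as_volume(mask) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(mask, (str, Path)):
        img = nib.load(str(mask))
        return np.asanyarray(img.dataobj), np.asarray(img.affine)
    if isinstance(mask, nib.spatialimages.SpatialImage):
        return np.asanyarray(mask.dataobj), np.asarray(mask.affine)
    return np.asarray(mask), None


def count_lesion_load(
    mask, atlas: AtlasParcellation, patient_id: str = "patient"
) -> RegionLesionLoad:
    """Count lesioned voxels per atlas-defined region.

    ``mask`` may be a NIfTI path, an image, or a bare binary array (in which
    case the affine check is skipped). Values must be exactly 0/1.
    """
    data, affine = _as_volume(mask)
    if data.shape != atlas.labels.shape:
        raise GeometryError(
            f"mask grid {data.shape} does not match atlas grid {atlas.labels.shape}"
        )
    if affine is not None and not np.allclose(affine, atlas.affine, atol=AFFINE_ATOL):
        raise GeometryError("mask affine differs from atlas affine beyond tolerance")
    values = np.unique(data)
    if not np.all(np.isin(values, (0, 1))):
        raise FormatError(f"mask is not binary (values {values[:5]}...)")
    lesioned = atlas.labels[data > 0]
    flat = np.bincount(lesioned.ravel())
    labels = atlas.region_table["label"].to_numpy()
    counts = pd.Series(
        [int(flat[lab]) if lab < len(flat) else 0 for lab in labels],
        index=labels,
        name=patient_id,
    )
    background = int(flat[0]) if len(flat) else 0
    return RegionLesionLoad(patient_id=patient_id, counts=counts, background=background)


def classify_laterality(
    load: RegionLesionLoad, atlas: AtlasParcellation, tolerance: int = 0
) -> str:
    """Label a lesion as left, right, bilateral or none.

    A hemisphere counts as affected when its summed load exceeds
    ``tolerance`` voxels (default 0: a single voxel makes it bilateral,
    mirroring the strict exclusion of bilateral strokes).
    """
    sums = {
        h: int(load.counts.loc[atlas.labels_of(h)].sum()) for h in HEMISPHERES
    }
    left, right = sums["L"] > tolerance, sums["R"] > tolerance
    if left and right:
        return "bilateral"
    if left:
        return "left"
    if right:
        return "right"
    return "none"


def zscore(values: np.ndarray) -> np.ndarray:
    """Population (divide-by-n) z-scoring; constant input maps to zeros."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def assemble_lesion_matrix(
    loads: list[RegionLesionLoad],
    atlas: AtlasParcellation,
    include_background_in_volume: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Stack per-patient loads into the log-transformed lesion matrix.

    Returns the patients x (2 * n_regions) matrix with entries
    ``log1p(count)`` — log1p so that the ubiquitous zero loads map to 0 —
    column order all left regions then all right regions (region-table
    order), plus the z-scored total lesion volume vector. Voxels on atlas
    background are excluded from the totals unless
    ``include_background_in_volume`` is set.
    """
    ids = [ld.patient_id for ld in loads]
    if len(set(ids)) != len(ids):
        raise AlignmentError("duplicate patient_id in lesion loads")
    order = np.concatenate([atlas.labels_of(h) for h in HEMISPHERES])
    rows = np.stack([ld.counts.loc[order].to_numpy(dtype=float) for ld in loads])
    matrix = pd.DataFrame(
        np.log1p(rows), index=pd.Index(ids, name="patient_id"),
        columns=atlas.column_names(),
    )
    volumes = np.array(
        [ld.total_volume(include_background_in_volume) for ld in loads], dtype=float
    )
    volume_z = pd.Series(
        zscore(volumes), index=matrix.index, name="lesion_volume_z"
    )
    return matrix, volume_z
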