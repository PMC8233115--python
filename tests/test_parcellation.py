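"""Atlas parcellation: lesion-load counting, laterality, lesion matrix."""

import nibabel as nib
import numpy as np
import pandas as pd
import pytest

from lesionatoms.errors import (
    AlignmentError,
    FormatError,
    GeometryError,
    SchemaError,
)
from lesionatoms.parcellation import (
    AtlasParcellation,
    assemble_lesion_matrix,
    classify_laterality,
    count_lesion_load,
    load_atlas,
    zscore,
)
from lesionatoms.simulate import (
    SimulationConfig,
    generate_cohort,
    make_toy_atlas,
    write_voxel_masks,
)


class TestAtlasValidation:
    def test_toy_atlas_has_108_region_rows(self, toy_atlas):
        assert len(toy_atlas.region_table) == 108
        assert toy_atlas.n_regions_per_hemisphere == 54

    def test_roundtrip_through_files(self, tiny_atlas, tmp_path):
        tiny_atlas.to_files(tmp_path / "atlas.nii.gz", tmp_path / "regions.tsv")
        loaded = load_atlas(tmp_path / "atlas.nii.gz", tmp_path / "regions.tsv")
        np.testing.assert_array_equal(loaded.labels, tiny_atlas.labels)
        pd.testing.assert_frame_equal(loaded.region_table, tiny_atlas.region_table)

    def test_label_missing_from_table_is_named_in_error(self, tiny_atlas):
        table = tiny_atlas.region_table[tiny_atlas.region_table["label"] != 3]
        with pytest.raises(SchemaError, match="3"):
            AtlasParcellation(tiny_atlas.labels, tiny_atlas.affine, table)

    def test_non_mutual_homolog_pairing_rejected(self, tiny_atlas):
        table = tiny_atlas.region_table.copy()
        # A->B but B->C breaks mutuality
        table.loc[table["label"] == 5, "homolog_label"] = 2
        with pytest.raises(SchemaError, match="mutual"):
            AtlasParcellation(tiny_atlas.labels, tiny_atlas.affine, table)

    def test_non_integer_volume_rejected(self, tiny_atlas, tmp_path):
        img = nib.Nifti1Image(tiny_atlas.labels.astype(float) + 0.5, np.eye(4))
        nib.save(img, str(tmp_path / "bad.nii.gz"))
        tiny_atlas.region_table.to_csv(tmp_path / "regions.tsv", sep="\t", index=False)
        with pytest.raises(FormatError):
            load_atlas(tmp_path / "bad.nii.gz", tmp_path / "regions.tsv")


class TestCountLesionLoad:
    def test_counts_exactly_the_painted_voxels(self, toy_atlas):
        mask = np.zeros_like(toy_atlas.labels, dtype=np.uint8)
        where3 = np.argwhere(toy_atlas.labels == 3)[:5]
        where7 = np.argwhere(toy_atlas.labels == 7)[:2]
        for x, y, z in np.vstack([where3, where7]):
            mask[x, y, z] = 1
        load = count_lesion_load(mask, toy_atlas)
        assert load.counts.loc[3] == 5
        assert load.counts.loc[7] == 2
        assert load.counts.drop([3, 7]).eq(0).all()
        assert load.total_volume() == 7

    def test_empty_mask_counts_zero(self, toy_atlas):
        load = count_lesion_load(np.zeros_like(toy_atlas.labels), toy_atlas)
        assert load.counts.eq(0).all()
        assert load.total_volume() == 0

    def test_full_region_counts_its_size(self, tiny_atlas):
        mask = (tiny_atlas.labels == 2).astype(np.uint8)
        load = count_lesion_load(mask, tiny_atlas)
        assert load.counts.loc[2] == int((tiny_atlas.labels == 2).sum())

    def test_background_voxels_tracked_separately(self, tiny_atlas):
        labels = tiny_atlas.labels.copy()
        labels[0, 0, 0] = 0  # carve one background voxel
        atlas = AtlasParcellation(labels, tiny_atlas.affine, tiny_atlas.region_table)
        mask = np.zeros_like(labels, dtype=np.uint8)
        mask[0, 0, 0] = 1
        load = count_lesion_load(mask, atlas)
        assert load.background == 1
        assert load.total_volume() == 0
        assert load.total_volume(include_background=True) == 1

    def test_grid_mismatch_rejected(self, tiny_atlas):
        with pytest.raises(GeometryError):
            count_lesion_load(np.zeros((2, 2, 2)), tiny_atlas)

    def test_affine_mismatch_rejected(self, tiny_atlas, tmp_path):
        affine = np.eye(4)
        affine[0, 3] = 5.0
        img = nib.Nifti1Image(
            np.zeros_like(tiny_atlas.labels, dtype=np.uint8), affine
        )
        with pytest.raises(GeometryError):
            count_lesion_load(img, tiny_atlas)

    def test_non_binary_mask_rejected(self, tiny_atlas):
        mask = np.zeros_like(tiny_atlas.labels)
        mask[0, 0, 0] = 2
        with pytest.raises(FormatError):
            count_lesion_load(mask, tiny_atlas)


class TestLaterality:
    def _load(self, atlas, left=0, right=0):
        counts = pd.Series(0, index=atlas.region_table["label"].to_numpy())
        if left:
            counts.loc[atlas.labels_of("L")[0]] = left
        if right:
            counts.loc[atlas.labels_of("R")[0]] = right
        from lesionatoms.parcellation import RegionLesionLoad

        return RegionLesionLoad("p", counts)

    def test_left_only(self, tiny_atlas):
        assert classify_laterality(self._load(tiny_atlas, left=10), tiny_atlas) == "left"

    def test_single_contralateral_voxel_makes_bilateral(self, tiny_atlas):
        load = self._load(tiny_atlas, left=100, right=1)
        assert classify_laterality(load, tiny_atlas, tolerance=0) == "bilateral"
        assert classify_laterality(load, tiny_atlas, tolerance=1) == "left"

    def test_empty_is_none(self, tiny_atlas):
        assert classify_laterality(self._load(tiny_atlas), tiny_atlas) == "none"


class TestLesionMatrix:
    def _loads(self, atlas, rows):
        from lesionatoms.parcellation import RegionLesionLoad

        labels = atlas.region_table["label"].to_numpy()
        return [
            RegionLesionLoad(pid, pd.Series(row, index=labels))
            for pid, row in rows.items()
        ]

    def test_log1p_and_column_order(self, tiny_atlas):
        labels = tiny_atlas.region_table["label"].to_numpy()
        row = np.zeros(len(labels), dtype=int)
        row[0] = 1  # first left region
        loads = self._loads(tiny_atlas, {"a": row, "b": np.zeros_like(row)})
        matrix, volume_z = assemble_lesion_matrix(loads, tiny_atlas)
        assert matrix.shape == (2, len(labels))
        assert matrix.columns[0].startswith("L_")
        assert matrix.iloc[0, 0] == pytest.approx(np.log1p(1))
        assert (matrix.iloc[1] == 0).all()
        np.testing.assert_allclose(np.sort(volume_z), [-1.0, 1.0])

    def test_duplicate_patient_rejected(self, tiny_atlas):
        labels = tiny_atlas.region_table["label"].to_numpy()
        row = np.zeros(len(labels), dtype=int)
        loads = self._loads(tiny_atlas, {"a": row})
        with pytest.raises(AlignmentError):
            assemble_lesion_matrix(loads + loads, tiny_atlas)

    def test_row_permutation_permutes_matrix(self, tiny_atlas):
        rng = np.random.default_rng(0)
        labels = tiny_atlas.region_table["label"].to_numpy()
        rows = {
            f"p{i}": rng.integers(0, 5, len(labels)) for i in range(5)
        }
        loads = self._loads(tiny_atlas, rows)
        m1, _ = assemble_lesion_matrix(loads, tiny_atlas)
        m2, _ = assemble_lesion_matrix(loads[::-1], tiny_atlas)
        pd.testing.assert_frame_equal(m1, m2.iloc[::-1])

    def test_adding_voxels_never_decreases_entries(self, tiny_atlas):
        labels = tiny_atlas.region_table["label"].to_numpy()
        base = np.ones(len(labels), dtype=int)
        more = base.copy()
        more[2] += 10
        loads = self._loads(tiny_atlas, {"base": base, "more": more})
        matrix, _ = assemble_lesion_matrix(loads, tiny_atlas)
        assert (matrix.loc["more"] >= matrix.loc["base"]).all()


def test_mask_roundtrip_recovers_counts_exactly(toy_atlas, tmp_path):
    """write_voxel_masks -> count_lesion_load is the identity on counts."""
    cohort = generate_cohort(SimulationConfig(n_patients=20, seed=42))
    paths = write_voxel_masks(cohort.lesion_loads, toy_atlas, tmp_path)
    order = np.concatenate([toy_atlas.labels_of(h) for h in ("L", "R")])
    for pid, path in paths.items():
        load = count_lesion_load(path, toy_atlas, patient_id=pid)
        np.testing.assert_array_equal(
            load.counts.loc[order].to_numpy(),
            cohort.lesion_loads.loc[pid].to_numpy(),
        )


def test_zscore_constant_input_is_zero():
    np.testing.assert_array_equal(zscore(np.full(5, 3.0)), np.zeros(5))
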