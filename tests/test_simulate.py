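"""Synthetic-cohort generator: shapes, invariants, degenerate limits."""

import numpy as np
import pandas as pd
import pytest

from lesionatoms.errors import AlignmentError, CapacityError, InvalidConfigError
from lesionatoms.simulate import (
    COVARIATE_COLUMNS,
    SimulationConfig,
    generate_atom_basis,
    generate_cohort,
    generate_covariates,
    generate_lesions,
    generate_outcomes,
    make_toy_atlas,
    write_voxel_masks,
)


class TestAtomBasis:
    def test_shape_and_positivity(self):
        W = generate_atom_basis(54, 10, seed=0)
        assert W.shape == (54, 10)
        assert (W.to_numpy() > 0).all()  # background keeps every region nonzero
        assert (W.sum(axis=0) > 0).all()
        np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-12)

    def test_blocks_are_distinct_even_when_tiny(self):
        W = generate_atom_basis(2, 2, seed=1).to_numpy()
        corr = np.corrcoef(W[:, 0], W[:, 1])[0, 1]
        assert corr < 1.0

    def test_block_structure(self):
        W = generate_atom_basis(54, 10, seed=3).to_numpy()
        for a in range(10):
            high = W[:, a] > 0.1
            assert 3 <= high.sum() <= 8
            idx = np.flatnonzero(high)
            assert (np.diff(idx) == 1).all()  # contiguous block

    def test_seeded_determinism(self):
        pd.testing.assert_frame_equal(
            generate_atom_basis(54, 10, seed=7), generate_atom_basis(54, 10, seed=7)
        )

    def test_too_many_atoms_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_atom_basis(5, 6, seed=0)


class TestLesions:
    def test_single_atom_loads_proportional_to_basis_column(self):
        # with no multiplicative noise, V = W h exactly (up to rounding)
        config = SimulationConfig(
            n_patients=1, n_regions=20, n_atoms=5, load_noise_sd=0.0,
            loading_scale=200.0, prob_left=1.0, seed=2,
        )
        basis = generate_atom_basis(20, 5, seed=2)
        loads, loadings, hemis = generate_lesions(config, basis)
        h = loadings.iloc[0, :5].to_numpy()
        expected = np.round(basis.to_numpy() @ h)
        np.testing.assert_array_equal(loads.iloc[0, :20].to_numpy(), expected)
        assert (loads.iloc[0, 20:] == 0).all()

    def test_prob_left_one_keeps_right_empty(self):
        config = SimulationConfig(n_patients=40, prob_left=1.0, seed=3)
        basis = generate_atom_basis(54, 10, seed=3)
        loads, _, hemis = generate_lesions(config, basis)
        assert (hemis == "left").all()
        assert (loads.iloc[:, 54:] == 0).all().all()

    def test_zero_loading_scale_gives_empty_lesions(self):
        config = SimulationConfig(n_patients=10, loading_scale=0.0, seed=4)
        basis = generate_atom_basis(54, 10, seed=4)
        loads, loadings, _ = generate_lesions(config, basis)
        assert (loads == 0).all().all()
        assert loads.sum(axis=1).eq(0).all()

    def test_unilaterality_invariant(self):
        cohort = generate_cohort(SimulationConfig(n_patients=100, seed=5))
        left = cohort.loadings_true.iloc[:, :10].sum(axis=1)
        right = cohort.loadings_true.iloc[:, 10:].sum(axis=1)
        assert (((left > 0) & (right == 0)) | ((left == 0) & (right > 0))).all()


class TestCovariates:
    def test_continuous_columns_z_scored(self):
        cov = generate_covariates(SimulationConfig(n_patients=200, seed=6))
        assert list(cov.columns) == list(COVARIATE_COLUMNS)
        for col in cov.columns:
            if col == "sex":
                assert set(np.unique(cov[col])) <= {0.0, 1.0}
            else:
                assert abs(cov[col].mean()) < 1e-10
                assert abs(cov[col].to_numpy().std() - 1.0) < 1e-10

    def test_two_patients_give_plus_minus_one(self):
        # population-sd z-scoring of two distinct points is exactly +/-1
        cov = generate_covariates(SimulationConfig(n_patients=2, seed=7))
        for col in ("age", "education", "iqcode"):
            np.testing.assert_allclose(np.sort(np.abs(cov[col])), [1.0, 1.0], atol=1e-12)

    def test_single_patient_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_covariates(SimulationConfig(n_patients=1, seed=0))

    def test_seeded_determinism(self):
        a = generate_covariates(SimulationConfig(n_patients=30, seed=8))
        b = generate_covariates(SimulationConfig(n_patients=30, seed=8))
        pd.testing.assert_frame_equal(a, b)


class TestOutcomes:
    def test_fully_degenerate_config_gives_constant_outcome(self):
        config = SimulationConfig(
            n_patients=20, true_sigma_left=0.0, true_sigma_right=0.0,
            true_gamma=(0.0,) * 8, true_alpha=2.0, noise_sd=0.0, seed=9,
        )
        cohort = generate_cohort(config)
        np.testing.assert_allclose(cohort.outcomes.to_numpy(), 2.0, atol=1e-12)

    def test_zero_noise_outcomes_match_linear_predictor(self):
        config = SimulationConfig(n_patients=50, noise_sd=0.0, seed=10)
        cohort = generate_cohort(config)
        truth = cohort.truth
        H = cohort.loadings_true.to_numpy() / truth["loading_scale_used"]
        X = cohort.covariates.to_numpy()
        beta = np.concatenate([truth["beta_left"], truth["beta_right"]])
        mu = truth["alpha"] + H @ beta + X @ np.asarray(truth["gamma"])
        np.testing.assert_allclose(cohort.outcomes.to_numpy(), mu, atol=1e-10)

    def test_hemisphere_dispersions_order_coefficient_spread(self):
        # Monte-Carlo check of the prior draw: sd 0.3 vs 0.0 per hemisphere
        wins = 0
        for seed in range(100):
            config = SimulationConfig(
                n_patients=2, true_sigma_left=0.3, true_sigma_right=0.0, seed=seed
            )
            cohort = generate_cohort(config)
            var_l = np.var(cohort.truth["beta_left"])
            var_r = np.var(cohort.truth["beta_right"])
            wins += var_l > var_r
        assert wins >= 95

    def test_noise_calibration_hits_target_r2(self):
        cohort = generate_cohort(SimulationConfig(n_patients=400, seed=12))
        assert abs(cohort.truth["generative_r2"] - 0.5) < 1e-9

    def test_misaligned_rows_rejected(self):
        config = SimulationConfig(n_patients=20, seed=13)
        cohort = generate_cohort(config)
        with pytest.raises(AlignmentError):
            generate_outcomes(
                cohort.loadings_true.iloc[:10], cohort.covariates, config
            )


class TestVoxelMasks:
    def test_mask_paints_exact_counts(self, tmp_path):
        atlas = make_toy_atlas(n_regions=4, cube=3)
        loads = pd.DataFrame(
            [[5, 0, 2, 0, 0, 0, 0, 0]],
            index=pd.Index(["p0001"], name="patient_id"),
            columns=atlas.column_names(),
        )
        paths = write_voxel_masks(loads, atlas, tmp_path)
        import nibabel as nib

        mask = np.asanyarray(nib.load(str(paths["p0001"])).dataobj)
        assert mask.sum() == 7
        assert (mask[atlas.labels == 1]).sum() == 5
        assert (mask[atlas.labels == 3]).sum() == 2

    def test_all_zero_loads_give_empty_mask(self, tmp_path):
        atlas = make_toy_atlas(n_regions=4, cube=3)
        loads = pd.DataFrame(
            np.zeros((1, 8), dtype=int),
            index=pd.Index(["p0001"], name="patient_id"),
            columns=atlas.column_names(),
        )
        paths = write_voxel_masks(loads, atlas, tmp_path)
        import nibabel as nib

        assert np.asanyarray(nib.load(str(paths["p0001"])).dataobj).sum() == 0

    def test_overfull_region_raises_capacity_error(self, tmp_path):
        atlas = make_toy_atlas(n_regions=4, cube=3)  # 27 voxels per region
        loads = pd.DataFrame(
            [[28, 0, 0, 0, 0, 0, 0, 0]],
            index=pd.Index(["p0001"], name="patient_id"),
            columns=atlas.column_names(),
        )
        with pytest.raises(CapacityError, match="region"):
            write_voxel_masks(loads, atlas, tmp_path)


def test_cohort_is_bitwise_reproducible():
    config = SimulationConfig(n_patients=40, seed=99)
    a, b = generate_cohort(config), generate_cohort(config)
    pd.testing.assert_frame_equal(a.lesion_loads, b.lesion_loads)
    pd.testing.assert_frame_equal(a.covariates, b.covariates)
    pd.testing.assert_series_equal(a.outcomes, b.outcomes)
    assert a.truth["beta_left"] == b.truth["beta_left"]


def test_invalid_configs_rejected():
    with pytest.raises(InvalidConfigError):
        SimulationConfig(n_patients=0)
    with pytest.raises(InvalidConfigError):
        SimulationConfig(prob_left=1.5)
    with pytest.raises(InvalidConfigError):
        SimulationConfig(true_sigma_left=-0.1)
    with pytest.raises(InvalidConfigError):
        SimulationConfig(n_regions=5, n_atoms=6)
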