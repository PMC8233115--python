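"""Synthetic stroke-cohort generator.

Emulates the statistical structure the downstream analysis assumes: unilateral
lesions over 54 homologous regions per hemisphere, low-rank non-negative
lesion-load structure (region loads = W @ h per patient, up to multiplicative
noise and integer rounding), z-scored covariates, and a Gaussian cognitive
outcome driven by hemisphere-grouped atom coefficients drawn from
hemisphere-specific dispersions. Every draw is reproducible from the config
seed, and the full ground truth is recorded for parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import AlignmentError, CapacityError, InvalidConfigError
from .parcellation import AtlasParcellation, HEMISPHERES, zscore

#: fixed covariate column order used throughout the pipeline
COVARIATE_COLUMNS = (
    "age",
    "age2",
    "sex",
    "age_x_sex",
    "time_since_stroke",
    "education",
    "iqcode",
    "lesion_volume",
)

#: continuous columns that are z-scored (sex stays binary; the derived
#: age2 / age_x_sex are built from z-scored age, then z-scored themselves)
_RAW_CONTINUOUS = ("age", "time_since_stroke", "education", "iqcode", "lesion_volume")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults encode the reference scenario used across the test-bed: a
     600-patient unilateral cohort, 10 atoms on 54 homologous regions,
    strongly left-dominant atom dispersions (0.30 vs 0.03 on the z-scored
    outcome scale) and residual noise calibrated so the generative
    signal-to-total variance ratio is ~0.5 (``noise_sd=None`` triggers the
    calibration; set an explicit value to override).

    The gamma-distributed atom loadings (shape 2, mean ``loading_scale``)
    are a modelling stand-in: non-negative and right-skewed like real lesion
    loads, but not estimated from any empirical loading distribution.
    """

    n_patients: int = 600
    n_regions: int = 54
    n_atoms: int = 10
    prob_left: float = 0.5
    true_sigma_left: float = 0.30
    true_sigma_right: float = 0.03
    true_gamma: tuple[float, ...] = (
        -0.10,  # age
        -0.02,  # age2
        0.02,  # sex
        0.00,  # age x sex
        -0.03,  # time since stroke
        0.06,  # education
        -0.35,  # iqcode
        -0.21,  # lesion volume
    )
    true_alpha: float = 0.0
    noise_sd: float | None = None
    target_r2: float = 0.5
    #: share one coefficient draw between homologous atoms, making every
    #: true left-minus-right difference exactly zero (atom-level null)
    mirror_beta: bool = False
    loading_scale: float = 30.0
    load_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be positive")
        if not 0.0 <= self.prob_left <= 1.0:
            raise InvalidConfigError("prob_left must lie in [0, 1]")
        if self.n_atoms > self.n_regions:
            raise InvalidConfigError("n_atoms cannot exceed n_regions")
        for name in (
            "true_sigma_left",
            "true_sigma_right",
            "loading_scale",
            "load_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be non-negative")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if len(self.true_gamma) != len(COVARIATE_COLUMNS):
            raise InvalidConfigError(
                f"true_gamma must have {len(COVARIATE_COLUMNS)} entries "
                f"(order {COVARIATE_COLUMNS})"
            )


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it."""

    config: SimulationConfig
    lesion_loads: pd.DataFrame  # patients x 2*n_regions integer counts
    loadings_true: pd.DataFrame  # patients x 2*n_atoms slotted loadings
    basis_true: pd.DataFrame  # n_regions x n_atoms, unit-L2 columns
    hemispheres: pd.Series  # "left"/"right" per patient
    covariates: pd.DataFrame
    outcomes: pd.Series
    truth: dict

    def total_volumes(self) -> pd.Series:
        return self.lesion_loads.sum(axis=1).rename("total_volume")


def _rng(seed, stream: int) -> np.random.Generator:
    # documented seed fan-out: every sub-draw gets its own (seed, stream) pair
    return np.random.default_rng([int(seed), int(stream)])


def atom_column_names(n_atoms: int) -> list[str]:
    return [f"{h}_atom{a + 1:02d}" for h in HEMISPHERES for a in range(n_atoms)]


def make_toy_atlas(n_regions: int = 54, cube: int = 6) -> AtlasParcellation:
    """Grid atlas with one ``cube``-edged block per region, mirrored L/R.

    Left-hemisphere labels are 1..n, right labels n+1..2n with mutual
    homolog pairing; small enough for sub-second mask round-trips.
    """
    n_cols = int(np.ceil(np.sqrt(n_regions)))
    n_rows = int(np.ceil(n_regions / n_cols))
    shape = (2 * cube, n_rows * cube, n_cols * cube)
    labels = np.zeros(shape, dtype=np.int64)
    rows = []
    for hemi_idx, hemi in enumerate(HEMISPHERES):
        x0 = hemi_idx * cube
        for r in range(n_regions):
            label = r + 1 + hemi_idx * n_regions
            row, col = divmod(r, n_cols)
            labels[
                x0 : x0 + cube,
                row * cube : (row + 1) * cube,
                col * cube : (col + 1) * cube,
            ] = label
            rows.append(
                {
                    "label": label,
                    "name": f"region_{r + 1:02d}",
                    "hemisphere": hemi,
                    "homolog_label": r + 1 + (1 - hemi_idx) * n_regions,
                }
            )
    table = pd.DataFrame(rows)
    return AtlasParcellation(labels=labels, affine=np.eye(4), region_table=table)


def generate_atom_basis(
    n_regions: int = 54, n_atoms: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Draw a block-structured non-negative atom basis (unit-L2 columns).

    Each atom gets a contiguous block of 3-8 high-weight regions anchored in
    its own stretch of the region axis (so atoms are well separated), plus a
    tiny uniform background so no region has weight exactly zero.
    """
    if n_atoms > n_regions:
        raise InvalidConfigError("n_atoms cannot exceed n_regions")
    rng = np.random.default_rng(seed)
    W = rng.uniform(0.001, 0.004, size=(n_regions, n_atoms))
    for a in range(n_atoms):
        start = int(np.floor(a * n_regions / n_atoms))
        if n_regions >= 3 * n_atoms:
            length = int(rng.integers(3, 9))
        else:
            # too few regions for 3-8-wide blocks: one disjoint segment each
            length = max(1, n_regions // n_atoms)
        length = min(length, n_regions - start)
        W[start : start + length, a] = rng.uniform(0.6, 1.0, size=length)
    W /= np.linalg.norm(W, axis=0, keepdims=True)
    return pd.DataFrame(
        W,
        index=[f"region_{r + 1:02d}" for r in range(n_regions)],
        columns=[f"atom{a + 1:02d}" for a in range(n_atoms)],
    )


def generate_lesions(
    config: SimulationConfig, basis: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Draw unilateral lesion loads as integer-rounded noisy W @ h.

    Per patient: hemisphere ~ Bernoulli(prob_left); atom loadings h are
    Gamma(shape=2, mean=loading_scale) draws for the lesioned hemisphere and
    exactly zero for the other; region loads are
    ``round(exp(noise) * (W @ h))`` with elementwise log-normal noise of
    sd ``load_noise_sd``.

    Returns (region loads [patients x 2*n_regions], slotted true loadings
    [patients x 2*n_atoms], hemisphere labels).
    """
    W = basis.to_numpy()
    if W.shape != (config.n_regions, config.n_atoms):
        raise AlignmentError(
            f"basis shape {W.shape} does not match config "
            f"({config.n_regions}, {config.n_atoms})"
        )
    n, p, k = config.n_patients, config.n_regions, config.n_atoms
    rng = _rng(config.seed, 1)
    is_left = rng.random(n) < config.prob_left
    if config.loading_scale > 0:
        h = rng.gamma(shape=2.0, scale=config.loading_scale / 2.0, size=(n, k))
    else:
        h = np.zeros((n, k))
    noise = rng.normal(0.0, config.load_noise_sd, size=(n, p))
    raw = np.exp(noise) * (h @ W.T)
    loads_hemi = np.round(raw).clip(min=0).astype(np.int64)

    ids = pd.Index([f"p{i + 1:04d}" for i in range(n)], name="patient_id")
    atlas_cols = [f"{hemi}_{name}" for hemi in HEMISPHERES for name in basis.index]
    loads = np.zeros((n, 2 * p), dtype=np.int64)
    loadings = np.zeros((n, 2 * k))
    loads[is_left, :p] = loads_hemi[is_left]
    loads[~is_left, p:] = loads_hemi[~is_left]
    loadings[is_left, :k] = h[is_left]
    loadings[~is_left, k:] = h[~is_left]
    hemispheres = pd.Series(
        np.where(is_left, "left", "right"), index=ids, name="hemisphere"
    )
    return (
        pd.DataFrame(loads, index=ids, columns=atlas_cols),
        pd.DataFrame(loadings, index=ids, columns=atom_column_names(k)),
        hemispheres,
    )


def generate_covariates(
    config: SimulationConfig, total_volumes: pd.Series | np.ndarray | None = None
) -> pd.DataFrame:
    """Draw the covariate table on the z-score scale.

    Continuous columns (age, time since stroke, education, IQCODE, lesion
    volume) are z-scored over the cohort with the population (divide-by-n)
    standard deviation; sex is binary 0/1; age^2 and age x sex are computed
    from the z-scored age and then z-scored themselves. When
    ``total_volumes`` is given (the realized per-patient lesion totals) it
    supplies the lesion-volume column; otherwise volumes are drawn
    log-normally.
    """
    n = config.n_patients
    if n < 2:
        raise InvalidConfigError("cannot z-score covariates with fewer than 2 patients")
    rng = _rng(config.seed, 2)
    raw = pd.DataFrame(index=pd.Index([f"p{i + 1:04d}" for i in range(n)], name="patient_id"))
    raw["age"] = rng.normal(67.4, 11.0, n)
    raw["sex"] = (rng.random(n) < 0.43).astype(float)
    raw["time_since_stroke"] = rng.normal(98.0, 30.0, n).clip(min=1.0)
    raw["education"] = rng.normal(9.3, 4.5, n).clip(min=0.0)
    raw["iqcode"] = rng.normal(3.38, 0.5, n).clip(1.0, 5.0)
    if total_volumes is None:
        raw["lesion_volume"] = rng.lognormal(mean=3.0, sigma=1.0, size=n)
    else:
        vols = np.asarray(total_volumes, dtype=float)
        if len(vols) != n:
            raise AlignmentError("total_volumes length does not match n_patients")
        raw["lesion_volume"] = vols

    out = pd.DataFrame(index=raw.index)
    for col in _RAW_CONTINUOUS:
        out[col] = zscore(raw[col].to_numpy())
    out["sex"] = raw["sex"]
    out["age2"] = zscore(out["age"].to_numpy() ** 2)
    out["age_x_sex"] = zscore(out["age"].to_numpy() * out["sex"].to_numpy())
    return out[list(COVARIATE_COLUMNS)]


def pooled_nonzero_sd(loadings: pd.DataFrame | np.ndarray) -> float:
    """Population sd of the nonzero slotted-loading entries (1.0 if none)."""
    values = np.asarray(loadings, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        return 1.0
    sd = float(nonzero.std())
    return sd if sd > 0 else 1.0


def generate_outcomes(
    loadings: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.Series, dict]:
    """Draw outcomes from the hemisphere-grouped linear model.

    beta_{h,a} ~ Normal(0, sigma_h^2) per hemisphere/atom;
    y = alpha + H_std @ beta + X @ gamma + Normal(0, noise_sd^2), where
    H_std are the slotted loadings standardized by their pooled nonzero sd
    (the same convention the analysis side uses). When ``config.noise_sd``
    is None the residual scale is calibrated from the realized signal
    variance so that the generative R^2 equals ``config.target_r2``.
    """
    if not loadings.index.equals(covariates.index):
        raise AlignmentError("loadings and covariates are not row-aligned")
    k = loadings.shape[1] // 2
    rng = _rng(config.seed, 3)
    beta_left = rng.normal(0.0, config.true_sigma_left, k)
    if config.mirror_beta:
        beta_right = beta_left.copy()  # homologous atoms share coefficients
    else:
        beta_right = rng.normal(0.0, config.true_sigma_right, k)
    beta = np.concatenate([beta_left, beta_right])
    gamma = np.asarray(config.true_gamma, dtype=float)

    scale = pooled_nonzero_sd(loadings)
    H_std = loadings.to_numpy() / scale
    X = covariates[list(COVARIATE_COLUMNS)].to_numpy()
    signal = config.true_alpha + H_std @ beta + X @ gamma

    if config.noise_sd is None:
        sig_var = float(np.var(signal))
        r2 = config.target_r2
        noise_sd = float(np.sqrt(sig_var * (1.0 - r2) / r2)) if sig_var > 0 else 0.0
    else:
        noise_sd = config.noise_sd
    y = signal + rng.normal(0.0, noise_sd, len(signal))
    outcomes = pd.Series(y, index=loadings.index, name="outcome")
    truth = {
        "alpha": config.true_alpha,
        "beta_left": beta_left.tolist(),
        "beta_right": beta_right.tolist(),
        "gamma": gamma.tolist(),
        "sigma_left": config.true_sigma_left,
        "sigma_right": config.true_sigma_right,
        "noise_sd": noise_sd,
        "loading_scale_used": scale,
        "generative_r2": float(np.var(signal) / (np.var(signal) + noise_sd**2))
        if (np.var(signal) + noise_sd**2) > 0
        else float("nan"),
    }
    return outcomes, truth


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (basis, lesions, covariates, outcomes)."""
    basis = generate_atom_basis(config.n_regions, config.n_atoms, config.seed)
    loads, loadings, hemispheres = generate_lesions(config, basis)
    covariates = generate_covariates(config, loads.sum(axis=1))
    outcomes, truth = generate_outcomes(loadings, covariates, config)
    truth = dict(truth, config=asdict(config))
    return SyntheticCohort(
        config=config,
        lesion_loads=loads,
        loadings_true=loadings,
        basis_true=basis,
        hemispheres=hemispheres,
        covariates=covariates,
        outcomes=outcomes,
        truth=truth,
    )


def write_voxel_masks(
    lesion_loads: pd.DataFrame,
    atlas: AtlasParcellation,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Paint per-region voxel counts into binary NIfTI masks, one per patient.

    Voxels are painted deterministically (lowest flat indices first) inside
    each region's atlas support, so a mask round-trips exactly through
    ``parcellation.count_lesion_load``. A load exceeding the region's voxel
    capacity raises :class:`CapacityError` naming the region.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # per-label flat voxel indices, sorted: deterministic painting order
    flat_labels = atlas.labels.ravel()
    order = np.argsort(flat_labels, kind="stable")
    sorted_labels = flat_labels[order]
    boundaries = np.searchsorted(sorted_labels, np.arange(sorted_labels.max() + 2))
    label_to_cols = {
        lab: i for i, lab in enumerate(atlas.column_names())
    }  # column order matches lesion_loads
    col_labels = np.concatenate([atlas.labels_of(h) for h in HEMISPHERES])
    paths: dict[str, Path] = {}
    for patient_id, row in lesion_loads.iterrows():
        mask = np.zeros(flat_labels.shape, dtype=np.uint8)
        counts = row.to_numpy()
        for j, lab in enumerate(col_labels):
            c = int(counts[j])
            if c == 0:
                continue
            lo, hi = boundaries[lab], boundaries[lab + 1]
            if c > hi - lo:
                raise CapacityError(
                    f"load {c} exceeds capacity {hi - lo} of region label {lab} "
                    f"({atlas.column_names()[j]}) for patient {patient_id}"
                )
            mask[order[lo : lo + c]] = 1
        img = nib.Nifti1Image(mask.reshape(atlas.labels.shape), atlas.affine)
        path = out_dir / f"{patient_id}_mask.nii.gz"
        nib.save(img, str(path))
        paths[str(patient_id)] = path
    return paths


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Persist cohort tables as CSV and the truth record as JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "lesion_loads": out_dir / "lesion_loads.csv",
        "loadings_true": out_dir / "loadings_true.csv",
        "basis_true": out_dir / "basis_true.csv",
        "covariates": out_dir / "covariates.csv",
        "outcomes": out_dir / "outcomes.csv",
        "hemispheres": out_dir / "hemispheres.csv",
        "truth": out_dir / "truth.json",
    }
    cohort.lesion_loads.to_csv(paths["lesion_loads"])
    cohort.loadings_true.to_csv(paths["loadings_true"])
    cohort.basis_true.to_csv(paths["basis_true"])
    cohort.covariates.to_csv(paths["covariates"])
    cohort.outcomes.to_frame().to_csv(paths["outcomes"])
    cohort.hemispheres.to_frame().to_csv(paths["hemispheres"])
    paths["truth"].write_text(json.dumps(cohort.truth, indent=2))
    return paths
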