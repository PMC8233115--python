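"""End-to-end pipeline wiring: simulate -> parcellate -> decompose -> fit -> report.

Each stage persists its inputs/outputs under the bundle directory and a
manifest JSON records package version, seeds, and content hashes of every
file written, so a rerun with the same config and seed is byte-reproducible
and any stage can be resumed in isolation. The global seed fans out to
per-stage seeds through a documented rule (`stage_seed`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atoms import AtomBasis, AtomLoadings, fit_nmf, reconstruction_correlation
from .errors import InvalidConfigError, LesionAtomsError
from .model import (
    ModelSpec,
    build_model,
    build_model_data,
    posterior_predictive_r2,
    sample_posterior,
)
from .parcellation import (
    assemble_lesion_matrix,
    classify_laterality,
    count_lesion_load,
    load_atlas,
    zscore,
)
from .relevance import build_relevance_report
from .simulate import (
    COVARIATE_COLUMNS,
    SimulationConfig,
    generate_cohort,
    make_toy_atlas,
    write_cohort,
    write_voxel_masks,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "parcellate", "decompose", "fit", "report")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([global_seed, stage index]).

    Keeps every derived seed below 2**31 so it can be passed anywhere.
    """
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(global_seed), idx]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    out_dir: str = "results/pipeline"
    mode: str = "simulate"  # "simulate" or "data"
    seed: int = 0
    log_level: str = "INFO"
    # data-mode paths
    masks_dir: str | None = None
    atlas_volume: str | None = None
    atlas_table: str | None = None
    covariate_table: str | None = None
    # analysis settings
    outcomes: list[str] = field(default_factory=lambda: ["outcome"])
    k: int = 10
    n_restarts: int = 5
    nmf_mode: str = "pooled"
    subset: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    model: dict = field(default_factory=dict)  # ModelSpec overrides per run
    model_per_outcome: dict = field(default_factory=dict)
    write_masks: bool = True
    resume: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = raw.pop("simulation", {})
        config = cls(**raw)
        if isinstance(sim, dict):
            config.simulation = SimulationConfig(**sim)
        return config

    def validate(self) -> None:
        if self.mode not in ("simulate", "data"):
            raise InvalidConfigError(f"unknown mode {self.mode!r}")
        if self.mode == "data":
            for name in ("masks_dir", "atlas_volume", "atlas_table", "covariate_table"):
                value = getattr(self, name)
                if value is None:
                    raise InvalidConfigError(f"data mode requires {name}")
                if not Path(value).exists():
                    raise InvalidConfigError(f"{name} path does not exist: {value}")

    def model_spec(self, outcome: str) -> ModelSpec:
        settings = dict(self.model)
        settings.update(self.model_per_outcome.get(outcome, {}))
        settings.setdefault("seed", stage_seed(self.seed, "fit"))
        settings["outcome_name"] = outcome
        return ModelSpec(**settings)


def subset_filter(covariates: pd.DataFrame, rule: str | None) -> np.ndarray:
    """Boolean row mask from a rule like ``"age>=65"`` (None keeps all rows).

    The caller re-z-scores continuous covariates on the retained subset
    (see :func:`apply_subset`); an empty subset is an error because it
    cannot be z-scored.
    """
    if rule is None or rule.strip() == "":
        return np.ones(len(covariates), dtype=bool)
    match = re.fullmatch(
        r"\s*(\w+)\s*(<=|>=|<|>|==|!=)\s*(-?\d+(?:\.\d+)?)\s*", rule
    )
    if not match:
        raise InvalidConfigError(f"cannot parse subset rule {rule!r}")
    column, op, value = match.group(1), match.group(2), float(match.group(3))
    if column not in covariates.columns:
        raise InvalidConfigError(f"subset rule references unknown column {column!r}")
    series = covariates[column].to_numpy(dtype=float)
    ops = {
        "<=": series <= value,
        ">=": series >= value,
        "<": series < value,
        ">": series > value,
        "==": series == value,
        "!=": series != value,
    }
    mask = ops[op]
    if not mask.any():
        raise InvalidConfigError(f"subset rule {rule!r} matches no rows; cannot z-score")
    return mask


def apply_subset(covariates: pd.DataFrame, mask: np.ndarray) -> pd.DataFrame:
    """Restrict rows and recompute z-scores of continuous columns on the subset."""
    sub = covariates.loc[mask].copy()
    for col in sub.columns:
        if col == "sex":
            continue
        sub[col] = zscore(sub[col].to_numpy())
    return sub


def _hash_file(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


class _Bundle:
    """Tracks files written by the run for the manifest."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.files: dict[str, str] = {}

    def register(self, *paths: Path) -> None:
        for path in paths:
            self.files[str(path.relative_to(self.out_dir))] = _hash_file(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the report bundle description.

    Any stage error aborts with the stage name; outputs of completed stages
    stay on disk.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = _Bundle(out_dir)
    report: dict = {"out_dir": str(out_dir), "stages": {}}
    stage = "setup"
    try:
        # --- simulate ---------------------------------------------------
        if config.mode == "simulate":
            stage = "simulate"
            sim_dir = out_dir / "simulate"
            sim = dataclasses.replace(
                config.simulation, seed=stage_seed(config.seed, "simulate")
            )
            cohort = generate_cohort(sim)
            atlas = make_toy_atlas(sim.n_regions)
            paths = write_cohort(cohort, sim_dir)
            atlas.to_files(sim_dir / "atlas.nii.gz", sim_dir / "atlas_regions.tsv")
            paths["atlas_volume"] = sim_dir / "atlas.nii.gz"
            paths["atlas_table"] = sim_dir / "atlas_regions.tsv"
            if config.write_masks:
                mask_paths = write_voxel_masks(
                    cohort.lesion_loads, atlas, sim_dir / "masks"
                )
                bundle.register(*mask_paths.values())
                config.masks_dir = str(sim_dir / "masks")
            bundle.register(*paths.values())
            config.atlas_volume = str(paths["atlas_volume"])
            config.atlas_table = str(paths["atlas_table"])
            covariates = cohort.covariates
            outcome_table = cohort.outcomes.to_frame()
            report["stages"]["simulate"] = {"n_patients": sim.n_patients}
        else:
            covariates_full = pd.read_csv(config.covariate_table, index_col=0)
            covariates = covariates_full[list(COVARIATE_COLUMNS)]
            outcome_table = covariates_full[config.outcomes]
            cohort = None

        # --- parcellate -------------------------------------------------
        stage = "parcellate"
        atlas = load_atlas(config.atlas_volume, config.atlas_table)
        if config.mode == "simulate" and not config.write_masks:
            # counts already exist in the cohort tables; skip voxel I/O
            loads_df = cohort.lesion_loads
            matrix = pd.DataFrame(
                np.log1p(loads_df.to_numpy(dtype=float)),
                index=loads_df.index,
                columns=loads_df.columns,
            )
            volume_z = pd.Series(
                zscore(loads_df.sum(axis=1).to_numpy()),
                index=loads_df.index,
                name="lesion_volume_z",
            )
        else:
            mask_files = sorted(Path(config.masks_dir).glob("*_mask.nii.gz"))
            loads, kept = [], []
            for mask_file in mask_files:
                pid = mask_file.name.replace("_mask.nii.gz", "")
                load = count_lesion_load(mask_file, atlas, patient_id=pid)
                side = classify_laterality(load, atlas)
                if side in ("bilateral", "none"):
                    logger.warning("dropping %s patient %s", side, pid)
                    continue
                loads.append(load)
                kept.append(pid)
            matrix, volume_z = assemble_lesion_matrix(loads, atlas)
            covariates = covariates.loc[matrix.index]
            outcome_table = outcome_table.loc[matrix.index]
        parc_dir = out_dir / "parcellate"
        parc_dir.mkdir(exist_ok=True)
        matrix.to_csv(parc_dir / "lesion_matrix.csv")
        volume_z.to_frame().to_csv(parc_dir / "lesion_volume_z.csv")
        bundle.register(parc_dir / "lesion_matrix.csv", parc_dir / "lesion_volume_z.csv")
        report["stages"]["parcellate"] = {"n_patients": len(matrix)}

        # --- optional subset (sensitivity rerun) ------------------------
        if config.subset:
            mask = subset_filter(covariates, config.subset)
            matrix = matrix.loc[mask]
            covariates = apply_subset(covariates, mask)
            outcome_table = outcome_table.loc[mask]
            report["stages"]["subset"] = {"rule": config.subset, "n_kept": int(mask.sum())}

        # --- decompose --------------------------------------------------
        stage = "decompose"
        basis, loadings, fit_report = fit_nmf(
            matrix,
            k=config.k,
            seed=stage_seed(config.seed, "decompose"),
            n_restarts=config.n_restarts,
            mode=config.nmf_mode,
        )
        fit_report["reconstruction_r"] = reconstruction_correlation(
            matrix, basis, loadings
        )
        dec_dir = out_dir / "decompose"
        dec_dir.mkdir(exist_ok=True)
        basis.W.to_csv(dec_dir / "atom_basis.csv")
        loadings.H_slotted.to_csv(dec_dir / "atom_loadings.csv")
        (dec_dir / "nmf_report.json").write_text(json.dumps(fit_report, indent=2))
        bundle.register(
            dec_dir / "atom_basis.csv",
            dec_dir / "atom_loadings.csv",
            dec_dir / "nmf_report.json",
        )
        report["stages"]["decompose"] = fit_report

        # --- fit + report per outcome -----------------------------------
        fit_dir = out_dir / "fit"
        rep_dir = out_dir / "report"
        fit_dir.mkdir(exist_ok=True)
        rep_dir.mkdir(exist_ok=True)
        report["stages"]["fit"] = {}
        for outcome_name in config.outcomes:
            stage = "fit"
            spec = config.model_spec(outcome_name)
            data = build_model_data(
                loadings,
                covariates,
                outcome_table[outcome_name],
                include_lesion_volume=spec.include_lesion_volume,
                outcome_name=outcome_name,
            )
            model = build_model(data, spec)
            samples = sample_posterior(model, spec)
            samples.to_dataframe().to_csv(
                fit_dir / f"posterior_{outcome_name}.csv", index=False
            )
            (fit_dir / f"diagnostics_{outcome_name}.json").write_text(
                json.dumps(samples.diagnostics, indent=2, default=float)
            )
            bundle.register(
                fit_dir / f"posterior_{outcome_name}.csv",
                fit_dir / f"diagnostics_{outcome_name}.json",
            )

            stage = "report"
            r2 = posterior_predictive_r2(samples, data)
            relevance = build_relevance_report(
                samples, basis, r2=r2, outcome_name=outcome_name
            )
            paths = relevance.write(rep_dir)
            bundle.register(*paths.values())
            report["stages"]["fit"][outcome_name] = {
                "n": data.n,
                "r2_mean": r2["mean"],
                "converged": samples.diagnostics["converged"],
            }

        # --- manifest ----------------------------------------------------
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
            "config": {
                key: (dataclasses.asdict(val) if dataclasses.is_dataclass(val) else val)
                for key, val in dataclasses.asdict(config).items()
            },
            "files": bundle.files,
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        report["manifest"] = str(out_dir / "manifest.json")
        return report
    except LesionAtomsError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
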