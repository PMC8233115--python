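#!/usr/bin/env python
"""Summarize the posterior into hemisphere / atom / region relevance tables.

Reads the posterior from 04_fit_outcome_model.py, reports which atoms are
lateralized (left-minus-right difference HPDI excluding zero), back-projects
atom coefficients to the 54 regions per hemisphere, and writes the tidy
relevance tables plus a region-relevance NIfTI volume to results/report/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lesionatoms.atoms import AtomBasis
from lesionatoms.model import PosteriorSamples
from lesionatoms.parcellation import load_atlas
from lesionatoms.relevance import build_relevance_report, export_region_volume
from lesionatoms.simulate import COVARIATE_COLUMNS

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--atoms", type=Path, default=Path("results/atoms"))
parser.add_argument("--fit", type=Path, default=Path("results/fit"))
parser.add_argument("--out", type=Path, default=Path("results/report"))
args = parser.parse_args()

posterior = pd.read_csv(args.fit / "posterior.csv")
basis = AtomBasis(W=pd.read_csv(args.atoms / "atom_basis.csv", index_col=0))
k = basis.n_atoms

beta_cols = [c for c in posterior.columns if c.startswith("beta_")]
gamma_cols = [c for c in posterior.columns if c.startswith("gamma_")]
n_chains = posterior["chain"].nunique()
n_draws = len(posterior) // n_chains


def stack(cols):
    return posterior[cols].to_numpy().reshape(n_chains, n_draws, len(cols))


samples = PosteriorSamples(
    alpha=posterior["alpha"].to_numpy().reshape(n_chains, n_draws),
    beta=stack(beta_cols),
    gamma=stack(gamma_cols),
    tau=posterior["tau"].to_numpy().reshape(n_chains, n_draws),
    sigma_left=posterior["sigma_left"].to_numpy().reshape(n_chains, n_draws),
    sigma_right=posterior["sigma_right"].to_numpy().reshape(n_chains, n_draws),
    sigma_eps=posterior["sigma_eps"].to_numpy().reshape(n_chains, n_draws),
    atom_names=[c.removeprefix("beta_") for c in beta_cols],
    covariate_names=[c.removeprefix("gamma_") for c in gamma_cols],
)

report = build_relevance_report(samples, basis, outcome_name="outcome")
paths = report.write(args.out)
atlas = load_atlas(args.cohort / "atlas.nii.gz", args.cohort / "atlas_regions.tsv")
export_region_volume(report, atlas, args.out / "region_relevance.nii.gz")

hemi = report.hemisphere
print("hemisphere relevance (posterior of the dispersion parameters):")
for _, row in hemi.iterrows():
    print(f"  {row['hemisphere']:>5}: mean {row['mean']:.4f}, "
          f"94% HPDI [{row['hpdi_lower']:.4f}, {row['hpdi_upper']:.4f}]")
print(f"  dominance (descriptive): {hemi['dominance'].iloc[0]}")

lateralized = report.atoms[report.atoms["lateralized"]]
print(f"lateralized atoms ({len(lateralized)} of {k}, "
      "left-minus-right HPDI excluding zero):")
for _, row in lateralized.iterrows():
    print(f"  {row['atom']}: delta mean {row['delta_mean']:+.3f} "
          f"[{row['delta_hpdi_lower']:+.3f}, {row['delta_hpdi_upper']:+.3f}] "
          f"-> {row['direction']}")

regions = report.regions
top = regions.reindex(regions["mean"].abs().sort_values(ascending=False).index).head(5)
print("strongest region-level relevances (W @ beta back-projection):")
for _, row in top.iterrows():
    print(f"  {row['hemisphere']:>5} {row['region']}: {row['mean']:+.4f}")
print(f"report written to {args.out}")
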