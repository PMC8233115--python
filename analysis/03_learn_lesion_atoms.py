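#!/usr/bin/env python
"""Learn 10 lesion atoms from the lesion matrix and assess the encoding.

Fits the shared-basis NMF on each patient's lesioned-hemisphere 54-region
log-load vector (best of 5 restarts), slots per-patient loadings into
left/right predictor columns, and reports the reconstruction fidelity of
the 108-dimensional region representation and the left/right similarity of
atom-loading correlation patterns. Writes results/atoms/.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from lesionatoms.atoms import (
    atom_correlation_matrix,
    fit_nmf,
    reconstruction_correlation,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--matrix", type=Path,
                    default=Path("results/parcellation/lesion_matrix.csv"))
parser.add_argument("--out", type=Path, default=Path("results/atoms"))
parser.add_argument("--k", type=int, default=10)
args = parser.parse_args()

matrix = pd.read_csv(args.matrix, index_col=0)
basis, loadings, report = fit_nmf(matrix, k=args.k, seed=args.seed, n_restarts=5)
r = reconstruction_correlation(matrix, basis, loadings)
report["reconstruction_r"] = r

corr_left = atom_correlation_matrix(loadings, "left")
corr_right = atom_correlation_matrix(loadings, "right")
off = ~np.eye(args.k, dtype=bool)
hemi_sim = np.corrcoef(
    corr_left.to_numpy()[off], corr_right.to_numpy()[off]
)[0, 1]

args.out.mkdir(parents=True, exist_ok=True)
basis.W.to_csv(args.out / "atom_basis.csv")
loadings.H_slotted.to_csv(args.out / "atom_loadings.csv")
corr_left.to_csv(args.out / "atom_correlations_left.csv")
corr_right.to_csv(args.out / "atom_correlations_right.csv")
(args.out / "nmf_report.json").write_text(json.dumps(report, indent=2))

print(f"NMF k={args.k}: objective {report['objective']:.2f} "
      f"(restart {report['restart_chosen']} of {report['n_restarts']})")
print(f"reconstruction of the 108-dim region representation: r = {r:.3f}")
print(f"left/right atom correlation patterns agree at r = {hemi_sim:.2f}")
print(f"basis and loadings written to {args.out}")
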