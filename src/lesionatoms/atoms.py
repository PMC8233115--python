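"""Non-negative matrix factorization of lesion-load topographies.

Learns k lesion atoms — latent non-negative spatial patterns of co-occurring
regional damage — from the log-transformed lesion matrix, and slots each
patient's atom loadings into left/right predictor columns according to the
patient's lesioned hemisphere.

The default ("pooled") mode fits one shared basis on the 54 homologous-region
space: every patient contributes their lesioned-hemisphere 54-vector to a
single sample pool, which yields homologous left/right atom pairs by
construction. The alternative "concatenated" mode fits the basis on the full
108-dimensional left+right space; both modes slot loadings the same way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr
from sklearn.decomposition import NMF

from .errors import DomainError, InvalidConfigError, UndefinedStatisticError
from .parcellation import HEMISPHERES
from .simulate import atom_column_names, pooled_nonzero_sd

logger = logging.getLogger(__name__)


@dataclass
class AtomBasis:
    """Region x atom matrix W with unit-L2, non-negative columns."""

    W: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.W.to_numpy() < 0).any():
            raise DomainError("atom basis must be non-negative")

    @property
    def n_atoms(self) -> int:
        return self.W.shape[1]

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]


@dataclass
class AtomLoadings:
    """Per-patient slotted atom loadings (left atoms then right atoms).

    ``H_slotted`` holds the raw non-negative loadings; ``scale`` is the
    pooled nonzero-loading standard deviation used to standardize them
    before they enter the outcome model (1.0 when standardization is off).
    """

    H_slotted: pd.DataFrame
    hemispheres: pd.Series = field(repr=False)
    scale: float = 1.0

    @property
    def n_atoms(self) -> int:
        return self.H_slotted.shape[1] // 2

    def standardized(self) -> pd.DataFrame:
        return self.H_slotted / self.scale


def _split_hemispheres(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = matrix.shape[1] // 2
    return matrix[:, :p], matrix[:, p:]


def infer_hemispheres(lesion_matrix: pd.DataFrame) -> pd.Series:
    """Label each row left/right/none from which half carries nonzero load.

    Rows with load in both halves are rejected: bilateral patients are
    excluded upstream by design.
    """
    left, right = _split_hemispheres(lesion_matrix.to_numpy())
    has_l, has_r = left.sum(axis=1) > 0, right.sum(axis=1) > 0
    if (has_l & has_r).any():
        bad = lesion_matrix.index[has_l & has_r][:5].tolist()
        raise DomainError(
            f"bilateral rows in lesion matrix (e.g. {bad}); exclude them first"
        )
    labels = np.where(has_l, "left", np.where(has_r, "right", "none"))
    return pd.Series(labels, index=lesion_matrix.index, name="hemisphere")


def fit_nmf(
    lesion_matrix: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    n_restarts: int = 5,
    mode: str = "pooled",
    standardize_loadings: bool = True,
    max_iter: int = 1000,
) -> tuple[AtomBasis, AtomLoadings, dict]:
    """Learn k lesion atoms and slotted per-patient loadings.

    Minimizes the squared Frobenius reconstruction error by coordinate
    descent; the first restart uses the deterministic nndsvda
    initialization, the remaining restarts seeded random initializations,
    and the best objective wins. Columns of W are L2-normalized (scale
    pushed into H so atom coefficients are comparable across atoms) and
    atoms are ordered by descending W-column L1 mass, ties broken by the
    lowest dominant-region index.
    """
    V = lesion_matrix.to_numpy(dtype=float)
    if (V < 0).any():
        raise DomainError("lesion matrix must be non-negative")
    p = V.shape[1] // 2
    if mode not in ("pooled", "concatenated"):
        raise InvalidConfigError(f"unknown NMF mode {mode!r}")
    if k > (p if mode == "pooled" else 2 * p):
        raise InvalidConfigError("k cannot exceed the number of regions")

    hemispheres = infer_hemispheres(lesion_matrix)
    left_cols = lesion_matrix.columns[:p]
    region_names = [c.split("_", 1)[1] for c in left_cols]

    if mode == "pooled":
        X = np.where(
            (hemispheres == "left").to_numpy()[:, None], V[:, :p], V[:, p:]
        )
        basis_index = region_names
    else:
        X = V
        basis_index = list(lesion_matrix.columns)

    best = None
    objectives = []
    import warnings

    from sklearn.exceptions import ConvergenceWarning

    for restart in range(max(1, n_restarts)):
        init = "nndsvda" if restart == 0 else "random"
        model = NMF(
            n_components=k,
            init=init,
            solver="cd",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=1e-6,
            random_state=seed + restart,
        )
        with warnings.catch_warnings():
            # the iteration cap is tracked via the fit report instead
            warnings.simplefilter("ignore", ConvergenceWarning)
            H_fit = model.fit_transform(X)  # patients x k
        objective = float(model.reconstruction_err_)
        objectives.append(objective)
        if best is None or objective < best["objective"]:
            best = {
                "objective": objective,
                "H": H_fit,
                "W": model.components_.T,  # regions x k
                "iterations": int(model.n_iter_),
                "restart": restart,
            }
    W, H = best["W"], best["H"]

    # push scale into H, unit-L2 columns in W
    norms = np.linalg.norm(W, axis=0)
    keep = norms > 0
    if not keep.all():
        logger.warning("NMF produced %d empty atoms", int((~keep).sum()))
        norms = np.where(keep, norms, 1.0)
    W = W / norms
    H = H * norms

    # deterministic atom ordering: descending L1 mass, ties by dominant region
    mass = W.sum(axis=0)
    dominant = W.argmax(axis=0)
    order = np.lexsort((dominant, -mass))
    W, H = W[:, order], H[:, order]

    basis = AtomBasis(
        W=pd.DataFrame(
            W, index=basis_index, columns=[f"atom{a + 1:02d}" for a in range(k)]
        )
    )

    n = V.shape[0]
    H_slotted = np.zeros((n, 2 * k))
    is_left = (hemispheres == "left").to_numpy()
    is_right = (hemispheres == "right").to_numpy()
    H_slotted[is_left, :k] = H[is_left]
    H_slotted[is_right, k:] = H[is_right]
    loadings = AtomLoadings(
        H_slotted=pd.DataFrame(
            H_slotted, index=lesion_matrix.index, columns=atom_column_names(k)
        ),
        hemispheres=hemispheres,
        scale=pooled_nonzero_sd(H_slotted) if standardize_loadings else 1.0,
    )
    fit_report = {
        "objective": best["objective"],
        "iterations": best["iterations"],
        "restart_chosen": best["restart"],
        "restart_objectives": objectives,
        "iteration_cap_reached": best["iterations"] >= max_iter,
        "n_restarts": max(1, n_restarts),
        "mode": mode,
        "k": k,
        "seed": seed,
    }
    return basis, loadings, fit_report


def _is_concatenated(basis: AtomBasis) -> bool:
    # concatenated bases carry hemisphere-prefixed row names ("L_...", "R_...")
    first = str(basis.W.index[0])
    return first.startswith("L_") or first.startswith("R_")


def reconstruct_lesion_matrix(
    basis: AtomBasis, loadings: AtomLoadings
) -> np.ndarray:
    """Rebuild the patients x 108 matrix from W and the slotted loadings.

    For the pooled basis the off-hemisphere block is reconstructed as 0;
    for a concatenated basis (2 * n_regions rows in W) the full row comes
    from W @ h directly.
    """
    k = loadings.n_atoms
    H = loadings.H_slotted.to_numpy()
    W = basis.W.to_numpy()
    if _is_concatenated(basis):
        h = H[:, :k] + H[:, k:]  # exactly one block is nonzero per patient
        return h @ W.T
    p = W.shape[0]
    out = np.zeros((H.shape[0], 2 * p))
    out[:, :p] = H[:, :k] @ W.T
    out[:, p:] = H[:, k:] @ W.T
    return out


def reconstruction_correlation(
    lesion_matrix: pd.DataFrame, basis: AtomBasis, loadings: AtomLoadings
) -> float:
    """Pearson r between all entries of the lesion matrix and its NMF
    reconstruction (off-hemisphere block reconstructed as 0)."""
    V = lesion_matrix.to_numpy(dtype=float)
    recon = reconstruct_lesion_matrix(basis, loadings)
    if recon.shape != V.shape:
        raise DomainError(
            f"reconstruction shape {recon.shape} does not match input {V.shape}"
        )
    if np.ptp(V) == 0:
        raise UndefinedStatisticError(
            "correlation undefined: lesion matrix is constant"
        )
    r, _ = pearsonr(V.ravel(), recon.ravel())
    return float(r)


def atom_correlation_matrix(loadings: AtomLoadings, hemisphere: str) -> pd.DataFrame:
    """Pearson correlations between atom-loading columns across the patients
    lesioned in ``hemisphere``; constant columns yield NaN rows (logged)."""
    if hemisphere not in ("left", "right"):
        raise InvalidConfigError(f"hemisphere must be 'left' or 'right', got {hemisphere!r}")
    k = loadings.n_atoms
    block = slice(0, k) if hemisphere == "left" else slice(k, 2 * k)
    rows = loadings.hemispheres == hemisphere
    if int(rows.sum()) < 2:
        raise DomainError(
            f"need at least 2 patients with {hemisphere} lesions, have {int(rows.sum())}"
        )
    sub = loadings.H_slotted.loc[rows.to_numpy()].iloc[:, block]
    constant = sub.std(ddof=0) == 0
    if constant.any():
        logger.warning(
            "constant loading columns in %s hemisphere: %s",
            hemisphere,
            list(sub.columns[constant]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub.to_numpy(), rowvar=False)
    corr[constant.to_numpy(), :] = np.nan
    corr[:, constant.to_numpy()] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    atom_names = [c.split("_", 1)[1] for c in sub.columns]
    return pd.DataFrame(corr, index=atom_names, columns=atom_names)


def match_atoms(learned: pd.DataFrame | AtomBasis, true: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Hungarian-match learned atoms to true atoms by column cosine similarity.

    Returns the permutation (index j holds the learned column matched to
    true column j) and the mean matched cosine similarity.
    """
    Wl = (learned.W if isinstance(learned, AtomBasis) else learned).to_numpy()
    Wt = true.to_numpy()
    ln = Wl / np.maximum(np.linalg.norm(Wl, axis=0, keepdims=True), 1e-12)
    tn = Wt / np.maximum(np.linalg.norm(Wt, axis=0, keepdims=True), 1e-12)
    cosine = ln.T @ tn  # learned x true
    row, col = linear_sum_assignment(-cosine)
    perm = np.empty(len(col), dtype=int)
    perm[col] = row
    mean_cos = float(cosine[row, col].mean())
    return perm, mean_cos
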