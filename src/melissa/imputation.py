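"""Posterior-predictive imputation of unobserved CpG states.

Given a variational fit, the probability that a held-out CpG at scaled
position x in region m is methylated is a cluster mixture of probit
predictive probabilities,

    p(y = 1) = sum_k omega_k * Phi( h(x)^T lam_mk / sqrt(1 + h(x)^T S_mk h(x)) ),

where (lam_mk, S_mk) is the Gaussian posterior over the region's profile
weights for cluster k.  For a cell seen during training the mixing weights
omega are that cell's responsibilities r_nk — its cluster assignment was
inferred from its training CpGs, which is what lets clustering inform
imputation.  For a new, unseen cell omega_k = delta_k / sum_j delta_j, the
posterior-mean mixing proportions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .basis import design_matrix
from .melissa_vb import MelissaFit
from .region_data import MethylomeDataset

__all__ = ["NEW_CELL", "predict_cpgs", "impute_dataset", "write_predictions"]

NEW_CELL = "__new__"
_PROB_EPS = 1e-10

PREDICTION_COLUMNS = ["cell", "region", "rel_pos", "prob", "pred_state", "true_state"]


def _cluster_probs(fit: MelissaFit, region_index: int, H: np.ndarray) -> np.ndarray:
    """Per-cluster predictive probabilities, shape (len(H), K)."""
    lam = fit.state.lam[region_index]  # (K, D)
    S = fit.state.S[region_index]  # (K, D, D)
    num = H @ lam.T  # (n, K)
    quad = np.einsum("nd,kde,ne->nk", H, S, H)
    return ndtr(num / np.sqrt(1.0 + quad))


def _mixing_weights(fit: MelissaFit, cell: str) -> np.ndarray:
    if cell == NEW_CELL:
        return fit.state.delta / fit.state.delta.sum()
    try:
        n = fit.cells.index(cell)
    except ValueError:
        raise KeyError(
            f"cell {cell!r} was not in the training set; pass NEW_CELL to "
            "predict for an unseen cell"
        ) from None
    return fit.state.r[n]


def predict_cpgs(
    fit: MelissaFit,
    cell: str,
    region: str,
    positions: np.ndarray,
    true_states: np.ndarray | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Predict methylation probabilities at scaled positions in one region.

    Returns a DataFrame with columns ``cell, region, rel_pos, prob,
    pred_state, true_state``; probabilities are clamped to
    (1e-10, 1 - 1e-10) so downstream metrics stay defined, and states are
    binarised at ``threshold`` (default 0.5).
    """
    if region not in fit.region_ids:
        raise KeyError(f"region {region!r} was not in the training set")
    positions = np.atleast_1d(np.asarray(positions, dtype=float))
    H = design_matrix(positions, fit.basis)
    probs_k = _cluster_probs(fit, fit.region_ids.index(region), H)
    omega = _mixing_weights(fit, cell)
    prob = np.clip(probs_k @ omega, _PROB_EPS, 1.0 - _PROB_EPS)
    return pd.DataFrame(
        {
            "cell": cell,
            "region": region,
            "rel_pos": positions,
            "prob": prob,
            "pred_state": (prob > threshold).astype(np.int8),
            "true_state": (
                np.asarray(true_states, dtype=float)
                if true_states is not None
                else np.nan
            ),
        }
    )


def impute_dataset(
    fit: MelissaFit, test: MethylomeDataset, threshold: float = 0.5
) -> pd.DataFrame:
    """Impute every held-out CpG of ``test``, carrying true states.

    Every observed (cell, region) block of the test set receives exactly
    one prediction per CpG; test regions must be a subset of the fit's
    training regions.
    """
    missing = set(test.region_ids) - set(fit.region_ids)
    covered = {region for (_, region) in test.data}
    if missing & covered:
        raise KeyError(f"test regions not in the fit: {sorted(missing & covered)}")
    cell_index = {c: i for i, c in enumerate(fit.cells)}
    cols: dict[str, list] = {c: [] for c in PREDICTION_COLUMNS}
    # vectorise per region: one design-matrix evaluation covers all cells
    by_region: dict[str, list[tuple[str, np.ndarray, np.ndarray]]] = {}
    for (cell, region), rcd in sorted(test.data.items()):
        if len(rcd):
            by_region.setdefault(region, []).append((cell, rcd.positions, rcd.states))
    for region, blocks in by_region.items():
        j = fit.region_ids.index(region)
        positions = np.concatenate([p for _, p, _ in blocks])
        states = np.concatenate([s for _, _, s in blocks])
        H = design_matrix(positions, fit.basis)
        probs_k = _cluster_probs(fit, j, H)  # (n, K)
        rows = np.concatenate(
            [np.full(len(p), cell_index[cell]) for cell, p, _ in blocks]
        )
        omega = fit.state.r[rows]  # (n, K)
        prob = np.clip(
            np.einsum("nk,nk->n", probs_k, omega), _PROB_EPS, 1.0 - _PROB_EPS
        )
        cols["cell"].extend(
            np.repeat([c for c, _, _ in blocks], [len(p) for _, p, _ in blocks])
        )
        cols["region"].extend([region] * len(positions))
        cols["rel_pos"].append(positions)
        cols["prob"].append(prob)
        cols["pred_state"].append((prob > threshold).astype(np.int8))
        cols["true_state"].append(states.astype(float))
    if not cols["region"]:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    return pd.DataFrame(
        {
            "cell": cols["cell"],
            "region": cols["region"],
            "rel_pos": np.concatenate(cols["rel_pos"]),
            "prob": np.concatenate(cols["prob"]),
            "pred_state": np.concatenate(cols["pred_state"]),
            "true_state": np.concatenate(cols["true_state"]),
        }
    )


def write_predictions(predictions: pd.DataFrame, path) -> None:
    """Export predictions as tab-separated text."""
    predictions.to_csv(path, sep="\t", index=False)
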