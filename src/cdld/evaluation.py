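"""RMSE evaluation, baseline comparison, and latent-recovery scoring.

RMSE is reported on the normalized unit outcome scale and in
mg/dL, where one unit spans 375 mg/dL (the 125-500 band). Latent recovery
scores how well learned provider embeddings align with the simulator's true
provider latents via mean canonical correlation — the appropriate notion
because latent factors are identifiable only up to invertible linear maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelState, predict_phase
from .preprocessing import GLUCOSE_SPAN, SplitIndices

logger = logging.getLogger("cdld.evaluation")

SPLITS = ("train", "valid", "test")


def rmse(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Root mean square error: sqrt(mean((pred - target)^2))."""
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(targets, dtype=float)
    if p.shape != t.shape or p.size == 0:
        raise ValueError(f"need equal-length non-empty arrays, got {p.shape} vs {t.shape}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(t))):
        raise ValueError("predictions and targets must be finite")
    return float(np.sqrt(np.mean((p - t) ** 2)))


@dataclass
class EvalReport:
    """Per-(phase, split) RMSE table for one fitted model."""

    table: pd.DataFrame  # columns: phase, split, n, mse, rmse_unit, rmse_mgdl

    def cell(self, phase: str, split: str, column: str = "rmse_unit") -> float:
        sel = self.table[(self.table["phase"] == phase) & (self.table["split"] == split)]
        if len(sel) != 1:
            raise KeyError(f"no unique report cell for ({phase}, {split})")
        return float(sel[column].iloc[0])


def evaluate_model(
    model: ModelState, table: pd.DataFrame, splits: SplitIndices
) -> EvalReport:
    """RMSE on train/valid/test for every completed phase snapshot.

    Evaluation always uses the un-augmented interaction table.
    """
    if not model.snapshots:
        raise RuntimeError("model has no completed phases to evaluate")
    split_rows = {
        "train": splits.train_rows,
        "valid": splits.valid_rows,
        "test": splits.test_rows,
    }
    for name, rows in split_rows.items():
        if len(rows) == 0:
            raise ValueError(f"missing {name} split")
    records = []
    for phase in model.snapshots:
        for split, rows in split_rows.items():
            sub = table.iloc[rows]
            preds = predict_phase(model, phase, sub)
            err = rmse(preds, sub["target_last_glucose_norm"].to_numpy(dtype=float))
            records.append(
                {
                    "phase": phase,
                    "split": split,
                    "n": len(rows),
                    "mse": err**2,
                    "rmse_unit": err,
                    "rmse_mgdl": GLUCOSE_SPAN * err,
                }
            )
    return EvalReport(table=pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# latent recovery


def canonical_correlations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Canonical correlations between the column spaces of two centred matrices.

    Computed by orthonormalising each centred matrix (SVD, rank-truncated at
    a relative tolerance) and taking the singular values of the cross
    product of the orthonormal bases. Values are clipped into [0, 1].
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("need the same number of rows (entities) in both matrices")

    def orthobasis(M: np.ndarray) -> np.ndarray:
        Mc = M - M.mean(axis=0)
        U, s, _ = np.linalg.svd(Mc, full_matrices=False)
        keep = s > s[0] * 1e-10 if s.size and s[0] > 0 else np.zeros_like(s, dtype=bool)
        return U[:, keep]

    Qx, Qy = orthobasis(X), orthobasis(Y)
    if Qx.shape[1] == 0 or Qy.shape[1] == 0:
        return np.zeros(0)
    s = np.linalg.svd(Qx.T @ Qy, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def latent_recovery(learned: np.ndarray, true_latents: np.ndarray) -> float:
    """Mean canonical correlation between learned and true latent matrices.

    Averaged over ``min(rank(learned), d_true)`` canonical directions, so the
    score lies in [0, 1] with 1 meaning the true latent space is linearly
    recoverable from the learned embeddings.
    """
    true_latents = np.asarray(true_latents, dtype=float)
    n, d_true = true_latents.shape
    if n < d_true or n < np.asarray(learned).shape[1]:
        logger.warning(
            "fewer entities (%d) than latent dimensions: reduced-rank canonical analysis", n
        )
    cors = canonical_correlations(learned, true_latents)
    k = min(d_true, len(cors)) if len(cors) else 0
    if k == 0:
        return 0.0
    padded = np.zeros(d_true)
    padded[:k] = cors[:k]
    return float(padded.mean())


def permutation_null(
    learned: np.ndarray,
    true_latents: np.ndarray,
    n_permutations: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the recovery score under row shuffling."""
    rng = np.random.default_rng(seed)
    learned = np.asarray(learned, dtype=float)
    out = np.empty(n_permutations)
    for b in range(n_permutations):
        out[b] = latent_recovery(learned[rng.permutation(len(learned))], true_latents)
    return out


# ---------------------------------------------------------------------------
# model comparison


def compare_models(cdld_report: EvalReport, baseline_report: EvalReport) -> pd.DataFrame:
    """Per-split RMSE deltas between the final CDLD phase and the baseline.

    ``delta`` is baseline minus CDLD (positive favours CDLD);
    ``relative_improvement`` is ``1 - rmse_cdld / rmse_baseline``.
    """
    cdld_final = cdld_report.table[cdld_report.table["phase"] == "synthesis"]
    base_final = baseline_report.table[
        baseline_report.table["phase"] == baseline_report.table["phase"].iloc[-1]
    ]
    if set(cdld_final["split"]) != set(base_final["split"]):
        raise ValueError("reports cover different splits")
    c = cdld_final.set_index("split")
    b = base_final.set_index("split")
    if not (c["n"].sort_index() == b["n"].sort_index()).all():
        raise ValueError("reports computed on different split sizes")
    rows = []
    for split in SPLITS:
        rc, rb = float(c.loc[split, "rmse_unit"]), float(b.loc[split, "rmse_unit"])
        rows.append(
            {
                "split": split,
                "rmse_cdld": rc,
                "rmse_baseline": rb,
                "delta": rb - rc,
                "relative_improvement": 1.0 - rc / rb if rb > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def evaluate_baseline(baseline, table: pd.DataFrame, splits: SplitIndices) -> EvalReport:
    """RMSE report for a patient-only model, phase-labelled ``patient_only``."""
    split_rows = {
        "train": splits.train_rows,
        "valid": splits.valid_rows,
        "test": splits.test_rows,
    }
    records = []
    for split, rows in split_rows.items():
        sub = table.iloc[rows]
        err = rmse(baseline.predict(sub), sub["target_last_glucose_norm"].to_numpy(dtype=float))
        records.append(
            {
                "phase": "patient_only",
                "split": split,
                "n": len(rows),
                "mse": err**2,
                "rmse_unit": err,
                "rmse_mgdl": GLUCOSE_SPAN * err,
            }
        )
    return EvalReport(table=pd.DataFrame.from_records(records))
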