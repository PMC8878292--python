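"""Internal and external validation: RMSE, R², through-origin regression
statistics, the Golbraikh-Tropsha acceptability multicriterion and
label-stratified 10-fold cross-validation with pooled RMSECV / Q².

A QSAR model is considered acceptable when all five conditions hold:

    Q² > 0.5,   R² > 0.6,   (R² − R0²)/R² < 0.1,
    0.9 ≤ k ≤ 1.1,   |R0² − R0′²| < 0.3,

where R0² / R0′² are the coefficients of determination of the trendline
through the origin with predicted values on the X-axis (resp. observed on
the X-axis), and k the through-origin slope of observed on predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone

from .chem import bulk_tanimoto, canonicalize_desalt, ecfp4
from .curation import stratified_kfold

logger = logging.getLogger(__name__)

__all__ = [
    "rmse",
    "r_squared",
    "through_origin_stats",
    "golbraikh_tropsha",
    "CriteriaVerdict",
    "cross_validate",
    "CrossValResult",
    "external_validation",
]


def rmse(pred, obs) -> float:
    """Root of the mean squared residual, in pIC50 units."""
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def r_squared(pred, obs) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (observed mean)."""
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape or pred.size < 2:
        raise ValueError("need >= 2 paired values")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    return float(1.0 - np.sum((pred - obs) ** 2) / ss_tot)


def through_origin_stats(x, y) -> tuple[float, float]:
    """Through-origin trendline of y on x: slope k = Σxy/Σx² and
    r0² = 1 − Σ(y − kx)²/Σ(y − ȳ)²."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    sxx = np.sum(x * x)
    if sxx <= 0:
        raise ValueError("degenerate x: sum of squares is zero")
    k = float(np.sum(x * y) / sxx)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("y has zero variance; r0^2 undefined")
    r0sq = float(1.0 - np.sum((y - k * x) ** 2) / ss_tot)
    return r0sq, k


@dataclass(frozen=True)
class CriteriaVerdict:
    q2_pass: bool
    r2_pass: bool
    rel_r0_pass: bool
    k_pass: bool
    r0_diff_pass: bool

    @property
    def overall(self) -> bool:
        return (self.q2_pass and self.r2_pass and self.rel_r0_pass
                and self.k_pass and self.r0_diff_pass)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["overall"] = self.overall
        return d


def golbraikh_tropsha(
    q2: float,
    r2: float,
    r0sq_pred_x: float,
    r0sq_obs_x: float,
    k_slope: float,
) -> CriteriaVerdict:
    """Evaluate the five acceptability conditions.

    ``r0sq_pred_x`` is R0² with predictions on the X-axis (the orientation
    used in the (R² − R0²)/R² condition); ``r0sq_obs_x`` is the opposite
    orientation; ``k_slope`` the through-origin slope of observed on
    predicted.
    """
    return CriteriaVerdict(
        q2_pass=q2 > 0.5,
        r2_pass=r2 > 0.6,
        rel_r0_pass=(r2 != 0) and ((r2 - r0sq_pred_x) / r2 < 0.1),
        k_pass=0.9 <= k_slope <= 1.1,
        r0_diff_pass=abs(r0sq_pred_x - r0sq_obs_x) < 0.3,
    )


def external_metrics(pred, obs) -> dict:
    """All external-validation statistics for one target."""
    r0sq_pred_x, k = through_origin_stats(pred, obs)
    r0sq_obs_x, _ = through_origin_stats(obs, pred)
    r2 = r_squared(pred, obs)
    return {
        "rmsep": rmse(pred, obs),
        "r2": r2,
        "r0sq_pred_x": r0sq_pred_x,
        "r0sq_obs_x": r0sq_obs_x,
        "k_slope": k,
        "rel_r0": (r2 - r0sq_pred_x) / r2 if r2 != 0 else np.nan,
        "r0_diff": abs(r0sq_pred_x - r0sq_obs_x),
        "n": int(np.asarray(pred).size),
    }


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CrossValResult:
    per_target: pd.DataFrame        # rmsecv, q2, n per target
    residuals: pd.DataFrame         # smiles, fold, target, y, yhat, sq_err, nn_similarity


def cross_validate(
    estimator,
    smiles: Sequence[str],
    Y: np.ndarray,
    task_labels: Sequence[str],
    targets: Sequence[str],
    k: int = 10,
    seed: int = 0,
) -> CrossValResult:
    """Label-stratified k-fold cross-validation with pooled RMSECV and Q².

    Each fold trains a fresh clone of ``estimator`` on the in-fold data and
    predicts the holdout.  Out-of-fold squared residuals and the holdout
    compounds' nearest-neighbor ECFP4 Tanimoto similarity to that fold's
    training compounds are retained for applicability-domain calibration.
    """
    Y = np.asarray(Y, dtype=np.float64)
    folds = stratified_kfold(task_labels, k=k, seed=seed)
    keys = np.stack([ecfp4(canonicalize_desalt(s)) for s in smiles])
    rows = []
    for f, (tr, ho) in enumerate(folds):
        if ho.size == 0:
            continue
        est = clone(estimator)
        est.set_params(seed=seed + f)
        try:
            est.fit([smiles[i] for i in tr], Y[tr])
        except Exception as exc:
            raise RuntimeError(f"training failed in fold {f}") from exc
        pred = est.predict([smiles[i] for i in ho])
        train_keys = keys[tr]
        for row_pos, i in enumerate(ho):
            sims = bulk_tanimoto(keys[i], train_keys)
            nn_sim = float(sims.max()) if sims.size else 0.0
            for t_idx, t in enumerate(targets):
                if np.isnan(Y[i, t_idx]):
                    continue
                err = pred[row_pos, t_idx] - Y[i, t_idx]
                rows.append({
                    "smiles": smiles[i], "fold": f, "target": t,
                    "y": Y[i, t_idx], "yhat": pred[row_pos, t_idx],
                    "sq_err": err * err, "nn_similarity": nn_sim,
                })
    residuals = pd.DataFrame(rows)
    per_target = []
    for t in targets:
        sub = residuals[residuals["target"] == t]
        if len(sub) < 2:
            per_target.append({"target": t, "rmsecv": np.nan, "q2": np.nan,
                               "n": len(sub)})
            continue
        per_target.append({
            "target": t,
            "rmsecv": rmse(sub["yhat"], sub["y"]),
            "q2": r_squared(sub["yhat"], sub["y"]),
            "n": len(sub),
        })
    return CrossValResult(
        per_target=pd.DataFrame(per_target).set_index("target"),
        residuals=residuals,
    )


def external_validation(
    estimator, smiles: Sequence[str], Y: np.ndarray,
    targets: Sequence[str], q2: dict | None = None,
) -> pd.DataFrame:
    """Evaluate a fitted estimator on an external test set, per target.

    If per-target Q² values from cross-validation are supplied, the
    Golbraikh-Tropsha verdict is included.
    """
    Y = np.asarray(Y, dtype=np.float64)
    pred = estimator.predict(smiles)
    rows = []
    for t_idx, t in enumerate(targets):
        m = ~np.isnan(Y[:, t_idx]) & ~np.isnan(pred[:, t_idx])
        if m.sum() < 3:
            rows.append({"target": t, "n": int(m.sum())})
            continue
        stats = external_metrics(pred[m, t_idx], Y[m, t_idx])
        if q2 is not None and t in q2 and np.isfinite(q2[t]):
            verdict = golbraikh_tropsha(
                q2[t], stats["r2"], stats["r0sq_pred_x"],
                stats["r0sq_obs_x"], stats["k_slope"],
            )
            stats["q2"] = q2[t]
            stats.update({f"gt_{k}": v for k, v in verdict.as_dict().items()})
        stats["target"] = t
        rows.append(stats)
    return pd.DataFrame(rows).set_index("target")
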