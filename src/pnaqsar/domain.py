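"""Two-stage applicability domain on ECFP4 Tanimoto similarity.

Stage 1 (global): a query compound must have a nearest-neighbor Tanimoto
similarity to the all-target training compounds at or above a global
threshold.  The threshold is calibrated from cross-validation: per fold,
keep the holdout compounds whose squared error is within the third quartile
of that fold's squared-error distribution, z-score their similarities, and
take the minimum similarity among compounds with |z| within the critical
value at 95% confidence; the calibrated threshold is the mean over folds.

Stage 2 (per target): the training compounds labeled for the target with
Tanimoto >= 0.35 to the query are its target neighbors; their mean squared
cross-validation residual measures how well the model performs in the
query's neighborhood.  The prediction is reliable when that neighborhood
error is below a per-target cutoff of 10% of the target's training pIC50
range (compared on the root scale by default; the literal squared-scale
comparison is available via ``squared_scale=True``).

A compound is "inside" the domain for a target iff both stages pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import bulk_tanimoto, canonicalize_desalt, ecfp4

logger = logging.getLogger(__name__)

__all__ = [
    "ADParams",
    "ADVerdict",
    "nearest_neighbor_similarity",
    "optimize_global_threshold",
    "target_cutoffs",
    "target_reliability",
    "assign_ad",
    "fit_applicability_domain",
]

NEIGHBOR_SIMILARITY = 0.35
CONFIDENCE_Z = 1.96
CUTOFF_RANGE_FRACTION = 0.10


@dataclass
class ADParams:
    """Calibrated applicability-domain parameters, stored in the checkpoint."""

    global_threshold: float
    per_target_cutoff: dict[str, float]           # squared-pIC50 units
    per_target_range: dict[str, float]            # pIC50 units
    neighbor_similarity: float = NEIGHBOR_SIMILARITY
    confidence_z: float = CONFIDENCE_Z
    squared_scale: bool = False


@dataclass
class ADVerdict:
    flags: dict[str, str]                          # target -> "inside"/"outside"
    nearest_similarity: float
    neighbor_count: dict[str, int]
    neighbor_msr: dict[str, float]


def nearest_neighbor_similarity(
    query_key: np.ndarray, train_keys: np.ndarray
) -> tuple[float, int]:
    """Maximum Tanimoto of the query over the training keys, with argmax index
    (lowest index on ties)."""
    if len(train_keys) == 0:
        raise ValueError("empty training key set")
    sims = bulk_tanimoto(query_key, train_keys)
    idx = int(np.argmax(sims))
    return float(sims[idx]), idx


def optimize_global_threshold(
    cv_residuals: pd.DataFrame,
    confidence_z: float = CONFIDENCE_Z,
    q3_band: bool = False,
) -> float:
    """Calibrate the global similarity threshold from CV residuals.

    ``cv_residuals`` needs columns ``fold``, ``sq_err`` and ``nn_similarity``
    (one row per compound; multi-target rows are first collapsed to one row
    per (fold, smiles) by mean squared error).  ``q3_band=False`` keeps the
    best-predicted 75% (squared error <= Q3); ``q3_band=True`` keeps only
    the strict Q2..Q3 band.
    """
    df = cv_residuals
    if "smiles" in df.columns:
        df = (df.groupby(["fold", "smiles"], sort=False)
                .agg(sq_err=("sq_err", "mean"),
                     nn_similarity=("nn_similarity", "first"))
                .reset_index())
    thresholds = []
    for fold, sub in df.groupby("fold"):
        if len(sub) < 4:
            logger.warning("fold %s has %d compounds; skipped", fold, len(sub))
            continue
        q3 = np.percentile(sub["sq_err"], 75, method="linear")
        if q3_band:
            q2 = np.percentile(sub["sq_err"], 50, method="linear")
            kept = sub[(sub["sq_err"] >= q2) & (sub["sq_err"] <= q3)]
        else:
            kept = sub[sub["sq_err"] <= q3]
        sims = kept["nn_similarity"].to_numpy(dtype=np.float64)
        mu, sd = sims.mean(), sims.std()
        z = np.zeros_like(sims) if sd == 0 else (sims - mu) / sd
        within = sims[np.abs(z) <= confidence_z]
        if within.size == 0:
            logger.warning("fold %s: no compound within the z-window; skipped", fold)
            continue
        thresholds.append(float(within.min()))
    if not thresholds:
        raise ValueError("no fold produced a similarity threshold")
    return float(np.mean(thresholds))


def target_cutoffs(
    train_activities: pd.DataFrame, targets: Sequence[str],
    fraction: float = CUTOFF_RANGE_FRACTION,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-target cutoff: (fraction x training pIC50 range)², plus the ranges."""
    cutoffs, ranges = {}, {}
    for t in targets:
        vals = train_activities[t].dropna()
        rng = float(vals.max() - vals.min()) if len(vals) else 0.0
        ranges[t] = rng
        cutoffs[t] = (fraction * rng) ** 2
    return cutoffs, ranges


def target_reliability(
    query_key: np.ndarray,
    target: str,
    train_keys: np.ndarray,
    train_sq_residuals: np.ndarray,
    params: ADParams,
) -> tuple[int, float, bool]:
    """Neighborhood reliability check for one (query, target).

    ``train_keys``/``train_sq_residuals`` are restricted to training
    compounds labeled with the target and their CV squared residuals on it.
    Returns (neighbor_count, neighbor mean squared residual, pass).  Zero
    neighbors fail: no evidence of reliability.
    """
    if len(train_keys) == 0:
        return 0, np.nan, False
    sims = bulk_tanimoto(query_key, train_keys)
    nb = sims >= params.neighbor_similarity
    count = int(nb.sum())
    if count == 0:
        return 0, np.nan, False
    msr = float(np.mean(train_sq_residuals[nb]))
    cutoff = params.per_target_cutoff[target]
    if params.squared_scale:
        ok = msr < cutoff
    else:
        ok = np.sqrt(msr) < np.sqrt(cutoff)  # root-scale comparison (default)
    return count, msr, bool(ok)


def assign_ad(
    query_keys: np.ndarray,
    train_keys: np.ndarray,
    per_target_train: Mapping[str, tuple[np.ndarray, np.ndarray]],
    params: ADParams,
) -> list[ADVerdict]:
    """Full two-stage verdict per query compound.

    ``per_target_train`` maps target -> (keys, cv squared residuals) for the
    training compounds carrying that target's label.
    """
    verdicts = []
    for qk in np.atleast_2d(query_keys):
        nn_sim, _ = nearest_neighbor_similarity(qk, train_keys)
        flags, counts, msrs = {}, {}, {}
        for t, (keys_t, res_t) in per_target_train.items():
            count, msr, ok = target_reliability(qk, t, keys_t, res_t, params)
            inside = (nn_sim >= params.global_threshold) and ok
            flags[t] = "inside" if inside else "outside"
            counts[t] = count
            msrs[t] = msr
        verdicts.append(ADVerdict(
            flags=flags, nearest_similarity=nn_sim,
            neighbor_count=counts, neighbor_msr=msrs,
        ))
    return verdicts


@dataclass
class FittedAD:
    params: ADParams
    train_keys: np.ndarray
    per_target_train: dict[str, tuple[np.ndarray, np.ndarray]]

    def verdicts(self, smiles: Sequence[str]) -> list[ADVerdict]:
        keys = np.stack([ecfp4(canonicalize_desalt(s)) for s in smiles])
        return assign_ad(keys, self.train_keys, self.per_target_train, self.params)

    def frame(self, smiles: Sequence[str]) -> pd.DataFrame:
        rows = []
        for s, v in zip(smiles, self.verdicts(smiles)):
            row = {"smiles": s, "nearest_similarity": v.nearest_similarity}
            row.update({f"AD_{t}": f for t, f in v.flags.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def fit_applicability_domain(
    train_smiles: Sequence[str],
    train_activities: pd.DataFrame,
    cv_residuals: pd.DataFrame,
    targets: Sequence[str],
    neighbor_similarity: float = NEIGHBOR_SIMILARITY,
    confidence_z: float = CONFIDENCE_Z,
    squared_scale: bool = False,
) -> FittedAD:
    """Calibrate both AD stages from the training set and its CV residuals.

    ``train_activities`` is the wide per-target pIC50 table aligned with
    ``train_smiles``; ``cv_residuals`` the residual table from
    :func:`pnaqsar.validation.cross_validate` on the same pool.
    """
    threshold = optimize_global_threshold(cv_residuals, confidence_z)
    cutoffs, ranges = target_cutoffs(train_activities, targets)
    params = ADParams(
        global_threshold=threshold,
        per_target_cutoff=cutoffs,
        per_target_range=ranges,
        neighbor_similarity=neighbor_similarity,
        confidence_z=confidence_z,
        squared_scale=squared_scale,
    )
    keys = np.stack([ecfp4(canonicalize_desalt(s)) for s in train_smiles])
    res_by_smiles = cv_residuals.set_index(["smiles", "target"])["sq_err"]
    per_target: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for t in targets:
        rows, res = [], []
        for i, s in enumerate(train_smiles):
            if pd.isna(train_activities.iloc[i][t]):
                continue
            try:
                r = res_by_smiles.loc[(s, t)]
            except KeyError:
                continue
            rows.append(i)
            res.append(float(np.mean(r)))  # mean if a compound recurs
        per_target[t] = (keys[rows], np.asarray(res, dtype=np.float64))
    return FittedAD(params=params, train_keys=keys, per_target_train=per_target)
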