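"""Synthetic benchmark studies: learning sanity, multitask transfer, AD behavior.

Each study generates a controlled synthetic library, runs the full package
path (curation, featurization, training, cross-validation, applicability
domain) and measures the headline quantities.  Problem sizes default to
desk scale (a few hundred compounds, one small network per seed) so a full
study completes in minutes on one CPU; the designs are documented in the
methods note.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import curation
from .domain import fit_applicability_domain
from .model import PNAMultitaskRegressor
from .synthetic import (
    ALIEN_ARMS_A,
    ALIEN_ARMS_B,
    SCAFFOLDS,
    SyntheticSpec,
    generate_library,
)
from .validation import cross_validate, r_squared, rmse

logger = logging.getLogger(__name__)

__all__ = ["learning_sanity_study", "transfer_study", "ad_study"]

_TT = ("T1", "T2")


def _records_to_table(records: pd.DataFrame, targets) -> pd.DataFrame:
    """Collapse raw records to the wide compound table via the curation path."""
    kept, _ = curation.normalize_records(records, targets=targets)
    kept, _ = curation.canonicalize_records(kept)
    per_source = [curation.dedupe_within_source(s) for _, s in kept.groupby("source")]
    table = curation.merge_sources(per_source, targets=targets)
    return curation.assign_task_labels(table, targets=targets)


def _masked_rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    m = ~np.isnan(obs) & ~np.isnan(pred)
    return rmse(pred[m], obs[m])


def _fit_eval(est, table, targets, seed):
    """Split externally, fit, and measure model vs mean-baseline RMSE and R^2."""
    table = curation.stratified_split(table, seed=seed)
    ext = table[table["split"] == "external_test"]
    tr = table[table["split"] == "train"]
    val = table[table["split"] == "validation"]
    cols = list(targets)
    est.fit(tr["smiles"].tolist(), tr[cols].to_numpy(),
            X_val=val["smiles"].tolist(), y_val=val[cols].to_numpy())
    pred = est.predict(ext["smiles"].tolist())
    obs = ext[cols].to_numpy()
    train_means = np.nanmean(tr[cols].to_numpy(), axis=0)
    baseline = np.broadcast_to(train_means, obs.shape)
    r2s = []
    for ti in range(len(targets)):
        m = ~np.isnan(obs[:, ti])
        if m.sum() >= 3:
            r2s.append(r_squared(pred[m, ti], obs[m, ti]))
    return {
        "model_rmse": _masked_rmse(pred, obs),
        "baseline_rmse": _masked_rmse(np.asarray(baseline), obs),
        "mean_external_r2": float(np.mean(r2s)) if r2s else np.nan,
    }


def learning_sanity_study(
    n_seeds: int = 20,
    n_r2_seeds: int = 10,
    n_compounds: int = 500,
    noise_sd: float = 0.3,
    base_seed: int = 0,
    max_epochs: int = 100,
) -> dict:
    """Trained model vs mean-predictor baseline on a 2-task synthetic library.

    Per seed: generate the library, curate, split (10% external), train the
    multitask model and compare its external RMSE with the per-target
    training-mean baseline.  The mean per-target external R^2 is recorded
    for the first ``n_r2_seeds`` seeds.
    """
    wins = 0
    r2_values: list[float] = []
    per_seed = []
    for s in range(n_seeds):
        seed = base_seed + s
        spec = SyntheticSpec(n_compounds=n_compounds, targets=_TT,
                             noise_sd=noise_sd, seed=seed)
        records, _ = generate_library(spec)
        table = _records_to_table(records, _TT)
        est = PNAMultitaskRegressor(targets=_TT, seed=seed, max_epochs=max_epochs)
        out = _fit_eval(est, table, _TT, seed=seed)
        win = out["model_rmse"] < out["baseline_rmse"]
        wins += int(win)
        if s < n_r2_seeds:
            r2_values.append(out["mean_external_r2"])
        per_seed.append({**out, "seed": seed, "win": bool(win)})
        logger.info("learning sanity seed %d: %s", seed, out)
    return {
        "n_seeds": n_seeds,
        "baseline_wins": wins,
        "external_r2": r2_values,
        "n_r2_above_0.6": int(sum(r > 0.6 for r in r2_values)),
        "median_external_r2": float(np.median(r2_values)),
        "median_model_rmse": float(np.median([p["model_rmse"] for p in per_seed])),
        "per_seed": per_seed,
    }


def transfer_study(
    n_seeds: int = 10,
    n_compounds: int = 470,
    small_labels: int = 40,
    noise_sd: float = 0.3,
    base_seed: int = 0,
    max_epochs: int = 100,
) -> dict:
    """Multitask vs single-task RMSE on a data-poor task.

    A small task (~``small_labels`` labeled compounds) shares structural
    truth with a data-rich task.  Per seed, a quarter of the small task's
    compounds are held out entirely; the multitask model trains on
    everything else (both tasks), the single-task model only on the small
    task's remaining labels.  Both are scored on the held-out small-task
    compounds; the study compares median RMSE over seeds.
    """
    mt_rmse, st_rmse = [], []
    for s in range(n_seeds):
        seed = base_seed + s
        coverage = {"T1": 0.9, "T2": small_labels / n_compounds}
        spec = SyntheticSpec(n_compounds=n_compounds, targets=_TT,
                             coverage=coverage, noise_sd=noise_sd,
                             design_correlation=0.9, seed=seed)
        records, _ = generate_library(spec)
        table = _records_to_table(records, _TT)
        rng = np.random.default_rng(seed)
        small_idx = table.index[table["T2"].notna()].to_numpy()
        rng.shuffle(small_idx)
        n_test = max(3, len(small_idx) // 4)
        test_idx = small_idx[:n_test]
        train_tab = table.drop(index=test_idx)
        test_tab = table.loc[test_idx]
        obs = test_tab["T2"].to_numpy()

        mt = PNAMultitaskRegressor(targets=_TT, seed=seed, max_epochs=max_epochs)
        mt.fit(train_tab["smiles"].tolist(), train_tab[list(_TT)].to_numpy())
        pred_mt = mt.predict(test_tab["smiles"].tolist())[:, 1]
        mt_rmse.append(rmse(pred_mt, obs))

        st_tab = train_tab[train_tab["T2"].notna()]
        st = PNAMultitaskRegressor(targets=("T2",), seed=seed,
                                   max_epochs=max_epochs,
                                   validation_fraction=0.15)
        st.fit(st_tab["smiles"].tolist(), st_tab[["T2"]].to_numpy())
        pred_st = st.predict(test_tab["smiles"].tolist())[:, 0]
        st_rmse.append(rmse(pred_st, obs))
        logger.info("transfer seed %d: multitask %.3f single %.3f",
                    seed, mt_rmse[-1], st_rmse[-1])
    return {
        "n_seeds": n_seeds,
        "multitask_rmse": mt_rmse,
        "singletask_rmse": st_rmse,
        "median_multitask_rmse": float(np.median(mt_rmse)),
        "median_singletask_rmse": float(np.median(st_rmse)),
    }


def ad_study(
    n_seeds: int = 10,
    n_train_pool: int = 320,
    n_alien: int = 60,
    noise_sd: float = 0.3,
    k_folds: int = 3,
    base_seed: int = 0,
    max_epochs: int = 80,
) -> dict:
    """Inside- vs outside-domain external RMSE with a structurally alien subset.

    The training pool is generated from one part of the scaffold grammar;
    the alien external compounds come from scaffolds the model never sees.
    Per seed: fit the model and its applicability domain (global threshold
    from k-fold CV residuals, per-target neighborhood reliability), predict
    the combined external set and pool RMSE by verdict.
    """
    inside_rmse, outside_rmse, thresholds = [], [], []
    wins = 0
    for s in range(n_seeds):
        seed = base_seed + s
        pool_spec = SyntheticSpec(n_compounds=n_train_pool, targets=_TT,
                                  noise_sd=noise_sd, seed=seed,
                                  scaffolds=SCAFFOLDS[:14])
        alien_spec = SyntheticSpec(n_compounds=n_alien, targets=_TT,
                                   noise_sd=noise_sd, seed=seed + 5000,
                                   scaffolds=SCAFFOLDS[14:],
                                   arms_a=ALIEN_ARMS_A, arms_b=ALIEN_ARMS_B)
        pool = _records_to_table(generate_library(pool_spec)[0], _TT)
        alien = _records_to_table(generate_library(alien_spec)[0], _TT)
        pool = curation.stratified_split(pool, seed=seed)
        ext_in = pool[pool["split"] == "external_test"]
        trainval = pool[pool["split"] != "external_test"].reset_index(drop=True)

        est = PNAMultitaskRegressor(targets=_TT, seed=seed, max_epochs=max_epochs)
        est.fit(trainval["smiles"].tolist(), trainval[list(_TT)].to_numpy())
        cv = cross_validate(
            PNAMultitaskRegressor(targets=_TT, seed=seed, max_epochs=max_epochs),
            trainval["smiles"].tolist(), trainval[list(_TT)].to_numpy(),
            trainval["task_label"].tolist(), _TT, k=k_folds, seed=seed,
        )
        ad = fit_applicability_domain(
            trainval["smiles"].tolist(), trainval[list(_TT)], cv.residuals, _TT
        )
        thresholds.append(ad.params.global_threshold)

        ext = pd.concat([ext_in, alien], ignore_index=True)
        pred = est.predict(ext["smiles"].tolist())
        verdicts = ad.verdicts(ext["smiles"].tolist())
        err_in, err_out = [], []
        for i, v in enumerate(verdicts):
            for ti, t in enumerate(_TT):
                obs = ext.iloc[i][t]
                if pd.isna(obs):
                    continue
                e2 = (pred[i, ti] - obs) ** 2
                (err_in if v.flags[t] == "inside" else err_out).append(e2)
        r_in = float(np.sqrt(np.mean(err_in))) if err_in else np.nan
        r_out = float(np.sqrt(np.mean(err_out))) if err_out else np.nan
        inside_rmse.append(r_in)
        outside_rmse.append(r_out)
        win = np.isfinite(r_in) and np.isfinite(r_out) and r_in <= r_out
        wins += int(win)
        logger.info("AD seed %d: inside %.3f (n=%d) outside %.3f (n=%d)",
                    seed, r_in, len(err_in), r_out, len(err_out))
    return {
        "n_seeds": n_seeds,
        "inside_rmse": inside_rmse,
        "outside_rmse": outside_rmse,
        "wins": wins,
        "median_inside_rmse": float(np.nanmedian(inside_rmse)),
        "median_outside_rmse": float(np.nanmedian(outside_rmse)),
        "mean_global_threshold": float(np.mean(thresholds)),
    }
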