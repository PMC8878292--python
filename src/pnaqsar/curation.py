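"""Curation of raw activity records into a cliff-filtered, split, task-labeled dataset.

The pipeline mirrors standard practice for assembling kinase bioactivity
sets from public-database exports:

1. unit conversion to pIC50 = -log10(IC50 [M]), rejecting non-positive IC50;
2. SMILES canonicalization and desalting, rejecting unparsable input;
3. optional assay-text filtering (regex, e.g. restrict to biochemical assays);
4. within-source deduplication: exact (assay, value) duplicates collapsed,
   conflicting values resolved by keeping the lowest IC50 (highest pIC50);
5. per-target IQR outlier removal on provided physchem properties
   (bounds Q1 - 3*IQR, Q3 + 3*IQR, linear-interpolation quartiles);
6. cross-source merge keyed by canonical SMILES, keeping the higher pIC50
   per (compound, target);
7. task labeling: a multitarget compound is labeled with its rarest target;
8. stratified external-test / validation / train split;
9. activity-cliff generator removal on the train-validation pool only.

Records travel as pandas DataFrames.  The curated compound table is wide:
one row per compound, one pIC50 column per target (NaN = unmeasured), plus
``task_label`` and ``split`` columns.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import bulk_tanimoto, canonicalize_desalt, ecfp4
from .model import RTK_TARGETS

logger = logging.getLogger(__name__)

__all__ = [
    "to_pic50",
    "load_activity_csv",
    "normalize_records",
    "canonicalize_records",
    "filter_assays",
    "dedupe_within_source",
    "iqr_outlier_filter",
    "merge_sources",
    "remove_activity_cliff_generators",
    "assign_task_labels",
    "stratified_split",
    "stratified_kfold",
    "curate",
    "is_active",
]

PROPERTY_COLUMNS = ("mw", "logp", "ro5_violations")


def to_pic50(ic50_molar):
    """pIC50 = -log10(IC50 in molar units). Raises on non-positive input."""
    arr = np.asarray(ic50_molar, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive to convert to pIC50")
    out = -np.log10(arr)
    return float(out) if np.isscalar(ic50_molar) else out


def is_active(pic50) -> np.ndarray:
    """Reporting convention: active iff pIC50 > 7."""
    return np.asarray(pic50) > 7


# ---------------------------------------------------------------------------
# record-level steps
# ---------------------------------------------------------------------------

def load_activity_csv(path, targets: Sequence[str] = RTK_TARGETS) -> pd.DataFrame:
    df = pd.read_csv(path)
    return normalize_records(df, targets=targets)[0]


def normalize_records(
    df: pd.DataFrame, targets: Sequence[str] = RTK_TARGETS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate schema, convert activity to pIC50; return (kept, rejected).

    Requires ``smiles``, ``target`` and exactly one activity column among
    ``pic50``, ``ic50_M``, ``ic50_nM`` per row.  Rejected rows carry a
    ``reject_reason`` code.
    """
    df = df.copy()
    for col in ("smiles", "target"):
        if col not in df.columns:
            raise ValueError(f"input is missing required column {col!r}")
    activity_cols = [c for c in ("pic50", "ic50_M", "ic50_nM") if c in df.columns]
    if not activity_cols:
        raise ValueError("input needs one of: pic50, ic50_M, ic50_nM")
    for col in ("source", "assay"):
        if col not in df.columns:
            df[col] = "" if col == "assay" else "A"
    reasons = pd.Series("", index=df.index)

    bad_target = ~df["target"].isin(list(targets))
    reasons[bad_target] = "unknown_target"

    pic50 = pd.Series(np.nan, index=df.index)
    if "pic50" in df.columns:
        pic50 = pd.to_numeric(df["pic50"], errors="coerce")
    for col, scale in (("ic50_M", 1.0), ("ic50_nM", 1e-9)):
        if col in df.columns:
            ic50 = pd.to_numeric(df[col], errors="coerce") * scale
            nonpos = ic50 <= 0
            reasons[nonpos & (reasons == "")] = "nonpositive_ic50"
            fill = pic50.isna() & ic50.notna() & ~nonpos
            pic50[fill] = -np.log10(ic50[fill])
    missing = pic50.isna() & (reasons == "")
    reasons[missing] = "missing_activity"
    df["pic50"] = pic50

    rejected = df[reasons != ""].assign(reject_reason=reasons[reasons != ""])
    kept = df[reasons == ""].copy()
    return kept, rejected


def canonicalize_records(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Desalt and canonicalize SMILES; unparsable rows are rejected, not raised."""
    cache: dict[str, str | None] = {}
    canon = []
    for s in df["smiles"]:
        if s not in cache:
            m = canonicalize_desalt(str(s))
            cache[s] = m.smiles if m.parse_ok else None
        canon.append(cache[s])
    df = df.assign(canonical_smiles=canon)
    bad = df["canonical_smiles"].isna()
    if bad.any():
        logger.info("dropping %d unparsable SMILES", int(bad.sum()))
    rejected = df[bad].assign(reject_reason="unparsable_smiles")
    return df[~bad].copy(), rejected


def filter_assays(df: pd.DataFrame, pattern: str | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep rows whose assay text matches ``pattern`` (None keeps everything)."""
    if not pattern:
        return df, df.iloc[0:0].assign(reject_reason=pd.Series(dtype=str))
    keep = df["assay"].astype(str).str.contains(pattern, flags=re.IGNORECASE, regex=True)
    return df[keep].copy(), df[~keep].assign(reject_reason="assay_filtered")


def dedupe_within_source(df: pd.DataFrame) -> pd.DataFrame:
    """One record per (canonical SMILES, target) within one source.

    Exact (assay, pIC50) duplicates collapse; conflicting values keep the
    lowest IC50, i.e. the highest pIC50.
    """
    df = df.drop_duplicates(subset=["canonical_smiles", "target", "assay", "pic50"])
    idx = df.groupby(["canonical_smiles", "target"], sort=False)["pic50"].idxmax()
    return df.loc[idx.sort_values()].copy()


def _quartiles(values: np.ndarray) -> tuple[float, float]:
    # linear interpolation between order statistics (Tukey-style)
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    return float(q1), float(q3)


def iqr_outlier_filter(
    df: pd.DataFrame,
    property_names: Sequence[str] = PROPERTY_COLUMNS,
    k: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records whose properties fall outside [Q1 - k*IQR, Q3 + k*IQR].

    Bounds are computed per target dataset.  A record is removed iff ANY
    listed property is out of bounds; missing properties pass with a warning.
    """
    if not property_names:
        return df, df.iloc[0:0].assign(reject_reason=pd.Series(dtype=str))
    out_mask = pd.Series(False, index=df.index)
    for target, sub in df.groupby("target"):
        for prop in property_names:
            if prop not in sub.columns:
                logger.warning("property %r absent; records pass unfiltered", prop)
                continue
            vals = pd.to_numeric(sub[prop], errors="coerce")
            known = vals.notna()
            if known.sum() == 0:
                continue
            q1, q3 = _quartiles(vals[known].to_numpy())
            iqr = q3 - q1
            lo, hi = q1 - k * iqr, q3 + k * iqr
            out = known & ((vals < lo) | (vals > hi))
            out_mask.loc[out[out].index] = True
    removed = df[out_mask].assign(reject_reason="property_outlier")
    return df[~out_mask].copy(), removed


# ---------------------------------------------------------------------------
# compound table
# ---------------------------------------------------------------------------

def merge_sources(
    per_source: Sequence[pd.DataFrame], targets: Sequence[str] = RTK_TARGETS
) -> pd.DataFrame:
    """Merge deduped per-source records into the wide compound table.

    Keyed by canonical SMILES; per (compound, target) the maximum pIC50
    across sources is kept.
    """
    stacked = pd.concat(per_source, ignore_index=True)
    best = (
        stacked.groupby(["canonical_smiles", "target"], sort=False)["pic50"]
        .max()
        .reset_index()
    )
    wide = best.pivot(index="canonical_smiles", columns="target", values="pic50")
    for t in targets:
        if t not in wide.columns:
            wide[t] = np.nan
    wide = wide[list(targets)]
    wide.index.name = "smiles"
    return wide.reset_index()


def assign_task_labels(
    compounds: pd.DataFrame,
    targets: Sequence[str] = RTK_TARGETS,
    target_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Label each compound with its reported target that has the fewest
    compounds globally; ties break by target order."""
    compounds = compounds.copy()
    if target_counts is None:
        target_counts = {t: int(compounds[t].notna().sum()) for t in targets}
    order = {t: i for i, t in enumerate(targets)}
    labels = []
    for _, row in compounds.iterrows():
        reported = [t for t in targets if pd.notna(row[t])]
        if not reported:
            labels.append(None)
            continue
        labels.append(min(reported, key=lambda t: (target_counts[t], order[t])))
    compounds["task_label"] = labels
    return compounds.dropna(subset=["task_label"]).reset_index(drop=True)


def stratified_split(
    compounds: pd.DataFrame,
    external_fraction: float = 0.10,
    validation_fraction: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train / validation / external_test per task label.

    Per label, ~``external_fraction`` goes to the external test set first,
    then ``validation_fraction`` of the remainder to validation.  Labels with
    fewer than 3 compounds all go to train.  Deterministic under the seed.
    """
    if not (0 < external_fraction < 1 and 0 < validation_fraction < 1):
        raise ValueError("fractions must be in (0, 1)")
    rng = np.random.default_rng(seed)
    split = pd.Series("train", index=compounds.index)
    for label, sub in compounds.groupby("task_label"):
        n = len(sub)
        if n < 3:
            logger.warning("label %s has %d compounds; all assigned to train", label, n)
            continue
        idx = sub.index.to_numpy()[rng.permutation(n)]
        n_ext = int(round(external_fraction * n))
        n_val = int(round(validation_fraction * (n - n_ext)))
        split[idx[:n_ext]] = "external_test"
        split[idx[n_ext:n_ext + n_val]] = "validation"
    out = compounds.copy()
    out["split"] = split
    return out


def stratified_kfold(
    labels: Sequence, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Label-stratified k-fold partition; returns (train_idx, holdout_idx) pairs.

    Implemented as per-label seeded round-robin so labels with fewer than k
    members degrade gracefully (they simply miss some folds) instead of
    raising.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = pd.Series(list(labels))
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(labels), dtype=np.int64)
    for label, sub in labels.groupby(labels):
        idx = sub.index.to_numpy()[rng.permutation(len(sub))]
        if len(idx) < k:
            logger.warning("label %r has %d < k=%d members", label, len(idx), k)
        fold_of[idx] = np.arange(len(idx)) % k
    folds = []
    all_idx = np.arange(len(labels))
    for f in range(k):
        hold = all_idx[fold_of == f]
        folds.append((all_idx[fold_of != f], hold))
    return folds


# ---------------------------------------------------------------------------
# activity cliffs
# ---------------------------------------------------------------------------

def remove_activity_cliff_generators(
    compounds: pd.DataFrame,
    target: str,
    sim_threshold: float = 0.9,
    delta_threshold: float = 1.0,
    keys: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iteratively remove activity-cliff generators for one target.

    An AC pair is two compounds with ECFP4 Tanimoto >= ``sim_threshold`` and
    |delta pIC50| >= ``delta_threshold`` on the target.  A generator is a
    compound in at least one pair whose mean activity-similarity difference,
    mean over its pairs of |delta pIC50| - (1 - T), exceeds 0.  Generators
    lose their activity on the target (set to NaN); the procedure repeats
    until no pair remains.  Returns (compounds, removal_log).
    """
    compounds = compounds.copy().reset_index(drop=True)
    labeled = compounds[target].notna()
    if labeled.sum() < 2:
        return compounds, pd.DataFrame(columns=["smiles", "target", "mean_asd"])
    if keys is None:
        keys = np.stack([
            ecfp4(canonicalize_desalt(s)) for s in compounds["smiles"]
        ])
    removed_rows = []
    alive = labeled.to_numpy().copy()
    while True:
        idx = np.flatnonzero(alive)
        if len(idx) < 2:
            break
        sub_keys = keys[idx]
        acts = compounds.loc[idx, target].to_numpy()
        # pairwise Tanimoto via bit-matrix products
        inter = sub_keys.astype(np.float64) @ sub_keys.T.astype(np.float64)
        pops = sub_keys.sum(axis=1)
        union = pops[:, None] + pops[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / union, 0.0)
        delta = np.abs(acts[:, None] - acts[None, :])
        pair = (sim >= sim_threshold) & (delta >= delta_threshold)
        np.fill_diagonal(pair, False)
        if not pair.any():
            break
        asd = np.where(pair, delta - (1.0 - sim), 0.0)
        n_pairs = pair.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean_asd = np.where(n_pairs > 0, asd.sum(axis=1) / np.maximum(n_pairs, 1), -np.inf)
        generators = np.flatnonzero((n_pairs > 0) & (mean_asd > 0))
        if generators.size == 0:
            # pairs remain but no generator qualifies: remove the worst pair
            # member to guarantee termination is NOT done; the landscape is
            # accepted as-is
            break
        for g in generators:
            removed_rows.append({
                "smiles": compounds.loc[idx[g], "smiles"],
                "target": target,
                "mean_asd": float(mean_asd[g]),
            })
            alive[idx[g]] = False
    dropped = labeled.to_numpy() & ~alive
    compounds.loc[dropped, target] = np.nan
    log = pd.DataFrame(removed_rows, columns=["smiles", "target", "mean_asd"])
    return compounds, log


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class CurationResult:
    compounds: pd.DataFrame
    report: dict
    cliff_log: pd.DataFrame


def curate(
    raw: pd.DataFrame,
    targets: Sequence[str] = RTK_TARGETS,
    assay_pattern: str | None = None,
    iqr_properties: Sequence[str] = PROPERTY_COLUMNS,
    iqr_sources: Sequence[str] | None = None,
    cliff_sim_threshold: float = 0.9,
    cliff_delta_threshold: float = 1.0,
    external_fraction: float = 0.10,
    validation_fraction: float = 0.10,
    seed: int = 0,
) -> CurationResult:
    """Run the full curation pipeline on raw activity records.

    ``iqr_sources`` restricts the property-outlier filter to the named
    sources (None = every source that carries the property columns).
    """
    report: dict = {"input_records": int(len(raw))}
    kept, rej_norm = normalize_records(raw, targets=targets)
    kept, rej_parse = canonicalize_records(kept)
    kept, rej_assay = filter_assays(kept, assay_pattern)
    report["rejected"] = {
        "normalize": rej_norm["reject_reason"].value_counts().to_dict(),
        "unparsable_smiles": int(len(rej_parse)),
        "assay_filtered": int(len(rej_assay)),
    }

    per_source, n_outliers = [], 0
    for source, sub in kept.groupby("source"):
        sub = dedupe_within_source(sub)
        if iqr_sources is None or source in iqr_sources:
            props = [p for p in iqr_properties if p in sub.columns]
            if props:
                sub, removed = iqr_outlier_filter(sub, props)
                n_outliers += len(removed)
        per_source.append(sub)
    report["rejected"]["property_outlier"] = int(n_outliers)
    report["records_after_dedupe"] = int(sum(len(s) for s in per_source))
    entering = (report["input_records"]
                - sum(report["rejected"]["normalize"].values())
                - report["rejected"]["unparsable_smiles"]
                - report["rejected"]["assay_filtered"])
    report["dedupe_removed"] = int(entering - n_outliers
                                   - report["records_after_dedupe"])

    compounds = merge_sources(per_source, targets=targets)
    report["unique_compounds"] = int(len(compounds))

    compounds = assign_task_labels(compounds, targets=targets)
    compounds = stratified_split(
        compounds, external_fraction, validation_fraction, seed=seed
    )

    # activity-cliff removal strictly on the train-validation pool
    pool = compounds["split"] != "external_test"
    trainval = compounds[pool].reset_index(drop=True)
    keys = np.stack([ecfp4(canonicalize_desalt(s)) for s in trainval["smiles"]]) \
        if len(trainval) else None
    logs = []
    for t in targets:
        trainval, log = remove_activity_cliff_generators(
            trainval, t, cliff_sim_threshold, cliff_delta_threshold, keys=keys
        )
        logs.append(log)
    logs = [l for l in logs if len(l)]
    cliff_log = pd.concat(logs, ignore_index=True) if logs else \
        pd.DataFrame(columns=["smiles", "target", "mean_asd"])
    report["cliff_removals"] = int(len(cliff_log))

    # stitch the pool back, drop compounds that lost every label,
    # refresh task labels for compounds whose label target was cleared
    external = compounds[~pool]
    trainval = trainval[trainval[list(targets)].notna().any(axis=1)]
    stale = trainval.apply(lambda r: pd.isna(r[r["task_label"]]), axis=1) \
        if len(trainval) else pd.Series(dtype=bool)
    if len(trainval) and stale.any():
        counts = {t: int(compounds[t].notna().sum()) for t in targets}
        relabeled = assign_task_labels(
            trainval[stale].drop(columns=["task_label"]), targets, counts
        )
        trainval = pd.concat([trainval[~stale], relabeled], ignore_index=False)
    compounds = pd.concat([trainval, external], ignore_index=True)

    report["final_compounds"] = int(len(compounds))
    report["per_target_counts"] = {
        t: int(compounds[t].notna().sum()) for t in targets
    }
    report["per_target_actives"] = {
        t: int(is_active(compounds[t].dropna()).sum()) for t in targets
    }
    report["split_counts"] = compounds["split"].value_counts().to_dict()
    return CurationResult(compounds=compounds, report=report, cliff_log=cliff_log)
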