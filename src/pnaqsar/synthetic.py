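"""Deterministic synthetic molecular libraries with known structure-activity truth.

Molecules are assembled from a fixed grammar of kinase-inhibitor-like
heteroaromatic scaffolds and substituent arms, so the fingerprint families
are informative by construction.  True activity is additive in the
structural parts (or linear in physchem descriptors), shared across targets
through a tunable mixing weight, so multitask transfer is present in the
truth.  Observed labels add Gaussian noise; requested fractions of salts,
exact and conflicting duplicates, and engineered activity cliffs are
injected on top.  The emitted record table uses the same CSV schema the
curation module reads, so fixtures are indistinguishable from real exports.

Nothing here aims for medicinal-chemistry plausibility; the point is a
controlled truth against which every pipeline stage is testable offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .chem import canonicalize_desalt, ecfp4, tanimoto

logger = logging.getLogger(__name__)

__all__ = ["SyntheticSpec", "SyntheticTruth", "generate_library",
           "corrupt_for_curation_tests", "SCAFFOLDS", "ARMS_A", "ARMS_B"]

#: heteroaromatic cores; substituents attach at the first and last aromatic
#: CH carbons
SCAFFOLDS: tuple[str, ...] = (
    "c1ccc2ncncc2c1",        # quinazoline-like
    "c1ccc2ncccc2c1",        # quinoline
    "c1ccc2[nH]ccc2c1",      # indole
    "c1ccc2[nH]cnc2c1",      # benzimidazole
    "c1ccc2scnc2c1",         # benzothiazole
    "c1ccc2occc2c1",         # benzofuran
    "c1ccc2[nH]ncc2c1",      # indazole
    "c1cncnc1",              # pyrimidine
    "c1ccncc1",              # pyridine
    "c1cnccn1",              # pyrazine
    "c1ccc(-c2ccncc2)cc1",   # phenylpyridine
    "c1ccc2ccccc2c1",        # naphthalene
    "c1ccc2ncnc(N)c2c1",     # 4-aminoquinazoline
    "c1cc2cncnc2[nH]1",      # pyrrolopyrimidine
    "c1cc2cccnc2[nH]1",      # azaindole
    "c1ccc2nccnc2c1",        # quinoxaline
    "c1ccc2cnccc2c1",        # isoquinoline
    "c1cnc2[nH]ccc2c1",      # another azaindole
)

ARMS_A: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CO", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F",
)

ARMS_B: tuple[str, ...] = (
    "c1ccccc1", "c1ccc(F)cc1", "c1ccc(Cl)cc1", "c1ccc(C)cc1", "c1ccc(OC)cc1",
    "N1CCOCC1", "N1CCNCC1", "N1CCCC1", "OCc1ccccc1", "Nc1ccccc1",
    "S(C)(=O)=O", "C(=O)N",
)

#: deliberately dissimilar grammar (aliphatic/exotic decorations) for building
#: structurally alien query sets in applicability-domain studies
ALIEN_ARMS_A: tuple[str, ...] = (
    "CCCCCC", "C1CCCCC1", "OCCOC", "SCC", "CC(C)(C)C", "OC(F)F",
    "CCCO", "C1CCOC1", "SC", "CCN(CC)CC",
)
ALIEN_ARMS_B: tuple[str, ...] = (
    "C1CCCCC1", "N1CCC(C)CC1", "C1CCNC1", "OCC(C)C", "CC1CCCO1",
    "CCCCN", "C(=S)N", "S(=O)CC",
)

#: symmetric 1,3,5-trisubstituted benzene with three para-substituted phenyl
#: arms, for engineered activity cliffs: swapping arm b from X to Y while a
#: Y-arm is already present elsewhere leaves the circular-fingerprint bit set
#: essentially unchanged (pair similarity verified at generation time)
_CLIFF_CORE = "c1c(-c2ccc({a})cc2)cc(-c2ccc({b})cc2)cc1-c2ccc({c})cc2"
_CLIFF_SUBS = ("F", "Cl", "Br", "C", "CC", "OC", "N", "C(F)(F)F", "C#N")


def _attachment_sites(core: Chem.Mol) -> list[int]:
    sites = [a.GetIdx() for a in core.GetAtoms()
             if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() > 0]
    return [sites[0], sites[-1]]


def assemble(scaffold: str, arm_a: str | None, arm_b: str | None) -> str | None:
    """Attach up to two arms to a scaffold; returns canonical SMILES or None."""
    core = Chem.MolFromSmiles(scaffold)
    sites = _attachment_sites(core)
    combo = core
    for site, arm in zip(sites, (arm_a, arm_b)):
        if arm is None:
            continue
        frag = Chem.MolFromSmiles(arm)
        if frag is None:
            return None
        offset = combo.GetNumAtoms()
        emol = Chem.RWMol(Chem.CombineMols(combo, frag))
        emol.AddBond(site, offset, Chem.BondType.SINGLE)
        combo = emol.GetMol()
        try:
            Chem.SanitizeMol(combo)
        except Exception:
            return None
    return Chem.MolToSmiles(combo)


# ---------------------------------------------------------------------------
# spec and truth
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Conditions of a synthetic study.

    ``coverage`` maps target -> probability that a compound carries that
    target's label; ``design_correlation`` is the intended cross-target
    Pearson correlation of the truth; ``noise_sd`` the Gaussian observation
    noise in pIC50 units.
    """

    n_compounds: int = 500
    targets: Sequence[str] = ("T1", "T2")
    coverage: dict | None = None                  # default: 0.8 everywhere
    activity_model: str = "substructure_additive" # or "descriptor_linear"
    noise_sd: float = 0.3
    design_correlation: float = 0.8
    cliff_fraction: float = 0.0
    salt_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0
    scaffolds: Sequence[str] = SCAFFOLDS
    arms_a: Sequence[str] = ARMS_A
    arms_b: Sequence[str] = ARMS_B
    pic50_range: tuple[float, float] = (4.0, 10.0)

    def __post_init__(self):
        for name in ("cliff_fraction", "salt_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 0.5:
                raise ValueError(f"{name} must be in [0, 0.5], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.activity_model not in ("substructure_additive", "descriptor_linear"):
            raise ValueError(f"unknown activity model {self.activity_model!r}")
        if self.coverage is None:
            self.coverage = {t: 0.8 for t in self.targets}


@dataclass
class SyntheticTruth:
    """True per-target activity of every generated compound plus the
    generating coefficients; regenerating with the same spec reproduces it."""

    table: pd.DataFrame            # smiles + true_<target> columns
    coefficients: dict


def _mixed_coefs(rng: np.random.Generator, n_items: int, n_targets: int,
                 rho: float, scale: float) -> np.ndarray:
    """(n_items, n_targets) coefficients with cross-target correlation ~= rho."""
    shared = rng.normal(0.0, 1.0, size=(n_items, 1))
    indep = rng.normal(0.0, 1.0, size=(n_items, n_targets))
    return scale * (np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep)


_DESCRIPTOR_FNS = (
    lambda m: Descriptors.MolWt(m) / 100.0,
    lambda m: Crippen.MolLogP(m),
    lambda m: rdMolDescriptors.CalcTPSA(m) / 50.0,
    lambda m: float(rdMolDescriptors.CalcNumRings(m)),
    lambda m: float(rdMolDescriptors.CalcNumHBD(m)),
    lambda m: float(rdMolDescriptors.CalcNumRotatableBonds(m)),
)


def _truth_for(spec: SyntheticSpec, rng: np.random.Generator,
               parts: list[tuple[int, int, int]], smiles: list[str]) -> tuple[np.ndarray, dict]:
    T = len(spec.targets)
    rho = spec.design_correlation
    base = 6.5 + rng.normal(0.0, 0.3, size=T)
    if spec.activity_model == "substructure_additive":
        c_sc = _mixed_coefs(rng, len(spec.scaffolds), T, rho, 0.9)
        c_a = _mixed_coefs(rng, len(spec.arms_a), T, rho, 0.6)
        c_b = _mixed_coefs(rng, len(spec.arms_b), T, rho, 0.6)
        truth = np.stack([
            base + c_sc[s] + c_a[a] + c_b[b] for s, a, b in parts
        ])
        coefs = {"base": base, "scaffold": c_sc, "arm_a": c_a, "arm_b": c_b}
    else:
        w = _mixed_coefs(rng, len(_DESCRIPTOR_FNS), T, rho, 1.0)
        desc = np.array([[fn(Chem.MolFromSmiles(s)) for fn in _DESCRIPTOR_FNS]
                         for s in smiles])
        mu, sd = desc.mean(axis=0), desc.std(axis=0) + 1e-9
        z = (desc - mu) / sd
        raw = z @ w
        raw = raw / (raw.std(axis=0) + 1e-9) * 1.2
        truth = base + raw
        coefs = {"base": base, "weights": w, "descriptor_mean": mu,
                 "descriptor_sd": sd}
    lo, hi = spec.pic50_range
    return np.clip(truth, lo, hi), coefs


def _cliff_pairs(spec: SyntheticSpec, rng: np.random.Generator,
                 n_pairs: int) -> list[tuple[str, str]]:
    """Engineered cliff pairs: same symmetric core, one halogen-arm swap,
    fingerprint-verified Tanimoto >= 0.9."""
    pairs = []
    combos = [(x, y) for x in _CLIFF_SUBS for y in _CLIFF_SUBS if x != y]
    rng.shuffle(combos)
    for x, y in combos:
        if len(pairs) >= n_pairs:
            break
        a = _CLIFF_CORE.format(a=x, b=x, c=y)
        b = _CLIFF_CORE.format(a=x, b=y, c=y)
        ma, mb = canonicalize_desalt(a), canonicalize_desalt(b)
        if not (ma.parse_ok and mb.parse_ok) or ma.smiles == mb.smiles:
            continue
        if tanimoto(ecfp4(ma), ecfp4(mb)) < 0.9:
            continue
        pairs.append((ma.smiles, mb.smiles))
    return pairs


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------

def generate_library(spec: SyntheticSpec) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate activity records plus the underlying truth table.

    Returns ``(records, truth)``: records carry smiles (with injected
    salts/duplicates), target, activity (pic50 or ic50_nM), source, assay
    and physchem property columns; the truth table holds the noiseless
    per-target activities of each unique base compound.
    """
    rng = np.random.default_rng(spec.seed)
    targets = list(spec.targets)
    T = len(targets)

    n_cliff_pairs = int(round(spec.cliff_fraction * spec.n_compounds))
    n_regular = spec.n_compounds - 2 * n_cliff_pairs
    if n_regular < 1:
        raise ValueError("cliff_fraction too large for n_compounds")

    # enumerate regular compounds from the grammar
    seen: set[str] = set()
    parts: list[tuple[int, int, int]] = []
    smiles: list[str] = []
    attempts = 0
    while len(smiles) < n_regular:
        attempts += 1
        if attempts > 50 * spec.n_compounds:
            raise ValueError("grammar exhausted before reaching n_compounds")
        s = int(rng.integers(len(spec.scaffolds)))
        a = int(rng.integers(len(spec.arms_a)))
        b = int(rng.integers(len(spec.arms_b)))
        smi = assemble(spec.scaffolds[s], spec.arms_a[a], spec.arms_b[b])
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        parts.append((s, a, b))
        smiles.append(smi)

    truth, coefs = _truth_for(spec, rng, parts, smiles)

    # engineered cliffs: partner activity displaced by >= 2 pIC50 units;
    # draw from a candidate surplus so collisions with the regular set
    # never shrink the requested pair count
    if n_cliff_pairs:
        appended = 0
        for base_smi, part_smi in _cliff_pairs(spec, rng, n_cliff_pairs + 8):
            if appended >= n_cliff_pairs:
                break
            if base_smi in seen or part_smi in seen:
                continue
            lo, hi = spec.pic50_range
            t_base = np.clip(6.5 + rng.normal(0, 0.5, size=T), lo, hi - 2.5)
            t_part = t_base + (2.0 + rng.uniform(0.3, 0.5))
            smiles.extend([base_smi, part_smi])
            seen.update([base_smi, part_smi])
            truth = np.vstack([truth, t_base[None, :], t_part[None, :]])
            appended += 1
        if appended < n_cliff_pairs:
            raise ValueError(
                f"cliff grammar exhausted: requested {n_cliff_pairs} pairs, "
                f"built {appended}"
            )

    n = len(smiles)
    truth_table = pd.DataFrame({"smiles": smiles})
    for ti, t in enumerate(targets):
        truth_table[f"true_{t}"] = truth[:, ti]

    # label coverage: every compound keeps at least one label
    labeled = np.zeros((n, T), dtype=bool)
    for ti, t in enumerate(targets):
        labeled[:, ti] = rng.random(n) < spec.coverage[t]
    none = ~labeled.any(axis=1)
    labeled[none, rng.integers(0, T, size=int(none.sum()))] = True

    observed = truth + rng.normal(0.0, spec.noise_sd, size=truth.shape)

    rows = []
    for i, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        mw = Descriptors.MolWt(mol)
        logp = Crippen.MolLogP(mol)
        ro5 = int(Descriptors.NumHDonors(mol) > 5) + int(mw > 500) + \
            int(logp > 5) + int(Descriptors.NumHAcceptors(mol) > 10)
        rec_smi = smi
        if rng.random() < spec.salt_fraction:
            rec_smi = smi + rng.choice([".Cl", ".[Na+].[Cl-]", ".OS(=O)(=O)O"])
        for ti, t in enumerate(targets):
            if not labeled[i, ti]:
                continue
            row = {
                "smiles": rec_smi,
                "target": t,
                "source": "A" if rng.random() < 0.6 else "B",
                "assay": "biochemical single-protein IC50",
                "mw": round(mw, 2),
                "logp": round(logp, 3),
                "ro5_violations": ro5,
            }
            val = float(observed[i, ti])
            if i % 7 == 3:  # exercise unit conversion on a deterministic subset
                row["ic50_nM"] = 10 ** (9 - val)
                row["pic50"] = np.nan
            else:
                row["pic50"] = val
            rows.append(row)
    records = pd.DataFrame(rows)
    if "ic50_nM" not in records.columns:
        records["ic50_nM"] = np.nan

    # duplicates: half exact, half conflicting (weaker reported value)
    n_dup = int(round(spec.duplicate_fraction * len(records)))
    if n_dup:
        dup_idx = rng.choice(len(records), size=n_dup, replace=False)
        dups = records.iloc[dup_idx].copy()
        half = n_dup // 2
        conflict = dups.iloc[half:].copy()
        # weaker reported value (higher IC50): dropped again on dedupe
        eff = conflict["pic50"].fillna(9.0 - np.log10(conflict["ic50_nM"]))
        conflict["pic50"] = eff - 0.5
        conflict["ic50_nM"] = np.nan
        records = pd.concat([records, dups.iloc[:half], conflict],
                            ignore_index=True)

    return records, SyntheticTruth(table=truth_table, coefficients=coefs)


# ---------------------------------------------------------------------------
# corruption for curation tests
# ---------------------------------------------------------------------------

def corrupt_for_curation_tests(
    records: pd.DataFrame,
    n_bad_smiles: int = 3,
    n_nonpositive: int = 3,
    n_property_outliers: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject known faults; returns (corrupted records, tamper log).

    Faults are appended as new rows so the clean base set is untouched; the
    tamper log records each injected row's index and fault kind.
    """
    rng = np.random.default_rng(seed)
    records = records.copy().reset_index(drop=True)
    template = records.iloc[0].copy()
    tampered = []
    new_rows = []

    def push(row, kind):
        new_rows.append(row)
        tampered.append({"index": len(records) + len(new_rows) - 1, "kind": kind})

    for i in range(n_bad_smiles):
        row = template.copy()
        row["smiles"] = f"C1CC{'C' * i}"  # unclosed ring: unparsable
        push(row, "unparsable_smiles")
    for i in range(n_nonpositive):
        row = template.copy()
        row["pic50"] = np.nan
        row["ic50_nM"] = -float(i + 1)
        push(row, "nonpositive_ic50")
    for i in range(n_property_outliers):
        row = records.iloc[int(rng.integers(len(records)))].copy()
        # absurd alkane; distinct length per fault so dedupe cannot merge them
        row["smiles"] = "CC(C)(C)" * (30 + i) + "C"
        row["mw"] = 50000.0 + 1000 * i
        row["logp"] = 80.0 + i
        push(row, "property_outlier")

    corrupted = pd.concat([records, pd.DataFrame(new_rows)], ignore_index=True)
    return corrupted, pd.DataFrame(tampered)
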