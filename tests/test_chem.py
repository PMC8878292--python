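import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from pnaqsar.chem import (
    DEFAULT_FAMILIES,
    FeatureReducer,
    canonicalize_desalt,
    ecfp4,
    family_lengths,
    fingerprint_block,
    fit_feature_reducer,
    smiles_to_graph,
    tanimoto,
)


class TestCanonicalizeDesalt:
    @pytest.mark.parametrize("smiles,expected", [
        ("CCO", "CCO"),
        ("CCO.[Na+].[Cl-]", "CCO"),          # largest covalent fragment kept
        ("OCC", "CCO"),                       # canonicalization collapses forms
    ])
    def test_desalting_and_canonical_form(self, smiles, expected):
        mol = canonicalize_desalt(smiles)
        assert mol.parse_ok and mol.smiles == expected

    @pytest.mark.parametrize("bad", ["C1CC", "not_a_smiles", "", "  "])
    def test_unparsable_never_raises(self, bad):
        assert not canonicalize_desalt(bad).parse_ok

    def test_idempotent(self, small_library):
        _, _, truth = small_library
        for s in truth.table["smiles"].head(25):
            once = canonicalize_desalt(s)
            twice = canonicalize_desalt(once.smiles)
            assert twice.smiles == once.smiles

    def test_desalt_matches_reference_fragment_chooser(self):
        from rdkit.Chem.MolStandardize import rdMolStandardize

        # cases where the largest fragment is unambiguous under both the
        # heavy-atom and the all-atom counting conventions
        for s in ["c1ccccc1.[K+].[Br-]", "CCO.O.O", "CCCCCCN.Cl"]:
            ours = canonicalize_desalt(s).smiles
            ref = Chem.MolToSmiles(
                rdMolStandardize.LargestFragmentChooser().choose(Chem.MolFromSmiles(s))
            )
            assert ours == ref


class TestFingerprintBlock:
    def test_deterministic_and_aromatic_form_collapses(self):
        a = fingerprint_block(canonicalize_desalt("c1ccccc1"))
        b = fingerprint_block(canonicalize_desalt("C1=CC=CC=C1"))
        assert np.array_equal(a.bits, b.bits)

    def test_block_length_is_sum_of_family_lengths(self):
        fams = ("maccs", "ecfp4", "torsion")
        block = fingerprint_block(canonicalize_desalt("CCN"), fams)
        assert block.bits.shape[0] == sum(family_lengths(fams).values())
        starts = [block.family_offsets[f] for f in fams]
        assert starts[0] == (0, 167)

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError, match="unknown fingerprint family"):
            fingerprint_block(canonicalize_desalt("CC"), ["nope"])

    def test_default_roster_has_sixteen_families(self):
        assert len(DEFAULT_FAMILIES) == 16


class TestFeatureReducer:
    def test_collinear_points_need_one_component(self):
        # 3 points on a line in 10-D: the covariance is rank 1, so a single
        # component explains all variance (checked by hand eigen-decomposition:
        # the only nonzero eigenvalue carries 100% of the trace)
        from pnaqsar.chem import FeatureBlock

        direction = np.random.default_rng(0).normal(size=10)
        blocks = [FeatureBlock(bits=t * direction,
                               family_offsets={"synthetic": (0, 10)})
                  for t in (0.0, 1.0, 2.0)]
        red = fit_feature_reducer(blocks, 0.95)
        assert red.n_components_ == 1
        assert red.explained_variance_ == pytest.approx(1.0)

    def test_minimality_of_component_count(self, small_library):
        _, _, truth = small_library
        blocks = [fingerprint_block(canonicalize_desalt(s))
                  for s in truth.table["smiles"].head(30)]
        red = fit_feature_reducer(blocks, 0.95)
        ratios = red._pca.explained_variance_ratio_
        assert ratios.sum() >= 0.95
        assert ratios[:-1].sum() < 0.95  # one fewer would fall short

    def test_training_mean_projects_to_zero(self):
        blocks = [fingerprint_block(canonicalize_desalt(s))
                  for s in ("CCO", "CCN", "CCC", "CCS")]
        red = fit_feature_reducer(blocks, 1.0)
        X = np.stack([b.bits for b in blocks]).astype(float)
        z = red._pca.transform(X.mean(axis=0, keepdims=True))
        assert np.allclose(z, 0.0, atol=1e-9)

    def test_constant_input_rejected(self):
        blocks = [fingerprint_block(canonicalize_desalt("CC"))
                  for _ in range(3)]
        with pytest.raises(ValueError, match="constant"):
            fit_feature_reducer(blocks, 0.95)


class TestMolGraph:
    @pytest.mark.parametrize("smiles,n,m,degs", [
        ("C", 1, 0, [0]),
        ("CC", 2, 2, [1, 1]),
        ("c1ccccc1", 6, 12, [2] * 6),
    ])
    def test_reference_graphs(self, smiles, n, m, degs):
        g = smiles_to_graph(canonicalize_desalt(smiles))
        assert g.n_nodes == n and g.n_edges == m
        assert list(g.degrees) == degs
        assert g.node_features.shape == (n, 30)
        assert g.edge_features.shape == (m, 75)

    def test_degrees_match_edge_list(self, fixture_graphs):
        for g in fixture_graphs:
            g.validate()  # raises if degree vector disagrees with adjacency

    def test_every_bond_gives_both_directions(self, fixture_graphs):
        for g in fixture_graphs:
            fwd = set(map(tuple, g.edges))
            assert all((i, j) in fwd for j, i in fwd)


class TestEcfp4Tanimoto:
    def test_deterministic_and_discriminative(self):
        a1 = ecfp4(canonicalize_desalt("CCO"))
        a2 = ecfp4(canonicalize_desalt("CCO"))
        b = ecfp4(canonicalize_desalt("CCN"))
        assert np.array_equal(a1, a2)
        assert np.any(a1 != b)

    def test_matches_rdkit_reference_similarity(self, small_library):
        _, _, truth = small_library
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        smiles = truth.table["smiles"].head(10).tolist()
        for i in range(0, len(smiles) - 1, 2):
            ours = tanimoto(ecfp4(canonicalize_desalt(smiles[i])),
                            ecfp4(canonicalize_desalt(smiles[i + 1])))
            ref = DataStructs.TanimotoSimilarity(
                gen.GetFingerprint(Chem.MolFromSmiles(smiles[i])),
                gen.GetFingerprint(Chem.MolFromSmiles(smiles[i + 1])),
            )
            assert ours == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("a,b,expected", [
        ([1, 1, 0, 0], [1, 0, 1, 0], 1 / 3),
        ([1, 0, 1], [1, 0, 1], 1.0),
        ([1, 1, 0, 0], [0, 0, 1, 1], 0.0),
    ])
    def test_hand_values(self, a, b, expected):
        assert tanimoto(np.array(a, bool), np.array(b, bool)) == pytest.approx(expected)

    def test_all_zero_keys_warn_and_return_zero(self):
        z = np.zeros(8, dtype=bool)
        with pytest.warns(UserWarning, match="all-zero"):
            assert tanimoto(z, z) == 0.0

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(st.lists(st.booleans(), min_size=16, max_size=16),
           st.lists(st.booleans(), min_size=16, max_size=16))
    def test_symmetry_and_self_similarity(self, a, b):
        a = np.array(a, bool)
        b = np.array(b, bool)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert tanimoto(a, b) == pytest.approx(tanimoto(b, a))
            if a.any():
                assert tanimoto(a, a) == 1.0
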