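import numpy as np
import pandas as pd
import pytest

from pnaqsar.chem import canonicalize_desalt, ecfp4
from pnaqsar.domain import (
    ADParams,
    assign_ad,
    fit_applicability_domain,
    nearest_neighbor_similarity,
    optimize_global_threshold,
    target_cutoffs,
    target_reliability,
)


def _key(bits, n=16):
    v = np.zeros(n, dtype=bool)
    v[list(bits)] = True
    return v


class TestNearestNeighbor:
    def test_member_of_training_set_scores_one(self):
        keys = np.stack([_key([0, 1]), _key([2, 3]), _key([4, 5])])
        sim, idx = nearest_neighbor_similarity(_key([2, 3]), keys)
        assert sim == 1.0 and idx == 1

    def test_disjoint_scores_zero(self):
        keys = np.stack([_key([0, 1]), _key([2, 3])])
        sim, _ = nearest_neighbor_similarity(_key([10, 11]), keys)
        assert sim == 0.0

    def test_maximum_selected(self):
        # similarities {0.2, 0.7} -> 0.7
        q = _key([0, 1, 2, 3, 4])                  # |q| = 5
        far = _key([0, 5, 6, 7, 8, 9, 10, 11, 12]) # inter 1, union 13
        near = _key([0, 1, 2, 3, 5, 6])            # inter 4, union 7
        sims = [1 / 13, 4 / 7]
        keys = np.stack([far, near])
        sim, idx = nearest_neighbor_similarity(q, keys)
        assert sim == pytest.approx(max(sims)) and idx == 1

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            nearest_neighbor_similarity(_key([0]), np.zeros((0, 16), bool))


class TestGlobalThreshold:
    def test_degenerate_distributions_return_that_similarity(self):
        df = pd.DataFrame({"fold": [0] * 6, "sq_err": [0.2] * 6,
                           "nn_similarity": [0.4] * 6})
        assert optimize_global_threshold(df) == pytest.approx(0.4)

    def test_extreme_low_similarity_cannot_set_minimum(self):
        """A well-predicted compound whose similarity z-score is beyond the
        95% window is excluded before taking the minimum."""
        sims = [0.50, 0.52, 0.48, 0.51, 0.49, 0.50, 0.53, 0.47, 0.50, 0.05]
        df = pd.DataFrame({"fold": 0, "sq_err": [0.1] * 10,
                           "nn_similarity": sims})
        thr = optimize_global_threshold(df)
        z = (np.array(sims) - np.mean(sims)) / np.std(sims)
        assert abs(z[-1]) > 1.96          # the outlier really is outside
        assert thr == pytest.approx(0.47)  # minimum among |z| <= 1.96

    def test_mean_over_folds(self):
        # two scripted folds whose thresholds are 0.3 and 0.5
        fold0 = pd.DataFrame({"fold": 0, "sq_err": [0.1] * 5,
                              "nn_similarity": [0.3, 0.35, 0.4, 0.33, 0.31]})
        fold1 = pd.DataFrame({"fold": 1, "sq_err": [0.1] * 5,
                              "nn_similarity": [0.5, 0.55, 0.6, 0.53, 0.51]})
        thr = optimize_global_threshold(pd.concat([fold0, fold1]))
        assert thr == pytest.approx((0.3 + 0.5) / 2)

    def test_q3_keeps_best_predicted_three_quarters(self):
        # the worst-predicted compound's similarity is the lowest, but it is
        # beyond Q3 of the squared errors so it cannot set the threshold
        df = pd.DataFrame({"fold": 0,
                           "sq_err": [0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 9.0],
                           "nn_similarity": [0.5, 0.52, 0.48, 0.51, 0.49,
                                             0.50, 0.53, 0.10]})
        assert optimize_global_threshold(df) == pytest.approx(0.48)

    def test_small_folds_skipped(self):
        df = pd.DataFrame({"fold": [0, 0, 0, 1, 1, 1, 1],
                           "sq_err": [0.1] * 7,
                           "nn_similarity": [0.2, 0.2, 0.2, 0.6, 0.6, 0.6, 0.6]})
        assert optimize_global_threshold(df) == pytest.approx(0.6)

    def test_threshold_within_observed_range(self, clean_library):
        rng = np.random.default_rng(0)
        sims = rng.uniform(0.1, 0.9, size=60)
        df = pd.DataFrame({"fold": np.repeat(np.arange(6), 10),
                           "sq_err": rng.uniform(0, 1, size=60),
                           "nn_similarity": sims})
        thr = optimize_global_threshold(df)
        assert sims.min() <= thr <= sims.max()


class TestTargetReliability:
    PARAMS = ADParams(global_threshold=0.4,
                      per_target_cutoff={"T1": 0.25},
                      per_target_range={"T1": 5.0})

    def test_zero_residual_neighbors_pass(self):
        keys = np.stack([_key([0, 1, 2]), _key([0, 1, 3])])
        n, msr, ok = target_reliability(_key([0, 1, 2]), "T1", keys,
                                        np.zeros(2), self.PARAMS)
        assert ok and n == 2 and msr == 0.0

    def test_no_neighbor_within_035_fails(self):
        keys = np.stack([_key([10, 11, 12, 13, 14, 15])])
        n, msr, ok = target_reliability(_key([0, 1, 2]), "T1", keys,
                                        np.zeros(1), self.PARAMS)
        assert not ok and n == 0

    def test_hand_msr_against_cutoff(self):
        # neighbors with squared residuals {0.1, 0.3}: msr 0.2 < cutoff 0.25
        keys = np.stack([_key([0, 1, 2]), _key([0, 1, 2, 3])])
        n, msr, ok = target_reliability(_key([0, 1, 2]), "T1", keys,
                                        np.array([0.1, 0.3]), self.PARAMS)
        assert msr == pytest.approx(0.2)
        assert ok  # root-scale comparison: sqrt(0.2) < sqrt(0.25)

    def test_literal_squared_scale_option(self):
        params = ADParams(global_threshold=0.4, per_target_cutoff={"T1": 0.15},
                          per_target_range={"T1": 5.0}, squared_scale=True)
        keys = np.stack([_key([0, 1, 2])])
        _, msr, ok = target_reliability(_key([0, 1, 2]), "T1", keys,
                                        np.array([0.2]), params)
        assert msr == pytest.approx(0.2) and not ok


class TestAssignAd:
    def _setup(self):
        train_keys = np.stack([_key([0, 1, 2, 3]), _key([4, 5, 6, 7]),
                               _key([0, 1, 2, 4])])
        per_target = {"T1": (train_keys, np.array([0.01, 0.01, 0.01]))}
        params = ADParams(global_threshold=0.5,
                          per_target_cutoff={"T1": 0.25},
                          per_target_range={"T1": 5.0})
        return train_keys, per_target, params

    def test_training_compound_inside_when_reliable(self):
        train_keys, per_target, params = self._setup()
        v = assign_ad(train_keys[0], train_keys, per_target, params)[0]
        assert v.nearest_similarity == 1.0 and v.flags["T1"] == "inside"

    def test_below_threshold_is_outside_everywhere(self):
        train_keys, per_target, params = self._setup()
        v = assign_ad(_key([10, 11, 12]), train_keys, per_target, params)[0]
        assert v.flags["T1"] == "outside"

    def test_pure_function_of_inputs(self):
        train_keys, per_target, params = self._setup()
        q = _key([0, 1, 2, 5])
        a = assign_ad(q, train_keys, per_target, params)[0]
        b = assign_ad(q, train_keys, per_target, params)[0]
        assert a.flags == b.flags and a.nearest_similarity == b.nearest_similarity

    def test_raising_threshold_is_monotone(self):
        """No compound ever flips outside -> inside as the global similarity
        threshold increases."""
        rng = np.random.default_rng(0)
        train_keys = rng.random((20, 32)) < 0.3
        queries = rng.random((15, 32)) < 0.3
        per_target = {"T1": (train_keys, rng.uniform(0, 0.5, 20))}
        previous_inside = None
        for thr in np.linspace(0.0, 1.0, 21):
            params = ADParams(global_threshold=float(thr),
                              per_target_cutoff={"T1": 0.2},
                              per_target_range={"T1": 5.0})
            inside = {i for i, v in enumerate(
                assign_ad(queries, train_keys, per_target, params))
                if v.flags["T1"] == "inside"}
            if previous_inside is not None:
                assert inside <= previous_inside
            previous_inside = inside


class TestFitApplicabilityDomain:
    def test_cutoffs_are_ten_percent_of_range_squared(self):
        acts = pd.DataFrame({"T1": [4.0, 9.0, 6.0], "T2": [5.0, 5.5, np.nan]})
        cutoffs, ranges = target_cutoffs(acts, ("T1", "T2"))
        assert ranges["T1"] == 5.0 and cutoffs["T1"] == pytest.approx(0.25)
        assert cutoffs["T2"] == pytest.approx((0.1 * 0.5) ** 2)

    def test_end_to_end_frame(self, clean_library):
        _, _, truth = clean_library
        smiles = truth.table["smiles"].tolist()[:30]
        acts = truth.table[["true_T1", "true_T2"]].head(30)
        acts.columns = ["T1", "T2"]
        rng = np.random.default_rng(0)
        residuals = pd.DataFrame({
            "smiles": smiles * 2,
            "target": ["T1"] * 30 + ["T2"] * 30,
            "fold": list(np.repeat([0, 1, 2], 10)) * 2,
            "sq_err": rng.uniform(0, 0.4, 60),
            "nn_similarity": rng.uniform(0.3, 0.9, 60),
        })
        ad = fit_applicability_domain(smiles, acts, residuals, ("T1", "T2"))
        frame = ad.frame(smiles[:5])
        assert set(frame["AD_T1"]) <= {"inside", "outside"}
        assert (frame["nearest_similarity"] == 1.0).all()
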