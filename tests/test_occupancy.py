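import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermodiv.occupancy import (OccupancyClassifier, OccupancyResult,
                                 classify_species, compute_occupancy,
                                 occupancy_null, occupancy_sampling_law)

from .conftest import toy_2x2_table


def eight_group_meta():
    rows = []
    for g in range(8):
        for r in range(7):
            rows.append({"sample_id": f"G{g+1}R{r+1}", "group": f"G{g+1}",
                         "temperature_C": 80.0 - 3 * g, "replicate": r + 1})
    return pd.DataFrame(rows)


class TestComputeOccupancy:
    def test_all_replicates_one_group(self):
        meta = eight_group_meta()
        table = pd.DataFrame(0, index=["sp"], columns=meta["sample_id"])
        table.loc["sp", [f"G3R{r}" for r in range(1, 8)]] = 10
        assert compute_occupancy(table, meta).loc["sp"] == 1

    def test_one_sample_in_each_group(self):
        meta = eight_group_meta()
        table = pd.DataFrame(0, index=["sp"], columns=meta["sample_id"])
        table.loc["sp", [f"G{g}R1" for g in range(1, 9)]] = 1
        assert compute_occupancy(table, meta).loc["sp"] == 8

    def test_min_count_threshold(self):
        meta = eight_group_meta()
        table = pd.DataFrame(0, index=["sp"], columns=meta["sample_id"])
        table.loc["sp", "G1R1"] = 1
        table.loc["sp", "G2R1"] = 5
        assert compute_occupancy(table, meta, min_count=2).loc["sp"] == 1

    def test_empty_table_raises(self):
        meta = eight_group_meta()
        table = pd.DataFrame(index=pd.Index([], name="species"),
                             columns=meta["sample_id"])
        with pytest.raises(ValueError):
            compute_occupancy(table, meta)


class TestSamplingLaw:
    def test_toy_enumeration(self):
        # 2 groups x 2 samples, 2 occupied samples: C(4,2)=6 placements,
        # 2 keep both in one group
        law = occupancy_sampling_law(2, [2, 2])
        assert law == pytest.approx([2 / 6, 4 / 6])

    def test_k1_always_one_group(self):
        law = occupancy_sampling_law(1, [7] * 8)
        assert law[0] == pytest.approx(1.0)

    def test_all_samples_cover_all_groups(self):
        law = occupancy_sampling_law(56, [7] * 8)
        assert law[-1] == pytest.approx(1.0)

    @given(st.integers(1, 20))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_law_is_distribution(self, k):
        law = occupancy_sampling_law(k, [7, 5, 3, 7, 6])
        assert np.all(law >= 0)
        assert law.sum() == pytest.approx(1.0)
        # can't cover more groups than samples drawn
        assert np.all(law[min(k, 5):] == 0) or k >= 5


class TestOccupancyNull:
    def test_forced_single_sample(self):
        table, meta = toy_2x2_table()
        table.loc["sp1"] = [5, 0, 0, 0]  # one occupied sample
        res = occupancy_null(table, meta, n_perm=200, seed=0)
        assert res.expected_hist == pytest.approx([1.0, 0.0])
        assert not res.exceedance.any()

    def test_toy_estimate_within_monte_carlo_error(self):
        table, meta = toy_2x2_table()
        res = occupancy_null(table, meta, n_perm=10000, seed=1)
        for cls, p in [(0, 2 / 6), (1, 4 / 6)]:
            se = np.sqrt(p * (1 - p) / res.n_perm)
            assert abs(res.expected_hist[cls] - p) < 3 * se

    def test_species_in_every_sample_never_exceeds(self):
        meta = eight_group_meta()
        table = pd.DataFrame(3, index=["sp"], columns=meta["sample_id"])
        res = occupancy_null(table, meta, n_perm=500, seed=0)
        assert res.observed_hist[-1] == 1
        assert res.expected_hist[-1] == pytest.approx(1.0)
        assert not res.exceedance.any()

    def test_pvalues_carry_plus_one_correction(self):
        table, meta = toy_2x2_table()
        res = occupancy_null(table, meta, n_perm=100, seed=3)
        assert (res.pvalues >= 1 / 101).all()
        assert (res.pvalues <= 1.0).all()

    def test_incidence_counts_preserved_fixedfixed(self):
        # curveball null keeps row and column sums; histogram totals match
        meta = eight_group_meta()
        rng = np.random.default_rng(0)
        table = pd.DataFrame(rng.integers(0, 2, size=(12, 56)),
                             index=[f"s{i}" for i in range(12)],
                             columns=meta["sample_id"])
        table.iloc[:, 0] = 1  # no empty species
        res = occupancy_null(table, meta, n_perm=20, seed=1,
                             null="fixedfixed")
        assert res.observed_hist.sum() == 12
        assert res.expected_hist.sum() == pytest.approx(12.0)


class TestClassification:
    def test_criteria_shape_and_recovery(self, default_community):
        table, meta, truth = default_community
        clf = OccupancyClassifier(n_perm=20000, random_state=0)
        clf.fit(table, meta)
        assert clf.sensitive_classes_ == (1,)
        assert clf.resistant_classes_ == (5, 6, 7, 8)
        planted = truth["planted_class"]
        spec = planted.index[planted == "specialist"]
        gen = planted.index[planted == "generalist"]
        assert (clf.labels_.loc[spec] == "sensitive").mean() >= 0.99
        assert (clf.labels_.loc[gen] == "resistant").mean() >= 0.99

    def test_invariant_to_row_and_column_order(self, default_community):
        table, meta, _ = default_community
        rng = np.random.default_rng(4)
        shuffled = table.iloc[rng.permutation(table.shape[0]),
                              rng.permutation(table.shape[1])]
        a = OccupancyClassifier(n_perm=2000, random_state=0).fit(table, meta)
        b = OccupancyClassifier(n_perm=2000, random_state=0).fit(shuffled,
                                                                 meta)
        assert a.sensitive_classes_ == b.sensitive_classes_
        assert a.resistant_classes_ == b.resistant_classes_
        assert (a.labels_.sort_index() == b.labels_.sort_index()).all()

    def test_missing_high_end_run_empty_resistant(self):
        occ = pd.Series([1, 1, 2], index=["a", "b", "c"])
        res = OccupancyResult(
            occupancy=occ, classes=np.arange(1, 9),
            observed_hist=np.array([2, 1, 0, 0, 0, 0, 0, 0]),
            expected_hist=np.array([0.5, 2.0, 0.3, 0, 0, 0, 0.1, 0.2]),
            exceedance=np.array([True] + [False] * 7),
            pvalues=np.full(8, 0.5), n_perm=10, null="redraw")
        with pytest.warns(UserWarning, match="resistant set empty"):
            cls = classify_species(res)
        assert cls.resistant_classes == ()
        assert cls.sensitive_classes == (1,)
        assert (cls.labels.loc[["a", "b"]] == "sensitive").all()
        assert cls.labels.loc["c"] == "other"
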