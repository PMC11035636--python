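import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import halolipidome as hl
from halolipidome.composition import NH4_H_DELTA, upset_counts_frame
from halolipidome.io import FeatureTable, ValidationError


def _table(values, features, samples, feature_meta=None, groups=None):
    ab = pd.DataFrame(values, index=features, columns=samples, dtype=float)
    sm = pd.DataFrame(index=pd.Index(samples))
    if groups is not None:
        sm["group"] = groups
    fm = feature_meta if feature_meta is not None else pd.DataFrame(index=ab.index)
    return FeatureTable(abundance=ab, feature_meta=fm, sample_meta=sm)


class TestRecoveryCorrection:
    def test_uniform_standard_scales_proportionally(self):
        t = _table([[10, 20], [30, 40], [5, 5]], ["f1", "f2", "IS"], ["a", "b"])
        out = hl.correct_recovery(t, "IS")
        assert "IS" not in out.abundance.index
        assert np.allclose(out.abundance.to_numpy(), [[2, 4], [6, 8]])

    def test_higher_standard_halves_a_sample(self):
        t = _table([[10, 10], [2, 4]], ["f1", "IS"], ["a", "b"])
        out = hl.correct_recovery(t, "IS")
        assert out.abundance.loc["f1", "b"] == pytest.approx(
            out.abundance.loc["f1", "a"] / 2
        )

    def test_zero_standard_names_sample(self):
        t = _table([[10, 10], [2, 0]], ["f1", "IS"], ["a", "b"])
        with pytest.raises(ValidationError, match="b"):
            hl.correct_recovery(t, "IS")


class TestMergeAdducts:
    def _pair_table(self, rt_nh4=100.0, mz_nh4=653.681 + NH4_H_DELTA):
        fm = pd.DataFrame(
            {
                "precursor_mz": [653.681, mz_nh4, 900.0],
                "adduct": ["M+H", "M+NH4", "M+H"],
                "retention_time": [100.0, rt_nh4, 300.0],
            },
            index=["fH", "fN", "other"],
        )
        return _table([[70, 7], [30, 3], [5, 5]], ["fH", "fN", "other"], ["a", "b"], fm)

    def test_coeluting_pair_merges_and_sums(self):
        merged, report = hl.merge_adducts(self._pair_table())
        assert list(merged.abundance.index) == ["fH", "other"]
        assert merged.abundance.loc["fH"].tolist() == [100.0, 10.0]
        assert report.iloc[0]["kept"] == "fH"

    def test_no_candidates_is_identity(self):
        t = self._pair_table(mz_nh4=700.0)
        merged, report = hl.merge_adducts(t)
        assert report.empty
        pd.testing.assert_frame_equal(merged.abundance, t.abundance)

    def test_rt_gap_blocks_merge(self):
        merged, report = hl.merge_adducts(self._pair_table(rt_nh4=200.0), rt_tol=10.0)
        assert report.empty
        assert merged.n_features == 3

    def test_total_abundance_conserved(self, noiseless_study):
        table, _, _ = noiseless_study
        merged, _ = hl.merge_adducts(table)
        before = table.abundance.sum(axis=0)
        after = merged.abundance.sum(axis=0)
        assert np.allclose(before.to_numpy(), after.to_numpy(), rtol=0, atol=1e-6)

    def test_ambiguity_resolved_by_smallest_mass_error(self):
        fm = pd.DataFrame(
            {
                "precursor_mz": [500.0, 500.0 + NH4_H_DELTA + 0.004, 500.0 + NH4_H_DELTA],
                "adduct": ["M+H", "M+NH4", "M+NH4"],
                "retention_time": [50.0, 50.0, 50.0],
            },
            index=["h1", "n_far", "n_near"],
        )
        t = _table([[1, 1], [1, 1], [1, 1]], ["h1", "n_far", "n_near"], ["a", "b"], fm)
        _, report = hl.merge_adducts(t)
        assert len(report) == 1
        assert report.iloc[0]["merged"] == "n_near"


class TestRelativeAbundance:
    def test_column_closure(self):
        prof = hl.relative_abundance(_table([[1], [1], [2]], ["a", "b", "c"], ["s"]))
        assert prof.relative_abundance["s"].tolist() == [0.25, 0.25, 0.5]

    def test_scale_invariance(self):
        t1 = _table([[1, 3], [3, 5]], ["a", "b"], ["s1", "s2"])
        t2 = _table([[10, 3], [30, 5]], ["a", "b"], ["s1", "s2"])
        p1 = hl.relative_abundance(t1).relative_abundance
        p2 = hl.relative_abundance(t2).relative_abundance
        pd.testing.assert_frame_equal(p1, p2)

    def test_empty_sample_warns_and_stays_zero(self):
        with pytest.warns(UserWarning, match="zero total"):
            prof = hl.relative_abundance(_table([[1, 0], [1, 0]], ["a", "b"], ["s1", "s2"]))
        assert prof.relative_abundance["s2"].tolist() == [0.0, 0.0]


class TestClassAggregation:
    def test_single_class_share_is_one(self):
        prof = hl.relative_abundance(_table([[1], [3]], ["a", "b"], ["s"]))
        anns = {f: hl.LipidAnnotation(lipid_class="PG") for f in ("a", "b")}
        ca = hl.aggregate_classes(prof, anns)
        assert ca.loc["PG", "s"] == pytest.approx(1.0)

    def test_even_split_recovered(self):
        prof = hl.relative_abundance(_table([[2], [2]], ["a", "b"], ["s"]))
        anns = {
            "a": hl.LipidAnnotation(lipid_class="PG"),
            "b": hl.LipidAnnotation(lipid_class="MK"),
        }
        ca = hl.aggregate_classes(prof, anns)
        assert ca["s"].tolist() == pytest.approx([0.5, 0.5])


class TestPresence:
    def _profile(self, values, features):
        t = _table(values, features, ["g1_r1", "g1_r2", "g2_r1", "g2_r2"],
                   groups=["g1", "g1", "g2", "g2"])
        return hl.relative_abundance(t)

    def test_below_threshold_is_absent_everywhere(self):
        # one feature at 0.005% of total in every sample
        prof = self._profile([[0.00005] * 4, [0.99995] * 4], ["tiny", "big"])
        presence = hl.call_presence(prof)
        assert not presence.loc["tiny"].any()
        assert presence.loc["big"].all()

    def test_exactly_at_threshold_counts_as_present(self):
        prof = self._profile([[0.0001] * 4, [0.9999] * 4], ["edge", "big"])
        assert hl.call_presence(prof).loc["edge"].all()

    def test_zero_is_absent(self):
        prof = self._profile([[0.0] * 4, [1.0] * 4], ["gone", "big"])
        assert not hl.call_presence(prof).loc["gone"].any()

    def test_any_mode_differs_from_mean_mode(self):
        prof = self._profile(
            [[0.00015, 0.0, 0.0, 0.0], [0.99985, 1.0, 1.0, 1.0]], ["spiky", "big"]
        )
        assert not hl.call_presence(prof, mode="mean").loc["spiky", "g1"]
        assert hl.call_presence(prof, mode="any").loc["spiky", "g1"]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((6, 4))
        prof = self._profile(values, [f"f{i}" for i in range(6)])
        low = hl.call_presence(prof, threshold=0.01)
        high = hl.call_presence(prof, threshold=0.05)
        assert not (high & ~low).any().any()


class TestUpset:
    def test_full_membership_counted_once(self):
        presence = pd.DataFrame(
            [[True, True, True]], index=["f"], columns=["A", "B", "C"]
        )
        assert hl.upset_counts(presence) == {frozenset("ABC"): 1}

    def test_absent_feature_contributes_nothing(self):
        presence = pd.DataFrame(
            [[False, False], [True, False]], index=["gone", "a_only"], columns=["A", "B"]
        )
        counts = hl.upset_counts(presence)
        assert counts == {frozenset("A"): 1}

    def test_known_pattern_fixture_recovered_exactly(self):
        """Planted membership patterns come back from a brute-force census."""
        rng = np.random.default_rng(1)
        groups = ["A", "B", "C"]
        patterns = [
            frozenset(p)
            for p in (("A",), ("B",), ("C",), ("A", "B"), ("A", "C"), ("B", "C"),
                      ("A", "B", "C"))
        ]
        planted = {p: int(rng.integers(1, 9)) for p in patterns}
        rows, index = [], []
        i = 0
        for pattern, count in planted.items():
            for _ in range(count):
                rows.append([g in pattern for g in groups])
                index.append(f"f{i}")
                i += 1
        presence = pd.DataFrame(rows, index=index, columns=groups)
        counts = hl.upset_counts(presence)
        assert counts == planted
        assert sum(counts.values()) == len(index)

    def test_frame_output_partitions_features(self):
        rng = np.random.default_rng(2)
        presence = pd.DataFrame(
            rng.random((30, 3)) > 0.5, columns=["A", "B", "C"],
            index=[f"f{i}" for i in range(30)],
        )
        frame = upset_counts_frame(presence)
        assert frame["count"].sum() == int(presence.any(axis=1).sum())
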