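"""Probe-level expression preprocessing pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mindsubtypes.ahba import (
    preprocess,
    assign_samples,
    build_matrix,
    filter_probes,
    scaled_robust_sigmoid,
    select_probe,
    select_probes,
)


class TestFilterProbes:
    def _tables(self, below_counts, n_samples=6):
        probes = pd.DataFrame({"probe_id": [f"p{i}" for i in range(len(below_counts))],
                               "gene_symbol": [f"g{i}" for i in range(len(below_counts))]})
        above = pd.DataFrame(
            [[False] * b + [True] * (n_samples - b) for b in below_counts],
            index=list(probes["probe_id"]))
        return probes, above

    def test_boundary_half_is_kept(self):
        probes, above = self._tables([3])  # 3/6 below: exactly 50%, not "over"
        assert len(filter_probes(probes, above)) == 1

    def test_over_half_removed(self):
        probes, above = self._tables([4])
        assert len(filter_probes(probes, above)) == 0

    def test_all_above_kept(self):
        probes, above = self._tables([0, 0])
        assert len(filter_probes(probes, above)) == 2

    def test_missing_calls_rejected(self):
        probes, above = self._tables([0])
        probes.loc[0, "probe_id"] = "other"
        with pytest.raises(ValueError, match="missing"):
            filter_probes(probes, above)


class TestSelectProbe:
    def test_single_probe_passes_through(self):
        assert select_probe(["p0"], {}) == "p0"

    def test_stable_probe_beats_sign_flipped(self):
        regions = range(6)
        prof = np.arange(6, dtype=float)
        d1 = pd.DataFrame({"stable": prof, "flipped": prof}, index=regions)
        d2 = pd.DataFrame({"stable": prof, "flipped": prof[::-1]}, index=regions)
        assert select_probe(["stable", "flipped"], {"a": d1, "b": d2}) == "stable"

    def test_matches_brute_force_over_probes(self):
        rng = np.random.default_rng(0)
        probes = [f"p{i}" for i in range(3)]
        profiles = {d: pd.DataFrame(rng.normal(size=(8, 3)), columns=probes)
                    for d in ("d1", "d2")}

        def ds(p):
            return stats.spearmanr(profiles["d1"][p], profiles["d2"][p]).statistic

        assert select_probe(probes, profiles) == max(probes, key=ds)

    def test_single_donor_fallback_highest_variance(self):
        probes = ["low", "high"]
        prof = pd.DataFrame({"low": [1.0, 1.1, 0.9], "high": [0.0, 5.0, -5.0]})
        assert select_probe(probes, {"only": prof}) == "high"

    def test_select_probes_per_gene(self):
        probes = pd.DataFrame({"probe_id": ["a", "b", "c"],
                               "gene_symbol": ["g1", "g1", "g2"]})
        prof = pd.DataFrame({"a": [0, 1, 2.0], "b": [1, 1, 1.001], "c": [5, 4, 3.0]})
        out = select_probes(probes, {"donor": prof})
        assert set(out["probe_id"]) == {"a", "c"}


class TestAssignSamples:
    def _regions(self):
        return pd.DataFrame({"region_id": [1, 2], "hemisphere": ["L", "L"],
                             "x": [0.0, 10.0], "y": [0.0, 0.0], "z": [0.0, 0.0]})

    def test_sample_at_centroid(self):
        samples = pd.DataFrame({"sample_id": ["s1"], "x": [0.0], "y": [0.0],
                                "z": [0.0]})
        out = assign_samples(samples, self._regions(), region_radius=1.0)
        assert out["s1"] == 1

    def test_sample_beyond_tolerance_dropped(self):
        samples = pd.DataFrame({"sample_id": ["s1"], "x": [0.0], "y": [3.2],
                                "z": [0.0]})
        out = assign_samples(samples, self._regions(), region_radius=1.0,
                             tolerance=2.0)
        assert "s1" not in out.index

    def test_sample_within_tolerance_nearest(self):
        samples = pd.DataFrame({"sample_id": ["s1"], "x": [8.0], "y": [0.0],
                                "z": [0.0]})
        out = assign_samples(samples, self._regions(), region_radius=1.0)
        assert out["s1"] == 2

    def test_no_regions_rejected(self):
        samples = pd.DataFrame({"sample_id": ["s"], "x": [0.0], "y": [0], "z": [0]})
        with pytest.raises(ValueError, match="region"):
            assign_samples(samples, self._regions().iloc[:0], region_radius=1.0)


class TestScaledRobustSigmoid:
    def test_direct_evaluation(self):
        x = np.array([0, 1, 2, 3, 4.0])  # median 2, IQR 2
        pre = 1 / (1 + np.exp(-(x - 2) / 2))
        expect = (pre - pre.min()) / (pre.max() - pre.min())
        np.testing.assert_allclose(scaled_robust_sigmoid(x), expect, atol=1e-12)
        assert scaled_robust_sigmoid(x)[0] == 0.0
        assert scaled_robust_sigmoid(x)[-1] == 1.0

    def test_monotone(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.normal(size=30))
        y = scaled_robust_sigmoid(x)
        assert np.all(np.diff(y) > 0)

    def test_zero_iqr_rejected(self):
        with pytest.raises(ValueError, match="interquartile"):
            scaled_robust_sigmoid(np.ones(10))


class TestBuildMatrix:
    def _toy(self):
        regions = pd.DataFrame({"region_id": [1, 2, 3],
                                "hemisphere": ["L", "L", "L"],
                                "x": [-1.0, -2, -3], "y": [0.0, 0, 0],
                                "z": [0.0, 0, 0]})
        meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(6)],
                             "donor_id": ["d1"] * 3 + ["d2"] * 3})
        assignment = pd.Series([1, 2, 3, 1, 2, 3],
                               index=meta["sample_id"], name="region_id")
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.normal(size=(6, 2)), index=meta["sample_id"],
                            columns=["gA", "gB"])
        return regions, meta, assignment, expr

    def test_hand_computed_two_donor_average(self):
        regions, meta, assignment, expr = self._toy()
        out = build_matrix(expr, meta, assignment, regions, normalize=False)
        for rid, sids in ((1, ["s0", "s3"]), (2, ["s1", "s4"]), (3, ["s2", "s5"])):
            np.testing.assert_allclose(out.loc[rid],
                                       expr.loc[sids].mean(), atol=1e-12)

    def test_duplicated_sample_idempotent(self):
        regions, meta, assignment, expr = self._toy()
        meta2 = pd.concat([meta, meta.iloc[[0]].assign(sample_id="s0b")],
                          ignore_index=True)
        expr2 = pd.concat([expr, expr.iloc[[0]].rename(index={"s0": "s0b"})])
        expr2.loc["s0b"] = expr.loc["s0"]
        assign2 = pd.concat([assignment, pd.Series([1], index=["s0b"])])
        out1 = build_matrix(expr, meta, assignment, regions, normalize=False)
        # duplicating a sample with identical values shifts the within-region
        # mean toward it but leaves a single-sample region untouched
        out2 = build_matrix(expr2, meta2, assign2, regions, normalize=False)
        np.testing.assert_allclose(out1.loc[3], out2.loc[3], atol=1e-12)

    def test_values_in_unit_interval_when_normalized(self):
        regions, meta, assignment, expr = self._toy()
        out = build_matrix(expr, meta, assignment, regions, normalize=True)
        assert out.to_numpy().min() >= 0.0
        assert out.to_numpy().max() <= 1.0

    def test_right_hemisphere_excluded(self):
        regions, meta, assignment, expr = self._toy()
        regions.loc[2, "hemisphere"] = "R"
        out = build_matrix(expr, meta, assignment, regions, normalize=False)
        assert 3 not in out.index


class TestPreprocess:
    def _inputs(self):
        rng = np.random.default_rng(3)
        regions = pd.DataFrame({
            "region_id": [1, 2, 3, 4],
            "hemisphere": ["L", "L", "L", "R"],
            "x": [-10.0, -20, -30, 10], "y": [0.0, 5, -5, 0],
            "z": [0.0, 0, 0, 0]})
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "donor_id": ["d1"] * 4 + ["d2"] * 4,
            "x": [-10, -20, -30, -10, -10, -20, -30, 99.0],
            "y": [0.0, 5, -5, 0, 0, 5, -5, 0],
            "z": [0.0] * 8})
        probes = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(5)],
            "gene_symbol": ["gA", "gA", "gB", None, "gC"]})
        above = pd.DataFrame(True, index=list(probes["probe_id"]),
                             columns=samples["sample_id"])
        above.loc["p4"] = [True, False, False, False] * 2  # 6/8 below
        expr = pd.DataFrame(rng.normal(size=(8, 5)),
                            index=list(samples["sample_id"]),
                            columns=list(probes["probe_id"]))
        return probes, above, expr, samples, regions

    def test_provenance_counts(self):
        probes, above, expr, samples, regions = self._inputs()
        mat, prov = preprocess(probes, above, expr, samples, regions,
                               region_radius=1.0)
        assert prov["n_probes_in"] == 5
        assert prov["n_probes_mapped"] == 4      # unmapped probe dropped
        assert prov["n_probes_above_background"] == 3  # p4 was unmapped anyway
        assert prov["n_samples_assigned"] == 7   # far-away sample dropped
        assert prov["n_genes"] == 2              # gA (one of two probes), gB
        assert prov["n_regions_out"] == 3        # left hemisphere only
        assert set(mat.columns) == {"gA", "gB"}

    def test_probe_filter_and_selection_idempotent(self):
        """Re-running steps (i)-(iii) on their own output changes nothing."""
        probes, above, expr, samples, regions = self._inputs()
        mapped = probes.dropna(subset=["gene_symbol"]).reset_index(drop=True)
        kept = filter_probes(mapped, above)
        assignment = assign_samples(samples, regions, region_radius=1.0)
        meta = samples.set_index("sample_id")
        profiles = {}
        for donor, sids in meta.groupby("donor_id").groups.items():
            sids = [s for s in sids if s in assignment.index]
            prof = expr.loc[sids, kept["probe_id"]].copy()
            prof["region_id"] = assignment.loc[sids].to_numpy()
            profiles[donor] = prof.groupby("region_id").mean()
        selected = select_probes(kept, profiles)
        again = select_probes(filter_probes(selected, above), profiles)
        pd.testing.assert_frame_equal(selected, again)
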