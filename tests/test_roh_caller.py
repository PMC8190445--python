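import numpy as np
import pandas as pd
import pytest

from roh_oracle import oracle_segments
from rohload.roh import (HET, HOM_ALT, HOM_REF, MISSING, ROHClassBounds,
                         ROHParams, call_roh, classify_segments, compute_froh,
                         scale_cm_coordinates)

DEFAULTS = ROHParams()

# small-scale parameters for <= 200-marker oracle instances: zero het/missing
# allowance, window = min SNP count, spacing always under the density bound
ORACLE_PARAMS = ROHParams(window_snps=10, min_snps=10, min_length_cm=0.2,
                          max_gap_cm=0.25, window_het=0, window_missing=0,
                          segment_het=0, window_hit_threshold=0.05)


def segments_as_tuples(seg, cm):
    idx = {round(c * 1e6): i for i, c in enumerate(cm)}
    return [(idx[round(r.start_cm * 1e6)], idx[round(r.end_cm * 1e6)])
            for r in seg.itertuples()]


class TestScaleCoordinates:
    @pytest.mark.parametrize("cm,pseudo", [(0.39, 390_000), (0.25, 250_000),
                                           (0.0, 0)])
    def test_scaling(self, cm, pseudo):
        assert scale_cm_coordinates(cm) == pseudo


class TestCallRoh:
    def test_fully_homozygous_chromosome(self, genotypes_factory):
        gm = genotypes_factory(np.zeros(100, dtype=int))
        seg = call_roh(gm, DEFAULTS)
        assert len(seg) == 1
        row = seg.iloc[0]
        assert row["n_snps"] == 100
        assert row["length_cm"] == pytest.approx(4.95)
        assert row["n_het"] == 0

    def test_all_heterozygous_yields_nothing(self, genotypes_factory):
        gm = genotypes_factory(np.ones(100, dtype=int))
        assert len(call_roh(gm, DEFAULTS)) == 0

    def test_two_hets_within_allowance(self, genotypes_factory):
        calls = np.zeros(60, dtype=int)
        calls[[20, 40]] = HET
        gm = genotypes_factory(calls)
        seg = call_roh(gm, DEFAULTS)
        cm = gm.markers["cm"].to_numpy()
        assert segments_as_tuples(seg, cm) == oracle_segments(calls, cm, DEFAULTS)
        assert seg.iloc[0]["n_het"] == 2

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence_random_fixtures(self, seed, genotypes_factory):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(30, 200))
        calls = rng.choice([HOM_REF, HOM_ALT, HET, MISSING], size=m,
                           p=[0.45, 0.35, 0.15, 0.05])
        spacing = rng.uniform(0.01, 0.09, size=m - 1)
        big = rng.random(m - 1) < 0.03  # occasional gap above the split bound
        spacing[big] = rng.uniform(0.3, 0.5, size=int(big.sum()))
        cm = np.concatenate([[0.0], np.cumsum(spacing)])
        markers = pd.DataFrame({"marker_id": [f"s{i}" for i in range(m)],
                                "chromosome": "1", "cm": cm})
        from rohload.roh import GenotypeMatrix
        gm = GenotypeMatrix(["ind0"], markers, calls[None, :])
        seg = call_roh(gm, ORACLE_PARAMS)
        assert segments_as_tuples(seg, cm) == oracle_segments(
            calls, cm, ORACLE_PARAMS)

    def test_short_chromosome_yields_nothing(self, genotypes_factory):
        gm = genotypes_factory(np.zeros(10, dtype=int))
        assert len(call_roh(gm, DEFAULTS)) == 0

    def test_unsorted_markers_error(self, genotypes_factory):
        gm = genotypes_factory(np.zeros(30, dtype=int))
        gm.markers.loc[5, "cm"] = 10.0  # corrupt after validation
        with pytest.raises(ValueError, match="not sorted"):
            call_roh(gm, DEFAULTS)

    def test_gap_splits_run(self, genotypes_factory):
        gm = genotypes_factory(np.zeros(100, dtype=int))
        gm.markers.loc[50:, "cm"] += 1.0  # 1.05 cM gap between 49 and 50
        seg = call_roh(gm, DEFAULTS)
        assert len(seg) == 2
        assert seg["n_snps"].tolist() == [50, 50]

    def test_determinism(self, genotypes_factory):
        rng = np.random.default_rng(0)
        calls = rng.choice([0, 2, 1], size=(4, 300), p=[0.5, 0.4, 0.1])
        gm = genotypes_factory(calls)
        a, b = call_roh(gm, DEFAULTS), call_roh(gm, DEFAULTS)
        pd.testing.assert_frame_equal(a, b)

    def test_reported_segments_satisfy_constraints(self, genotypes_factory):
        rng = np.random.default_rng(42)
        calls = rng.choice([0, 2, 1, -1], size=(6, 400), p=[0.5, 0.4, 0.07, 0.03])
        gm = genotypes_factory(calls)
        seg = call_roh(gm, DEFAULTS)
        p = DEFAULTS
        if len(seg):
            assert (seg["n_snps"] >= p.min_snps).all()
            assert (seg["length_cm"] >= p.min_length_cm - 1e-9).all()
            assert (seg["n_het"] <= p.segment_het).all()
            assert (seg["length_cm"] / seg["n_snps"]
                    <= p.max_avg_spacing_cm_per_snp + 1e-12).all()
        # non-overlap within individual
        for _, grp in seg.groupby("individual"):
            grp = grp.sort_values("start_cm")
            assert (grp["start_cm"].to_numpy()[1:]
                    > grp["end_cm"].to_numpy()[:-1]).all()

    def test_adding_hets_never_increases_froh(self, genotypes_factory):
        rng = np.random.default_rng(3)
        calls = np.zeros((1, 300), dtype=int)
        gm = genotypes_factory(calls)
        base = classify_segments(call_roh(gm, DEFAULTS),
                                 ROHClassBounds())["length_cm"].sum()
        for n_extra in (1, 3, 6, 10):
            noisy = calls.copy()
            noisy[0, rng.choice(300, size=n_extra, replace=False)] = HET
            got = classify_segments(call_roh(genotypes_factory(noisy), DEFAULTS),
                                    ROHClassBounds())["length_cm"].sum()
            assert got <= base + 1e-12
            base = base  # monotone against the clean baseline


class TestClassification:
    @pytest.mark.parametrize("length,cls", [(80.55, "long"), (1.0, "short"),
                                            (12.5, "medium"), (1.56, "medium"),
                                            (0.39, "short"), (12.51, "long")])
    def test_boundaries(self, length, cls):
        seg = pd.DataFrame({"length_cm": [length]})
        assert classify_segments(seg)["length_class"].iloc[0] == cls

    def test_below_minimum_errors(self):
        with pytest.raises(ValueError):
            classify_segments(pd.DataFrame({"length_cm": [0.1]}))


class TestFroh:
    def make_segments(self, rows):
        df = pd.DataFrame(rows, columns=["individual", "length_cm"])
        df["chromosome"] = "1"
        df["start_cm"] = 0.0
        df["end_cm"] = df["length_cm"]
        return classify_segments(df)

    def test_direct_arithmetic(self):
        seg = self.make_segments([("a", 15.0), ("a", 5.0)])
        out = compute_froh(seg, 100.0)
        row = out.iloc[0]
        assert row["f_long"] == pytest.approx(0.15)
        assert row["f_medium"] == pytest.approx(0.05)
        assert row["f_total"] == pytest.approx(0.20)
        assert row["mean_roh_length_cm"] == pytest.approx(10.0)

    def test_no_segments_all_zero(self):
        seg = self.make_segments([("a", 15.0)])
        out = compute_froh(seg, 100.0, individuals=["a", "b"])
        b = out[out["individual"] == "b"].iloc[0]
        assert b[["f_long", "f_medium", "f_short", "f_total"]].sum() == 0
        assert np.isnan(b["mean_roh_length_cm"])

    def test_whole_map_coverage_is_one(self):
        seg = self.make_segments([("a", 3146.0)])
        assert compute_froh(seg, 3146.0)["f_total"].iloc[0] == pytest.approx(1.0)

    def test_class_sum_equals_total(self, genotypes_factory):
        rng = np.random.default_rng(11)
        calls = rng.choice([0, 2, 1], size=(5, 500), p=[0.48, 0.48, 0.04])
        seg = classify_segments(call_roh(genotypes_factory(calls), DEFAULTS))
        froh = compute_froh(seg, 3146.0)
        np.testing.assert_allclose(
            froh[["f_long", "f_medium", "f_short"]].sum(axis=1),
            froh["f_total"], atol=1e-9)

    def test_negative_length_errors(self):
        seg = self.make_segments([("a", 5.0)])
        seg.loc[0, "length_cm"] = -1.0
        with pytest.raises(ValueError):
            compute_froh(seg, 100.0)
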