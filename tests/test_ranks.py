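"""Scaled ranks, the relative-rank transform, GRP collapse, and panel ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ranksig.errors import PreconditionError
from ranksig.matrix import ExpressionMatrix, ProbeGeneMap
from ranksig.ranks import (
    RankProfile,
    ScaledRankVector,
    build_grp,
    compare_rank_profiles,
    compendium_background_ranks,
    compute_scaled_ranks,
    rank_panel,
    relative_rank,
)


def _em(data: dict, probes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(data, index=pd.Index(probes, name="probe")))


class TestScaledRanks:
    def test_descending_scaling(self):
        m = _em({"s1": [5.0, 3.0, 1.0]}, ["a", "b", "c"])
        v = compute_scaled_ranks(m, ["s1"])
        assert v.ranks.tolist() == [0.0, 0.5, 1.0]

    def test_average_tie_rule(self):
        m = _em({"s1": [5.0, 5.0, 1.0]}, ["a", "b", "c"])
        v = compute_scaled_ranks(m, ["s1"])
        assert v.ranks.tolist() == [0.25, 0.25, 1.0]

    def test_identical_samples_average_to_each(self):
        m = _em({"s1": [5.0, 3.0, 1.0], "s2": [5.0, 3.0, 1.0]}, ["a", "b", "c"])
        one = compute_scaled_ranks(m, ["s1"]).ranks
        both = compute_scaled_ranks(m, ["s1", "s2"]).ranks
        pd.testing.assert_series_equal(one, both)

    def test_empty_subset_rejected(self):
        m = _em({"s1": [1.0, 2.0]}, ["a", "b"])
        with pytest.raises(PreconditionError):
            compute_scaled_ranks(m, [])

    def test_permutation_within_sample(self):
        """Without ties, one sample's scaled ranks are {0, 1/(P−1), ..., 1}."""
        rng = np.random.default_rng(7)
        m = _em({"s1": rng.permutation(20).astype(float)}, [f"p{i}" for i in range(20)])
        v = compute_scaled_ranks(m, ["s1"]).ranks
        assert sorted(v.tolist()) == pytest.approx(np.linspace(0, 1, 20).tolist())

    @given(
        st.lists(st.integers(min_value=-500, max_value=500), min_size=3, max_size=12,
                 unique=True),
        st.sampled_from([0.5, 1.0, 3.0]),
        st.integers(min_value=-10, max_value=10),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, vals, scale, shift):
        """Any strictly increasing transform of intensities leaves ranks fixed."""
        probes = [f"p{i}" for i in range(len(vals))]
        floats = [float(v) for v in vals]
        a = compute_scaled_ranks(_em({"s": floats}, probes), ["s"]).ranks
        transformed = [scale * v + shift for v in floats]
        b = compute_scaled_ranks(_em({"s": transformed}, probes), ["s"]).ranks
        assert np.allclose(a.to_numpy(), b.to_numpy())


class TestRelativeRank:
    @pytest.mark.parametrize(
        "r,r0,expected",
        [
            (0.5, 0.5, 0.0),    # agreement
            (0.0, 0.5, 1.0),    # top-ranked vs middling background
            (1.0, 0.5, -1.0),   # bottom-ranked
            (0.75, 0.5, -0.5),  # (0.5-0.75)/(1-0.5)
            (0.25, 0.5, 0.5),
            (0.3, 0.0, -0.3),   # degenerate r0=0 → below-background branch
            (0.3, 1.0, 0.7),    # degenerate r0=1 → above-background branch
            (0.0, 0.0, 0.0),
            (1.0, 1.0, 0.0),
        ],
    )
    def test_known_values(self, r, r0, expected):
        assert relative_rank(r, r0) == pytest.approx(expected)

    @pytest.mark.parametrize("r,r0", [(-0.1, 0.5), (1.1, 0.5), (0.5, 2.0)])
    def test_domain_enforced(self, r, r0):
        with pytest.raises(PreconditionError):
            relative_rank(r, r0)

    @given(
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
        st.floats(min_value=0, max_value=1),
    )
    @settings(max_examples=200, deadline=None)
    def test_range_and_monotonicity(self, r1, r2, r0):
        """Values stay in [−1, 1]; at fixed r0 the transform is non-increasing in r."""
        v1, v2 = relative_rank(r1, r0), relative_rank(r2, r0)
        assert -1.0 <= v1 <= 1.0 and -1.0 <= v2 <= 1.0
        if r1 < r2:
            assert v1 >= v2

    def test_vectorized_matches_scalar(self, rng):
        r = rng.random(100)
        r0 = rng.random(100)
        vec = relative_rank(r, r0)
        assert np.allclose(vec, [relative_rank(a, b) for a, b in zip(r, r0)])


class TestBuildGrp:
    def test_background_equal_sample_is_zero(self, simple_map):
        v = ScaledRankVector(pd.Series({"pA": 0.1, "pB": 0.5, "pC": 0.9}))
        grp = build_grp(v, v, simple_map)
        assert (grp.values == 0).all()

    def test_magnitude_collapse_rule(self):
        # GENE1 probes have relative ranks +0.2 and −0.9 → −0.9 survives
        sample = ScaledRankVector(pd.Series({"p1": 0.4, "p2": 0.95}))
        background = ScaledRankVector(pd.Series({"p1": 0.5, "p2": 0.5}))
        pmap = ProbeGeneMap({"p1": "GENE1", "p2": "GENE1"})
        grp = build_grp(sample, background, pmap)
        assert grp.values["GENE1"] == pytest.approx(-0.9)

    def test_magnitude_tie_prefers_positive(self):
        sample = ScaledRankVector(pd.Series({"p1": 0.25, "p2": 0.75}))
        background = ScaledRankVector(pd.Series({"p1": 0.5, "p2": 0.5}))
        pmap = ProbeGeneMap({"p1": "G", "p2": "G"})
        grp = build_grp(sample, background, pmap)
        assert grp.values["G"] == pytest.approx(0.5)

    def test_single_probe_gene_passthrough(self, simple_map):
        sample = ScaledRankVector(pd.Series({"pA": 0.5, "pB": 0.5, "pC": 0.2}))
        background = ScaledRankVector(pd.Series({"pA": 0.5, "pB": 0.5, "pC": 0.4}))
        grp = build_grp(sample, background, simple_map)
        assert grp.values["GENE2"] == pytest.approx(relative_rank(0.2, 0.4))

    def test_unmapped_probes_dropped(self):
        sample = ScaledRankVector(pd.Series({"p1": 0.1, "p2": 0.9}))
        background = ScaledRankVector(pd.Series({"p1": 0.5, "p2": 0.5}))
        grp = build_grp(sample, background, ProbeGeneMap({"p1": "G"}))
        assert list(grp.values.index) == ["G"]

    def test_universe_mismatch_rejected(self):
        a = ScaledRankVector(pd.Series({"p1": 0.1}))
        b = ScaledRankVector(pd.Series({"q1": 0.1}))
        with pytest.raises(PreconditionError):
            build_grp(a, b, ProbeGeneMap({"p1": "G"}))

    def test_ten_probe_toy_hand_oracle(self):
        """Exhaustive hand computation on a 10-probe, 4-gene toy."""
        r = {f"p{i}": v for i, v in enumerate(
            [0.0, 0.9, 0.4, 0.6, 0.25, 0.75, 0.5, 0.375, 0.7, 0.1])}
        r0 = {f"p{i}": 0.5 for i in range(10)}
        pmap = ProbeGeneMap({
            "p0": "A", "p1": "A",          # rel +1.0, −0.8 → +1.0
            "p2": "B", "p3": "B",          # rel +0.2, −0.2 → tie → +0.2
            "p4": "C", "p5": "C", "p6": "C",  # rel +0.5, −0.5, 0 → tie → +0.5
            "p7": "D",                     # rel +0.25
            # p8, p9 unmapped
        })
        grp = build_grp(
            ScaledRankVector(pd.Series(r)), ScaledRankVector(pd.Series(r0)), pmap
        )
        expected = {"A": 1.0, "B": 0.2, "C": 0.5, "D": 0.25}
        assert {k: pytest.approx(v) for k, v in grp.values.items()} == expected


class TestCompareProfiles:
    def _profile(self, values, name=None):
        return RankProfile(pd.Series(values), name=name)

    def test_self_correlation_is_one(self, rng):
        p = self._profile(dict(zip("abcdefgh", rng.uniform(-1, 1, 8))))
        res = compare_rank_profiles(p, p)
        assert res.rho == pytest.approx(1.0)
        assert res.z == pytest.approx(np.sqrt(7))

    def test_negation_gives_minus_one(self, rng):
        vals = dict(zip("abcdefgh", rng.uniform(-1, 1, 8)))
        p = self._profile(vals)
        q = self._profile({k: -v for k, v in vals.items()})
        assert compare_rank_profiles(p, q).rho == pytest.approx(-1.0)

    def test_too_few_shared_keys(self):
        p = self._profile({"a": 0.1, "b": 0.2})
        with pytest.raises(PreconditionError):
            compare_rank_profiles(p, p)

    def test_null_z_is_standard_normal_scale(self):
        """Independent profiles of 5000 genes: |z| < 3 in ≥ 99% of draws."""
        rng = np.random.default_rng(42)
        keys = [f"g{i}" for i in range(5000)]
        hits = 0
        n_sim = 100
        for _ in range(n_sim):
            a = self._profile(pd.Series(rng.uniform(-1, 1, 5000), index=keys))
            b = self._profile(pd.Series(rng.uniform(-1, 1, 5000), index=keys))
            if abs(compare_rank_profiles(a, b).z) < 3:
                hits += 1
        assert hits >= 99

    def test_panel_self_query_first(self, rng):
        keys = [f"g{i}" for i in range(50)]
        query = self._profile(pd.Series(rng.uniform(-1, 1, 50), index=keys))
        panel = [
            ("other", self._profile(pd.Series(rng.uniform(-1, 1, 50), index=keys))),
            ("self", query),
        ]
        rows = rank_panel(query, panel)
        assert rows[0][0] == "self"
        assert rows[0][1].rho == pytest.approx(1.0)

    def test_panel_of_one(self, rng):
        keys = [f"g{i}" for i in range(30)]
        query = self._profile(pd.Series(rng.uniform(-1, 1, 30), index=keys))
        assert len(rank_panel(query, [("only", query)])) == 1

    def test_empty_panel_rejected(self, rng):
        query = self._profile({"a": 0.1, "b": 0.2, "c": 0.3})
        with pytest.raises(PreconditionError):
            rank_panel(query, [])


def test_background_ranks_require_shared_universe():
    a = ExpressionMatrix(pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]},
                                      index=["p1", "p2"]))
    b = ExpressionMatrix(pd.DataFrame({"t1": [1.0, 2.0], "t2": [2.0, 1.0]},
                                      index=["p1", "p3"]))
    with pytest.raises(PreconditionError):
        compendium_background_ranks([a, b])
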