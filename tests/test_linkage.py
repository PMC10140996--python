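"""rf/LOD computation, grouping, ordering, map distances, trait placement."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from auricolor.core import Haplotype, MatingType
from auricolor.linkage import (
    MapGapError,
    MarkerMatrix,
    TwoPointLinkage,
    group_markers,
    map_distance,
    order_markers,
    pairwise_rf_lod,
    place_trait,
    trait_vector_from_colors,
)
from auricolor.simulate import MarkerLocus, MeiosisParams, simulate_meiosis

F1 = (
    Haplotype.from_class("ab", MatingType.MAT1),
    Haplotype.from_class("AB", MatingType.MAT2),
)


def chain_matrix(n_strains, adjacent_r, n_markers, rng, prefix="m"):
    """Simulate a haploid marker chain with fixed adjacent rf (oracle-free)."""
    cols = {}
    state = rng.integers(0, 2, size=n_strains)
    cols[f"{prefix}1"] = state.copy()
    for i in range(2, n_markers + 1):
        flip = rng.random(n_strains) < adjacent_r
        state = np.where(flip, 1 - state, state)
        cols[f"{prefix}{i}"] = state.copy()
    df = pd.DataFrame(cols, index=[f"s{j}" for j in range(n_strains)])
    return MarkerMatrix(df.replace({0: "A", 1: "B"}))


class TestPairwiseRfLod:
    def test_identical_columns(self):
        m = MarkerMatrix(
            pd.DataFrame({"m1": ["A"] * 10 + ["B"] * 10, "m2": ["A"] * 10 + ["B"] * 10})
        )
        rf, lod, n_inf = pairwise_rf_lod(m)
        assert rf.loc["m1", "m2"] == 0.0
        assert lod.loc["m1", "m2"] == pytest.approx(20 * math.log10(2), abs=1e-9)
        assert n_inf.loc["m1", "m2"] == 20

    def test_half_mismatch_gives_zero_lod(self):
        m = MarkerMatrix(
            pd.DataFrame({"m1": ["A", "A", "B", "B"], "m2": ["A", "B", "A", "B"]})
        )
        rf, lod, _ = pairwise_rf_lod(m)
        assert rf.loc["m1", "m2"] == 0.5
        assert lod.loc["m1", "m2"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_calls_excluded_pairwise(self):
        m = MarkerMatrix(
            pd.DataFrame(
                {"m1": ["A", "B", np.nan, "B"], "m2": ["A", "B", "A", np.nan]}
            )
        )
        rf, _, n_inf = pairwise_rf_lod(m)
        assert n_inf.loc["m1", "m2"] == 2
        assert rf.loc["m1", "m2"] == 0.0

    def test_simulated_pair_recovers_r(self, rng):
        est = []
        m = chain_matrix(87, 0.1, 2, rng)
        rf, _, _ = pairwise_rf_lod(m)
        lo, hi = stats.binom.ppf([0.005, 0.995], 87, 0.1) / 87
        assert lo <= rf.loc["m1", "m2"] <= hi

    def test_lod_monotone_decreasing_in_mismatches(self):
        lods = []
        for k in range(0, 10):
            calls = ["B"] * k + ["A"] * (20 - k)
            m = MarkerMatrix(pd.DataFrame({"m1": ["A"] * 20, "m2": calls}))
            _, lod, _ = pairwise_rf_lod(m)
            lods.append(lod.loc["m1", "m2"])
        assert all(a > b for a, b in zip(lods, lods[1:]))
        assert all(l >= 0 for l in lods)

    def test_single_marker_rejected(self):
        with pytest.raises(ValueError):
            pairwise_rf_lod(MarkerMatrix(pd.DataFrame({"m1": ["A", "B"]})))

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="invalid marker code"):
            MarkerMatrix(pd.DataFrame({"m1": ["A", "C"]}))


class TestGrouping:
    def test_two_contigs_two_groups(self, rng):
        a = chain_matrix(87, 0.05, 4, rng, prefix="a")
        b = chain_matrix(87, 0.05, 4, rng, prefix="b")
        m = MarkerMatrix(pd.concat([a.calls, b.calls], axis=1))
        _, lod, _ = pairwise_rf_lod(m)
        groups = group_markers(lod, threshold=3.0)
        assert sorted(map(tuple, groups)) == [
            ("a1", "a2", "a3", "a4"), ("b1", "b2", "b3", "b4"),
        ]

    def test_grouping_invariant_to_marker_order(self, rng):
        a = chain_matrix(100, 0.05, 3, rng, prefix="a")
        b = chain_matrix(100, 0.05, 3, rng, prefix="b")
        joined = pd.concat([a.calls, b.calls], axis=1)
        _, lod1, _ = pairwise_rf_lod(MarkerMatrix(joined))
        shuffled = joined[["b2", "a1", "b3", "a3", "b1", "a2"]]
        _, lod2, _ = pairwise_rf_lod(MarkerMatrix(shuffled))
        assert group_markers(lod1) == group_markers(lod2)

    def test_threshold_above_max_lod_isolates_everything(self, rng):
        m = chain_matrix(50, 0.05, 3, rng)
        _, lod, _ = pairwise_rf_lod(m)
        groups = group_markers(lod, threshold=1e6)
        assert all(len(g) == 1 for g in groups)

    def test_identical_markers_one_group(self):
        m = MarkerMatrix(
            pd.DataFrame({f"m{i}": ["A"] * 10 + ["B"] * 10 for i in range(1, 4)})
        )
        _, lod, _ = pairwise_rf_lod(m)
        assert group_markers(lod) == [["m1", "m2", "m3"]]


class TestOrdering:
    def test_known_chain_order_recovered(self, rng):
        m = chain_matrix(500, 0.1, 6, rng)
        rf, lod, _ = pairwise_rf_lod(m)
        (group,) = group_markers(lod)
        names, cum = order_markers(group, rf)
        truth = [f"m{i}" for i in range(1, 7)]
        assert names in (truth, truth[::-1])
        assert cum[0] == 0.0
        assert all(a <= b for a, b in zip(cum, cum[1:]))

    def test_larger_group_uses_heuristic_and_recovers(self, rng):
        m = chain_matrix(800, 0.08, 10, rng)  # > exhaustive cutoff
        rf, lod, _ = pairwise_rf_lod(m)
        (group,) = group_markers(lod)
        names, _ = order_markers(group, rf)
        # m10 sorts before m2 lexicographically; compare as sets of adjacencies
        truth_adj = {frozenset((f"m{i}", f"m{i+1}")) for i in range(1, 10)}
        got_adj = {frozenset(p) for p in zip(names, names[1:])}
        assert got_adj == truth_adj

    def test_two_markers_trivial(self):
        rf = pd.DataFrame(
            [[0.0, 0.1], [0.1, 0.0]], index=["x", "y"], columns=["x", "y"]
        )
        names, cum = order_markers(["y", "x"], rf)
        assert names == ["x", "y"]
        assert cum[1] == pytest.approx(map_distance(0.1, "kosambi"))

    def test_gap_in_rf_matrix_is_named(self):
        rf = pd.DataFrame(
            [[0.0, np.nan], [np.nan, 0.0]], index=["x", "y"], columns=["x", "y"]
        )
        with pytest.raises(MapGapError, match="x-y"):
            order_markers(["x", "y"], rf)


class TestMapDistance:
    @pytest.mark.parametrize(
        "r,fn,expected",
        [
            (0.0, "haldane", 0.0),
            (0.0, "kosambi", 0.0),
            (0.1, "haldane", 11.157),
            (0.1, "kosambi", 10.137),
        ],
    )
    def test_closed_forms(self, r, fn, expected):
        assert map_distance(r, fn) == pytest.approx(expected, abs=1e-3)

    def test_monotone(self):
        rs = np.linspace(0.0, 0.45, 10)
        for fn in ("haldane", "kosambi"):
            ds = [map_distance(float(r), fn) for r in rs]
            assert all(a < b for a, b in zip(ds, ds[1:]))

    def test_unlinked_signalled(self):
        with pytest.raises(ValueError):
            map_distance(0.5, "haldane")


MAP10 = tuple(
    MarkerLocus("C1", i * 2_000_000, f"k{i:02d}") for i in range(1, 11)
)


class TestTraitPlacement:
    def test_trait_identical_to_marker(self, rng):
        m = chain_matrix(87, 0.1, 4, rng)
        res = TwoPointLinkage(m).fit()
        trait = m.calls["m2"]
        placement = place_trait(trait, m, res.genetic_map, trait_name="t")
        assert placement.placed
        assert placement.flanking[0][0] == "m2"
        assert placement.flanking[0][1] == 0.0

    def test_independent_trait_unplaced(self, rng):
        m = chain_matrix(87, 0.05, 4, rng)
        trait = pd.Series(
            np.where(rng.random(87) < 0.5, "A", "B"), index=m.calls.index
        )
        res = TwoPointLinkage(m).fit()
        placement = place_trait(trait, m, res.genetic_map, trait_name="t")
        assert not placement.placed

    def test_synthetic_locus_flanked_by_true_neighbours(self):
        # trait at 9 Mb on a 2 Mb-spaced 10-marker contig: between k04 and k05
        params = MeiosisParams(r=0.5, marker_map=MAP10)
        hits = 0
        for seed in range(10):
            gametes = simulate_meiosis(
                F1, params, 200, seed=seed,
                trait_positions={"A": ("C1", 9_000_000)},
            )
            calls = pd.DataFrame(
                [list(g.haplotype.marker_alleles) for g in gametes],
                index=[g.id for g in gametes],
                columns=[l.name for l in MAP10],
            )
            trait = pd.Series(
                [
                    "B" if g.haplotype.haplotype_class.dominant_a else "A"
                    for g in gametes
                ],
                index=calls.index,
            )
            res = TwoPointLinkage(MarkerMatrix(calls), traits={"A": trait}).fit()
            (placement,) = res.placements
            assert placement.placed
            if {f[0] for f in placement.flanking} == {"k04", "k05"}:
                hits += 1
        assert hits >= 6  # majority of seeds

    def test_colors_encode_to_origin_codes(self):
        colors = pd.Series(["purple", "white", None])
        vec = trait_vector_from_colors(colors)
        assert vec.tolist()[:2] == ["B", "A"]
        assert pd.isna(vec.iloc[2])


class TestFacade:
    def test_full_pipeline_recovers_contigs_and_order(self, rng):
        a = chain_matrix(300, 0.08, 5, rng, prefix="a")
        b = chain_matrix(300, 0.08, 4, rng, prefix="b")
        m = MarkerMatrix(pd.concat([a.calls, b.calls], axis=1))
        res = TwoPointLinkage(m).fit(lod_threshold=3.0, map_function="haldane")
        assert sorted(sorted(g.markers) for g in res.groups) == [
            ["a1", "a2", "a3", "a4", "a5"], ["b1", "b2", "b3", "b4"],
        ]
        for g in res.groups:
            first = g.markers[0][0]
            truth = sorted(m_ for m_ in m.markers if m_.startswith(first))
            assert list(g.markers) in (truth, truth[::-1])

    def test_map_frame_and_tsv(self, rng, tmp_path):
        m = chain_matrix(100, 0.1, 3, rng)
        res = TwoPointLinkage(m).fit()
        df = res.map_frame()
        assert set(df.columns) == {"group", "marker", "position_cm"}
        res.to_tsv(tmp_path / "map.tsv", tmp_path / "pw.tsv")
        assert (tmp_path / "map.tsv").read_text().startswith("group\tmarker")
        pw = pd.read_csv(tmp_path / "pw.tsv", sep="\t")
        assert {"marker1", "marker2", "rf", "lod"} <= set(pw.columns)

    def test_loc_export(self, rng, tmp_path):
        m = chain_matrix(10, 0.1, 2, rng)
        res = TwoPointLinkage(m).fit()
        res.to_loc(tmp_path / "pop.loc")
        text = (tmp_path / "pop.loc").read_text()
        assert "nloc = 2" in text and "nind = 10" in text
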