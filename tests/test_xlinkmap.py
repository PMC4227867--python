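import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlms import structio, synthetic_data, xlinkmap
from xlms.structio import ResidueRef
from xlms.xlinkmap import (
    CrossLink,
    EmptyScoreError,
    FlatHarmonicParams,
    ScoreRow,
    flat_harmonic,
    nonredundant,
    parse_constraints,
    select_models,
    write_constraints,
)


class TestFlatHarmonic:
    @pytest.mark.parametrize(
        "distance,tol,sd,expected",
        [
            (26.0, 26.0, 1.0, 0.0),  # boundary of the flat region
            (28.0, 26.0, 1.0, 4.0),  # ((28-26)/1)^2
            (10.0, 26.0, 1.0, 0.0),  # inside the flat region
            (30.0, 26.0, 2.0, 4.0),  # sd rescales the slope
        ],
    )
    def test_pointwise(self, distance, tol, sd, expected):
        p = FlatHarmonicParams(tol=tol, sd=sd)
        assert flat_harmonic(distance, p) == pytest.approx(expected)

    @given(d=st.floats(0, 100), tol=st.floats(1, 50), sd=st.floats(0.1, 5))
    @settings(deadline=None)
    def test_zero_iff_within_tolerance(self, d, tol, sd):
        p = FlatHarmonicParams(tol=tol, sd=sd)
        pen = flat_harmonic(d, p)
        assert (pen == 0.0) == (d <= tol)
        assert pen >= 0.0

    def test_weight_scales_linearly(self):
        p1 = FlatHarmonicParams(tol=10.0, weight=1.0)
        p3 = FlatHarmonicParams(tol=10.0, weight=3.0)
        assert flat_harmonic(14.0, p3) == 3 * flat_harmonic(14.0, p1)


class TestAssess:
    def test_close_pair_is_within_with_zero_penalty(self, compact_chain, compact_chain_map):
        # consecutive residues sit ~3.8 A apart: below every bound
        xl = CrossLink(
            "t", ResidueRef("synthetic", 1, "K"), ResidueRef("synthetic", 3, "K"), "BS2G"
        )
        a = xlinkmap.assess(xl, compact_chain, compact_chain_map)
        assert a.status == "within"
        assert a.penalty == 0.0

    def test_unknown_protein_is_unmappable_not_error(self, compact_chain, compact_chain_map):
        xl = CrossLink(
            "t", ResidueRef("other", 1, "K"), ResidueRef("synthetic", 3, "K"), "BS2G"
        )
        a = xlinkmap.assess(xl, compact_chain, compact_chain_map)
        assert a.status == "unmappable"
        assert a.distance is None

    def test_ambiguous_link_scores_minimum_distance(self, compact_chain, compact_chain_map):
        far = (ResidueRef("synthetic", 1, "K"), ResidueRef("synthetic", 120, "K"))
        near = (ResidueRef("synthetic", 1, "K"), ResidueRef("synthetic", 3, "K"))
        xl = CrossLink("amb", *far, "BS2G", alternatives=(near,))
        a = xlinkmap.assess(xl, compact_chain, compact_chain_map)
        d_near = structio.ca_distance(compact_chain, ("A", 1), ("A", 3))
        assert a.distance == pytest.approx(d_near)

    def test_status_monotone_in_distance(self):
        # pull a synthetic pair apart; status must never move back toward
        # "within" as distance grows
        rank = {"within": 0, "tolerated": 1, "violated": 2}
        seen = []
        for d in [5.0, 15.0, 22.0, 27.0, 33.0, 40.0, 80.0]:
            model = structio.StructureModel("pair")
            model.chains["A"] = [
                structio.ResidueEntry(1, "", "LYS", np.zeros(3)),
                structio.ResidueEntry(2, "", "LYS", np.array([d, 0.0, 0.0])),
            ]
            maps = {"p": structio.identity_map(model, "A", "p")}
            xl = CrossLink("m", ResidueRef("p", 1, "K"), ResidueRef("p", 2, "K"), "BS2G")
            seen.append(rank[xlinkmap.assess(xl, model, maps).status])
        assert seen == sorted(seen)


class TestConstraintScore:
    def test_sum_matches_per_link_brute_force(self, compact_chain, compact_chain_map):
        links, _truth = synthetic_data.gen_crosslink_set(
            compact_chain, "BS2G", 2, 2, 1, seed=23
        )
        total, table = xlinkmap.constraint_score(compact_chain, links, compact_chain_map)
        # independent route: per-link distances and hand-applied penalty
        expected = 0.0
        for xl in links:
            d = structio.ca_distance(
                compact_chain, ("A", xl.site_a.position), ("A", xl.site_b.position)
            )
            tol = 26.0  # BS2G K-K base-tolerance bound
            expected += max(0.0, (d - tol)) ** 2
        assert total == pytest.approx(expected)
        assert len(table) == len(links)

    def test_all_within_scores_zero(self, compact_chain, compact_chain_map):
        links, _ = synthetic_data.gen_crosslink_set(compact_chain, "BS2G", 3, 0, 0, seed=2)
        total, _ = xlinkmap.constraint_score(compact_chain, links, compact_chain_map)
        assert total == 0.0

    def test_no_mappable_links_raises(self, compact_chain):
        xl = CrossLink("x", ResidueRef("p", 1, "K"), ResidueRef("p", 2, "K"), "BS2G")
        with pytest.raises(EmptyScoreError):
            xlinkmap.constraint_score(compact_chain, [xl], {})


class TestWriteConstraints:
    def test_emitted_line_md_bound(self, compact_chain, compact_chain_map):
        xl = CrossLink(
            "c", ResidueRef("synthetic", 10, "K"), ResidueRef("synthetic", 40, "K"), "BS2G"
        )
        text, skipped = write_constraints(
            [xl], compact_chain_map, bound_mode="md"
        )
        assert skipped == 0
        assert text.strip().endswith("FLAT_HARMONIC 0.0 1.0 34.0")
        assert text.startswith("AtomPair CA 10 A CA 40 A")

    def test_round_trip_identity(self, compact_chain, compact_chain_map):
        links, _ = synthetic_data.gen_crosslink_set(compact_chain, "BS2G", 2, 2, 2, seed=4)
        text, _ = write_constraints(links, compact_chain_map, bound_mode="base")
        parsed = parse_constraints(text)
        assert len(parsed) == len(links)
        for rec in parsed:
            assert rec["params"] == FlatHarmonicParams(tol=26.0, x0=0.0, sd=1.0)

    def test_override_passthrough(self, compact_chain, compact_chain_map):
        xl = CrossLink(
            "c", ResidueRef("synthetic", 10, "K"), ResidueRef("synthetic", 40, "K"), "BS2G"
        )
        text, _ = write_constraints(
            [xl], compact_chain_map,
            overrides={"c": FlatHarmonicParams(tol=26.0, sd=2.0)},
        )
        assert text.strip().endswith("FLAT_HARMONIC 0.0 2.0 26.0")

    def test_empty_set(self, compact_chain_map):
        text, skipped = write_constraints([], compact_chain_map)
        assert text == ""
        assert skipped == 0

    def test_unmappable_links_skipped_and_counted(self, compact_chain_map):
        xl = CrossLink("u", ResidueRef("ghost", 1, "K"), ResidueRef("ghost", 9, "K"), "BS2G")
        text, skipped = write_constraints([xl], compact_chain_map)
        assert text == ""
        assert skipped == 1


class TestNonredundant:
    def test_pair_symmetry_collapses(self):
        mk = lambda i, a, b: CrossLink(
            f"o{i}", ResidueRef("A", a, "K"), ResidueRef("A", b, "K"), "BS2G"
        )
        xls = [mk(1, 10, 20), mk(2, 20, 10), mk(3, 10, 30)]
        out = nonredundant(xls)
        assert len(out) == 2
        assert out[0].evidence_count == 2

    def test_empty_input(self):
        assert nonredundant([]) == []

    def test_47_observations_collapse_to_26_planted_pairs(self, compact_chain):
        links, _ = synthetic_data.gen_crosslink_set(compact_chain, "BS2G", 10, 10, 6, seed=9)
        assert len(links) == 26
        obs = synthetic_data.gen_redundant_observations(links, 47, seed=1)
        assert len(obs) == 47
        assert len(nonredundant(obs)) == 26

    def test_order_insensitive(self, compact_chain):
        links, _ = synthetic_data.gen_crosslink_set(compact_chain, "BS2G", 3, 3, 2, seed=6)
        obs = synthetic_data.gen_redundant_observations(links, 20, seed=2)
        a = [xl.pair_key for xl in nonredundant(obs)]
        b = [xl.pair_key for xl in nonredundant(obs[::-1])]
        assert a == b


class TestSelectModels:
    def test_shared_leaders(self):
        rows = [
            ScoreRow("m1", -10.0, 0.0),
            ScoreRow("m2", -9.0, 1.0),
            ScoreRow("m3", -1.0, 9.0),
            ScoreRow("m4", -0.5, 8.0),
            ScoreRow("m5", 0.0, 7.0),
        ]
        assert select_models(rows, 2) == ["m1", "m2"]

    def test_disjoint_rankings_give_empty_set(self):
        rows = [ScoreRow("a", 0.0, 5.0), ScoreRow("b", 5.0, 0.0)]
        assert select_models(rows, 1) == []

    def test_against_double_sort_oracle(self):
        rng = np.random.default_rng(17)
        rows = [
            ScoreRow(f"m{i:03d}", float(rng.normal()), float(rng.normal()))
            for i in range(800)
        ]
        picked = select_models(rows, 20)
        top_total = {
            r.model_id for r in sorted(rows, key=lambda r: (r.total_score, r.model_id))[:20]
        }
        top_cst = {
            r.model_id
            for r in sorted(rows, key=lambda r: (r.constraint_score, r.model_id))[:20]
        }
        assert set(picked) == top_total & top_cst


class TestCrosslinkTableIO:
    def test_round_trip(self, tmp_path, compact_chain):
        links, _ = synthetic_data.gen_crosslink_set(compact_chain, "BS2G", 2, 2, 2, seed=3)
        path = tmp_path / "links.tsv"
        xlinkmap.write_crosslinks(links, path)
        back = xlinkmap.read_crosslinks(path)
        assert [x.pair_key for x in back] == [x.pair_key for x in links]
        assert [x.linker_name for x in back] == [x.linker_name for x in links]
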