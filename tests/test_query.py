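"""Query execution, result algebra, links, plot tables and the grammar."""

import numpy as np
import pandas as pd
import pytest

import padelql as pql
from padelql import query as q
from padelql.expressions import ExpressionError, compile_expression

import oracle


def extra_corpus_defs():
    """Predicates beyond the built-in ten, paired with oracle keys."""
    return {
        "p_bottom_wins": q.QueryDef(
            "bottom_wins", "point",
            lambda p: bool(p.winner) and p.winner.name == "Bottom"),
        "p_salazar_back": q.QueryDef(
            "salazar_near_back_wall", "shot",
            "like('by-salazar') and hitter.distance_to_back_wall < 3"),
    }


def result_keys(result):
    return {p.start_frame for p in result.provenance}


class TestExecuteAgainstOracle:
    @pytest.mark.parametrize("qid", ["q1", "q2", "q3", "q4", "q5", "q6",
                                     "q7a", "q7b", "q8", "q9", "q10"])
    def test_builtin_queries_equal_flat_scan(self, qid, small_corpus):
        qdef, attribs = q.builtin_catalog()[qid]
        for bundle, match in small_corpus:
            got = result_keys(q.execute(qdef, match, attribs))
            assert got == oracle.expected_keys(bundle, qid), qid

    @pytest.mark.parametrize("pid", ["p_bottom_wins", "p_salazar_back"])
    def test_extra_predicates_equal_flat_scan(self, pid, small_corpus):
        qdef = extra_corpus_defs()[pid]
        for bundle, match in small_corpus:
            got = result_keys(q.execute(qdef, match, []))
            assert got == oracle.expected_keys(bundle, pid), pid

    def test_q3_row_count_is_shots_minus_points(self, small_corpus):
        qdef, attribs = q.builtin_catalog()["q3"]
        for bundle, match in small_corpus:
            r = q.execute(qdef, match, attribs)
            assert len(r) == len(bundle.shots) - len(bundle.points)

    def test_q4_on_worked_example(self, fixture_match):
        qdef, attribs = q.builtin_catalog()["q4"]
        r = q.execute(qdef, fixture_match, attribs)
        assert len(r) == 1
        assert r.df["hitter.last_name"].iloc[0] == "Sainz"

    def test_q10_short_rally_yields_no_row_no_error(self, fixture_match):
        # the worked example has one 5-shot rally and four shotless ones
        qdef, attribs = q.builtin_catalog()["q10"]
        r = q.execute(qdef, fixture_match, attribs)
        assert len(r) == 0
        assert r.columns == [pql.AttributeSpec.coerce(a).alias
                             for a in attribs]


class TestExecuteSemantics:
    def test_constant_false_keeps_columns(self, synth_match):
        qdef = q.QueryDef("none", "shot", lambda s: False)
        r = q.execute(qdef, synth_match, ["hitter.last_name", "duration"])
        assert len(r) == 0
        assert r.columns == ["hitter.last_name", "duration"]

    def test_absent_attribute_becomes_null(self, synth_match):
        qdef = q.QueryDef("all", "shot", lambda s: True)
        r = q.execute(qdef, synth_match, ["duration"])
        # the last shot of every rally has no duration
        n_points = len(list(synth_match.iter_units("point")))
        assert int(r.df["duration"].isna().sum()) == n_points

    def test_scope_additivity(self, small_corpus):
        (_, m1), (_, m2) = small_corpus[:2]
        qdef, attribs = q.builtin_catalog()["q3"]
        both = q.execute(qdef, [m1, m2], attribs)
        parts = q.concat([q.execute(qdef, m1, attribs),
                          q.execute(qdef, m2, attribs)])
        assert both.df.equals(parts.df)

    def test_deterministic_csv_export(self, synth_match):
        qdef, attribs = q.builtin_catalog()["q1"]
        a = q.execute(qdef, synth_match, attribs).to_csv(None, links=True)
        b = q.execute(qdef, synth_match, attribs).to_csv(None, links=True)
        assert a == b

    def test_unresolvable_attribute_names_level(self, synth_match):
        qdef = q.QueryDef("all", "shot", lambda s: True)
        with pytest.raises(RuntimeError, match="nonexistent_thing"):
            q.execute(qdef, synth_match, ["nonexistent_thing.x"])

    def test_predicate_error_carries_provenance(self, synth_match):
        qdef = q.QueryDef("boom", "shot", lambda s: 1 / 0)
        with pytest.raises(RuntimeError, match="boom"):
            q.execute(qdef, synth_match, [])


class TestResultAlgebra:
    def test_analyze_single_row(self):
        r = q.QueryResult(pd.DataFrame({"v": [2.0]}))
        summary = r.analyze()
        assert summary.loc["v", "mean"] == 2.0
        assert summary.loc["v", "std"] == 0.0

    def test_analyze_mean_matches_brute_force(self, small_corpus):
        bundle, match = small_corpus[0]
        qdef, attribs = q.builtin_catalog()["q3"]
        r = q.execute(qdef, match, attribs)
        sf = oracle.shot_features(bundle)
        brute = sf.loc[sf["has_next"], "duration"].mean()
        assert r.analyze().loc["duration", "mean"] == pytest.approx(brute)

    def test_analyze_empty_warns(self):
        r = q.QueryResult(pd.DataFrame())
        with pytest.warns(UserWarning):
            assert len(r.analyze()) == 0

    def test_sum_by_toy_example(self):
        r = q.QueryResult(pd.DataFrame(
            {"point": ["p1", "p1", "p2"], "v": [1.0, 2.0, 4.0]}))
        g = r.sum_by("point")
        assert list(g.df["point"]) == ["p1", "p2"]
        assert list(g.df["v"]) == [3.0, 4.0]

    def test_sum_by_missing_key_errors(self):
        with pytest.raises(KeyError):
            q.QueryResult(pd.DataFrame({"v": [1]})).sum_by("nope")

    def test_frame_durations_group_to_point_durations(self, synth_match):
        qdef, attribs = q.builtin_catalog()["q8"]
        per_point = q.execute(qdef, synth_match, attribs).sum_by("point")
        durations = {p.id: p.duration
                     for p in synth_match.iter_units("point")}
        frame_time = 1.0 / synth_match.video.fps
        for _, row in per_point.df.iterrows():
            assert abs(row["duration"] - durations[row["point"]]) \
                <= frame_time + 1e-9

    def test_add_column_then_concat(self):
        r1 = q.QueryResult(pd.DataFrame({"v": [1.0, 2.0]}))
        r2 = q.QueryResult(pd.DataFrame({"v": [3.0, 4.0]}))
        r1 = r1.add_column("Team", "Point Winner")
        r2 = r2.addColumn("Team", "Point Loser")
        both = q.concat([r1, r2], "Time on the net")
        assert len(both) == 4
        assert list(both.df["Team"]) == ["Point Winner"] * 2 \
            + ["Point Loser"] * 2

    def test_concat_single_is_identity(self):
        r = q.QueryResult(pd.DataFrame({"v": [1.0]}))
        assert q.concat([r]).df.equals(r.df)

    def test_concat_rejects_column_mismatch(self):
        r1 = q.QueryResult(pd.DataFrame({"a": [1]}))
        r2 = q.QueryResult(pd.DataFrame({"b": [1]}))
        with pytest.raises(ValueError, match="difference"):
            q.concat([r1, r2])


class TestVideoLinks:
    def test_offset_is_floor_of_seconds(self, fixture_match):
        link = q.video_link(fixture_match, 13606)
        assert link.endswith("t=453")        # 13606 // 30

    def test_frame_zero(self, fixture_match):
        assert q.video_link(fixture_match, 0).endswith("t=0")

    def test_offsets_nondecreasing_across_a_result(self, synth_match):
        qdef, attribs = q.builtin_catalog()["q3"]
        r = q.execute(qdef, synth_match, attribs)
        offsets = [int(l.rsplit("t=", 1)[1]) for l in r.links]
        assert offsets == sorted(offsets)

    def test_missing_video_gives_null_link(self, small_corpus):
        from conftest import assemble_bundle
        bundle, _ = small_corpus[0]
        match = assemble_bundle(bundle, video_url=None)
        assert q.video_link(match, 100) is None


class TestPlotData:
    def test_directions_one_row_per_non_last_shot(self, fixture_match):
        qdef, attribs = q.builtin_catalog()["q1"]
        r = q.execute(qdef, fixture_match, attribs)
        plot = q.plot_data(r, "directions", color="angle")
        # the worked example has one volley, and it ends the rally
        assert len(plot["data"]) == \
            int(r.df["next.hitter.position.x"].notna().sum())
        assert "court" in plot

    def test_positions_single_row(self):
        r = q.QueryResult(pd.DataFrame({"hitter.position.x": [2.5],
                                        "hitter.position.y": [1.6]}))
        plot = q.plot_data(r, "positions")
        assert plot["data"].iloc[0].tolist() == [2.5, 1.6]
        assert plot["court"]["net"] == [(0, 10.0), (10.0, 10.0)]

    def test_histogram_counts_conserve_rows(self, synth_match):
        qdef, attribs = q.builtin_catalog()["q3"]
        r = q.execute(qdef, synth_match, attribs)
        plot = q.plot_data(r, "histogram", column="duration", bins=7)
        assert int(plot["data"]["count"].sum()) == len(r)

    def test_missing_mapping_errors(self):
        r = q.QueryResult(pd.DataFrame({"a": [1]}))
        with pytest.raises(KeyError, match="bar_chart"):
            q.plot_data(r, "bar_chart", x="a", y="nope")
        with pytest.raises(ValueError, match="kind"):
            q.plot_data(r, "sparkline")


class TestExpressionGrammar:
    def test_player_resolution_by_last_name(self, synth_match):
        qdef, _ = q.builtin_catalog()["q8"]
        r = q.execute(qdef, synth_match,
                      [("salazar.distance_from_prev_frame", "distance")])
        frames = list(synth_match.iter_units("frame"))
        player = synth_match.player_by_last_name("Salazar")
        expected = pql.bind(player, frames[3]).distance_from_prev_frame
        assert r.df["distance"].iloc[3] == pytest.approx(expected)

    def test_expression_predicate_equals_function_predicate(self, synth_match):
        fn = q.builtin_catalog()["q2"][0]
        ex = q.QueryDef("q2_expr", "shot",
                        "one_of('vd,vr') and duration < 1 and abs_angle < 8")
        assert result_keys(q.execute(fn, synth_match, [])) == \
            result_keys(q.execute(ex, synth_match, []))

    @pytest.mark.parametrize("bad", [
        "shots[0]",
        "[a for a in b]",
        "lambda x: x",
        "{'a': 1}",
        "x if y else z",
        "(a := 3)",
    ])
    def test_out_of_grammar_rejected(self, bad):
        with pytest.raises(ExpressionError):
            compile_expression(bad)

    def test_unknown_root_names_item_level(self, synth_match):
        expr = compile_expression("no_such_symbol > 1")
        shot = next(iter(synth_match.iter_units("shot")))
        with pytest.raises(ExpressionError, match="shot"):
            expr.evaluate(shot)

    def test_helpers_resolve_last(self, synth_match):
        expr = compile_expression("net_zone(hitter)")
        shot = next(iter(synth_match.iter_units("shot")))
        val = expr.evaluate(shot,
                            {"net_zone": lambda bp: bp.distance_to_net < 4})
        assert val in (True, False)
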