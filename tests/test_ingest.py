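"""Table readers, fps inference, the scoring automaton and assembly."""

import io

import pandas as pd
import pytest

import padelql as pql
from padelql import ingest as ing
from padelql.scoring import ScoreKeeper, detect_mode, score_automaton


class TestReaders:
    def test_points_first_row(self, fixture_records):
        points, _, _ = fixture_records
        r = points[0]
        assert (r.start, r.end, r.duration_frames, r.winner) == \
            (13606, 13820, 214, "B")
        assert r.duration_seconds == pytest.approx(7.1)
        assert r.corner_names["BL"] == "A Sánchez"

    def test_shot_and_frame_rows(self, fixture_records):
        _, shots, frames = fixture_records
        assert shots[0].frame == 13604 and shots[0].corner == "TL"
        assert shots[1].lob is True
        assert frames[0].court["BL"] == (2.50, 1.60)
        assert frames[0].image["TL"] == (478, 202)

    def test_empty_file_with_header(self):
        empty = io.StringIO("Frame,Player,Shot Type,Lob\n")
        assert ing.read_shots(empty) == []

    def test_missing_column_is_schema_error(self):
        bad = io.StringIO("Frame,Shot Type\n10,s\n")
        with pytest.raises(ing.SchemaError, match="missing required column"):
            ing.read_shots(bad)

    def test_unparsable_cell_reports_row(self):
        bad = io.StringIO("Frame,Player,Shot Type,Lob\nxx,TL,s,F\n")
        with pytest.raises(ing.SchemaError, match="row 1"):
            ing.read_shots(bad)

    def test_roundtrip_canonical_tables(self, synth_bundle):
        text = synth_bundle.shots.to_csv(index=False)
        records = ing.read_shots(io.StringIO(text))
        again = ing.shots_to_df(records).to_csv(index=False)
        assert again == text


class TestFpsInference:
    def test_worked_example_is_30(self, fixture_records):
        points, _, _ = fixture_records
        est = ing.infer_fps(points)
        assert est.fps == 30

    def test_single_record(self):
        rec = ing.PointRecord(0, 300, 300, 10.0, "T", "", "", {})
        assert ing.infer_fps([rec]).fps == 30

    def test_returned_fps_is_globally_optimal(self, fixture_records):
        points, _, _ = fixture_records
        est = ing.infer_fps(points)
        for fps in range(1, 241):
            resid = sum(abs(p.duration_frames / fps - p.duration_seconds)
                        for p in points)
            assert est.residual <= resid + 1e-12

    def test_scale_consistency(self, fixture_records):
        points, _, _ = fixture_records
        doubled = [ing.PointRecord(p.start * 2, p.end * 2,
                                   p.duration_frames * 2, p.duration_seconds,
                                   p.winner, p.points_a, p.points_b,
                                   p.corner_names) for p in points]
        assert ing.infer_fps(doubled).fps == 2 * ing.infer_fps(points).fps

    def test_no_usable_record_errors(self):
        rec = ing.PointRecord(0, 300, 300, None, "T", "", "", {})
        with pytest.raises(ing.SchemaError, match="fps"):
            ing.infer_fps([rec])


class TestScoreAutomaton:
    def test_worked_example_progression(self):
        states, games, sets = score_automaton(list("BTTBB"))
        assert [s.labels for s in states] == [
            ("0", "15"), ("15", "15"), ("30", "15"), ("30", "30"),
            ("30", "40")]
        assert games == [(0, 4)]

    def test_four_straight_points_win_a_game(self):
        states, games, _ = score_automaton(list("TTTT"))
        assert states[-1].game_winner == "T"
        assert states[-1].labels == ("0", "0")
        assert states[-1].games_A == 1
        assert games == [(0, 3)]

    def test_advantage_mode_hand_traced(self):
        # reach 30-30 with TTBB, then trade deuce/advantage three times and
        # let T convert the fourth advantage:
        # 40-30, 40-40, Ad-40, 40-40, Ad-40, 40-40, Ad-40, game T
        winners = list("TTBB") + list("TBTBTBTT")
        states, _, _ = score_automaton(winners, "advantage")
        tail = [s.labels for s in states[4:]]
        assert tail == [("40", "30"), ("40", "40"), ("Ad", "40"),
                        ("40", "40"), ("Ad", "40"), ("40", "40"),
                        ("Ad", "40"), ("0", "0")]
        assert states[-1].game_winner == "T"

    def test_golden_point_decides_at_deuce(self):
        winners = list("TTBBTBB")       # 40-40 after six, then B wins
        states, _, _ = score_automaton(winners, "golden_point")
        assert states[5].labels == ("40", "40")
        assert states[6].game_winner == "B"

    def test_set_needs_two_clear_games_or_seventh(self):
        def play_games(seq):
            return [w for w in seq for _ in range(4)]
        states, _, _ = score_automaton(play_games("TBTBTBTBTBTT"), "advantage")
        assert states[-1].set_winner == "T"      # 7-5
        states, _, sets = score_automaton(play_games("TBTBTBTBTBTBT"),
                                          "advantage")
        assert states[-1].set_winner == "T"      # 7-6 via deciding game
        assert len(sets) == 1

    def test_mode_detection_prefers_the_generating_mode(self):
        winners = list("TTBBTB") * 3
        for mode in ("advantage", "golden_point"):
            states, _, _ = score_automaton(winners, mode)
            detected, misses = detect_mode(winners,
                                           [s.labels for s in states])
            assert detected == mode
            assert misses == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            score_automaton([])


class TestAssembly:
    def test_fixture_structure(self, fixture_match):
        points = list(fixture_match.iter_units("point"))
        games = list(fixture_match.iter_units("game"))
        assert len(points) == 5
        assert len(games) >= 1
        assert len(points[0].shots) == 5

    def test_fixture_scores_replay_printed_columns(self, fixture_records):
        points, _, _ = fixture_records
        states, _, _ = score_automaton([p.winner for p in points])
        assert [s.labels for s in states] == \
            [(p.points_a, p.points_b) for p in points]

    def test_serve_outside_span_is_clamped(self, fixture_match):
        serve = list(fixture_match.iter_units("shot"))[0]
        point = serve.point
        # the annotated serve frame (13,604) precedes the printed rally
        # start (13,606); attachment clamps it into the rally
        assert serve.start_frame == point.start_frame == 13606

    def test_empty_shots_table_gives_shotless_points(self, fixture_records):
        points, _, frames = fixture_records
        m = ing.assemble_match(points, [], frames)
        assert all(len(p.shots) == 0 for p in m.iter_units("point"))
        rep = ing.validate(m)
        assert rep.ok and len(rep.warnings) >= 5

    def test_strict_mode_rejects_divergent_scores(self, fixture_records):
        points, shots, frames = fixture_records
        broken = list(points)
        p = broken[2]
        broken[2] = ing.PointRecord(p.start, p.end, p.duration_frames,
                                    p.duration_seconds, p.winner, "40", "0",
                                    p.corner_names)
        with pytest.raises(ing.SchemaError, match="point 3"):
            ing.assemble_match(broken, shots, frames,
                               ing.IngestConfig(strict=True,
                                                scoring_mode="advantage"))

    def test_shot_in_no_rally_errors(self, fixture_records):
        points, shots, frames = fixture_records
        stray = ing.ShotRecord(frame=99999, corner="TL", shot_code="d",
                               lob=False)
        with pytest.raises(ing.SchemaError, match="no rally"):
            ing.assemble_match(points, list(shots) + [stray], frames)

    def test_forehand_backhand_sides(self, synth_match):
        for team in synth_match.teams:
            assert team.forehand_player is not team.backhand_player
            assert team.forehand_player in team


class TestValidate:
    def test_fixture_validates_without_errors(self, fixture_match):
        assert ing.validate(fixture_match).ok

    def test_synthetic_matches_validate_clean(self, small_corpus):
        for _, match in small_corpus:
            rep = ing.validate(match)
            assert rep.ok and not rep.warnings

    def test_displaced_frame_breaks_containment(self, fixture_records):
        points, shots, frames = fixture_records
        m = ing.assemble_match(points, shots, frames)
        frame = next(iter(m.iter_units("frame")))
        frame.start_frame = frame.frame_number = 10 ** 7
        frame.end_frame = 10 ** 7 + 1
        rep = ing.validate(m)
        assert any("containment" in e for e in rep.errors)

    def test_out_of_court_position_is_flagged(self, fixture_records):
        points, shots, frames = fixture_records
        m = ing.assemble_match(points, shots, frames)
        frame = next(iter(m.iter_units("frame")))
        player = next(iter(frame.positions))
        frame.positions[player] = (25.0, -3.0)
        rep = ing.validate(m)
        assert any("outside the court" in e for e in rep.errors)


class TestBundleIO:
    def test_save_and_load_roundtrip(self, synth_bundle, tmp_path):
        out = ing.save_bundle(tmp_path / "b", synth_bundle.points,
                              synth_bundle.shots, synth_bundle.frames,
                              {"title": "demo", "fps": 30,
                               "video_url": "https://v.example/x"})
        match = ing.load_bundle(out)
        assert match.title == "demo"
        assert match.video.fps == 30
        assert len(list(match.iter_units("point"))) == len(synth_bundle.points)
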