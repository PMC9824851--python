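"""Distances, speeds and shot-direction angles."""

import math

import numpy as np
import pandas as pd
import pytest

import padelql as pql
from padelql import ingest as ing
from padelql.kinematics import oriented_wall_distances, shot_direction


def build_match(frame_positions, shots=(), n_frames=60, fps=30):
    """Assemble a one-rally match from per-corner position functions.

    ``frame_positions`` maps corner -> callable(frame_index) -> (x, y).
    """
    points = pd.DataFrame([[0, n_frames, n_frames, round(n_frames / fps, 1),
                            "B", "0", "15",
                            "T One", "U Two", "B Three", "C Four"]],
                          columns=ing.POINTS_COLUMNS)
    default_shots = [[0, "BL", "s", "F"], [n_frames // 2, "TL", "d", "F"]]
    shots_df = pd.DataFrame(list(shots) or default_shots,
                            columns=ing.SHOTS_COLUMNS)
    rows = []
    for f in range(n_frames):
        row = [f] + [0] * 8
        for c in ("TL", "TR", "BL", "BR"):
            row.extend(frame_positions[c](f))
        rows.append(row)
    frames_df = pd.DataFrame(rows, columns=ing.FRAMES_COLUMNS)
    return ing.assemble_match(
        ing.read_points(points.astype(str)),
        ing.read_shots(shots_df.astype(str)),
        ing.read_frames(frames_df.astype(str)),
        ing.IngestConfig(fps=fps))


STATIC = {"TL": lambda f: (2.0, 18.0), "TR": lambda f: (8.0, 18.0),
          "BL": lambda f: (2.0, 2.0), "BR": lambda f: (8.0, 2.0)}


class TestDistances:
    def test_net_distance_from_printed_frame(self, fixture_match):
        frame = next(iter(fixture_match.iter_units("frame")))
        bl = fixture_match.player_by_last_name("Sánchez")
        assert frame.distance_to_net(bl) == pytest.approx(8.40)

    def test_player_on_the_net_line(self):
        pos = dict(STATIC)
        pos["BL"] = lambda f: (5.0, 10.0)
        m = build_match(pos)
        bp = pql.bind(m.player_by_last_name("Three"),
                      next(iter(m.iter_units("frame"))))
        assert bp.distance_to_net == 0.0

    def test_oriented_walls_bottom_player(self, fixture_match):
        frame = next(iter(fixture_match.iter_units("frame")))
        br = pql.bind(fixture_match.player_by_last_name("Salazar"), frame)
        back, side, right, left = oriented_wall_distances(br)
        assert right == pytest.approx(10 - 7.87)
        assert back == pytest.approx(1.66)
        assert side == pytest.approx(2.13)
        assert left == pytest.approx(7.87)

    def test_oriented_walls_top_player(self, fixture_match):
        frame = next(iter(fixture_match.iter_units("frame")))
        tl = pql.bind(fixture_match.player_by_last_name("Sainz"), frame)
        # top players face -y: their right wall is x=0
        assert tl.distance_to_right_wall == pytest.approx(1.89)
        assert tl.distance_to_back_wall == pytest.approx(20 - 18.53)
        assert tl.distance_to_backwall == tl.distance_to_back_wall

    def test_left_plus_right_is_court_width(self, synth_match):
        geo = synth_match.geometry
        for frame in list(synth_match.iter_units("frame"))[::37]:
            for player in frame.players:
                bp = pql.bind(player, frame)
                assert bp.distance_to_left_wall + bp.distance_to_right_wall \
                    == pytest.approx(geo.width)
                assert bp.distance_to_side_wall == pytest.approx(
                    min(bp.distance_to_left_wall, bp.distance_to_right_wall))

    def test_unbound_player_is_rejected_by_ops(self):
        with pytest.raises(TypeError, match="frame context"):
            pql.distance_to_net(pql.Player("A", "B"))


class TestSpeed:
    def test_stationary_player(self):
        m = build_match(STATIC)
        f = list(m.iter_units("frame"))[20]
        v = pql.bind(m.player_by_last_name("One"), f).speed
        assert (v.x, v.y) == (0.0, 0.0)

    def test_constant_velocity_recovered(self):
        pos = dict(STATIC)
        pos["BL"] = lambda f: (2.0, 1.0 + 2.0 * f / 30.0)   # +2 m/s along y
        m = build_match(pos)
        f = list(m.iter_units("frame"))[20]
        bp = pql.bind(m.player_by_last_name("Three"), f)
        assert bp.speed.y == pytest.approx(2.0, abs=1e-9)
        assert bp.speed.x == pytest.approx(0.0, abs=1e-9)
        assert bp.acceleration.magnitude == pytest.approx(0.0, abs=1e-9)

    def test_window_truncates_at_rally_boundaries(self):
        pos = dict(STATIC)
        pos["BL"] = lambda f: (2.0, 1.0 + 2.0 * f / 30.0)
        m = build_match(pos)
        first = list(m.iter_units("frame"))[0]
        bp = pql.bind(m.player_by_last_name("Three"), first)
        assert bp.speed.y == pytest.approx(2.0, abs=1e-9)

    def test_speed_bounded_by_generator_cap(self, synth_bundle, synth_match):
        cap = synth_bundle.config.max_speed_mps
        for frame in list(synth_match.iter_units("frame"))[::53]:
            for player in frame.players:
                v = pql.bind(player, frame).speed
                assert v.magnitude <= cap + 0.2   # 2-decimal table rounding


class TestStepDistance:
    def test_printed_consecutive_frames(self, fixture_match):
        frames = list(fixture_match.iter_units("frame"))
        bl = fixture_match.player_by_last_name("Sánchez")
        # BL moves (2.50,1.60) -> (2.50,1.59) between 13,614 and 13,615
        assert pql.bind(bl, frames[1]).distance_from_prev_frame == \
            pytest.approx(0.01)

    def test_zero_at_rally_start(self, fixture_match):
        frames = list(fixture_match.iter_units("frame"))
        bl = fixture_match.player_by_last_name("Sánchez")
        assert pql.bind(bl, frames[0]).distance_from_prev_frame == 0.0

    def test_steps_sum_to_path_length(self, synth_bundle, synth_match):
        point = list(synth_match.iter_units("point"))[0]
        player = point.shots[0].hitter_player
        total = sum(pql.bind(player, f).distance_from_prev_frame
                    for f in point.frames)
        xy = np.array([f.position_of(player) for f in point.frames])
        brute = float(np.sum(np.hypot(*np.diff(xy, axis=0).T)))
        assert total == pytest.approx(brute)


class TestShotDirection:
    def test_straight_down_the_line_is_zero(self):
        pos = dict(STATIC)
        pos["BL"] = lambda f: (2.5, 1.6)
        pos["TL"] = lambda f: (2.5, 18.5)
        m = build_match(pos)
        serve = list(m.iter_units("shot"))[0]
        d = shot_direction(serve)
        assert d.angle == pytest.approx(0.0)
        assert d.abs_angle == pytest.approx(0.0)

    def test_diagonal_angle_by_hand_trigonometry(self):
        pos = dict(STATIC)
        pos["BL"] = lambda f: (2.0, 2.0)
        pos["TL"] = lambda f: (8.0, 14.0)
        m = build_match(pos)
        serve = list(m.iter_units("shot"))[0]
        d = shot_direction(serve)
        assert d.abs_angle == pytest.approx(math.degrees(math.atan(6 / 12)))
        assert d.angle > 0    # toward a bottom hitter's right (+x)

    def test_last_shot_has_no_direction(self, synth_match):
        point = list(synth_match.iter_units("point"))[0]
        last = point.shots[-1]
        assert shot_direction(last) is pql.ABSENT
        assert last.duration is pql.ABSENT
        assert last.receiver is pql.ABSENT

    def test_mirror_antisymmetry(self, synth_match):
        geo = synth_match.geometry
        for shot in list(synth_match.iter_units("shot"))[:40]:
            d = shot_direction(shot)
            if d is pql.ABSENT:
                continue
            # mirror all x about the court midline by hand
            o = (geo.width - d.origin.x, d.origin.y)
            t = (geo.width - d.destination.x, d.destination.y)
            faces_up = d.origin.y < geo.net_y
            dx, dy = t[0] - o[0], t[1] - o[1]
            fwd = dy if faces_up else -dy
            rgt = dx if faces_up else -dx
            mirrored = math.degrees(math.atan2(rgt, fwd))
            assert mirrored == pytest.approx(-d.angle)
            assert abs(mirrored) == pytest.approx(d.abs_angle)

    def test_shot_angle_properties_delegate(self, synth_match):
        shot = next(s for s in synth_match.iter_units("shot")
                    if s.next is not pql.ABSENT)
        d = shot_direction(shot)
        assert shot.angle == d.angle
        assert shot.abs_angle == abs(d.angle)
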