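"""Spatial quantities for frame-bound players and shots.

All geometry lives in court space: x across the court (0..width), y along
it (0..length), net at ``net_y``.  Oriented distances are taken from the
player's point of view facing the net: for a player on the bottom half
(y < net_y) the right wall is x = width and the back wall y = 0; for a
player on the top half the roles flip.

Velocities and accelerations are central finite differences of position
over a +/-``window``-frame stencil (default 5 frames, about 0.33 s at
30 fps), truncated one-sided at rally boundaries; positions are never
differentiated across points.  Shot direction is the vector from the
hitter at the hit to the opponent who returns the ball at the return
(there is no ball track, so the receiver's position proxies the ball's
destination); its angle is 0 for a shot straight along the court's long
axis, positive toward the hitter's right, in (-180, 180] degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

from .model import ABSENT, Frame, Player

log = logging.getLogger(__name__)

DEFAULT_SPEED_WINDOW = 5


class Vec2(NamedTuple):
    x: float
    y: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.x, self.y)


@dataclass(frozen=True)
class ShotDirection:
    origin: Vec2
    destination: Vec2
    angle: float        # signed degrees, 0 = down the line, + = hitter's right
    abs_angle: float


class BoundPlayer:
    """A player identity attached to one frame of the video.

    Identity attributes (``last_name`` ...) pass through to the underlying
    :class:`Player`; positional and kinematic attributes are computed from
    the frames table.  Equality compares player identity only, ignoring
    the bound frame — required so that e.g. the serve returner can be
    compared with the hitter three shots later.
    """

    __slots__ = ("player", "frame")

    def __init__(self, player: Player, frame: Frame):
        self.player = player
        self.frame = frame

    # -- identity -----------------------------------------------------------
    def __getattr__(self, name: str):
        return getattr(self.player, name)

    def __eq__(self, other) -> bool:
        return getattr(other, "player", other) is self.player

    def __ne__(self, other) -> bool:
        return not self.__eq__(other)

    def __hash__(self) -> int:
        return hash(self.player)

    def __repr__(self) -> str:
        return f"BoundPlayer({self.player.name!r} @ {self.frame.frame_number})"

    # -- geometry -----------------------------------------------------------
    @property
    def _geometry(self):
        return self.frame.match.geometry

    @property
    def position(self) -> Vec2:
        return Vec2(*self.frame.position_of(self.player))

    @property
    def _faces_up(self) -> bool:
        """True if the player faces +y (bottom half of the court)."""
        geo = self._geometry
        y = self.position.y
        if y < geo.net_y:
            return True
        if y > geo.net_y:
            return False
        # exactly on the net line: fall back to the team's assembly-time half
        side = getattr(self.player.team, "side", None)
        if side is None:
            log.warning("player %s exactly on the net line and team side "
                        "unknown; assuming bottom half", self.player.last_name)
            return True
        return side == "bottom"

    @property
    def distance_to_net(self) -> float:
        geo = self._geometry
        return abs(self.position.y - geo.net_y)

    @property
    def distance_to_back_wall(self) -> float:
        geo = self._geometry
        y = self.position.y
        return y if self._faces_up else geo.length - y

    # both spellings occur in practice
    distance_to_backwall = distance_to_back_wall

    @property
    def distance_to_right_wall(self) -> float:
        geo = self._geometry
        x = self.position.x
        return geo.width - x if self._faces_up else x

    @property
    def distance_to_left_wall(self) -> float:
        return self._geometry.width - self.distance_to_right_wall

    @property
    def distance_to_side_wall(self) -> float:
        return min(self.distance_to_right_wall, self.distance_to_left_wall)

    # -- kinematics ---------------------------------------------------------
    @property
    def _point_frames(self) -> list[Frame]:
        point = self.frame.point
        if point is ABSENT:
            return [self.frame]
        return point.frames

    @property
    def _index_in_point(self) -> int:
        idx = getattr(self.frame, "_point_index", None)
        if idx is None:
            idx = self._point_frames.index(self.frame)
        return idx

    def _pos_at(self, frame: Frame) -> Vec2:
        return Vec2(*frame.position_of(self.player))

    def speed_with_window(self, window: int = DEFAULT_SPEED_WINDOW) -> Vec2:
        frames = self._point_frames
        i = self._index_in_point
        j0, j1 = max(0, i - window), min(len(frames) - 1, i + window)
        if j0 == j1:
            log.warning("speed undefined on a single-frame rally; returning 0")
            return Vec2(0.0, 0.0)
        p0, p1 = self._pos_at(frames[j0]), self._pos_at(frames[j1])
        dt = frames[j1].time - frames[j0].time
        return Vec2((p1.x - p0.x) / dt, (p1.y - p0.y) / dt)

    @property
    def speed(self) -> Vec2:
        return self.speed_with_window()

    def acceleration_with_window(self, window: int = DEFAULT_SPEED_WINDOW) -> Vec2:
        frames = self._point_frames
        i = self._index_in_point
        j0, j1 = max(0, i - window), min(len(frames) - 1, i + window)
        if j0 == j1:
            return Vec2(0.0, 0.0)
        v0 = BoundPlayer(self.player, frames[j0]).speed_with_window(window)
        v1 = BoundPlayer(self.player, frames[j1]).speed_with_window(window)
        dt = frames[j1].time - frames[j0].time
        return Vec2((v1.x - v0.x) / dt, (v1.y - v0.y) / dt)

    @property
    def acceleration(self) -> Vec2:
        return self.acceleration_with_window()

    @property
    def distance_from_prev_frame(self) -> float:
        """Euclidean step from the previous frame of the same rally;
        0 at the rally's first frame."""
        frames = self._point_frames
        i = self._index_in_point
        if i == 0:
            return 0.0
        p0, p1 = self._pos_at(frames[i - 1]), self._pos_at(frames[i])
        return math.hypot(p1.x - p0.x, p1.y - p0.y)

    # -- play context -------------------------------------------------------
    @property
    def partner(self) -> "BoundPlayer":
        team = self.player.team
        other = (team.players[1] if team.players[0] is self.player
                 else team.players[0])
        return BoundPlayer(other, self.frame)

    @property
    def from_point_winning_team(self) -> bool:
        point = self.frame.point
        if point is ABSENT:
            return False
        winner = point.winner
        return bool(winner) and self.player in winner


# ---------------------------------------------------------------------------
# Function views of the operations above
# ---------------------------------------------------------------------------

def _require_bound(bp) -> BoundPlayer:
    if not isinstance(bp, BoundPlayer):
        raise TypeError(
            f"{bp!r} requires a frame context; bind the player to a frame")
    return bp


def distance_to_net(bp) -> float:
    return _require_bound(bp).distance_to_net


def oriented_wall_distances(bp) -> tuple[float, float, float, float]:
    """(back, side, right, left) wall distances from the player's view."""
    bp = _require_bound(bp)
    return (bp.distance_to_back_wall, bp.distance_to_side_wall,
            bp.distance_to_right_wall, bp.distance_to_left_wall)


def speed(bp, window: int = DEFAULT_SPEED_WINDOW) -> Vec2:
    return _require_bound(bp).speed_with_window(window)


def acceleration(bp, window: int = DEFAULT_SPEED_WINDOW) -> Vec2:
    return _require_bound(bp).acceleration_with_window(window)


def distance_from_prev_frame(bp) -> float:
    return _require_bound(bp).distance_from_prev_frame


def shot_direction(shot):
    """Direction of a shot, or Absent for the last shot of a rally
    (no return exists to estimate the destination from)."""
    nxt = shot.next
    if nxt is ABSENT:
        return ABSENT
    f0, f1 = shot.frame, nxt.frame
    if f0 is ABSENT or f1 is ABSENT:
        return ABSENT
    hitter = shot.hitter_player
    receiver = nxt.hitter_player
    try:
        origin = Vec2(*f0.position_of(hitter))
        dest = Vec2(*f1.position_of(receiver))
    except KeyError:
        return ABSENT
    geo = shot.match.geometry
    faces_up = origin.y < geo.net_y or (
        origin.y == geo.net_y and getattr(hitter.team, "side", "bottom") == "bottom")
    dx, dy = dest.x - origin.x, dest.y - origin.y
    forward = dy if faces_up else -dy
    rightward = dx if faces_up else -dx
    angle = math.degrees(math.atan2(rightward, forward))
    if angle <= -180.0:
        angle += 360.0
    return ShotDirection(origin=origin, destination=dest,
                         angle=angle, abs_angle=abs(angle))
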