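"""In-memory model of a video-recorded padel match.

A match is broken into nested temporal play units —
``Match > Set > Game > Point > Shot > Frame`` — each carrying a frame
interval on the source video, an ordinal within its parent and a dynamic
tag set.  Units can be navigated downwards (``match.sets``,
``point.shots``), upwards with skip levels (``frame.match`` is the same
object as ``frame.shot.point.game.set.match``) and sideways
(``shot.next`` / ``shot.prev``).

Off-end navigation never raises: it returns the :data:`ABSENT` sentinel,
which swallows any further attribute access and compares false against
everything, so a chained predicate such as
``shot.next.next.next.hitter.distance_to_net < 3`` simply evaluates to
``False`` on a short rally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .tags import TagSet

LEVELS = ("match", "set", "game", "point", "shot", "frame")
#: immediate child level for each level that has one
CHILD_LEVEL = {
    "match": "set",
    "set": "game",
    "game": "point",
    "point": "shot",
    "shot": "frame",
}
PLURAL = {
    "match": "matches",
    "set": "sets",
    "game": "games",
    "point": "points",
    "shot": "shots",
    "frame": "frames",
}


class NavigationError(AttributeError):
    """Raised for navigation requests outside the hierarchy contract."""


# ---------------------------------------------------------------------------
# Absent sentinel
# ---------------------------------------------------------------------------

class _AbsentType:
    """Null-propagating sentinel for missing units and attributes.

    Any attribute access or call on Absent yields Absent; Absent is falsy;
    every ordering comparison with Absent is ``False``; ``Absent == x`` is
    ``True`` only for Absent itself.  Arithmetic propagates Absent.
    """

    _instance: Optional["_AbsentType"] = None

    def __new__(cls) -> "_AbsentType":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __bool__(self) -> bool:
        return False

    def __getattr__(self, name: str):
        if name.startswith("__") and name.endswith("__"):
            raise AttributeError(name)
        return self

    def __call__(self, *args, **kwargs):
        return self

    def __iter__(self) -> Iterator:
        return iter(())

    def __eq__(self, other) -> bool:
        return other is self

    def __ne__(self, other) -> bool:
        return other is not self

    def __lt__(self, other) -> bool:
        return False

    __le__ = __gt__ = __ge__ = __lt__

    def __hash__(self) -> int:
        return hash("padelql.Absent")

    def _arith(self, *_) -> "_AbsentType":
        return self

    __add__ = __radd__ = __sub__ = __rsub__ = _arith
    __mul__ = __rmul__ = _arith
    __truediv__ = __rtruediv__ = _arith
    __neg__ = __abs__ = _arith

    def __repr__(self) -> str:
        return "Absent"


ABSENT = _AbsentType()


def is_absent(value) -> bool:
    return value is ABSENT


# ---------------------------------------------------------------------------
# Court, players, teams
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CourtGeometry:
    """Court reference frame: x across the court, y along it, net at mid-court.

    Defaults describe a regulation padel court (20 m x 10 m, net at y=10).
    All court-space positions downstream are interpreted in this frame.
    """

    width: float = 10.0
    length: float = 20.0
    net_y: Optional[float] = None

    def __post_init__(self):
        if self.net_y is None:
            object.__setattr__(self, "net_y", self.length / 2.0)


@dataclass(frozen=True)
class VideoInfo:
    url: Optional[str]
    fps: float


#: attributes that only exist once a player is bound to a frame
_FRAME_BOUND_ATTRS = frozenset({
    "position", "speed", "acceleration", "distance_to_net",
    "distance_to_back_wall", "distance_to_backwall", "distance_to_side_wall",
    "distance_to_right_wall", "distance_to_left_wall",
    "distance_from_prev_frame", "partner", "from_point_winning_team",
})


class Player:
    """A player's identity; positional state lives on :class:`BoundPlayer`.

    Accessing a frame-bound attribute (position, speed, wall distances...)
    on a bare Player yields :data:`ABSENT`, so predicates written against
    bound players degrade to ``False`` rather than raising when no frame
    data exists.
    """

    def __getattr__(self, name: str):
        if name in _FRAME_BOUND_ATTRS:
            return ABSENT
        raise AttributeError(
            f"Player has no attribute {name!r}")

    def __init__(self, first_name: str, last_name: str,
                 gender: Optional[str] = None, team: Optional["Team"] = None):
        self.first_name = first_name
        self.last_name = last_name
        self.gender = gender
        self.team = team

    @property
    def name(self) -> str:
        return f"{self.first_name} {self.last_name}".strip()

    def __eq__(self, other) -> bool:
        # a Player equals a BoundPlayer of the same identity, whatever the
        # bound frame: required so that chained hitter comparisons work
        return getattr(other, "player", other) is self

    def __ne__(self, other) -> bool:
        return not self.__eq__(other)

    def __hash__(self) -> int:
        return id(self)

    def __repr__(self) -> str:
        return f"Player({self.name!r})"


class Team:
    """A doubles pair.  ``forehand_player`` covers the right side facing
    the net (the "drive" side), ``backhand_player`` the left."""

    def __init__(self, players: tuple[Player, Player], name: str = "",
                 forehand_player: Optional[Player] = None,
                 backhand_player: Optional[Player] = None):
        if len(players) != 2 or players[0] is players[1]:
            raise ValueError("a team is a pair of two distinct players")
        self.players = tuple(players)
        self.name = name
        for p in self.players:
            p.team = self
        if forehand_player is not None:
            self.set_sides(forehand_player)
        else:
            self.forehand_player = players[0]
            self.backhand_player = players[1]

    def set_sides(self, forehand_player: Player) -> None:
        if forehand_player not in self.players:
            raise ValueError("forehand player must belong to the team")
        self.forehand_player = forehand_player
        self.backhand_player = (
            self.players[1] if forehand_player is self.players[0] else self.players[0]
        )

    def __contains__(self, player) -> bool:
        player = getattr(player, "player", player)
        return any(p is player for p in self.players)

    def __repr__(self) -> str:
        return f"Team({self.name or '/'.join(p.last_name for p in self.players)})"


# ---------------------------------------------------------------------------
# Temporal units
# ---------------------------------------------------------------------------

class TemporalUnit:
    """Shared contract of all play units: a frame interval, an ordinal,
    a tag set and navigation."""

    level: str = ""

    def __init__(self, start_frame: int, end_frame: int):
        if end_frame < start_frame:
            raise ValueError(
                f"end_frame {end_frame} precedes start_frame {start_frame}")
        self.start_frame = int(start_frame)
        self.end_frame = int(end_frame)
        self.number: int = 0            # 1-based ordinal, set on assembly
        self.tags = TagSet()
        self.parent: Optional[TemporalUnit] = None
        self.children: list[TemporalUnit] = []
        self._siblings: Optional[list] = None   # list this unit is ordered in

    # -- time ---------------------------------------------------------------
    @property
    def fps(self) -> float:
        return self.match.video.fps

    @property
    def start_time(self) -> float:
        return self.start_frame / self.fps

    @property
    def end_time(self) -> float:
        return self.end_frame / self.fps

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    # -- hierarchy ----------------------------------------------------------
    def ancestor(self, level: str):
        if level not in LEVELS:
            raise NavigationError(f"unknown level {level!r}; expected one of {LEVELS}")
        if LEVELS.index(level) > LEVELS.index(self.level):
            raise NavigationError(
                f"{level!r} is a descendant of {self.level!r}, not an ancestor")
        unit: Optional[TemporalUnit] = self
        while unit is not None and unit.level != level:
            unit = unit.parent
        if unit is None:
            return ABSENT
        return unit

    def __getattr__(self, name: str):
        # skip-level ancestor access: frame.match, shot.game, ...
        if name in LEVELS and self.__class__.level and name != self.__class__.level:
            if LEVELS.index(name) < LEVELS.index(self.__class__.level):
                return self.ancestor(name)
        raise AttributeError(
            f"{type(self).__name__!s} object has no attribute {name!r}")

    # -- siblings -----------------------------------------------------------
    @property
    def next(self):
        sibs = self._siblings
        if sibs is None:
            return ABSENT
        i = self.number  # number is 1-based index into siblings
        if 0 < i < len(sibs):
            return sibs[i]
        return ABSENT

    @property
    def prev(self):
        sibs = self._siblings
        if sibs is None:
            return ABSENT
        i = self.number - 2
        if 0 <= i < len(sibs):
            return sibs[i]
        return ABSENT

    # -- tags ---------------------------------------------------------------
    def like(self, query: str) -> bool:
        return self.tags.like(query)

    def one_of(self, codes_csv: str) -> bool:
        return self.tags.one_of(codes_csv)

    def __repr__(self) -> str:
        return (f"{type(self).__name__}(#{self.number} "
                f"[{self.start_frame},{self.end_frame}))")


def link_children(parent: TemporalUnit, children: Iterable[TemporalUnit]) -> None:
    """Attach ``children`` (already in temporal order) to ``parent``,
    numbering them 1..n and wiring sibling navigation."""
    kids = list(children)
    parent.children = kids
    for i, child in enumerate(kids, start=1):
        child.parent = parent
        child.number = i
        child._siblings = kids


class Match(TemporalUnit):
    level = "match"

    def __init__(self, title: str, teams: tuple[Team, Team],
                 video: VideoInfo, geometry: CourtGeometry = CourtGeometry(),
                 gender: Optional[str] = None,
                 start_frame: int = 0, end_frame: int = 0):
        super().__init__(start_frame, max(start_frame, end_frame))
        if len(teams) != 2:
            raise ValueError("a match needs exactly two teams")
        self.title = title
        self.teams = tuple(teams)
        self.video = video
        self.geometry = geometry
        self.gender = gender

    @property
    def players(self) -> tuple[Player, ...]:
        return self.teams[0].players + self.teams[1].players

    @property
    def sets(self) -> list["Set"]:
        return self.children  # type: ignore[return-value]

    @property
    def match(self) -> "Match":
        return self

    def player_by_last_name(self, last_name: str):
        hits = [p for p in self.players
                if p.last_name.lower() == last_name.lower()]
        if len(hits) == 1:
            return hits[0]
        return None

    def iter_units(self, level: str) -> Iterator[TemporalUnit]:
        """All units of ``level`` in temporal order (frames include those of
        zero-shot points)."""
        if level == "match":
            yield self
            return
        if level not in LEVELS:
            raise NavigationError(f"unknown level {level!r}")
        if level == "frame":
            for point in self.iter_units("point"):
                yield from point.frames  # type: ignore[union-attr]
            return
        units: list[TemporalUnit] = [self]
        for lvl in LEVELS[1:]:
            units = [c for u in units for c in u.children]
            if lvl == level:
                break
        yield from units


class Set(TemporalUnit):
    level = "set"

    def __init__(self, start_frame: int, end_frame: int,
                 winner=ABSENT, loser=ABSENT, score: str = ""):
        super().__init__(start_frame, end_frame)
        self.winner = winner
        self.loser = loser
        self.score = score

    @property
    def games(self) -> list["Game"]:
        return self.children  # type: ignore[return-value]


class Game(TemporalUnit):
    level = "game"

    def __init__(self, start_frame: int, end_frame: int,
                 winner=ABSENT, loser=ABSENT, score: str = ""):
        super().__init__(start_frame, end_frame)
        self.winner = winner
        self.loser = loser
        self.score = score

    @property
    def points(self) -> list["Point"]:
        return self.children  # type: ignore[return-value]


class Point(TemporalUnit):
    """One rally: from the serve until a team wins the exchange."""

    level = "point"

    def __init__(self, start_frame: int, end_frame: int,
                 winner=ABSENT, loser=ABSENT, valid: bool = True,
                 score_after: tuple[str, str] = ("", "")):
        super().__init__(start_frame, end_frame)
        self.winner = winner
        self.loser = loser
        self.valid = valid
        self.score_after = score_after
        self.frames: list[Frame] = []   # every frame of the rally, in order

    @property
    def shots(self) -> list["Shot"]:
        return self.children  # type: ignore[return-value]

    @property
    def id(self) -> str:
        game = self.ancestor("game")
        set_ = self.ancestor("set")
        g = game.number if game is not ABSENT else 0
        s = set_.number if set_ is not ABSENT else 0
        return f"g{g}-s{s}-p{self.number}"


class Shot(TemporalUnit):
    """One ball strike.  Its temporal span runs from the hit to the next
    shot's hit (or to the end of the rally for the last shot)."""

    level = "shot"

    def __init__(self, start_frame: int, end_frame: int,
                 hitter_player: Player, shot_type=None, lob: bool = False):
        super().__init__(start_frame, end_frame)
        self.hitter_player = hitter_player
        self.shot_type = shot_type
        self.lob = bool(lob)

    @property
    def point(self) -> Point:
        return self.parent  # type: ignore[return-value]

    @property
    def frames(self) -> list["Frame"]:
        return self.children  # type: ignore[return-value]

    @property
    def frame(self):
        """The frame at which the shot is struck (first owned frame)."""
        if self.children:
            return self.children[0]
        return ABSENT

    @property
    def hitter(self):
        """The hitter bound to the shot's start frame (positional attributes
        become available); falls back to the bare player with no frame data."""
        f = self.frame
        if f is ABSENT:
            return self.hitter_player
        from .kinematics import BoundPlayer
        return BoundPlayer(self.hitter_player, f)

    @property
    def receiver(self):
        nxt = self.next
        if nxt is ABSENT:
            return ABSENT
        return nxt.hitter

    @property
    def duration(self):
        """Seconds from this hit to the next; Absent for the rally's last
        shot, whose span is cut by the end of the point, not by a hit."""
        nxt = self.next
        if nxt is ABSENT:
            return ABSENT
        return nxt.start_time - self.start_time

    @property
    def angle(self):
        from .kinematics import shot_direction
        d = shot_direction(self)
        return d.angle if d is not ABSENT else ABSENT

    @property
    def abs_angle(self):
        from .kinematics import shot_direction
        d = shot_direction(self)
        return d.abs_angle if d is not ABSENT else ABSENT

    @property
    def id(self) -> str:
        p = self.point
        return f"{p.id}-sh{self.number}" if p is not None else f"sh{self.number}"


class Frame(TemporalUnit):
    """One video sampling instant with the four players' positions.

    Its parent is the owning shot; for rallies annotated without shots it
    hangs directly off the point.  ``duration`` is one frame-time (1/fps).
    """

    level = "frame"

    def __init__(self, frame_number: int,
                 positions: dict[Player, tuple[float, float]],
                 image_positions: Optional[dict[Player, tuple[float, float]]] = None):
        super().__init__(frame_number, frame_number + 1)
        self.frame_number = int(frame_number)
        self.positions = positions
        self.image_positions = image_positions or {}
        self._point: Optional[Point] = None   # direct ref; survives shot-less points

    @property
    def time(self) -> float:
        return self.start_time

    @property
    def shot(self):
        if isinstance(self.parent, Shot):
            return self.parent
        return ABSENT

    @property
    def point(self):
        if self._point is not None:
            return self._point
        s = self.shot
        return s.point if s is not ABSENT else ABSENT

    def position_of(self, player) -> tuple[float, float]:
        player = getattr(player, "player", player)
        try:
            return self.positions[player]
        except KeyError:
            raise KeyError(f"{player!r} has no position in frame "
                           f"{self.frame_number}") from None

    def bound(self, player):
        from .kinematics import BoundPlayer
        return BoundPlayer(getattr(player, "player", player), self)

    def distance_to_net(self, player):
        if player is ABSENT or not player:
            return ABSENT
        return self.bound(player).distance_to_net

    @property
    def players(self):
        return tuple(self.positions)


# ---------------------------------------------------------------------------
# Navigation as plain functions
# ---------------------------------------------------------------------------

def nav_children(unit: TemporalUnit, kind: str) -> list[TemporalUnit]:
    """Immediate children of ``unit`` at level ``kind``, in temporal order."""
    expected = CHILD_LEVEL.get(unit.level)
    if kind != expected and kind != PLURAL.get(expected or "", None):
        raise NavigationError(
            f"{unit.level!r} units have {expected!r} children, not {kind!r}")
    return list(unit.children)


def nav_parent(unit: TemporalUnit, level: str) -> TemporalUnit:
    """The unique ancestor of ``unit`` at ``level`` (skip levels allowed)."""
    return unit.ancestor(level)


def nav_next(unit: TemporalUnit):
    return unit.next


def nav_prev(unit: TemporalUnit):
    return unit.prev


def bind(player: Player, frame: Frame):
    """Bind ``player`` to ``frame``, exposing positional attributes."""
    match = frame.ancestor("match")
    if match is not ABSENT and all(p is not player for p in match.players):
        raise ValueError(f"{player!r} is not part of {match!r}")
    return frame.bound(player)
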