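"""Reading the three tabular match schemas and assembling the hierarchy.

A digitized match arrives as three tables:

* **points** — one row per rally: start/end frame, durations, winning
  team (T/B, top/bottom on the video), the within-game score labels after
  the point, and the four player names by video corner (TL/TR/BL/BR);
* **shots** — one row per ball strike: frame, hitter corner, shot-type
  code and a lob flag;
* **frames** — one row per video frame: the four players' image-space
  (i, j pixels) and court-space (x, y meters) positions.

Assembly infers the frame rate from the points table (the integer fps
best reconciling frame counts with printed second durations), replays
the point winners through the scoring automaton to reconstruct game and
set boundaries (mode auto-detected against the printed score columns),
maps shot corners to players, attaches frames to rallies by interval and
to shots by the half-open rule (a shot owns frames from its hit to the
next hit), and applies the built-in tags.

Annotated frame numbers are approximate, so a shot falling slightly
outside its rally (the serve is often stamped a couple of frames before
the rally start) is clamped into the enclosing span within a configurable
tolerance rather than rejected.
"""

from __future__ import annotations

import io
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from . import scoring
from .model import (ABSENT, CourtGeometry, Frame, Game, Match, Player, Point,
                    Set, Shot, Team, VideoInfo, link_children)
from .tags import ShotTypeRegistry, auto_tags, default_registry

log = logging.getLogger(__name__)

CORNERS = ("TL", "TR", "BL", "BR")

# canonical on-disk headers (the shapes the annotation pipeline prints)
POINTS_COLUMNS = ["Start (f)", "End (f)", "Duration (f)", "Duration (s)",
                  "Winner", "Points A", "Points B",
                  "Top Left", "Top Right", "Bottom Left", "Bottom Right"]
SHOTS_COLUMNS = ["Frame", "Player", "Shot Type", "Lob"]
FRAMES_COLUMNS = ["Frame"] + [f"{c} {axis}" for c in CORNERS for axis in "ij"] \
    + [f"{c} {axis}" for c in CORNERS for axis in "xy"]

# header aliases, lowercase: dialect drift absorbed here
_POINTS_ALIASES = {
    "start": "start", "start (f)": "start", "start_frame": "start",
    "end": "end", "end (f)": "end", "end_frame": "end",
    "duration (f)": "duration_frames", "duration_frames": "duration_frames",
    "duration (s)": "duration_seconds", "duration_seconds": "duration_seconds",
    "winner": "winner",
    "points a": "points_a", "points_a": "points_a",
    "points b": "points_b", "points_b": "points_b",
    "top left": "TL", "tl": "TL", "top right": "TR", "tr": "TR",
    "bottom left": "BL", "bl": "BL", "bottom right": "BR", "br": "BR",
}
_SHOTS_ALIASES = {
    "frame": "frame", "player": "corner", "corner": "corner",
    "shot type": "shot_code", "shot_type": "shot_code", "shot_code": "shot_code",
    "lob": "lob",
}


class SchemaError(ValueError):
    """A table does not match its expected schema."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointRecord:
    start: int
    end: int
    duration_frames: Optional[int]
    duration_seconds: Optional[float]
    winner: str                       # "T" or "B"
    points_a: str
    points_b: str
    corner_names: dict[str, str]      # TL/TR/BL/BR -> player name


@dataclass(frozen=True)
class ShotRecord:
    frame: int
    corner: str
    shot_code: str
    lob: bool


@dataclass(frozen=True)
class FrameRecord:
    frame_number: int
    court: dict[str, tuple[float, float]]            # corner -> (x, y) m
    image: dict[str, tuple[float, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cell coercion
# ---------------------------------------------------------------------------

def _to_int(cell, row: int, col: str) -> int:
    try:
        return int(str(cell).replace(",", "").replace(" ", "").strip())
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: cannot parse {col!r}={cell!r} as an "
                          f"integer frame number") from None


def _to_float(cell, row: int, col: str) -> float:
    try:
        return float(str(cell).replace(",", "").strip())
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: cannot parse {col!r}={cell!r} as a "
                          f"number") from None


def _to_bool(cell, row: int, col: str) -> bool:
    t = str(cell).strip().lower()
    if t in ("t", "true", "1", "yes", "y"):
        return True
    if t in ("f", "false", "0", "no", "n", ""):
        return False
    raise SchemaError(f"row {row}: cannot parse {col!r}={cell!r} as a Boolean")


def _read_table(path_or_buffer) -> pd.DataFrame:
    """Read a comma- or tab-delimited table with string cells."""
    if isinstance(path_or_buffer, pd.DataFrame):
        return path_or_buffer.astype(str)
    df = pd.read_csv(path_or_buffer, sep=None, engine="python", dtype=str,
                     skipinitialspace=True)
    return df


def _canonical_headers(df: pd.DataFrame, aliases: dict[str, str],
                       required: Sequence[str], what: str) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in aliases:
            mapping[aliases[key]] = col
    missing = [c for c in required if c not in mapping]
    if missing:
        raise SchemaError(
            f"{what} table is missing required column(s) {missing}; "
            f"got headers {list(df.columns)}; expected names like "
            f"{sorted(set(aliases))}")
    return mapping


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_points(path_or_buffer) -> list[PointRecord]:
    """Parse a points table (any mix of canonical or aliased headers,
    comma or tab delimited; thousands separators accepted)."""
    df = _read_table(path_or_buffer)
    cols = _canonical_headers(df, _POINTS_ALIASES,
                              ["start", "end", "winner"], "points")
    records: list[PointRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        start = _to_int(r[cols["start"]], i, "start")
        end = _to_int(r[cols["end"]], i, "end")
        dur_f = (_to_int(r[cols["duration_frames"]], i, "duration_frames")
                 if "duration_frames" in cols else end - start)
        dur_s = (_to_float(r[cols["duration_seconds"]], i, "duration_seconds")
                 if "duration_seconds" in cols else None)
        winner = str(r[cols["winner"]]).strip().upper()
        if winner not in ("T", "B"):
            raise SchemaError(f"row {i}: winner must be T or B, got {winner!r}")
        corner_names = {c: str(r[cols[c]]).strip() for c in CORNERS
                        if c in cols}
        records.append(PointRecord(
            start=start, end=end, duration_frames=dur_f,
            duration_seconds=dur_s, winner=winner,
            points_a=str(r[cols["points_a"]]).strip() if "points_a" in cols else "",
            points_b=str(r[cols["points_b"]]).strip() if "points_b" in cols else "",
            corner_names=corner_names))
    return records


def read_shots(path_or_buffer) -> list[ShotRecord]:
    df = _read_table(path_or_buffer)
    cols = _canonical_headers(df, _SHOTS_ALIASES,
                              ["frame", "corner", "shot_code"], "shots")
    records: list[ShotRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        corner = str(r[cols["corner"]]).strip().upper()
        if corner not in CORNERS:
            raise SchemaError(f"row {i}: player corner must be one of "
                              f"{CORNERS}, got {corner!r}")
        records.append(ShotRecord(
            frame=_to_int(r[cols["frame"]], i, "frame"),
            corner=corner,
            shot_code=str(r[cols["shot_code"]]).strip(),
            lob=_to_bool(r[cols["lob"]], i, "lob") if "lob" in cols else False))
    return records


def read_frames(path_or_buffer) -> list[FrameRecord]:
    df = _read_table(path_or_buffer)
    headers = {str(c).strip().lower(): c for c in df.columns}
    frame_col = headers.get("frame") or headers.get("frame_number")
    if frame_col is None:
        raise SchemaError(f"frames table is missing a 'Frame' column; got "
                          f"{list(df.columns)}")
    missing = [f"{c} {a}" for c in CORNERS for a in "xy"
               if f"{c.lower()} {a}" not in headers]
    if missing:
        raise SchemaError(f"frames table is missing court-space column(s) "
                          f"{missing}")
    records: list[FrameRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        r = dict(zip(df.columns, row))
        court = {c: (_to_float(r[headers[f"{c.lower()} x"]], i, f"{c} x"),
                     _to_float(r[headers[f"{c.lower()} y"]], i, f"{c} y"))
                 for c in CORNERS}
        image = {}
        for c in CORNERS:
            ki, kj = f"{c.lower()} i", f"{c.lower()} j"
            if ki in headers and kj in headers:
                image[c] = (_to_float(r[headers[ki]], i, f"{c} i"),
                            _to_float(r[headers[kj]], i, f"{c} j"))
        records.append(FrameRecord(
            frame_number=_to_int(r[frame_col], i, "frame"),
            court=court, image=image))
    return records


# ---------------------------------------------------------------------------
# Writers (canonical dialect)
# ---------------------------------------------------------------------------

def points_to_df(records: Iterable[PointRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append([r.start, r.end,
                     r.duration_frames if r.duration_frames is not None
                     else r.end - r.start,
                     r.duration_seconds, r.winner, r.points_a, r.points_b]
                    + [r.corner_names.get(c, "") for c in CORNERS])
    return pd.DataFrame(rows, columns=POINTS_COLUMNS)


def shots_to_df(records: Iterable[ShotRecord]) -> pd.DataFrame:
    rows = [[r.frame, r.corner, r.shot_code, "T" if r.lob else "F"]
            for r in records]
    return pd.DataFrame(rows, columns=SHOTS_COLUMNS)


def frames_to_df(records: Iterable[FrameRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = [r.frame_number]
        for c in CORNERS:
            ij = r.image.get(c, (math.nan, math.nan))
            row.extend(ij)
        for c in CORNERS:
            row.extend(r.court[c])
        rows.append(row)
    return pd.DataFrame(rows, columns=FRAMES_COLUMNS)


# ---------------------------------------------------------------------------
# fps inference
# ---------------------------------------------------------------------------

class FpsEstimate(NamedTuple):
    fps: int
    residual: float      # sum of |frames/fps - printed seconds|


def infer_fps(points: Sequence[PointRecord],
              candidates: Iterable[int] = range(1, 241)) -> FpsEstimate:
    """The integer frame rate that best reconciles each rally's frame count
    with its printed duration in seconds (exhaustive search)."""
    usable = [(p.duration_frames if p.duration_frames is not None
               else p.end - p.start, p.duration_seconds)
              for p in points if p.duration_seconds is not None]
    if not usable:
        raise SchemaError(
            "no point carries both a frame count and a second duration; "
            "configure the frame rate explicitly (fps=...)")
    best: Optional[FpsEstimate] = None
    for fps in candidates:
        resid = sum(abs(df / fps - ds) for df, ds in usable)
        if best is None or resid < best.residual:
            best = FpsEstimate(int(fps), float(resid))
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class IngestConfig:
    """Knobs for assembly; defaults suit the annotation pipeline's output."""

    fps: Optional[float] = None          # override inference
    scoring_mode: str = "auto"           # advantage | golden_point | auto
    strict: bool = False                 # score divergence: error vs warning
    clamp_tolerance_frames: int = 10     # shots stamped just outside a rally
    court_tolerance_m: float = 0.5       # positions may exceed bounds by this
    title: str = "match"
    video_url: Optional[str] = None
    gender: Optional[str] = None
    geometry: CourtGeometry = field(default_factory=CourtGeometry)
    registry: Optional[ShotTypeRegistry] = None
    #: override the inferred forehand (right-side) player per team name
    forehand_overrides: dict[str, str] = field(default_factory=dict)


def _split_name(name: str) -> tuple[str, str]:
    parts = name.split()
    if len(parts) >= 2:
        return " ".join(parts[:-1]), parts[-1]
    return "", name


def _roster(points: Sequence[PointRecord], gender) -> tuple[Team, Team, dict[str, Player]]:
    """Players and teams from the corner-name columns; top corners form one
    team, bottom corners the other.  Court-half swaps between points are
    absorbed by the per-point corner->name mapping."""
    names: dict[str, None] = {}
    for p in points:
        for c in CORNERS:
            n = p.corner_names.get(c)
            if n:
                names.setdefault(n, None)
    by_name: dict[str, Player] = {}
    for n in names:
        first, last = _split_name(n)
        if any(p.last_name.lower() == last.lower() for p in by_name.values()):
            raise SchemaError(f"duplicate last name {last!r}; last names must "
                              f"be unique within a match")
        by_name[n] = Player(first, last, gender=gender)
    first_point = points[0]
    top = [by_name[first_point.corner_names[c]] for c in ("TL", "TR")
           if first_point.corner_names.get(c)]
    bottom = [by_name[first_point.corner_names[c]] for c in ("BL", "BR")
              if first_point.corner_names.get(c)]
    if len(top) != 2 or len(bottom) != 2:
        raise SchemaError("points table must name four players by corner "
                          "(Top/Bottom Left/Right)")
    team_top = Team(tuple(top), name="Top")
    team_bottom = Team(tuple(bottom), name="Bottom")
    team_top.side = "top"
    team_bottom.side = "bottom"
    return team_top, team_bottom, by_name


def assemble_match(points: Sequence[PointRecord],
                   shots: Sequence[ShotRecord] = (),
                   frames: Sequence[FrameRecord] = (),
                   config: Optional[IngestConfig] = None) -> Match:
    """Build and wire the full ``Match`` hierarchy from typed records."""
    config = config or IngestConfig()
    if not points:
        raise SchemaError("cannot assemble a match from an empty points table")
    registry = config.registry or default_registry()
    fps = config.fps if config.fps else infer_fps(points).fps

    team_top, team_bottom, by_name = _roster(points, config.gender)
    match = Match(title=config.title, teams=(team_top, team_bottom),
                  video=VideoInfo(url=config.video_url, fps=fps),
                  geometry=config.geometry, gender=config.gender)

    # --- score replay: mode detection and game/set boundaries -------------
    winners = [p.winner for p in points]
    printed = [(p.points_a, p.points_b) for p in points]
    if config.scoring_mode == "auto":
        mode, misses = scoring.detect_mode(winners, printed)
    else:
        mode = config.scoring_mode
        states, _, _ = scoring.score_automaton(winners, mode)
        misses = sum(1 for s, lab in zip(states, printed)
                     if any(lab) and s.labels != lab)
    states, game_bounds, set_bounds = scoring.score_automaton(winners, mode)
    if misses:
        divergent = next(i for i, (s, lab) in enumerate(zip(states, printed))
                         if s.labels != tuple(lab))
        msg = (f"printed score columns diverge from the {mode} automaton at "
               f"point {divergent + 1}: printed {printed[divergent]}, "
               f"replayed {states[divergent].labels}")
        if config.strict:
            raise SchemaError(msg)
        log.warning(msg)

    team_of = {"T": team_top, "B": team_bottom}
    point_units: list[Point] = []
    for rec, state in zip(points, states):
        w = team_of[rec.winner]
        loser = team_bottom if w is team_top else team_top
        pt = Point(rec.start, rec.end, winner=w, loser=loser,
                   score_after=(rec.points_a or state.score_A,
                                rec.points_b or state.score_B))
        pt._corner_names = rec.corner_names
        point_units.append(pt)

    game_units: list[Game] = []
    for (i0, i1) in game_bounds:
        gw = states[i1].game_winner
        game = Game(point_units[i0].start_frame, point_units[i1].end_frame,
                    winner=team_of[gw] if gw else ABSENT,
                    loser=(team_of["B" if gw == "T" else "T"] if gw else ABSENT))
        link_children(game, point_units[i0:i1 + 1])
        game._point_range = (i0, i1)
        game_units.append(game)

    set_units: list[Set] = []
    for (i0, i1) in set_bounds:
        sw = states[i1].set_winner
        games_in = [g for g in game_units
                    if i0 <= g._point_range[0] and g._point_range[1] <= i1]
        st = Set(point_units[i0].start_frame, point_units[i1].end_frame,
                 winner=team_of[sw] if sw else ABSENT,
                 loser=(team_of["B" if sw == "T" else "T"] if sw else ABSENT))
        link_children(st, games_in)
        set_units.append(st)
    match.start_frame = point_units[0].start_frame
    match.end_frame = point_units[-1].end_frame
    link_children(match, set_units)

    # --- shots -------------------------------------------------------------
    def enclosing_point(f: int) -> Optional[tuple[Point, int]]:
        for pt in point_units:
            if pt.start_frame <= f < pt.end_frame:
                return pt, f
        # clamp: annotated frame numbers are approximate
        best, dist = None, None
        for pt in point_units:
            d = (pt.start_frame - f if f < pt.start_frame
                 else f - (pt.end_frame - 1))
            if d > 0 and (dist is None or d < dist):
                best, dist = pt, d
        if best is not None and dist is not None \
                and dist <= config.clamp_tolerance_frames:
            clamped = min(max(f, best.start_frame), best.end_frame - 1)
            log.warning("frame %d outside every rally; clamped by %d frame(s) "
                        "into [%d, %d)", f, dist, best.start_frame,
                        best.end_frame)
            return best, clamped
        return None

    shots_by_point: dict[int, list[tuple[int, ShotRecord]]] = {}
    for rec in sorted(shots, key=lambda r: r.frame):
        hit = enclosing_point(rec.frame)
        if hit is None:
            raise SchemaError(
                f"shot at frame {rec.frame} lies inside no rally and beyond "
                f"the {config.clamp_tolerance_frames}-frame clamp tolerance")
        pt, frame = hit
        shots_by_point.setdefault(id(pt), []).append((frame, rec))

    for pt in point_units:
        entries = sorted(shots_by_point.get(id(pt), []), key=lambda e: e[0])
        shot_units: list[Shot] = []
        for k, (f, rec) in enumerate(entries):
            span_end = entries[k + 1][0] if k + 1 < len(entries) \
                else pt.end_frame
            st = registry.resolve(rec.shot_code)
            if st is None:
                raise SchemaError(f"shot code {rec.shot_code!r} at frame "
                                  f"{rec.frame} is not in the shot-type "
                                  f"registry")
            name = pt._corner_names.get(rec.corner, "")
            hitter = by_name.get(name)
            if hitter is None:
                raise SchemaError(f"shot at frame {rec.frame}: corner "
                                  f"{rec.corner} names no known player")
            shot_units.append(Shot(f, max(span_end, f + 1), hitter_player=hitter,
                                   shot_type=st, lob=rec.lob))
        link_children(pt, shot_units)
        if not shot_units:
            log.warning("rally %s has no shots", pt.id)

    # --- frames ------------------------------------------------------------
    frames_sorted = sorted(frames, key=lambda r: r.frame_number)
    fi = 0
    for pt in point_units:
        in_point: list[Frame] = []
        corner_to_player = {c: by_name.get(pt._corner_names.get(c, ""))
                            for c in CORNERS}
        while fi < len(frames_sorted) \
                and frames_sorted[fi].frame_number < pt.end_frame:
            rec = frames_sorted[fi]
            fi += 1
            if rec.frame_number < pt.start_frame:
                continue   # between rallies
            positions = {corner_to_player[c]: rec.court[c]
                         for c in CORNERS if corner_to_player[c] is not None}
            image = {corner_to_player[c]: rec.image[c]
                     for c in rec.image if corner_to_player.get(c) is not None}
            fr = Frame(rec.frame_number, positions, image)
            fr._point = pt
            fr._point_index = len(in_point)
            in_point.append(fr)
        pt.frames = in_point
        # hand frames to shots by the half-open ownership rule
        for shot in pt.shots:
            owned = [fr for fr in in_point
                     if shot.start_frame <= fr.frame_number < shot.end_frame]
            link_children(shot, owned)
            for fr in owned:
                fr._point = pt     # link_children reset parent; keep point ref

    _assign_sides(match, config)
    auto_tags(match)
    return match


def _assign_sides(match: Match, config: IngestConfig) -> None:
    """Infer each team's forehand (right-side facing the net) player from
    mean x position during the games their team served; overridable."""
    serving_games: dict[Team, list[Game]] = {t: [] for t in match.teams}
    for game in match.iter_units("game"):
        for pt in game.points:
            if pt.shots:
                serving_games[pt.shots[0].hitter_player.team].append(game)
                break
    for team in match.teams:
        override = config.forehand_overrides.get(team.name)
        if override:
            player = match.player_by_last_name(override)
            if player is None or player not in team:
                raise SchemaError(f"forehand override {override!r} is not a "
                                  f"player of team {team.name}")
            team.set_sides(player)
            continue
        games = serving_games[team] or list(match.iter_units("game"))
        xsum = {p: [0.0, 0] for p in team.players}
        for game in games:
            for pt in game.points:
                for fr in pt.frames:
                    for p in team.players:
                        if p in fr.positions:
                            xsum[p][0] += fr.positions[p][0]
                            xsum[p][1] += 1
        if any(n == 0 for _, n in xsum.values()):
            continue    # no positional data; keep declaration order
        mean_x = {p: s / n for p, (s, n) in xsum.items()}
        p0, p1 = team.players
        # bottom team faces +y: right side is larger x; top team the reverse
        if getattr(team, "side", "bottom") == "bottom":
            team.set_sides(p0 if mean_x[p0] >= mean_x[p1] else p1)
        else:
            team.set_sides(p0 if mean_x[p0] <= mean_x[p1] else p1)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __repr__(self) -> str:
        return (f"ValidationReport({len(self.errors)} error(s), "
                f"{len(self.warnings)} warning(s))")


def validate(match: Match,
             court_tolerance_m: float = 0.5) -> ValidationReport:
    """Structural and positional consistency checks on an assembled match."""
    rep = ValidationReport()
    geo = match.geometry

    def walk(unit):
        for child in unit.children:
            if child.start_frame < unit.start_frame \
                    or child.end_frame > unit.end_frame:
                rep.errors.append(
                    f"containment: {child!r} [{child.start_frame},"
                    f"{child.end_frame}) outside {unit!r} "
                    f"[{unit.start_frame},{unit.end_frame})")
            walk(child)
        nums = [c.number for c in unit.children]
        if nums != list(range(1, len(nums) + 1)):
            rep.errors.append(f"numbering: children of {unit!r} are {nums}")
        starts = [c.start_frame for c in unit.children]
        if starts != sorted(starts):
            rep.errors.append(f"ordering: children of {unit!r} not in "
                              f"temporal order")

    walk(match)
    for pt in match.iter_units("point"):
        if not pt.shots:
            rep.warnings.append(f"rally {pt.id} has no shots")
        else:
            first = pt.shots[0]
            if not first.like("serve"):
                rep.warnings.append(f"rally {pt.id} does not start with a "
                                    f"serve")
            teams = [s.hitter_player.team for s in pt.shots]
            if any(a is b for a, b in zip(teams, teams[1:])):
                rep.warnings.append(f"rally {pt.id}: consecutive shots by the "
                                    f"same team (annotation noise?)")
        last_fn = None
        for fr in pt.frames:
            if last_fn is not None and fr.frame_number <= last_fn:
                rep.errors.append(f"rally {pt.id}: non-monotone frame numbers "
                                  f"at {fr.frame_number}")
            last_fn = fr.frame_number
            for p, (x, y) in fr.positions.items():
                if not (-court_tolerance_m <= x <= geo.width + court_tolerance_m
                        and -court_tolerance_m <= y
                        <= geo.length + court_tolerance_m):
                    rep.errors.append(
                        f"rally {pt.id} frame {fr.frame_number}: "
                        f"{p.last_name} at ({x:.2f}, {y:.2f}) is outside the "
                        f"court beyond {court_tolerance_m} m tolerance")
    return rep


# ---------------------------------------------------------------------------
# Match bundles on disk
# ---------------------------------------------------------------------------

def save_bundle(out_dir, points_df: pd.DataFrame, shots_df: pd.DataFrame,
                frames_df: pd.DataFrame, manifest: Optional[dict] = None) -> Path:
    """Write the canonical on-disk bundle: a JSON manifest plus the three
    canonical CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    points_df.to_csv(out / "points.csv", index=False)
    shots_df.to_csv(out / "shots.csv", index=False)
    frames_df.to_csv(out / "frames.csv", index=False)
    (out / "manifest.json").write_text(
        json.dumps(manifest or {}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return out


def load_bundle(bundle_dir, config: Optional[IngestConfig] = None) -> Match:
    """Read a bundle directory back into an assembled match."""
    bundle = Path(bundle_dir)
    manifest = {}
    mpath = bundle / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text(encoding="utf-8"))
    if config is None:
        config = IngestConfig()
    for key in ("title", "video_url", "gender"):
        if manifest.get(key) and getattr(config, key, None) in (None, "match"):
            setattr(config, key, manifest[key])
    if manifest.get("fps") and config.fps is None:
        config.fps = manifest["fps"]
    if manifest.get("scoring_mode") and config.scoring_mode == "auto":
        config.scoring_mode = manifest["scoring_mode"]
    points = read_points(bundle / "points.csv")
    shots = read_shots(bundle / "shots.csv") if (bundle / "shots.csv").exists() else []
    frames = read_frames(bundle / "frames.csv") if (bundle / "frames.csv").exists() else []
    return assemble_match(points, shots, frames, config)
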