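"""Predicate queries over the play-unit hierarchy.

A query has four parts: a *type* (the play-unit level its rows come
from), a Boolean *predicate* deciding membership, a *scope* (one match or
a list of matches) and *attributes* (expressions evaluated per selected
item into the output columns).  Predicates can be host-language
functions — the fluent style::

    @shot_query
    def volleys(shot):
        return shot.one_of("vd,vr")

    result = volleys(match, ["hitter.last_name", "hitter.position.x"])

— or text expressions in the query mini-grammar, which makes the same
queries writable from YAML files and the command line.

The result is a :class:`QueryResult`: an ordered table (pandas DataFrame
inside) where every row carries provenance back to the video — the match,
the item's start frame, and a deep link that starts playback at that
moment.  Attributes that evaluate to Absent become explicit nulls;
membership is decided by the predicate alone.

The module also ships a ten-query catalog covering the standard analysis
repertoire (volleys and their directions, shot durations, serves and
server-partner positioning, net-zone occupancy, winning shots, covered
distance, lob effectiveness, serve-return-volley patterns).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .expressions import CompiledExpression, compile_expression
from .model import ABSENT, LEVELS, Match, Player, TemporalUnit, is_absent
from .kinematics import BoundPlayer, Vec2
from .tags import ShotType, TagSet

log = logging.getLogger(__name__)

Predicate = Union[Callable[[Any], Any], str, CompiledExpression]

#: the 16 codes analysts group as defensive strokes
DEFENSIVE_CODES = "d,r,ad,ar,pld,plr,spd,spr,bpd,bpr,dpa,dpc,dpag,cp,cpld,cplr"


@dataclass
class QueryDef:
    """A named, typed Boolean predicate over one play-unit level.

    Calling a QueryDef executes it: ``qdef(scope, attribs)``.
    """

    name: str
    kind: str
    predicate: Predicate

    def __post_init__(self):
        if self.kind not in LEVELS:
            raise ValueError(f"unknown query kind {self.kind!r}; expected one "
                             f"of {LEVELS}")
        if isinstance(self.predicate, str):
            self.predicate = compile_expression(self.predicate)

    def __call__(self, scope, attribs: Sequence = (), **kwargs) -> "QueryResult":
        return execute(self, scope, attribs, **kwargs)


def _query_decorator(kind: str):
    def deco(fn: Callable) -> QueryDef:
        return QueryDef(name=fn.__name__, kind=kind, predicate=fn)
    deco.__name__ = f"{kind}_query"
    return deco


match_query = _query_decorator("match")
set_query = _query_decorator("set")
game_query = _query_decorator("game")
point_query = _query_decorator("point")
shot_query = _query_decorator("shot")
frame_query = _query_decorator("frame")


def _tag_decorator(kind: str):
    """Decorator pair to ``*_query``: the decorated predicate becomes a tag
    rule; calling it on a match (or list) inserts the tag."""
    from .tags import TagRule, apply_tags, register_tag

    def deco(fn: Callable):
        rule = register_tag(TagRule(name=fn.__name__, kind=kind, predicate=fn))

        def apply(scope) -> int:
            return apply_tags(rule, scope)

        apply.rule = rule
        apply.__name__ = fn.__name__
        return apply
    deco.__name__ = f"{kind}_tag"
    return deco


match_tag = _tag_decorator("match")
point_tag = _tag_decorator("point")
shot_tag = _tag_decorator("shot")
frame_tag = _tag_decorator("frame")


@dataclass(frozen=True)
class AttributeSpec:
    """One output column: an expression and the alias it is shown under."""

    expression: str
    alias: str = ""

    @staticmethod
    def coerce(spec) -> "AttributeSpec":
        if isinstance(spec, AttributeSpec):
            return spec
        if isinstance(spec, str):
            return AttributeSpec(spec, spec)
        if isinstance(spec, (tuple, list)) and len(spec) == 2:
            return AttributeSpec(spec[0], spec[1])
        raise TypeError(f"attribute spec must be a string or an "
                        f"(expression, alias) pair, got {spec!r}")

    def __post_init__(self):
        if not self.alias:
            object.__setattr__(self, "alias", self.expression)


@dataclass(frozen=True)
class RowProvenance:
    match_title: str
    start_frame: int
    link: Optional[str]


class QueryResult:
    """Ordered tabular query output with per-row video provenance."""

    def __init__(self, df: pd.DataFrame,
                 provenance: Optional[list[RowProvenance]] = None,
                 title: str = "", items: Optional[list] = None):
        self.df = df.reset_index(drop=True)
        self.provenance = provenance if provenance is not None else []
        self.title = title
        self.items = items or []

    # -- basic access -------------------------------------------------------
    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    @property
    def rows(self) -> list[dict]:
        return self.df.to_dict(orient="records")

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        t = f" {self.title!r}" if self.title else ""
        return f"QueryResult{t}({len(self)} rows x {len(self.columns)} cols)"

    @property
    def links(self) -> list[Optional[str]]:
        return [p.link for p in self.provenance]

    # -- transformations ----------------------------------------------------
    def analyze(self) -> pd.DataFrame:
        """Summary per column: count/mean/std/min/max for numeric columns,
        count/distinct for the rest."""
        if self.df.empty:
            warnings.warn("analyze() on an empty result", stacklevel=2)
            return pd.DataFrame(
                columns=["count", "mean", "std", "min", "max", "distinct"])
        out = {}
        for col in self.df.columns:
            s = self.df[col]
            if pd.api.types.is_numeric_dtype(s):
                out[col] = {"count": int(s.count()),
                            "mean": float(s.mean()),
                            "std": float(s.std(ddof=0)) if s.count() else math.nan,
                            "min": float(s.min()), "max": float(s.max()),
                            "distinct": math.nan}
            else:
                out[col] = {"count": int(s.count()), "mean": math.nan,
                            "std": math.nan, "min": math.nan, "max": math.nan,
                            "distinct": int(s.nunique())}
        return pd.DataFrame(out).T[["count", "mean", "std", "min", "max",
                                    "distinct"]]

    def sum_by(self, key_column: str) -> "QueryResult":
        """One row per distinct key in first-appearance order; numeric
        columns are summed, other non-key columns dropped (warning)."""
        if key_column not in self.df.columns:
            raise KeyError(f"no column {key_column!r}; have {self.columns}")
        numeric = [c for c in self.df.columns if c != key_column
                   and pd.api.types.is_numeric_dtype(self.df[c])]
        dropped = [c for c in self.df.columns
                   if c != key_column and c not in numeric]
        if dropped:
            warnings.warn(f"sum_by({key_column!r}) drops non-numeric "
                          f"column(s) {dropped}", stacklevel=2)
        grouped = (self.df[[key_column] + numeric]
                   .groupby(key_column, sort=False, as_index=False).sum())
        return QueryResult(grouped, provenance=None, title=self.title)

    # the fluent spelling used in analysis notebooks
    def sum(self, key_column: str) -> "QueryResult":  # noqa: A003
        return self.sum_by(key_column)

    def add_column(self, name: str, constant) -> "QueryResult":
        df = self.df.copy()
        df[name] = constant
        return QueryResult(df, provenance=list(self.provenance),
                           title=self.title, items=list(self.items))

    addColumn = add_column

    def to_csv(self, path_or_buffer=None, links: bool = False):
        df = self.df
        if links and self.provenance:
            df = df.copy()
            df["video_link"] = [p.link for p in self.provenance]
        return df.to_csv(path_or_buffer, index=False)

    # -- plotting -----------------------------------------------------------
    def plot_data(self, kind: str, **options) -> dict:
        return plot_data(self, kind, **options)


def concat(results: Sequence[QueryResult], title: str = "") -> QueryResult:
    """Row-concatenate results sharing the same column set, in list order."""
    if not results:
        raise ValueError("concat() needs at least one result")
    cols0 = set(results[0].columns)
    for r in results[1:]:
        if set(r.columns) != cols0:
            diff = cols0.symmetric_difference(r.columns)
            raise ValueError(f"cannot concat results with different columns; "
                             f"difference: {sorted(diff)}")
    df = pd.concat([r.df[results[0].columns] for r in results],
                   ignore_index=True)
    prov = [p for r in results for p in r.provenance]
    items = [i for r in results for i in r.items]
    return QueryResult(df, provenance=prov or None, title=title, items=items)


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def video_link(match: Match, start_frame: int) -> Optional[str]:
    """Deep link into the match video, starting playback at the item:
    the URL gains a ``t=<seconds>`` parameter (floor(start_frame/fps))."""
    url = match.video.url
    if not url:
        log.warning("match %r has no video URL; link is null", match.title)
        return None
    offset = int(start_frame // match.video.fps)
    sep = "&" if "?" in url else "?"
    return f"{url}{sep}t={offset}"


def _cell(value):
    """Convert an evaluated attribute into a table cell."""
    if is_absent(value) or value is None:
        return None
    if isinstance(value, (bool, int, float, str)):
        return value
    if isinstance(value, ShotType):
        return value.code
    if isinstance(value, TagSet):
        return str(value)
    if isinstance(value, BoundPlayer):
        return value.player.name
    if isinstance(value, Player):
        return value.name
    if isinstance(value, Vec2):
        return (value.x, value.y)
    if isinstance(value, TemporalUnit):
        return getattr(value, "id", repr(value))
    if hasattr(value, "name"):
        return value.name
    return str(value)


def _eval_predicate(pred: Predicate, item, helpers):
    if isinstance(pred, CompiledExpression):
        return pred.evaluate(item, helpers)
    return pred(item)


def execute(q: QueryDef, scope, attribs: Sequence = (),
            helpers: Optional[Mapping[str, Any]] = None,
            links: bool = True) -> QueryResult:
    """Run ``q`` over ``scope`` (a match or list of matches).

    One output row per item whose predicate is truthy; a predicate that
    evaluates to Absent omits the row without error.  Attribute
    expressions that evaluate to Absent yield explicit nulls.
    """
    matches = list(scope) if isinstance(scope, (list, tuple)) else [scope]
    specs = [AttributeSpec.coerce(a) for a in attribs]
    compiled = [compile_expression(s.expression) for s in specs]
    columns = [s.alias for s in specs]
    if len(set(columns)) != len(columns):
        raise ValueError(f"duplicate column aliases in {columns}")
    rows: list[list] = []
    prov: list[RowProvenance] = []
    items: list = []
    for match in matches:
        for item in match.iter_units(q.kind):
            try:
                keep = _eval_predicate(q.predicate, item, helpers)
            except Exception as exc:
                raise RuntimeError(
                    f"query {q.name!r} predicate failed on {item!r} "
                    f"(match {match.title!r}): {exc}") from exc
            if is_absent(keep) or not keep:
                continue
            row = []
            for spec, expr in zip(specs, compiled):
                try:
                    row.append(_cell(expr.evaluate(item, helpers)))
                except Exception as exc:
                    raise RuntimeError(
                        f"attribute {spec.expression!r} failed on {item!r} "
                        f"at level {q.kind!r}: {exc}") from exc
            rows.append(row)
            items.append(item)
            prov.append(RowProvenance(
                match_title=match.title, start_frame=item.start_frame,
                link=video_link(match, item.start_frame)
                if links and match.video.url else None))
    df = pd.DataFrame(rows, columns=columns)
    return QueryResult(df, provenance=prov, title=q.name, items=items)


# ---------------------------------------------------------------------------
# Built-in catalog
# ---------------------------------------------------------------------------

def _q1(shot):
    return shot.one_of("vd,vr")


def _q2(shot):
    return shot.one_of("vd,vr") and shot.duration < 1 and shot.abs_angle < 8


def _q3(shot):
    return shot.next


def _q4(shot):
    return shot.like("serve") and shot.next


def _q6(frame):
    return (frame.time - frame.point.start_time) < 1


def _q7a(frame):
    winner = frame.point.winner
    return (winner and frame.distance_to_net(winner.forehand_player) < 4
            and frame.distance_to_net(winner.backhand_player) < 4)


def _q7b(shot):
    winner = shot.point.winner
    if not winner or shot.hitter_player not in winner:
        return False
    return not shot.next or not shot.next.next


def _q8(frame):
    return True


def _q9(shot):
    return shot.like("lob") and shot.next.one_of(DEFENSIVE_CODES)


def _q10(shot):
    return (shot.like("serve") and shot.next.hitter.distance_to_side_wall > 2.5
            and shot.next.next.one_of("vd,vr")
            and shot.next.next.next.hitter.distance_to_side_wall < 2.5
            and shot.next.hitter == shot.next.next.next.hitter)


_POSITION_ATTRIBS = ["hitter.position.x", "hitter.position.y",
                     "hitter.last_name", "frame.frame_number"]
_DIRECTION_ATTRIBS = _POSITION_ATTRIBS + [
    "next.hitter.position.x", "next.hitter.position.y", "angle", "abs_angle"]
_FRAME_ATTRIBS = ["frame_number", "time", "duration", ("point.id", "point")]


def builtin_catalog() -> dict[str, tuple[QueryDef, list]]:
    """The ten standard queries, each with its default attribute list.

    q1  volleys (forehand or backhand) and their directions
    q2  fast (<1 s) down-the-line (|angle|<8 deg) volleys
    q3  every non-last shot, carrying its duration
    q4  serves and their directions
    q5  serves with the server partner's position
    q6  frames within 1 s of the rally start
    q7a frames where both point winners occupy the net zone (<4 m)
    q7b winning shots (hitter on the winning team, at most one shot follows)
    q8  every frame, with per-frame displacement attributes
    q9  lobs answered by a defensive stroke
    q10 serve -> wide return -> volley at the returner (2.5 m thresholds)
    """
    cat: dict[str, tuple[QueryDef, list]] = {
        "q1": (QueryDef("volleys", "shot", _q1), list(_DIRECTION_ATTRIBS)),
        "q2": (QueryDef("fast_down_the_line_volleys", "shot", _q2),
               list(_DIRECTION_ATTRIBS) + ["duration"]),
        "q3": (QueryDef("all_non_last_shots", "shot", _q3),
               ["hitter.position.x", "hitter.position.y", "id", "duration"]),
        "q4": (QueryDef("serves", "shot", _q4), list(_DIRECTION_ATTRIBS)),
        "q5": (QueryDef("serves_with_partner", "shot", _q4),
               list(_POSITION_ATTRIBS) + [
                   "hitter.partner.last_name", "hitter.partner.position.x",
                   "hitter.partner.position.y"]),
        "q6": (QueryDef("all_frames_after_serve", "frame", _q6),
               list(_FRAME_ATTRIBS)),
        "q7a": (QueryDef("time_on_net_for_winning_team", "frame", _q7a),
                ["duration", ("point.id", "point")]),
        "q7b": (QueryDef("winning_shots", "shot", _q7b),
                ["hitter.last_name", "hitter.position.x", "hitter.position.y",
                 "frame.frame_number", ("hitter.distance_to_net", "distance")]),
        "q8": (QueryDef("all_frames", "frame", _q8), list(_FRAME_ATTRIBS)),
        "q9": (QueryDef("lobs_followed_by_defensive", "shot", _q9),
               list(_POSITION_ATTRIBS) + [
                   "next.hitter.distance_to_back_wall",
                   "next.next.hitter.distance_to_net"]),
        "q10": (QueryDef("serve_return_volley", "shot", _q10),
                list(_POSITION_ATTRIBS) + [
                    "next.hitter.last_name",
                    "next.hitter.distance_to_side_wall",
                    "next.next.next.hitter.distance_to_side_wall"]),
    }
    return cat


# ---------------------------------------------------------------------------
# Plot-data extraction
# ---------------------------------------------------------------------------

PLOT_KINDS = ("positions", "player_positions", "directions", "distribution",
              "histogram", "bar_chart")


def _court_overlay(geometry=None) -> dict:
    from .model import CourtGeometry
    geo = geometry or CourtGeometry()
    w, l, n = geo.width, geo.length, geo.net_y
    return {"boundary": [(0, 0), (w, 0), (w, l), (0, l), (0, 0)],
            "net": [(0, n), (w, n)],
            "width": w, "length": l}


def _find_column(df: pd.DataFrame, requested: Optional[str],
                 suffixes: tuple[str, ...], what: str) -> str:
    if requested is not None:
        if requested not in df.columns:
            raise KeyError(f"plot mapping {what}={requested!r} names no "
                           f"column; have {list(df.columns)}")
        return requested
    for col in df.columns:
        if any(str(col).endswith(sfx) for sfx in suffixes):
            return col
    raise KeyError(f"cannot infer the {what!r} column; pass {what}=<column>; "
                   f"have {list(df.columns)}")


def plot_data(result: QueryResult, kind: str, geometry=None,
              **options) -> dict:
    """The exact table handed to a renderer for one plot kind, plus court
    overlay geometry where positions are drawn.  Rendering itself is a
    thin adapter (see :func:`render_mpl`)."""
    if kind not in PLOT_KINDS:
        raise ValueError(f"unknown plot kind {kind!r}; expected one of "
                         f"{PLOT_KINDS}")
    df = result.df
    out: dict = {"kind": kind}
    if kind == "positions":
        x = _find_column(df, options.get("x"), ("position.x", ".x", "x"), "x")
        y = _find_column(df, options.get("y"), ("position.y", ".y", "y"), "y")
        data = df[[x, y]].rename(columns={x: "x", y: "y"})
        if options.get("color") in df.columns:
            data["color"] = df[options["color"]]
        out.update(data=data, court=_court_overlay(geometry))
    elif kind == "player_positions":
        pairs = []
        for col in df.columns:
            if str(col).endswith(".x"):
                prefix = str(col)[:-2]
                ycol = prefix + ".y"
                if ycol in df.columns:
                    pairs.append((prefix.rstrip("."), col, ycol))
        if not pairs:
            raise KeyError("player_positions needs '<name>.x'/'<name>.y' "
                           f"column pairs; have {list(df.columns)}")
        frames = [pd.DataFrame({"player": name, "x": df[xc], "y": df[yc]})
                  for name, xc, yc in pairs]
        out.update(data=pd.concat(frames, ignore_index=True),
                   court=_court_overlay(geometry))
    elif kind == "directions":
        x0 = _find_column(df, options.get("x0"), ("hitter.position.x",), "x0")
        y0 = _find_column(df, options.get("y0"), ("hitter.position.y",), "y0")
        x1 = _find_column(df, options.get("x1"), ("next.hitter.position.x",), "x1")
        y1 = _find_column(df, options.get("y1"), ("next.hitter.position.y",), "y1")
        data = df[[x0, y0, x1, y1]].rename(
            columns={x0: "x0", y0: "y0", x1: "x1", y1: "y1"})
        color = options.get("color")
        if color is not None and color in df.columns:
            data["color"] = df[color]
        data = data.dropna(subset=["x0", "y0", "x1", "y1"])
        out.update(data=data, court=_court_overlay(geometry))
    elif kind == "distribution":
        col = options.get("density") or options.get("column")
        if col not in df.columns:
            raise KeyError(f"distribution needs density=<column>; have "
                           f"{list(df.columns)}")
        data = df[[col]].rename(columns={col: "value"}).dropna()
        groupby = options.get("groupby")
        if groupby is not None and groupby in df.columns:
            data["group"] = df.loc[data.index, groupby]
        out.update(data=data.reset_index(drop=True))
    elif kind == "histogram":
        col = options.get("column")
        if col is None and len(df.columns) == 1:
            col = df.columns[0]
        if col not in df.columns:
            raise KeyError(f"histogram needs column=<column>; have "
                           f"{list(df.columns)}")
        values = pd.to_numeric(df[col], errors="coerce").dropna().to_numpy()
        counts, edges = np.histogram(values, bins=options.get("bins", 10))
        out.update(data=pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:],
             "count": counts}), values=values)
    elif kind == "bar_chart":
        for key in ("x", "y"):
            if options.get(key) not in df.columns:
                raise KeyError(f"bar_chart needs {key}=<column>; have "
                               f"{list(df.columns)}")
        data = df[[options["x"], options["y"]]].rename(
            columns={options["x"]: "x", options["y"]: "y"})
        color = options.get("color")
        if color is not None:
            if color not in df.columns:
                raise KeyError(f"bar_chart color={color!r} names no column")
            data["color"] = df[color]
        out.update(data=data)
    return out


def render_mpl(plot: dict, ax=None):
    """Minimal matplotlib adapter for :func:`plot_data` output; replace
    freely with any other backend."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    data = plot["data"]
    kind = plot["kind"]
    if "court" in plot:
        bx, by = zip(*plot["court"]["boundary"])
        nx, ny = zip(*plot["court"]["net"])
        ax.plot(bx, by, color="k", lw=1)
        ax.plot(nx, ny, color="k", lw=1, ls="--")
        ax.set_aspect("equal")
    if kind in ("positions", "player_positions"):
        ax.scatter(data["x"], data["y"], s=12)
    elif kind == "directions":
        for _, r in data.iterrows():
            ax.annotate("", xy=(r["x1"], r["y1"]), xytext=(r["x0"], r["y0"]),
                        arrowprops=dict(arrowstyle="->", lw=0.8))
    elif kind == "distribution":
        ax.hist(data["value"], bins=30, density=True)
    elif kind == "histogram":
        ax.bar(data["bin_left"], data["count"],
               width=data["bin_right"] - data["bin_left"], align="edge")
    elif kind == "bar_chart":
        ax.bar(data["x"].astype(str), data["y"])
    return ax
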