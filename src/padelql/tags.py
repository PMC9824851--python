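"""Extensible tag system over the padel shot taxonomy.

Every play unit carries a :class:`TagSet` — a growing set of tokens that
queries test with two membership operators:

* ``like("cross-court volley")`` — AND semantics: the whole query string
  matches one member (important for multi-word shot-type aliases such as
  "forehand volley"), otherwise every whitespace token must match.
* ``one_of("vd,vr")`` — OR semantics over a comma-separated code list.

Tokens may be plain strings or :class:`ShotType` objects, which answer to
their code and to every registered alias ("vd", "drive volley",
"forehand volley", optionally the Spanish name).  The built-in registry
ships the 27-entry taxonomy used for annotating padel shots; analysts can
extend it, and can add arbitrary tags at runtime through
:class:`TagRule` / :func:`apply_tags`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Iterator, Optional


def _norm(token: str) -> str:
    return str(token).strip().lower()


class ShotType:
    """One taxonomy entry: a short code, its Spanish expansion and the
    English aliases it answers to.  Matching is case-insensitive; the
    Spanish name only matches when ``match_spanish`` is enabled (off by
    default to avoid token collisions in mixed-language tag sets)."""

    __slots__ = ("code", "spanish_name", "aliases", "match_spanish")

    def __init__(self, code: str, spanish_name: str = "",
                 aliases: Iterable[str] = (), match_spanish: bool = False):
        self.code = _norm(code)
        self.spanish_name = spanish_name.strip()
        self.aliases = tuple(_norm(a) for a in aliases if str(a).strip())
        self.match_spanish = match_spanish

    def matches(self, token: str) -> bool:
        t = _norm(token)
        if t == self.code or t in self.aliases:
            return True
        return self.match_spanish and t == _norm(self.spanish_name)

    def __eq__(self, other) -> bool:
        if isinstance(other, ShotType):
            return other.code == self.code
        if isinstance(other, str):
            return self.matches(other)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(("ShotType", self.code))

    def __str__(self) -> str:
        return self.code

    def __repr__(self) -> str:
        return f"ShotType({self.code!r})"


class ShotTypeRegistry:
    """Lookup table from codes/aliases to :class:`ShotType` entries."""

    def __init__(self, types: Iterable[ShotType] = ()):
        self._types: dict[str, ShotType] = {}
        for t in types:
            self.add(t)

    def add(self, shot_type: ShotType) -> None:
        if shot_type.code in self._types:
            raise ValueError(f"duplicate shot code {shot_type.code!r}")
        self._types[shot_type.code] = shot_type

    def resolve(self, token: str) -> Optional[ShotType]:
        """The entry whose code or alias equals ``token`` (case-insensitive),
        or None."""
        t = _norm(token)
        hit = self._types.get(t)
        if hit is not None:
            return hit
        for st in self._types.values():
            if st.matches(t):
                return st
        return None

    def __getitem__(self, code: str) -> ShotType:
        st = self.resolve(code)
        if st is None:
            raise KeyError(f"unknown shot type {code!r}")
        return st

    def __contains__(self, token: str) -> bool:
        return self.resolve(token) is not None

    def __iter__(self) -> Iterator[ShotType]:
        return iter(self._types.values())

    def __len__(self) -> int:
        return len(self._types)

    @classmethod
    def from_csv(cls, path_or_buffer, match_spanish: bool = False) -> "ShotTypeRegistry":
        reg = cls()
        if hasattr(path_or_buffer, "read"):
            rows = list(csv.DictReader(path_or_buffer))
        else:
            with open(path_or_buffer, newline="", encoding="utf-8") as fh:
                rows = list(csv.DictReader(fh))
        for row in rows:
            reg.add(ShotType(row["code"], row.get("spanish_name", ""),
                             (row.get("aliases") or "").split(";"),
                             match_spanish=match_spanish))
        return reg


def default_registry(match_spanish: bool = False) -> ShotTypeRegistry:
    """The packaged 27-entry shot taxonomy."""
    data = resources.files("padelql").joinpath("data/shot_types.csv")
    with data.open("r", encoding="utf-8") as fh:
        return ShotTypeRegistry.from_csv(fh, match_spanish=match_spanish)


class TagSet:
    """A dynamic, grow-only set of tag tokens (strings and ShotTypes)."""

    __slots__ = ("_members",)

    def __init__(self, members: Iterable = ()):
        self._members: list = []
        for m in members:
            self.add(m)

    def add(self, token) -> None:
        if token is None:
            return
        if not self._has_exact(token):
            self._members.append(token)

    def _has_exact(self, token) -> bool:
        if isinstance(token, ShotType):
            return any(isinstance(m, ShotType) and m.code == token.code
                       for m in self._members)
        t = _norm(token)
        return any(not isinstance(m, ShotType) and _norm(m) == t
                   for m in self._members)

    def _matches_member(self, token: str) -> bool:
        t = _norm(token)
        for m in self._members:
            if isinstance(m, ShotType):
                if m.matches(t):
                    return True
            elif _norm(m) == t:
                return True
        return False

    def like(self, query: str) -> bool:
        """True if the whole query matches one member, else if every
        whitespace-separated token matches a member (AND)."""
        if not str(query).strip():
            raise ValueError("like() requires a non-empty query")
        if self._matches_member(query):
            return True
        return all(self._matches_member(tok) for tok in str(query).split())

    def one_of(self, codes_csv: str) -> bool:
        """True if any comma-separated token matches a member (OR)."""
        tokens = [t for t in (p.strip() for p in str(codes_csv).split(",")) if t]
        if not tokens:
            raise ValueError("one_of() requires a non-empty code list")
        return any(self._matches_member(tok) for tok in tokens)

    def __contains__(self, token) -> bool:
        return self._matches_member(str(token))

    def __iter__(self) -> Iterator:
        return iter(self._members)

    def __len__(self) -> int:
        return len(self._members)

    def __str__(self) -> str:
        return " ".join(sorted(str(m) for m in self._members))

    def __repr__(self) -> str:
        return f"TagSet({{{', '.join(repr(str(m)) for m in self._members)}}})"


@dataclass
class TagRule:
    """A user-defined tag: a name plus a Boolean predicate applied to
    every unit of ``kind`` in a scope.  Application is idempotent."""

    name: str
    kind: str
    predicate: Callable[[object], object]


_RULES: dict[str, TagRule] = {}


def register_tag(rule: TagRule) -> TagRule:
    from .model import LEVELS
    if rule.kind not in LEVELS:
        raise ValueError(f"unknown unit kind {rule.kind!r}; expected one of {LEVELS}")
    _RULES[rule.name] = rule
    return rule


def registered_rules() -> dict[str, TagRule]:
    return dict(_RULES)


def apply_tags(rule: TagRule, scope) -> int:
    """Traverse every unit of ``rule.kind`` in ``scope`` (a match or a list
    of matches) and insert ``rule.name`` where the predicate holds.
    Returns the number of units tagged (idempotent on re-application)."""
    matches = scope if isinstance(scope, (list, tuple)) else [scope]
    count = 0
    for match in matches:
        for item in match.iter_units(rule.kind):
            try:
                hit = bool(rule.predicate(item))
            except Exception as exc:
                raise RuntimeError(
                    f"tag rule {rule.name!r} raised on {item!r}: {exc}") from exc
            if hit:
                item.tags.add(rule.name)
                count += 1
    return count


def auto_tags(match) -> None:
    """Insert the built-in tags on an assembled match: each shot's
    ShotType, "serve", "lob", "by-<lastname>", and "winning" for shots
    whose hitter's team won the point."""
    for shot in match.iter_units("shot"):
        st = shot.shot_type
        if st is not None:
            shot.tags.add(st)
            if isinstance(st, ShotType) and st.code == "s":
                shot.tags.add("serve")
        if getattr(shot, "lob", False):
            shot.tags.add("lob")
        hitter = shot.hitter_player
        if hitter is not None:
            shot.tags.add(f"by-{hitter.last_name.lower()}")
            point = shot.point
            winner = getattr(point, "winner", None)
            if winner and hitter in winner:
                shot.tags.add("winning")
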