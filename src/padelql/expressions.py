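"""Safe evaluator for the query expression mini-grammar.

Attribute expressions and YAML/CLI predicates are plain text such as
``shot.next.hitter.distance_to_net < 3`` or
``frame.time - frame.point.start_time < 1``.  The grammar covers dotted
member paths, numeric/text/Boolean literals, arithmetic, comparisons,
``and``/``or``/``not``, parentheses and method calls on members
(``shot.like("volley")``).  It is a strict whitelist over the host
language's syntax tree: no subscripts, no imports, no builtins, no side
effects.

Root names resolve in order: (1) the level name of the current item
("shot" inside a shot query), (2) a property of the current item
("hitter" for ``hitter.position.x``), (3) a match player by lowercase
last name, bound to the current frame context
("salazar.distance_from_prev_frame"), (4) registered helper names.
Evaluation follows the Absent contract: a missing link anywhere in a
path yields Absent, which compares false and propagates through
arithmetic.
"""

from __future__ import annotations

import ast
import operator
from typing import Any, Callable, Mapping, Optional

from .model import ABSENT, Frame, Shot, TemporalUnit

__all__ = ["ExpressionError", "CompiledExpression", "compile_expression"]


class ExpressionError(ValueError):
    """Malformed or out-of-grammar expression, or unresolvable name."""


_BIN_OPS: dict[type, Callable] = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Mod: operator.mod,
}

_CMP_OPS: dict[type, Callable] = {
    ast.Eq: operator.eq,
    ast.NotEq: operator.ne,
    ast.Lt: operator.lt,
    ast.LtE: operator.le,
    ast.Gt: operator.gt,
    ast.GtE: operator.ge,
}

_ALLOWED = (
    ast.Expression, ast.BoolOp, ast.And, ast.Or, ast.UnaryOp, ast.Not,
    ast.USub, ast.BinOp, ast.Compare, ast.Call, ast.Attribute, ast.Name,
    ast.Constant, ast.Load, ast.keyword,
) + tuple(_BIN_OPS) + tuple(_CMP_OPS)


class CompiledExpression:
    """A parsed, validated expression ready to evaluate against an item."""

    def __init__(self, text: str):
        self.text = text
        try:
            tree = ast.parse(text, mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(f"cannot parse {text!r}: {exc.msg}") from None
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED):
                raise ExpressionError(
                    f"{type(node).__name__} is not allowed in query "
                    f"expressions: {text!r}")
            if isinstance(node, ast.Constant) and not isinstance(
                    node.value, (int, float, str, bool, type(None))):
                raise ExpressionError(f"unsupported literal in {text!r}")
        self._tree = tree

    def __call__(self, item, helpers: Optional[Mapping[str, Any]] = None):
        return self.evaluate(item, helpers)

    def evaluate(self, item, helpers: Optional[Mapping[str, Any]] = None):
        return _eval(self._tree.body, item, helpers or {}, self.text)

    def __repr__(self) -> str:
        return f"CompiledExpression({self.text!r})"


def compile_expression(text: str) -> CompiledExpression:
    return CompiledExpression(text)


def _frame_context(item) -> Optional[Frame]:
    if isinstance(item, Frame):
        return item
    if isinstance(item, Shot):
        f = item.frame
        return None if f is ABSENT else f
    return None


def _resolve_name(name: str, item, helpers: Mapping[str, Any], text: str):
    level = getattr(item, "level", None)
    if name == level:
        return item
    try:
        return getattr(item, name)
    except AttributeError:
        pass
    match = item.ancestor("match") if isinstance(item, TemporalUnit) else None
    if match is not None and match is not ABSENT:
        player = match.player_by_last_name(name)
        if player is not None:
            frame = _frame_context(item)
            return frame.bound(player) if frame is not None else player
    if name in helpers:
        return helpers[name]
    if name in ("True", "False", "None"):  # pragma: no cover - literal names
        return {"True": True, "False": False, "None": None}[name]
    raise ExpressionError(
        f"cannot resolve {name!r} in {text!r} from a "
        f"{level or type(item).__name__} item: not a property, a player "
        f"last name, or a registered helper")


def _eval(node: ast.AST, item, helpers: Mapping[str, Any], text: str):
    if isinstance(node, ast.Constant):
        return node.value
    if isinstance(node, ast.Name):
        return _resolve_name(node.id, item, helpers, text)
    if isinstance(node, ast.Attribute):
        value = _eval(node.value, item, helpers, text)
        if value is ABSENT or value is None:
            return ABSENT
        try:
            return getattr(value, node.attr)
        except AttributeError as exc:
            raise ExpressionError(
                f"{type(value).__name__} object has no attribute "
                f"{node.attr!r} (in {text!r})") from exc
    if isinstance(node, ast.Call):
        func = _eval(node.func, item, helpers, text)
        if func is ABSENT:
            return ABSENT
        args = [_eval(a, item, helpers, text) for a in node.args]
        kwargs = {kw.arg: _eval(kw.value, item, helpers, text)
                  for kw in node.keywords}
        return func(*args, **kwargs)
    if isinstance(node, ast.BoolOp):
        if isinstance(node.op, ast.And):
            result: Any = True
            for sub in node.values:
                result = _eval(sub, item, helpers, text)
                if not result:
                    return result
            return result
        result = False
        for sub in node.values:
            result = _eval(sub, item, helpers, text)
            if result:
                return result
        return result
    if isinstance(node, ast.UnaryOp):
        val = _eval(node.operand, item, helpers, text)
        if isinstance(node.op, ast.Not):
            return not val
        return -val
    if isinstance(node, ast.BinOp):
        left = _eval(node.left, item, helpers, text)
        right = _eval(node.right, item, helpers, text)
        return _BIN_OPS[type(node.op)](left, right)
    if isinstance(node, ast.Compare):
        left = _eval(node.left, item, helpers, text)
        for op, comparator in zip(node.ops, node.comparators):
            right = _eval(comparator, item, helpers, text)
            if not _CMP_OPS[type(op)](left, right):
                return False
            left = right
        return True
    raise ExpressionError(f"unsupported construct in {text!r}")
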