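"""Tennis-style scoring automaton shared by ingest and the synthetic
generator.

Padel scores exactly like tennis: points run 0 -> 15 -> 30 -> 40 -> game.
At 40-40 two modes exist: *advantage* (a two-point lead is needed, via the
"Ad" label) and *golden_point* (the next point decides the game, the rule
adopted by the professional tour).  Games accumulate into sets (first to
six, two clear; 6-6 is resolved by a single deciding game, a tie-break
modeled as one game).  The automaton is total: any winner sequence is
legal and replayable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

POINT_LABELS = ("0", "15", "30", "40")
MODES = ("advantage", "golden_point")


@dataclass(frozen=True)
class ScoreState:
    """Score after one point: within-game labels for the Top (A) and
    Bottom (B) teams, accumulated games and sets, and what the point
    closed."""

    mode: str
    score_A: str
    score_B: str
    games_A: int
    games_B: int
    sets_A: int
    sets_B: int
    game_winner: str | None = None   # "T"/"B" when this point ended a game
    set_winner: str | None = None

    @property
    def labels(self) -> tuple[str, str]:
        return (self.score_A, self.score_B)


def _labels(a: int, b: int) -> tuple[str, str]:
    if a >= 3 and b >= 3:
        if a == b:
            return ("40", "40")
        return ("Ad", "40") if a > b else ("40", "Ad")
    return (POINT_LABELS[min(a, 3)], POINT_LABELS[min(b, 3)])


class ScoreKeeper:
    """Incremental form of the automaton; feed point winners one at a
    time with :meth:`record`."""

    def __init__(self, mode: str = "advantage"):
        if mode not in MODES:
            raise ValueError(f"unknown scoring mode {mode!r}; expected one of {MODES}")
        self.mode = mode
        self._pts = {"T": 0, "B": 0}
        self.games = {"T": 0, "B": 0}
        self.sets = {"T": 0, "B": 0}

    def _game_won(self, w: str) -> bool:
        a, b = self._pts[w], self._pts["B" if w == "T" else "T"]
        if self.mode == "golden_point":
            return a >= 4
        return a >= 4 and a - b >= 2

    def _set_won(self, w: str) -> bool:
        g, o = self.games[w], self.games["B" if w == "T" else "T"]
        # first to 6 two clear; 6-6 decided by a single extra game (7-6)
        return (g >= 6 and g - o >= 2) or g == 7

    def record(self, winner: str) -> ScoreState:
        if winner not in ("T", "B"):
            raise ValueError(f"winner must be 'T' or 'B', got {winner!r}")
        self._pts[winner] += 1
        game_winner = set_winner = None
        if self._game_won(winner):
            game_winner = winner
            self._pts = {"T": 0, "B": 0}
            self.games[winner] += 1
            if self._set_won(winner):
                set_winner = winner
                self.sets[winner] += 1
                self.games = {"T": 0, "B": 0}
        la, lb = _labels(self._pts["T"], self._pts["B"])
        if game_winner is not None:
            la, lb = "0", "0"
        return ScoreState(mode=self.mode, score_A=la, score_B=lb,
                          games_A=self.games["T"], games_B=self.games["B"],
                          sets_A=self.sets["T"], sets_B=self.sets["B"],
                          game_winner=game_winner, set_winner=set_winner)


def score_automaton(
    winners: Sequence[str], mode: str = "advantage"
) -> tuple[list[ScoreState], list[tuple[int, int]], list[tuple[int, int]]]:
    """Replay a winner sequence.

    Returns per-point states, game boundaries and set boundaries, both as
    inclusive ``(first_point_index, last_point_index)`` ranges; a trailing
    unfinished game/set is included as a partial range.
    """
    if not winners:
        raise ValueError("winner sequence must be nonempty")
    keeper = ScoreKeeper(mode)
    states: list[ScoreState] = []
    game_bounds: list[tuple[int, int]] = []
    set_bounds: list[tuple[int, int]] = []
    game_start = set_start = 0
    for i, w in enumerate(winners):
        state = keeper.record(w)
        states.append(state)
        if state.game_winner is not None:
            game_bounds.append((game_start, i))
            game_start = i + 1
        if state.set_winner is not None:
            set_bounds.append((set_start, i))
            set_start = i + 1
    n = len(winners)
    if game_start < n:
        game_bounds.append((game_start, n - 1))
    if set_start < n:
        set_bounds.append((set_start, n - 1))
    return states, game_bounds, set_bounds


def detect_mode(winners: Sequence[str],
                printed_labels: Iterable[tuple[str, str]]) -> tuple[str, int]:
    """Pick the scoring mode whose replay best agrees with printed
    per-point score labels.  Returns (mode, number of disagreements)."""
    printed = list(printed_labels)
    best_mode, best_miss = MODES[0], None
    for mode in MODES:
        states, _, _ = score_automaton(winners, mode)
        miss = sum(1 for s, lab in zip(states, printed)
                   if any(lab) and s.labels != tuple(lab))
        if best_miss is None or miss < best_miss:
            best_mode, best_miss = mode, miss
    return best_mode, int(best_miss or 0)
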