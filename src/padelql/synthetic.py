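"""Seeded generator of padel-consistent match bundles.

Emits the three tabular schemas (points, shots, frames) with a known
ground truth, so the whole pipeline — ingest, navigation, kinematics,
tags, queries — is testable without any recorded match.  The simulation
is deliberately simple but padel-shaped:

* rallies open with a serve (server deep in their own half, partner
  about 2 m from the net) and hitters alternate teams, the team-mate
  nearer the simulated contact point taking the ball;
* rally lengths are geometric (mean 6 shots) and inter-shot intervals
  lognormal with a mean near 1.3 s, the scale observed in elite women's
  padel;
* shot codes follow a small transition table over the standard taxonomy
  (serve -> return family -> volleys / smashes / lobs), with the lob
  flag raised on lofted groundstrokes;
* players head toward waypoints at a capped speed (default 7 m/s) with
  jitter, the serving team advancing to the net with probability
  ``net_approach_prob``;
* score columns are produced by the same scoring automaton the ingest
  side replays, so reconstruction is exact by construction.

The ball itself is not simulated (the schemas carry no ball data): shot
positions are the hitters' positions at hit time, and the image-space
columns come from a fixed synthetic camera projection purely to populate
the schema.  Identical seeds produce byte-identical bundles.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .ingest import FRAMES_COLUMNS, POINTS_COLUMNS, SHOTS_COLUMNS
from .model import CourtGeometry
from .scoring import ScoreKeeper

RETURN_CODES = ["d", "r", "spd", "spr", "pld", "plr"]
NET_CODES = ["vd", "vr", "b", "r1", "djd"]
BACK_CODES = ["d", "r", "cp", "spd", "spr", "dpa", "dpc", "cd", "cr"]
LOBBABLE = {"d", "r", "pld", "plr"}

ROSTER = {
    "TOP": [("C", "Garcia"), ("M", "Lopez")],
    "BOTTOM": [("A", "Sanchez"), ("P", "Salazar")],
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults describe a realistic elite rally."""

    seed: int = 0
    fps: int = 30
    scoring_mode: str = "golden_point"   # the professional-tour rule
    sets: int = 1                        # sets to play to completion
    max_points: Optional[int] = None     # truncate the match after N rallies
    mean_rally_shots: float = 6.0
    shot_interval_mean_s: float = 1.3
    shot_interval_sigma: float = 0.35    # lognormal shape parameter
    serve_depth_m: float = 1.5           # server's distance from the back wall
    partner_net_distance_m: float = 2.0  # server partner's distance to net
    max_speed_mps: float = 7.0
    waypoint_noise_m: float = 0.15
    net_approach_prob: float = 0.8
    inter_point_gap_s: float = 3.0
    court: CourtGeometry = field(default_factory=CourtGeometry)

    def __post_init__(self):
        if self.fps < 1:
            raise ValueError("fps must be >= 1")
        if self.mean_rally_shots < 1:
            raise ValueError("mean rally length must be >= 1 shot")
        for name in ("shot_interval_mean_s", "shot_interval_sigma",
                     "max_speed_mps", "inter_point_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """What the generator actually did, keyed the same way the tables are."""

    winners: list[str]                         # per point: "T"/"B"
    score_labels: list[tuple[str, str]]        # after each point
    game_bounds: list[tuple[int, int]]
    set_bounds: list[tuple[int, int]]
    shot_hitters: list[str]                    # per shot: hitter last name
    shot_codes: list[str]
    shot_frames: list[int]
    point_spans: list[tuple[int, int]]
    #: exact (unrounded) per-frame positions: frame -> last name -> (x, y)
    exact_positions: dict[int, dict[str, tuple[float, float]]]


@dataclass
class Bundle:
    """A generated match: the three tables plus roster and ground truth."""

    points: pd.DataFrame
    shots: pd.DataFrame
    frames: pd.DataFrame
    roster: dict[str, list[tuple[str, str]]]
    ground_truth: GroundTruth
    config: SynthConfig


class _SimPlayer:
    __slots__ = ("last", "first", "team", "pos", "target")

    def __init__(self, first: str, last: str, team: str,
                 pos: np.ndarray):
        self.first, self.last, self.team = first, last, team
        self.pos = pos.astype(float)
        self.target = pos.astype(float)


def _half_bounds(team: str, geo: CourtGeometry, margin: float = 0.25):
    if team == "BOTTOM":
        return (margin, geo.width - margin, margin, geo.net_y - margin)
    return (margin, geo.width - margin, geo.net_y + margin,
            geo.length - margin)


def _clip_to_half(pos: np.ndarray, team: str, geo: CourtGeometry) -> np.ndarray:
    x0, x1, y0, y1 = _half_bounds(team, geo)
    return np.clip(pos, [x0, y0], [x1, y1])


def _project_image(x: float, y: float, geo: CourtGeometry) -> tuple[int, int]:
    # fixed synthetic camera behind the bottom baseline: farther players sit
    # higher and more centered in the image
    depth = 0.35 + 0.65 * (1.0 - y / geo.length)
    i = 640 + (x - geo.width / 2) * 72 * depth
    j = 80 + 560 * depth
    return int(round(i)), int(round(j))


def generate_match(config: SynthConfig) -> Bundle:
    """Simulate a match under ``config`` and emit its tables."""
    rng = np.random.default_rng(config.seed)
    geo = config.court
    fps = config.fps
    dt = 1.0 / fps
    # strictly below the cap so that 2-decimal rounding in the emitted
    # table cannot push an observed step over max_speed/fps
    max_step = config.max_speed_mps * dt * 0.9

    players = {
        team: [_SimPlayer(f, l, team, np.zeros(2))
               for f, l in ROSTER[team]]
        for team in ("TOP", "BOTTOM")
    }
    all_players = players["TOP"] + players["BOTTOM"]

    keeper = ScoreKeeper(config.scoring_mode)
    gt = GroundTruth([], [], [], [], [], [], [], [], {})
    points_rows, shots_rows, frames_rows = [], [], []
    frame_cursor = 1000
    point_index = 0
    game_start = set_start = 0
    serving_team = "TOP"
    game_number = 0

    def other(team: str) -> str:
        return "BOTTOM" if team == "TOP" else "TOP"

    while True:
        if config.max_points is not None and point_index >= config.max_points:
            break
        if keeper.sets["T"] + keeper.sets["B"] >= config.sets:
            break

        # --- place the players for the serve --------------------------------
        deuce_side = point_index % 2 == 0   # serve alternates court halves
        server_team = serving_team
        recv_team = other(server_team)
        sx = geo.width * (0.72 if deuce_side else 0.28)
        if server_team == "BOTTOM":
            server_y = config.serve_depth_m
            partner_y = geo.net_y - config.partner_net_distance_m
            recv_y = geo.length - config.serve_depth_m - 0.5
            recv_partner_y = geo.net_y + 4.5
        else:
            server_y = geo.length - config.serve_depth_m
            partner_y = geo.net_y + config.partner_net_distance_m
            recv_y = config.serve_depth_m + 0.5
            recv_partner_y = geo.net_y - 4.5
        server_idx = game_number % 2
        server = players[server_team][server_idx]
        partner = players[server_team][1 - server_idx]
        receiver = players[recv_team][point_index % 2]
        recv_partner = players[recv_team][1 - point_index % 2]
        server.pos = np.array([sx, server_y])
        partner.pos = np.array([geo.width - sx, partner_y])
        receiver.pos = np.array([geo.width - sx, recv_y])
        recv_partner.pos = np.array([sx, recv_partner_y])
        for p in all_players:
            p.pos = _clip_to_half(
                p.pos + rng.normal(0, config.waypoint_noise_m, 2),
                p.team, geo)
            p.target = p.pos.copy()

        # --- plan the rally --------------------------------------------------
        n_shots = int(rng.geometric(1.0 / config.mean_rally_shots))
        mu = np.log(config.shot_interval_mean_s) \
            - config.shot_interval_sigma ** 2 / 2.0
        intervals = rng.lognormal(mu, config.shot_interval_sigma, n_shots)
        gap_frames = [max(2, int(round(iv * fps))) for iv in intervals]

        start_frame = frame_cursor
        # plan the rally: each entry is (frame, hitter, code, lob, responder,
        # contact point the responder runs to)
        shot_plan = []
        hitter = server
        hit_team = server_team
        sim_pos = {p: p.pos.copy() for p in all_players}
        f = start_frame
        for k in range(n_shots):
            if k == 0:
                code = "s"
            elif k == 1:
                code = RETURN_CODES[int(rng.integers(len(RETURN_CODES)))]
            else:
                near_net = abs(sim_pos[hitter][1] - geo.net_y) < 4.0
                pool = NET_CODES if near_net else BACK_CODES
                code = pool[int(rng.integers(len(pool)))]
            lob = bool(code in LOBBABLE and k > 0 and rng.random() < 0.18)
            # where the ball goes: deep for lobs, otherwise mixed depth
            hit_team = other(hit_team)
            tx = rng.uniform(1.0, geo.width - 1.0)
            if hit_team == "BOTTOM":
                ty = rng.uniform(1.0, geo.net_y - 1.0) if lob or rng.random() < 0.5 \
                    else rng.uniform(geo.net_y - 6.0, geo.net_y - 1.0)
            else:
                ty = rng.uniform(geo.net_y + 1.0, geo.length - 1.0) if lob or rng.random() < 0.5 \
                    else rng.uniform(geo.net_y + 1.0, geo.net_y + 6.0)
            contact = np.array([tx, ty])
            pair = players[hit_team]
            responder = min(
                pair, key=lambda p: float(np.linalg.norm(sim_pos[p] - contact)))
            shot_plan.append((f, hitter, code, lob, responder, contact))
            sim_pos[responder] = contact       # planning-time estimate only
            hitter = responder
            if k + 1 < n_shots:
                f += gap_frames[k]
        last_shot_frame = f
        end_frame = last_shot_frame + max(2, int(round(fps * rng.uniform(0.5, 1.0))))

        approach = rng.random() < config.net_approach_prob

        # --- simulate the frames ---------------------------------------------
        shot_iter = iter(shot_plan)
        next_shot = next(shot_iter, None)
        for fr in range(start_frame, end_frame):
            while next_shot is not None and next_shot[0] == fr:
                # at a hit, the answering player starts running to the ball
                _, _, _, _, responder, contact = next_shot
                responder.target = contact.copy()
                next_shot = next(shot_iter, None)
            for p in all_players:
                # serving team presses the net; everyone else drifts to target
                tgt = p.target.copy()
                if approach and p.team == server_team:
                    net_edge = geo.net_y - 2.0 if p.team == "BOTTOM" \
                        else geo.net_y + 2.0
                    tgt[1] = net_edge
                delta = tgt - p.pos
                dist = float(np.linalg.norm(delta))
                if dist > 1e-9:
                    step = min(max_step * 0.85, dist)
                    move = delta / dist * step
                else:
                    move = np.zeros(2)
                move = move + rng.normal(0, config.waypoint_noise_m * dt, 2)
                norm = float(np.linalg.norm(move))
                if norm > max_step:
                    move *= max_step / norm
                newpos = _clip_to_half(p.pos + move, p.team, geo)
                # clipping can only shorten the step, never lengthen it
                p.pos = newpos
            gt.exact_positions[fr] = {
                p.last: (float(p.pos[0]), float(p.pos[1]))
                for p in all_players}

        # --- corner labels at the rally's first frame ------------------------
        first_pos = gt.exact_positions[start_frame]
        tops = sorted(players["TOP"], key=lambda p: first_pos[p.last][0])
        bots = sorted(players["BOTTOM"], key=lambda p: first_pos[p.last][0])
        corner_of = {tops[0].last: "TL", tops[1].last: "TR",
                     bots[0].last: "BL", bots[1].last: "BR"}
        name_of = {v: f"{p.first} {p.last}"
                   for p, v in ((p, corner_of[p.last]) for p in all_players)}

        # --- emit rows --------------------------------------------------------
        winner = "T" if rng.random() < 0.5 else "B"
        state = keeper.record(winner)
        gt.winners.append(winner)
        gt.score_labels.append(state.labels)
        for (sf, hp, code, lob, _resp, _contact) in shot_plan:
            shots_rows.append([sf, corner_of[hp.last], code,
                               "T" if lob else "F"])
            gt.shot_hitters.append(hp.last)
            gt.shot_codes.append(code)
            gt.shot_frames.append(sf)
        for fr in range(start_frame, end_frame):
            pos = gt.exact_positions[fr]
            row = [fr]
            for c in ("TL", "TR", "BL", "BR"):
                last = next(l for l, cc in corner_of.items() if cc == c)
                x, y = pos[last]
                row.extend(_project_image(round(x, 2), round(y, 2), geo))
            for c in ("TL", "TR", "BL", "BR"):
                last = next(l for l, cc in corner_of.items() if cc == c)
                x, y = pos[last]
                row.extend([round(x, 2), round(y, 2)])
            frames_rows.append(row)
        dur_f = end_frame - start_frame
        points_rows.append([start_frame, end_frame, dur_f,
                            round(dur_f / fps, 1), winner,
                            state.score_A, state.score_B,
                            name_of["TL"], name_of["TR"],
                            name_of["BL"], name_of["BR"]])
        gt.point_spans.append((start_frame, end_frame))

        if state.game_winner is not None:
            gt.game_bounds.append((game_start, point_index))
            game_start = point_index + 1
            game_number += 1
            serving_team = other(serving_team)
        if state.set_winner is not None:
            gt.set_bounds.append((set_start, point_index))
            set_start = point_index + 1
        point_index += 1
        frame_cursor = end_frame + max(
            1, int(round(fps * rng.uniform(0.6, 1.4) * config.inter_point_gap_s)))

    if game_start < point_index:
        gt.game_bounds.append((game_start, point_index - 1))
    if set_start < point_index:
        gt.set_bounds.append((set_start, point_index - 1))

    return Bundle(
        points=pd.DataFrame(points_rows, columns=POINTS_COLUMNS),
        shots=pd.DataFrame(shots_rows, columns=SHOTS_COLUMNS),
        frames=pd.DataFrame(frames_rows, columns=FRAMES_COLUMNS),
        roster={t: list(ROSTER[t]) for t in ROSTER},
        ground_truth=gt, config=config)


def perturb(bundle: Bundle, sigma: float,
            seed: Optional[int] = None,
            tolerance_m: float = 0.5) -> Bundle:
    """Gaussian position noise (clipped to court bounds + tolerance) on the
    frames table, emulating tracking error; sigma=0 is the identity."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    geo = bundle.config.court
    frames = bundle.frames.copy()
    rng = np.random.default_rng(bundle.config.seed if seed is None else seed)
    for c in ("TL", "TR", "BL", "BR"):
        for axis, hi in (("x", geo.width), ("y", geo.length)):
            col = f"{c} {axis}"
            noisy = frames[col].astype(float) \
                + rng.normal(0.0, sigma, len(frames))
            frames[col] = np.clip(noisy, -tolerance_m, hi + tolerance_m).round(2)
    return replace_frames(bundle, frames)


def replace_frames(bundle: Bundle, frames: pd.DataFrame) -> Bundle:
    return Bundle(points=bundle.points, shots=bundle.shots, frames=frames,
                  roster=bundle.roster, ground_truth=bundle.ground_truth,
                  config=bundle.config)


# ---------------------------------------------------------------------------
# The printed example tables (five points, five shots, five frames) used as
# a self-contained worked fixture throughout the tests and docs.
# ---------------------------------------------------------------------------

_FIXTURE_POINTS = """\
Start (f)\tEnd (f)\tDuration (f)\tDuration (s)\tWinner\tPoints A\tPoints B\tTop Left\tTop Right\tBottom Left\tBottom Right
13,606\t13,820\t214\t7.1\tB\t0\t15\tL Sainz\tG Triay\tA Sánchez\tA Salazar
14,093\t14,785\t692\t23.1\tT\t15\t15\tL Sainz\tG Triay\tA Sánchez\tA Salazar
15,332\t16,204\t872\t29.1\tT\t30\t15\tL Sainz\tG Triay\tA Sánchez\tA Salazar
16,932\t17,004\t72\t2.4\tB\t30\t30\tL Sainz\tG Triay\tA Sánchez\tA Salazar
17,378\t17,661\t283\t9.4\tB\t30\t40\tL Sainz\tG Triay\tA Sánchez\tA Salazar
"""

_FIXTURE_SHOTS = """\
Frame\tPlayer\tShot Type\tLob
13,604\tTL\tServe\tF
13,633\tBR\tD\tT
13,656\tTL\tB\tF
13,676\tBR\tD\tF
13,696\tTL\tVD\tF
"""

_FIXTURE_FRAMES = """\
Frame\tTL i\tTL j\tTR i\tTR j\tBL i\tBL j\tBR i\tBR j\tTL x\tTL y\tTR x\tTR y\tBL x\tBL y\tBR x\tBR y
13,614\t478\t202\t785\t266\t401\t554\t911\t553\t1.89\t18.53\t7.49\t13.60\t2.50\t1.60\t7.87\t1.66
13,615\t477\t202\t785\t266\t401\t555\t912\t554\t1.87\t18.52\t7.49\t13.60\t2.50\t1.59\t7.88\t1.62
13,616\t477\t203\t785\t266\t400\t553\t914\t555\t1.89\t18.43\t7.49\t13.60\t2.49\t1.63\t7.89\t1.60
13,617\t479\t204\t785\t266\t399\t550\t915\t556\t1.94\t18.35\t7.49\t13.59\t2.47\t1.70\t7.90\t1.57
13,618\t480\t206\t785\t266\t398\t549\t918\t556\t1.96\t18.21\t7.49\t13.59\t2.46\t1.74\t7.93\t1.58
"""


def make_fixture_tables() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """The worked-example fragments of the three schemas (tab-delimited,
    thousands separators included) parsed into raw string DataFrames."""
    read = lambda s: pd.read_csv(io.StringIO(s), sep="\t", dtype=str)
    return (read(_FIXTURE_POINTS), read(_FIXTURE_SHOTS), read(_FIXTURE_FRAMES))
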