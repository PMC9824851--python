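# Methods

This note documents the data model, the conventions behind every derived
quantity, the synthetic generator, and the numerical and design choices
that were genuinely open.

## Data model

A digitized match arrives as three tables:

- **points** — start/end frame, durations (frames and seconds), winning
  team (`T`/`B`, the top/bottom half of the video), within-game score
  labels after the point, and the four player names keyed by video
  corner (`TL`/`TR`/`BL`/`BR` at serve time);
- **shots** — frame, hitter corner, shot-type code, lob flag;
- **frames** — per-frame image-space (pixels) and court-space (meters)
  positions of the four players.

Court space is x ∈ [0, 10] across the court, y ∈ [0, 20] along it, net
at y = 10 (configurable `CourtGeometry`). Image-space columns are
carried as opaque metadata; the camera-to-court homography belongs to
the upstream tracking pipeline, not to this package.

Assembly builds `Match > Set > Game > Point > Shot > Frame`. Every unit
has a half-open frame interval, a 1-based ordinal within its parent, a
tag set, and `next`/`prev` siblings. Time is `frame / fps` seconds.

**Frame rate inference.** The integer fps minimizing
Σ|duration_frames/fps − duration_seconds| over all points (exhaustive
search over 1–240). The residual is reported; an explicit `fps` override
is available when no second durations exist. The search is
scale-consistent: multiplying all frame columns by k multiplies the
inferred rate by k.

**Score reconstruction.** Point winners are replayed through a
tennis-style automaton (0→15→30→40; *advantage* requires a two-point
lead at deuce, *golden point* awards the game to the next point winner;
games accumulate to sets, first to six with two clear, 6–6 resolved by a
single deciding game standing in for the tie-break). Game and set
boundaries come from the automaton, not from score resets in the file,
so truncated tables still parse. The mode is auto-detected by best
agreement with the printed score columns; disagreements degrade to
warnings unless `strict=True`. We read "Points A" as the top team's
label, "Points B" as the bottom team's, both *after* the row's point —
the only reading consistent with a row whose winner is `B` and whose
labels are 0/15.

**Shot attachment.** A shot owns the frames in
[its start frame, the next shot's start frame), the last shot running to
the rally's end. Annotated frame numbers are approximate (they come from
video-player timestamps), so a shot stamped slightly outside its rally —
serves are typically stamped a frame or two before the printed rally
start — is clamped into the enclosing span within a tolerance
(default 10 frames) and logged, rather than rejected.

**Absent sentinel.** Off-end navigation returns `Absent` instead of
raising: any attribute access or call on it yields `Absent`, it is
falsy, propagates through arithmetic, and every comparison with it is
false except `Absent == Absent`. This is what makes chained predicates
such as `shot.next.next.next.hitter...` total on short rallies. Bare
(frame-less) players answer positional attributes with `Absent` for the
same reason; the functional kinematics API (`distance_to_net(bp)`,
`speed(bp)`) instead raises on unbound players, since a silent false
would hide a caller bug.

**Player sides.** Each team's `forehand_player` (the right side facing
the net) is inferred from mean x position during the games that team
served: for the bottom team (facing +y) the right side is larger x, for
the top team smaller x. The annotation schemas never state this mapping,
so it is overridable per team in `IngestConfig`.

## Kinematic conventions

- `distance_to_net` = |y − net_y|.
- Oriented wall distances take the player's view facing the net: bottom
  half (y < net_y) faces +y, so its right wall is x = width and its back
  wall y = 0; the top half is mirrored. `distance_to_side_wall` is
  min(left, right); left + right = width always. A player exactly on the
  net line takes facing from the team's assembly-time half, with a
  logged warning.
- `speed`/`acceleration` are central finite differences of position over
  a ±`window`-frame stencil (default 5 frames ≈ 0.33 s at 30 fps),
  truncated one-sided at rally boundaries and never differentiated
  across rallies. Single-frame rallies give a zero vector with a
  warning. Whether the upstream positions are smoothed before
  differencing is unknown, so the window is configurable and no extra
  smoothing is applied by default.
- `distance_from_prev_frame` is the Euclidean step between consecutive
  rally frames, 0 at the rally's first frame.
- **Shot direction.** No ball track exists, so a shot's destination is
  proxied by the position of the opponent who returns it, at the return
  frame. The angle is measured against the court long axis oriented
  *away* from the hitter: 0° is straight down the line, positive is
  toward the hitter's right, range (−180°, 180°]. Mirroring the court
  about its long midline negates the angle and preserves `abs_angle`.
  Any consistent sign convention would serve; this one makes "toward the
  right" positive for both halves. Rally-ending shots have no direction
  (`Absent`).

## Tag semantics

`like(q)` first tests the whole query string against every member
(including multi-word shot-type aliases such as "forehand volley"), then
falls back to AND over whitespace tokens — both behaviors are needed, as
"forehand volley" must match the `vd` alias while "cross-court volley"
must decompose into two independent tokens. `one_of(csv)` is OR over
comma-separated codes. Matching is case-insensitive and
whitespace-trimmed. Spanish expansions are shipped in the registry but
disabled by default to avoid token collisions in mixed-language tag
sets; a flag enables them. Built-in tags inserted on assembly: the
shot's `ShotType`, `serve`, `lob`, `by-<lastname>`, and `winning` for
shots whose hitter's team won the point. No built-in zone tags exist —
zone definitions vary by analyst and belong in user rules.

## Query engine

Predicates and attributes come in two forms: host-language callables
(the fluent decorator API) and text expressions in a strict
whitelist-grammar (dotted paths, literals, arithmetic, comparisons,
and/or/not, parentheses, member method calls), which makes queries
writable from YAML and the CLI. Root names resolve in order: the item's
level name, the item's own properties, a match player by lowercase last
name (bound to the current frame context), registered helpers.

Membership is decided by the predicate alone: an attribute that
evaluates to `Absent` produces an explicit null in its cell, never a
dropped row. The default column alias is the expression text. Row order
follows item temporal order within scope order, so repeated runs over
the same bundle export byte-identical CSVs. Video deep links append
`t = floor(start_frame/fps)` seconds to the match URL.

A "winning shot" (catalog q7b) is operationalized as: the hitter's team
won the point and at most one shot follows — the rally's closing strike
or the stroke that forced the final error.

`plot_data` returns the exact table a renderer would consume (plus court
overlay geometry for positional kinds); the bundled matplotlib adapter
is deliberately thin and replaceable.

## Synthetic generator

The generator emulates the study conditions the schemas describe:
30 fps video, a 10 × 20 m court, golden-point scoring (the professional
tour rule), geometric rally lengths with mean 6 shots, lognormal
inter-shot intervals with mean 1.3 s (the observed scale of elite
women's padel; shape σ = 0.35), serves struck ~1.5 m from the back wall
with the partner ~2 m from the net, player speeds capped at 7 m/s, and a
0.8 probability that the serving team presses the net. Hitters alternate
teams; within a team the player nearer the simulated contact point
answers (real intra-team alternation is unconstrained — this is a
modeling convenience). Corner labels are assigned from positions at each
rally's first frame. Score columns are produced by the same automaton
ingest replays, making the round trip exact by construction.

What it does **not** emulate: the ball (absent from the schemas),
realistic biomechanics or shot-type statistics (the transition table is
a placeholder exposed in config, not a claim), annotation noise (frames
are exact up to 2-decimal rounding; `perturb` adds Gaussian tracking
error on demand), camera distortion (the image columns come from a fixed
synthetic projection). Passing tests therefore demonstrate correctness
of the query semantics and reconstruction logic, not fidelity to any
real match's statistics.

Positions are emitted rounded to 2 decimals; the movement step is capped
strictly below max_speed/fps so the cap survives rounding. `sigma = 0`
perturbation is the identity; σ ≈ 0.1 m stays within the 0.5 m court
tolerance (players may legitimately step through the net-side openings,
and tracking error is ~30 cm), σ ≈ 5 m is designed to trip the
validator.

## Problem sizes in the test suite

Unit tests run on matches truncated to 6–12 rallies; the query-oracle
sweep uses 50 seeded 8-rally matches, and the generator round trip 20
seeds at 6 rallies — enough rallies for every query shape to fire while
keeping the default suite under a minute. The interval-statistics check
generates ≥1000 shots. The whole suite is seeded/derandomized.

## Known limitations

- Frames between rallies are not modeled; frames before a rally's first
  annotated shot attach to the rally but to no shot.
- `Point.valid` is stored and exposed, never interpreted: the criteria
  distinguishing, e.g., net serves are annotation-side policy.
- Whether teams switch court halves between games is not assumed; the
  per-point corner→name columns are authoritative.
- Kinematics assume feet on the floor (2-D court space); jumps and 3-D
  motion are out of scope, as is ball speed.
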