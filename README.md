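# padelql

A domain-specific query language (embedded in Python) for exploratory
analysis of video-based player-tracking data from **padel** matches.

Semi-automatic annotation of a padel video yields three tables: one row
per *point* (rally), one per *shot*, and one per video *frame* with the
court-space positions of the four players. Asking even simple tactical
questions of these tables — "where was the server's partner standing?",
"which lobs were answered by a defensive stroke?", "find every
serve → return → volley pattern" — requires joins, lookups and index
offsets that sports analysts should not have to write. `padelql` turns
the tables into a navigable hierarchy

```
Match > Set > Game > Point > Shot > Frame
```

and lets analysts express such questions as one-line Boolean predicates.

## Core ideas

- **Fluent navigation.** Every play unit knows its parent, children and
  temporal siblings: `shot.point.winner`, `shot.next.hitter`,
  `frame.match.gender` (skip levels allowed). Navigating off the end
  (`shot.next` on a rally's last shot) yields an `Absent` sentinel that
  swallows further attribute access and compares false against
  everything, so `shot.next.next.next.hitter.distance_to_side_wall < 2.5`
  is simply `False` on a three-shot rally — never an exception.
- **Frame-bound players.** A `Player` bound to a `Frame` exposes
  kinematics computed from the positions table: `position`, `speed`,
  `acceleration`, `distance_to_net`, oriented wall distances (a player's
  *right* wall depends on which half they face the net from),
  `distance_from_prev_frame`, `partner`, `from_point_winning_team`.
- **Tags over a shot taxonomy.** Units carry a growing tag set tested
  with `like` (AND over whitespace tokens, whole-alias match first) and
  `one_of` (OR over a comma-separated code list). A 27-entry shot-type
  registry maps codes to multilingual aliases (`vd` ≡ "drive volley" ≡
  "forehand volley"), and analysts register their own concepts as
  predicates (`@shot_tag`).
- **Queries return tables with video provenance.** A query is a typed
  predicate executed over one or more matches; each output row links
  back to the video second where the item starts (`...?t=453`). Results
  support `analyze()`, `sum_by()`, `add_column()`, `concat()` and
  plot-table extraction (positions, directions, distributions,
  histograms, bar charts) over an overhead court view.
- **Scoring automaton.** Padel scores like tennis
  (0→15→30→40, advantage or golden-point at deuce; games to six, two
  clear, 6–6 decided by a single extra game). The automaton replays the
  points table's winner column to reconstruct games and sets, and the
  same code generates score columns in the synthetic module.
- **Synthetic matches.** A seeded generator emits the three schemas with
  known ground truth — serves from the back of the court, alternating
  teams, geometric rally lengths, lognormal shot intervals (~1.3 s),
  bounded player speeds — so the entire pipeline is testable offline.

## Worked example

```python
import padelql as pql
from padelql import ingest as ing

bundle = pql.generate_match(pql.SynthConfig(seed=1, max_points=8))
match = ing.assemble_match(
    ing.read_points(bundle.points.astype(str)),
    ing.read_shots(bundle.shots.astype(str)),
    ing.read_frames(bundle.frames.astype(str)),
    ing.IngestConfig(fps=30, title="synthetic demo",
                     video_url="https://video.example/demo"))

@pql.shot_query
def attack_volleys(shot):
    return shot.one_of("vd,vr") and shot.hitter.distance_to_net < 4

result = attack_volleys(match, ["hitter.last_name", "hitter.position.x",
                                "hitter.position.y",
                                ("hitter.distance_to_net", "dnet"),
                                "duration"])
print(result)                      # QueryResult 'attack_volleys'(7 rows x 5 cols)
print(result.analyze().round(3))
```

prints

```
                   count   mean    std   min    max  distinct
hitter.last_name     7.0    NaN    NaN   NaN    NaN       2.0
hitter.position.x    7.0  3.731  2.000  1.15   6.48       NaN
hitter.position.y    7.0  9.269  2.504  6.45  12.12       NaN
dnet                 7.0  2.480  0.809  1.20   3.55       NaN
duration             4.0  1.550  0.229  1.30   1.90       NaN
```

Seven volleys were struck within 4 m of the net; `dnet` is the hitter's
net distance in meters, `duration` the seconds until the next shot
(null for rally-ending shots — three of the seven here ended their
rally). `result.links[0]` is
`https://video.example/demo?t=37`: playback of the match video from the
second where the first selected volley occurs.

The built-in catalog (`padelql.builtin_catalog()`) ships ten standard
queries — volleys and directions, fast down-the-line volleys, shot
durations, serves, server-partner positioning, frames after the serve,
net-zone occupancy of the point winners, winning shots, lob
effectiveness, serve-return-volley patterns — each with default
attribute lists.

## Command line

```bash
padelql synth --seed 9 --out bundles/demo          # generate a bundle
padelql validate bundles/demo                      # structural checks
padelql query --match bundles/demo --name q1 --out volleys.csv
padelql tags --rules rules.yaml bundles/demo       # YAML tag rules
```

A bundle directory holds `manifest.json` plus the three canonical CSVs
(and, for generated bundles, roster and ground truth).

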