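"""Brute-force flat-table oracle for query results.

Works directly on the three raw DataFrames of a bundle with plain pandas
and trigonometry — no play-unit objects, no navigation, no tag system —
so it is an independent route to the same row sets the query engine
produces.  Items are identified by start frame (shots, points) or frame
number (frames), which are unique within a match.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

DEFENSIVE = set("d r ad ar pld plr spd spr bpd bpr dpa dpc dpag cp cpld cplr"
                .split())
CORNER_COLS = {"TL": "Top Left", "TR": "Top Right",
               "BL": "Bottom Left", "BR": "Bottom Right"}
WIDTH, LENGTH, NET_Y = 10.0, 20.0, 10.0


def shot_features(bundle, fps: int = 30) -> pd.DataFrame:
    pts = bundle.points
    starts = pts["Start (f)"].astype(int).to_numpy()
    ends = pts["End (f)"].astype(int).to_numpy()
    winners = pts["Winner"].astype(str).to_numpy()
    fr = bundle.frames.copy()
    fr.index = fr["Frame"].astype(int)

    rows = []
    for _, srow in bundle.shots.iterrows():
        f = int(srow["Frame"])
        corner = str(srow["Player"]).strip().upper()
        j = int(np.where((starts <= f) & (f < ends))[0][0])
        frow = fr.loc[f]
        x, y = float(frow[f"{corner} x"]), float(frow[f"{corner} y"])
        code = str(srow["Shot Type"]).strip().lower()
        if code == "serve":
            code = "s"
        rows.append({
            "frame": f, "point": j, "corner": corner, "code": code,
            "lob": str(srow["Lob"]).strip().upper() in ("T", "TRUE", "1"),
            "name": str(pts.iloc[j][CORNER_COLS[corner]]),
            "x": x, "y": y,
            "d_net": abs(y - NET_Y),
            "d_side": min(x, WIDTH - x),
            "d_back": y if y < NET_Y else LENGTH - y,
            "team": "T" if corner in ("TL", "TR") else "B",
            "winner": winners[j],
        })
    df = pd.DataFrame(rows).sort_values(["point", "frame"]).reset_index(drop=True)
    if df.empty:
        return df
    df["order"] = df.groupby("point").cumcount()
    df["n_in_point"] = df.groupby("point")["frame"].transform("size")
    for col in ("frame", "code", "name", "x", "y", "d_side", "d_net"):
        shifted = df.groupby("point")[col].shift(-1)
        df[f"next_{col}"] = shifted
    for col in ("code", "name", "d_side"):
        df[f"next2_{col}"] = df.groupby("point")[col].shift(-2)
        df[f"next3_{col}"] = df.groupby("point")[col].shift(-3)
    df["has_next"] = df["next_frame"].notna()
    df["duration"] = (df["next_frame"] - df["frame"]) / fps

    # signed direction angle: forward axis points away from the hitter
    faces_up = df["y"] < NET_Y
    dx = df["next_x"] - df["x"]
    dy = df["next_y"] - df["y"]
    fwd = np.where(faces_up, dy, -dy)
    rgt = np.where(faces_up, dx, -dx)
    df["angle"] = np.degrees(np.arctan2(rgt, fwd))
    return df


def frame_features(bundle, fps: int = 30) -> pd.DataFrame:
    pts = bundle.points
    starts = pts["Start (f)"].astype(int).to_numpy()
    ends = pts["End (f)"].astype(int).to_numpy()
    winners = pts["Winner"].astype(str).to_numpy()
    fr = bundle.frames.copy()
    f = fr["Frame"].astype(int).to_numpy()
    idx = np.full(len(f), -1)
    for j, (s, e) in enumerate(zip(starts, ends)):
        idx[(f >= s) & (f < e)] = j
    keep = idx >= 0
    out = pd.DataFrame({"frame": f[keep], "point": idx[keep]})
    out["start"] = starts[out["point"]]
    out["winner"] = winners[out["point"]]
    # difference of the two timestamps, matching the query's definition
    # (boundary ties at exactly 1 s follow float evaluation order)
    out["within_1s"] = (out["frame"] / fps - out["start"] / fps) < 1
    near = {}
    for c in CORNER_COLS:
        y = fr[f"{c} y"].astype(float).to_numpy()[keep]
        near[c] = np.abs(y - NET_Y) < 4
    out["winner_pair_on_net"] = np.where(
        out["winner"] == "T", near["TL"] & near["TR"], near["BL"] & near["BR"])
    return out


def expected_keys(bundle, query: str, fps: int = 30) -> set[int]:
    """The start-frame / frame-number key set a query should select."""
    if query in ("q6", "q7a", "q8"):
        ff = frame_features(bundle, fps)
        if query == "q6":
            sel = ff[ff["within_1s"]]
        elif query == "q7a":
            sel = ff[ff["winner_pair_on_net"]]
        else:
            sel = ff
        return set(sel["frame"].astype(int))
    if query == "p_bottom_wins":
        pts = bundle.points
        return set(pts.loc[pts["Winner"].astype(str) == "B",
                           "Start (f)"].astype(int))
    sf = shot_features(bundle, fps)
    if sf.empty:
        return set()
    if query == "q1":
        sel = sf[sf["code"].isin(["vd", "vr"])]
    elif query == "q2":
        sel = sf[sf["code"].isin(["vd", "vr"]) & (sf["duration"] < 1)
                 & (sf["angle"].abs() < 8)]
    elif query == "q3":
        sel = sf[sf["has_next"]]
    elif query in ("q4", "q5"):
        sel = sf[(sf["code"] == "s") & sf["has_next"]]
    elif query == "q7b":
        sel = sf[(sf["team"] == sf["winner"])
                 & (sf["order"] >= sf["n_in_point"] - 2)]
    elif query == "q9":
        sel = sf[sf["lob"] & sf["next_code"].isin(DEFENSIVE)]
    elif query == "q10":
        sel = sf[(sf["code"] == "s")
                 & (sf["next_d_side"] > 2.5)
                 & sf["next2_code"].isin(["vd", "vr"])
                 & (sf["next3_d_side"] < 2.5)
                 & (sf["next_name"] == sf["next3_name"])]
    elif query == "p_salazar_back":
        sel = sf[sf["name"].str.lower().str.endswith("salazar")
                 & (sf["d_back"] < 3)]
    else:
        raise KeyError(query)
    return set(sel["frame"].astype(int))
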