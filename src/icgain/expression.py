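"""Marker co-expression tabulation for RNAscope-style cell tables.

Input is a per-cell table (cell id, mouse, slice, IC subdivision, tdTomato
positivity, and puncta counts for the Glun2c and Glun2d channels).  A cell
counts as positive for a channel when at least one punctum co-localizes
with its tdTomato signal.  Summaries report, per grouping, the counts and
percentages of tdTomato+ cells expressing Glun2d, Glun2c, both, exactly
one, or neither; percentages use the tdTomato+ count of the group as
denominator and are rounded half-away-from-zero to one decimal.

``VIP_RNASCOPE_COUNTS`` ships the published per-mouse/slice marginal counts
for tdTomato+ (VIP) neurons of the mouse inferior colliculus, and
``VIP_RNASCOPE_SUBDIVISION_COUNTS`` the same broken down by IC subdivision;
:func:`fixture_from_counts` expands such marginals into a minimal per-cell
table for analysis.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "SUBDIVISIONS",
    "COLUMNS",
    "VIP_RNASCOPE_COUNTS",
    "VIP_RNASCOPE_SUBDIVISION_COUNTS",
    "classify_cell",
    "summarize",
    "fixture_from_counts",
    "load_table",
    "marker_table",
]

SUBDIVISIONS = ("central nucleus", "dorsal cortex", "lateral cortex",
                "unassigned")
COLUMNS = ("cell_id", "mouse_id", "slice_id", "subdivision",
           "tdTomato_positive", "glun2c_puncta", "glun2d_puncta")
CLASSES = ("only2d", "only2c", "both", "neither")

# Published RNAscope marginal counts for tdTomato+ (VIP) neurons:
# (mouse, slice) -> (n tdT+, n Glun2d+, n Glun2c+, n double-positive)
VIP_RNASCOPE_COUNTS = {
    ("mouse1", "A caudal"): (42, 36, 3, 3),
    ("mouse1", "B caudal"): (52, 49, 4, 4),
    ("mouse1", "C caudal"): (48, 47, 2, 2),
    ("mouse1", "D rostral"): (3, 3, 0, 0),
    ("mouse1", "E rostral"): (4, 4, 0, 0),
    ("mouse2", "D caudal"): (71, 68, 9, 9),
    ("mouse2", "B medial"): (13, 10, 2, 1),
    ("mouse2", "C medial"): (26, 26, 4, 4),
    ("mouse2", "A rostral"): (3, 3, 0, 0),
    ("mouse3", "B caudal"): (94, 83, 10, 7),
    ("mouse3", "D caudal"): (85, 76, 5, 5),
    ("mouse3", "A medial"): (70, 62, 2, 1),
    ("mouse3", "C rostral"): (10, 9, 1, 1),
}

# subdivision -> mouse -> (n tdT+, n Glun2d+, n Glun2c+, n double-positive)
VIP_RNASCOPE_SUBDIVISION_COUNTS = {
    "central nucleus": {"mouse1": (89, 84, 5, 5),
                        "mouse2": (68, 67, 12, 12),
                        "mouse3": (199, 175, 14, 11)},
    "dorsal cortex": {"mouse1": (47, 42, 4, 4),
                      "mouse2": (28, 25, 1, 1),
                      "mouse3": (38, 36, 2, 2)},
    "lateral cortex": {"mouse1": (13, 13, 0, 0),
                       "mouse2": (17, 15, 2, 1),
                       "mouse3": (22, 19, 2, 1)},
}


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return math.copysign(math.floor(abs(x) * 10.0 + 0.5) / 10.0, x)


def marker_table(rows) -> pd.DataFrame:
    """Validate and normalize a per-cell marker table."""
    df = pd.DataFrame(rows, columns=list(COLUMNS))
    if df["cell_id"].duplicated().any():
        raise ValueError("cell_id values must be unique")
    for col in ("glun2c_puncta", "glun2d_puncta"):
        counts = df[col]
        if (counts < 0).any() or not np.allclose(counts, counts.astype(int)):
            raise ValueError(f"{col} must hold non-negative integers")
        df[col] = counts.astype(int)
    bad = ~df["subdivision"].isin(SUBDIVISIONS)
    if bad.any():
        raise ValueError(f"unknown subdivision(s): "
                         f"{sorted(df.loc[bad, 'subdivision'].unique())}")
    df["tdTomato_positive"] = df["tdTomato_positive"].astype(bool)
    return df


def load_table(path, sep="\t") -> pd.DataFrame:
    return marker_table(pd.read_csv(path, sep=sep))


def classify_cell(row) -> str:
    """Co-expression class of a tdTomato+ cell (positivity = ≥1 punctum)."""
    if not row["tdTomato_positive"]:
        raise ValueError("only tdTomato+ cells are classified")
    c2c = int(row["glun2c_puncta"])
    c2d = int(row["glun2d_puncta"])
    if c2c < 0 or c2d < 0:
        raise ValueError("puncta counts must be non-negative")
    pos2c, pos2d = c2c >= 1, c2d >= 1
    if pos2c and pos2d:
        return "both"
    if pos2d:
        return "only2d"
    if pos2c:
        return "only2c"
    return "neither"


def _summarize_group(df: pd.DataFrame) -> dict:
    tdt = df[df["tdTomato_positive"]]
    n_tdt = len(tdt)
    counts = {
        "n_tdt": n_tdt,
        "n_2d": int((tdt["glun2d_puncta"] >= 1).sum()),
        "n_2c": int((tdt["glun2c_puncta"] >= 1).sum()),
        "n_both": int(((tdt["glun2d_puncta"] >= 1)
                       & (tdt["glun2c_puncta"] >= 1)).sum()),
    }
    counts["n_only2d"] = counts["n_2d"] - counts["n_both"]
    counts["n_only2c"] = counts["n_2c"] - counts["n_both"]
    counts["n_neither"] = (n_tdt - counts["n_only2d"] - counts["n_only2c"]
                           - counts["n_both"])
    defined = n_tdt > 0
    counts["percent_defined"] = defined
    for key in ("2d", "2c", "both", "only2d", "only2c", "neither"):
        counts[f"pct_{key}"] = (_round1(100.0 * counts[f"n_{key}"] / n_tdt)
                                if defined else np.nan)
    return counts


def summarize(table: pd.DataFrame, group_by: str = "overall") -> pd.DataFrame:
    """Expression summary per group: counts and percentages of tdT+ cells.

    ``group_by`` ∈ {"overall", "mouse", "subdivision"}.  Percentages are
    relative to the group's tdTomato+ count; groups with no tdT+ cells get
    NaN percentages and ``percent_defined = False``.  The partition
    only2d + only2c + both + neither = tdT+ holds exactly per group.
    """
    df = marker_table(table)
    if group_by == "overall":
        groups = [("overall", df)]
    elif group_by == "mouse":
        groups = list(df.groupby("mouse_id", sort=True))
    elif group_by == "subdivision":
        groups = list(df.groupby("subdivision", sort=True))
    else:
        raise ValueError("group_by must be 'overall', 'mouse' or "
                         "'subdivision'")
    rows = []
    for name, sub in groups:
        row = {"group": name}
        row.update(_summarize_group(sub))
        rows.append(row)
    return pd.DataFrame(rows)


def fixture_from_counts(n_tdt: int, n_2d: int, n_2c: int, n_both: int,
                        mouse_id: str = "mouse", slice_id: str = "slice",
                        subdivision: str = "unassigned",
                        start_id: int = 0) -> pd.DataFrame:
    """Minimal per-cell table consistent with marginal counts.

    Emits ``n_both`` double-positive cells, ``n_2d − n_both`` 2d-only,
    ``n_2c − n_both`` 2c-only, and the remainder negative for both, each
    with the smallest puncta count realizing its class.  ``summarize`` of
    the result reproduces the input marginals exactly.
    """
    n_only2d = n_2d - n_both
    n_only2c = n_2c - n_both
    n_neither = n_tdt - n_only2d - n_only2c - n_both
    if min(n_tdt, n_2d, n_2c, n_both, n_only2d, n_only2c, n_neither) < 0:
        raise ValueError(
            f"inconsistent marginals: tdT+={n_tdt}, 2d+={n_2d}, "
            f"2c+={n_2c}, both={n_both}")
    spec = [("both", 1, 1)] * n_both + [("only2d", 0, 1)] * n_only2d + \
           [("only2c", 1, 0)] * n_only2c + [("neither", 0, 0)] * n_neither
    rows = [(f"{mouse_id}_{slice_id}_c{start_id + i}", mouse_id, slice_id,
             subdivision, True, c2c, c2d)
            for i, (_cls, c2c, c2d) in enumerate(spec)]
    return marker_table(pd.DataFrame(rows, columns=list(COLUMNS)))


def published_vip_table() -> pd.DataFrame:
    """Per-cell table expanded from the published subdivision marginals.

    Reconstructs one cell row per counted tdTomato+ neuron from
    ``VIP_RNASCOPE_SUBDIVISION_COUNTS`` (which partitions the same 521
    cells as the per-slice table); the grand totals and every per-mouse and
    per-subdivision marginal are preserved exactly.
    """
    frames = []
    start = 0
    for subdiv, per_mouse in VIP_RNASCOPE_SUBDIVISION_COUNTS.items():
        for mouse, (n_tdt, n_2d, n_2c, n_both) in per_mouse.items():
            frames.append(fixture_from_counts(
                n_tdt, n_2d, n_2c, n_both, mouse_id=mouse,
                slice_id=subdiv.replace(" ", "_"), subdivision=subdiv,
                start_id=start))
            start += n_tdt
    return pd.concat(frames, ignore_index=True)
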