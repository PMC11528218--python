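"""Ionocyte classification and counting conventions.

A neuromast ionocyte *unit* is a pair of cells (or a solitary cell) that
develops together; pairs and singletons both count as one unit.  Cells
are classified from their HCR marker states:

* progenitor — foxi3a+ (or foxi3b+), trpv6-, immediately adjacent to the
  neuromast, crescent morphology;
* mature — foxi3a+ (or foxi3b+) and trpv6+, located inside the neuromast
  or fixed while invading it;
* other — anything else.

Counts are summarized per larva over its quantified neuromast panel (the
five anterior and five posterior lateral-line neuromasts), so per-larva
averages can fall below 1 when some neuromasts are empty.  For
experiments whose replicates scatter widely, values are normalized by
the mean of the embryo-medium control within each replicate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellRecord",
    "classify_cell",
    "group_progenitor_units",
    "count_units",
    "per_larva_average",
    "frequency",
    "normalize_to_control",
    "NEUROMAST_PANEL",
]

#: quantified neuromast panel: anterior (Ml1, O2, Ml2, IO4, O1) and
#: posterior (L1-L3, LII.1, LII.2) lateral line
NEUROMAST_PANEL = ("Ml1", "O2", "Ml2", "IO4", "O1",
                   "L1", "L2", "L3", "LII.1", "LII.2")

Marker = Literal["+", "-"]


@dataclass
class CellRecord:
    """One annotated cell near or in a neuromast."""

    larva_id: str
    neuromast_id: str
    foxi3a: Marker
    foxi3b: Marker = "-"
    trpv6: Marker = "-"
    location: Literal["inside", "adjacent", "invading"] = "adjacent"
    morphology: Literal["crescent", "round", "other"] = "other"
    position_um: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        for m in (self.foxi3a, self.foxi3b, self.trpv6):
            if m not in ("+", "-"):
                raise ValueError(f"marker state must be '+' or '-', got {m!r}")
        if self.location not in ("inside", "adjacent", "invading"):
            raise ValueError(f"invalid location {self.location!r}")


def classify_cell(record: CellRecord) -> str:
    """Classify a cell as progenitor, mature, or other."""
    foxi = record.foxi3a == "+" or record.foxi3b == "+"
    if (record.foxi3a == "+" and record.trpv6 == "-"
            and record.location == "adjacent"
            and record.morphology == "crescent"):
        return "progenitor"
    if foxi and record.trpv6 == "+" and record.location in ("inside", "invading"):
        return "mature"
    return "other"


def _greedy_pairs(positions: np.ndarray, pair_distance: float) -> int:
    """Greedy nearest-neighbor pairing; returns the number of pairs."""
    n = len(positions)
    unpaired = set(range(n))
    dists = [(float(np.linalg.norm(positions[i] - positions[j])), i, j)
             for i in range(n) for j in range(i + 1, n)]
    dists.sort()
    pairs = 0
    for d, i, j in dists:
        if d > pair_distance:
            break
        if i in unpaired and j in unpaired:
            unpaired.discard(i)
            unpaired.discard(j)
            pairs += 1
    return pairs


def max_pairs_bruteforce(positions: np.ndarray, pair_distance: float) -> int:
    """Exhaustive maximum matching under the distance cap (small n only)."""
    n = len(positions)
    if n > 8:
        raise ValueError("brute force limited to n <= 8")
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if np.linalg.norm(positions[i] - positions[j]) <= pair_distance]
    best = 0
    for k in range(len(edges), 0, -1):
        for combo in itertools.combinations(edges, k):
            used = [v for e in combo for v in e]
            if len(used) == len(set(used)):
                best = k
                break
        if best:
            break
    return best


def group_progenitor_units(progenitors: Sequence[CellRecord],
                           pair_distance: float = 10.0,
                           pairing: bool = True) -> int:
    """Count progenitor units in one neuromast.

    Cells within ``pair_distance`` (µm; default one cell diameter) are
    paired greedily nearest-first; each pair counts as one unit and each
    leftover singleton as one unit.  With pairing disabled every cell is
    its own unit.
    """
    cells = list(progenitors)
    if not cells:
        return 0
    if not pairing or len(cells) == 1:
        return len(cells)
    if any(c.position_um is None for c in cells):
        raise ValueError("cell positions required to pair >1 progenitors; "
                         "pass pairing=False to count cells individually")
    positions = np.array([c.position_um for c in cells], dtype=float)
    pairs = _greedy_pairs(positions, pair_distance)
    return len(cells) - pairs


def count_units(records: Sequence[CellRecord],
                pair_distance: float = 10.0,
                condition: str = "", replicate: int = 0) -> pd.DataFrame:
    """Build a long-format count table from annotated cells.

    Mature cells are paired into units the same way as progenitors (a
    mature unit is the invaded pair); rows cover every (larva, neuromast)
    that has at least one record.
    """
    rows = []
    key = lambda r: (r.larva_id, r.neuromast_id)
    for (larva, nm), group in itertools.groupby(sorted(records, key=key), key=key):
        group = list(group)
        prog = [r for r in group if classify_cell(r) == "progenitor"]
        mat = [r for r in group if classify_cell(r) == "mature"]
        rows.append((condition, replicate, larva, nm,
                     group_progenitor_units(mat, pair_distance),
                     group_progenitor_units(prog, pair_distance)))
    return pd.DataFrame(rows, columns=["condition", "replicate", "larva_id",
                                       "neuromast_id", "mature_units",
                                       "progenitor_units"])


def _unit_column(kind: str) -> str:
    if kind not in ("mature", "progenitor"):
        raise ValueError("kind must be 'mature' or 'progenitor'")
    return f"{kind}_units"


def per_larva_average(table: pd.DataFrame, kind: str = "mature") -> pd.DataFrame:
    """Mean unit count per larva over its quantified neuromasts.

    Returns one row per (condition, replicate, larva) with column
    ``value``; values below 1 mean not every neuromast held a unit.
    """
    col = _unit_column(kind)
    out = (table.groupby(["condition", "replicate", "larva_id"], sort=False)[col]
           .mean().reset_index().rename(columns={col: "value"}))
    return out


def frequency(table: pd.DataFrame, kind: str = "mature") -> float:
    """Percentage of neuromasts containing at least one unit."""
    col = _unit_column(kind)
    if len(table) == 0:
        raise ValueError("empty count table")
    return float((table[col] > 0).mean() * 100.0)


def normalize_to_control(values: pd.DataFrame, control_condition: str,
                         by_replicate: bool = True) -> pd.DataFrame:
    """Divide each larva's value by its replicate's control-group mean.

    ``values`` is the output of :func:`per_larva_average`.  After
    normalization the control group's mean is exactly 1 in every
    replicate.
    """
    values = values.copy()
    if by_replicate:
        groups = values.groupby("replicate", sort=False)
    else:
        groups = [(None, values)]
    for rep, sub in groups:
        ctrl = sub.loc[sub["condition"] == control_condition, "value"]
        if len(ctrl) == 0:
            raise ValueError(f"no control larvae ({control_condition!r}) in "
                             f"replicate {rep!r}")
        m = ctrl.mean()
        if m == 0:
            raise ValueError(f"control mean is zero in replicate {rep!r}")
        values.loc[sub.index, "value"] = sub["value"] / m
    return values
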