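"""Deterministic reconstruction of a published DLBCL baseline table.

The cohort's per-variable marginals against R/R status are public as a
baseline-characteristics table (227 patients; 118 R/R, 109 non-relapsed &
non-refractory). Only the marginals are published, so each variable is
filled independently within each label group; the joint distribution is
arbitrary but fixed, and every per-variable cross-tabulation against the
label reproduces the printed counts cell-for-cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["TABLE1_COUNTS", "reconstruct_table1_fixture", "crosstab_counts"]

N_RR = 118
N_NON = 109

# variable -> list of (level, count in R/R group, count in non-R/R group).
# Groups smaller than the cohort (unprinted missing cells) are padded with
# an "Unknown" level so every column has 227 entries.
TABLE1_COUNTS: dict[str, list[tuple[str, int, int]]] = {
    "gender": [("Male", 68, 54), ("Female", 50, 55)],
    "age_group": [("<60", 49, 58), (">=60", 69, 51)],
    "tumor_stage": [("I", 28, 38), ("II", 31, 39), ("III", 31, 19), ("IV", 28, 13)],
    "rituximab": [("Yes", 44, 59), ("No", 74, 46), ("Unknown", 0, 4)],
    "response": [
        ("CR", 2, 58),
        ("PR", 20, 20),
        ("SD", 7, 16),
        ("PD", 86, 14),
        ("Unknown", 3, 1),
    ],
    "extranodal_sites": [("0", 19, 26), (">=1", 99, 83)],
    "ipi_score": [("0-2", 72, 77), ("3-5", 35, 19), ("Unknown", 11, 13)],
    "cell_of_origin": [("GCB", 67, 65), ("Non-GCB", 50, 43), ("Unknown", 1, 1)],
    "double_expression": [("Yes", 40, 19), ("No", 78, 90)],
    "double_hit": [("Yes", 1, 1), ("No", 105, 101)],
}


def _fill_column(levels: list[tuple[str, int, int]]) -> np.ndarray:
    """Sequential deterministic fill: R/R rows first, then non-R/R rows."""
    col = []
    for group_idx, group_n in ((1, N_RR), (2, N_NON)):
        vals: list[str] = []
        for level, n_rr, n_non in levels:
            vals.extend([level] * (n_rr if group_idx == 1 else n_non))
        if len(vals) > group_n:
            raise ValueError("level counts exceed group size")
        vals.extend(["Unknown"] * (group_n - len(vals)))
        col.extend(vals)
    return np.asarray(col, dtype=object)


def reconstruct_table1_fixture() -> pd.DataFrame:
    """227-row clinical table whose per-variable cross-tabulations against
    the R/R label equal the published baseline counts exactly."""
    data = {"label": np.array([1] * N_RR + [0] * N_NON)}
    for name, levels in TABLE1_COUNTS.items():
        data[name] = _fill_column(levels)
    df = pd.DataFrame(data)
    df.index = [f"T{i:04d}" for i in range(len(df))]
    return df


def crosstab_counts(
    table: pd.DataFrame, variable: str, drop_unknown: bool = True
) -> np.ndarray:
    """levels x label count matrix (columns ordered label=1 then label=0),
    with rows in the published level order."""
    levels = [lv for lv, _, _ in TABLE1_COUNTS[variable]]
    if drop_unknown:
        levels = [lv for lv in levels if lv != "Unknown"]
    out = np.zeros((len(levels), 2), dtype=int)
    for i, lv in enumerate(levels):
        sel = table[variable] == lv
        out[i, 0] = int((sel & (table["label"] == 1)).sum())
        out[i, 1] = int((sel & (table["label"] == 0)).sum())
    return out
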