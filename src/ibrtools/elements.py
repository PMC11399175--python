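"""Leachate element-concentration tables and their summary.

A packaged fixture carries the detected-element table of the reference
e-waste (waste printed circuit board) leaching cycle — mean and SD in
µg/L per element — together with the full panel of elements assayed by
ICP-MS, of which only a subset fell within detectable range.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = ["ElementTable", "load_leachate_fixture", "summarize_leachate", "LeachateSummary"]


class ElementInputError(ValueError):
    """Malformed element table (duplicate symbols, negative concentrations)."""


@dataclass
class LeachateSummary:
    detected_count: int
    ranking: pd.DataFrame  # descending by mean concentration
    order_string: str  # "Ni > Ba > Li > ..." for the top-k elements


def load_leachate_fixture() -> tuple[pd.DataFrame, list[str]]:
    """Return (detected-element table, full tested-element panel)."""
    pkg = resources.files("ibrtools.data")
    with resources.as_file(pkg / "leachate_elements.csv") as p:
        table = pd.read_csv(p)
    tested = (pkg / "tested_elements.txt").read_text().split()
    return table, tested


def summarize_leachate(
    table: pd.DataFrame,
    tested_elements: list[str] | None = None,
    top: int = 7,
) -> LeachateSummary:
    """Count detected elements and rank them by mean concentration.

    Rows of ``table`` are the detected elements (columns ``element``,
    ``mean_ug_per_L``, ``sd_ug_per_L``).  Ties in concentration are broken
    alphabetically.  ``tested_elements``, when given, must cover every
    detected element.
    """
    if table.empty:
        return LeachateSummary(0, table.copy(), "")
    if table["element"].duplicated().any():
        dups = sorted(table.loc[table["element"].duplicated(), "element"])
        raise ElementInputError(f"duplicate element symbol(s): {dups}")
    if (table["mean_ug_per_L"] < 0).any() or (table["sd_ug_per_L"] < 0).any():
        raise ElementInputError("concentrations and SDs must be >= 0")
    if tested_elements is not None:
        missing = sorted(set(table["element"]) - set(tested_elements))
        if missing:
            raise ElementInputError(
                f"detected element(s) absent from the tested panel: {missing}"
            )
    ranking = table.sort_values(
        ["mean_ug_per_L", "element"], ascending=[False, True]
    ).reset_index(drop=True)
    order = " > ".join(ranking["element"].head(top))
    return LeachateSummary(len(table), ranking, order)
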