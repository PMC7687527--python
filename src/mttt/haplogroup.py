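"""mtDNA haplogroup assignment and frequency tables.

A full-mitogenome variant profile is assigned to the tree node whose
root->node defining-variant path it best supports.  Each node is scored
``matched - missing`` over its path variants; the best node maximizes
the score, with ties broken by fewer missing variants, then greater
depth, then name.  The fewer-missing tie-break means a lineage that
carries a clade's shallow motif but lacks part of a deeper branch motif
is called at the shallower (fully supported) node.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .reference_model import HaplogroupTree
from .variants import MtVariant

MACRO_ORDER = ["D", "G", "M7", "M8", "A", "B", "N", "H2", "F"]


@dataclass
class HaplogroupCall:
    subject_id: str
    best_node: str
    matched: int
    missing: int

    @property
    def score(self) -> int:
        return self.matched - self.missing


def assign_haplogroup(
    profile: list[MtVariant], tree: HaplogroupTree, subject_id: str = "subject"
) -> HaplogroupCall:
    """Deepest consistent node for a variant profile; root for an empty one."""
    carried = {v.label for v in profile}
    best: tuple[int, int, int, str] | None = None
    best_call: HaplogroupCall | None = None
    for name in tree.nodes:
        path = tree.path_variants(name)
        matched = sum(1 for v in path if v.label in carried)
        missing = len(path) - matched
        # sort key: score desc, missing asc, depth desc, name asc
        key = (-(matched - missing), missing, -tree.depth(name), name)
        if best is None or key < best:
            best = key
            best_call = HaplogroupCall(subject_id, name, matched, missing)
    assert best_call is not None
    return best_call


def frequency_table(
    calls_by_subgroup: dict[str, list[HaplogroupCall]],
    tree: HaplogroupTree,
    macro_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-subgroup macro-haplogroup percentages (one decimal, half-up).

    Empty subgroups are dropped with a warning column-free row omitted;
    unlisted macro-haplogroups accumulate under "other".
    """
    macro_order = macro_order or MACRO_ORDER
    rows = []
    index = []
    for subgroup, calls in calls_by_subgroup.items():
        if not calls:
            import warnings

            warnings.warn(f"empty subgroup {subgroup!r} omitted from frequency table")
            continue
        n = len(calls)
        counts: dict[str, int] = {}
        for call in calls:
            macro = tree.macro(call.best_node)
            counts[macro] = counts.get(macro, 0) + 1
        row = {}
        for macro in macro_order + ["other"]:
            pct = Decimal(100) * Decimal(counts.get(macro, 0)) / Decimal(n)
            row[macro] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        row["n"] = n
        rows.append(row)
        index.append(subgroup)
    return pd.DataFrame(rows, index=index, columns=macro_order + ["other", "n"])


def calls_to_frame(calls: list[HaplogroupCall], tree: HaplogroupTree) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": c.subject_id,
                "haplogroup": c.best_node,
                "macro": tree.macro(c.best_node),
                "matched": c.matched,
                "missing": c.missing,
                "score": c.score,
            }
            for c in calls
        ],
        columns=["subject_id", "haplogroup", "macro", "matched", "missing", "score"],
    )
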