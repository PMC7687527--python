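"""Conservation index (CI) from a multi-species alignment.

The CI of a site is the percentage of species in a fixed vertebrate
alignment whose base matches the human base, the human row included.
Values are rendered to two decimals with half-up rounding, matching the
published tables (e.g. 10/44 -> 22.73, 31/44 -> 70.45).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .reference_model import TrnaGeneModel

GAP_CHARS = frozenset("-.")


class AlignmentError(ValueError):
    """Ragged alignment or position outside the gene."""


def round_half_up(value_numerator: int, value_denominator: int, places: int = 2) -> float:
    """``100 * num / den`` rounded half-up to ``places`` decimals."""
    q = Decimal(1).scaleb(-places)
    frac = Decimal(100) * Decimal(value_numerator) / Decimal(value_denominator)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def _column_index(model: TrnaGeneModel, trnadb_pos: int) -> int:
    positions = model.trnadb_positions
    try:
        return positions.index(trnadb_pos)
    except ValueError:
        raise AlignmentError(f"tRNAdb position {trnadb_pos} outside {model.gene_name}")


def conservation_index(
    alignment: list[tuple[str, str]],
    model: TrnaGeneModel,
    trnadb_pos: int,
    gap_mode: str = "mismatch",
) -> float:
    """CI of one tRNAdb position; the first row is the human sequence.

    ``gap_mode`` "mismatch" counts gapped rows as non-matching species;
    "exclude" drops them from the denominator.
    """
    if not alignment:
        raise AlignmentError("empty alignment")
    width = len(alignment[0][1])
    for name, seq in alignment:
        if len(seq) != width:
            raise AlignmentError(f"ragged alignment: row {name!r} has length {len(seq)}")
    col = _column_index(model, trnadb_pos)
    human = alignment[0][1][col].upper()
    n_total = 0
    n_match = 0
    for _, seq in alignment:
        base = seq[col].upper()
        if base in GAP_CHARS:
            if gap_mode == "exclude":
                continue
            n_total += 1
            continue
        n_total += 1
        if base == human:
            n_match += 1
    return round_half_up(n_match, n_total)


def ci_threshold_flag(ci_percent: float, threshold: float = 70.0) -> bool:
    """Inclusive conservation cut: True iff CI >= threshold."""
    return ci_percent >= threshold


def conservation_table(
    alignment: list[tuple[str, str]], model: TrnaGeneModel, gap_mode: str = "mismatch"
) -> pd.DataFrame:
    """Per-position CI table over the whole gene."""
    rows = [
        {
            "trnadb_pos": pos,
            "coordinate": model.coordinate_map[pos],
            "element": model.element_map[pos],
            "ci_percent": conservation_index(alignment, model, pos, gap_mode),
        }
        for pos in model.trnadb_positions
    ]
    return pd.DataFrame(rows)
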