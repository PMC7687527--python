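"""Structural annotation and rule-based pathogenicity classification.

Each called variant is annotated with its tRNAdb position, structural
element and Watson-Crick pairing consequence, then sorted into one of
three bins:

* ``known`` - an established LHON-associated MT-TT mutation (catalog);
* ``putative`` - conserved (CI >= threshold) or structure-removing
  (deletion), and essentially absent from controls;
* ``polymorphism`` - everything else.

The default rule set (CI >= 70 OR deletion, control carrier frequency
<= 1%) reproduces the published three-way grouping of the 15 observed
variants.  A stricter preset requiring strict absence from controls and
CI strictly above 70 is available as ``RuleConfig.strict_absence()``;
it mirrors the narrative phrasing of the original evaluation but does
not reproduce the published table, which lists control carriers for
five putative variants and a CI of 22.73 for the deletion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .conservation import round_half_up
from .reference_model import GeneModelError, KnownMutationCatalog, TrnaGeneModel, pairing_partner
from .variants import DELETION, MtVariant

WC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")})

KNOWN = "known"
PUTATIVE = "putative"
POLYMORPHISM = "polymorphism"


def annotate_structure(
    variant: MtVariant, model: TrnaGeneModel
) -> tuple[int, str, int | None, bool]:
    """(tRNAdb position, element, WC partner, WC pair disrupted).

    A substitution disrupts its stem pair when the new base no longer
    forms A-U or G-C with the partner's reference base; a deletion at a
    paired position always disrupts.
    """
    if variant.position not in model.position_map:
        raise GeneModelError(f"{variant.label} outside {model.gene_name}")
    trnadb_pos = model.position_map[variant.position]
    element = model.element_map[trnadb_pos]
    partner = pairing_partner(model, trnadb_pos)
    if partner is None:
        return trnadb_pos, element, None, False
    if variant.vtype == DELETION:
        return trnadb_pos, element, partner, True
    partner_base = model.base_at_trnadb(partner)
    disrupted = (variant.alt, partner_base) not in WC_PAIRS
    return trnadb_pos, element, partner, disrupted


@dataclass
class VariantAnnotation:
    """One row of the evaluation table: structure, conservation, counts."""

    variant: MtVariant
    trnadb_pos: int
    element: str
    wc_partner: int | None
    wc_disrupted: bool
    ci_percent: float
    case_count: int
    control_count: int
    case_total: int
    control_total: int
    partner_base: str = ""  # reference base at the WC partner, if any

    @property
    def case_freq(self) -> float:
        return round_half_up(self.case_count, self.case_total)

    @property
    def control_freq(self) -> float:
        return round_half_up(self.control_count, self.control_total)

    @property
    def wc_pair_label(self) -> str:
        """The abolished stem pair in RNA letters, pyrimidine first
        (e.g. "C-G" for m.15927G>A at 28:42, "U-A" for m.15924A>G at 31:39)."""
        if self.wc_partner is None:
            return ""
        a = self.variant.ref[0].replace("T", "U")
        b = self.partner_base.replace("T", "U")
        pair = {a, b}
        if pair == {"A", "U"}:
            return "U-A"
        if pair == {"C", "G"}:
            return "C-G"
        return f"{a}-{b}"


def annotate_variant(
    variant: MtVariant,
    model: TrnaGeneModel,
    ci_percent: float,
    case_count: int,
    control_count: int,
    case_total: int,
    control_total: int,
) -> VariantAnnotation:
    trnadb_pos, element, partner, disrupted = annotate_structure(variant, model)
    partner_base = model.base_at_trnadb(partner) if partner is not None else ""
    return VariantAnnotation(
        variant,
        trnadb_pos,
        element,
        partner,
        disrupted,
        ci_percent,
        case_count,
        control_count,
        case_total,
        control_total,
        partner_base,
    )


@dataclass(frozen=True)
class RuleConfig:
    """Tunable classification rule set."""

    ci_threshold: float = 70.0  # percent, inclusive
    control_freq_cap: float = 1.0  # percent, inclusive
    deletion_is_putative: bool = True

    @classmethod
    def default(cls) -> "RuleConfig":
        return cls()

    @classmethod
    def strict_absence(cls) -> "RuleConfig":
        """Conserved AND strictly absent from controls; deletions get no pass."""
        return cls(ci_threshold=70.0, control_freq_cap=0.0, deletion_is_putative=False)

    def with_threshold(self, ci_threshold: float) -> "RuleConfig":
        return replace(self, ci_threshold=ci_threshold)


@dataclass
class Classification:
    label: str
    rule_trace: list[str]


def classify(
    annotation: VariantAnnotation,
    catalog: KnownMutationCatalog,
    rules: RuleConfig | None = None,
) -> Classification:
    """Assign known / putative / polymorphism with a full rule trace."""
    rules = rules or RuleConfig.default()
    v = annotation.variant
    trace: list[str] = []

    in_known = catalog.category(v) == "known_MT_TT"
    trace.append(f"known MT-TT catalog: {'hit' if in_known else 'miss'}")
    if in_known:
        return Classification(KNOWN, trace)

    conserved = annotation.ci_percent >= rules.ci_threshold
    trace.append(
        f"CI {annotation.ci_percent:.2f} >= {rules.ci_threshold:g}: "
        f"{'yes' if conserved else 'no'}"
    )
    is_deletion = v.vtype == DELETION and rules.deletion_is_putative
    if v.vtype == DELETION:
        trace.append(
            "deletion treated as structure-disrupting: "
            f"{'yes' if rules.deletion_is_putative else 'no'}"
        )
    rare_in_controls = annotation.control_freq <= rules.control_freq_cap
    trace.append(
        f"control frequency {annotation.control_freq:.2f}% <= "
        f"{rules.control_freq_cap:g}%: {'yes' if rare_in_controls else 'no'}"
    )
    if (conserved or is_deletion) and rare_in_controls:
        return Classification(PUTATIVE, trace)
    return Classification(POLYMORPHISM, trace)


def classify_table(
    annotations: list[VariantAnnotation],
    catalog: KnownMutationCatalog,
    rules: RuleConfig | None = None,
) -> pd.DataFrame:
    """Evaluation table with one classified row per variant.

    Columns mirror the published layout: position, replacement,
    structural location, tRNAdb site, abolished WC pair, CI, per-arm
    carrier counts with percentages, label and the fired rule trace.
    """
    rules = rules or RuleConfig.default()
    rows = []
    for ann in annotations:
        cls = classify(ann, catalog, rules)
        v = ann.variant
        rows.append(
            {
                "position": v.position,
                "replacement": f"{v.ref}-{v.alt}" if v.vtype != DELETION else f"{v.ref}-Del",
                "variant": v.label,
                "location": ann.element,
                "site": ann.trnadb_pos,
                "wc_pair": ann.wc_pair_label if ann.wc_disrupted else "",
                "ci_percent": ann.ci_percent,
                "cases": f"{ann.case_count}({ann.case_freq:.2f})",
                "controls": f"{ann.control_count}({ann.control_freq:.2f})",
                "label": cls.label,
                "rule_trace": "; ".join(cls.rule_trace),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "position",
            "replacement",
            "variant",
            "location",
            "site",
            "wc_pair",
            "ci_percent",
            "cases",
            "controls",
            "label",
            "rule_trace",
        ],
    )
    return df.sort_values(["label", "position"], key=_label_order).reset_index(drop=True)


def _label_order(col: pd.Series) -> pd.Series:
    if col.name == "label":
        order = {KNOWN: 0, PUTATIVE: 1, POLYMORPHISM: 2}
        return col.map(order)
    return col


def group_counts(table: pd.DataFrame) -> dict[str, int]:
    """{'known': n, 'putative': n, 'polymorphism': n} for a classified table."""
    counts = table["label"].value_counts().to_dict() if len(table) else {}
    return {lab: int(counts.get(lab, 0)) for lab in (KNOWN, PUTATIVE, POLYMORPHISM)}
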