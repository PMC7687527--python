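"""Structural annotation and the three-way classification rule."""

import pytest

from mttt.classification import (
    KNOWN,
    POLYMORPHISM,
    PUTATIVE,
    RuleConfig,
    annotate_structure,
    annotate_variant,
    classify,
    classify_table,
    group_counts,
)
from mttt.reference_model import GeneModelError
from mttt.variants import parse_variant

# The 15 observed variants with their published conservation index and
# per-arm carrier counts (cases of 352, controls of 376).
OBSERVED = [
    ("m.15927G>A", 75.45, 8, 0, KNOWN),
    ("m.15951A>G", 70.45, 4, 0, KNOWN),
    ("m.15900T>C", 72.73, 1, 1, PUTATIVE),
    ("m.15901A>G", 100.00, 1, 0, PUTATIVE),
    ("m.15908T>C", 93.18, 1, 1, PUTATIVE),
    ("m.15924A>G", 90.91, 9, 3, PUTATIVE),
    ("m.15928G>A", 77.27, 3, 2, PUTATIVE),
    ("m.15931A>C", 97.73, 1, 0, PUTATIVE),
    ("m.15940DelT", 22.73, 1, 0, PUTATIVE),
    ("m.15943T>C", 79.55, 2, 1, PUTATIVE),
    ("m.15949G>A", 88.64, 1, 0, PUTATIVE),
    ("m.15907A>G", 65.91, 1, 0, POLYMORPHISM),
    ("m.15930G>A", 25.00, 2, 13, POLYMORPHISM),
    ("m.15938C>T", 40.91, 1, 0, POLYMORPHISM),
    ("m.15941T>C", 47.73, 5, 2, POLYMORPHISM),
]


def make_annotations(model):
    return [
        annotate_variant(parse_variant(label), model, ci, n_case, n_control, 352, 376)
        for label, ci, n_case, n_control, _ in OBSERVED
    ]


@pytest.mark.parametrize(
    "label,site,element,partner,disrupted",
    [
        ("m.15927G>A", 42, "anticodon stem", 28, True),
        ("m.15931A>C", 46, "variable loop", None, False),
        ("m.15908T>C", 23, "DHU stem", 12, True),
        ("m.15940DelT", 56, "T-loop", None, False),
        ("m.15924A>G", 39, "anticodon stem", 31, True),
        ("m.15941T>C", 61, "T-loop", None, False),
    ],
)
def test_annotate_structure(model, label, site, element, partner, disrupted):
    variant = parse_variant(label)
    assert annotate_structure(variant, model) == (site, element, partner, disrupted)


def test_substitution_preserving_wc_pair_not_disrupted(model):
    # site 23 ref is T pairing 12A; T>A would break it, but a
    # hypothetical partner-compatible change is the control case here:
    # site 42 ref G pairs 28C; G>A breaks, nothing restores, so instead
    # check a non-paired site stays undisrupted for every alt.
    for alt in "CGT":
        v = parse_variant(f"m.15907A>{alt}")
        assert annotate_structure(v, model)[3] is False


def test_deletion_at_paired_position_always_disrupts(model):
    v = parse_variant("m.15908DelT")
    assert annotate_structure(v, model) == (23, "DHU stem", 12, True)


def test_position_outside_gene_rejected(model):
    with pytest.raises(GeneModelError):
        annotate_structure(parse_variant("m.11778G>A"), model)


def test_wc_pair_rendering(model):
    ann = annotate_variant(parse_variant("m.15927G>A"), model, 75.45, 8, 0, 352, 376)
    assert ann.wc_pair_label == "C-G"
    ann = annotate_variant(parse_variant("m.15924A>G"), model, 90.91, 9, 3, 352, 376)
    assert ann.wc_pair_label == "U-A"


@pytest.mark.parametrize("label,ci,ncase,nctrl,expected", [
    (lab, ci, a, b, lab_expected) for lab, ci, a, b, lab_expected in OBSERVED
])
def test_default_rules_reproduce_published_labels(
    model, catalog, label, ci, ncase, nctrl, expected
):
    ann = annotate_variant(parse_variant(label), model, ci, ncase, nctrl, 352, 376)
    result = classify(ann, catalog)
    assert result.label == expected
    assert result.rule_trace  # every decision leaves a trace


def test_group_sizes_2_9_4(model, catalog):
    table = classify_table(make_annotations(model), catalog)
    assert group_counts(table) == {"known": 2, "putative": 9, "polymorphism": 4}
    assert len(table) == 15


def test_empty_input_gives_zero_groups(catalog):
    table = classify_table([], catalog)
    assert group_counts(table) == {"known": 0, "putative": 0, "polymorphism": 0}


def test_classification_is_pure(model, catalog):
    ann = annotate_variant(parse_variant("m.15924A>G"), model, 90.91, 9, 3, 352, 376)
    first = classify(ann, catalog)
    second = classify(ann, catalog)
    assert first.label == second.label and first.rule_trace == second.rule_trace


def test_monotone_in_ci_threshold(model, catalog):
    """Raising the CI cut can only shrink the putative group."""
    annotations = make_annotations(model)
    previous = None
    for threshold in (0.0, 25.0, 50.0, 70.0, 80.0, 95.0, 100.1):
        rules = RuleConfig(ci_threshold=threshold)
        putative = {
            ann.variant.label
            for ann in annotations
            if classify(ann, catalog, rules).label == PUTATIVE
        }
        if previous is not None:
            assert putative <= previous
        previous = putative


def test_strict_absence_preset_differs_from_table(model, catalog):
    """The narrative rule (absent in controls, CI > 70, no deletion pass)
    drops the control-carrying and deletion variants from the putative set."""
    annotations = make_annotations(model)
    rules = RuleConfig.strict_absence()
    labels = {
        ann.variant.label: classify(ann, catalog, rules).label for ann in annotations
    }
    assert labels["m.15901A>G"] == PUTATIVE  # conserved, absent in controls
    assert labels["m.15900T>C"] == POLYMORPHISM  # 1 control carrier
    assert labels["m.15940DelT"] == POLYMORPHISM  # low CI, no deletion pass
    assert labels["m.15927G>A"] == KNOWN  # catalog membership still wins
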