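"""Synthetic cohort, alignment and profile generators."""

import pytest

from mttt.conservation import conservation_index
from mttt.haplogroup import assign_haplogroup
from mttt.synthetic import (
    AlignmentSpec,
    CohortSpec,
    SyntheticSpecError,
    generate_alignment,
    generate_cohort,
    generate_profile,
)
from mttt.variants import MtVariant, parse_variant


def test_cohort_counts_match_spec_exactly(cohort_spec, model):
    cases, controls, truth = generate_cohort(cohort_spec, model)
    assert len(cases) == 352 and len(controls) == 376
    ref = model.segment.sequence
    changed_cases = [sid for sid, seq in cases if seq != ref]
    changed_controls = [sid for sid, seq in controls if seq != ref]
    assert len(changed_cases) == 41
    assert len(changed_controls) == 23
    # per-variant carrier counts are assigned, not sampled
    counts = truth.groupby(["arm", "variant"]).size()
    for variant, n_case, n_control in cohort_spec.implants:
        assert counts.get(("case", variant.label), 0) == n_case
        assert counts.get(("control", variant.label), 0) == n_control


def test_cohort_deterministic_under_seed(cohort_spec, model):
    a = generate_cohort(cohort_spec, model)
    b = generate_cohort(cohort_spec, model)
    assert a[0] == b[0] and a[1] == b[1]
    assert a[2].equals(b[2])


def test_empty_implants_gives_reference_cohort(model):
    spec = CohortSpec(n_cases=5, n_controls=3, implants=[], seed=0)
    cases, controls, truth = generate_cohort(spec, model)
    assert all(seq == model.segment.sequence for _, seq in cases + controls)
    assert truth.empty


def test_implant_ref_mismatch_rejected(model):
    spec = CohortSpec(
        n_cases=2, n_controls=2, implants=[(MtVariant(15927, "A", "G"), 1, 0)], seed=0
    )
    with pytest.raises(SyntheticSpecError, match="15927"):
        generate_cohort(spec, model)


def test_more_carriers_than_subjects_rejected():
    with pytest.raises(SyntheticSpecError):
        CohortSpec(n_cases=2, n_controls=2, implants=[(MtVariant(15927, "G", "A"), 3, 0)])


def test_deletion_implant_shortens_sequence(model):
    spec = CohortSpec(
        n_cases=1, n_controls=1, implants=[(parse_variant("m.15940DelT"), 1, 0)], seed=3
    )
    cases, _, _ = generate_cohort(spec, model)
    assert len(cases[0][1]) == 65


def test_alignment_match_counts_honoured(model):
    spec = AlignmentSpec(n_species=44, match_counts={56: 10, 39: 40, 14: 44}, seed=5)
    alignment = generate_alignment(spec, model)
    assert len(alignment) == 44
    assert alignment[0][0] == "Homo_sapiens"
    cols = {pos: model.trnadb_positions.index(pos) for pos in (56, 39, 14)}
    for pos, k in (56, 10), (39, 40), (14, 44):
        col = cols[pos]
        human = alignment[0][1][col]
        assert sum(1 for _, seq in alignment if seq[col] == human) == k
    # and the CI comes out as the printed two-decimal value
    assert conservation_index(alignment, model, 56) == 22.73
    assert conservation_index(alignment, model, 39) == 90.91
    assert conservation_index(alignment, model, 14) == 100.00


def test_alignment_deterministic_and_rectangular(alignment_spec, model):
    a = generate_alignment(alignment_spec, model)
    b = generate_alignment(alignment_spec, model)
    assert a == b
    assert len({len(seq) for _, seq in a}) == 1


def test_alignment_invalid_match_count_rejected():
    with pytest.raises(SyntheticSpecError):
        AlignmentSpec(n_species=44, match_counts={56: 45})
    with pytest.raises(SyntheticSpecError):
        # the human row always matches itself, so 0 is impossible
        AlignmentSpec(n_species=44, match_counts={56: 0})


def test_profile_round_trip_and_determinism(tree):
    p1 = generate_profile(tree, "F1a1", n_private=5, seed=7)
    p2 = generate_profile(tree, "F1a1", n_private=5, seed=7)
    assert p1 == p2
    assert assign_haplogroup(p1, tree).best_node == "F1a1"
    path_labels = {v.label for v in tree.path_variants("F1a1")}
    assert path_labels <= {v.label for v in p1}
    assert len(p1) == len(path_labels) + 5


def test_profile_private_variants_avoid_defining_positions(tree):
    forbidden = tree.all_defining_positions()
    profile = generate_profile(tree, "D4", n_private=10, seed=1)
    defining = {v.label for v in tree.path_variants("D4")}
    for v in profile:
        if v.label not in defining:
            assert v.position not in forbidden


def test_profile_root_is_empty(tree):
    assert generate_profile(tree, "rCRS", n_private=0, seed=0) == []


def test_profile_unknown_haplogroup_errors(tree):
    with pytest.raises(Exception, match="unknown haplogroup"):
        generate_profile(tree, "Q99", n_private=0, seed=0)
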