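"""Variant calling: oracle equivalence, round trips, normalization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mttt.calling import CallingError, call_variants, normalize_deletion, screen_known
from mttt.variants import MtVariant, apply_variants, parse_variant

BASES = "ACGT"


def brute_force_single_edit(subject: str, reference) -> MtVariant | None:
    """Independent oracle: enumerate every single substitution and every
    single-base deletion of the reference and return the variant whose
    product equals the subject (deletions: the 5'-most such position)."""
    ref = reference.sequence
    if len(subject) == len(ref):
        for i, (r, s) in enumerate(zip(ref, subject)):
            if r != s:
                candidate = ref[:i] + s + ref[i + 1 :]
                if candidate == subject:
                    return MtVariant(reference.start + i, r, s)
        return None
    for i in range(len(ref)):  # first (5'-most) matching deletion wins
        if ref[:i] + ref[i + 1 :] == subject:
            return MtVariant(reference.start + i, ref[i], "Del")
    return None


def test_identity_yields_empty_callset(model):
    assert call_variants(model.segment.sequence, model.segment).variants == []


def test_single_substitution_called(model):
    seg = model.segment
    seq = apply_variants(seg.sequence, seg.start, [MtVariant(15927, "G", "A")])
    calls = call_variants(seq, seg).variants
    assert [v.label for v in calls] == ["m.15927G>A"]


def test_all_single_substitutions_match_oracle(model):
    seg = model.segment
    for i, ref_base in enumerate(seg.sequence):
        for alt in BASES:
            if alt == ref_base:
                continue
            subject = seg.sequence[:i] + alt + seg.sequence[i + 1 :]
            called = call_variants(subject, seg).variants
            expected = brute_force_single_edit(subject, seg)
            assert called == [expected], f"offset {i} {ref_base}>{alt}"


def test_all_single_deletions_match_oracle(model):
    seg = model.segment
    for i in range(len(seg.sequence)):
        subject = seg.sequence[:i] + seg.sequence[i + 1 :]
        called = call_variants(subject, seg).variants
        expected = brute_force_single_edit(subject, seg)
        assert called == [expected], f"deletion at offset {i}"


def test_homopolymer_deletion_normalized_to_5prime(model):
    # the T-run spans 15940-15944; removing any T must be reported
    # at the run's 5'-most coordinate, the community label m.15940DelT
    seg = model.segment
    for offset in range(15940, 15945):
        i = offset - seg.start
        assert seg.sequence[i] == "T"
        subject = seg.sequence[:i] + seg.sequence[i + 1 :]
        calls = call_variants(subject, seg).variants
        assert [v.label for v in calls] == ["m.15940DelT"]


def test_3prime_normalization_mode(model):
    seg = model.segment
    raw = MtVariant(15940, "T", "Del")
    assert normalize_deletion(raw, seg, mode="3prime").position == 15944
    assert normalize_deletion(raw, seg, mode="5prime").position == 15940
    i = 15942 - seg.start
    subject = seg.sequence[:i] + seg.sequence[i + 1 :]
    calls = call_variants(subject, seg, deletion_mode="3prime").variants
    assert [v.label for v in calls] == ["m.15944DelT"]


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.data())
def test_multi_substitution_round_trip(model, data):
    """Applying the called variants to rCRS reproduces the subject."""
    seg = model.segment
    n = data.draw(st.integers(min_value=0, max_value=5))
    offsets = data.draw(
        st.lists(
            st.integers(min_value=0, max_value=65), min_size=n, max_size=n, unique=True
        )
    )
    seq = list(seg.sequence)
    for i in offsets:
        seq[i] = data.draw(st.sampled_from([b for b in BASES if b != seq[i]]))
    subject = "".join(seq)
    calls = call_variants(subject, seg).variants
    assert apply_variants(seg.sequence, seg.start, calls) == subject
    assert len(calls) == len(offsets)


def test_ambiguity_codes_rejected(model):
    seg = model.segment
    subject = "R" + seg.sequence[1:]
    with pytest.raises(CallingError, match="ambiguity"):
        call_variants(subject, seg)


def test_large_length_difference_rejected(model):
    seg = model.segment
    with pytest.raises(CallingError, match="length"):
        call_variants(seg.sequence[:-4], seg)
    with pytest.raises(CallingError, match="length"):
        call_variants(seg.sequence + "A", seg)


def test_screen_known_categories(catalog):
    profile = [parse_variant("m.11778G>A"), parse_variant("m.73A>G")]
    assert screen_known(profile, catalog) == [(parse_variant("m.11778G>A"), "primary")]
    assert screen_known([], catalog) == []
    hit = screen_known([parse_variant("m.15927G>A")], catalog)
    assert hit == [(parse_variant("m.15927G>A"), "known_MT_TT")]


def test_full_cohort_recovers_truth_table(study_result):
    """Zero false positives/negatives over the whole synthetic cohort."""
    truth = {
        (row.subject_id, row.variant)
        for row in study_result.truth.itertuples(index=False)
    }
    called = {
        (cs.subject_id, v.label)
        for cs in study_result.case_callsets + study_result.control_callsets
        for v in cs.variants
    }
    assert called == truth
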