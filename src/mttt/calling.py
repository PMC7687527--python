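"""Variant calling over the MT-TT segment.

Each subject's consensus sequence is compared with the rCRS segment by
exact global alignment (the segment is 66 nt, so exactness is cheap) and
reduced to substitutions and deletions.  Deletions inside homopolymer
runs are ambiguous in placement; by default they are normalized to the
5'-most position of the run on the forward rCRS strand, which is the
convention behind the community label m.15940DelT for the T-run at
15940-15944.  A "3prime" mode is available.
"""

from __future__ import annotations

import re

import edlib

from .reference_model import KnownMutationCatalog, RcrsSegment
from .variants import VALID_BASES, CallSet, MtVariant, apply_variants

MAX_LENGTH_DIFF = 3

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


class CallingError(ValueError):
    """Sequence that cannot be resolved into substitutions/deletions."""


def normalize_deletion(
    variant: MtVariant, reference: RcrsSegment, mode: str = "5prime"
) -> MtVariant:
    """Shift a deletion to the 5'-most (or 3'-most) equivalent position.

    A deletion of ``ref[p..p+n-1]`` can slide left while the base before
    it equals the last deleted base (and right symmetrically) without
    changing the resulting sequence.
    """
    if variant.vtype != "deletion":
        return variant
    pos, n = variant.position, len(variant.ref)
    if mode == "5prime":
        while pos > reference.start and reference.base_at(pos - 1) == reference.base_at(
            pos + n - 1
        ):
            pos -= 1
    elif mode == "3prime":
        while pos + n - 1 < reference.end and reference.base_at(pos + n) == reference.base_at(
            pos
        ):
            pos += 1
    else:
        raise ValueError(f"unknown deletion normalization mode {mode!r}")
    return MtVariant(pos, reference.run_at(pos, n), "Del")


def call_variants(
    subject_seq: str,
    reference: RcrsSegment,
    subject_id: str = "subject",
    arm: str = "case",
    deletion_mode: str = "5prime",
) -> CallSet:
    """Minimal substitution/deletion call set transforming rCRS into the subject.

    Raises :class:`CallingError` for ambiguity codes, insertions
    relative to rCRS, or length differences beyond 3 nt.
    """
    seq = subject_seq.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise CallingError(
            f"{subject_id}: ambiguity/invalid characters {sorted(bad)} in consensus "
            "(heteroplasmy codes are not interpreted)"
        )
    ref = reference.sequence
    if len(ref) - len(seq) > MAX_LENGTH_DIFF or len(seq) > len(ref):
        raise CallingError(
            f"{subject_id}: length {len(seq)} vs reference {len(ref)} "
            f"(insertions / more than {MAX_LENGTH_DIFF} deleted bases unsupported)"
        )
    if len(seq) == len(ref):
        # equal length: under a substitution/deletion-only model the
        # minimal edit script is the position-wise difference
        variants = [
            MtVariant(reference.start + i, r, s)
            for i, (r, s) in enumerate(zip(ref, seq))
            if r != s
        ]
        return CallSet(subject_id, arm, variants)

    result = edlib.align(seq, ref, mode="NW", task="path")
    variants: list[MtVariant] = []
    ref_pos = reference.start
    qry_idx = 0
    del_start: int | None = None
    del_len = 0

    def flush_deletion() -> None:
        nonlocal del_start, del_len
        if del_start is not None:
            raw = MtVariant(del_start, reference.run_at(del_start, del_len), "Del")
            variants.append(normalize_deletion(raw, reference, deletion_mode))
            del_start, del_len = None, 0

    for count, op in _CIGAR_RE.findall(result["cigar"]):
        n = int(count)
        if op == "=":
            flush_deletion()
            ref_pos += n
            qry_idx += n
        elif op == "X":
            flush_deletion()
            for i in range(n):
                variants.append(
                    MtVariant(ref_pos + i, reference.base_at(ref_pos + i), seq[qry_idx + i])
                )
            ref_pos += n
            qry_idx += n
        elif op == "D":  # consumes reference only: deletion in the subject
            if del_start is None:
                del_start = ref_pos
            del_len += n
            ref_pos += n
        else:  # "I": subject has extra bases
            raise CallingError(f"{subject_id}: insertion relative to rCRS not supported")
    flush_deletion()

    if apply_variants(ref, reference.start, variants) != seq:
        raise CallingError(f"{subject_id}: unresolvable alignment")  # pragma: no cover
    return CallSet(subject_id, arm, variants)


def call_cohort(
    records: list[tuple[str, str]],
    reference: RcrsSegment,
    arm: str,
    deletion_mode: str = "5prime",
) -> list[CallSet]:
    return [
        call_variants(seq, reference, sid, arm, deletion_mode) for sid, seq in records
    ]


def screen_known(
    profile: list[MtVariant], catalog: KnownMutationCatalog
) -> list[tuple[MtVariant, str]]:
    """Catalog hits in a full-mtDNA profile, tagged by category."""
    hits = []
    for variant in profile:
        category = catalog.category(variant)
        if category is not None:
            hits.append((variant, category))
    return hits
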