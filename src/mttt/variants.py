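"""mtDNA variant objects and HGVS-like label handling.

Variants are expressed as differences from the revised Cambridge
Reference Sequence (rCRS, NC_012920.1) using 1-based coordinates and the
mitochondrial community notation: ``m.15927G>A`` for substitutions,
``m.15940DelT`` for single-base deletions and ``m.8281_8289del`` for
multi-base deletions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGT")

SUBSTITUTION = "substitution"
DELETION = "deletion"

_SUB_RE = re.compile(r"^(?:m\.)?(\d+)([ACGT])>([ACGT])$")
_DEL1_RE = re.compile(r"^(?:m\.)?(\d+)Del([ACGT])$", re.IGNORECASE)
_DELN_RE = re.compile(r"^(?:m\.)?(\d+)_(\d+)del$", re.IGNORECASE)


class VariantError(ValueError):
    """Malformed variant label or inconsistent variant fields."""


@dataclass(frozen=True, order=True)
class MtVariant:
    """One difference from rCRS: a substitution or a deletion.

    ``ref`` is the reference base (or base run, for multi-base
    deletions); ``alt`` is the replacement base, or ``"Del"`` for
    deletions.
    """

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantError(f"position must be >= 1, got {self.position}")
        if not self.ref or any(b not in VALID_BASES for b in self.ref):
            raise VariantError(f"invalid ref allele {self.ref!r} at {self.position}")
        if self.alt == "Del":
            return
        if len(self.ref) != 1 or self.alt not in VALID_BASES:
            raise VariantError(
                f"invalid substitution {self.ref!r}>{self.alt!r} at {self.position}"
            )
        if self.alt == self.ref:
            raise VariantError(f"ref == alt ({self.ref}) at {self.position}")

    @property
    def vtype(self) -> str:
        return DELETION if self.alt == "Del" else SUBSTITUTION

    @property
    def end(self) -> int:
        """Last reference position touched (== position for substitutions)."""
        return self.position + len(self.ref) - 1

    @property
    def label(self) -> str:
        if self.vtype == SUBSTITUTION:
            return f"m.{self.position}{self.ref}>{self.alt}"
        if len(self.ref) == 1:
            return f"m.{self.position}Del{self.ref}"
        return f"m.{self.position}_{self.end}del"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_variant(label: str, ref_run: str | None = None) -> MtVariant:
    """Parse a variant label into an :class:`MtVariant`.

    Multi-base deletion labels (``m.8281_8289del``) do not carry the
    deleted bases; supply them via ``ref_run`` or a run of the correct
    length is required from the caller downstream.  For the shipped
    haplogroup tree the only such variant is the well-known 9-bp
    COII/tRNA-Lys repeat deletion, whose bases are filled in here.
    """
    label = label.strip()
    m = _SUB_RE.match(label)
    if m:
        return MtVariant(int(m.group(1)), m.group(2), m.group(3))
    m = _DEL1_RE.match(label)
    if m:
        return MtVariant(int(m.group(1)), m.group(2).upper(), "Del")
    m = _DELN_RE.match(label)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end < start:
            raise VariantError(f"deletion end < start in {label!r}")
        n = end - start + 1
        if ref_run is None:
            if (start, end) == (8281, 8289):
                ref_run = "CCCCCTCTA"  # the mtDNA 9-bp repeat unit
            else:
                ref_run = "A" * n  # placeholder run; used for identity only
        if len(ref_run) != n:
            raise VariantError(f"ref run length {len(ref_run)} != span {n} in {label!r}")
        return MtVariant(start, ref_run, "Del")
    raise VariantError(f"unparseable variant label {label!r}")


@dataclass
class CallSet:
    """Variants called for one subject over the gene segment."""

    subject_id: str
    arm: str  # "case" or "control"
    variants: list[MtVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arm not in ("case", "control"):
            raise VariantError(f"arm must be case/control, got {self.arm!r}")
        self.variants = sorted(self.variants, key=lambda v: v.position)
        positions = [v.position for v in self.variants]
        if len(set(positions)) != len(positions):
            raise VariantError(f"duplicate positions in call set for {self.subject_id}")


def apply_variants(sequence: str, start: int, variants: list[MtVariant]) -> str:
    """Apply variants to a reference ``sequence`` whose first base has
    coordinate ``start``; returns the mutated sequence.

    Variants must lie within the sequence and their ref alleles must
    match it.  Applied right-to-left so deletion index shifts cannot
    interfere.
    """
    seq = list(sequence)
    for v in sorted(variants, key=lambda v: v.position, reverse=True):
        i = v.position - start
        if i < 0 or v.end - start >= len(sequence):
            raise VariantError(f"{v.label} outside segment {start}..{start + len(sequence) - 1}")
        run = sequence[i : i + len(v.ref)]
        if run != v.ref:
            raise VariantError(
                f"ref mismatch at {v.position}: variant says {v.ref!r}, reference has {run!r}"
            )
        if v.vtype == SUBSTITUTION:
            seq[i] = v.alt
        else:
            del seq[i : i + len(v.ref)]
    return "".join(seq)
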