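"""Synthetic input generator.

The published screen worked from Sanger consensus sequences, a
44-vertebrate alignment and full-mitogenome variant profiles, none of
which are shipped here.  This module fabricates all three from explicit
specifications so the whole pipeline runs self-contained:

* a case/control cohort of MT-TT segment sequences with variants
  implanted at exact per-arm carrier counts (counts are assigned, not
  sampled, because the study's printed counts are the condition being
  reproduced; one variant per carrier, matching the published
  arithmetic);
* a multi-species alignment with a prescribed number of matching
  species per site;
* full-mtDNA variant profiles drawn from the haplogroup tree (the
  root->node defining variants plus seeded private variants).

Homoplasmy is assumed throughout: every implanted variant fully
replaces the reference base, as all changes in the study appeared to be
homoplasmic.  Sequencing error is not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reference_model import HaplogroupTree, TrnaGeneModel, _data_path
from .variants import VALID_BASES, MtVariant, apply_variants, parse_variant


class SyntheticSpecError(ValueError):
    """Impossible or inconsistent generator specification."""


@dataclass
class CohortSpec:
    """Cohort sizes and exact per-variant carrier counts per arm."""

    n_cases: int
    n_controls: int
    implants: list[tuple[MtVariant, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(k for _, k, _ in self.implants) > self.n_cases:
            raise SyntheticSpecError("more case carriers requested than cases")
        if sum(k for _, _, k in self.implants) > self.n_controls:
            raise SyntheticSpecError("more control carriers requested than controls")


@dataclass
class AlignmentSpec:
    """Species count and per-site human-match counts for the alignment."""

    n_species: int = 44
    match_counts: dict[int, int] = field(default_factory=dict)  # tRNAdb pos -> k
    seed: int = 0

    def __post_init__(self) -> None:
        for pos, k in self.match_counts.items():
            if not 1 <= k <= self.n_species:
                raise SyntheticSpecError(
                    f"match count {k} at tRNAdb {pos} outside 1..{self.n_species} "
                    "(the human row always matches itself)"
                )


def load_cohort_spec(path: str | Path | None = None, seed: int = 0) -> CohortSpec:
    """Load a cohort spec YAML (default: the shipped study counts)."""
    path = Path(path) if path else _data_path("cohort_study.yaml")
    cfg = yaml.safe_load(path.read_text())
    implants = [
        (parse_variant(row["variant"]), int(row["cases"]), int(row["controls"]))
        for row in cfg["implants"]
    ]
    return CohortSpec(int(cfg["n_cases"]), int(cfg["n_controls"]), implants, seed)


def load_alignment_spec(path: str | Path | None = None, seed: int = 0) -> AlignmentSpec:
    path = Path(path) if path else _data_path("alignment_study.yaml")
    cfg = yaml.safe_load(path.read_text())
    counts = {int(k): int(v) for k, v in cfg["match_counts"].items()}
    return AlignmentSpec(int(cfg["n_species"]), counts, seed)


def _assign_arm(
    rng: np.random.Generator,
    arm: str,
    n_subjects: int,
    counts: list[tuple[MtVariant, int]],
    model: TrnaGeneModel,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    seg = model.segment
    for variant, _ in counts:
        run = seg.run_at(variant.position, len(variant.ref))
        if run != variant.ref:
            raise SyntheticSpecError(
                f"implant {variant.label}: reference has {run!r} at m.{variant.position}"
            )
    width = len(str(n_subjects))
    ids = [f"{arm}_{i + 1:0{width}d}" for i in range(n_subjects)]
    order = rng.permutation(n_subjects)
    records: list[tuple[str, str]] = [(sid, seg.sequence) for sid in ids]
    truth_rows = []
    cursor = 0
    for variant, k in counts:
        for idx in order[cursor : cursor + k]:
            sid = ids[idx]
            records[idx] = (sid, apply_variants(seg.sequence, seg.start, [variant]))
            truth_rows.append({"subject_id": sid, "arm": arm, "variant": variant.label})
        cursor += k
    truth = pd.DataFrame(truth_rows, columns=["subject_id", "arm", "variant"])
    return records, truth


def generate_cohort(
    spec: CohortSpec, model: TrnaGeneModel
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Build (cases, controls, truth_table).

    Sequences are (subject_id, sequence) pairs over the gene segment;
    carriers differ from rCRS by exactly their implanted variant and
    every carrier set is disjoint (subjects are shuffled by the seed,
    then assigned to variants in spec order).  The truth table records
    subject -> variant assignments.
    """
    rng = np.random.default_rng(spec.seed)
    cases, truth_cases = _assign_arm(
        rng, "case", spec.n_cases, [(v, k) for v, k, _ in spec.implants], model
    )
    controls, truth_controls = _assign_arm(
        rng, "control", spec.n_controls, [(v, k) for v, _, k in spec.implants], model
    )
    truth = pd.concat([truth_cases, truth_controls], ignore_index=True)
    return cases, controls, truth


def generate_alignment(
    spec: AlignmentSpec, model: TrnaGeneModel
) -> list[tuple[str, str]]:
    """Build a gap-free multi-species alignment over the gene.

    Row 0 is the human sequence; at each tRNAdb position with a
    specified match count k, exactly k rows (human included) carry the
    human base and the rest carry a seeded random other base.
    Unspecified positions are fully conserved.
    """
    rng = np.random.default_rng(spec.seed)
    human = "".join(model.base_at_trnadb(p) for p in model.trnadb_positions)
    n_other = spec.n_species - 1
    rows = [list(human) for _ in range(n_other)]
    for col, pos in enumerate(model.trnadb_positions):
        k = spec.match_counts.get(pos, spec.n_species)
        n_mismatch = spec.n_species - k
        if n_mismatch == 0:
            continue
        which = rng.choice(n_other, size=n_mismatch, replace=False)
        others = sorted(VALID_BASES - {human[col]})
        for r in which:
            rows[r][col] = others[rng.integers(len(others))]
    out = [("Homo_sapiens", human)]
    out += [(f"vertebrate_{i + 1:02d}", "".join(row)) for i, row in enumerate(rows)]
    return out


def generate_profile(
    tree: HaplogroupTree, haplogroup: str, n_private: int = 0, seed: int = 0
) -> list[MtVariant]:
    """Full-mtDNA variant profile for a lineage of the given haplogroup.

    The profile is the union of defining variants along the root->node
    path plus ``n_private`` seeded random substitutions that avoid every
    defining-variant position in the whole tree (collisions are redrawn),
    so haplogroup assignment round-trips by construction.
    """
    path_variants = tree.path_variants(haplogroup)  # raises on unknown name
    rng = np.random.default_rng(seed)
    forbidden = tree.all_defining_positions()
    taken = set(forbidden)
    bases = sorted(VALID_BASES)
    private: list[MtVariant] = []
    while len(private) < n_private:
        pos = int(rng.integers(1, 16570))
        if pos in taken:
            continue
        taken.add(pos)
        ref = bases[rng.integers(4)]
        alt = sorted(VALID_BASES - {ref})[rng.integers(3)]
        private.append(MtVariant(pos, ref, alt))
    return sorted(path_variants + private, key=lambda v: v.position)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_profiles(profiles: dict[str, list[MtVariant]], path: str | Path) -> None:
    rows = [
        {"subject_id": sid, "position": v.position, "ref": v.ref, "alt": v.alt}
        for sid, variants in profiles.items()
        for v in variants
    ]
    pd.DataFrame(rows, columns=["subject_id", "position", "ref", "alt"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(path: str | Path) -> dict[str, list[MtVariant]]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "ref": str, "alt": str})
    out: dict[str, list[MtVariant]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.subject_id, []).append(
            MtVariant(int(row.position), row.ref, row.alt)
        )
    return out
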