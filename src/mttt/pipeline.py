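"""End-to-end orchestration of the MT-TT screening study.

``run_study`` executes the whole analysis in memory: simulate (or load)
the cohort, call variants against rCRS, compute conservation indices,
annotate and classify each variant, compute cohort statistics, and
assign haplogroups to the carrier mitogenomes.  ``run_pipeline`` wraps
it with file output: a report bundle of plain-text tables plus a run
log, byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import call_cohort, screen_known
from .classification import (
    RuleConfig,
    VariantAnnotation,
    annotate_variant,
    classify_table,
    group_counts,
)
from .conservation import conservation_index
from .haplogroup import (
    HaplogroupCall,
    assign_haplogroup,
    calls_to_frame,
    frequency_table,
)
from .reference_model import (
    _data_path,
    load_catalog,
    load_gene_model,
    load_haplogroup_tree,
)
from .synthetic import (
    generate_alignment,
    generate_cohort,
    generate_profile,
    load_alignment_spec,
    load_cohort_spec,
    write_fasta,
    write_profiles,
)
from .variants import CallSet, MtVariant

N_PRIVATE_VARIANTS = 8  # private substitutions per simulated mitogenome


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 1
    gene_model: Path | None = None
    cohort_spec: Path | None = None
    alignment_spec: Path | None = None
    catalog: Path | None = None
    tree: Path | None = None
    carrier_table: Path | None = None
    rules: RuleConfig = field(default_factory=RuleConfig.default)
    gap_mode: str = "mismatch"
    deletion_mode: str = "5prime"
    continuity_correction: bool = False

    def echo(self) -> dict:
        return {
            "seed": self.seed,
            "gene_model": str(self.gene_model or _data_path("gene_model.yaml")),
            "cohort_spec": str(self.cohort_spec or _data_path("cohort_study.yaml")),
            "alignment_spec": str(self.alignment_spec or _data_path("alignment_study.yaml")),
            "catalog": str(self.catalog or _data_path("known_mutations.tsv")),
            "tree": str(self.tree or _data_path("haplogroup_tree.yaml")),
            "carrier_table": str(self.carrier_table or _data_path("carrier_haplogroups.tsv")),
            "rules": {
                "ci_threshold": self.rules.ci_threshold,
                "control_freq_cap": self.rules.control_freq_cap,
                "deletion_is_putative": self.rules.deletion_is_putative,
            },
            "gap_mode": self.gap_mode,
            "deletion_mode": self.deletion_mode,
            "continuity_correction": self.continuity_correction,
            "n_private_variants": N_PRIVATE_VARIANTS,
            "version": __version__,
        }


@dataclass
class StudyResult:
    """Everything the analysis computes, in memory."""

    model: object
    cases: list[tuple[str, str]]
    controls: list[tuple[str, str]]
    truth: pd.DataFrame
    alignment: list[tuple[str, str]]
    case_callsets: list[CallSet]
    control_callsets: list[CallSet]
    annotations: list[VariantAnnotation]
    table: pd.DataFrame  # classified evaluation table
    groups: dict[str, int]
    report: dict
    profiles: dict[str, list[MtVariant]]
    haplogroup_calls: list[HaplogroupCall]
    haplogroup_freq: pd.DataFrame
    known_screen: dict[str, list[tuple[MtVariant, str]]]


def _tabulate(callsets: list[CallSet]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for cs in callsets:
        for v in cs.variants:
            counts[v.label] = counts.get(v.label, 0) + 1
    return counts


def run_study(config: RunConfig | None = None, seed: int = 1) -> StudyResult:
    """Run the full screening study on synthetic inputs."""
    if config is None:
        config = RunConfig(out_dir=Path("."), seed=seed)
    model = load_gene_model(config.gene_model)
    catalog = load_catalog(config.catalog)
    tree = load_haplogroup_tree(config.tree)

    cohort_spec = load_cohort_spec(config.cohort_spec, seed=config.seed)
    cases, controls, truth = generate_cohort(cohort_spec, model)
    alignment = generate_alignment(
        load_alignment_spec(config.alignment_spec, seed=config.seed), model
    )

    case_callsets = call_cohort(cases, model.segment, "case", config.deletion_mode)
    control_callsets = call_cohort(controls, model.segment, "control", config.deletion_mode)

    case_counts = _tabulate(case_callsets)
    control_counts = _tabulate(control_callsets)
    observed: dict[str, MtVariant] = {}
    for cs in case_callsets + control_callsets:
        for v in cs.variants:
            observed.setdefault(v.label, v)

    annotations = []
    for label in sorted(observed, key=lambda lab: observed[lab].position):
        v = observed[label]
        ci = conservation_index(
            alignment, model, model.trnadb_position(v.position), config.gap_mode
        )
        annotations.append(
            annotate_variant(
                v,
                model,
                ci,
                case_counts.get(label, 0),
                control_counts.get(label, 0),
                cohort_spec.n_cases,
                cohort_spec.n_controls,
            )
        )
    table = classify_table(annotations, catalog, config.rules)
    groups = group_counts(table)
    labels = dict(zip(table["variant"], table["label"]))
    report = _aggregate(case_callsets, control_callsets, catalog, labels)

    # Haplogroup analysis of the 41 case carriers: simulate one full
    # mitogenome per carrier from its published lineage, screen it for
    # known LHON mutations, then recover the haplogroup from the profile.
    carrier_path = config.carrier_table or _data_path("carrier_haplogroups.tsv")
    carriers = pd.read_csv(carrier_path, sep="\t")
    rng = np.random.default_rng(config.seed)
    profiles: dict[str, list[MtVariant]] = {}
    calls: list[HaplogroupCall] = []
    known_screen: dict[str, list[tuple[MtVariant, str]]] = {}
    for row in carriers.itertuples(index=False):
        subject_seed = int(rng.integers(2**31))
        profile = generate_profile(tree, row.haplogroup, N_PRIVATE_VARIANTS, subject_seed)
        profiles[row.subject_id] = profile
        known_screen[row.subject_id] = screen_known(profile, catalog)
        calls.append(assign_haplogroup(profile, tree, row.subject_id))

    subgroup_of = dict(zip(carriers["subject_id"], carriers["subgroup"]))
    by_subgroup: dict[str, list[HaplogroupCall]] = {"all sequenced carriers": list(calls)}
    for call in calls:
        by_subgroup.setdefault(subgroup_of[call.subject_id], []).append(call)
    freq = frequency_table(by_subgroup, tree)

    return StudyResult(
        model,
        cases,
        controls,
        truth,
        alignment,
        case_callsets,
        control_callsets,
        annotations,
        table,
        groups,
        report,
        profiles,
        calls,
        freq,
        known_screen,
    )


def _aggregate(case_callsets, control_callsets, catalog, labels) -> dict:
    from .stats import aggregate_report

    return aggregate_report(case_callsets, control_callsets, catalog, labels)


def callsets_to_frame(callsets: list[CallSet]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": cs.subject_id,
            "arm": cs.arm,
            "variant": v.label,
            "position": v.position,
            "ref": v.ref,
            "alt": v.alt,
            "vtype": v.vtype,
        }
        for cs in callsets
        for v in cs.variants
    ]
    return pd.DataFrame(
        rows, columns=["subject_id", "arm", "variant", "position", "ref", "alt", "vtype"]
    )


def run_pipeline(config: RunConfig) -> StudyResult:
    """Run the study and write the report bundle under ``config.out_dir``.

    Bundle contents: simulated inputs (FASTA + truth table + profiles),
    per-subject calls, the classified evaluation table, cohort
    statistics JSON, haplogroup calls and frequency table, and a run
    log echoing the full configuration with a content hash.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_study(config)

    write_fasta(result.cases, out / "cases.fa")
    write_fasta(result.controls, out / "controls.fa")
    write_fasta(result.alignment, out / "alignment.fa")
    result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    write_profiles(result.profiles, out / "profiles.tsv")

    calls = pd.concat(
        [
            callsets_to_frame(result.case_callsets),
            callsets_to_frame(result.control_callsets),
        ],
        ignore_index=True,
    )
    calls.to_csv(out / "calls.tsv", sep="\t", index=False)
    result.table.to_csv(out / "variant_table.tsv", sep="\t", index=False)
    (out / "stats.json").write_text(json.dumps(result.report, indent=2) + "\n")
    tree = load_haplogroup_tree(config.tree)
    calls_to_frame(result.haplogroup_calls, tree).to_csv(
        out / "haplogroup_calls.tsv", sep="\t", index=False
    )
    result.haplogroup_freq.to_csv(out / "haplogroup_freq.tsv", sep="\t")

    echo = config.echo()
    digest = hashlib.sha256(
        json.dumps(echo, sort_keys=True).encode()
    ).hexdigest()[:16]
    echo["config_hash"] = digest
    (out / "run.json").write_text(json.dumps(echo, indent=2) + "\n")
    return result
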