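"""Cohort-level statistics of the MT-TT screen.

From the per-subject calls: distinct-variant and carrier counts per
arm, variant-free subject counts, the combined known-mutation carrier
frequency, putative-variant carrier frequency, and the Pearson
chi-square comparison of carrier rates between cases and controls
(uncorrected; the Yates-corrected value is reported alongside for
reference).  Writes results/stats.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mttt.reference_model import load_catalog
from mttt.stats import aggregate_report, chi_square_2x2
from mttt.variants import CallSet, MtVariant

N_CASES, N_CONTROLS = 352, 376


def callsets_from_frame(calls: pd.DataFrame, arm: str, total: int) -> list[CallSet]:
    sub = calls[calls.arm == arm]
    carriers = {
        sid: CallSet(sid, arm, [MtVariant(int(r.position), r.ref, r.alt)
                                for r in grp.itertuples(index=False)])
        for sid, grp in sub.groupby("subject_id")
    }
    free = [CallSet(f"{arm}_free_{i}", arm) for i in range(total - len(carriers))]
    return list(carriers.values()) + free


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--calls", type=Path, default=Path("results/calls.tsv"))
    parser.add_argument("--table", type=Path, default=Path("results/variant_table.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/stats.json"))
    args = parser.parse_args()

    calls = pd.read_csv(args.calls, sep="\t")
    table = pd.read_csv(args.table, sep="\t")
    labels = dict(zip(table.variant, table.label))
    cases = callsets_from_frame(calls, "case", N_CASES)
    controls = callsets_from_frame(calls, "control", N_CONTROLS)

    report = aggregate_report(cases, controls, load_catalog(), labels)
    corrected = chi_square_2x2(
        report["cases_with_any_variant"], report["variant_free_cases"],
        report["controls_with_any_variant"], report["variant_free_controls"],
        continuity_correction=True,
    )
    report["carrier_p_value_yates"] = corrected.p_value
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(report, indent=2) + "\n")

    print(f"carriers: {report['cases_with_any_variant']}/{N_CASES} cases vs "
          f"{report['controls_with_any_variant']}/{N_CONTROLS} controls")
    print(f"chi-square = {report['carrier_chi2']:.4f}, "
          f"p = {report['carrier_p_value']:.4f} (uncorrected); "
          f"p = {corrected.p_value:.4f} with Yates correction")
    print(f"known MT-TT mutation carriers: {report['known_mutation_case_carriers']} "
          f"({report['known_mutation_case_percent']}% of cases)")
    print(f"putative-variant carriers: {report['putative_case_carriers']} cases")


if __name__ == "__main__":
    main()
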