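"""Simulate every input of the MT-TT screening study.

Builds, from the shipped study specifications:
  * a cohort of 352 LHON case and 376 control consensus sequences over
    the MT-TT segment (m.15888-15953), with the 15 observed variants
    implanted at their published carrier counts and a truth table;
  * a 44-vertebrate alignment whose per-site match counts reproduce the
    published conservation indices;
  * one full-mitogenome variant profile per sequenced carrier (32
    subjects), drawn from the curated haplogroup tree.

Writes results/simulated/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mttt.pipeline import N_PRIVATE_VARIANTS
from mttt.reference_model import _data_path, load_gene_model, load_haplogroup_tree
from mttt.synthetic import (
    generate_alignment,
    generate_cohort,
    generate_profile,
    load_alignment_spec,
    load_cohort_spec,
    write_fasta,
    write_profiles,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/simulated"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    model = load_gene_model()
    tree = load_haplogroup_tree()

    spec = load_cohort_spec(seed=args.seed)
    cases, controls, truth = generate_cohort(spec, model)
    write_fasta(cases, out / "cases.fa")
    write_fasta(controls, out / "controls.fa")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    n_case_carriers = truth[truth.arm == "case"].shape[0]
    print(f"cohort: {len(cases)} cases ({n_case_carriers} carriers), {len(controls)} controls")

    alignment = generate_alignment(load_alignment_spec(seed=args.seed), model)
    write_fasta(alignment, out / "alignment.fa")
    print(f"alignment: {len(alignment)} species x {len(alignment[0][1])} columns")

    carriers = pd.read_csv(_data_path("carrier_haplogroups.tsv"), sep="\t")
    rng = np.random.default_rng(args.seed)
    profiles = {
        row.subject_id: generate_profile(
            tree, row.haplogroup, N_PRIVATE_VARIANTS, int(rng.integers(2**31))
        )
        for row in carriers.itertuples(index=False)
    }
    write_profiles(profiles, out / "profiles.tsv")
    print(f"profiles: {len(profiles)} carrier mitogenomes "
          f"({sum(len(p) for p in profiles.values())} variants total)")


if __name__ == "__main__":
    main()
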