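#!/usr/bin/env python
"""Estimate the cross-species transcriptional baseline.

Selects core non-DE homology groups with a single expressed ortholog per
species, computes pairwise log2 ratios of treatment-pooled mean TPM,
summarizes each pair by its median offset and exceedance fraction, and
compares the recovered per-species offsets with the generator's planted
truth. Writes the pairwise report and per-species offsets to results/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from xslux.abundance import mean_tpm, tpm
from xslux.cross_species import pairwise_log2_ratios, select_baseline_groups
from xslux.io_formats import read_count_matrix, read_homology_table, read_sample_table
from xslux.synthetic import SimConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixture", type=Path, default=Path("results/fixture"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--min-tpm", type=float, default=1.0)
    parser.add_argument("--exceedance-threshold", type=float, default=0.0)
    args = parser.parse_args()

    species = SimConfig().species
    samples = read_sample_table(args.fixture / "samples.tsv")
    table = read_homology_table(args.fixture / "homology.tsv")
    cls = pd.read_csv(args.out / "hg_classification.tsv", sep="\t", index_col=0)

    mean_sp = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sp in species:
            cm = read_count_matrix(
                args.fixture / f"counts_{sp}.tsv",
                args.fixture / f"lengths_{sp}.tsv",
                species_id=sp,
            )
            mean_sp[sp] = mean_tpm(tpm(cm), samples, "species")
        groups = select_baseline_groups(cls, table, mean_sp, min_tpm=args.min_tpm)
        model = pairwise_log2_ratios(groups, table, mean_sp)

    summary = model.summary(args.exceedance_threshold)
    summary.to_csv(args.out / "baseline_report.tsv", sep="\t", index=False)
    offsets = model.species_offsets()
    offsets.rename_axis("species_id").to_frame().to_csv(
        args.out / "baseline_offsets.tsv", sep="\t"
    )

    print(f"baseline estimated from {model.n_groups} single-copy non-DE core groups")
    print(summary.round(3).to_string(index=False))
    truth_path = args.fixture / "truth_offsets.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0).iloc[:, 0]
        cmp = pd.DataFrame({"estimated": offsets, "planted": truth})
        cmp["abs_error"] = (cmp["estimated"] - cmp["planted"]).abs()
        print("\nper-species offsets vs planted truth (log2):")
        print(cmp.round(3).to_string())


if __name__ == "__main__":
    main()
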