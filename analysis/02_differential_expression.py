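#!/usr/bin/env python
"""Per-species differential expression between the two light treatments.

Runs the NB Wald contrast (HL over LL) on each species' count matrix from
results/fixture/ and writes per-species DE tables plus a summary of
up/down/unchanged counts with one-decimal percentages.
"""

import argparse
import warnings
from pathlib import Path

from xslux.de_stats import summarize_deg_counts, wald_de_test, write_de_table
from xslux.io_formats import read_count_matrix, read_sample_table
from xslux.synthetic import SimConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixture", type=Path, default=Path("results/fixture"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    samples = read_sample_table(args.fixture / "samples.tsv", for_de=True)
    species = SimConfig().species
    de = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sp in species:
            cm = read_count_matrix(
                args.fixture / f"counts_{sp}.tsv",
                args.fixture / f"lengths_{sp}.tsv",
                species_id=sp,
            )
            de[sp] = wald_de_test(cm, samples, alpha_sig=args.alpha)
            write_de_table(de[sp], args.out / f"de_{sp}.tsv")

    summary = summarize_deg_counts(de)
    summary.to_csv(args.out / "deg_summary.tsv", sep="\t")
    print("differentially expressed genes per species (HL vs LL):")
    print(summary.to_string())


if __name__ == "__main__":
    main()
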