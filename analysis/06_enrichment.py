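#!/usr/bin/env python
"""Over-representation analysis of focal-species-specific response genes.

Builds the study set from non-ambiguous core DE groups whose response is
up uniquely in the focal species, extracts the reference-species gene IDs,
and tests each term of the fixture's term map with a one-sided
hypergeometric test against the universe of reference-species genes that
received an adjusted P-value. Writes the enrichment table to results/.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from xslux.de_stats import read_de_table
from xslux.enrichment import fisher_ora
from xslux.homology_integration import select_species_specific_sets
from xslux.io_formats import read_homology_table, read_term_map
from xslux.synthetic import SimConfig


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixture", type=Path, default=Path("results/fixture"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    parser.add_argument("--reference", default="At")
    parser.add_argument("--min-term-size", type=int, default=5)
    args = parser.parse_args()

    cfg = SimConfig()
    focal = cfg.focal_species
    table = read_homology_table(args.fixture / "homology.tsv")
    cls = pd.read_csv(args.out / "hg_classification.tsv", sep="\t", index_col=0)
    de_ref = read_de_table(args.out / f"de_{args.reference}.tsv")

    nonamb = cls[
        (cls["membership"] == "core")
        & (cls["de_status"] == "DE")
        & (cls["ambiguity"] == "non_ambiguous")
    ]
    scores = nonamb[[f"score_{sp}" for sp in cfg.species]].rename(
        columns={f"score_{sp}": sp for sp in cfg.species}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        study = select_species_specific_sets(
            nonamb, scores, table, "up", [focal],
            reference_species=args.reference,
        )
        universe = set(de_ref.index[de_ref["padj"].notna()])
        terms = read_term_map(args.fixture / "terms.tsv")
        result = fisher_ora(
            study, universe, terms, min_term_size=args.min_term_size
        )
    result.to_csv(args.out / f"enrichment_{focal}_up.tsv", sep="\t", index=False)

    print(f"study set: {len(study)} {args.reference} genes from groups "
          f"up uniquely in {focal}; universe: {len(universe)} genes")
    print("top terms:")
    cols = ["term_id", "n_annotated_in_universe", "n_overlap", "pvalue", "padj"]
    print(result[cols].head(5).to_string(index=False))


if __name__ == "__main__":
    main()
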