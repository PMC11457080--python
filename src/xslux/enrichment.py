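"""Per-term over-representation analysis (one-sided Fisher / hypergeometric).

For a study set of size n drawn from a universe of size N, and a term
annotating K universe genes of which k are in the study set, the p-value is
the hypergeometric upper tail P(X >= k). Terms annotated to fewer than
``min_term_size`` genes (counted within the universe by default, optionally
within the study set) are excluded before testing; BH adjustment runs
across the surviving terms. Each term is tested independently (the
"classic" per-term test); any parent/ancestor propagation is input
preparation, not part of the test.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Set

import numpy as np
import pandas as pd
from scipy import stats

from .de_stats import adjust_bh
from .io_formats import TermMap

__all__ = ["fisher_ora"]


def fisher_ora(
    study: Iterable[str],
    universe: Iterable[str],
    terms: TermMap,
    min_term_size: int = 5,
    size_filter_scope: str = "universe",
) -> pd.DataFrame:
    """One-sided hypergeometric ORA of ``study`` against ``universe``.

    Study genes outside the universe are dropped with a warning; term gene
    sets are intersected with the universe before counting. Returns one row
    per surviving term with counts, odds ratio, p-value and BH-adjusted p,
    sorted by p-value.
    """
    universe_set: Set[str] = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    study_set: Set[str] = set(study)
    outside = study_set - universe_set
    if outside:
        warnings.warn(f"{len(outside)} study genes outside the universe; dropped")
        study_set &= universe_set

    N = len(universe_set)
    n = len(study_set)
    rows = []
    for term in terms.values():
        annotated = term.genes & universe_set
        K = len(annotated)
        k = len(annotated & study_set)
        size = K if size_filter_scope == "universe" else len(annotated & study_set)
        if size_filter_scope not in ("universe", "study"):
            raise ValueError(f"unknown size_filter_scope {size_filter_scope!r}")
        if size < min_term_size or K == 0:
            continue
        pvalue = float(stats.hypergeom.sf(k - 1, N, K, n))
        # sample odds ratio of the 2x2 table (inf when a margin is exhausted)
        a, b, c, d = k, n - k, K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.name,
                "n_annotated_in_universe": K,
                "n_study": n,
                "n_overlap": k,
                "odds_ratio": odds,
                "pvalue": min(pvalue, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "n_annotated_in_universe",
            "n_study",
            "n_overlap",
            "odds_ratio",
            "pvalue",
        ],
    )
    out["padj"] = adjust_bh(out["pvalue"].to_numpy()) if len(out) else np.nan
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)
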