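"""Integration of homology groups with per-species differential-expression calls.

A homology group (HG) clusters orthologs and paralogs across species. With
respect to a declared set of focal species, a group is *core* when every
focal species contributes at least one gene, *unique* when exactly one
does, and *accessory* otherwise. A group is *DE* when at least one of its
genes is differentially expressed in any species, and *ambiguous* when some
species contributes both a significantly up- and a significantly
down-regulated gene (ns/untested genes never create ambiguity).

For non-ambiguous core DE groups the per-species *response score*
``(n_up - n_down) / n_total`` lies in [-1, 1]; its sign pattern across
species assigns each group to one of seven exhaustive expression profiles
(up/down in all species, shared by 2-3 species, unique to one species, or
contrasting directions).
"""

from __future__ import annotations

import warnings
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .io_formats import HomologyTable

__all__ = [
    "classify_membership",
    "integrate_de_status",
    "response_score_matrix",
    "classify_profile",
    "assign_profiles",
    "profile_census",
    "select_species_specific_sets",
    "cluster_score_matrix",
    "PROFILE_CATEGORIES",
]

PROFILE_CATEGORIES = [
    "up_all",
    "down_all",
    "up_shared",
    "down_shared",
    "up_unique",
    "down_unique",
    "contrasting",
]


def classify_membership(
    table: HomologyTable, focal_species: Sequence[str]
) -> Tuple[pd.Series, int]:
    """Classify each group as core/accessory/unique relative to focal species.

    Groups containing no gene from any focal species are excluded; their
    count is returned alongside the per-group membership Series.
    """
    focal = set(focal_species)
    membership = {}
    n_excluded = 0
    for gid in table.group_ids:
        present = table.species_present(gid) & focal
        if not present:
            n_excluded += 1
        elif len(present) == len(focal):
            membership[gid] = "core"
        elif len(present) == 1:
            membership[gid] = "unique"
        else:
            membership[gid] = "accessory"
    return pd.Series(membership, name="membership"), n_excluded


def integrate_de_status(
    table: HomologyTable,
    de: Mapping[str, pd.DataFrame],
    focal_species: Sequence[str],
) -> pd.DataFrame:
    """Fill per-species up/down/total/untested counts, DE status and ambiguity.

    ``de`` maps species IDs to DE result tables (indexed by gene, with a
    ``call`` column). Genes present in the homology table but absent from
    their species' DE table are counted as untested; their total count is
    reported via a warning.
    """
    membership, _ = classify_membership(table, focal_species)
    calls: Dict[str, pd.Series] = {
        sp: de[sp]["call"].astype(str) for sp in focal_species if sp in de
    }
    rows = []
    n_missing = 0
    for gid in membership.index:
        row: Dict[str, object] = {"group_id": gid, "membership": membership[gid]}
        ambiguous = False
        any_de = False
        for sp in focal_species:
            genes = table.species_genes(gid, sp)
            n_up = n_down = n_untested = 0
            sp_calls = calls.get(sp)
            for gene in genes:
                call = "untested"
                if sp_calls is not None and gene in sp_calls.index:
                    call = sp_calls[gene]
                else:
                    n_missing += 1
                if call == "up":
                    n_up += 1
                elif call == "down":
                    n_down += 1
                elif call == "untested":
                    n_untested += 1
            row[f"n_up_{sp}"] = n_up
            row[f"n_down_{sp}"] = n_down
            row[f"n_total_{sp}"] = len(genes)
            row[f"n_untested_{sp}"] = n_untested
            if n_up and n_down:
                ambiguous = True
            if n_up or n_down:
                any_de = True
        row["de_status"] = "DE" if any_de else "nonDE"
        row["ambiguity"] = "ambiguous" if ambiguous else "non_ambiguous"
        rows.append(row)
    if n_missing:
        warnings.warn(
            f"{n_missing} homology-table genes absent from their DE table; "
            "counted as untested"
        )
    out = pd.DataFrame(rows).set_index("group_id")
    out.attrs["species"] = list(focal_species)
    return out


def response_score_matrix(
    cls: pd.DataFrame,
    species: Sequence[str] | None = None,
    include_untested_in_total: bool = True,
) -> pd.DataFrame:
    """Per-species response scores for non-ambiguous core DE groups.

    score = (n_up - n_down) / n_total, in [-1, 1]. Raises if any ambiguous
    group is passed. By default untested genes count in the denominator
    (the total number of gene models present in the group); set
    ``include_untested_in_total=False`` to exclude them.
    """
    if species is None:
        species = cls.attrs.get("species")
    if (cls["ambiguity"] == "ambiguous").any():
        bad = cls.index[cls["ambiguity"] == "ambiguous"][0]
        raise ValueError(f"ambiguous group {bad!r} passed to response scores")
    scores = {}
    for sp in species:
        total = cls[f"n_total_{sp}"].astype(float)
        if not include_untested_in_total:
            total = total - cls[f"n_untested_{sp}"]
        net = cls[f"n_up_{sp}"] - cls[f"n_down_{sp}"]
        with np.errstate(divide="ignore", invalid="ignore"):
            scores[sp] = np.where(total > 0, net / total, 0.0)
    return pd.DataFrame(scores, index=cls.index)


def classify_profile(signs: Iterable[int]) -> str:
    """Map per-species score signs (+1/-1/0) to a profile category."""
    signs = list(signs)
    n_pos = sum(s > 0 for s in signs)
    n_neg = sum(s < 0 for s in signs)
    if n_pos and n_neg:
        return "contrasting"
    if n_pos == len(signs):
        return "up_all"
    if n_neg == len(signs):
        return "down_all"
    if n_pos == 1 and n_neg == 0:
        return "up_unique"
    if n_neg == 1 and n_pos == 0:
        return "down_unique"
    if n_pos >= 2:
        return "up_shared"
    if n_neg >= 2:
        return "down_shared"
    return "null"  # no species responds


def assign_profiles(scores: pd.DataFrame) -> pd.Series:
    """Profile category per group from the sign pattern of its scores."""
    signs = np.sign(scores.to_numpy())
    return pd.Series(
        [classify_profile(row) for row in signs], index=scores.index, name="profile"
    )


def profile_census(profiles: pd.Series) -> pd.Series:
    """Counts per profile category; the partition sums to the input size."""
    counts = profiles.value_counts()
    out = counts.reindex(PROFILE_CATEGORIES, fill_value=0)
    extra = counts.drop(index=[c for c in PROFILE_CATEGORIES if c in counts.index])
    for cat, n in extra.items():
        out[cat] = n
    out.name = "n_groups"
    return out


def select_species_specific_sets(
    cls: pd.DataFrame,
    scores: pd.DataFrame,
    table: HomologyTable,
    direction: str,
    species_subset: Sequence[str],
    reference_species: str = "At",
    exclusive: bool = True,
) -> Set[str]:
    """Reference-species gene IDs from groups responding in a species subset.

    A group qualifies when its score sign matches ``direction`` ("up" or
    "down") for every species in ``species_subset``; with
    ``exclusive=True`` no species outside the subset may share that
    direction. Returns the union of the reference species' gene IDs over
    qualifying groups (empty selection yields an empty set with a warning).
    """
    want = 1 if direction == "up" else -1
    signs = np.sign(scores.to_numpy())
    species = list(scores.columns)
    inside = [species.index(sp) for sp in species_subset]
    outside = [i for i in range(len(species)) if i not in inside]
    sel = np.all(signs[:, inside] == want, axis=1)
    if exclusive and outside:
        sel &= np.all(signs[:, outside] != want, axis=1)
    genes: Set[str] = set()
    for gid in scores.index[sel]:
        genes.update(table.species_genes(gid, reference_species))
    if not genes:
        warnings.warn(
            f"empty selection for direction={direction!r}, subset={list(species_subset)}"
        )
    return genes


def cluster_score_matrix(scores: pd.DataFrame) -> pd.DataFrame:
    """Reorder score-matrix rows by hierarchical clustering (Euclidean,
    average linkage); provided for heatmap parity, ordering is cosmetic."""
    if len(scores) < 3:
        return scores
    order = leaves_list(average(pdist(scores.to_numpy(), metric="euclidean")))
    return scores.iloc[order]
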