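"""Cross-species abundance machinery: transcriptional baseline and expression modes.

TPM values are not directly comparable between species (library and
annotation composition differ), so a per-species-pair *transcriptional
baseline* is estimated from homology groups that are core, non-DE, contain
exactly one expressed ortholog per species, and exceed a minimum mean TPM:
for each ordered species pair (a, b) the vector of per-group
``log2(mean_tpm_a / mean_tpm_b)`` is summarized by its median (the
baseline offset) and by exceedance fractions at a caller-chosen threshold.
Cross-species ratios of genes of interest are then corrected by
subtracting the pair offset.

On top of the corrected ratios, each core group can be assigned one of
three expression modes with respect to a focal species:

* ``treatment_DE`` — the focal species has a significant up call under HL
  while no other species has any significant call;
* ``constitutive_high`` — a single-copy focal gene, not DE, whose corrected
  ratio against every other species exceeds a threshold under both
  treatments;
* ``cumulative_paralog`` — two or more focal copies whose *summed*
  abundance exceeds every other species by the same margin under both
  treatments.

Precedence when several fire: treatment_DE > cumulative_paralog >
constitutive_high.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .abundance import TPMMatrix
from .io_formats import HomologyTable, validate_sample_table

__all__ = [
    "BaselineModel",
    "ExpressionModeCall",
    "select_baseline_groups",
    "pairwise_log2_ratios",
    "exceedance_fraction",
    "baseline_offset",
    "corrected_ratio",
    "cumulative_paralog_abundance",
    "pool_fractions",
    "classify_expression_mode",
    "classify_all_modes",
]

MODES = ["treatment_DE", "constitutive_high", "cumulative_paralog", "none"]


def exceedance_fraction(ratios, threshold: float) -> float:
    """Empirical proportion of entries strictly greater than ``threshold``."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("empty ratio vector")
    return float((ratios > threshold).mean())


def baseline_offset(ratios) -> float:
    """Median of per-group log2 ratios (robust baseline summary)."""
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ValueError("empty ratio vector")
    return float(np.median(ratios))


@dataclass
class BaselineModel:
    """Per-species-pair log2-ratio vectors from single-copy non-DE core groups.

    Ratio vectors are stored for canonical ordered pairs (a before b in the
    declared species order); the reversed pair is the elementwise negation,
    so antisymmetry holds by construction.
    """

    species: Tuple[str, ...]
    group_ids: List[str]
    _ratios: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def pairs(self) -> List[Tuple[str, str]]:
        return list(itertools.permutations(self.species, 2))

    def ratios(self, a: str, b: str) -> np.ndarray:
        if (a, b) in self._ratios:
            return self._ratios[(a, b)]
        if (b, a) in self._ratios:
            return -self._ratios[(b, a)]
        raise KeyError(f"no ratio vector for pair ({a}, {b})")

    def offset(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return baseline_offset(self.ratios(a, b))

    def exceedance(self, a: str, b: str, threshold: float) -> float:
        return exceedance_fraction(self.ratios(a, b), threshold)

    def species_offsets(self) -> pd.Series:
        """Per-species offsets (mean of pairwise offsets, centered to sum 0)."""
        # average over all species including the zero self-pair: for centered
        # true offsets, mean_b(off_a - off_b) = off_a only when b ranges over
        # all K species
        vals = {
            a: np.mean([self.offset(a, b) if b != a else 0.0 for b in self.species])
            for a in self.species
        }
        out = pd.Series(vals, name="baseline_offset")
        return out - out.mean()

    def summary(self, threshold: float) -> pd.DataFrame:
        """One row per ordered pair: n_groups, offset, exceedance@threshold.

        The exceedance threshold must be supplied explicitly; reports never
        assume a default.
        """
        rows = [
            {
                "species_a": a,
                "species_b": b,
                "n_groups": self.n_groups,
                "offset": self.offset(a, b),
                f"exceedance_gt_{threshold:g}": self.exceedance(a, b, threshold),
            }
            for a, b in self.pairs()
        ]
        return pd.DataFrame(rows)


def select_baseline_groups(
    cls: pd.DataFrame,
    table: HomologyTable,
    mean_tpm_by_species: Mapping[str, pd.Series],
    min_tpm: float = 1.0,
) -> List[str]:
    """Groups usable for baseline estimation.

    Selected groups are core, non-DE, contain exactly one gene per species,
    and that gene's species-mean TPM is >= ``min_tpm`` ("expressed") in all
    species. Fewer than 50 qualifying groups triggers a warning (unstable
    baseline).
    """
    species = list(mean_tpm_by_species)
    candidates = cls[(cls["membership"] == "core") & (cls["de_status"] == "nonDE")]
    selected = []
    for gid in candidates.index:
        ok = True
        for sp in species:
            genes = table.species_genes(gid, sp)
            if len(genes) != 1:
                ok = False
                break
            mean = mean_tpm_by_species[sp].get(genes[0], 0.0)
            if mean < min_tpm:
                ok = False
                break
        if ok:
            selected.append(gid)
    if len(selected) < 50:
        warnings.warn(
            f"only {len(selected)} baseline groups selected; "
            "offset estimates may be unstable"
        )
    return selected


def pairwise_log2_ratios(
    groups: Sequence[str],
    table: HomologyTable,
    mean_tpm_by_species: Mapping[str, pd.Series],
) -> BaselineModel:
    """Per-pair log2 ratios of species-mean TPM over baseline groups.

    Groups with a zero mean in any species are dropped with a count
    (cannot occur when the selection used ``min_tpm > 0``).
    """
    species = tuple(mean_tpm_by_species)
    means = np.empty((len(groups), len(species)))
    for i, gid in enumerate(groups):
        for j, sp in enumerate(species):
            genes = table.species_genes(gid, sp)
            if len(genes) != 1:
                raise ValueError(f"group {gid!r} is not single-copy in {sp!r}")
            means[i, j] = mean_tpm_by_species[sp].get(genes[0], 0.0)
    keep = (means > 0).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} baseline groups with a zero mean")
    means = means[keep]
    kept_groups = [g for g, k in zip(groups, keep) if k]
    log2m = np.log2(means)
    model = BaselineModel(species=species, group_ids=kept_groups)
    for ia, ib in itertools.combinations(range(len(species)), 2):
        model._ratios[(species[ia], species[ib])] = log2m[:, ia] - log2m[:, ib]
    return model


def corrected_ratio(
    mean_a: float, mean_b: float, offset_ab: float, pseudo: float = 0.01
) -> float:
    """Baseline-corrected log2 abundance ratio between two species.

    ``log2((mean_a + pseudo) / (mean_b + pseudo)) - offset_ab``; the pseudo
    value guards logs of near-zero means.
    """
    return float(np.log2((mean_a + pseudo) / (mean_b + pseudo)) - offset_ab)


def cumulative_paralog_abundance(
    genes: Sequence[str],
    tpm_matrix: TPMMatrix,
    samples: pd.DataFrame,
) -> Dict[str, float]:
    """Per-treatment mean of the summed TPM over a species' group members.

    Per sample the paralog TPMs are summed first; the sums are then averaged
    within treatment, so the result for a single-copy group equals the
    gene's own treatment means.
    """
    if not genes:
        raise ValueError("no focal genes supplied")
    samples = validate_sample_table(samples)
    sub = samples[
        (samples["species_id"] == tpm_matrix.species_id)
        & samples["sample_id"].isin(tpm_matrix.sample_ids)
    ]
    summed = tpm_matrix.tpm.loc[list(genes)].sum(axis=0)
    out = {}
    for treatment, grp in sub.groupby("treatment", observed=True):
        out[treatment] = float(summed[list(grp["sample_id"])].mean())
    return out


def pool_fractions(
    groups: Sequence[str],
    species_id: str,
    treatment: str,
    table: HomologyTable,
    tpm_matrix: TPMMatrix,
    samples: pd.DataFrame,
) -> pd.Series:
    """Each group's share of the summed abundance of a gene-set "pool".

    Group abundance is the cumulative (summed-paralog) treatment mean;
    fractions sum to 1. An all-zero pool is an error.
    """
    if not groups:
        raise ValueError("empty gene set")
    abundances = {}
    for gid in groups:
        genes = table.species_genes(gid, species_id)
        abundances[gid] = (
            cumulative_paralog_abundance(genes, tpm_matrix, samples)[treatment]
            if genes
            else 0.0
        )
    series = pd.Series(abundances, name=f"fraction_{treatment}")
    total = series.sum()
    if total == 0:
        raise ValueError("all-zero transcript pool")
    return series / total


def _group_abundance_by_treatment(
    gid: str,
    species_id: str,
    table: HomologyTable,
    tpm_by_species: Mapping[str, TPMMatrix],
    samples: pd.DataFrame,
) -> Dict[str, float]:
    genes = table.species_genes(gid, species_id)
    return cumulative_paralog_abundance(genes, tpm_by_species[species_id], samples)


@dataclass
class ExpressionModeCall:
    """Mode assignment for one group/focal-species combination."""

    group_id: str
    focal_species: str
    mode: str
    evidence: Dict[str, object] = field(default_factory=dict)


def classify_expression_mode(
    gid: str,
    focal_species: str,
    de: Mapping[str, pd.DataFrame],
    baseline: BaselineModel,
    table: HomologyTable,
    tpm_by_species: Mapping[str, TPMMatrix],
    samples: pd.DataFrame,
    ratio_t: float = 1.0,
    pseudo: float = 0.01,
) -> ExpressionModeCall:
    """Assign a group one of the three expression modes (or ``none``)."""
    focal_genes = table.species_genes(gid, focal_species)
    if not focal_genes:
        raise ValueError(f"focal species {focal_species!r} absent from group {gid!r}")
    others = [sp for sp in baseline.species if sp != focal_species]

    def calls_for(sp: str) -> List[str]:
        calls = de[sp]["call"].astype(str)
        return [calls.get(g, "untested") for g in table.species_genes(gid, sp)]

    focal_calls = calls_for(focal_species)
    focal_up = "up" in focal_calls
    focal_sig = any(c in ("up", "down") for c in focal_calls)
    others_sig = any(
        c in ("up", "down") for sp in others for c in calls_for(sp)
    )

    abund = {
        sp: _group_abundance_by_treatment(gid, sp, table, tpm_by_species, samples)
        if table.species_genes(gid, sp)
        else {}
        for sp in baseline.species
    }
    treatments = sorted(abund[focal_species])
    ratios = {}
    dominant = True
    for sp in others:
        for trt in treatments:
            other_mean = abund[sp].get(trt, 0.0)
            r = corrected_ratio(
                abund[focal_species][trt],
                other_mean,
                baseline.offset(focal_species, sp),
                pseudo=pseudo,
            )
            ratios[(sp, trt)] = r
            if r <= ratio_t:
                dominant = False

    copy_number = len(focal_genes)
    if focal_up and not others_sig:
        mode = "treatment_DE"
    elif copy_number >= 2 and dominant:
        mode = "cumulative_paralog"
    elif copy_number == 1 and not focal_sig and dominant:
        mode = "constitutive_high"
    else:
        mode = "none"
    evidence = {
        "copy_number": copy_number,
        "focal_calls": focal_calls,
        "others_significant": others_sig,
        "corrected_ratios": ratios,
    }
    return ExpressionModeCall(gid, focal_species, mode, evidence)


def classify_all_modes(
    group_ids: Sequence[str],
    focal_species: str,
    de: Mapping[str, pd.DataFrame],
    baseline: BaselineModel,
    table: HomologyTable,
    tpm_by_species: Mapping[str, TPMMatrix],
    samples: pd.DataFrame,
    ratio_t: float = 1.0,
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Mode calls for many groups; returns group_id -> mode (+ copy number)."""
    rows = []
    for gid in group_ids:
        call = classify_expression_mode(
            gid, focal_species, de, baseline, table, tpm_by_species,
            samples, ratio_t=ratio_t, pseudo=pseudo,
        )
        rows.append(
            {
                "group_id": gid,
                "mode": call.mode,
                "copy_number": call.evidence["copy_number"],
            }
        )
    return pd.DataFrame(rows).set_index("group_id")
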