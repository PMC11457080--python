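"""TPM normalization and per-group abundance summaries.

TPM (transcripts per million) is the within-sample, length-normalized
abundance: ``rate_g = count_g / length_g``, ``tpm_g = rate_g / sum(rates)
* 1e6``, so every sample column sums to one million. Means over sample
groups are plain arithmetic means of raw TPM; log transforms (with explicit
pseudo-value handling) happen only downstream in the cross-species layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, validate_sample_table

__all__ = ["TPMMatrix", "tpm", "mean_tpm"]


@dataclass
class TPMMatrix:
    """TPM abundances for one species; columns sum to 1e6."""

    species_id: str
    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.tpm.to_numpy().sum(axis=0)
        if not np.allclose(sums, 1e6, rtol=1e-6):
            raise ValueError("TPM columns must sum to 1e6")

    @property
    def gene_ids(self) -> pd.Index:
        return self.tpm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.tpm.columns


def tpm(counts: CountMatrix) -> TPMMatrix:
    """Convert a count matrix (with gene lengths) to TPM."""
    values = counts.counts.to_numpy(dtype=float)
    rates = values / counts.gene_lengths.to_numpy(dtype=float)[:, None]
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        bad = counts.sample_ids[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    out = pd.DataFrame(
        rates / totals * 1e6, index=counts.gene_ids, columns=counts.sample_ids
    )
    return TPMMatrix(species_id=counts.species_id, tpm=out)


def mean_tpm(
    tpm_matrix: TPMMatrix, samples: pd.DataFrame, by: str = "species"
):
    """Per-gene arithmetic mean TPM over a sample grouping.

    ``by="species"`` pools both treatments and returns a Series;
    ``by="species_x_treatment"`` returns a DataFrame with one column per
    treatment present.
    """
    samples = validate_sample_table(samples)
    sub = samples[samples["sample_id"].isin(tpm_matrix.sample_ids)]
    sub = sub[sub["species_id"] == tpm_matrix.species_id]
    if sub.empty:
        raise ValueError(
            f"no samples for species {tpm_matrix.species_id!r} in the table"
        )
    if by == "species":
        return tpm_matrix.tpm[list(sub["sample_id"])].mean(axis=1)
    if by == "species_x_treatment":
        cols = {}
        for treatment, grp in sub.groupby("treatment", observed=True):
            cols[treatment] = tpm_matrix.tpm[list(grp["sample_id"])].mean(axis=1)
        return pd.DataFrame(cols)
    raise ValueError(f"unknown grouping key {by!r}")
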